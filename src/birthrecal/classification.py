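"""Size-for-gestational-age, low-birth-weight and gestational-age categories.

Classification is performed against a pluggable percentile *growth standard*:
a table keyed by (sex, gestational age in weeks) holding the 3rd, 10th, 50th
and 90th percentile weights in grams.  Cutoffs are linearly interpolated in
gestational age between tabulated points.  A birth weight below the 10th
percentile is small-for-gestational-age (SGA; below the 3rd: severe SGA),
above the 90th is large-for-gestational-age (LGA), and weights exactly at the
10th or 90th percentile count as appropriate-for-gestational-age (AGA) — the
AGA band is the closed interval [p10, p90].

The package does not ship any published standard (the extrapolated standard
used in the source setting is not publicly available); :func:`synthetic_standard`
builds a clearly-labelled synthetic stand-in adequate for simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrowthStandard",
    "synthetic_standard",
    "classify_size_for_ga",
    "classify_lbw",
    "ga_category",
    "SGA",
    "AGA",
    "LGA",
    "UNCLASSIFIABLE",
    "GA_BANDS_DEFAULT",
    "GA_BANDS_ALTERNATE",
]

SGA = "SGA"
AGA = "AGA"
LGA = "LGA"
UNCLASSIFIABLE = "unclassifiable"

#: Valid gestational-age range of a standard: 22+0 to 44+6 weeks.
GA_MIN = 22.0
GA_MAX = 44.0 + 6.0 / 7.0

_STANDARD_COLUMNS = ["sex", "ga_weeks", "p03", "p10", "p50", "p90"]
_PCT_COLS = ["p03", "p10", "p50", "p90"]


@dataclass
class GrowthStandard:
    """Percentile table for weight-for-gestational-age classification.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``sex`` ('male'/'female'), ``ga_weeks`` (fractional weeks),
        ``p03``, ``p10``, ``p50``, ``p90`` (grams).
    label : str
        Provenance label (e.g. ``"synthetic"``).
    """

    table: pd.DataFrame
    label: str = "unlabelled"
    ga_min: float = GA_MIN
    ga_max: float = GA_MAX
    _interp: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _STANDARD_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"standard table missing columns: {missing}")
        extra = [c for c in t.columns if c not in _STANDARD_COLUMNS]
        if extra:
            raise ValueError(f"standard table has unknown columns: {extra}")
        bad_sex = set(t["sex"].unique()) - {"male", "female"}
        if bad_sex:
            raise ValueError(f"standard table has unknown sex values: {bad_sex}")
        for sex, sub in t.groupby("sex"):
            sub = sub.sort_values("ga_weeks")
            vals = sub[_PCT_COLS].to_numpy(float)
            if not np.all(np.diff(vals, axis=1) > 0):
                raise ValueError(
                    f"percentiles not strictly increasing within a row (sex={sex})"
                )
            ga = sub["ga_weeks"].to_numpy(float)
            if np.any(np.diff(ga) <= 0):
                raise ValueError(f"duplicate/unsorted ga_weeks for sex={sex}")
            self._interp[sex] = (ga, vals)

    def cutoffs(self, sex, ga_weeks):
        """Interpolated (p03, p10, p50, p90) in grams; NaN rows out of range.

        ``sex`` and ``ga_weeks`` are broadcast array-likes; returns an
        (n, 4) array.
        """
        sex = np.asarray(sex, dtype=object)
        ga = np.asarray(ga_weeks, dtype=float)
        sex, ga = np.broadcast_arrays(sex, ga)
        out = np.full(sex.shape + (4,), np.nan)
        in_range = (ga >= self.ga_min) & (ga <= self.ga_max)
        for s, (grid, vals) in self._interp.items():
            mask = (sex == s) & in_range
            if not mask.any():
                continue
            for j in range(4):
                out[mask, j] = np.interp(ga[mask], grid, vals[:, j])
        return out

    def save(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path, label: str | None = None) -> "GrowthStandard":
        table = pd.read_csv(path, sep="\t")
        return cls(table=table, label=label or str(path))


def synthetic_standard(
    asymptote: float = 4650.0,
    rate: float = 0.1184,
    inflection_week: float = 31.0,
    female_factor: float = 0.955,
    cv: float = 0.125,
    step_weeks: float = 0.5,
) -> GrowthStandard:
    """SYNTHETIC weight-for-gestational-age standard (not a published reference).

    Median curve is a Gompertz function of gestational age,
    ``p50 = A * exp(-exp(-rate * (ga - inflection)))`` for males, scaled by
    ``female_factor`` for females; other percentiles assume a normal spread
    proportional to the median (coefficient of variation ``cv``), so
    ``p_q = p50 * (1 + z_q * cv)``.  Values are in the right range for a
    South-Asian birth cohort (male p50 ≈ 3.3 kg at 40 weeks) but carry no
    clinical authority; real analyses must supply a real standard table.
    """
    from scipy.stats import norm

    ga = np.arange(GA_MIN, 45.0 + 1e-9, step_weeks)
    ga = ga[ga <= GA_MAX + step_weeks]  # cover the full valid range
    ga[-1] = min(ga[-1], GA_MAX) if ga[-1] > GA_MAX else ga[-1]
    ga = np.unique(np.clip(ga, GA_MIN, GA_MAX))
    z = {q: norm.ppf(q) for q in (0.03, 0.10, 0.90)}
    rows = []
    for sex, factor in (("male", 1.0), ("female", female_factor)):
        p50 = asymptote * factor * np.exp(-np.exp(-rate * (ga - inflection_week)))
        rows.append(
            pd.DataFrame(
                {
                    "sex": sex,
                    "ga_weeks": ga,
                    "p03": p50 * (1 + z[0.03] * cv),
                    "p10": p50 * (1 + z[0.10] * cv),
                    "p50": p50,
                    "p90": p50 * (1 + z[0.90] * cv),
                }
            )
        )
    return GrowthStandard(pd.concat(rows, ignore_index=True), label="synthetic")


def classify_size_for_ga(weight, ga_weeks, sex, standard: GrowthStandard):
    """Classify birth weight against the standard.

    Returns ``(category, severe_sga)`` where ``category`` is an object array
    over {'SGA', 'AGA', 'LGA', 'unclassifiable'} and ``severe_sga`` a boolean
    array (weight below the 3rd percentile; implies SGA).  Gestational ages
    outside the standard's valid range yield 'unclassifiable', never a silent
    AGA.  Weights exactly at the 10th or 90th percentile are AGA (closed
    interval).
    """
    w = np.asarray(weight, dtype=float)
    cut = standard.cutoffs(sex, ga_weeks)
    w, _ = np.broadcast_arrays(w, cut[..., 0])
    category = np.full(w.shape, UNCLASSIFIABLE, dtype=object)
    ok = ~np.isnan(cut[..., 0]) & ~np.isnan(w) & (w > 0)
    p03, p10, _, p90 = (cut[..., j] for j in range(4))
    category[ok & (w < p10)] = SGA
    category[ok & (w >= p10) & (w <= p90)] = AGA
    category[ok & (w > p90)] = LGA
    severe = ok & (w < p03)
    return category, severe


def classify_lbw(weight):
    """Low (<2500 g) / very low (<1500 g) birth weight flags.

    Strict inequalities: exactly 2500 g is not LBW.  VLBW implies LBW.
    Returns ``(lbw, vlbw)`` boolean arrays; NaN weights are False in both.
    """
    w = np.asarray(weight, dtype=float)
    with np.errstate(invalid="ignore"):
        lbw = w < 2500.0
        vlbw = w < 1500.0
    return lbw, vlbw


# Gestational-age band schemes.  The default uses the descriptive bands
# (term covers ≥37 to <45); the alternate splits off post-term (42–45) and
# labels 28–32 weeks "very preterm", 24–27 "extremely preterm".
GA_BANDS_DEFAULT = "default"
GA_BANDS_ALTERNATE = "with_post_term"

_BANDS = {
    GA_BANDS_DEFAULT: [
        ("extremely preterm", 0.0, 28.0),
        ("early preterm", 28.0, 32.0),
        ("moderate-to-late preterm", 32.0, 37.0),
        ("term", 37.0, 45.0),
    ],
    GA_BANDS_ALTERNATE: [
        ("extremely preterm", 0.0, 28.0),
        ("very preterm", 28.0, 32.0),
        ("moderate-to-late preterm", 32.0, 37.0),
        ("term", 37.0, 42.0),
        ("post-term", 42.0, 45.0),
    ],
}


def ga_category(ga_weeks, scheme: str = GA_BANDS_DEFAULT):
    """Gestational-age band labels on half-open intervals [lo, hi).

    ``scheme='default'`` gives extremely preterm (<28), early preterm
    (≥28 to <32), moderate-to-late preterm (≥32 to <37), term (≥37 to <45);
    ``scheme='with_post_term'`` splits term at 42 weeks into term (37–42) and
    post-term (42–45) and renames the 28–32 band 'very preterm'.
    """
    if scheme not in _BANDS:
        raise ValueError(f"unknown GA band scheme: {scheme!r}")
    ga = np.asarray(ga_weeks, dtype=float)
    out = np.full(ga.shape, UNCLASSIFIABLE, dtype=object)
    for name, lo, hi in _BANDS[scheme]:
        out[(ga >= lo) & (ga < hi)] = name
    return out


def ga_band_names(scheme: str = GA_BANDS_DEFAULT):
    return [name for name, _, _ in _BANDS[scheme]]
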