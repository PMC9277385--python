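"""Pooling, prevalence and descriptive reporting across imputed datasets.

Prevalences (SGA/AGA/LGA, low and very low birth weight, gestational-age
bands, sex, neonatal mortality) are estimated within each completed dataset
with a Wald interval (Wilson available), then combined across the m
imputations with Rubin's rules: pooled point estimate q̄ = mean(q_k),
within-imputation variance W = mean(U_k), between-imputation variance
B = var(q_k), total T = W + (1 + 1/m)·B, and a t reference distribution
with ν = (m − 1)(1 + W/((1 + 1/m)B))² degrees of freedom.

The headline comparison table contrasts each indicator estimated from
measured weights taken within 72 h of delivery against the multiply-imputed
estimate, reporting the unsigned relative change in percent and the signed
absolute difference (imputed − measured).  Also provided: the neonatal
mortality rate per 1000 live births (lost-to-follow-up counted as
survivors by default), a digit-preference heaping index, and a descriptive
covariate summary in the shape of a cohort table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classification import (
    GA_BANDS_ALTERNATE,
    classify_lbw,
    classify_size_for_ga,
    ga_band_names,
    ga_category,
)

__all__ = [
    "PrevalenceEstimate",
    "rubin_pool",
    "prevalence",
    "mi_prevalence",
    "comparison_table",
    "nmr",
    "heaping_index",
    "describe_cohort",
]

_Z = stats.norm.ppf(0.975)


@dataclass
class PrevalenceEstimate:
    """Point estimate with CI on its reporting scale, plus MI components."""

    estimate: float
    lower: float
    upper: float
    n: int = 0
    numerator: int = 0
    scale: str = "percent"  # 'percent' | 'per1000' | 'raw'
    W: float = np.nan       # within-imputation variance (on the scale)
    B: float = np.nan       # between-imputation variance
    T: float = np.nan       # total variance
    df: float = np.inf
    degenerate: bool = False  # boundary estimate (0 or full), Wald CI collapses


def prevalence(flags, scale: str = "percent", method: str = "wald") -> PrevalenceEstimate:
    """Proportion of true flags with a 95% CI on the chosen scale.

    ``scale`` is 'percent' (×100), 'per1000' (×1000) or 'raw'.  The default
    Wald interval matches tight large-sample CIs; Wilson is available for
    small samples or boundary proportions.  Boundary estimates (0% or 100%)
    under Wald yield a degenerate zero-width CI and are flagged.
    """
    flags = np.asarray(flags, dtype=bool)
    n = flags.size
    if n == 0:
        raise ValueError("no observations")
    k = int(flags.sum())
    p = k / n
    mult = {"percent": 100.0, "per1000": 1000.0, "raw": 1.0}[scale]
    if method == "wald":
        se = np.sqrt(p * (1.0 - p) / n)
        lo, hi = p - _Z * se, p + _Z * se
    elif method == "wilson":
        lo, hi = _wilson(p, n)
    else:
        raise ValueError(f"unknown CI method: {method!r}")
    var = p * (1.0 - p) / n * mult**2
    return PrevalenceEstimate(
        estimate=p * mult, lower=max(lo, 0.0) * mult, upper=min(hi, 1.0) * mult,
        n=n, numerator=k, scale=scale, W=var, T=var,
        degenerate=(k == 0 or k == n) and method == "wald",
    )


def _wilson(p: float, n: int) -> tuple[float, float]:
    z2 = _Z**2
    denom = 1.0 + z2 / n
    center = (p + z2 / (2 * n)) / denom
    half = _Z * np.sqrt(p * (1 - p) / n + z2 / (4 * n**2)) / denom
    return center - half, center + half


def rubin_pool(point_estimates, variances, scale: str = "raw") -> PrevalenceEstimate:
    """Combine m estimates and their variances with Rubin's rules.

    With all estimates identical (B = 0) or m = 1 the pooled CI collapses to
    the single-imputation normal interval.
    """
    q = np.asarray(point_estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = q.size
    if m == 0:
        raise ValueError("need at least one imputation")
    if np.any(u < 0):
        raise ValueError("variances must be non-negative")
    qbar = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1)) if m > 1 else 0.0
    T = W + (1.0 + 1.0 / m) * B
    if m > 1 and B > 0 and W >= 0:
        df = (m - 1) * (1.0 + W / ((1.0 + 1.0 / m) * B)) ** 2
        crit = stats.t.ppf(0.975, df)
    else:
        df = np.inf
        crit = _Z
    half = crit * np.sqrt(T)
    return PrevalenceEstimate(
        estimate=qbar, lower=qbar - half, upper=qbar + half,
        n=0, scale=scale, W=W, B=B, T=T, df=df,
    )


def mi_prevalence(flag_sets, scale: str = "percent",
                  method: str = "wald") -> PrevalenceEstimate:
    """Prevalence pooled over m imputed datasets (Rubin's rules)."""
    singles = [prevalence(f, scale=scale, method=method) for f in flag_sets]
    pooled = rubin_pool([s.estimate for s in singles], [s.W for s in singles],
                        scale=scale)
    pooled.n = singles[0].n
    return pooled


def nmr(df: pd.DataFrame, ltfu_as_alive: bool = True) -> PrevalenceEstimate:
    """Neonatal mortality rate: deaths within 28 days per 1000 live births.

    Lost-to-follow-up births count as survivors by default (the reference
    category of the survival definition); set ``ltfu_as_alive=False`` to
    drop them from the denominator instead.
    """
    surv = df["survival"]
    if not ltfu_as_alive:
        df = df.loc[surv != "lost"]
        surv = df["survival"]
    known = surv.notna()
    if not known.any():
        raise ValueError("no live births with known survival status")
    died = (surv[known] == "dead").to_numpy()
    return prevalence(died, scale="per1000")


def heaping_index(weights, target: float = 4500.0, band: float = 250.0) -> float:
    """Digit-preference heaping: % exactly at ``target`` among weights within
    ``target ± band`` grams.  Returns NaN when no weight falls in the band.
    """
    if band <= 0:
        raise ValueError("band must be positive")
    w = np.asarray(weights, dtype=float)
    w = w[~np.isnan(w)]
    in_band = (w >= target - band) & (w <= target + band)
    denom = int(in_band.sum())
    if denom == 0:
        return np.nan
    return 100.0 * float((w[in_band] == target).sum()) / denom


def relative_change(measured: float, imputed: float) -> float:
    """Unsigned relative change in percent: 100·|imputed − measured|/measured.

    Undefined (NaN) when the measured estimate is zero.
    """
    if measured == 0:
        return np.nan
    return 100.0 * abs(imputed - measured) / measured


# ---------------------------------------------------------------------------
# indicator machinery for the comparison table


def _indicator_flags(df: pd.DataFrame, weight_col: str, standard,
                     ga_scheme: str) -> dict[str, np.ndarray]:
    """Boolean indicator arrays for one completed dataset."""
    w = df[weight_col].to_numpy(dtype=float)
    ok_w = ~np.isnan(w)
    lbw, vlbw = classify_lbw(w)
    flags: dict[str, np.ndarray] = {}
    flags["Low birth weight (<2500 g)"] = lbw[ok_w]
    flags["Very low birth weight (<1500 g)"] = vlbw[ok_w]
    sex = df["sex"].to_numpy(dtype=object)
    cat, _ = classify_size_for_ga(w, df["ga_weeks"].to_numpy(), sex, standard)
    classifiable = ok_w & (cat != "unclassifiable")
    for name, lab in (("Appropriate-for-gestational age", "AGA"),
                      ("Small-for-gestational age", "SGA"),
                      ("Large-for-gestational age", "LGA")):
        flags[name] = (cat[classifiable] == lab)
    bands = ga_category(df["ga_weeks"].to_numpy(), scheme=ga_scheme)
    band_ok = bands != "unclassifiable"
    for name in ga_band_names(ga_scheme):
        flags[f"GA band: {name}"] = (bands[band_ok] == name)
    known_sex = pd.notna(df["sex"]).to_numpy()
    flags["Female"] = (sex[known_sex] == "female")
    flags["Male"] = (sex[known_sex] == "male")
    return flags


_PER1000 = ("Neonatal mortality rate (per 1000)",)


def comparison_table(
    cohort: pd.DataFrame,
    imputed_datasets: list[pd.DataFrame],
    standard,
    ga_scheme: str = GA_BANDS_ALTERNATE,
    measured_max_hours: float = 72.0,
    ci_method: str = "wald",
) -> pd.DataFrame:
    """Measured-within-72h vs multiply-imputed estimates per indicator.

    The measured arm restricts to births with a weight taken before
    ``measured_max_hours``; the imputed arm pools all m completed datasets
    with Rubin's rules.  Relative change is unsigned, absolute difference is
    signed (imputed − measured); ``*_display`` columns round at 1 decimal.
    """
    measured = cohort.loc[
        cohort["weight"].notna() & (cohort["t_hours"] < measured_max_hours)
    ]
    if len(measured) == 0:
        raise ValueError("measured arm is empty")
    if len(imputed_datasets) == 0:
        raise ValueError("imputed arm is empty")
    m_flags = _indicator_flags(measured, "weight", standard, ga_scheme)
    imp_flags = [
        _indicator_flags(d.loc[d["birth_weight_imputed"].notna()],
                         "birth_weight_imputed", standard, ga_scheme)
        for d in imputed_datasets
    ]
    rows = []
    for name in m_flags:
        meas = prevalence(m_flags[name], scale="percent", method=ci_method)
        imp = mi_prevalence([f[name] for f in imp_flags], scale="percent",
                            method=ci_method)
        rows.append(_comparison_row(name, meas, imp))
    # neonatal mortality rate, per 1000
    meas_nmr = nmr(measured)
    imp_nmrs = [nmr(d.loc[d["birth_weight_imputed"].notna()])
                for d in imputed_datasets]
    imp_nmr = rubin_pool([e.estimate for e in imp_nmrs],
                         [e.W for e in imp_nmrs], scale="per1000")
    rows.append(_comparison_row("Neonatal mortality rate (per 1000)",
                                meas_nmr, imp_nmr))
    # mean birth weight by survival status
    for status, label in (("alive", "Mean weight (g), survived"),
                          ("dead", "Mean weight (g), neonatal death")):
        sel = measured["survival"] == status if status == "dead" else (
            measured["survival"] != "dead")
        mw = measured.loc[sel & measured["weight"].notna(), "weight"]
        if len(mw) == 0:
            continue
        meas = _mean_estimate(mw)
        imp_means = []
        for d in imputed_datasets:
            sel_d = (d["survival"] == "dead") if status == "dead" else (
                d["survival"] != "dead")
            vals = d.loc[sel_d & d["weight"].notna(), "birth_weight_imputed"].dropna()
            imp_means.append(_mean_estimate(vals))
        imp = rubin_pool([e.estimate for e in imp_means],
                         [e.W for e in imp_means], scale="raw")
        rows.append(_comparison_row(label, meas, imp))
    return pd.DataFrame(rows)


def _mean_estimate(values: pd.Series) -> PrevalenceEstimate:
    x = np.asarray(values, dtype=float)
    mean = float(x.mean())
    var = float(x.var(ddof=1) / x.size) if x.size > 1 else 0.0
    half = _Z * np.sqrt(var)
    return PrevalenceEstimate(estimate=mean, lower=mean - half, upper=mean + half,
                              n=x.size, scale="raw", W=var, T=var)


def _comparison_row(name: str, measured: PrevalenceEstimate,
                    imputed: PrevalenceEstimate) -> dict:
    rel = relative_change(measured.estimate, imputed.estimate)
    diff = imputed.estimate - measured.estimate
    return {
        "indicator": name,
        "measured": measured.estimate,
        "measured_lower": measured.lower,
        "measured_upper": measured.upper,
        "imputed": imputed.estimate,
        "imputed_lower": imputed.lower,
        "imputed_upper": imputed.upper,
        "relative_change_pct": rel,
        "absolute_difference": diff,
        "relative_change_display": round(rel, 1),
        "absolute_difference_display": round(diff, 1),
    }


# ---------------------------------------------------------------------------
# descriptive covariate summary

_TIMING_BANDS = [("0-5 h", 0.0, 6.0), ("6-23 h", 6.0, 24.0),
                 ("24-72 h", 24.0, 72.0 + 1e-12), (">72 h", 72.0, np.inf)]


def describe_cohort(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Descriptive frequency tables (percent and n) plus continuous medians.

    Categorical blocks: maternal age bands, education bands, parity,
    gestational-age bands, sex, multiples, survival, missing weight, and the
    timing of the weight measurement in bands 0–5, 6–23, 24–72 and >72 h
    (the 24–72 band is closed at 72.0: a measurement at exactly 72 h falls
    in it).  Empty categories are retained as 0 (0) rows.
    """
    n = len(df)
    out: dict[str, pd.DataFrame] = {}

    def freq(name: str, labels, values):
        counts = pd.Series(values).value_counts()
        rows = [
            {"category": lab, "percent": 100.0 * counts.get(lab, 0) / n,
             "n": int(counts.get(lab, 0))}
            for lab in labels
        ]
        n_missing = int(pd.isna(pd.Series(values)).sum())
        rows.append({"category": "missing", "percent": 100.0 * n_missing / n,
                     "n": n_missing})
        out[name] = pd.DataFrame(rows)

    age = pd.cut(df["mat_age"], bins=[0, 18, 35, 200], right=False,
                 labels=["<18", "18-35", ">35"])
    freq("maternal_age", ["<18", "18-35", ">35"], age)

    edu = pd.cut(df["mat_edu"], bins=[-0.5, 0.5, 5.5, 100],
                 labels=["no school", "1-5 years", ">5 years"])
    freq("maternal_education", ["no school", "1-5 years", ">5 years"], edu)

    parity = df["parity"].map(
        lambda p: np.nan if pd.isna(p) else ("4+" if p >= 4 else str(int(p)))
    )
    freq("parity", ["0", "1", "2", "3", "4+"], parity)

    bands = ga_category(df["ga_weeks"].to_numpy())
    freq("gestational_age", ga_band_names(), pd.Series(bands))

    freq("infant_sex", ["female", "male"], df["sex"])
    if "multiple" in df.columns:
        mult = df["multiple"].map({0.0: "singleton", 1.0: "twin/triplet"})
        freq("multiple_births", ["singleton", "twin/triplet"], mult)
    if "survival" in df.columns:
        freq("survival", ["alive", "lost", "dead"], df["survival"])

    if "weight" in df.columns:
        missing_w = df["weight"].isna().map({False: "measured", True: "not measured"})
        freq("birth_weight_missing", ["measured", "not measured"], missing_w)
        timed = df.loc[df["weight"].notna() & df["t_hours"].notna()]
        n_t = len(timed)
        rows = []
        for lab, lo, hi in _TIMING_BANDS:
            if lab == "24-72 h":
                mask = (timed["t_hours"] >= lo) & (timed["t_hours"] <= 72.0)
            elif lab == ">72 h":
                mask = timed["t_hours"] > 72.0
            else:
                mask = (timed["t_hours"] >= lo) & (timed["t_hours"] < hi)
            k = int(mask.sum())
            rows.append({"category": lab,
                         "percent": 100.0 * k / n_t if n_t else np.nan, "n": k})
        out["measurement_timing"] = pd.DataFrame(rows)

    cont_rows = []
    for col, label in (("ga_weeks", "gestational age (weeks)"),
                       ("mat_age", "maternal age (years)"),
                       ("weight", "measured weight (g)")):
        if col in df.columns:
            x = df[col].dropna()
            if len(x):
                q1, med, q3 = np.percentile(x, [25, 50, 75])
                cont_rows.append({"quantity": label, "median": med,
                                  "q1": q1, "q3": q3})
    out["continuous"] = pd.DataFrame(cont_rows)
    return out
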