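"""Basic diagnostic plots (matplotlib imported lazily)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_km_return(km: pd.DataFrame, ax=None):
    """Step plot of P(not yet returned to birth weight) with its 95% band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.step(km["time"], km["estimate"], where="post", color="C0")
    ax.fill_between(km["time"], km["lower"], km["upper"], step="post",
                    alpha=0.2, color="C0")
    ax.set_xlabel("days since delivery")
    ax.set_ylabel("P(not yet returned to birth weight)")
    ax.set_ylim(0, 1.02)
    return ax


def plot_recalibration_by_timing(recal: pd.DataFrame, ax=None):
    """Measured vs recalibrated weight against measurement age in days."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.clip(recal["t_days"], 0, None)
    ax.scatter(t, recal["w_it"], s=4, alpha=0.3, label="measured")
    ax.scatter(t, recal["w_tilde_i0"], s=4, alpha=0.3, label="recalibrated")
    ax.set_xscale("symlog", linthresh=1.0)
    ax.set_xlabel("age at measurement (days)")
    ax.set_ylabel("weight (g)")
    ax.legend()
    return ax
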