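"""Forest-plot writer for estimator comparisons (courtesy utility).

Requires matplotlib (install the ``plots`` extra); everything else in
the package works without it.
"""
from __future__ import annotations

import numpy as np
import pandas as pd


def forest_plot(summary: pd.DataFrame, truth: float | None = None,
                contrast: str | None = None, ax=None):
    """Draw point estimates and 95% CIs per estimator on the IRR scale.

    ``summary`` is a :class:`~threephase.simulate.StudyReport` summary
    table (or any frame with ``estimator``, ``mean_log_irr``,
    ``mean_se`` columns); ``truth`` adds a reference line.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    df = summary
    if contrast is not None:
        df = df[df["contrast"] == contrast]
    df = df.dropna(subset=["mean_log_irr"]).reset_index(drop=True)
    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 0.5 * len(df) + 1.5))
    y = np.arange(len(df))[::-1]
    est = np.exp(df["mean_log_irr"])
    lo = np.exp(df["mean_log_irr"] - 1.96 * df["mean_se"])
    hi = np.exp(df["mean_log_irr"] + 1.96 * df["mean_se"])
    ax.hlines(y, lo, hi, color="0.3")
    ax.plot(est, y, "s", color="0.1")
    if truth is not None:
        ax.axvline(np.exp(truth), color="firebrick", ls="--", lw=1,
                   label="truth")
        ax.legend(frameon=False)
    ax.set_xscale("log")
    ax.set_yticks(y)
    ax.set_yticklabels(df["estimator"])
    ax.set_xlabel("incidence rate ratio (95% CI)")
    ax.figure.tight_layout()
    return ax
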