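"""Diagnostic line plots: fitted vital-rate curves with credible bands.

Thin matplotlib helpers; nothing here is required by the numerical
pipeline.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .fertility import ProjectedTrajectories, TFRSeries
from .mortality import E0Series

__all__ = ["plot_fit_band", "plot_projection_fan"]


def plot_fit_band(
    observed: TFRSeries | E0Series,
    projected: ProjectedTrajectories,
    *,
    ylabel: str = "rate",
    ax=None,
):
    """Observed points, posterior-median curve and 95% band."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    s = projected.summary
    ax.plot(s["year"], s["median"], color="C0", label="posterior median")
    ax.fill_between(
        s["year"], s["q2.5"], s["q97.5"], color="C0", alpha=0.25, label="95% interval"
    )
    ax.plot(observed.years, observed.values, "ko", ms=4, label="observed")
    ax.set_xlabel("year")
    ax.set_ylabel(ylabel)
    ax.legend()
    return ax


def plot_projection_fan(result, *, sex: str = "male", ax=None):
    """Total projected population per year with 95% band for one sex."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    s_idx = {"male": 0, "female": 1}[sex]
    totals = result.draws[:, :, s_idx, :].sum(axis=2)  # (n_draws, n_years)
    q = np.percentile(totals, [2.5, 50.0, 97.5], axis=0)
    ax.plot(result.years, q[1], color="C1", label=f"{sex} median")
    ax.fill_between(result.years, q[0], q[2], color="C1", alpha=0.25, label="95% interval")
    ax.set_xlabel("year")
    ax.set_ylabel("population (thousands)")
    ax.legend()
    return ax
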