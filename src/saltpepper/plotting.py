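"""Summary figure: tuning similarity versus cortical distance."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .clustering import ExponentialDecayFit, SimilarityCurve

__all__ = ["plot_similarity_curve"]


def plot_similarity_curve(
    curve: SimilarityCurve,
    fit: ExponentialDecayFit | None = None,
    path=None,
    ax=None,
):
    """Binned mean similarity with s.e.m. bars and the exponential fit.

    Marker size scales with the significance of each bin's rank-sum test
    against the farthest bin.  Returns the axes; writes a PNG if ``path``
    is given.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 3.2))
    x = curve.bin_centers_um
    ok = np.isfinite(curve.mean)
    p = np.where(np.isfinite(curve.ranksum_p_vs_last), curve.ranksum_p_vs_last, 1.0)
    size = 20 + 60 * np.clip(-np.log10(np.maximum(p, 1e-10)) / 10, 0, 1)
    ax.errorbar(x[ok], curve.mean[ok], yerr=curve.sem[ok], fmt="none",
                ecolor="0.4", capsize=2, zorder=1)
    ax.scatter(x[ok], curve.mean[ok], s=size[ok], color="k", zorder=2)
    if fit is not None and fit.identifiable:
        d = np.linspace(x[ok].min(), x[ok].max(), 200)
        lo, hi = fit.ci95_lambda_um
        ax.plot(d, fit(d), "r--", zorder=3,
                label=(rf"$\lambda$ = {fit.length_constant_um:.0f} $\mu$m "
                       rf"(95% CI {lo:.0f}-{hi:.0f})"))
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel(r"cortical distance ($\mu$m)")
    ax.set_ylabel("tuning similarity")
    ax.spines[["top", "right"]].set_visible(False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
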