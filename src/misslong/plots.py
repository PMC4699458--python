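"""Diagnostic plots: missingness map, overimputation, concordance."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_missingness_map(mm: dict, ax=None):
    """Heatmap of the subject-visit × variable missingness mask."""
    ax = ax or plt.gca()
    M = mm["matrix"].to_numpy()
    ax.imshow(M, aspect="auto", cmap="Greys", interpolation="nearest")
    ax.set_xticks(range(M.shape[1]))
    ax.set_xticklabels(mm["matrix"].columns, rotation=90, fontsize=6)
    ax.set_ylabel("subject-visit record")
    ax.set_title("Missingness map (dark = missing)")
    return ax


def plot_overimputation(report, ax=None):
    """Observed values vs mean re-imputations with 90% intervals."""
    ax = ax or plt.gca()
    order = np.argsort(report.observed)
    x = report.observed[order]
    ax.errorbar(x, report.mean_imputation[order],
                yerr=[report.mean_imputation[order] - report.lower[order],
                      report.upper[order] - report.mean_imputation[order]],
                fmt="o", ms=3, lw=0.8, alpha=0.7)
    lim = [min(x.min(), report.lower.min()), max(x.max(), report.upper.max())]
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel(f"observed {report.variable}")
    ax.set_ylabel("re-imputed (90% interval)")
    ax.set_title(f"Overimputation: coverage {report.coverage:.2f}")
    return ax


def plot_concordance(a, b, result, labels=("method A", "method B"), ax=None):
    """Scatter of estimate vectors with the fitted Pearson regression line."""
    ax = ax or plt.gca()
    a, b = np.asarray(a, float), np.asarray(b, float)
    ax.scatter(a, b, s=20)
    xs = np.linspace(a.min(), a.max(), 50)
    ax.plot(xs, result.intercept + result.slope * xs, "r-", lw=1)
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    ax.set_title(f"slope={result.slope:.2f}, R$^2$={result.r2:.2f}, "
                 f"p={result.p_value:.2g}")
    return ax
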