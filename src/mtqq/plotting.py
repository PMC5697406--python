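"""Figure helpers for the cohort summaries.

Each function draws onto a provided matplotlib Axes (or creates one) and
returns it, so figures compose the usual way.
"""

from __future__ import annotations

import numpy as np

from .calling import DEFAULT_MAF_BIN_LABELS, HeteroplasmyCall, maf_spectrum

__all__ = ["plot_maf_spectrum", "plot_copy_number_vs_age", "plot_score_cdf"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_maf_spectrum(calls: list[HeteroplasmyCall], ax=None):
    """Histogram of heteroplasmy minor-allele fractions with the report-bin
    proportions in the title."""
    ax = _axes(ax)
    mafs = [c.maf for c in calls]
    ax.hist(mafs, bins=np.arange(0.02, 0.52, 0.02), edgecolor="white")
    props = 100 * maf_spectrum(calls)
    ax.set_xlabel("minor allele fraction")
    ax.set_ylabel("heteroplasmies")
    ax.set_title(
        ", ".join(f"{lab}: {p:.1f}%" for lab, p in zip(DEFAULT_MAF_BIN_LABELS, props))
    )
    return ax


def plot_copy_number_vs_age(ages, copy_numbers, model=None, ax=None):
    """Scatter of copy number against age with the fitted regression line
    (pass the 'cn_vs_age' RegressionResult)."""
    ax = _axes(ax)
    ages = np.asarray(ages, dtype=float)
    ax.scatter(ages, np.asarray(copy_numbers, dtype=float), s=8, alpha=0.5)
    if model is not None:
        xs = np.linspace(ages.min(), ages.max(), 50)
        intercept = model["const"]["estimate"]
        slope = model["age"]["estimate"]
        ax.plot(xs, intercept + slope * xs, lw=2)
        ax.set_title(f"slope {slope:.3f} copies/yr (p={model['age']['p']:.2g})")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("mtDNA copy number")
    return ax


def plot_score_cdf(groups: dict[str, list[float]], ax=None):
    """Cumulative pathogenicity-score distributions for named variant groups
    (e.g. disease-associated, low-MAF het, high-MAF het, homoplasmy)."""
    ax = _axes(ax)
    for label, scores in groups.items():
        xs = np.sort(np.asarray(scores, dtype=float))
        if xs.size == 0:
            continue
        ax.step(xs, np.arange(1, xs.size + 1) / xs.size, where="post", label=label)
    ax.set_xlabel("scaled pathogenicity score")
    ax.set_ylabel("cumulative fraction")
    ax.legend()
    return ax
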