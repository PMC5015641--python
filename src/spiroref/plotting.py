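"""Simple report figures: prevalence by age and severity distributions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_prevalence_by_age", "plot_severity_distribution"]


def plot_prevalence_by_age(tables: dict[str, pd.DataFrame], sex: str = "all",
                           ax=None):
    """Prevalence (%) across age strata, one line per equation set.

    ``tables`` maps an equation-set label to a prevalence table from
    :func:`spiroref.cohort.prevalence`.  Points computed outside a set's
    valid age range (any extrapolated subjects in the stratum) are drawn
    with a dashed line.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, table in tables.items():
        sub = table[(table["sex"] == sex)
                    & (table["age_stratum"] != "all")].reset_index(drop=True)
        extrap = sub["n_extrapolated"] > 0
        ax.plot(sub["age_stratum"], sub["prevalence"], marker="o", label=label,
                linestyle="--" if extrap.any() else "-")
    ax.set_xlabel("age stratum (years)")
    ax.set_ylabel("prevalence (%)")
    ax.legend()
    return ax


def plot_severity_distribution(dists: dict[str, pd.DataFrame],
                               sex: str = "male", ax=None):
    """Grouped bars of severity-grade proportions, one group per grade."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    labels = list(dists)
    grades = dists[labels[0]]["grade"].unique()
    width = 0.8 / len(labels)
    for i, label in enumerate(labels):
        sub = dists[label]
        sub = sub[sub["sex"] == sex].set_index("grade").loc[grades]
        ax.bar([g + i * width for g in range(len(grades))],
               100 * sub["proportion"], width=width, label=label)
    ax.set_xticks([g + 0.4 - width / 2 for g in range(len(grades))])
    ax.set_xticklabels(grades, rotation=30, ha="right")
    ax.set_ylabel("share of subjects (%)")
    ax.legend()
    return ax
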