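"""Optional figures: AF concordance scatter, population PCA, RMSD bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .simulate import ReferencePanel
from .spectrum import PopulationDistance


def plot_af_scatter(cohort_af: pd.Series, panel: ReferencePanel, population: str,
                    path=None):
    joint = panel.afs.index.intersection(cohort_af.dropna().index)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(panel.afs.loc[joint, population], cohort_af.loc[joint],
               s=4, alpha=0.3, edgecolors="none")
    ax.plot([0, 1], [0, 1], lw=0.8, color="grey")
    ax.set_xlabel(f"{population} allele frequency")
    ax.set_ylabel("cohort allele frequency")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_pca(coords: pd.DataFrame, path=None):
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(coords["PC1"], coords["PC2"], s=30)
    for label, row in coords.iterrows():
        ax.annotate(label, (row["PC1"], row["PC2"]), fontsize=8,
                    xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_rmsd(distances: list[PopulationDistance], path=None):
    fig, ax = plt.subplots(figsize=(4, 3))
    pops = [d.population for d in distances]
    vals = [d.rmsd for d in distances]
    err_lo = [d.rmsd - d.ci_lower for d in distances]
    err_hi = [d.ci_upper - d.rmsd for d in distances]
    ax.bar(pops, vals, yerr=[err_lo, err_hi], capsize=3)
    ax.set_ylabel("AF RMSD vs cohort")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
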