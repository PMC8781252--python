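"""Figure rendering: coverage track plot and delta-PTM correlation boxplots."""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .peptide_model import ReferenceProtein
from .ptm_consolidation import VariantPairObservation
from .sequence_mapping import LocatedPeptide

__all__ = ["render_coverage_figure", "render_delta_ptm_figure"]

CLASS_COLORS = {
    "strong_pos": "#2ca02c",          # green
    "strong_neg": "#d62728",          # red
    "significant_moderate": "#7f7f7f",
    "not_significant": "#c7c7c7",
}


def render_coverage_figure(located: Sequence[LocatedPeptide],
                           classes: Mapping[str, str],
                           reference: ReferenceProtein,
                           path: str | Path,
                           abundances: Mapping[str, float] | None = None,
                           ) -> None:
    """Peptide tracks along the precursor, coloured by association class.

    Tracks are ordered by start coordinate; an optional right-hand bar per
    track shows relative total abundance.  Writes SVG and/or PNG according
    to the suffix of ``path`` (both when the suffix is omitted).
    """
    ordered = sorted(located, key=lambda p: (p.start, p.stop, p.unmod_seq))
    L = len(reference)
    n = max(len(ordered), 1)
    fig, ax = plt.subplots(figsize=(10, max(2.0, 0.09 * n + 1.2)))
    for y, pep in enumerate(ordered):
        color = CLASS_COLORS.get(classes.get(pep.unmod_seq, "not_significant"),
                                 "#c7c7c7")
        ax.hlines(n - y, pep.start, pep.stop, color=color, lw=2)
    if abundances and ordered:
        amax = max(abundances.get(p.unmod_seq, 0.0) for p in ordered) or 1.0
        for y, pep in enumerate(ordered):
            w = 0.06 * L * abundances.get(pep.unmod_seq, 0.0) / amax
            ax.barh(n - y, w, left=L * 1.02, height=0.8,
                    color="#ff7f0e", edgecolor="none")
    for name, a, b in reference.regions:
        ax.axvspan(a, b, ymin=0, ymax=0.02, alpha=0.3)
        ax.text((a + b) / 2, -0.02 * n - 1, name, ha="center", va="top",
                fontsize=7)
    ax.set_xlim(0, L * (1.1 if abundances else 1.02))
    ax.set_ylim(-0.05 * n - 2, n + 1)
    ax.set_xlabel("precursor residue (1-based)")
    ax.set_yticks([])
    ax.set_title(f"{len(ordered)} peptides on {reference.accession}")
    _save(fig, Path(path))


def render_delta_ptm_figure(observations: Sequence[VariantPairObservation],
                            path: str | Path,
                            merge_threshold: float = 0.5) -> None:
    """Boxplots of inter-variant Spearman rho per hydroxyproline difference.

    Individual pairs are overplotted, coloured by whether they reach the
    merge threshold (drawn as a horizontal line).
    """
    if not observations:
        raise ValueError("no variant-pair observations to plot")
    deltas = sorted({o.delta_hyp for o in observations})
    series = [[o.rho for o in observations if o.delta_hyp == d] for d in deltas]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(series, positions=range(len(deltas)), showfliers=False,
               medianprops={"color": "black"})
    rng = np.random.default_rng(0)  # jitter only
    for i, vals in enumerate(series):
        x = i + rng.uniform(-0.18, 0.18, size=len(vals))
        colors = ["#2ca02c" if v >= merge_threshold else "#d62728"
                  for v in vals]
        ax.scatter(x, vals, s=12, c=colors, alpha=0.7, zorder=3)
    ax.axhline(merge_threshold, ls="--", color="grey", lw=1)
    ax.set_xticks(range(len(deltas)), [str(d) for d in deltas])
    ax.set_xlabel("hydroxyproline number difference")
    ax.set_ylabel("Spearman rho between variants")
    _save(fig, Path(path))


def _save(fig, path: Path) -> None:
    if path.suffix:
        fig.savefig(path, bbox_inches="tight", dpi=150)
    else:
        for ext in (".svg", ".png"):
            fig.savefig(path.with_suffix(ext), bbox_inches="tight", dpi=150)
    plt.close(fig)
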