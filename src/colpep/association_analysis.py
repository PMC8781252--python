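"""Spearman association screen of peptide abundances against a covariate.

Each consolidated peptide is tested against one covariate (eGFR, age, or
age-corrected eGFR) with Spearman's rank correlation; p-values come from
the t-distribution approximation with average ranks on ties.  One
Benjamini-Hochberg family per covariate run; peptides whose rho is
undefined (constant vector after the missing-data policy) are excluded
from the family before adjustment.  Significant associations are classed
strong positive / strong negative at |rho| > strong_rho (default 0.3).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .peptide_model import Participant
from .ptm_consolidation import ConsolidatedPeptide

log = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "spearman_assoc",
    "bh_adjust",
    "classify_association",
    "rank_top",
    "associate_peptides",
    "results_to_frame",
]

CLASSES = ("strong_pos", "strong_neg", "significant_moderate", "not_significant")


@dataclass(frozen=True)
class AssociationResult:
    unmod_seq: str
    covariate: str
    rho: float
    p_raw: float
    p_adj: float
    n_used: int
    assoc_class: str


def spearman_assoc(intensities: Mapping[str, float],
                   covariate: Mapping[str, float],
                   missing_policy: str = "zero_fill",
                   ) -> tuple[float, float, int]:
    """Spearman rho, raw p and sample count for one peptide.

    ``covariate`` defines the sample space (participant -> value).  With
    ``zero_fill`` undetected intensities enter as 0 (tied lowest rank);
    with ``complete_case`` only detected participants are used.  Returns
    (nan, nan, n) when fewer than 3 samples remain or a vector is
    constant after ranking.
    """
    ids = list(covariate)
    if missing_policy == "complete_case":
        ids = [i for i in ids if i in intensities]
    x = np.array([intensities.get(i, 0.0) for i in ids])
    y = np.array([covariate[i] for i in ids])
    n = len(ids)
    if n < 3:
        return float("nan"), float("nan"), n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue), n


def bh_adjust(p_raw: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_association(rho: float, p_adj: float,
                         strong_rho: float = 0.3,
                         alpha: float = 0.05) -> str:
    """Class label from (rho, adjusted p): significance gates strength."""
    if not np.isfinite(rho) or not np.isfinite(p_adj) or p_adj >= alpha:
        return "not_significant"
    if rho > strong_rho:
        return "strong_pos"
    if rho < -strong_rho:
        return "strong_neg"
    return "significant_moderate"


def rank_top(results: Sequence[AssociationResult], k: int,
             ) -> list[AssociationResult]:
    """Top-k by |rho| descending, then adjusted p ascending, then sequence."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return sorted(results,
                  key=lambda r: (-abs(r.rho), r.p_adj, r.unmod_seq))[:k]


def associate_peptides(peptides: Sequence[ConsolidatedPeptide],
                       cohort: Sequence[Participant],
                       covariate: str = "egfr",
                       covariate_values: Mapping[str, float] | None = None,
                       missing_policy: str = "zero_fill",
                       strong_rho: float = 0.3,
                       alpha: float = 0.05) -> list[AssociationResult]:
    """Run the full screen for one covariate (one BH family).

    ``covariate`` is an attribute of Participant (``egfr`` or ``age``)
    unless ``covariate_values`` supplies the participant -> value map
    directly (e.g. age-corrected eGFR).
    """
    if covariate_values is None:
        covariate_values = {p.id: getattr(p, covariate) for p in cohort}
    tested, skipped = [], []
    for pep in peptides:
        rho, p, n = spearman_assoc(pep.intensities, covariate_values,
                                   missing_policy)
        if np.isfinite(rho) and np.isfinite(p):
            tested.append((pep, rho, p, n))
        else:
            skipped.append(pep.unmod_seq)
    if skipped:
        log.info("%d peptide(s) excluded from the %s family (undefined rho): %s",
                 len(skipped), covariate, skipped[:5])
    p_adj = bh_adjust([t[2] for t in tested])
    out = []
    for (pep, rho, p, n), pa in zip(tested, p_adj):
        out.append(AssociationResult(
            pep.unmod_seq, covariate, rho, p, float(pa), n,
            classify_association(rho, pa, strong_rho, alpha)))
    return out


def results_to_frame(results: Sequence[AssociationResult],
                     locations: Mapping[str, tuple[int, int]] | None = None,
                     ) -> pd.DataFrame:
    """Results table mirroring the published layout (sequence, start, stop,
    rho, p_raw, p_adj, class, n_used)."""
    rows = []
    for r in results:
        start, stop = (locations or {}).get(r.unmod_seq, (None, None))
        rows.append((r.unmod_seq, start, stop, r.rho, r.p_raw, r.p_adj,
                     r.assoc_class, r.n_used))
    return pd.DataFrame(rows, columns=[
        "sequence", "start", "stop", "rho", "p_raw", "p_adj", "class", "n_used"])
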