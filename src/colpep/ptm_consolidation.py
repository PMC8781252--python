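"""Consolidation of hydroxyproline variants of identical peptide backbones.

CE-MS distinguishes peptides that share an amino-acid backbone but carry
different numbers of hydroxyprolines.  When such variants rise and fall
together across participants (pairwise Spearman rho at or above the merge
threshold, default 0.5) they are treated as one biological fragment and
their intensities are aggregated; when they do not, only the most frequently
detected variant is retained so that every backbone sequence appears once in
the final list.  The delta-PTM profile summarises how inter-variant
correlation decays with the difference in hydroxyproline count.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peptide_model import Participant, PeptideRecord

__all__ = [
    "VariantGroup",
    "ConsolidatedPeptide",
    "VariantPairObservation",
    "ConsolidationReport",
    "group_variants",
    "pairwise_variant_rho",
    "consolidate",
    "delta_ptm_profile",
]


@dataclass
class VariantGroup:
    """All detected hydroxyproline variants of one backbone sequence."""

    unmod_seq: str
    variants: list[PeptideRecord]
    rho_matrix: np.ndarray | None = None

    @property
    def is_singleton(self) -> bool:
        return len(self.variants) == 1


@dataclass
class ConsolidatedPeptide:
    """One backbone sequence after consolidation.

    provenance is ``singleton`` (the only variant, passed through),
    ``merged`` (aggregate of a well-correlated variant set) or
    ``representative`` (most frequent variant of a poorly-correlated group).
    """

    unmod_seq: str
    intensities: dict[str, float]
    provenance: Literal["singleton", "merged", "representative"]
    source_modified_seqs: tuple[str, ...]
    n_hyp_set: tuple[int, ...]

    @property
    def frequency(self) -> int:
        return len(self.intensities)


@dataclass(frozen=True)
class VariantPairObservation:
    unmod_seq: str
    delta_hyp: int
    rho: float


@dataclass
class ConsolidationReport:
    """Stage counts of the consolidation flow.

    ``final_sequences = singleton_sequences + merged_sequences +
    representative_sequences``; ``unmerged_peptides`` counts every
    multi-variant peptide that did not enter a merge set (discarded
    group-mates of merged sets plus all members of unmerged groups).
    """

    stages: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": list(self.stages), "count": list(self.stages.values())})


def group_variants(records: Sequence[PeptideRecord]) -> list[VariantGroup]:
    """Partition peptide records by backbone (unmodified) sequence."""
    by_seq: dict[str, list[PeptideRecord]] = {}
    for rec in records:
        by_seq.setdefault(rec.unmod_seq, []).append(rec)
    return [VariantGroup(seq, var) for seq, var in sorted(by_seq.items())]


def _cohort_ids(cohort: Sequence[Participant] | Sequence[str]) -> list[str]:
    return [p.id if isinstance(p, Participant) else str(p) for p in cohort]


def _pair_rho(a: dict[str, float], b: dict[str, float], ids: list[str],
              missing_policy: str) -> float:
    """Spearman rho of two sparse intensity vectors; NaN when undefined."""
    if missing_policy == "complete_case":
        shared = [i for i in ids if i in a and i in b]
        if len(shared) < 3:
            return float("nan")
        x = np.array([a[i] for i in shared])
        y = np.array([b[i] for i in shared])
    else:
        x = np.array([a.get(i, 0.0) for i in ids])
        y = np.array([b.get(i, 0.0) for i in ids])
        if len(x) < 3:
            return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(x, y).statistic
    return float(rho)


def pairwise_variant_rho(group: VariantGroup,
                         cohort: Sequence[Participant] | Sequence[str],
                         missing_policy: str = "zero_fill") -> np.ndarray:
    """Symmetric matrix of pairwise Spearman rho among a group's variants.

    Undefined entries (fewer than 3 usable paired observations, or a
    constant vector) are NaN and are treated as below any merge threshold.
    """
    ids = _cohort_ids(cohort)
    k = len(group.variants)
    mat = np.eye(k)
    for i, j in itertools.combinations(range(k), 2):
        rho = _pair_rho(group.variants[i].intensities,
                        group.variants[j].intensities, ids, missing_policy)
        mat[i, j] = mat[j, i] = rho
    group.rho_matrix = mat
    return mat


def _priority(rec: PeptideRecord) -> tuple:
    # most frequent first; ties by total intensity, then modified sequence
    return (-rec.frequency, -rec.total_intensity, rec.modified_seq)


def _greedy_merge_set(group: VariantGroup, threshold: float) -> list[int]:
    """Indices of the greedy all-pairs clique, seeded by the top-priority variant."""
    order = sorted(range(len(group.variants)),
                   key=lambda i: _priority(group.variants[i]))
    mat = group.rho_matrix
    clique = [order[0]]
    for idx in order[1:]:
        if all(np.isfinite(mat[idx, j]) and mat[idx, j] >= threshold
               for j in clique):
            clique.append(idx)
    return clique


def _aggregate(variants: Sequence[PeptideRecord], how: str) -> dict[str, float]:
    ids = sorted({pid for v in variants for pid in v.intensities})
    out = {}
    for pid in ids:
        total = sum(v.intensities.get(pid, 0.0) for v in variants)
        out[pid] = total / len(variants) if how == "mean" else total
    return out


def consolidate(groups: Sequence[VariantGroup],
                cohort: Sequence[Participant] | Sequence[str],
                rho_merge_threshold: float = 0.5,
                aggregate: str = "sum",
                missing_policy: str = "zero_fill",
                ) -> tuple[list[ConsolidatedPeptide], ConsolidationReport]:
    """Collapse variant groups to one consolidated peptide per backbone.

    Singletons pass through.  In a multi-variant group, if the greedy
    all-pairs clique at ``rho_merge_threshold`` has at least two members,
    those variants are aggregated participant-wise (absent = 0 within the
    merge set) and the group's remaining variants are discarded; otherwise
    the single most frequent variant represents the backbone.
    """
    out: list[ConsolidatedPeptide] = []
    n_single = n_multi_pep = n_multi_seq = 0
    n_merged_pep = n_merged_seq = n_repr = n_discarded = 0
    for group in groups:
        if group.is_singleton:
            n_single += 1
            v = group.variants[0]
            out.append(ConsolidatedPeptide(
                group.unmod_seq, dict(v.intensities), "singleton",
                (v.modified_seq,), (v.n_hyp,)))
            continue
        n_multi_seq += 1
        n_multi_pep += len(group.variants)
        if group.rho_matrix is None:
            pairwise_variant_rho(group, cohort, missing_policy)
        clique = _greedy_merge_set(group, rho_merge_threshold)
        if len(clique) >= 2:
            chosen = [group.variants[i] for i in sorted(clique)]
            n_merged_seq += 1
            n_merged_pep += len(chosen)
            n_discarded += len(group.variants) - len(chosen)
            out.append(ConsolidatedPeptide(
                group.unmod_seq, _aggregate(chosen, aggregate), "merged",
                tuple(v.modified_seq for v in chosen),
                tuple(v.n_hyp for v in chosen)))
        else:
            n_repr += 1
            rep = min(group.variants, key=_priority)
            out.append(ConsolidatedPeptide(
                group.unmod_seq, dict(rep.intensities), "representative",
                (rep.modified_seq,), (rep.n_hyp,)))
    report = ConsolidationReport({
        "input_peptides": n_single + n_multi_pep,
        "singleton_sequences": n_single,
        "multivariant_peptides": n_multi_pep,
        "multivariant_sequences": n_multi_seq,
        "merged_peptides": n_merged_pep,
        "merged_sequences": n_merged_seq,
        "unmerged_peptides": n_multi_pep - n_merged_pep,
        "discarded_groupmates": n_discarded,
        "representative_sequences": n_repr,
        "final_sequences": n_single + n_merged_seq + n_repr,
    })
    assert len(out) == report.stages["final_sequences"]
    assert len({c.unmod_seq for c in out}) == len(out)
    return out, report


def delta_ptm_profile(groups: Sequence[VariantGroup],
                      cohort: Sequence[Participant] | Sequence[str] | None = None,
                      missing_policy: str = "zero_fill",
                      ) -> tuple[list[VariantPairObservation], pd.DataFrame]:
    """Inter-variant Spearman rho as a function of hydroxyproline difference.

    One observation per unordered variant pair (within multi-variant
    groups) with distinct hydroxyproline counts; the summary frame gives
    n, median and quartiles of rho per delta.  Pairs with undefined rho
    are dropped from both outputs.
    """
    obs: list[VariantPairObservation] = []
    for group in groups:
        if group.is_singleton:
            continue
        if group.rho_matrix is None:
            if cohort is None:
                raise ValueError(
                    "rho_matrix not computed; pass a cohort to compute it")
            pairwise_variant_rho(group, cohort, missing_policy)
        for i, j in itertools.combinations(range(len(group.variants)), 2):
            delta = abs(group.variants[i].n_hyp - group.variants[j].n_hyp)
            rho = group.rho_matrix[i, j]
            if delta >= 1 and np.isfinite(rho):
                obs.append(VariantPairObservation(group.unmod_seq, delta, rho))
    if obs:
        df = pd.DataFrame([(o.delta_hyp, o.rho) for o in obs],
                          columns=["delta_hyp", "rho"])
        summary = df.groupby("delta_hyp")["rho"].agg(
            n="count", median="median",
            q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75),
        ).reset_index()
    else:
        summary = pd.DataFrame(columns=["delta_hyp", "n", "median", "q1", "q3"])
    return obs, summary
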