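"""Age/eGFR disentanglement: age-corrected eGFR and eGFR-matched age bins.

eGFR declines with age even in healthy kidneys, so peptide-age and
peptide-eGFR associations confound each other.  Two complementary tools:
(1) an age-corrected eGFR that credits back an assumed physiological loss
(default 1 mL/min/1.73 m^2 per year beyond age 30), and (2) eGFR-matched
age sub-cohorts — 10-year age bins matched 1:1 on eGFR by greedy nearest
neighbour without replacement — in which age varies while kidney function
does not.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peptide_model import InputError, Participant

__all__ = [
    "MatchedCohort",
    "age_corrected_egfr",
    "bin_label",
    "assign_age_bins",
    "match_bins_on_egfr",
    "balance_check",
]

DEFAULT_BIN_EDGES = (30.0, 40.0, 50.0, 60.0, 70.0)


@dataclass
class MatchedCohort:
    bin_edges: tuple[float, ...]
    selected: dict[str, list[Participant]]   # bin label -> members
    n_per_bin: int
    seed: int
    balance_rho: float
    balance_p: float

    @property
    def participants(self) -> list[Participant]:
        return [p for members in self.selected.values() for p in members]

    def to_frame(self) -> pd.DataFrame:
        rows = [(p.id, label, p.age, p.egfr)
                for label, members in self.selected.items() for p in members]
        return pd.DataFrame(rows, columns=["id", "bin", "age", "egfr"])


def age_corrected_egfr(egfr: float, age: float,
                       onset: float = 30.0, slope: float = 1.0) -> float:
    """eGFR credited for the assumed physiological loss of ``slope``
    mL/min/1.73 m^2 per year lived beyond ``onset``; ages at or below the
    onset are returned unchanged."""
    return egfr + slope * max(0.0, age - onset)


def bin_label(edges: Sequence[float], index: int) -> str:
    if index == 0:
        return f"<{edges[0]:g}"
    if index == len(edges):
        return f">{edges[-1]:g}"
    return f"{edges[index - 1]:g}-{edges[index]:g}"


def assign_age_bins(cohort: Sequence[Participant],
                    edges: Sequence[float] = DEFAULT_BIN_EDGES,
                    ) -> dict[str, list[Participant]]:
    """Assign participants to age bins.

    Interior bins are left-closed / right-open ([30, 40), [40, 50), ...);
    the first and last bins are open-ended.  Every bin label appears in
    the result, possibly empty, in ascending age order.
    """
    edges = tuple(edges)
    if list(edges) != sorted(set(edges)):
        raise InputError("bin edges must be strictly increasing")
    bins: dict[str, list[Participant]] = {
        bin_label(edges, i): [] for i in range(len(edges) + 1)}
    for p in cohort:
        idx = int(np.searchsorted(edges, p.age, side="right"))
        bins[bin_label(edges, idx)].append(p)
    return bins


def match_bins_on_egfr(bins: dict[str, list[Participant]],
                       n_per_bin: int = 160,
                       seed: int = 0) -> MatchedCohort:
    """Build eGFR-matched equal-size sub-cohorts across age bins.

    The reference bin is the smallest (ties: the youngest).  ``n_per_bin``
    reference members are sampled uniformly without replacement (seeded);
    walking them in ascending eGFR order, each is matched in every other
    bin to the unused member with the smallest |eGFR difference| (ties:
    smaller id).  Deterministic given the seed.
    """
    for label, members in bins.items():
        if len(members) < n_per_bin:
            raise InputError(
                f"age bin {label!r} has {len(members)} members, "
                f"fewer than n_per_bin={n_per_bin}")
    labels = list(bins)
    ref_label = min(labels, key=lambda l: (len(bins[l]), labels.index(l)))
    rng = np.random.default_rng(seed)
    ref_members = sorted(bins[ref_label], key=lambda p: p.id)
    take = rng.choice(len(ref_members), size=n_per_bin, replace=False)
    ref_sel = sorted((ref_members[i] for i in take), key=lambda p: p.egfr)

    selected = {label: [] for label in labels}
    selected[ref_label] = list(ref_sel)
    for label in labels:
        if label == ref_label:
            continue
        pool = sorted(bins[label], key=lambda p: (p.egfr, p.id))
        used = np.zeros(len(pool), dtype=bool)
        egfrs = np.array([p.egfr for p in pool], dtype=float)
        for ref in ref_sel:
            dist = np.abs(egfrs - ref.egfr)
            dist[used] = np.inf
            best = np.flatnonzero(dist == dist.min())
            # ties: smaller id (pool is egfr- then id-sorted, so pick by id)
            j = min(best, key=lambda i: pool[i].id)
            used[j] = True
            selected[label].append(pool[j])

    all_sel = [p for members in selected.values() for p in members]
    rho, p = balance_check(all_sel)
    edges = _edges_from_labels(labels)
    return MatchedCohort(edges, selected, n_per_bin, seed, rho, p)


def _edges_from_labels(labels: Sequence[str]) -> tuple[float, ...]:
    edges = []
    for label in labels:
        if label.startswith(">"):
            edges.append(float(label[1:]))
        elif "-" in label and not label.startswith("<"):
            edges.append(float(label.split("-")[0]))
    return tuple(sorted(set(edges)))


def balance_check(cohort: Sequence[Participant]) -> tuple[float, float]:
    """Spearman rho and p of age vs eGFR over the given participants."""
    if len(cohort) < 3:
        raise InputError("balance check needs at least 3 participants")
    res = stats.spearmanr([p.age for p in cohort], [p.egfr for p in cohort])
    return float(res.statistic), float(res.pvalue)
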