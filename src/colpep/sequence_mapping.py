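"""Mapping of consolidated peptides onto the reference precursor.

Exact substring location (leftmost occurrence, multiplicity reported),
per-residue coverage depth with covered/gap interval accounting, region
classification against the precursor annotation, and hotspot calls over
strong-positive peptide stacks.  Coordinates are 1-based inclusive on the
full precursor throughout; only the BED export uses 0-based half-open
intervals.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .peptide_model import ReferenceProtein

log = logging.getLogger(__name__)

__all__ = [
    "LocatedPeptide",
    "CoverageMap",
    "HotspotCall",
    "locate_peptide",
    "locate_all",
    "build_coverage",
    "classify_regions",
    "find_hotspots",
    "write_coverage_bed",
]


@dataclass(frozen=True)
class LocatedPeptide:
    """A peptide placed on the reference (leftmost exact match)."""

    unmod_seq: str
    start: int   # 1-based, inclusive
    stop: int    # 1-based, inclusive
    multiplicity: int

    def __post_init__(self) -> None:
        assert self.stop - self.start + 1 == len(self.unmod_seq)


@dataclass
class CoverageMap:
    depth: np.ndarray                       # length L, counts per residue
    covered_intervals: list[tuple[int, int]]
    gap_intervals: list[tuple[int, int]]
    covered_fraction_full: float
    covered_fraction_mature: float | None


@dataclass(frozen=True)
class HotspotCall:
    start: int
    stop: int
    n_peptides_inside: int
    min_count: int


def locate_peptide(unmod_seq: str, reference: ReferenceProtein,
                   ) -> LocatedPeptide | None:
    """Locate an exact occurrence of ``unmod_seq`` on the reference.

    Returns the leftmost match with the total occurrence count, or None
    when the peptide does not occur (unmapped).
    """
    if not unmod_seq or unmod_seq != unmod_seq.upper():
        raise ValueError("unmod_seq must be a non-empty uppercase string")
    seq = reference.sequence
    first = seq.find(unmod_seq)
    if first == -1:
        return None
    n, i = 0, first
    while i != -1:
        n += 1
        i = seq.find(unmod_seq, i + 1)
    if n > 1:
        log.warning("peptide %s matches the reference %d times; using the "
                    "leftmost occurrence", unmod_seq, n)
    return LocatedPeptide(unmod_seq, first + 1, first + len(unmod_seq), n)


def locate_all(unmod_seqs: Sequence[str], reference: ReferenceProtein,
               ) -> tuple[list[LocatedPeptide], list[str]]:
    """Locate many peptides; returns (located, unmapped sequences)."""
    located, unmapped = [], []
    for seq in unmod_seqs:
        hit = locate_peptide(seq, reference)
        (located.append(hit) if hit else unmapped.append(seq))
    return located, unmapped


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as 1-based inclusive intervals."""
    out = []
    start = None
    for i, v in enumerate(mask, start=1):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def build_coverage(located: Sequence[LocatedPeptide],
                   reference: ReferenceProtein) -> CoverageMap:
    """Per-residue depth and covered/gap intervals over the reference."""
    L = len(reference)
    depth = np.zeros(L, dtype=int)
    for pep in located:
        depth[pep.start - 1:pep.stop] += 1
    covered = depth > 0
    frac_mature = None
    try:
        a, b = reference.region("mature")
    except KeyError:
        pass
    else:
        frac_mature = float(covered[a - 1:b].sum()) / (b - a + 1)
    return CoverageMap(
        depth=depth,
        covered_intervals=_runs(covered),
        gap_intervals=_runs(~covered),
        covered_fraction_full=float(covered.sum()) / L,
        covered_fraction_mature=frac_mature,
    )


def classify_regions(pep: LocatedPeptide, reference: ReferenceProtein,
                     ) -> set[str]:
    """Names of annotated regions the peptide overlaps."""
    return {name for name, a, b in reference.regions
            if pep.start <= b and pep.stop >= a}


def find_hotspots(located: Sequence[LocatedPeptide],
                  classes: Mapping[str, str],
                  reference: ReferenceProtein,
                  min_count: int = 5,
                  window: int = 1) -> list[HotspotCall]:
    """Residue runs where >= ``min_count`` strong-positive peptides stack.

    ``classes`` maps backbone sequence to an association class; only
    ``strong_pos`` peptides contribute.  ``window`` > 1 smooths the depth
    with a centred moving average before thresholding (heuristic; the
    hotspot is a descriptive call, not a formal statistic).
    """
    L = len(reference)
    depth = np.zeros(L)
    strong = [p for p in located if classes.get(p.unmod_seq) == "strong_pos"]
    for pep in strong:
        depth[pep.start - 1:pep.stop] += 1
    if window > 1:
        kernel = np.ones(window) / window
        depth = np.convolve(depth, kernel, mode="same")
    calls = []
    for start, stop in _runs(depth >= min_count):
        inside = sum(1 for p in strong if p.start >= start and p.stop <= stop)
        calls.append(HotspotCall(start, stop, inside, min_count))
    return calls


def write_coverage_bed(cov: CoverageMap, reference: ReferenceProtein,
                       bed_path: str | Path,
                       json_path: str | Path | None = None) -> None:
    """Export covered intervals as BED (0-based half-open) plus a JSON summary."""
    with open(bed_path, "w") as fh:
        for start, stop in cov.covered_intervals:
            fh.write(f"{reference.accession}\t{start - 1}\t{stop}\tcovered\n")
    if json_path is not None:
        summary = {
            "reference": reference.accession,
            "length": len(reference),
            "covered_fraction_full": cov.covered_fraction_full,
            "covered_fraction_mature": cov.covered_fraction_mature,
            "n_covered_intervals": len(cov.covered_intervals),
            "gap_intervals": [list(g) for g in cov.gap_intervals],
            "max_depth": int(cov.depth.max(initial=0)),
        }
        Path(json_path).write_text(json.dumps(summary, indent=2))
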