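"""End-to-end orchestration: filter -> consolidate -> map -> associate ->
match, with per-stage logging, serialized outputs and a run manifest.

The manifest records the configuration snapshot, seeds, stage counts and a
SHA-256 digest of every output file, so identical inputs and configuration
provably produce identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .association_analysis import (AssociationResult, associate_peptides,
                                   results_to_frame)
from .cohort_adjustment import (MatchedCohort, age_corrected_egfr,
                                assign_age_bins, match_bins_on_egfr)
from .peptide_model import (AnalysisConfig, Participant, PeptideRecord,
                            ReferenceProtein, filter_by_frequency,
                            write_peptide_table)
from .ptm_consolidation import (ConsolidationReport, consolidate,
                                delta_ptm_profile, group_variants)
from .sequence_mapping import (CoverageMap, build_coverage, locate_all,
                               write_coverage_bed)

log = logging.getLogger(__name__)

__all__ = ["PipelineError", "PipelineResult", "RunManifest", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunManifest:
    version: str
    seed: int
    config: dict
    stage_counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # file -> sha256

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


@dataclass
class PipelineResult:
    consolidated: list
    report: ConsolidationReport
    coverage: CoverageMap
    locations: dict[str, tuple[int, int]]
    unmapped: list[str]
    associations: dict[str, list[AssociationResult]]
    matched: MatchedCohort | None
    delta_profile: pd.DataFrame
    manifest: RunManifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(records: Sequence[PeptideRecord],
                 cohort: Sequence[Participant],
                 reference: ReferenceProtein,
                 config: AnalysisConfig | None = None,
                 outdir: str | Path | None = None,
                 seed: int = 0) -> PipelineResult:
    """Run the full analysis and (optionally) write all stage outputs.

    Stages: frequency filter; hydroxyproline-variant consolidation;
    location and coverage on the reference; Spearman/BH association with
    eGFR, age and age-corrected eGFR; eGFR-matched age sub-cohorts and the
    age association within them.  The matching stage is skipped (with a
    log message) when any age bin is smaller than ``n_per_bin``.
    """
    config = config or AnalysisConfig()
    manifest = RunManifest(__version__, seed, config.to_dict())
    counts = manifest.stage_counts

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    counts["input_peptides"] = len(records)
    counts["participants"] = len(cohort)
    kept = stage("filter", filter_by_frequency, records, config.min_frequency)
    counts["frequency_filtered"] = len(kept)
    log.info("filter: %d -> %d peptides (min frequency %d)",
             len(records), len(kept), config.min_frequency)

    groups = stage("group", group_variants, kept)
    consolidated, report = stage(
        "consolidate", consolidate, groups, cohort,
        config.rho_merge_threshold, config.aggregate, config.missing_policy)
    counts.update(report.stages)
    log.info("consolidate: %s", report.stages)
    obs, delta_summary = stage("delta_ptm", delta_ptm_profile, groups)

    located, unmapped = stage(
        "map", locate_all, [c.unmod_seq for c in consolidated], reference)
    locations = {p.unmod_seq: (p.start, p.stop) for p in located}
    coverage = stage("coverage", build_coverage, located, reference)
    counts["located_peptides"] = len(located)
    counts["unmapped_peptides"] = len(unmapped)
    log.info("map: %d located, %d unmapped; coverage %.1f%% of precursor",
             len(located), len(unmapped), 100 * coverage.covered_fraction_full)

    associations: dict[str, list[AssociationResult]] = {}
    for cov in ("egfr", "age"):
        associations[cov] = stage(
            f"associate[{cov}]", associate_peptides, consolidated, cohort,
            cov, None, config.missing_policy, config.strong_rho, config.alpha)
    acorr = {p.id: age_corrected_egfr(p.egfr, p.age, config.age_correction_onset,
                                      config.age_correction_slope)
             for p in cohort}
    associations["age_corrected_egfr"] = stage(
        "associate[age_corrected_egfr]", associate_peptides, consolidated,
        cohort, "age_corrected_egfr", acorr, config.missing_policy,
        config.strong_rho, config.alpha)
    for cov, res in associations.items():
        counts[f"significant_{cov}"] = sum(
            r.assoc_class != "not_significant" for r in res)

    bins = stage("bin", assign_age_bins, cohort, config.age_bin_edges)
    matched = None
    if all(len(m) >= config.n_per_bin for m in bins.values()):
        matched = stage("match", match_bins_on_egfr, bins,
                        config.n_per_bin, seed)
        counts["matched_participants"] = len(matched.participants)
        associations["age_in_egfr_matched"] = stage(
            "associate[age_in_egfr_matched]", associate_peptides,
            consolidated, matched.participants, "age", None,
            config.missing_policy, config.strong_rho, config.alpha)
        counts["significant_age_in_egfr_matched"] = sum(
            r.assoc_class != "not_significant"
            for r in associations["age_in_egfr_matched"])
    else:
        small = {l: len(m) for l, m in bins.items() if len(m) < config.n_per_bin}
        log.warning("matching skipped: bins smaller than n_per_bin=%d: %s",
                    config.n_per_bin, small)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_outputs(outdir, consolidated, report, coverage, reference,
                       locations, associations, matched, delta_summary,
                       manifest)
    return PipelineResult(consolidated, report, coverage, locations, unmapped,
                          associations, matched, delta_summary, manifest)


def _write_outputs(outdir, consolidated, report, coverage, reference,
                   locations, associations, matched, delta_summary, manifest):
    paths = []

    def emit(name: str) -> Path:
        p = outdir / name
        paths.append(p)
        return p

    write_peptide_table(
        [PeptideRecord(c.unmod_seq, c.intensities) for c in consolidated],
        emit("consolidated_peptides.tsv"))
    report.to_frame().to_csv(emit("consolidation_report.tsv"),
                             sep="\t", index=False)
    emit("consolidation_report.json").write_text(
        json.dumps(report.stages, indent=2))
    write_coverage_bed(coverage, reference, emit("coverage.bed"),
                       emit("coverage.json"))
    delta_summary.to_csv(emit("delta_ptm_profile.tsv"), sep="\t", index=False)
    for cov, res in associations.items():
        results_to_frame(res, locations).to_csv(
            emit(f"associations_{cov}.tsv"), sep="\t", index=False)
    if matched is not None:
        matched.to_frame().to_csv(emit("matched_cohort.tsv"),
                                  sep="\t", index=False)
        emit("balance.json").write_text(json.dumps({
            "seed": matched.seed, "n_per_bin": matched.n_per_bin,
            "rho_age_egfr": matched.balance_rho,
            "p_age_egfr": matched.balance_p}, indent=2))
    manifest.outputs = {p.name: _sha256(p) for p in paths}
    manifest.write(outdir / "manifest.json")
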