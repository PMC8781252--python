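"""Hydroxyproline-variant grouping, pairwise correlation and consolidation."""
import itertools
import random

import numpy as np
import pytest

from colpep import (consolidate, delta_ptm_profile, group_variants,
                    pairwise_variant_rho)
from colpep.ptm_consolidation import VariantGroup
from colpep.synthetic_cohort import (SimulationParams, generate_cohort,
                                     generate_peptides)
from colpep.peptide_model import bundled_reference

from conftest import make_record


def exact_spearman_no_ties(x, y):
    """Closed form 1 - 6*sum(d^2)/(n(n^2-1)); valid only without ties."""
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    n = len(x)
    return 1 - 6 * float(((rx - ry) ** 2).sum()) / (n * (n * n - 1))


class TestGroupVariants:
    def test_partitions_by_backbone(self):
        recs = [make_record("GPpGA", [1]), make_record("GPPGA", [2]),
                make_record("GAKGD", [3]), make_record("GESGP", [4])]
        groups = group_variants(recs)
        assert len(groups) == 3
        sizes = sorted(len(g.variants) for g in groups)
        assert sizes == [1, 1, 2]
        assert sum(len(g.variants) for g in groups) == len(recs)

    def test_variants_differing_only_in_hyp_share_a_group(self):
        recs = [make_record("GPpGAp", [1]), make_record("GppGAp", [1]),
                make_record("GPPGAP", [1])]
        (group,) = group_variants(recs)
        assert group.unmod_seq == "GPPGAP"
        assert sorted(v.n_hyp for v in group.variants) == [0, 2, 3]

    def test_empty_input(self):
        assert group_variants([]) == []


class TestPairwiseRho:
    def test_identical_vectors(self, five_ids):
        g = VariantGroup("GPPGA", [make_record("GPpGA", [1, 2, 3, 4, 5]),
                                   make_record("GppGA", [1, 2, 3, 4, 5])])
        mat = pairwise_variant_rho(g, five_ids)
        assert mat[0, 1] == pytest.approx(1.0)

    def test_monotone_transform_gives_rho_one(self, five_ids):
        a = [1, 2, 3, 4, 5]
        g = VariantGroup("GPPGA", [make_record("GPpGA", a),
                                   make_record("GppGA", [x ** 3 for x in a])])
        assert pairwise_variant_rho(g, five_ids)[0, 1] == pytest.approx(1.0)

    def test_closed_form_example(self, five_ids):
        g = VariantGroup("GPPGA", [make_record("GPpGA", [1, 2, 3, 4, 5]),
                                   make_record("GppGA", [2, 1, 4, 3, 5])])
        mat = pairwise_variant_rho(g, five_ids)
        assert mat[0, 1] == pytest.approx(0.8)
        assert mat[0, 1] == pytest.approx(
            exact_spearman_no_ties([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]))

    def test_matrix_is_symmetric_with_unit_diagonal(self, five_ids):
        g = VariantGroup("GPPGAP", [make_record("GPpGAp", [1, 2, 3, 4, 5]),
                                    make_record("GppGAp", [5, 1, 2, 4, 3]),
                                    make_record("GPPGAP", [2, 3, 1, 5, 4])])
        mat = pairwise_variant_rho(g, five_ids)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)

    def test_too_few_shared_observations_is_undefined(self):
        ids = [f"s{i}" for i in range(1, 7)]
        a = make_record("GPpGA", [1, 2, 3, 0, 0, 0], ids)
        b = make_record("GppGA", [0, 0, 0, 1, 2, 3], ids)
        mat = pairwise_variant_rho(VariantGroup("GPPGA", [a, b]), ids,
                                   missing_policy="complete_case")
        assert np.isnan(mat[0, 1])


class TestConsolidate:
    def test_correlated_pair_merges_to_participant_wise_sum(self, five_ids):
        a = make_record("GPpGA", [1, 2, 3, 4, 5])
        b = make_record("GppGA", [0, 4, 6, 8, 10])  # rho = 1, absent in s1
        (out,), report = consolidate(group_variants([a, b]), five_ids)
        assert out.provenance == "merged"
        # hand-summed table, absent treated as 0 within the merge set
        assert out.intensities == {"s1": 1, "s2": 6, "s3": 9, "s4": 12, "s5": 15}
        assert report.stages["merged_sequences"] == 1

    def test_uncorrelated_pair_keeps_most_frequent_variant(self, five_ids):
        a = make_record("GPpGA", [5, 4, 1, 2, 3])
        b = make_record("GppGA", [1, 5, 3, 2, 0])  # lower frequency
        (out,), report = consolidate(group_variants([a, b]), five_ids,
                                     rho_merge_threshold=0.95)
        assert out.provenance == "representative"
        assert out.source_modified_seqs == ("GPpGA",)
        assert out.intensities == a.intensities
        assert report.stages["unmerged_peptides"] == 2

    def test_singleton_passthrough(self, five_ids):
        a = make_record("GAKGD", [1, 0, 2, 0, 3])
        (out,), report = consolidate(group_variants([a]), five_ids)
        assert out.provenance == "singleton"
        assert out.intensities == a.intensities
        assert report.stages == {
            "input_peptides": 1, "singleton_sequences": 1,
            "multivariant_peptides": 0, "multivariant_sequences": 0,
            "merged_peptides": 0, "merged_sequences": 0,
            "unmerged_peptides": 0, "discarded_groupmates": 0,
            "representative_sequences": 0, "final_sequences": 1}

    def test_undefined_rho_counts_as_below_threshold(self):
        ids = [f"s{i}" for i in range(1, 7)]
        a = make_record("GPpGA", [1, 2, 3, 4, 0, 0], ids)
        b = make_record("GppGA", [0, 0, 0, 0, 1, 2], ids)
        (out,), _ = consolidate(group_variants([a, b]), ids,
                                missing_policy="complete_case")
        assert out.provenance == "representative"

    def test_output_backbones_unique_and_order_invariant(self, five_ids):
        rng = random.Random(7)
        recs = [make_record("GPpGAp", [1, 2, 3, 4, 5]),
                make_record("GppGAp", [1, 2, 3, 4, 5]),
                make_record("GPPGAP", [5, 3, 1, 2, 4]),
                make_record("GAKGD", [1, 1, 2, 2, 3])]
        out_ref, rep_ref = consolidate(group_variants(recs), five_ids)
        for _ in range(5):
            rng.shuffle(recs)
            out, rep = consolidate(group_variants(recs), five_ids)
            assert rep.stages == rep_ref.stages
            assert {(o.unmod_seq, o.provenance,
                     tuple(sorted(o.intensities.items()))) for o in out} == \
                   {(o.unmod_seq, o.provenance,
                     tuple(sorted(o.intensities.items()))) for o in out_ref}

    def test_stage_counts_sum_on_synthetic_run(self):
        params = SimulationParams(n_participants=250, n_fragments=40, seed=11)
        cohort = generate_cohort(params)
        records, _ = generate_peptides(params, cohort, bundled_reference())
        groups = group_variants(records)
        out, rep = consolidate(groups, cohort)
        s = rep.stages
        assert s["input_peptides"] == len(records)
        assert s["singleton_sequences"] + s["multivariant_peptides"] == \
            s["input_peptides"]
        assert s["merged_peptides"] + s["unmerged_peptides"] == \
            s["multivariant_peptides"]
        assert s["merged_sequences"] + s["representative_sequences"] == \
            s["multivariant_sequences"]
        assert s["final_sequences"] == len(out) == len(
            {o.unmod_seq for o in out})
        # conservation: merged intensities are exact participant-wise sums
        by_mod = {r.modified_seq: r for r in records}
        for pep in out:
            if pep.provenance != "merged":
                continue
            sources = [by_mod[m] for m in pep.source_modified_seqs]
            ids = {p for s_ in sources for p in s_.intensities}
            assert set(pep.intensities) == ids
            for pid in ids:
                assert pep.intensities[pid] == sum(
                    s_.intensities.get(pid, 0.0) for s_ in sources)


class TestDeltaPtmProfile:
    def test_pair_combinatorics(self, five_ids):
        # one backbone GPPGAPPP with hydroxyproline counts 3, 4, 5
        recs = [make_record("GppGApPP", [1, 2, 3, 4, 5]),
                make_record("GppGAppP", [2, 1, 4, 3, 5]),
                make_record("GppGAppp", [1, 3, 2, 5, 4])]
        # pairwise count differences -> deltas 1, 1, 2
        obs, summary = delta_ptm_profile(group_variants(recs), five_ids)
        assert sorted(o.delta_hyp for o in obs) == [1, 1, 2]
        assert summary.set_index("delta_hyp")["n"].to_dict() == {1: 2, 2: 1}

    def test_identical_vectors_give_median_one(self, five_ids):
        recs = [make_record("GPpGA", [1, 2, 3, 4, 5]),
                make_record("GppGA", [1, 2, 3, 4, 5])]
        _, summary = delta_ptm_profile(group_variants(recs), five_ids)
        assert summary["median"].tolist() == [pytest.approx(1.0)]

    def test_planted_decay_is_recovered(self):
        params = SimulationParams(
            n_participants=800, n_fragments=60, seed=5,
            variant_count_probs=((3, 1.0),), censor_quantile=0.0,
            effects=("null",) * 60)
        cohort = generate_cohort(params)
        records, _ = generate_peptides(params, cohort, bundled_reference())
        obs, summary = delta_ptm_profile(group_variants(records), cohort)
        med = summary.set_index("delta_hyp")["median"]
        deltas = [d for d in (1, 2, 3, 4) if d in med.index]
        assert len(deltas) >= 3
        assert all(med[a] > med[b]
                   for a, b in itertools.pairwise(deltas))
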