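"""Ground-truth generator: determinism, margins, planted structure."""
import numpy as np
import pytest
from scipy import stats

from colpep import (consolidate, fig1_scenario, generate_cohort,
                    generate_peptides, group_variants, locate_peptide)
from colpep.synthetic_cohort import (SimulationParams, gaussian_to_spearman,
                                     spearman_to_gaussian)


class TestParams:
    @pytest.mark.parametrize("kw", [
        {"age_min": 90, "age_max": 30},
        {"fragment_len_min": 3},
        {"censor_quantile": 1.0},
        {"target_rho_egfr": (("strong_pos", 1.0),)},
        {"effects": ("strong_pos", "nope")},
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationParams(**kw)

    def test_copula_conversion_round_trip(self):
        for r in (-0.8, -0.3, 0.0, 0.5, 0.9):
            assert gaussian_to_spearman(spearman_to_gaussian(r)) == \
                pytest.approx(r)


class TestGenerateCohort:
    def test_same_seed_identical(self):
        p = SimulationParams(n_participants=100, seed=42)
        c1, c2 = generate_cohort(p), generate_cohort(p)
        assert [(a.id, a.age, a.egfr) for a in c1] == \
            [(a.id, a.age, a.egfr) for a in c2]

    def test_age_margin_at_scale(self):
        cohort = generate_cohort(SimulationParams(n_participants=5000, seed=7))
        ages = np.array([p.age for p in cohort])
        assert abs(ages.mean() - 55.8) < 0.5
        assert ages.min() >= 18 and ages.max() <= 95
        egfr = np.array([p.egfr for p in cohort])
        assert egfr.min() >= 15 and egfr.max() <= 150

    def test_zero_confounding(self):
        cohort = generate_cohort(SimulationParams(
            n_participants=5000, seed=8, age_egfr_rho=0.0))
        rho = stats.spearmanr([p.age for p in cohort],
                              [p.egfr for p in cohort]).statistic
        assert abs(rho) < 0.05

    def test_planted_confounding_recovered(self):
        cohort = generate_cohort(SimulationParams(
            n_participants=5000, seed=9, age_egfr_rho=-0.4))
        rho = stats.spearmanr([p.age for p in cohort],
                              [p.egfr for p in cohort]).statistic
        assert rho == pytest.approx(-0.4, abs=0.06)

    def test_impossible_bounds_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(egfr_min=100, egfr_max=50)


class TestGeneratePeptides:
    def test_deterministic_and_true_substrings(self, reference):
        params = SimulationParams(n_participants=150, n_fragments=25, seed=3)
        cohort = generate_cohort(params)
        r1, t1 = generate_peptides(params, cohort, reference)
        r2, _ = generate_peptides(params, cohort, reference)
        assert [(a.modified_seq, a.intensities) for a in r1] == \
            [(a.modified_seq, a.intensities) for a in r2]
        for v in t1.variants:
            assert reference.sequence[v.start - 1:v.stop] == v.unmod_seq

    def test_recorded_positions_agree_with_locate(self, reference):
        params = SimulationParams(n_participants=120, n_fragments=40, seed=13)
        cohort = generate_cohort(params)
        _, truth = generate_peptides(params, cohort, reference)
        for v in truth.variants:
            hit = locate_peptide(v.unmod_seq, reference)
            if not v.repeated_in_reference:
                assert (hit.start, hit.stop) == (v.start, v.stop)
                assert hit.multiplicity == 1

    def test_no_censoring_full_frequency(self, reference):
        params = SimulationParams(n_participants=80, n_fragments=10, seed=5,
                                  censor_quantile=0.0)
        cohort = generate_cohort(params)
        records, _ = generate_peptides(params, cohort, reference)
        assert all(r.frequency == 80 for r in records)

    def test_censoring_trims_bottom_quantile(self, reference):
        params = SimulationParams(n_participants=200, n_fragments=10, seed=5,
                                  censor_quantile=0.25)
        cohort = generate_cohort(params)
        records, _ = generate_peptides(params, cohort, reference)
        for r in records:
            assert r.frequency == pytest.approx(150, abs=2)

    def test_zero_decay_gives_near_perfect_variant_correlation(self, reference):
        params = SimulationParams(
            n_participants=800, n_fragments=20, seed=21,
            variant_count_probs=((2, 1.0),), rho_decay_per_delta=0.0,
            base_variant_rho=0.95, censor_quantile=0.0,
            effects=("null",) * 20)
        cohort = generate_cohort(params)
        records, _ = generate_peptides(params, cohort, reference)
        groups = [g for g in group_variants(records) if not g.is_singleton]
        from colpep import pairwise_variant_rho
        for g in groups:
            mat = pairwise_variant_rho(g, cohort)
            assert mat[0, 1] > 0.9

    def test_planted_positive_effect_recovered(self, reference):
        params = SimulationParams(
            n_participants=2000, n_fragments=10, seed=17,
            variant_count_probs=((1, 1.0),), effects=("strong_pos",) * 10,
            censor_quantile=0.0)
        cohort = generate_cohort(params)
        records, truth = generate_peptides(params, cohort, reference)
        egfr = {p.id: p.egfr for p in cohort}
        ids = list(egfr)
        for rec in records:
            rho = stats.spearmanr([rec.intensities[i] for i in ids],
                                  [egfr[i] for i in ids]).statistic
            assert rho == pytest.approx(0.5, abs=0.1)


class TestFig1Scenario:
    def test_single_mergeable_group(self):
        records = fig1_scenario(0, 1, 0, n_participants=60, seed=2)
        assert len(records) == 2
        out, report = consolidate(group_variants(records),
                                  sorted({p for r in records
                                          for p in r.intensities}))
        assert len(out) == 1 and out[0].provenance == "merged"

    def test_pure_singletons_pass_through(self):
        records = fig1_scenario(7, 0, 0, n_participants=40, seed=3)
        out, report = consolidate(group_variants(records),
                                  sorted({p for r in records
                                          for p in r.intensities}))
        assert len(out) == 7
        assert all(o.provenance == "singleton" for o in out)

    def test_default_peptide_totals(self):
        records = fig1_scenario(n_participants=120, seed=4)
        assert len(records) == 707
        assert len({r.modified_seq for r in records}) == 707
        assert len({r.unmod_seq for r in records}) == 503
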