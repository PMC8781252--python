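"""Synthetic cohorts and peptide tables with known ground truth.

The study-scale urinary peptide database behind this kind of analysis is
not public, so every downstream module is exercised on simulated data that
reproduces its statistical structure: ~5000 participants (age truncated
normal, mean 55.8, SD 15.8, range 18-95; eGFR truncated normal within
15-150 with configurable age confounding), several hundred peptides that
are true substrings of the reference precursor, hydroxyproline variants
whose mutual rank correlation decays with the difference in hydroxyproline
count, monotone eGFR/age effects of configurable strength, and value-based
detection censoring.

Rank-correlation targets are planted through a Gaussian copula: a target
Spearman coefficient ``r`` is converted to the latent Gaussian correlation
``g = 2 sin(pi * r / 6)``, latent scores are mixed accordingly, and
intensities are any monotone transform of the latent — so the planted
Spearman value is calibrated regardless of the intensity distribution.

``fig1_scenario`` plants an exact consolidation group structure
(singletons / mergeable / non-mergeable groups), so the consolidation
count flow is forced by construction.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .peptide_model import Participant, PeptideRecord, ReferenceProtein

__all__ = [
    "SimulationParams",
    "VariantTruth",
    "GroundTruth",
    "generate_cohort",
    "generate_peptides",
    "fig1_scenario",
    "spearman_to_gaussian",
    "gaussian_to_spearman",
]

EFFECT_CLASSES = ("strong_pos", "strong_neg", "null")


def spearman_to_gaussian(r: float) -> float:
    """Latent Gaussian correlation that yields Spearman ``r`` under a
    Gaussian copula (inverse of ``r = (6/pi) asin(g/2)``)."""
    return 2.0 * np.sin(np.pi * r / 6.0)


def gaussian_to_spearman(g: float) -> float:
    return (6.0 / np.pi) * np.arcsin(g / 2.0)


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; defaults emulate the study conditions."""

    n_participants: int = 5000
    seed: int = 0
    # cohort margins
    age_mean: float = 55.8
    age_sd: float = 15.8
    age_min: float = 18.0
    age_max: float = 95.0
    egfr_mean: float = 81.0
    egfr_sd: float = 25.0
    egfr_min: float = 15.0
    egfr_max: float = 150.0
    #: target Spearman correlation between age and eGFR (confounding)
    age_egfr_rho: float = -0.4
    # peptide layer
    n_fragments: int = 150
    fragment_len_min: int = 8
    fragment_len_max: int = 45
    variant_count_probs: tuple[tuple[int, float], ...] = (
        (1, 0.5), (2, 0.3), (3, 0.2))
    #: Spearman between variants extrapolated to zero hydroxyproline
    #: difference, and its linear decay per unit difference
    base_variant_rho: float = 0.8
    rho_decay_per_delta: float = 0.15
    effect_probs: tuple[tuple[str, float], ...] = (
        ("strong_pos", 0.35), ("strong_neg", 0.05), ("null", 0.60))
    target_rho_egfr: tuple[tuple[str, float], ...] = (
        ("strong_pos", 0.5), ("strong_neg", -0.5), ("null", 0.0))
    #: optional explicit Spearman targets versus age (per class); when None
    #: the age association arises solely through the age-eGFR confounding
    target_rho_age: tuple[tuple[str, float], ...] | None = None
    #: explicit per-fragment effect classes (overrides effect_probs)
    effects: tuple[str, ...] | None = None
    log_sigma: float = 1.0
    #: per-peptide bottom intensity quantile reported as "not detected"
    censor_quantile: float = 0.2

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if not (self.age_min < self.age_max and self.egfr_min < self.egfr_max):
            raise ValueError("impossible truncation bounds")
        if self.fragment_len_min < 5:
            raise ValueError("fragment lengths must be >= 5")
        for _, r in self.target_rho_egfr:
            if not abs(r) < 1:
                raise ValueError("target |rho| must be < 1")
        if not 0 <= self.censor_quantile < 1:
            raise ValueError("censor_quantile must be in [0, 1)")
        if abs(self.age_egfr_rho) >= 1:
            raise ValueError("age_egfr_rho must be in (-1, 1)")
        for probs in (self.variant_count_probs, self.effect_probs):
            total = sum(p for _, p in probs)
            if not np.isclose(total, 1.0):
                raise ValueError(f"probabilities must sum to 1, got {total}")
        if self.effects is not None:
            bad = set(self.effects) - set(EFFECT_CLASSES)
            if bad:
                raise ValueError(f"unknown effect classes {sorted(bad)}")


@dataclass(frozen=True)
class VariantTruth:
    modified_seq: str
    unmod_seq: str
    fragment_id: int
    start: int
    stop: int
    n_hyp: int
    effect_class: str
    target_rho_egfr: float
    repeated_in_reference: bool


@dataclass
class GroundTruth:
    variants: list[VariantTruth] = field(default_factory=list)

    @property
    def fragment_classes(self) -> dict[str, str]:
        """Backbone sequence -> planted effect class."""
        return {v.unmod_seq: v.effect_class for v in self.variants}

    @property
    def fragment_positions(self) -> dict[str, tuple[int, int]]:
        return {v.unmod_seq: (v.start, v.stop) for v in self.variants}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            [v.__dict__ for v in self.variants], indent=2))


def _truncnorm(mean: float, sd: float, lo: float, hi: float):
    return stats.truncnorm((lo - mean) / sd, (hi - mean) / sd,
                           loc=mean, scale=sd)


def generate_cohort(params: SimulationParams) -> list[Participant]:
    """Draw a cohort with truncated-normal age/eGFR margins and the
    configured age-eGFR Spearman confounding (Gaussian copula)."""
    rng = np.random.default_rng([params.seed, 11])
    n = params.n_participants
    g = spearman_to_gaussian(params.age_egfr_rho)
    w_age = rng.standard_normal(n)
    w_egfr = g * w_age + np.sqrt(1 - g * g) * rng.standard_normal(n)
    age = _truncnorm(params.age_mean, params.age_sd,
                     params.age_min, params.age_max).ppf(stats.norm.cdf(w_age))
    egfr = _truncnorm(params.egfr_mean, params.egfr_sd,
                      params.egfr_min, params.egfr_max).ppf(stats.norm.cdf(w_egfr))
    width = len(str(n - 1))
    return [Participant(f"S{i:0{width}d}", float(age[i]), float(egfr[i]),
                        "control" if egfr[i] >= 90 else "CKD")
            for i in range(n)]


def _normal_scores(values: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(values)
    return stats.norm.ppf(ranks / (len(values) + 1))


def _psd_corr(K: np.ndarray) -> np.ndarray:
    """Nearest-enough PSD correlation matrix (eigenvalue clipping)."""
    w, V = np.linalg.eigh(K)
    if w.min() >= 1e-10:
        return K
    w = np.clip(w, 1e-8, None)
    K = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(K))
    return K / np.outer(d, d)


def _draw_correlated(rng: np.random.Generator, K: np.ndarray,
                     n: int) -> np.ndarray:
    """n draws of a k-variate standard normal with correlation K; (n, k)."""
    K = _psd_corr(K)
    w, V = np.linalg.eigh(K)
    A = V * np.sqrt(np.clip(w, 0, None))
    return rng.standard_normal((n, K.shape[0])) @ A.T


def _sample_fragment(rng: np.random.Generator, reference: ReferenceProtein,
                     len_lo: int, len_hi: int, n_variants: int,
                     taken: set[str]) -> tuple[str, int] | None:
    """A fresh backbone substring with enough prolines for the variant set."""
    try:
        lo, hi = reference.region("mature")
    except KeyError:
        lo, hi = 1, len(reference)
    if hi - lo + 1 < len_lo:
        raise ValueError("fragment longer than the sampling region")
    for _ in range(500):
        length = int(rng.integers(len_lo, min(len_hi, hi - lo + 1) + 1))
        start = int(rng.integers(lo, hi - length + 2))
        seq = reference.sequence[start - 1:start - 1 + length]
        if seq in taken or seq.count("P") < 2 * n_variants:
            continue
        return seq, start
    return None


def _hyp_counts(rng: np.random.Generator, n_variants: int, n_pro: int,
                ) -> list[int]:
    """Distinct increasing hydroxyproline counts (steps of 1 or 2)."""
    span = 2 * (n_variants - 1)
    k0 = int(rng.integers(0, max(1, n_pro - span)))
    counts = [k0]
    for _ in range(n_variants - 1):
        counts.append(counts[-1] + int(rng.integers(1, 3)))
    return counts


def _modify(backbone: str, n_hyp: int) -> str:
    """Lowercase the first ``n_hyp`` prolines of the backbone."""
    out, done = [], 0
    for ch in backbone:
        if ch == "P" and done < n_hyp:
            out.append("p")
            done += 1
        else:
            out.append(ch)
    return "".join(out)


def generate_peptides(params: SimulationParams,
                      cohort: Sequence[Participant],
                      reference: ReferenceProtein,
                      ) -> tuple[list[PeptideRecord], GroundTruth]:
    """Simulate a peptide table over an existing cohort.

    Fragments are true substrings of the reference (sampled within the
    mature region when annotated).  Each fragment's latent signal carries
    the class-specific monotone eGFR (and optionally age) effect; each
    variant adds noise scaled so that inter-variant Spearman decays by
    ``rho_decay_per_delta`` per unit hydroxyproline difference.  Observed
    intensities are log-normal transforms of the latents, censored below
    the per-peptide detection quantile.
    """
    rng = np.random.default_rng([params.seed, 23])
    n = len(cohort)
    z_e = _normal_scores(np.array([p.egfr for p in cohort]))
    z_a = _normal_scores(np.array([p.age for p in cohort]))
    g_c = float(np.corrcoef(z_a, z_e)[0, 1])

    rho_e = dict(params.target_rho_egfr)
    rho_a = dict(params.target_rho_age) if params.target_rho_age else None
    if params.effects is not None:
        if len(params.effects) != params.n_fragments:
            raise ValueError("effects must list one class per fragment")
        classes = list(params.effects)
    else:
        names = [c for c, _ in params.effect_probs]
        probs = [p for _, p in params.effect_probs]
        classes = list(rng.choice(names, size=params.n_fragments, p=probs))
    var_counts = np.array([k for k, _ in params.variant_count_probs])
    var_probs = np.array([p for _, p in params.variant_count_probs])

    records: list[PeptideRecord] = []
    truth = GroundTruth()
    taken: set[str] = set()
    ids = [p.id for p in cohort]
    for frag_id in range(params.n_fragments):
        n_var = int(rng.choice(var_counts, p=var_probs))
        got = _sample_fragment(rng, reference, params.fragment_len_min,
                               params.fragment_len_max, n_var, taken)
        if got is None:
            raise RuntimeError("could not sample a fresh fragment; "
                               "reference too short or too proline-poor")
        backbone, start = got
        taken.add(backbone)
        effect = classes[frag_id]

        # effect direction coefficients on the latent covariate scores
        g_e = spearman_to_gaussian(rho_e.get(effect, 0.0))
        if rho_a is not None:
            g_a = spearman_to_gaussian(rho_a.get(effect, 0.0))
            R = np.array([[1.0, g_c], [g_c, 1.0]])
            b = np.linalg.solve(R, np.array([g_e, g_a]))
            v = float(b @ R @ b)
        else:
            b = np.array([g_e, 0.0])
            v = g_e * g_e
        v = min(v, 0.98)

        counts = _hyp_counts(rng, n_var, backbone.count("P"))
        deltas = np.abs(np.subtract.outer(counts, counts))
        r_v = np.clip(params.base_variant_rho
                      - params.rho_decay_per_delta * deltas, -0.95, 0.95)
        g_v = spearman_to_gaussian(r_v)
        np.fill_diagonal(g_v, 1.0)
        K = np.clip((g_v - v) / (1.0 - v), -0.99, 1.0)
        np.fill_diagonal(K, 1.0)
        u = _draw_correlated(rng, K, n)
        z = (b[0] * z_e + b[1] * z_a)[:, None] + np.sqrt(1.0 - v) * u

        repeated = reference.sequence.count(backbone) > 1
        for j, n_hyp in enumerate(counts):
            mu = rng.normal(10.0, 1.0)
            values = np.exp(mu + params.log_sigma * z[:, j])
            if params.censor_quantile > 0:
                thr = np.quantile(values, params.censor_quantile)
                keep = values > thr
            else:
                keep = np.ones(n, dtype=bool)
            modified = _modify(backbone, n_hyp)
            records.append(PeptideRecord(
                modified,
                {ids[i]: float(values[i]) for i in range(n) if keep[i]}))
            truth.variants.append(VariantTruth(
                modified, backbone, frag_id, start, start + len(backbone) - 1,
                n_hyp, effect, rho_e.get(effect, 0.0), repeated))
    return records, truth


def fig1_scenario(n_singletons: int = 359,
                  n_mergeable: int = 55,
                  n_nonmergeable: int = 89,
                  n_mergeable_peptides: int | None = None,
                  n_nonmergeable_peptides: int | None = None,
                  n_participants: int = 300,
                  reference: ReferenceProtein | None = None,
                  seed: int = 0) -> list[PeptideRecord]:
    """Plant an exact consolidation group structure.

    Produces ``n_singletons`` single-variant backbones, ``n_mergeable``
    multi-variant groups whose variants are near-perfectly correlated
    (every pair lands far above the 0.5 merge threshold) and
    ``n_nonmergeable`` groups of mutually independent variants (every pair
    far below it), so consolidation must yield ``n_singletons +
    n_mergeable + n_nonmergeable`` unique backbones.  Peptide totals per
    multi-variant tier default to the published flow at the default group
    counts, otherwise to two variants per group.
    """
    published_flow = (n_singletons, n_mergeable, n_nonmergeable) == (359, 55, 89)
    if n_mergeable_peptides is None:
        n_mergeable_peptides = 119 if published_flow else 2 * n_mergeable
    if n_nonmergeable_peptides is None:
        n_nonmergeable_peptides = 229 if published_flow else 2 * n_nonmergeable
    if n_mergeable and n_mergeable_peptides < 2 * n_mergeable:
        raise ValueError("mergeable tier needs >= 2 peptides per group")
    if n_nonmergeable and n_nonmergeable_peptides < 2 * n_nonmergeable:
        raise ValueError("non-mergeable tier needs >= 2 peptides per group")
    if reference is None:
        from .peptide_model import bundled_reference
        reference = bundled_reference()

    rng = np.random.default_rng([seed, 37])
    n_groups = n_singletons + n_mergeable + n_nonmergeable

    def sizes(n_groups: int, n_peptides: int) -> list[int]:
        out = [2] * n_groups
        extra = n_peptides - 2 * n_groups
        i = 0
        while extra > 0:
            out[i % n_groups] += 1
            extra -= 1
            i += 1
        return out

    plan = ([("single", 1)] * n_singletons
            + [("merge", k) for k in sizes(n_mergeable, n_mergeable_peptides)]
            + [("split", k) for k in sizes(n_nonmergeable,
                                           n_nonmergeable_peptides)])

    taken: set[str] = set()
    ids = [f"S{i:04d}" for i in range(n_participants)]
    records: list[PeptideRecord] = []
    for kind, n_var in plan:
        got = _sample_fragment(rng, reference, 10, 35, max(n_var, 1), taken)
        if got is None:
            raise RuntimeError("reference exhausted while planting groups")
        backbone, _ = got
        taken.add(backbone)
        counts = _hyp_counts(rng, n_var, backbone.count("P"))
        if kind == "merge":
            shared = rng.standard_normal(n_participants)
            z = (np.sqrt(0.95) * shared[:, None]
                 + np.sqrt(0.05) * rng.standard_normal((n_participants, n_var)))
        else:
            z = rng.standard_normal((n_participants, n_var))
        for j, n_hyp in enumerate(counts):
            values = np.exp(10.0 + z[:, j])
            records.append(PeptideRecord(
                _modify(backbone, n_hyp),
                dict(zip(ids, map(float, values)))))
    assert len(records) == (n_singletons + n_mergeable_peptides
                            + n_nonmergeable_peptides)
    return records
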