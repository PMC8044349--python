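"""Synthetic-cohort generator: determinism, invariants, planted effects."""

import numpy as np
import pytest

from strucnet.cohort import (
    CohortSpec,
    EffectProfile,
    apply_effect,
    bc_reduction_profile,
    default_effect_profiles,
    generate_cohort,
    hub_knockout_profiles,
    identity_profile,
    make_base_template,
    manifest_frame,
    sample_covariates,
)


def test_same_seed_reproduces_cohort_exactly():
    spec = CohortSpec(n_per_group={"AD": 4, "NC": 4}, n_nodes=40, n_modules=4, seed=1)
    subs_a, truth_a = generate_cohort(spec)
    subs_b, truth_b = generate_cohort(spec)
    assert np.array_equal(truth_a.base_template, truth_b.base_template)
    for sa, sb in zip(subs_a, subs_b):
        assert sa.subject_id == sb.subject_id
        assert sa.age == sb.age and sa.sex == sb.sex and sa.education == sb.education
        assert np.array_equal(sa.counts, sb.counts)
    pd_a = manifest_frame(subs_a)
    pd_b = manifest_frame(subs_b)
    assert pd_a.equals(pd_b)


def test_cohort_counts_symmetric_nonnegative_zero_diagonal(default_cohort):
    _, subjects, _ = default_cohort
    assert len(subjects) == 18
    for s in subjects:
        assert np.array_equal(s.counts, s.counts.T)
        assert np.all(np.diagonal(s.counts) == 0)
        assert np.all(s.counts >= 0)
        assert np.issubdtype(s.counts.dtype, np.integer)


def test_saturated_probabilities_force_complete_binary_graph(rng):
    spec = CohortSpec(
        n_per_group={"g": 2},
        n_nodes=20,
        n_modules=2,
        intra_module_edge_prob=1.0,
        inter_module_edge_prob=1.0,
        count_mean=200.0,
        count_dispersion=20.0,
        seed=0,
    )
    base = make_base_template(spec, rng)
    adj = base > 3
    off = ~np.eye(20, dtype=bool)
    assert adj[off].all()


def test_zero_inter_module_probability_is_degenerate(rng):
    spec = CohortSpec(
        n_per_group={"g": 2},
        n_nodes=20,
        n_modules=2,
        inter_module_edge_prob=0.0,
        seed=0,
    )
    with pytest.raises(RuntimeError, match="disconnected"):
        make_base_template(spec, rng, max_redraws=5)


def test_identity_profile_with_zero_noise_returns_base(rng):
    spec = CohortSpec(n_per_group={"g": 2}, n_nodes=30, n_modules=3, seed=3)
    base = make_base_template(spec, rng)
    out = apply_effect(base, identity_profile, rng, noise_sigma=0.0)
    assert np.array_equal(out, base)


def test_block_factor_scales_counts_elementwise(rng):
    spec = CohortSpec(n_per_group={"g": 2}, n_nodes=30, n_modules=3, seed=3)
    base = make_base_template(spec, rng)
    block_a, block_b = tuple(range(0, 5)), tuple(range(5, 10))
    prof = EffectProfile(attenuated_blocks=((block_a, block_b, 0.3),))
    out = apply_effect(base, prof, rng, noise_sigma=0.0)
    sub = np.ix_(block_a, block_b)
    assert np.array_equal(out[sub], np.rint(0.3 * base[sub]).astype(int))
    # everything outside the block untouched
    mask = np.ones_like(base, dtype=bool)
    mask[sub] = False
    mask[np.ix_(block_b, block_a)] = False
    assert np.array_equal(out[mask], base[mask])


def test_zero_factor_empties_block(rng):
    spec = CohortSpec(n_per_group={"g": 2}, n_nodes=30, n_modules=3, seed=3)
    base = make_base_template(spec, rng)
    prof = EffectProfile(attenuated_blocks=(((0, 1, 2), (3, 4, 5), 0.0),))
    out = apply_effect(base, prof, rng, noise_sigma=0.0)
    assert np.all(out[np.ix_((0, 1, 2), (3, 4, 5))] == 0)


def test_attenuation_monotone_in_factor(rng):
    spec = CohortSpec(n_per_group={"g": 2}, n_nodes=30, n_modules=3, seed=3)
    base = make_base_template(spec, rng)
    block = (tuple(range(10)), tuple(range(10, 20)))
    means = []
    for f in (0.2, 0.5, 0.9):
        prof = EffectProfile(attenuated_blocks=((*block, f),))
        out = apply_effect(base, prof, rng, noise_sigma=0.0)
        means.append(out[np.ix_(*block)].mean())
    assert means[0] <= means[1] <= means[2]


def test_node_swap_moves_hub_connections(rng):
    spec = CohortSpec(n_per_group={"g": 2}, n_nodes=30, n_modules=3, seed=3)
    base = make_base_template(spec, rng)
    ref, ko = hub_knockout_profiles(base, targets=[4])
    ref_counts = apply_effect(base, ref, rng, noise_sigma=0.0)
    ko_counts = apply_effect(base, ko, rng, noise_sigma=0.0)
    spare = ko.node_swaps[0][1]
    assert np.all(ko_counts[4] == 0)  # target knocked out
    others = [i for i in range(30) if i not in (4, spare)]
    # spare inherited the target's connections to everyone else
    assert np.array_equal(ko_counts[spare][others], ref_counts[4][others])
    # the two graphs are isomorphic under the transposition
    perm = np.arange(30)
    perm[4], perm[spare] = spare, 4
    assert np.array_equal(ko_counts, ref_counts[np.ix_(perm, perm)])


def test_covariate_sampling_matches_group_moments():
    spec = CohortSpec(seed=0)
    rng = np.random.default_rng(5)
    ages = np.array([sample_covariates("AD", spec, rng)[0] for _ in range(20000)])
    se = 8.90 / np.sqrt(len(ages))
    assert abs(ages.mean() - 72.19) < 2 * se + 0.05  # small truncation shift allowed
    females = sum(sample_covariates("NC", spec, rng)[1] == "F" for _ in range(10000))
    frac = females / 10000
    assert abs(frac - 11 / 17) < 3 * np.sqrt((11 / 17) * (6 / 17) / 10000)


def test_degenerate_zero_variance_covariates():
    from strucnet.cohort import CovariateModel

    spec = CohortSpec(
        covariate_models={"NC": CovariateModel(70.0, 0.0, 12.0, 0.0, 1.0)}, seed=0
    )
    rng = np.random.default_rng(0)
    for _ in range(5):
        age, sex, edu = sample_covariates("NC", spec, rng)
        assert age == 70.0 and edu == 12.0 and sex == "F"


def test_unknown_group_raises():
    spec = CohortSpec(seed=0)
    with pytest.raises(KeyError):
        sample_covariates("XX", spec, np.random.default_rng(0))


def test_default_ad_profile_attenuates_temporal_occipital_block():
    spec = CohortSpec(n_per_group={"AD": 8, "NC": 8}, seed=21)
    subs, truth = generate_cohort(spec)
    mods = spec.module_nodes()
    sub = np.ix_(mods["temporal"], mods["occipital"])
    ad = np.mean([s.counts[sub].mean() for s in subs if s.group == "AD"])
    nc = np.mean([s.counts[sub].mean() for s in subs if s.group == "NC"])
    assert ad < nc
    # ground truth records the planted edges with their factors
    assert truth.perturbed_edges["AD"]
    assert all(f != 1.0 for _, _, f in truth.perturbed_edges["AD"])
    base = truth.base_template
    assert all(base[i, j] > 0 for i, j, _ in truth.perturbed_edges["AD"])


def test_profile_validation_rejects_bad_indices_and_factors():
    with pytest.raises(ValueError):
        EffectProfile(attenuated_blocks=(((0,), (99,), 0.5),)).validate(10)
    with pytest.raises(ValueError):
        EffectProfile(attenuated_blocks=(((0,), (1,), 1.5),)).validate(10)
    with pytest.raises(ValueError):
        EffectProfile(node_swaps=((3, 3),)).validate(10)
    bc_reduction_profile([0, 5], 0.1, 10).validate(10)  # valid constructions pass
    default_effect_profiles(CohortSpec())["SIVD"].validate(90)
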