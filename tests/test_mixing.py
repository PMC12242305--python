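"""Mixing-model likelihood, sampler and convergence diagnostics.

The likelihood is checked against an independently coded brute-force density
(explicit per-observation scipy logpdf loop, no shared code with the
implementation); sampler checks use symmetry, degenerate cases and seeded
parameter recovery.
"""

import numpy as np
import pytest
from scipy import stats

from isocline.data_model import SourceDistribution
from isocline.mixing import (
    McmcSettings,
    MixingProblem,
    TracerTEF,
    _stick_forward,
    build_likelihood,
    gelman_rubin,
    geweke_z,
    fingerprint_foraging,
    sample_posterior,
)
from isocline.synthetic import MixtureSpec, generate_mixture_consumers

FAST = McmcSettings(n_chains=3, n_iter=12_000, burn_in=6_000, thin=10, seed=11)


def brute_force_logdensity(p, xi, consumers, sources, lam, tau):
    """Independent oracle: loop over observations and tracers with scipy."""
    p = np.asarray(p)
    total = 0.0
    for row in np.atleast_2d(consumers):
        for j, x in enumerate(row):
            mus = [[s.mu_d13c, s.mu_d15n][j] + lam[j] for s in sources]
            sds = [[s.sd_d13c, s.sd_d15n][j] for s in sources]
            mean = sum(pk * m for pk, m in zip(p, mus))
            var = sum(pk**2 * (sd**2 + tau[j] ** 2) for pk, sd in zip(p, sds))
            var += xi[j] ** 2
            total += stats.norm.logpdf(x, mean, np.sqrt(var))
    return total


# ------------------------------------------------------------ stick transform


def test_stick_transform_is_simplex_bijection():
    rng = np.random.default_rng(0)
    z = rng.normal(size=(200, 4))
    p, logj = _stick_forward(z)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(p > 0)
    assert np.all(np.isfinite(logj))
    # z = 0 maps to the uniform point
    p0, _ = _stick_forward(np.zeros(4))
    assert np.allclose(p0, 0.2)


def test_stick_jacobian_matches_numerical():
    rng = np.random.default_rng(1)
    for _ in range(5):
        z = rng.normal(size=3)
        _, logj = _stick_forward(z)
        eps = 1e-6
        J = np.empty((3, 3))
        for i in range(3):
            zp, zm = z.copy(), z.copy()
            zp[i] += eps
            zm[i] -= eps
            pp, _ = _stick_forward(zp)
            pm, _ = _stick_forward(zm)
            J[:, i] = (pp[:3] - pm[:3]) / (2 * eps)
        num = np.log(abs(np.linalg.det(J)))
        assert logj == pytest.approx(num, abs=1e-4)


# ---------------------------------------------------------------- likelihood


def test_likelihood_single_source_independent_of_p():
    src = [SourceDistribution("only", "x", 5, -20.0, 1.0, 8.0, 1.0)]
    prob = MixingProblem(
        consumers=np.array([[-19.0, 10.0]]), sources=src,
        fixed_xi=np.array([0.5, 0.5]),
    )
    f = build_likelihood(prob)
    expected = brute_force_logdensity(
        [1.0], [0.5, 0.5], prob.consumers, src, prob.tef.lam, prob.tef.tau
    )
    assert f([1.0]) == pytest.approx(expected, abs=1e-10)


def test_likelihood_symmetric_two_source_peaks_at_half():
    srcs = [
        SourceDistribution("A", "x", 5, 0.0, 0.0, 0.0, 0.0),
        SourceDistribution("B", "x", 5, 10.0, 0.0, 0.0, 0.0),
    ]
    prob = MixingProblem(
        consumers=np.array([[5.0]]), sources=srcs,
        tef=TracerTEF((0.0,), (0.0,)), fixed_xi=np.array([1.0]),
    )
    f = build_likelihood(prob)
    grid = np.linspace(0.01, 0.99, 99)
    vals = [f([a, 1 - a]) for a in grid]
    assert grid[int(np.argmax(vals))] == pytest.approx(0.5, abs=0.011)


def test_likelihood_grid_matches_bruteforce_oracle():
    """101-point simplex grid agreement to 1e−10 on a K=2, J=1 problem."""
    srcs = [
        SourceDistribution("A", "x", 5, -24.0, 1.1, 0.0, 0.0),
        SourceDistribution("B", "x", 5, -16.0, 0.7, 0.0, 0.0),
    ]
    consumers = np.array([[-21.0], [-19.5], [-18.0]])
    prob = MixingProblem(
        consumers=consumers, sources=srcs,
        tef=TracerTEF((0.4,), (0.2,)), fixed_xi=np.array([0.6]),
    )
    f = build_likelihood(prob)
    for a in np.linspace(0.0, 1.0, 101)[1:-1]:
        ours = f([a, 1 - a])
        oracle = brute_force_logdensity(
            [a, 1 - a], [0.6], consumers, srcs, [0.4], [0.2]
        )
        assert ours == pytest.approx(oracle, abs=1e-10)


def test_likelihood_outside_simplex_is_minus_inf():
    srcs = [
        SourceDistribution("A", "x", 5, 0.0, 1.0, 0.0, 1.0),
        SourceDistribution("B", "x", 5, 5.0, 1.0, 5.0, 1.0),
    ]
    prob = MixingProblem(consumers=np.array([[2.0, 2.0]]), sources=srcs,
                         fixed_xi=np.array([1.0, 1.0]))
    f = build_likelihood(prob)
    assert f([-0.1, 1.1]) == -np.inf
    assert f([0.7, 0.7]) == -np.inf


def test_process_only_zero_variance_advises_residual():
    srcs = [
        SourceDistribution("A", "x", 5, 0.0, 0.0, 0.0, 0.0),
        SourceDistribution("B", "x", 5, 5.0, 0.0, 5.0, 0.0),
    ]
    prob = MixingProblem(
        consumers=np.array([[2.0, 2.0]]), sources=srcs,
        tef=TracerTEF((0.0, 0.0), (0.0, 0.0)), error_model="process",
    )
    with pytest.raises(ValueError, match="residual"):
        build_likelihood(prob)


# ------------------------------------------------------------------ sampler


def test_single_source_posterior_degenerate():
    src = [SourceDistribution("only", "x", 5, -20.0, 1.0, 8.0, 1.0)]
    prob = MixingProblem(consumers=np.array([[-19.0, 10.0]]), sources=src,
                         fixed_xi=np.array([1.0, 1.0]))
    post = sample_posterior(prob, FAST)
    assert post.mean[0] == 1.0 and post.sd[0] == 0.0


def test_symmetric_problem_recovers_half():
    srcs = [
        SourceDistribution("A", "x", 5, 0.0, 0.0, 0.0, 0.0),
        SourceDistribution("B", "x", 5, 10.0, 0.0, 0.0, 0.0),
    ]
    prob = MixingProblem(
        consumers=np.array([[5.0]]), sources=srcs,
        tef=TracerTEF((0.0,), (0.0,)), fixed_xi=np.array([1.0]),
    )
    post = sample_posterior(prob, FAST)
    assert post.mean[0] == pytest.approx(0.5, abs=0.05)
    assert max(post.rhat.values()) < 1.05


def test_posterior_draws_on_simplex_and_quantiles_ordered(separated_sources):
    spec = MixtureSpec((0.6, 0.3, 0.1), 30, ("s1", "s2", "s3"),
                       residual=(0.5, 0.5))
    obs, _ = generate_mixture_consumers(spec, separated_sources, seed=3)
    post = sample_posterior(
        MixingProblem(consumers=obs, sources=separated_sources), FAST
    )
    assert np.allclose(post.draws.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(np.diff(post.percentiles, axis=0) >= 0)
    assert np.all(post.percentiles >= 0) and np.all(post.percentiles <= 1)
    assert post.mean.sum() == pytest.approx(1.0, abs=1e-6)
    assert post.n_retained == 3 * 600


def test_parameter_recovery_seeded(separated_sources):
    spec = MixtureSpec((0.6, 0.3, 0.1), 30, ("s1", "s2", "s3"),
                       residual=(0.5, 0.5))
    obs, truth = generate_mixture_consumers(spec, separated_sources, seed=7)
    post = sample_posterior(
        MixingProblem(consumers=obs, sources=separated_sources), FAST
    )
    for k in range(3):
        assert post.mean[k] == pytest.approx(truth[k], abs=0.10)
        lo, hi = post.credible_interval(k)
        assert lo <= truth[k] <= hi


def test_source_order_permutation_equivariance(separated_sources):
    spec = MixtureSpec((0.6, 0.3, 0.1), 20, ("s1", "s2", "s3"),
                       residual=(0.5, 0.5))
    obs, _ = generate_mixture_consumers(spec, separated_sources, seed=5)
    post_a = sample_posterior(
        MixingProblem(consumers=obs, sources=separated_sources), FAST
    )
    perm = [2, 0, 1]
    post_b = sample_posterior(
        MixingProblem(consumers=obs, sources=[separated_sources[i] for i in perm]),
        FAST,
    )
    # same problem up to relabeling: posterior means agree within MC error
    for out_idx, src_idx in enumerate(perm):
        assert post_b.mean[out_idx] == pytest.approx(post_a.mean[src_idx], abs=0.03)
    assert post_b.source_ids == tuple(separated_sources[i].source_id for i in perm)


def test_sampler_reproducible_for_seed(separated_sources):
    spec = MixtureSpec((0.5, 0.3, 0.2), 10, ("s1", "s2", "s3"),
                       residual=(0.5, 0.5))
    obs, _ = generate_mixture_consumers(spec, separated_sources, seed=9)
    prob = MixingProblem(consumers=obs, sources=separated_sources)
    a = sample_posterior(prob, FAST)
    b = sample_posterior(prob, FAST)
    assert np.array_equal(a.draws, b.draws)


def test_prior_recovery_large_residual(separated_sources):
    """With a huge fixed residual scale the posterior reverts to Dirichlet(1)."""
    prob = MixingProblem(
        consumers=np.array([[-20.0, 8.0]]), sources=separated_sources,
        fixed_xi=np.array([1e4, 1e4]),
    )
    post = sample_posterior(prob, FAST)
    assert np.allclose(post.mean, 1 / 3, atol=0.05)


# -------------------------------------------------------------- diagnostics


def test_gelman_rubin_identical_constant_chains():
    assert gelman_rubin(np.ones((3, 50))) == 1.0


def test_gelman_rubin_same_distribution_near_one():
    rng = np.random.default_rng(4)
    chains = rng.normal(size=(2, 10_000))
    assert gelman_rubin(chains) < 1.05


def test_gelman_rubin_separated_means_large():
    rng = np.random.default_rng(5)
    chains = np.vstack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
    assert gelman_rubin(chains) > 3


def test_gelman_rubin_requires_two_chains():
    with pytest.raises(ValueError):
        gelman_rubin(np.ones((1, 100)))


def test_geweke_stationary_chain_small_z():
    rng = np.random.default_rng(6)
    zs = [abs(geweke_z(rng.normal(size=4000))) for _ in range(20)]
    assert np.mean(np.asarray(zs) < 2.5) >= 0.9


def test_geweke_drifting_chain_large_z():
    drift = np.linspace(0, 5, 4000) + np.random.default_rng(7).normal(size=4000)
    assert abs(geweke_z(drift)) > 3


# ------------------------------------------------------------ fingerprinting


def test_fingerprint_consumer_at_source_mean(separated_sources):
    """A consumer placed exactly at one source's TEF-shifted mean dominates."""
    from isocline.data_model import SpecimenRecord, YearSpec

    tef = TracerTEF((0.0, 2.0), (0.0, 0.0))
    tight = [
        type(s)(s.source_id, s.region_label, s.n, s.mu_d13c, 0.1, s.mu_d15n, 0.1)
        for s in separated_sources
    ]
    target = tight[1]
    rec = SpecimenRecord(
        "SYN.at.s2", "sp", "x", YearSpec("exact", 1900),
        d15n=target.mu_d15n + 2.0, d13c_se=target.mu_d13c,
        d13c_normalized=target.mu_d13c,
    )
    out = fingerprint_foraging(
        [rec], tight, FAST, tef, regions=None,
        era_correct_sources=False, resid_scale=0.1,
    )
    post, dominant = out["SYN.at.s2"]
    assert dominant == "s2"
    assert post.mean[1] > 0.9


def test_fingerprint_humboldt_consumer_against_krill_panel():
    """A consumer carrying the Humboldt-krill signature is assigned to it."""
    from isocline.data_model import SpecimenRecord, YearSpec, load_sources

    srcs = load_sources("blue_whale")
    hum = next(s for s in srcs if "mucronata" in s.source_id)
    rec = SpecimenRecord(
        "SYN.pygmy", "Balaenoptera musculus", "x", YearSpec("exact", 1900),
        d15n=hum.mu_d15n + 2.03, d13c_se=hum.mu_d13c,
        d13c_normalized=hum.mu_d13c,
    )
    out = fingerprint_foraging([rec], srcs, FAST, era_correct_sources=False)
    post, dominant = out["SYN.pygmy"]
    assert dominant == hum.source_id
    assert post.mean[post.source_ids.index(hum.source_id)] > 0.5


def test_fingerprint_equidistant_consumer_stays_mixed():
    """A consumer midway between two sources dominates neither."""
    from isocline.data_model import SpecimenRecord, YearSpec

    srcs = [
        SourceDistribution("A", "x", 5, -24.0, 0.5, 4.0, 0.5),
        SourceDistribution("B", "x", 5, -16.0, 0.5, 12.0, 0.5),
    ]
    tef = TracerTEF((0.0, 0.0), (0.0, 0.0))
    rec = SpecimenRecord(
        "SYN.mid", "sp", "x", YearSpec("exact", 1900),
        d15n=8.0, d13c_se=-20.0, d13c_normalized=-20.0,
    )
    out = fingerprint_foraging(
        [rec], srcs, FAST, tef, era_correct_sources=False, resid_scale=1.0,
        dominance_threshold=0.6,
    )
    post, dominant = out["SYN.mid"]
    assert dominant == "mixed"
    assert 0.25 <= post.mean[0] <= 0.75 and 0.25 <= post.mean[1] <= 0.75


def test_fingerprint_skips_uncorrected_records():
    from isocline.data_model import SpecimenRecord, YearSpec

    rec = SpecimenRecord("no-se", "sp", "x", YearSpec("exact", 1900), d15n=8.0)
    with pytest.warns(UserWarning, match="skipped"):
        out = fingerprint_foraging([rec], [
            SourceDistribution("A", "x", 5, -20.0, 1.0, 8.0, 1.0),
        ], FAST, era_correct_sources=False)
    assert out == {}


def test_mcmc_settings_validation():
    with pytest.raises(ValueError):
        McmcSettings(n_iter=1000, burn_in=2000)
    with pytest.raises(ValueError):
        McmcSettings(n_iter=1000, burn_in=900, thin=50)  # <100 retained
    assert McmcSettings().retained_per_chain == 1000
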