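"""Simulator checks: coalescent moments, mutation model, determinism."""

import io

import numpy as np
import pytest
from scipy import stats

from tspecies import (
    SaturationError,
    SimulationConfig,
    jc_expected_p,
    correct_multiple_hits,
    sample_tmrca,
    simulate_bottleneck_scenario,
    simulate_ks_values,
    simulate_sequence_pairs,
)
from tspecies.coalsim import simulate_loci, write_locus_tsv


@pytest.mark.parametrize(
    "kwargs",
    [
        {"ne": 0},
        {"ne": -5},
        {"mu": 0},
        {"t_div": -1},
        {"seq_len": 0},
        {"n_loci": 0},
        {"bottleneck_fraction": 0.0},
        {"bottleneck_fraction": 1.5},
    ],
)
def test_config_validation(kwargs):
    base = dict(ne=1000.0, mu=1e-8, t_div=1e5)
    base.update(kwargs)
    with pytest.raises(ValueError):
        SimulationConfig(**base)


def test_ms_parameterization_round_trip():
    # theta = 4*Ne*mu (per site), t = T/(4*Ne)
    cfg = SimulationConfig.from_ms_params(theta=0.002, t=5.0, ne=50_000)
    assert cfg.mu == pytest.approx(0.002 / (4 * 50_000))
    assert cfg.t_div == pytest.approx(5.0 * 4 * 50_000)
    assert cfg.ne == 50_000


def test_tmrca_mean_and_variance():
    ne, t_div, n = 50_000.0, 1e6, 100_000
    cfg = SimulationConfig(ne=ne, mu=1e-8, t_div=t_div, n_loci=n)
    tm = sample_tmrca(cfg, np.random.default_rng(0))
    se = tm.std(ddof=1) / np.sqrt(n)
    assert abs(tm.mean() - (t_div + 2 * ne)) < 3 * se
    assert tm.var(ddof=1) == pytest.approx(4 * ne**2, rel=0.05)
    assert tm.min() >= t_div


def test_tmrca_pure_ancestral_coalescent():
    # With t_div=0 every draw is the ancestral exponential, mean 2*Ne.
    cfg = SimulationConfig(ne=500.0, mu=1e-8, t_div=0.0, n_loci=100_000)
    tm = sample_tmrca(cfg, np.random.default_rng(1))
    assert np.all(tm > 0)
    assert tm.mean() == pytest.approx(1000.0, rel=0.02)


def test_tmrca_matches_msprime_split_model():
    """Independent genealogy oracle: a two-population split in msprime."""
    msprime = pytest.importorskip("msprime")
    ne, t_div, reps = 50_000, 1e6, 2000
    dem = msprime.Demography()
    dem.add_population(name="A", initial_size=1000)
    dem.add_population(name="B", initial_size=1000)
    dem.add_population(name="ANC", initial_size=ne)
    dem.add_population_split(time=t_div, derived=["A", "B"], ancestral="ANC")
    tm_ms = np.fromiter(
        (next(ts.trees()).time(ts.first().root) for ts in msprime.sim_ancestry(
            samples=[
                msprime.SampleSet(1, population="A", ploidy=1),
                msprime.SampleSet(1, population="B", ploidy=1),
            ],
            demography=dem, num_replicates=reps, random_seed=99,
        )),
        dtype=float, count=reps,
    )
    cfg = SimulationConfig(ne=ne, mu=1e-8, t_div=t_div, n_loci=reps)
    tm_own = sample_tmrca(cfg, np.random.default_rng(3))
    assert stats.ks_2samp(tm_ms, tm_own).pvalue > 0.01


def test_mean_ks_matches_clock_expectation():
    ne, mu, t_div = 500_000.0, 1e-8, 1e6
    cfg = SimulationConfig(ne=ne, mu=mu, t_div=t_div, seed=5)
    dist = simulate_ks_values(cfg)
    se = dist.values.std(ddof=1) / np.sqrt(dist.n_loci)
    assert abs(dist.mean_ks - 2 * mu * (t_div + 2 * ne)) < 3 * se


def test_tiny_ne_variance_matches_binomial_oracle():
    """At negligible Ne the Ks variance is pure finite-length sampling noise.

    Oracle: fixed TMRCA=T, observed differences drawn binomially with the JC
    site-difference probability, then JC-corrected — brute force, no shared
    code path with the simulator's coalescent machinery.
    """
    mu, t_div, L, n = 1e-8, 1e6, 1000, 40_000
    cfg = SimulationConfig(ne=5.0, mu=mu, t_div=t_div, seq_len=L,
                           n_loci=n, seed=6)
    dist = simulate_ks_values(cfg)
    rng = np.random.default_rng(7)
    p_site = jc_expected_p(2 * mu * t_div)
    ks_oracle = correct_multiple_hits(rng.binomial(L, p_site, size=n) / L)
    assert dist.var_ks == pytest.approx(np.var(ks_oracle, ddof=1), rel=0.1)
    assert dist.mean_ks == pytest.approx(ks_oracle.mean(), rel=0.02)


def test_seeded_determinism_and_tsv_output():
    cfg = SimulationConfig(ne=2e4, mu=1e-8, t_div=1e5, n_loci=500, seed=11)
    a, b = simulate_ks_values(cfg), simulate_ks_values(cfg)
    np.testing.assert_array_equal(a.values, b.values)
    buf_a, buf_b = io.StringIO(), io.StringIO()
    write_locus_tsv(simulate_loci(cfg), buf_a)
    write_locus_tsv(simulate_loci(cfg), buf_b)
    assert buf_a.getvalue() == buf_b.getvalue()
    header = buf_a.getvalue().splitlines()[0]
    assert header.split("\t") == ["locus", "tmrca", "n_diff", "p_dist", "ks"]


def test_saturated_parameters_rejected():
    cfg = SimulationConfig(ne=5e5, mu=1e-7, t_div=1e8)
    with pytest.raises(SaturationError):
        simulate_ks_values(cfg)


def test_sequence_pairs_count_and_length():
    cfg = SimulationConfig(ne=1000, mu=1e-8, t_div=1e4, seq_len=120,
                           n_loci=50, seed=2)
    pairs = simulate_sequence_pairs(cfg)
    assert len(pairs) == 50
    assert all(len(sa) == 120 and len(sb) == 120 for _, sa, _, sb in pairs)
    assert pairs[0][0] == "locus0_A" and pairs[0][2] == "locus0_B"


def test_sequence_pairs_identical_without_mutation():
    cfg = SimulationConfig(ne=1000, mu=1e-30, t_div=1e4, seq_len=100,
                           n_loci=20, seed=2)
    for _, sa, _, sb in simulate_sequence_pairs(cfg):
        assert sa == sb


def test_sequence_path_agrees_with_fast_path():
    """Explicit sequences and the binomial fast path sample the same Ks law."""
    ne, mu, t_div, n = 5e4, 1e-8, 1e6, 5000
    pairs = simulate_sequence_pairs(
        SimulationConfig(ne=ne, mu=mu, t_div=t_div, n_loci=n, seed=21)
    )
    from tspecies import pairwise_p_distance

    ks_seq = np.array(
        [correct_multiple_hits(pairwise_p_distance(sa, sb)[0])
         for _, sa, _, sb in pairs]
    )
    ks_fast = simulate_ks_values(
        SimulationConfig(ne=ne, mu=mu, t_div=t_div, n_loci=n, seed=22)
    ).values
    assert stats.mannwhitneyu(ks_seq, ks_fast).pvalue > 0.01


def test_bottleneck_requires_fraction():
    cfg = SimulationConfig(ne=5e4, mu=1e-8, t_div=1e6)
    with pytest.raises(ValueError, match="bottleneck_fraction"):
        simulate_bottleneck_scenario(cfg)


@pytest.mark.parametrize("fraction", [1.0, 0.1])
def test_bottleneck_leaves_ks_distribution_unchanged(fraction):
    # One lineage per species: a daughter-population size change cannot touch
    # the genealogy, so the Ks law matches the constant-size fast path.
    base = dict(ne=5e4, mu=1e-8, t_div=1e6, n_loci=8000)
    dist_b = simulate_bottleneck_scenario(
        SimulationConfig(**base, seed=31, bottleneck_fraction=fraction)
    )
    dist_0 = simulate_ks_values(SimulationConfig(**base, seed=32))
    assert stats.ks_2samp(dist_b.values, dist_0.values).pvalue > 0.01


def test_variance_decomposition_coalescent_dominates_at_large_ne():
    """Var(Ks) ~ 16 mu^2 Ne^2 + finite-length noise; the coalescent term
    carries >= 95% of the total at Ne=5e5, mu=1e-8."""
    ne, mu = 500_000.0, 1e-8
    cfg = SimulationConfig(ne=ne, mu=mu, t_div=1e6, n_loci=100_000, seed=41)
    var_total = simulate_ks_values(cfg).var_ks
    # remove the coalescent part by freezing tmrca at its mean
    rng = np.random.default_rng(42)
    p_site = jc_expected_p(2 * mu * (1e6 + 2 * ne))
    ks_fixed = correct_multiple_hits(
        rng.binomial(1000, p_site, size=100_000) / 1000
    )
    noise = np.var(ks_fixed, ddof=1)
    assert (var_total - noise) / var_total >= 0.85
    assert var_total == pytest.approx(16 * mu**2 * ne**2 + noise, rel=0.1)
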