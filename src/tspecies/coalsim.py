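"""Coalescent simulation of ortholog divergence between two sister species.

Model: two species split ``T`` generations ago from a single panmictic
ancestral population of constant diploid size ``Ne``.  One lineage is sampled
per species, so the two lineages can only coalesce in the ancestral
population; their TMRCA is ``T + c`` with ``c ~ Exponential(mean 2·Ne)``.
No migration, recombination or selection; time is treated as continuous.

Sequence divergence is neutral Jukes–Cantor: substitution events at rate
``mu`` per site per generation accumulate over the two branches (total path
length ``2·TMRCA``), multiple hits at a site collapse through the JC jump
chain.  Summing JC jumps over a Poisson number of events gives the closed
form ``P(site differs) = 3/4·(1 − exp(−8·mu·tmrca/3))``, so the fast path
draws the observed difference count per locus as a single binomial — exactly
equivalent to placing Poisson substitution events uniformly over sites.

This yields the two moments the rest of the package lives on::

    E[Ks]   = 2·mu·(T + 2·Ne)
    Var(Ks) = 16·mu²·Ne²  +  finite-length sampling noise

The ``ms`` parameterization (θ = 4·Ne·mu per site, t = T/(4·Ne)) is accepted
as an alternative input via :meth:`SimulationConfig.from_ms_params`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ksdist import (
    KsDistribution,
    SaturationError,
    SATURATION_P,
    correct_multiple_hits,
    jc_expected_p,
)

#: Expected p-distance above this leaves no Monte-Carlo headroom before the
#: Jukes–Cantor pole at 3/4; parameters implying more are outside model validity.
P_EXPECTATION_GUARD = 0.70

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation scenario: a single cell of the (Ne, mu, T) grid.

    Parameters
    ----------
    ne : float
        Ancestral effective population size (diploid individuals).
    mu : float
        Substitution rate per site per generation.
    t_div : float
        Species divergence time in generations.
    seq_len : int
        Locus length L in bp (default 1,000).
    n_loci : int
        Number of ortholog pairs (default 10,000).
    seed : int, optional
        Master RNG seed; per-locus draws derive deterministically from it.
    bottleneck_fraction : float, optional
        Post-divergence size fraction for one daughter population, in (0, 1];
        1.0 means constant size.  Only used by
        :func:`simulate_bottleneck_scenario`.
    """

    ne: float
    mu: float
    t_div: float
    seq_len: int = 1000
    n_loci: int = 10000
    seed: int | None = None
    bottleneck_fraction: float | None = None

    def __post_init__(self):
        if not self.ne > 0:
            raise ValueError("ne must be > 0")
        if not self.mu > 0:
            raise ValueError("mu must be > 0")
        if self.t_div < 0:
            raise ValueError("t_div must be >= 0")
        if int(self.seq_len) < 1:
            raise ValueError("seq_len must be >= 1")
        if int(self.n_loci) < 1:
            raise ValueError("n_loci must be >= 1")
        bf = self.bottleneck_fraction
        if bf is not None and not (0 < bf <= 1.0):
            raise ValueError("bottleneck_fraction must be in (0, 1]")

    @classmethod
    def from_ms_params(cls, theta: float, t: float, ne: float, **kwargs):
        """Build a config from Hudson's ``ms`` units.

        ``theta = 4·Ne·mu`` (per site) and ``t = T/(4·Ne)``; with ``ne`` given,
        these convert to the native ``(ne, mu, t_div)`` parameterization.
        """
        if theta <= 0 or t < 0 or ne <= 0:
            raise ValueError("theta and ne must be > 0, t >= 0")
        return cls(ne=ne, mu=theta / (4.0 * ne), t_div=t * 4.0 * ne, **kwargs)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def sample_tmrca(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw per-locus gene divergence times (generations), one per locus.

    With one lineage per species, TMRCA = ``t_div + c`` where ``c`` is
    exponential with mean ``2·ne`` (coalescence only in the ancestral
    population).
    """
    return config.t_div + rng.exponential(2.0 * config.ne, size=config.n_loci)


def _check_expectation(config: SimulationConfig) -> None:
    p_exp = jc_expected_p(2.0 * config.mu * (config.t_div + 2.0 * config.ne))
    if p_exp > P_EXPECTATION_GUARD:
        raise SaturationError(
            f"expected p-distance {p_exp:.3f} exceeds {P_EXPECTATION_GUARD}: "
            "parameters are outside the multiple-hit correction's validity"
        )


def _finish_loci(config: SimulationConfig, tmrca: np.ndarray,
                 d_total: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Shared tail of the fast paths: collapse hits, correct, tabulate."""
    L = int(config.seq_len)
    p_site = jc_expected_p(d_total)
    n_diff = rng.binomial(L, p_site)
    p_hat = n_diff / L
    ks = np.full(config.n_loci, np.nan)
    unsat = p_hat < SATURATION_P
    ks[unsat] = correct_multiple_hits(p_hat[unsat])
    return pd.DataFrame(
        {
            "locus": np.arange(config.n_loci),
            "tmrca": tmrca,
            "n_diff": n_diff,
            "p_dist": p_hat,
            "ks": ks,
        }
    )


def simulate_loci(config: SimulationConfig,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate per-locus results; columns ``locus, tmrca, n_diff, p_dist, ks``.

    ``ks`` is NaN for (vanishingly rare) saturated loci.
    """
    _check_expectation(config)
    rng = config.rng() if rng is None else rng
    tmrca = sample_tmrca(config, rng)
    return _finish_loci(config, tmrca, 2.0 * config.mu * tmrca, rng)


def _table_to_dist(config: SimulationConfig, table: pd.DataFrame) -> KsDistribution:
    ks = table["ks"].to_numpy()
    good = np.isfinite(ks)
    return KsDistribution(
        values=ks[good],
        mu_per_gen=config.mu,
        source="simulator",
        n_dropped=int((~good).sum()),
        loci=table,
    )


def simulate_ks_values(config: SimulationConfig) -> KsDistribution:
    """Fast-path simulation: Ks values without explicit sequences.

    Per locus: draw TMRCA, draw the observed-difference count under JC
    multiple-hit collapse, apply the JC correction.  Deterministic given
    ``config.seed``.
    """
    return _table_to_dist(config, simulate_loci(config))


def simulate_bottleneck_scenario(config: SimulationConfig) -> KsDistribution:
    """Simulate a post-divergence bottleneck in one daughter population.

    After the split, one daughter population drops instantaneously to
    ``bottleneck_fraction`` of the ancestral size.  With a single lineage
    sampled per species no coalescence can happen inside a daughter
    population, so the size change cannot alter the genealogy: the TMRCA
    distribution and branch lengths are unchanged.  The daughter-phase and
    ancestral-phase mutation accumulation are nevertheless composed explicitly
    here; the scenario exists to confirm the estimator is insensitive to
    post-divergence size dynamics.

    Raises
    ------
    ValueError
        If ``bottleneck_fraction`` is not set.
    """
    if config.bottleneck_fraction is None:
        raise ValueError("bottleneck_fraction must be set for this scenario")
    _check_expectation(config)
    rng = config.rng()
    tmrca = sample_tmrca(config, rng)
    # Per-lineage daughter-phase branches (mutation rate per generation does
    # not depend on population size) plus the shared ancestral phase.
    d_daughter_a = config.mu * config.t_div
    d_daughter_b = config.mu * config.t_div
    d_ancestral = 2.0 * config.mu * (tmrca - config.t_div)
    d_total = d_daughter_a + d_daughter_b + d_ancestral
    return _table_to_dist(config, _finish_loci(config, tmrca, d_total, rng))


def _mutate_branch(seq: np.ndarray, d: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Evolve sequences (n_loci × L uint8) along branches of length d (subs/site)."""
    q = jc_expected_p(d)[:, None]
    hit = rng.random(seq.shape) < q
    # JC: a substituted site ends in one of the other three bases uniformly.
    offset = rng.integers(1, 4, size=seq.shape, dtype=np.uint8)
    return np.where(hit, (seq + offset) % 4, seq)


def simulate_sequence_pairs(
    config: SimulationConfig,
    path=None,
    paired_paths: tuple | None = None,
):
    """Simulate explicit aligned ortholog pairs under the same model.

    A random ancestral sequence per locus is mutated independently along each
    of the two branches (each of length TMRCA generations) under Jukes–Cantor
    dynamics.  Output records are named ``locus<i>_A`` / ``locus<i>_B``.

    Parameters
    ----------
    path : path-like, optional
        Write all pairs to a single FASTA file.
    paired_paths : (path, path), optional
        Write the A and B sides to two parallel FASTA files instead.

    Returns
    -------
    list of (id_a, seq_a, id_b, seq_b) when no output path is given,
    otherwise the path(s) written.
    """
    if path is not None and paired_paths is not None:
        raise ValueError("give at most one of `path` or `paired_paths`")
    _check_expectation(config)
    rng = config.rng()
    tmrca = sample_tmrca(config, rng)
    d_branch = config.mu * tmrca
    n, L = config.n_loci, int(config.seq_len)
    anc = rng.integers(0, 4, size=(n, L), dtype=np.uint8)
    side_a = _mutate_branch(anc, d_branch, rng)
    side_b = _mutate_branch(anc, d_branch, rng)

    lookup = np.array(list("ACGT"))

    def _records(side, tag):
        for i in range(n):
            yield f"locus{i}_{tag}", "".join(lookup[side[i]])

    if path is None and paired_paths is None:
        return [
            (f"locus{i}_A", "".join(lookup[side_a[i]]),
             f"locus{i}_B", "".join(lookup[side_b[i]]))
            for i in range(n)
        ]

    def _write(fh, records):
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")

    if path is not None:
        with open(path, "w") as fh:
            for (ra, rb) in zip(_records(side_a, "A"), _records(side_b, "B")):
                _write(fh, [ra, rb])
        return Path(path)
    pa, pb = paired_paths
    with open(pa, "w") as fh:
        _write(fh, _records(side_a, "A"))
    with open(pb, "w") as fh:
        _write(fh, _records(side_b, "B"))
    return Path(pa), Path(pb)


def write_locus_tsv(table: pd.DataFrame, path) -> None:
    """Write a per-locus table (``locus, tmrca, n_diff, p_dist, ks``); missing
    values (saturated loci) are written as ``.``."""
    table.to_csv(path, sep="\t", index=False, na_rep=".")
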