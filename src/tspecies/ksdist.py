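"""Per-locus Ks computation and Ks-distribution summaries.

The Ks distribution — one synonymous-divergence value per ortholog pair —
is the raw material for everything downstream: its mean carries the
molecular-clock signal (``E[Ks] = 2·mu·(T + 2·Ne)``) and its variance carries
the ancestral-population signal (``Var(Ks) -> 16·mu²·Ne²`` when the coalescent
variance dominates).

Values can come from three sources:

* the built-in coalescent simulator (:mod:`tspecies.coalsim`),
* aligned ortholog FASTA pairs (p-distance + multiple-hit correction), or
* a precomputed Ks table (e.g. the TSV written by the ``wgd`` pipeline).

For simulated neutral sequences every site evolves at the synonymous rate, so
all-site divergence and Ks are the same quantity; for empirical tables Ks is
whatever the upstream codon-model pipeline produced.  Both are treated
identically downstream.
"""

from __future__ import annotations

import gzip
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Jukes–Cantor saturation bound: an observed p-distance at or above 3/4 has no
#: finite distance estimate.
SATURATION_P = 0.75

#: Default ceiling for Ks values ingested from empirical tables.  Saturated
#: values (wgd caps at Ks ~ 5) destroy the variance estimate.
DEFAULT_KS_CEILING = 5.0

_VALID_BASES = frozenset(b"ACGT")


class SaturationError(ValueError):
    """Raised when a p-distance reaches the multiple-hit correction's pole."""


def jc_expected_p(d):
    """Expected proportion of differing sites after ``d`` substitutions/site.

    Jukes–Cantor forward map ``p(d) = 3/4·(1 − exp(−4d/3))``; inverse of
    :func:`correct_multiple_hits`.
    """
    d = np.asarray(d, dtype=float)
    out = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    return float(out) if out.ndim == 0 else out


def correct_multiple_hits(p):
    """Convert an observed p-distance into substitutions per site.

    Applies the Jukes–Cantor inversion ``d = −(3/4)·ln(1 − 4p/3)``, which
    accounts for repeated substitutions at the same site.  Monotone increasing
    and always ``>= p``.

    Parameters
    ----------
    p : float or array-like
        Proportion of differing sites, ``0 <= p < 3/4``.

    Raises
    ------
    SaturationError
        If any ``p >= 3/4`` (distance not estimable).
    ValueError
        If any ``p < 0``.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0):
        raise ValueError("p-distance must be non-negative")
    if np.any(arr >= SATURATION_P):
        raise SaturationError(
            f"p-distance >= {SATURATION_P}: sequence pair is saturated, "
            "multiple-hit correction is undefined"
        )
    out = -0.75 * np.log1p(-4.0 * arr / 3.0)
    return float(out) if out.ndim == 0 else out


def pairwise_p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Raw proportion of differing sites between two aligned sequences.

    Sites where either sequence carries a gap or an ambiguity code (anything
    outside A/C/G/T, case-insensitive) are excluded from both numerator and
    denominator.

    Returns
    -------
    (p, n_sites) : tuple of (float, int)
        Proportion of differences and the number of comparable sites.

    Raises
    ------
    ValueError
        On unequal lengths or zero comparable sites.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned sequences differ in length ({len(seq_a)} vs {len(seq_b)})"
        )
    a = np.frombuffer(str(seq_a).upper().encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(str(seq_b).upper().encode("ascii"), dtype=np.uint8)
    valid_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    ok = np.isin(a, valid_codes) & np.isin(b, valid_codes)
    n_sites = int(ok.sum())
    if n_sites == 0:
        raise ValueError("no comparable sites (all gapped or ambiguous)")
    n_diff = int((a[ok] != b[ok]).sum())
    return n_diff / n_sites, n_sites


@dataclass
class KsDistribution:
    """Per-locus Ks values with their summary statistics.

    Attributes
    ----------
    values : numpy.ndarray
        One non-negative Ks value (substitutions/site) per ortholog pair.
    mu_per_gen : float, optional
        Substitution rate tag (per site per generation) when known.
    source : str
        ``"simulator"``, ``"fasta"`` or ``"table"``.
    n_dropped : int
        Rows/pairs excluded upstream (saturated, negative, NaN, above ceiling).
    """

    values: np.ndarray
    mu_per_gen: float | None = None
    source: str = "table"
    n_dropped: int = 0
    loci: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.values.size < 2:
            raise ValueError("need at least 2 Ks values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Ks values must be finite")
        if np.any(self.values < 0):
            raise ValueError("Ks values must be non-negative")

    @property
    def n_loci(self) -> int:
        return int(self.values.size)

    @property
    def mean_ks(self) -> float:
        return float(np.mean(self.values))

    @property
    def var_ks(self) -> float:
        """Unbiased (n−1 denominator) sample variance."""
        return float(np.var(self.values, ddof=1))

    def summary_dict(self) -> dict:
        return {
            "n_loci": self.n_loci,
            "mean_ks": self.mean_ks,
            "var_ks": self.var_ks,
            "dropped": self.n_dropped,
        }

    def write_tsv(self, path) -> None:
        """Write per-locus values as a two-column ``locus<TAB>ks`` table."""
        df = pd.DataFrame(
            {"locus": np.arange(self.n_loci), "ks": self.values}
        )
        df.to_csv(path, sep="\t", index=False)

    def write_summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def summarize(
    values: Sequence[float] | np.ndarray,
    mu_per_gen: float | None = None,
    source: str = "table",
    n_dropped: int = 0,
) -> KsDistribution:
    """Build a :class:`KsDistribution` from raw per-locus Ks values.

    Rejects NaN and negative inputs and requires at least two finite values;
    mean and variance are then available as properties (arithmetic mean,
    unbiased sample variance).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 Ks values to summarize")
    if np.any(~np.isfinite(arr)):
        raise ValueError("NaN/inf Ks values are not allowed; filter first")
    if np.any(arr < 0):
        raise ValueError("negative Ks values are not allowed; filter first")
    return KsDistribution(
        values=arr, mu_per_gen=mu_per_gen, source=source, n_dropped=n_dropped
    )


def read_ks_table(
    path,
    column: str = "dS",
    ceiling: float = DEFAULT_KS_CEILING,
    mu_per_gen: float | None = None,
) -> KsDistribution:
    """Load a Ks distribution from a wgd-style TSV/CSV table.

    Keeps finite, non-negative values at or below ``ceiling``; the number of
    dropped rows is logged and recorded on the result.

    Raises
    ------
    ValueError
        If the named column is missing (the error lists available columns) or
        no usable rows remain.
    """
    sep = "," if str(path).endswith((".csv", ".csv.gz")) else "\t"
    df = pd.read_csv(path, sep=sep)
    if column not in df.columns:
        raise ValueError(
            f"column {column!r} not found; available columns: "
            + ", ".join(map(str, df.columns))
        )
    raw = pd.to_numeric(df[column], errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(raw) & (raw >= 0) & (raw <= ceiling)
    dropped = int(raw.size - keep.sum())
    if dropped:
        logger.info(
            "read_ks_table: dropped %d of %d rows (NaN, negative, or Ks > %g)",
            dropped, raw.size, ceiling,
        )
    if keep.sum() < 2:
        raise ValueError(f"fewer than 2 usable Ks values in {path!r}")
    return summarize(
        raw[keep], mu_per_gen=mu_per_gen, source="table", n_dropped=dropped
    )


def _open_maybe_gzip(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    with _open_maybe_gzip(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def read_fasta_pairs(
    path=None,
    paths: tuple | None = None,
    mu_per_gen: float | None = None,
) -> KsDistribution:
    """Compute a Ks distribution from aligned ortholog FASTA pairs.

    Two layouts are accepted:

    * a single FASTA where records pair up by ID as ``<locus>_A`` / ``<locus>_B``
      (the convention the simulator writes), or
    * two parallel FASTA files matched record-by-record (``paths=(a, b)``).

    Per pair: p-distance → Jukes–Cantor multiple-hit correction → Ks.
    Saturated pairs (p ≥ 3/4) are excluded with a warning and counted in
    ``n_dropped``.

    Raises
    ------
    ValueError
        On unpaired records (lists the orphan IDs) or an empty/too-small input.
    """
    if (path is None) == (paths is None):
        raise ValueError("provide exactly one of `path` or `paths`")

    pairs: list[tuple[str, str, str]] = []  # (locus, seq_a, seq_b)
    if path is not None:
        records = _read_fasta(path)
        if not records:
            raise ValueError(f"no FASTA records in {path!r}")
        by_locus: dict[str, dict[str, str]] = {}
        orphans = []
        for rid, seq in records:
            if rid.endswith("_A") or rid.endswith("_B"):
                by_locus.setdefault(rid[:-2], {})[rid[-1]] = seq
            else:
                orphans.append(rid)
        for locus, sides in by_locus.items():
            if set(sides) != {"A", "B"}:
                orphans.append(locus + "_" + next(iter(sides)))
            else:
                pairs.append((locus, sides["A"], sides["B"]))
        if orphans:
            raise ValueError(
                "unpaired FASTA records (expected <locus>_A/<locus>_B): "
                + ", ".join(sorted(orphans)[:10])
            )
    else:
        rec_a, rec_b = _read_fasta(paths[0]), _read_fasta(paths[1])
        if len(rec_a) != len(rec_b):
            raise ValueError(
                f"paired FASTA files differ in record count "
                f"({len(rec_a)} vs {len(rec_b)})"
            )
        if not rec_a:
            raise ValueError("no FASTA records in paired input")
        pairs = [(ra[0], ra[1], rb[1]) for ra, rb in zip(rec_a, rec_b)]

    values = []
    n_saturated = 0
    for locus, sa, sb in pairs:
        p, _ = pairwise_p_distance(sa, sb)
        if p >= SATURATION_P:
            n_saturated += 1
            continue
        values.append(correct_multiple_hits(p))
    if n_saturated:
        logger.warning(
            "read_fasta_pairs: excluded %d saturated pair(s) (p >= %g)",
            n_saturated, SATURATION_P,
        )
    if len(values) < 2:
        raise ValueError("fewer than 2 usable pairs after saturation filtering")
    return summarize(
        values, mu_per_gen=mu_per_gen, source="fasta", n_dropped=n_saturated
    )
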