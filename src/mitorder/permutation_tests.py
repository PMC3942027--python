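"""Randomization tests for gene-order conservation and tRNA clustering.

Two Monte-Carlo procedures:

* ``goc_shuffle_test`` — is the observed GOC between two genomes higher
  than expected if gene order were random?  The null shuffles the order of
  one genome's shared genes (signs travel with their genes) and recomputes
  GOC each time.
* ``trna_clustering_test`` — are a genome's tRNAs clustered among its other
  genes?  The statistic is the number of noncontiguous tRNAs (tRNAs with no
  tRNA in either adjacent position on the circular gene list); the null
  permutes the combined gene+tRNA label sequence.  Clustering means *fewer*
  noncontiguous tRNAs than expected, so the test is one-sided (less).

Monte-Carlo p values use the standard add-one correction
p = (k + 1) / (B + 1), so they are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedInputError
from .gene_order import GeneOrder, adjacency_set, goc_gol, shared_gene_set

__all__ = [
    "PermutationResult",
    "goc_shuffle_test",
    "bonferroni_adjust",
    "trna_clustering_test",
    "noncontiguous_trna_count",
    "trna_run_count",
]

DEFAULT_N_PERM = 100_000


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    n_perm: int
    n_as_extreme: int
    p_value: float
    direction: str  # "greater" or "less"
    seed: int | None
    statistic: str

    def __post_init__(self):
        assert 0 <= self.n_as_extreme <= self.n_perm
        assert 0.0 < self.p_value <= 1.0


def _result(observed, n_perm, k, direction, seed, statistic) -> PermutationResult:
    return PermutationResult(
        observed=float(observed),
        n_perm=int(n_perm),
        n_as_extreme=int(k),
        p_value=(k + 1) / (n_perm + 1),
        direction=direction,
        seed=seed,
        statistic=statistic,
    )


def goc_shuffle_test(
    g1: GeneOrder,
    g2: GeneOrder,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> PermutationResult:
    """One-sided (greater) shuffle test of gene-order conservation.

    p = (#{GOC_perm >= GOC_obs} + 1) / (n_perm + 1), with the null obtained
    by uniformly permuting the shared-gene order of the second genome.
    """
    if n_perm < 1:
        raise UndefinedInputError("n_perm must be >= 1")
    shared = shared_gene_set(g1, g2)
    m = len(shared)
    observed, _ = goc_gol(g1, g2)  # raises if m < 3
    a1 = adjacency_set(g1, restrict_to=shared)
    base = g2.restrict(shared)
    genes = list(base.genes)
    rng = np.random.default_rng(seed)
    k = 0
    content = sorted(s for s, _ in genes)
    for _ in range(n_perm):
        perm = rng.permutation(m)
        shuffled = tuple(genes[i] for i in perm)
        assert sorted(s for s, _ in shuffled) == content  # content preserved
        g_perm = GeneOrder(base.genome_id, shuffled, circular=base.circular)
        goc_perm = len(a1 & adjacency_set(g_perm)) / m
        if goc_perm >= observed - 1e-12:
            k += 1
    return _result(observed, n_perm, k, "greater", seed, "goc")


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: adjusted = min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return np.minimum(1.0, p * m)


def _trna_mask(order: GeneOrder) -> np.ndarray:
    if order.classes is not None:
        return np.array([c == "tRNA" for c in order.classes])
    return np.array([s.startswith("trn") for s in order.symbols])


def noncontiguous_trna_count(is_trna: np.ndarray, circular: bool = True) -> int:
    """tRNAs with no tRNA in either adjacent position."""
    n = is_trna.size
    count = 0
    for i in np.flatnonzero(is_trna):
        if circular:
            left, right = is_trna[(i - 1) % n], is_trna[(i + 1) % n]
        else:
            left = is_trna[i - 1] if i > 0 else False
            right = is_trna[i + 1] if i < n - 1 else False
        if not (left or right):
            count += 1
    return count


def trna_run_count(is_trna: np.ndarray, circular: bool = True) -> int:
    """Number of maximal runs of consecutive tRNAs (alternative statistic)."""
    n = is_trna.size
    if is_trna.all():
        return 1
    runs = 0
    for i in range(n):
        prev = is_trna[(i - 1) % n] if circular else (is_trna[i - 1] if i else False)
        if is_trna[i] and not prev:
            runs += 1
    return runs


def trna_clustering_test(
    order_with_trnas: GeneOrder,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    statistic: str = "noncontiguous",
) -> PermutationResult:
    """One-sided (less) permutation test for tRNA clustering.

    Requires >= 2 tRNAs and >= 1 non-tRNA in the order.  ``statistic`` is
    ``"noncontiguous"`` (default) or ``"runs"``.
    """
    if n_perm < 1:
        raise UndefinedInputError("n_perm must be >= 1")
    stat_fn = {
        "noncontiguous": noncontiguous_trna_count,
        "runs": trna_run_count,
    }.get(statistic)
    if stat_fn is None:
        raise ValueError(f"unknown statistic {statistic!r}")
    is_trna = _trna_mask(order_with_trnas)
    n_trna = int(is_trna.sum())
    if n_trna < 2:
        raise UndefinedInputError(f"need >= 2 tRNAs, have {n_trna}")
    if n_trna == is_trna.size:
        raise UndefinedInputError("need at least one non-tRNA gene")
    circular = order_with_trnas.circular
    observed = stat_fn(is_trna, circular)
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_perm):
        perm = rng.permutation(is_trna)
        if stat_fn(perm, circular) <= observed:
            k += 1
    return _result(observed, n_perm, k, "less", seed, f"trna_{statistic}")
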