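"""Core gene-order mathematics.

A genome is modelled as a signed (usually circular) arrangement of uniquely
named genes.  On top of that sit the comparative statistics used throughout
the package:

* the gene order conservation index GOC — the fraction of contiguous
  ortholog pairs two genomes share, normalized by the number of shared
  orthologs — and its complement GOL = 1 - GOC;
* the breakpoint distance, the number of adjacencies of one genome missing
  from the other on the shared gene set;
* the double-cut-and-join (DCJ) distance, the minimal number of operations
  that cut two adjacencies and rejoin the four loose ends needed to
  transform one signed circular genome into another.  For two single
  circular chromosomes with equal gene content it equals ``n - c`` where
  ``c`` is the number of cycles in the adjacency graph built on gene
  extremities (heads/tails).

GOC adjacencies are deliberately sign- and orientation-blind (unordered
symbol pairs): fungal mitochondrial genes sit on both strands in
basidiomycetes, and a contiguous pair remains contiguous whichever strand
either member is read from.  A strand-aware variant is available via
``signed=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import (
    ContentMismatchError,
    DuplicateGeneError,
    UndefinedInputError,
)

__all__ = [
    "GeneOrder",
    "shared_gene_set",
    "adjacency_set",
    "goc_gol",
    "breakpoint_distance",
    "dcj_distance",
]

_VALID_CLASSES = {"protein", "tRNA", "rRNA", "intronic_orf", "other"}


@dataclass(frozen=True)
class GeneOrder:
    """Signed arrangement of uniquely named genes for one genome.

    Parameters
    ----------
    genome_id:
        Identifier of the genome (e.g. an accession or species name).
    genes:
        Ordered ``(symbol, sign)`` pairs with ``sign`` in ``{+1, -1}``.
    circular:
        Topology flag; fungal mtDNAs are circular, the default.
    classes:
        Optional per-gene feature class (``protein``, ``tRNA``, ...),
        aligned with ``genes``.  ``None`` means unannotated (treated as
        protein-coding by operations that filter by class).
    """

    genome_id: str
    genes: tuple[tuple[str, int], ...]
    circular: bool = True
    classes: tuple[str, ...] | None = None

    def __post_init__(self):
        genes = tuple((str(s), int(sg)) for s, sg in self.genes)
        object.__setattr__(self, "genes", genes)
        if len(genes) < 1:
            raise UndefinedInputError(f"{self.genome_id}: empty gene order")
        symbols = [s for s, _ in genes]
        if len(set(symbols)) != len(symbols):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise DuplicateGeneError(
                f"{self.genome_id}: duplicate gene symbols {dupes}"
            )
        for s, sg in genes:
            if sg not in (1, -1):
                raise UndefinedInputError(
                    f"{self.genome_id}: sign of {s} must be +1 or -1, got {sg}"
                )
        if self.classes is not None:
            cls = tuple(self.classes)
            object.__setattr__(self, "classes", cls)
            if len(cls) != len(genes):
                raise UndefinedInputError(
                    f"{self.genome_id}: classes length {len(cls)} != "
                    f"gene count {len(genes)}"
                )
            bad = set(cls) - _VALID_CLASSES
            if bad:
                raise UndefinedInputError(
                    f"{self.genome_id}: unknown feature classes {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.genes)

    def class_of(self, index: int) -> str:
        if self.classes is None:
            return "protein"
        return self.classes[index]

    def restrict(self, symbols: Iterable[str]) -> "GeneOrder":
        """Delete genes outside ``symbols``, joining their neighbours."""
        keep = set(symbols)
        idx = [i for i, (s, _) in enumerate(self.genes) if s in keep]
        if not idx:
            raise UndefinedInputError(
                f"{self.genome_id}: restriction to {sorted(keep)} is empty"
            )
        return GeneOrder(
            genome_id=self.genome_id,
            genes=tuple(self.genes[i] for i in idx),
            circular=self.circular,
            classes=None
            if self.classes is None
            else tuple(self.classes[i] for i in idx),
        )

    def filter_classes(self, include: Iterable[str]) -> "GeneOrder":
        """Keep only genes whose feature class is in ``include``."""
        inc = set(include)
        idx = [i for i in range(len(self)) if self.class_of(i) in inc]
        if not idx:
            raise UndefinedInputError(
                f"{self.genome_id}: no genes with class in {sorted(inc)}"
            )
        return GeneOrder(
            genome_id=self.genome_id,
            genes=tuple(self.genes[i] for i in idx),
            circular=self.circular,
            classes=tuple(self.class_of(i) for i in idx),
        )

    def rotate(self, k: int) -> "GeneOrder":
        """Rotate a circular order by ``k`` positions (no-op re-labelling)."""
        if not self.circular:
            raise UndefinedInputError("rotation is only defined for circular orders")
        n = len(self)
        k %= n
        genes = self.genes[k:] + self.genes[:k]
        cls = None
        if self.classes is not None:
            cls = self.classes[k:] + self.classes[:k]
        return GeneOrder(self.genome_id, genes, self.circular, cls)

    def reverse(self) -> "GeneOrder":
        """Whole-order reversal with sign flips (reading the other strand)."""
        genes = tuple((s, -sg) for s, sg in reversed(self.genes))
        cls = None if self.classes is None else tuple(reversed(self.classes))
        return GeneOrder(self.genome_id, genes, self.circular, cls)


def shared_gene_set(g1: GeneOrder, g2: GeneOrder) -> set[str]:
    """Symbols present in both genomes (the shared orthologs)."""
    return set(g1.symbols) & set(g2.symbols)


def adjacency_set(
    g: GeneOrder,
    restrict_to: Iterable[str] | None = None,
    signed: bool = False,
) -> frozenset:
    """Adjacencies (unordered neighbour pairs) of a gene order.

    Genes outside ``restrict_to`` are deleted and their neighbours joined
    before adjacencies are read off.  For a circular order over m >= 3 genes
    this yields exactly m adjacencies; a linear order yields m - 1.

    With ``signed=True`` each adjacency records which gene ends meet
    (head/tail extremities) instead of the bare symbol pair.
    """
    if restrict_to is not None:
        g = g.restrict(restrict_to)
    m = len(g)
    if m < 2:
        raise UndefinedInputError(
            f"{g.genome_id}: need >= 2 genes for adjacencies, have {m}"
        )
    if signed:
        adj = set()
        pairs = _extremity_adjacencies(g)
        for a, b in pairs:
            adj.add(frozenset((a, b)))
        return frozenset(adj)
    seq = g.symbols
    adj = set()
    last = m if g.circular else m - 1
    for i in range(last):
        a, b = seq[i], seq[(i + 1) % m]
        if a != b:
            adj.add(frozenset((a, b)))
    return frozenset(adj)


def goc_gol(
    g1: GeneOrder, g2: GeneOrder, signed: bool = False
) -> tuple[float, float]:
    """Gene order conservation (GOC) and loss (GOL = 1 - GOC).

    GOC is the number of contiguous ortholog pairs in common between the two
    genomes, normalized by the number m of shared orthologs.  Both orders
    are first restricted to the shared gene set (delete-and-join).  Requires
    m >= 3.
    """
    shared = shared_gene_set(g1, g2)
    m = len(shared)
    if m < 3:
        raise UndefinedInputError(
            f"GOC undefined: only {m} shared genes between "
            f"{g1.genome_id} and {g2.genome_id} (need >= 3)"
        )
    a1 = adjacency_set(g1, restrict_to=shared, signed=signed)
    a2 = adjacency_set(g2, restrict_to=shared, signed=signed)
    goc = len(a1 & a2) / m
    return goc, 1.0 - goc


def breakpoint_distance(g1: GeneOrder, g2: GeneOrder, signed: bool = False) -> int:
    """Number of adjacencies of the shared gene set not conserved.

    For circular genomes this is ``m - |A1 & A2|``; with the default
    sign-blind adjacencies it equals ``m * GOL``.  ``signed=True`` counts
    breakpoints on gene extremities (the classical definition for signed
    genomes); only that variant is an upper bound on the DCJ distance.
    """
    shared = shared_gene_set(g1, g2)
    m = len(shared)
    if m < 3:
        raise UndefinedInputError(
            f"breakpoint distance undefined: only {m} shared genes"
        )
    a1 = adjacency_set(g1, restrict_to=shared, signed=signed)
    a2 = adjacency_set(g2, restrict_to=shared, signed=signed)
    total = m if (g1.circular and g2.circular) else m - 1
    return total - len(a1 & a2)


# -- DCJ -----------------------------------------------------------------

def _extremity_adjacencies(g: GeneOrder) -> list[tuple]:
    """Adjacencies as pairs of signed gene extremities (symbol, 'h'/'t')."""
    n = len(g)
    out = []
    last = n if g.circular else n - 1
    for i in range(last):
        a, sa = g.genes[i]
        b, sb = g.genes[(i + 1) % n]
        right = (a, "h") if sa > 0 else (a, "t")
        left = (b, "t") if sb > 0 else (b, "h")
        out.append((right, left))
    return out


def dcj_distance(g1: GeneOrder, g2: GeneOrder) -> int:
    """Minimal number of double-cut-and-join operations between two genomes.

    Both genomes must be single circular chromosomes over the same gene set
    (mirroring the equal-content requirement of classical rearrangement
    sorters).  The distance is ``n - c`` with ``c`` the number of cycles in
    the adjacency graph on gene extremities.
    """
    if not (g1.circular and g2.circular):
        raise UndefinedInputError("DCJ distance implemented for circular genomes")
    s1, s2 = set(g1.symbols), set(g2.symbols)
    if s1 != s2:
        raise ContentMismatchError(
            f"DCJ requires identical gene content; "
            f"{sorted(s1 ^ s2)} not shared between "
            f"{g1.genome_id} and {g2.genome_id}"
        )
    n = len(g1)
    if n == 1:
        return 0
    p1 = _partner_map(g1)
    p2 = _partner_map(g2)
    seen: set = set()
    cycles = 0
    for start in p1:
        if start in seen:
            continue
        cycles += 1
        x = start
        use_first = True
        while x not in seen:
            seen.add(x)
            x = p1[x] if use_first else p2[x]
            use_first = not use_first
    return n - cycles


def _partner_map(g: GeneOrder) -> dict:
    partner = {}
    for a, b in _extremity_adjacencies(g):
        partner[a] = b
        partner[b] = a
    return partner
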