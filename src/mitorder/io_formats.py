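"""Readers and writers for gene-order tables, GenBank records, trees, and
the packaged per-species / per-cluster fixtures.

The canonical exchange format is a tab-separated gene-order table with
columns ``genome_id, rank, gene, strand, feature_class`` — one row per
annotated feature, ranks consecutive from 1 along each genome.  GenBank
parsing is a convenience importer on top of Biopython; all downstream
mathematics is rank-based and never touches coordinates.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .errors import DuplicateGeneError, FormatError, SchemaError
from .gene_order import GeneOrder
from .phylo import PhyloTree, read_tree, write_tree  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

__all__ = [
    "read_gene_order_table",
    "write_gene_order_table",
    "extract_gene_orders_from_genbank",
    "load_species_stats",
    "load_cluster_counts",
    "read_tree",
    "write_tree",
]

GENE_ORDER_COLUMNS = ["genome_id", "rank", "gene", "strand", "feature_class"]

SPECIES_STATS_COLUMNS = [
    "taxon",
    "cluster",
    "bsgol",
    "branch_length",
    "nprs_rate",
    "n_trna",
    "n_intronic_orfs",
    "n_introns",
    "n_repeats",
    "n_intergenic_repeats",
    "genome_size",
]

CLUSTER_COUNT_COLUMNS = [
    "cluster",
    "intergenic_repeats",
    "intergenic_repeats_no_outliers",
    "rearrangement_events",
]

_STRANDS = {"+": 1, "-": -1, "−": -1}  # accept the typographic minus

# one-letter amino-acid codes for normalizing tRNA product names
_AA3TO1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}


def read_gene_order_table(path) -> list[GeneOrder]:
    """Read a TSV gene-order table into one ``GeneOrder`` per genome.

    Rows may be in any order; genes are sorted by rank within each genome.
    Ranks must be consecutive from 1 with no duplicates, strand must be
    ``+``/``-``, and protein-coding gene symbols must be unique per genome.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENE_ORDER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"gene-order table missing columns {missing}")
    if df.empty:
        raise SchemaError("gene-order table has no rows")
    try:
        df["rank"] = df["rank"].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer rank in gene-order table: {exc}") from exc

    orders = []
    for genome_id, grp in df.groupby("genome_id", sort=True):
        grp = grp.sort_values("rank")
        ranks = grp["rank"].tolist()
        if len(set(ranks)) != len(ranks):
            raise FormatError(f"{genome_id}: duplicate (genome, rank) entries")
        if ranks != list(range(1, len(ranks) + 1)):
            raise FormatError(
                f"{genome_id}: ranks must be consecutive from 1, got {ranks}"
            )
        signs = []
        for s in grp["strand"]:
            if s not in _STRANDS:
                raise FormatError(f"{genome_id}: unknown strand symbol {s!r}")
            signs.append(_STRANDS[s])
        genes = tuple(zip(grp["gene"].tolist(), signs))
        classes = tuple(grp["feature_class"].tolist())
        proteins = [g for (g, _), c in zip(genes, classes) if c == "protein"]
        if len(set(proteins)) != len(proteins):
            dupes = sorted({g for g in proteins if proteins.count(g) > 1})
            raise DuplicateGeneError(
                f"{genome_id}: duplicate protein gene symbols {dupes}"
            )
        orders.append(GeneOrder(genome_id, genes, circular=True, classes=classes))
    return orders


def write_gene_order_table(orders: Iterable[GeneOrder], path) -> None:
    rows = []
    for g in orders:
        for i, (sym, sign) in enumerate(g.genes):
            rows.append(
                {
                    "genome_id": g.genome_id,
                    "rank": i + 1,
                    "gene": sym,
                    "strand": "+" if sign > 0 else "-",
                    "feature_class": g.class_of(i),
                }
            )
    pd.DataFrame(rows, columns=GENE_ORDER_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def _trna_symbol(product: str) -> str:
    """Normalize e.g. 'tRNA-Met' to 'trnM'; fall back to the raw name."""
    name = product.strip()
    low = name.lower()
    if low.startswith("trna-") and low[5:8] in _AA3TO1:
        return "trn" + _AA3TO1[low[5:8]]
    return name


def _feature_name(feature) -> str | None:
    for key in ("gene", "product", "locus_tag", "label"):
        if key in feature.qualifiers:
            return str(feature.qualifiers[key][0])
    return None


def extract_gene_orders_from_genbank(
    path, include_classes: set[str] | None = None
) -> list[GeneOrder]:
    """Extract gene orders from a GenBank flat file, one per record.

    Features (CDS -> protein, tRNA, rRNA) are ordered by their leftmost
    coordinate; strand comes from ``complement(...)`` notation.  A CDS whose
    span is strictly nested inside another CDS's span is classified as an
    intron-encoded ORF (``intronic_orf``).  Features without any name
    qualifier are skipped with a warning.  ``include_classes`` restricts the
    returned order to the given feature classes (default: all).
    """
    keymap = {"CDS": "protein", "tRNA": "tRNA", "rRNA": "rRNA"}
    orders = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:
        raise FormatError(f"unparseable GenBank file {path}: {exc}") from exc
    if not records:
        raise FormatError(f"no GenBank records in {path}")
    for record in records:
        feats = []
        for feature in record.features:
            if feature.type not in keymap:
                continue
            name = _feature_name(feature)
            if name is None:
                logger.warning(
                    "%s: skipping unnamed %s feature at %s",
                    record.id, feature.type, feature.location,
                )
                continue
            fclass = keymap[feature.type]
            if fclass == "tRNA":
                name = _trna_symbol(name)
            start = int(feature.location.start)  # 0-based internally
            end = int(feature.location.end)
            strand = 1 if (feature.location.strand or 1) >= 0 else -1
            feats.append([start, end, name, strand, fclass])
        feats.sort(key=lambda f: (f[0], f[1]))
        # CDS nested strictly within another CDS span -> intron-encoded ORF
        cds_spans = [(s, e, n) for s, e, n, _, c in feats if c == "protein"]
        for f in feats:
            if f[4] != "protein":
                continue
            for s, e, n in cds_spans:
                if n != f[2] and s <= f[0] and f[1] <= e and (e - s) > (f[1] - f[0]):
                    f[4] = "intronic_orf"
                    break
        if include_classes is not None:
            feats = [f for f in feats if f[4] in include_classes]
        if not feats:
            logger.warning("%s: no named features retained", record.id)
            continue
        genes = tuple((f[2], f[3]) for f in feats)
        classes = tuple(f[4] for f in feats)
        topology = record.annotations.get("topology", "circular")
        orders.append(
            GeneOrder(
                genome_id=record.id,
                genes=genes,
                circular=(topology != "linear"),
                classes=classes,
            )
        )
    return orders


# -- packaged fixtures ---------------------------------------------------

def _packaged(name: str):
    return resources.files("mitorder.data").joinpath(name)


def load_species_stats(path=None) -> pd.DataFrame:
    """Load the per-species statistics table (packaged 38-taxon fixture by
    default): cluster membership, bsGOL, branch length, NPRS substitution
    rate, and element counts.  Numeric columns accept scientific notation.
    """
    source = _packaged("dikarya_species_stats.csv") if path is None else path
    df = pd.read_csv(source)
    missing = [c for c in SPECIES_STATS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"species-stats table missing columns {missing}")
    if df.empty:
        raise SchemaError("species-stats table has no rows")
    if df["taxon"].duplicated().any():
        raise SchemaError("species-stats table has duplicate taxa")
    numeric = [c for c in df.columns if c not in ("taxon", "cluster", "accession")]
    for col in numeric:
        df[col] = pd.to_numeric(df[col])
    if ((df["bsgol"] < 0) | (df["bsgol"] > 1)).any():
        raise SchemaError("bsgol values must lie in [0, 1]")
    counts = ["n_trna", "n_intronic_orfs", "n_introns", "n_repeats",
              "n_intergenic_repeats", "genome_size"]
    if (df[counts] < 0).any().any():
        raise SchemaError("element counts must be non-negative")
    return df


def load_cluster_counts(path=None) -> pd.DataFrame:
    """Load the per-cluster intergenic-repeat / rearrangement-event counts
    (packaged seven-cluster fixture by default)."""
    source = _packaged("cluster_repeat_rearrangements.csv") if path is None else path
    df = pd.read_csv(source)
    missing = [c for c in CLUSTER_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cluster-counts table missing columns {missing}")
    if df.empty:
        raise SchemaError("cluster-counts table has no rows")
    num = [c for c in CLUSTER_COUNT_COLUMNS if c != "cluster"]
    if (df[num] < 0).any().any():
        raise SchemaError("cluster counts must be non-negative")
    return df
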