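"""Orchestration: fixture integrity, headline-statistic reproduction, and
the end-to-end analysis report.

``reproduce_reference_stats`` recomputes, from the packaged per-species and
per-cluster tables, the summary statistics reported for this 38-genome
fungal data set: per-cluster mean bsGOL, the Pearson correlation of bsGOL
with branch length, and the chi-squared / G2 / Monte-Carlo association
between intergenic repeats and rearrangement events.  The basal cluster is
excluded from the headline contingency test (df = 5 over the six dikarya
clusters); a seven-row variant is available via ``exclude_basals=False``.

``run_full_analysis`` chains the pipeline on arbitrary inputs: pairwise GOC
-> decay-model fits -> branch-specific GOL -> permutation tests ->
association tests, returning a deterministic, JSON-serializable report.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import __version__
from .association_stats import (
    cluster_mean_bsgol,
    contingency_tests,
    fisher_exact,
    monte_carlo_independence,
    pearson_correlation,
)
from .branch_gol import estimate_branch_gol
from .decay_models import fit_all_models, pairwise_scores
from .errors import IntegrityError
from .gene_order import GeneOrder, breakpoint_distance, dcj_distance
from .io_formats import load_cluster_counts, load_species_stats
from .permutation_tests import (
    bonferroni_adjust,
    goc_shuffle_test,
    trna_clustering_test,
)
from .phylo import PhyloTree

__all__ = [
    "DIKARYA_CLUSTERS",
    "load_verified_fixtures",
    "reproduce_reference_stats",
    "run_full_analysis",
    "AnalysisReport",
]

# the six dikarya clusters entering the headline association test
DIKARYA_CLUSTERS = (
    "basidiomycetes",
    "sordariomycetes",
    "dothideomycetes",
    "eurotiomycetes",
    "saccharomycetes1",
    "saccharomycetes2",
)


def _verify_checksums() -> None:
    data = resources.files("mitorder.data")
    recorded = {}
    for line in data.joinpath("CHECKSUMS.sha256").read_text().splitlines():
        digest, name = line.split()
        recorded[name] = digest
    for name, digest in recorded.items():
        actual = hashlib.sha256(data.joinpath(name).read_bytes()).hexdigest()
        if actual != digest:
            raise IntegrityError(
                f"packaged fixture {name} does not match its checksum"
            )


def load_verified_fixtures() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Packaged species-stats and cluster-counts tables, checksum-verified."""
    _verify_checksums()
    return load_species_stats(), load_cluster_counts()


def reproduce_reference_stats(
    stats: pd.DataFrame | None = None,
    counts: pd.DataFrame | None = None,
    n_sim: int = 5000,
    seed: int = 0,
    exclude_basals: bool = True,
    cluster_filter: list[str] | None = None,
) -> pd.DataFrame:
    """Recompute the headline statistics from the packaged tables.

    Returns a tidy frame of (statistic, value) rows: one mean-bsGOL row per
    cluster, the bsGOL/branch-length Pearson r and p, and the chi2, G2,
    degrees of freedom and Monte-Carlo p of the intergenic-repeat x
    rearrangement-event contingency table.
    """
    if stats is None or counts is None:
        fx_stats, fx_counts = load_verified_fixtures()
        stats = fx_stats if stats is None else stats
        counts = fx_counts if counts is None else counts

    clusters = list(cluster_filter) if cluster_filter else list(DIKARYA_CLUSTERS)
    rows = [
        {
            "statistic": f"mean_bsgol_{c}",
            "value": cluster_mean_bsgol(stats, c),
        }
        for c in clusters
    ]

    r, p = pearson_correlation(stats["bsgol"], stats["branch_length"])
    rows += [
        {"statistic": "pearson_r_bsgol_branch_length", "value": r},
        {"statistic": "pearson_p_bsgol_branch_length", "value": p},
    ]

    ctab = counts.set_index("cluster")
    if exclude_basals:
        ctab = ctab.drop(index="basals", errors="ignore")
    mat = ctab[["intergenic_repeats", "rearrangement_events"]]
    res = contingency_tests(mat)
    p_mc = monte_carlo_independence(mat, n_sim=n_sim, seed=seed)
    p_fisher = fisher_exact(mat, mode="monte_carlo", n_sim=n_sim, seed=seed)
    rows += [
        {"statistic": "chi2_repeats_rearrangements", "value": res.chi2},
        {"statistic": "chi2_df", "value": float(res.df)},
        {"statistic": "chi2_p", "value": res.p_chi2},
        {"statistic": "g2_repeats_rearrangements", "value": res.g2},
        {"statistic": "g2_p", "value": res.p_g2},
        {"statistic": "monte_carlo_independence_p", "value": p_mc},
        {"statistic": "fisher_monte_carlo_p", "value": p_fisher},
    ]
    return pd.DataFrame(rows)


@dataclass
class AnalysisReport:
    """All pipeline outputs for one run, JSON-serializable."""

    provenance: dict
    pairwise: pd.DataFrame | None = None
    decay_fits: pd.DataFrame | None = None
    branch_gol: pd.DataFrame | None = None
    species_bsgol: dict | None = None
    distances: pd.DataFrame | None = None
    shuffle_tests: pd.DataFrame | None = None
    trna_tests: pd.DataFrame | None = None
    associations: pd.DataFrame | None = None
    notices: list = field(default_factory=list)

    def to_json(self, indent: int = 2) -> str:
        def enc(x):
            if isinstance(x, pd.DataFrame):
                return x.to_dict(orient="records")
            return x

        body = {k: enc(v) for k, v in asdict(self).items() if k != "provenance"}
        # timestamps and the like belong only in provenance, keeping the
        # report body byte-reproducible under fixed seeds
        return json.dumps(
            {"provenance": self.provenance, **body},
            indent=indent,
            sort_keys=True,
            default=float,
        )


def run_full_analysis(
    orders: list[GeneOrder],
    tree: PhyloTree | None = None,
    n_perm: int = 1000,
    n_sim: int = 5000,
    seed: int = 0,
    counts: pd.DataFrame | None = None,
    run_shuffle_tests: bool = True,
    run_trna_tests: bool = True,
) -> AnalysisReport:
    """Run GOC -> decay fits -> bsGOL -> permutation tests -> associations.

    Stages needing a tree (decay fits against patristic distance, bsGOL) are
    skipped with a notice when none is given; association tests run only
    when a per-cluster count table is supplied.
    """
    notices: list[str] = []
    provenance = {
        "package": "mitorder",
        "version": __version__,
        "n_genomes": len(orders),
        "seed": seed,
        "n_perm": n_perm,
        "n_sim": n_sim,
    }
    report = AnalysisReport(provenance=provenance, notices=notices)

    protein_orders = []
    for g in orders:
        try:
            protein_orders.append(g.filter_classes({"protein"}))
        except Exception:
            protein_orders.append(g)

    report.pairwise = pairwise_scores(protein_orders, tree=tree)

    if tree is not None:
        report.decay_fits = fit_all_models(report.pairwise)
        problem = estimate_branch_gol(tree, report.pairwise)
        report.branch_gol = problem.per_branch_table()
        report.species_bsgol = problem.per_species().to_dict()
    else:
        notices.append("no tree supplied: decay-model and bsGOL stages skipped")

    rows = []
    for g1, g2 in itertools.combinations(protein_orders, 2):
        row = {"genome_a": g1.genome_id, "genome_b": g2.genome_id}
        row["breakpoints"] = breakpoint_distance(g1, g2)
        try:
            row["dcj"] = dcj_distance(g1, g2)
        except Exception:
            row["dcj"] = np.nan
        rows.append(row)
    report.distances = pd.DataFrame(rows)

    if run_shuffle_tests:
        srows = []
        for g1, g2 in itertools.combinations(protein_orders, 2):
            res = goc_shuffle_test(g1, g2, n_perm=n_perm, seed=seed)
            srows.append(
                {
                    "genome_a": g1.genome_id,
                    "genome_b": g2.genome_id,
                    "goc": res.observed,
                    "p": res.p_value,
                    "n_perm": res.n_perm,
                    "seed": seed,
                }
            )
        shuffle = pd.DataFrame(srows)
        if len(shuffle):
            shuffle["p_bonferroni"] = bonferroni_adjust(shuffle["p"])
        report.shuffle_tests = shuffle

    if run_trna_tests:
        trows = []
        for g in orders:
            if g.classes is None or sum(c == "tRNA" for c in g.classes) < 2:
                continue
            res = trna_clustering_test(g, n_perm=n_perm, seed=seed)
            trows.append(
                {
                    "genome_id": g.genome_id,
                    "noncontiguous_trnas": res.observed,
                    "p": res.p_value,
                    "n_perm": res.n_perm,
                    "seed": seed,
                }
            )
        report.trna_tests = pd.DataFrame(trows)

    if counts is not None:
        mat = counts.set_index("cluster")[
            ["intergenic_repeats", "rearrangement_events"]
        ]
        res = contingency_tests(mat)
        p_mc = monte_carlo_independence(mat, n_sim=n_sim, seed=seed)
        report.associations = pd.DataFrame(
            [
                {"statistic": "chi2", "value": res.chi2},
                {"statistic": "df", "value": float(res.df)},
                {"statistic": "p_chi2", "value": res.p_chi2},
                {"statistic": "g2", "value": res.g2},
                {"statistic": "p_g2", "value": res.p_g2},
                {"statistic": "p_monte_carlo", "value": p_mc},
            ]
        )
    return report
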