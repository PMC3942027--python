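"""Association and correlation statistics for element counts.

The headline question these serve: are rearrangement events associated with
the number of intergenic repeats across fungal clusters?  The per-cluster
count table is treated as a contingency table and tested with Pearson's
chi-squared, the likelihood-ratio (Wilks) G2, a Monte-Carlo randomization
test of independence with fixed margins, and Fisher-style exact/Monte-Carlo
tests.  Pearson correlation (with its t-distribution p value) and
per-cluster bsGOL means round out the module.

Treating count totals as independent observations in a contingency test is
statistically generous — counts within a cluster are not independent
trials — but it is the conventional screen for this kind of summary table;
the caveat is documented in the methods note rather than "corrected" here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError, LookupError_, UndefinedInputError

__all__ = [
    "ContingencyResult",
    "as_count_matrix",
    "contingency_tests",
    "monte_carlo_independence",
    "fisher_exact",
    "pearson_correlation",
    "cluster_mean_bsgol",
]


@dataclass(frozen=True)
class ContingencyResult:
    chi2: float
    df: int
    p_chi2: float
    g2: float
    p_g2: float


def as_count_matrix(table) -> np.ndarray:
    """Coerce a DataFrame/array of counts to a validated 2-D numpy array."""
    if isinstance(table, pd.DataFrame):
        table = table.to_numpy()
    mat = np.asarray(table, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise DegenerateTableError("contingency table must be at least 2x2")
    if (mat < 0).any():
        raise DegenerateTableError("counts must be non-negative")
    if (mat.sum(axis=0) == 0).any() or (mat.sum(axis=1) == 0).any():
        raise DegenerateTableError("contingency table has a zero margin")
    return mat


def _expected(mat: np.ndarray) -> np.ndarray:
    return np.outer(mat.sum(axis=1), mat.sum(axis=0)) / mat.sum()


def contingency_tests(table) -> ContingencyResult:
    """Pearson chi2 and Wilks G2 with their chi-square p values.

    chi2 = sum (O - E)^2 / E; G2 = 2 sum O ln(O / E) with 0 ln 0 := 0;
    E from the product of the row/column margins.  No continuity correction.
    """
    mat = as_count_matrix(table)
    chi2, p_chi2, df, _ = stats.chi2_contingency(mat, correction=False)
    g2, p_g2, _, _ = stats.chi2_contingency(
        mat, correction=False, lambda_="log-likelihood"
    )
    return ContingencyResult(
        chi2=float(chi2), df=int(df), p_chi2=float(p_chi2),
        g2=float(g2), p_g2=float(p_g2),
    )


def _chi2_stat(tables: np.ndarray, expected: np.ndarray) -> np.ndarray:
    return ((tables - expected) ** 2 / expected).sum(axis=(-2, -1))


def monte_carlo_independence(
    table, n_sim: int = 5000, seed: int | None = None
) -> float:
    """Randomization test of independence with fixed margins.

    Simulates ``n_sim`` tables with the observed row and column totals
    (multivariate hypergeometric sampling via Patefield's algorithm) and
    returns p = (#{chi2_sim >= chi2_obs} + 1) / (n_sim + 1).
    """
    if n_sim < 1:
        raise UndefinedInputError("n_sim must be >= 1")
    mat = as_count_matrix(table)
    expected = _expected(mat)
    obs = _chi2_stat(mat, expected)
    rng = np.random.default_rng(seed)
    dist = stats.random_table(
        mat.sum(axis=1).astype(int), mat.sum(axis=0).astype(int)
    )
    sims = dist.rvs(n_sim, random_state=rng)
    assert np.array_equal(
        sims.sum(axis=-1), np.broadcast_to(mat.sum(axis=1), sims.shape[:-1])
    )  # margins preserved in every draw
    k = int((_chi2_stat(sims, expected) >= obs - 1e-9).sum())
    return (k + 1) / (n_sim + 1)


def _log_table_prob(tables: np.ndarray) -> np.ndarray:
    # log P(table | margins) up to the margin-only constant
    from scipy.special import gammaln

    return -gammaln(tables + 1).sum(axis=(-2, -1))


def fisher_exact(
    table,
    mode: str = "exact_2x2",
    n_sim: int = 5000,
    seed: int | None = None,
) -> float:
    """Two-tailed Fisher test of independence.

    ``exact_2x2`` sums hypergeometric probabilities of all 2x2 tables (with
    the observed margins) no more probable than the observed one.
    ``monte_carlo`` generalizes to r x c by sampling fixed-margin tables and
    comparing their conditional probabilities to the observed table's.
    """
    mat = as_count_matrix(table)
    if mode == "exact_2x2":
        if mat.shape != (2, 2):
            raise ValueError("exact_2x2 mode requires a 2x2 table")
        _, p = stats.fisher_exact(mat.astype(int), alternative="two-sided")
        return float(p)
    if mode == "monte_carlo":
        if n_sim < 1:
            raise UndefinedInputError("n_sim must be >= 1")
        rng = np.random.default_rng(seed)
        dist = stats.random_table(
            mat.sum(axis=1).astype(int), mat.sum(axis=0).astype(int)
        )
        sims = dist.rvs(n_sim, random_state=rng)
        obs_lp = _log_table_prob(mat)
        k = int((_log_table_prob(sims) <= obs_lp + 1e-9).sum())
        return (k + 1) / (n_sim + 1)
    raise ValueError(f"unknown mode {mode!r}")


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with its two-sided t-distribution p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise UndefinedInputError("need two equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedInputError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cluster_mean_bsgol(stats_table: pd.DataFrame, cluster: str) -> float:
    """Arithmetic mean bsGOL over the taxa of one fungal cluster."""
    sub = stats_table.loc[stats_table["cluster"] == cluster, "bsgol"]
    if sub.empty:
        known = sorted(stats_table["cluster"].unique())
        raise LookupError_(f"unknown cluster {cluster!r}; have {known}")
    return float(sub.mean())
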