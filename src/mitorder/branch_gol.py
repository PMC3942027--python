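"""Branch-specific gene-order loss (bsGOL) by least-squares decomposition.

Each observed pairwise gene-order loss GOL_i is modelled as the sum of
per-branch contributions x_j over the branches on the tree path between the
pair's leaves:

    L = sum_i ( sum_j b_ij * x_j  -  GOL_i )^2

with b_ij = 1 iff branch j lies on pair i's path.  Minimizing L over x >= 0
yields the bsGOL scores; the value reported for a species is the score of
its terminal branch.  Nonnegativity is imposed because a branch's
contribution is a loss fraction — a negative loss has no meaning — with an
unconstrained ordinary-least-squares option available for comparison.

Branch identity is the bipartition of the leaf set, so the decomposition is
invariant to where the tree is rooted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import LookupError_, RateUndefinedError, UndefinedInputError
from .phylo import Branch, PhyloTree

__all__ = ["BranchGOLProblem", "estimate_branch_gol", "normalize_rates"]


@dataclass
class BranchGOLProblem:
    """Path-indicator design, observed GOL vector, and per-branch solution."""

    branches: tuple[Branch, ...]
    pairs: pd.DataFrame            # genome_a, genome_b, gol
    design: np.ndarray             # (n_pairs, n_branches) 0/1
    solution: np.ndarray           # x_j >= 0 (or unconstrained OLS)
    residual: float                # L at the solution
    underdetermined: bool
    nonnegative: bool

    @property
    def predicted(self) -> np.ndarray:
        return self.design @ self.solution

    def per_branch_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "branch_id": [b.branch_id for b in self.branches],
                "length": [b.length for b in self.branches],
                "n_leaves_below": [len(b.clade) for b in self.branches],
                "bsgol": self.solution,
            }
        )

    def per_species(self) -> pd.Series:
        """bsGOL of each terminal branch, indexed by leaf label."""
        out = {}
        for branch, x in zip(self.branches, self.solution):
            if len(branch.clade) == 1:
                (leaf,) = branch.clade
                out[leaf] = float(x)
        return pd.Series(out, name="bsgol").sort_index()


def estimate_branch_gol(
    tree: PhyloTree,
    pairs: pd.DataFrame,
    nonnegative: bool = True,
) -> BranchGOLProblem:
    """Decompose pairwise GOL values into per-branch contributions.

    ``pairs`` needs columns ``genome_a, genome_b, gol``; every named genome
    must be a leaf of ``tree``.
    """
    if len(pairs) < 1:
        raise UndefinedInputError("empty pair table")
    leaves = set(tree.leaf_labels)
    branches = tree.branches
    design = np.zeros((len(pairs), len(branches)))
    gol = np.asarray(pairs["gol"], dtype=float)
    for i, row in enumerate(pairs.itertuples(index=False)):
        a, b = row.genome_a, row.genome_b
        for leaf in (a, b):
            if leaf not in leaves:
                raise LookupError_(f"pair leaf {leaf!r} not in tree")
        for j, branch in enumerate(branches):
            if branch.on_path(a, b):
                design[i, j] = 1.0
    if not design.any(axis=1).all():
        bad = [i for i in range(len(pairs)) if not design[i].any()]
        raise UndefinedInputError(
            f"pairs {bad} have no branch on their path (identical leaves?)"
        )

    rank = np.linalg.matrix_rank(design)
    underdetermined = rank < len(branches)
    if underdetermined:
        warnings.warn(
            "bsGOL system is underdetermined "
            f"(rank {rank} < {len(branches)} branches); "
            "returned solution is one minimizer among many",
            stacklevel=2,
        )

    if nonnegative:
        solution, rnorm = nnls(design, gol)
        residual = float(rnorm**2)
    else:
        solution, *_ = np.linalg.lstsq(design, gol, rcond=None)
        resid = design @ solution - gol
        residual = float(resid @ resid)

    return BranchGOLProblem(
        branches=branches,
        pairs=pairs.reset_index(drop=True),
        design=design,
        solution=np.asarray(solution, dtype=float),
        residual=residual,
        underdetermined=underdetermined,
        nonnegative=nonnegative,
    )


def normalize_rates(
    values: pd.Series,
    denominators: pd.Series,
    relative_to_mean: bool = False,
) -> pd.Series:
    """Elementwise ``values / denominators`` (e.g. bsGOL per branch length,
    or rearrangement events per substitution rate).

    Entries with a non-positive denominator come back as NaN and are listed
    in a ``RateUndefinedError`` warning rather than aborting the rest.  With
    ``relative_to_mean=True`` the ratios are further divided by their mean.
    """
    values = pd.Series(values, dtype=float)
    denominators = pd.Series(denominators, dtype=float).reindex(values.index)
    bad = denominators <= 0
    if bad.any():
        warnings.warn(
            RateUndefinedError(
                f"rate undefined for {list(values.index[bad])}: "
                "non-positive denominator"
            ).args[0],
            stacklevel=2,
        )
    rates = values / denominators.where(~bad)
    if relative_to_mean:
        rates = rates / rates.mean()
    return rates
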