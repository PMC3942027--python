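"""Empirical models of gene-order conservation decay with divergence time.

Four single-parameter curves describe how the pairwise gene order
conservation index (GOC) decays with the patristic distance t between two
genomes:

* model 0 (sigmoidal):    GOC = 2 / (1 + exp(alpha * t))
* model 1 (square root):  GOC = 1 - sqrt(alpha * t), clamped to [0, 1]
* model 2 (hyperbolic):   1 / GOC = alpha * t + 1
* model 3 (geometric):    GOC = p ** t, with p the per-unit-time
  probability that two neighbouring genes stay together

All four satisfy GOC(0) = 1.  The free parameter is adjusted by nonlinear
least squares in GOC space and the goodness of fit reported is the residual
sum of squares.  The optimizer is a deterministic coarse log-grid scan
followed by bounded scalar refinement — no randomness, no starting-point
sensitivity.

Model 1 leaves its natural domain at alpha * t > 1; predictions are clamped
at 0 there and residuals are computed against the clamped curve.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import FitError, UndefinedInputError
from .gene_order import GeneOrder, goc_gol
from .phylo import PhyloTree

__all__ = [
    "DecayModelFit",
    "MODEL_IDS",
    "predict",
    "fit_decay_model",
    "fit_all_models",
    "patristic_distances",
    "pairwise_scores",
]

MODEL_IDS = (0, 1, 2, 3)

_ALPHA_BOUNDS = (0.0, 100.0)
_P_BOUNDS = (1e-9, 1.0)
_XTOL = 1e-10


@dataclass(frozen=True)
class DecayModelFit:
    """Result of fitting one decay model to pairwise (t, GOC) data."""

    model_id: int
    parameter: float  # alpha for models 0-2, p for model 3
    rss: float
    n_pairs: int

    @property
    def parameter_name(self) -> str:
        return "p" if self.model_id == 3 else "alpha"


def predict(model_id: int, parameter: float, t) -> np.ndarray:
    """Model GOC at patristic distance(s) ``t``."""
    t = np.asarray(t, dtype=float)
    if model_id == 0:
        with np.errstate(over="ignore"):  # exp overflow -> GOC 0, correct limit
            return 2.0 / (1.0 + np.exp(parameter * t))
    if model_id == 1:
        return np.clip(1.0 - np.sqrt(parameter * t), 0.0, 1.0)
    if model_id == 2:
        return 1.0 / (parameter * t + 1.0)
    if model_id == 3:
        return np.power(parameter, t)
    raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")


def fit_decay_model(pairs: pd.DataFrame, model_id: int) -> DecayModelFit:
    """Fit one decay model to a pairwise score table.

    ``pairs`` needs columns ``t`` (patristic distance >= 0) and ``goc``.
    Returns the fitted parameter and the residual sum of squares.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
    t = np.asarray(pairs["t"], dtype=float)
    goc = np.asarray(pairs["goc"], dtype=float)
    if t.size < 2:
        raise UndefinedInputError("need >= 2 pairs to fit a decay model")
    if not (np.isfinite(t).all() and np.isfinite(goc).all()):
        raise UndefinedInputError("non-finite t or GOC in pair table")
    if (t < 0).any():
        raise UndefinedInputError("patristic distances must be >= 0")

    lo, hi = _P_BOUNDS if model_id == 3 else _ALPHA_BOUNDS

    def rss(param: float) -> float:
        resid = goc - predict(model_id, param, t)
        return float(resid @ resid)

    # deterministic multi-start: coarse grid (log-spaced plus the bounds),
    # then bounded Brent refinement around the best grid cell
    grid = np.concatenate(
        ([lo], np.geomspace(max(lo, 1e-6), hi, 60), [hi])
    )
    grid = np.unique(np.clip(grid, lo, hi))
    values = np.array([rss(g) for g in grid])
    best = int(np.argmin(values))
    lo_b = grid[max(best - 1, 0)]
    hi_b = grid[min(best + 1, grid.size - 1)]
    if lo_b == hi_b:
        param, fval = grid[best], values[best]
    else:
        res = minimize_scalar(
            rss, bounds=(lo_b, hi_b), method="bounded",
            options={"xatol": _XTOL},
        )
        if not res.success:
            raise FitError(
                f"model {model_id} fit did not converge",
                diagnostics={"result": res, "grid_best": grid[best]},
            )
        param, fval = float(res.x), float(res.fun)
        if values[best] < fval:  # keep the grid point if refinement regressed
            param, fval = float(grid[best]), float(values[best])
    return DecayModelFit(model_id, param, fval, int(t.size))


def fit_all_models(pairs: pd.DataFrame) -> pd.DataFrame:
    """Fit all four models; one row per model, sorted by model id."""
    fits = [fit_decay_model(pairs, m) for m in MODEL_IDS]
    return pd.DataFrame(
        {
            "model_id": [f.model_id for f in fits],
            "parameter_name": [f.parameter_name for f in fits],
            "parameter": [f.parameter for f in fits],
            "rss": [f.rss for f in fits],
            "n_pairs": [f.n_pairs for f in fits],
        }
    )


def patristic_distances(tree: PhyloTree) -> pd.DataFrame:
    """Symmetric leaf-by-leaf matrix of path-length distances."""
    return tree.patristic_distance_matrix()


def pairwise_scores(
    orders: list[GeneOrder],
    tree: PhyloTree | None = None,
    signed: bool = False,
) -> pd.DataFrame:
    """All-pairs GOC/GOL table, with patristic distances when a tree is given.

    One row per unordered genome pair: ``genome_a, genome_b, t, goc, gol``
    (``t`` is NaN without a tree).
    """
    dist = patristic_distances(tree) if tree is not None else None
    rows = []
    for g1, g2 in itertools.combinations(orders, 2):
        goc, gol = goc_gol(g1, g2, signed=signed)
        t = np.nan
        if dist is not None:
            t = float(dist.loc[g1.genome_id, g2.genome_id])
        rows.append(
            {
                "genome_a": g1.genome_id,
                "genome_b": g2.genome_id,
                "t": t,
                "goc": goc,
                "gol": gol,
            }
        )
    return pd.DataFrame(rows, columns=["genome_a", "genome_b", "t", "goc", "gol"])
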