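"""Condition-specific gene regulatory network estimation.

Each target gene is regressed on all other genes with an L1 penalty:

    min_beta  (1/2) ||x_l - X_{-l} beta||^2  +  lambda ||beta||_1

The shrinkage level lambda is chosen per target by minimizing
BIC = n*log(RSS/n) + df*log(n), with df = the active-set size (number of
nonzero coefficients). Predictors and response are mean-centered (the model
has no intercept); predictors are scaled to unit variance for the penalty
and coefficients are reported on the original scale. The nonzero pattern of
the resulting p x p coefficient matrix is the directed network: an edge
j -> l means gene j was selected as a regulator of target l.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import lasso_path

from .io import ExpressionMatrix


@dataclass
class GeneNetwork:
    """Directed weighted gene-gene adjacency for one condition.

    ``coef[j, l]`` is the lasso coefficient of regulator gene ``j`` in the
    regression for target gene ``l`` (diagonal forced to zero).
    """

    genes: list[str]
    coef: np.ndarray
    lambda_per_target: np.ndarray

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        p = len(self.genes)
        if self.coef.shape != (p, p):
            raise ValueError(f"coef shape {self.coef.shape} != ({p}, {p})")
        if np.any(np.diag(self.coef) != 0):
            raise ValueError("network diagonal must be zero")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def neighbor_sets(self) -> list[set[int]]:
        """N_j: indices directly linked to gene j in either direction."""
        nz = self.coef != 0
        linked = nz | nz.T
        return [set(np.flatnonzero(linked[j])) - {j} for j in range(self.n_genes)]

    def edge_list(self) -> list[tuple[str, str, float]]:
        """(regulator, target, weight) triples for the nonzero coefficients."""
        rows, cols = np.nonzero(self.coef)
        return [
            (self.genes[j], self.genes[l], float(self.coef[j, l]))
            for j, l in zip(rows, cols)
        ]


def default_lambda_grid(X: np.ndarray, target: int, n_lambda: int = 50,
                        eps: float = 1e-3) -> np.ndarray:
    """Log-spaced grid from lambda_max down to eps*lambda_max.

    lambda_max = max_j |x_j^T x_l| over centered, penalty-standardized
    predictors: the smallest penalty at which every coefficient is zero.
    """
    y = X[:, target] - X[:, target].mean()
    Z = np.delete(X, target, axis=1)
    Z = Z - Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    lam_max = np.max(np.abs((Z / sd).T @ y)) if Z.size else 0.0
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, eps * lam_max, n_lambda)


def fit_target_lasso(
    X: ExpressionMatrix | np.ndarray,
    target: int,
    lambda_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Lasso fit of one target column on all other columns, BIC-selected.

    Returns the length-p coefficient vector (zero at ``target``) at the
    BIC-minimizing lambda, and that lambda. BIC ties break toward the
    largest lambda (sparsest model). A zero-variance target yields all-zero
    coefficients with a warning.
    """
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    n, p = V.shape
    if n < 2:
        raise ValueError("need at least 2 cells")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(V, target)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")
    lambda_grid = np.sort(lambda_grid)[::-1]

    y = V[:, target] - V[:, target].mean()
    if np.allclose(y, 0):
        warnings.warn(f"target column {target} has zero variance; empty fit")
        return np.zeros(p), float(lambda_grid[0])

    Z = np.delete(V, target, axis=1)
    Z = Z - Z.mean(axis=0)
    sd = Z.std(axis=0)
    keep = sd > 0
    sd_safe = np.where(keep, sd, 1.0)
    Zs = Z / sd_safe
    Zs[:, ~keep] = 0.0

    # sklearn objective is (1/(2n))RSS + alpha*||b||_1  ->  alpha = lambda/n
    alphas = lambda_grid / n
    with warnings.catch_warnings():
        # tiny grid penalties on collinear columns can stop at max_iter;
        # the BIC minimum almost never sits there, so don't spam callers
        warnings.simplefilter("ignore")
        alphas_used, coefs_std, _ = lasso_path(
            Zs, y, alphas=alphas, tol=1e-10, max_iter=100_000
        )
    order = np.argsort(alphas_used)[::-1]  # guarantee descending-lambda order
    alphas_used, coefs_std = alphas_used[order], coefs_std[:, order]
    # coordinate-descent dust (~1e-16) is not a selected coefficient; it
    # must not count toward the BIC degrees of freedom
    coefs_std[np.abs(coefs_std) < 1e-12] = 0.0
    rss = np.sum((y[:, None] - Zs @ coefs_std) ** 2, axis=0)
    rss = np.maximum(rss, 1e-300)
    df = np.count_nonzero(coefs_std, axis=0)
    bic = n * np.log(rss / n) + df * np.log(n)
    best = int(np.argmin(bic))  # argmin takes the first = largest lambda on ties
    beta_std = coefs_std[:, best]
    beta = np.where(keep, beta_std / sd_safe, 0.0)

    out = np.zeros(p)
    out[np.arange(p) != target] = beta
    return out, float(alphas_used[best] * n)


def estimate_network(
    X: ExpressionMatrix | np.ndarray,
    lambda_grid: np.ndarray | None = None,
    genes: list[str] | None = None,
    fixed_lambdas: np.ndarray | None = None,
) -> GeneNetwork:
    """Estimate the directed network by p independent per-target lasso fits.

    ``coef[j, l]`` is taken from target-l's fit; fits are independent, so
    the result does not depend on target order. Zero-variance columns stay
    in the node set as isolated nodes. ``fixed_lambdas`` (one shrinkage
    value per target) bypasses BIC selection — used by the fast
    permutation mode that conditions on the observed penalty levels.
    """
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    if genes is None:
        genes = (
            list(X.gene_names)
            if isinstance(X, ExpressionMatrix)
            else [f"g{i}" for i in range(V.shape[1])]
        )
    p = V.shape[1]
    if p < 2:
        raise ValueError("need at least 2 genes to estimate a network")
    coef = np.zeros((p, p))
    lambdas = np.zeros(p)
    for target in range(p):
        grid = (
            np.array([fixed_lambdas[target]])
            if fixed_lambdas is not None
            else lambda_grid
        )
        beta, lam = fit_target_lasso(V, target, grid)
        coef[:, target] = beta
        lambdas[target] = lam
    return GeneNetwork(genes, coef, lambdas)


def aggregate_edges_median(
    networks: list[GeneNetwork], top_k: int = 20
) -> list[tuple[str, str, float]]:
    """Top directed edges by |median weight| across repeated estimates.

    An edge absent from a network contributes weight 0 to its median, so
    an edge must recur in more than half the networks to keep a nonzero
    median. Returns up to ``top_k`` (regulator, target, median_weight)
    triples ranked by |median|.
    """
    if not networks:
        raise ValueError("empty network list")
    genes = networks[0].genes
    for net in networks[1:]:
        if net.genes != genes:
            raise ValueError("networks must share the same gene set")
    stack = np.stack([net.coef for net in networks])
    med = np.median(stack, axis=0)
    np.fill_diagonal(med, 0.0)
    order = np.argsort(-np.abs(med), axis=None)
    out = []
    for flat in order[:top_k]:
        j, l = np.unravel_index(flat, med.shape)
        out.append((genes[j], genes[l], float(med[j, l])))
    return out


def write_edge_list(net: GeneNetwork, path: str) -> None:
    """Export the network as a regulator<TAB>target<TAB>weight TSV."""
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tweight\n")
        for reg, tgt, w in net.edge_list():
            fh.write(f"{reg}\t{tgt}\t{w:.10g}\n")
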