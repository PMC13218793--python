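"""Eigen-cells and their between-group correlation network.

The expression submatrix of the differentially-regulated genes (cells x
p* genes) is factored by thin SVD, X = W S E^T. The columns of E — gene-
loading profiles, here called eigen-cells — are treated as the functional
modules of a cell population. Two populations computed on the same gene
set live in an identical feature space, so the Pearson correlation over
the p* loadings of an eigen-cell pair quantifies module sharing; pairs
whose correlation is significant (two-sided t test, p* - 2 df) form the
eigen-cell correlation network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ExpressionMatrix


@dataclass
class EigenCellSet:
    """Thin-SVD factors of a cells x selected-genes submatrix.

    ``E`` columns are the eigen-cells (gene loadings); numerically-zero
    singular values (< 1e-10 * s_1) are dropped, and each eigen-cell's
    largest-|loading| entry is made positive so the factorization is
    deterministic across SVD backends.
    """

    W: np.ndarray  # n_cells x R
    S: np.ndarray  # R
    E: np.ndarray  # p* x R
    gene_names: list[str]

    @property
    def rank(self) -> int:
        return len(self.S)

    def reconstruct(self) -> np.ndarray:
        return self.W @ np.diag(self.S) @ self.E.T


def compute_eigencells(X_sub: ExpressionMatrix | np.ndarray,
                       gene_names: list[str] | None = None,
                       rank_tol: float = 1e-10,
                       var_cutoff: float | None = None,
                       sv_median_factor: float | None = None) -> EigenCellSet:
    """Thin SVD of the selected-gene submatrix with deterministic signs.

    Two optional truncation rules restrict the eigen-cells entering the
    downstream correlation network (the default keeps every numerically
    nonzero component):

    * ``var_cutoff`` keeps components whose explained-variance fraction
      s_r^2 / sum(s^2) is at least the cutoff;
    * ``sv_median_factor`` keeps components with s_r >= factor *
      median(s) — with more than half the spectrum at the noise floor the
      median estimates that floor, so this drops components indistinguishable
      from noise.

    The leading component is always retained.
    """
    if isinstance(X_sub, ExpressionMatrix):
        V = X_sub.values
        gene_names = list(X_sub.gene_names)
    else:
        V = np.asarray(X_sub, dtype=float)
        if gene_names is None:
            gene_names = [f"g{i}" for i in range(V.shape[1])]
    n, p = V.shape
    if p < 2:
        raise ValueError("too few differentially regulated genes (p* < 2)")
    if n < 2:
        raise ValueError("need at least 2 cells")
    W, S, Et = np.linalg.svd(V, full_matrices=False)
    E = Et.T
    keep = S >= rank_tol * (S[0] if S[0] > 0 else 1.0)
    W, S, E = W[:, keep], S[keep], E[:, keep]
    if var_cutoff is not None and len(S):
        frac = S**2 / np.sum(S**2)
        keep = frac >= var_cutoff
        keep[0] = True  # never drop the leading component
        W, S, E = W[:, keep], S[keep], E[:, keep]
    if sv_median_factor is not None and len(S):
        keep = S >= sv_median_factor * np.median(S)
        keep[0] = True
        W, S, E = W[:, keep], S[keep], E[:, keep]
    # sign convention: largest-|loading| entry of each eigen-cell positive
    for r in range(E.shape[1]):
        k = int(np.argmax(np.abs(E[:, r])))
        if E[k, r] < 0:
            E[:, r] = -E[:, r]
            W[:, r] = -W[:, r]
    return EigenCellSet(W, S, E, gene_names)


@dataclass
class CorrelationNetwork:
    """Pearson correlations between two groups' eigen-cells.

    ``gamma[i, j]`` correlates query eigen-cell i with target eigen-cell j
    over the shared p* gene loadings; ``significant`` marks pairs with
    two-sided p <= alpha.
    """

    gamma: np.ndarray
    pvalues: np.ndarray
    significant: np.ndarray
    alpha: float

    @property
    def n_pairs(self) -> int:
        return self.gamma.size

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def _pearson_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Columnwise Pearson correlations between columns of A and of B."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    denom = np.outer(
        np.sqrt(np.sum(Ac**2, axis=0)), np.sqrt(np.sum(Bc**2, axis=0))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        g = (Ac.T @ Bc) / denom
    g[~np.isfinite(g)] = 0.0
    return np.clip(g, -1.0, 1.0)


def eigencell_correlation(
    EQ: EigenCellSet, ET: EigenCellSet, alpha: float = 0.05
) -> CorrelationNetwork:
    """Eigen-cell correlation network between a query and a target group.

    Both sets must be computed on the same ordered gene list; p-values use
    the t statistic t = gamma * sqrt((p*-2)/(1-gamma^2)) with p*-2 degrees
    of freedom, two-sided.
    """
    if EQ.gene_names != ET.gene_names:
        raise ValueError("eigen-cell sets must share the same ordered gene set")
    pstar = len(EQ.gene_names)
    if pstar < 3:
        raise ValueError("p-values undefined for p* < 3")
    g = _pearson_matrix(EQ.E, ET.E)
    df = pstar - 2
    with np.errstate(divide="ignore"):
        t = g * np.sqrt(df / np.maximum(1.0 - g**2, 1e-300))
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals = np.minimum(pvals, 1.0)
    return CorrelationNetwork(g, pvals, pvals <= alpha, alpha)


def top_loading_genes(
    sets: list[EigenCellSet], k: int = 10
) -> list[tuple[str, float]]:
    """Genes ranked by mean |loading| on the first eigen-cell.

    Across repeated estimations the gene universes may differ (each
    iteration selects its own gene set); the union is taken, and a gene
    absent from an iteration contributes |loading| 0 for it. Returns the
    top ``k`` (gene, mean |loading|) pairs.
    """
    if not sets:
        raise ValueError("empty eigen-cell set list")
    universe: dict[str, None] = {}
    for s in sets:
        for g in s.gene_names:
            universe.setdefault(g)
    genes = list(universe)
    acc = np.zeros(len(genes))
    pos = {g: i for i, g in enumerate(genes)}
    for s in sets:
        lead = np.abs(s.E[:, 0])
        for g, v in zip(s.gene_names, lead):
            acc[pos[g]] += v
    mean_abs = acc / len(sets)
    if k > len(genes):
        warnings.warn(
            f"k={k} exceeds the {len(genes)}-gene universe; returning all genes"
        )
        k = len(genes)
    order = np.argsort(-mean_abs)[:k]
    return [(genes[i], float(mean_abs[i])) for i in order]
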