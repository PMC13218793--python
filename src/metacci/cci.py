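"""Cell-group interaction calls from eigen-cell correlation networks.

For a query group Q, every target group T contributes n_T = R_Q * R_T
candidate eigen-cell pairs, z_T of which are significantly correlated.
With N = sum_T n_T and K = sum_T z_T over all targets of the query, the
number of significant pairs falling on one target under no association is
hypergeometric, Z ~ Hypergeom(N, K, n_T), and the overrepresentation
p-value is P(Z >= z_T). Benjamini-Hochberg correction is applied across
the targets of each query; Q-T is significant when q <= alpha.

To suppress subsampling noise the whole procedure is repeated over
independent cell subsamples; an interaction is declared only when it is
significant in more than 50% of iterations, and its edge weight is the
mean of -log(q) across iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffreg import permutation_pvalues, select_differential_genes
from .eigencell import (
    CorrelationNetwork,
    EigenCellSet,
    compute_eigencells,
    eigencell_correlation,
)
from .grn import GeneNetwork, estimate_network
from .io import ExpressionMatrix, subsample_group

logger = logging.getLogger(__name__)

_Q_FLOOR = np.finfo(float).tiny  # guard for -log(q) at q == 0


def hypergeom_pvalue(z: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(Z >= z).

    Equals 1 - sum_{i=0}^{z-1} C(K,i) C(N-K, n-i) / C(N,n); the empty sum
    at z = 0 gives p = 1.
    """
    if not (0 <= z <= n <= N) or not (0 <= K <= N):
        raise ValueError(f"invalid hypergeometric counts z={z}, N={N}, K={K}, n={n}")
    if z == 0:
        return 1.0
    return float(stats.hypergeom.sf(z - 1, N, K, n))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_query_vs_targets(
    corr_nets: dict[str, CorrelationNetwork], alpha: float = 0.05
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of significant pairs per target.

    Returns a frame indexed by target with columns z, n, N, K, p_value,
    q_value, significant; BH is applied across the targets of this query.
    """
    if not corr_nets:
        raise ValueError("need at least one target")
    targets = list(corr_nets)
    n_arr = np.array([corr_nets[t].n_pairs for t in targets])
    z_arr = np.array([corr_nets[t].n_significant for t in targets])
    N, K = int(n_arr.sum()), int(z_arr.sum())
    pvals = np.array(
        [hypergeom_pvalue(int(z), N, K, int(n)) for z, n in zip(z_arr, n_arr)]
    )
    qvals = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "z": z_arr,
            "n": n_arr,
            "N": N,
            "K": K,
            "p_value": pvals,
            "q_value": qvals,
            "significant": qvals <= alpha,
        },
        index=pd.Index(targets, name="target"),
    )


@dataclass
class CCIConfig:
    """Tunable parameters of the inference pipeline.

    ``n_cells``: per-group subsample size per iteration (300 balances
    network stability against runtime). ``omega``: permutations for the
    differential-regulation screen. ``n_iterations``: independent
    subsampling rounds aggregated into frequencies and edge weights.
    ``log_base``: 'e' or '10' for the -log(q) edge weight.
    ``bh_scope``: 'per_query' (default) or 'global' BH correction.
    """

    n_cells: int = 300
    n_iterations: int = 50
    alpha: float = 0.05
    omega: int = 100
    n_lambda: int = 50
    seed: int = 0
    log_base: str = "e"
    bh_scope: str = "per_query"
    conservative_perm: bool = False
    reuse_lambda: bool = False  # fast permutation mode (see diffreg)
    var_cutoff: float | None = None  # eigen-cell explained-variance cutoff
    sv_median_factor: float | None = None  # eigen-cell noise-floor cutoff
    control_groups: tuple[str, ...] | None = None  # restrict control draws


def _neglog(q: np.ndarray | float, base: str) -> np.ndarray | float:
    q = np.maximum(q, _Q_FLOOR)
    return -np.log10(q) if base == "10" else -np.log(q)


@dataclass
class CCIResult:
    """Aggregated interaction calls plus per-iteration records.

    ``summary`` rows are ordered (query, target) pairs with the fraction
    of iterations significant, the mean -log(q) edge weight, and the
    declared flag (frequency strictly above 0.5). ``eigencells`` and
    ``networks`` keep the per-iteration query-group factors/networks for
    marker extraction and edge aggregation.
    """

    summary: pd.DataFrame
    iterations: pd.DataFrame
    config: CCIConfig
    eigencells: dict[str, list[EigenCellSet]] = field(default_factory=dict)
    networks: dict[str, list[GeneNetwork]] = field(default_factory=dict)

    def declared(self) -> pd.DataFrame:
        return self.summary[self.summary["declared"]]


def _iteration_seed(master_seed: int, query_index: int, iteration: int) -> int:
    """Fixed seed derivation: reruns reproduce bit-identically."""
    return int((master_seed + 1_000_003 * iteration + 7_919 * query_index) % (2**31))


def run_query_iteration(
    X: ExpressionMatrix,
    query: str,
    groups: list[str],
    config: CCIConfig,
    seed: int,
) -> tuple[pd.DataFrame | None, EigenCellSet | None, GeneNetwork | None]:
    """One subsample-screen-correlate-test round for one query group.

    Returns (per-target test frame, query eigen-cells, query network);
    all None when the screen selects fewer than 3 genes (the iteration
    then records no significant pairs for this query).
    """
    rng = np.random.default_rng(seed)
    sub_seeds = {g: int(rng.integers(2**31)) for g in groups}
    subs = {g: subsample_group(X, g, config.n_cells, sub_seeds[g]) for g in groups}

    others = [g for g in groups if g != query]
    pool = (
        [g for g in others if g in config.control_groups]
        if config.control_groups is not None
        else others
    )
    if not pool:
        raise ValueError("no eligible control group for query " + query)
    control = pool[int(rng.integers(len(pool)))]

    XQ, XC = subs[query], subs[control]
    screen = permutation_pvalues(
        XQ,
        XC,
        omega=config.omega,
        seed=int(rng.integers(2**31)),
        conservative=config.conservative_perm,
        reuse_lambda=config.reuse_lambda,
    )
    vstar = select_differential_genes(screen, config.alpha)
    if len(vstar) < 3:
        logger.info(
            "query %s: %d differentially regulated genes (<3); "
            "no significant pairs this iteration", query, len(vstar)
        )
        return None, None, None

    eigen = {
        g: compute_eigencells(
            subs[g].select_genes(vstar),
            var_cutoff=config.var_cutoff,
            sv_median_factor=config.sv_median_factor,
        )
        for g in groups
    }
    corr = {
        t: eigencell_correlation(eigen[query], eigen[t], config.alpha)
        for t in others
    }
    tests = test_query_vs_targets(corr, config.alpha)
    net_q = estimate_network(XQ.select_genes(vstar))
    return tests, eigen[query], net_q


def infer_cci(
    X: ExpressionMatrix,
    queries: list[str] | None = None,
    config: CCIConfig | None = None,
) -> CCIResult:
    """Full interaction inference over repeated subsampling iterations.

    ``X`` must already be restricted to the ligand-receptor gene universe
    (see :func:`metacci.io.restrict_to_lr_genes`). Groups smaller than the
    subsample size are excluded (with a log message); each remaining query
    group is tested against every other group. Deterministic given
    ``config.seed``.
    """
    config = config or CCIConfig()
    all_groups = X.groups
    sizes = {g: int((X.group_labels == g).sum()) for g in all_groups}
    groups = [g for g in all_groups if sizes[g] >= config.n_cells]
    skipped = [g for g in all_groups if sizes[g] < config.n_cells]
    if skipped:
        logger.info("skipping groups below %d cells: %s", config.n_cells, skipped)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with enough cells")
    if queries is None:
        queries = list(groups)
    else:
        bad = [q for q in queries if q not in groups]
        if bad:
            raise ValueError(f"query groups unavailable or too small: {bad}")

    records = []
    eigencells: dict[str, list[EigenCellSet]] = {q: [] for q in queries}
    networks: dict[str, list[GeneNetwork]] = {q: [] for q in queries}
    for qi, query in enumerate(queries):
        targets = [g for g in groups if g != query]
        for it in range(config.n_iterations):
            seed = _iteration_seed(config.seed, qi, it)
            tests, eig, net = run_query_iteration(X, query, groups, config, seed)
            if eig is not None:
                eigencells[query].append(eig)
                networks[query].append(net)
            for t in targets:
                if tests is None:
                    p_val, q_val, sig, z, n = 1.0, 1.0, False, 0, 0
                else:
                    row = tests.loc[t]
                    p_val = float(row["p_value"])
                    q_val = float(row["q_value"])
                    sig = bool(row["significant"])
                    z, n = int(row["z"]), int(row["n"])
                records.append(
                    {
                        "query": query,
                        "target": t,
                        "iteration": it,
                        "z": z,
                        "n": n,
                        "p_value": p_val,
                        "q_value": q_val,
                        "significant": sig,
                    }
                )

    iters = pd.DataFrame.from_records(records)
    if config.bh_scope == "global":
        # BH jointly across all query-target pairs within each iteration
        for it in iters["iteration"].unique():
            mask = iters["iteration"] == it
            q = bh_adjust(iters.loc[mask, "p_value"].to_numpy())
            iters.loc[mask, "q_value"] = q
            iters.loc[mask, "significant"] = q <= config.alpha
    grouped = iters.groupby(["query", "target"], sort=False)
    summary = grouped.agg(
        frequency=("significant", "mean"),
        mean_q=("q_value", "mean"),
        mean_sig_pairs=("z", "mean"),
    ).reset_index()
    summary["edge_weight"] = grouped["q_value"].apply(
        lambda q: float(np.mean(_neglog(q.to_numpy(), config.log_base)))
    ).to_numpy()
    summary["declared"] = summary["frequency"] > 0.5
    return CCIResult(summary, iters, config, eigencells, networks)
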