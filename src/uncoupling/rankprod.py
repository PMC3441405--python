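"""Rank-product differential expression with permutation-based pfp.

The unpaired two-class rank product: every control x treated replicate
pair yields one log2 fold-change vector, genes are ranked within each
vector (rank 1 = strongest change in the requested direction, average
ranks on ties), and a gene's statistic is the geometric mean of its ranks
across the K pairings. Small rank products indicate consistent regulation
regardless of the expression scale, which makes the caller robust to
between-dataset heterogeneity.

Significance is expressed as the pfp (percentage of false prediction): the
expected number of permuted rank products at least as extreme as a gene's,
divided by the gene's position in the observed ranking. The permutation
null shuffles gene labels independently within each replicate ranking. A
two-sample t-test caller with Benjamini-Hochberg correction is provided as
the standard alternative.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down")


class RankProdError(ValueError):
    pass


@dataclass
class RankProductResult:
    """Per-gene rank products plus the per-pairing rank matrix behind them."""

    rp: pd.Series                 # per-gene geometric-mean rank
    ranks: np.ndarray             # K x G matrix of within-pairing ranks
    direction: str
    constant_features: list[str]  # genes flat across all samples (middle ranks)
    control: np.ndarray | None = None  # G x n_c log2 intensities
    treated: np.ndarray | None = None  # G x n_t


def rank_product_statistic(
    control: pd.DataFrame, treated: pd.DataFrame, direction: str
) -> RankProductResult:
    """Rank product over all control x treated replicate pairings.

    ``direction='up'`` ranks the largest treated-minus-control fold change
    first; ``'down'`` the smallest. Ties receive average ranks, so a gene
    constant across all samples lands mid-ranking (flagged).
    """
    if direction not in DIRECTIONS:
        raise RankProdError(f"direction must be one of {DIRECTIONS}")
    if control.shape[1] < 2 or treated.shape[1] < 2:
        raise RankProdError("need >= 2 replicates per group")
    if not control.index.equals(treated.index):
        raise RankProdError("control and treated gene universes differ")
    genes = control.index
    C = control.to_numpy(dtype=float)
    T = treated.to_numpy(dtype=float)
    sign = -1.0 if direction == "up" else 1.0
    rank_rows = []
    for i in range(C.shape[1]):
        for j in range(T.shape[1]):
            fc = T[:, j] - C[:, i]
            rank_rows.append(stats.rankdata(sign * fc, method="average"))
    ranks = np.asarray(rank_rows)
    rp = np.exp(np.mean(np.log(ranks), axis=0))
    flat = (np.ptp(C, axis=1) == 0) & (np.ptp(T, axis=1) == 0) & (T[:, 0] == C[:, 0])
    constant = list(genes[flat])
    if constant:
        logger.info("%d constant features received middle ranks", len(constant))
    return RankProductResult(
        rp=pd.Series(rp, index=genes, name=f"rp_{direction}"),
        ranks=ranks,
        direction=direction,
        constant_features=constant,
        control=C,
        treated=T,
    )


def _pfp_from_null(
    rp_obs: np.ndarray, null_rp_sorted: np.ndarray, n_draws: int
) -> np.ndarray:
    """pfp from a pooled null sample of ``n_draws`` full-ranking draws."""
    # rank position r = number of observed rank products <= this gene's
    order_rank = stats.rankdata(rp_obs, method="max")
    expected_fp = np.searchsorted(null_rp_sorted, rp_obs, side="right") / n_draws
    pfp = expected_fp / order_rank
    # step-down: cumulative max in increasing rank-product order
    order = np.argsort(rp_obs, kind="mergesort")
    pfp[order] = np.maximum.accumulate(pfp[order])
    return pfp


def estimate_pfp(
    result: RankProductResult,
    n_permutations: int = 1000,
    seed: int = 0,
    *,
    scheme: str = "array",
    exhaustive: bool = False,
    max_exhaustive: int = 200_000,
) -> pd.Series:
    """Permutation pfp for each gene's rank product.

    A gene's pfp is the expected count of permuted rank products at or
    below its observed value, divided by its position in the observed
    ordering, with cumulative-max enforcement of monotonicity.

    Two permutation nulls are offered. ``scheme='array'`` (default)
    shuffles gene labels independently within each sample array and
    recomputes every replicate-pairing ranking, preserving the rank
    correlation induced by pairings that share an array — the calibrated
    null for the all-pairings statistic. ``scheme='ranking'`` shuffles
    gene labels independently within each of the K rankings (a stricter
    independence null, anti-conservative on shared-replicate designs but
    exhaustively enumerable). ``exhaustive=True`` enumerates every tuple
    of per-ranking permutations of the ``'ranking'`` null (tiny instances
    only).
    """
    ranks = result.ranks
    K, G = ranks.shape
    rp_obs = result.rp.to_numpy()
    if exhaustive:
        n_tuples = math.factorial(G) ** K
        if n_tuples > max_exhaustive:
            raise RankProdError(
                f"exhaustive enumeration of {n_tuples} permutation tuples refused"
            )
        log_rows = [np.log(row) for row in ranks]
        null_vals = []
        for perm_tuple in itertools.product(
            *(itertools.permutations(row) for row in log_rows)
        ):
            null_vals.append(np.exp(np.mean(np.asarray(perm_tuple), axis=0)))
        null = np.sort(np.concatenate(null_vals))
        pfp = _pfp_from_null(rp_obs, null, n_tuples)
        return pd.Series(pfp, index=result.rp.index, name="pfp")
    if n_permutations < 100:
        logger.warning(
            "estimate_pfp: %d permutations gives an unstable pfp estimate", n_permutations
        )
    rng = np.random.default_rng(seed)
    if scheme == "ranking":
        log_sum = np.zeros((n_permutations, G))
        for k in range(K):
            tiled = np.tile(np.log(ranks[k]), (n_permutations, 1))
            log_sum += rng.permuted(tiled, axis=1)
        null = np.sort((np.exp(log_sum / K)).ravel())
    elif scheme == "array":
        if result.control is None or result.treated is None:
            raise RankProdError("array scheme needs the expression matrices")
        C, T = result.control, result.treated
        sign = -1.0 if result.direction == "up" else 1.0
        null_chunks = []
        for _ in range(n_permutations):
            Cp = np.take_along_axis(
                C, rng.permuted(np.tile(np.arange(G)[:, None], (1, C.shape[1])), axis=0), 0
            )
            Tp = np.take_along_axis(
                T, rng.permuted(np.tile(np.arange(G)[:, None], (1, T.shape[1])), axis=0), 0
            )
            fc = sign * (Tp[:, None, :] - Cp[:, :, None]).reshape(G, K)
            perm_ranks = stats.rankdata(fc, axis=0, method="average")
            null_chunks.append(np.exp(np.mean(np.log(perm_ranks), axis=1)))
        null = np.sort(np.concatenate(null_chunks))
    else:
        raise RankProdError(f"unknown permutation scheme {scheme!r}")
    pfp = _pfp_from_null(rp_obs, null, n_permutations)
    return pd.Series(pfp, index=result.rp.index, name="pfp")


def rankprod_deg_table(
    control: pd.DataFrame,
    treated: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
    threshold: float = 0.2,
    *,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Full two-directional rank-product DEG table for one comparison.

    Up- and down-regulation are analyzed as separate one-sided rankings
    and combined per gene by the smaller pfp; ``direction`` is the argmin.
    """
    fc = treated.mean(axis=1) - control.mean(axis=1)
    table = pd.DataFrame({"log2fc": fc})
    for i, direction in enumerate(DIRECTIONS):
        res = rank_product_statistic(control, treated, direction)
        pfp = estimate_pfp(
            res, n_permutations=n_permutations, seed=seed + i, exhaustive=exhaustive
        )
        table[f"rp_{direction}"] = res.rp
        table[f"pfp_{direction}"] = pfp
    up_best = table["pfp_up"] <= table["pfp_down"]
    table["direction"] = np.where(up_best, "up", "down")
    table["pfp"] = np.where(up_best, table["pfp_up"], table["pfp_down"])
    table["significant"] = table["pfp"] < threshold
    return table


def call_degs(
    deg_table: pd.DataFrame, threshold: float
) -> tuple[set[str], dict[str, str]]:
    """Significant genes (min-direction pfp or adjusted p below threshold)."""
    col = "pfp" if "pfp" in deg_table.columns else "p_adjusted"
    sig = deg_table.index[deg_table[col] < threshold]
    directions = deg_table.loc[sig, "direction"].to_dict()
    return set(sig), directions


def ttest_bh_caller(
    control: pd.DataFrame,
    treated: pd.DataFrame,
    alpha: float = 0.05,
    *,
    variance_floor: float = 1e-12,
) -> pd.DataFrame:
    """Two-sided Welch-free two-sample t per gene with BH step-up.

    Genes with zero variance in both groups get p = 1 when the group means
    are equal; otherwise the pooled variance is floored (logged), which
    drives p toward 0 for a genuine mean shift.
    """
    if control.shape[1] < 2 or treated.shape[1] < 2:
        raise RankProdError("need >= 2 replicates per group")
    C = control.to_numpy(dtype=float)
    T = treated.to_numpy(dtype=float)
    fc = T.mean(axis=1) - C.mean(axis=1)
    t_stat, p = stats.ttest_ind(T, C, axis=1, equal_var=True)
    zero_var = (C.var(axis=1) == 0) & (T.var(axis=1) == 0)
    if zero_var.any():
        logger.info("ttest_bh_caller: %d genes with zero within-group variance", zero_var.sum())
        n1, n2 = T.shape[1], C.shape[1]
        se = np.sqrt(variance_floor * (1 / n1 + 1 / n2))
        t_floor = fc / se
        df = n1 + n2 - 2
        p_floor = 2 * stats.t.sf(np.abs(t_floor), df)
        p = np.where(zero_var, np.where(fc == 0, 1.0, p_floor), p)
        t_stat = np.where(zero_var, np.where(fc == 0, 0.0, t_floor), t_stat)
    reject, padj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "log2fc": fc,
            "t_stat": t_stat,
            "p_value": p,
            "p_adjusted": padj,
            "direction": np.where(fc >= 0, "up", "down"),
            "significant": reject,
        },
        index=control.index,
    )
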