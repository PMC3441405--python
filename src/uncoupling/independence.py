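"""Three tests of transcriptome-translatome dependence on DEG labels.

Given N measured genes, n1 transcriptome DEGs, n2 translatome DEGs and an
observed overlap k, the module provides:

* a likelihood-ratio test of equal DEG proportions at the two levels
  (two-binomial model, shared-proportion null, chi-square with 1 df);
* a random-overlap bootstrap: repeatedly draw n1- and n2-gene subsets of
  the universe without replacement and compare the observed overlap with
  the resampled one (the exact hypergeometric upper tail is the
  closed-form oracle);
* plug-in mutual information (bits) between the two binary DEG indicator
  vectors, with the feasibility bounds implied by (n1, n2, N) — zero
  overlap at the low end, complete overlap of two lists of size
  (n1+n2)/2 at the high end — and a bootstrap null for the observed MI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


class IndependenceError(ValueError):
    pass


def _validate_counts(n1: int, n2: int, N: int) -> None:
    if N <= 0:
        raise IndependenceError("universe size N must be positive")
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise IndependenceError(f"need 0 <= n1, n2 <= N; got n1={n1}, n2={n2}, N={N}")


def likelihood_ratio_test(n1: int, n2: int, N: int) -> tuple[float, float]:
    """Test the null that the DEG proportion is the same at both levels.

    Under H0 both counts are Binomial(N, p0) with p0 = (n1+n2)/(2N); under
    H1 each level has its own proportion. Returns (G, p) with
    G = 2(l1 - l0) referred to chi-square with 1 df.
    """
    _validate_counts(n1, n2, N)
    if n1 == n2:
        return 0.0, 1.0
    p0 = (n1 + n2) / (2 * N)
    ll0 = stats.binom.logpmf(n1, N, p0) + stats.binom.logpmf(n2, N, p0)
    ll1 = stats.binom.logpmf(n1, N, n1 / N) + stats.binom.logpmf(n2, N, n2 / N)
    g = float(2.0 * (ll1 - ll0))
    return g, float(stats.chi2.sf(g, df=1))


def _sample_overlaps(
    N: int, n1: int, n2: int, n_iter: int, rng: np.random.Generator, chunk: int = 2000
) -> np.ndarray:
    """Overlap sizes between a fixed n1-subset and random n2-subsets.

    By exchangeability the first list can be held fixed at {0..n1-1}; each
    iteration draws a uniform n2-subset of the N indices (the n2 smallest
    of N iid uniforms) and records the intersection size.
    """
    if n1 == 0 or n2 == 0:
        return np.zeros(n_iter, dtype=np.int64)
    if n2 == N:
        return np.full(n_iter, n1, dtype=np.int64)
    out = np.empty(n_iter, dtype=np.int64)
    done = 0
    while done < n_iter:
        c = min(chunk, n_iter - done)
        u = rng.random((c, N))
        subset = np.argpartition(u, n2 - 1, axis=1)[:, :n2]
        out[done : done + c] = (subset < n1).sum(axis=1)
        done += c
    return out


def random_overlap_test(
    n1: int,
    n2: int,
    N: int,
    k_observed: int,
    n_iter: int = 100_000,
    seed: int = 0,
) -> tuple[float, dict]:
    """Bootstrap p-value for the observed DEG overlap.

    p = (#{resampled overlap >= k_observed} + 1) / (n_iter + 1), with the
    add-one correction so p is never exactly zero.
    """
    _validate_counts(n1, n2, N)
    if not 0 <= k_observed <= min(n1, n2):
        raise IndependenceError("k_observed must be in [0, min(n1, n2)]")
    rng = np.random.default_rng(seed)
    overlaps = _sample_overlaps(N, n1, n2, n_iter, rng)
    p = (int((overlaps >= k_observed).sum()) + 1) / (n_iter + 1)
    summary = {
        "n_iter": n_iter,
        "mean": float(overlaps.mean()),
        "sd": float(overlaps.std()),
        "min": int(overlaps.min()),
        "max": int(overlaps.max()),
    }
    return float(p), summary


def hypergeometric_overlap_pvalue(n1: int, n2: int, N: int, k: int) -> float:
    """Exact upper tail P(X >= k), X ~ Hypergeom(N, n1, n2)."""
    _validate_counts(n1, n2, N)
    if not 0 <= k <= min(n1, n2):
        raise IndependenceError("k must be in [0, min(n1, n2)]")
    return float(stats.hypergeom.sf(k - 1, N, n1, n2))


def _mi_from_overlap(k, n1: int, n2: int, N: int):
    """Plug-in MI (bits) of the 2x2 DEG-indicator table with overlap k.

    Vectorized over ``k``. Cells: (k, n1-k, n2-k, N-n1-n2+k); 0*log 0 = 0.
    """
    scalar = np.isscalar(k) or np.ndim(k) == 0
    k = np.atleast_1d(np.asarray(k, dtype=float))
    cells = np.stack([k, n1 - k, n2 - k, N - n1 - n2 + k])
    px = np.array([n1, n1, N - n1, N - n1], dtype=float)[:, None] / N
    py = np.array([n2, N - n2, n2, N - n2], dtype=float)[:, None] / N
    p = cells / N
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / (px * py)), 0.0)
    mi = np.maximum(terms.sum(axis=0), 0.0)
    return float(mi[0]) if scalar else mi


def mutual_information_binary(x, y) -> float:
    """Plug-in mutual information (bits) of two binary vectors."""
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise IndependenceError("x and y must be equal-length 1-D vectors")
    N = len(x)
    n1, n2 = int(x.sum()), int(y.sum())
    k = int((x & y).sum())
    return float(_mi_from_overlap(k, n1, n2, N))


def mi_bounds(n1: int, n2: int, N: int) -> tuple[float, float]:
    """Feasibility bounds on MI given the two DEG counts.

    The minimum is the smallest plug-in MI over all realizable overlaps
    k in [max(0, n1+n2-N), min(n1, n2)]; it is attained near the
    independence overlap n1*n2/N (exactly 0 when that is an integer) and
    never exceeds the zero-overlap MI. The maximum is the MI of two
    completely overlapping lists of size floor((n1+n2)/2), i.e. the
    binary entropy H(floor((n1+n2)/2)/N).
    """
    _validate_counts(n1, n2, N)
    if n1 == 0 and n2 == 0:
        return 0.0, 0.0
    k_lo = max(0, n1 + n2 - N)
    if k_lo > 0:
        logger.info("mi_bounds: lists cannot be disjoint, overlap forced >= %d", k_lo)
    feasible = np.arange(k_lo, min(n1, n2) + 1)
    mi_min = float(_mi_from_overlap(feasible, n1, n2, N).min())
    s = (n1 + n2) // 2
    if (n1 + n2) % 2:
        logger.debug("mi_bounds: odd n1+n2, floored joint list size to %d", s)
    q = s / N
    mi_max = float(stats.entropy([q, 1 - q], base=2)) if 0 < q < 1 else 0.0
    return mi_min, mi_max


def mi_test(
    x,
    y,
    n_iter: int = 100_000,
    seed: int = 0,
) -> dict:
    """Bootstrap test of the observed MI between two binary DEG vectors.

    Resamples keep the two DEG counts fixed and re-draw the gene
    assignments uniformly; p = (#{MI_resampled >= MI_observed} + 1) /
    (n_iter + 1). Also reports the position of the observed MI inside the
    feasibility range, (MI - min) / (max - min) (``None`` when the range
    is degenerate).
    """
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape:
        raise IndependenceError("length mismatch between DEG indicator vectors")
    N = len(x)
    n1, n2 = int(x.sum()), int(y.sum())
    mi_obs = mutual_information_binary(x, y)
    lo, hi = mi_bounds(n1, n2, N)
    rng = np.random.default_rng(seed)
    overlaps = _sample_overlaps(N, n1, n2, n_iter, rng)
    mi_null = _mi_from_overlap(overlaps, n1, n2, N)
    p = (int((mi_null >= mi_obs).sum()) + 1) / (n_iter + 1)
    midrange = None if hi == lo else (mi_obs - lo) / (hi - lo)
    return {
        "mi_observed": mi_obs,
        "mi_min": lo,
        "mi_max": hi,
        "mi_midrange_position": midrange,
        "mi_p": float(p),
        "n_iter": n_iter,
    }


@dataclass
class IndependenceResult:
    """All three independence tests for one dataset pair."""

    N: int
    n1: int
    n2: int
    k: int
    lrt_stat: float
    lrt_p: float
    overlap_p: float
    overlap_p_exact: float
    mi_observed: float
    mi_min: float
    mi_max: float
    mi_midrange_position: float | None
    mi_p: float

    def to_dict(self) -> dict:
        return asdict(self)


def independence_tests(
    transcriptome_degs,
    translatome_degs,
    universe,
    n_iter: int = 100_000,
    seed: int = 0,
) -> IndependenceResult:
    """Run all three tests on two DEG sets over a gene universe."""
    universe = list(universe)
    uni = set(universe)
    tc = set(transcriptome_degs) & uni
    tl = set(translatome_degs) & uni
    N, n1, n2 = len(uni), len(tc), len(tl)
    k = len(tc & tl)
    lrt_stat, lrt_p = likelihood_ratio_test(n1, n2, N)
    overlap_p, _ = random_overlap_test(n1, n2, N, k, n_iter=n_iter, seed=seed)
    exact = hypergeometric_overlap_pvalue(n1, n2, N, k)
    x = np.array([g in tc for g in universe])
    y = np.array([g in tl for g in universe])
    mi = mi_test(x, y, n_iter=n_iter, seed=seed + 1)
    return IndependenceResult(
        N=N,
        n1=n1,
        n2=n2,
        k=k,
        lrt_stat=lrt_stat,
        lrt_p=lrt_p,
        overlap_p=overlap_p,
        overlap_p_exact=exact,
        mi_observed=mi["mi_observed"],
        mi_min=mi["mi_min"],
        mi_max=mi["mi_max"],
        mi_midrange_position=mi["mi_midrange_position"],
        mi_p=mi["mi_p"],
    )
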