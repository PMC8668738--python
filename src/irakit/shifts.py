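"""Three detectors of step changes in annual series.

* CONISS — constrained incremental sum-of-squares chronological
  clustering: agglomerative clustering in which only temporally adjacent
  clusters may merge, the merge cost being the increase in total
  within-cluster sum of squares (Ward increment).
* Breakpoint structural analysis — dynamic-programming segmentation of a
  score series into constant-mean segments, number of breakpoints chosen
  by BIC, with a sup-F test of "no break" by permutation.
* STARS — the sequential t-test analysis of regime shifts with the
  Regime Shift Index (RSI) confirming or rejecting candidate shifts.

All detectors report threshold years using the last-year-of-the-old-regime
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .data import AnnualMatrix, SeriesVector
from .errors import DataError

__all__ = [
    "ConissResult",
    "coniss",
    "cut_dendrogram",
    "BreakpointResult",
    "detect_breakpoints",
    "supf_test",
    "StarsParams",
    "StarsResult",
    "stars",
]


# ---------------------------------------------------------------------------
# CONISS

@dataclass(frozen=True)
class ConissMerge:
    """One agglomeration step: clusters at adjacent positions joined."""

    left_node: int
    right_node: int
    height: float  # within-cluster sum-of-squares increment
    node: int  # id of the new cluster (leaves are 0..n-1)


@dataclass(frozen=True)
class ConissResult:
    years: np.ndarray
    merges: tuple[ConissMerge, ...]
    children: dict  # node id -> (left child, right child)
    heights: dict  # node id -> merge height

    @property
    def n(self) -> int:
        return len(self.years)

    def to_newick(self) -> str:
        """Dendrogram as a Newick string, merge heights as branch lengths."""

        def rec(node: int) -> str:
            if node < self.n:
                return str(self.years[node])
            left, right = self.children[node]
            h = self.heights[node]
            return f"({rec(left)}:{h:.8g},{rec(right)}:{h:.8g})"

        root = self.merges[-1].node
        return rec(root) + ";"


def coniss(m: AnnualMatrix) -> ConissResult:
    """Constrained incremental sum-of-squares clustering of annual rows.

    At each step the pair of temporally adjacent clusters whose merge
    least increases the total within-cluster sum of squares is joined;
    the increment for clusters i, j is n_i n_j / (n_i + n_j) *
    ||mean_i - mean_j||^2. Ties go to the earlier pair. The caller
    decides whether rows are standardized first (the pipeline does).
    """
    x = m.values
    n = len(m.years)
    if n < 3:
        raise DataError("CONISS needs at least 3 years")
    sizes = [1] * n
    means = [x[i].astype(float) for i in range(n)]
    nodes = list(range(n))
    merges: list[ConissMerge] = []
    children: dict[int, tuple[int, int]] = {}
    heights: dict[int, float] = {}
    next_id = n
    while len(nodes) > 1:
        costs = np.array(
            [
                sizes[i] * sizes[i + 1] / (sizes[i] + sizes[i + 1])
                * float(np.sum((means[i] - means[i + 1]) ** 2))
                for i in range(len(nodes) - 1)
            ]
        )
        i = int(np.argmin(costs))
        h = float(costs[i])
        ni, nj = sizes[i], sizes[i + 1]
        merged_mean = (ni * means[i] + nj * means[i + 1]) / (ni + nj)
        merges.append(
            ConissMerge(left_node=nodes[i], right_node=nodes[i + 1],
                        height=h, node=next_id)
        )
        children[next_id] = (nodes[i], nodes[i + 1])
        heights[next_id] = h
        nodes[i : i + 2] = [next_id]
        sizes[i : i + 2] = [ni + nj]
        means[i : i + 2] = [merged_mean]
        next_id += 1
    return ConissResult(
        years=m.years, merges=tuple(merges), children=children, heights=heights
    )


def cut_dendrogram(r: ConissResult, k: int) -> tuple[np.ndarray, list[int]]:
    """Cut the CONISS tree into ``k`` contiguous blocks of years.

    Splits greedily from the root: k-1 times, the current component
    whose root merge has the largest height is split into its two
    children (with monotone heights this equals undoing the k-1 most
    expensive merges). Returns (regime labels per year, threshold years
    = last year of each earlier block).
    """
    n = r.n
    if not 1 <= k <= n:
        raise DataError(f"k must be in [1, {n}], got {k}")
    roots = [r.merges[-1].node]
    for _ in range(k - 1):
        internal = [nd for nd in roots if nd >= n]
        pick = max(internal, key=lambda nd: (r.heights[nd], nd))
        roots.remove(pick)
        roots.extend(r.children[pick])

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = r.children[node]
        return leaves(a) + leaves(b)

    blocks = sorted((leaves(nd) for nd in roots), key=min)
    labels = np.empty(n, dtype=int)
    for lab, block in enumerate(blocks, start=1):
        labels[block] = lab
    thresholds = [int(r.years[max(block)]) for block in blocks[:-1]]
    return labels, thresholds


# ---------------------------------------------------------------------------
# Breakpoint structural analysis

def _segment_cost_matrix(v: np.ndarray) -> np.ndarray:
    """cost[i, j] = RSS of a constant-mean fit on v[i..j] (inclusive)."""
    n = len(v)
    c1 = np.concatenate([[0.0], np.cumsum(v)])
    c2 = np.concatenate([[0.0], np.cumsum(v * v)])
    cost = np.full((n, n), np.inf)
    for i in range(n):
        ln = np.arange(1, n - i + 1)
        s1 = c1[i + 1 : n + 1] - c1[i]
        s2 = c2[i + 1 : n + 1] - c2[i]
        cost[i, i:] = s2 - s1 * s1 / ln
    return np.clip(cost, 0.0, None)


@dataclass(frozen=True)
class BreakpointResult:
    years: np.ndarray
    m_optimal: int
    breakpoint_years: list[int]
    segment_means: list[float]
    rss_by_m: dict[int, float]
    bic_by_m: dict[int, float]
    supf_statistic: float
    supf_pvalue: float
    confidence_intervals: list[tuple[int, int]]
    min_segment: int


def _dp_segment(cost: np.ndarray, n: int, m: int, min_seg: int):
    """Optimal (m+1)-segment partition by dynamic programming.

    Returns (rss, boundary indices = last index of each segment except
    the final one).
    """
    # dp[r][j]: best RSS of splitting v[0..j] into r+1 segments
    dp = np.full((m + 1, n), np.inf)
    arg = np.zeros((m + 1, n), dtype=int)
    dp[0] = cost[0]
    for r in range(1, m + 1):
        for j in range(n):
            if j + 1 < (r + 1) * min_seg:
                continue
            # previous segment ends at t, current segment t+1..j
            ts = np.arange(r * min_seg - 1, j - min_seg + 1)
            if len(ts) == 0:
                continue
            totals = dp[r - 1, ts] + cost[ts + 1, j]
            b = int(np.argmin(totals))
            dp[r, j] = totals[b]
            arg[r, j] = ts[b]
    rss = dp[m, n - 1]
    bounds = []
    j = n - 1
    for r in range(m, 0, -1):
        t = int(arg[r, j])
        bounds.append(t)
        j = t
    return float(rss), sorted(bounds)


def detect_breakpoints(
    x: SeriesVector,
    max_m: int = 5,
    min_seg_frac: float = 0.15,
    n_perm: int = 199,
    seed: int = 0,
) -> BreakpointResult:
    """Segment a series into constant-mean regimes; pick the number of
    breakpoints by BIC.

    For each candidate count m <= max_m a dynamic program minimizes the
    total residual sum of squares subject to a minimum segment length of
    floor(min_seg_frac * n); BIC(m) = n log(RSS_m / n) + (2m + 1) log n.
    95% confidence intervals per breakpoint come from the RSS profile of
    sliding that boundary (chi-square, 1 df). A sup-F permutation test
    of "no break at all" is attached.
    """
    v = x.values
    n = len(v)
    min_seg = int(np.floor(min_seg_frac * n))
    if min_seg < 2:
        raise DataError("floor(min_seg_frac * n) must be >= 2")
    if n < 2 * min_seg:
        raise DataError("series shorter than two minimum segments")
    max_m = min(max_m, n // min_seg - 1)
    cost = _segment_cost_matrix(v)
    tss = cost[0, n - 1]
    rss_floor = max(tss, 1.0) * 1e-12  # keep log() finite on exact fits
    rss_by_m: dict[int, float] = {}
    bic_by_m: dict[int, float] = {}
    bounds_by_m: dict[int, list[int]] = {}
    for m in range(0, max_m + 1):
        if m == 0:
            rss, bounds = float(cost[0, n - 1]), []
        else:
            rss, bounds = _dp_segment(cost, n, m, min_seg)
        rss_by_m[m] = rss
        bounds_by_m[m] = bounds
        bic_by_m[m] = n * np.log(max(rss, rss_floor) / n) + (2 * m + 1) * np.log(n)
    m_opt = min(bic_by_m, key=lambda m: (round(bic_by_m[m], 10), m))
    bounds = bounds_by_m[m_opt]
    edges = [-1] + bounds + [n - 1]
    seg_means = [float(v[a + 1 : b + 1].mean()) for a, b in zip(edges[:-1], edges[1:])]

    # RSS-profile confidence intervals: slide one boundary, others fixed
    sigma2 = max(rss_by_m[m_opt], rss_floor) / n
    crit = stats.chi2.ppf(0.95, 1) * sigma2
    cis = []
    for bi, b in enumerate(bounds):
        lo_edge = edges[bi]  # end of previous segment
        hi_edge = edges[bi + 2]  # end of next segment
        admissible = []
        for t in range(lo_edge + min_seg, hi_edge - min_seg + 1):
            rss_t = (
                rss_by_m[m_opt]
                - cost[lo_edge + 1, b] - cost[b + 1, hi_edge]
                + cost[lo_edge + 1, t] + cost[t + 1, hi_edge]
            )
            if rss_t - rss_by_m[m_opt] <= crit:
                admissible.append(t)
        cis.append((int(x.years[min(admissible)]), int(x.years[max(admissible)])))

    fstat, pval = supf_test(x, n_perm=n_perm, seed=seed)
    return BreakpointResult(
        years=x.years,
        m_optimal=m_opt,
        breakpoint_years=[int(x.years[b]) for b in bounds],
        segment_means=seg_means,
        rss_by_m=rss_by_m,
        bic_by_m=bic_by_m,
        supf_statistic=fstat,
        supf_pvalue=pval,
        confidence_intervals=cis,
        min_segment=min_seg,
    )


def _supf_stat(v: np.ndarray, trim: float = 0.15) -> float:
    n = len(v)
    rss0 = float(np.sum((v - v.mean()) ** 2))
    if rss0 == 0:
        return 0.0
    lo = max(int(np.ceil(trim * n)), 1)
    hi = n - lo  # first segment lengths lo..hi
    c1 = np.concatenate([[0.0], np.cumsum(v)])
    c2 = np.concatenate([[0.0], np.cumsum(v * v)])
    ln1 = np.arange(lo, hi + 1, dtype=float)
    s1 = c1[lo : hi + 1]
    s2 = c2[lo : hi + 1]
    rss1 = s2 - s1 * s1 / ln1
    ln2 = n - ln1
    t1 = c1[n] - s1
    t2 = c2[n] - s2
    rss2 = t2 - t1 * t1 / ln2
    rss = np.clip(rss1 + rss2, 0.0, None)
    with np.errstate(divide="ignore"):
        f = (rss0 - rss) / (rss / (n - 2))
    return float(np.max(f))


def supf_test(
    x: SeriesVector, n_perm: int = 199, seed: int = 0, trim: float = 0.15
) -> tuple[float, float]:
    """Sup-F test of a single mean shift against a constant mean.

    F(t) compares the one-mean fit with the two-means-split-at-t fit over
    admissible t (15% trimming); the statistic is max_t F(t) and its
    p-value the permutation fraction of shuffled series reaching it.
    """
    v = x.values
    n = len(v)
    if n < 6:
        raise DataError("sup-F needs at least 6 observations")
    if n_perm < 99:
        raise DataError("need at least 99 permutations")
    obs = _supf_stat(v, trim)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _supf_stat(rng.permutation(v), trim) >= obs:
            count += 1
    return obs, (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# STARS

@dataclass(frozen=True)
class StarsParams:
    """Cut-off length (minimum regime length whose shift magnitude is
    kept intact) and the t-test significance level."""

    cutoff_length: int = 15
    significance: float = 0.05

    def __post_init__(self) -> None:
        if self.cutoff_length < 2:
            raise DataError("cutoff_length must be >= 2")
        if not 0 < self.significance < 1:
            raise DataError("significance must be in (0, 1)")


@dataclass(frozen=True)
class StarsResult:
    years: np.ndarray
    shift_years: list[int]  # first year of each new regime
    rsi: list[float]  # one per accepted shift
    regime_means: list[float]
    diff: float  # critical difference used
    sigma_l: float

    @property
    def threshold_years(self) -> list[int]:
        """Last year of each old regime (the package-wide convention)."""
        return [y - 1 for y in self.shift_years]


def stars(x: SeriesVector, params: StarsParams = StarsParams()) -> StarsResult:
    """Sequential t-test analysis of regime shifts (Rodionov's algorithm).

    The regime-scale variance sigma^2_L is the average sample variance
    over all consecutive L-year windows; the critical difference is
    diff = t_crit(p, 2L-2) sqrt(2 sigma^2_L / L). Scanning forward, a
    year departing from the current regime mean by more than diff starts
    an RSI confirmation window of up to L years: normalized exceedances
    beyond the critical level are accumulated, and the candidate is
    rejected as soon as the running sum turns non-positive, otherwise
    accepted as the first year of a new regime. The current regime mean
    is recomputed as the regime grows; candidate-window values never
    update the old regime's mean.
    """
    v = x.values
    n = len(v)
    L = params.cutoff_length
    if n <= L:
        raise DataError(f"series length {n} must exceed cutoff length {L}")
    windows = sliding_window_view(v, L)
    sigma2 = float(windows.var(axis=1, ddof=1).mean())
    sigma = np.sqrt(sigma2)
    tcrit = stats.t.ppf(1 - params.significance / 2, 2 * L - 2)
    diff = float(tcrit * np.sqrt(2 * sigma2 / L))

    shifts: list[int] = []
    rsis: list[float] = []
    regime_start = 0
    j = 1
    while j < n:
        rbar = v[regime_start:j].mean()
        if v[j] > rbar + diff:
            sign, level = 1.0, rbar + diff
        elif v[j] < rbar - diff:
            sign, level = -1.0, rbar - diff
        else:
            j += 1
            continue
        window = (v[j : min(j + L, n)] - level) * sign
        csum = np.cumsum(window)
        if np.any(csum <= 0):
            j += 1
            continue
        rsi = float(csum[-1] / (L * sigma)) if sigma > 0 else np.inf
        shifts.append(j)
        rsis.append(rsi)
        regime_start = j
        j += 1

    edges = [0] + shifts + [n]
    means = [float(v[a:b].mean()) for a, b in zip(edges[:-1], edges[1:])]
    return StarsResult(
        years=x.years,
        shift_years=[int(x.years[s]) for s in shifts],
        rsi=rsis,
        regime_means=means,
        diff=diff,
        sigma_l=float(sigma),
    )
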