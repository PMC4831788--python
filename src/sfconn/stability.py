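"""Bootstrap stability selection with binomial accept/reject inference.

The sparse CCA fit is repeated over B bootstrap resamples of subjects,
each with freshly drawn randomised-Lasso penalty weights.  Every edge's
selection probability is the fraction of iterations in which its canonical
loading was nonzero.  Because the sparsity budgets are held fixed across
iterations, the number of selected edges per iteration is roughly constant,
and under the null of exchangeable edges each available edge is selected
with a common chance probability

    p_chance = mean(#selected per iteration) / mean(#available per iteration).

Comparing an edge's selection count against the exact tails of
Binomial(B, p_chance) then yields a three-way decision: selected
significantly above chance, rejected significantly below chance, or
undetermined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import binom

from .atlas import EdgeIndex, build_edge_index
from .io import ConnectivityMatrix, vectorize_upper
from .scca import SCCAConfig, _scca_core, randomized_weights

logger = logging.getLogger(__name__)


def chance_probability(mean_selected: float, mean_available: float) -> float:
    """Per-edge chance selection probability: mean selected / mean available."""
    if mean_available <= 0:
        raise ValueError("mean available count must be positive")
    if not 0 <= mean_selected <= mean_available:
        raise ValueError("mean selected count must lie in [0, mean available]")
    return mean_selected / mean_available


@dataclass
class StabilityConfig:
    """Bootstrap settings: B iterations, two-tailed level alpha, RNG seed."""

    B: int = 1000
    alpha: float = 0.05
    seed: int = 0
    scca: SCCAConfig = field(default_factory=SCCAConfig)

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")


@dataclass
class StabilityResult:
    """Per-edge selection counts over B bootstrap iterations.

    Count/tested/loading arrays span the full canonical edge index of each
    stack; edges never retained in any resample have tested count 0.
    ``loading_mean_*`` is the average canonical loading over the iterations
    in which the edge was available (0 where never available).
    """

    B: int
    counts_structural: np.ndarray
    counts_functional: np.ndarray
    tested_structural: np.ndarray
    tested_functional: np.ndarray
    loading_mean_structural: np.ndarray
    loading_mean_functional: np.ndarray
    available_per_iter: np.ndarray
    selected_per_iter: np.ndarray
    p_chance: float
    subjects: tuple
    edge_index_structural: Optional[EdgeIndex] = None
    edge_index_functional: Optional[EdgeIndex] = None

    @property
    def probabilities_structural(self) -> np.ndarray:
        return self.counts_structural / self.B

    @property
    def probabilities_functional(self) -> np.ndarray:
        return self.counts_functional / self.B


def _stack_edge_values(stack: Sequence[ConnectivityMatrix]):
    idx = build_edge_index(stack[0].atlas)
    V = np.vstack([vectorize_upper(cm, idx) for cm in stack])  # m x k, NaN = missing
    return idx, V


def bootstrap_stability(
    struct_stack: Sequence[ConnectivityMatrix],
    func_stack: Sequence[ConnectivityMatrix],
    cfg: Optional[StabilityConfig] = None,
) -> StabilityResult:
    """Run B bootstrap iterations of randomised sCCA over subject resamples.

    Each iteration draws m subjects with replacement, recomputes the
    common-edge mask on the resample (so the available-edge count varies),
    re-standardises both panels within the resample, draws fresh penalty
    weights, and fits a single sparse canonical pair.  Edges with nonzero
    loadings are counted as selected.  Rows that are constant within a
    resample (e.g. a resample dominated by duplicated subjects) are dropped
    for that iteration and logged.
    """
    cfg = cfg or StabilityConfig()
    m = len(struct_stack)
    if len(func_stack) != m:
        raise ValueError("structural and functional stacks must cover the same subjects")
    if m < 8:
        raise ValueError("bootstrap stability needs at least 8 subjects")
    sub_s = tuple(cm.subject for cm in struct_stack)
    sub_f = tuple(cm.subject for cm in func_stack)
    if sub_s != sub_f:
        raise ValueError("subject order differs between the two stacks")

    idx_x, Vx = _stack_edge_values(struct_stack)
    idx_y, Vy = _stack_edge_values(func_stack)
    kx_full, ky_full = idx_x.k, idx_y.k

    counts_x = np.zeros(kx_full, dtype=np.int64)
    counts_y = np.zeros(ky_full, dtype=np.int64)
    tested_x = np.zeros(kx_full, dtype=np.int64)
    tested_y = np.zeros(ky_full, dtype=np.int64)
    load_x = np.zeros(kx_full)
    load_y = np.zeros(ky_full)
    available = np.zeros(cfg.B, dtype=np.int64)
    selected = np.zeros(cfg.B, dtype=np.int64)

    rng = np.random.default_rng(cfg.seed)
    for b in range(cfg.B):
        draw = rng.integers(0, m, size=m)
        ex, Xs = _resampled_panel(Vx[draw])
        ey, Ys = _resampled_panel(Vy[draw])
        if Xs.shape[0] == 0 or Ys.shape[0] == 0:
            raise ValueError("a bootstrap resample retained no usable edges")
        w_u = randomized_weights(Xs.shape[0], cfg.scca.weakness, rng)
        w_v = randomized_weights(Ys.shape[0], cfg.scca.weakness, rng)
        res = _scca_core(Xs, Ys, cfg.scca, w_u, w_v)
        sel_x = res.u != 0
        sel_y = res.v != 0
        counts_x[ex[sel_x]] += 1
        counts_y[ey[sel_y]] += 1
        tested_x[ex] += 1
        tested_y[ey] += 1
        load_x[ex] += res.u
        load_y[ey] += res.v
        available[b] = ex.size
        selected[b] = int(sel_x.sum())

    p_chance = chance_probability(float(selected.mean()), float(available.mean()))
    with np.errstate(invalid="ignore", divide="ignore"):
        lm_x = np.where(tested_x > 0, load_x / np.maximum(tested_x, 1), 0.0)
        lm_y = np.where(tested_y > 0, load_y / np.maximum(tested_y, 1), 0.0)
    return StabilityResult(
        B=cfg.B,
        counts_structural=counts_x,
        counts_functional=counts_y,
        tested_structural=tested_x,
        tested_functional=tested_y,
        loading_mean_structural=lm_x,
        loading_mean_functional=lm_y,
        available_per_iter=available,
        selected_per_iter=selected,
        p_chance=p_chance,
        subjects=sub_s,
        edge_index_structural=idx_x,
        edge_index_functional=idx_y,
    )


def _resampled_panel(sub: np.ndarray):
    """Common-edge mask, standardisation and constant-row dropping for a resample.

    ``sub`` is subjects x full-edge values with NaN at missing entries.
    Returns the retained edge positions and the standardised edges-by-subjects
    array.
    """
    mask = ~np.isnan(sub).any(axis=0)
    E = sub[:, mask].T  # k x m
    mu = E.mean(axis=1, keepdims=True)
    sd = E.std(axis=1, ddof=1, keepdims=True)
    keep = sd.ravel() > 0
    if not keep.all():
        logger.debug("dropping %d constant edge rows in a resample", int((~keep).sum()))
    E = (E[keep] - mu[keep]) / sd[keep]
    return np.flatnonzero(mask)[keep], E


def binomial_thresholds(B: int, p0: float, alpha: float):
    """Exact binomial tail thresholds for selection counts.

    Returns ``(k_lo, k_hi)`` where ``k_hi`` is the smallest count with
    ``P(K >= k_hi) < alpha`` and ``k_lo`` the largest count with
    ``P(K <= k_lo) < alpha`` for ``K ~ Binomial(B, p0)``.  If no count in
    [0, B] satisfies the upper-tail condition, ``k_hi = B + 1`` (nothing can
    be accepted); if none satisfies the lower-tail condition, ``k_lo = -1``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < p0 < 1:
        raise ValueError("degenerate chance probability")
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    ks = np.arange(0, B + 1)
    upper = binom.sf(ks - 1, B, p0)  # P(K >= k)
    hits = np.flatnonzero(upper < alpha)
    k_hi = int(ks[hits[0]]) if hits.size else B + 1
    lower = binom.cdf(ks, B, p0)  # P(K <= k)
    hits = np.flatnonzero(lower < alpha)
    k_lo = int(ks[hits[-1]]) if hits.size else -1
    return k_lo, k_hi


def selection_count_gof(counts: np.ndarray, B: int, p0: float, min_expected: float = 5.0):
    """Chi-square goodness-of-fit of per-edge selection counts to Binomial(B, p0).

    Adjacent count values are pooled into bins with expected frequency at
    least ``min_expected``; one degree of freedom is subtracted for the
    estimated chance probability.  Returns ``(statistic, p_value)``.

    This probes the chance model underlying the accept/reject rule: under a
    complete absence of structure-function coupling, and to the extent that
    the randomised penalties make edge selection exchangeable, every edge's
    count should look like an independent Binomial(B, p0) draw.
    """
    from scipy.stats import chisquare

    counts = np.asarray(counts)
    k = counts.size
    expected = binom.pmf(np.arange(B + 1), B, p0) * k
    groups = []
    acc, lo = 0.0, 0
    for c in range(B + 1):
        acc += expected[c]
        if acc >= min_expected:
            groups.append((lo, c, acc))
            acc, lo = 0.0, c + 1
    if not groups:
        raise ValueError("B too small to form a single bin")
    if acc > 0:
        l0, _, e0 = groups[-1]
        groups[-1] = (l0, B, e0 + acc)
    obs = np.array([np.sum((counts >= l) & (counts <= h)) for l, h, _ in groups])
    exp = np.array([e for _, _, e in groups])
    exp *= obs.sum() / exp.sum()
    stat, p = chisquare(obs, exp, ddof=1)
    return float(stat), float(p)


@dataclass
class SelectionDecision:
    """Three-way partition of the tested edges of one panel."""

    selected: np.ndarray
    rejected: np.ndarray
    undetermined: np.ndarray
    k_lo: int
    k_hi: int
    loading_mean: np.ndarray
    panel: str = "structural"


def classify_edges(
    res: StabilityResult,
    cfg: StabilityConfig,
    panel: str = "structural",
) -> SelectionDecision:
    """Accept/reject each tested edge by exact binomial tails at level alpha.

    Edges with selection count >= k_hi are *selected* (above chance), those
    with count <= k_lo are *rejected* (below chance), the rest are
    *undetermined*.  Only edges available in at least one resample are
    classified.
    """
    if panel == "structural":
        counts, tested, lm = (
            res.counts_structural, res.tested_structural, res.loading_mean_structural,
        )
    elif panel == "functional":
        counts, tested, lm = (
            res.counts_functional, res.tested_functional, res.loading_mean_functional,
        )
    else:
        raise ValueError("panel must be 'structural' or 'functional'")
    k_lo, k_hi = binomial_thresholds(res.B, res.p_chance, cfg.alpha)
    testable = tested > 0
    sel = testable & (counts >= k_hi)
    rej = testable & (counts <= k_lo)
    und = testable & ~sel & ~rej
    return SelectionDecision(
        selected=np.flatnonzero(sel),
        rejected=np.flatnonzero(rej),
        undetermined=np.flatnonzero(und),
        k_lo=k_lo,
        k_hi=k_hi,
        loading_mean=lm,
        panel=panel,
    )
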