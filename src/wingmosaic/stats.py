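"""Mosaic statistics of the chromosome-loss wing assay.

Quantities follow the standard accounting of the assay:

* clones are binned into size classes I, II, III, ... covering 1, 2, 3-4,
  5-8, ... cells; the class index is the minimum number of divisions since
  the loss event, assuming the loss labels exactly one daughter cell;
* ``m`` is the average clone size in cells per clone, computed as the mean
  size-class index (classes I and II contain exactly 1 and 2 cells, so the
  index tracks cell count closely for the small clones that dominate);
* the induction frequency per cell division is ``f = 2 n m / (N C)`` for
  ``n`` clones over ``N`` wings of ``C`` screened cells each. The factor 2
  enters because only one daughter of the losing division is labeled, so
  ``N C / (2 m)`` is the effective number of exposed target cells;
* under a constant per-division loss rate the class counts decay
  geometrically (``halve-by-half``: each class holds half the clones of the
  previous one), and clone counts per wing are Poisson.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .config import SimulationConfig

__all__ = [
    "size_class",
    "round_half_away",
    "MosaicSummary",
    "summarize_group",
    "HalveByHalfExpectation",
    "halve_by_half_expected",
    "PoissonFitResult",
    "poisson_expected",
    "chisq_gof",
    "compare_frequencies",
    "ExpectedMosaic",
    "expected_mosaic_statistics",
    "estimate_loss_probability",
    "LossRateEstimate",
    "recover_loss_rate",
]


def size_class(s: int) -> int:
    """Size class of a clone of ``s`` cells: 1, 2, 3-4, 5-8, ... cells.

    Class 1 for a single cell, otherwise ``ceil(log2(s)) + 1`` — the
    minimum number of divisions needed to grow one labeled daughter into
    ``s`` cells. Clones above 128 cells continue the same rule (class 9,
    10, ...).
    """
    s = int(s)
    if s < 1:
        raise ValueError(f"clone size must be >= 1, got {s}")
    if s == 1:
        return 1
    return (s - 1).bit_length() + 1  # == ceil(log2(s)) + 1, exact on ints


def size_classes(sizes: Iterable[int]) -> np.ndarray:
    return np.array([size_class(s) for s in sizes], dtype=np.int64)


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero at ``decimals`` (table-printing convention)."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MosaicSummary:
    """Per-group summary row: the published table layout.

    ``m`` is the rounded mean size-class index unless an override (a
    published value) was supplied; ``f`` uses that ``m`` unrounded further,
    and ``f_per_1e4`` is ``f`` on the 1e-4 scale rounded to one decimal,
    the convention of the published table.
    """

    group: str
    N: int
    n: int
    class_counts: tuple[int, ...]
    C: int
    mean_class: float
    m: float
    f: float
    m_overridden: bool = False

    @property
    def clones_per_wing(self) -> float:
        return self.n / self.N

    @property
    def f_per_1e4(self) -> float:
        return round_half_away(self.f * 1e4, 1)

    @property
    def target_cells(self) -> float:
        """Effective exposed target cells per wing, C / (2 m)."""
        if self.n == 0 or not math.isfinite(self.m):
            return math.nan
        return self.C / (2.0 * self.m)


def summarize_group(
    clones: Sequence[int] | None = None,
    N: int = 1,
    C: int = 30000,
    classes: int = 8,
    m_override: float | None = None,
    group: str = "",
    class_counts: Sequence[int] | None = None,
) -> MosaicSummary:
    """Summarise one treatment group.

    Parameters
    ----------
    clones : sequence of int, optional
        Clone sizes in cells. Alternatively pass ``class_counts`` directly
        (e.g. transcribed from a published table).
    N : int
        Wings screened.
    C : int
        Screened cells per wing.
    classes : int
        Minimum number of size-class bins reported (extended if larger
        clones occur).
    m_override : float, optional
        Published average clone size to use instead of the mean-class-index
        estimate (the published interpolation uses within-class average
        sizes that are not recoverable from class counts alone).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if (clones is None) == (class_counts is None):
        raise ValueError("pass exactly one of clones= or class_counts=")

    if class_counts is None:
        cls = size_classes(clones)
        k = max(classes, int(cls.max()) if len(cls) else classes)
        counts = np.bincount(cls, minlength=k + 1)[1:]
    else:
        counts = np.asarray(class_counts, dtype=np.int64)
        if (counts < 0).any():
            raise ValueError("class counts must be non-negative")
        if len(counts) < classes:
            counts = np.concatenate(
                [counts, np.zeros(classes - len(counts), dtype=np.int64)]
            )
    n = int(counts.sum())

    if n == 0:
        mean_class = math.nan
        m = math.nan if m_override is None else float(m_override)
        f = 0.0
    else:
        idx = np.arange(1, len(counts) + 1)
        mean_class = float((idx * counts).sum() / n)
        m = float(m_override) if m_override is not None else round_half_away(mean_class, 1)
        f = 2.0 * n * m / (N * C)
    return MosaicSummary(
        group=group,
        N=int(N),
        n=n,
        class_counts=tuple(int(c) for c in counts),
        C=int(C),
        mean_class=mean_class,
        m=m,
        f=f,
        m_overridden=m_override is not None,
    )


@dataclass(frozen=True)
class HalveByHalfExpectation:
    """Geometric (ratio 1/2) expected class counts for ``n`` clones."""

    n: int
    K: int
    expected: tuple[float, ...]

    @property
    def expected_rounded(self) -> tuple[int, ...]:
        return tuple(int(round_half_away(e, 0)) for e in self.expected)

    def gof(
        self, observed: Sequence[int], pool_below: float = 1.0
    ) -> tuple[float, int, float]:
        return chisq_gof(observed, self.expected, pool_below=pool_below)


def halve_by_half_expected(n: int, K: int) -> HalveByHalfExpectation:
    """Expected counts when each class holds half the clones of the previous.

    ``expected_i = n * 2**(1-i) / sum_j 2**(1-j)`` for i = 1..K; the
    expectation sums to ``n`` exactly.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if K < 1:
        raise ValueError("K must be >= 1")
    weights = np.power(2.0, 1 - np.arange(1, K + 1))
    expected = n * weights / weights.sum()
    return HalveByHalfExpectation(n=int(n), K=int(K), expected=tuple(expected.tolist()))


@dataclass(frozen=True)
class PoissonFitResult:
    """Poisson model of clone counts per wing: nu = n/N, P(i) = nu^i e^-nu / i!."""

    nu: float
    N: int
    i_max: int
    expected: tuple[float, ...]
    observed: tuple[int, ...] | None = None
    statistic: float = math.nan
    df: int = 0
    pvalue: float = math.nan
    pooled_expected: tuple[float, ...] = field(default=())
    pooled_observed: tuple[int, ...] = field(default=())

    @property
    def truncated_mass(self) -> float:
        """Expected wings beyond ``i_max``: N * (1 - CDF(i_max))."""
        return self.N * float(sps.poisson.sf(self.i_max, self.nu))


def poisson_expected(
    n: int,
    N: int,
    i_max: int,
    observed: Sequence[int] | None = None,
    pool_below: float = 1.0,
    estimate_rate_df: bool = False,
) -> PoissonFitResult:
    """Expected numbers of wings bearing 0..i_max clones under Poisson.

    ``nu = n/N`` unrounded. When per-wing observed counts are given, a
    chi-square goodness-of-fit is run after pooling sparse tail bins
    (``pool_below``); ``estimate_rate_df`` subtracts one further degree of
    freedom for the rate having been estimated from the same data.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if i_max < 0:
        raise ValueError("i_max must be >= 0")
    nu = n / N
    i = np.arange(i_max + 1)
    expected = N * sps.poisson.pmf(i, nu)
    result = PoissonFitResult(
        nu=nu, N=int(N), i_max=int(i_max), expected=tuple(expected.tolist())
    )
    if observed is None:
        return result
    observed = tuple(int(v) for v in observed)
    if len(observed) != i_max + 1:
        raise ValueError("observed must have i_max + 1 bins")
    if sum(observed) != N:
        raise ValueError(f"observed wings sum to {sum(observed)}, expected N={N}")
    stat, df, p = chisq_gof(
        observed,
        expected,
        pool_below=pool_below,
        extra_df_loss=1 if estimate_rate_df else 0,
    )
    pooled_o, pooled_e = _pool_tail(
        np.asarray(observed, dtype=float), expected.astype(float), pool_below
    )
    return PoissonFitResult(
        nu=nu,
        N=int(N),
        i_max=int(i_max),
        expected=tuple(expected.tolist()),
        observed=observed,
        statistic=stat,
        df=df,
        pvalue=p,
        pooled_expected=tuple(pooled_e.tolist()),
        pooled_observed=tuple(int(v) for v in pooled_o.tolist()),
    )


def _pool_tail(
    observed: np.ndarray, expected: np.ndarray, pool_below: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge sparse tail bins (expected < pool_below) into their neighbour."""
    obs = observed.astype(float).copy()
    exp = expected.astype(float).copy()
    while len(exp) > 1 and exp[-1] < pool_below:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        exp = exp[:-1]
        obs = obs[:-1]
    return obs, exp


def chisq_gof(
    observed: Sequence[float],
    expected: Sequence[float],
    pool_below: float = 1.0,
    extra_df_loss: int = 0,
) -> tuple[float, int, float]:
    """Pearson chi-square goodness-of-fit with tail pooling.

    Adjacent tail bins with expected count below ``pool_below`` are merged
    into the neighbouring lower bin before the statistic is computed.
    Degrees of freedom are ``bins - 1 - extra_df_loss``.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1:
        raise ValueError("observed and expected must be equal-length vectors")
    if not np.any(exp > 0):
        raise ValueError("expected counts are all zero")
    obs, exp = _pool_tail(obs, exp, pool_below)
    if (exp <= 0).any():
        raise ValueError("expected counts must be positive after pooling")
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = len(exp) - 1 - extra_df_loss
    if df < 1:
        return stat, df, 1.0 if stat == 0 else math.nan
    p = float(sps.chi2.sf(stat, df))
    return stat, df, p


def compare_frequencies(
    groups: Sequence[tuple[int, int]],
) -> tuple[float, int, float]:
    """Chi-square homogeneity test of clones-per-wing rates across groups.

    Under a common rate, group ``i`` with ``N_i`` wings expects
    ``sum(n) * N_i / sum(N)`` clones; the statistic compares observed clone
    counts with those expectations on ``len(groups) - 1`` degrees of
    freedom.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n = np.array([g[0] for g in groups], dtype=float)
    N = np.array([g[1] for g in groups], dtype=float)
    if (N < 1).any():
        raise ValueError("every group needs N >= 1 wings")
    total_n, total_N = n.sum(), N.sum()
    df = len(groups) - 1
    if total_n == 0:
        warnings.warn("no clones in any group; homogeneity is vacuous")
        return 0.0, df, 1.0
    expected = total_n * N / total_N
    stat = float(((n - expected) ** 2 / expected).sum())
    return stat, df, float(sps.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Branching-model expectations and loss-rate recovery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpectedMosaic:
    """Branching-model expectations for one wing under a given loss rate."""

    p_loss: float
    clones_per_wing: float
    class_expected: tuple[float, ...]
    mean_class: float
    expected_f: float
    retention: float


def expected_mosaic_statistics(
    config: SimulationConfig, p_loss: float | None = None
) -> ExpectedMosaic:
    """Exact expectations of the observed mosaic statistics per wing.

    A dynamic program over division rounds: the expected number of
    unlabeled divisions at round ``r`` is ``n0' (2 - p)**(r-1)`` (each
    division yields two unlabeled daughters except when a loss converts
    one), so losses at round ``r`` arise at rate ``p`` per such division
    and found clones of final size ``2**(T - r)``. Blade sampling and the
    truncation to ``screened_cells`` thin every clone binomially with
    per-cell retention ``q = min(blade_fraction, C / population)``; the
    observed-size distribution of each cohort is the conditional binomial,
    from which expected class counts, the mean class index, and the
    expectation of the published estimator ``f = 2 n m / (N C)`` follow.
    Used to invert the estimator back to the mechanistic per-division rate.
    """
    p = config.p_loss if p_loss is None else float(p_loss)
    if not 0.0 <= p <= 1.0:
        raise ValueError("p_loss must be in [0, 1]")
    n_start = config.n0 - int(round(config.death_fraction * config.n0))
    T = config.total_rounds
    if T == 0 or p == 0.0:
        return ExpectedMosaic(p, 0.0, (), math.nan, 0.0, config.blade_fraction)

    rounds = np.arange(1, T + 1)
    divisions = n_start * np.power(2.0 - p, rounds - 1)
    events = p * divisions  # expected loss events founding at round r
    disc_sizes = 2 ** (T - rounds)

    unlabeled_final = n_start * (2.0 - p) ** T
    population = unlabeled_final + float((events * disc_sizes).sum())
    q = min(config.blade_fraction, config.screened_cells / population)

    max_size = int(disc_sizes.max())
    class_exp = np.zeros(max(8, size_class(max_size)) + 1)
    n_exp = 0.0
    class_index_sum = 0.0
    for e_r, s_r in zip(events.tolist(), disc_sizes.tolist()):
        j = np.arange(1, s_r + 1)
        pmf = sps.binom.pmf(j, s_r, q)
        for jj, pj in zip(j.tolist(), pmf.tolist()):
            c = size_class(jj)
            class_exp[c] += e_r * pj
            n_exp += e_r * pj
            class_index_sum += e_r * pj * c
    if n_exp <= 0:
        return ExpectedMosaic(p, 0.0, (), math.nan, 0.0, q)
    mean_class = class_index_sum / n_exp
    expected_f = 2.0 * n_exp * mean_class / config.screened_cells
    return ExpectedMosaic(
        p_loss=p,
        clones_per_wing=float(n_exp),
        class_expected=tuple(class_exp[1:].tolist()),
        mean_class=float(mean_class),
        expected_f=float(expected_f),
        retention=float(q),
    )


def estimate_loss_probability(f_hat: float, config: SimulationConfig) -> float:
    """Invert the published estimator to the per-division loss probability.

    The estimator ``f = 2 n m / (N C)`` counts every loss event across all
    division rounds but normalises by a single effective target-cell count,
    so its expectation exceeds the mechanistic per-division rate (by a
    factor close to the number of division rounds when the blade is fully
    sampled). This solves ``E[f | p] = f_hat`` for ``p`` under the
    branching model via root-finding; the expectation is strictly
    increasing in ``p``.
    """
    if f_hat < 0:
        raise ValueError("f_hat must be >= 0")
    if f_hat == 0:
        return 0.0

    def g(p: float) -> float:
        return expected_mosaic_statistics(config, p).expected_f - f_hat

    hi = 0.999
    if g(hi) < 0:
        raise ValueError(f"f_hat={f_hat} unreachable under this configuration")
    return float(optimize.brentq(g, 1e-15, hi, xtol=1e-15, rtol=1e-12))


@dataclass(frozen=True)
class LossRateEstimate:
    """Induction-frequency estimate with a wing-bootstrap interval."""

    f_hat: float
    f_interval: tuple[float, float] | None
    p_loss_hat: float | None
    p_loss_interval: tuple[float, float] | None
    n_wings: int
    n_clones: int
    n_bootstrap: int
    confidence: float


def recover_loss_rate(
    per_wing_sizes: Sequence[Sequence[int]],
    C: int = 30000,
    n_bootstrap: int = 500,
    confidence: float = 0.95,
    seed: int | None = None,
    config: SimulationConfig | None = None,
    classes: int = 8,
) -> LossRateEstimate:
    """Estimate the induction frequency f from called clones, with a bootstrap.

    ``per_wing_sizes`` holds one list of clone sizes per screened wing
    (empty lists for clone-free wings keep N honest). The point estimate is
    the published ``f = 2 n m / (N C)``; uncertainty comes from resampling
    whole wings with replacement. When the generating
    :class:`SimulationConfig` is supplied, the mechanistic per-division
    loss probability is additionally recovered by inverting the
    branching-model expectation of ``f`` (monotone, so the interval maps
    through directly).
    """
    N = len(per_wing_sizes)
    if N < 1:
        raise ValueError("need at least one wing")
    all_sizes = [s for wing in per_wing_sizes for s in wing]
    summary = summarize_group(all_sizes, N=N, C=C, classes=classes)
    f_hat = summary.f

    f_interval = None
    if N >= 2 and n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        # per-wing class-count matrix lets each replicate be a row-sum
        k = max(classes, max((size_class(s) for s in all_sizes), default=classes))
        mat = np.zeros((N, k), dtype=np.int64)
        for i, wing in enumerate(per_wing_sizes):
            for s in wing:
                mat[i, size_class(s) - 1] += 1
        idx_classes = np.arange(1, k + 1)
        f_boot = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            pick = rng.integers(0, N, size=N)
            counts = mat[pick].sum(axis=0)
            n_b = counts.sum()
            if n_b == 0:
                f_boot[b] = 0.0
                continue
            m_b = round_half_away(float((idx_classes * counts).sum() / n_b), 1)
            f_boot[b] = 2.0 * n_b * m_b / (N * C)
        alpha = (1.0 - confidence) / 2.0
        f_interval = (
            float(np.quantile(f_boot, alpha)),
            float(np.quantile(f_boot, 1.0 - alpha)),
        )

    p_hat = p_interval = None
    if config is not None:
        p_hat = estimate_loss_probability(f_hat, config)
        if f_interval is not None:
            p_interval = (
                estimate_loss_probability(f_interval[0], config),
                estimate_loss_probability(f_interval[1], config),
            )
    return LossRateEstimate(
        f_hat=f_hat,
        f_interval=f_interval,
        p_loss_hat=p_hat,
        p_loss_interval=p_interval,
        n_wings=N,
        n_clones=summary.n,
        n_bootstrap=n_bootstrap if f_interval is not None else 0,
        confidence=confidence,
    )
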