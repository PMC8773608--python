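"""Statistical machinery for condition contrasts.

Aggregate-data inference uses a nonparametric bootstrap: trials are
resampled with replacement (as many draws as the original table), the
log10-Gaussian is refitted per resample, and the peak (PSE) of each
refit is collected.  Two conditions are compared with a Z-test on the
peak distributions,

    Z = |mean_a - mean_b| / sqrt(se_a**2 + se_b**2),

with the SEs taken as the standard deviations of the bootstrap peaks
and a Bonferroni-corrected alpha when several contrasts are run
(0.05 / 3 = 0.017 for the three while-running contrasts).

Individual-data inference uses paired t-tests on per-participant PSEs
(log units by default), Cohen's d on the differences, and the default
JZS Bayes factor — a Cauchy(0, 0.707) prior on standardized effect size
against the point null — reported as log10(BF10).  Precision is
compared across tasks with a Pearson correlation of per-participant
Weber fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .errors import (
    DegenerateModelError,
    InsufficientDataError,
    InvalidArgumentError,
    NumericalFailureError,
)
from .psychometric import (
    LevelProportions,
    PsychometricFit,
    aggregate_proportions,
    fit_gaussian,
)

__all__ = [
    "BootstrapDistribution",
    "ComparisonResult",
    "MedianSplitResult",
    "bootstrap_pse",
    "z_compare",
    "bonferroni_alpha",
    "t_compare",
    "jzs_log10_bf",
    "median_split_compare",
    "precision_correlation",
    "DEFAULT_CAUCHY_SCALE",
]

log = logging.getLogger(__name__)

#: Conventional width of the default JZS Cauchy prior on effect size.
DEFAULT_CAUCHY_SCALE = 0.707
DEFAULT_BOOTSTRAP_ITERATIONS = 10_000
#: Fraction of failed refits above which a bootstrap is flagged unstable.
UNSTABLE_FRACTION = 0.10


@dataclass(frozen=True)
class BootstrapDistribution:
    """Fitted peaks across bootstrap resamples of one condition."""

    peaks: np.ndarray
    n_iterations: int
    seed: int
    n_failed: int = 0
    unstable: bool = field(init=False, default=False)

    def __post_init__(self):
        peaks = np.asarray(self.peaks, dtype=float)
        if peaks.size != self.n_iterations - self.n_failed:
            raise InvalidArgumentError("peaks length must be n_iterations - n_failed")
        object.__setattr__(self, "peaks", peaks)
        object.__setattr__(
            self, "unstable", self.n_failed > UNSTABLE_FRACTION * self.n_iterations
        )

    @property
    def mean_peak(self) -> float:
        return float(self.peaks.mean())

    @property
    def se_peak(self) -> float:
        """Bootstrap SE of the PSE: SD of the peak distribution."""
        return float(self.peaks.std(ddof=1))


@dataclass(frozen=True)
class ComparisonResult:
    """One two-condition contrast (Z, t, or r) with its decision."""

    statistic_kind: str  # bootstrap_z | one_sample_t | paired_t | pearson_r
    statistic: float
    p_value: float
    alpha_corrected: float
    df: float | None = None
    effect_size_d: float | None = None
    log10_bf10: float | None = None
    n: int | None = None
    seed: int | None = None
    n_iterations: int | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_corrected


def bonferroni_alpha(alpha: float = 0.05, k: int = 1) -> float:
    """Bonferroni-corrected per-comparison threshold: alpha / k."""
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if not 0 < alpha < 1:
        raise InvalidArgumentError("alpha must be in (0, 1)")
    return alpha / k


def bootstrap_pse(
    trials: pd.DataFrame,
    phase: str | None = None,
    n_iterations: int = DEFAULT_BOOTSTRAP_ITERATIONS,
    seed: int = 0,
    weighted: bool = False,
) -> BootstrapDistribution:
    """Bootstrap the aggregate PSE of one condition.

    Each iteration resamples trial rows with replacement to the original
    count, re-aggregates per-level proportions, and refits the Gaussian
    starting from the full-data solution; the refit's peak is one
    bootstrap PSE.  Iterations whose refit does not converge are counted
    in ``n_failed`` and excluded; a distribution losing more than 10% of
    its iterations is flagged ``unstable``.
    """
    if n_iterations < 1:
        raise InvalidArgumentError("n_iterations must be >= 1")
    props = aggregate_proportions(trials, "aggregate", phase)
    point = fit_gaussian(props, weighted=weighted)
    if not point.converged:
        raise DegenerateModelError(
            f"point fit did not converge: {point.message or 'unknown'}"
        )
    df = trials if phase is None else trials[trials["phase"] == phase]
    levels = props.levels
    codes = np.searchsorted(levels, df["test_magnitude"].to_numpy(float))
    same = (df["response"].to_numpy() == "same").astype(float)
    n = codes.size
    k = levels.size
    rng = np.random.default_rng(seed)
    init = (point.amplitude, point.mu, point.sigma)
    peaks = np.empty(n_iterations)
    n_failed = 0
    kept = 0
    for _ in range(n_iterations):
        idx = rng.integers(0, n, n)
        tot = np.bincount(codes[idx], minlength=k)
        sm = np.bincount(codes[idx], weights=same[idx], minlength=k).astype(int)
        present = tot > 0
        if present.sum() < 4:
            n_failed += 1
            continue
        props_b = LevelProportions(levels[present], sm[present], tot[present])
        fit = fit_gaussian(props_b, weighted=weighted, init=init)
        if not fit.converged:
            n_failed += 1
            continue
        peaks[kept] = fit.pse
        kept += 1
    dist = BootstrapDistribution(
        peaks=peaks[:kept], n_iterations=n_iterations, seed=seed, n_failed=n_failed
    )
    if dist.unstable:
        log.warning(
            "bootstrap unstable: %d/%d iterations failed to converge",
            n_failed, n_iterations,
        )
    return dist


def z_compare(
    a: BootstrapDistribution | tuple[float, float],
    b: BootstrapDistribution | tuple[float, float],
    alpha_corrected: float = 0.05,
) -> ComparisonResult:
    """Z-test between two bootstrap peak distributions.

    Also accepts plain ``(mean, se)`` pairs, so printed summary values
    can be re-tested directly.  The statistic is the absolute mean
    difference over the combined standard error
    sqrt(se_a**2 + se_b**2); p is two-sided from the standard normal.
    """
    mean_a, se_a = _mean_se(a)
    mean_b, se_b = _mean_se(b)
    if se_a < 0 or se_b < 0:
        raise InvalidArgumentError("standard errors must be >= 0")
    pooled = float(np.hypot(se_a, se_b))
    if pooled == 0:
        raise InvalidArgumentError("zero combined variance: Z undefined")
    zval = abs(mean_a - mean_b) / pooled
    p = 2.0 * stats.norm.sf(zval)
    return ComparisonResult(
        statistic_kind="bootstrap_z", statistic=float(zval),
        p_value=float(p), alpha_corrected=alpha_corrected,
    )


def _mean_se(x) -> tuple[float, float]:
    if isinstance(x, BootstrapDistribution):
        return x.mean_peak, x.se_peak
    mean, se = x
    return float(mean), float(se)


def t_compare(
    pse_condition: np.ndarray,
    pse_baseline: np.ndarray,
    log_units: bool = True,
    alpha_corrected: float = 0.05,
    cauchy_scale: float = DEFAULT_CAUCHY_SCALE,
) -> ComparisonResult:
    """Paired t-test on per-participant PSEs with d and log10 BF10.

    Differences are taken in log10 units by default (multiplicative
    biases become additive shifts); pass ``log_units=False`` to contrast
    the raw magnitudes.  Cohen's d is mean(diff)/sd(diff); the Bayes
    factor is the one-sample JZS value on the same t.
    """
    cond = np.asarray(pse_condition, dtype=float)
    base = np.asarray(pse_baseline, dtype=float)
    if cond.shape != base.shape:
        raise InvalidArgumentError("paired samples must have equal length")
    n = cond.size
    if n < 3:
        raise InvalidArgumentError("need n >= 3 pairs")
    diff = np.log10(cond) - np.log10(base) if log_units else cond - base
    sd = float(diff.std(ddof=1))
    mean = float(diff.mean())
    # a spread at floating-point roundoff scale is a zero spread
    if sd <= 1e-10 * abs(mean):
        sd = 0.0
    if sd == 0:
        if mean == 0:
            return ComparisonResult(
                statistic_kind="paired_t", statistic=0.0, p_value=1.0,
                alpha_corrected=alpha_corrected, df=float(n - 1),
                effect_size_d=0.0,
                log10_bf10=jzs_log10_bf(0.0, n, cauchy_scale), n=n,
            )
        raise DegenerateModelError(
            "zero variance of nonzero differences: |t| unbounded"
        )
    tval = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(tval), n - 1)
    return ComparisonResult(
        statistic_kind="paired_t", statistic=float(tval), p_value=float(p),
        alpha_corrected=alpha_corrected, df=float(n - 1),
        effect_size_d=mean / sd,
        log10_bf10=jzs_log10_bf(tval, n, cauchy_scale), n=n,
    )


def jzs_log10_bf(
    t: float, n: int, cauchy_scale: float = DEFAULT_CAUCHY_SCALE
) -> float:
    """Default JZS Bayes factor for a one-sample (or paired) t, as log10(BF10).

    Computed by numerical integration of the marginal likelihood under a
    Cauchy(0, ``cauchy_scale``) prior on the standardized effect size:

        BF10 = [ integral T_nct(t; df, delta*sqrt(n)) Cauchy(delta; 0, r) d delta ]
               / T(t; df)

    with df = n - 1.  With the conventional scale r = 0.707, t(14) = 7.27
    gives log10(BF10) ~ 3.69 and t(14) = 0.21 gives ~ -0.57.
    """
    if n < 2:
        raise InvalidArgumentError("need n >= 2")
    if cauchy_scale <= 0:
        raise InvalidArgumentError("cauchy_scale must be positive")
    df = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta):
        return stats.nct.pdf(t, df, delta * sqrt_n) * stats.cauchy.pdf(
            delta, 0.0, cauchy_scale
        )

    # split at the likelihood peak (delta ~ t/sqrt(n)) so the narrow mass
    # sits at an endpoint of each half-infinite panel
    center = t / sqrt_n
    parts = [
        integrate.quad(integrand, -np.inf, center, epsabs=0, epsrel=1e-10,
                       limit=200),
        integrate.quad(integrand, center, np.inf, epsabs=0, epsrel=1e-10,
                       limit=200),
    ]
    marginal = sum(p[0] for p in parts)
    err = sum(p[1] for p in parts)
    if marginal <= 0 or not np.isfinite(marginal) or err > 1e-6 * marginal:
        raise NumericalFailureError(
            f"JZS marginal likelihood integration failed (t={t}, n={n})"
        )
    null = stats.t.pdf(t, df)
    return float(np.log10(marginal) - np.log10(null))


@dataclass(frozen=True)
class MedianSplitResult:
    """Early/late halves of an after-run contrast."""

    baseline_fit: PsychometricFit
    test_fit: PsychometricFit
    comparison: ComparisonResult
    n_baseline: int
    n_test: int


def median_split_compare(
    trials: pd.DataFrame,
    baseline_phase: str = "T1",
    test_phase: str = "TEST_AFTER",
    time_column: str = "seconds_since_phase_start",
    n_iterations: int = 1000,
    seed: int = 0,
    alpha_corrected: float = 0.05,
) -> dict[str, MedianSplitResult]:
    """Split each phase's trials at its median timestamp and compare halves.

    Models the question of whether an after-run effect was present only
    in the first trials after the treadmill stopped: the aggregated
    baseline and test trials are each partitioned at their phase-median
    time (ties assigned to the early half), then each half's baseline
    and test conditions are fitted, bootstrapped and Z-compared
    independently.  Returns ``{"early": ..., "late": ...}``.
    """
    if time_column not in trials.columns:
        raise InvalidArgumentError(f"trials lack time column {time_column!r}")
    halves: dict[str, list[pd.DataFrame]] = {"early": [], "late": []}
    for phase in (baseline_phase, test_phase):
        sub = trials[trials["phase"] == phase]
        if sub.empty:
            raise InsufficientDataError(f"no trials for phase {phase!r}")
        med = sub[time_column].median()
        early = sub[sub[time_column] <= med]
        late = sub[sub[time_column] > med]
        if late.empty:
            raise InsufficientDataError(
                f"degenerate partition for phase {phase!r}: all trials at or "
                "before the median timestamp fall in the early half"
            )
        halves["early"].append(early)
        halves["late"].append(late)
    out: dict[str, MedianSplitResult] = {}
    ss = np.random.SeedSequence(seed).spawn(4)
    for i, name in enumerate(("early", "late")):
        base_df, test_df = halves[name]
        base_props = aggregate_proportions(base_df, "aggregate", baseline_phase)
        test_props = aggregate_proportions(test_df, "aggregate", test_phase)
        for props, phase in ((base_props, baseline_phase), (test_props, test_phase)):
            if props.n_levels < 4:
                raise InsufficientDataError(
                    f"{name} half of {phase!r} has {props.n_levels} levels (< 4)"
                )
        boot_b = bootstrap_pse(
            base_df, baseline_phase, n_iterations,
            seed=int(ss[2 * i].generate_state(1)[0] % 2**31),
        )
        boot_t = bootstrap_pse(
            test_df, test_phase, n_iterations,
            seed=int(ss[2 * i + 1].generate_state(1)[0] % 2**31),
        )
        out[name] = MedianSplitResult(
            baseline_fit=fit_gaussian(base_props),
            test_fit=fit_gaussian(test_props),
            comparison=z_compare(boot_b, boot_t, alpha_corrected),
            n_baseline=len(base_df),
            n_test=len(test_df),
        )
    return out


def precision_correlation(
    wf_a: np.ndarray,
    wf_b: np.ndarray,
    alpha_corrected: float = 0.05,
) -> ComparisonResult:
    """Pearson correlation between per-participant precision indices.

    Used to ask whether participants precise in one task (e.g. duration)
    are also precise in the other (numerosity), as a shared-mechanism
    signature.
    """
    a = np.asarray(wf_a, dtype=float)
    b = np.asarray(wf_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError("paired samples must have equal length")
    if a.size < 3:
        raise InvalidArgumentError("need n >= 3 pairs")
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        raise DegenerateModelError("zero variance: correlation undefined")
    res = stats.pearsonr(a, b)
    return ComparisonResult(
        statistic_kind="pearson_r", statistic=float(res.statistic),
        p_value=float(res.pvalue), alpha_corrected=alpha_corrected,
        df=float(a.size - 2), n=int(a.size),
    )
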