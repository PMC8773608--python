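"""Log-Gaussian psychometric fitting for same/different data.

Same/different judgments produce a bump-shaped (not sigmoid) curve: the
proportion of "same" responses peaks where the test perceptually matches
the reference.  Plotted against log10 magnitude, the curve is fitted
with a three-parameter Gaussian

    p(x) = A * exp(-(log10(x) - mu)**2 / (2 * sigma**2))

whose peak location gives the point of subjective equality
(PSE = 10**mu), and whose width gives the Weber fraction
(Wf = 10**sigma - 1, the antilog of the log-axis SD minus one).  The
accuracy measure is the signed bias,
(reference - PSE) / reference * 100%: positive bias means the PSE fell
below the reference, i.e. test magnitudes were overestimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, leastsq

from .errors import InsufficientDataError, InvalidArgumentError, SchemaError

__all__ = [
    "LevelProportions",
    "PsychometricFit",
    "aggregate_proportions",
    "fit_gaussian",
    "bias_percent",
    "weber_fraction",
    "gaussian_curve",
]

#: Multistart grid for the fitted width, log10 units.
SIGMA_STARTS = (0.05, 0.1, 0.2)
#: Bounds for the optimiser: amplitude in (0, 1], width up to 2 log10
#: units (a 100-fold Weber fraction; anything wider is a failed fit).
SIGMA_MAX = 2.0
MIN_LEVELS = 4


def gaussian_curve(x, amplitude, mu, sigma):
    """The fitted model: Gaussian in log10(x)."""
    lx = np.log10(x)
    return amplitude * np.exp(-((lx - mu) ** 2) / (2.0 * sigma**2))


@dataclass(frozen=True)
class LevelProportions:
    """Per-level counts of "same" responses."""

    levels: np.ndarray
    n_same: np.ndarray
    n_total: np.ndarray

    def __post_init__(self):
        levels = np.asarray(self.levels, dtype=float)
        n_same = np.asarray(self.n_same, dtype=int)
        n_total = np.asarray(self.n_total, dtype=int)
        if not (levels.shape == n_same.shape == n_total.shape):
            raise InvalidArgumentError("levels and counts must align")
        if np.any(np.diff(levels) <= 0):
            raise InvalidArgumentError("levels must be strictly increasing")
        if np.any(levels <= 0):
            raise InvalidArgumentError("levels must be positive")
        if np.any(n_same > n_total) or np.any(n_same < 0) or np.any(n_total <= 0):
            raise InvalidArgumentError("counts must satisfy 0 <= n_same <= n_total")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "n_same", n_same)
        object.__setattr__(self, "n_total", n_total)

    @property
    def p_same(self) -> np.ndarray:
        return self.n_same / self.n_total

    @property
    def n_levels(self) -> int:
        return int(self.levels.size)


@dataclass(frozen=True)
class PsychometricFit:
    """A fitted log10-Gaussian with its derived psychophysical indices."""

    amplitude: float
    mu: float
    sigma: float
    r_squared: float
    converged: bool
    ss_res: float = np.nan
    message: str = ""

    @property
    def pse(self) -> float:
        """Point of subjective equality, in stimulus units."""
        return float(10.0**self.mu)

    @property
    def weber_fraction(self) -> float:
        """Precision index: 10**sigma - 1 (smaller = more precise)."""
        return float(10.0**self.sigma - 1.0)

    @property
    def weber_fraction_jnd_ratio(self) -> float:
        """Alternative reading of Wf as JND/PSE.

        With the JND taken as the linear-unit width of the fitted curve,
        (10**(mu + sigma) - 10**mu) / 10**mu, this is algebraically
        identical to ``weber_fraction``; kept as a named accessor to
        document the equivalence.
        """
        return float((10.0 ** (self.mu + self.sigma) - self.pse) / self.pse)

    def bias_percent(self, reference: float) -> float:
        return bias_percent(reference, self.pse)


def aggregate_proportions(
    trials: pd.DataFrame,
    grouping: str = "aggregate",
    phase: str | None = None,
) -> LevelProportions | dict[str, LevelProportions]:
    """Count "same" responses per test level.

    ``grouping="aggregate"`` pools all participants' trials before
    counting (the aggregate-observer analysis); ``"per_participant"``
    returns a dict keyed by participant id.  ``phase`` restricts to one
    phase label.
    """
    required = {"test_magnitude", "response"}
    missing = sorted(required - set(trials.columns))
    if missing:
        raise SchemaError(f"trial table lacks columns: {missing}", missing)
    df = trials if phase is None else trials[trials["phase"] == phase]
    if df.empty:
        raise InsufficientDataError(
            f"no trials{f' for phase {phase!r}' if phase else ''}"
        )
    bad = set(df["response"].unique()) - {"same", "different"}
    if bad:
        raise SchemaError(f"non-binary response values: {sorted(bad)}", ["response"])
    if grouping == "per_participant":
        if "participant_id" not in df.columns:
            raise SchemaError("per_participant grouping needs participant_id",
                              ["participant_id"])
        return {
            pid: _count_levels(sub)
            for pid, sub in df.groupby("participant_id", sort=True)
        }
    if grouping != "aggregate":
        raise InvalidArgumentError(f"unknown grouping {grouping!r}")
    return _count_levels(df)


def _count_levels(df: pd.DataFrame) -> LevelProportions:
    g = df.groupby("test_magnitude", sort=True)["response"]
    n_total = g.size()
    n_same = g.apply(lambda s: int((s == "same").sum()))
    return LevelProportions(
        levels=n_total.index.to_numpy(float),
        n_same=n_same.to_numpy(int),
        n_total=n_total.to_numpy(int),
    )


def fit_gaussian(
    props: LevelProportions,
    weighted: bool = False,
    init: tuple[float, float, float] | None = None,
) -> PsychometricFit:
    """Least-squares fit of the log10-Gaussian to per-level proportions.

    By default a deterministic multistart is used: mu initialized at
    every observed level, sigma at 0.05/0.1/0.2 log10 units, amplitude
    at the maximum observed proportion; the start reaching the lowest
    residual sum of squares wins, earlier starts breaking ties.  Passing
    ``init=(A, mu, sigma)`` replaces the multistart with a single start
    (used by the bootstrap, which refits resamples near a known
    solution).

    ``weighted=True`` weights each level by its binomial count (the
    reference level contributes 18 trials per phase against 6 for the
    others); the default is the unweighted fit of the plotted
    proportions.

    Degenerate inputs (flat proportions, widths escaping to the bound)
    and optimiser failures return ``converged=False`` with a diagnostic
    message rather than raising.
    """
    if props.n_levels < MIN_LEVELS:
        raise InsufficientDataError(
            f"need >= {MIN_LEVELS} distinct levels, got {props.n_levels}"
        )
    x = props.levels
    y = props.p_same
    if float(np.ptp(y)) < 1e-9:
        return PsychometricFit(
            amplitude=float(y[0]), mu=float(np.log10(x).mean()), sigma=np.nan,
            r_squared=np.nan, converged=False,
            message="flat proportions: peak location and width unidentified",
        )
    sig = None
    if weighted:
        # binomial-count weighting via per-point sigma ~ 1/sqrt(n)
        sig = 1.0 / np.sqrt(props.n_total.astype(float))
    amp0 = float(np.clip(y.max(), 1e-3, 1.0))
    lo = [1e-6, np.log10(x.min()) - 0.5, 1e-4]
    hi = [1.0, np.log10(x.max()) + 0.5, SIGMA_MAX]
    if init is not None:
        fast = _refit_from(init, x, y, sig, lo, hi)
        if fast is not None:
            return _finish_fit(fast[1], fast[0], y)
        starts: Iterable[tuple[float, float, float]] = [init]
    else:
        starts = [
            (amp0, float(np.log10(level)), s0)
            for level in x
            for s0 in SIGMA_STARTS
        ]
    best = None
    for p0 in starts:
        p0 = (
            float(np.clip(p0[0], lo[0], hi[0])),
            float(np.clip(p0[1], lo[1], hi[1])),
            float(np.clip(p0[2], lo[2], hi[2])),
        )
        # unbounded LM first (fast); bounded trust-region when the
        # unconstrained optimum leaves the valid region
        fast = _refit_from(p0, x, y, sig, lo, hi)
        if fast is not None:
            ss, popt = fast
        else:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # singular pcov is irrelevant
                    popt, _ = curve_fit(
                        gaussian_curve, x, y, p0=p0, sigma=sig,
                        bounds=(lo, hi), maxfev=400,
                    )
            except RuntimeError:
                continue
            ss = float(np.sum((y - gaussian_curve(x, *popt)) ** 2))
        if best is None or ss < best[0] - 1e-15:
            best = (ss, popt)
    if best is None:
        return PsychometricFit(
            amplitude=np.nan, mu=np.nan, sigma=np.nan, r_squared=np.nan,
            converged=False, message="no start converged",
        )
    ss_res, popt = best
    return _finish_fit(popt, ss_res, y)


def _finish_fit(popt, ss_res: float, y: np.ndarray) -> PsychometricFit:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    converged = True
    message = ""
    if popt[2] >= 0.95 * SIGMA_MAX:
        converged = False
        message = "width escaped to bound: data carry no peak"
    return PsychometricFit(
        amplitude=float(popt[0]), mu=float(popt[1]), sigma=float(popt[2]),
        r_squared=r2, converged=converged, ss_res=float(ss_res), message=message,
    )


def _refit_from(init, x, y, sig, lo, hi):
    """Fast unbounded Levenberg-Marquardt refit from a known solution.

    Used by the bootstrap, whose resamples sit close to the full-data
    fit.  Returns ``(ss_res, params)`` or None when the unbounded
    solution leaves the valid region (the caller then falls back to the
    bounded multipath optimiser).
    """
    lx = np.log10(x)
    w = 1.0 / sig if sig is not None else None

    def resid(p):
        r = p[0] * np.exp(-((lx - p[1]) ** 2) / (2.0 * p[2] ** 2)) - y
        return r * w if w is not None else r

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MINPACK gtol chatter on exact fits
        popt, ier = leastsq(resid, np.asarray(init, dtype=float))
    if ier not in (1, 2, 3, 4):
        return None
    popt = popt.copy()
    popt[2] = abs(popt[2])  # model depends on sigma**2 only
    if not (lo[0] <= popt[0] <= hi[0] and lo[1] <= popt[1] <= hi[1]
            and lo[2] <= popt[2] <= hi[2]):
        return None
    r = resid(popt)
    if w is not None:
        r = r / w
    return float(r @ r), popt


def bias_percent(reference: float, pse: float) -> float:
    """Signed bias, percent: (reference - PSE) / reference * 100.

    Positive when the PSE falls below the reference, i.e. the test was
    overestimated.
    """
    if reference <= 0:
        raise InvalidArgumentError("reference must be positive")
    return (reference - pse) / reference * 100.0


def weber_fraction(sigma_log: float, log_base: float = 10.0) -> float:
    """Weber fraction from a fitted log-axis width: base**sigma - 1.

    ``sigma_log`` must be expressed in the units of ``log_base``; the
    result is base-invariant as long as the two agree (a width of
    sigma_e natural-log units gives the same Wf via base e as
    sigma_e/ln(10) does via base 10).
    """
    if sigma_log <= 0:
        raise InvalidArgumentError("sigma_log must be positive")
    if log_base <= 1:
        raise InvalidArgumentError("log_base must exceed 1")
    return float(log_base**sigma_log - 1.0)
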