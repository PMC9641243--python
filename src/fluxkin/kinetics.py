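"""Time-binned median-fluorescence kinetics and double-logistic model fitting.

The activation curve of a gated subset is summarized as per-bin medians of the
calcium-indicator channel, fitted with a double-logistic model

    f(t) = S + A1 / (1 + exp(-r1 (t - tau1))) - A2 / (1 + exp(-r2 (t - tau2)))

whose limits are ``S`` at ``-inf`` and ``S + A1 - A2`` at ``+inf``.  Ten
derived parameters (plus the raw pre-stimulation baseline MFI) describe each
standardized curve: starting value (fixed at 1 after dividing by ``S``),
timing/slope of the half-maximal crossings on both branches, the maximum,
the ending plateau, and the area under the curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.special import expit

__all__ = [
    "KineticSeries",
    "DoubleLogisticFit",
    "KineticParameterSet",
    "TooFewEventsError",
    "UnusableFitError",
    "double_logistic",
    "double_logistic_derivative",
    "double_logistic_integral",
    "bin_median_series",
    "baseline_mfi",
    "fit_double_logistic",
    "derive_parameters",
    "area_under_curve",
    "PARAMETER_NAMES",
]

#: Names of the derived kinetic parameters, in reporting order.
PARAMETER_NAMES = (
    "starting_value",
    "time_to_first_50",
    "slope_first_50",
    "time_first50_to_max",
    "time_to_max",
    "max_value",
    "time_max_to_second_50",
    "slope_second_50",
    "ending_value",
    "auc",
    "baseline_mfi_raw",
)


class TooFewEventsError(ValueError):
    """Raised when no time bin survives the minimum-event filter."""


class UnusableFitError(RuntimeError):
    """Raised when the nonlinear fit fails to converge after restarts."""


# ---------------------------------------------------------------------------
# Model functions
# ---------------------------------------------------------------------------


def double_logistic(t, S, A1, r1, tau1, A2, r2, tau2):
    """Evaluate the double-logistic curve at time(s) ``t``.

    Rising logistic of amplitude ``A1`` (rate ``r1``, midpoint ``tau1``) minus
    a falling logistic of amplitude ``A2`` (rate ``r2``, midpoint ``tau2``),
    on a pre-stimulus plateau ``S``.
    """
    t = np.asarray(t, dtype=float)
    return S + A1 * expit(r1 * (t - tau1)) - A2 * expit(r2 * (t - tau2))


def double_logistic_derivative(t, S, A1, r1, tau1, A2, r2, tau2):
    """Analytic time derivative of :func:`double_logistic`."""
    t = np.asarray(t, dtype=float)
    p1 = expit(r1 * (t - tau1))
    p2 = expit(r2 * (t - tau2))
    return A1 * r1 * p1 * (1.0 - p1) - A2 * r2 * p2 * (1.0 - p2)


def _softplus(x):
    # log(1 + exp(x)), overflow-safe
    return np.logaddexp(0.0, x)


def double_logistic_integral(t0, t1, S, A1, r1, tau1, A2, r2, tau2):
    """Closed-form definite integral of :func:`double_logistic` on [t0, t1].

    Each logistic term has the primitive ``(A/r) * log(1 + exp(r (t - tau)))``.
    """
    if t1 < t0:
        raise ValueError("t1 must be >= t0")

    def term(A, r, tau):
        return (A / r) * (_softplus(r * (t1 - tau)) - _softplus(r * (t0 - tau)))

    return S * (t1 - t0) + term(A1, r1, tau1) - term(A2, r2, tau2)


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticSeries:
    """Time-binned median fluorescence for one gated subset of one sample."""

    centers: np.ndarray
    medians: np.ndarray
    counts: np.ndarray
    subset: str = ""
    sample_id: str = ""
    bin_width: float = 5.0

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        m = np.asarray(self.medians, dtype=float)
        n = np.asarray(self.counts)
        if not (len(c) == len(m) == len(n)):
            raise ValueError("centers, medians and counts must have equal length")
        if len(c) > 1 and not np.all(np.diff(c) > 0):
            raise ValueError("bin centers must be strictly increasing")
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "medians", m)
        object.__setattr__(self, "counts", np.asarray(n, dtype=int))

    def __len__(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class DoubleLogisticFit:
    """Fitted double-logistic coefficients with fit diagnostics."""

    S: float
    A1: float
    r1: float
    tau1: float
    A2: float
    r2: float
    tau2: float
    rss: float
    converged: bool
    n_bins: int

    @property
    def coefficients(self) -> tuple[float, ...]:
        return (self.S, self.A1, self.r1, self.tau1, self.A2, self.r2, self.tau2)

    def __call__(self, t):
        return double_logistic(t, *self.coefficients)


@dataclass(frozen=True)
class KineticParameterSet:
    """The ten derived curve parameters plus the raw baseline MFI.

    All curve values are on the standardized (relative) scale where the limit
    of the fitted curve at ``-inf`` equals 1.  ``baseline_mfi_raw`` is the only
    unstandardized quantity.  When the curve has no descending branch inside
    the evaluation window the descending-phase entries are NaN and
    ``descending_defined`` is False.
    """

    starting_value: float
    time_to_first_50: float
    slope_first_50: float
    time_first50_to_max: float
    time_to_max: float
    max_value: float
    time_max_to_second_50: float
    slope_second_50: float
    ending_value: float
    auc: float
    baseline_mfi_raw: float = math.nan
    descending_defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}


# ---------------------------------------------------------------------------
# Series construction
# ---------------------------------------------------------------------------


def bin_median_series(
    times,
    fluo,
    bin_width: float = 5.0,
    min_per_bin: int = 5,
    subset: str = "",
    sample_id: str = "",
) -> KineticSeries:
    """Median fluorescence per fixed-width time bin.

    Events are grouped by ``[k*w, (k+1)*w)``; bins with fewer than
    ``min_per_bin`` events are dropped.  Raises :class:`TooFewEventsError` if
    no bin survives — the exclusion rule for subsets with too few events.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    times = np.asarray(times, dtype=float)
    fluo = np.asarray(fluo, dtype=float)
    if times.shape != fluo.shape:
        raise ValueError("times and fluorescence must have equal length")

    if len(times) == 0:
        raise TooFewEventsError("no events to bin")

    idx = np.floor(times / bin_width).astype(int)
    order = np.argsort(idx, kind="stable")
    idx_sorted = idx[order]
    fluo_sorted = fluo[order]
    uniq, starts, counts = np.unique(idx_sorted, return_index=True, return_counts=True)

    centers, medians, kept_counts = [], [], []
    for k, start, cnt in zip(uniq, starts, counts):
        if cnt < min_per_bin:
            continue
        centers.append((k + 0.5) * bin_width)
        medians.append(float(np.median(fluo_sorted[start : start + cnt])))
        kept_counts.append(int(cnt))

    if not centers:
        raise TooFewEventsError(
            f"no bin reaches min_per_bin={min_per_bin}; subset excluded"
        )
    return KineticSeries(
        centers=np.array(centers),
        medians=np.array(medians),
        counts=np.array(kept_counts),
        subset=subset,
        sample_id=sample_id,
        bin_width=bin_width,
    )


def baseline_mfi(times, fluo, stim_time: float = 120.0) -> float:
    """Raw median fluorescence of events acquired before stimulation."""
    times = np.asarray(times, dtype=float)
    fluo = np.asarray(fluo, dtype=float)
    pre = fluo[times < stim_time]
    if len(pre) == 0:
        raise ValueError("no events before stimulation time")
    return float(np.median(pre))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_MIN_BINS = 8


def _initial_guess(x, y, stim_time):
    pre = y[x < stim_time]
    s0 = float(np.median(pre)) if len(pre) else float(y[0])
    s0 = max(s0, 1e-9)
    tail = y[x >= x[-1] - 60.0]
    e0 = float(np.median(tail)) if len(tail) else float(y[-1])
    ymax = float(np.max(y))
    imax = int(np.argmax(y))
    a1 = max(ymax - s0, 1e-3 * s0)
    a2 = max(ymax - e0, 1e-3 * s0)

    half_up = (s0 + ymax) / 2.0
    above = np.nonzero(y > half_up)[0]
    tau1 = float(x[above[0]]) if len(above) else float(x[imax])

    half_dn = (ymax + e0) / 2.0
    post = np.nonzero((np.arange(len(y)) > imax) & (y < half_dn))[0]
    tau2 = float(x[post[0]]) if len(post) else (tau1 + x[-1]) / 2.0
    tau2 = max(tau2, tau1 + 1.0)
    return np.array([s0, a1, 0.05, tau1, a2, 0.05, tau2])


def fit_double_logistic(
    series: KineticSeries,
    stim_time: float = 120.0,
    max_restarts: int = 5,
) -> DoubleLogisticFit:
    """Bounded nonlinear least squares of the double-logistic model.

    Deterministic: fixed data-driven initialization followed by up to
    ``max_restarts`` fixed perturbed restarts.  Raises
    :class:`UnusableFitError` if no attempt converges, mirroring the rule
    that poorly fittable samples are excluded rather than reported.
    """
    x = series.centers
    y = series.medians
    if len(x) < _MIN_BINS:
        raise TooFewEventsError(
            f"need at least {_MIN_BINS} bins to fit, got {len(x)}"
        )
    if not (x[0] < stim_time < x[-1]):
        raise ValueError("series must span both pre- and post-stimulation time")

    span = float(x[-1] - x[0])
    lo = np.array([1e-12, 0.0, 1e-5, x[0] - span, 0.0, 1e-5, x[0] - span])
    hi = np.array([np.inf, np.inf, 5.0, x[-1] + span, np.inf, 5.0, x[-1] + span])

    def residuals(theta):
        return double_logistic(x, *theta) - y

    x0 = _initial_guess(x, y, stim_time)

    # fixed multiplicative tweaks on (r1, r2) and shifts on (tau1, tau2)
    perturbations = [
        (1.0, 1.0, 0.0, 0.0),
        (0.2, 0.2, 0.0, 0.0),
        (5.0, 5.0, 0.0, 0.0),
        (1.0, 1.0, -30.0, 30.0),
        (0.5, 2.0, 15.0, -15.0),
        (2.0, 0.5, 0.0, 60.0),
    ]

    # flat-model RSS: reference scale to recognize an adequate fit early
    rss_flat = float(np.sum((y - np.median(y)) ** 2))
    good_enough = max(0.02 * rss_flat, 1e-12 * float(np.sum(y**2)))

    best = None
    for k in range(min(max_restarts + 1, len(perturbations))):
        fr1, fr2, dt1, dt2 = perturbations[k]
        guess = x0.copy()
        guess[2] = np.clip(guess[2] * fr1, lo[2], hi[2])
        guess[5] = np.clip(guess[5] * fr2, lo[5], hi[5])
        guess[3] = np.clip(guess[3] + dt1, lo[3], hi[3])
        guess[6] = np.clip(guess[6] + dt2, lo[6], hi[6])
        guess = np.clip(guess, lo, hi)
        try:
            res = optimize.least_squares(
                residuals, guess, bounds=(lo, hi), method="trf", xtol=1e-12,
                ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        if not res.success or not np.all(np.isfinite(res.x)):
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[1]:
            best = (res.x, rss)
        if rss <= good_enough:
            break

    if best is None:
        raise UnusableFitError("double-logistic fit did not converge")

    theta, rss = best
    return DoubleLogisticFit(
        S=float(theta[0]), A1=float(theta[1]), r1=float(theta[2]),
        tau1=float(theta[3]), A2=float(theta[4]), r2=float(theta[5]),
        tau2=float(theta[6]), rss=rss, converged=True, n_bins=len(x),
    )


# ---------------------------------------------------------------------------
# Derived parameters
# ---------------------------------------------------------------------------

_FLAT_TOL = 1e-9  # relative amplitude below which the curve counts as flat


def area_under_curve(fit: DoubleLogisticFit, t0: float, t1: float) -> float:
    """Definite integral of the standardized fitted curve over [t0, t1]."""
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    raw = double_logistic_integral(t0, t1, *fit.coefficients)
    return float(raw / fit.S)


def _standardized(fit):
    coef = fit.coefficients

    def g(t):
        return double_logistic(t, *coef) / fit.S

    def dg(t):
        return double_logistic_derivative(t, *coef) / fit.S

    return g, dg


def derive_parameters(
    fit: DoubleLogisticFit,
    t_end: float = 1020.0,
    baseline: float = math.nan,
) -> KineticParameterSet:
    """Derive the ten kinetic parameters from a converged fit.

    The fitted curve is standardized by its limit at ``-inf`` (the fitted
    ``S``), so the starting value is exactly 1.  The maximum is located on
    ``[0, t_end]`` by grid scan plus local refinement; the half-maximal
    crossings are located by root-finding on each branch and the slopes are
    the analytic derivative of the standardized curve at those times.
    """
    if not fit.converged:
        raise UnusableFitError("cannot derive parameters from a non-converged fit")

    g, dg = _standardized(fit)
    ending = float((fit.S + fit.A1 - fit.A2) / fit.S)
    rel_amp = (fit.A1 + fit.A2) / fit.S
    auc = area_under_curve(fit, 0.0, t_end)

    if rel_amp < _FLAT_TOL:
        return KineticParameterSet(
            starting_value=1.0,
            time_to_first_50=math.nan, slope_first_50=math.nan,
            time_first50_to_max=math.nan, time_to_max=math.nan,
            max_value=1.0, time_max_to_second_50=math.nan,
            slope_second_50=math.nan, ending_value=1.0, auc=auc,
            baseline_mfi_raw=baseline, descending_defined=False,
        )

    grid = np.linspace(0.0, t_end, 4097)
    vals = g(grid)
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda t: -g(t), bounds=(a, b), method="bounded",
        options={"xatol": 1e-8},
    )
    t_max = float(res.x)
    max_val = float(g(t_max))
    # boundary maximum: no interior peak
    at_right_edge = t_end - t_max < 1e-3 * t_end

    # ascending 50%: level midway between start (1) and max
    level_up = (1.0 + max_val) / 2.0
    t50a = _cross_ascending(g, level_up, t_max, fit)
    slope_up = float(dg(t50a)) if not math.isnan(t50a) else math.nan

    if at_right_edge or max_val <= ending + _FLAT_TOL:
        # purely rising curve inside the window: descending phase undefined
        return KineticParameterSet(
            starting_value=1.0,
            time_to_first_50=t50a, slope_first_50=slope_up,
            time_first50_to_max=t_max - t50a, time_to_max=t_max,
            max_value=max_val, time_max_to_second_50=math.nan,
            slope_second_50=math.nan, ending_value=ending, auc=auc,
            baseline_mfi_raw=baseline, descending_defined=False,
        )

    level_dn = (max_val + ending) / 2.0
    t50b = _cross_descending(g, level_dn, t_max, fit)
    slope_dn = float(dg(t50b)) if not math.isnan(t50b) else math.nan

    return KineticParameterSet(
        starting_value=1.0,
        time_to_first_50=t50a, slope_first_50=slope_up,
        time_first50_to_max=t_max - t50a, time_to_max=t_max,
        max_value=max_val, time_max_to_second_50=t50b - t_max,
        slope_second_50=slope_dn, ending_value=ending, auc=auc,
        baseline_mfi_raw=baseline, descending_defined=True,
    )


def _cross_ascending(g, level, t_max, fit):
    """Time where the standardized curve first reaches ``level``, left of the max."""
    lo = min(0.0, fit.tau1 - 5.0 / fit.r1)
    width = max(t_max - lo, 1.0)
    for _ in range(60):
        if g(lo) < level:
            break
        width *= 2.0
        lo -= width
    else:
        return math.nan
    if g(t_max) <= level:
        return math.nan
    return float(optimize.brentq(lambda t: g(t) - level, lo, t_max, xtol=1e-9))


def _cross_descending(g, level, t_max, fit):
    """Time where the standardized curve falls back to ``level``, right of the max."""
    hi = max(t_max + 1.0, fit.tau2 + 5.0 / fit.r2)
    width = hi - t_max
    for _ in range(60):
        if g(hi) < level:
            break
        width *= 2.0
        hi += width
    else:
        return math.nan
    return float(optimize.brentq(lambda t: g(t) - level, t_max, hi, xtol=1e-9))
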