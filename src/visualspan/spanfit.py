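"""Span-profile curve fitting and span-size extraction.

A visual-span profile is percent-correct recognition accuracy as a function of
character position relative to fixation. Span size is read from a fitted
curve — a single Gaussian A*exp(-(x-mu)^2/(2*sigma^2)) or the sum of two such
Gaussians — as the width (in character positions) of the region where the
curve stays at or above a criterion accuracy, by convention 80% correct.
Profiles whose fitted curve never reaches the criterion have a span of zero.

Span can also be expressed in bits of information transmitted, summing a
mutual-information measure of single-character recognition accuracy over the
scored positions; this avoids committing to a criterion level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, least_squares

from .design import SpanProfile
from .errors import FitSelectionError

#: default percent-correct criterion defining the span
DEFAULT_CRITERION = 80.0
#: evaluation window for threshold crossings (positions)
EVAL_RANGE = (-9.0, 9.0)
#: grid step for the crossing scan
GRID_STEP = 1e-3

# least-squares box constraints (percent / position units)
AMP_BOUNDS = (0.0, 110.0)
MU_BOUNDS = (-9.0, 9.0)
SIGMA_BOUNDS = (0.3, 12.0)


def gaussian(x, amplitude, mu, sigma):
    x = np.asarray(x, dtype=float)
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2))


@dataclass(frozen=True)
class ProfileFit:
    """A fitted accuracy curve.

    ``params`` is (A, mu, sigma) for the single model and
    (A1, mu1, sigma1, A2, mu2, sigma2) for the double model; amplitudes are in
    percent, means and standard deviations in character positions.
    """

    model: str  # "single" or "double"
    params: tuple[float, ...]
    r_squared: float
    converged: bool = True

    def __post_init__(self) -> None:
        n = 3 if self.model == "single" else 6
        if self.model not in ("single", "double"):
            raise ValueError(f"unknown model {self.model!r}")
        if len(self.params) != n:
            raise ValueError(f"{self.model} model takes {n} parameters")
        for i in range(0, n, 3):
            if self.params[i] < 0:
                raise ValueError("amplitudes must be non-negative")
            if self.params[i + 2] <= 0:
                raise ValueError("sigma must be positive")

    def fitted(self, x):
        """Evaluate the fitted curve (percent) at real-valued position(s)."""
        if self.model == "single":
            return gaussian(x, *self.params)
        a1, m1, s1, a2, m2, s2 = self.params
        return gaussian(x, a1, m1, s1) + gaussian(x, a2, m2, s2)


@dataclass(frozen=True)
class SpanEstimate:
    """Span size at a percent-correct criterion.

    Extents are measured from fixation (position 0): ``left_extent`` is how
    far the supra-criterion region reaches leftward, ``right_extent``
    rightward; ``asymmetry = right_extent - left_extent`` (positive means a
    larger rightward span). ``span_bits`` is filled in separately from the raw
    profile. A profile that never reaches the criterion has span 0, extents 0
    and undefined (NaN) asymmetry.
    """

    span_chars: float
    left_extent: float
    right_extent: float
    asymmetry: float
    span_bits: float = float("nan")
    criterion: float = DEFAULT_CRITERION


def _residual_factory(x, y, model):
    if model == "single":
        def resid(p):
            return gaussian(x, *p) - y

        def jac(p):
            a, m, s = p
            e = np.exp(-((x - m) ** 2) / (2 * s ** 2))
            return np.column_stack([
                e,
                a * e * (x - m) / s ** 2,
                a * e * (x - m) ** 2 / s ** 3,
            ])
    else:
        def resid(p):
            return gaussian(x, *p[:3]) + gaussian(x, *p[3:]) - y

        def jac(p):
            cols = []
            for a, m, s in (p[:3], p[3:]):
                e = np.exp(-((x - m) ** 2) / (2 * s ** 2))
                cols += [e, a * e * (x - m) / s ** 2,
                         a * e * (x - m) ** 2 / s ** 3]
            return np.column_stack(cols)
    return resid, jac


def _starts(x, y, model):
    ymax = float(np.max(y))
    xmax = float(x[np.argmax(y)])
    a0 = min(max(ymax, 1.0), AMP_BOUNDS[1])
    if model == "single":
        return [(a0, xmax, 2.0), (a0, xmax, 4.0)]
    return [
        (0.7 * a0, xmax - 2.0, 2.0, 0.7 * a0, xmax + 2.0, 2.0),
        (a0, xmax - 2.0, 3.0, a0, xmax + 2.0, 3.0),
        (a0, xmax, 2.0, 0.3 * a0, xmax, 6.0),
    ]


def _clip_start(p0, lb, ub):
    return np.minimum(np.maximum(p0, lb), ub)


def fit_accuracy_curve(positions, accuracy, model: str = "single") -> ProfileFit:
    """Bounded least-squares fit of a Gaussian (or sum of two) to accuracy data.

    Multi-start (deterministic initial points derived from the data maximum)
    bounded fitting; the best converged attempt is kept. If no attempt
    converges the best attempt is still returned with ``converged=False``.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(accuracy, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("positions and accuracy must be aligned 1-d arrays")
    k = 1 if model == "single" else 2
    lb = np.array([AMP_BOUNDS[0], MU_BOUNDS[0], SIGMA_BOUNDS[0]] * k)
    ub = np.array([AMP_BOUNDS[1], MU_BOUNDS[1], SIGMA_BOUNDS[1]] * k)
    resid, jac = _residual_factory(x, y, model)
    best = None
    any_ok = False
    for p0 in _starts(x, y, model):
        res = least_squares(resid, _clip_start(np.array(p0, float), lb, ub),
                            jac=jac, bounds=(lb, ub), method="trf",
                            xtol=1e-10, ftol=1e-10, gtol=1e-10)
        any_ok = any_ok or res.success
        if best is None or res.cost < best.cost:
            best = res
    ss_res = float(2.0 * best.cost)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-10 else -math.inf
    else:
        r2 = 1.0 - ss_res / ss_tot
    return ProfileFit(model=model, params=tuple(float(v) for v in best.x),
                      r_squared=r2, converged=bool(any_ok))


def fit_gaussian(profile: SpanProfile, model: str = "single") -> ProfileFit:
    """Fit the chosen curve model to one span profile."""
    return fit_accuracy_curve(profile.positions, profile.accuracy, model)


def _supra_region_is_interval(fit: ProfileFit, criterion: float) -> bool:
    x = np.arange(EVAL_RANGE[0], EVAL_RANGE[1] + GRID_STEP / 2, GRID_STEP)
    above = fit.fitted(x) >= criterion
    if not above.any():
        return True  # empty region: nothing disconnected to report
    changes = int(np.count_nonzero(np.diff(above.astype(np.int8))))
    return changes <= 2


def select_best_fit(fit_single: ProfileFit, fit_double: ProfileFit,
                    delta_r2: float = 0.01,
                    criterion: float = DEFAULT_CRITERION) -> ProfileFit:
    """Deterministic stand-in for by-eye model choice between the two fits.

    The double-Gaussian fit is preferred only when it earns it: its r^2 must
    exceed the single fit's by at least ``delta_r2`` AND it must be admissible
    (both amplitudes positive, both means within the scored range -7..+7, and
    its supra-criterion region a single interval — a span is one contiguous
    stretch of positions). Otherwise the single fit is returned.
    """
    if not (fit_single.converged or fit_double.converged):
        raise FitSelectionError("neither curve fit converged")
    if not fit_double.converged:
        return fit_single
    if not fit_single.converged:
        return fit_double
    a1, m1, _, a2, m2, _ = fit_double.params
    admissible = (a1 > 0 and a2 > 0
                  and -7.0 <= m1 <= 7.0 and -7.0 <= m2 <= 7.0
                  and _supra_region_is_interval(fit_double, criterion))
    if admissible and fit_double.r_squared - fit_single.r_squared >= delta_r2:
        return fit_double
    return fit_single


def compute_span(fit: ProfileFit,
                 criterion: float = DEFAULT_CRITERION) -> SpanEstimate:
    """Width of the fitted curve at the criterion, in character positions.

    The outermost criterion crossings are located by a 0.001-position grid
    scan over [-9, +9] with bracketed root refinement. If the curve never
    reaches the criterion in that window the span is zero (extents zero,
    asymmetry undefined). If the curve is still above the criterion at a
    window edge the crossing is clamped to the edge.
    """
    x = np.arange(EVAL_RANGE[0], EVAL_RANGE[1] + GRID_STEP / 2, GRID_STEP)
    y = np.asarray(fit.fitted(x), dtype=float)
    if float(np.max(y)) < criterion:
        return SpanEstimate(span_chars=0.0, left_extent=0.0, right_extent=0.0,
                            asymmetry=float("nan"), criterion=criterion)
    i_peak = int(np.argmax(y))

    def f(t):
        return float(fit.fitted(t)) - criterion

    above = y >= criterion
    # leftmost upward crossing at or before the peak
    left_idx = np.flatnonzero(above[:i_peak + 1])
    i0 = int(left_idx[0])
    if i0 == 0:
        x_left = float(x[0])
    else:
        x_left = brentq(f, x[i0 - 1], x[i0], xtol=1e-9)
    # rightmost downward crossing at or after the peak
    right_idx = np.flatnonzero(above[i_peak:]) + i_peak
    i1 = int(right_idx[-1])
    if i1 == len(x) - 1:
        x_right = float(x[-1])
    else:
        x_right = brentq(f, x[i1], x[i1 + 1], xtol=1e-9)
    left_extent = max(0.0, -x_left)
    right_extent = max(0.0, x_right)
    return SpanEstimate(
        span_chars=x_right - x_left,
        left_extent=left_extent,
        right_extent=right_extent,
        asymmetry=right_extent - left_extent,
        criterion=criterion,
    )


def info_transmitted(p: float, set_size: int = 26) -> float:
    """Information transmitted (bits) by one character report at accuracy p.

    Mutual information between stimulus and response for an N-character set
    under the standard confusion model: the correct character is reported with
    probability p and errors fall uniformly on the remaining N-1 characters:

        I(p) = log2(N) + p*log2(p) + (1-p)*log2((1-p)/(N-1))

    p is clamped to [1/N, 1] first, so chance performance maps to 0 bits and
    perfect performance to log2(N) bits (4.7 for N = 26).
    """
    if set_size < 2:
        raise ValueError("set_size must be at least 2")
    n = float(set_size)
    p = min(max(float(p), 1.0 / n), 1.0)
    bits = math.log2(n) + p * math.log2(p)
    if p < 1.0:
        bits += (1.0 - p) * math.log2((1.0 - p) / (n - 1.0))
    return max(bits, 0.0)


def span_bits(profile: SpanProfile, set_size: int = 26) -> float:
    """Span size in bits: information transmitted summed over scored positions.

    Uses the raw per-position accuracies, not a fitted curve.
    """
    return float(sum(info_transmitted(a / 100.0, set_size)
                     for a in profile.accuracy))


def asymmetry(estimate: SpanEstimate) -> float:
    """Rightward asymmetry (right minus left extent); NaN for zero spans."""
    if estimate.span_chars <= 0.0:
        return float("nan")
    return estimate.right_extent - estimate.left_extent


def estimate_span(profile: SpanProfile,
                  criterion: float = DEFAULT_CRITERION,
                  delta_r2: float = 0.01,
                  set_size: int = 26) -> tuple[SpanEstimate, ProfileFit]:
    """Full span estimation for one profile: fit both models, select, measure.

    Returns the span estimate (with bits computed from the raw profile) and
    the selected fit.
    """
    fit_s = fit_gaussian(profile, "single")
    fit_d = fit_gaussian(profile, "double")
    chosen = select_best_fit(fit_s, fit_d, delta_r2=delta_r2,
                             criterion=criterion)
    est = compute_span(chosen, criterion=criterion)
    est = replace(est, span_bits=span_bits(profile, set_size))
    return est, chosen
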