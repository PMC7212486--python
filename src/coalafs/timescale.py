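"""The coalescent time-scaling function g and its inverses.

g(t) = integral_0^t 1/N(u) du maps generations to coalescent-scaled time,
in which the sample behaves as a standard Kingman coalescent.  Expected
coalescence times in generations are recovered by inverting g at the
standard-coalescent expectations.  Three interchangeable inversion schemes
are provided:

* **finite-sum scan** (:func:`invert_scale_finite_sum`): approximate g by a
  left-endpoint Riemann sum with a fixed generation step and scan forward
  once, harvesting every target along the way.  Works for any history; the
  number of N(t) evaluations depends only on the oldest target, not on the
  number of targets.
* **bracketed root-finding** (:func:`invert_scale_root`): solve
  g(t) - mu = 0 with geometric bracket expansion followed by Brent's
  method, using an exact/closed-form g where one exists.
* **closed form** (:func:`invert_scale_analytic`): constant and exponential
  histories invert elementarily; the logistic history inverts through the
  principal branch of the Lambert W function.

Derivations used here (logistic):
    1/N(t) = 1/Nk + (Nk - 1) e^{gamma (t - T)} / Nk
    g(t)   = [ (Nk-1) e^{-gamma T} (e^{gamma t} - 1) + gamma t ] / (Nk gamma)
and with A = (Nk-1) e^{-gamma T}, C = Nk gamma tau + A the inverse is
    g^{-1}(tau) = ( C - W(A e^C) ) / gamma .
Both are cross-validated against adaptive quadrature / root-finding in the
test suite before being relied on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expi, lambertw

from .demography import DemographyModel, population_size
from .errors import (NonCoalescingHistoryError, NumericDomainError,
                     UnsupportedFamilyError, ValidationError)

logger = logging.getLogger(__name__)

_BLOCK = 8192  # vectorized scan block; does not affect results or counts

OVERSHOOT_RULES = ("first_crossing", "nearest")


@dataclass(frozen=True)
class FiniteSumConfig:
    """Controls for the discrete finite-sum scan.

    step
        Generation increment of the sum.  The default of 1 generation
        matches the algorithm's natural unit; sub-generation steps sharpen
        the approximation when N(t) is small (per-step mass 1/N becomes
        coarse near a founding size of 1).
    max_time
        Guard on the total generations scanned before declaring the
        history non-coalescing.
    overshoot_rule
        How to settle the final step once the accumulator G first reaches a
        target mu: ``first_crossing`` returns t when G - mu < step/N(t)
        and t - step otherwise; ``nearest`` returns whichever of the two
        has G closest to mu.  With a G < mu loop guard the first_crossing
        else-branch is mathematically unreachable (the final increment is
        exactly step/N(t), so G - mu < step/N(t) always holds); it is kept
        as protection against floating-point rounding.
    """

    step: float = 1.0
    max_time: float = 1e8
    overshoot_rule: str = "first_crossing"

    def __post_init__(self):
        if not (self.step > 0 and math.isfinite(self.step)):
            raise ValidationError(f"step must be finite > 0, got {self.step}")
        if not (self.max_time > 0):
            raise ValidationError(f"max_time must be > 0, got {self.max_time}")
        if self.overshoot_rule not in OVERSHOOT_RULES:
            raise ValidationError(
                f"overshoot_rule must be one of {OVERSHOOT_RULES}, "
                f"got {self.overshoot_rule!r}")


# ---------------------------------------------------------------------------
# Forward evaluation of g
# ---------------------------------------------------------------------------

def scale_time_numeric(model: DemographyModel, t: float,
                       cfg: FiniteSumConfig | None = None) -> float:
    """Left-endpoint finite-sum approximation of g(t).

    Returns sum over u = 0, step, 2*step, ... <= t of step / N(u); with the
    default step of 1 this is the accumulator G of the scan algorithm
    evaluated at generation t.
    """
    cfg = cfg or FiniteSumConfig()
    if t < 0:
        raise ValidationError(f"t must be >= 0, got {t}")
    n_steps = int(math.floor(t / cfg.step + 1e-12))
    total = 0.0
    for start in range(0, n_steps + 1, _BLOCK):
        stop = min(start + _BLOCK, n_steps + 1)
        u = np.arange(start, stop, dtype=float) * cfg.step
        total += float(np.sum(cfg.step / population_size(model, u)))
    return total


def scale_time_analytic(model: DemographyModel, t: float) -> float:
    """Closed-form g(t) for constant, exponential and logistic histories."""
    if model.family not in ("constant", "exponential", "logistic"):
        raise UnsupportedFamilyError(
            f"no closed-form time scale for family {model.family!r}; "
            "use scale_time_numeric or invert_scale_finite_sum")
    if t < 0:
        raise ValidationError(f"t must be >= 0, got {t}")
    p = model.params
    if model.family == "constant":
        return t / p["N0"]
    # e^{gamma t} saturates at exp(600): beyond that point g exceeds any
    # attainable scaled-time target by hundreds of orders of magnitude, and
    # the cap keeps deep bracket probes finite
    if model.family == "exponential":
        g = p["gamma"]
        return math.expm1(min(g * t, 600.0)) / (p["N0"] * g)
    nk, g, big_t = p["Nk"], p["gamma"], p["T"]
    growth = (nk - 1.0) * math.exp(-g * big_t) * math.expm1(min(g * t, 600.0))
    return (growth + g * t) / (nk * g)


def _exact_scale(model: DemographyModel) -> Callable[[float], float]:
    """A fast, quadrature-grade scalar g(t) for *any* family.

    Beyond the three closed forms, the gompertz integral has an exact
    expression through the exponential integral Ei, and a piecewise-constant
    history integrates exactly epoch by epoch.  Each form is verified
    against adaptive quadrature in the test suite.
    """
    p = model.params
    if model.family in ("constant", "exponential", "logistic"):
        return lambda t: scale_time_analytic(model, t)
    if model.family == "gompertz":
        n0, g, a, big_t = p["N0"], p["gamma"], p["alpha"], p["T"]
        r = g / a
        pref = math.exp(-r) / (n0 * a)
        base = expi(r * math.exp(-a * big_t))
        # past t_cap the Ei argument exceeds ~700 and g is astronomically
        # large (~1e300); saturate there so bracket probes stay finite
        t_cap = big_t + math.log(700.0 / r) / a if r < 700.0 else big_t

        def g_gompertz(t: float) -> float:
            return pref * (expi(r * math.exp(-a * (big_t - min(t, t_cap)))) - base)

        return g_gompertz
    # piecewise: exact cumulative integral at the breakpoints
    times = np.asarray(model.breakpoint_times)
    sizes = np.asarray(model.breakpoint_sizes)
    widths = np.diff(times)
    cum = np.concatenate([[0.0], np.cumsum(widths / sizes[:-1])])

    def g_piecewise(t: float) -> float:
        i = int(np.searchsorted(times, t, side="right") - 1)
        return float(cum[i] + (t - times[i]) / sizes[i])

    return g_piecewise


# ---------------------------------------------------------------------------
# Inversion scheme 1: single-pass finite-sum scan
# ---------------------------------------------------------------------------

class _BlockScanner:
    """Sequential per-step accumulation of G with blocked N evaluation.

    Semantically identical to advancing one step at a time; blocks only
    batch the N(t) calls.  ``steps`` counts generations advanced, which is
    the algorithmic number of N evaluations past the initialization.
    """

    def __init__(self, model: DemographyModel, cfg: FiniteSumConfig):
        self.model = model
        self.step = cfg.step
        self.max_time = cfg.max_time
        self.t = 0.0
        inv0 = cfg.step / population_size(model, 0.0)
        self.G = inv0
        self.last_inv = inv0
        self.steps = 0
        self._buf_cum: np.ndarray | None = None
        self._buf_inv: np.ndarray | None = None
        self._buf_t0 = 0.0  # time of the step *before* the buffer start
        self._ptr = 0

    def _refill(self):
        t0 = self.t
        u = t0 + self.step * np.arange(1, _BLOCK + 1, dtype=float)
        inv = self.step / population_size(self.model, u)
        self._buf_inv = inv
        self._buf_cum = self.G + np.cumsum(inv)
        self._buf_t0 = t0
        self._ptr = 0

    def advance_to(self, mu: float) -> None:
        """Advance while G < mu (possibly zero steps)."""
        while self.G < mu:
            if self._buf_cum is None or self._ptr >= _BLOCK:
                if self.t > self.max_time:
                    raise NonCoalescingHistoryError(
                        f"accumulated scaled time {self.G:.6g} has not reached "
                        f"target {mu:.6g} after {self.t:.6g} generations; the "
                        "population is too large into the past")
                self._refill()
            idx = int(np.searchsorted(self._buf_cum[self._ptr:], mu, side="left"))
            idx += self._ptr
            if idx >= _BLOCK:
                # consume the whole buffer and refill
                self.steps += _BLOCK - self._ptr
                self.t = self._buf_t0 + _BLOCK * self.step
                self.G = float(self._buf_cum[-1])
                self.last_inv = float(self._buf_inv[-1])
                self._ptr = _BLOCK
            else:
                self.steps += idx - self._ptr + 1
                self.t = self._buf_t0 + (idx + 1) * self.step
                self.G = float(self._buf_cum[idx])
                self.last_inv = float(self._buf_inv[idx])
                self._ptr = idx + 1


def invert_scale_finite_sum(model: DemographyModel,
                            targets: Sequence[float],
                            cfg: FiniteSumConfig | None = None,
                            *,
                            return_eval_count: bool = False):
    """Invert g at many targets in one forward scan (finite-sum scheme).

    ``targets`` must be positive and sorted ascending (the scan consumes
    the smallest scaled time first, i.e. the most recent coalescence).
    Returns generation times in consumption order, non-decreasing.  With
    ``return_eval_count=True`` also returns the number of N(t) evaluations
    performed (initialization included), which depends only on the largest
    target — the source of the scheme's near-constant cost in sample size.
    """
    cfg = cfg or FiniteSumConfig()
    targets = np.asarray(targets, dtype=float)
    if targets.ndim != 1 or targets.size == 0:
        raise ValidationError("targets must be a non-empty 1-D sequence")
    if np.any(targets <= 0):
        raise ValidationError("all targets must be > 0")
    if np.any(np.diff(targets) < 0):
        raise ValidationError("targets must be sorted ascending")

    n0 = population_size(model, 0.0)
    if n0 < 100 and cfg.step >= 1.0:
        logger.warning(
            "N(0)=%.3g is small relative to step=%g; per-step scaled mass "
            "1/N is coarse — consider a sub-generation step (e.g. 0.01)",
            n0, cfg.step)

    scanner = _BlockScanner(model, cfg)
    out = np.empty_like(targets)
    for i, mu in enumerate(targets):
        scanner.advance_to(mu)
        t, G, inv = scanner.t, scanner.G, scanner.last_inv
        if cfg.overshoot_rule == "first_crossing":
            out[i] = t if (G - mu) < inv else t - cfg.step
        else:  # nearest
            prev_closer = t > 0 and abs((G - inv) - mu) < abs(G - mu)
            out[i] = t - cfg.step if prev_closer else t
    if return_eval_count:
        return out, scanner.steps + 1
    return out


# ---------------------------------------------------------------------------
# Inversion scheme 2: bracketed root-finding
# ---------------------------------------------------------------------------

def invert_scale_root(model: DemographyModel, target: float,
                      tol: float = 1e-10, *, max_time: float = 1e8) -> float:
    """Solve g(t) = target by bracket expansion plus Brent's method.

    The bracket starts at N(0) * target (exact for a constant history) and
    doubles until g exceeds the target.  The returned t* satisfies
    |g(t*) - target| <= tol * max(1, target).
    """
    if not (target > 0):
        raise ValidationError(f"target must be > 0, got {target}")
    if not (tol > 0):
        raise ValidationError(f"tol must be > 0, got {tol}")
    g = _exact_scale(model)
    return _invert_bracketed(g, target, tol, max_time,
                             hi0=population_size(model, 0.0) * target,
                             deriv=lambda t: 1.0 / population_size(model, t))


def _invert_bracketed(g: Callable[[float], float], target: float,
                      tol: float, max_time: float, hi0: float,
                      lo: float = 0.0,
                      deriv: Callable[[float], float] | None = None) -> float:
    hi = max(hi0, 1.0)
    while g(hi) < target:
        hi *= 2.0
        if hi > max_time:
            raise NonCoalescingHistoryError(
                f"no bracket for scaled time {target:.6g} within "
                f"{max_time:.3g} generations")
    if g(lo) > target:
        lo = 0.0
    root = float(brentq(lambda t: g(t) - target, lo, hi,
                        xtol=1e-12, rtol=4 * np.finfo(float).eps,
                        maxiter=200))
    if deriv is not None:
        # Newton polish with the exact derivative g' = 1/N
        for _ in range(8):
            err = g(root) - target
            if abs(err) <= tol * max(1.0, target):
                break
            root = root - err / deriv(root)
    if abs(g(root) - target) > tol * max(1.0, target):
        raise NumericDomainError(
            f"root refinement failed: |g(t)-mu| = {abs(g(root) - target):.3g} "
            f"exceeds tolerance at mu={target:.6g}")
    return float(root)


# ---------------------------------------------------------------------------
# Inversion scheme 3: closed forms (Lambert W for logistic)
# ---------------------------------------------------------------------------

def _lambertw_principal(log_arg: float) -> float:
    """W0 at a point given by its natural log (robust to exp overflow)."""
    if log_arg < 700.0:
        w = lambertw(math.exp(log_arg), k=0)
        if abs(w.imag) > 1e-12:
            raise NumericDomainError(
                f"Lambert W returned a complex value for log-argument {log_arg}")
        return float(w.real)
    # asymptotic regime: solve w + log w = log_arg by Newton
    w = log_arg - math.log(log_arg)
    for _ in range(50):
        f = w + math.log(w) - log_arg
        w_new = w - f / (1.0 + 1.0 / w)
        if abs(w_new - w) <= 1e-14 * w_new:
            return w_new
        w = w_new
    return w


def invert_scale_analytic(model: DemographyModel, target: float) -> float:
    """Closed-form g^{-1}(target) for constant/exponential/logistic."""
    if not (target > 0):
        raise ValidationError(f"target must be > 0, got {target}")
    p = model.params
    if model.family == "constant":
        return p["N0"] * target
    if model.family == "exponential":
        g = p["gamma"]
        return math.log1p(p["N0"] * g * target) / g
    if model.family == "logistic":
        nk, g, big_t = p["Nk"], p["gamma"], p["T"]
        a = (nk - 1.0) * math.exp(-g * big_t)
        c = nk * g * target + a
        # W argument is A e^C > 0, always inside the principal branch; the
        # -1/e boundary can only be approached through invalid parameters.
        log_arg = math.log(a) + c
        if not math.isfinite(log_arg):
            raise NumericDomainError(
                f"Lambert W argument out of range for Nk={nk}, gamma={g}, "
                f"T={big_t}, target={target}")
        w = _lambertw_principal(log_arg)
        return (c - w) / g
    raise UnsupportedFamilyError(
        f"no closed-form inverse for family {model.family!r}; "
        "use invert_scale_root or invert_scale_finite_sum")
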