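"""Population-size histories N(t) in backward time.

Time ``t`` is measured in generations backward from the present (``t = 0``
is today).  Sizes are *haploid* throughout: N counts sequences, which for an
autosomal diploid census is twice the number of individuals.  Five families
are supported:

``constant``
    N(t) = N0.
``exponential``
    N(t) = N0 * exp(-gamma * t): a population that grew exponentially
    forward in time at rate ``gamma`` per generation shrinks exponentially
    backward.
``logistic``
    Growth from a founding size of 1 toward a carrying capacity ``Nk``,
    starting ``T`` generations ago with intrinsic rate ``gamma``.  In
    backward time N(t) = Nk e^{gamma T} / (e^{gamma T} + (Nk - 1) e^{gamma t}).
    The formula is evaluated for *all* t >= 0; beyond the onset (t > T) the
    size decays below 1, which guarantees coalescence and is deliberately
    not clamped unless ``size_floor`` is set.
``gompertz``
    Growth from founding size ``N0`` starting ``T`` generations ago, with a
    per-capita growth rate that starts at ``gamma`` and decays exponentially
    at rate ``alpha``.  Forward solution N(s) = N0 exp((gamma/alpha)(1 -
    e^{-alpha s})); the backward form substitutes s = T - t.
``piecewise``
    A right-continuous step function over ordered breakpoints (t_i, N_i)
    with t_0 = 0, the last size extending to infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, NumericDomainError, ValidationError

FAMILIES = ("constant", "exponential", "logistic", "gompertz", "piecewise")

_REQUIRED_PARAMS = {
    "constant": ("N0",),
    "exponential": ("N0", "gamma"),
    "logistic": ("Nk", "gamma", "T"),
    "gompertz": ("N0", "gamma", "alpha", "T"),
}


@dataclass(frozen=True)
class DemographyModel:
    """A validated backward-time haploid size history.

    Construct via :func:`build_demography` (or
    :func:`read_piecewise_table` for tabulated histories) rather than
    directly, so that parameter validation always runs.
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)
    size_floor: float | None = None
    # piecewise only: parallel arrays of breakpoint times and sizes
    breakpoint_times: tuple[float, ...] = ()
    breakpoint_sizes: tuple[float, ...] = ()

    def size(self, t):
        """Shorthand for :func:`population_size`."""
        return population_size(self, t)


def _require_positive(family: str, params: Mapping[str, float], name: str,
                      strict_gt: float = 0.0) -> float:
    if name not in params:
        raise ValidationError(f"{family}: missing parameter '{name}'")
    value = float(params[name])
    if not math.isfinite(value) or value <= strict_gt:
        raise ValidationError(
            f"{family}: parameter '{name}' must be > {strict_gt}, got {value!r}")
    return value


def build_demography(family: str,
                     params: Mapping[str, float] | None = None,
                     *,
                     size_floor: float | None = None,
                     **kwargs) -> DemographyModel:
    """Validate a parameter record and return a :class:`DemographyModel`.

    Parameters may be given as a mapping or as keyword arguments.  For the
    ``piecewise`` family supply ``times`` and ``sizes`` sequences (first
    time must be 0, times strictly increasing, sizes positive).
    """
    merged = dict(params or {})
    merged.update(kwargs)
    if family not in FAMILIES:
        raise ValidationError(
            f"unknown model family {family!r}; expected one of {FAMILIES}")

    if size_floor is not None and size_floor <= 0:
        raise ValidationError(f"size_floor must be > 0, got {size_floor!r}")

    if family == "piecewise":
        times = merged.pop("times", None)
        sizes = merged.pop("sizes", None)
        if merged:
            raise ValidationError(
                f"piecewise: unexpected parameters {sorted(merged)}")
        if times is None or sizes is None:
            raise ValidationError("piecewise: 'times' and 'sizes' are required")
        times = tuple(float(t) for t in times)
        sizes = tuple(float(s) for s in sizes)
        if len(times) != len(sizes) or not times:
            raise ValidationError(
                "piecewise: 'times' and 'sizes' must be equal-length, non-empty")
        if times[0] != 0.0:
            raise ValidationError(
                f"piecewise: first breakpoint time must be 0, got {times[0]}")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(
                "piecewise: breakpoint times must be strictly increasing")
        if any(s <= 0 or not math.isfinite(s) for s in sizes):
            raise ValidationError("piecewise: all sizes must be positive finite")
        return DemographyModel("piecewise", {}, size_floor,
                               breakpoint_times=times, breakpoint_sizes=sizes)

    clean: dict[str, float] = {}
    for name in _REQUIRED_PARAMS[family]:
        clean[name] = _require_positive(family, merged, name)
    extra = set(merged) - set(clean)
    if extra:
        raise ValidationError(f"{family}: unexpected parameters {sorted(extra)}")
    if family == "logistic" and clean["Nk"] <= 1.0:
        raise ValidationError(
            f"logistic: carrying capacity Nk must exceed the founding size 1, "
            f"got {clean['Nk']}")
    return DemographyModel(family, clean, size_floor)


def read_piecewise_table(path) -> DemographyModel:
    """Load a piecewise history from a headered TSV.

    Columns: ``time_generations`` (>= 0, strictly increasing, first row 0)
    and ``haploid_size`` (> 0).
    """
    df = pd.read_csv(path, sep="\t")
    expected = {"time_generations", "haploid_size"}
    if set(df.columns) != expected:
        raise ValidationError(
            f"piecewise table must have columns {sorted(expected)}, "
            f"got {sorted(df.columns)}")
    return build_demography("piecewise",
                            times=df["time_generations"].to_list(),
                            sizes=df["haploid_size"].to_list())


def _eval_size(model: DemographyModel, t: np.ndarray) -> np.ndarray:
    """N(t) elementwise; logistic goes through log space for stability."""
    p = model.params
    if model.family == "constant":
        return np.full_like(t, p["N0"])
    if model.family == "exponential":
        return p["N0"] * np.exp(-p["gamma"] * t)
    if model.family == "logistic":
        nk, g, big_t = p["Nk"], p["gamma"], p["T"]
        # N(t) = Nk / (1 + (Nk-1) e^{gamma (t - T)}), kept in log space so
        # that deep-past evaluations underflow gracefully instead of
        # overflowing the denominator
        return np.exp(math.log(nk)
                      - np.logaddexp(0.0, math.log(nk - 1.0) + g * (t - big_t)))
    if model.family == "gompertz":
        n0, g, a, big_t = p["N0"], p["gamma"], p["alpha"], p["T"]
        return n0 * np.exp((g / a) * (1.0 - np.exp(-a * (big_t - t))))
    raise AssertionError(model.family)


def population_size(model: DemographyModel, t):
    """Evaluate N(t) at backward time(s) ``t`` (generations, >= 0).

    Accepts a scalar or array; returns the matching shape.  Raises
    :class:`DomainError` for negative times and :class:`NumericDomainError`
    if the evaluated size is non-positive or non-finite.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        bad = arr[~((arr >= 0) & np.isfinite(arr))].flat[0]
        raise DomainError(f"backward time must be finite and >= 0, got {bad}")

    if model.family == "piecewise":
        times = np.asarray(model.breakpoint_times)
        sizes = np.asarray(model.breakpoint_sizes)
        idx = np.searchsorted(times, arr, side="right") - 1
        out = sizes[idx]
    else:
        with np.errstate(over="ignore", under="ignore"):
            out = _eval_size(model, arr)

    if model.size_floor is not None:
        out = np.maximum(out, model.size_floor)

    bad = ~(np.isfinite(out) & (out > 0))
    if np.any(bad):
        t_bad = arr[bad].flat[0] if arr.shape else float(arr)
        raise NumericDomainError(
            f"population size underflowed to a non-positive value at t={t_bad} "
            f"(family={model.family}); consider setting size_floor")
    if np.isscalar(t) or arr.shape == ():
        return float(out)
    return out


def relative_size(model: DemographyModel, t):
    """lambda(t) = N(t) / N(0), the relative size function."""
    return population_size(model, t) / population_size(model, 0.0)
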