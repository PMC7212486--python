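"""Expected coalescence quantities for a sample of n lineages.

For a sample of n haplotypes, T_m is the backward time at which m+1
ancestral lineages merge into m, and W_k = T_{k-1} - T_k is the duration
with exactly k lineages.  In coalescent-scaled time the standard Kingman
coalescent gives E[tau_m] = mu_m = 2(1/m - 1/n) and a variance obtained by
summing the squared means of the independent exponential epochs.  Under a
varying size history, first-order Taylor expansion of g^{-1} around mu_m
yields

    E[T_m]   ~= g^{-1}(mu_m)
    Var[T_m] ~= sigma_m^2 / g'(g^{-1}(mu_m))^2 = sigma_m^2 * N(E[T_m])^2

since g'(t) = 1/N(t).  For a constant history g is linear and both
expressions are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import DemographyModel, population_size
from .errors import ValidationError
from .timescale import (FiniteSumConfig, invert_scale_analytic,
                        invert_scale_finite_sum, invert_scale_root)

METHODS = ("finite_sum", "root", "analytic")


@dataclass(frozen=True)
class CoalescentSchedule:
    """Per-level expected coalescence quantities for a sample of n.

    Vectors are indexed m = 1..n-1 for scaled times / coalescence times
    (``mu_scaled``, ``sigma2_scaled``, ``ET``, ``VarT``) and k = 2..n for
    intercoalescence times (``EW``); T_n = 0 by convention so
    EW_n = E[T_{n-1}].
    """

    n: int
    mu_scaled: np.ndarray
    sigma2_scaled: np.ndarray
    ET: np.ndarray
    VarT: np.ndarray
    EW: np.ndarray
    method: str


def _check_n(n: int) -> int:
    if int(n) != n or n < 2:
        raise ValidationError(f"sample size n must be an integer >= 2, got {n!r}")
    return int(n)


def kingman_expected_scaled(n: int) -> np.ndarray:
    """mu_m = 2(1/m - 1/n) for m = 1..n-1 (units of haploid size N)."""
    n = _check_n(n)
    m = np.arange(1, n, dtype=float)
    return 2.0 * (1.0 / m - 1.0 / n)


def kingman_variance_scaled(n: int) -> np.ndarray:
    """sigma_m^2 = sum_{k=m+1}^{n} 4 / (k^2 (k-1)^2), m = 1..n-1.

    Variance of tau_m as the sum of the independent Exp(k(k-1)/2) epochs of
    the standard coalescent from k = n down to m+1.
    """
    n = _check_n(n)
    k = np.arange(2, n + 1, dtype=float)
    per_epoch = (2.0 / (k * (k - 1.0))) ** 2  # epoch k variance, k=2..n
    # sigma_m^2 sums epochs k = m+1..n -> suffix sums over the k axis
    return np.cumsum(per_epoch[::-1])[::-1]


def expected_times(model: DemographyModel, n: int, method: str = "finite_sum",
                   cfg: FiniteSumConfig | None = None,
                   tol: float = 1e-10) -> np.ndarray:
    """E[T_m] = g^{-1}(mu_m), m = 1..n-1, by the chosen inversion scheme."""
    n = _check_n(n)
    if method not in METHODS:
        raise ValidationError(f"method must be one of {METHODS}, got {method!r}")
    mu = kingman_expected_scaled(n)
    ascending = mu[::-1]  # consume smallest (most recent) first
    if method == "finite_sum":
        times = invert_scale_finite_sum(model, ascending, cfg)
    elif method == "root":
        times = np.array([invert_scale_root(model, m, tol) for m in ascending])
    else:
        times = np.array([invert_scale_analytic(model, m) for m in ascending])
    return times[::-1]


def variance_times(model: DemographyModel, n: int, method: str = "finite_sum",
                   cfg: FiniteSumConfig | None = None,
                   ET: np.ndarray | None = None) -> np.ndarray:
    """First-order Var[T_m] = sigma_m^2 * N(E[T_m])^2, m = 1..n-1."""
    n = _check_n(n)
    if ET is None:
        ET = expected_times(model, n, method, cfg)
    sigma2 = kingman_variance_scaled(n)
    sizes = np.asarray(population_size(model, np.asarray(ET, dtype=float)))
    return sigma2 * sizes ** 2


def intercoalescence_times(ET: np.ndarray, n: int) -> np.ndarray:
    """E[W_k] for k = 2..n from the expected coalescence times.

    E[W_k] = E[T_{k-1}] - E[T_k] with the boundary T_n = 0, so
    EW[-1] = E[T_{n-1}].  Requires ET non-increasing in m (older events
    first); an increasing pair signals a broken inversion upstream.  Exact
    ties are tolerated because a step-discretized inversion can place two
    adjacent levels on the same generation.
    """
    n = _check_n(n)
    ET = np.asarray(ET, dtype=float)
    if ET.shape != (n - 1,):
        raise ValidationError(
            f"ET must have length n-1 = {n - 1}, got shape {ET.shape}")
    if n > 2 and np.any(np.diff(ET) > 0):
        raise ValidationError(
            "ET must be decreasing in m (older events first); "
            "non-monotone input indicates a failed inversion")
    ew = ET - np.append(ET[1:], 0.0)
    return ew


def coalescent_schedule(model: DemographyModel, n: int,
                        method: str = "finite_sum",
                        cfg: FiniteSumConfig | None = None) -> CoalescentSchedule:
    """Assemble the full :class:`CoalescentSchedule` for a sample of n."""
    n = _check_n(n)
    mu = kingman_expected_scaled(n)
    sigma2 = kingman_variance_scaled(n)
    et = expected_times(model, n, method, cfg)
    var = variance_times(model, n, method, cfg, ET=et)
    ew = intercoalescence_times(et, n)
    return CoalescentSchedule(n=n, mu_scaled=mu, sigma2_scaled=sigma2,
                              ET=et, VarT=var, EW=ew, method=method)
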