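"""Monte-Carlo coalescent oracle under a variable-size history.

Validates the deterministic machinery independently: scaled
intercoalescence epochs are drawn from the standard Kingman coalescent
(Exp(k(k-1)/2) while k lineages remain), accumulated into scaled
coalescence times tau_m, and mapped to generations through the numeric
inverse of the time-scaling function g.  Spectrum estimates are
Rao-Blackwellized over mutation placement: each replicate contributes the
*expected* spectrum given its sampled intercoalescence times, so standard
errors reflect genealogical noise only.

The MC truth for coalescence times is E[g^{-1}(tau_m)] (Jensen-correct),
whereas the first-order point estimate used elsewhere is g^{-1}(E[tau_m]);
the two differ by the curvature of g^{-1}, which is exactly the
approximation the oracle is designed to audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import DemographyModel, population_size
from .errors import ValidationError
from .spectrum import _branch_weight_matrix
from .timescale import _exact_scale, _invert_bracketed

_INVERSION_TOL = 1e-8


@dataclass(frozen=True)
class McEstimate:
    """Across-replicate summaries of a seeded coalescent simulation.

    ``mean_T``/``se_T`` are indexed m = 1..n-1 (generations);
    ``mean_counts``/``se_counts`` are indexed j = 1..n-1.  Standard errors
    are NaN when ``reps == 1``.  Identical (seed, parameters) reproduce the
    estimate bit-for-bit.
    """

    n: int
    reps: int
    seed: int
    mean_T: np.ndarray
    se_T: np.ndarray
    mean_counts: np.ndarray
    se_counts: np.ndarray


def _scaled_epochs(n: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """(reps, n-1) scaled epoch lengths, columns k = n down to 2."""
    k = np.arange(n, 1, -1, dtype=float)
    rates = k * (k - 1.0) / 2.0
    return rng.exponential(1.0 / rates, size=(reps, n - 1))


def _invert_many(model: DemographyModel, taus: np.ndarray) -> np.ndarray:
    """g^{-1} applied elementwise, warm-starting brackets in sorted order."""
    g = _exact_scale(model)
    flat = taus.ravel()
    order = np.argsort(flat)
    out = np.empty_like(flat)
    n0 = population_size(model, 0.0)
    deriv = lambda t: 1.0 / population_size(model, t)  # noqa: E731
    lo = 0.0
    hi_hint = 1.0
    for idx in order:
        mu = flat[idx]
        t = _invert_bracketed(g, mu, _INVERSION_TOL, 1e8,
                              hi0=max(n0 * mu, hi_hint), lo=lo, deriv=deriv)
        out[idx] = t
        lo = t
        hi_hint = max(hi_hint, t)
    return out.reshape(taus.shape)


def sample_genealogy_times(model: DemographyModel, n: int,
                           rng: np.random.Generator) -> np.ndarray:
    """One replicate of coalescence times T_m (generations), m = 1..n-1.

    Strictly decreasing in m: T_1 (the TMRCA) is largest.
    """
    if int(n) != n or n < 2:
        raise ValidationError(f"n must be an integer >= 2, got {n!r}")
    epochs = _scaled_epochs(int(n), 1, rng)[0]
    taus = np.cumsum(epochs)  # tau_{n-1}, ..., tau_1 (ascending)
    times = _invert_many(model, taus)
    return times[::-1]


def estimate_afs_mc(model: DemographyModel, n: int, mutation_rate: float,
                    reps: int, seed: int) -> McEstimate:
    """Seeded MC estimate of coalescence times and the expected AFS."""
    if int(n) != n or n < 2:
        raise ValidationError(f"n must be an integer >= 2, got {n!r}")
    if int(reps) != reps or reps < 1:
        raise ValidationError(f"reps must be an integer >= 1, got {reps!r}")
    n, reps = int(n), int(reps)
    rng = np.random.default_rng(seed)

    epochs = _scaled_epochs(n, reps, rng)
    taus = np.cumsum(epochs, axis=1)          # columns: tau_{n-1} .. tau_1
    times = _invert_many(model, taus)         # same layout, generations
    T = times[:, ::-1]                        # columns: T_1 .. T_{n-1}

    # W_k = T_{k-1} - T_k with T_n = 0; columns k = 2..n
    W = T - np.concatenate([T[:, 1:], np.zeros((reps, 1))], axis=1)
    counts = W @ _branch_weight_matrix(n, float(mutation_rate)).T

    def summarize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mean = x.mean(axis=0)
        if reps == 1:
            return mean, np.full_like(mean, np.nan)
        se = x.std(axis=0, ddof=1) / np.sqrt(reps)
        return mean, se

    mean_T, se_T = summarize(T)
    mean_counts, se_counts = summarize(counts)
    return McEstimate(n=n, reps=reps, seed=int(seed),
                      mean_T=mean_T, se_T=se_T,
                      mean_counts=mean_counts, se_counts=se_counts)
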