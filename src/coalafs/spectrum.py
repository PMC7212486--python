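"""Expected allele frequency spectrum from intercoalescence times.

Under the infinitely-many-sites model, mutations on a branch of "size k"
(one of the k branches present during W_k) are Poisson with mean
mu * E[W_k], and each such mutation is carried by j of the n sampled
haplotypes with probability

    p_{n,k}(j) = C(n-j-1, k-2) / C(n-1, k-1),

so the expected number of sites at derived-allele count j is

    E[S_j] = sum_{k=2}^{n} p_{n,k}(j) * mu * k * E[W_k],   1 <= j <= n-1.

An algebraically equivalent form pulls the factorial front factor
(n-j-1)!(j-1)!/(n-1)! out of the sum; its coefficients grow explosively
with n and overflow double precision for large samples.  This module
therefore always evaluates term-by-term with log-gamma binomials, which
remains accurate for n in the thousands.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln

from .errors import DegenerateSpectrumError, ValidationError


@dataclass(frozen=True)
class FrequencySpectrum:
    """Expected AFS: counts E[S_j] for j = 1..n-1 and their proportions.

    ``mutation_rate`` is per locus per generation; for per-site rates
    multiply by the locus length upstream.  ``proportions`` is the
    mutation-rate-free spectrum counts / sum(counts) (all-NaN when the
    counts are identically zero).
    """

    n: int
    mutation_rate: float
    counts: np.ndarray
    proportions: np.ndarray


def _log_binom(a, b):
    """log C(a, b) elementwise, valid for 0 <= b <= a."""
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


def lineage_frequency_prob(n: int, k: int, j: int) -> float:
    """P(a mutation on a size-k branch is carried by j of n haplotypes).

    C(n-j-1, k-2) / C(n-1, k-1), exactly 0 when j > n-k+1 (a branch among
    k ancestors cannot subtend more than n-k+1 leaves).
    """
    if int(n) != n or n < 2:
        raise ValidationError(f"n must be an integer >= 2, got {n!r}")
    if not (2 <= k <= n):
        raise ValidationError(f"k must satisfy 2 <= k <= n, got k={k}, n={n}")
    if not (1 <= j <= n - 1):
        raise ValidationError(f"j must satisfy 1 <= j <= n-1, got j={j}, n={n}")
    if n - j - 1 < k - 2:
        return 0.0
    return float(np.exp(_log_binom(n - j - 1, k - 2) - _log_binom(n - 1, k - 1)))


def _branch_weight_matrix(n: int, mutation_rate: float) -> np.ndarray:
    """M[j-1, k-2] = p_{n,k}(j) * mu * k, so counts = M @ EW."""
    j = np.arange(1, n, dtype=float)[:, None]
    k = np.arange(2, n + 1, dtype=float)[None, :]
    valid = (n - j - 1.0) >= (k - 2.0)
    logp = np.where(
        valid,
        _log_binom(np.maximum(n - j - 1.0, k - 2.0), k - 2.0)
        - _log_binom(float(n - 1), k - 1.0),
        -np.inf)
    with np.errstate(under="ignore"):
        p = np.where(valid, np.exp(logp), 0.0)
    return p * mutation_rate * k


def expected_spectrum(EW: np.ndarray, n: int,
                      mutation_rate: float) -> FrequencySpectrum:
    """Assemble E[S_j], j = 1..n-1, from E[W_k], k = 2..n."""
    if int(n) != n or n < 2:
        raise ValidationError(f"n must be an integer >= 2, got {n!r}")
    if mutation_rate < 0:
        raise ValidationError(f"mutation_rate must be >= 0, got {mutation_rate}")
    ew = np.asarray(EW, dtype=float)
    if ew.shape != (n - 1,):
        raise ValidationError(
            f"EW must have length n-1 = {n - 1} (k = 2..n), got {ew.shape}")
    if np.any(ew < 0) or not np.all(np.isfinite(ew)):
        raise ValidationError("EW entries must be finite and >= 0")
    counts = _branch_weight_matrix(int(n), float(mutation_rate)) @ ew
    total = counts.sum()
    if total > 0:
        proportions = counts / total
    else:
        proportions = np.full_like(counts, np.nan)
    return FrequencySpectrum(n=int(n), mutation_rate=float(mutation_rate),
                             counts=counts, proportions=proportions)


def normalize_spectrum(spec: FrequencySpectrum) -> FrequencySpectrum:
    """Return a copy with proportions = counts / sum(counts).

    Raises :class:`DegenerateSpectrumError` when the counts are all zero.
    """
    total = spec.counts.sum()
    if not (total > 0):
        raise DegenerateSpectrumError(
            "cannot normalize an all-zero spectrum (mutation_rate or tree "
            "length is zero)")
    return replace(spec, proportions=spec.counts / total)
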