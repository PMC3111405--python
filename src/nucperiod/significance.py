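"""Single-fragment confirmatory measures: Fisher g, chi-squared, SNR and CRB.

Three measures computable from one fragment (or its profile) complement the
resampling test in :mod:`nucperiod.bootstrap`:

* **g-statistic** — the ratio of the peak profile value to the profile sum,
  with Fisher's exact null distribution for the p-value.  The exact
  distribution is derived for periodogram ordinates of Gaussian white noise;
  applying the same ratio form to autocorrelation or Hybrid profiles keeps
  the statistic but makes the p-value an approximation (documented caveat).
* **Pearson chi-squared deviation** — treats perfect p-periodicity as the
  model: every occurrence of the symbol set should be followed, p positions
  later, by another occurrence.  The observed p-spaced match/mismatch counts
  are compared against that model; the deviation is zero exactly when the
  empirical p-spaced pmf equals the perfect model, and the p-value comes
  from the chi-square distribution with one degree of freedom.  The set of
  k-mers is lumped as a single 'symbol'.
* **Cramér-Rao bound** — a lower bound on the variance of a sinusoidal
  period estimate, ``var(p_hat) >= 3 p^4 / (pi^2 * SNR * N (N^2 - 1))``,
  obtained from the classical sinusoid-frequency bound
  ``var(omega_hat) >= 12 / (SNR * N (N^2 - 1))`` via ``omega = 2 pi / p``.
  It is a strength measure, not a test: it falls as the signal-to-noise
  ratio rises and grows steeply (as p^4) with the period, reflecting the
  Fourier period-resolution limit.  The SNR is estimated from the DFT (not
  the IPDFT, whose components are not orthogonal, so Parseval does not
  apply): the energy in the harmonic bins of the candidate period over the
  remaining non-DC spectral energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import stats

from .estimators import PeriodicityProfile
from .seqs import IndicatorSequence, SymbolicFragment, SymbolSet, NPS_DINUCLEOTIDES, indicator

__all__ = [
    "GStatResult",
    "ChiSquaredResult",
    "CRBResult",
    "UndefinedStatisticError",
    "InapplicableTestError",
    "g_statistic",
    "fisher_g_pvalue",
    "chi_squared_test",
    "snr_estimate",
    "crb_bound",
]


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. all-zero profile)."""


class InapplicableTestError(ValueError):
    """A test has no qualifying observations on the given input."""


@dataclass(frozen=True)
class GStatResult:
    g: float
    n_components: int
    p_value: float
    method: str


@dataclass(frozen=True)
class ChiSquaredResult:
    deviation: float
    p_value: float
    period: int
    n_obs: int
    matches: int
    mismatches: int

    @property
    def empirical_pmf(self) -> tuple[float, float]:
        """(P(match), P(mismatch)) at spacing p, aggregated over occurrences."""
        return (self.matches / self.n_obs, self.mismatches / self.n_obs)


@dataclass(frozen=True)
class CRBResult:
    snr_hat: float
    bound: float
    p: int
    N: int


def fisher_g_pvalue(g_obs: float, n: int) -> float:
    """Exact upper-tail probability of Fisher's g for n exponential ordinates.

    P(g > g_obs) = sum_{k=1}^{min(n, floor(1/g_obs))}
                   (-1)^(k-1) C(n, k) (1 - k g_obs)^(n-1).
    """
    if not (0.0 < g_obs <= 1.0):
        raise ValueError(f"g must lie in (0, 1], got {g_obs}")
    if n < 1:
        raise ValueError("need at least one component")
    kmax = min(n, int(math.floor(1.0 / g_obs)))
    total = 0.0
    for k in range(1, kmax + 1):
        base = 1.0 - k * g_obs
        if base < 0.0:  # floor(1/g) edge with float round-off
            base = 0.0
        total += (-1.0) ** (k - 1) * math.comb(n, k) * base ** (n - 1)
    return float(min(max(total, 0.0), 1.0))


def g_statistic(profile: PeriodicityProfile) -> GStatResult:
    """Peak-to-sum ratio of a profile with Fisher's exact p-value.

    Assumes the non-dominant components behave as Gaussian-noise periodogram
    ordinates; exact for DFT/IPDFT-style profiles, approximate otherwise.
    """
    total = float(profile.values.sum())
    if total <= 0.0:
        raise UndefinedStatisticError("g-statistic undefined for an all-zero profile")
    g = float(profile.values.max()) / total
    n = int(profile.values.size)
    return GStatResult(g=g, n_components=n, p_value=fisher_g_pvalue(g, n), method=profile.method)


def chi_squared_test(
    source: Union[SymbolicFragment, IndicatorSequence],
    symbol_set: Optional[SymbolSet] = None,
    p: int = 10,
) -> ChiSquaredResult:
    """Pearson deviation of p-spaced matches from the perfect-periodicity model.

    For every occurrence at position n whose look-ahead n + p can still host
    a k-mer, record whether an occurrence follows at n + p.  Under perfect
    p-periodicity every look-ahead matches; the expected counts are
    (n_obs, 0).  The zero-expectation mismatch cell is floored at
    eps = 1/(2 n_obs) in the denominator (continuity-style regularization),
    so the deviation is exactly 0 for a perfect fragment and finite
    otherwise.
    """
    if isinstance(source, SymbolicFragment):
        sset = symbol_set if symbol_set is not None else NPS_DINUCLEOTIDES
        x = indicator(source, sset).values
        k = sset.k
    else:
        x = source.values
        k = 1
    N = x.size
    # occurrences whose p-spaced look-ahead can host a k-mer
    last_start = N - k
    ns = np.flatnonzero(x[: max(last_start - p + 1, 0)])
    n_obs = int(ns.size)
    if n_obs == 0:
        raise InapplicableTestError(f"no occurrence with a look-ahead of {p} inside bounds")
    matches = int(x[ns + p].sum())
    mismatches = n_obs - matches
    eps = 1.0 / (2.0 * n_obs)
    deviation = (matches - n_obs) ** 2 / n_obs + mismatches**2 / (n_obs * eps)
    p_value = float(stats.chi2.sf(deviation, df=1))
    return ChiSquaredResult(
        deviation=float(deviation),
        p_value=p_value,
        period=p,
        n_obs=n_obs,
        matches=matches,
        mismatches=mismatches,
    )


def snr_estimate(x: Union[IndicatorSequence, np.ndarray], p: int, rtol: float = 1e-9) -> float:
    """DFT-based signal-to-noise ratio of the period-p component.

    Periodic-component energy is the summed ``|X[k]|^2`` over the harmonic
    bins (integer k nearest each multiple m*N/p, m = 1..p-1, deduplicated,
    DC excluded); residual energy is the remaining non-DC spectral energy.
    Returns ``inf`` when the residual is numerically zero (perfectly
    periodic input).
    """
    if p < 2:
        raise ValueError(f"need p >= 2, got {p}")
    v = x.values.astype(float) if isinstance(x, IndicatorSequence) else np.asarray(x, dtype=float)
    N = v.size
    if N < p:
        raise ValueError(f"need N >= p, got N={N}, p={p}")
    X = np.fft.fft(v)
    energy = np.abs(X) ** 2
    total = float(energy[1:].sum())
    if total <= 0.0:
        raise UndefinedStatisticError("SNR undefined for a zero-energy (constant) sequence")
    harmonics = sorted({int(round(m * N / p)) for m in range(1, p)} - {0, N})
    periodic = float(energy[harmonics].sum())
    residual = total - periodic
    if residual <= rtol * total:
        return math.inf
    return periodic / residual


def crb_bound(snr_hat: float, p: int, N: int) -> CRBResult:
    """Cramér-Rao lower bound on the variance of the period estimate.

    ``bound = 3 p^4 / (pi^2 * snr * N (N^2 - 1))`` (units: period squared).
    An infinite SNR maps to bound 0.
    """
    if N < 3:
        raise ValueError(f"need N >= 3, got {N}")
    if not snr_hat > 0.0:
        raise ValueError(f"need snr_hat > 0, got {snr_hat}")
    if math.isinf(snr_hat):
        bound = 0.0
    else:
        bound = 3.0 * p**4 / (math.pi**2 * snr_hat * N * (N**2 - 1))
    return CRBResult(snr_hat=float(snr_hat), bound=float(bound), p=int(p), N=int(N))
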