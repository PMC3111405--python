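"""Exploratory period estimation: periodicity profiles and the dominant period.

Four estimators are provided, all evaluated by direct summation over a small
integer period range (default 2..20, cheap enough that no FFT is needed and
the IPDFT avoids any DFT-grid mismatch):

* DFT magnitude ``|X[k]|`` with ``X[k] = sum_n x[n] exp(-2j pi k n / N)``,
  reported only at integer frequency indices ``k`` whose period ``N/k`` falls
  in the requested range.  DFT periods depend on ``N``; the profile keeps the
  raw fractional period and bins the dominant period by rounding.
* IPDFT magnitude ``|X_IP[p]|`` with ``X_IP[p] = sum_n x[n] exp(-2j pi n / p)``
  at every integer period ``p``.  Its components are *not* mutually
  orthogonal.
* Finite-window sample autocorrelation
  ``r_xx[p] = sum_{n=0}^{N-1-p} x[n] x[n+p]`` (unnormalized; its decay with
  ``p`` is intentional and is what the Hybrid relies on).
* Hybrid: the per-period product ``H[p] = r_xx[p] * |X_IP[p]|``, combining
  the complementary failure modes of the two factors (autocorrelation
  suppresses the Fourier sub-multiple harmonics at divisors of the true
  period, the IPDFT factor suppresses the autocorrelation's multiple-period
  aliases).

The dominant period is the argmax of the profile.  Exact magnitude ties occur
structurally: a perfect period-p impulse train has equal Fourier magnitude at
p and at every divisor of p (harmonics), so ties (detected with relative
tolerance 1e-9) are broken toward the *largest* tied period, which recovers
the fundamental.  An all-zero profile has no dominant period (None).

The Fourier resolution limit means adjacent integer periods beyond roughly
sqrt(N) cannot be resolved; for fragment work p_max defaults to 20 at N=150.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .seqs import IndicatorSequence

__all__ = [
    "PeriodRange",
    "PeriodicityProfile",
    "dft_profile",
    "ipdft_profile",
    "autocorr_profile",
    "hybrid_profile",
    "profile",
    "dominant_period",
    "METHODS",
]

METHODS = ("dft", "ipdft", "autocorr", "hybrid")

#: Relative tolerance used to declare two profile values tied at the maximum.
TIE_RTOL = 1e-9


@dataclass(frozen=True)
class PeriodRange:
    """Closed integer period range [p_min, p_max] to evaluate."""

    p_min: int = 2
    p_max: int = 20

    def __post_init__(self) -> None:
        if not (2 <= self.p_min <= self.p_max):
            raise ValueError(f"need 2 <= p_min <= p_max, got {self}")

    @property
    def periods(self) -> np.ndarray:
        return np.arange(self.p_min, self.p_max + 1)


@dataclass
class PeriodicityProfile:
    """Per-period strength values S[p] from one estimator."""

    method: str
    periods: np.ndarray  # integer (binned) periods, one per value
    values: np.ndarray  # nonnegative strengths
    N: int
    raw_periods: Optional[np.ndarray] = None  # fractional N/k periods (DFT only)

    @property
    def dominant(self) -> Optional[int]:
        return dominant_period(self)

    def value_at(self, p: int) -> float:
        idx = np.flatnonzero(self.periods == p)
        if idx.size == 0:
            raise KeyError(f"period {p} not in profile range")
        return float(self.values[idx].max())


def _as_values(x: Union[IndicatorSequence, np.ndarray]) -> np.ndarray:
    if isinstance(x, IndicatorSequence):
        return x.values.astype(float)
    return np.asarray(x, dtype=float)


def dominant_period(profile: PeriodicityProfile) -> Optional[int]:
    """Argmax period of a profile; None when the profile is all zero.

    Values within a relative tolerance of the maximum count as tied, and the
    largest tied period wins (harmonic ties sit at divisors of the true
    period, so the fundamental is the largest member of the tie).
    """
    if profile.values.size == 0:
        raise ValueError("empty profile")
    vmax = float(profile.values.max())
    if vmax <= 0.0:
        return None
    tied = profile.periods[profile.values >= vmax * (1.0 - TIE_RTOL)]
    return int(tied.max())


def _ipdft_matrix(N: int, periods: np.ndarray) -> np.ndarray:
    n = np.arange(N)
    return np.exp(-2j * np.pi * n[None, :] / periods[:, None].astype(float))


def dft_profile(x, prange: PeriodRange = PeriodRange()) -> PeriodicityProfile:
    """DFT magnitude profile over integer frequency indices with N/k in range."""
    v = _as_values(x)
    N = v.size
    if N < 2 * prange.p_min:
        raise ValueError(f"need N >= 2*p_min, got N={N}")
    k_lo = int(np.ceil(N / prange.p_max))
    k_hi = int(np.floor(N / prange.p_min))
    ks = np.arange(max(k_lo, 1), k_hi + 1)
    n = np.arange(N)
    phasors = np.exp(-2j * np.pi * ks[:, None] * n[None, :] / N)
    values = np.abs(phasors @ v)
    raw = N / ks
    periods = np.rint(raw).astype(int)
    return PeriodicityProfile("dft", periods=periods, values=values, N=N, raw_periods=raw)


def ipdft_profile(x, prange: PeriodRange = PeriodRange()) -> PeriodicityProfile:
    """Integer-period DFT magnitude profile |X_IP[p]| for p in range."""
    v = _as_values(x)
    N = v.size
    if N < 2 * prange.p_min:
        raise ValueError(f"need N >= 2*p_min, got N={N}")
    periods = prange.periods
    values = np.abs(_ipdft_matrix(N, periods) @ v)
    return PeriodicityProfile("ipdft", periods=periods, values=values, N=N)


def autocorr_profile(x, prange: PeriodRange = PeriodRange()) -> PeriodicityProfile:
    """Finite-window sample autocorrelation r_xx[p] for p in range (lag 0 excluded)."""
    v = _as_values(x)
    N = v.size
    if prange.p_max >= N:
        raise ValueError(f"need p_max < N, got p_max={prange.p_max}, N={N}")
    periods = prange.periods
    values = np.array([float(v[: N - p] @ v[p:]) for p in periods])
    return PeriodicityProfile("autocorr", periods=periods, values=values, N=N)


def hybrid_profile(x, prange: PeriodRange = PeriodRange()) -> PeriodicityProfile:
    """Hybrid autocorrelation-IPDFT profile H[p] = r_xx[p] * |X_IP[p]|."""
    ac = autocorr_profile(x, prange)
    ip = ipdft_profile(x, prange)
    return PeriodicityProfile("hybrid", periods=prange.periods, values=ac.values * ip.values, N=ac.N)


_PROFILE_FNS = {
    "dft": dft_profile,
    "ipdft": ipdft_profile,
    "autocorr": autocorr_profile,
    "hybrid": hybrid_profile,
}


def profile(x, method: str, prange: PeriodRange = PeriodRange()) -> PeriodicityProfile:
    """Dispatch to one of the four estimators by name."""
    try:
        fn = _PROFILE_FNS[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}") from None
    return fn(x, prange)


# --- single-period statistics -------------------------------------------------
#
# The blockwise bootstrap only needs the embedded metric's value at one tested
# period for each of R resamples; these vectorized helpers evaluate that value
# for a whole (R, N) matrix of 0/1 rows at once.


def stat_matrix(X: np.ndarray, method: str, p: int) -> np.ndarray:
    """Embedded-metric value at period ``p`` for each row of a 0/1 matrix."""
    X = np.asarray(X, dtype=float)
    N = X.shape[1]
    if method == "ipdft":
        phasor = np.exp(-2j * np.pi * np.arange(N) / p)
        return np.abs(X @ phasor)
    if method == "autocorr":
        return (X[:, : N - p] * X[:, p:]).sum(axis=1)
    if method == "hybrid":
        return stat_matrix(X, "autocorr", p) * stat_matrix(X, "ipdft", p)
    if method == "dft":
        k = max(int(round(N / p)), 1)
        phasor = np.exp(-2j * np.pi * k * np.arange(N) / N)
        return np.abs(X @ phasor)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def stat_at(x, method: str, p: int) -> float:
    """Embedded-metric value at period ``p`` for a single indicator."""
    return float(stat_matrix(_as_values(x)[None, :], method, p)[0])


def dominant_of_matrix(X: np.ndarray, method: str, prange: PeriodRange = PeriodRange()) -> np.ndarray:
    """Vectorized dominant period per row; 0 encodes 'no periodicity'.

    Only the integer-period estimators (ipdft, autocorr, hybrid) are
    supported here; the DFT's rounded-period binning goes through
    :func:`dft_profile` row by row.
    """
    X = np.asarray(X, dtype=float)
    N = X.shape[1]
    periods = prange.periods
    if method == "ipdft":
        V = np.abs(X @ _ipdft_matrix(N, periods).T)
    elif method == "autocorr":
        V = np.stack([(X[:, : N - p] * X[:, p:]).sum(axis=1) for p in periods], axis=1)
    elif method == "hybrid":
        V = np.abs(X @ _ipdft_matrix(N, periods).T) * np.stack(
            [(X[:, : N - p] * X[:, p:]).sum(axis=1) for p in periods], axis=1
        )
    else:
        raise ValueError(f"vectorized dominant period not available for {method!r}")
    vmax = V.max(axis=1)
    tied = V >= vmax[:, None] * (1.0 - TIE_RTOL)
    # largest tied period: scan periods in descending order
    idx = tied.shape[1] - 1 - np.argmax(tied[:, ::-1], axis=1)
    out = periods[idx]
    return np.where(vmax > 0.0, out, 0)
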