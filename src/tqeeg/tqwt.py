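"""Tunable-Q wavelet transform (TQWT).

The TQWT is a discrete, perfectly reconstructing, oversampled wavelet
transform for oscillatory signals.  It is controlled by three parameters:

``Q``
    quality factor (center frequency / bandwidth of the wavelet); higher Q
    means a more oscillatory wavelet, suited to rhythmic signals such as EEG.
``r``
    redundancy (oversampling) rate; it widens the transition bands of the
    two-channel filter bank, controlling ringing, without changing the
    wavelet shape.
``J``
    number of decomposition levels; a J-level decomposition yields J
    highpass subbands plus one lowpass residual.

The low- and highpass scaling factors follow from Q and r::

    beta = 2 / (Q + 1),        alpha = 1 - beta / r

with the perfect-reconstruction constraints ``0 < alpha < 1``,
``0 < beta <= 1`` and ``alpha + beta > 1``.

The filter bank is realized directly in the DFT domain: at each level the
unitary spectrum of the current lowpass signal is partitioned into a
shorter lowpass spectrum (length ``~alpha*N``) and a highpass subband
spectrum (length ``~beta*N``), with a Daubechies-type power-complementary
transition function

    theta(w) = 0.5 * (1 + cos w) * sqrt(2 - cos w),   w in [0, pi]

on the shared transition band.  Because ``theta(w)^2 + theta(pi-w)^2 = 1``
and the unitary DFT preserves energy, the transform is a tight frame:
subband energies sum exactly to the input energy and reconstruction is
exact to rounding error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TQWTParams",
    "SubbandSet",
    "FrequencyResponse",
    "derive_filter_params",
    "max_levels",
    "decompose",
    "reconstruct",
    "subband_frequency_range",
    "frequency_response",
    "write_subbands",
    "read_subbands",
]


def derive_filter_params(Q: float, r: float) -> tuple[float, float]:
    """Derive the lowpass/highpass scaling factors (alpha, beta) from (Q, r).

    Inverts ``Q = (2 - beta)/beta`` and applies ``alpha = 1 - beta/r``.

    Raises
    ------
    ValueError
        If ``Q < 1`` or ``r <= 1`` (the perfect-reconstruction condition
        ``alpha + beta > 1`` with ``0 < alpha < 1`` would be violated).
    """
    if Q < 1:
        raise ValueError(f"quality factor Q must be >= 1, got {Q}")
    if r <= 1:
        raise ValueError(f"redundancy r must be > 1, got {r}")
    beta = 2.0 / (Q + 1.0)
    alpha = 1.0 - beta / r
    return alpha, beta


def max_levels(n_samples: int, alpha: float, beta: float) -> int:
    """Maximum decomposition depth ``floor(log(beta*N/8) / log(1/alpha))``.

    Deeper decompositions would shrink the lowpass signal below the minimum
    length the filter-bank partition supports.
    """
    arg = beta * n_samples / 8.0
    if arg < 1.0:
        raise ValueError(
            f"signal too short for any decomposition level: need "
            f"N >= {8.0 / beta:.1f} samples for beta={beta:.4g}, got {n_samples}"
        )
    return int(math.floor(math.log(arg) / math.log(1.0 / alpha)))


@dataclass(frozen=True)
class TQWTParams:
    """Transform parameters (Q, r, J) with derived scaling factors.

    ``alpha`` and ``beta`` are computed from Q and r at construction; the
    perfect-reconstruction constraints are enforced.
    """

    Q: float
    r: float
    J: int
    alpha: float = field(init=False)
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        alpha, beta = derive_filter_params(self.Q, self.r)
        if self.J < 1 or int(self.J) != self.J:
            raise ValueError(f"J must be a positive integer, got {self.J}")
        if not (0.0 < alpha < 1.0 and 0.0 < beta <= 1.0 and alpha + beta > 1.0):
            raise ValueError(
                f"scaling factors alpha={alpha}, beta={beta} violate the "
                "perfect-reconstruction constraints"
            )
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)

    def max_levels(self, n_samples: int) -> int:
        return max_levels(n_samples, self.alpha, self.beta)


@dataclass
class SubbandSet:
    """The J+1 coefficient sequences of a J-level decomposition.

    ``subbands[0] .. subbands[J-1]`` are the highpass subbands from level 1
    (highest frequencies) to level J; ``subbands[J]`` is the lowpass
    residual.  ``original_length`` is the sample count of the analyzed
    signal before any internal zero padding.
    """

    subbands: list[np.ndarray]
    params: TQWTParams
    original_length: int
    fs: float | None = None

    def __len__(self) -> int:
        return len(self.subbands)

    @property
    def energies(self) -> np.ndarray:
        """Per-subband energies (sum of squared coefficients)."""
        return np.array([float(np.sum(np.square(s))) for s in self.subbands])


@dataclass
class FrequencyResponse:
    """Magnitude response sampled on a normalized radian-frequency grid."""

    omega_grid: np.ndarray
    magnitude: np.ndarray


# ---------------------------------------------------------------------------
# frequency-domain two-channel filter bank


def _theta(v: np.ndarray) -> np.ndarray:
    """Daubechies-type power-complementary transition function on [0, pi]."""
    c = np.cos(v)
    return 0.5 * (1.0 + c) * np.sqrt(2.0 - c)


def _stage_lengths(n: int, alpha: float, beta: float) -> tuple[int, int]:
    """(lowpass, highpass) output lengths for one filter-bank stage.

    Lengths are rounded to the nearest even integer so every stage operates
    on an even-length spectrum; this rule makes decompositions
    bit-reproducible.
    """
    n0 = 2 * int(round(alpha * n / 2.0))
    n1 = 2 * int(round(beta * n / 2.0))
    return n0, n1


def _length_chain(n_padded: int, params: TQWTParams) -> list[tuple[int, int, int]]:
    """Per-level (parent, lowpass, highpass) lengths for the full cascade."""
    chain = []
    n = n_padded
    for _ in range(params.J):
        n0, n1 = _stage_lengths(n, params.alpha, params.beta)
        t = (n0 + n1 - n) // 2 - 1
        if n0 < 4 or n1 < 2 or t < 0:
            raise ValueError(
                "filter-bank partition degenerate at this depth; "
                "decrease J (see max_levels)"
            )
        chain.append((n, n0, n1))
        n = n0
    return chain


def _afb(X: np.ndarray, n0: int, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Analysis filter bank: split spectrum X into lowpass/highpass spectra."""
    n = X.shape[0]
    p = (n - n1) // 2            # last fully passed lowpass bin
    t = (n0 + n1 - n) // 2 - 1   # transition bins

    v = np.arange(1, t + 1) * (np.pi / (t + 1))
    lp_gain = _theta(v)
    hp_gain = lp_gain[::-1]      # theta(pi - v): power complement

    V0 = np.zeros(n0, dtype=complex)
    V0[: p + 1] = X[: p + 1]
    V0[p + 1 : p + 1 + t] = X[p + 1 : p + 1 + t] * lp_gain
    # bin n0//2 (the lowpass Nyquist) stays zero
    V0[n0 // 2 + 1 :] = np.conj(V0[1 : n0 // 2][::-1])

    V1 = np.zeros(n1, dtype=complex)
    V1[1 : t + 1] = X[p + 1 : p + 1 + t] * hp_gain
    V1[t + 1 : n1 // 2 + 1] = X[p + t + 1 : n // 2 + 1]
    V1[n1 // 2 + 1 :] = np.conj(V1[1 : n1 // 2][::-1])
    return V0, V1


def _sfb(V0: np.ndarray, V1: np.ndarray, n: int) -> np.ndarray:
    """Synthesis filter bank: merge lowpass/highpass spectra back to length n."""
    n0, n1 = V0.shape[0], V1.shape[0]
    p = (n - n1) // 2
    t = (n0 + n1 - n) // 2 - 1

    v = np.arange(1, t + 1) * (np.pi / (t + 1))
    lp_gain = _theta(v)
    hp_gain = lp_gain[::-1]

    Y = np.zeros(n, dtype=complex)
    Y[: p + 1] = V0[: p + 1]
    Y[p + 1 : p + 1 + t] = V0[p + 1 : p + 1 + t] * lp_gain + V1[1 : t + 1] * hp_gain
    Y[p + t + 1 : n // 2 + 1] = V1[t + 1 : n1 // 2 + 1]
    Y[n // 2 + 1 :] = np.conj(Y[1 : n // 2][::-1])
    return Y


def decompose(x: np.ndarray, params: TQWTParams, fs: float | None = None) -> SubbandSet:
    """Decompose a real signal into J highpass subbands plus a lowpass residual.

    Odd-length inputs are zero padded to even length internally; the pad is
    trimmed again by :func:`reconstruct` (``original_length`` records the
    true length).  The unitary DFT convention is used throughout, so the
    subband energies sum exactly to the input energy (tight frame).
    """
    x = np.asarray(x)
    if np.iscomplexobj(x):
        raise ValueError("complex input rejected: the transform is defined for real signals")
    x = x.astype(float, copy=False)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D signal, got shape {x.shape}")
    if x.shape[0] < 4:
        raise ValueError(f"signal too short: need at least 4 samples, got {x.shape[0]}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")

    n_orig = x.shape[0]
    if n_orig % 2:
        x = np.concatenate([x, [0.0]])
    n = x.shape[0]

    jmax = params.max_levels(n)
    if params.J > jmax:
        raise ValueError(
            f"decomposition depth J={params.J} exceeds the maximum "
            f"J_max={jmax} for a {n}-sample signal"
        )

    chain = _length_chain(n, params)
    X = np.fft.fft(x) / math.sqrt(n)
    subbands: list[np.ndarray] = []
    for _, n0, n1 in chain:
        X, V1 = _afb(X, n0, n1)
        subbands.append(np.real(np.fft.ifft(V1) * math.sqrt(n1)))
    subbands.append(np.real(np.fft.ifft(X) * math.sqrt(len(X))))
    return SubbandSet(subbands=subbands, params=params, original_length=n_orig, fs=fs)


def reconstruct(sb: SubbandSet) -> np.ndarray:
    """Invert :func:`decompose`; exact to rounding error (tight frame)."""
    params = sb.params
    if len(sb.subbands) != params.J + 1:
        raise ValueError(
            f"expected {params.J + 1} subbands for J={params.J}, got {len(sb.subbands)}"
        )
    n_padded = sb.original_length + (sb.original_length % 2)
    chain = _length_chain(n_padded, params)
    for (_, n0, n1), band in zip(chain, sb.subbands):
        if band.shape[0] != n1:
            raise ValueError(
                f"subband length {band.shape[0]} inconsistent with expected {n1} "
                "for these parameters"
            )
    if sb.subbands[-1].shape[0] != chain[-1][1]:
        raise ValueError(
            f"lowpass length {sb.subbands[-1].shape[0]} inconsistent with "
            f"expected {chain[-1][1]}"
        )

    low = sb.subbands[-1]
    X = np.fft.fft(low) / math.sqrt(len(low))
    for (n, _, n1), band in zip(reversed(chain), reversed(sb.subbands[:-1])):
        V1 = np.fft.fft(band) / math.sqrt(n1)
        X = _sfb(X, V1, n)
    y = np.real(np.fft.ifft(X) * math.sqrt(n_padded))
    return y[: sb.original_length]


def subband_frequency_range(
    params: TQWTParams, level: int, fs: float
) -> tuple[float, float]:
    """Nominal passband of a subband in Hz.

    Levels ``1..J`` are the highpass subbands, covering
    ``[(1-beta) * alpha^(j-1) * fs/2, alpha^(j-1) * fs/2]``; level ``J+1``
    denotes the lowpass residual, covering ``[0, alpha^J * fs/2]``.
    """
    if not 1 <= level <= params.J + 1:
        raise IndexError(f"level must be in 1..{params.J + 1}, got {level}")
    nyq = fs / 2.0
    if level == params.J + 1:
        return 0.0, params.alpha**params.J * nyq
    hi = params.alpha ** (level - 1) * nyq
    lo = (1.0 - params.beta) * params.alpha ** (level - 1) * nyq
    return lo, hi


def _g0(omega: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Base lowpass magnitude response on [0, pi]."""
    w = np.abs(omega)
    lo, hi = (1.0 - beta) * np.pi, alpha * np.pi
    out = np.zeros_like(w)
    out[w <= lo] = 1.0
    band = (w > lo) & (w < hi)
    out[band] = _theta((w[band] - lo) / (alpha + beta - 1.0))
    return out


def _g1(omega: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Base highpass magnitude response on [0, pi]."""
    w = np.abs(omega)
    lo, hi = (1.0 - beta) * np.pi, alpha * np.pi
    out = np.zeros_like(w)
    out[w >= hi] = 1.0
    band = (w > lo) & (w < hi)
    out[band] = _theta((hi - w[band]) / (alpha + beta - 1.0))
    return out


def frequency_response(
    params: TQWTParams, level: int, n_points: int = 1024
) -> FrequencyResponse:
    """Equivalent magnitude response of one subband's cascade.

    For highpass level ``j`` this is ``G1(w/alpha^(j-1)) *
    prod_{m=0}^{j-2} G0(w/alpha^m)``; for the lowpass residual (level
    ``J+1``), ``prod_{m=0}^{J-1} G0(w/alpha^m)``.  Each lowpass stage
    compresses the frequency axis by alpha, hence the division when the
    cascade is referred back to the input axis; the level-j support is
    ``[(1-beta)*alpha^(j-1)*pi, alpha^(j-1)*pi]``.
    """
    if not 1 <= level <= params.J + 1:
        raise IndexError(f"level must be in 1..{params.J + 1}, got {level}")
    a, b = params.alpha, params.beta
    omega = np.linspace(0.0, np.pi, n_points)
    if level == params.J + 1:
        mag = np.ones_like(omega)
        for m in range(params.J):
            mag = mag * _g0(omega / a**m, a, b)
    else:
        mag = _g1(omega / a ** (level - 1), a, b)
        for m in range(level - 1):
            mag = mag * _g0(omega / a**m, a, b)
    return FrequencyResponse(omega_grid=omega, magnitude=mag)


# ---------------------------------------------------------------------------
# plain-text dump of a SubbandSet

def write_subbands(sb: SubbandSet, path) -> None:
    """Dump a SubbandSet as CSV: comment header, then one row per subband
    (level index, length, coefficients...)."""
    with open(path, "w") as fh:
        fs = "" if sb.fs is None else repr(sb.fs)
        fh.write(
            f"# tqwt subbands Q={sb.params.Q!r} r={sb.params.r!r} "
            f"J={sb.params.J} N={sb.original_length} fs={fs}\n"
        )
        fh.write("# columns: level,length,coefficients...\n")
        for j, band in enumerate(sb.subbands, start=1):
            coeffs = ",".join(repr(float(c)) for c in band)
            fh.write(f"{j},{len(band)},{coeffs}\n")


def read_subbands(path) -> SubbandSet:
    """Read a SubbandSet written by :func:`write_subbands`."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# tqwt subbands"):
            raise ValueError(f"{path}: not a tqwt subband dump")
        meta = dict(tok.split("=", 1) for tok in header.split()[3:])
        fh.readline()  # column comment
        bands = []
        for line in fh:
            parts = line.strip().split(",")
            level, length = int(parts[0]), int(parts[1])
            coeffs = np.array([float(v) for v in parts[2:]])
            if len(coeffs) != length:
                raise ValueError(f"{path}: subband {level} length mismatch")
            bands.append(coeffs)
    params = TQWTParams(Q=float(meta["Q"]), r=float(meta["r"]), J=int(meta["J"]))
    fs = float(meta["fs"]) if meta.get("fs") else None
    return SubbandSet(
        subbands=bands, params=params, original_length=int(meta["N"]), fs=fs
    )
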