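"""Per-subband feature extraction.

Eleven features are computed from each wavelet subband: mean, variance
(sample, N-1 denominator), skewness, kurtosis (non-excess: Gaussian -> 3),
energy (sum of squares), power (mean of squares), and five entropies —
Shannon, Tsallis (order q), approximate (ApEn), sample (SampEn) and fuzzy.

Histogram-based entropies (Shannon, Tsallis) estimate bin probabilities
with an equal-width histogram over [min(x), max(x)].  ApEn/SampEn use
Chebyshev distances between delay embeddings with tolerance
``tol_frac * SD(x)``; fuzzy entropy applies the binary (De Luca–Termini)
entropy to min-max-normalized memberships, scaled by the constant K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tqwt import TQWTParams, decompose

__all__ = [
    "FeatureConfig",
    "FEATURE_NAMES",
    "moment_features",
    "power",
    "energy",
    "shannon_entropy",
    "tsallis_entropy",
    "approximate_entropy",
    "sample_entropy",
    "fuzzy_entropy",
    "subband_features",
    "extract_features",
]

#: Canonical feature column order.
FEATURE_NAMES = (
    "mean",
    "kurtosis",
    "skewness",
    "energy",
    "power",
    "apen",
    "tsallis",
    "fuzzy",
    "sampen",
    "shannon",
    "variance",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable constants for the entropy estimators.

    q_tsallis : Tsallis order (q=2 reduces Tsallis entropy to 1 - sum p^2).
    K_fuzzy : multiplicative constant of the fuzzy entropy.
    m_embed : embedding dimension for ApEn/SampEn.
    tol_frac : ApEn/SampEn tolerance as a fraction of the subband SD.
    n_bins : histogram bins for Shannon/Tsallis probability estimates.
    eps_clip : clipping floor for memberships/probabilities.
    tsallis_verbatim : if True, sum p^(q-1) instead of p^q in the Tsallis
        sum (a non-standard normalization; the standard form is default).
    """

    q_tsallis: float = 2.0
    K_fuzzy: float = 2.0
    m_embed: int = 2
    tol_frac: float = 0.2
    n_bins: int = 16
    eps_clip: float = 1e-12
    tsallis_verbatim: bool = False

    def __post_init__(self) -> None:
        if self.q_tsallis == 1.0:
            raise ValueError("Tsallis order q must differ from 1")
        if self.m_embed < 1:
            raise ValueError("embedding dimension must be >= 1")
        if self.tol_frac <= 0:
            raise ValueError("tolerance fraction must be positive")
        if self.n_bins < 2:
            raise ValueError("need at least 2 histogram bins")


_DEFAULT = FeatureConfig()


def _as_signal(x, min_len: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_len:
        raise ValueError(f"sequence too short: need >= {min_len} samples, got {x.size}")
    return x


def moment_features(x) -> tuple[float, float, float, float]:
    """(mean, variance, skewness, kurtosis) of a coefficient sequence.

    Variance uses the N-1 denominator; skewness and kurtosis are the
    standardized third and fourth central moments (kurtosis non-excess, so
    a Gaussian gives 3).  A constant sequence returns skewness 0 and
    kurtosis 3 (division-by-zero guard).
    """
    x = _as_signal(x, 2)
    mu = float(np.mean(x))
    var = float(np.var(x, ddof=1))
    d = x - mu
    m2 = float(np.mean(d**2))
    if m2 == 0.0:
        return mu, var, 0.0, 3.0
    skew = float(np.mean(d**3)) / m2**1.5
    kurt = float(np.mean(d**4)) / m2**2
    return mu, var, skew, kurt


def power(x) -> float:
    """Mean of squares."""
    x = _as_signal(x, 1)
    return float(np.mean(np.square(x)))


def energy(x) -> float:
    """Sum of squares (``energy == N * power`` exactly)."""
    x = _as_signal(x, 1)
    return float(np.sum(np.square(x)))


def _histogram_probs(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width histogram probabilities over [min(x), max(x)]."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        return np.array([1.0])
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts / counts.sum()
    return p[p > 0]


def shannon_entropy(x, cfg: FeatureConfig = _DEFAULT) -> float:
    """Shannon entropy (natural log) of the histogram distribution."""
    x = _as_signal(x, 2)
    p = _histogram_probs(x, cfg.n_bins)
    return float(-np.sum(p * np.log(p)))


def tsallis_entropy(x, cfg: FeatureConfig = _DEFAULT) -> float:
    """Tsallis entropy ``(1 - sum p^q) / (q - 1)`` of the histogram
    distribution; with q=2 this is ``1 - sum p^2``.

    With ``cfg.tsallis_verbatim`` the exponent ``q-1`` is used in the sum
    instead of ``q`` (an alternative normalization occasionally seen; not
    the standard non-extensive form).
    """
    x = _as_signal(x, 2)
    p = _histogram_probs(x, cfg.n_bins)
    if p.size == 1:
        return 0.0
    q = cfg.q_tsallis
    expo = q - 1.0 if cfg.tsallis_verbatim else q
    return float((1.0 - np.sum(p**expo)) / (q - 1.0))


def _embedding_count_matrices(x: np.ndarray, m: int, r: float):
    """Chebyshev-distance match matrices for m- and (m+1)-embeddings.

    Returns boolean matrices ``(Dm <= r, Dm1 <= r)`` where ``Dm`` has shape
    (N-m+1, N-m+1) and ``Dm1`` shape (N-m, N-m).  Built incrementally from
    the pointwise |x_i - x_j| matrix via shifted maxima, so both embedding
    orders share one O(N^2) pass.
    """
    d1 = np.abs(x[:, None] - x[None, :])
    dm = d1
    for k in range(2, m + 1):
        dm = np.maximum(dm[:-1, :-1], d1[k - 1 :, k - 1 :])
    dm1 = np.maximum(dm[:-1, :-1], d1[m:, m:])
    return dm <= r, dm1 <= r


def approximate_entropy(x, cfg: FeatureConfig = _DEFAULT) -> float:
    """Approximate entropy ApEn(m, r, N), self-matches included.

    ``Phi(m)`` is the mean log of the fraction of m-embeddings within
    Chebyshev tolerance ``r = tol_frac * SD(x)`` of each template;
    ``ApEn = Phi(m) - Phi(m+1)`` — the log-ratio of m- to (m+1)-pattern
    match probabilities.
    """
    x = _as_signal(x)
    m = cfg.m_embed
    if x.size <= m + 1:
        raise ValueError(f"need more than {m + 1} samples for ApEn(m={m}), got {x.size}")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = cfg.tol_frac * sd
    match_m, match_m1 = _embedding_count_matrices(x, m, r)
    phi_m = float(np.mean(np.log(match_m.mean(axis=1))))
    phi_m1 = float(np.mean(np.log(match_m1.mean(axis=1))))
    return phi_m - phi_m1


def sample_entropy(x, cfg: FeatureConfig = _DEFAULT) -> float:
    """Sample entropy ``-ln(A/B)``, self-matches excluded.

    ``B`` counts m-embedding pairs (over the first N-m templates) within
    tolerance, ``A`` the (m+1)-embedding pairs.  If either count is zero
    the value is undefined and ``+inf`` is returned; table assembly caps it
    (see :func:`subband_features`).
    """
    x = _as_signal(x)
    m = cfg.m_embed
    if x.size <= m + 1:
        raise ValueError(f"need more than {m + 1} samples for SampEn(m={m}), got {x.size}")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = cfg.tol_frac * sd
    match_m, match_m1 = _embedding_count_matrices(x, m, r)
    nm = match_m1.shape[0]  # N - m templates for both orders
    b = int(match_m[:nm, :nm].sum()) - nm  # off-diagonal matches (twice each pair)
    a = int(match_m1.sum()) - nm
    if a == 0 or b == 0:
        return float("inf")
    return float(-np.log(a / b))


def _sampen_cap(n: int, m: int) -> float:
    """Finite stand-in for an undefined (zero-match) sample entropy: the
    log of the number of possible (m+1)-pattern pairs, ln((N-m)(N-m-1))."""
    return float(np.log(max((n - m) * (n - m - 1), 2)))


def fuzzy_entropy(x, cfg: FeatureConfig = _DEFAULT) -> float:
    """Fuzzy entropy ``-K * sum_i [m_i ln m_i + (1-m_i) ln(1-m_i)]``.

    Memberships ``m_i`` are the min-max normalization of x to [0, 1],
    clipped to ``[eps_clip, 1-eps_clip]``; a constant sequence yields ~0.
    """
    x = _as_signal(x, 2)
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        m = np.full(x.size, cfg.eps_clip)
    else:
        m = np.clip((x - lo) / (hi - lo), cfg.eps_clip, 1.0 - cfg.eps_clip)
    return float(-cfg.K_fuzzy * np.sum(m * np.log(m) + (1.0 - m) * np.log(1.0 - m)))


def subband_features(x, cfg: FeatureConfig = _DEFAULT) -> dict[str, float]:
    """All eleven features of one coefficient sequence, keyed by name.

    ApEn and SampEn share one distance-matrix pass.  An undefined SampEn
    (zero matches at either embedding order) is replaced by the documented
    finite cap ``ln((N-m)(N-m-1))`` so tables stay finite.
    """
    x = _as_signal(x, cfg.m_embed + 2)
    mu, var, skew, kurt = moment_features(x)
    en = energy(x)
    out = {
        "mean": mu,
        "kurtosis": kurt,
        "skewness": skew,
        "energy": en,
        "power": en / x.size,
        "tsallis": tsallis_entropy(x, cfg),
        "fuzzy": fuzzy_entropy(x, cfg),
        "shannon": shannon_entropy(x, cfg),
        "variance": var,
    }
    sd = float(np.std(x))
    if sd == 0.0:
        out["apen"] = 0.0
        out["sampen"] = 0.0
        return {k: out[k] for k in FEATURE_NAMES}
    m = cfg.m_embed
    r = cfg.tol_frac * sd
    match_m, match_m1 = _embedding_count_matrices(x, m, r)
    phi_m = float(np.mean(np.log(match_m.mean(axis=1))))
    phi_m1 = float(np.mean(np.log(match_m1.mean(axis=1))))
    out["apen"] = phi_m - phi_m1
    nm = match_m1.shape[0]
    b = int(match_m[:nm, :nm].sum()) - nm
    a = int(match_m1.sum()) - nm
    out["sampen"] = _sampen_cap(x.size, m) if (a == 0 or b == 0) else float(-np.log(a / b))
    return {k: out[k] for k in FEATURE_NAMES}


def extract_features(
    epochs,
    params: TQWTParams,
    cfg: FeatureConfig = _DEFAULT,
    labels=None,
    group: str | None = None,
    channel_mode: str = "mean",
) -> pd.DataFrame:
    """Decompose every epoch and assemble the epochs x (subband, feature) table.

    Parameters
    ----------
    epochs
        Array of shape (n_epochs, n_channels, n_samples) or an
        :class:`~tqeeg.data.EpochSet`.
    params
        Transform parameters shared by all epochs.
    labels, group
        Optional per-epoch class labels and cohort tag, attached as
        ``label`` / ``group`` columns (taken from the EpochSet if given).
    channel_mode
        ``"mean"`` (default): compute features per channel, then average
        across channels, giving ``(J+1) * 11`` columns named
        ``sb{j}_{feature}``.  ``"stack"``: keep per-channel columns
        ``ch{c}_sb{j}_{feature}``.
    """
    if hasattr(epochs, "labels") and hasattr(epochs, "data"):  # EpochSet duck-typing
        if labels is None:
            labels = epochs.labels
        if group is None:
            group = epochs.group
        epochs = epochs.data
    arr = np.asarray(epochs, dtype=float)
    if arr.ndim == 2:  # single-channel epochs
        arr = arr[:, None, :]
    if arr.ndim != 3:
        raise ValueError(
            f"epochs must have shape (n_epochs, n_channels, n_samples), got {arr.shape}"
        )
    if channel_mode not in ("mean", "stack"):
        raise ValueError(f"unknown channel_mode {channel_mode!r}")
    n_epochs, n_channels, _ = arr.shape
    n_sb = params.J + 1

    rows = []
    for e in range(n_epochs):
        per_channel = np.empty((n_channels, n_sb, len(FEATURE_NAMES)))
        for c in range(n_channels):
            sb = decompose(arr[e, c], params)
            for j, band in enumerate(sb.subbands):
                feats = subband_features(band, cfg)
                per_channel[c, j] = [feats[name] for name in FEATURE_NAMES]
        if channel_mode == "mean":
            rows.append(per_channel.mean(axis=0).ravel())
        else:
            rows.append(per_channel.ravel())

    if channel_mode == "mean":
        cols = [f"sb{j + 1}_{f}" for j in range(n_sb) for f in FEATURE_NAMES]
    else:
        cols = [
            f"ch{c + 1}_sb{j + 1}_{f}"
            for c in range(n_channels)
            for j in range(n_sb)
            for f in FEATURE_NAMES
        ]
    table = pd.DataFrame(np.asarray(rows), columns=cols)
    if not np.all(np.isfinite(table.to_numpy())):
        raise ValueError("feature table contains non-finite entries")
    if labels is not None:
        if len(labels) != n_epochs:
            raise ValueError("label count does not match epoch count")
        table["label"] = list(labels)
    if group is not None:
        table["group"] = group
    return table
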