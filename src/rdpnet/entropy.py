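"""Per-channel entropy descriptors of 1-D feature maps.

Differential entropy — the default statistical pathway of the fusion
module — operates directly on continuous feature values via the Gaussian
closed form on the unbiased temporal variance.  Four comparison
descriptors (Shannon, Rényi, spectral, Tsallis) are provided for the
entropy-type sensitivity study; the histogram-based ones discretize each
channel into equal-width bins over its own min–max range, and spectral
entropy applies the Shannon formula to the normalized periodogram with
the DC bin removed.

All entropies are reported in nats (natural logarithm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

ENTROPY_KINDS = ("differential", "shannon", "renyi", "spectral", "tsallis")


@dataclass(frozen=True)
class EntropySpec:
    """Configuration of the entropy descriptor used in feature fusion.

    Parameters
    ----------
    kind:
        One of ``differential``, ``shannon``, ``renyi``, ``spectral``,
        ``tsallis``.
    eps:
        Stability constant added to the variance inside the differential
        entropy logarithm.
    n_bins:
        Number of equal-width histogram bins for the discretizing kinds.
    order:
        Rényi order alpha, or Tsallis index q (must be positive and != 1).
    """

    kind: str = "differential"
    eps: float = 1e-6
    n_bins: int = 16
    order: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ENTROPY_KINDS:
            raise ValueError(
                f"unknown entropy kind {self.kind!r}; expected one of {ENTROPY_KINDS}")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if self.kind in ("renyi", "tsallis") and (
                self.order <= 0 or self.order == 1.0):
            raise ValueError("order must be positive and != 1")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "eps": self.eps,
                "n_bins": self.n_bins, "order": self.order}

    @classmethod
    def from_dict(cls, d: dict) -> "EntropySpec":
        return cls(**d)


def differential_entropy(feature_map: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Gaussian differential entropy of each channel, in nats.

    For each channel the unbiased (N-1 denominator) temporal variance s2
    is computed and ``0.5 * ln(2*pi*e*(s2 + eps))`` returned.  ``eps``
    keeps the logarithm finite on constant channels.
    """
    fm = np.asarray(feature_map, dtype=np.float64)
    if fm.ndim == 1:
        fm = fm[None, :]
    if fm.shape[-1] < 2:
        raise ValueError("need at least 2 time samples for a variance")
    var = fm.var(axis=-1, ddof=1)
    return 0.5 * np.log(2.0 * np.pi * np.e * (var + eps))


def _histogram_probs(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width histogram frequencies per channel, vectorized.

    ``x`` has shape (..., T); returns (..., n_bins).  Each channel is
    binned over its own min–max range; a constant channel puts all mass
    in one bin.
    """
    T = x.shape[-1]
    lo = x.min(axis=-1, keepdims=True)
    hi = x.max(axis=-1, keepdims=True)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    idx = np.floor((x - lo) / safe * n_bins).astype(np.int64)
    np.clip(idx, 0, n_bins - 1, out=idx)
    flat = idx.reshape(-1, T)
    base = np.arange(flat.shape[0], dtype=np.int64)[:, None] * n_bins
    counts = np.bincount((flat + base).ravel(),
                         minlength=flat.shape[0] * n_bins)
    probs = counts.reshape(*x.shape[:-1], n_bins) / T
    return probs


def _shannon(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return -terms.sum(axis=-1)


def batched_entropy(x: np.ndarray, spec: EntropySpec) -> np.ndarray:
    """Entropy of each channel of ``x`` (..., T), any descriptor kind."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 2:
        raise ValueError("need at least 2 time samples")
    if spec.kind == "differential":
        return differential_entropy(x, eps=spec.eps)
    if spec.kind == "spectral":
        _, pxx = periodogram(x, axis=-1)
        pxx = pxx[..., 1:]  # DC reflects offset, not oscillatory structure
        total = pxx.sum(axis=-1, keepdims=True)
        p = np.where(total > 0, pxx / np.where(total > 0, total, 1.0), 0.0)
        # zero-power channels: define entropy as 0 (degenerate spectrum)
        return _shannon(p)
    p = _histogram_probs(x, spec.n_bins)
    if spec.kind == "shannon":
        return _shannon(p)
    if spec.kind == "renyi":
        return np.log((p ** spec.order).sum(axis=-1)) / (1.0 - spec.order)
    # tsallis
    q = spec.order
    return (1.0 - (p ** q).sum(axis=-1)) / (q - 1.0)


def entropy_descriptor(feature_map: np.ndarray, spec: EntropySpec) -> np.ndarray:
    """One entropy value per channel of a (channels, time) feature map."""
    fm = np.asarray(feature_map, dtype=np.float64)
    if fm.ndim == 1:
        fm = fm[None, :]
    if fm.ndim != 2:
        raise ValueError("feature map must be (channels, time)")
    return batched_entropy(fm, spec)
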