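"""Storage-quality metrics: net information density, SSIM, pool summaries.

Net information density is the size of the stored file in bits divided by
the total number of synthesized nucleotides (bits/nt); it can exceed the
2 bits/nt mapping ceiling only through compression.  File sizes quoted in
KB use the binary convention 1 KB = 1024 bytes.

SSIM follows the standard Wang et al. formulation — Gaussian 11×11 window
(σ = 1.5), K1 = 0.01, K2 = 0.03, population covariances — as implemented by
scikit-image.  Multichannel images are either averaged per-channel SSIM
(default) or reduced to ITU-R BT.601 luma first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from skimage.metrics import structural_similarity

from .constrained_mapper import audit
from .errors import InvalidInputError
from .packetizer import Oligo

__all__ = [
    "KB",
    "net_information_density",
    "ssim",
    "MetricsReport",
    "pool_summary",
]

#: Binary kilobyte — the convention under which the published oligo counts
#: and densities are mutually consistent.
KB = 1024

_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def net_information_density(
    original_size_bytes: float, oligo_count: int, oligo_length_nt: int
) -> float:
    """Stored bits per synthesized nucleotide.

    ``original_size_bytes`` may be fractional (e.g. ``95.2 * KB``).
    """
    total_nt = oligo_count * oligo_length_nt
    if total_nt <= 0 or original_size_bytes <= 0:
        raise InvalidInputError("sizes and pool dimensions must be positive")
    return original_size_bytes * 8 / total_nt


def _as_float(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim not in (2, 3):
        raise InvalidInputError(f"expected a 2-D or 3-D image, got ndim={arr.ndim}")
    return arr


def _data_range(arr: np.ndarray, data_range: Optional[float]) -> float:
    if data_range is not None:
        return float(data_range)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return float(info.max - info.min)
    raise InvalidInputError(
        "data_range must be given explicitly for float images"
    )


def ssim(
    image_a,
    image_b,
    data_range: Optional[float] = None,
    channel_mode: str = "mean",
) -> float:
    """Structural similarity index in [−1, 1]; 1 iff the images are identical.

    ``channel_mode`` is ``"mean"`` (average the per-channel SSIM) or
    ``"luma"`` (convert RGB to BT.601 luma first).
    """
    a, b = _as_float(image_a), _as_float(image_b)
    if a.shape != b.shape:
        raise InvalidInputError(f"image shapes differ: {a.shape} vs {b.shape}")
    dr = _data_range(a, data_range)
    kwargs = dict(
        data_range=dr,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        K1=0.01,
        K2=0.03,
    )
    if a.ndim == 2:
        return float(structural_similarity(a, b, **kwargs))
    if channel_mode == "luma":
        ya = a.astype(float) @ _LUMA_WEIGHTS
        yb = b.astype(float) @ _LUMA_WEIGHTS
        return float(structural_similarity(ya, yb, **kwargs))
    if channel_mode != "mean":
        raise InvalidInputError(f"unknown channel_mode {channel_mode!r}")
    return float(
        np.mean(
            [
                structural_similarity(a[..., c], b[..., c], **kwargs)
                for c in range(a.shape[-1])
            ]
        )
    )


@dataclass(frozen=True)
class MetricsReport:
    oligo_count: int
    oligo_length_nt: Optional[int]  # None for non-uniform pools
    total_nt: int
    gc_percent: float               # pool-wide
    gc_percent_min: float           # per-oligo extremes
    gc_percent_max: float
    max_homopolymer: int
    motif_count: int
    net_information_density: Optional[float] = None
    ssim: Optional[float] = None

    def to_tsv(self) -> str:
        rows = [
            ("oligo_count", self.oligo_count),
            ("oligo_length_nt", self.oligo_length_nt),
            ("total_nt", self.total_nt),
            ("gc_percent", round(self.gc_percent, 4)),
            ("gc_percent_min", round(self.gc_percent_min, 4)),
            ("gc_percent_max", round(self.gc_percent_max, 4)),
            ("max_homopolymer", self.max_homopolymer),
            ("motif_count", self.motif_count),
            ("net_information_density",
             None if self.net_information_density is None
             else round(self.net_information_density, 4)),
            ("ssim", None if self.ssim is None else round(self.ssim, 6)),
        ]
        return "".join(f"{k}\t{v}\n" for k, v in rows if v is not None)


def pool_summary(
    pool: Iterable[Oligo | str],
    original_size_bytes: Optional[float] = None,
    ssim_value: Optional[float] = None,
) -> MetricsReport:
    """Aggregate per-oligo constraint audits over a whole pool."""
    seqs = [o.sequence if isinstance(o, Oligo) else str(o) for o in pool]
    if not seqs:
        raise InvalidInputError("cannot summarize an empty pool")
    audits = [audit(s) for s in seqs]
    lengths = {len(s) for s in seqs}
    total_nt = sum(len(s) for s in seqs)
    gc_total = 100.0 * sum(
        len(s) * a.gc_percent / 100.0 for s, a in zip(seqs, audits)
    ) / total_nt
    uniform_len = lengths.pop() if len(lengths) == 1 else None
    density = None
    if original_size_bytes is not None:
        density = original_size_bytes * 8 / total_nt
    return MetricsReport(
        oligo_count=len(seqs),
        oligo_length_nt=uniform_len,
        total_nt=total_nt,
        gc_percent=gc_total,
        gc_percent_min=min(a.gc_percent for a in audits),
        gc_percent_max=max(a.gc_percent for a in audits),
        max_homopolymer=max(a.max_homopolymer for a in audits),
        motif_count=sum(len(a.motif_hits) for a in audits),
        net_information_density=density,
        ssim=ssim_value,
    )
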