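"""SAAID index maps from co-registered SHG and TPEAF channels.

SAAID (SHG-to-Autofluorescence Aging Index of Dermis) is the normalized
contrast SAAID = (SHG − TPEAF)/(SHG + TPEAF): +1 on pure-collagen pixels,
−1 on pure-autofluorescence (elastin-rich) pixels, 0 where the channels
balance.  Because fixed numeric SAAID thresholds only make sense on
comparable channel scales, channels are rescaled (99th-percentile by
default) before the index is formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import ChannelMaps

__all__ = ["SAAIDMap", "normalize_channels", "compute_saaid"]


@dataclass
class SAAIDMap:
    """Per-pixel SAAID values with a definedness mask.

    ``saaid`` is NaN wherever SHG + TPEAF == 0 (index undefined there —
    never silently zero-filled); ``defined`` marks the usable pixels.
    """

    saaid: np.ndarray
    defined: np.ndarray


def _rescale(img: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return img
    if method == "max":
        denom = float(img.max())
    elif method == "percentile99":
        denom = float(np.percentile(img, 99.0))
        if denom <= 0:  # degenerate sparse image; fall back to max
            denom = float(img.max())
    else:
        raise ValueError(f"unknown normalization method '{method}'")
    if denom <= 0:
        raise ValueError("cannot normalize an all-zero channel")
    return img / denom


def normalize_channels(channels: ChannelMaps, method: str = "percentile99") -> ChannelMaps:
    """Rescale each channel ({none, percentile99, max}) onto a common scale.

    Scale-invariant: two acquisitions differing only by a global detector
    gain normalize to the same images (for percentile99/max).
    """
    channels.validate()
    return ChannelMaps(
        shg=_rescale(channels.shg, method),
        tpeaf=_rescale(channels.tpeaf, method),
    )


def compute_saaid(channels: ChannelMaps) -> SAAIDMap:
    """Pixel-wise SAAID = (SHG − TPEAF)/(SHG + TPEAF) on defined pixels.

    Expects channels already normalized onto comparable scales.  The map
    is antisymmetric under channel swap and bounded in [−1, 1].
    """
    channels.validate()
    shg, tpeaf = channels.shg, channels.tpeaf
    total = shg + tpeaf
    defined = total > 0
    saaid = np.full(shg.shape, np.nan)
    saaid[defined] = (shg[defined] - tpeaf[defined]) / total[defined]
    return SAAIDMap(saaid=saaid, defined=defined)
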