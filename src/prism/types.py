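"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ChannelImage", "ImageSet"]


@dataclass(frozen=True)
class ChannelImage:
    """One grayscale confocal plane with its acquisition metadata.

    ``mask`` marks valid pixels (None means all valid); registration
    zero-fills out-of-frame pixels and flags them here so they can be
    excluded from measurements.
    """

    data: np.ndarray
    channel: str
    round_id: str = "0"
    well: str = "A1"
    image_id: str = "0"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.asarray(self.data).ndim != 2:
            raise ValueError("ChannelImage holds a single 2D plane")
        if self.mask is not None and self.mask.shape != self.data.shape:
            raise ValueError("mask shape must match image shape")

    def with_data(self, data: np.ndarray, mask: np.ndarray | None = None) -> "ChannelImage":
        return replace(self, data=data, mask=self.mask if mask is None else mask)


@dataclass(frozen=True)
class ImageSet:
    """A collection of channel planes from one field of view (or well).

    All planes share the pixel size (nm); channels may come from different
    imaging rounds, each with its own drift.
    """

    images: list[ChannelImage] = field(default_factory=list)
    pixel_size_nm: float = 187.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")
        shapes = {im.data.shape for im in self.images}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent image shapes in set: {sorted(shapes)}")

    def channels(self) -> list[str]:
        seen: list[str] = []
        for im in self.images:
            if im.channel not in seen:
                seen.append(im.channel)
        return seen

    def round_ids(self) -> list[str]:
        seen: list[str] = []
        for im in self.images:
            if im.round_id not in seen:
                seen.append(im.round_id)
        return seen

    def get(self, channel: str, round_id: str | None = None) -> ChannelImage:
        for im in self.images:
            if im.channel == channel and (round_id is None or im.round_id == round_id):
                return im
        raise KeyError(f"channel {channel!r} (round {round_id!r}) not in image set")
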