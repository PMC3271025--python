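"""Multi-channel 3-D confocal stack container.

Axes are (z, y, x) with z index 0 the *deepest* optical section in the
tissue, matching the order in which the segmentation sweeps the stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class StackError(ValueError):
    """Raised for malformed stacks or channel lookups."""


@dataclass
class ConfocalStack:
    """8-bit multi-channel voxel grid with physical voxel sizes (µm).

    Attributes
    ----------
    channels : dict of str -> ndarray
        Channel name to (z, y, x) array of uint8 intensities.
    voxel_size_um : tuple
        (z, y, x) voxel edge lengths in microns.
    """

    channels: dict[str, np.ndarray]
    voxel_size_um: tuple[float, float, float] = (0.25, 0.16, 0.16)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise StackError("stack must contain at least one channel")
        shapes = {c: a.shape for c, a in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise StackError(f"channel shapes differ: {shapes}")
        if len(first) != 3:
            raise StackError(f"channels must be 3-D (z, y, x), got shape {first}")
        if any(v <= 0 for v in self.voxel_size_um):
            raise StackError("voxel sizes must be positive")
        for name, arr in self.channels.items():
            if arr.dtype != np.uint8:
                amin, amax = float(arr.min()), float(arr.max())
                if amin < 0 or amax > 255:
                    raise StackError(
                        f"channel {name!r} intensities outside [0, 255]: [{amin}, {amax}]"
                    )

    @property
    def n_slices(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise StackError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None

    def validate_for_linking(self, window: int = 5) -> None:
        if self.n_slices < window:
            raise StackError(
                f"stack has {self.n_slices} slices; 3-D linking needs at least {window}"
            )
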