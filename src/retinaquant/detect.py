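"""Ommatidium segmentation: per-slice contour-level thresholding and 3-D linking.

Step 1 finds candidate ommatidial regions in each optical section: the
structural channel is max-filtered to blur out individual rhabdomeres, then
thresholded at 20 equally spaced intensity levels from high to low; connected
components grow as the level drops and are frozen once their pixel count
enters the acceptable size range.  Step 2 links the per-slice regions through
z with a sliding 5-slice window, starting from the deepest slice, merging
overlapping regions into nascent ommatidia and splitting fused regions using
running size statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

_EIGHT = np.ones((3, 3), dtype=bool)


# --------------------------------------------------------------------------
# Step 1: per-slice region finding
# --------------------------------------------------------------------------

def max_filter(image: np.ndarray, window: int = 5, mode: str = "tiled") -> np.ndarray:
    """Maximum-value filter emphasizing ommatidia over individual cells.

    ``mode="tiled"`` partitions the image into non-overlapping window x window
    blocks and assigns each block its maximum (the literal textual rule);
    ``mode="sliding"`` is the conventional moving-window maximum filter.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    img = np.asarray(image)
    if mode == "sliding":
        return ndimage.maximum_filter(img, size=window)
    if mode != "tiled":
        raise ValueError(f"unknown mode {mode!r}")
    ny, nx = img.shape
    py = (-ny) % window
    px = (-nx) % window
    padded = np.pad(img, ((0, py), (0, px)), mode="edge")
    by, bx = padded.shape[0] // window, padded.shape[1] // window
    blocks = padded.reshape(by, window, bx, window).max(axis=(1, 3))
    return np.repeat(np.repeat(blocks, window, axis=0), window, axis=1)[:ny, :nx]


@dataclass
class Region:
    """A candidate ommatidial cross-section in one slice."""

    pixels: np.ndarray  # raveled pixel indices into the slice
    shape: tuple[int, int]
    level: float = 0.0

    @property
    def size(self) -> int:
        return int(self.pixels.size)

    @property
    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        return np.unravel_index(self.pixels, self.shape)

    @property
    def centroid(self) -> np.ndarray:
        yy, xx = self.coords
        return np.array([yy.mean(), xx.mean()])

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        yy, xx = self.coords
        return int(yy.min()), int(xx.min()), int(yy.max()) + 1, int(xx.max()) + 1

    def touches_border(self) -> bool:
        y0, x0, y1, x1 = self.bbox
        return y0 == 0 or x0 == 0 or y1 == self.shape[0] or x1 == self.shape[1]


@dataclass
class SliceRegionSet:
    slice_index: int
    regions: list[Region] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)


def detection_levels(n_levels: int = 20, max_intensity: float = 255.0) -> np.ndarray:
    """Equally spaced threshold levels from 0 to the intensity maximum."""
    return np.linspace(0.0, max_intensity, n_levels)


def find_ommatidia_2d(
    image: np.ndarray,
    n_levels: int = 20,
    size_range: tuple[int, int] = (500, 1000),
    slice_index: int = 0,
) -> SliceRegionSet:
    """Contour-level local thresholding of one (max-filtered) optical section.

    Iterating threshold levels from the highest down, connected components
    grow as the threshold falls; a component is accepted (and frozen) the
    first time its size enters ``size_range``.  Components that merge into or
    touch an already accepted region are considered part of it and are not
    re-accepted, so within a slice no pixel belongs to two regions.
    Components never in range at any level are discarded.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = size_range
    accepted = np.zeros(img.shape, dtype=bool)
    regions: list[Region] = []
    for level in detection_levels(n_levels)[::-1]:
        if level <= 0:
            continue
        binary = img >= level
        if not binary.any():
            continue
        binary &= ~accepted
        labeled, n = ndimage.label(binary, structure=_EIGHT)
        if n == 0:
            continue
        # components adjacent to frozen regions are their continuation
        touching = np.unique(
            labeled[ndimage.binary_dilation(accepted, structure=_EIGHT) & binary]
        )
        sizes = np.bincount(labeled.ravel())
        for comp in range(1, n + 1):
            if lo <= sizes[comp] <= hi and comp not in touching:
                mask = labeled == comp
                accepted |= mask
                regions.append(
                    Region(
                        pixels=np.flatnonzero(mask.ravel()),
                        shape=img.shape,
                        level=float(level),
                    )
                )
    return SliceRegionSet(slice_index=slice_index, regions=regions)


# --------------------------------------------------------------------------
# Step 2: 3-D linking
# --------------------------------------------------------------------------

@dataclass
class OmmatidiumVolume:
    """A nascent ommatidium: per-slice regions linked through z."""

    id: int
    shape: tuple[int, int]
    regions: dict[int, np.ndarray] = field(default_factory=dict)  # z -> pixel idx

    @property
    def zmin(self) -> int:
        return min(self.regions)

    @property
    def zmax(self) -> int:
        return max(self.regions)

    @property
    def z_extent(self) -> tuple[int, int]:
        return self.zmin, self.zmax

    @property
    def n_slices(self) -> int:
        return len(self.regions)

    def centroid(self, z: int) -> np.ndarray:
        yy, xx = np.unravel_index(self.regions[z], self.shape)
        return np.array([yy.mean(), xx.mean()])

    def mean_centroid(self) -> np.ndarray:
        return np.mean([self.centroid(z) for z in self.regions], axis=0)

    def sizes(self) -> dict[int, int]:
        return {z: len(p) for z, p in self.regions.items()}

    def bbox(self, pad: int = 0) -> tuple[int, int, int, int]:
        ys, xs = [], []
        for p in self.regions.values():
            yy, xx = np.unravel_index(p, self.shape)
            ys.extend((yy.min(), yy.max()))
            xs.extend((xx.min(), xx.max()))
        y0 = max(min(ys) - pad, 0)
        x0 = max(min(xs) - pad, 0)
        y1 = min(max(ys) + 1 + pad, self.shape[0])
        x1 = min(max(xs) + 1 + pad, self.shape[1])
        return y0, x0, y1, x1

    def touches_border(self) -> bool:
        y0, x0, y1, x1 = self.bbox()
        return y0 == 0 or x0 == 0 or y1 == self.shape[0] or x1 == self.shape[1]

    def running_size_stats(self, z: int, lookback: int = 20) -> tuple[float, float]:
        """Mean and SD of region sizes over the last ``lookback`` slices below z."""
        recent = [len(p) for zz, p in self.regions.items() if z - lookback <= zz < z]
        if not recent:
            return np.nan, np.nan
        return float(np.mean(recent)), float(np.std(recent))


def split_fused_regions(
    region_pixels: np.ndarray,
    footprint_pixels: np.ndarray,
    running_mean: float,
    running_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Fused-region correction for an oversized incoming region.

    If the region's size is within one SD of the volume's running mean size,
    the whole region is assigned (empty remainder). Otherwise only the pixels
    directly overlapping the volume's recent footprint are assigned; the rest
    is returned for testing against adjacent ommatidia (or seeding a new one).
    """
    region_pixels = np.asarray(region_pixels)
    if not np.isfinite(running_mean) or region_pixels.size <= running_mean + running_sd:
        return region_pixels, np.array([], dtype=region_pixels.dtype)
    overlap = np.isin(region_pixels, footprint_pixels)
    return region_pixels[overlap], region_pixels[~overlap]


def link_ommatidia_3d(
    per_slice: list[SliceRegionSet],
    window: int = 5,
    min_extent: int | None = None,
    size_lookback: int = 20,
    seed_size_range: tuple[int, int] | None = None,
) -> list[OmmatidiumVolume]:
    """Link per-slice regions into 3-D ommatidium volumes.

    Sweeping from the deepest slice upward, each region is matched against the
    footprints (union of assigned pixels over the previous ``window - 1``
    slices) of the nascent ommatidia: an overlapping region joins the
    ommatidium it shares most pixels with (after the fused-region correction),
    and a non-overlapping region seeds a new nascent ommatidium.  Volumes
    spanning fewer than ``min_extent`` slices (default: the window) are
    dropped — an isolated single-slice anomaly is not an ommatidium.
    """
    if min_extent is None:
        min_extent = window
    if not per_slice:
        return []
    shape = None
    for srs in per_slice:
        for r in srs.regions:
            shape = r.shape
            break
        if shape:
            break
    if shape is None:
        return []
    if len(per_slice) < window:
        raise ValueError(f"need at least {window} slices, got {len(per_slice)}")

    volumes: list[OmmatidiumVolume] = []
    footprint = np.full(shape[0] * shape[1], -1, dtype=np.int32)
    order = sorted(per_slice, key=lambda s: s.slice_index)

    def rebuild_footprint(z: int) -> None:
        footprint.fill(-1)
        for vol in volumes:
            for zz in range(max(z - (window - 1), 0), z):
                if zz in vol.regions:
                    footprint[vol.regions[zz]] = vol.id

    def assign(vol: OmmatidiumVolume, z: int, pixels: np.ndarray) -> None:
        if pixels.size == 0:
            return
        if z in vol.regions:
            vol.regions[z] = np.union1d(vol.regions[z], pixels)
        else:
            vol.regions[z] = np.asarray(pixels)

    for srs in order:
        z = srs.slice_index
        rebuild_footprint(z)
        for region in srs.regions:
            ids = footprint[region.pixels]
            hit = ids[ids >= 0]
            if hit.size == 0:
                vol = OmmatidiumVolume(id=len(volumes), shape=shape)
                volumes.append(vol)
                assign(vol, z, region.pixels)
                continue
            counts = np.bincount(hit)
            primary = int(np.argmax(counts))
            vol = volumes[primary]
            mean, sd = vol.running_size_stats(z, size_lookback)
            # guard the degenerate case of near-constant sizes (SD -> 0), which
            # would otherwise split every region that grows by a pixel
            if np.isfinite(sd):
                sd = max(sd, 0.1 * mean)
            fp_pixels = np.flatnonzero(footprint == primary)
            assigned, remainder = split_fused_regions(
                region.pixels, fp_pixels, mean, sd
            )
            assign(vol, z, assigned)
            if remainder.size:
                rem_ids = footprint[remainder]
                for other in np.unique(rem_ids[rem_ids >= 0]):
                    part = remainder[rem_ids == other]
                    assign(volumes[int(other)], z, part)
                leftover = remainder[rem_ids < 0]
                if leftover.size and (
                    seed_size_range is None
                    or seed_size_range[0] <= leftover.size <= seed_size_range[1]
                ):
                    nv = OmmatidiumVolume(id=len(volumes), shape=shape)
                    volumes.append(nv)
                    assign(nv, z, leftover)

    kept = []
    for vol in volumes:
        if not vol.regions:
            continue
        if vol.zmax - vol.zmin + 1 >= min_extent:
            kept.append(vol)
    for k, vol in enumerate(kept):
        vol.id = k
    return kept


def detect_ommatidia(
    stack_channel: np.ndarray,
    n_levels: int = 20,
    size_range: tuple[int, int] = (500, 1000),
    max_filter_window: int = 5,
    max_filter_mode: str = "tiled",
    link_window: int = 5,
    min_extent: int | None = None,
) -> tuple[list[SliceRegionSet], list[OmmatidiumVolume]]:
    """Full Step 1 + Step 2 segmentation of a structural-channel stack."""
    per_slice = []
    for z in range(stack_channel.shape[0]):
        filtered = max_filter(stack_channel[z], max_filter_window, max_filter_mode)
        per_slice.append(
            find_ommatidia_2d(filtered, n_levels, size_range, slice_index=z)
        )
    volumes = link_ommatidia_3d(
        per_slice,
        window=link_window,
        min_extent=min_extent,
        seed_size_range=size_range,
    )
    return per_slice, volumes


def label_volume(volumes: list[OmmatidiumVolume], shape: tuple[int, int], n_slices: int) -> np.ndarray:
    """16-bit label image stack: 0 = background, k = ommatidium id + 1."""
    out = np.zeros((n_slices,) + shape, dtype=np.uint16)
    for vol in volumes:
        for z, pixels in vol.regions.items():
            yy, xx = np.unravel_index(pixels, shape)
            out[z, yy, xx] = vol.id + 1
    return out
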