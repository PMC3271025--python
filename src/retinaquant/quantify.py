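"""Local relative Rhodopsin quantification by iso-intensity contour assignment.

For each ommatidium and optical section, closed iso-intensity contours of the
reporter channel are partitioned into mutually exclusive sets: A_x, contours
exclusively overlapping the circular mask of photoreceptor x; B, contours
enclosing all 7 masks (the ommatidium's local background); and discarded
contours that overlap several masks — the signature of scattering bleed from
a bright cell, which is thereby rejected.  Length-weighted averages of
contour levels give the photoreceptor level I_pr = sum(l_j I_j)/sum(l_j) over
A_x, and the local background reference I_omma over B; the local relative
intensity I_l = <I_pr / I_omma> averaged over the quantification z-range is
insensitive to the depth- and curvature-dependent attenuation that scales a
whole ommatidium-slice's intensities.

Contour levels are by default drawn from the crop's local intensity range
(scale-covariant, so I_l is invariant under per-slice intensity rescaling);
a fixed 0-255 grid is available via ``level_mode="global"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath
from skimage import measure

logger = logging.getLogger(__name__)


class EmptyBackgroundError(ValueError):
    """No background (B) contours in this ommatidium-slice."""


@dataclass
class Contour:
    """A closed iso-intensity polyline in crop pixel coordinates (y, x)."""

    slice_index: int
    vertices: np.ndarray  # (n, 2), closed (first == last)
    level: float
    clipped: bool = False  # was open at the crop edge and closed along it

    _path: MplPath | None = field(default=None, repr=False, compare=False)
    _bbox: tuple[float, float, float, float] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def length(self) -> float:
        d = np.diff(self.vertices, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """(ymin, xmin, ymax, xmax) of the vertices."""
        if self._bbox is None:
            v = self.vertices
            self._bbox = (
                float(v[:, 0].min()),
                float(v[:, 1].min()),
                float(v[:, 0].max()),
                float(v[:, 1].max()),
            )
        return self._bbox

    @property
    def path(self) -> MplPath:
        if self._path is None:
            self._path = MplPath(self.vertices[:, ::-1])  # Path wants (x, y)
        return self._path

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)[:, ::-1]
        return self.path.contains_points(pts)


@dataclass
class CircularMask:
    """Photoreceptor mask: a disc of radius 0.45 x (distance to nearest center)."""

    center: np.ndarray  # (y, x)
    radius: float
    grown_px: float = 0.0


@dataclass
class ContourAssignment:
    """Partition of an ommatidium-slice's contours into exclusive sets."""

    A: dict[int, list[Contour]]  # cell index -> exclusive contours
    B: list[Contour]  # enclosing all 7 masks
    discarded: list[Contour]  # multi-cell overlap (scatter artifacts)
    unassigned: list[Contour]


def quantification_levels(
    lo: float, hi: float, n_levels: int = 128, mode: str = "local"
) -> np.ndarray:
    """Iso-intensity levels strictly inside the crop's intensity range."""
    if mode == "global":
        lo, hi = 0.0, 255.0
    elif mode != "local":
        raise ValueError(f"unknown level mode {mode!r}")
    if hi <= lo:
        return np.empty(0)
    return np.linspace(lo, hi, n_levels + 2)[1:-1]


def build_contour_map(
    crop: np.ndarray,
    n_levels: int = 128,
    level_mode: str = "local",
    slice_index: int = 0,
) -> list[Contour]:
    """Closed iso-intensity contours of a reporter-channel crop.

    Open contours clipped by the crop boundary are closed with a straight
    segment along the boundary and flagged.  A flat crop yields no contours.
    """
    crop = np.asarray(crop, dtype=float)
    levels = quantification_levels(crop.min(), crop.max(), n_levels, level_mode)
    contours: list[Contour] = []
    for level in levels:
        for verts in measure.find_contours(crop, level):
            closed = bool(
                abs(verts[0, 0] - verts[-1, 0]) < 1e-9
                and abs(verts[0, 1] - verts[-1, 1]) < 1e-9
            )
            if not closed:
                verts = np.vstack([verts, verts[:1]])
            contours.append(
                Contour(
                    slice_index=slice_index,
                    vertices=verts,
                    level=float(level),
                    clipped=not closed,
                )
            )
    return contours


def make_pr_masks(
    centers: np.ndarray, grow_px: dict[int, float] | None = None
) -> list[CircularMask]:
    """Circular masks of radius 0.45 d at each traced center.

    d is each cell's minimal distance to the other six centers, so masks from
    any valid geometry never overlap (0.45 < 0.5).  Masks may be grown by at
    most 3 px, and only for photoreceptors left without contours.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.shape[0] < 2:
        raise ValueError("need at least 2 centers")
    masks = []
    for i, c in enumerate(centers):
        d = np.linalg.norm(centers - c, axis=1)
        d[i] = np.inf
        dmin = float(d.min())
        if dmin <= 1e-9:
            raise ValueError(f"coincident photoreceptor centers at index {i}")
        grow = min(float((grow_px or {}).get(i, 0.0)), 3.0)
        masks.append(CircularMask(center=c, radius=0.45 * dmin + grow, grown_px=grow))
    return masks


def _overlaps(contour: Contour, mask: CircularMask) -> bool:
    """Contour-mask overlap: any vertex inside the disc, or the disc's center
    enclosed by the contour (the enclosed area then intersects the disc)."""
    dy = contour.vertices[:, 0] - mask.center[0]
    dx = contour.vertices[:, 1] - mask.center[1]
    if (dy * dy + dx * dx <= mask.radius * mask.radius).any():
        return True
    return bool(contour.contains(mask.center[None, :])[0])


def assign_contours(
    contours: list[Contour],
    masks: list[CircularMask],
    grow_missing: bool = True,
) -> ContourAssignment:
    """Partition contours into the exclusive sets A_x, B and discards.

    A contour enclosing all mask centers is background (B); a contour
    overlapping exactly one mask joins that cell's A_x; a contour overlapping
    two or more masks (without enclosing all) is a scattering artifact and is
    discarded; others stay unassigned.  Cells with empty A_x trigger one
    retry with their mask grown by 3 px.
    """
    centers = np.stack([m.center for m in masks])
    A: dict[int, list[Contour]] = {i: [] for i in range(len(masks))}
    B: list[Contour] = []
    discarded: list[Contour] = []
    unassigned: list[Contour] = []

    def classify(contour: Contour, mask_set: list[CircularMask]):
        y0, x0, y1, x1 = contour.bbox
        # cheap bbox pre-filters: enclosure needs every center inside the
        # bbox; overlap needs the center within one radius of the bbox
        if (
            (centers[:, 0] >= y0).all()
            and (centers[:, 0] <= y1).all()
            and (centers[:, 1] >= x0).all()
            and (centers[:, 1] <= x1).all()
            and contour.contains(centers).all()
        ):
            return "B", None
        hits = []
        for i, m in enumerate(mask_set):
            r = m.radius
            cy, cx = m.center
            if cy < y0 - r or cy > y1 + r or cx < x0 - r or cx > x1 + r:
                continue
            if _overlaps(contour, m):
                hits.append(i)
                if len(hits) == 2:
                    return "discard", None
        if len(hits) == 1:
            return "A", hits[0]
        return "none", None

    for contour in contours:
        kind, idx = classify(contour, masks)
        if kind == "B":
            B.append(contour)
        elif kind == "A":
            A[idx].append(contour)
        elif kind == "discard":
            discarded.append(contour)
        else:
            unassigned.append(contour)

    if grow_missing:
        missing = [i for i, lst in A.items() if not lst]
        if missing and unassigned:
            grown = make_pr_masks(
                centers, grow_px={i: 3.0 for i in missing}
            )
            still_unassigned = []
            for contour in unassigned:
                y0, x0, y1, x1 = contour.bbox
                hits = []
                for i, m in enumerate(grown):
                    r = m.radius
                    cy, cx = m.center
                    if cy < y0 - r or cy > y1 + r or cx < x0 - r or cx > x1 + r:
                        continue
                    if _overlaps(contour, m):
                        hits.append(i)
                if len(hits) == 1 and hits[0] in missing:
                    A[hits[0]].append(contour)
                else:
                    still_unassigned.append(contour)
            unassigned = still_unassigned
    return ContourAssignment(A=A, B=B, discarded=discarded, unassigned=unassigned)


def _length_weighted_level(contours: list[Contour]) -> float:
    lengths = np.array([c.length for c in contours])
    levels = np.array([c.level for c in contours])
    return float(np.sum(lengths * levels) / np.sum(lengths))


def reference_level(B_contours: list[Contour]) -> float:
    """Ommatidial background reference: length-weighted mean of B levels."""
    if not B_contours:
        raise EmptyBackgroundError("no background contours; slice excluded")
    return _length_weighted_level(B_contours)


def pr_level(A_x_contours: list[Contour]) -> float | None:
    """Photoreceptor level: length-weighted mean of its exclusive contour levels."""
    if not A_x_contours:
        return None
    return _length_weighted_level(A_x_contours)


@dataclass
class IntensityRecord:
    """Final per-cell measurement: I_l averaged over the usable z-slices."""

    ommatidium_id: int
    pr_label: str
    channel: str
    i_l: float
    n_slices_used: int
    per_slice: dict[int, tuple[float, float]] = field(default_factory=dict)


def local_relative_intensity(
    ratios_by_slice: dict[int, float],
) -> tuple[float, int] | None:
    """Mean of I_pr/I_omma over qualifying slices; None if no slice qualifies."""
    vals = [v for v in ratios_by_slice.values() if v is not None and np.isfinite(v)]
    if not vals:
        return None
    return float(np.mean(vals)), len(vals)


def quantify_ommatidium(
    reporter: np.ndarray,
    volume,
    centers: np.ndarray,
    labels: dict[int, str],
    z_slices,
    channel: str = "",
    n_levels: int = 128,
    level_mode: str = "local",
    pad: int = 4,
) -> list[IntensityRecord]:
    """Quantify one ommatidium in one reporter channel over the z-range.

    ``centers`` are the traced cell centers averaged over the z-range (full
    image frame); contour maps are built on the volume's padded bounding box.
    Slices with no background contour are skipped; cells with no usable slice
    are dropped (and logged).
    """
    y0, x0, y1, x1 = volume.bbox(pad=pad)
    local_centers = np.asarray(centers, dtype=float) - [y0, x0]
    masks = make_pr_masks(local_centers)
    ratios: dict[int, dict[int, float]] = {i: {} for i in range(len(masks))}
    detail: dict[int, dict[int, tuple[float, float]]] = {i: {} for i in range(len(masks))}
    for z in z_slices:
        if not (volume.zmin <= z <= volume.zmax):
            continue
        crop = reporter[z, y0:y1, x0:x1]
        contours = build_contour_map(crop, n_levels, level_mode, slice_index=z)
        assignment = assign_contours(contours, masks)
        try:
            i_omma = reference_level(assignment.B)
        except EmptyBackgroundError:
            logger.info(
                "ommatidium %s slice %d: empty background set, skipped",
                volume.id,
                z,
            )
            continue
        if i_omma <= 0:
            continue
        for i in range(len(masks)):
            i_pr = pr_level(assignment.A[i])
            if i_pr is None:
                continue
            ratios[i][z] = i_pr / i_omma
            detail[i][z] = (i_pr, i_omma)
    records = []
    for i in range(len(masks)):
        res = local_relative_intensity(ratios[i])
        if res is None:
            logger.info(
                "ommatidium %s cell %s (%s): no usable slices, record dropped",
                volume.id,
                i,
                labels.get(i, "?"),
            )
            continue
        i_l, n_used = res
        records.append(
            IntensityRecord(
                ommatidium_id=volume.id,
                pr_label=labels.get(i, str(i)),
                channel=channel,
                i_l=i_l,
                n_slices_used=n_used,
                per_slice=detail[i],
            )
        )
    return records
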