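"""Photoreceptor tracing and type labeling within segmented ommatidia.

Step 3 traces the 7 photoreceptors (R1-R6 outer cells plus the central R7/R8
pair, reported jointly) through each ommatidium volume: k-means with k = 7 on
the (y, x) positions of the brightest structural-channel pixels in a 5-slice
window, the first window randomly seeded, each subsequent window (shifted by
one slice) seeded with the previous centers so cluster lineages follow cells.

Cluster quality is the maximal displacement of cell centers between
consecutive slices; the quantification z-range maximizes (number of
well-resolved ommatidia) x (interval length) over contiguous slice intervals.

Step 4 assigns R1-R6 labels from the inter-center distance geometry: the cell
farthest from the central cell is R3, its two nearest neighbors are R2/R4,
their remaining neighbors are R1/R5 (R1 being the one with no further
neighbor), R5's neighbor closest to R3 is R4, the other is R6, and the cell
between R1 and R3 is R2.  The rule chain uses only pairwise distances, so it
is invariant under rigid motions and uniform scaling, and it resolves both
eye chiralities consistently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .detect import OmmatidiumVolume
from .simulate import CENTRAL_LABEL

OUTER_LABELS = ("R1", "R2", "R3", "R4", "R5", "R6")


class LabelingError(ValueError):
    """Raised when the distance geometry is too ambiguous to label."""


@dataclass
class PRTrace:
    """One traced photoreceptor: per-slice centers and member pixels."""

    ommatidium_id: int
    cell_index: int
    centers: dict[int, np.ndarray] = field(default_factory=dict)  # z -> (y, x)
    members: dict[int, np.ndarray] = field(default_factory=dict)  # z -> (n, 2) px

    @property
    def zmin(self) -> int:
        return min(self.centers)

    @property
    def zmax(self) -> int:
        return max(self.centers)

    def mean_center(self, z_range=None) -> np.ndarray:
        zs = list(z_range) if z_range is not None else list(self.centers)
        pts = [self.centers[z] for z in zs if z in self.centers]
        return np.mean(pts, axis=0)


def trace_photoreceptors(
    volume: OmmatidiumVolume,
    structural: np.ndarray,
    n_points: int = 800,
    window: int = 5,
    seed: int = 0,
    n_init: int = 10,
) -> list[PRTrace]:
    """Trace the 7 photoreceptors through one ommatidium volume.

    ``structural`` is the full (z, y, x) structural-channel array.  Pixels are
    drawn from the volume's per-slice regions; each 5-slice window pools its
    ``n_points`` brightest pixels (ties broken by pixel index for
    determinism).  Fewer than ``n_points`` candidates triggers a warning and
    uses all available.
    """
    zmin, zmax = volume.z_extent
    if zmax - zmin + 1 < window:
        raise ValueError(
            f"volume {volume.id} spans {zmax - zmin + 1} slices; needs >= {window}"
        )
    shape = volume.shape

    def window_points(z0: int):
        ys, xs, zs, vals = [], [], [], []
        for z in range(z0, z0 + window):
            pix = volume.regions.get(z)
            if pix is None or pix.size == 0:
                continue
            yy, xx = np.unravel_index(pix, shape)
            ys.append(yy)
            xs.append(xx)
            zs.append(np.full(yy.size, z))
            vals.append(structural[z, yy, xx].astype(float))
        if not ys:
            return None
        yy = np.concatenate(ys)
        xx = np.concatenate(xs)
        zz = np.concatenate(zs)
        vv = np.concatenate(vals)
        if vv.size < n_points:
            warnings.warn(
                f"ommatidium {volume.id}: window at z={z0} has only {vv.size} "
                f"candidate pixels (< {n_points}); using all",
                stacklevel=2,
            )
            order = np.arange(vv.size)
        else:
            order = np.argsort(-vv, kind="stable")[:n_points]
        pts = np.stack([yy[order], xx[order]], axis=1).astype(float)
        return pts, zz[order]

    traces = [PRTrace(volume.id, k) for k in range(7)]
    prev_centers = None
    for z0 in range(zmin, zmax - window + 2):
        got = window_points(z0)
        if got is None:
            continue
        pts, zz = got
        if prev_centers is None:
            km = KMeans(n_clusters=7, n_init=n_init, random_state=seed).fit(pts)
        else:
            km = KMeans(n_clusters=7, init=prev_centers, n_init=1, max_iter=50).fit(pts)
        prev_centers = km.cluster_centers_
        labels = km.labels_
        # per-slice centers from member pixels; the first window fills all its
        # slices, later windows contribute their newest slice
        new_slices = (
            range(z0, z0 + window) if z0 == zmin else [z0 + window - 1]
        )
        for z in new_slices:
            in_slice = zz == z
            for k in range(7):
                sel = in_slice & (labels == k)
                if sel.any():
                    traces[k].members[z] = pts[sel].astype(int)
                    traces[k].centers[z] = pts[sel].mean(axis=0)
                else:
                    traces[k].members[z] = np.empty((0, 2), dtype=int)
                    traces[k].centers[z] = prev_centers[k].copy()
    return traces


@dataclass
class ClusterQuality:
    """Per-transition maximal center displacement for one ommatidium."""

    ommatidium_id: int
    transitions: dict[int, float]  # z -> max displacement between z and z+1

    def max_over(self, zmin: int, zmax: int) -> float:
        vals = [d for z, d in self.transitions.items() if zmin <= z < zmax]
        return max(vals) if vals else 0.0

    def mean_over(self, zmin: int, zmax: int) -> float:
        vals = [d for z, d in self.transitions.items() if zmin <= z < zmax]
        return float(np.mean(vals)) if vals else 0.0

    @property
    def zmin(self) -> int:
        return min(self.transitions) if self.transitions else 0

    @property
    def zmax(self) -> int:
        return max(self.transitions) + 1 if self.transitions else 0


def clustering_goodness(traces: list[PRTrace]) -> ClusterQuality:
    """Maximal displacement of cell centers between consecutive slices."""
    if not traces:
        raise ValueError("no traces")
    zs = sorted(set.intersection(*(set(t.centers) for t in traces)))
    transitions: dict[int, float] = {}
    for z0, z1 in zip(zs[:-1], zs[1:]):
        if z1 != z0 + 1:
            continue
        disp = max(
            float(np.linalg.norm(t.centers[z1] - t.centers[z0])) for t in traces
        )
        transitions[z0] = disp
    return ClusterQuality(traces[0].ommatidium_id, transitions)


@dataclass
class QuantificationRange:
    """Contiguous slice interval used for quantification, with inclusion flags."""

    zmin: int
    zmax: int  # inclusive
    included: dict[int, bool]

    @property
    def slices(self) -> range:
        return range(self.zmin, self.zmax + 1)

    @property
    def length(self) -> int:
        return self.zmax - self.zmin + 1


def select_quantification_zrange(
    qualities: dict[int, ClusterQuality],
    displacement_cap: float = 2.0,
) -> QuantificationRange:
    """Pick the interval maximizing (qualifying ommatidia) x (interval length).

    An ommatidium qualifies for interval [a, b] when its trace covers the
    interval and its maximal center displacement within it is at most the
    cap.  Ties prefer longer intervals, then deeper starts, making the choice
    deterministic.  This automates the semi-automatic interval selection: the
    full landscape (interval length versus number of well-resolved ommatidia)
    is scanned exhaustively.
    """
    if not qualities:
        raise ValueError("no ommatidia traced")
    zlo = min(q.zmin for q in qualities.values())
    zhi = max(q.zmax for q in qualities.values())
    if zhi == zlo:  # degenerate single-slice extent: nothing to compare
        return QuantificationRange(
            zmin=zlo, zmax=zhi, included={oid: True for oid in qualities}
        )
    best = None  # (score, length, -a, a, b, included)
    for a in range(zlo, zhi + 1):
        # running max displacement per ommatidium as the interval extends;
        # intervals must span at least one slice transition
        running: dict[int, float] = {}
        for b in range(a + 1, zhi + 1):
            included = {}
            for oid, q in qualities.items():
                if q.zmin > a or q.zmax < b:
                    included[oid] = False
                    continue
                if b > a:
                    d = q.transitions.get(b - 1, np.inf)
                    running[oid] = max(running.get(oid, 0.0), d)
                included[oid] = running.get(oid, 0.0) <= displacement_cap
            n_ok = sum(included.values())
            if n_ok == 0:
                continue
            length = b - a + 1
            key = (n_ok * length, length, -a)
            if best is None or key > best[0]:
                best = (key, a, b, included)
    if best is None:
        raise ValueError(
            f"no interval contains an ommatidium with max displacement <= "
            f"{displacement_cap}"
        )
    _, a, b, included = best
    return QuantificationRange(zmin=a, zmax=b, included=included)


# --------------------------------------------------------------------------
# Step 4: geometric labeling
# --------------------------------------------------------------------------

def label_pr_types(
    centers: np.ndarray,
    central_index: int | None = None,
    neighbor_factor: float = 1.3,
    tie_tol: float = 0.03,
) -> dict[int, str]:
    """Assign {R1..R6, R7/8} labels to 7 cell centers from their distances.

    ``centers`` is a (7, 2) array of mean (y, x) positions.  The central cell
    defaults to the one nearest the centroid of all seven.  Outer-cell
    neighborhoods are pairs within ``neighbor_factor`` times the minimum
    outer-outer distance.  Any decision whose top two candidates differ by
    less than ``tie_tol`` (relative) raises :class:`LabelingError` and the
    ommatidium should be excluded rather than guessed.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.shape != (7, 2):
        raise ValueError(f"expected (7, 2) centers, got {centers.shape}")

    def dist(i, j):
        return float(np.linalg.norm(centers[i] - centers[j]))

    if central_index is None:
        centroid = centers.mean(axis=0)
        dc = np.linalg.norm(centers - centroid, axis=1)
        order = np.argsort(dc)
        if dc[order[1]] - dc[order[0]] < tie_tol * max(dc[order[1]], 1e-9):
            raise LabelingError("central cell ambiguous")
        central_index = int(order[0])
    outer = [i for i in range(7) if i != central_index]

    # R3: farthest outer cell from the center cell
    dcen = sorted(((dist(central_index, i), i) for i in outer), reverse=True)
    if (dcen[0][0] - dcen[1][0]) < tie_tol * dcen[0][0]:
        raise LabelingError("farthest cell (R3) ambiguous")
    r3 = dcen[0][1]

    # neighbor graph among outer cells
    pair_d = {(i, j): dist(i, j) for i in outer for j in outer if i < j}
    mind = min(pair_d.values())
    nbrs = {i: set() for i in outer}
    for (i, j), d in pair_d.items():
        if d <= neighbor_factor * mind:
            nbrs[i].add(j)
            nbrs[j].add(i)

    # R3's two nearest outer cells are R2/R4 (order resolved below)
    near_r3 = sorted((dist(r3, i), i) for i in outer if i != r3)
    if (near_r3[2][0] - near_r3[1][0]) < tie_tol * near_r3[2][0]:
        raise LabelingError("R2/R4 pair ambiguous")
    a, b = near_r3[0][1], near_r3[1][1]

    # remaining neighbors of R2/R4 are R1/R5
    rest_a = nbrs[a] - {r3}
    rest_b = nbrs[b] - {r3}
    if len(rest_a) != 1 or len(rest_b) != 1:
        raise LabelingError("neighbor chain from R2/R4 ambiguous")
    c = rest_a.pop()
    d = rest_b.pop()
    if c == d:
        raise LabelingError("degenerate neighbor chain")

    # of these, the cell with no further neighbor is R1
    deg_c = len(nbrs[c] - {a})
    deg_d = len(nbrs[d] - {b})
    if deg_c == 0 and deg_d > 0:
        r1, r2, r5, via = c, a, d, b
    elif deg_d == 0 and deg_c > 0:
        r1, r2, r5, via = d, b, c, a
    else:
        raise LabelingError("R1 (gap-side cell) ambiguous")

    # R5's neighbor closest to R3 is R4; the other is R6
    r5_nbrs = sorted(nbrs[r5], key=lambda i: dist(i, r3))
    if len(r5_nbrs) < 2:
        raise LabelingError("R5 neighborhood incomplete")
    r4, r6 = r5_nbrs[0], r5_nbrs[-1]
    if r4 != via:
        raise LabelingError("R4 inconsistent with the R2/R4 pair")

    labels = {central_index: CENTRAL_LABEL, r3: "R3", r2: "R2", r1: "R1",
              r5: "R5", r4: "R4", r6: "R6"}
    if len(labels) != 7:
        raise LabelingError("labeling did not produce a bijection")
    return labels


def labeling_chirality(centers: np.ndarray, labels: dict[int, str]) -> int:
    """Orientation (+1/-1) of the labeled arrangement.

    Sign of the cross product (R3 - center) x (R2 - center); +1 matches the
    generator's default chirality.
    """
    inv = {v: k for k, v in labels.items()}
    c = np.asarray(centers, dtype=float)
    v1 = c[inv["R3"]] - c[inv[CENTRAL_LABEL]]
    v2 = c[inv["R2"]] - c[inv[CENTRAL_LABEL]]
    # centers are (y, x); use (x, y) cross product orientation
    cross = v1[1] * v2[0] - v1[0] * v2[1]
    return 1 if cross >= 0 else -1
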