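"""Synthetic fly-retina confocal stack generator with known ground truth.

The generator emulates the geometry and optics the analysis pipeline assumes:

* a hexagonal lattice of ommatidia on a spherical cap, ommatidial long axes
  pointing at the cap's center of curvature, so central ommatidia are aligned
  with the optical (z) axis and peripheral ones tilt progressively;
* 7 cylindrical rhabdomeres per ommatidium — six outer photoreceptors on a
  circle with a one-slot gap (the stereotyped trapezoid) plus the central
  R7/R8 pair traced as a single cell — with configurable chirality and an
  optional parametric helical twist;
* depth- and curvature-dependent intensity attenuation
  exp(-attenuation_coeff x overlying tissue path length);
* scattering bleed from bright cells as a Gaussian-blurred halo;
* per-cell reporter expression drawn from a two-state shifted-gamma mixture;
* additive sensor noise and 8-bit clipping.

Expression levels are defined on the analyzer's local-relative-intensity
scale: a cell with level L is rendered as a rhabdomere plateau
P = cytoplasm_level x (L - 1) against cytoplasm at ``cytoplasm_level``, so the
contour method's idealized response — PR level ~ (cytoplasm + P)/2 against a
background reference ~ cytoplasm/2 — returns I_l ~ L.  The 8-bit range
therefore right-censors levels above ~(255 + b0)/b0 (~5 with the default
b0 = 64), as a real 8-bit acquisition would saturate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk

from .models import sample_two_state
from .params import TwoStateParams
from .stack import ConfocalStack

STRUCTURAL_CHANNEL = "phalloidin"

#: outer-photoreceptor slot order around the 7-fold circle (slot 3 is the gap)
_SLOT_LABELS = {0: "R3", 1: "R2", 2: "R1", 4: "R6", 5: "R5", 6: "R4"}
CENTRAL_LABEL = "R7/8"
PR_LABELS = ("R1", "R2", "R3", "R4", "R5", "R6", CENTRAL_LABEL)


class ConfigurationError(ValueError):
    """Raised when the requested geometry cannot be rendered."""


@dataclass
class RetinaSimConfig:
    """Geometry, optics and rendering parameters of the synthetic retina.

    Lengths are microns. ``curvature_radius_um=inf`` gives a flat retina.
    ``cytoplasm_level`` sets the rendered ommatidial cytoplasm intensity (the
    background-to-rhabdomere contrast is not constrained by published imaging
    parameters, so it is exposed rather than fixed).
    """

    n_ommatidia: int = 37
    lattice_spacing_um: float = 13.0
    ommatidium_radius_um: float = 4.0
    pr_center_spacing_um: float = 2.0
    rhabdomere_radius_um: float = 0.5
    voxel_size_um: tuple[float, float, float] = (0.25, 0.16, 0.16)
    n_slices: int = 80
    curvature_radius_um: float = 250.0
    attenuation_coeff: float = 0.02
    scatter_fraction: float = 0.05
    scatter_sigma_um: float = 1.5
    scatter_threshold: float = 128.0
    noise_sd: float = 2.0
    bit_depth: int = 8
    seed: int = 0
    # rendering levels (8-bit intensity units)
    cytoplasm_level: float = 64.0
    rhabdomere_level: float = 200.0
    # pattern details
    chirality: int = 1
    twist_deg_per_um: float = 0.0
    margin_um: float = 3.0
    field_size_um: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "lattice_spacing_um",
            "ommatidium_radius_um",
            "pr_center_spacing_um",
            "rhabdomere_radius_um",
            "curvature_radius_um",
        ):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ConfigurationError("voxel sizes must be positive")
        if self.n_ommatidia < 1 or self.n_slices < 1:
            raise ConfigurationError("n_ommatidia and n_slices must be >= 1")
        if not 0.0 <= self.scatter_fraction < 1.0:
            raise ConfigurationError("scatter_fraction must lie in [0, 1)")
        if self.lattice_spacing_um <= 2 * self.ommatidium_radius_um:
            raise ConfigurationError(
                "lattice_spacing must exceed twice the ommatidium radius"
            )
        if self.bit_depth != 8:
            raise ConfigurationError("only 8-bit rendering is supported")
        if self.chirality not in (-1, 1):
            raise ConfigurationError("chirality must be +1 or -1")

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def stack_depth_um(self) -> float:
        return self.n_slices * self.voxel_size_um[0]

    def z_um(self, k) -> np.ndarray:
        """Depth coordinate of slice k (z=0 is the deepest section)."""
        return np.asarray(k, dtype=float) * self.voxel_size_um[0]


def hex_lattice(n: int, spacing: float) -> np.ndarray:
    """First ``n`` points of a hexagonal lattice in ring (spiral) order, (x, y)."""
    pts = [(0.0, 0.0)]
    ring = 1
    while len(pts) < n:
        # walk the hexagonal ring at distance ring*spacing
        corner_dirs = [
            (np.cos(np.pi / 3 * k), np.sin(np.pi / 3 * k)) for k in range(6)
        ]
        pos = np.array(corner_dirs[4]) * ring * spacing  # start corner
        step_dirs = [corner_dirs[k] for k in [0, 1, 2, 3, 4, 5]]
        for d in step_dirs:
            for _ in range(ring):
                pos = pos + np.array(d) * spacing
                pts.append((float(pos[0]), float(pos[1])))
        ring += 1
    return np.array(pts[:n])


def pr_pattern(cfg: RetinaSimConfig) -> tuple[np.ndarray, list[str]]:
    """Local (x, y) offsets (µm) of the 7 photoreceptor centers and labels.

    Six outer cells occupy slots of a 7-fold circle with slot 3 empty (the
    trapezoid's open side); the central R7/R8 cell is displaced off the
    mirror axis so that R3 is strictly the farthest cell from the center.
    """
    r = cfg.pr_center_spacing_um / (2.0 * np.sin(np.pi / 7.0))
    angles = {k: 2.0 * np.pi * k / 7.0 for k in range(7)}
    offsets = []
    labels = []
    for slot, lab in _SLOT_LABELS.items():
        a = angles[slot]
        offsets.append((r * np.cos(a), r * np.sin(a)))
        labels.append(lab)
    u3 = np.array([np.cos(angles[3]), np.sin(angles[3])])
    u5 = np.array([np.cos(angles[5]), np.sin(angles[5])])
    center = 0.25 * r * u3 + 0.15 * r * u5
    offsets.append((float(center[0]), float(center[1])))
    labels.append(CENTRAL_LABEL)
    pat = np.array(offsets)
    if cfg.chirality == -1:
        pat = pat * np.array([1.0, -1.0])
    return pat, labels


@dataclass
class SyntheticGroundTruth:
    """Programmed geometry and expression of a synthetic retina.

    ``cells[i][j]`` describes photoreceptor j of ommatidium i with its label,
    local pattern offset, and per-channel programmed level/state. Helper
    methods give voxel-frame positions at any slice, accounting for lattice
    curvature tilt and twist.
    """

    config: RetinaSimConfig
    lattice_xy_um: np.ndarray  # (n_omm, 2) surface positions
    axes: np.ndarray  # (n_omm, 3) unit axis vectors (x, y, z)
    surface_z_um: np.ndarray  # (n_omm,) z of the retinal surface over each center
    pattern_um: np.ndarray  # (7, 2) local offsets
    labels: list[str]
    levels: dict[str, np.ndarray]  # channel -> (n_omm, 7)
    states: dict[str, np.ndarray]  # channel -> (n_omm, 7) bool
    field_half_um: float = 0.0

    @property
    def n_ommatidia(self) -> int:
        return len(self.lattice_xy_um)

    @property
    def n_cells(self) -> int:
        return 7 * self.n_ommatidia

    def _basis(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal in-plane basis perpendicular to ommatidium i's axis."""
        u = self.axes[i]
        e1 = np.cross(u, [0.0, 0.0, 1.0])
        n1 = np.linalg.norm(e1)
        if n1 < 1e-9:
            e1 = np.array([1.0, 0.0, 0.0])
        else:
            e1 = e1 / n1
        e2 = np.cross(u, e1)
        return e1, e2

    def ommatidium_center_um(self, i: int, z_um: float) -> np.ndarray:
        """Bundle axis position (x, y) at depth z."""
        u = self.axes[i]
        t = (z_um - self.surface_z_um[i]) / u[2]
        return self.lattice_xy_um[i] + t * u[:2]

    def pr_center_um(self, i: int, j: int, z_um: float) -> np.ndarray:
        cfg = self.config
        u = self.axes[i]
        off = self.pattern_um[j]
        twist = np.deg2rad(cfg.twist_deg_per_um * cfg.chirality) * (
            z_um - self.surface_z_um[i]
        )
        c, s = np.cos(twist), np.sin(twist)
        off = np.array([c * off[0] - s * off[1], s * off[0] + c * off[1]])
        e1, e2 = self._basis(i)
        p3 = off[0] * e1 + off[1] * e2
        base = self.lattice_xy_um[i] + p3[:2]
        zc = self.surface_z_um[i] + p3[2]
        t = (z_um - zc) / u[2]
        return base + t * u[:2]

    def um_to_px(self, xy_um: np.ndarray) -> np.ndarray:
        """(x, y) µm in the retina frame -> (y, x) pixel coordinates."""
        _, vy, vx = self.config.voxel_size_um
        x = (np.asarray(xy_um)[..., 0] + self.field_half_um) / vx
        y = (np.asarray(xy_um)[..., 1] + self.field_half_um) / vy
        return np.stack([y, x], axis=-1)

    def pr_center_px(self, i: int, j: int, z_index: int) -> np.ndarray:
        return self.um_to_px(self.pr_center_um(i, j, self.config.z_um(z_index)))

    def ommatidium_center_px(self, i: int, z_index: int) -> np.ndarray:
        return self.um_to_px(self.ommatidium_center_um(i, self.config.z_um(z_index)))

    def mean_pr_center_px(self, i: int, j: int, z_range) -> np.ndarray:
        zs = list(z_range)
        return np.mean([self.pr_center_px(i, j, z) for z in zs], axis=0)

    def to_json(self) -> str:
        d = {
            "config": asdict(self.config),
            "lattice_xy_um": self.lattice_xy_um.tolist(),
            "axes": self.axes.tolist(),
            "surface_z_um": self.surface_z_um.tolist(),
            "pattern_um": self.pattern_um.tolist(),
            "labels": self.labels,
            "levels": {c: a.tolist() for c, a in self.levels.items()},
            "states": {c: a.astype(int).tolist() for c, a in self.states.items()},
            "field_half_um": self.field_half_um,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticGroundTruth":
        d = json.loads(text)
        cfgd = d["config"]
        cfgd["voxel_size_um"] = tuple(cfgd["voxel_size_um"])
        return cls(
            config=RetinaSimConfig(**cfgd),
            lattice_xy_um=np.array(d["lattice_xy_um"]),
            axes=np.array(d["axes"]),
            surface_z_um=np.array(d["surface_z_um"]),
            pattern_um=np.array(d["pattern_um"]),
            labels=list(d["labels"]),
            levels={c: np.array(a) for c, a in d["levels"].items()},
            states={c: np.array(a, dtype=bool) for c, a in d["states"].items()},
            field_half_um=float(d["field_half_um"]),
        )


def sample_two_state_levels(
    params: TwoStateParams, n: int, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-cell expression levels and on/off states from the two-state mixture."""
    return sample_two_state(params, n, seed)


def _geometry(cfg: RetinaSimConfig):
    """Lay out the lattice on the spherical cap; returns ground-truth geometry."""
    lattice = hex_lattice(cfg.n_ommatidia, cfg.lattice_spacing_um)
    rho = np.hypot(lattice[:, 0], lattice[:, 1])
    max_rho = float(rho.max())
    R = cfg.curvature_radius_um
    if np.isfinite(R) and max_rho >= R:
        raise ConfigurationError(
            f"lattice extent {max_rho:.1f} µm exceeds curvature radius {R} µm"
        )
    half = max_rho + cfg.ommatidium_radius_um + cfg.margin_um
    if cfg.field_size_um is not None:
        if cfg.field_size_um / 2.0 < half:
            raise ConfigurationError(
                f"field_size_um={cfg.field_size_um} cannot fit {cfg.n_ommatidia} "
                f"ommatidia (needs {2 * half:.1f} µm)"
            )
        half = cfg.field_size_um / 2.0

    z0 = cfg.stack_depth_um + 1.0  # surface just above the imaged volume
    if np.isfinite(R):
        # the mounted retina is a bowl: the surface is lowest over the center,
        # so central voxels sit under the least overlying tissue and image
        # brightest; ommatidial axes point at the center of curvature above
        sagitta = R - np.sqrt(R**2 - rho**2)
        surface_z = z0 + sagitta
        sphere_c = np.array([0.0, 0.0, z0 + R])
        axes = sphere_c[None, :] - np.stack(
            [lattice[:, 0], lattice[:, 1], surface_z], axis=1
        )
        axes = axes / np.linalg.norm(axes, axis=1, keepdims=True)
    else:
        surface_z = np.full(len(lattice), z0)
        axes = np.tile([0.0, 0.0, 1.0], (len(lattice), 1))
    return lattice, axes, surface_z, half, z0


def attenuation_field(cfg: RetinaSimConfig, shape_yx: tuple[int, int], field_half_um: float):
    """Per-slice attenuation factor maps exp(-c x overlying path length).

    Returns a function z_index -> (y, x) float32 map. The tissue surface is
    the spherical cap; the path length of a voxel is the vertical distance to
    the surface above it (light travels through less tissue near the cap
    apex, so equal-depth voxels are brighter near the retina's center).
    """
    ny, nx = shape_yx
    _, vy, vx = cfg.voxel_size_um
    xs = np.arange(nx) * vx - field_half_um
    ys = np.arange(ny) * vy - field_half_um
    XX, YY = np.meshgrid(xs, ys)
    rho2 = XX**2 + YY**2
    R = cfg.curvature_radius_um
    z0 = cfg.stack_depth_um + 1.0
    if np.isfinite(R):
        sag = R - np.sqrt(np.maximum(R**2 - rho2, 0.0))
        z_surf = z0 + sag
    else:
        z_surf = np.full((ny, nx), z0)

    c = cfg.attenuation_coeff

    def factor(z_index: int) -> np.ndarray:
        if c == 0.0:
            return np.ones((ny, nx))
        path = np.maximum(z_surf - cfg.z_um(z_index), 0.0)
        return np.exp(-c * path)

    return factor


def apply_depth_attenuation(stack: ConfocalStack, cfg: RetinaSimConfig) -> ConfocalStack:
    """Scale every voxel by exp(-attenuation_coeff x overlying tissue path).

    Float channels stay float (useful for closed-form checks); 8-bit channels
    are rescaled and re-quantized.
    """
    ny, nx = stack.shape[1:]
    # infer field origin consistent with the generator's centered frame
    field_half = nx * cfg.voxel_size_um[2] / 2.0
    fac = attenuation_field(cfg, (ny, nx), field_half)
    out = {}
    for name, arr in stack.channels.items():
        res = np.empty(arr.shape, dtype=np.float64)
        for z in range(arr.shape[0]):
            res[z] = arr[z].astype(np.float64) * fac(z)
        if arr.dtype == np.uint8:
            res = np.clip(np.rint(res), 0, 255).astype(np.uint8)
        out[name] = res
    return ConfocalStack(out, stack.voxel_size_um, dict(stack.meta))


def generate_retina_stack(
    cfg: RetinaSimConfig,
    expression: dict[str, TwoStateParams] | None = None,
) -> tuple[ConfocalStack, SyntheticGroundTruth]:
    """Render a synthetic retina and its ground truth.

    ``expression`` maps reporter channel names to two-state mixture
    parameters; the structural (phalloidin) channel is always rendered. A
    fixed ``cfg.seed`` yields a bit-identical stack.
    """
    rng = np.random.default_rng(cfg.seed)
    lattice, axes, surface_z, half, _ = _geometry(cfg)
    pattern, labels = pr_pattern(cfg)

    expression = dict(expression or {})
    levels: dict[str, np.ndarray] = {}
    states: dict[str, np.ndarray] = {}
    for chan, par in expression.items():
        lv, st = sample_two_state(
            par, 7 * cfg.n_ommatidia, seed=rng.integers(0, 2**31 - 1)
        )
        levels[chan] = lv.reshape(cfg.n_ommatidia, 7)
        states[chan] = st.reshape(cfg.n_ommatidia, 7)

    gt = SyntheticGroundTruth(
        config=cfg,
        lattice_xy_um=lattice,
        axes=axes,
        surface_z_um=surface_z,
        pattern_um=pattern,
        labels=labels,
        levels=levels,
        states=states,
        field_half_um=half,
    )

    _, vy, vx = cfg.voxel_size_um
    ny = int(np.ceil(2 * half / vy))
    nx = int(np.ceil(2 * half / vx))
    att = attenuation_field(cfg, (ny, nx), half)
    r_cyt_px = cfg.ommatidium_radius_um / vx
    r_rh_px = cfg.rhabdomere_radius_um / vx
    sigma_px = cfg.scatter_sigma_um / vx
    b0 = cfg.cytoplasm_level

    chan_names = [STRUCTURAL_CHANNEL] + list(expression)
    out = {name: np.empty((cfg.n_slices, ny, nx), dtype=np.uint8) for name in chan_names}

    for z in range(cfg.n_slices):
        z_um = cfg.z_um(z)
        fac = att(z)
        # geometry of this slice
        omma_px = gt.um_to_px(
            np.stack([gt.ommatidium_center_um(i, z_um) for i in range(cfg.n_ommatidia)])
        )
        cell_px = np.stack(
            [
                [gt.pr_center_um(i, j, z_um) for j in range(7)]
                for i in range(cfg.n_ommatidia)
            ]
        )
        cell_px = gt.um_to_px(cell_px)

        for name in chan_names:
            img = np.zeros((ny, nx), dtype=np.float32)
            for i in range(cfg.n_ommatidia):
                rr, cc = disk(tuple(omma_px[i]), r_cyt_px, shape=(ny, nx))
                img[rr, cc] = b0
            for i in range(cfg.n_ommatidia):
                for j in range(7):
                    if name == STRUCTURAL_CHANNEL:
                        val = cfg.rhabdomere_level
                    else:
                        val = max(b0 * (levels[name][i, j] - 1.0), 0.0)
                    rr, cc = disk(tuple(cell_px[i, j]), r_rh_px, shape=(ny, nx))
                    img[rr, cc] = val
            if cfg.scatter_fraction > 0:
                bright = np.where(img > cfg.scatter_threshold, img, 0.0)
                if bright.any():
                    img = img + cfg.scatter_fraction * gaussian_filter(bright, sigma_px)
            img *= fac
            if cfg.noise_sd > 0:
                img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
            out[name][z] = np.clip(np.rint(img), 0, cfg.max_intensity).astype(np.uint8)

    stack = ConfocalStack(out, cfg.voxel_size_um, meta={"synthetic": True, "seed": cfg.seed})
    return stack, gt


def write_simulation(stack: ConfocalStack, gt: SyntheticGroundTruth, outdir) -> None:
    """Write one multi-page TIFF per channel plus the ground-truth JSON sidecar."""
    from pathlib import Path

    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, arr in stack.channels.items():
        tifffile.imwrite(outdir / f"{name}.tif", arr)
    (outdir / "ground_truth.json").write_text(gt.to_json())
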