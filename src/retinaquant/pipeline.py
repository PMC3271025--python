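"""End-to-end orchestration: segment -> trace -> z-range -> label -> quantify -> fit.

File formats: multi-page 8-bit TIFF stacks in; TSV tables (region, trace,
measurement, fit), a 16-bit label-volume TIFF and a JSON manifest out.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .detect import OmmatidiumVolume, detect_ommatidia, label_volume
from .models import fit_two_state
from .quantify import IntensityRecord, quantify_ommatidium
from .simulate import (
    STRUCTURAL_CHANNEL,
    RetinaSimConfig,
    SyntheticGroundTruth,
    generate_retina_stack,
)
from .stack import ConfocalStack, StackError
from .trace import (
    ClusterQuality,
    LabelingError,
    PRTrace,
    QuantificationRange,
    clustering_goodness,
    label_pr_types,
    select_quantification_zrange,
    trace_photoreceptors,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class PipelineConfig:
    """All stage parameters, validated against module preconditions."""

    structural_channel: str = STRUCTURAL_CHANNEL
    reporter_channels: list[str] | None = None  # None = all non-structural
    max_filter_window: int = 5
    max_filter_mode: str = "tiled"
    n_levels_detect: int = 20
    size_range: tuple[int, int] | None = None  # None = derive from sim geometry
    link_window: int = 5
    n_points: int = 800
    trace_window: int = 5
    kmeans_restarts: int = 10
    displacement_cap: float = 2.0
    n_levels_quant: int = 128
    quant_level_mode: str = "local"
    exclude_border: bool = False
    fit_models: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_filter_window < 1 or self.max_filter_window % 2 == 0:
            raise ValueError("max_filter_window must be odd and >= 1")
        if self.n_levels_detect < 2 or self.n_levels_quant < 2:
            raise ValueError("need at least 2 contour levels")
        if self.size_range is not None and not (0 < self.size_range[0] < self.size_range[1]):
            raise ValueError("size_range must be increasing and positive")
        if self.link_window < 1 or self.trace_window < 1:
            raise ValueError("windows must be >= 1")
        if self.n_points < 7:
            raise ValueError("n_points must cover at least 7 cells")
        if self.displacement_cap <= 0:
            raise ValueError("displacement_cap must be positive")


def geometry_size_range(
    sim_cfg: RetinaSimConfig, slack: tuple[float, float] = (0.55, 1.35)
) -> tuple[int, int]:
    """Acceptable region size derived from the rendered ommatidium geometry.

    The detected cross-section is the cytoplasm disc dilated by the max
    filter (~2 px); the range brackets its area with multiplicative slack.
    """
    r_px = sim_cfg.ommatidium_radius_um / sim_cfg.voxel_size_um[2]
    area = math.pi * (r_px + 2.0) ** 2
    return int(slack[0] * area), int(slack[1] * area)


@dataclass
class OmmatidiumResult:
    volume: OmmatidiumVolume
    traces: list[PRTrace]
    quality: ClusterQuality
    labels: dict[int, str] | None = None  # None = undetermined / excluded
    centers: np.ndarray | None = None


@dataclass
class PipelineResult:
    config: PipelineConfig
    volumes: list[OmmatidiumVolume]
    ommatidia: dict[int, OmmatidiumResult]
    z_range: QuantificationRange
    measurements: pd.DataFrame
    records: list[IntensityRecord] = field(default_factory=list)
    fits: dict[str, dict] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def resolved_ids(self) -> list[int]:
        return [
            oid
            for oid, res in self.ommatidia.items()
            if res.labels is not None and self.z_range.included.get(oid, False)
        ]


def run_pipeline(
    stack: ConfocalStack,
    config: PipelineConfig | None = None,
    sim_cfg: RetinaSimConfig | None = None,
) -> PipelineResult:
    """Run the full analysis chain on a stack.

    ``sim_cfg`` (when analyzing synthetic data) supplies the geometry from
    which the detection size range is derived if not set explicitly.
    """
    config = config or PipelineConfig()
    timings: dict[str, float] = {}

    stage = "validate"
    try:
        stack.validate_for_linking(config.link_window)
        structural = stack.channel(config.structural_channel)
        reporters = config.reporter_channels
        if reporters is None:
            reporters = [c for c in stack.channel_names if c != config.structural_channel]
        for r in reporters:
            stack.channel(r)
        size_range = config.size_range
        if size_range is None:
            size_range = (
                geometry_size_range(sim_cfg) if sim_cfg is not None else (500, 1000)
            )

        stage = "segment"
        t0 = time.perf_counter()
        _, volumes = detect_ommatidia(
            structural,
            n_levels=config.n_levels_detect,
            size_range=size_range,
            max_filter_window=config.max_filter_window,
            max_filter_mode=config.max_filter_mode,
            link_window=config.link_window,
        )
        if config.exclude_border:
            volumes = [v for v in volumes if not v.touches_border()]
            for k, v in enumerate(volumes):
                v.id = k
        timings["segment"] = time.perf_counter() - t0
        logger.info("segment: %d volumes in %.1fs", len(volumes), timings["segment"])

        stage = "trace"
        t0 = time.perf_counter()
        ommatidia: dict[int, OmmatidiumResult] = {}
        for vol in volumes:
            if vol.zmax - vol.zmin + 1 < config.trace_window:
                continue
            traces = trace_photoreceptors(
                vol,
                structural,
                n_points=config.n_points,
                window=config.trace_window,
                seed=config.seed,
                n_init=config.kmeans_restarts,
            )
            ommatidia[vol.id] = OmmatidiumResult(
                volume=vol, traces=traces, quality=clustering_goodness(traces)
            )
        if not ommatidia:
            raise PipelineError("trace: no ommatidium spans the tracing window")
        timings["trace"] = time.perf_counter() - t0

        stage = "zrange"
        z_range = select_quantification_zrange(
            {oid: r.quality for oid, r in ommatidia.items()},
            displacement_cap=config.displacement_cap,
        )

        stage = "label"
        for oid, res in ommatidia.items():
            if not z_range.included.get(oid, False):
                continue
            centers = np.stack([t.mean_center(z_range.slices) for t in res.traces])
            res.centers = centers
            try:
                res.labels = label_pr_types(centers)
            except LabelingError as exc:
                logger.info("ommatidium %d unlabeled: %s", oid, exc)
                res.labels = None

        stage = "quantify"
        t0 = time.perf_counter()
        records: list[IntensityRecord] = []
        for chan in reporters:
            rep = stack.channel(chan)
            for oid, res in ommatidia.items():
                if res.labels is None or not z_range.included.get(oid, False):
                    continue
                records.extend(
                    quantify_ommatidium(
                        rep,
                        res.volume,
                        res.centers,
                        res.labels,
                        z_range.slices,
                        channel=chan,
                        n_levels=config.n_levels_quant,
                        level_mode=config.quant_level_mode,
                    )
                )
        timings["quantify"] = time.perf_counter() - t0
        measurements = pd.DataFrame(
            [
                {
                    "ommatidium": r.ommatidium_id,
                    "pr_label": r.pr_label,
                    "channel": r.channel,
                    "i_l": r.i_l,
                    "n_slices_used": r.n_slices_used,
                }
                for r in records
            ]
        )

        fits: dict[str, dict] = {}
        if config.fit_models and len(measurements):
            stage = "fit"
            for chan, grp in measurements.groupby("channel"):
                if len(grp) < 100:
                    continue
                params = fit_two_state(grp["i_l"].to_numpy(), random_state=config.seed)
                fits[chan] = asdict(params)
    except PipelineError:
        raise
    except (StackError, ValueError) as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    return PipelineResult(
        config=config,
        volumes=volumes,
        ommatidia=ommatidia,
        z_range=z_range,
        measurements=measurements,
        records=records,
        fits=fits,
        timings=timings,
    )


# --------------------------------------------------------------------------
# ground-truth evaluation (synthetic benchmarks)
# --------------------------------------------------------------------------

def match_volumes_to_truth(
    result: PipelineResult, gt: SyntheticGroundTruth
) -> dict[int, int]:
    """Map resolved volume ids to ground-truth ommatidium indices.

    A volume matches the ground-truth ommatidium whose bundle axis (at the
    volume's mid-slice) lies within one ommatidium radius of its centroid.
    """
    cfg = gt.config
    r_px = cfg.ommatidium_radius_um / cfg.voxel_size_um[2]
    out = {}
    for oid in result.resolved_ids:
        vol = result.ommatidia[oid].volume
        zmid = (vol.zmin + vol.zmax) // 2
        c = vol.mean_centroid()
        d = [
            np.linalg.norm(c - gt.ommatidium_center_px(i, zmid))
            for i in range(gt.n_ommatidia)
        ]
        gi = int(np.argmin(d))
        if d[gi] <= r_px:
            out[oid] = gi
    return out


def detection_scores(
    volumes: list[OmmatidiumVolume], gt: SyntheticGroundTruth
) -> tuple[float, float]:
    """(recall, precision) of ommatidium detection against ground truth."""
    cfg = gt.config
    r_px = cfg.ommatidium_radius_um / cfg.voxel_size_um[2]
    matched = set()
    fp = 0
    for vol in volumes:
        zmid = (vol.zmin + vol.zmax) // 2
        c = vol.mean_centroid()
        d = [
            np.linalg.norm(c - gt.ommatidium_center_px(i, zmid))
            for i in range(gt.n_ommatidia)
        ]
        gi = int(np.argmin(d))
        if d[gi] <= r_px:
            matched.add(gi)
        else:
            fp += 1
    recall = len(matched) / gt.n_ommatidia
    precision = (len(volumes) - fp) / len(volumes) if volumes else 0.0
    return recall, precision


def identity_errors(
    result: PipelineResult, gt: SyntheticGroundTruth
) -> tuple[int, int]:
    """(wrong, total) photoreceptor identities over resolved, matched ommatidia.

    Every ground-truth cell of a matched ommatidium is attributed to its
    nearest traced center; its predicted label is compared with the truth.
    """
    mapping = match_volumes_to_truth(result, gt)
    wrong = total = 0
    zr = result.z_range
    for oid, gi in mapping.items():
        res = result.ommatidia[oid]
        centers = res.centers
        for j in range(7):
            gt_c = gt.mean_pr_center_px(gi, j, zr.slices)
            k = int(np.argmin(np.linalg.norm(centers - gt_c, axis=1)))
            total += 1
            if res.labels[k] != gt.labels[j]:
                wrong += 1
    return wrong, total


def labeling_benchmark(
    n_retinae: int = 20,
    base_seed: int = 0,
    sim_cfg: RetinaSimConfig | None = None,
) -> tuple[int, int]:
    """Photoreceptor-identity benchmark on seeded synthetic retinae.

    Generates ``n_retinae`` structural-channel stacks with the default
    generator, runs segmentation, tracing, z-range selection and labeling,
    and pools (wrong, total) identity counts over all resolved ommatidia.
    """
    from dataclasses import replace

    base = sim_cfg or RetinaSimConfig()
    wrong = total = 0
    rng = np.random.default_rng(base_seed)
    for k in range(n_retinae):
        seed = int(rng.integers(0, 2**31 - 1))
        cfg = replace(base, seed=seed)
        stack, gt = generate_retina_stack(cfg)
        result = run_pipeline(stack, PipelineConfig(seed=seed % 2**16), sim_cfg=cfg)
        w, t = identity_errors(result, gt)
        wrong += w
        total += t
    return wrong, total


# --------------------------------------------------------------------------
# file I/O
# --------------------------------------------------------------------------

def read_stack(
    paths: dict[str, str | Path], voxel_size_um=(0.25, 0.16, 0.16)
) -> ConfocalStack:
    """Read one multi-page TIFF per channel into a ConfocalStack."""
    import tifffile

    channels = {}
    for name, path in paths.items():
        path = Path(path)
        try:
            arr = tifffile.imread(path)
        except Exception as exc:  # tifffile raises various parse errors
            raise PipelineError(f"read: malformed TIFF {path}: {exc}") from exc
        if arr.ndim == 2:
            arr = arr[None]
        channels[name] = arr
    return ConfocalStack(channels, tuple(voxel_size_um))


def write_tables(result: PipelineResult, outdir: str | Path, gt=None) -> dict[str, Path]:
    """Write all result tables, the label volume, and a run manifest."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["measurements"] = outdir / "measurements.tsv"
    result.measurements.to_csv(paths["measurements"], sep="\t", index=False)

    rows = []
    for oid, res in result.ommatidia.items():
        lab = res.labels or {}
        for k, tr in enumerate(res.traces):
            for z, c in sorted(tr.centers.items()):
                rows.append(
                    {
                        "ommatidium": oid,
                        "cell": k,
                        "label": lab.get(k, ""),
                        "slice": z,
                        "y": c[0],
                        "x": c[1],
                    }
                )
    paths["traces"] = outdir / "traces.tsv"
    pd.DataFrame(rows).to_csv(paths["traces"], sep="\t", index=False)

    rows = []
    for vol in result.volumes:
        for z in sorted(vol.regions):
            c = vol.centroid(z)
            rows.append(
                {
                    "id": vol.id,
                    "slice": z,
                    "centroid_y": c[0],
                    "centroid_x": c[1],
                    "size": len(vol.regions[z]),
                }
            )
    paths["regions"] = outdir / "regions.tsv"
    pd.DataFrame(rows).to_csv(paths["regions"], sep="\t", index=False)

    if result.volumes:
        shape = result.volumes[0].shape
        n_slices = max(v.zmax for v in result.volumes) + 1
        paths["labels"] = outdir / "label_volume.tif"
        tifffile.imwrite(paths["labels"], label_volume(result.volumes, shape, n_slices))

    manifest = {
        "version": _version,
        "schema": 1,
        "config": asdict(result.config),
        "seed": result.config.seed,
        "z_range": [result.z_range.zmin, result.z_range.zmax],
        "included": {str(k): bool(v) for k, v in result.z_range.included.items()},
        "n_volumes": len(result.volumes),
        "n_resolved": len(result.resolved_ids),
        "n_measurements": int(len(result.measurements)),
        "fits": result.fits,
        "timings_s": {k: round(v, 3) for k, v in result.timings.items()},
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=1))
    return paths
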