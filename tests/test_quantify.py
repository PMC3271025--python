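"""Contour-based local relative intensity quantification."""

import numpy as np
import pytest
from skimage.draw import disk

from retinaquant.quantify import (
    Contour,
    EmptyBackgroundError,
    assign_contours,
    build_contour_map,
    local_relative_intensity,
    make_pr_masks,
    pr_level,
    quantify_ommatidium,
    reference_level,
)


def _contour(level, vertices, z=0):
    v = np.asarray(vertices, dtype=float)
    if not np.allclose(v[0], v[-1]):
        v = np.vstack([v, v[:1]])
    return Contour(slice_index=z, vertices=v, level=level)


def _circle(cy, cx, r, level, n=64):
    t = np.linspace(0, 2 * np.pi, n)
    return _contour(level, np.stack([cy + r * np.sin(t), cx + r * np.cos(t)], axis=1))


class TestContourMap:
    def test_flat_crop_empty(self):
        assert build_contour_map(np.full((30, 30), 9.0)) == []

    def test_single_bump_nested_contours(self):
        yy, xx = np.mgrid[0:41, 0:41]
        crop = np.maximum(40.0 - 4 * np.hypot(yy - 20, xx - 20), 0.0)
        contours = build_contour_map(crop, n_levels=3)  # levels at 10, 20, 30
        assert len(contours) == 3
        by_level = sorted(contours, key=lambda c: c.level)
        lengths = [c.length for c in by_level]
        assert lengths[0] > lengths[1] > lengths[2]
        # nesting: lower-level contour encloses the higher ones' vertices
        assert by_level[0].contains(by_level[2].vertices[:-1]).all()

    def test_two_bumps_two_nests(self):
        yy, xx = np.mgrid[0:40, 0:80]
        crop = np.maximum(35.0 - 4 * np.hypot(yy - 20, xx - 20), 0.0)
        crop += np.maximum(35.0 - 4 * np.hypot(yy - 20, xx - 60), 0.0)
        contours = build_contour_map(crop, n_levels=2)
        assert len(contours) == 4  # 2 levels x 2 bumps
        centers = np.array([c.vertices[:-1].mean(axis=0) for c in contours])
        left = (centers[:, 1] < 40).sum()
        assert left == 2


class TestMasks:
    def test_hexagon_radius_forced_arithmetic(self):
        ang = np.linspace(0, 2 * np.pi, 7)[:-1]
        centers = np.concatenate(
            [12.0 * np.stack([np.sin(ang), np.cos(ang)], axis=1), [[0.0, 0.0]]]
        )
        masks = make_pr_masks(centers)
        for m in masks[:-1]:
            assert m.radius == pytest.approx(0.45 * 12.0)

    def test_growth_capped_at_three_px(self):
        centers = np.array([[0.0, 0.0], [10.0, 0.0]])
        masks = make_pr_masks(centers, grow_px={0: 4.0})
        assert masks[0].radius == pytest.approx(0.45 * 10 + 3.0)

    def test_masks_never_overlap(self, rng):
        from retinaquant.simulate import RetinaSimConfig, pr_pattern

        for _ in range(20):
            pat, _ = pr_pattern(RetinaSimConfig())
            centers = pat[:, ::-1] * rng.uniform(5, 30) + rng.normal(0, 0.2, (7, 2))
            masks = make_pr_masks(centers)
            for i in range(7):
                for j in range(i + 1, 7):
                    d = np.linalg.norm(masks[i].center - masks[j].center)
                    assert d > masks[i].radius + masks[j].radius - 1e-9

    def test_coincident_centers_rejected(self):
        with pytest.raises(ValueError):
            make_pr_masks(np.zeros((3, 2)))


class TestAssignment:
    @pytest.fixture
    def seven_masks(self):
        ang = np.linspace(0, 2 * np.pi, 7)[:-1]
        centers = np.concatenate(
            [14.0 * np.stack([np.sin(ang), np.cos(ang)], axis=1), [[0.0, 0.0]]]
        ) + 30.0
        return make_pr_masks(centers)

    def test_exclusive_small_contour(self, seven_masks):
        m3 = seven_masks[3]
        c = _circle(m3.center[0], m3.center[1], 2.0, level=120.0)
        out = assign_contours([c], seven_masks)
        assert out.A[3] == [c]
        assert not out.B and not out.discarded

    def test_scatter_lobe_discarded(self, seven_masks):
        # low-level lobe spanning masks 2 and 3: scattering bleed signature
        m2, m3 = seven_masks[2], seven_masks[3]
        mid = (m2.center + m3.center) / 2
        t = np.linspace(0, 2 * np.pi, 80)
        major = np.linalg.norm(m3.center - m2.center) / 2 + 3
        lobe = _contour(
            15.0,
            np.stack(
                [mid[0] + 4 * np.sin(t), mid[1] + major * np.cos(t)], axis=1
            ),
        )
        out = assign_contours([lobe], seven_masks)
        assert out.discarded == [lobe]

    def test_enclosing_contour_is_background(self, seven_masks):
        big = _circle(30.0, 30.0, 25.0, level=10.0)
        out = assign_contours([big], seven_masks)
        assert out.B == [big]

    def test_growth_retry_rescues_contourless_cell(self, seven_masks):
        # cells 1..6 have exclusive contours; cell 0's only contour sits just
        # outside its base mask radius but within the +3 px growth allowance
        m0 = seven_masks[0]
        inside = [
            _circle(m.center[0], m.center[1], 1.5, level=100.0)
            for m in seven_masks[1:]
        ]
        c = _circle(m0.center[0] + m0.radius + 2.0, m0.center[1], 1.0, level=80.0)
        out = assign_contours(inside + [c], seven_masks)
        assert out.A[0] == [c]
        out2 = assign_contours(inside + [c], seven_masks, grow_missing=False)
        assert not out2.A[0] and out2.unassigned == [c]


class TestLevels:
    def test_reference_level_arithmetic(self):
        c1 = _circle(0, 0, 10 / (2 * np.pi), 50.0)
        assert reference_level([c1]) == pytest.approx(50.0)
        ca = _circle(0, 0, 10 / (2 * np.pi), 100.0)
        cb = _circle(0, 0, 30 / (2 * np.pi), 60.0)
        # weights proportional to circumference: (10*100 + 30*60)/40 = 70
        assert reference_level([ca, cb]) == pytest.approx(70.0, rel=1e-3)

    def test_reference_level_invariant_when_levels_equal(self):
        cs = [_circle(0, 0, r, 42.0) for r in (2.0, 5.0, 9.0)]
        assert reference_level(cs) == pytest.approx(42.0)

    def test_reference_level_empty_raises(self):
        with pytest.raises(EmptyBackgroundError):
            reference_level([])

    def test_pr_level_arithmetic(self):
        c = _circle(0, 0, 8 / (2 * np.pi), 200.0)
        assert pr_level([c]) == pytest.approx(200.0)
        ca = _circle(0, 0, 20 / (2 * np.pi), 120.0)
        cb = _circle(0, 0, 10 / (2 * np.pi), 180.0)
        assert pr_level([ca, cb]) == pytest.approx(140.0, rel=1e-3)
        assert pr_level([]) is None

    def test_weighted_mean_bounded_by_levels(self, rng):
        cs = [
            _circle(0, 0, rng.uniform(1, 9), rng.uniform(10, 200)) for _ in range(6)
        ]
        levels = [c.level for c in cs]
        v = pr_level(cs)
        assert min(levels) <= v <= max(levels)

    def test_plateau_rhabdomere_oracle(self):
        # uniform disc of brightness P on cytoplasm b0: iso-contours ring the
        # disc at every level in (b0, P), so the length-weighted mean sits at
        # the midpoint; freeze against a marching-squares oracle
        b0, P = 60.0, 200.0
        crop = np.full((40, 40), b0)
        rr, cc = disk((20, 20), 4.0, shape=crop.shape)
        crop[rr, cc] = P
        crop[0, 0] = 0.0  # pin the local range
        crop[1, 1] = 255.0
        contours = build_contour_map(crop, n_levels=50)
        masks = make_pr_masks(np.array([[20.0, 20.0], [5.0, 35.0]]))
        out = assign_contours(contours, masks)
        got = pr_level(out.A[0])
        # independent oracle: marching squares directly plus hand-rolled
        # length weighting over the rings around the disc
        from skimage import measure

        levels = np.linspace(0, 255, 52)[1:-1]
        num = den = 0.0
        for level in levels:
            for verts in measure.find_contours(crop, level):
                centroid = verts.mean(axis=0)
                if np.linalg.norm(centroid - [20, 20]) > 6:
                    continue
                closed = np.vstack([verts, verts[:1]])
                seg = np.diff(closed, axis=0)
                length = np.hypot(seg[:, 0], seg[:, 1]).sum()
                num += length * level
                den += length
        oracle = num / den
        assert got == pytest.approx(oracle, rel=1e-6)
        # the length-weighted response of a plateau sits near the midpoint
        # between cytoplasm and plateau, not at the plateau itself
        assert abs(oracle - (b0 + P) / 2) < 10.0

    def test_local_relative_intensity(self):
        assert local_relative_intensity({0: 1.0, 1: 1.0}) == (1.0, 2)
        assert local_relative_intensity({0: 2.0, 1: 3.0, 2: 4.0}) == (3.0, 3)
        assert local_relative_intensity({}) is None


class TestIntegration:
    def test_scale_invariance_of_i_l(self, clean_sim):
        # multiplying a whole ommatidium-slice by a constant leaves I_l fixed
        from retinaquant.pipeline import PipelineConfig, run_pipeline

        cfg, stack, gt = clean_sim
        res = run_pipeline(stack, PipelineConfig(seed=0), sim_cfg=cfg)
        oid = res.resolved_ids[0]
        r = res.ommatidia[oid]
        rep = stack.channel("Rh3").astype(float)
        recs1 = quantify_ommatidium(
            rep, r.volume, r.centers, r.labels, res.z_range.slices, channel="Rh3"
        )
        recs2 = quantify_ommatidium(
            rep * 3.7, r.volume, r.centers, r.labels, res.z_range.slices, channel="Rh3"
        )
        il1 = {x.pr_label: x.i_l for x in recs1}
        il2 = {x.pr_label: x.i_l for x in recs2}
        assert il1.keys() == il2.keys()
        for k in il1:
            assert il1[k] == pytest.approx(il2[k], rel=1e-9)

    def test_recovers_programmed_levels(self, clean_sim):
        # zero noise/attenuation/scatter: >= 95 % of cells within 5 %
        from retinaquant.pipeline import (
            PipelineConfig,
            match_volumes_to_truth,
            run_pipeline,
        )

        cfg, stack, gt = clean_sim
        res = run_pipeline(stack, PipelineConfig(seed=0), sim_cfg=cfg)
        mapping = match_volumes_to_truth(res, gt)
        errs = []
        truth_by_label = {
            gi: {gt.labels[j]: gt.levels["Rh3"][gi, j] for j in range(7)}
            for gi in mapping.values()
        }
        for rec in res.records:
            gi = mapping.get(rec.ommatidium_id)
            if gi is None:
                continue
            true = truth_by_label[gi][rec.pr_label]
            errs.append(abs(rec.i_l - true) / true)
        assert len(errs) >= 40
        assert np.mean(np.array(errs) <= 0.05) >= 0.95

    def test_attenuation_cancels_in_i_l(self):
        # programmed-contrast cells measure within 10 % between central and
        # peripheral ommatidia despite curvature attenuation
        from retinaquant.pipeline import (
            PipelineConfig,
            match_volumes_to_truth,
            run_pipeline,
        )
        from retinaquant.params import TwoStateParams
        from retinaquant.simulate import RetinaSimConfig, generate_retina_stack

        const = TwoStateParams(400.0, 0.008, 1.0, 1.0, 0.0, shift=0.0)  # level ~3.2
        cfg = RetinaSimConfig(
            n_ommatidia=19,
            n_slices=12,
            seed=6,
            noise_sd=0.0,
            scatter_fraction=0.0,
            attenuation_coeff=0.10,
            curvature_radius_um=150.0,
        )
        stack, gt = generate_retina_stack(cfg, {"Rh3": const})
        res = run_pipeline(stack, PipelineConfig(seed=0), sim_cfg=cfg)
        mapping = match_volumes_to_truth(res, gt)
        rho = np.linalg.norm(gt.lattice_xy_um, axis=1)
        central = [o for o, g in mapping.items() if rho[g] < 1.0]
        periph = [o for o, g in mapping.items() if rho[g] > 12.0]
        assert central and periph
        df = res.measurements
        m_c = df[df.ommatidium.isin(central)].i_l.mean()
        m_p = df[df.ommatidium.isin(periph)].i_l.mean()
        assert abs(m_c - m_p) / m_c < 0.10
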