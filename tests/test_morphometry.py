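import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinemorph import (
    LEVELS,
    LabelMask,
    LevelAxis,
    SpinePhantomSpec,
    centroid_mm,
    compute_all_dhi,
    compute_dhi,
    generate_phantom,
    level_axis,
    measure_height,
)
from spinemorph.errors import DegenerateGeometryError, MissingStructureError
from conftest import rectangle_mask


def brute_force_mean_chord(mask, structure, unit_vector):
    """Independent chord-mean oracle: explicit loops over member pixels,
    binning across the axis at the pixel pitch, central-80% trim."""
    sr, sc = mask.spacing_mm
    u = np.asarray(unit_vector, dtype=float)
    v_dir = np.array([-u[1], u[0]])
    vs = []
    rows, cols = np.nonzero(mask.structure_pixels(structure))
    for r, c in zip(rows.tolist(), cols.tolist()):
        vs.append(r * sr * v_dir[0] + c * sc * v_dir[1])
    bw = min(sr, sc)
    v_min, v_max = min(vs), max(vs)
    counts = {}
    for v in vs:
        i = int(np.floor((v - v_min) / bw + 1e-9))
        counts[i] = counts.get(i, 0) + 1
    margin = 0.1 * (v_max - v_min)
    chords = []
    for i, n in sorted(counts.items()):
        center = v_min + (i + 0.5) * bw
        if v_min + margin <= center <= v_max - margin:
            chords.append(n * sr * sc / bw)
    if not chords:
        chords = [n * sr * sc / bw for _, n in sorted(counts.items())]
    return sum(chords) / len(chords)


class TestCentroid:
    def test_single_pixel(self, scheme):
        mask = rectangle_mask(8, 8, 3, 5, 1, 1)
        assert centroid_mm(mask, "L1") == (3.0, 5.0)

    def test_block_under_anisotropic_spacing(self):
        mask = rectangle_mask(4, 4, 0, 0, 2, 2, spacing=(2.0, 1.0))
        assert centroid_mm(mask, "L1") == (1.0, 0.5)

    def test_symmetric_rectangle_center(self):
        mask = rectangle_mask(20, 20, 4, 6, 7, 9)
        r, c = centroid_mm(mask, "L1")
        assert (r, c) == (4 + 3.0, 6 + 4.0)

    def test_absent_structure_raises(self, scheme):
        mask = rectangle_mask(8, 8, 0, 0, 2, 2, code=1)
        with pytest.raises(MissingStructureError) as exc:
            centroid_mm(mask, "L2")
        assert exc.value.structure == "L2"


class TestLevelAxis:
    def test_vertical_stack_gives_row_axis(self, scheme):
        px = np.zeros((30, 10), dtype=np.int64)
        px[2:8, 3:7] = 1  # L1
        px[12:18, 3:7] = 2  # L2
        mask = LabelMask(px, (1.0, 1.0), scheme)
        ax = level_axis(mask, "L1/2")
        assert ax.unit_vector == pytest.approx((1.0, 0.0), abs=1e-12)
        assert (ax.cranial_vb, ax.caudal_vb) == ("L1", "L2")

    def test_3_4_5_direction(self, scheme):
        px = np.zeros((40, 50), dtype=np.int64)
        px[0, 0] = 1
        px[30, 40] = 2
        ax = level_axis(LabelMask(px, (1.0, 1.0), scheme), "L1/2")
        assert ax.unit_vector == pytest.approx((0.6, 0.8), abs=1e-12)

    def test_quarter_turn_equivariance(self, straight_phantom):
        mask, _ = straight_phantom
        rotated = mask.with_pixels(np.ascontiguousarray(np.rot90(mask.pixels)))
        for lvl, _, _ in LEVELS:
            u = np.array(level_axis(mask, lvl).unit_vector)
            w = np.array(level_axis(rotated, lvl).unit_vector)
            # rot90 maps (dr, dc) -> (-dc, dr)
            assert w == pytest.approx((-u[1], u[0]), abs=1e-9)

    def test_coincident_centroids_degenerate(self, scheme):
        px = np.zeros((10, 10), dtype=np.int64)
        px[3, 5] = px[5, 5] = 1  # L1 centroid at (4, 5)
        px[4, 5] = 2  # L2 centroid also at (4, 5)
        mask = LabelMask(px, (1.0, 1.0), scheme)
        with pytest.raises(DegenerateGeometryError):
            level_axis(mask, "L1/2")

    def test_missing_vertebral_body_raises(self, scheme):
        px = np.zeros((10, 10), dtype=np.int64)
        px[4, 4] = 1
        mask = LabelMask(px, (1.0, 1.0), scheme)
        with pytest.raises(MissingStructureError):
            level_axis(mask, "L1/2")


class TestMeasureHeight:
    @pytest.mark.parametrize("spacing", [(1.0, 1.0), (0.5, 0.5), (2.0, 1.0), (0.5, 0.25)])
    def test_axis_aligned_rectangle_exact(self, spacing):
        mask = rectangle_mask(60, 80, 10, 10, 8, 30, spacing=spacing)
        axis = LevelAxis("L1/2", (1.0, 0.0), "L1", "L2")
        h = measure_height(mask, "L1", axis)
        assert h.height_mm == pytest.approx(8 * spacing[0], abs=1e-12)

    def test_rotated_rectangle_near_exact(self, scheme):
        # 8 mm x 30 mm rectangle rotated 20 deg, rasterized at 0.25 mm
        theta = np.deg2rad(20.0)
        d = np.array([np.cos(theta), np.sin(theta)])
        v = np.array([-d[1], d[0]])
        sp = 0.25
        n = 240
        rr, cc = np.meshgrid(np.arange(n) * sp, np.arange(n) * sp, indexing="ij")
        center = np.array([30.0, 30.0])
        U = (rr - center[0]) * d[0] + (cc - center[1]) * d[1]
        V = (rr - center[0]) * v[0] + (cc - center[1]) * v[1]
        px = ((np.abs(U) <= 4.0) & (np.abs(V) <= 15.0)).astype(np.int64)
        mask = LabelMask(px, (sp, sp), scheme)
        axis = LevelAxis("L1/2", (float(d[0]), float(d[1])), "L1", "L2")
        assert measure_height(mask, "L1", axis).height_mm == pytest.approx(8.0, abs=0.3)

    def test_plus_sign_matches_brute_force_oracle(self, scheme):
        px = np.zeros((15, 15), dtype=np.int64)
        px[2:13, 6:9] = 1  # vertical bar, 3 px wide
        px[6:9, 2:13] = 1  # horizontal bar
        mask = LabelMask(px, (1.0, 1.0), scheme)
        axis = LevelAxis("L1/2", (1.0, 0.0), "L1", "L2")
        got = measure_height(mask, "L1", axis).height_mm
        assert got == brute_force_mean_chord(mask, "L1", (1.0, 0.0))

    @pytest.mark.parametrize("seed", range(6))
    def test_random_blobs_match_brute_force_oracle(self, seed, scheme):
        rng = np.random.default_rng(seed)
        px = (rng.random((12, 12)) < 0.4).astype(np.int64)
        px[5, 5] = 1  # never empty
        mask = LabelMask(px, (1.0, 1.0), scheme)
        theta = rng.uniform(0, 2 * np.pi)
        u = (float(np.cos(theta)), float(np.sin(theta)))
        axis = LevelAxis("L1/2", u, "L1", "L2")
        got = measure_height(mask, "L1", axis).height_mm
        assert got == pytest.approx(brute_force_mean_chord(mask, "L1", u), rel=1e-12)


class TestDHI:
    def test_formula_on_known_heights(self, scheme):
        # ivd = 10, cranial VB = 20, caudal VB = 20 -> DHI = 0.5
        px = np.zeros((80, 40), dtype=np.int64)
        px[5:25, 5:35] = 1  # L1, 20 mm
        px[25:35, 5:35] = 7  # L1/2 disc, 10 mm
        px[35:55, 5:35] = 2  # L2, 20 mm
        rec = compute_dhi(LabelMask(px, (1.0, 1.0), scheme), "L1/2")
        assert rec.complete
        assert rec.dhi == pytest.approx(0.5, rel=1e-12)
        assert rec.dhi == pytest.approx(
            2 * rec.ivd_height_mm / (rec.cranial_vb_height_mm + rec.caudal_vb_height_mm),
            rel=1e-12,
        )

    def test_missing_structures_flagged_not_raised(self, straight_phantom):
        mask, _ = straight_phantom
        erased = mask.with_pixels(
            np.where(mask.pixels == mask.scheme.code("L3"), 0, mask.pixels)
        )
        recs = {r.level: r for r in compute_all_dhi(erased)}
        assert not recs["L2/3"].complete and not recs["L3/4"].complete
        assert all(recs[lvl].complete for lvl in ("L1/2", "L4/5", "L5/S1"))
        assert np.isnan(recs["L2/3"].dhi)

    def test_all_background_gives_five_incomplete_records(self, scheme):
        mask = LabelMask(np.zeros((10, 10), dtype=np.int64), (1.0, 1.0), scheme)
        recs = compute_all_dhi(mask)
        assert len(recs) == 5 and not any(r.complete for r in recs)

    def test_complete_phantom_gives_five_complete_records(self, straight_phantom):
        mask, _ = straight_phantom
        recs = compute_all_dhi(mask)
        assert [r.level for r in recs] == [lvl for lvl, _, _ in LEVELS]
        assert all(r.complete for r in recs)

    @given(factor=st.floats(min_value=0.1, max_value=10.0, allow_nan=False))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_dhi_invariant_under_isotropic_spacing(self, factor):
        px = np.zeros((80, 40), dtype=np.int64)
        px[5:25, 5:35] = 1
        px[25:35, 5:35] = 7
        px[35:55, 5:35] = 2
        base = LabelMask(px, (1.0, 1.0))
        scaled = LabelMask(px, (factor, factor))
        r0 = compute_dhi(base, "L1/2")
        r1 = compute_dhi(scaled, "L1/2")
        assert r1.dhi == pytest.approx(r0.dhi, rel=1e-12)
        assert r1.ivd_height_mm == pytest.approx(r0.ivd_height_mm * factor, rel=1e-9)

    def test_dhi_stable_under_global_rotation(self):
        from scipy import ndimage

        spec = SpinePhantomSpec(inter_level_angle_deg=4.0)
        mask, _ = generate_phantom(spec)
        rot = ndimage.rotate(mask.pixels, 17.0, order=0, reshape=True)
        rotated = LabelMask(rot, mask.spacing_mm, mask.scheme)
        base = {r.level: r.dhi for r in compute_all_dhi(mask)}
        after = {r.level: r.dhi for r in compute_all_dhi(rotated)}
        for lvl in base:
            assert abs(after[lvl] - base[lvl]) <= 0.03


class TestPhantomRecovery:
    def test_dhi_recovered_across_random_phantoms(self):
        errs = []
        for seed in range(50):
            spec = SpinePhantomSpec.sample(seed)
            mask, gt = generate_phantom(spec)
            for rec in compute_all_dhi(mask):
                errs.append(abs(rec.dhi - gt.dhi[rec.level]))
        assert max(errs) <= 0.02
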