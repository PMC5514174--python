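"""Scene rendering, manipulation masks and set calibration."""

import numpy as np
import pytest

from photoforge import scenegen as sg
from photoforge.colordiff import delta_e76, srgb_to_lab
from photoforge.gridchance import mask_regions


def one_building_spec(azimuth=90.0):
    return sg.SceneSpec(
        seed=0,
        light_azimuth=azimuth,
        objects=(sg.ObjectSpec("building", cx=250.0, base_y=200.0, w=70.0, h=120.0,
                               color=(160, 150, 140)),),
    )


def test_render_is_deterministic():
    spec = one_building_spec()
    a, b = sg.render_scene(spec), sg.render_scene(spec)
    assert a.dtype == np.uint8 and a.shape == (300, 400, 3)
    assert np.array_equal(a, b)


def test_empty_scene_is_pure_gradient_without_shadows():
    spec = sg.SceneSpec(seed=1, objects=())
    img = sg.render_scene(spec)
    # a vertical gradient: every row is constant across columns
    assert (img == img[:, :1, :]).all()
    scene = sg._render(spec)
    assert not any(m.any() for m in scene.shadow_masks)


def test_shadow_falls_west_of_building_when_lit_from_east():
    """Light azimuth 90 deg (east) must throw the cast shadow westward."""
    spec = one_building_spec(azimuth=90.0)
    scene = sg._render(spec)
    shadow, footprint = scene.shadow_masks[0], scene.object_masks[0]
    assert shadow.any()
    sh_cols = np.flatnonzero(shadow.any(axis=0))
    fp_cols = np.flatnonzero(footprint.any(axis=0))
    # recompute the projection: offset is -sin(90deg) * len_frac * h, due west
    expected_dx = spec.shadow_len_frac * 120.0
    assert sh_cols.min() <= fp_cols.min() - 0.8 * expected_dx  # extends west
    # never east of the building (1 px slack: polygon vs. rectangle rasterization)
    assert sh_cols.max() <= fp_cols.max() + 1
    # and flipping the light to the west must mirror the shadow eastward
    east = sg._render(one_building_spec(azimuth=270.0)).shadow_masks[0]
    assert np.flatnonzero(east.any(axis=0)).max() > fp_cols.max()


def test_zero_strength_is_degenerate():
    spec = one_building_spec()
    with pytest.raises(sg.DegenerateManipulationError):
        sg.apply_manipulation(sg.render_scene(spec), spec, "geometry", 0.0,
                              np.random.default_rng(0))


def test_shadow_deletion_mask_is_exactly_the_shadow_polygon():
    """Deleting a cast shadow must change exactly its visible pixels."""
    spec = one_building_spec()
    scene = sg._render(spec)
    manip, evidence, variant = sg._shadow(
        scene.image, scene, spec, 1.0, np.random.default_rng(0), target=0, variant="delete"
    )
    diff = (scene.image != manip).any(axis=2)
    assert variant == "delete"
    assert np.array_equal(diff, scene.shadow_masks[0])
    assert np.array_equal(evidence, scene.object_masks[0])


def test_unsupported_manipulations_raise():
    person_only = sg.SceneSpec(
        seed=2,
        cast_shadows=False,
        objects=(sg.ObjectSpec("person", cx=100.0, base_y=250.0, w=26.0, h=100.0,
                               color=(60, 70, 120)),),
    )
    img = sg.render_scene(person_only)
    rng = np.random.default_rng(0)
    sg.apply_manipulation(img, person_only, "airbrush", 0.5, rng)  # supported
    for label in ("shadow", "geometry", "superadditive"):
        with pytest.raises(sg.UnsupportedManipulationError):
            sg.apply_manipulation(img, person_only, label, 1.0, rng)


def test_set_counts_and_mask_properties(exp1_set6):
    """6 scenes x 5 types -> 6 originals + 30 pairs, every mask nonempty and
    exactly the set of differing pixels."""
    assert len(exp1_set6.originals) == 6
    assert len(exp1_set6.pairs) == 30
    for p in exp1_set6.pairs:
        assert p.mask.any()
        assert np.array_equal(p.mask, (p.original != p.manipulated).any(axis=2))
        assert len(mask_regions(p.mask, exp1_set6.grid)) >= 1


def test_grid_span_calibration(exp1_set6):
    counts = [len(mask_regions(p.mask, exp1_set6.grid)) for p in exp1_set6.pairs]
    assert abs(float(np.mean(counts)) - 2.0) <= 0.5


def test_superadditive_components_disjoint_and_additive(exp1_set6):
    """Component masks partition the composite mask, so mean Delta-E adds."""
    for p in exp1_set6.pairs:
        if p.mtype.label != "superadditive":
            continue
        masks = list(p.component_masks.values())
        union = np.zeros_like(p.mask)
        for i, m in enumerate(masks):
            for other in masks[i + 1:]:
                assert not (m & other).any()
            union |= m
        assert np.array_equal(union, p.mask)
        lab0 = srgb_to_lab(p.original)
        total = delta_e76(lab0, srgb_to_lab(p.manipulated)).mean
        parts = sum(
            delta_e76(lab0, srgb_to_lab(np.where(m[..., None], p.manipulated, p.original))).mean
            for m in masks
        )
        assert abs(total - parts) <= 1e-6


def test_delta_e_strength_ordering(exp1_set6):
    """Airbrushing is the subtlest change; the composite is the largest."""
    by_type = {}
    for p in exp1_set6.pairs:
        lab0 = srgb_to_lab(p.original)
        by_type.setdefault(p.mtype.label, []).append(
            delta_e76(lab0, srgb_to_lab(p.manipulated)).mean
        )
    means = {k: float(np.mean(v)) for k, v in by_type.items()}
    for mid in ("addsub", "geometry", "shadow"):
        assert means["airbrush"] < means[mid] < means["superadditive"]


def test_identical_seeds_reproduce_pairs():
    a = sg.build_stimulus_set(2, "exp1", rng=np.random.default_rng(5), n_manipulated_scenes=2)
    b = sg.build_stimulus_set(2, "exp1", rng=np.random.default_rng(5), n_manipulated_scenes=2)
    for pa, pb in zip(a.pairs, b.pairs):
        assert np.array_equal(pa.manipulated, pb.manipulated)


def test_png_round_trip(exp1_set6, tmp_path):
    """PNG output is lossless: saved pairs reload byte-identically."""
    manifest = sg.save_stimulus_set(exp1_set6, tmp_path)
    assert len(manifest) == 30
    reloaded = sg.load_stimulus_pairs(tmp_path)
    for orig, back in zip(exp1_set6.pairs, reloaded):
        assert np.array_equal(orig.original, back.original)
        assert np.array_equal(orig.manipulated, back.manipulated)
        assert np.array_equal(orig.mask, back.mask)


def test_unattainable_span_target_raises_calibration_error():
    with pytest.raises(sg.CalibrationError, match="history"):
        sg.build_stimulus_set(
            1, "exp1", rng=np.random.default_rng(0), n_manipulated_scenes=1,
            target_regions=8.5, region_tol=0.05, max_retries=2,
        )


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        sg.SceneSpec(seed=0, width=0)
    with pytest.raises(ValueError):
        sg.SceneSpec(seed=0, light_azimuth=360.0)
    with pytest.raises(ValueError):
        sg.SceneSpec(
            seed=0,
            objects=(sg.ObjectSpec("tree", cx=5.0, base_y=250.0, w=50.0, h=80.0,
                                   color=(60, 110, 55)),),
        )
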