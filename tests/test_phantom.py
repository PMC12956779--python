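"""Unit tests for the phantom generator and its analytic ground truth."""

import dataclasses

import numpy as np
import pytest

from cordmorph import (LABELS, build_default_config, match_csf_total,
                       render_phantom, shrink_volume, subset_config,
                       truth_value)
from cordmorph.phantom import (REFERENCE_DORSAL_COUNTS,
                               REFERENCE_VENTRAL_COUNTS, SEGMENT_NAMES,
                               ResolutionError, bend_volume, validate_config)


def test_default_config_covers_c3_to_s2():
    cfg = build_default_config(seed=1, spacing=0.1)
    assert [s.segment_id for s in cfg.segments] == list(SEGMENT_NAMES)
    assert len(cfg.segments) == 28
    # contiguous z-ranges
    for a, b in zip(cfg.segments, cfg.segments[1:]):
        assert a.z_range[1] == pytest.approx(b.z_range[0])


def test_default_config_uses_reference_counts():
    cfg = build_default_config(seed=1, spacing=0.1)
    by_id = {s.segment_id: s for s in cfg.segments}
    for name, n in REFERENCE_DORSAL_COUNTS.items():
        assert by_id[name].n_dorsal_rootlets == n
    for name, n in REFERENCE_VENTRAL_COUNTS.items():
        assert by_id[name].n_ventral_rootlets == n


def test_render_is_deterministic():
    cfg = subset_config(build_default_config(seed=7, spacing=0.1), ["C6"])
    v1, t1 = render_phantom(cfg)
    v2, t2 = render_phantom(cfg)
    assert np.array_equal(v1.array, v2.array)
    assert t1.equals(t2)


def test_seed_changes_jittered_shells_only():
    c1 = build_default_config(seed=1, spacing=0.1)
    c2 = build_default_config(seed=2, spacing=0.1)
    s1, s2 = c1.segments[0], c2.segments[0]
    # deterministic morphometric dimensions are unchanged
    assert s1.D1 == s2.D1 and s1.D2 == s2.D2 and s1.D7 == s2.D7
    # jitter perturbs shell thicknesses
    assert s1.dura_thickness != s2.dura_thickness


def test_render_contains_all_labels(small_volume):
    present = set(np.unique(small_volume.array))
    assert set(LABELS.values()) <= present


def test_truth_table_has_per_side_shell_records(small_truth):
    for side in ("dorsal", "ventral", "left", "right"):
        v = truth_value(small_truth, "C6", "dura_thickness", side)
        assert 83.0 <= v <= 135.0          # micrometres, configured band
    with pytest.raises(KeyError):
        truth_value(small_truth, "C6", "no_such_quantity")


def test_truth_csf_volume_close_to_voxel_count(small_config, small_volume,
                                               small_truth):
    seg = next(s for s in small_config.segments if s.segment_id == "C6")
    zsl = small_volume.z_slice_range(*seg.z_range)
    n = int((small_volume.array[:, :, zsl] == LABELS["csf"]).sum())
    voxel = n * small_volume.voxel_volume()
    analytic = truth_value(small_truth, "C6", "csf_volume")
    assert voxel == pytest.approx(analytic, rel=0.03)


def test_resolution_guard():
    cfg = subset_config(build_default_config(seed=1, spacing=0.1), ["C6"])
    coarse = dataclasses.replace(cfg, spacing=0.2)
    with pytest.raises(ResolutionError):
        render_phantom(coarse)


def test_validate_config_rejects_inverted_horn_depths():
    cfg = subset_config(build_default_config(seed=1, spacing=0.1), ["C6"])
    seg = dataclasses.replace(cfg.segments[0], D7=cfg.segments[0].D6 / 2)
    bad = dataclasses.replace(cfg, segments=[seg])
    with pytest.raises(ValueError):
        validate_config(bad)


def test_match_csf_total_hits_target():
    cfg = subset_config(build_default_config(seed=1, spacing=0.1),
                        ["C5", "C6", "C7"])
    target = 500.0
    tuned = match_csf_total(cfg, target)
    _, truth = render_phantom(tuned)
    total = truth.loc[truth["quantity"] == "csf_volume", "value"].sum()
    assert total == pytest.approx(target, rel=1e-6)


def test_shrink_volume_scales_extents(small_volume):
    shrunk = shrink_volume(small_volume, (10.0, 10.0, 45.0))
    # shrinkage inverts the elongation percentages: new = old / (1 + e/100)
    assert shrunk.shape[0] == pytest.approx(small_volume.shape[0] / 1.10, abs=1)
    assert shrunk.shape[2] == pytest.approx(
        small_volume.shape[2] / 1.45, abs=1)


def test_bend_volume_shifts_by_sine(small_volume):
    from cordmorph import pad_volume
    padded = pad_volume(small_volume, 2.5, axes=(0,))
    bent = bend_volume(padded, amplitude=2.0, wavelength=60.0)
    assert bent.shape == padded.shape
    # per-slice voxel counts are preserved (integer in-plane shifts)
    assert np.array_equal(
        (bent.array > 0).sum(axis=(0, 1)), (padded.array > 0).sum(axis=(0, 1)))
    assert "true_centerline" in bent.meta
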