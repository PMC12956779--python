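"""Unit tests for segmental morphometry on the shared three-segment phantom."""

import numpy as np
import pytest

from cordmorph import (LABELS, count_rootlets, cross_section_metrics,
                       csf_segment_volume, dural_circumference, measure_all,
                       measure_drg, radial_thickness, rootlet_coverage,
                       rootlet_zone_metrics, truth_value)

def _seg(cfg, name):
    return next(s for s in cfg.segments if s.segment_id == name)


def test_count_rootlets_matches_config(small_config, small_volume):
    for seg in small_config.segments:
        assert count_rootlets(small_volume, seg.z_range, "dorsal") == \
            seg.n_dorsal_rootlets
        assert count_rootlets(small_volume, seg.z_range, "ventral") == \
            seg.n_ventral_rootlets


def test_csf_segment_volume_equals_voxel_count(small_config, small_volume):
    seg = _seg(small_config, "C6")
    zsl = small_volume.z_slice_range(*seg.z_range)
    n = int((small_volume.array[:, :, zsl] == LABELS["csf"]).sum())
    got = csf_segment_volume(small_volume, seg.z_range)
    assert got == pytest.approx(n * small_volume.voxel_volume())


def test_radial_thickness_recovers_configured_shells(small_config,
                                                     small_volume):
    # at 0.1 mm a ~0.12 mm shell quantizes to 1-2 voxels; allow 1 voxel
    seg = _seg(small_config, "C6")
    for side in ("dorsal", "ventral", "left", "right"):
        t_um = radial_thickness(small_volume, seg.z_range, "dura", side)
        assert abs(t_um - seg.dura_thickness[side]) <= 100.0
        c_um = radial_thickness(small_volume, seg.z_range, "csf", side)
        assert abs(c_um - seg.csf_gap[side]) <= 100.0


def test_radial_thickness_rejects_bad_arguments(small_volume, small_config):
    import numpy as np
    from cordmorph import VoxelLabelVolume
    seg = _seg(small_config, "C6")
    with pytest.raises(ValueError):
        radial_thickness(small_volume, seg.z_range, "dura", "oblique")
    empty = VoxelLabelVolume(np.zeros((20, 20, 10), dtype=np.int16),
                             (0.1, 0.1, 0.1))
    with pytest.raises(ValueError):
        radial_thickness(empty, (0.0, 1.0), "dura", "dorsal")


def test_cross_section_metrics_match_truth(small_config, small_volume,
                                           small_truth):
    seg = _seg(small_config, "C6")
    z_mid = 0.5 * (seg.z_range[0] + seg.z_range[1])
    m = cross_section_metrics(small_volume, z_mid)
    sx = small_volume.spacing[0]
    for q in ("D1", "D2"):
        assert abs(m[q] - truth_value(small_truth, "C6", q)) <= 2 * sx, q
    for q in ("D3", "D4", "D5", "D6", "D7"):
        for side in ("left", "right"):
            t = truth_value(small_truth, "C6", q, side)
            assert abs(m[q][side] - t) <= 2 * sx, (q, side)
    for q in ("A1", "A2"):
        t = truth_value(small_truth, "C6", q)
        assert m[q] == pytest.approx(t, rel=0.05), q
    # cord perimeter (sub-voxel contour) within 1% of the analytic ellipse
    assert m["C1"] == pytest.approx(truth_value(small_truth, "C6", "C1"),
                                    rel=0.01)


def test_dural_circumference_close_to_truth(small_config, small_volume,
                                            small_truth):
    seg = _seg(small_config, "C6")
    c = dural_circumference(small_volume, seg.z_range)
    t = truth_value(small_truth, "C6", "dura_circumference")
    assert c == pytest.approx(t, rel=0.02)


def test_rootlet_zone_metrics_recover_truth(small_config, small_volume,
                                            small_truth):
    seg = _seg(small_config, "C6")
    w, l_rez, _ = rootlet_zone_metrics(small_volume, seg.z_range, "dorsal")
    assert w == pytest.approx(
        truth_value(small_truth, "C6", "W_D", "dorsal"), abs=0.3)
    assert l_rez == pytest.approx(
        truth_value(small_truth, "C6", "L_DREZ", "dorsal"), abs=0.3)


def test_rootlet_coverage_in_unit_range_and_near_truth(small_config,
                                                       small_volume,
                                                       small_truth):
    seg = _seg(small_config, "C6")
    for view in ("dorsal", "ventral", "left", "right"):
        p = rootlet_coverage(small_volume, seg.z_range, view)
        assert 0.0 <= p <= 100.0
    p_d = rootlet_coverage(small_volume, seg.z_range, "dorsal")
    t_d = truth_value(small_truth, "C6", "rootlet_proportion", "dorsal")
    assert abs(p_d - t_d) <= 5.0


def test_measure_drg_finds_both_sides(small_config, small_volume):
    drg = measure_drg(small_volume, small_config.segment_table())
    by_seg = drg.groupby("segment")["side"].nunique()
    assert (by_seg == 2).all()
    seg = _seg(small_config, "C6")
    row = drg[(drg["segment"] == "C6") & (drg["side"] == "left")].iloc[0]
    # 0.1 mm voxels: principal-axis lengths within 2 voxels of configured axes
    assert abs(row["L_DRG"] - seg.drg_axes[0]) <= 0.2
    assert abs(row["W_DRG"] - seg.drg_axes[1]) <= 0.2


def test_measure_all_structure(small_config, small_volume):
    table = measure_all(small_volume, small_config.segment_table())
    assert set(table.columns) == {"segment", "quantity", "side_or_view",
                                  "value", "units", "method_version", "reason"}
    assert set(table["segment"]) == {"C5", "C6", "C7"}
    # every record carries the method version; failures carry a reason instead
    ok = table["value"].notna()
    assert (table.loc[ok, "method_version"] != "").all()
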