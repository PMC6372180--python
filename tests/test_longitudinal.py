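"""Tumour tracking, growth tables and Welch group statistics."""

import numpy as np
import pytest

from crbssfp import longitudinal, quantify, register
from crbssfp.errors import InvalidParameterError, UntrackableError
from crbssfp.longitudinal import Correspondence, build_growth_table, group_stats
from crbssfp.quantify import Mask
from crbssfp.register import AUTO, FAIL, MANUAL, RigidTransform
from crbssfp.tables import load_table_fixtures

SPACING = (0.4, 0.4, 0.4)


def blob_mask(shape, centre, r=2):
    data = np.zeros(shape, bool)
    sl = tuple(slice(max(c - r, 0), c + r + 1) for c in centre)
    data[sl] = True
    return Mask(data, SPACING)


def test_identity_tracking_links_everything():
    masks = [(i, blob_mask((32, 32, 32), c))
             for i, c in enumerate([(8, 8, 8), (20, 20, 20), (8, 22, 10)], 1)]
    corr = longitudinal.track_tumours(masks, masks, RigidTransform.identity(), AUTO)
    assert corr.links == {1: 1, 2: 2, 3: 3}
    assert corr.new_t2 == ()
    assert corr.unmatched_t1 == ()


def test_fail_tier_is_untrackable():
    masks = [(1, blob_mask((16, 16, 16), (8, 8, 8)))]
    with pytest.raises(UntrackableError):
        longitudinal.track_tumours(masks, masks, RigidTransform.identity(), FAIL)


def test_manual_override_rewires_links():
    t1 = [(1, blob_mask((32, 32, 32), (8, 8, 8))), (2, blob_mask((32, 32, 32), (20, 20, 20)))]
    t2 = [(7, blob_mask((32, 32, 32), (8, 8, 8))), (8, blob_mask((32, 32, 32), (20, 20, 20)))]
    corr = longitudinal.track_tumours(t1, t2, RigidTransform.identity(), MANUAL,
                                      manual_links={8: None})
    assert corr.links == {7: 1}
    assert corr.new_t2 == (8,)


def test_tracking_recovers_truth_on_evolved_phantom(scene64, evolved64):
    """Grown tumours link to themselves; late-only tumours come out NEW."""
    m13 = Mask(scene64.lung_mask(), scene64.spacing)
    m18 = Mask(evolved64.lung_mask(), evolved64.spacing)
    tf, d, tier, _ = register.register_and_qc(m13, m18)
    assert tier == AUTO
    t1 = [(tid, Mask(scene64.tumour_mask(tid), scene64.spacing))
          for tid in sorted(scene64.tumour_truth)]
    t2 = [(tid, Mask(evolved64.tumour_mask(tid), evolved64.spacing))
          for tid in sorted(evolved64.tumour_truth)]
    corr = longitudinal.track_tumours(t1, t2, tf, tier)
    old = set(scene64.tumour_truth)
    assert corr.links == {tid: tid for tid in old}
    assert set(corr.new_t2) == set(evolved64.tumour_truth) - old


def test_many_new_tumours_pattern(seq64):
    """5 early tumours, 18 late: 5 links and 13 NEW, as in the most
    tumour-laden reference mouse."""
    from crbssfp import phantom

    scene = phantom.make_scene(
        n_tumours=5, tumour_volume_range=(0.256, 0.6), lung_volume_target=440.0,
        seed=21, shape=tuple(seq64.matrix), spacing=seq64.voxel_size_mm,
        growth_headroom=3.0,
    )
    evolved = phantom.evolve_scene(
        scene, growth_factors={tid: 2.5 for tid in scene.tumour_truth},
        new_tumours=13, seed=22,
    )
    t1 = [(tid, Mask(scene.tumour_mask(tid), scene.spacing))
          for tid in sorted(scene.tumour_truth)]
    t2 = [(tid, Mask(evolved.tumour_mask(tid), evolved.spacing))
          for tid in sorted(evolved.tumour_truth)]
    corr = longitudinal.track_tumours(t1, t2, RigidTransform.identity(), AUTO)
    assert len(corr.links) == 5
    assert len(corr.new_t2) == 13


def fixture_record(mouse="M1"):
    """Build a growth record for one reference mouse from the fixture table."""
    fx = load_table_fixtures()
    rows = fx.tumour_volumes(mouse)
    links = {}
    vols1, vols2 = {}, {}
    new = []
    for i, row in rows.iterrows():
        vols2[i] = float(row.volume_w18_mm3)
        if np.isnan(row.volume_w13_mm3):
            new.append(i)
        else:
            links[i] = i
            vols1[i] = float(row.volume_w13_mm3)
    corr = Correspondence(links=links, new_t2=tuple(new), unmatched_t1=())
    return build_growth_table(corr, vols1, vols2, (508.0, 488.3), mouse=mouse)


def test_growth_table_reproduces_reference_summaries():
    """The heaviest-burden reference mouse: week-18 TTV 4.848, AVT 0.269,
    SDV 0.160 (population SD), and week-13 TTV 0.560 over 5 tumours."""
    rec = fixture_record("M1")
    assert rec.ttv(1) == pytest.approx(4.848)
    assert rec.avt(1) == pytest.approx(0.269)
    assert rec.sdv(1) == pytest.approx(0.160)
    assert rec.ttv(0) == pytest.approx(0.560)
    assert len(rec.present(0)) == 5 and len(rec.present(1)) == 18


def test_growth_table_layout_renders_absent_as_dash():
    rec = fixture_record("M1")
    table = longitudinal.GrowthTable([rec])
    frame = table.to_frame()
    assert frame.loc["T6", ("M1", "w13")] == "-"
    assert frame.loc["TTV", ("M1", "w18")] == "4.848"
    assert frame.loc["AVT", ("M1", "w18")] == "0.269"


def test_single_tumour_summaries():
    corr = Correspondence(links={1: 1}, new_t2=(), unmatched_t1=())
    rec = build_growth_table(corr, {1: 0.5}, {1: 1.25}, (400.0, 420.0))
    assert rec.avt(0) == rec.ttv(0) == 0.5
    assert rec.sdv(0) == 0.0


def test_all_absent_at_t1():
    corr = Correspondence(links={}, new_t2=(1, 2), unmatched_t1=())
    rec = build_growth_table(corr, {}, {1: 0.2, 2: 0.3}, (400.0, 420.0))
    assert rec.ttv(0) == 0.0
    assert rec.avt(0) is None and rec.sdv(0) is None
    assert rec.ttv(1) == pytest.approx(0.5)


def test_burden_and_zero_lung_volume():
    corr = Correspondence(links={1: 1}, new_t2=(), unmatched_t1=())
    rec = build_growth_table(corr, {1: 4.0}, {1: 8.0}, (400.0, 0.0))
    assert rec.burden_percent(0) == pytest.approx(1.0)  # 4 mm^3 of 400 mm^3
    with pytest.raises(InvalidParameterError):
        rec.burden_percent(1)


def test_summaries_invariant_to_tumour_order():
    fx = load_table_fixtures()
    rows = fx.tumour_volumes("M5")
    vols = rows.volume_w18_mm3.to_numpy()
    rng = np.random.default_rng(0)
    ttv = round(vols.sum(), 3)
    sdv = round(float(np.std(vols)), 3)
    for _ in range(5):
        p = rng.permutation(vols)
        assert round(p.sum(), 3) == ttv
        assert round(float(np.std(p)), 3) == sdv


def test_group_stats_reproduce_reference_lung_volumes():
    """Week-18 mask volumes: controls 434.18 +/- 111.311, urethane group
    444.31 +/- 45.34 (population SDs)."""
    fx = load_table_fixtures()
    stats = group_stats(fx.mask_volumes("control"), fx.mask_volumes("urethane"))
    assert round(stats.mean_a, 2) == 434.18
    assert round(stats.sd_a, 3) == 111.311
    assert round(stats.mean_b, 2) == 444.31
    assert round(stats.sd_b, 2) == 45.34
    assert stats.p_value > 0.05  # group means are not distinguishable


def test_identical_groups_give_t0_p1():
    stats = group_stats([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert stats.t_statistic == 0.0
    assert stats.p_value == 1.0


def test_group_too_small_rejected():
    with pytest.raises(InvalidParameterError):
        group_stats([1.0], [1.0, 2.0])


def test_welch_p_agrees_with_permutation_test():
    """Welch p vs a seeded permutation test of the t statistic."""
    rng = np.random.default_rng(11)
    a = rng.normal(0.8, 1.0, 15)
    b = rng.normal(0.0, 1.5, 15)
    stats = group_stats(a, b)

    def welch_t(x, y):
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        return (x.mean() - y.mean()) / np.sqrt(vx + vy)

    obs = abs(welch_t(a, b))
    pooled = np.concatenate([a, b])
    n_perm = 4000
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        count += abs(welch_t(pooled[:15], pooled[15:])) >= obs
    p_perm = count / n_perm
    assert stats.p_value == pytest.approx(p_perm, abs=0.03)
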