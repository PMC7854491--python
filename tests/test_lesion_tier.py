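import numpy as np
import pandas as pd
import pytest

from connectotier.lesion_tier import (
    BinaryMask,
    TierLabelVolume,
    compare_native_vs_mapped,
    discretise_tier_probability,
    lesion_load_by_region,
    normal_appearing_gm_percent,
    read_binary_mask,
    read_tier_labels,
    tier_probability_map,
    write_volume,
)

AFF = np.diag([2.0, 2.0, 2.0, 1.0])


def mask_of(grid):
    return BinaryMask(grid=np.asarray(grid, bool), affine=AFF)


def tiers_of(grid):
    return TierLabelVolume(grid=np.asarray(grid, int), affine=AFF)


def random_volumes(rng, shape=(8, 8, 8)):
    tiers = tiers_of(rng.integers(0, 6, size=shape))
    wmh = mask_of(rng.random(shape) < 0.3)
    gm = mask_of(rng.random(shape) < 0.4)
    return tiers, wmh, gm


class TestLesionLoad:
    def test_four_of_two_hundred_voxels(self):
        grid = np.zeros((10, 10, 10), int)
        grid.ravel()[:200] = 1
        wmh = np.zeros((10, 10, 10), bool)
        wmh.ravel()[:4] = True
        loads = lesion_load_by_region(tiers_of(grid), mask_of(wmh))
        assert loads[1] == pytest.approx(2.0)

    def test_no_overlap_is_zero(self):
        grid = np.zeros((4, 4, 4), int)
        grid[0] = 2
        wmh = np.zeros((4, 4, 4), bool)
        wmh[3] = True
        loads = lesion_load_by_region(tiers_of(grid), mask_of(wmh))
        assert loads[2] == 0.0

    def test_empty_tier_reported_missing(self):
        grid = np.zeros((4, 4, 4), int)
        grid[0] = 1
        loads = lesion_load_by_region(tiers_of(grid),
                                      mask_of(np.zeros((4, 4, 4))))
        assert np.isnan(loads[3])

    def test_matches_voxel_loop_oracle(self, rng):
        tiers, wmh, _ = random_volumes(rng)
        loads = lesion_load_by_region(tiers, wmh, region_labels=(1, 2, 3, 4, 5))
        for lab in (1, 2, 3, 4, 5):
            size = hit = 0
            for idx in np.ndindex(*tiers.grid.shape):
                if tiers.grid[idx] == lab:
                    size += 1
                    hit += bool(wmh.grid[idx])
            expected = 100.0 * hit / size if size else float("nan")
            if size:
                assert loads[lab] == pytest.approx(expected)

    def test_shape_mismatch_rejected(self, rng):
        tiers, _, _ = random_volumes(rng)
        with pytest.raises(ValueError, match="shape"):
            lesion_load_by_region(tiers, mask_of(np.zeros((4, 4, 4))))

    def test_tierwise_overlap_bounded_by_total(self, rng):
        tiers, wmh, _ = random_volumes(rng)
        total = 0
        for lab in (1, 2, 3, 4, 5):
            region = tiers.grid == lab
            total += int((region & wmh.grid).sum())
        assert total <= int(wmh.grid.sum())

    def test_volume_uses_voxel_volume(self):
        m = mask_of(np.ones((4, 4, 4)))
        assert m.voxel_volume == pytest.approx(0.008)  # 2 mm cube in ml
        assert m.volume_ml == pytest.approx(64 * 0.008)


class TestNormalAppearingGm:
    def test_full_gm_no_lesions(self):
        grid = np.ones((4, 4, 4), int)
        out = normal_appearing_gm_percent(
            tiers_of(grid), mask_of(np.ones((4, 4, 4))),
            mask_of(np.zeros((4, 4, 4))))
        assert out[1] == pytest.approx(100.0)

    def test_gm_fully_lesioned_is_zero(self):
        grid = np.ones((4, 4, 4), int)
        ones = np.ones((4, 4, 4))
        out = normal_appearing_gm_percent(
            tiers_of(grid), mask_of(ones), mask_of(ones))
        assert out[1] == 0.0

    def test_matches_set_difference_oracle(self, rng):
        tiers, wmh, gm = random_volumes(rng)
        out = normal_appearing_gm_percent(tiers, gm, wmh)
        for lab in (1, 2, 3, 4):
            region = tiers.grid == lab
            if not region.any():
                continue
            expected = 100.0 * (region & gm.grid & ~wmh.grid).sum() / region.sum()
            assert out[lab] == pytest.approx(expected)


class TestTierProbabilityMap:
    def test_identical_inputs_give_indicators(self, rng):
        tiers, _, _ = random_volumes(rng)
        maps = tier_probability_map([tiers] * 4)
        assert set(np.unique(maps)) <= {0.0, 1.0}

    def test_two_of_three_subjects(self):
        a = np.zeros((3, 3, 3), int)
        b = np.zeros((3, 3, 3), int)
        a[0, 0, 0] = 1
        b[0, 0, 0] = 1
        c = np.zeros((3, 3, 3), int)
        maps = tier_probability_map([tiers_of(a), tiers_of(b), tiers_of(c)])
        assert maps[0][0, 0, 0] == pytest.approx(2 / 3)

    def test_sums_with_background_to_one(self, rng):
        vols = [random_volumes(rng)[0] for _ in range(5)]
        maps = tier_probability_map(vols)
        na_or_bg = np.mean(
            [np.isin(v.grid, (0, 5)) for v in vols], axis=0)
        np.testing.assert_allclose(maps.sum(axis=0) + na_or_bg, 1.0)

    def test_discretise_argmax_with_low_tie_preference(self):
        maps = np.zeros((4, 2, 1, 1))
        maps[0, 0] = 0.5
        maps[1, 0] = 0.5   # tie between tiers 1 and 2 -> tier 1
        maps[3, 1] = 0.4   # background 0.6 wins
        vol = discretise_tier_probability(maps, AFF)
        assert vol.grid[0, 0, 0] == 1
        assert vol.grid[1, 0, 0] == 0


class TestNiftiRoundTrip:
    def test_mask_and_labels_preserve_affine(self, tmp_path, rng):
        tiers, wmh, _ = random_volumes(rng)
        write_volume(wmh.grid, AFF, tmp_path / "wmh.nii")
        write_volume(tiers.grid, AFF, tmp_path / "tiers.nii.gz")
        m = read_binary_mask(tmp_path / "wmh.nii")
        t = read_tier_labels(tmp_path / "tiers.nii.gz")
        np.testing.assert_array_equal(m.grid, wmh.grid)
        np.testing.assert_array_equal(t.grid, tiers.grid)
        np.testing.assert_allclose(m.affine, AFF)

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            tiers_of(np.full((3, 3, 3), 9))


def load_frame(values_by_tier, n):
    rows = []
    for s in range(n):
        for t in (1, 2, 3, 4):
            rows.append({"subject_id": f"s{s}", "tier": t,
                         "wmh_percent": values_by_tier[t][s]})
    return pd.DataFrame(rows)


class TestCompareNativeVsMapped:
    def test_identical_tables_degenerate(self, rng):
        vals = {t: rng.random(8) * 5 for t in (1, 2, 3, 4)}
        native = load_frame(vals, 8)
        out = compare_native_vs_mapped(native, native.copy(), seed=0)
        assert out["signed_rank_p"].isna().all()  # all differences zero
        np.testing.assert_allclose(out["pearson_r"], 1.0)

    def test_dominating_shift_detected_exactly(self, rng):
        vals = {t: rng.random(6) * 5 for t in (1, 2, 3, 4)}
        # strictly positive, distinct shifts: one-sided dominance with
        # untied |differences|, so the exact path applies
        shift = 1.0 + np.arange(6) * 0.01
        shifted = {t: v + shift for t, v in vals.items()}
        out = compare_native_vs_mapped(load_frame(vals, 6),
                                       load_frame(shifted, 6), seed=0)
        # all six differences share one sign: exact two-sided p = 2/2^6
        np.testing.assert_allclose(out["signed_rank_p"], 2 / 64)

    def test_subject_mismatch_rejected(self, rng):
        vals = {t: rng.random(5) for t in (1, 2, 3, 4)}
        native = load_frame(vals, 5)
        mapped = load_frame(vals, 5)
        mapped.loc[0, "subject_id"] = "zz"
        with pytest.raises(ValueError, match="mismatch"):
            compare_native_vs_mapped(native, mapped)

    def test_planted_tier_one_shift_recovered(self):
        detected = 0
        false_pos = {2: 0, 3: 0, 4: 0}
        runs = 30
        for run in range(runs):
            r = np.random.default_rng(run)
            base = {t: r.random(20) * 2 for t in (1, 2, 3, 4)}
            mapped = {t: v + r.normal(0, 0.3, 20) for t, v in base.items()}
            mapped[1] = mapped[1] + 0.8  # planted shift in tier 1 only
            out = compare_native_vs_mapped(load_frame(base, 20),
                                           load_frame(mapped, 20), seed=run)
            p = out.set_index("tier")["signed_rank_p"]
            detected += p[1] < 0.05
            for t in (2, 3, 4):
                false_pos[t] += p[t] < 0.05
        assert detected >= 0.9 * runs
        for t in (2, 3, 4):  # null tiers stay near the nominal level
            assert false_pos[t] <= 0.15 * runs
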