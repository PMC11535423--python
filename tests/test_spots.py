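"""Spot-caller unit tests: each stage against its brute-force oracle, plus
the geometric and statistical invariants of the full pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellquant.spots import (
    ImageStack,
    SpheroidRadii,
    SpotCallingConfig,
    SpotCandidate,
    call_spots,
    count_spots_per_cell,
    find_local_maxima,
    glass_delta,
    iterative_effect_size_filter,
    merge_resolution_limited,
    prefilter,
    resolution_spheroid_radii,
    segment_spot_signal,
    _peaks_mask,
    _spheroid_offsets,
    _within_spheroid,
)
from cellquant.synth import StackSimParams, generate_smfish_stack

from _oracles import (
    brute_glass_delta,
    brute_iterative_filter,
    brute_local_maxima,
    brute_otsu_mask,
)


class TestResolutionSpheroid:
    def test_worked_optical_example(self):
        """A 1.4 NA objective at 668 nm emission resolves 0.291 µm laterally."""
        r = resolution_spheroid_radii(1.4, 668.0)
        assert round(r.r_xy_um, 3) == 0.291
        assert r.r_z_um == 1.0

    def test_lateral_radius_linear_in_wavelength(self):
        r1 = resolution_spheroid_radii(1.4, 500.0)
        r2 = resolution_spheroid_radii(1.4, 1000.0)
        assert r2.r_xy_um == pytest.approx(2 * r1.r_xy_um)

    def test_direct_formula_evaluation(self):
        """0.61 * 0.5 µm / 1.0 = 0.305 µm."""
        r = resolution_spheroid_radii(1.0, 500.0)
        assert r.r_xy_um == pytest.approx(0.305)

    def test_voxel_radii_use_voxel_sizes(self):
        r = resolution_spheroid_radii(1.4, 668.0, voxel_size_z=0.25, pixel_size_xy=0.1)
        assert r.r_z_vox == pytest.approx(r.r_z_um / 0.25)
        assert r.r_xy_vox == pytest.approx(r.r_xy_um / 0.1)

    @pytest.mark.parametrize("na,wl", [(0.0, 668.0), (1.4, 0.0), (-1.0, 500.0)])
    def test_nonpositive_inputs_rejected(self, na, wl):
        with pytest.raises(ValueError):
            resolution_spheroid_radii(na, wl)


class TestPrefilter:
    def test_constant_stack_unchanged(self):
        stack = np.full((6, 8, 8), 7.0)
        assert np.allclose(prefilter(stack, 0.75), 7.0)

    def test_sigma_zero_is_identity(self, rng):
        stack = rng.normal(size=(5, 6, 7))
        np.testing.assert_array_equal(prefilter(stack, 0.0), stack)

    def test_impulse_response_matches_sampled_gaussian(self):
        """Smoothing a unit impulse must reproduce the sampled, normalized
        3D Gaussian kernel (separable closed form)."""
        sigma = 0.75
        stack = np.zeros((21, 21, 21))
        stack[10, 10, 10] = 1.0
        out = prefilter(stack, sigma)
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-(x**2) / (2 * sigma**2))
        k1 /= k1.sum()
        expected = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        region = out[10 - radius : 10 + radius + 1,
                     10 - radius : 10 + radius + 1,
                     10 - radius : 10 + radius + 1]
        np.testing.assert_allclose(region, expected, atol=1e-6)


class TestSegmentation:
    def test_otsu_on_two_level_image_matches_exhaustive_search(self, rng):
        """On a 2-level histogram the Otsu split is forced; compare against
        an exhaustive between-class-variance maximization."""
        flat = np.full(1100, 10.0)
        bright_idx = rng.choice(1100, size=100, replace=False)
        flat[bright_idx] = 200.0
        image = flat.reshape(11, 10, 10)
        mask = segment_spot_signal(image, "otsu")
        np.testing.assert_array_equal(mask, brute_otsu_mask(image))
        assert mask.sum() == 100
        assert np.all(image[mask] == 200.0)

    def test_constant_image_yields_empty_mask_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = segment_spot_signal(np.full((4, 5, 5), 3.0), "otsu")
        assert not mask.any()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="yen"):
            segment_spot_signal(np.zeros((2, 2, 2)), "yen")

    @pytest.mark.parametrize("method", ["triangle", "li", "otsu"])
    def test_all_methods_separate_bright_spot(self, method, rng):
        image = rng.normal(10, 0.5, size=(8, 16, 16))
        image[4, 8, 8] = 100.0
        mask = segment_spot_signal(image, method)
        assert mask[4, 8, 8]


class TestLocalMaxima:
    def test_single_spot_single_candidate(self):
        stack = np.zeros((9, 9, 9))
        stack[4, 4, 4] = 10.0
        stack[4, 4, 5] = 5.0
        mask = stack > 0
        cands = find_local_maxima(stack, mask)
        assert [c.center for c in cands] == [(4, 4, 4)]
        assert cands[0].intensity == 10.0

    def test_two_separated_spots(self):
        stack = np.zeros((9, 20, 9))
        stack[4, 4, 4] = 10.0
        stack[4, 14, 4] = 8.0
        cands = find_local_maxima(stack, stack > 0)
        assert {c.center for c in cands} == {(4, 4, 4), (4, 14, 4)}

    def test_plateau_collapses_to_lexicographic_minimum(self):
        stack = np.zeros((5, 6, 6))
        stack[2, 2:4, 2:4] = 9.0  # 2x2x1 plateau
        cands = find_local_maxima(stack, stack > 0)
        assert [c.center for c in cands] == [(2, 2, 2)]

    def test_matches_brute_force_on_random_stack(self, rng):
        stack = rng.integers(0, 5, size=(7, 10, 10)).astype(float)
        mask = stack >= 2
        module = sorted(c.center for c in find_local_maxima(stack, mask))
        assert module == brute_local_maxima(stack, mask)

    def test_empty_mask_gives_no_candidates(self):
        assert find_local_maxima(np.ones((3, 3, 3)), np.zeros((3, 3, 3), bool)) == []


class TestMerging:
    def _radii(self, pixel=0.1, r_xy=0.291, r_z=1.0, vz=0.24):
        return SpheroidRadii(r_xy_um=r_xy, r_z_um=r_z,
                             r_xy_vox=r_xy / pixel, r_z_vox=r_z / vz)

    def test_peaks_closer_than_lateral_radius_merge_to_brightest(self):
        radii = self._radii()
        cands = [
            SpotCandidate(center=(5, 10, 10), intensity=100.0),
            SpotCandidate(center=(5, 10, 12), intensity=80.0),  # 0.2 µm away
        ]
        kept = merge_resolution_limited(cands, radii)
        assert [c.center for c in kept] == [(5, 10, 10)]

    def test_peaks_beyond_lateral_radius_both_kept(self):
        radii = self._radii()
        cands = [
            SpotCandidate(center=(5, 10, 10), intensity=100.0),
            SpotCandidate(center=(5, 10, 15), intensity=80.0),  # 0.5 µm away
        ]
        assert len(merge_resolution_limited(cands, radii)) == 2

    def test_axial_merge_inside_unit_spheroid(self):
        """Peaks 0.96 µm apart in z: membership value 0.92 <= 1, merged."""
        radii = self._radii()
        cands = [
            SpotCandidate(center=(0, 10, 10), intensity=100.0),
            SpotCandidate(center=(4, 10, 10), intensity=80.0),  # 4 * 0.24 µm
        ]
        assert ((4 * 0.24) / radii.r_z_um) ** 2 == pytest.approx(0.9216)
        kept = merge_resolution_limited(cands, radii)
        assert [c.center for c in kept] == [(0, 10, 10)]

    def test_no_retained_peak_inside_brighter_retained_spheroid(self, rng):
        radii = self._radii()
        cands = [
            SpotCandidate(center=tuple(int(v) for v in c), intensity=float(i))
            for c, i in zip(rng.integers(0, 15, size=(40, 3)), rng.uniform(1, 100, 40))
        ]
        kept = merge_resolution_limited(cands, radii)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert not _within_spheroid(a.center, b.center, radii)

    def test_intensity_tie_broken_lexicographically(self):
        radii = self._radii()
        cands = [
            SpotCandidate(center=(5, 10, 12), intensity=50.0),
            SpotCandidate(center=(5, 10, 10), intensity=50.0),
        ]
        kept = merge_resolution_limited(cands, radii)
        assert [c.center for c in kept] == [(5, 10, 10)]


class TestGlassDelta:
    def test_forced_arithmetic(self, small_radii):
        """Peak voxels all 10 against background of mean 2 and sd 1 gives
        delta = 8 by the defining formula."""
        radii = SpheroidRadii(r_xy_um=0.5, r_z_um=0.5, r_xy_vox=0.5, r_z_vox=0.5)
        data = np.zeros((1, 5, 5))
        cell = np.ones((5, 5), bool)
        data[0, 2, 2] = 10.0  # the single peak voxel (radii < 1 voxel)
        bg = [(y, x) for y in range(5) for x in range(5) if (y, x) != (2, 2)]
        for i, (y, x) in enumerate(bg):
            data[0, y, x] = 1.0 if i < 12 else 3.0
        peaks_mask = np.zeros_like(data, bool)
        peaks_mask[0, 2, 2] = True
        delta = glass_delta(data, (0, 2, 2), cell, peaks_mask, radii)
        assert delta == pytest.approx(8.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        scale=st.floats(min_value=0.01, max_value=100.0),
        shift=st.floats(min_value=-50.0, max_value=50.0),
    )
    def test_affine_invariance(self, scale, shift):
        """Delta is a standardized contrast: unchanged by positive affine
        transforms of the intensities."""
        rng = np.random.default_rng(7)
        data = rng.normal(10, 2, size=(7, 12, 12))
        data[3, 6, 6] += 40
        radii = SpheroidRadii(r_xy_um=2.0, r_z_um=2.0, r_xy_vox=2.0, r_z_vox=2.0)
        cell = np.ones((12, 12), bool)
        mask = _peaks_mask(data.shape, [(3, 6, 6)], _spheroid_offsets(radii))
        d0 = glass_delta(data, (3, 6, 6), cell, mask, radii)
        d1 = glass_delta(scale * data + shift, (3, 6, 6), cell, mask, radii)
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_matches_brute_force_on_simulated_spot(self, small_radii):
        """One isolated simulated spot: module delta equals the voxel-loop
        oracle to 1e-6."""
        rng = np.random.default_rng(5)
        data = np.full((9, 16, 16), 10.0) + rng.normal(0, 2, size=(9, 16, 16))
        zz, yy, xx = np.mgrid[0:9, 0:16, 0:16]
        data += 50.0 * np.exp(
            -((zz - 4.0) ** 2) / (2 * 1.4**2)
            - ((yy - 8.0) ** 2) / (2 * 1.0**2)
            - ((xx - 8.0) ** 2) / (2 * 1.0**2)
        )
        cell = np.ones((16, 16), bool)
        labels = cell.astype(int)
        mask = _peaks_mask(data.shape, [(4, 8, 8)], _spheroid_offsets(small_radii))
        module = glass_delta(data, (4, 8, 8), cell, mask, small_radii)
        oracle = brute_glass_delta(
            data, (4, 8, 8), cell, [(4, 8, 8)],
            small_radii.r_z_vox, small_radii.r_xy_vox,
        )
        assert module == pytest.approx(oracle, abs=1e-6)
        del labels

    def test_degenerate_background_rejected(self, small_radii):
        data = np.full((5, 8, 8), 4.0)
        data[2, 4, 4] = 10.0
        cell = np.ones((8, 8), bool)
        mask = _peaks_mask(data.shape, [(2, 4, 4)], _spheroid_offsets(small_radii))
        with pytest.raises(ValueError, match="degenerate background"):
            glass_delta(data, (2, 4, 4), cell, mask, small_radii)


def _spike_stack():
    """A hand-built one-cell stack engineered so that discarding one dim
    peak inflates the background sd enough to drop a second peak below
    threshold on the next round."""
    rng = np.random.default_rng(3)
    data = 10.0 + rng.normal(0, 0.5, size=(7, 20, 20))
    labels = np.ones((20, 20), dtype=int)
    radii = SpheroidRadii(r_xy_um=2.0, r_z_um=2.0, r_xy_vox=2.0, r_z_vox=2.0)
    # A: clearly real; B: marginal; C: single-voxel spike with low spheroid mean
    offsets = _spheroid_offsets(radii)
    for dz, dy, dx in offsets:
        data[3 + dz, 4 + dy, 4 + dx] += 8.0  # peak A
        data[3 + dz, 4 + dy, 14 + dx] += 1.15  # peak B, just above tau at first
    data[3, 14, 10] += 25.0  # peak C: spike
    centers = [(3, 4, 4), (3, 4, 14), (3, 14, 10)]
    cands = [SpotCandidate(center=c, intensity=float(data[c])) for c in centers]
    return data, labels, radii, cands


class TestIterativeFilter:
    def test_all_above_threshold_pass_through(self, small_radii, rng):
        data = 10.0 + rng.normal(0, 0.5, size=(7, 16, 16))
        labels = np.ones((16, 16), dtype=int)
        for c in [(3, 4, 4), (3, 11, 11)]:
            for dz, dy, dx in _spheroid_offsets(small_radii):
                data[c[0] + dz, c[1] + dy, c[2] + dx] += 10.0
        cands = [
            SpotCandidate(center=(3, 4, 4), intensity=20.0),
            SpotCandidate(center=(3, 11, 11), intensity=20.0),
        ]
        spots = iterative_effect_size_filter(data, cands, labels, small_radii, 2.0)
        assert {s.center for s in spots} == {c.center for c in cands}
        assert all(s.glass_delta >= 2.0 for s in spots)

    def test_empty_candidates_give_empty_result(self, small_radii):
        out = iterative_effect_size_filter(
            np.ones((4, 6, 6)), [], np.ones((6, 6), int), small_radii, 0.5
        )
        assert out == []

    def test_cascaded_discard_matches_brute_force_fixed_point(self):
        """Removing the sub-threshold spike changes the background sd and
        drags a second marginal peak below threshold; final set must match
        the independent fixed-point oracle."""
        data, labels, radii, cands = _spike_stack()
        tau = 2.0
        spots = iterative_effect_size_filter(data, cands, labels, radii, tau)
        oracle_set, history = brute_iterative_filter(
            data, [c.center for c in cands], labels, radii.r_z_vox,
            radii.r_xy_vox, tau,
        )
        assert sorted(s.center for s in spots) == sorted(oracle_set)
        non_empty_rounds = [h for h in history if h]
        assert len(non_empty_rounds) >= 2, "fixture must exercise a cascade"

    def test_final_deltas_match_oracle(self):
        data, labels, radii, cands = _spike_stack()
        spots = iterative_effect_size_filter(data, cands, labels, radii, 2.0)
        survivors = [s.center for s in spots]
        for s in spots:
            lab = labels[s.center[1], s.center[2]]
            oracle = brute_glass_delta(
                data, s.center, labels == lab, survivors,
                radii.r_z_vox, radii.r_xy_vox,
            )
            assert s.glass_delta == pytest.approx(oracle, abs=1e-6)

    def test_peak_count_non_increasing(self):
        data, labels, radii, cands = _spike_stack()
        _, history = brute_iterative_filter(
            data, [c.center for c in cands], labels,
            radii.r_z_vox, radii.r_xy_vox, 2.0,
        )
        assert len(history) <= len(cands) + 1


class TestCallSpots:
    def test_blank_stack_has_no_spots(self, strict_config):
        params = StackSimParams(n_cells=4, n_spots=0, seed=0, shape=(20, 96, 96))
        stack, cells, _, truth = generate_smfish_stack(params)
        assert truth.empty
        table = call_spots(stack, cells, config=strict_config)
        assert len(table) == 0
        counts = count_spots_per_cell(table, cells)
        assert (counts["n_spots"] == 0).all()

    def test_high_snr_spots_all_recovered(self, high_snr_stack, strict_config):
        """30 bright simulated spots: all called, each within one voxel of a
        distinct ground-truth center."""
        stack, cells, _, truth = high_snr_stack
        table = call_spots(stack, cells, config=strict_config)
        assert len(table) == 30
        gt = truth[["z", "y", "x"]].to_numpy()
        called = table[["z_vox", "y_vox", "x_vox"]].to_numpy(dtype=float)
        taken = set()
        for spot in called:
            d = np.linalg.norm(gt - spot, axis=1)
            best = int(np.argmin(d))
            assert d[best] <= 1.0
            assert best not in taken
            taken.add(best)

    def test_cell_assignment_matches_ground_truth(self, high_snr_stack, strict_config):
        stack, cells, _, truth = high_snr_stack
        table = call_spots(stack, cells, config=strict_config)
        called = table.sort_values(["z_vox", "y_vox", "x_vox"]).reset_index(drop=True)
        for _, row in called.iterrows():
            d = np.linalg.norm(
                truth[["z", "y", "x"]].to_numpy()
                - np.array([row.z_vox, row.y_vox, row.x_vox]),
                axis=1,
            )
            assert truth.iloc[int(np.argmin(d))].cell_label == row.cell_id

    def test_unresolvable_pair_called_as_one(self):
        """Two emitters 0.15 µm apart laterally are below the resolution
        limit and must be reported as a single spot."""
        table = _call_close_pair(separation_um=0.15)
        assert len(table) == 1

    def test_resolved_pair_called_as_two(self):
        table = _call_close_pair(separation_um=0.5)
        assert len(table) == 2

    def test_misaligned_mask_rejected(self, strict_config):
        stack = ImageStack(np.zeros((5, 16, 16)), 0.24, 0.103)
        with pytest.raises(ValueError, match="match the stack"):
            call_spots(stack, np.ones((8, 8), int), config=strict_config)


def _call_close_pair(separation_um: float):
    """Build a one-cell stack with two equal emitters a given lateral
    distance apart and run the full caller."""
    pixel, vz = 0.103, 0.24
    rng = np.random.default_rng(11)
    yy, xx = np.mgrid[0:64, 0:64]
    cells = ((((yy - 32) / 28.0) ** 2 + ((xx - 32) / 28.0) ** 2) <= 1).astype(int)
    data = 10.0 * cells[None].repeat(20, axis=0).astype(float)
    sep_px = separation_um / pixel
    zzz, yyy, xxx = np.mgrid[0:20, 0:64, 0:64]
    for xc in (32 - sep_px / 2, 32 + sep_px / 2):
        data += 100.0 * np.exp(
            -((zzz - 10.0) ** 2) / (2 * (0.35 / vz) ** 2)
            - ((yyy - 32.0) ** 2) / (2 * (0.10 / pixel) ** 2)
            - ((xxx - xc) ** 2) / (2 * (0.10 / pixel) ** 2)
        )
    data += rng.normal(0, 2.0, size=data.shape)
    stack = ImageStack(np.clip(data, 0, None), vz, pixel)
    return call_spots(stack, cells, config=SpotCallingConfig(effect_size_threshold=1.0))


class TestDetectionPerformance:
    def test_recall_and_precision_on_seeded_stacks(self, strict_config):
        """Bright, well-separated spots: recall and precision both >= 0.95
        over several seeded stacks."""
        tp = fp = fn = 0
        for seed in (1, 2, 3, 4):
            params = StackSimParams(
                n_cells=6, n_spots=5, spot_amplitude=100.0, seed=seed,
                shape=(20, 128, 128),
            )
            stack, cells, _, truth = generate_smfish_stack(params)
            table = call_spots(stack, cells, config=strict_config)
            gt = truth[["z", "y", "x"]].to_numpy()
            taken = set()
            for _, row in table.iterrows():
                d = np.linalg.norm(
                    gt - np.array([row.z_vox, row.y_vox, row.x_vox]), axis=1
                )
                best = int(np.argmin(d))
                if d[best] <= 2.0 and best not in taken:
                    taken.add(best)
                    tp += 1
                else:
                    fp += 1
            fn += len(gt) - len(taken)
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95
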