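"""Unit tests for penalty-graph construction and phasor selection."""

import numpy as np
import pytest

import dixonsep as dx
from dixonsep.selector import _reselect, upsample_phasor
from conftest import random_graph


def two_pixel_graph(p_r=1.0 + 0j, p_s=-1.0 + 0j):
    """1x2 image, |S1| = (2, 3), horizontal nearest-neighbor offsets."""
    s1 = np.array([[2.0, 3.0]])
    p1 = np.array([[p_r, p_s]])
    p2 = np.array([[p_r, p_s]])
    nbrs = dx.NeighborSpec(offsets=((0, 1), (0, -1)))
    return dx.build_penalty_graph(s1, p1, p2, nbrs)


class TestNeighborSpec:
    def test_disk_radius_4_has_48_offsets(self):
        assert len(dx.NeighborSpec.disk(4.0).offsets) == 48

    def test_rejects_center_and_duplicates(self):
        with pytest.raises(ValueError):
            dx.NeighborSpec(offsets=((0, 0), (0, 1)))
        with pytest.raises(ValueError):
            dx.NeighborSpec(offsets=((0, 1), (0, 1)))
        with pytest.raises(ValueError):
            dx.NeighborSpec(offsets=())


class TestPenaltyGraph:
    def test_identical_phasor_maps_give_zero_blocks(self):
        p = np.full((5, 5), np.exp(0.3j))
        g = dx.build_penalty_graph(np.ones((5, 5)), p, p, dx.NeighborSpec.disk(2))
        for blk in g.blocks.values():
            np.testing.assert_allclose(blk, 0.0, atol=1e-15)

    def test_hand_computed_two_pixel_penalty(self):
        g = two_pixel_graph()
        blk = g.block((0, 0), (0, 1))
        # min(2,3)/1 * |1 - (-1)|^2 = 8 for every candidate pair here
        np.testing.assert_allclose(blk, 8.0)

    def test_out_of_neighborhood_pairs_have_no_block(self):
        g = dx.build_penalty_graph(
            np.ones((6, 6)), np.ones((6, 6), complex), np.ones((6, 6), complex),
            dx.NeighborSpec.disk(1.0),
        )
        assert g.has_block((0, 0), (0, 1))
        assert not g.has_block((0, 0), (0, 3))  # outside radius
        assert not g.has_block((0, 0), (-1, 0))  # outside image
        assert g.block((0, 0), (0, 3)) is None

    def test_distance_divides_penalty(self):
        s1 = np.ones((1, 3))
        p1 = np.array([[1.0, 1.0, -1.0]], dtype=complex)
        g = dx.build_penalty_graph(s1, p1, p1, dx.NeighborSpec(offsets=((0, 2), (0, -2))))
        np.testing.assert_allclose(g.block((0, 0), (0, 2)), 4.0 / 2.0)


class TestSelectionEnergy:
    def test_zero_graph_energy_zero_for_any_labels(self):
        p = np.ones((3, 3), complex)
        g = dx.build_penalty_graph(np.ones((3, 3)), p, p, dx.NeighborSpec.disk(1))
        rng = np.random.default_rng(0)
        labels = rng.integers(1, 3, (3, 3))
        assert dx.selection_energy(g, labels) == 0.0

    def test_two_pixel_energy_counts_ordered_pairs(self):
        g = two_pixel_graph()
        assert dx.selection_energy(g, np.array([[1, 1]])) == pytest.approx(16.0)

    def test_candidate_relabeling_symmetry(self):
        rng = np.random.default_rng(7)
        s1 = rng.uniform(0.1, 1, (4, 4))
        p1 = np.exp(1j * rng.uniform(-np.pi, np.pi, (4, 4)))
        p2 = np.exp(1j * rng.uniform(-np.pi, np.pi, (4, 4)))
        nbrs = dx.NeighborSpec.disk(2)
        g = dx.build_penalty_graph(s1, p1, p2, nbrs)
        g_sw = dx.build_penalty_graph(s1, p2, p1, nbrs)
        labels = rng.integers(1, 3, (4, 4))
        flipped = 3 - labels
        assert dx.selection_energy(g, labels) == pytest.approx(
            dx.selection_energy(g_sw, flipped)
        )

    def test_rejects_invalid_labels(self):
        g = two_pixel_graph()
        with pytest.raises(ValueError):
            dx.selection_energy(g, np.array([[0, 1]]))


class TestBruteForce:
    def test_zero_graph_tie_breaks_to_all_ones(self):
        p = np.ones((1, 3), complex)
        g = dx.build_penalty_graph(np.ones((1, 3)), p, p, dx.NeighborSpec(offsets=((0, 1), (0, -1))))
        sel = dx.brute_force_select(g)
        np.testing.assert_array_equal(sel.labels, 1)
        assert sel.energy == 0.0

    def test_finds_unique_zero_penalty_assignment(self):
        # p1 at pixel 0 matches p2 at pixel 1; all other pairs clash
        s1 = np.array([[1.0, 1.0]])
        p1 = np.array([[1.0 + 0j, -1.0 + 0j]])
        p2 = np.array([[-1.0 + 0j, 1.0 + 0j]])
        g = dx.build_penalty_graph(s1, p1, p2, dx.NeighborSpec(offsets=((0, 1), (0, -1))))
        sel = dx.brute_force_select(g)
        np.testing.assert_array_equal(sel.labels, [[1, 2]])
        assert sel.energy == 0.0

    def test_beats_random_labelings(self):
        g = random_graph(99, shape=(2, 4))
        sel = dx.brute_force_select(g)
        rng = np.random.default_rng(1)
        for _ in range(50):
            labels = rng.integers(1, 3, (2, 4))
            assert sel.energy <= dx.selection_energy(g, labels) + 1e-12

    def test_refuses_large_graphs(self):
        g = random_graph(0, shape=(5, 5))
        with pytest.raises(ValueError, match="refuses"):
            dx.brute_force_select(g)


class TestProjectedPower:
    def test_zero_graph_returns_init_unchanged(self):
        p = np.ones((3, 3), complex)
        g = dx.build_penalty_graph(np.ones((3, 3)), p, p, dx.NeighborSpec.disk(1))
        sel = dx.projected_power_select(g)
        assert sel.converged
        assert sel.iterations == 1
        np.testing.assert_array_equal(sel.labels, 1)

    def test_matches_oracle_on_most_random_graphs(self):
        equal = 0
        for k in range(20):
            g = random_graph(500 + k)
            bf = dx.brute_force_select(g)
            pp = dx.projected_power_select(g)
            assert pp.energy >= bf.energy - 1e-9
            assert pp.energy <= 1.1 * bf.energy + 1e-12
            if pp.energy <= bf.energy + 1e-9 * max(1.0, bf.energy):
                equal += 1
        assert equal >= 18

    def test_energy_history_non_increasing_and_consistent(self):
        g = random_graph(321)
        sel = dx.projected_power_select(g)
        hist = sel.meta["energy_history"]
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))
        assert sel.energy == pytest.approx(dx.selection_energy(g, sel.labels))

    def test_recovers_true_labels_on_smooth_phantom(self):
        truth = dx.generate_phantom(dx.smooth_spec(shape=(32, 32)), seed=5)
        img = dx.simulate_acquisition(truth, noise_sigma=0.0)
        res = dx.separate_dual_echo(img)
        labels_true = dx.true_labels(truth)
        tissue = (truth.tissue_mask > 0) & (
            np.abs(truth.water - truth.fat) > 0.05 * truth.water.max()
        )
        agree = (res.selection == labels_true)[tissue].mean()
        assert agree >= 0.99

    def test_rejects_bad_max_iter(self):
        g = random_graph(1)
        with pytest.raises(ValueError):
            dx.projected_power_select(g, max_iter=0)


class TestResampling:
    def test_downsample_identity_and_constant(self):
        img = np.full((4, 4), 2.0 + 1.0j)
        np.testing.assert_array_equal(dx.downsample_complex(img, 1), img)
        out = dx.downsample_complex(img, 2)
        assert out.shape == (2, 2)
        np.testing.assert_allclose(out, 2.0 + 1.0j)

    def test_downsample_block_mean(self):
        img = np.array([[1.0 + 0j, 1j], [-1.0 + 0j, -1j]])
        np.testing.assert_allclose(dx.downsample_complex(img, 2), 0.0, atol=1e-15)

    def test_downsample_partial_blocks_average_actual_size(self):
        img = np.arange(15, dtype=float).reshape(3, 5).astype(complex)
        out = dx.downsample_complex(img, 2)
        assert out.shape == (2, 3)
        # trailing column block is a single column; trailing row block one row
        np.testing.assert_allclose(out[0, 2], (4 + 9) / 2)
        np.testing.assert_allclose(out[1, 0], (10 + 11) / 2)
        np.testing.assert_allclose(out[1, 2], 14.0)

    def test_downsample_rejects_bad_factor(self):
        with pytest.raises(ValueError):
            dx.downsample_complex(np.ones((4, 4), complex), 5)
        with pytest.raises(ValueError):
            dx.downsample_complex(np.ones((4, 4), complex), 0)

    def test_upsample_constant_and_unit_modulus(self):
        p = np.full((4, 4), np.exp(0.7j))
        up = upsample_phasor(p, (9, 9))
        np.testing.assert_allclose(up, np.exp(0.7j), atol=1e-12)
        rng = np.random.default_rng(2)
        p = np.exp(1j * rng.uniform(-np.pi, np.pi, (4, 4)))
        up = upsample_phasor(p, (8, 8))
        np.testing.assert_allclose(np.abs(up), 1.0, atol=1e-12)

    def test_upsample_linear_phase_ramp(self):
        y = np.linspace(0, 1.5, 16)
        ramp = np.tile(y, (16, 1))
        up = upsample_phasor(np.exp(1j * ramp), (32, 32))
        y2 = np.linspace(0, 1.5, 16)
        # compare against the analytic ramp at the interpolated grid
        from skimage.transform import resize
        ramp_up = resize(ramp, (32, 32), order=1, mode="edge", anti_aliasing=False)
        dev = np.abs(np.angle(up * np.exp(-1j * ramp_up)))
        assert dev[4:-4, 4:-4].max() < 0.05


class TestSeparatePipeline:
    def test_noiseless_smooth_phantom_exact(self, smooth_truth, noiseless_img):
        res = dx.separate_dual_echo(noiseless_img, downsample_factor=1)
        assert np.abs(res.water - smooth_truth.water).max() < 1e-6
        assert np.abs(res.fat - smooth_truth.fat).max() < 1e-6

    def test_multiresolution_factor_4_close(self, smooth_truth, noiseless_img):
        res = dx.separate_dual_echo(noiseless_img, downsample_factor=4)
        rel = np.abs(res.water - smooth_truth.water).sum() / smooth_truth.water.sum()
        assert rel < 0.02

    def test_factor_1_vs_2_resolution_consistency(self, noiseless_img):
        r1 = dx.separate_dual_echo(noiseless_img, downsample_factor=1)
        r2 = dx.separate_dual_echo(noiseless_img, downsample_factor=2)
        rel = np.abs(r1.water - r2.water).sum() / max(r1.water.sum(), 1e-30)
        assert rel < 0.01

    def test_amplitude_upsampling_mode_runs_coarse(self, smooth_truth, noiseless_img):
        # the literal upsample-water/fat ordering blurs tissue boundaries at
        # coarse factors; it should still be globally consistent with truth
        res = dx.separate_dual_echo(noiseless_img, downsample_factor=4,
                                    upsample_mode="amplitude")
        rel = np.abs(res.water - smooth_truth.water).sum() / smooth_truth.water.sum()
        assert rel < 0.5
        assert dx.swapped_fraction(res.water, res.fat, smooth_truth) < 0.15

    def test_swap_robustness_vs_baseline(self):
        truth = dx.generate_phantom(dx.swap_inducing_spec(), seed=3)
        img = dx.simulate_acquisition(truth, noise_sigma=0.0)
        base = dx.separate_no_smoothness(img)
        full = dx.separate_dual_echo(img)
        sf_base = dx.swapped_fraction(base.water, base.fat, truth)
        sf_full = dx.swapped_fraction(full.water, full.fat, truth)
        assert sf_base >= 0.10
        assert sf_full <= 0.01

    def test_reselect_candidate_exchange_symmetry(self, noiseless_img, params):
        from dixonsep.selector import _candidates_with_phasors

        cands = _candidates_with_phasors(noiseless_img)
        field = cands.p1
        sel_a, ph_a = _reselect(cands, field)
        swapped = type(cands)(w1=cands.w2, f1=cands.f2, w2=cands.w1, f2=cands.f1,
                              p1=cands.p2, p2=cands.p1,
                              degenerate_mask=cands.degenerate_mask)
        sel_b, ph_b = _reselect(swapped, field)
        # exchanging the candidate maps flips labels but not the chosen phasor
        np.testing.assert_allclose(ph_a, ph_b)
        tie = np.isclose(
            np.abs(np.angle(cands.p1 * np.conj(field))),
            np.abs(np.angle(cands.p2 * np.conj(field))),
        )
        np.testing.assert_array_equal(sel_a[~tie], (3 - sel_b)[~tie])


class TestGlobalSwapCorrect:
    def test_keep_is_identity(self, noiseless_img):
        res = dx.separate_dual_echo(noiseless_img)
        out = dx.global_swap_correct(res, mode="keep")
        np.testing.assert_array_equal(out.water, res.water)
        np.testing.assert_array_equal(out.fat, res.fat)

    def test_swap_is_involution(self, noiseless_img):
        res = dx.separate_dual_echo(noiseless_img)
        twice = dx.global_swap_correct(dx.global_swap_correct(res, "swap"), "swap")
        np.testing.assert_array_equal(twice.water, res.water)
        np.testing.assert_array_equal(twice.selection, res.selection)

    def test_auto_restores_globally_swapped_fat_rim_phantom(self, smooth_truth, noiseless_img):
        res = dx.separate_dual_echo(noiseless_img)
        swapped = dx.global_swap_correct(res, "swap")
        fixed = dx.global_swap_correct(swapped, "auto")
        assert fixed.meta["swapped"]
        np.testing.assert_allclose(fixed.water, smooth_truth.water, atol=1e-6)
        # and a correctly assigned image is left alone
        kept = dx.global_swap_correct(res, "auto")
        assert not kept.meta["swapped"]


def test_downsampling_voxel_ratio_clinical_resolutions():
    ratio = dx.downsampling_voxel_ratio((0.6, 0.6, 1.0), (6.0, 6.0, 6.0))
    assert ratio == pytest.approx(600.0)
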