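import numpy as np
import pytest

from txmkit.io import EnergyStack
from txmkit.phantoms import arctan_edge, default_xanes_phantom, make_xanes_stack
from txmkit.xanes import (
    EdgeConfig,
    ReferenceSet,
    analyze,
    bulk_xanes,
    cluster_by_edge_energy,
    edge_energy_histogram,
    edge_energy_map,
    edge_jump_map,
    jump_vs_rfactor_cluster,
    lc_fit,
    noise_filter,
    normalize_stack,
    rfactor_of,
    rgb_phase_map,
)

from conftest import ENERGIES, normalized_references


def pixel_stack(spectrum, energies):
    """1x1 stack from a single spectrum."""
    return EnergyStack(np.asarray(spectrum)[:, None, None], energies)


class TestEdgeConfig:
    def test_window_ordering_enforced(self):
        with pytest.raises(ValueError, match="pre_lo"):
            EdgeConfig(7110.0, 7090.0, 7150.0, 7180.0, 7120.0)

    def test_sparse_window_rejected(self, edge_cfg):
        energies = np.array([7080.0, 7120.0, 7200.0])
        with pytest.raises(ValueError, match="< 2 energy points"):
            edge_cfg.pre_idx(energies)


class TestEdgeJump:
    def test_constant_spectrum_zero_jump(self, edge_cfg):
        stack = pixel_stack(np.full(50, 0.7), ENERGIES)
        assert edge_jump_map(stack, edge_cfg)[0, 0] == pytest.approx(0.0)

    def test_unit_step(self, edge_cfg):
        spec = np.where(ENERGIES > edge_cfg.e0, 1.0, 0.0)
        stack = pixel_stack(spec, ENERGIES)
        assert edge_jump_map(stack, edge_cfg)[0, 0] == pytest.approx(1.0)

    def test_jump_proportional_to_thickness(self, edge_cfg):
        # thickness scaling a fixed edge profile, flat per-pixel baselines
        phantom = default_xanes_phantom(noise_sigma=0.0, seed=4)
        phantom.baseline_slope[:] = 0.0
        phantom.truth_weights[0] = phantom.truth_weights.sum(axis=0)
        phantom.truth_weights[1:] = 0.0
        stack, truth = make_xanes_stack(phantom, ENERGIES)
        jump = edge_jump_map(stack, edge_cfg)
        inside = phantom.thickness > 0
        r = np.corrcoef(jump[inside], phantom.thickness[inside])[0, 1]
        assert r > 0.999


class TestNoiseFilter:
    @staticmethod
    def _stack_with_known_sigma(jump):
        """Pre-edge samples with sample std exactly 0.01, then a clean jump."""
        energies = np.array([7091.0, 7092.0, 7093.0, 7160.0, 7170.0])
        spec = np.array([0.49, 0.50, 0.51, 0.50 + jump, 0.50 + jump])
        return EnergyStack(spec[:, None, None], energies)

    def test_kept_above_threshold(self):
        cfg = EdgeConfig(7090.0, 7100.0, 7150.0, 7180.0, 7120.0, k=3.0)
        stack = self._stack_with_known_sigma(0.05)
        assert noise_filter(stack, cfg)[0, 0]

    def test_removed_below_threshold(self):
        cfg = EdgeConfig(7090.0, 7100.0, 7150.0, 7180.0, 7120.0, k=3.0)
        stack = self._stack_with_known_sigma(0.02)
        assert not noise_filter(stack, cfg)[0, 0]

    def test_pure_noise_mostly_removed(self, edge_cfg):
        rng = np.random.default_rng(0)
        data = rng.normal(0.0, 0.05, (50, 64, 64))
        stack = EnergyStack(data, ENERGIES)
        mask = noise_filter(stack, edge_cfg)
        assert mask.mean() < 0.05

    def test_monotone_in_k(self, xanes_data):
        _, stack, _, _ = xanes_data
        base_cfg = EdgeConfig(7090.0, 7110.0, 7150.0, 7180.0, 7120.0, k=2.0)
        tight_cfg = EdgeConfig(7090.0, 7110.0, 7150.0, 7180.0, 7120.0, k=4.0)
        loose = noise_filter(stack, base_cfg)
        tight = noise_filter(stack, tight_cfg)
        assert not np.any(tight & ~loose)


class TestNormalize:
    def test_step_with_sloped_baseline(self, edge_cfg):
        # construction: exact line below/above the edge normalizes exactly
        spec = 0.2 + 0.004 * (ENERGIES - 7090.0)
        spec = spec + np.where(ENERGIES > edge_cfg.e0, 1.0, 0.0)
        stack = pixel_stack(spec, ENERGIES)
        norm, mask = normalize_stack(stack, edge_cfg)
        assert mask[0, 0]
        pre = edge_cfg.pre_idx(ENERGIES)
        post = edge_cfg.post_idx(ENERGIES)
        assert norm.data[pre, 0, 0].mean() == pytest.approx(0.0, abs=1e-10)
        assert norm.data[post, 0, 0].mean() == pytest.approx(1.0, abs=1e-10)

    def test_steep_pre_slope_masked(self, edge_cfg):
        spec = 0.2 + 10 * edge_cfg.slope_pre_max * (ENERGIES - 7090.0)
        spec = spec + np.where(ENERGIES > edge_cfg.e0, 1.0, 0.0)
        stack = pixel_stack(spec, ENERGIES)
        norm, mask = normalize_stack(stack, edge_cfg)
        assert not mask[0, 0]
        np.testing.assert_array_equal(norm.data[:, 0, 0], 0.0)

    def test_negative_step_masked(self, edge_cfg):
        spec = 1.0 - np.where(ENERGIES > edge_cfg.e0, 0.8, 0.0)
        stack = pixel_stack(spec, ENERGIES)
        _, mask = normalize_stack(stack, edge_cfg)
        assert not mask[0, 0]

    def test_filter_economy_on_phantom(self, xanes_data, edge_cfg):
        _, stack, _, _ = xanes_data
        nmask = noise_filter(stack, edge_cfg)
        _, norm_mask = normalize_stack(stack, edge_cfg, mask=nmask)
        newly_removed = (nmask & ~norm_mask).sum()
        assert newly_removed / nmask.sum() < 0.01


class TestEdgeEnergy:
    def test_symmetric_bracket_midpoint(self, edge_cfg):
        # oracle: a 0.4 -> 0.6 bracket on consecutive grid energies crosses
        # 0.5 exactly at their midpoint
        i = 17  # a grid point between the pre and post windows
        spec = np.interp(
            ENERGIES,
            [7090.0, ENERGIES[i], ENERGIES[i + 1], 7180.0],
            [0.0, 0.4, 0.6, 1.0],
        )
        stack = pixel_stack(spec, ENERGIES)
        e_half = edge_energy_map(stack, edge_cfg)[0, 0]
        assert e_half == pytest.approx(
            0.5 * (ENERGIES[i] + ENERGIES[i + 1]), abs=1e-9
        )

    def test_arctan_profile_recovered(self, edge_cfg):
        energies = np.arange(7090.0, 7180.5, 0.5)
        cfg = EdgeConfig(7090.0, 7110.0, 7150.0, 7180.0, 7120.0)
        spec = arctan_edge(energies, 7123.0, 1.5)
        stack = EnergyStack(spec[:, None, None], energies)
        e_half = edge_energy_map(stack, cfg)[0, 0]
        assert e_half == pytest.approx(7123.0, abs=0.05)

    def test_decreasing_spectrum_nan(self, edge_cfg):
        spec = np.linspace(1.0, 0.0, 50)
        stack = pixel_stack(spec, ENERGIES)
        assert np.isnan(edge_energy_map(stack, edge_cfg)[0, 0])


class TestEdgeHistogram:
    def test_uniform_map_single_bin(self):
        e_map = np.full((8, 8), 7120.5)
        hist = edge_energy_histogram(e_map, ENERGIES)
        assert hist.counts.sum() == 64
        assert (hist.counts > 0).sum() == 1

    def test_two_phase_modes(self):
        e_map = np.full((4, 8), ENERGIES[15])
        e_map[:, 4:] = ENERGIES[18]  # 3 steps away
        hist = edge_energy_histogram(e_map, ENERGIES)
        occupied = np.where(hist.counts > 0)[0]
        np.testing.assert_array_equal(occupied, [15, 18])
        assert hist.counts[15] == hist.counts[18] == 16

    def test_all_nan_empty(self):
        hist = edge_energy_histogram(np.full((4, 4), np.nan), ENERGIES)
        assert hist.counts.sum() == 0


class TestClusterByEdgeEnergy:
    @staticmethod
    def _two_phase(edge_cfg):
        spec_a = arctan_edge(ENERGIES, 7116.0, 1.5)
        spec_b = arctan_edge(ENERGIES, 7128.0, 1.5)
        data = np.empty((50, 4, 8))
        data[:, :, :4] = spec_a[:, None, None]
        data[:, :, 4:] = spec_b[:, None, None]
        stack = EnergyStack(data, ENERGIES)
        e_map = edge_energy_map(stack, edge_cfg)
        return stack, edge_energy_histogram(e_map, ENERGIES)

    def test_select_everything_labels_all(self, edge_cfg):
        stack, hist = self._two_phase(edge_cfg)
        labels, _ = cluster_by_edge_energy(
            stack, hist, [list(range(50))]
        )
        assert (labels == 1).sum() == 32

    def test_mode_means_match_profiles(self, edge_cfg):
        stack, hist = self._two_phase(edge_cfg)
        occupied = np.where(hist.counts > 0)[0]
        labels, means = cluster_by_edge_energy(
            stack, hist, [[int(b)] for b in occupied]
        )
        assert len(means) == len(occupied)
        spec_a = arctan_edge(ENERGIES, 7116.0, 1.5)
        np.testing.assert_allclose(means[0], spec_a, atol=1e-9)

    def test_empty_bin_warns(self, edge_cfg):
        stack, hist = self._two_phase(edge_cfg)
        empty_bin = int(np.where(hist.counts == 0)[0][0])
        with pytest.warns(UserWarning, match="empty"):
            labels, means = cluster_by_edge_energy(stack, hist, [[empty_bin]])
        assert (labels == 1).sum() == 0
        assert np.all(np.isnan(means[0]))


class TestLCFit:
    def test_exact_mixture_recovered(self, edge_cfg, xanes_data):
        _, _, truth, refs = xanes_data
        mix = 0.3 * refs.spectra[0] + 0.7 * refs.spectra[1]
        stack = pixel_stack(mix, ENERGIES)
        w, r = lc_fit(stack, refs, edge_cfg)
        assert w[0, 0, 0] == pytest.approx(0.3, abs=1e-8)
        assert w[1, 0, 0] == pytest.approx(0.7, abs=1e-8)
        assert r[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_rfactor_hand_example(self):
        # oracle: R = (0 + 1) / (1 + 4) = 0.2, evaluated by hand
        assert rfactor_of([1.0, 2.0], [1.0, 1.0]) == 0.2

    def test_rfactor_scale_invariance(self):
        rng = np.random.default_rng(0)
        data = rng.random(20) + 0.5
        fit = data + rng.normal(0, 0.1, 20)
        r1 = rfactor_of(data, fit)
        r2 = rfactor_of(3.7 * data, 3.7 * fit)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_weight_recovery_under_noise(self, edge_cfg, xanes_data):
        phantom, stack, truth, refs = xanes_data
        nmask = noise_filter(stack, edge_cfg)
        norm, norm_mask = normalize_stack(stack, edge_cfg, mask=nmask)
        m = nmask & norm_mask
        w, r = lc_fit(norm, refs, edge_cfg, mask=m)
        wsum = phantom.truth_weights.sum(axis=0)
        rel = np.where(wsum > 0, phantom.truth_weights
                       / np.where(wsum > 0, wsum, 1.0), 0.0)
        rmse = np.sqrt(np.mean((w[:, m] - rel[:, m]) ** 2))
        assert rmse < 0.05
        # NNLS invariants
        assert w.min() >= 0.0
        total = w[:, m].sum(axis=0)
        assert 0.9 < total.mean() < 1.1
        # masked pixels: zero weights, NaN R
        assert np.all(w[:, ~m] == 0.0)
        assert np.all(np.isnan(r[~m]))

    def test_sum_near_one_for_noiseless_mixture(self, edge_cfg, xanes_data):
        _, _, _, refs = xanes_data
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.uniform(0.1, 0.9)
            mix = a * refs.spectra[0] + (1 - a) * refs.spectra[1]
            w, _ = lc_fit(pixel_stack(mix, ENERGIES), refs, edge_cfg)
            assert 0.98 <= w[:, 0, 0].sum() <= 1.02

    def test_single_reference_rejected(self, edge_cfg):
        refs = ReferenceSet(["only"], np.ones((1, 50)))
        with pytest.raises(ValueError, match="at least 2"):
            lc_fit(pixel_stack(np.ones(50), ENERGIES), refs, edge_cfg)

    def test_collinear_references_named(self, edge_cfg, xanes_data):
        _, _, _, refs = xanes_data
        dup = ReferenceSet(
            ["alpha", "beta", "gamma"],
            np.stack([refs.spectra[0], refs.spectra[1],
                      2.0 * refs.spectra[1]]),
        )
        with pytest.raises(ValueError, match="beta.*gamma|gamma.*beta"):
            lc_fit(pixel_stack(np.ones(50), ENERGIES), dup, edge_cfg)


class TestReferenceSet:
    def test_from_files_resamples(self, tmp_path):
        e = np.arange(7080.0, 7200.0, 0.25)
        mu = arctan_edge(e, 7120.0, 2.0)
        p = tmp_path / "refA.txt"
        np.savetxt(p, np.column_stack([e, mu]))
        refs = ReferenceSet.from_files([p], ENERGIES)
        assert refs.names == ["refA"]
        np.testing.assert_allclose(
            refs.spectra[0], arctan_edge(ENERGIES, 7120.0, 2.0), atol=1e-3
        )

    def test_extrapolation_refused(self, tmp_path):
        e = np.arange(7100.0, 7150.0, 2.0)  # narrower than the stack grid
        p = tmp_path / "short.txt"
        np.savetxt(p, np.column_stack([e, np.ones_like(e)]))
        with pytest.raises(ValueError, match="outside"):
            ReferenceSet.from_files([p], ENERGIES)


class TestJumpVsRfactor:
    def test_full_plane_polygon(self):
        jump = np.array([[0.5, 1.0], [1.5, 2.0]])
        r = np.array([[0.01, 0.02], [np.nan, 0.04]])
        poly = np.array([[-10, -1], [10, -1], [10, 1], [-10, 1]])
        labels = jump_vs_rfactor_cluster(jump, r, [poly])
        assert (labels == 1).sum() == 3  # NaN pixel never selected
        assert labels[1, 0] == 0

    def test_empty_polygon(self):
        jump = np.ones((2, 2))
        r = np.full((2, 2), 0.01)
        poly = np.array([[5.0, 5.0], [6.0, 5.0], [6.0, 6.0]])
        labels = jump_vs_rfactor_cluster(jump, r, [poly])
        assert (labels > 0).sum() == 0

    def test_withheld_reference_cluster(self, edge_cfg):
        phantom = default_xanes_phantom(n_refs=3, seed=0)
        stack, truth = make_xanes_stack(phantom, ENERGIES)
        refs3 = normalized_references(truth["profiles"], ENERGIES, edge_cfg)
        refs2 = ReferenceSet(refs3.names[:2], refs3.spectra[:2])
        nmask = noise_filter(stack, edge_cfg)
        norm, norm_mask = normalize_stack(stack, edge_cfg, mask=nmask)
        m = nmask & norm_mask
        w, r = lc_fit(norm, refs2, edge_cfg, mask=m)
        jump = edge_jump_map(stack, edge_cfg)
        # high-J / high-R box selection in the correlation plot
        poly = np.array([[0.3, 0.03], [50.0, 0.03], [50.0, 10.0], [0.3, 10.0]])
        labels = jump_vs_rfactor_cluster(jump, r, [poly])
        third = (phantom.truth_weights[2] > 0.5) & m
        captured = (labels == 1) & third
        assert captured.sum() / third.sum() > 0.90


class TestRGB:
    def test_pure_phase_red(self):
        w = np.zeros((2, 1, 1))
        w[0] = 1.0
        rgb = rgb_phase_map(w, np.ones((1, 1)), {"r": [0], "g": [1], "b": []})
        np.testing.assert_allclose(rgb[0, 0], [1.0, 0.0, 0.0])

    def test_additive_mixing(self):
        w = np.zeros((3, 1, 1))
        w[0] = 0.5
        w[1] = 0.5
        rgb = rgb_phase_map(
            w, np.ones((1, 1)), {"r": [0], "g": [1], "b": [2]}
        )
        np.testing.assert_allclose(rgb[0, 0], [0.5, 0.5, 0.0])

    def test_surplus_references_summed(self):
        # oracle: (0.2 + 0.3) / 0.5 total = 1.0 in blue
        w = np.zeros((4, 1, 1))
        w[2] = 0.2
        w[3] = 0.3
        rgb = rgb_phase_map(
            w, np.ones((1, 1)), {"r": [0], "g": [1], "b": [2, 3]}
        )
        np.testing.assert_allclose(rgb[0, 0], [0.0, 0.0, 1.0])

    def test_incomplete_assignment_rejected(self):
        w = np.zeros((3, 1, 1))
        with pytest.raises(ValueError, match="cover"):
            rgb_phase_map(w, np.ones((1, 1)), {"r": [0], "g": [1], "b": []})

    def test_masked_pixels_black(self):
        w = np.ones((2, 2, 2))
        mask = np.array([[True, False], [True, True]])
        rgb = rgb_phase_map(
            w, np.ones((2, 2)), {"r": [0], "g": [1], "b": []}, mask=mask
        )
        np.testing.assert_array_equal(rgb[0, 1], 0.0)


class TestBulkXanes:
    def test_uniform_stack(self, edge_cfg):
        spec = arctan_edge(ENERGIES, 7120.0, 2.0)
        data = np.broadcast_to(spec[:, None, None], (50, 4, 4)).copy()
        stack = EnergyStack(data, ENERGIES)
        np.testing.assert_allclose(bulk_xanes(stack), spec)

    def test_two_phase_mean(self):
        spec_a = arctan_edge(ENERGIES, 7116.0, 1.5)
        spec_b = arctan_edge(ENERGIES, 7128.0, 1.5)
        data = np.empty((50, 2, 2))
        data[:, :, 0] = spec_a[:, None]
        data[:, :, 1] = spec_b[:, None]
        stack = EnergyStack(data, ENERGIES)
        np.testing.assert_allclose(
            bulk_xanes(stack), 0.5 * (spec_a + spec_b), atol=1e-12
        )

    def test_empty_selection_rejected(self):
        stack = EnergyStack(np.ones((3, 2, 2)), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="empty selection"):
            bulk_xanes(stack, mask=np.zeros((2, 2), dtype=bool))


class TestPipeline:
    def test_determinism(self, edge_cfg, xanes_data):
        _, stack, _, refs = xanes_data
        a = analyze(stack, edge_cfg, refs=refs)
        b = analyze(stack, edge_cfg, refs=refs)
        np.testing.assert_array_equal(a.edge_jump, b.edge_jump)
        np.testing.assert_array_equal(a.normalized.data, b.normalized.data)
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.rgb, b.rgb)

    def test_combined_mask_is_and(self, edge_cfg, xanes_data):
        _, stack, _, _ = xanes_data
        res = analyze(stack, edge_cfg)
        np.testing.assert_array_equal(
            res.combined_mask, res.noise_mask & res.norm_mask
        )
        # filtered pixels are zero at all energies
        np.testing.assert_array_equal(
            res.normalized.data[:, ~res.combined_mask], 0.0
        )

    def test_edge_energy_within_scan(self, edge_cfg, xanes_data):
        _, stack, _, _ = xanes_data
        res = analyze(stack, edge_cfg)
        vals = res.edge_energy[np.isfinite(res.edge_energy)]
        assert vals.min() >= ENERGIES[0]
        assert vals.max() <= ENERGIES[-1]
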