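"""Degree-centrality engine: correlations, thresholded degree, z maps, smoothing."""

import numpy as np
import pytest

from neurodc.dc import (
    FWHM_TO_SIGMA,
    MaskedBOLD,
    compute_dc,
    dc_pipeline,
    smooth_map,
    to_z_map,
    voxel_correlation_row,
)
from neurodc.grids import ToyGeometry, generate_toy_atlas, generate_toy_geometry
from neurodc.simulate import CohortSpec, simulate_subject, subject_seed


def dense_dc_oracle(data: np.ndarray, r0: float, variant: str) -> np.ndarray:
    """Brute-force dense N x N reference for the chunked implementation."""
    r = np.corrcoef(data)
    np.fill_diagonal(r, 0.0)
    above = r > r0
    if variant == "binary":
        return above.sum(axis=1).astype(float)
    return np.where(above, r, 0.0).sum(axis=1)


def random_bold(n_voxels: int, n_t: int, seed: int) -> MaskedBOLD:
    rng = np.random.default_rng(seed)
    shape = (n_voxels, 1, 1)
    geom = ToyGeometry(shape=shape, voxel_size_mm=(3, 3, 3), mask=np.ones(shape, bool))
    return MaskedBOLD(
        data=rng.standard_normal((n_voxels, n_t)),
        geometry=geom,
        voxel_index=geom.mask_coordinates(),
    )


class TestCorrelationRow:
    @pytest.mark.parametrize(
        "j, expected",
        [(1, 1.0), (2, -1.0), (3, 0.8)],
        ids=["proportional", "reversed", "hand_computed"],
    )
    def test_hand_computed_correlations(self, micro_bold, j, expected):
        row = voxel_correlation_row(micro_bold, 0)
        assert row[j] == pytest.approx(expected, abs=1e-12)

    def test_affine_rescaling_is_invariant(self, micro_bold):
        row0 = voxel_correlation_row(micro_bold, 0)
        micro_bold.data[2] = 3.7 * micro_bold.data[2] + 12.0
        assert np.allclose(voxel_correlation_row(micro_bold, 0), row0, atol=1e-12)

    def test_zero_variance_voxel_reports_coordinate(self, micro_bold):
        micro_bold.data[3] = 5.0
        with pytest.raises(ValueError, match=r"\(0, 0, 3\)"):
            voxel_correlation_row(micro_bold, 0)


class TestComputeDC:
    def test_weighted_micro_example(self, micro_bold):
        dc = compute_dc(micro_bold, r0=0.25, variant="weighted")
        assert np.allclose(dc.values, [1.8, 1.8, 0.0, 1.6], atol=1e-12)

    def test_binary_micro_example(self, micro_bold):
        dc = compute_dc(micro_bold, r0=0.25, variant="binary")
        assert np.allclose(dc.values, [2, 2, 0, 2])

    def test_near_unity_threshold_keeps_only_perfect_edge(self, micro_bold):
        dc = compute_dc(micro_bold, r0=0.999, variant="weighted")
        assert np.allclose(dc.values, [1.0, 1.0, 0.0, 0.0], atol=1e-9)

    @pytest.mark.parametrize("variant", ["weighted", "binary"])
    def test_chunked_equals_dense_oracle(self, variant):
        bold = random_bold(120, 40, seed=8)
        rng = np.random.default_rng(99)
        for r0 in rng.uniform(0.05, 0.95, size=5):
            oracle = dense_dc_oracle(bold.data, r0, variant)
            for chunk in (1, 7, 64, 1024):
                dc = compute_dc(bold, r0=r0, variant=variant, chunk_size=chunk)
                assert np.allclose(dc.values, oracle, atol=1e-10)

    def test_scale_invariance(self):
        bold = random_bold(50, 30, seed=2)
        base = compute_dc(bold, r0=0.25).values
        bold.data[7] = 3.7 * bold.data[7] + 12.0
        assert np.max(np.abs(compute_dc(bold, r0=0.25).values - base)) < 1e-10

    def test_degree_monotone_nonincreasing_in_threshold(self):
        bold = random_bold(60, 25, seed=5)
        for variant in ("weighted", "binary"):
            prev = compute_dc(bold, r0=0.05, variant=variant).values
            for r0 in (0.2, 0.4, 0.6, 0.8):
                cur = compute_dc(bold, r0=r0, variant=variant).values
                assert np.all(cur <= prev + 1e-12)
                prev = cur

    @pytest.mark.parametrize("bad_r0", [0.0, 1.0, -0.5, 1.5])
    def test_threshold_outside_open_interval_rejected(self, micro_bold, bad_r0):
        with pytest.raises(ValueError, match="r0"):
            compute_dc(micro_bold, r0=bad_r0)


class TestZTransform:
    def test_map_standardize_gives_zero_mean_unit_sd(self):
        bold = random_bold(80, 30, seed=3)
        z = to_z_map(compute_dc(bold, r0=0.25))
        assert abs(z.values.mean()) < 1e-12
        assert abs(z.values.std() - 1.0) < 1e-12

    def test_degenerate_constant_map_rejected(self, small_geometry):
        from neurodc.dc import DCMap

        coords = small_geometry.mask_coordinates()
        flat = DCMap(
            values=np.full(len(coords), 2.0),
            stage="raw_degree",
            variant="weighted",
            r0=0.25,
            geometry=small_geometry,
            voxel_index=coords,
        )
        with pytest.raises(ValueError, match="degenerate"):
            to_z_map(flat)

    def test_fisher_rz_sums_atanh_of_suprathreshold_edges(self, micro_bold):
        raw = compute_dc(micro_bold, r0=0.25)
        z = to_z_map(raw, method="fisher_rz", bold=micro_bold)
        atanh_08 = 0.5 * np.log(9.0)  # atanh(0.8) = 1.0986...
        atanh_1 = np.arctanh(1 - 1e-7)
        expected = [atanh_1 + atanh_08, atanh_1 + atanh_08, 0.0, 2 * atanh_08]
        assert np.allclose(z.values, expected, atol=1e-6)
        assert atanh_08 == pytest.approx(1.0986, abs=1e-4)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self):
        bold = random_bold(40, 20, seed=1)
        z = to_z_map(compute_dc(bold, r0=0.25))
        assert np.array_equal(smooth_map(z, fwhm_mm=0.0).values, z.values)

    def test_constant_map_is_fixed_point_under_renormalized_smoothing(self, small_geometry):
        from neurodc.dc import DCMap

        coords = small_geometry.mask_coordinates()
        const = DCMap(
            values=np.full(len(coords), 3.5),
            stage="z_transformed",
            variant="weighted",
            r0=0.25,
            geometry=small_geometry,
            voxel_index=coords,
        )
        out = smooth_map(const, fwhm_mm=6.0, renormalize_in_mask=True)
        assert np.allclose(out.values, 3.5, atol=1e-10)

    def test_impulse_response_matches_direct_kernel_evaluation(self):
        from neurodc.dc import DCMap

        geom = generate_toy_geometry(shape=(9, 9, 9), mask_rule="full")
        coords = geom.mask_coordinates()
        values = np.zeros(len(coords))
        center = np.array([4, 4, 4])
        values[np.all(coords == center, axis=1)] = 1.0
        impulse = DCMap(
            values=values,
            stage="z_transformed",
            variant="weighted",
            r0=0.25,
            geometry=geom,
            voxel_index=coords,
        )
        out = smooth_map(impulse, fwhm_mm=6.0)
        sigma = 6.0 * FWHM_TO_SIGMA / 3.0  # voxel units
        k = np.arange(-30, 31)
        norm1d = np.exp(-0.5 * (k / sigma) ** 2).sum()
        offsets = coords - center
        expected = np.exp(-0.5 * (offsets**2).sum(axis=1) / sigma**2) / norm1d**3
        assert np.allclose(out.values, expected, atol=1e-8)

    def test_negative_fwhm_rejected(self):
        bold = random_bold(20, 20, seed=0)
        z = to_z_map(compute_dc(bold, r0=0.25))
        with pytest.raises(ValueError, match="fwhm"):
            smooth_map(z, fwhm_mm=-1.0)


class TestPipeline:
    def test_noise_free_single_region_is_flat(self, small_geometry):
        atlas = generate_toy_atlas(small_geometry, 1, seed=0)
        spec = CohortSpec(noise_sd=0.0, base_coupling=1.0, n_timepoints=30)
        rec = simulate_subject(small_geometry, atlas, 2, spec, subject_seed(4, 0))
        raw = compute_dc(rec.bold, r0=0.25)
        # every voxel correlates 1 with every other: identical raw degree
        assert np.allclose(raw.values, raw.values[0], atol=1e-8)

    def test_stage_and_provenance_recorded(self, small_geometry):
        atlas = generate_toy_atlas(small_geometry, 2, seed=0)
        spec = CohortSpec(n_timepoints=30)
        rec = simulate_subject(small_geometry, atlas, 2, spec, subject_seed(6, 0))
        out = dc_pipeline(rec.bold, r0=0.3, variant="binary", fwhm_mm=4.0)
        assert out.stage == "smoothed"
        assert out.variant == "binary"
        assert out.r0 == 0.3
        assert out.meta["z_method"] == "map_standardize"

    def test_chunking_invariance_end_to_end(self, small_geometry):
        atlas = generate_toy_atlas(small_geometry, 3, seed=0)
        spec = CohortSpec(n_timepoints=40)
        rec = simulate_subject(small_geometry, atlas, 1, spec, subject_seed(7, 0))
        a = dc_pipeline(rec.bold, chunk_size=1)
        b = dc_pipeline(rec.bold, chunk_size=10**6)
        assert np.allclose(a.values, b.values, atol=1e-10)


class TestPlantedDegreeRecovery:
    def test_higher_coupling_region_has_higher_degree(self):
        geom = generate_toy_geometry(shape=(6, 6, 6), mask_rule="full")
        atlas = generate_toy_atlas(geom, 2, seed=13)
        wins = 0
        for rep in range(100):
            spec = CohortSpec(
                effect_regions=(1,), effect_size=0.5, n_timepoints=240, seed=rep
            )
            rec = simulate_subject(geom, atlas, 1, spec, subject_seed(1000, rep))
            dc = compute_dc(rec.bold, r0=0.25)
            in_a = atlas.labels[tuple(rec.bold.voxel_index.T)] == 1
            wins += dc.values[in_a].mean() > dc.values[~in_a].mean()
        assert wins >= 95
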