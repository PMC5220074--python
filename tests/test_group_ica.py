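"""Concatenation, spatial ICA, mixture thresholding, template matching."""

import numpy as np
import pytest

from cvqc.bold import BoldRun, MaskedRun
from cvqc.group_ica import (
    DataMatrix,
    concatenate,
    fit_group_ica,
    match_rsn,
    threshold_map,
)
from cvqc.phantom import bandlimited_timecourse


def _masked_run(data_2d: np.ndarray, subject_id: str = "s0") -> MaskedRun:
    """Wrap a (t x voxels) matrix as a MaskedRun on a 1-voxel-thick grid."""
    t, v = data_2d.shape
    data = data_2d.T.reshape(v, 1, 1, t)
    run = BoldRun(data=data, tr_seconds=1.8, subject_id=subject_id)
    idx = np.column_stack([np.arange(v), np.zeros(v, int), np.zeros(v, int)])
    return MaskedRun(run=run, voxel_index=idx)


def _synthetic_network_matrix(seed: int, n_sub: int = 4, t: int = 80,
                              v: int = 600, k: int = 3, noise: float = 0.2):
    """Subjects sharing k disjoint sparse spatial blocks (networks cover
    a small fraction of voxels, as in real maps) with subject-specific
    band-limited time courses; returns (masked runs, ground-truth maps)."""
    rng = np.random.default_rng(seed)
    maps = np.zeros((k, v))
    block = v // (10 * k)
    for c in range(k):
        start = c * (v // k)
        maps[c, start: start + block] = 1.0
    runs = []
    for s in range(n_sub):
        data = np.zeros((t, v))
        for c in range(k):
            tc = bandlimited_timecourse(rng, t, 1.8, (0.01, 0.1))
            data += np.outer(tc, maps[c])
        data += noise * rng.standard_normal((t, v))
        runs.append(_masked_run(data, f"s{s}"))
    return runs, maps


class TestConcatenate:
    def test_two_subjects_boundaries(self):
        rng = np.random.default_rng(0)
        runs = [_masked_run(rng.normal(size=(100, 30)), f"s{i}") for i in range(2)]
        mat = concatenate(runs)
        assert mat.values.shape == (200, 30)
        assert mat.subject_boundaries == [(0, 100), (100, 200)]

    def test_single_subject_equals_normalised_data(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(50, 20))
        mat = concatenate([_masked_run(raw)])
        expected = raw - raw.mean(axis=0)
        expected /= expected.std(axis=0, ddof=1)
        assert np.allclose(mat.values, expected)
        assert np.allclose(mat.values.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(mat.values.std(axis=0, ddof=1), 1.0)

    def test_full_cohort_row_arithmetic(self):
        """69 subjects x 199 volumes concatenate to 13,731 rows."""
        rng = np.random.default_rng(2)
        runs = [_masked_run(rng.normal(size=(199, 5)), f"s{i}")
                for i in range(69)]
        assert concatenate(runs).n_rows == 13731

    def test_voxel_set_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        a = _masked_run(rng.normal(size=(20, 10)), "a")
        b = _masked_run(rng.normal(size=(20, 11)), "b")
        with pytest.raises(ValueError):
            concatenate([a, b])


class TestGroupICA:
    def test_three_disjoint_networks_recovered(self):
        runs, maps = _synthetic_network_matrix(seed=0)
        decomp = fit_group_ica(concatenate(runs), k=3, seed=0)
        for truth in maps:
            rs = [abs(np.corrcoef(truth, comp)[0, 1])
                  for comp in decomp.spatial_maps]
            assert max(rs) >= 0.9

    def test_rank_one_network_recovered_almost_exactly(self):
        """A single rank-one source is recovered up to sign/scale."""
        rng = np.random.default_rng(1)
        v, t = 500, 80
        truth = rng.gamma(2.0, 1.0, size=v)  # skewed spatial source
        tc = bandlimited_timecourse(rng, t, 1.8, (0.01, 0.1))
        values = np.outer(tc, truth) + 0.01 * rng.standard_normal((t, v))
        idx = np.column_stack([np.arange(v), np.zeros(v, int), np.zeros(v, int)])
        mat = DataMatrix(values=values, subject_boundaries=[(0, t)],
                         subject_ids=["s0"], voxel_index=idx)
        decomp = fit_group_ica(mat, k=1, seed=0)
        r = abs(np.corrcoef(truth, decomp.spatial_maps[0])[0, 1])
        assert r >= 0.99

    def test_reconstruction_spans_principal_subspace(self):
        """mixing @ maps explains at least the variance captured by the
        k-dimensional principal subspace of the demeaned data."""
        runs, _ = _synthetic_network_matrix(seed=2)
        mat = concatenate(runs)
        k = 3
        decomp = fit_group_ica(mat, k=k, seed=0)
        x = mat.values.T  # voxels x rows, ICA's sample orientation
        xc = x - x.mean(axis=0, keepdims=True)
        recon = decomp.spatial_maps.T @ decomp.mixing.T
        resid = ((xc - recon) ** 2).sum()
        svals = np.linalg.svd(xc, compute_uv=False)
        pca_resid = (svals[k:] ** 2).sum()
        total = (xc**2).sum()
        explained = 1 - resid / total
        pca_explained = 1 - pca_resid / total
        assert explained >= pca_explained - 1e-6

    def test_same_seed_reproducible_and_sign_fixed(self):
        runs, _ = _synthetic_network_matrix(seed=3)
        mat = concatenate(runs)
        a = fit_group_ica(mat, k=3, seed=5)
        b = fit_group_ica(mat, k=3, seed=5)
        assert np.array_equal(a.spatial_maps, b.spatial_maps)
        assert np.array_equal(a.mixing, b.mixing)
        from scipy.stats import skew

        assert np.all(skew(a.spatial_maps, axis=1) >= 0)

    def test_different_seeds_pairable(self):
        runs, _ = _synthetic_network_matrix(seed=4)
        mat = concatenate(runs)
        a = fit_group_ica(mat, k=3, seed=0)
        b = fit_group_ica(mat, k=3, seed=99)
        corr = np.abs(np.corrcoef(a.spatial_maps, b.spatial_maps)[:3, 3:])
        # each component of a has a counterpart in b
        assert np.all(corr.max(axis=1) >= 0.95)

    def test_voxel_permutation_equivariance(self):
        runs, _ = _synthetic_network_matrix(seed=5, n_sub=2, v=300)
        mat = concatenate(runs)
        decomp = fit_group_ica(mat, k=3, seed=0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(mat.n_voxels)
        mat_p = DataMatrix(values=mat.values[:, perm],
                           subject_boundaries=mat.subject_boundaries,
                           subject_ids=mat.subject_ids,
                           voxel_index=mat.voxel_index[perm])
        decomp_p = fit_group_ica(mat_p, k=3, seed=0)
        # pair components by correlation; permuted maps must agree
        for comp in range(3):
            target = decomp.spatial_maps[comp, perm]
            rs = [abs(np.corrcoef(target, other)[0, 1])
                  for other in decomp_p.spatial_maps]
            assert max(rs) > 0.9999

    def test_k_exceeding_rank_rejected(self):
        runs, _ = _synthetic_network_matrix(seed=6, n_sub=1, t=10, v=50)
        with pytest.raises(ValueError):
            fit_group_ica(concatenate(runs), k=11, seed=0)


class TestMixtureThreshold:
    def test_null_gaussian_map_keeps_almost_nothing(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(20000)
        active, fit = threshold_map(z)
        assert active.mean() <= 0.01

    def test_strong_activation_mostly_retained(self):
        rng = np.random.default_rng(1)
        n = 20000
        labels = rng.uniform(size=n) < 0.10
        z = rng.standard_normal(n)
        z[labels] = rng.gamma(4.0, 1.0, size=labels.sum()) + 4.0
        active, fit = threshold_map(z)
        assert fit is not None
        assert active[labels].mean() >= 0.95
        assert active[~labels].mean() <= 0.05

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            threshold_map(np.zeros(500))

    def test_small_map_rejected(self):
        with pytest.raises(ValueError):
            threshold_map(np.random.default_rng(0).normal(size=50))


class TestTemplateMatching:
    def test_maps_match_themselves_perfectly(self):
        runs, _ = _synthetic_network_matrix(seed=7)
        decomp = fit_group_ica(concatenate(runs), k=3, seed=0)
        templates = {f"c{c}": decomp.spatial_maps[c] for c in range(3)}
        for m in match_rsn(decomp, templates):
            assert m.matched
            assert m.component_id == int(m.template_name[1])
            assert abs(m.correlation) == pytest.approx(1.0)

    def test_orthogonal_template_unmatched(self):
        runs, _ = _synthetic_network_matrix(seed=8)
        decomp = fit_group_ica(concatenate(runs), k=3, seed=0)
        rng = np.random.default_rng(0)
        noise_template = rng.standard_normal(decomp.spatial_maps.shape[1])
        matches = match_rsn(decomp, {"noise": noise_template}, r_min=0.2)
        assert not matches[0].matched

    def test_phantom_template_matches_seeding_network(self):
        from cvqc.phantom import PhantomSpec, default_networks, generate_cohort
        from cvqc.preprocess import apply_gm_mask

        spec = PhantomSpec(grid_shape=(16, 16, 8), n_volumes=60,
                           n_per_group=(3, 3), atrophy_fraction=0.0, seed=6)
        cohort = generate_cohort(spec)
        gm = cohort.ground_truth["compartments"] == 3
        masked = [apply_gm_mask(r, gm) for r in cohort.runs]
        decomp = fit_group_ica(concatenate(masked), k=3, seed=0)
        templates = cohort.ground_truth["network_maps"]
        matches = match_rsn(decomp, templates)
        comp_ids = [m.component_id for m in matches]
        assert all(m.matched for m in matches)
        assert len(set(comp_ids)) == 3  # distinct components per network
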