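"""CV / tSNR maps, normative reference, deviation scores, Mann-Whitney."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from cvqc import qc
from cvqc.bold import BoldRun, estimate_brain_mask
from cvqc.qc import (
    CVMap,
    build_normative_reference,
    compute_cv_map,
    compute_tsnr_map,
    defect_score,
    deviation_zmap,
    flag_runs,
    mann_whitney_u,
    mean_tsnr,
    score_thresholds,
    stripe_score,
)

from conftest import make_run


class TestCVAndTSNR:
    def test_constant_series_gives_zero_cv_full_valid(self):
        run = make_run([5.0, 5.0, 5.0])
        cv = compute_cv_map(run, mean_floor=1.0)
        assert np.all(cv.values == 0.0)
        assert cv.valid_mask.all()

    def test_one_two_three_analytic_values(self):
        run = make_run([1.0, 2.0, 3.0])
        cv = compute_cv_map(run, mean_floor=0.1)
        tsnr = compute_tsnr_map(run, sd_floor=0.1)
        assert cv.values[0, 0, 0] == pytest.approx(0.5)
        assert tsnr.values[0, 0, 0] == pytest.approx(2.0)

    def test_sub_floor_mean_marked_invalid(self):
        run = make_run([1e-9, 2e-9, 3e-9])
        cv = compute_cv_map(run, mean_floor=1.0)
        assert not cv.valid_mask.any()
        assert np.all(cv.values == 0.0)

    def test_constant_series_tsnr_invalid_not_infinite(self):
        run = make_run([5.0, 5.0, 5.0])
        tsnr = compute_tsnr_map(run, sd_floor=1e-3)
        assert not tsnr.valid_mask.any()
        assert np.all(np.isfinite(tsnr.values))

    def test_reciprocity_on_jointly_valid_voxels(self, tiny_cohort):
        run = tiny_cohort.runs[0]
        cv = compute_cv_map(run)
        tsnr = compute_tsnr_map(run)
        joint = cv.valid_mask & tsnr.valid_mask
        assert joint.any()
        prod = cv.values[joint] * tsnr.values[joint]
        assert np.abs(prod - 1.0).max() < 1e-10

    @pytest.mark.parametrize("scale", [0.5, 3.0, 1234.5])
    def test_scale_invariance(self, tiny_cohort, scale):
        run = tiny_cohort.runs[0]
        scaled = run.with_data(run.data * scale)
        cv0, cv1 = compute_cv_map(run), compute_cv_map(scaled)
        t0, t1 = compute_tsnr_map(run), compute_tsnr_map(scaled)
        assert np.allclose(cv0.values, cv1.values)
        assert np.allclose(t0.values, t1.values)
        assert np.array_equal(cv0.valid_mask, cv1.valid_mask)

    def test_rejects_single_volume(self):
        with pytest.raises(ValueError):
            BoldRun(data=np.ones((8, 8, 8, 1)), tr_seconds=1.8)


class TestMeanTSNR:
    def test_uniform_value(self):
        tsnr = compute_tsnr_map(make_run([49.0, 50.0, 51.0]), sd_floor=0.1)
        mask = np.ones(tsnr.values.shape, dtype=bool)
        assert mean_tsnr(tsnr, mask) == pytest.approx(50.0)

    def test_two_voxel_average(self):
        values = np.zeros((2, 1, 1))
        values[0, 0, 0], values[1, 0, 0] = 10.0, 30.0
        tsnr = qc.TSNRMap(values=values, valid_mask=np.ones((2, 1, 1), bool))
        assert mean_tsnr(tsnr, np.ones((2, 1, 1), bool)) == pytest.approx(20.0)

    def test_empty_intersection_rejected(self):
        tsnr = qc.TSNRMap(values=np.ones((2, 2, 2)),
                          valid_mask=np.zeros((2, 2, 2), bool))
        with pytest.raises(ValueError):
            mean_tsnr(tsnr, np.ones((2, 2, 2), bool))

    def test_stripe_artifact_lowers_mean_tsnr(self, striped_pair):
        artifacted, clean, _ = striped_pair
        ra, rc = artifacted.run_for("pat001"), clean.run_for("pat001")
        brain = estimate_brain_mask(rc)
        assert mean_tsnr(compute_tsnr_map(ra), brain) < mean_tsnr(
            compute_tsnr_map(rc), brain
        )


class TestNormativeReference:
    def test_two_uniform_maps(self):
        shape = (4, 4, 4)
        maps = [
            CVMap(values=np.full(shape, v), valid_mask=np.ones(shape, bool))
            for v in (0.1, 0.3)
        ]
        ref = build_normative_reference(maps)
        assert np.allclose(ref.mean_cv, 0.2)
        assert np.allclose(ref.sd_cv, 0.2 / np.sqrt(2))  # approx 0.1414
        assert ref.n_subjects == 2

    def test_identical_maps_zero_sd(self):
        shape = (4, 4, 4)
        maps = [CVMap(values=np.full(shape, 0.07), valid_mask=np.ones(shape, bool))
                for _ in range(5)]
        assert np.allclose(build_normative_reference(maps).sd_cv, 0.0)

    def test_grid_mismatch_rejected(self):
        a = CVMap(values=np.zeros((4, 4, 4)), valid_mask=np.ones((4, 4, 4), bool))
        b = CVMap(values=np.zeros((5, 4, 4)), valid_mask=np.ones((5, 4, 4), bool))
        with pytest.raises(ValueError):
            build_normative_reference([a, b])

    def test_clean_phantom_mean_matches_generative_cv_in_wm(self):
        """Voxelwise normative mean CV in white matter agrees with the
        closed-form noise_sd / baseline within 3 SE almost everywhere."""
        from cvqc.phantom import WM, PhantomSpec, generate_normative_cohort

        spec = PhantomSpec(grid_shape=(12, 12, 8), n_volumes=60,
                           n_per_group=(2, 2), seed=5)
        norm = generate_normative_cohort(spec, 20)
        ref = build_normative_reference([compute_cv_map(r) for r in norm.runs])
        wm = (norm.ground_truth["compartments"] == WM) & ref.valid_mask
        expected = spec.noise_sd / spec.baseline
        se = ref.sd_cv[wm] / np.sqrt(ref.n_subjects)
        within = np.abs(ref.mean_cv[wm] - expected) <= 3 * se
        assert within.mean() > 0.98


class TestDeviationScores:
    @pytest.fixture()
    def reference(self):
        shape = (8, 8, 6)
        return qc.NormativeReference(
            mean_cv=np.full(shape, 0.02),
            sd_cv=np.full(shape, 0.005),
            n_subjects=20,
            valid_mask=np.ones(shape, bool),
        )

    def test_subject_equal_to_mean_gives_zero_z(self, reference):
        cv = CVMap(values=reference.mean_cv.copy(),
                   valid_mask=np.ones(reference.mean_cv.shape, bool))
        assert np.all(deviation_zmap(cv, reference) == 0.0)

    def test_two_sd_above_gives_z_two(self, reference):
        values = reference.mean_cv.copy()
        values[3, 3, 3] += 2 * reference.sd_cv[3, 3, 3]
        cv = CVMap(values=values, valid_mask=np.ones(values.shape, bool))
        z = deviation_zmap(cv, reference)
        assert z[3, 3, 3] == pytest.approx(2.0)

    def test_stripe_subject_z_elevated_on_affected_slices(self, striped_pair):
        artifacted, clean, stripe = striped_pair
        ref = build_normative_reference(
            [compute_cv_map(r) for r in clean.runs]
        )
        z = deviation_zmap(compute_cv_map(artifacted.run_for("pat001")), ref)
        hit = np.zeros(z.shape[2], dtype=bool)
        hit[list(stripe.affected_slices)] = True
        assert np.abs(z[:, :, hit]).mean() > np.abs(z[:, :, ~hit]).mean()

    def test_stripe_score_zero_for_flat_maps(self):
        assert stripe_score(np.zeros((6, 6, 5))) == 0.0
        # a global offset is not a stripe
        assert stripe_score(np.full((6, 6, 5), 3.7)) == pytest.approx(0.0)

    def test_stripe_score_needs_three_slices(self):
        with pytest.raises(ValueError):
            stripe_score(np.zeros((6, 6, 2)))

    def test_stripe_score_monotone_in_amplitude(self):
        """Raising the stripe amplitude never lowers the stripe score."""
        from dataclasses import replace

        from cvqc.phantom import ArtifactSpec, PhantomSpec, generate_cohort

        base = PhantomSpec(grid_shape=(12, 12, 8), n_volumes=40,
                           n_per_group=(1, 0), atrophy_fraction=0.0, seed=11)
        clean = generate_cohort(base)
        ref_maps = []
        for s in range(6):
            norm = generate_cohort(replace(base, seed=100 + s))
            ref_maps.append(compute_cv_map(norm.runs[0]))
        ref = build_normative_reference(ref_maps)
        scores = []
        for amp in (0.0, 50.0, 100.0, 200.0, 400.0):
            if amp == 0.0:
                cohort = clean
            else:
                art = ArtifactSpec("stripe", affected_slices=(3, 4),
                                   affected_volumes=tuple(range(10, 20)),
                                   amplitude=amp, target_subjects=("con001",))
                cohort = generate_cohort(replace(base, artifact_specs=(art,)))
            z = deviation_zmap(compute_cv_map(cohort.runs[0]), ref)
            scores.append(stripe_score(z))
        assert all(b >= a for a, b in zip(scores, scores[1:]))
        assert scores[-1] > scores[0]

    def test_defect_score_examples(self):
        assert defect_score(np.zeros((6, 6, 4))) == 0.0
        z = np.zeros((10, 10, 1))
        z.flat[:10] = 4.0  # 10% of voxels beyond threshold 3
        assert defect_score(z) == pytest.approx(0.10)
        with pytest.raises(ValueError):
            defect_score(z, valid_mask=np.zeros_like(z, dtype=bool))


class TestFlagging:
    def _scores(self, stripe, defect):
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(len(stripe))],
            "mean_tsnr": [50.0] * len(stripe),
            "stripe_score": stripe,
            "defect_score": defect,
        })

    def test_all_zero_scores_no_flags(self):
        report = flag_runs(self._scores([0.0, 0.0], [0.0, 0.0]),
                           {"stripe": 1.0, "defect": 0.01})
        assert not report["flag"].any()

    def test_infinite_thresholds_never_flag(self):
        report = flag_runs(self._scores([1e6, 5.0], [0.9, 0.2]),
                           {"stripe": np.inf, "defect": np.inf})
        assert not report["flag"].any()

    def test_reasons_are_machine_readable(self):
        report = flag_runs(self._scores([5.0, 0.0], [0.0, 0.5]),
                           {"stripe": 1.0, "defect": 0.1})
        assert list(report["reason"]) == ["cv_stripe", "cv_defect"]
        assert report["flag"].all()

    def test_missing_scores_rejected(self):
        df = self._scores([0.0], [0.0]).drop(columns=["defect_score"])
        with pytest.raises(ValueError):
            flag_runs(df, {"stripe": 1.0, "defect": 1.0})

    def test_thresholds_median_plus_five_mad(self):
        stripe = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        thr = score_thresholds(stripe, stripe)
        assert thr["stripe"] == pytest.approx(3.0 + 5.0 * 1.0)


class TestMannWhitney:
    def test_small_sample_exact_enumeration(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1.0 / 3.0)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.normal(size=4)
            b = rng.normal(size=5)
            _, p = mann_whitney_u(a, b)
            ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                           method="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_exact_matches_monte_carlo_permutation(self):
        """The enumerated p agrees with a label-permutation resampling
        oracle within 3 SE at 10,000 draws."""
        a = np.array([1.2, 3.4, 2.2, 5.0])
        b = np.array([2.0, 4.4, 6.1])
        u_obs, p_exact = mann_whitney_u(a, b)
        pooled = np.concatenate([a, b])
        center = a.size * b.size / 2.0
        dev_obs = abs(u_obs - center)
        rng = np.random.default_rng(1)
        hits = 0
        n_draw = 10000
        for _ in range(n_draw):
            perm = rng.permutation(pooled)
            diff = perm[:4][:, None] - perm[4:][None, :]
            u = (diff > 0).sum() + 0.5 * (diff == 0).sum()
            hits += abs(u - center) >= dev_obs - 1e-12
        p_mc = hits / n_draw
        se = np.sqrt(p_exact * (1 - p_exact) / n_draw)
        assert abs(p_mc - p_exact) <= 3 * se

    def test_large_samples_use_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(2)
        a = np.round(rng.normal(size=20), 1)  # induces ties
        b = np.round(rng.normal(0.5, size=20), 1)
        _, p = mann_whitney_u(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="asymptotic").pvalue
        assert p == pytest.approx(ref)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])
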