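"""Lock-mass recalibration, greedy binning, axis intersection, cube."""

import numpy as np
import pandas as pd
import pytest

from msipipe import (DEFAULT_LOCKMASSES, LockMassSet, MassAxis, PeakTable,
                     PhantomConfig, Species, assemble_cube, build_common_axis,
                     intersect_runs, make_phantom, pick_peaks_image,
                     recalibrate_pixel, recalibrate_table)


def _peaks(mzs, intensities=None):
    mzs = np.asarray(mzs, dtype=float)
    inten = np.ones_like(mzs) if intensities is None else np.asarray(intensities)
    return pd.DataFrame({"mz": mzs, "intensity": inten,
                         "snr": np.full(mzs.size, 10.0)})


def _table(rows, width=2, height=2):
    df = pd.DataFrame(rows, columns=["pixel", "mz", "intensity"])
    df["snr"] = 10.0
    df["row"] = df["pixel"] // width
    df["col"] = df["pixel"] % width
    return PeakTable(df=df[["pixel", "row", "col", "mz", "intensity", "snr"]],
                     width=width, height=height)


class TestRecalibratePixel:
    def test_exact_references_give_identity_with_zero_residuals(self):
        peaks = _peaks(DEFAULT_LOCKMASSES)
        out, model = recalibrate_pixel(peaks, LockMassSet())
        assert model.calibrated and model.n_matched == 3
        assert np.allclose(out["mz"], DEFAULT_LOCKMASSES, atol=1e-9)
        assert np.allclose(model.residuals, 0.0, atol=1e-9)

    def test_uniform_ppm_shift_recovered_closed_form(self):
        """Peaks shifted by +10 ppm: the fitted correction is a -10 ppm
        rescaling (closed form for a pure multiplicative shift) and the
        corrected residual at m/z 255 is < 0.0005."""
        shift = 1 + 10e-6
        peaks = _peaks([m * shift for m in DEFAULT_LOCKMASSES])
        out, model = recalibrate_pixel(peaks, LockMassSet())
        assert model.n_matched == 3
        corrected = out["mz"].to_numpy()
        assert np.all(np.abs(corrected - DEFAULT_LOCKMASSES) < 0.0005)
        # effective scale ~ 1/(1+1e-5): alpha ~ -10 ppm (affine absorbs
        # part into the offset, so compare the end-to-end map)
        assert np.allclose(model.apply(np.array([255.2324 * shift])),
                           255.2324, atol=5e-4)

    def test_no_match_returns_input_flagged(self):
        peaks = _peaks([100.0, 150.0])
        out, model = recalibrate_pixel(peaks, LockMassSet())
        assert not model.calibrated and model.n_matched == 0
        assert np.array_equal(out["mz"], peaks["mz"])

    def test_single_match_is_constant_ppm_shift(self):
        obs = 174.0408 * (1 + 8e-6)
        peaks = _peaks([obs, 500.0])
        out, model = recalibrate_pixel(peaks, LockMassSet())
        assert model.n_matched == 1 and model.beta == 0.0
        assert np.isclose(out["mz"].iloc[0], 174.0408, atol=1e-9)

    def test_correction_never_worsens_lockmass_residuals(self, rng):
        for _ in range(20):
            drift = rng.normal(0, 10e-6, 3)
            obs = np.array(DEFAULT_LOCKMASSES) * (1 + drift)
            _, model = recalibrate_pixel(_peaks(obs), LockMassSet())
            before = obs - DEFAULT_LOCKMASSES
            assert np.sum(model.residuals ** 2) <= np.sum(before ** 2) + 1e-18


class TestBuildCommonAxis:
    def test_identical_peak_everywhere_gives_single_feature(self):
        table = _table([(p, 200.0, 5.0) for p in range(4)])
        axis, assign = build_common_axis(table, tol_ppm=5.0)
        assert len(axis) == 1
        assert np.isclose(axis.centers[0], 200.0)
        assert np.all(assign == 0)

    def test_20ppm_separation_splits_at_5ppm_tolerance(self):
        table = _table([(0, 100.0000, 1.0), (1, 100.0020, 1.0)])
        axis, _ = build_common_axis(table, tol_ppm=5.0)
        assert len(axis) == 2

    def test_chain_matches_hand_traced_greedy_oracle(self):
        """Chain 100.0000, 100.0004, 100.0008 at 5 ppm: equal weights.
        Hand trace — peak 1 opens bin (centre 100.0000); peak 2 is 4 ppm
        away, joins (centre 100.0002); peak 3 is 6 ppm from the running
        centre, opens a second bin."""
        table = _table([(0, 100.0000, 1.0), (1, 100.0004, 1.0),
                        (2, 100.0008, 1.0)], width=2, height=2)
        axis, assign = build_common_axis(table, tol_ppm=5.0)
        assert len(axis) == 2
        assert assign.tolist() == [0, 0, 1]
        assert np.isclose(axis.centers[0], 100.0002)
        assert np.isclose(axis.centers[1], 100.0008)

    def test_permutation_invariant_over_pixels(self):
        rows = [(p, 200.0 + 0.001 * (p % 3), 1.0 + p) for p in range(9)]
        t1 = _table(rows, width=3, height=3)
        t2 = _table(rows[::-1], width=3, height=3)
        a1, _ = build_common_axis(t1, tol_ppm=3.0)
        a2, _ = build_common_axis(t2, tol_ppm=3.0)
        assert np.allclose(a1.centers, a2.centers)
        assert np.array_equal(a1.counts, a2.counts)

    def test_empty_input_gives_empty_axis(self):
        axis, assign = build_common_axis(_table([]), tol_ppm=5.0)
        assert len(axis) == 0 and assign.size == 0


class TestIntersectRuns:
    def test_identical_axes_unchanged(self):
        ax = MassAxis(np.array([100.0, 200.0]), np.array([5, 5]))
        out = intersect_runs([ax, ax], tol_ppm=5.0)
        assert np.allclose(out.centers, ax.centers)

    def test_feature_missing_from_one_run_is_dropped(self):
        a = MassAxis(np.array([100.0, 200.0]), np.array([5, 5]))
        b = MassAxis(np.array([200.0]), np.array([4]))
        out = intersect_runs([a, b], tol_ppm=5.0)
        assert np.allclose(out.centers, [200.0])

    def test_3ppm_apart_merge_within_5ppm_tolerance(self):
        a = MassAxis(np.array([300.0000]), np.array([2]))
        b = MassAxis(np.array([300.0009]), np.array([3]))
        out = intersect_runs([a, b], tol_ppm=5.0)
        assert len(out) == 1
        assert np.isclose(out.centers[0], 300.00045)
        assert out.counts[0] == 5


class TestAssembleCube:
    def test_noiseless_phantom_nonzero_exactly_where_planted(self, clean_phantom):
        cfg, image, truth = clean_phantom
        table = pick_peaks_image(image, snr_min=3.0, min_dist=10)
        axis, _ = build_common_axis(table, tol_ppm=10.0)
        cube = assemble_cube(table, axis, tol_ppm=10.0)
        labels = truth.labels_flat()
        lesion = truth.region_index("lesion")
        j = int(np.argmin(np.abs(axis.centers - 200.10)))
        assert np.all(cube.X[labels == lesion, j] > 0)
        assert np.all(cube.X[labels != lesion, j] == 0)

    def test_pixel_without_peaks_is_all_zero_row(self):
        table = _table([(0, 200.0, 7.0)])
        axis, _ = build_common_axis(table)
        cube = assemble_cube(table, axis)
        assert np.all(cube.X[1:] == 0)

    def test_two_peaks_in_one_bin_are_summed(self):
        table = _table([(0, 200.0000, 3.0), (0, 200.0004, 4.0)])
        axis, _ = build_common_axis(table, tol_ppm=5.0)
        cube = assemble_cube(table, axis, tol_ppm=5.0)
        assert len(axis) == 1
        assert cube.X[0, 0] == 7.0         # hand sum

    def test_intensity_conserved_exactly(self, noisy_phantom):
        _, image, _ = noisy_phantom
        table = pick_peaks_image(image, snr_min=5.0, min_dist=10)
        axis, _ = build_common_axis(table, tol_ppm=10.0)
        cube = assemble_cube(table, axis, tol_ppm=50.0)   # generous: all assigned
        assert np.isclose(cube.X.sum(), table.df["intensity"].sum(), rtol=0, atol=1e-9)

    def test_geometry_mismatch_raises(self):
        table = _table([(7, 200.0, 1.0)], width=2, height=2)
        table.df.loc[0, "pixel"] = 99
        axis, _ = build_common_axis(table)
        with pytest.raises(ValueError):
            assemble_cube(table, axis)


class TestRecalibrationRecovery:
    def test_drifted_phantom_recovers_references(self):
        """Phantom at 5 ppm drift: post-correction median lock-mass error
        <= 1/10 of pre-correction, and mean recovered centroids within
        2 ppm of the configured references."""
        cfg = PhantomConfig(
            width=16, height=16,
            species_table=[Species("m", 400.0, {"tissue": 50.0, "lesion": 50.0})],
            drift_ppm_sd=5.0, noise_sd=1.0, baseline_level=5.0, seed=42)
        image, _ = make_phantom(cfg)
        table = pick_peaks_image(image, snr_min=5.0, min_dist=10)
        refs = np.array(DEFAULT_LOCKMASSES)

        def lockmass_errors_ppm(df):
            errs = {r: [] for r in refs}
            for _, grp in df.groupby("pixel"):
                mz = grp["mz"].to_numpy()
                for r in refs:
                    d = np.abs(mz - r)
                    if d.min() / r * 1e6 < 30:
                        errs[r].append((mz[np.argmin(d)] - r) / r * 1e6)
            return errs

        before = lockmass_errors_ppm(table.df)
        corrected, report = recalibrate_table(table, LockMassSet())
        after = lockmass_errors_ppm(corrected.df)
        for r in refs:
            med_before = np.median(np.abs(before[r]))
            med_after = np.median(np.abs(after[r]))
            assert med_after <= med_before / 10
            mean_centroid_ppm = np.mean(after[r])
            assert abs(mean_centroid_ppm) < 2.0
        assert report["calibrated"].all()
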