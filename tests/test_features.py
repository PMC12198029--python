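"""Feature catalogues, normalisation, filtering, clustering."""

import numpy as np
import pandas as pd
import pytest

from pgtrange.features import (
    IMAGE_FEATURE_NAMES,
    TIME_FEATURE_NAMES,
    _glcm_features,
    assemble_feature_sets,
    cluster_features,
    energy_features,
    energy_restricted_time_features,
    feature_columns,
    filter_features,
    icc_1_1,
    image_features,
    normalize_to_reference,
    time_features,
)
from pgtrange.spectra import BinningSpec, ValidationError

from conftest import make_meta, make_spectrum


def centres(n, width=1.0, start=0.0):
    return start + (np.arange(n) + 0.5) * width


class TestTimeFeatures:
    def test_symmetric_triangle(self):
        hist = np.array([0, 1, 2, 3, 4, 3, 2, 1, 0], dtype=float)
        c = centres(9)
        f = time_features(hist, c)
        assert f["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert f["mean"] == pytest.approx(f["median"]) == pytest.approx(f["mode"]) == 4.5

    def test_length_one_histogram(self):
        f = time_features(np.array([5.0]), np.array([2.0]))
        assert f["entropy"] == 0.0
        assert f["std"] == 0.0
        assert f["fwhm"] == 0.0
        assert f["total"] == 5.0

    def test_brute_force_moment_oracle(self, rng):
        hist = rng.poisson(8.0, 40).astype(float)
        c = centres(40, 0.5)
        f = time_features(hist, c)
        p = hist / hist.sum()
        mean = sum(pi * ci for pi, ci in zip(p, c))
        std = np.sqrt(sum(pi * (ci - mean) ** 2 for pi, ci in zip(p, c)))
        entropy = -sum(pi * np.log(pi) for pi in p if pi > 0)
        assert f["mean"] == pytest.approx(mean, rel=1e-12)
        assert f["std"] == pytest.approx(std, rel=1e-12)
        assert f["entropy"] == pytest.approx(entropy, rel=1e-12)
        assert f["mad"] == pytest.approx(sum(pi * abs(ci - mean) for pi, ci in zip(p, c)))

    def test_all_zero_histogram_is_undefined(self):
        f = time_features(np.zeros(10), centres(10))
        assert len(f) == len(TIME_FEATURE_NAMES)
        assert all(np.isnan(v) for v in f.values())

    def test_catalogue_has_15_features(self):
        assert len(TIME_FEATURE_NAMES) == 15
        f = time_features(np.ones(10), centres(10))
        assert set(f) == set(TIME_FEATURE_NAMES)

    def test_shift_equivariance(self, rng):
        """A circular shift away from the wrap moves positional features by
        k·bin_width and leaves shape features unchanged."""
        hist = np.zeros(60)
        hist[20:30] = rng.poisson(30.0, 10) + 1.0
        c = centres(60, 0.1)
        k = 7
        base = time_features(hist, c)
        shifted = time_features(np.roll(hist, k), c)
        for name in ("mean", "median", "mode", "falloff", "rise"):
            assert shifted[name] == pytest.approx(base[name] + k * 0.1, abs=1e-9)
        for name in ("std", "entropy", "fwhm", "iqr", "skewness", "total", "max"):
            assert shifted[name] == pytest.approx(base[name], abs=1e-9)

    def test_fwhm_of_plateau(self):
        # 5-bin boxcar of a wide plateau: half-max crossings at the flanks
        hist = np.zeros(40)
        hist[10:30] = 10.0
        f = time_features(hist, centres(40))
        assert f["fwhm"] == pytest.approx(20.0, abs=1.0)
        assert f["rise"] < 11 and f["falloff"] > 29


ANALYSIS_BINNING = BinningSpec(
    time_bin_width_ns=1.06 / 230,
    n_time_bins=1150,
    energy_bin_width_MeV=0.1,
    energy_min_MeV=0.1,
    energy_max_MeV=8.1,
)


def analysis_spectrum(counts):
    return make_spectrum(counts, ANALYSIS_BINNING)


class TestEnergyRestrictedTime:
    def test_counts_only_in_o16_window(self, rng):
        counts = np.zeros((1150, 80))
        col = 52  # 5.3-5.4 MeV: inside the 16O window only
        counts[:, col] = rng.poisson(5.0, 1150)
        f = energy_restricted_time_features(analysis_spectrum(counts))
        assert len(f) == 5 * 15
        for base in TIME_FEATURE_NAMES:
            assert np.isnan(f[f"ert:511keV:all:{base}"])
        from pgtrange.features import full_time_features

        unrestricted = full_time_features(analysis_spectrum(counts))
        for base in TIME_FEATURE_NAMES:
            assert f[f"ert:O16:all:{base}"] == pytest.approx(
                unrestricted[f"time:all:all:{base}"], nan_ok=True
            )


class TestEnergyFeatures:
    def test_uniform_spectrum_relative_intensities(self):
        counts = np.full((1150, 80), 2.0)
        f = energy_features(analysis_spectrum(counts))
        # analytic fraction: window width / full energy span
        for name, width in (("511keV", 0.3), ("B10", 0.2), ("O16", 1.3)):
            assert f[f"energy:{name}:all:relative"] == pytest.approx(width / 8.0)

    def test_counts_only_in_511_window(self):
        counts = np.zeros((1150, 80))
        counts[:, 3] = 1.0  # 0.4-0.5 MeV
        f = energy_features(analysis_spectrum(counts))
        assert f["energy:511keV:all:relative"] == pytest.approx(1.0)
        for other in ("B10", "C11", "C12_B11", "O16"):
            assert np.isnan(f[f"energy:511keV_{other}:all:ratio"])

    def test_cardinality_126(self, rng):
        counts = rng.poisson(1.0, (1150, 80)).astype(float)
        f = energy_features(analysis_spectrum(counts))
        assert len(f) == (5 + 1 + 5 + 10) * 6

    def test_segment_counts_match_slices(self, rng):
        counts = rng.poisson(1.0, (1150, 80)).astype(float)
        f = energy_features(analysis_spectrum(counts))
        for i in range(5):
            sl = counts[i * 230 : (i + 1) * 230]
            assert f[f"energy:all:t{i}:total"] == sl.sum()


class TestImageFeatures:
    def test_constant_image(self):
        spec = make_spectrum(
            np.full((20, 16), 3.0),
            BinningSpec(
                time_bin_width_ns=0.25,
                n_time_bins=20,
                energy_bin_width_MeV=0.5,
                energy_min_MeV=0.1,
                energy_max_MeV=8.1,
            ),
        )
        f = image_features(spec)
        assert f["image:full:all:variance"] == 0.0
        assert f["image:full:all:glcm_contrast"] == 0.0
        assert np.isnan(f["image:full:all:glcm_correlation"])
        assert f["image:full:all:foreground_fraction"] == 0.0

    def test_checkerboard_glcm_contrast(self):
        """2-level checkerboard: axis-aligned neighbours differ by one level
        (contrast 1), diagonal neighbours are equal (contrast 0) → mean 0.5."""
        board = np.indices((16, 16)).sum(axis=0) % 2
        f = _glcm_features(board.astype(np.uint8), n_levels=2)
        assert f["glcm_contrast"] == pytest.approx(0.5)
        assert f["glcm_dissimilarity"] == pytest.approx(0.5)

    def test_first_order_brute_force_oracle(self, rng, small_binning):
        counts = rng.poisson(5.0, (20, 16)).astype(float)
        f = image_features(make_spectrum(counts, small_binning))
        v = counts.ravel()
        assert f["image:full:all:mean"] == pytest.approx(v.mean(), rel=1e-12)
        assert f["image:full:all:variance"] == pytest.approx(v.var(), rel=1e-12)
        assert f["image:full:all:rms"] == pytest.approx(np.sqrt((v**2).mean()), rel=1e-12)
        assert f["image:full:all:p90"] == pytest.approx(np.percentile(v, 90))

    def test_cardinality_26_per_image_6_images(self, rng, small_binning):
        counts = rng.poisson(5.0, (20, 16)).astype(float)
        f = image_features(make_spectrum(counts, small_binning))
        assert len(IMAGE_FEATURE_NAMES) == 26
        assert len(f) == 26 * 6


class TestAssembly:
    @pytest.fixture
    def tables(self, rng):
        rows = []
        for i in range(8):
            meta = make_meta(f"s{i}", cavity=float(5 * (i % 4)), split="train", seed=i)
            counts = rng.poisson(2.0, (1150, 80)).astype(float)
            spec = analysis_spectrum(counts)
            values = {}
            from pgtrange.features import extract_spot_features

            values = extract_spot_features(spec, sets=("time", "ert", "energy"))
            rows.append((meta, values))
        return assemble_feature_sets(rows)

    def test_combined_is_union_without_overlap(self, tables):
        n = sum(len(feature_columns(tables[s])) for s in ("time", "ert", "energy", "image"))
        assert len(feature_columns(tables["combined"])) == n

    def test_time_table_has_15_columns(self, tables):
        assert len(feature_columns(tables["time"])) == 15

    def test_shared_columns_identical_across_tables(self, tables):
        col = "time:all:all:mean"
        pd.testing.assert_series_equal(tables["time"][col], tables["combined"][col])

    def test_duplicate_spot_ids_rejected(self, rng):
        meta = make_meta("dup", split="train")
        with pytest.raises(ValidationError, match="duplicate"):
            assemble_feature_sets([(meta, {"time:all:all:mean": 1.0})] * 2)


def toy_table(values: np.ndarray, cavities, splits, energy=162.0, dataset="static"):
    n = len(values)
    return pd.DataFrame(
        {
            "beam_energy": energy,
            "mode": "static",
            "dataset": dataset,
            "cavity_mm": cavities,
            "split": splits,
            **{f"f{j}": values[:, j] for j in range(values.shape[1])},
        },
        index=[f"s{i}" for i in range(n)],
    )


class TestNormalization:
    def test_reference_median_maps_to_one(self):
        values = np.array([[2.0], [4.0], [6.0], [8.0]])
        t = toy_table(values, [0, 0, 0, 10], ["train", "train", "train", "test"])
        out = normalize_to_reference(t)
        assert out.loc["s1", "f0"] == pytest.approx(1.0)  # 4 / median(2,4,6)

    def test_scale_invariance(self):
        values = np.array([[2.0, 1.0], [4.0, 3.0], [6.0, 2.0], [8.0, 9.0]])
        t = toy_table(values, [0, 0, 0, 10], ["train", "train", "train", "test"])
        a = normalize_to_reference(t)
        t7 = t.copy()
        t7["f0"] = t7["f0"] * 7
        b = normalize_to_reference(t7)
        pd.testing.assert_frame_equal(a, b)

    def test_hand_computed_three_spot_toy(self):
        values = np.array([[1.0], [3.0], [10.0]])
        t = toy_table(values, [0, 0, 5], ["train", "train", "test"])
        out = normalize_to_reference(t)
        np.testing.assert_allclose(out["f0"], [0.5, 1.5, 5.0])

    def test_zero_reference_median_marks_feature(self):
        values = np.array([[0.0, 1.0], [0.0, 2.0], [5.0, 3.0]])
        t = toy_table(values, [0, 0, 5], ["train", "train", "test"])
        out = normalize_to_reference(t)
        assert out["f0"].isna().all()
        assert out["f1"].notna().all()

    def test_missing_reference_errors(self):
        values = np.ones((3, 1))
        t = toy_table(values, [5, 5, 10], ["train", "train", "test"])
        with pytest.raises(ValidationError, match="reference"):
            normalize_to_reference(t)


class TestFiltering:
    def test_constant_column_dropped_and_target_like_retained(self, rng):
        cav = np.repeat([0.0, 5.0, 10.0, 20.0], 5)
        values = np.column_stack(
            [
                np.ones(20),  # constant
                cav + 0.0,  # exactly the target, identical across repeats
                rng.normal(size=20),  # pure noise: low ICC
            ]
        )
        t = toy_table(values, cav, ["train"] * 20)
        filtered, log = filter_features(t)
        assert log["f0"] == "near_zero_variance"
        assert "f1" in filtered.columns
        assert log.get("f2") == "low_icc"

    def test_nan_marker_dropped(self):
        cav = np.repeat([0.0, 5.0], 3)
        values = np.column_stack([np.arange(6.0), np.arange(6.0)])
        values[2, 0] = np.nan
        t = toy_table(values, cav, ["train"] * 6)
        filtered, log = filter_features(t)
        assert log["f0"] == "undefined"

    def test_all_dropped_errors(self):
        t = toy_table(np.ones((6, 1)), np.repeat([0.0, 5.0], 3), ["train"] * 6)
        with pytest.raises(ValidationError, match="all features dropped"):
            filter_features(t)

    def test_icc_matches_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        k, m = 4, 5
        y = (np.repeat(rng.normal(0, 2, k), m) + rng.normal(0, 1, k * m))
        groups = np.repeat(np.arange(k), m)
        data = pd.DataFrame({"g": groups, "rater": np.tile(np.arange(m), k), "y": y})
        icc_table = pingouin.intraclass_corr(
            data, targets="g", raters="rater", ratings="y"
        )
        expected = float(
            icc_table.loc[icc_table["Type"].isin(["ICC1", "ICC(1,1)"]), "ICC"].iloc[0]
        )
        assert icc_1_1(y, groups) == pytest.approx(expected, rel=1e-9)


class TestClustering:
    def test_affine_transform_merges(self, rng):
        base = rng.normal(size=40)
        values = np.column_stack([base, 3.0 * base + 1.0, rng.normal(size=40)])
        t = toy_table(values, rng.choice([0.0, 5.0], 40), ["train"] * 40)
        cmap = cluster_features(t)
        merged = [c for c in cmap.clusters.values() if set(c) == {"f0", "f1"}]
        assert merged, cmap.clusters

    def test_independent_features_stay_separate(self, rng):
        values = rng.normal(size=(100, 2))
        t = toy_table(values, rng.choice([0.0, 5.0], 100), ["train"] * 100)
        cmap = cluster_features(t)
        assert len(cmap.clusters) == 2

    def test_partition_and_representatives(self, rng):
        values = rng.normal(size=(50, 6))
        values[:, 1] = values[:, 0] + 0.01 * rng.normal(size=50)
        t = toy_table(values, rng.choice([0.0, 5.0, 10.0], 50), ["train"] * 50)
        cmap = cluster_features(t)
        members = sorted(m for c in cmap.clusters.values() for m in c)
        assert members == sorted(feature_columns(t))
        for cid, rep in cmap.representatives.items():
            assert rep in cmap.clusters[cid]

    def test_single_feature_single_cluster(self):
        t = toy_table(np.arange(12.0)[:, None], [0.0] * 12, ["train"] * 12)
        cmap = cluster_features(t)
        assert cmap.representative_names == ["f0"]
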