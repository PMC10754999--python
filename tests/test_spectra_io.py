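"""Spectral containers, preprocessing and file round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ftirnet.exceptions import AxisMismatchError, DataError, LabelConflictError
from ftirnet.io import read_spectra, write_spectra
from ftirnet.spectra import (
    SpectralDataset,
    WavenumberGrid,
    average_replicates,
    mean_spectrum_by_class,
    normalize,
)


class TestWavenumberGrid:
    def test_default_serum_grid_has_826_points(self):
        grid = WavenumberGrid()
        assert (grid.start, grid.stop, grid.step) == (700.0, 4000.0, 4.0)
        assert grid.n_points == 826
        assert grid.wavenumbers[0] == 700.0 and grid.wavenumbers[-1] == 4000.0

    def test_descending_axis_is_reversed_on_inference(self):
        grid = WavenumberGrid.from_axis(np.array([716.0, 712.0, 708.0, 704.0, 700.0]))
        assert grid.start == 700.0 and grid.stop == 716.0

    def test_nonuniform_axis_rejected(self):
        with pytest.raises(AxisMismatchError):
            WavenumberGrid.from_axis(np.array([700.0, 704.0, 710.0]))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(DataError):
            WavenumberGrid(start=4000, stop=700, step=4)


class TestDatasetValidation:
    def test_wrong_length_rejected(self, small_dataset):
        with pytest.raises(AxisMismatchError):
            SpectralDataset(
                grid=WavenumberGrid(),  # 826 points vs 10-point data
                absorbance=small_dataset.absorbance,
                meta=small_dataset.meta,
                class_names=small_dataset.class_names,
            )

    def test_nonfinite_rejected(self, small_dataset):
        bad = small_dataset.absorbance.copy()
        bad[0, 0] = np.nan
        with pytest.raises(DataError, match="non-finite"):
            SpectralDataset(small_dataset.grid, bad, small_dataset.meta,
                            small_dataset.class_names)

    def test_duplicate_sample_replicate_rejected(self, small_dataset):
        meta = small_dataset.meta.copy()
        meta.loc[1, ["sample_id", "replicate_id"]] = meta.loc[0, ["sample_id", "replicate_id"]]
        with pytest.raises(DataError, match="duplicate"):
            SpectralDataset(small_dataset.grid, small_dataset.absorbance, meta,
                            small_dataset.class_names)


class TestAverageReplicates:
    def test_constant_replicates_average_to_midpoint(self):
        grid = WavenumberGrid(700, 708, 4)
        meta = pd.DataFrame(
            {"sample_id": ["s"] * 3, "replicate_id": [0, 1, 2], "class_label": ["HC"] * 3}
        )
        ds = SpectralDataset(grid, np.array([[1.0] * 3, [2.0] * 3, [3.0] * 3]), meta, ("HC",))
        out = average_replicates(ds)
        assert len(out) == 1
        np.testing.assert_allclose(out.absorbance[0], 2.0)

    def test_single_replicate_is_identity(self, small_dataset):
        once = average_replicates(small_dataset)
        assert len(once) == 6  # 2 classes x 3 samples
        again = average_replicates(once)  # idempotent
        np.testing.assert_array_equal(once.absorbance, again.absorbance)
        assert once.meta.equals(again.meta)

    def test_conflicting_labels_raise(self, small_dataset):
        meta = small_dataset.meta.copy()
        meta.loc[0, "class_label"] = "HC"  # row 0/1 share sample_id, labels now differ
        ds = SpectralDataset(small_dataset.grid, small_dataset.absorbance, meta,
                             small_dataset.class_names)
        with pytest.raises(LabelConflictError):
            average_replicates(ds)

    def test_full_cohort_shape(self):
        # 320 samples x 3 replicates -> 320 averaged spectra
        from ftirnet.synth import generate, preset

        ds = generate(preset("null", seed=0))
        assert len(ds) == 960
        avg = average_replicates(ds)
        assert len(avg) == 320
        assert avg.class_counts() == {"AS": 80, "RA": 80, "OA": 80, "HC": 80}


class TestNormalize:
    def _one(self, values, n=3):
        grid = WavenumberGrid(700, 700 + 4 * (len(values) - 1), 4)
        meta = pd.DataFrame({"sample_id": ["a"], "replicate_id": [0], "class_label": ["HC"]})
        return SpectralDataset(grid, np.array([values], dtype=float), meta, ("HC",))

    def test_none_is_identity(self, small_dataset):
        out = normalize(small_dataset, "none")
        assert out is small_dataset

    def test_minmax_affine_map(self):
        out = normalize(self._one([0.0, 2.0, 4.0]), "minmax")
        np.testing.assert_allclose(out.absorbance[0], [0.0, 0.5, 1.0])

    def test_vector_unit_norm(self):
        out = normalize(self._one([3.0, 4.0]), "vector")
        np.testing.assert_allclose(out.absorbance[0], [0.6, 0.8])

    def test_constant_spectrum_under_minmax_is_zero(self):
        out = normalize(self._one([5.0, 5.0, 5.0]), "minmax")
        np.testing.assert_array_equal(out.absorbance[0], 0.0)

    def test_unknown_method_rejected(self, small_dataset):
        with pytest.raises(DataError):
            normalize(small_dataset, "zscore")


class TestMeanSpectrumByClass:
    def test_identical_spectra_have_zero_envelope(self):
        grid = WavenumberGrid(700, 704, 4)
        meta = pd.DataFrame(
            {"sample_id": ["a", "b"], "replicate_id": [0, 0], "class_label": ["HC", "HC"]}
        )
        ds = SpectralDataset(grid, np.array([[1.0, 2.0], [1.0, 2.0]]), meta, ("HC",))
        out = mean_spectrum_by_class(ds)
        np.testing.assert_array_equal(out["HC"]["mean"], [1.0, 2.0])
        np.testing.assert_array_equal(out["HC"]["upper"] - out["HC"]["lower"], 0.0)

    def test_mean_and_envelope_hand_case(self):
        grid = WavenumberGrid(700, 704, 4)
        meta = pd.DataFrame(
            {"sample_id": ["a", "b"], "replicate_id": [0, 0], "class_label": ["HC", "HC"]}
        )
        ds = SpectralDataset(grid, np.array([[0.0, 0.0], [2.0, 2.0]]), meta, ("HC",))
        out = mean_spectrum_by_class(ds)
        np.testing.assert_array_equal(out["HC"]["mean"], [1.0, 1.0])
        np.testing.assert_array_equal(out["HC"]["lower"], [0.0, 0.0])
        np.testing.assert_array_equal(out["HC"]["upper"], [2.0, 2.0])

    def test_four_class_synthetic_gives_full_length_means(self, tiny_easy_dataset):
        out = mean_spectrum_by_class(tiny_easy_dataset)
        assert set(out) == {"AS", "RA", "OA", "HC"}
        # (4000 - 700) / 4 + 1 points
        assert all(v["mean"].shape == (826,) for v in out.values())

    def test_empty_class_raises(self, small_dataset):
        ds = SpectralDataset(small_dataset.grid, small_dataset.absorbance,
                             small_dataset.meta, ("AS", "HC", "OA"))
        with pytest.raises(DataError, match="OA"):
            mean_spectrum_by_class(ds)


class TestRoundTrips:
    @pytest.mark.parametrize("fmt", ["csv_wide", "csv_long", "jcampdx"])
    def test_round_trip_preserves_data(self, fmt, small_dataset, tmp_path):
        target = tmp_path / ("data.csv" if fmt.startswith("csv") else "jdx_dir")
        write_spectra(small_dataset, target, fmt)
        back = read_spectra(target, fmt, class_names=small_dataset.class_names)
        assert len(back) == len(small_dataset)
        # file order may differ for directory formats: align on identity
        key = lambda ds: ds.meta.sort_values(["sample_id", "replicate_id"]).index.to_numpy()
        a = small_dataset.absorbance[key(small_dataset)]
        b = back.absorbance[key(back)]
        np.testing.assert_allclose(b, a, rtol=1e-9, atol=1e-12)
        assert sorted(back.meta["class_label"]) == sorted(small_dataset.meta["class_label"])
        assert back.grid == small_dataset.grid

    def test_empty_dataset_round_trip(self, tmp_path):
        ds = SpectralDataset(
            WavenumberGrid(), np.empty((0, 826)),
            pd.DataFrame(columns=["sample_id", "replicate_id", "class_label"]),
        )
        write_spectra(ds, tmp_path / "empty.csv", "csv_wide")
        back = read_spectra(tmp_path / "empty.csv", "csv_wide")
        assert len(back) == 0

    def test_round_trip_preserves_class_counts(self, tmp_path):
        from ftirnet.synth import generate, preset

        ds = average_replicates(generate(preset("null", n_samples_per_class=5, seed=3)))
        write_spectra(ds, tmp_path / "d.csv", "csv_wide")
        back = read_spectra(tmp_path / "d.csv", "csv_wide", class_names=ds.class_names)
        assert back.class_counts() == {"AS": 5, "RA": 5, "OA": 5, "HC": 5}

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        n_points=st.integers(3, 20),
        n_spec=st.integers(1, 5),
        fmt=st.sampled_from(["csv_wide", "csv_long"]),
        data=st.data(),
    )
    def test_csv_round_trip_property(self, n_points, n_spec, fmt, data, tmp_path_factory):
        vals = data.draw(
            st.lists(
                st.lists(
                    st.floats(-1e6, 1e6, allow_nan=False, width=32),
                    min_size=n_points, max_size=n_points,
                ),
                min_size=n_spec, max_size=n_spec,
            )
        )
        grid = WavenumberGrid(700, 700 + 4 * (n_points - 1), 4)
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n_spec)],
                "replicate_id": [0] * n_spec,
                "class_label": ["HC"] * n_spec,
            }
        )
        ds = SpectralDataset(grid, np.array(vals, dtype=float), meta, ("HC",))
        path = tmp_path_factory.mktemp("rt") / "f.csv"
        write_spectra(ds, path, fmt)
        back = read_spectra(path, fmt, class_names=("HC",))
        np.testing.assert_allclose(back.absorbance, ds.absorbance, rtol=1e-9, atol=1e-9)


class TestMalformedFiles:
    def test_mismatched_axis_lengths_rejected(self, tmp_path):
        # two spectra declaring different axes in long format
        rows = []
        for w in (700, 704, 708):
            rows.append({"sample_id": "a", "replicate_id": 0, "class_label": "HC",
                         "wavenumber": w, "absorbance": 1.0})
        for w in (700, 704):  # one point short
            rows.append({"sample_id": "b", "replicate_id": 0, "class_label": "HC",
                         "wavenumber": w, "absorbance": 1.0})
        p = tmp_path / "bad.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        with pytest.raises(AxisMismatchError):
            read_spectra(p, "csv_long")

    def test_short_row_in_wide_file_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "sample_id,replicate_id,class_label,700,704,708\n"
            "a,0,HC,1.0,2.0,3.0\n"
            "b,0,HC,1.0,2.0\n"  # 2 points where header declares 3
        )
        with pytest.raises(DataError):
            read_spectra(p, "csv_wide")

    def test_non_numeric_absorbance_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame(
            {
                "sample_id": ["a", "b"], "replicate_id": [0, 0], "class_label": ["HC", "HC"],
                "wavenumber": [700, 700], "absorbance": [1.0, "oops"],
            }
        ).to_csv(p, index=False)
        with pytest.raises(DataError, match="row"):
            read_spectra(p, "csv_long")

    def test_missing_file(self):
        with pytest.raises(DataError):
            read_spectra("/nonexistent/x.csv", "csv_wide")


class TestJcampDx:
    def test_yfactor_scaling_hand_computed(self, tmp_path):
        # 5-point toy file: absorbance must equal raw ordinates x YFACTOR
        p = tmp_path / "toy.jdx"
        p.write_text(
            "##TITLE=s1|0|HC\n"
            "##XUNITS=1/CM\n"
            "##XFACTOR=1.0\n"
            "##YFACTOR=0.5\n"
            "##FIRSTX=700\n"
            "##LASTX=716\n"
            "##NPOINTS=5\n"
            "##XYDATA=(X++(Y..Y))\n"
            "700 2 4 6\n"
            "712 8 10\n"
            "##END=\n"
        )
        ds = read_spectra(p, "jcampdx", class_names=("HC",))
        np.testing.assert_allclose(ds.absorbance[0], [1.0, 2.0, 3.0, 4.0, 5.0])
        assert ds.grid == WavenumberGrid(700, 716, 4)

    def test_npoints_mismatch_rejected(self, tmp_path):
        p = tmp_path / "toy.jdx"
        p.write_text(
            "##TITLE=s\n##FIRSTX=700\n##LASTX=716\n##NPOINTS=5\n"
            "##XYDATA=(X++(Y..Y))\n700 1 2 3 4\n##END=\n"
        )
        with pytest.raises(AxisMismatchError):
            read_spectra(p, "jcampdx")

    def test_unsupported_table_form_rejected(self, tmp_path):
        p = tmp_path / "toy.jdx"
        p.write_text("##TITLE=s\n##XYDATA=(XY..XY)\n700 1\n##END=\n")
        with pytest.raises(DataError):
            read_spectra(p, "jcampdx")
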