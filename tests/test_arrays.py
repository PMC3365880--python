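"""Array-sample IO, filtering, normalization, and LAIR computation."""

import numpy as np
import pandas as pd
import pytest

from lairkit.arrays import (
    ArrayParseError,
    ArraySample,
    compute_lair,
    filter_markers,
    normalize_intensities,
    read_array,
    write_array,
    write_tracks,
)
from lairkit.simulate import (
    ScenarioProfile,
    SignalModel,
    make_marker_panel,
    simulate_array,
    simulate_karyotype,
    simulate_reference,
)


def tiny_frame():
    return pd.DataFrame(
        {
            "marker_id": ["m3", "m1", "m2"],
            "chrom": ["chr2", "chr1", "chr1"],
            "pos": [500, 100, 900],
            "gtype_ref": ["AB", "AA", "AB"],
            "x_raw": [100.0, 220.0, 105.0],
            "y_raw": [95.0, 2.0, 98.0],
            "gcs": [0.9, 0.8, 0.7],
        }
    )


class TestReadWrite:
    def test_small_file_parsed_and_sorted(self, tmp_path):
        path = tmp_path / "sample.tsv"
        tiny_frame().to_csv(path, sep="\t", index=False)
        s = read_array(path, sample_id="tiny")
        assert s.n_markers == 3
        assert list(s.markers.marker_id) == ["m1", "m2", "m3"]

    def test_duplicate_marker_id_rejected(self, tmp_path):
        df = tiny_frame()
        df.loc[0, "marker_id"] = "m1"
        path = tmp_path / "dup.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ArrayParseError, match="m1"):
            read_array(path)

    def test_missing_column_rejected(self, tmp_path):
        df = tiny_frame().drop(columns=["gcs"])
        path = tmp_path / "short.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ArrayParseError, match="gcs"):
            read_array(path)

    def test_unsortable_chromosome_rejected(self):
        df = tiny_frame()
        df.loc[0, "chrom"] = "chr_funky"
        with pytest.raises(ArrayParseError, match="chr_funky"):
            ArraySample("bad", df)

    def test_simulated_sample_round_trips(self, tmp_path, default_model):
        k = simulate_karyotype(ScenarioProfile("diploid_normal"))
        panel = make_marker_panel(default_model, chromosomes=["chr20", "chr21"], seed=1)
        arr, _ = simulate_array(k, default_model, panel=panel, seed=2)
        path = tmp_path / "sim.tsv"
        write_array(arr, path)
        back = read_array(path, sample_id=arr.sample_id)
        pd.testing.assert_frame_equal(arr.markers, back.markers, check_dtype=False)

    def test_track_output_has_empty_lair_where_undefined(self, tmp_path):
        s = ArraySample("t", tiny_frame())
        s.markers["r"] = 1.0
        s.markers["lair"] = [np.nan, 0.9, np.nan]
        path = tmp_path / "tracks.tsv"
        write_tracks(s, path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == ["marker_id", "chrom", "pos", "r", "lair"]
        assert lines[1].endswith("\t")  # undefined LAIR is an empty field


class TestFiltering:
    def test_zero_threshold_is_identity(self):
        s = ArraySample("t", tiny_frame())
        out = filter_markers(s, min_gcs=0.0)
        assert out.n_markers == 3

    def test_no_call_markers_removed_and_logged(self):
        df = tiny_frame()
        df.loc[1, "gtype_ref"] = "NC"
        out = filter_markers(ArraySample("t", df), min_gcs=0.0)
        assert out.n_markers == 2
        assert out.filter_log["no_call"] == 1

    def test_uniform_gcs_quartile_threshold(self, rng):
        n = 1000
        df = pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(n)],
                "chrom": "chr1",
                "pos": np.arange(1, n + 1) * 1000,
                "gtype_ref": "AB",
                "x_raw": 100.0,
                "y_raw": 100.0,
                "gcs": rng.uniform(0, 1, n),
            }
        )
        out = filter_markers(ArraySample("t", df), min_gcs=0.25)
        # binomial expectation 750, allow ~4 sd
        assert 695 <= out.n_markers <= 805

    def test_empty_result_rejected(self):
        s = ArraySample("t", tiny_frame())
        with pytest.raises(ValueError, match="no markers"):
            filter_markers(s, min_gcs=1.0)


@pytest.fixture(scope="module")
def panels():
    # scale_sd=0 keeps the reference-relative R on the absolute copy scale,
    # so the closed-form medians (0.5 haploid, 2.0 tetraploid) apply directly
    model = SignalModel(seed=40, scale_sd=0.0)
    panel = make_marker_panel(model, chromosomes=["chr19", "chr20", "chr21", "chr22"], seed=41)
    refs = [simulate_reference(panel, model, seed=s) for s in (42, 43)]
    return model, panel, refs


class TestNormalization:
    def test_self_reference_gives_unit_r(self):
        df = tiny_frame()
        s = ArraySample("t", df)
        out = normalize_intensities(s, [ArraySample("r", df.copy())])
        assert np.allclose(out.markers.r_ref, 1.0)
        assert np.allclose(out.markers.r, 1.0)

    def test_haploid_genome_half_intensity(self, panels):
        model, panel, refs = panels
        k = simulate_karyotype(
            ScenarioProfile("near_haploid_chr7AB", retained=frozenset({7}))
        )
        arr, _ = simulate_array(k, model, panel=panel, seed=44)
        out = normalize_intensities(arr, refs)
        assert np.nanmedian(out.markers.r_ref) == pytest.approx(0.5, abs=0.03)

    def test_tetraploid_genome_double_intensity(self, panels):
        model, panel, refs = panels
        k = simulate_karyotype(ScenarioProfile("near_tetraploid"))
        arr, _ = simulate_array(k, model, panel=panel, seed=45)
        out = normalize_intensities(arr, refs)
        assert np.nanmedian(out.markers.r_ref) == pytest.approx(2.0, abs=0.08)

    def test_reference_panel_mismatch_reported(self, panels):
        model, panel, refs = panels
        k = simulate_karyotype(ScenarioProfile("diploid_normal"))
        arr, _ = simulate_array(k, model, panel=panel, seed=46)
        short_ref = ArraySample("short", refs[0].markers.iloc[10:].reset_index(drop=True))
        with pytest.raises(ValueError, match="lacks"):
            normalize_intensities(arr, [short_ref])


class TestLair:
    def test_balanced_marker_unit_lair(self):
        df = tiny_frame()
        df["x_raw"] = [100.0, 220.0, 100.0]
        df["y_raw"] = [100.0, 2.0, 100.0]
        s = ArraySample("t", df)
        out = compute_lair(s, [ArraySample("r", df.copy())])
        lair = out.markers.set_index("marker_id").lair
        assert lair["m2"] == pytest.approx(1.0)
        assert np.isnan(lair["m1"])  # homozygous marker: LAIR undefined

    def test_absent_allele_zero_lair(self, panels):
        model, panel, refs = panels
        k = simulate_karyotype(ScenarioProfile("near_haploid_chr7AB", retained=frozenset({7})))
        arr, truth = simulate_array(k, model, panel=panel, seed=47)
        out = compute_lair(normalize_intensities(arr, refs), refs)
        df = out.markers.merge(truth[["marker_id", "true_state"]], on="marker_id")
        loh = df[(df.true_state == "A")].lair.dropna()
        assert np.median(loh) == pytest.approx(0.0, abs=0.05)

    def test_imbalanced_gain_intermediate_lair(self, panels):
        model, panel, refs = panels
        from lairkit.genome import Karyotype, Segment, canonical_state, GRCH37

        segs = [
            (Segment(c, 1, GRCH37.length(c)), canonical_state(2, 1))
            for c in ["chr19", "chr20", "chr21", "chr22"]
        ]
        arr, _ = simulate_array(Karyotype(segments=segs), model, panel=panel, seed=48)
        out = compute_lair(normalize_intensities(arr, refs), refs)
        assert np.nanmedian(out.markers.lair) == pytest.approx(0.5, abs=0.03)

    def test_global_intensity_scale_cancels(self, panels):
        model, panel, refs = panels
        k = simulate_karyotype(ScenarioProfile("diploid_normal"))
        arr, _ = simulate_array(k, model, panel=panel, seed=49)
        scaled = arr.copy()
        scaled.markers[["x_raw", "y_raw"]] *= 13.7
        out1 = compute_lair(normalize_intensities(arr, refs), refs)
        out2 = compute_lair(normalize_intensities(scaled, refs), refs)
        assert np.allclose(out1.markers.r, out2.markers.r, equal_nan=True)
        assert np.allclose(out1.markers.lair, out2.markers.lair, equal_nan=True)

    def test_symmetric_under_allele_swap(self, panels):
        model, panel, refs = panels
        k = simulate_karyotype(ScenarioProfile("diploid_normal"))
        arr, _ = simulate_array(k, model, panel=panel, seed=50)
        swapped = arr.copy()
        swapped.markers[["x_raw", "y_raw"]] = swapped.markers[["y_raw", "x_raw"]].to_numpy()
        swapped_refs = []
        for r in refs:
            rr = r.copy()
            rr.markers[["x_raw", "y_raw"]] = rr.markers[["y_raw", "x_raw"]].to_numpy()
            swapped_refs.append(rr)
        out1 = compute_lair(normalize_intensities(arr, refs), refs)
        out2 = compute_lair(normalize_intensities(swapped, swapped_refs), swapped_refs)
        assert np.allclose(out1.markers.lair, out2.markers.lair, equal_nan=True)
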