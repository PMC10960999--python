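import numpy as np
import pandas as pd
import pytest

from ricelwc.records import (SchemaError, SpectrumRecord, ValidationError,
                             WAVELENGTH_GRID, average_replicate_scans,
                             merge_observations, read_spectra,
                             records_to_collection, write_spectra)


def _record(plot="p1", value=0.3, stage="flowering", **kw):
    refl = np.full(WAVELENGTH_GRID.size, value)
    return SpectrumRecord(plot_id=plot, year=2022, site="S1", cultivar="C1",
                          treatment="CK", stage=stage,
                          wavelengths=WAVELENGTH_GRID, reflectance=refl, **kw)


class TestSpectrumValidation:
    def test_reflectance_bound_violation_names_the_band(self):
        refl = np.full(WAVELENGTH_GRID.size, 0.3)
        refl[WAVELENGTH_GRID == 1450] = 1.7
        with pytest.raises(ValidationError, match="1450"):
            SpectrumRecord(plot_id="p1", year=2022, site="S1", cultivar="C1",
                           treatment="CK", stage="booting",
                           wavelengths=WAVELENGTH_GRID, reflectance=refl)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            SpectrumRecord(plot_id="p1", year=2022, site="S1", cultivar="C1",
                           treatment="CK", stage="booting",
                           wavelengths=WAVELENGTH_GRID,
                           reflectance=np.full(10, 0.3))

    def test_decreasing_wavelengths_rejected(self):
        with pytest.raises(ValidationError, match="increasing"):
            SpectrumRecord(plot_id="p1", year=2022, site="S1", cultivar="C1",
                           treatment="CK", stage="booting",
                           wavelengths=np.array([400, 399, 401]),
                           reflectance=np.array([0.1, 0.1, 0.1]))


class TestReadWrite:
    def test_wide_and_long_dialects_parse_identically(self, tmp_path):
        records = [_record("p1", 0.2), _record("p2", 0.35), _record("p3", 0.5)]
        wide, long = tmp_path / "wide.csv", tmp_path / "long.csv"
        write_spectra(records, wide, fmt="wide")
        write_spectra(records, long, fmt="long")
        parsed_wide = read_spectra(wide)
        parsed_long = read_spectra(long)
        assert len(parsed_wide) == len(parsed_long) == 3
        assert all(r.reflectance.size == 2151 for r in parsed_wide)
        for a, b in zip(parsed_wide, parsed_long):
            assert a.key == b.key
            np.testing.assert_allclose(a.reflectance, b.reflectance, atol=1e-12)

    def test_round_trip_preserves_values_at_declared_precision(self, tmp_path):
        rng = np.random.default_rng(3)
        rec = _record("p9")
        rec.reflectance = rng.uniform(0, 1, rec.reflectance.size)
        path = tmp_path / "s.csv"
        write_spectra([rec], path)
        back = read_spectra(path)[0]
        np.testing.assert_allclose(back.reflectance, rec.reflectance, atol=5e-7)

    def test_missing_band_columns_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"plot_id": ["p1"], "year": [2022], "site": ["S1"],
                      "cultivar": ["C1"], "treatment": ["CK"],
                      "stage": ["booting"], "x": [1.0]}).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="R350"):
            read_spectra(path)

    def test_percent_scale_autoconverted(self, tmp_path):
        rec = _record("p1", 0.4)
        path = tmp_path / "pct.csv"
        coll = records_to_collection([rec])
        coll.reflectance = coll.reflectance * 100.0
        wide = pd.DataFrame(coll.reflectance, columns=[f"R{w}" for w in coll.wavelengths])
        pd.concat([coll.meta, wide], axis=1).to_csv(path, index=False)
        back = read_spectra(path)[0]
        np.testing.assert_allclose(back.reflectance, 0.4)

    def test_tab_delimited_accepted(self, tmp_path):
        path = tmp_path / "s.tsv"
        write_spectra([_record()], path, sep="\t")
        assert len(read_spectra(path)) == 1


class TestAverageScans:
    def test_identical_scans_mean_is_identity(self):
        scans = [_record("p1", 0.3) for _ in range(10)]
        avg = average_replicate_scans(scans)
        np.testing.assert_array_equal(avg.reflectance, scans[0].reflectance)
        assert avg.n_scans == 10

    def test_two_scans_average_pointwise(self):
        avg = average_replicate_scans([_record("p1", 0.2), _record("p1", 0.4)])
        np.testing.assert_allclose(avg.reflectance, 0.3)

    def test_mismatched_plots_rejected(self):
        with pytest.raises(ValidationError, match="mix"):
            average_replicate_scans([_record("p1"), _record("p2")])

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            average_replicate_scans([])

    def test_noise_attenuated_by_sqrt_n(self):
        """Averaging 10 scans with sigma=0.01 noise leaves per-band error with
        sd about 0.01/sqrt(10); the 2151 bands act as Monte-Carlo draws."""
        rng = np.random.default_rng(0)
        truth = _record("p1", 0.3)
        scans = []
        for _ in range(10):
            s = _record("p1", 0.3)
            s.reflectance = truth.reflectance + rng.normal(0, 0.01, 2151)
            scans.append(s)
        avg = average_replicate_scans(scans)
        dev = avg.reflectance - truth.reflectance
        assert dev.std() == pytest.approx(0.01 / np.sqrt(10), rel=0.15)

    def test_averaging_commutes_with_band_subsetting(self):
        rng = np.random.default_rng(1)
        wl = np.arange(400, 420)
        scans = []
        for _ in range(4):
            scans.append(SpectrumRecord(
                plot_id="p1", year=2022, site="S1", cultivar="C1",
                treatment="CK", stage="booting", wavelengths=wl,
                reflectance=rng.uniform(0.1, 0.5, wl.size)))
        full = average_replicate_scans(scans).reflectance[5:12]
        from dataclasses import replace
        subs = [replace(s, wavelengths=wl[5:12], reflectance=s.reflectance[5:12])
                for s in scans]
        np.testing.assert_array_equal(full, average_replicate_scans(subs).reflectance)


class TestMerge:
    @staticmethod
    def _tables(n=12):
        keys = pd.DataFrame({"plot_id": [f"p{i}" for i in range(n)],
                             "stage": "flowering"})
        a = keys.assign(LWC=np.linspace(0.6, 0.8, n))
        b = keys.assign(CWSI=np.linspace(0.1, 0.9, n))
        c = keys.assign(LAI=np.linspace(2, 6, n))
        return a, b, c

    def test_fully_matched_join(self):
        a, b, c = self._tables()
        merged = merge_observations(a, b, c)
        assert len(merged) == 12
        assert {"LWC", "CWSI", "LAI"} <= set(merged.columns)

    def test_orphan_key_dropped(self):
        a, b, c = self._tables()
        merged = merge_observations(a, b.iloc[:-1], c)
        assert len(merged) == 11

    def test_join_preserves_values(self):
        a, b, c = self._tables()
        merged = merge_observations(a, b, c).set_index("plot_id")
        for _, row in b.iterrows():
            assert merged.loc[row["plot_id"], "CWSI"] == row["CWSI"]

    def test_duplicate_keys_rejected(self):
        a, b, _ = self._tables()
        with pytest.raises(ValidationError, match="duplicate"):
            merge_observations(a, pd.concat([b, b.iloc[:1]]))
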