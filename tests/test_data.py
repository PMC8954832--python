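"""Library I/O, stratified splitting and delta-notation arithmetic."""

import numpy as np
import pytest

from isolocal import (
    IsotopeLibrary,
    IsotopeRecord,
    ParseError,
    delta_permil,
    read_library,
    stratified_split,
    write_library,
)
from isolocal.data import group_for_banner


class TestRecordsAndLibrary:
    def test_group_derived_from_banner(self):
        assert group_for_banner("SuniteRight") == "PGI"
        assert group_for_banner("Abaga") == "nonPGI"
        rec = IsotopeRecord("x", "SuniteLeft", -19, 7, -100, 13)
        assert rec.group == "PGI"

    def test_inconsistent_group_rejected(self):
        with pytest.raises(ParseError, match="inconsistent"):
            IsotopeRecord("x", "Siziwang", -21, 6, -120, 8, group="PGI")

    def test_non_finite_delta_rejected(self):
        with pytest.raises(ParseError, match="d2H"):
            IsotopeRecord("x", "Abaga", -21, 6, float("nan"), 8)

    def test_duplicate_ids_rejected(self):
        rec = IsotopeRecord("dup", "Abaga", -21, 6, -118, 8)
        with pytest.raises(ValueError, match="duplicate"):
            IsotopeLibrary([rec, rec])

    def test_toy_library_counts(self, toy_library):
        assert len(toy_library) == 4
        assert sum(g == "PGI" for g in toy_library.groups) == 2
        assert toy_library.values.shape == (4, 4)


class TestCsvRoundTrip:
    def test_round_trip_preserves_records(self, toy_library, tmp_path):
        path = tmp_path / "lib.csv"
        write_library(toy_library, path)
        back = read_library(path)
        assert back.sample_ids == toy_library.sample_ids
        assert back.groups == toy_library.groups
        np.testing.assert_allclose(back.values, toy_library.values)

    def test_missing_column_named_in_error(self, toy_library, tmp_path):
        path = tmp_path / "broken.csv"
        frame = toy_library.to_frame().drop(columns=["d18O"])
        frame.to_csv(path, index=False)
        with pytest.raises(ParseError, match="d18O"):
            read_library(path)

    def test_non_numeric_delta_names_row(self, toy_library, tmp_path):
        path = tmp_path / "broken.csv"
        frame = toy_library.to_frame().astype({"d13C": object})
        frame.loc[2, "d13C"] = "not-a-number"
        frame.to_csv(path, index=False)
        with pytest.raises(ParseError, match="row 2"):
            read_library(path)

    def test_unknown_banner_rejected(self, toy_library, tmp_path):
        path = tmp_path / "broken.csv"
        frame = toy_library.to_frame()
        frame.loc[0, "banner"] = "Atlantis"
        frame.to_csv(path, index=False)
        with pytest.raises(ParseError, match="Atlantis"):
            read_library(path)


class TestStratifiedSplit:
    def test_116_samples_split_93_23(self):
        from isolocal import full_config, generate_library

        lib = generate_library(full_config(seed=3))
        assert len(lib) == 116
        split = stratified_split(lib, test_fraction=0.2, seed=3)
        assert len(split.training) == 93
        assert len(split.testing) == 23
        # per-banner training counts reproduce the published 68/5/15/5
        counts = {b: split.training.banners.count(b) for b in set(lib.banners)}
        assert counts == {"SuniteRight": 68, "SuniteLeft": 5,
                          "Siziwang": 15, "Abaga": 5}

    def test_split_is_a_partition(self, split_116):
        train_ids = set(split_116.training.sample_ids)
        test_ids = set(split_116.testing.sample_ids)
        assert not train_ids & test_ids
        assert len(train_ids | test_ids) == 116

    def test_single_banner_exact_four_to_one(self):
        recs = [IsotopeRecord(f"s{i}", "Abaga", -21, 6, -118 + i, 8) for i in range(5)]
        split = stratified_split(IsotopeLibrary(recs), test_fraction=0.2, seed=0)
        assert (len(split.training), len(split.testing)) == (4, 1)

    def test_same_seed_same_partition(self, split_116):
        from isolocal import full_config, generate_library

        lib = generate_library(full_config(seed=11), label="full116")
        again = stratified_split(lib, test_fraction=0.2, seed=11)
        assert again.testing.sample_ids == split_116.testing.sample_ids

    def test_singleton_banner_cannot_stratify(self):
        recs = [
            IsotopeRecord("a", "Abaga", -21, 6, -118, 8),
            IsotopeRecord("b", "Abaga", -22, 6, -119, 8),
            IsotopeRecord("c", "Siziwang", -21, 6, -120, 8),
        ]
        with pytest.raises(ValueError, match="Siziwang"):
            stratified_split(IsotopeLibrary(recs), test_fraction=0.2, seed=0)

    @pytest.mark.parametrize("fraction", [0.1, 0.2, 0.3])
    def test_per_banner_ratio_within_one_sample(self, fraction):
        from isolocal import full_config, generate_library

        lib = generate_library(full_config(seed=5))
        split = stratified_split(lib, test_fraction=fraction, seed=5)
        for b in set(lib.banners):
            n = lib.banners.count(b)
            got = split.testing.banners.count(b)
            assert abs(got - n * fraction) <= 1


class TestDeltaPermil:
    def test_equal_ratios_give_zero(self):
        assert delta_permil(0.0112, 0.0112, "conventional") == 0.0
        assert delta_permil(0.0112, 0.0112, "as_printed") == 0.0

    def test_conventional_arithmetic(self):
        assert delta_permil(0.0112, 0.0111, "conventional") == pytest.approx(
            (0.0112 / 0.0111 - 1) * 1000, abs=1e-9
        )

    def test_as_printed_arithmetic(self):
        assert delta_permil(0.0112, 0.0111, "as_printed") == pytest.approx(
            (0.0001 / 0.0112) * 1000, abs=1e-9
        )

    def test_conventions_agree_to_first_order(self):
        for r in (0.01101, 0.011087, 0.01115):
            a = delta_permil(r, 0.0111, "conventional")
            b = delta_permil(r, 0.0111, "as_printed")
            assert abs(a - b) < 0.05 * max(abs(a), 1e-12)

    def test_non_positive_ratio_rejected(self):
        with pytest.raises(ValueError):
            delta_permil(0.0, 0.0111)
        with pytest.raises(ValueError):
            delta_permil(0.0112, -1.0)
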