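import math

import numpy as np
import pytest

from topomol import (
    Bar,
    Barcode,
    BinSpec,
    assemble_features,
    barcode_statistics,
    build_2d_image,
    counts_in_bins,
    feature_schema,
    make_toy_molecule,
    slice_statistics,
)
from topomol.vectorize import (
    ELECTROSTATIC_BINS,
    FEATURE_GROUPS,
    IMAGE_BINS,
    IMAGE_COMBINATIONS_128,
    INTERACTIVE_DISTANCE_BINS,
    INTERACTIVE_PAIRS_36,
    INTERACTIVE_PAIRS_50,
    INTERACTIVE_PAIRS_160,
    LIGAND_COMBINATIONS_32,
    LIGAND_COMBINATIONS_36,
)


def bc(pairs, dim=1, cap=12.0):
    return Barcode([Bar(dim, b, d) for b, d in pairs], cap=cap)


class TestCountsInBins:
    def test_enumerated_counts(self):
        bins = BinSpec.from_intervals([(0, 2), (2, 4)], closure="[)", last="[)")
        births, deaths, overlaps = counts_in_bins(bc([(0, 1), (0, 3)]), bins, dim=1)
        np.testing.assert_array_equal(births, [2, 0])
        np.testing.assert_array_equal(deaths, [1, 1])
        np.testing.assert_array_equal(overlaps, [2, 1])

    def test_empty_barcode(self):
        bins = BinSpec.uniform(0, 5, 5)
        births, deaths, overlaps = counts_in_bins(Barcode([], 5.0), bins, dim=1)
        assert births.sum() == deaths.sum() == overlaps.sum() == 0

    def test_interactive_bin_list(self):
        b = bc([(0, 2.7), (0, 5.0)], dim=0)
        _, deaths, _ = counts_in_bins(b, INTERACTIVE_DISTANCE_BINS, dim=0)
        np.testing.assert_array_equal(deaths, [0, 1, 0, 0, 1, 0])

    def test_dim0_has_no_birth_vector(self):
        births, _, _ = counts_in_bins(bc([(0, 1)], dim=0), INTERACTIVE_DISTANCE_BINS, 0)
        assert births is None

    def test_open_bar_overlaps_right_of_birth(self):
        bins = BinSpec.uniform(0, 4, 4)
        b = Barcode([Bar(0, 0.0, math.inf)], cap=4.0)
        _, deaths, overlaps = counts_in_bins(b, bins, dim=0)
        assert deaths.sum() == 0
        np.testing.assert_array_equal(overlaps, [1, 1, 1, 1])

    def test_birth_cover_totals(self):
        rng = np.random.default_rng(2)
        bars = [(x, x + y) for x, y in rng.uniform(0, 4, size=(30, 2))]
        b = bc(bars, dim=1, cap=20.0)
        bins = BinSpec.uniform(0, 8, 16)
        births, _, _ = counts_in_bins(b, bins, dim=1)
        assert births.sum() == len(bars)


class TestBarcodeStatistics:
    def test_enumerated_blocks(self):
        block = barcode_statistics(bc([(0, 1), (0, 3)]), dim=1)
        by_name = dict(zip(block.schema, block.values))
        assert by_name["d1|birth|cnt"] == 2
        assert by_name["d1|birth|sum"] == 0
        np.testing.assert_allclose(
            [by_name[f"d1|pers|{s}"] for s in ("avg", "std", "max", "min", "sum", "cnt")],
            [2, 1, 3, 1, 4, 2],
        )
        assert by_name["d1|pers|longest_birth"] == 0
        assert by_name["d1|pers|longest_death"] == 3

    def test_single_bar_longest_terms(self):
        block = barcode_statistics(bc([(2, 5)]), dim=1)
        by_name = dict(zip(block.schema, block.values))
        assert (by_name["d1|pers|longest_birth"], by_name["d1|pers|longest_death"]) == (2, 5)
        assert by_name["d1|pers|std"] == 0.0

    def test_empty_zero_block(self):
        block = barcode_statistics(Barcode([], 12.0), dim=2)
        assert np.all(block.values == 0)
        assert len(block) == 20

    def test_dim0_death_only(self):
        block = barcode_statistics(bc([(0, 1.5)], dim=0), dim=0)
        assert len(block) == 6
        assert all("death" in s for s in block.schema)

    def test_open_bars_capped(self):
        b = Barcode([Bar(1, 1.0, math.inf)], cap=10.0)
        block = barcode_statistics(b, 1)
        by_name = dict(zip(block.schema, block.values))
        assert by_name["d1|death|max"] == 10.0


class TestSliceStatistics:
    def test_death_sliced_partition(self):
        bins = BinSpec.from_intervals([(0, 2), (2, 4)], closure="[)", last="[)")
        block = slice_statistics(bc([(0, 1), (2, 3)]), "death", bins, dim=1)
        by_name = dict(zip(block.schema, block.values))
        assert by_name["d1|death-slice0|birth|cnt"] == 1
        assert by_name["d1|death-slice0|birth|avg"] == 0
        assert by_name["d1|death-slice1|birth|avg"] == 2

    def test_all_bars_one_slice(self):
        bins = BinSpec.from_intervals([(0, 2), (2, 4)])
        block = slice_statistics(bc([(0.1, 1), (0.2, 1.5)]), "death", bins, dim=1)
        by_name = dict(zip(block.schema, block.values))
        assert by_name["d1|death-slice1|birth|cnt"] == 0

    def test_persistence_sliced_has_both_blocks(self):
        bins = BinSpec.uniform(0, 5, 10)
        block = slice_statistics(bc([(0, 1)]), "persistence", bins, dim=1)
        assert len(block) == 10 * 12  # birth and death stats per slice

    def test_unknown_axis(self):
        with pytest.raises(ValueError):
            slice_statistics(bc([(0, 1)]), "diagonal", BinSpec.uniform(0, 5, 10), 1)


class TestTopoImage:
    def _barcodes(self, labels, with_bars=True):
        out = {}
        for lab in labels:
            bars = [Bar(0, 0, 1.0), Bar(1, 2.0, 3.0)] if with_bars else []
            out[lab] = Barcode(bars, cap=12.0)
        return out

    def test_complex_mode_16_channels(self):
        labels = [f"{p}-{l}" for p, l in IMAGE_COMBINATIONS_128]
        img = build_2d_image(
            self._barcodes(labels), IMAGE_BINS, labels,
            protein_barcodes=self._barcodes(labels, with_bars=False),
        )
        assert img.tensor.shape == (120, 128, 16)

    def test_single_structure_8_channels(self):
        img = build_2d_image(self._barcodes(["C"]), IMAGE_BINS, ["C"])
        assert img.tensor.shape == (120, 1, 8)

    def test_empty_barcodes_zero_tensor(self):
        img = build_2d_image(
            self._barcodes(["C", "N"], with_bars=False), IMAGE_BINS, ["C", "N"]
        )
        assert np.all(img.tensor == 0)

    def test_channel_sums_match_counts(self):
        b = self._barcodes(["C"])
        img = build_2d_image(b, IMAGE_BINS, ["C"])
        _, deaths0, _ = counts_in_bins(b["C"], IMAGE_BINS, 0)
        np.testing.assert_array_equal(img.tensor[:, 0, 0], deaths0)
        births1, _, _ = counts_in_bins(b["C"], IMAGE_BINS, 1)
        np.testing.assert_array_equal(img.tensor[:, 0, 2], births1)

    def test_missing_combination(self):
        with pytest.raises(ValueError, match="missing"):
            build_2d_image(self._barcodes(["C"]), IMAGE_BINS, ["C", "N"])

    def test_difference_channels_subtract(self):
        full = self._barcodes(["C"])
        img = build_2d_image(full, IMAGE_BINS, ["C"], protein_barcodes=full)
        assert np.all(img.tensor[:, :, 8:] == 0)


class TestFeatureGroups:
    def test_combination_list_sizes(self):
        assert len(LIGAND_COMBINATIONS_32) == 32
        assert len(LIGAND_COMBINATIONS_36) == 36
        assert len(INTERACTIVE_PAIRS_160) == 160
        assert len(INTERACTIVE_PAIRS_36) == 36
        assert len(INTERACTIVE_PAIRS_50) == 50
        assert len(IMAGE_COMBINATIONS_128) == 128

    @pytest.mark.parametrize(
        "group,length",
        [
            ("R-B0-I-C", 960),       # 6 bins x 160 pairs
            ("R-B0-I-BP", 216),      # 6 bins x 36 pairs
            ("R-B0-CI-C", 500),      # 10 bins x 50 pairs
            ("R-B0-CI-S", 300),      # 6 stats x 50 pairs
            ("A-B012-E-S", 1472),    # 46 stats x 32 combos
            ("A-B12-E-S", 80),       # 40 stats x 2 selections
        ],
    )
    def test_schema_lengths(self, group, length):
        assert len(feature_schema(group)) == length

    def test_a_b12_selections(self):
        group = FEATURE_GROUPS["A-B12-E-S"]
        assert group.combinations == ("heavy", "C")

    def test_assemble_matches_schema(self, small_complex):
        block = assemble_features(small_complex, "R-B0-I-BP")
        assert block.schema == feature_schema("R-B0-I-BP")
        assert len(block) == 216
        assert np.isfinite(block.values).all()

    def test_assemble_ligand_group(self):
        mol = make_toy_molecule(8, seed=4)
        block = assemble_features(mol, "A-B012-E-S")
        assert len(block) == 1472

    def test_electrostatic_group(self, small_complex):
        block = assemble_features(small_complex, "R-B0-CI-C")
        assert len(block) == 500
        assert block.values.sum() > 0  # the C-O cross pairs merge on axis

    def test_unknown_group(self, small_complex):
        with pytest.raises(KeyError):
            assemble_features(small_complex, "NOT-A-GROUP")

    def test_bar_order_irrelevant(self):
        bins = BinSpec.uniform(0, 5, 5)
        b1 = bc([(0, 1), (1, 2), (0.5, 3)])
        b2 = bc([(0.5, 3), (0, 1), (1, 2)])
        for dim_vecs in zip(counts_in_bins(b1, bins, 1), counts_in_bins(b2, bins, 1)):
            np.testing.assert_array_equal(*dim_vecs)
        np.testing.assert_array_equal(
            barcode_statistics(b1, 1).values, barcode_statistics(b2, 1).values
        )
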