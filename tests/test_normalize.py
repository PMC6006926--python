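import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apicomp.io import CopyNumberMap
from apicomp.normalize import (cells_from_reads, clr_from_cells, clr_transform,
                               copy_corrected_proportions, normalize_study,
                               percent_change_with_age, pool_low_abundance)

hyp = settings(derandomize=True, max_examples=60, deadline=None)


class TestCellsFromReads:
    def test_hand_computed_two_taxa(self):
        cells = cells_from_reads([0.5, 0.5], [4.0, 1.0], 1e6)
        assert cells == pytest.approx([125_000.0, 500_000.0])
        assert cells @ np.array([4.0, 1.0]) == pytest.approx(1e6)

    def test_single_taxon(self):
        assert cells_from_reads([1.0, 0.0], [2.5, 7.0], 1000)[0] \
            == pytest.approx(400.0)

    def test_equal_copies_symmetry(self):
        cells = cells_from_reads([0.25] * 4, [4.0] * 4, 4000)
        assert cells == pytest.approx([250.0] * 4)

    def test_multiply_convention_exposed(self):
        cells = cells_from_reads([0.5, 0.5], [4.0, 1.0], 100,
                                 convention="multiply")
        assert cells == pytest.approx([200.0, 50.0])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="total"):
            cells_from_reads([1.0], [4.0], 0.0)
        with pytest.raises(ValueError, match="sum"):
            cells_from_reads([0.7, 0.7], [4.0, 4.0], 10)


class TestPooling:
    def test_hand_computed(self):
        assert pool_low_abundance(0.042, 4.2, 1e6) == pytest.approx(10_000.0)

    def test_zero_rare_mass(self):
        assert pool_low_abundance(0.0, 4.2, 1e6) == 0.0

    def test_rare_biosphere_fraction(self):
        # the dataset-wide rare-biosphere mass of 1.2% at the mean copy number
        assert pool_low_abundance(0.012, 4.2, 1e8) \
            == pytest.approx(1e8 * 0.012 / 4.2)


class TestCopyCorrectedProportions:
    def test_hand_computed(self):
        q = copy_corrected_proportions([0.5, 0.5], [4.0, 1.0])
        assert q == pytest.approx([0.2, 0.8])

    def test_equal_copies_identity(self):
        p = np.array([0.2, 0.3, 0.5])
        assert copy_corrected_proportions(p, [4.0] * 3) == pytest.approx(p)

    def test_single_taxon(self):
        assert copy_corrected_proportions([0.4], [5.0]) == pytest.approx([1.0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            copy_corrected_proportions([0.0, 0.0], [4.0, 1.0])


class TestClr:
    def test_constant_composition_is_zero(self):
        assert clr_transform([1.0, 1.0, 1.0]) == pytest.approx([0, 0, 0])

    def test_hand_computed_zero_mean_logs(self):
        x = np.exp([2.0, -1.0, -1.0])
        assert clr_transform(x) == pytest.approx([2.0, -1.0, -1.0])

    @hyp
    @given(st.lists(st.floats(0.01, 1e4), min_size=2, max_size=12),
           st.floats(1e-6, 1e6))
    def test_scale_invariance_and_zero_row_sum(self, x, k):
        x = np.asarray(x)
        z = clr_transform(x)
        assert abs(z.sum()) < 1e-9
        assert np.allclose(clr_transform(k * x), z, atol=1e-9)

    def test_permutation_equivariance(self, rng):
        x = rng.uniform(0.1, 10, size=7)
        perm = rng.permutation(7)
        assert np.allclose(clr_transform(x[perm]),
                           clr_transform(x)[perm])

    def test_zeros_need_pseudocount(self):
        with pytest.raises(ValueError, match="pseudocount"):
            clr_transform([1.0, 0.0, 2.0])
        z = clr_transform([1.0, 0.0, 2.0], pseudocount=0.5)
        assert abs(z.sum()) < 1e-9

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            clr_transform([0.0, 0.0])


class TestPercentChange:
    def test_doubling_is_plus_100(self):
        assert percent_change_with_age(200, 100) == pytest.approx(100.0)

    def test_total_loss_bounded_at_minus_100(self):
        assert percent_change_with_age(0, 100) == pytest.approx(-100.0)

    def test_ratio_1_59_gives_plus_59(self):
        assert percent_change_with_age(159, 100) == pytest.approx(59.0)

    def test_zero_young_mean_undefined(self):
        assert np.isnan(percent_change_with_age(100, 0))

    @hyp
    @given(st.floats(0, 1e6), st.floats(0, 1e6), st.floats(1e-3, 1e6))
    def test_monotone_in_old_and_bounded(self, old1, old2, young):
        p1 = percent_change_with_age(old1, young)
        p2 = percent_change_with_age(old2, young)
        assert p1 >= -100 and p2 >= -100
        if old1 <= old2:
            assert p1 <= p2


class TestNormalizeStudy:
    def test_conservation_all_mode(self, small_study):
        cells = normalize_study(small_study["otu_table"], small_study["qpcr"])
        c = np.array([cells.provenance["copy_numbers"][t]
                      for t in cells.panel if t != "other"])
        named = [t for t in cells.panel if t != "other"]
        lhs = (cells.cells[named].to_numpy() * c).sum(axis=1) \
            + cells.cells["other"].to_numpy() * 4.2
        T = small_study["qpcr"].totals.loc[cells.cells.index].to_numpy()
        assert np.abs(lhs / T - 1).max() < 1e-9

    def test_conservation_panel_mode(self, small_study):
        cells = normalize_study(small_study["otu_table"], small_study["qpcr"],
                                renormalize="panel", include_other=False)
        c = np.array([cells.provenance["copy_numbers"][t] for t in cells.panel])
        lhs = (cells.cells.to_numpy() * c).sum(axis=1)
        T = small_study["qpcr"].totals.loc[cells.cells.index].to_numpy()
        assert np.abs(lhs / T - 1).max() < 1e-9

    def test_panel_is_top_otus_by_reads(self, small_study):
        cells = normalize_study(small_study["otu_table"], small_study["qpcr"])
        ranked = small_study["otu_table"].rank_otus()[:9]
        assert [t for t in cells.panel if t != "other"] == ranked

    def test_clr_rows_sum_to_zero(self, small_study):
        cells = normalize_study(small_study["otu_table"], small_study["qpcr"])
        clr = clr_from_cells(cells, small_study["otu_table"])
        assert np.abs(clr.z.to_numpy().sum(axis=1)).max() < 1e-9

    def test_unknown_taxon_uses_default_mean(self, small_study, caplog):
        cm = CopyNumberMap({"firm5": 4.0}, default_mean=4.2)
        with caplog.at_level("WARNING"):
            cells = normalize_study(small_study["otu_table"],
                                    small_study["qpcr"], cm)
        assert cells.provenance["copy_numbers"]["apium"] == pytest.approx(4.2)
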