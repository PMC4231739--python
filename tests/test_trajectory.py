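"""Series table dialect, strand flipping, selection and WC filtering."""

import numpy as np
import pandas as pd
import pytest

from tetradna import simulate as sim
from tetradna import trajectory as tj
from tetradna.sequence import Occurrence, reverse_complement


@pytest.fixture(scope="module")
def small_table(preset):
    return sim.generate_series(preset, "AGGC", 2000, seed=77)


class TestRoundTrip:
    def test_write_read_lossless(self, small_table, tmp_path):
        path = tmp_path / "series.csv"
        tj.write_series(small_table, path)
        back = tj.read_series(path)
        assert back.meta["sequence"] == "AGGC"
        assert list(back.df.columns) == list(small_table.df.columns)
        for col in small_table.df.columns:
            np.testing.assert_allclose(
                back.df[col], small_table.df[col], rtol=0, atol=1e-6
            )

    def test_shuffled_columns_same_logical_table(self, small_table, tmp_path):
        path = tmp_path / "shuffled.csv"
        cols = list(small_table.df.columns)
        shuffled = [cols[0]] + cols[:0:-1]
        tj.SeriesTable(small_table.df[shuffled], small_table.meta)
        tj.write_series(tj.SeriesTable(small_table.df[shuffled], small_table.meta), path)
        back = tj.read_series(path)
        np.testing.assert_allclose(back.get("twist", 2), small_table.get("twist", 2), atol=1e-6)

    def test_ragged_row_rejected_with_line(self, small_table, tmp_path):
        path = tmp_path / "ragged.csv"
        tj.write_series(small_table.iloc_slice(0, 10), path)
        lines = path.read_text().splitlines()
        lines[5] += ",1.0,2.0"
        path.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="line 6"):
            tj.read_series(path)

    def test_non_monotone_snapshot_rejected(self):
        df = pd.DataFrame({"snapshot": [0, 2, 1], "twist_1": [30.0, 31.0, 32.0],
                           "shift_1": [0.0, 0.1, 0.2]})
        with pytest.raises(ValueError, match="strictly increasing"):
            tj.SeriesTable(df, {"sequence": "AG"})

    def test_level_junction_inconsistency(self):
        df = pd.DataFrame({"twist_3": [30.0], "shear_3": [0.1]})  # 3 junctions, 3 levels
        with pytest.raises(ValueError, match="inconsistent"):
            tj.SeriesTable(df)

    def test_unknown_columns_pass_through(self, tmp_path):
        df = pd.DataFrame({"snapshot": [0, 1], "twist_1": [30.0, 31.0],
                           "mystery": [1.0, 2.0]})
        t = tj.SeriesTable(df, {"sequence": "AG"})
        path = tmp_path / "x.csv"
        tj.write_series(t, path)
        assert "mystery" in tj.read_series(path).df.columns


class TestStrandFlip:
    def test_double_flip_is_identity(self, small_table):
        flipped = tj.strand_flip(tj.strand_flip(small_table))
        assert flipped.meta["sequence"] == small_table.meta["sequence"]
        for col in small_table.df.columns:
            np.testing.assert_allclose(flipped.df[col], small_table.df[col])

    def test_sign_flips_and_renumbering(self, small_table):
        flipped = tj.strand_flip(small_table)
        assert flipped.meta["sequence"] == reverse_complement("AGGC")
        np.testing.assert_allclose(flipped.get("shift", 2), -small_table.get("shift", 2))
        np.testing.assert_allclose(flipped.get("slide", 2), small_table.get("slide", 2))
        np.testing.assert_allclose(flipped.get("twist", 1), small_table.get("twist", 3))


class TestCentralSelection:
    def test_central_junction_pick(self, small_table):
        occ = Occurrence("AGGC", "Watson", 1, (1, 2, 3, 4))
        sel = tj.central_selection(occ, small_table)
        assert sel["_junction"] == 2
        np.testing.assert_allclose(sel["twist"], small_table.get("twist", 2))
        np.testing.assert_allclose(sel["epsilon_W"], small_table.get("epsilon", 2, "W"))
        # Crick ε/ζ of junction 2 live on Crick nucleotide N−j = 2
        np.testing.assert_allclose(sel["epsilon_C"], small_table.get("epsilon", 2, "C"))
        # α/β/γ are the 3'-side nucleotide's
        np.testing.assert_allclose(sel["alpha_W"], small_table.get("alpha", 3, "W"))

    def test_crick_occurrence_matches_flipped_record(self, small_table):
        occ_crick = Occurrence("GCCT", "Crick", 1, (1, 2, 3, 4))
        sel = tj.central_selection(occ_crick, small_table)
        flipped = tj.strand_flip(small_table)
        occ_watson = Occurrence("GCCT", "Watson", 1, (1, 2, 3, 4))
        oracle = tj.central_selection(occ_watson, flipped)
        for key in oracle:
            if key.startswith("_"):
                continue
            np.testing.assert_allclose(sel[key], oracle[key], err_msg=key)

    def test_trinucleotide_fragment_selects_level(self, small_table):
        occ = Occurrence("AGG", "Watson", 1, (1, 2, 3))
        sel = tj.central_selection(occ, small_table)
        assert sel["_level"] == 2
        np.testing.assert_allclose(sel["propeller"], small_table.get("propeller", 2))
        np.testing.assert_allclose(sel["chi_W"], small_table.get("chi", 2, "W"))

    def test_edge_occurrence_rejected(self, small_table):
        occ = Occurrence("GCCT", "Watson", 4, (4, 5, 6, 7))
        with pytest.raises((ValueError, KeyError)):
            tj.central_selection(occ, small_table)


class TestWCFilter:
    def make_table(self, d_by_level):
        n = len(next(iter(d_by_level.values())))
        cols = {"snapshot": np.arange(n)}
        for lev, d in d_by_level.items():
            cols[f"wcdist1_{lev}"] = np.asarray(d, dtype=float)
            cols[f"wcdist2_{lev}"] = np.full(n, 2.9)
        for j in range(1, len(d_by_level)):
            cols[f"twist_{j}"] = np.full(n, 33.0)
        return tj.SeriesTable(pd.DataFrame(cols))

    def test_nothing_masked_when_intact(self):
        t = self.make_table({1: [2.9] * 5, 2: [2.9] * 5, 3: [2.9] * 5})
        assert not tj.wc_filter(t).any()

    def test_both_adjacent_junctions_masked(self):
        t = self.make_table({1: [2.9, 2.9], 2: [2.9, 3.6], 3: [2.9, 2.9], 4: [2.9, 2.9]})
        mask = tj.wc_filter(t)
        assert mask[1].tolist() == [True, True, False]
        assert not mask[0].any()

    def test_cutoff_is_strict(self):
        t = self.make_table({1: [3.5], 2: [3.5], 3: [3.5]})
        assert not tj.wc_filter(t).any()
        t2 = self.make_table({1: [3.5000001], 2: [2.9], 3: [2.9]})
        assert tj.wc_filter(t2)[0, 0]

    def test_masked_fraction_monotone_in_cutoff(self, small_table):
        fracs = [tj.wc_filter(small_table, cutoff=c).mean() for c in (4.5, 3.5, 3.0, 2.9)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_missing_columns_refused(self):
        df = pd.DataFrame({"snapshot": [0], "twist_1": [30.0], "twist_2": [30.0],
                           "twist_3": [30.0]})
        t = tj.SeriesTable(df, {"sequence": "AGGC"})
        with pytest.raises(ValueError, match="cannot filter"):
            tj.wc_filter(t)
        with pytest.warns(UserWarning):
            mask = tj.wc_filter(t, permissive=True)
        assert not mask.any()
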