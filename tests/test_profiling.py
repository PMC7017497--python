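"""Relative/absolute conversion, taxonomic collapse, contaminant calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from quantgut.loads import LoadEstimate
from quantgut.profiling import (
    Taxonomy,
    collapse_taxa,
    flag_contaminants_prevalence,
    mean_group_profile,
    remove_contaminants,
    score_contaminant_frequency,
    to_absolute,
    to_relative,
)
from quantgut.samples import SampleRecord


@pytest.fixture()
def five_asv_taxonomy():
    return Taxonomy.from_strings(
        {
            "a1": "d__B;p__F;c__C;o__Clostridiales;f__L;g__Roseburia;s__",
            "a2": "d__B;p__F;c__C;o__Clostridiales;f__R;g__Faecalibacterium;s__",
            "a3": "d__B;p__F;c__C;o__Clostridiales;f__;g__;s__",  # unassigned below order
            "a4": "d__B;p__F;c__B;o__Lactobacillales;f__L;g__Lactobacillus;s__",
            "a5": "d__B;p__F;c__B;o__Lactobacillales;f__L;g__Lactobacillus;s__",
        }
    )


class TestRelative:
    def test_rows_close_to_fractions(self):
        counts = pd.DataFrame({"t1": [30, 0, 5], "t2": [70, 0, 0]},
                              index=["s1", "s2", "s3"])
        rel = to_relative(counts)
        assert rel.loc["s1"].tolist() == [0.3, 0.7]
        assert rel.loc["s2"].isna().all()  # empty sample flagged
        assert rel.loc["s3"].tolist() == [1.0, 0.0]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            to_relative(pd.DataFrame())


class TestCollapse:
    def test_sums_within_order(self, five_asv_taxonomy):
        table = pd.DataFrame(
            [[2e5, 3e5, 1e5, 4e5, 1e5]], columns=list("a1 a2 a3 a4 a5".split()),
            index=["s"],
        )
        out = collapse_taxa(table, five_asv_taxonomy, "order")
        clost = [c for c in out.columns if "Clostridiales" in c][0]
        lacto = [c for c in out.columns if "Lactobacillales" in c][0]
        assert out.loc["s", clost] == pytest.approx(6e5)
        assert out.loc["s", lacto] == pytest.approx(5e5)

    def test_genus_then_order_equals_order_directly(self, five_asv_taxonomy):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            rng.integers(0, 100, size=(4, 5)).astype(float),
            columns=list("a1 a2 a3 a4 a5".split()),
            index=[f"s{i}" for i in range(4)],
        )
        by_genus = collapse_taxa(table, five_asv_taxonomy, "genus")
        genus_tax = Taxonomy.from_strings({c: c for c in by_genus.columns})
        re_order = collapse_taxa(by_genus, genus_tax, "order")
        direct = collapse_taxa(table, five_asv_taxonomy, "order")
        pd.testing.assert_frame_equal(
            re_order.sort_index(axis=1), direct.sort_index(axis=1)
        )

    def test_unassigned_below_level_groups_under_deepest_prefix(self, five_asv_taxonomy):
        table = pd.DataFrame([[1.0, 1.0, 1.0, 1.0, 1.0]],
                             columns=list("a1 a2 a3 a4 a5".split()), index=["s"])
        out = collapse_taxa(table, five_asv_taxonomy, "genus")
        # a3 is unassigned below order: it forms its own placeholder group
        placeholder = [c for c in out.columns if c.endswith(";;")]
        assert len(placeholder) == 1
        assert out.loc["s", placeholder[0]] == 1.0
        # a4 and a5 share the full genus lineage and merge
        lacto = [c for c in out.columns if "Lactobacillus" in c]
        assert len(lacto) == 1 and out.loc["s", lacto[0]] == 2.0

    def test_row_sums_conserved_at_every_level(self, five_asv_taxonomy):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            rng.random((3, 5)) * 1e6, columns=list("a1 a2 a3 a4 a5".split()),
            index=["x", "y", "z"],
        )
        for level in ("domain", "class", "order", "genus", "species"):
            out = collapse_taxa(table, five_asv_taxonomy, level)
            np.testing.assert_allclose(out.sum(axis=1), table.sum(axis=1))

    def test_unknown_level_rejected(self, five_asv_taxonomy):
        with pytest.raises(ValueError):
            collapse_taxa(pd.DataFrame({"a1": [1.0]}), five_asv_taxonomy, "kingdom")


def _meta(n_cecum=4, n_other=4):
    recs = []
    for i in range(n_cecum):
        recs.append(SampleRecord(f"c{i}", f"m{i}", "CTRL", "CEC", "contents", mass_g=0.05))
    for i in range(n_other):
        recs.append(SampleRecord(f"s{i}", f"m{i}", "CTRL", "STM", "contents", mass_g=0.05))
    return recs


class TestPrevalenceRule:
    def test_cases(self):
        meta = _meta()
        counts = pd.DataFrame(
            {
                "only_stomach": [0, 0, 0, 0, 9, 4, 2, 1],
                "one_cecum_read": [1, 0, 0, 0, 5, 5, 5, 5],
                "absent_everywhere": [0] * 8,
                "everywhere": [10] * 8,
            },
            index=[f"c{i}" for i in range(4)] + [f"s{i}" for i in range(4)],
        )
        calls = flag_contaminants_prevalence(counts, meta)
        assert [c.taxon for c in calls] == ["only_stomach"]

    def test_requires_cecum_samples(self):
        counts = pd.DataFrame({"t": [1, 2]}, index=["s0", "s1"])
        with pytest.raises(ValueError):
            flag_contaminants_prevalence(counts, _meta(n_cecum=0, n_other=2))


class TestFrequencyScore:
    def test_inverse_proportional_frequency_scores_zero(self):
        conc = pd.Series([1.0, 10.0, 100.0, 1000.0, 10000.0],
                         index=[f"s{i}" for i in range(5)])
        rel = pd.DataFrame(
            {"contam": 0.5 / conc, "biol": [0.2] * 5}, index=conc.index
        )
        calls = score_contaminant_frequency(rel, conc, threshold=0.5)
        assert [c.taxon for c in calls] == ["contam"]
        assert calls[0].score == pytest.approx(0.0, abs=1e-12)

    def test_constant_frequency_scores_one(self):
        conc = pd.Series(np.logspace(0, 4, 6), index=[f"s{i}" for i in range(6)])
        rel = pd.DataFrame({"biol": [0.3] * 6}, index=conc.index)
        assert score_contaminant_frequency(rel, conc) == []

    def test_too_few_presences_skipped_and_bad_conc_rejected(self):
        conc = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=[f"s{i}" for i in range(5)])
        rel = pd.DataFrame({"rare": [0.1, 0.0, 0.0, 0.0, 0.0]}, index=conc.index)
        assert score_contaminant_frequency(rel, conc) == []
        with pytest.raises(ValueError):
            score_contaminant_frequency(rel, conc * 0)


class TestRemoval:
    def test_relative_renormalized_absolute_not_rescaled(self):
        from quantgut.profiling import ContaminantCall

        rel = pd.DataFrame([[0.2, 0.3, 0.5]], columns=["a", "b", "c"], index=["s"])
        calls = [ContaminantCall("a", "cecum_prevalence")]
        out = remove_contaminants(rel, calls, is_relative=True)
        assert out.loc["s"].tolist() == pytest.approx([0.375, 0.625])
        absolute = pd.DataFrame([[2e5, 3e5, 5e5]], columns=["a", "b", "c"], index=["s"])
        out = remove_contaminants(absolute, calls, is_relative=False)
        assert out.loc["s"].tolist() == [3e5, 5e5]
        assert out.loc["s"].sum() == 8e5

    def test_organellar_switch(self):
        table = pd.DataFrame([[1.0, 2.0]], columns=["x;o__Chloroplast;y", "t"], index=["s"])
        kept = remove_contaminants(table, [], keep_organellar=True)
        assert "x;o__Chloroplast;y" in kept.columns
        dropped = remove_contaminants(table, [], keep_organellar=False)
        assert list(dropped.columns) == ["t"]


class TestAbsolute:
    def test_fraction_times_load(self):
        rel = pd.DataFrame([[0.25, 0.75]], columns=["a", "b"], index=["s"])
        loads = {"s": LoadEstimate("s", 4e6, "copies/g", "qpcr")}
        table = to_absolute(rel, loads)
        assert table.values.loc["s"].tolist() == [1e6, 3e6]
        assert table.unit == "copies/g"

    def test_below_llod_load_flags_whole_row(self):
        rel = pd.DataFrame([[0.5, 0.5]], columns=["a", "b"], index=["s"])
        loads = {"s": LoadEstimate("s", 0.0, "copies/g", "qpcr", flag="below_llod")}
        table = to_absolute(rel, loads)
        assert table.flags.loc["s"].all()

    def test_missing_load_names_sample(self):
        rel = pd.DataFrame([[1.0]], columns=["a"], index=["orphan"])
        with pytest.raises(KeyError, match="orphan"):
            to_absolute(rel, {})

    def test_cell_llod_one_read_equivalent(self):
        rel = pd.DataFrame([[0.00005, 0.99995]], columns=["a", "b"], index=["s"])
        loads = {"s": LoadEstimate("s", 1e6, "copies/g", "qpcr")}
        depths = pd.Series({"s": 10000.0})
        table = to_absolute(rel, loads, depths=depths)
        # cell LLOD = 1e6/1e4 = 100 copies/g; taxon a sits at 50
        assert bool(table.flags.loc["s", "a"]) is True
        assert bool(table.flags.loc["s", "b"]) is False

    @given(st.integers(min_value=1, max_value=6))
    @settings(max_examples=10, deadline=None)
    def test_relative_absolute_round_trip_conserves(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        counts = pd.DataFrame(
            rng.integers(1, 50, size=(3, n_taxa)).astype(float),
            index=["s1", "s2", "s3"],
        )
        rel = to_relative(counts)
        loads = {
            s: LoadEstimate(s, float(counts.loc[s].sum()), "copies/g", "qpcr")
            for s in counts.index
        }
        table = to_absolute(rel, loads)
        np.testing.assert_allclose(table.values.to_numpy(), counts.to_numpy(), rtol=1e-12)


class TestGroupMeans:
    def test_mean_and_renormalized_relative(self):
        meta = [
            SampleRecord("s1", "m1", "CTRL", "SI2", "contents", mass_g=0.05),
            SampleRecord("s2", "m2", "CTRL", "SI2", "contents", mass_g=0.05),
        ]
        table = pd.DataFrame([[1e6, 0.0], [0.0, 1e6]], columns=["a", "b"],
                             index=["s1", "s2"])
        absolute, relative = mean_group_profile(table, meta)
        key = ("CTRL", "SI2")
        assert absolute.loc[[key]].iloc[0].tolist() == [5e5, 5e5]
        assert relative.loc[[key]].iloc[0].tolist() == [0.5, 0.5]
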