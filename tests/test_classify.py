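import numpy as np
import pandas as pd
import pytest

from pioneerdep.classify import (
    classify_dependency,
    classify_elements,
    percent,
    summarize_categories,
)
from pioneerdep.genomic_io import GenomicInterval


def iv(name, start=1_000, chrom="chr1", width=200):
    return GenomicInterval(chrom, start, start + width, name, ".", width // 2)


def diff_table(statuses):
    return pd.DataFrame(
        {"element_id": list(statuses), "log2fc": 0.0, "pvalue": 0.5,
         "padj": 0.5, "status": list(statuses.values())}
    )


def run_one(ac, atac, wt_open=True, wt_active=True, locale="distal",
            scope="enhancer"):
    el = iv("e1")
    atac_peaks = [iv("atac1")] if wt_open else []
    ac_peaks = [iv("ac1")] if wt_active else []
    tss = pd.DataFrame(
        {"element_id": ["e1"], "nearest_gene": ["g1"],
         "tss_distance": [10_000], "locale": [locale]}
    )
    return classify_elements(
        [el], atac_peaks, ac_peaks, diff_table({"e1": ac}),
        diff_table({"e1": atac}), None, tss, scope=scope,
    )


class TestElementTaxonomy:
    @pytest.mark.parametrize(
        "ac,atac,expected",
        [
            ("down", "down", "pioneered_activated"),
            ("down", "unchanged", "nonpioneered_activated"),
            ("up", "up", "pioneered_inhibited"),
            ("up", "unchanged", "nonpioneered_inhibited_candidate"),
            ("unchanged", "unchanged", "quiescent"),
            ("down", "up", "unclassified_atac_discordant"),
            ("unchanged", "down", "unclassified_atac_discordant"),
        ],
    )
    def test_category_definitions(self, ac, atac, expected):
        res = run_one(ac, atac)
        assert list(res["category"]) == [expected]

    def test_activated_requires_open_and_active_in_wt(self):
        res = run_one("down", "down", wt_open=False)
        assert list(res["category"]) == ["unclassified_atac_discordant"]

    def test_inhibited_does_not_require_open_chromatin(self):
        res = run_one("up", "up", wt_open=False, wt_active=False)
        assert list(res["category"]) == ["pioneered_inhibited"]

    def test_scope_filters_locale(self):
        assert run_one("down", "down", locale="promoter_proximal").empty
        prom = run_one("down", "down", locale="promoter_proximal", scope="promoter")
        assert list(prom["category"]) == ["pioneered_activated"]

    def test_orphans_excluded_from_both_scopes(self):
        for scope in ("enhancer", "promoter"):
            assert run_one("down", "down", locale="orphan", scope=scope).empty

    def test_missing_differential_entry_is_an_error(self):
        el = iv("e1")
        tss = pd.DataFrame(
            {"element_id": ["e1"], "nearest_gene": ["g1"],
             "tss_distance": [10_000], "locale": ["distal"]}
        )
        with pytest.raises(KeyError, match="e1"):
            classify_elements(
                [el], [], [], diff_table({"other": "up"}),
                diff_table({"e1": "up"}), None, tss,
            )

    def test_input_order_invariance(self, standard_bundle):
        b = standard_bundle
        tss = pd.DataFrame(
            {
                "element_id": [e.name for e in b.elements()],
                "nearest_gene": "g",
                "tss_distance": 10_000,
                "locale": "distal",
            }
        )
        ac = diff_table({e.name: "down" for e in b.elements()})
        atac = diff_table({e.name: "down" for e in b.elements()})
        peaks = b.peaks["TF_A:WT"]
        fwd = classify_elements(peaks, b.peaks["ATAC:WT"], b.peaks["H3K27Ac:WT"],
                                ac, atac, None, tss)
        rev = classify_elements(peaks[::-1], b.peaks["ATAC:WT"],
                                b.peaks["H3K27Ac:WT"], ac, atac, None, tss)
        pd.testing.assert_frame_equal(fwd, rev)


def dep_run(tf, atac, recip="unchanged", cobound=True):
    second = [iv("m1")]
    primary = [iv("t1")] if cobound else [iv("t1", start=50_000)]
    return classify_dependency(
        second, primary, diff_table({"m1": tf}), diff_table({"m1": atac}),
        diff_table({"m1": recip}),
    )


class TestDependencyTaxonomy:
    @pytest.mark.parametrize(
        "tf,atac,recip,expected",
        [
            ("down", "down", "unchanged", "activated_pioneered"),
            ("down", "unchanged", "unchanged", "activated_nonpioneered"),
            ("down", "up", "unchanged", "activated_atac_up"),
            ("up", "up", "unchanged", "inhibited_pioneered"),
            ("up", "unchanged", "unchanged", "inhibited_nonpioneered"),
            ("unchanged", "down", "unchanged", "independent"),
            ("down", "down", "down", "mutually_dependent"),
            ("down", "unchanged", "down", "mutually_dependent"),
        ],
    )
    def test_category_definitions(self, tf, atac, recip, expected):
        res = dep_run(tf, atac, recip)
        assert list(res["category"]) == [expected]

    def test_not_cobound(self):
        res = dep_run("down", "down", cobound=False)
        assert list(res["category"]) == ["not_cobound"]
        assert not res["cobound"].iloc[0]

    def test_reciprocal_down_does_not_rescue_inhibited(self):
        # the mutual override only applies to activated peaks
        res = dep_run("up", "up", recip="down")
        assert list(res["category"]) == ["inhibited_pioneered"]

    def test_missing_reciprocal_table_warns_and_disables_mutual(self):
        second, primary = [iv("m1")], [iv("t1")]
        with pytest.warns(UserWarning, match="reciprocal"):
            res = classify_dependency(
                second, primary, diff_table({"m1": "down"}),
                diff_table({"m1": "down"}), None,
            )
        assert list(res["reciprocal_status"]) == ["not_tested"]
        assert list(res["category"]) == ["activated_pioneered"]


class TestSummaries:
    def test_paper_style_percent_split(self):
        # 3,083 / 2,022 / 338 of 5,443 print as 57 / 37 / 6
        cls = pd.DataFrame(
            {"category": ["A"] * 3083 + ["B"] * 2022 + ["C"] * 338}
        )
        summ = summarize_categories(cls, parent="dependent_peaks")
        got = dict(zip(summ["category"], summ["percent"]))
        assert got == {"A": 57, "B": 37, "C": 6}

    def test_single_category_is_100(self):
        summ = summarize_categories(pd.DataFrame({"category": ["only"] * 7}))
        assert list(summ["percent"]) == [100]

    def test_round_half_away_from_zero(self):
        assert percent(1, 200) == 1  # 0.5 -> 1
        assert percent(3, 200) == 2  # 1.5 -> 2
        assert percent(-1, 200) == -1

    def test_exclusion_shrinks_denominator(self):
        cls = pd.DataFrame({"category": ["x"] * 30 + ["not_cobound"] * 70})
        summ = summarize_categories(cls, exclude=("not_cobound",))
        assert list(summ["category"]) == ["x"]
        assert summ["parent_n"].iloc[0] == 30
        assert summ["percent"].iloc[0] == 100

    @pytest.mark.parametrize("seed", range(5))
    def test_exhaustive_partition_sums_to_100_within_rounding(self, seed):
        rng = np.random.default_rng(seed)
        cls = pd.DataFrame(
            {"category": rng.choice(list("abcde"), size=rng.integers(50, 500))}
        )
        summ = summarize_categories(cls)
        assert summ["count"].sum() == len(cls)
        assert abs(summ["percent"].sum() - 100) <= 1 + len(summ) // 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_categories(pd.DataFrame({"category": []}))
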