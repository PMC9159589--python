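import numpy as np
import pandas as pd
import pytest

from pioneerdep.diffsignal import (
    bh_adjust,
    call_status,
    differential_test,
    rpkm,
)
from pioneerdep.genomic_io import SampleSheet, SignalMatrix

from conftest import make_matrix

METHODS = ("moderated_t", "logratio_t", "nb_wald")


class TestRpkm:
    def test_closed_form(self, small_sheet):
        m = make_matrix(np.full((1, 8), 100), small_sheet, length=1000)
        vals = rpkm(m, small_sheet)
        assert np.allclose(vals.to_numpy(), 10.0)

    def test_zero_count(self, small_sheet):
        m = make_matrix(np.zeros((2, 8), dtype=int), small_sheet)
        assert (rpkm(m, small_sheet).to_numpy() == 0).all()

    def test_scale_invariance(self, small_sheet):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 500, size=(10, 8))
        m1 = make_matrix(counts, small_sheet)
        doubled = small_sheet.df.copy()
        doubled["library_size"] *= 2
        m2 = make_matrix(counts * 2, SampleSheet(doubled))
        assert np.allclose(
            rpkm(m1, small_sheet).to_numpy(),
            rpkm(m2, SampleSheet(doubled)).to_numpy(),
        )


class TestDifferentialTest:
    def test_identical_groups_are_exact_null(self, small_sheet):
        counts = np.tile([100, 120, 90, 110], (5, 2))
        m = make_matrix(counts, small_sheet)
        res = differential_test(m, small_sheet, method="logratio_t")
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["pvalue"], 1.0)

    @pytest.mark.parametrize("method", METHODS)
    def test_planted_depletion_recovers_log2fc(self, method, small_sheet):
        # 4-fold knockout depletion at mean 200: log2fc within +-0.5 of -2
        # for >= 90% of peaks (dispersion 0.05: at 0.1 the replicate-level
        # noise alone puts ~14% of peaks outside the half-unit window)
        rng = np.random.default_rng(12)
        r = 20.0  # dispersion 0.05
        mu_wt, mu_ko = 200.0, 50.0
        wt = rng.negative_binomial(r, r / (r + mu_wt), size=(500, 4))
        ko = rng.negative_binomial(r, r / (r + mu_ko), size=(500, 4))
        m = make_matrix(np.hstack([wt, ko]), small_sheet, length=400)
        res = differential_test(m, small_sheet, method=method)
        frac = np.mean(np.abs(res["log2fc"] - (-2)) <= 0.5)
        assert frac >= 0.90

    @pytest.mark.parametrize("method", METHODS)
    def test_group_swap_negates_log2fc_and_flips_status(self, method, small_sheet):
        rng = np.random.default_rng(5)
        counts = rng.integers(10, 2_000, size=(40, 8))
        m = make_matrix(counts, small_sheet)
        fwd = call_status(differential_test(m, small_sheet, ("KO_A", "WT"), method))
        rev = call_status(differential_test(m, small_sheet, ("WT", "KO_A"), method))
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        flip = {"up": "down", "down": "up", "unchanged": "unchanged"}
        assert list(rev["status"]) == [flip[s] for s in fwd["status"]]

    def test_zero_variance_degenerate_input_does_not_crash(self, small_sheet):
        counts = np.tile([50, 50, 50, 50, 10, 10, 10, 10], (3, 1))
        m = make_matrix(counts, small_sheet)
        for method in METHODS:
            res = differential_test(m, small_sheet, method=method)
            assert np.isfinite(res["pvalue"]).all()

    def test_single_replicate_group_rejected(self):
        rows = [
            {"sample_id": s, "assay": "ATAC", "genotype": g, "replicate": 1,
             "library_size": 1_000_000}
            for s, g in [("a", "WT"), ("b", "WT"), ("c", "KO_A")]
        ]
        sheet = SampleSheet(pd.DataFrame(rows))
        m = SignalMatrix(["p0"], ["a", "b", "c"], np.array([[1, 2, 3]]), np.array([100]))
        with pytest.raises(ValueError, match="replicate"):
            differential_test(m, sheet)

    def test_unknown_method_rejected(self, small_sheet):
        m = make_matrix(np.ones((1, 8), dtype=int), small_sheet)
        with pytest.raises(ValueError, match="method"):
            differential_test(m, small_sheet, method="deseq")


def bh_oracle(pvals):
    """Hand-rolled step-up: sort, p*n/rank, right-to-left cumulative min."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestBhAdjust:
    def test_hand_computed_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_identity(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    @pytest.mark.parametrize("n", [2, 17, 1_000, 10_000])
    def test_matches_step_up_oracle(self, n):
        rng = np.random.default_rng(n)
        p = rng.uniform(size=n)
        assert np.allclose(bh_adjust(p), bh_oracle(p))

    def test_dominates_input_and_preserves_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        # significance order preserved: adj is non-decreasing in p
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallStatus:
    def make(self, log2fc, pvalue):
        return pd.DataFrame(
            {"element_id": [f"e{i}" for i in range(len(log2fc))],
             "mean_wt": 1.0, "mean_ko": 1.0,
             "log2fc": log2fc, "pvalue": pvalue}
        )

    def test_fdr_mode_definitions(self):
        res = call_status(self.make([-1.4, -3.0, 1.2], [0.001, 0.9, 0.002]), mode="fdr")
        assert list(res["status"]) == ["down", "unchanged", "up"]

    def test_raw_p_mode(self):
        res = call_status(self.make([1.2], [1e-6]), mode="raw_p", alpha=1e-5)
        assert list(res["status"]) == ["up"]
        # same evidence fails the stricter default raw_p gate
        res2 = call_status(self.make([1.2], [1e-4]), mode="raw_p")
        assert list(res2["status"]) == ["unchanged"]

    def test_padj_dominates_pvalue(self):
        rng = np.random.default_rng(2)
        res = call_status(self.make(rng.normal(size=50), rng.uniform(size=50)))
        assert (res["padj"] >= res["pvalue"] - 1e-12).all()

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            call_status(self.make([0.0], [0.5]), mode="bonferroni")
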