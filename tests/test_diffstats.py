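"""NB Wald test, BH adjustment, rank-sum and effect-size primitives."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from minquant.diffstats import (
    ClassResponse,
    bh_adjust,
    call_significant,
    class_response,
    cohens_d,
    nb_wald_test,
)
from minquant.errors import ConfigurationError, DataError


def _nb_counts(rng, mu, disp, reps=3, prefix="a"):
    r = 1.0 / disp
    return {
        f"{prefix}_rep{i + 1}": rng.negative_binomial(r, r / (r + mu))
        for i in range(reps)
    }


class TestBhAdjust:
    def test_closed_form_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_nan_propagated_and_excluded(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 40)))
            got = bh_adjust(p)
            # brute-force step-up: p(i) * m / i with running minimum from the top
            m = len(p)
            order = np.argsort(p)
            oracle = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                running = min(running, p[order[rank - 1]] * m / rank)
                oracle[order[rank - 1]] = running
            np.testing.assert_allclose(got, oracle)

    def test_readjustment_never_lowers_and_fixes_constants(self):
        # step-up re-application can only raise values (p(j) * m/j >= p(j));
        # constant vectors, the fixed points, are unchanged
        rng = np.random.default_rng(1)
        p = rng.random(30)
        once = bh_adjust(p)
        assert (bh_adjust(once) >= once - 1e-12).all()
        np.testing.assert_allclose(bh_adjust([0.04] * 4), [0.04] * 4)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(2)
        p = rng.random(50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestNbWaldTest:
    def test_identical_counts_give_null_result(self):
        counts = pd.DataFrame(
            {
                "a_rep1": [10, 50], "a_rep2": [12, 55], "a_rep3": [9, 48],
                "b_rep1": [10, 50], "b_rep2": [12, 55], "b_rep3": [9, 48],
            }
        )
        res = nb_wald_test(counts, {c: c[0] for c in counts}, "a", "b")
        assert np.allclose(res["log2fc"], 0.0, atol=1e-6)
        assert (res["wald_p"] > 0.5).all()

    def test_all_zero_feature_excluded_from_bh(self):
        counts = pd.DataFrame(
            {c: [0, 100, 120] for c in
             ["a_rep1", "a_rep2", "b_rep1", "b_rep2"]}
        )
        res = nb_wald_test(counts, {c: c[0] for c in counts}, "a", "b")
        assert res["log2fc"].iloc[0] == 0.0
        assert np.isnan(res["wald_p"].iloc[0])
        assert np.isnan(res["padj"].iloc[0])

    def test_requires_two_replicates(self):
        counts = pd.DataFrame({"a_rep1": [1], "b_rep1": [2], "b_rep2": [3]})
        with pytest.raises(ConfigurationError, match="replicates"):
            nb_wald_test(counts, {c: c[0] for c in counts}, "a", "b")

    def test_size_factors_shift_the_estimate(self):
        rng = np.random.default_rng(3)
        mu = np.full(500, 100.0)
        disp = np.full(500, 0.02)
        counts = pd.DataFrame(
            {**_nb_counts(rng, mu, disp), **_nb_counts(rng, mu, disp, prefix="b")}
        )
        sf = pd.Series(1.0, index=counts.columns)
        sf[["b_rep1", "b_rep2", "b_rep3"]] = 2.0
        res = nb_wald_test(counts, {c: c[0] for c in counts}, "a", "b",
                           size_factors=sf)
        # same raw counts at doubled size factors = halved concentration
        assert res["log2fc"].mean() == pytest.approx(-1.0, abs=0.05)

    def test_type_one_error_is_calibrated(self):
        rng = np.random.default_rng(11)
        n = 2_000
        mu = np.exp(rng.uniform(np.log(20), np.log(500), n))
        disp = rng.uniform(0.01, 0.15, n)
        cols = {}
        for g in ("a", "b"):
            r = 1.0 / disp
            for i in range(3):
                cols[f"{g}_rep{i + 1}"] = rng.negative_binomial(r, r / (r + mu))
        counts = pd.DataFrame(cols)
        res = nb_wald_test(counts, {c: c[0] for c in counts}, "a", "b")
        frac = float((res["wald_p"] < 0.05).mean())
        assert 0.035 <= frac <= 0.065

    def test_effect_size_recovery(self):
        rng = np.random.default_rng(12)
        n = 1_000
        counts = pd.DataFrame(
            {
                **_nb_counts(rng, np.full(n, 100.0), np.full(n, 0.05)),
                **_nb_counts(rng, np.full(n, 400.0), np.full(n, 0.05), prefix="b"),
            }
        )
        res = nb_wald_test(counts, {c: c[0] for c in counts}, "a", "b")
        assert abs(res["log2fc"].mean() - 2.0) < 0.1

    def test_agrees_with_independent_nb_glm_oracle(self):
        # cross-check against pydeseq2 on a small fixture; the oracle shares
        # the model family but none of the implementation
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(3)
        n = 200
        mu = np.exp(rng.uniform(np.log(50), np.log(500), n))
        disp = rng.uniform(0.02, 0.1, n)
        lfc_true = np.where(rng.random(n) < 0.3, rng.normal(0, 1.5, n), 0.0)
        r = 1.0 / disp
        ya = rng.negative_binomial(r[:, None], (r / (r + mu))[:, None], (n, 3))
        yb = rng.negative_binomial(
            r[:, None], (r / (r + mu * 2.0**lfc_true))[:, None], (n, 3)
        )
        counts = pd.DataFrame(
            np.hstack([ya, yb]),
            columns=[f"{g}_rep{i}" for g in "ab" for i in (1, 2, 3)],
            index=[f"g{i}" for i in range(n)],
        )
        meta = pd.DataFrame({"condition": ["a"] * 3 + ["b"] * 3},
                            index=counts.columns)
        dds = DeseqDataSet(counts=counts.T, metadata=meta,
                           design="~condition", quiet=True)
        dds.deseq2()
        st = DeseqStats(dds, contrast=["condition", "b", "a"], quiet=True)
        st.summary()
        oracle = st.results_df["log2FoldChange"].to_numpy()
        mine = nb_wald_test(counts, {c: c[0] for c in counts}, "a", "b")
        ok = np.isfinite(oracle)
        assert np.corrcoef(oracle[ok], mine["log2fc"].to_numpy()[ok])[0, 1] > 0.999
        assert np.max(np.abs(oracle[ok] - mine["log2fc"].to_numpy()[ok])) < 0.2
        sig_o = st.results_df["padj"].to_numpy() < 0.05
        sig_m = mine["padj"].to_numpy() < 0.05
        assert (sig_o == sig_m).mean() > 0.9


class TestCallSignificant:
    def _diff(self, padj, lfc):
        return pd.DataFrame({"padj": padj, "log2fc": lfc},
                            index=[f"g{i}" for i in range(len(padj))])

    def test_chip_rule(self):
        up, down = call_significant(
            self._diff([0.04, 0.04, 0.2], [0.7, 0.5, 3.0]), 0.05, 1.5
        )
        assert up == {"g0"} and down == set()

    def test_rna_volcano_rule(self):
        # FDR < 5% and fold change 2 is the |log2FC| > 1 rule
        up, down = call_significant(
            self._diff([0.01, 0.01, 0.01], [1.1, 0.9, -1.2]), 0.05, 2.0
        )
        assert up == {"g0"} and down == {"g2"}


class TestClassResponse:
    def test_worked_cohens_d_example(self):
        # class {2,3,4} against the all-genes background {2,3,4,0,0,0,0}
        lfc = pd.Series([2.0, 3.0, 4.0, 0, 0, 0, 0],
                        index=[f"g{i}" for i in range(7)])
        got = cohens_d(np.array([2.0, 3.0, 4.0]), lfc.to_numpy())
        x = np.array([2.0, 3.0, 4.0])
        y = lfc.to_numpy()
        sp = np.sqrt(((2) * x.var(ddof=1) + 6 * y.var(ddof=1)) / 8)
        assert got == pytest.approx((3.0 - 9.0 / 7.0) / sp)
        resp = class_response(lfc, ["g0", "g1", "g2"], label="demo")
        assert resp.cohens_d == pytest.approx(got)
        assert resp.median_log2fc == 3.0

    def test_d_sign_flips_when_groups_swap(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(1, 1, 20), rng.normal(0, 1, 30)
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x))

    def test_zero_pooled_variance_gives_nan(self):
        assert np.isnan(cohens_d([1.0, 1.0], [1.0, 1.0, 1.0]))

    def test_small_groups_match_exact_enumeration(self):
        # the "at least as extreme" enumeration agrees with scipy's exact
        # rank-sum distribution on disjoint, tie-free samples away from the
        # distribution centre
        from minquant.diffstats import _exact_ranksum_p

        rng = np.random.default_rng(6)
        for _ in range(5):
            x = rng.normal(2, 1, 4)
            y = rng.normal(0, 1, 7)
            expected = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="exact"
            ).pvalue
            assert _exact_ranksum_p(x, y) == pytest.approx(expected, rel=1e-9)

    def test_class_response_uses_exact_branch_for_small_groups(self):
        lfc = pd.Series([5.0, 6.0, 7.0, 0.1, 0.2, 0.3, 0.4],
                        index=[f"g{i}" for i in range(7)])
        resp = class_response(lfc, ["g0", "g1", "g2"], label="small")
        assert 0.0 < resp.wilcoxon_p < 1.0
        # enumeration over C(10,3) assignments is deterministic
        again = class_response(lfc, ["g0", "g1", "g2"], label="small")
        assert resp.wilcoxon_p == again.wilcoxon_p

    def test_wilcoxon_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        lfc = pd.Series(rng.normal(size=200), index=[f"g{i}" for i in range(200)])
        members = [f"g{i}" for i in range(40)]
        p1 = class_response(lfc, members).wilcoxon_p
        p2 = class_response(np.exp(lfc), members).wilcoxon_p
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_class_equal_to_background_sample_is_null(self):
        rng = np.random.default_rng(8)
        lfc = pd.Series(rng.normal(size=500), index=[f"g{i}" for i in range(500)])
        members = list(rng.choice(lfc.index, 100, replace=False))
        resp = class_response(lfc, members)
        assert resp.wilcoxon_p > 0.05
        assert abs(resp.cohens_d) < 0.2

    def test_empty_class_rejected(self):
        lfc = pd.Series([1.0], index=["g0"])
        with pytest.raises(ConfigurationError):
            class_response(lfc, ["missing"])
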