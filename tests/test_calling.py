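"""Genotype calls, NoCall thresholding, concordance tables, MAF, quality."""

import numpy as np
import pandas as pd
import pytest

from snpmix import (
    ConfigError,
    GridSpec,
    InputError,
    MixtureFit,
    apply_nocall_threshold,
    call_genotypes,
    compute_maf,
    crosstab,
    preset,
    pstar_ecdf,
    quality_summaries,
    simulate_array,
    transform_signals,
)
from snpmix.pipeline import call_array


def _toy_fit(memberships):
    """A 1x1-bin mixture with prescribed membership probabilities."""
    m = np.asarray(memberships, float).reshape(3, 1, 1)
    grid = GridSpec(x_edges=np.array([0.0, 1.0]), y_edges=np.array([0.0, 1.0]))
    return MixtureFit(
        components=[None] * 3, mu=m.copy(), membership=m,
        pstar=m.max(axis=0), grid=grid, em_iterations=1, converged=True,
        loglik_trace=np.array([0.0]), frozen=np.zeros(3, bool),
    )


def _one_snp():
    return pd.DataFrame({"snp_id": ["s0"], "strength": [0.5], "contrast": [0.5]})


class TestCallGenotypes:
    def test_argmax_rule(self):
        calls = call_genotypes(_one_snp(), _toy_fit([0.2, 0.5, 0.3]))
        assert calls["call"].iloc[0] == "AB"
        assert calls["pstar"].iloc[0] == pytest.approx(0.5)

    def test_exact_tie_prefers_ab_and_flags(self):
        third = 1.0 / 3.0
        calls = call_genotypes(_one_snp(), _toy_fit([third, third, third]))
        assert calls["call"].iloc[0] == "AB"
        assert bool(calls["tie"].iloc[0])

    def test_two_way_tie_prefers_aa_over_bb(self):
        calls = call_genotypes(_one_snp(), _toy_fit([0.4, 0.2, 0.4]))
        assert calls["call"].iloc[0] == "AA"
        assert bool(calls["tie"].iloc[0])

    def test_probabilities_sum_to_one(self, affy_result):
        calls = affy_result.calls
        total = calls[["p_AA", "p_AB", "p_BB"]].sum(axis=1)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)
        assert (calls["pstar"] >= 1.0 / 3.0 - 1e-12).all()

    def test_every_snp_called(self, affy_array, affy_result):
        signals, _ = affy_array
        assert len(affy_result.calls) == len(signals)
        assert not (affy_result.calls["call"] == "NN").any()


class TestNoCallThreshold:
    def _calls(self, pstars):
        n = len(pstars)
        p = np.asarray(pstars)
        return pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(n)],
                "call": ["AB"] * n,
                "p_AA": (1 - p) / 2, "p_AB": p, "p_BB": (1 - p) / 2,
                "pstar": p,
            }
        )

    def test_none_is_identity(self):
        calls = self._calls([0.4, 0.9])
        out = apply_nocall_threshold(calls, None)
        pd.testing.assert_frame_equal(out, calls)

    def test_below_threshold_becomes_nn(self):
        out = apply_nocall_threshold(self._calls([0.40, 0.90]), 0.5)
        assert out["call"].tolist() == ["NN", "AB"]
        # probabilities are retained for later re-thresholding
        assert out["pstar"].iloc[0] == pytest.approx(0.40)

    def test_threshold_one_third_never_fires(self, affy_result):
        out = apply_nocall_threshold(affy_result.calls, 1.0 / 3.0)
        assert not (out["call"] == "NN").any()

    def test_idempotent_and_monotone(self):
        calls = self._calls([0.35, 0.55, 0.75, 0.95])
        once = apply_nocall_threshold(calls, 0.6)
        twice = apply_nocall_threshold(once, 0.6)
        pd.testing.assert_frame_equal(once, twice)
        higher = apply_nocall_threshold(once, 0.8)
        was_nn = once["call"] == "NN"
        assert (higher.loc[was_nn, "call"] == "NN").all()

    @pytest.mark.parametrize("bad", [0.2, 1.1, 0.0])
    def test_threshold_outside_range_rejected(self, bad):
        with pytest.raises(ConfigError):
            apply_nocall_threshold(self._calls([0.5]), bad)


class TestCrosstab:
    def _frame(self, ids, calls):
        return pd.DataFrame({"snp_id": ids, "call": calls})

    def test_self_comparison_is_diagonal(self):
        f = self._frame(list("abcdef"), ["AA", "AA", "AB", "BB", "NN", "BB"])
        table = crosstab(f, f)
        counts = table.counts.to_numpy()
        assert counts.sum() == 6
        assert np.trace(counts) == 6

    def test_hand_enumerated_toy_table(self):
        mine = self._frame(
            [f"s{i}" for i in range(10)],
            ["AA", "AA", "AB", "AB", "BB", "BB", "AA", "AB", "BB", "AA"],
        )
        ref = self._frame(
            [f"s{i}" for i in range(10)],
            ["AA", "AB", "AB", "AB", "BB", "NN", "AA", "BB", "BB", "AA"],
        )
        table = crosstab(mine, ref).counts
        assert table.loc["AA", "AA"] == 3
        assert table.loc["AA", "AB"] == 1
        assert table.loc["AB", "AB"] == 2
        assert table.loc["AB", "BB"] == 1
        assert table.loc["BB", "BB"] == 2
        assert table.loc["BB", "NN"] == 1
        assert table.to_numpy().sum() == 10

    def test_percent_columns_sum_to_100(self):
        rng = np.random.default_rng(4)
        labels = np.array(["AA", "AB", "BB", "NN"])
        mine = self._frame([f"s{i}" for i in range(200)], labels[rng.integers(0, 3, 200)])
        ref = self._frame([f"s{i}" for i in range(200)], labels[rng.integers(0, 4, 200)])
        pct = crosstab(mine, ref).percent()
        totals = crosstab(mine, ref).counts.sum(axis=0)
        for col in pct.columns:
            if totals[col] > 0:
                assert pct[col].sum() == pytest.approx(100.0, abs=1e-9)

    def test_disjoint_ids_rejected(self):
        with pytest.raises(InputError):
            crosstab(self._frame(["a"], ["AA"]), self._frame(["b"], ["AA"]))

    def test_unmatched_snps_counted(self):
        table = crosstab(
            self._frame(["a", "b", "c"], ["AA"] * 3),
            self._frame(["b", "c", "d"], ["AA"] * 3),
        )
        assert table.n_compared == 2
        assert table.n_only_calls == 1
        assert table.n_only_reference == 1


def test_channel_swap_symmetry_end_to_end():
    """Swapping the two signal channels swaps AA and BB everywhere."""
    cfg = preset("affymetrix_like", n_snps=5000, seed=13)
    signals, truth = simulate_array(cfg)
    swapped = signals.rename(columns={"signal_A": "signal_B", "signal_B": "signal_A"})
    res = call_array(signals)
    res_sw = call_array(swapped)
    swap = {"AA": "BB", "AB": "AB", "BB": "AA", "NN": "NN"}
    assert (
        res.calls["call"].astype(str).map(swap).tolist()
        == res_sw.calls["call"].astype(str).tolist()
    )
    tab = crosstab(res.calls, truth)
    truth_sw = truth.assign(genotype=truth["genotype"].map(swap))
    tab_sw = crosstab(res_sw.calls, truth_sw)
    np.testing.assert_array_equal(
        tab.counts.to_numpy(),
        tab_sw.counts.reindex(index=["BB", "AB", "AA", "NN"],
                              columns=["BB", "AB", "AA", "NN"]).to_numpy(),
    )


class TestMAF:
    def _tables(self, calls_per_array):
        out = []
        for calls in calls_per_array:
            out.append(
                pd.DataFrame(
                    {"snp_id": [f"s{i}" for i in range(len(calls))], "call": calls}
                )
            )
        return out

    def test_definition_arithmetic(self):
        # one SNP observed across 100 arrays: 50 AA, 40 AB, 10 BB
        tables = self._tables([["AA"]] * 50 + [["AB"]] * 40 + [["BB"]] * 10)
        maf = compute_maf(tables)
        assert maf["f_B"].iloc[0] == pytest.approx(0.3)
        assert maf["maf"].iloc[0] == pytest.approx(0.3)

    def test_monomorphic_is_zero(self):
        maf = compute_maf(self._tables([["AA", "AA"], ["AA", "AA"]]))
        assert (maf["maf"] == 0.0).all()

    def test_matches_direct_tally_oracle(self):
        rng = np.random.default_rng(6)
        labels = np.array(["AA", "AB", "BB", "NN"])
        arrays = [labels[rng.integers(0, 4, 30)] for _ in range(7)]
        maf = compute_maf(self._tables(arrays)).set_index("snp_id")
        for i in range(30):
            snp = f"s{i}"
            calls = [arr[i] for arr in arrays if arr[i] != "NN"]
            if not calls:
                assert np.isnan(maf.loc[snp, "maf"])
                continue
            n_b = sum(2 if c == "BB" else (1 if c == "AB" else 0) for c in calls)
            f = n_b / (2 * len(calls))
            assert maf.loc[snp, "maf"] == pytest.approx(min(f, 1 - f))


class TestQuality:
    def test_summaries_and_presence_counts(self, affy_result):
        calls = affy_result.calls
        summ = quality_summaries([calls, calls])
        assert summ["per_array"]["median_pstar"].iloc[0] > 0.99
        assert set(summ["per_snp"]["n_genotypes"].unique()) <= {1, 2, 3}
        # identical arrays: every SNP shows exactly one genotype
        assert (summ["per_snp"]["n_genotypes"] == 1).all()

    def test_ecdf_support_and_terminal_value(self, affy_result):
        x, f = pstar_ecdf(affy_result.calls["pstar"])
        assert x.min() >= 1.0 / 3.0 - 1e-12
        assert x.max() <= 1.0 + 1e-12
        assert f[-1] == pytest.approx(1.0)
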