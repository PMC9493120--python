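"""TPM identity, size factors, NB test behavior, ddCt arithmetic."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pirnakit.diffexp import call_de, ddct, nb_test, size_factors, tpm
from pirnakit.io import ValidationError
from pirnakit.synth import simulate_counts


class TestTPM:
    def test_single_tag_is_one_million(self):
        counts = pd.DataFrame({"s1": [7]}, index=["t1"])
        assert tpm(counts).iloc[0, 0] == pytest.approx(1e6)

    def test_three_to_one_split(self):
        counts = pd.DataFrame({"s1": [3, 1]}, index=["a", "b"])
        out = tpm(counts)
        assert out.loc["a", "s1"] == pytest.approx(750_000)
        assert out.loc["b", "s1"] == pytest.approx(250_000)

    def test_column_sums_on_random_matrix(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, (50, 6)).astype(float))
        counts.iloc[0] += 1  # keep every library non-empty
        sums = tpm(counts).sum(axis=0)
        assert np.allclose(sums, 1e6, atol=1e-6)

    def test_zero_library_is_an_error(self):
        counts = pd.DataFrame({"s1": [0, 0]})
        with pytest.raises(ValidationError):
            tpm(counts)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self, rng):
        col = rng.integers(1, 100, 40)
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_sample_gets_factor_two(self, rng):
        col = rng.integers(1, 100, 40)
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        counts["s0"] = counts["s0"] * 2
        sf = size_factors(counts)
        assert sf["s0"] == pytest.approx(2.0)
        assert np.allclose(sf[["s1", "s2", "s3"]], 1.0)

    def test_depth_gradient_recovered_within_5pct(self):
        counts, _, _ = simulate_counts(800, 3, dispersion=0.05, seed=4)
        depths = np.array([1.0, 1.5, 2.0, 0.5, 1.0, 1.2])
        scaled = (counts * depths).round().astype(int)
        sf = size_factors(scaled).to_numpy()
        rel = sf / sf[0]
        expected = depths / depths[0]
        assert np.all(np.abs(rel - expected) / expected < 0.05)

    def test_agrees_with_deseq2_reference(self):
        from pydeseq2.preprocessing import deseq2_norm

        counts, _, _ = simulate_counts(300, 4, dispersion=0.1, seed=5)
        ours = size_factors(counts).to_numpy()
        _, theirs = deseq2_norm(counts.T.to_numpy())  # samples x genes
        # factors are defined up to a global scale (we fix median factor = 1)
        np.testing.assert_allclose(ours / ours[0], theirs / theirs[0], rtol=1e-6)


class TestNBTest:
    def test_identical_groups_are_null(self):
        row = [20, 20, 20, 20, 20, 20]
        counts = pd.DataFrame([row] * 5, columns=[f"s{i}" for i in range(6)])
        groups = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        res = nb_test(counts, groups, dispersion=0.1)
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["pvalue"] > 0.99).all()

    def test_poisson_limit_matches_binomial_split_oracle(self, rng):
        n = 40
        counts = pd.DataFrame(
            rng.poisson(30, (n, 8)), columns=[f"s{i}" for i in range(8)]
        )
        counts += 1  # keep size factors well-defined
        groups = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        res = nb_test(counts, groups, dispersion=0.0)
        sf = size_factors(counts)
        sa = sf[[f"s{i}" for i in range(4)]].sum()
        sb = sf[[f"s{i}" for i in range(4, 8)]].sum()
        prob = sa / (sa + sb)
        for i in range(n):
            ka = counts.iloc[i, :4].sum()
            S = counts.iloc[i].sum()
            pmf = stats.binom.pmf(np.arange(S + 1), S, prob)
            expected = pmf[pmf <= pmf[ka] * (1 + 1e-9)].sum()
            assert res["pvalue"].iloc[i] == pytest.approx(expected, rel=1e-4)

    def test_label_swap_symmetry(self):
        counts, _, groups = simulate_counts(100, 4, dispersion=0.1, de_fraction=0.2, seed=6)
        res_ab = nb_test(counts, groups, numerator="FP", denominator="LP")
        res_ba = nb_test(counts, groups, numerator="LP", denominator="FP")
        np.testing.assert_allclose(res_ab["pvalue"], res_ba["pvalue"], rtol=1e-10)
        np.testing.assert_allclose(res_ab["log2fc"], -res_ba["log2fc"], rtol=1e-10)

    def test_stable_under_single_sample_scaling(self):
        # doubling one library is absorbed by its size factor: normalized
        # fold changes barely move and p-value ranking stays aligned (the
        # split test conditions on raw sums, so p-values are only
        # approximately invariant)
        counts, _, groups = simulate_counts(200, 4, dispersion=0.1, seed=7)
        scaled = counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 2
        a = nb_test(counts, groups)
        b = nb_test(scaled, groups)
        np.testing.assert_allclose(a["log2fc"], b["log2fc"], atol=0.1)
        assert stats.spearmanr(a["pvalue"], b["pvalue"]).statistic > 0.9

    def test_single_sample_group_rejected(self):
        counts = pd.DataFrame({"s1": [5], "s2": [5], "s3": [5]})
        with pytest.raises(ValidationError):
            nb_test(counts, {"s1": "A", "s2": "B", "s3": "B"})


class TestCallDE:
    def test_joint_screen_thresholds(self):
        res = pd.DataFrame(
            {
                "mean_count_FP": [50.0, 50.0],
                "mean_count_LP": [10.0, 30.0],
                "log2fc": [np.log2(3.0), np.log2(1.5)],
                "pvalue": [0.04, 0.04],
            }
        )
        res.attrs["groups"] = ("FP", "LP")
        out = call_de(res)
        assert list(out["direction"]) == ["up_in_FP", "ns"]

    def test_count_gate_is_strict_on_toy_table(self):
        # group means {3, 10, 11, 100, 0}: only >10 passes, i.e. two tags
        res = pd.DataFrame(
            {
                "mean_count_FP": [3.0, 10.0, 11.0, 100.0, 0.0],
                "mean_count_LP": [0.0, 1.0, 1.0, 1.0, 0.0],
                "log2fc": [3.0] * 5,
                "pvalue": [0.001] * 5,
            }
        )
        res.attrs["groups"] = ("FP", "LP")
        out = call_de(res)
        assert int(out["eligible"].sum()) == 2
        assert list(out.loc[out["eligible"], "direction"]) == ["up_in_FP", "up_in_FP"]


class TestDdct:
    def _records(self, dct_fp, dct_lp):
        rows = []
        for i, d in enumerate(dct_fp):
            rows.append({"sample": f"FP{i}", "group": "FP", "ct_target": 20.0 + d, "ct_reference": 20.0})
        for i, d in enumerate(dct_lp):
            rows.append({"sample": f"LP{i}", "group": "LP", "ct_target": 20.0 + d, "ct_reference": 20.0})
        return pd.DataFrame(rows)

    def test_calibrator_is_unity(self):
        rec = self._records([5, 5], [5, 5])
        out = ddct(rec, "LP")
        assert out["LP"] == pytest.approx(1.0) and out["FP"] == pytest.approx(1.0)

    def test_two_cycle_difference_is_fourfold(self):
        rec = self._records([5, 5], [7, 7])
        out = ddct(rec, "LP")
        assert out["FP"] == pytest.approx(4.0)

    def test_missing_reference_is_an_error(self):
        rec = self._records([5], [5])
        rec.loc[0, "ct_reference"] = np.nan
        with pytest.raises(ValidationError, match="Ct"):
            ddct(rec, "LP")
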