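"""Filtering, batch correction, normalization, imputation and ratio
summaries, checked against closed-form and simulation oracles."""

import numpy as np
import pandas as pd
import pytest

import heatsol as hs
from heatsol.io import IntensityTable
from heatsol.preprocess import glog2


def make_table(values, meta_rows, support=None, scale="raw"):
    channels = list(values.columns)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index").reindex(channels)
    for col in ("condition", "time_h", "silac", "replicate", "batch",
                "lysis", "temperature_C", "tmt_label"):
        if col not in meta.columns:
            meta[col] = np.nan
    return IntensityTable(values=values, channel_meta=meta,
                          peptide_support=support, scale=scale)


class TestFilterQuality:
    def _table(self, support):
        n = len(support)
        values = pd.DataFrame(
            {"c1": np.ones(n)},
            index=pd.Index([f"P{i}" for i in range(n)], name="protein_id"))
        sup = pd.DataFrame(support, index=values.index,
                           columns=["rep1", "rep2", "rep3"])
        return make_table(values, {"c1": {"condition": "heat"}}, sup)

    def test_single_peptide_everywhere_removed(self):
        tab = self._table([[1, 1, 1], [2, 2, 2]])
        out = hs.filter_quality(tab)
        assert list(out.proteins) == ["P1"]

    def test_two_peptides_in_two_replicates_retained(self):
        tab = self._table([[2, 2, 0], [2, 0, 0]])
        out = hs.filter_quality(tab)
        assert list(out.proteins) == ["P0"]

    def test_empty_table_passes_through(self):
        tab = self._table(np.empty((0, 3)))
        assert len(hs.filter_quality(tab).proteins) == 0

    def test_requires_support(self):
        tab = self._table([[2, 2, 2]])
        tab.peptide_support = None
        with pytest.raises(ValueError):
            hs.filter_quality(tab)


class TestCorrectBatches:
    def _table(self, values, batches):
        meta = {c: {"batch": b} for c, b in zip(values.columns, batches)}
        return make_table(values, meta, scale="log2")

    def test_single_batch_unchanged(self):
        vals = pd.DataFrame(np.arange(6.0).reshape(2, 3),
                            columns=["a", "b", "c"])
        tab = self._table(vals, ["x", "x", "x"])
        out = hs.correct_batches(tab)
        pd.testing.assert_frame_equal(out.values, vals)

    def test_constant_offset_removed_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, size=(20, 4))
        vals = np.hstack([base, base + 1.0])  # second batch offset +1
        cols = [f"c{i}" for i in range(8)]
        tab = self._table(pd.DataFrame(vals, columns=cols),
                          ["b1"] * 4 + ["b2"] * 4)
        out = hs.correct_batches(tab).values.to_numpy()
        # within-batch contrasts unchanged, batch means equalised
        assert np.allclose(out[:, :4] - out[:, :4].mean(1, keepdims=True),
                           base - base.mean(1, keepdims=True))
        assert np.allclose(out[:, :4].mean(1), out[:, 4:].mean(1))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(size=(30, 9)),
                            columns=[f"c{i}" for i in range(9)])
        batches = ["b1"] * 2 + ["b2"] * 3 + ["b3"] * 4
        tab = self._table(vals, batches)
        out = hs.correct_batches(tab).values.to_numpy()
        # oracle: per protein, OLS fit of mean + batch dummies; corrected
        # values are residuals re-centred to the protein grand mean
        X = np.zeros((9, 3))
        for j, b in enumerate(batches):
            X[j, ["b1", "b2", "b3"].index(b)] = 1.0
        for i in range(30):
            y = vals.to_numpy()[i]
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            fitted = X @ beta
            expected = y - fitted + y.mean()
            assert np.allclose(out[i], expected, atol=1e-9)

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        vals = pd.DataFrame(rng.normal(size=(10, 6)),
                            columns=[f"c{i}" for i in range(6)])
        tab = self._table(vals, ["b1"] * 3 + ["b2"] * 3)
        once = hs.correct_batches(tab)
        twice = hs.correct_batches(once)
        assert np.allclose(once.values.to_numpy(),
                           twice.values.to_numpy(), atol=1e-9)


class TestNormalizeVS:
    def _raw(self, arrays):
        vals = pd.DataFrame({f"c{i}": a for i, a in enumerate(arrays)})
        meta = {c: {"condition": "mock"} for c in vals.columns}
        return make_table(vals, meta)

    def test_identical_channels_identical_coefficients(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(12, 1, size=300)
        tab = self._raw([x, x, x])
        out, coeffs = hs.normalize_vs(tab)
        assert np.allclose(coeffs["a"], coeffs["a"].iloc[0])
        assert np.allclose(coeffs["b"], coeffs["b"].iloc[0])
        assert np.allclose(out.values["c0"], out.values["c1"])

    def test_doubled_channel_recovered_exactly(self):
        rng = np.random.default_rng(4)
        x = rng.lognormal(12, 1, size=500)
        tab = self._raw([x, 2 * x])
        out, _ = hs.normalize_vs(tab)
        q = np.linspace(0.1, 0.9, 17)
        assert np.allclose(np.quantile(out.values["c0"], q),
                           np.quantile(out.values["c1"], q), atol=1e-6)

    def test_glog2_asymptotic_identity(self):
        x = np.array([1e4, 1e5, 3e6])
        assert np.allclose(glog2(x), np.log2(2 * x), atol=1e-6)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(12, 2, size=400)
        tab = self._raw([x, x * rng.uniform(0.5, 2)])
        out, _ = hs.normalize_vs(tab)
        for c in ("c0", "c1"):
            assert (out.values[c].rank() == tab.values[c].rank()).all()

    def test_all_missing_channel_rejected(self):
        x = np.full(50, np.nan)
        y = np.ones(50)
        with pytest.raises(ValueError):
            hs.normalize_vs(self._raw([y, x]))


class TestTransferNormalization:
    def test_identical_tables_identical_output(self):
        rng = np.random.default_rng(6)
        x = rng.lognormal(12, 1, size=200)
        vals = pd.DataFrame({"c0": x, "c1": x * 1.5})
        meta = {c: {"condition": "mock"} for c in vals.columns}
        light = make_table(vals.copy(), meta)
        heavy = make_table(vals.copy(), meta)
        norm_light, coeffs = hs.normalize_vs(light)
        norm_heavy = hs.transfer_normalization(heavy, coeffs)
        pd.testing.assert_frame_equal(norm_light.values, norm_heavy.values)

    def test_shift_preserved_not_normalized_away(self):
        rng = np.random.default_rng(7)
        x = rng.lognormal(12, 1, size=500)
        vals = pd.DataFrame({"c0": x, "c1": x})
        meta = {c: {"condition": "mock"} for c in vals.columns}
        light = make_table(vals.copy(), meta)
        _, coeffs = hs.normalize_vs(light)
        heavy = make_table(pd.DataFrame({"c0": x, "c1": 4 * x}), meta)
        out = hs.transfer_normalization(heavy, coeffs)
        shift = (out.values["c1"] - out.values["c0"]).median()
        assert shift == pytest.approx(2.0, abs=0.01)

    def test_missing_coefficient_rejected(self):
        vals = pd.DataFrame({"c0": [1.0], "c9": [1.0]})
        meta = {c: {"condition": "mock"} for c in vals.columns}
        heavy = make_table(vals, meta)
        coeffs = pd.DataFrame({"a": [0.0], "b": [1.0]}, index=["c0"])
        with pytest.raises(ValueError):
            hs.transfer_normalization(heavy, coeffs)


class TestImputeMissing:
    def _table(self, vals):
        meta = {c: {"condition": "mock"} for c in vals.columns}
        return make_table(vals, meta, scale="log2")

    def test_no_missing_returns_same(self):
        vals = pd.DataFrame({"c0": [1.0, 2.0], "c1": [3.0, 4.0]})
        tab = self._table(vals)
        out = hs.impute_missing(tab, seed=0)
        pd.testing.assert_frame_equal(out.values, vals)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        vals = pd.DataFrame(rng.normal(20, 1, size=(100, 3)),
                            columns=["c0", "c1", "c2"])
        vals.iloc[rng.random(size=vals.shape) < 0.2] = np.nan
        a = hs.impute_missing(self._table(vals.copy()), seed=5)
        b = hs.impute_missing(self._table(vals.copy()), seed=5)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_imputed_distribution_matches_contract(self):
        # channel with mu = 20, sigma = 1: imputed mean ~ 20 - 1.8 = 18.2
        rng = np.random.default_rng(9)
        observed = rng.normal(20, 1, size=20000)
        col = np.concatenate([observed, np.full(10000, np.nan)])
        vals = pd.DataFrame({"c0": col})
        out = hs.impute_missing(self._table(vals), seed=11)
        imputed = out.values["c0"].to_numpy()[20000:]
        mu, sd = observed.mean(), observed.std(ddof=1)
        assert 18.1 <= imputed.mean() <= 18.3
        assert imputed.std() == pytest.approx(0.3 * sd, rel=0.05)
        assert np.allclose(out.values["c0"].to_numpy()[:20000], observed)


class TestRatioSummaries:
    def _paired_table(self, heat, mock, n_reps=1):
        """One channel pair per time point (single replicate)."""
        times = [0.0, 1.0, 2.0, 3.0, 5.0]
        cols, meta = {}, {}
        for t, h, m in zip(times, heat, mock):
            cols[f"heat_{t}"] = h
            cols[f"mock_{t}"] = m
            meta[f"heat_{t}"] = {"condition": "heat", "time_h": t,
                                 "silac": "light", "replicate": 1,
                                 "lysis": "NP40"}
            meta[f"mock_{t}"] = {"condition": "mock", "time_h": t,
                                 "silac": "light", "replicate": 1,
                                 "lysis": "NP40"}
        vals = pd.DataFrame(cols, index=["P0"])
        return make_table(vals, meta, scale="log2")

    def test_equal_channels_give_zero(self):
        tab = self._paired_table([np.array([5.0])] * 5,
                                 [np.array([5.0])] * 5)
        prof = hs.compute_solubility(tab)
        assert np.allclose(prof.s.to_numpy(), 0.0)

    def test_halved_intensity_gives_minus_one(self):
        tab = self._paired_table([np.array([9.0])] * 5,
                                 [np.array([10.0])] * 5)
        prof = hs.compute_solubility(tab)
        assert np.allclose(prof.s.to_numpy(), -1.0)

    def test_random_table_matches_subtraction_oracle(self):
        rng = np.random.default_rng(12)
        n, times, reps = 40, [0.0, 1.0, 2.0, 3.0, 5.0], [1, 2, 3]
        cols, meta = {}, {}
        for cond in ("heat", "mock"):
            for t in times:
                for r in reps:
                    cid = f"{cond}_{t}_{r}"
                    cols[cid] = rng.normal(20, 2, size=n)
                    meta[cid] = {"condition": cond, "time_h": t,
                                 "silac": "light", "replicate": r,
                                 "lysis": "NP40"}
        vals = pd.DataFrame(cols,
                            index=pd.Index([f"P{i}" for i in range(n)]))
        tab = make_table(vals, meta, scale="log2")
        prof = hs.compute_solubility(tab)
        for t in times:
            for r in reps:
                expected = (vals[f"heat_{t}_{r}"]
                            - vals[f"mock_{t}_{r}"]).to_numpy()
                assert np.array_equal(prof.s[(t, r)].to_numpy(), expected)

    def test_unmatched_replicates_rejected(self):
        tab = self._paired_table([np.array([5.0])] * 5,
                                 [np.array([5.0])] * 5)
        dropped = tab.values.drop(columns=["mock_1.0"])
        tab2 = make_table(dropped,
                          tab.channel_meta.drop(index=["mock_1.0"]).to_dict(
                              orient="index"), scale="log2")
        with pytest.raises(ValueError, match="unmatched"):
            hs.compute_solubility(tab2)


class TestTotalSolubility:
    def _lysis_tables(self, np40_vals, sds_vals, index):
        meta = {"pre": {"condition": "preshock", "time_h": np.nan,
                        "silac": "light", "replicate": 1}}
        np40 = make_table(pd.DataFrame({"pre": np40_vals}, index=index),
                          meta, scale="log2")
        sds = make_table(pd.DataFrame({"pre": sds_vals}, index=index),
                         meta, scale="log2")
        return np40, sds

    def test_equal_tables_fully_soluble(self):
        np40, sds = self._lysis_tables([5.0, 6.0], [5.0, 6.0],
                                       ["P0", "P1"])
        ts = hs.compute_total_solubility(np40, sds)
        assert np.allclose(ts["preshock"], 0.0)

    def test_quarter_ratio(self):
        np40, sds = self._lysis_tables([3.0], [5.0], ["P0"])
        ts = hs.compute_total_solubility(np40, sds)
        assert ts["preshock"].iloc[0] == pytest.approx(-2.0)

    def test_planted_insoluble_subpopulation_flagged(self, small_proteome,
                                                     noisefree_course):
        log2 = noisefree_course.log2()
        np40 = log2.select_channels(silac="light", lysis="NP40")
        sds = log2.select_channels(silac="light", lysis="SDS")
        ts = hs.compute_total_solubility(np40, sds)
        flags = hs.flag_insoluble_subpop(ts)
        expected = small_proteome.truth["insoluble_subpop"]
        assert (flags.loc[expected.index] == expected).all()


class TestSynthesisRatios:
    def _heavy_table(self, series_by_time, pre_value):
        cols = {"pre": np.array([pre_value])}
        meta = {"pre": {"condition": "preshock", "time_h": np.nan,
                        "silac": "heavy", "replicate": 1, "lysis": "NP40"}}
        for t, v in series_by_time.items():
            cid = f"heat_{t}"
            cols[cid] = np.array([v])
            meta[cid] = {"condition": "heat", "time_h": t,
                         "silac": "heavy", "replicate": 1, "lysis": "NP40"}
        vals = pd.DataFrame(cols, index=["P0"])
        return make_table(vals, meta, scale="log2")

    def test_doubling_gives_ratio_one(self):
        tab = self._heavy_table({5.0: 11.0}, 10.0)
        ratios = hs.compute_synthesis_ratios(tab)
        assert ratios[("heat", 5.0)].iloc[0] == pytest.approx(1.0)

    def test_constant_intensity_gives_zero(self):
        tab = self._heavy_table({1.0: 10.0, 5.0: 10.0}, 10.0)
        ratios = hs.compute_synthesis_ratios(tab)
        assert np.allclose(ratios.to_numpy(), 0.0)

    def test_missing_preshock_rejected(self):
        tab = self._heavy_table({5.0: 11.0}, 10.0)
        stripped = make_table(
            tab.values.drop(columns=["pre"]),
            tab.channel_meta.drop(index=["pre"]).to_dict(orient="index"),
            scale="log2")
        with pytest.raises(ValueError, match="pre-shock"):
            hs.compute_synthesis_ratios(stripped)

    def test_planted_top_induced_protein_ranks_first(self, big_proteome):
        tab = hs.simulate_solubility_course(
            big_proteome, noise=hs.NoiseParams.none(), seed=13,
            include_sds=False)
        heavy = tab.select_channels(silac="heavy").log2()
        ratios = hs.compute_synthesis_ratios(heavy)
        ranked = hs.rank_upregulated(ratios)
        truth = big_proteome.truth
        # expected winner maximises induction * synthesis accumulation
        accum = (1 - np.exp(-truth["synthesis_rate"] * 6.5)) \
            / (1 - np.exp(-truth["synthesis_rate"] * 1.5))
        stall = 1 - 0.5 * np.exp(-5.0 / 2.0)
        expected = (np.log2(accum) + np.log2(truth["heat_induction"])
                    + np.log2(stall)).idxmax()
        assert ranked.index[0] == expected
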