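"""Pseudo-bulk aggregation, quantile normalisation, moderated testing and
composite significance calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fibreomics import diffabund as da
from fibreomics.exceptions import InsufficientDataError, InvalidParameterError
from tests.conftest import make_matrix


def _pb(values: dict) -> da.PseudoBulkMatrix:
    """values: {(participant, group): {protein: value}}."""
    df = pd.DataFrame(values)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["participant", "group"])
    return da.PseudoBulkMatrix(values=df, n_fibres=df.notna().astype(int))


class TestPseudobulkMedian:
    def _matrix(self, fibre_values, participants):
        vals = {"P1": fibre_values}
        annotations = {
            f: {"participant": p, "condition": "control"}
            for f, p in participants.items()
        }
        return make_matrix(vals, annotations=annotations)

    @pytest.mark.parametrize(
        "fibre_vals,expected",
        [
            ({"f1": 7.0}, 7.0),
            ({"f1": 1.0, "f2": 2.0, "f3": 10.0}, 2.0),
            ({"f1": 1.0, "f2": 2.0, "f3": 3.0, "f4": 10.0}, 2.5),
        ],
    )
    def test_median_conventions(self, fibre_vals, expected):
        m = self._matrix(fibre_vals, {f: "p1" for f in fibre_vals})
        grouping = pd.Series("g", index=list(fibre_vals))
        pb = da.pseudobulk_median(m, grouping)
        assert pb.values.at["P1", ("p1", "g")] == expected
        assert pb.n_fibres.at["P1", ("p1", "g")] == len(fibre_vals)

    def test_fibre_order_invariance(self):
        vals = {"f1": 3.0, "f2": 1.0, "f3": 2.0}
        m = self._matrix(vals, {f: "p1" for f in vals})
        a = da.pseudobulk_median(m, pd.Series("g", index=["f1", "f2", "f3"]))
        b = da.pseudobulk_median(m, pd.Series("g", index=["f3", "f1", "f2"]))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_empty_grouping_raises(self):
        m = self._matrix({"f1": 1.0}, {"f1": "p1"})
        with pytest.raises(ValueError):
            da.pseudobulk_median(m, pd.Series(dtype=object))


class TestQuantileNormalise:
    def test_worked_two_column_example(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = da.quantile_normalise_frame(df)
        assert out["a"].tolist() == [2.5, 3.5, 4.5]
        assert out["b"].tolist() == [2.5, 3.5, 4.5]

    def test_identical_columns_fixed_point(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = da.quantile_normalise_frame(df)
        pd.testing.assert_frame_equal(out, df)

    def test_complete_columns_share_value_multiset(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        out = da.quantile_normalise_frame(df)
        ref = np.sort(out["a"].to_numpy())
        for col in "bcd":
            assert np.allclose(np.sort(out[col].to_numpy()), ref)

    def test_rank_order_preserved_within_columns(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("abc"))
        df.iloc[2, 0] = np.nan  # incomplete row exercises interpolation
        out = da.quantile_normalise_frame(df)
        for col in df:
            obs = df[col].dropna()
            assert (
                out.loc[obs.index, col].rank().tolist() == obs.rank().tolist()
            )

    def test_ties_get_mean_of_targets(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [10.0, 20.0, 30.0]})
        out = da.quantile_normalise_frame(df)
        ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)  # [5.5, 10.5, 17.5]
        assert out["a"].iloc[0] == out["a"].iloc[1] == pytest.approx(ref[:2].mean())

    def test_single_column_identity_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            out = da.quantile_normalise_frame(df)
        pd.testing.assert_frame_equal(out, df)


class TestModeratedFit:
    def test_zero_difference_protein(self):
        pb = _pb(
            {
                ("p1", "A"): {"P1": 1.0, "P2": 5.0},
                ("p2", "A"): {"P1": 2.0, "P2": 6.0},
                ("p1", "B"): {"P1": 1.0, "P2": 1.0},
                ("p2", "B"): {"P1": 2.0, "P2": 2.0},
            }
        )
        res = da.moderated_fit(pb, ("A", "B"), paired=True)
        assert res.loc["P1", "log2fc"] == 0.0
        assert res.loc["P1", "p_raw"] == pytest.approx(1.0)

    def test_equal_variance_limit_matches_pooled_ordinary_t(self):
        # every protein has the same residual pattern => d0 -> inf and the
        # moderated statistic collapses to the common-variance t
        base_a = np.array([0.0, 1.0, 2.0])
        base_b = np.array([0.0, 1.0, 2.0])
        shifts = [0.5, 1.0, 1.5, 2.0, 2.5, 3.0]
        cols = {}
        for part, val in zip(["p1", "p2", "p3"], base_a):
            cols[(part, "A")] = {f"P{i}": val + s for i, s in enumerate(shifts)}
        for part, val in zip(["p4", "p5", "p6"], base_b):
            cols[(part, "B")] = {f"P{i}": val for i, s in enumerate(shifts)}
        res = da.moderated_fit(_pb(cols), ("A", "B"), paired=False)
        s2 = 1.0  # var of [0,1,2] around mean, ddof within groups: SS=2+2 over df 4
        pooled_t = np.array(shifts) / np.sqrt(s2 * (1 / 3 + 1 / 3))
        assert np.allclose(res["t_mod"].to_numpy(), pooled_t)
        assert np.isinf(res["df_total"]).all()

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(0)
        cols = {}
        for part in ["p1", "p2", "p3", "p4"]:
            cols[(part, "A")] = {}
            cols[(part, "B")] = {}
        values = rng.normal(size=(500, 8))
        for g in range(500):
            for j, part in enumerate(["p1", "p2", "p3", "p4"]):
                cols[(part, "A")][f"P{g}"] = values[g, j]
                cols[(part, "B")][f"P{g}"] = values[g, 4 + j]
        res = da.moderated_fit(_pb(cols), ("A", "B"), paired=False)
        rate = (res["p_raw"] < 0.05).mean()
        ci = 1.96 * np.sqrt(0.05 * 0.95 / 500)
        assert 0.05 - ci <= rate <= 0.05 + ci

    def test_insufficient_groups(self):
        pb = _pb({("p1", "A"): {"P1": 1.0}})
        with pytest.raises(InsufficientDataError):
            da.moderated_fit(pb, ("A", "B"))

    def test_paired_equals_unpaired_without_participant_effects(self):
        rng = np.random.default_rng(2)
        n_part, n_prot = 40, 30
        cols = {}
        truth = rng.normal(0, 1, n_prot)
        for i in range(n_part):
            part = f"p{i}"
            cols[(part, "A")] = {
                f"P{g}": truth[g] + rng.normal(0, 0.5) for g in range(n_prot)
            }
            cols[(part, "B")] = {f"P{g}": rng.normal(truth[g], 0.5) for g in range(n_prot)}
        pb = _pb(cols)
        paired = da.moderated_fit(pb, ("A", "B"), paired=True)
        unpaired = da.moderated_fit(pb, ("A", "B"), paired=False)
        assert np.allclose(paired["log2fc"], unpaired["log2fc"], atol=1e-12)
        assert np.corrcoef(paired["t_mod"], unpaired["t_mod"])[0, 1] > 0.95


class TestXiaoScore:
    @pytest.mark.parametrize(
        "p,lfc,expected",
        [(0.05, 1.0, 0.05), (0.01, 2.0, 1e-4), (0.04, 0.5, 0.2), (1.0, 3.0, 1.0)],
    )
    def test_closed_form(self, p, lfc, expected):
        assert da.xiao_score(p, lfc) == pytest.approx(expected, rel=1e-12)

    def test_matches_log10_formulation(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(1e-6, 1, 50)
        lfc = rng.normal(0, 2, 50)
        s = np.abs(lfc) * (-np.log10(p))
        assert np.allclose(da.xiao_score(p, lfc), 10.0 ** (-s))

    def test_monotone_decreasing_in_fold_change(self):
        lfcs = np.linspace(0, 5, 40)
        pis = da.xiao_score(np.full_like(lfcs, 0.3), lfcs)
        assert np.all(np.diff(pis) < 0)

    def test_monotone_increasing_in_p(self):
        ps = np.linspace(0.001, 1, 40)
        pis = da.xiao_score(ps, np.full_like(ps, 1.7))
        assert np.all(np.diff(pis) > 0)

    def test_zero_p_clipped_before_exponentiation(self):
        # p=0 is clipped to the smallest positive float; the power may then
        # underflow to exactly 0, which still compares below any alpha
        pi = da.xiao_score(0.0, 2.0)
        assert 0 <= pi < 1e-300
        assert da.xiao_score(0.0, 0.5) == pytest.approx(np.finfo(float).tiny ** 0.5)

    def test_invalid_p(self):
        with pytest.raises(InvalidParameterError):
            da.xiao_score(1.5, 1.0)


class TestCalls:
    def _results(self, pis, lfcs):
        return pd.DataFrame(
            {
                "log2fc": lfcs,
                "p_raw": [0.5] * len(pis),
                "xiao_pi": pis,
                "significant": [pi < 0.05 for pi in pis],
            },
            index=[f"P{i}" for i in range(len(pis))],
        )

    def test_strict_threshold(self):
        res = self._results([0.049, 0.05], [1.0, 1.0])
        sig = da.call_significant(res)
        assert list(sig.index) == ["P0"]

    def test_empty_input(self):
        res = self._results([], [])
        assert da.call_significant(res).empty

    def test_unit_fold_change_reduces_to_raw_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.001, 0.2, 100)
        pi = da.xiao_score(p, np.ones(100))
        assert np.array_equal(pi < 0.05, p < 0.05)

    def test_overlap_direction(self):
        a = pd.DataFrame(
            {"log2fc": [1.0, -1.0], "significant": [True, True]}, index=["X", "Y"]
        )
        b = pd.DataFrame(
            {"log2fc": [1.0, 1.0], "significant": [True, True]}, index=["X", "Z"]
        )
        out = da.overlap_direction(a, b)
        assert out == {"common": ["X"], "concordant_count": 1, "discordant": []}
        b2 = pd.DataFrame({"log2fc": [-1.0], "significant": [True]}, index=["X"])
        out2 = da.overlap_direction(a, b2)
        assert out2["concordant_count"] == 0 and out2["discordant"] == ["X"]


class TestSrxClusterContrast:
    def _study_matrix(self, srx_by_fibre, participants):
        rng = np.random.default_rng(5)
        vals = {
            f"P{g}": {f: rng.normal(15, 1) for f in srx_by_fibre.index}
            for g in range(10)
        }
        annotations = {
            f: {"participant": p, "condition": "control"}
            for f, p in participants.items()
        }
        return make_matrix(vals, annotations=annotations)

    def test_participant_without_both_clusters_excluded(self):
        srx = pd.Series(
            {"f1": 10.0, "f2": 90.0, "f3": 20.0, "f4": 80.0, "f5": 95.0}
        )
        participants = {"f1": "p1", "f2": "p1", "f3": "p2", "f4": "p2", "f5": "p3"}
        m = self._study_matrix(srx, participants)
        res = da.srx_cluster_contrast(m, srx)
        assert (res["n_A"] == 2).all()  # p3 (high only) dropped

    def test_too_few_qualifying_participants(self):
        srx = pd.Series({"f1": 10.0, "f2": 90.0, "f3": 95.0})
        participants = {"f1": "p1", "f2": "p1", "f3": "p2"}
        m = self._study_matrix(srx, participants)
        with pytest.raises(InsufficientDataError):
            da.srx_cluster_contrast(m, srx)


def test_power_on_planted_effects():
    """>=90% of strong planted effects are recalled at the composite threshold."""
    rng = np.random.default_rng(6)
    parts = [f"p{i}" for i in range(4)]
    cols = {(p, g): {} for p in parts for g in ("A", "B")}
    n_prot, n_eff = 500, 50
    for g in range(n_prot):
        delta = 1.5 if g < n_eff else 0.0
        for p in parts:
            cols[(p, "A")][f"P{g:03d}"] = rng.normal(delta, 0.2)
            cols[(p, "B")][f"P{g:03d}"] = rng.normal(0.0, 0.2)
    res = da.moderated_fit(_pb(cols), ("A", "B"), paired=False)
    scored = da.score_results(res)
    hits = scored[scored["significant"]]
    true_ids = {f"P{g:03d}" for g in range(n_eff)}
    recall = len(true_ids & set(hits.index)) / n_eff
    assert recall >= 0.9
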