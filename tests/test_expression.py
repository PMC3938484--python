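"""Permutation t-tests, BH q-values, significance calls, reference table."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from acidstress.errors import InvalidInputError
from acidstress.expression import (
    ExpressionStudy,
    call_significant,
    de_analysis,
    fdr_qvalues,
    fold_changes,
    load_reference_table,
    median_center,
    permutation_t_test,
    signed_ratio,
    table_extremes,
)
from acidstress.synth import gen_de_study


def make_study(control_rows, treated_rows, genes=None):
    """Build a study from per-gene lists of (control values, treated values)."""
    n_c = len(control_rows[0])
    n_t = len(treated_rows[0])
    cols = [f"c{i}" for i in range(n_c)] + [f"t{i}" for i in range(n_t)]
    data = np.hstack([np.array(control_rows), np.array(treated_rows)])
    genes = genes or [f"g{i}" for i in range(data.shape[0])]
    conds = ["control"] * n_c + ["treated"] * n_t
    return ExpressionStudy(
        matrix=pd.DataFrame(data, index=genes, columns=cols),
        conditions=pd.Series(conds, index=cols),
    )


def brute_force_perm_p(control, treated):
    """Independent enumeration oracle over all label splits."""
    values = np.array(list(control) + list(treated))
    k = len(treated)
    idx = range(len(values))

    def tstat(tr, ct):
        tr, ct = np.asarray(tr, float), np.asarray(ct, float)
        n1, n2 = len(tr), len(ct)
        sp2 = (tr.var(ddof=1) * (n1 - 1) + ct.var(ddof=1) * (n2 - 1)) / (n1 + n2 - 2)
        denom = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        diff = tr.mean() - ct.mean()
        if denom == 0:
            return 0.0 if diff == 0 else np.inf * np.sign(diff)
        return diff / denom

    obs = abs(tstat(treated, control))
    count, total = 0, 0
    for treat_idx in combinations(idx, k):
        tr = values[list(treat_idx)]
        ct = np.delete(values, list(treat_idx))
        total += 1
        if abs(tstat(tr, ct)) >= obs - 1e-12:
            count += 1
    return count / total


class TestPermutationTTest:
    def test_worked_exhaustive_example(self):
        # 3v3, clean separation: 2 of the 20 splits reach |t_obs|
        study = make_study([[1, 2, 3]], [[11, 12, 13]])
        res = permutation_t_test(study, n_perm=10000)
        assert res.attrs["exhaustive"]
        assert res["p"].iloc[0] == pytest.approx(2 / 20)

    def test_identical_groups_p_one(self):
        study = make_study([[5, 6, 7]], [[5, 6, 7]])
        res = permutation_t_test(study, n_perm=1000)
        assert res["p"].iloc[0] == 1.0

    def test_degenerate_gene_flagged(self):
        study = make_study([[4, 4, 4]], [[4, 4, 4]])
        res = permutation_t_test(study)
        assert res["degenerate"].iloc[0]
        assert res["p"].iloc[0] == 1.0

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, (2, 4))
        s1 = make_study([a], [b])
        s2 = make_study([b], [a])
        p1 = permutation_t_test(s1)["p"].iloc[0]
        p2 = permutation_t_test(s2)["p"].iloc[0]
        assert p1 == pytest.approx(p2)

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 3), (4, 4)])
    def test_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(3):
            ct = rng.normal(0, 1, n1)
            tr = rng.normal(0.8, 1, n2)
            study = make_study([ct], [tr])
            res = permutation_t_test(study, n_perm=10000)
            assert res.attrs["exhaustive"]
            assert res["p"].iloc[0] == pytest.approx(
                brute_force_perm_p(ct, tr), abs=1e-12
            )

    def test_sampled_mode_uses_add_one_estimator(self):
        rng = np.random.default_rng(0)
        study = make_study([rng.normal(0, 1, 6)], [rng.normal(3, 1, 6)])
        # C(12,6)=924 > 500 → sampled
        res = permutation_t_test(study, n_perm=500, seed=11)
        assert not res.attrs["exhaustive"]
        assert res["p"].iloc[0] >= 1 / 501

    def test_type_one_error_control_under_null(self):
        """Null simulation: fraction with p<=0.1 near the achievable level."""
        rng = np.random.default_rng(19)
        n_genes = 1000
        data = rng.normal(8, 1, size=(n_genes, 6))
        cols = [f"s{i}" for i in range(6)]
        study = ExpressionStudy(
            matrix=pd.DataFrame(data, index=[f"g{i}" for i in range(n_genes)],
                                columns=cols),
            conditions=pd.Series(["control"] * 3 + ["treated"] * 3, index=cols),
        )
        res = permutation_t_test(study, n_perm=10000)
        assert res.attrs["exhaustive"]
        frac = float((res["p"] <= 0.1).mean())
        # discrete null with 20 splits: achievable level is 2/20 = 0.1;
        # binomial 3σ band around 0.1 with n=1000
        assert abs(frac - 0.1) <= 3 * np.sqrt(0.1 * 0.9 / n_genes)


class TestFdrQvalues:
    def test_hand_worked_bh(self):
        q = fdr_qvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(fdr_qvalues([1.0, 1.0, 1.0]), 1.0)

    def test_order_invariance(self):
        p = np.array([0.3, 0.01, 0.7, 0.04, 0.02])
        q = fdr_qvalues(p)
        perm = np.array([4, 2, 0, 3, 1])
        assert np.allclose(fdr_qvalues(p[perm]), q[perm])

    def test_bh_rank_bound_and_monotonicity(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 200)
        q = fdr_qvalues(p)
        order = np.argsort(p)
        q_sorted = q[order]
        assert np.all(np.diff(q_sorted) >= -1e-12)
        m = len(p)
        ranks = np.arange(1, m + 1)
        # BH sandwich: p <= q <= p·m/rank after sorting
        assert np.all(q_sorted >= p[order] - 1e-12)
        assert np.all(q_sorted <= p[order] * m / ranks + 1e-12)
        assert np.all(q <= 1.0)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(InvalidInputError):
            fdr_qvalues([0.5, 1.2])


class TestFoldChangeAndCalls:
    def test_signed_ratio_convention(self):
        assert signed_ratio(1.0) == pytest.approx(2.0)
        assert signed_ratio(-1.0) == pytest.approx(-2.0)
        assert signed_ratio(np.log2(25.3)) == pytest.approx(25.3)

    def test_ratio_and_fc_mutually_recoverable(self):
        for fc in np.linspace(-6, 6, 25):
            r = signed_ratio(fc)
            back = np.sign(r) * np.log2(abs(r))
            assert back == pytest.approx(fc, abs=1e-9)

    def test_fc_cut_excludes_small_effects(self):
        df = pd.DataFrame(
            {"q": [0.04, 0.04], "log2_fc": [0.5, 1.0],
             "ratio": [signed_ratio(0.5), signed_ratio(1.0)]},
            index=["small", "boundary"],
        )
        kept = call_significant(df)
        assert "small" not in kept.index
        assert "boundary" in kept.index  # |FC| >= 1 is inclusive

    def test_q_cut_is_strict(self):
        df = pd.DataFrame(
            {"q": [0.05, 0.049], "log2_fc": [2.0, 2.0],
             "ratio": [4.0, 4.0]},
            index=["at", "under"],
        )
        kept = call_significant(df)
        assert list(kept.index) == ["under"]

    def test_spiked_study_recovery(self):
        """10 true 4-fold genes among 500 nulls: all recovered, <=1 false."""
        study, truth = gen_de_study(
            n_genes=500, n_spiked=10, effect_log2=2.0, noise_sd=0.25, seed=123
        )
        res = de_analysis(study, n_perm=2000, seed=123)
        hits = call_significant(res)
        spiked = set(truth.params["spiked_genes"])
        assert spiked <= set(hits.index)
        assert len(set(hits.index) - spiked) <= 1

    def test_median_center_removes_sample_offsets(self):
        study, _ = gen_de_study(n_genes=50, n_spiked=0, seed=1)
        shifted = ExpressionStudy(
            matrix=study.matrix + np.arange(6) * 1.5,
            conditions=study.conditions,
        )
        centered = median_center(shifted)
        assert np.allclose(centered.matrix.median(axis=0), 0.0)
        # centering restores the (median-centered) original fold changes
        assert np.allclose(
            fold_changes(centered), fold_changes(median_center(study)), atol=1e-9
        )


class TestReferenceTable:
    def test_extremes_match_printed_values(self):
        table = load_reference_table()
        (gmax, vmax), (gmin, vmin) = table_extremes(table)
        assert (gmax, vmax) == ("gadB", pytest.approx(25.3))
        assert (gmin, vmin) == ("nmpC", pytest.approx(-16.3))

    def test_table_filtering_and_ranking(self):
        table = load_reference_table()
        assert len(table) == 79
        assert (table["ratio"].abs() >= 2.0).all()
        # sorted by signed ratio descending (magnitude within each sign block)
        assert table["ratio"].iloc[0] == 25.3
        assert table["ratio"].iloc[-1] == -16.3

    def test_single_row_table(self):
        one = load_reference_table().iloc[[0]]
        (gmax, vmax), (gmin, vmin) = table_extremes(one)
        assert gmax == gmin == "gadB"

    def test_empty_table_rejected(self):
        with pytest.raises(InvalidInputError):
            table_extremes(load_reference_table().iloc[0:0])


def test_tsv_roundtrip(tmp_path):
    study, _ = gen_de_study(n_genes=20, n_spiked=2, seed=9)
    mpath, spath = tmp_path / "m.tsv", tmp_path / "s.tsv"
    study.matrix.reset_index(names="gene_id").to_csv(mpath, sep="\t", index=False)
    pd.DataFrame({
        "sample_id": study.conditions.index,
        "condition": study.conditions.values,
    }).to_csv(spath, sep="\t", index=False)
    loaded = ExpressionStudy.from_tsv(mpath, spath)
    assert np.allclose(loaded.matrix.to_numpy(), study.matrix.to_numpy())
    assert list(loaded.conditions) == list(study.conditions)
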