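from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigstrat.cohort_io import ExpressionMatrix, Scale, SignatureCollection
from sigstrat.enrichment import (
    CombineMode,
    EnrichmentResult,
    ScoreTable,
    SsgseaParams,
    combine_updn,
    concordant_enrichment,
    filter_geneset_categories,
    gsea_two_class,
    ssgsea_score,
)


def ssgsea_oracle(expr: pd.Series, gene_set: set[str], alpha: float) -> float:
    """Independent step-by-step running-sum computation of the single-sample
    score: rank genes descending (ties by gene id), accumulate the difference
    between weighted in-set and uniform out-of-set cumulative fractions."""
    ordered = sorted(expr.index, key=lambda g: (-expr[g], g))
    n = len(ordered)
    ranks = {g: n - i for i, g in enumerate(ordered)}
    in_total = sum(ranks[g] ** alpha for g in ordered if g in gene_set)
    n_out = n - sum(1 for g in ordered if g in gene_set)
    es = 0.0
    cum_in = 0.0
    cum_out = 0
    for g in ordered:
        if g in gene_set:
            cum_in += ranks[g] ** alpha
        else:
            cum_out += 1
        es += cum_in / in_total - cum_out / n_out
    return es


def random_matrix(rng, n_genes, n_samples):
    values = pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(n_samples)],
    )
    return ExpressionMatrix(values=values, scale=Scale.log2CPM)


class TestSsgsea:
    def test_five_gene_toy_matches_running_sum_oracle(self, tiny_matrix):
        score = ssgsea_score(tiny_matrix, ["G1", "G3"], SsgseaParams(alpha=0.75))
        expected = ssgsea_oracle(tiny_matrix.values["s1"], {"G1", "G3"}, 0.75)
        assert score["s1"] == pytest.approx(expected)
        # frozen value from the oracle: ranks 5..1, set at ranks 5 and 3
        assert score["s1"] == pytest.approx(1.8559170656941385)

    @pytest.mark.parametrize("n_genes,set_size,alpha", [(5, 2, 0.75), (20, 5, 0.75), (50, 10, 1.0), (37, 7, 0.25)])
    def test_random_toys_match_oracle(self, n_genes, set_size, alpha):
        rng = np.random.default_rng(n_genes * 7 + set_size)
        matrix = random_matrix(rng, n_genes, 3)
        gene_set = list(rng.choice(matrix.gene_ids, size=set_size, replace=False))
        scores = ssgsea_score(matrix, gene_set, SsgseaParams(alpha=alpha))
        for sample in matrix.sample_ids:
            expected = ssgsea_oracle(matrix.values[sample], set(gene_set), alpha)
            assert scores[sample] == pytest.approx(expected)

    def test_top_ranked_set_positive_bottom_ranked_negative(self):
        values = pd.DataFrame(
            {"s": np.arange(20, 0, -1, dtype=float)},
            index=[f"G{i:02d}" for i in range(20)],
        )
        matrix = ExpressionMatrix(values=values, scale=Scale.log2CPM)
        top = [f"G{i:02d}" for i in range(4)]
        bottom = [f"G{i:02d}" for i in range(16, 20)]
        assert ssgsea_score(matrix, top)["s"] > 0
        assert ssgsea_score(matrix, bottom)["s"] < 0

    def test_invariance_under_strictly_monotone_transforms(self):
        """Scores depend on within-sample ranks only: 100 fuzzed matrices."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(10, 40))
            matrix = random_matrix(rng, n, 2)
            gene_set = list(rng.choice(matrix.gene_ids, size=int(rng.integers(2, n // 2)), replace=False))
            base = ssgsea_score(matrix, gene_set)
            # random strictly increasing map: positive-slope piecewise-linear
            a, b, c = rng.uniform(0.1, 3, 3)
            transformed = ExpressionMatrix(
                values=a * np.exp(b * (matrix.values / matrix.values.abs().max().max())) + c,
                scale=Scale.log2CPM,
            )
            after = ssgsea_score(transformed, gene_set)
            np.testing.assert_allclose(base.to_numpy(), after.to_numpy(), rtol=1e-12)

    def test_random_signature_scores_center_near_zero_unweighted(self):
        """With alpha=0 the running sum is a difference of exchangeable
        empirical CDFs, so random signatures score ~0 on average. (The
        alpha-weighted statistic carries a known positive offset for random
        sets because early, high-rank in-set genes get extra mass.)"""
        rng = np.random.default_rng(7)
        matrix = random_matrix(rng, 200, 1)
        params = SsgseaParams(alpha=0.0)
        scores = [
            ssgsea_score(
                matrix, list(rng.choice(matrix.gene_ids, 20, replace=False)), params
            )[matrix.sample_ids[0]]
            for _ in range(200)
        ]
        assert abs(np.mean(scores)) < 3 * np.std(scores) / np.sqrt(len(scores)) + 0.5

    def test_empty_intersection_errors(self, tiny_matrix):
        with pytest.raises(ValueError, match="no genes"):
            ssgsea_score(tiny_matrix, ["NOPE"])

    def test_full_coverage_signature_errors(self, tiny_matrix):
        with pytest.raises(ValueError, match="complement"):
            ssgsea_score(tiny_matrix, tiny_matrix.gene_ids)


class TestCombineUpdn:
    def test_add_appends_difference(self):
        table = ScoreTable(
            values=pd.DataFrame({"s1": [2.0, 0.5]}, index=["S_UP", "S_DN"])
        )
        out = combine_updn(table, CombineMode.add)
        assert out.values.loc["S", "s1"] == pytest.approx(1.5)
        assert set(out.signatures) == {"S_UP", "S_DN", "S"}

    def test_no_pairs_identity(self):
        table = ScoreTable(values=pd.DataFrame({"s1": [1.0]}, index=["A"]))
        out = combine_updn(table, CombineMode.add)
        pd.testing.assert_frame_equal(out.values, table.values)

    def test_off_identity_and_replace_drops(self):
        table = ScoreTable(
            values=pd.DataFrame({"s1": [2.0, 0.5]}, index=["S_UP", "S_DN"])
        )
        off = combine_updn(table, "off")
        pd.testing.assert_frame_equal(off.values, table.values)
        rep = combine_updn(table, "replace")
        assert rep.signatures == ["S"]


def es_oracle(metric: np.ndarray, in_set: np.ndarray) -> float:
    """Plain-loop weighted KS enrichment score (weight exponent 1)."""
    order = sorted(range(len(metric)), key=lambda i: (-metric[i], i))
    w_total = sum(abs(metric[i]) for i in order if in_set[i])
    n_out = sum(1 for i in order if not in_set[i])
    best = 0.0
    cum_in = cum_out = 0.0
    for i in order:
        if in_set[i]:
            cum_in += abs(metric[i]) / w_total
        else:
            cum_out += 1 / n_out
        if abs(cum_in - cum_out) > abs(best):
            best = cum_in - cum_out
    return best


def snr_oracle(values: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    a, b = values[:, mask_a], values[:, ~mask_a]
    out = []
    for row_a, row_b in zip(a, b):
        ma, mb = row_a.mean(), row_b.mean()
        sa = max(row_a.std(ddof=1), 0.2 * abs(ma) if ma != 0 else 0.2)
        sb = max(row_b.std(ddof=1), 0.2 * abs(mb) if mb != 0 else 0.2)
        out.append((ma - mb) / (sa + sb))
    return np.array(out)


class TestGseaTwoClass:
    def test_exhaustive_3v3_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        matrix = random_matrix(rng, 30, 6)
        labels = pd.Series(["x", "x", "x", "y", "y", "y"], index=matrix.sample_ids)
        gene_set = matrix.gene_ids[:6]
        sigs = SignatureCollection({"SET": gene_set})
        results = gsea_two_class(matrix, labels, sigs, n_perm=1000, seed=1)
        res = results[0]

        # oracle: enumerate all 20 assignments of 3-of-6 to group "x"
        values = matrix.values.to_numpy()
        in_set = np.isin(matrix.gene_ids, gene_set)
        obs_mask = np.array([True, True, True, False, False, False])
        es_obs = es_oracle(snr_oracle(values, obs_mask), in_set)
        null = []
        for idx in combinations(range(6), 3):
            mask = np.zeros(6, dtype=bool)
            mask[list(idx)] = True
            null.append(es_oracle(snr_oracle(values, mask), in_set))
        null = np.array(null)
        same_sign = null * np.sign(es_obs) > 0
        tol = 1e-12 * max(1.0, abs(es_obs))  # ulp-level values are ties
        p_oracle = np.sum(np.abs(null[same_sign]) >= abs(es_obs) - tol) / same_sign.sum()
        assert res.es == pytest.approx(es_obs)
        assert res.p == pytest.approx(p_oracle)

    def test_planted_signature_reaches_permutation_floor(self):
        rng = np.random.default_rng(9)
        n_genes, n = 200, 20
        values = rng.normal(0, 1, (n_genes, n))
        labels = np.array(["hi"] * 10 + ["lo"] * 10)
        values[:10, :10] += 3.0  # 10 strongly up genes in group hi
        matrix = ExpressionMatrix(
            values=pd.DataFrame(
                values, index=[f"G{i:03d}" for i in range(n_genes)],
                columns=[f"s{i}" for i in range(n)],
            ),
            scale=Scale.log2CPM,
        )
        sigs = SignatureCollection({"PLANTED": matrix.gene_ids[:10]})
        n_perm = 200
        res = gsea_two_class(matrix, pd.Series(labels, index=matrix.sample_ids), sigs,
                             n_perm=n_perm, seed=3)[0]
        assert res.es > 0
        assert res.p <= 1 / n_perm

    def test_null_labels_give_moderate_nes(self):
        rng = np.random.default_rng(13)
        matrix = random_matrix(rng, 300, 16)
        labels = pd.Series(["a"] * 8 + ["b"] * 8, index=matrix.sample_ids)
        sigs = SignatureCollection(
            {f"R{i}": list(rng.choice(matrix.gene_ids, 15, replace=False)) for i in range(20)}
        )
        results = gsea_two_class(matrix, labels, sigs, n_perm=100, seed=2)
        nes = np.array([r.nes for r in results])
        assert abs(np.mean(np.abs(nes)) - 1) < 0.5  # centered near +/-1
        assert np.mean(np.abs(nes) > 2.5) <= 0.1

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(17)
        matrix = random_matrix(rng, 50, 12)
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=matrix.sample_ids)
        sigs = SignatureCollection({"S": matrix.gene_ids[:8]})
        r1 = gsea_two_class(matrix, labels, sigs, n_perm=50, seed=7)
        r2 = gsea_two_class(matrix, labels, sigs, n_perm=50, seed=7)
        assert [(r.es, r.nes, r.p, r.q) for r in r1] == [(r.es, r.nes, r.p, r.q) for r in r2]

    def test_missing_signature_skipped_with_warning(self):
        rng = np.random.default_rng(19)
        matrix = random_matrix(rng, 20, 8)
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=matrix.sample_ids)
        sigs = SignatureCollection({"GONE": ["ZZZ"], "OK": matrix.gene_ids[:5]})
        with pytest.warns(UserWarning, match="GONE"):
            results = gsea_two_class(matrix, labels, sigs, n_perm=20, seed=1)
        assert [r.signature for r in results] == ["OK"]


def _res(name, nes, q):
    return EnrichmentResult(signature=name, es=np.sign(nes), nes=nes, p=0.01, q=q)


class TestFiltersAndConcordance:
    def test_whitelist_subset_preserving_order(self):
        results = [_res("A", 2, 0.01), _res("B", -2, 0.01), _res("C", 1, 0.5)]
        kept = filter_geneset_categories(results, ["C", "A"])
        assert [r.signature for r in kept] == ["A", "C"]

    def test_empty_whitelist_warns_and_passes_through(self):
        results = [_res("A", 2, 0.01)]
        with pytest.warns(UserWarning):
            assert filter_geneset_categories(results, []) == results

    def test_concordant_same_sign_retained_opposite_dropped(self):
        a = [_res("SAME", -2, 0.01), _res("FLIP", -2, 0.01), _res("WEAK", -2, 0.5)]
        b = [_res("SAME", -1.8, 0.02), _res("FLIP", 2, 0.01), _res("WEAK", -2, 0.01)]
        assert concordant_enrichment(a, b, max_q=0.25) == ["SAME"]

    def test_eleven_name_whitelist_bounds_output(self):
        from test_cohort_io import TABLE1_SET_NAMES

        results = [_res(n, -2, 0.01) for n in TABLE1_SET_NAMES] + [_res("OTHER", 2, 0.01)]
        kept = filter_geneset_categories(results, TABLE1_SET_NAMES)
        assert len(kept) <= 11
        assert all(r.signature in TABLE1_SET_NAMES for r in kept)
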