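"""geNORM engine: Ct transform, V_jk, M, stepwise ranking, V series."""
import statistics

import numpy as np
import pandas as pd
import pytest

from refstab import (
    GenormParams,
    ct_to_relative_quantity,
    normalization_factor,
    pairwise_variation,
    run_genorm,
    stability_m,
    stepwise_ranking,
)


def brute_force_m(matrix: pd.DataFrame) -> dict[str, float]:
    """Independent oracle: M_j = mean over k != j of stdev(log2 a_j/a_k)."""
    genes = list(matrix.index)
    out = {}
    for g in genes:
        vs = []
        for k in genes:
            if k == g:
                continue
            ratios = [
                float(np.log2(matrix.loc[g, s] / matrix.loc[k, s]))
                for s in matrix.columns
            ]
            vs.append(statistics.stdev(ratios))
        out[g] = sum(vs) / len(vs)
    return out


def brute_force_ranking(matrix: pd.DataFrame):
    """Full stepwise re-enumeration, highest M out first, ties by gene id."""
    remaining = list(matrix.index)
    order = []
    while len(remaining) > 2:
        m = brute_force_m(matrix.loc[remaining])
        worst = max(remaining, key=lambda g: (m[g], g))
        order.append((worst, m[worst]))
        remaining.remove(worst)
    pair = sorted(remaining)
    ratios = [
        float(np.log2(matrix.loc[pair[0], s] / matrix.loc[pair[1], s]))
        for s in matrix.columns
    ]
    final = statistics.stdev(ratios)
    order.extend([(pair[1], final), (pair[0], final)])
    return order


def random_quantities(rng, genes, samples):
    return pd.DataFrame(
        np.power(2.0, rng.normal(0, 1, size=(genes, samples))),
        index=[f"g{i}" for i in range(genes)],
        columns=[f"s{j}" for j in range(samples)],
    )


class TestCtTransform:
    def test_powers_of_two(self):
        ct = pd.DataFrame([[20.0, 21.0, 23.0]], index=["g"], columns=list("abc"))
        q = ct_to_relative_quantity(ct, efficiency=2.0)
        assert list(q.loc["g"]) == pytest.approx([1.0, 0.5, 0.125])

    def test_constant_row_maps_to_ones(self):
        ct = pd.DataFrame([[25.0, 25.0, 25.0]], index=["g"], columns=list("abc"))
        assert (ct_to_relative_quantity(ct).loc["g"] == 1.0).all()

    def test_fractional_efficiency(self):
        ct = pd.DataFrame([[18.0, 19.5]], index=["g"], columns=list("ab"))
        q = ct_to_relative_quantity(ct, efficiency=1.9)
        assert q.loc["g", "b"] == pytest.approx(1.9 ** -1.5)
        assert q.loc["g", "b"] == pytest.approx(0.38183, abs=1e-4)

    def test_missing_ct_propagates(self):
        ct = pd.DataFrame([[20.0, np.nan, 22.0]], index=["g"], columns=list("abc"))
        q = ct_to_relative_quantity(ct)
        assert np.isnan(q.loc["g", "b"]) and q.loc["g", "a"] == 1.0

    def test_efficiency_must_exceed_one(self):
        ct = pd.DataFrame([[20.0, 21.0]], index=["g"], columns=list("ab"))
        with pytest.raises(ValueError, match="efficiency"):
            ct_to_relative_quantity(ct, efficiency=1.0)


class TestPairwiseVariation:
    def test_proportional_genes_have_zero_v(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert pairwise_variation(2 * a, a) == pytest.approx(0.0)

    def test_two_point_value(self):
        assert pairwise_variation([1.0, 2.0], [1.0, 1.0]) == pytest.approx(
            np.sqrt(0.5)
        )

    def test_symmetry_and_sample_scaling_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(0.1, 4, 6), rng.uniform(0.1, 4, 6)
        assert pairwise_variation(a, b) == pytest.approx(pairwise_variation(b, a))
        c = rng.uniform(0.5, 2, 6)  # per-sample scaling hits both genes
        assert pairwise_variation(a * c, b * c) == pytest.approx(
            pairwise_variation(a, b)
        )

    def test_requires_two_common_samples(self):
        with pytest.raises(ValueError, match="2 common"):
            pairwise_variation([1.0, np.nan], [np.nan, 1.0])


class TestStabilityM:
    def test_proportional_set_is_all_zero(self):
        base = np.array([1.0, 0.5, 2.0, 0.25])
        matrix = pd.DataFrame(
            [base, 2 * base, 0.5 * base], index=list("abc"), columns=list("wxyz")
        )
        assert stability_m(matrix).to_numpy() == pytest.approx([0.0, 0.0, 0.0])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        matrix = random_quantities(rng, 4, 5)
        oracle = brute_force_m(matrix)
        m = stability_m(matrix)
        for g in matrix.index:
            assert m[g] == pytest.approx(oracle[g], abs=1e-12)

    def test_adding_variable_gene_effect_on_m(self):
        rng = np.random.default_rng(9)
        matrix = random_quantities(rng, 4, 6)
        noisy = pd.DataFrame(
            np.power(2.0, rng.normal(0, 5, size=(1, 6))), index=["zz"],
            columns=matrix.columns,
        )
        extended = pd.concat([matrix, noisy])
        m_before = stability_m(matrix)
        m_after = stability_m(extended)
        oracle_after = brute_force_m(extended)
        for g in matrix.index:
            v_new = pairwise_variation(matrix.loc[g], noisy.loc["zz"])
            if v_new >= m_before[g]:
                assert m_after[g] >= m_before[g] - 1e-12
            assert m_after[g] == pytest.approx(oracle_after[g], abs=1e-12)


class TestStepwiseRanking:
    def test_planted_noisy_gene_excluded_first(self):
        rng = np.random.default_rng(21)
        base = rng.uniform(0.5, 2, size=8)
        rows = {f"g{i}": base * 2 ** rng.normal(0, 0.05, 8) for i in range(5)}
        rows["noisy"] = base * 2 ** rng.normal(0, 2.0, 8)
        matrix = pd.DataFrame(rows).T
        result = stepwise_ranking(matrix)
        assert result.exclusion_order[0][0] == "noisy"
        oracle = brute_force_ranking(matrix)
        assert [g for g, _ in result.exclusion_order] == [g for g, _ in oracle]

    def test_exactly_proportional_genes_use_tie_rule(self):
        base = np.array([1.0, 2.0, 4.0])
        matrix = pd.DataFrame(
            [base, base * 3, base * 0.5], index=["b", "a", "c"], columns=list("xyz")
        )
        result = stepwise_ranking(matrix)
        # all M = 0; lexicographically greatest id treated least stable
        assert [g for g, _ in result.exclusion_order] == ["c", "b", "a"]
        assert [m for _, m in result.exclusion_order] == pytest.approx([0, 0, 0])

    def test_final_pair_shares_its_pairwise_v(self):
        rng = np.random.default_rng(4)
        matrix = random_quantities(rng, 5, 7)
        result = stepwise_ranking(matrix)
        (g_b, m_b), (g_a, m_a) = result.exclusion_order[-2:]
        assert m_a == m_b == pytest.approx(
            pairwise_variation(matrix.loc[g_a], matrix.loc[g_b])
        )

    def test_invariant_under_per_sample_scaling(self):
        rng = np.random.default_rng(8)
        matrix = random_quantities(rng, 5, 6)
        scale = rng.uniform(0.1, 10, size=6)
        scaled = matrix * scale
        a, b = stepwise_ranking(matrix), stepwise_ranking(scaled)
        assert [g for g, _ in a.exclusion_order] == [g for g, _ in b.exclusion_order]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_full_reenumeration(self, seed):
        rng = np.random.default_rng(200 + seed)
        g = int(rng.integers(3, 7))
        s = int(rng.integers(3, 9))
        matrix = random_quantities(rng, g, s)
        result = stepwise_ranking(matrix)
        oracle = brute_force_ranking(matrix)
        assert [x[0] for x in result.exclusion_order] == [x[0] for x in oracle]
        for (ga, ma), (gb, mb) in zip(result.exclusion_order, oracle):
            assert ma == pytest.approx(mb, abs=1e-12)


class TestNormalizationFactorAndVSeries:
    def test_geometric_mean(self):
        matrix = pd.DataFrame([[4.0], [1.0]], index=["a", "b"], columns=["s"])
        assert normalization_factor(matrix, ["a", "b"])["s"] == pytest.approx(2.0)

    def test_all_ones_gives_unit_factors(self):
        matrix = pd.DataFrame(1.0, index=list("abc"), columns=list("xy"))
        assert (normalization_factor(matrix, list("abc")) == 1.0).all()

    def test_matches_exp_mean_log_oracle_and_scaling_law(self):
        rng = np.random.default_rng(6)
        matrix = random_quantities(rng, 3, 5)
        nf = normalization_factor(matrix, list(matrix.index))
        oracle = np.exp(np.mean(np.log(matrix.to_numpy()), axis=0))
        assert nf.to_numpy() == pytest.approx(oracle)
        scaled = matrix.copy()
        scaled.loc["g0"] *= 8.0
        nf2 = normalization_factor(scaled, list(matrix.index))
        assert nf2.to_numpy() == pytest.approx(oracle * 8 ** (1 / 3))

    def test_proportional_matrix_v_series_zero_recommends_two(self):
        base = np.array([1.0, 0.5, 2.0, 0.25, 0.125])
        matrix = pd.DataFrame(
            [base * c for c in (1, 2, 4, 0.5)], index=list("abcd"),
            columns=[f"s{i}" for i in range(5)],
        )
        result = run_genorm(matrix)
        assert result.v_series.to_numpy() == pytest.approx([0.0, 0.0])
        assert result.recommended_n == 2 and result.threshold_met

    def test_v_series_matches_direct_recomputation(self):
        rng = np.random.default_rng(13)
        matrix = random_quantities(rng, 6, 8)
        result = run_genorm(matrix)
        for n in result.v_series.index:
            nf_n = np.exp(
                np.mean(np.log(matrix.loc[result.ranking[:n]].to_numpy()), axis=0)
            )
            nf_n1 = np.exp(
                np.mean(np.log(matrix.loc[result.ranking[: n + 1]].to_numpy()), axis=0)
            )
            v = statistics.stdev(np.log2(nf_n / nf_n1))
            assert result.v_series[n] == pytest.approx(v, abs=1e-12)

    def test_zero_threshold_never_met_on_noisy_data(self):
        rng = np.random.default_rng(14)
        matrix = random_quantities(rng, 5, 6)
        with pytest.raises(ValueError):
            GenormParams(v_threshold=0)  # 0 is not a valid threshold
        tiny = run_genorm(matrix, GenormParams(v_threshold=1e-12))
        assert not tiny.threshold_met
        assert tiny.recommended_n == len(matrix) - 1

    def test_planted_unstable_gene_eliminated_first_in_95pct_of_replicates(self):
        wins = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            base = rng.uniform(0.5, 2, size=6)
            rows = {f"g{i}": base * 2 ** rng.normal(0, 0.2, 6) for i in range(5)}
            rows["unstable"] = base * 2 ** rng.normal(0, 1.0, 6)  # 5x noise SD
            matrix = pd.DataFrame(rows).T
            if stepwise_ranking(matrix).exclusion_order[0][0] == "unstable":
                wins += 1
        assert wins / n_rep >= 0.95
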