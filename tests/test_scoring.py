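"""Kinase statistics: MKS against a brute-force oracle, permutation scores,
MFS composition, and the activation call."""

import numpy as np
import pandas as pd
import pytest

from kinoflow import (
    call_activated,
    mean_final_score,
    mean_kinase_statistic,
    peptide_group_stats,
    score_kinases,
    significance_score,
    specificity_score,
)


def mks_oracle(values, groups, peptides):
    """Term-by-term evaluation with plain Python arithmetic."""
    g1 = [s for s, g in groups.items() if g == 1]
    g2 = [s for s, g in groups.items() if g == 2]
    terms = []
    for p in peptides:
        x1, x2 = values.loc[p, g1].to_numpy(), values.loc[p, g2].to_numpy()
        denom = x1.var(ddof=1) + x2.var(ddof=1)
        if denom > 0:
            terms.append((x1.mean() - x2.mean()) / denom**0.5)
    return sum(terms) / len(terms) if terms else float("nan")


class TestGroupStats:
    def test_two_point_group(self, random_values):
        values, groups = random_values
        values.iloc[0, :] = [1, 3, 1, 3, 0, 0, 0, 0]
        stats = peptide_group_stats(values, groups)
        assert stats.loc[values.index[0], "mean_g1"] == 2
        assert stats.loc[values.index[0], "var_g1"] == pytest.approx(4 / 3)
        two = peptide_group_stats(
            pd.DataFrame([[1.0, 3.0, 5.0, 5.0]], index=["P1"], columns=["a", "b", "c", "d"]),
            {"a": 1, "b": 1, "c": 2, "d": 2},
        )
        assert two.loc["P1", "var_g1"] == pytest.approx(2.0)
        assert two.loc["P1", "var_g2"] == 0.0

    def test_matches_hand_rolled_oracle(self, random_values):
        values, groups = random_values
        stats = peptide_group_stats(values, groups)
        g1 = [s for s, g in groups.items() if g == 1]
        for p in values.index:
            x = values.loc[p, g1].to_numpy()
            m = sum(x) / len(x)
            v = sum((xi - m) ** 2 for xi in x) / (len(x) - 1)
            assert stats.loc[p, "mean_g1"] == pytest.approx(m, abs=1e-12)
            assert stats.loc[p, "var_g1"] == pytest.approx(v, abs=1e-12)

    def test_empty_group_rejected(self, random_values):
        values, _ = random_values
        with pytest.raises(ValueError, match="group"):
            peptide_group_stats(values, {s: 1 for s in values.columns})


class TestMeanKinaseStatistic:
    def test_single_term(self):
        stats = pd.DataFrame(
            {"mean_g1": [2.0], "mean_g2": [1.0], "var_g1": [0.5], "var_g2": [0.5]},
            index=["P1"],
        )
        mks, n = mean_kinase_statistic(stats, ["P1"])
        assert mks == pytest.approx(1.0, abs=1e-12)
        assert n == 1

    def test_identical_groups_give_zero(self, random_values):
        values, groups = random_values
        mirrored = values.copy()
        g1 = [s for s, g in groups.items() if g == 1]
        g2 = [s for s, g in groups.items() if g == 2]
        mirrored[g2] = mirrored[g1].to_numpy()
        stats = peptide_group_stats(mirrored, groups)
        mks, _ = mean_kinase_statistic(stats, list(values.index))
        assert mks == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, random_values):
        values, groups = random_values
        stats = peptide_group_stats(values, groups)
        peptides = list(values.index[:9])
        mks, n = mean_kinase_statistic(stats, peptides)
        assert n == 9
        assert mks == pytest.approx(mks_oracle(values, groups, peptides), abs=1e-12)

    def test_zero_variance_peptides_dropped(self, random_values):
        values, groups = random_values
        values.iloc[0, :] = 1.0
        stats = peptide_group_stats(values, groups)
        mks, n = mean_kinase_statistic(stats, list(values.index[:3]))
        assert n == 2
        allzero, n0 = mean_kinase_statistic(stats.iloc[[0]], [values.index[0]])
        assert np.isnan(allzero) and n0 == 0


class TestSignificance:
    def test_constant_matrix_gives_p_one(self, random_values):
        values, groups = random_values
        const = pd.DataFrame(1.0, index=values.index, columns=values.columns)
        p, s = significance_score(const, groups, list(const.index[:4]))
        assert p == 1.0 and s == 0.0

    def test_exact_mode_matches_brute_force(self, rng):
        """3v3: the exhaustive permutation p equals independent enumeration
        over all 20 label assignments."""
        from itertools import combinations

        samples = [f"S{i}" for i in range(6)]
        groups = {s: (1 if i < 3 else 2) for i, s in enumerate(samples)}
        values = pd.DataFrame(rng.normal(0, 1, (7, 6)), index=[f"P{i}" for i in range(7)], columns=samples)
        peptides = ["P0", "P1", "P2"]
        p, _ = significance_score(values, groups, peptides, n_perm=1000)

        def tau(g1_idx):
            terms = []
            for pep in peptides:
                x = values.loc[pep].to_numpy()
                x1 = x[list(g1_idx)]
                x2 = x[[i for i in range(6) if i not in g1_idx]]
                d = x1.var(ddof=1) + x2.var(ddof=1)
                terms.append((x1.mean() - x2.mean()) / d**0.5)
            return sum(terms) / len(terms)

        t_obs = tau((0, 1, 2))
        taus = [tau(c) for c in combinations(range(6), 3)]
        p_oracle = sum(abs(t) >= abs(t_obs) - 1e-9 for t in taus) / 20
        assert p == p_oracle

    def test_degenerate_grouping_rejected(self, random_values):
        values, _ = random_values
        with pytest.raises(ValueError, match="group"):
            significance_score(values, {s: 1 for s in values.columns}, list(values.index[:2]))

    def test_deterministic_given_seed(self, rng):
        samples = [f"S{i}" for i in range(12)]  # 6v6: C(12,6)=924 <= 1000 exact; force MC with n_perm=500
        groups = {s: (1 if i < 6 else 2) for i, s in enumerate(samples)}
        values = pd.DataFrame(rng.normal(0, 1, (5, 12)), index=[f"P{i}" for i in range(5)], columns=samples)
        a = significance_score(values, groups, ["P0", "P1"], n_perm=500, seed=3, kinase_id="KX")
        b = significance_score(values, groups, ["P0", "P1"], n_perm=500, seed=3, kinase_id="KX")
        assert a == b


class TestSpecificity:
    def test_whole_pool_kinase_has_p_one(self, random_values):
        values, groups = random_values
        pool = list(values.index)
        p, s = specificity_score(values, groups, pool, pool, n_perm=200)
        assert p == 1.0 and s == 0.0

    def test_oversized_kinase_rejected(self, random_values):
        values, groups = random_values
        with pytest.raises(ValueError, match="pool"):
            specificity_score(values, groups, list(values.index), list(values.index[:3]))

    def test_kinase_specific_shift_is_detected(self, random_values):
        values, groups = random_values
        g1 = [s for s, g in groups.items() if g == 1]
        target = list(values.index[:4])
        values.loc[target, g1] += 5.0
        p, _ = specificity_score(values, groups, target, list(values.index), n_perm=500, seed=1)
        assert p < 0.05


class TestMfsAndCall:
    @pytest.mark.parametrize(
        "sig, spec, singlicate, expected",
        [(0.9, 0.4, False, 1.3), (0.9, 0.4, True, 0.4), (0.0, 0.0, False, 0.0)],
    )
    def test_mfs_composition(self, sig, spec, singlicate, expected):
        assert mean_final_score(sig, spec, singlicate) == pytest.approx(expected)

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            mean_final_score(-0.1, 0.2, False)

    def test_activation_boundaries(self):
        scores = pd.DataFrame(
            {
                "mks": [0.5, -0.2, 1.0, 0.8],
                "mfs": [0.6, 0.9, 0.5, 2.0],
            },
            index=pd.Index(["A", "B", "C", "D"], name="kinase_id"),
        )
        hits = call_activated(scores)
        assert list(hits.index) == ["D", "A"]  # strict >0 and >0.5; sorted by mfs desc


class TestScoreKinases:
    def test_antisymmetry_under_label_swap(self, random_values):
        values, groups = random_values
        kmap = {"KA": list(values.index[:5]), "KB": list(values.index[5:9])}
        fwd = score_kinases(values, groups, kmap, n_perm=50, seed=2)
        swapped = {s: (2 if g == 1 else 1) for s, g in groups.items()}
        rev = score_kinases(values, swapped, kmap, n_perm=50, seed=2)
        assert np.array_equal(fwd["mks"].to_numpy(), -rev["mks"].to_numpy())

    def test_location_invariance(self, random_values):
        values, groups = random_values
        kmap = {"KA": list(values.index[:5])}
        a = score_kinases(values, groups, kmap, n_perm=100, seed=2)
        b = score_kinases(values + 7.5, groups, kmap, n_perm=100, seed=2)
        assert a["significance_p"].iloc[0] == b["significance_p"].iloc[0]
        assert a["specificity_p"].iloc[0] == b["specificity_p"].iloc[0]
        assert a["mks"].iloc[0] == pytest.approx(b["mks"].iloc[0], abs=1e-9)

    def test_per_kinase_results_independent_of_map_composition(self, random_values):
        """Scoring a kinase alone or with others gives identical numbers
        (per-kinase RNG streams)."""
        values, groups = random_values
        full = score_kinases(
            values, groups, {"KA": list(values.index[:5]), "KB": list(values.index[5:8])},
            n_perm=100, seed=5,
        )
        alone = score_kinases(values, groups, {"KB": list(values.index[5:8])}, n_perm=100, seed=5)
        pd.testing.assert_series_equal(
            full.loc["KB"].drop("significance_q"), alone.loc["KB"].drop("significance_q")
        )

    def test_singlicate_mfs_is_specificity_only(self, rng):
        # one sample in group 1: sample-label permutation is impossible
        samples = ["a", "b", "c", "d"]
        groups = {"a": 1, "b": 2, "c": 2, "d": 2}
        values = pd.DataFrame(
            rng.normal(0, 1, (6, 4)), index=[f"P{i}" for i in range(6)], columns=samples
        )
        scores = score_kinases(values, groups, {"KA": ["P0", "P1"]}, n_perm=50, seed=1)
        row = scores.loc["KA"]
        assert np.isnan(row["significance_p"])
        assert row["mfs"] == row["specificity_score"]
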