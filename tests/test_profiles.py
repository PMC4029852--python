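"""Model-profile assignment, permutation-expected counts and binomial
profile significance."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from co2prof import (
    ModelProfile,
    assign_profiles,
    default_profiles,
    expected_counts,
    log2_ratio_vectors,
    profile_significance,
    significant_profiles,
)
from co2prof.profiles import ProfileStats, profile_log10_significance, profile_stats

from conftest import matrix_from_groups, random_matrix

# profile counts of a published 5,127-gene poplar CO2 series, used as a
# frozen reference input (assigned, expected, printed p)
REFERENCE_TABLE = {
    1: (73, 127.00, 1.0), 2: (100, 172.33, 1.0), 3: (212, 304.83, 1.0),
    4: (72, 127.00, 1.0), 5: (440, 362.67, 2.24e-05), 6: (498, 368.33, 1.13e-11),
    7: (94, 207.00, 1.0), 8: (290, 362.67, 1.0), 9: (119, 172.33, 1.0),
    10: (499, 362.67, 8.22e-13), 11: (136, 207.00, 1.0), 12: (864, 483.67, 2.17e-62),
    13: (171, 403.50, 1.0), 14: (322, 403.50, 1.0), 15: (311, 304.83, 0.37),
    16: (531, 362.67, 3.00e-18),
}
REFERENCE_TOTAL = 5127


def vectors_df(rows: dict[str, tuple[float, ...]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index")


class TestRatioVectors:
    def test_powers_of_two(self):
        m = matrix_from_groups(
            {"g": [[math.log2(100)] * 2, [math.log2(200)] * 2, [math.log2(50)] * 2]}
        )
        v = log2_ratio_vectors(m, ["g"])
        np.testing.assert_allclose(v.loc["g"].to_numpy(), [0.0, 1.0, -1.0], atol=1e-12)

    def test_equal_means_flat(self):
        m = matrix_from_groups({"g": [[3.0, 5.0], [4.0, 4.0], [2.0, 6.0]]})
        np.testing.assert_allclose(
            log2_ratio_vectors(m, ["g"]).loc["g"].to_numpy(), [0.0, 0.0, 0.0], atol=1e-12
        )

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(11)
        m = random_matrix(rng, n_genes=100)
        v = log2_ratio_vectors(m)
        log = np.log2(m.signals)
        for g in rng.choice(m.probe_ids, 20, replace=False):
            means = [log.loc[g, m.samples_of(c)].mean() for c in m.condition_order]
            expect = np.array(means) - means[0]
            np.testing.assert_allclose(v.loc[g].to_numpy(), expect, rtol=1e-12)

    def test_unknown_gene_raises(self, tiny_matrix):
        with pytest.raises(KeyError):
            log2_ratio_vectors(tiny_matrix, ["nope"])


class TestDefaultProfiles:
    def test_sixteen_valid_unique_shapes(self):
        profs = default_profiles()
        assert len(profs) == 16
        shapes = [p.shape for p in profs]
        assert len(set(shapes)) == 16  # profiles 14 and 15 differ
        for p in profs:
            assert p.shape[0] == 0
            assert any(s != 0 for s in p.shape)
            assert max(abs(b - a) for a, b in zip(p.shape, p.shape[1:])) <= 2

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            ModelProfile(id=1, shape=(1, 2, 3))  # not anchored
        with pytest.raises(ValueError):
            ModelProfile(id=1, shape=(0, 0, 0))  # constant
        with pytest.raises(ValueError):
            ModelProfile(id=1, shape=(0, 3, 0))  # step of 3


class TestAssignment:
    def test_exact_shape_match(self):
        assignment, un = assign_profiles(vectors_df({"g": (0, 1, 0)}), default_profiles())
        assert assignment["g"] == 12
        assert un == []

    def test_brute_force_best_correlation(self):
        v = np.array([0.0, 0.8, 1.7])
        best = max(
            default_profiles(),
            key=lambda p: np.corrcoef(v, np.array(p.shape, dtype=float))[0, 1],
        )
        assert best.shape == (0, 1, 2)
        assignment, _ = assign_profiles(vectors_df({"g": tuple(v)}), default_profiles())
        assert assignment["g"] == best.id == 1

    def test_flat_vector_unassigned(self):
        assignment, un = assign_profiles(vectors_df({"g": (0, 0, 0)}), default_profiles())
        assert len(assignment) == 0
        assert un == ["g"]

    def test_empty_profile_set_rejected(self):
        with pytest.raises(ValueError):
            assign_profiles(vectors_df({"g": (0, 1, 0)}), [])

    @settings(max_examples=50, deadline=None)
    @given(
        v1=st.floats(-3, 3, allow_nan=False), v2=st.floats(-3, 3, allow_nan=False),
        scale=st.floats(0.01, 100, allow_nan=False),
    )
    def test_scale_invariance(self, v1, v2, scale):
        """Pearson correlation ignores positive scaling of the ratio vector
        (checked away from exact ties, where float rounding may pick either
        of two equally correlated profiles)."""
        from hypothesis import assume

        assume(abs(v1) > 1e-6 or abs(v2) > 1e-6)
        v = np.array([0.0, v1, v2])
        corrs = sorted(
            np.corrcoef(v, np.array(p.shape, dtype=float))[0, 1]
            for p in default_profiles()
        )
        assume(corrs[-1] - corrs[-2] > 1e-6)
        a1, _ = assign_profiles(vectors_df({"g": (0, v1, v2)}), default_profiles())
        a2, _ = assign_profiles(
            vectors_df({"g": (0, v1 * scale, v2 * scale)}), default_profiles()
        )
        assert a1.get("g") == a2.get("g")


class TestExpectedCounts:
    def test_single_gene_enumeration(self):
        """(0,1,0) permuted 6 ways re-anchors to (0,1,0), (0,0,1) and
        (0,-1,-1) twice each: expectation 1/3 on profiles 12, 15, 13."""
        exp = expected_counts(vectors_df({"g": (0, 1, 0)}), default_profiles())
        assert exp[12] == pytest.approx(1 / 3)
        assert exp[15] == pytest.approx(1 / 3)
        assert exp[13] == pytest.approx(1 / 3)
        assert exp.drop([12, 15, 13]).abs().sum() == 0.0

    def test_flat_gene_contributes_nothing(self):
        exp = expected_counts(vectors_df({"g": (0, 0, 0)}), default_profiles())
        assert exp.sum() == 0.0

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 40))
    def test_conservation_and_sixth_granularity(self, seed, n):
        """Sum of expectations equals the number of assigned genes exactly,
        and every expectation is a multiple of 1/6 for three conditions."""
        rng = np.random.default_rng(seed)
        v = pd.DataFrame(rng.normal(0, 1.5, size=(n, 3)), index=[f"g{i}" for i in range(n)])
        v.iloc[:, 0] = 0.0
        profs = default_profiles()
        assignment, _ = assign_profiles(v, profs)
        exp = expected_counts(v, profs)
        assert exp.sum() * 6 == pytest.approx(len(assignment) * 6, abs=1e-9)
        np.testing.assert_allclose(exp * 6, np.round(exp * 6), atol=1e-9)

    def test_reference_table_columns_balance(self):
        """In the frozen reference table both the assigned and the expected
        columns sum to 4,732."""
        assert sum(a for a, _, _ in REFERENCE_TABLE.values()) == 4732
        assert sum(e for _, e, _ in REFERENCE_TABLE.values()) == pytest.approx(4732.00, abs=0.02)

    def test_reference_expectations_are_sixths(self):
        for _, e, _ in REFERENCE_TABLE.values():
            assert abs(e * 6 - round(e * 6)) < 0.03  # printed to 2 decimals


class TestSignificance:
    def test_zero_assigned_is_one(self):
        assert profile_significance(0, 10.0, 100) == 1.0

    def test_exhaustive_binomial_enumeration(self):
        """P(X >= 8), X ~ Binomial(10, 1/2) equals 56/1024 by direct count."""
        p = profile_significance(8, 5.0, 10)
        assert p == pytest.approx(56 / 1024, rel=1e-12)
        # independent enumeration
        brute = sum(math.comb(10, k) for k in range(8, 11)) / 2**10
        assert p == pytest.approx(brute, rel=1e-12)

    def test_zero_expected_convention(self):
        with pytest.warns(RuntimeWarning):
            assert profile_significance(3, 0.0, 10) == 0.0

    def test_log_space_survives_extreme_tails(self):
        lp = profile_log10_significance(5000, 5.0, 5127)
        assert np.isfinite(lp)
        assert lp < -300

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            profile_significance(11, 5.0, 10)

    def test_reference_nonsignificant_profile(self):
        assigned, expected, printed = REFERENCE_TABLE[15]
        p = profile_significance(assigned, expected, REFERENCE_TOTAL)
        assert round(p, 2) == printed


class TestSignificantProfiles:
    def _reference_stats(self) -> ProfileStats:
        rows = [
            {"profile": pid, "shape": "", "assigned": a, "expected": e, "p": p}
            for pid, (a, e, p) in sorted(REFERENCE_TABLE.items())
        ]
        return ProfileStats(table=pd.DataFrame(rows))

    def test_reference_selection_order(self):
        assert significant_profiles(self._reference_stats()) == [12, 16, 10, 6, 5]

    def test_alpha_zero_empty(self):
        assert significant_profiles(self._reference_stats(), alpha=0.0) == []

    def test_order_matches_independent_sort(self):
        stats_ = self._reference_stats()
        sig = significant_profiles(stats_, alpha=0.05)
        ps = {pid: REFERENCE_TABLE[pid][2] for pid in sig}
        assert sig == sorted(sig, key=lambda pid: ps[pid])


class TestPlantedRecovery:
    def test_high_snr_genes_recover_true_profile(self):
        """With a planted effect of four noise SDs and 3 replicates, at
        least 90% of DE genes land on their true profile."""
        from co2prof import SyntheticConfig, generate_expression

        cfg = SyntheticConfig(n_genes=2000, seed=5, effect_scale=4.0)
        matrix, truth = generate_expression(cfg)
        de = truth.de_genes
        vectors = log2_ratio_vectors(matrix, de)
        assignment, _ = assign_profiles(vectors, default_profiles())
        truth_profiles = truth.genes.loc[de, "profile"]
        hits = sum(
            1 for g in de if g in assignment.index and assignment[g] == truth_profiles[g]
        )
        assert hits / len(de) >= 0.90
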