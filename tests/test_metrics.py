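"""Metric-layer tests: each fast-path matrix is checked against a naive
per-pair loop oracle, and the algebraic identities linking the three
measures are asserted on random data."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lrprop import (
    CountMatrix,
    clr,
    extract_pairs,
    filter_features,
    phi,
    phi_s,
    proportionality,
    replace_zeros,
    rho,
    vlr_matrix,
)
from lrprop.evaluate import comparability_transform
from lrprop.metrics import feature_variances
from lrprop.transforms import LogRatioMatrix


def naive_metric(A, which):
    """Direct per-pair evaluation of the metric definitions."""
    x = A.values
    m = x.shape[1]
    out = np.zeros((m, m))
    for i, j in itertools.product(range(m), repeat=2):
        vlr = np.var(x[:, i] - x[:, j], ddof=1)
        if which == "vlr":
            out[i, j] = vlr
        elif which == "phi":
            out[i, j] = vlr / np.var(x[:, i], ddof=1)
        elif which == "rho":
            out[i, j] = 1 - vlr / (np.var(x[:, i], ddof=1) + np.var(x[:, j], ddof=1))
        elif which == "phi_s":
            denom = np.var(x[:, i] + x[:, j], ddof=1)
            out[i, j] = vlr / denom if denom > 0 else np.nan
    return out


@pytest.fixture
def oracle_logratios(rng):
    """Matrices up to 20 x 15 for the fast-path vs naive-loop comparison."""
    return [
        clr(CountMatrix(rng.integers(1, 1000, size=shape).astype(float)))
        for shape in [(6, 5), (8, 6), (20, 15)]
    ]


class TestVlr:
    def test_fast_path_matches_naive_loop(self, oracle_logratios):
        for A in oracle_logratios:
            assert np.abs(vlr_matrix(A) - naive_metric(A, "vlr")).max() < 1e-10

    def test_proportional_pair_has_zero_vlr(self, proportional_counts):
        A = clr(proportional_counts)
        assert vlr_matrix(A)[1, 3] == 0.0

    def test_closure_invariance(self, random_counts):
        rel = random_counts.values / random_counts.values.sum(axis=1, keepdims=True)
        A_abs = clr(random_counts)
        A_rel = clr(CountMatrix.unchecked(rel, None, random_counts.feature_ids))
        assert np.abs(vlr_matrix(A_abs) - vlr_matrix(A_rel)).max() < 1e-10

    def test_blocked_equals_one_shot_exactly(self, random_logratios):
        full = vlr_matrix(random_logratios)
        for bs in (1, 7, 13):
            assert np.array_equal(vlr_matrix(random_logratios, block_size=bs), full)

    def test_single_sample_rejected(self):
        A = LogRatioMatrix(np.zeros((1, 3)), ("a", "b", "c"), ("s1",), "clr")
        with pytest.raises(ValueError, match="2 samples"):
            vlr_matrix(A)


class TestPhi:
    def test_matches_naive_loop(self, oracle_logratios):
        for A in oracle_logratios:
            assert np.abs(phi(A).matrix.to_numpy() - naive_metric(A, "phi")).max() < 1e-10

    def test_diagonal_zero_and_nonnegative(self, random_logratios):
        m = phi(random_logratios).matrix.to_numpy()
        assert np.all(np.diag(m) == 0.0)
        assert np.all(m >= 0.0)

    def test_asymmetry_identity(self, random_logratios):
        # phi(i,j) var_i and phi(j,i) var_j are both vlr(i,j)
        m = phi(random_logratios).matrix.to_numpy()
        v = feature_variances(random_logratios)
        assert np.abs(m * v[:, None] - (m * v[:, None]).T).max() < 1e-10

    def test_constant_feature_named_in_error(self):
        A = LogRatioMatrix(
            np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 3.0]]), ("const", "ok"), None, "clr"
        )
        with pytest.raises(ValueError, match="const"):
            phi(A)


class TestRho:
    def test_matches_naive_loop(self, oracle_logratios):
        for A in oracle_logratios:
            assert np.abs(rho(A).matrix.to_numpy() - naive_metric(A, "rho")).max() < 1e-10

    def test_proportional_pair_is_exactly_one(self, proportional_counts):
        m = rho(clr(proportional_counts)).matrix.to_numpy()
        assert m[1, 3] == 1.0

    def test_anti_proportional_logratios_give_minus_one(self):
        x = np.array([[1.0], [2.0], [-0.5], [3.0]])
        A = LogRatioMatrix(np.hstack([x, -x]), ("a", "b"), None, "clr")
        m = rho(A).matrix.to_numpy()
        assert m[0, 1] == -1.0

    def test_bounds_symmetry_diagonal(self, random_logratios):
        m = rho(random_logratios).matrix.to_numpy()
        assert np.all(m >= -1.0) and np.all(m <= 1.0)
        assert np.abs(m - m.T).max() < 1e-12
        assert np.all(np.diag(m) == 1.0)


class TestPhiS:
    def test_matches_naive_loop(self, oracle_logratios):
        for A in oracle_logratios:
            got = phi_s(A).matrix.to_numpy()
            want = naive_metric(A, "phi_s")
            assert np.allclose(got, want, atol=1e-10, equal_nan=True)

    def test_monotone_link_to_rho(self, random_logratios):
        ps = phi_s(random_logratios).matrix.to_numpy()
        r = rho(random_logratios).matrix.to_numpy()
        # 1 - 2*logistic(ln phi_s), evaluated directly from its definition
        with np.errstate(divide="ignore"):
            linked = 1.0 - 2.0 / (1.0 + np.exp(-np.log(ps)))
        assert np.abs(linked - r).max() < 1e-10

    def test_anti_proportional_pair_flagged_undefined(self):
        x = np.array([[1.0], [2.0], [-0.5], [3.0]])
        A = LogRatioMatrix(np.hstack([x, -x]), ("a", "b"), None, "clr")
        m = phi_s(A).matrix.to_numpy()
        assert np.isnan(m[0, 1])
        assert m[0, 0] == 0.0


class TestFilterFeatures:
    def test_boundary_is_inclusive(self):
        values = np.full((10, 2), 10.0)
        values[:, 1] = 9.0
        cm = CountMatrix(values, None, ("kept", "dropped"))
        assert filter_features(cm, 10, 10) == ["kept"]

    def test_matches_brute_force(self, rng):
        cm = CountMatrix(rng.integers(0, 20, size=(12, 5)).astype(float))
        expected = []
        for j, fid in enumerate(cm.feature_ids):
            n_ok = sum(1 for i in range(12) if cm.values[i, j] >= 7)
            if n_ok >= 4:
                expected.append(fid)
        assert filter_features(cm, 7, 4) == expected

    def test_min_samples_above_n_warns(self, toy_counts):
        with pytest.warns(UserWarning, match="exceeds"):
            out = filter_features(toy_counts, 1, 99)
        assert out == []


class TestProportionalityPipeline:
    def test_equals_composing_public_ops(self, toy_counts):
        got = proportionality(toy_counts, metric="rho")
        want = rho(clr(replace_zeros(toy_counts)))
        assert np.array_equal(got.matrix.to_numpy(), want.matrix.to_numpy())

    def test_filter_only_subsets_the_matrix(self, rng):
        values = rng.integers(0, 2000, size=(15, 8)).astype(float)
        values[:, [2, 5]] = rng.integers(0, 9, size=(15, 2))  # low-count features
        cm = CountMatrix(values)
        full = proportionality(cm, metric="rho")
        filtered = proportionality(cm, metric="rho", filter=(10, 10))
        survivors = list(filtered.matrix.columns)
        assert set(survivors) < set(cm.feature_ids)
        sub = full.matrix.loc[survivors, survivors]
        assert np.array_equal(sub.to_numpy(), filtered.matrix.to_numpy())

    def test_alr_with_fixed_reference_recovers_absolute_rho(self, rng):
        # a truly unchanged reference lets alr back-calculate absolute
        # abundances from closed data, so rho matches the absolute analysis
        values = rng.integers(10, 2000, size=(12, 6)).astype(float)
        values[:, 5] = 500.0  # experimentally fixed reference feature
        absolute = CountMatrix(values)
        ref = absolute.feature_ids[5]
        rel = absolute.values / absolute.values.sum(axis=1, keepdims=True)
        relative = CountMatrix.unchecked(rel, None, absolute.feature_ids)
        from lrprop import alr

        r_abs = rho(alr(absolute, ref)).matrix.to_numpy()
        r_rel = rho(alr(relative, ref)).matrix.to_numpy()
        assert np.abs(r_abs - r_rel).max() < 1e-10

    def test_alr_reference_failing_filter_is_an_error(self, rng):
        values = rng.integers(100, 2000, size=(12, 5)).astype(float)
        values[:, 0] = 1.0  # reference below the count filter
        cm = CountMatrix(values)
        with pytest.raises(ValueError, match="filter"):
            proportionality(
                cm, metric="rho", transform="alr",
                reference=cm.feature_ids[0], filter=(10, 10),
            )

    def test_permutation_equivariance(self, random_counts, rng):
        perm = rng.permutation(random_counts.n_features)
        permuted = CountMatrix(
            random_counts.values[:, perm],
            random_counts.sample_ids,
            tuple(random_counts.feature_ids[i] for i in perm),
        )
        r1 = proportionality(random_counts, metric="rho").matrix
        r2 = proportionality(permuted, metric="rho").matrix
        realigned = r2.loc[list(r1.index), list(r1.columns)]
        assert np.abs(realigned.to_numpy() - r1.to_numpy()).max() < 1e-12


class TestExtractPairs:
    def test_recovers_planted_pairs_exactly(self, rng):
        # three planted proportional pairs on an independent background
        n, d = 25, 12
        values = rng.integers(50, 2000, size=(n, d)).astype(float)
        planted = [(0, 1), (4, 5), (8, 9)]
        for a, b in planted:
            values[:, b] = np.round(values[:, a] * rng.uniform(1.5, 4.0))
        cm = CountMatrix(values)
        result = proportionality(cm, metric="rho")
        pairs = extract_pairs(result, cutoff=0.95, direction="greater")
        got = {tuple(sorted((r.feature_i, r.feature_j))) for r in pairs.itertuples()}
        want = {
            tuple(sorted((cm.feature_ids[a], cm.feature_ids[b]))) for a, b in planted
        }
        assert got == want
        # brute-force scan of the matrix agrees
        m = result.matrix.to_numpy()
        n_brute = sum(
            1 for i in range(d) for j in range(i + 1, d) if m[i, j] > 0.95
        )
        assert n_brute == len(pairs)

    def test_cutoff_above_max_gives_empty_table(self, random_counts):
        result = proportionality(random_counts, metric="rho")
        assert extract_pairs(result, cutoff=1.1, direction="greater").empty

    def test_vlr_vls_identity_for_rho_rows(self, random_counts):
        result = proportionality(random_counts, metric="rho")
        pairs = extract_pairs(result, cutoff=-1.0, direction="greater")  # all pairs
        lhs = pairs["vlr"] / pairs["vls"]
        rhs = 1.0 - pairs["metric_value"]
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_phi_pairs_symmetrized_by_min(self, random_logratios):
        result = phi(random_logratios)
        m = result.matrix.to_numpy()
        cutoff = np.percentile(np.fmin(m, m.T)[np.triu_indices(m.shape[0], 1)], 20)
        pairs = extract_pairs(result, cutoff=cutoff, direction="less")
        ids = list(result.matrix.columns)
        for row in pairs.itertuples():
            i, j = ids.index(row.feature_i), ids.index(row.feature_j)
            assert row.metric_value == min(m[i, j], m[j, i])
            assert min(m[i, j], m[j, i]) < cutoff

    def test_comparability_transform_consistency(self, random_logratios):
        # f(phi_s) pairs and rho pairs select the same pair set
        r = rho(random_logratios)
        ps = phi_s(random_logratios)
        rho_pairs = extract_pairs(r, cutoff=0.5, direction="greater")
        f = comparability_transform(ps.matrix.to_numpy())
        ids = list(ps.matrix.columns)
        brute = {
            (ids[i], ids[j])
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
            if f[i, j] > 0.5
        }
        assert {(p.feature_i, p.feature_j) for p in rho_pairs.itertuples()} == brute
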