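import itertools

import numpy as np
import pytest

import streambeta as sb
from streambeta.io import ValidationError
from streambeta.mantel import unfold


def _random_distance(rng, n, ids=None):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return sb.DistanceMatrix(ids or tuple(f"s{i}" for i in range(n)), m)


def _std_predictors(rng, n, names):
    return {nm: sb.standardize_matrix(_random_distance(rng, n)) for nm in names}


def _r2_oracle(y, X):
    """Plain normal-equation R^2 with intercept."""
    X1 = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.lstsq(X1, y, rcond=None)[0]
    resid = y - X1 @ beta
    yc = y - y.mean()
    return 1 - (resid @ resid) / (yc @ yc)


class TestStandardizeMatrix:
    def test_moments_and_idempotence(self, rng):
        D = _random_distance(rng, 8)
        Z = sb.standardize_matrix(D)
        v = unfold(Z)
        assert abs(v.mean()) < 1e-12 and abs(v.std(ddof=1) - 1) < 1e-12
        assert np.allclose(np.diag(Z.values), 0)
        Z2 = sb.standardize_matrix(Z)
        np.testing.assert_allclose(Z.values, Z2.values, atol=1e-12)

    def test_affine_invariance(self, rng):
        D = _random_distance(rng, 7)
        Z1 = sb.standardize_matrix(D)
        affine = 3 + 2 * D.values
        np.fill_diagonal(affine, 0.0)
        Z2 = sb.standardize_matrix(sb.DistanceMatrix(D.site_ids, affine))
        np.testing.assert_allclose(Z1.values, Z2.values, atol=1e-10)

    def test_constant_matrix_rejected(self):
        ids = tuple("abc")
        flat = sb.DistanceMatrix(ids, np.ones((3, 3)) - np.eye(3))
        with pytest.raises(ValidationError, match="constant"):
            sb.standardize_matrix(flat)


class TestMRM:
    def test_coefficients_match_normal_equation_oracle(self, rng):
        Dy = _random_distance(rng, 8)
        preds = _std_predictors(rng, 8, ("a", "b", "c"))
        res = sb.mrm(Dy, preds, n_perm=99, seed=0)
        X = np.column_stack([unfold(D) for D in preds.values()])
        y = unfold(Dy)
        X1 = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.solve(X1.T @ X1, X1.T @ y)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        for b_hat, nm in zip(beta[1:], preds):
            assert res.coefficients[nm] == pytest.approx(b_hat, abs=1e-10)
        assert res.r_squared == pytest.approx(_r2_oracle(y, X), abs=1e-10)

    def test_planted_single_driver_recovered(self, rng):
        n = 12
        driver = sb.standardize_matrix(_random_distance(rng, n))
        noise = _std_predictors(rng, n, ("n1", "n2"))
        Dy = sb.DistanceMatrix(driver.site_ids, driver.values, signed=True)
        res = sb.mrm(Dy, {"driver": driver, **noise}, n_perm=199, seed=1)
        assert res.coefficients["driver"] == pytest.approx(1.0, abs=0.05)
        assert res.r_squared > 0.95
        assert res.p_coef["driver"] == pytest.approx(1 / 200)

    def test_single_predictor_reproduces_distance_decay_fit(self, rng):
        Dy = _random_distance(rng, 9)
        Dx = _random_distance(rng, 9)
        res = sb.mrm(Dy, {"x": Dx}, n_perm=99, seed=0)
        fit = sb.distance_decay(Dy, Dx)
        assert res.r_squared == pytest.approx(fit.r_squared, abs=1e-12)
        assert res.coefficients["x"] == pytest.approx(fit.slope, abs=1e-12)

    def test_seed_reproducible_and_order_invariant(self, rng):
        Dy = _random_distance(rng, 9)
        preds = _std_predictors(rng, 9, ("a", "b"))
        r1 = sb.mrm(Dy, preds, n_perm=199, seed=5)
        r2 = sb.mrm(Dy, dict(reversed(list(preds.items()))), n_perm=199, seed=5)
        assert r1.p_model == r2.p_model
        for nm in preds:
            assert r1.p_coef[nm] == r2.p_coef[nm]

    def test_rank_deficient_design_rejected(self, rng):
        D = sb.standardize_matrix(_random_distance(rng, 8))
        with pytest.raises(ValidationError, match="rank-deficient"):
            sb.mrm(_random_distance(rng, 8), {"a": D, "b": D}, n_perm=99)

    def test_too_few_pairs_rejected(self, rng):
        Dy = _random_distance(rng, 3)  # 3 pairs
        preds = _std_predictors(rng, 3, ("a", "b", "c"))
        with pytest.raises(ValidationError, match="pairs"):
            sb.mrm(Dy, preds, n_perm=99)


def _hier_part_ordering_oracle(y, X_cols):
    """Average incremental R^2 over all k! predictor orderings."""
    names = list(X_cols)
    k = len(names)
    increments = {nm: [] for nm in names}
    for order in itertools.permutations(names):
        cols = []
        prev = 0.0
        for nm in order:
            cols.append(X_cols[nm])
            cur = _r2_oracle(y, np.column_stack(cols))
            increments[nm].append(cur - prev)
            prev = cur
    return {nm: np.mean(v) for nm, v in increments.items()}


class TestHierPart:
    def test_single_predictor_degenerate_case(self, rng):
        Dy = _random_distance(rng, 8)
        preds = _std_predictors(rng, 8, ("only",))
        res = sb.hier_part(Dy, preds)
        uni = sb.mrm(Dy, preds, n_perm=99, seed=0).r_squared
        assert res.independent["only"] == pytest.approx(uni, abs=1e-12)
        assert res.joint["only"] == pytest.approx(0.0, abs=1e-12)
        assert res.independent_pct["only"] == pytest.approx(100.0)

    def test_orthogonal_predictors_have_no_joint_contribution(self):
        # build two centered, orthogonal unfolded predictors on 5 sites
        n, m = 5, 10
        v1 = np.zeros(m); v1[:5] = [1, -1, 1, -1, 0]
        v2 = np.zeros(m); v2[5:] = [1, 1, -1, -1, 0]
        ids = tuple(f"s{i}" for i in range(n))
        D1, D2 = sb.refold(v1, ids), sb.refold(v2, ids)
        D1 = sb.DistanceMatrix(ids, D1.values, signed=True)
        D2 = sb.DistanceMatrix(ids, D2.values, signed=True)
        rng = np.random.default_rng(0)
        Dy = _random_distance(rng, n)
        res = sb.hier_part(Dy, {"a": D1, "b": D2})
        y = unfold(Dy)
        for nm, v in (("a", v1), ("b", v2)):
            uni = _r2_oracle(y, v[:, None])
            assert res.independent[nm] == pytest.approx(uni, abs=1e-10)
            assert res.joint[nm] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("k", [3, 4])
    def test_subset_weights_equal_all_orderings_average(self, rng, k):
        Dy = _random_distance(rng, 9)
        preds = _std_predictors(rng, 9, tuple(f"p{i}" for i in range(k)))
        res = sb.hier_part(Dy, preds)
        oracle = _hier_part_ordering_oracle(
            unfold(Dy), {nm: unfold(D) for nm, D in preds.items()}
        )
        for nm in preds:
            assert res.independent[nm] == pytest.approx(oracle[nm], abs=1e-10)

    def test_partition_identities_and_percentages(self, rng):
        Dy = _random_distance(rng, 10)
        preds = _std_predictors(rng, 10, tuple("abcde"))
        res = sb.hier_part(Dy, preds)
        full = sb.mrm(Dy, preds, n_perm=99, seed=0).r_squared
        assert sum(res.independent.values()) == pytest.approx(full, abs=1e-8)
        for nm in preds:
            uni = sb.mrm(Dy, {nm: preds[nm]}, n_perm=99, seed=0).r_squared
            assert res.independent[nm] + res.joint[nm] == pytest.approx(uni, abs=1e-8)
        assert sum(res.independent_pct.values()) == pytest.approx(100.0)

    def test_predictor_cap_enforced(self, rng):
        Dy = _random_distance(rng, 8)
        preds = _std_predictors(rng, 8, tuple(f"p{i}" for i in range(17)))
        with pytest.raises(ValidationError, match="cap"):
            sb.hier_part(Dy, preds)


def test_partition_table_identical_responses_and_round_trip(rng):
    D = _random_distance(rng, 8)
    beta = {"total": D, "turnover": D, "nestedness": D}
    preds = _std_predictors(rng, 8, ("a", "b"))
    out = sb.partition_table(beta, preds, n_perm=99, seed=2)
    r2s = {out[k]["mrm"].r_squared for k in beta}
    assert len(r2s) == 1
    mrm_df, pct_df = sb.partition_frames(out)
    assert set(mrm_df.index) == set(beta)
    assert np.allclose(pct_df.sum(axis=0), 100.0)
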