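import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import streambeta as sb
from streambeta.distances import EARTH_RADIUS_M
from streambeta.io import ValidationError


def _meta(lat, lon, elev):
    ids = [f"s{i}" for i in range(len(lat))]
    return sb.TransectMeta(
        pd.DataFrame({"latitude": lat, "longitude": lon, "elevation": elev}, index=ids)
    )


class TestGeographicDistance:
    def test_identical_coordinates_give_zero(self):
        D = sb.geographic_distance(_meta([29.3, 29.3], [103.4, 103.4], [500, 600]))
        assert D.values[0, 1] == 0.0

    def test_one_degree_of_latitude_arc(self):
        # closed form: (pi/180) * R
        D = sb.geographic_distance(_meta([0.0, 1.0], [103.0, 103.0], [0, 0]))
        np.testing.assert_allclose(D.values[0, 1], np.pi / 180 * EARTH_RADIUS_M)
        np.testing.assert_allclose(D.values[0, 1], 111_319.49, rtol=1e-7)

    def test_antipodal_points_are_half_circumference(self):
        D = sb.geographic_distance(_meta([0.0, 0.0], [0.0, 180.0], [0, 0]))
        np.testing.assert_allclose(D.values[0, 1], np.pi * EARTH_RADIUS_M)

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValidationError, match="latitude"):
            _meta([95.0, 0.0], [0.0, 0.0], [0, 0])

    def test_triangle_inequality_on_random_sites(self, rng):
        lat = rng.uniform(-60, 60, 8)
        lon = rng.uniform(-170, 170, 8)
        D = sb.geographic_distance(_meta(lat, lon, np.zeros(8))).values
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-6


class TestElevationalDistance:
    def test_gradient_extremes(self):
        D = sb.elevational_distance(_meta([29.3, 29.4], [103.4, 103.4], [485.0, 2865.0]))
        assert D.values[0, 1] == 2380.0

    def test_equal_elevations_give_zero(self):
        D = sb.elevational_distance(_meta([29.3, 29.4], [103.4, 103.5], [900.0, 900.0]))
        assert D.values[0, 1] == 0.0

    def test_triangle_inequality(self, rng):
        elev = rng.uniform(400, 3000, 10)
        D = sb.elevational_distance(_meta(np.zeros(10), np.zeros(10), elev)).values
        for i in range(10):
            for j in range(10):
                for k in range(10):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


class TestStandardize:
    def test_hand_z_scores(self):
        env = sb.EnvTable(pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=list("abc")))
        z = sb.standardize(env).table["x"].to_numpy()
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])

    def test_idempotent_and_moments(self, rng):
        env = sb.EnvTable(
            pd.DataFrame(rng.normal(5, 3, (10, 4)), columns=list("wxyz"))
        )
        z1 = sb.standardize(env)
        assert np.allclose(z1.table.mean(), 0, atol=1e-10)
        assert np.allclose(z1.table.std(ddof=1), 1, atol=1e-10)
        z2 = sb.standardize(z1)
        np.testing.assert_allclose(z1.table.to_numpy(), z2.table.to_numpy(), atol=1e-12)

    def test_constant_column_is_named_in_error(self):
        env = sb.EnvTable(pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]}))
        with pytest.raises(ValidationError, match="x"):
            sb.standardize(env)


class TestEnvironmentalDistance:
    def test_unit_displacement_in_one_variable(self):
        # two sites differing by exactly 1 SD in one standardized variable
        z = sb.EnvTable(pd.DataFrame({"a": [0.5, -0.5], "b": [0.3, 0.3]}, index=["x", "y"]))
        D = sb.environmental_distance(z, standardized=True)
        np.testing.assert_allclose(D.values[0, 1], 1.0)

    def test_matches_brute_force_loop(self, rng):
        df = pd.DataFrame(rng.normal(size=(8, 5)), columns=list("abcde"))
        env = sb.EnvTable(df)
        D = sb.environmental_distance(env).values
        z = sb.standardize(env).table.to_numpy()
        for i in range(8):
            for j in range(8):
                expect = np.sqrt(((z[i] - z[j]) ** 2).sum())
                np.testing.assert_allclose(D[i, j], expect, atol=1e-12)

    def test_invariant_to_column_order_and_location_shift(self, rng):
        df = pd.DataFrame(rng.normal(size=(9, 4)), columns=list("abcd"))
        D1 = sb.environmental_distance(sb.EnvTable(df)).values
        D2 = sb.environmental_distance(sb.EnvTable(df[list("dcba")] + 100.0)).values
        np.testing.assert_allclose(D1, D2, atol=1e-9)


class TestSingleVariableDistance:
    def test_standardized_column_hand_case(self):
        env = sb.EnvTable(pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=list("abc")))
        D = sb.single_variable_distance(env, "x")
        expect = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        np.testing.assert_allclose(D.values, expect)

    def test_unknown_variable_rejected(self):
        env = sb.EnvTable(pd.DataFrame({"x": [1.0, 2.0]}))
        with pytest.raises(ValidationError, match="unknown variable"):
            sb.single_variable_distance(env, "nope")

    def test_substrate_proportion_and_dominant_encodings(self):
        df = pd.DataFrame(
            {
                "substrate_sand": [0.7, 0.1, 0.6],
                "substrate_gravel": [0.1, 0.2, 0.2],
                "substrate_rock": [0.1, 0.6, 0.1],
                "substrate_humus": [0.1, 0.1, 0.1],
            },
            index=list("abc"),
        )
        env = sb.EnvTable(df)
        Dp = sb.single_variable_distance(env, "substrate")
        np.testing.assert_allclose(
            Dp.values[0, 1], np.sqrt(0.6**2 + 0.1**2 + 0.5**2 + 0.0)
        )
        Dd = sb.single_variable_distance(env, "substrate", substrate_encoding="dominant")
        assert Dd.values[0, 1] == 1.0 and Dd.values[0, 2] == 0.0


class TestScreening:
    def _env(self, rng, n=18):
        elev = np.linspace(485, 2865, n)
        return elev, pd.DataFrame(
            {
                "elevation": elev,
                "temp": 25 - 0.005 * elev,
                "noise": rng.normal(size=n),
            },
            index=[f"s{i}" for i in range(n)],
        )

    def test_monotone_pair_flagged_and_lower_priority_removed(self, rng):
        elev, df = self._env(rng)
        rep = sb.screen_variables(sb.EnvTable(df), threshold=0.7, priority=["elevation"])
        assert ("elevation", "temp") in [(a, b) for a, b, _ in rep.flagged_pairs]
        assert rep.removed == ["temp"]
        assert set(rep.kept) == {"elevation", "noise"}
        assert abs(rep.spearman_rho.loc["elevation", "temp"]) == 1.0

    def test_calibrated_correlation_near_target_is_flagged(self):
        elev = np.linspace(485, 2865, 18)
        temp_z = sb.calibrate_env_correlation(elev, 0.81, seed=11)
        rho = spearmanr(temp_z, elev).statistic
        assert 0.76 <= rho <= 0.86
        df = pd.DataFrame({"elevation": elev, "temp": 22 - 6 * temp_z})
        rep = sb.screen_variables(sb.EnvTable(df), threshold=0.7, priority=["elevation"])
        assert rep.removed == ["temp"]

    def test_independent_variables_rarely_flagged(self):
        # null Spearman at n = 50: |rho| >= 0.7 is far in the tail
        hits = 0
        for seed in range(200):
            r = np.random.default_rng(seed)
            df = pd.DataFrame(r.normal(size=(50, 3)), columns=list("abc"))
            rep = sb.screen_variables(sb.EnvTable(df), threshold=0.7)
            hits += bool(rep.flagged_pairs)
        assert hits <= 10  # >= 95% clean

    def test_report_partitions_variables(self, rng):
        elev, df = self._env(rng)
        rep = sb.screen_variables(sb.EnvTable(df), threshold=0.7, priority=["elevation"])
        assert set(rep.removed) | set(rep.kept) == set(df.columns)
        assert not set(rep.removed) & set(rep.kept)
        assert set(rep.normality_p) == set(df.columns)

    def test_threshold_bounds(self, rng):
        elev, df = self._env(rng)
        with pytest.raises(ValidationError):
            sb.screen_variables(sb.EnvTable(df), threshold=1.5)
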