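"""GLS power: covariance model, oracle equivalence, monotonicity, inversion."""

import numpy as np
import pytest

from mdisw import (
    CorrelationModel,
    InestimableError,
    PowerSpec,
    build_schedule_A,
    design_matrix,
    detectable_difference,
    gls_effect_variance,
    power,
    pseudo_cluster_expansion,
)
from mdisw.design_core import DesignMatrix
from mdisw.power_calc import binary_sigma2, cluster_period_covariance


def client_level_gls_variance(dm, m, sigma2, corr):
    """Brute-force oracle: GLS variance from the full client-level covariance.

    Builds one row per client with correlation rho within the same month and
    rho * r^{|j-k|} across months, and reads off the treatment entry of
    (X' V^-1 X)^-1 accumulated over clusters.
    """
    months_used = sorted(
        {dm.months[int(j)] for row in dm.rows for j in np.flatnonzero(row >= 0)}
    )
    col = {mth: i for i, mth in enumerate(months_used[1:])}
    p = 1 + len(col) + 1
    A = np.zeros((p, p))
    for row, count in zip(dm.rows, dm.clusters_per_sequence):
        obs = np.flatnonzero(row >= 0)
        if obs.size == 0 or count == 0:
            continue
        k = obs.size * m
        X = np.zeros((k, p))
        X[:, 0] = 1.0
        mths = np.repeat([dm.months[int(j)] for j in obs], m).astype(float)
        treat = np.repeat(row[obs].astype(float), m)
        for i, mth in enumerate(mths):
            if mth in col:
                X[i, 1 + col[int(mth)]] = 1.0
        X[:, -1] = treat
        V = sigma2 * corr.icc * corr.cac ** np.abs(mths[:, None] - mths[None, :])
        V[mths[:, None] == mths[None, :]] = sigma2 * corr.icc
        np.fill_diagonal(V, sigma2)
        A += count * X.T @ np.linalg.inv(V) @ X
    return float(np.linalg.inv(A)[-1, -1])


def random_small_design(rng):
    """A random estimable design with <= 4 clusters and <= 4 periods."""
    while True:
        n_clust = int(rng.integers(2, 5))
        n_per = int(rng.integers(2, 5))
        rows = np.sort(rng.integers(0, 2, size=(n_clust, n_per)), axis=1).astype(np.int8)
        if n_per > 2:  # punch an incomplete cell
            rows[0, int(rng.integers(n_per))] = -1
        dm = DesignMatrix(
            "x",
            list(range(1, n_per + 1)),
            rows,
            rng.integers(1, 4, size=n_clust),
        )
        try:
            gls_effect_variance(dm, 2, 1.0, CorrelationModel(0.05, 1.0))
            return dm
        except InestimableError:
            continue


class TestClusterPeriodCovariance:
    def test_no_clustering_gives_scaled_identity(self):
        cov = cluster_period_covariance([1, 2, 3], 1, 2.0, CorrelationModel(0.0, 1.0))
        assert np.allclose(cov, 2.0 * np.eye(3))

    def test_unit_autocorrelation_is_exchangeable(self):
        cov = cluster_period_covariance([1, 4, 9], 5, 1.0, CorrelationModel(0.2, 1.0))
        off = cov[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.2)

    def test_decay_matches_client_level_construction(self):
        """Averaging an explicit 4-client model over months reproduces the
        cluster-period covariance, including the r^2 decay for months {1, 3}."""
        m, rho, r, s2 = 2, 0.1, 0.8, 1.7
        months = np.array([1.0, 1.0, 3.0, 3.0])  # 2 clients in each of 2 months
        V = s2 * rho * r ** np.abs(months[:, None] - months[None, :])
        V[months[:, None] == months[None, :]] = s2 * rho
        np.fill_diagonal(V, s2)
        avg = np.array(
            [
                [V[:2, :2].mean(), V[:2, 2:].mean()],
                [V[2:, :2].mean(), V[2:, 2:].mean()],
            ]
        )
        cov = cluster_period_covariance([1, 3], m, s2, CorrelationModel(rho, r))
        assert np.allclose(cov, avg)
        assert np.isclose(cov[0, 1], s2 * rho * r**2)


class TestGLSEffectVariance:
    def test_parallel_groups_closed_form(self):
        dm = DesignMatrix(
            "x", [1, 2], np.array([[0, 0], [1, 1]], dtype=np.int8), [1, 1]
        )
        v = gls_effect_variance(dm, 5, 2.0, CorrelationModel(0.0, 1.0))
        # independent clients: two-sample variance 2 sigma2 / (m * periods)
        assert np.isclose(v, 2 * 2.0 / (5 * 2))

    @pytest.mark.parametrize("rho", [0.0, 0.05, 0.2])
    @pytest.mark.parametrize("r", [0.5, 1.0])
    def test_equals_client_level_oracle(self, rho, r):
        rng = np.random.default_rng(17)
        corr = CorrelationModel(rho, r)
        for _ in range(6):
            dm = random_small_design(rng)
            m = int(rng.integers(1, 4))
            v1 = gls_effect_variance(dm, m, 1.3, corr)
            v2 = client_level_gls_variance(dm, m, 1.3, corr)
            assert abs(v1 - v2) < 1e-8

    def test_unstratified_variant_A_is_confounded(self):
        """With every facility starting in month 1, the treatment indicator
        is a function of month and the effect is inestimable."""
        table = [(f"f{i}", "Sa", "Sb", 1) for i in range(10)]
        table += [(f"g{i}", "Sb", "Sa", 1) for i in range(10)]
        dm = design_matrix(build_schedule_A(table), "Sa")
        with pytest.raises(InestimableError):
            gls_effect_variance(dm, 25, 0.25, CorrelationModel(0.05, 1.0))

    def test_doubling_clusters_halves_variance(self, design_B_schedules):
        dm = design_matrix(design_B_schedules, "Sa")
        corr = CorrelationModel(0.05, 0.8)
        v1 = gls_effect_variance(dm, 25, 0.25, corr)
        dm.clusters_per_sequence = dm.clusters_per_sequence * 2
        v2 = gls_effect_variance(dm, 25, 0.25, corr)
        assert np.isclose(v2, v1 / 2)

    def test_variance_decreases_with_m(self, design_B_schedules):
        dm = design_matrix(design_B_schedules, "Sa")
        corr = CorrelationModel(0.05, 0.8)
        vs = [gls_effect_variance(dm, m, 0.25, corr) for m in (1, 5, 25, 100)]
        assert all(a > b for a, b in zip(vs, vs[1:]))


class TestPower:
    def test_null_effect_gives_alpha_over_two(self, design_B_schedules):
        dm = design_matrix(design_B_schedules, "Sa")
        spec = PowerSpec(design=dm, delta=0.0, corr=CorrelationModel(0.05, 0.8))
        assert np.isclose(power(spec).power, 0.025)

    def test_power_increases_with_effect_size(self, design_B_schedules):
        dm = design_matrix(design_B_schedules, "Sa")
        powers = [
            power(PowerSpec(design=dm, delta=d, corr=CorrelationModel(0.05, 0.8))).power
            for d in (0.02, 0.05, 0.1, 0.2)
        ]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_detectable_difference_inverts_power(self, design_B_schedules):
        dm = design_matrix(design_B_schedules, "Sa")
        dm.clusters_per_sequence = pseudo_cluster_expansion(18, 6, 12)
        corr = CorrelationModel(0.05, 0.8)
        d = detectable_difference(dm, m=25, p0=0.5, corr=corr, target_power=0.8)
        achieved = power(
            PowerSpec(design=dm, m=25, p0=0.5, delta=d, corr=corr)
        ).power
        assert abs(achieved - 0.8) < 1e-4

    def test_richer_design_detects_smaller_difference(self, design_B_schedules):
        dm = design_matrix(design_B_schedules, "Sa")
        corr = CorrelationModel(0.05, 0.8)
        d_small = detectable_difference(dm, corr=corr)
        dm.clusters_per_sequence = pseudo_cluster_expansion(18, 6, 12)
        d_big = detectable_difference(dm, corr=corr)
        assert d_big < d_small

    def test_minimal_design_A_cross_check(self):
        """Six facilities covering the six sequences of one standard, with 25
        clients per month and baseline compliance 50%: the detectable
        improvement at 80% power is of the same order as the closed-form
        two-proportion value for the matched per-arm client totals (the GLS
        value is larger because it adjusts for month effects)."""
        table = [(f"f{i}", "Sa", "Sb", 1 + i % 3) for i in range(3)]
        table += [(f"g{i}", "Sb", "Sa", 1 + i % 3) for i in range(3)]
        dm = design_matrix(build_schedule_A(table), "Sa")
        d = detectable_difference(dm, m=25, p0=0.5, corr=CorrelationModel(0.0, 1.0))
        from scipy import optimize, stats

        def two_prop_power(delta, n0, n1, p0=0.5):
            p1 = p0 + delta
            se = np.sqrt(p0 * (1 - p0) / n0 + p1 * (1 - p1) / n1)
            return float(stats.norm.cdf(delta / se - 1.959964))

        # 9 collection events per arm across the 6 sequences, 25 clients each
        closed = optimize.brentq(
            lambda x: two_prop_power(x, 225, 225) - 0.8, 1e-6, 0.49
        )
        assert closed < d < 3 * closed

    def test_pseudo_cluster_expansion_counts(self):
        assert pseudo_cluster_expansion(18, 6, 12).tolist() == [9] * 12
        assert pseudo_cluster_expansion(1, 1, 1).tolist() == [1]
        counts = pseudo_cluster_expansion(40, 2, 36, seed=3)
        assert counts.sum() == 80
        assert set(counts.tolist()) == {2, 3}

    def test_sigma2_conventions(self):
        assert np.isclose(binary_sigma2(0.5, 0.6), 0.245)
        assert np.isclose(binary_sigma2(0.5, 0.6, "control"), 0.25)
        assert np.isclose(binary_sigma2(0.5, 0.6, "pooled"), 0.55 * 0.45)
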