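"""Grouping rules, partial effects/correlations, moving windows, dominance."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from resdiv import pbr, synthetic


def group_sizes(scheme):
    return [len(scheme.assignment[lab]) for lab in scheme.labels]


class TestQuantileGroups:
    @pytest.mark.parametrize(
        "n,g,expected",
        [(97, 5, [19, 19, 19, 19, 21]), (100, 5, [20] * 5), (7, 3, [2, 2, 3])],
    )
    def test_floor_rule_sizes(self, n, g, expected):
        rng = np.random.default_rng(0)
        scheme = pbr.rd_quantile_groups(rng.uniform(size=n), g)
        assert group_sizes(scheme) == expected

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            pbr.rd_quantile_groups([0.1, 0.2], 3)

    def test_groups_partition_and_rd_ranges_are_ordered(self):
        rng = np.random.default_rng(1)
        rd = rng.uniform(size=53)
        scheme = pbr.rd_quantile_groups(rd, 5)
        all_idx = np.concatenate([scheme.assignment[lab] for lab in scheme.labels])
        assert sorted(all_idx) == list(range(53))
        maxes = [rd[scheme.assignment[lab]].max() for lab in scheme.labels]
        mins = [rd[scheme.assignment[lab]].min() for lab in scheme.labels]
        assert all(maxes[i] <= mins[i + 1] for i in range(4))

    def test_ties_broken_by_stable_input_order(self):
        rd = np.zeros(10)
        scheme = pbr.rd_quantile_groups(rd, 2)
        assert list(scheme.assignment["Q1"]) == list(range(5))


class TestCumulativeGroups:
    def test_ceiling_rule_low(self):
        rd = np.arange(97.0)
        scheme = pbr.cumulative_groups(rd, fractions=(0.2,), from_="low")
        assert group_sizes(scheme) == [20]  # ceil(19.4)
        assert set(scheme.assignment["low_20"]) == set(range(20))

    def test_full_fraction_takes_all_sites(self):
        rd = np.arange(30.0)
        for from_ in ("low", "high"):
            scheme = pbr.cumulative_groups(rd, fractions=(1.0,), from_=from_)
            assert group_sizes(scheme) == [30]

    def test_high_mirror(self):
        rd = np.arange(97.0)
        scheme = pbr.cumulative_groups(rd, fractions=(0.2,), from_="high")
        assert set(scheme.assignment["high_20"]) == set(range(77, 97))

    def test_nesting(self):
        rd = np.random.default_rng(2).uniform(size=50)
        scheme = pbr.cumulative_groups(rd, fractions=(0.2, 0.5, 1.0), from_="low")
        s1, s2, s3 = (set(scheme.assignment[lab]) for lab in scheme.labels)
        assert s1 < s2 < s3

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            pbr.cumulative_groups(np.arange(10.0), fractions=(0.5, 0.3))


class TestObservedRelationship:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        fit = pbr.observed_relationship(x, 3.0 * x)
        assert fit.slope == pytest.approx(3.0)
        assert fit.ci_high - fit.ci_low == pytest.approx(0.0, abs=1e-9)
        assert fit.p_value < 1e-12

    def test_independent_data_ci_covers_zero(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        fit = pbr.observed_relationship(x, y)
        assert fit.ci_low < 0 < fit.ci_high

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pbr.observed_relationship(np.ones(10), np.arange(10.0))


class TestPartialEffects:
    def test_orthogonal_predictor_identity(self):
        # make RD exactly orthogonal to AGB in sample: AGB coefficient in
        # SR ~ RD + AGB then equals the simple correlation r(SR, AGB)
        rng = np.random.default_rng(6)
        agb = rng.normal(size=200)
        agb -= agb.mean()
        rd = rng.normal(size=200)
        rd -= rd.mean()
        rd -= agb * (rd @ agb) / (agb @ agb)  # exact zero sample correlation
        sr = 0.5 * agb + rng.normal(size=200)
        effects = pbr.partial_effects(agb, sr, rd)
        agb_eff = effects[2]
        r_simple = float(np.corrcoef(sr, agb)[0, 1])
        assert agb_eff.coef == pytest.approx(r_simple, abs=1e-10)

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(10, 60)
            agb = rng.normal(size=n)
            rd = 0.5 * agb + rng.normal(size=n)
            sr = 0.3 * rd - 0.4 * agb + rng.normal(size=n)
            effects = pbr.partial_effects(agb, sr, rd)
            z = lambda v: (v - v.mean()) / v.std(ddof=1)
            zr, za, zs = z(rd), z(agb), z(sr)
            r_ra = float(zr @ za) / (n - 1)
            beta = np.linalg.inv(np.array([[1.0, r_ra], [r_ra, 1.0]])) @ np.array(
                [float(zr @ zs) / (n - 1), float(za @ zs) / (n - 1)]
            )
            assert effects[1].coef == pytest.approx(beta[0], abs=1e-10)
            assert effects[2].coef == pytest.approx(beta[1], abs=1e-10)

    def test_deterministic_dependence(self):
        rng = np.random.default_rng(8)
        rd = rng.normal(size=100)
        agb = rng.normal(size=100)
        effects = pbr.partial_effects(agb, rd.copy(), rd)  # SR identical to RD
        assert effects[1].coef == pytest.approx(1.0, abs=1e-10)
        assert effects[2].coef == pytest.approx(0.0, abs=1e-10)

    def test_collinear_inputs_rejected(self):
        rd = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            pbr.partial_effects(2.0 * rd + 1.0, rd + np.random.default_rng(0).normal(size=10), rd)


class TestPartialCorrelation:
    def test_uncorrelated_control_reduces_to_pearson(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=300)
        y = 0.6 * x + rng.normal(size=300)
        z = rng.normal(size=300)
        # force exact zero sample correlation of z with x and y
        X = np.column_stack([x - x.mean(), y - y.mean()])
        z -= X @ np.linalg.lstsq(X, z, rcond=None)[0]
        r, _ = pbr.partial_correlation(x, y, z)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_identical_variables_give_unit_correlation(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        r, p = pbr.partial_correlation(x, x.copy(), z)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0)

    def test_residual_method_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(8, 50))
            x, y, z = rng.normal(size=(3, n))
            r, _ = pbr.partial_correlation(x, y, z)
            zc = np.column_stack([np.ones(n), z])
            rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
            ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
            assert r == pytest.approx(float(np.corrcoef(rx, ry)[0, 1]), abs=1e-10)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=["x", "y", "z"])
        r, p = pbr.partial_correlation(df.x, df.y, df.z)
        out = pg.partial_corr(df, x="x", y="y", covar="z")
        assert r == pytest.approx(float(out["r"].iloc[0]), abs=1e-9)
        pcol = [c for c in out.columns if c.startswith("p")][0]
        assert p == pytest.approx(float(out[pcol].iloc[0]), abs=1e-9)

    def test_perfect_control_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            pbr.partial_correlation(x, np.random.default_rng(0).normal(size=10), 2 * x)


class TestMovingWindows:
    def test_block_layout_97_by_10(self):
        wins = pbr.moving_windows(97, 10, mode="block")
        assert len(wins) == 10
        assert list(wins[0]) == list(range(10))
        assert list(wins[-1]) == list(range(87, 97))  # sites 88-97, 1-based

    def test_sliding_count(self):
        wins = pbr.moving_windows(97, 10, mode="sliding")
        assert len(wins) == 88
        assert list(wins[0]) == list(range(10))
        assert list(wins[-1]) == list(range(87, 97))

    def test_exact_division_blocks(self):
        wins = pbr.moving_windows(20, 10, mode="block")
        assert [list(w) for w in wins] == [list(range(10)), list(range(10, 20))]

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            pbr.moving_windows(10, 11)
        with pytest.raises(ValueError):
            pbr.moving_windows(10, 4)

    @given(st.integers(min_value=5, max_value=60))
    def test_w_equals_n_reduces_both_modes_to_one_window(self, n):
        for mode in ("sliding", "block"):
            wins = pbr.moving_windows(n, n, mode=mode)
            assert len(wins) == 1
            assert list(wins[0]) == list(range(n))


class TestWindowPartialSeries:
    def test_single_window_equals_global_partial_correlation(self, default_table):
        table, indices = default_table
        rd = indices["RD"].to_numpy()
        agb = table["agb_g_m2"].to_numpy(float)
        sr = table["sr_count"].to_numpy(float)
        ws = pbr.window_partial_series(rd, agb, sr, w=rd.size, mode="block")
        assert len(ws) == 1
        r_global, _ = pbr.partial_correlation(agb, sr, rd)
        assert ws.partial_r.iloc[0] == pytest.approx(r_global)

    def test_no_interaction_windows_scatter_around_zero(self):
        means = []
        for seed in range(50):
            cfg = synthetic.GeneratorConfig(seed=seed, interaction_gamma0=0.0)
            table = synthetic.generate_site_table(cfg)
            from resdiv import radar

            rd = radar.compute_indices(
                table[list(synthetic.RESOURCE_COLUMNS)], shift=cfg.shift
            )["RD"].to_numpy()
            ws = pbr.window_partial_series(
                rd, table["agb_g_m2"].to_numpy(float), table["sr_count"].to_numpy(float), w=10
            )
            means.append(ws.partial_r.mean())
        grand = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(grand) < 2 * se + 0.02

    def test_default_generator_trend_is_negative(self, default_table):
        table, indices = default_table
        ws = pbr.window_partial_series(
            indices["RD"].to_numpy(),
            table["agb_g_m2"].to_numpy(float),
            table["sr_count"].to_numpy(float),
            w=10,
        )
        slope = np.polyfit(ws.mean_rd, ws.partial_r, 1)[0]
        assert slope < 0


class TestSimpsonsDominance:
    @pytest.mark.parametrize(
        "p,expected",
        [([1.0], 1.0), ([0.25] * 4, 0.25), ([0.5, 0.3, 0.2], 0.38)],
    )
    def test_known_values(self, p, expected):
        assert pbr.simpsons_dominance(p) == pytest.approx(expected)

    def test_unnormalized_vector_reports_sum(self):
        with pytest.raises(ValueError, match="0.9"):
            pbr.simpsons_dominance([0.5, 0.4])

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            pbr.simpsons_dominance([1.2, -0.2])
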