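"""ISD permeability, Table-style decompositions, stitching, O-antigen."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ompermeate as om
from ompermeate.permeability import (
    breakdown_table,
    decompose_permeability,
    find_region_boundaries,
    isd_permeability,
    oantigen_thickness,
    partition_coefficient,
    recombine,
    spline_fit,
    stitch_segments,
)
from ompermeate.profiles import Profile

from .conftest import KBT_310

RT_LN10_310 = KBT_310 * np.log(10.0)  # 1.4184 kcal/mol


def flat_profiles(g0=0.0, d0=80.0, span=(-35.0, 65.0), n=201):
    grid = np.linspace(span[0], span[1], n)
    g = spline_fit(Profile(grid=grid, values=np.full(n, g0)))
    d = spline_fit(Profile(grid=grid, values=np.full(n, d0), kind="diffusivity"))
    return g, d


class TestSplineFit:
    def test_reproduces_cubic_polynomial_exactly(self):
        grid = np.linspace(-5, 5, 25)
        vals = 0.3 * grid**3 - grid**2 + 2 * grid - 7
        p = spline_fit(Profile(grid=grid, values=vals))
        probe = np.linspace(-5, 5, 501)
        np.testing.assert_allclose(
            p(probe), 0.3 * probe**3 - probe**2 + 2 * probe - 7, atol=1e-8
        )

    def test_zero_smoothing_interpolates(self):
        rng = np.random.default_rng(2)
        grid = np.linspace(0, 10, 15)
        vals = rng.normal(size=15)
        p = spline_fit(Profile(grid=grid, values=vals), smoothing=0.0)
        np.testing.assert_allclose(p(grid), vals, atol=1e-10)

    def test_smoothing_reduces_noise_amplitude(self):
        rng = np.random.default_rng(5)
        grid = np.linspace(0, 20, 81)
        noise = rng.normal(0.0, 0.3, grid.size)
        p = spline_fit(Profile(grid=grid, values=noise), smoothing=5.0)
        assert np.max(np.abs(p(grid))) < np.max(np.abs(noise))

    def test_masked_points_excluded(self):
        grid = np.linspace(0, 10, 21)
        vals = grid.copy()
        vals[8:12] = np.nan
        p = spline_fit(Profile(grid=grid, values=vals))
        assert p(5.0) == pytest.approx(5.0, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            spline_fit(Profile(grid=np.array([0.0, 1, 2]), values=np.zeros(3)))


class TestIsdPermeability:
    def test_flat_profile_closed_form(self):
        # G=0, D=80 A^2/ns over 100 A: Pm = D/L = 0.8 A/ns = 8 cm/s
        g, d = flat_profiles()
        pm = isd_permeability(g, d, -35.0, 65.0)
        assert pm == pytest.approx(8.0, rel=1e-6)

    def test_doubling_range_halves_pm(self):
        g, d = flat_profiles(span=(-100, 100), n=401)
        pm1 = isd_permeability(g, d, -50.0, 0.0)
        pm2 = isd_permeability(g, d, -50.0, 50.0)
        assert pm2 == pytest.approx(pm1 / 2.0, rel=1e-9)

    def test_unit_chain_factor_ten(self):
        # D/L in A/ns must convert to cm/s by exactly 10
        g, d = flat_profiles(d0=42.0, span=(0.0, 21.0), n=64)
        pm = isd_permeability(g, d, 0.0, 21.0)
        assert pm == pytest.approx(10.0 * 42.0 / 21.0, rel=1e-9)

    def test_gaussian_barrier_matches_brute_force(self):
        grid = np.linspace(-35, 65, 401)
        g = spline_fit(Profile(grid=grid, values=5.0 * np.exp(-(grid - 10) ** 2 / (2 * 9.0))))
        d = spline_fit(Profile(grid=grid, values=np.full(grid.size, 60.0), kind="diffusivity"))
        pm = isd_permeability(g, d, -35.0, 65.0)
        dense = np.linspace(-35, 65, 100_001)
        integrand = np.exp(g(dense) / KBT_310) / d(dense)
        pm_bf = 10.0 / np.trapezoid(integrand, dense)
        assert pm == pytest.approx(pm_bf, rel=1e-3)

    def test_random_smooth_profiles_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            grid = np.linspace(-20, 20, 161)
            n_g = rng.integers(1, 4)
            g_vals = np.zeros(grid.size)
            for _ in range(n_g):
                h = rng.uniform(-3, 5)
                c = rng.uniform(-15, 15)
                s = rng.uniform(2, 6)
                g_vals += h * np.exp(-((grid - c) ** 2) / (2 * s * s))
            d_vals = 40 + 30 * np.sin(grid / rng.uniform(3, 9)) + rng.uniform(10, 20)
            g = spline_fit(Profile(grid=grid, values=g_vals))
            d = spline_fit(Profile(grid=grid, values=d_vals, kind="diffusivity"))
            pm = isd_permeability(g, d, -20, 20)
            dense = np.linspace(-20, 20, 50_001)
            pm_bf = 10.0 / np.trapezoid(np.exp(g(dense) / KBT_310) / d(dense), dense)
            assert pm == pytest.approx(pm_bf, rel=1e-3)

    def test_uncovered_range_rejected(self):
        g, d = flat_profiles(span=(-10, 10), n=41)
        with pytest.raises(ValueError, match="does not cover"):
            isd_permeability(g, d, -35.0, 65.0)


class TestRegionBoundaries:
    def make_g(self, min_u, min_g):
        grid = np.linspace(-35, 65, 401)
        vals = (
            -2.0 * np.exp(-((grid - min_u) ** 2) / 8.0)
            - 1.5 * np.exp(-((grid - min_g) ** 2) / 8.0)
            + 1.0 * np.exp(-(grid**2) / 50.0)
        )
        return spline_fit(Profile(grid=grid, values=vals))

    def test_constructed_minima_found(self):
        bu, bg = find_region_boundaries(self.make_g(-14.0, 12.0))
        assert bu == pytest.approx(-14.0, abs=0.1)
        assert bg == pytest.approx(12.0, abs=0.1)

    def test_monotone_interval_warns_and_returns_edge(self):
        grid = np.linspace(-35, 65, 401)
        g = spline_fit(Profile(grid=grid, values=0.1 * grid))
        with pytest.warns(RuntimeWarning, match="monotone"):
            bu, _ = find_region_boundaries(g)
        assert bu == pytest.approx(-22.0, abs=0.05)

    def test_symmetric_double_well_symmetric_boundaries(self):
        grid = np.linspace(-30, 30, 601)
        vals = -2.0 * (
            np.exp(-((grid + 12) ** 2) / 10.0) + np.exp(-((grid - 12) ** 2) / 10.0)
        )
        g = spline_fit(Profile(grid=grid, values=vals))
        bu, bg = find_region_boundaries(g)
        assert bu == pytest.approx(-bg, abs=0.05)


class TestPartitionCoefficient:
    def test_zero_when_membrane_equals_solution(self):
        g, _ = flat_profiles()
        assert partition_coefficient(g, (45, 65), -14.0, 12.0) == pytest.approx(0.0)

    def test_deep_minimum_gives_logp_four(self):
        # membrane minimum at -5.67 kcal/mol, RT ln10 = 1.4184 at 310 K
        grid = np.linspace(-35, 65, 401)
        vals = -5.67 * np.exp(-((grid + 14) ** 2) / 4.0)
        g = spline_fit(Profile(grid=grid, values=vals))
        logp = partition_coefficient(g, (45, 65), -14.0, 12.0)
        assert logp == pytest.approx(5.67 / RT_LN10_310, abs=1e-6)
        assert logp == pytest.approx(4.0, abs=0.01)

    def test_deeper_minimum_strictly_increases_logp(self):
        grid = np.linspace(-35, 65, 401)
        logps = []
        for depth in (1.0, 2.0, 4.0):
            vals = -depth * np.exp(-((grid + 14) ** 2) / 4.0)
            g = spline_fit(Profile(grid=grid, values=vals))
            logps.append(partition_coefficient(g, (45, 65), -14.0, 12.0))
        assert logps[0] < logps[1] < logps[2]


TABLE2_ROWS = [
    # compound, logP, logPm, logPm_u, logPm_c, logPm_g
    ("guaiacol", 4.0, -0.8, -1.9, -0.3, -4.8),
    ("vanillyl alcohol", 1.0, -0.4, 0.8, -0.9, -1.3),
    ("vanillin", 2.5, -1.6, -0.5, -1.4, -4.1),
    ("coniferyl alcohol", 1.9, -1.0, -0.0, -0.4, -2.9),
    ("vanillate", 1.3, -10.7, -0.9, -12.0, 1.0),
]


class TestRecombine:
    @pytest.mark.parametrize("name,logp,total,lu,lc,lg", TABLE2_ROWS)
    def test_published_component_rows(self, name, logp, total, lu, lc, lg):
        assert recombine(logp, lu, lc, lg) == pytest.approx(total, abs=0.05)

    @given(
        logp=st.floats(-5, 5),
        x=st.floats(-10, 10),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_equal_components_closed_form(self, logp, x):
        assert recombine(logp, x, x, x) == pytest.approx(
            logp + x - np.log10(3.0), abs=1e-9
        )

    def test_smallest_component_dominates(self):
        assert recombine(0.0, 0.0, 3.0, 3.0) == pytest.approx(-0.0009, abs=1e-4)

    def test_neg_inf_component_blocks(self):
        assert recombine(2.0, -np.inf, 1.0, 1.0) == -np.inf
        assert recombine(2.0, -np.inf, -np.inf, -np.inf) == -np.inf

    @given(
        logp=st.floats(-3, 3),
        lu=st.floats(-8, 8),
        lc=st.floats(-8, 8),
        lg=st.floats(-8, 8),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_total_bounded_by_smallest_component(self, logp, lu, lc, lg):
        total = recombine(logp, lu, lc, lg)
        assert total <= logp + min(lu, lc, lg) + 1e-9


@pytest.fixture(scope="module")
def om_like_profiles():
    grid = np.linspace(-35, 65, 401)
    g_vals = (
        -3.0 * np.exp(-((grid + 10) ** 2) / 18.0)
        + 2.5 * np.exp(-((grid - 14) ** 2) / 20.0)
        - 1.8 * np.exp(-((grid - 8) ** 2) / 10.0)
    )
    d_vals = 80.0 - 55.0 * np.exp(-((grid - 12) ** 2) / 60.0) - 30.0 * np.exp(
        -((grid + 12) ** 2) / 80.0
    )
    g = spline_fit(Profile(grid=grid, values=g_vals))
    d = spline_fit(Profile(grid=grid, values=d_vals, kind="diffusivity"))
    return g, d


class TestDecompose:
    def test_breakdown_satisfies_serial_identity(self, om_like_profiles):
        g, d = om_like_profiles
        bd = decompose_permeability(g, d, solution_range=(45.0, 65.0))
        assert bd.logPm == pytest.approx(
            recombine(bd.logP, bd.logPm_u, bd.logPm_c, bd.logPm_g), abs=1e-9
        )
        assert -22 < bd.boundary_u < -5
        assert 5 < bd.boundary_g < 22

    def test_posterior_draws_fill_sd(self, om_like_profiles):
        g, d = om_like_profiles
        rng = np.random.default_rng(0)
        draws = [g.values + rng.normal(0.0, 0.1, g.values.size) for _ in range(20)]
        bd = decompose_permeability(g, d, solution_range=(45.0, 65.0), g_draws=draws)
        assert set(bd.sd) >= {"logP", "logPm"}
        assert 0 < bd.sd["logPm"] < 1.0

    def test_table_layout(self, om_like_profiles):
        g, d = om_like_profiles
        bd = decompose_permeability(g, d, solution_range=(45.0, 65.0))
        df = breakdown_table({"compound-a": bd})
        assert list(df.columns) == [
            "Compound", "logP", "logPm", "logPm_u", "logPm_c", "logPm_g",
        ]


class TestOantigenThickness:
    def test_unit_closed_form(self):
        # G(xi_max)=0, D=1 A^2/ns, Pm_ref = 1 A/ns (10 cm/s), factor 10:
        # resistance must grow from 1 to 10 ns/A at unit incremental
        # resistance, so L = 9 A
        grid = np.linspace(0, 30, 121)
        g = spline_fit(Profile(grid=grid, values=np.zeros(grid.size)))
        d = spline_fit(Profile(grid=grid, values=np.ones(grid.size), kind="diffusivity"))
        with pytest.warns(RuntimeWarning, match="flat"):
            L = oantigen_thickness(g, d, (5.0, 25.0), Pm_reference=10.0, factor=10)
        assert L == pytest.approx(9.0, rel=1e-9)

    def test_printed_equation_reading(self):
        grid = np.linspace(0, 30, 121)
        g = spline_fit(Profile(grid=grid, values=np.zeros(grid.size)))
        d = spline_fit(Profile(grid=grid, values=np.ones(grid.size), kind="diffusivity"))
        with pytest.warns(RuntimeWarning, match="flat"):
            L = oantigen_thickness(
                g, d, (5.0, 25.0), Pm_reference=10.0, factor=10,
                added_resistance_multiple=10.0,
            )
        assert L == pytest.approx(10.0, rel=1e-9)

    def test_higher_barrier_shrinks_thickness(self):
        grid = np.linspace(0, 30, 301)
        d = spline_fit(Profile(grid=grid, values=np.full(grid.size, 20.0), kind="diffusivity"))
        thicknesses = []
        for h in (1.0, 2.0, 3.0):
            g = spline_fit(
                Profile(grid=grid, values=h * np.exp(-((grid - 15) ** 2) / 8.0))
            )
            thicknesses.append(
                oantigen_thickness(g, d, (5.0, 25.0), Pm_reference=2.0)
            )
        assert thicknesses[0] > thicknesses[1] > thicknesses[2]

    def test_inverted_construction_recovers_target_length(self):
        # build a profile whose barrier and diffusivity imply L = 28 A
        # (2.8 nm, the scale of a realistic lower bound) and invert
        pm_ref = 2.0  # cm/s
        r_ref = 1.0 / (pm_ref / 10.0)  # 5 ns/A
        target = 28.0
        d_at_max = 40.0
        # need exp(beta G)/D = 9 * r_ref / target
        g_needed = KBT_310 * np.log(9.0 * r_ref * d_at_max / target)
        grid = np.linspace(0, 40, 401)
        g = spline_fit(
            Profile(grid=grid, values=g_needed * np.exp(-((grid - 20) ** 2) / 18.0))
        )
        d = spline_fit(
            Profile(grid=grid, values=np.full(grid.size, d_at_max), kind="diffusivity")
        )
        L = oantigen_thickness(g, d, (10.0, 30.0), Pm_reference=pm_ref)
        assert L == pytest.approx(target, rel=1e-3)
        assert 2.0 < g_needed < 6.0  # a typical interfacial barrier height


class TestStitchSegments:
    def cut(self, grid, vals, n_seg=15, width=13.0, overlap=2.0, seed=0):
        rng = np.random.default_rng(seed)
        segs = []
        start = grid[0]
        for i in range(n_seg):
            sel = (grid >= start - 1e-9) & (grid <= start + width + 1e-9)
            offset = 0.0 if i == 0 else rng.uniform(-5, 5)
            segs.append(Profile(grid=grid[sel], values=vals[sel] + offset))
            start += width - overlap
        return segs

    def master(self):
        grid = np.arange(-40.0, 127.0 + 0.5, 0.5)
        vals = 3 * np.sin(grid / 9.0) + 0.01 * grid
        return grid, vals

    def test_exact_reconstruction_up_to_constant(self):
        grid, vals = self.master()
        segs = self.cut(grid, vals)
        res = stitch_segments(segs)
        m = np.isin(np.round(res.merged.grid, 6), np.round(grid, 6))
        recon = res.merged.values - res.merged.values[0] + vals[0]
        np.testing.assert_allclose(recon, vals[: recon.size], atol=1e-8)

    def test_order_invariance(self):
        grid, vals = self.master()
        segs = self.cut(grid, vals, seed=1)
        a = stitch_segments(segs)
        b = stitch_segments(segs[::-1])
        np.testing.assert_allclose(
            a.merged.values - a.merged.values[0],
            b.merged.values - b.merged.values[0],
            atol=1e-8,
        )

    def test_injected_discontinuity_warns(self):
        grid, vals = self.master()
        segs = self.cut(grid, vals, seed=2)
        bad = segs[7].values.copy()
        bad[:3] += 3.0  # a step cutting through the 5-point overlap region
        segs[7] = Profile(grid=segs[7].grid, values=bad)
        with pytest.warns(RuntimeWarning, match="inconsistent overlap"):
            res = stitch_segments(segs)
        assert max(res.join_residuals) > 0.25

    def test_disjoint_segments_rejected(self):
        a = Profile(grid=np.linspace(0, 5, 6), values=np.zeros(6))
        b = Profile(grid=np.linspace(10, 15, 6), values=np.zeros(6))
        with pytest.raises(ValueError, match="overlap"):
            stitch_segments([a, b])
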