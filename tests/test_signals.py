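"""Signal propensities, static patterns and the Turing generator."""

import numpy as np
import pytest

from stemdish import lattice
from stemdish.signals import (LeadingSignalConfig, TerritorySignalParams,
                              diffusion_propensity, fixed_pattern,
                              generate_turing_field, leading_propensities,
                              partner_propensities, territory_propensities,
                              turing_uniform_start, PATTERN_MAX)

TS = TerritorySignalParams()


class TestTerritoryPropensities:
    def test_a_cell_full_production(self):
        p = territory_propensities(lattice.A, 0, 0, 4, TS)
        assert p["s1_prod"] == pytest.approx(220.0)
        assert p["s2_prod"] == 0.0

    def test_half_saturation(self):
        p = territory_propensities(lattice.A, 0, 2, 4, TS)
        assert p["s1_prod"] == pytest.approx(110.0)

    def test_zero_count_no_decay_or_diffusion(self):
        p = territory_propensities(lattice.EMPTY, 0, 0, 4, TS)
        assert p["s1_deg"] == p["s1_diff"] == 0.0

    def test_out_of_dish_rejected(self):
        with pytest.raises(ValueError):
            territory_propensities(lattice.OUT, 0, 0, 0, TS)

    def test_mass_action_scales_with_count(self):
        assert diffusion_propensity(110.0, 3, 4, "mass_action") == 110.0 * 12
        assert diffusion_propensity(110.0, 3, 4, "table") == 110.0 * 4
        assert diffusion_propensity(110.0, 0, 4, "table") == 0.0


class TestLeadingPropensities:
    def test_phase_three_all_off(self):
        cfg = LeadingSignalConfig(scenario="turing")
        assert all(v == 0 for v in
                   leading_propensities(lattice.S, 4, 4, 4, cfg, 3).values())
        assert all(v == 0 for v in
                   partner_propensities(4, 4, 4, cfg, 3).values())

    def test_turing_production_clipped_at_upper(self):
        cfg = LeadingSignalConfig(scenario="turing", s_upper=10)
        p = leading_propensities(lattice.EMPTY, 10, 4, 4, cfg, 1)
        assert p["sl_prod"] == 0.0

    def test_turing_constant_source_at_zero(self):
        cfg = LeadingSignalConfig(scenario="turing")
        p = leading_propensities(lattice.EMPTY, 0, 0, 4, cfg, 1)
        assert p["sl_prod"] == pytest.approx(cfg.gamma_sl * cfg.C)
        assert p["sl_deg"] == 0.0

    def test_partner_production_and_offset_degradation(self):
        cfg = LeadingSignalConfig(scenario="turing")
        p = partner_propensities(10, 0, 4, cfg, 1)
        assert p["sa_prod"] == pytest.approx(cfg.gamma_sa * cfg.B * 10)
        assert p["sa_deg"] == pytest.approx(cfg.gamma_sa * 1.0)

    def test_diffusive_sources_cells_only(self):
        cfg = LeadingSignalConfig(scenario="diffusive", sources="cells")
        assert leading_propensities(lattice.EMPTY, 0, 0, 4, cfg, 1)["sl_prod"] == 0
        assert leading_propensities(lattice.S, 0, 0, 4, cfg, 1)["sl_prod"] == cfg.alpha_sl


class TestFixedPatterns:
    def test_unknown_name_lists_valid(self):
        with pytest.raises(ValueError, match="half"):
            fixed_pattern("blob", 10)

    def test_half_pattern_values(self):
        field = fixed_pattern("half", 10)
        mask = lattice.dish_mask(10)
        c = mask.shape[0] // 2
        assert set(np.unique(field[mask])) <= {0, PATTERN_MAX}
        assert (field[:, :c][mask[:, :c]] == PATTERN_MAX).all()
        assert (field[:, c:] == 0).all()

    def test_gaussian_peak_at_centre(self):
        field = fixed_pattern("gaussian", 10)
        c = field.shape[0] // 2
        assert field[c, c] == PATTERN_MAX == field.max()

    def test_out_of_dish_zero(self):
        for name in ("half", "stripes", "spots", "gaussian", "checker"):
            field = fixed_pattern(name, 8)
            assert (field[~lattice.dish_mask(8)] == 0).all()

    def test_reversed_spots_complements_spots(self):
        mask = lattice.dish_mask(10)
        spots = fixed_pattern("spots", 10)
        rev = fixed_pattern("reversed_spots", 10)
        assert ((spots[mask] > 0) ^ (rev[mask] > 0)).all()

    def test_none_is_zero_field(self):
        assert fixed_pattern("none", 6).sum() == 0


class TestTuring:
    def test_uniform_start_is_reaction_balance(self):
        cfg = LeadingSignalConfig(scenario="turing")
        s, sa = turing_uniform_start(cfg)
        # A*s + C = sa and B*s - 1 = sa at s = (1 + C)/(B - A) = 4
        assert s == 4 and sa == 4

    def test_field_respects_bounds_and_breaks_symmetry(self):
        cfg = LeadingSignalConfig(scenario="turing", d_l=1e4, d_a=2e5,
                                  s_upper=10)
        field = generate_turing_field(12, cfg, seed=3, horizon=0.004)
        mask = lattice.dish_mask(12)
        assert field[mask].min() >= 0 and field[mask].max() <= 10
        assert (field[~mask] == 0).all()
        # stripe regime: spatial variance well above the well-mixed
        # (Poisson-like) null at the same mean, and both clip levels present
        vals = field[mask]
        assert vals.var() > 2.0 * vals.mean()
        assert (vals == 0).any() and (vals == 10).any()

    def test_rejects_nonpositive_horizon(self):
        cfg = LeadingSignalConfig(scenario="turing")
        with pytest.raises(ValueError):
            generate_turing_field(6, cfg, 0, horizon=0.0)


class TestDiffusiveMeanField:
    def test_ensemble_mean_matches_deterministic_discretization(self):
        """Averaged stochastic trajectories of the secreted leading signal
        match the deterministic rate equations of its production, decay and
        (mass-action) diffusion on the same small dish."""
        from scipy.integrate import solve_ivp

        from stemdish import lattice as lat
        from stemdish.config import EngineParams, SimConfig
        from stemdish.engine import Simulation

        radius = 2
        mask = lat.dish_mask(radius)
        nbr, nnbr = lat.neighbor_table(mask)
        n = mask.size
        lead = LeadingSignalConfig(scenario="diffusive", alpha_sl=50.0,
                                   k_sl=1.0, D_sl=10.0)
        base = lat.empty_dish(radius)
        cells = [(2, 2), (1, 2), (3, 1)]
        for r, c in cells:
            base.occ[r, c] = lattice.S

        checkpoints = np.linspace(0.4, 2.0, 5)
        n_runs = 200
        centre = (mask.shape[1] // 2) * mask.shape[1] + mask.shape[1] // 2
        totals = np.zeros((n_runs, len(checkpoints)))
        at_centre = np.zeros((n_runs, len(checkpoints)))
        for run in range(n_runs):
            cfg = SimConfig(radius=radius, seed=1000 + run, leading=lead,
                            engine=EngineParams(m_s=0.0),
                            diffusion_kinetics="mass_action",
                            division_target=0.0)
            sim = Simulation(cfg, initial_state=base)
            for k, t in enumerate(checkpoints):
                sim.advance(10**9, t_stop=float(t))
                totals[run, k] = sim.sl.sum()
                at_centre[run, k] = sim.sl[centre]

        # deterministic discretization: ds/dt = a 1_cell - k s + D (sum_j s_j - n_i s_i)
        src = np.zeros(n)
        for r, c in cells:
            src[r * mask.shape[1] + c] = lead.alpha_sl

        def rhs(_, s):
            out = src - lead.k_sl * s
            for i in range(n):
                if not mask.ravel()[i]:
                    continue
                acc = 0.0
                for q in range(nnbr[i]):
                    acc += s[nbr[i, q]]
                out[i] += lead.D_sl * (acc - nnbr[i] * s[i])
            return out

        sol = solve_ivp(rhs, (0.0, 2.0), np.zeros(n), t_eval=checkpoints,
                        rtol=1e-8, atol=1e-8)
        expect = sol.y.sum(axis=0)
        mean = totals.mean(axis=0)
        se = totals.std(axis=0) / np.sqrt(n_runs)
        assert np.all(np.abs(mean - expect) <= 3 * np.maximum(se, 1e-9))
        # and the spatial profile at the central source mesh
        mean_c = at_centre.mean(axis=0)
        se_c = at_centre.std(axis=0) / np.sqrt(n_runs)
        assert np.all(np.abs(mean_c - sol.y[centre]) <= 3 * np.maximum(se_c, 1e-9))
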