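import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from confkin import (
    AffinityRatio,
    ApparentRates,
    StatePopulations,
    StateRates,
    apparent_rates,
    bound_populations,
    deconvolve_state_rates,
    koff_from_kd,
)
from confkin.deconv import RateEntry


def _rates(kon, koff):
    sr = StateRates()
    for s in kon:
        sr.kon[s] = RateEntry(kon[s])
        sr.koff[s] = RateEntry(koff[s])
    return sr


class TestBoundPopulations:
    def test_equal_affinities_leave_fractions_unchanged(self):
        pops = StatePopulations(free={"BC": 0.5, "EC": 0.3, "EO": 0.2})
        out = bound_populations(pops, AffinityRatio(1.0))
        assert out.bound == pytest.approx(out.free)

    def test_two_state_enrichment(self):
        pops = StatePopulations(free={"EC": 0.5, "EO": 0.5})
        out = bound_populations(pops, AffinityRatio(1000.0))
        assert out.bound["EO"] == pytest.approx(1000 / 1001)
        assert out.bound["EC"] == pytest.approx(1 / 1001)

    def test_cell_surface_ratio_three_state(self):
        # with the alpha4-type affinity ratio 729, equal free thirds give
        # g_EO = 729/731 and g_BC = g_EC = 1/731
        third = 1.0 / 3.0
        pops = StatePopulations(free={"BC": third, "EC": third, "EO": third})
        out = bound_populations(pops, AffinityRatio(729.0))
        assert out.bound["EO"] == pytest.approx(729 / 731, rel=1e-12)
        assert out.bound["BC"] == pytest.approx(1 / 731, rel=1e-12)
        assert out.bound["EC"] == pytest.approx(1 / 731, rel=1e-12)

    def test_matches_mass_action_equilibrium(self):
        # oracle: saturating-ligand equilibrium of the explicit scheme
        from confkin.synth import ExperimentProtocol, Segment, build_scheme, simulate_protocol

        free = {"EC": 0.5, "EO": 0.5}
        r = 1000.0
        kon = {"EC": 4e5, "EO": 4e5}
        koff = {"EC": 0.1, "EO": 0.1 / r}
        scheme = build_scheme(kon=kon, koff=koff, free_populations=free,
                              exchange_scale=10.0)
        # saturating ligand, run to equilibrium
        prot = ExperimentProtocol(
            segments=[Segment(5000.0, ligand_conc=1e-5, n_points=50)]
        )
        tr = simulate_protocol(scheme, prot)
        assert tr.signal[-1] == pytest.approx(1.0, abs=1e-3)  # near saturation
        out = bound_populations(StatePopulations(free=free), AffinityRatio(r))
        # occupancy-weighted bound split from the simulator
        from confkin.synth import _rate_matrix, _species
        from scipy.linalg import expm as _expm

        a = _rate_matrix(scheme, 1e-5, 0.0)
        sp = _species(scheme)
        y = np.zeros(len(sp))
        y[0] = 0.5
        y[1] = 0.5
        yeq = _expm(a * 1e6) @ y
        bound_idx = {s: i for i, (kind, s) in enumerate(sp) if kind == "bound"}
        total = sum(yeq[i] for i in bound_idx.values())
        for s in free:
            assert out.bound[s] == pytest.approx(yeq[bound_idx[s]] / total, rel=1e-6)

    def test_error_propagation_against_monte_carlo(self):
        # in the linear regime (small relative SD on r) the first-order SD
        # matches a Monte-Carlo draw; near saturation with large SD the
        # delta method is a documented underestimate
        pops = StatePopulations(free={"EC": 0.6, "EO": 0.4})
        out = bound_populations(pops, AffinityRatio(40.0, sd=2.0))
        rng = np.random.default_rng(3)
        rs = rng.normal(40.0, 2.0, 100_000)
        g_eo = 0.4 * rs / (0.6 + 0.4 * rs)
        assert out.bound_sd["EO"] == pytest.approx(g_eo.std(), rel=0.1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="sum"):
            StatePopulations(free={"EC": 0.5, "EO": 0.4})
        with pytest.raises(ValueError, match="> 0"):
            AffinityRatio(0.0)


class TestApparentRates:
    def test_single_state_identity(self):
        pops = bound_populations(
            StatePopulations(free={"EO": 1.0}), AffinityRatio(729.0)
        )
        kon, koff = apparent_rates(pops, _rates({"EO": 1e4}, {"EO": 1e-4}))
        assert (kon, koff) == (1e4, 1e-4)

    def test_two_state_weighted_sum(self):
        pops = bound_populations(
            StatePopulations(free={"EC": 0.5, "EO": 0.5}), AffinityRatio(1000.0)
        )
        kon, koff = apparent_rates(
            pops, _rates({"EC": 4e5, "EO": 1e4}, {"EC": 2.5, "EO": 1e-4})
        )
        assert kon == pytest.approx(2.05e5)
        assert koff == pytest.approx((1000 * 1e-4 + 2.5) / 1001, rel=1e-12)

    def test_missing_state_rate_reported(self):
        pops = bound_populations(
            StatePopulations(free={"EC": 0.5, "EO": 0.5}), AffinityRatio(10.0)
        )
        with pytest.raises(ValueError, match="'EC'"):
            apparent_rates(pops, _rates({"EO": 1e4}, {"EO": 1e-4}))

    def test_apparent_kon_matches_fast_exchange_simulation(self):
        # ODE oracle: global 1:1 fit of a fast-exchange two-state simulation
        # recovers the free-fraction-weighted on-rate within 2%
        from confkin import LangmuirGlobal
        from confkin.synth import ExperimentProtocol, Segment, build_scheme, simulate_protocol

        free = {"EC": 0.5, "EO": 0.5}
        kon = {"EC": 4e5, "EO": 1e4}
        koff = {"EC": 0.05, "EO": 1e-4}
        scheme = build_scheme(kon=kon, koff=koff, free_populations=free,
                              exchange_scale=100.0)
        traces = []
        for c in (2e-8, 5e-8, 1e-7):
            prot = ExperimentProtocol(
                segments=[
                    Segment(400.0, ligand_conc=c, n_points=150),
                    Segment(400.0, ligand_conc=c, competitor=True, n_points=150),
                ]
            )
            traces.append(simulate_protocol(scheme, prot))
        fit = LangmuirGlobal(traces).fit()
        assert fit.kon_app == pytest.approx(2.05e5, rel=0.02)


class TestDeconvolve:
    def _forward(self, kon, koff, pops_free, r):
        pops = bound_populations(StatePopulations(free=pops_free), AffinityRatio(r))
        return apparent_rates(pops, _rates(kon, koff))

    def test_two_state_exact_inverse(self):
        kon = {"EC": 4e5, "EO": 1e4}
        koff = {"EC": 0.05, "EO": 1e-4}
        free = {"EC": 0.7, "EO": 0.3}
        ka, kf = self._forward(kon, koff, free, 729.0)
        out = deconvolve_state_rates(
            extended=ApparentRates(ka, kf),
            eo_rates=ApparentRates(kon["EO"], koff["EO"]),
            pops_extended=StatePopulations(free=free),
            ratio=AffinityRatio(729.0),
        )
        assert out.kon["EC"].value == pytest.approx(kon["EC"], rel=1e-12)
        assert out.koff["EC"].value == pytest.approx(koff["EC"], rel=1e-12)

    def test_homogeneous_ensemble_returns_shared_rate(self):
        out = deconvolve_state_rates(
            extended=ApparentRates(1e4, 1e-4),
            eo_rates=ApparentRates(1e4, 1e-4),
            pops_extended=StatePopulations(free={"EC": 0.4, "EO": 0.6}),
            ratio=AffinityRatio(1.0),
        )
        assert out.kon["EC"].value == pytest.approx(1e4, rel=1e-12)
        assert out.koff["EC"].value == pytest.approx(1e-4, rel=1e-12)

    def test_three_state_round_trip(self):
        kon = {"BC": 5e5, "EC": 2.5e5, "EO": 2e4}
        koff = {"BC": 0.08, "EC": 0.04, "EO": 4e-4}
        r = 8.0
        free_ext = {"EC": 0.6, "EO": 0.4}
        free_bas = {"BC": 0.5, "EC": 0.3, "EO": 0.2}
        ext = self._forward(kon, koff, free_ext, r)
        bas = self._forward(kon, koff, free_bas, r)
        out = deconvolve_state_rates(
            extended=ApparentRates(*ext),
            eo_rates=ApparentRates(kon["EO"], koff["EO"]),
            pops_extended=StatePopulations(free=free_ext),
            ratio=AffinityRatio(r),
            basal=ApparentRates(*bas),
            pops_basal=StatePopulations(free=free_bas),
        )
        for s in ("BC", "EC", "EO"):
            assert out.kon[s].value == pytest.approx(kon[s], rel=1e-10)
            assert out.koff[s].value == pytest.approx(koff[s], rel=1e-10)
        assert not out.flags

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        kon_ec=st.floats(1e4, 1e7),
        kon_ratio=st.floats(1.5, 100.0),
        koff_ec=st.floats(1e-3, 10.0),
        r=st.floats(2.0, 5000.0),
        f_eo=st.floats(0.01, 0.99),
        f_bc=st.floats(0.01, 0.9),
    )
    def test_identity_property(self, kon_ec, kon_ratio, koff_ec, r, f_eo, f_bc):
        """apparent_rates then deconvolve recovers the generating rates."""
        kon = {"BC": kon_ec, "EC": kon_ec, "EO": kon_ec / kon_ratio}
        koff = {"BC": koff_ec, "EC": koff_ec, "EO": koff_ec * kon[
            "EO"] / (kon_ec * r)}
        free_ext = {"EC": 1 - f_eo, "EO": f_eo}
        rest = 1 - f_bc
        free_bas = {"BC": f_bc, "EC": rest * (1 - f_eo), "EO": rest * f_eo}
        ext = self._forward(kon, koff, free_ext, r)
        bas = self._forward(kon, koff, free_bas, r)
        out = deconvolve_state_rates(
            extended=ApparentRates(*ext),
            eo_rates=ApparentRates(kon["EO"], koff["EO"]),
            pops_extended=StatePopulations(free=free_ext),
            ratio=AffinityRatio(r),
            basal=ApparentRates(*bas),
            pops_basal=StatePopulations(free=free_bas),
        )
        for s in ("BC", "EC"):
            assert out.kon[s].value == pytest.approx(kon[s], rel=1e-9)
            assert out.koff[s].value == pytest.approx(koff[s], rel=1e-9)

    def test_kon_app_is_convex_combination(self):
        kon = {"EC": 4e5, "EO": 1e4}
        koff = {"EC": 0.05, "EO": 1e-4}
        for f_eo in (0.1, 0.5, 0.9):
            ka, _ = self._forward(kon, koff, {"EC": 1 - f_eo, "EO": f_eo}, 100.0)
            assert min(kon.values()) <= ka <= max(kon.values())

    def test_infeasible_rates_flagged(self):
        out = deconvolve_state_rates(
            extended=ApparentRates(5e3, 1e-4),  # below the EO contribution
            eo_rates=ApparentRates(1e4, 1e-4),
            pops_extended=StatePopulations(free={"EC": 0.2, "EO": 0.8}),
            ratio=AffinityRatio(100.0),
        )
        assert any("infeasible" in f for f in out.flags)

    def test_zero_population_unidentifiable(self):
        with pytest.raises(ValueError, match="no EC population"):
            deconvolve_state_rates(
                extended=ApparentRates(1e5, 1e-3),
                eo_rates=ApparentRates(1e4, 1e-4),
                pops_extended=StatePopulations(free={"EO": 1.0}),
                ratio=AffinityRatio(100.0),
            )

    def test_se_propagation_cross_checked_by_monte_carlo(self):
        kon = {"EC": 4e5, "EO": 1e4}
        koff = {"EC": 0.05, "EO": 1e-4}
        free = {"EC": 0.7, "EO": 0.3}
        ka, kf = self._forward(kon, koff, free, 729.0)
        out = deconvolve_state_rates(
            extended=ApparentRates(ka, kf, kon_se=0.05 * ka, koff_se=0.05 * kf),
            eo_rates=ApparentRates(1e4, 1e-4, kon_se=500.0, koff_se=5e-6),
            pops_extended=StatePopulations(free=free),
            ratio=AffinityRatio(729.0),
            monte_carlo_check=20_000,
            seed=17,
        )
        dev = [f for f in out.flags if f.startswith("mc_se_check")]
        assert dev, "Monte-Carlo cross-check did not run"
        assert float(dev[0].split("=")[1]) < 0.05


class TestKoffFromKd:
    def test_direct_product(self):
        out = koff_from_kd(1e-8, 1e5)
        assert out.value == pytest.approx(1e-3)
        assert out.se == 0.0
        assert out.provenance == "Kd*kon"

    def test_quadrature_se(self):
        out = koff_from_kd(2e-8, 2e5, kd_sd=0.5e-8, kon_se=0.2e5)
        assert out.value == pytest.approx(4e-3)
        assert out.se == pytest.approx(4e-3 * np.sqrt(0.0625 + 0.01), rel=1e-12)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(23)
        draws = rng.normal(2e-8, 0.2e-8, 100_000) * rng.normal(2e5, 1e4, 100_000)
        out = koff_from_kd(2e-8, 2e5, kd_sd=0.2e-8, kon_se=1e4)
        assert out.se == pytest.approx(draws.std(), rel=0.03)

    def test_positivity_required(self):
        with pytest.raises(ValueError):
            koff_from_kd(0.0, 1e5)
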