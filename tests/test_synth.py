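import numpy as np
import pytest

from confkin import (
    ExperimentProtocol,
    LangmuirGlobal,
    PARAM_SETS,
    Segment,
    TrapFab,
    build_scheme,
    eval_1v1,
    simulate_protocol,
    synth_bundle,
)
from confkin.synth import _rate_matrix, _species


class TestBuildScheme:
    def test_single_state_has_no_exchange(self):
        scheme = build_scheme(kon={"EO": 1e5}, koff={"EO": 0.01})
        assert scheme.states == ("EO",)
        assert not scheme.exchange

    def test_bound_equilibrium_scaled_by_affinity_ratio(self):
        # free K(EC<->EO) = 1; Ka_EO/Ka_EC = 1000 => bound K' = 1000
        scheme = build_scheme(
            kon={"EC": 4e5, "EO": 4e5},
            koff={"EC": 0.1, "EO": 1e-4},
            free_populations={"EC": 0.5, "EO": 0.5},
            exchange_scale=10.0,
        )
        kf, kr = scheme.exchange[("EC", "EO")]
        bf, br = scheme.bound_exchange[("EC", "EO")]
        assert (bf / br) / (kf / kr) == pytest.approx(1000.0, rel=1e-12)

    @pytest.mark.parametrize("split", ["forward", "sqrt"])
    def test_cycle_closure_for_any_split(self, split):
        scheme = build_scheme(
            kon={"BC": 4e5, "EC": 4e5, "EO": 2e4},
            koff={"BC": 0.12, "EC": 0.12, "EO": 8.23e-6},
            free_populations={"BC": 0.9, "EC": 0.093, "EO": 0.007},
            exchange_scale=50.0,
            bound_split=split,
        )
        assert scheme.cycle_residual() < 1e-12
        scheme.check_detailed_balance()

    def test_violating_exchange_rates_rejected(self):
        with pytest.raises(ValueError, match="detailed balance"):
            build_scheme(
                kon={"BC": 1e5, "EC": 1e5, "EO": 1e5},
                koff={"BC": 0.1, "EC": 0.1, "EO": 0.1},
                exchange_rates={
                    ("BC", "EC"): (1.0, 1.0),
                    ("BC", "EO"): (1.0, 1.0),
                    ("EC", "EO"): (5.0, 1.0),  # breaks the cycle
                },
            )

    def test_equilibrium_populations_recovered(self):
        free = {"BC": 0.6, "EC": 0.3, "EO": 0.1}
        scheme = build_scheme(
            kon={s: 1e5 for s in free},
            koff={s: 0.1 for s in free},
            free_populations=free,
            exchange_scale=5.0,
        )
        pops = scheme.free_equilibrium_populations()
        for s, f in free.items():
            assert pops.free[s] == pytest.approx(f, rel=1e-10)


class TestSimulateProtocol:
    def test_single_state_matches_analytic_curve(self):
        scheme = build_scheme(kon={"EO": 1e5}, koff={"EO": 0.01})
        prot = ExperimentProtocol(
            segments=[
                Segment(300.0, ligand_conc=1e-7, n_points=100),
                Segment(300.0, ligand_conc=1e-7, competitor=True, n_points=101),
            ]
        )
        for method in ("expm", "ode"):
            tr = simulate_protocol(scheme, prot, method=method)
            expected = eval_1v1(1e5, 0.01, 1.0, 1e-7, tr.t_dis, tr.times)
            np.testing.assert_allclose(tr.signal, expected, rtol=1e-8,
                                       atol=1e-8 * expected.max())

    def test_zero_ligand_gives_flat_zero(self):
        scheme = build_scheme(
            kon={"EC": 4e5, "EO": 1e4},
            koff={"EC": 0.05, "EO": 1e-4},
            free_populations={"EC": 0.5, "EO": 0.5},
            exchange_scale=10.0,
        )
        prot = ExperimentProtocol(segments=[Segment(100.0, ligand_conc=0.0)])
        tr = simulate_protocol(scheme, prot)
        np.testing.assert_allclose(tr.signal, 0.0, atol=1e-14)

    def test_species_conservation(self):
        scheme = build_scheme(
            kon={"BC": 4e5, "EC": 4e5, "EO": 2e4},
            koff={"BC": 0.12, "EC": 0.12, "EO": 8.23e-6},
            free_populations={"BC": 0.9, "EC": 0.093, "EO": 0.007},
            exchange_scale=50.0,
            trap=TrapFab(kon=1e6, koff=1e-4),
        )
        # rate matrix columns sum to zero => total mass conserved
        a = _rate_matrix(scheme, 2e-8, 1e-6)
        assert np.max(np.abs(a.sum(axis=0))) < 1e-12
        from scipy.linalg import expm

        sp = _species(scheme)
        y0 = np.zeros(len(sp))
        y0[0] = 1.0
        for t in (0.1, 10.0, 1000.0):
            y = expm(a * t) @ y0
            assert y.sum() == pytest.approx(1.0, rel=1e-10)

    def test_equilibrium_occupancy_matches_apparent_kd(self):
        # long association reaches [A]/([A] + koffapp/konapp) in fast exchange
        from confkin import AffinityRatio, StatePopulations, apparent_rates, bound_populations
        from confkin.deconv import RateEntry, StateRates

        free = {"EC": 0.5, "EO": 0.5}
        kon = {"EC": 4e5, "EO": 1e4}
        koff = {"EC": 0.05, "EO": 1e-4}
        r = (kon["EO"] / koff["EO"]) / (kon["EC"] / koff["EC"])
        scheme = build_scheme(kon=kon, koff=koff, free_populations=free,
                              exchange_scale=100.0)
        rates = StateRates()
        for s in free:
            rates.kon[s] = RateEntry(kon[s])
            rates.koff[s] = RateEntry(koff[s])
        pops = bound_populations(StatePopulations(free=free), AffinityRatio(r))
        kon_app, koff_app = apparent_rates(pops, rates)
        conc = 5e-8
        prot = ExperimentProtocol(
            segments=[Segment(20_000.0, ligand_conc=conc, n_points=60)]
        )
        tr = simulate_protocol(scheme, prot)
        expected = conc / (conc + koff_app / kon_app)
        assert tr.signal[-1] == pytest.approx(expected, rel=0.01)

    def test_slow_exchange_breaks_single_exponential_fit(self):
        # detectable failure mode: residuals far above the noise floor
        free = {"EC": 0.5, "EO": 0.5}
        scheme = build_scheme(
            kon={"EC": 4e5, "EO": 1e4},
            koff={"EC": 0.05, "EO": 1e-4},
            free_populations=free,
            exchange_scale=1e-4,
        )
        noise = 0.002
        traces = []
        for i, c in enumerate((2e-8, 5e-8, 1e-7)):
            prot = ExperimentProtocol(
                segments=[
                    Segment(400.0, ligand_conc=c, n_points=150),
                    Segment(400.0, ligand_conc=c, competitor=True, n_points=150),
                ],
                noise_sd=noise,
                seed=100 + i,
            )
            traces.append(simulate_protocol(scheme, prot))
        fit = LangmuirGlobal(traces).fit()
        rms = np.sqrt(fit.rss / fit.n_points)
        assert rms > 5 * noise

    def test_noise_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            ExperimentProtocol(
                segments=[Segment(10.0, ligand_conc=1e-8)], noise_sd=0.1
            )


class TestSynthBundle:
    def test_deterministic_regeneration(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        synth_bundle("alpha4_flow", seed=7).write(d1)
        synth_bundle("alpha4_flow", seed=7).write(d2)
        for name in ("traces.csv", "series.csv", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
        assert (
            synth_bundle("alpha4_flow", seed=8).sample_traces["basal"][0].signal[5]
            != synth_bundle("alpha4_flow", seed=7).sample_traces["basal"][0].signal[5]
        )

    def test_truth_apparent_rates_match_noiseless_fits(self):
        # end-to-end oracle: population-weighted truth vs global 1:1 fits
        from confkin import subtract_background_flow

        bundle = synth_bundle("alpha4_flow", seed=0, noise=False)
        for label in ("basal", "extended", "open"):
            traces = [
                subtract_background_flow(t, bundle.background_traces)
                for t in bundle.sample_traces[label]
            ]
            fit = LangmuirGlobal(traces).fit()
            truth = bundle.truth["apparent"][label]
            assert fit.kon_app == pytest.approx(truth["kon_app"], rel=0.02)
            assert fit.koff_app == pytest.approx(truth["koff_app"], rel=0.02)

    def test_trap_sub_bundle_bounded_by_closed_off_rate(self):
        from confkin import TrapDissociation, TrapSeries

        bundle = synth_bundle(
            "alpha4_flow", seed=0, noise=False, ensembles=("basal",)
        )
        series = [
            TrapSeries(fab_conc=f, trace=tr.dissociation_phase())
            for f, tr in bundle.trap_series
        ]
        fit = TrapDissociation(series, mode="flow_global").fit()
        koff_c = bundle.truth["trap"]["koff_C_true"]
        assert np.all(fit.koff_app <= koff_c * 1.001)
        assert np.all(np.diff(fit.koff_app) > -1e-4)  # monotone within jitter

    def test_bli_bundle_reference_traces_present(self):
        bundle = synth_bundle("alpha5_bli", seed=4, ensembles=("open",),
                              trap_ensemble=None)
        assert bundle.reference_traces["open"]
        assert not bundle.background_traces
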