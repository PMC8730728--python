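"""Population-weighted deconvolution of per-state rates.

Under fast conformational exchange the apparent rate constants of a
Fab-defined ensemble are population-weighted averages of the intrinsic
per-state rates: on-rates are weighted by the *free* state fractions
(binding flux out of the unbound pool) and off-rates by the *saturably
ligand-bound* fractions (release flux out of the bound pool)::

    kon_app  = sum_S f_S * kon_S
    koff_app = sum_S g_S * koff_S

The bound fractions follow from the free fractions and the intrinsic
affinity ratio r = Ka_EO / Ka_closed (the two closed states share one
intrinsic affinity): at ligand saturation ``g_S ~ f_S * Ka_S`` renormalized
over the states present.  Inverting the weighted sums state by state —
extended ensemble (EC+EO) gives EC once EO is measured directly; the basal
ensemble (BC+EC+EO) then gives BC — recovers the intrinsic rates of the
closed states.  SEs are propagated first order (delta method, independent
inputs) with an optional seeded Monte-Carlo cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._uncertainty import central_gradient, monte_carlo_se, ratio_se

__all__ = [
    "STATES",
    "StatePopulations",
    "AffinityRatio",
    "ApparentRates",
    "RateEntry",
    "StateRates",
    "bound_populations",
    "apparent_rates",
    "deconvolve_state_rates",
    "koff_from_kd",
]

STATES = ("BC", "EC", "EO")
_SUM_TOL = 1e-9


@dataclass
class StatePopulations:
    """Free and (optionally) ligand-bound conformational-state fractions.

    Fractions over the states present must each sum to 1; absent states are
    exactly 0.  SDs are optional and treated as exact (0) when omitted.
    """

    free: Mapping[str, float]
    bound: Mapping[str, float] | None = None
    free_sd: Mapping[str, float] | None = None
    bound_sd: Mapping[str, float] | None = None
    ensemble_label: str = ""

    def __post_init__(self) -> None:
        self.free = {s: float(v) for s, v in self.free.items()}
        unknown = set(self.free) - set(STATES)
        if unknown:
            raise ValueError(f"unknown states: {sorted(unknown)}")
        _check_fractions(self.free, "free")
        if self.bound is not None:
            self.bound = {s: float(v) for s, v in self.bound.items()}
            if set(self.bound) != set(self.free):
                raise ValueError("bound fractions must cover the same states as free")
            _check_fractions(self.bound, "bound")

    @property
    def states_present(self) -> tuple[str, ...]:
        return tuple(s for s in STATES if s in self.free)


def _check_fractions(frac: Mapping[str, float], label: str) -> None:
    vals = np.array(list(frac.values()))
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError(f"{label} fractions must lie in [0, 1]")
    total = vals.sum()
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"{label} fractions sum to {total!r}, expected 1")


@dataclass(frozen=True)
class AffinityRatio:
    """Intrinsic affinity ratio r = Ka_EO / Ka_closed (Ka_BC = Ka_EC)."""

    r: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("affinity ratio must be > 0")
        if self.sd < 0:
            raise ValueError("affinity-ratio SD must be >= 0")


@dataclass(frozen=True)
class ApparentRates:
    """One ensemble's apparent (kon, koff) with SEs."""

    kon: float  # 1/(M s)
    koff: float  # 1/s
    kon_se: float = 0.0
    koff_se: float = 0.0

    @classmethod
    def from_fit(cls, fit) -> "ApparentRates":
        """Build from a :class:`~confkin.langmuir.LangmuirGlobalResults`."""
        return cls(fit.kon_app, fit.koff_app, fit.kon_app_se, fit.koff_app_se)


@dataclass
class RateEntry:
    value: float
    se: float = 0.0
    provenance: str = "measured"  # measured | deconvolved | Kd*kon


@dataclass
class StateRates:
    """Per-state intrinsic kon/koff (and derived Kd) with provenance tags."""

    kon: dict[str, RateEntry] = field(default_factory=dict)
    koff: dict[str, RateEntry] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def kd(self, state: str) -> RateEntry:
        kon, koff = self.kon[state], self.koff[state]
        se = (
            0.0
            if kon.se == 0 and koff.se == 0
            else ratio_se(koff.value, koff.se, kon.value, kon.se)
        )
        return RateEntry(
            koff.value / kon.value, se, f"{koff.provenance}/{kon.provenance}"
        )

    def summary(self) -> str:
        lines = [
            "Intrinsic per-state ligand-binding kinetics",
            f"  {'state':5s} {'kon (1/M/s)':>14s} {'koff (1/s)':>14s} "
            f"{'koff (1e-3/s)':>14s} {'Kd (M)':>12s}  provenance",
        ]
        for s in STATES:
            if s not in self.kon:
                continue
            kon, koff = self.kon[s], self.koff[s]
            kd = self.kd(s)
            lines.append(
                f"  {s:5s} {kon.value:14.4g} {koff.value:14.4g} "
                f"{koff.value * 1e3:14.4g} {kd.value:12.4g}  "
                f"kon:{kon.provenance} koff:{koff.provenance}"
            )
            lines.append(
                f"  {'':5s} {'+/- ' + format(kon.se, '.2g'):>14s} "
                f"{'+/- ' + format(koff.se, '.2g'):>14s}"
            )
        if self.flags:
            lines.append(f"  flags: {', '.join(self.flags)}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# operations


def _bound_from_free(free_vals: np.ndarray, states: Sequence[str], r: float) -> np.ndarray:
    ka = np.array([r if s == "EO" else 1.0 for s in states])
    w = free_vals * ka
    return w / w.sum()


def bound_populations(
    free: StatePopulations, ratio: AffinityRatio
) -> StatePopulations:
    """Fill in saturably ligand-bound fractions from free fractions and r.

    At ligand saturation each state's bound fraction is proportional to its
    free fraction times its intrinsic association constant (closed states
    Ka = 1, EO Ka = r), renormalized over the states present.  SDs, when
    present on the free fractions or on r, are propagated first order by
    numeric differentiation.
    """
    states = free.states_present
    fvals = np.array([free.free[s] for s in states])
    if fvals.sum() == 0:
        raise ValueError("all free fractions are zero")
    g = _bound_from_free(fvals, states, ratio.r)
    bound = {s: float(v) for s, v in zip(states, g)}

    bound_sd = None
    have_sd = ratio.sd > 0 or (
        free.free_sd is not None and any(v > 0 for v in free.free_sd.values())
    )
    if have_sd:
        f_sd = np.array(
            [0.0 if free.free_sd is None else free.free_sd.get(s, 0.0) for s in states]
        )
        x0 = np.concatenate((fvals, [ratio.r]))
        sds = np.concatenate((f_sd, [ratio.sd]))
        bound_sd = {}
        for i, s in enumerate(states):
            gfun = lambda x, i=i: _bound_from_free(x[:-1], states, x[-1])[i]
            grad = central_gradient(gfun, x0)
            bound_sd[s] = float(np.sqrt(np.sum((grad * sds) ** 2)))
    return StatePopulations(
        free=dict(free.free),
        bound=bound,
        free_sd=free.free_sd,
        bound_sd=bound_sd,
        ensemble_label=free.ensemble_label,
    )


def apparent_rates(pops: StatePopulations, rates: StateRates) -> tuple[float, float]:
    """Population-weighted apparent (kon_app, koff_app) of an ensemble.

    On-rates are weighted by free fractions, off-rates by bound fractions
    (which must already be filled in, e.g. via :func:`bound_populations`).
    """
    if pops.bound is None:
        raise ValueError("bound fractions missing; call bound_populations first")
    kon_app = 0.0
    koff_app = 0.0
    for s in pops.states_present:
        if s not in rates.kon or s not in rates.koff:
            raise ValueError(f"no intrinsic rates supplied for state {s!r}")
        kon_app += pops.free[s] * rates.kon[s].value
        koff_app += pops.bound[s] * rates.koff[s].value
    return kon_app, koff_app


def _deconv_core(x: np.ndarray, have_basal: bool) -> np.ndarray:
    """Map inputs -> (kon_EC, koff_EC[, kon_BC, koff_BC]).

    x = [kon_ext, koff_ext, kon_eo, koff_eo, r, f_ext(EC), f_ext(EO),
         (kon_bas, koff_bas, f_bas(BC), f_bas(EC), f_bas(EO))]
    """
    kon_ext, koff_ext, kon_eo, koff_eo, r, fe_ec, fe_eo = x[:7]
    g = _bound_from_free(np.array([fe_ec, fe_eo]), ("EC", "EO"), r)
    kon_ec = (kon_ext - fe_eo * kon_eo) / fe_ec
    koff_ec = (koff_ext - g[1] * koff_eo) / g[0]
    if not have_basal:
        return np.array([kon_ec, koff_ec])
    kon_bas, koff_bas, fb_bc, fb_ec, fb_eo = x[7:]
    gb = _bound_from_free(np.array([fb_bc, fb_ec, fb_eo]), ("BC", "EC", "EO"), r)
    kon_bc = (kon_bas - fb_ec * kon_ec - fb_eo * kon_eo) / fb_bc
    koff_bc = (koff_bas - gb[1] * koff_ec - gb[2] * koff_eo) / gb[0]
    return np.array([kon_ec, koff_ec, kon_bc, koff_bc])


def deconvolve_state_rates(
    extended: ApparentRates,
    eo_rates: ApparentRates,
    pops_extended: StatePopulations,
    ratio: AffinityRatio,
    basal: ApparentRates | None = None,
    pops_basal: StatePopulations | None = None,
    include_population_error: bool = False,
    monte_carlo_check: int = 0,
    seed: int = 0,
) -> StateRates:
    """Recover intrinsic EC (and BC) rates from ensemble apparent rates.

    EC rates come from the extended (EC+EO) ensemble given directly
    measured EO rates; BC rates then come from the basal (BC+EC+EO)
    ensemble given EC and EO.  Off-rate weights use the saturably-bound
    fractions derived from the free fractions and the affinity ratio.

    SEs are propagated first order treating inputs as independent; by
    default only the rate SEs enter.  ``include_population_error`` also
    propagates the affinity-ratio SD and any free-fraction SDs.
    ``monte_carlo_check > 0`` recomputes every SE by that many seeded
    Gaussian draws and records the worst delta-vs-MC discrepancy in the
    flags.  Negative deconvolved rates are returned as-is with an
    ``infeasible`` flag.
    """
    if eo_rates.kon <= 0 or eo_rates.koff <= 0:
        raise ValueError("EO rates must be positive")
    if "EC" not in pops_extended.free or pops_extended.free["EC"] == 0:
        raise ValueError("extended ensemble has no EC population; unidentifiable")
    have_basal = basal is not None
    if have_basal:
        if pops_basal is None:
            raise ValueError("pops_basal required when basal apparent rates given")
        if "BC" not in pops_basal.free or pops_basal.free["BC"] == 0:
            raise ValueError("basal ensemble has no BC population; unidentifiable")

    x = [
        extended.kon,
        extended.koff,
        eo_rates.kon,
        eo_rates.koff,
        ratio.r,
        pops_extended.free["EC"],
        pops_extended.free["EO"],
    ]
    sds = [
        extended.kon_se,
        extended.koff_se,
        eo_rates.kon_se,
        eo_rates.koff_se,
        ratio.sd if include_population_error else 0.0,
        _frac_sd(pops_extended, "EC") if include_population_error else 0.0,
        _frac_sd(pops_extended, "EO") if include_population_error else 0.0,
    ]
    if have_basal:
        x += [
            basal.kon,
            basal.koff,
            pops_basal.free["BC"],
            pops_basal.free["EC"],
            pops_basal.free["EO"],
        ]
        sds += [
            basal.kon_se,
            basal.koff_se,
        ] + [
            _frac_sd(pops_basal, s) if include_population_error else 0.0
            for s in ("BC", "EC", "EO")
        ]
    x = np.asarray(x, dtype=float)
    sds = np.asarray(sds, dtype=float)

    vals = _deconv_core(x, have_basal)
    names = ["kon_EC", "koff_EC"] + (["kon_BC", "koff_BC"] if have_basal else [])
    ses = np.empty_like(vals)
    for i in range(vals.size):
        grad = central_gradient(lambda z, i=i: _deconv_core(z, have_basal)[i], x)
        ses[i] = np.sqrt(np.sum((grad * sds) ** 2))

    out = StateRates()
    out.kon["EO"] = RateEntry(eo_rates.kon, eo_rates.kon_se, "measured")
    out.koff["EO"] = RateEntry(eo_rates.koff, eo_rates.koff_se, "measured")
    out.kon["EC"] = RateEntry(float(vals[0]), float(ses[0]), "deconvolved")
    out.koff["EC"] = RateEntry(float(vals[1]), float(ses[1]), "deconvolved")
    if have_basal:
        out.kon["BC"] = RateEntry(float(vals[2]), float(ses[2]), "deconvolved")
        out.koff["BC"] = RateEntry(float(vals[3]), float(ses[3]), "deconvolved")
    if np.any(vals <= 0):
        bad = [n for n, v in zip(names, vals) if v <= 0]
        out.flags.append(f"infeasible: non-positive deconvolved {', '.join(bad)}")

    if monte_carlo_check > 0 and np.any(sds > 0):
        worst = 0.0
        for i in range(vals.size):
            mc = monte_carlo_se(
                lambda z, i=i: _deconv_core(z, have_basal)[i],
                x,
                sds,
                n_draws=monte_carlo_check,
                rng=seed,
            )
            if ses[i] > 0:
                worst = max(worst, abs(mc - ses[i]) / ses[i])
        out.flags.append(f"mc_se_check_max_rel_dev={worst:.3g}")
    return out


def _frac_sd(pops: StatePopulations, state: str) -> float:
    if pops.free_sd is None:
        return 0.0
    return float(pops.free_sd.get(state, 0.0))


def koff_from_kd(
    kd: float, kon: float, kd_sd: float = 0.0, kon_se: float = 0.0
) -> RateEntry:
    """koff = Kd * kon with relative errors combined in quadrature.

    The equilibrium-route off-rate used to cross-check deconvolved values.
    """
    if kd <= 0 or kon <= 0:
        raise ValueError("Kd and kon must be positive")
    koff = kd * kon
    if kd_sd == 0 and kon_se == 0:
        se = 0.0
    else:
        se = koff * float(np.sqrt((kd_sd / kd) ** 2 + (kon_se / kon) ** 2))
    return RateEntry(koff, se, "Kd*kon")
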