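"""Global 1:1 Langmuir fitting of association/dissociation traces.

The observable follows the piecewise pseudo-first-order solution of
``dR/dt = kon*[A]*(Rmax - R) - koff*R``::

    R(t) = Req * (1 - exp(-(koff + kon*[A]) * t))            t <= t_D
    R(t) = R(t_D) * exp(-koff * (t - t_D))                   t >  t_D

with ``Req = Rmax * kon*[A] / (koff + kon*[A])`` and ``t_D`` the time
dissociation is initiated (a large excess of unlabeled competitor, or a
ligand-free well, suppresses rebinding, so the free-ligand term vanishes
after ``t_D``).  :class:`LangmuirGlobal` fits ``kon`` and ``koff`` shared
across all analyte concentrations with one ``Rmax`` per trace — a global
fit pools the concentration dependence into a single pair of apparent rate
constants and exposes deviations from 1:1 behaviour as lack of fit.

Rates are optimized on a log scale (positivity without constraints) from a
fixed 3x3 multi-start grid so the fit is deterministic; SEs come from the
Gauss-Newton covariance at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from ._uncertainty import ratio_se
from .doseresponse import DoseResponse, DoseResponseResults
from .traces import KineticTrace

__all__ = [
    "eval_1v1",
    "LangmuirGlobal",
    "LangmuirGlobalResults",
    "RatioReport",
    "equilibrium_kd",
    "kd_consistency",
]

#: Fixed multi-start grid for the shared rate constants.
START_GRID_KON = (1e4, 1e5, 1e6)  # 1/(M s)
START_GRID_KOFF = (1e-4, 1e-2, 1.0)  # 1/s

_LN10 = np.log(10.0)


def eval_1v1(
    kon: float,
    koff: float,
    rmax: float,
    conc: float,
    t_dis: float | None,
    times,
) -> np.ndarray:
    """Evaluate the piecewise 1:1 Langmuir association/dissociation curve.

    Parameters are the on-rate (1/(M s)), off-rate (1/s), maximum response
    (signal units), analyte concentration (molar), dissociation start time
    (seconds, ``None`` for association only) and the evaluation times
    (seconds).  The curve is continuous at ``t_dis`` by construction; the
    degenerate case ``koff + kon*conc == 0`` returns an all-zero trace.
    """
    if kon < 0 or koff < 0 or conc < 0:
        raise ValueError("rates and concentration must be non-negative")
    times = np.asarray(times, dtype=float)
    kobs = koff + kon * conc
    if kobs == 0.0:
        return np.zeros_like(times)
    req = rmax * kon * conc / kobs
    assoc = req * (1.0 - np.exp(-kobs * times))
    if t_dis is None:
        return assoc
    r_at_td = req * (1.0 - np.exp(-kobs * t_dis))
    dissoc = r_at_td * np.exp(-koff * np.maximum(times - t_dis, 0.0))
    return np.where(times <= t_dis, assoc, dissoc)


@dataclass
class RatioReport:
    """koff_app/kon_app with propagated SE and fold-difference from an
    independently measured equilibrium Kd."""

    ratio: float  # molar
    ratio_se: float
    kd_equilibrium: float
    fold_difference: float
    flags: list[str] = field(default_factory=list)


@dataclass
class LangmuirGlobalResults:
    """Shared apparent rates with per-trace Rmax from a global 1:1 fit."""

    kon_app: float  # 1/(M s)
    koff_app: float  # 1/s
    rmax: np.ndarray  # per trace, signal units
    kon_app_se: float
    koff_app_se: float
    rmax_se: np.ndarray
    rss: float
    n_points: int
    n_params: int
    concs: np.ndarray  # per trace, molar
    model: "LangmuirGlobal" = field(repr=False, default=None)
    start_index: int = 0  # winning point of the fixed multi-start grid
    flags: list[str] = field(default_factory=list)

    @property
    def df_resid(self) -> int:
        return self.n_points - self.n_params

    @property
    def kd_ratio(self) -> float:
        """koff_app / kon_app in molar."""
        return self.koff_app / self.kon_app

    def conf_int(self) -> dict[str, tuple[float, float]]:
        """95% confidence intervals as estimate ± 2·SE."""
        out = {
            "kon_app": (
                self.kon_app - 2 * self.kon_app_se,
                self.kon_app + 2 * self.kon_app_se,
            ),
            "koff_app": (
                self.koff_app - 2 * self.koff_app_se,
                self.koff_app + 2 * self.koff_app_se,
            ),
        }
        for i, (r, se) in enumerate(zip(self.rmax, self.rmax_se)):
            out[f"rmax_{i}"] = (r - 2 * se, r + 2 * se)
        return out

    def predict(self, trace_index: int, times=None) -> np.ndarray:
        tr = self.model.traces[trace_index]
        if times is None:
            times = tr.times
        return eval_1v1(
            self.kon_app,
            self.koff_app,
            float(self.rmax[trace_index]),
            tr.analyte_conc,
            tr.t_dis,
            times,
        )

    @property
    def fittedvalues(self) -> list[np.ndarray]:
        return [self.predict(i) for i in range(len(self.model.traces))]

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Global 1:1 Langmuir fit",
            f"  traces / points : {self.rmax.size} / {self.n_points}",
            f"  kon_app  : {self.kon_app:.4g} 1/(M s)  +/- {self.kon_app_se:.3g}"
            f"   95% CI [{ci['kon_app'][0]:.4g}, {ci['kon_app'][1]:.4g}]",
            f"  koff_app : {self.koff_app:.4g} 1/s      +/- {self.koff_app_se:.3g}"
            f"   95% CI [{ci['koff_app'][0]:.4g}, {ci['koff_app'][1]:.4g}]",
            f"  koff/kon : {self.kd_ratio:.4g} M "
            f"({self.kd_ratio * 1e9:.4g} nM)",
        ]
        for i, (c, r, se) in enumerate(zip(self.concs, self.rmax, self.rmax_se)):
            lines.append(
                f"  Rmax[{c * 1e9:g} nM] : {r:.5g} +/- {se:.3g}"
            )
        lines.append(f"  RSS      : {self.rss:.6g}  (dof {self.df_resid})")
        if self.flags:
            lines.append(f"  flags    : {', '.join(self.flags)}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay data and fits, one color per analyte concentration."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, tr in enumerate(self.model.traces):
            line = ax.plot(
                tr.times, tr.signal, ".", ms=3,
                label=f"{tr.analyte_conc * 1e9:g} nM",
            )[0]
            ax.plot(tr.times, self.predict(i), "-", color=line.get_color())
        ax.set_xlabel("time (s)")
        ax.set_ylabel("response")
        ax.legend()
        return ax


class LangmuirGlobal:
    """Global 1:1 Langmuir model over traces at multiple analyte concentrations.

    Parameters
    ----------
    traces
        Kinetic traces (association or association+dissociation), each with
        ``analyte_conc > 0``.  Replicates at a shared concentration are
        allowed; each trace gets its own Rmax.
    weights
        Optional per-trace scalar weights (e.g. inverse variances).
        Unweighted by default.
    """

    def __init__(
        self,
        traces: Sequence[KineticTrace],
        weights: Sequence[float] | None = None,
    ):
        traces = list(traces)
        if not traces:
            raise ValueError("at least one trace is required")
        for tr in traces:
            if tr.analyte_conc <= 0:
                raise ValueError(
                    f"trace {tr.series_id!r} has analyte_conc <= 0; a positive "
                    "concentration is required for a binding fit"
                )
        self.traces = traces
        if weights is None:
            self.weights = np.ones(len(traces))
        else:
            self.weights = np.asarray(weights, dtype=float)
            if self.weights.shape != (len(traces),):
                raise ValueError("weights must be one scalar per trace")

    # -- internals --------------------------------------------------------

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        log_kon, log_koff = theta[0], theta[1]
        kon, koff = 10.0**log_kon, 10.0**log_koff
        parts = []
        for i, tr in enumerate(self.traces):
            pred = eval_1v1(kon, koff, theta[2 + i], tr.analyte_conc, tr.t_dis, tr.times)
            parts.append(np.sqrt(self.weights[i]) * (pred - tr.signal))
        return np.concatenate(parts)

    def fit(self, xtol: float = 1e-14, ftol: float = 1e-14) -> LangmuirGlobalResults:
        """Multi-start trust-region least squares; best residual wins.

        Raises if there are fewer residual points than parameters, or if no
        start converges (the error carries the best residual seen).
        """
        n_traces = len(self.traces)
        n_params = 2 + n_traces
        n_points = sum(tr.n_points for tr in self.traces)
        if n_points <= n_params:
            raise ValueError(
                f"{n_points} data points cannot constrain {n_params} parameters"
            )

        rmax0 = np.array(
            [max(float(np.max(np.abs(tr.signal))), 1e-6) for tr in self.traces]
        )
        lower = np.concatenate(([-12.0, -12.0], np.full(n_traces, 1e-12)))
        upper = np.concatenate(([12.0, 12.0], np.full(n_traces, np.inf)))

        best = None
        best_idx = -1
        best_cost = np.inf
        idx = 0
        for kon0 in START_GRID_KON:
            for koff0 in START_GRID_KOFF:
                theta0 = np.concatenate(
                    ([np.log10(kon0), np.log10(koff0)], rmax0)
                )
                sol = least_squares(
                    self._residuals,
                    theta0,
                    bounds=(lower, upper),
                    method="trf",
                    xtol=xtol,
                    ftol=ftol,
                    gtol=1e-14,
                    max_nfev=5000,
                )
                improved = best is None or sol.cost < best_cost * (1 - 1e-12)
                if sol.status > 0 and np.isfinite(sol.cost) and improved:
                    best, best_cost, best_idx = sol, sol.cost, idx
                idx += 1
        if best is None:
            raise RuntimeError(
                f"global 1:1 fit failed to converge from any start "
                f"(best residual 2*cost = {2 * best_cost:.6g})"
            )

        kon = float(10.0 ** best.x[0])
        koff = float(10.0 ** best.x[1])
        rmax = np.asarray(best.x[2:], dtype=float)

        flags: list[str] = []
        dof = max(n_points - n_params, 1)
        s2 = 2.0 * best.cost / dof
        jtj = best.jac.T @ best.jac
        try:
            cov_log = np.linalg.inv(jtj) * s2
        except np.linalg.LinAlgError:
            cov_log = np.linalg.pinv(jtj) * s2
            flags.append("singular_covariance")
        se = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
        # rates were fitted on log10 scale: SE(k) = SE(log10 k) * k * ln 10
        kon_se = float(se[0] * kon * _LN10)
        koff_se = float(se[1] * koff * _LN10)
        rmax_se = np.asarray(se[2:], dtype=float)

        return LangmuirGlobalResults(
            kon_app=kon,
            koff_app=koff,
            rmax=rmax,
            kon_app_se=kon_se,
            koff_app_se=koff_se,
            rmax_se=rmax_se,
            rss=float(2.0 * best.cost),
            n_points=n_points,
            n_params=n_params,
            concs=np.array([tr.analyte_conc for tr in self.traces]),
            model=self,
            start_index=best_idx,
            flags=flags,
        )


def equilibrium_kd(
    fit: LangmuirGlobalResults, concs=None
) -> DoseResponseResults:
    """Equilibrium-response dose-response fit as a Kd cross-check.

    For each analyte concentration the equilibrium response is
    reconstructed from the fitted rates at a time 1000-fold longer than the
    binding time, ``t = 1000 / (kon * [A])``::

        Req = Rmax * kon[A]/(koff + kon[A]) * (1 - exp(-(koff + kon[A]) t))

    and the Req points are fitted to ``Req = plateau*[A]/(Kd + [A])`` with
    the baseline fixed at 0.  The fitted half-max concentration is the
    equilibrium Kd.
    """
    if concs is None:
        concs = fit.concs
    concs = np.asarray(concs, dtype=float)
    if np.unique(concs).size < 2:
        raise ValueError("Kd is unidentifiable from a single concentration")
    if concs.shape != fit.concs.shape or not np.allclose(concs, fit.concs):
        raise ValueError("concs must match the fitted traces' concentrations")

    kon, koff = fit.kon_app, fit.koff_app
    t_eq = 1000.0 / (kon * concs)
    kobs = koff + kon * concs
    req = fit.rmax * kon * concs / kobs * (1.0 - np.exp(-kobs * t_eq))

    dr = DoseResponse(concs, req, fix_baseline=0.0).fit()
    if koff == 0.0:
        dr.flags.append("degenerate")  # Req = Rmax everywhere; Kd meaningless
    return dr


def kd_consistency(
    fit: LangmuirGlobalResults,
    kd_equilibrium: float,
    kd_equilibrium_sd: float | None = None,
) -> RatioReport:
    """koff_app/kon_app with propagated SE and fold-difference from an
    equilibrium Kd measurement.

    The SE of the ratio combines the relative errors in quadrature
    (first-order delta method).  An SE on kon at or above kon itself makes
    the propagation unreliable and is flagged.
    """
    flags: list[str] = []
    ratio = fit.koff_app / fit.kon_app
    if fit.kon_app_se >= fit.kon_app:
        flags.append("unreliable_propagation")
    if fit.kon_app_se == 0 and fit.koff_app_se == 0:
        se = 0.0
    else:
        se = ratio_se(fit.koff_app, fit.koff_app_se, fit.kon_app, fit.kon_app_se)
    fold = ratio / kd_equilibrium if kd_equilibrium > 0 else np.inf
    if fold < 1 and fold > 0:
        pass  # fold-difference reported as ratio/Kd_eq; callers may invert
    return RatioReport(
        ratio=ratio,
        ratio_se=se,
        kd_equilibrium=kd_equilibrium,
        fold_difference=fold,
        flags=flags,
    )
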