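"""Closure-trap (mAb13 Fab) dissociation analysis.

Ligand pre-bound to an ensemble dominated by the slowly dissociating
extended-open (EO) state is chased with competitor in the presence of a
closure-stabilizing Fab.  The Fab binds ligand-bound closed states as they
arise from EO•L and prevents reopening, so at saturating Fab every
EO•L -> C•L conversion is followed by ligand release at the closed-state
off-rate.  The observed single-exponential off-rate rises hyperbolically
with Fab concentration to a plateau ``koffmax`` that bounds the
closed-state koff from below (the conversion step can only slow, never
speed, the observed release).

Two fitting modes mirror the two assay formats:

* ``flow_global`` — all Fab concentrations fitted jointly to
  ``MFI(t) = MFI0 * exp(-koff_app * t) + MFI_bg`` with MFI0 and the
  background shared and one koff_app per Fab concentration;
* ``bli_individual`` — each reference-subtracted BLI trace fitted
  separately to ``R(t) = R0 * exp(-koff_app * t)`` (background 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .doseresponse import DoseResponse, DoseResponseResults
from .traces import KineticTrace

__all__ = [
    "TrapSeries",
    "TrapFitResults",
    "TrapDissociation",
    "fit_koffmax_dose_response",
]


@dataclass
class TrapSeries:
    """One dissociation trace at one closure-Fab concentration."""

    fab_conc: float  # molar
    trace: KineticTrace  # dissociation phase, re-zeroed at competitor addition
    koff_app: float | None = None  # 1/s, filled by the fit
    koff_app_se: float | None = None

    def __post_init__(self) -> None:
        if self.fab_conc < 0:
            raise ValueError("Fab concentration must be >= 0")
        if self.trace.n_points < 4:
            raise ValueError("need at least 4 points per dissociation trace")


@dataclass
class TrapFitResults:
    """Per-Fab-concentration off-rates plus shared amplitude parameters."""

    series: list[TrapSeries]
    mode: str
    amplitude: float | np.ndarray  # shared MFI0 (flow) or per-trace R0 (BLI)
    background: float  # shared MFI background (flow); 0 for BLI
    amplitude_se: float | np.ndarray
    background_se: float
    rss: float
    n_points: int
    flags: list[str] = field(default_factory=list)

    @property
    def fab_concs(self) -> np.ndarray:
        return np.array([s.fab_conc for s in self.series])

    @property
    def koff_app(self) -> np.ndarray:
        return np.array([s.koff_app for s in self.series])

    @property
    def koff_app_se(self) -> np.ndarray:
        return np.array([s.koff_app_se for s in self.series])

    def dose_response(self, fix_baseline: float | None = None) -> DoseResponseResults:
        return fit_koffmax_dose_response(
            list(zip(self.fab_concs, self.koff_app, self.koff_app_se)),
            fix_baseline=fix_baseline,
        )

    def summary(self) -> str:
        lines = [f"Closure-trap dissociation fit ({self.mode})"]
        for s in self.series:
            lines.append(
                f"  [Fab] {s.fab_conc * 1e6:8.3g} uM : koff_app = "
                f"{s.koff_app:.5g} +/- {s.koff_app_se:.2g} 1/s"
            )
        if self.mode == "flow_global":
            lines.append(
                f"  shared MFI0 = {self.amplitude:.5g} +/- {self.amplitude_se:.2g}, "
                f"background = {self.background:.5g} +/- {self.background_se:.2g}"
            )
        lines.append(f"  RSS = {self.rss:.6g} over {self.n_points} points")
        if self.flags:
            lines.append(f"  flags: {', '.join(self.flags)}")
        return "\n".join(lines)


class TrapDissociation:
    """Exponential dissociation model across a closure-Fab titration.

    Parameters
    ----------
    series
        One :class:`TrapSeries` per Fab concentration; traces must be
        dissociation-phase only with time re-zeroed at competitor addition.
    mode
        ``flow_global`` (shared MFI0/background) or ``bli_individual``.
    """

    def __init__(
        self,
        series: Sequence[TrapSeries],
        mode: Literal["flow_global", "bli_individual"] = "flow_global",
    ):
        if mode not in ("flow_global", "bli_individual"):
            raise ValueError(f"unknown mode {mode!r}")
        self.series = list(series)
        if not self.series:
            raise ValueError("at least one trap series required")
        self.mode = mode

    def fit(self) -> TrapFitResults:
        if self.mode == "flow_global":
            return self._fit_flow_global()
        return self._fit_bli_individual()

    # -- flow: shared MFI0 and background, one koff per Fab conc ----------

    def _fit_flow_global(self) -> TrapFitResults:
        flags: list[str] = []
        n_ser = len(self.series)
        if n_ser == 1:
            # MFI0 + background + koff against a single decaying trace:
            # the plateau and amplitude trade off against each other.
            flags.append("shared_parameters_unidentifiable")
        times = [s.trace.times for s in self.series]
        signals = [s.trace.signal for s in self.series]
        n_points = sum(t.size for t in times)

        # theta = [MFI0, MFI_bg, log10 koff_1..n]
        sig_all = np.concatenate(signals)
        mfi0_0 = float(np.max(sig_all) - np.min(sig_all)) or 1.0
        bg0 = float(np.min(sig_all))
        k0 = []
        for t, s in zip(times, signals):
            span = s[0] - s[-1]
            frac = max(min((s[0] - bg0) / max(abs(s[0] - bg0), 1e-12), 1.0), 1e-3)
            k0.append(1.0 / max(t[-1], 1e-6))
        theta0 = np.concatenate(([mfi0_0, bg0], np.log10(np.maximum(k0, 1e-6))))

        def resid(theta):
            mfi0, bg = theta[0], theta[1]
            parts = []
            for i in range(n_ser):
                k = 10.0 ** theta[2 + i]
                parts.append(mfi0 * np.exp(-k * times[i]) + bg - signals[i])
            return np.concatenate(parts)

        sol = least_squares(resid, theta0, method="lm", max_nfev=20_000)
        se, s2 = _gauss_newton_se(sol, n_points)
        mfi0, bg = float(sol.x[0]), float(sol.x[1])
        series_out = []
        for i, s in enumerate(self.series):
            k = float(10.0 ** sol.x[2 + i])
            k_se = float(se[2 + i] * k * np.log(10.0))
            series_out.append(replace(s, koff_app=k, koff_app_se=k_se))
        return TrapFitResults(
            series=series_out,
            mode=self.mode,
            amplitude=mfi0,
            background=bg,
            amplitude_se=float(se[0]),
            background_se=float(se[1]),
            rss=float(2.0 * sol.cost),
            n_points=n_points,
            flags=flags,
        )

    # -- BLI: independent (R0, koff) per trace, background 0 --------------

    def _fit_bli_individual(self) -> TrapFitResults:
        series_out = []
        amps, amp_ses = [], []
        rss_total = 0.0
        n_points = 0
        for s in self.series:
            t, y = s.trace.times, s.trace.signal
            n_points += t.size

            def resid(theta, t=t, y=y):
                r0, log_k = theta
                return r0 * np.exp(-(10.0 ** log_k) * t) - y

            span = max(t[-1], 1e-6)
            theta0 = [float(y[0]) or 1.0, np.log10(1.0 / span)]
            sol = least_squares(resid, theta0, method="lm", max_nfev=20_000)
            se, _ = _gauss_newton_se(sol, t.size)
            k = float(10.0 ** sol.x[1])
            series_out.append(
                replace(
                    s,
                    koff_app=k,
                    koff_app_se=float(se[1] * k * np.log(10.0)),
                )
            )
            amps.append(float(sol.x[0]))
            amp_ses.append(float(se[0]))
            rss_total += float(2.0 * sol.cost)
        return TrapFitResults(
            series=series_out,
            mode=self.mode,
            amplitude=np.array(amps),
            background=0.0,
            amplitude_se=np.array(amp_ses),
            background_se=0.0,
            rss=rss_total,
            n_points=n_points,
        )


def _gauss_newton_se(sol, n_points: int) -> tuple[np.ndarray, float]:
    dof = max(n_points - sol.x.size, 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj) * s2
    return np.sqrt(np.maximum(np.diag(cov), 0.0)), s2


def fit_koffmax_dose_response(
    points: Sequence[tuple[float, float, float | None]],
    fix_baseline: float | None = None,
) -> DoseResponseResults:
    """Saturating dose-response fit of koff_app against Fab concentration.

    ``points`` are ``(fab_conc_molar, koff_app, koff_app_se)`` triples; at
    least four distinct Fab concentrations including 0 are required.  Fits
    ``koff_app([Fab]) = baseline + (koffmax - baseline)*[Fab]/(EC50+[Fab])``
    with the baseline free by default (anchored by the no-Fab point) or
    fixed via ``fix_baseline``.  A titration whose off-rate does not
    increase is flagged ``non_saturating``.
    """
    pts = [(float(c), float(k), None if se is None else float(se)) for c, k, se in points]
    concs = np.array([p[0] for p in pts])
    if np.unique(concs).size < 4:
        raise ValueError("need >= 4 distinct Fab concentrations")
    if not np.any(concs == 0):
        raise ValueError("the titration must include a no-Fab (0) point")
    koffs = np.array([p[1] for p in pts])
    ses = np.array([np.nan if p[2] is None else p[2] for p in pts])
    y_se = None if np.any(np.isnan(ses)) else ses
    return DoseResponse(concs, koffs, y_se=y_se, fix_baseline=fix_baseline).fit()
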