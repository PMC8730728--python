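"""Hyperbolic (Hill slope 1) dose-response model.

Fits ``y(x) = baseline + (plateau - baseline) * x / (ec50 + x)``, the
saturation form used both for equilibrium-response Kd estimation (baseline
fixed at 0, ec50 = Kd) and for the closure-trap off-rate titration
(baseline = no-Fab apparent off-rate, plateau = koffmax, ec50 = EC50).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = ["DoseResponse", "DoseResponseResults"]


@dataclass
class DoseResponseResults:
    """Fitted plateau / half-max concentration / baseline with SEs.

    ``conf_int`` bounds are estimate ± 2·SE.  ``flags`` lists fit
    pathologies (``degenerate``: no dose dependence, half-max
    unidentifiable; ``non_saturating``: response not increasing over the
    titration).
    """

    plateau: float
    half_max_conc: float
    baseline: float
    plateau_se: float
    half_max_conc_se: float
    baseline_se: float
    rss: float
    n_points: int
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    flags: list[str] = field(default_factory=list)
    baseline_fixed: bool = False

    @property
    def ec50(self) -> float:
        return self.half_max_conc

    def conf_int(self) -> dict[str, tuple[float, float]]:
        out = {}
        for name in ("plateau", "half_max_conc", "baseline"):
            v = getattr(self, name)
            se = getattr(self, f"{name}_se")
            out[name] = (v - 2 * se, v + 2 * se)
        return out

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.baseline + (self.plateau - self.baseline) * x / (
            self.half_max_conc + x
        )

    def summary(self) -> str:
        lines = [
            "Dose-response fit (Hill slope 1)",
            f"  n points        : {self.n_points}",
            f"  plateau         : {self.plateau:.6g} +/- {self.plateau_se:.3g}",
            f"  half-max conc   : {self.half_max_conc:.6g} +/- "
            f"{self.half_max_conc_se:.3g}",
            f"  baseline        : {self.baseline:.6g} +/- {self.baseline_se:.3g}"
            + ("  (fixed)" if self.baseline_fixed else ""),
            f"  RSS             : {self.rss:.6g}",
        ]
        if self.flags:
            lines.append(f"  flags           : {', '.join(self.flags)}")
        return "\n".join(lines)


class DoseResponse:
    """Saturation dose-response model for (x, y) points.

    Parameters
    ----------
    x : array-like
        Doses (concentration, molar); non-negative.
    y : array-like
        Responses (signal units or 1/s).
    y_se : array-like, optional
        Per-point SEs; used as inverse-variance weights when given.
    fix_baseline : float or None
        Fix the baseline at this value (0 for the equilibrium-Kd use);
        ``None`` fits it freely.
    """

    def __init__(self, x, y, y_se=None, fix_baseline: float | None = None):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if np.any(self.x < 0):
            raise ValueError("doses must be >= 0")
        if np.unique(self.x).size < 2:
            raise ValueError(
                "at least two distinct doses required; half-max concentration "
                "is unidentifiable from a single dose"
            )
        self.y_se = None if y_se is None else np.asarray(y_se, dtype=float)
        self.fix_baseline = fix_baseline

    def fit(self) -> DoseResponseResults:
        x, y = self.x, self.y
        flags: list[str] = []
        free_baseline = self.fix_baseline is None
        base0 = float(y[x == x.min()].mean()) if free_baseline else self.fix_baseline

        spread = np.ptp(y)
        scale = max(abs(y).max(), 1.0)
        if spread <= 1e-12 * scale:
            # No dose dependence at all: plateau = baseline, EC50 meaningless.
            flags.append("degenerate")
            val = float(y.mean())
            return DoseResponseResults(
                plateau=val,
                half_max_conc=np.nan,
                baseline=val if free_baseline else base0,
                plateau_se=float(y.std(ddof=1) / np.sqrt(y.size)) if y.size > 1 else 0.0,
                half_max_conc_se=np.nan,
                baseline_se=0.0,
                rss=float(np.sum((y - val) ** 2)),
                n_points=y.size,
                x=x,
                y=y,
                flags=flags,
                baseline_fixed=not free_baseline,
            )

        # order-of-magnitude starts: plateau from the top dose, EC50 from the
        # dose bracketing half-maximal response
        plat0 = float(y[x == x.max()].mean())
        half = base0 + 0.5 * (plat0 - base0)
        above = x[np.argsort(np.abs(y - half))[:1]]
        ec0 = float(above[0]) if above.size and above[0] > 0 else float(
            np.median(x[x > 0])
        )

        if self.y_se is not None:
            w = 1.0 / np.where(self.y_se > 0, self.y_se, np.nanmin(self.y_se[self.y_se > 0]))
        else:
            w = np.ones_like(y)

        def model(theta):
            if free_baseline:
                plat, log_ec, base = theta
            else:
                plat, log_ec = theta
                base = base0
            ec = 10.0 ** log_ec
            return base + (plat - base) * x / (ec + x)

        def resid(theta):
            return w * (model(theta) - y)

        theta0 = [plat0, np.log10(ec0)] + ([base0] if free_baseline else [])
        sol = least_squares(resid, theta0, method="lm", max_nfev=20_000)
        n_par = len(theta0)
        dof = max(y.size - n_par, 1)
        s2 = float(np.sum(sol.fun**2)) / dof
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * s2
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(jtj) * s2
            flags.append("singular_covariance")
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))

        plat = float(sol.x[0])
        ec50 = float(10.0 ** sol.x[1])
        base = float(sol.x[2]) if free_baseline else base0
        se_plat = float(se[0])
        se_ec50 = float(se[1] * ec50 * np.log(10.0))  # delta method off the log scale
        se_base = float(se[2]) if free_baseline else 0.0

        # saturating response should increase with dose overall
        order = np.argsort(x)
        if y[order][-1] <= y[order][0]:
            flags.append("non_saturating")

        return DoseResponseResults(
            plateau=plat,
            half_max_conc=ec50,
            baseline=base,
            plateau_se=se_plat,
            half_max_conc_se=se_ec50,
            baseline_se=se_base,
            rss=float(np.sum((model(sol.x) - y) ** 2)),
            n_points=y.size,
            x=x,
            y=y,
            flags=flags,
            baseline_fixed=not free_baseline,
        )
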