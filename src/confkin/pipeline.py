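"""End-to-end orchestration: preprocess -> global fits -> trap -> deconvolution.

`run_pipeline` composes the stages in the order of the two assay designs
(cell-surface flow cytometry and ectodomain BLI): specific-binding
correction, a global 1:1 fit per Fab-defined ensemble, the closure-Fab
titration analysis when a titration is present, and population-weighted
deconvolution of per-state rates when at least the open and extended
ensembles were fitted.  Every decision (background scalar, winning start
point, flags, skipped stages) is logged so reruns are auditable; output is
deterministic given identical inputs and config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .deconv import (
    AffinityRatio,
    ApparentRates,
    StatePopulations,
    StateRates,
    bound_populations,
    deconvolve_state_rates,
)
from .langmuir import LangmuirGlobal, LangmuirGlobalResults, equilibrium_kd, kd_consistency
from .preprocess import subtract_background_flow, subtract_reference_bli
from .trap import TrapDissociation, TrapSeries
from .traces import KineticTrace, Modality, TraceRole, read_trace_tables

__all__ = ["RunConfig", "PipelineReport", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    ``populations`` maps ensemble label to free-state fractions (as
    supplied per preparation; Fab stabilization redistributes states, so
    these are inputs, not derived).  ``affinity_ratio`` is r = Ka_EO /
    Ka_closed with its SD.
    """

    trace_table: str | None = None
    series_table: str | None = None
    traces: list[KineticTrace] | None = None  # in-memory alternative
    populations: dict[str, dict[str, float]] = field(default_factory=dict)
    affinity_ratio: float | None = None
    affinity_ratio_sd: float = 0.0
    kd_equilibrium: dict[str, float] = field(default_factory=dict)  # per ensemble, M
    pooled_background: bool = False
    trap_baseline_free: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "traces"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        base = Path(path).parent
        for attr in ("trace_table", "series_table"):
            p = getattr(cfg, attr)
            if p is not None:
                p = str((base / p) if not Path(p).is_absolute() else Path(p))
                if not Path(p).exists():
                    raise FileNotFoundError(f"{attr} not found: {p}")
                setattr(cfg, attr, p)
        return cfg


@dataclass
class PipelineReport:
    ensemble_fits: dict[str, LangmuirGlobalResults] = field(default_factory=dict)
    kd_checks: dict[str, dict] = field(default_factory=dict)
    trap_result: object = None
    trap_dose_response: object = None
    state_rates: StateRates | None = None
    log: list[str] = field(default_factory=list)

    def summary(self) -> str:
        parts = []
        for label, fit in self.ensemble_fits.items():
            parts.append(f"== ensemble: {label} ==")
            parts.append(fit.summary())
            chk = self.kd_checks.get(label)
            if chk:
                parts.append(
                    f"  equilibrium Kd = {chk['kd_equilibrium_fit']:.4g} M; "
                    f"koff/kon = {chk['kd_ratio']:.4g} M "
                    f"(fold-diff {chk['fold_difference']:.3g})"
                )
        if self.trap_result is not None:
            parts.append("== closure-trap titration ==")
            parts.append(self.trap_result.summary())
            if self.trap_dose_response is not None:
                dr = self.trap_dose_response
                parts.append(
                    f"  koffmax = {dr.plateau:.4g} 1/s "
                    f"({dr.plateau * 1e3:.4g} x 1e-3/s) +/- {dr.plateau_se:.2g}; "
                    f"EC50 = {dr.half_max_conc:.4g} M"
                )
        if self.state_rates is not None:
            parts.append("== deconvolved state rates ==")
            parts.append(self.state_rates.summary())
        parts.append("== log ==")
        parts.extend(f"  {line}" for line in self.log)
        return "\n".join(parts)

    def to_dict(self) -> dict:
        out: dict = {"ensembles": {}, "log": self.log}
        for label, fit in self.ensemble_fits.items():
            out["ensembles"][label] = {
                "kon_app": fit.kon_app,
                "kon_app_se": fit.kon_app_se,
                "koff_app": fit.koff_app,
                "koff_app_se": fit.koff_app_se,
                "rmax": fit.rmax.tolist(),
                "rss": fit.rss,
                "conf_int": {k: list(v) for k, v in fit.conf_int().items()},
                "kd_ratio_M": fit.kd_ratio,
            }
            if label in self.kd_checks:
                out["ensembles"][label]["kd_check"] = self.kd_checks[label]
        if self.trap_dose_response is not None:
            dr = self.trap_dose_response
            out["trap"] = {
                "koffmax": dr.plateau,
                "koffmax_se": dr.plateau_se,
                "koffmax_1e-3_per_s": dr.plateau * 1e3,
                "EC50_M": dr.half_max_conc,
                "EC50_se": dr.half_max_conc_se,
                "baseline": dr.baseline,
                "flags": dr.flags,
                "koff_app_points": {
                    "fab_conc_M": self.trap_result.fab_concs.tolist(),
                    "koff_app": self.trap_result.koff_app.tolist(),
                },
            }
        if self.state_rates is not None:
            out["state_rates"] = {
                s: {
                    "kon": self.state_rates.kon[s].value,
                    "kon_se": self.state_rates.kon[s].se,
                    "kon_provenance": self.state_rates.kon[s].provenance,
                    "koff": self.state_rates.koff[s].value,
                    "koff_se": self.state_rates.koff[s].se,
                    "koff_provenance": self.state_rates.koff[s].provenance,
                    "Kd_M": self.state_rates.kd(s).value,
                }
                for s in self.state_rates.kon
            }
            out["state_rates_flags"] = self.state_rates.flags
        return out

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _match_reference(sample: KineticTrace, references: list[KineticTrace]):
    for ref in references:
        if ref.series_id == f"ref_{sample.series_id}":
            return ref
    for ref in references:
        if np.isclose(ref.analyte_conc, sample.analyte_conc, rtol=1e-9, atol=0):
            return ref
    return None


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Run every stage the inputs support; report skipped stages in the log."""
    report = PipelineReport()
    log = report.log

    if config.traces is not None:
        traces = list(config.traces)
    elif config.trace_table and config.series_table:
        traces = read_trace_tables(config.trace_table, config.series_table)
        log.append(f"read {len(traces)} traces from {config.trace_table}")
    else:
        raise ValueError("config must provide traces or trace/series tables")

    backgrounds = [t for t in traces if t.role is TraceRole.background_EDTA]
    references = [t for t in traces if t.role is TraceRole.reference_sensor]
    samples = [t for t in traces if t.role is TraceRole.sample]
    trap_traces = [t for t in samples if "fab_conc_uM" in t.meta]
    trap_ids = {id(t) for t in trap_traces}
    ensemble_samples: dict[str, list[KineticTrace]] = {}
    for t in samples:
        if id(t) in trap_ids:
            continue
        ensemble_samples.setdefault(t.condition.ensemble_label, []).append(t)

    # ---- preprocess -----------------------------------------------------
    for label, trs in ensemble_samples.items():
        corrected = []
        for tr in trs:
            if tr.modality is Modality.flow_MFI and backgrounds:
                tr = subtract_background_flow(
                    tr, backgrounds, pooled=config.pooled_background
                )
                log.append(
                    f"{tr.series_id}: subtracted background "
                    f"{tr.meta['background_subtracted']:.4g}"
                )
            elif tr.modality is Modality.BLI_nm and references:
                ref = _match_reference(tr, references)
                if ref is not None:
                    tr = subtract_reference_bli(tr, ref)
                    log.append(f"{tr.series_id}: subtracted reference {ref.series_id}")
            corrected.append(tr)
        ensemble_samples[label] = corrected

    # ---- global 1:1 fits per ensemble ----------------------------------
    for label, trs in sorted(ensemble_samples.items()):
        try:
            fit = LangmuirGlobal(trs).fit()
        except (ValueError, RuntimeError) as exc:
            log.append(f"ensemble {label}: fit skipped ({exc})")
            continue
        report.ensemble_fits[label] = fit
        log.append(
            f"ensemble {label}: kon_app={fit.kon_app:.4g} koff_app="
            f"{fit.koff_app:.4g} (start point {fit.start_index})"
        )
        if len(np.unique(fit.concs)) >= 2:
            dr = equilibrium_kd(fit)
            check = {
                "kd_equilibrium_fit": dr.half_max_conc,
                "kd_ratio": fit.kd_ratio,
                "fold_difference": fit.kd_ratio / dr.half_max_conc,
            }
            if label in config.kd_equilibrium:
                rep = kd_consistency(fit, config.kd_equilibrium[label])
                check["kd_external"] = config.kd_equilibrium[label]
                check["fold_vs_external"] = rep.fold_difference
            report.kd_checks[label] = check

    # ---- closure-trap titration -----------------------------------------
    if trap_traces:
        mode = (
            "flow_global"
            if trap_traces[0].modality is Modality.flow_MFI
            else "bli_individual"
        )
        series = []
        for tr in sorted(trap_traces, key=lambda t: t.meta["fab_conc_uM"]):
            phase = tr.dissociation_phase() if tr.t_dis is not None else tr
            series.append(
                TrapSeries(fab_conc=tr.meta["fab_conc_uM"] * 1e-6, trace=phase)
            )
        trap_fit = TrapDissociation(series, mode=mode).fit()
        report.trap_result = trap_fit
        try:
            report.trap_dose_response = trap_fit.dose_response(
                fix_baseline=None if config.trap_baseline_free else 0.0
            )
            log.append(
                f"trap: koffmax={report.trap_dose_response.plateau:.4g} 1/s, "
                f"EC50={report.trap_dose_response.half_max_conc:.4g} M"
            )
        except ValueError as exc:
            log.append(f"trap dose-response skipped ({exc})")
    else:
        log.append("no closure-Fab titration present; trap stage skipped")

    # ---- deconvolution --------------------------------------------------
    have = set(report.ensemble_fits)
    if {"open", "extended"} <= have and config.affinity_ratio is not None:
        ratio = AffinityRatio(config.affinity_ratio, config.affinity_ratio_sd)
        eo = ApparentRates.from_fit(report.ensemble_fits["open"])
        ext = ApparentRates.from_fit(report.ensemble_fits["extended"])
        pops_ext = StatePopulations(
            free=config.populations["extended"], ensemble_label="extended"
        )
        kwargs = {}
        if "basal" in have and "basal" in config.populations:
            kwargs["basal"] = ApparentRates.from_fit(report.ensemble_fits["basal"])
            kwargs["pops_basal"] = StatePopulations(
                free=config.populations["basal"], ensemble_label="basal"
            )
        report.state_rates = deconvolve_state_rates(
            extended=ext,
            eo_rates=eo,
            pops_extended=pops_ext,
            ratio=ratio,
            **kwargs,
        )
        log.append(
            "deconvolved state rates from ensembles: "
            + ", ".join(sorted(have & {"open", "extended", "basal"}))
        )
    else:
        missing = sorted({"open", "extended"} - have)
        why = (
            f"missing ensembles {missing}"
            if missing
            else "no affinity ratio configured"
        )
        log.append(f"deconvolution skipped ({why})")
    return report
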