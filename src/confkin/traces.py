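"""Kinetic trace containers and delimited-table IO.

A :class:`KineticTrace` holds one association(+dissociation) time series with
its analyte concentration and condition metadata.  Traces are exchanged on
disk as two delimited text tables: a long *trace* table with columns
``series_id, time_s, signal`` and a companion *series* table with one row of
metadata per ``series_id``.  Concentrations are entered in nM in the tables
and converted to molar internally.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "TraceRole",
    "EnsembleCondition",
    "KineticTrace",
    "read_trace_tables",
    "write_trace_tables",
    "ENSEMBLE_STATES",
]


class Modality(str, enum.Enum):
    """Measurement modality: flow-cytometry MFI or BLI response in nm."""

    flow_MFI = "flow_MFI"
    BLI_nm = "BLI_nm"


class TraceRole(str, enum.Enum):
    sample = "sample"
    background_EDTA = "background_EDTA"
    reference_sensor = "reference_sensor"


#: States present in each named ensemble (closure of the Fab-stabilization map).
ENSEMBLE_STATES: dict[str, tuple[str, ...]] = {
    "basal": ("BC", "EC", "EO"),
    "extended": ("EC", "EO"),
    "open": ("EO",),
}


@dataclass(frozen=True)
class EnsembleCondition:
    """Fab-defined conformational ensemble a trace was measured on.

    Parameters
    ----------
    ensemble_label
        One of ``basal``, ``extended``, ``open`` or ``custom``.
    states_present
        Conformational states populated in the ensemble, subset of
        ``{"BC", "EC", "EO"}``.  Defaults follow the label for the three
        named ensembles.
    fabs
        Mapping of Fab name to concentration in molar.
    competitor
        Free-text description of the unlabeled competitor used for the chase.
    """

    ensemble_label: str = "basal"
    states_present: tuple[str, ...] = ()
    fabs: Mapping[str, float] = field(default_factory=dict)
    competitor: str = ""

    def __post_init__(self) -> None:
        states = tuple(self.states_present)
        if not states:
            if self.ensemble_label not in ENSEMBLE_STATES:
                raise ValueError(
                    f"states_present required for custom ensemble "
                    f"{self.ensemble_label!r}"
                )
            states = ENSEMBLE_STATES[self.ensemble_label]
        unknown = set(states) - {"BC", "EC", "EO"}
        if unknown:
            raise ValueError(f"unknown conformational states: {sorted(unknown)}")
        if self.ensemble_label in ENSEMBLE_STATES:
            expected = ENSEMBLE_STATES[self.ensemble_label]
            if set(states) != set(expected):
                raise ValueError(
                    f"{self.ensemble_label!r} ensemble must contain states "
                    f"{expected}, got {states}"
                )
        object.__setattr__(self, "states_present", states)


@dataclass(eq=False)
class KineticTrace:
    """One kinetic binding time series.

    ``times`` are in seconds and must be finite and non-decreasing;
    ``signal`` is in MFI arbitrary units (flow) or nm (BLI).  ``t_dis`` is
    the time dissociation was initiated (competitor added or sensor moved to
    a ligand-free well); ``None`` for single-phase traces.
    """

    times: np.ndarray
    signal: np.ndarray
    analyte_conc: float = 0.0  # molar
    t_dis: float | None = None  # seconds
    modality: Modality = Modality.flow_MFI
    condition: EnsembleCondition = field(default_factory=EnsembleCondition)
    role: TraceRole = TraceRole.sample
    series_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.modality = Modality(self.modality)
        self.role = TraceRole(self.role)
        if self.times.ndim != 1 or self.times.shape != self.signal.shape:
            raise ValueError("times and signal must be 1-D arrays of equal length")
        if self.times.size < 2:
            raise ValueError("a trace needs at least two points")
        if not np.all(np.isfinite(self.times)):
            raise ValueError("times must be finite")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if self.analyte_conc < 0:
            raise ValueError("analyte_conc must be >= 0")
        if self.t_dis is not None and not (
            self.times[0] <= self.t_dis <= self.times[-1]
        ):
            raise ValueError(
                f"t_dis={self.t_dis} outside the sampled span "
                f"[{self.times[0]}, {self.times[-1]}]"
            )

    # -- convenience ------------------------------------------------------

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    def with_signal(self, signal: np.ndarray, **meta) -> "KineticTrace":
        """Copy of the trace with a new signal array; times/metadata untouched."""
        new = dataclasses.replace(self, signal=np.asarray(signal, dtype=float))
        new.meta = {**self.meta, **meta}
        return new

    def dissociation_phase(self, rezero: bool = True) -> "KineticTrace":
        """Return the t >= t_dis portion, optionally re-zeroed at t_dis."""
        if self.t_dis is None:
            raise ValueError("trace has no dissociation phase (t_dis is None)")
        mask = self.times >= self.t_dis
        times = self.times[mask]
        if rezero:
            times = times - self.t_dis
        out = dataclasses.replace(
            self,
            times=times,
            signal=self.signal[mask],
            t_dis=None if rezero else self.t_dis,
        )
        out.meta = dict(self.meta)
        return out


# ---------------------------------------------------------------------------
# Table IO

_SERIES_COLUMNS = [
    "series_id",
    "modality",
    "analyte_conc_nM",
    "t_D_s",
    "role",
    "ensemble_label",
    "fabs",
    "notes",
]


def _fabs_to_str(fabs: Mapping[str, float]) -> str:
    # serialized as "name:conc_uM;name:conc_uM"
    return ";".join(f"{k}:{v * 1e6:g}" for k, v in fabs.items())


def _fabs_from_str(s: str) -> dict[str, float]:
    out: dict[str, float] = {}
    if not isinstance(s, str) or not s.strip():
        return out
    for part in s.split(";"):
        name, _, conc = part.partition(":")
        out[name.strip()] = float(conc) * 1e-6
    return out


def write_trace_tables(
    traces: Iterable[KineticTrace], trace_path, series_path, sep: str = ","
) -> None:
    """Write traces as the long-format trace table plus the series table."""
    long_rows = []
    series_rows = []
    for tr in traces:
        if not tr.series_id:
            raise ValueError("every trace needs a series_id for table output")
        for t, s in zip(tr.times, tr.signal):
            long_rows.append((tr.series_id, t, s))
        series_rows.append(
            {
                "series_id": tr.series_id,
                "modality": tr.modality.value,
                "analyte_conc_nM": tr.analyte_conc * 1e9,
                "t_D_s": "" if tr.t_dis is None else tr.t_dis,
                "role": tr.role.value,
                "ensemble_label": tr.condition.ensemble_label,
                "fabs": _fabs_to_str(tr.condition.fabs),
                "notes": tr.meta.get("notes", ""),
                "fab_conc_uM": tr.meta.get("fab_conc_uM", ""),
            }
        )
    pd.DataFrame(long_rows, columns=["series_id", "time_s", "signal"]).to_csv(
        trace_path, sep=sep, index=False
    )
    pd.DataFrame(series_rows).to_csv(series_path, sep=sep, index=False)


def read_trace_tables(trace_path, series_path, sep: str = ",") -> list[KineticTrace]:
    """Read traces from the trace/series table pair.

    The series table must contain ``series_id, modality, analyte_conc_nM,
    t_D_s, role, ensemble_label``; ``fabs``, ``notes`` and ``fab_conc_uM``
    are optional.  Concentrations in the tables are nM (fab_conc_uM is µM)
    and are converted to molar.
    """
    long_df = pd.read_csv(trace_path, sep=sep)
    series_df = pd.read_csv(series_path, sep=sep)
    missing = {"series_id", "time_s", "signal"} - set(long_df.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    traces = []
    grouped = long_df.groupby("series_id", sort=False)
    for row in series_df.itertuples(index=False):
        sid = row.series_id
        if sid not in grouped.groups:
            raise ValueError(f"series {sid!r} has no rows in the trace table")
        g = grouped.get_group(sid).sort_values("time_s")
        t_dis = getattr(row, "t_D_s", None)
        if t_dis is not None and (pd.isna(t_dis) or t_dis == ""):
            t_dis = None
        label = getattr(row, "ensemble_label", "basal")
        if not isinstance(label, str) or not label:
            label = "basal"
        cond = EnsembleCondition(
            ensemble_label=label if label in ENSEMBLE_STATES else "custom",
            states_present=ENSEMBLE_STATES.get(label, ("BC", "EC", "EO")),
            fabs=_fabs_from_str(getattr(row, "fabs", "")),
        )
        meta: dict = {}
        fab_uM = getattr(row, "fab_conc_uM", None)
        if fab_uM is not None and not pd.isna(fab_uM) and fab_uM != "":
            meta["fab_conc_uM"] = float(fab_uM)
        traces.append(
            KineticTrace(
                times=g["time_s"].to_numpy(),
                signal=g["signal"].to_numpy(),
                analyte_conc=float(row.analyte_conc_nM) * 1e-9,
                t_dis=None if t_dis is None else float(t_dis),
                modality=Modality(row.modality),
                condition=cond,
                role=TraceRole(row.role),
                series_id=str(sid),
                meta=meta,
            )
        )
    return traces


def read_source_spreadsheet(
    path, column_map: Mapping[str, Sequence[str] | str], sheet_name=0
) -> list[KineticTrace]:
    """Read a figure source-data style spreadsheet via a user-supplied column map.

    ``column_map`` maps each output series_id to ``(time_column, signal_column)``
    in the sheet; per-series metadata may be attached afterwards by the caller.
    Requires openpyxl for .xlsx input.
    """
    df = pd.read_excel(path, sheet_name=sheet_name)
    traces = []
    for sid, cols in column_map.items():
        tcol, scol = cols
        sub = df[[tcol, scol]].dropna()
        traces.append(
            KineticTrace(
                times=sub[tcol].to_numpy(dtype=float),
                signal=sub[scol].to_numpy(dtype=float),
                series_id=str(sid),
            )
        )
    return traces
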