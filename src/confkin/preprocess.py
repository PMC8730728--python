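"""Background and reference subtraction.

Flow-cytometry traces carry a nonspecific-binding background measured in
10 mM EDTA (which abolishes divalent-cation-dependent integrin binding);
because the background shows no systematic time dependence it is pooled to
a single scalar per analyte concentration and subtracted.  BLI traces are
corrected pointwise against a matched reference sensor carrying an inactive
ligand.  Negative specific signals after subtraction are retained; the
fitting stage handles them.
"""

from __future__ import annotations

import numpy as np

from .traces import KineticTrace, TraceRole

__all__ = ["subtract_background_flow", "subtract_reference_bli"]

_CONC_RTOL = 1e-9


def subtract_background_flow(
    sample: KineticTrace,
    backgrounds: list[KineticTrace],
    pooled: bool = False,
) -> KineticTrace:
    """Subtract the pooled EDTA-background scalar from a flow-cytometry trace.

    All background signal values (across time points, and across background
    traces at the sample's analyte concentration) are pooled into a single
    mean, which is subtracted from every point of the sample.  With
    ``pooled=True`` backgrounds at all concentrations are pooled instead of
    concentration matching.

    The subtracted scalar is recorded in ``meta["background_subtracted"]``.
    Times, t_dis and condition metadata are untouched.
    """
    if not backgrounds:
        raise ValueError("no background traces supplied")
    for bg in backgrounds:
        if bg.role is not TraceRole.background_EDTA:
            raise ValueError(
                f"background trace {bg.series_id!r} has role {bg.role.value}, "
                "expected background_EDTA"
            )
        if bg.modality is not sample.modality:
            raise ValueError(
                f"modality mismatch: sample is {sample.modality.value}, "
                f"background {bg.series_id!r} is {bg.modality.value}"
            )
    if pooled:
        matched = list(backgrounds)
    else:
        matched = [
            bg
            for bg in backgrounds
            if np.isclose(bg.analyte_conc, sample.analyte_conc, rtol=_CONC_RTOL, atol=0)
        ]
        if not matched:
            raise ValueError(
                "no background trace at analyte concentration "
                f"{sample.analyte_conc * 1e9:g} nM"
            )
    pooled_values = np.concatenate([bg.signal for bg in matched])
    offset = float(np.mean(pooled_values))
    return sample.with_signal(sample.signal - offset, background_subtracted=offset)


def subtract_reference_bli(
    sample: KineticTrace, reference: KineticTrace
) -> KineticTrace:
    """Subtract a reference-sensor trace from a BLI sample trace pointwise.

    The reference is linearly interpolated onto the sample's time grid when
    the grids differ; extrapolation outside the reference span is refused.
    """
    if reference.role is not TraceRole.reference_sensor:
        raise ValueError(
            f"reference trace {reference.series_id!r} has role "
            f"{reference.role.value}, expected reference_sensor"
        )
    if (
        sample.times[0] < reference.times[0] - 1e-12
        or sample.times[-1] > reference.times[-1] + 1e-12
    ):
        raise ValueError(
            "reference span "
            f"[{reference.times[0]}, {reference.times[-1]}] s does not cover "
            f"sample span [{sample.times[0]}, {sample.times[-1]}] s"
        )
    ref_on_grid = np.interp(sample.times, reference.times, reference.signal)
    return sample.with_signal(
        sample.signal - ref_on_grid, reference_subtracted=reference.series_id or True
    )
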