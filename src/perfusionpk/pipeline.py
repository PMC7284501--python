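"""Initial-uptake pharmacokinetics of in situ brain perfusion.

Five elementary calculations, applied per dissected tissue:

* vascular volume            Vv      = Xstar / Cstar_perf
* vascular-corrected amount  Xtissue = Xtot - Vv * Cperf
* distribution volume        Vtissue = Xtissue / Cperf
* transport clearance        Kin     = Vtissue / T
* extraction                 E%      = 100 * Kin / F

where F is the regional perfusion flow measured with a ~100 %-extracted flow
marker (diazepam) in separate animals.  Uptake with E below 30 % is termed
flow independent; at or above that threshold Kin is partly flow-limited and
the sample is flagged.

A negative corrected amount (counting noise can push a low-uptake sample
below the vascular background) is retained as a signed diagnostic, while the
reported Vtissue is clamped to zero and the sample flagged.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .io import (
    FLAG_BELOW_VASCULAR,
    FLAG_FLOW_DEPENDENT,
    FLAG_MISSING_FLOW,
    FlowEstimate,
    PerfusateSpec,
    PerfusionSample,
    RegionPK,
    ValidationError,
)

#: E (%) at or above which uptake is considered flow dependent.
FLOW_DEPENDENT_THRESHOLD = 30.0


def vascular_volume(Xstar: float, Cstar_perf: float) -> float:
    """Vascular (marker) distribution volume Vv in uL g^-1."""
    if not Cstar_perf > 0:
        raise ValidationError("Cstar_perf must be > 0")
    if Xstar < 0:
        raise ValidationError("Xstar must be >= 0")
    return Xstar / Cstar_perf


def corrected_tissue_amount(
    Xtot: float, Vv: float, Cperf: float
) -> tuple[float, bool]:
    """Subtract the tracer held in the vascular space from the total.

    Returns the signed corrected amount (dpm g^-1) and whether it fell below
    the vascular background (i.e. came out negative).
    """
    if not Cperf > 0:
        raise ValidationError("Cperf must be > 0")
    if Vv < 0:
        raise ValidationError("Vv must be >= 0")
    Xtissue = Xtot - Vv * Cperf
    return Xtissue, Xtissue < 0


def distribution_volume(Xtissue: float, Cperf: float) -> tuple[float, float]:
    """Apparent tissue distribution volume (uL g^-1).

    Returns ``(reported, signed)``: the reported value is clamped at zero,
    the signed value is kept for diagnostics.
    """
    if not Cperf > 0:
        raise ValidationError("Cperf must be > 0")
    signed = Xtissue / Cperf
    return (signed if signed > 0 else 0.0), signed


def transport_clearance(Vtissue: float, T: float) -> float:
    """Initial transport clearance Kin = Vtissue / T (uL s^-1 g^-1)."""
    if not T > 0:
        raise ValidationError("T must be > 0")
    return Vtissue / T


def extraction(Kin: float, F: float) -> tuple[float, bool]:
    """Tissue extraction E (%) of the perfusion flow, with flow-dependence.

    Returns ``(E, flow_dependent)`` where ``flow_dependent`` is True iff
    E >= 30 % (below 30 % the uptake is flow independent).
    """
    if not F > 0:
        raise ValidationError("F must be > 0")
    E = 100.0 * Kin / F
    return E, E >= FLOW_DEPENDENT_THRESHOLD


def _single_sample_pk(
    sample: PerfusionSample,
    perfusate: PerfusateSpec,
    F: float | None,
) -> RegionPK:
    Vv = vascular_volume(sample.Xstar, perfusate.Cstar_perf)
    Xtissue, below = corrected_tissue_amount(sample.Xtot, Vv, perfusate.Cperf)
    Vtissue, _signed = distribution_volume(Xtissue, perfusate.Cperf)
    Kin = transport_clearance(Vtissue, sample.T)

    flags: set[str] = set()
    if below:
        flags.add(FLAG_BELOW_VASCULAR)
    E: float | None = None
    if F is None:
        flags.add(FLAG_MISSING_FLOW)
    else:
        E, flow_dep = extraction(Kin, F)
        if flow_dep:
            flags.add(FLAG_FLOW_DEPENDENT)

    return RegionPK(
        sample_id=sample.sample_id,
        Vv=Vv,
        Xtissue=Xtissue,
        Vtissue=Vtissue,
        Kin=Kin,
        E=E,
        flags=frozenset(flags),
        region=sample.region,
        species=sample.species,
        group=sample.group,
        treatment=sample.treatment,
    )


def estimate_flow(
    diazepam_samples: Sequence[PerfusionSample],
    perfusate: PerfusateSpec,
) -> list[FlowEstimate]:
    """Regional perfusion flow from flow-marker animals.

    Runs the full per-sample pipeline on each flow-marker sample (with the
    marker's own perfusate concentration and its own, typically shorter,
    perfusion time) and averages Kin per (region, species).  Flow is never
    pooled across species or regions, because it differs among brain
    structures.
    """
    bad = [s.sample_id for s in diazepam_samples if s.tracer != "diazepam"]
    if bad:
        raise ValidationError(f"non-flow-marker sample(s) passed: {', '.join(bad)}")
    kins: dict[tuple[str, str], list[float]] = defaultdict(list)
    for s in diazepam_samples:
        pk = _single_sample_pk(s, perfusate, F=None)
        kins[(s.region, s.species)].append(pk.Kin)
    out = []
    for (region, species), values in sorted(kins.items()):
        out.append(
            FlowEstimate(
                region=region,
                species=species,
                F=sum(values) / len(values),
                n=len(values),
            )
        )
    return out


def _flow_lookup(
    flow_estimates: Iterable[FlowEstimate] | Mapping[tuple[str, str], float] | None,
) -> Mapping[tuple[str, str], float]:
    if flow_estimates is None:
        return {}
    if isinstance(flow_estimates, Mapping):
        return flow_estimates
    return {(fe.region, fe.species): fe.F for fe in flow_estimates}


def run_pipeline(
    samples: Sequence[PerfusionSample],
    perfusate: PerfusateSpec,
    flow_estimates: Iterable[FlowEstimate] | Mapping[tuple[str, str], float] | None = None,
) -> list[RegionPK]:
    """Apply the four uptake equations (plus extraction) to every sample.

    Per-sample results are independent of batch composition and of row
    order.  Samples whose region/species has no flow estimate get ``E=None``
    and the ``missing_flow_reference`` flag.  Validation failures are
    aggregated and reported with the offending sample ids.
    """
    lookup = _flow_lookup(flow_estimates)
    out: list[RegionPK] = []
    errors: list[str] = []
    for s in samples:
        try:
            out.append(_single_sample_pk(s, perfusate, lookup.get((s.region, s.species))))
        except ValidationError as exc:
            errors.append(f"{s.sample_id}: {exc}")
    if errors:
        raise ValidationError("; ".join(errors))
    return out
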