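"""Domain types and tabular I/O for in situ brain perfusion experiments.

The atomic observation of the technique is one dissected brain structure from
one perfused animal, counted for two isotopes: a test tracer (e.g. a tritiated
drug) and a vascular-space marker (e.g. [14C]-sucrose) that does not cross an
intact blood-brain barrier.  Everything downstream — vascular correction,
transport clearance Kin, extraction, group contrasts — consumes the records
defined here.

Units are fixed at the boundary and never inferred: tissue amounts in
dpm g^-1, perfusate concentrations in dpm uL^-1, times in seconds, volumes in
uL g^-1 and clearances in uL s^-1 g^-1.  The readers validate tokens and signs
but perform no unit conversion; silent conversion is the main corruption risk
in a unit-rigid calculation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("perfusionpk")

# ---------------------------------------------------------------------------
# Vocabularies and flags
# ---------------------------------------------------------------------------

REGIONS: tuple[str, ...] = ("cerebrum", "cerebellum", "brainstem")
SPECIES: tuple[str, ...] = ("rat", "mouse")
TRACERS: tuple[str, ...] = ("SN38", "diazepam", "other")

#: Free-text escape hatch for structures beyond the three dissected regions.
OTHER_REGION_PREFIX = "other:"

FLAG_BELOW_VASCULAR = "below_vascular_background"
FLAG_FLOW_DEPENDENT = "flow_dependent"
FLAG_MISSING_FLOW = "missing_flow_reference"
ALL_FLAGS = frozenset({FLAG_BELOW_VASCULAR, FLAG_FLOW_DEPENDENT, FLAG_MISSING_FLOW})


class SchemaError(ValueError):
    """A tabular input does not have the documented column layout."""


class ValidationError(ValueError):
    """A record violates a domain invariant (sign, vocabulary, positivity)."""


def validate_region(token: str) -> str:
    """Accept one of the closed region tokens or ``other:<name>``."""
    if token in REGIONS or (
        token.startswith(OTHER_REGION_PREFIX) and len(token) > len(OTHER_REGION_PREFIX)
    ):
        return token
    raise ValidationError(
        f"unknown region {token!r}; allowed: {', '.join(REGIONS)} or "
        f"'{OTHER_REGION_PREFIX}<name>'"
    )


def _validate_token(value: str, allowed: tuple[str, ...], what: str) -> str:
    if value not in allowed:
        raise ValidationError(f"unknown {what} {value!r}; allowed: {', '.join(allowed)}")
    return value


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerfusionSample:
    """Dual-isotope counts for one dissected tissue plus perfusion metadata.

    ``Xtot`` is the total test-tracer amount in the tissue and ``Xstar`` the
    vascular-marker amount, both per gram of wet tissue; ``T`` is the
    perfusion duration in seconds.
    """

    sample_id: str
    animal_id: str
    species: str
    region: str
    group: str
    treatment: str
    tracer: str
    Xtot: float  # dpm g^-1
    Xstar: float  # dpm g^-1
    T: float  # s

    def __post_init__(self) -> None:
        _validate_token(self.species, SPECIES, "species")
        validate_region(self.region)
        _validate_token(self.tracer, TRACERS, "tracer")
        if self.Xtot < 0:
            raise ValidationError(f"sample {self.sample_id}: Xtot must be >= 0")
        if self.Xstar < 0:
            raise ValidationError(f"sample {self.sample_id}: Xstar must be >= 0")
        if not self.T > 0:
            raise ValidationError(f"sample {self.sample_id}: T must be > 0")


@dataclass(frozen=True)
class PerfusateSpec:
    """Composition of the artificial perfusion fluid.

    ``Cperf`` / ``Cstar_perf`` are the test-tracer and vascular-marker
    concentrations (dpm uL^-1); ``flow_rate`` is the pump setting (mL min^-1);
    ``inhibitors`` maps a treatment label to the inhibitor concentration in
    umol L^-1 (10 uM elacridar, valspodar, Ko143; 100 uM MK571 in the
    reference design).
    """

    Cperf: float  # dpm uL^-1
    Cstar_perf: float  # dpm uL^-1
    flow_rate: float = 10.0  # mL min^-1
    inhibitors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.Cperf > 0:
            raise ValidationError("Cperf must be > 0")
        if not self.Cstar_perf > 0:
            raise ValidationError("Cstar_perf must be > 0")
        if not self.flow_rate > 0:
            raise ValidationError("flow_rate must be > 0")


@dataclass(frozen=True)
class RegionPK:
    """Derived pharmacokinetic quantities for one sample.

    ``Xtissue`` keeps its sign as a diagnostic; ``Vtissue`` is the reported
    (clamped, non-negative) distribution volume.  ``E`` is extraction in
    percent and is ``None`` when the run had no flow reference.  Sample
    metadata (region, group, ...) is carried along so that group contrasts can
    be formed from the output table alone.
    """

    sample_id: str
    Vv: float  # uL g^-1
    Xtissue: float  # dpm g^-1, signed
    Vtissue: float  # uL g^-1, reported >= 0
    Kin: float  # uL s^-1 g^-1
    E: float | None = None  # percent
    flags: frozenset[str] = frozenset()
    region: str | None = None
    species: str | None = None
    group: str | None = None
    treatment: str | None = None

    def __post_init__(self) -> None:
        if self.Vv < 0:
            raise ValidationError(f"{self.sample_id}: Vv must be >= 0")
        if self.Vtissue < 0:
            raise ValidationError(f"{self.sample_id}: reported Vtissue must be >= 0")
        unknown = set(self.flags) - ALL_FLAGS
        if unknown:
            raise ValidationError(f"{self.sample_id}: unknown flags {sorted(unknown)}")


@dataclass(frozen=True)
class FlowEstimate:
    """Regional perfusion flow F from a fully extracted flow marker."""

    region: str
    species: str
    F: float  # uL s^-1 g^-1
    n: int

    def __post_init__(self) -> None:
        if not self.F > 0:
            raise ValidationError(f"F must be > 0 for {self.region}")
        if self.n < 1:
            raise ValidationError("n must be >= 1")


@dataclass(frozen=True)
class GroupComparison:
    """Two-group Kin contrast: summaries, fold-change with CI, test p-value."""

    region: str | None
    reference_group: str
    test_group: str
    mean_ref: float
    sd_ref: float | None
    n_ref: int
    mean_test: float
    sd_test: float | None
    n_test: int
    fold_change: float
    fold_ci: tuple[float, float]
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if self.mean_ref > 0 and self.mean_test > 0 and not self.fold_change > 0:
            raise ValidationError("fold_change must be > 0 for positive means")
        lo, hi = self.fold_ci
        if lo > hi:
            raise ValidationError("fold_ci must be ordered (lo <= hi)")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p_value must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Tabular readers
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "animal_id",
    "species",
    "region",
    "group",
    "treatment",
    "tracer",
    "Xtot_dpm_per_g",
    "Xstar_dpm_per_g",
    "T_s",
)


def read_samples(
    path: str | Path, perfusate: PerfusateSpec | None = None
) -> list[PerfusionSample]:
    """Read a samples table (CSV, comma-separated, UTF-8, header required).

    Returns one validated :class:`PerfusionSample` per row, preserving row
    order.  Unknown columns are ignored with a logged warning.  Missing
    mandatory columns raise :class:`SchemaError` naming the column; invalid
    values raise :class:`ValidationError` with the 1-based data row number.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in SAMPLE_COLUMNS]
    if extra:
        logger.warning("ignoring unknown column(s): %s", ", ".join(extra))

    samples: list[PerfusionSample] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        try:
            samples.append(
                PerfusionSample(
                    sample_id=str(rec["sample_id"]),
                    animal_id=str(rec["animal_id"]),
                    species=str(rec["species"]),
                    region=str(rec["region"]),
                    group=str(rec["group"]),
                    treatment=str(rec["treatment"]),
                    tracer=str(rec["tracer"]),
                    Xtot=float(rec["Xtot_dpm_per_g"]),
                    Xstar=float(rec["Xstar_dpm_per_g"]),
                    T=float(rec["T_s"]),
                )
            )
        except (ValidationError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
        except ValueError as exc:  # unparseable numerics
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError("; ".join(errors))
    return samples


def samples_to_frame(samples: Iterable[PerfusionSample]) -> pd.DataFrame:
    """Tabulate samples with the documented column names."""
    rows = [
        {
            "sample_id": s.sample_id,
            "animal_id": s.animal_id,
            "species": s.species,
            "region": s.region,
            "group": s.group,
            "treatment": s.treatment,
            "tracer": s.tracer,
            "Xtot_dpm_per_g": s.Xtot,
            "Xstar_dpm_per_g": s.Xstar,
            "T_s": s.T,
        }
        for s in samples
    ]
    return pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS))


def write_samples(samples: Iterable[PerfusionSample], path: str | Path) -> None:
    samples_to_frame(samples).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_perfusate(path: str | Path) -> PerfusateSpec:
    """Read a perfusate key-value file (YAML).

    Keys: ``Cperf_dpm_per_uL``, ``Cstar_perf_dpm_per_uL``,
    ``flow_rate_mL_per_min`` and an optional ``inhibitors`` map (name -> uM).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError("perfusate file must be a key-value mapping")
    for key in ("Cperf_dpm_per_uL", "Cstar_perf_dpm_per_uL"):
        if key not in raw:
            raise SchemaError(f"missing mandatory key: {key}")
    return PerfusateSpec(
        Cperf=float(raw["Cperf_dpm_per_uL"]),
        Cstar_perf=float(raw["Cstar_perf_dpm_per_uL"]),
        flow_rate=float(raw.get("flow_rate_mL_per_min", 10.0)),
        inhibitors={k: float(v) for k, v in (raw.get("inhibitors") or {}).items()},
    )


# ---------------------------------------------------------------------------
# Report writer
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"

REGIONPK_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "region",
    "species",
    "group",
    "treatment",
    "Vv_uL_per_g",
    "Xtissue_dpm_per_g",
    "Vtissue_uL_per_g",
    "Kin_uL_per_s_per_g",
    "E_percent",
    "flags",
)

COMPARISON_COLUMNS: tuple[str, ...] = (
    "region",
    "reference_group",
    "test_group",
    "mean_ref",
    "sd_ref",
    "n_ref",
    "mean_test",
    "sd_test",
    "n_test",
    "fold_change",
    "fold_lo",
    "fold_hi",
    "p_value",
    "test_name",
)


def _fmt(x: float | None) -> str:
    return "" if x is None else _FLOAT_FMT % x


def regionpk_to_frame(results: Sequence[RegionPK]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id,
            "region": r.region or "",
            "species": r.species or "",
            "group": r.group or "",
            "treatment": r.treatment or "",
            "Vv_uL_per_g": r.Vv,
            "Xtissue_dpm_per_g": r.Xtissue,
            "Vtissue_uL_per_g": r.Vtissue,
            "Kin_uL_per_s_per_g": r.Kin,
            "E_percent": r.E,
            "flags": "|".join(sorted(r.flags)),
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=list(REGIONPK_COLUMNS))


def write_report(
    results: Sequence[RegionPK],
    comparisons: Sequence[GroupComparison],
    outdir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write ``regionpk.csv``, ``comparisons.csv`` and ``run.log``.

    Output is deterministic: fixed column order, fixed float formatting, no
    timestamps — identical inputs produce byte-identical files.  ``run.log``
    records a SHA-256 hash of the canonicalized config and the seed.
    """
    if not results:
        raise ValueError("results must be non-empty")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pk_path = outdir / "regionpk.csv"
    regionpk_to_frame(results).to_csv(pk_path, index=False, float_format=_FLOAT_FMT)

    cmp_path = outdir / "comparisons.csv"
    cmp_rows = [
        {
            "region": c.region or "",
            "reference_group": c.reference_group,
            "test_group": c.test_group,
            "mean_ref": c.mean_ref,
            "sd_ref": c.sd_ref,
            "n_ref": c.n_ref,
            "mean_test": c.mean_test,
            "sd_test": c.sd_test,
            "n_test": c.n_test,
            "fold_change": c.fold_change,
            "fold_lo": c.fold_ci[0],
            "fold_hi": c.fold_ci[1],
            "p_value": c.p_value,
            "test_name": c.test_name,
        }
        for c in comparisons
    ]
    pd.DataFrame(cmp_rows, columns=list(COMPARISON_COLUMNS)).to_csv(
        cmp_path, index=False, float_format=_FLOAT_FMT
    )

    cfg_json = json.dumps(dict(config or {}), sort_keys=True, default=str)
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()
    log_path = outdir / "run.log"
    log_path.write_text(
        "perfusionpk run report\n"
        f"n_results={len(results)}\n"
        f"n_comparisons={len(comparisons)}\n"
        f"config_sha256={cfg_hash}\n"
        f"seed={'' if seed is None else seed}\n",
        encoding="utf-8",
    )
    return {"regionpk": pk_path, "comparisons": cmp_path, "log": log_path}


def read_regionpk(path: str | Path) -> list[RegionPK]:
    """Read back a ``regionpk.csv`` written by :func:`write_report`."""
    df = pd.read_csv(
        path,
        dtype={"flags": str},
        keep_default_na=False,
        na_values=[""],
        float_precision="round_trip",
    )
    missing = [c for c in REGIONPK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    out: list[RegionPK] = []
    for rec in df.to_dict("records"):
        raw_flags = rec["flags"]
        flag_set = frozenset(
            t for t in str(raw_flags).split("|") if t
        ) if not pd.isna(raw_flags) else frozenset()
        e_val = rec["E_percent"]
        out.append(
            RegionPK(
                sample_id=str(rec["sample_id"]),
                Vv=float(rec["Vv_uL_per_g"]),
                Xtissue=float(rec["Xtissue_dpm_per_g"]),
                Vtissue=float(rec["Vtissue_uL_per_g"]),
                Kin=float(rec["Kin_uL_per_s_per_g"]),
                E=None if pd.isna(e_val) else float(e_val),
                flags=flag_set,
                region=str(rec["region"]) or None,
                species=str(rec["species"]) or None,
                group=str(rec["group"]) or None,
                treatment=str(rec["treatment"]) or None,
            )
        )
    return out
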