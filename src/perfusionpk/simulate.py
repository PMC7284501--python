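"""Mechanistic generator of in situ brain perfusion experiments.

The generator produces dual-isotope scintillation tables with known ground
truth, mirroring the study design of the perfusion experiments: three brain
regions, control / sham / tumor or WT / knockout groups, co-perfused
transporter inhibitors, flow-marker (diazepam) animals perfused separately at
60 s, and a vascular marker in every sample.

Generation physics
------------------
Efflux transporters reduce the passive luminal permeability-surface product
through a divisor form,

    PS_app = PS_passive / (1 + sum_t a_t * g_t * (1 - i_t)),

where ``a_t`` is the transporter's activity, ``g_t`` is 1 when the gene is
present (0 for a knockout) and ``i_t`` the fractional inhibition by the
co-perfused treatment.  A knockout and complete inhibition are equivalent by
construction, and PS_app stays positive for any parameter choice.

The single-capillary (Crone-Renkin) relation converts permeability to an
uptake clearance at flow F:

    Kin_true = F * (1 - exp(-PS_app / F)),

which makes low-PS tracers flow independent (Kin ~ PS_app) and a very high-PS
marker flow limited (Kin ~ F, i.e. ~100 % extracted).

Noise enters in two independently switchable layers: a multiplicative
lognormal animal-to-animal variability on Kin_true and Vv_true, and Poisson
counting noise on the total dpm of each isotope in the weighed specimen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PerfusateSpec, PerfusionSample, ValidationError

# ---------------------------------------------------------------------------
# Scenario description
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionPhysiology:
    """Ground-truth regional physiology (all rates per gram of tissue)."""

    F: float  # perfusion flow, uL s^-1 g^-1
    Vv: float  # vascular volume, uL g^-1
    PS_passive: float  # passive permeability-surface product, uL s^-1 g^-1

    def __post_init__(self) -> None:
        if not self.F > 0 or self.Vv < 0 or self.PS_passive < 0:
            raise ValidationError("F > 0, Vv >= 0 and PS_passive >= 0 required")


@dataclass(frozen=True)
class Transporter:
    activity: float  # dimensionless efflux activity a >= 0
    genotype_present: bool = True

    def __post_init__(self) -> None:
        if self.activity < 0:
            raise ValidationError("transporter activity must be >= 0")


@dataclass(frozen=True)
class CountingModel:
    """Scintillation-counting configuration.

    The dpm scale and specimen mass set the relative Poisson error; defaults
    correspond to the tracer levels of the reference design (0.011 MBq mL^-1
    test tracer ~ 660 dpm uL^-1; 0.0037 MBq mL^-1 marker ~ 222 dpm uL^-1)
    and keep counting error small next to the biological variability.
    """

    Cperf: float = 660.0  # dpm uL^-1
    Cstar_perf: float = 222.0  # dpm uL^-1
    background_dpm: float = 0.0  # dpm g^-1, added to both isotopes
    specimen_mass_g: float = 0.4
    counting_noise: bool = True

    def __post_init__(self) -> None:
        if not (self.Cperf > 0 and self.Cstar_perf > 0 and self.specimen_mass_g > 0):
            raise ValidationError("Cperf, Cstar_perf and specimen_mass_g must be > 0")
        if self.background_dpm < 0:
            raise ValidationError("background_dpm must be >= 0")


@dataclass(frozen=True)
class StudyCell:
    """One design cell: a group label, a co-perfused treatment, and n animals.

    ``knockout`` lists transporters genetically absent in this cell (e.g.
    P-gp/Bcrp for a triple-knockout group), overriding ``genotype_present``.
    """

    group: str
    treatment: str = "none"
    n: int = 5
    knockout: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")


@dataclass(frozen=True)
class SimScenario:
    species: str
    regions: Mapping[str, RegionPhysiology]
    transporters: Mapping[str, Transporter] = field(default_factory=dict)
    inhibitor_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    design: Sequence[StudyCell] = ()
    biological_cv: float = 0.25
    counting: CountingModel = field(default_factory=CountingModel)
    T: float = 120.0  # s, test-tracer perfusion time
    T_flow: float = 60.0  # s, flow-marker perfusion time
    n_flow: int = 5  # flow-marker animals per region
    flow_marker_ps_ratio: float = 50.0  # PS_app/F for the flow marker
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.biological_cv < 1.0):
            raise ValidationError("biological_cv must lie in [0, 1)")
        if not (self.T > 0 and self.T_flow > 0):
            raise ValidationError("perfusion times must be > 0")
        if self.n_flow < 0:
            raise ValidationError("n_flow must be >= 0")
        for tr, effects in self.inhibitor_effects.items():
            for t, i in effects.items():
                if not (0.0 <= i <= 1.0):
                    raise ValidationError(
                        f"inhibition fraction for {tr}/{t} must lie in [0, 1]"
                    )

    @property
    def perfusate(self) -> PerfusateSpec:
        """Perfusate record matching the generated tables."""
        return PerfusateSpec(
            Cperf=self.counting.Cperf, Cstar_perf=self.counting.Cstar_perf
        )


# ---------------------------------------------------------------------------
# Generation physics
# ---------------------------------------------------------------------------


def apparent_PS(
    PS_passive: float,
    transporters: Mapping[str, Transporter],
    treatment: str,
    inhibitor_effects: Mapping[str, Mapping[str, float]],
) -> float:
    """Apparent luminal permeability under efflux and inhibition.

    ``PS_app = PS_passive / (1 + sum_t a_t * g_t * (1 - i_t))`` where the sum
    runs over transporters, ``g_t`` is the genotype indicator and ``i_t`` the
    fractional inhibition exerted by ``treatment`` on transporter ``t``
    (0 when the treatment does not touch it).
    """
    effects = inhibitor_effects.get(treatment, {})
    denom = 1.0
    for name, t in transporters.items():
        if not t.genotype_present:
            continue
        denom += t.activity * (1.0 - effects.get(name, 0.0))
    return PS_passive / denom


def crone_renkin_kin(PS_app: float, F: float) -> float:
    """Single-capillary uptake clearance ``Kin = F * (1 - exp(-PS_app/F))``."""
    if not F > 0:
        raise ValidationError("F must be > 0")
    if PS_app < 0:
        raise ValidationError("PS_app must be >= 0")
    return F * (1.0 - math.exp(-PS_app / F))


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-one multiplicative lognormal factor with coefficient of variation cv."""
    if cv == 0.0:
        return 1.0
    sigma2 = math.log1p(cv * cv)
    return float(rng.lognormal(mean=-0.5 * sigma2, sigma=math.sqrt(sigma2)))


def _effective_transporters(
    scenario: SimScenario, knockout: frozenset[str]
) -> dict[str, Transporter]:
    out = {}
    for name, t in scenario.transporters.items():
        if name in knockout:
            t = replace(t, genotype_present=False)
        out[name] = t
    return out


def _measured_dpm_per_g(
    clean: float, counting: CountingModel, rng: np.random.Generator
) -> float:
    expected = clean + counting.background_dpm
    if not counting.counting_noise:
        return expected
    lam = expected * counting.specimen_mass_g
    return float(rng.poisson(lam)) / counting.specimen_mass_g


def _sample_with_truth(
    scenario: SimScenario,
    region: str,
    group: str,
    treatment: str,
    tracer: str,
    rng: np.random.Generator,
    knockout: frozenset[str] = frozenset(),
    sample_id: str = "S0000",
    animal_id: str = "A0000",
) -> tuple[PerfusionSample, dict]:
    phys = scenario.regions[region]
    if tracer == "diazepam":
        PS_app = scenario.flow_marker_ps_ratio * phys.F
        T = scenario.T_flow
    else:
        PS_app = apparent_PS(
            phys.PS_passive,
            _effective_transporters(scenario, knockout),
            treatment,
            scenario.inhibitor_effects,
        )
        T = scenario.T
    kin_expected = crone_renkin_kin(PS_app, phys.F)

    # animal-level biological variability (independent draws for Kin and Vv)
    Kin_true = kin_expected * _lognormal_factor(rng, scenario.biological_cv)
    Vv_true = phys.Vv * _lognormal_factor(rng, scenario.biological_cv)

    counting = scenario.counting
    Xtot_clean = (Vv_true + Kin_true * T) * counting.Cperf
    Xstar_clean = Vv_true * counting.Cstar_perf
    Xtot = _measured_dpm_per_g(Xtot_clean, counting, rng)
    Xstar = _measured_dpm_per_g(Xstar_clean, counting, rng)

    sample = PerfusionSample(
        sample_id=sample_id,
        animal_id=animal_id,
        species=scenario.species,
        region=region,
        group=group,
        treatment=treatment,
        tracer=tracer,
        Xtot=Xtot,
        Xstar=Xstar,
        T=T,
    )
    truth = {
        "sample_id": sample_id,
        "region": region,
        "group": group,
        "treatment": treatment,
        "tracer": tracer,
        "F": phys.F,
        "PS_app": PS_app,
        "Kin_true": Kin_true,
        "Vv_true": Vv_true,
    }
    return sample, truth


def generate_sample(
    scenario: SimScenario,
    region: str,
    group: str,
    treatment: str,
    tracer: str,
    rng: np.random.Generator,
    knockout: frozenset[str] = frozenset(),
    sample_id: str = "S0000",
    animal_id: str = "A0000",
) -> PerfusionSample:
    """Generate one perfused-animal sample; reproducible given the rng state."""
    if region not in scenario.regions:
        raise ValidationError(f"region {region!r} not defined in scenario")
    sample, _ = _sample_with_truth(
        scenario, region, group, treatment, tracer, rng, knockout, sample_id, animal_id
    )
    return sample


def _rng_for_index(seed: int, index: int) -> np.random.Generator:
    # counter-based substream: row order never changes any sample's draws
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def generate_study(
    scenario: SimScenario,
) -> tuple[list[PerfusionSample], pd.DataFrame]:
    """Generate the full factorial study plus flow-marker animals.

    Returns the samples (design cells x regions x n test-tracer animals,
    followed by ``n_flow`` diazepam animals per region at the flow-marker
    perfusion time) and a truth table recording each animal's realized
    ``Kin_true``, ``Vv_true`` and ``PS_app`` for recovery scoring.  Every
    sample is co-perfused with the vascular marker.  Draws are tied to the
    (seed, sample index) pair, so each row is reproducible in isolation.
    """
    samples: list[PerfusionSample] = []
    truths: list[dict] = []
    idx = 0
    for cell in scenario.design:
        for region in scenario.regions:
            for _ in range(cell.n):
                rng = _rng_for_index(scenario.seed, idx)
                s, t = _sample_with_truth(
                    scenario,
                    region,
                    cell.group,
                    cell.treatment,
                    tracer="SN38",
                    rng=rng,
                    knockout=cell.knockout,
                    sample_id=f"S{idx:04d}",
                    animal_id=f"A{idx:04d}",
                )
                samples.append(s)
                truths.append(t)
                idx += 1
    for region in scenario.regions:
        for _ in range(scenario.n_flow):
            rng = _rng_for_index(scenario.seed, idx)
            s, t = _sample_with_truth(
                scenario,
                region,
                group="flow",
                treatment="none",
                tracer="diazepam",
                rng=rng,
                sample_id=f"S{idx:04d}",
                animal_id=f"A{idx:04d}",
            )
            samples.append(s)
            truths.append(t)
            idx += 1
    truth = pd.DataFrame(
        truths,
        columns=[
            "sample_id",
            "region",
            "group",
            "treatment",
            "tracer",
            "F",
            "PS_app",
            "Kin_true",
            "Vv_true",
        ],
    )
    return samples, truth


# ---------------------------------------------------------------------------
# Default scenarios
# ---------------------------------------------------------------------------

#: Regional physiology consistent with the reference rat experiments: flows
#: back-calculated from the observed control clearances and extractions
#: (E ~ 0.5 % cerebrum, ~2 % cerebellum, ~0.6 % brainstem at Kin ~ 0.18,
#: 0.10, 0.09 uL s^-1 g^-1), vascular volumes higher in cerebellum and
#: brainstem than cerebrum.  PS_passive is set so the efflux-divided
#: apparent PS (denominator 7 with the default transporter activities) puts
#: the control Crone-Renkin extraction at ~0.55 / 1.8 / 0.65 %, i.e.
#: PS_passive = 7 * (-F * ln(1 - E/100)).
_RAT_REGIONS = {
    "cerebrum": RegionPhysiology(F=36.0, Vv=10.0, PS_passive=1.39),
    "cerebellum": RegionPhysiology(F=5.0, Vv=16.0, PS_passive=0.636),
    "brainstem": RegionPhysiology(F=15.0, Vv=14.0, PS_passive=0.685),
}

_RAT_TRANSPORTERS = {
    "pgp": Transporter(activity=0.6),
    "bcrp": Transporter(activity=0.6),
    "mrp": Transporter(activity=1.5),
    # elacridar-sensitive efflux beyond P-gp/Bcrp, required to reproduce the
    # dissociation between dual inhibition and the double/triple knockout
    "ext": Transporter(activity=3.3),
}

#: Fractional inhibition exerted by each co-perfused treatment.
INHIBITOR_EFFECTS: dict[str, dict[str, float]] = {
    "valspodar": {"pgp": 1.0},
    "Ko143": {"bcrp": 1.0},
    "elacridar": {"pgp": 1.0, "bcrp": 1.0, "ext": 1.0},
    "MK571": {"mrp": 1.0},
}

TKO_KNOCKOUT = frozenset({"pgp", "bcrp"})


def default_rat_scenario(seed: int = 0, n: int = 5) -> SimScenario:
    """Rat inhibitor panel: control plus four co-perfused inhibitors."""
    design = [
        StudyCell(group="control", treatment="none", n=n),
        StudyCell(group="control", treatment="valspodar", n=n),
        StudyCell(group="control", treatment="Ko143", n=n),
        StudyCell(group="control", treatment="elacridar", n=n),
        StudyCell(group="control", treatment="MK571", n=n),
    ]
    return SimScenario(
        species="rat",
        regions=dict(_RAT_REGIONS),
        transporters=dict(_RAT_TRANSPORTERS),
        inhibitor_effects=INHIBITOR_EFFECTS,
        design=design,
        seed=seed,
    )


def default_disease_scenario(seed: int = 0, n: int = 7) -> SimScenario:
    """Rat control / sham / tumor-bearing contrast (no inhibitors).

    The tumor model leaves barrier integrity and transporter function intact,
    so all three groups share the same ground-truth physiology; differences in
    the generated data are noise alone.
    """
    design = [
        StudyCell(group="control", treatment="none", n=n),
        StudyCell(group="sham", treatment="none", n=n),
        StudyCell(group="DIPG", treatment="none", n=n),
    ]
    return SimScenario(
        species="rat",
        regions=dict(_RAT_REGIONS),
        transporters=dict(_RAT_TRANSPORTERS),
        inhibitor_effects=INHIBITOR_EFFECTS,
        design=design,
        seed=seed,
    )


_MOUSE_REGIONS = {
    "cerebrum": RegionPhysiology(F=10.0, Vv=10.0, PS_passive=0.49),
    "cerebellum": RegionPhysiology(F=4.0, Vv=16.0, PS_passive=0.30),
    "brainstem": RegionPhysiology(F=6.0, Vv=14.0, PS_passive=0.25),
}

_MOUSE_TRANSPORTERS = {
    "pgp": Transporter(activity=1.0),
    "bcrp": Transporter(activity=1.0),
    "mrp": Transporter(activity=0.2),
    "ext": Transporter(activity=1.7),
}


def default_mouse_scenario(seed: int = 0, n: int = 5) -> SimScenario:
    """WT vs triple-knockout mouse panel with elacridar and MK-571 arms."""
    design = [
        StudyCell(group="WT", treatment="none", n=n),
        StudyCell(group="WT", treatment="elacridar", n=n),
        StudyCell(group="WT", treatment="MK571", n=n),
        StudyCell(group="TKO", treatment="none", n=n, knockout=TKO_KNOCKOUT),
        StudyCell(group="TKO", treatment="elacridar", n=n, knockout=TKO_KNOCKOUT),
        StudyCell(group="TKO", treatment="MK571", n=n, knockout=TKO_KNOCKOUT),
    ]
    return SimScenario(
        species="mouse",
        regions=dict(_MOUSE_REGIONS),
        transporters=dict(_MOUSE_TRANSPORTERS),
        inhibitor_effects=INHIBITOR_EFFECTS,
        design=design,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Scenario (de)serialization for the CLI
# ---------------------------------------------------------------------------


def scenario_to_dict(scenario: SimScenario) -> dict:
    return {
        "species": scenario.species,
        "seed": scenario.seed,
        "T_s": scenario.T,
        "T_flow_s": scenario.T_flow,
        "n_flow": scenario.n_flow,
        "flow_marker_ps_ratio": scenario.flow_marker_ps_ratio,
        "biological_cv": scenario.biological_cv,
        "counting": {
            "Cperf_dpm_per_uL": scenario.counting.Cperf,
            "Cstar_perf_dpm_per_uL": scenario.counting.Cstar_perf,
            "background_dpm_per_g": scenario.counting.background_dpm,
            "specimen_mass_g": scenario.counting.specimen_mass_g,
            "counting_noise": scenario.counting.counting_noise,
        },
        "regions": {
            name: {"F": p.F, "Vv": p.Vv, "PS_passive": p.PS_passive}
            for name, p in scenario.regions.items()
        },
        "transporters": {
            name: {"activity": t.activity, "genotype_present": t.genotype_present}
            for name, t in scenario.transporters.items()
        },
        "inhibitor_effects": {
            tr: dict(eff) for tr, eff in scenario.inhibitor_effects.items()
        },
        "design": [
            {
                "group": c.group,
                "treatment": c.treatment,
                "n": c.n,
                "knockout": sorted(c.knockout),
            }
            for c in scenario.design
        ],
    }


def scenario_from_dict(raw: Mapping) -> SimScenario:
    counting_raw = raw.get("counting", {})
    counting = CountingModel(
        Cperf=float(counting_raw.get("Cperf_dpm_per_uL", 660.0)),
        Cstar_perf=float(counting_raw.get("Cstar_perf_dpm_per_uL", 222.0)),
        background_dpm=float(counting_raw.get("background_dpm_per_g", 0.0)),
        specimen_mass_g=float(counting_raw.get("specimen_mass_g", 0.4)),
        counting_noise=bool(counting_raw.get("counting_noise", True)),
    )
    return SimScenario(
        species=str(raw["species"]),
        regions={
            name: RegionPhysiology(
                F=float(p["F"]), Vv=float(p["Vv"]), PS_passive=float(p["PS_passive"])
            )
            for name, p in raw["regions"].items()
        },
        transporters={
            name: Transporter(
                activity=float(t["activity"]),
                genotype_present=bool(t.get("genotype_present", True)),
            )
            for name, t in raw.get("transporters", {}).items()
        },
        inhibitor_effects={
            tr: {t: float(i) for t, i in eff.items()}
            for tr, eff in raw.get("inhibitor_effects", {}).items()
        },
        design=[
            StudyCell(
                group=str(c["group"]),
                treatment=str(c.get("treatment", "none")),
                n=int(c.get("n", 5)),
                knockout=frozenset(c.get("knockout", ())),
            )
            for c in raw.get("design", [])
        ],
        biological_cv=float(raw.get("biological_cv", 0.25)),
        counting=counting,
        T=float(raw.get("T_s", 120.0)),
        T_flow=float(raw.get("T_flow_s", 60.0)),
        n_flow=int(raw.get("n_flow", 5)),
        flow_marker_ps_ratio=float(raw.get("flow_marker_ps_ratio", 50.0)),
        seed=int(raw.get("seed", 0)),
    )
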