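"""Synthetic flow-cytometry screen generator.

Emulates the structure of the quiescence screen so the gating, fitting,
clustering and enrichment stages are testable end to end without instrument
data: per-well event tables (~20,000 living events per well) with doublet
contamination, a dead-cell subpopulation whose fraction over time follows a
planted kinetic model, and live-cell DNA-content subpopulations —

* G0: mononuclear 1C, DNA-A low / DNA-W low (small round quiescent cells),
* G2: mononuclear 2C, DNA-A high / DNA-W low,
* G1/M: binuclear 2C, DNA-A high / DNA-W high (septation delayed in fission
  yeast, so two G1 nuclei share one particle).

Event intensities are log-normal within each population (strictly positive,
the usual cytometry noise shape).  FSC-H is generated as a tight multiple of
FSC-A per particle: singlets keep FSC-H ~ FSC-A, doublets double FSC-A (and
DNA-A) while keeping FSC-H near singlet level, so the H/A ratio gate works
by construction.  Dead cells carry ~10x viability-dye intensity (amine
stain) and arbitrary DNA values — they are excluded before DNA analysis.

All randomness flows from a single global seed; each well gets a derived
substream keyed by (strain, day) via CRC32, so wells are independently
reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import evaluate_model

CHANNELS = ("FSC_A", "FSC_H", "SSC_A", "VIAB", "DNA_A", "DNA_W")

POPULATION_NAMES = ("singlet_live_G0", "singlet_live_G2", "singlet_live_G1M",
                    "singlet_dead", "doublet")


@dataclass(frozen=True)
class PopulationSpec:
    """One planted event population: per-channel log-normal location/CV.

    ``channel_cvs['FSC_H']`` is interpreted as the CV of the per-particle
    FSC-H/FSC-A ratio (not of FSC-H marginally), which keeps the singlet
    ratio band tight the way real scatter pulses are.
    """

    name: str
    channel_means: Mapping[str, float]
    channel_cvs: Mapping[str, float]
    weight: float

    def __post_init__(self):
        if self.name not in POPULATION_NAMES:
            raise ValueError(f"unknown population name {self.name!r}")
        for ch in CHANNELS:
            if ch not in self.channel_means or ch not in self.channel_cvs:
                raise ValueError(f"population {self.name}: missing channel {ch}")
            if self.channel_means[ch] <= 0:
                raise ValueError(f"population {self.name}: mean for {ch} must be > 0")
            if self.channel_cvs[ch] <= 0:
                raise ValueError(f"population {self.name}: CV for {ch} must be > 0")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"population {self.name}: weight outside [0, 1]")


@dataclass(frozen=True)
class TrajectorySpec:
    """Planted mortality kinetics for one strain."""

    model_id: str
    params: Tuple[float, ...]
    timepoints: Tuple[float, ...] = (0.0, 1.0, 7.0, 14.0, 21.0, 28.0)
    noise_sd: float = 0.0

    def __post_init__(self):
        tp = self.timepoints
        for i in range(1, len(tp)):
            if tp[i] <= tp[i - 1]:
                raise ValueError(
                    f"timepoints must be strictly increasing; "
                    f"offending index {i} (value {tp[i]})")
        if tp[0] != 0.0:
            raise ValueError("timepoints must include day 0 first")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        evaluate_model(self.model_id, self.params, 0.0)  # validates id/arity


def simulate_trajectory(spec: TrajectorySpec, seed: int) -> List[Tuple[float, float]]:
    """Planted mortality (%) at each time point: model value + noise, clamped.

    Deterministic given ``seed``; values clamped to [0, 100] after additive
    Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    out = []
    for day in spec.timepoints:
        m = float(evaluate_model(spec.model_id, spec.params, day))
        if spec.noise_sd > 0:
            m += float(rng.normal(0.0, spec.noise_sd))
        out.append((day, float(np.clip(m, 0.0, 100.0))))
    return out


# --- default channel geometry ------------------------------------------------

_SCATTER = dict(FSC_A=100.0, FSC_H=100.0, SSC_A=80.0)
_SCATTER_CV = dict(FSC_A=0.30, FSC_H=0.05, SSC_A=0.30)


def _pop(name: str, weight: float, *, fsc_a=100.0, fsc_h=None, viab=10.0,
         dna_a=100.0, dna_w=100.0, dna_cv=0.12, viab_cv=0.30) -> PopulationSpec:
    means = dict(_SCATTER, FSC_A=fsc_a, FSC_H=fsc_h if fsc_h is not None else fsc_a,
                 VIAB=viab, DNA_A=dna_a, DNA_W=dna_w)
    cvs = dict(_SCATTER_CV, VIAB=viab_cv, DNA_A=dna_cv, DNA_W=dna_cv)
    return PopulationSpec(name, means, cvs, weight)


def default_populations(dead_frac: float, g0: float, g2: float, g1m: float,
                        doublet_frac: float = 0.05) -> List[PopulationSpec]:
    """Default screen geometry for one well.

    ``dead_frac`` is the dead fraction among singlets; ``g0``/``g2``/``g1m``
    partition the live singlets (must sum to 1).  DNA means follow the
    1C/2C geometry: G0 at 1 unit DNA-A, G2 and G1/M at 2 units, with DNA-W
    doubled for binuclear G1/M particles.  Viability separation live:dead is
    10x in mean.  Doublets double FSC-A and DNA-A but keep FSC-H at singlet
    level.
    """
    for v, nm in ((dead_frac, "dead_frac"), (g0, "g0"), (g2, "g2"),
                  (g1m, "g1m"), (doublet_frac, "doublet_frac")):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{nm} outside [0, 1]")
    if abs(g0 + g2 + g1m - 1.0) > 1e-9:
        raise ValueError("g0 + g2 + g1m must sum to 1")
    singlet = 1.0 - doublet_frac
    live = singlet * (1.0 - dead_frac)
    return [
        _pop("singlet_live_G0", live * g0, fsc_a=90.0, dna_a=100.0, dna_w=100.0),
        _pop("singlet_live_G2", live * g2, fsc_a=120.0, dna_a=200.0, dna_w=100.0),
        _pop("singlet_live_G1M", live * g1m, fsc_a=130.0, dna_a=200.0, dna_w=200.0),
        # dead-cell DNA values are arbitrary: dead events are gated out
        # before DNA-content analysis, so they must not matter downstream
        _pop("singlet_dead", singlet * dead_frac, fsc_a=90.0, viab=100.0,
             dna_a=150.0, dna_w=150.0, dna_cv=0.5),
        _pop("doublet", doublet_frac, fsc_a=200.0, fsc_h=100.0,
             dna_a=200.0, dna_w=150.0, dna_cv=0.2),
    ]


def _lognormal(rng: np.random.Generator, mean: float, cv: float,
               size: int) -> np.ndarray:
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def simulate_well_events(populations: Sequence[PopulationSpec], n_events: int,
                         seed: int) -> Tuple[pd.DataFrame, np.ndarray]:
    """Draw one well's event table from the planted mixture.

    Returns ``(events, labels)``: a DataFrame with columns ``event_id`` plus
    the six channels, and the per-event true-population name array
    (ground truth, not written into the event table itself).
    """
    if not populations:
        raise ValueError("population list must not be empty")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    weights = np.array([p.weight for p in populations], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"population weights sum to {weights.sum()}, not 1")
    rng = np.random.default_rng(seed)
    labels_idx = rng.choice(len(populations), size=n_events, p=weights)
    data = {ch: np.empty(n_events) for ch in CHANNELS}
    for i, pop in enumerate(populations):
        idx = np.flatnonzero(labels_idx == i)
        if idx.size == 0:
            continue
        fsc_a = _lognormal(rng, pop.channel_means["FSC_A"],
                           pop.channel_cvs["FSC_A"], idx.size)
        ratio = pop.channel_means["FSC_H"] / pop.channel_means["FSC_A"]
        fsc_h = fsc_a * ratio * _lognormal(rng, 1.0,
                                           pop.channel_cvs["FSC_H"], idx.size)
        data["FSC_A"][idx] = fsc_a
        data["FSC_H"][idx] = fsc_h
        for ch in ("SSC_A", "VIAB", "DNA_A", "DNA_W"):
            data[ch][idx] = _lognormal(rng, pop.channel_means[ch],
                                       pop.channel_cvs[ch], idx.size)
    events = pd.DataFrame({"event_id": np.arange(n_events), **data})
    labels = np.array([populations[i].name for i in labels_idx])
    return events, labels


# --- whole-screen simulation -------------------------------------------------

@dataclass(frozen=True)
class StrainSpec:
    """One strain: its planted kinetics and cell-cycle schedule.

    ``g0_by_day`` maps day -> G0 fraction of live singlets; days not listed
    use the value of the latest listed day not after them.  The remaining
    live fraction splits G2:G1/M as ``g2_of_rest`` : (1 - g2_of_rest).
    """

    strain_id: str
    trajectory: TrajectorySpec
    g0_by_day: Mapping[float, float]
    g2_of_rest: float = 0.7

    def cycle_fractions(self, day: float) -> Tuple[float, float, float]:
        days = sorted(self.g0_by_day)
        g0 = self.g0_by_day[days[0]]
        for d in days:
            if d <= day:
                g0 = self.g0_by_day[d]
        rest = 1.0 - g0
        return g0, rest * self.g2_of_rest, rest * (1.0 - self.g2_of_rest)


@dataclass
class ScreenConfig:
    strains: List[StrainSpec]
    control_id: str
    days: Tuple[float, ...] = (0.0, 1.0, 7.0, 14.0, 21.0, 28.0)
    n_events: int = 20000
    doublet_frac: float = 0.05

    def __post_init__(self):
        ids = [s.strain_id for s in self.strains]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate strain_id in screen config")
        if not self.strains:
            raise ValueError("screen config names no strains")
        if self.control_id not in ids:
            raise ValueError(f"control strain {self.control_id!r} not in strains")


@dataclass
class ScreenGroundTruth:
    """Planted parameters of a simulated screen (reproducibility record)."""

    seed: int
    control_id: str
    strains: Dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"seed": self.seed, "control_id": self.control_id,
                "strains": self.strains}


def well_seed(global_seed: int, strain_id: str, day: float) -> int:
    """Derived integer substream seed for one well (< 2**31), stable across
    runs and platforms: CRC32 of the strain id plus the day, mixed through a
    SeedSequence."""
    ss = np.random.SeedSequence(
        [int(global_seed), zlib.crc32(strain_id.encode()),
         int(round(day * 1000)) & 0xFFFFFFFF])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class WellData:
    strain_id: str
    day: float
    events: pd.DataFrame
    labels: np.ndarray
    weights: Dict[str, float]


def simulate_screen(config: ScreenConfig, seed: int
                    ) -> Tuple[Dict[Tuple[str, float], WellData], ScreenGroundTruth]:
    """Simulate event tables for every (strain, day) well plus ground truth."""
    truth = ScreenGroundTruth(seed=seed, control_id=config.control_id)
    wells: Dict[Tuple[str, float], WellData] = {}
    for strain in config.strains:
        spec = TrajectorySpec(strain.trajectory.model_id, strain.trajectory.params,
                              tuple(config.days), strain.trajectory.noise_sd)
        traj = simulate_trajectory(spec, well_seed(seed, strain.strain_id, -1.0))
        model_vals = [float(evaluate_model(spec.model_id, spec.params, d))
                      for d in config.days]
        strain_truth = {
            "model_id": spec.model_id,
            "params": list(spec.params),
            "noise_sd": spec.noise_sd,
            "mortality_model": dict(zip(map(float, config.days), model_vals)),
            "mortality_planted": {d: m for d, m in traj},
            "wells": {},
        }
        for day, mort in traj:
            key = (strain.strain_id, day)
            if key in wells:
                raise ValueError(f"duplicate (strain, day) key {key}")
            g0, g2, g1m = strain.cycle_fractions(day)
            pops = default_populations(mort / 100.0, g0, g2, g1m,
                                       config.doublet_frac)
            events, labels = simulate_well_events(
                pops, config.n_events, well_seed(seed, strain.strain_id, day))
            weights = {p.name: p.weight for p in pops}
            wells[key] = WellData(strain.strain_id, day, events, labels, weights)
            strain_truth["wells"][float(day)] = weights
        truth.strains[strain.strain_id] = strain_truth
    return wells, truth


# --- built-in archetypes ------------------------------------------------------

@dataclass(frozen=True)
class Archetype:
    """A quiescence-phenotype class used to assemble demo screens."""

    name: str
    model_id: str
    params: Tuple[float, ...]
    g0_day1: float
    g0_day7: float
    g2_day0_of_rest: float = 0.7


#: Seven phenotype archetypes spanning the screen's observed behaviors:
#: control-like slow mortality, fast death with normal G0 entry, intermediate
#: sigmoid death, strong and mild G0-entry defects, a high-G2 class, and a
#: low-asymptote class whose curve never reaches 99% (exercises censoring).
ARCHETYPES: Tuple[Archetype, ...] = (
    Archetype("control_like", "exp2p", (2.0, 0.08), 0.70, 0.80),
    Archetype("fast_death", "exp2p", (10.0, 0.25), 0.70, 0.55),
    Archetype("sigmoid_death", "logistic3p", (100.0, 0.3, 18.0), 0.70, 0.75),
    Archetype("entry_defect_strong", "gompertz3p", (90.0, 0.2, 25.0), 0.10, 0.20, 0.85),
    Archetype("entry_defect_mild", "exp3p", (3.0, 2.0, 0.08), 0.35, 0.50),
    Archetype("high_g2", "mech_growth", (100.0, 0.97, 0.05), 0.60, 0.70, 0.95),
    Archetype("low_asymptote", "probit4p", (80.0, 0.25, 14.0, 3.0), 0.55, 0.65),
)


def make_archetype_screen(n_per_archetype: int = 2, noise_sd: float = 2.0,
                          n_events: int = 20000, seed: int = 0,
                          days: Sequence[float] = (0, 1, 7, 14, 21, 28),
                          doublet_frac: float = 0.05) -> ScreenConfig:
    """Build a screen config with jittered strains from the seven archetypes.

    The first control-like strain is named ``smt0`` and serves as the
    wild-type control.  Parameter jitter (5% relative) and G0-schedule jitter
    make strains within an archetype distinct but clusterable.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA5C]))
    strains: List[StrainSpec] = []
    for arch in ARCHETYPES:
        for i in range(n_per_archetype):
            if arch.name == "control_like" and i == 0:
                sid, params, g0d1, g0d7 = "smt0", arch.params, arch.g0_day1, arch.g0_day7
            else:
                sid = f"{arch.name}_{i:02d}"
                params = tuple(p * (1.0 + 0.05 * rng.standard_normal())
                               for p in arch.params)
                g0d1 = float(np.clip(arch.g0_day1 + 0.03 * rng.standard_normal(),
                                     0.01, 0.95))
                g0d7 = float(np.clip(arch.g0_day7 + 0.03 * rng.standard_normal(),
                                     0.01, 0.95))
            traj = TrajectorySpec(arch.model_id, params, tuple(float(d) for d in days),
                                  noise_sd)
            strains.append(StrainSpec(sid, traj,
                                      {0.0: 0.03, 1.0: g0d1, 7.0: g0d7},
                                      g2_of_rest=arch.g2_day0_of_rest))
    return ScreenConfig(strains=strains, control_id="smt0",
                        days=tuple(float(d) for d in days),
                        n_events=n_events, doublet_frac=doublet_frac)


#: Archetype centroids in standardized feature space for the five clustering
#: features (t50, t25, g2_day0, g0_day1, g0_day7); entries are z units.
PHENOTYPE_ARCHETYPE_MEANS = np.array([
    [1.0, 1.0, 0.0, 1.0, 1.0],     # control-like survivors
    [-1.0, -1.0, 0.0, 1.0, 1.0],   # mild mortality, normal entry
    [-2.0, -2.0, 0.0, 1.0, -1.0],  # strong mortality
    [1.0, 1.0, 1.0, -2.0, -2.0],   # strong G0-entry defect
    [0.0, 0.0, 1.0, -1.0, -1.0],   # mild entry defect
    [0.0, 1.0, 2.0, 0.0, 0.0],     # high vegetative G2
    [-1.0, 0.0, -2.0, 0.0, 1.0],   # miscellaneous
])


def simulate_phenotype_archetypes(n_per_archetype: int = 20,
                                  separation: float = 6.0,
                                  seed: int = 0
                                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Draw a planted phenotype matrix with 7 archetype blobs.

    Gaussian noise sd is scaled so the minimum pairwise centroid distance is
    ``separation`` noise-sd units.  Returns ``(X, labels)`` with X of shape
    (7 * n_per_archetype, 5).
    """
    means = PHENOTYPE_ARCHETYPE_MEANS
    dists = [np.linalg.norm(means[i] - means[j])
             for i in range(len(means)) for j in range(i + 1, len(means))]
    sd = min(dists) / separation
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for k, mu in enumerate(means):
        blocks.append(mu + sd * rng.standard_normal((n_per_archetype, means.shape[1])))
        labels.extend([k] * n_per_archetype)
    return np.vstack(blocks), np.array(labels)
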