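"""Gating cascade for per-well event tables.

The cascade mirrors the screen's acquisition gates:

1. **Doublet exclusion** — singlets have FSC-H ~ FSC-A; particles whose
   H/A ratio falls outside the singlet band (doublets double FSC-A but not
   FSC-H) are removed.
2. **Viability** — the amine-reactive dye marks dead cells; singlets split
   into live/dead on the VIAB channel; mortality% = dead / (dead + live).
3. **DNA content** — live singlets classify by quadrant on (DNA-A, DNA-W):
   G0 = low/low, G2 = high/low, G1/M (binuclear) = high/high; the low/high
   quadrant (e.g. S-phase oddities) stays unclassified rather than being
   forced into a class.

"auto" thresholds are placed by minimizing within-class variance of the
log-intensity over a two-class split (the exact order-statistics version of
Otsu's rule).  When the split quality (between-class variance fraction) is
below ``min_split_quality`` the distribution is effectively unimodal, the
configured fixed fallback threshold is used instead, and the well is
flagged.  All thresholds used are recorded in the summary for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd

Threshold = Union[str, float]  # "auto" or a fixed intensity


@dataclass(frozen=True)
class GateParams:
    singlet_ratio_band: Tuple[float, float] = (0.7, 1.3)
    viability_threshold: Threshold = "auto"
    dna_a_split: Threshold = "auto"
    dna_w_split: Threshold = "auto"
    min_singlets: int = 1000
    #: fixed fallbacks when an "auto" split degenerates (geometric midpoints
    #: of the default simulator geometry)
    fallback_viability_threshold: float = 31.6
    fallback_dna_a_split: float = 141.4
    fallback_dna_w_split: float = 141.4
    #: minimum between-class variance fraction for an auto split to count
    min_split_quality: float = 0.8

    def __post_init__(self):
        lo, hi = self.singlet_ratio_band
        if not lo < hi:
            raise ValueError("singlet_ratio_band must be a nonempty interval")
        if self.min_singlets < 1:
            raise ValueError("min_singlets must be >= 1")


@dataclass
class WellSummary:
    """Gated fractions for one well."""

    n_events: int
    n_singlets: int
    n_doublets: int
    n_live: int
    n_dead: int
    mortality_pct: float
    g0_pct: float
    g2_pct: float
    g1m_pct: float
    unclassified_pct: float
    qc_pass: bool
    thresholds: Dict[str, float] = field(default_factory=dict)
    anomalies: Dict[str, int] = field(default_factory=dict)
    flags: Tuple[str, ...] = ()


REQUIRED_CHANNELS = ("FSC_A", "FSC_H", "SSC_A", "VIAB", "DNA_A", "DNA_W")


def _validate_events(events: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_CHANNELS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing channels: {missing}")
    if len(events) == 0:
        raise ValueError("event table is empty")
    if events[list(REQUIRED_CHANNELS)].isna().any().any():
        raise ValueError("event table contains missing channel values")


def two_class_split(values: np.ndarray) -> Tuple[float, float]:
    """Exact two-class minimum-within-variance split of log-intensities.

    Returns ``(threshold, quality)`` where the threshold is on the original
    intensity scale (midpoint between the flanking order statistics on the
    log scale) and quality is the between-class variance fraction of the
    log values (1 = perfectly separated, ~0.64 for a single Gaussian).
    """
    x = np.sort(np.log(values[values > 0]))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return float(np.exp(x[0])) if n else float("nan"), 0.0
    cum = np.cumsum(x)
    total = cum[-1]
    mean = total / n
    i = np.arange(1, n)
    m1 = cum[:-1] / i
    m2 = (total - cum[:-1]) / (n - i)
    between = i * (m1 - mean) ** 2 + (n - i) * (m2 - mean) ** 2
    j = int(np.argmax(between))
    split = j + 1  # first class is x[:split]
    thr_log = 0.5 * (x[split - 1] + x[split])
    total_ss = float(np.sum((x - mean) ** 2))
    quality = float(between[j] / total_ss) if total_ss > 0 else 0.0
    return float(np.exp(thr_log)), quality


def _resolve_threshold(values: np.ndarray, setting: Threshold, fallback: float,
                       min_quality: float) -> Tuple[float, bool]:
    """Resolve an "auto" threshold; returns (threshold, used_fallback)."""
    if setting != "auto":
        return float(setting), False
    thr, quality = two_class_split(values)
    if not np.isfinite(thr) or quality < min_quality:
        return fallback, True
    return thr, False


def gate_singlets(events: pd.DataFrame, params: GateParams
                  ) -> Tuple[pd.DataFrame, pd.DataFrame, int]:
    """Partition events into singlets and doublets by the FSC-H/FSC-A band.

    Events with zero FSC-A cannot form a ratio; they are assigned to the
    doublet class and counted in the returned anomaly tally.
    """
    _validate_events(events)
    lo, hi = params.singlet_ratio_band
    fsc_a = events["FSC_A"].to_numpy(dtype=float)
    zero = fsc_a <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(zero, np.nan, events["FSC_H"].to_numpy(dtype=float) / fsc_a)
    is_singlet = (ratio >= lo) & (ratio <= hi) & ~zero
    return events[is_singlet], events[~is_singlet], int(zero.sum())


def gate_viability(singlets: pd.DataFrame, params: GateParams
                   ) -> Tuple[pd.DataFrame, pd.DataFrame, float, Dict]:
    """Split singlets into live/dead on the viability-dye channel.

    Returns ``(live, dead, mortality_pct, info)``; ``info`` records the
    threshold used and whether the auto split fell back to the fixed value.
    """
    if len(singlets) == 0:
        raise ValueError("gate_viability requires at least one singlet")
    viab = singlets["VIAB"].to_numpy(dtype=float)
    thr, fellback = _resolve_threshold(viab, params.viability_threshold,
                                       params.fallback_viability_threshold,
                                       params.min_split_quality)
    dead_mask = viab > thr
    live, dead = singlets[~dead_mask], singlets[dead_mask]
    mortality = 100.0 * len(dead) / len(singlets)
    return live, dead, mortality, {"viability_threshold": thr,
                                   "viability_fallback": fellback}


def gate_dna_content(live_singlets: pd.DataFrame, params: GateParams
                     ) -> Tuple[float, float, float, float, Dict]:
    """Classify live singlets into G0 / G2 / G1M quadrants on (DNA-A, DNA-W).

    Returns percentages of live singlets ``(g0, g2, g1m, unclassified)``
    plus split info.  The DNA-A split separates 1C from 2C; the DNA-W split
    separates mononuclear from binuclear among 2C particles.
    """
    if len(live_singlets) == 0:
        raise ValueError("gate_dna_content requires at least one live singlet")
    dna_a = live_singlets["DNA_A"].to_numpy(dtype=float)
    dna_w = live_singlets["DNA_W"].to_numpy(dtype=float)
    a_thr, a_fb = _resolve_threshold(dna_a, params.dna_a_split,
                                     params.fallback_dna_a_split,
                                     params.min_split_quality)
    w_thr, w_fb = _resolve_threshold(dna_w, params.dna_w_split,
                                     params.fallback_dna_w_split,
                                     params.min_split_quality)
    n = len(live_singlets)
    low_a, low_w = dna_a <= a_thr, dna_w <= w_thr
    g0 = 100.0 * np.sum(low_a & low_w) / n
    g2 = 100.0 * np.sum(~low_a & low_w) / n
    g1m = 100.0 * np.sum(~low_a & ~low_w) / n
    uncl = 100.0 * np.sum(low_a & ~low_w) / n
    info = {"dna_a_split": a_thr, "dna_a_fallback": a_fb,
            "dna_w_split": w_thr, "dna_w_fallback": w_fb}
    return float(g0), float(g2), float(g1m), float(uncl), info


def summarize_well(events: pd.DataFrame, params: GateParams = GateParams()
                   ) -> WellSummary:
    """Run the full gating cascade on one well and summarize it.

    ``qc_pass`` is False when fewer than ``min_singlets`` single cells were
    recovered; fractions are still reported but flagged.
    """
    singlets, doublets, n_zero = gate_singlets(events, params)
    flags = []
    anomalies = {"zero_fsc_a": n_zero}
    thresholds: Dict[str, float] = {}
    if len(singlets) == 0:
        flags.append("no_singlets")
        return WellSummary(len(events), 0, len(doublets), 0, 0,
                           float("nan"), 0.0, 0.0, 0.0, 0.0, False,
                           thresholds, anomalies, tuple(flags))
    live, dead, mortality, vinfo = gate_viability(singlets, params)
    thresholds["viability"] = vinfo["viability_threshold"]
    if vinfo["viability_fallback"]:
        flags.append("viability_auto_fallback")
    if len(live) == 0:
        flags.append("no_live_cells")
        g0 = g2 = g1m = uncl = 0.0
    else:
        g0, g2, g1m, uncl, dinfo = gate_dna_content(live, params)
        thresholds["dna_a"] = dinfo["dna_a_split"]
        thresholds["dna_w"] = dinfo["dna_w_split"]
        if dinfo["dna_a_fallback"]:
            flags.append("dna_a_auto_fallback")
        if dinfo["dna_w_fallback"]:
            flags.append("dna_w_auto_fallback")
    qc = len(singlets) >= params.min_singlets
    if not qc:
        flags.append("below_min_singlets")
    return WellSummary(
        n_events=len(events), n_singlets=len(singlets),
        n_doublets=len(doublets), n_live=len(live), n_dead=len(dead),
        mortality_pct=float(mortality), g0_pct=g0, g2_pct=g2, g1m_pct=g1m,
        unclassified_pct=uncl, qc_pass=qc, thresholds=thresholds,
        anomalies=anomalies, flags=tuple(flags))
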