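"""End-to-end orchestration: simulate -> gate -> fit -> cluster -> enrich.

A :class:`RunConfig` fully determines a run; identical config + seed gives
byte-identical output tables.  Every output file carries the config hash in
a header comment, QC exclusions are enumerated in the run report and log,
and each stage writes a table the next stage can consume, so stages are
independently re-runnable from the CLI.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as qio
from .clustering import (FEATURES, build_phenotype_matrix, cluster_phenotypes,
                         records_to_matrix)
from .enrichment import cluster_enrichment, read_catalog
from .fitting import (UnfittableStrainError, fit_all_models,
                      halflife_confidence_interval, select_model)
from .gating import GateParams, summarize_well
from .simulate import make_archetype_screen, simulate_screen

log = logging.getLogger("quiescreen")


def _from_dict(cls, d: dict):
    if d is None:
        return cls()
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown config keys {sorted(unknown)}")
    return cls(**d)


@dataclass
class SimulateOptions:
    n_per_archetype: int = 2
    n_events: int = 20000
    doublet_frac: float = 0.05
    noise_sd: float = 2.0
    days: Tuple[float, ...] = (0.0, 1.0, 7.0, 14.0, 21.0, 28.0)


@dataclass
class GateOptions:
    singlet_ratio_band: Tuple[float, float] = (0.7, 1.3)
    viability_threshold: object = "auto"
    dna_a_split: object = "auto"
    dna_w_split: object = "auto"
    min_singlets: int = 1000

    def to_params(self) -> GateParams:
        return GateParams(tuple(self.singlet_ratio_band),
                          self.viability_threshold, self.dna_a_split,
                          self.dna_w_split, self.min_singlets)


@dataclass
class FitOptions:
    horizon: float = 1000.0
    n_starts: int = 8
    ci_level: float = 50.0
    n_boot: int = 0  # bootstrap CIs off by default (expensive)


@dataclass
class ClusterOptions:
    k_min: int = 2
    k_max: int = 15
    standardize: bool = True
    censored_policy: str = "horizon"


@dataclass
class EnrichOptions:
    catalog: Optional[str] = None
    background: Optional[str] = None


@dataclass
class RunConfig:
    seed: int = 0
    event_dir: Optional[str] = None  # gate existing tables instead of simulating
    layout: Optional[str] = None
    simulate: SimulateOptions = field(default_factory=SimulateOptions)
    gating: GateOptions = field(default_factory=GateOptions)
    fitting: FitOptions = field(default_factory=FitOptions)
    clustering: ClusterOptions = field(default_factory=ClusterOptions)
    enrichment: EnrichOptions = field(default_factory=EnrichOptions)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"RunConfig: unknown config keys {sorted(unknown)}")
        sub = {"simulate": SimulateOptions, "gating": GateOptions,
               "fitting": FitOptions, "clustering": ClusterOptions,
               "enrichment": EnrichOptions}
        kwargs = {}
        for key, val in d.items():
            kwargs[key] = _from_dict(sub[key], val) if key in sub else val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(qio.load_yaml(path))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return qio.config_hash(self.to_dict())


def _provenance(config: RunConfig) -> str:
    return f"quiescreen config={config.hash()} seed={config.seed}"


def stage_simulate(config: RunConfig, outdir: Path) -> pd.DataFrame:
    """Simulate the archetype screen and write per-well event tables."""
    sim = config.simulate
    screen = make_archetype_screen(
        n_per_archetype=sim.n_per_archetype, noise_sd=sim.noise_sd,
        n_events=sim.n_events, seed=config.seed, days=sim.days,
        doublet_frac=sim.doublet_frac)
    wells, truth = simulate_screen(screen, config.seed)
    events_dir = outdir / "events"
    layout_rows = []
    for i, ((sid, day), well) in enumerate(sorted(wells.items())):
        fname = f"{sid}_d{day:g}.csv"
        qio.write_event_table(well.events, events_dir / fname,
                              _provenance(config))
        layout_rows.append({"strain_id": sid, "well": f"W{i:03d}", "day": day,
                            "path": f"events/{fname}"})
    layout = pd.DataFrame(layout_rows)
    qio.write_table(layout, outdir / "layout.csv", _provenance(config))
    qio.write_ground_truth(truth.to_dict(), outdir / "ground_truth.json")
    log.info("simulated %d wells for %d strains", len(wells),
             len(screen.strains))
    return layout


def stage_gate(config: RunConfig, outdir: Path,
               layout: pd.DataFrame, events_root: Path) -> pd.DataFrame:
    """Gate every well listed in the layout into a summary table."""
    params = config.gating.to_params()
    rows = []
    for row in layout.itertuples(index=False):
        path = events_root / row.path if hasattr(row, "path") else (
            events_root / f"{row.strain_id}_d{row.day:g}.csv")
        try:
            result = qio.read_event_table(path)
            summary = summarize_well(result.events, params)
        except (ValueError, OSError) as exc:
            raise RuntimeError(
                f"gating failed for strain {row.strain_id} day {row.day}: {exc}"
            ) from exc
        rows.append(qio.summary_to_row(row.strain_id, float(row.day), summary))
    summaries = pd.DataFrame(rows)
    qio.write_table(summaries, outdir / "well_summaries.csv",
                    _provenance(config))
    n_fail = int((~summaries["qc_pass"]).sum())
    if n_fail:
        bad = summaries.loc[~summaries["qc_pass"], ["strain_id", "day"]]
        log.warning("QC failures (below min singlets): %s",
                    bad.to_dict("records"))
    return summaries


def stage_fit(config: RunConfig, outdir: Path,
              summaries: pd.DataFrame) -> pd.DataFrame:
    """Fit the seven models per strain and select the optimal one.

    QC-failed wells are dropped (missing time points), not imputed.
    """
    opts = config.fitting
    rows = []
    for sid, grp in summaries.groupby("strain_id"):
        ok = grp[grp["qc_pass"].astype(bool)].sort_values("day")
        days = ok["day"].to_numpy(float)
        y = ok["mortality_pct"].to_numpy(float)
        try:
            fits = fit_all_models(days, y, horizon=opts.horizon,
                                  n_starts=opts.n_starts)
            best = select_model(fits, horizon=opts.horizon)
        except (UnfittableStrainError, ValueError) as exc:
            log.warning("strain %s unfittable: %s", sid, exc)
            continue
        row = {"strain_id": sid, "model_id": best.model_id,
               "params": ";".join(f"{p:.10g}" for p in best.params),
               "rss": best.rss, "r2": best.r2, "fit_zscore": best.fit_zscore,
               "n_obs": best.n_obs,
               "t25": best.t25.value, "t25_censored": best.t25.censored,
               "t50": best.t50.value, "t50_censored": best.t50.censored,
               "t99": best.t99.value, "t99_censored": best.t99.censored,
               "horizon": opts.horizon}
        if opts.n_boot > 0 and not best.t50.censored:
            ci = halflife_confidence_interval(
                best, days, y, level=opts.ci_level, n_boot=opts.n_boot,
                seed=config.seed, horizon=opts.horizon)
            row.update({"t50_ci_low": ci.low, "t50_ci_high": ci.high,
                        "t50_ci_reliable": ci.reliable})
        rows.append(row)
    fit_table = pd.DataFrame(rows)
    qio.write_table(fit_table, outdir / "fits.csv", _provenance(config))
    return fit_table


def stage_cluster(config: RunConfig, outdir: Path, fit_table: pd.DataFrame,
                  summaries: pd.DataFrame):
    """Assemble phenotypes, Ward-cluster and pick k by CCC."""
    copts = config.clustering
    records, exclusions = build_phenotype_matrix(
        fit_table, summaries, censored_policy=copts.censored_policy)
    for sid, reason in exclusions.items():
        log.warning("excluded from clustering: %s (%s)", sid, reason)
    if len(records) < 3:
        raise RuntimeError("clustering needs >= 3 complete phenotype records")
    k_hi = min(copts.k_max, len(records) - 1)
    model = cluster_phenotypes(records, k_range=range(copts.k_min, k_hi + 1),
                               standardize=copts.standardize)
    assign = pd.DataFrame({"strain_id": [r.strain_id for r in records],
                           "cluster": model.assignments})
    qio.write_table(assign, outdir / "assignments.csv", _provenance(config))
    ccc = pd.DataFrame(sorted(model.ccc_by_k.items()), columns=["k", "ccc"])
    qio.write_table(ccc, outdir / "ccc_by_k.csv", _provenance(config))
    merge = pd.DataFrame(model.linkage,
                         columns=["left", "right", "height", "size"])
    qio.write_table(merge, outdir / "merge_sequence.csv", _provenance(config))
    X = records_to_matrix(records)
    prof = pd.DataFrame(X, columns=FEATURES)
    prof["cluster"] = model.assignments
    profiles = prof.groupby("cluster").mean().reset_index()
    qio.write_table(profiles, outdir / "cluster_profiles.csv",
                    _provenance(config))
    return records, model, exclusions


def stage_enrich(config: RunConfig, outdir: Path,
                 assignments: pd.DataFrame) -> Optional[pd.DataFrame]:
    """Category enrichment per cluster; skipped when no catalog is given."""
    eopts = config.enrichment
    if not eopts.catalog:
        log.info("no category catalog configured; enrichment stage skipped")
        return None
    catalog = read_catalog(eopts.catalog, eopts.background)
    mapping = dict(zip(assignments["strain_id"], assignments["cluster"]))
    table = cluster_enrichment(mapping, catalog)
    qio.write_table(table, outdir / "enrichment.csv", _provenance(config))
    return table


def run_pipeline(config: RunConfig, outdir) -> Dict[str, object]:
    """Run every stage; returns the key artifacts in memory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        (outdir / "config.yaml").write_text(
            __import__("yaml").safe_dump(config.to_dict(), sort_keys=True))
        if config.event_dir:
            layout = qio.read_layout(config.layout)
            events_root = Path(config.event_dir)
        else:
            layout = stage_simulate(config, outdir)
            events_root = outdir
        summaries = stage_gate(config, outdir, layout, events_root)
        fit_table = stage_fit(config, outdir, summaries)
        records, model, exclusions = stage_cluster(config, outdir, fit_table,
                                                   summaries)
        assignments = pd.DataFrame(
            {"strain_id": [r.strain_id for r in records],
             "cluster": model.assignments})
        enrich = stage_enrich(config, outdir, assignments)
        report = [
            f"quiescreen run report (config {config.hash()}, seed {config.seed})",
            f"wells gated: {len(summaries)}",
            f"wells failing QC (<{config.gating.min_singlets} singlets): "
            f"{int((~summaries['qc_pass']).sum())}",
            f"strains fitted: {len(fit_table)}",
            f"strains clustered: {len(records)}",
            f"clustering exclusions: {exclusions or 'none'}",
            f"chosen number of clusters (CCC): {model.chosen_k}",
            f"max CCC: {max(model.ccc_by_k.values()):.3f}",
            f"enrichment rows: {'skipped' if enrich is None else len(enrich)}",
        ]
        (outdir / "report.txt").write_text("\n".join(report) + "\n")
        log.info("pipeline complete; chosen_k=%d", model.chosen_k)
        return {"summaries": summaries, "fits": fit_table, "records": records,
                "cluster_model": model, "enrichment": enrich,
                "outdir": outdir}
    finally:
        log.removeHandler(handler)
        handler.close()
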