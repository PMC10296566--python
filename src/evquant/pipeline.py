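"""End-to-end orchestration of the EV spectral-counting analysis.

Stages: simulate (or ingest) -> species filter -> aggregate -> normalize ->
condition aPSM -> repeatability -> frequency filter -> MAProMa comparisons
and common trends -> F-ratio screen -> clustering/PCA -> PTM rates ->
combined selection -> summary JSON. Every stage writes its outputs to the
run directory, so any downstream stage can be resumed from disk, and the
summary digest is reproducible for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io, maproma, multivariate, ptm, quantify, simulate


@dataclass
class PipelineConfig:
    """Full parameter set of one pipeline run (echoed into the summary)."""

    outdir: str = "evquant_out"
    # input: either simulate on the fly, or read PSM tables + design
    simulate: bool = True
    psm_tables: list[str] = field(default_factory=list)
    design_path: str | None = None
    keep_species: str = "human"
    dave_threshold: float = maproma.DAVE_THRESHOLD
    dci_threshold: float = maproma.DCI_THRESHOLD
    f_min: float = multivariate.F_MIN
    p_max: float = multivariate.P_MAX
    min_conditions: int = 2
    screen_grouping: str = "condition"
    min_support: int | None = None  # common trend: None = all comparisons
    seed: int = 0
    # simulator overrides (only used when simulate=True)
    sim: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("dave_threshold", "dci_threshold", "f_min", "p_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.simulate and (not self.psm_tables or self.design_path is None):
            raise ValueError("need psm_tables and design_path when simulate=False")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def simulation_config(self) -> simulate.SimulationConfig:
        return simulate.SimulationConfig(seed=self.seed, **self.sim)


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the machine-readable summary dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(msg: str) -> None:
        log.append(msg)

    # -- input ------------------------------------------------------------
    if config.simulate:
        sim_cfg = config.simulation_config()
        tables, truth = simulate.simulate_experiment(sim_cfg)
        design = sim_cfg.resolved_design()
        design.to_tsv(outdir / "design.tsv")
        truth.to_json(outdir / "ground_truth.json")
        psm = pd.concat(tables.values(), ignore_index=True)
        stage(f"simulate: {len(tables)} runs, {len(psm)} PSMs (seed {config.seed})")
    else:
        frames = [io.read_psm_frame(p) for p in config.psm_tables]
        psm = pd.concat(frames, ignore_index=True)
        design = io.ConditionDesign.from_tsv(config.design_path)
        stage(f"ingest: {len(frames)} tables, {len(psm)} PSMs")

    n_psm_total = len(psm)

    # -- species filter ----------------------------------------------------
    kept, removed = io.filter_species(psm, keep=config.keep_species)
    removed_fraction = removed / n_psm_total if n_psm_total else 0.0
    stage(
        f"filter_species: kept {len(kept)} {config.keep_species} PSMs, "
        f"removed {removed} ({100 * removed_fraction:.1f}%)"
    )

    # -- aggregate + normalize + average -----------------------------------
    raw = io.aggregate_counts(kept, design)
    raw.to_tsv(outdir / "counts_raw.tsv")
    norm = quantify.normalize_runs(raw)
    norm.to_tsv(outdir / "counts_normalized.tsv")
    apsm = quantify.average_condition(norm, design)
    apsm.to_tsv(outdir / "apsm_conditions.tsv")
    stage(
        f"quantify: {len(raw.proteins)} proteins x {len(raw.columns)} runs "
        f"-> {len(apsm.columns)} conditions"
    )

    # -- repeatability ------------------------------------------------------
    repeat = {}
    for kind in ("technical", "biological"):
        try:
            summary = quantify.repeatability_r2(norm, design, kind)
            repeat[kind] = {
                "mean_r2": summary.mean_r2,
                "sd_r2": summary.sd_r2,
                "n_pairs": len(summary.r2_values),
            }
        except ValueError:
            repeat[kind] = None
    stage(f"repeatability: {repeat}")

    # -- frequency filter ----------------------------------------------------
    frequent = quantify.frequency_filter(apsm, config.min_conditions)
    stage(f"frequency_filter: {len(frequent)} proteins in >= {config.min_conditions} conditions")

    # -- MAProMa comparisons --------------------------------------------------
    specs = maproma.comparison_family(
        design, config.dave_threshold, config.dci_threshold
    )
    dep_counts = {}
    bpa_family = []
    all_deps: set[str] = set()
    for spec in specs:
        calls = maproma.compare(apsm.restrict(frequent), spec)
        maproma.write_comparison(calls, outdir / f"compare_{spec.name}.tsv")
        deps = [c.protein for c in calls if c.is_dep]
        dep_counts[spec.name] = len(deps)
        all_deps.update(deps)
        if "_vs_BPA-" in spec.name:
            bpa_family.append(calls)
    trend = (
        maproma.common_trend(bpa_family, config.min_support)
        if len(bpa_family) >= 2
        else {"up_in_X": set(), "up_in_Y": set()}
    )
    pd.DataFrame(
        [
            {"direction": d, "protein": p}
            for d, ps in trend.items()
            for p in sorted(ps)
        ]
    ).to_csv(outdir / "common_trend.tsv", sep="\t", index=False)
    stage(f"maproma: {len(specs)} comparisons, {len(all_deps)} distinct DEPs")

    # -- F screen + clustering + PCA -------------------------------------------
    screen = multivariate.f_screen(
        norm.restrict(frequent), design, config.screen_grouping,
        config.f_min, config.p_max,
    )
    multivariate.screen_to_frame(screen).to_csv(
        outdir / "f_screen.tsv", sep="\t", index=False
    )
    retained = multivariate.retained_proteins(screen)
    stage(f"f_screen: {len(retained)} proteins retained of {len(screen)}")

    newick = None
    pca_info = None
    if len(retained) >= 1:
        dend = multivariate.cluster(norm.restrict(retained))
        newick = dend.to_newick()
        (outdir / "dendrogram_runs.nwk").write_text(newick + "\n")
        pca_res = multivariate.pca(apsm.restrict(retained))
        pca_res.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        pca_info = {
            "explained_variance_ratio": [
                float(v) for v in pca_res.explained_variance_ratio[:5]
            ]
        }
        stage("multivariate: dendrogram + PCA written")

    combined = multivariate.combine_selections(retained, all_deps)
    pd.DataFrame(
        [
            {"protein": p, "sources": "+".join(sorted(src))}
            for p, src in sorted(combined.items())
        ]
    ).to_csv(outdir / "combined_selection.tsv", sep="\t", index=False)

    # -- PTM ---------------------------------------------------------------
    contrasts = _dose_contrasts(design)
    report = ptm.ptm_report(kept, design, contrasts)
    report.to_csv(outdir / "ptm_report.tsv", sep="\t", index=False)
    met = ptm.ptm_rate(kept, "Met")
    tyr = ptm.ptm_rate(kept, "Tyr")
    ratio = ptm.contribution_ratio(met, tyr)
    stage(
        f"ptm: Met {met.modified_psms}/{met.containing_psms}, "
        f"Tyr {tyr.modified_psms}/{tyr.containing_psms}"
    )

    summary = {
        "parameters": {
            k: v for k, v in asdict(config).items() if k != "outdir"
        },
        "n_runs": len(design),
        "n_conditions": len(design.condition_labels),
        "n_psms_total": int(n_psm_total),
        "n_psms_kept": int(len(kept)),
        "removed_species_fraction": removed_fraction,
        "n_proteins": len(raw.proteins),
        "n_proteins_frequent": len(frequent),
        "repeatability": repeat,
        "n_comparisons": len(specs),
        "deps_per_comparison": dep_counts,
        "n_deps_total": len(all_deps),
        "common_trend_up_in_bpa_plus": sorted(trend["up_in_X"]),
        "common_trend_up_in_bpa_minus": sorted(trend["up_in_Y"]),
        "n_retained_f_screen": len(retained),
        "n_combined_selection": len(combined),
        "pca": pca_info,
        "ptm": {
            "met_rate": met.rate,
            "tyr_rate": tyr.rate,
            "met_tyr_contribution_ratio": ratio,
        },
    }
    summary["digest"] = _digest(summary)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    return summary


def _dose_contrasts(design: io.ConditionDesign) -> list[tuple[str, str]]:
    """0 Gy vs highest dose at each harvest time, within BPA+ if present."""
    table = design.condition_table()
    contrasts = []
    bpa = "plus" if (table["bpa"] == "plus").any() else "minus"
    sub = table[table["bpa"] == bpa]
    doses = sorted(sub["dose_gy"].unique())
    if len(doses) < 2:
        return []
    lo, hi = doses[0], doses[-1]
    for harvest in sorted(sub["harvest_h"].unique()):
        a = sub[(sub["dose_gy"] == lo) & (sub["harvest_h"] == harvest)]
        b = sub[(sub["dose_gy"] == hi) & (sub["harvest_h"] == harvest)]
        if len(a) and len(b):
            contrasts.append(
                (a["condition"].iloc[0], b["condition"].iloc[0])
            )
    return contrasts
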