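"""PSM-level simulator for the 72-run BNCT EV proteomics design.

The generator emulates the statistical structure of a label-free
spectral-counting experiment on extracellular vesicles harvested from
FBS-containing culture medium:

* a human proteome whose per-run PSM counts follow a negative-binomial law
  around log-normally distributed baseline abundances,
* a small bovine contaminant proteome carrying a configurable fraction of
  the total PSM mass, half of it on a single albumin-like protein,
* planted differentially expressed proteins (DEPs) whose abundance is
  multiplied by a fold in every BPA+ condition (optionally with a per-dose
  trend),
* biological replicates that jitter protein abundance (log-normal), while
  technical replicates are pure resampling noise — so technical R^2 exceeds
  biological R^2,
* per-PSM peptides drawn from a fixed tryptic-like pool per protein, with
  Bernoulli Met-oxidation / Tyr-nitrosylation flags at condition-specific
  rates (the Met rate may rise at the highest dose, 11.3 Gy).

Everything needed to score recovery — planted folds, the expected DAve
2(f-1)/(f+1) each fold implies, and the per-condition modification rates —
is returned as a machine-readable :class:`GroundTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ConditionDesign, CountMatrix, PSM_COLUMNS, write_psm_frame

HIGH_DOSE_GY = 11.3
_AA_POOL = list("ACDEFGHILNPQSTVW")  # M and Y inserted separately


def expected_dave(fold: float) -> float:
    """DAve implied by a fold change f: 2(f-1)/(f+1), bounded in (-2, 2)."""
    return 2.0 * (fold - 1.0) / (fold + 1.0)


@dataclass
class SimulationConfig:
    """Study conditions of the simulated experiment.

    Defaults reproduce the 12-condition x 3-biorep x 2-techrep layout with
    ~50% FBS contaminant PSM mass and pooled Met/Tyr modification rates of
    11.5% and 10.3%.
    """

    n_human_proteins: int = 1000
    n_bovine_proteins: int = 20
    contaminant_psm_fraction: float = 0.5
    design: ConditionDesign | None = None
    base_abundance_log_mean: float = 0.0
    base_abundance_log_sd: float = 1.5
    dispersion: float = 0.005
    depth_per_run: float = 20000.0
    n_dep: int = 50
    dep_fold: float = 2.0
    dose_trend_fold: float | None = None
    met_ox_rate: float = 0.115
    tyr_no2_rate: float = 0.103
    met_ox_rate_high_dose: float = 0.14
    bio_sd: float = 0.12
    peptides_per_protein: int = 8
    met_occurrence: float = 0.5
    tyr_occurrence: float = 0.5
    seed: int = 0

    def resolved_design(self) -> ConditionDesign:
        return self.design if self.design is not None else ConditionDesign.default()

    def validate(self) -> None:
        if not 0 <= self.contaminant_psm_fraction < 1:
            raise ValueError("contaminant_psm_fraction must be in [0, 1)")
        if self.n_dep > self.n_human_proteins:
            raise ValueError("n_dep exceeds n_human_proteins")
        for name in ("met_ox_rate", "tyr_no2_rate", "met_ox_rate_high_dose"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dep_fold <= 0:
            raise ValueError("dep_fold must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.depth_per_run <= 0:
            raise ValueError("depth_per_run must be > 0")
        self.resolved_design()  # raises on invalid design


@dataclass
class GroundTruth:
    """Planted effects of one simulated experiment."""

    seed: int
    dep_proteins: dict[str, dict]
    modification_rates: dict[str, dict[str, float]]
    contaminant_psm_fraction: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _condition_met_rate(config: SimulationConfig, dose_gy: float) -> float:
    if dose_gy == HIGH_DOSE_GY:
        return config.met_ox_rate_high_dose
    return config.met_ox_rate


def _protein_universe(config: SimulationConfig, rng: np.random.Generator):
    """Baseline expected PSM count per protein per run, plus identities."""
    h = config.n_human_proteins
    b = config.n_bovine_proteins if config.contaminant_psm_fraction > 0 else 0
    human_acc = [f"HP_{i:05d}" for i in range(1, h + 1)]
    human_gene = [f"GENE{i:04d}" for i in range(1, h + 1)]
    rel = rng.lognormal(
        config.base_abundance_log_mean, config.base_abundance_log_sd, size=h
    )
    human_mass = config.depth_per_run * (1.0 - config.contaminant_psm_fraction)
    mu_human = human_mass * rel / rel.sum()

    if b > 0:
        bov_acc = ["BV_ALB"] + [f"BV_{i:04d}" for i in range(2, b + 1)]
        bov_gene = ["ALB"] + [f"BGEN{i:03d}" for i in range(2, b + 1)]
        # albumin-like protein takes half the contaminant mass
        w = rng.lognormal(0.0, 1.0, size=b - 1) if b > 1 else np.array([])
        bov_mass = config.depth_per_run * config.contaminant_psm_fraction
        if b == 1:
            mu_bov = np.array([bov_mass])
        else:
            mu_bov = np.concatenate([[0.5 * bov_mass], 0.5 * bov_mass * w / w.sum()])
    else:
        bov_acc, bov_gene, mu_bov = [], [], np.array([])

    accessions = human_acc + bov_acc
    genes = human_gene + bov_gene
    species = ["human"] * h + ["bovine"] * len(bov_acc)
    mu0 = np.concatenate([mu_human, mu_bov])
    return accessions, genes, species, mu0


def _plant_deps(
    config: SimulationConfig, rng: np.random.Generator, accessions, mu0
) -> dict[str, dict]:
    dep_idx = rng.choice(config.n_human_proteins, size=config.n_dep, replace=False)
    deps: dict[str, dict] = {}
    for i in sorted(int(j) for j in dep_idx):
        deps[accessions[i]] = {
            "fold": config.dep_fold,
            "direction": "up_in_bpa_plus",
            "expected_dave": expected_dave(config.dep_fold),
            "baseline_mean": float(mu0[i]),
        }
    return deps


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw the protein x run count matrix (no per-PSM expansion).

    This is the generative core: :func:`simulate_experiment` expands exactly
    these counts into per-spectrum rows.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = config.resolved_design()
    accessions, _genes, species, mu0 = _protein_universe(config, rng)
    deps = _plant_deps(config, rng, accessions, mu0)
    dep_mask = np.array([a in deps for a in accessions])

    dose_rank = {d: r for r, d in enumerate(sorted(design.frame["dose_gy"].unique()))}
    cond = design.condition_of()
    n_prot = len(accessions)

    # biological jitter: one log-normal factor per (human protein, condition
    # cell, biorep); bovine serum background gets resampling noise only
    jitter_cache: dict[tuple[str, int], np.ndarray] = {}
    cells = design.frame.copy()
    cells["condition"] = cond.values
    for key in (
        cells[["condition", "biorep"]].drop_duplicates().itertuples(index=False)
    ):
        fac = np.ones(n_prot)
        human = np.array([s == "human" for s in species])
        fac[human] = rng.lognormal(0.0, config.bio_sd, size=human.sum())
        jitter_cache[(key.condition, key.biorep)] = fac

    counts = np.zeros((n_prot, len(design)), dtype=np.int64)
    for j, row in enumerate(design.frame.itertuples(index=False)):
        label = ConditionDesign.condition_label(row.bpa, row.dose_gy, row.harvest_h)
        mu = mu0.copy()
        if row.bpa == "plus":
            factor = config.dep_fold
            if config.dose_trend_fold is not None:
                factor = factor * config.dose_trend_fold ** dose_rank[row.dose_gy]
            mu[dep_mask] *= factor
        mu = mu * jitter_cache[(label, row.biorep)]
        if config.dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            shape = 1.0 / config.dispersion
            lam = rng.gamma(shape, mu * config.dispersion)
            counts[:, j] = rng.poisson(lam)

    mod_rates = {
        ConditionDesign.condition_label(r.bpa, r.dose_gy, r.harvest_h): {
            "Met": _condition_met_rate(config, r.dose_gy),
            "Tyr": config.tyr_no2_rate,
        }
        for r in design.condition_table().itertuples(index=False)
    }
    truth = GroundTruth(
        seed=config.seed,
        dep_proteins=deps,
        modification_rates=mod_rates,
        contaminant_psm_fraction=config.contaminant_psm_fraction,
    )
    matrix = CountMatrix(
        pd.DataFrame(counts.astype(float), index=accessions, columns=design.run_ids),
        "run",
        pd.Series(species, index=accessions),
    )
    return matrix, truth


def _peptide_pool(config: SimulationConfig, rng: np.random.Generator, n_proteins: int):
    """Fixed tryptic-like peptides per protein with known Met/Tyr content."""
    k = config.peptides_per_protein
    peptides: list[list[str]] = []
    has_met = np.zeros((n_proteins, k), dtype=bool)
    has_tyr = np.zeros((n_proteins, k), dtype=bool)
    for i in range(n_proteins):
        pool = []
        for p in range(k):
            length = int(rng.integers(7, 21))
            body = rng.choice(_AA_POOL, size=length - 1)
            if rng.random() < config.met_occurrence:
                body[int(rng.integers(0, length - 1))] = "M"
            if rng.random() < config.tyr_occurrence:
                # overwrite a position that is not the M we just placed
                pos = int(rng.integers(0, length - 1))
                if body[pos] == "M":
                    pos = (pos + 1) % (length - 1)
                body[pos] = "Y"
            pep = "".join(body) + ("K" if rng.random() < 0.5 else "R")
            pool.append(pep)
            has_met[i, p] = "M" in pep
            has_tyr[i, p] = "Y" in pep
        peptides.append(pool)
    return peptides, has_met, has_tyr


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Generate one PSM table per run of the design, plus the ground truth.

    Deterministic: identical config (including seed) gives byte-identical
    tables when written with :func:`evquant.io.write_psm_frame`.
    """
    counts, truth = simulate_counts(config)
    design = config.resolved_design()
    # a second, independent stream for the PSM-level expansion so that the
    # counts layer is reproducible on its own
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    accessions = counts.proteins
    species = counts.species
    genes = {}
    for acc in accessions:
        if acc.startswith("HP_"):
            genes[acc] = f"GENE{int(acc.split('_')[1]):04d}"
        elif acc == "BV_ALB":
            genes[acc] = "ALB"
        else:
            genes[acc] = f"BGEN{int(acc.split('_')[1]):03d}"
    peptides, has_met, has_tyr = _peptide_pool(config, rng, len(accessions))

    cond = design.condition_of()
    dose_of_run = dict(zip(design.frame["run_id"], design.frame["dose_gy"]))
    acc_arr = np.array(accessions)
    sp_arr = species.values.astype(object)
    gene_arr = np.array([genes[a] for a in accessions], dtype=object)

    tables: dict[str, pd.DataFrame] = {}
    for run in design.run_ids:
        n_per_protein = counts.data[run].to_numpy().astype(np.int64)
        prot_idx = np.repeat(np.arange(len(accessions)), n_per_protein)
        n = len(prot_idx)
        pep_idx = rng.integers(0, config.peptides_per_protein, size=n)
        met_rate = _condition_met_rate(config, dose_of_run[run])
        pep_has_met = has_met[prot_idx, pep_idx]
        pep_has_tyr = has_tyr[prot_idx, pep_idx]
        met_ox = pep_has_met & (rng.random(n) < met_rate)
        tyr_no2 = pep_has_tyr & (rng.random(n) < config.tyr_no2_rate)
        peps = np.array(
            [peptides[i][j] for i, j in zip(prot_idx, pep_idx)], dtype=object
        )
        tables[run] = pd.DataFrame(
            {
                "run_id": run,
                "protein_accession": acc_arr[prot_idx],
                "species": sp_arr[prot_idx],
                "gene_symbol": gene_arr[prot_idx],
                "peptide": peps,
                "met_oxidized": met_ox,
                "tyr_nitrosylated": tyr_no2,
            },
            columns=PSM_COLUMNS,
        )
    return tables, truth


def write_experiment(
    config: SimulationConfig, outdir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Emit per-run PSM TSVs, the design table and ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables, truth = simulate_experiment(config)
    design = config.resolved_design()
    design.to_tsv(outdir / "design.tsv")
    paths: dict[str, Path] = {}
    for run, frame in tables.items():
        path = outdir / f"psm_{run}.tsv"
        write_psm_frame(frame, path)
        paths[run] = path
    truth.to_json(outdir / "ground_truth.json")
    return paths, truth


def write_fasta_pair(
    config: SimulationConfig, outdir: str | Path
) -> dict[str, Path]:
    """Synthetic human/bovine FASTA pair matching the simulated accessions.

    Protein sequences are the concatenated peptide pool of each protein —
    synthetic stand-ins sufficient for accession -> species mapping.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, _ = simulate_counts(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    peptides, _, _ = _peptide_pool(config, rng, len(counts.proteins))
    paths = {}
    for species in ("human", "bovine"):
        path = outdir / f"{species}_synthetic.fasta"
        with open(path, "w") as fh:
            for i, acc in enumerate(counts.proteins):
                if counts.species[acc] != species:
                    continue
                fh.write(f">{acc} synthetic {species} protein\n")
                fh.write("".join(peptides[i]) + "\n")
        paths[species] = path
    return paths
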