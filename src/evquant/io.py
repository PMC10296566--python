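"""PSM tables, experimental design and count matrices.

The atomic unit of quantification is the PSM (peptide spectrum match): one
fragmentation spectrum assigned to a peptide of one protein in one LC-MS run.
PSM tables are plain TSV, one row per spectrum, with the header

    run_id  protein_accession  species  gene_symbol  peptide  met_oxidized  tyr_nitrosylated

Species is one of ``human``, ``bovine``, ``other``; in culture-medium EV
preparations the bovine rows are fetal-bovine-serum carry-over (dominated by
serum albumin) and are filtered out before quantification.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

SPECIES = ("human", "bovine", "other")

PSM_COLUMNS = [
    "run_id",
    "protein_accession",
    "species",
    "gene_symbol",
    "peptide",
    "met_oxidized",
    "tyr_nitrosylated",
]

DESIGN_COLUMNS = [
    "run_id",
    "bpa",
    "dose_gy",
    "irradiation_min",
    "harvest_h",
    "biorep",
    "techrep",
]

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")
MIN_PEPTIDE_LENGTH = 6

_TRUE_TOKENS = {"1", "true", "True", "TRUE", True, 1}
_FALSE_TOKENS = {"0", "false", "False", "FALSE", False, 0}


class PsmParseError(ValueError):
    """Raised when a PSM table violates the format contract."""


@dataclass(frozen=True)
class PsmRecord:
    """One identified spectrum.

    ``has_met`` / ``has_tyr`` are derived from the peptide sequence; a
    modification flag may only be set when the residue is present.
    """

    run_id: str
    protein_accession: str
    species: str
    gene_symbol: str
    peptide: str
    met_oxidized: bool
    tyr_nitrosylated: bool

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise PsmParseError(
                f"unknown species {self.species!r} for {self.protein_accession}"
            )
        if len(self.peptide) < MIN_PEPTIDE_LENGTH or not _AA_RE.match(self.peptide):
            raise PsmParseError(
                f"invalid peptide {self.peptide!r} (uppercase amino acids, "
                f"length >= {MIN_PEPTIDE_LENGTH})"
            )
        if self.met_oxidized and not self.has_met:
            raise PsmParseError(
                f"met_oxidized set but peptide {self.peptide!r} lacks M"
            )
        if self.tyr_nitrosylated and not self.has_tyr:
            raise PsmParseError(
                f"tyr_nitrosylated set but peptide {self.peptide!r} lacks Y"
            )

    @property
    def has_met(self) -> bool:
        return "M" in self.peptide

    @property
    def has_tyr(self) -> bool:
        return "Y" in self.peptide


def _coerce_flag(series: pd.Series, name: str) -> pd.Series:
    out = pd.Series(index=series.index, dtype=bool)
    truthy = series.isin(_TRUE_TOKENS)
    falsy = series.isin(_FALSE_TOKENS)
    bad = ~(truthy | falsy)
    if bad.any():
        line = int(series.index[bad][0]) + 2  # header + 1-based
        raise PsmParseError(f"non-boolean value for {name} at line {line}")
    out[:] = truthy
    return out


def validate_psm_frame(frame: pd.DataFrame, *, source: str = "<frame>") -> pd.DataFrame:
    """Validate (and coerce) a PSM DataFrame against the format contract."""
    missing = [c for c in PSM_COLUMNS if c not in frame.columns]
    if missing:
        raise PsmParseError(f"{source}: missing column(s) {missing}")
    frame = frame[PSM_COLUMNS].copy().reset_index(drop=True)
    frame["gene_symbol"] = frame["gene_symbol"].fillna("").astype(str)
    for col in ("run_id", "protein_accession", "species", "peptide"):
        frame[col] = frame[col].astype(str)
    for col in ("met_oxidized", "tyr_nitrosylated"):
        frame[col] = _coerce_flag(frame[col], col)

    bad_species = ~frame["species"].isin(SPECIES)
    if bad_species.any():
        line = int(frame.index[bad_species][0]) + 2
        tok = frame.loc[frame.index[bad_species][0], "species"]
        raise PsmParseError(f"{source}: unknown species {tok!r} at line {line}")
    pep = frame["peptide"]
    bad_pep = (pep.str.len() < MIN_PEPTIDE_LENGTH) | ~pep.str.match(_AA_RE)
    if bad_pep.any():
        line = int(frame.index[bad_pep][0]) + 2
        raise PsmParseError(
            f"{source}: invalid peptide {pep[frame.index[bad_pep][0]]!r} at line {line}"
        )
    has_met = pep.str.contains("M", regex=False)
    has_tyr = pep.str.contains("Y", regex=False)
    bad_ox = frame["met_oxidized"] & ~has_met
    if bad_ox.any():
        line = int(frame.index[bad_ox][0]) + 2
        raise PsmParseError(f"{source}: met_oxidized without Met at line {line}")
    bad_no2 = frame["tyr_nitrosylated"] & ~has_tyr
    if bad_no2.any():
        line = int(frame.index[bad_no2][0]) + 2
        raise PsmParseError(f"{source}: tyr_nitrosylated without Tyr at line {line}")
    return frame


def read_psm_frame(path: str | Path) -> pd.DataFrame:
    """Read a PSM table into a validated DataFrame (one row per spectrum)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return validate_psm_frame(frame, source=str(path))


def read_psm_table(path: str | Path) -> list[PsmRecord]:
    frame = read_psm_frame(path)
    return frame_to_records(frame)


def write_psm_frame(frame: pd.DataFrame, path: str | Path) -> None:
    frame = validate_psm_frame(frame)
    out = frame.copy()
    for col in ("met_oxidized", "tyr_nitrosylated"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False)


def write_psm_table(records: Iterable[PsmRecord], path: str | Path) -> None:
    write_psm_frame(records_to_frame(records), path)


def records_to_frame(records: Iterable[PsmRecord]) -> pd.DataFrame:
    rows = [
        (
            r.run_id,
            r.protein_accession,
            r.species,
            r.gene_symbol,
            r.peptide,
            r.met_oxidized,
            r.tyr_nitrosylated,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[PsmRecord]:
    return [
        PsmRecord(
            row.run_id,
            row.protein_accession,
            row.species,
            row.gene_symbol,
            row.peptide,
            bool(row.met_oxidized),
            bool(row.tyr_nitrosylated),
        )
        for row in frame.itertuples(index=False)
    ]


def _as_frame(records: pd.DataFrame | Iterable[PsmRecord]) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


def filter_species(
    records: pd.DataFrame | Iterable[PsmRecord], keep: str = "human"
) -> tuple[pd.DataFrame, int]:
    """Keep only PSMs of one species; returns (kept frame, n removed).

    Mirrors the exclusion of bovine (FBS) identifications before label-free
    comparison.
    """
    if keep not in SPECIES:
        raise ValueError(f"unknown species {keep!r}; expected one of {SPECIES}")
    frame = _as_frame(records)
    unknown = ~frame["species"].isin(SPECIES)
    if unknown.any():
        offending = sorted(frame.loc[unknown, "protein_accession"].unique())
        raise PsmParseError(f"unknown species token(s) for accessions {offending}")
    mask = frame["species"] == keep
    removed = int((~mask).sum())
    kept = frame[mask].reset_index(drop=True)
    if kept.empty:
        warnings.warn(f"no PSMs of species {keep!r} remain after filtering")
    return kept, removed


def map_species_from_fasta(
    records: pd.DataFrame | Iterable[PsmRecord],
    fasta_paths: dict[str, str | Path],
) -> pd.DataFrame:
    """Populate the species column from per-species FASTA files.

    ``fasta_paths`` maps a species label to a FASTA path; the accession is the
    first whitespace-delimited token of each FASTA header. Every accession in
    the records must occur in exactly one FASTA.
    """
    accession_species: dict[str, str] = {}
    for species, path in fasta_paths.items():
        if species not in SPECIES:
            raise ValueError(f"unknown species label {species!r}")
        for rec in SeqIO.parse(str(path), "fasta"):
            acc = rec.id
            if acc in accession_species and accession_species[acc] != species:
                raise PsmParseError(
                    f"accession {acc} present in more than one species FASTA"
                )
            accession_species[acc] = species
    frame = _as_frame(records).copy()
    unmapped = sorted(
        set(frame["protein_accession"]) - set(accession_species)
    )
    if unmapped:
        raise PsmParseError(f"accession(s) absent from every FASTA: {unmapped}")
    frame["species"] = frame["protein_accession"].map(accession_species)
    return frame


class ConditionDesign:
    """Run -> condition mapping for the BNCT EV study layout.

    The default design is 2 BPA arms x 3 neutron doses (0 Gy / 0 min,
    1.9 Gy / 10 min, 11.3 Gy / 60 min) x 2 EV harvest times (6 h, 24 h),
    each cell with 3 biological replicates analysed in 2 technical runs:
    72 runs over 12 conditions.
    """

    DOSE_IRRADIATION = {0.0: 0.0, 1.9: 10.0, 11.3: 60.0}
    HARVESTS = (6.0, 24.0)

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in DESIGN_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"design table missing column(s) {missing}")
        frame = frame[DESIGN_COLUMNS].copy().reset_index(drop=True)
        frame["run_id"] = frame["run_id"].astype(str)
        frame["bpa"] = frame["bpa"].astype(str)
        bad = ~frame["bpa"].isin(("minus", "plus"))
        if bad.any():
            raise ValueError(
                f"bpa must be 'minus' or 'plus', got {sorted(frame.loc[bad, 'bpa'].unique())}"
            )
        for col in ("dose_gy", "irradiation_min", "harvest_h"):
            frame[col] = frame[col].astype(float)
        for col in ("biorep", "techrep"):
            frame[col] = frame[col].astype(int)
        if frame["run_id"].duplicated().any():
            dup = sorted(frame.loc[frame["run_id"].duplicated(), "run_id"].unique())
            raise ValueError(f"duplicate run id(s) in design: {dup}")
        if frame.empty:
            raise ValueError("design table is empty")
        self.frame = frame

    @staticmethod
    def condition_label(bpa: str, dose_gy: float, harvest_h: float) -> str:
        sign = "+" if bpa == "plus" else "-"
        return f"BPA{sign}_{dose_gy:g}Gy_{harvest_h:g}h"

    @classmethod
    def default(cls, n_biorep: int = 3, n_techrep: int = 2) -> "ConditionDesign":
        rows = []
        for bpa in ("minus", "plus"):
            for dose, irr in cls.DOSE_IRRADIATION.items():
                for harvest in cls.HARVESTS:
                    for b in range(1, n_biorep + 1):
                        for t in range(1, n_techrep + 1):
                            label = cls.condition_label(bpa, dose, harvest)
                            rows.append(
                                (f"{label}_b{b}_t{t}", bpa, dose, irr, harvest, b, t)
                            )
        return cls(pd.DataFrame(rows, columns=DESIGN_COLUMNS))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def run_ids(self) -> list[str]:
        return list(self.frame["run_id"])

    def condition_of(self) -> pd.Series:
        """run_id -> condition label, in design order."""
        labels = [
            self.condition_label(r.bpa, r.dose_gy, r.harvest_h)
            for r in self.frame.itertuples(index=False)
        ]
        return pd.Series(labels, index=self.frame["run_id"].values, name="condition")

    @property
    def condition_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.condition_of():
            seen.setdefault(lab)
        return list(seen)

    def runs_of(self, condition: str) -> list[str]:
        cond = self.condition_of()
        runs = [r for r, c in cond.items() if c == condition]
        if not runs:
            raise ValueError(f"condition {condition!r} has zero runs")
        return runs

    def condition_table(self) -> pd.DataFrame:
        """One row per condition cell with its factor levels."""
        frame = self.frame.copy()
        frame["condition"] = self.condition_of().values
        return (
            frame[["condition", "bpa", "dose_gy", "irradiation_min", "harvest_h"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConditionDesign":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class CountMatrix:
    """Protein x column spectral-count table.

    ``column_kind`` is ``"run"`` for raw/normalized per-run PSM counts and
    ``"condition"`` for condition-averaged aPSM profiles. ``species`` is an
    optional per-protein annotation aligned to ``data.index``.
    """

    data: pd.DataFrame
    column_kind: str = "run"
    species: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.column_kind not in ("run", "condition"):
            raise ValueError(f"bad column_kind {self.column_kind!r}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate protein ids")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate column ids")
        if (self.data.values < 0).any():
            raise ValueError("negative counts")
        if self.species is not None:
            self.species = self.species.reindex(self.data.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def restrict(self, proteins: Sequence[str]) -> "CountMatrix":
        keep = [p for p in self.proteins if p in set(proteins)]
        sp = self.species.loc[keep] if self.species is not None else None
        return CountMatrix(self.data.loc[keep], self.column_kind, sp)

    def total(self) -> float:
        return float(self.data.values.sum())

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "protein", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, column_kind: str = "run") -> "CountMatrix":
        frame = pd.read_csv(path, sep="\t")
        frame = frame.set_index("protein")
        frame.index.name = None
        return cls(frame, column_kind)


def aggregate_counts(
    records: pd.DataFrame | Iterable[PsmRecord], design: ConditionDesign
) -> CountMatrix:
    """Count PSMs per protein per run (proteins absent from a run get 0)."""
    frame = _as_frame(records)
    known = set(design.run_ids)
    stray = sorted(set(frame["run_id"]) - known)
    if stray:
        raise ValueError(f"run id(s) not in design: {stray}")
    table = (
        frame.groupby(["protein_accession", "run_id"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=design.run_ids, fill_value=0)
    )
    table.index.name = None
    table.columns.name = None
    species = None
    if "species" in frame.columns:
        species = (
            frame.drop_duplicates("protein_accession")
            .set_index("protein_accession")["species"]
            .reindex(table.index)
        )
    return CountMatrix(table.astype(float), "run", species)
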