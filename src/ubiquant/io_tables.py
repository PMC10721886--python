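"""Readers and writers for the tabular and sequence formats the pipeline touches.

Protein-group and peptide evidence tables follow the MaxQuant tab-separated
dialect: per-sample intensity columns named ``LFQ intensity <sample>`` /
``iBAQ <sample>``, decoy rows flagged ``+`` in a ``Reverse`` column,
contaminants in ``Potential contaminant``, site-only identifications in
``Only identified by site``. Zero or blank intensities both mean "not
quantified in this sample".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .design import SampleDesign

__all__ = [
    "ProteinTable",
    "PeptideTable",
    "ProteinSequences",
    "read_protein_groups",
    "read_peptide_table",
    "read_fasta",
    "write_results",
    "read_results",
]

FLAG_COLUMNS = {
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "site_only": "Only identified by site",
}


@dataclass
class ProteinTable:
    """One row per protein group, with per-sample linear-scale intensities.

    ``lfq`` and ``ibaq`` are proteins x samples DataFrames (0 = missing);
    ``flags`` holds the boolean reverse/contaminant/site_only columns;
    ``protein_ids`` the semicolon-joined accession list per row. Row index
    (the first accession of each group) is unique.
    """

    protein_ids: pd.Series
    gene_names: pd.Series
    flags: pd.DataFrame
    lfq: pd.DataFrame
    ibaq: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        idx = self.lfq.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein row identifiers: {dups}")
        for frame, name in ((self.lfq, "LFQ"), (self.ibaq, "iBAQ")):
            if list(frame.columns) != list(self.design.samples):
                raise ValueError(
                    f"{name} columns {list(frame.columns)} do not match design "
                    f"samples {list(self.design.samples)}"
                )
            if (frame.to_numpy() < 0).any():
                raise ValueError(f"negative {name} intensity encountered")

    def __len__(self) -> int:
        return len(self.lfq)

    @property
    def ids(self) -> pd.Index:
        return self.lfq.index

    def accessions(self, row_id: str) -> tuple[str, ...]:
        return tuple(self.protein_ids.loc[row_id].split(";"))

    def remove_flagged(
        self,
        *,
        reverse: bool = True,
        contaminant: bool = True,
        site_only: bool = True,
    ) -> "ProteinTable":
        """Drop decoy/contaminant/site-only rows (the conventional filter
        applied before quantification); each flag class is configurable."""
        drop = pd.Series(False, index=self.ids)
        if reverse:
            drop |= self.flags["reverse"]
        if contaminant:
            drop |= self.flags["contaminant"]
        if site_only:
            drop |= self.flags["site_only"]
        keep = ~drop
        return ProteinTable(
            protein_ids=self.protein_ids[keep],
            gene_names=self.gene_names[keep],
            flags=self.flags[keep],
            lfq=self.lfq[keep],
            ibaq=self.ibaq[keep],
            design=self.design,
        )


@dataclass
class PeptideTable:
    """Long-format peptide evidence: one row per (peptide, sample) observation."""

    df: pd.DataFrame  # columns: peptide_sequence, protein_ids, sample, intensity
    design: SampleDesign

    def __post_init__(self) -> None:
        required = {"peptide_sequence", "protein_ids", "sample", "intensity"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"peptide table missing columns: {sorted(missing)}")
        if (self.df["intensity"].to_numpy() < 0).any():
            raise ValueError("negative peptide intensity encountered")
        unknown = set(self.df["sample"]) - set(self.design.samples)
        if unknown:
            raise ValueError(f"peptide rows reference samples not in design: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class ProteinSequences:
    """Amino-acid sequences keyed by accession (UniProt ``db|ACC|name``
    headers reduce to the ACC field)."""

    records: dict[str, tuple[str, str]]  # accession -> (description, sequence)

    def __post_init__(self) -> None:
        for acc, (_, seq) in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence for accession {acc!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.items())

    def sequence(self, accession: str) -> str:
        return self.records[accession][1]


def _parse_accession(header_id: str) -> str:
    parts = header_id.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return header_id


def read_fasta(path) -> ProteinSequences:
    """Read a FASTA file into :class:`ProteinSequences`.

    The accession is the first whitespace-delimited header token, reduced to
    the ACC field for UniProt-style ``db|ACC|name`` identifiers.
    """
    records: dict[str, tuple[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = _parse_accession(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        if acc in records:
            raise ValueError(f"duplicate accession {acc!r} in FASTA")
        records[acc] = (rec.description, seq)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return ProteinSequences(records)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"Reverse": str}, low_memory=False)


def read_protein_groups(path, design: SampleDesign) -> ProteinTable:
    """Parse a protein-groups table into a :class:`ProteinTable`.

    Rows flagged reverse / contaminant / site-only are *marked*, not removed;
    removal is a separate configurable step (:meth:`ProteinTable.remove_flagged`).
    Zero intensities are preserved as zero (meaning missing).
    """
    raw = _read_tsv(path)
    id_col = "Protein IDs"
    if id_col not in raw.columns:
        raise ValueError(f"missing required column {id_col!r}")
    needed = [f"LFQ intensity {s}" for s in design.samples]
    needed += [f"iBAQ {s}" for s in design.samples]
    absent = [c for c in needed if c not in raw.columns]
    if absent:
        raise ValueError(f"missing required intensity column(s): {absent}")

    ids = raw[id_col].astype(str).str.split(";").str[0]
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein row identifiers: {dups}")
    index = pd.Index(ids, name="protein")

    def intensity_frame(prefix: str) -> pd.DataFrame:
        cols = {s: raw[f"{prefix} {s}"] for s in design.samples}
        frame = pd.DataFrame(cols).apply(pd.to_numeric, errors="coerce").fillna(0.0)
        frame.index = index
        if (frame.to_numpy() < 0).any():
            raise ValueError(f"negative {prefix} intensity in {path}")
        return frame.astype(float)

    flags = pd.DataFrame(index=index)
    for key, col in FLAG_COLUMNS.items():
        if col in raw.columns:
            flags[key] = (raw[col].astype(str).str.strip() == "+").to_numpy()
        else:
            flags[key] = False

    gene_col = "Gene names" if "Gene names" in raw.columns else None
    genes = raw[gene_col].fillna("") if gene_col else pd.Series("", index=raw.index)

    return ProteinTable(
        protein_ids=pd.Series(raw[id_col].astype(str).to_numpy(), index=index),
        gene_names=pd.Series(genes.astype(str).to_numpy(), index=index),
        flags=flags,
        lfq=intensity_frame("LFQ intensity"),
        ibaq=intensity_frame("iBAQ"),
        design=design,
    )


def read_peptide_table(path, design: SampleDesign) -> PeptideTable:
    """Parse a peptide evidence table into long format.

    Rows are keyed by raw file; raw files map to samples through
    ``design.raw_file_of`` when provided, otherwise raw-file names must be
    sample names. Blank intensities become 0.
    """
    raw = _read_tsv(path)
    for col in ("Sequence", "Proteins", "Raw file"):
        if col not in raw.columns:
            raise ValueError(f"missing required column {col!r}")
    if "Intensity" not in raw.columns:
        raise ValueError("missing required column 'Intensity'")

    raw_files = raw["Raw file"].astype(str)
    mapping = dict(design.raw_file_of) if design.raw_file_of else {s: s for s in design.samples}
    unmapped = sorted(set(raw_files) - set(mapping))
    if unmapped:
        raise ValueError(f"raw file(s) not mapped to any designed sample: {unmapped}")

    df = pd.DataFrame(
        {
            "peptide_sequence": raw["Sequence"].astype(str).to_numpy(),
            "protein_ids": raw["Proteins"].fillna("").astype(str).to_numpy(),
            "sample": raw_files.map(mapping).to_numpy(),
            "intensity": pd.to_numeric(raw["Intensity"], errors="coerce")
            .fillna(0.0)
            .to_numpy(),
        }
    )
    return PeptideTable(df=df, design=design)


# -- result output --------------------------------------------------------


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    *,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write result tables as TSV with a run-metadata JSON sidecar.

    Column order is preserved as given; two runs with the same inputs and
    seed produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise ValueError(f"not a writable directory: {out}")
    from . import __version__

    paths: dict[str, Path] = {}
    for name, df in tables.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=True)
        paths[name] = p
    meta = {
        "version": __version__,
        "seed": seed,
        "config": dict(config) if config is not None else None,
        "tables": {name: int(len(df)) for name, df in tables.items()},
    }
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    paths["run_metadata"] = meta_path
    return paths


def read_results(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results` (round-trip helper)."""
    return pd.read_csv(path, sep="\t", index_col=0)
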