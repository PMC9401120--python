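"""Reading, preprocessing and writing of clonotype tables.

Consumes MiTCR-style / AIRR-rearrangement-style tab-separated tables (one row
per CDR3beta nucleotide sequence with a read count, amino-acid sequence and
V/J calls) and applies the standard preprocessing pipeline:

1. optional downsampling of reads to a common depth (without replacement),
2. merging nucleotide sequences coding the same amino-acid sequence into one
   clonotype (V/J taken from the variant with the highest read count),
3. removal of copy-number-1 clonotypes (likely polymerase/sequencing errors).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Clonotype, NucleotideVariant, Repertoire

logger = logging.getLogger(__name__)

#: canonical internal column names
_CANON = ["nt_sequence", "read_count", "cdr3_aa", "v_segment", "j_segment"]

#: dialect -> {file column -> canonical column}
DIALECTS: dict[str, dict[str, str]] = {
    "mitcr": {
        "Read count": "read_count",
        "CDR3 nucleotide sequence": "nt_sequence",
        "CDR3 amino acid sequence": "cdr3_aa",
        "V segments": "v_segment",
        "J segments": "j_segment",
    },
    "airr": {
        "duplicate_count": "read_count",
        "junction": "nt_sequence",
        "junction_aa": "cdr3_aa",
        "v_call": "v_segment",
        "j_call": "j_segment",
    },
    "simple-tsv": {
        "count": "read_count",
        "nt": "nt_sequence",
        "aa": "cdr3_aa",
        "v": "v_segment",
        "j": "j_segment",
    },
}


class FormatError(ValueError):
    """Malformed or incomplete clonotype table."""


@dataclass
class RawSequenceTable:
    """Pre-merge representation: one row per nucleotide sequence."""

    df: pd.DataFrame  # columns _CANON, unique nt_sequence

    def __post_init__(self) -> None:
        missing = [c for c in _CANON if c not in self.df.columns]
        if missing:
            raise FormatError(f"missing columns: {missing}")
        if self.df["nt_sequence"].duplicated().any():
            raise FormatError("duplicate nt_sequence rows after merge")

    @property
    def total_reads(self) -> int:
        return int(self.df["read_count"].sum())

    def __len__(self) -> int:
        return len(self.df)


def read_clonotype_table(
    path: str | Path,
    dialect: str = "simple-tsv",
    drop_nonfunctional: bool = True,
) -> RawSequenceTable:
    """Read a tab-separated clonotype table in the given dialect.

    Duplicate nucleotide-sequence rows are merged by summing read counts.
    Rows whose amino-acid sequence contains ``*`` or ``_`` (stop codon /
    frameshift markers) are dropped as a safety filter when
    ``drop_nonfunctional`` is set; upstream processing normally removes them.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    colmap = DIALECTS[dialect]
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty input file") from None
    missing = [c for c in colmap if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: dialect {dialect!r} requires column(s) {missing}")
    df = df[list(colmap)].rename(columns=colmap)
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    df["read_count"] = df["read_count"].astype(np.int64)
    if (df["read_count"] < 1).any():
        raise FormatError(f"{path}: read counts must be >= 1")
    if drop_nonfunctional:
        bad = df["cdr3_aa"].str.contains(r"[*_]", regex=True)
        if bad.any():
            logger.info("%s: dropped %d nonfunctional rows", path, int(bad.sum()))
            df = df[~bad]
        if df.empty:
            raise FormatError(f"{path}: all rows nonfunctional")
    # merge duplicate nucleotide rows by summing reads
    df = (
        df.groupby("nt_sequence", as_index=False, sort=False)
        .agg(
            read_count=("read_count", "sum"),
            cdr3_aa=("cdr3_aa", "first"),
            v_segment=("v_segment", "first"),
            j_segment=("j_segment", "first"),
        )
    )
    return RawSequenceTable(df[_CANON].reset_index(drop=True))


def downsample_reads(
    table: RawSequenceTable, target_reads: int, seed: int
) -> RawSequenceTable:
    """Downsample the read pool to exactly ``target_reads`` reads.

    Sampling is without replacement from the pooled reads (multivariate
    hypergeometric over per-sequence counts); sequences reduced to zero reads
    are dropped. Deterministic given ``seed``.
    """
    total = table.total_reads
    if target_reads > total:
        raise ValueError(f"target_reads {target_reads} exceeds total reads {total}")
    if target_reads == total:
        return RawSequenceTable(table.df.copy())
    rng = np.random.default_rng(seed)
    counts = table.df["read_count"].to_numpy()
    new_counts = rng.multivariate_hypergeometric(counts, target_reads)
    df = table.df.copy()
    df["read_count"] = new_counts
    df = df[df["read_count"] > 0].reset_index(drop=True)
    return RawSequenceTable(df)


def merge_to_clonotypes(
    table: RawSequenceTable,
    sample_id: str = "",
    group_label: str = "",
    timepoint: str = "",
) -> Repertoire:
    """Merge nucleotide sequences coding identical amino-acid sequences.

    Each clonotype receives the summed read count of its members as copy
    number and the V/J segments of the member with the highest read count
    (ties broken by lexicographically smallest nucleotide sequence — the
    underlying study does not state a tie rule, so this is a documented
    deterministic convention).
    """
    if len(table) == 0:
        raise FormatError("cannot merge an empty table")
    clonotypes: list[Clonotype] = []
    for aa, grp in table.df.groupby("cdr3_aa", sort=False):
        variants = tuple(
            NucleotideVariant(nt, int(rc))
            for nt, rc in zip(grp["nt_sequence"], grp["read_count"])
        )
        # max read count, tie-break on smallest nt sequence
        top = min(variants, key=lambda v: (-v.read_count, v.nt_sequence))
        row = grp[grp["nt_sequence"] == top.nt_sequence].iloc[0]
        clonotypes.append(
            Clonotype(
                cdr3_aa=str(aa),
                v_segment=str(row["v_segment"]),
                j_segment=str(row["j_segment"]),
                copy_number=int(grp["read_count"].sum()),
                variants=variants,
            )
        )
    return Repertoire(sample_id, clonotypes, group_label, timepoint)


def remove_singletons(rep: Repertoire) -> Repertoire:
    """Drop clonotypes with copy number 1 (putative sequencing artefacts)."""
    kept = [c for c in rep.clonotypes if c.copy_number >= 2]
    if not kept:
        logger.warning("%s: repertoire empty after singleton removal", rep.sample_id)
    return Repertoire(rep.sample_id, kept, rep.group_label, rep.timepoint)


def write_repertoire(rep: Repertoire, path: str | Path, dialect: str = "simple-tsv") -> None:
    """Write a repertoire as a clonotype table, one row per nucleotide variant."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    inv = {v: k for k, v in DIALECTS[dialect].items()}
    rows = []
    for c in rep.clonotypes:
        if not c.variants:
            raise ValueError(
                f"clonotype {c.cdr3_aa!r} has no nucleotide variants; cannot be written"
            )
        for v in c.variants:
            rows.append(
                {
                    inv["nt_sequence"]: v.nt_sequence,
                    inv["read_count"]: v.read_count,
                    inv["cdr3_aa"]: c.cdr3_aa,
                    inv["v_segment"]: c.v_segment,
                    inv["j_segment"]: c.j_segment,
                }
            )
    cols = list(DIALECTS[dialect])
    df = pd.DataFrame(rows, columns=cols)
    try:
        df.to_csv(path, sep="\t", index=False)
    except OSError as e:
        raise OSError(f"cannot write repertoire to {path}: {e}") from e


def preprocess(
    path: str | Path,
    dialect: str = "simple-tsv",
    downsample_to: int | None = None,
    seed: int = 0,
    sample_id: str = "",
    group_label: str = "",
    timepoint: str = "",
) -> Repertoire:
    """Full preprocessing pipeline: read -> (downsample) -> merge -> drop CN-1."""
    table = read_clonotype_table(path, dialect)
    if downsample_to is not None and downsample_to < table.total_reads:
        table = downsample_reads(table, downsample_to, seed)
    rep = merge_to_clonotypes(
        table, sample_id=sample_id or Path(path).stem,
        group_label=group_label, timepoint=timepoint,
    )
    return remove_singletons(rep)
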