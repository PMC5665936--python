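"""Readers and writers for the plain-text formats used across the pipeline.

FASTA/FASTQ parsing is delegated to Biopython; writing is done locally so the
line-wrap width stays configurable.  Tabular outputs (alignments, edit
ledgers, dotplot segments) are documented TSVs handled with pandas.  All
coordinates in every emitted file are 0-based, half-open.  Gzipped inputs are
read transparently (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

_IUPAC_CHARS = set("ACGTRYSWKMBDHVN")


class FormatError(ValueError):
    """Malformed input file (message names the file and offending position)."""


@dataclass
class SeqRecord:
    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}")


@dataclass
class AlignmentRow:
    """One pairwise alignment, PAF-inspired flat record.

    ``edit_string`` is a CIGAR-like run-length string over =/X/I/D where I
    consumes query only and D consumes reference only.  Query coordinates
    refer to the query in its aligned orientation (reverse-complemented when
    strand is '-').
    """

    query_id: str
    ref_id: str
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    strand: str
    score: float
    identity: float
    mismap: float
    edit_string: str

    def __post_init__(self) -> None:
        if self.query_end < self.query_start or self.ref_end < self.ref_start:
            raise FormatError("interval end before start")
        if not 0.0 <= self.mismap <= 1.0:
            raise FormatError(f"mismap {self.mismap} outside [0, 1]")


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz" and "r" in mode:
        return gzip.open(path, mode)
    return open(path, mode)


def _clean_seq(seq: str, rec_id: str, path) -> str:
    seq = seq.upper().replace("U", "T")
    for i, c in enumerate(seq):
        if c not in _IUPAC_CHARS:
            raise FormatError(
                f"{path}: record {rec_id!r} has non-IUPAC character "
                f"{c!r} at position {i}")
    if not seq:
        raise FormatError(f"{path}: record {rec_id!r} has empty sequence")
    return seq


def read_fasta(path) -> list[SeqRecord]:
    with _open_text(path) as fh:
        recs = [SeqRecord(r.id, _clean_seq(str(r.seq), r.id, path))
                for r in SeqIO.parse(fh, "fasta")]
    if not recs:
        raise FormatError(f"{path}: no FASTA records found")
    return recs


def write_fasta(records: Iterable[SeqRecord], path, wrap: int = 60) -> None:
    records = list(records)
    if not records:
        raise FormatError("refusing to write empty FASTA")
    with open(path, "w") as fh:
        for r in records:
            if not r.sequence:
                raise FormatError(f"record {r.id!r} has empty sequence")
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), wrap):
                fh.write(r.sequence[i:i + wrap] + "\n")


def read_fastq(path) -> list[SeqRecord]:
    recs: list[SeqRecord] = []
    try:
        with _open_text(path) as fh:
            for r in SeqIO.parse(fh, "fastq"):
                qual = "".join(chr(q + 33) for q in r.letter_annotations["phred_quality"])
                recs.append(SeqRecord(r.id, _clean_seq(str(r.seq), r.id, path), qual))
    except ValueError as exc:  # Biopython signals truncation/length mismatch
        raise FormatError(f"{path}: {exc}") from exc
    if not recs:
        raise FormatError(f"{path}: no FASTQ records found")
    return recs


def write_fastq(records: Iterable[SeqRecord], path, default_quality: str = "I") -> None:
    records = list(records)
    if not records:
        raise FormatError("refusing to write empty FASTQ")
    with open(path, "w") as fh:
        for r in records:
            qual = r.quality if r.quality is not None else default_quality * len(r.sequence)
            if len(qual) != len(r.sequence):
                raise FormatError(f"record {r.id!r}: quality/sequence length mismatch")
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


ALIGNMENT_COLUMNS = ["query_id", "ref_id", "query_start", "query_end",
                     "ref_start", "ref_end", "strand", "score", "identity",
                     "mismap", "edit_string"]


def write_alignment_table(rows: Sequence[AlignmentRow], path) -> None:
    df = pd.DataFrame([asdict(r) for r in rows], columns=ALIGNMENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_alignment_table(path) -> list[AlignmentRow]:
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "ref_id": str,
                                            "strand": str, "edit_string": str})
    if list(df.columns) != ALIGNMENT_COLUMNS:
        raise FormatError(f"{path}: unexpected columns {list(df.columns)}")
    rows = []
    for rec in df.itertuples(index=False):
        d = rec._asdict()
        if min(d["query_start"], d["ref_start"]) < 0:
            raise FormatError(f"{path}: negative coordinate in row {d}")
        rows.append(AlignmentRow(**d))
    return rows


def write_bed(intervals: Sequence[tuple], path) -> None:
    """BED6 writer: tuples of (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            if start < 0 or end < start:
                raise FormatError(f"bad BED interval {chrom}:{start}-{end}")
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def locus_bed_intervals(locus) -> list[tuple]:
    """Truth annotation of a LocusSequence as BED6 tuples."""
    name = locus.preset.name
    rows = [(name, locus.flank5_iv.start, locus.flank5_iv.end, "flank5", 0, "+")]
    for i, iv in enumerate(locus.unit_ivs):
        rows.append((name, iv.start, iv.end, f"unit{i:03d}", 0, "+"))
    rows.append((name, locus.flank3_iv.start, locus.flank3_iv.end, "flank3", 0, "+"))
    for pos in locus.motif_positions:
        rows.append((name, pos, pos + 1, "motif_center", 0, "+"))
    return rows


DOTPLOT_COLUMNS = ["query_id", "ref_id", "query_start", "query_end",
                   "ref_start", "ref_end", "strand"]


def write_dotplot_tsv(segments: Sequence[tuple], path) -> None:
    """Segments are (query_id, ref_id, qs, qe, rs, re, strand) tuples."""
    df = pd.DataFrame(list(segments), columns=DOTPLOT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


LEDGER_COLUMNS = ["read_id", "locus_pos", "type", "ref", "alt"]


def write_ledger(reads, path) -> None:
    rows = [(r.read_id, pos, typ, ref, alt)
            for r in reads for (pos, typ, ref, alt) in r.edits]
    pd.DataFrame(rows, columns=LEDGER_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ledger(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       dtype={"read_id": str, "type": str, "ref": str, "alt": str})
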