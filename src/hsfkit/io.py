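"""Readers and writers for the plain-text formats the pipeline touches.

FASTA and GFF3 use 1-based inclusive coordinates end to end; conversions to
0-based happen only inside alignment internals.  The FASTA reader is
deliberately line-oriented so that format errors can name the offending line.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

DNA_ALPHABET = set("ACGTURYSWKMBDHVN-")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")


class FormatError(ValueError):
    """A structural problem in an input file (names the line when known)."""


@dataclass
class SequenceRecord:
    """A named sequence, either nucleotide or amino acid."""

    id: str
    sequence: str
    description: str = ""
    moltype: str = "dna"  # {"dna", "protein"}

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        alphabet = DNA_ALPHABET if self.moltype == "dna" else PROTEIN_ALPHABET
        bad = set(self.sequence) - alphabet
        if bad:
            raise FormatError(
                f"record {self.id!r}: characters {sorted(bad)} outside "
                f"{self.moltype} alphabet"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneLocus:
    """A gene's genomic placement (1-based inclusive)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise FormatError(f"{self.gene_id}: empty chromosome")
        if self.start > self.end:
            raise FormatError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")


def _infer_moltype(sequences: Iterable[str]) -> str:
    letters: set[str] = set()
    for seq in sequences:
        letters |= set(seq)
    return "dna" if letters <= DNA_ALPHABET else "protein"


def read_fasta(path: str | Path, moltype: str = "infer") -> list[SequenceRecord]:
    """Read a FASTA file, preserving record order.

    Raises :class:`FormatError` (with a line number) on sequence data before
    the first header, empty sequences, or duplicate record ids.
    """
    entries: list[tuple[str, str, str, int]] = []  # id, desc, seq, header line
    header_line = 0
    current: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current is not None and not current:
                    raise FormatError(
                        f"{path}: line {header_line}: header with empty sequence"
                    )
                name = line[1:].strip()
                if not name:
                    raise FormatError(f"{path}: line {lineno}: empty FASTA header")
                seq_id, _, desc = name.partition(" ")
                entries.append((seq_id, desc, "", lineno))
                header_line = lineno
                current = []
            else:
                if current is None:
                    raise FormatError(
                        f"{path}: line {lineno}: sequence data before first header"
                    )
                current.append(re.sub(r"\s", "", line))
                seq_id, desc, _, hline = entries[-1]
                entries[-1] = (seq_id, desc, "".join(current), hline)
    if current is not None and not current:
        raise FormatError(f"{path}: line {header_line}: header with empty sequence")
    if not entries:
        raise FormatError(f"{path}: no FASTA records found")

    seen: dict[str, int] = {}
    for seq_id, _, _, hline in entries:
        if seq_id in seen:
            raise FormatError(
                f"{path}: line {hline}: duplicate record id {seq_id!r} "
                f"(first seen at line {seen[seq_id]})"
            )
        seen[seq_id] = hline

    if moltype == "infer":
        moltype = _infer_moltype(seq for _, _, seq, _ in entries)
    records = []
    for seq_id, desc, seq, hline in entries:
        if not seq:
            raise FormatError(f"{path}: line {hline}: header with empty sequence")
        records.append(SequenceRecord(seq_id, seq, desc, moltype))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def read_gff_gene_loci(path: str | Path) -> list[GeneLocus]:
    """Read gene-level features from a GFF3 file; other feature types are ignored."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF_COLUMNS,
        dtype={"seqid": str, "start": int, "end": int},
    )
    loci = []
    for row in df.itertuples(index=False):
        if row.type != "gene":
            continue
        m = re.search(r"ID=([^;]+)", row.attributes)
        gene_id = m.group(1) if m else f"{row.seqid}:{row.start}-{row.end}"
        if row.end < row.start:
            raise FormatError(f"{path}: gene {gene_id}: end {row.end} < start {row.start}")
        loci.append(GeneLocus(gene_id, str(row.seqid), int(row.start), int(row.end),
                              row.strand if row.strand in {"+", "-"} else "+"))
    return loci


def write_gff_gene_loci(loci: Iterable[GeneLocus], path: str | Path,
                        source: str = "hsfkit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            fh.write(
                f"{loc.chromosome}\t{source}\tgene\t{loc.start}\t{loc.end}\t.\t"
                f"{loc.strand}\t.\tID={loc.gene_id}\n"
            )


@dataclass
class CtTable:
    """Replicate-resolved Ct matrix (gene x sample)."""

    data: pd.DataFrame = field(repr=False)  # columns: gene, sample, replicate, ct

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample"].unique())

    def cell(self, gene: str, sample: str) -> list[float]:
        sel = self.data[(self.data["gene"] == gene) & (self.data["sample"] == sample)]
        return sel["ct"].tolist()

    def replicate_counts(self) -> pd.DataFrame:
        return (
            self.data.groupby(["gene", "sample"])["ct"].size().unstack(fill_value=0)
        )

    def missing_cells(self) -> list[tuple[str, str]]:
        counts = self.replicate_counts()
        full = counts.reindex(index=self.genes, columns=self.samples, fill_value=0)
        return [(g, s) for g in full.index for s in full.columns if full.loc[g, s] == 0]


def read_ct_table(path: str | Path) -> CtTable:
    """Read a TSV of qPCR cycle-threshold values.

    Required columns: gene, sample, replicate, ct.  Non-numeric Ct values are
    a parse error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["gene", "sample", "replicate", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; required header is "
            f"{required}"
        )
    ct = pd.to_numeric(df["ct"], errors="coerce")
    if ct.isna().any():
        bad = df.loc[ct.isna(), "ct"].iloc[0]
        raise FormatError(f"{path}: non-numeric Ct value {bad!r}")
    out = df[required].copy()
    out["ct"] = ct
    return CtTable(out)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)
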