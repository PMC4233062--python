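"""Packaged family-census fixtures and cross-table consistency checks.

Three census tables for the 40-member cotton Hsf family ship with the
package: the gene/locus/length/pI/MW census, the functional-domain census
(class label, DBD and HR-A/B coordinates, printed linker lengths, NLS/NES/
AHA motifs) and the exon-intron structure census.  The tables are kept
exactly as printed; where their internal arithmetic disagrees (printed
linker vs coordinate difference, stated DBD length vs coordinates, implied
protein length vs census length) the discrepancy report surfaces the
conflict rather than correcting it.
"""
from __future__ import annotations

import importlib.resources
import re

import pandas as pd

from .genome import ConsistencyReport, GeneModel, check_length_consistency
from .io import GeneLocus


def _read(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("hsfkit.data").joinpath(name)
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_family_table() -> pd.DataFrame:
    """Gene census: gene, locus, protein length, pI, MW, chromosome."""
    return _read("family_table.tsv")


def load_domain_table() -> pd.DataFrame:
    """Functional-domain census with parsed coordinate columns added."""
    df = _read("domain_table.tsv")
    df["klass"] = df["protein_type"].str[0]
    dbd = df["dbd"].map(parse_range)
    df["dbd_start"] = [r[0] for r in dbd]
    df["dbd_end"] = [r[1] for r in dbd]
    df["dbd_len"] = df["dbd_end"] - df["dbd_start"] + 1
    df["hrab_segments"] = df["hrab"].map(parse_segments)
    df["hrab_start"] = df["hrab_segments"].map(lambda segs: segs[0][0])
    df["hrab_end"] = df["hrab_segments"].map(lambda segs: segs[-1][1])
    return df


def load_structure_table() -> pd.DataFrame:
    """Exon-intron census (transcript-relative exons, printed intron bp)."""
    return _read("gene_structure_table.tsv")


def load_dbd_length_claims() -> pd.DataFrame:
    return _read("dbd_length_claims.tsv")


def parse_range(text: str) -> tuple[int, int]:
    m = re.fullmatch(r"(\d+)-(\d+)", text.strip())
    if not m:
        raise ValueError(f"malformed range {text!r}")
    return int(m.group(1)), int(m.group(2))


def parse_segments(text: str) -> list[tuple[int, int]]:
    return [parse_range(part) for part in str(text).split("/")]


def parse_motif(text: str) -> tuple[int, str]:
    """'(248)KKRRLK' -> (248, 'KKRRLK')."""
    m = re.fullmatch(r"\((\d+)\)([A-Z]+)", text.strip())
    if not m:
        raise ValueError(f"malformed motif entry {text!r}")
    return int(m.group(1)), m.group(2)


_LOCUS_RE = re.compile(r"Gorai\.(?:(\d{3})G|([A-Z]))(\d+)")


def family_loci() -> list[GeneLocus]:
    """Gene loci from the census; position comes from the locus identifier
    (locus numbers increase along each chromosome)."""
    loci = []
    for row in load_family_table().itertuples(index=False):
        m = _LOCUS_RE.fullmatch(row.locus)
        if not m:
            raise ValueError(f"unparseable locus id {row.locus!r}")
        position = int(m.group(3))
        loci.append(GeneLocus(row.gene, str(row.chromosome), position, position))
    return loci


def gene_models_from_structure_table(space: str = "transcript") -> list[GeneModel]:
    """Gene models from the structure census.

    ``space='transcript'`` keeps the printed exon coordinates (contiguous);
    ``space='genomic'`` shifts downstream exons by the printed intron
    lengths, recovering locus-relative coordinates.
    """
    models = []
    for row in load_structure_table().itertuples(index=False):
        exons = [(int(row.exon1_start), int(row.exon1_end))]
        introns = []
        if not pd.isna(row.exon2_start):
            introns.append(int(row.intron1))
            exons.append((int(row.exon2_start), int(row.exon2_end)))
        if "exon3_start" in row._fields and not pd.isna(row.exon3_start):
            introns.append(int(row.intron2))
            exons.append((int(row.exon3_start), int(row.exon3_end)))
        if space == "genomic":
            shifted = [exons[0]]
            offset = 0
            for intron_len, (s, e) in zip(introns, exons[1:]):
                offset += intron_len
                shifted.append((s + offset, e + offset))
            exons = shifted
        models.append(GeneModel(row.gene, exons, coordinate_space=space))
    return models


def build_consistency_report() -> ConsistencyReport:
    """Cross-table arithmetic checks over the packaged census tables."""
    report = ConsistencyReport()
    family = load_family_table().set_index("gene")
    domains = load_domain_table()
    claims = load_dbd_length_claims().set_index("gene")

    for row in domains.itertuples(index=False):
        coordinate_linker = row.hrab_start - row.dbd_end
        if coordinate_linker != row.linker:
            report.linker_mismatches.append({
                "gene": row.gene, "printed_linker": int(row.linker),
                "coordinate_linker": int(coordinate_linker)})
        if row.gene in claims.index:
            stated = int(claims.loc[row.gene, "dbd_len_text"])
            if stated != row.dbd_len:
                report.dbd_length_mismatches.append({
                    "gene": row.gene, "stated_dbd_len": stated,
                    "coordinate_dbd_len": int(row.dbd_len)})

    for model in gene_models_from_structure_table():
        stated_length = int(family.loc[model.gene_id, "length"])
        ok, implied = check_length_consistency(model, stated_length)
        if not ok:
            report.length_mismatches.append({
                "gene": model.gene_id, "stated_length": stated_length,
                "implied_length": implied})
    return report
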