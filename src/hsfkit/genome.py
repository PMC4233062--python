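"""Duplication calling, tandem clusters, and exon-intron structure.

Duplication follows the classic 80/80 rule: a gene pair is a duplication
event when the aligned region covers more than 80% of the longer gene and
the identity over that aligned region exceeds 80%.  Pairs on the same
chromosome within a small adjacency window are tandem; everything else is
segmental.  Gene structure derives from spliced alignment of a CDS to its
genomic locus with introns required to start GT and end AG.
"""
from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner

from .io import GeneLocus, SequenceRecord


class StructureNotFoundError(ValueError):
    """The CDS could not be spliced onto the genomic sequence."""


@dataclass
class DuplicationPair:
    gene_a: str
    gene_b: str
    coverage: float
    similarity: float
    type: str  # {"segmental", "tandem"}

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("a duplication pair needs two distinct genes")
        if self.gene_a > self.gene_b:  # canonical unordered storage
            self.gene_a, self.gene_b = self.gene_b, self.gene_a
        if not (0 <= self.coverage <= 1 and 0 <= self.similarity <= 1):
            raise ValueError("coverage and similarity must be in [0, 1]")


@dataclass
class GeneModel:
    gene_id: str
    exons: list[tuple[int, int]]  # ascending, non-overlapping, 1-based inclusive
    strand: str = "+"
    coordinate_space: str = "genomic"  # or "transcript"
    gtag_consistent: bool = True

    def __post_init__(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
        for s, e in self.exons:
            if e < s:
                raise ValueError(f"{self.gene_id}: exon end before start")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    @property
    def intron_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.introns]

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def coding_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


# ---------------------------------------------------------------------------
# duplication calling

def _nt_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    # free end gaps: coverage is judged from the aligned region, not forced
    try:
        aligner.end_deletion_score = 0.0
        aligner.end_insertion_score = 0.0
    except AttributeError:  # older attribute names
        aligner.query_end_gap_score = 0.0
        aligner.target_end_gap_score = 0.0
    return aligner


def pair_alignment_stats(a: str, b: str) -> tuple[float, float]:
    """(coverage, similarity) of the best end-gap-free global alignment.

    Coverage = aligned (both-residue) columns / length of the longer
    sequence; similarity = identical columns / aligned columns.
    """
    aligner = _nt_aligner()
    alignment = next(iter(aligner.align(a, b)))
    blocks_a, blocks_b = alignment.aligned
    aligned_cols = 0
    matches = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        aligned_cols += ae - as_
        matches += sum(1 for x, y in zip(a[as_:ae], b[bs:be]) if x == y)
    coverage = aligned_cols / max(len(a), len(b))
    similarity = matches / aligned_cols if aligned_cols else 0.0
    return coverage, similarity


def _adjacency_ranks(loci: list[GeneLocus],
                     census: list[GeneLocus] | None) -> dict[str, tuple[str, int]]:
    """Per gene: (chromosome, rank along the chromosome in the reference set)."""
    reference = census if census is not None else loci
    ranks: dict[str, tuple[str, int]] = {}
    by_chrom: dict[str, list[GeneLocus]] = {}
    for loc in reference:
        by_chrom.setdefault(loc.chromosome, []).append(loc)
    for chrom, items in by_chrom.items():
        for rank, loc in enumerate(sorted(items, key=lambda l: (l.start, l.gene_id))):
            ranks[loc.gene_id] = (chrom, rank)
    for loc in loci:  # family genes absent from the census get their own rank
        if loc.gene_id not in ranks:
            ranks[loc.gene_id] = (loc.chromosome, -1)
    return ranks


def detect_duplications(genes: list[SequenceRecord], loci: list[GeneLocus],
                        min_cov: float = 0.80, min_sim: float = 0.80,
                        tandem_window: int = 5,
                        census: list[GeneLocus] | None = None,
                        ) -> list[DuplicationPair]:
    """All unordered gene pairs passing the coverage/similarity thresholds.

    A passing pair is tandem when both genes sit on one chromosome with at
    most ``tandem_window`` intervening genes, segmental otherwise.
    """
    locus_of = {l.gene_id: l for l in loci}
    ranks = _adjacency_ranks(loci, census)
    pairs = []
    for rec_a, rec_b in itertools.combinations(sorted(genes, key=lambda r: r.id), 2):
        coverage, similarity = pair_alignment_stats(rec_a.sequence, rec_b.sequence)
        if coverage <= min_cov or similarity <= min_sim:
            continue
        kind = "segmental"
        la, lb = locus_of.get(rec_a.id), locus_of.get(rec_b.id)
        if la is not None and lb is not None and la.chromosome == lb.chromosome:
            (_, ra), (_, rb) = ranks[rec_a.id], ranks[rec_b.id]
            if ra >= 0 and rb >= 0 and abs(ra - rb) - 1 <= tandem_window:
                kind = "tandem"
        pairs.append(DuplicationPair(rec_a.id, rec_b.id, coverage, similarity, kind))
    return pairs


# ---------------------------------------------------------------------------
# spliced alignment

def _chain_exons(cds: str, genomic: str, require_gtag: bool, anchor: int = 20,
                 max_backtrack: int = 12, ci: int = 0, gstart: int = 0,
                 depth: int = 0) -> list[tuple[int, int]] | None:
    """Exon chain (0-based half-open on ``genomic``) spelling out ``cds``."""
    if depth > 6:
        return None
    anchor_len = min(anchor, len(cds) - ci)
    if anchor_len <= 0:
        return None
    pos = gstart
    while True:
        s = genomic.find(cds[ci : ci + anchor_len], pos)
        if s < 0:
            return None
        if ci > 0 and require_gtag and genomic[max(s - 2, 0) : s] != "AG":
            pos = s + 1
            continue
        j = 0
        while ci + j < len(cds) and s + j < len(genomic) and genomic[s + j] == cds[ci + j]:
            j += 1
        if ci + j == len(cds):
            return [(s, s + j)]
        for delta in range(0, min(max_backtrack, j - anchor_len) + 1):
            end = j - delta
            if end < anchor_len:
                break
            if require_gtag and genomic[s + end : s + end + 2] != "GT":
                continue
            rest = _chain_exons(cds, genomic, require_gtag, anchor, max_backtrack,
                                ci + end, s + end + 2, depth + 1)
            if rest is not None:
                return [(s, s + end)] + rest
        pos = s + 1


def spliced_align(cds: SequenceRecord, genomic: SequenceRecord,
                  anchor: int = 20) -> GeneModel:
    """Splice a CDS onto a genomic sequence, introns bounded by GT..AG.

    Both strands are tried; when no GT-AG-consistent chain exists, the best
    chain without the dinucleotide constraint is returned with
    ``gtag_consistent=False``.  Raises :class:`StructureNotFoundError` when
    the CDS cannot be placed at all.
    """
    from .simulate import reverse_complement

    g = genomic.sequence
    attempts = [("+", g, True), ("-", reverse_complement(g), True),
                ("+", g, False), ("-", reverse_complement(g), False)]
    for strand, target, gtag in attempts:
        chain = _chain_exons(cds.sequence, target, require_gtag=gtag, anchor=anchor)
        if chain is None:
            continue
        if strand == "+":
            exons = [(s + 1, e) for s, e in chain]
        else:
            L = len(g)
            exons = sorted((L - e + 1, L - s) for s, e in chain)
        return GeneModel(cds.id, exons, strand=strand, gtag_consistent=gtag)
    raise StructureNotFoundError(f"{cds.id}: CDS not alignable to the genomic sequence")


# ---------------------------------------------------------------------------
# summaries and cross-checks

def summarize_intron_counts(models: list[GeneModel]) -> dict[int, int]:
    return dict(Counter(m.n_introns for m in models))


def check_length_consistency(model: GeneModel, protein_length: int,
                             ) -> tuple[bool, float]:
    """Does the exon structure imply the stated protein length?

    Implied length = (sum of exon lengths) / 3 - 1 (terminal stop removed).
    """
    total = model.coding_length
    implied = total / 3 - 1
    ok = total % 3 == 0 and int(implied) == protein_length
    return ok, implied


def find_tandem_clusters(loci: list[GeneLocus], window: int = 5,
                         census: list[GeneLocus] | None = None,
                         max_gap_bp: int = 50_000) -> list[list[str]]:
    """Maximal runs of family genes on one chromosome.

    With a genome-wide gene ``census``, adjacency means at most ``window``
    intervening non-family genes; without one, consecutive family genes must
    start within ``max_gap_bp`` of each other.
    """
    ranks = _adjacency_ranks(loci, census) if census is not None else None
    clusters: list[list[str]] = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chromosome, []).append(loc)
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda l: (l.start, l.gene_id))
        run = [items[0]]
        for prev, cur in zip(items, items[1:]):
            if ranks is not None:
                adjacent = abs(ranks[cur.gene_id][1] - ranks[prev.gene_id][1]) - 1 <= window
            else:
                adjacent = cur.start - prev.start <= max_gap_bp
            if adjacent:
                run.append(cur)
            else:
                if len(run) >= 2:
                    clusters.append([l.gene_id for l in run])
                run = [cur]
        if len(run) >= 2:
            clusters.append([l.gene_id for l in run])
    return clusters


@dataclass
class ConsistencyReport:
    """Cross-table discrepancy report; inconsistencies are surfaced, never
    silently corrected."""

    length_mismatches: list[dict] = field(default_factory=list)
    linker_mismatches: list[dict] = field(default_factory=list)
    dbd_length_mismatches: list[dict] = field(default_factory=list)

    @property
    def flagged_genes(self) -> set[str]:
        return ({d["gene"] for d in self.length_mismatches}
                | {d["gene"] for d in self.linker_mismatches}
                | {d["gene"] for d in self.dbd_length_mismatches})
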