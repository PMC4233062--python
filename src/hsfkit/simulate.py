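"""Synthetic Hsf families with machine-readable planted truth.

Every downstream stage of the pipeline is tested against data produced here:
proteins carry a planted DBD (sampled from the packaged profile), heptad
HR-A/HR-B blocks with the class-defining insertion (21 residues for class A,
none for class B, 7 for class C), a class-appropriate linker, an NLS, and -
for class A - an AHA window and a canonical NES.  Genome construction embeds
reverse-translated coding sequences in plant-like background (GC 0.35 by
default) with GT..AG introns, planted inter-chromosomal duplications at
controlled identity/coverage and an optional tandem cluster.  EST reads,
ortholog CDS pairs with exact planted synonymous/non-synonymous change
counts, and qPCR Ct tables with planted heat-shock response patterns follow
the same pattern: the generating parameters are recorded as truth.

Outside the planted elements, protein filler is low-complexity (no K/R, no
hydrophobic or aromatic residues) so that the planted motif set is exactly
the detectable motif set; see the methods note for what this does and does
not emulate.
"""
from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .io import CtTable, GeneLocus, SequenceRecord
from .profile import default_profile

CLASS_INSERTION = {"A": 21, "B": 0, "C": 7}
LINKER_RANGE = {"A": (12, 37), "B": (16, 77), "C": (10, 29)}
_FILLER = np.array(list("AGSTNQPHED"))
_FILLER_P = np.array([0.14, 0.12, 0.14, 0.12, 0.10, 0.10, 0.08, 0.05, 0.08, 0.07])
_HEPTAD_CORE = np.array(list("LLLIVMF"))  # leucine-biased hydrophobic core
_NLS_TEMPLATES = ["KKRR", "RKRR", "KKRRLK", "KRRK", "KKRKR", "KKR"]
_CANONICAL_NES = "LTEQMGLL"
_AHA_POOL = np.array(list("WFYLIVED"))

_CODON_TO_AA = dict(standard_dna_table.forward_table)
_STOP_CODONS = list(standard_dna_table.stop_codons)
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_CODON_TO_AA.items()):
    _AA_TO_CODONS.setdefault(aa, []).append(codon)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode())


def _filler(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(_FILLER, size=n, p=_FILLER_P))


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.35) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(np.array(list("ACGT")), size=n, p=p))


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return seq.translate(comp)[::-1]


# ---------------------------------------------------------------------------
# truth containers

@dataclass
class TruthGene:
    gene_id: str
    klass: str
    subclass: str
    protein: str = ""
    cds: str = ""
    dbd: tuple[int, int] | None = None
    hra: tuple[int, int] | None = None
    hrb: tuple[int, int] | None = None
    insertion: int | None = None
    linker: int | None = None
    nls_pos: int | None = None
    nes_pos: int | None = None
    aha_pos: int | None = None
    chromosome: str | None = None
    strand: str = "+"
    gene_span: tuple[int, int] | None = None      # chromosome coords
    exons_genomic: list[tuple[int, int]] = field(default_factory=list)
    exons_local: list[tuple[int, int]] = field(default_factory=list)
    # exons_local: coordinates on the gene's own transcribed-orientation sequence


@dataclass
class PlantedFamilyTruth:
    genes: dict[str, TruthGene] = field(default_factory=dict)
    duplication_pairs: list[dict] = field(default_factory=list)
    tandem_cluster: list[str] = field(default_factory=list)
    ortholog_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    ct_patterns: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair in self.duplication_pairs:
            if not (0 < pair["identity"] <= 1):
                raise ValueError("planted identity must be in (0, 1]")

    def validate(self) -> None:
        for pair in self.duplication_pairs:
            for key in ("gene_a", "gene_b"):
                if pair[key] not in self.genes:
                    raise ValueError(f"duplication pair references unknown {pair[key]}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": {g: dataclasses.asdict(t) for g, t in self.genes.items()},
            "duplication_pairs": self.duplication_pairs,
            "tandem_cluster": self.tandem_cluster,
            "ortholog_counts": self.ortholog_counts,
            "ct_patterns": self.ct_patterns,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# proteins

def generate_hsf_protein(klass: str, subclass: str = "", seed: int | np.random.Generator = 0,
                         within_divergence: float = 0.05, with_nes: bool | None = None,
                         gene_id: str = "gene",
                         ) -> tuple[SequenceRecord, TruthGene]:
    """Generate one Hsf-like protein of the requested class.

    ``subclass`` acts as a template id: all proteins generated with the same
    subclass share a subclass-specific DBD base sequence (mutated per protein
    at ``within_divergence``), so exemplar-based subclass assignment has a
    signal to recover.
    """
    if klass not in CLASS_INSERTION:
        raise ValueError(f"unknown Hsf class {klass!r}; expected A, B or C")
    rng = _rng(seed)
    profile = default_profile()
    if with_nes is None:
        with_nes = klass == "A"

    if subclass:
        sub_rng = np.random.default_rng(_stable_hash(f"{klass}:{subclass}"))
        dbd_base = profile.sample(sub_rng)
        dbd_chars = list(dbd_base)
        aa20 = list("ACDEFGHIKLMNPQRSTVWY")
        for i in range(len(dbd_chars)):
            if rng.random() < within_divergence:
                dbd_chars[i] = aa20[rng.integers(20)]
        dbd_seq = "".join(dbd_chars)
    else:
        dbd_seq = profile.sample(rng)

    def heptad_block() -> str:
        chars = list(_filler(rng, 15))
        for pos in (0, 7, 14):
            chars[pos] = str(rng.choice(_HEPTAD_CORE))
        return "".join(chars)

    # The census convention counts the linker as HR-A/B start - DBD end,
    # i.e. one more than the number of residues strictly between them.
    lo, hi = LINKER_RANGE[klass]
    linker_len = int(rng.integers(lo, hi + 1))
    insertion_len = CLASS_INSERTION[klass]

    parts: list[str] = []
    cursor = 0

    def emit(seq: str) -> tuple[int, int]:
        nonlocal cursor
        parts.append(seq)
        start = cursor + 1
        cursor += len(seq)
        return start, cursor

    emit(_filler(rng, int(rng.integers(10, 31))))         # N-terminal leader
    dbd_span = emit(dbd_seq)
    emit(_filler(rng, linker_len - 1))                    # linker (census convention)
    hra_span = emit(heptad_block())
    emit(_filler(rng, insertion_len))                     # class signature
    hrb_span = emit(heptad_block())
    emit(_filler(rng, int(rng.integers(15, 40))))
    nls_pos = emit(str(rng.choice(_NLS_TEMPLATES)))[0]
    emit(_filler(rng, int(rng.integers(10, 31))))

    aha_pos = None
    if klass == "A":
        win = list(_filler(rng, 12))
        favoured = rng.choice(12, size=9, replace=False)
        win[favoured[0]] = str(rng.choice(np.array(list("WFY"))))
        win[favoured[1]] = str(rng.choice(np.array(list("ED"))))
        for j in favoured[2:]:
            win[j] = str(rng.choice(_AHA_POOL))
        aha_pos = emit("".join(win))[0]
        emit(_filler(rng, int(rng.integers(10, 21))))

    nes_pos = None
    if with_nes:
        motif = _CANONICAL_NES if klass == "A" else "L" + str(rng.choice(["G", "R"])) + "LNLM"
        nes_pos = emit(motif)[0]
    emit(_filler(rng, int(rng.integers(5, 16))))          # C-terminal tail

    protein = "".join(parts)
    truth = TruthGene(
        gene_id=gene_id, klass=klass, subclass=subclass, protein=protein,
        dbd=dbd_span, hra=hra_span, hrb=hrb_span,
        insertion=insertion_len, linker=linker_len,
        nls_pos=nls_pos, nes_pos=nes_pos, aha_pos=aha_pos,
    )
    record = SequenceRecord(gene_id, protein, description=f"synthetic Hsf class {klass}",
                            moltype="protein")
    return record, truth


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [str(rng.choice(_AA_TO_CODONS[aa])) for aa in protein]
    codons.append(str(rng.choice(_STOP_CODONS)))
    return "".join(codons)


# ---------------------------------------------------------------------------
# genomes

def _mutate(seq: str, n_changes: int, rng: np.random.Generator) -> str:
    chars = list(seq)
    positions = rng.choice(len(chars), size=min(n_changes, len(chars)), replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(3)]
    return "".join(chars)


def _split_exons(cds_genomic: str, n_introns: int, rng: np.random.Generator,
                 gc: float) -> tuple[str, list[tuple[int, int]]]:
    """Insert GT..AG introns; returns gene sequence + exon coords on it."""
    L = len(cds_genomic)
    if n_introns == 0:
        return cds_genomic, [(1, L)]
    cuts = sorted(rng.choice(np.arange(30, L - 30), size=n_introns, replace=False))
    # enforce a minimum exon of 30 nt between cuts
    for k in range(1, len(cuts)):
        if cuts[k] - cuts[k - 1] < 30:
            cuts[k] = cuts[k - 1] + 30
    pieces = []
    exons = []
    prev = 0
    offset = 0
    for cut in cuts:
        exon = cds_genomic[prev:cut]
        pieces.append(exon)
        exons.append((offset + 1, offset + len(exon)))
        offset += len(exon)
        intron = "GT" + random_dna(rng, int(rng.integers(60, 400)), gc) + "AG"
        pieces.append(intron)
        offset += len(intron)
        prev = cut
    exon = cds_genomic[prev:]
    pieces.append(exon)
    exons.append((offset + 1, offset + len(exon)))
    return "".join(pieces), exons


def generate_family_genome(n_genes: int, n_chromosomes: int = 3,
                           dup_pairs: list[tuple[float, float]] | None = None,
                           tandem_cluster_size: int = 0,
                           seed: int | np.random.Generator = 0,
                           gc: float = 0.35,
                           intron_count_probs: tuple[float, float] = (0.95, 0.05),
                           class_probs: tuple[float, float, float] = (0.55, 0.37, 0.08),
                           ) -> tuple[list[SequenceRecord], list[GeneLocus],
                                      list[SequenceRecord], PlantedFamilyTruth]:
    """Build a synthetic family genome: (chromosomes, gene loci, CDS, truth).

    ``n_genes`` counts base genes; planted duplicates (one per entry of
    ``dup_pairs``) and the extra members of the tandem cluster are added on
    top.  Duplicate copies are substrings of their source CDS covering the
    requested fraction of the longer gene, mutated to the requested identity;
    they are always placed on a different chromosome (segmental).  The tandem
    cluster places near-identical copies of one gene adjacently on a single
    chromosome.
    """
    dup_pairs = dup_pairs or []
    rng = _rng(seed)
    if dup_pairs and n_genes < 2:
        raise ValueError("need at least 2 base genes to plant duplications")
    for identity, coverage in dup_pairs:
        if not (0 < identity <= 1) or not (0 < coverage <= 1):
            raise ValueError("planted identity and coverage must be in (0, 1]")
    if tandem_cluster_size == 1:
        raise ValueError("a tandem cluster needs at least 2 genes")

    truth = PlantedFamilyTruth()
    subclass_pool = {"A": ["A1", "A2", "A4"], "B": ["B1", "B2"], "C": ["C1"]}
    cds_records: list[SequenceRecord] = []
    gene_seqs: dict[str, tuple[str, list[tuple[int, int]]]] = {}

    def make_gene(gene_id: str, klass: str, subclass: str) -> None:
        _, tgene = generate_hsf_protein(klass, subclass, rng, gene_id=gene_id)
        cds = reverse_translate(tgene.protein, rng)
        tgene.cds = cds
        n_introns = int(rng.choice([1, 2], p=intron_count_probs))
        gene_seq, exons_local = _split_exons(cds, n_introns, rng, gc)
        tgene.exons_local = exons_local
        truth.genes[gene_id] = tgene
        gene_seqs[gene_id] = (gene_seq, exons_local)
        cds_records.append(SequenceRecord(gene_id, cds, moltype="dna"))

    base_ids = []
    for i in range(n_genes):
        klass = str(rng.choice(["A", "B", "C"], p=class_probs))
        subclass = str(rng.choice(subclass_pool[klass]))
        gene_id = f"hsf{i + 1:03d}"
        make_gene(gene_id, klass, subclass)
        base_ids.append(gene_id)

    # planted segmental duplicates
    for k, (identity, coverage) in enumerate(dup_pairs):
        src_id = base_ids[int(rng.integers(len(base_ids)))]
        src = truth.genes[src_id]
        dup_id = f"hsfdup{k + 1:02d}"
        cds_len = len(src.cds)
        keep = max(60, int(round(coverage * cds_len)))
        keep -= keep % 3
        start = 0  # prefix keeps the duplicate in frame with its source
        dup_cds = src.cds[start : start + keep]
        n_changes = int(round((1 - identity) * len(dup_cds)))
        dup_cds = _mutate(dup_cds, n_changes, rng)
        tgene = TruthGene(gene_id=dup_id, klass=src.klass, subclass=src.subclass,
                          cds=dup_cds)
        n_introns = int(rng.choice([1, 2], p=intron_count_probs))
        gene_seq, exons_local = _split_exons(dup_cds, n_introns, rng, gc)
        tgene.exons_local = exons_local
        truth.genes[dup_id] = tgene
        gene_seqs[dup_id] = (gene_seq, exons_local)
        cds_records.append(SequenceRecord(dup_id, dup_cds, moltype="dna"))
        truth.duplication_pairs.append(
            {"gene_a": src_id, "gene_b": dup_id,
             "identity": identity, "coverage": coverage,
             "source_chromosome": None, "type": "segmental"})

    # tandem cluster: near-identical copies of one gene, adjacent on one chromosome
    cluster_ids: list[str] = []
    if tandem_cluster_size >= 2:
        src_id = base_ids[0]
        cluster_ids = [src_id]
        src = truth.genes[src_id]
        for k in range(tandem_cluster_size - 1):
            copy_id = f"{src_id}t{k + 1}"
            copy_cds = _mutate(src.cds, int(round(0.05 * len(src.cds))), rng)
            tgene = TruthGene(gene_id=copy_id, klass=src.klass, subclass=src.subclass,
                              cds=copy_cds)
            gene_seq, exons_local = _split_exons(copy_cds, 1, rng, gc)
            tgene.exons_local = exons_local
            truth.genes[copy_id] = tgene
            gene_seqs[copy_id] = (gene_seq, exons_local)
            cds_records.append(SequenceRecord(copy_id, copy_cds, moltype="dna"))
            cluster_ids.append(copy_id)
        truth.tandem_cluster = cluster_ids

    # chromosome assignment
    placement: dict[str, list[str]] = {f"chr{i + 1}": [] for i in range(n_chromosomes)}
    chrom_names = list(placement)
    cluster_chrom = chrom_names[0] if cluster_ids else None
    for gene_id in truth.genes:
        if gene_id in cluster_ids:
            continue
        if any(gene_id == p["gene_b"] for p in truth.duplication_pairs):
            pair = next(p for p in truth.duplication_pairs if p["gene_b"] == gene_id)
            src_chrom = truth.genes[pair["gene_a"]].chromosome
            options = [c for c in chrom_names if c != src_chrom] or chrom_names
            chrom = options[int(rng.integers(len(options)))]
        else:
            chrom = chrom_names[int(rng.integers(n_chromosomes))]
        placement[chrom].append(gene_id)
        truth.genes[gene_id].chromosome = chrom
    if cluster_ids:
        # cluster members are adjacent: insert as a block at the front
        placement[cluster_chrom] = cluster_ids + placement[cluster_chrom]
        for gid in cluster_ids:
            truth.genes[gid].chromosome = cluster_chrom

    genome_records: list[SequenceRecord] = []
    loci: list[GeneLocus] = []
    for chrom in chrom_names:
        seq_parts: list[str] = []
        pos = 0
        for gene_id in placement[chrom]:
            gap = random_dna(rng, int(rng.integers(200, 1000)), gc)
            seq_parts.append(gap)
            pos += len(gap)
            gene_seq, exons_local = gene_seqs[gene_id]
            strand = str(rng.choice(["+", "-"]))
            placed = gene_seq if strand == "+" else reverse_complement(gene_seq)
            start = pos + 1
            seq_parts.append(placed)
            pos += len(placed)
            end = pos
            tgene = truth.genes[gene_id]
            tgene.strand = strand
            tgene.gene_span = (start, end)
            glen = len(gene_seq)
            if strand == "+":
                tgene.exons_genomic = [(start + s - 1, start + e - 1)
                                       for s, e in exons_local]
            else:
                tgene.exons_genomic = sorted(
                    (start + (glen - e), start + (glen - s))
                    for s, e in exons_local)
            loci.append(GeneLocus(gene_id, chrom, start, end, strand))
        seq_parts.append(random_dna(rng, int(rng.integers(200, 1000)), gc))
        genome_records.append(SequenceRecord(chrom, "".join(seq_parts), moltype="dna"))

    # record source chromosomes on planted pairs now that placement is known
    for pair in truth.duplication_pairs:
        pair["source_chromosome"] = truth.genes[pair["gene_a"]].chromosome
    truth.validate()
    loci.sort(key=lambda l: (l.chromosome, l.start))
    return genome_records, loci, cds_records, truth


# ---------------------------------------------------------------------------
# ESTs

def generate_ests(cds: SequenceRecord, coverage: float, read_len: int = 300,
                  error_rate: float = 0.0, seed: int | np.random.Generator = 0,
                  ) -> list[SequenceRecord]:
    """Simulate EST reads: substrings with iid substitution errors, both strands."""
    rng = _rng(seed)
    L = len(cds.sequence)
    if read_len > L:
        raise ValueError(f"read_len {read_len} exceeds CDS length {L}")
    n_reads = int(round(coverage * L / read_len))
    reads = []
    for i in range(n_reads):
        # anchor the first two reads at the termini so that sufficient
        # coverage always tiles the whole source
        if i == 0:
            start = 0
        elif i == 1:
            start = L - read_len
        else:
            start = int(rng.integers(0, L - read_len + 1))
        seq = cds.sequence[start : start + read_len]
        if error_rate > 0:
            errors = rng.random(read_len) < error_rate
            chars = list(seq)
            for pos in np.nonzero(errors)[0]:
                alternatives = [b for b in "ACGT" if b != chars[pos]]
                chars[pos] = alternatives[rng.integers(3)]
            seq = "".join(chars)
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append(SequenceRecord(f"{cds.id}_est{i + 1:04d}", seq, moltype="dna"))
    return reads


# ---------------------------------------------------------------------------
# ortholog pairs

def _codon_changes(codon: str) -> list[tuple[int, str, bool]]:
    """All single-nt changes of a codon: (position, new base, synonymous)."""
    aa = _CODON_TO_AA.get(codon)
    if aa is None:
        return []
    out = []
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            new = codon[:pos] + base + codon[pos + 1 :]
            new_aa = _CODON_TO_AA.get(new)
            if new_aa is None:  # stop codon: never planted
                continue
            out.append((pos, base, new_aa == aa))
    return out


def generate_ortholog_pair(cds: SequenceRecord, n_syn: int, n_nonsyn: int,
                           seed: int | np.random.Generator = 0,
                           ) -> tuple[SequenceRecord, SequenceRecord]:
    """Derive an ortholog differing by exactly the planted change counts.

    Each change is a single-nucleotide substitution in a distinct codon
    (verified against the standard codon table), so unweighted-pathway
    counting recovers the planted (Sd, Nd) exactly.
    """
    rng = _rng(seed)
    seq = cds.sequence
    if len(seq) % 3:
        raise ValueError("CDS length must be divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    syn_options: list[tuple[int, list]] = []
    nonsyn_options: list[tuple[int, list]] = []
    for ci, codon in enumerate(codons):
        changes = _codon_changes(codon)
        syn = [c for c in changes if c[2]]
        nonsyn = [c for c in changes if not c[2]]
        if syn:
            syn_options.append((ci, syn))
        if nonsyn:
            nonsyn_options.append((ci, nonsyn))
    rng.shuffle(syn_options)
    rng.shuffle(nonsyn_options)
    chosen: dict[int, tuple[int, str]] = {}
    for ci, options in syn_options:
        if len(chosen) < n_syn:
            pos, base, _ = options[int(rng.integers(len(options)))]
            chosen[ci] = (pos, base)
    if len(chosen) < n_syn:
        raise ValueError("CDS too short to plant the requested synonymous changes")
    for ci, options in nonsyn_options:
        if ci in chosen:
            continue
        if len(chosen) < n_syn + n_nonsyn:
            pos, base, _ = options[int(rng.integers(len(options)))]
            chosen[ci] = (pos, base)
    if len(chosen) < n_syn + n_nonsyn:
        raise ValueError("CDS too short to plant the requested non-synonymous changes")
    new_codons = list(codons)
    for ci, (pos, base) in chosen.items():
        c = new_codons[ci]
        new_codons[ci] = c[:pos] + base + c[pos + 1 :]
    ortholog = SequenceRecord(f"{cds.id}_orth", "".join(new_codons), moltype="dna")
    return cds, ortholog


# ---------------------------------------------------------------------------
# qPCR Ct tables

DEFAULT_FOLD_PARAMS = {
    "unchanged": (1.0, 1.0, 1.0),
    "inhibited": (0.30, 0.35, 0.50),
    "immediate_up": (400.0, 50.0, 5.0),
    "late_up": (0.40, 1.20, 4.00),
}
TIMEPOINTS = ["CK", "1h", "2h", "4h"]


def generate_ct_table(pattern_per_gene: dict[str, str],
                      fold_params: dict[str, tuple[float, float, float]] | None = None,
                      noise_sd: float = 0.0, n_replicates: int = 4,
                      reference_gene: str = "UBQ",
                      seed: int | np.random.Generator = 0,
                      ) -> tuple[CtTable, dict[str, str]]:
    """Plant heat-shock response patterns into a replicate-resolved Ct table.

    Target Cts are shifted by -log2(fold) relative to the untreated control
    (CK); the reference gene is constant across samples up to noise.
    """
    fold_params = fold_params or DEFAULT_FOLD_PARAMS
    rng = _rng(seed)
    rows = []
    for sample in TIMEPOINTS:
        for rep in range(1, n_replicates + 1):
            ct = 18.0 + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            rows.append((reference_gene, sample, rep, ct))
    for gene, pattern in pattern_per_gene.items():
        if pattern not in fold_params:
            raise ValueError(f"unknown pattern {pattern!r}")
        base = float(rng.uniform(22, 28))
        folds = (1.0,) + tuple(fold_params[pattern])
        for sample, fold in zip(TIMEPOINTS, folds):
            for rep in range(1, n_replicates + 1):
                ct = base - np.log2(fold) + (rng.normal(0, noise_sd) if noise_sd else 0.0)
                rows.append((gene, sample, rep, float(ct)))
    df = pd.DataFrame(rows, columns=["gene", "sample", "replicate", "ct"])
    return CtTable(df), dict(pattern_per_gene)
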