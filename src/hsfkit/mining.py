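"""In-silico cloning: find Hsf-like sequences in an EST/CDS pool.

The search mimics a protein-vs-translated-nucleotide homology scan: each
pool sequence is translated in all six frames, locally aligned against the
reference proteins under BLOSUM62 with affine gaps, and hits are kept when
the fraction of positive-scoring columns ("similarity") reaches the
threshold and the Karlin-Altschul expectation E = K*m*n*exp(-lambda*S) falls
below the cutoff.  Overlapping reads are then assembled greedily into
contigs, and candidate contigs are accepted as full-length family members
only when their best ORF matches a reference significantly AND the protein
carries both a DBD and an HR-A/B region.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from . import features
from .io import SequenceRecord
from .profile import DbdProfile

# Gapped Karlin-Altschul parameters for BLOSUM62 with open 11 / extend 1.
KA_LAMBDA = 0.267
KA_K = 0.041

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _protein_aligner(gap_open: float = 11.0, gap_extend: float = 1.0,
                     mode: str = "local") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass
class HomologyHit:
    query_id: str
    subject_id: str
    frame: int                 # one of +-1, +-2, +-3
    subject_start: int         # 1-based on the nucleotide subject
    subject_end: int
    score: float
    similarity: float          # positive-scoring columns / aligned columns
    evalue: float

    def __post_init__(self) -> None:
        if not 0 <= self.similarity <= 1:
            raise ValueError("similarity outside [0, 1]")
        if self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass
class Contig:
    id: str
    consensus: str
    members: dict[str, int] = field(default_factory=dict)  # read id -> 0-based offset

    @property
    def depth_profile(self) -> np.ndarray:
        depth = np.zeros(len(self.consensus), dtype=int)
        for _, (offset, length) in self._member_extents.items():
            depth[offset : offset + length] += 1
        return depth

    _member_extents: dict[str, tuple[int, int]] = field(default_factory=dict, repr=False)


def translate_six_frames(nt: SequenceRecord | str) -> dict[int, str]:
    """Translate a nucleotide sequence in all six frames (stop = '*').

    Frames +1/+2/+3 read the forward strand with offsets 0/1/2; -1/-2/-3
    read the reverse complement likewise.  Trailing partial codons drop.
    """
    seq = nt.sequence if isinstance(nt, SequenceRecord) else nt.upper()
    rc = str(Seq(seq).reverse_complement())
    frames = {}
    for offset in range(3):
        for sign, strand_seq in ((1, seq), (-1, rc)):
            sub = strand_seq[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames[sign * (offset + 1)] = str(Seq(sub).translate())
    return frames


def local_align(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0,
                ) -> tuple[float, tuple[str, str], float]:
    """Optimal Smith-Waterman alignment of two proteins under BLOSUM62.

    Returns (score, (aligned_a, aligned_b), similarity) where similarity is
    the fraction of alignment columns with a positive substitution score
    (gap columns count in the denominator, as in BLAST "Positives").
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _protein_aligner(gap_open, gap_extend)
    score = aligner.score(a, b)
    if score <= 0:
        return 0.0, ("", ""), 0.0
    alignment = next(iter(aligner.align(a, b)))
    aligned_a, aligned_b = alignment[0], alignment[1]
    positives = 0
    columns = len(aligned_a)
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            continue
        if _BLOSUM62[x, y] > 0:
            positives += 1
    similarity = positives / columns if columns else 0.0
    return float(score), (str(aligned_a), str(aligned_b)), similarity


def karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    """Expectation of a local score >= S in an m x n search space."""
    return float(KA_K * m * n * np.exp(-KA_LAMBDA * score))


def search_homologs(refs: list[SequenceRecord], pool: list[SequenceRecord],
                    min_similarity: float = 0.60, max_evalue: float = 1e-4,
                    ) -> list[HomologyHit]:
    """Protein-vs-six-frame-translation homology search over a pool."""
    if not pool:
        raise ValueError("empty search pool")
    aligner = _protein_aligner()
    hits = []
    for subject in pool:
        frames = translate_six_frames(subject)
        nt_len = len(subject.sequence)
        search_space = max(2 * nt_len, 1)  # aa positions over six frames
        for ref in refs:
            best = None
            for frame, prot in sorted(frames.items()):
                if not prot:
                    continue
                score = aligner.score(ref.sequence, prot)
                if score <= 0:
                    continue
                if best is None or score > best[0]:
                    best = (score, frame, prot)
            if best is None:
                continue
            score, frame, prot = best
            evalue = karlin_altschul_evalue(score, len(ref.sequence), search_space)
            if evalue > max_evalue:
                continue
            alignment = next(iter(aligner.align(ref.sequence, prot)))
            aligned_q, aligned_s = str(alignment[0]), str(alignment[1])
            positives = sum(
                1 for x, y in zip(aligned_q, aligned_s)
                if x != "-" and y != "-" and _BLOSUM62[x, y] > 0
            )
            similarity = positives / len(aligned_q) if aligned_q else 0.0
            if similarity < min_similarity:
                continue
            # protein coords on the frame -> nucleotide coords on the subject
            p_start, p_end = alignment.aligned[1][0][0], alignment.aligned[1][-1][-1]
            offset = abs(frame) - 1
            if frame > 0:
                s_start = offset + 3 * p_start + 1
                s_end = offset + 3 * p_end
            else:
                s_end = nt_len - (offset + 3 * p_start)
                s_start = nt_len - (offset + 3 * p_end) + 1
            hits.append(HomologyHit(ref.id, subject.id, frame,
                                    int(s_start), int(s_end),
                                    float(score), similarity, evalue))
    hits.sort(key=lambda h: (h.evalue, h.subject_id, h.query_id))
    return hits


# ---------------------------------------------------------------------------
# greedy overlap assembly

def _best_overlap(a: str, b: str, min_overlap: int, min_identity: float,
                  ) -> int | None:
    """Longest suffix(a)/prefix(b) overlap with Hamming identity >= threshold."""
    best = None
    max_k = min(len(a), len(b))
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    for k in range(max_k, min_overlap - 1, -1):
        matches = int((arr_a[len(a) - k :] == arr_b[:k]).sum())
        if matches / k >= min_identity:
            best = k
            break
    return best


def _contained(inner: str, outer: str, min_identity: float) -> int | None:
    """Offset at which ``inner`` maps inside ``outer``, or None."""
    if len(inner) > len(outer):
        return None
    arr_i = np.frombuffer(inner.encode(), dtype=np.uint8)
    arr_o = np.frombuffer(outer.encode(), dtype=np.uint8)
    n = len(inner)
    for off in range(len(outer) - n + 1):
        matches = int((arr_o[off : off + n] == arr_i).sum())
        if matches / n >= min_identity:
            return off
    return None


def assemble_contigs(reads: list[SequenceRecord], min_overlap: int = 40,
                     min_identity: float = 0.95) -> list[Contig]:
    """Greedy longest-overlap-first assembly (both orientations considered).

    Ties break on the lexicographically smallest contig-id pair, so assembly
    is deterministic.  Unmergeable reads become singleton contigs.
    """
    from .simulate import reverse_complement

    working: dict[str, tuple[str, dict[str, tuple[int, int]]]] = {}
    for read in sorted(reads, key=lambda r: r.id):
        working[read.id] = (read.sequence, {read.id: (0, len(read.sequence))})

    def pair_candidate(ia: str, ib: str):
        """Best merge candidate for an unordered contig pair, or None."""
        sa = working[ia][0]
        best = None
        for flip in (False, True):
            sb = working[ib][0] if not flip else reverse_complement(working[ib][0])
            cand = None
            off = _contained(sb, sa, min_identity)
            if off is not None:
                cand = (len(sb), ia, ib, flip, "b_in_a", off)
            else:
                off = _contained(sa, sb, min_identity)
                if off is not None:
                    cand = (len(sa), ia, ib, flip, "a_in_b", off)
                else:
                    k_ab = _best_overlap(sa, sb, min_overlap, min_identity)
                    k_ba = _best_overlap(sb, sa, min_overlap, min_identity)
                    if k_ab is not None and (k_ba is None or k_ab >= k_ba):
                        cand = (k_ab, ia, ib, flip, "a_then_b", None)
                    elif k_ba is not None:
                        cand = (k_ba, ia, ib, flip, "b_then_a", None)
            if cand is not None and (best is None or cand[0] > best[0]):
                best = cand
        return best

    cache: dict[tuple[str, str], tuple | None] = {}
    while True:
        ids = sorted(working)
        best = None  # (overlap, id_a, id_b, flip_b, kind, offset)
        for i, ia in enumerate(ids):
            for ib in ids[i + 1 :]:
                key = (ia, ib)
                if key not in cache:
                    cache[key] = pair_candidate(ia, ib)
                cand = cache[key]
                if cand is not None and (best is None or cand[0] > best[0]):
                    best = cand
        if best is None:
            break
        overlap, ia, ib, flip, kind, off = best
        seq_a, members_a = working[ia]
        seq_b, members_b = working[ib]
        if flip:
            old_len = len(seq_b)
            seq_b = reverse_complement(seq_b)
            members_b = {rid: (old_len - o - length, length)
                         for rid, (o, length) in members_b.items()}
        if kind == "b_in_a":
            merged = seq_a
            members = dict(members_a)
            members.update({rid: (off + o, length) for rid, (o, length) in members_b.items()})
        elif kind == "a_in_b":
            merged = seq_b
            members = {rid: (off + o, length) for rid, (o, length) in members_a.items()}
            members.update(members_b)
        elif kind == "a_then_b":
            merged = seq_a + seq_b[overlap:]
            shift = len(seq_a) - overlap
            members = dict(members_a)
            members.update({rid: (o + shift, length) for rid, (o, length) in members_b.items()})
        else:  # b_then_a
            merged = seq_b + seq_a[overlap:]
            shift = len(seq_b) - overlap
            members = {rid: (o + shift, length) for rid, (o, length) in members_a.items()}
            members.update(members_b)
        del working[ib]
        working[ia] = (merged, members)
        cache = {key: cand for key, cand in cache.items()
                 if ia not in key and ib not in key}

    contigs = []
    for idx, cid in enumerate(sorted(working), start=1):
        seq, members = working[cid]
        contig = Contig(f"contig{idx:03d}", seq,
                        members={rid: off for rid, (off, _) in members.items()})
        contig._member_extents = members
        contigs.append(contig)
    return contigs


# ---------------------------------------------------------------------------
# full-length validation

def best_orf(nt: SequenceRecord | str) -> str:
    """Longest stop-free translated stretch over the six frames."""
    frames = translate_six_frames(nt)
    best = ""
    for frame in sorted(frames):
        for piece in frames[frame].split("*"):
            if len(piece) > len(best):
                best = piece
    return best


def validate_full_length(contig: Contig, refs: list[SequenceRecord],
                         pvalue_max: float = 1e-4,
                         profile: DbdProfile | None = None,
                         ) -> tuple[bool, str]:
    """Accept a contig as a full-length family member.

    Acceptance requires (i) the best ORF's protein to match a reference with
    expectation below ``pvalue_max`` (P ~ E at this magnitude) and (ii) both
    a DBD and an HR-A/B region detectable in the protein.
    """
    protein = best_orf(contig.consensus)
    if len(protein) < 30:
        return False, "no credible ORF"
    aligner = _protein_aligner()
    best_e = np.inf
    for ref in refs:
        score = aligner.score(ref.sequence, protein)
        e = karlin_altschul_evalue(score, len(ref.sequence), len(protein))
        best_e = min(best_e, e)
    if best_e > pvalue_max:
        return False, f"no significant reference match (best E={best_e:.3g})"
    dbd = features.detect_dbd(protein, profile=profile)
    if dbd is None:
        return False, "missing DBD"
    hrab = features.detect_hrab(protein, dbd[1])
    if hrab is None:
        return False, "missing HR-A/B"
    return True, "full-length Hsf"
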