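"""Distances, neighbor-joining phylogeny and substitution-rate statistics.

Amino-acid distances follow the classic recipe: per-pair p-distance with
pairwise deletion of gap columns, then Poisson multiple-hit correction
d = -ln(1 - p).  Trees come from Saitou-Nei neighbor joining with a
deterministic tie-break, and node support from column-resampling bootstrap.
Synonymous/non-synonymous substitution counting between in-frame coding
sequences uses the unweighted-pathway (Nei-Gojobori) method.
"""
from __future__ import annotations

import itertools
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

GAP_CHARS = set("-.?")

_CODON_TO_AA = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


# ---------------------------------------------------------------------------
# distances

def p_distance_pairwise_deletion(a: str, b: str) -> float:
    """Mismatch fraction over columns where both sequences have a residue."""
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    compared = 0
    mismatches = 0
    for x, y in zip(a, b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise ValueError("no comparable columns after pairwise deletion")
    return mismatches / compared


def poisson_correct(p: float) -> float | None:
    """Poisson multiple-hit correction d = -ln(1 - p); None when p >= 1."""
    if p < 0:
        raise ValueError("p-distance cannot be negative")
    if p >= 1:
        return None
    return -math.log(1.0 - p)


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.diag(m).any():
            raise ValueError("distance matrix must have a zero diagonal")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m


def distance_matrix(alignment: dict[str, str], deletion: str = "pairwise",
                    correction: str = "poisson") -> DistanceMatrix:
    """Distance matrix from an aligned set of sequences.

    ``deletion``: "pairwise" drops gap columns per pair; "complete" drops
    any column gapped in any sequence before all comparisons.  Pairs whose
    p-distance reaches 1 (Poisson correction undefined) are capped at the
    largest defined distance and reported in ``undefined_pairs``.
    """
    labels = sorted(alignment)
    seqs = {l: alignment[l] for l in labels}
    if deletion == "complete":
        keep = [i for i in range(len(next(iter(seqs.values()))))
                if all(s[i] not in GAP_CHARS for s in seqs.values())]
        seqs = {l: "".join(s[i] for i in keep) for l, s in seqs.items()}
    n = len(labels)
    m = np.zeros((n, n))
    undefined = []
    for i, j in itertools.combinations(range(n), 2):
        p = p_distance_pairwise_deletion(seqs[labels[i]], seqs[labels[j]])
        if correction == "poisson":
            d = poisson_correct(p)
            if d is None:
                undefined.append((labels[i], labels[j]))
                d = poisson_correct(0.999)
        else:
            d = p
        m[i, j] = m[j, i] = d
    return DistanceMatrix(labels, m, undefined)


# ---------------------------------------------------------------------------
# neighbor joining

@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return self.label
        inner = ",".join(f"{c._newick_inner()}:{round(bl, 10):g}"
                         for c, bl in self.children)
        return f"({inner})"


@dataclass
class NjResult:
    tree: TreeNode
    newick: str
    clamped_negative: bool


def build_nj(dm: DistanceMatrix) -> NjResult:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the lexicographically lowest pair of
    cluster labels (a cluster is labeled by its smallest leaf).  Negative
    branch lengths are clamped to zero and flagged.
    """
    labels = list(dm.labels)
    if len(labels) < 2:
        raise ValueError("need at least two taxa")
    nodes: dict[str, TreeNode] = {l: TreeNode(label=l) for l in labels}
    dist: dict[frozenset, float] = {}
    for i, j in itertools.combinations(range(len(labels)), 2):
        dist[frozenset((labels[i], labels[j]))] = dm.matrix[i, j]
    active = sorted(nodes)
    clamped = False

    def d(x: str, y: str) -> float:
        return 0.0 if x == y else dist[frozenset((x, y))]

    while len(active) > 2:
        n = len(active)
        r = {x: sum(d(x, y) for y in active) for x in active}
        best = None
        for x, y in itertools.combinations(active, 2):
            q = (n - 2) * d(x, y) - r[x] - r[y]
            key = (q, min(x, y), max(x, y))
            if best is None or key < best:
                best = key
        _, x, y = best
        dxy = d(x, y)
        lx = dxy / 2 + (r[x] - r[y]) / (2 * (n - 2))
        ly = dxy - lx
        if lx < 0 or ly < 0:
            clamped = True
            lx, ly = max(lx, 0.0), max(ly, 0.0)
        new_label = min(x, y)
        parent = TreeNode(children=[(nodes[x], lx), (nodes[y], ly)])
        for z in active:
            if z in (x, y):
                continue
            dz = (d(x, z) + d(y, z) - dxy) / 2
            dist[frozenset((new_label, z))] = max(dz, 0.0)
        active = sorted(set(active) - {x, y} | {new_label})
        nodes[new_label] = parent

    x, y = active
    dxy = d(x, y)
    a, b = nodes[x], nodes[y]
    if not a.is_leaf:
        root = TreeNode(children=a.children + [(b, max(dxy, 0.0))])
    elif not b.is_leaf:
        root = TreeNode(children=b.children + [(a, max(dxy, 0.0))])
    else:
        root = TreeNode(children=[(a, 0.0), (b, max(dxy, 0.0))])
    if dxy < 0:
        clamped = True
    return NjResult(root, root.to_newick(), clamped)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions (as frozensets of the two leaf sets)."""
    all_leaves = frozenset(tree.leaves())
    parts: set[frozenset] = set()

    def visit(node: TreeNode) -> None:
        for child, _ in node.children:
            if not child.is_leaf:
                side = frozenset(child.leaves())
                other = all_leaves - side
                if len(side) >= 2 and len(other) >= 2:
                    parts.add(frozenset((side, other)))
            visit(child)

    visit(tree)
    return parts


def bootstrap_support(alignment: dict[str, str], n_reps: int = 1000,
                      seed: int = 0) -> tuple[NjResult, dict[frozenset, float]]:
    """Column-resampling bootstrap support for the NJ tree of an alignment.

    Returns the full-data tree and, per internal edge (bipartition), the
    fraction of replicate trees containing it.
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    labels = sorted(alignment)
    length = len(alignment[labels[0]])
    if any(len(alignment[l]) != length for l in labels):
        raise ValueError("alignment rows must have equal length")
    reference = build_nj(distance_matrix(alignment))
    ref_parts = bipartitions(reference.tree)
    counts = {part: 0 for part in ref_parts}
    rng = np.random.default_rng(seed)
    cols = {l: np.array(list(alignment[l])) for l in labels}
    for _ in range(n_reps):
        idx = rng.integers(0, length, size=length)
        resampled = {l: "".join(cols[l][idx]) for l in labels}
        tree = build_nj(distance_matrix(resampled))
        parts = bipartitions(tree.tree)
        for part in counts:
            if part in parts:
                counts[part] += 1
    support = {part: c / n_reps for part, c in counts.items()}
    return reference, support


# ---------------------------------------------------------------------------
# Nei-Gojobori substitution counting

def _syn_fraction(codon: str) -> float:
    """Synonymous site count of one codon (sum over positions of the
    fraction of single-nt changes that preserve the amino acid; changes to
    stop codons count as non-synonymous)."""
    aa = _CODON_TO_AA.get(codon)
    if aa is None:
        raise ValueError(f"stop or invalid codon {codon!r} inside CDS")
    syn_sites = 0.0
    for pos in range(3):
        syn = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            new = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_TO_AA.get(new) == aa:
                syn += 1
        syn_sites += syn / 3.0
    return syn_sites


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences between two codons, averaged
    over all shortest mutational pathways; pathways crossing a stop codon are
    excluded (all-stop-crossing pairs fall back to averaging over all)."""
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    nd = len(diff_positions)
    if nd == 0:
        return 0.0, 0.0
    if nd == 1:
        pos = diff_positions[0]
        new = c1[:pos] + c2[pos] + c1[pos + 1 :]
        if _CODON_TO_AA.get(new) == _CODON_TO_AA.get(c1):
            return 1.0, 0.0
        return 0.0, 1.0
    paths = []
    for order in itertools.permutations(diff_positions):
        current = c1
        syn = nonsyn = 0
        crosses_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in _STOPS:
                crosses_stop = True
            if _CODON_TO_AA.get(nxt) == _CODON_TO_AA.get(current) and nxt not in _STOPS \
                    and current not in _STOPS:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        paths.append((syn, nonsyn, crosses_stop))
    valid = [(s, n) for s, n, crossed in paths if not crossed]
    if not valid:
        valid = [(s, n) for s, n, _ in paths]
    syn = sum(s for s, _ in valid) / len(valid)
    nonsyn = sum(n for _, n in valid) / len(valid)
    return syn, nonsyn


def count_substitutions_ng(cds_a: str, cds_b: str) -> tuple[float, float, float, float]:
    """Nei-Gojobori counts between two in-frame, equal-length CDS.

    Returns (Sd, Nd, S, N): observed synonymous / non-synonymous differences
    and synonymous / non-synonymous site counts (averaged over both
    sequences).  Codons containing gaps or ambiguity codes are skipped.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("CDS pair must be aligned to equal length")
    if len(cds_a) % 3:
        raise ValueError("CDS length must be divisible by 3")
    sd = nd_total = 0.0
    s_a = s_b = 0.0
    n_codons = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if set(ca + cb) - set("ACGT"):
            continue
        if ca in _STOPS or cb in _STOPS:
            continue
        n_codons += 1
        s_a += _syn_fraction(ca)
        s_b += _syn_fraction(cb)
        syn, nonsyn = _pathway_counts(ca, cb)
        sd += syn
        nd_total += nonsyn
    s_sites = (s_a + s_b) / 2
    n_sites = 3 * n_codons - s_sites
    return sd, nd_total, s_sites, n_sites


@dataclass
class SubstitutionStats:
    sites_compared: int
    total_freq: float
    syn_freq: float
    nonsyn_freq: float
    per_pair: list[dict] = field(default_factory=list)


def mutation_frequency(pairs: list[tuple[str, str]]) -> SubstitutionStats:
    """Pooled substitution frequencies across aligned ortholog CDS pairs.

    The denominator is the total number of compared sites (pairwise
    deletion: codons containing gaps or ambiguity are dropped), so the
    synonymous and non-synonymous frequencies sum exactly to the total.
    """
    total_sites = 0
    total_diffs = 0.0
    total_sd = total_nd = 0.0
    per_pair = []
    for a, b in pairs:
        sd, nd, s_sites, n_sites = count_substitutions_ng(a, b)
        codons = int(round((s_sites + n_sites) / 3))
        sites = 3 * codons
        total_sites += sites
        total_sd += sd
        total_nd += nd
        total_diffs += sd + nd
        per_pair.append({"Sd": sd, "Nd": nd, "S": s_sites, "N": n_sites,
                         "sites": sites})
    if total_sites == 0:
        return SubstitutionStats(0, 0.0, 0.0, 0.0, per_pair)
    return SubstitutionStats(
        sites_compared=total_sites,
        total_freq=total_diffs / total_sites,
        syn_freq=total_sd / total_sites,
        nonsyn_freq=total_nd / total_sites,
        per_pair=per_pair,
    )


# ---------------------------------------------------------------------------
# multiple alignment convenience

def multiple_align(records: dict[str, str]) -> dict[str, str]:
    """Multiple protein alignment via MAFFT (used for tree input when no
    user-supplied alignment exists)."""
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fasta"
        with open(fasta, "w") as fh:
            for label, seq in records.items():
                fh.write(f">{label}\n{seq}\n")
        out = subprocess.run(["mafft", "--auto", "--quiet", str(fasta)],
                             capture_output=True, text=True, check=True)
    aligned: dict[str, str] = {}
    label = None
    for line in out.stdout.splitlines():
        if line.startswith(">"):
            label = line[1:].split()[0]
            aligned[label] = ""
        elif label:
            aligned[label] += line.strip().upper()
    return aligned
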