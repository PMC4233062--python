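"""Physical properties and functional-region detection for Hsf proteins.

An Hsf protein carries five recognizable regions: the DNA-binding domain
(DBD) near the N-terminus, the oligomerization region of two hydrophobic
heptad-repeat blocks (HR-A and HR-B) whose inter-block insertion length is
the class signature (21 residues in class A, none in class B, 7 in class C),
basic K/R clusters acting as nuclear localization signals (NLS), a
leucine-rich C-terminal nuclear export signal (NES), and - in class A only -
short acidic/aromatic activator (AHA) windows.

All coordinates are 1-based inclusive.  The linker length follows the
family-census convention ``linker = HR-A/B start - DBD end`` (no -1).
"""
from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profile import DbdProfile, DBD_MIN_LENGTH, default_profile

HYDROPHOBIC = set("LIVMF")
AROMATIC = set("WFY")
ACIDIC = set("ED")
AHA_FAVOURED = AROMATIC | ACIDIC | set("LIV")

CANONICAL_NES = "LTEQMGLL"
CANONICAL_NES_B = re.compile(r"L[GR]LNLM")
_NES_GENERAL = re.compile(r"[LIVMF].{1,3}[LIVMF].{1,3}[LIVMF].[LIVMF]")
_NLS_RUN = re.compile(r"[KR]+(?:[^KR][KR]+)?")

WATER_MASS = 18.0153


def _load_table(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("hsfkit.data").joinpath(name)
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


_MASSES: dict[str, float] | None = None
_PKA: pd.DataFrame | None = None


def residue_masses() -> dict[str, float]:
    global _MASSES
    if _MASSES is None:
        df = _load_table("aa_masses.tsv")
        _MASSES = dict(zip(df["aa"], df["mass"]))
    return _MASSES


def pka_table() -> pd.DataFrame:
    global _PKA
    if _PKA is None:
        _PKA = _load_table("pka_bjellqvist.tsv")
    return _PKA


@dataclass(frozen=True)
class ProteinProperties:
    length: int
    pi: float
    mw: float


@dataclass
class NlsHit:
    position: int  # 1-based start
    motif: str


@dataclass
class NesHit:
    position: int
    motif: str
    canonical: bool


@dataclass
class AhaHit:
    position: int
    window: str
    score: float


@dataclass
class DomainAnnotation:
    """Coordinates and evidence for the functional regions of one protein."""

    protein_id: str
    length: int
    dbd: tuple[int, int] | None = None
    dbd_score: float = float("nan")
    hra: tuple[int, int] | None = None
    hrb: tuple[int, int] | None = None
    insertion_raw: int | None = None
    insertion_snapped: int | None = None
    nls_hits: list[NlsHit] = field(default_factory=list)
    nes_hits: list[NesHit] = field(default_factory=list)
    aha_hits: list[AhaHit] = field(default_factory=list)

    @property
    def linker_length(self) -> int | None:
        if self.dbd is None or self.hra is None:
            return None
        return self.hra[0] - self.dbd[1]

    @property
    def insertion_length(self) -> int | None:
        """Snapped insertion when within tolerance of a class signature, else raw."""
        if self.insertion_snapped is not None:
            return self.insertion_snapped
        return self.insertion_raw

    @property
    def has_dbd(self) -> bool:
        return self.dbd is not None

    @property
    def has_hrab(self) -> bool:
        return self.hra is not None and self.hrb is not None


# ---------------------------------------------------------------------------
# physical properties

def compute_mw(protein: str) -> float:
    """Average molecular mass in Daltons (residue masses + one water)."""
    if not protein:
        raise ValueError("empty protein sequence")
    masses = residue_masses()
    try:
        total = sum(masses[a] for a in protein)
    except KeyError as exc:
        raise ValueError(f"no average mass for residue {exc.args[0]!r}") from None
    return total + WATER_MASS


def net_charge(protein: str, ph: float) -> float:
    """Net charge of the protein at a given pH under the packaged pKa set."""
    counts: dict[str, int] = {}
    for a in protein:
        counts[a] = counts.get(a, 0) + 1
    charge = 0.0
    for row in pka_table().itertuples(index=False):
        if row.group == "nterm":
            n = 1
        elif row.group == "cterm":
            n = 1
        else:
            n = counts.get(row.group, 0)
        if n == 0:
            continue
        if row.kind == "positive":
            charge += n / (1.0 + 10.0 ** (ph - row.pka))
        else:
            charge -= n / (1.0 + 10.0 ** (row.pka - ph))
    return charge


def compute_pi(protein: str, tol: float = 1e-3) -> float:
    """Isoelectric point by bisection on the net-charge curve."""
    if not protein:
        raise ValueError("empty protein sequence")
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        q = net_charge(protein, mid)
        if abs(q) < tol and (hi - lo) < 1e-4:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def compute_properties(protein: str) -> ProteinProperties:
    return ProteinProperties(len(protein), compute_pi(protein), compute_mw(protein))


# ---------------------------------------------------------------------------
# DBD detection

def _best_window(protein: str, profile: DbdProfile) -> tuple[int, int, float] | None:
    """Best full or terminally truncated profile placement (1-based coords)."""
    best: tuple[int, int, float] | None = None
    scores = profile.window_scores(protein)
    if scores.size:
        i = int(np.argmax(scores))
        best = (i + 1, i + profile.length, float(scores[i]))
    lo = profile.log_odds
    enc = np.array([profile_index(a) for a in protein])
    n = len(protein)
    for trunc_len in range(DBD_MIN_LENGTH, min(profile.length, n + 1)):
        # N-terminal truncation: profile suffix aligned at protein start
        if trunc_len <= n:
            window = enc[:trunc_len]
            rows = np.arange(profile.length - trunc_len, profile.length)
            score = float(np.where(window >= 0,
                                   lo[rows, np.clip(window, 0, 19)], 0.0).sum())
            if best is None or score > best[2]:
                best = (1, trunc_len, score)
            # C-terminal truncation: profile prefix aligned at protein end
            window = enc[n - trunc_len:]
            rows = np.arange(trunc_len)
            score = float(np.where(window >= 0,
                                   lo[rows, np.clip(window, 0, 19)], 0.0).sum())
            if best is None or score > best[2]:
                best = (n - trunc_len + 1, n, score)
    return best


def profile_index(a: str) -> int:
    from .profile import AA_INDEX

    return AA_INDEX.get(a, -1)


def calibrate_dbd_threshold(protein: str, profile: DbdProfile,
                            n_shuffles: int = 100, seed: int = 0) -> float:
    """Null score threshold: 99.9th percentile of the best-window score
    distribution on shuffled copies of the query.

    Best-window scores of shuffled sequences are near-Gumbel (extreme values
    of many window scores); the quantile comes from a moment-fit Gumbel
    rather than the empirical maximum, so the false-positive rate is
    controlled beyond the number of shuffles actually drawn.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(protein))
    maxima = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuffled = "".join(rng.permutation(letters))
        scores = profile.window_scores(shuffled)
        if scores.size:
            maxima[k] = scores.max()
        else:  # query shorter than the profile: use truncated placements
            hit = _best_window(shuffled, profile)
            maxima[k] = hit[2] if hit is not None else -np.inf
    scale = np.sqrt(6.0 * maxima.var()) / np.pi
    loc = maxima.mean() - np.euler_gamma * scale
    return float(loc - scale * np.log(-np.log(0.999)))


def detect_dbd(protein: str, profile: DbdProfile | None = None,
               n_shuffles: int = 200, seed: int = 0,
               ) -> tuple[int, int, float] | None:
    """Locate the DBD as the best profile placement above the null threshold.

    Terminal truncations down to 83 residues are admitted so that proteins
    starting or ending mid-domain are still annotated.
    """
    if profile is None:
        profile = default_profile()
    if len(protein) < DBD_MIN_LENGTH:
        return None
    best = _best_window(protein, profile)
    if best is None:
        return None
    threshold = calibrate_dbd_threshold(protein, profile, n_shuffles, seed)
    if best[2] <= threshold:
        return None
    return best


# ---------------------------------------------------------------------------
# heptad repeats

def _heptad_block_starts(protein: str, start0: int) -> list[int]:
    """0-based starts i with hydrophobic residues at i, i+7 and i+14."""
    starts = []
    for i in range(max(start0, 0), len(protein) - 14):
        if (protein[i] in HYDROPHOBIC and protein[i + 7] in HYDROPHOBIC
                and protein[i + 14] in HYDROPHOBIC):
            starts.append(i)
    return starts


def detect_hrab(protein: str, dbd_end: int, snap_targets: tuple[int, ...] = (0, 7, 21),
                snap_tol: int = 2,
                ) -> tuple[tuple[int, int], tuple[int, int], int, int | None] | None:
    """Find the HR-A and HR-B heptad blocks C-terminal of the DBD.

    Returns ``(hra, hrb, insertion_raw, insertion_snapped)`` with 1-based
    inclusive block coordinates, or None when two blocks cannot be found.
    The raw insertion (residues strictly between the HR-A and HR-B cores) is
    snapped to the nearest class signature in ``snap_targets`` when within
    ``snap_tol``; otherwise the snapped value is None.
    """
    starts = _heptad_block_starts(protein, dbd_end)
    if not starts:
        return None
    s0 = starts[0]
    later = [s for s in starts if s >= s0 + 15]
    if not later:
        return None
    s1 = later[0]
    insertion_raw = s1 - s0 - 15
    snapped = None
    deltas = sorted((abs(insertion_raw - t), t) for t in snap_targets)
    if deltas and deltas[0][0] <= snap_tol:
        snapped = deltas[0][1]
    return (s0 + 1, s0 + 15), (s1 + 1, s1 + 15), insertion_raw, snapped


# ---------------------------------------------------------------------------
# short motifs

def find_nls(protein: str, search_from: int = 0) -> list[NlsHit]:
    """Basic K/R clusters: maximal runs of >=3 K/R residues allowing one
    single-residue interruption, C-terminal of ``search_from`` (1-based)."""
    hits = []
    for m in _NLS_RUN.finditer(protein):
        if sum(1 for a in m.group(0) if a in "KR") < 3:
            continue
        pos = m.start() + 1
        if pos <= search_from:
            continue
        hits.append(NlsHit(pos, m.group(0)))
    return hits


def find_nes(protein: str) -> list[NesHit]:
    """Leucine-rich export signals in the C-terminal 30% of the protein."""
    region_start0 = int(np.floor(len(protein) * 0.7))
    hits: list[NesHit] = []
    taken: list[tuple[int, int]] = []
    for m in re.finditer(re.escape(CANONICAL_NES), protein):
        if m.start() >= region_start0:
            hits.append(NesHit(m.start() + 1, m.group(0), True))
            taken.append((m.start(), m.end()))
    for m in CANONICAL_NES_B.finditer(protein):
        if m.start() >= region_start0:
            hits.append(NesHit(m.start() + 1, m.group(0), True))
            taken.append((m.start(), m.end()))
    for m in _NES_GENERAL.finditer(protein):
        if m.start() < region_start0:
            continue
        if any(m.start() < e and m.end() > s for s, e in taken):
            continue
        hits.append(NesHit(m.start() + 1, m.group(0), False))
    hits.sort(key=lambda h: h.position)
    return hits


def find_aha(protein: str, window: int = 12, search_from: int = 0,
             min_score: float = 0.6) -> list[AhaHit]:
    """Activator windows rich in aromatic (W/F/Y), large hydrophobic (L/I/V)
    and acidic (E/D) residues; requires at least one aromatic and one acidic
    residue.  Overlapping passing windows are merged."""
    passing: list[tuple[int, float]] = []  # 0-based start, score
    for i in range(max(search_from, 0), len(protein) - window + 1):
        win = protein[i : i + window]
        score = sum(1 for a in win if a in AHA_FAVOURED) / window
        if score < min_score:
            continue
        if not any(a in AROMATIC for a in win) or not any(a in ACIDIC for a in win):
            continue
        passing.append((i, score))
    hits: list[AhaHit] = []
    for start0, score in passing:
        if hits and start0 <= hits[-1].position - 1 + len(hits[-1].window) - 1:
            prev = hits[-1]
            new_end0 = start0 + window
            prev_start0 = prev.position - 1
            hits[-1] = AhaHit(prev.position,
                              protein[prev_start0:new_end0],
                              max(prev.score, score))
        else:
            hits.append(AhaHit(start0 + 1, protein[start0 : start0 + window], score))
    return hits


def predict_localization(annotation: DomainAnnotation) -> tuple[str, bool]:
    """Rule-based compartment call from NLS/NES presence.

    Returns ``(label, low_confidence)``.  NLS without NES keeps the protein
    nuclear; NLS plus NES implies nucleocytoplasmic shuttling.  With no NLS
    at all the call defaults to shuttling and is flagged low-confidence.
    """
    has_nls = bool(annotation.nls_hits)
    has_nes = bool(annotation.nes_hits)
    if has_nls and not has_nes:
        return "nucleus", False
    if has_nls and has_nes:
        return "nucleus+cytoplasm", False
    return "nucleus+cytoplasm", True


# ---------------------------------------------------------------------------
# full annotation

def annotate(protein_id: str, protein: str, profile: DbdProfile | None = None,
             seed: int = 0) -> DomainAnnotation:
    """Run every detector and assemble a :class:`DomainAnnotation`."""
    ann = DomainAnnotation(protein_id=protein_id, length=len(protein))
    dbd = detect_dbd(protein, profile=profile, seed=seed)
    if dbd is not None:
        ann.dbd = (dbd[0], dbd[1])
        ann.dbd_score = dbd[2]
    dbd_end = ann.dbd[1] if ann.dbd else 0
    hr = detect_hrab(protein, dbd_end)
    if hr is not None:
        ann.hra, ann.hrb, ann.insertion_raw, ann.insertion_snapped = hr
    ann.nls_hits = find_nls(protein, search_from=dbd_end)
    ann.nes_hits = find_nes(protein)
    hrb_end = ann.hrb[1] if ann.hrb else dbd_end
    ann.aha_hits = find_aha(protein, search_from=hrb_end)
    return ann
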