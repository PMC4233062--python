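"""Position-weight model of the Hsf DNA-binding domain (DBD).

The DBD is a compact fold of an antiparallel four-stranded beta-sheet packed
against three alpha-helices.  The packaged default profile is *synthetic*: it
is built deterministically from that secondary-structure layout (helix
positions favour helix-forming residues, strand positions favour
beta-branched/aromatic residues, loops favour turn formers), not from any
biological alignment, so the package carries no licensed sequence data.  Both
the protein generator (which samples planted DBDs from the profile) and the
detector (which scans query proteins with it) share this object.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

# Residue pools by secondary-structure state.
_HELIX = "AELKQRM"
_STRAND = "VIFYTW"
_LOOP = "GSNPD"

# Layout of the canonical 94-residue DBD: three helices, four strands.
_LAYOUT = [
    ("H", 15), ("L", 4), ("E", 7), ("L", 4), ("E", 7), ("L", 5),
    ("H", 15), ("L", 5), ("E", 7), ("L", 4), ("E", 7), ("L", 4), ("H", 10),
]
_POOLS = {"H": _HELIX, "E": _STRAND, "L": _LOOP}

#: Full profile length (majority DBD length in the family).
DBD_LENGTH = 94
#: Shortest admitted terminal truncation (shortest DBD variant).
DBD_MIN_LENGTH = 83

_BACKGROUND = np.full(20, 1.0 / 20)
_PROFILE_SEED = 940083  # fixed: the profile is package data, not a run parameter


@dataclass
class DbdProfile:
    """Position-weight matrix over the 20 amino acids plus its log-odds form."""

    pwm: np.ndarray  # (length, 20) probabilities
    consensus: str

    @property
    def length(self) -> int:
        return self.pwm.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.pwm / _BACKGROUND)

    def sample(self, rng: np.random.Generator) -> str:
        """Draw one DBD-like sequence from the per-position distributions."""
        idx = [rng.choice(20, p=row) for row in self.pwm]
        return "".join(AA[i] for i in idx)

    def window_scores(self, protein: str) -> np.ndarray:
        """Log-odds score of every full-length window of ``protein``.

        Unknown letters (X and friends) score neutrally (0 log-odds).
        """
        n = len(protein) - self.length + 1
        if n <= 0:
            return np.array([])
        encoded = np.array([AA_INDEX.get(a, -1) for a in protein])
        windows = np.lib.stride_tricks.sliding_window_view(encoded, self.length)
        lo = self.log_odds
        gathered = lo[np.arange(self.length)[None, :], np.clip(windows, 0, 19)]
        gathered = np.where(windows >= 0, gathered, 0.0)
        return gathered.sum(axis=1)


def build_default_profile() -> DbdProfile:
    """Construct the packaged synthetic DBD profile (deterministic)."""
    rng = np.random.default_rng(_PROFILE_SEED)
    consensus = []
    states = []
    for state, length in _LAYOUT:
        pool = _POOLS[state]
        for _ in range(length):
            consensus.append(pool[rng.integers(len(pool))])
            states.append(state)
    assert len(consensus) == DBD_LENGTH
    pwm = np.full((DBD_LENGTH, 20), 0.01 / 16)
    for pos, (aa, state) in enumerate(zip(consensus, states)):
        pool = _POOLS[state]
        alts = [a for a in pool if a != aa]
        pwm[pos, AA_INDEX[aa]] = 0.70
        for a in alts:
            pwm[pos, AA_INDEX[a]] = 0.29 / len(alts)
    pwm /= pwm.sum(axis=1, keepdims=True)
    return DbdProfile(pwm=pwm, consensus="".join(consensus))


_DEFAULT: DbdProfile | None = None


def default_profile() -> DbdProfile:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = build_default_profile()
    return _DEFAULT
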