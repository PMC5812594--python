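"""Per-residue SAH-score profiles.

Every sequence is treated as one continuous right-handed alpha-helix: residue 1
sits at heptad position ``a`` and the register never resets.  For each window
size w the raw score of the window anchored at a residue is the sum of all
outgoing i,i+3 / i,i+4 pair scores and network-triple scores of positions
inside the window; partners beyond the window end are included whenever they
exist in the sequence (the trailing helical turn interacts with the next
heptad), while partners beyond either sequence end are neutral dummies.
The raw sum is divided by the EEEEKKK window score, so 1.0 means "as good as a
perfect ER/K motif".  The score is assigned to the window's central residue
(windows 21/49) or to residue 8/15 of the window (windows 14/28); windows
overhanging a terminus are completed with dummy residues.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import (
    AA_INDEX,
    AMINO_ACIDS,
    HYDROPHOBIC,
    NETWORK_PATTERNS,
    NEUTRAL_SYMBOLS,
    NetworkKind,
    ScoringConfig,
    assignment_offset,
)
from .errors import ConfigError, InputError

HEPTAD_LETTERS = "abcdefg"
_ALLOWED = set(AMINO_ACIDS) | set(NEUTRAL_SYMBOLS)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence, optionally annotated with gene/transcript ids."""

    seq_id: str
    residues: str
    gene_id: Optional[str] = None
    transcript_id: Optional[str] = None

    def __post_init__(self):
        if not self.residues:
            raise InputError(f"sequence {self.seq_id!r} is empty")
        bad = sorted(set(self.residues) - _ALLOWED)
        if bad:
            raise InputError(
                f"sequence {self.seq_id!r} contains unsupported symbols {bad}; "
                f"allowed are the 20 standard residues plus {sorted(NEUTRAL_SYMBOLS)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ScoreProfile:
    """Normalized per-residue SAH-scores of one sequence for one window size."""

    seq_id: str
    window_size: int
    scores: np.ndarray  # one entry per residue, sequence order

    def __post_init__(self):
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        if not np.all(np.isfinite(self.scores)):
            raise ValueError(f"profile of {self.seq_id!r} contains non-finite scores")


def heptad_position(index: int) -> str:
    """Heptad letter (a-g) of a 1-based residue index; residue 1 is ``a``."""
    if index < 1:
        raise InputError(f"residue index must be >= 1, got {index}")
    return HEPTAD_LETTERS[(index - 1) % 7]


def _encode(residues: str) -> np.ndarray:
    """Map residues to matrix indices; neutral/dummy symbols become -1."""
    table = np.full(128, -1, dtype=np.int8)
    for aa, i in AA_INDEX.items():
        table[ord(aa)] = i
    codes = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return table[codes]


def position_contributions(residues: str, config: ScoringConfig) -> np.ndarray:
    """Outgoing score contribution of every position (0-based array).

    Entry i sums the i,i+3 and i,i+4 pair scores of position i plus the
    network scores of all triples whose first member is i.  Partners that fall
    beyond the sequence end, and any pair or triple with a dummy member,
    contribute zero.
    """
    codes = _encode(residues)
    n = codes.size
    contrib = np.zeros(n, dtype=float)
    for spacing, matrix in ((3, config.matrix_i3), (4, config.matrix_i4)):
        if n <= spacing:
            continue
        left = codes[:-spacing]
        right = codes[spacing:]
        valid = (left >= 0) & (right >= 0)
        vals = np.where(valid, matrix.scores[left, right], 0.0)
        contrib[: n - spacing] += vals

    hydro = np.zeros(n, dtype=bool)
    charge = np.zeros(n, dtype=np.int8)
    for i, aa in enumerate(residues):
        if aa in HYDROPHOBIC:
            hydro[i] = True
        if aa in "DE":
            charge[i] = -1
        elif aa in "KR":
            charge[i] = 1

    for rule in config.network_rules:
        if rule.score == 0:
            continue
        for (_, d1, d2) in NETWORK_PATTERNS:
            if n <= d2:
                continue
            a = slice(0, n - d2)
            b = slice(d1, n - d2 + d1)
            c = slice(d2, n)
            if rule.kind is NetworkKind.HYDROPHOBIC:
                hit = hydro[a] & hydro[b] & hydro[c]
            else:
                hit = (charge[a] * charge[b] == -1) & (charge[b] * charge[c] == -1)
            contrib[: n - d2] += rule.score * hit
    return contrib


def window_raw_score_unchecked(
    residues: str, start: int, window_size: int, config: ScoringConfig
) -> float:
    """Raw window score for a window starting at 1-based residue ``start``.

    ``start`` may be non-positive or the window may overhang the end: the
    out-of-sequence part is dummy padding and contributes nothing.
    """
    contrib = position_contributions(residues, config)
    lo = max(start - 1, 0)
    hi = min(start - 1 + window_size, len(residues))
    if hi <= lo:
        return 0.0
    return float(np.sum(contrib[lo:hi]))


def window_raw_score(
    record: ProteinRecord, start: int, window_size: int, config: ScoringConfig
) -> float:
    """Raw (unnormalized) score of one window of a protein sequence."""
    if window_size not in config.window_sizes:
        raise ConfigError(
            f"window size {window_size} is not configured (configured: {config.window_sizes})"
        )
    return window_raw_score_unchecked(record.residues, start, window_size, config)


def score_profile(
    record: ProteinRecord, window_size: int, config: ScoringConfig
) -> ScoreProfile:
    """Normalized SAH-score profile of a sequence for one window size.

    The profile has one score per residue.  Residue r (1-based) receives the
    score of the window in which it occupies the assignment position
    (``assignment_offset(window_size)``), i.e. the window starting at
    ``r - offset + 1``; terminal windows are dummy-padded.
    """
    if window_size not in config.window_sizes:
        raise ConfigError(
            f"window size {window_size} is not configured (configured: {config.window_sizes})"
        )
    norm = config.max_window_scores[window_size]
    contrib = position_contributions(record.residues, config)
    n = contrib.size
    offset = assignment_offset(window_size)
    # window of residue r (0-based r0): [r0 - offset + 1, r0 - offset + window_size]
    csum = np.concatenate(([0.0], np.cumsum(contrib)))
    r0 = np.arange(n)
    lo = np.clip(r0 - offset + 1, 0, n)
    hi = np.clip(r0 - offset + 1 + window_size, 0, n)
    scores = (csum[hi] - csum[lo]) / norm
    return ScoreProfile(seq_id=record.seq_id, window_size=window_size, scores=scores)


def score_profiles(record: ProteinRecord, config: ScoringConfig) -> dict:
    """Profiles for all configured window sizes, keyed by window size."""
    return {w: score_profile(record, w, config) for w in config.window_sizes}
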