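"""Scoring model configuration: interaction matrices, network rules, cutoffs.

The SAH (single alpha-helix) score of a sequence window is the sum of pairwise
side-chain interaction scores at i,i+3 and i,i+4 spacing -- the two spacings at
which side chains meet on one face of an alpha-helix -- plus network scores for
residue triples, normalized so that a perfect EEEEKKK repeat scores 1.  The two
20x20 matrices are directional: the row is the N-terminal partner (position i),
the column the C-terminal partner (i+3 or i+4), so that e.g. the E->R salt
bridge can score higher than R->E.
"""
from __future__ import annotations

import enum
import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError

#: The 20 standard amino acids, in the row/column order of the matrix files.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWVY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Symbols tolerated in input sequences but treated as strictly neutral
#: (no interactions), like the dummy residues used to pad terminal windows.
NEUTRAL_SYMBOLS = frozenset("XUBZO*")

ACIDIC = frozenset("DE")
BASIC = frozenset("KR")
HYDROPHOBIC = frozenset("VILMFY")

#: Index offsets of the four network-interaction triples, relative to the
#: first member: i,i+3,i+6 / i,i+3,i+7 / i,i+4,i+7 / i,i+4,i+8.
NETWORK_PATTERNS = ((0, 3, 6), (0, 3, 7), (0, 4, 7), (0, 4, 8))

#: The canonical SAH motif used for normalization.
PERFECT_REPEAT = "EEEEKKK"


class Spacing(enum.Enum):
    I3 = 3
    I4 = 4


class NetworkKind(enum.Enum):
    HYDROPHOBIC = "hydrophobic"
    CHARGED = "charged"


@dataclass(frozen=True)
class ScoringMatrix:
    """Directional 20x20 interaction score table for one spacing."""

    spacing: Spacing
    scores: np.ndarray  # shape (20, 20), row = residue i, col = partner

    def __post_init__(self):
        if self.scores.shape != (20, 20):
            raise ConfigError(
                f"scoring matrix for {self.spacing.name} must be 20x20, "
                f"got {self.scores.shape}"
            )
        if not np.all(np.isfinite(self.scores)):
            raise ConfigError(f"scoring matrix for {self.spacing.name} has non-finite entries")

    def pair_score(self, donor: str, acceptor: str) -> float:
        """Interaction score of residue ``donor`` at i with ``acceptor`` at i+spacing.

        Symbols outside the 20 standard residues are neutral and score 0.
        """
        i = AA_INDEX.get(donor)
        j = AA_INDEX.get(acceptor)
        if i is None or j is None:
            return 0.0
        return float(self.scores[i, j])


@dataclass(frozen=True)
class NetworkRule:
    """A triple-interaction rule on the four canonical spacing patterns.

    Hydrophobic triples mark potential coiled-coil seams and score negatively;
    alternating oppositely-charged triples stabilize single helices beyond the
    sum of their pairwise salt bridges and score positively.
    """

    kind: NetworkKind
    score: float
    spacing_patterns: tuple = NETWORK_PATTERNS

    def __post_init__(self):
        if tuple(self.spacing_patterns) != NETWORK_PATTERNS:
            raise ConfigError("network rules are defined on the four canonical triples only")
        if self.kind is NetworkKind.HYDROPHOBIC and self.score > 0:
            raise ConfigError("hydrophobic network score must be <= 0")
        if self.kind is NetworkKind.CHARGED and self.score < 0:
            raise ConfigError("charged network score must be >= 0")

    def matches(self, a: str, b: str, c: str) -> bool:
        if self.kind is NetworkKind.HYDROPHOBIC:
            return a in HYDROPHOBIC and b in HYDROPHOBIC and c in HYDROPHOBIC
        qa, qb, qc = (_charge(a), _charge(b), _charge(c))
        return qa * qb == -1 and qb * qc == -1


def _charge(aa: str) -> int:
    if aa in ACIDIC:
        return -1
    if aa in BASIC:
        return 1
    return 0


def assignment_offset(window_size: int) -> int:
    """1-based position within a window to which its score is assigned.

    Central residue for odd windows (21 -> 11, 49 -> 25), the residue just
    past the midpoint for even ones (14 -> 8, 28 -> 15).
    """
    return window_size // 2 + 1


@dataclass
class ScoringConfig:
    """Full scoring model: matrices, network rules, windows, and cutoffs."""

    matrix_i3: ScoringMatrix
    matrix_i4: ScoringMatrix
    network_rules: list = field(default_factory=list)
    window_sizes: tuple = (14, 21, 28, 49)
    residue_cutoff: float = 0.25
    domain_score_cutoffs: dict = field(
        default_factory=lambda: {14: 0.35, 21: 0.32, 28: 0.29, 49: 0.25}
    )
    domain_subwindow: int = 14
    below_cutoff_tolerance: float = 0.20
    min_overlap_aa: int = 5
    #: raw EEEEKKK window scores per window size; derived, not user-set.
    max_window_scores: dict = field(default_factory=dict)

    def __post_init__(self):
        self.window_sizes = tuple(sorted(int(w) for w in self.window_sizes))
        if not self.window_sizes:
            raise ConfigError("at least one window size is required")
        if any(w < 1 for w in self.window_sizes):
            raise ConfigError("window sizes must be positive")
        if not 0.0 < self.residue_cutoff < 1.0:
            raise ConfigError("residue_cutoff must lie in (0, 1)")
        if not 0.0 <= self.below_cutoff_tolerance < 1.0:
            raise ConfigError("below_cutoff_tolerance must lie in [0, 1)")
        missing = [w for w in self.window_sizes if w not in self.domain_score_cutoffs]
        if missing:
            raise ConfigError(f"no domain-score cutoff configured for windows {missing}")
        if self.domain_subwindow < 1:
            raise ConfigError("domain_subwindow must be positive")
        if not self.max_window_scores:
            self.max_window_scores = {
                w: compute_normalization(self, w) for w in self.window_sizes
            }

    @property
    def min_window(self) -> int:
        return self.window_sizes[0]

    def network_scores(self) -> tuple:
        """(hydrophobic, charged) network scores, 0 for absent rules."""
        hydro = charged = 0.0
        for rule in self.network_rules:
            if rule.kind is NetworkKind.HYDROPHOBIC:
                hydro = rule.score
            else:
                charged = rule.score
        return hydro, charged

    def snapshot(self) -> dict:
        """JSON-serializable snapshot sufficient to reproduce the run."""
        hydro, charged = self.network_scores()
        return {
            "window_sizes": list(self.window_sizes),
            "residue_cutoff": self.residue_cutoff,
            "domain_score_cutoffs": {str(k): v for k, v in self.domain_score_cutoffs.items()},
            "domain_subwindow": self.domain_subwindow,
            "below_cutoff_tolerance": self.below_cutoff_tolerance,
            "min_overlap_aa": self.min_overlap_aa,
            "network_score_hydrophobic": hydro,
            "network_score_charged": charged,
            "max_window_scores": {str(k): v for k, v in self.max_window_scores.items()},
            "matrix_i3": [list(map(float, row)) for row in self.matrix_i3.scores],
            "matrix_i4": [list(map(float, row)) for row in self.matrix_i4.scores],
        }

    @classmethod
    def from_snapshot(cls, snap: dict) -> "ScoringConfig":
        rules = [
            NetworkRule(NetworkKind.HYDROPHOBIC, snap["network_score_hydrophobic"]),
            NetworkRule(NetworkKind.CHARGED, snap["network_score_charged"]),
        ]
        return cls(
            matrix_i3=ScoringMatrix(Spacing.I3, np.asarray(snap["matrix_i3"], dtype=float)),
            matrix_i4=ScoringMatrix(Spacing.I4, np.asarray(snap["matrix_i4"], dtype=float)),
            network_rules=rules,
            window_sizes=tuple(snap["window_sizes"]),
            residue_cutoff=snap["residue_cutoff"],
            domain_score_cutoffs={int(k): v for k, v in snap["domain_score_cutoffs"].items()},
            domain_subwindow=snap["domain_subwindow"],
            below_cutoff_tolerance=snap["below_cutoff_tolerance"],
            min_overlap_aa=snap["min_overlap_aa"],
            max_window_scores={int(k): v for k, v in snap["max_window_scores"].items()},
        )


def load_matrix(path, spacing: Spacing) -> ScoringMatrix:
    """Load one 20x20 interaction matrix from a labelled CSV file.

    The first column holds the donor residue (position i), the header row the
    acceptor residue (position i+3 or i+4).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"scoring matrix file not found: {path}")
    try:
        frame = pd.read_csv(path, index_col=0)
    except Exception as exc:  # malformed CSV
        raise ConfigError(f"cannot parse scoring matrix {path}: {exc}") from exc
    frame.index = frame.index.astype(str).str.strip()
    frame.columns = frame.columns.astype(str).str.strip()
    for aa in AMINO_ACIDS:
        if aa not in frame.index:
            raise ConfigError(f"scoring matrix {path} is missing a row for residue {aa!r}")
        if aa not in frame.columns:
            raise ConfigError(f"scoring matrix {path} is missing a column for residue {aa!r}")
    frame = frame.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)]
    values = np.empty((20, 20), dtype=float)
    for i, row_aa in enumerate(AMINO_ACIDS):
        for j, col_aa in enumerate(AMINO_ACIDS):
            cell = frame.iat[i, j]
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise ConfigError(
                    f"non-numeric entry {cell!r} in {path} at row {row_aa!r}, column {col_aa!r}"
                ) from None
            if not math.isfinite(v):
                raise ConfigError(f"non-finite entry in {path} at row {row_aa!r}, column {col_aa!r}")
            values[i, j] = v
    return ScoringMatrix(spacing=spacing, scores=values)


def compute_normalization(config: ScoringConfig, window_size: int) -> float:
    """Raw window score of a ``window_size`` window at the start of a long
    (EEEEKKK)n repeat, under exactly the window-scoring rules applied to real
    sequences (including the trailing-turn pairs into the next heptad).

    This is the score that normalizes to 1; it must be positive.
    """
    # local import: scoring builds on this module
    from .scoring import window_raw_score_unchecked

    n_repeats = (window_size + 8) // 7 + 2
    repeat = PERFECT_REPEAT * n_repeats
    raw = window_raw_score_unchecked(repeat, 1, window_size, config)
    if raw <= 0:
        raise ConfigError(
            f"matrices cannot normalize: EEEEKKK window score for window "
            f"{window_size} is {raw:g} (must be positive)"
        )
    return raw


def default_network_rules(hydrophobic: float = -0.25, charged: float = 0.25) -> list:
    return [
        NetworkRule(NetworkKind.HYDROPHOBIC, hydrophobic),
        NetworkRule(NetworkKind.CHARGED, charged),
    ]


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("sahscan") / "data" / name)


def load_config(path=None, **overrides) -> ScoringConfig:
    """Build a ScoringConfig from a YAML config file (default: bundled config).

    Keyword overrides replace individual keys of the loaded document, e.g.
    ``load_config(residue_cutoff=0.3)``.
    """
    cfg_path = _data_path("default_config.yaml") if path is None else Path(path)
    if not cfg_path.exists():
        raise ConfigError(f"config file not found: {cfg_path}")
    with open(cfg_path) as fh:
        doc = yaml.safe_load(fh) or {}
    doc.update({k: v for k, v in overrides.items() if v is not None})

    base = cfg_path.parent

    def resolve(name, default_name):
        raw = doc.get(name, default_name)
        p = Path(raw)
        return p if p.is_absolute() else base / p

    matrix_i3 = load_matrix(resolve("matrix_i3", "scoring_matrix_i_3.csv"), Spacing.I3)
    matrix_i4 = load_matrix(resolve("matrix_i4", "scoring_matrix_i_4.csv"), Spacing.I4)
    cutoffs = {int(k): float(v) for k, v in dict(doc.get("domain_score_cutoffs", {})).items()}
    if not cutoffs:
        cutoffs = {14: 0.35, 21: 0.32, 28: 0.29, 49: 0.25}
    return ScoringConfig(
        matrix_i3=matrix_i3,
        matrix_i4=matrix_i4,
        network_rules=default_network_rules(
            hydrophobic=float(doc.get("network_score_hydrophobic", -0.25)),
            charged=float(doc.get("network_score_charged", 0.25)),
        ),
        window_sizes=tuple(doc.get("window_sizes", (14, 21, 28, 49))),
        residue_cutoff=float(doc.get("residue_cutoff", 0.25)),
        domain_score_cutoffs=cutoffs,
        domain_subwindow=int(doc.get("domain_subwindow", 14)),
        below_cutoff_tolerance=float(doc.get("below_cutoff_tolerance", 0.20)),
        min_overlap_aa=int(doc.get("min_overlap_aa", 5)),
    )


def default_config() -> ScoringConfig:
    """The shipped default configuration (bundled matrices and cutoffs)."""
    return load_config(None)
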