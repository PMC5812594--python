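"""SAH-domain segmentation and scoring.

A domain is a maximal stretch of a score profile that starts and ends above
the residue cutoff, contains at most a tolerated fraction (default 20%) of
at-or-below-cutoff residues, and is at least as long as the detection window.
Its SAH-domain-score is the maximum mean score over all sub-windows of a fixed
length (default 14), which makes domains of different lengths comparable.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import ScoringConfig
from .errors import ConfigError, SahScanError
from .scoring import ProteinRecord, ScoreProfile


@dataclass(frozen=True)
class SahDomain:
    """A detected SAH-domain, 1-based inclusive coordinates."""

    seq_id: str
    window_size: int
    start: int
    end: int
    subsequence: str
    residue_scores: np.ndarray
    domain_score: float
    below_cutoff_fraction: float

    def __post_init__(self):
        object.__setattr__(
            self, "residue_scores", np.asarray(self.residue_scores, dtype=float)
        )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def detect_domains(
    profile: ScoreProfile, config: ScoringConfig, record: ProteinRecord
) -> list:
    """Segment a profile into unfiltered SAH-domain candidates.

    Candidates are built deterministically: maximal runs of residues strictly
    above the residue cutoff are scanned left to right and greedily merged
    with the next run whenever the union span (gap included) keeps its
    below-cutoff fraction within tolerance; spans shorter than the window are
    discarded.  Candidates carry their SAH-domain-score; filtering against the
    per-window cutoff is a separate step (:func:`filter_domains`).
    """
    if record.seq_id != profile.seq_id:
        raise SahScanError(
            f"profile {profile.seq_id!r} does not belong to sequence {record.seq_id!r}"
        )
    scores = profile.scores
    above = scores > config.residue_cutoff
    tol = config.below_cutoff_tolerance

    runs = _runs(above)
    spans = []
    for run in runs:
        if spans:
            s0 = spans[-1][0]
            e1 = run[1]
            below = int(np.sum(~above[s0 : e1 + 1]))
            if below / (e1 - s0 + 1) <= tol:
                spans[-1][1] = e1
                continue
        spans.append(list(run))

    domains = []
    for s0, e0 in spans:
        length = e0 - s0 + 1
        if length < profile.window_size:
            continue
        below = int(np.sum(~above[s0 : e0 + 1]))
        candidate = SahDomain(
            seq_id=profile.seq_id,
            window_size=profile.window_size,
            start=s0 + 1,
            end=e0 + 1,
            subsequence=record.residues[s0 : e0 + 1],
            residue_scores=scores[s0 : e0 + 1].copy(),
            domain_score=float("nan"),
            below_cutoff_fraction=below / length,
        )
        domains.append(replace(candidate, domain_score=domain_score(candidate, config)))
    return domains


def _runs(mask: np.ndarray) -> list:
    """Maximal runs of True as (start, end) 0-based inclusive pairs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return [(int(s), int(e - 1)) for s, e in zip(edges[::2], edges[1::2])]


def domain_score(candidate: SahDomain, config: ScoringConfig) -> float:
    """Maximum mean residue score over all contiguous sub-windows.

    The sub-window length is ``config.domain_subwindow``, capped at the
    candidate's detection window so every candidate is scorable; a candidate
    of length L yields L - subwindow + 1 evaluated means.
    """
    sub = min(config.domain_subwindow, candidate.window_size)
    scores = candidate.residue_scores
    if scores.size < sub:
        raise SahScanError(
            f"candidate of length {scores.size} is shorter than sub-window {sub}"
        )
    csum = np.concatenate(([0.0], np.cumsum(scores)))
    means = (csum[sub:] - csum[:-sub]) / sub
    return float(means.max())


def filter_domains(candidates: list, config: ScoringConfig) -> list:
    """Keep candidates whose SAH-domain-score reaches the per-window cutoff."""
    kept = []
    for cand in candidates:
        try:
            cutoff = config.domain_score_cutoffs[cand.window_size]
        except KeyError:
            raise ConfigError(
                f"no domain-score cutoff configured for window {cand.window_size}"
            ) from None
        if cand.domain_score >= cutoff:
            kept.append(cand)
    return kept


def predict_domains(
    record: ProteinRecord, config: ScoringConfig, window_sizes=None
) -> dict:
    """Full per-sequence prediction: profiles -> candidates -> filtered domains.

    Returns ``{window_size: (profile, domains)}``.
    """
    from .scoring import score_profile

    out = {}
    for w in window_sizes or config.window_sizes:
        profile = score_profile(record, w, config)
        candidates = detect_domains(profile, config, record)
        out[w] = (profile, filter_domains(candidates, config))
    return out
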