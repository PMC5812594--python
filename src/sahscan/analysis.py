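"""Dataset-level analytics over predicted SAH-domains.

Covers the descriptive statistics used to characterize SAH-domains across a
proteome: amino-acid composition, heptad-pattern frequencies, domain counts
per sequence, protein-length distributions, and the comparison of domains
across alternative transcripts of a gene (unique domains, their presence
fractions, and inclusion/overlap relations).
"""
from __future__ import annotations

import enum
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .config import AMINO_ACIDS
from .errors import AnalysisError, InputError

#: Charged or polar residues whose side chains dominate SAH stabilization.
CHARGED_POLAR = frozenset("DEKRNQ")


class RelationFlag(enum.Enum):
    INCLUDING = "including"
    INCLUDED = "included"
    OVERLAPPING = "overlapping"


@dataclass(frozen=True)
class HeptadCount:
    heptad: str
    count: int

    def __post_init__(self):
        if len(self.heptad) != 7:
            raise ValueError(f"heptad must have 7 residues, got {self.heptad!r}")


@dataclass(frozen=True)
class CompositionTable:
    """Pooled residue composition of a set of SAH-domains."""

    fractions: dict  # residue -> fraction over all domain residues
    charged_polar_fraction: float
    heptad_equivalent: float  # charged/polar fraction expressed in heptad positions

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": list(self.fractions), "fraction": list(self.fractions.values())}
        )


@dataclass
class UniqueDomain:
    """A gene-level deduplicated SAH sequence with transcript presence info."""

    gene_id: str
    sequence: str
    carrier_transcripts: frozenset
    gene_transcript_count: int
    relation_flags: set = field(default_factory=set)

    @property
    def presence_fraction(self) -> float:
        return len(self.carrier_transcripts) / self.gene_transcript_count


def composition(domains: list) -> CompositionTable:
    """Residue composition pooled over all domains.

    Counts only the 20 standard residues (rare neutral placeholder symbols
    inside a domain are ignored).
    """
    if not domains:
        raise AnalysisError("composition requires at least one domain")
    counts = Counter()
    for dom in domains:
        counts.update(dom.subsequence)
    total = sum(counts[aa] for aa in AMINO_ACIDS)
    if total == 0:
        raise AnalysisError("domains contain no standard residues")
    fractions = {aa: counts[aa] / total for aa in AMINO_ACIDS}
    cp = sum(counts[aa] for aa in CHARGED_POLAR) / total
    return CompositionTable(
        fractions=fractions, charged_polar_fraction=cp, heptad_equivalent=cp * 7
    )


def heptad_frequency(domains: list, top_n: int = 10) -> list:
    """The ``top_n`` most frequent 7-residue substrings across all domains.

    Heptads are counted per occurrence with a sliding step of 1, ignoring the
    helix register; ties rank lexicographically.
    """
    if top_n < 1:
        raise AnalysisError("top_n must be >= 1")
    counts = Counter()
    for dom in domains:
        seq = dom.subsequence
        for i in range(len(seq) - 6):
            counts[seq[i : i + 7]] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [HeptadCount(heptad=h, count=c) for h, c in ranked[:top_n]]


def _terminal_overlap(a: str, b: str) -> int:
    """Longest terminal overlap (suffix of one == prefix of the other)."""
    best = 0
    for x, y in ((a, b), (b, a)):
        for k in range(min(len(x), len(y)) - 1, 0, -1):
            if x[-k:] == y[:k]:
                best = max(best, k)
                break
    return best


def unique_domains(
    domains: list, gene_map: dict, transcript_counts: dict, min_overlap_aa: int = 5
) -> list:
    """Deduplicate domain sequences per gene and relate them to each other.

    Identical domain subsequences within one gene collapse into a single
    UniqueDomain carrying the set of transcripts it occurs in.  Within a gene,
    a unique sequence that is a strict substring of a longer one is flagged
    INCLUDED (the longer one INCLUDING); two sequences sharing a terminal
    overlap of at least ``min_overlap_aa`` residues, neither containing the
    other, are both flagged OVERLAPPING.
    """
    groups = defaultdict(set)  # (gene, sequence) -> transcripts
    for dom in domains:
        if dom.seq_id not in gene_map:
            raise InputError(f"transcript {dom.seq_id!r} has no gene mapping")
        gene = gene_map[dom.seq_id]
        groups[(gene, dom.subsequence)].add(dom.seq_id)

    uniques = []
    for (gene, seq), transcripts in sorted(groups.items()):
        if gene not in transcript_counts:
            raise InputError(f"gene {gene!r} has no transcript count")
        uniques.append(
            UniqueDomain(
                gene_id=gene,
                sequence=seq,
                carrier_transcripts=frozenset(transcripts),
                gene_transcript_count=transcript_counts[gene],
            )
        )

    by_gene = defaultdict(list)
    for u in uniques:
        by_gene[u.gene_id].append(u)
    for members in by_gene.values():
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                shorter, longer = sorted((a, b), key=lambda u: len(u.sequence))
                if len(shorter.sequence) < len(longer.sequence) and shorter.sequence in longer.sequence:
                    shorter.relation_flags.add(RelationFlag.INCLUDED)
                    longer.relation_flags.add(RelationFlag.INCLUDING)
                elif _terminal_overlap(a.sequence, b.sequence) >= min_overlap_aa:
                    a.relation_flags.add(RelationFlag.OVERLAPPING)
                    b.relation_flags.add(RelationFlag.OVERLAPPING)
    return uniques


def presence_histogram(uniques: list, bin_width: float = 0.05) -> pd.DataFrame:
    """Histogram of presence fractions over (0, 1] in half-open bins (lo, hi]."""
    if not uniques:
        raise AnalysisError("presence_histogram requires at least one unique domain")
    n_bins = round(1.0 / bin_width)
    counts = [0] * n_bins
    for u in uniques:
        f = u.presence_fraction
        # ceil(f / bin_width) - 1, robust to float representation of the edges
        idx = min(n_bins - 1, max(0, math.ceil(f / bin_width - 1e-9) - 1))
        counts[idx] += 1
    lo = [i * bin_width for i in range(n_bins)]
    hi = [(i + 1) * bin_width for i in range(n_bins)]
    return pd.DataFrame({"bin_lo": lo, "bin_hi": hi, "count": counts})


def cross_gene_identity(uniques: list):
    """Identical and included unique-domain sequences across genes.

    Returns ``(identity_groups, inclusion_pairs)``: groups of genes sharing a
    verbatim unique-domain sequence, and (shorter, longer) pairs from
    different genes where one sequence is a strict substring of the other.
    """
    by_seq = defaultdict(set)
    for u in uniques:
        by_seq[u.sequence].add(u.gene_id)
    identity_groups = [
        {"sequence": seq, "genes": sorted(genes)}
        for seq, genes in sorted(by_seq.items())
        if len(genes) >= 2
    ]
    inclusion_pairs = []
    for i, a in enumerate(uniques):
        for b in uniques[i + 1 :]:
            if a.gene_id == b.gene_id:
                continue
            shorter, longer = sorted((a, b), key=lambda u: len(u.sequence))
            if len(shorter.sequence) < len(longer.sequence) and shorter.sequence in longer.sequence:
                inclusion_pairs.append((shorter, longer))
    return identity_groups, inclusion_pairs


def length_histogram(
    records: list, domains: list, bin: int = 50, max_len: int = 3000
) -> pd.DataFrame:
    """Aligned length histograms of all proteins vs. SAH-containing proteins.

    Lengths are binned in ``bin``-residue bins (1-50, 51-100, ...); proteins
    longer than ``max_len`` are omitted from both histograms.
    """
    with_domain = {d.seq_id for d in domains}
    n_bins = max_len // bin
    all_counts = [0] * n_bins
    sah_counts = [0] * n_bins
    for rec in records:
        if rec.length > max_len:
            continue
        idx = (rec.length - 1) // bin
        all_counts[idx] += 1
        if rec.seq_id in with_domain:
            sah_counts[idx] += 1
    return pd.DataFrame(
        {
            "bin_lo": [i * bin + 1 for i in range(n_bins)],
            "bin_hi": [(i + 1) * bin for i in range(n_bins)],
            "n_proteins": all_counts,
            "n_sah_proteins": sah_counts,
        }
    )


def multi_domain_counts(domains: list) -> tuple:
    """(total domains, sequences with >= 1 domain, sequences with >= 2)."""
    per_seq = Counter(d.seq_id for d in domains)
    return (
        len(domains),
        len(per_seq),
        sum(1 for c in per_seq.values() if c >= 2),
    )


def domains_by_length(domains: list) -> pd.DataFrame:
    """Count of predicted domains per domain length."""
    counts = Counter(d.length for d in domains)
    lengths = sorted(counts)
    return pd.DataFrame({"length": lengths, "count": [counts[l] for l in lengths]})
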