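"""Synthetic sequence generators and bundled reference sequences.

Planted datasets embed perfect ER/K motifs ((EEEEKKK)n repeats) inside
low-charge random flanks, so the inserts are the only high-scoring regions
and every pipeline stage can be exercised without external downloads.  The
generator also emits isoform families (several transcripts of one gene
sharing, extending, or truncating a domain) to exercise the transcript-level
comparisons.
"""
from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import InputError
from .scoring import ProteinRecord

#: Low-charge alphabet: none of these residues form salt bridges, so random
#: flanks stay far below the SAH residue cutoff.
BACKGROUND_ALPHABET = "GSTAPVL"

#: The 62-residue SAH region of human myosin-10 (ENSP00000421280), a
#: canonical natural SAH whose core carries the RERERER pattern.
MYO10_SAH = "AEKREQEEKKKQEEEEKKKREEEERERERERREAELRAQQEEETRKQQELEALQKSQKEAEL"


def make_perfect_sah(n_repeats: int) -> str:
    """(EEEEKKK) repeated ``n_repeats`` times."""
    if n_repeats < 1:
        raise InputError(f"n_repeats must be >= 1, got {n_repeats}")
    return "EEEEKKK" * n_repeats


@dataclass
class FixtureSpec:
    """Parameters of a planted synthetic dataset."""

    seed: int = 0
    n_planted: int = 6
    n_background: int = 2
    flank_length: tuple = (30, 50)
    insert_repeats: int = 5
    n_isoform_families: int = 0
    transcripts_per_gene: int = 4


def generate_planted_records(spec: FixtureSpec) -> tuple:
    """Build records and a ground-truth table for a FixtureSpec.

    Returns ``(records, truth)`` where truth has one row per planted insert
    with 1-based inclusive coordinates.  Identical specs produce identical
    records.
    """
    rng = random.Random(spec.seed)
    insert = make_perfect_sah(spec.insert_repeats)
    records = []
    truth_rows = []

    def flank():
        n = rng.randint(*spec.flank_length)
        return "".join(rng.choice(BACKGROUND_ALPHABET) for _ in range(n))

    for i in range(spec.n_planted):
        left, right = flank(), flank()
        seq_id = f"planted_{spec.seed}_{i}"
        records.append(ProteinRecord(seq_id=seq_id, residues=left + insert + right))
        truth_rows.append(
            {
                "seq_id": seq_id,
                "insert_start": len(left) + 1,
                "insert_end": len(left) + len(insert),
            }
        )
    for i in range(spec.n_background):
        records.append(
            ProteinRecord(
                seq_id=f"background_{spec.seed}_{i}", residues=flank() + flank() + flank()
            )
        )

    for fam in range(spec.n_isoform_families):
        gene = f"GENE{spec.seed}_{fam}"
        shared = insert
        longer = make_perfect_sah(spec.insert_repeats + 2)
        variants = [shared, shared, longer] + [None] * (spec.transcripts_per_gene - 3)
        for t, domain_seq in enumerate(variants[: spec.transcripts_per_gene]):
            body = flank() + (domain_seq or "") + flank()
            records.append(
                ProteinRecord(
                    seq_id=f"{gene}_T{t}",
                    residues=body,
                    gene_id=gene,
                    transcript_id=f"{gene}_T{t}",
                )
            )
    truth = pd.DataFrame(truth_rows, columns=["seq_id", "insert_start", "insert_end"])
    return records, truth


def make_planted_dataset(spec: FixtureSpec, fasta_path, truth_path=None) -> tuple:
    """Write a planted dataset as FASTA plus a TSV ground-truth table."""
    records, truth = generate_planted_records(spec)
    fasta_path = Path(fasta_path)
    with open(fasta_path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            header = rec.seq_id
            if rec.gene_id:
                header += f" gene:{rec.gene_id} transcript:{rec.transcript_id}"
            fh.write(f">{header}\n{rec.residues}\n")
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return records, truth


def reference_sah_records() -> list:
    """Bundled reference sequences, including the human myosin-10 SAH region."""
    return [
        ProteinRecord(
            seq_id="ENSP00000421280_SAH",
            residues=MYO10_SAH,
            gene_id="MYO10",
            transcript_id="ENSP00000421280",
        )
    ]
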