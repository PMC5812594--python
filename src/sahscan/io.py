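"""FASTA input, the SQLite result store, and report/plot output.

The store keeps sequences, per-residue profiles (for domain-bearing
sequences), detected domains and a config snapshot for one run, so that
domain filtering and all downstream analytics can be repeated with different
cutoffs without re-scoring.  All tabular reports are TSV, UTF-8, with a
header row, 1-based inclusive coordinates, and scores rounded to 4 decimals.
"""
from __future__ import annotations

import json
import re
import sqlite3
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .analysis import composition, domains_by_length, heptad_frequency
from .config import ScoringConfig
from .domains import SahDomain
from .errors import InputError, SahScanError
from .scoring import ProteinRecord, ScoreProfile

_ID_TOKEN = re.compile(r"\b(gene|transcript):(\S+)")


def parse_header_ids(description: str) -> tuple:
    """Extract (gene_id, transcript_id) from an Ensembl-style FASTA header."""
    found = {kind: value for kind, value in _ID_TOKEN.findall(description)}
    return found.get("gene"), found.get("transcript")


def read_fasta(path) -> list:
    """Read a protein multi-FASTA into ProteinRecords.

    Trailing stop symbols ('*') are stripped; gene/transcript ids are parsed
    from ``gene:<ID>`` / ``transcript:<ID>`` header tokens when present.
    Length-based validity (shorter than the smallest scoring window) is
    decided later by the pipeline, not here.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        residues = str(entry.seq).upper().rstrip("*")
        gene_id, transcript_id = parse_header_ids(entry.description)
        if not residues:
            continue
        records.append(
            ProteinRecord(
                seq_id=entry.id,
                residues=residues,
                gene_id=gene_id,
                transcript_id=transcript_id or entry.id,
            )
        )
    if not records:
        raise InputError(f"no sequences found in {path}")
    return records


def split_valid(records: list, min_length: int) -> tuple:
    """Partition records into (valid, invalid) by minimum scoreable length."""
    valid = [r for r in records if r.length >= min_length]
    invalid = [r for r in records if r.length < min_length]
    return valid, invalid


class ResultStore:
    """Single-file SQLite store for the results of one prediction run."""

    def __init__(self, path, run_id: str):
        self.path = Path(path)
        self.run_id = run_id
        self._conn = sqlite3.connect(self.path)
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._create_schema()

    def _create_schema(self):
        self._conn.executescript(
            """
            CREATE TABLE IF NOT EXISTS runs (
                run_id TEXT PRIMARY KEY,
                config_json TEXT NOT NULL
            );
            CREATE TABLE IF NOT EXISTS sequences (
                run_id TEXT NOT NULL,
                seq_id TEXT NOT NULL,
                gene_id TEXT,
                transcript_id TEXT,
                residues TEXT NOT NULL,
                length INTEGER NOT NULL,
                valid INTEGER NOT NULL,
                PRIMARY KEY (run_id, seq_id)
            );
            CREATE TABLE IF NOT EXISTS profiles (
                run_id TEXT NOT NULL,
                seq_id TEXT NOT NULL,
                window_size INTEGER NOT NULL,
                scores_json TEXT NOT NULL,
                PRIMARY KEY (run_id, seq_id, window_size)
            );
            CREATE TABLE IF NOT EXISTS domains (
                run_id TEXT NOT NULL,
                seq_id TEXT NOT NULL,
                window_size INTEGER NOT NULL,
                start INTEGER NOT NULL,
                end INTEGER NOT NULL,
                subsequence TEXT NOT NULL,
                scores_json TEXT NOT NULL,
                domain_score REAL NOT NULL,
                below_cutoff_fraction REAL NOT NULL
            );
            """
        )
        self._conn.commit()

    # -- write ---------------------------------------------------------------

    def has_run(self) -> bool:
        cur = self._conn.execute("SELECT 1 FROM runs WHERE run_id = ?", (self.run_id,))
        return cur.fetchone() is not None

    def delete_run(self):
        for table in ("runs", "sequences", "profiles", "domains"):
            self._conn.execute(f"DELETE FROM {table} WHERE run_id = ?", (self.run_id,))
        self._conn.commit()

    def save_config(self, config: ScoringConfig):
        self._conn.execute(
            "INSERT OR REPLACE INTO runs (run_id, config_json) VALUES (?, ?)",
            (self.run_id, json.dumps(config.snapshot())),
        )
        self._conn.commit()

    def load_config(self) -> ScoringConfig:
        cur = self._conn.execute(
            "SELECT config_json FROM runs WHERE run_id = ?", (self.run_id,)
        )
        row = cur.fetchone()
        if row is None:
            raise SahScanError(f"no stored run {self.run_id!r} in {self.path}")
        return ScoringConfig.from_snapshot(json.loads(row[0]))

    def add_sequences(self, records: list, valid: bool):
        self._conn.executemany(
            "INSERT OR REPLACE INTO sequences VALUES (?, ?, ?, ?, ?, ?, ?)",
            [
                (self.run_id, r.seq_id, r.gene_id, r.transcript_id, r.residues, r.length, int(valid))
                for r in records
            ],
        )
        self._conn.commit()

    def add_profile(self, profile: ScoreProfile):
        self._conn.execute(
            "INSERT OR REPLACE INTO profiles VALUES (?, ?, ?, ?)",
            (
                self.run_id,
                profile.seq_id,
                profile.window_size,
                json.dumps(list(profile.scores)),
            ),
        )
        self._conn.commit()

    def add_domains(self, domains: list):
        self._conn.executemany(
            "INSERT INTO domains VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?)",
            [
                (
                    self.run_id,
                    d.seq_id,
                    d.window_size,
                    d.start,
                    d.end,
                    d.subsequence,
                    json.dumps(list(d.residue_scores)),
                    d.domain_score,
                    d.below_cutoff_fraction,
                )
                for d in domains
            ],
        )
        self._conn.commit()

    def clear_domains(self):
        self._conn.execute("DELETE FROM domains WHERE run_id = ?", (self.run_id,))
        self._conn.commit()

    # -- read ----------------------------------------------------------------

    def sequences(self, valid_only: bool = False) -> list:
        sql = (
            "SELECT seq_id, gene_id, transcript_id, residues FROM sequences "
            "WHERE run_id = ?" + (" AND valid = 1" if valid_only else "") + " ORDER BY rowid"
        )
        return [
            ProteinRecord(seq_id=s, gene_id=g, transcript_id=t, residues=res)
            for s, g, t, res in self._conn.execute(sql, (self.run_id,))
        ]

    def sequence_counts(self) -> tuple:
        cur = self._conn.execute(
            "SELECT COUNT(*), SUM(valid) FROM sequences WHERE run_id = ?", (self.run_id,)
        )
        total, valid = cur.fetchone()
        return int(total or 0), int(valid or 0)

    def profiles(self, window_size=None) -> list:
        sql = "SELECT seq_id, window_size, scores_json FROM profiles WHERE run_id = ?"
        args = [self.run_id]
        if window_size is not None:
            sql += " AND window_size = ?"
            args.append(window_size)
        sql += " ORDER BY seq_id, window_size"
        return [
            ScoreProfile(seq_id=s, window_size=w, scores=np.array(json.loads(js)))
            for s, w, js in self._conn.execute(sql, args)
        ]

    def domains(self, window_size=None) -> list:
        sql = (
            "SELECT seq_id, window_size, start, end, subsequence, scores_json, "
            "domain_score, below_cutoff_fraction FROM domains WHERE run_id = ?"
        )
        args = [self.run_id]
        if window_size is not None:
            sql += " AND window_size = ?"
            args.append(window_size)
        sql += " ORDER BY window_size, seq_id, start"
        return [
            SahDomain(
                seq_id=s,
                window_size=w,
                start=st,
                end=en,
                subsequence=sub,
                residue_scores=np.array(json.loads(js)),
                domain_score=ds,
                below_cutoff_fraction=bf,
            )
            for s, w, st, en, sub, js, ds, bf in self._conn.execute(sql, args)
        ]

    def close(self):
        self._conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


# -- reports ------------------------------------------------------------------


def _write_tsv(path: Path, header: list, rows: list):
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


def _fmt(score: float) -> str:
    return f"{score:.4f}"


def write_reports(store: ResultStore, out_dir, windows=None, top_heptads: int = 10) -> list:
    """Write per-window summary tables for a completed run.

    Creates ``out_dir/<run_id>/`` with, per window size: a composition table,
    a domains-by-length table, a heptad-frequency table, and a detailed domain
    table.  Returns the written paths.
    """
    config = store.load_config()
    run_dir = Path(out_dir) / store.run_id
    run_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for w in windows or config.window_sizes:
        doms = store.domains(window_size=w)

        path = run_dir / f"composition_w{w}.tsv"
        if doms:
            comp = composition(doms)
            rows = [(aa, _fmt(frac)) for aa, frac in comp.fractions.items()]
            rows.append(("charged_polar", _fmt(comp.charged_polar_fraction)))
            rows.append(("heptad_equivalent", _fmt(comp.heptad_equivalent)))
        else:
            rows = []
        _write_tsv(path, ["residue", "fraction"], rows)
        written.append(path)

        path = run_dir / f"domains_by_length_w{w}.tsv"
        frame = domains_by_length(doms)
        _write_tsv(path, ["length", "count"], list(frame.itertuples(index=False)))
        written.append(path)

        path = run_dir / f"heptads_w{w}.tsv"
        heptads = heptad_frequency(doms, top_n=top_heptads) if doms else []
        _write_tsv(path, ["heptad", "count"], [(h.heptad, h.count) for h in heptads])
        written.append(path)

        path = run_dir / f"domains_w{w}.tsv"
        _write_tsv(
            path,
            [
                "seq_id",
                "start",
                "end",
                "length",
                "domain_score",
                "below_cutoff_fraction",
                "subsequence",
                "residue_scores",
            ],
            [
                (
                    d.seq_id,
                    d.start,
                    d.end,
                    d.length,
                    _fmt(d.domain_score),
                    _fmt(d.below_cutoff_fraction),
                    d.subsequence,
                    ",".join(_fmt(s) for s in d.residue_scores),
                )
                for d in doms
            ],
        )
        written.append(path)
    return written


def write_sequence_reports(store: ResultStore, out_dir, windows=None) -> list:
    """Per-sequence text reports, only for sequences with retained domains."""
    config = store.load_config()
    windows = tuple(windows or config.window_sizes)
    run_dir = Path(out_dir) / store.run_id / "sequences"
    by_seq = {}
    for w in windows:
        for d in store.domains(window_size=w):
            by_seq.setdefault(d.seq_id, []).append(d)
    if by_seq:
        run_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for seq_id in sorted(by_seq):
        path = run_dir / f"{_safe_name(seq_id)}.txt"
        lines = [f"# SAH-domain report for {seq_id}", ""]
        for d in sorted(by_seq[seq_id], key=lambda d: (d.window_size, d.start)):
            lines.append(
                f"window {d.window_size}: domain {d.start}-{d.end} "
                f"(length {d.length}, SAH-domain-score {_fmt(d.domain_score)})"
            )
            lines.append(f"  sequence: {d.subsequence}")
            lines.append(
                "  scores:   " + ",".join(_fmt(s) for s in d.residue_scores)
            )
            lines.append("")
        path.write_text("\n".join(lines), encoding="utf-8")
        written.append(path)
    return written


def _safe_name(seq_id: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", seq_id)


def export_profile_plot(profile: ScoreProfile, domains, out_path, svg: bool = False,
                        cutoff: float = 0.25) -> list:
    """Export a score profile as (position, score) TSV and optionally as SVG.

    The TSV stores full-precision scores so a reimport reproduces the profile
    exactly.  The SVG is a simple line plot with detected domain spans shaded.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("position\tscore\n")
        for i, s in enumerate(profile.scores, start=1):
            fh.write(f"{i}\t{float(s)!r}\n")
    written = [out_path]
    if svg:
        svg_path = out_path.with_suffix(".svg")
        svg_path.write_text(_profile_svg(profile, domains, cutoff), encoding="utf-8")
        written.append(svg_path)
    return written


def _profile_svg(profile: ScoreProfile, domains, cutoff: float) -> str:
    width, height, pad = 800, 240, 30
    scores = profile.scores
    n = scores.size
    y_min = min(-0.1, float(scores.min()))
    y_max = max(1.1, float(scores.max()))

    def x(i):
        return pad + (width - 2 * pad) * (i / max(n - 1, 1))

    def y(v):
        return height - pad - (height - 2 * pad) * ((v - y_min) / (y_max - y_min))

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">',
        f'<rect width="{width}" height="{height}" fill="white"/>',
    ]
    for d in domains or []:
        parts.append(
            f'<rect class="domain-span" x="{x(d.start - 1):.1f}" y="{pad}" '
            f'width="{x(d.end - 1) - x(d.start - 1):.1f}" height="{height - 2 * pad}" '
            f'fill="#ffd27f" opacity="0.6"/>'
        )
    parts.append(
        f'<line x1="{pad}" y1="{y(cutoff):.1f}" x2="{width - pad}" y2="{y(cutoff):.1f}" '
        f'stroke="#cc0000" stroke-dasharray="4 3"/>'
    )
    points = " ".join(f"{x(i):.1f},{y(float(s)):.1f}" for i, s in enumerate(scores))
    parts.append(f'<polyline points="{points}" fill="none" stroke="#003366"/>')
    parts.append(
        f'<text x="{pad}" y="{pad - 8}" font-size="12">'
        f"{profile.seq_id} (window {profile.window_size})</text>"
    )
    parts.append("</svg>")
    return "\n".join(parts)
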