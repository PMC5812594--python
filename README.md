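# sahscan

Prediction and analysis of **stable single α-helix (SAH) domains** in protein
sequences.

SAH-domains (also called charged single α-helices, CSAH) are highly charged
ER/K motifs that form monomeric, stable α-helices in polar solution without
any tertiary contacts.  They work as rigid connectors and constant-force
springs, most famously as the lever-arm extensions of myosins.  Because their
stability comes from dense networks of i,i+3 and i,i+4 salt bridges on one
helix face, they can be predicted directly from sequence — which is what this
package does, for single sequences or whole proteome FASTA files.

## The scoring model

Each sequence is treated as one continuous right-handed α-helix and laid out
on a *helical net*: residue 1 is heptad position *a* and positions repeat with
period 7.  For a window of *w* residues (defaults: 14, 21, 28, 49) the raw
window score is

```
S(window) = Σ_i  M3[x_i, x_{i+3}] + M4[x_i, x_{i+4}] + network(i)
```

where `M3`/`M4` are directional 20×20 interaction matrices for the two helix
spacings (so E→R may score more than R→E), and `network(i)` adds a bonus for
alternating oppositely charged triples and a penalty for hydrophobic triples
(potential coiled-coil seams) in i,i+3,i+6 / i,i+3,i+7 / i,i+4,i+7 / i,i+4,i+8
spacing.  Residues of the window's last helical turn keep their outgoing
interactions into the next heptad.  The sum is normalized by the score of a
perfect `(EEEEKKK)n` repeat, so **1.0 = perfect ER/K motif**, and assigned to
the window's central residue (residue 8/15 for windows 14/28); terminal
windows are padded with neutral dummy residues.

An **SAH-domain** is a maximal profile stretch that starts and ends above the
per-residue cutoff (default 0.25), with at most 20% of its residues at or
below the cutoff, and at least one window in length.  Its length-independent
**SAH-domain-score** is the maximum mean score over all 14-residue
sub-windows; domains must reach a per-window minimum (0.35/0.32/0.29/0.25 for
windows 14/21/28/49).

Downstream analytics reproduce the standard dataset-level views: residue
composition and charged/polar heptad occupancy, ranked heptad patterns,
domain-per-sequence counts, protein-length histograms, and the comparison of
unique SAH-domains across alternative transcripts of a gene (presence
fractions, inclusion, and terminal overlap).

## Worked example

The package bundles the 62-residue SAH region of human myosin-10
(ENSP00000421280):

```python
from sahscan import (default_config, reference_sah_records, score_profile,
                     detect_domains, filter_domains, heptad_frequency)

cfg = default_config()
rec = reference_sah_records()[0]
prof = score_profile(rec, 14, cfg)
print(f"min={prof.scores.min():.3f} max={prof.scores.max():.3f}")
dom = filter_domains(detect_domains(prof, cfg, rec), cfg)[0]
print(f"domain {dom.start}-{dom.end}, SAH-domain-score {dom.domain_score:.3f}")
```

prints

```
min=0.271 max=1.129
domain 1-62, SAH-domain-score 1.030
```

i.e. every residue of the region scores above the 0.25 cutoff (the minimum
0.271 sits at the dummy-padded C-terminus), the whole region is reported as a
single SAH-domain, and its best 14-residue stretch is better than a perfect
EEEEKKK repeat (score > 1) thanks to its E→R-rich RERERER core.

From the shell, a whole FASTA file is processed in one call:

```bash
sahscan --id demo --input demo.fasta --out results --top-heptads 5
```

```
[demo] sequences: 9 total, 9 valid, 6 with domains; domains per window: w14=6, w21=6, w28=6, w49=6
```

`results/demo/` then contains a SQLite store (`store.sqlite`) plus, per
window, TSV tables: `domains_w14.tsv` (coordinates, sequence, per-residue
scores, SAH-domain-score per domain), `composition_w14.tsv`,
`domains_by_length_w14.tsv`, and `heptads_w14.tsv`, along with per-sequence
text reports and profile plot data (`--svg` adds SVG line plots).  Scoring
and analysis are separate stages: `--stages analyze --residue-cutoff 0.3`
re-filters the stored profiles under stricter cutoffs without re-scoring.

The default matrices live in `src/sahscan/data/scoring_matrix_i_3.csv` /
`scoring_matrix_i_4.csv` and can be replaced via the YAML config (see
`src/sahscan/data/default_config.yaml`); normalization constants are
recomputed automatically.  See `docs/methods.md` for the model details,
parameter rationale, and known limitations.

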