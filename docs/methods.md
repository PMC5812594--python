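# Methods

## Model

sahscan predicts stable single α-helix (SAH) domains by scoring every residue
of a protein sequence for its local density of helix-stabilizing side-chain
interactions.  The model's assumptions:

* **Continuous helix, fixed register.**  The whole sequence is treated as one
  right-handed α-helix; residue 1 is heptad position *a* and the register is
  global (period 7, never re-derived from coiled-coil predictions).  This is a
  deliberate simplification: it makes the score a pure sequence property and
  lets batches of arbitrary FASTA files be scored without any external
  predictor.
* **Pairwise interactions at i,i+3 and i,i+4.**  These are the two spacings at
  which side chains meet on one helix face.  Interaction scores come from two
  directional 20×20 matrices (row = N-terminal partner), so forward salt
  bridges (E→R, E→K) can outscore their reverses (R→E, K→E), matching peptide
  helicity measurements.  Identically charged pairs and oppositely charged
  i,i+1/i,i+2 pairs are deliberately scored 0: they occur in canonical SAH
  motifs themselves (e.g. within EEEEKKK) and do not discriminate.
* **Triple networks.**  Alternating oppositely charged triples in
  i,i+3,i+6 / i,i+3,i+7 / i,i+4,i+7 / i,i+4,i+8 spacing stabilize beyond the
  sum of their pairs (+0.25 per triple by default); all-hydrophobic triples
  (V,I,L,M,F,Y) at the same spacings mark potential coiled-coil seams and
  score −0.25.  Both values are configurable.
* **Windowing and normalization.**  The raw window score sums the outgoing
  contributions of every window position; positions in the window's final
  helical turn keep their partners in the next heptad.  Each window's sum is
  divided by the score of a `(EEEEKKK)n` window of the same size — computed
  from the active matrices at configuration time — so 1.0 means "as
  stabilizing as a perfect ER/K motif" under *any* matrix choice.  Scores are
  not clamped: sequences can exceed 1 when they beat EEEEKKK (the bundled
  myosin-10 region does, via E→R bridges).  The score is assigned to the
  central residue (windows 21/49) or to window position 8/15 (windows 14/28,
  the position just past the midpoint); windows overhanging a terminus are
  filled with neutral dummy residues, so the first/last ~offset residues have
  systematically reduced scores.  With the default windows (all multiples of
  7) the normalization is independent of the window's heptad phase; for
  non-multiples of 7 it would not be, which is one reason the window sizes
  are fixed by default.

## Domain calls

A candidate SAH-domain is a maximal run of residues strictly above the
residue cutoff (default 0.25), extended by a deterministic left-to-right
greedy merge: the current span absorbs the next above-cutoff run whenever the
union span (gap included) keeps its at-or-below-cutoff fraction within the
tolerance (default 20%).  This implements the "don't split long domains over
single dips" intent with a linear, tie-free procedure; a globally optimal
merge could occasionally join more aggressively, but the greedy rule is the
package's canonical, documented behaviour.  Spans shorter than the detection
window are discarded, so the window size is also the minimum domain length.

The SAH-domain-score is the maximum mean residue score over all contiguous
sub-windows of 14 residues (configurable; capped at the detection window so
every candidate is scorable).  A domain of length L yields L − 14 + 1
evaluated means — all possible sub-windows.  Domains are kept when the score
reaches the per-window minimum: 0.35 (w14) and 0.25 (w49) with linear
interpolation for the unspecified intermediate windows (0.32 for w21, 0.29
for w28).  Residue comparisons are strict (> cutoff); domain-score
comparisons are non-strict (≥ minimum).

## Default matrices

The shipped matrices are tiered rather than fitted: strong (E→R at i+4 = 10),
medium (E→K 8.5, D→R 7, R→E 6.5, K→E 6 at i+4; E→R 7 at i+3), weak
(D-mediated and reverse bridges at i+3, 3–5), polar/helix-propensity support
pairs involving Q/N/S/T/A/L/M with charged partners (0.5–9), small self-pair
support for Q and A, and destabilizing entries for proline in any pair (−1.5)
and G–G (−1).  Two calibration anchors fix the magnitudes:

1. `(EEEEKKK)n` normalizes to exactly 1 for every window (by construction).
2. The canonical 62-residue human myosin-10 SAH region must score above the
   0.25 cutoff at *every* residue under window 14, including the
   dummy-padded termini, and be reported as one single domain.

Anchor 2 is demanding: the C-terminal residue's window retains only ~1/3 of
its interactions (the rest is padding), so the few pairs present there
(K→E, S→E, S→A, Q→A, Q→E, K→L, E→L) must carry nearly salt-bridge-level
weight.  That is why the Q→charged and Q→A support entries are as large as
medium salt bridges; they should be read as calibration devices for terminal
sensitivity, not as measured interaction energies.  The flank-crossing
entries (S/T/A/L→charged) are kept small in the opposite direction so that
domain boundaries stay sharp.  Replacing the matrices is fully supported;
normalization constants are recomputed and the architecture is
matrix-agnostic.

## Boundary resolution

At cutoff 0.25, a window-w profile intrinsically smears a sharp domain edge
by roughly w/4 residues on the N-terminal side: a flank residue whose window
covers ≥ w/4 of a perfect insert scores above the cutoff no matter what the
flank is.  With window 14 this keeps detected boundaries within ~4 residues
of a planted insert; with windows 21 and 28 the overshoot is ~5–8 residues
and cannot be reduced without inverting the forward/reverse salt-bridge
ordering (the E-heptad phases would have to carry less than a quarter of the
EEEEKKK mass).  The C-terminal side is sharper because the last insert
residues lose their outgoing interactions into the flank.  Consequence for
users: report boundaries from the 14-residue window (the default for all
analytics); the larger windows are sensitivity/length filters, not boundary
estimators.

## Synthetic data

The fixture generator plants `(EEEEKKK)5` inserts (35 aa) inside random
flanks drawn uniformly from the low-charge alphabet {G,S,T,A,P,V,L} (flank
lengths 30–50), plus pure-background sequences and optional isoform families
(4 transcripts per gene: two sharing a domain, one carrying a longer
superset, one without) to exercise the transcript-level comparisons.  All
generation is seeded and byte-reproducible.  What this emulates: sharp,
high-contrast SAH domains in neutral context.  What it does not: real
proteome composition (charged/polar background, borderline "twilight-zone"
domains, compositional drift between species), domains interrupted by
structured regions, or genomic-coordinate-level isoform structure.  Passing
the planted-recovery tests therefore demonstrates correctness of the
segmentation machinery, not field performance on real proteomes.

## Numerical choices

* Profiles are computed from a per-position contribution array via cumulative
  sums (O(L) per window); the test suite pins them elementwise (1e-9) to a
  naive double-loop enumerator.
* Normalization uses a repeat long enough that every pair and triple of the
  first window exists (n = (w+8)//7 + 2 repeats).
* Dummy handling: trailing `*` is stripped on input; internal `*`, X, U, B,
  Z, O are neutral (every pair/triple containing them scores 0).  Sequences
  shorter than the smallest configured window are flagged invalid, counted,
  and excluded from scoring.
* Presence-fraction histogram bins are half-open (lo, hi] with the top bin
  closed at 1; bin indices are computed with a 1e-9 guard against float edge
  effects.
* Ties in heptad ranking break lexicographically; all outputs are
  deterministic for identical inputs and configuration.

## Result store and stages

Prediction (parse → score → detect → persist) and analysis (filter →
tables/reports) are separate stages over a single-file SQLite store per run
id.  The store keeps the full config snapshot and per-residue profiles for
domain-bearing sequences only; re-analysis with *stricter* cutoffs therefore
never re-scores, while a more permissive cutoff than the predict-time one
requires a fresh predict run (profiles of sequences without any retained
domain are not kept, a space/utility trade-off).  Reports are plain TSV with
4-decimal scores and 1-based inclusive coordinates; profile exports keep full
float precision so they roundtrip exactly.  SVG plots are generated natively
(no external plotting dependency).

## Problem sizes in the shipped checks

The bundled test-suite and acceptance checks run on synthetic datasets of
~8–10 sequences of 95–170 residues per replicate (50 replicates for the
recovery checks, 200 random sequences for the oracle-equivalence check) —
sizes chosen so the whole suite completes in seconds while every code path,
including the batch CLI, is exercised end to end.

## Known limitations

* The heptad register is fixed at residue 1 = *a*; an SAH preceded by a
  frame-shifting insertion relative to a true helix start is still scored,
  but its (register-free) pair scores are what matter, so this only affects
  the reported heptad letters, not scores.
* Default matrix magnitudes are curated/calibrated, not fitted to helicity
  data; absolute scores between 0.25 and ~0.4 are a twilight zone that
  warrants experimental confirmation.
* Boundary resolution beyond window 14 is intrinsically coarse (see above).
* Overlap between isoform domains is detected on protein sequence (terminal
  suffix/prefix matches ≥ 5 aa), not on genomic coordinates.
* GO-term or other functional enrichment of SAH-carrying genes is out of
  scope; the unique-domain gene lists that such analyses consume are exported.
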