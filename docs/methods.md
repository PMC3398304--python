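# Methods

This note documents the models, conventions and numerical choices behind
`mirdev`, and what the synthetic study conditions do and do not establish
about real data.

## Data model and conventions

All sequences are stored in the DNA alphabet (`U` → `T` on input; tables
report added bases back in RNA letters). Coordinates are 0-based
half-open. Stage labels are free strings; the eight-stage teleost series
(BL, EP, SS, HA, FF, EM, CM, JU) is a default, not a constraint. A
mature miRNA's *seed* is positions 2–8 (1-based) from the 5' end; two
references with identical seeds share a family label.

Offsets follow an added/missing convention relative to the canonical
mature: positive = extra bases beyond the canonical end, negative =
canonical bases missing. An isomiR is identified by
(miRNA, 5' offset, 3' offset, tail sequence), so "+1A" and "+1U" are
distinct variants; tail bases are labelled templated/untemplated per base
against the precursor flank, and a tail is summarized as untemplated when
at least one base is.

## Read annotation

Historical color-space mapping parameters are reinterpreted in nucleotide
space: "2 color mismatches" becomes ≤ 2 substitutions, and the 25/20
color seed lengths become minimum nucleotide overlaps for the contaminant
screen and the mature-miRNA assignment respectively. Alignment is
ungapped (collapsed small-RNA reads are short; indels are not modelled);
`N` counts as a mismatch. The best placement minimizes
(mismatches, |5' offset|, |3' offset|), sense preferred over antisense on
ties, then lexicographic reference name — a deterministic total order. A
read that maps within a seed family is counted once, toward the
best-scoring member only. Added bases are bounded by the alignment window
(3 at the 5' end, 6 at the 3' end, both configurable); missing bases are
bounded by the legitimacy filters (≥ −5 at 3', ≥ −1 at 5', boundary
inclusive). The ≥ 5-copies rule is applied at the whole-miRNA level
(summed over isomiRs, after the per-read rules), per stage.

The vectorized kernels (reads grouped by length, one comparison per
reference × orientation × shift) implement exactly the brute-force
per-read scan; the test suite asserts equality against an independent
exhaustive oracle.

## Synthetic study conditions

The generator emulates a staged developmental study with known truth:

- **Temporal classes.** Four trajectory shapes over the eight stages —
  early (peaks BL/EP, ~100-fold decay by FF, maternal-clearance-like),
  embryonic (SS/HA), feeding (FF) and metamorphosis (EM/CM). Within a
  stage, expected counts split across loci by class shape times a
  lognormal(0, 0.5) abundance factor, scaled to the stage's depth.
  Depth may vary per stage (in the emulated study design the
  miRNA-mapped fraction rises steeply across development).
- **isomiR model.** Planted offset distribution (default: canonical 0.55,
  3' additions +1/+2 at 0.16/0.06, 3' truncations −1/−2/−3 at
  0.10/0.05/0.03, 5' ±1 at 0.03/0.02); added bases are untemplated with
  probability 0.3, drawn A:U = 60:40 (the bias reported for this class of
  data), otherwise templated from the precursor flank.
- **Identifiability choice.** Generated precursors place G/C at the
  positions flanking each arm, so A/U untemplated additions can never
  coincide with a templated base. This makes template labels exactly
  recoverable; real loci with A/T flanks are intrinsically ambiguous for
  single-base tails, and the pipeline would label such additions
  templated (the conservative call).
- **Counts.** Poisson around expectations (single library per stage in
  the emulated design — no replicate information to estimate
  overdispersion). Sequencing error is substitution-only at 0.5% per
  base; an error-carrying read receives one guaranteed substitution plus
  Binomial(L−1, rate) extras.
- **Strand structure.** Each locus has a star arm (reverse complement of
  the guide with two substitutions) at a planted star fraction (8%
  default, 75% for designated high-star loci). One designated locus
  carries antisense transcription with a strictly decreasing
  antisense:sense ratio (200 → 0.05) crossing 1.0 at first feeding,
  mirroring the reciprocal strand switch described for miR-204-like loci.
  The antisense pair sits on an embryonic-class locus so both strands
  stay measurable at every stage. The published ratio table this emulates
  rises slightly again after first feeding; the planted sequence is kept
  strictly decreasing because the recovery criterion tests estimator
  fidelity on a monotone truth, not the biological tail uptick.
- **Contaminants.** tRNA/rRNA/mt-like random references; contaminant
  reads are exact substrings (18–36 nt) plus a 10–11 nt degradation
  class. Default contaminant fraction 5%.

Default scale: 20 loci, 125,000 miRNA-locus reads per stage (~1M reads,
~50,000 per locus over the study), chosen to match the recovery analyses;
the README example uses a smaller instance for speed.

**What passing tests show.** Recovery results on these conditions
demonstrate correctness of the bookkeeping and estimators under the
stated model — they do not establish robustness to adapter read-through,
quality artifacts, gapped variation, cross-mapping among paralogs with
near-identical sequences, or overdispersed biological replication, none
of which the generator emulates.

## Expression profiling

Normalization is per-stage relative frequency (each column sums to 1),
with counts-per-million scaling for reporting. The heatmap transform is
`log2((f + p) / (f_ref + p))` against the hatching stage; the pseudocount
defaults to one read equivalent per stage (1/stage depth), so zero counts
map to finite values and the reference column is exactly zero. Clustering
is agglomerative with Euclidean distance and average linkage (UPGMA) via
`scipy.cluster.hierarchy`; flat clusters come from cutting at k (default
4, the number of described temporal patterns); distance ties resolve
deterministically by scipy's index-order convention, and dendrograms are
serialized to Newick. Strand ratios are taken on normalized frequencies
(depth-invariant); 0-denominator ratios report +inf, 0/0 reports NaN.

## Discovery

Window gates: length 62–132 nt, GC% in [30, 70] (inclusive), folding
energy strictly below −25 kcal/mol, a single terminal loop, no ambiguous
base, no homopolymer run ≥ 8, no tandem repeat spanning ≥ 12 nt.
Overlapping accepted windows of one source collapse to the lowest-energy
window. The folding backend is pluggable: ViennaRNA's MFE fold is the
default (energies on the kcal/mol scale, so the −25 gate applies as
stated); a weighted base-pair-maximization DP (GC/AU/GU = −3/−2/−1,
stacking bonus −0.5, minimum loop 3) is the fallback, and since its score
is not calibrated to kcal/mol the energy gate is configurable. The "big
loop" is the maximal unpaired interval enclosed by an innermost stem
pair; multibranch folds (≥ 2 terminal loops) are rejected outright.

Redundancy collapse replaces a database-dependent E-value with the two
explicit rules stated alongside it: best ungapped overlap with ≤ 1
mismatch per 14 aligned nt covering > 80% of the candidate. Read support
requires > 50 reads (strict) starting within ±1 of a common position
whose supported interval stays outside the loop. Homolog variant calls
allow ≤ 2 mismatches, all inside the seed (the stricter reading of the
search rule); antisense calls allow ≤ 1 mismatch after trimming up to 4
extension bases, and every call needs > 1,000 reads (strict).

## qPCR

Pfaffl quantification with per-assay efficiency E supplied via
configuration (default 2.0; the emulated study does not print its
efficiencies). Technical replicates average on the Cq scale before the
exponential transform. The calibrator sample defaults to hatching, for
consistency with the sequencing reference stage. Cq = 40 is the detection
cut-off; censored wells propagate as flagged NaN and are excluded from
correlations. Platform correlation is Pearson's r on linear normalized
values (a log-scale option exists; the choice is not dictated by the
emulated protocol). ANOVA/post-hoc testing of stage differences is out of
scope: the module stops at normalized quantities and correlations.

## Acceptance checks and problem sizes

The acceptance suite runs the default conditions on ten fixed seeds
(~10M simulated reads in total, about 70 s): filter equivalence against a
literal brute-force oracle (1,000 random assignments), per-miRNA isomiR
fraction recovery within 3 binomial SE of the realized planted truth plus
pooled convergence to the model probabilities, tail A:U = 60:40 recovery
and 100% template-label agreement, ARI ≥ 0.9 clustering of 20 loci in 4
classes with a brute-force UPGMA cross-check on ≤ 8-row instances, strict
antisense-ratio decrease with the planted crossing stage, perfect
partition of a 50-hairpin constructed gate fixture with strict 50/51 and
1,000/1,001 boundaries, Pfaffl equivalence with 2^(−ΔΔCq) to 1e−12, and
exact conservation invariants. The per-miRNA recovery check is made
against the *realized* per-read truth rather than the model
probabilities: with ~160 simultaneous 3-SE comparisons per replicate, a
perfect estimator would still exceed 3 SE somewhere by multinomial
sampling alone, so the realized-truth comparison is the one that isolates
pipeline fidelity (measured max |z| ≤ 0.4); convergence to the model is
asserted on the pooled estimate, where the comparison count is small.

## Known limitations

- Ungapped alignment only; indel isomiRs and A-to-I editing are invisible.
- No genome: discovery is homology/EST-based, as in the emulated design.
- The simplified fold is a screening score, not a thermodynamic model.
- Multi-mapping resolution is winner-takes-all; fractional assignment for
  near-identical paralogs is not implemented.
- The generator's contaminants are random sequences; real tRNA/rRNA share
  structure with miRNAs and could collide with mature references at rates
  the synthetic conditions do not probe.
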