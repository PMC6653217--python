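# Methods

This note documents the models, parameter choices and numerical conventions
behind `cistro`, what the synthetic-data generator does and does not
emulate, and the design decisions made where the published procedure left
the choice open.

## Coordinates and formats

All intervals are 0-based, half-open (BED); on the minus strand the TSS is
the last covered base (`end - 1`).  Peaks are read from BED5+/broadPeak
with a configurable tag-count column (column 5 by default, column 7 for
broadPeak signal), because the provenance of per-peak tag counts (pileup vs
read overlap) differs between peak callers.  Expression fold change for
zero-abundance genes uses a pseudocount of 1 FPKM on both sides.  DEG
down-regulation is symmetric on the ratio scale (fc ≤ 1/1.5), since up- and
down-regulated calls are reported separately but no asymmetric convention
is standard.

## Promoter states

Promoters are TSS ± 2 kb.  The per-mark enrichment thresholds behind the
published four-state calls are not recoverable, so enrichment here is
peak-overlap based with two explicit knobs: minimum overlap (default 1 bp)
and minimum normalized tag density over the window (default 0, i.e. peak
presence is the criterion).  "Dominantly modified" is operationalized as:
Active ⇔ (H3K4me3 ∨ H3K27ac) ∧ ¬H3K27me3; Poised ⇔ active mark ∧ H3K27me3;
Repressive ⇔ H3K27me3 alone; None otherwise.  H3K4me1/H3K9me3 do not enter
the call.  Overlapping promoter windows share peaks — no peak is consumed.

## Differential enhancers

Distal enhancers are H3K27ac peaks whose nearest edge is ≥ 2 kb from every
TSS (edge-to-TSS for the distal filter; midpoint-to-TSS for nearest-gene
assignment — each is a separate, logged convention because the published
rule does not say which anchor it measures).  Per-cell distal peaks are
merged (single linkage on ≥ 1 bp overlap) into union regions, per-cell tag
counts are scaled to a common 10 M library, and significance is a Poisson
tail with a +1 pseudocount: p = P(Pois(s_min + 1) ≥ s_max).  This is the
documented model family of the differential-peak tool the original
analysis wrapped; only the 4-fold and p < 10⁻⁴ cutoffs were stated.  The
test is antisymmetric by construction (swapping cells maps gained ↔ lost
with identical p).

## Super-enhancers

H3K27ac peaks fully inside TSS ± 2 kb are removed (the reference
rank-ordering implementation's practice; the flag is explicit because the
original account is silent), survivors are stitched at gaps ≤ 12.5 kb, and
regions are ranked by increasing summed tag count.  Both rank and signal
are min–max rescaled to [0, 1] and the cutoff is the (unscaled) signal at
the left endpoint of the first one-rank secant with slope > 1 — a discrete,
smoothing-free version of the "tangent of slope 1" rule that is exactly
checkable against a brute-force slope scan.  Degenerate inputs are defined:
all-equal signals or a perfectly linear curve yield an infinite cutoff (no
super-enhancers); fewer than three regions cannot define a cutoff.  Input
(control) subtraction is supported but off by default, as inputs were used
for peak calling rather than SE signal in the source procedure.  On any
signal distribution with a smooth bulk, this rule admits the strongest
single enhancers along with clustered loci — that is inherent to
rank-ordering cutoffs, and recovery of planted loci is therefore measured
per truth region.

## Motif scanning, enrichment and networks

Scanning uses log₂-odds against a background base composition (uniform by
default, estimable from the scanned sequences); an offset is a hit when its
score reaches 0.8 × the PWM's maximum achievable score, on either strand,
with N-containing windows skipped.  A fraction-of-max threshold was chosen
over a per-PWM p-value because it is deterministic and directly checkable
by exhaustive word enumeration; it is configurable.  Motif enrichment is an
upper-tail hypergeometric test on element hit counts — targets are one
cell's specific elements, background all other profiled elements (the
published analysis names only the scanning tool and its 10⁻¹⁰ display
threshold; a GC-matched-random background is the main untested
alternative).  "Cell-specific" promoters are Active in exactly one cell;
enhancer elements become cell-specific through a gained/lost call.  Edges
from promoter hits are proximal, from enhancer hits distal, collapsed to
"both"; only differentially expressed TFs enter the network by default.
Cooperation is the Jaccard index of target-gene sets; hub factors need
JI > 0.3 with more than 10 partners (both inequalities strict).

## Cohort validation

The patient expression panel is log₂(x+1)-transformed and factorized with
hand-written multiplicative-update NMF (Frobenius objective) — written
in-package because the per-iteration objective is asserted non-increasing
on every run, which off-the-shelf implementations do not expose.  Factor
scales are arbitrary, so basis columns are L2-normalized before the
per-patient argmax that defines cluster membership; the best of 30 seeded
restarts (by final objective) is kept and a rank-selection study is out of
scope (k = 2 throughout).  Cluster–metastasis association uses Pearson
chi-square without continuity correction (the original software default is
unknown; Yates correction is available by flag).  Survival groups split at
the arithmetic mean ("greater than average" is high; ties go low; a median
split is available by flag).  Kaplan–Meier estimation and the unweighted
log-rank test are computed via `lifelines` behind the module surface, with
hand-derived product-limit and log-rank worked examples frozen in the
tests.

## Functional summaries

Gene-set enrichment is a plain upper-tail hypergeometric test per set with
Benjamini–Hochberg correction across sets (kept at FDR ≤ 0.05), against a
universe defaulting to all annotated genes — a generic stand-in for
ontology-backed web tools, applied to whatever GMT collections are
supplied.  Hallmark percentages use the hallmark set size as denominator;
"changed promoter" means any off-diagonal state transition and "changed
enhancer" means at least one assigned gained/lost enhancer.

## The synthetic study

The generator emits a single ~20 Mb toy chromosome with 500 genes (TSS on a
40 kb grid with ± 5 kb jitter, never closer than 20 kb, so promoter windows
cannot collide).  Per gene, a (state A, state B) pair is drawn from a
distribution that is mostly stable but activation-biased in the metastatic
cell; promoter peaks realize the states with Poisson tag counts at
intensity 100 tags per 10 M depth.  Distal enhancers (1 kb, 5–15 kb from
the TSS) receive a log-normal base intensity (median 500, σ = 0.5 in log
space) — continuous variation matters, because the rank-curve cutoff is
only meaningful on a smooth signal distribution — and are gained, lost
(8-fold between cells) or stable.  Five percent of loci instead carry three
clustered 2 500-intensity constituents within the stitching distance, split
60/25/15 between gained, stable and lost super-enhancers so both cells own
strong loci.  Expression obeys
log₂FC = transition effect + enhancer effect ± noise (σ = 0.5), with
Repressive→Active at +3.2 and None→Repressive at −3.4 matching the observed
extremes, ±1 per gained/lost enhancer and ±2 per gained/lost
super-enhancer.  Motifs are planted as exact consensus words of
high-information synthetic PWMs (consensus probability 0.85, width 8 —
at the 0.8 scan threshold only the exact word hits, so recovery is
deterministic), into metastatic-specific elements, with designated TF pairs
co-occurring at probability 0.3.  The cohort has 404 patients in two latent
groups; 30 up- and 30 down-markers shift by ±2 log₂ units in group 2, whose
metastasis rate is 0.30 vs 0.08 and whose exponential hazard (baseline
median 60 months) is multiplied by 3; censoring is independent uniform at
rate 0.2.  All patients are ER-negative — the cohort emulates the receptor
subset in which the cluster–metastasis association is expected to hold.

What the generator does **not** emulate: mappability and GC structure, peak
shape and width variation, overdispersed counts (a Poisson model matches
the differential test's assumptions; an overdispersion knob exists for
robustness work), correlated marks beyond the state rules, enhancer–gene
assignments other than nearest-TSS, and PWM-sampled (inexact) motif
instances.  Passing tests therefore demonstrate that the implementations
recover what they assume, at realistic desk-scale sizes — not that the
biological conclusions transfer to real data, whose headline counts depend
on genome-scale inputs and upstream alignment/peak calling that are out of
scope here.

## Determinism and problem sizes

Every stochastic component flows from a single seed (the generator through
fixed sub-streams, NMF restarts through seeded initializations, tag
scattering for profiles through a seeded spread of each peak's count over
its interval), and `run_all` reruns are byte-identical, which the manifest
checksums make observable.  Default analysis sizes — 500 genes, ~360
enhancer-union regions, 12 TFs over ~1 100 scanned elements, 404 patients —
were chosen so that every planted structure is recoverable with comfortable
statistical margins while a full simulate-plus-pipeline pass stays in the
tens of seconds; power-style checks (log-rank power and null calibration,
NMF recovery across seeds, null hub rates) use dedicated smaller cohorts
sized for the property being measured.
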