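# Methods

This note documents the models, statistics and design choices in `adrnmes`:
what each stage computes, which parameters matter, what the synthetic data
does and does not emulate, and the numerical conventions that make results
reproducible.

## Signature derivation and scoring

**Derivation.** Input is a panel of isogenic MES/ADRN cell-line pairs on a
linear intensity scale (MAS5-like) with Present/Absent detection calls. For
each gene and pair, the pair is *passed* when three criteria hold
simultaneously: (1) fold change ≥ `per_pair_fold_change` (default 2) with the
smaller intensity floored at `ratio_floor` (default 1 linear unit); (2)
absolute linear difference ≥ `min_linear_diff` (default 100); (3) at least
`min_present_calls` (default 1) Present calls among the two pair members. A
gene enters the MES signature when it passes ≥ `min_pairs` (default 3) pairs,
all with MES > ADRN; the ADRN signature is symmetric; a gene whose passing
pairs disagree in direction is excluded outright.

Two interpretive choices were genuinely open and are exposed as parameters.
First, with one sample per condition per pair there is no replicate structure
for a significance test, so "significantly different per pair" is
operationalized as the fold-change proxy. Second, the difference threshold of
100 is meaningful only on the linear intensity scale (on log2 data it would
exclude everything), so all derivation arithmetic stays linear. "Merged"
across pairs means the union of survivors, not an intersection.

**Rank-percentile score.** Within each sample the full probeset list is
ranked ascending with average ranks on ties; the percentile of gene *g* is
rank(*g*)/*N* with *N* the number of probesets, and the score is the mean
percentile over the signature genes, hence in [1/N, 1]. The denominator is
the *full* list, making scores comparable across samples, and the tie policy
is explicit because reproducibility demands it. Because only ranks enter,
the score is bit-identical under any strictly increasing per-sample
transform — a property the test suite asserts literally. The per-sample mean
is computed as a contiguous 1-D reduction so that any straightforward mean
over the same percentile vector reproduces it to the last bit.

**Summed z-score.** For time-course figures a second readout sums per-gene
z-scores (sample sd, ddof = 1) over a gene set; genes with zero variance are
rejected by name rather than silently dropped.

## Super-enhancer landscape

Coverage is fixed-width binned H3K27ac signal (default 50 bp bins),
normalized to reads per 20 million mapped reads. Peaks are maximal runs of
bins at or above a threshold, discarding runs shorter than `min_width`
(pipeline default 200 bp); the pipeline's default threshold is 2× the mean
normalized bin value, a scale-free choice that sits between the background
and typical-enhancer levels of any reasonably sequenced library. Peaks
within `stitch_distance` (default 12,500 bp, the classic SE convention;
TSS exclusion is off) merge transitively into enhancer regions.

**Elbow cutoff.** Regions are ranked ascending by summed normalized signal;
both axes are min–max rescaled to [0, 1]. Scanning the discrete slope of the
signal-vs-rank curve from the top down, the cutoff sits at the first rank
where the slope is no longer above 1; regions whose signal *strictly*
exceeds the cutoff signal are super-enhancers. Strict inequality resolves
plateaus and ties toward fewer SEs; a perfectly linear curve (slope 1
everywhere) and a perfectly flat curve therefore both yield zero SEs, the
latter with a warning.

**Differential surface.** For a region spanning bins *i*, the directional
surface is `bin_width × Σ_i (B_i − A_i)` on normalized tracks — a signed
area with units of (normalized reads × bp). Direction is increased /
decreased / unchanged against a threshold ε (default 0, so sign alone
decides). Swapping the tracks negates every surface exactly. Because
Poisson counting noise gives every region a nonzero surface, the pipeline
additionally applies a Poisson error-bar filter before selecting induced
regions: the variance of a region's surface is
`bin_width² (f_A² Σ rawA + f_B² Σ rawB)` with *f* the per-track
normalization factors, and surfaces within *z* = 3 sd of zero are demoted to
"unchanged". Induced regions are then the top-*n* by surface (leftmost-first
on ties), and the motif background defaults to the remaining stitched
regions of the induced state.

This signed-area statistic replaces the external two-state segmentation tool
used upstream in the original workflow; it matches the "size × difference"
semantics of that tool's directional-surface sort while being fully
specified and testable.

## Motif scanning and enrichment

JASPAR count matrices are parsed with Biopython; a pseudocount (default 0.8,
split over the uniform background) converts counts to log2-odds against
0.25-per-base. Every position of both strands is scored (the reverse strand
via the reverse-complement matrix at the same coordinates, so hit sets
mirror exactly under reverse complementation); a window is a hit when its
score reaches `score_fraction` (default 0.8) of the maximum achievable
score. A relative threshold is scale-free: it needs no null model and is
comparable across motifs of different lengths. N-containing windows are
skipped.

Enrichment: a region counts as hit when ≥ 1 occurrence overlaps it; the 2×2
table (foreground hit/miss vs background hit/miss) goes through a one-sided
Fisher's exact test (enrichment direction only, matching the directional
claim the analysis makes) and Bonferroni correction over the motifs tested;
`enriched` means corrected p < 0.05. Foreground and background must be
disjoint. The bundled demo motif file contains three synthetic matrices of
equal length and information content — an RBPJ-style 8-mer (consensus
CGTGGGAA, the motif the generator plants), an unplanted HES-style 8-mer, and
a column-shuffled RBPJ control. Equal lengths matter: a short, permissive
motif accumulates random hits at a rate proportional to region length, and
since induced regions are wider than typical enhancers this length effect
could masquerade as enrichment.

## Cascade dynamics

**Endogenous vs transgene.** The NOTCH3-IC transgene lacks the 3′UTR, so a
3′UTR probeset reports only the endogenous receptor while the CDS probeset
also sees the transgene; their difference is the transgene-attributable
component. The generator emits explicit probeset → (gene, region)
annotations, and NOTCH1/2/3 each carry both probeset types.

**Regulation calls.** Per CRC TF, log2 of induced mean over control mean at
the comparison time point, with both means floored at 1 linear unit so
Absent-level intensities cannot explode the ratio; |log2FC| ≥ 1 calls
induced or repressed, and counts are reported as "k of n" per CRC set.

**Onset times.** For one trajectory (one sample per time point, ≥ 3 points)
each gene's series is standardized as z(t) = (x(t) − x(t₀)) / sd(x), i.e.
deviation from the baseline time point in units of the within-gene sd of the
series. The onset is the earliest time with |z| ≥ `z_threshold` (default
1.5) whose sign persists at every later time point; the persistence
requirement prevents single-point noise calls, and raising the threshold can
only delay an onset. A deviation-from-baseline z was chosen over a
mean-centered z deliberately: for a step-like trajectory observed on a
sparse grid, a mean-centered z can never exceed ~1.1 on the majority side of
the step, so it cannot detect late onsets at any sensible threshold, whereas
the baseline-referenced form detects exactly the first persistent departure.

**Scenario verdicts.** From MES/ADRN score trajectories: *transitioned* when
the final time point has mes − adrn > margin (default 0); otherwise
*blocked* when the gamma-secretase inhibitor was active, else *reverted*.
"Reverted" also labels scenarios whose induction was too short to produce
any transition at all — the taxonomy has no separate "never started" state,
and for commitment-boundary sweeps this keeps the verdict sequence a single
reverted → transitioned switch.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed once and
the tests run against them.

**Expression panel.** 5000 probesets, four isogenic pairs (one MES + one
ADRN sample each) plus eight unpaired lines, 300 planted MES and 250 planted
ADRN genes. Per-gene baselines are lognormal (ln-mean ln 150, ln-sd 0.5 —
right-skewed linear intensities with a realistic dynamic range); each
planted gene's high state exceeds its low state by exactly `effect_linear`
(500 linear units, five times the derivation difference threshold). Noise is
a unit-mean multiplicative lognormal with CV 0.2 per cell — multiplicative
because linear-scale array intensities scatter proportionally — and
detection calls threshold the noisy value at 30. With CV = 0 every value
equals its configured mean exactly, enabling closed-form tests. The time
course reuses the same probeset universe, baselines and planted membership
(both designs model one array platform), so panel-derived signatures score
time-course samples directly.

**Induction time course.** Per-gene trajectories interpolate logistically
between endpoints with a normalized logistic (exactly 0 at effective time
0). ADRN-down genes are centered at `adrn_switch_day` = 0.5 d and MES-up
genes at `mes_switch_day` = 6 d with steepness 4 /d: repression is largely
complete by day 1 and MES induction happens around a week, reproducing the
observed onset ordering on the sparse default harvest grid (0/1/7/14/21 d).
The cascade is modelled as an effective-time clock: it advances 1:1 while
the transgene is on without inhibitor, decays 1:1 toward zero otherwise
(relaxation after an uncommitted washout), and after cumulative induction
reaches `commitment_days` (default 5 d) it advances unconditionally — a hard
threshold standing in for bistability, since the underlying experiments
show a threshold phenomenon but define no dynamical equations. MES genes,
the CRC TFs and the six endogenous cascade genes (JAG1, NOTCH1/2/3, MAML2,
HES1; fixed baselines of 250–350 units) are driven by this clock; under
gamma-secretase inhibition the clock never advances, but a `direct_adrn_fraction`
(default 0.15) of ADRN genes responds directly to the transgene — the
already-cleaved NOTCH3-IC needs no gamma-secretase — so the inhibitor
suppresses all MES and cascade movement and *most* ADRN movement. Of the 20
MES CRC TFs only 8 are cascade-responsive by default (partial MES CRC
induction), while all 18 ADRN TFs respond. The transgene contributes
`transgene_level` (2000 units) to the NOTCH3 CDS probeset only, while
doxycycline is on.

**ChIP landscape.** A toy 3.5 Mb chromosome carries 216 regions on a 16 kb
pitch (wider than the 12.5 kb stitch, so planted regions never merge): 200
typical enhancers (1 kb, level 8 in both states), 8 MES-SEs and 8 ADRN-SEs
(3 kb, graded active-state levels 25–53 so ranked SE signals are well
separated on the elbow curve, inactive-state level 3), background level 1.
Bin counts are Poisson(level × library factor); totals are the realized
library sizes, so reads-per-20-million normalization cancels depth
differences exactly in expectation. The sequence is uniform random with
forward-strand insertions of the RBPJ consensus at 3.3 × 10⁻⁴ /bp genome-wide
and 5× that inside MES-SEs; chance occurrences of the consensus are scrubbed
(one-base mutation) before planting, so the recorded truth enumerates all
forward occurrences exactly. Each planted SE overlaps one gene; a few
intergenic genes exercise nearest-TSS assignment.

**What the generator does not emulate.** Probe-level effects and
normalization artifacts of real arrays; correlated noise between genes;
chromatin input bias, fragment-length effects and mappability of real
ChIP-seq; motif occurrences of related-but-different TFs; partial or
heterogeneous (per-cell) state transitions. Passing tests therefore show
that the statistics recover *planted* structure under idealized noise, not
that they would perform identically on deposited datasets — the published
gene counts (485/369 signature genes, 1662 lineage SEs, 16/18 and 8/20 TF
counts) depend on the original data and an unstated per-pair test and are
not reproduction targets here, although the acceptance script's regulation
counts land in the same regime by construction.

## Reproducibility and numerics

One seed drives everything: each stage derives its substream by salting the
seed with a CRC32 of the stage name, so any stage reproduces in isolation
exactly what it saw in a full run, and two runs with the same config + seed
produce byte-identical outputs (the manifest records a sha256 per artifact;
wall-clock times are recorded but excluded from comparisons). Intervals are
0-based half-open everywhere, bedGraph bins must sit on a contiguous
fixed-width grid (validated on read), floats are written with a fixed
`%.10g` format, and region/gene ties break deterministically (leftmost
start, lexicographically smaller id). Degenerate inputs have defined
behaviour: zero planted enhancers propagate to an empty SE set and a
gracefully skipped motif stage; an all-identical signal curve calls no SEs
with a warning; empty gene sets, missing probesets, overlapping
foreground/background and malformed pairings raise typed errors naming the
offender.

Problem sizes throughout (5000-gene panels, a 3.5 Mb single-chromosome
landscape, 6–9-scenario time courses) are the package's default study
conditions: large enough that rank statistics, elbow geometry and Fisher
tests operate in their intended regime, small enough that the full test
suite and the acceptance script each run in well under a minute.

## Known limitations

* The per-pair significance criterion is a fold-change proxy; with
  replicated designs a real test would replace it.
* The elbow cutoff inspects adjacent-rank slopes only; pathological signal
  distributions whose slopes hover near 1 on both sides of the knee can
  shift the cutoff by a rank or two (graded planted SE levels keep the
  default landscape far from this regime).
* The commitment clock is deterministic and population-level; it cannot
  represent mixed populations partially committing.
* Motif enrichment uses binary region hits; a count- or score-based
  statistic would be more powerful for small foreground sets.
* `run_all` always recomputes every stage; since stages are deterministic
  under the salted seeds, a re-run is digest-identical, and no
  resume-from-manifest machinery is provided.
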