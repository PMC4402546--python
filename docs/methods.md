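# Methods

## Scope and model

`orgedit` analyses C-to-U RNA editing in plant organelle transcripts from
strand- and transcript-specific amplicon sequencing. The pipeline starts from
alignments (or pre-computed per-site base counts); read processing and
alignment are upstream concerns. Three stages carry the statistics:

1. **Pileup.** Candidate sites are all cytidines on the sense strand of
   annotated transcripts — genomic Cs on `+` transcripts and genomic Gs on
   `-` transcripts. Counting is done in sense orientation, so at a `-` site a
   forward-strand A is an edited (T) observation. Reads with a deletion, an N
   or any base other than sense-C/T at the site are tallied as `nOther`:
   they witness coverage but carry no C/T signal, and are excluded from all
   likelihoods and from the extent T/(C+T). Coordinates are 0-based
   half-open internally; site labels are 1-based gene-relative with negative
   leader positions and no position 0 (C1 is the first base of the start
   codon, C-1 the base upstream).

2. **Editing detection.** Conditional on the C/T reads at a site, each read
   shows T with probability θ. The null is θ = ε, the library's empirical
   C→T error rate; the alternative is θ ∈ [ε, 1], i.e. editing extent
   p = (θ − ε)/(1 − ε) > 0. The LRT statistic λ = 2[ℓ(θ̂) − ℓ(ε)] with
   θ̂ = max(ε, n_T/(n_C+n_T)) is referred to the boundary mixture
   ½χ²₀ + ½χ²₁, the standard null law for a one-sided test with the null on
   the parameter-space boundary; a plain χ²₁ reference would be needlessly
   conservative by a factor of two in p-value. With ε = 0 and n_T > 0 the
   null likelihood vanishes and λ is reported as +∞ with p = 0; the 0.5
   pseudocount in error estimation makes this unreachable in practice.

3. **Differential calling.** Replicate C/T counts are pooled per condition
   (pooling equal-depth replicates averages their extents); each site gets a
   Pearson χ² (1 df, no continuity correction) on the 2×2 pooled table,
   treatment vs each control, a per-organelle Bonferroni threshold
   α_family / (edited sites of that organelle), and an effect-size gate
   Δ ≥ `min_delta` per control. Sites significantly reduced in the
   GFP-silenced control versus uninoculated plants are flagged
   control-affected and excluded before treatment testing; the final verdict
   requires passing against **both** controls. The χ² statistic itself is
   symmetric in the two rows; directionality comes entirely from the Δ gate,
   so increases in editing are never called.

## Error-rate calibration

ε is estimated per library from genome-wide sense-orientation base tallies:
rate(X→Y) = (mismatches + c) / (bases at X + 2c) with pseudocount c = 0.5, so
no rate is ever exactly 0 (ℓ(θ = 0) is degenerate when n_T > 0). Estimation
is two-pass to break the circularity between error rates and edit calls:
pass 1 calls provisional edits under a fixed prior ε = 10⁻³; pass 2
re-estimates rates with provisionally edited positions excluded from the C
class and re-calls. On synthetic data this recovers the planted error rate
where a naive single-pass estimate that keeps edited sites in the C class is
inflated several-fold.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `alpha_family_detection` | 1e-3 | familywise rate for edit detection, Bonferroni-divided by the number of scanned candidate Cs |
| `min_libraries` | 2 | libraries in which a site must be individually significant to enter the edited universe (both replicates of some condition under the default 2+2+2 design) |
| `alpha_family_differential` | 1e-3 | familywise rate for the reduced-editing test, divided per organelle by the edited-universe size (618 → 1.6e-6, 38 → 2.6e-5) |
| `min_delta` | 0.1 | minimum absolute extent reduction, in extent units (10 percentage points, not a 10% relative drop) |
| `pooling_mode` | pooled | treatment replicates pooled before testing; `per_replicate` tests each replicate against the pooled controls and requires all to pass |
| `prior_epsilon` | 1e-3 | pass-1 C→T error rate |
| pseudocount | 0.5 | mismatch-rate smoothing |

The Bonferroni divisor for the differential stage is the edited-site count
*before* the control-affected exclusion — that is the universe the thresholds
1.6×10⁻⁶ and 2.6×10⁻⁵ correspond to. Percentages in reports are rounded
half-up to whole percent.

## The synthetic-data generator

The generator's defaults encode the study design the package targets: a
mitochondrial genome with 7000 candidate Cs of which 618 are edited (54
virus-affected, 35 silencing-affected) and a plastid genome with 1320
candidates, 38 edited (3 virus-affected, none silencing-affected) — 8320
scanned candidates in all; two replicates each of uninoculated, GFP-silenced
and treatment conditions; uniform per-substitution error 10⁻³; Poisson depth
with mean 1000 per site, reflecting equimolar amplicon pooling (the achieved
depth is not published for this design, so the default is chosen for
statistical power). True extents follow Beta(5, 2) truncated to [0.05, 1] —
most organelle sites are highly edited. Planted reductions are uniform on
[0.2, 0.5] and assigned to sites whose baseline extent can absorb them;
virus-affected sites lose their delta in both inoculated conditions,
silencing-affected sites only in the treatment. `SimConfig.desk_scale()` is a
single 10-gene organelle at ~80× depth for fast end-to-end runs including SAM
emission; `SimConfig.mito_universe()` reproduces the edited-site universe
alone (every candidate edited), the input situation of the differential
stage.

Counts are multinomial per site and library with
θ = p(1 − ε_T→C − ε_T→other) + (1 − p)ε_C→T and the analogous C probability —
errors act symmetrically on edited and unedited molecules, with no
read-position effects. Replicates differ only by sampling noise
(`depth_dispersion` adds gamma-Poisson depth variation but defaults to 0).
When alignments are emitted, every read is clipped to the open window between
neighbouring candidate sites, so each read covers exactly one candidate; the
site base realises the drawn category and all other positions accrue
substitution errors. This construction makes the pileup↔counts round trip
exact by design, at the cost of slightly shortened reads near dense candidate
clusters — a deliberate trade of read-length realism for an exact
simulator/pileup consistency check.

What the generator does **not** emulate: quality scores, indels, PCR
duplicates, alignment artefacts, position-dependent or strand-asymmetric
error profiles, amplicon-boundary coverage ramps, and biological
extra-binomial variation between plants. Passing tests therefore demonstrate
the correctness and calibration of the statistics under the stated sampling
model, not robustness to alignment artefacts or hidden overdispersion in
real tissue.

## Numerical choices and degenerate inputs

- `xlogy` implements the 0·ln 0 = 0 convention throughout the likelihood.
- λ is clamped at 0 against floating-point rounding when θ̂ ≈ ε.
- A 2×2 table with a zero column margin (no C anywhere or no T anywhere) is
  not testable: the scalar API returns NaN, the batch path propagates NaN,
  and such sites are never significant.
- Sites with no C/T coverage in a library get NaN statistics; pooled
  conditions with no coverage make the site untestable rather than erroring
  the run.
- Simulation, detection and differential stages are deterministic functions
  of their inputs; the generator derives independent substreams per stage
  from the configuration seed, so reference, truth, counts and reads are
  individually reproducible.

## Calibration behaviour and limitations

The ½χ²₀ + ½χ²₁ reference is asymptotic. Its tail is accurate once the
expected null T count ε·(n_C+n_T) is not tiny; at, say, ε = 10⁻³ and depth
500 (expected count 0.5) the discreteness of the null makes moderate
quantiles (q ≈ 0.01) anti-conservative by about half a percentage point,
while the extreme familywise thresholds actually used for detection remain
conservative. The differential stage's familywise control is verified by
simulation (2000 null experiments over the 618-site universe at depth 1000;
see `scripts/acceptance.py`), where the Bonferroni correction plus the Δ
gate hold the empirical familywise error rate at zero, far below the 10⁻³
target.

Problem sizes used in the test suite — 618-site universes at depths 1000 and
2000, a 5000-site extent-recovery panel, 2000 null simulations, 50
planted-effect seeds, and a 150-site desk experiment for SAM round trips —
were chosen so the whole suite characterises calibration, power and exactness
at the study's own scale while remaining quick to run.

## Open design points, resolved

- Whether treatment replicates are pooled like controls, or each tested
  separately, is ambiguous in the underlying design; pooling both is the
  symmetric reading and the default, with `per_replicate` (all replicates
  must pass) available.
- Δ ≥ 0.1 is interpreted as 10 percentage points of extent, not a 10%
  relative reduction.
- The detection-stage familywise rate is not pinned by the source protocol;
  it defaults to 10⁻³ over scanned candidates, mirroring the differential
  stage, and is configurable.
- Chi-square tests use no continuity correction by default (none is part of
  the procedure as stated); `chi2_2x2(..., continuity=True)` applies Yates'
  correction for sensitivity analyses.
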