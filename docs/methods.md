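# Methods

This note documents the models, numerical choices and limitations behind
`hrdscar`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate model

All internal coordinates are 0-based half-open; every TSV on disk is
1-based inclusive (SEG convention). The bundled hg19 table carries
chromosome lengths (UCSC chromInfo) and centromere spans taken as the
union of the acen cytobands (100-kb band resolution). Arms are
`[0, centromere_start)` and `[centromere_end, length)`; telomeres are the
first and last base, with no subtelomeric buffer. Chromosome X is scored
for every sample; Y only for XY samples (switchable via `ScarConfig`).
No liftover or alternate contigs.

## Signal model

A specimen is modelled as a clonal mixture of tumor cells (purity ρ) and
normal diploid cells. A segment with allele-specific tumor copy numbers
(n_a, n_b) produces

* total signal `T = 2(1−ρ) + ρ(n_a + n_b)`,
* `LogR = γ·log2(T / (2(1−ρ) + ρψ))`, ψ the reference tumor ploidy,
* `BAF = ((1−ρ) + ρ n_b) / T` at germline-heterozygous probes.

γ is the platform compression factor — array LogR under-responds to copy
number — with the customary SNP-array default 0.55, exposed in
`FitConfig`. The simulator's forward model is this exact algebra, which
makes the fit stage testable against ground truth: the closed-form
inversion `segment_copy_numbers` recovers the integers to machine
precision (verified over 1000 random mixtures in the suite and the
acceptance script).

## QC

MAPD is the median of |ΔLogR| over consecutive same-chromosome probe
pairs; cross-chromosome pairs are excluded because real copy-number jumps
are not noise. The gate passes iff MAPD ≤ 0.30 and, when supplied,
ndSNPQC ≥ 26 (both inclusive). ndSNPQC is a vendor metric computed on
normal diploid markers inside proprietary software with no published
formula; it is accepted as a pass-through value and only compared against
its threshold.

## Segmentation

Joint piecewise-constant segmentation of LogR (all probes) and mirrored
BAF `|BAF−0.5|+0.5` (informative probes only) minimises, per chromosome,

    Σ_segments [ SSE_logr/σ̂_r² + SSE_mbaf/σ̂_b² ] + penalty × #breakpoints

solved exactly by an O(n²) dynamic program (vectorised prefix sums) with
a minimum segment length of 5 probes. Residuals are normalised by robust
noise estimates — median absolute successive difference / 0.954, floored
at 1e-3 so zero-noise input stays well posed — which puts the default
penalty of 70 on a noise-independent, BIC-like scale; on the raw SSE
scale the same number would be inert at realistic signal amplitudes.
Probe-coverage gaps ≥ 3 Mb force a segment boundary: uncovered sequence
(centromeres, array deserts) should never be bridged by a segment, and
without the rule a single-probe breakpoint jitter can silently attach a
probe across a large gap. The DP is checked against an independent
exhaustive enumeration on ≤ 30-probe tracks.

### Segment BAF estimation

Folding BAF turns noise into positive bias: a balanced segment's folded
mean is 0.5 + σ√(2/π), which is enough to drag the purity fit several
grid steps. Each segment's allelic displacement δ is therefore
re-estimated from two moments of |BAF−0.5| over its n heterozygous
probes: E|BAF−0.5| is the folded-normal mean(δ, σ) and E(BAF−0.5)² =
δ² + σ², a pair solvable for δ without any external noise estimate (and
hence robust on genomes whose *baseline* state is imbalanced, e.g.
triploid). Because the folded mean is flat in δ near zero, the moment
root is positively biased under sampling noise; a one-sided balance test
(ratio d/rms against √(2/π) + 3·0.212/√n, the delta-method sd of the
ratio under the balanced null) snaps such segments to exactly 0.5.
Consequence: true displacements below roughly one noise-sd are reported
as balance — at default noise (σ_BAF 0.03) this only matters below ~20%
purity, the specimen acceptance floor.

## Purity/ploidy grid search

Candidate grid ρ ∈ [0.10, 1.00] step 0.01 (covering the 20% pathology
minimum with margin) × ψ ∈ [1.0, 5.4] step 0.05. For every grid point the
implied (n_a, n_b) of each informative segment is compared to its nearest
non-negative integers; the goodness of fit is the segment-length-weighted
mean squared distance. Three regularisations:

* a small linear ploidy term (0.002·ψ) resolves the whole-genome-doubling
  degeneracy — doubling all states with ρ′ = ρ/(2−ρ) fits almost as well —
  toward the more parsimonious solution, and is far below the within-basin
  curvature of the surface;
* an optional soft constraint down-ranks (never excludes) purities outside
  a tolerance band around the pathologist's tumor-content estimate;
* exact ties break toward lower ψ, then higher ρ.

A profile whose informative segments are all balanced and flat carries no
purity information (the surface is a ridge); it is flagged
non-identifiable, and scoring requires user-fixed (ρ, ψ) — the manual
re-fit path that mirrors reviewer confirmation of tumor content.
Segments with no informative probes get their LogR-implied total split as
evenly as possible. Rounded states are clamped at 0 (counted and logged);
adjacent same-state segments merge.

## Scar rules

* **LOH**: maximal runs of n_minor = 0 ∧ n_major ≥ 1 per chromosome;
  homozygous deletions (0,0) do not interrupt a run but add no length;
  coverage gaps < 3 Mb are bridged, larger gaps break the run. Counted if
  run length (sum of qualifying segment lengths) **> 15 Mb** (strict) and
  the run does not span the whole covered chromosome.
* **LST**: per arm, segments < 3 Mb are removed iteratively (flanks merge
  when they share a state, lengths re-checked until stable, shortest
  first for determinism); then every adjacent pair with different
  (n_major, n_minor), both segments **≥ 10 Mb** (inclusive) and gap
  < 3 Mb, counts one transition. Computing per arm means breaks never
  span the centromere.
* **TAI**: maximal equal-imbalance runs per chromosome; an imbalanced run
  counts if it touches the first or last covered base, does not span the
  centromere entirely, meets the minimum length (default 0), and is not
  whole-chromosome.

Whole-chromosome LOH/TAI exclusion and the 3-Mb smoothing/gap threshold
follow the scar literature the score descends from; both are
config-switchable. GIS = LOH + LST + TAI. All three counters are verified
against an independent brute-force maximal-run enumeration on random toy
profiles, and satisfy merge/split, relabeling and row-order invariances.

## Calibration and agreement

Calibration is ordinary least squares of reference score on raw score
(≥ 2 pairs, non-constant x). The corrected score stays continuous for
thresholding — display values are rounded half-away-from-zero — and the
HRD call is positive iff corrected ≥ 42 (inclusive). Agreement between
assays uses OPA = concordant/n and PPA/NPA margined on the **test** assay
(that orientation reproduces the published 26/28 and 18/19 fractions),
each with a Wilson score 95% CI; Wilson (not Clopper–Pearson) is the
family that reproduces all published interval bounds. Zero-denominator
statistics are reported as undefined rather than raising.

## Simulator

The generator emulates a clonal FFPE tumor on a whole-genome SNP array:
default 60% purity, diploid baseline, 100-kb probe spacing, LogR noise
sd 0.12 (MAPD ≈ 0.11, inside the 0.30 gate), BAF noise sd 0.03, 25%
of probes germline-heterozygous — with configurable event counts
(default 3 LOH, 5 LST, 2 TAI). Each injected event owns one chromosome
arm and is geometrically isolated so it scores as exactly one event of
its own type: LOH runs (16–40 Mb, copy-neutral or deletion) sit in arm
interiors behind 3.5-Mb coverage gaps; LST events are one contiguous
transition with ≥ 11 Mb flanks, gap-terminated on the telomere side; TAI
blocks (5–30 Mb) touch the telomere behind a gap. One RNG stream per
run, split into fixed substreams for event placement and probe
rendering; identical configs reproduce identical samples bit for bit.

What the simulator does **not** model: FFPE wave/GC artifacts, probe-level
bias, subclonality, non-integer states, germline CNVs. Passing round-trip
tests therefore shows the pipeline's stages are mutually consistent and
correctly implemented — not that the pipeline is robust to every artifact
of real FFPE arrays.

Problem sizes used in the shipped checks: ~30k probes per simulated
genome, 10 zero-noise and 10 default-noise round-trip replicates, 10–20
grid-recovery replicates, 200 random profiles against the scar oracle —
sizes at which each check completes in seconds while still exercising
whole-genome structure.

## Known limitations

* The penalty-70 scale is calibrated to this objective's noise-normalised
  residuals; equivalence to the original ASPCF penalty scale cannot be
  established without the original software.
* Sub-noise allelic displacements are deliberately reported as balance
  (see above), so very-low-purity specimens (< 20%) are outside the
  validated envelope — matching the assay's own acceptance criterion.
* PPA/NPA orientation is test-margined; users comparing against
  reference-margined conventions should transpose their table.
* Per-gene annotation of scar events, ploidy-corrected LOH variants, and
  multi-sample fitting are not implemented.
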