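# Methods

## Model overview

The package couples a forward model of an alkaline-gel experiment to the
inverse analysis that estimates embedded-ribonucleotide frequency. The
forward model exists so that the inverse chain can be validated against
known ground truth; every default parameter below is the condition under
which the package's claims are tested.

### Lesion genomes

A genome is a duplex of length `L` base pairs carrying per-strand
lesions, each a `(strand, position, run_length, kind)` record with
1-based coordinates. No base sequence is stored: lesion placement in the
biological system is (to first order) sequence-independent, and a purely
positional representation makes 10⁹-nt molecules cheap. Sequence-backed
site counting lives separately in `motif_spacing`.

Lesion counts are Poisson with means `rate × L` per strand and positions
uniform; overlapping draws are resolved by rejection re-draw, which is
statistically negligible at rates ≪ 1/run_length. Kinds:

* **ribo runs** — `run_length` consecutive embedded ribonucleotides.
  Default run-length distribution: 0.9 on length 1, 0.1 on length 2,
  reflecting that these lesions are single or at most double
  ribonucleotides. Default rate for "mutant" (RNase H2-null) genomes:
  1/7,600 runs per nucleotide per strand. `rate_multiplier` scales this
  rate only — it models hydroxyurea treatment, which shifts dNTP:rNTP
  ratios and increases polymerase ribonucleotide incorporation; it has
  no effect on shear or pre-existing nicks.
* **nicks** — single-strand backbone breaks; a nick at position `i`
  severs the strand between nucleotides `i` and `i+1`.
* **shear** — background double-strand breaks from nucleic-acid
  extraction, stored as coincident nick pairs on both strands. Default
  1/30,000 per bp, giving the 30 kb-mean control lane.

### Cleavage agents

Specific agents convert every ribo run of at least `min_run`
ribonucleotides into exactly one nick:

| agent    | min_run | cut side | rationale                                      |
|----------|---------|----------|------------------------------------------------|
| alkali   | 1       | 3′       | the 2′-OH attacks the 3′ phosphodiester bond   |
| RNase H2 | 1       | 5′       | incises 5′ of an embedded ribonucleotide       |
| RNase HI | 3       | 5′       | requires ≥3 consecutive ribonucleotides        |

The 5′ cut is placed 5′ of the run's 3′-most ribonucleotide, so for any
run length the alkali and RNase H2 cut positions differ by exactly one
nucleotide — matching the observation that the two reagents fragment
null-cell DNA essentially identically. An abstract *nickase* mode
instead adds Poisson nicks at a configured per-nucleotide rate on each
strand, emulating a nicking endonuclease of known mean site spacing.

### Electrophoresis modes

Denaturing separation releases, per strand, the fragments between
consecutive nicks (intact ribo runs are not breaks — formamide denatures
without hydrolysing them); per-strand fragment lengths always sum to the
genome length. Native separation keeps the duplex together: only
opposing-strand nicks within `ds_break_window` (default 10 nt; greedy
two-pointer matching) count as double-strand breaks, so nicked or
ribonucleotide-bearing genomes are indistinguishable from their
shear-only controls on a native gel. The 10-nt default makes
native-mode behaviour testable while keeping random nick coincidence
negligible; it is not an empirically measured quantity.

### Gel rendering

Migration is log-linear, `d = α + β·ln(size)` with `β < 0`. Defaults
`α = 120`, `β = −9` over a 512-point grid on [2, 130] distance units
place 0.5–50 kb comfortably inside the lane and resolve sizes up to
~3×10⁵ nt. Each fragment deposits a Gaussian band (σ = 1.5 distance
units, size-independent) whose area is `mass_scale × length` — staining
with intercalating dyes reports mass, not molecule count, and scanner
response is assumed linear. Fragments whose ideal migration falls above
the resolvable range pile up at a limiting mobility
(`grid_min + 3σ`), emulating the compression zone near the well; without
this, the large-fragment mass of lightly cut lanes would leave the
modelled lane and the subsequent 10⁹-nt normalization would inflate
their fragment counts. Background (default 2.0) and truncated-Gaussian
noise (default sd 0.1 per grid point) are added last. Ladder lanes use
quarter-width bands at the 1-kb-ladder sizes (1–12 kb) and return exact
(distance, size) annotations, emulating supervised peak identification.

## Inverse chain

Per lane, in order: uniform background subtraction (auto level = 5th
percentile of the lane, clipped at zero) → cubic smoothing spline with
40 effective degrees of freedom in the distance domain → transform to a
nucleotide-coordinate histogram via the ladder calibration → rescale to
10⁹ nt → counts.

* **Calibration** is ordinary least squares of distance on `ln(size)`
  over the annotated ladder peaks; predictions outside the fitted range
  are permitted (extrapolated where necessary) but can be flagged.
  The size↔distance round trip is exact to machine precision.
* **Smoothing** uses a natural cubic smoothing spline in Reinsch form,
  with the penalty weight solved (via the eigenvalues of the penalty
  matrix) so that the trace of the smoother matrix equals the requested
  effective df — the same parameterization as `smooth.spline(df=)` in
  R. Implemented here because scipy exposes only the raw penalty
  weight. The 40-df default is defined relative to the 512-point grid
  and is exposed in configuration, since its effect depends on grid
  resolution.
* **Size transform.** The lane is integrated piecewise-linearly between
  the migration distances of consecutive bin edges (200 log-spaced bins
  over 50 nt–100 kb by default), so total mass is conserved exactly and
  no aliasing occurs when bin width is comparable to the grid step; the
  Jacobian of the change of variables is implicit in binning masses
  rather than densities. Mass conservation is what forces this
  construction: without it, total "nucleotides" would depend on gel
  geometry and the 10⁹-nt scaling step would be meaningless. Mass
  mapping outside the window accumulates in the edge bins, with the
  fraction reported. The window floor of 50 nt keeps the
  small-fragment tail of heavily fragmented lanes countable: with a
  200-nt floor, ~3% of the mutant lane's fragments fall below the
  window and the spacing estimate acquires a ~+4% bias.
* **Counting.** Counts per bin are mass divided by the bin's geometric
  mid — the unbiased representative length for log-spaced bins.
* **Pipeline cropping.** At the pipeline level, quantification stops at
  the migration distance of the smallest window size. Background
  estimation still uses the whole lane, but residual baseline beyond
  that distance contains no resolvable DNA; mapped through the
  calibration it would be converted into spurious small-fragment counts
  whose lane-to-lane fluctuation dominates the subtraction estimator.

All inverse operations are deterministic given their inputs.

## Estimators

**Analytic subtraction.** With mutant and control histograms normalized
to the same 10⁹ nt, each extra cleavage site adds exactly one fragment,
so `ΔN = N_mutant − N_control` estimates the extra sites per 10⁹ nt;
`rate = ΔN/10⁹`, `spacing = 1/rate`. A non-positive ΔN (possible under
noise at low true rates) is reported as "no detectable additional
sites" with rate 0, not raised. Replicate pairs are summarized as mean
spacing ± SD.

**Random-cut hill climbing.** Starting fragments are reconstructed from
the control histogram (rounded counts at bin geometric mids, rescaled to
10⁹ nt); `n` uniform cuts are added and the simulated histogram is
compared to the target by Manhattan (L1) distance after both are
smoothed with the same effective-df spline, applied in the size domain
on log-mid abscissae. The search is 1-D hill climbing over integer `n`:
50 iterations of multiplicative proposals `n(1 ± step)` with the step
halved on rejection, initialized from the analytic estimate (1,000 when
unavailable). The iteration count (50) and the Manhattan objective are
the fixed elements of the procedure; the neighbourhood, step schedule
and initialization are this package's choices, selected for robustness
on a one-dimensional integer parameter. Every objective evaluation reuses one fixed random cut
stream (common random numbers — cut sets for different `n` share their
prefix), without which hill climbing on a stochastic objective would be
ill-defined; it also makes the accepted objective non-increasing by
construction.

**Per-cell arithmetic.** `sites = haploid_bp × ploidy × 2 × rate`, with
2.5×10⁹ bp and ploidy 2 by default (10¹⁰ nt per cell); "sites" and
"runs" are used interchangeably (a di-ribonucleotide counts once). The
directly-opposed-pair expectation is `bp × rate²` under independent
placement on the two strands; the often-quoted estimate of ~50 opposed
sites per cell is closer to the haploid-bp evaluation (≈43) than the
diploid one (≈87), so the base-pair count is an explicit parameter
rather than a default.

## Motif spacing

Recognition sites are counted on both strands (reverse-complement
matching on the top strand), overlaps allowed — each occurrence is an
independent nick opportunity. Palindromic sites describe one duplex site
and are counted once. The i.i.d. expectation is
`1 / (2 × Π p(letter))` for non-palindromic sites (factor 1 for
palindromes), with IUPAC letters expanding to summed base frequencies.
`N` in the *sequence* never matches. Recognition strings for the two
ruler enzymes (GCTCTTC, GCAGTG) are standard REBASE sequences and are
user-overridable; the genome-derived 11 kb / 3.7 kb figures depend on
the reference assembly and are reproduced only in order of magnitude
(e.g. a 4-S/3-W 7-mer at mouse-like GC 0.417 gives ≈10.7 kb).

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure of the experiment:
Poisson lesion placement, agent specificity, mass-proportional staining,
log-linear migration with Gaussian band spread, uniform background,
additive scanner noise, and replicate-to-replicate variation from
independent draws. It does not model sequence-context preferences of
polymerase misincorporation, replication-fork or repair dynamics,
non-linear scanner response, lane-to-lane loading differences, or
partial digestion. Passing tests therefore demonstrate that the analysis
chain is correct and well-calibrated under the stated noise model — not
that real gels are free of systematic effects outside it.

## Problem sizes and numerical choices

Tests and the acceptance script use 5×10⁸-bp duplex genomes (10⁹ nt of
single strands per lane, the scale the normalization is defined on) for
headline checks, and 0.5–2.5×10⁸ bp for unit-level checks; these sizes
keep every Poisson count large enough that 4-SD bounds are tight.
Fragment binning uses 200 log bins; the hill climber's objective is
evaluated on the same bins. Degenerate inputs (all-zero histograms,
zero-mass starts, sub-unit sizes, non-overlapping windows, saturated
smoothing df) raise `ValueError` rather than propagating NaNs. Ties in
the hill climb (equal objectives) keep the incumbent. Known
limitations: the analytic estimator inherits a small (<1%) downward
count bias from band-spread smearing; fragment counts for mass piled at
the limiting-mobility position are approximated by the calibration size
at that position, which slightly overcounts very lightly cut lanes.
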