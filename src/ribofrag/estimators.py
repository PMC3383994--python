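"""Frequency estimators for embedded ribonucleotides.

Two routes from normalized fragment histograms to an incorporation rate:

* analytic subtraction -- each extra cleavage site adds exactly one
  fragment, so the difference in total fragment count between a mutant
  and a control lane, both normalized to the same total nucleotide mass,
  equals the number of extra sites per that mass;
* random-cut simulation -- random cuts are added to a starting fragment
  population until the simulated histogram best matches the target, the
  optimal cut number found by hill climbing on the Manhattan (L1)
  distance between smoothed histograms.

Genome-scale arithmetic (sites per cell) and summary statistics of
fragment histograms live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .densitometry import (
    DEFAULT_SMOOTH_DF,
    DEFAULT_TOTAL_MASS,
    SizeHistogram,
    default_bin_edges,
    normalize_and_count,
)
from .smoothing import smooth_values

ANALYTIC = "analytic"
SIMULATION = "simulation"


@dataclass
class FrequencyEstimate:
    """A ribonucleotide-frequency estimate.

    ``rate`` is ribonucleotide sites per nucleotide, ``spacing`` its
    reciprocal (nt per site), and ``delta_fragments`` the excess fragment
    count per ``10^9`` nt from which the rate was derived.  When built
    from replicate lane pairs, the per-replicate spacings and their SD
    are carried along.
    """

    delta_fragments: float
    rate: float
    spacing: float
    method: str
    replicate_spacings: list[float] | None = None
    spacing_sd: float | None = None
    n_cuts: int | None = None
    objective_trace: list[float] | None = None
    note: str = ""


@dataclass
class GenomeConstants:
    """Genome-scale bookkeeping: 2.5e9 bp haploid, diploid, two strands."""

    haploid_bp: float = 2.5e9
    ploidy: int = 2
    strands_per_bp: int = 2

    @property
    def nucleotides_per_cell(self) -> float:
        return self.haploid_bp * self.ploidy * self.strands_per_bp


def analytic_estimate(
    mutant: SizeHistogram, control: SizeHistogram
) -> FrequencyEstimate:
    """Fragment-count subtraction between identically normalized lanes.

    A non-positive difference (control at least as fragmented as the
    mutant) is reported as rate zero with a diagnostic note rather than
    raised -- it occurs under noise at low true rates.
    """
    if not np.isclose(mutant.total_mass, control.total_mass, rtol=1e-6):
        raise ValueError("histograms must be normalized to the same total mass")
    target = mutant.total_mass_target
    delta = mutant.n_fragments - control.n_fragments
    if delta <= 0:
        return FrequencyEstimate(
            delta_fragments=float(delta),
            rate=0.0,
            spacing=float("inf"),
            method=ANALYTIC,
            note="no detectable additional sites",
        )
    rate = delta / target
    return FrequencyEstimate(
        delta_fragments=float(delta), rate=rate, spacing=1.0 / rate, method=ANALYTIC
    )


def combine_replicates(estimates: list[FrequencyEstimate]) -> FrequencyEstimate:
    """Mean spacing +/- SD across replicate pair estimates."""
    if not estimates:
        raise ValueError("no estimates to combine")
    spacings = [e.spacing for e in estimates]
    finite = [s for s in spacings if np.isfinite(s)]
    if not finite:
        return FrequencyEstimate(
            delta_fragments=0.0, rate=0.0, spacing=float("inf"),
            method=estimates[0].method, replicate_spacings=spacings,
            note="no detectable additional sites in any replicate",
        )
    mean_spacing = float(np.mean(finite))
    sd = float(np.std(finite, ddof=1)) if len(finite) > 1 else 0.0
    rate = 1.0 / mean_spacing
    return FrequencyEstimate(
        delta_fragments=float(np.mean([e.delta_fragments for e in estimates])),
        rate=rate,
        spacing=mean_spacing,
        method=estimates[0].method,
        replicate_spacings=spacings,
        spacing_sd=sd,
    )


def _fragments_from_histogram(hist: SizeHistogram, genome_nt: float) -> np.ndarray:
    """Expand a histogram into a concrete fragment population of the
    requested total length: round(counts) fragments at each bin's
    geometric mid, lengths rescaled to sum to ``genome_nt``."""
    counts = np.rint(hist.counts).astype(np.int64)
    if counts.sum() <= 0:
        raise ValueError("start histogram has zero fragment count")
    lengths = np.repeat(hist.mid_sizes, counts)
    lengths = lengths * (genome_nt / lengths.sum())
    return lengths


def _bin_lengths(
    lengths: np.ndarray, edges: np.ndarray, total_mass_target: float
) -> SizeHistogram:
    n_bins = len(edges) - 1
    idx = np.clip(np.searchsorted(edges, lengths, side="right") - 1, 0, n_bins - 1)
    mass = np.bincount(idx, weights=lengths, minlength=n_bins)
    outside = (lengths < edges[0]) | (lengths > edges[-1])
    frac = float(lengths[outside].sum() / lengths.sum()) if lengths.sum() else 0.0
    return SizeHistogram(
        edges, mass, total_mass_target=total_mass_target, out_of_window_fraction=frac
    )


def simulate_fragment_histogram(
    n_cuts: int,
    start: SizeHistogram | None = None,
    genome_nt: float = DEFAULT_TOTAL_MASS,
    seed: int = 0,
    bin_edges: np.ndarray | None = None,
) -> SizeHistogram:
    """Add ``n_cuts`` uniform random cuts to a starting fragment population.

    With no start, the genome begins as a single intact fragment of
    ``genome_nt``.  Cut positions are uniform over the concatenated total
    length; the resulting fragment lengths are binned on the start's (or
    default) log-spaced bins.  Because cut positions are drawn as one
    sequential uniform stream, runs with the same seed share their first
    ``min(n, n')`` cuts -- the common-random-numbers coupling that the
    hill climber relies on.
    """
    if n_cuts < 0:
        raise ValueError("n_cuts must be >= 0")
    if genome_nt < 1:
        raise ValueError("genome_nt must be >= 1")
    if start is None:
        lengths = np.asarray([float(genome_nt)])
        edges = np.asarray(bin_edges) if bin_edges is not None else default_bin_edges()
        target = genome_nt
    else:
        lengths = _fragments_from_histogram(start, genome_nt)
        edges = start.bin_edges
        target = start.total_mass_target
    rng = np.random.default_rng(seed)
    cuts = rng.uniform(0.0, genome_nt, size=int(n_cuts))
    bounds = np.concatenate(([0.0], np.cumsum(lengths)))
    bounds[-1] = genome_nt  # guard against float drift
    allb = np.sort(np.concatenate((bounds, cuts)))
    new_lengths = np.diff(allb)
    new_lengths = new_lengths[new_lengths > 0]
    return _bin_lengths(new_lengths, edges, target)


def _smoothed_counts(hist: SizeHistogram, df: int) -> np.ndarray:
    x = np.log(hist.mid_sizes)
    df = min(df, len(x))
    return np.clip(smooth_values(x, hist.counts, df), 0.0, None)


def hill_climb_fit(
    target: SizeHistogram,
    start: SizeHistogram,
    iterations: int = 50,
    seed: int = 0,
    smooth_df: int = DEFAULT_SMOOTH_DF,
    genome_nt: float | None = None,
    initial_step: float = 0.5,
) -> FrequencyEstimate:
    """Find the cut count that best turns ``start`` into ``target``.

    One-dimensional hill climbing over the integer number of added random
    cuts: multiplicative proposals ``n * (1 +/- step)`` with the step
    halved on rejection, initialized from the analytic subtraction
    estimate (or 1000 when that is unavailable).  The objective is the
    Manhattan distance between the smoothed simulated histogram and the
    smoothed target; every objective evaluation reuses the same random cut
    stream (common random numbers), so the accepted objective is
    non-increasing and the search is well defined despite the stochastic
    forward model.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not np.allclose(target.bin_edges, start.bin_edges):
        raise ValueError("target and start must share bin edges")
    if not np.isclose(target.total_mass, start.total_mass, rtol=1e-6):
        raise ValueError("target and start must be normalized identically")
    if genome_nt is None:
        genome_nt = target.total_mass_target

    target_smooth = _smoothed_counts(target, smooth_df)
    eval_seed = seed  # identical stream for every candidate: CRN coupling

    def objective(n: int) -> float:
        sim = simulate_fragment_histogram(
            n, start=start, genome_nt=genome_nt, seed=eval_seed
        )
        sim = normalize_and_count(sim, target.total_mass_target)
        return float(np.abs(_smoothed_counts(sim, smooth_df) - target_smooth).sum())

    init = analytic_estimate(target, start)
    n_best = int(round(init.delta_fragments)) if init.delta_fragments > 0 else 1000
    n_best = max(n_best, 0)
    best_obj = objective(n_best)
    accepted = [best_obj]
    step = initial_step
    for _ in range(iterations):
        candidates = {
            max(0, int(round(n_best * (1.0 + step)))),
            max(0, int(round(n_best * (1.0 - step)))),
        }
        candidates.discard(n_best)
        improved = False
        for n in sorted(candidates):
            obj = objective(n)
            if obj < best_obj:
                n_best, best_obj = n, obj
                improved = True
        if not improved:
            step /= 2.0
        accepted.append(best_obj)

    rate = n_best / genome_nt
    return FrequencyEstimate(
        delta_fragments=float(n_best),
        rate=rate,
        spacing=(1.0 / rate) if rate > 0 else float("inf"),
        method=SIMULATION,
        n_cuts=n_best,
        objective_trace=accepted,
    )


def sites_per_cell(
    estimate: FrequencyEstimate, constants: GenomeConstants | None = None
) -> float:
    """Expected embedded-ribonucleotide sites per (diploid) cell."""
    if estimate.rate < 0:
        raise ValueError("rate must be >= 0")
    constants = constants or GenomeConstants()
    return constants.nucleotides_per_cell * estimate.rate


def mean_fragment_size(hist: SizeHistogram) -> float:
    """Count-weighted mean fragment length, in nt."""
    n = hist.n_fragments
    if n <= 0:
        raise ValueError("histogram has no fragments")
    return hist.total_mass / n
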