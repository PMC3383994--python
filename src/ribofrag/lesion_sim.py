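"""Positional simulation of ribonucleotide-bearing duplex genomes.

Genomes are modelled abstractly as a duplex length plus per-strand lesion
coordinate lists -- no base sequence is stored, so billion-nucleotide
molecules are cheap to simulate.  Lesions are either runs of consecutive
embedded ribonucleotides (mostly length 1, occasionally 2) or
single-strand nicks.  Cleavage agents convert ribo runs into nicks
according to their substrate specificity, and electrophoresis modes
resolve the nicked duplex into single-strand (denaturing) or duplex
(native) fragment-length multisets.

Coordinates are 1-based.  A nick stored at position ``i`` breaks the
backbone between nucleotides ``i`` and ``i + 1`` of its strand, matching
the 5'/3' phosphodiester-bond language used throughout: the alkali-labile
bond sits 3' of a ribonucleotide, so alkali cleavage of a run ending at
``i`` yields a nick at ``i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

TOP = "top"
BOTTOM = "bottom"
STRANDS = (TOP, BOTTOM)

RIBO_RUN = "ribo_run"
NICK = "nick"

THREE_PRIME = "three_prime"
FIVE_PRIME = "five_prime"

LESION_COLUMNS = ["strand", "position", "run_length", "kind"]


def _empty_lesions() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strand": pd.Series(dtype=str),
            "position": pd.Series(dtype=np.int64),
            "run_length": pd.Series(dtype=np.int64),
            "kind": pd.Series(dtype=str),
        }
    )


@dataclass
class LesionModel:
    """Per-nucleotide rates governing lesion placement.

    ribo_rate
        Expected ribonucleotide runs per nucleotide per strand.  The
        headline frequency of ~1 run in 7,600 nt corresponds to
        ``ribo_rate = 1 / 7600``.
    run_length_dist
        Discrete distribution over run lengths; embedded ribonucleotides
        occur overwhelmingly as mono- or di-nucleotide runs, hence the
        default mass of 0.9 on length 1 and 0.1 on length 2.
    nick_rate
        Expected pre-existing single-strand nicks per nucleotide per strand.
    shear_rate
        Expected double-strand breaks per base pair (background shear from
        nucleic-acid extraction); each shear break is represented as a pair
        of coincident nicks on the two strands.
    rate_multiplier
        Dimensionless scaling of ``ribo_rate`` modelling hydroxyurea
        treatment, which lowers dNTP:rNTP ratios and increases polymerase
        ribonucleotide incorporation.
    """

    ribo_rate: float = 0.0
    run_length_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.9, 2: 0.1}
    )
    nick_rate: float = 0.0
    shear_rate: float = 0.0
    rate_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ribo_rate", "nick_rate", "shear_rate", "rate_multiplier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        probs = np.asarray(list(self.run_length_dist.values()), dtype=float)
        lengths = np.asarray(list(self.run_length_dist.keys()), dtype=np.int64)
        if len(probs) == 0 or np.any(probs < 0) or not math.isclose(
            probs.sum(), 1.0, rel_tol=0, abs_tol=1e-9
        ):
            raise ValueError("run_length_dist must be a probability distribution")
        if np.any(lengths < 1):
            raise ValueError("run lengths must be >= 1")


@dataclass
class LesionGenome:
    """A duplex molecule of given length with per-strand lesions."""

    length: int
    lesions: pd.DataFrame = field(default_factory=_empty_lesions)
    label: str = ""

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("genome length must be >= 1")
        self.lesions = self.lesions.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        les = self.lesions
        if list(les.columns) != LESION_COLUMNS:
            raise ValueError(f"lesion table must have columns {LESION_COLUMNS}")
        if len(les) == 0:
            return
        if not les["strand"].isin(STRANDS).all():
            raise ValueError("unknown strand")
        if not les["kind"].isin((RIBO_RUN, NICK)).all():
            raise ValueError("unknown lesion kind")
        pos = les["position"].to_numpy()
        run = les["run_length"].to_numpy()
        if np.any(pos < 1) or np.any(pos + run - 1 > self.length):
            raise ValueError("lesion outside genome")
        if np.any(run[les["kind"].to_numpy() == NICK] != 1):
            raise ValueError("nicks must have run_length 1")
        for strand in STRANDS:
            sub = les[les["strand"] == strand].sort_values("position")
            p = sub["position"].to_numpy()
            e = p + sub["run_length"].to_numpy() - 1
            if len(p) > 1 and np.any(p[1:] <= e[:-1]):
                raise ValueError(f"overlapping lesions on {strand} strand")

    def nick_positions(self, strand: str) -> np.ndarray:
        """Sorted nick positions on one strand."""
        les = self.lesions
        mask = (les["strand"] == strand) & (les["kind"] == NICK)
        return np.sort(les.loc[mask, "position"].to_numpy())

    def ribo_runs(self, strand: str) -> pd.DataFrame:
        les = self.lesions
        mask = (les["strand"] == strand) & (les["kind"] == RIBO_RUN)
        return les.loc[mask, ["position", "run_length"]].sort_values("position")

    def count(self, kind: str) -> int:
        return int((self.lesions["kind"] == kind).sum())


@dataclass(frozen=True)
class CleavageAgent:
    """A reagent that converts ribonucleotide runs (or random positions)
    into single-strand nicks.

    Exactly one of ``min_run`` and ``extra_nick_rate`` is set: specific
    agents cleave every run of at least ``min_run`` consecutive
    ribonucleotides, while the abstract nickase mode adds Poisson nicks
    at ``extra_nick_rate`` per nucleotide on each strand, emulating a
    nicking endonuclease of known mean site spacing.
    """

    name: str
    min_run: int | None = None
    cut_side: str = THREE_PRIME
    extra_nick_rate: float | None = None

    def __post_init__(self) -> None:
        if (self.min_run is None) == (self.extra_nick_rate is None):
            raise ValueError("exactly one of min_run and extra_nick_rate must be set")
        if self.min_run is not None and self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.extra_nick_rate is not None and self.extra_nick_rate < 0:
            raise ValueError("extra_nick_rate must be >= 0")
        if self.cut_side not in (THREE_PRIME, FIVE_PRIME):
            raise ValueError("cut_side must be three_prime or five_prime")


# Hot alkali hydrolyses the phosphodiester bond 3' of every embedded
# ribonucleotide; RNase H2 incises 5' of an embedded ribonucleotide and
# recognises even a single one; E. coli RNase HI requires at least three
# consecutive ribonucleotides.
ALKALI = CleavageAgent("alkali", min_run=1, cut_side=THREE_PRIME)
RNASE_H2 = CleavageAgent("rnaseh2", min_run=1, cut_side=FIVE_PRIME)
RNASE_HI = CleavageAgent("rnasehi", min_run=3, cut_side=FIVE_PRIME)

AGENTS: dict[str, CleavageAgent] = {
    a.name: a for a in (ALKALI, RNASE_H2, RNASE_HI)
}


def nickase(rate: float, name: str = "nickase") -> CleavageAgent:
    """Abstract nicking endonuclease with mean site spacing ``1 / rate`` nt."""
    return CleavageAgent(name, min_run=None, extra_nick_rate=rate)


@dataclass
class FragmentSet:
    """Multiset of fragment lengths (nt for single-strand, bp for duplex)."""

    lengths: np.ndarray
    strandedness: str = "single"
    source: str = ""

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths)
        if self.strandedness not in ("single", "double"):
            raise ValueError("strandedness must be 'single' or 'double'")
        if len(self.lengths) and self.lengths.min() < 1:
            raise ValueError("fragment lengths must be >= 1")

    @property
    def total_nt(self) -> float:
        return float(self.lengths.sum())

    @property
    def n_fragments(self) -> int:
        return int(len(self.lengths))

    def mean_length(self) -> float:
        return float(self.lengths.mean())


def _resolve_overlaps(
    rng: np.random.Generator,
    length: int,
    position: np.ndarray,
    run: np.ndarray,
    fixed: np.ndarray,
) -> np.ndarray:
    """Re-draw positions of non-fixed lesions until no interval overlaps.

    Lesion rates are always << 1 / run_length, so collisions are rare and
    the rejection loop terminates after a couple of passes in practice.
    """
    position = position.copy()
    for _ in range(1000):
        order = np.argsort(position, kind="stable")
        p = position[order]
        e = p + run[order] - 1
        clash = np.zeros(len(p), dtype=bool)
        bad = p[1:] <= e[:-1]
        # mark the later (and, unless fixed, the earlier) member of each pair
        clash[1:] |= bad
        clash[:-1] |= bad
        clash_idx = order[clash]
        # prefer re-drawing non-fixed lesions; if a pair is fixed-vs-free
        # only the free one moves
        redraw = clash_idx[~fixed[clash_idx]]
        if len(clash_idx) == 0:
            return position
        if len(redraw) == 0:  # all clashes among fixed lesions: drop dupes later
            return position
        position[redraw] = rng.integers(
            1, length - run[redraw] + 2, size=len(redraw)
        )
    raise RuntimeError("could not resolve lesion overlaps; rates too high?")


def simulate_genome(length: int, model: LesionModel) -> LesionGenome:
    """Draw a lesion-bearing duplex genome.

    Per-strand ribo-run and nick counts are Poisson with means
    ``ribo_rate * rate_multiplier * length`` and ``nick_rate * length``;
    shear (double-strand break) counts are Poisson with mean
    ``shear_rate * length`` and appear as coincident nicks on both
    strands.  Positions are uniform; overlapping draws are re-drawn.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(model.seed)
    run_values = np.asarray(list(model.run_length_dist.keys()), dtype=np.int64)
    run_probs = np.asarray(list(model.run_length_dist.values()), dtype=float)
    run_probs = run_probs / run_probs.sum()

    n_shear = rng.poisson(model.shear_rate * length)
    shear_pos = (
        rng.integers(1, length, size=n_shear) if length > 1
        else np.empty(0, dtype=np.int64)
    )

    frames = []
    for strand in STRANDS:
        parts_pos: list[np.ndarray] = []
        parts_run: list[np.ndarray] = []
        parts_kind: list[np.ndarray] = []
        parts_fixed: list[np.ndarray] = []

        if n_shear:
            parts_pos.append(shear_pos.astype(np.int64))
            parts_run.append(np.ones(n_shear, dtype=np.int64))
            parts_kind.append(np.full(n_shear, NICK))
            parts_fixed.append(np.ones(n_shear, dtype=bool))

        n_nick = rng.poisson(model.nick_rate * length)
        if n_nick and length > 1:
            parts_pos.append(rng.integers(1, length, size=n_nick))
            parts_run.append(np.ones(n_nick, dtype=np.int64))
            parts_kind.append(np.full(n_nick, NICK))
            parts_fixed.append(np.zeros(n_nick, dtype=bool))

        n_ribo = rng.poisson(model.ribo_rate * model.rate_multiplier * length)
        if n_ribo:
            runs = rng.choice(run_values, size=n_ribo, p=run_probs)
            runs = runs[runs <= length]
            pos = rng.integers(1, length - runs + 2)
            parts_pos.append(pos)
            parts_run.append(runs)
            parts_kind.append(np.full(len(runs), RIBO_RUN))
            parts_fixed.append(np.zeros(len(runs), dtype=bool))

        if not parts_pos:
            continue
        pos = np.concatenate(parts_pos)
        run = np.concatenate(parts_run)
        kind = np.concatenate(parts_kind)
        fixed = np.concatenate(parts_fixed)
        pos = _resolve_overlaps(rng, length, pos, run, fixed)
        frame = pd.DataFrame(
            {"strand": strand, "position": pos, "run_length": run, "kind": kind}
        )
        # identical coincident nicks (possible when fixed shear positions
        # collide) collapse to one
        frame = frame.drop_duplicates()
        frames.append(frame)

    lesions = (
        pd.concat(frames, ignore_index=True) if frames else _empty_lesions()
    )
    return LesionGenome(length=length, lesions=lesions, label="simulated")


def digest(
    genome: LesionGenome, agent: CleavageAgent, seed: int = 0
) -> LesionGenome:
    """Apply a cleavage agent, converting susceptible ribo runs to nicks.

    A run of ``r`` consecutive ribonucleotides starting at ``p`` is cleaved
    once: 3'-side agents (alkali) nick at ``p + r - 1`` (3' of the last
    ribonucleotide), 5'-side agents (the RNase H enzymes) nick at
    ``p + r - 2`` (5' of the 3'-most ribonucleotide), so for any run the
    two conventions differ by exactly one nucleotide.  Runs shorter than
    the agent's ``min_run`` are untouched.  Nicks falling at a strand
    terminus (position 0 or the full length) do not create new fragments
    and are dropped.  The abstract nickase mode instead adds Poisson nicks
    at ``extra_nick_rate`` per nucleotide on each strand.
    """
    les = genome.lesions

    if agent.extra_nick_rate is not None:
        rng = np.random.default_rng(seed)
        frames = [les]
        for strand in STRANDS:
            n = rng.poisson(agent.extra_nick_rate * genome.length)
            if n == 0 or genome.length < 2:
                continue
            pos = rng.integers(1, genome.length, size=n)
            frames.append(
                pd.DataFrame(
                    {
                        "strand": strand,
                        "position": pos,
                        "run_length": np.ones(n, dtype=np.int64),
                        "kind": NICK,
                    }
                )
            )
        out = pd.concat(frames, ignore_index=True)
        out = _drop_conflicting_nicks(out)
        return LesionGenome(
            genome.length, out, label=f"{genome.label}+{agent.name}"
        )

    kind = les["kind"].to_numpy() if len(les) else np.empty(0, dtype=object)
    run = les["run_length"].to_numpy() if len(les) else np.empty(0, dtype=np.int64)
    cleave = (kind == RIBO_RUN) & (run >= agent.min_run)

    keep = les[~cleave]
    cut = les[cleave]
    if len(cut):
        offset = -1 if agent.cut_side == THREE_PRIME else -2
        nick_pos = cut["position"].to_numpy() + cut["run_length"].to_numpy() + offset
        valid = (nick_pos >= 1) & (nick_pos <= genome.length - 1)
        nicks = pd.DataFrame(
            {
                "strand": cut["strand"].to_numpy()[valid],
                "position": nick_pos[valid],
                "run_length": np.int64(1),
                "kind": NICK,
            }
        )
        out = pd.concat([keep, nicks], ignore_index=True)
    else:
        out = keep.reset_index(drop=True)
    out = _drop_conflicting_nicks(out)
    return LesionGenome(genome.length, out, label=f"{genome.label}+{agent.name}")


def _drop_conflicting_nicks(les: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate nicks and drop nicks inside surviving ribo runs."""
    les = les.drop_duplicates().reset_index(drop=True)
    drop = np.zeros(len(les), dtype=bool)
    for strand in STRANDS:
        runs = les[(les["strand"] == strand) & (les["kind"] == RIBO_RUN)]
        nick_mask = (
            (les["strand"] == strand) & (les["kind"] == NICK)
        ).to_numpy()
        if not len(runs) or not nick_mask.any():
            continue
        starts = np.sort(runs["position"].to_numpy())
        ends = (runs["position"] + runs["run_length"] - 1).to_numpy()
        ends = ends[np.argsort(runs["position"].to_numpy())]
        npos = les.loc[nick_mask, "position"].to_numpy()
        idx = np.searchsorted(starts, npos, side="right") - 1
        inside = (idx >= 0) & (npos <= ends[np.clip(idx, 0, None)])
        drop[np.flatnonzero(nick_mask)[inside]] = True
    return les[~drop].reset_index(drop=True)


def _fragments_from_cuts(cuts: np.ndarray, length: int) -> np.ndarray:
    cuts = np.unique(cuts)
    bounds = np.concatenate(([0], cuts, [length]))
    lengths = np.diff(bounds)
    return lengths[lengths > 0]


def electrophorese(
    genome: LesionGenome, mode: str, ds_break_window: int = 10
) -> FragmentSet:
    """Resolve a nicked duplex into a fragment-length multiset.

    Denaturing (hot alkali or formamide) separation releases, per strand,
    the fragments between consecutive nicks on that strand; embedded ribo
    runs are *not* breaks (formamide denatures without hydrolysing the
    ribonucleotide phosphodiester bond).  Native separation keeps the
    duplex intact, so only double-strand breaks -- opposing-strand nicks
    within ``ds_break_window`` nt of each other, which includes shear
    breaks stored as coincident nick pairs -- terminate fragments.
    """
    if ds_break_window < 0:
        raise ValueError("ds_break_window must be >= 0")
    if mode == "denaturing":
        pieces = [
            _fragments_from_cuts(genome.nick_positions(s), genome.length)
            for s in STRANDS
        ]
        lengths = np.concatenate(pieces)
        return FragmentSet(
            lengths, strandedness="single",
            source=f"{genome.label}|denaturing",
        )
    if mode == "native":
        top = genome.nick_positions(TOP)
        bottom = genome.nick_positions(BOTTOM)
        breaks = []
        i = j = 0
        while i < len(top) and j < len(bottom):
            if abs(int(top[i]) - int(bottom[j])) <= ds_break_window:
                breaks.append(int(top[i]))
                i += 1
                j += 1
            elif top[i] < bottom[j]:
                i += 1
            else:
                j += 1
        lengths = _fragments_from_cuts(
            np.asarray(breaks, dtype=np.int64), genome.length
        )
        return FragmentSet(
            lengths, strandedness="double", source=f"{genome.label}|native"
        )
    raise ValueError(f"unknown electrophoresis mode {mode!r}")


def opposed_pair_expectation(bp_count: float, per_strand_rate: float) -> float:
    """Expected number of base pairs with a ribonucleotide on *both* strands.

    Under independent uniform placement at ``per_strand_rate`` sites per
    nucleotide on each strand, each base-pair position is doubly occupied
    with probability ``rate**2``, giving ``bp_count * rate**2`` expected
    directly-opposed pairs -- the configuration proposed to yield
    double-strand breaks by simultaneous hydrolysis on opposing strands.
    """
    if bp_count < 1:
        raise ValueError("bp_count must be >= 1")
    if not 0 <= per_strand_rate <= 1:
        raise ValueError("per_strand_rate must be within [0, 1]")
    return bp_count * per_strand_rate**2
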