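"""Nicking-endonuclease site-frequency statistics.

Nicking enzymes of known mean site spacing (e.g. a 7-cutter nicking
roughly every 11 kb of mouse genomic DNA, a 6-cutter roughly every
3.7 kb) serve as fragmentation-scale rulers against which the
ribonucleotide-driven fragmentation is compared.  This module counts
recognition sites on real or simulated sequence and provides the
closed-form expectation under an independent-base model.

Sites are counted on both strands of the duplex (overlaps allowed --
each occurrence is an independent nick opportunity); for palindromic
motifs the two strands carry the same duplex site, which is counted
once.  Recognition strings are IUPAC; ``N`` in the *sequence* never
matches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

_VALID_SEQ = set("ACGTN")


@dataclass(frozen=True)
class MotifSpec:
    """A nicking-endonuclease recognition site."""

    name: str
    site: str
    nicked_strand_only: bool = True

    def __post_init__(self) -> None:
        site = self.site.upper()
        object.__setattr__(self, "site", site)
        if len(site) < 4:
            raise ValueError("site must be at least 4 bases long")
        if any(c not in ambiguous_dna_values for c in site):
            raise ValueError(f"invalid IUPAC characters in site {site!r}")

    @property
    def reverse_complement(self) -> str:
        return str(Seq(self.site).reverse_complement())

    @property
    def is_palindromic(self) -> bool:
        return self.site == self.reverse_complement


# REBASE recognition strings for the two enzymes used as spacing rulers;
# user-supplied motifs are equally accepted anywhere a MotifSpec is taken.
NT_BSPQI = MotifSpec("Nt.BspQI", "GCTCTTC")
NB_BTSI = MotifSpec("Nb.BtsI", "GCAGTG")


def _site_regex(site: str) -> str:
    parts = []
    for c in site:
        bases = ambiguous_dna_values[c]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


@dataclass
class ScanResult:
    """1-based match start positions on each strand (top-strand coordinates)."""

    top: np.ndarray
    bottom: np.ndarray

    @property
    def n_sites(self) -> int:
        return int(len(self.top) + len(self.bottom))


def scan(sequence: str, motif: MotifSpec) -> ScanResult:
    """All (overlapping) occurrences of the site on both strands.

    Bottom-strand sites are located by matching the reverse complement of
    the site against the top-strand sequence; positions are 1-based start
    positions in top-strand coordinates.  For palindromic sites the
    bottom-strand list is empty: both orientations describe the same
    duplex site.
    """
    seq = sequence.upper()
    if set(seq) - _VALID_SEQ:
        bad = sorted(set(seq) - _VALID_SEQ)
        raise ValueError(f"invalid sequence characters: {bad}")
    top_pat = re.compile(f"(?=({_site_regex(motif.site)}))")
    top = np.asarray([m.start() + 1 for m in top_pat.finditer(seq)], dtype=np.int64)
    if motif.is_palindromic:
        bottom = np.empty(0, dtype=np.int64)
    else:
        rc_pat = re.compile(f"(?=({_site_regex(motif.reverse_complement)}))")
        bottom = np.asarray(
            [m.start() + 1 for m in rc_pat.finditer(seq)], dtype=np.int64
        )
    return ScanResult(top=top, bottom=bottom)


def mean_spacing(sequence_length: float, n_sites: int) -> float | None:
    """Mean nt between sites (both-strand sites pooled over the duplex).

    ``None`` when no sites were found (spacing undefined).
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    if n_sites == 0:
        return None
    return sequence_length / n_sites


def expected_spacing_iid(
    motif: MotifSpec, base_freqs: dict[str, float] | None = None
) -> float:
    """Expected duplex site spacing under an independent-base model.

    Per-position match probability is the product over site letters of
    the summed frequencies of the bases each letter matches; both strands
    contribute for non-palindromic sites (factor 2), a palindromic site
    is one duplex site (factor 1).
    """
    if base_freqs is None:
        base_freqs = {b: 0.25 for b in "ACGT"}
    total = sum(base_freqs.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError("base frequencies must sum to 1")
    p = 1.0
    for c in motif.site:
        p *= sum(base_freqs[b] for b in ambiguous_dna_values[c])
    factor = 1.0 if motif.is_palindromic else 2.0
    return 1.0 / (factor * p)


def random_sequence(length: int, seed: int = 0, gc: float = 0.5) -> str:
    """Uniform (or GC-biased) i.i.d. random sequence, for simulation checks."""
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))
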