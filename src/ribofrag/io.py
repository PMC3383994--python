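"""Plain-text serialization: TSV lanes/histograms/genomes, YAML config, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .densitometry import SizeHistogram
from .gel_render import DensitometryTrace, LadderAnnotation
from .lesion_sim import LESION_COLUMNS, FragmentSet, LesionGenome


def write_trace(trace: DensitometryTrace, path) -> None:
    pd.DataFrame(
        {"distance": trace.distances, "intensity": trace.intensities}
    ).to_csv(path, sep="\t", index=False)


def read_trace(path, lane_label: str = "") -> DensitometryTrace:
    df = pd.read_csv(path, sep="\t")
    return DensitometryTrace(
        df["distance"].to_numpy(), df["intensity"].to_numpy(),
        lane_label or Path(path).stem,
    )


def write_annotation(annotation: LadderAnnotation, path) -> None:
    pd.DataFrame(
        {"distance": annotation.distances, "size": annotation.sizes}
    ).to_csv(path, sep="\t", index=False)


def read_annotation(path) -> LadderAnnotation:
    df = pd.read_csv(path, sep="\t")
    return LadderAnnotation(df["distance"].to_numpy(), df["size"].to_numpy())


def write_fragments(fragments: FragmentSet, path) -> None:
    lengths, counts = np.unique(fragments.lengths, return_counts=True)
    pd.DataFrame({"length_nt": lengths, "count": counts}).to_csv(
        path, sep="\t", index=False
    )


def read_fragments(path, strandedness: str = "single") -> FragmentSet:
    df = pd.read_csv(path, sep="\t")
    lengths = np.repeat(df["length_nt"].to_numpy(), df["count"].to_numpy())
    return FragmentSet(lengths, strandedness=strandedness, source=str(path))


def write_genome(genome: LesionGenome, path) -> None:
    genome.lesions[LESION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_genome(path, length: int, label: str = "") -> LesionGenome:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        df = df.reindex(columns=LESION_COLUMNS)
    return LesionGenome(length=length, lesions=df[LESION_COLUMNS], label=label)


def write_histogram(hist: SizeHistogram, path) -> None:
    pd.DataFrame(
        {
            "bin_lo": hist.bin_edges[:-1],
            "bin_hi": hist.bin_edges[1:],
            "mass_nt": hist.mass,
            "count": hist.counts,
        }
    ).to_csv(path, sep="\t", index=False)


def read_histogram(path, total_mass_target: float = 1e9) -> SizeHistogram:
    df = pd.read_csv(path, sep="\t")
    edges = np.concatenate((df["bin_lo"].to_numpy(), df["bin_hi"].to_numpy()[-1:]))
    return SizeHistogram(edges, df["mass_nt"].to_numpy(), total_mass_target)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=False)
        fh.write("\n")
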