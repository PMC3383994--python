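"""Orchestration: reproducible synthetic datasets and the end-to-end estimate.

``generate_dataset`` writes a complete synthetic experiment to disk --
ladder lane with supervised peak annotations, shear-only control lanes
and ribonucleotide-bearing mutant lanes (before digestion under native
electrophoresis, and after each configured cleavage agent under
denaturing electrophoresis), plus a truth table for oracle checks.
``run_pipeline`` reads such a dataset back and runs the full analysis
chain: background subtraction, ladder calibration, 40-df smoothing,
size-domain transform, 10^9-nt normalization, fragment counting and
analytic subtraction (optionally followed by the random-cut hill climb).

All randomness descends from one root seed through named substreams, so
datasets and reports are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .densitometry import (
    DEFAULT_N_BINS,
    DEFAULT_SMOOTH_DF,
    DEFAULT_TOTAL_MASS,
    DEFAULT_WINDOW,
    fit_calibration,
    normalize_and_count,
    smooth_trace,
    subtract_background,
    to_size_domain,
)
from .estimators import (
    FrequencyEstimate,
    analytic_estimate,
    combine_replicates,
    hill_climb_fit,
    mean_fragment_size,
)
from .gel_render import DensitometryTrace, GelModel, render_ladder, render_trace
from .lesion_sim import AGENTS, LesionModel, digest, electrophorese, simulate_genome

REPORT_SCHEMA_VERSION = 1

# Invitrogen-style 1 kb ladder bands (nt)
DEFAULT_LADDER_SIZES = (
    1000, 2000, 3000, 4000, 5000, 6000, 8000, 10000, 12000,
)

MEF_RIBO_RATE = 1.0 / 7600.0  # headline incorporation rate, runs per nt per strand
CONTROL_SHEAR_RATE = 1.0 / 30000.0  # background shear, breaks per bp


def child_seed(root: int, *indices: int) -> int:
    """Deterministic named substream seed, kept below 2**31."""
    state = np.random.SeedSequence([int(root), *[int(i) for i in indices]])
    return int(state.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunConfig:
    """Everything needed to regenerate a dataset and its analysis."""

    seed: int = 0
    genome_length: int = 500_000_000  # duplex bp -> 1e9 nt of ssDNA per lane
    n_replicates: int = 4
    ribo_rate: float = MEF_RIBO_RATE
    run_length_dist: dict = field(default_factory=lambda: {1: 0.9, 2: 0.1})
    shear_rate: float = CONTROL_SHEAR_RATE
    nick_rate: float = 0.0
    rate_multiplier: float = 1.0
    agents: tuple = ("alkali",)
    ladder_sizes: tuple = DEFAULT_LADDER_SIZES
    smoothing_df: int = DEFAULT_SMOOTH_DF
    n_bins: int = DEFAULT_N_BINS
    window: tuple = DEFAULT_WINDOW
    total_mass_target: float = DEFAULT_TOTAL_MASS
    hill_climb: bool = False
    iterations: int = 50
    write_native_lanes: bool = False
    gel: GelModel = field(default_factory=GelModel)

    @classmethod
    def from_yaml_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        gel_raw = dict(raw.pop("gel", {}) or {})
        grid = gel_raw.pop("distance_grid", None)
        if grid is not None:
            gel_raw["distance_grid"] = np.asarray(grid, dtype=float)
        cfg = cls(**raw)
        if gel_raw:
            cfg.gel = GelModel(**gel_raw)
        cfg.agents = tuple(cfg.agents)
        cfg.ladder_sizes = tuple(cfg.ladder_sizes)
        cfg.window = tuple(cfg.window)
        cfg.run_length_dist = {int(k): float(v) for k, v in cfg.run_length_dist.items()}
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_yaml_dict(io.load_yaml(path))

    def to_dict(self) -> dict:
        d = asdict(self)
        gel = d.pop("gel")
        gel["distance_grid"] = [float(x) for x in gel["distance_grid"]]
        d["gel"] = gel
        d["agents"] = list(self.agents)
        d["ladder_sizes"] = list(self.ladder_sizes)
        d["window"] = list(self.window)
        return d

    def lesion_model(self, role: str, seed: int) -> LesionModel:
        ribo = self.ribo_rate if role == "mutant" else 0.0
        return LesionModel(
            ribo_rate=ribo,
            run_length_dist=dict(self.run_length_dist),
            nick_rate=self.nick_rate,
            shear_rate=self.shear_rate,
            rate_multiplier=self.rate_multiplier,
            seed=seed,
        )


def generate_dataset(config: RunConfig, outdir) -> dict:
    """Write lane files, ladder, manifest and truth table; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ladder_trace, annotation = render_ladder(config.ladder_sizes, config.gel)
    io.write_trace(ladder_trace, outdir / "ladder.tsv")
    io.write_annotation(annotation, outdir / "ladder_peaks.tsv")

    lanes = []
    truth_rows = []
    for rep in range(config.n_replicates):
        for role_idx, role in enumerate(("control", "mutant")):
            genome_seed = child_seed(config.seed, rep, role_idx, 0)
            genome = simulate_genome(
                config.genome_length, config.lesion_model(role, genome_seed)
            )
            if config.write_native_lanes:
                native = electrophorese(genome, "native")
                fname = f"rep{rep}_{role}_native.tsv"
                trace = render_trace(
                    native, config.gel,
                    seed=child_seed(config.seed, rep, role_idx, 1),
                    lane_label=fname,
                )
                io.write_trace(trace, outdir / fname)
                lanes.append(
                    {"file": fname, "role": role, "replicate": rep,
                     "agent": None, "mode": "native"}
                )
            for agent_idx, agent_name in enumerate(config.agents):
                digested = digest(
                    genome, AGENTS[agent_name],
                    seed=child_seed(config.seed, rep, role_idx, 2 + agent_idx),
                )
                fragments = electrophorese(digested, "denaturing")
                fname = f"rep{rep}_{role}_{agent_name}.tsv"
                trace = render_trace(
                    fragments, config.gel,
                    seed=child_seed(config.seed, rep, role_idx, 100 + agent_idx),
                    lane_label=fname,
                )
                io.write_trace(trace, outdir / fname)
                lanes.append(
                    {"file": fname, "role": role, "replicate": rep,
                     "agent": agent_name, "mode": "denaturing"}
                )
                truth_rows.append(
                    {
                        "replicate": rep,
                        "lane": fname,
                        "role": role,
                        "agent": agent_name,
                        "true_ribo_rate": config.ribo_rate if role == "mutant" else 0.0,
                        "n_ribo_runs": genome.count("ribo_run"),
                        "n_fragments": fragments.n_fragments,
                        "mean_fragment_nt": fragments.mean_length(),
                    }
                )

    manifest = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "ladder": "ladder.tsv",
        "ladder_peaks": "ladder_peaks.tsv",
        "lanes": lanes,
        "config": config.to_dict(),
    }
    io.dump_yaml(manifest, outdir / "manifest.yaml")
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return manifest


def quantify_lane(trace, cal, config: RunConfig):
    """Single-lane analysis chain: subtract, smooth, transform, normalize.

    Background estimation uses the whole lane, but quantification stops at
    the migration distance of the smallest window size: beyond it no
    resolvable DNA runs, and any residual baseline there would otherwise
    be converted into spurious small-fragment counts.
    """
    sub = subtract_background(trace, "auto")
    d_max = cal.distance_at(config.window[0])
    keep = sub.distances <= d_max
    cropped = DensitometryTrace(
        sub.distances[keep], sub.intensities[keep], sub.lane_label
    )
    smoothed = smooth_trace(cropped, min(config.smoothing_df, int(keep.sum())))
    hist = to_size_domain(smoothed, cal, window=config.window, n_bins=config.n_bins)
    return normalize_and_count(hist, config.total_mass_target)


def run_pipeline(data_dir, agent: str | None = None, hill_climb: bool | None = None) -> dict:
    """Full analysis of a generated dataset directory; returns the report."""
    data_dir = Path(data_dir)
    manifest = io.load_yaml(data_dir / "manifest.yaml")
    config = RunConfig.from_yaml_dict(manifest["config"])

    annotation = io.read_annotation(data_dir / manifest["ladder_peaks"])
    cal = fit_calibration(annotation)

    agent = agent or config.agents[0]
    if hill_climb is None:
        hill_climb = config.hill_climb

    pair_estimates: list[FrequencyEstimate] = []
    per_replicate = []
    mutant_hists = []
    control_hists = []
    for rep in range(config.n_replicates):
        hists = {}
        for role in ("control", "mutant"):
            fname = f"rep{rep}_{role}_{agent}.tsv"
            trace = io.read_trace(data_dir / fname)
            hists[role] = quantify_lane(trace, cal, config)
            io.write_histogram(hists[role], data_dir / f"rep{rep}_{role}_{agent}_hist.tsv")
        est = analytic_estimate(hists["mutant"], hists["control"])
        pair_estimates.append(est)
        mutant_hists.append(hists["mutant"])
        control_hists.append(hists["control"])
        per_replicate.append(
            {
                "replicate": rep,
                "delta_fragments": est.delta_fragments,
                "rate": est.rate,
                "spacing_nt": est.spacing,
                "mutant_mean_fragment_nt": mean_fragment_size(hists["mutant"]),
                "control_mean_fragment_nt": mean_fragment_size(hists["control"]),
            }
        )

    combined = combine_replicates(pair_estimates)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "method": "analytic",
        "agent": agent,
        "seed": config.seed,
        "calibration": {
            "alpha": cal.alpha, "beta": cal.beta, "residual_sd": cal.residual_sd,
        },
        "replicates": per_replicate,
        "delta_fragments_per_1e9nt": combined.delta_fragments,
        "rate_per_nt": combined.rate,
        "spacing_nt": combined.spacing,
        "spacing_sd_nt": combined.spacing_sd,
        "settings": {
            "smoothing_df": config.smoothing_df,
            "n_bins": config.n_bins,
            "window": list(config.window),
            "total_mass_target": config.total_mass_target,
        },
    }

    if hill_climb:
        hc = hill_climb_fit(
            mutant_hists[0], control_hists[0],
            iterations=config.iterations,
            seed=child_seed(config.seed, 9999),
            smooth_df=config.smoothing_df,
        )
        report["hill_climb"] = {
            "n_cuts": hc.n_cuts,
            "rate_per_nt": hc.rate,
            "spacing_nt": hc.spacing,
            "objective_trace": hc.objective_trace,
        }

    io.write_json(report, data_dir / "report.json")
    return report
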