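"""The four-condition pattern-separation experiment, end to end.

Conditions are the cross of pathway (CA3 or EC, driven alone) and input-pair
similarity:

* ``distinct`` — input pairs at the chance-level (binomial-mean) Hamming
  distance, i.e. as different as two random patterns typically are;
* ``similar`` — input pairs at 2% of the maximal achievable distance.

For each pathway the pipeline calibrates the surrogate threshold, sweeps
activity levels, fits a Boltzmann curve and inverts it at the target CA1
spiking probability (default 0.14 per 20 ms gamma window); it then pushes
20 input pairs per condition through the network and summarizes the output
Hamming distances against the analytic chance level.

The default ("desk") scale runs a 500-cell CA1 patch in seconds while
preserving the full-scale structure: the CA3-like pathway has more synapses
per cell and a much larger fan-out than the EC-like pathway, and activity
levels sit near 5-7%.  The "paper" scale exists to emit analytic reference
numbers for the full-size populations; running the simulation at that scale
with a compartmental neuron backend is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from .connectivity import PathwaySpec, ProjectionMap, build_projection
from .hd_analysis import (
    HDStats,
    HDSummary,
    binomial_hd_stats,
    empirical_hd_summary,
    normal_approx_pdf,
)
from .patterns import (
    BinaryPattern,
    PatternPair,
    distinct_hd,
    max_hd,
    pair_with_hd,
    similar_hd,
    write_patterns,
    write_pair_manifest,
)
from .response_models import ThresholdSurrogate, population_response

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "ConditionResult",
    "PathwayCalibration",
    "ConfigError",
    "PAPER_SCALE",
    "REFERENCE_BIOPHYSICAL",
    "make_desk_config",
    "make_paper_config",
    "run_experiment",
    "report",
    "write_result",
    "load_provenance",
]

CONDITIONS = ("distinct", "similar")

#: Full-scale population parameters: a 1 mm^2 CA1 patch of 23,500 principal
#: cells, 28,009 CA3 afferents (4407 slots/cell, fan-out 3697) and 45,073 EC
#: afferents (1918 slots/cell, fan-out 1000); operating activities 5.50% and
#: 6.85% give the 0.14 CA1 spiking probability.
PAPER_SCALE = {
    "n_post": 23500,
    "pathways": {
        "CA3": PathwaySpec(name="CA3", n_pre=28009, synapses_per_post=4407, fanout=3697),
        "EC": PathwaySpec(name="EC", n_pre=45073, synapses_per_post=1918, fanout=1000),
    },
    "nominal_activity": {"CA3": 0.0550, "EC": 0.0685},
    "p_target": 0.14,
}

#: Output statistics reported for the full-scale simulations with the
#: 1330-compartment biophysical CA1 model that this surrogate pipeline
#: mirrors.  Kept for comparison tables only — the threshold surrogate is
#: not expected to reproduce them quantitatively.
REFERENCE_BIOPHYSICAL = {
    ("CA3", "distinct"): {"mean_hd": 5688, "sd_hd": 56, "mean_spikes": 3316, "sd_spikes": 52},
    ("EC", "distinct"): {"mean_hd": 5696, "sd_hd": 63, "mean_spikes": 3313, "sd_spikes": 56},
    ("CA3", "similar"): {"mean_hd": 2931, "sd_hd": 50, "mean_spikes": 3296, "sd_spikes": 43},
    ("EC", "similar"): {"mean_hd": 4315, "sd_hd": 63, "mean_spikes": 3307, "sd_spikes": 52},
}


class ConfigError(ValueError):
    """Invalid or infeasible experiment configuration."""


@dataclass(frozen=True)
class ExperimentConfig:
    n_post: int
    pathways: dict
    nominal_activity: dict
    seeds: dict
    p_target: float = 0.14
    n_pairs_per_condition: int = 20
    similar_fraction: float = 0.02
    scale: str = "desk"
    sweep_n_levels: int = 11
    sweep_n_patterns: int = 200
    calib_n_patterns: int = 50
    weight_distribution: tuple = ("lognormal", 0.0, 0.5)

    def validate(self) -> None:
        if not 0 < self.p_target < 1:
            raise ConfigError(f"p_target={self.p_target} outside (0, 1)")
        if not 0 < self.similar_fraction <= 1:
            raise ConfigError(f"similar_fraction={self.similar_fraction} outside (0, 1]")
        if self.n_pairs_per_condition < 2:
            raise ConfigError("need at least 2 pairs per condition")
        for key in ("connectivity", "weights", "patterns"):
            if key not in self.seeds:
                raise ConfigError(f"missing seed {key!r}")
        if set(self.pathways) != set(self.nominal_activity):
            raise ConfigError("pathways and nominal_activity keys differ")
        for name, spec in self.pathways.items():
            try:
                spec.check_consistency(self.n_post)
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc
            k = cal.active_count_at(self.nominal_activity[name], spec.n_pre)
            if not 0 < k < spec.n_pre:
                raise ConfigError(f"{name}: nominal activity gives k={k}")
            if similar_hd(spec.n_pre, k, self.similar_fraction) > max_hd(spec.n_pre, k):
                raise ConfigError(f"{name}: similar-pair HD exceeds the maximum")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pathways"] = {k: asdict(v) for k, v in self.pathways.items()}
        d["weight_distribution"] = list(self.weight_distribution)
        return d


def _spawn_seeds(seed: int) -> dict:
    state = np.random.SeedSequence(seed).generate_state(3)
    return {
        "connectivity": int(state[0] % (2**31)),
        "weights": int(state[1] % (2**31)),
        "patterns": int(state[2] % (2**31)),
    }


def make_desk_config(seed: int = 0) -> ExperimentConfig:
    """Scaled study conditions that preserve the full-scale structure.

    500 CA1 cells; CA3-like pathway n_pre=600 with 90 slots/cell (fan-out
    75), EC-like pathway n_pre=1000 with 40 slots/cell (fan-out 20) — so, as
    at full scale, the CA3 route has the larger synapse count and the much
    larger fan-out — with operating activities near 5-7%.
    """
    return ExperimentConfig(
        n_post=500,
        pathways={
            "CA3": PathwaySpec(name="CA3", n_pre=600, synapses_per_post=90, fanout=75),
            "EC": PathwaySpec(name="EC", n_pre=1000, synapses_per_post=40, fanout=20),
        },
        nominal_activity={"CA3": 0.0550, "EC": 0.0685},
        seeds=_spawn_seeds(seed),
        scale="desk",
    )


def make_paper_config(seed: int = 0) -> ExperimentConfig:
    """Full-scale parameterization; for analytic reference numbers only."""
    return ExperimentConfig(
        n_post=PAPER_SCALE["n_post"],
        pathways=dict(PAPER_SCALE["pathways"]),
        nominal_activity=dict(PAPER_SCALE["nominal_activity"]),
        seeds=_spawn_seeds(seed),
        scale="paper",
    )


@dataclass(frozen=True)
class PathwayCalibration:
    pathway: str
    theta: float
    achieved_at_nominal: float
    fit: cal.BoltzmannFit
    operating_activity: float
    k_operating: int
    sweep: cal.ActivitySweep


@dataclass(frozen=True)
class ConditionResult:
    pathway: str
    condition: str
    target_input_hd: int
    input_pairs: list
    output_pairs: list
    summary: HDSummary
    analytic_target: HDStats
    analytic_realized: HDStats
    mean_output_k: float
    sd_output_k: float

    @property
    def output_fraction(self) -> float:
        return self.mean_output_k / self.analytic_target.n

    @property
    def separation_ratio(self) -> float:
        """Empirical mean output HD relative to the chance-level mean at the
        realized output activity; 1 means no retained similarity."""
        return self.summary.mean / self.analytic_realized.mean_hd


@dataclass(frozen=True)
class ExperimentResult:
    config: ExperimentConfig
    calibrations: dict
    conditions: dict  # (pathway, condition) -> ConditionResult


def _sweep_levels(nominal: float, n_levels: int) -> np.ndarray:
    """Geometric grid bracketing the operating region around the nominal
    activity.  The grid is deliberately local (0.8-1.3x nominal): the
    Boltzmann form is only an approximation to the network's activation
    curve, and fitting it far into the tails biases the inversion at the
    target probability (see the methods note)."""
    hi = min(1.3 * nominal, 0.9)
    return np.geomspace(0.8 * nominal, hi, n_levels)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run calibration plus the four conditions; reproducible from the seeds."""
    config.validate()
    rng_conn = np.random.default_rng(config.seeds["connectivity"])
    rng_pat = np.random.default_rng(config.seeds["patterns"])
    weight_seeds = {
        name: int(
            np.random.SeedSequence(config.seeds["weights"], spawn_key=(i,))
            .generate_state(1)[0] % (2**31)
        )
        for i, name in enumerate(sorted(config.pathways))
    }

    maps: dict[str, ProjectionMap] = {}
    models: dict[str, ThresholdSurrogate] = {}
    calibrations: dict[str, PathwayCalibration] = {}
    for name in sorted(config.pathways):
        spec = config.pathways[name]
        pmap = build_projection(spec, config.n_post, rng_conn)
        model = ThresholdSurrogate(
            pathway_shapes={name: (config.n_post, spec.synapses_per_post)},
            weight_distribution=config.weight_distribution,
            seed=weight_seeds[name],
        )
        nominal = config.nominal_activity[name]
        calres = cal.calibrate_threshold(
            model, pmap, nominal, config.p_target, rng_pat,
            n_patterns=config.calib_n_patterns,
        )
        sw = cal.sweep(
            model, pmap, _sweep_levels(nominal, config.sweep_n_levels),
            config.sweep_n_patterns, rng_pat,
        )
        fit = cal.fit_boltzmann(sw)
        p_op = cal.invert_for_target(fit, config.p_target)
        k_op = cal.active_count_at(p_op, spec.n_pre)
        maps[name] = pmap
        models[name] = model
        calibrations[name] = PathwayCalibration(
            pathway=name, theta=calres.theta, achieved_at_nominal=calres.achieved,
            fit=fit, operating_activity=p_op, k_operating=k_op, sweep=sw,
        )

    conditions: dict[tuple, ConditionResult] = {}
    for name in sorted(config.pathways):
        spec = config.pathways[name]
        k_op = calibrations[name].k_operating
        targets = {
            "distinct": distinct_hd(spec.n_pre, k_op),
            "similar": similar_hd(spec.n_pre, k_op, config.similar_fraction),
        }
        for condition in CONDITIONS:
            d = targets[condition]
            pairs, outputs = [], []
            for _ in range(config.n_pairs_per_condition):
                pair = pair_with_hd(spec.n_pre, k_op, d, rng_pat, condition=condition)
                out_a = population_response(models[name], {name: maps[name]}, {name: pair.a})
                out_b = population_response(models[name], {name: maps[name]}, {name: pair.b})
                pairs.append(pair)
                outputs.append((out_a, out_b))
            summary = empirical_hd_summary(outputs)
            ks = np.array([o.k for pair_out in outputs for o in pair_out], dtype=float)
            realized_p = float(ks.mean()) / config.n_post
            conditions[(name, condition)] = ConditionResult(
                pathway=name,
                condition=condition,
                target_input_hd=d,
                input_pairs=pairs,
                output_pairs=outputs,
                summary=summary,
                analytic_target=binomial_hd_stats(config.n_post, config.p_target),
                analytic_realized=binomial_hd_stats(config.n_post, realized_p),
                mean_output_k=float(ks.mean()),
                sd_output_k=float(ks.std(ddof=1)),
            )
    return ExperimentResult(config=config, calibrations=calibrations, conditions=conditions)


def report(result: ExperimentResult) -> pd.DataFrame:
    """Condition table: empirical vs analytic output-HD statistics.

    Raises on an incomplete result (a missing pathway x condition cell).
    """
    expected = {(p, c) for p in result.config.pathways for c in CONDITIONS}
    missing = expected - set(result.conditions)
    if missing:
        raise ValueError(f"incomplete result: missing conditions {sorted(missing)}")
    rows = []
    for (pathway, condition), cr in sorted(result.conditions.items()):
        rows.append({
            "pathway": pathway,
            "condition": condition,
            "n_pairs": cr.summary.n_pairs,
            "target_input_hd": cr.target_input_hd,
            "mean_hd": cr.summary.mean,
            "sd_hd": cr.summary.sd,
            "analytic_mean": cr.analytic_realized.mean_hd,
            "analytic_sd": cr.analytic_realized.sd_hd,
            "separation_ratio": cr.separation_ratio,
            "mean_output_spikes": cr.mean_output_k,
            "sd_output_spikes": cr.sd_output_k,
            "output_fraction": cr.output_fraction,
        })
    return pd.DataFrame(rows)


def write_result(result: ExperimentResult, outdir) -> None:
    """Write the summary table, per-condition artifacts and provenance JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = report(result)
    df.to_csv(outdir / "summary.csv", index=False)

    pat_dir = outdir / "patterns"
    pat_dir.mkdir(exist_ok=True)
    for (pathway, condition), cr in sorted(result.conditions.items()):
        stem = f"{pathway}_{condition}"
        write_patterns(pat_dir / f"{stem}_in_a.txt", [p.a for p in cr.input_pairs])
        write_patterns(pat_dir / f"{stem}_in_b.txt", [p.b for p in cr.input_pairs])
        write_patterns(pat_dir / f"{stem}_out_a.txt", [a for a, _ in cr.output_pairs])
        write_patterns(pat_dir / f"{stem}_out_b.txt", [b for _, b in cr.output_pairs])
        write_pair_manifest(
            pat_dir / f"{stem}_pairs.csv",
            [
                {
                    "pair_id": i,
                    "condition": condition,
                    "file_a": f"{stem}_in_a.txt",
                    "file_b": f"{stem}_in_b.txt",
                    "target_hd": cr.target_input_hd,
                    "realized_hd": p.realized_hd,
                    "seed": result.config.seeds["patterns"],
                }
                for i, p in enumerate(cr.input_pairs)
            ],
        )
        # histogram with the chance-level normal overlay
        centers = 0.5 * (cr.summary.bin_edges[:-1] + cr.summary.bin_edges[1:])
        dens = normal_approx_pdf(cr.analytic_realized).pdf(centers)
        pd.DataFrame({
            "bin_left": cr.summary.bin_edges[:-1],
            "bin_right": cr.summary.bin_edges[1:],
            "count": cr.summary.counts,
            "normal_density": dens,
        }).to_csv(outdir / f"{stem}_hist.csv", index=False)

    provenance = {
        "config": result.config.to_dict(),
        "calibration": {
            name: {
                "theta": c.theta,
                "achieved_at_nominal": c.achieved_at_nominal,
                "x_half": c.fit.x_half,
                "slope": c.fit.slope,
                "operating_activity": c.operating_activity,
                "k_operating": c.k_operating,
            }
            for name, c in sorted(result.calibrations.items())
        },
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))


def load_provenance(path) -> dict:
    return json.loads(Path(path).read_text())
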