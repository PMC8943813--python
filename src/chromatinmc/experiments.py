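"""End-to-end in-silico experiment plans.

A plan runs a list of variants of one chromatin region — nucleosome
removal counts, internucleosomal interaction strengths (E_max), H1
binding modes — through the full pipeline: build chain, simulated
annealing, (replica-exchange) Monte Carlo, equilibration and thinning,
marker-pair distances, cutoff, histogram and summary statistics, and an
optional constrained mixture fit of all variants against a target
distance dataset.  All artifacts are written with the config hash and
seeds for provenance, and identical plans reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .chain import NucleosomeGeometry, assign_h1, build_chain, initial_configuration
from .distances import (
    DistanceDataset,
    MarkerPair,
    apply_cutoff,
    fit_mixture,
    histogram,
    marker_distance,
    max_extension,
    summary_stats,
    write_distance_table,
)
from .forcefield import ForceField
from .regions import NucleosomeSet, OccupancyTrack, remove_lowest
from .sampler import (
    RunControl,
    TemperatureLadder,
    autocorrelation_time,
    equilibration_cut,
    optimize_ladder,
    replica_exchange_run,
    simulated_annealing,
    thin,
)

__all__ = ["Variant", "ExperimentPlan", "VariantResult", "run_experiment"]


@dataclass(frozen=True)
class Variant:
    """One condition: nucleosomes removed, E_max (kT), H1 binding mode."""

    label: str
    remove_k: int = 0
    emax: float = 4.0
    h1_mode: str | float = "none"   # "none" | "all" | fraction in [0, 1]

    def h1_fraction(self) -> float:
        if self.h1_mode == "none":
            return 0.0
        if self.h1_mode == "all":
            return 1.0
        frac = float(self.h1_mode)
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"invalid h1_mode {self.h1_mode!r}")
        return frac


@dataclass
class ExperimentPlan:
    """A set of variants sharing one topology source and one marker pair."""

    variants: list
    pair: MarkerPair
    control: RunControl = field(default_factory=RunControl)
    n_replicas: int = 1
    t_max: float = 2.0
    optimize_temperatures: bool = False
    bin_width_nm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("plan needs at least one variant")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentPlan":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        variants = [Variant(**v) for v in data.pop("variants")]
        pair = MarkerPair(**data.pop("pair"))
        control = RunControl(**data.pop("control", {}))
        return cls(variants=variants, pair=pair, control=control, **data)


@dataclass
class VariantResult:
    variant: Variant
    dataset: DistanceDataset
    summary: dict
    hist: object
    n_excluded: int
    trajectory: object


def _config_hash(plan: ExperimentPlan, ff: ForceField, geometry: NucleosomeGeometry) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(
        {"plan": dataclasses.asdict(plan), "ff": ff.describe(),
         "geometry": dataclasses.asdict(geometry)},
        default=enc, sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_experiment(
    plan: ExperimentPlan,
    ns: NucleosomeSet,
    ff: ForceField | None = None,
    geometry: NucleosomeGeometry | None = None,
    track: OccupancyTrack | None = None,
    target: DistanceDataset | None = None,
    out_dir=None,
) -> dict:
    """Run every variant of *plan* on nucleosome set *ns*.

    Returns a dict with per-variant :class:`VariantResult` objects and,
    if a *target* dataset is given, a mixture fit of all variant
    histograms against it.  Artifacts (distance tables, histograms,
    summaries, the plan report with config hash) are written under
    *out_dir* when given; a stage failure raises with a stage label and
    leaves earlier artifacts in place.
    """
    if ff is None:
        ff = ForceField()
    if geometry is None:
        geometry = NucleosomeGeometry()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(plan, ff, geometry)

    edges = np.arange(
        0.0, max_extension(plan.pair.span) + plan.bin_width_nm, plan.bin_width_nm
    )
    results: list[VariantResult] = []
    for iv, var in enumerate(plan.variants):
        stage = "build"
        try:
            ns_v = remove_lowest(ns, var.remove_k, track=track)
            h1 = assign_h1(
                len(ns_v), var.h1_fraction(), seed=plan.seed * 1000 + iv
            )
            topo = build_chain(ns_v, geometry, h1)
            ff_v = replace(ff, emax=var.emax)

            stage = "anneal"
            cfg0 = initial_configuration(topo, "straight")
            control = replace(plan.control, seed=plan.control.seed + 17 * iv)
            schedule = np.geomspace(control.annealing_from, 1.0, control.annealing_stages)
            moves = control.annealing_moves_per_stage or 20 * topo.n_segments
            cfg, moveset = simulated_annealing(
                cfg0, topo, ff_v, schedule, moves, seed=control.seed + 1
            )

            stage = "ladder"
            ladder = TemperatureLadder.geometric(1.0, plan.t_max, plan.n_replicas)
            if plan.optimize_temperatures and plan.n_replicas >= 3:
                pilot = replace(control, n_steps=max(control.n_steps // 10, 1))
                ladder = optimize_ladder(topo, ff_v, ladder, pilot, initial=cfg)

            stage = "sample"
            trajs = replica_exchange_run(
                topo, ff_v, ladder, control, initial=cfg, moveset=moveset
            )
            traj = trajs[0]  # target temperature

            stage = "equilibrate"
            try:
                cut = equilibration_cut(
                    traj.energy_total, traj.end_to_end,
                    override=control.equilibration_cut,
                )
            except ValueError:
                # short pilot-scale runs: fall back to a fixed 25% burn-in
                warnings.warn(
                    f"variant {var.label}: no stationary window detected; "
                    "discarding the first quarter of samples"
                )
                cut = len(traj) // 4
            traj_eq = traj.select(np.arange(cut, len(traj)))
            tau = control.thin_tau
            if tau is None:
                try:
                    tau = max(
                        autocorrelation_time(traj_eq.energy_total),
                        autocorrelation_time(traj_eq.end_to_end),
                    )
                except ValueError:
                    warnings.warn("autocorrelation estimate failed; thinning by 2")
                    tau = 2.0
            traj_thin = thin(traj_eq, tau)

            stage = "distances"
            from .chain import Configuration

            dists = np.array(
                [
                    marker_distance(
                        Configuration(pos, np.zeros((0, 3, 3))), topo, plan.pair
                    )
                    for pos in traj_thin.positions
                ]
            )
            ds = DistanceDataset(dists, "3D", "simulated", span_bp=plan.pair.span)
            ds, n_excl = apply_cutoff(ds)
            summary = summary_stats(ds)
            hist = histogram(ds, edges=edges)
        except Exception as exc:
            raise RuntimeError(f"[variant {var.label} / stage {stage}] {exc}") from exc

        results.append(VariantResult(var, ds, summary, hist, n_excl, traj_thin))
        if out is not None:
            vdir = out / var.label
            vdir.mkdir(exist_ok=True)
            write_distance_table(ds, vdir / "distances.tsv", pair_label=plan.pair.label)
            np.savetxt(
                vdir / "histogram.tsv",
                np.column_stack([hist.centers, hist.density]),
                header="center_nm\tdensity", delimiter="\t", comments="",
            )
            (vdir / "summary.json").write_text(
                json.dumps(
                    {**summary, "n_excluded": n_excl, "variant": var.label,
                     "config_hash": cfg_hash, "seed": control.seed},
                    indent=2,
                )
            )

    report: dict = {
        "config_hash": cfg_hash,
        "variants": {r.variant.label: r.summary for r in results},
    }
    mixture = None
    if target is not None:
        tgt_ds, _ = apply_cutoff(
            DistanceDataset(
                target.distances, target.dimensionality, target.source,
                target.span_bp or plan.pair.span,
            )
        )
        tgt_hist = histogram(tgt_ds, edges=edges)
        mixture = fit_mixture(tgt_hist, [r.hist for r in results])
        report["mixture"] = {
            "weights": {
                r.variant.label: float(w)
                for r, w in zip(results, mixture.weights)
            },
            "rmse": mixture.rmse,
        }
    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return {"results": results, "mixture": mixture, "report": report}
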