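"""End-to-end orchestration: simulate -> GLM -> PPI -> cluster -> decode -> edges.

A :class:`PipelineConfig` captures every stage's parameters and seeds and
round-trips through YAML. :func:`run_pipeline` executes the toggled
stages in dependency order on synthetic data, materializes intermediate
artifacts under a fixed run-directory layout (events/, maps/,
parcellation/, connectivity/, decoding/, edges/, report.json), and
captures stage failures in the report instead of aborting downstream
independent stages.
"""

from __future__ import annotations

import dataclasses
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from wmnet import io
from wmnet._version import __version__
from wmnet.clustering import cluster_axis, condition_average, purity
from wmnet.decoding import permutation_null
from wmnet.edges import fit_edge_mixed
from wmnet.glm import assemble_beta_stack
from wmnet.gppi import event_connectivity_stack
from wmnet.parcellation import watershed_3d
from wmnet.simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_design,
    simulate_roi_bold,
    simulate_statmap,
)
from wmnet.types import FeatureStack


@dataclass
class PipelineConfig:
    """Serializable configuration of a full synthetic run."""

    simulation: dict = field(
        default_factory=lambda: {"n_subjects": 8, "n_runs": 1, "n_rois": 6}
    )
    activation_scale: float = 1.5
    coupling_strength: float = 0.6
    n_coupled_edges: int = 4
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "glm": True,
            "parcellate": True,
            "ppi": True,
            "cluster": True,
            "decode": True,
            "edgemodel": True,
        }
    )
    cluster_threshold: float = 1.15
    cluster_depth: int = 5
    decode_label: str = "domain"
    n_partitions: int = 5
    n_bootstraps: int = 20
    edge_q: float = 0.05
    seed: int = 0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self)))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def sim_config(self) -> SimulationConfig:
        params = dict(self.simulation)
        params.setdefault("seed", self.seed)
        return SimulationConfig(**params)


def default_truth(cfg: PipelineConfig, sim: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    """Ground truth with domain-specific activation and domain x load coupling.

    Each domain level gets a distinct ROI activation pattern (so betas
    carry decodable domain information), and ``n_coupled_edges`` random
    edges receive maintenance-stage coupling that scales with load and
    differs by domain (so edge models have a true interaction to find).
    """
    n = sim.n_rois
    domains = sim.factors.get("domain", ["none"])
    loads = sorted(sim.factors.get("load", [0]))
    amplitudes = {}
    for d_idx, dom in enumerate(domains):
        pattern = rng.normal(scale=cfg.activation_scale, size=n)
        for stage in ("encode", "maintain", "probe"):
            amplitudes[f"{stage}:{dom}"] = pattern * {"encode": 1.0, "maintain": 0.8, "probe": 0.9}[stage]

    coupling = {}
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    order = rng.permutation(len(edges))
    chosen = [edges[i] for i in order[: cfg.n_coupled_edges]]
    for d_idx, dom in enumerate(domains):
        for l_idx, load in enumerate(loads):
            mat = np.zeros((n, n))
            gain = (1 + l_idx) / len(loads)
            for e_idx, (i, j) in enumerate(chosen):
                # domain-dependent scale makes the load effect non-additive
                scale = 1.0 if (e_idx + d_idx) % 2 == 0 else 0.25
                mat[i, j] = mat[j, i] = cfg.coupling_strength * gain * scale
            coupling[f"maintain:{dom}:{load}"] = mat
    return GroundTruth(activation_amplitudes=amplitudes, coupling=coupling)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the toggled stages and write a structured run report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": {},
        "metrics": {},
    }
    rng = np.random.default_rng(cfg.seed)
    cfg.to_yaml(out / "config.yaml")

    state: dict = {}

    def run_stage(name: str, fn, *deps: str) -> None:
        if not cfg.stages.get(name, True):
            report["stages"][name] = {"status": "skipped"}
            return
        for dep in deps:
            if report["stages"].get(dep, {}).get("status") != "ok":
                report["stages"][name] = {"status": "skipped", "reason": f"dependency {dep} not ok"}
                return
        t0 = time.perf_counter()
        try:
            fn()
            report["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
        except Exception as err:  # noqa: BLE001 - captured in report by design
            report["stages"][name] = {
                "status": "failed",
                "error": f"{type(err).__name__}: {err}",
                "traceback": traceback.format_exc(),
            }

    def stage_simulate() -> None:
        sim = cfg.sim_config()
        (out / "events").mkdir(exist_ok=True)
        events = simulate_design(sim)
        io.write_events_tsv(events, out / "events" / "events.tsv")
        truth = default_truth(cfg, sim, rng)
        runs = []
        for subj in sorted(events["subject"].unique()):
            for run in sorted(events.loc[events["subject"] == subj, "run"].unique()):
                sel = (events["subject"] == subj) & (events["run"] == run)
                ev = events.loc[sel].reset_index(drop=True)
                bold = simulate_roi_bold(ev, truth, sim, rng)
                runs.append((ev, bold))
        state["events"] = events
        state["truth"] = truth
        state["runs"] = runs

    def stage_glm() -> None:
        stack = assemble_beta_stack(state["runs"])
        io.write_stack(stack, out / "beta_stack")
        state["beta_stack"] = stack

    def stage_parcellate() -> None:
        (out / "parcellation").mkdir(exist_ok=True)
        blobs = [((8, 8, 8), 2.5, 6.0), ((20, 20, 20), 2.5, 5.0), ((8, 20, 14), 2.0, 5.0)]
        smap = simulate_statmap(blobs, shape=(28, 28, 28), noise_sd=0.2, seed=cfg.seed)
        mask = smap.data > 1.0
        parc = watershed_3d(smap, mask, min_size=50)
        io.write_nifti(parc.labels, out / "parcellation" / "labels.nii.gz")
        parc.roi_table.assign(
            centroid=parc.roi_table["centroid"].astype(str),
            peak_ijk=parc.roi_table["peak_ijk"].astype(str),
        ).to_csv(out / "parcellation" / "roi_table.tsv", sep="\t", index=False)
        report["metrics"]["parcellation_n_rois"] = parc.n_rois

    def stage_ppi() -> None:
        (out / "connectivity").mkdir(exist_ok=True)
        stacks = []
        for ev, bold in state["runs"]:
            stacks.append(event_connectivity_stack(bold, ev))
        edge_stack = FeatureStack(
            features=np.vstack([s.features for s in stacks]),
            meta=pd.concat([s.meta for s in stacks], ignore_index=True),
            kind="connectivity",
            feature_names=stacks[0].feature_names,
        )
        io.write_stack(edge_stack, out / "connectivity" / "edge_stack")
        state["edge_stack"] = edge_stack

    def stage_cluster() -> None:
        stack = state["beta_stack"]
        keep = stack.meta["stage"] != "cue"
        feats, cell_meta = condition_average(
            stack.features[keep.to_numpy()], stack.meta.loc[keep].reset_index(drop=True)
        )
        result = cluster_axis(feats, "rows", cfg.cluster_threshold, cfg.cluster_depth)
        pur = purity(result.labels, cell_meta["domain"].to_numpy())
        report["metrics"]["cluster_purity"] = pur
        report["metrics"]["n_clusters"] = result.n_clusters

    def stage_decode() -> None:
        (out / "decoding").mkdir(exist_ok=True)
        stack = state["beta_stack"]
        keep = (stack.meta["stage"] != "cue").to_numpy()
        sub = stack.select(keep)
        rep = permutation_null(
            sub,
            label=cfg.decode_label,
            n_partitions=cfg.n_partitions,
            n_bootstraps=cfg.n_bootstraps,
            seed=int(rng.integers(2**31)),
        )
        io.write_json(
            {
                "p": rep.p,
                "effect_size": rep.effect_size,
                "mean_observed_accuracy": float(rep.observed.mean()),
                "mean_null_accuracy": float(rep.null.mean()),
                "mean_observed_f1": float(rep.observed_f1.mean()),
            },
            out / "decoding" / "report.json",
        )
        report["metrics"]["decoding_p"] = rep.p
        report["metrics"]["decoding_accuracy"] = float(rep.observed.mean())
        report["metrics"]["decoding_null_accuracy"] = float(rep.null.mean())

    def stage_edgemodel() -> None:
        (out / "edges").mkdir(exist_ok=True)
        res = fit_edge_mixed(state["edge_stack"], q=cfg.edge_q)
        res.table.to_csv(out / "edges" / "edge_tests.tsv", sep="\t", index=False)
        report["metrics"]["edges_interaction_hits"] = int(
            res.masks.get("domain:load", np.zeros(0, bool)).sum()
        )
        report["metrics"]["edges_tested"] = len(res.edge_names)

    run_stage("simulate", stage_simulate)
    run_stage("glm", stage_glm, "simulate")
    run_stage("parcellate", stage_parcellate)
    run_stage("ppi", stage_ppi, "simulate")
    run_stage("cluster", stage_cluster, "glm")
    run_stage("decode", stage_decode, "glm")
    run_stage("edgemodel", stage_edgemodel, "ppi")

    io.write_json(report, out / "report.json")
    return report
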