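"""Synthetic factorial working-memory designs and BOLD data.

Emulates the two deposited study designs: Study 1 crosses three stimulus
domains (number, fractal, spatial) with three loads, two repeats per cell
per run (18 trials/run); Study 2 crosses manipulation (on/off), two
domains and two loads, two repeats (16 trials/run). Each trial unfolds as
cue -> encode -> maintain -> probe with 10 s stages (2 s cue) and a 10 s
inter-trial interval that serves as the implicit baseline.

ROI-level BOLD is generated with the same regression form the gPPI
estimator fits: a target series receives, per condition c and source s,
the term ``coupling[c][s, t] * (source ⊙ H(X_c))`` on top of
HRF-convolved activation, cosine drift, simulated motion nuisance and
white Gaussian noise — so estimators can be validated by parameter
recovery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wmnet.hrf import convolve_boxcar, sample_boxcar
from wmnet.types import BoldData, FeatureStack, StatMap, validate_events

_DEFAULT_FACTORS = {
    "domain": ["number", "fractal", "spatial"],
    "load": [3, 5, 7],
}

#: Stages modeled per trial, in presentation order.
_STAGE_ORDER = ("cue", "encode", "maintain", "probe")


@dataclass
class SimulationConfig:
    """Parameters of a synthetic factorial WM experiment.

    ``factors`` maps factor names to level lists (stage is implicit: every
    trial has cue/encode/maintain/probe). The seed fully determines every
    output drawn from the config.
    """

    n_subjects: int = 19
    n_runs: int = 3
    factors: dict = field(default_factory=lambda: dict(_DEFAULT_FACTORS))
    repeats_per_cell: int = 2
    stage_duration_s: float = 10.0
    iti_s: float = 10.0
    cue_duration_s: float = 2.0
    tr_s: float = 2.0
    n_rois: int = 8
    noise_sd: float = 1.0
    drift_amplitude: float = 0.5
    hrf_oversampling: int = 16
    study: str = "study1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stage_duration_s", "iti_s", "cue_duration_s", "tr_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        if self.n_subjects < 1 or self.n_runs < 1 or self.repeats_per_cell < 1:
            raise ValueError("counts must be >= 1")
        if not self.factors:
            raise ValueError("factors must be non-empty")
        for name, levels in self.factors.items():
            if not levels:
                raise ValueError(f"factor {name!r} has no levels")

    @property
    def trials_per_run(self) -> int:
        n_cells = int(np.prod([len(v) for v in self.factors.values()]))
        return n_cells * self.repeats_per_cell

    @property
    def trial_duration_s(self) -> float:
        return self.cue_duration_s + 3 * self.stage_duration_s + self.iti_s

    @property
    def run_duration_s(self) -> float:
        # trailing rest so the last HRF response is sampled
        return self.trials_per_run * self.trial_duration_s + 20.0

    @property
    def n_scans(self) -> int:
        return int(np.ceil(self.run_duration_s / self.tr_s))


def study1_config(**overrides) -> SimulationConfig:
    """3 domains x 3 loads, 2 repeats per cell: 18 trials per run."""
    cfg = dict(
        n_subjects=19,
        factors={"domain": ["number", "fractal", "spatial"], "load": [3, 5, 7]},
        study="study1",
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def study2_config(**overrides) -> SimulationConfig:
    """2 manipulation x 2 domains x 2 loads, 2 repeats: 16 trials per run."""
    cfg = dict(
        n_subjects=16,
        factors={
            "manipulation": [False, True],
            "domain": ["number", "spatial"],
            "load": [3, 6],
        },
        study="study2",
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


@dataclass
class GroundTruth:
    """Known generative parameters for recovery testing.

    ``activation_amplitudes`` maps condition -> length-n_rois amplitude
    vector; ``coupling`` maps condition -> ROI x ROI matrix whose (s, t)
    entry is the interaction coefficient carrying source s into target t
    during that condition (zero diagonal). ``class_effect_size`` and
    ``load_gain`` parameterize feature-stack generation: between-class
    centroid separation in noise-sd units, and the multiplicative gain of
    that separation from lowest to highest load.
    """

    activation_amplitudes: dict = field(default_factory=dict)
    coupling: dict = field(default_factory=dict)
    class_effect_size: float = 1.0
    load_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.load_gain <= 0:
            raise ValueError("load_gain must be > 0")
        if self.class_effect_size < 0:
            raise ValueError("class_effect_size must be >= 0")
        for cond, mat in self.coupling.items():
            mat = np.asarray(mat, dtype=float)
            if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
                raise ValueError(f"coupling[{cond!r}] must be square")
            if np.any(np.diag(mat) != 0):
                raise ValueError(f"coupling[{cond!r}] must have zero diagonal")
            self.coupling[cond] = mat


def simulate_design(config: SimulationConfig) -> pd.DataFrame:
    """Pseudo-randomized factorial events table.

    Each factorial cell appears exactly ``repeats_per_cell`` times per
    run; trial order is a uniform shuffle under the config seed. Every
    trial expands to one row per stage with onsets/durations implied by
    the stage timing parameters.
    """
    rng = np.random.default_rng(config.seed)
    factor_names = list(config.factors)
    cells = list(itertools.product(*config.factors.values()))
    rows = []
    stage_durs = {
        "cue": config.cue_duration_s,
        "encode": config.stage_duration_s,
        "maintain": config.stage_duration_s,
        "probe": config.stage_duration_s,
    }
    for subj in range(config.n_subjects):
        for run in range(config.n_runs):
            trial_cells = cells * config.repeats_per_cell
            order = rng.permutation(len(trial_cells))
            t = 0.0
            for trial_idx, cell_idx in enumerate(order):
                cell = dict(zip(factor_names, trial_cells[cell_idx]))
                onset = t
                for stage in _STAGE_ORDER:
                    rows.append(
                        {
                            "onset": onset,
                            "duration": stage_durs[stage],
                            "subject": f"sub{subj:02d}",
                            "run": run,
                            "study": config.study,
                            "trial": trial_idx,
                            "stage": stage,
                            "domain": cell.get("domain", "none"),
                            "load": cell.get("load", 0),
                            "manipulation": bool(cell.get("manipulation", False)),
                        }
                    )
                    onset += stage_durs[stage]
                t += config.trial_duration_s
    events = pd.DataFrame(rows)
    return validate_events(events)


def simulate_nuisance(
    n_scans: int, rng: np.random.Generator, amplitude: float = 0.1
) -> np.ndarray:
    """Six slow random-walk 'motion' traces, standardized, scaled by amplitude."""
    steps = rng.normal(scale=1.0, size=(n_scans, 6))
    walk = np.cumsum(steps, axis=0)
    walk -= walk.mean(axis=0)
    sd = walk.std(axis=0)
    sd[sd == 0] = 1.0
    return amplitude * walk / sd


def _condition_mask(events: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Rows of ``events`` belonging to a condition label.

    A condition is a stage name ("maintain"), a factor level
    ("spatial"), a stage:level compound ("maintain:spatial"), or a
    stage:level:level cell ("maintain:spatial:7").
    """
    if ":" in condition:
        stage, *levels = condition.split(":")
        sel = events["stage"] == stage
        for level in levels:
            sel &= (
                (events["domain"].astype(str) == level)
                | (events["load"].astype(str) == level)
            )
    elif condition in set(events["stage"]):
        sel = events["stage"] == condition
    else:
        sel = (events["domain"].astype(str) == condition) | (
            events["load"].astype(str) == condition
        )
        # exclude cue rows from factor-level conditions: the cue precedes
        # domain-specific processing
        sel &= events["stage"] != "cue"
    sub = events.loc[sel]
    if sub.empty:
        raise ValueError(f"condition {condition!r} matches no events")
    return sub


def condition_regressors(
    events: pd.DataFrame,
    conditions: list[str],
    n_scans: int,
    tr: float,
    oversampling: int = 16,
    convolved: bool = True,
) -> np.ndarray:
    """scans x conditions matrix of (optionally HRF-convolved) boxcars."""
    cols = []
    for cond in conditions:
        sub = _condition_mask(events, cond)
        fn = convolve_boxcar if convolved else sample_boxcar
        cols.append(
            fn(
                sub["onset"].to_numpy(),
                sub["duration"].to_numpy(),
                n_scans,
                tr,
                oversampling,
            )
        )
    return np.column_stack(cols)


def simulate_roi_bold(
    events: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> BoldData:
    """Generate one run of ROI-level BOLD under known coupling.

    The generative model mirrors the gPPI regression: each target t
    receives ``sum_c sum_s coupling[c][s, t] * (base_s ⊙ H(X_c))`` where
    ``base_s`` is source s's pre-coupling series (activation + drift +
    noise). Returns BoldData with the nuisance matrix attached.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_scans = config.n_scans
    n_rois = config.n_rois
    tr = config.tr_s

    conditions = sorted(set(truth.activation_amplitudes) | set(truth.coupling))
    for cond, mat in truth.coupling.items():
        if np.asarray(mat).shape != (n_rois, n_rois):
            raise ValueError(
                f"coupling[{cond!r}] shaped {np.asarray(mat).shape}, "
                f"expected ({n_rois}, {n_rois})"
            )

    hx = {}
    for cond in conditions:
        hx[cond] = condition_regressors(
            events, [cond], n_scans, tr, config.hrf_oversampling
        )[:, 0]

    # base (pre-coupling) series: activation + drift + noise
    base = np.zeros((n_scans, n_rois))
    for cond, amps in truth.activation_amplitudes.items():
        amps = np.asarray(amps, dtype=float)
        if amps.shape != (n_rois,):
            raise ValueError(f"activation_amplitudes[{cond!r}] must have length n_rois")
        base += np.outer(hx[cond], amps)
    t = np.arange(n_scans) * tr
    drift_phase = rng.uniform(0, 2 * np.pi, size=n_rois)
    drift_period = config.run_duration_s  # slower than the high-pass cutoff
    base += config.drift_amplitude * np.cos(
        2 * np.pi * t[:, None] / drift_period + drift_phase[None, :]
    )
    base += rng.normal(scale=config.noise_sd, size=(n_scans, n_rois))

    # coupling: targets receive source ⊙ H(X_c) terms from base series
    data = base.copy()
    for cond, mat in truth.coupling.items():
        mod = hx[cond][:, None] * base  # scans x sources
        data += mod @ mat

    nuis = simulate_nuisance(n_scans, rng)
    return BoldData(data=data, tr=tr, nuisance=nuis)


def simulate_statmap(
    blobs: list[tuple[tuple[float, float, float], float, float]],
    shape: tuple[int, int, int] = (24, 24, 24),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> StatMap:
    """Sum of 3-D Gaussian bumps plus optional white noise.

    ``blobs`` is a list of (center, width, amplitude); width is the
    Gaussian sigma in voxels. The mask covers the full volume.
    """
    rng = np.random.default_rng(seed)
    vol = np.zeros(shape)
    grid = np.indices(shape).astype(float)
    for center, width, amplitude in blobs:
        center = np.asarray(center, dtype=float)
        if width <= 0:
            raise ValueError("blob width must be > 0")
        if np.any(center < 0) or np.any(center >= np.asarray(shape)):
            raise ValueError(f"blob center {center} outside volume {shape}")
        d2 = sum((grid[i] - center[i]) ** 2 for i in range(3))
        vol += amplitude * np.exp(-d2 / (2 * width**2))
    if noise_sd > 0:
        vol += rng.normal(scale=noise_sd, size=shape)
    return StatMap(data=vol)


def simulate_feature_stack(
    n_events_per_class: int = 24,
    n_features: int = 20,
    classes: tuple[str, ...] = ("number", "fractal", "spatial"),
    effect_size: float = 1.0,
    load_gain: float = 1.0,
    stage_specific: bool = False,
    n_subjects: int = 12,
    loads: tuple = (3, 5, 7),
    stages: tuple[str, ...] = ("encode", "maintain", "probe"),
    subject_sd: float = 0.25,
    seed: int = 0,
    label_factor: str = "domain",
) -> tuple[FeatureStack, GroundTruth]:
    """Class-conditional Gaussian feature stack with known structure.

    Between-class centroid separation equals ``effect_size`` (in units of
    the unit noise sd) at the lowest load and ``effect_size * load_gain``
    at the highest; intermediate loads interpolate geometrically. With
    ``stage_specific``, half of the class pattern variance is shared
    across stages and half is stage-unique, so a stage-trained decoder
    transfers imperfectly to other stages.
    """
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    rng = np.random.default_rng(seed)

    n_classes = len(classes)
    n_loads = len(loads)
    # orthonormal class directions (shared and per-stage sets)
    needed = n_classes * (1 + len(stages))
    if n_features < needed:
        dirs = rng.normal(size=(needed, n_features))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    else:
        dirs = np.zeros((needed, n_features))
        dirs[np.arange(needed), np.arange(needed)] = 1.0
    shared_dirs = dirs[:n_classes]
    stage_dirs = {
        st: dirs[n_classes * (i + 1) : n_classes * (i + 2)]
        for i, st in enumerate(stages)
    }

    subj_ids = [f"sub{i:02d}" for i in range(n_subjects)]
    subj_offsets = rng.normal(scale=subject_sd, size=(n_subjects, n_features))

    rows, feats = [], []
    for ci, cls in enumerate(classes):
        for ev in range(n_events_per_class):
            # mixed-radix assignment crosses subject, load and stage
            subj = ev % n_subjects
            load = loads[(ev // n_subjects) % n_loads]
            stage = stages[(ev // (n_subjects * n_loads)) % len(stages)]
            load_idx = loads.index(load)
            gain = load_gain ** (load_idx / max(n_loads - 1, 1))
            # centroid separation between orthogonal class means m*sqrt(2) = effect
            scale = effect_size * gain / np.sqrt(2)
            if stage_specific:
                mean = scale * (
                    shared_dirs[ci] / np.sqrt(2)
                    + stage_dirs[stage][ci] / np.sqrt(2)
                )
            else:
                mean = scale * shared_dirs[ci]
            x = mean + subj_offsets[subj] + rng.normal(size=n_features)
            feats.append(x)
            rows.append(
                {
                    "subject": subj_ids[subj],
                    "study": "synthetic",
                    "run": ev % 3,
                    "trial": ev,
                    "stage": stage,
                    "domain": cls if label_factor == "domain" else "none",
                    "load": load,
                    "manipulation": False,
                    "label": cls,
                }
            )
    meta = pd.DataFrame(rows)
    order = rng.permutation(len(meta))
    stack = FeatureStack(
        features=np.asarray(feats)[order],
        meta=meta.iloc[order].reset_index(drop=True),
        kind="activity",
    )
    truth = GroundTruth(class_effect_size=effect_size, load_gain=load_gain)
    return stack, truth
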