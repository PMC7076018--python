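"""Synthetic BOLD cohort generator with planted ground truth.

Emulates the ingredients of a blocked emotional-face paradigm at desk scale:

* resting runs whose latent signals follow a block-structured covariance
  (``within_module_corr`` inside each planted module, ``between_module_corr``
  elsewhere), so that a consensus clustering of partial correlations can be
  scored against the planted partition;
* a blocked two-condition task design (21 s blocks of six 2 s trials with 1 s
  inter-trial intervals and a 3 s cue, two sessions of 176 volumes at
  TR = 0.72 s);
* task sessions in which chosen directed edges gain a multiplicative
  seed-by-condition coupling at the latent ("neural") level before HRF
  convolution — the quantity a generalized psychophysiological-interaction
  regression estimates — plus per-module mean activation for the emotion
  condition;
* AR(1) observation noise, slow cosine drift, and motion-like nuisance
  signals (smooth random walks) that leak into the data with small random
  loadings.

Everything is driven by integer seeds and is bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .core import Partition, RoiTimeSeries, TaskDesign
from .hrf import HRF, boxcar

__all__ = [
    "SynthConfig", "GroundTruth", "generate_task_design",
    "generate_rest_timeseries", "generate_task_timeseries",
    "subject_seeds", "write_cohort",
]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Defaults follow the acquisition constants of the emulated paradigm
    (TR 0.72 s, 176 task volumes per session, two sessions, 1200 resting
    volumes per run, two concatenated resting runs) at a desk-scale network
    size of 60 nodes in 6 equal modules.
    """

    n_nodes: int = 60
    n_modules: int = 6
    module_sizes: tuple = None
    within_module_corr: float = 0.5
    between_module_corr: float = 0.0
    n_subjects: int = 50
    tr: float = 0.72
    rest_volumes_per_run: int = 1200
    n_rest_runs: int = 2
    task_volumes_per_session: int = 176
    n_sessions: int = 2
    ppi_edges: tuple = ()          # (seed, target, condition, gamma)
    ar_coefficient: float = 0.3
    noise_std: float = 0.2
    drift_amplitude: float = 0.2
    motion_amplitude: float = 0.5
    activation_effects: dict = field(default_factory=dict)  # module -> amplitude
    hrf: HRF = field(default_factory=HRF)
    seed: int = 0

    def __post_init__(self):
        if self.module_sizes is None:
            base, extra = divmod(self.n_nodes, self.n_modules)
            self.module_sizes = tuple(
                base + (1 if i < extra else 0) for i in range(self.n_modules))
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        if sum(self.module_sizes) != self.n_nodes:
            raise ValueError("module_sizes must sum to n_nodes")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if not (-1 < self.ar_coefficient < 1):
            raise ValueError("|ar_coefficient| must be < 1")
        if not (0 <= self.within_module_corr < 1):
            raise ValueError("within_module_corr must be in [0, 1)")
        if self.within_module_corr <= self.between_module_corr:
            raise ValueError(
                "within_module_corr must exceed between_module_corr "
                "(planted modularity must be recoverable)")
        for e in self.ppi_edges:
            s, t, cond, gamma = e
            if not np.isfinite(gamma):
                raise ValueError(f"non-finite effect size in ppi edge {e}")
            if s == t:
                raise ValueError(f"self-loop ppi edge {e}")
            if not (0 <= s < self.n_nodes and 0 <= t < self.n_nodes):
                raise ValueError(f"ppi edge {e} references out-of-range node")

    @property
    def true_labels(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_modules), self.module_sizes)

    def covariance(self) -> np.ndarray:
        """Implied latent covariance; raises if not positive definite."""
        lab = self.true_labels
        same = lab[:, None] == lab[None, :]
        cov = np.where(same, self.within_module_corr, self.between_module_corr)
        np.fill_diagonal(cov, 1.0)
        return cov

    def _cholesky(self) -> np.ndarray:
        try:
            return np.linalg.cholesky(self.covariance())
        except np.linalg.LinAlgError as err:
            raise ValueError(
                "implied latent covariance is not positive definite") from err


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    true_partition: Partition
    true_ppi_edges: tuple
    true_active_modules: dict
    generator_seed: int

    @classmethod
    def from_config(cls, cfg: SynthConfig) -> "GroundTruth":
        return cls(true_partition=Partition(labels=cfg.true_labels),
                   true_ppi_edges=tuple(cfg.ppi_edges),
                   true_active_modules=dict(cfg.activation_effects),
                   generator_seed=cfg.seed)

    def to_json(self) -> str:
        return json.dumps({
            "true_partition": self.true_partition.labels.tolist(),
            "true_ppi_edges": [list(e) for e in self.true_ppi_edges],
            "true_active_modules": {str(k): v for k, v in
                                    self.true_active_modules.items()},
            "generator_seed": self.generator_seed,
        }, indent=1)


def generate_task_design(tr: float = 0.72, n_volumes: int = 176,
                         block_s: float = 21.0, trial_s: float = 2.0,
                         iti_s: float = 1.0, cue_s: float = 3.0,
                         fix_s: float = 0.0, blocks_per_condition: int = 3,
                         n_sessions: int = 2,
                         conditions: tuple = ("emotion", "shape")) -> TaskDesign:
    """Alternating blocked two-condition design.

    Each block spans ``block_s`` seconds starting with a ``cue_s`` cue
    followed by trials of ``trial_s`` with ``iti_s`` gaps; consecutive blocks
    are spaced by ``fix_s`` of fixation. One row per block is emitted with the
    onset at the cue and the full block duration (cue handling is decided at
    design-matrix construction). Raises when the sequence does not fit the
    session, naming the overrun in seconds.
    """
    for name, v in [("tr", tr), ("block_s", block_s), ("trial_s", trial_s)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if iti_s < 0 or cue_s < 0 or fix_s < 0:
        raise ValueError("durations must be non-negative")
    if blocks_per_condition == 0:
        warnings.warn("blocks_per_condition=0: empty design")
        return TaskDesign(table=pd.DataFrame(
            columns=["session", "condition", "onset", "duration"]),
            tr=tr, n_volumes=n_volumes, conditions=conditions)
    n_trials = (block_s - cue_s) / (trial_s + iti_s)
    if abs(n_trials - round(n_trials)) > 1e-9:
        warnings.warn(
            f"block_s={block_s} does not evenly tile cue + trials "
            f"({n_trials:.2f} trials)")
    rows = []
    for sess in range(1, n_sessions + 1):
        t = 0.0
        for b in range(2 * blocks_per_condition):
            cond = conditions[b % len(conditions)]
            rows.append({"session": sess, "condition": cond,
                         "onset": t, "duration": block_s})
            t += block_s
            if b < 2 * blocks_per_condition - 1:
                t += fix_s
    table = pd.DataFrame(rows)
    scan_s = n_volumes * tr
    end = (table["onset"] + table["duration"]).max()
    if end > scan_s + 1e-9:
        raise ValueError(
            f"design exceeds scan duration by {end - scan_s:.2f} s "
            f"(needs {end:.2f} s, scan is {scan_s:.2f} s)")
    return TaskDesign(table=table, tr=tr, n_volumes=n_volumes,
                      conditions=conditions)


def _ar1_noise(rng: np.random.Generator, shape, rho: float, std: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``std``."""
    white = rng.standard_normal(shape) * std * np.sqrt(max(1 - rho ** 2, 1e-12))
    return sp_signal.lfilter([1.0], [1.0, -rho], white, axis=0)


def _drift(rng: np.random.Generator, n: int, n_nodes: int, tr: float,
           amplitude: float) -> np.ndarray:
    """Slow cosine drift per node, periods 250-1000 s (outside every passband
    used downstream)."""
    t = np.arange(n) * tr
    freqs = rng.uniform(1 / 1000.0, 1 / 250.0, size=n_nodes)
    phases = rng.uniform(0, 2 * np.pi, size=n_nodes)
    return amplitude * np.cos(2 * np.pi * t[:, None] * freqs[None, :]
                              + phases[None, :])


def _motion(rng: np.random.Generator, n: int, amplitude: float,
            n_params: int = 6) -> np.ndarray:
    """Motion-like smooth random walks, scaled to the requested amplitude."""
    steps = rng.standard_normal((n, n_params))
    walk = np.cumsum(steps, axis=0)
    walk -= walk.mean(axis=0)
    sd = walk.std(axis=0)
    sd[sd == 0] = 1.0
    return amplitude * walk / sd


def generate_rest_timeseries(cfg: SynthConfig, subject_seed: int) -> RoiTimeSeries:
    """Resting runs: block-covariance latents + AR(1) noise + drift.

    ``n_rest_runs`` runs of ``rest_volumes_per_run`` volumes are generated
    independently and concatenated, mirroring the concatenation of opposing
    encoding directions in the emulated acquisition.
    """
    chol = cfg._cholesky()
    rng = np.random.default_rng(subject_seed)
    runs = []
    labels = []
    for run in range(cfg.n_rest_runs):
        T = cfg.rest_volumes_per_run
        latent = rng.standard_normal((T, cfg.n_nodes)) @ chol.T
        noise = _ar1_noise(rng, (T, cfg.n_nodes), cfg.ar_coefficient, cfg.noise_std)
        drift = _drift(rng, T, cfg.n_nodes, cfg.tr, cfg.drift_amplitude)
        runs.append(latent + noise + drift)
        labels.append(np.full(T, run))
    return RoiTimeSeries(values=np.concatenate(runs), tr=cfg.tr,
                         run_labels=np.concatenate(labels))


def generate_task_timeseries(cfg: SynthConfig, design: TaskDesign,
                             truth: GroundTruth, subject_seed: int):
    """Task sessions with planted activations and PPI couplings.

    Latent module-structured signals receive, per planted edge
    ``(s, t, condition, gamma)``, the term ``gamma * latent_s * boxcar_c`` on
    the target before HRF convolution; per-module emotion activation enters as
    an amplitude-scaled condition boxcar. The convolved signal is observed
    with AR(1) noise, drift, and leaked motion signals.

    Returns
    -------
    (RoiTimeSeries over all sessions, nuisance DataFrame with six motion
    regressors aligned to the rows)
    """
    for s, t, cond, gamma in truth.true_ppi_edges:
        if not (0 <= s < cfg.n_nodes and 0 <= t < cfg.n_nodes):
            raise ValueError(f"ppi edge ({s}->{t}) references out-of-range node")
    chol = cfg._cholesky()
    rng = np.random.default_rng(subject_seed)
    kernel = cfg.hrf.kernel(cfg.tr)
    kernel = kernel / kernel.sum()  # unit-sum: preserves slow amplitudes
    labels = cfg.true_labels
    sessions, run_labels, motions = [], [], []
    for sess in design.sessions:
        T = design.n_volumes
        events = design.session_events(sess)
        boxes = {c: boxcar(events[events.condition == c]["onset"].values,
                           events[events.condition == c]["duration"].values,
                           cfg.tr, T)
                 for c in design.conditions}
        latent = rng.standard_normal((T, cfg.n_nodes)) @ chol.T
        neural = latent.copy()
        for s, t, cond, gamma in truth.true_ppi_edges:
            neural[:, t] = neural[:, t] + gamma * latent[:, s] * boxes[cond]
        for m, amp in truth.true_active_modules.items():
            neural[:, labels == int(m)] += amp * boxes["emotion"][:, None]
        bold = np.apply_along_axis(
            lambda x: np.convolve(x, kernel)[:T], 0, neural)
        noise = _ar1_noise(rng, (T, cfg.n_nodes), cfg.ar_coefficient, cfg.noise_std)
        drift = _drift(rng, T, cfg.n_nodes, cfg.tr, cfg.drift_amplitude)
        motion = _motion(rng, T, cfg.motion_amplitude)
        loadings = 0.1 * rng.standard_normal((motion.shape[1], cfg.n_nodes))
        sessions.append(bold + noise + drift + motion @ loadings)
        run_labels.append(np.full(T, sess))
        motions.append(motion)
    ts = RoiTimeSeries(values=np.concatenate(sessions), tr=cfg.tr,
                       run_labels=np.concatenate(run_labels))
    nuisance = pd.DataFrame(np.concatenate(motions),
                            columns=[f"motion{i+1}" for i in range(6)])
    return ts, nuisance


def subject_seeds(master_seed: int, n_subjects: int) -> list[int]:
    """Deterministic per-subject integer seeds derived from a master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n_subjects)
    return [int(s) & 0x7FFFFFFF for s in state]


def write_cohort(cfg: SynthConfig, out_dir, rest: bool = True,
                 task: bool = True) -> dict:
    """Generate and write a full cohort; returns the manifest dict.

    Writes per-subject TSV time series, the task design TSV, the ground truth
    JSON, and a manifest JSON listing every file and the master seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = GroundTruth.from_config(cfg)
    design = generate_task_design(tr=cfg.tr,
                                  n_volumes=cfg.task_volumes_per_session,
                                  n_sessions=cfg.n_sessions)
    files = {}
    design_path = out / "task_design.tsv"
    design.table.to_csv(design_path, sep="\t", index=False)
    files["task_design"] = design_path.name
    truth_path = out / "ground_truth.json"
    truth_path.write_text(truth.to_json())
    files["ground_truth"] = truth_path.name
    seeds = subject_seeds(cfg.seed, cfg.n_subjects)
    files["subjects"] = []
    for i, sd in enumerate(seeds):
        entry = {"subject": f"sub{i:03d}", "seed": sd}
        if rest:
            ts = generate_rest_timeseries(cfg, sd)
            p = out / f"sub{i:03d}_rest.tsv"
            ts.to_frame().to_csv(p, sep="\t", index=False)
            entry["rest"] = p.name
        if task:
            ts, nuis = generate_task_timeseries(cfg, design, truth, sd)
            p = out / f"sub{i:03d}_task.tsv"
            ts.to_frame().to_csv(p, sep="\t", index=False)
            entry["task"] = p.name
            q = out / f"sub{i:03d}_nuisance.tsv"
            nuis.to_csv(q, sep="\t", index=False)
            entry["nuisance"] = q.name
        files["subjects"].append(entry)
    manifest = {"master_seed": cfg.seed, "n_subjects": cfg.n_subjects,
                "tr": cfg.tr, "files": files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
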