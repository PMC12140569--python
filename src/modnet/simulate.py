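"""Synthetic multi-subject, two-task node time series with known coupling.

Emulates the ingredients the pipeline must handle — module-structured
correlations that differ by task, a shared global signal, between-subject
coupling variability, and motion spikes with coupled signal artifacts —
while staying analytically tractable: every expected pairwise correlation
follows in closed form from the generative model, so parameter recovery can
be checked against ground truth.

Generative model for node i in module m, subject s, task tau::

    x_i(t) = sqrt(c) s_m(t) + sqrt(rho) h(t) + sqrt(b) g(t)
             + sqrt(1 - c - rho - b) eps_i(t)

with s_m a module-shared latent, h a latent shared by all module nodes,
g the global signal shared by every node, eps_i node noise, all unit
variance and mutually independent; c is the (subject-jittered) within-
module coupling for (tau, m). Unassigned nodes carry only g and noise.
Hence expected correlations: within module c + rho + b, between modules
rho + b, module vs unassigned (or unassigned pairs) b.

Latents are Gaussian white noise by default (the tractable case); an AR(1)
option exists because BOLD is temporally smooth. Motion spikes enter both
the motion parameters (a one-volume translation jump sized to cross the
scrubbing threshold) and the data (an additive transient on every node), so
scrubbing has a measurable benefit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .preprocess import TimeSeries


def _default_modules() -> dict[str, list[int]]:
    # two task-modulated 10-node modules plus two independent task-invariant
    # background systems. The background keeps the within-module pair count
    # above the 30% edge budget (otherwise every within-module pair clears a
    # relative threshold and local density saturates at 1), and splitting it
    # into two systems with independent latents keeps the threshold cut from
    # moving both task modules' densities in lockstep.
    return {"Motoric language L": list(range(0, 10)),
            "Word recognition L": list(range(10, 20)),
            "Background A": list(range(20, 50)),
            "Background B": list(range(50, 80))}


def _default_coupling() -> dict[tuple[str, str], float]:
    # double dissociation: the motor-like module couples more strongly during
    # generation, the sensory-like module during comprehension; the background
    # systems are task-invariant
    return {("wc", "Motoric language L"): 0.15, ("wg", "Motoric language L"): 0.45,
            ("wc", "Word recognition L"): 0.45, ("wg", "Word recognition L"): 0.15,
            ("wc", "Background A"): 0.3, ("wg", "Background A"): 0.3,
            ("wc", "Background B"): 0.3, ("wg", "Background B"): 0.3}


def recovery_config(seed: int = 0, **overrides) -> "SyntheticConfig":
    """The double-dissociation study design (the generator defaults)."""
    return SyntheticConfig(seed=seed, **overrides)


def null_config(seed: int = 0, **overrides) -> "SyntheticConfig":
    """Same design with task-invariant coupling everywhere (no interaction)."""
    coupling = {k: 0.3 for k in _default_coupling()}
    return SyntheticConfig(seed=seed, coupling=coupling, **overrides)


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the generator.

    Defaults describe a desk-scale two-task double-dissociation study:
    20 subjects, 80 nodes (two 10-node task-modulated modules plus two
    30-node task-invariant background systems), 200 volumes at TR 2 s,
    within-module coupling 0.15 vs 0.45 crossed over tasks (background
    0.3), global-signal weight 0.1, 10% between-subject coupling jitter,
    no motion spikes unless requested.
    """

    n_subjects: int = 20
    n_nodes: int = 80
    modules: dict = field(default_factory=_default_modules)
    tasks: tuple = ("wc", "wg")
    coupling: dict = field(default_factory=_default_coupling)
    cross_module_coupling: float = 0.0
    global_signal_weight: float = 0.1
    tr: float = 2.0
    n_volumes: int = 200
    spike_prob: float = 0.0
    spike_magnitude_mm: float = 1.0
    spike_amplitude: float = 4.0
    subject_sd: float = 0.1
    ar_coef: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        idx_all: list[int] = []
        for idx in self.modules.values():
            idx_all.extend(idx)
        if len(idx_all) != len(set(idx_all)):
            raise ValueError("module node sets must be disjoint")
        if idx_all and max(idx_all) >= self.n_nodes:
            raise ValueError("module node index out of range")
        for (tau, m), c in self.coupling.items():
            if tau not in self.tasks or m not in self.modules:
                raise ValueError(f"coupling cell ({tau}, {m}) not in design")
            if not 0 <= c < 1:
                raise ValueError("coupling must be in [0, 1)")
            if c + self.cross_module_coupling + self.global_signal_weight >= 1:
                raise ValueError(f"variance budget exceeded for ({tau}, {m})")
        for p in (self.spike_prob, self.global_signal_weight, self.cross_module_coupling):
            if not 0 <= p < 1:
                raise ValueError("rates/weights must be in [0, 1)")
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must be in [0, 1)")


@dataclass
class SubjectRun:
    """One subject x task acquisition plus its nuisance channels."""

    subject: int
    task: str
    ts: TimeSeries
    motion: np.ndarray          # (n_volumes, 6)
    csf: np.ndarray
    wm: np.ndarray
    spike_volumes: np.ndarray   # indices where a spike was injected


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    runs: dict                  # (subject, task) -> SubjectRun
    truth: dict                 # realized couplings etc., see generate_dataset

    def run(self, subject: int, task: str) -> SubjectRun:
        return self.runs[(subject, task)]


def _latent(rng: np.random.Generator, n: int, ar: float) -> np.ndarray:
    x = rng.standard_normal(n)
    if ar > 0:
        y = np.empty(n)
        y[0] = x[0]
        for t in range(1, n):
            y[t] = ar * y[t - 1] + x[t]
        y *= np.sqrt(1 - ar**2)  # unit marginal variance
        return y
    return x


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Draw the full multi-subject, multi-task dataset.

    The returned ``truth`` dict records, per subject, the coupling
    multiplier and per (subject, task, module) the realized coupling c, so
    expected correlations are recoverable in closed form
    (see :func:`truth_expected_correlation`).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    node_module = np.full(cfg.n_nodes, "", dtype=object)
    for name, idx in cfg.modules.items():
        node_module[np.asarray(idx, dtype=int)] = name

    budget_cap = 1.0 - cfg.cross_module_coupling - cfg.global_signal_weight - 1e-6
    multipliers = {}
    realized = {}
    runs = {}
    for s in range(cfg.n_subjects):
        mult = max(0.0, 1.0 + rng.normal(0.0, cfg.subject_sd))
        multipliers[s] = mult
        for tau in cfg.tasks:
            n_t = cfg.n_volumes
            g = _latent(rng, n_t, cfg.ar_coef)
            h = _latent(rng, n_t, cfg.ar_coef)
            lat = {m: _latent(rng, n_t, cfg.ar_coef) for m in cfg.modules}
            X = np.empty((cfg.n_nodes, n_t))
            for i in range(cfg.n_nodes):
                m = node_module[i]
                eps = _latent(rng, n_t, cfg.ar_coef)
                if m:
                    c = min(cfg.coupling[(tau, m)] * mult, budget_cap)
                    realized[(s, tau, m)] = c
                    X[i] = (np.sqrt(c) * lat[m]
                            + np.sqrt(cfg.cross_module_coupling) * h
                            + np.sqrt(cfg.global_signal_weight) * g
                            + np.sqrt(1 - c - cfg.cross_module_coupling
                                      - cfg.global_signal_weight) * eps)
                else:
                    X[i] = (np.sqrt(cfg.global_signal_weight) * g
                            + np.sqrt(1 - cfg.global_signal_weight) * eps)

            motion = np.hstack([rng.normal(0, 0.02, (n_t, 3)),
                                rng.normal(0, 4e-4, (n_t, 3))])
            spikes = np.flatnonzero(rng.random(n_t) < cfg.spike_prob)
            for t in spikes:
                motion[t, 0] += cfg.spike_magnitude_mm
                X[:, t] += cfg.spike_amplitude
            csf = rng.standard_normal(n_t)
            wm = rng.standard_normal(n_t)
            runs[(s, tau)] = SubjectRun(s, tau, TimeSeries(X, cfg.tr),
                                        motion, csf, wm, spikes)
    truth = {"multipliers": multipliers, "realized_coupling": realized,
             "node_module": node_module.tolist()}
    return SyntheticDataset(cfg, runs, truth)


def truth_expected_correlation(dataset: SyntheticDataset, subject: int,
                               task: str, i: int, j: int) -> float:
    """Closed-form expected correlation between two nodes under the model."""
    cfg = dataset.config
    if i == j:
        return 1.0
    mods = dataset.truth["node_module"]
    mi, mj = mods[i], mods[j]
    b = cfg.global_signal_weight
    if not mi or not mj:
        return b
    rho_b = cfg.cross_module_coupling + b
    if mi == mj:
        return dataset.truth["realized_coupling"][(subject, task, mi)] + rho_b
    return rho_b


# ---------------------------------------------------------------------------
# on-disk layout (same TSVs the pipeline reads)
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write per-run time series / motion / confound TSVs plus a truth JSON."""
    import pandas as pd
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (s, tau), run in dataset.runs.items():
        stem = f"sub-{s:02d}_task-{tau}"
        pd.DataFrame(run.ts.values.T).to_csv(outdir / f"{stem}_ts.tsv",
                                             sep="\t", index=False)
        pd.DataFrame(run.motion,
                     columns=["trans_x", "trans_y", "trans_z",
                              "rot_x", "rot_y", "rot_z"]
                     ).to_csv(outdir / f"{stem}_motion.tsv", sep="\t", index=False)
        pd.DataFrame({"csf": run.csf, "wm": run.wm}
                     ).to_csv(outdir / f"{stem}_confounds.tsv", sep="\t", index=False)
    truth = {
        "tr": dataset.config.tr,
        "multipliers": {str(k): v for k, v in dataset.truth["multipliers"].items()},
        "realized_coupling": {f"{s}|{tau}|{m}": v for (s, tau, m), v
                              in dataset.truth["realized_coupling"].items()},
        "node_module": dataset.truth["node_module"],
        "config": {k: v for k, v in asdict(dataset.config).items()
                   if k not in ("modules", "coupling")},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
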