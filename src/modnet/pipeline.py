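"""End-to-end study orchestration.

Runs the stage sequence — (optional) temporal denoising, connectivity,
relative thresholding at one or more proportions, local/global module
metrics, Task x Module statistics and null models — from a single run
configuration, and writes tidy TSV outputs plus a JSON manifest that
records every stage parameter and seed so deterministic stages re-execute
bit-identically.
"""

from __future__ import annotations

import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import global_fc, partial_corr_global, pearson_matrix, relative_threshold
from .graph_metrics import ALL_METRICS, module_metrics
from .inference import lmm_task_module, node_randomization_null, paired_t, template_graph
from .preprocess import denoise
from .simulate import SyntheticConfig, SyntheticDataset, generate_dataset


def connectivity_for_run(run, scaling: str = "none", do_denoise: bool = False,
                         fd_threshold_mm: float = 0.5, n_back: int = 1,
                         n_forward: int = 2, highpass_hz: float = 0.008):
    """Correlation matrix and global FC for one subject/task run.

    ``scaling='global'`` partials out the mean signal over all nodes (the
    stand-in for the whole-volume average); ``do_denoise`` applies the
    scrub -> nuisance -> high-pass chain first.
    """
    ts = run.ts
    if do_denoise:
        ts = denoise(ts, run.motion, run.csf, run.wm,
                     fd_threshold_mm=fd_threshold_mm, n_back=n_back,
                     n_forward=n_forward, highpass_hz=highpass_hz)
    if scaling == "global":
        corr = partial_corr_global(ts, ts.values.mean(axis=0))
    elif scaling == "none":
        corr = pearson_matrix(ts)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return corr, global_fc(corr)


def dataset_module_indices(dataset: SyntheticDataset) -> dict[str, np.ndarray]:
    return {name: np.asarray(idx, dtype=int)
            for name, idx in dataset.config.modules.items()}


def metric_table(dataset: SyntheticDataset, proportions, modes=("local",),
                 metrics=ALL_METRICS, scaling: str = "none",
                 do_denoise: bool = False, rank: str = "signed",
                 modules: dict | None = None) -> pd.DataFrame:
    """Tidy metric table over subjects x tasks x thresholds x modes.

    One row per subject, task, threshold proportion, mode, module and
    metric, with the run's global FC attached as a covariate column.
    """
    if np.isscalar(proportions):
        proportions = [proportions]
    modules = modules if modules is not None else dataset_module_indices(dataset)
    frames = []
    for (s, tau), run in sorted(dataset.runs.items()):
        corr, gfc = connectivity_for_run(run, scaling=scaling, do_denoise=do_denoise)
        for prop in proportions:
            g = relative_threshold(corr, prop, rank=rank)
            for mode in modes:
                tab = module_metrics(g, modules, mode, metrics=metrics,
                                     subject=s, task=tau)
                tab["threshold"] = prop
                tab["scaling"] = scaling
                tab["global_fc"] = gfc
                frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def interaction_test(table: pd.DataFrame, metric: str, modules: list[str],
                     include_global_fc: bool = False):
    """LMM Task x Module interaction for one metric over two modules.

    Returns the LmmResult plus the cell-mean interaction contrast
    (module2 - module1) x (task2 - task1) under name-sorted ordering, whose
    sign matches the LMM interaction coefficient under treatment coding.
    """
    sub = table[(table["metric"] == metric) & (table["module"].isin(modules))]
    res = lmm_task_module(sub.rename(columns=str), include_global_fc=include_global_fc)
    cell = sub.groupby(["module", "task"])["value"].mean().unstack()
    mods = sorted(cell.index)
    tasks = sorted(cell.columns)
    contrast = ((cell.loc[mods[1], tasks[1]] - cell.loc[mods[1], tasks[0]])
                - (cell.loc[mods[0], tasks[1]] - cell.loc[mods[0], tasks[0]]))
    return res, float(contrast)


def task_difference_signs(table: pd.DataFrame) -> pd.DataFrame:
    """Sign of the mean task difference per threshold/mode/module/metric.

    Tasks are name-sorted; the difference is second minus first. Used for
    the threshold-robustness check: the sign pattern should not depend on
    the proportion.
    """
    tasks = sorted(table["task"].unique())
    if len(tasks) != 2:
        raise ValueError("need exactly 2 tasks")
    wide = table.pivot_table(index=["threshold", "mode", "module", "metric"],
                             columns="task", values="value", aggfunc="mean")
    out = wide.reset_index()
    out["difference"] = out[tasks[1]] - out[tasks[0]]
    out["sign"] = np.sign(out["difference"]).astype(int)
    return out


def paired_task_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Paired t per threshold/mode/module/metric across subjects."""
    from .inference import fdr_bh

    tasks = sorted(table["task"].unique())
    rows = []
    for key, grp in table.groupby(["threshold", "mode", "module", "metric"]):
        wide = grp.pivot_table(index="subject", columns="task", values="value")
        if wide.isna().any().any() or len(wide) < 3:
            continue
        t, df, p = paired_t(wide[tasks[1]], wide[tasks[0]])
        rows.append(dict(zip(["threshold", "mode", "module", "metric"], key),
                         t=t, df=df, p=p))
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = fdr_bh(out["p"])
    return out


def run_pipeline(config, outdir) -> Path:
    """Execute a full study from a config mapping (or YAML path).

    Config keys: ``simulate`` (SyntheticConfig fields), ``thresholds``
    (list), ``scaling``, ``modes``, ``metrics``, ``denoise`` (bool),
    ``stats`` ({lmm_metric, lmm_modules, include_global_fc}), ``null``
    ({module_size, metrics, mode, reps, seed}), ``seed``. Writes
    metrics.tsv, stats.tsv, nulls.tsv (if requested) and manifest.json.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sim = dict(config.get("simulate", {}))
    sim.setdefault("seed", config.get("seed", 0))
    if "modules" in sim:
        sim["modules"] = {k: list(v) for k, v in sim["modules"].items()}
    if "coupling" in sim:
        sim["coupling"] = {tuple(k.split("|")) if isinstance(k, str) else tuple(k): v
                           for k, v in sim["coupling"].items()}
    cfg = SyntheticConfig(**sim)
    dataset = generate_dataset(cfg)

    thresholds = config.get("thresholds", [0.3])
    metrics = tuple(config.get("metrics", ALL_METRICS))
    unknown = set(metrics) - set(ALL_METRICS)
    if unknown:
        raise ValueError(f"unknown metric(s): {sorted(unknown)}")
    modes = tuple(config.get("modes", ("local", "global")))
    scaling = config.get("scaling", "none")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        table = metric_table(dataset, thresholds, modes=modes, metrics=metrics,
                             scaling=scaling, do_denoise=config.get("denoise", False))
    table.to_csv(outdir / "metrics.tsv", sep="\t", index=False)

    stats_rows = paired_task_tests(table)
    stats_cfg = config.get("stats", {})
    lmm_summary = None
    if stats_cfg.get("lmm_metric"):
        mods = stats_cfg.get("lmm_modules") or sorted(table["module"].unique())[:2]
        sub = table[(table["threshold"] == thresholds[0])
                    & (table["mode"] == modes[0])]
        res, contrast = interaction_test(sub, stats_cfg["lmm_metric"], mods,
                                         include_global_fc=stats_cfg.get(
                                             "include_global_fc", False))
        lmm_summary = {"metric": stats_cfg["lmm_metric"], "modules": mods,
                       "interaction_t": res.interaction_t,
                       "interaction_p": res.interaction_p,
                       "cell_contrast": contrast, "formula": res.formula}
    stats_rows.to_csv(outdir / "stats.tsv", sep="\t", index=False)

    null_cfg = config.get("null")
    if null_cfg:
        mats = [connectivity_for_run(dataset.run(s, null_cfg.get("task", cfg.tasks[0])))[0]
                for s in range(cfg.n_subjects)]
        tmpl = template_graph(mats, thresholds[0])
        nd = node_randomization_null(
            tmpl, null_cfg["module_size"],
            null_cfg.get("metrics", ["degree_density"]),
            null_cfg.get("mode", "local"),
            n_replicates=null_cfg.get("reps", 10000),
            seed=null_cfg.get("seed", config.get("seed", 0)))
        nd.replicates.to_csv(outdir / "nulls.tsv", sep="\t", index=False)

    manifest = {
        "tool": "modnet", "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": _jsonable(config),
        "seed": config.get("seed", 0),
        "warnings": [str(w.message) for w in caught],
        "lmm": lmm_summary,
        "stages": ["simulate", "connectivity", "threshold", "module_metrics",
                   "stats"] + (["null"] if null_cfg else []),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
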