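"""Task x Module statistics and null-model validations.

Paired t tests, a linear mixed-effects model (metric value ~ module * task
with a by-subject random intercept, optionally adjusted by the subject's
per-task global FC), Benjamini-Hochberg FDR, and the two null models: node
randomization (pseudofunctional modules of matched size drawn from a
group-template graph) and subject-level bootstrap of resting connectivity
matrices. Empirical p-values use the add-one rule, so they are never
exactly zero; two-sided p doubles the smaller tail, capped at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .connectivity import BinaryGraph, relative_threshold
from .graph_metrics import module_metrics


def paired_t(values_a, values_b) -> tuple[float, int, float]:
    """Classical paired t test; returns (t, df, two-sided p).

    Zero-variance differences: t = 0, p = 1 when every difference is zero
    (no evidence either way); otherwise undefined and an error is raised.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, a.size - 1, 1.0
        raise ValueError("constant nonzero differences: t undefined")
    t, p = scipy.stats.ttest_rel(a, b)
    return float(t), a.size - 1, float(p)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class LmmResult:
    """Fixed-effect table plus the primary Task x Module interaction test."""

    fixed_effects: pd.DataFrame      # estimate, se, t, p per fixed-effect term
    interaction_t: float
    interaction_p: float
    converged: bool
    formula: str


def lmm_task_module(data: pd.DataFrame, include_global_fc: bool = False) -> LmmResult:
    """Mixed model value ~ module + task + module:task (+ global_fc), random
    intercept per subject.

    ``data`` is long-form with columns subject, task, module, value and,
    when ``include_global_fc``, a per-subject-per-task ``global_fc`` column.
    Subjects missing either task are dropped with a warning so the tested
    contrast stays balanced. With two modules and two tasks the interaction
    is a single term; with more, the smallest interaction p is reported as
    primary alongside the full table.
    """
    data = data.copy()
    n_tasks = data["task"].nunique()
    if data["module"].nunique() < 2 or n_tasks != 2 or data["subject"].nunique() < 5:
        raise ValueError("need >=2 modules, exactly 2 tasks and >=5 subjects")
    complete = data.groupby("subject")["task"].nunique() == n_tasks
    bad = complete.index[~complete]
    if len(bad):
        warnings.warn(f"dropping unbalanced subject(s): {list(bad)}", stacklevel=2)
        data = data[~data["subject"].isin(bad)]

    formula = "value ~ C(module) * C(task)"
    if include_global_fc:
        formula += " + global_fc"
    model = smf.mixedlm(formula, data, groups=data["subject"])
    with warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            fit = model.fit(reml=True)
        except np.linalg.LinAlgError:
            warnings.warn("singular mixed-model fit; refitting with lbfgs", stacklevel=2)
            fit = model.fit(reml=True, method="lbfgs")

    fe = pd.DataFrame({
        "estimate": fit.fe_params,
        "se": fit.bse_fe,
        "t": fit.fe_params / fit.bse_fe,
    })
    fe["p"] = 2.0 * scipy.stats.norm.sf(np.abs(fe["t"]))
    inter = fe.index.str.contains(":")
    if not inter.any():
        raise RuntimeError("model has no interaction term")
    primary = fe[inter].sort_values("p").iloc[0]
    return LmmResult(fe, float(primary["t"]), float(primary["p"]),
                     bool(fit.converged), formula)


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Replicate metric values under a randomization/bootstrap scheme."""

    scheme: str
    replicates: pd.DataFrame          # one row per replicate x metric cell
    observed: pd.DataFrame | None     # observed values with empirical p / p_fdr
    seed: int
    n_replicates: int
    meta: dict = field(default_factory=dict)


def empirical_p_two_sided(replicates: np.ndarray, observed: float) -> float:
    """Add-one two-sided empirical p: double the smaller tail, cap at 1."""
    r = np.asarray(replicates, dtype=float)
    n = r.size
    hi = (np.sum(r >= observed) + 1) / (n + 1)
    lo = (np.sum(r <= observed) + 1) / (n + 1)
    return min(1.0, 2.0 * min(hi, lo))


def template_graph(matrices, proportion: float, rank: str = "signed") -> BinaryGraph:
    """Average the subjects' connectivity matrices, then threshold."""
    mats = [np.asarray(m, dtype=float) for m in matrices]
    if not mats:
        raise ValueError("need at least one matrix")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("connectivity matrices differ in shape")
    return relative_threshold(np.mean(mats, axis=0), proportion, rank=rank)


def node_randomization_null(template: BinaryGraph, module_size: int, metrics,
                            mode: str, n_replicates: int = 10000,
                            seed: int = 0,
                            observed: dict[str, float] | None = None) -> NullDistribution:
    """Metric distribution over random pseudofunctional modules.

    Each replicate draws ``module_size`` nodes uniformly without replacement
    from the template graph and computes the module metrics in the requested
    mode. When observed values are supplied (metric name -> value) they are
    scored with two-sided empirical p, FDR-corrected across the metric cells
    tested in this invocation.
    """
    n = template.n_nodes
    if not 0 < module_size <= n:
        raise ValueError("module_size must be in 1..n_nodes")
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_replicates):
        idx = rng.choice(n, size=module_size, replace=False)
        tab = module_metrics(template, {"pseudo": np.sort(idx)}, mode, metrics=metrics)
        for _, row in tab.iterrows():
            rows.append({"replicate": r, "metric": row["metric"], "value": row["value"]})
    reps = pd.DataFrame(rows)

    obs_df = None
    if observed:
        recs = []
        for metric, value in observed.items():
            dist = reps.loc[reps["metric"] == metric, "value"].to_numpy()
            recs.append({"metric": metric, "value": value,
                         "p": empirical_p_two_sided(dist, value)})
        obs_df = pd.DataFrame(recs)
        obs_df["p_fdr"] = fdr_bh(obs_df["p"])
    return NullDistribution("node_randomization", reps, obs_df, seed, n_replicates,
                            {"module_size": module_size, "mode": mode})


def bootstrap_rest_comparison(rest_matrices, modules: dict[str, np.ndarray],
                              metrics, mode: str, proportion: float = 0.3,
                              n_replicates: int = 10000, seed: int = 0,
                              observed: pd.DataFrame | None = None) -> NullDistribution:
    """Bootstrap of resting connectivity: resample subjects with replacement,
    average into a template, threshold, compute true-module metrics.

    ``observed`` is a DataFrame with columns task, module, metric, value
    (e.g. per-task across-subject means); each cell is scored against the
    matching module/metric bootstrap distribution, FDR across all cells.
    """
    mats = [np.asarray(m, dtype=float) for m in rest_matrices]
    if len(mats) < 2:
        raise ValueError("need at least 2 subjects to bootstrap")
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_replicates):
        pick = rng.integers(0, len(mats), size=len(mats))
        g = template_graph([mats[i] for i in pick], proportion)
        tab = module_metrics(g, modules, mode, metrics=metrics)
        for _, row in tab.iterrows():
            rows.append({"replicate": r, "module": row["module"],
                         "metric": row["metric"], "value": row["value"]})
    reps = pd.DataFrame(rows)

    obs_df = None
    if observed is not None and len(observed):
        obs_df = observed.copy()
        ps = []
        for _, row in obs_df.iterrows():
            dist = reps.loc[(reps["module"] == row["module"]) &
                            (reps["metric"] == row["metric"]), "value"].to_numpy()
            ps.append(empirical_p_two_sided(dist, row["value"]))
        obs_df["p"] = ps
        obs_df["p_fdr"] = fdr_bh(obs_df["p"])
    return NullDistribution("bootstrap_rest", reps, obs_df, seed, n_replicates,
                            {"proportion": proportion, "mode": mode})
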