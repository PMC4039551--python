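"""Monte Carlo replication harness for the merge scenarios.

Each cell of the experimental grid (scenario x merge counts x analysis
strategy) is replicated many times: simulate a trial, apply the merges,
build the analysis set, fit the random-intercept model, and aggregate the
estimates into Monte Carlo means with normal-approximation 95% intervals
plus the empirical power of the treatment-effect Wald test.

Replicate ``r`` of a cell draws from an RNG substream keyed on the master
seed, the cell coordinates and ``r``, so any single cell (or replicate) is
reproducible in isolation and results do not depend on execution order.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import TrialDesign
from .fit import FitResult, fit_random_intercept, significant
from .simulate import (
    SCENARIOS,
    STRATEGIES,
    MergeSpec,
    apply_heterogeneous_merges,
    apply_homogeneous_merges,
    build_analysis_set,
    generate_trial,
)

__all__ = ["ScenarioSummary", "run_cell", "run_table", "figure1_data", "figure2_data"]

_PARAMS = ("beta0", "beta1", "sigma_b2", "sigma_w2", "icc")


@dataclass
class ScenarioSummary:
    """Monte Carlo aggregates for one cell of the simulation grid."""

    scenario: str
    strategy: str
    k0: int
    k1: int
    k: int
    n_reps: int
    n_failed: int
    mean: dict[str, float] = field(default_factory=dict)
    ci_low: dict[str, float] = field(default_factory=dict)
    ci_high: dict[str, float] = field(default_factory=dict)
    empirical_power: float = float("nan")
    mean_size_variance: float = float("nan")

    def to_row(self) -> dict:
        row = {
            "scenario": self.scenario,
            "strategy": self.strategy,
            "k0": self.k0,
            "k1": self.k1,
            "k": self.k,
            "n_reps": self.n_reps,
            "n_failed": self.n_failed,
        }
        for name in _PARAMS:
            row[f"{name}_mean"] = self.mean[name]
            row[f"{name}_ci_low"] = self.ci_low[name]
            row[f"{name}_ci_high"] = self.ci_high[name]
        row["empirical_power"] = self.empirical_power
        row["mean_size_variance"] = self.mean_size_variance
        return row


def _replicate_seed(master_seed: int, spec: MergeSpec, r: int) -> np.random.Generator:
    key = (
        int(master_seed),
        SCENARIOS.index(spec.scenario),
        STRATEGIES.index(spec.strategy),
        spec.k0,
        spec.k1,
        spec.k,
        r,
    )
    return np.random.default_rng(np.random.SeedSequence(key))


def simulate_one(
    design: TrialDesign, spec: MergeSpec, rng, mu0: float = 0.0, mu1: float = 0.2
) -> tuple[FitResult, float]:
    """One replicate: generate, merge, build the analysis set, fit."""
    data = generate_trial(design, mu0=mu0, mu1=mu1, seed=rng)
    if spec.homogeneous:
        data = apply_homogeneous_merges(data, spec, seed=rng)
    else:
        data = apply_heterogeneous_merges(data, spec, seed=rng)
    analysis = build_analysis_set(data, spec.strategy)
    sizes = analysis.analysis_cluster_sizes()
    size_var = float(np.var(sizes, ddof=1)) if sizes.size > 1 else 0.0
    fit = fit_random_intercept(analysis)
    return fit, size_var


def run_cell(
    design: TrialDesign,
    spec: MergeSpec,
    n_reps: int = 1000,
    master_seed: int = 0,
    mu0: float = 0.0,
    mu1: float = 0.2,
    alpha: float = 0.05,
) -> ScenarioSummary:
    """Replicate one cell ``n_reps`` times and aggregate.

    Non-convergent fits are dropped from the aggregates but counted in
    ``n_failed``; ``n_reps`` always refers to attempted replicates.
    """
    if n_reps < 2:
        raise ValueError("need at least two replicates to form intervals")
    rows = np.empty((n_reps, len(_PARAMS)), dtype=float)
    sig = np.zeros(n_reps, dtype=bool)
    size_vars = np.empty(n_reps, dtype=float)
    ok = np.zeros(n_reps, dtype=bool)
    for r in range(n_reps):
        rng = _replicate_seed(master_seed, spec, r)
        try:
            fit, size_vars[r] = simulate_one(design, spec, rng, mu0=mu0, mu1=mu1)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not fit.converged:
            continue
        rows[r] = (fit.beta0, fit.beta1, fit.sigma_b2_hat, fit.sigma_w2_hat, fit.icc_hat)
        sig[r] = significant(fit, alpha)
        ok[r] = True
    n_ok = int(ok.sum())
    if n_ok < 2:
        raise RuntimeError("fewer than two replicates converged")
    vals = rows[ok]
    mean = vals.mean(axis=0)
    half = 1.96 * vals.std(axis=0, ddof=1) / np.sqrt(n_ok)
    summary = ScenarioSummary(
        scenario=spec.scenario,
        strategy=spec.strategy,
        k0=spec.k0,
        k1=spec.k1,
        k=spec.k,
        n_reps=n_reps,
        n_failed=n_reps - n_ok,
        empirical_power=float(sig[ok].mean()),
        mean_size_variance=float(size_vars[ok].mean()),
    )
    for i, name in enumerate(_PARAMS):
        summary.mean[name] = float(mean[i])
        summary.ci_low[name] = float(mean[i] - half[i])
        summary.ci_high[name] = float(mean[i] + half[i])
    return summary


def run_table(
    design: TrialDesign,
    scenario: str,
    strategies: list[str] | tuple[str, ...],
    merge_grid=(0, 1, 2, 5, 10, 20),
    n_reps: int = 1000,
    master_seed: int = 0,
    full_grid: bool = False,
    mu0: float = 0.0,
    mu1: float = 0.2,
    progress: bool = False,
) -> pd.DataFrame:
    """Run a whole table: strategies x merge counts, one ``run_cell`` each.

    For homogeneous scenarios the grid values are merges per arm
    (``k0 = k1 = k`` on the diagonal, the printed-table layout); with
    ``full_grid=True`` every ``(k0, k1)`` pair is run (figure data). For
    heterogeneous scenarios the grid is the number of cross-arm merges.
    """
    rows = []
    homogeneous = MergeSpec(scenario=scenario, strategy=strategies[0]).homogeneous
    if homogeneous and full_grid:
        cells = [(a, b) for a in merge_grid for b in merge_grid]
    else:
        cells = [(v, v) for v in merge_grid]
    for strategy in strategies:
        for a, b in cells:
            if homogeneous:
                spec = MergeSpec(scenario=scenario, k0=a, k1=b, strategy=strategy)
            else:
                spec = MergeSpec(scenario=scenario, k=a, strategy=strategy)
            if progress:
                print(
                    f"cell scenario={scenario} strategy={strategy} k0={spec.k0} "
                    f"k1={spec.k1} k={spec.k} reps={n_reps}",
                    file=sys.stderr,
                )
            summary = run_cell(
                design, spec, n_reps=n_reps, master_seed=master_seed, mu0=mu0, mu1=mu1
            )
            rows.append(summary.to_row())
    return pd.DataFrame(rows)


def figure1_data(m: int = 20, cluster_counts=(10, 20, 40, 80)) -> pd.DataFrame:
    """Post-merge cluster-size variance as a function of the number of merges.

    Closed-form curves for several starting numbers of clusters ``c`` at a
    fixed pre-merge size ``m``.
    """
    from .design import merged_size_variance

    rows = [
        {"c": c, "m": m, "k": k, "size_variance": merged_size_variance(m, c, k)}
        for c in cluster_counts
        for k in range(0, c // 2 + 1)
    ]
    return pd.DataFrame(rows)


def figure2_data(design: TrialDesign, k0_max: int = 3, k1_max: int = 2) -> pd.DataFrame:
    """Analytic power surface over per-arm merge counts ``(k0, k1)``."""
    from .design import MergeCounts, power

    rows = [
        {"k0": k0, "k1": k1, "power": power(design, MergeCounts(k0, k1))}
        for k0 in range(k0_max + 1)
        for k1 in range(k1_max + 1)
    ]
    return pd.DataFrame(rows)
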