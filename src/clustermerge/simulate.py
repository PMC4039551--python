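"""Simulation of two-level cluster-RCT data and post-randomisation merges.

Outcomes follow the random-intercept model ``Y_ij = mu_arm + u_j + e_ij``
with cluster effects ``u_j ~ N(0, sigma_b2)`` and individual errors
``e_ij ~ N(0, sigma_w2)``. Four merge scenarios are supported:

* S1 — homogeneous (same-arm) merges, all individuals completed treatment
  before the merge, so outcomes are untouched and only labels change.
* S2 — homogeneous merges where only a fraction completed; non-completers'
  outcomes are regenerated with one new shared cluster effect.
* S3 — heterogeneous (cross-arm) merges, outcomes untouched.
* S4 — heterogeneous merges with partial completion; non-completers'
  treatment-mean component follows the merged cluster's post-merge arm.

Analysis-set construction (who is analysed, under which cluster and arm
label) is a separate step so several strategies can be applied to the same
merged dataset.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import TrialDesign

__all__ = [
    "EXCLUDED",
    "SCENARIOS",
    "STRATEGIES",
    "MergeSpec",
    "TrialDataset",
    "generate_trial",
    "apply_homogeneous_merges",
    "apply_heterogeneous_merges",
    "build_analysis_set",
]

#: analysis_arm sentinel for records removed from the analysis set.
EXCLUDED = -1

SCENARIOS = ("S1_homog_full", "S2_homog_partial", "S3_heter_full", "S4_heter_partial")
_SCENARIO_ALIASES = {"S1": SCENARIOS[0], "S2": SCENARIOS[1], "S3": SCENARIOS[2], "S4": SCENARIOS[3]}
STRATEGIES = ("as_one_cluster", "assign_control", "assign_intervention", "drop_merged", "completers_only")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class MergeSpec:
    """Which merge scenario to apply, how many merges, and the analysis strategy.

    Homogeneous scenarios (S1/S2) merge ``k0`` pairs in the control arm and
    ``k1`` in the intervention arm; heterogeneous scenarios (S3/S4) perform
    ``k`` merges, each pairing one control with one intervention cluster.
    ``completer_fraction`` is the fraction of each source cluster that
    finished treatment before the merge (1.0 in S1/S3, 0.5 in S2/S4 by
    convention).
    """

    scenario: str
    k0: int = 0
    k1: int = 0
    k: int = 0
    completer_fraction: float | None = None
    strategy: str = "as_one_cluster"

    def __post_init__(self) -> None:
        scen = _SCENARIO_ALIASES.get(self.scenario, self.scenario)
        if scen not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        object.__setattr__(self, "scenario", scen)
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}")
        if self.heterogeneous and self.strategy == "as_one_cluster":
            raise ValueError("as_one_cluster is only valid for homogeneous (same-arm) merges")
        if min(self.k0, self.k1, self.k) < 0:
            raise ValueError("merge counts must be non-negative")
        if self.completer_fraction is None:
            default = 1.0 if self.scenario in (SCENARIOS[0], SCENARIOS[2]) else 0.5
            object.__setattr__(self, "completer_fraction", default)
        if not 0.0 <= self.completer_fraction <= 1.0:
            raise ValueError("completer_fraction must lie in [0, 1]")

    @property
    def homogeneous(self) -> bool:
        return self.scenario in (SCENARIOS[0], SCENARIOS[1])

    @property
    def heterogeneous(self) -> bool:
        return not self.homogeneous

    @property
    def regenerates(self) -> bool:
        """Whether non-completer outcomes are re-drawn (partial-completion scenarios)."""
        return self.scenario in (SCENARIOS[1], SCENARIOS[3]) and self.completer_fraction < 1.0


@dataclass
class TrialDataset:
    """Individual-level records of one simulated trial.

    Arrays are aligned by subject; ``analysis_cluster`` / ``analysis_arm``
    start equal to the original labels and are rewritten by the merge and
    analysis-set operations. ``analysis_arm == EXCLUDED`` marks records
    outside the analysis set. ``merged_from`` maps each merged cluster
    label to its two parent labels.
    """

    subject_id: np.ndarray
    orig_cluster: np.ndarray
    analysis_cluster: np.ndarray
    orig_arm: np.ndarray
    analysis_arm: np.ndarray
    completer: np.ndarray
    outcome: np.ndarray
    design: TrialDesign
    mu0: float = 0.0
    mu1: float = 0.2
    seed: object = None
    merge_spec: MergeSpec | None = None
    merged_from: dict[int, tuple[int, int]] = field(default_factory=dict)

    def copy(self) -> "TrialDataset":
        return dataclasses.replace(
            self,
            subject_id=self.subject_id.copy(),
            orig_cluster=self.orig_cluster.copy(),
            analysis_cluster=self.analysis_cluster.copy(),
            orig_arm=self.orig_arm.copy(),
            analysis_arm=self.analysis_arm.copy(),
            completer=self.completer.copy(),
            outcome=self.outcome.copy(),
            merged_from=dict(self.merged_from),
        )

    @property
    def n_subjects(self) -> int:
        return self.subject_id.size

    @property
    def included(self) -> np.ndarray:
        """Boolean mask of records in the analysis set."""
        return self.analysis_arm != EXCLUDED

    @property
    def in_merged_cluster(self) -> np.ndarray:
        if not self.merged_from:
            return np.zeros(self.n_subjects, dtype=bool)
        return np.isin(self.analysis_cluster, list(self.merged_from))

    def analysis_cluster_sizes(self) -> np.ndarray:
        """Sizes of the analysis clusters (included records only)."""
        return np.unique(self.analysis_cluster[self.included], return_counts=True)[1]

    def cluster_table(self) -> pd.DataFrame:
        """Per-cluster summary: label, arm (-1 if mixed/excluded), size, parents."""
        rows = []
        for label in np.unique(self.analysis_cluster[self.included]):
            mask = (self.analysis_cluster == label) & self.included
            arms = np.unique(self.analysis_arm[mask])
            rows.append(
                {
                    "cluster": int(label),
                    "arm": int(arms[0]) if arms.size == 1 else -1,
                    "size": int(mask.sum()),
                    "merged_from": self.merged_from.get(int(label)),
                }
            )
        return pd.DataFrame(rows)

    # ---- serialisation -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        arm = np.where(self.included, self.analysis_arm.astype(object), "excluded")
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "orig_cluster": self.orig_cluster,
                "analysis_cluster": self.analysis_cluster,
                "orig_arm": self.orig_arm,
                "analysis_arm": arm,
                "completer": self.completer,
                "outcome": self.outcome,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the long-format CSV plus a JSON metadata sidecar (``<path>.meta.json``)."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "design": dataclasses.asdict(self.design),
            "merge_spec": dataclasses.asdict(self.merge_spec) if self.merge_spec else None,
            "mu0": self.mu0,
            "mu1": self.mu1,
            "seed": self.seed if isinstance(self.seed, (int, str, type(None))) else str(self.seed),
            "merged_from": {str(k): list(v) for k, v in self.merged_from.items()},
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialDataset":
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else None
        arm = df["analysis_arm"].replace("excluded", EXCLUDED).astype(int).to_numpy()
        design = (
            TrialDesign(**meta["design"])
            if meta
            else TrialDesign(delta=0.2, c=int(df["orig_cluster"].nunique()))
        )
        spec = MergeSpec(**meta["merge_spec"]) if meta and meta.get("merge_spec") else None
        return cls(
            subject_id=df["subject_id"].to_numpy(),
            orig_cluster=df["orig_cluster"].to_numpy(),
            analysis_cluster=df["analysis_cluster"].to_numpy(),
            orig_arm=df["orig_arm"].to_numpy(),
            analysis_arm=arm,
            completer=df["completer"].to_numpy(dtype=bool),
            outcome=df["outcome"].to_numpy(dtype=float),
            design=design,
            mu0=meta["mu0"] if meta else 0.0,
            mu1=meta["mu1"] if meta else 0.2,
            seed=meta.get("seed") if meta else None,
            merge_spec=spec,
            merged_from={int(k): tuple(v) for k, v in meta["merged_from"].items()} if meta else {},
        )


def generate_trial(design: TrialDesign, mu0: float = 0.0, mu1: float = 0.2, seed=None) -> TrialDataset:
    """Draw one trial from the two-level model.

    Clusters ``0 .. c0-1`` form the control arm and the remainder the
    intervention arm (counts per ``design.lam``); every cluster holds
    ``design.m`` individuals. One cluster effect is drawn per cluster and
    one error per individual; the same seed reproduces the dataset exactly.
    """
    rng = _as_rng(seed)
    c, m = design.c, design.m
    c0, _ = design.arm_sizes
    n = c * m
    cluster = np.repeat(np.arange(c), m)
    arm = (cluster >= c0).astype(np.int64)
    u = rng.normal(0.0, math.sqrt(design.sigma_b2), size=c)
    eps = rng.normal(0.0, math.sqrt(design.sigma_w2), size=n)
    mu = np.where(arm == 1, mu1, mu0)
    outcome = mu + u[cluster] + eps
    return TrialDataset(
        subject_id=np.arange(n),
        orig_cluster=cluster,
        analysis_cluster=cluster.copy(),
        orig_arm=arm,
        analysis_arm=arm.copy(),
        completer=np.ones(n, dtype=bool),
        outcome=outcome,
        design=design,
        mu0=mu0,
        mu1=mu1,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
    )


def _mark_completers(data: TrialDataset, parents: np.ndarray, fraction: float) -> None:
    """Flag the first ``floor(fraction*m)`` members (by within-cluster index) of
    each parent cluster as completers, the rest as non-completers."""
    m = data.design.m
    n_keep = math.floor(fraction * m)
    within = data.subject_id % m  # generation layout: cluster j fills j*m .. (j+1)*m - 1
    in_parent = np.isin(data.orig_cluster, parents)
    data.completer[in_parent & (within >= n_keep)] = False


def _regenerate_noncompleters(
    data: TrialDataset, merged_labels: list[int], mu_fn, rng: np.random.Generator
) -> None:
    """Redraw non-completer outcomes in each merged cluster: one fresh shared
    cluster effect per merged cluster plus independent individual errors.
    ``mu_fn(label, orig_arm_array) -> mean array`` supplies the treatment mean."""
    sb = math.sqrt(data.design.sigma_b2)
    sw = math.sqrt(data.design.sigma_w2)
    for label in merged_labels:
        mask = (data.analysis_cluster == label) & ~data.completer
        n_new = int(mask.sum())
        if n_new == 0:
            continue
        u_new = rng.normal(0.0, sb)
        mu = mu_fn(label, data.orig_arm[mask])
        data.outcome[mask] = mu + u_new + rng.normal(0.0, sw, size=n_new)


def _pair_up(eligible: np.ndarray, k: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    chosen = rng.permutation(eligible)[: 2 * k]
    return [(int(chosen[2 * i]), int(chosen[2 * i + 1])) for i in range(k)]


def apply_homogeneous_merges(data: TrialDataset, spec: MergeSpec, seed=None) -> TrialDataset:
    """Merge ``k0`` / ``k1`` same-arm cluster pairs (scenarios S1 and S2).

    Pairs are sampled uniformly without replacement among never-merged
    clusters of each arm and relabelled to a fresh merged cluster. S1 leaves
    every outcome untouched; S2 regenerates non-completers' outcomes with
    the arm's own treatment mean and one new shared cluster effect.
    """
    if not spec.homogeneous:
        raise ValueError("apply_homogeneous_merges requires scenario S1 or S2")
    rng = _as_rng(seed)
    out = data.copy()
    out.merge_spec = spec
    c0, c1 = data.design.arm_sizes
    if 2 * spec.k0 > c0 or 2 * spec.k1 > c1:
        raise ValueError("not enough unmerged clusters in an arm for the requested merges")
    next_label = max(out.merged_from, default=data.design.c - 1) + 1
    arm_clusters = (np.arange(0, c0), np.arange(c0, c0 + c1))
    merged_labels: list[int] = []
    for arm, k_arm in ((0, spec.k0), (1, spec.k1)):
        for a, b in _pair_up(arm_clusters[arm], k_arm, rng):
            out.analysis_cluster[np.isin(out.orig_cluster, (a, b))] = next_label
            out.merged_from[next_label] = (a, b)
            merged_labels.append(next_label)
            if spec.regenerates:
                _mark_completers(out, np.array([a, b]), spec.completer_fraction)
            next_label += 1
    if spec.regenerates:
        _regenerate_noncompleters(
            out,
            merged_labels,
            lambda label, arms: np.where(arms == 1, out.mu1, out.mu0),
            rng,
        )
    return out


def apply_heterogeneous_merges(data: TrialDataset, spec: MergeSpec, seed=None) -> TrialDataset:
    """Merge ``k`` cross-arm cluster pairs (scenarios S3 and S4).

    Each merge joins one randomly chosen control cluster with one
    intervention cluster. S3 keeps all outcomes (everyone completed). S4
    regenerates non-completers with the treatment mean of the merged
    cluster's post-merge arm: ``mu0`` under ``assign_control``, ``mu1``
    under ``assign_intervention``; under ``drop_merged`` /
    ``completers_only`` those records never enter the analysis, and the
    pre-merge arm's mean is used so the record stream does not depend on
    the discarded value.
    """
    if not spec.heterogeneous:
        raise ValueError("apply_heterogeneous_merges requires scenario S3 or S4")
    rng = _as_rng(seed)
    out = data.copy()
    out.merge_spec = spec
    c0, c1 = data.design.arm_sizes
    if spec.k > min(c0, c1):
        raise ValueError("not enough clusters in an arm for the requested cross-arm merges")
    ctrl = rng.permutation(np.arange(0, c0))[: spec.k]
    trt = rng.permutation(np.arange(c0, c0 + c1))[: spec.k]
    next_label = max(out.merged_from, default=data.design.c - 1) + 1
    merged_labels: list[int] = []
    for a, b in zip(ctrl, trt):
        out.analysis_cluster[np.isin(out.orig_cluster, (a, b))] = next_label
        out.merged_from[next_label] = (int(a), int(b))
        merged_labels.append(next_label)
        if spec.regenerates:
            _mark_completers(out, np.array([a, b]), spec.completer_fraction)
        next_label += 1
    if spec.regenerates:
        if spec.strategy == "assign_control":
            mu_fn = lambda label, arms: out.mu0
        elif spec.strategy == "assign_intervention":
            mu_fn = lambda label, arms: out.mu1
        else:  # drop_merged / completers_only: value never analysed
            mu_fn = lambda label, arms: np.where(arms == 1, out.mu1, out.mu0)
        _regenerate_noncompleters(out, merged_labels, mu_fn, rng)
    return out


def build_analysis_set(data: TrialDataset, strategy: str | None = None) -> TrialDataset:
    """Assign analysis arm/cluster labels (or exclusion) per the chosen strategy.

    * ``as_one_cluster`` — merged pair analysed as a single cluster in its
      (common) randomised arm; homogeneous merges only.
    * ``assign_control`` / ``assign_intervention`` — every member of a
      merged cluster is analysed in arm 0 / 1.
    * ``drop_merged`` — merged clusters excluded entirely.
    * ``completers_only`` — non-completers excluded; completers analysed
      under their original cluster and arm.
    """
    if strategy is None:
        strategy = data.merge_spec.strategy if data.merge_spec else "as_one_cluster"
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    out = data.copy()
    merged = out.in_merged_cluster
    out.analysis_arm = out.orig_arm.copy()
    if strategy == "as_one_cluster":
        het = any(
            data.orig_arm[data.orig_cluster == a][0] != data.orig_arm[data.orig_cluster == b][0]
            for a, b in data.merged_from.values()
        )
        if het:
            raise ValueError("as_one_cluster cannot be applied to heterogeneous (cross-arm) merges")
    elif strategy == "assign_control":
        out.analysis_arm[merged] = 0
    elif strategy == "assign_intervention":
        out.analysis_arm[merged] = 1
    elif strategy == "drop_merged":
        out.analysis_arm[merged] = EXCLUDED
    elif strategy == "completers_only":
        out.analysis_cluster = out.orig_cluster.copy()
        out.analysis_arm[~out.completer] = EXCLUDED
    return out
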