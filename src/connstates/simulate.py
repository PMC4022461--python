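"""Seeded synthetic cohort generator.

Emulates the data structure the analysis consumes: sparse per-subject SC
matrices sharing a cross-subject backbone, state-dependent FC whose upper
tail is enriched or depleted in specific coupling classes, and behavioral
scores with group-dependent deviations.

Three subject archetypes plant the grouping structure:

* ``primary`` — attention and memory engage similar structural couplings
  (both PN- plus within-network-enriched), distinct from rest.
* ``secondary_RM`` — the memory-state deviations are rest-like, so rest and
  memory are the least-separated states.
* ``secondary_RA`` — the attention-state deviations are rest-like.

All archetypes share the same resting-state structure: NN couplings carry
the strongest correlations, PP next, and PN couplings are anticorrelated
relative to both (weak r), mirroring the task-positive/task-negative
anticorrelation that defines the networks.

FC for pair (i, j) of coupling class c in state s is generated edgewise as

    FC_ij = base_c(s) + slope_c(s) * log(1 + w_ij) * 1[w_ij > 0] + eps,
    eps ~ Normal(0, fc_noise_sd),  clipped to [-0.999, 0.999],

so strong structural connections can carry systematically stronger
correlations (slope > 0). Task states are generated directly as deviations
from rest (dFC), the quantity the pipeline thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core import (
    Cohort,
    CouplingClass,
    COUPLING_CLASSES,
    LabelingError,
    RegionLabeling,
    STATES,
    SubjectConnectome,
    pair_class_indices,
)

ARCHETYPES = ("primary", "secondary_RM", "secondary_RA")

_CLASS_ORDER = [c.value for c in COUPLING_CLASSES]


def _class_vector(d: dict[str, float]) -> np.ndarray:
    return np.array([d[c] for c in _CLASS_ORDER], dtype=float)


# Per-state class baselines/slopes for each archetype. Values are synthetic
# design choices (no empirical effect sizes exist for these enrichments),
# chosen so each archetype's three states occupy well-separated directions
# in the (delta_n_PN, delta_n_PP - delta_n_NN) plane.
_REST = {
    "base": {"PP": 0.35, "NN": 0.37, "PN": 0.02, "PO": 0.15, "NO": 0.15, "OO": 0.15},
    "slope": {"PP": 0.02, "NN": 0.02, "PN": 0.02, "PO": 0.02, "NO": 0.02, "OO": 0.02},
}
# Task-like deviations: PN plus one within-network class enriched.
_TASK_ATT = {
    "base": {"PP": 0.19, "PN": 0.19, "NN": 0.02, "PO": 0.02, "NO": 0.02, "OO": 0.02},
    "slope": {"PP": 0.02, "PN": 0.02, "NN": 0.0, "PO": 0.0, "NO": 0.0, "OO": 0.0},
}
_TASK_MEM = {
    "base": {"NN": 0.19, "PN": 0.19, "PP": 0.02, "PO": 0.02, "NO": 0.02, "OO": 0.02},
    "slope": {"NN": 0.02, "PN": 0.02, "PP": 0.0, "PO": 0.0, "NO": 0.0, "OO": 0.0},
}
# Rest-like deviations: within-network enrichment with PN depletion, so the
# state lands in the same state-space direction as rest.
_TASK_RESTLIKE = {
    "base": {"NN": 0.19, "PP": 0.17, "PN": -0.06, "PO": 0.02, "NO": 0.02, "OO": 0.02},
    "slope": {"NN": 0.02, "PP": 0.02, "PN": 0.0, "PO": 0.0, "NO": 0.0, "OO": 0.0},
}


@dataclass(frozen=True)
class ArchetypeSpec:
    """FC generation parameters for one subject archetype."""

    name: str
    fc_base: dict[str, dict[str, float]]   # state -> class -> baseline
    fc_slope: dict[str, dict[str, float]]  # state -> class -> log-SC coefficient
    fc_noise_sd: float = 0.08

    def __post_init__(self):
        if self.fc_noise_sd <= 0:
            raise ValueError("fc_noise_sd must be > 0")
        for state in STATES:
            if state not in self.fc_base or state not in self.fc_slope:
                raise ValueError(f"archetype {self.name}: missing state {state}")

    def base_vector(self, state: str) -> np.ndarray:
        return _class_vector(self.fc_base[state])

    def slope_vector(self, state: str) -> np.ndarray:
        return _class_vector(self.fc_slope[state])


def default_archetypes(fc_noise_sd: float = 0.08) -> dict[str, ArchetypeSpec]:
    """The three built-in archetypes with the default planted effect sizes."""
    def mk(name, att, mem):
        return ArchetypeSpec(
            name=name,
            fc_base={"rest": _REST["base"], "attention": att["base"], "memory": mem["base"]},
            fc_slope={"rest": _REST["slope"], "attention": att["slope"], "memory": mem["slope"]},
            fc_noise_sd=fc_noise_sd,
        )

    return {
        "primary": mk("primary", _TASK_ATT, _TASK_MEM),
        "secondary_RM": mk("secondary_RM", _TASK_ATT, _TASK_RESTLIKE),
        "secondary_RA": mk("secondary_RA", _TASK_RESTLIKE, _TASK_MEM),
    }


def structureless_archetypes(fc_noise_sd: float = 0.08) -> dict[str, ArchetypeSpec]:
    """Archetypes with NO class structure: every coupling class shares the
    same baseline and slope in every state. Used to calibrate the
    label-permutation null (nothing is planted, so the null should hold).
    """
    flat_rest = {c: 0.20 for c in _CLASS_ORDER}
    flat_task = {c: 0.05 for c in _CLASS_ORDER}
    slope = {c: 0.02 for c in _CLASS_ORDER}
    spec = ArchetypeSpec(
        name="structureless",
        fc_base={"rest": flat_rest, "attention": flat_task, "memory": flat_task},
        fc_slope={"rest": slope, "attention": slope, "memory": slope},
        fc_noise_sd=fc_noise_sd,
    )
    return {name: spec for name in ARCHETYPES}


#: Behavioral group means. Secondary groups are planted as outliers: RT offset
#: from the cohort center (slow for RM, fast for RA) and larger attention-vs-
#: memory splits in criterion-switch score and d-prime.
DEFAULT_BEHAVIOR_SPEC = {
    "primary": {
        "RT_A": 0.72, "RT_M": 0.75, "CS_A": 0.50, "CS_M": 0.50, "DP_A": 2.0, "DP_M": 2.0,
    },
    "secondary_RM": {
        "RT_A": 0.92, "RT_M": 0.95, "CS_A": 0.70, "CS_M": 0.30, "DP_A": 2.6, "DP_M": 1.4,
    },
    "secondary_RA": {
        "RT_A": 0.52, "RT_M": 0.55, "CS_A": 0.30, "CS_M": 0.70, "DP_A": 1.4, "DP_M": 2.6,
    },
    "sd": {"RT": 0.08, "CS": 0.10, "DP": 0.30},
}


@dataclass
class CohortSpec:
    """Full configuration of one synthetic cohort.

    Defaults mirror the study conditions: 71 subjects, archetype mixture
    (0.66, 0.23, 0.11), and a structural backbone retained per subject with
    probability 0.9 so the 80%-consistency mask is exercised nontrivially.
    """

    n_subjects: int = 71
    n_regions: int = 200
    label_fractions: tuple[float, float, float] = (0.3, 0.3, 0.4)  # (P, N, O)
    backbone_edge_prob: dict[str, float] = field(
        default_factory=lambda: {c: 0.2 for c in _CLASS_ORDER}
    )
    weight_lognormal: tuple[float, float] = (1.0, 1.0)  # (mu, sigma)
    backbone_retention_prob: float = 0.9
    spurious_edge_prob: float = 0.01
    archetype_mixture: tuple[float, float, float] = (0.66, 0.23, 0.11)
    fc_noise_sd: float = 0.08
    behavior_spec: dict = field(default_factory=lambda: DEFAULT_BEHAVIOR_SPEC)
    structureless: bool = False  # drop all planted class structure (null calibration)
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 9:
            raise ValueError("n_regions must be >= 9")
        if abs(sum(self.label_fractions) - 1.0) > 1e-9:
            raise ValueError("label_fractions must sum to 1")
        if abs(sum(self.archetype_mixture) - 1.0) > 1e-9:
            raise ValueError("archetype_mixture must sum to 1")
        for name, p in self.backbone_edge_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"backbone_edge_prob[{name}] not in [0,1]")
        for p in (self.backbone_retention_prob, self.spurious_edge_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")

    def archetypes(self) -> dict[str, ArchetypeSpec]:
        if self.structureless:
            return structureless_archetypes(self.fc_noise_sd)
        return default_archetypes(self.fc_noise_sd)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["label_fractions"] = list(self.label_fractions)
        d["archetype_mixture"] = list(self.archetype_mixture)
        d["weight_lognormal"] = list(self.weight_lognormal)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortSpec":
        d = yaml.safe_load(text)
        for key in ("label_fractions", "archetype_mixture", "weight_lognormal"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def largest_remainder_counts(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer counts summing exactly to n, by largest-remainder rounding."""
    raw = [n * f for f in fractions]
    counts = [math.floor(x) for x in raw]
    remainders = [x - c for x, c in zip(raw, counts)]
    short = n - sum(counts)
    # break remainder ties by position for determinism
    order = sorted(range(len(fractions)), key=lambda i: (-remainders[i], i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def generate_labels(spec: CohortSpec, rng: Optional[np.random.Generator] = None) -> RegionLabeling:
    """Assign P/N/O labels with exact largest-remainder class counts."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    counts = largest_remainder_counts(spec.n_regions, spec.label_fractions)
    if min(counts) == 0:
        raise LabelingError(
            f"label_fractions {spec.label_fractions} leave a class empty at "
            f"n_regions={spec.n_regions}; raise the fraction or region count"
        )
    labels = np.repeat(np.array(["P", "N", "O"]), counts)
    rng.shuffle(labels)
    return RegionLabeling(labels=labels.tolist())


@dataclass
class Backbone:
    """Cross-subject consistent structural scaffold (upper-triangle edges)."""

    rows: np.ndarray
    cols: np.ndarray
    weights: np.ndarray
    n_regions: int

    @property
    def n_edges(self) -> int:
        return len(self.rows)

    def support_matrix(self) -> np.ndarray:
        m = np.zeros((self.n_regions, self.n_regions), dtype=bool)
        m[self.rows, self.cols] = True
        return m | m.T


def generate_structural_backbone(
    labeling: RegionLabeling, spec: CohortSpec, rng: Optional[np.random.Generator] = None
) -> Backbone:
    """Sample the shared backbone: per-class edge probabilities, lognormal weights."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
    n = labeling.n_regions
    iu, ju = np.triu_indices(n, k=1)
    cls_idx = labeling.pair_class_indices(iu, ju)
    probs = _class_vector(spec.backbone_edge_prob)[cls_idx]
    present = rng.random(len(iu)) < probs
    rows, cols, cls_sel = iu[present], ju[present], cls_idx[present]
    mu, sigma = spec.weight_lognormal
    weights = np.ceil(rng.lognormal(mean=mu, sigma=sigma, size=len(rows)))
    weights = np.maximum(weights, 1.0)
    for want, name in ((0, "PP"), (1, "NN"), (2, "PN")):
        if not (cls_sel == want).any():
            raise ValueError(
                f"backbone has no {name} edges; raise backbone_edge_prob['{name}'] "
                "or the region count"
            )
    return Backbone(rows=rows, cols=cols, weights=weights, n_regions=n)


def generate_subject_sc(
    backbone: Backbone, spec: CohortSpec, rng: np.random.Generator
) -> np.ndarray:
    """Subject SC: backbone edges retained with jittered weights, plus spurious edges."""
    n = backbone.n_regions
    sc = np.zeros((n, n), dtype=float)
    keep = rng.random(backbone.n_edges) < spec.backbone_retention_prob
    jitter = rng.uniform(0.8, 1.2, size=backbone.n_edges)
    w = np.maximum(np.rint(backbone.weights * jitter), 1.0)
    sc[backbone.rows[keep], backbone.cols[keep]] = w[keep]
    if spec.spurious_edge_prob > 0:
        iu, ju = np.triu_indices(n, k=1)
        empty = sc[iu, ju] == 0
        bb = np.zeros(len(iu), dtype=bool)
        support = backbone.support_matrix()
        bb = support[iu, ju]
        candidate = empty & ~bb
        add = candidate & (rng.random(len(iu)) < spec.spurious_edge_prob)
        sc[iu[add], ju[add]] = 1.0
    return sc + sc.T


def generate_subject_fc(
    sc: np.ndarray,
    labeling: RegionLabeling,
    archetype: ArchetypeSpec,
    state: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Edgewise FC (rest) or dFC (tasks) with planted class structure."""
    n = labeling.n_regions
    iu, ju = np.triu_indices(n, k=1)
    cls_idx = labeling.pair_class_indices(iu, ju)
    base = archetype.base_vector(state)[cls_idx]
    slope = archetype.slope_vector(state)[cls_idx]
    w = sc[iu, ju]
    vals = base + slope * np.log1p(w) * (w > 0)
    vals = vals + rng.normal(0.0, archetype.fc_noise_sd, size=len(iu))
    vals = np.clip(vals, -0.999, 0.999)
    fc = np.zeros((n, n), dtype=float)
    fc[iu, ju] = vals
    return fc + fc.T


_BEHAVIOR_MEASURES = ("RT_A", "RT_M", "CS_A", "CS_M", "DP_A", "DP_M")


def generate_behavior(
    group: str, behavior_spec: dict, rng: np.random.Generator
) -> dict[str, float]:
    """One subject's behavioral record drawn from group-specific normals."""
    if group not in ARCHETYPES:
        raise ValueError(f"unknown group {group!r}")
    means = behavior_spec[group]
    sds = behavior_spec["sd"]
    rec = {}
    for m in _BEHAVIOR_MEASURES:
        sd = sds[m.split("_")[0]]
        val = float(rng.normal(means[m], sd)) if sd > 0 else float(means[m])
        if m.startswith("RT"):
            val = max(val, 1e-3)  # reaction times are strictly positive
        rec[m] = val
    return rec


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full cohort, reproducible from ``spec.seed``.

    Per-subject randomness is drawn from independent children of the spec's
    seed sequence, so cohorts are identical across runs with the same spec.
    The planted per-subject archetype is recorded in ``cohort.ground_truth``.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_labels, ss_backbone, ss_arch, *ss_subjects = root.spawn(3 + spec.n_subjects)
    labeling = generate_labels(spec, np.random.default_rng(ss_labels))
    backbone = generate_structural_backbone(labeling, spec, np.random.default_rng(ss_backbone))
    archetypes = spec.archetypes()
    arch_rng = np.random.default_rng(ss_arch)
    assignment = arch_rng.choice(len(ARCHETYPES), size=spec.n_subjects, p=spec.archetype_mixture)

    subjects, behavior_rows, truth_rows = [], [], []
    for k in range(spec.n_subjects):
        rng = np.random.default_rng(ss_subjects[k])
        sid = f"sub-{k:03d}"
        group = ARCHETYPES[assignment[k]]
        arch = archetypes[group]
        sc = generate_subject_sc(backbone, spec, rng)
        fc = {s: generate_subject_fc(sc, labeling, arch, s, rng) for s in STATES}
        subjects.append(
            SubjectConnectome(
                subject_id=sid,
                sc=sc,
                fc_rest=fc["rest"],
                fc_attention=fc["attention"],
                fc_memory=fc["memory"],
            )
        )
        behavior_rows.append({"subject_id": sid, **generate_behavior(group, spec.behavior_spec, rng)})
        truth_rows.append({"subject_id": sid, "archetype": group})

    return Cohort(
        subjects=subjects,
        labeling=labeling,
        behavior=pd.DataFrame(behavior_rows),
        ground_truth=pd.DataFrame(truth_rows),
    )


def generate_behavior_table(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Behavior and planted group labels only, without connectome synthesis.

    Light-weight path for behavioral power studies: archetypes are drawn
    from the mixture and behavioral records from the group normals, using
    a seed stream independent of :func:`generate_cohort`'s.

    Returns ``(behavior, ground_truth)`` data frames.
    """
    root = np.random.SeedSequence([spec.seed, 0x0BE4])
    ss_arch, ss_beh = root.spawn(2)
    assignment = np.random.default_rng(ss_arch).choice(
        len(ARCHETYPES), size=spec.n_subjects, p=spec.archetype_mixture
    )
    rng = np.random.default_rng(ss_beh)
    behavior_rows, truth_rows = [], []
    for k in range(spec.n_subjects):
        sid = f"sub-{k:03d}"
        group = ARCHETYPES[assignment[k]]
        behavior_rows.append({"subject_id": sid, **generate_behavior(group, spec.behavior_spec, rng)})
        truth_rows.append({"subject_id": sid, "archetype": group})
    return pd.DataFrame(behavior_rows), pd.DataFrame(truth_rows)


def raw_task_fc(subject: SubjectConnectome, state: str) -> np.ndarray:
    """Convenience: reconstruct raw task FC as rest + deviation for round-trips."""
    if state not in ("attention", "memory"):
        raise ValueError("raw task FC defined for attention/memory only")
    return subject.fc_rest + subject.fc_for_state(state)
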