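"""Synthetic multi-subject cohorts with planted community structure.

Each subject gets a continuous covariate (log contrast sensitivity drawn from
a truncated normal), a binary sex indicator, motion traces with occasional
spike frames, and a node time-series whose correlation structure encodes a
jittered copy of a planted partition. The jitter rate of one target community
is a clamped linear function of the covariate, so lower covariate values yield
more degraded community structure — the effect every downstream stage is
designed to detect.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .community_detect import CommunityPartition
from .signal_cleaning import framewise_displacement

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "plant_partition",
    "jitter_membership",
    "simulate_bold",
    "generate_cohort",
    "generate_conditions",
    "pelli_robson_to_logcs",
    "write_cohort",
    "read_cohort",
]

#: physical range of the 48-letter chart in log units (0.05 per letter)
CS_RANGE = (0.0, 2.4)
LETTERS_PER_LOG_UNIT = 20  # 0.05 log units per letter

#: BOLD-like scaling applied to the unit-variance simulated signals so that
#: percent-signal-change DVARS is well defined (~0.2% frame-to-frame change);
#: an affine rescaling leaves every correlation untouched.
BOLD_BASELINE = 100.0
BOLD_AMPLITUDE = 0.15


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 40
    n_nodes: int = 600
    n_timepoints: int = 150
    tr_seconds: float = 2.0
    community_sizes: tuple[int, ...] = (75,) * 8
    target_community: int = 0
    within_corr: float = 0.4
    covariate_mean: float = 1.71
    covariate_sd: float = 0.14
    jitter_slope: float = 1.5
    jitter_intercept: float = 0.35
    sex_fraction: float = 0.5
    motion_spike_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.community_sizes) != self.n_nodes:
            raise ValueError("community_sizes must sum to n_nodes")
        if not 0 <= self.within_corr < 1:
            raise ValueError("within_corr must lie in [0, 1)")
        if not 0 <= self.jitter_intercept <= 1:
            raise ValueError("jitter_intercept must lie in [0, 1]")
        if not 0 <= self.target_community < len(self.community_sizes):
            raise ValueError("target_community out of range")
        if self.covariate_sd < 0:
            raise ValueError("covariate_sd must be nonnegative")

    def jitter_rate(self, cs: float) -> float:
        """Clamped linear covariate -> jitter link g(c)."""
        g = self.jitter_intercept - self.jitter_slope * (cs - self.covariate_mean)
        return float(np.clip(g, 0.0, 1.0))

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["community_sizes"] = list(d["community_sizes"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        d = json.loads(text)
        d["community_sizes"] = tuple(d["community_sizes"])
        return cls(**d)


@dataclass
class SubjectRecord:
    subject_id: str
    cs: float
    sex: int
    volumes_removed: int
    timeseries: np.ndarray          # n_nodes x n_timepoints
    motion_params: np.ndarray       # n_timepoints x 6
    true_partition: Optional[CommunityPartition] = None


def plant_partition(community_sizes: Sequence[int], seed: int = 0) -> CommunityPartition:
    """Assign each node to exactly one community with the requested sizes.

    Node-to-community assignment is shuffled so community membership carries
    no positional structure.
    """
    sizes = list(community_sizes)
    if not sizes:
        raise ValueError("community_sizes must be non-empty")
    if any(s <= 0 for s in sizes):
        raise ValueError("every community size must be positive")
    labels = np.repeat(np.arange(len(sizes)), sizes)
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    return CommunityPartition(labels)


def jitter_membership(
    partition: CommunityPartition,
    target: int,
    rate: float,
    seed: int = 0,
) -> CommunityPartition:
    """Independently reassign each target-community node with probability
    ``rate`` to a uniformly chosen *other* community."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    labels = partition.labels.copy()
    uniq = np.unique(labels)
    if target not in uniq:
        raise ValueError(f"target community {target} not present")
    if rate > 0 and uniq.size < 2:
        raise ValueError("cannot jitter with a single community")
    rng = np.random.default_rng(seed)
    members = np.flatnonzero(labels == target)
    move = members[rng.random(members.size) < rate]
    others = uniq[uniq != target]
    labels[move] = rng.choice(others, size=move.size)
    return CommunityPartition(labels)


def simulate_bold(
    partition: CommunityPartition,
    n_timepoints: int,
    within_corr: float,
    seed: int = 0,
) -> np.ndarray:
    """One-factor-per-community Gaussian signals.

    node_i(t) = sqrt(rho) * latent[c(i)](t) + sqrt(1-rho) * noise_i(t), so the
    expected Pearson correlation is rho within a community and 0 across.
    """
    if not 0 <= within_corr < 1:
        raise ValueError("within_corr must lie in [0, 1)")
    if n_timepoints < 3:
        raise ValueError("n_timepoints must be >= 3")
    rng = np.random.default_rng(seed)
    labels = partition.labels
    uniq, inv = np.unique(labels, return_inverse=True)
    latents = rng.standard_normal((uniq.size, n_timepoints))
    noise = rng.standard_normal((labels.size, n_timepoints))
    return np.sqrt(within_corr) * latents[inv] + np.sqrt(1.0 - within_corr) * noise


def _simulate_motion(n_timepoints: int, spike_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Small-amplitude drifting motion with occasional >0.5 mm spike frames."""
    steps = rng.normal(0.0, 0.01, size=(n_timepoints, 6))
    steps[:, 3:] *= 1e-3  # rotations in radians stay small
    motion = np.cumsum(steps, axis=0)
    spikes = np.flatnonzero(rng.random(n_timepoints - 1) < spike_rate) + 1
    motion[spikes, 0] += 1.0  # one-frame 1 mm translation excursions
    return motion


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw covariates, jitter the planted partition per subject, and simulate
    time-series and motion traces. Deterministic given the config."""
    conditions = generate_conditions(config, {"default": (config.jitter_intercept,
                                                          config.jitter_slope)})
    return conditions["default"]


def generate_conditions(
    config: CohortConfig,
    condition_jitter: dict[str, tuple[float, float]],
) -> dict[str, list[SubjectRecord]]:
    """Generate one cohort per condition, sharing the per-subject covariate,
    sex and motion draws across conditions (as in a within-subject design);
    only the planted jitter (and BOLD noise) differs between conditions."""
    root = np.random.SeedSequence(config.seed)
    template = plant_partition(config.community_sizes, config.seed)
    subject_seeds = root.spawn(config.n_subjects)

    lo, hi = CS_RANGE
    a = (lo - config.covariate_mean) / config.covariate_sd
    b = (hi - config.covariate_mean) / config.covariate_sd

    out: dict[str, list[SubjectRecord]] = {name: [] for name in condition_jitter}
    for i, sseed in enumerate(subject_seeds):
        rng = np.random.default_rng(sseed)
        cs = float(stats.truncnorm.rvs(
            a, b, loc=config.covariate_mean, scale=config.covariate_sd, random_state=rng
        ))
        sex = int(rng.random() < config.sex_fraction)
        motion = _simulate_motion(config.n_timepoints, config.motion_spike_rate, rng)
        fd = framewise_displacement(motion)
        volumes_removed = int(np.sum(fd > 0.5))
        for cond, (intercept, slope) in condition_jitter.items():
            cfg = dataclasses.replace(config, jitter_intercept=intercept,
                                      jitter_slope=slope)
            rate = cfg.jitter_rate(cs)
            jit_seed, bold_seed = rng.integers(0, 2**63 - 1, size=2)
            planted = jitter_membership(template, config.target_community, rate,
                                        seed=int(jit_seed))
            ts = BOLD_BASELINE + BOLD_AMPLITUDE * simulate_bold(
                planted, config.n_timepoints, config.within_corr,
                seed=int(bold_seed))
            out[cond].append(SubjectRecord(
                subject_id=f"sub-{i:03d}",
                cs=cs,
                sex=sex,
                volumes_removed=volumes_removed,
                timeseries=ts,
                motion_params=motion,
                true_partition=planted,
            ))
    return out


def pelli_robson_to_logcs(n_letters_correct: int) -> float:
    """Letter-by-letter chart scoring: 0.05 log units per correct letter."""
    if not 0 <= n_letters_correct <= 48:
        raise ValueError("letter count must lie in [0, 48]")
    return n_letters_correct / LETTERS_PER_LOG_UNIT


# ---------------------------------------------------------------------------
# serialization (plain-text, byte-stable)

def write_cohort(directory: str | Path, subjects: list[SubjectRecord],
                 config: Optional[CohortConfig] = None) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    if config is not None:
        (d / "config.json").write_text(config.to_json() + "\n")
    with open(d / "covariates.tsv", "w") as fh:
        fh.write("subject_id\tcs\tsex\tvolumes_removed\n")
        for s in subjects:
            fh.write(f"{s.subject_id}\t{s.cs:.10g}\t{s.sex}\t{s.volumes_removed}\n")
    for s in subjects:
        np.savetxt(d / f"timeseries_{s.subject_id}.tsv", s.timeseries,
                   fmt="%.10g", delimiter="\t")
        np.savetxt(d / f"motion_{s.subject_id}.tsv", s.motion_params,
                   fmt="%.10g", delimiter="\t")
        if s.true_partition is not None:
            np.savetxt(d / f"true_partition_{s.subject_id}.tsv",
                       np.column_stack((np.arange(s.true_partition.n_nodes),
                                        s.true_partition.labels)),
                       fmt="%d", delimiter="\t", header="node\tcommunity",
                       comments="")


def read_cohort(directory: str | Path) -> list[SubjectRecord]:
    d = Path(directory)
    subjects = []
    with open(d / "covariates.tsv") as fh:
        header = fh.readline()
        for line in fh:
            sid, cs, sex, vols = line.rstrip("\n").split("\t")
            ts = np.loadtxt(d / f"timeseries_{sid}.tsv", delimiter="\t", ndmin=2)
            motion = np.loadtxt(d / f"motion_{sid}.tsv", delimiter="\t", ndmin=2)
            part_path = d / f"true_partition_{sid}.tsv"
            part = None
            if part_path.exists():
                arr = np.loadtxt(part_path, delimiter="\t", skiprows=1, dtype=np.int64,
                                 ndmin=2)
                part = CommunityPartition(arr[np.argsort(arr[:, 0]), 1])
            subjects.append(SubjectRecord(sid, float(cs), int(sex), int(vols),
                                          ts, motion, part))
    return subjects
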