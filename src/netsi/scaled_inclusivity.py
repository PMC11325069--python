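"""Node-wise scaled inclusivity (SI) of subject partitions against templates.

For a node n inside template T, with C the subject community containing n,
SI(n) = |C & T|^2 / (|C| * |T|): 1 under perfect alignment, shrinking as the
community either misses template nodes or dilutes them with extra members.
Nodes outside the template score 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .community_detect import CommunityPartition

__all__ = [
    "TemplateSet",
    "SIMap",
    "subject_si_map",
    "group_si_map",
    "tertile_maps",
    "tertile_sizes",
]

DEFAULT_TEMPLATE_NAMES = ("VN", "DMN", "SMN", "BGN", "CEN", "DAN", "FTN", "SN")


@dataclass
class TemplateSet:
    """Disjoint reference communities over a fixed node space.

    ``membership[i]`` is the index into ``names`` of the template containing
    node i, or -1 for nodes belonging to no template. Disjointness is
    structural: a node holds at most one label.
    """

    names: tuple[str, ...]
    membership: np.ndarray

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.membership = np.asarray(self.membership, dtype=np.int64)
        if self.membership.size and self.membership.max() >= len(self.names):
            raise ValueError("membership refers to an unnamed template")

    @property
    def n_nodes(self) -> int:
        return self.membership.size

    def nodes_of(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.membership == self.names.index(name))

    @classmethod
    def from_partition(
        cls, partition: CommunityPartition, names: Optional[Sequence[str]] = None
    ) -> "TemplateSet":
        labels = partition.labels
        uniq = np.unique(labels)
        if names is None:
            names = DEFAULT_TEMPLATE_NAMES[: uniq.size] if uniq.size <= 8 else tuple(
                f"C{c}" for c in uniq
            )
        if len(names) != uniq.size:
            raise ValueError("need one name per community")
        membership = np.searchsorted(uniq, labels)
        return cls(tuple(names), membership)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node\ttemplate\n")
            for i, m in enumerate(self.membership):
                fh.write(f"{i}\t{self.names[m] if m >= 0 else 'none'}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TemplateSet":
        nodes, labels = [], []
        with open(path) as fh:
            fh.readline()
            for line in fh:
                node, name = line.rstrip("\n").split("\t")
                nodes.append(int(node))
                labels.append(name)
        names = tuple(dict.fromkeys(l for l in labels if l != "none"))
        membership = np.full(len(nodes), -1, dtype=np.int64)
        for node, name in zip(nodes, labels):
            if name != "none":
                membership[node] = names.index(name)
        return cls(names, membership)


@dataclass
class SIMap:
    subject_id: str
    template_name: str
    values: np.ndarray  # per-node, in [0, 1]; 0 outside the template

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack((np.arange(self.values.size), self.values)),
                   fmt=("%d", "%.10g"), delimiter="\t", header="node\tsi",
                   comments="")


def subject_si_map(
    partition: CommunityPartition,
    template_nodes: np.ndarray,
    subject_id: str = "",
    template_name: str = "",
) -> SIMap:
    """Scaled inclusivity of one subject's partition against one template."""
    T = np.asarray(template_nodes, dtype=np.int64)
    if T.size == 0:
        raise ValueError("template is empty")
    labels = partition.labels
    values = np.zeros(labels.size)
    t_labels = labels[T]
    for lab in np.unique(t_labels):
        community_size = int(np.sum(labels == lab))
        overlap = int(np.sum(t_labels == lab))
        si = overlap**2 / (community_size * T.size)
        values[T[t_labels == lab]] = si
    return SIMap(subject_id, template_name, values)


def group_si_map(maps: Sequence[SIMap]) -> np.ndarray:
    """Node-wise arithmetic mean of SI values across subjects."""
    if not maps:
        raise ValueError("no SI maps given")
    stack = np.stack([m.values for m in maps])
    return stack.mean(axis=0)


def tertile_sizes(n: int) -> tuple[int, int, int]:
    """Near-equal covariate-ordered group sizes (lower, middle, upper);
    remainder members go to the lower tertiles first."""
    base, rem = divmod(n, 3)
    return (base + (rem >= 1), base + (rem >= 2), base)


def tertile_maps(
    maps: Sequence[SIMap],
    covariate: Mapping[str, float] | Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Group SI maps of the upper and lower covariate tertiles.

    Subjects are stably sorted by covariate value; tied values are assigned
    by position, filling the lower tertiles first.
    """
    if len(maps) < 3:
        raise ValueError("need at least 3 subjects")
    if isinstance(covariate, Mapping):
        values = np.array([covariate[m.subject_id] for m in maps], dtype=float)
    else:
        values = np.asarray(covariate, dtype=float)
        if values.size != len(maps):
            raise ValueError("covariate length does not match the map list")
    if np.unique(values).size < 3:
        raise ValueError("covariate must take at least 3 distinct values")
    order = np.argsort(values, kind="stable")
    lo, mid, hi = tertile_sizes(len(maps))
    lower_idx = order[:lo]
    upper_idx = order[lo + mid:]
    upper = group_si_map([maps[i] for i in upper_idx])
    lower = group_si_map([maps[i] for i in lower_idx])
    return upper, lower
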