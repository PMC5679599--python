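"""Hybrid-clone content classification and initial breakpoint intervals.

A somatic cell hybrid panel scores each clone for presence/absence of PCR
markers.  Clones retaining a single derivative chromosome show a
characteristic pattern: on each of the two translocated chromosomes the
positive markers form a contiguous block at the proximal end.  The interval
between the last positive and the first negative marker contains the
breakpoint.  When a flanking marker has no physical position, the nearest
physically mapped marker on the genetic map (in the direction away from the
interval interior) is substituted, and the substitution is recorded.
"""

from __future__ import annotations


from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .scenario import MarkerMap, ScenarioError


class ContentLabel(str, Enum):
    EMPTY = "EMPTY"
    SINGLE_DERIVATIVE = "SINGLE_DERIVATIVE"
    ALL_POSITIVE = "ALL_POSITIVE"
    INCONSISTENT = "INCONSISTENT"


class UnboundedIntervalError(ScenarioError):
    """Raised when a retention pattern has no informative flank."""


@dataclass
class RetentionMatrix:
    """Clones x markers 0/1 calls (markers as rows, clones as columns)."""

    calls: pd.DataFrame
    marker_map: MarkerMap

    def __post_init__(self):
        vals = self.calls.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ScenarioError("retention calls must be 0/1")
        known = set(self.marker_map.names())
        missing = [m for m in self.calls.index if m not in known]
        if missing:
            raise ScenarioError(f"markers absent from marker map: {missing}")

    @property
    def markers(self) -> list[str]:
        return list(self.calls.index)

    @property
    def clones(self) -> list[str]:
        return list(self.calls.columns)

    def to_tsv(self, path) -> None:
        self.calls.rename_axis("marker").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, marker_map: MarkerMap) -> "RetentionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="marker")
        return cls(df.astype(np.int8), marker_map)


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ScenarioError(f"empty interval [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def width_mb(self) -> float:
        return self.width / 1e6

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class PatternGroup:
    pattern: tuple[int, ...]
    markers: tuple[str, ...]
    clones: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.clones)


@dataclass(frozen=True)
class CloneContentCall:
    clone: str
    label: ContentLabel
    positive_count: int
    group_id: int


@dataclass(frozen=True)
class FlankMarker:
    """One interval endpoint: the marker that defines it and, when that
    marker had no physical position, the mapped neighbour substituted."""

    marker: str
    position_bp: int
    substituted_from: str | None = None


@dataclass(frozen=True)
class InferredInterval:
    interval: Interval
    left: FlankMarker
    right: FlankMarker
    order_basis: str  # 'physical' | 'genetic' | 'row'


def screen_pig_content(matrix: RetentionMatrix, genomewide_markers) -> pd.DataFrame:
    """Count positive genome-wide markers per clone (donor-content screen).

    Returns a DataFrame indexed by clone with columns ``count`` and
    ``positives`` (tuple of positive marker names).
    """
    genomewide_markers = list(genomewide_markers)
    if not genomewide_markers:
        raise ScenarioError("empty genome-wide marker subset")
    unknown = [m for m in genomewide_markers if m not in matrix.calls.index]
    if unknown:
        raise KeyError(f"unknown markers: {unknown}")
    sub = matrix.calls.loc[genomewide_markers]
    rows = []
    for clone in matrix.clones:
        positives = tuple(sub.index[sub[clone] == 1])
        rows.append({"clone": clone, "count": len(positives), "positives": positives})
    return pd.DataFrame(rows).set_index("clone")


def group_retention_patterns(matrix: RetentionMatrix, target_markers) -> list[PatternGroup]:
    """Partition clones by identical 0/1 vectors over the target markers.

    Groups are ordered by size descending, ties broken by the first clone
    name in column order.
    """
    target_markers = list(target_markers)
    if not target_markers:
        raise ScenarioError("empty target marker subset")
    sub = matrix.calls.loc[target_markers]
    by_pattern: dict[tuple[int, ...], list[str]] = {}
    for clone in matrix.clones:
        key = tuple(int(v) for v in sub[clone])
        by_pattern.setdefault(key, []).append(clone)
    groups = [
        PatternGroup(pattern=pat, markers=tuple(target_markers), clones=tuple(clones))
        for pat, clones in by_pattern.items()
    ]
    groups.sort(key=lambda g: (-g.size, g.clones[0]))
    return groups


def _chrom_order(marker_map: MarkerMap, chrom: str, markers: list[str]):
    """Position order of markers on one chromosome, with the coordinate basis
    used: physical positions when complete, else genetic, else row order."""
    sub = marker_map.df[marker_map.df["name"].isin(markers) & (marker_map.df["chrom"] == chrom)]
    sub = sub.set_index("name").loc[[m for m in markers if m in set(sub["name"])]]
    if len(sub) and sub["pos_bp"].notna().all():
        basis = "physical"
        order = sub["pos_bp"].astype(float)
    elif len(sub) and sub["cm"].notna().all():
        basis = "genetic"
        order = sub["cm"].astype(float)
    else:
        basis = "row"
        order = pd.Series(range(len(sub)), index=sub.index, dtype=float)
    ordered = order.sort_values(kind="stable").index.tolist()
    return ordered, basis


def _is_prefix(bits: list[int]) -> bool:
    seen_zero = False
    for b in bits:
        if b == 0:
            seen_zero = True
        elif seen_zero:
            return False
    return True


def classify_clone_content(
    groups: list[PatternGroup], marker_map: MarkerMap
) -> list[CloneContentCall]:
    """Label each clone EMPTY / SINGLE_DERIVATIVE / ALL_POSITIVE / INCONSISTENT.

    SINGLE_DERIVATIVE requires the positives to form one contiguous block
    anchored at the same chromosome end on every chromosome with markers: a
    proximal prefix for the derivative carrying both proximal segments, or a
    distal suffix for its reciprocal partner.  INCONSISTENT patterns are
    reported as such, never repaired.
    """
    calls = []
    for gid, group in enumerate(groups):
        marker_calls = dict(zip(group.markers, group.pattern))
        total_pos = sum(group.pattern)
        if total_pos == 0:
            label = ContentLabel.EMPTY
        elif total_pos == len(group.pattern):
            label = ContentLabel.ALL_POSITIVE
        else:
            chroms = sorted(
                set(
                    marker_map.df.set_index("name").loc[list(group.markers), "chrom"]
                )
            )
            can_prefix = can_suffix = True
            for chrom in chroms:
                ordered, _ = _chrom_order(marker_map, chrom, list(group.markers))
                bits = [marker_calls[m] for m in ordered]
                can_prefix &= _is_prefix(bits)
                can_suffix &= _is_prefix(bits[::-1])
            label = (
                ContentLabel.SINGLE_DERIVATIVE
                if can_prefix or can_suffix
                else ContentLabel.INCONSISTENT
            )
        for clone in group.clones:
            calls.append(CloneContentCall(clone, label, total_pos, gid))
    return calls


def _substitute_position(marker_map: MarkerMap, chrom: str, marker: str, direction: int):
    """Physical position for an interval flank.  If ``marker`` has none,
    walk the genetic map away from the interval interior (direction -1 =>
    lower cM, +1 => higher cM) to the nearest physically mapped marker."""
    df = marker_map.on_chrom(chrom).set_index("name")
    pos = df.loc[marker, "pos_bp"]
    if pd.notna(pos):
        return FlankMarker(marker, int(pos))
    cm0 = df.loc[marker, "cm"]
    if pd.isna(cm0):
        raise UnboundedIntervalError(
            f"flank marker {marker} has neither physical nor genetic position"
        )
    mapped = df[df["pos_bp"].notna() & df["cm"].notna()]
    if direction < 0:
        cand = mapped[mapped["cm"] <= cm0].sort_values("cm", kind="stable")
        cand = cand.iloc[::-1]
    else:
        cand = mapped[mapped["cm"] >= cm0].sort_values("cm", kind="stable")
    if cand.empty:
        raise UnboundedIntervalError(
            f"no physically mapped neighbour for {marker} on the genetic map"
        )
    sub = cand.iloc[0]
    return FlankMarker(marker, int(sub["pos_bp"]), substituted_from=sub.name)


def infer_initial_interval(
    pattern: pd.Series, marker_map: MarkerMap, chrom: str
) -> InferredInterval:
    """Breakpoint-containing interval from a monotone retention pattern.

    ``pattern`` maps marker name -> 0/1 for one clone; only markers on
    ``chrom`` are used.  The interval runs from the last positive marker to
    the first negative marker in position order.
    """
    markers = list(pattern.index)
    ordered, basis = _chrom_order(marker_map, chrom, markers)
    if not ordered:
        raise ScenarioError(f"no markers on {chrom}")
    bits = [int(pattern[m]) for m in ordered]
    if not _is_prefix(bits):
        raise ScenarioError(f"pattern on {chrom} is not a contiguous proximal prefix")
    n_pos = sum(bits)
    if n_pos == 0 or n_pos == len(bits):
        raise UnboundedIntervalError(
            f"pattern on {chrom} is all-{'positive' if n_pos else 'negative'}: no flank"
        )
    last_pos = ordered[n_pos - 1]
    first_neg = ordered[n_pos]
    left = _substitute_position(marker_map, chrom, last_pos, direction=-1)
    right = _substitute_position(marker_map, chrom, first_neg, direction=+1)
    interval = Interval(chrom, left.position_bp, right.position_bp)
    return InferredInterval(interval, left, right, basis)


def write_clone_calls_tsv(calls: list[CloneContentCall], path) -> None:
    pd.DataFrame(
        [
            {
                "clone": c.clone,
                "label": c.label.value,
                "positive_count": c.positive_count,
                "group_id": c.group_id,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def write_intervals_bed(intervals: list[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
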