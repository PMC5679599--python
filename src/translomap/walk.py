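"""Iterative STS chromosome walking on an informative hybrid clone.

Starting from a Mb-scale interval known to contain the breakpoint, each
round selects k STS positions that divide the interval into k+1 roughly
equal sub-intervals (snapped to the nearest available marker), assays them
by PCR on a clone carrying a single derivative chromosome, and shrinks the
interval to the span between the last positive and the first negative
probe.  Marker availability comes in phases — sparse microsatellites, a
finite SNP-chip set, then freely designable sequence STSs — and the walk
falls through the phases as each one runs out of markers inside the
current interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hybrid_panel import Interval
from .scenario import Scenario, ScenarioError, marker_on_derivative


class InconsistentAssayError(ScenarioError):
    """Probe results are not monotone 1...0 across the interval."""

    def __init__(self, message, log=None):
        super().__init__(message)
        self.log = log


class NoMarkersError(ScenarioError):
    """No marker of any phase is available strictly inside the interval."""


@dataclass(frozen=True)
class WalkPhase:
    """A marker-availability phase.  ``positions`` is a sorted array of
    candidate STS positions, or None for a dense phase where an STS can be
    designed at any base (sequence-derived markers)."""

    name: str
    positions: np.ndarray | None = None


def phases_from_scenario(scenario: Scenario, chrom: str, include_dense: bool = True):
    """Default coarse-to-fine phase list for one chromosome of a scenario."""
    df = scenario.markers.on_chrom(chrom)
    out = []
    for phase_name in ("MICROSAT", "SNPCHIP"):
        pos = np.sort(df[df["phase"] == phase_name]["pos_bp"].dropna().astype(int).to_numpy())
        if pos.size:
            out.append(WalkPhase(phase_name, pos))
    if include_dense:
        out.append(WalkPhase("SEQ_STS", None))
    return out


def dense_phase() -> WalkPhase:
    return WalkPhase("SEQ_STS", None)


@dataclass(frozen=True)
class WalkConfig:
    k: int = 3
    target_width: int = 1000
    phases: tuple[WalkPhase, ...] = (WalkPhase("SEQ_STS", None),)
    assay_failure_prob: float = 0.0
    retest_budget: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ScenarioError("k must be >= 1")
        if self.target_width < 1:
            raise ScenarioError("target width must be >= 1")


@dataclass(frozen=True)
class WalkRound:
    interval_before: Interval
    phase: str
    probes: tuple[int, ...]
    results: tuple[int, ...]
    interval_after: Interval


@dataclass
class WalkLog:
    chrom: str
    start_interval: Interval | None = None
    rounds: list[WalkRound] = field(default_factory=list)
    status: str = "RUNNING"  # REACHED_TARGET | NO_MARKERS | INCONSISTENT

    @property
    def final_interval(self) -> Interval:
        if self.rounds:
            return self.rounds[-1].interval_after
        if self.start_interval is not None:
            return self.start_interval
        raise ScenarioError("walk has no rounds")

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = []
        for i, r in enumerate(self.rounds):
            for p, res in zip(r.probes, r.results):
                rows.append(
                    {
                        "round": i + 1,
                        "phase": r.phase,
                        "start": r.interval_before.start,
                        "end": r.interval_before.end,
                        "probe": p,
                        "result": res,
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def plan_round(interval: Interval, k: int, available: np.ndarray | None) -> list[int]:
    """Choose up to k probe positions splitting the interval ~equally.

    Ideal points ``start + i*width/(k+1)`` are snapped to the nearest
    available marker strictly inside the interval (ties toward the lower
    coordinate); duplicates collapse.  ``available`` None means any integer
    position is usable.
    """
    if interval.width <= 0:
        raise ScenarioError("cannot plan a round on an empty interval")
    if available is None:
        candidates = None
    else:
        candidates = available[(available > interval.start) & (available < interval.end)]
        if candidates.size == 0:
            raise NoMarkersError(f"no marker strictly inside [{interval.start},{interval.end})")
    probes = []
    for i in range(1, k + 1):
        ideal = interval.start + (i * interval.width) // (k + 1)
        if candidates is None:
            p = min(max(ideal, interval.start + 1), interval.end - 1)
        else:
            j = int(np.searchsorted(candidates, ideal))
            best = None
            for idx in (j - 1, j):
                if 0 <= idx < candidates.size:
                    c = int(candidates[idx])
                    d = abs(c - ideal)
                    if best is None or d < best[0] or (d == best[0] and c < best[1]):
                        best = (d, c)
            p = best[1]
        probes.append(p)
    return sorted(set(probes))


def assay_sts(
    position: int,
    chrom: str,
    clone_content: set[str],
    scenario: Scenario,
    failure_prob: float = 0.0,
    rng: np.random.Generator | None = None,
) -> int:
    """PCR presence (1) / absence (0) of an STS at ``position`` on a clone.

    The STS amplifies iff the position lies on a derivative fragment the
    clone retains; positions inside the deleted motif never amplify.
    Failures flip a true 1 to 0 with probability ``failure_prob``.
    """
    present = any(
        marker_on_derivative(position, chrom, d, scenario.breakpoint) for d in clone_content
    )
    if present and failure_prob > 0:
        rng = rng or np.random.default_rng()
        if rng.random() < failure_prob:
            return 0
    return int(present)


def refine_interval(interval: Interval, probes, results) -> Interval:
    """Shrink the interval to between the last positive and first negative.

    The augmented result vector (left flank = 1, probes, right flank = 0)
    must be monotone non-increasing; anything else is reported as
    INCONSISTENT, never repaired.
    """
    probes = list(probes)
    results = list(results)
    if probes != sorted(probes):
        raise ScenarioError("probes must be sorted")
    aug_pos = [interval.start] + probes + [interval.end]
    aug_res = [1] + results + [0]
    for a, b in zip(aug_res, aug_res[1:]):
        if b > a:
            raise InconsistentAssayError(
                f"non-monotone assay results {results} for probes {probes}"
            )
    last_one = max(i for i, r in enumerate(aug_res) if r == 1)
    return Interval(interval.chrom, aug_pos[last_one], aug_pos[last_one + 1])


def run_walk(
    scenario: Scenario,
    config: WalkConfig,
    start_interval: Interval,
    chrom: str,
    clone_content: set[str] = frozenset({"der4"}),
    max_rounds: int = 200,
) -> WalkLog:
    """Iterate plan/assay/refine until the target width is reached.

    Phases are tried coarse-to-fine: the first phase with a marker strictly
    inside the current interval supplies the probes.  A discordant
    (non-monotone) round is re-assayed up to ``retest_budget`` times before
    the walk stops with status INCONSISTENT.
    """
    rng = np.random.default_rng(config.seed)
    log = WalkLog(chrom=chrom, start_interval=start_interval)
    interval = start_interval
    for _ in range(max_rounds):
        if interval.width <= config.target_width:
            log.status = "REACHED_TARGET"
            return log
        probes = None
        phase_name = None
        for phase in config.phases:
            try:
                probes = plan_round(interval, config.k, phase.positions)
                phase_name = phase.name
                break
            except NoMarkersError:
                continue
        if probes is None:
            log.status = "NO_MARKERS"
            return log

        for attempt in range(config.retest_budget + 1):
            results = [
                assay_sts(p, chrom, clone_content, scenario, config.assay_failure_prob, rng)
                for p in probes
            ]
            try:
                new_interval = refine_interval(interval, probes, results)
                break
            except InconsistentAssayError as err:
                if attempt == config.retest_budget:
                    log.status = "INCONSISTENT"
                    raise InconsistentAssayError(str(err), log=log) from err
        if new_interval.width == interval.width:
            # probes could not split the interval any further in this phase
            log.rounds.append(
                WalkRound(interval, phase_name, tuple(probes), tuple(results), new_interval)
            )
            log.status = "NO_MARKERS"
            return log
        log.rounds.append(
            WalkRound(interval, phase_name, tuple(probes), tuple(results), new_interval)
        )
        interval = new_interval
    log.status = "NO_MARKERS"
    return log
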