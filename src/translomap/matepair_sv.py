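"""Inter-chromosomal translocation screen from mate-pair alignments.

Pipeline: classify pairs (mapping-quality gate, concordance window), keep
inter-chromosomal discordant pairs, cluster them by chromosome pair and
strand signature with single-linkage chaining, estimate breakend confidence
intervals from the read-end / insert-bound geometry, merge complementary
clusters into reciprocal (balanced) translocation calls, apply the support
threshold, and remove calls recurring in a control pool.  Output is VCF 4.2
breakend (BND) records.

Both thresholds are exclusive: a pair is kept when mapq is strictly above
``mapq_min`` and a call when supported by strictly more than ``support_min``
mate-pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

from .scenario import LibraryModel, ScenarioError, ToyAssembly


class PairClass(str, Enum):
    LOWQ = "LOWQ"
    CONCORDANT = "CONCORDANT"
    DISCORDANT_INTRA = "DISCORDANT_INTRA"
    INTERCHROM = "INTERCHROM"


class FilterStatus(str, Enum):
    PASS = "PASS"
    IN_CONTROL = "IN_CONTROL"
    LOW_SUPPORT = "LOW_SUPPORT"


@dataclass(frozen=True)
class MatePairRecord:
    read_id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    mapq: int
    pool: str = ""
    read_len: int = 100

    def __post_init__(self):
        if self.pos1 < 0 or self.pos2 < 0:
            raise ScenarioError("negative read position")
        if self.strand1 not in "+-" or self.strand2 not in "+-":
            raise ScenarioError("strand must be + or -")


@dataclass(frozen=True)
class DetectorConfig:
    mapq_min: int = 10          # exclusive: keep mapq > mapq_min
    support_min: int = 10       # exclusive: call needs support > support_min
    concordance_sigmas: float = 3.0
    cluster_max_gap: float | None = None   # default insert_mean + 3*sd
    pairing_tol: float | None = None       # default insert_mean + 3*sd
    differential_tol: float | None = None  # default insert_mean
    interval_reach: float | None = None    # default: library's maximal insert
    balanced_only: bool = False

    def gap(self, lib: LibraryModel) -> float:
        return self.cluster_max_gap if self.cluster_max_gap is not None else lib.insert_mean + 3 * lib.insert_sd

    def reach(self, lib: LibraryModel) -> float:
        # breakend intervals must cover the largest insert the library can
        # produce, i.e. its truncation bound, not just mu+3*sigma
        return self.interval_reach if self.interval_reach is not None else lib.insert_bounds[1]

    def pair_tol(self, lib: LibraryModel) -> float:
        return self.pairing_tol if self.pairing_tol is not None else lib.insert_mean + 3 * lib.insert_sd

    def diff_tol(self, lib: LibraryModel) -> float:
        return self.differential_tol if self.differential_tol is not None else lib.insert_mean


@dataclass
class BreakendCluster:
    chrom_a: str
    chrom_b: str
    strand_a: str
    strand_b: str
    member_ids: tuple[str, ...]
    pos_a: np.ndarray  # leftmost read positions on chrom A, one per member
    pos_b: np.ndarray
    read_len: int
    interval_a: tuple[int, int] = (0, 0)
    interval_b: tuple[int, int] = (0, 0)

    @property
    def support(self) -> int:
        return len(self.member_ids)

    @property
    def span_a(self) -> tuple[int, int]:
        return int(self.pos_a.min()), int(self.pos_a.max()) + self.read_len

    @property
    def span_b(self) -> tuple[int, int]:
        return int(self.pos_b.min()), int(self.pos_b.max()) + self.read_len

    @property
    def signature(self) -> tuple[str, str]:
        return (self.strand_a, self.strand_b)

    def midpoint_a(self) -> float:
        return (self.interval_a[0] + self.interval_a[1]) / 2

    def midpoint_b(self) -> float:
        return (self.interval_b[0] + self.interval_b[1]) / 2


@dataclass
class TranslocationCall:
    chrom_a: str
    chrom_b: str
    clusters: tuple[BreakendCluster, ...]
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    support: int
    status: FilterStatus
    reciprocal: bool

    @property
    def signatures(self) -> tuple[tuple[str, str], ...]:
        return tuple(c.signature for c in self.clusters)

    def midpoint_a(self) -> float:
        return (self.interval_a[0] + self.interval_a[1]) / 2

    def midpoint_b(self) -> float:
        return (self.interval_b[0] + self.interval_b[1]) / 2

    def essentials(self):
        """The fields preserved by VCF export (used for round-trip checks)."""
        junctions = tuple(
            sorted(
                (c.signature, tuple(c.interval_a), tuple(c.interval_b), c.support)
                for c in self.clusters
            )
        )
        return (self.chrom_a, self.chrom_b, junctions, self.support, self.status.value, self.reciprocal)


# ---------------------------------------------------------------------------
# pair classification
# ---------------------------------------------------------------------------


def classify_pair(rec: MatePairRecord, lib: LibraryModel, cfg: DetectorConfig) -> PairClass:
    """Classify one mate-pair; see the class docstring for the rules."""
    if rec.mapq <= cfg.mapq_min:
        return PairClass.LOWQ
    if rec.chrom1 != rec.chrom2:
        return PairClass.INTERCHROM
    if rec.pos1 <= rec.pos2:
        left, right = (rec.pos1, rec.strand1), (rec.pos2, rec.strand2)
    else:
        left, right = (rec.pos2, rec.strand2), (rec.pos1, rec.strand1)
    innie = left[1] == "+" and right[1] == "-"
    span = right[0] + rec.read_len - left[0]
    if innie and abs(span - lib.insert_mean) <= cfg.concordance_sigmas * lib.insert_sd:
        return PairClass.CONCORDANT
    return PairClass.DISCORDANT_INTRA


def classify_pairs(df: pd.DataFrame, lib: LibraryModel, cfg: DetectorConfig) -> pd.Series:
    """Vectorized :func:`classify_pair` over a pair table."""
    lowq = df["mapq"] <= cfg.mapq_min
    inter = df["chrom1"] != df["chrom2"]
    p1, p2 = df["pos1"].to_numpy(), df["pos2"].to_numpy()
    s1, s2 = df["strand1"].to_numpy(), df["strand2"].to_numpy()
    swap = p1 > p2
    left_pos = np.where(swap, p2, p1)
    right_pos = np.where(swap, p1, p2)
    left_s = np.where(swap, s2, s1)
    right_s = np.where(swap, s1, s2)
    span = right_pos + lib.read_len - left_pos
    innie = (left_s == "+") & (right_s == "-")
    concord = innie & (np.abs(span - lib.insert_mean) <= cfg.concordance_sigmas * lib.insert_sd)
    out = np.where(
        lowq,
        PairClass.LOWQ.value,
        np.where(
            inter,
            PairClass.INTERCHROM.value,
            np.where(concord, PairClass.CONCORDANT.value, PairClass.DISCORDANT_INTRA.value),
        ),
    )
    return pd.Series(out, index=df.index)


def interchrom_table(df: pd.DataFrame, lib: LibraryModel, cfg: DetectorConfig) -> pd.DataFrame:
    """High-quality inter-chromosomal pairs with canonical end order
    (end A = lexicographically smaller chromosome name)."""
    cls = classify_pairs(df, lib, cfg)
    sub = df[cls == PairClass.INTERCHROM.value].copy()
    swap = sub["chrom1"] > sub["chrom2"]
    for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")):
        va, vb = sub[a].copy(), sub[b].copy()
        sub.loc[swap, a] = vb[swap]
        sub.loc[swap, b] = va[swap]
    return sub


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj


def cluster_discordant(
    inter: pd.DataFrame, lib: LibraryModel, cfg: DetectorConfig
) -> list[BreakendCluster]:
    """Single-linkage clustering of inter-chromosomal pairs.

    Pairs are binned by (chrom A, chrom B, strand signature); within a bin
    two pairs link iff their positions differ by at most the gap on *both*
    chromosomes.  Connected components become clusters.  The input must
    already be the canonical inter-chromosomal table.
    """
    clusters = []
    if inter.empty:
        return clusters
    gap = cfg.gap(lib)
    for (ca, cb, sa, sb), bin_df in inter.groupby(
        ["chrom1", "chrom2", "strand1", "strand2"], sort=True
    ):
        bin_df = bin_df.sort_values("pos1", kind="stable")
        pa = bin_df["pos1"].to_numpy(dtype=np.int64)
        pb = bin_df["pos2"].to_numpy(dtype=np.int64)
        ids = bin_df["read_id"].to_numpy()
        n = len(bin_df)
        uf = _UnionFind(n)
        for i in range(n):
            j = i + 1
            while j < n and pa[j] - pa[i] <= gap:
                if abs(pb[j] - pb[i]) <= gap:
                    uf.union(i, j)
                j += 1
        comp: dict[int, list[int]] = {}
        for i in range(n):
            comp.setdefault(uf.find(i), []).append(i)
        for members in comp.values():
            idx = np.array(members)
            cluster = BreakendCluster(
                chrom_a=ca,
                chrom_b=cb,
                strand_a=sa,
                strand_b=sb,
                member_ids=tuple(ids[idx]),
                pos_a=pa[idx],
                pos_b=pb[idx],
                read_len=lib.read_len,
            )
            ia, ib = estimate_breakend_interval(cluster, lib, cfg)
            cluster.interval_a = ia
            cluster.interval_b = ib
            clusters.append(cluster)
    clusters.sort(key=lambda c: (-c.support, c.chrom_a, c.chrom_b, c.interval_a))
    return clusters


def _side_interval(pos: np.ndarray, strand: str, read_len: int, reach: float):
    """Breakend confidence interval for one cluster side.

    A read on '+' points rightward toward the junction: the junction lies
    right of the read end and within one maximal insert (``reach``) of the
    read start, so each member implies the interval
    ``[pos + read_len, pos + reach]`` (mirrored for '-').  A consistent
    cluster yields the exact intersection
    ``[max(read end), min(read start) + reach]``.  When stray chained-in
    members (background pairs picked up by single linkage) can bias a pure
    min/max construction, the interval is the quorum consensus: the hull of
    the region supported by at least 80% of the members, which each bound
    realizes as its ceil(0.2 n)-trimmed order statistic.  A minority of
    chained-in outliers therefore cannot displace the interval.  Should the
    quorum region be empty (no coherent majority), the hull of the
    maximal-coverage region is used instead.
    """
    n = len(pos)
    if strand == "+":
        los, his = pos + read_len, pos + reach
    else:
        los, his = pos + read_len - reach, pos
    t = n - math.ceil(0.8 * n)
    lo = int(np.sort(los)[::-1][t])
    hi = int(np.sort(his)[t])
    if lo < hi:
        return lo, hi
    events = sorted([(int(l), 1) for l in los] + [(int(h), -1) for h in his])
    segments = []
    cov = 0
    prev = None
    for x, delta in events:
        if prev is not None and cov > 0 and x > prev:
            segments.append((cov, prev, x))
        cov += delta
        prev = x
    max_cov = max(c for c, _, _ in segments)
    kept = [(a, b) for c, a, b in segments if c == max_cov]
    return min(a for a, _ in kept), max(b for _, b in kept)


def estimate_breakend_interval(
    cluster: BreakendCluster, lib: LibraryModel, cfg: DetectorConfig | None = None
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Confidence intervals for the two breakends of a cluster."""
    cfg = cfg or DetectorConfig()
    reach = cfg.reach(lib)
    ia = _side_interval(cluster.pos_a, cluster.strand_a, cluster.read_len, reach)
    ib = _side_interval(cluster.pos_b, cluster.strand_b, cluster.read_len, reach)
    return ia, ib


# ---------------------------------------------------------------------------
# calling, reciprocal pairing, differential filtering
# ---------------------------------------------------------------------------


def _complement_signature(sig: tuple[str, str]) -> tuple[str, str]:
    flip = {"+": "-", "-": "+"}
    return (flip[sig[0]], flip[sig[1]])


def _consensus(i1: tuple[int, int], i2: tuple[int, int]) -> tuple[int, int]:
    lo, hi = max(i1[0], i2[0]), min(i1[1], i2[1])
    if lo < hi:
        return lo, hi
    return min(i1[0], i2[0]), max(i1[1], i2[1])


def call_translocations(
    clusters: list[BreakendCluster], cfg: DetectorConfig, lib: LibraryModel
) -> list[TranslocationCall]:
    """Merge complementary clusters into reciprocal calls and apply the
    support threshold.

    Clusters at or below ``support_min`` are emitted flagged LOW_SUPPORT.
    Complementary-signature clusters on the same chromosome pair whose
    breakend midpoints lie within the pairing tolerance on both chromosomes
    merge into one balanced call; unpaired passing clusters are emitted
    flagged non-reciprocal (dropped entirely in balanced-only mode).
    """
    calls = []
    passing = [c for c in clusters if c.support > cfg.support_min]
    for c in clusters:
        if c.support <= cfg.support_min:
            calls.append(
                TranslocationCall(
                    c.chrom_a, c.chrom_b, (c,), c.interval_a, c.interval_b,
                    c.support, FilterStatus.LOW_SUPPORT, reciprocal=False,
                )
            )
    tol = cfg.pair_tol(lib)
    used = set()
    for i, c in enumerate(passing):
        if i in used:
            continue
        best = None
        for j in range(i + 1, len(passing)):
            if j in used:
                continue
            d = passing[j]
            if (d.chrom_a, d.chrom_b) != (c.chrom_a, c.chrom_b):
                continue
            if d.signature != _complement_signature(c.signature):
                continue
            # distance between breakend intervals (0 when they overlap):
            # reciprocal junctions abut, so their intervals nearly touch
            da = max(
                max(d.interval_a[0], c.interval_a[0]) - min(d.interval_a[1], c.interval_a[1]), 0
            )
            db = max(
                max(d.interval_b[0], c.interval_b[0]) - min(d.interval_b[1], c.interval_b[1]), 0
            )
            if da <= tol and db <= tol:
                if best is None or da + db < best[0]:
                    best = (da + db, j)
        if best is not None:
            j = best[1]
            used.update((i, j))
            d = passing[j]
            calls.append(
                TranslocationCall(
                    c.chrom_a, c.chrom_b, (c, d),
                    _consensus(c.interval_a, d.interval_a),
                    _consensus(c.interval_b, d.interval_b),
                    c.support + d.support, FilterStatus.PASS, reciprocal=True,
                )
            )
        else:
            used.add(i)
            if not cfg.balanced_only:
                calls.append(
                    TranslocationCall(
                        c.chrom_a, c.chrom_b, (c,), c.interval_a, c.interval_b,
                        c.support, FilterStatus.PASS, reciprocal=False,
                    )
                )
    calls.sort(key=lambda t: (-t.support, t.chrom_a, t.chrom_b, t.interval_a))
    return calls


def differential_filter(
    case_calls: list[TranslocationCall],
    control_calls: list[TranslocationCall],
    tolerance: float,
) -> list[TranslocationCall]:
    """Flag case calls recurring in the control pool.

    A case call is IN_CONTROL iff any supplied control call shares the
    chromosome pair and has both breakend midpoints within ``tolerance``.
    Returns a new list with updated statuses.
    """
    out = []
    for call in case_calls:
        if call.status != FilterStatus.PASS:
            out.append(call)
            continue
        matched = any(
            (ctl.chrom_a, ctl.chrom_b) == (call.chrom_a, call.chrom_b)
            and abs(ctl.midpoint_a() - call.midpoint_a()) <= tolerance
            and abs(ctl.midpoint_b() - call.midpoint_b()) <= tolerance
            for ctl in control_calls
        )
        if matched:
            out.append(replace(call, status=FilterStatus.IN_CONTROL))
        else:
            out.append(call)
    return out


def scan(
    case: pd.DataFrame,
    control: pd.DataFrame | None,
    lib: LibraryModel,
    cfg: DetectorConfig | None = None,
) -> list[TranslocationCall]:
    """End-to-end screen: classify, cluster, call, differential-filter.

    Returns all case calls with their final status; PASS calls are the
    case-specific translocations.
    """
    cfg = cfg or DetectorConfig()
    case_clusters = cluster_discordant(interchrom_table(case, lib, cfg), lib, cfg)
    case_calls = call_translocations(case_clusters, cfg, lib)
    if control is not None:
        ctl_clusters = cluster_discordant(interchrom_table(control, lib, cfg), lib, cfg)
        ctl_calls = call_translocations(ctl_clusters, cfg, lib)
        # only supported control candidates count as recurrences: a stray
        # single noise pair in the control must not veto a strong case call
        ctl_candidates = pass_calls(ctl_calls)
        case_calls = differential_filter(case_calls, ctl_candidates, cfg.diff_tol(lib))
    return case_calls


def pass_calls(calls: list[TranslocationCall]) -> list[TranslocationCall]:
    return [c for c in calls if c.status == FilterStatus.PASS]


# ---------------------------------------------------------------------------
# VCF BND output and minimal SAM input
# ---------------------------------------------------------------------------


def _bnd_alt(base: str, strand: str, mate_chrom: str, mate_pos_1based: int) -> str:
    """ALT bracket string for a fold-back breakend.

    '+' side: the retained segment extends left of the breakend and joins
    the reverse-complemented mate segment that also extends left -> t]p].
    '-' side: retained segment extends right, joins a reverse-complemented
    segment extending right -> [p[t.
    """
    if strand == "+":
        return f"{base}]{mate_chrom}:{mate_pos_1based}]"
    return f"[{mate_chrom}:{mate_pos_1based}[{base}"


def write_bnd_vcf(calls: list[TranslocationCall], assembly: ToyAssembly) -> str:
    """Render calls as VCF 4.2 breakend records (two per junction).

    POS is the 1-based position of the 0-based breakend coordinate (the
    start of the confidence interval); CIPOS carries the interval width.
    """
    lengths = assembly.lengths()
    lines = [
        "##fileformat=VCFv4.2",
        '##ALT=<ID=BND,Description="Breakend">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of the mate breakend">',
        '##INFO=<ID=EVENT,Number=1,Type=String,Description="Event identifier">',
        '##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Confidence interval around POS">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting mate-pairs">',
        '##INFO=<ID=RECIPROCAL,Number=0,Type=Flag,Description="Part of a reciprocal pair of junctions">',
        '##FILTER=<ID=LOW_SUPPORT,Description="Support below threshold">',
        '##FILTER=<ID=IN_CONTROL,Description="Recurs in the control pool">',
    ]
    for name, length in lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    rows = []
    for ei, call in enumerate(calls):
        event = f"TRA{ei}"
        filt = "PASS" if call.status == FilterStatus.PASS else call.status.value
        for ji, cluster in enumerate(call.clusters):
            ja = f"{event}_J{ji}"
            for side, (chrom, interval, strand, mate_chrom, mate_interval) in enumerate(
                (
                    (cluster.chrom_a, cluster.interval_a, cluster.strand_a,
                     cluster.chrom_b, cluster.interval_b),
                    (cluster.chrom_b, cluster.interval_b, cluster.strand_b,
                     cluster.chrom_a, cluster.interval_a),
                )
            ):
                pos0 = interval[0]
                mate_pos0 = mate_interval[0]
                if chrom not in lengths or not (0 <= pos0 < lengths[chrom]):
                    raise ScenarioError(f"breakend {chrom}:{pos0} outside assembly")
                base = assembly[chrom][pos0]
                rid = f"{ja}_{'AB'[side]}"
                mate_id = f"{ja}_{'BA'[side]}"
                info = (
                    f"SVTYPE=BND;MATEID={mate_id};EVENT={event};"
                    f"CIPOS=0,{interval[1] - interval[0]};SUPPORT={cluster.support}"
                )
                if call.reciprocal:
                    info += ";RECIPROCAL"
                alt = _bnd_alt(base, strand, mate_chrom, mate_pos0 + 1)
                rows.append(f"{chrom}\t{pos0 + 1}\t{rid}\t{base}\t{alt}\t.\t{filt}\t{info}")
    return "\n".join(lines + rows) + "\n"


def parse_bnd_vcf(text: str) -> list[TranslocationCall]:
    """Parse VCF text written by :func:`write_bnd_vcf` back into calls.

    Clusters are reconstructed with their intervals, signatures and support;
    per-read member information is not stored in VCF and is left empty.
    """
    events: dict[str, dict[str, dict]] = {}
    order: list[str] = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, pos, rid, _ref, alt, _qual, filt, info = line.split("\t")[:8]
        fields = dict(
            kv.split("=", 1) if "=" in kv else (kv, True) for kv in info.split(";")
        )
        event = fields["EVENT"]
        junction = rid.rsplit("_", 1)[0]
        side = rid.rsplit("_", 1)[1]
        strand = "+" if alt.startswith(tuple("ACGTN")) and "]" in alt else "-"
        ci = [int(x) for x in fields["CIPOS"].split(",")]
        if event not in events:
            events[event] = {}
            order.append(event)
        rec = events[event].setdefault(
            junction,
            {"support": int(fields["SUPPORT"]), "filter": filt,
             "reciprocal": "RECIPROCAL" in fields, "sides": {}},
        )
        rec["sides"][side] = (chrom, int(pos) - 1, strand, ci[1])

    calls = []
    for event in order:
        clusters = []
        filt = "PASS"
        reciprocal = False
        for junction in sorted(events[event]):
            rec = events[event][junction]
            filt = rec["filter"]
            reciprocal = rec["reciprocal"]
            (ca, pa, sa, wa) = rec["sides"]["A"]
            (cb, pb, sb, wb) = rec["sides"]["B"]
            clusters.append(
                BreakendCluster(
                    chrom_a=ca, chrom_b=cb, strand_a=sa, strand_b=sb,
                    member_ids=tuple(f"{junction}_m{i}" for i in range(rec["support"])),
                    pos_a=np.array([pa]), pos_b=np.array([pb]), read_len=0,
                    interval_a=(pa, pa + wa), interval_b=(pb, pb + wb),
                )
            )
        interval_a = clusters[0].interval_a
        interval_b = clusters[0].interval_b
        if len(clusters) == 2:
            interval_a = _consensus(clusters[0].interval_a, clusters[1].interval_a)
            interval_b = _consensus(clusters[0].interval_b, clusters[1].interval_b)
        calls.append(
            TranslocationCall(
                clusters[0].chrom_a, clusters[0].chrom_b, tuple(clusters),
                interval_a, interval_b,
                sum(c.support for c in clusters),
                FilterStatus(filt), reciprocal=reciprocal,
            )
        )
    return calls


_FLAG_PAIRED = 0x1
_FLAG_REVERSE = 0x10
_FLAG_MATE_REVERSE = 0x20
_FLAG_FIRST = 0x40
_FLAG_LAST = 0x80


def read_minimal_sam(path_or_text, default_read_len: int = 100, pool: str = "") -> pd.DataFrame:
    """Import mate-pairs from a minimal SAM: only QNAME/FLAG/RNAME/POS/MAPQ/
    RNEXT/PNEXT are interpreted (flags 0x1, 0x10, 0x20, 0x40, 0x80).

    Each QNAME contributes one pair, assembled from its first-in-pair line
    (falling back to the mate fields when only one line is present).
    POS/PNEXT are converted from SAM 1-based to 0-based.
    """
    if isinstance(path_or_text, str) and "\n" in path_or_text:
        lines = path_or_text.splitlines()
    else:
        with open(path_or_text) as fh:
            lines = fh.read().splitlines()
    by_name: dict[str, dict] = {}
    for line in lines:
        if not line or line.startswith("@"):
            continue
        f = line.split("\t")
        qname, flag, rname, pos, mapq, rnext, pnext = (
            f[0], int(f[1]), f[2], int(f[3]), int(f[4]), f[6], int(f[7]),
        )
        if not flag & _FLAG_PAIRED or rname == "*":
            continue
        entry = by_name.setdefault(qname, {"mapq": 0})
        strand = "-" if flag & _FLAG_REVERSE else "+"
        end = 1 if flag & _FLAG_FIRST or not flag & _FLAG_LAST else 2
        entry[f"end{end}"] = (rname, pos - 1, strand)
        entry["mapq"] = max(entry["mapq"], mapq)
        if rnext != "*" and f"end{2 if end == 1 else 1}" not in entry:
            mate_chrom = rname if rnext == "=" else rnext
            mate_strand = "-" if flag & _FLAG_MATE_REVERSE else "+"
            entry[f"mate{end}"] = (mate_chrom, pnext - 1, mate_strand)
    rows = []
    for qname, entry in by_name.items():
        e1 = entry.get("end1") or entry.get("mate2")
        e2 = entry.get("end2") or entry.get("mate1")
        if e1 is None or e2 is None:
            continue
        rows.append(
            {
                "read_id": qname,
                "chrom1": e1[0], "pos1": e1[1], "strand1": e1[2],
                "chrom2": e2[0], "pos2": e2[1], "strand2": e2[2],
                "mapq": entry["mapq"], "pool": pool,
            }
        )
    return pd.DataFrame(rows, columns=[
        "read_id", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2", "mapq", "pool",
    ])


def write_cluster_tsv(clusters: list[BreakendCluster], path) -> None:
    rows = []
    for i, c in enumerate(clusters):
        rows.append(
            {
                "cluster_id": i, "chrom_a": c.chrom_a, "chrom_b": c.chrom_b,
                "strand_a": c.strand_a, "strand_b": c.strand_b, "support": c.support,
                "interval_a_start": c.interval_a[0], "interval_a_end": c.interval_a[1],
                "interval_b_start": c.interval_b[0], "interval_b_end": c.interval_b[1],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_scatter_tsv(inter: pd.DataFrame, clusters: list[BreakendCluster], path) -> None:
    """Dot-plot export: one row per inter-chromosomal pair with its cluster id."""
    id_to_cluster = {}
    for i, c in enumerate(clusters):
        for rid in c.member_ids:
            id_to_cluster[rid] = i
    out = inter[["read_id", "pos1", "pos2"]].copy()
    out.columns = ["read_id", "pos_a", "pos_b"]
    out["cluster_id"] = [id_to_cluster.get(r, -1) for r in out["read_id"]]
    out.to_csv(path, sep="\t", index=False)
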