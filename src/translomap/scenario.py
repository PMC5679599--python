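"""Synthetic scenario generator for reciprocal-translocation breakpoint mapping.

Everything downstream of this module — hybrid-clone retention mapping, STS
chromosome walking, in-silico PCR junction calling and the mate-pair
translocation screen — consumes data produced here.  The generator builds a
desk-sized two-chromosome genome carrying a reciprocal translocation
t(A;B) with a small microdeletion at one junction, the two derivative
chromosomes, a marker universe (microsatellites, a finite SNP-chip set, and
dense sequence-derived STSs), a truncated gene model, PCR primer placements,
simulated somatic-hybrid retention panels, and simulated pooled mate-pair
libraries with chimeric background noise.

Coordinates are 0-based, half-open throughout; 1-based coordinates appear
only in VCF output.  All simulators are pure functions of (config, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

FOLD_BACK_JOIN = "FOLD_BACK_JOIN"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# Pinned digests: verified at load time so silent fixture edits fail loudly.
_FIXTURE_DIGESTS = {
    "table1_markers.tsv": "9161c1fe1c6afd1bef59215b286f558a76f65635ca043e3cb023febe53f0de91",
    "table1_retention.tsv": "0130c0e47de1dee2ec7f2a08569a02abb36474b092ade473d6b00833ccc16153",
}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ScenarioError(ValueError):
    """Raised when a scenario configuration violates an invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyAssembly:
    """A small reference assembly: ordered mapping of chromosome name -> sequence."""

    chromosomes: dict[str, str]

    def __post_init__(self):
        if not self.chromosomes:
            raise ScenarioError("assembly has no chromosomes")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ScenarioError(f"chromosome {name!r} is empty")
            if set(seq) - set("ACGT"):
                raise ScenarioError(f"chromosome {name!r} has non-ACGT characters")

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.chromosomes.items()}


@dataclass(frozen=True)
class BreakpointPair:
    """The two breakends of a reciprocal translocation with fold-back topology.

    der(4) retains ``chrom_a[0, pos_a)`` and ``chrom_b[0, pos_b)``; der(3)
    retains the two distal segments.  ``del_len`` bases of chromosome A
    starting at ``pos_a`` are lost at the der(3) junction (the microdeletion).
    """

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    topology: str = FOLD_BACK_JOIN
    del_len: int = 0
    del_motif: str = ""

    def __post_init__(self):
        if self.topology != FOLD_BACK_JOIN:
            raise ScenarioError(f"unsupported topology {self.topology!r}")
        if self.del_len != len(self.del_motif):
            raise ScenarioError("del_motif length != del_len")
        if self.del_len < 0:
            raise ScenarioError("del_len must be >= 0")

    def validate_on(self, assembly: ToyAssembly) -> None:
        seq_a = assembly[self.chrom_a]
        seq_b = assembly[self.chrom_b]
        if not 0 < self.pos_a < len(seq_a):
            raise ScenarioError("pos_a outside chromosome")
        if not 0 < self.pos_b < len(seq_b):
            raise ScenarioError("pos_b outside chromosome")
        if self.pos_a + self.del_len > len(seq_a):
            raise ScenarioError("deleted motif extends past chromosome end")
        observed = seq_a[self.pos_a : self.pos_a + self.del_len]
        if observed != self.del_motif:
            raise ScenarioError(
                f"deleted motif mismatch: reference has {observed!r}, "
                f"breakpoint declares {self.del_motif!r}"
            )


@dataclass(frozen=True)
class SegmentProvenance:
    """One building block of a derivative: a source interval and orientation."""

    source: str
    start: int
    end: int
    strand: str  # '+' copied as-is, '-' reverse-complemented

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Derivative:
    name: str
    seq: str
    segments: tuple[SegmentProvenance, ...]


@dataclass(frozen=True)
class DerivativePair:
    der3: Derivative
    der4: Derivative


@dataclass
class MarkerMap:
    """Markers with optional physical (bp) and genetic (cM) positions.

    Backed by a DataFrame with columns name, chrom, pos_bp, cm, phase.
    phase is one of MICROSAT, SNPCHIP, SEQ_STS and records which stage of the
    mapping effort a marker belongs to.
    """

    df: pd.DataFrame

    def __post_init__(self):
        required = {"name", "chrom", "pos_bp", "cm", "phase"}
        if not required.issubset(self.df.columns):
            raise ScenarioError(f"marker map needs columns {sorted(required)}")
        if self.df["name"].duplicated().any():
            raise ScenarioError("duplicate marker names")
        if (self.df["pos_bp"].isna() & self.df["cm"].isna()).any():
            raise ScenarioError("every marker needs a physical or genetic position")

    @classmethod
    def from_records(cls, records) -> "MarkerMap":
        df = pd.DataFrame(records, columns=["name", "chrom", "pos_bp", "cm", "phase"])
        df["pos_bp"] = df["pos_bp"].astype("Int64")
        return cls(df)

    def on_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def names(self) -> list[str]:
        return list(self.df["name"])

    def position_bp(self, name: str):
        row = self.df.loc[self.df["name"] == name]
        if row.empty:
            raise KeyError(name)
        v = row["pos_bp"].iloc[0]
        return None if pd.isna(v) else int(v)

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "MarkerMap":
        df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})
        df["pos_bp"] = df["pos_bp"].astype("Int64")
        return cls(df)


@dataclass(frozen=True)
class GeneModel:
    """An exon/intron model on one chromosome (exons 0-based half-open)."""

    name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ScenarioError("empty exon")
            if s <= prev_end:
                raise ScenarioError("exons must be strictly increasing, non-overlapping")
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class LibraryModel:
    """Long-insert mate-pair library: innie/FR orientation after the standard
    reverse-complement preprocessing of raw outie mate-pair reads."""

    insert_mean: float = 6000.0
    insert_sd: float = 600.0
    read_len: int = 100
    insert_bounds: tuple[float, float] = (1000.0, 12000.0)
    mapq_high: int = 60
    mapq_low: int = 5
    low_mapq_frac: float = 0.05

    def __post_init__(self):
        if self.insert_mean <= 0 or self.insert_sd < 0:
            raise ScenarioError("invalid insert distribution")
        if self.read_len >= self.insert_mean:
            raise ScenarioError("read length must be shorter than the mean insert")
        lo, hi = self.insert_bounds
        if not lo <= self.insert_mean <= hi:
            raise ScenarioError("truncation bounds must bracket the mean insert")


GENOTYPES = ("N/N", "N/T", "T/T")


@dataclass(frozen=True)
class PoolSpec:
    """A pooled sequencing sample: individuals with translocation genotypes,
    plus the chimeric-noise burden and recurrent artifact loci of the library."""

    pool_id: str
    genotypes: tuple[tuple[str, str], ...]
    noise_pairs: int = 60
    artifact_loci: tuple[tuple[int, int, int], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not self.genotypes:
            raise ScenarioError("pool needs at least one individual")
        for _, g in self.genotypes:
            if g not in GENOTYPES:
                raise ScenarioError(f"unknown genotype {g!r}")


@dataclass(frozen=True)
class PrimerPlacement:
    """A named primer: its synthesized 5'->3' sequence plus where it sits."""

    name: str
    seq: str
    template: str
    start: int
    end: int
    strand: str  # '+': seq == template[start:end]; '-': seq == revcomp(template[start:end])


@dataclass
class Scenario:
    """A fully materialized synthetic study: genome, derivatives, markers,
    primers, gene model, library model, and the master seed."""

    name: str
    assembly: ToyAssembly
    breakpoint: BreakpointPair
    derivatives: DerivativePair
    markers: MarkerMap
    primers: dict[str, PrimerPlacement]
    gene: GeneModel
    library: LibraryModel
    seed: int
    config: "ScenarioConfig"

    @property
    def chrom_a(self) -> str:
        return self.breakpoint.chrom_a

    @property
    def chrom_b(self) -> str:
        return self.breakpoint.chrom_b

    def haplotypes(self) -> dict[str, str]:
        """All four distinct haplotype sequences relevant to the translocation."""
        return {
            self.chrom_a: self.assembly[self.chrom_a],
            self.chrom_b: self.assembly[self.chrom_b],
            "der3": self.derivatives.der3.seq,
            "der4": self.derivatives.der4.seq,
        }

    def genotype_haplotypes(self, genotype: str) -> list[str]:
        """Haplotype names carried by one individual for the two chromosomes."""
        a, b = self.chrom_a, self.chrom_b
        return {
            "N/N": [a, a, b, b],
            "N/T": [a, b, "der3", "der4"],
            "T/T": ["der3", "der3", "der4", "der4"],
        }[genotype]

    def primer_seq(self, name: str) -> str:
        return self.primers[name].seq


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the synthetic study.  The defaults are the 'feve_toy'
    scenario: the real chromosomes scaled by 1e-3 so that Mb coordinates
    become bp coordinates (23.8 Mb -> 23,800 bp)."""

    name: str = "feve_toy"
    chrom_a: str = "SSC3"
    len_a: int = 50_000
    chrom_b: str = "SSC4"
    len_b: int = 150_000
    pos_a: int = 23_800
    pos_b: int = 107_800
    del_motif: str = "TACAC"
    # marker universe
    n_microsat_a: int = 12
    n_microsat_b: int = 13
    snp_spacing: int = 200
    snp_gap_radius: int = 1_500
    # gene model: exon count is configurable because only "intron 15" and
    # "four exons lost" are fixed facts about the modeled gene
    gene_name: str = "ADAMTSL4"
    n_exons: int = 19
    library: LibraryModel = field(default_factory=LibraryModel)

    def validate(self) -> None:
        if not 0 < self.pos_a < self.len_a:
            raise ScenarioError("pos_a outside chromosome A")
        if not 0 < self.pos_b < self.len_b:
            raise ScenarioError("pos_b outside chromosome B")
        if self.pos_a + len(self.del_motif) >= self.len_a:
            raise ScenarioError("deletion extends past chromosome A")


DEFAULT_SEED = 20171109


# ---------------------------------------------------------------------------
# derivative construction
# ---------------------------------------------------------------------------


def construct_derivatives(assembly: ToyAssembly, breakpoint: BreakpointPair) -> DerivativePair:
    """Build der(3)/der(4) sequences under the fold-back topology.

    der(4) = chrB[0,posB) ++ revcomp(chrA[0,posA))   (right end joins right end)
    der(3) = revcomp(chrB[posB,end)) ++ chrA[posA+delLen,end)

    This is the only join topology consistent with a hybrid-panel pattern in
    which the same derivative is positive for the proximal markers of *both*
    chromosomes.
    """
    breakpoint.validate_on(assembly)
    a, b = breakpoint.chrom_a, breakpoint.chrom_b
    seq_a, seq_b = assembly[a], assembly[b]
    pa, pb, d = breakpoint.pos_a, breakpoint.pos_b, breakpoint.del_len

    der4_seq = seq_b[:pb] + revcomp(seq_a[:pa])
    der4 = Derivative(
        "der4",
        der4_seq,
        (
            SegmentProvenance(b, 0, pb, "+"),
            SegmentProvenance(a, 0, pa, "-"),
        ),
    )
    der3_seq = revcomp(seq_b[pb:]) + seq_a[pa + d :]
    der3 = Derivative(
        "der3",
        der3_seq,
        (
            SegmentProvenance(b, pb, len(seq_b), "-"),
            SegmentProvenance(a, pa + d, len(seq_a), "+"),
        ),
    )
    assert len(der3_seq) + len(der4_seq) == len(seq_a) + len(seq_b) - d
    return DerivativePair(der3=der3, der4=der4)


# ---------------------------------------------------------------------------
# scenario construction
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def _build_markers(cfg: ScenarioConfig, rng: np.random.Generator) -> MarkerMap:
    """Marker universe in three phases, mirroring a real mapping effort:
    sparse microsatellites with genetic positions, a finite SNP-chip set with
    a marker drought around each breakpoint, and dense sequence STSs
    (represented implicitly; see walk.dense_phase)."""
    records = []
    for chrom, length, n_ms in (
        (cfg.chrom_a, cfg.len_a, cfg.n_microsat_a),
        (cfg.chrom_b, cfg.len_b, cfg.n_microsat_b),
    ):
        pos = np.sort(rng.choice(np.arange(500, length - 500), size=n_ms, replace=False))
        for i, p in enumerate(pos):
            # toy genetic map: 1 cM per kb, monotone with physical order
            records.append((f"MS_{chrom}_{i:02d}", chrom, int(p), round(p / 1000.0, 3), "MICROSAT"))
        bp = cfg.pos_a if chrom == cfg.chrom_a else cfg.pos_b
        snp_pos = np.arange(cfg.snp_spacing, length - 1, cfg.snp_spacing)
        snp_pos = snp_pos + rng.integers(-cfg.snp_spacing // 4, cfg.snp_spacing // 4 + 1, snp_pos.size)
        snp_pos = snp_pos[(np.abs(snp_pos - bp) > cfg.snp_gap_radius) & (snp_pos > 0) & (snp_pos < length)]
        for i, p in enumerate(np.unique(snp_pos)):
            records.append((f"SNP_{chrom}_{i:04d}", chrom, int(p), None, "SNPCHIP"))
    return MarkerMap.from_records(records)


def _build_gene(cfg: ScenarioConfig) -> GeneModel:
    """Exons 1..15 proximal to the B breakpoint, remainder distal, all 100 bp.
    The breakpoint falls in intron 15, so the derivative keeps 15 exons."""
    exons = [(100_000 + k * 500, 100_000 + k * 500 + 100) for k in range(15)]
    for k in range(cfg.n_exons - 15):
        start = 110_000 + k * 500
        exons.append((start, start + 100))
    return GeneModel(cfg.gene_name, cfg.chrom_b, "+", tuple(exons))


def _build_primers(cfg: ScenarioConfig, assembly: ToyAssembly, gene: GeneModel) -> dict[str, PrimerPlacement]:
    """Genotyping, junction-validation and RT-PCR primer placements.

    The three-primer genotyping assay is sized so the normal-copy product is
    346 bp and the der(4) junction product is 277 bp.  The reverse primer for
    the translocated product sits upstream of the A breakpoint and is stored
    as the top-strand sequence of chromosome A: on der(4), where that segment
    is inverted, it acts as a reverse primer.
    """
    seq_a, seq_b = assembly[cfg.chrom_a], assembly[cfg.chrom_b]
    placements = {}

    def place(name, template, seq, start, end, strand):
        placements[name] = PrimerPlacement(name, seq, template, start, end, strand)

    place("Trsl_SSC4.Up", cfg.chrom_b, seq_b[107_601:107_621], 107_601, 107_621, "+")
    place("Trsl_SSC4.Dn", cfg.chrom_b, revcomp(seq_b[107_927:107_947]), 107_927, 107_947, "-")
    place("Trsl_SSC3.Dn", cfg.chrom_a, seq_a[23_722:23_742], 23_722, 23_742, "+")
    place("Trsl_SSC3.Up", cfg.chrom_a, revcomp(seq_a[23_950:23_970]), 23_950, 23_970, "-")

    # RT-PCR primers, defined inside exon sequences (1-based exon numbering)
    def exon_seq(k):
        s, e = gene.exons[k - 1]
        return seq_b[s:e], s

    for name, fwd_exon, rev_exon in (("Ex13_14", 13, 14), ("Ex15_17", 15, 17)):
        fseq, fs = exon_seq(fwd_exon)
        rseq, rs = exon_seq(rev_exon)
        place(f"{name}.Up", cfg.chrom_b, fseq[10:30], fs + 10, fs + 30, "+")
        place(f"{name}.Dn", cfg.chrom_b, revcomp(rseq[40:60]), rs + 40, rs + 60, "-")

    for p in placements.values():
        template = assembly[p.template]
        site = template[p.start : p.end]
        expected = p.seq if p.strand == "+" else revcomp(p.seq)
        if site != expected:
            raise ScenarioError(f"primer {p.name} placed off-template")
    return placements


def build_scenario(config: ScenarioConfig | None = None, seed: int = DEFAULT_SEED) -> Scenario:
    """Materialize a scenario deterministically from (config, seed)."""
    cfg = config or ScenarioConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    seq_a = _random_sequence(rng, cfg.len_a)
    seq_b = _random_sequence(rng, cfg.len_b)
    d = len(cfg.del_motif)
    if d:
        seq_a = seq_a[: cfg.pos_a] + cfg.del_motif + seq_a[cfg.pos_a + d :]
    assembly = ToyAssembly({cfg.chrom_a: seq_a, cfg.chrom_b: seq_b})
    bp = BreakpointPair(
        chrom_a=cfg.chrom_a,
        pos_a=cfg.pos_a,
        chrom_b=cfg.chrom_b,
        pos_b=cfg.pos_b,
        del_len=d,
        del_motif=cfg.del_motif,
    )
    derivatives = construct_derivatives(assembly, bp)
    markers = _build_markers(cfg, rng)
    gene = _build_gene(cfg)
    primers = _build_primers(cfg, assembly, gene)
    return Scenario(
        name=cfg.name,
        assembly=assembly,
        breakpoint=bp,
        derivatives=derivatives,
        markers=markers,
        primers=primers,
        gene=gene,
        library=cfg.library,
        seed=seed,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# hybrid-panel simulation
# ---------------------------------------------------------------------------


def marker_on_derivative(pos: int, chrom: str, derivative: str, breakpoint: BreakpointPair) -> bool:
    """Whether a marker at ``pos`` on ``chrom`` lies on the given derivative.

    Markers inside the deleted motif lie on neither derivative.
    """
    pa, pb, d = breakpoint.pos_a, breakpoint.pos_b, breakpoint.del_len
    if chrom == breakpoint.chrom_a:
        return pos < pa if derivative == "der4" else pos >= pa + d
    if chrom == breakpoint.chrom_b:
        return pos < pb if derivative == "der4" else pos >= pb
    return False


def simulate_hybrid_panel(
    scenario: Scenario,
    n_clones: int = 12,
    retention_prob: float = 0.4,
    assay_failure_prob: float = 0.0,
    seed: int = 0,
    marker_phase: str = "MICROSAT",
):
    """Simulate a somatic-hybrid clone panel from a homozygous-carrier donor.

    The donor contributes only der(3)/der(4) for the two chromosomes of
    interest; each clone independently retains each derivative with
    ``retention_prob``.  A marker scores 1 iff it lies on a retained fragment
    and the PCR assay did not fail (failures flip 1 -> 0).

    Returns (RetentionMatrix, contents) where contents maps clone name to the
    set of retained derivatives.
    """
    from .hybrid_panel import RetentionMatrix

    if not (0 <= retention_prob <= 1 and 0 <= assay_failure_prob <= 1):
        raise ScenarioError("probabilities must be in [0, 1]")
    if n_clones < 1:
        raise ScenarioError("need at least one clone")
    rng = np.random.default_rng(seed)
    mdf = scenario.markers.df
    mdf = mdf[mdf["phase"] == marker_phase] if marker_phase else mdf
    clone_names = [f"Hc{i + 1}" for i in range(n_clones)]
    contents = {}
    calls = np.zeros((len(mdf), n_clones), dtype=np.int8)
    positions = mdf["pos_bp"].astype(int).to_numpy()
    chroms = mdf["chrom"].to_numpy()
    for j, clone in enumerate(clone_names):
        content = {d for d in ("der3", "der4") if rng.random() < retention_prob}
        contents[clone] = content
        for i, (pos, chrom) in enumerate(zip(positions, chroms)):
            present = any(
                marker_on_derivative(int(pos), chrom, d, scenario.breakpoint) for d in content
            )
            if present and rng.random() >= assay_failure_prob:
                calls[i, j] = 1
    matrix = pd.DataFrame(calls, index=list(mdf["name"]), columns=clone_names)
    return RetentionMatrix(matrix, MarkerMap(mdf.reset_index(drop=True))), contents


# ---------------------------------------------------------------------------
# mate-pair simulation
# ---------------------------------------------------------------------------

PAIR_TABLE_COLUMNS = [
    "read_id",
    "chrom1",
    "pos1",
    "strand1",
    "chrom2",
    "pos2",
    "strand2",
    "mapq",
    "pool",
]


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Sample a truncated normal by rejection; exact, vectorized."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _map_reads_through(derivative: Derivative, starts, strands, read_len):
    """Map read intervals on a derivative back to reference coordinates.

    Returns (chrom array, ref start array, ref strand array, ok mask); reads
    crossing a provenance boundary are masked out (they would not align).
    """
    n = starts.shape[0]
    chroms = np.empty(n, dtype=object)
    ref_start = np.zeros(n, dtype=np.int64)
    ref_strand = np.empty(n, dtype="U1")
    ok = np.zeros(n, dtype=bool)
    offset = 0
    for seg in derivative.segments:
        lo, hi = offset, offset + seg.length
        inside = (starts >= lo) & (starts + read_len <= hi)
        if inside.any():
            s = starts[inside] - lo
            if seg.strand == "+":
                ref_start[inside] = seg.start + s
                ref_strand[inside] = strands[inside]
            else:
                ref_start[inside] = seg.end - s - read_len
                flipped = np.where(strands[inside] == "+", "-", "+")
                ref_strand[inside] = flipped
            chroms[inside] = seg.source
            ok |= inside
        offset = hi
    return chroms, ref_start, ref_strand, ok


def simulate_pool_matepairs(
    scenario: Scenario,
    pool: PoolSpec,
    physical_coverage: float = 17.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a pooled 6-kb-insert mate-pair library over all haplotypes.

    Fragment counts per haplotype are Poisson with mean
    ``length * coverage / insert_mean`` so every haplotype copy carries the
    requested physical coverage.  Each fragment emits two ``read_len`` reads
    in reference coordinates (innie orientation on a normal chromosome); a
    fragment spanning a derivative junction yields an inter-chromosomal pair
    with the strand signature implied by the fold-back topology.  Uniform
    chimeric noise pairs and recurrent artifact pairs are appended.

    Returns a pair-table DataFrame (see PAIR_TABLE_COLUMNS).
    """
    if physical_coverage <= 0:
        raise ScenarioError("coverage must be positive")
    lib = scenario.library
    rng = np.random.default_rng(seed)
    haps = scenario.haplotypes()
    by_name = {
        scenario.chrom_a: haps[scenario.chrom_a],
        scenario.chrom_b: haps[scenario.chrom_b],
    }
    derivs = {"der3": scenario.derivatives.der3, "der4": scenario.derivatives.der4}
    L = lib.read_len
    lo, hi = lib.insert_bounds

    rows_c1, rows_p1, rows_s1 = [], [], []
    rows_c2, rows_p2, rows_s2 = [], [], []
    hap_list = []
    for _, genotype in pool.genotypes:
        hap_list.extend(scenario.genotype_haplotypes(genotype))

    for hap in hap_list:
        seq_len = len(haps[hap])
        n = rng.poisson(physical_coverage * seq_len / lib.insert_mean)
        if n == 0:
            continue
        ins = np.round(
            _truncated_normal(rng, lib.insert_mean, lib.insert_sd, lo, max(hi, 2 * L + 2), n)
        ).astype(np.int64)
        ins = np.clip(ins, 2 * L + 1, seq_len - 1)
        starts = np.floor(rng.random(n) * (seq_len - ins + 1)).astype(np.int64)
        r1 = starts
        r2 = starts + ins - L
        s1 = np.full(n, "+", dtype="U1")
        s2 = np.full(n, "-", dtype="U1")
        if hap in derivs:
            c1, p1, st1, ok1 = _map_reads_through(derivs[hap], r1, s1, L)
            c2, p2, st2, ok2 = _map_reads_through(derivs[hap], r2, s2, L)
            keep = ok1 & ok2
            rows_c1.append(c1[keep]); rows_p1.append(p1[keep]); rows_s1.append(st1[keep])
            rows_c2.append(c2[keep]); rows_p2.append(p2[keep]); rows_s2.append(st2[keep])
        else:
            rows_c1.append(np.full(n, hap, dtype=object)); rows_p1.append(r1); rows_s1.append(s1)
            rows_c2.append(np.full(n, hap, dtype=object)); rows_p2.append(r2); rows_s2.append(s2)

    # chimeric background: uniformly random inter-chromosomal pairs
    if pool.noise_pairs:
        n = pool.noise_pairs
        la, lb = len(by_name[scenario.chrom_a]), len(by_name[scenario.chrom_b])
        rows_c1.append(np.full(n, scenario.chrom_a, dtype=object))
        rows_p1.append(rng.integers(0, la - L, n))
        rows_s1.append(rng.choice(np.array(["+", "-"]), n))
        rows_c2.append(np.full(n, scenario.chrom_b, dtype=object))
        rows_p2.append(rng.integers(0, lb - L, n))
        rows_s2.append(rng.choice(np.array(["+", "-"]), n))

    # recurrent artifact loci: tight pseudo-clusters present in every pool
    for pa, pb, support in pool.artifact_loci:
        off_a = np.floor(rng.random(support) * (lib.insert_mean - L)).astype(np.int64)
        off_b = np.floor(rng.random(support) * (lib.insert_mean - L)).astype(np.int64)
        rows_c1.append(np.full(support, scenario.chrom_a, dtype=object))
        rows_p1.append(np.maximum(pa - L - off_a, 0))
        rows_s1.append(np.full(support, "+", dtype="U1"))
        rows_c2.append(np.full(support, scenario.chrom_b, dtype=object))
        rows_p2.append(np.maximum(pb - L - off_b, 0))
        rows_s2.append(np.full(support, "+", dtype="U1"))

    c1 = np.concatenate(rows_c1); p1 = np.concatenate(rows_p1); s1 = np.concatenate(rows_s1)
    c2 = np.concatenate(rows_c2); p2 = np.concatenate(rows_p2); s2 = np.concatenate(rows_s2)
    total = c1.shape[0]
    mapq = np.where(rng.random(total) < lib.low_mapq_frac, lib.mapq_low, lib.mapq_high)
    df = pd.DataFrame(
        {
            "read_id": [f"{pool.pool_id}_{i}" for i in range(total)],
            "chrom1": c1,
            "pos1": p1,
            "strand1": s1,
            "chrom2": c2,
            "pos2": p2,
            "strand2": s2,
            "mapq": mapq,
            "pool": pool.pool_id,
        }
    )
    return df


def expected_junction_pairs(scenario: Scenario, pool: PoolSpec, physical_coverage: float) -> float:
    """Closed-form expectation of junction-spanning mate-pairs in a pool.

    A fragment of insert ``i`` on a derivative spans the junction with both
    reads clear of it for ``i - 2L + 1`` of its ``len - i + 1`` possible
    starts.  Summed over every derivative haplotype copy in the pool.
    """
    lib = scenario.library
    L = lib.read_len
    lo, hi = lib.insert_bounds
    # numeric expectation over the (rounded) truncated-normal insert
    xs = np.arange(int(np.floor(lo)), int(np.ceil(hi)) + 1)
    z = (xs - lib.insert_mean) / lib.insert_sd
    w = np.exp(-0.5 * z * z)
    w /= w.sum()
    total = 0.0
    der_lens = {
        "der3": len(scenario.derivatives.der3.seq),
        "der4": len(scenario.derivatives.der4.seq),
    }
    for _, genotype in pool.genotypes:
        for hap in scenario.genotype_haplotypes(genotype):
            if hap not in der_lens:
                continue
            n_mean = physical_coverage * der_lens[hap] / lib.insert_mean
            frac = np.sum(w * np.maximum(xs - 2 * L + 1, 0) / (der_lens[hap] - xs + 1))
            total += n_mean * frac
    return float(total)


# ---------------------------------------------------------------------------
# Table 1 fixture
# ---------------------------------------------------------------------------


def _fixture_bytes(fname: str) -> bytes:
    data = resources.files("translomap.data").joinpath(fname).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    expected = _FIXTURE_DIGESTS[fname]
    if expected and digest != expected:
        raise ScenarioError(f"fixture {fname} checksum mismatch: {digest}")
    return data


def load_table1():
    """Load the packaged hybrid-clone retention panel: 37 microsatellites
    (12 genome-wide, 12 on SSC3, 13 on SSC4) scored on 12 hybrid clones.

    Returns (MarkerMap, RetentionMatrix).  Physical positions (bp) are known
    only for SW251, SW487, SW512 and SW2435.
    """
    import io as _io

    from .hybrid_panel import RetentionMatrix

    markers = MarkerMap.from_tsv(_io.BytesIO(_fixture_bytes("table1_markers.tsv")))
    calls = pd.read_csv(
        _io.BytesIO(_fixture_bytes("table1_retention.tsv")), sep="\t", index_col="marker"
    )
    matrix = RetentionMatrix(calls.astype(np.int8), markers)
    return markers, matrix


# ---------------------------------------------------------------------------
# external interfaces: FASTA / TSV writers, scenario persistence
# ---------------------------------------------------------------------------


def write_fasta(scenario: Scenario, path) -> None:
    """Write the two reference chromosomes and both derivatives as FASTA."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in scenario.haplotypes().items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_pair_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=PAIR_TABLE_COLUMNS)


def read_pair_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})


def save_scenario(scenario: Scenario, outdir) -> None:
    """Persist a scenario as FASTA + marker TSV + a YAML config/seed stub
    from which it can be rebuilt deterministically."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(scenario, outdir / "genome.fasta")
    scenario.markers.to_tsv(outdir / "markers.tsv")
    cfg = scenario.config
    lib = cfg.library
    payload = {
        "seed": scenario.seed,
        "config": {
            "name": cfg.name,
            "chrom_a": cfg.chrom_a,
            "len_a": cfg.len_a,
            "chrom_b": cfg.chrom_b,
            "len_b": cfg.len_b,
            "pos_a": cfg.pos_a,
            "pos_b": cfg.pos_b,
            "del_motif": cfg.del_motif,
            "n_microsat_a": cfg.n_microsat_a,
            "n_microsat_b": cfg.n_microsat_b,
            "snp_spacing": cfg.snp_spacing,
            "snp_gap_radius": cfg.snp_gap_radius,
            "gene_name": cfg.gene_name,
            "n_exons": cfg.n_exons,
            "library": {
                "insert_mean": lib.insert_mean,
                "insert_sd": lib.insert_sd,
                "read_len": lib.read_len,
                "insert_bounds": list(lib.insert_bounds),
                "mapq_high": lib.mapq_high,
                "mapq_low": lib.mapq_low,
                "low_mapq_frac": lib.low_mapq_frac,
            },
        },
    }
    (outdir / "scenario.yaml").write_text(yaml.safe_dump(payload))


def load_scenario(outdir) -> Scenario:
    """Rebuild a scenario from a directory written by :func:`save_scenario`."""
    import yaml

    payload = yaml.safe_load((Path(outdir) / "scenario.yaml").read_text())
    cfg_dict = dict(payload["config"])
    lib_dict = cfg_dict.pop("library")
    lib = LibraryModel(
        insert_mean=lib_dict["insert_mean"],
        insert_sd=lib_dict["insert_sd"],
        read_len=lib_dict["read_len"],
        insert_bounds=tuple(lib_dict["insert_bounds"]),
        mapq_high=lib_dict["mapq_high"],
        mapq_low=lib_dict["mapq_low"],
        low_mapq_frac=lib_dict["low_mapq_frac"],
    )
    cfg = ScenarioConfig(library=lib, **cfg_dict)
    return build_scenario(cfg, seed=payload["seed"])


def default_pools(scenario: Scenario) -> tuple[PoolSpec, PoolSpec]:
    """The study's case/control pools: five individuals each, one heterozygous
    carrier in the case pool, shared recurrent artifact loci in both."""
    artifacts = ((8_000, 30_000, 15), (15_000, 70_000, 15), (40_000, 130_000, 15))
    case = PoolSpec(
        pool_id="case",
        genotypes=tuple((f"LW{i}", "N/T" if i == 0 else "N/N") for i in range(5)),
        noise_pairs=60,
        artifact_loci=artifacts,
    )
    control = PoolSpec(
        pool_id="control",
        genotypes=tuple((f"DU{i}", "N/N") for i in range(5)),
        noise_pairs=60,
        artifact_loci=artifacts,
    )
    return case, control
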