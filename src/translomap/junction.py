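"""In-silico PCR, junction discovery and base-pair breakpoint calling.

The PCR engine is a pure site-logic model: primers match exactly (the
forward primer as-is, the reverse primer as its reverse complement), and
every ordered site pair on a template within the size limit yields an
amplicon.  On top of it sit the cross-primer junction search, the split
breakpoint caller with microhomology/microdeletion reconciliation, the
three-primer genotyping assay, and the truncated-transcript RT-PCR
prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .scenario import (
    Derivative,
    GeneModel,
    Scenario,
    ScenarioError,
    revcomp,
)

DEFAULT_MAX_LEN = 10_000
MIN_ANCHOR = 20
_SEED_LEN = 30


class NoCallError(ScenarioError):
    """The junction sequence cannot be anchored on both references."""


class StraddleError(ScenarioError):
    """An exon straddles the breakpoint; refusing to truncate it silently."""


class UnresolvedGenotypeError(ScenarioError):
    def __init__(self, message, products=None):
        super().__init__(message)
        self.products = products or []


@dataclass(frozen=True)
class Primer:
    name: str
    seq: str

    def __post_init__(self):
        if len(self.seq) < 15:
            raise ScenarioError(f"primer {self.name} shorter than 15 nt")
        if set(self.seq) - set("ACGT"):
            raise ScenarioError(f"primer {self.name} has non-ACGT characters")

    def __len__(self):
        return len(self.seq)


@dataclass(frozen=True)
class Amplicon:
    template: str
    start: int
    end: int
    forward: str  # primer name annealing at start on the top strand
    reverse: str  # primer name whose reverse complement ends at end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class JunctionCall:
    """One derivative junction located on both references.

    ``pos_a``/``pos_b`` are the canonical (left-aligned on chromosome A)
    breakend coordinates; the intervals have width == microhomology.
    """

    chrom_a: str
    pos_a: int
    interval_a: tuple[int, int]
    chrom_b: str
    pos_b: int
    interval_b: tuple[int, int]
    microhomology: int
    derivative: str  # 'der3' | 'der4'


@dataclass(frozen=True)
class ReconciledBreakpoint:
    del_len: int
    del_motif: str
    chrom_b_gap: int
    duplicated: bool  # True when the two junctions overlap on chromosome A
    pos_a: int = 0    # resolved der(4) breakend on chromosome A
    pos_b: int = 0    # resolved common breakpoint on chromosome B


@dataclass(frozen=True)
class GenotypeCall:
    sample: str
    genotype: str
    product_lengths: tuple[int, ...]


@dataclass(frozen=True)
class TranscriptResult:
    cdna: str
    exons_retained: int
    exons_lost: int


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def insilico_pcr(
    templates: dict[str, str],
    forward: Primer,
    reverse: Primer,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[Amplicon]:
    """Predict amplicons by exact primer-site matching.

    Both strand assignments are considered, so the amplicon set is symmetric
    in the two primers.  Products are sorted by (template, start).
    """
    if max_len <= max(len(forward), len(reverse)):
        raise ScenarioError("max_len must exceed the primer lengths")
    seen = set()
    out = []
    for p, q in ((forward, reverse), (reverse, forward)):
        for tname, tseq in templates.items():
            fwd_sites = _find_all(tseq, p.seq)
            rev_sites = _find_all(tseq, revcomp(q.seq))
            for i in fwd_sites:
                for j in rev_sites:
                    end = j + len(q)
                    length = end - i
                    if j < i or length > max_len or length < max(len(p), len(q)):
                        continue
                    key = (tname, i, end)
                    if key not in seen:
                        seen.add(key)
                        out.append(Amplicon(tname, i, end, p.name, q.name))
    out.sort(key=lambda a: (a.template, a.start, a.end))
    return out


def cross_primer_search(
    primers_a: list[Primer],
    primers_b: list[Primer],
    templates: dict[str, str],
    max_len: int = DEFAULT_MAX_LEN,
) -> list[tuple[Primer, Primer, list[Amplicon]]]:
    """Test every A-side x B-side primer combination; keep the productive ones.

    This is the junction-bridging experiment: on a derivative template only
    the combination whose two primers point toward the junction from the two
    retained segments can amplify.
    """
    if not primers_a or not primers_b:
        return []
    viable = []
    for pa in primers_a:
        for pb in primers_b:
            amps = insilico_pcr(templates, pa, pb, max_len=max_len)
            if amps:
                viable.append((pa, pb, amps))
    return viable


# ---------------------------------------------------------------------------
# breakpoint calling
# ---------------------------------------------------------------------------


def _anchor_forward(query: str, ref: str) -> tuple[int, int]:
    """Locate query[:seed] in ref and extend the exact match rightward.

    Returns (ref offset of the match start, matched length).
    """
    seed = query[:_SEED_LEN]
    p = ref.find(seed)
    if p == -1:
        raise NoCallError("anchor seed not found in reference")
    m = _SEED_LEN
    while m < len(query) and p + m < len(ref) and query[m] == ref[p + m]:
        m += 1
    return p, m


def call_breakpoint(
    junction_seq: str,
    ref_a: tuple[str, str],
    ref_b: tuple[str, str],
    derivative: str = "der4",
) -> JunctionCall:
    """Split a sequenced junction fragment against the two references.

    Under the fold-back topology a der(4) junction reads as
    ``chrB[...b) ++ revcomp(chrA[...a))`` and a der(3) junction as
    ``revcomp(chrB[b...]) ++ chrA[a...]``.  The call maximizes the exact
    match extending from each end; bases matching both references are
    reported as microhomology, left-aligned on chromosome A, with
    breakend-interval width equal to the homology length.
    """
    name_a, seq_a = ref_a
    name_b, seq_b = ref_b
    if len(junction_seq) < 2 * _SEED_LEN:
        raise NoCallError("junction sequence shorter than twice the anchor seed")

    if derivative == "der4":
        # left part matches chrB forward; rc(junction) starts with chrA forward
        qb, qa = junction_seq, revcomp(junction_seq)
        b0, mb = _anchor_forward(qb, seq_b)
        a0, ma = _anchor_forward(qa, seq_a)
        b_right = b0 + mb
        a_right = a0 + ma
        overlap = mb + ma - len(junction_seq)
        if overlap < 0:
            raise NoCallError("unmatched bases between the two anchors")
        if mb - overlap < MIN_ANCHOR or ma - overlap < MIN_ANCHOR:
            raise NoCallError("anchored match shorter than the minimum on one side")
        mh = overlap
        pos_a = a_right - mh  # left-aligned on chromosome A
        pos_b = b_right
        return JunctionCall(
            chrom_a=name_a,
            pos_a=pos_a,
            interval_a=(pos_a, pos_a + mh),
            chrom_b=name_b,
            pos_b=pos_b,
            interval_b=(pos_b - mh, pos_b),
            microhomology=mh,
            derivative="der4",
        )
    if derivative == "der3":
        return call_breakpoint_der3(junction_seq, ref_a, ref_b)
    raise ScenarioError(f"unknown derivative {derivative!r}")


def _anchor_backward(query: str, ref: str) -> tuple[int, int]:
    """Locate query[-seed:] in ref and extend the exact match leftward.

    Returns (ref offset just past the match end, matched length).
    """
    seed = query[-_SEED_LEN:]
    p = ref.find(seed)
    if p == -1:
        raise NoCallError("anchor seed not found in reference")
    end = p + _SEED_LEN
    n = _SEED_LEN
    while n < len(query) and end - n - 1 >= 0 and query[len(query) - n - 1] == ref[end - n - 1]:
        n += 1
    return end, n


def call_breakpoint_der3(
    junction_seq: str, ref_a: tuple[str, str], ref_b: tuple[str, str]
) -> JunctionCall:
    """der(3) junction: ``revcomp(chrB[b...]) ++ chrA[a...]``."""
    name_a, seq_a = ref_a
    name_b, seq_b = ref_b
    if len(junction_seq) < 2 * _SEED_LEN:
        raise NoCallError("junction sequence shorter than twice the anchor seed")
    a_end, na = _anchor_backward(junction_seq, seq_a)
    rc = revcomp(junction_seq)
    b_end, nb = _anchor_backward(rc, seq_b)
    overlap = na + nb - len(junction_seq)
    if overlap < 0:
        raise NoCallError("unmatched bases between the two anchors")
    if na - overlap < MIN_ANCHOR or nb - overlap < MIN_ANCHOR:
        raise NoCallError("anchored match shorter than the minimum on one side")
    mh = overlap
    pos_a = a_end - na  # left-aligned on chromosome A (smallest resume point)
    pos_b = b_end - nb + mh  # the B resume point paired with that A breakend
    return JunctionCall(
        chrom_a=name_a,
        pos_a=pos_a,
        interval_a=(pos_a, pos_a + mh),
        chrom_b=name_b,
        pos_b=pos_b,
        interval_b=(pos_b - mh, pos_b),
        microhomology=mh,
        derivative="der3",
    )


def reconcile_junctions(
    der3_call: JunctionCall, der4_call: JunctionCall, ref_a: tuple[str, str]
) -> ReconciledBreakpoint:
    """Net microdeletion between the two derivative junctions.

    The deleted bases are those of chromosome A present in neither
    derivative: the gap between der(4)'s A breakend and der(3)'s A resume
    point.  A negative gap means the junctions overlap (duplicated bases).
    """
    if (der3_call.chrom_a, der3_call.chrom_b) != (der4_call.chrom_a, der4_call.chrom_b):
        raise ScenarioError("junction calls are on different chromosome pairs")
    name_a, seq_a = ref_a
    # Each call is ambiguous across its microhomology: the admissible breakend
    # pairs are (pos_a + t, pos_b - t) for t in [0, mh].  The net deletion is
    # invariant under that choice; the motif is read at the representation
    # that places both junctions on one common chromosome-B breakpoint.
    del_len = (der3_call.pos_a - der4_call.pos_a) + (der3_call.pos_b - der4_call.pos_b)
    b_hi = min(der4_call.pos_b, der3_call.pos_b)
    b_lo = max(
        der4_call.pos_b - der4_call.microhomology,
        der3_call.pos_b - der3_call.microhomology,
    )
    if b_lo <= b_hi:
        gap_b = 0
        b_common = b_hi
        a4 = der4_call.pos_a + (der4_call.pos_b - b_hi)  # left-align motif on A
    else:
        gap_b = b_lo - b_hi  # no single consistent B breakpoint
        b_common = der4_call.pos_b
        a4 = der4_call.pos_a
    if del_len < 0:
        return ReconciledBreakpoint(
            -del_len, seq_a[a4 + del_len : a4], gap_b, duplicated=True,
            pos_a=a4, pos_b=b_common,
        )
    return ReconciledBreakpoint(
        del_len, seq_a[a4 : a4 + del_len], gap_b, duplicated=False,
        pos_a=a4, pos_b=b_common,
    )


# ---------------------------------------------------------------------------
# genotyping and expression assays
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypingAssay:
    """Three-primer multiplex: one shared forward primer, the normal-copy
    reverse primer and the translocated-copy reverse primer, decoded from
    the set of product lengths."""

    forward: Primer
    reverse_normal: Primer
    reverse_translocated: Primer
    normal_len: int = 346
    translocated_len: int = 277

    @classmethod
    def from_scenario(cls, scenario: Scenario) -> "GenotypingAssay":
        return cls(
            forward=Primer("Trsl_SSC4.Up", scenario.primer_seq("Trsl_SSC4.Up")),
            reverse_normal=Primer("Trsl_SSC4.Dn", scenario.primer_seq("Trsl_SSC4.Dn")),
            reverse_translocated=Primer("Trsl_SSC3.Dn", scenario.primer_seq("Trsl_SSC3.Dn")),
        )


def genotype_sample(
    haplotypes: dict[str, str],
    assay: GenotypingAssay,
    max_len: int = DEFAULT_MAX_LEN,
    sample: str = "sample",
) -> GenotypeCall:
    """Genotype one individual from its haplotype sequences.

    Product length sets decode as {normal} -> N/N, {translocated} -> T/T,
    both -> N/T; anything else raises UnresolvedGenotypeError.
    """
    if not haplotypes:
        raise UnresolvedGenotypeError("no haplotypes supplied")
    products = []
    for rev in (assay.reverse_normal, assay.reverse_translocated):
        products.extend(insilico_pcr(haplotypes, assay.forward, rev, max_len=max_len))
    lengths = tuple(sorted({a.length for a in products}))
    decode = {
        (assay.normal_len,): "N/N",
        (assay.translocated_len,): "T/T",
        tuple(sorted((assay.normal_len, assay.translocated_len))): "N/T",
    }
    genotype = decode.get(lengths)
    if genotype is None:
        raise UnresolvedGenotypeError(
            f"unexpected product length set {lengths}", products=products
        )
    return GenotypeCall(sample, genotype, lengths)


def splice_transcript(gene: GeneModel, target) -> TranscriptResult:
    """Splice the gene on a normal chromosome or on a derivative.

    ``target`` is either ``(chrom_name, sequence)`` for a normal chromosome
    or a :class:`Derivative`; on a derivative only exons wholly contained in
    a colinear (source == gene chromosome, '+' orientation) provenance
    segment are retained.  An exon cut by a segment boundary raises
    StraddleError rather than being silently truncated.
    """
    if isinstance(target, Derivative):
        parts = []
        retained = 0
        for s, e in gene.exons:
            offset = 0
            kept = False
            for seg in target.segments:
                if seg.source == gene.chrom and seg.strand == "+":
                    if seg.start <= s and e <= seg.end:
                        parts.append(target.seq[offset + (s - seg.start) : offset + (e - seg.start)])
                        kept = True
                    elif s < seg.end and e > seg.start:
                        raise StraddleError(
                            f"exon [{s},{e}) straddles a junction of {target.name}"
                        )
                elif seg.source == gene.chrom and (s < seg.end and e > seg.start):
                    # exon carried in inverted orientation: not a functional exon
                    pass
                offset += seg.length
            retained += int(kept)
        cdna = "".join(parts)
        return TranscriptResult(cdna, retained, gene.n_exons - retained)
    name, seq = target
    if name != gene.chrom:
        return TranscriptResult("", 0, gene.n_exons)
    for s, e in gene.exons:
        if e > len(seq):
            raise ScenarioError("exon outside chromosome")
    cdna = "".join(seq[s:e] for s, e in gene.exons)
    return TranscriptResult(cdna, gene.n_exons, 0)


def rtpcr_predict(
    transcripts: dict[str, str],
    primer_pairs: dict[str, tuple[Primer, Primer]],
    max_len: int = DEFAULT_MAX_LEN,
) -> pd.DataFrame:
    """Amplicon counts and lengths for each transcript x primer pair.

    Returns a DataFrame indexed by transcript label with one column per
    primer pair holding (product count, tuple of lengths).
    """
    rows = {}
    for label, cdna in transcripts.items():
        row = {}
        for pair_name, (fwd, rev) in primer_pairs.items():
            amps = insilico_pcr({label: cdna}, fwd, rev, max_len=max_len)
            row[pair_name] = (len(amps), tuple(a.length for a in amps))
        rows[label] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def rtpcr_pairs_from_scenario(scenario: Scenario) -> dict[str, tuple[Primer, Primer]]:
    return {
        name: (
            Primer(f"{name}.Up", scenario.primer_seq(f"{name}.Up")),
            Primer(f"{name}.Dn", scenario.primer_seq(f"{name}.Dn")),
        )
        for name in ("Ex13_14", "Ex15_17")
    }


def read_primer_tsv(path) -> list[Primer]:
    df = pd.read_csv(path, sep="\t")
    return [Primer(r["name"], r["sequence"]) for _, r in df.iterrows()]


def write_primer_tsv(primers: list[Primer], path) -> None:
    pd.DataFrame({"name": [p.name for p in primers], "sequence": [p.seq for p in primers]}).to_csv(
        path, sep="\t", index=False
    )


def write_amplicons_tsv(amplicons: list[Amplicon], path) -> None:
    pd.DataFrame(
        [
            {"template": a.template, "start": a.start, "end": a.end,
             "length": a.length, "forward": a.forward, "reverse": a.reverse}
            for a in amplicons
        ]
    ).to_csv(path, sep="\t", index=False)


def junction_neighborhood(scenario: Scenario, derivative: str, flank: int = 200) -> str:
    """Sequence around a derivative junction, ``flank`` bp on each side."""
    der = {"der3": scenario.derivatives.der3, "der4": scenario.derivatives.der4}[derivative]
    j = der.segments[0].length
    return der.seq[max(j - flank, 0) : j + flank]


def call_scenario_junctions(scenario: Scenario, flank: int = 200):
    """Convenience: call both junctions of a scenario and reconcile them."""
    ref_a = (scenario.chrom_a, scenario.assembly[scenario.chrom_a])
    ref_b = (scenario.chrom_b, scenario.assembly[scenario.chrom_b])
    der4 = call_breakpoint(junction_neighborhood(scenario, "der4", flank), ref_a, ref_b, "der4")
    der3 = call_breakpoint_der3(junction_neighborhood(scenario, "der3", flank), ref_a, ref_b)
    rec = reconcile_junctions(der3, der4, ref_a)
    return der4, der3, rec
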