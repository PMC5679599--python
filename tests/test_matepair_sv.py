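"""Mate-pair screen: classification, clustering, calling, filtering, IO."""

import itertools

import numpy as np
import pandas as pd
import pytest

from translomap import LibraryModel, PoolSpec, build_scenario, default_pools
from translomap.matepair_sv import (
    BreakendCluster,
    DetectorConfig,
    FilterStatus,
    MatePairRecord,
    PairClass,
    call_translocations,
    classify_pair,
    classify_pairs,
    cluster_discordant,
    differential_filter,
    estimate_breakend_interval,
    interchrom_table,
    parse_bnd_vcf,
    pass_calls,
    read_minimal_sam,
    scan,
    write_bnd_vcf,
)
from translomap.scenario import expected_junction_pairs, simulate_pool_matepairs

LIB = LibraryModel()
CFG = DetectorConfig()


def _record(**kw):
    base = dict(
        read_id="r", chrom1="SSC3", pos1=1000, strand1="+",
        chrom2="SSC3", pos2=6900, strand2="-", mapq=60,
    )
    base.update(kw)
    return MatePairRecord(**base)


class TestClassifyPair:
    def test_concordant(self):
        assert classify_pair(_record(), LIB, CFG) is PairClass.CONCORDANT

    def test_mapq_threshold_exclusive(self):
        assert classify_pair(_record(mapq=10), LIB, CFG) is PairClass.LOWQ
        assert classify_pair(_record(mapq=11), LIB, CFG) is PairClass.CONCORDANT

    def test_interchromosomal(self):
        assert classify_pair(_record(chrom2="SSC4"), LIB, CFG) is PairClass.INTERCHROM

    def test_matches_truth_table_oracle(self):
        """Enumerate all condition combinations against an independent oracle."""

        def oracle(rec):
            if rec.mapq <= 10:
                return PairClass.LOWQ
            if rec.chrom1 != rec.chrom2:
                return PairClass.INTERCHROM
            ends = sorted(
                [(rec.pos1, rec.strand1), (rec.pos2, rec.strand2)], key=lambda e: e[0]
            )
            span = ends[1][0] + rec.read_len - ends[0][0]
            if ends[0][1] == "+" and ends[1][1] == "-" and 4200 <= span <= 7800:
                return PairClass.CONCORDANT
            return PairClass.DISCORDANT_INTRA

        cases = itertools.product(
            [5, 10, 11, 60],                      # mapq
            ["SSC3", "SSC4"],                     # chrom2
            ["+", "-"], ["+", "-"],               # strands
            [1000, 5000], [2000, 6900, 20000],    # positions
        )
        for mapq, c2, s1, s2, p1, p2 in cases:
            rec = _record(mapq=mapq, chrom2=c2, strand1=s1, strand2=s2, pos1=p1, pos2=p2)
            assert classify_pair(rec, LIB, CFG) is oracle(rec)

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(300):
            rows.append(
                dict(
                    read_id=f"r{i}",
                    chrom1=rng.choice(["SSC3", "SSC4"]),
                    pos1=int(rng.integers(0, 50_000)),
                    strand1=rng.choice(["+", "-"]),
                    chrom2=rng.choice(["SSC3", "SSC4"]),
                    pos2=int(rng.integers(0, 50_000)),
                    strand2=rng.choice(["+", "-"]),
                    mapq=int(rng.choice([5, 10, 11, 60])),
                    pool="p",
                )
            )
        df = pd.DataFrame(rows)
        vec = classify_pairs(df, LIB, CFG)
        for i, row in df.iterrows():
            rec = MatePairRecord(**row.to_dict())
            assert vec[i] == classify_pair(rec, LIB, CFG).value


def _planted_pairs(n, rng, center_a=23_800, center_b=107_800, sig=("+", "+")):
    rows = []
    for i in range(n):
        off_a = int(rng.integers(100, 5_800))
        off_b = int(rng.integers(100, 5_800))
        pa = center_a - off_a if sig[0] == "+" else center_a + off_a
        pb = center_b - off_b if sig[1] == "+" else center_b + off_b
        rows.append(
            dict(read_id=f"plant{i}", chrom1="SSC3", pos1=pa, strand1=sig[0],
                 chrom2="SSC4", pos2=pb, strand2=sig[1], mapq=60, pool="p")
        )
    return rows


class TestClustering:
    def test_planted_cluster_with_uniform_noise(self):
        """34 junction-spanning pairs plus background noise: the planted
        pairs end up together in a single cluster."""
        rng = np.random.default_rng(4)
        rows = _planted_pairs(34, rng)
        for i in range(60):
            rows.append(
                dict(read_id=f"noise{i}", chrom1="SSC3",
                     pos1=int(rng.integers(0, 49_900)), strand1=rng.choice(["+", "-"]),
                     chrom2="SSC4", pos2=int(rng.integers(0, 149_900)),
                     strand2=rng.choice(["+", "-"]), mapq=60, pool="p")
            )
        df = pd.DataFrame(rows)
        clusters = cluster_discordant(interchrom_table(df, LIB, CFG), LIB, CFG)
        planted = {f"plant{i}" for i in range(34)}
        hosts = [c for c in clusters if planted & set(c.member_ids)]
        assert len(hosts) == 1
        assert planted <= set(hosts[0].member_ids)

    def test_planted_cluster_alone_has_exact_support(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(_planted_pairs(34, rng))
        clusters = cluster_discordant(interchrom_table(df, LIB, CFG), LIB, CFG)
        assert len(clusters) == 1 and clusters[0].support == 34

    def test_empty_input(self):
        df = pd.DataFrame(
            columns=["read_id", "chrom1", "pos1", "strand1", "chrom2", "pos2",
                     "strand2", "mapq", "pool"]
        )
        assert cluster_discordant(df, LIB, CFG) == []

    def test_matches_bruteforce_union_find(self):
        """Components identical to O(n^2) single-linkage over the full
        pairwise link matrix."""
        rng = np.random.default_rng(8)
        for trial in range(5):
            n = int(rng.integers(20, 200))
            df = pd.DataFrame(
                dict(
                    read_id=[f"r{i}" for i in range(n)],
                    chrom1="SSC3",
                    pos1=rng.integers(0, 60_000, n),
                    strand1="+",
                    chrom2="SSC4",
                    pos2=rng.integers(0, 60_000, n),
                    strand2="+",
                    mapq=60,
                    pool="p",
                )
            )
            clusters = cluster_discordant(df, LIB, CFG)
            gap = CFG.gap(LIB)
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            pa = df["pos1"].to_numpy()
            pb = df["pos2"].to_numpy()
            for i in range(n):
                for j in range(i + 1, n):
                    if abs(int(pa[i]) - int(pa[j])) <= gap and abs(int(pb[i]) - int(pb[j])) <= gap:
                        parent[find(i)] = find(j)
            oracle = {}
            for i in range(n):
                oracle.setdefault(find(i), set()).add(f"r{i}")
            assert {frozenset(c.member_ids) for c in clusters} == {
                frozenset(v) for v in oracle.values()
            }


class TestBreakendInterval:
    def test_single_member_formula(self):
        c = BreakendCluster(
            chrom_a="SSC3", chrom_b="SSC4", strand_a="+", strand_b="-",
            member_ids=("r0",), pos_a=np.array([20_000]), pos_b=np.array([110_000]),
            read_len=100,
        )
        ia, ib = estimate_breakend_interval(c, LIB, CFG)
        reach = LIB.insert_bounds[1]  # the largest insert the library allows
        assert ia == (20_100, int(20_000 + reach))
        assert ib == (int(110_100 - reach), 110_000)

    def test_width_never_grows_with_members(self):
        """At a fixed outlier-trim level the quorum bounds are order
        statistics, so adding consistent members can only tighten them;
        the overall width also shrinks from start to finish."""
        import math

        rng = np.random.default_rng(12)
        rows = _planted_pairs(30, rng)
        widths_a, widths_b, trims = [], [], []
        for m in range(1, 31):
            sub = rows[:m]
            c = BreakendCluster(
                chrom_a="SSC3", chrom_b="SSC4", strand_a="+", strand_b="+",
                member_ids=tuple(r["read_id"] for r in sub),
                pos_a=np.array([r["pos1"] for r in sub]),
                pos_b=np.array([r["pos2"] for r in sub]),
                read_len=100,
            )
            ia, ib = estimate_breakend_interval(c, LIB, CFG)
            widths_a.append(ia[1] - ia[0])
            widths_b.append(ib[1] - ib[0])
            trims.append(m - math.ceil(0.8 * m))
        for i in range(1, 30):
            if trims[i] == trims[i - 1]:
                assert widths_a[i] <= widths_a[i - 1]
                assert widths_b[i] <= widths_b[i - 1]
        assert widths_a[-1] < widths_a[0] and widths_b[-1] < widths_b[0]

    def test_cluster_interval_contains_truth(self, scen):
        pool = PoolSpec("het", (("i0", "N/T"),), noise_pairs=0)
        df = simulate_pool_matepairs(scen, pool, 17.5, seed=3)
        clusters = cluster_discordant(interchrom_table(df, LIB, CFG), LIB, CFG)
        assert len(clusters) == 2
        for c in clusters:
            assert c.interval_a[0] <= 23_800 + 5 and c.interval_a[1] >= 23_800
            assert c.interval_b[0] <= 107_800 and c.interval_b[1] >= 107_800


def _cluster_at(pos_a, pos_b, support, sig, rng):
    return BreakendCluster(
        chrom_a="SSC3", chrom_b="SSC4", strand_a=sig[0], strand_b=sig[1],
        member_ids=tuple(f"m{rng.integers(1 << 30)}_{i}" for i in range(support)),
        pos_a=pos_a - rng.integers(100, 5000, support) * (1 if sig[0] == "+" else -1),
        pos_b=pos_b - rng.integers(100, 5000, support) * (1 if sig[1] == "+" else -1),
        read_len=100,
        interval_a=(pos_a - 200, pos_a + 200),
        interval_b=(pos_b - 200, pos_b + 200),
    )


class TestCalling:
    def test_reciprocal_merge(self):
        rng = np.random.default_rng(14)
        c1 = _cluster_at(23_800, 107_800, 18, ("+", "+"), rng)
        c2 = _cluster_at(23_805, 107_800, 16, ("-", "-"), rng)
        calls = call_translocations([c1, c2], CFG, LIB)
        assert len(calls) == 1
        call = calls[0]
        assert call.status is FilterStatus.PASS and call.reciprocal
        assert call.support == 34

    def test_support_threshold_exclusive(self):
        rng = np.random.default_rng(16)
        c = _cluster_at(23_800, 107_800, 10, ("+", "+"), rng)
        calls = call_translocations([c], CFG, LIB)
        assert calls[0].status is FilterStatus.LOW_SUPPORT
        c11 = _cluster_at(23_800, 107_800, 11, ("+", "+"), rng)
        calls = call_translocations([c11], CFG, LIB)
        assert calls[0].status is FilterStatus.PASS and not calls[0].reciprocal

    def test_empty(self):
        assert call_translocations([], CFG, LIB) == []

    def test_balanced_only_drops_non_reciprocal(self):
        rng = np.random.default_rng(18)
        c = _cluster_at(23_800, 107_800, 15, ("+", "+"), rng)
        cfg = DetectorConfig(balanced_only=True)
        assert call_translocations([c], cfg, LIB) == []


class TestDifferentialFilter:
    def test_artifacts_removed_planted_survives(self):
        rng = np.random.default_rng(20)
        planted = [
            _cluster_at(23_800, 107_800, 18, ("+", "+"), rng),
            _cluster_at(23_805, 107_800, 16, ("-", "-"), rng),
        ]
        artifacts = [
            _cluster_at(8_000, 30_000, 15, ("+", "-"), rng),
            _cluster_at(15_000, 70_000, 15, ("+", "-"), rng),
            _cluster_at(40_000, 130_000, 15, ("+", "-"), rng),
        ]
        case_calls = call_translocations(planted + artifacts, CFG, LIB)
        control_calls = call_translocations(
            [_cluster_at(8_100, 30_200, 14, ("+", "-"), rng),
             _cluster_at(14_900, 69_800, 13, ("+", "-"), rng),
             _cluster_at(40_050, 130_100, 15, ("+", "-"), rng)],
            CFG, LIB,
        )
        out = differential_filter(case_calls, control_calls, CFG.diff_tol(LIB))
        statuses = sorted(c.status.value for c in out)
        assert statuses.count("PASS") == 1
        assert statuses.count("IN_CONTROL") == 3
        surviving = pass_calls(out)[0]
        assert surviving.reciprocal and surviving.support == 34

    def test_empty_control_is_identity(self):
        rng = np.random.default_rng(22)
        calls = call_translocations([_cluster_at(23_800, 107_800, 15, ("+", "+"), rng)], CFG, LIB)
        out = differential_filter(calls, [], CFG.diff_tol(LIB))
        assert [c.status for c in out] == [c.status for c in calls]

    def test_matches_bruteforce_matching(self):
        rng = np.random.default_rng(24)
        for _ in range(10):
            case = call_translocations(
                [_cluster_at(int(rng.integers(6000, 44_000)), int(rng.integers(6000, 144_000)),
                             int(rng.integers(11, 30)), ("+", "+"), rng) for _ in range(5)],
                CFG, LIB,
            )
            control = call_translocations(
                [_cluster_at(int(rng.integers(6000, 44_000)), int(rng.integers(6000, 144_000)),
                             int(rng.integers(11, 30)), ("+", "+"), rng) for _ in range(5)],
                CFG, LIB,
            )
            tol = CFG.diff_tol(LIB)
            out = differential_filter(case, control, tol)
            for before, after in zip(case, out):
                expect_match = any(
                    abs(ctl.midpoint_a() - before.midpoint_a()) <= tol
                    and abs(ctl.midpoint_b() - before.midpoint_b()) <= tol
                    for ctl in control
                )
                if before.status is FilterStatus.PASS:
                    assert (after.status is FilterStatus.IN_CONTROL) == expect_match


class TestVcf:
    def _one_call(self, rng):
        c1 = _cluster_at(23_800, 107_800, 18, ("+", "+"), rng)
        c2 = _cluster_at(23_805, 107_800, 16, ("-", "-"), rng)
        return call_translocations([c1, c2], CFG, LIB)

    def test_four_bnd_records_with_resolving_mateids(self, scen):
        rng = np.random.default_rng(26)
        calls = self._one_call(rng)
        text = write_bnd_vcf(calls, scen.assembly)
        body = [l for l in text.splitlines() if l and not l.startswith("#")]
        assert len(body) == 4
        ids = {l.split("\t")[2] for l in body}
        mates = {kv.split("=")[1] for l in body for kv in l.split("\t")[7].split(";") if kv.startswith("MATEID")}
        assert mates == ids

    def test_pos_is_one_based(self, scen):
        rng = np.random.default_rng(28)
        c = _cluster_at(25_000, 110_000, 12, ("+", "+"), rng)
        c.interval_a = (23_800, 24_000)
        c.interval_b = (107_800, 107_900)
        calls = call_translocations([c], CFG, LIB)
        text = write_bnd_vcf(calls, scen.assembly)
        body = [l.split("\t") for l in text.splitlines() if not l.startswith("#")]
        pos_by_chrom = {row[0]: int(row[1]) for row in body}
        assert pos_by_chrom["SSC3"] == 23_801
        assert pos_by_chrom["SSC4"] == 107_801

    def test_roundtrip_fuzzed(self, scen):
        rng = np.random.default_rng(30)
        for _ in range(20):
            clusters = []
            for _ in range(int(rng.integers(1, 4))):
                sig = tuple(rng.choice(["+", "-"], 2))
                clusters.append(
                    _cluster_at(int(rng.integers(7000, 42_000)),
                                int(rng.integers(7000, 142_000)),
                                int(rng.integers(2, 40)), sig, rng)
                )
            calls = call_translocations(clusters, CFG, LIB)
            parsed = parse_bnd_vcf(write_bnd_vcf(calls, scen.assembly))
            assert [c.essentials() for c in parsed] == [c.essentials() for c in calls]

    def test_pysam_parses_output(self, scen, tmp_path):
        pysam = pytest.importorskip("pysam")
        rng = np.random.default_rng(32)
        calls = self._one_call(rng)
        path = tmp_path / "out.vcf"
        path.write_text(write_bnd_vcf(calls, scen.assembly))
        with pysam.VariantFile(str(path)) as vcf:
            records = list(vcf)
        assert len(records) == 4
        for rec in records:
            assert rec.info["SVTYPE"] == "BND"
            assert rec.info["MATEID"] in {r.id for r in records}
            assert rec.info["SUPPORT"] in (16, 18)
            assert rec.pos == rec.start + 1  # 1-based rendering


class TestSamImport:
    def test_roundtrip_via_pysam_written_sam(self, scen, tmp_path):
        """Write a SAM with pysam from a known pair table; our minimal
        importer must recover the same pairs."""
        pysam = pytest.importorskip("pysam")
        pool = PoolSpec("p", (("i0", "N/T"),), noise_pairs=5)
        df = simulate_pool_matepairs(scen, pool, 2.0, seed=7).head(50)
        header = pysam.AlignmentHeader.from_references(
            list(scen.assembly.lengths()), list(scen.assembly.lengths().values())
        )
        path = tmp_path / "pairs.sam"
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            for _, r in df.iterrows():
                for end in (1, 2):
                    seg = pysam.AlignedSegment(header)
                    seg.query_name = r["read_id"]
                    seg.reference_name = r[f"chrom{end}"]
                    seg.reference_start = int(r[f"pos{end}"])
                    seg.mapping_quality = int(r["mapq"])
                    other = 2 if end == 1 else 1
                    seg.next_reference_name = r[f"chrom{other}"]
                    seg.next_reference_start = int(r[f"pos{other}"])
                    flag = 0x1 | (0x40 if end == 1 else 0x80)
                    if r[f"strand{end}"] == "-":
                        flag |= 0x10
                    if r[f"strand{other}"] == "-":
                        flag |= 0x20
                    seg.flag = flag
                    seg.query_sequence = "A" * 100
                    seg.cigarstring = "100M"
                    out.write(seg)
        got = read_minimal_sam(path, pool="p").set_index("read_id")
        want = df.set_index("read_id")
        assert set(got.index) == set(want.index)
        for rid in want.index:
            for col in ("chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2", "mapq"):
                assert got.loc[rid, col] == want.loc[rid, col], (rid, col)


class TestEndToEnd:
    def test_planted_translocation_recovered_across_seeds(self, scen):
        """Across 20 seeds: the planted translocation is the only PASS call
        and its breakend intervals contain the true breakpoints in >=95%."""
        case, control = default_pools(scen)
        hits = 0
        supports = []
        n_pass = []
        for seed in range(20):
            case_df = simulate_pool_matepairs(scen, case, 17.5, seed=1000 + seed)
            ctl_df = simulate_pool_matepairs(scen, control, 17.5, seed=2000 + seed)
            calls = scan(case_df, ctl_df, scen.library, CFG)
            passing = pass_calls(calls)
            n_pass.append(len(passing))
            assert passing, f"no PASS call at seed {seed}"
            best = passing[0]
            supports.append(best.support)
            if (
                best.interval_a[0] <= 23_800 <= best.interval_a[1]
                and best.interval_b[0] <= 107_800 <= best.interval_b[1]
            ):
                hits += 1
        assert hits >= 19
        assert np.mean(n_pass) == 1.0
        expected = expected_junction_pairs(scen, case, 17.5)
        se = np.std(supports, ddof=1) / np.sqrt(len(supports))
        # noise pairs can attach to the junction cluster, so compare the
        # mean against the junction-spanning expectation generously
        assert abs(np.mean(supports) - expected) <= 3 * se + 3

    def test_support_increases_with_carrier_dose(self, scen):
        doses = {
            "het": tuple([("i0", "N/T")] + [(f"i{k}", "N/N") for k in range(1, 5)]),
            "hom": tuple([("i0", "T/T")] + [(f"i{k}", "N/N") for k in range(1, 5)]),
            "all_hom": tuple((f"i{k}", "T/T") for k in range(5)),
        }
        means = {}
        for name, genos in doses.items():
            pool = PoolSpec(name, genos, noise_pairs=0)
            supports = []
            for seed in range(6):
                df = simulate_pool_matepairs(scen, pool, 8.0, seed=3000 + seed)
                calls = scan(df, None, scen.library, CFG)
                supports.append(sum(c.support for c in pass_calls(calls)))
            means[name] = np.mean(supports)
        assert means["het"] < means["hom"] < means["all_hom"]

    def test_noise_only_yields_no_pass_calls(self, scen):
        """Uniform chimeric noise alone must not produce a PASS call."""
        total = 0
        for seed in range(20):
            pool = PoolSpec("noise", (("i0", "N/N"),) * 1, noise_pairs=60)
            df = simulate_pool_matepairs(scen, pool, 17.5, seed=4000 + seed)
            total += len(pass_calls(scan(df, None, scen.library, CFG)))
        assert total == 0
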