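"""BED reading, site merging, normalization, control attachment, mapping."""

import math

import numpy as np
import pytest

from pras import (
    CrossLinkSite,
    SiteKind,
    attach_control,
    map_peaks,
    merge_sites,
    normalize_intensity,
    read_bed,
)
from pras.peaks import BedParseError, PeakCluster

from conftest import make_catalog, make_transcript


def site(start, end, intensity=1.0, chrom="chr1", strand="+"):
    return CrossLinkSite(chrom, strand, start, end, intensity)


class TestReadBed:
    def test_valid_bed6(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text(
            "chr1\t10\t11\ts1\t4\t+\n"
            "chr1\t30\t31\ts2\t7\t+\n"
            "chr2\t5\t6\ts3\t2\t-\n"
        )
        sites = read_bed(p)
        assert [s.intensity for s in sites] == [4, 7, 2]
        assert sites[2].strand == "-"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert read_bed(p) == []

    def test_missing_strand_column_instructs(self, tmp_path):
        p = tmp_path / "b5.bed"
        p.write_text("chr1\t10\t11\ts1\t4\n")
        with pytest.raises(BedParseError, match="unstranded"):
            read_bed(p)
        assert read_bed(p, unstranded=True)[0].strand == "."

    def test_missing_score_column_defaults_with_warning(self, tmp_path):
        p = tmp_path / "b4.bed"
        p.write_text("chr1\t10\t11\n")
        with pytest.warns(UserWarning, match="score"):
            sites = read_bed(p, unstranded=True)
        assert sites[0].intensity == 1.0

    @pytest.mark.parametrize(
        "line,msg",
        [
            ("chr1\t20\t10\ts\t1\t+\n", "start >= end"),
            ("chr1\t10\t20\ts\tabc\t+\n", "non-numeric score"),
        ],
    )
    def test_line_numbered_errors(self, tmp_path, line, msg):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t2\ts\t1\t+\n" + line)
        with pytest.raises(BedParseError, match=f"line 2.*{msg}"):
            read_bed(p)


def brute_force_merge(sites, gap):
    """Union-find over the pairwise merge relation (independent oracle)."""
    n = len(sites)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = sites[i], sites[j]
            if (a.chrom, a.strand) != (b.chrom, b.strand):
                continue
            empty = max(a.start, b.start) - min(a.end, b.end)
            if empty <= gap:
                parent[find(i)] = find(j)
    groups = {}
    for i, s in enumerate(sites):
        groups.setdefault(find(i), []).append(s)
    out = []
    for g in groups.values():
        out.append(
            (
                g[0].chrom,
                g[0].strand,
                min(s.start for s in g),
                max(s.end for s in g),
                sum(s.intensity for s in g),
            )
        )
    return sorted(out)


class TestMergeSites:
    def test_nearby_sites_merge(self):
        clusters = merge_sites([site(100, 101, 3), site(115, 116, 5)], gap=20)
        assert len(clusters) == 1
        c = clusters[0]
        assert (c.start, c.end, c.r) == (100, 116, 8)

    def test_distant_sites_stay_apart(self):
        clusters = merge_sites([site(100, 101), site(130, 131)], gap=20)
        assert len(clusters) == 2

    def test_transitive_chain(self):
        clusters = merge_sites(
            [site(100, 101), site(118, 119), site(136, 137)], gap=20
        )
        assert len(clusters) == 1
        assert (clusters[0].start, clusters[0].end) == (100, 137)

    def test_gap_zero_merges_touching_only(self):
        assert len(merge_sites([site(100, 110), site(110, 120)], gap=0)) == 1
        assert len(merge_sites([site(100, 110), site(111, 120)], gap=0)) == 2

    def test_huge_gap_one_cluster_per_chrom_strand(self):
        sites = [site(0, 1), site(10_000, 10_001), site(5, 6, strand="-")]
        clusters = merge_sites(sites, gap=10**9)
        assert len(clusters) == 2  # one per strand

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 25))
            sites = []
            for _ in range(n):
                s = int(rng.integers(0, 400))
                w = int(rng.integers(1, 30))
                sites.append(
                    site(
                        s, s + w, float(rng.integers(1, 9)),
                        chrom=f"chr{rng.integers(1, 3)}",
                        strand="+" if rng.random() < 0.5 else "-",
                    )
                )
            gap = int(rng.integers(0, 40))
            got = sorted(
                (c.chrom, c.strand, c.start, c.end, c.r)
                for c in merge_sites(sites, gap=gap)
            )
            assert got == brute_force_merge(sites, gap)

    def test_exactly_default_gap_chain_merges(self):
        # empty space of exactly 20 nt between interval ends
        clusters = merge_sites(
            [site(0, 10), site(30, 40), site(60, 70)], gap=20
        )
        assert len(clusters) == 1

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        sites = [
            site(int(rng.integers(0, 500)), int(rng.integers(0, 500)) + 505, 2.0)
            for _ in range(40)
        ]
        once = merge_sites(sites, gap=20)
        again = merge_sites(
            [CrossLinkSite(c.chrom, c.strand, c.start, c.end, c.r) for c in once],
            gap=20,
        )
        assert [(c.start, c.end, c.r) for c in again] == [
            (c.start, c.end, c.r) for c in once
        ]

    def test_intensity_conserved(self):
        rng = np.random.default_rng(3)
        sites = [
            site(int(rng.integers(0, 2000)), int(rng.integers(0, 2000)) + 2005,
                 float(rng.integers(1, 20)))
            for _ in range(100)
        ]
        clusters = merge_sites(sites, gap=20)
        assert math.isclose(
            sum(c.r for c in clusters), sum(s.intensity for s in sites)
        )


class TestNormalizeIntensity:
    def test_enrichment_formula(self):
        assert normalize_intensity(8, 2, pseudocount=0) == pytest.approx(16.0)

    def test_equal_counts_zero(self):
        assert normalize_intensity(5, 5) == 0.0

    def test_depletion_clamped(self):
        assert normalize_intensity(2, 8, pseudocount=0) == 0.0

    def test_monotone_decreasing_in_control(self):
        vals = [normalize_intensity(10, c) for c in range(0, 30)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_zero_control_with_pseudocount(self):
        assert normalize_intensity(7, 0) == pytest.approx(7 * math.log2(8 / 1))


class TestAttachControl:
    def test_midpoint_rule(self):
        clusters = [PeakCluster("chr1", "+", 100, 120, 5.0)]
        ctrl = [site(110, 111, 3), site(119, 120, 2), site(120, 121, 9)]
        out = attach_control(clusters, ctrl)
        assert out[0].c == 5.0  # 120..121 midpoint lies outside [100,120)


class TestMapPeaks:
    def test_distance_to_tes_upstream(self):
        t = make_transcript([(0, 1000)], cds=(100, 700))
        cat = make_catalog(t)
        # midpoint at transcript position 936 -> 63 nt upstream of TES (999)
        cl = PeakCluster("chr1", "+", 936, 937, 4.0)
        mapped = map_peaks([cl], cat, SiteKind.TES)
        assert len(mapped) == 1
        assert mapped[0].d == 63

    def test_strand_mismatch_not_mapped(self):
        t = make_transcript([(0, 1000)])
        cl = PeakCluster("chr1", "-", 500, 501, 1.0)
        assert map_peaks([cl], make_catalog(t), SiteKind.TES) == []
        assert len(map_peaks([cl], make_catalog(t), SiteKind.TES, unstranded=True)) == 1

    def test_matches_exhaustive_membership_scan(self):
        t1 = make_transcript([(0, 300), (500, 800)], tid="T1", gid="G1")
        t2 = make_transcript([(700, 1200)], strand="-", tid="T2", gid="G2")
        cat = make_catalog(t1, t2)
        rng = np.random.default_rng(9)
        clusters = [
            PeakCluster(
                "chr1",
                "+" if rng.random() < 0.5 else "-",
                int(s := rng.integers(0, 1300)),
                int(s + rng.integers(1, 40)),
                1.0,
            )
            for _ in range(200)
        ]
        mapped = map_peaks(clusters, cat, SiteKind.TES)
        got = {(id(m.cluster), m.transcript_id) for m in mapped}
        expected = set()
        for cl in clusters:
            for t in (t1, t2):
                if cl.strand != t.strand:
                    continue
                exonic = any(s <= cl.midpoint < e for s, e in t.exons)
                if exonic:
                    expected.add((id(cl), t.transcript_id))
        assert got == expected

    def test_peak_shared_by_two_genes_maps_twice(self):
        a = make_transcript([(0, 500)], tid="TA", gid="GA")
        b = make_transcript([(300, 900)], tid="TB", gid="GB")
        cl = PeakCluster("chr1", "+", 400, 401, 1.0)
        mapped = map_peaks([cl], make_catalog(a, b), SiteKind.TES)
        assert {m.transcript_id for m in mapped} == {"TA", "TB"}
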