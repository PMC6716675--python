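"""Association score (exponential decay weighting) and its comparators."""

import math

import numpy as np
import pytest

from pras import (
    DecayModel,
    SiteKind,
    expressrna_score,
    ppk_score,
    pras_score,
    score_all,
)
from pras.peaks import MappedPeak, PeakCluster

from conftest import make_catalog, make_transcript


def mapped_peak(r, d, t=None, c=None):
    t = t or make_transcript([(0, 100_000)])
    tpos = t.spliced_length - 1 - d
    cl = PeakCluster(t.chrom, t.strand, tpos, tpos + 1, float(r), c=c)
    return MappedPeak(cl, t, tpos, int(d))


class TestPrasScore:
    def test_zero_distance_full_weight(self):
        assert pras_score([mapped_peak(5, 0)], d0=1000) == pytest.approx(5.0)

    def test_distance_d0_gives_e_minus_one(self):
        assert pras_score([mapped_peak(1, 777)], d0=777) == pytest.approx(
            math.exp(-1)
        )

    def test_two_peak_arithmetic(self):
        peaks = [mapped_peak(2, 100), mapped_peak(3, 500)]
        expected = 2 * math.exp(-0.1) + 3 * math.exp(-0.5)
        assert pras_score(peaks, d0=1000) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.62927, abs=5e-6)

    def test_empty_scores_zero(self):
        assert pras_score([], d0=1000) == 0.0

    def test_invalid_d0(self):
        with pytest.raises(ValueError):
            pras_score([mapped_peak(1, 1)], d0=0)

    def test_matches_term_by_term_oracle_on_random_transcripts(self):
        rng = np.random.default_rng(12)
        for _ in range(120):
            n = int(rng.integers(1, 15))
            rs = rng.integers(1, 50, size=n).astype(float)
            ds = rng.integers(0, 5000, size=n)
            d0 = float(rng.uniform(50, 3000))
            peaks = [mapped_peak(r, d) for r, d in zip(rs, ds)]
            oracle = math.fsum(
                float(r) * math.exp(-float(d) / d0) for r, d in zip(rs, ds)
            )
            assert pras_score(peaks, d0) == pytest.approx(oracle, rel=1e-9)

    def test_linearity_and_monotone_decay(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n = int(rng.integers(1, 8))
            peaks = [
                mapped_peak(float(rng.integers(1, 30)), int(rng.integers(0, 3000)))
                for _ in range(n)
            ]
            d0 = float(rng.uniform(100, 2000))
            s = pras_score(peaks, d0)
            k = float(rng.uniform(0.1, 10))
            scaled = [
                mapped_peak(p.cluster.r * k, p.d) for p in peaks
            ]
            assert pras_score(scaled, d0) == pytest.approx(k * s, rel=1e-9)
            # move one peak strictly farther: score strictly decreases
            i = int(rng.integers(0, n))
            moved = list(peaks)
            moved[i] = mapped_peak(peaks[i].cluster.r, peaks[i].d + 1 + int(rng.integers(0, 500)))
            assert pras_score(moved, d0) < s

    def test_d0_limit_recovers_total_intensity(self):
        peaks = [mapped_peak(2, 100), mapped_peak(3, 2500), mapped_peak(7, 40)]
        assert pras_score(peaks, d0=1e12) == pytest.approx(12.0)
        # and equals the flank sum once the flank covers every peak
        assert expressrna_score(peaks, flank=2500) == 12.0

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        peaks = [
            mapped_peak(float(rng.integers(1, 9)), int(rng.integers(0, 999)))
            for _ in range(10)
        ]
        perm = [peaks[i] for i in rng.permutation(10)]
        assert pras_score(peaks, 500) == pytest.approx(pras_score(perm, 500))


class TestComparators:
    def test_flank_boundary_inclusive(self):
        assert expressrna_score([mapped_peak(4, 200)], flank=200) == 4.0
        assert expressrna_score([mapped_peak(4, 201)], flank=200) == 0.0

    def test_mixed_distances(self):
        peaks = [mapped_peak(1, 50), mapped_peak(2, 150), mapped_peak(4, 250)]
        assert expressrna_score(peaks, flank=200) == 3.0

    def test_flank_filter_matches_brute_force(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            n = int(rng.integers(0, 12))
            rs = rng.integers(1, 20, size=n).astype(float)
            ds = rng.integers(0, 600, size=n)
            flank = int(rng.integers(0, 600))
            peaks = [mapped_peak(r, d) for r, d in zip(rs, ds)]
            brute = sum(float(r) for r, d in zip(rs, ds) if d <= flank)
            assert expressrna_score(peaks, flank) == pytest.approx(brute)

    @pytest.mark.parametrize(
        "n,length,expected", [(4, 2000, 2.0), (0, 777, 0.0), (3, 1500, 2.0)]
    )
    def test_ppk_examples(self, n, length, expected):
        assert ppk_score(n, length) == pytest.approx(expected)

    def test_ppk_random_matches_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(0, 50))
            L = int(rng.integers(1, 100_000))
            assert ppk_score(n, L) == pytest.approx(n / (L / 1000))

    def test_ppk_zero_length_errors(self):
        with pytest.raises(ValueError):
            ppk_score(3, 0)


class TestScoreAll:
    def _two_transcript_setup(self):
        ta = make_transcript([(0, 1000)], tid="TA", gid="GA")
        tb = make_transcript([(5000, 6000)], tid="TB", gid="GB")
        cat = make_catalog(ta, tb)
        mapped = [
            mapped_peak(10, 0, t=ta),
            mapped_peak(3, 500, t=tb),
        ]
        return cat, mapped

    def test_ranked_descending(self):
        cat, mapped = self._two_transcript_setup()
        scores = score_all(cat, mapped, DecayModel(SiteKind.TES, 1000))
        assert [s.transcript_id for s in scores] == ["TA", "TB"]
        assert scores[0].S > scores[1].S

    def test_tie_broken_by_peak_count(self):
        ta = make_transcript([(0, 1000)], tid="TA", gid="GA")
        tb = make_transcript([(5000, 6000)], tid="TB", gid="GB")
        cat = make_catalog(ta, tb)
        mapped = [
            mapped_peak(6, 0, t=ta),
            mapped_peak(3, 0, t=tb),
            mapped_peak(3, 0, t=tb),
        ]
        scores = score_all(cat, mapped, DecayModel(SiteKind.TES, 1000))
        assert scores[0].S == pytest.approx(scores[1].S)
        assert scores[0].transcript_id == "TB"  # 2 peaks beats 1

    def test_ranking_matches_independent_resort(self, big_sim):
        """On the reference simulation the emitted order equals a re-sort by
        an oracle recomputing the weighted sum per transcript."""
        scores = big_sim.truth[:500]
        oracle = {}
        by_tid = {}
        for mp in big_sim.mapped:
            by_tid.setdefault(mp.transcript_id, []).append(mp)
        for tid, plist in by_tid.items():
            oracle[tid] = math.fsum(
                mp.cluster.r * math.exp(-mp.d / big_sim.cfg.d0_true)
                for mp in plist
            )
        for s in scores:
            assert s.S == pytest.approx(oracle[s.transcript_id], rel=1e-9)
        resorted = sorted(
            scores, key=lambda s: (-oracle[s.transcript_id], -s.n_peaks, s.transcript_id)
        )
        assert [s.transcript_id for s in resorted] == [
            s.transcript_id for s in scores
        ]

    def test_scaling_preserves_ranking(self):
        cat, mapped = self._two_transcript_setup()
        decay = DecayModel(SiteKind.TES, 1000)
        base = score_all(cat, mapped, decay)
        scaled_mapped = [mapped_peak(m.cluster.r * 4.5, m.d, t=m.transcript) for m in mapped]
        scaled = score_all(cat, scaled_mapped, decay)
        assert [s.transcript_id for s in scaled] == [s.transcript_id for s in base]
        for a, b in zip(scaled, base):
            assert a.S == pytest.approx(4.5 * b.S, rel=1e-9)
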