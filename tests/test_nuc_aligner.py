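"""Envelopes, seed matches, HSPs, chaining, gapped extension and fills."""

import itertools
from functools import lru_cache

import numpy as np
import pytest

from coalign.block_aligner import Colony
from coalign.nuc_aligner import (
    HSP,
    NAParams,
    PairScorer,
    SeqView,
    _SCORE_TABLE,
    chain_hsps,
    envelope,
    fill_interval,
    find_matches,
    gapless_extend,
    gapped_extend,
    global_dp,
    integrate_matches,
    align_envelope,
    cigar_from_string,
    cigar_to_string,
)
from coalign.seedkit import parse_seed_pattern
from coalign.synthgen import SynthSpec, generate_pair
from conftest import random_seq

SEED7 = parse_seed_pattern("1111111")


def make_colony(path, orientation="forward"):
    xs = [p[0] for p in path]
    ys = [p[1] for p in path]
    return Colony(path=list(path), peak_score=1e9,
                  bounds=(min(xs), max(xs), min(ys), max(ys)),
                  orientation=orientation)


class TestEnvelope:
    def test_single_cell_rectangle(self):
        env = envelope(make_colony([(3, 5)]), 10_000, (10**6, 10**6))
        assert env.a_range == (20_000, 50_000)
        assert env.b_range == (40_000, 70_000)
        assert env.area() == 30_000 * 30_000

    def test_clipped_at_origin(self):
        env = envelope(make_colony([(0, 0)]), 10_000, (10**6, 10**6))
        assert env.a_range == (0, 20_000)
        assert env.b_range == (0, 20_000)

    def test_union_area_matches_rasterization_oracle(self):
        J = 100
        la = lb = 2000
        path = [(4, 4), (5, 5), (6, 6)]
        env = envelope(make_colony(path), J, (la, lb))
        # oracle: paint the dilated rectangles on a block-resolution grid
        grid = np.zeros((la // J, lb // J), dtype=bool)
        for x, y in path:
            grid[max(0, x - 1) : x + 2, max(0, y - 1) : y + 2] = True
        assert env.area() == int(grid.sum()) * J * J
        # membership agrees with the painted grid on a coordinate sample
        rng = np.random.default_rng(0)
        aq = rng.integers(0, la, 300)
        bq = rng.integers(0, lb, 300)
        got = env.contains(aq, bq)
        want = grid[aq // J, bq // J]
        assert np.array_equal(got, want)


class TestFindMatches:
    def test_identical_regions_full_diagonal(self):
        s = random_seq(1000, seed=1)
        sv = SeqView.from_seq(s)
        ap, bp = find_matches(sv, sv, (0, 1000), (0, 1000), SEED7)
        diag_hits = ap[ap == bp]
        assert len(diag_hits) == 1000 - SEED7.span + 1

    def test_disjoint_alphabets_empty(self):
        sva = SeqView.from_seq("A" * 200)
        svb = SeqView.from_seq("C" * 200)
        ap, _ = find_matches(sva, svb, (0, 200), (0, 200), SEED7)
        assert ap.size == 0

    def test_matches_equal_quadratic_oracle(self):
        a = random_seq(300, seed=2)
        b = random_seq(300, seed=3)
        sva, svb = SeqView.from_seq(a), SeqView.from_seq(b)
        ap, bp = find_matches(sva, svb, (0, 300), (0, 300), SEED7, occ_cap=10**9)
        got = set(zip(ap.tolist(), bp.tolist()))
        want = set()
        k = SEED7.span
        for i in range(300 - k + 1):
            for j in range(300 - k + 1):
                if a[i : i + k] == b[j : j + k]:
                    want.add((i, j))
        assert got == want


class TestIntegrateMatches:
    def scorer(self, a, b):
        return PairScorer(SeqView.from_seq(a), SeqView.from_seq(b), _SCORE_TABLE)

    def test_nearby_same_diagonal_merge(self):
        s = random_seq(60, seed=4)
        sc = self.scorer(s, s)
        ap = np.array([10, 10 + SEED7.span + 5])
        bp = ap.copy()
        hsps = integrate_matches(ap, bp, SEED7.span, 20, sc)
        assert len(hsps) == 1
        assert hsps[0].a_start == 10
        assert hsps[0].a_end == 10 + SEED7.span + 5 + SEED7.span

    def test_lonesome_match_dropped(self):
        s = random_seq(60, seed=5)
        sc = self.scorer(s, s)
        assert integrate_matches(np.array([10]), np.array([10]), 7, 20, sc) == []

    def test_adjacent_diagonals_never_merge(self):
        s = random_seq(80, seed=6)
        sc = self.scorer(s, s)
        ap = np.array([10, 20])
        bp = np.array([10, 21])  # different diagonal
        assert integrate_matches(ap, bp, 7, 20, sc) == []  # both lonesome


def oracle_gapless_right(scorer, a_end, b_end, limit, xdrop):
    """Scalar re-implementation of X-drop gapless extension."""
    best, best_off, run = 0.0, 0, 0.0
    for k in range(limit):
        run += float(scorer.scores(a_end + k, b_end + k, 1)[0])
        if run > best:
            best, best_off = run, k + 1
        if best - run > xdrop:
            break
    return best_off


class TestGaplessExtend:
    def test_extends_through_exact_identity(self):
        s = random_seq(200, seed=7)
        sc = PairScorer(SeqView.from_seq(s), SeqView.from_seq(s), _SCORE_TABLE)
        h = HSP(80, 100, 80, 100, 0.0)
        e = gapless_extend(h, sc, 200, (0, 200), (0, 200))
        assert (e.a_start, e.a_end) == (0, 200)
        assert e.n_mismatches == 0

    def test_matches_bruteforce_endpoint_oracle(self):
        rng = np.random.default_rng(8)
        for trial in range(20):
            a = random_seq(400, seed=100 + trial)
            b = list(random_seq(400, seed=200 + trial))
            # plant a homologous core with noisy flanks
            core = a[150:250]
            b[150:250] = core
            b = "".join(b)
            sc = PairScorer(SeqView.from_seq(a), SeqView.from_seq(b), _SCORE_TABLE)
            h = HSP(180, 220, 180, 220, 0.0)
            e = gapless_extend(h, sc, 200, (0, 400), (0, 400))
            right = oracle_gapless_right(sc, 220, 220, 180, 200)
            assert e.a_end == 220 + right
            # leftward oracle by mirroring
            best, off, run = 0.0, 0, 0.0
            for k in range(1, 181):
                run += float(sc.scores(180 - k, 180 - k, 1)[0])
                if run > best:
                    best, off = run, k
                if best - run > 200:
                    break
            assert e.a_start == 180 - off


def oracle_chain(hsps, slack, cs):
    """Exhaustive subset search with the consecutive-pair overlap penalty."""
    hs = sorted(hsps, key=lambda h: (h.a_start, h.b_start, h.a_end, h.b_end))
    best = 0.0
    for r in range(1, len(hs) + 1):
        for sub in itertools.combinations(range(len(hs)), r):
            total = sum(hs[i].score for i in sub)
            ok = True
            for i, j in zip(sub, sub[1:]):
                hi, hj = hs[i], hs[j]
                if not (hi.a_start <= hj.a_start and hi.b_start <= hj.b_start
                        and (hi.a_start < hj.a_start or hi.b_start < hj.b_start)):
                    ok = False
                    break
                ova = hi.a_end - hj.a_start
                ovb = hi.b_end - hj.b_start
                if cs and (ova > 0 or ovb > 0):
                    ok = False
                    break
                total -= max(max(ova, ovb, 0) - slack, 0)
            if ok and total > best:
                best = total
    return best


def random_hsps(rng, n):
    out = []
    for _ in range(n):
        a0 = int(rng.integers(0, 300))
        b0 = int(rng.integers(0, 300))
        ln = int(rng.integers(10, 60))
        out.append(HSP(a0, a0 + ln, b0, b0 + ln, float(rng.integers(20, 400))))
    return out


class TestChaining:
    def test_disjoint_collinear_all_chained(self):
        hs = [HSP(0, 10, 0, 10, 100), HSP(20, 30, 20, 30, 50), HSP(40, 60, 45, 65, 70)]
        c = chain_hsps(hs)
        assert len(c.hsps) == 3
        assert c.total_score == pytest.approx(220)

    def test_overlap_penalty_value(self):
        # 15 bp overlap costs max(15 - 10, 0) = 5
        hs = [HSP(0, 50, 0, 50, 100), HSP(35, 80, 35, 80, 100)]
        c = chain_hsps(hs, overlap_slack=10)
        assert c.total_score == pytest.approx(195)

    def test_cs_forbids_overlap(self):
        hs = [HSP(0, 50, 0, 50, 100), HSP(35, 80, 35, 80, 90)]
        c = chain_hsps(hs, cs_enabled=True)
        assert len(c.hsps) == 1
        assert c.total_score == pytest.approx(100)

    @pytest.mark.parametrize("cs", [False, True])
    def test_matches_exhaustive_subset_oracle(self, cs):
        rng = np.random.default_rng(9 if cs else 10)
        for _ in range(30):
            hs = random_hsps(rng, int(rng.integers(2, 11)))
            got = chain_hsps(hs, overlap_slack=10, cs_enabled=cs).total_score
            want = oracle_chain(hs, 10, cs)
            assert got == pytest.approx(want)


def oracle_global_affine(a, b, open_=400, ext=30):
    """Independent recursion over the 3-state affine alignment graph."""
    table = _SCORE_TABLE
    code = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

    @lru_cache(maxsize=None)
    def rec(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        best = -1e18
        if i < len(a) and j < len(b):
            best = max(best, table[code[a[i]], code[b[j]]] + rec(i + 1, j + 1, 0))
        if i < len(a):
            cost = ext if state == 1 else open_ + ext
            best = max(best, -cost + rec(i + 1, j, 1))
        if j < len(b):
            cost = ext if state == 2 else open_ + ext
            best = max(best, -cost + rec(i, j + 1, 2))
        return best

    return rec(0, 0, 0)


class TestGlobalDP:
    def test_identical_sequences(self):
        s = "ACGT" * 3
        score, cigar = global_dp(s, s)
        assert cigar == [("M", 12)]
        assert score == 3 * (91 + 100 + 100 + 91)

    def test_sequence_vs_empty_gap_cost(self):
        score, cigar = global_dp("ACGT", "")
        assert score == -(400 + 4 * 30)
        assert cigar == [("D", 4)]

    def test_matches_recursion_oracle(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        for _ in range(40):
            la, lb = int(rng.integers(0, 13)), int(rng.integers(0, 13))
            a = "".join(rng.choice(bases, la))
            b = "".join(rng.choice(bases, lb))
            score, _ = global_dp(a, b)
            assert score == pytest.approx(oracle_global_affine(a, b))

    def test_cap_refused(self):
        with pytest.raises(ValueError):
            global_dp("A" * 30_000, "A" * 10, dp_cap=20_000)


class TestGappedExtend:
    def _chain_at(self, a0, a1):
        h = HSP(a0, a1, a0, a1, 1000.0)
        from coalign.nuc_aligner import Chain
        return Chain(hsps=[h], total_score=1000.0)

    def test_identical_flanks_fully_covered_without_gaps(self):
        s = random_seq(300, seed=12)
        sva = SeqView.from_seq(s)
        frags = gapped_extend(self._chain_at(100, 200), sva, sva,
                              NAParams(), (0, 300), (0, 300))
        assert len(frags) == 2
        for f in frags:
            assert f.cigar == [("M", 100)]
            assert f.n_mismatches == 0

    def test_pure_n_flank_no_extension(self):
        core = random_seq(100, seed=13)
        s = "N" * 100 + core + "N" * 100
        sva = SeqView.from_seq(s)
        frags = gapped_extend(self._chain_at(100, 200), sva, sva,
                              NAParams(), (0, 300), (0, 300))
        assert frags == []


class TestFillInterval:
    def test_short_interval_single_global_dp(self):
        a = random_seq(200, seed=14)
        sva = SeqView.from_seq(a)
        frags = fill_interval((50, 90), (50, 90), sva, sva, NAParams())
        assert len(frags) == 1
        assert frags[0].ftype == "DP-fill"
        assert frags[0].cigar == [("M", 40)]

    def test_interval_beyond_t_high_left_unaligned(self):
        a = random_seq(30_000, seed=15)
        sva = SeqView.from_seq(a)
        frags = fill_interval((0, 25_000), (0, 25_000), sva, sva, NAParams())
        assert len(frags) == 1
        assert frags[0].ftype == "gap"
        assert frags[0].cigar is None

    def test_medium_interval_recovers_planted_homology(self):
        spec = SynthSpec(length=5000, identity=0.90, indel_rate=1e-3, rng_seed=16)
        a, b, _ = generate_pair(spec)
        sva, svb = SeqView.from_seq(a), SeqView.from_seq(b)
        frags = fill_interval((0, len(a)), (0, len(b)), sva, svb, NAParams())
        cov = np.zeros(len(a), dtype=bool)
        for f in frags:
            if f.cigar is not None:
                cov[f.a_start : f.a_end] = True
        assert cov.mean() >= 0.90


class TestSelfAlignmentStage:
    def test_full_na_stage_covers_self(self):
        s = random_seq(30_000, seed=17)
        sv = SeqView.from_seq(s)
        J = 5000
        path = [(i, i) for i in range(-(-len(s) // J))]
        env = envelope(make_colony(path), J, (len(s), len(s)))
        params = NAParams(t_high=2 * J, cs_enabled=True)
        chain, frags = align_envelope(sv, sv, env, params)
        cov = np.zeros(len(s), dtype=bool)
        for f in frags:
            assert f.a_start >= env.a_range[0] and f.a_end <= env.a_range[1]
            assert f.b_start >= env.b_range[0] and f.b_end <= env.b_range[1]
            if f.cigar is not None:
                assert f.n_mismatches == 0
                cov[f.a_start : f.a_end] = True
        assert cov.mean() >= 0.999
        # cs: projections pairwise disjoint
        ivs = sorted((f.a_start, f.a_end) for f in frags if f.cigar is not None)
        assert all(x1 <= x2 for (_, x1), (x2, _) in zip(ivs, ivs[1:]))


def test_cigar_string_roundtrip():
    cig = [("M", 120), ("D", 2), ("M", 30), ("I", 1), ("M", 7)]
    assert cigar_from_string(cigar_to_string(cig)) == cig
    assert cigar_to_string(None) == "*"
    assert cigar_from_string("*") is None
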