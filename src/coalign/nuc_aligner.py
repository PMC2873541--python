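"""Nucleotide-level alignment (NA) within block-colony envelopes.

Seed matches are found inside the envelope (the one-block dilation of a
colony's cell path), integrated into gapless HSPs, extended without gaps
under an X-drop rule, chained by a collinear-chaining DP with an overlap
penalty, and finally the chain is completed by gapped extension at its
ends and recursive filling of inter-HSP gaps (global affine DP for short
gaps, a shorter contiguous seed for medium ones, nothing for gaps longer
than T_high).  Nucleotide match/mismatch scores are the Chiaromonte et
al. values with affine gap penalties 400 (open) + 30 per base.

Soft-masked (lowercase) bases score 0 during HSP building; the iterative
fill and gapped-extension steps unmask, since repeats may still harbour
homology.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from coalign.block_aligner import Colony
from coalign.seedkit import SpacedSeed, encode_positions, parse_seed_pattern, seq_to_arrays

__all__ = [
    "NAParams", "HSP", "Chain", "Fragment", "SeqView", "Envelope",
    "load_score_table", "envelope", "find_matches", "integrate_matches",
    "gapless_extend", "chain_hsps", "gapped_extend", "fill_interval",
    "global_dp", "align_colony", "cigar_to_string", "cigar_from_string",
]

_N_SCORE = -100  # score for any pair involving an ambiguous base


def load_score_table() -> np.ndarray:
    """5x5 nucleotide scoring table (A,C,G,T,N order), Chiaromonte values."""
    table = np.full((5, 5), _N_SCORE, dtype=np.int32)
    ref = importlib.resources.files("coalign").joinpath("data/chiaromonte.tsv")
    lines = ref.read_text().strip().splitlines()
    for i, line in enumerate(lines[1:]):
        parts = line.split("\t")
        table[i, :4] = [int(v) for v in parts[1:5]]
    return table


_SCORE_TABLE = load_score_table()


@dataclass
class NAParams:
    """Nucleotide-level alignment parameters.

    t_low/t_high/t_dp control the iterative fill: gaps shorter than t_low
    get direct global DP, gaps below t_high are re-seeded with the
    contiguous inner seed (7-mer) and their sub-gaps DP-filled when below
    t_dp, longer gaps stay unaligned.  X-drop thresholds and the minimum
    HSP score are on the Chiaromonte score scale.
    """

    na_seed: SpacedSeed = field(default_factory=lambda: parse_seed_pattern("111*1**1*1**11*111"))
    merge_dist: int = 20
    t_low: int = 50
    t_high: int = 20_000  # 2 x default block size
    t_dp: int = 200
    inner_seed: SpacedSeed = field(default_factory=lambda: parse_seed_pattern("1111111"))
    overlap_slack: int = 10
    xdrop_gapless: int = 200
    xdrop_gapped: int = 600
    hsp_min_score: int = 1500
    inner_hsp_min_score: int = 500
    match_scores: np.ndarray = field(default_factory=lambda: _SCORE_TABLE.copy())
    gap_open: int = 400
    gap_extend: int = 30
    cs_enabled: bool = False
    region_occ_cap: int = 256
    dp_cap: int = 20_000
    max_extend: int = 2048

    def __post_init__(self) -> None:
        if not self.t_low < self.t_high:
            raise ValueError("t_low must be < t_high")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be > 0")


@dataclass
class HSP:
    """Gapless matching segment on one diagonal (0-based half-open)."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    score: float
    n_matches: int = 0
    n_mismatches: int = 0
    strand: str = "+"

    @property
    def diag(self) -> int:
        return self.a_start - self.b_start

    def __len__(self) -> int:
        return self.a_end - self.a_start


@dataclass
class Chain:
    """Maximal-scoring collinear subset of HSPs plus its gap fills."""

    hsps: list[HSP]
    total_score: float
    fills: list["Fragment"] = field(default_factory=list)


@dataclass
class Fragment:
    """One output alignment piece: an HSP, a DP fill, or an unaligned gap.

    Coordinates are 0-based half-open on the working orientation; the
    orchestrator maps reverse-colony b coordinates back to the forward
    strand.  `cigar` ops: M consumes both sequences, D consumes only A,
    I consumes only B; None for gap records.
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str
    score: float
    ftype: str  # "HSP" | "DP-fill" | "gap"
    cigar: list[tuple[str, int]] | None
    n_matches: int = 0
    n_mismatches: int = 0
    a_id: str = ""
    b_id: str = ""

    @property
    def identity(self) -> float:
        tot = self.n_matches + self.n_mismatches
        return self.n_matches / tot if tot else float("nan")


def cigar_to_string(cigar: list[tuple[str, int]] | None) -> str:
    if not cigar:
        return "*"
    return "".join(f"{n}{op}" for op, n in cigar)


def cigar_from_string(text: str) -> list[tuple[str, int]] | None:
    if text == "*" or not text:
        return None
    out: list[tuple[str, int]] = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out


# ---------------------------------------------------------------------------
# sequence views and pairwise scoring

@dataclass
class SeqView:
    """Cached numeric view of one sequence (one orientation)."""

    seq: str
    codes: np.ndarray
    masked: np.ndarray

    @classmethod
    def from_seq(cls, seq: str) -> "SeqView":
        codes, masked = seq_to_arrays(seq)
        return cls(seq=seq, codes=codes, masked=masked)

    def __len__(self) -> int:
        return len(self.codes)


class PairScorer:
    """Vectorised per-base scores/counts along diagonals of a sequence pair."""

    def __init__(self, sv_a: SeqView, sv_b: SeqView, table: np.ndarray, unmask: bool = False):
        self.a = sv_a
        self.b = sv_b
        self.table = table
        self.unmask = unmask

    def scores(self, a0: int, b0: int, n: int) -> np.ndarray:
        ca = self.a.codes[a0 : a0 + n]
        cb = self.b.codes[b0 : b0 + n]
        s = self.table[ca, cb].astype(np.float64)
        if not self.unmask:
            soft = (self.a.masked[a0 : a0 + n] & (ca < 4)) | (
                self.b.masked[b0 : b0 + n] & (cb < 4)
            )
            s[soft] = 0.0
        return s

    def match_counts(self, a0: int, b0: int, n: int) -> tuple[int, int]:
        ca = self.a.codes[a0 : a0 + n]
        cb = self.b.codes[b0 : b0 + n]
        known = (ca < 4) & (cb < 4)
        eq = known & (ca == cb)
        return int(eq.sum()), int((known & ~eq).sum())


# ---------------------------------------------------------------------------
# envelope

@dataclass
class Envelope:
    """Dilated nucleotide neighbourhood of a colony's cell path.

    The region is the union, over path cells (x, y), of the 3x3-block
    rectangles [(x-1)J, (x+2)J) x [(y-1)J, (y+2)J), clipped to the
    sequence bounds.  Membership tests use the dilated block-cell set.
    """

    block_size: int
    len_a: int
    len_b: int
    cells: frozenset[tuple[int, int]]
    a_range: tuple[int, int]
    b_range: tuple[int, int]
    _keys: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self._keys is None:
            mb = -(-self.len_b // self.block_size) + 2
            keys = np.array(sorted(x * mb + y for x, y in self.cells), dtype=np.int64)
            object.__setattr__(self, "_keys", keys)
            object.__setattr__(self, "_mb", mb)

    def contains(self, a_pos: np.ndarray, b_pos: np.ndarray) -> np.ndarray:
        """Vectorised membership of nucleotide coordinate pairs."""
        J = self.block_size
        q = (np.asarray(a_pos, dtype=np.int64) // J) * self._mb + (
            np.asarray(b_pos, dtype=np.int64) // J
        )
        idx = np.searchsorted(self._keys, q)
        idx = np.minimum(idx, len(self._keys) - 1)
        return self._keys[idx] == q

    def area(self) -> int:
        """Union area in square bp (clipped at sequence bounds)."""
        J = self.block_size
        total = 0
        for x, y in self.cells:
            wa = min((x + 1) * J, self.len_a) - max(x * J, 0)
            wb = min((y + 1) * J, self.len_b) - max(y * J, 0)
            if wa > 0 and wb > 0:
                total += wa * wb
        return total


def envelope(colony: Colony, block_size: int, lengths: tuple[int, int]) -> Envelope:
    """Envelope of a colony: 3x3-block dilation of its path cells."""
    if not colony.path:
        raise ValueError("empty colony")
    len_a, len_b = lengths
    m_a = -(-len_a // block_size)
    m_b = -(-len_b // block_size)
    cells = set()
    for x, y in colony.path:
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                cx, cy = x + dx, y + dy
                if 0 <= cx < m_a and 0 <= cy < m_b:
                    cells.add((cx, cy))
    xs = [c[0] for c in cells]
    ys = [c[1] for c in cells]
    a_range = (min(xs) * block_size, min((max(xs) + 1) * block_size, len_a))
    b_range = (min(ys) * block_size, min((max(ys) + 1) * block_size, len_b))
    return Envelope(
        block_size=block_size, len_a=len_a, len_b=len_b,
        cells=frozenset(cells), a_range=a_range, b_range=b_range,
    )


# ---------------------------------------------------------------------------
# seed matching

def _region_codes(sv: SeqView, lo: int, hi: int, seed: SpacedSeed, unmask: bool):
    codes = sv.codes[lo:hi]
    masked = np.zeros(hi - lo, dtype=bool) if unmask else sv.masked[lo:hi]
    win, ok = encode_positions(codes, masked, seed)
    pos = np.nonzero(ok)[0] + lo
    return win[np.nonzero(ok)[0]], pos


def find_matches(
    sv_a: SeqView,
    sv_b: SeqView,
    region_a: tuple[int, int],
    region_b: tuple[int, int],
    seed: SpacedSeed,
    env: Envelope | None = None,
    occ_cap: int = 256,
    unmask: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """All (a_pos, b_pos) where window codes agree between the regions.

    Codes occurring more than `occ_cap` times within either region are
    skipped as local repeats.  When `env` is given, matches outside the
    envelope are dropped.
    """
    wa, pa = _region_codes(sv_a, *region_a, seed, unmask)
    wb, pb = _region_codes(sv_b, *region_b, seed, unmask)
    if not wa.size or not wb.size:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(wa, kind="stable")
    wa_s, pa_s = wa[order], pa[order]
    # drop over-represented codes on either side
    ua, ca = np.unique(wa_s, return_counts=True)
    ub, cb = np.unique(wb, return_counts=True)
    bad = np.union1d(ua[ca > occ_cap], ub[cb > occ_cap])
    lo = np.searchsorted(wa_s, wb, side="left")
    hi = np.searchsorted(wa_s, wb, side="right")
    cnt = hi - lo
    if bad.size:
        j = np.searchsorted(bad, wb)
        j = np.minimum(j, len(bad) - 1)
        cnt = np.where(bad[j] == wb, 0, cnt)
    total = int(cnt.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    grp = np.repeat(np.arange(len(wb)), cnt)
    off = np.concatenate(([0], np.cumsum(cnt)[:-1]))
    within = np.arange(total) - off[grp]
    a_pos = pa_s[lo[grp] + within]
    b_pos = pb[grp]
    if env is not None:
        keep = env.contains(a_pos, b_pos)
        a_pos, b_pos = a_pos[keep], b_pos[keep]
    order = np.lexsort((b_pos, a_pos))
    return a_pos[order], b_pos[order]


def integrate_matches(
    a_pos: np.ndarray,
    b_pos: np.ndarray,
    span: int,
    merge_dist: int,
    scorer: PairScorer,
) -> list[HSP]:
    """Merge same-diagonal matches with gaps <= merge_dist into HSPs.

    Lonesome matches (segments containing a single seed match) are
    discarded.  Each HSP is scored per base over its full span, masked
    positions contributing 0.
    """
    if a_pos.size == 0:
        return []
    diag = a_pos - b_pos
    order = np.lexsort((a_pos, diag))
    d_s, a_s = diag[order], a_pos[order]
    new_seg = np.ones(len(a_s), dtype=bool)
    new_seg[1:] = (d_s[1:] != d_s[:-1]) | (a_s[1:] - (a_s[:-1] + span) > merge_dist)
    hsps: list[HSP] = []
    starts = np.nonzero(new_seg)[0]
    ends = np.append(starts[1:], len(a_s))
    for s, e in zip(starts, ends):
        if e - s < 2:
            continue  # lonesome
        a0 = int(a_s[s])
        a1 = int(a_s[e - 1]) + span
        b0 = a0 - int(d_s[s])
        n = a1 - a0
        score = float(scorer.scores(a0, b0, n).sum())
        nm, nx = scorer.match_counts(a0, b0, n)
        hsps.append(HSP(a0, a1, b0, b0 + n, score, nm, nx))
    return hsps


# ---------------------------------------------------------------------------
# gapless extension

def _extend_dir(scorer: PairScorer, a: int, b: int, limit: int, xdrop: float, step: int,
                chunk: int = 256) -> int:
    """Bases gained extending from (a, b) in direction `step` (+1/-1).

    `limit` is the maximum number of bases available.  Returns the offset
    (in bases) of the maximal-score end; 0 if no gain.
    """
    best = 0.0
    best_off = 0
    running = 0.0
    done = 0
    while done < limit:
        n = min(chunk, limit - done)
        if step > 0:
            s = scorer.scores(a + done, b + done, n)
        else:
            s = scorer.scores(a - done - n, b - done - n, n)[::-1]
        cum = running + np.cumsum(s)
        # X-drop: extension stops at the first position where the running
        # score falls more than xdrop below its maximum so far; the best
        # end may only be taken from positions before that point.
        runmax = np.maximum.accumulate(np.maximum(cum, best))
        drop = runmax - cum > xdrop
        stop = int(np.argmax(drop)) if drop.any() else len(cum)
        seg = cum[:stop] if drop.any() else cum
        if seg.size:
            i = int(np.argmax(seg))
            if seg[i] > best:
                best = float(seg[i])
                best_off = done + i + 1
        if drop.any():
            return best_off
        running = float(cum[-1])
        done += n
    return best_off


def gapless_extend(
    hsp: HSP,
    scorer: PairScorer,
    xdrop: float,
    bounds_a: tuple[int, int],
    bounds_b: tuple[int, int],
) -> HSP:
    """Extend an HSP outward on its diagonal while the score stays within
    `xdrop` of its running maximum; ends land on the maximal-score
    prefix/suffix."""
    right = _extend_dir(
        scorer, hsp.a_end, hsp.b_end,
        min(bounds_a[1] - hsp.a_end, bounds_b[1] - hsp.b_end), xdrop, +1,
    )
    left = _extend_dir(
        scorer, hsp.a_start, hsp.b_start,
        min(hsp.a_start - bounds_a[0], hsp.b_start - bounds_b[0]), xdrop, -1,
    )
    a0 = hsp.a_start - left
    a1 = hsp.a_end + right
    b0 = hsp.b_start - left
    n = a1 - a0
    score = float(scorer.scores(a0, b0, n).sum())
    nm, nx = scorer.match_counts(a0, b0, n)
    return HSP(a0, a1, b0, b0 + n, score, nm, nx, hsp.strand)


def _dedupe_hsps(hsps: list[HSP], scorer: PairScorer) -> list[HSP]:
    """Merge same-diagonal overlapping/touching HSPs after extension."""
    out: list[HSP] = []
    hsps = sorted(hsps, key=lambda h: (h.diag, h.a_start, h.a_end))
    for h in hsps:
        if out and out[-1].diag == h.diag and h.a_start <= out[-1].a_end:
            prev = out[-1]
            if h.a_end > prev.a_end:
                a0 = prev.a_start
                a1 = h.a_end
                b0 = prev.b_start
                n = a1 - a0
                score = float(scorer.scores(a0, b0, n).sum())
                nm, nx = scorer.match_counts(a0, b0, n)
                out[-1] = HSP(a0, a1, b0, b0 + n, score, nm, nx, h.strand)
        else:
            out.append(h)
    return out


# ---------------------------------------------------------------------------
# chaining

def chain_hsps(
    hsps: list[HSP],
    overlap_slack: int = 10,
    cs_enabled: bool = False,
) -> Chain:
    """Maximal-scoring collinear subset by DP with an overlap penalty.

    Consecutive chain members may overlap in a projection; each link pays
    pen_overlap = max(overlap_len - overlap_slack, 0) where overlap_len is
    the larger projection overlap.  With `cs_enabled` any overlap is
    forbidden.  Ties break toward the earliest sorted HSP.
    """
    if not hsps:
        return Chain(hsps=[], total_score=0.0)
    hs = sorted(hsps, key=lambda h: (h.a_start, h.b_start, h.a_end, h.b_end))
    n = len(hs)
    a0 = np.array([h.a_start for h in hs])
    a1 = np.array([h.a_end for h in hs])
    b0 = np.array([h.b_start for h in hs])
    b1 = np.array([h.b_end for h in hs])
    sc = np.array([h.score for h in hs], dtype=np.float64)
    dp = sc.copy()
    parent = np.full(n, -1, dtype=np.int64)
    for j in range(1, n):
        prev = np.arange(j)
        valid = (a0[prev] <= a0[j]) & (b0[prev] <= b0[j]) & (
            (a0[prev] < a0[j]) | (b0[prev] < b0[j])
        )
        ova = a1[prev] - a0[j]
        ovb = b1[prev] - b0[j]
        if cs_enabled:
            valid &= (ova <= 0) & (ovb <= 0)
        ov = np.maximum(np.maximum(ova, ovb), 0)
        pen = np.maximum(ov - overlap_slack, 0)
        cand = np.where(valid, dp[prev] - pen, -np.inf)
        if cand.size:
            i = int(np.argmax(cand))
            if cand[i] > 0:
                dp[j] = sc[j] + cand[i]
                parent[j] = i
    end = int(np.argmax(dp))
    members: list[HSP] = []
    i = end
    while i >= 0:
        members.append(hs[i])
        i = int(parent[i])
    members.reverse()
    return Chain(hsps=members, total_score=float(dp[end]))


# ---------------------------------------------------------------------------
# gapped extension and global DP

def _xdrop_affine_best(
    sa: np.ndarray, sb: np.ndarray, table: np.ndarray,
    gap_open: int, gap_extend: int, xdrop: float,
) -> tuple[int, int, float]:
    """Best-scoring cell of an affine extension DP with X-drop termination.

    Sequences are numeric codes in extension order starting at the anchor.
    Returns (consumed_a, consumed_b, score); (0, 0, 0.0) if no gain.
    """
    na, nb = len(sa), len(sb)
    if na == 0 or nb == 0:
        return 0, 0, 0.0
    first = gap_open + gap_extend
    NEG = -1e18
    js = np.arange(nb + 1)
    H = np.where(js == 0, 0.0, -(gap_open + js * gap_extend))
    Fv = np.full(nb + 1, NEG)
    best = 0.0
    bi = bj = 0
    for i in range(1, na + 1):
        sub = table[sa[i - 1], sb].astype(np.float64)
        M = H[:-1] + sub  # diagonal from previous row
        Fv = np.maximum(H - first, Fv - gap_extend)  # vertical gap
        Hn = np.empty(nb + 1)
        Hn[0] = -(gap_open + i * gap_extend)
        Hn[1:] = np.maximum(M, Fv[1:])
        # horizontal gaps via prefix max of (H_noE[j'] + j'*extend)
        run = np.maximum.accumulate(Hn + js * gap_extend)
        E = np.full(nb + 1, NEG)
        E[1:] = run[:-1] - first - js[1:] * gap_extend + gap_extend
        Hn = np.maximum(Hn, E)
        H = Hn
        row_best = float(H[1:].max())
        if row_best > best:
            j = int(np.argmax(H[1:])) + 1
            best, bi, bj = row_best, i, j
        if row_best < best - xdrop:
            break
    return bi, bj, best


_ALPHABET = "ACGTN"


def _make_aligner(table: np.ndarray, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    mat = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for i, x in enumerate(_ALPHABET):
        for j, y in enumerate(_ALPHABET):
            mat[x, y] = float(table[i, j])
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_dp(
    seq_a: str,
    seq_b: str,
    match_scores: np.ndarray | None = None,
    gap_open: int = 400,
    gap_extend: int = 30,
    dp_cap: int = 20_000,
) -> tuple[float, list[tuple[str, int]]]:
    """Optimal global affine-gap alignment of two (unmasked) sequences.

    Returns (score, cigar); a gap of length g costs gap_open + g *
    gap_extend.  Refuses sequences longer than `dp_cap` (callers must fall
    back to seeding or leave the region unaligned).
    """
    if len(seq_a) > dp_cap or len(seq_b) > dp_cap:
        raise ValueError(f"global_dp refuses sequences > {dp_cap} bp")
    table = _SCORE_TABLE if match_scores is None else match_scores
    a = seq_a.upper()
    b = seq_b.upper()
    if not a and not b:
        return 0.0, []
    if not a:
        return -(gap_open + len(b) * gap_extend), [("I", len(b))]
    if not b:
        return -(gap_open + len(a) * gap_extend), [("D", len(a))]
    a = "".join(ch if ch in _ALPHABET else "N" for ch in a)
    b = "".join(ch if ch in _ALPHABET else "N" for ch in b)
    aligner = _make_aligner(table, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    cigar: list[tuple[str, int]] = []
    pa = pb = 0
    blocks_a, blocks_b = aln.aligned
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        if sa > pa:
            cigar.append(("D", sa - pa))
        if sb > pb:
            cigar.append(("I", sb - pb))
        cigar.append(("M", ea - sa))
        pa, pb = ea, eb
    if len(a) > pa:
        cigar.append(("D", len(a) - pa))
    if len(b) > pb:
        cigar.append(("I", len(b) - pb))
    # merge adjacent same-op runs for a canonical cigar
    merged: list[tuple[str, int]] = []
    for op, ln in cigar:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return float(aln.score), merged


def _fragment_from_cigar(
    a0: int, b0: int, cigar: list[tuple[str, int]],
    scorer: PairScorer, ftype: str, score: float,
) -> Fragment:
    """Build a Fragment, counting matches/mismatches along the cigar."""
    nm = nx = 0
    ai, bi = a0, b0
    for op, ln in cigar:
        if op == "M":
            m, x = scorer.match_counts(ai, bi, ln)
            nm += m
            nx += x
            ai += ln
            bi += ln
        elif op == "D":
            ai += ln
        else:
            bi += ln
    return Fragment(
        a_start=a0, a_end=ai, b_start=b0, b_end=bi, strand="+",
        score=score, ftype=ftype, cigar=cigar, n_matches=nm, n_mismatches=nx,
    )


def gapped_extend(
    chain: Chain,
    sv_a: SeqView,
    sv_b: SeqView,
    params: NAParams,
    bounds_a: tuple[int, int],
    bounds_b: tuple[int, int],
) -> list[Fragment]:
    """Gapped X-drop extension from the outer ends of a chain.

    Repetitive sequence is unmasked here.  Each extension locates the
    best-scoring end cell with an affine X-drop DP, then recovers the
    alignment path by global DP over the consumed prefixes.
    """
    if not chain.hsps:
        return []
    out: list[Fragment] = []
    scorer = PairScorer(sv_a, sv_b, params.match_scores, unmask=True)
    first, last = chain.hsps[0], chain.hsps[-1]
    # leftward: reversed prefixes ending at the chain start
    la = min(first.a_start - bounds_a[0], params.max_extend)
    lb = min(first.b_start - bounds_b[0], params.max_extend)
    sa = sv_a.codes[first.a_start - la : first.a_start][::-1]
    sb = sv_b.codes[first.b_start - lb : first.b_start][::-1]
    ia, ib, sc = _xdrop_affine_best(sa, sb, params.match_scores,
                                    params.gap_open, params.gap_extend,
                                    params.xdrop_gapped)
    if ia and ib:
        seg_a = sv_a.seq[first.a_start - ia : first.a_start]
        seg_b = sv_b.seq[first.b_start - ib : first.b_start]
        _, cigar = global_dp(seg_a, seg_b, params.match_scores,
                             params.gap_open, params.gap_extend, params.dp_cap)
        out.append(_fragment_from_cigar(
            first.a_start - ia, first.b_start - ib, cigar, scorer, "DP-fill", sc))
    # rightward from the chain end
    ra = min(bounds_a[1] - last.a_end, params.max_extend)
    rb = min(bounds_b[1] - last.b_end, params.max_extend)
    sa = sv_a.codes[last.a_end : last.a_end + ra]
    sb = sv_b.codes[last.b_end : last.b_end + rb]
    ia, ib, sc = _xdrop_affine_best(sa, sb, params.match_scores,
                                    params.gap_open, params.gap_extend,
                                    params.xdrop_gapped)
    if ia and ib:
        seg_a = sv_a.seq[last.a_end : last.a_end + ia]
        seg_b = sv_b.seq[last.b_end : last.b_end + ib]
        _, cigar = global_dp(seg_a, seg_b, params.match_scores,
                             params.gap_open, params.gap_extend, params.dp_cap)
        out.append(_fragment_from_cigar(
            last.a_end, last.b_end, cigar, scorer, "DP-fill", sc))
    return out


def fill_interval(
    a_itv: tuple[int, int],
    b_itv: tuple[int, int],
    sv_a: SeqView,
    sv_b: SeqView,
    params: NAParams,
    depth: int = 1,
) -> list[Fragment]:
    """Align one inter-HSP gap; sequence is unmasked throughout.

    Short gaps (longer side < t_low) get direct global DP; medium gaps
    (< t_high) are re-seeded with the contiguous inner seed and chained,
    their sub-gaps DP-filled when below t_dp; long gaps are reported as
    unaligned gap records.  Recursion depth is capped at 2 (outer spaced
    seed, then the inner contiguous seed).
    """
    a0, a1 = a_itv
    b0, b1 = b_itv
    la, lb = a1 - a0, b1 - b0
    if la < 0 or lb < 0:
        raise ValueError("negative interval")
    if la == 0 or lb == 0:
        return []  # pure indel between anchors; implied by coordinates
    longer = max(la, lb)
    scorer = PairScorer(sv_a, sv_b, params.match_scores, unmask=True)

    def dp_fragment() -> list[Fragment]:
        score, cigar = global_dp(sv_a.seq[a0:a1], sv_b.seq[b0:b1],
                                 params.match_scores, params.gap_open,
                                 params.gap_extend, params.dp_cap)
        return [_fragment_from_cigar(a0, b0, cigar, scorer, "DP-fill", score)]

    def gap_record() -> list[Fragment]:
        return [Fragment(a0, a1, b0, b1, "+", 0.0, "gap", None)]

    if longer < params.t_low:
        return dp_fragment()
    if longer >= params.t_high or depth >= 2:
        if longer < params.t_dp:
            return dp_fragment()
        return gap_record()

    # medium gap: re-seed with the inner contiguous 7-mer, unmasked
    ap, bp = find_matches(sv_a, sv_b, (a0, a1), (b0, b1), params.inner_seed,
                          env=None, occ_cap=params.region_occ_cap, unmask=True)
    hsps = integrate_matches(ap, bp, params.inner_seed.span, params.merge_dist, scorer)
    hsps = [
        gapless_extend(h, scorer, params.xdrop_gapless, (a0, a1), (b0, b1))
        for h in hsps
    ]
    hsps = _dedupe_hsps([h for h in hsps if h.score >= params.inner_hsp_min_score], scorer)
    if not hsps:
        if longer < params.t_dp:
            return dp_fragment()
        return gap_record()
    chain = chain_hsps(hsps, params.overlap_slack, params.cs_enabled)
    frags: list[Fragment] = []
    prev_a, prev_b = a0, b0
    for h in chain.hsps:
        if h.a_start >= prev_a and h.b_start >= prev_b:
            sub = _subgap(prev_a, h.a_start, prev_b, h.b_start, sv_a, sv_b, params, scorer)
            frags.extend(sub)
        frags.append(_fragment_from_cigar(
            h.a_start, h.b_start, [("M", len(h))], scorer, "HSP", h.score))
        prev_a, prev_b = h.a_end, h.b_end
    if a1 >= prev_a and b1 >= prev_b:
        frags.extend(_subgap(prev_a, a1, prev_b, b1, sv_a, sv_b, params, scorer))
    return frags


def _subgap(a0, a1, b0, b1, sv_a, sv_b, params, scorer) -> list[Fragment]:
    """Sub-interval between inner-seed HSPs: DP when short, else a gap."""
    la, lb = a1 - a0, b1 - b0
    if la <= 0 or lb <= 0:
        return []
    if max(la, lb) < params.t_dp:
        score, cigar = global_dp(sv_a.seq[a0:a1], sv_b.seq[b0:b1],
                                 params.match_scores, params.gap_open,
                                 params.gap_extend, params.dp_cap)
        return [_fragment_from_cigar(a0, b0, cigar, scorer, "DP-fill", score)]
    return [Fragment(a0, a1, b0, b1, "+", 0.0, "gap", None)]


# ---------------------------------------------------------------------------
# per-colony NA driver

def align_colony(
    sv_a: SeqView,
    sv_b: SeqView,
    colony: Colony,
    params: NAParams,
    block_size: int,
) -> tuple[Chain, list[Fragment]]:
    """Full NA within one colony's envelope.

    Seed matching and HSP building run on the masked sequence; gapped
    extension and gap filling unmask.  Returns the chain and the ordered
    fragments (HSPs, DP fills, gap records) in the working orientation.
    """
    env = envelope(colony, block_size, (len(sv_a), len(sv_b)))
    return align_envelope(sv_a, sv_b, env, params)


def align_envelope(
    sv_a: SeqView,
    sv_b: SeqView,
    env: Envelope,
    params: NAParams,
) -> tuple[Chain, list[Fragment]]:
    scorer = PairScorer(sv_a, sv_b, params.match_scores, unmask=False)
    ap, bp = find_matches(sv_a, sv_b, env.a_range, env.b_range, params.na_seed,
                          env=env, occ_cap=params.region_occ_cap)
    hsps = integrate_matches(ap, bp, params.na_seed.span, params.merge_dist, scorer)
    hsps = [
        gapless_extend(h, scorer, params.xdrop_gapless, env.a_range, env.b_range)
        for h in hsps
    ]
    hsps = _dedupe_hsps([h for h in hsps if h.score >= params.hsp_min_score], scorer)
    if not hsps:
        return Chain(hsps=[], total_score=0.0), []
    chain = chain_hsps(hsps, params.overlap_slack, params.cs_enabled)

    frags: list[Fragment] = []
    ext = gapped_extend(chain, sv_a, sv_b, params, env.a_range, env.b_range)
    frags.extend(ext)
    prev_a = prev_b = None
    for h in chain.hsps:
        if prev_a is not None and h.a_start >= prev_a and h.b_start >= prev_b:
            fills = fill_interval((prev_a, h.a_start), (prev_b, h.b_start),
                                  sv_a, sv_b, params, depth=1)
            frags.extend(fills)
            chain.fills.extend(fills)
        frags.append(_fragment_from_cigar(
            h.a_start, h.b_start, [("M", len(h))], scorer, "HSP", h.score))
        prev_a, prev_b = h.a_end, h.b_end
    frags.sort(key=lambda f: (f.a_start, f.b_start))
    return chain, frags
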