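"""Block-level alignment (BA).

Fixed-length genome blocks are the DP elements.  The similarity of block
pair (x, y) is

    M[x, y] = sum over codes i present in both blocks of
              -log p_a(>= m_i) - log p_b(>= m_i),   m_i = min(f_i, h_i)

where f_i and h_i are the per-block occurrence counts and p(>= x) is the
Poisson tail of the code's chance occurrence in one block.  M is always
>= 0, so a constant bias B is subtracted inside the local DP

    F[x, y] = max(0, F[x-1, y-1] + M[x, y] - B,
                     F[x-1, y] - d, F[x, y-1] - d)

with linear gap penalty d.  The DP assigns cells to "colonies" (candidate
local alignments) delimited by X-drop-off: a colony opens when F rises
from 0, a cell leaves the colony when F falls to 0 or more than T_col
below the colony's running maximum, and only colonies whose peak exceeds
T_col are significant.  B is tuned so that a run of unrelated cells
exhausts T_col after about `a_cells` cells on average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from coalign.seedkit import GenomeIndex

__all__ = [
    "BAParams", "BlockCell", "Colony",
    "seed_block_score", "block_similarity", "similarity_matrix",
    "compute_bias", "block_local_dp", "colony_dp", "filter_colonies",
    "scale_tcol", "write_colony_table",
]


@dataclass
class BAParams:
    """Block-level alignment parameters.

    t_col is the colony significance / X-drop-off threshold; d defaults to
    t_col / 15; `a_cells` sets the bias so an unrelated run X-drops after
    about that many cells.  `log_scale` multiplies the -log seed scores
    (1.0 keeps t_col = 3000 on the natural-log scale).
    """

    block_size: int = 10_000
    t_col: float = 3000.0
    gap_penalty: float | None = None
    a_cells: int = 5
    bias: float | None = None
    log_scale: float = 1.0
    max_occ: int = 3

    def __post_init__(self) -> None:
        if self.t_col <= 0:
            raise ValueError("t_col must be > 0")
        if self.gap_penalty is None:
            self.gap_penalty = self.t_col / 15.0
        if self.gap_penalty <= 0:
            raise ValueError("gap_penalty must be > 0")
        if self.a_cells < 1:
            raise ValueError("a_cells must be >= 1")


@dataclass
class BlockCell:
    """One cell of the block DP matrix."""

    x: int
    y: int
    m_score: float
    f_score: float


@dataclass
class Colony:
    """A significant block-level local alignment.

    `path` is the traceback path of block cells from the colony start to
    its peak, monotone non-decreasing in both coordinates.
    """

    path: list[tuple[int, int]]
    peak_score: float
    bounds: tuple[int, int, int, int]  # x_min, x_max, y_min, y_max (inclusive)
    orientation: str = "forward"

    def overlaps(self, other: "Colony") -> bool:
        """Overlap in either projection (x-range or y-range)."""
        ax0, ax1, ay0, ay1 = self.bounds
        bx0, bx1, by0, by1 = other.bounds
        x_ov = ax0 <= bx1 and bx0 <= ax1
        y_ov = ay0 <= by1 and by0 <= ay1
        return x_ov or y_ov


# ---------------------------------------------------------------------------
# block similarity

def seed_block_score(
    code: int, f: int, h: int,
    index_a: GenomeIndex, index_b: GenomeIndex,
    log_scale: float = 1.0,
) -> float:
    """Score of one code shared by a block pair.

    m = min(f, h) matches are credited (true homologous matches line up on
    one diagonal, so f*h would overestimate); the score is the summed
    negative log Poisson tails of >= m chance occurrences in each genome's
    block.  Returns 0 when m exceeds the repeat cap max_occ.
    """
    if f < 1 or h < 1:
        raise ValueError("seed_block_score requires f >= 1 and h >= 1")
    m = min(f, h)
    if m > index_a.max_occ:
        return 0.0
    cls_a = index_a._class_of(code)
    cls_b = index_b._class_of(code)
    return float(
        log_scale * (index_a.neg_log_tail[cls_a, m] + index_b.neg_log_tail[cls_b, m])
    )


def _entries_of_block(index: GenomeIndex, block: int):
    sel = index.entry_blocks == block
    return index.entry_codes[sel], index.entry_counts[sel], index.entry_class[sel]


def block_similarity(
    x: int, y: int,
    index_a: GenomeIndex, index_b: GenomeIndex,
    params: BAParams | None = None,
) -> float:
    """M[x, y]: summed seed scores over codes present in both blocks.

    Codes whose per-block count exceeds max_occ on either side are treated
    as repeats for that block and contribute nothing.
    """
    params = params or BAParams(block_size=index_a.block_size)
    if not (0 <= x < index_a.num_blocks and 0 <= y < index_b.num_blocks):
        raise ValueError("block ordinal out of range")
    ca, fa, cls_a = _entries_of_block(index_a, x)
    cb, hb, cls_b = _entries_of_block(index_b, y)
    common, ia, ib = np.intersect1d(ca, cb, return_indices=True)
    if not common.size:
        return 0.0
    f = fa[ia].astype(np.int64)
    h = hb[ib].astype(np.int64)
    m = np.minimum(f, h)
    ok = (f <= index_a.max_occ) & (h <= index_b.max_occ)
    s = index_a.neg_log_tail[cls_a[ia], m] + index_b.neg_log_tail[cls_b[ib], m]
    return float(params.log_scale * np.sum(s[ok]))


def _grouped(index: GenomeIndex):
    """Group index-table entries by code: (codes, start, count) slices."""
    codes, start, cnt = np.unique(index.entry_codes, return_index=True, return_counts=True)
    return codes, start, cnt


def similarity_matrix(
    index_a: GenomeIndex, index_b: GenomeIndex, params: BAParams
) -> np.ndarray:
    """Dense M over all block pairs, by a vectorised join on shared codes."""
    m_a, m_b = index_a.num_blocks, index_b.num_blocks
    M = np.zeros((m_a, m_b), dtype=np.float64)
    ca, sa, na = _grouped(index_a)
    cb, sb, nb = _grouped(index_b)
    common, ia, ib = np.intersect1d(ca, cb, return_indices=True)
    if not common.size:
        return M
    p = na[ia].astype(np.int64)
    q = nb[ib].astype(np.int64)
    pq = p * q
    total = int(pq.sum())
    grp = np.repeat(np.arange(len(pq)), pq)
    off = np.concatenate(([0], np.cumsum(pq)[:-1]))
    within = np.arange(total) - off[grp]
    ai = sa[ia][grp] + within // q[grp]
    bi = sb[ib][grp] + within % q[grp]
    f = index_a.entry_counts[ai].astype(np.int64)
    h = index_b.entry_counts[bi].astype(np.int64)
    mm = np.minimum(f, h)
    ok = (f <= index_a.max_occ) & (h <= index_b.max_occ)
    s = index_a.neg_log_tail[index_a.entry_class[ai], mm]
    s += index_b.neg_log_tail[index_b.entry_class[bi], mm]
    s *= params.log_scale
    key = index_a.entry_blocks[ai].astype(np.int64) * m_b + index_b.entry_blocks[bi]
    M.ravel()[:] = np.bincount(key[ok], weights=s[ok], minlength=m_a * m_b)
    return M


def compute_bias(
    index_a: GenomeIndex, index_b: GenomeIndex,
    params: BAParams, rng_seed: int = 0,
    n_samples: int = 1000,
) -> float:
    """Bias B = mean M over sampled cells + t_col / a_cells.

    The mean chance similarity is estimated from `n_samples` uniformly
    sampled block pairs with a fixed RNG seed, so a colony traversing
    unrelated cells X-drops after about `a_cells` cells on average.
    """
    if index_a.num_blocks < 2 or index_b.num_blocks < 2:
        raise ValueError("bias estimation needs at least 2 blocks per genome")
    rng = np.random.default_rng(rng_seed)
    xs = rng.integers(0, index_a.num_blocks, size=n_samples)
    ys = rng.integers(0, index_b.num_blocks, size=n_samples)
    mean = float(np.mean([
        block_similarity(int(x), int(y), index_a, index_b, params)
        for x, y in zip(xs, ys)
    ]))
    return mean + params.t_col / params.a_cells


# ---------------------------------------------------------------------------
# colony local DP

def colony_dp(net: np.ndarray, t_col: float, gap_penalty: float) -> list["Colony"]:
    """Colony local DP over a net score grid (M - B already applied).

    Smith-Waterman recurrence with linear gap penalty; cells are assigned
    to colonies which X-drop when F falls more than t_col below the colony
    maximum.  Significant colonies (peak > t_col) are returned with the
    traceback path from their peak.  Ties break diagonal > up > left > stop
    for bit-reproducible runs.
    """
    m_a, m_b = net.shape
    F = np.zeros((m_a + 1, m_b + 1), dtype=np.float64)
    direction = np.zeros((m_a + 1, m_b + 1), dtype=np.int8)  # 0 stop,1 diag,2 up,3 left
    col_id = np.zeros((m_a + 1, m_b + 1), dtype=np.int32)
    # per-colony state, 1-based ids
    peaks: list[float] = [0.0]
    peak_cells: list[tuple[int, int]] = [(-1, -1)]
    boxes: list[list[int]] = [[0, 0, 0, 0]]

    for x in range(1, m_a + 1):
        Fprev = F[x - 1]
        Frow = F[x]
        for y in range(1, m_b + 1):
            diag = Fprev[y - 1] + net[x - 1, y - 1]
            up = Fprev[y] - gap_penalty
            left = Frow[y - 1] - gap_penalty
            best = diag
            move = 1
            if up > best:
                best, move = up, 2
            if left > best:
                best, move = left, 3
            if best <= 0.0:
                Frow[y] = 0.0
                continue
            if move == 1:
                cid = col_id[x - 1, y - 1]
            elif move == 2:
                cid = col_id[x - 1, y]
            else:
                cid = col_id[x, y - 1]
            if cid == 0:
                cid = len(peaks)
                peaks.append(0.0)
                peak_cells.append((x, y))
                boxes.append([x, x, y, y])
            if best > peaks[cid]:
                peaks[cid] = best
                peak_cells[cid] = (x, y)
            elif peaks[cid] - best > t_col:
                # X-drop: this branch leaves the colony
                Frow[y] = 0.0
                continue
            Frow[y] = best
            direction[x, y] = move
            col_id[x, y] = cid
            box = boxes[cid]
            if x < box[0]:
                box[0] = x
            if x > box[1]:
                box[1] = x
            if y < box[2]:
                box[2] = y
            if y > box[3]:
                box[3] = y

    colonies: list[Colony] = []
    for cid in range(1, len(peaks)):
        if peaks[cid] <= t_col:
            continue
        # traceback from the peak to the colony start
        x, y = peak_cells[cid]
        path: list[tuple[int, int]] = []
        while x >= 1 and y >= 1 and direction[x, y] != 0:
            path.append((x - 1, y - 1))
            d = direction[x, y]
            if d == 1:
                x, y = x - 1, y - 1
            elif d == 2:
                x -= 1
            else:
                y -= 1
        path.reverse()
        b = boxes[cid]
        colonies.append(Colony(
            path=path,
            peak_score=float(peaks[cid]),
            bounds=(b[0] - 1, b[1] - 1, b[2] - 1, b[3] - 1),
        ))
    colonies.sort(key=lambda c: (c.bounds[0], c.bounds[2]))
    return colonies


def block_local_dp(
    index_a: GenomeIndex, index_b: GenomeIndex,
    params: BAParams,
    bias: float | None = None,
    orientation: str = "forward",
    rng_seed: int = 0,
) -> list[Colony]:
    """Run the block-level DP between two indexed genomes.

    `index_b` indexes either the forward genome or its reverse complement;
    colonies are tagged with `orientation` accordingly.  When `bias` (and
    `params.bias`) is None it is estimated by :func:`compute_bias`.
    """
    if bias is None:
        bias = params.bias
    if bias is None:
        bias = compute_bias(index_a, index_b, params, rng_seed=rng_seed)
    M = similarity_matrix(index_a, index_b, params)
    colonies = colony_dp(M - bias, params.t_col, params.gap_penalty)
    for c in colonies:
        c.orientation = orientation
    return colonies


def filter_colonies(colonies: list[Colony], fc_enabled: bool = True) -> list[Colony]:
    """Keep only the best colony of every mutually-overlapping set.

    Overlap is tested on either projection.  Within each connected
    component of the overlap graph the highest-scoring colony survives;
    ties break toward the smallest (x_min, y_min).
    """
    if not fc_enabled or len(colonies) <= 1:
        return list(colonies)
    n = len(colonies)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if colonies[i].overlaps(colonies[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    best: dict[int, Colony] = {}
    for i, c in enumerate(colonies):
        r = find(i)
        cur = best.get(r)
        if cur is None:
            best[r] = c
        else:
            key_new = (-c.peak_score, c.bounds[0], c.bounds[2])
            key_cur = (-cur.peak_score, cur.bounds[0], cur.bounds[2])
            if key_new < key_cur:
                best[r] = c
    kept = list(best.values())
    kept.sort(key=lambda c: (c.bounds[0], c.bounds[2]))
    return kept


def scale_tcol(
    t_col_default: float,
    block_size_ratio: float,
    k_diff: int = 0,
    g=None,
    h=None,
    c: float = 0.5,
) -> float:
    """Empirical T_col rescaling for non-default block and k-mer sizes.

    Returns ``t_col_default * g(r_b) * h(k_diff)``.  The default shapes —
    g(r_b) = r_b (threshold proportional to block size) and
    h(k_diff) = 4**(-k_diff * c) (larger seeds are rarer by chance, so the
    threshold falls) — are monotone, pass through 1 at the default
    configuration, and are exposed as configuration; they are this
    package's documented choice, not a canonical rule.
    """
    if block_size_ratio <= 0:
        raise ValueError("block_size_ratio must be > 0")
    if g is None:
        g = lambda r: r
    if h is None:
        h = lambda kd: 4.0 ** (-kd * c)
    return float(t_col_default * g(block_size_ratio) * h(k_diff))


def write_colony_table(
    colonies: list[Colony], block_size: int,
    len_a: int, len_b: int, path,
) -> None:
    """Dot-plot export: tab-separated nucleotide block coordinates.

    Columns: x_start, x_end, y_start, y_end, strand, score.  Reverse
    colonies carry y coordinates already mapped to the forward strand by
    the caller's convention (bounds are on the indexed orientation; the
    strand column records it).
    """
    with open(path, "w") as fh:
        fh.write("x_start\tx_end\ty_start\ty_end\tstrand\tscore\n")
        for c in colonies:
            x0, x1, y0, y1 = c.bounds
            strand = "+" if c.orientation == "forward" else "-"
            fh.write(
                f"{x0 * block_size}\t{min((x1 + 1) * block_size, len_a)}\t"
                f"{y0 * block_size}\t{min((y1 + 1) * block_size, len_b)}\t"
                f"{strand}\t{c.peak_score:.3f}\n"
            )
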