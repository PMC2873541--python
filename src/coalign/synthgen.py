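"""Deterministic synthetic homologous genome pairs with ground truth.

Genome B is derived from genome A by point substitutions (at rate
1 - identity, transition:transversion 2:1), short indels, and then
large-scale rearrangements (inversions, translocations, duplications)
applied as a segment permutation.  Every orthologously aligned base pair
survives into a ground-truth runs file; duplication *copies* are
paralogous and therefore excluded from the truth.  Repeat families can be
planted and soft-masked (lowercased) before divergence, emulating
ancestral repeats shared by both genomes.

All randomness flows from one integer seed; equal seeds give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from coalign.seedkit import revcomp

__all__ = ["SynthSpec", "Rearrangement", "generate_pair", "plant_repeats", "pairs_to_runs"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# transition partner (A<->G, C<->T) and the two transversion partners
_TRANSITION = np.array([2, 3, 0, 1])
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


@dataclass(frozen=True)
class Rearrangement:
    """One planted rearrangement, on coordinates of the pre-rearranged B.

    `position`/`length` locate the source segment; `dest` (required for
    translocation and duplication, ignored for inversion) is the insertion
    point and may not fall inside any source segment.
    """

    kind: str  # "inversion" | "translocation" | "duplication"
    position: int
    length: int
    dest: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("inversion", "translocation", "duplication"):
            raise ValueError(f"unknown rearrangement kind {self.kind!r}")
        if self.kind != "inversion" and self.dest is None:
            raise ValueError(f"{self.kind} requires a dest coordinate")


@dataclass
class SynthSpec:
    """Study conditions for one synthetic genome pair.

    identity is the substitution-adjusted identity over aligned bases;
    indel_rate is the per-base probability of opening an indel (split
    evenly between insertions and deletions, geometric lengths with mean
    `indel_mean`).
    """

    length: int = 1_000_000
    identity: float = 0.85
    indel_rate: float = 5e-4
    indel_mean: float = 3.0
    rearrangements: list[Rearrangement] = field(default_factory=list)
    repeat_fraction: float = 0.0
    rng_seed: int = 0
    a_id: str = "synthA"
    b_id: str = "synthB"

    def __post_init__(self) -> None:
        if not (0.0 < self.identity <= 1.0):
            raise ValueError("identity must be in (0, 1]")
        if not (0.0 <= self.repeat_fraction < 1.0):
            raise ValueError("repeat_fraction must be in [0, 1)")


def plant_repeats(sequence: str, repeat_fraction: float, rng_seed: int = 0) -> str:
    """Soft-mask a sequence by pasting lowercased repeat-family copies.

    Copies of a randomly drawn family consensus (about 10% diverged per
    copy) are pasted at random positions and lowercased until the masked
    fraction reaches the request (within +-0.02).  fraction 0 returns the
    input unchanged.
    """
    if not (0.0 <= repeat_fraction < 1.0):
        raise ValueError("repeat_fraction must be in [0, 1)")
    if repeat_fraction == 0.0 or not sequence:
        return sequence
    rng = np.random.default_rng(rng_seed)
    L = len(sequence)
    rep_len = min(300, max(20, L // 100))
    consensus = rng.integers(0, 4, size=rep_len)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    lower = np.zeros(L, dtype=bool)
    target = repeat_fraction * L
    guard = 0
    while lower.sum() < target and guard < 100 * L // rep_len + 100:
        guard += 1
        pos = int(rng.integers(0, max(1, L - rep_len)))
        copy = consensus.copy()
        mut = rng.random(rep_len) < 0.10
        copy[mut] = (copy[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
        arr[pos : pos + rep_len] = _BASES[copy] + 32  # lowercase
        lower[pos : pos + rep_len] = True
    return arr.tobytes().decode("ascii")


def _mutate(seq_a: str, spec: SynthSpec, rng: np.random.Generator):
    """Substitutions and indels; returns (seq_b0, a_pos, b_pos) pair arrays."""
    arr = np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)
    lower = (arr >= 97)
    codes = np.zeros(len(arr), dtype=np.int64)
    up = np.where(lower, arr - 32, arr)
    for i, b in enumerate(b"ACGT"):
        codes[up == b] = i

    L = len(arr)
    p_sub = 1.0 - spec.identity
    u = rng.random(L)
    half = spec.indel_rate / 2.0
    deleted = u < half
    inserting = (u >= half) & (u < spec.indel_rate)
    substituted = (~deleted) & (rng.random(L) < p_sub)

    # substitution with ts:tv = 2:1  (P(ts) = 2/3)
    new_codes = codes.copy()
    sub_idx = np.nonzero(substituted)[0]
    r = rng.random(sub_idx.size)
    ts = r < 2.0 / 3.0
    tv_side = (r >= 5.0 / 6.0).astype(np.int64)
    repl = np.where(ts, _TRANSITION[codes[sub_idx]],
                    _TRANSVERSIONS[codes[sub_idx], tv_side])
    new_codes[sub_idx] = repl

    ins_len = np.zeros(L, dtype=np.int64)
    n_ins_sites = int(inserting.sum())
    if n_ins_sites:
        ins_len[inserting] = rng.geometric(1.0 / spec.indel_mean, size=n_ins_sites)
    # deletions also take geometric lengths: extend each deletion start
    del_idx = np.nonzero(deleted)[0]
    if del_idx.size:
        dlen = rng.geometric(1.0 / spec.indel_mean, size=del_idx.size)
        dmask = np.zeros(L + 1, dtype=np.int64)
        np.add.at(dmask, del_idx, 1)
        np.add.at(dmask, np.minimum(del_idx + dlen, L), -1)
        deleted = np.cumsum(dmask[:-1]) > 0

    kept = ~deleted
    ins_len[deleted] = 0
    a_pos = np.nonzero(kept)[0].astype(np.int64)
    n_kept = a_pos.size
    ins_before = np.concatenate(([0], np.cumsum(ins_len[kept])[:-1]))
    b_pos = np.arange(n_kept, dtype=np.int64) + ins_before

    total = n_kept + int(ins_len[kept].sum())
    out_codes = np.empty(total, dtype=np.int64)
    out_lower = np.zeros(total, dtype=bool)
    ins_slots = np.ones(total, dtype=bool)
    ins_slots[b_pos] = False
    out_codes[b_pos] = new_codes[a_pos]
    out_lower[b_pos] = lower[a_pos]
    n_slots = int(ins_slots.sum())
    if n_slots:
        out_codes[ins_slots] = rng.integers(0, 4, size=n_slots)
    chars = _BASES[out_codes] + np.where(out_lower, 32, 0).astype(np.uint8)
    seq_b0 = chars.tobytes().decode("ascii")
    return seq_b0, a_pos, b_pos


def _apply_rearrangements(seq_b0: str, a_pos, b_pos, rearrs: list[Rearrangement]):
    """Apply the segment permutation; returns (seq_b, a_pos, b_pos, strand)."""
    L = len(seq_b0)
    segs = []
    for i, r in enumerate(rearrs):
        s, e = r.position, r.position + r.length
        if not (0 <= s < e <= L):
            raise ValueError(f"rearrangement segment [{s}, {e}) outside sequence")
        segs.append((s, e, i))
    segs.sort()
    for (s1, e1, _), (s2, e2, _) in zip(segs, segs[1:]):
        if s2 < e1:
            raise ValueError("overlapping rearrangement segments")
    seg_of = {i: (s, e) for s, e, i in segs}
    for r in rearrs:
        if r.dest is not None:
            for s, e, _ in segs:
                if s < r.dest < e:
                    raise ValueError("rearrangement dest inside a source segment")

    cut = {0, L}
    for s, e, _ in segs:
        cut.update((s, e))
    dest_at: dict[int, list[int]] = {}
    for i, r in enumerate(rearrs):
        if r.dest is not None:
            cut.add(r.dest)
            dest_at.setdefault(r.dest, []).append(i)
    cuts = sorted(cut)

    kind_of_atomic = {}
    for s, e, i in segs:
        kind_of_atomic[(s, e)] = (rearrs[i].kind, i)

    # output pieces: (orient, s, e, paired)
    pieces: list[tuple[str, int, int, bool]] = []

    def emit_dests(p: int) -> None:
        for i in dest_at.get(p, []):
            s, e = seg_of[i]
            pieces.append(("+", s, e, rearrs[i].kind == "translocation"))

    for lo, hi in zip(cuts, cuts[1:]):
        emit_dests(lo)
        kind, _ = kind_of_atomic.get((lo, hi), (None, None))
        if kind == "translocation":
            continue  # moved to its dest
        if kind == "inversion":
            pieces.append(("-", lo, hi, True))
        else:
            pieces.append(("+", lo, hi, True))
    emit_dests(L)

    parts: list[str] = []
    strand = np.ones(a_pos.size, dtype=np.int8)
    new_b = np.full(a_pos.size, -1, dtype=np.int64)
    offset = 0
    for orient, s, e, paired in pieces:
        seg = seq_b0[s:e]
        parts.append(seg if orient == "+" else revcomp(seg))
        if paired:
            sel = (b_pos >= s) & (b_pos < e)
            if orient == "+":
                new_b[sel] = offset + (b_pos[sel] - s)
            else:
                new_b[sel] = offset + (e - 1 - b_pos[sel])
                strand[sel] = -1
        offset += e - s
    keep = new_b >= 0
    return "".join(parts), a_pos[keep], new_b[keep], strand[keep]


def pairs_to_runs(a_pos, b_pos, strand, a_id: str = "synthA", b_id: str = "synthB") -> list[dict]:
    """Compress aligned base pairs into maximal collinear runs."""
    if len(a_pos) == 0:
        return []
    order = np.argsort(a_pos, kind="stable")
    a, b, st = a_pos[order], b_pos[order], strand[order]
    brk = np.ones(len(a), dtype=bool)
    brk[1:] = (a[1:] != a[:-1] + 1) | (st[1:] != st[:-1]) | (b[1:] != b[:-1] + st[:-1])
    starts = np.nonzero(brk)[0]
    ends = np.append(starts[1:], len(a))
    rows = []
    for s, e in zip(starts, ends):
        if st[s] > 0:
            b0, b1 = int(b[s]), int(b[e - 1]) + 1
            sd = "+"
        else:
            b0, b1 = int(b[e - 1]), int(b[s]) + 1
            sd = "-"
        rows.append({
            "a_id": a_id, "a_start": int(a[s]), "a_end": int(a[e - 1]) + 1,
            "b_id": b_id, "b_start": b0, "b_end": b1, "strand": sd,
        })
    return rows


def generate_pair(spec: SynthSpec, out_dir: str | Path | None = None):
    """Generate (seq_a, seq_b, truth runs) for a spec.

    When `out_dir` is given, additionally writes ``a.fa``, ``b.fa`` and
    ``truth.tsv`` there and returns their paths; otherwise returns the
    sequences and truth rows directly.
    """
    rng = np.random.default_rng(spec.rng_seed)
    base = _BASES[rng.integers(0, 4, size=spec.length)].tobytes().decode("ascii")
    if spec.repeat_fraction > 0:
        base = plant_repeats(base, spec.repeat_fraction,
                             rng_seed=int(rng.integers(0, 2**31 - 1)))
    seq_b0, a_pos, b_pos = _mutate(base, spec, rng)
    seq_b, a_pos, b_pos, strand = _apply_rearrangements(
        seq_b0, a_pos, b_pos, spec.rearrangements)
    rows = pairs_to_runs(a_pos, b_pos, strand, spec.a_id, spec.b_id)
    if out_dir is None:
        return base, seq_b, rows
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fa_a = out_dir / "a.fa"
    fa_b = out_dir / "b.fa"
    truth = out_dir / "truth.tsv"
    _write_fasta(fa_a, spec.a_id, base)
    _write_fasta(fa_b, spec.b_id, seq_b)
    from coalign.evaluator import write_pairs_file

    write_pairs_file(rows, truth)
    return fa_a, fa_b, truth


def _write_fasta(path: Path, name: str, seq: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")
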