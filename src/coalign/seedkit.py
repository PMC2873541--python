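"""Spaced-seed patterns, k-mer coding, and per-genome index tables.

A k/w spaced seed examines k of the w positions in a sliding window; a
window's *code* is the quaternary numeral read off the examined positions
(A, C, G, T -> 0, 1, 2, 3), so codes lie in [0, 4**k).  The block-level
aligner consumes four per-genome tables built here: a *seed table* (the
genome-wide occurrence count N_i of each code), an *index table* (which
blocks each code occurs in, with per-block counts), and two *Poisson
tables* (the probability of a code occurring exactly x / at least x times
in one block, under a Poisson model with mean mu_i = N_i / num_blocks).

Masking convention: a window is skipped whenever any examined position is
soft-masked (lowercase) or is not an unambiguous A/C/G/T.  The
nucleotide-level aligner unmasks sequence only in its iterative fill step.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import poisson

__all__ = [
    "SpacedSeed", "GenomeIndex", "BUILTIN_SEEDS",
    "parse_seed_pattern", "encode_window", "build_genome_index",
    "save_index", "load_index",
    "seq_to_arrays", "revcomp", "encode_positions",
    "PatternError", "IndexCompatibilityError", "ConfigurationError",
]

# 64-bit limit on the number of blocks so ordinals fit unsigned shorts.
MAX_BLOCKS = 2 ** 16

# Built-in patterns: the default 11/18 PatternHunter-style seed and the
# 12/19 and 13/20 alternatives of Mak & Benson.
BUILTIN_SEEDS = {
    11: "111*1**1*1**11*111",
    12: "1111*1*1**11**1*111",
    13: "1111*1**11**11*1*111",
}


class PatternError(ValueError):
    """Malformed spaced-seed pattern."""


class IndexCompatibilityError(ValueError):
    """An index file does not match the expected format or seed."""


class ConfigurationError(ValueError):
    """Invalid index-building configuration (e.g. too many blocks)."""


@dataclass(frozen=True)
class SpacedSeed:
    """A k/w spaced-seed pattern.

    Attributes
    ----------
    pattern : str
        Text of '1' (examined) and '*' (ignored) symbols.
    span : int
        Window length w in bp.
    weight : int
        Number k of examined positions.
    offsets : tuple[int, ...]
        0-based examined positions within the window, strictly increasing.
    """

    pattern: str
    span: int
    weight: int
    offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (1 <= self.weight <= self.span):
            raise PatternError(f"weight {self.weight} outside [1, span={self.span}]")


def parse_seed_pattern(pattern: str) -> SpacedSeed:
    """Parse a '1'/'*' text pattern into a :class:`SpacedSeed`."""
    if not pattern:
        raise PatternError("empty seed pattern")
    bad = set(pattern) - {"1", "*"}
    if bad:
        raise PatternError(f"seed pattern may contain only '1' and '*', got {sorted(bad)!r}")
    offsets = tuple(i for i, c in enumerate(pattern) if c == "1")
    return SpacedSeed(pattern=pattern, span=len(pattern), weight=len(offsets), offsets=offsets)


def builtin_seed(k: int) -> SpacedSeed:
    """Return the built-in k-mer spaced seed (k in {11, 12, 13})."""
    try:
        return parse_seed_pattern(BUILTIN_SEEDS[k])
    except KeyError:
        raise ConfigurationError(f"no built-in seed of weight {k}; choose from {sorted(BUILTIN_SEEDS)}")


# ---------------------------------------------------------------------------
# sequence <-> numeric arrays

_CODE_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
    _CODE_LUT[_b + 32] = _i  # lowercase maps to the same base value

_UNMASKED_LUT = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _UNMASKED_LUT[_b] = True

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_RC_TABLE = str.maketrans(
    "ACGTacgtNnRYSWKMBDHVryswkmbdhv",
    "TGCAtgcaNnYRSWMKVHDByrswmkvhdb",
)


def seq_to_arrays(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Map a sequence to (base codes, masked flags).

    Returns ``codes`` (int8; A/C/G/T -> 0..3 case-insensitively, anything
    else -> 4) and ``masked`` (True where the base is lowercase or not an
    unambiguous A/C/G/T).
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw], ~_UNMASKED_LUT[raw]


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case; IUPAC codes complemented."""
    return seq.translate(_RC_TABLE)[::-1]


def encode_positions(
    codes: np.ndarray, masked: np.ndarray, seed: SpacedSeed
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised window coding over every window start of a sequence.

    Returns (window codes, validity).  The first examined position is the
    most significant quaternary digit.  A window is invalid when any
    examined position is masked or ambiguous.
    """
    n = len(codes) - seed.span + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    val = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for off in seed.offsets:
        c = codes[off : off + n]
        ok &= ~masked[off : off + n]
        ok &= c < 4
        val *= 4
        val += np.where(c < 4, c, 0)
    return val, ok


def encode_window(window: str, seed: SpacedSeed) -> int | None:
    """Code of a single window, or None if any examined base is masked.

    The window must have length ``seed.span``.
    """
    if len(window) != seed.span:
        raise ValueError(f"window length {len(window)} != seed span {seed.span}")
    codes, masked = seq_to_arrays(window)
    val, ok = encode_positions(codes, masked, seed)
    return int(val[0]) if ok[0] else None


# ---------------------------------------------------------------------------
# genome index

@dataclass
class GenomeIndex:
    """Seed, index and Poisson tables of one genome (one orientation).

    The seed table is held sparsely as the sorted array ``uniq_codes`` with
    genome-wide counts ``uniq_counts``.  The index table is the triple
    ``(entry_codes, entry_blocks, entry_counts)`` sorted by code then block;
    per-block counts are clipped to ``max_occ + 1``, the clip value marking
    "repeat in this block" (contributes nothing to block similarity).
    Codes with a genome-wide count above ``repeat_cutoff`` are dropped from
    the index table entirely.  Poisson tables are tabulated exactly per
    code class (distinct genome-wide count N): ``pois_tail[cls, x]`` is
    P(occurrences >= x) in one block for x in 0..max_occ+1 under
    mu = N / num_blocks.
    """

    seed: SpacedSeed
    block_size: int
    num_blocks: int
    genome_length: int
    repeat_cutoff: int
    max_occ: int
    uniq_codes: np.ndarray
    uniq_counts: np.ndarray
    entry_codes: np.ndarray
    entry_blocks: np.ndarray
    entry_counts: np.ndarray
    # per-code-class Poisson tables (derived, rebuilt on load)
    class_counts: np.ndarray = field(default=None, repr=False)
    pois_tail: np.ndarray = field(default=None, repr=False)
    neg_log_tail: np.ndarray = field(default=None, repr=False)
    entry_class: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.pois_tail is None:
            self._build_poisson()

    def _build_poisson(self) -> None:
        # class 0 (mu = 0) covers codes absent from the genome
        classes = np.unique(np.concatenate(([0], self.uniq_counts)))
        mu = classes / self.num_blocks
        xs = np.arange(self.max_occ + 2)
        # P(X >= x) = sf(x - 1)
        tail = poisson.sf(xs[None, :] - 1, mu[:, None])
        self.class_counts = classes
        self.pois_tail = tail
        with np.errstate(divide="ignore"):
            self.neg_log_tail = -np.log(tail)
        # class index of every index-table entry, for fast score lookups
        code_cls = np.searchsorted(classes, self.uniq_counts)
        pos = np.searchsorted(self.uniq_codes, self.entry_codes)
        self.entry_class = code_cls[pos].astype(np.int32)

    # -- seed table -----------------------------------------------------
    def seed_count(self, code: int) -> int:
        """Genome-wide occurrence count N_i of a code."""
        i = np.searchsorted(self.uniq_codes, code)
        if i < len(self.uniq_codes) and self.uniq_codes[i] == code:
            return int(self.uniq_counts[i])
        return 0

    @property
    def seed_counts(self) -> dict[int, int]:
        """Seed table as a plain mapping code -> N_i (test/debug view)."""
        return dict(zip(self.uniq_codes.tolist(), self.uniq_counts.tolist()))

    @property
    def block_lists(self) -> dict[int, list[int]]:
        """Index table as mapping code -> ordered block ordinals."""
        out: dict[int, list[int]] = {}
        for c, b in zip(self.entry_codes.tolist(), self.entry_blocks.tolist()):
            out.setdefault(c, []).append(b)
        return out

    # -- Poisson tables -------------------------------------------------
    def _class_of(self, code: int) -> int:
        n = self.seed_count(code)
        return int(np.searchsorted(self.class_counts, n))

    def poisson_ptail(self, code: int, x: int) -> float:
        """P(code occurs >= x times in one block); tabulated x <= max_occ+1."""
        if x <= 0:
            return 1.0
        x = min(x, self.max_occ + 1)
        return float(self.pois_tail[self._class_of(code), x])

    def poisson_p(self, code: int, x: int) -> float:
        """P(code occurs exactly x times in one block), x <= max_occ."""
        return self.poisson_ptail(code, x) - self.poisson_ptail(code, x + 1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeIndex):
            return NotImplemented
        return (
            self.seed == other.seed
            and self.block_size == other.block_size
            and self.num_blocks == other.num_blocks
            and self.genome_length == other.genome_length
            and self.repeat_cutoff == other.repeat_cutoff
            and self.max_occ == other.max_occ
            and np.array_equal(self.uniq_codes, other.uniq_codes)
            and np.array_equal(self.uniq_counts, other.uniq_counts)
            and np.array_equal(self.entry_codes, other.entry_codes)
            and np.array_equal(self.entry_blocks, other.entry_blocks)
            and np.array_equal(self.entry_counts, other.entry_counts)
        )


def build_genome_index(
    genome: str | tuple[np.ndarray, np.ndarray],
    seed: SpacedSeed,
    block_size: int = 10_000,
    repeat_cutoff: int = 1024,
    max_occ: int = 3,
) -> GenomeIndex:
    """Build the four tables of one genome (one orientation).

    ``genome`` is a sequence string (case carries soft-masking) or a
    pre-computed ``(codes, masked)`` pair from :func:`seq_to_arrays`.
    Blocks have fixed length ``block_size``; the last may be shorter.
    """
    if isinstance(genome, str):
        codes, masked = seq_to_arrays(genome)
    else:
        codes, masked = genome
    length = len(codes)
    num_blocks = max(1, -(-length // block_size))
    if num_blocks >= MAX_BLOCKS:
        raise ConfigurationError(
            f"{num_blocks} blocks >= 2**16; raise block_size (got {block_size})"
        )
    if block_size >= MAX_BLOCKS:
        warnings.warn(
            f"block_size {block_size} >= 2**16 exceeds the unsigned-short "
            "storage convention; proceeding anyway", stacklevel=2,
        )

    win, ok = encode_positions(codes, masked, seed)
    valid = win[ok]
    if valid.size:
        uniq_codes, uniq_counts = np.unique(valid, return_counts=True)
        blocks = (np.nonzero(ok)[0] // block_size).astype(np.int64)
        key = valid * num_blocks + blocks
        ukey, kcount = np.unique(key, return_counts=True)
        entry_codes = ukey // num_blocks
        entry_blocks = (ukey % num_blocks).astype(np.uint16)
        entry_counts = np.minimum(kcount, max_occ + 1).astype(np.uint8)
        # drop genome-wide repeats from the index table
        pos = np.searchsorted(uniq_codes, entry_codes)
        keep = uniq_counts[pos] <= repeat_cutoff
        entry_codes = entry_codes[keep]
        entry_blocks = entry_blocks[keep]
        entry_counts = entry_counts[keep]
    else:
        uniq_codes = np.empty(0, dtype=np.int64)
        uniq_counts = np.empty(0, dtype=np.int64)
        entry_codes = np.empty(0, dtype=np.int64)
        entry_blocks = np.empty(0, dtype=np.uint16)
        entry_counts = np.empty(0, dtype=np.uint8)

    return GenomeIndex(
        seed=seed,
        block_size=block_size,
        num_blocks=num_blocks,
        genome_length=length,
        repeat_cutoff=repeat_cutoff,
        max_occ=max_occ,
        uniq_codes=uniq_codes,
        uniq_counts=uniq_counts.astype(np.int64),
        entry_codes=entry_codes,
        entry_blocks=entry_blocks,
        entry_counts=entry_counts,
    )


# ---------------------------------------------------------------------------
# binary persistence: little-endian, magic string, version byte, embedded
# seed pattern -- fail-fast compatibility checks at load time.

_MAGIC = b"COALNIDX"
_VERSION = 1


def save_index(index: GenomeIndex, path: str | Path) -> None:
    """Write an index to a little-endian binary file."""
    path = Path(path)
    pat = index.seed.pattern.encode("ascii")
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<B", _VERSION))
        fh.write(struct.pack("<H", len(pat)))
        fh.write(pat)
        fh.write(struct.pack(
            "<qqqqq",
            index.block_size, index.num_blocks, index.genome_length,
            index.repeat_cutoff, index.max_occ,
        ))
        fh.write(struct.pack("<qq", len(index.uniq_codes), len(index.entry_codes)))
        index.uniq_codes.astype("<i8").tofile(fh)
        index.uniq_counts.astype("<i8").tofile(fh)
        index.entry_codes.astype("<i8").tofile(fh)
        index.entry_blocks.astype("<u2").tofile(fh)
        index.entry_counts.astype("<u1").tofile(fh)


def load_index(path: str | Path, expected_seed: SpacedSeed | None = None) -> GenomeIndex:
    """Read an index file; verify magic, version and (optionally) the seed."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise IndexCompatibilityError(f"{path}: not an index file (bad magic)")
        (version,) = struct.unpack("<B", fh.read(1))
        if version != _VERSION:
            raise IndexCompatibilityError(f"{path}: unsupported index version {version}")
        (patlen,) = struct.unpack("<H", fh.read(2))
        pattern = fh.read(patlen).decode("ascii")
        seed = parse_seed_pattern(pattern)
        if expected_seed is not None and seed != expected_seed:
            raise IndexCompatibilityError(
                f"{path}: built with seed {pattern!r}, expected {expected_seed.pattern!r}"
            )
        block_size, num_blocks, genome_length, repeat_cutoff, max_occ = struct.unpack(
            "<qqqqq", fh.read(40)
        )
        n_uniq, n_entry = struct.unpack("<qq", fh.read(16))
        uniq_codes = np.fromfile(fh, dtype="<i8", count=n_uniq)
        uniq_counts = np.fromfile(fh, dtype="<i8", count=n_uniq)
        entry_codes = np.fromfile(fh, dtype="<i8", count=n_entry)
        entry_blocks = np.fromfile(fh, dtype="<u2", count=n_entry)
        entry_counts = np.fromfile(fh, dtype="<u1", count=n_entry)
    return GenomeIndex(
        seed=seed,
        block_size=int(block_size),
        num_blocks=int(num_blocks),
        genome_length=int(genome_length),
        repeat_cutoff=int(repeat_cutoff),
        max_occ=int(max_occ),
        uniq_codes=uniq_codes.astype(np.int64),
        uniq_counts=uniq_counts.astype(np.int64),
        entry_codes=entry_codes.astype(np.int64),
        entry_blocks=entry_blocks.astype(np.uint16),
        entry_counts=entry_counts.astype(np.uint8),
    )
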