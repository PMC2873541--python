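"""Base-level sensitivity/specificity against a reference alignment.

The unit of truth is the aligned base *pair*: a prediction gets credit for
pairing base a of genome A with base b of genome B only when the reference
pairs exactly those two coordinates (interval overlap is not enough).
With TP/FP/FN counted over aligned base pairs,

    Sn = TP / (TP + FN)        Sp = TP / (TP + FP).

For chromosome-vs-genome protocols where biological specificity is not
directly measurable, the ratio of restricted-run to all-run total HSP
length serves as a specificity proxy (``sp_ratio``).

Aligned-pair collections are exchanged as "runs": rows
(a_id, a_start, a_end, b_id, b_start, b_end, strand), 0-based half-open,
collinear within a row.  A '+' row pairs a_start+i with b_start+i; a '-'
row pairs a_start+i with b_end-1-i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from coalign.nuc_aligner import Fragment

__all__ = [
    "EvalResult", "compute_sn_sp", "sp_ratio", "extract_mismatches",
    "MismatchSummary", "runs_to_pairs", "fragment_pairs",
    "read_pairs_file", "write_pairs_file",
]

_ENC = 1 << 31  # coordinate packing base; positions must stay below this


@dataclass
class EvalResult:
    """Base-pair level confusion counts and rates."""

    tp: int
    fp: int
    fn: int
    sn: float
    sp: float
    total_hsp_len: int = 0


def _encode(a_pos: np.ndarray, b_pos: np.ndarray) -> np.ndarray:
    return np.asarray(a_pos, dtype=np.int64) * _ENC + np.asarray(b_pos, dtype=np.int64)


def runs_to_pairs(runs) -> np.ndarray:
    """Expand (a_start, a_end, b_start, b_end, strand) runs to packed pairs.

    Accepts iterables of 5-tuples or of dict rows from the pairs file.
    """
    chunks = []
    for r in runs:
        if isinstance(r, dict):
            a0, a1, b0, b1, strand = r["a_start"], r["a_end"], r["b_start"], r["b_end"], r["strand"]
        else:
            a0, a1, b0, b1, strand = r
        n = a1 - a0
        if n <= 0:
            continue
        a = np.arange(a0, a1, dtype=np.int64)
        if strand == "+":
            b = np.arange(b0, b0 + n, dtype=np.int64)
        else:
            b = np.arange(b1 - 1, b1 - 1 - n, -1, dtype=np.int64)
        chunks.append(_encode(a, b))
    if not chunks:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(chunks))


def fragment_pairs(fragments: list[Fragment], len_b: int | None = None) -> np.ndarray:
    """Packed aligned base pairs of a fragment list (gap records skipped).

    Fragment b coordinates are on the forward strand; for '-' fragments
    the cigar walks B from b_end-1 downward.
    """
    chunks = []
    for f in fragments:
        if f.cigar is None:
            continue
        ai = f.a_start
        bi = f.b_start if f.strand == "+" else f.b_end - 1
        step = 1 if f.strand == "+" else -1
        for op, ln in f.cigar:
            if op == "M":
                a = np.arange(ai, ai + ln, dtype=np.int64)
                b = np.arange(bi, bi + step * ln, step, dtype=np.int64)
                chunks.append(_encode(a, b))
                ai += ln
                bi += step * ln
            elif op == "D":
                ai += ln
            else:
                bi += step * ln
    if not chunks:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(chunks))


def compute_sn_sp(predicted, reference) -> EvalResult:
    """Sensitivity/specificity over aligned base pairs.

    Inputs are run collections (see module docstring) or already-packed
    pair arrays from :func:`runs_to_pairs` / :func:`fragment_pairs`.
    """
    pred = predicted if isinstance(predicted, np.ndarray) else runs_to_pairs(predicted)
    ref = reference if isinstance(reference, np.ndarray) else runs_to_pairs(reference)
    tp = int(np.intersect1d(pred, ref, assume_unique=True).size)
    fp = int(pred.size) - tp
    fn = int(ref.size) - tp
    if ref.size == 0:
        warnings.warn("empty reference: sensitivity undefined", stacklevel=2)
        sn = float("nan")
    else:
        sn = tp / (tp + fn)
    if pred.size == 0:
        sp = float("nan")
    else:
        sp = tp / (tp + fp)
    return EvalResult(tp=tp, fp=fp, fn=fn, sn=sn, sp=sp, total_hsp_len=int(pred.size))


def sp_ratio(len_restricted: int, len_all: int) -> float:
    """Specificity proxy: restricted-run HSP length over all-run length."""
    if len_all == 0:
        raise ValueError("len_all is 0: ratio undefined")
    r = len_restricted / len_all
    if r > 1.0:
        warnings.warn(f"sp_ratio {r:.4f} > 1: restricted run aligned more than the full run",
                      stacklevel=2)
    return r


@dataclass
class MismatchSummary:
    """Mismatch listing from finished alignments.

    `records` rows are (a_pos, b_pos, base_a, base_b, masked_flag) for
    substitutions between unambiguous bases; `n_snps` counts them;
    `n_with_n` tallies aligned mismatching pairs involving N separately.
    """

    records: list[tuple[int, int, str, str, bool]]
    n_snps: int
    n_masked: int
    n_with_n: int


def extract_mismatches(
    fragments: list[Fragment], seq_a: str, seq_b: str
) -> MismatchSummary:
    """List every aligned mismatching base pair of an alignment.

    Comparison is case-insensitive; the masked flag records whether either
    base was soft-masked (lowercase) in the input.  Pairs involving N are
    excluded from the SNP records and tallied separately.
    """
    records: list[tuple[int, int, str, str, bool]] = []
    n_with_n = 0
    n_masked = 0
    for f in fragments:
        if f.cigar is None:
            continue
        ai = f.a_start
        bi = f.b_start if f.strand == "+" else f.b_end - 1
        step = 1 if f.strand == "+" else -1
        for op, ln in f.cigar:
            if op == "M":
                for k in range(ln):
                    ca = seq_a[ai + k]
                    cb = seq_b[bi + step * k]
                    ua, ub = ca.upper(), cb.upper()
                    if f.strand == "-":
                        ub = {"A": "T", "C": "G", "G": "C", "T": "A"}.get(ub, ub)
                    if ua == ub:
                        continue
                    if ua not in "ACGT" or ub not in "ACGT":
                        n_with_n += 1
                        continue
                    masked = ca.islower() or cb.islower()
                    if masked:
                        n_masked += 1
                    records.append((ai + k, bi + step * k, ca, cb, masked))
                ai += ln
                bi += step * ln
            elif op == "D":
                ai += ln
            else:
                bi += step * ln
    return MismatchSummary(records=records, n_snps=len(records),
                           n_masked=n_masked, n_with_n=n_with_n)


# ---------------------------------------------------------------------------
# pairs file IO: 7-column TSV, 0-based half-open, collinear rows

_COLUMNS = ("a_id", "a_start", "a_end", "b_id", "b_start", "b_end", "strand")


def write_pairs_file(rows: list[dict], path) -> None:
    """Write reference/truth runs as tab-separated text."""
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in _COLUMNS) + "\n")


def read_pairs_file(path) -> list[dict]:
    """Read a pairs file written by :func:`write_pairs_file`."""
    rows: list[dict] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _COLUMNS:
            raise ValueError(f"unexpected pairs-file header: {header}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append({
                "a_id": parts[0], "a_start": int(parts[1]), "a_end": int(parts[2]),
                "b_id": parts[3], "b_start": int(parts[4]), "b_end": int(parts[5]),
                "strand": parts[6],
            })
    return rows
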