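"""Pairwise divergence of homologous chromosome copies.

Two homologous copies are aligned by a desk-scale collinear anchor chain:
k-mers (default k=21) occurring exactly once in each sequence are matched,
chained by longest increasing subsequence on both coordinates, and merged
into maximal exact-match blocks. The gaps between blocks are then
classified by size:

* equal-length gaps: position-by-position comparison emits SNPs, unless the
  block is longer than the PAV threshold and its identity falls below the
  homology cutoff, in which case it is presence-absence variation of
  homologous sequence rather than point divergence;
* unequal-length gaps: a single net-length event — an InDel when the length
  difference is 1-200 bp, a PAV when it exceeds 200 bp.

Inversions and translocations are not typed; unchainable diverged blocks
fall into PAV via the identity rule. Window summaries count SNPs/InDels and
sum PAV base pairs on a fixed 500-kb grid anchored at position 0, events
attributed to the window containing their reference start.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from ._kmers import encode, kmer_hashes
from .genome_io import Genome, GenomicInterval

INDEL_MAX_BP = 200  # events of 1-200 bp are InDels, > 200 bp are PAVs
PAV_IDENTITY_PCT = 75.0


class VariantKind(str, Enum):
    SNP = "SNP"
    INDEL = "INDEL"
    PAV = "PAV"


@dataclass(frozen=True)
class VariantCall:
    """One classified difference between a reference and an alternate copy.

    ``ref_seq``/``alt_seq`` carry the event's sequence content so a call set
    can be replayed onto the reference to reconstruct the alternate copy.
    """

    ref_copy: str
    alt_copy: str
    ref_interval: GenomicInterval | None  # None for pure insertions (empty ref span)
    alt_interval: GenomicInterval | None
    kind: VariantKind
    length_bp: int
    ref_seq: str
    alt_seq: str
    ref_start: int  # always defined, even for zero-length ref spans
    alt_start: int

    @property
    def ref_span(self) -> tuple[int, int]:
        return (self.ref_start, self.ref_start + len(self.ref_seq))


@dataclass(frozen=True)
class AnchorBlock:
    """A maximal exact-match run between the two sequences."""

    ref_start: int
    alt_start: int
    length: int

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length

    @property
    def alt_end(self) -> int:
        return self.alt_start + self.length


def _unique_kmer_positions(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    h, valid = kmer_hashes(codes, k)
    if h.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    uq, inv, cnt = np.unique(h, return_inverse=True, return_counts=True)
    unique = valid & (cnt[inv] == 1)
    pos = np.flatnonzero(unique)
    return pos.astype(np.int64), h[pos]


def _lis_indices(values: np.ndarray) -> np.ndarray:
    """Indices of a longest strictly increasing subsequence (patience sorting)."""
    n = values.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    vals = values.tolist()
    tails: list[int] = []
    tails_idx: list[int] = []
    prev = np.full(n, -1, dtype=np.int64)
    for i, v in enumerate(vals):
        j = bisect.bisect_left(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_idx.append(i)
        else:
            tails[j] = v
            tails_idx[j] = i
        if j > 0:
            prev[i] = tails_idx[j - 1]
    out = []
    i = tails_idx[-1]
    while i != -1:
        out.append(i)
        i = prev[i]
    return np.array(out[::-1], dtype=np.int64)


def anchor_align(ref_seq: str, alt_seq: str, k: int = 21) -> list[AnchorBlock]:
    """Chain of collinear exact-match blocks between two sequences.

    Anchors are k-mers unique in *both* sequences; the maximal collinear
    chain is the longest increasing subsequence over both coordinates, and
    consecutive same-diagonal anchors merge into blocks. No inversions are
    recovered: whatever cannot be chained becomes inter-block gap.
    """
    rp, rh = _unique_kmer_positions(encode(ref_seq), k)
    ap, ah = _unique_kmer_positions(encode(alt_seq), k)
    if rp.size == 0 or ap.size == 0:
        return []
    r_order = np.argsort(rh, kind="stable")
    a_order = np.argsort(ah, kind="stable")
    common, ir, ia = np.intersect1d(
        rh[r_order], ah[a_order], assume_unique=True, return_indices=True
    )
    if common.size == 0:
        return []
    R = rp[r_order[ir]]
    A = ap[a_order[ia]]
    order = np.argsort(R, kind="stable")
    R, A = R[order], A[order]
    # fast path: anchors already collinear
    if not np.all(np.diff(A) > 0):
        keep = _lis_indices(A)
        R, A = R[keep], A[keep]
    if R.size == 0:
        return []
    # merge same-diagonal consecutive anchors into blocks (vectorized)
    diag = A - R
    brk = np.flatnonzero((np.diff(R) != 1) | (np.diff(diag) != 0))
    starts = np.concatenate(([0], brk + 1))
    ends = np.concatenate((brk, [R.size - 1]))
    blocks: list[AnchorBlock] = []
    for s, e in zip(starts.tolist(), ends.tolist()):
        b = AnchorBlock(int(R[s]), int(A[s]), int(R[e] - R[s]) + k)
        if blocks:
            p = blocks[-1]
            ov = max(p.ref_end - b.ref_start, p.alt_end - b.alt_start, 0)
            if ov >= b.length:
                continue
            if ov:
                b = AnchorBlock(b.ref_start + ov, b.alt_start + ov, b.length - ov)
        blocks.append(b)
    return blocks


def _identity_pct(a: np.ndarray, b: np.ndarray) -> float:
    return 100.0 * float((a == b).sum()) / a.size


def classify_gaps(
    chain: list[AnchorBlock],
    ref_seq: str,
    alt_seq: str,
    ref_copy: str = "ref",
    alt_copy: str = "alt",
    indel_max: int = INDEL_MAX_BP,
    pav_identity_pct: float = PAV_IDENTITY_PCT,
) -> list[VariantCall]:
    """Classify every inter-anchor gap into SNP / InDel / PAV calls.

    The chain must be collinear (as produced by :func:`anchor_align`). An
    empty chain makes the whole pair one gap. Boundary semantics: a net
    length difference of exactly ``indel_max`` (200) is an InDel; one more
    base pair makes it a PAV.
    """
    rc = encode(ref_seq)
    ac = encode(alt_seq)
    calls: list[VariantCall] = []

    def interval(copy_id: str, a: int, b: int) -> GenomicInterval | None:
        return GenomicInterval(copy_id, a, b) if b > a else None

    def emit_gap(r0: int, r1: int, a0: int, a1: int) -> None:
        rl, al = r1 - r0, a1 - a0
        if rl == 0 and al == 0:
            return
        if rl == al:
            seg_r, seg_a = rc[r0:r1], ac[a0:a1]
            if rl > indel_max and _identity_pct(seg_r, seg_a) < pav_identity_pct:
                calls.append(
                    VariantCall(
                        ref_copy,
                        alt_copy,
                        interval(ref_copy, r0, r1),
                        interval(alt_copy, a0, a1),
                        VariantKind.PAV,
                        rl,
                        ref_seq[r0:r1],
                        alt_seq[a0:a1],
                        r0,
                        a0,
                    )
                )
                return
            for m in np.flatnonzero(seg_r != seg_a).tolist():
                calls.append(
                    VariantCall(
                        ref_copy,
                        alt_copy,
                        interval(ref_copy, r0 + m, r0 + m + 1),
                        interval(alt_copy, a0 + m, a0 + m + 1),
                        VariantKind.SNP,
                        1,
                        ref_seq[r0 + m],
                        alt_seq[a0 + m],
                        r0 + m,
                        a0 + m,
                    )
                )
            return
        d = abs(rl - al)
        kind = VariantKind.INDEL if d <= indel_max else VariantKind.PAV
        calls.append(
            VariantCall(
                ref_copy,
                alt_copy,
                interval(ref_copy, r0, r1),
                interval(alt_copy, a0, a1),
                kind,
                d,
                ref_seq[r0:r1],
                alt_seq[a0:a1],
                r0,
                a0,
            )
        )

    pr = pa = 0
    for blk in chain:
        emit_gap(pr, blk.ref_start, pa, blk.alt_start)
        pr, pa = blk.ref_end, blk.alt_end
    emit_gap(pr, len(ref_seq), pa, len(alt_seq))
    return calls


def compare_copies(
    genome: Genome, ref_copy: str, alt_copy: str, k: int = 21
) -> list[VariantCall]:
    """Align two copies and return the classified variant calls."""
    ref = genome.copies[ref_copy]
    alt = genome.copies[alt_copy]
    chain = anchor_align(ref, alt, k=k)
    return classify_gaps(chain, ref, alt, ref_copy=ref_copy, alt_copy=alt_copy)


def apply_calls(ref_seq: str, calls: list[VariantCall]) -> str:
    """Replay a call set onto the reference, reconstructing the alternate copy.

    Valid for the output of :func:`classify_gaps` on one pair (calls cover
    every difference; regions between calls are identical in both copies).
    """
    ordered = sorted(calls, key=lambda c: (c.ref_start, c.alt_start))
    parts: list[str] = []
    pos = 0
    for c in ordered:
        a, b = c.ref_span
        if a < pos:
            raise ValueError("overlapping calls cannot be replayed")
        parts.append(ref_seq[pos:a])
        parts.append(c.alt_seq)
        pos = b
    parts.append(ref_seq[pos:])
    return "".join(parts)


def window_summaries(
    calls: list[VariantCall], ref_length: int, window: int = 500_000
) -> pd.DataFrame:
    """SNP/InDel counts and PAV base pairs on a fixed window grid.

    Windows are non-overlapping, anchored at 0; the last window may be
    short. Events spanning a boundary are attributed to the window holding
    their reference start.
    """
    n_win = max(1, -(-ref_length // window))
    snp = np.zeros(n_win, dtype=int)
    indel = np.zeros(n_win, dtype=int)
    pav = np.zeros(n_win, dtype=int)
    for c in calls:
        w = min(c.ref_start // window, n_win - 1)
        if c.kind is VariantKind.SNP:
            snp[w] += 1
        elif c.kind is VariantKind.INDEL:
            indel[w] += 1
        else:
            pav[w] += c.length_bp
    return pd.DataFrame(
        {
            "window_start": np.arange(n_win) * window,
            "window_stop": np.minimum((np.arange(n_win) + 1) * window, ref_length),
            "snp_count": snp,
            "indel_count": indel,
            "pav_bp": pav,
        }
    )


def pav_burden_rank(genome: Genome, k: int = 21) -> pd.DataFrame:
    """Total PAV base pairs per homolog copy pair, ranked descending.

    Each chromosome's first listed copy serves as the reference (the "A"
    copy) and is compared against every other copy of its group. The
    ordering is deterministic: by descending PAV burden, then chromosome,
    then copy pair.
    """
    rows = []
    for chrom in sorted(genome.homolog_groups):
        members = genome.homolog_groups[chrom]
        if len(members) < 2:
            raise ValueError(f"homolog group {chrom!r} has fewer than 2 copies")
        ref = members[0]
        for alt in members[1:]:
            calls = compare_copies(genome, ref, alt, k=k)
            pav_bp = sum(c.length_bp for c in calls if c.kind is VariantKind.PAV)
            rows.append(
                {"chromosome": chrom, "ref_copy": ref, "alt_copy": alt, "pav_bp": pav_bp}
            )
    df = pd.DataFrame(rows).sort_values(
        ["pav_bp", "chromosome", "alt_copy"], ascending=[False, True, True]
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def calls_table(calls: list[VariantCall]) -> pd.DataFrame:
    """VCF-like tabular view (1-based positions on the reference copy)."""
    rows = []
    for c in sorted(calls, key=lambda c: (c.ref_copy, c.ref_start, c.alt_start)):
        rows.append(
            {
                "CHROM_ref": c.ref_copy,
                "POS1based": c.ref_start + 1,
                "kind": c.kind.value,
                "ref_len": len(c.ref_seq),
                "alt_len": len(c.alt_seq),
                "length_bp": c.length_bp,
            }
        )
    return pd.DataFrame(rows)
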