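"""Independent reference computations used only by the test suite.

These deliberately avoid the package's implementation paths: specificity is
re-derived with one-hot cross-correlation (match counting as a sum of
per-channel convolutions) and pure-Python k-mer tallies over string slices;
thinning and coloring are checked by exhaustive enumeration.
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _onehot(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.zeros((4, len(seq)), dtype=np.float64)
    for i, b in enumerate(b"ACGT"):
        out[i] = arr == b
    return out


def max_identity_matches(genome_seq: str, oligo: str) -> int:
    """Best ungapped match count of the oligo at any offset (one strand)."""
    if len(genome_seq) < len(oligo):
        return 0
    g = _onehot(genome_seq)
    o = _onehot(oligo)
    total = np.zeros(len(genome_seq) - len(oligo) + 1)
    for c in range(4):
        total += np.correlate(g[c], o[c], mode="valid")
    return int(round(total.max()))


def oracle_specificity_labels(genome, candidates, policy) -> list[str]:
    """Exhaustive all-offset, both-strand screening labels."""
    k = policy.kmer_len
    counts: dict[str, int] = {}
    for seq in genome.copies.values():
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" not in km:
                counts[km] = counts.get(km, 0) + 1
    cutoff = policy.max_kmer_genome_count
    if cutoff is None:
        cutoff = max(len(g) for g in genome.homolog_groups.values()) + 1
    labels = []
    for cand in candidates:
        oligo = cand.sequence
        l = len(oligo)
        repetitive = False
        for i in range(l - k + 1):
            km = oligo[i : i + k]
            if "N" in km:
                continue
            if counts.get(km, 0) + counts.get(revcomp(km), 0) > cutoff:
                repetitive = True
                break
        if repetitive:
            labels.append("REPETITIVE")
            continue
        need = math.ceil(l * policy.homology_pct / 100.0 - 1e-9)
        hit = False
        for cid, seq in genome.copies.items():
            if cid in policy.allowed_targets:
                continue
            if (
                max_identity_matches(seq, oligo) >= need
                or max_identity_matches(seq, revcomp(oligo)) >= need
            ):
                hit = True
                break
        labels.append("CROSS_HYBRIDIZING" if hit else "SINGLE_COPY")
    return labels


def brute_best_max_gap(starts: list[int], k: int, min_gap: int) -> int | None:
    """Smallest achievable max inter-pick gap over all order-respecting subsets."""
    best = None
    for combo in combinations(range(len(starts)), k):
        picks = [starts[i] for i in combo]
        if any(b - a < min_gap for a, b in zip(picks, picks[1:])):
            continue
        gap = max((b - a) for a, b in zip(picks, picks[1:])) if k > 1 else 0
        if best is None or gap < best:
            best = gap
    return best


def enumerate_valid_colorings(mark_counts: dict[str, int], n_colors: int = 2):
    """All globally valid color assignments, by brute force over every choice.

    A coloring is valid when no two chromosomes have equal signatures, where
    a signature here is the color tuple tagged with its mark count and
    compared up to reversal (terminal-symmetric layouts).
    """
    chroms = sorted(mark_counts)
    spaces = [list(product(range(n_colors), repeat=mark_counts[c])) for c in chroms]
    valid = []
    for combo in product(*spaces):
        sigs = [(mark_counts[c], combo[i]) for i, c in enumerate(chroms)]
        ok = True
        for i in range(len(sigs)):
            for j in range(i + 1, len(sigs)):
                (ma, ca), (mb, cb) = sigs[i], sigs[j]
                if ma == mb and (ca == cb or ca == cb[::-1]):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            valid.append(dict(zip(chroms, combo)))
    return valid
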