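"""Candidate oligo generation and single-copy specificity screening.

The probe substrate is a tiling of a design region into short oligos
(default 45 bp at a 5-bp step). Each candidate is then screened against the
whole genome, at homolog-group granularity:

* ``REPETITIVE`` — a constituent k-mer (default k=17) occurs more often in
  the genome (both strands) than the repeat cutoff. The default cutoff is
  ploidy+1, which permits the expected one-hit-per-homolog-copy in an
  autopolyploid plus one spare.
* ``CROSS_HYBRIDIZING`` — an ungapped full-length alignment with identity at
  or above the homology threshold (default 75%) exists on some copy outside
  the oligo's own homolog group, on either strand.
* ``SINGLE_COPY`` — neither of the above. Hits on the oligo's own homolog
  copies never disqualify: a chromosome-specific FISH probe is expected to
  light up every homologous copy.

The cross-hybridization test is an exact scan: every genomic offset on every
disallowed copy is evaluated on both strands with vectorized window
comparisons, so the labels are reproducible and independently checkable by
brute force. Gapped cross-hybridization is deliberately out of scope.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from enum import Enum
from itertools import groupby
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._kmers import encode, kmer_hashes, revcomp_codes
from .genome_io import Genome, GenomicInterval


class Specificity(Enum):
    UNTESTED = "UNTESTED"
    SINGLE_COPY = "SINGLE_COPY"
    REPETITIVE = "REPETITIVE"
    CROSS_HYBRIDIZING = "CROSS_HYBRIDIZING"


@dataclass
class OligoCandidate:
    """One tiled oligo window with its genomic locus and screening status."""

    sequence: str
    locus: GenomicInterval
    gc_fraction: float
    passes_composition: bool
    specificity: Specificity = Specificity.UNTESTED

    def __post_init__(self) -> None:
        if len(self.sequence) != self.locus.length:
            raise ValueError("oligo sequence length does not match its locus")


@dataclass(frozen=True)
class CompositionPolicy:
    """Composition filters applied at tiling time.

    Defaults are common oligo-probe practice: GC within [0.30, 0.70], no
    homopolymer run of 8 or more, and no N anywhere in the window.
    """

    gc_min: float = 0.30
    gc_max: float = 0.70
    max_homopolymer_run: int = 7


@dataclass
class SpecificityPolicy:
    """Parameters of the single-copy screen.

    ``allowed_targets`` is the set of copies where hits are permitted —
    normally the oligo's own homolog group. ``max_kmer_genome_count`` of
    ``None`` resolves to (largest homolog group size) + 1 at screening time.
    """

    homology_pct: float = 75.0
    allowed_targets: frozenset = frozenset()
    kmer_len: int = 17
    max_kmer_genome_count: int | None = None

    def __post_init__(self) -> None:
        if not (50.0 <= self.homology_pct <= 100.0):
            raise ValueError("homology_pct must lie in [50, 100]")
        self.allowed_targets = frozenset(self.allowed_targets)


def policy_for(genome: Genome, chromosome_id: str, **kwargs) -> SpecificityPolicy:
    """Specificity policy whose allowed targets are one chromosome's homolog group."""
    return SpecificityPolicy(
        allowed_targets=frozenset(genome.homolog_groups[chromosome_id]), **kwargs
    )


class GenomeIndex:
    """Encoded copies, genome-wide k-mer counts and cached window views.

    Built once per genome and shared across screening calls; the k-mer table
    counts forward-strand occurrences over all copies, and both-strand counts
    are obtained by also looking up the reverse-complement hash.
    """

    def __init__(self, genome: Genome, kmer_len: int = 17):
        self.genome = genome
        self.kmer_len = kmer_len
        self.codes = {cid: encode(seq) for cid, seq in genome.copies.items()}
        counts: dict[int, int] = {}
        for codes in self.codes.values():
            h, valid = kmer_hashes(codes, kmer_len)
            if h.size == 0:
                continue
            uq, c = np.unique(h[valid], return_counts=True)
            for hh, cc in zip(uq.tolist(), c.tolist()):
                counts[hh] = counts.get(hh, 0) + cc
        self._kmer_counts = counts
        self._window_cache: dict[tuple[str, int], np.ndarray] = {}

    @property
    def default_repeat_cutoff(self) -> int:
        return max(len(g) for g in self.genome.homolog_groups.values()) + 1

    def both_strand_kmer_counts(self, oligo_codes: np.ndarray) -> np.ndarray:
        """Genome-wide both-strand count for every k-mer of an oligo."""
        k = self.kmer_len
        hf, vf = kmer_hashes(oligo_codes, k)
        hr, vr = kmer_hashes(revcomp_codes(oligo_codes), k)
        hr = hr[::-1]
        vr = vr[::-1]
        get = self._kmer_counts.get
        out = np.zeros(hf.size, dtype=np.int64)
        for i in range(hf.size):
            n = 0
            if vf[i]:
                n += get(int(hf[i]), 0)
            if vr[i]:
                n += get(int(hr[i]), 0)
            out[i] = n
        return out

    def windows(self, copy_id: str, l: int) -> np.ndarray:
        key = (copy_id, l)
        view = self._window_cache.get(key)
        if view is None:
            codes = self.codes[copy_id]
            if codes.size < l:
                view = np.empty((0, l), dtype=np.uint8)
            else:
                view = sliding_window_view(codes, l)
            self._window_cache[key] = view
        return view

    def windows_onehot(self, copy_id: str, l: int) -> np.ndarray:
        """One-hot window matrix (W, 4l) float32; N contributes no channel."""
        key = ("onehot", copy_id, l)
        mat = self._window_cache.get(key)
        if mat is None:
            win = self.windows(copy_id, l)
            mat = np.zeros((win.shape[0], 4 * l), dtype=np.float32)
            for b in range(4):
                mat[:, b * l : (b + 1) * l] = win == b
            self._window_cache[key] = mat
        return mat


def gc_fraction(sequence: str) -> float:
    if not sequence:
        return 0.0
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def _max_run(sequence: str) -> int:
    return max((len(list(g)) for _, g in groupby(sequence)), default=0)


def tile_candidates(
    genome: Genome,
    chromosome_id: str,
    region: GenomicInterval,
    l: int = 45,
    step: int = 5,
    composition: CompositionPolicy = CompositionPolicy(),
) -> list[OligoCandidate]:
    """Tile a region of the design copy into candidate oligos.

    Windows start at ``region.start, region.start+step, ...`` while the whole
    window fits in the region. Windows failing composition filters (N, GC
    bounds, homopolymer runs) are returned with ``passes_composition=False``
    rather than dropped, so downstream bookkeeping sees the full tiling.
    A region shorter than ``l`` yields an empty list.
    """
    design = genome.design_copy[chromosome_id]
    if region.copy_id != design:
        raise ValueError(
            f"region is on {region.copy_id!r} but the design copy of "
            f"{chromosome_id!r} is {design!r}"
        )
    seq = genome.copies[design]
    out: list[OligoCandidate] = []
    for start in range(region.start, region.stop - l + 1, step):
        window = seq[start : start + l]
        gc = gc_fraction(window)
        ok = (
            "N" not in window
            and composition.gc_min <= gc <= composition.gc_max
            and _max_run(window) <= composition.max_homopolymer_run
        )
        out.append(
            OligoCandidate(
                sequence=window,
                locus=GenomicInterval(design, start, start + l),
                gc_fraction=gc,
                passes_composition=ok,
            )
        )
    return out


def _min_matches(l: int, homology_pct: float) -> int:
    return math.ceil(l * homology_pct / 100.0 - 1e-9)


def screen_specificity(
    candidates: list[OligoCandidate],
    genome: Genome,
    policy: SpecificityPolicy,
    index: GenomeIndex | None = None,
) -> list[OligoCandidate]:
    """Label each candidate REPETITIVE, CROSS_HYBRIDIZING or SINGLE_COPY.

    Pure labeling: the input list is returned with ``specificity`` set.
    Candidates are screened regardless of their composition flag (an
    N-containing window simply never matches an ACGT base).
    """
    if index is None or index.kmer_len != policy.kmer_len:
        index = GenomeIndex(genome, policy.kmer_len)
    cutoff = policy.max_kmer_genome_count
    if cutoff is None:
        cutoff = index.default_repeat_cutoff
    disallowed = [cid for cid in genome.copies if cid not in policy.allowed_targets]
    survivors: list[OligoCandidate] = []
    for cand in candidates:
        codes = encode(cand.sequence)
        counts = index.both_strand_kmer_counts(codes)
        if counts.size and counts.max() > cutoff:
            cand.specificity = Specificity.REPETITIVE
        else:
            cand.specificity = Specificity.SINGLE_COPY  # until a scan hit says otherwise
            survivors.append(cand)
    if not survivors or not disallowed:
        return candidates
    # exact all-offset scan, batched: one-hot probes (both strands) against
    # one-hot windows via matmul; entries are integer match counts (<= l),
    # exact in float32
    by_len: dict[int, list[OligoCandidate]] = {}
    for cand in survivors:
        by_len.setdefault(len(cand.sequence), []).append(cand)
    for l, group in by_len.items():
        need = _min_matches(l, policy.homology_pct)
        probes = np.zeros((2 * len(group), 4 * l), dtype=np.float32)
        for i, cand in enumerate(group):
            codes = encode(cand.sequence)
            rc = revcomp_codes(codes)
            for b in range(4):
                probes[2 * i, b * l : (b + 1) * l] = codes == b
                probes[2 * i + 1, b * l : (b + 1) * l] = rc == b
        hit = np.zeros(len(group), dtype=bool)
        chunk = 256
        for cid in disallowed:
            win = index.windows_onehot(cid, l)
            if win.shape[0] == 0:
                continue
            for a in range(0, probes.shape[0], chunk):
                scores = probes[a : a + chunk] @ win.T
                best = scores.max(axis=1) >= need - 0.5
                idx = (np.flatnonzero(best) + a) // 2
                hit[idx] = True
        for cand, h in zip(group, hit):
            if h:
                cand.specificity = Specificity.CROSS_HYBRIDIZING
    return candidates


def density(n_oligos: int, region_length_bp: int) -> float:
    """Oligos per kilobase; exports round this to 2 decimals."""
    if region_length_bp <= 0:
        raise ValueError("region_length_bp must be positive")
    return n_oligos / (region_length_bp / 1000.0)


def thin_to_target(
    singlecopy_oligos: list[OligoCandidate], n_target: int, min_start_gap: int | None = None
) -> list[OligoCandidate]:
    """Thin a sorted oligo list to ``n_target`` maximally uniform picks.

    Greedy: lay ``n_target`` ideal target positions at the centers of equal
    slices of the occupied span and pick for each the nearest not-yet-used
    oligo (ties go left), preserving genomic order. On a uniform tiling this
    reduces to an exact every-(n/k)-th subsample. ``min_start_gap`` (default:
    the minimum adjacent start difference of the input, i.e. the tiling step)
    keeps picked oligos from overlapping more than l - step bp.
    """
    if n_target <= 0:
        raise ValueError("n_target must be positive")
    n = len(singlecopy_oligos)
    if n <= n_target:
        return list(singlecopy_oligos)
    starts = [o.locus.start for o in singlecopy_oligos]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("input oligos must be sorted by locus")
    if min_start_gap is None:
        min_start_gap = min((b - a) for a, b in zip(starts, starts[1:]) if b > a)
    # widen the span by one average spacing so slice centers tile the region
    width = (starts[-1] - starts[0]) * n / (n - 1)
    chosen: list[int] = []
    lo = 0  # first eligible index
    for i in range(n_target):
        ideal = starts[0] + (i + 0.5) * width / n_target
        hi = n - (n_target - i - 1)  # leave room for the remaining picks
        if chosen:
            min_start = starts[chosen[-1]] + min_start_gap
            lo = max(lo, bisect.bisect_left(starts, min_start, lo, hi))
        if lo >= hi:
            break
        j = bisect.bisect_left(starts, ideal, lo, hi)
        # nearest eligible start to the ideal position; ties -> leftmost
        if j >= hi:
            pick = hi - 1
        elif j == lo:
            pick = lo
        else:
            pick = j - 1 if (ideal - starts[j - 1]) <= (starts[j] - ideal) else j
        chosen.append(pick)
        lo = pick + 1
    return [singlecopy_oligos[i] for i in chosen]


def single_copy_oligos(
    candidates: list[OligoCandidate],
) -> list[OligoCandidate]:
    """The screened candidates that are both composition-clean and single copy."""
    return [
        c
        for c in candidates
        if c.passes_composition and c.specificity is Specificity.SINGLE_COPY
    ]


def write_oligos_fasta(oligos, path: str | Path, name_prefix: str = "oligo") -> None:
    with open(path, "w") as fh:
        for i, o in enumerate(oligos, start=1):
            fh.write(f">{name_prefix}{i}\n{o.sequence}\n")


def write_oligos_tsv(oligos, path: str | Path, name_prefix: str = "oligo") -> None:
    with open(path, "w") as fh:
        fh.write("oligo_id\tcopy_id\tstart0\tstop0\tstrand\tgc\tsequence\n")
        for i, o in enumerate(oligos, start=1):
            fh.write(
                f"{name_prefix}{i}\t{o.locus.copy_id}\t{o.locus.start}\t{o.locus.stop}"
                f"\t+\t{o.gc_fraction:.3f}\t{o.sequence}\n"
            )
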