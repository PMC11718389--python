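"""Per-chromosome barcode planning: region placement, sizing and coloring.

A barcode plan gives every chromosome an ordered pattern of probe regions
("marks"): short chromosomes carry two terminal marks, long chromosomes add
an interstitial one. Each region is sized to hold a target number of
single-copy oligos (default 4800 at >= ~1 oligo/kb, region 3.8-5.0 Mb) and
consecutive regions on a chromosome keep a minimum start-to-start
separation so their FISH signals stay resolvable. Finally a two-color
(green/red) assignment is searched such that every chromosome's ordered
(position, color) signature is unique *even under reversal* — metaphase
chromosomes of a uniform metacentric karyotype carry no intrinsic
orientation, so a pattern and its mirror image are indistinguishable at the
microscope.

Placement of the interstitial mark follows oligo availability, not
geometry: among all placements satisfying the separation floor it maximizes
the retained single-copy oligo count (ties prefer the chromosome midpoint,
then the leftmost position).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib.resources import files
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import Genome, GenomicInterval
from .oligo_select import (
    CompositionPolicy,
    GenomeIndex,
    OligoCandidate,
    density,
    policy_for,
    screen_specificity,
    single_copy_oligos,
    thin_to_target,
    tile_candidates,
)


class DesignError(ValueError):
    """A chromosome cannot accommodate the requested barcode layout."""


class Color(Enum):
    GREEN = "G"
    RED = "R"


class PositionClass(Enum):
    TERMINAL_LEFT = "TL"
    INTERSTITIAL = "I"
    TERMINAL_RIGHT = "TR"


_SWAP = {
    PositionClass.TERMINAL_LEFT: PositionClass.TERMINAL_RIGHT,
    PositionClass.TERMINAL_RIGHT: PositionClass.TERMINAL_LEFT,
    PositionClass.INTERSTITIAL: PositionClass.INTERSTITIAL,
}


@dataclass
class DesignParams:
    """Numeric design parameters.

    The defaults are the published autotetraploid-alfalfa design: 45-bp
    oligos tiled at a 5-bp step, 75% homology cutoff, regions of 3.8-5.0 Mb
    holding 4800 oligos each at >= 0.9 oligos/kb, and a 35.8-Mb minimum
    start-to-start separation between marks on one chromosome.
    """

    oligo_len: int = 45
    step: int = 5
    homology_pct: float = 75.0
    kmer_len: int = 17
    max_kmer_genome_count: int | None = None
    min_region_bp: int = 3_800_000
    max_region_bp: int = 5_000_000
    n_target: int = 4800
    density_min: float = 0.9
    separation_bp: int = 35_800_000
    grow_step: int = 100_000
    placement_grid: int = 100_000
    composition: CompositionPolicy = field(default_factory=CompositionPolicy)


ALFALFA_PRESET = DesignParams()


@dataclass
class ProbeRegion:
    """A contiguous design region with its selected oligos and color."""

    name: str
    chromosome_id: str
    interval: GenomicInterval
    oligos: list[OligoCandidate] = field(default_factory=list)
    color: Color | None = None
    position_class: PositionClass = PositionClass.INTERSTITIAL
    n_oligos_hint: int | None = None

    @property
    def n_oligos(self) -> int:
        return self.n_oligos_hint if self.n_oligos_hint is not None else len(self.oligos)

    @property
    def density_per_kb(self) -> float:
        return density(self.n_oligos, self.interval.length)


@dataclass
class BarcodePlan:
    """All probe regions of a design, grouped by chromosome."""

    regions: list[ProbeRegion]

    def by_chromosome(self) -> dict[str, list[ProbeRegion]]:
        out: dict[str, list[ProbeRegion]] = {}
        for r in self.regions:
            out.setdefault(r.chromosome_id, []).append(r)
        for regs in out.values():
            regs.sort(key=lambda r: r.interval.start)
        return out

    def signatures(self) -> dict[str, tuple]:
        return {
            chrom: signature(regs) for chrom, regs in self.by_chromosome().items()
        }

    @property
    def total_oligos(self) -> int:
        return sum(r.n_oligos for r in self.regions)

    @property
    def min_start_separation_bp(self) -> int | None:
        return min_start_separation(self)


def assign_mark_counts(
    genome: Genome,
    rule: str = "length-rank",
    explicit: dict[str, int] | None = None,
    two_mark_fraction: float = 3 / 8,
) -> dict[str, int]:
    """Decide how many marks (2 or 3) each chromosome carries.

    ``length-rank``: the shortest ``two_mark_fraction`` of chromosomes
    (rounded; default 3 of 8) get two terminal marks, the rest get three.
    An explicit map overrides the rule entirely and must cover every
    chromosome. A single-chromosome genome falls into the majority class
    (three marks).
    """
    chroms = sorted(genome.homolog_groups)
    if explicit is not None:
        missing = [c for c in chroms if c not in explicit]
        if missing:
            raise DesignError(f"explicit mark map missing chromosomes: {', '.join(missing)}")
        bad = {c: n for c, n in explicit.items() if n not in (2, 3)}
        if bad:
            raise DesignError(f"mark counts must be 2 or 3, got {bad}")
        return {c: explicit[c] for c in chroms}
    if rule != "length-rank":
        raise DesignError(f"unknown mark-count rule {rule!r}")
    n_two = int(len(chroms) * two_mark_fraction + 0.5)
    by_len = sorted(chroms, key=lambda c: (len(genome.copies[genome.design_copy[c]]), c))
    two_set = set(by_len[:n_two])
    return {c: (2 if c in two_set else 3) for c in chroms}


def single_copy_starts(
    genome: Genome,
    chromosome_id: str,
    params: DesignParams,
    index: GenomeIndex | None = None,
) -> list[OligoCandidate]:
    """All composition-clean single-copy oligos tiled over the design copy."""
    design = genome.design_copy[chromosome_id]
    full = GenomicInterval(design, 0, genome.length(design))
    cands = tile_candidates(
        genome, chromosome_id, full, params.oligo_len, params.step, params.composition
    )
    policy = policy_for(
        genome,
        chromosome_id,
        homology_pct=params.homology_pct,
        kmer_len=params.kmer_len,
        max_kmer_genome_count=params.max_kmer_genome_count,
    )
    screen_specificity(cands, genome, policy, index=index)
    return single_copy_oligos(cands)


def _count_in(starts: np.ndarray, a: int, b: int, l: int) -> int:
    """Number of oligo starts fully inside [a, b)."""
    return int(np.searchsorted(starts, b - l, side="right") - np.searchsorted(starts, a))


def plan_regions(
    genome: Genome,
    chromosome_id: str,
    n_marks: int,
    params: DesignParams,
    index: GenomeIndex | None = None,
    eligible: list[OligoCandidate] | None = None,
) -> list[ProbeRegion]:
    """Place and size ``n_marks`` probe regions on one chromosome.

    Terminal regions are anchored exactly at the chromosome ends and grown
    inward from ``min_region_bp`` in ``grow_step`` increments until they hold
    ``n_target`` single-copy oligos or reach ``max_region_bp`` (then the
    shortfall is accepted with a warning). The interstitial region (three-mark
    layouts) scans a placement grid constrained by the start-to-start
    separation floor and takes the placement retaining the most single-copy
    oligos.
    """
    if n_marks not in (2, 3):
        raise DesignError("n_marks must be 2 or 3")
    design = genome.design_copy[chromosome_id]
    clen = genome.length(design)
    need = n_marks * params.min_region_bp + (n_marks - 1) * params.separation_bp
    if clen <= need:
        raise DesignError(
            f"{chromosome_id}: design copy length {clen} bp cannot fit {n_marks} regions "
            f"of >= {params.min_region_bp} bp with {params.separation_bp} bp start-to-start "
            f"separation (needs > {need} bp)"
        )
    if eligible is None:
        eligible = single_copy_starts(genome, chromosome_id, params, index=index)
    starts = np.array([o.locus.start for o in eligible], dtype=np.int64)
    l = params.oligo_len

    def grow_terminal(left: bool) -> GenomicInterval:
        size = min(params.min_region_bp, clen)
        while True:
            a, b = (0, size) if left else (clen - size, clen)
            if (
                _count_in(starts, a, b, l) >= params.n_target
                or size >= params.max_region_bp
                or size >= clen
            ):
                break
            size = min(size + params.grow_step, params.max_region_bp, clen)
        iv = GenomicInterval(design, 0, size) if left else GenomicInterval(design, clen - size, clen)
        return iv

    left_iv = grow_terminal(left=True)
    right_iv = grow_terminal(left=False)
    intervals: list[tuple[GenomicInterval, PositionClass]] = [
        (left_iv, PositionClass.TERMINAL_LEFT)
    ]

    if n_marks == 3:
        s_lo = max(params.separation_bp, left_iv.stop)
        s_hi = min(
            right_iv.start - params.separation_bp,
            right_iv.start - params.min_region_bp,
        )
        if s_lo > s_hi:
            raise DesignError(
                f"{chromosome_id}: no feasible interstitial placement with separation "
                f">= {params.separation_bp} bp"
            )
        grid = np.arange(s_lo, s_hi + 1, params.placement_grid, dtype=np.int64)
        if grid.size == 0 or grid[-1] != s_hi:
            grid = np.append(grid, s_hi)
        counts = np.array(
            [_count_in(starts, int(s), int(s) + params.min_region_bp, l) for s in grid]
        )
        mid = clen / 2.0
        off_center = np.abs(grid + params.min_region_bp / 2.0 - mid)
        # argmax count; ties -> closest to midpoint; ties -> leftmost
        order = sorted(
            range(grid.size), key=lambda i: (-counts[i], off_center[i], grid[i])
        )
        s = int(grid[order[0]])
        a, b = s, s + params.min_region_bp
        # grow around the candidate midpoint while constraints allow
        while (
            _count_in(starts, a, b, l) < params.n_target
            and (b - a) < params.max_region_bp
        ):
            inc = min(params.grow_step, params.max_region_bp - (b - a))
            if b + inc <= right_iv.start:
                b += inc
            elif a - inc >= s_lo:
                a -= inc
            else:
                break
        intervals.append((GenomicInterval(design, a, b), PositionClass.INTERSTITIAL))

    intervals.append((right_iv, PositionClass.TERMINAL_RIGHT))

    regions: list[ProbeRegion] = []
    for i, (iv, pcls) in enumerate(intervals, start=1):
        inside = [
            o for o in eligible if iv.start <= o.locus.start and o.locus.stop <= iv.stop
        ]
        picked = thin_to_target(inside, params.n_target) if inside else []
        if len(picked) < params.n_target:
            warnings.warn(
                f"{chromosome_id} region {i}: only {len(picked)} single-copy oligos "
                f"available (target {params.n_target})",
                stacklevel=2,
            )
        regions.append(
            ProbeRegion(
                name=f"{chromosome_id}_P{i}",
                chromosome_id=chromosome_id,
                interval=iv,
                oligos=picked,
                position_class=pcls,
            )
        )
    return regions


def min_start_separation(plan: BarcodePlan) -> int | None:
    """Minimum start-to-start distance of consecutive regions on any chromosome.

    ``None`` (reported as NA in exports) when no chromosome carries more than
    one region.
    """
    best: int | None = None
    for regs in plan.by_chromosome().values():
        for a, b in zip(regs, regs[1:]):
            d = b.interval.start - a.interval.start
            if best is None or d < best:
                best = d
    return best


def signature(regions: list[ProbeRegion]) -> tuple:
    """Ordered (position_class, color) tuple of one chromosome's marks."""
    regs = sorted(regions, key=lambda r: r.interval.start)
    return tuple((r.position_class, r.color) for r in regs)


def _reverse_signature(sig: tuple) -> tuple:
    return tuple((_SWAP[p], c) for p, c in reversed(sig))


def signatures_equal(a: tuple, b: tuple) -> bool:
    """Signature comparison treating a pattern and its mirror image as equal."""
    return a == b or a == _reverse_signature(b)


class InfeasibleColoringError(ValueError):
    """No two-color assignment separates all chromosomes; carries a certificate."""

    def __init__(self, message: str, certificate: dict):
        super().__init__(message)
        self.certificate = certificate


def _profile_canonical(profile: tuple) -> tuple:
    rev = tuple(_SWAP[p] for p in reversed(profile))
    return min(profile, rev)


def _coloring_classes(profile: tuple, palette: tuple) -> list[tuple]:
    """Distinct signature equivalence classes for one position profile.

    Classes are represented by their lexicographically smallest coloring.
    Reversal merges two colorings only when the reversed position profile
    equals the profile itself (true for any terminal-symmetric layout).
    """
    palindromic = tuple(_SWAP[p] for p in reversed(profile)) == profile
    seen: dict[tuple, tuple] = {}
    order = sorted(palette, key=lambda c: c.value)
    for coloring in product(order, repeat=len(profile)):
        key = min(coloring, coloring[::-1], key=lambda c: [x.value for x in c]) if palindromic else coloring
        seen.setdefault(key, coloring)
    return list(seen.values())


def solve_colors(
    profiles: dict[str, tuple], palette: tuple = (Color.GREEN, Color.RED)
) -> dict[str, tuple]:
    """Find the lexicographically smallest reversal-robust coloring.

    ``profiles`` maps chromosome -> ordered position-class tuple. Chromosomes
    whose position profiles differ (up to reversal) can never collide, so the
    search decomposes by profile group; within a group the distinct
    reversal-equivalence classes are enumerated exhaustively (at most 2^m per
    chromosome, globally bounded by the total mark count) and assigned
    greedily in lexicographic order. Infeasibility is certified by the
    pigeonhole: a group with more chromosomes than available classes.
    """
    groups: dict[tuple, list[str]] = {}
    for chrom in profiles:
        groups.setdefault(_profile_canonical(profiles[chrom]), []).append(chrom)
    class_pool: dict[tuple, list[tuple]] = {
        key: _coloring_classes(key, palette) for key in groups
    }
    for key, members in groups.items():
        n_classes = len(class_pool[key])
        if len(members) > n_classes:
            raise InfeasibleColoringError(
                f"{len(members)} chromosomes share the mark layout "
                f"{'/'.join(p.value for p in key)} but only {n_classes} "
                f"reversal-distinct colorings exist: {', '.join(sorted(members))} "
                "cannot all be separated",
                certificate={
                    "profile": tuple(p.value for p in key),
                    "chromosomes": sorted(members),
                    "n_classes": n_classes,
                },
            )
    assignment: dict[str, tuple] = {}
    used: dict[tuple, set] = {key: set() for key in groups}
    for chrom in sorted(profiles):
        key = _profile_canonical(profiles[chrom])
        for coloring in class_pool[key]:
            canon = min(
                coloring, coloring[::-1], key=lambda c: [x.value for x in c]
            ) if tuple(_SWAP[p] for p in reversed(key)) == key else coloring
            if canon not in used[key]:
                used[key].add(canon)
                # express the coloring on the chromosome's own profile order
                if profiles[chrom] == key:
                    assignment[chrom] = coloring
                else:
                    assignment[chrom] = coloring[::-1]
                break
    return assignment


def assign_colors(
    plan: BarcodePlan, palette: tuple = (Color.GREEN, Color.RED)
) -> BarcodePlan:
    """Color every region of a plan so all chromosome signatures are unique."""
    by_chrom = plan.by_chromosome()
    profiles = {
        chrom: tuple(r.position_class for r in regs) for chrom, regs in by_chrom.items()
    }
    assignment = solve_colors(profiles, palette)
    for chrom, regs in by_chrom.items():
        for region, color in zip(regs, assignment[chrom]):
            region.color = color
    sigs = plan.signatures()
    chroms = sorted(sigs)
    for i, a in enumerate(chroms):
        for b in chroms[i + 1 :]:
            if signatures_equal(sigs[a], sigs[b]):  # pragma: no cover - defensive
                raise InfeasibleColoringError(
                    f"signature collision between {a} and {b} after coloring",
                    certificate={"chromosomes": [a, b]},
                )
    return plan


def design_barcode(
    genome: Genome,
    params: DesignParams = ALFALFA_PRESET,
    mark_rule: str = "length-rank",
    explicit_marks: dict[str, int] | None = None,
) -> BarcodePlan:
    """Full design pipeline: mark counts, region placement, coloring."""
    index = GenomeIndex(genome, params.kmer_len)
    marks = assign_mark_counts(genome, rule=mark_rule, explicit=explicit_marks)
    regions: list[ProbeRegion] = []
    for chrom in sorted(genome.homolog_groups):
        regions.extend(
            plan_regions(genome, chrom, marks[chrom], params, index=index)
        )
    return assign_colors(BarcodePlan(regions))


def plan_table(plan: BarcodePlan) -> pd.DataFrame:
    """Tabular view of a plan (densities rounded to 2 decimals)."""
    rows = []
    for chrom, regs in sorted(plan.by_chromosome().items()):
        for r in regs:
            rows.append(
                {
                    "chromosome": chrom,
                    "probe": r.name,
                    "copy_id": r.interval.copy_id,
                    "start_bp": r.interval.start,
                    "stop_bp": r.interval.stop,
                    "region_length_bp": r.interval.length,
                    "n_oligos": r.n_oligos,
                    "density_per_kb": round(r.density_per_kb, 2),
                    "color": r.color.name if r.color else "NA",
                    "position_class": r.position_class.value,
                }
            )
    return pd.DataFrame(rows)


_ITEM_RGB = {Color.GREEN: "0,255,0", Color.RED: "255,0,0"}


def write_plan(plan: BarcodePlan, outdir: str | Path, prefix: str = "barcode") -> None:
    """Write plan TSV, BED6 and per-region probe FASTA deterministically."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plan_table(plan).to_csv(outdir / f"{prefix}_plan.tsv", sep="\t", index=False)
    with open(outdir / f"{prefix}_plan.bed", "w") as fh:
        for chrom, regs in sorted(plan.by_chromosome().items()):
            for r in regs:
                rgb = _ITEM_RGB.get(r.color, "0,0,0")
                fh.write(
                    f"{r.interval.copy_id}\t{r.interval.start}\t{r.interval.stop}"
                    f"\t{r.name}\t0\t+\t{r.interval.start}\t{r.interval.stop}\t{rgb}\n"
                )
    with open(outdir / f"{prefix}_probes.fasta", "w") as fh:
        for chrom, regs in sorted(plan.by_chromosome().items()):
            for r in regs:
                for i, o in enumerate(r.oligos, start=1):
                    fh.write(f">{r.name}_{i}\n{o.sequence}\n")


def load_published_design() -> pd.DataFrame:
    """The published 21-region autotetraploid-alfalfa barcode coordinates.

    Columns: chromosome, probe, start_bp, stop_bp (0-based half-open on the
    design copy) and n_oligos. Used as an input table for arithmetic checks
    and layout summaries; the alfalfa assembly itself is not bundled.
    """
    path = files("oligobar").joinpath("data/alfalfa_barcode_regions.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")


def plan_from_table(df: pd.DataFrame) -> BarcodePlan:
    """Build a (sequence-free) plan from a region coordinate table."""
    regions: list[ProbeRegion] = []
    for chrom, sub in df.groupby("chromosome", sort=True):
        sub = sub.sort_values("start_bp")
        n = len(sub)
        for i, row in enumerate(sub.itertuples(index=False)):
            if i == 0:
                pcls = PositionClass.TERMINAL_LEFT
            elif i == n - 1:
                pcls = PositionClass.TERMINAL_RIGHT
            else:
                pcls = PositionClass.INTERSTITIAL
            regions.append(
                ProbeRegion(
                    name=str(row.probe),
                    chromosome_id=str(chrom),
                    interval=GenomicInterval(str(chrom), int(row.start_bp), int(row.stop_bp)),
                    n_oligos_hint=int(row.n_oligos),
                    position_class=pcls,
                )
            )
    return BarcodePlan(regions)
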