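"""Synthetic autopolyploid genomes and screening tables with known truth.

The generator emulates the statistical structure the downstream analyses
assume: a small autotetraploid genome whose homologous copies diverge by
SNPs, short insertions/deletions (1-200 bp) and larger presence-absence
events (> 200 bp), optionally carrying planted repeat families shared
across chromosomes. Copy 1 of each chromosome is the un-mutated base
sequence; every difference planted into copies 2..ploidy is recorded in a
truth ledger with coordinates on both copies, so detection code can be
scored exactly.

It also fabricates the cytogenetic screening inputs: per-cell FISH
signal-count tables for seed populations with planted aneuploidies and
segment deletions, and arm-length measurement tables for karyotyping.

All randomness flows from a single integer seed through one generator
stream; identical specs produce byte-identical FASTA files and ledgers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import Genome

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(RuntimeError):
    """Raised when planted events cannot be placed without collisions."""


@dataclass(frozen=True)
class RepeatFamily:
    """An exact repeat family planted into the base sequences.

    ``placement`` is ``dispersed`` (copies land at random positions on
    random chromosomes) or ``tandem`` (copies laid head-to-tail at one
    site). Family members are exact copies by default so the single-copy
    specificity truth is unambiguous.
    """

    name: str
    unit_length: int
    copy_number: int
    placement: str = "dispersed"

    def __post_init__(self) -> None:
        if self.unit_length <= 0 or self.copy_number <= 0:
            raise ValueError("repeat unit_length and copy_number must be positive")
        if self.placement not in ("dispersed", "tandem"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass(frozen=True)
class PavSpec:
    """An explicit presence-absence event planted into one copy.

    ``chromosome``/``copy`` are 1-based indices (copy >= 2; copy 1 is the
    base). ``position`` of None means a random collision-free placement.
    """

    chromosome: int
    copy: int
    length: int
    kind: str = "deletion"
    position: int | None = None

    def __post_init__(self) -> None:
        if self.length <= 200:
            raise ValueError("PAV events must exceed 200 bp")
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"unknown PAV kind {self.kind!r}")
        if self.copy < 2:
            raise ValueError("PAV events go into copies >= 2 (copy 1 is the base)")


@dataclass
class SimulationSpec:
    """Full description of a synthetic genome draw."""

    n_chromosomes: int = 2
    chromosome_lengths: tuple = (50_000, 50_000)
    ploidy: int = 4
    gc_target: float = 0.40
    repeat_families: tuple = ()
    snp_rate: float = 0.0
    indel_rate: float = 0.0
    indel_length_p: float = 0.1  # geometric length parameter, capped at 200
    pav_events: tuple = ()
    rng_seed: int = 0
    min_event_spacing: int = 50  # keeps planted events separable by 21-mer anchors
    edge_margin: int = 500

    def __post_init__(self) -> None:
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ValueError("chromosome_lengths must list one length per chromosome")
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        if not (0 <= self.snp_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("rates must lie in [0, 1)")
        if not (0 < self.gc_target < 1):
            raise ValueError("gc_target must lie in (0, 1)")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")


def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _place_nonoverlapping(
    rng: np.random.Generator,
    length: int,
    event_len: int,
    occupied: list[tuple[int, int]],
    margin: int,
    retries: int = 100,
) -> int:
    for _ in range(retries):
        if length - margin - event_len <= margin:
            break
        pos = int(rng.integers(margin, length - margin - event_len))
        if all(pos + event_len + margin <= a or pos >= b + margin for a, b in occupied):
            return pos
    raise SimulationError(
        "could not place a planted event without collisions after "
        f"{retries} retries; lower the event density or enlarge the genome"
    )


def simulate_genome(spec: SimulationSpec) -> tuple[Genome, pd.DataFrame]:
    """Draw a genome per the spec; return it with the planted-event ledger.

    Ledger columns: chromosome_id, ref_copy, alt_copy, kind (SNP/INDEL/PAV),
    ref_start/ref_stop (on the base copy), alt_start/alt_stop (on the
    mutated copy), length_bp. Repeat placements are returned in the ledger
    too, under kind REPEAT with alt_copy equal to the ref copy.
    """
    rng = np.random.default_rng(spec.rng_seed)
    bases: dict[int, np.ndarray] = {
        ci: _random_codes(rng, spec.chromosome_lengths[ci], spec.gc_target)
        for ci in range(spec.n_chromosomes)
    }
    ledger_rows: list[dict] = []
    repeat_zones: dict[int, list[tuple[int, int]]] = {ci: [] for ci in bases}

    for fam in spec.repeat_families:
        unit = _random_codes(rng, fam.unit_length, spec.gc_target)
        if fam.placement == "tandem":
            ci = int(rng.integers(0, spec.n_chromosomes))
            total = fam.unit_length * fam.copy_number
            pos = _place_nonoverlapping(
                rng, spec.chromosome_lengths[ci], total, repeat_zones[ci], spec.edge_margin
            )
            for j in range(fam.copy_number):
                a = pos + j * fam.unit_length
                bases[ci][a : a + fam.unit_length] = unit
                repeat_zones[ci].append((a, a + fam.unit_length))
                ledger_rows.append(
                    _repeat_row(ci, fam, a, fam.unit_length)
                )
        else:
            for _ in range(fam.copy_number):
                ci = int(rng.integers(0, spec.n_chromosomes))
                pos = _place_nonoverlapping(
                    rng,
                    spec.chromosome_lengths[ci],
                    fam.unit_length,
                    repeat_zones[ci],
                    spec.edge_margin,
                )
                bases[ci][pos : pos + fam.unit_length] = unit
                repeat_zones[ci].append((pos, pos + fam.unit_length))
                ledger_rows.append(_repeat_row(ci, fam, pos, fam.unit_length))

    copies: dict[str, str] = {}
    groups: dict[str, list[str]] = {}
    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        base = bases[ci]
        L = base.size
        groups[chrom] = [f"{chrom}.{m}" for m in range(1, spec.ploidy + 1)]
        copies[f"{chrom}.1"] = _decode(base)
        forbidden = list(repeat_zones[ci])
        for m in range(2, spec.ploidy + 1):
            alt_codes, rows = _mutate_copy(rng, spec, ci, m, base, forbidden)
            copies[f"{chrom}.{m}"] = _decode(alt_codes)
            ledger_rows.extend(rows)

    ledger = pd.DataFrame(
        ledger_rows,
        columns=[
            "chromosome_id",
            "ref_copy",
            "alt_copy",
            "kind",
            "ref_start",
            "ref_stop",
            "alt_start",
            "alt_stop",
            "length_bp",
        ],
    )
    return Genome(copies=copies, homolog_groups=groups), ledger


def _repeat_row(ci: int, fam: RepeatFamily, start: int, length: int) -> dict:
    chrom = f"chr{ci + 1}"
    return {
        "chromosome_id": chrom,
        "ref_copy": f"{chrom}.1",
        "alt_copy": f"{chrom}.1",
        "kind": f"REPEAT:{fam.name}",
        "ref_start": start,
        "ref_stop": start + length,
        "alt_start": start,
        "alt_stop": start + length,
        "length_bp": length,
    }


def _mutate_copy(
    rng: np.random.Generator,
    spec: SimulationSpec,
    ci: int,
    m: int,
    base: np.ndarray,
    forbidden: list[tuple[int, int]],
) -> tuple[np.ndarray, list[dict]]:
    """Mutate the base into copy ``m``; return the sequence and ledger rows."""
    chrom = f"chr{ci + 1}"
    ref_copy, alt_copy = f"{chrom}.1", f"{chrom}.{m}"
    L = base.size
    spacing = spec.min_event_spacing
    margin = spec.edge_margin

    # structural events first: explicit PAVs, then rate-sampled indels
    structural: list[tuple[int, int, str, str]] = []  # (pos, len, kind, direction)
    occupied = list(forbidden)
    for pav in spec.pav_events:
        if pav.chromosome != ci + 1 or pav.copy != m:
            continue
        if pav.position is not None:
            pos = pav.position
            span = pav.length if pav.kind == "deletion" else 0
            if not all(
                pos + span + spacing <= a or pos >= b + spacing for a, b in occupied
            ):
                raise SimulationError(
                    f"explicit PAV at {chrom}:{pos} collides with another planted feature"
                )
        else:
            pos = _place_nonoverlapping(rng, L, pav.length, occupied, margin)
        span = pav.length if pav.kind == "deletion" else 0
        occupied.append((pos - spacing, pos + span + spacing))
        structural.append((pos, pav.length, "PAV", pav.kind))
    if spec.indel_rate > 0:
        for pos in np.flatnonzero(rng.random(L) < spec.indel_rate).tolist():
            length = int(min(rng.geometric(spec.indel_length_p), 200))
            direction = "deletion" if rng.random() < 0.5 else "insertion"
            span = length if direction == "deletion" else 0
            if pos < margin or pos + span > L - margin:
                continue
            if not all(
                pos + span + spacing <= a or pos >= b + spacing for a, b in occupied
            ):
                continue
            occupied.append((pos - spacing, pos + span + spacing))
            structural.append((pos, length, "INDEL", direction))

    # SNPs last: anywhere except inside/near structural events or repeats
    events: list[tuple[int, int, str, str]] = sorted(structural)
    if spec.snp_rate > 0:
        snp_pos = np.flatnonzero(rng.random(L) < spec.snp_rate)
        blocked: list[tuple[int, int]] = []
        for a, b in sorted(occupied):
            if blocked and a <= blocked[-1][1]:
                blocked[-1] = (blocked[-1][0], max(blocked[-1][1], b))
            else:
                blocked.append((a, b))
        starts = np.array([a for a, _ in blocked], dtype=np.int64)
        stops = np.array([b for _, b in blocked], dtype=np.int64)
        for pos in snp_pos.tolist():
            if pos < margin or pos >= L - margin:
                continue
            i = np.searchsorted(stops, pos, side="right")
            if i < starts.size and starts[i] <= pos:
                continue
            events.append((pos, 1, "SNP", "substitution"))
        events.sort()

    parts: list[np.ndarray] = []
    rows: list[dict] = []
    cur = 0
    offset = 0  # alt position - ref position so far
    for pos, length, kind, direction in events:
        parts.append(base[cur:pos])
        alt_pos = pos + offset
        if kind == "SNP":
            new = np.array([(int(base[pos]) + int(rng.integers(1, 4))) % 4], dtype=np.uint8)
            parts.append(new)
            cur = pos + 1
            rows.append(
                _event_row(chrom, ref_copy, alt_copy, "SNP", pos, pos + 1, alt_pos, alt_pos + 1, 1)
            )
        elif direction == "deletion":
            cur = pos + length
            rows.append(
                _event_row(chrom, ref_copy, alt_copy, kind, pos, pos + length, alt_pos, alt_pos, length)
            )
            offset -= length
        else:  # insertion
            ins = _random_codes(rng, length, spec.gc_target)
            parts.append(ins)
            cur = pos
            rows.append(
                _event_row(chrom, ref_copy, alt_copy, kind, pos, pos, alt_pos, alt_pos + length, length)
            )
            offset += length
    parts.append(base[cur:])
    return np.concatenate(parts) if parts else base.copy(), rows


def _event_row(chrom, ref_copy, alt_copy, kind, r0, r1, a0, a1, length) -> dict:
    return {
        "chromosome_id": chrom,
        "ref_copy": ref_copy,
        "alt_copy": alt_copy,
        "kind": kind,
        "ref_start": r0,
        "ref_stop": r1,
        "alt_start": a0,
        "alt_stop": a1,
        "length_bp": length,
    }


_ABERRATION_KINDS = ("aneuploid_gain", "aneuploid_loss", "segment_deletion")


def simulate_screen(
    n_seeds: int,
    aberrations: list[tuple[int, str, str]] = (),
    ploidy: int = 4,
    complement: int = 8,
    cells_per_seed: int = 3,
    noise: float = 0.0,
    variety: str = "synthetic",
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell FISH signal-count tables for a seed population with known truth.

    ``aberrations`` lists ``(seed_id, kind, chromosome)`` with kind one of
    ``aneuploid_gain``, ``aneuploid_loss``, ``segment_deletion``; every other
    seed is euploid. Painting counts are only recorded for the affected
    chromosome of segment-deletion seeds (painting is the confirmatory
    follow-up assay, not part of the primary barcode screen); all other
    painting entries are missing. With probability ``noise`` per cell, one
    chromosome's barcode count is perturbed by +-1 — the model of a
    miscounted spread (DAPI and painting untouched).
    Returns ``(signal_table, truth_table)``.
    """
    rng = np.random.default_rng(rng_seed)
    planted = {}
    for seed_id, kind, chrom in aberrations:
        if kind not in _ABERRATION_KINDS:
            raise ValueError(f"unknown aberration kind {kind!r}")
        if not (0 <= seed_id < n_seeds):
            raise ValueError(f"seed_id {seed_id} outside 0..{n_seeds - 1}")
        planted[int(seed_id)] = (kind, chrom)
    chroms = [f"chr{i + 1}" for i in range(complement)]
    euploid_total = complement * ploidy
    sig_rows = []
    truth_rows = []
    for s in range(n_seeds):
        kind, aff = planted.get(s, (None, None))
        for cell in range(cells_per_seed):
            barcode = {c: ploidy for c in chroms}
            paint: dict[str, float] = {c: np.nan for c in chroms}
            dapi = euploid_total
            if kind == "aneuploid_gain":
                barcode[aff] += 1
                dapi += 1
            elif kind == "aneuploid_loss":
                barcode[aff] -= 1
                dapi -= 1
            elif kind == "segment_deletion":
                barcode[aff] -= 1  # the broken copy lost its terminal marks
                paint[aff] = ploidy  # confirmatory painting assay on that chromosome
            if noise > 0 and rng.random() < noise:
                c = chroms[int(rng.integers(0, complement))]
                barcode[c] = max(0, barcode[c] + (1 if rng.random() < 0.5 else -1))
            for c in chroms:
                sig_rows.append(
                    {
                        "variety": variety,
                        "seed_id": f"seed{s:03d}",
                        "cell_id": f"cell{cell}",
                        "chromosome": c,
                        "barcode_clusters": barcode[c],
                        "partial_barcode_clusters": 0,
                        "painting_clusters": paint[c],
                        "dapi_total": dapi,
                    }
                )
        truth_rows.append(
            {
                "variety": variety,
                "seed_id": f"seed{s:03d}",
                "call": {
                    None: "EUPLOID",
                    "aneuploid_gain": "ANEUPLOID",
                    "aneuploid_loss": "ANEUPLOID",
                    "segment_deletion": "SEGMENT_DELETION",
                }[kind],
                "affected_chromosome": aff,
                "direction": {"aneuploid_gain": 1, "aneuploid_loss": -1}.get(kind, 0),
            }
        )
    return pd.DataFrame(sig_rows), pd.DataFrame(truth_rows)


def simulate_arm_table(
    n_chromosomes: int = 8,
    varieties: tuple = ("synthetic",),
    rng_seed: int = 0,
    tl_range: tuple = (2.0, 3.0),
    ar_range: tuple = (1.01, 1.70),
) -> pd.DataFrame:
    """Arm-length measurement tables for metacentric-like complements (um)."""
    rng = np.random.default_rng(rng_seed)
    rows = []
    for v in varieties:
        for i in range(n_chromosomes):
            tl = float(rng.uniform(*tl_range))
            ar = float(rng.uniform(*ar_range))
            s = tl / (1 + ar)
            rows.append(
                {"variety": v, "chromosome": f"chr{i + 1}", "L": tl - s, "S": s}
            )
    return pd.DataFrame(rows)
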