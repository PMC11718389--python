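"""Genome and interval input/output with one fixed coordinate convention.

All internal coordinates are 0-based, half-open. Human-readable TSV exports
use 1-based inclusive coordinates and say so in their header, so an interval
``(chrA, 0, 10)`` is written ``chrA 0 10`` in BED and ``chrA 1 10`` in TSV.

A :class:`Genome` holds one sequence per *chromosome copy* (in a polyploid,
every homologous copy is its own FASTA record) together with a homolog-group
mapping that states which copies belong to the same chromosome. Probe design
always runs on one designated copy per chromosome — the longest assembled
copy, with lexicographic tie-breaking.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._kmers import encode

_VALID = frozenset("ACGTN")


class GenomeError(ValueError):
    """Raised for malformed genomes, configs or interval files."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome copy."""

    copy_id: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.stop):
            raise ValueError(
                f"invalid interval [{self.start}, {self.stop}) on {self.copy_id}: "
                "require 0 <= start < stop"
            )

    @property
    def length(self) -> int:
        return self.stop - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.copy_id == other.copy_id
            and self.start <= other.start
            and other.stop <= self.stop
        )


@dataclass
class Genome:
    """Chromosome-copy sequences plus the homolog grouping.

    ``design_copy`` maps each chromosome to the copy used for probe design:
    the longest copy in its homolog group (ties broken by copy_id sort order).
    It is computed on construction; passing it explicitly overrides the rule.
    """

    copies: dict[str, str]
    homolog_groups: dict[str, list[str]]
    design_copy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for chrom, members in self.homolog_groups.items():
            if not members:
                raise GenomeError(f"homolog group {chrom!r} is empty")
            for cid in members:
                if cid in seen:
                    raise GenomeError(
                        f"copy {cid!r} listed in groups {seen[cid]!r} and {chrom!r}; "
                        "each copy must belong to exactly one homolog group"
                    )
                if cid not in self.copies:
                    raise GenomeError(f"record {cid!r} named in homolog config is missing from the genome")
                seen[cid] = chrom
        unassigned = sorted(set(self.copies) - set(seen))
        if unassigned:
            raise GenomeError(f"records not assigned to any homolog group: {', '.join(unassigned)}")
        if not self.design_copy:
            self.design_copy = {
                chrom: min(members, key=lambda c: (-len(self.copies[c]), c))
                for chrom, members in self.homolog_groups.items()
            }

    def length(self, copy_id: str) -> int:
        return len(self.copies[copy_id])

    def group_of(self, copy_id: str) -> str:
        for chrom, members in self.homolog_groups.items():
            if copy_id in members:
                return chrom
        raise GenomeError(f"copy {copy_id!r} not in any homolog group")

    def sequence(self, interval: GenomicInterval) -> str:
        seq = self.copies[interval.copy_id]
        if interval.stop > len(seq):
            raise GenomeError(f"interval {interval} exceeds copy length {len(seq)}")
        return seq[interval.start : interval.stop]


def _check_alphabet(name: str, seq: str) -> None:
    codes = encode(seq)
    bad = np.flatnonzero(codes > 4)
    if bad.size:
        pos = int(bad[0])
        raise GenomeError(
            f"record {name!r} contains invalid character {seq[pos]!r} at position {pos} "
            "(only A/C/G/T/N allowed)"
        )


def load_homolog_config(source: str | Path | dict) -> dict[str, list[str]]:
    """Load a homolog-group mapping: ``chromosome -> [copy ids]`` (YAML)."""
    if isinstance(source, dict):
        mapping = source
    else:
        with open(source) as fh:
            mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise GenomeError("homolog config must map chromosome ids to lists of copy ids")
    out: dict[str, list[str]] = {}
    for chrom, members in mapping.items():
        if isinstance(members, str):
            members = [members]
        out[str(chrom)] = [str(m) for m in members]
    return out


def read_genome(fasta_source, homolog_config) -> Genome:
    """Read a multi-FASTA genome and group its records into homolog groups.

    ``fasta_source`` may be a path or an open text handle; ``homolog_config``
    a mapping or a YAML file path. Duplicate record names, records missing
    from the FASTA, and non-ACGTN characters are all fatal.
    """
    groups = load_homolog_config(homolog_config)
    copies: dict[str, str] = {}
    handle = fasta_source
    close = False
    if not isinstance(fasta_source, io.IOBase):
        handle = open(fasta_source)
        close = True
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in copies:
                raise GenomeError(f"duplicate FASTA record name {rec.id!r}")
            seq = str(rec.seq).upper()
            _check_alphabet(rec.id, seq)
            copies[rec.id] = seq
    finally:
        if close:
            handle.close()
    if not copies:
        raise GenomeError("no FASTA records parsed")
    return Genome(copies=copies, homolog_groups=groups)


def write_genome(genome: Genome, path: str | Path, wrap: int = 80) -> None:
    records = [
        SeqRecord(Seq(genome.copies[cid]), id=cid, description="")
        for cid in genome.copies
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


_TSV_HEADER = "# coordinates: 1-based inclusive"


def write_intervals(intervals, sink, dialect: str = "BED") -> None:
    """Write intervals as BED3 (0-based half-open) or TSV (1-based inclusive).

    The TSV dialect carries a header line naming its coordinate convention to
    keep the off-by-one explicit for human readers.
    """
    d = dialect.upper().replace("-", "").replace("_", "")
    close = False
    if not hasattr(sink, "write"):
        sink = open(sink, "w")
        close = True
    try:
        if d == "BED":
            for iv in intervals:
                sink.write(f"{iv.copy_id}\t{iv.start}\t{iv.stop}\n")
        elif d in ("TSV1BASED", "TSV1"):
            sink.write(_TSV_HEADER + "\n")
            sink.write("copy_id\tstart\tstop\n")
            for iv in intervals:
                sink.write(f"{iv.copy_id}\t{iv.start + 1}\t{iv.stop}\n")
        else:
            raise GenomeError(f"unknown interval dialect {dialect!r}")
    finally:
        if close:
            sink.close()


def read_intervals(source, dialect: str = "BED") -> list[GenomicInterval]:
    d = dialect.upper().replace("-", "").replace("_", "")
    close = False
    if not hasattr(source, "read"):
        source = open(source)
        close = True
    out: list[GenomicInterval] = []
    try:
        for line in source:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("copy_id\t"):
                continue
            fields = line.split("\t")
            cid, a, b = fields[0], int(fields[1]), int(fields[2])
            if d == "BED":
                out.append(GenomicInterval(cid, a, b))
            elif d in ("TSV1BASED", "TSV1"):
                out.append(GenomicInterval(cid, a - 1, b))
            else:
                raise GenomeError(f"unknown interval dialect {dialect!r}")
    finally:
        if close:
            source.close()
    return out
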