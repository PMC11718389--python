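"""Whole-chromosome painting probe extraction.

A painting probe is the *complete* single-copy oligo set of one chromosome
— every composition-clean oligo with no repeat hit and no cross-homolog
match anywhere else in the genome. Unlike barcode regions, the painting set
is not thinned: it tags every homologous copy of the chromosome including
rearranged or broken-off fragments, which is what makes it the arbiter for
segment-deletion calls (a shortened chromosome that lost its terminal
barcode marks still lights up with the paint).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .genome_io import Genome, GenomicInterval
from .oligo_select import (
    CompositionPolicy,
    GenomeIndex,
    OligoCandidate,
    SpecificityPolicy,
    policy_for,
    screen_specificity,
    single_copy_oligos,
    tile_candidates,
)


def paint_chromosome(
    genome: Genome,
    chromosome_id: str,
    policy: SpecificityPolicy | None = None,
    l: int = 45,
    step: int = 5,
    composition: CompositionPolicy = CompositionPolicy(),
    index: GenomeIndex | None = None,
) -> list[OligoCandidate]:
    """All single-copy oligos across the full design copy of one chromosome.

    Hits on the chromosome's own homolog group are permitted (the paint is
    meant to label all copies); any sufficiently similar match elsewhere
    disqualifies. An empty result is a warning, not an error.
    """
    if policy is None:
        policy = policy_for(genome, chromosome_id)
    design = genome.design_copy[chromosome_id]
    full = GenomicInterval(design, 0, genome.length(design))
    cands = tile_candidates(genome, chromosome_id, full, l, step, composition)
    screen_specificity(cands, genome, policy, index=index)
    kept = single_copy_oligos(cands)
    if not kept:
        warnings.warn(
            f"no single-copy oligos found on {chromosome_id}; the chromosome may be "
            "entirely repetitive or shared",
            stacklevel=2,
        )
    return kept


def coverage_summary(
    oligos: list[OligoCandidate], copy_length: int, bin_bp: int = 1_000_000
) -> dict:
    """Oligo count plus a fixed-grid positional histogram (default per Mb)."""
    n_bins = max(1, -(-copy_length // bin_bp))
    hist = np.zeros(n_bins, dtype=int)
    for o in oligos:
        hist[min(o.locus.start // bin_bp, n_bins - 1)] += 1
    return {
        "count": len(oligos),
        "bin_bp": bin_bp,
        "bins": hist.tolist(),
    }


def write_summary_json(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
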