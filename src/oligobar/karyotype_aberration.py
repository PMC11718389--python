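"""Karyotype metrics, arm-ratio classification and aberration calling.

Arm measurements come from image analysis outside this package; the module
ingests a per-chromosome table of long-arm (L) and short-arm (S) lengths
(units arbitrary but consistent within one complement) and derives

* total length  tl = L + S
* arm ratio     AR = L / S                (>= 1 after arm normalization)
* relative length RL = tl / TL x 100     (TL = sum of tl over the complement)

Arm-ratio classes follow the Levan convention with the 1.7 boundary
assigned to metacentric: m (AR <= 1.7), sm (<= 3.0), st (<= 7.0), t (> 7).

Aberration calling consumes per-cell FISH signal-count tables: for every
chromosome in every metaphase cell, how many distinct chromosomes carried
its full barcode, optionally how many carried the painting probe, and the
DAPI-stained total chromosome count. Cells are classified individually and
a per-seed consensus is taken by majority across cells (ties are reported
AMBIGUOUS, never resolved silently). A chromosome with one extra/missing
barcode cluster with a corroborating DAPI total is an aneuploid gain/loss;
a missing barcode cluster with a full painting count indicates a chromosome
that lost its terminal barcode segments — a large segment deletion. Without
painting confirmation a barcode loss on a full complement stays ambiguous.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from enum import Enum

import pandas as pd
from statsmodels.stats.proportion import proportion_confint


class AberrationType(str, Enum):
    EUPLOID = "EUPLOID"
    ANEUPLOID = "ANEUPLOID"
    SEGMENT_DELETION = "SEGMENT_DELETION"
    AMBIGUOUS = "AMBIGUOUS"


ARM_TABLE_COLUMNS = ["variety", "chromosome", "L", "S"]
SIGNAL_TABLE_COLUMNS = [
    "variety",
    "seed_id",
    "cell_id",
    "chromosome",
    "barcode_clusters",
    "partial_barcode_clusters",
    "painting_clusters",
    "dapi_total",
]


def karyotype_metrics(arm_table: pd.DataFrame) -> pd.DataFrame:
    """Derive tl, AR and RL for every complement in an arm-length table.

    Rows with L < S are swapped with a warning (arm labeling error); S == 0
    is fatal. RL is normalized within each variety's complement, so it sums
    to 100 exactly.
    """
    df = arm_table.copy()
    missing = [c for c in ARM_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"arm table missing columns: {missing}")
    if (df["S"] <= 0).any() or (df["L"] <= 0).any():
        raise ValueError("arm lengths must be strictly positive")
    swapped = df["L"] < df["S"]
    if swapped.any():
        warnings.warn(
            f"{int(swapped.sum())} rows had L < S; arms swapped (labeling error)",
            stacklevel=2,
        )
        df.loc[swapped, ["L", "S"]] = df.loc[swapped, ["S", "L"]].values
    df["tl"] = df["L"] + df["S"]
    df["AR"] = df["L"] / df["S"]
    df["RL"] = df.groupby("variety")["tl"].transform(lambda s: s / s.sum() * 100.0)
    df["arm_type"] = df["AR"].map(classify_arm_ratio)
    return df


def classify_arm_ratio(ar: float) -> str:
    """Levan arm-ratio class: m / sm / st / t (boundaries inclusive on the left class)."""
    if ar < 1.0:
        raise ValueError("arm ratio below 1; normalize records first (L >= S)")
    if ar <= 1.7:
        return "m"
    if ar <= 3.0:
        return "sm"
    if ar <= 7.0:
        return "st"
    return "t"


@dataclass(frozen=True)
class AberrationCall:
    variety: str
    seed_id: str
    call: AberrationType
    affected_chromosome: str | None
    direction: int  # +1 gain, -1 loss, 0 otherwise
    evidence: str


def _classify_cell(
    cell: pd.DataFrame,
    chromosomes: list[str],
    ploidy: int,
    euploid_total: int,
    complement_size: int,
) -> tuple[AberrationType, str | None, int, str]:
    counts = dict(zip(cell["chromosome"], cell["barcode_clusters"]))
    missing = [c for c in chromosomes if c not in counts]
    if missing:
        return (AberrationType.AMBIGUOUS, None, 0, f"MISSING_ROWS({','.join(missing)})")
    if len(counts) < complement_size:
        return (
            AberrationType.AMBIGUOUS,
            None,
            0,
            f"INCOMPLETE_COMPLEMENT({len(counts)}/{complement_size})",
        )
    painting = dict(zip(cell["chromosome"], cell["painting_clusters"]))
    dapi = int(cell["dapi_total"].iloc[0])
    deviants = {c: int(counts[c]) for c in chromosomes if int(counts[c]) != ploidy}
    if not deviants:
        if dapi == euploid_total:
            return (AberrationType.EUPLOID, None, 0, "ALL_NORMAL")
        return (AberrationType.AMBIGUOUS, None, 0, f"DAPI_MISMATCH({dapi})")
    if len(deviants) > 1:
        return (
            AberrationType.AMBIGUOUS,
            None,
            0,
            "MULTI_DEVIANT(" + ",".join(sorted(deviants)) + ")",
        )
    chrom, n = next(iter(deviants.items()))
    if n == ploidy + 1:
        if dapi == euploid_total + 1:
            return (AberrationType.ANEUPLOID, chrom, +1, f"GAIN({chrom}:{n})")
        return (AberrationType.AMBIGUOUS, chrom, 0, f"GAIN_DAPI_MISMATCH({chrom}:{dapi})")
    if n == ploidy - 1:
        paint = painting.get(chrom)
        if paint is not None and not pd.isna(paint) and int(paint) == ploidy:
            return (
                AberrationType.SEGMENT_DELETION,
                chrom,
                0,
                f"BARCODE_LOSS_PAINT_OK({chrom})",
            )
        if dapi == euploid_total - 1:
            return (AberrationType.ANEUPLOID, chrom, -1, f"LOSS({chrom}:{n})")
        if dapi == euploid_total:
            # barcode loss on a full complement but no painting confirmation:
            # could be a deletion or a miscounted spread
            return (AberrationType.AMBIGUOUS, chrom, 0, f"BARCODE_LOSS_UNCONFIRMED({chrom})")
        return (AberrationType.AMBIGUOUS, chrom, 0, f"UNRESOLVED_LOSS({chrom})")
    return (AberrationType.AMBIGUOUS, chrom, 0, f"COUNT_OUT_OF_RANGE({chrom}:{n})")


def call_aberrations(
    signal_table: pd.DataFrame, ploidy: int = 4, complement_size: int = 8
) -> pd.DataFrame:
    """Per-seed aberration calls from a per-cell signal-count table.

    Every cell is classified independently; the seed-level call is the
    strict majority of its cells' (call, chromosome, direction) tuples, a
    tie yielding AMBIGUOUS. Euploid means every chromosome shows ``ploidy``
    barcode clusters and the DAPI count equals ``complement_size x ploidy``.
    """
    df = signal_table.copy()
    missing = [c for c in SIGNAL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"signal table missing columns: {missing}")
    chromosomes = sorted(df["chromosome"].unique())
    if len(chromosomes) != complement_size:
        warnings.warn(
            f"signal table names {len(chromosomes)} chromosomes; expected "
            f"complement_size={complement_size}",
            stacklevel=2,
        )
    euploid_total = complement_size * ploidy
    rows = []
    for (variety, seed), seed_df in df.groupby(["variety", "seed_id"], sort=True):
        votes: Counter = Counter()
        evid: dict = {}
        for _, cell_df in seed_df.groupby("cell_id", sort=True):
            call, chrom, direction, evidence = _classify_cell(
                cell_df, chromosomes, ploidy, euploid_total, complement_size
            )
            votes[(call, chrom, direction)] += 1
            evid.setdefault((call, chrom, direction), evidence)
        ranked = votes.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            call, chrom, direction, evidence = (
                AberrationType.AMBIGUOUS,
                None,
                0,
                "CELL_VOTE_TIE",
            )
        else:
            (call, chrom, direction), _ = ranked[0]
            evidence = evid[(call, chrom, direction)]
        rows.append(
            {
                "variety": variety,
                "seed_id": seed,
                "call": call.value,
                "affected_chromosome": chrom,
                "direction": direction,
                "evidence": evidence,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class VariationFrequency:
    pct: float
    ci_low_pct: float
    ci_high_pct: float
    n_variant: int
    n_total: int


def variation_frequency(n_variant: int, n_total: int) -> VariationFrequency:
    """Variant fraction as a percentage (2 dp) with a Wilson 95% CI."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_variant <= n_total):
        raise ValueError("need 0 <= n_variant <= n_total")
    lo, hi = proportion_confint(n_variant, n_total, alpha=0.05, method="wilson")
    return VariationFrequency(
        pct=round(100.0 * n_variant / n_total, 2),
        ci_low_pct=100.0 * lo,
        ci_high_pct=100.0 * hi,
        n_variant=n_variant,
        n_total=n_total,
    )


def frequency_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-variety variation frequencies from a seed-level call table."""
    rows = []
    for variety, sub in calls.groupby("variety", sort=True):
        n = len(sub)
        n_aneu = int((sub["call"] == AberrationType.ANEUPLOID.value).sum())
        n_del = int((sub["call"] == AberrationType.SEGMENT_DELETION.value).sum())
        n_var = n_aneu + n_del
        freq = variation_frequency(n_var, n)
        rows.append(
            {
                "variety": variety,
                "n_seeds": n,
                "n_aneuploid": n_aneu,
                "n_segment_deletion": n_del,
                "n_variant": n_var,
                "variant_pct": freq.pct,
                "ci_low_pct": round(freq.ci_low_pct, 2),
                "ci_high_pct": round(freq.ci_high_pct, 2),
            }
        )
    return pd.DataFrame(rows)
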