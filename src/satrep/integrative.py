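"""Overlap-based secondary analyses around the enrichment matrix.

Peak concordance (reciprocal 50% overlap with called peaks), RNA contig
levels at satellite loci, chromatin-state composition in base pairs, MNase
nucleosome-occupancy comparison against shuffled null placements, and gene
overlap proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import (
    GenomicInterval,
    IntervalSet,
    RepeatInstance,
    overlap_bp,
    reciprocal_overlap,
    shuffle_intervals,
)
from .signal import SignalTrack, mean_signal

logger = logging.getLogger(__name__)

__all__ = [
    "RNAContig",
    "SegmentationRecord",
    "peak_concordance",
    "rna_level",
    "chromatin_state_tally",
    "mnase_occupancy",
    "gene_overlap",
]


@dataclass(frozen=True)
class RNAContig:
    """A block of overlapping mapped RNA reads with its expression level.

    ``level`` is BPKM for long-RNA libraries and RPKM for short-RNA ones.
    """

    interval: GenomicInterval
    level: float
    library: str = "polyA+"

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("expression level must be >= 0")


@dataclass(frozen=True)
class SegmentationRecord:
    """One genome-segmentation interval with its chromatin state label."""

    interval: GenomicInterval
    state: str


def peak_concordance(
    elements: Sequence[RepeatInstance],
    peaks: IntervalSet,
    log2fc: pd.Series | None = None,
    frac: float = 0.5,
    fc_min: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Which elements reciprocally overlap a called peak, and summary counts.

    An element is concordant when some peak shares >= ``frac`` of the length
    of both.  The summary stratifies by enrichment: all elements vs those
    with linear FC >= ``fc_min`` (log2 FC >= log2(fc_min)) when per-element
    log2 FC values are supplied.
    """
    rows = []
    log2_min = float(np.log2(fc_min))
    for e in elements:
        hit = any(
            reciprocal_overlap(e.interval, p, frac) for p in peaks.overlapping(e.interval)
        )
        fc_ok = bool(log2fc is not None and log2fc.get(e.id, 0.0) >= log2_min)
        rows.append({"element_id": e.id, "concordant": hit, "fc_pass": fc_ok})
    df = pd.DataFrame(rows)
    summary = {
        "n_elements": len(df),
        "n_concordant": int(df["concordant"].sum()) if len(df) else 0,
        "n_concordant_fc": int((df["concordant"] & df["fc_pass"]).sum()) if len(df) else 0,
    }
    return df, summary


def rna_level(
    elements: Sequence[RepeatInstance],
    contigs: Sequence[RNAContig],
    weighting: str = "none",
) -> pd.DataFrame:
    """Transcript level at each satellite locus from overlapping RNA contigs.

    The level is the mean BPKM/RPKM over contigs sharing >= 1 base with the
    element — unweighted by default, or weighted by overlap bp with
    ``weighting="overlap_bp"``.  ``has_evidence`` marks any overlap;
    ``n_full_overlap`` counts contigs fully contained in the element (in the
    real data transcripts extend past satellite boundaries, so this stays 0).
    """
    if weighting not in {"none", "overlap_bp"}:
        raise ValueError("weighting must be 'none' or 'overlap_bp'")
    cset = IntervalSet((c.interval for c in contigs), label="contigs")
    by_iv: dict[GenomicInterval, list[RNAContig]] = {}
    for c in contigs:
        by_iv.setdefault(c.interval, []).append(c)
    rows = []
    for e in elements:
        hits = [c for iv in cset.overlapping(e.interval) for c in by_iv[iv]]
        if not hits:
            rows.append({"element_id": e.id, "level": np.nan, "has_evidence": False,
                         "n_contigs": 0, "n_full_overlap": 0})
            continue
        levels = np.array([c.level for c in hits])
        if weighting == "overlap_bp":
            w = np.array([overlap_bp(c.interval, e.interval) for c in hits], dtype=float)
            level = float((levels * w).sum() / w.sum())
        else:
            level = float(levels.mean())
        n_full = sum(
            1 for c in hits
            if c.interval.start >= e.start and c.interval.end <= e.end
        )
        rows.append({"element_id": e.id, "level": level, "has_evidence": True,
                     "n_contigs": len(hits), "n_full_overlap": n_full})
    return pd.DataFrame(rows)


def chromatin_state_tally(
    elements: Sequence[RepeatInstance],
    segments: Sequence[SegmentationRecord],
) -> tuple[dict[str, int], dict[str, int]]:
    """Base pairs of element sequence per chromatin state.

    Segments must be non-overlapping within the segmentation (fatal
    otherwise).  Element bases outside every segment go to the
    ``"unsegmented"`` bucket.  Also returns the genome-wide bp per state for
    relative-representation comparisons.
    """
    by_chrom: dict[str, list[SegmentationRecord]] = {}
    for s in segments:
        by_chrom.setdefault(s.interval.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.interval.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.interval.start < prev.interval.end:
                raise ValueError(
                    f"segmentation intervals overlap on {chrom}: "
                    f"[{prev.interval.start},{prev.interval.end}) and "
                    f"[{cur.interval.start},{cur.interval.end})"
                )
    seg_set = IntervalSet((s.interval for s in segments), label="segments")
    state_of: dict[GenomicInterval, str] = {s.interval: s.state for s in segments}

    tally: dict[str, int] = {}
    for e in elements:
        covered = 0
        for iv in seg_set.overlapping(e.interval):
            ov = overlap_bp(iv, e.interval)
            covered += ov
            st = state_of[iv]
            tally[st] = tally.get(st, 0) + ov
        gap = e.length - covered
        if gap > 0:
            tally["unsegmented"] = tally.get("unsegmented", 0) + gap

    genome_bp: dict[str, int] = {}
    for s in segments:
        genome_bp[s.state] = genome_bp.get(s.state, 0) + s.interval.length
    return tally, genome_bp


def mnase_occupancy(
    elements: Sequence[RepeatInstance],
    mnase_track: SignalTrack,
    chrom_sizes: dict[str, int],
    exclude: IntervalSet | None = None,
    n_null: int = 1,
    seed: int | np.random.Generator = 0,
    log2fc: pd.Series | None = None,
) -> dict:
    """Nucleosome occupancy at elements vs shuffled null placements.

    Observed per-element mean MNase signal; a null distribution of means over
    ``n_null`` rounds of length-preserving random placement avoiding
    ``exclude``; and (when per-element log2 FC is given) Pearson and Spearman
    correlations between occupancy and enrichment.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = pd.Series(
        {e.id: mean_signal(mnase_track, e.interval) for e in elements}, name="mnase"
    )
    null_vals: list[float] = []
    for _ in range(n_null):
        placed = shuffle_intervals(list(elements), chrom_sizes, exclude, seed=rng)
        null_vals.extend(mean_signal(mnase_track, iv) for iv in placed)
    result = {"observed": observed, "null": np.asarray(null_vals)}
    if log2fc is not None:
        common = observed.index.intersection(log2fc.index)
        x = observed.loc[common].to_numpy()
        y = log2fc.loc[common].to_numpy()
        if len(common) >= 3 and np.std(x) > 0 and np.std(y) > 0:
            result["pearson_r"] = float(stats.pearsonr(x, y).statistic)
            result["spearman_rho"] = float(stats.spearmanr(x, y).statistic)
        else:
            result["pearson_r"] = np.nan
            result["spearman_rho"] = np.nan
    return result


def gene_overlap(
    elements: Sequence[RepeatInstance], genes: IntervalSet
) -> tuple[int, float]:
    """How many elements share >= 1 bp with a gene, and the exact proportion."""
    if not elements:
        return 0, 0.0
    n = sum(1 for e in elements if genes.overlaps(e.interval))
    return n, n / len(elements)
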