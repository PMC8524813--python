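"""Ambiguously mapped reads and consensus-dimer re-mapping enrichment.

Highly repetitive satellite arrays cannot be quantified from genome-mapped
coverage: their reads carry MAPQ 0 (multiple equally good placements).  The
pipeline instead (1) removes duplicates and unmapped reads and merges
replicates, (2) downsamples ChIP and input to the same read count,
(3) extracts the MAPQ-0 reads and re-maps them onto satellite consensus
*dimers* (monomer concatenated with itself, so reads spanning the monomer
junction still align end-to-end), and (4) reports per-family enrichment as
the ratio of aligned ChIP to aligned input reads.

The built-in matcher scans every ungapped end-to-end placement of a read on
each dimer (both strands) and accepts the family with the fewest mismatches
if the mismatch rate is within a cap (default 0.1).  A SAM stream produced
by an external sensitive end-to-end aligner can be ingested instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .annotations import GenomicInterval, IntervalSet, RepeatInstance

logger = logging.getLogger(__name__)

__all__ = [
    "ReadRecord",
    "ConsensusReference",
    "ConsensusEnrichment",
    "read_sam",
    "load_consensus_fasta",
    "mapq0_fraction",
    "element_mapq0",
    "preprocess_alignments",
    "downsample",
    "align_to_consensus",
    "consensus_enrichment",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """One alignment record (genome coordinates 0-based; None if unmapped)."""

    read_id: str
    chrom: str | None
    pos: int | None
    mapq: int
    sequence: str
    duplicate: bool = False

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")

    @property
    def unmapped(self) -> bool:
        return self.chrom is None

    @property
    def interval(self) -> GenomicInterval | None:
        if self.unmapped:
            return None
        return GenomicInterval(self.chrom, self.pos, self.pos + len(self.sequence))


@dataclass(frozen=True)
class ConsensusReference:
    """Satellite family consensus monomer and its self-concatenated dimer."""

    family: str
    monomer: str

    @property
    def dimer(self) -> str:
        return self.monomer + self.monomer


@dataclass
class ConsensusEnrichment:
    """Per-family re-mapping enrichment of ChIP over input."""

    family: str
    chip_aligned: int
    input_aligned: int
    chip_total: int
    input_total: int
    fc: float | None  # None when input_aligned == 0 but chip_aligned > 0
    alignment_rate: float
    uniformity: float | None = None
    uniformity_flag: bool = False
    no_reads: bool = False


def read_sam(path) -> list[ReadRecord]:
    """Read a SAM (or BAM) file into ReadRecords."""
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            seq = aln.query_sequence or ""
            out.append(
                ReadRecord(
                    read_id=aln.query_name,
                    chrom=None if aln.is_unmapped else aln.reference_name,
                    pos=None if aln.is_unmapped else aln.reference_start,
                    mapq=aln.mapping_quality,
                    sequence=seq.upper(),
                    duplicate=aln.is_duplicate,
                )
            )
    return out


def load_consensus_fasta(path) -> list[ConsensusReference]:
    """Load satellite monomer consensus sequences from FASTA."""
    refs = [
        ConsensusReference(family=rec.id, monomer=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not refs:
        raise ValueError(f"no sequences in consensus FASTA {path}")
    return refs


def mapq0_fraction(reads: Sequence[ReadRecord]) -> tuple[float | None, int]:
    """Fraction of reads with MAPQ 0 among the given reads.

    Returns (fraction, n_reads); fraction is None when no reads overlap so
    low-support elements can be distinguished from fully unique ones.
    """
    n = len(reads)
    if n == 0:
        return None, 0
    return sum(1 for r in reads if r.mapq == 0) / n, n


def element_mapq0(
    reads: Sequence[ReadRecord], elements: Sequence[RepeatInstance]
) -> pd.DataFrame:
    """Per-element MAPQ-0 fraction for mapped reads overlapping each element."""
    eset = IntervalSet((e.interval for e in elements), label="elements")
    by_id: dict[str, list[ReadRecord]] = {e.id: [] for e in elements}
    iv_to_ids: dict[GenomicInterval, list[str]] = {}
    for e in elements:
        iv_to_ids.setdefault(e.interval, []).append(e.id)
    for r in reads:
        iv = r.interval
        if iv is None:
            continue
        for hit in eset.overlapping(iv):
            for eid in iv_to_ids[hit]:
                by_id[eid].append(r)
    rows = []
    for e in elements:
        frac, n = mapq0_fraction(by_id[e.id])
        rows.append({"element_id": e.id, "mapq0_fraction": np.nan if frac is None else frac,
                     "n_reads": n, "low_support": n < 6})
    return pd.DataFrame(rows)


def preprocess_alignments(replicates: Sequence[Sequence[ReadRecord]]) -> list[ReadRecord]:
    """Drop duplicate and unmapped reads, then merge the replicates."""
    merged = [r for rep in replicates for r in rep if not r.duplicate and not r.unmapped]
    if not merged:
        raise ValueError("no reads remain after removing duplicates and unmapped reads")
    return merged


def downsample(
    reads: Sequence[ReadRecord], n: int, seed: int | np.random.Generator = 0,
    label: str = "reads",
) -> list[ReadRecord]:
    """Uniform sample of exactly n reads without replacement (order preserved)."""
    if n > len(reads):
        raise ValueError(
            f"cannot downsample {label}: requested {n} > available {len(reads)}"
        )
    if n == len(reads):
        return list(reads)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=n, replace=False))
    return [reads[i] for i in idx]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _min_mismatches(read: np.ndarray, dimer_windows: np.ndarray, is_n: np.ndarray) -> int:
    """Fewest mismatches over all end-to-end placements; N always mismatches."""
    mm = ((dimer_windows != read) | is_n).sum(axis=1)
    return int(mm.min())


def align_to_consensus(
    reads: Sequence[ReadRecord],
    refs: Sequence[ConsensusReference],
    max_mismatch_rate: float = 0.1,
) -> dict:
    """Assign each read to the best-matching consensus dimer.

    A read aligns to a family if some ungapped end-to-end placement on the
    dimer (either strand) has mismatch rate <= ``max_mismatch_rate``.  Each
    read goes to the single family with the fewest mismatches; ties between
    families leave the read unassigned (counted separately).  Per-family
    per-position coverage of best placements is accumulated so non-uniform
    pile-ups (e.g. low-complexity inserts) can be flagged.

    Returns a dict with keys ``counts`` (family -> aligned reads), ``total``,
    ``aligned``, ``tied``, ``alignment_rate`` and ``coverage``
    (family -> per-dimer-position depth array).
    """
    if not refs:
        raise ValueError("empty consensus reference set")
    fams = [r.family for r in refs]
    enc = {}
    for ref in refs:
        d = _encode(ref.dimer)
        enc[ref.family] = d
    counts = {f: 0 for f in fams}
    coverage = {f: np.zeros(len(enc[f]), dtype=np.int64) for f in fams}
    tied = 0
    total = 0
    win_cache: dict[tuple[str, int], np.ndarray] = {}
    for read in reads:
        seq = read.sequence.upper()
        L = len(seq)
        if L == 0:
            continue
        total += 1
        fwd = _encode(seq)
        rev = _encode(revcomp(seq))
        best_mm = None
        best_fams: list[str] = []
        best_place: dict[str, tuple[int, bool]] = {}
        for fam in fams:
            dimer = enc[fam]
            if L > len(dimer):
                continue
            key = (fam, L)
            if key not in win_cache:
                win_cache[key] = np.lib.stride_tricks.sliding_window_view(dimer, L)
            windows = win_cache[key]
            fam_best = None
            fam_off = 0
            fam_rev = False
            for arr, is_rev in ((fwd, False), (rev, True)):
                is_n = arr == ord("N")
                mm = ((windows != arr) | is_n).sum(axis=1)
                off = int(mm.argmin())
                if fam_best is None or mm[off] < fam_best:
                    fam_best, fam_off, fam_rev = int(mm[off]), off, is_rev
            if fam_best is None or fam_best / L > max_mismatch_rate:
                continue
            if best_mm is None or fam_best < best_mm:
                best_mm = fam_best
                best_fams = [fam]
            elif fam_best == best_mm:
                best_fams.append(fam)
            best_place[fam] = (fam_off, fam_rev)
        if best_mm is None:
            continue
        if len(best_fams) > 1:
            tied += 1
            continue
        fam = best_fams[0]
        counts[fam] += 1
        off, _ = best_place[fam]
        coverage[fam][off:off + L] += 1
    aligned = sum(counts.values())
    return {
        "counts": counts,
        "total": total,
        "aligned": aligned,
        "tied": tied,
        "alignment_rate": aligned / total if total else 0.0,
        "coverage": coverage,
    }


def _uniformity(cov: np.ndarray, window: int = 10) -> float | None:
    """Max/mean of windowed coverage along the dimer (None if no coverage)."""
    if cov.sum() == 0:
        return None
    k = min(window, len(cov))
    kernel = np.ones(k) / k
    smooth = np.convolve(cov.astype(float), kernel, mode="valid")
    mean = smooth.mean()
    return float(smooth.max() / mean) if mean > 0 else None


def consensus_enrichment(
    chip: dict,
    input_: dict,
    uniformity_threshold: float = 10.0,
) -> list[ConsensusEnrichment]:
    """Per-family ChIP/input enrichment from align_to_consensus results.

    Both inputs must come from read sets downsampled to the same total (the
    normalization is defeated otherwise — fatal).  fc = chip_aligned /
    input_aligned; a family with ChIP reads but no input reads gets fc=None
    with a flag; a family with no reads at all is reported ``no_reads``.
    """
    if chip["total"] != input_["total"]:
        raise ValueError(
            f"ChIP and input totals differ ({chip['total']} vs {input_['total']}); "
            "downsample both to the same read count first"
        )
    out = []
    for fam in chip["counts"]:
        c = chip["counts"][fam]
        i = input_["counts"].get(fam, 0)
        if c == 0 and i == 0:
            fc = None
            no_reads = True
        elif i == 0:
            fc = None
            no_reads = False
        else:
            fc = c / i
            no_reads = False
        cov = chip["coverage"][fam] + input_["coverage"].get(fam, 0)
        uni = _uniformity(np.asarray(cov))
        out.append(
            ConsensusEnrichment(
                family=fam,
                chip_aligned=c,
                input_aligned=i,
                chip_total=chip["total"],
                input_total=input_["total"],
                fc=fc,
                alignment_rate=chip["alignment_rate"],
                uniformity=uni,
                uniformity_flag=bool(uni is not None and uni > uniformity_threshold),
                no_reads=no_reads,
            )
        )
    return out
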