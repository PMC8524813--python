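"""Coverage tracks and genome-median-normalized fold-change enrichment.

The enrichment statistic for a satellite element is

    log2FC = max(0, log2( (m_chip / M_chip + 1) / (m_input / M_input + 1) ))

where ``m`` is the length-weighted mean signal over the element and ``M`` the
median of the per-base signal distribution over the analyzed chromosomes
(uncovered bases count as 0 by default).  Dividing by the genome median
normalizes sequencing coverage between samples; the +1 pseudocount avoids
division by zero; negative log2 values correspond to input stronger than
ChIP, considered nonspecific and clamped to zero.  Precomputed fold-change
tracks (the mouse case) skip normalization: the element value is simply the
length-weighted mean of the linear FC track.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import GenomicInterval, RepeatInstance

logger = logging.getLogger(__name__)

__all__ = [
    "SignalTrack",
    "SampleRecord",
    "EnrichmentMatrix",
    "WindowProfile",
    "read_bedgraph",
    "mean_signal",
    "genome_median",
    "normalize_value",
    "clamped_log2_fc",
    "element_enrichment",
    "element_fc_from_fc_track",
    "window_profile",
    "build_enrichment_matrix",
]


class SignalTrack:
    """Piecewise-constant non-negative signal, one run array per chromosome.

    Runs are stored as sorted, non-overlapping (starts, ends, values) arrays;
    bases not covered by any run have implicit value 0.  ``chrom_sizes``
    bounds each chromosome; when not supplied it is inferred as the last
    covered base of each chromosome.
    """

    def __init__(self, runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                 chrom_sizes: dict[str, int] | None = None):
        self.runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (s, e, v) in runs.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=np.float64)
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if np.any(e <= s):
                raise ValueError(f"{chrom}: runs must have end > start")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"{chrom}: runs overlap")
            if np.any(v < 0):
                n_neg = int((v < 0).sum())
                logger.warning("%s: flooring %d negative run value(s) at 0", chrom, n_neg)
                v = np.maximum(v, 0.0)
            self.runs[chrom] = (s, e, v)
        if chrom_sizes is None:
            chrom_sizes = {c: int(e[-1]) for c, (s, e, v) in self.runs.items() if len(e)}
        self.chrom_sizes = dict(chrom_sizes)
        self._median_cache: dict[tuple[str, ...], float] = {}

    @property
    def chroms(self) -> list[str]:
        return sorted(self.runs)

    def scaled(self, c: float) -> "SignalTrack":
        """Return a copy with every run value multiplied by c > 0."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return SignalTrack(
            {ch: (s.copy(), e.copy(), v * c) for ch, (s, e, v) in self.runs.items()},
            chrom_sizes=self.chrom_sizes,
        )


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one sample column of the enrichment matrix."""

    sample_id: str
    assay: str  # ChIP | input | FC_track
    mark: str = "H3K9me3"
    group: str = ""  # karyotype (normal/cancer) or developmental stage
    tissue: str = ""
    sex: str = ""
    stage: str = ""


@dataclass
class EnrichmentMatrix:
    """Elements x samples clamped log2 fold-change values plus metadata."""

    values: pd.DataFrame  # rows: element ids, cols: sample ids
    metadata: pd.DataFrame  # index: sample ids

    def __post_init__(self) -> None:
        if not self.values.index.is_unique or not self.values.columns.is_unique:
            raise ValueError("row/column labels must be unique")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("enrichment values must be finite")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("enrichment values must be >= 0 (clamped log2 FC)")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)}")

    def groups(self, column: str = "group") -> pd.Series:
        return self.metadata.loc[self.values.columns, column]

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="element_id",
                           float_format="%.6g")

    @classmethod
    def from_tsv(cls, matrix_path, metadata_path) -> "EnrichmentMatrix":
        vals = pd.read_csv(matrix_path, sep="\t", index_col="element_id")
        meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id",
                           keep_default_na=False)
        return cls(values=vals, metadata=meta)


@dataclass
class WindowProfile:
    """Equal-window fold-change profile over an element plus its flanks."""

    element_id: str
    region: GenomicInterval
    boundaries: np.ndarray  # n_windows + 1 ints partitioning the region
    log2fc: np.ndarray  # per-window clamped log2 FC
    clipped: bool = False

    @property
    def n_windows(self) -> int:
        return len(self.log2fc)

    def to_frame(self, sample_id: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "element": self.element_id,
                "sample": sample_id,
                "window_index": np.arange(self.n_windows),
                "window_start": self.boundaries[:-1],
                "window_end": self.boundaries[1:],
                "log2fc": self.log2fc,
            }
        )


def read_bedgraph(path, chrom_sizes: dict[str, int] | None = None) -> SignalTrack:
    """Read a 4-column bedGraph (or a bigWig, by extension) into a SignalTrack."""
    p = str(path)
    if p.endswith((".bw", ".bigwig", ".bigWig")):
        return _read_bigwig(p)
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": np.float64},
    )
    runs = {
        str(chrom): (g["start"].to_numpy(), g["end"].to_numpy(), g["value"].to_numpy())
        for chrom, g in df.groupby("chrom", sort=True)
    }
    return SignalTrack(runs, chrom_sizes=chrom_sizes)


def _read_bigwig(path: str) -> SignalTrack:
    import pyBigWig  # optional dependency

    bw = pyBigWig.open(path)
    runs = {}
    sizes = {}
    for chrom, size in bw.chroms().items():
        ivs = bw.intervals(chrom) or []
        if ivs:
            s, e, v = (np.array(x) for x in zip(*ivs))
            runs[chrom] = (s, e, v)
        sizes[chrom] = size
    bw.close()
    return SignalTrack(runs, chrom_sizes=sizes)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            s, e, v = track.runs[chrom]
            for si, ei, vi in zip(s, e, v):
                fh.write(f"{chrom}\t{si}\t{ei}\t{vi:.6g}\n")


def mean_signal(track: SignalTrack, interval: GenomicInterval) -> float:
    """Length-weighted mean of track values over every base of the interval.

    Uncovered bases count as 0.  Intervals extending past the chromosome end
    are clipped with a warning; a chromosome absent from the track yields 0.
    """
    if interval.chrom not in track.runs:
        logger.warning("chromosome %s absent from track; mean_signal -> 0", interval.chrom)
        return 0.0
    size = track.chrom_sizes.get(interval.chrom)
    lo, hi = interval.start, interval.end
    if size is not None and hi > size:
        logger.warning("interval %s:[%d,%d) clipped to chromosome size %d",
                       interval.chrom, lo, hi, size)
        hi = size
        if hi <= lo:
            return 0.0
    s, e, v = track.runs[interval.chrom]
    i0 = np.searchsorted(e, lo, side="right")
    i1 = np.searchsorted(s, hi, side="left")
    if i1 <= i0:
        return 0.0
    ov = np.minimum(e[i0:i1], hi) - np.maximum(s[i0:i1], lo)
    return float((ov * v[i0:i1]).sum() / (interval.end - interval.start))


def genome_median(track: SignalTrack, chroms: Sequence[str],
                  include_zeros: bool = True) -> float:
    """Median of the per-base value distribution over the given chromosomes.

    Computed from run lengths without per-base expansion; bases not covered
    by any run contribute value 0 when ``include_zeros`` (the default — the
    density graphs this pipeline consumes leave genuine gaps).  Even total
    base counts take the mean of the central pair.  A zero median is fatal:
    the track is degenerate and normalization by it is meaningless.
    """
    chroms = list(chroms)
    if not chroms:
        raise ValueError("chroms must be nonempty")
    key = (tuple(sorted(chroms)), include_zeros)
    if key in track._median_cache:
        return track._median_cache[key]
    vals: list[np.ndarray] = []
    wts: list[np.ndarray] = []
    for chrom in chroms:
        s, e, v = track.runs.get(chrom, (np.array([], dtype=np.int64),) * 2 + (np.array([]),))
        lengths = (e - s).astype(np.float64)
        vals.append(v)
        wts.append(lengths)
        if include_zeros:
            size = track.chrom_sizes.get(chrom, int(e[-1]) if len(e) else 0)
            gap = size - lengths.sum()
            if gap > 0:
                vals.append(np.array([0.0]))
                wts.append(np.array([float(gap)]))
    values = np.concatenate(vals) if vals else np.array([])
    weights = np.concatenate(wts) if wts else np.array([])
    if values.size == 0 or weights.sum() <= 0:
        raise ValueError("track is empty on the requested chromosomes")
    med = _weighted_median(values, weights)
    if med == 0:
        raise ValueError(
            "genome median signal is 0 — degenerate track; check coverage or "
            "set include_zeros=False if gaps should not count"
        )
    track._median_cache[key] = med
    return med


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Median of the expanded distribution where values[i] repeats weights[i] times."""
    order = np.argsort(values, kind="stable")
    values = values[order]
    weights = weights[order].astype(np.int64)
    n = int(weights.sum())
    cum = np.cumsum(weights)
    if n % 2 == 1:
        rank = n // 2  # 0-based middle
        return float(values[np.searchsorted(cum, rank + 1)])
    r1, r2 = n // 2 - 1, n // 2
    v1 = values[np.searchsorted(cum, r1 + 1)]
    v2 = values[np.searchsorted(cum, r2 + 1)]
    return float((v1 + v2) / 2.0)


def normalize_value(mean_sig: float, median: float) -> float:
    """Coverage-normalized signal with +1 pseudocount: mean/median + 1 (>= 1)."""
    if median <= 0:
        raise ValueError("median must be positive")
    return mean_sig / median + 1.0


def clamped_log2_fc(chip_norm: float, input_norm: float) -> float:
    """max(0, log2(chip_norm / input_norm)); negative log2 FC is nonspecific."""
    return max(0.0, float(np.log2(chip_norm / input_norm)))


def element_enrichment(
    chip: SignalTrack,
    input_: SignalTrack,
    instances: Sequence[RepeatInstance],
    chroms: Sequence[str] | None = None,
    include_zeros: bool = True,
) -> pd.Series:
    """Per-element clamped log2 FC for one paired ChIP/input sample.

    ``chroms`` defaults to all chromosomes carrying instances; genome medians
    are computed once per track over that set and cached on the track.
    """
    if chroms is None:
        chroms = sorted({i.chrom for i in instances})
    med_c = genome_median(chip, chroms, include_zeros)
    med_i = genome_median(input_, chroms, include_zeros)
    out = {}
    for inst in instances:
        nc = normalize_value(mean_signal(chip, inst.interval), med_c)
        ni = normalize_value(mean_signal(input_, inst.interval), med_i)
        out[inst.id] = clamped_log2_fc(nc, ni)
    return pd.Series(out, name="log2fc")


def element_fc_from_fc_track(
    fc_track: SignalTrack,
    instances: Sequence[RepeatInstance],
    scale: str = "log2",
) -> pd.Series:
    """Per-element mean of a precomputed linear fold-change track.

    ``scale="linear"`` returns the length-weighted mean FC itself (used for
    stage-mean summaries); ``scale="log2"`` returns max(0, log2(mean FC))
    for use in the enrichment matrix.
    """
    if scale not in {"linear", "log2"}:
        raise ValueError("scale must be 'linear' or 'log2'")
    vals = {i.id: mean_signal(fc_track, i.interval) for i in instances}
    s = pd.Series(vals, name="fc")
    if scale == "linear":
        return s
    with np.errstate(divide="ignore"):
        return pd.Series(np.maximum(0.0, np.log2(s.where(s > 0, np.nan))).fillna(0.0),
                         index=s.index, name="log2fc")


def _window_boundaries(start: int, end: int, n: int) -> np.ndarray:
    """n+1 integer boundaries tiling [start, end) into windows differing <= 1 bp."""
    length = end - start
    return start + (np.arange(n + 1) * length) // n


def window_profile(
    chip: SignalTrack,
    input_: SignalTrack,
    element: GenomicInterval,
    element_id: str = "",
    min_windows: int = 50,
    n_windows: int | None = None,
    chroms: Sequence[str] | None = None,
    include_zeros: bool = True,
) -> WindowProfile:
    """Clamped log2 FC in equal windows over the element plus one-length flanks.

    The element is extended by its own length up- and downstream, clipped at
    chromosome bounds (flagged), and split into ``max(min_windows, n_windows)``
    consecutive non-overlapping windows whose integer lengths differ by at
    most 1 bp and sum exactly to the region length.
    """
    n = max(min_windows, n_windows or 0)
    L = element.length
    size = chip.chrom_sizes.get(element.chrom, element.end + L)
    lo = element.start - L
    hi = element.end + L
    clipped = False
    if lo < 0:
        lo, clipped = 0, True
    if hi > size:
        hi, clipped = size, True
    if clipped:
        logger.info("window profile region for %s clipped to [%d,%d)", element_id, lo, hi)
    region_len = hi - lo
    if region_len < n:
        logger.warning("region length %d < %d windows; reducing window count", region_len, n)
        n = region_len
    region = GenomicInterval(element.chrom, lo, hi, element.strand)
    bounds = _window_boundaries(lo, hi, n)
    if chroms is None:
        chroms = [element.chrom]
    med_c = genome_median(chip, chroms, include_zeros)
    med_i = genome_median(input_, chroms, include_zeros)
    vals = np.empty(n)
    for k in range(n):
        w = GenomicInterval(element.chrom, int(bounds[k]), int(bounds[k + 1]))
        nc = normalize_value(mean_signal(chip, w), med_c)
        ni = normalize_value(mean_signal(input_, w), med_i)
        vals[k] = clamped_log2_fc(nc, ni)
    return WindowProfile(element_id=element_id, region=region,
                         boundaries=bounds, log2fc=vals, clipped=clipped)


def build_enrichment_matrix(
    columns: dict[str, pd.Series], samples: Sequence[SampleRecord]
) -> EnrichmentMatrix:
    """Assemble per-sample element series into an EnrichmentMatrix."""
    meta = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id, "assay": s.assay, "mark": s.mark,
                "group": s.group, "tissue": s.tissue, "sex": s.sex,
                "stage": s.stage,
            }
            for s in samples
        ]
    ).set_index("sample_id")
    vals = pd.DataFrame(columns)
    return EnrichmentMatrix(values=vals, metadata=meta)
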