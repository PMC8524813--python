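"""Repeat annotations and interval algebra.

Satellite-DNA instances come from UCSC-style RepeatMasker (rmsk) tables.
Before any signal is quantified they are filtered against a blocklist of
problematic genomic regions (any shared base excludes an instance) and,
optionally, restricted to autosomes so that samples of different sex remain
comparable.  All coordinates in this package are 0-based half-open (BED
convention); rmsk genoStart/genoEnd are consumed as already 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "RepeatInstance",
    "IntervalSet",
    "parse_rmsk",
    "read_bed",
    "filter_blocklist",
    "filter_chromosomes",
    "reciprocal_overlap",
    "overlap_bp",
    "shuffle_intervals",
    "write_instances",
]

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}
MITO_CHROMS = {"chrM", "chrMT", "M", "MT"}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``.

    Strand is informational only: signal tracks are unstranded and strand
    never enters any computation.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"strand must be one of +,-,. got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatInstance:
    """One annotated repeat element admitted to (or excluded from) analysis."""

    interval: GenomicInterval
    name: str
    family_class: str
    id: str
    blocklisted: bool = False

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases between two intervals (0 if different chrom)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class IntervalSet:
    """Chromosome-indexed interval collection with O(log n + k) overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str = ""):
        self.label = label
        self._trees: dict[str, IntervalTree] = {}
        self._intervals: list[GenomicInterval] = []
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._intervals.append(iv)
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self):
        return iter(self._intervals)

    @property
    def chroms(self) -> set[str]:
        return set(self._trees)

    def overlapping(self, iv: GenomicInterval) -> list[GenomicInterval]:
        """All member intervals sharing >= 1 base with ``iv``."""
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(iv.start, iv.end)]

    def overlaps(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return False
        return tree.overlaps(iv.start, iv.end)

    def overlap_bp(self, iv: GenomicInterval) -> int:
        """Bases of ``iv`` covered by the union of member intervals."""
        hits = self.overlapping(iv)
        if not hits:
            return 0
        segs = sorted((max(h.start, iv.start), min(h.end, iv.end)) for h in hits)
        total = 0
        cur_s, cur_e = segs[0]
        for s, e in segs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
        return total


# UCSC rmsk table columns, with and without the leading bin column.
_RMSK_COLS = [
    "swScore", "milliDiv", "milliDel", "milliIns", "genoName", "genoStart",
    "genoEnd", "genoLeft", "strand", "repName", "repClass", "repFamily",
    "repStart", "repEnd", "repLeft", "id",
]


def parse_rmsk(
    source,
    class_filter: str | None = "Satellite",
    on_error: str = "skip",
) -> list[RepeatInstance]:
    """Parse a UCSC rmsk-format table into :class:`RepeatInstance` records.

    Parameters
    ----------
    source:
        Path or open text stream of a tab-separated rmsk table (16 columns,
        or 17 with the leading UCSC bin column — auto-detected).
    class_filter:
        Keep only rows whose repClass equals this label (default "Satellite");
        ``None`` keeps every row.
    on_error:
        "skip" reports malformed rows with their line number and drops them;
        "raise" makes them fatal.

    Returns instances sorted by (chrom, start) with deterministic ids
    ``chrom:start-end:name``; identical rows get a numeric suffix.
    """
    if on_error not in {"skip", "raise"}:
        raise ValueError("on_error must be 'skip' or 'raise'")
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        stream = open(source, "rt")
        close = True
    else:
        stream = source
    raw: list[tuple[str, int, int, str, str, str]] = []
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == len(_RMSK_COLS) + 1:
                fields = fields[1:]  # leading bin column
            elif len(fields) != len(_RMSK_COLS):
                raise ValueError(
                    f"rmsk table: line {lineno} has {len(fields)} columns, "
                    f"expected {len(_RMSK_COLS)} or {len(_RMSK_COLS) + 1}"
                )
            row = dict(zip(_RMSK_COLS, fields))
            try:
                chrom = row["genoName"]
                start = int(row["genoStart"])
                end = int(row["genoEnd"])
                strand = row["strand"] if row["strand"] in {"+", "-"} else "."
                if not chrom or start < 0 or end <= start:
                    raise ValueError("invalid coordinates")
            except ValueError as exc:
                if on_error == "raise":
                    raise ValueError(f"rmsk table: malformed line {lineno}: {exc}") from exc
                logger.warning("rmsk table: skipping malformed line %d (%s)", lineno, exc)
                continue
            if class_filter is not None and row["repClass"] != class_filter:
                continue
            raw.append((chrom, start, end, strand, row["repName"], row["repClass"]))
    finally:
        if close:
            stream.close()

    raw.sort(key=lambda r: (r[0], r[1], r[2], r[4]))
    counts: dict[str, int] = {}
    out: list[RepeatInstance] = []
    for chrom, start, end, strand, name, cls in raw:
        base = f"{chrom}:{start}-{end}:{name}"
        n = counts.get(base, 0)
        counts[base] = n + 1
        uid = base if n == 0 else f"{base}#{n}"
        out.append(
            RepeatInstance(
                interval=GenomicInterval(chrom, start, end, strand),
                name=name,
                family_class=cls,
                id=uid,
            )
        )
    return out


def read_bed(source, label: str = "") -> IntervalSet:
    """Read BED3/BED4/BED6 into an IntervalSet.

    A name column (BED4+) is preserved on the returned intervals'
    companion attribute mapping ``set.names``; a score column (BED5+/BED6)
    in ``set.scores``.  Strand (column 6) is parsed when present.
    """
    df = pd.read_csv(source, sep="\t", header=None, comment="#", dtype=str)
    iset = IntervalSet(label=label)
    names: dict[GenomicInterval, str] = {}
    scores: dict[GenomicInterval, float] = {}
    ncol = df.shape[1]
    for row in df.itertuples(index=False):
        strand = row[5] if ncol >= 6 and row[5] in {"+", "-"} else "."
        iv = GenomicInterval(row[0], int(row[1]), int(row[2]), strand)
        iset.add(iv)
        if ncol >= 4:
            names[iv] = row[3]
        if ncol >= 5:
            try:
                scores[iv] = float(row[4])
            except (TypeError, ValueError):
                pass
    iset.names = names  # type: ignore[attr-defined]
    iset.scores = scores  # type: ignore[attr-defined]
    return iset


def filter_blocklist(
    instances: Sequence[RepeatInstance], blocklist: IntervalSet
) -> tuple[list[RepeatInstance], list[RepeatInstance]]:
    """Split instances into (kept, removed) by blocklist overlap.

    Any overlap — a single shared base under half-open semantics — removes an
    instance; touching intervals do not overlap.  Chromosomes absent from the
    blocklist are treated as having no overlap (logged at debug level).
    """
    kept: list[RepeatInstance] = []
    removed: list[RepeatInstance] = []
    missing: set[str] = set()
    for inst in instances:
        if inst.chrom not in blocklist.chroms:
            missing.add(inst.chrom)
        if blocklist.overlaps(inst.interval):
            removed.append(replace(inst, blocklisted=True))
        else:
            kept.append(replace(inst, blocklisted=False))
    if missing:
        logger.debug(
            "blocklist has no intervals on %d chromosome(s): %s",
            len(missing), ", ".join(sorted(missing)),
        )
    return kept, removed


def filter_chromosomes(
    instances: Sequence[RepeatInstance],
    mode: str = "autosomes_only",
    chroms: Sequence[str] | None = None,
) -> list[RepeatInstance]:
    """Drop instances on excluded chromosomes, preserving order.

    mode "autosomes_only" excludes sex and mitochondrial chromosomes and
    unplaced scaffolds; "assembled_only" excludes only unplaced/random
    scaffolds; "custom" keeps exactly the chromosomes listed in ``chroms``.
    """
    if mode == "custom":
        if not chroms:
            raise ValueError("custom mode requires a chromosome list")
        allowed = set(chroms)
        out = [i for i in instances if i.chrom in allowed]
    elif mode == "autosomes_only":
        out = [
            i
            for i in instances
            if i.chrom not in SEX_CHROMS
            and i.chrom not in MITO_CHROMS
            and not _is_scaffold(i.chrom)
        ]
    elif mode == "assembled_only":
        out = [i for i in instances if not _is_scaffold(i.chrom)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not out:
        logger.warning("chromosome filter %r left zero instances", mode)
    return out


def _is_scaffold(chrom: str) -> bool:
    return "_" in chrom or chrom.startswith("chrUn")


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval, frac: float) -> bool:
    """True iff a and b share >= frac of the length of *each*.

    This is the peak-concordance criterion (default frac 0.5 downstream).
    """
    if not 0 < frac <= 1:
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    ov = overlap_bp(a, b)
    return ov >= frac * a.length and ov >= frac * b.length


def shuffle_intervals(
    intervals: Sequence[GenomicInterval] | Sequence[RepeatInstance],
    chrom_sizes: dict[str, int],
    exclude: IntervalSet | None = None,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 1000,
) -> list[GenomicInterval]:
    """Place each interval's length uniformly at random in the genome.

    Output preserves the multiset of input lengths; no placement overlaps
    ``exclude``.  Placement is uniform over all allowed start positions
    genome-wide (chromosome chosen proportionally to the number of valid
    starts for that length), implemented by rejection sampling against the
    exclude set.  Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    out: list[GenomicInterval] = []
    for item in intervals:
        iv = item.interval if isinstance(item, RepeatInstance) else item
        length = iv.length
        starts_per_chrom = np.array(
            [max(0, chrom_sizes[c] - length + 1) for c in chroms], dtype=float
        )
        total = starts_per_chrom.sum()
        if total <= 0:
            raise RuntimeError(f"no chromosome can host an interval of length {length}")
        probs = starts_per_chrom / total
        placed = None
        for _ in range(max_attempts):
            ci = rng.choice(len(chroms), p=probs)
            start = int(rng.integers(0, int(starts_per_chrom[ci])))
            cand = GenomicInterval(chroms[ci], start, start + length)
            if exclude is None or not exclude.overlaps(cand):
                placed = cand
                break
        if placed is None:
            raise RuntimeError(
                f"could not place interval of length {length} after "
                f"{max_attempts} attempts (exclude set too dense?)"
            )
        out.append(placed)
    return out


def write_instances(instances: Sequence[RepeatInstance], path) -> None:
    """Write an instance table as TSV (id, chrom, start, end, name, blocklisted)."""
    df = pd.DataFrame(
        {
            "id": [i.id for i in instances],
            "chrom": [i.chrom for i in instances],
            "start": [i.start for i in instances],
            "end": [i.end for i in instances],
            "name": [i.name for i in instances],
            "blocklisted": [i.blocklisted for i in instances],
        }
    )
    df.to_csv(path, sep="\t", index=False)
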