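"""Seeded miniature datasets exercising every pipeline stage.

The generator emits a complete file bundle — repeat annotation table,
blocklist, paired ChIP/input (or precomputed fold-change) coverage tracks
per sample with planted group or stage effects, SAM read files with
multimappers and consensus-derived satellite reads, consensus FASTA, RNA
contigs, genome segmentation, peaks, genes, sample metadata — plus a
ground-truth table, so differential-enrichment recovery can be validated
without any downloads.

Two named scenarios mirror the study designs this pipeline targets:

``cancer_hypomethylation``
    Two karyotype groups (8 normal vs 13 cancer cell lines).  Twenty true
    differential elements — a clustered block plus dispersed singles — carry
    a Delta log2 FC of 1.0 (normal above cancer) with within-group sd 0.3;
    enrichment spreads into the flanks of clustered elements.

``fetal_wave``
    Eight developmental stages x three tissues of precomputed fold-change
    tracks.  Twenty true elements follow a wave trajectory (highest at the
    earliest stage, sharp drop, partial recovery, drop again at birth) whose
    largest +1-shifted stage-mean ratio is exactly 2.0.

Planted element-level log2 FC values are exact by construction: the ChIP
multiplier for each element is solved from the actually generated background
(input element mean and the genome medians of both tracks, iterated to
absorb the small median shift the multipliers themselves cause), so the
pipeline's normalized clamped log2 FC recovers the planted value up to
bedGraph rounding.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotations import (
    GenomicInterval,
    IntervalSet,
    RepeatInstance,
    filter_blocklist,
    parse_rmsk,
    read_bed,
)
from .signal import SignalTrack, genome_median, mean_signal

logger = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "audit", "scenario_config"]

STAGES = ["E10.5", "E11.5", "E12.5", "E13.5", "E14.5", "E15.5", "E16.5", "P0"]
# nine tissues per stage, 72 fold-change samples in total (the fetal design)
TISSUES = ["forebrain", "midbrain", "hindbrain", "neural_tube", "heart",
           "liver", "limb", "EFP", "kidney"]
# +1-shifted stage means for true stage-differential elements: the largest
# pairwise ratio is (2.0+1)/(0.5+1) = 2.0 exactly.
FETAL_TRAJECTORY = [2.0, 0.5, 1.0, 1.1, 1.2, 1.0, 0.8, 0.5]


@dataclass
class SyntheticConfig:
    seed: int = 0
    scenario: str = "cancer_hypomethylation"  # or "fetal_wave"
    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 1_500_000, "chr2": 1_000_000, "chrX": 300_000}
    )
    # elements
    n_elements: int = 200  # analyzed (kept, autosomal) elements
    n_blocklisted: int = 20
    n_chrx: int = 8
    element_length_range: tuple = (200, 1500)
    cluster_size: int = 30
    cluster_element_length: int = 800
    cluster_spacing: int = 200
    families: dict = field(
        default_factory=lambda: {
            "GSATII": 0.25, "ALR/Alpha": 0.20, "HSATII": 0.15,
            "(CACTT)n": 0.10, "MMSAT4": 0.20, "SAR": 0.10,
        }
    )
    cluster_family: str = "GSATII"
    # sample design
    n_normal: int = 8
    n_cancer: int = 13
    stages: list = field(default_factory=lambda: list(STAGES))
    tissues: list = field(default_factory=lambda: list(TISSUES))
    # effect model
    baseline_range: tuple = (0.2, 1.0)
    n_true_differential: int = 20
    n_true_in_cluster: int = 12
    effect_size: float = 1.0  # Delta log2 FC, normal over cancer
    within_sd: float = 0.3
    blocklist_hot_log2fc: float = 3.0  # anomalous signal planted on blocklisted elements
    flank_spread: bool = True
    # coverage model
    bin_size: int = 200
    depth: float = 10.0
    gamma_shape: float = 20.0
    smooth_window: int = 3
    # read model
    read_length: int = 36
    monomer_length: int = 120
    n_consensus_input: int = 600
    consensus_fc: float = 3.0  # planted ChIP/input ratio of consensus-derived reads
    n_reads_total: int = 6000  # per assay after dedup/merge, background + consensus
    n_replicates: int = 2
    dup_per_replicate: int = 50
    unmapped_per_replicate: int = 25
    mutation_rate: float = 0.02
    # secondary annotations
    rna_fractions: dict = field(
        default_factory=lambda: {"polyA+": 0.30, "polyA-": 0.36, "short": 0.036}
    )
    peak_fraction: float = 0.15
    gene_fraction: float = 0.5
    segment_states: list = field(
        default_factory=lambda: ["Repressed", "Active", "Heterochrom", "Quiescent"]
    )
    segment_mean_length: int = 5000

    def validate(self) -> None:
        if self.scenario not in {"cancer_hypomethylation", "fetal_wave"}:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_true_differential > self.n_elements:
            raise ValueError("more true differential elements than elements")
        if self.n_true_in_cluster > min(self.cluster_size, self.n_true_differential):
            raise ValueError("n_true_in_cluster exceeds cluster or true set size")
        if not 0 < self.consensus_fc:
            raise ValueError("consensus_fc must be positive")
        n_cons_chip = int(round(self.n_consensus_input * self.consensus_fc))
        if n_cons_chip >= self.n_reads_total:
            raise ValueError("consensus reads exceed total read budget")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("element_length_range", "baseline_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key in ("element_length_range", "baseline_range"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def scenario_config(name: str, seed: int = 0, **overrides) -> SyntheticConfig:
    """Named scenario presets."""
    cfg = SyntheticConfig(seed=seed, scenario=name, **overrides)
    cfg.validate()
    return cfg


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the file bundle."""

    elements: pd.DataFrame  # per-element truth table
    planted_log2fc: pd.DataFrame  # analyzed elements x samples
    reads: pd.DataFrame  # per-assay read bookkeeping
    group_means: pd.DataFrame  # per-element per-group/stage planted means


def _write_tsv(df: pd.DataFrame, path, **kw) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", **kw)


# ---------------------------------------------------------------------------
# element layout


def _plan_elements(cfg: SyntheticConfig, rng: np.random.Generator):
    """Place cluster, dispersed, blocklisted and chrX elements; returns a frame."""
    autosomes = [c for c in cfg.chrom_sizes if c not in {"chrX", "chrY"}]
    c1, c2 = autosomes[0], autosomes[1 % len(autosomes)]
    s1, s2 = cfg.chrom_sizes[c1], cfg.chrom_sizes[c2]
    # pericentromere-analog blocklisted region mid-chr1 plus a chr2 start block
    blocklist = [
        GenomicInterval(c1, int(0.47 * s1), int(0.51 * s1)),
        GenomicInterval(c2, 0, int(0.03 * s2)),
    ]
    cluster_span = cfg.cluster_size * (cfg.cluster_element_length + cfg.cluster_spacing)
    if int(0.51 * s1) + 500 + cluster_span >= s1:
        raise ValueError("chr1-analog too small for the configured cluster")
    rows = []
    occupied = IntervalSet(blocklist, label="occupied")

    # clustered elements, just outside the blocklisted pericentromere-analog
    pos = int(0.51 * s1) + 500
    for k in range(cfg.cluster_size):
        iv = GenomicInterval(c1, pos, pos + cfg.cluster_element_length)
        rows.append((iv, cfg.cluster_family, "cluster", 0))
        occupied.add(iv)
        pos = iv.end + cfg.cluster_spacing

    fams = list(cfg.families)
    probs = np.array([cfg.families[f] for f in fams], dtype=float)
    probs /= probs.sum()

    def _rand_length() -> int:
        lo, hi = cfg.element_length_range
        x = rng.lognormal(mean=np.log(600), sigma=0.5)
        return int(np.clip(x, lo, hi))

    def _place(chroms: list[str], length: int, avoid: IntervalSet, margin: int = 100):
        sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
        for _ in range(500):
            ci = rng.choice(len(chroms), p=sizes / sizes.sum())
            start = int(rng.integers(0, cfg.chrom_sizes[chroms[ci]] - length))
            cand = GenomicInterval(chroms[ci], max(0, start - margin), start + length + margin)
            if not avoid.overlaps(cand):
                return GenomicInterval(chroms[ci], start, start + length)
        raise RuntimeError("could not place element; genome too crowded")

    n_dispersed = cfg.n_elements - cfg.cluster_size
    for k in range(n_dispersed):
        iv = _place(autosomes, _rand_length(), occupied)
        fam = fams[rng.choice(len(fams), p=probs)]
        rows.append((iv, fam, "dispersed", -1))
        occupied.add(iv)

    # elements planted inside blocklisted regions (anomalous-signal analogs)
    bl_regions = blocklist
    for k in range(cfg.n_blocklisted):
        region = bl_regions[k % len(bl_regions)]
        length = _rand_length()
        span = region.length // max(1, (cfg.n_blocklisted // len(bl_regions)) + 1)
        start = region.start + (k // len(bl_regions)) * span
        end = min(start + min(length, span - 10), region.end)
        if end <= start:
            start, end = region.start, region.start + 200
        iv = GenomicInterval(region.chrom, start, end)
        fam = fams[rng.choice(len(fams), p=probs)]
        rows.append((iv, fam, "blocklisted", -1))

    for k in range(cfg.n_chrx):
        iv = _place(["chrX"], _rand_length(), occupied)
        fam = fams[rng.choice(len(fams), p=probs)]
        rows.append((iv, fam, "chrX", -1))
        occupied.add(iv)

    df = pd.DataFrame(
        {
            "chrom": [r[0].chrom for r in rows],
            "start": [r[0].start for r in rows],
            "end": [r[0].end for r in rows],
            "family": [r[1] for r in rows],
            "role": [r[2] for r in rows],
            "cluster_id": [r[3] for r in rows],
        }
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    df["element_id"] = [
        f"{c}:{s}-{e}:{f}" for c, s, e, f in zip(df.chrom, df.start, df.end, df.family)
    ]
    # duplicate-row suffixing mirrors the annotation parser
    dup = df.groupby("element_id").cumcount()
    df.loc[dup > 0, "element_id"] = [
        f"{eid}#{k}" for eid, k in zip(df.element_id[dup > 0], dup[dup > 0])
    ]
    return df, blocklist


def _assign_effects(cfg: SyntheticConfig, elements: pd.DataFrame, rng: np.random.Generator):
    """Choose true differential elements and their per-group/stage means."""
    analyzed = elements[elements.role.isin(["cluster", "dispersed"])]
    cluster_ids = analyzed[analyzed.role == "cluster"].element_id.to_numpy()
    dispersed_ids = analyzed[analyzed.role == "dispersed"].element_id.to_numpy()
    n_cl = min(cfg.n_true_in_cluster, len(cluster_ids), cfg.n_true_differential)
    n_disp = cfg.n_true_differential - n_cl
    true_ids = list(rng.choice(cluster_ids, size=n_cl, replace=False)) + list(
        rng.choice(dispersed_ids, size=n_disp, replace=False)
    )
    true_set = set(true_ids)

    baseline = pd.Series(
        rng.uniform(*cfg.baseline_range, size=len(elements)),
        index=elements.element_id,
    )
    if cfg.scenario == "cancer_hypomethylation":
        groups = ["normal", "cancer"]
        means = pd.DataFrame(index=elements.element_id, columns=groups, dtype=float)
        means["cancer"] = baseline
        means["normal"] = baseline
        means.loc[list(true_set), "normal"] = baseline.loc[list(true_set)] + cfg.effect_size
    else:
        groups = list(cfg.stages)
        means = pd.DataFrame(
            np.tile(baseline.to_numpy()[:, None], (1, len(groups))),
            index=elements.element_id, columns=groups,
        )
        for eid in true_set:
            means.loc[eid] = FETAL_TRAJECTORY[: len(groups)]
    # anomalous signal at blocklisted elements, both groups alike
    hot = elements.loc[elements.role == "blocklisted", "element_id"]
    means.loc[hot] = cfg.blocklist_hot_log2fc
    return true_set, means


# ---------------------------------------------------------------------------
# coverage tracks


def _background_bins(cfg: SyntheticConfig, rng: np.random.Generator):
    """Gamma-distributed per-bin coverage with short-range smoothing."""
    bins = {}
    for chrom, size in cfg.chrom_sizes.items():
        n = int(np.ceil(size / cfg.bin_size))
        vals = rng.gamma(cfg.gamma_shape, cfg.depth / cfg.gamma_shape, size=n)
        if cfg.smooth_window > 1:
            k = np.ones(cfg.smooth_window) / cfg.smooth_window
            vals = np.convolve(vals, k, mode="same")
        starts = np.arange(n, dtype=np.int64) * cfg.bin_size
        ends = np.minimum(starts + cfg.bin_size, size)
        bins[chrom] = (starts, ends, vals)
    return bins


def _apply_multipliers(bins, mult_intervals):
    """Split runs at multiplier boundaries and scale.

    ``mult_intervals``: list of (chrom, start, end, factor, is_element).
    Element intervals are disjoint and take their own factor exactly; flank
    intervals apply (max over overlapping flanks) only where no element
    covers the base.
    """
    out = {}
    by_chrom: dict[str, list] = {}
    for chrom, s, e, f, is_el in mult_intervals:
        by_chrom.setdefault(chrom, []).append((s, e, f, is_el))
    for chrom, (bs, be, bv) in bins.items():
        ivs = by_chrom.get(chrom, [])
        edges = set(bs.tolist()) | {int(be[-1])}
        for s, e, _, _ in ivs:
            edges.add(int(s))
            edges.add(int(e))
        edges = np.array(sorted(x for x in edges if 0 <= x <= int(be[-1])), dtype=np.int64)
        seg_s, seg_e = edges[:-1], edges[1:]
        bin_idx = np.searchsorted(bs, seg_s, side="right") - 1
        vals = bv[bin_idx].copy()
        elem_f = np.full(len(seg_s), np.nan)
        flank_f = np.ones(len(seg_s))
        for s, e, f, is_el in ivs:
            i0 = np.searchsorted(seg_s, s, side="left")
            i1 = np.searchsorted(seg_s, e, side="left")
            if is_el:
                elem_f[i0:i1] = f
            else:
                flank_f[i0:i1] = np.maximum(flank_f[i0:i1], f)
        factor = np.where(np.isnan(elem_f), flank_f, elem_f)
        out[chrom] = (seg_s, seg_e, vals * factor)
    return out


def _chip_track_for_sample(
    cfg: SyntheticConfig,
    elements: pd.DataFrame,
    g: pd.Series,  # planted clamped log2 FC per element for this sample
    input_track: SignalTrack,
    rng: np.random.Generator,
    chroms: list[str],
) -> SignalTrack:
    """Solve per-element ChIP multipliers so the planted values are exact."""
    bg = _background_bins(cfg, rng)
    bg_track = SignalTrack({c: (s.copy(), e.copy(), v.copy()) for c, (s, e, v) in bg.items()},
                           chrom_sizes=cfg.chrom_sizes)
    med_i = genome_median(input_track, chroms)
    i_norm = {}
    c_bg = {}
    spread = set()
    for row in elements.itertuples(index=False):
        iv = GenomicInterval(row.chrom, row.start, row.end)
        i_norm[row.element_id] = mean_signal(input_track, iv) / med_i + 1.0
        c_bg[row.element_id] = mean_signal(bg_track, iv)
        if cfg.flank_spread and row.role == "cluster" and g.get(row.element_id, 0) > 0:
            spread.add(row.element_id)

    med_c = genome_median(bg_track, chroms)
    track = bg_track
    for _ in range(3):  # absorb the median shift the multipliers cause
        mult = []
        for row in elements.itertuples(index=False):
            eid = row.element_id
            r = 2.0 ** float(g.get(eid, 0.0))
            f = (r * i_norm[eid] - 1.0) * med_c / max(c_bg[eid], 1e-9)
            f = max(f, 0.0)
            mult.append((row.chrom, row.start, row.end, f, True))
            if eid in spread:
                L = row.end - row.start
                size = cfg.chrom_sizes[row.chrom]
                mult.append((row.chrom, max(0, row.start - L), row.start, f, False))
                mult.append((row.chrom, row.end, min(size, row.end + L), f, False))
        runs = _apply_multipliers(bg, mult)
        track = SignalTrack(runs, chrom_sizes=cfg.chrom_sizes)
        med_c = genome_median(track, chroms)
    return track


def _fc_track_for_sample(
    cfg: SyntheticConfig,
    elements: pd.DataFrame,
    g: pd.Series,
    rng: np.random.Generator,
) -> SignalTrack:
    """Precomputed linear fold-change track with planted element values."""
    bins = {}
    for chrom, size in cfg.chrom_sizes.items():
        n = int(np.ceil(size / cfg.bin_size))
        vals = np.clip(rng.normal(1.0, 0.08, size=n), 0.05, None)
        starts = np.arange(n, dtype=np.int64) * cfg.bin_size
        ends = np.minimum(starts + cfg.bin_size, size)
        bins[chrom] = (starts, ends, vals)
    base = SignalTrack(bins, chrom_sizes=cfg.chrom_sizes)
    mult = []
    for row in elements.itertuples(index=False):
        r = 2.0 ** float(g.get(row.element_id, 0.0))
        mult.append((row.chrom, row.start, row.end, np.nan, True, r))
    # set element segments to the exact planted linear FC
    by_chrom: dict[str, list] = {}
    for chrom, s, e, _, _, r in mult:
        by_chrom.setdefault(chrom, []).append((s, e, r))
    out = {}
    for chrom, (bs, be, bv) in bins.items():
        ivs = by_chrom.get(chrom, [])
        edges = set(bs.tolist()) | {int(be[-1])}
        for s, e, _ in ivs:
            edges.add(int(s))
            edges.add(int(e))
        edges = np.array(sorted(edges), dtype=np.int64)
        seg_s, seg_e = edges[:-1], edges[1:]
        bin_idx = np.searchsorted(bs, seg_s, side="right") - 1
        vals = bv[bin_idx].copy()
        for s, e, r in ivs:
            i0 = np.searchsorted(seg_s, s, side="left")
            i1 = np.searchsorted(seg_s, e, side="left")
            vals[i0:i1] = r
        out[chrom] = (seg_s, seg_e, vals)
    return SignalTrack(out, chrom_sizes=cfg.chrom_sizes)


def _write_track(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            s, e, v = track.runs[chrom]
            for si, ei, vi in zip(s, e, v):
                fh.write(f"{chrom}\t{si}\t{ei}\t{vi:.6g}\n")


# ---------------------------------------------------------------------------
# reads


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        cur = out[i]
        out[i] = "ACGT"[(("ACGT".index(cur) if cur in "ACGT" else 0) +
                         int(rng.integers(1, 4))) % 4]
    return "".join(out)


def _make_reads(cfg: SyntheticConfig, elements: pd.DataFrame,
                monomers: dict[str, str], rng: np.random.Generator):
    """Per-assay read sets: background (MAPQ 30), cluster multimappers drawn
    from the cluster family's consensus dimer (MAPQ 0), plus flagged
    duplicates and unmapped reads that preprocessing must remove."""
    n_cons_chip = int(round(cfg.n_consensus_input * cfg.consensus_fc))
    n_cons = {"chip": n_cons_chip, "input": cfg.n_consensus_input}
    dimer = monomers[cfg.cluster_family] * 2
    cluster = elements[elements.role == "cluster"]
    chroms = [c for c in cfg.chrom_sizes if c != "chrX"]
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    reads = {}
    book = []
    for assay in ("chip", "input"):
        n_bg = cfg.n_reads_total - n_cons[assay]
        lines = []
        # background reads: unique placements
        for k in range(n_bg):
            ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
            pos = int(rng.integers(0, cfg.chrom_sizes[chroms[ci]] - cfg.read_length))
            lines.append((f"{assay}_bg_{k}", 0, chroms[ci], pos, 30,
                          _random_seq(rng, cfg.read_length)))
        # consensus-derived multimappers, placed at cluster elements
        for k in range(n_cons[assay]):
            off = int(rng.integers(0, len(dimer) - cfg.read_length + 1))
            seq = _mutate(dimer[off:off + cfg.read_length], cfg.mutation_rate, rng)
            row = cluster.iloc[int(rng.integers(0, len(cluster)))]
            pos = int(rng.integers(row.start, max(row.start + 1, row.end - cfg.read_length)))
            lines.append((f"{assay}_sat_{k}", 0, row.chrom, pos, 0, seq))
        # extras removed by preprocessing
        extras = []
        for r in range(cfg.n_replicates):
            for k in range(cfg.dup_per_replicate):
                src = lines[int(rng.integers(0, len(lines)))]
                extras.append((f"{assay}_dup_{r}_{k}", 1024, src[2], src[3], src[4], src[5]))
            for k in range(cfg.unmapped_per_replicate):
                extras.append((f"{assay}_un_{r}_{k}", 4, "*", -1, 0,
                               _random_seq(rng, cfg.read_length)))
        reads[assay] = (lines, extras)
        book.append({"assay": assay, "n_clean": len(lines),
                     "n_consensus": n_cons[assay],
                     "n_background": n_bg,
                     "n_duplicates": cfg.n_replicates * cfg.dup_per_replicate,
                     "n_unmapped": cfg.n_replicates * cfg.unmapped_per_replicate})
    return reads, pd.DataFrame(book)


def _write_sam(lines, extras, cfg: SyntheticConfig, paths) -> None:
    """Split clean reads round-robin across replicate files; extras appended."""
    n_rep = len(paths)
    handles = [open(p, "w") for p in paths]
    try:
        for fh in handles:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for chrom, size in cfg.chrom_sizes.items():
                fh.write(f"@SQ\tSN:{chrom}\tLN:{size}\n")
        qual = "I" * cfg.read_length
        for i, (qname, flag, chrom, pos, mapq, seq) in enumerate(lines):
            fh = handles[i % n_rep]
            cigar = f"{len(seq)}M"
            fh.write(f"{qname}\t{flag}\t{chrom}\t{pos + 1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}\n")
        for i, (qname, flag, chrom, pos, mapq, seq) in enumerate(extras):
            fh = handles[i % n_rep]
            if flag & 4:
                fh.write(f"{qname}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}\n")
            else:
                fh.write(f"{qname}\t{flag}\t{chrom}\t{pos + 1}\t{mapq}\t{len(seq)}M\t*\t0\t0\t{seq}\t{qual}\n")
    finally:
        for fh in handles:
            fh.close()


# ---------------------------------------------------------------------------
# secondary annotations


def _make_rna(cfg, analyzed: pd.DataFrame, rng):
    files = {}
    truth_cols = {}
    for lib, frac in cfg.rna_fractions.items():
        n = int(round(frac * len(analyzed)))
        idx = rng.choice(len(analyzed), size=n, replace=False)
        rows = []
        levels = {}
        for j in idx:
            el = analyzed.iloc[j]
            ext5 = int(rng.integers(50, 500))
            ext3 = int(rng.integers(50, 500))
            start = max(0, el.start - ext5)
            end = min(cfg.chrom_sizes[el.chrom], el.end + ext3)
            level = float(np.round(rng.lognormal(0.0, 1.0), 4))
            rows.append((el.chrom, start, end, f"{lib}_contig_{len(rows)}", level))
            levels[el.element_id] = level
        rows.sort(key=lambda r: (r[0], r[1]))
        files[lib] = rows
        truth_cols[lib] = levels
    return files, truth_cols


def _make_peaks(cfg, analyzed: pd.DataFrame, occupied: IntervalSet, rng):
    n = int(round(cfg.peak_fraction * len(analyzed)))
    idx = rng.choice(len(analyzed), size=n, replace=False)
    peaks = []
    matched = set()
    for j in idx:
        el = analyzed.iloc[j]
        L = el.end - el.start
        shift = int(rng.integers(-L // 10, L // 10 + 1))
        s = max(0, el.start + shift)
        peaks.append((el.chrom, s, s + L))
        matched.add(el.element_id)
    # decoys away from every element
    for k in range(20):
        for _ in range(200):
            chrom = list(cfg.chrom_sizes)[int(rng.integers(0, len(cfg.chrom_sizes)))]
            length = int(rng.integers(300, 2000))
            s = int(rng.integers(0, cfg.chrom_sizes[chrom] - length))
            cand = GenomicInterval(chrom, s, s + length)
            if not occupied.overlaps(cand):
                peaks.append((chrom, s, s + length))
                break
    peaks.sort()
    return peaks, matched


def _make_genes(cfg, analyzed: pd.DataFrame, rng):
    n = int(round(cfg.gene_fraction * len(analyzed)))
    idx = rng.choice(len(analyzed), size=n, replace=False)
    genes = []
    for gi, j in enumerate(idx):
        el = analyzed.iloc[j]
        s = max(0, el.start - int(rng.integers(500, 5000)))
        e = min(cfg.chrom_sizes[el.chrom], el.end + int(rng.integers(500, 5000)))
        genes.append((el.chrom, s, e, f"gene_{gi}"))
    genes.sort()
    return genes


def _make_segmentation(cfg, rng):
    segs = []
    for chrom, size in sorted(cfg.chrom_sizes.items()):
        pos = 0
        while pos < size:
            length = int(np.clip(rng.exponential(cfg.segment_mean_length), 1000, 20000))
            end = min(pos + length, size)
            state = cfg.segment_states[int(rng.integers(0, len(cfg.segment_states)))]
            segs.append((chrom, pos, end, state))
            pos = end
    return segs


# ---------------------------------------------------------------------------
# driver


def generate(cfg: SyntheticConfig, outdir, force: bool = False) -> SyntheticTruth:
    """Write the full synthetic bundle to ``outdir`` and return ground truth.

    Byte-identical across runs with the same config (the seed lives in the
    config).  Refuses to write into a non-empty directory unless ``force``.
    """
    cfg.validate()
    out = Path(outdir)
    if out.exists() and any(out.iterdir()):
        if not force:
            raise FileExistsError(f"{out} exists and is non-empty (use force=True)")
        shutil.rmtree(out)
    (out / "tracks").mkdir(parents=True, exist_ok=True)
    (out / "reads").mkdir(exist_ok=True)

    master = np.random.default_rng(cfg.seed)
    rngs = master.spawn(8)
    (rng_layout, rng_effects, rng_tracks, rng_reads,
     rng_rna, rng_peaks, rng_genes, rng_seg) = rngs

    elements, blocklist = _plan_elements(cfg, rng_layout)
    true_set, means = _assign_effects(cfg, elements, rng_effects)
    analyzed = elements[elements.role.isin(["cluster", "dispersed"])].reset_index(drop=True)
    chroms = sorted(set(analyzed.chrom))

    # sample design
    samples = []
    if cfg.scenario == "cancer_hypomethylation":
        for i in range(cfg.n_normal):
            samples.append({"sample_id": f"normal_{i + 1:02d}", "group": "normal",
                            "tissue": ["lung", "breast", "skin", "blood"][i % 4],
                            "sex": "F" if i % 2 else "M", "stage": "",
                            "assay": "ChIP+input", "mark": "H3K9me3"})
        for i in range(cfg.n_cancer):
            samples.append({"sample_id": f"cancer_{i + 1:02d}", "group": "cancer",
                            "tissue": ["lung", "breast", "cervix", "liver", "bone"][i % 5],
                            "sex": "F" if i % 2 else "M", "stage": "",
                            "assay": "ChIP+input", "mark": "H3K9me3"})
    else:
        for stage in cfg.stages:
            for tissue in cfg.tissues:
                samples.append({"sample_id": f"{stage}_{tissue}", "group": stage,
                                "tissue": tissue, "sex": "", "stage": stage,
                                "assay": "FC_track", "mark": "H3K9me3"})
    meta = pd.DataFrame(samples)

    # planted per-sample values and coverage tracks
    planted = pd.DataFrame(index=elements.element_id, columns=meta.sample_id, dtype=float)
    for _, srow in meta.iterrows():
        sid = srow.sample_id
        mu = means[srow.group] if srow.group in means.columns else means.iloc[:, 0]
        g = np.maximum(0.0, rng_effects.normal(mu.to_numpy(), cfg.within_sd))
        planted[sid] = g
        gser = pd.Series(g, index=elements.element_id)
        if cfg.scenario == "cancer_hypomethylation":
            input_bins = _background_bins(cfg, rng_tracks)
            input_track = SignalTrack(input_bins, chrom_sizes=cfg.chrom_sizes)
            chip_track = _chip_track_for_sample(cfg, elements, gser, input_track,
                                                rng_tracks, chroms)
            _write_track(input_track, out / "tracks" / f"{sid}_input.bedgraph")
            _write_track(chip_track, out / "tracks" / f"{sid}_chip.bedgraph")
            meta.loc[meta.sample_id == sid, "chip_path"] = f"tracks/{sid}_chip.bedgraph"
            meta.loc[meta.sample_id == sid, "input_path"] = f"tracks/{sid}_input.bedgraph"
        else:
            fc_track = _fc_track_for_sample(cfg, elements, gser, rng_tracks)
            _write_track(fc_track, out / "tracks" / f"{sid}_fc.bedgraph")
            meta.loc[meta.sample_id == sid, "fc_path"] = f"tracks/{sid}_fc.bedgraph"

    # annotation files
    _write_rmsk(elements, out / "rmsk.tsv")
    with open(out / "blocklist.bed", "w") as fh:
        for iv in blocklist:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    with open(out / "chrom_sizes.tsv", "w") as fh:
        for chrom, size in sorted(cfg.chrom_sizes.items()):
            fh.write(f"{chrom}\t{size}\n")

    # consensus references and reads
    monomers = {fam: _random_seq(np.random.default_rng(
        int(hashlib.sha256(f"{cfg.seed}:{fam}".encode()).hexdigest()[:8], 16)),
        cfg.monomer_length) for fam in cfg.families}
    with open(out / "consensus.fasta", "w") as fh:
        for fam in sorted(monomers):
            safe = fam.replace("/", "_").replace("(", "").replace(")", "")
            fh.write(f">{safe}\n{monomers[fam]}\n")
    reads, reads_truth = _make_reads(cfg, elements, monomers, rng_reads)
    for assay in ("chip", "input"):
        lines, extras = reads[assay]
        paths = [out / "reads" / f"{assay}_rep{r + 1}.sam" for r in range(cfg.n_replicates)]
        _write_sam(lines, extras, cfg, paths)

    # secondary annotations
    occupied = IntervalSet(
        (GenomicInterval(r.chrom, r.start, r.end) for r in elements.itertuples(index=False)),
        label="elements",
    )
    rna_files, rna_truth = _make_rna(cfg, analyzed, rng_rna)
    lib_fname = {"polyA+": "rna_polyAplus.bed", "polyA-": "rna_polyAminus.bed",
                 "short": "rna_short.bed"}
    for lib, rows in rna_files.items():
        with open(out / lib_fname[lib], "w") as fh:
            for chrom, s, e, name, level in rows:
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{level:.4f}\t.\n")
    peaks, peak_matched = _make_peaks(cfg, analyzed, occupied, rng_peaks)
    with open(out / "peaks.bed", "w") as fh:
        for chrom, s, e in peaks:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    genes = _make_genes(cfg, analyzed, rng_genes)
    with open(out / "genes.bed", "w") as fh:
        for chrom, s, e, name in genes:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")
    segs = _make_segmentation(cfg, rng_seg)
    with open(out / "segmentation.bed", "w") as fh:
        for chrom, s, e, state in segs:
            fh.write(f"{chrom}\t{s}\t{e}\t{state}\n")

    # gene overlap truth from the final gene set (catches accidental overlaps)
    gene_set = IntervalSet((GenomicInterval(c, s, e) for c, s, e, _ in genes), "genes")
    elements = elements.assign(
        differential=elements.element_id.isin(true_set),
        blocklisted=elements.role.eq("blocklisted"),
        gene_overlapping=[
            gene_set.overlaps(GenomicInterval(r.chrom, r.start, r.end))
            for r in elements.itertuples(index=False)
        ],
        peak_matched=elements.element_id.isin(peak_matched),
    )
    for lib, levels in rna_truth.items():
        elements[f"rna_{lib}"] = elements.element_id.map(levels)

    meta_cols = [c for c in ["sample_id", "assay", "mark", "group", "tissue", "sex",
                             "stage", "chip_path", "input_path", "fc_path"]
                 if c in meta.columns]
    _write_tsv(meta[meta_cols], out / "metadata.tsv")
    _write_tsv(elements, out / "truth.tsv")
    planted.round(6).to_csv(out / "planted_log2fc.tsv", sep="\t",
                            index_label="element_id", float_format="%.6g")
    means.round(6).to_csv(out / "group_means.tsv", sep="\t",
                          index_label="element_id", float_format="%.6g")
    _write_tsv(reads_truth, out / "reads_truth.tsv")
    cfg.to_yaml(out / "config.yaml")

    return SyntheticTruth(elements=elements, planted_log2fc=planted,
                          reads=reads_truth, group_means=means)


_RMSK_HEADER_FILL = dict(swScore=1000, milliDiv=50, milliDel=0, milliIns=0,
                         genoLeft=0, repFamily="Satellite", repStart=1,
                         repEnd=100, repLeft=0)


def _write_rmsk(elements: pd.DataFrame, path) -> None:
    """UCSC rmsk layout (17 columns with bin) for every planted element."""
    with open(path, "w") as fh:
        for i, r in enumerate(elements.itertuples(index=False)):
            f = _RMSK_HEADER_FILL
            fh.write(
                "\t".join(str(x) for x in (
                    0, f["swScore"], f["milliDiv"], f["milliDel"], f["milliIns"],
                    r.chrom, r.start, r.end, f["genoLeft"], "+", r.family,
                    "Satellite", f["repFamily"], f["repStart"], f["repEnd"],
                    f["repLeft"], i,
                )) + "\n"
            )


@dataclass
class AuditReport:
    ok: bool
    violations: list


def audit(outdir) -> AuditReport:
    """Verify bundle/truth consistency: rmsk completeness, blocklist flags,
    read counts.  Any inconsistency is listed as a violation."""
    out = Path(outdir)
    violations = []
    truth = pd.read_csv(out / "truth.tsv", sep="\t")
    instances = parse_rmsk(out / "rmsk.tsv", class_filter="Satellite")
    ids = {i.id for i in instances}
    missing = set(truth.element_id) - ids
    if missing:
        violations.append(f"{len(missing)} truth element(s) absent from rmsk table")
    blocklist = read_bed(out / "blocklist.bed", label="blocklist")
    kept, removed = filter_blocklist(instances, blocklist)
    removed_ids = {i.id for i in removed}
    truth_bl = set(truth.loc[truth.blocklisted, "element_id"])
    if truth_bl != (removed_ids & set(truth.element_id)):
        violations.append("blocklisted flags disagree with blocklist BED overlap")
    reads_truth = pd.read_csv(out / "reads_truth.tsv", sep="\t")
    from .multimap import preprocess_alignments, read_sam

    cfg = SyntheticConfig.from_yaml(out / "config.yaml")
    for row in reads_truth.itertuples(index=False):
        reps = [read_sam(out / "reads" / f"{row.assay}_rep{r + 1}.sam")
                for r in range(cfg.n_replicates)]
        clean = preprocess_alignments(reps)
        if len(clean) != row.n_clean:
            violations.append(
                f"{row.assay}: {len(clean)} reads after preprocessing, "
                f"expected {row.n_clean}"
            )
    return AuditReport(ok=not violations, violations=violations)
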