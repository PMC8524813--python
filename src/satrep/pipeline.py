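"""Stage orchestration over a data bundle directory.

Each stage reads a bundle (as produced by :mod:`satrep.synthetic`, or any
directory with the same file layout), writes TSV outputs plus a provenance
manifest into a working directory, and is pure with respect to
(inputs, parameters, seed): reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotations import (
    GenomicInterval,
    IntervalSet,
    RepeatInstance,
    filter_blocklist,
    filter_chromosomes,
    parse_rmsk,
    read_bed,
    write_instances,
)
from .differential import (
    differential_stagewise,
    differential_two_group,
    family_overrepresentation,
    records_to_frame,
)
from .integrative import (
    RNAContig,
    SegmentationRecord,
    chromatin_state_tally,
    gene_overlap,
    mnase_occupancy,
    peak_concordance,
    rna_level,
)
from .multimap import (
    align_to_consensus,
    consensus_enrichment,
    downsample,
    element_mapq0,
    load_consensus_fasta,
    preprocess_alignments,
    read_sam,
)
from .multivariate import binomial_distance, pca, permanova, scale_rows
from .signal import (
    EnrichmentMatrix,
    SampleRecord,
    element_enrichment,
    element_fc_from_fc_track,
    read_bedgraph,
    window_profile,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline parameters; defaults are the analysis' stated values."""

    alpha: float = 0.05
    posthoc_alpha_adj: float = 0.01
    tukey_alpha: float = 0.05
    relevance_cutoff: float = 1.5
    reciprocal_frac: float = 0.5
    peak_fc_min: float = 2.0
    min_windows: int = 50
    n_perm: int = 999
    downsample_n: int | None = None
    max_mismatch_rate: float = 0.1
    chromosome_mode: str = "autosomes_only"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.posthoc_alpha_adj < 1:
            raise ValueError("alpha levels must be in (0, 1)")
        if not 0 < self.reciprocal_frac <= 1:
            raise ValueError("reciprocal_frac must be in (0, 1]")
        if self.relevance_cutoff < 1:
            raise ValueError("relevance_cutoff must be >= 1")
        if not 0 <= self.max_mismatch_rate < 1:
            raise ValueError("max_mismatch_rate must be in [0, 1)")
        if self.min_windows < 1 or self.n_perm < 1:
            raise ValueError("min_windows and n_perm must be >= 1")


def _manifest(workdir: Path, stage: str, inputs: dict, params: dict) -> None:
    payload = {
        "stage": stage,
        # base names only (directories elided): manifests stay byte-identical
        # across working directories, which reruns rely on
        "inputs": {k: (Path(v).name if Path(v).suffix else "<dir>")
                   for k, v in inputs.items()},
        "parameters": params,
        "version": __version__,
    }
    with open(workdir / f"{stage}.manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _read_chrom_sizes(bundle: Path) -> dict[str, int]:
    df = pd.read_csv(bundle / "chrom_sizes.tsv", sep="\t", header=None,
                     names=["chrom", "size"])
    return dict(zip(df.chrom, df["size"]))


def load_metadata(bundle: Path) -> pd.DataFrame:
    return pd.read_csv(bundle / "metadata.tsv", sep="\t", keep_default_na=False)


def stage_annotate(bundle, workdir, config: RunConfig) -> list[RepeatInstance]:
    """Parse rmsk, apply blocklist then chromosome filter; write kept/removed."""
    bundle, workdir = Path(bundle), Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    instances = parse_rmsk(bundle / "rmsk.tsv", class_filter="Satellite")
    blocklist = read_bed(bundle / "blocklist.bed", label="blocklist")
    kept, removed = filter_blocklist(instances, blocklist)
    analyzed = filter_chromosomes(kept, mode=config.chromosome_mode)
    write_instances(analyzed, workdir / "kept_instances.tsv")
    write_instances(removed, workdir / "removed_instances.tsv")
    _manifest(workdir, "annotate",
              {"rmsk": bundle / "rmsk.tsv", "blocklist": bundle / "blocklist.bed"},
              {"chromosome_mode": config.chromosome_mode, "class_filter": "Satellite"})
    return analyzed


def _instances_or_run(bundle, workdir, config) -> list[RepeatInstance]:
    return stage_annotate(bundle, workdir, config)


def stage_enrich(bundle, workdir, config: RunConfig) -> EnrichmentMatrix:
    """Per-sample element enrichment into the matrix TSV."""
    bundle, workdir = Path(bundle), Path(workdir)
    instances = _instances_or_run(bundle, workdir, config)
    meta = load_metadata(bundle)
    sizes = _read_chrom_sizes(bundle)
    chroms = sorted({i.chrom for i in instances})
    cols = {}
    records = []
    for row in meta.itertuples(index=False):
        if getattr(row, "fc_path", ""):
            track = read_bedgraph(bundle / row.fc_path, chrom_sizes=sizes)
            cols[row.sample_id] = element_fc_from_fc_track(track, instances, scale="log2")
        else:
            chip = read_bedgraph(bundle / row.chip_path, chrom_sizes=sizes)
            inp = read_bedgraph(bundle / row.input_path, chrom_sizes=sizes)
            cols[row.sample_id] = element_enrichment(chip, inp, instances, chroms=chroms)
        records.append(SampleRecord(
            sample_id=row.sample_id, assay=row.assay, mark=row.mark,
            group=row.group, tissue=row.tissue, sex=row.sex, stage=row.stage,
        ))
    from .signal import build_enrichment_matrix

    matrix = build_enrichment_matrix(cols, records)
    matrix.to_tsv(workdir / "enrichment_matrix.tsv")
    matrix.metadata.to_csv(workdir / "sample_metadata.tsv", sep="\t",
                           index_label="sample_id")
    _manifest(workdir, "enrich", {"bundle": bundle},
              {"chroms": chroms, "n_samples": len(records),
               "n_elements": len(instances)})
    return matrix


def _matrix_or_run(bundle, workdir, config) -> EnrichmentMatrix:
    workdir = Path(workdir)
    m = workdir / "enrichment_matrix.tsv"
    s = workdir / "sample_metadata.tsv"
    if m.exists() and s.exists():
        return EnrichmentMatrix.from_tsv(m, s)
    return stage_enrich(bundle, workdir, config)


def stage_profile(bundle, workdir, config: RunConfig,
                  element_ids: list[str] | None = None,
                  n_windows: int | None = None) -> pd.DataFrame:
    """Window profiles (element plus one-length flanks) for ChIP/input samples."""
    bundle, workdir = Path(bundle), Path(workdir)
    instances = _instances_or_run(bundle, workdir, config)
    by_id = {i.id: i for i in instances}
    if element_ids is None:
        element_ids = [i.id for i in instances[: min(5, len(instances))]]
    meta = load_metadata(bundle)
    sizes = _read_chrom_sizes(bundle)
    chroms = sorted({i.chrom for i in instances})
    frames = []
    for row in meta.itertuples(index=False):
        if not getattr(row, "chip_path", ""):
            continue
        chip = read_bedgraph(bundle / row.chip_path, chrom_sizes=sizes)
        inp = read_bedgraph(bundle / row.input_path, chrom_sizes=sizes)
        for eid in element_ids:
            prof = window_profile(chip, inp, by_id[eid].interval, element_id=eid,
                                  min_windows=config.min_windows,
                                  n_windows=n_windows, chroms=chroms)
            frames.append(prof.to_frame(sample_id=row.sample_id))
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["element", "sample", "window_index",
                                      "window_start", "window_end", "log2fc"]))
    out.to_csv(workdir / "window_profiles.tsv", sep="\t", index=False,
               float_format="%.6g")
    _manifest(workdir, "profile", {"bundle": bundle},
              {"min_windows": config.min_windows, "elements": element_ids})
    return out


def stage_diff2(bundle, workdir, config: RunConfig) -> pd.DataFrame:
    """Two-group Welch differential enrichment."""
    bundle, workdir = Path(bundle), Path(workdir)
    matrix = _matrix_or_run(bundle, workdir, config)
    records = differential_two_group(matrix, "group", alpha=config.alpha)
    df = records_to_frame(records)
    df.to_csv(workdir / "differential_two_group.tsv", sep="\t", index=False,
              float_format="%.6g")
    instances = parse_rmsk(bundle / "rmsk.tsv", class_filter="Satellite")
    known = {i.id for i in instances}
    sig = [r.element_id for r in records if r.significant and r.element_id in known]
    fam = family_overrepresentation(
        [i for i in instances if i.id in set(matrix.values.index)], sig
    ) if sig else []
    pd.DataFrame([vars(f) for f in fam]).to_csv(
        workdir / "family_enrichment_two_group.tsv", sep="\t", index=False,
        float_format="%.6g")
    _manifest(workdir, "diff2", {"bundle": bundle}, {"alpha": config.alpha})
    return df


def stage_diffstage(bundle, workdir, config: RunConfig) -> pd.DataFrame:
    """Stagewise ANOVA/Bonferroni/Tukey/relevance differential enrichment."""
    bundle, workdir = Path(bundle), Path(workdir)
    matrix = _matrix_or_run(bundle, workdir, config)
    records = differential_stagewise(
        matrix, "stage", posthoc_alpha_adj=config.posthoc_alpha_adj,
        tukey_alpha=config.tukey_alpha, relevance_cutoff=config.relevance_cutoff)
    df = records_to_frame(records)
    df.to_csv(workdir / "differential_stagewise.tsv", sep="\t", index=False,
              float_format="%.6g")
    instances = parse_rmsk(bundle / "rmsk.tsv", class_filter="Satellite")
    analyzed = [i for i in instances if i.id in set(matrix.values.index)]
    sig = [r.element_id for r in records if r.significant]
    fam = family_overrepresentation(analyzed, sig) if sig else []
    pd.DataFrame([vars(f) for f in fam]).to_csv(
        workdir / "family_enrichment_stagewise.tsv", sep="\t", index=False,
        float_format="%.6g")
    _manifest(workdir, "diffstage", {"bundle": bundle},
              {"posthoc_alpha_adj": config.posthoc_alpha_adj,
               "tukey_alpha": config.tukey_alpha,
               "relevance_cutoff": config.relevance_cutoff})
    return df


def stage_pca(bundle, workdir, config: RunConfig):
    """Row-scaled PCA of samples over autosomal elements."""
    bundle, workdir = Path(bundle), Path(workdir)
    matrix = _matrix_or_run(bundle, workdir, config)
    scaled, flagged = scale_rows(matrix.values)
    scores, loadings, var_exp = pca(scaled.T)
    scores.to_csv(workdir / "pca_scores.tsv", sep="\t", index_label="sample_id",
                  float_format="%.6g")
    pd.DataFrame({"component": [f"PC{i + 1}" for i in range(len(var_exp))],
                  "variance_explained": var_exp}).to_csv(
        workdir / "pca_variance.tsv", sep="\t", index=False, float_format="%.6g")
    _manifest(workdir, "pca", {"bundle": bundle},
              {"n_flagged_constant_rows": len(flagged)})
    return scores, var_exp


def stage_permanova(bundle, workdir, config: RunConfig):
    """PERMANOVA of group structure on the binomial distance matrix."""
    bundle, workdir = Path(bundle), Path(workdir)
    matrix = _matrix_or_run(bundle, workdir, config)
    dist = binomial_distance(matrix.values.T)
    groups = matrix.groups("group")
    F, r2, p = permanova(dist, groups, n_perm=config.n_perm, seed=config.seed)
    dist.to_frame().to_csv(workdir / "distance_matrix.tsv", sep="\t",
                           float_format="%.6g")
    pd.DataFrame([{"pseudo_F": F, "R2": r2, "p": p, "n_perm": config.n_perm}]).to_csv(
        workdir / "permanova.tsv", sep="\t", index=False, float_format="%.6g")
    _manifest(workdir, "permanova", {"bundle": bundle},
              {"n_perm": config.n_perm, "seed": config.seed})
    return F, r2, p


def stage_multimap(bundle, workdir, config: RunConfig) -> pd.DataFrame:
    """MAPQ-0 content per element plus consensus-dimer re-mapping enrichment."""
    bundle, workdir = Path(bundle), Path(workdir)
    instances = _instances_or_run(bundle, workdir, config)
    reads_dir = bundle / "reads"
    refs = load_consensus_fasta(bundle / "consensus.fasta")

    def _load(assay: str):
        reps = sorted(reads_dir.glob(f"{assay}_rep*.sam"))
        return preprocess_alignments([read_sam(p) for p in reps])

    chip = _load("chip")
    inp = _load("input")
    n = config.downsample_n or min(len(chip), len(inp))
    chip_ds = downsample(chip, n, seed=config.seed, label="ChIP")
    inp_ds = downsample(inp, n, seed=config.seed + 1, label="input")

    mapq_df = element_mapq0(chip_ds, instances)
    mapq_df.to_csv(workdir / "element_mapq0.tsv", sep="\t", index=False,
                   float_format="%.6g")

    chip_res = align_to_consensus([r for r in chip_ds if r.mapq == 0], refs,
                                  max_mismatch_rate=config.max_mismatch_rate)
    inp_res = align_to_consensus([r for r in inp_ds if r.mapq == 0], refs,
                                 max_mismatch_rate=config.max_mismatch_rate)
    # consensus normalization is by total (downsampled) library size
    chip_res["total"] = inp_res["total"] = n
    enr = consensus_enrichment(chip_res, inp_res)
    out = pd.DataFrame([
        {"family": e.family, "chip_aligned": e.chip_aligned,
         "input_aligned": e.input_aligned, "fc": np.nan if e.fc is None else e.fc,
         "alignment_rate": e.alignment_rate,
         "uniformity": np.nan if e.uniformity is None else e.uniformity,
         "uniformity_flag": e.uniformity_flag, "no_reads": e.no_reads}
        for e in enr
    ])
    out.to_csv(workdir / "consensus_enrichment.tsv", sep="\t", index=False,
               float_format="%.6g")
    _manifest(workdir, "multimap", {"bundle": bundle},
              {"downsample_n": n, "max_mismatch_rate": config.max_mismatch_rate,
               "seed": config.seed})
    return out


def stage_integrate(bundle, workdir, config: RunConfig) -> dict:
    """Peak concordance, RNA levels, chromatin states, gene overlap, MNase null."""
    bundle, workdir = Path(bundle), Path(workdir)
    instances = _instances_or_run(bundle, workdir, config)
    matrix = _matrix_or_run(bundle, workdir, config)
    mean_fc = matrix.values.mean(axis=1)
    sizes = _read_chrom_sizes(bundle)

    peaks = read_bed(bundle / "peaks.bed", label="peaks")
    pk_df, pk_summary = peak_concordance(instances, peaks, log2fc=mean_fc,
                                         frac=config.reciprocal_frac,
                                         fc_min=config.peak_fc_min)
    pk_df.to_csv(workdir / "peak_concordance.tsv", sep="\t", index=False)

    rna_results = {}
    lib_files = {"polyA+": "rna_polyAplus.bed", "polyA-": "rna_polyAminus.bed",
                 "short": "rna_short.bed"}
    for lib, fname in lib_files.items():
        path = bundle / fname
        if not path.exists():
            continue
        bed = read_bed(path, label=lib)
        contigs = [RNAContig(iv, bed.scores.get(iv, 0.0), library=lib) for iv in bed]
        df = rna_level(instances, contigs)
        df.to_csv(workdir / f"rna_level_{fname.replace('.bed', '')}.tsv",
                  sep="\t", index=False, float_format="%.6g")
        rna_results[lib] = df

    seg_bed = read_bed(bundle / "segmentation.bed", label="segmentation")
    segments = [SegmentationRecord(iv, seg_bed.names.get(iv, "NA")) for iv in seg_bed]
    tally, genome_bp = chromatin_state_tally(instances, segments)
    pd.DataFrame(
        [{"state": s, "element_bp": tally.get(s, 0), "genome_bp": genome_bp.get(s, 0)}
         for s in sorted(set(tally) | set(genome_bp))]
    ).to_csv(workdir / "chromatin_states.tsv", sep="\t", index=False)

    genes = read_bed(bundle / "genes.bed", label="genes")
    n_gene, prop = gene_overlap(instances, genes)

    blocklist = read_bed(bundle / "blocklist.bed", label="blocklist")
    meta = load_metadata(bundle)
    mnase_summary = {}
    chip_rows = [r for r in meta.itertuples(index=False) if getattr(r, "chip_path", "")]
    if chip_rows:
        # input coverage stands in for an occupancy-like track on the bundle
        track = read_bedgraph(bundle / chip_rows[0].input_path, chrom_sizes=sizes)
        res = mnase_occupancy(instances, track, sizes, exclude=blocklist,
                              n_null=1, seed=config.seed, log2fc=mean_fc)
        mnase_summary = {
            "observed_mean": float(res["observed"].mean()),
            "null_mean": float(res["null"].mean()),
            "pearson_r": res.get("pearson_r", np.nan),
            "spearman_rho": res.get("spearman_rho", np.nan),
        }

    summary = {
        "peaks": pk_summary,
        "gene_overlap_n": n_gene,
        "gene_overlap_proportion": prop,
        "rna_evidence": {lib: int(df.has_evidence.sum()) for lib, df in rna_results.items()},
        "mnase": mnase_summary,
    }
    with open(workdir / "integrate_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _manifest(workdir, "integrate", {"bundle": bundle},
              {"reciprocal_frac": config.reciprocal_frac,
               "peak_fc_min": config.peak_fc_min, "seed": config.seed})
    return summary


def stage_report(bundle, workdir, config: RunConfig) -> dict:
    """Aggregate per-run summary counts across all stages."""
    bundle, workdir = Path(bundle), Path(workdir)
    instances_all = parse_rmsk(bundle / "rmsk.tsv", class_filter="Satellite")
    analyzed = stage_annotate(bundle, workdir, config)
    matrix = _matrix_or_run(bundle, workdir, config)
    meta = load_metadata(bundle)
    two_group = len(set(meta.group)) == 2 and not (meta.stage != "").any()
    if two_group:
        diff = stage_diff2(bundle, workdir, config)
        n_sig = int(diff.significant.sum())
        n_sig_adj = int(diff.significant_adj.sum())
    else:
        diff = stage_diffstage(bundle, workdir, config)
        n_sig = int(diff.significant.sum())
        n_sig_adj = int(diff.significant_adj.sum())
    removed = pd.read_csv(workdir / "removed_instances.tsv", sep="\t")
    report = {
        "n_annotated": len(instances_all),
        "n_removed_blocklist": int(len(removed)),
        "n_analyzed": len(analyzed),
        "n_samples": int(matrix.values.shape[1]),
        "mean_log2fc": float(matrix.values.to_numpy().mean()),
        "n_significant": n_sig,
        "n_significant_adjusted": n_sig_adj,
        "mode": "two_group" if two_group else "stagewise",
    }
    with open(workdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _manifest(workdir, "report", {"bundle": bundle}, {"seed": config.seed})
    return report
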