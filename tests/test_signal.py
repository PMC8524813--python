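"""Signal extraction, genome-median normalization, and window profiles."""

import io

import numpy as np
import pandas as pd
import pytest

from conftest import expand_track
from satrep.annotations import GenomicInterval, RepeatInstance
from satrep.signal import (
    EnrichmentMatrix,
    SignalTrack,
    clamped_log2_fc,
    element_enrichment,
    element_fc_from_fc_track,
    genome_median,
    mean_signal,
    normalize_value,
    read_bedgraph,
    window_profile,
)


def make_track(runs, size=None, chrom="chr1"):
    s, e, v = zip(*runs)
    sizes = {chrom: size} if size else None
    return SignalTrack({chrom: (np.array(s), np.array(e), np.array(v))}, sizes)


def inst(chrom, start, end, name="S", k=0):
    return RepeatInstance(
        interval=GenomicInterval(chrom, start, end), name=name,
        family_class="Satellite", id=f"{chrom}:{start}-{end}:{name}{k}",
    )


class TestMeanSignal:
    def test_two_runs_full_interval(self):
        t = make_track([(0, 10, 2.0), (10, 20, 4.0)], size=20)
        assert mean_signal(t, GenomicInterval("chr1", 0, 20)) == pytest.approx(3.0)

    def test_partial_overlap_weighting(self):
        t = make_track([(0, 10, 2.0), (10, 20, 4.0)], size=20)
        assert mean_signal(t, GenomicInterval("chr1", 5, 15)) == pytest.approx(3.0)

    def test_uncovered_bases_count_as_zero(self):
        t = make_track([(0, 10, 4.0)], size=40)
        assert mean_signal(t, GenomicInterval("chr1", 0, 40)) == pytest.approx(1.0)

    def test_missing_chromosome_returns_zero(self):
        t = make_track([(0, 10, 4.0)], size=10)
        assert mean_signal(t, GenomicInterval("chr9", 0, 10)) == 0.0

    def test_random_tracks_vs_per_base_oracle(self, track_factory):
        rng = np.random.default_rng(0)
        for _ in range(500):
            t = track_factory(rng, size=200)
            arr = expand_track(t, "chr1")
            s = int(rng.integers(0, 190))
            e = int(rng.integers(s + 1, 200))
            got = mean_signal(t, GenomicInterval("chr1", s, e))
            assert got == pytest.approx(arr[s:e].mean(), abs=1e-9)


class TestGenomeMedian:
    def test_constant_track(self):
        t = make_track([(0, 100, 5.0)], size=100)
        assert genome_median(t, ["chr1"]) == 5.0

    def test_even_count_takes_central_pair_mean(self):
        t = make_track([(0, 50, 2.0), (50, 100, 6.0)], size=100)
        assert genome_median(t, ["chr1"]) == 4.0

    def test_uncovered_bases_enter_as_zero(self):
        t = make_track([(0, 10, 8.0)], size=100)
        with pytest.raises(ValueError, match="median.*0"):
            genome_median(t, ["chr1"])  # majority of bases are 0 -> degenerate

    def test_include_zeros_false_ignores_gaps(self):
        t = make_track([(0, 10, 8.0)], size=100)
        assert genome_median(t, ["chr1"], include_zeros=False) == 8.0

    def test_random_tracks_vs_expansion_oracle(self, track_factory):
        rng = np.random.default_rng(1)
        for _ in range(200):
            t = track_factory(rng, size=150)
            arr = expand_track(t, "chr1")
            if np.median(arr) == 0:
                continue
            assert genome_median(t, ["chr1"]) == pytest.approx(np.median(arr), abs=1e-12)


class TestNormalization:
    def test_normalize_value(self):
        assert normalize_value(10, 5) == 3.0
        assert normalize_value(0, 5) == 1.0

    def test_scaling_invariance_identity(self):
        assert normalize_value(10 * 3.7, 5 * 3.7) == pytest.approx(normalize_value(10, 5))

    def test_clamped_log2(self):
        assert clamped_log2_fc(3.0, 1.5) == pytest.approx(1.0)
        assert clamped_log2_fc(1.2, 2.4) == 0.0  # input stronger -> no true signal
        assert clamped_log2_fc(2.0, 2.0) == 0.0


class TestElementEnrichment:
    def test_equal_tracks_give_zero(self):
        t = make_track([(0, 100, 5.0)], size=100)
        out = element_enrichment(t, t, [inst("chr1", 10, 30)], chroms=["chr1"])
        assert out.iloc[0] == 0.0

    def test_hand_computed_three_element_toy(self):
        # chip: 100 bases, median 4; input: constant 2
        chip = make_track([(0, 25, 4.0), (25, 50, 8.0), (50, 100, 2.0)], size=100)
        # per-base: 25x4, 25x8, 50x2 -> sorted: 50x2, 25x4, 25x8 -> median 3
        inp = make_track([(0, 100, 2.0)], size=100)
        elements = [inst("chr1", 0, 25, "a"), inst("chr1", 25, 50, "b"),
                    inst("chr1", 50, 100, "c")]
        out = element_enrichment(chip, inp, elements, chroms=["chr1"])
        med_c, med_i = 3.0, 2.0
        for e, m in zip(elements, (4.0, 8.0, 2.0)):
            expected = max(0.0, np.log2((m / med_c + 1) / (2.0 / med_i + 1)))
            assert out[e.id] == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_independent_rescaling(self):
        rng = np.random.default_rng(3)
        chip = make_track([(i * 10, (i + 1) * 10, float(v))
                           for i, v in enumerate(rng.uniform(1, 9, 10))], size=100)
        inp = make_track([(i * 10, (i + 1) * 10, float(v))
                          for i, v in enumerate(rng.uniform(1, 9, 10))], size=100)
        elements = [inst("chr1", 5, 40), inst("chr1", 60, 95, "T")]
        base = element_enrichment(chip, inp, elements, chroms=["chr1"])
        scaled = element_enrichment(chip.scaled(13.7), inp.scaled(0.21), elements,
                                    chroms=["chr1"])
        assert np.allclose(base.to_numpy(), scaled.to_numpy(), atol=1e-9)


class TestFcTrack:
    def test_constant_fc(self):
        t = make_track([(0, 100, 1.6)], size=100)
        out = element_fc_from_fc_track(t, [inst("chr1", 10, 60)], scale="linear")
        assert out.iloc[0] == pytest.approx(1.6)

    def test_mixed_fc_mean(self):
        t = make_track([(0, 50, 1.0), (50, 100, 2.2)], size=100)
        out = element_fc_from_fc_track(t, [inst("chr1", 0, 100)], scale="linear")
        assert out.iloc[0] == pytest.approx(1.6)

    def test_log2_scale_clamps(self):
        t = make_track([(0, 100, 0.5)], size=100)
        out = element_fc_from_fc_track(t, [inst("chr1", 0, 100)], scale="log2")
        assert out.iloc[0] == 0.0

    def test_random_tracks_vs_per_base_oracle(self, track_factory):
        rng = np.random.default_rng(9)
        for _ in range(100):
            t = track_factory(rng, size=120)
            arr = expand_track(t, "chr1")
            s = int(rng.integers(0, 100))
            e = int(rng.integers(s + 1, 120))
            out = element_fc_from_fc_track(t, [inst("chr1", s, e)], scale="linear")
            assert out.iloc[0] == pytest.approx(arr[s:e].mean(), abs=1e-9)


class TestWindowProfile:
    def flat_pair(self, size=300):
        t = make_track([(0, size, 5.0)], size=size)
        return t, t

    def test_region_extension_and_equal_windows(self):
        chip, inp = self.flat_pair()
        prof = window_profile(chip, inp, GenomicInterval("chr1", 100, 200))
        assert (prof.region.start, prof.region.end) == (0, 300)
        widths = np.diff(prof.boundaries)
        assert prof.n_windows == 50 and set(widths) == {6}

    def test_flat_tracks_give_zero_profile(self):
        chip, inp = self.flat_pair()
        prof = window_profile(chip, inp, GenomicInterval("chr1", 100, 200))
        assert np.all(prof.log2fc == 0.0)

    def test_windows_tile_region_exactly(self):
        chip, inp = self.flat_pair(1000)
        prof = window_profile(chip, inp, GenomicInterval("chr1", 307, 484),
                              min_windows=50)
        widths = np.diff(prof.boundaries)
        assert widths.sum() == prof.region.length
        assert widths.max() - widths.min() <= 1
        assert prof.boundaries[0] == prof.region.start
        assert prof.boundaries[-1] == prof.region.end

    def test_clipping_at_chromosome_start(self):
        chip, inp = self.flat_pair()
        prof = window_profile(chip, inp, GenomicInterval("chr1", 10, 60))
        assert prof.clipped and prof.region.start == 0

    def test_tiny_region_reduces_window_count(self):
        chip = make_track([(0, 30, 2.0)], size=30)
        prof = window_profile(chip, chip, GenomicInterval("chr1", 10, 20))
        assert prof.n_windows == 30  # region [0,30) shorter than 50 windows

    def test_window_means_consistent_with_region_mean(self, track_factory):
        # length-weighted mean of window mean-signals == region mean-signal
        rng = np.random.default_rng(5)
        chip = track_factory(rng, size=600)
        element = GenomicInterval("chr1", 210, 330)
        prof = window_profile(chip, chip, element)
        widths = np.diff(prof.boundaries)
        wmeans = np.array([
            mean_signal(chip, GenomicInterval("chr1", int(a), int(b)))
            for a, b in zip(prof.boundaries[:-1], prof.boundaries[1:])
        ])
        region_mean = mean_signal(chip, prof.region)
        assert (wmeans * widths).sum() / widths.sum() == pytest.approx(region_mean, abs=1e-9)

    def test_planted_flank_spread_elevates_flanks(self, cancer_bundle):
        bundle, truth = cancer_bundle
        el = truth.elements
        target = el[(el.role == "cluster") & el.differential].iloc[0]
        meta = pd.read_csv(bundle / "metadata.tsv", sep="\t")
        srow = meta[meta.group == "normal"].iloc[0]
        sizes = dict(pd.read_csv(bundle / "chrom_sizes.tsv", sep="\t",
                                 header=None, names=["c", "s"]).values)
        chip = read_bedgraph(bundle / srow.chip_path, chrom_sizes=sizes)
        inp = read_bedgraph(bundle / srow.input_path, chrom_sizes=sizes)
        prof = window_profile(chip, inp, GenomicInterval(target.chrom, target.start,
                                                         target.end),
                              chroms=["chr1", "chr2"], min_windows=51)
        third = prof.n_windows // 3
        flanks = np.r_[prof.log2fc[:third], prof.log2fc[-third:]]
        assert flanks.mean() > 0.2  # enrichment spreads beyond the element


class TestEnrichmentMatrixInvariants:
    def test_rejects_negative_and_nonfinite(self):
        meta = pd.DataFrame({"group": ["a"]}, index=["s1"])
        with pytest.raises(ValueError):
            EnrichmentMatrix(pd.DataFrame({"s1": [-0.1]}, index=["e1"]), meta)
        with pytest.raises(ValueError):
            EnrichmentMatrix(pd.DataFrame({"s1": [np.inf]}, index=["e1"]), meta)

    def test_bedgraph_roundtrip(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t10\t2.5\nchr1\t10\t30\t0.5\nchr2\t5\t9\t1\n")
        t = read_bedgraph(p)
        assert mean_signal(t, GenomicInterval("chr1", 0, 30)) == pytest.approx(
            (10 * 2.5 + 20 * 0.5) / 30)
        assert t.chrom_sizes["chr2"] == 9

    def test_negative_bedgraph_values_floored(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t10\t-3.0\n")
        t = read_bedgraph(p)
        assert mean_signal(t, GenomicInterval("chr1", 0, 10)) == 0.0
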