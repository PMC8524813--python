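import numpy as np
import pytest

from satrep.pipeline import RunConfig
from satrep.signal import SignalTrack
from satrep.synthetic import generate, scenario_config


@pytest.fixture(scope="session")
def cancer_bundle(tmp_path_factory):
    """Two-group scenario bundle (8 normal vs 13 cancer) with ground truth."""
    d = tmp_path_factory.mktemp("cancer_bundle")
    truth = generate(scenario_config("cancer_hypomethylation", seed=1), d, force=True)
    return d, truth


@pytest.fixture(scope="session")
def fetal_bundle(tmp_path_factory):
    """Stagewise scenario bundle (8 stages x 9 tissues) with ground truth."""
    d = tmp_path_factory.mktemp("fetal_bundle")
    truth = generate(scenario_config("fetal_wave", seed=1), d, force=True)
    return d, truth


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale generator config for fast structural tests."""
    return dict(
        n_elements=60, n_blocklisted=6, n_chrx=2, cluster_size=12,
        n_true_differential=6, n_true_in_cluster=4,
        n_normal=3, n_cancer=4, n_reads_total=800, n_consensus_input=100,
        chrom_sizes={"chr1": 400_000, "chr2": 300_000, "chrX": 100_000},
    )


@pytest.fixture
def run_config():
    return RunConfig(seed=1)


@pytest.fixture
def track_factory():
    """Random run-length SignalTrack factory with gaps, for oracle tests."""

    def make(rng: np.random.Generator, chrom: str = "chr1", size: int = 200,
             max_runs: int = 12, max_value: float = 20.0) -> SignalTrack:
        n_runs = int(rng.integers(1, max_runs))
        cuts = np.sort(rng.choice(size, size=2 * n_runs, replace=False))
        starts, ends = cuts[0::2], cuts[1::2]
        keep = ends > starts
        starts, ends = starts[keep], ends[keep]
        values = rng.uniform(0, max_value, size=len(starts))
        return SignalTrack({chrom: (starts, ends, values)}, chrom_sizes={chrom: size})

    return make


def expand_track(track: SignalTrack, chrom: str) -> np.ndarray:
    """Per-base expansion of a run-length track (brute-force oracle helper)."""
    size = track.chrom_sizes[chrom]
    arr = np.zeros(size)
    s, e, v = track.runs.get(chrom, (np.array([]), np.array([]), np.array([])))
    for si, ei, vi in zip(s, e, v):
        arr[si:ei] = vi
    return arr
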