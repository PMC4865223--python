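import numpy as np
import pandas as pd
import pytest

from capmap.pipeline import PipelineConfig, run_pipeline
from capmap.simulate import MapSpec, WHEAT_CHROMOSOMES, simulate_ril_population


def make_grid_map_spec(
    n_chromosomes: int,
    markers_per_chromosome: int,
    length_cM: float = 200.0,
    jitter: float = 0.4,
    seed: int = 0,
) -> MapSpec:
    """A true map with roughly evenly spaced markers (jittered grid)."""
    rng = np.random.default_rng(seed)
    chroms = WHEAT_CHROMOSOMES[:n_chromosomes]
    rows = []
    for ci, chrom in enumerate(chroms):
        spacing = length_cM / markers_per_chromosome
        base = (np.arange(markers_per_chromosome) + 0.5) * spacing
        pos = np.sort(
            np.clip(base + rng.uniform(-jitter, jitter, markers_per_chromosome) * spacing * 0.5, 0, length_cM)
        )
        for j, cm in enumerate(pos):
            rows.append((f"m{ci:02d}_{j:03d}", chrom, float(cm), int(round(cm * 1e6)) + j))
    loci = pd.DataFrame(rows, columns=["contig_id", "chromosome", "position_cM", "position_bp"])
    return MapSpec(chromosomes=[(c, length_cM) for c in chroms], loci=loci)


def error_free_calls(truth) -> pd.DataFrame:
    """Perfect genotype matrix from a simulated truth (H kept as H)."""
    return truth.genotypes.copy()


@pytest.fixture(scope="session")
def small_truth():
    """2 chromosomes x 60 markers, 135 RILs — shared across mapping tests."""
    spec = make_grid_map_spec(2, 60, seed=3)
    return simulate_ril_population(spec, n_individuals=135, generations=6, seed=9)


@pytest.fixture(scope="session")
def small_pipeline_result():
    """One small but complete end-to-end synthetic run, reused read-only."""
    config = PipelineConfig(seed=11, n_contigs=240, n_chromosomes=4, n_individuals=135)
    return run_pipeline(config)
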