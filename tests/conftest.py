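import numpy as np
import pandas as pd
import pytest

import upfchip as u


@pytest.fixture(scope="session")
def small_annotation():
    """20 genes on 2 chromosomes, deterministic."""
    return u.simulate_annotation(101, 20, n_chroms=2)


@pytest.fixture(scope="session")
def small_truth(small_annotation):
    return u.simulate_occupancy(102, small_annotation)


@pytest.fixture()
def flat_track(small_annotation):
    values = {c: np.full(n, 3.5) for c, n in small_annotation.chrom_lengths.items()}
    return u.CoverageTrack(values, label="flat", normalized=True)


def make_probe_frame(rows):
    """Rows of (probe_id, chrom, position, strand, pm, mm, gene_id)."""
    return pd.DataFrame(
        rows,
        columns=["probe_id", "chrom", "position", "strand", "pm", "mm", "gene_id"],
    )
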