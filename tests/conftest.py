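from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from splicetile.arraydata import ProbeMatrix, SampleInfo
from splicetile.genome import GenomicInterval, Transcript


def iv(start: int, end: int, chrom: str = "chr1", strand: str = "+"):
    return GenomicInterval(chrom, start, end, strand)


def tx(tid: str, exons, gene_id: str = "G1", source: str = "annotation"):
    return Transcript(tid, gene_id, [iv(*e) for e in exons], source)


@pytest.fixture
def three_exon_transcript():
    return tx("t1", [(0, 100), (200, 300), (400, 500)])


@pytest.fixture
def simple_samples():
    return [
        SampleInfo("T01", "tissue"),
        SampleInfo("C01", "stress_control"),
        SampleInfo("S01", "stress_treatment", "C01"),
    ]


def make_matrix(values: np.ndarray, starts=None, chrom="chr1", samples=None):
    """Build a small ProbeMatrix around a (probe, sample, 3) tensor."""
    n = values.shape[0]
    if starts is None:
        starts = np.arange(n) * 35
    if samples is None:
        samples = [
            SampleInfo(f"T{j + 1:02d}", "tissue")
            for j in range(values.shape[1])
        ]
    probes = pd.DataFrame(
        {
            "probe_id": [f"P{i}" for i in range(n)],
            "chrom": [chrom] * n,
            "start": np.asarray(starts, dtype=int),
            "strand": ["+"] * n,
        }
    )
    return ProbeMatrix(probes=probes, values=values, samples=samples)


@pytest.fixture(scope="session")
def easy_sim():
    """Small noiseless dataset shared by exactness tests."""
    from splicetile.simulate import easy_config, simulate_dataset

    return simulate_dataset(easy_config(n_genes=60, seed=11))


@pytest.fixture(scope="session")
def default_sim():
    """Small default-noise dataset shared by statistical unit tests."""
    from splicetile.simulate import default_config, simulate_dataset

    return simulate_dataset(default_config(n_genes=80, seed=7))
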