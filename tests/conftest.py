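import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from elongrec import SimConfig, TranscriptAnnotation, build_profiles, simulate

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def toy_transcripts():
    """Two transcripts on opposite strands sharing a gene, one single-exon."""
    return [
        TranscriptAnnotation(
            transcript_id="tx_plus",
            gene_id="geneA",
            chrom="chr1",
            strand="+",
            exons=((100, 200), (300, 700), (800, 1000)),
        ),
        TranscriptAnnotation(
            transcript_id="tx_minus",
            gene_id="geneA",
            chrom="chr1",
            strand="-",
            exons=((2000, 2300), (2400, 2500), (2600, 2900), (3000, 3100)),
        ),
        TranscriptAnnotation(
            transcript_id="tx_single",
            gene_id="geneB",
            chrom="chr2",
            strand="+",
            exons=((0, 150),),
        ),
    ]


@pytest.fixture
def toy_meta():
    return pd.DataFrame(
        {
            "group": ["WT", "WT", "WT", "WT"],
            "condition": ["Untr", "Untr", "R0", "R0"],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(["u1", "u2", "t1", "t2"], name="specimen_id"),
    )


@pytest.fixture(scope="session")
def small_sim():
    """One default-condition simulated experiment reused across tests."""
    return simulate(SimConfig(n_transcripts=80, seed=42))


@pytest.fixture(scope="session")
def small_profiles(small_sim):
    pset, excluded = build_profiles(small_sim.counts, small_sim.annotation)
    return pset, excluded
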