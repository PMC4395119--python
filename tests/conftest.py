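"""Shared fixtures: a small simulated experiment reused across test modules."""

from __future__ import annotations

import pandas as pd
import pytest

from rdrnascan import SimConfig, analyze_libraries, emit_libraries, generate_genome
from rdrnascan.readmap import collapse_reads

SMALL_CONFIG = SimConfig(
    genome_length=200_000,
    n_contigs=2,
    n_exon_features=14,
    n_transposon_features=2,
    n_rdrna_loci={"rdrp1": 2, "rdrp2": 2, "both": 2},
    n_exsirna_loci={"I": 1, "II": 1, "III": 1, "IV": 1},
    n_background_loci=20,
    library_depth=50_000,
    rng_seed=7,
)


def collapse_library(placements: pd.DataFrame, library_id: str) -> pd.DataFrame:
    pairs = list(placements.groupby("sequence")["count"].sum().items())
    collapsed, _ = collapse_reads(pairs, library_id)
    return collapsed


def true_label_of(called_locus, truth: pd.DataFrame) -> str:
    """Class label of the planted locus overlapping a called locus (or 'none')."""
    hit = truth[
        (truth["contig"] == called_locus.contig)
        & (truth["start"] < called_locus.end)
        & (truth["end"] > called_locus.start)
    ]
    return hit.iloc[0]["class_label"] if len(hit) else "none"


@pytest.fixture(scope="session")
def small_dataset():
    return generate_genome(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_libraries(small_dataset):
    libs, expected_rpm = emit_libraries(small_dataset)
    return libs, expected_rpm


@pytest.fixture(scope="session")
def small_analysis(small_dataset, small_libraries):
    libs, _ = small_libraries
    collapsed = {g: collapse_library(lib, g) for g, lib in libs.items()}
    return analyze_libraries(small_dataset.genome, small_dataset.features, collapsed)
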