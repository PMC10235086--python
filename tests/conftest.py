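"""Shared fixtures: toy genome geometries and small simulation configs."""

from __future__ import annotations

import pandas as pd
import pytest

from cenrna.fragments import SampleSheet
from cenrna.genome import OrfFeature, build_genome_model
from cenrna.simulate import SimulationConfig


@pytest.fixture
def toy_model():
    """One 10 kb chromosome, core [1000,1117), 500 bp windows, no ORFs.

    Default CDE layout: CDEI [1000,1008), CDEII [1008,1092), CDEIII [1092,1117).
    """
    return build_genome_model({"chrT": 10_000}, {"chrT": (1000, 1117)})


@pytest.fixture
def toy_model_with_orf():
    """Toy model plus an up-side ORF [600,840) intersecting the up window."""
    orf = OrfFeature(chrom="chrT", start=600, end=840, strand="+", id="ORF1")
    return build_genome_model({"chrT": 10_000}, {"chrT": (1000, 1117)}, [orf])


@pytest.fixture
def tiny_model():
    """200 bp chromosome with a 20 bp core [90,110) and 40 bp windows.

    Small enough for exhaustive fragment-placement checks; CDE layout
    4 / 10 / 6 bp.
    """
    return build_genome_model(
        {"chrT": 200},
        {"chrT": (90, 110)},
        window_bp=40,
        cde1_len=4,
        cde3_len=6,
        core_width_band=(10, 30),
    )


@pytest.fixture
def two_sample_sheet():
    return SampleSheet(
        pd.DataFrame(
            {
                "sample": ["mock1", "auxin1"],
                "condition": ["mock", "auxin"],
                "replicate": [1, 1],
                "total_fragments": [1_000_000, 2_000_000],
            }
        )
    )


@pytest.fixture
def small_config():
    """Desk-scale config keeping the study-condition structure."""
    return SimulationConfig(
        seed=7,
        scale=1,
        noncoding_pericen_total=400,
        coding_pericen_multiplier=2.0,
        background_fragments=500,
        cen_total=200,
    )
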