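"""Shared builders: the two worked-example patients and small survival fixtures."""

from __future__ import annotations

import pytest

from hfscore import (
    FibrosisCategory,
    LAARead,
    ReaderAssessment,
    RegionRead,
    REGION_IDS,
)

N = FibrosisCategory.NORMAL
R = FibrosisCategory.RETICULAR
TB = FibrosisCategory.RETICULAR_TB
HC = FibrosisCategory.HONEYCOMB


def region(region_id: str, normal=0.0, reticular=0.0, reticular_tb=0.0, honeycomb=0.0):
    return RegionRead(
        region_id,
        {N: normal, R: reticular, TB: reticular_tb, HC: honeycomb},
    )


def assessment_from_reticular(patient_id, reader_id, reticular_by_region, laa_by_region=None):
    """Build an assessment from per-region reticular extents (rest normal)."""
    laa_by_region = laa_by_region or {}
    fibrosis = tuple(
        region(r, normal=100.0 - reticular_by_region.get(r, 0.0),
               reticular=reticular_by_region.get(r, 0.0))
        for r in REGION_IDS
    )
    emphysema = tuple(LAARead(r, laa_by_region.get(r, 0.0)) for r in REGION_IDS)
    return ReaderAssessment(reader_id=reader_id, patient_id=patient_id,
                            fibrosis=fibrosis, emphysema=emphysema)


@pytest.fixture
def patient_a_reader_hg():
    """Patient A, first reader: one region all-normal, four at 5% reticular,
    one at 10% reticular -> reader HFS 105."""
    return assessment_from_reticular(
        "A", "HG",
        {"carina_R": 0.0, "carina_L": 5.0, "mid_R": 5.0, "mid_L": 5.0,
         "ipv_R": 5.0, "ipv_L": 10.0},
    )


@pytest.fixture
def patient_b_reader_hg():
    """Patient B, first reader: 20/25/25/25/25/30% reticular -> reader HFS 125;
    all six lung fields in the 51-75% LAA band -> reader GS 18."""
    return assessment_from_reticular(
        "B", "HG",
        {"carina_L": 20.0, "carina_R": 25.0, "mid_R": 25.0, "mid_L": 25.0,
         "ipv_L": 25.0, "ipv_R": 30.0},
        laa_by_region={r: 60.0 for r in REGION_IDS},
    )


@pytest.fixture
def patient_b_reader_hi():
    """Patient B, second reader: uniform 20% reticular -> reader HFS 120;
    LAA pattern summing to GS 15 (three fields band 3, three band 2)."""
    laa = {"carina_R": 60.0, "carina_L": 60.0, "mid_R": 60.0,
           "mid_L": 40.0, "ipv_R": 40.0, "ipv_L": 40.0}
    return assessment_from_reticular(
        "B", "HI", {r: 20.0 for r in REGION_IDS}, laa_by_region=laa
    )
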