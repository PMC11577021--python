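import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ciber import BarcodeReference, SampleRecord

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def small_reference() -> list[BarcodeReference]:
    """Three genes x three guides in one sublibrary, key-free spacers."""
    rows = []
    spacers = [
        "ACGTACGTACGTACGTA",
        "CCGTACGTACGTACGTA",
        "GCGTACGTACGTACGTA",
        "TCGTACGTACGTACGTA",
        "ATGTACGTACGTACGTA",
        "CTGTACGTACGTACGTA",
        "GTGTACGTACGTACGTA",
        "TTGTACGTACGTACGTA",
        "AAGTACGTACGTACGTA",
    ]
    for i, spacer in enumerate(spacers):
        gene = f"GENE{i // 3 + 1}"
        rows.append(
            BarcodeReference(
                barcode_id=f"{gene}_{spacer}_{i % 3 + 1}_LIB1",
                gene=gene,
                spacer=spacer,
                sublibrary="LIB1",
            )
        )
    return rows


@pytest.fixture
def four_sample_manifest() -> list[SampleRecord]:
    return [
        SampleRecord("LIB1_cells_plus", "cells", "plus", "S1", "LIB1"),
        SampleRecord("LIB1_cells_minus", "cells", "minus", "S1", "LIB1"),
        SampleRecord("LIB1_sevs_plus", "sEVs", "plus", "S1", "LIB1"),
        SampleRecord("LIB1_sevs_minus", "sEVs", "minus", "S1", "LIB1"),
    ]


def make_counts(reference, values: dict[str, list[int]]) -> pd.DataFrame:
    frame = pd.DataFrame(values, index=pd.Index([r.barcode_id for r in reference], name="barcode_id"))
    return frame.astype("int64")
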