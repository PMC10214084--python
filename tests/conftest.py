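from pathlib import Path

import pytest

from toxscan.catalog import default_catalog, load_reference_panel
from toxscan.site_mapping import SiteProfile

EXTERNAL_DATA = Path(__file__).resolve().parent.parent / "data" / "external"


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def panel_rows():
    return load_reference_panel()


def panel_profile(row: dict) -> SiteProfile:
    """Literature panel row -> SiteProfile (inserts parsed from 'k:len' pairs)."""
    residues = tuple(row[f"site{i}"] for i in range(1, 11))
    inserts = [0] * 9
    if row.get("inserts"):
        for item in row["inserts"].split(","):
            k, length = item.split(":")
            inserts[int(k) - 1] = int(length)
    return SiteProfile(
        sequence_id=row["phosphatase"],
        site_residues=residues,
        insertion_lengths=tuple(inserts),
    )
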