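"""Shared fixtures: the hand-computable two-lake dataset in several forms."""

import pandas as pd
import pytest

from cpirank import (
    LakeRegistry,
    build_units,
    filter_records,
    records_from_frame,
    worked_fixture,
)


@pytest.fixture(scope="session")
def fixture_frames():
    """(occurrences, statuses, registry) data frames of the worked fixture."""
    return worked_fixture()


@pytest.fixture()
def fixture_files(tmp_path, fixture_frames):
    """The worked fixture written out as CSV files."""
    occ, st, reg = fixture_frames
    paths = {
        "occurrences": tmp_path / "occurrences.csv",
        "status": tmp_path / "status.csv",
        "registry": tmp_path / "registry.csv",
    }
    occ.to_csv(paths["occurrences"], index=False)
    st.to_csv(paths["status"], index=False)
    reg.to_csv(paths["registry"], index=False)
    return paths


@pytest.fixture(scope="session")
def fixture_units(fixture_frames):
    """Lake-country units built from the worked fixture."""
    occ, _, reg = fixture_frames
    registry = LakeRegistry.from_frame(reg)
    survivors, _ = filter_records(records_from_frame(occ), registry)
    return build_units(survivors, registry), registry
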