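"""Shared fixtures: the packaged study fixture and its recomputed products."""

from __future__ import annotations

import pandas as pd
import pytest

from tgfcys import (
    KnownInteractionSet,
    annotate_catalog,
    assign_cys_labels,
    conserved_cys_columns,
)
from tgfcys.fixture import load_study_fixture


@pytest.fixture(scope="session")
def fx():
    return load_study_fixture()


@pytest.fixture(scope="session")
def conserved(fx):
    """Conservation table recomputed from the fixture alignment."""
    tables = []
    for _, window in sorted(fx.windows.items()):
        cols = conserved_cys_columns(fx.alignment, window, fx.config["threshold"])
        tables.append(assign_cys_labels(fx.alignment, window, cols))
    return (
        pd.concat(tables, ignore_index=True)
        .sort_values(["region", "protein", "position"])
        .reset_index(drop=True)
    )


@pytest.fixture(scope="session")
def catalog(fx, conserved):
    """Fully annotated mutation catalog."""
    return annotate_catalog(
        fx.mutation_records,
        conserved,
        fx.records_by_id(),
        fx.partner_domains,
        fx.partner_ids,
        fx.synonyms,
    )


@pytest.fixture(scope="session")
def known(fx):
    return KnownInteractionSet(tuple(p) for p in fx.config["known_interactions"])
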