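"""Shared fixtures: synthetic panels, designs and screens built at test time."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

from odc.design import DrugPanel, DrugSpec, build_search1_design
from odc.screen_regression import ScreenDataset, model_matrix, second_order_terms

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def panel7() -> DrugPanel:
    return DrugPanel(
        tuple(DrugSpec.from_ic20(f"drug{i + 1:02d}", 0.5 * (i + 1)) for i in range(7))
    )


@pytest.fixture(scope="session")
def design50(panel7):
    return build_search1_design(panel7)


@pytest.fixture(scope="session")
def planted3(panel7, design50):
    """A 3-term sparse truth {drug01, drug02, drug01:drug02} on the 50-run design.

    Returns (true coefficient dict, noiseless per-condition response, helper
    that wraps replicate readouts into a ScreenDataset).
    """
    names = panel7.names
    terms = second_order_terms(names)
    X = model_matrix(design50.coded_scores(), names, terms)
    truth = {"drug01": -8.0, "drug02": -6.0, "drug01:drug02": -5.0}
    beta = np.array([truth.get(t, 0.0) for t in terms])
    y_true = 80.0 + X @ beta

    def make_ds(y: np.ndarray, model_id: str = "cancer") -> ScreenDataset:
        rec = [
            {"condition_id": cid, "replicate": r + 1, "viability_pct": float(v)}
            for cid, vals in zip(design50.row_ids, np.atleast_2d(y.T).T)
            for r, v in enumerate(np.atleast_1d(vals))
        ]
        return ScreenDataset(design50, model_id, pd.DataFrame(rec))

    return truth, y_true, make_ds


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
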