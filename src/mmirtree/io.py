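"""Reading and writing rating data, ground truth and fit outputs.

Canonical rating format: UTF-8 CSV with a header row of item ids, one
row per respondent, integer cells 1-5.  An optional leading column of
person ids is auto-detected (non-numeric header or non-rating values).
Rows with missing entries are listwise excluded with a logged count,
mirroring standard questionnaire preprocessing.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GeneratedDataset, get_condition, generate_condition
from .trees import InvalidResponseError, RatingMatrix

__all__ = ["read_ratings", "write_ratings", "write_truth", "read_truth",
           "make_fixture", "FIXTURE_KINDS"]

logger = logging.getLogger("mmirtree")


def read_ratings(path, sep=",") -> RatingMatrix:
    """Read a ratings CSV/TSV into a validated :class:`RatingMatrix`.

    Rows containing any missing cell are excluded listwise (the count is
    logged); non-integer or out-of-range cells raise a parse error
    naming the row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] > 1:
        first = df.iloc[:, 0]
        looks_like_ids = first.dtype == object or str(
            df.columns[0]).lower() in ("person", "person_id", "id", "respondent")
        if looks_like_ids:
            df = df.set_index(df.columns[0])
    n_before = len(df)
    complete = df.notna().all(axis=1)
    excluded = int(n_before - complete.sum())
    if excluded:
        logger.info("listwise excluded %d of %d rows with missing responses",
                    excluded, n_before)
    df = df.loc[complete]
    if df.empty:
        raise InvalidResponseError(f"{path}: no complete response rows")
    arr = df.to_numpy()
    flt = arr.astype(float)
    if not np.all(flt == np.round(flt)):
        p, j = np.argwhere(flt != np.round(flt))[0]
        raise InvalidResponseError(
            f"{path}: non-integer value {arr[p, j]!r} at row {df.index[p]!r}, "
            f"column {df.columns[j]!r}")
    bad = (flt < 1) | (flt > 5)
    if bad.any():
        p, j = np.argwhere(bad)[0]
        raise InvalidResponseError(
            f"{path}: rating {int(flt[p, j])} out of range [1, 5] at row "
            f"{df.index[p]!r}, column {df.columns[j]!r}")
    return RatingMatrix(flt.astype(np.int64), person_ids=df.index,
                        item_ids=df.columns)


def write_ratings(ratings: RatingMatrix, path) -> None:
    ratings.to_dataframe().to_csv(path, index_label="person_id")


def write_truth(dataset: GeneratedDataset, path) -> None:
    """Serialise a generated dataset's ground truth as JSON."""
    items = dataset.items
    persons = dataset.persons
    payload = {
        "condition": dataset.condition,
        "replication": dataset.replication,
        "pi_true": dataset.pi_true.tolist(),
        "z_true": dataset.z_true.tolist(),
        "seeds": dataset.seeds,
        "items": {
            "alpha_theta": items.alpha_theta.tolist(),
            "omega": items.omega,
            "alpha_ers": items.alpha_ers.tolist(),
            "alpha_mrs": items.alpha_mrs.tolist(),
            "beta": items.beta.tolist(),
        },
        "persons": {
            "theta": persons.theta.tolist(),
            "eta_ers": persons.eta_ers.tolist(),
            "eta_mrs": persons.eta_mrs.tolist(),
            "R": persons.R.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


#: registered unit-test fixture kinds -> (condition name, persons, items)
FIXTURE_KINDS = {
    "mixture_small": ("equal", 60, 8),
    "single_class_small": ("0rs_only", 60, 8),
    "dominated_small": ("ers_dominated", 80, 8),
}


def make_fixture(kind, seed=0) -> GeneratedDataset:
    """Deterministic tiny dataset with attached ground truth."""
    try:
        cond_name, n, J = FIXTURE_KINDS[kind]
    except KeyError:
        raise KeyError(
            f"unknown fixture kind {kind!r}; choose from {sorted(FIXTURE_KINDS)}"
        ) from None
    cond = get_condition(cond_name, n_persons=n, n_items=J,
                         n_replications=1, master_seed=seed)
    return generate_condition(cond)[0]
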