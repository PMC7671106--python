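"""Delimited-text readers and writers for the pipeline's table formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .diet import DietRecord, DietRecordSet
from .morpho import MEASUREMENTS, MeasurementSet
from .prey import CategorySet, PreyTraitMatrix, PreyValidationError

__all__ = [
    "read_prey_traits",
    "read_diet_records",
    "read_category_membership",
    "write_category_membership",
    "read_measurements",
    "read_habitat",
]


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def read_prey_traits(path) -> PreyTraitMatrix:
    """Prey-trait matrix: first column prey-item name, remaining {0,1} traits."""
    df = _read_table(path)
    items = df.iloc[:, 0].astype(str)
    vals = df.iloc[:, 1:]
    arr = vals.to_numpy()
    if arr.dtype == object or not np.isin(arr.astype(float), (0.0, 1.0)).all():
        bad = [
            (items.iloc[i], vals.columns[j], arr[i, j])
            for i in range(arr.shape[0])
            for j in range(arr.shape[1])
            if str(arr[i, j]) not in ("0", "1", "0.0", "1.0")
        ]
        if bad:
            it, tr, v = bad[0]
            raise PreyValidationError(
                f"non-binary cell {v!r} at item {it!r}, trait {tr!r}"
            )
    return PreyTraitMatrix(
        items=tuple(items),
        traits=tuple(str(c) for c in vals.columns),
        values=arr.astype(float),
    )


def read_diet_records(path) -> DietRecordSet:
    """Long-format records: species, study, prey_item, importance[, life_stage]."""
    df = _read_table(path)
    records = [
        DietRecord(
            species=str(r.species),
            study=str(r.study),
            prey_item=str(r.prey_item),
            importance=float(r.importance),
            life_stage=str(getattr(r, "life_stage", "adult")),
        )
        for r in df.itertuples(index=False)
    ]
    return DietRecordSet(records=records)


def read_category_membership(path) -> CategorySet:
    df = _read_table(path)
    membership = dict(zip(df["item"].astype(str), df["category_name"].astype(str)))
    names = tuple(dict.fromkeys(df["category_name"].astype(str)))
    return CategorySet(k=len(set(membership.values())), membership=membership,
                       names=tuple(sorted(names)))


def write_category_membership(cats: CategorySet, path) -> None:
    order = {c: i + 1 for i, c in enumerate(cats.categories)}
    rows = [
        {"item": item, "category_id": order[c], "category_name": c}
        for item, c in sorted(cats.membership.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_measurements(path) -> list[MeasurementSet]:
    """One row per specimen with the 12 measurement columns and a species key."""
    df = _read_table(path)
    out = []
    for r in df.itertuples(index=False):
        kwargs = {name: float(getattr(r, name)) for name in MEASUREMENTS}
        out.append(
            MeasurementSet(
                species=str(r.species),
                specimen_id=str(getattr(r, "specimen_id", "")),
                **kwargs,
            )
        )
    return out


def read_habitat(path) -> dict[str, str]:
    df = _read_table(path)
    return dict(zip(df["species"].astype(str), df["habitat"].astype(str)))
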