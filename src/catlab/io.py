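"""Delimited-text readers and writers for item banks and response matrices.

Item-bank files carry the header ``item_id,scale_id,model,m,a,b1,...,bK``
with unused threshold columns left blank. Response files have the
respondent id in the first column and one item per remaining column; empty
cells are missing. Likert codes on disk are 1-based by convention and are
shifted to the internal 0..m-1 coding on read (``origin=1``); pass
``origin=0`` for files already 0-based.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .irt import ItemBank, ItemParams, Model, ResponseMatrix

__all__ = ["read_item_bank", "write_item_bank", "read_responses", "write_responses"]


def read_item_bank(path: str | Path) -> ItemBank:
    df = pd.read_csv(path)
    required = {"item_id", "scale_id", "model", "m", "a"}
    if not required.issubset(df.columns):
        raise ValueError(f"bank file missing columns: {sorted(required - set(df.columns))}")
    bcols = sorted(
        (c for c in df.columns if c.startswith("b") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    items = []
    for row in df.itertuples(index=False):
        m = int(row.m)
        thr = [getattr(row, c) for c in bcols[: m - 1]]
        if any(pd.isna(t) for t in thr):
            raise ValueError(f"item {row.item_id}: expected {m - 1} thresholds")
        items.append(
            ItemParams(
                item_id=str(row.item_id),
                scale_id=str(row.scale_id),
                model=Model(str(row.model).upper()),
                m=m,
                a=float(row.a),
                thresholds=tuple(float(t) for t in thr),
                D=float(getattr(row, "D", 1.0)) if "D" in df.columns else 1.0,
            )
        )
    return ItemBank(items, provenance=str(path))


def write_item_bank(bank: ItemBank, path: str | Path) -> None:
    maxk = bank.max_m - 1
    rows = []
    for it in bank:
        row = {
            "item_id": it.item_id,
            "scale_id": it.scale_id,
            "model": it.model.value,
            "m": it.m,
            "a": it.a,
            "D": it.D,
        }
        for k in range(maxk):
            row[f"b{k + 1}"] = it.thresholds[k] if k < it.m - 1 else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_responses(path: str | Path, origin: int = 1) -> ResponseMatrix:
    df = pd.read_csv(path, index_col=0)
    codes = df.to_numpy(dtype=float) - origin
    if np.nanmin(codes) < 0:
        raise ValueError(f"codes below origin={origin} found in {path}")
    return ResponseMatrix(
        respondent_ids=[str(i) for i in df.index],
        item_ids=[str(c) for c in df.columns],
        codes=codes,
    )


def write_responses(X: ResponseMatrix, path: str | Path, origin: int = 1) -> None:
    df = pd.DataFrame(X.codes + origin, index=X.respondent_ids, columns=X.item_ids)
    df.index.name = "respondent_id"
    # keep integer appearance with blanks for missing
    df.to_csv(path, float_format="%.0f")
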