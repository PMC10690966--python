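"""Reading and writing cohort tables.

Cohort files are delimited text (comma by default, tab accepted) with a
header row, a respondent-id column and one column per schema item.  Column
matching is by header name, never by position.  Two raw coding dialects are
supported:

``zero_one``
    Values are integers on the item's own scale (0/1 for binary items,
    0..v for ordinal items).  Blank cells are missing; anything else that
    does not parse as an in-range integer is a located parse error.

``audadis_one_two``
    The lay-interview raw coding where 1 = present and 2 = absent.  1 is
    recoded to 1, 2 to 0, and any other code (blank, 9, ...) is treated as
    missing, which downstream listwise deletion then removes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .schema import Cohort, SchemaMismatchError, SymptomSchema

__all__ = ["read_cohort", "write_cohort", "CohortParseError", "DIALECTS"]

DIALECTS = ("zero_one", "audadis_one_two")
ID_COLUMN = "respondent_id"


class CohortParseError(ValueError):
    """A cell failed to parse; carries its row and column location."""

    def __init__(self, message: str, row: int, column: str) -> None:
        super().__init__(f"{message} (row {row}, column {column!r})")
        self.row = row
        self.column = column


def _read_table(path: Union[str, Path]) -> pd.DataFrame:
    # sep=None lets pandas sniff comma vs tab; everything read as string so
    # the dialect recode controls parsing, not pandas' type inference.
    return pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)


def read_cohort(
    path: Union[str, Path],
    schema: SymptomSchema,
    dialect: str = "zero_one",
    id_column: str = ID_COLUMN,
) -> Cohort:
    """Read a delimited cohort table aligned to *schema*.

    Raises :class:`SchemaMismatchError` if a required column is absent and
    :class:`CohortParseError` (with row/column location) on unparseable cells
    under the ``zero_one`` dialect.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    df = _read_table(path)
    if id_column not in df.columns:
        raise SchemaMismatchError(f"cohort file lacks id column {id_column!r}")
    for item_id in schema.item_ids:
        if item_id not in df.columns:
            raise SchemaMismatchError(f"cohort file lacks required column {item_id!r}")

    n, k = len(df), schema.k
    values = np.zeros((n, k), dtype=np.int64)
    missing = np.zeros((n, k), dtype=bool)
    lo, hi = schema.min_values, schema.max_values

    for j, item_id in enumerate(schema.item_ids):
        col = df[item_id].str.strip()
        if dialect == "audadis_one_two":
            values[:, j] = np.where(col == "1", 1, 0)
            missing[:, j] = ~col.isin(["1", "2"])
        else:
            blank = col == ""
            missing[:, j] = blank
            parsed = pd.to_numeric(col.where(~blank, other="0"), errors="coerce")
            bad = parsed.isna()
            if bad.any():
                row = int(np.argmax(bad.to_numpy()))
                raise CohortParseError(f"unparseable cell {col.iloc[row]!r}", row, item_id)
            iv = parsed.to_numpy()
            if not np.allclose(iv, np.round(iv)):
                row = int(np.argmax(~np.isclose(iv, np.round(iv))))
                raise CohortParseError(f"non-integer cell {col.iloc[row]!r}", row, item_id)
            iv = iv.astype(np.int64)
            out_of_range = (~blank.to_numpy()) & ((iv < lo[j]) | (iv > hi[j]))
            if out_of_range.any():
                row = int(np.argmax(out_of_range))
                raise CohortParseError(
                    f"value {iv[row]} outside scale [{lo[j]}, {hi[j]}]", row, item_id
                )
            values[:, j] = np.where(blank, 0, iv)

    return Cohort(schema, values, df[id_column].tolist(), missing)


def write_cohort(
    cohort: Cohort,
    path: Union[str, Path],
    id_column: str = ID_COLUMN,
    sep: str = ",",
) -> None:
    """Write a cohort in the ``zero_one`` dialect; missing cells are blank."""
    cols = {id_column: cohort.respondent_ids}
    for j, item_id in enumerate(cohort.schema.item_ids):
        col = cohort.values[:, j].astype(object)
        col[cohort.missing[:, j]] = ""
        cols[item_id] = col
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)
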