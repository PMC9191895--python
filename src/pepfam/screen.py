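"""Stage-0 discovery screen for short, putatively secreted proteins.

Replicates the opening move of the family hunt: take every protein
shorter than a length bound (strictly, default < 150 residues), keep
those with a positive signal-peptide call, and rank by elicitor-induced
transcript accumulation (log2 fold-change at a chosen timepoint column).
The screen ranks rather than cuts; an optional minimum log2FC is
available for pipeline use but off by default.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .famfilter import predict_signal_peptide
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)


def screen_short_secreted(proteome: Sequence[SequenceRecord],
                          expression: pd.DataFrame,
                          max_len: int = 150,
                          column: str = "flg22_90min",
                          require_sp: bool = True,
                          min_log2fc: float | None = None) -> pd.DataFrame:
    """Ranked candidate table of short secreted induced proteins.

    Keeps proteins with length strictly below ``max_len`` (and a positive
    SP call when ``require_sp``), sorted by descending log2FC in
    ``column`` with ties broken by id.  Proteins missing from the
    expression table are retained with a null log2FC and rank, sorted
    last, and logged — annotation gaps are expected for unannotated
    members.
    """
    if column not in expression.columns:
        raise KeyError(f"expression table has no column {column!r}")
    expr = expression.set_index("gene_id")[column]
    if expr.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression table")
    rows = []
    for rec in proteome:
        if len(rec) >= max_len:
            continue
        sp = predict_signal_peptide(rec) if len(rec) >= 25 else None
        if require_sp and sp is None:
            continue
        if rec.id in expr.index:
            fc = float(expr.loc[rec.id])
        else:
            fc = np.nan
            logger.warning("no expression row for %r; ranked last", rec.id)
        if min_log2fc is not None and not np.isnan(fc) and fc < min_log2fc:
            continue
        rows.append(dict(id=rec.id, species=rec.species, length=len(rec),
                         log2fc=fc, sp_call=sp is not None))
    table = pd.DataFrame(rows, columns=["id", "species", "length", "log2fc",
                                        "sp_call"])
    table = table.sort_values(
        ["log2fc", "id"], ascending=[False, True], na_position="last",
    ).reset_index(drop=True)
    table["rank"] = np.where(
        table["log2fc"].notna(), np.arange(1, len(table) + 1), np.nan
    )
    return table
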