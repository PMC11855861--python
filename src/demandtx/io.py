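"""Tab-separated readers and writers for the pipeline's file formats.

All files are UTF-8 TSV with a header row, ``.`` decimal point and ``#``
comment lines ignored on input.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .demand import ConsumptionCurve, DemandFit
from .errors import ValidationError
from .expression import ExpressionMatrix

__all__ = [
    "read_consumption_table",
    "write_consumption_table",
    "write_demand_fits",
    "read_demand_fits",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_meta",
    "read_de_table",
]

_TSV_KW = dict(sep="\t", comment="#", encoding="utf-8")


def _read_tsv(path, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path, **_TSV_KW)
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_consumption_table(path) -> list[ConsumptionCurve]:
    """Long format: ``subject_id, group, price, consumption`` -> curves."""
    df = _read_tsv(path, {"subject_id", "group", "price", "consumption"})
    curves = []
    for (subject, group), sub in df.groupby(["subject_id", "group"], sort=False):
        curves.append(
            ConsumptionCurve(
                str(subject), group, sub["price"].to_numpy(float), sub["consumption"].to_numpy(float)
            )
        )
    return curves


def write_consumption_table(curves: Sequence[ConsumptionCurve], path) -> None:
    rows = [
        dict(subject_id=c.subject_id, group=c.group.value, price=p, consumption=q)
        for c in curves
        for p, q in zip(c.prices, c.consumption)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_demand_fits(fits: Sequence[DemandFit], path) -> None:
    rows = [
        dict(
            subject_id=f.subject_id,
            group=f.group.value,
            q0=f.params.q0,
            alpha=f.params.alpha,
            k=f.params.k,
            ev=f.ev,
            pmax=f.pmax,
            omax_analytic=f.omax_analytic,
            omax_observed=np.nan if f.omax_observed is None else f.omax_observed,
            rss=f.rss,
            n_points_used=f.n_points_used,
            r_squared=f.r_squared,
        )
        for f in fits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_demand_fits(path) -> pd.DataFrame:
    return _read_tsv(path, {"subject_id", "group", "q0", "alpha", "k", "ev", "pmax"})


def write_expression_matrix(matrix: ExpressionMatrix, matrix_path, meta_path=None) -> None:
    df = pd.DataFrame(matrix.values, columns=matrix.sample_ids)
    df.insert(0, "gene_id", matrix.gene_ids)
    df.to_csv(matrix_path, sep="\t", index=False, lineterminator="\n")
    if meta_path is not None:
        matrix.sample_meta.reset_index().rename(columns={"index": "sample_id"}).to_csv(
            meta_path, sep="\t", index=False, lineterminator="\n"
        )


def read_sample_meta(path) -> pd.DataFrame:
    return _read_tsv(path, {"sample_id", "subject_id", "group"})


def read_expression_matrix(matrix_path, meta_path) -> ExpressionMatrix:
    """Gene-by-sample TSV (first column gene_id) plus sample metadata TSV."""
    df = pd.read_csv(matrix_path, **_TSV_KW)
    if df.columns[0] != "gene_id":
        raise ValidationError(f"{matrix_path}: first column must be gene_id")
    meta = read_sample_meta(meta_path)
    return ExpressionMatrix(
        gene_ids=df["gene_id"].astype(str).tolist(),
        sample_ids=[str(c) for c in df.columns[1:]],
        values=df.iloc[:, 1:].to_numpy(float),
        sample_meta=meta,
    )


def read_de_table(path) -> pd.DataFrame:
    return _read_tsv(path, {"gene_id", "log2_fc", "p_value"})
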