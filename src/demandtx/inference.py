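"""Group comparisons of fitted demand parameters.

Two-sample Student t tests (pooled variance by default, so two groups of six
give df = 10) on each derived demand index, plus per-group summary tables.
No multiplicity correction is applied across the four parameter tests; the
convention for this small, confirmatory family is to report raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .demand import DemandFit
from .errors import ValidationError

__all__ = ["ParamComparison", "pooled_t_test", "summarize_cohort", "compare_parameters"]

#: Demand indices compared between groups, in reporting order.
COMPARED_PARAMETERS = ("ev", "q0", "pmax", "omax")


@dataclass
class ParamComparison:
    """A two-sample t comparison of one demand parameter."""

    parameter: str
    t_stat: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float


def pooled_t_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    parameter: str = "",
    equal_var: bool = True,
) -> ParamComparison:
    """Two-sided two-sample t test.

    ``equal_var=True`` (default) is the classic pooled-variance Student test
    with ``df = n_a + n_b - 2``; ``equal_var=False`` switches to Welch.
    Degenerate case: zero pooled variance with equal means reports t = 0,
    p = 1; with unequal means it is an error (the statistic is undefined).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least 2 observations per group")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("non-finite values in t test input")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2 if equal_var else float("nan")
            return ParamComparison(parameter, 0.0, df, 1.0, a.mean(), b.mean(), 0.0, 0.0)
        raise ValidationError("zero variance with unequal means: t statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else float(res.df)
    return ParamComparison(
        parameter=parameter,
        t_stat=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
    )


def _fits_frame(fits: Iterable[DemandFit] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(fits, pd.DataFrame):
        return fits
    rows = []
    for f in fits:
        rows.append(
            dict(
                subject_id=f.subject_id,
                group=f.group.value,
                q0=f.params.q0,
                alpha=f.params.alpha,
                k=f.params.k,
                ev=f.ev,
                pmax=f.pmax,
                omax=f.omax_analytic,
            )
        )
    return pd.DataFrame(rows)


def summarize_cohort(fits: Iterable[DemandFit] | pd.DataFrame, by: str = "group") -> pd.DataFrame:
    """Per-group mean and sample SD of each demand parameter.

    Single-subject groups report SD as NaN (not available).
    """
    df = _fits_frame(fits)
    cols = [c for c in ("q0", "alpha", "ev", "pmax", "omax") if c in df.columns]
    if df.empty or not cols:
        raise ValidationError("no fits to summarize")
    agg = df.groupby(by)[cols].agg(["mean", lambda s: s.std(ddof=1)])
    agg.columns = [f"{p}_{'sd' if stat == '<lambda_0>' else stat}" for p, stat in agg.columns]
    return agg.reset_index()


def compare_parameters(
    fits: Iterable[DemandFit] | pd.DataFrame,
    group_a: str = "METH",
    group_b: str = "SAL",
    equal_var: bool = True,
) -> pd.DataFrame:
    """t-test table over EV, Q0, Pmax and Omax between two groups."""
    df = _fits_frame(fits)
    rows = []
    for param in COMPARED_PARAMETERS:
        if param not in df.columns:
            continue
        a = df.loc[df["group"] == group_a, param]
        b = df.loc[df["group"] == group_b, param]
        c = pooled_t_test(a, b, parameter=param, equal_var=equal_var)
        rows.append(
            dict(
                parameter=param,
                t=c.t_stat,
                df=c.df,
                p_value=c.p_value,
                mean_a=c.mean_a,
                mean_b=c.mean_b,
                sd_a=c.sd_a,
                sd_b=c.sd_b,
            )
        )
    return pd.DataFrame(rows)
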