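"""Synthetic cohorts with the statistical structure the pipeline assumes.

Two generators share one :class:`SimulationConfig`:

* :func:`simulate_demand_cohort` draws per-subject demand parameters
  (lognormal Q0 and alpha, group-separated) and realizes consumption on the
  escalating FR ladder with multiplicative (log10-additive Gaussian) noise,
  truncating each subject's ladder at the first price where the realized
  infusion count rounds to zero — the behavioral stopping rule.
* :func:`simulate_expression` draws an FPKM-like genes x samples matrix of
  negative-binomial counts whose log-mean is linear in each subject's
  essential value for a planted minority of genes.

Determinism: ``seed`` fully determines output, and behavior and expression
use independent child streams, so changing ``n_genes`` never perturbs the
behavioral draws.

Default parameter values emulate the 6 METH + 6 saline long-access
methamphetamine cohort this package ships as its reference dataset: the
lognormal hyperparameters reproduce that cohort's per-group geometric means
of Q0 and alpha (at k = 2.4), consumption is in mg/kg at 0.05 mg/kg per
infusion, and one METH expression sample can be dropped to mirror the
unbalanced 5 + 6 prefrontal-cortex design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict

import numpy as np
import pandas as pd

from .demand import (
    DEFAULT_PRICE_LADDER,
    UNIT_DOSE_MG_PER_KG,
    ConsumptionCurve,
    DemandParams,
    Group,
    derive_essential_value,
    predict_log10_consumption,
)
from .errors import ValidationError
from .expression import ExpressionMatrix

__all__ = ["SimulationConfig", "simulate_demand_cohort", "simulate_expression"]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic generators; ``seed`` fully determines output."""

    n_meth: int = 6
    n_sal: int = 6
    ladder: tuple = DEFAULT_PRICE_LADDER
    k_true: float = 2.4
    q0_logmean_meth: float = 1.93
    q0_logsd_meth: float = 0.64
    q0_logmean_sal: float = 0.10
    q0_logsd_sal: float = 0.56
    alpha_logmean_meth: float = -6.35
    alpha_logsd_meth: float = 0.66
    alpha_logmean_sal: float = -3.78
    alpha_logsd_sal: float = 0.39
    noise_sd_log10: float = 0.1
    unit_dose: float = UNIT_DOSE_MG_PER_KG
    n_genes: int = 2000
    frac_linked: float = 0.025
    slope_linked: float = 0.5
    baseline_logmean: float = 3.0
    baseline_logsd: float = 1.5
    theta: float = 10.0
    libsize_jitter: float = 0.1
    drop_meth_pfc_sample: bool = False
    region: str = "PFC"
    seed: int = 0

    def __post_init__(self):
        if self.n_meth < 1 or self.n_sal < 1:
            raise ValidationError("the two-group design needs at least 1 subject per group")
        ladder = tuple(float(p) for p in self.ladder)
        if any(p <= 0 for p in ladder) or any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValidationError("ladder must be strictly increasing and positive")
        self.ladder = ladder
        for name in ("k_true", "theta", "unit_dose"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("noise_sd_log10", "libsize_jitter", "q0_logsd_meth", "q0_logsd_sal",
                     "alpha_logsd_meth", "alpha_logsd_sal", "baseline_logsd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0.0 <= self.frac_linked <= 1.0):
            raise ValidationError("frac_linked must lie in [0, 1]")
        if self.n_genes < 0:
            raise ValidationError("n_genes must be >= 0")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimulationConfig":
        """Build from a flat key-value mapping; unknown keys are errors."""
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "ladder" in kwargs and isinstance(kwargs["ladder"], str):
            kwargs["ladder"] = tuple(float(v) for v in kwargs["ladder"].split(","))
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ladder"] = list(self.ladder)
        return d


def _streams(config: SimulationConfig):
    behavior_ss, expression_ss = np.random.SeedSequence(config.seed).spawn(2)
    return np.random.default_rng(behavior_ss), np.random.default_rng(expression_ss)


def simulate_demand_cohort(config: SimulationConfig):
    """Draw a cohort of consumption curves plus a generating-truth table.

    Returns ``(curves, truth)`` where ``truth`` records each subject's
    generating ``(Q0, alpha, k)`` and true EV.  Consumption is in mg/kg; the
    ladder is truncated after the first price whose realized infusion count
    (consumption / unit_dose) rounds to zero, and that failure price is
    recorded with zero consumption.
    """
    rng, _ = _streams(config)
    curves, rows = [], []
    subjects = [(f"M{i+1:02d}", Group.METH) for i in range(config.n_meth)] + [
        (f"S{i+1:02d}", Group.SAL) for i in range(config.n_sal)
    ]
    for subject_id, group in subjects:
        if group is Group.METH:
            q0 = float(np.exp(rng.normal(config.q0_logmean_meth, config.q0_logsd_meth)))
            alpha = float(np.exp(rng.normal(config.alpha_logmean_meth, config.alpha_logsd_meth)))
        else:
            q0 = float(np.exp(rng.normal(config.q0_logmean_sal, config.q0_logsd_sal)))
            alpha = float(np.exp(rng.normal(config.alpha_logmean_sal, config.alpha_logsd_sal)))
        params = DemandParams(q0=q0, alpha=alpha, k=config.k_true)
        prices, consumption = [], []
        for price in config.ladder:
            mean_log10 = predict_log10_consumption(params, price)
            q = 10.0 ** (mean_log10 + rng.normal(0.0, config.noise_sd_log10))
            infusions = q / config.unit_dose
            if round(infusions) == 0:
                prices.append(price)
                consumption.append(0.0)  # failed to earn a single infusion
                break
            prices.append(price)
            consumption.append(q)
        curves.append(ConsumptionCurve(subject_id, group, np.asarray(prices), np.asarray(consumption)))
        rows.append(
            dict(
                subject_id=subject_id,
                group=group.value,
                q0_true=q0,
                alpha_true=alpha,
                k_true=config.k_true,
                ev_true=derive_essential_value(params),
            )
        )
    return curves, pd.DataFrame(rows)


def simulate_expression(config: SimulationConfig, ev_by_subject: dict, groups_by_subject: dict | None = None):
    """Draw an NB expression matrix whose planted genes track EV.

    ``ev_by_subject`` maps subject_id -> EV (fitted or true).  One sample per
    subject is generated for ``config.region``; when ``drop_meth_pfc_sample``
    is set, the first METH subject's sample is omitted (the unbalanced
    design).  Returns ``(ExpressionMatrix, gene_truth)`` with per-gene true
    slopes in the truth table.
    """
    _, rng = _streams(config)
    subjects = list(ev_by_subject)
    if not subjects:
        raise ValidationError("ev_by_subject is empty")
    if groups_by_subject is None:
        groups_by_subject = {
            s: ("METH" if str(s).startswith("M") else "SAL") for s in subjects
        }
    if config.drop_meth_pfc_sample:
        meth = [s for s in subjects if groups_by_subject[s] == "METH"]
        if meth:
            subjects = [s for s in subjects if s != meth[0]]

    ev = np.asarray([float(ev_by_subject[s]) for s in subjects])
    if np.any(~np.isfinite(ev)):
        raise ValidationError("every subject needs a finite EV")

    n_genes = config.n_genes
    n_linked = int(round(config.frac_linked * n_genes))
    gene_ids = [f"gene{g+1:05d}" for g in range(n_genes)]
    linked_idx = rng.choice(n_genes, size=n_linked, replace=False) if n_linked else np.array([], dtype=int)
    slopes = np.zeros(n_genes)
    slopes[linked_idx] = config.slope_linked
    b0 = rng.normal(config.baseline_logmean, config.baseline_logsd, size=n_genes)
    libsize = 1.0 + rng.uniform(-config.libsize_jitter, config.libsize_jitter, size=len(subjects))

    log_mu = b0[:, None] + slopes[:, None] * ev[None, :] + np.log(libsize)[None, :]
    mu = np.exp(np.clip(log_mu, -30.0, 30.0))
    theta = config.theta
    counts = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)

    sample_ids = [f"{config.region}_{s}" for s in subjects]
    meta = pd.DataFrame(
        dict(
            sample_id=sample_ids,
            subject_id=subjects,
            group=[groups_by_subject[s] for s in subjects],
            region=config.region,
            ev=ev,
            libsize_factor=libsize,
        )
    )
    matrix = ExpressionMatrix(gene_ids, sample_ids, counts, meta)
    truth = pd.DataFrame(dict(gene_id=gene_ids, slope_true=slopes, baseline_logmean=b0))
    return matrix, truth
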