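"""End-to-end orchestration: simulate -> fit demand -> compare -> regress genes.

:func:`run_all` runs every stage in order against one output directory,
fails fast with a stage-tagged error, and records a manifest (config
snapshot, seed, versions, SHA-256 digest per output file) so that identical
config + seed provably reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .demand import compare_alpha_extra_ss_f, fit_demand_shared_k
from .errors import StageError
from .expression import filter_degs, nb_group_contrast, regress_all_genes
from .inference import compare_parameters
from .io import (
    write_consumption_table,
    write_demand_fits,
    write_expression_matrix,
)
from .simulate import SimulationConfig, simulate_demand_cohort, simulate_expression

log = logging.getLogger("demandtx")

__all__ = ["RunManifest", "run_all"]


@dataclasses.dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config: dict
    seed: int
    version: str
    digests: dict
    timestamps: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: SimulationConfig, out_dir, seed: int | None = None) -> RunManifest:
    """Run the full synthetic pipeline; returns the manifest (also written).

    Stages: ``simulate`` (behavior + expression), ``fit-demand`` (shared-k
    joint fit per subject), ``compare-groups`` (parameter t tests and the
    alpha extra-SS F test), ``gene-regression`` (per-gene NB on fitted EV,
    BH-corrected), ``filter-degs`` (NB group contrast through the threshold
    rule).  Partial outputs are retained on failure for debugging.
    """
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timestamps = {}
    outputs: dict[str, Path] = {}

    def stage(name):
        log.info("stage %s", name)
        timestamps[name] = time.strftime("%Y-%m-%dT%H:%M:%S")

    try:
        stage("simulate")
        curves, truth_behavior = simulate_demand_cohort(config)
        outputs["consumption.tsv"] = out / "consumption.tsv"
        write_consumption_table(curves, outputs["consumption.tsv"])
        truth_behavior.to_csv(out / "truth_behavior.tsv", sep="\t", index=False, lineterminator="\n")
        outputs["truth_behavior.tsv"] = out / "truth_behavior.tsv"
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    try:
        stage("fit-demand")
        k_shared, fits = fit_demand_shared_k(curves, grouping="per-subject",
                                             random_state=config.seed)
        outputs["demand_fits.tsv"] = out / "demand_fits.tsv"
        write_demand_fits(fits, outputs["demand_fits.tsv"])
        log.info("shared k = %.4f over %d curves", k_shared, len(fits))
    except Exception as exc:
        raise StageError("fit-demand", exc) from exc

    try:
        stage("compare-groups")
        comparisons = compare_parameters(fits)
        outputs["param_comparisons.tsv"] = out / "param_comparisons.tsv"
        comparisons.to_csv(outputs["param_comparisons.tsv"], sep="\t", index=False, lineterminator="\n")
        f_res = compare_alpha_extra_ss_f(curves, random_state=config.seed)
        outputs["curve_comparison.tsv"] = out / "curve_comparison.tsv"
        pd.DataFrame(
            [dict(f_stat=f_res.f_stat, df_num=f_res.df_num, df_den=f_res.df_den,
                  p_value=f_res.p_value, rss_full=f_res.rss_full, rss_reduced=f_res.rss_reduced)]
        ).to_csv(outputs["curve_comparison.tsv"], sep="\t", index=False, lineterminator="\n")
    except Exception as exc:
        raise StageError("compare-groups", exc) from exc

    try:
        stage("simulate-expression")
        ev_by_subject = {f.subject_id: f.ev for f in fits}
        groups = {f.subject_id: f.group.value for f in fits}
        matrix, truth_genes = simulate_expression(config, ev_by_subject, groups)
        outputs["expression.tsv"] = out / "expression.tsv"
        outputs["sample_meta.tsv"] = out / "sample_meta.tsv"
        write_expression_matrix(matrix, outputs["expression.tsv"], outputs["sample_meta.tsv"])
        truth_genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False, lineterminator="\n")
        outputs["truth_genes.tsv"] = out / "truth_genes.tsv"
    except Exception as exc:
        raise StageError("simulate-expression", exc) from exc

    try:
        stage("gene-regression")
        gene_results = regress_all_genes(matrix, predictor="ev")
        outputs["gene_ev_regression.tsv"] = out / "gene_ev_regression.tsv"
        gene_results.to_csv(outputs["gene_ev_regression.tsv"], sep="\t", index=False, lineterminator="\n")
    except Exception as exc:
        raise StageError("gene-regression", exc) from exc

    try:
        stage("filter-degs")
        contrast = nb_group_contrast(matrix)
        tested = contrast.dropna(subset=["log2_fc", "p_value"])
        degs = filter_degs(tested)
        outputs["degs.tsv"] = out / "degs.tsv"
        pd.DataFrame(
            [dict(gene_id=d.gene_id, log2_fc=d.log2_fc, p_value=d.p_value, direction=d.direction)
             for d in degs],
            columns=["gene_id", "log2_fc", "p_value", "direction"],
        ).to_csv(outputs["degs.tsv"], sep="\t", index=False, lineterminator="\n")
    except Exception as exc:
        raise StageError("filter-degs", exc) from exc

    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        version=__version__,
        digests={name: _sha256(path) for name, path in sorted(outputs.items())},
        timestamps=timestamps,
    )
    (out / "manifest.json").write_text(manifest.to_json() + "\n", encoding="utf-8")
    return manifest
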