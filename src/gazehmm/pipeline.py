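"""End-to-end orchestration: QC -> representative ROIs -> individual
models -> semantics -> gaze variables -> mixed-effects statistics.

Each stimulus id is analysed independently (its own feature transform,
representative model and individual fits); the statistics stage then
pools stimuli with the actor count as a fixed effect.  Every stage logs
its input/output sizes and the seed in use, and identical config + seed
reproduce identical outputs.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as gio
from .bhmm import decode
from .group import (IndividualModel, RepresentativeModel, fit_individual,
                    fit_representative)
from .preprocess import apply_qc
from .simulate import StimulusTemplate, match_states_to_template
from .stats import run_all_models, group_effect_pretest, format_report
from .types import FeatureTransform, PipelineConfig, Scanpath, \
    ValidationError
from .variables import (build_variable_table, flag_sparse_state,
                        participant_variables)

log = logging.getLogger("gazehmm")


@dataclass
class PipelineResult:
    config: PipelineConfig
    qc_report: pd.DataFrame
    representatives: dict              # stimulus_id -> RepresentativeModel
    individuals: dict                  # (pid, stimulus_id) -> IndividualModel
    labels: dict                       # stimulus_id -> {state: category}
    variable_table: pd.DataFrame
    stats_report: pd.DataFrame | None
    covariate_pretests: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, scanpaths: list[Scanpath],
                 cohort: pd.DataFrame, stimuli: dict,
                 labels: dict | None = None,
                 templates: dict[str, StimulusTemplate] | None = None,
                 tracking_ratios: dict | None = None,
                 stimulus_duration_ms: float = 120_000.0,
                 k_range_per_class: dict | None = None,
                 run_stats: bool = True,
                 out_dir: str | None = None) -> PipelineResult:
    """Run the full analysis.

    Parameters
    ----------
    labels
        Optional {stimulus_id: {state_index: category}} semantic map for
        the representative states.  Without it, ``templates`` (per
        stimulus class) must be given and states are labelled by their
        nearest template ROI — the synthetic stand-in for manual
        annotation.
    k_range_per_class
        Optional {stimulus_class: iterable of K} overriding the config
        state-count range, e.g. to pin K where it is known.
    """
    seed = config.seed
    group_of = dict(zip(cohort["participant_id"].astype(str),
                        cohort["group"]))
    missing = {sp.participant_id for sp in scanpaths} - set(group_of)
    if missing:
        raise ValidationError(f"participants without cohort rows: "
                              f"{sorted(missing)[:5]}")

    kept, qc_report = apply_qc(scanpaths, config,
                               tracking_ratios=tracking_ratios,
                               stimulus_duration_ms=stimulus_duration_ms)
    if not kept:
        raise RuntimeError("quality control excluded every recording")

    by_stim: dict[str, list[Scanpath]] = {}
    for sp in kept:
        if sp.stimulus_id not in stimuli:
            raise ValidationError(f"unknown stimulus id {sp.stimulus_id!r}")
        by_stim.setdefault(sp.stimulus_id, []).append(sp)

    representatives, individuals, all_labels = {}, {}, {}
    records = []
    for si, (stim_id, sps) in enumerate(sorted(by_stim.items())):
        n_participants = len({sp.participant_id for sp in sps})
        if n_participants < 2:
            raise RuntimeError(
                f"stimulus {stim_id}: fewer than 2 participants passed QC")
        cls = stimuli[stim_id]
        k_range = None
        if k_range_per_class and cls in k_range_per_class:
            k_range = k_range_per_class[cls]
        transform = FeatureTransform.fit(sps,
                                         log_duration=config.log_duration)
        rep = fit_representative(sps, config, transform=transform,
                                 stimulus_id=stim_id, k_range=k_range,
                                 seed=seed + 101 * (si + 1))
        representatives[stim_id] = rep

        if labels is not None and stim_id in labels:
            lab = dict(labels[stim_id])
        elif templates is not None and cls in templates:
            lab = match_states_to_template(rep.model, templates[cls])
        else:
            raise ValidationError(
                f"no semantic labels for stimulus {stim_id} and no "
                f"template to derive them from")
        sparse = flag_sparse_state(rep)
        if sparse is not None:
            lab[sparse] = "excluded"
            log.info("stage=sparse stimulus=%s state=%d excluded",
                     stim_id, sparse)
        all_labels[stim_id] = lab

        for pi, sp in enumerate(sorted(sps, key=lambda s: s.participant_id)):
            seq = transform.apply(sp)
            ind = fit_individual([seq], rep, config, sp.participant_id,
                                 seed=seed + 7919 * (si + 1) + pi)
            individuals[(sp.participant_id, stim_id)] = ind
            assignment = decode(ind.model, seq)
            rows = participant_variables(
                ind if not ind.infeasible else rep.model, assignment, sp,
                lab, occupancy_mode=config.occupancy_mode)
            if ind.infeasible:
                for r in rows:
                    if r["variable"] == "transition_probability":
                        r["value"] = float("nan")
            records.append({"participant": sp.participant_id,
                            "group": group_of[sp.participant_id],
                            "stimulus": stim_id, "actors": cls,
                            "rows": rows})

    table = build_variable_table(records)
    pretests, report = {}, None
    if run_stats:
        for covar in ("total_transitions", "total_fixation_duration"):
            try:
                pretests[covar] = group_effect_pretest(table, covar,
                                                       reml=config.reml)
            except Exception as exc:
                pretests[covar] = (float("nan"), float("nan"))
                log.warning("stage=pretest variable=%s failed: %s",
                            covar, exc)
        report = run_all_models(table, alpha=config.alpha, reml=config.reml,
                                fdr=config.fdr_correction)

    result = PipelineResult(config=config, qc_report=qc_report,
                            representatives=representatives,
                            individuals=individuals, labels=all_labels,
                            variable_table=table, stats_report=report,
                            covariate_pretests=pretests)
    if out_dir is not None:
        _write_bundle(result, out_dir)
    return result


def _write_bundle(result: PipelineResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    cfg, seed = result.config, result.config.seed
    hdr = gio._header_comment(cfg, seed)
    with open(os.path.join(out_dir, "qc_report.csv"), "w",
              encoding="utf-8", newline="") as fh:
        fh.write(hdr)
        result.qc_report.to_csv(fh, index=False)
    for stim_id, rep in result.representatives.items():
        gio.write_model(rep.model,
                        os.path.join(out_dir, f"representative_{stim_id}.json"),
                        config=cfg, seed=seed)
        gio.write_roi_labels(result.labels[stim_id],
                             os.path.join(out_dir, f"labels_{stim_id}.csv"),
                             config=cfg)
    rows = []
    for (pid, stim_id), ind in result.individuals.items():
        for k in range(len(ind.correspondence)):
            rows.append({"participant": pid, "stimulus": stim_id,
                         "individual_state": k,
                         "representative_state": int(ind.correspondence[k]),
                         "mean_drift_px": float(ind.mean_drift_px[k])})
    with open(os.path.join(out_dir, "correspondence.csv"), "w",
              encoding="utf-8", newline="") as fh:
        fh.write(hdr)
        pd.DataFrame(rows).to_csv(fh, index=False)
    gio.write_variable_table(result.variable_table,
                             os.path.join(out_dir, "variable_table.csv"),
                             config=cfg, seed=seed)
    if result.stats_report is not None:
        with open(os.path.join(out_dir, "stats_report.csv"), "w",
                  encoding="utf-8", newline="") as fh:
            fh.write(hdr)
            result.stats_report.to_csv(fh, index=False)
        with open(os.path.join(out_dir, "stats_report.txt"), "w",
                  encoding="utf-8") as fh:
            fh.write(hdr + format_report(result.stats_report) + "\n")
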