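"""Linear mixed-effects group comparison of the gaze variables.

Each gaze variable is analysed per ROI category with the model

    value ~ 1 + group + actors + group:actors + covariate_c + (1 | participant)

where group is the clinical group (reference TD), actors the stimulus
class (one vs four depicted actors) and covariate_c a mean-centred
per-recording covariate: total transition count for transition counts,
total fixation duration (s) for fixation and visit counts, and none for
transition probabilities.  Fits use REML (configurable); the group effect
is a joint Wald F test of the two TD contrasts with between-participant
denominator degrees of freedom, and post-hoc contrasts (TD vs ASD, TD vs
ASD+ADHD) are differences of estimated marginal means at centred
covariate and balanced actor conditions.  Significance is alpha = 0.05;
no multiple-testing correction is applied by default (a Benjamini-
Hochberg flag is available).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import GROUPS, CATEGORIES, PAIRS, ValidationError

log = logging.getLogger("gazehmm")

# which covariate accompanies which response family
COVARIATE_FOR = {"transition_count": "total_transitions",
                 "transition_probability": None,
                 "fixation_count": "total_fixation_duration",
                 "visit_count": "total_fixation_duration"}


@dataclass(frozen=True)
class LmmSpec:
    """One mixed-model specification: response + optional covariate."""

    variable: str
    category: str
    covariate: str | None

    def __post_init__(self):
        if (self.covariate is None) != \
                (self.variable == "transition_probability"):
            raise ValueError("probability variables take no covariate;"
                             " all others require one")


@dataclass
class LmmResult:
    spec: LmmSpec
    f_group: float
    p_group: float
    emmeans: dict            # group -> (estimate, SE)
    contrasts: dict          # (ref, other) -> (estimate, SE, p)
    n_obs: int
    n_participants: int
    converged: bool
    singular: bool
    error: str = ""


def center_covariate(table: pd.DataFrame, covariate: str) -> pd.DataFrame:
    """Replace a covariate column by its deviation from the grand mean."""
    if covariate not in table.columns:
        raise ValidationError(f"covariate column {covariate!r} absent")
    missing = table.index[table[covariate].isna()].tolist()
    if missing:
        raise ValidationError(
            f"covariate {covariate!r} missing in rows {missing[:10]}")
    out = table.copy()
    out[covariate] = out[covariate] - out[covariate].mean()
    return out


def pivot_for_model(table: pd.DataFrame, spec: LmmSpec) -> pd.DataFrame:
    """Wide frame (participant, group, stimulus, actors, value, covariate)
    for one model, dropping recordings where the response is undefined."""
    resp = table[(table["variable"] == spec.variable)
                 & (table["category"] == spec.category)]
    wide = resp[["participant", "group", "stimulus", "actors",
                 "value"]].copy()
    if spec.covariate is not None:
        cov = table[table["variable"] == spec.covariate][
            ["participant", "stimulus", "value"]].rename(
            columns={"value": "covariate"})
        wide = wide.merge(cov, on=["participant", "stimulus"], how="left")
    wide = wide.dropna(subset=["value"])
    return wide.sort_values(["participant", "stimulus"],
                            kind="mergesort").reset_index(drop=True)


def _marginal_row(exog_names, group, cov_center=0.0):
    """Design vector at the given group, balanced actors, centred covariate."""
    x = np.zeros(len(exog_names))
    for i, name in enumerate(exog_names):
        if name == "Intercept":
            x[i] = 1.0
        elif "covariate" in name:
            x[i] = cov_center
        elif "group" in name and "actors" in name:   # interaction
            x[i] = 0.5 if f"[T.{group}]" in name else 0.0
        elif "group" in name:
            x[i] = 1.0 if f"[T.{group}]" in name else 0.0
        elif "actors" in name:
            x[i] = 0.5
    return x


def fit_lmm(table: pd.DataFrame, spec: LmmSpec,
            reml: bool = True) -> LmmResult:
    """Fit one mixed model and summarise group effect and contrasts."""
    wide = pivot_for_model(table, spec)
    groups_present = sorted(set(wide["group"]))
    if len(groups_present) < 2:
        raise ValidationError("need at least two groups to compare")
    for g in groups_present:
        if g not in GROUPS:
            raise ValidationError(f"unknown group {g}")
    if spec.covariate is not None:
        wide = center_covariate(wide, "covariate")

    formula = "value ~ C(group, Treatment('TD')) * C(actors)"
    if spec.covariate is not None:
        formula += " + covariate"
    n_part = wide["participant"].nunique()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(formula, wide, groups=wide["participant"])
            try:
                res = md.fit(reml=reml)
            except Exception:
                res = md.fit(reml=reml, method="powell")
    except Exception as exc:
        return LmmResult(spec, np.nan, np.nan, {}, {}, len(wide), n_part,
                         False, False, error=str(exc))

    fe = res.fe_params
    names = list(fe.index)
    k = len(names)
    cov = np.asarray(res.cov_params())[:k, :k]
    beta = fe.to_numpy()
    singular = bool(np.asarray(res.cov_re).max() < 1e-8)

    ddf = max(n_part - len(groups_present), 1)
    others = [g for g in groups_present if g != "TD"]
    rows_em, contrasts = {}, {}
    for g in groups_present:
        x = _marginal_row(names, g)
        est = float(x @ beta)
        se = float(np.sqrt(x @ cov @ x))
        rows_em[g] = (est, se)
    L = []
    for g in others:
        c = _marginal_row(names, g) - _marginal_row(names, "TD")
        L.append(c)
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        t = est / se if se > 0 else np.nan
        p = float(2 * sps.t.sf(abs(t), ddf)) if np.isfinite(t) else np.nan
        contrasts[("TD", g)] = (est, se, p)
    L = np.array(L)
    try:
        M = L @ cov @ L.T
        F = float(beta @ L.T @ np.linalg.solve(M, L @ beta)) / len(L)
        p_group = float(sps.f.sf(F, len(L), ddf))
    except np.linalg.LinAlgError:
        F, p_group = np.nan, np.nan
    return LmmResult(spec, F, p_group, rows_em, contrasts, len(wide),
                     n_part, bool(res.converged), singular)


def group_effect_pretest(table: pd.DataFrame, variable: str,
                         reml: bool = True) -> tuple[float, float]:
    """Group-effect F and p for a candidate covariate variable.

    Run before total transitions / total fixation duration enter the main
    models as covariates, to verify they do not themselves differ by
    group.
    """
    wide = table[(table["variable"] == variable)][
        ["participant", "group", "stimulus", "actors", "value"]].copy()
    spec_like = wide.dropna(subset=["value"])
    n_part = spec_like["participant"].nunique()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm("value ~ C(group, Treatment('TD')) * C(actors)",
                         spec_like, groups=spec_like["participant"])
        try:
            res = md.fit(reml=reml)
        except Exception:
            res = md.fit(reml=reml, method="powell")
    fe = res.fe_params
    names = list(fe.index)
    cov = np.asarray(res.cov_params())[:len(names), :len(names)]
    groups_present = sorted(set(spec_like["group"]))
    others = [g for g in groups_present if g != "TD"]
    L = np.array([_marginal_row(names, g) - _marginal_row(names, "TD")
                  for g in others])
    M = L @ cov @ L.T
    beta = fe.to_numpy()
    F = float(beta @ L.T @ np.linalg.solve(M, L @ beta)) / len(L)
    ddf = max(n_part - len(groups_present), 1)
    return F, float(sps.f.sf(F, len(L), ddf))


def all_model_specs() -> list[LmmSpec]:
    """The 16 analysed models: counts and probabilities for the five ROI
    pairs, fixation and visit counts for the three ROI categories."""
    specs = []
    for pair in PAIRS:
        specs.append(LmmSpec("transition_count", pair,
                             COVARIATE_FOR["transition_count"]))
        specs.append(LmmSpec("transition_probability", pair, None))
    for cat in CATEGORIES:
        specs.append(LmmSpec("fixation_count", cat,
                             COVARIATE_FOR["fixation_count"]))
        specs.append(LmmSpec("visit_count", cat,
                             COVARIATE_FOR["visit_count"]))
    return specs


def run_all_models(table: pd.DataFrame, alpha: float = 0.05,
                   reml: bool = True, fdr: bool = False) -> pd.DataFrame:
    """Fit every specified model; one report row per model.

    Individual model failures are recorded in the report and do not stop
    the remaining fits.
    """
    rows = []
    for spec in all_model_specs():
        try:
            r = fit_lmm(table, spec, reml=reml)
        except ValidationError as exc:
            rows.append({"variable": spec.variable,
                         "category": spec.category, "error": str(exc)})
            continue
        row = {"variable": spec.variable, "category": spec.category,
               "covariate": spec.covariate or "",
               "F_group": r.f_group, "p_group": r.p_group,
               "n_obs": r.n_obs, "converged": r.converged,
               "singular": r.singular, "error": r.error}
        for g in GROUPS:
            if g in r.emmeans:
                row[f"emmean_{g}"] = r.emmeans[g][0]
                row[f"se_{g}"] = r.emmeans[g][1]
        for (ref, other), (est, se, p) in r.contrasts.items():
            row[f"contrast_{ref}_vs_{other}"] = est
            row[f"p_{ref}_vs_{other}"] = p
        rows.append(row)
    report = pd.DataFrame(rows)
    pcols = [c for c in report.columns if c.startswith("p_TD_vs_")]
    if fdr:
        for c in pcols:
            ok = report[c].notna()
            if ok.any():
                report.loc[ok, c + "_fdr"] = multipletests(
                    report.loc[ok, c], method="fdr_bh")[1]
    for c in pcols:
        report[c.replace("p_", "sig_")] = report[c] < alpha
    log.info("stage=stats n_models=%d alpha=%s", len(report), alpha)
    return report


def format_report(report: pd.DataFrame) -> str:
    """Human-readable table of the group effects and contrasts."""
    lines = ["variable                 category              F      p(TD/ASD)"
             "  p(TD/ASD+ADHD)   emmeans TD / ASD / ASD+ADHD"]
    for _, r in report.iterrows():
        if r.get("error"):
            lines.append(f"{r['variable']:<24} {r['category']:<20} "
                         f"failed: {r['error']}")
            continue
        em = " / ".join(
            f"{r.get(f'emmean_{g}', float('nan')):.3g}"
            f"±{r.get(f'se_{g}', float('nan')):.2g}" for g in GROUPS)
        lines.append(
            f"{r['variable']:<24} {r['category']:<20} "
            f"{r['F_group']:6.2f}  {r.get('p_TD_vs_ASD', float('nan')):9.3f}"
            f"  {r.get('p_TD_vs_ASD_ADHD', float('nan')):14.3f}   {em}")
    return "\n".join(lines)
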