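"""ROI semantics and derived gaze variables.

Learned states are categorised as face, body or non-social (social =
face + body); one state per stimulus typically captures sparse,
long-duration fixations with no regional pattern and is excluded from the
category variables.  From each participant's decoded state sequence and
fitted transition matrix the module derives, per stimulus:

* transition counts for the five analysed ROI pairs (face-face, body-body,
  face-body, body-face, nonsocial-nonsocial); social<->nonsocial changes
  are tallied as "mixed" for bookkeeping but not analysed;
* model-based transition probabilities per pair (self-transitions removed
  and rows renormalised, aggregated over source states with occupancy
  weights);
* fixation count and visit count per ROI category;
* total fixation duration (s) and total transition count.

A transition is a change between two *distinct* non-excluded states;
consecutive fixations in the same state belong to one visit and are not
transitions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import CATEGORIES, PAIRS, Scanpath, StateAssignment, \
    ValidationError

log = logging.getLogger("gazehmm")

SOCIAL = ("face", "body")


def flag_sparse_state(model) -> int | None:
    """Index of the sparse catch-all state, if one dominates both criteria.

    The candidate must simultaneously have the longest mean fixation
    duration and the largest spatial covariance determinant (no regional
    pattern); if no single state tops both rankings, returns None.
    """
    m = getattr(model, "model", model)
    dur = m.means[:, 2]
    spat = np.array([np.linalg.det(c[:2, :2]) for c in m.covariances])

    def unique_argmax(v):
        k = int(np.argmax(v))
        ties = np.isclose(v, v[k], rtol=1e-9, atol=1e-12).sum()
        return k if ties == 1 else None

    k_dur = unique_argmax(dur)
    k_spat = unique_argmax(spat)
    return k_dur if (k_dur is not None and k_dur == k_spat) else None


def _check_labels(labels: dict, n_states: int) -> None:
    if set(labels) != set(range(n_states)):
        raise ValidationError(
            f"label map must cover states 0..{n_states - 1} exactly")
    allowed = set(CATEGORIES) | {"excluded"}
    bad = {v for v in labels.values() if v not in allowed}
    if bad:
        raise ValidationError(f"unknown categories {sorted(bad)}")
    if all(v == "excluded" for v in labels.values()):
        raise ValidationError("at least one state must be analysable")


def _pair_name(c1: str, c2: str) -> str:
    if (c1 in SOCIAL) != (c2 in SOCIAL):
        return "mixed"
    return f"{c1}_{c2}"


def _collapse_runs(states: np.ndarray) -> np.ndarray:
    states = np.asarray(states)
    if len(states) == 0:
        return states
    keep = np.r_[True, states[1:] != states[:-1]]
    return states[keep]


def count_transitions(assignment: StateAssignment | np.ndarray,
                      labels: dict) -> dict:
    """Unidirectional transition counts per category pair.

    Transitions touching an excluded state are dropped from both the
    per-pair counts and the total.  Returns a dict with the five analysed
    pairs, "mixed", and "total".
    """
    states = assignment.map_states if isinstance(assignment, StateAssignment) \
        else np.asarray(assignment)
    if isinstance(assignment, StateAssignment):
        _check_labels(labels, assignment.n_states)
    elif len(states) and (states.max() not in labels or
                          int(states.min()) < 0):
        raise ValidationError("assignment states outside the label map")
    runs = _collapse_runs(states)
    counts = {p: 0 for p in PAIRS}
    counts["mixed"] = 0
    total = 0
    for a, b in zip(runs[:-1], runs[1:]):
        ca, cb = labels[int(a)], labels[int(b)]
        if ca == "excluded" or cb == "excluded":
            continue
        total += 1
        counts[_pair_name(ca, cb)] += 1
    counts["total"] = total
    return counts


def total_transitions(assignment, labels: dict) -> int:
    """Number of state changes between non-excluded states (incl. mixed)."""
    return count_transitions(assignment, labels)["total"]


def count_fixations_visits(assignment: StateAssignment, labels: dict,
                           scanpath: Scanpath) -> dict:
    """Fixation counts, visit counts per category and total duration (s).

    A visit is a maximal run of consecutive fixations in one state,
    attributed to that state's category; excluded-state fixations and
    visits are dropped.  Total fixation duration covers *all* fixations,
    regardless of ROI.
    """
    states = assignment.map_states
    if len(states) != len(scanpath):
        raise ValidationError("assignment and scanpath lengths differ")
    _check_labels(labels, assignment.n_states)
    fix = {c: 0 for c in CATEGORIES}
    vis = {c: 0 for c in CATEGORIES}
    for s in states:
        c = labels[int(s)]
        if c != "excluded":
            fix[c] += 1
    for s in _collapse_runs(states):
        c = labels[int(s)]
        if c != "excluded":
            vis[c] += 1
    return {"fixation_count": fix, "visit_count": vis,
            "total_fixation_duration_s":
                float(scanpath.duration_ms.sum()) / 1000.0}


def occupancy_weights(model, labels: dict, assignment=None,
                      mode: str = "responsibilities") -> np.ndarray:
    """Expected relative occupancy of the non-excluded states.

    "responsibilities" sums decoded responsibilities (requires
    ``assignment``; falls back to the stationary distribution without
    one), "stationary" uses the stationary distribution of the transition
    matrix restricted to non-excluded states, "uniform" weights states
    equally.
    """
    K = model.n_states
    keep = np.array([labels[k] != "excluded" for k in range(K)])
    if mode == "responsibilities" and assignment is not None:
        w = assignment.responsibilities.sum(axis=0)
    elif mode == "uniform":
        w = np.ones(K)
    else:
        A = model.transition[np.ix_(keep, keep)]
        A = A / A.sum(axis=1, keepdims=True)
        vals, vecs = np.linalg.eig(A.T)
        p = np.abs(np.real(vecs[:, np.argmin(np.abs(vals - 1.0))]))
        w = np.zeros(K)
        w[keep] = p
    w = np.where(keep, w, 0.0)
    s = w.sum()
    if s <= 0:
        raise ValidationError("no occupancy mass on analysable states")
    return w / s


def transition_probability(model, labels: dict, assignment=None,
                           occupancy_mode: str = "responsibilities") -> dict:
    """Model-based probability of a transition between two ROI categories.

    For each non-excluded source state the self-transition is removed and
    the row renormalised over the other non-excluded states; category
    pairs then aggregate with occupancy weights over the source category:

        P(c1 -> c2) = sum_{i in c1} w_i * sum_{j in c2, j != i} A~_ij
                      / sum_{i in c1} w_i

    so destination categories sum to 1 from each source category.  An
    empty source category yields NaN (undefined, not zero).
    """
    m = getattr(model, "model", model)
    K = m.n_states
    _check_labels(labels, K)
    keep = np.array([labels[k] != "excluded" for k in range(K)])
    w = occupancy_weights(m, labels, assignment=assignment,
                          mode=occupancy_mode)
    out = {}
    cat_states = {c: [k for k in range(K) if labels[k] == c]
                  for c in CATEGORIES}
    for c1 in CATEGORIES:
        src = cat_states[c1]
        wsrc = sum(w[i] for i in src)
        for c2 in CATEGORIES:
            name = _pair_name(c1, c2)
            if name == "mixed":
                continue
            if not src or wsrc <= 0:
                out[name] = float("nan")
                continue
            acc = 0.0
            for i in src:
                row = m.transition[i].copy()
                row[i] = 0.0
                row[~keep] = 0.0
                s = row.sum()
                if s <= 0:
                    continue
                row /= s
                acc += w[i] * sum(row[j] for j in cat_states[c2] if j != i)
            out[name] = acc / wsrc
    # mixed (social<->nonsocial) pairs are not analysed; report the
    # complement mass for completeness
    return out


def participant_variables(individual, assignment: StateAssignment,
                          scanpath: Scanpath, labels: dict,
                          occupancy_mode: str = "responsibilities"
                          ) -> list[dict]:
    """Long-format variable rows for one participant x stimulus."""
    rows = []
    tc = count_transitions(assignment, labels)
    for p in PAIRS:
        rows.append({"variable": "transition_count", "category": p,
                     "value": float(tc[p])})
    rows.append({"variable": "total_transitions", "category": "all",
                 "value": float(tc["total"])})
    model = getattr(individual, "model", individual)
    tp = transition_probability(model, labels, assignment=assignment,
                                occupancy_mode=occupancy_mode)
    for p in PAIRS:
        rows.append({"variable": "transition_probability", "category": p,
                     "value": float(tp[p])})
    fv = count_fixations_visits(assignment, labels, scanpath)
    for c in CATEGORIES:
        rows.append({"variable": "fixation_count", "category": c,
                     "value": float(fv["fixation_count"][c])})
        rows.append({"variable": "visit_count", "category": c,
                     "value": float(fv["visit_count"][c])})
    rows.append({"variable": "total_fixation_duration", "category": "all",
                 "value": fv["total_fixation_duration_s"]})
    return rows


def build_variable_table(records: list[dict]) -> pd.DataFrame:
    """Assemble participant rows (participant, group, stimulus, actors,
    rows=list from :func:`participant_variables`) into one long table."""
    out = []
    for rec in records:
        for row in rec["rows"]:
            out.append({"participant": rec["participant"],
                        "group": rec["group"],
                        "stimulus": rec["stimulus"],
                        "actors": rec["actors"], **row})
    df = pd.DataFrame(out)
    return df.sort_values(["participant", "stimulus", "variable",
                           "category"], kind="mergesort").reset_index(
        drop=True)
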