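"""Hierarchical synthetic cohort generator.

Emulates the study design the pipeline targets: three groups (TD n=25,
ASD+ADHD n=15, ASD n=12), each participant viewing two four-actor and two
one-actor scenes for 120 s.  A stimulus template defines the true ROIs —
12 for a four-actor scene (5 faces, 3 bodies, 4 non-social) and 9 for a
one-actor scene (1 face, 1 body, 7 non-social) on a 1920x1080 canvas —
with Gaussian spatial spread (SD 30-60 px) and lognormal fixation
durations (median ~300 ms).  One non-social state per template is a
sparse catch-all with 3x the median duration and 4x the spatial SD, so
downstream sparse-state flagging has a true positive.

Transition structure is planted at the *category* level: each state's
row has a self-transition mass, a small mass routed to the sparse state,
and the remainder distributed over destination categories by a kernel
whose face->face entry is the group's planted probability (0.30 TD-like;
scaled by 22/30 for the ASD+ADHD-like group, other destinations
renormalised).  Because the analysed transition-probability variable
removes self-transitions and excluded states before renormalising, the
kernel entries are exactly the values the pipeline should recover.
Participants deviate from their group by Dirichlet row jitter and small
emission-mean jitter; effects are planted only in transition structure,
never in ROI geometry.

Every generated artefact carries a truth record sufficient to recompute
each expected quantity independently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (CATEGORIES, GROUPS, BhmmModel, Scanpath)

log = logging.getLogger("gazehmm")

DEFAULT_GROUP_SIZES = {"TD": 25, "ASD_ADHD": 15, "ASD": 12}
# Table-1B-style planted magnitudes: TD face->face probability 0.30,
# reduced to 0.22 in the comorbid group
DEFAULT_EFFECT_MULTIPLIERS = {"TD": 1.0, "ASD": 1.0, "ASD_ADHD": 22.0 / 30.0}

ROI_COUNTS = {"four_actor": {"face": 5, "body": 3, "nonsocial": 4},
              "one_actor": {"face": 1, "body": 1, "nonsocial": 7}}

# destination-category kernels (rows sum to 1); structurally impossible
# within-category pairs (single-state categories) get 0
DEFAULT_KERNELS = {
    "four_actor": {"face": {"face": 0.30, "body": 0.20, "nonsocial": 0.50},
                   "body": {"face": 0.09, "body": 0.38, "nonsocial": 0.53},
                   "nonsocial": {"face": 0.18, "body": 0.12,
                                 "nonsocial": 0.70}},
    "one_actor": {"face": {"face": 0.0, "body": 0.30, "nonsocial": 0.70},
                  "body": {"face": 0.25, "body": 0.0, "nonsocial": 0.75},
                  "nonsocial": {"face": 0.12, "body": 0.08,
                                "nonsocial": 0.80}},
}

SELF_MASS = 0.30          # probability of staying in the same state
SPARSE_MASS = 0.04        # share of the move mass routed to the sparse state
JITTER_CONCENTRATION = 30.0
MEAN_JITTER_PX = 10.0
MEDIAN_DURATION_MS = 300.0
SIGMA_LOG_DURATION = 0.5
MIN_DURATION_MS = 80.0    # generator floor, above the 60 ms detector minimum


@dataclass
class RoiSpec:
    category: str
    mean_xy: np.ndarray       # (2,) px
    cov_xy: np.ndarray        # (2, 2)
    mu_log: float             # lognormal duration location
    sigma_log: float


@dataclass
class StimulusTemplate:
    stimulus_class: str
    rois: list[RoiSpec]
    sparse_index: int
    canvas: tuple = (1920, 1080)

    @property
    def n_states(self) -> int:
        return len(self.rois)

    def categories(self) -> list[str]:
        return [r.category for r in self.rois]

    def label_map(self, exclude_sparse: bool = False) -> dict:
        labels = {i: r.category for i, r in enumerate(self.rois)}
        if exclude_sparse:
            labels[self.sparse_index] = "excluded"
        return labels


def make_template(stimulus_class: str, seed: int = 0) -> StimulusTemplate:
    """Deterministic ROI layout for one stimulus class."""
    if stimulus_class not in ROI_COUNTS:
        raise ValueError(f"unknown stimulus class {stimulus_class!r}")
    rng = np.random.default_rng(seed)
    counts = ROI_COUNTS[stimulus_class]
    rois: list[RoiSpec] = []

    def add(category, cx, cy, sd_scale=1.0, dur_scale=1.0):
        sd = rng.uniform(30.0, 60.0) * sd_scale
        jitter = rng.normal(0.0, 8.0, size=2)
        mean = np.clip(np.array([cx, cy], dtype=float) + jitter,
                       [4 * sd, 4 * sd], [1920 - 4 * sd, 1080 - 4 * sd])
        rois.append(RoiSpec(category=category, mean_xy=mean,
                            cov_xy=np.diag([sd ** 2, sd ** 2]),
                            mu_log=float(np.log(MEDIAN_DURATION_MS
                                                * dur_scale)),
                            sigma_log=SIGMA_LOG_DURATION))

    if stimulus_class == "four_actor":
        for cx in (280.0, 640.0, 1000.0, 1360.0, 1680.0):   # faces, upper
            add("face", cx, 250.0)
        for cx in (420.0, 960.0, 1500.0):                    # bodies, mid
            add("body", cx, 600.0)
        add("nonsocial", 200.0, 930.0)                       # peripheral
        add("nonsocial", 960.0, 950.0)
        add("nonsocial", 1700.0, 930.0)
    else:
        add("face", 960.0, 260.0)
        add("body", 960.0, 580.0)
        for cx, cy in ((200.0, 250.0), (1700.0, 250.0), (250.0, 900.0),
                       (960.0, 950.0), (1680.0, 900.0), (450.0, 600.0)):
            add("nonsocial", cx, cy)
    # sparse catch-all: centre of the canvas, 4x spread, 3x median duration
    add("nonsocial", 960.0, 540.0, sd_scale=4.0, dur_scale=3.0)
    tpl = StimulusTemplate(stimulus_class=stimulus_class, rois=rois,
                           sparse_index=len(rois) - 1)
    got = {c: sum(1 for r in rois if r.category == c) for c in CATEGORIES}
    assert got == counts, got
    return tpl


def scaled_kernel(stimulus_class: str, face_face_multiplier: float = 1.0
                  ) -> dict:
    """Category kernel with the face->face entry scaled for a group.

    The face row's face->face entry becomes m * q_ff; the other
    destinations are rescaled so the row still sums to 1, leaving the
    planted face->face probability exactly m * q_ff.
    """
    base = {c1: dict(DEFAULT_KERNELS[stimulus_class][c1])
            for c1 in CATEGORIES}
    if face_face_multiplier <= 0:
        raise ValueError("effect multiplier must be positive")
    q = base["face"]["face"]
    if q > 0 and face_face_multiplier != 1.0:
        new_q = face_face_multiplier * q
        rest = 1.0 - q
        scale = (1.0 - new_q) / rest
        base["face"] = {c2: (new_q if c2 == "face" else base["face"][c2]
                             * scale) for c2 in CATEGORIES}
    return base


def template_transition_matrix(template: StimulusTemplate, kernel: dict,
                               self_mass: float = SELF_MASS,
                               sparse_mass: float = SPARSE_MASS
                               ) -> np.ndarray:
    """State-level transition matrix realising a category kernel.

    Rows: self-transition ``self_mass``; of the move mass, ``sparse_mass``
    goes to the sparse state and the rest follows the kernel, split
    uniformly over the destination category's non-sparse states (excluding
    the source itself).
    """
    K = template.n_states
    cats = template.categories()
    sparse = template.sparse_index
    A = np.zeros((K, K))
    for i in range(K):
        A[i, i] = self_mass
        move = 1.0 - self_mass
        A[i, sparse] += move * sparse_mass
        remaining = move * (1.0 - sparse_mass)
        weights = np.zeros(K)
        for c2 in CATEGORIES:
            dests = [j for j in range(K)
                     if cats[j] == c2 and j != i and j != sparse]
            q = kernel[cats[i]][c2]
            if not dests:
                continue
            for j in dests:
                weights[j] = q / len(dests)
        wsum = weights.sum()
        if wsum <= 0:
            # degenerate source: spread uniformly over everything else
            weights[:] = 1.0
            weights[i] = 0.0
            wsum = weights.sum()
        A[i] += remaining * weights / wsum
    A /= A.sum(axis=1, keepdims=True)
    return A


def template_model(template: StimulusTemplate, kernel: dict,
                   self_mass: float = SELF_MASS,
                   sparse_mass: float = SPARSE_MASS) -> BhmmModel:
    """Ground-truth model in raw units: means (x px, y px, log-duration)."""
    K = template.n_states
    A = template_transition_matrix(template, kernel, self_mass, sparse_mass)
    means = np.zeros((K, 3))
    covs = np.zeros((K, 3, 3))
    for i, r in enumerate(template.rois):
        means[i, :2] = r.mean_xy
        means[i, 2] = r.mu_log
        covs[i, :2, :2] = r.cov_xy
        covs[i, 2, 2] = r.sigma_log ** 2
    return BhmmModel(prior=np.full(K, 1.0 / K), transition=A, means=means,
                     covariances=covs)


def sample_participant_model(template: StimulusTemplate, kernel: dict,
                             seed: int,
                             jitter_concentration: float =
                             JITTER_CONCENTRATION,
                             mean_jitter_px: float = MEAN_JITTER_PX
                             ) -> BhmmModel:
    """Participant-level model: group matrix + Dirichlet row jitter and
    small emission-mean jitter.  Infinite concentration / zero jitter
    reproduce the group model exactly."""
    rng = np.random.default_rng(seed)
    base = template_model(template, kernel)
    A = base.transition.copy()
    if np.isfinite(jitter_concentration):
        for i in range(len(A)):
            conc = jitter_concentration * len(A) * A[i] + 1e-6
            A[i] = rng.dirichlet(conc)
    means = base.means.copy()
    if mean_jitter_px > 0:
        means[:, :2] += rng.normal(0.0, mean_jitter_px,
                                   size=means[:, :2].shape)
    return BhmmModel(prior=base.prior, transition=A, means=means,
                     covariances=base.covariances)


def simulate_scanpath(model: BhmmModel, participant_id: str,
                      stimulus_id: str, recording_s: float = 120.0,
                      seed: int = 0,
                      min_duration_ms: float = MIN_DURATION_MS,
                      canvas: tuple = (1920, 1080)
                      ) -> tuple[Scanpath, np.ndarray]:
    """Sample one recording from a raw-unit model (means hold log-duration).

    Fixations are emitted back-to-back until the cumulative duration
    reaches the recording length; the true hidden-state sequence is
    returned alongside.
    """
    rng = np.random.default_rng(seed)
    K = model.n_states
    states, xs, ys, ds = [], [], [], []
    t = 0.0
    s = int(rng.choice(K, p=model.prior))
    limit = recording_s * 1000.0
    while t < limit:
        mu = model.means[s]
        cov = model.covariances[s]
        xy = rng.multivariate_normal(mu[:2], cov[:2, :2])
        xy = np.clip(xy, [0.0, 0.0], [canvas[0] - 1e-6, canvas[1] - 1e-6])
        d = float(np.exp(rng.normal(mu[2], np.sqrt(cov[2, 2]))))
        d = max(d, min_duration_ms)
        states.append(s)
        xs.append(xy[0])
        ys.append(xy[1])
        ds.append(d)
        t += d
        s = int(rng.choice(K, p=model.transition[s]))
    onsets = np.concatenate([[0.0], np.cumsum(ds)[:-1]])
    sp = Scanpath(participant_id, stimulus_id, onsets, np.array(ds),
                  np.array(xs), np.array(ys))
    return sp, np.array(states, dtype=int)


def match_states_to_template(model: BhmmModel,
                             template: StimulusTemplate,
                             exclude_sparse: bool = False) -> dict:
    """Label learned states by their nearest template ROI (pixel space).

    Stands in for the manual semantic annotation a human would do on real
    stimuli; with ``exclude_sparse`` the template's sparse ROI maps to
    "excluded".
    """
    if model.transform is not None:
        means_px = model.transform.invert_mean(model.means)[:, :2]
    else:
        means_px = model.means[:, :2]
    tpl_means = np.array([r.mean_xy for r in template.rois])
    tpl_labels = template.label_map(exclude_sparse=exclude_sparse)
    labels = {}
    for k in range(model.n_states):
        j = int(np.argmin(np.linalg.norm(tpl_means - means_px[k], axis=1)))
        labels[k] = tpl_labels[j]
    return labels


@dataclass
class CohortData:
    """Everything one simulated cohort produced, truth included."""

    scanpaths: list[Scanpath]
    true_states: dict                  # (pid, stimulus) -> state array
    cohort: pd.DataFrame               # participant_id, group
    stimuli: dict                      # stimulus_id -> class
    templates: dict                    # class -> StimulusTemplate
    participant_models: dict           # (pid, class) -> BhmmModel
    effect_multipliers: dict
    seed: int

    def truth_record(self) -> dict:
        return {
            "seed": self.seed,
            "effect_multipliers": self.effect_multipliers,
            "kernels": {g: {cls: scaled_kernel(cls, m)
                            for cls in ROI_COUNTS}
                        for g, m in self.effect_multipliers.items()},
            "groups": dict(zip(self.cohort["participant_id"],
                               self.cohort["group"])),
            "true_states": {f"{p}|{s}": v.tolist()
                            for (p, s), v in self.true_states.items()},
        }


def simulate_cohort(group_sizes: dict | None = None,
                    effect_multipliers: dict | None = None,
                    seed: int = 0, recording_s: float = 120.0,
                    recordings_per_class: int = 2,
                    jitter_concentration: float = JITTER_CONCENTRATION,
                    mean_jitter_px: float = MEAN_JITTER_PX,
                    stimulus_classes=("four_actor", "one_actor")
                    ) -> CohortData:
    """Simulate a full cohort (defaults: 25/15/12 participants, 2 + 2
    recordings of 120 s each, face->face effect planted in ASD+ADHD)."""
    group_sizes = dict(DEFAULT_GROUP_SIZES if group_sizes is None
                       else group_sizes)
    effect = dict(DEFAULT_EFFECT_MULTIPLIERS if effect_multipliers is None
                  else effect_multipliers)
    ss = np.random.SeedSequence(seed)
    templates = {cls: make_template(cls, seed=seed)
                 for cls in stimulus_classes}
    stimuli = {}
    for cls in stimulus_classes:
        tag = "A" if cls == "four_actor" else "B"
        for r in range(recordings_per_class):
            stimuli[f"{tag}{r + 1}"] = cls

    scanpaths, true_states, part_models = [], {}, {}
    rows = []
    pid_counter = 0
    for group in sorted(group_sizes):
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        for _ in range(group_sizes[group]):
            pid_counter += 1
            pid = f"P{pid_counter:03d}"
            rows.append({"participant_id": pid, "group": group})
            child = ss.spawn(1)[0]
            pseeds = child.generate_state(2 * len(stimulus_classes)
                                          + len(stimuli)) % (2 ** 31)
            si = 0
            for ci, cls in enumerate(stimulus_classes):
                kern = scaled_kernel(cls, effect.get(group, 1.0))
                model = sample_participant_model(
                    templates[cls], kern, seed=int(pseeds[ci]),
                    jitter_concentration=jitter_concentration,
                    mean_jitter_px=mean_jitter_px)
                part_models[(pid, cls)] = model
                for stim_id, stim_cls in stimuli.items():
                    if stim_cls != cls:
                        continue
                    sp, st = simulate_scanpath(
                        model, pid, stim_id, recording_s=recording_s,
                        seed=int(pseeds[len(stimulus_classes) + si]))
                    si += 1
                    scanpaths.append(sp)
                    true_states[(pid, stim_id)] = st
    cohort = pd.DataFrame(rows)
    log.info("stage=simulate n_participants=%d n_recordings=%d seed=%d",
             len(cohort), len(scanpaths), seed)
    return CohortData(scanpaths=scanpaths, true_states=true_states,
                      cohort=cohort, stimuli=stimuli, templates=templates,
                      participant_models=part_models,
                      effect_multipliers=effect, seed=seed)


def render_raw_samples(scanpath: Scanpath, rate_hz: float = 120.0,
                       noise_px: float = 0.0, noise_ar: float = 0.99,
                       saccade_gap_ms: float = 20.0,
                       blink_fraction: float = 0.0,
                       seed: int = 0) -> pd.DataFrame:
    """Render a scanpath as a raw 120 Hz sample stream.

    Each fixation becomes round(duration * rate) samples at its position
    plus temporally correlated (AR(1), lag-1 correlation 0.99 at 120 Hz)
    Gaussian jitter: ocular drift and tremor are slow relative to the
    sampling rate, so the jitter wanders rather than flickering white.
    Saccade gaps between fixations and any configured blink stretches are
    emitted as invalid samples.
    """
    if noise_px < 0:
        raise ValueError("noise must be non-negative")
    rng = np.random.default_rng(seed)
    dt = 1000.0 / rate_hz
    ts, xs, ys, valid = [], [], [], []
    t = 0.0

    def ar1(n):
        if noise_px == 0 or n == 0:
            return np.zeros(n)
        e = rng.normal(0.0, noise_px * np.sqrt(1 - noise_ar ** 2), size=n)
        out = np.empty(n)
        out[0] = rng.normal(0.0, noise_px)
        for i in range(1, n):
            out[i] = noise_ar * out[i - 1] + e[i]
        return out

    n_gap = max(int(round(saccade_gap_ms / dt)), 1)
    for i in range(len(scanpath)):
        n = int(round(scanpath.duration_ms[i] * rate_hz / 1000.0))
        nx = ar1(n)
        ny = ar1(n)
        for j in range(n):
            ts.append(t)
            xs.append(scanpath.x[i] + nx[j])
            ys.append(scanpath.y[i] + ny[j])
            valid.append(True)
            t += dt
        if i < len(scanpath) - 1:
            for _ in range(n_gap):
                ts.append(t)
                xs.append(np.nan)
                ys.append(np.nan)
                valid.append(False)
                t += dt
    df = pd.DataFrame({"participant_id": scanpath.participant_id,
                       "stimulus_id": scanpath.stimulus_id,
                       "timestamp_ms": ts, "x_px": xs, "y_px": ys,
                       "valid": valid})
    if blink_fraction > 0:
        n = len(df)
        target = int(round(blink_fraction * n))
        inval = np.zeros(n, dtype=bool)
        while inval.sum() < target:
            start = int(rng.integers(0, n))
            length = int(rng.integers(10, 40))
            inval[start:start + length] = True
        idx = np.flatnonzero(inval)[:target]
        inval = np.zeros(n, dtype=bool)
        inval[idx] = True
        df.loc[inval, "valid"] = False
        df.loc[inval, ["x_px", "y_px"]] = np.nan
    return df


def write_truth_record(cohort: CohortData, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(cohort.truth_record(), fh)
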