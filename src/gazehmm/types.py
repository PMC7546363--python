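"""Core domain containers shared across the pipeline.

A *scanpath* is the ordered sequence of fixations one participant produced
on one stimulus; each fixation is summarised by its screen position (x, y,
pixels, origin top-left) and its duration (ms).  Hidden-Markov models over
scanpaths use a three-dimensional feature space (x, y, transformed
duration); the transform applied to raw fixations is recorded alongside the
data so that model parameters can always be mapped back to screen/ms units.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, asdict
from typing import Sequence

import numpy as np

GROUPS = ("TD", "ASD", "ASD_ADHD")
STIMULUS_CLASSES = ("four_actor", "one_actor")
CATEGORIES = ("face", "body", "nonsocial")
# analysed transition pairs: social-to-social and nonsocial-to-nonsocial;
# social<->nonsocial changes are tallied as "mixed" but never analysed
PAIRS = ("face_face", "body_body", "face_body", "body_face",
         "nonsocial_nonsocial")


class FormatError(ValueError):
    """A file does not conform to the documented CSV dialect."""


class ValidationError(ValueError):
    """Values violate a documented invariant (overlap, ordering, ...)."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical viewing setup used to convert visual angle to pixels.

    Defaults describe a 24-inch 16:9 screen (53.1 x 29.9 cm, 1920 x 1080 px)
    viewed from 70 cm.
    """

    viewing_distance_cm: float = 70.0
    screen_width_cm: float = 53.1
    screen_height_cm: float = 29.9
    resolution_x: int = 1920
    resolution_y: int = 1080

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")

    @property
    def px_per_cm(self) -> float:
        return self.resolution_x / self.screen_width_cm


@dataclass(frozen=True)
class RecordingQuality:
    """Quality summary of one recording and the pass/fail verdict.

    A recording passes only if tracking_ratio > 0.75 AND the fraction of
    stimulus time covered by fixations > 0.50 (both strict).
    """

    tracking_ratio: float
    total_fixation_time_ms: float
    stimulus_duration_ms: float
    passed: bool
    reason: str = ""


@dataclass
class Scanpath:
    """Ordered fixation sequence of one participant on one stimulus."""

    participant_id: str
    stimulus_id: str
    onset_ms: np.ndarray      # (T,)
    duration_ms: np.ndarray   # (T,) > 0
    x: np.ndarray             # (T,) px
    y: np.ndarray             # (T,) px

    def __post_init__(self) -> None:
        self.onset_ms = np.asarray(self.onset_ms, dtype=float)
        self.duration_ms = np.asarray(self.duration_ms, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.onset_ms)
        if not (len(self.duration_ms) == len(self.x) == len(self.y) == n):
            raise ValidationError("scanpath arrays must share one length")
        if n == 0:
            raise ValidationError("scanpath must contain at least one fixation")
        if np.any(self.duration_ms <= 0):
            raise ValidationError(
                f"non-positive fixation duration for {self.participant_id}")
        if np.any(np.diff(self.onset_ms) < 0):
            raise ValidationError(
                f"fixations not sorted by onset for {self.participant_id}")
        ends = self.onset_ms[:-1] + self.duration_ms[:-1]
        if np.any(self.onset_ms[1:] < ends - 1e-9):
            raise ValidationError(
                f"overlapping fixations for participant {self.participant_id}"
                f" on {self.stimulus_id}")

    def __len__(self) -> int:
        return len(self.onset_ms)


@dataclass(frozen=True)
class FeatureTransform:
    """Affine standardisation of (x, y, log-duration) features.

    Durations are log-transformed before standardisation so the duration
    axis neither dominates nor vanishes against the pixel axes; the stored
    means/scales allow exact back-transformation of model parameters.
    """

    mean: np.ndarray   # (3,)
    scale: np.ndarray  # (3,) > 0
    log_duration: bool = True

    def apply(self, scanpath: Scanpath) -> np.ndarray:
        d = np.log(scanpath.duration_ms) if self.log_duration \
            else scanpath.duration_ms
        raw = np.column_stack([scanpath.x, scanpath.y, d])
        return (raw - self.mean) / self.scale

    def invert_mean(self, z: np.ndarray) -> np.ndarray:
        """Map a feature-space mean back to (x px, y px, duration ms)."""
        raw = np.asarray(z) * self.scale + self.mean
        out = raw.copy()
        if self.log_duration:
            out[..., 2] = np.exp(raw[..., 2])
        return out

    @staticmethod
    def fit(scanpaths: Sequence[Scanpath], log_duration: bool = True
            ) -> "FeatureTransform":
        xs = np.concatenate([sp.x for sp in scanpaths])
        ys = np.concatenate([sp.y for sp in scanpaths])
        ds = np.concatenate([sp.duration_ms for sp in scanpaths])
        if log_duration:
            ds = np.log(ds)
        raw = np.column_stack([xs, ys, ds])
        scale = raw.std(axis=0, ddof=0)
        scale[scale < 1e-12] = 1.0
        return FeatureTransform(mean=raw.mean(axis=0), scale=scale,
                                log_duration=log_duration)


@dataclass
class BhmmModel:
    """Point hidden-Markov model: prior, transition matrix, Gaussian states.

    States are full-covariance 3-D Gaussians over the transformed
    (x, y, duration) feature space; ``transform`` records that space.
    """

    prior: np.ndarray        # (K,)
    transition: np.ndarray   # (K, K), rows sum to 1
    means: np.ndarray        # (K, 3)
    covariances: np.ndarray  # (K, 3, 3) symmetric positive definite
    transform: FeatureTransform | None = None

    def __post_init__(self) -> None:
        self.prior = np.asarray(self.prior, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.prior)

    def validate(self, tol: float = 1e-10) -> None:
        K = self.n_states
        if self.transition.shape != (K, K):
            raise ValidationError("transition matrix shape mismatch")
        if np.any(self.prior < -tol) or abs(self.prior.sum() - 1.0) > 1e-8:
            raise ValidationError("prior is not a probability vector")
        if np.any(self.transition < -tol):
            raise ValidationError("negative transition probability")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-8):
            raise ValidationError("transition rows must sum to 1")
        for k in range(K):
            ev = np.linalg.eigvalsh(self.covariances[k])
            if ev.min() <= 1e-12:
                raise ValidationError(f"covariance of state {k} not PD")

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix for eigenvalue 1."""
        w, v = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        p = np.real(v[:, i])
        p = np.abs(p)
        return p / p.sum()


@dataclass
class StateAssignment:
    """Posterior state responsibilities and MAP labels for one scanpath."""

    responsibilities: np.ndarray  # (T, K), rows sum to 1
    map_states: np.ndarray        # (T,) int

    def __post_init__(self) -> None:
        g = np.asarray(self.responsibilities, dtype=float)
        if np.any(np.abs(g.sum(axis=1) - 1.0) > 1e-6):
            raise ValidationError("responsibility rows must sum to 1")
        self.responsibilities = g
        self.map_states = np.asarray(self.map_states, dtype=int)

    @property
    def n_states(self) -> int:
        return self.responsibilities.shape[1]


@dataclass
class PipelineConfig:
    """All tunable settings of the pipeline, with study defaults.

    Flat key=value text files map one-to-one onto these attributes.
    """

    # quality control (strict > thresholds)
    tracking_ratio_min: float = 0.75
    fixation_time_fraction_min: float = 0.50
    # fixation detection (dispersion algorithm)
    min_fixation_ms: float = 60.0
    dispersion_deg: float = 2.0
    sampling_rate_hz: float = 120.0
    # screen geometry
    viewing_distance_cm: float = 70.0
    screen_width_cm: float = 53.1
    screen_height_cm: float = 29.9
    resolution_x: int = 1920
    resolution_y: int = 1080
    # model fitting
    k_min: int = 2
    k_max: int = 14
    restarts: int = 5
    max_iter: int = 300
    elbo_rel_tol: float = 1e-6
    log_duration: bool = True
    representative_mode: str = "pooled"   # or "vhem"
    init_duration_weight: float = 0.1     # duration weight in k-means init
    hold_emissions: bool = True           # step-2: keep emissions at the
                                          # representative ROIs (see docs)
    drift_flag_px: float = 150.0
    # statistics
    alpha: float = 0.05
    reml: bool = True
    fdr_correction: bool = False
    occupancy_mode: str = "responsibilities"  # uniform | stationary | responsibilities
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.tracking_ratio_min <= 1):
            raise ValueError("tracking_ratio_min must be in (0, 1]")
        if not (0 < self.fixation_time_fraction_min <= 1):
            raise ValueError("fixation_time_fraction_min must be in (0, 1]")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("state-count range empty or invalid")
        if self.representative_mode not in ("pooled", "vhem"):
            raise ValueError("representative_mode must be pooled or vhem")

    @property
    def geometry(self) -> ScreenGeometry:
        return ScreenGeometry(self.viewing_distance_cm, self.screen_width_cm,
                              self.screen_height_cm, self.resolution_x,
                              self.resolution_y)

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise FormatError(f"line {lineno}: expected key = value")
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key not in types:
                    raise FormatError(f"line {lineno}: unknown key {key!r}")
                current = getattr(defaults, key)
                if isinstance(current, bool):
                    kwargs[key] = val.lower() in ("1", "true", "yes")
                elif isinstance(current, int):
                    kwargs[key] = int(val)
                elif isinstance(current, float):
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = val
        return cls(**kwargs)
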