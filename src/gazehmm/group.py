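"""Two-step group modelling of scanpaths.

Step 1 learns one *representative* set of ROIs from every participant's
scanpaths on a stimulus, either by fitting a single model to the pooled
scanpaths (default) or by reducing per-participant models with a
hierarchical-EM style clustering of their Gaussian states.  Step 2 fits
each participant an individual model with the state count fixed to the
representative's, initialised from the representative parameters so that
state indices stay comparable across participants; states whose means
drift far from their representative counterpart are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bhmm import (InfeasibleModelError, VbPosterior, decode, default_priors,
                   vbem_fit, vbem_fit_fixed_emissions, select_state_count)
from .types import BhmmModel, Scanpath, FeatureTransform

log = logging.getLogger("gazehmm")


@dataclass
class RepresentativeModel:
    """Step-1 model shared by all participants on one stimulus."""

    model: BhmmModel
    posterior: VbPosterior | None
    mode: str                       # "pooled" | "vhem"
    participant_ids: list[str]
    stimulus_id: str = ""

    @property
    def n_states(self) -> int:
        return self.model.n_states


@dataclass
class IndividualModel:
    """Step-2 per-participant model tied to a representative model."""

    participant_id: str
    model: BhmmModel
    posterior: VbPosterior | None
    representative: RepresentativeModel
    correspondence: np.ndarray      # individual state -> representative state
    mean_drift_px: np.ndarray       # per-state drift in pixel space
    drift_flags: np.ndarray         # bool per state
    infeasible: bool = False


def _model_init_gamma(model: BhmmModel, sequences: list[np.ndarray]):
    """Responsibility statistics of sequences under a fixed point model."""
    gammas, xi, g1 = [], np.zeros((model.n_states,) * 2), \
        np.zeros(model.n_states)
    for seq in sequences:
        a = decode(model, seq)
        gammas.append(a.responsibilities)
        g1 += a.responsibilities[0]
        g = a.responsibilities
        # pairwise statistics approximated by outer products of marginals;
        # only used to seed the first M-step
        if len(g) > 1:
            xi += np.einsum("ti,tj->ij", g[:-1], g[1:])
    return np.concatenate(gammas, axis=0), xi, g1


def fit_representative(scanpaths: list[Scanpath], config,
                       transform: FeatureTransform | None = None,
                       stimulus_id: str = "", k_range=None,
                       seed: int | None = None) -> RepresentativeModel:
    """Step 1: learn representative ROIs from all participants' scanpaths."""
    if transform is None:
        transform = FeatureTransform.fit(scanpaths,
                                         log_duration=config.log_duration)
    seed = config.seed if seed is None else seed
    sequences = [transform.apply(sp) for sp in scanpaths]
    pids = sorted({sp.participant_id for sp in scanpaths})
    k_range = config.k_range if k_range is None else k_range
    w = getattr(config, "init_duration_weight", 1.0)
    scale = None if w == 1.0 else np.array([1.0, 1.0, w])
    if config.representative_mode == "pooled":
        _, results = select_state_count(
            sequences, k_range, restarts=config.restarts, seed=seed,
            max_iter=config.max_iter, rel_tol=config.elbo_rel_tol,
            transform=transform, init_feature_scale=scale)
        best_k = max(results,
                     key=lambda K: (results[K][1].elbo_trace[-1], -K))
        model, post = results[best_k]
        mode = "pooled"
    else:
        per_participant = {}
        by_pid = {}
        for sp, seq in zip(scanpaths, sequences):
            by_pid.setdefault(sp.participant_id, []).append(seq)
        for i, pid in enumerate(pids):
            _, res = select_state_count(
                by_pid[pid], k_range, restarts=config.restarts,
                seed=seed + 7919 * (i + 1), max_iter=config.max_iter,
                rel_tol=config.elbo_rel_tol, transform=transform,
                init_feature_scale=scale)
            bk = max(res, key=lambda K: (res[K][1].elbo_trace[-1], -K))
            per_participant[pid] = res[bk][0]
        k_target = int(round(np.median([m.n_states
                                        for m in per_participant.values()])))
        model = vhem_reduce(list(per_participant.values()), k_target,
                            seed=seed)
        model.transform = transform
        post = None
        mode = "vhem"
    log.info("stage=representative mode=%s stimulus=%s K=%d n_participants=%d"
             " seed=%d", mode, stimulus_id, model.n_states, len(pids), seed)
    return RepresentativeModel(model=model, posterior=post, mode=mode,
                               participant_ids=pids, stimulus_id=stimulus_id)


def vhem_reduce(models: list[BhmmModel], k_target: int, seed: int = 0,
                virtual_per_state: float = 100.0, max_iter: int = 50,
                tol: float = 1e-8) -> BhmmModel:
    """Reduce an ensemble of HMMs to one model with ``k_target`` states.

    Clusters the ensemble's Gaussian states by maximising a variational
    lower bound on the expected log-likelihood, under the reduced model,
    of virtual samples drawn from each input state (the expectation of a
    Gaussian log-density under another Gaussian is available in closed
    form, so no samples are actually drawn).  Each input state carries
    virtual weight proportional to its stationary occupancy; reduced-model
    transition rows are responsibility-weighted aggregates of the input
    transition rows.  Deterministic given the seed.
    """
    if k_target < 1:
        raise ValueError("target state count must be >= 1")
    dims = {m.means.shape[1] for m in models}
    if len(dims) != 1:
        raise ValueError("input models must share one feature space")
    D = dims.pop()
    total_states = sum(m.n_states for m in models)
    if k_target > total_states:
        raise ValueError("target state count exceeds total input states")

    mus = np.concatenate([m.means for m in models], axis=0)
    sigmas = np.concatenate([m.covariances for m in models], axis=0)
    occ = np.concatenate([m.stationary_distribution() * m.n_states
                          for m in models])
    n_i = virtual_per_state * occ                # virtual samples per state

    # deterministic farthest-point seeding on the input state means,
    # over a canonical (lexicographic) ordering so the result cannot
    # depend on the order the models were supplied in
    order = np.lexsort(mus.T[::-1])
    centers = [int(order[0])]
    for _ in range(1, k_target):
        d2 = np.min([((mus - mus[c]) ** 2).sum(axis=1) for c in centers],
                    axis=0)
        # farthest first; ties resolved by the canonical ordering
        best = max(order, key=lambda i: (d2[i], -int(np.where(
            order == i)[0][0])))
        centers.append(int(best))
    m_t = mus[centers].copy()
    S_t = sigmas[centers].copy()
    c_t = np.full(k_target, 1.0 / k_target)

    def expected_loglik(mu_i, Sig_i, m_j, S_j):
        L = np.linalg.cholesky(S_j)
        diff = mu_i - m_j
        sol = np.linalg.solve(L, diff)
        quad = float(sol @ sol)
        tr = float(np.trace(np.linalg.solve(S_j, Sig_i)))
        return (-0.5 * (quad + tr) - np.log(np.diag(L)).sum()
                - 0.5 * D * np.log(2 * np.pi))

    Z = None
    for _ in range(max_iter):
        ll = np.empty((len(mus), k_target))
        for i in range(len(mus)):
            for j in range(k_target):
                ll[i, j] = expected_loglik(mus[i], sigmas[i], m_t[j], S_t[j])
        logits = np.log(c_t + 1e-300)[None, :] + n_i[:, None] * ll
        logits -= logits.max(axis=1, keepdims=True)
        Znew = np.exp(logits)
        Znew /= Znew.sum(axis=1, keepdims=True)
        w = Znew * n_i[:, None]
        wsum = w.sum(axis=0) + 1e-300
        m_new = (w.T @ mus) / wsum[:, None]
        S_new = np.empty_like(S_t)
        for j in range(k_target):
            diff = mus - m_new[j]
            S_new[j] = (np.einsum("i,iab->ab", w[:, j], sigmas)
                        + (w[:, j][:, None] * diff).T @ diff) / wsum[j]
            S_new[j] = 0.5 * (S_new[j] + S_new[j].T)
        c_new = wsum / wsum.sum()
        shift = np.abs(m_new - m_t).max()
        m_t, S_t, c_t, Z = m_new, S_new, c_new, Znew
        if shift < tol:
            break

    # aggregate transition structure through the state-assignment map
    A_red = np.zeros((k_target, k_target))
    pi_red = np.zeros(k_target)
    pos = 0
    for m in models:
        K = m.n_states
        Zm = Z[pos:pos + K]
        occ_m = m.stationary_distribution()
        A_red += Zm.T @ (occ_m[:, None] * m.transition) @ Zm
        pi_red += Zm.T @ m.prior
        pos += K
    A_red /= A_red.sum(axis=1, keepdims=True)
    pi_red /= pi_red.sum()
    return BhmmModel(prior=pi_red, transition=A_red, means=m_t,
                     covariances=S_t)


def fit_individual(scanpath_sequences: list[np.ndarray],
                   representative: RepresentativeModel, config,
                   participant_id: str, seed: int | None = None
                   ) -> IndividualModel:
    """Step 2: fit one participant's model, initialised from Step 1.

    ``scanpath_sequences`` are the participant's feature-space sequences on
    the representative's stimulus.  K and the feature transform are
    inherited; initial responsibilities come from decoding under the
    representative model, which keeps state indices aligned (verified by
    nearest-mean matching and a drift flag).
    """
    rep = representative.model
    K = rep.n_states
    seed = config.seed if seed is None else seed
    n_obs = sum(len(s) for s in scanpath_sequences)
    if n_obs < K:
        log.warning("stage=individual participant=%s n_obs=%d < K=%d;"
                    " excluded from model-based variables", participant_id,
                    n_obs, K)
        return IndividualModel(participant_id, rep, None, representative,
                               np.arange(K), np.full(K, np.nan),
                               np.zeros(K, bool), infeasible=True)
    if config.hold_emissions:
        # unit total mass per transition row: a K-pseudocount symmetric
        # prior would outweigh the ~(fixations/K) observed transitions per
        # row of a single recording and erase the individual differences
        # Step 2 exists to measure
        model, post = vbem_fit_fixed_emissions(
            scanpath_sequences, rep, beta0=1.0 / K,
            max_iter=config.max_iter, rel_tol=config.elbo_rel_tol)
    else:
        init = _model_init_gamma(rep, scanpath_sequences)
        X = np.concatenate(scanpath_sequences, axis=0)
        priors = default_priors(X, K)
        model, post = vbem_fit(scanpath_sequences, K, priors=priors,
                               seed=seed, max_iter=config.max_iter,
                               rel_tol=config.elbo_rel_tol, init_gamma=init,
                               transform=rep.transform)

    # correspondence is identity by construction; verify by nearest mean
    corr = np.empty(K, dtype=int)
    tf = rep.transform
    for k in range(K):
        d = np.linalg.norm(rep.means - model.means[k], axis=1)
        corr[k] = int(np.argmin(d))
    if tf is not None:
        rep_px = tf.invert_mean(rep.means)[:, :2]
        ind_px = tf.invert_mean(model.means)[:, :2]
        drift = np.linalg.norm(ind_px - rep_px, axis=1)
    else:
        drift = np.linalg.norm(model.means - rep.means, axis=1)
    flags = drift > config.drift_flag_px
    if flags.any():
        log.warning("stage=individual participant=%s drifted_states=%s",
                    participant_id, np.flatnonzero(flags).tolist())
    return IndividualModel(participant_id=participant_id, model=model,
                           posterior=post, representative=representative,
                           correspondence=corr, mean_drift_px=drift,
                           drift_flags=flags)
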