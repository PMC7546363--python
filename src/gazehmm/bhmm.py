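"""Variational Bayesian learning of Gaussian hidden Markov models.

The observable process is the fixation sequence (position and duration in
a standardised 3-D feature space); the hidden process is a first-order
Markov chain over a finite set of states ("ROIs").  Parameters carry
conjugate priors — Dirichlet on the initial-state vector and on each
transition row, Normal-Wishart on each state's Gaussian emission — and are
learned with variational Bayesian EM (VBEM):

* E-step: forward-backward under the expected log-parameters
  (geometric-mean parameterisation), yielding smoothed responsibilities
  and pairwise transition statistics;
* M-step: closed-form conjugate hyperparameter updates.

The evidence lower bound (ELBO) is the per-iteration objective; because
the priors penalise parameters that the data do not support, comparing
best-restart ELBOs across state counts gives a complexity-penalised model
selection.  Decoding assigns each fixation to the state with the highest
smoothed marginal probability (per-fixation MAP, not the jointly best
path).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, multigammaln
from sklearn.cluster import KMeans

from .types import BhmmModel, StateAssignment

log = logging.getLogger("gazehmm")


class InfeasibleModelError(ValueError):
    """More states requested than observations available."""


@dataclass(frozen=True)
class VbPriors:
    """Conjugate prior hyperparameters for one model family.

    Dirichlet concentrations are symmetric; the Normal-Wishart prior is
    centred on the grand mean of the observations with an expected
    state covariance of (empirical feature variances) / K^(2/3), so the
    prior states start broad but shrink with the number of states.
    """

    alpha0: float            # Dirichlet concentration, initial-state vector
    beta0: float             # Dirichlet concentration, transition rows
    m0: np.ndarray           # (D,) Normal location
    kappa0: float            # Normal scale count
    W0inv: np.ndarray        # (D, D) inverse Wishart scale matrix
    nu0: float               # Wishart degrees of freedom (> D - 1)


def default_priors(X: np.ndarray, K: int, alpha0: float = 1.0,
                   beta0: float = 1.0, kappa0: float = 0.1) -> VbPriors:
    """Data-dependent default priors for K states on observations X."""
    X = np.asarray(X, dtype=float)
    D = X.shape[1]
    nu0 = float(D + 2)
    var = X.var(axis=0, ddof=0)
    var[var < 1e-12] = 1e-12
    # E[state covariance] = diag(var) / K^(2/3); with nu0 = D + 2 the
    # inverse-Wishart mean is W0inv / (nu0 - D - 1) = W0inv
    W0inv = np.diag(var) / K ** (2.0 / 3.0)
    return VbPriors(alpha0=alpha0, beta0=beta0, m0=X.mean(axis=0),
                    kappa0=kappa0, W0inv=W0inv, nu0=nu0)


@dataclass
class VbPosterior:
    """Posterior hyperparameters and the ELBO trace of one VBEM run."""

    alpha: np.ndarray        # (K,)   Dirichlet, initial-state vector
    beta: np.ndarray         # (K, K) Dirichlet, one row per transition row
    m: np.ndarray            # (K, D) Normal-Wishart location
    kappa: np.ndarray        # (K,)
    Winv: np.ndarray         # (K, D, D) inverse Wishart scale
    nu: np.ndarray           # (K,)
    priors: VbPriors = None
    elbo_trace: list = field(default_factory=list)
    converged: bool = False

    @property
    def n_states(self) -> int:
        return len(self.alpha)

    @property
    def dim(self) -> int:
        return self.m.shape[1]

    def point_model(self, transform=None) -> BhmmModel:
        """Posterior-mean point estimate of the model parameters."""
        D = self.dim
        covs = np.array([self.Winv[k] / (self.nu[k] - D - 1)
                         for k in range(self.n_states)])
        return BhmmModel(prior=self.alpha / self.alpha.sum(),
                         transition=self.beta / self.beta.sum(axis=1,
                                                              keepdims=True),
                         means=self.m.copy(), covariances=covs,
                         transform=transform)


# ---------------------------------------------------------------------------
# expected log-parameters and log emission densities

def _expected_log_pi_A(post: VbPosterior):
    elog_pi = digamma(post.alpha) - digamma(post.alpha.sum())
    elog_A = digamma(post.beta) - digamma(post.beta.sum(axis=1))[:, None]
    return elog_pi, elog_A


def _expected_log_gauss(X: np.ndarray, post: VbPosterior) -> np.ndarray:
    """E_q[log N(x | mu_k, Lambda_k^-1)] for every observation and state."""
    T, D = X.shape
    K = post.n_states
    logB = np.empty((T, K))
    for k in range(K):
        L = np.linalg.cholesky(post.Winv[k])
        elogdet = (digamma(0.5 * (post.nu[k] - np.arange(D))).sum()
                   + D * np.log(2.0)
                   - 2.0 * np.log(np.diag(L)).sum())
        diff = X - post.m[k]
        sol = np.linalg.solve(L, diff.T)          # (D, T)
        quad = np.einsum("dt,dt->t", sol, sol)    # (x-m)^T W (x-m)
        logB[:, k] = (0.5 * elogdet - 0.5 * D * np.log(2 * np.pi)
                      - 0.5 * (D / post.kappa[k] + post.nu[k] * quad))
    return logB


def _log_gauss(X: np.ndarray, means: np.ndarray, covs: np.ndarray
               ) -> np.ndarray:
    """Plain Gaussian log-densities, (T, K)."""
    T, D = X.shape
    K = len(means)
    logB = np.empty((T, K))
    for k in range(K):
        L = np.linalg.cholesky(covs[k])
        diff = X - means[k]
        sol = np.linalg.solve(L, diff.T)
        quad = np.einsum("dt,dt->t", sol, sol)
        logB[:, k] = (-0.5 * quad - np.log(np.diag(L)).sum()
                      - 0.5 * D * np.log(2 * np.pi))
    return logB


# ---------------------------------------------------------------------------
# scaled forward-backward, batched over sequences

def _forward_backward(log_pi: np.ndarray, log_A: np.ndarray,
                      logBs: list[np.ndarray]):
    """Smoothed marginals and sufficient statistics for many sequences.

    Works in scaled linear space after factoring out the per-timestep
    maximum of the emission terms, which is safe for arbitrary log
    densities.  ``log_pi`` / ``log_A`` may be sub-normalised (expected
    logs), as VBEM requires.

    Returns (gammas, xi_sum, gamma1_sum, total_logZ) where ``gammas`` is a
    list of (T_i, K) responsibility arrays, ``xi_sum`` the (K, K) sum of
    pairwise posteriors over all sequences and steps, ``gamma1_sum`` the
    (K,) sum of first-step responsibilities.
    """
    K = len(log_pi)
    N = len(logBs)
    lengths = np.array([b.shape[0] for b in logBs])
    Tmax = lengths.max()
    # pad emissions; offsets keep exponentials in (0, 1]
    logB = np.full((N, Tmax, K), -np.inf)
    for n, b in enumerate(logBs):
        logB[n, :len(b)] = b
    off = np.where(np.isfinite(logB).any(axis=2),
                   logB.max(axis=2, where=np.isfinite(logB), initial=-np.inf),
                   0.0)
    Bt = np.exp(logB - off[:, :, None])
    Bt[~np.isfinite(logB)] = 0.0

    A = np.exp(log_A)
    pi = np.exp(log_pi)

    alpha = np.empty((N, Tmax, K))
    c = np.ones((N, Tmax))
    a = pi[None, :] * Bt[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0][:, None]
    if np.all(lengths == Tmax):
        # uniform-length fast path: no per-step masking
        for t in range(1, Tmax):
            a = (alpha[:, t - 1] @ A) * Bt[:, t]
            s = a.sum(axis=1)
            alpha[:, t] = a / s[:, None]
            c[:, t] = s
        beta = np.empty((N, Tmax, K))
        beta[:, Tmax - 1] = 1.0
        xi_sum = np.zeros((K, K))
        for t in range(Tmax - 2, -1, -1):
            bb = (Bt[:, t + 1] * beta[:, t + 1]) / c[:, t + 1][:, None]
            beta[:, t] = bb @ A.T
            xi_sum += np.einsum("ni,nj->ij", alpha[:, t], bb)
        xi_sum *= A
        g = alpha * beta
        g /= g.sum(axis=2, keepdims=True)
        gammas = [g[n] for n in range(N)]
        logZ = float(np.log(c).sum() + off.sum())
        return gammas, xi_sum, g[:, 0].sum(axis=0), logZ
    for t in range(1, Tmax):
        active = t < lengths
        a = (alpha[:, t - 1] @ A) * Bt[:, t]
        s = a.sum(axis=1)
        s[~active] = 1.0
        a[~active] = alpha[~active, t - 1]
        alpha[:, t] = a / s[:, None]
        c[:, t] = np.where(active, s, 1.0)

    beta = np.zeros((N, Tmax, K))   # padded tail stays 0, masked below
    beta[np.arange(N), lengths - 1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(Tmax - 2, -1, -1):
        active = t + 1 < lengths
        bb = Bt[:, t + 1] * beta[:, t + 1]
        nb = (bb @ A.T) / c[:, t + 1][:, None]
        beta[:, t] = np.where(active[:, None], nb, 1.0)
        if active.any():
            xi = (alpha[active, t][:, :, None] * A[None, :, :]
                  * bb[active][:, None, :] / c[active, t + 1][:, None, None])
            xi_sum += xi.sum(axis=0)
    g = alpha * beta
    gsum = g.sum(axis=2, keepdims=True)
    gsum[gsum == 0] = 1.0
    gammas_pad = g / gsum
    gammas = [gammas_pad[n, :lengths[n]] for n in range(N)]
    gamma1_sum = gammas_pad[:, 0].sum(axis=0)
    logZ = float((np.log(c) * (np.arange(Tmax)[None, :] < lengths[:, None])
                  ).sum() + (off * (np.arange(Tmax)[None, :]
                                    < lengths[:, None])).sum())
    return gammas, xi_sum, gamma1_sum, logZ


# ---------------------------------------------------------------------------
# KL divergences of the variational factors from their priors

def _kl_dirichlet(a: np.ndarray, b0: float) -> float:
    a = np.asarray(a, dtype=float)
    K = len(a)
    b = np.full(K, b0)
    return float(gammaln(a.sum()) - gammaln(a).sum()
                 - gammaln(b.sum()) + gammaln(b).sum()
                 + ((a - b) * (digamma(a) - digamma(a.sum()))).sum())


def _kl_normal_wishart(post: VbPosterior, k: int) -> float:
    p = post.priors
    D = post.dim
    nu1, nu0 = post.nu[k], p.nu0
    W1inv = post.Winv[k]
    L1 = np.linalg.cholesky(W1inv)
    logdetW1 = -2.0 * np.log(np.diag(L1)).sum()     # log|W1|
    L0 = np.linalg.cholesky(p.W0inv)
    logdetW0 = -2.0 * np.log(np.diag(L0)).sum()
    elogdet = (digamma(0.5 * (nu1 - np.arange(D))).sum()
               + D * np.log(2.0) + logdetW1)
    # W1 = W1inv^-1 ; tr(W0inv^-1... careful: priors/posteriors are Wishart
    # on the precision with scale W = Winv^-1
    W1 = np.linalg.inv(W1inv)
    tr = float(np.trace(p.W0inv @ W1)) * nu1        # nu1 * tr(W0^-1 W1)
    dm = post.m[k] - p.m0
    quad = float(dm @ (W1 @ dm)) * nu1
    # Normal part
    kl_n = 0.5 * (D * np.log(post.kappa[k] / p.kappa0) - D
                  + D * p.kappa0 / post.kappa[k] + p.kappa0 * quad)

    def log_B(logdetW, nu):
        return (-0.5 * nu * logdetW - 0.5 * nu * D * np.log(2.0)
                - multigammaln(0.5 * nu, D))

    kl_w = (log_B(logdetW1, nu1) - log_B(logdetW0, nu0)
            + 0.5 * (nu1 - nu0) * elogdet + 0.5 * (tr - nu1 * D))
    return float(kl_n + kl_w)


def _elbo_from_estep(post: VbPosterior, logZ: float) -> float:
    kl = _kl_dirichlet(post.alpha, post.priors.alpha0)
    for j in range(post.n_states):
        kl += _kl_dirichlet(post.beta[j], post.priors.beta0)
    for k in range(post.n_states):
        kl += _kl_normal_wishart(post, k)
    return logZ - kl


def elbo(sequences: list[np.ndarray], posterior: VbPosterior) -> float:
    """Evidence lower bound of a posterior on the given sequences."""
    if posterior.priors is None:
        raise ValueError("posterior must carry its priors")
    if np.any(posterior.alpha <= 0) or np.any(posterior.beta <= 0):
        raise ValueError("Dirichlet concentrations must be positive")
    if np.any(posterior.nu <= posterior.dim - 1):
        raise ValueError("Wishart dof must exceed dimension - 1")
    elog_pi, elog_A = _expected_log_pi_A(posterior)
    logBs = [_expected_log_gauss(np.asarray(s, dtype=float), posterior)
             for s in sequences]
    _, _, _, logZ = _forward_backward(elog_pi, elog_A, logBs)
    return _elbo_from_estep(posterior, logZ)


# ---------------------------------------------------------------------------
# VBEM

def _m_step(X: np.ndarray, gamma: np.ndarray, xi_sum: np.ndarray,
            gamma1_sum: np.ndarray, priors: VbPriors) -> VbPosterior:
    K = gamma.shape[1]
    D = X.shape[1]
    Nk = gamma.sum(axis=0) + 1e-10
    xbar = (gamma.T @ X) / Nk[:, None]
    kappa = priors.kappa0 + Nk
    nu = priors.nu0 + Nk
    m = (priors.kappa0 * priors.m0[None, :] + Nk[:, None] * xbar) \
        / kappa[:, None]
    Winv = np.empty((K, D, D))
    for k in range(K):
        diff = X - xbar[k]
        Sk = (gamma[:, k][:, None] * diff).T @ diff
        dm = xbar[k] - priors.m0
        Winv[k] = (priors.W0inv + Sk
                   + priors.kappa0 * Nk[k] / (priors.kappa0 + Nk[k])
                   * np.outer(dm, dm))
        Winv[k] = 0.5 * (Winv[k] + Winv[k].T)
    return VbPosterior(alpha=priors.alpha0 + gamma1_sum,
                       beta=priors.beta0 + xi_sum,
                       m=m, kappa=kappa, Winv=Winv, nu=nu, priors=priors)


def _init_responsibilities(X: np.ndarray, lengths: np.ndarray, K: int,
                           rs: int, init_feature_scale=None):
    """Seeded k-means partition of the pooled observations.

    ``init_feature_scale`` rescales features for the partition only (the
    fit itself always sees the unscaled features); downweighting a noisy,
    weakly-separating axis such as fixation duration steers the initial
    partition toward spatial structure and empirically reaches higher
    ELBO optima.
    """
    Xi = X if init_feature_scale is None else X * np.asarray(
        init_feature_scale, dtype=float)
    if K == 1:
        labels = np.zeros(len(X), dtype=int)
    else:
        labels = KMeans(n_clusters=K, n_init=1, random_state=rs,
                        max_iter=50).fit_predict(Xi)
    gamma = np.zeros((len(X), K))
    gamma[np.arange(len(X)), labels] = 1.0
    xi_sum = np.zeros((K, K))
    gamma1 = np.zeros(K)
    pos = 0
    for T in lengths:
        seq = labels[pos:pos + T]
        gamma1[seq[0]] += 1.0
        np.add.at(xi_sum, (seq[:-1], seq[1:]), 1.0)
        pos += T
    return gamma, xi_sum, gamma1


def _vbem_single(sequences: list[np.ndarray], K: int, priors: VbPriors,
                 rs: int, max_iter: int, rel_tol: float,
                 init_gamma=None, init_feature_scale=None) -> VbPosterior:
    X = np.concatenate(sequences, axis=0)
    lengths = np.array([len(s) for s in sequences])
    if init_gamma is None:
        g, xi, g1 = _init_responsibilities(X, lengths, K, rs,
                                           init_feature_scale)
    else:
        g, xi, g1 = init_gamma
    post = _m_step(X, g, xi, g1, priors)
    prev = -np.inf
    for _ in range(max_iter):
        elog_pi, elog_A = _expected_log_pi_A(post)
        logB = _expected_log_gauss(X, post)
        logBs = np.split(logB, np.cumsum(lengths)[:-1])
        gammas, xi_sum, gamma1_sum, logZ = _forward_backward(
            elog_pi, elog_A, logBs)
        cur = _elbo_from_estep(post, logZ)
        post.elbo_trace.append(cur)
        if np.isfinite(prev) and abs(cur - prev) <= rel_tol * abs(prev):
            post.converged = True
            break
        prev = cur
        gamma = np.concatenate(gammas, axis=0)
        new = _m_step(X, gamma, xi_sum, gamma1_sum, priors)
        new.elbo_trace = post.elbo_trace
        new.converged = post.converged
        post = new
    return post


def vbem_fit(sequences: list[np.ndarray], K: int,
             priors: VbPriors | None = None, restarts: int = 5,
             seed: int = 0, max_iter: int = 300, rel_tol: float = 1e-6,
             init_gamma=None, transform=None, init_feature_scale=None
             ) -> tuple[BhmmModel, VbPosterior]:
    """Fit a K-state Gaussian HMM by VBEM with seeded restarts.

    ``sequences`` are (T_i, D) feature arrays.  The best restart by final
    ELBO wins; its posterior-mean point model is returned together with
    the posterior.  When ``init_gamma`` (responsibilities and pairwise
    statistics) is given, a single run starts from it instead of the
    seeded k-means partitions.
    """
    sequences = [np.asarray(s, dtype=float) for s in sequences]
    n_obs = sum(len(s) for s in sequences)
    if K < 1:
        raise InfeasibleModelError("state count must be >= 1")
    if K > n_obs:
        raise InfeasibleModelError(
            f"K={K} exceeds the {n_obs} available observations")
    if priors is None:
        priors = default_priors(np.concatenate(sequences, axis=0), K)
    ss = np.random.SeedSequence(seed)
    if init_gamma is not None:
        restarts = 1
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in ss.spawn(max(restarts, 1))]
    best = None
    for r in range(max(restarts, 1)):
        post = _vbem_single(sequences, K, priors, child_seeds[r], max_iter,
                            rel_tol, init_gamma=init_gamma,
                            init_feature_scale=init_feature_scale)
        if best is None or post.elbo_trace[-1] > best.elbo_trace[-1]:
            best = post
    log.debug("stage=vbem K=%d restarts=%d elbo=%.3f iters=%d", K,
              restarts, best.elbo_trace[-1], len(best.elbo_trace))
    return best.point_model(transform=transform), best


def vbem_fit_fixed_emissions(sequences: list[np.ndarray], model: BhmmModel,
                             alpha0: float = 1.0, beta0: float = 1.0,
                             max_iter: int = 300, rel_tol: float = 1e-6
                             ) -> tuple[BhmmModel, VbPosterior]:
    """Variational fit of initial-state and transition rows only.

    Emission parameters stay fixed at ``model``'s Gaussian states (the
    shared, semantically labelled ROIs); only the Dirichlet posteriors of
    the prior vector and the transition rows are learned.  Appropriate
    when a single recording is too short to support free re-estimation of
    all state Gaussians without breaking cross-participant state
    correspondence.
    """
    sequences = [np.asarray(s, dtype=float) for s in sequences]
    K = model.n_states
    logBs = [_log_gauss(s, model.means, model.covariances)
             for s in sequences]
    alpha = np.full(K, alpha0, dtype=float)
    beta = np.full((K, K), beta0, dtype=float)
    trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        elog_pi = digamma(alpha) - digamma(alpha.sum())
        elog_A = digamma(beta) - digamma(beta.sum(axis=1))[:, None]
        _, xi_sum, gamma1, logZ = _forward_backward(elog_pi, elog_A, logBs)
        kl = _kl_dirichlet(alpha, alpha0)
        for j in range(K):
            kl += _kl_dirichlet(beta[j], beta0)
        cur = logZ - kl
        trace.append(cur)
        if np.isfinite(prev) and abs(cur - prev) <= rel_tol * abs(prev):
            converged = True
            break
        prev = cur
        alpha = alpha0 + gamma1
        beta = beta0 + xi_sum
    fitted = BhmmModel(prior=alpha / alpha.sum(),
                       transition=beta / beta.sum(axis=1, keepdims=True),
                       means=model.means.copy(),
                       covariances=model.covariances.copy(),
                       transform=model.transform)
    post = VbPosterior(alpha=alpha, beta=beta, m=model.means.copy(),
                       kappa=np.full(K, np.inf),
                       Winv=model.covariances.copy(),
                       nu=np.full(K, np.inf), priors=None,
                       elbo_trace=trace, converged=converged)
    return fitted, post


def select_state_count(sequences: list[np.ndarray], k_range,
                       priors: VbPriors | None = None, restarts: int = 5,
                       seed: int = 0, max_iter: int = 300,
                       rel_tol: float = 1e-6, transform=None,
                       init_feature_scale=None):
    """Fit every K in ``k_range``; pick the best-ELBO K (ties -> smaller K).

    Returns (K*, {K: (model, posterior)}).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("state-count range is empty")
    results, failures = {}, {}
    for K in ks:
        try:
            results[K] = vbem_fit(sequences, K, priors=priors,
                                  restarts=restarts, seed=seed + K,
                                  max_iter=max_iter, rel_tol=rel_tol,
                                  transform=transform,
                                  init_feature_scale=init_feature_scale)
        except Exception as exc:   # propagate only if nothing fits
            failures[K] = exc
    if not results:
        raise RuntimeError(f"all state counts failed: {failures}")
    best_k = max(results, key=lambda K: (results[K][1].elbo_trace[-1], -K))
    log.info("stage=select_k k_range=%s chosen=%d elbos=%s", ks, best_k,
             {K: round(results[K][1].elbo_trace[-1], 2) for K in results})
    return best_k, results


def decode(model: BhmmModel, features: np.ndarray) -> StateAssignment:
    """Smoothed posterior state marginals and per-fixation MAP labels.

    Runs forward-backward under the point model in scaled space (robust
    to very unlikely observations).  Ties in the per-fixation argmax go
    to the lowest state index.
    """
    X = np.asarray(features, dtype=float)
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.prior)
        log_A = np.log(model.transition)
    logB = _log_gauss(X, model.means, model.covariances)
    gammas, _, _, _ = _forward_backward(log_pi, log_A, [logB])
    gamma = gammas[0]
    return StateAssignment(responsibilities=gamma,
                           map_states=gamma.argmax(axis=1))


def decode_scanpath(model: BhmmModel, scanpath) -> StateAssignment:
    """Decode a raw scanpath through the model's stored feature transform."""
    if model.transform is None:
        raise ValueError("model has no feature transform attached")
    return decode(model, model.transform.apply(scanpath))
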