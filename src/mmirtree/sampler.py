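"""Gibbs sampler for the mixture and single-class IRTree models.

Every decision node is a Bernoulli-logistic regression, so a
Pólya-Gamma augmented Gibbs sampler gives exact conjugate updates:

* person traits -- trivariate normal conditional per respondent,
* loadings -- truncated-normal conditionals (positivity constraint),
* node difficulties -- normal conditionals,
* omega -- normal conditional truncated to its U(0, 2) prior support,
* memberships z -- categorical conditional marginalising the PG
  variables (a valid partially collapsed ordering: z and pi are updated
  first, then the PG variables are redrawn from their full
  conditional),
* class proportions pi -- Dirichlet conditional,
* trait correlation matrix R -- per-element random-walk Metropolis with
  rejection of non-positive-definite proposals, matching the element-
  wise U(-1, 1) prior.

Model kinds: ``"mm"`` (four-class mixture) and the fixed single-class
benchmarks ``"ers"``, ``"mrs"``, ``"2rs"``, ``"0rs"``.  Single-class
kinds hold every respondent in one class and use the bivariate /
trivariate / univariate trait distribution their equations require
(correlations of unmodelled traits are fixed at zero).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import truncnorm

from .polya_gamma import sample_pg, seed_pg
from .simulate import _subseed
from .trees import N_CLASSES, PREDICTOR_CLIP, PROB_FLOOR

__all__ = ["PriorSpec", "McmcSettings", "run_mcmc", "MODEL_KINDS"]

logger = logging.getLogger("mmirtree")

#: model kind -> fixed class index (None = mixture)
MODEL_KINDS = {"mm": None, "ers": 1, "mrs": 2, "2rs": 3, "0rs": 4}

#: trait columns (theta, eta_ers, eta_mrs) with likelihood information
_ACTIVE_TRAITS = {
    "mm": (0, 1, 2),
    "ers": (0, 1),
    "mrs": (0, 2),
    "2rs": (0, 1, 2),
    "0rs": (0,),
}

_ERS_CLASSES = (0, 2)  # 0-based classes with free ERS loadings
_MRS_CLASSES = (1, 2)


@dataclass
class PriorSpec:
    """Priors of the Bayesian IRTree models.

    ``loading_var`` and ``difficulty_var`` are variances of the N(0, .)
    priors (the loading prior is truncated to (0, inf)); ``omega_bounds``
    are the limits of omega's uniform prior; correlations have
    element-wise U(-1, 1) priors subject to positive definiteness; class
    proportions have a Dirichlet prior with ``dirichlet_concentration``.
    """

    loading_var: float = 2.0
    difficulty_var: float = 2.0
    omega_bounds: tuple = (0.0, 2.0)
    dirichlet_concentration: tuple = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.loading_var <= 0 or self.difficulty_var <= 0:
            raise ValueError("prior variances must be positive")
        lo, hi = self.omega_bounds
        if not 0 <= lo < hi:
            raise ValueError("omega_bounds must satisfy 0 <= lo < hi")
        if len(self.dirichlet_concentration) != N_CLASSES or any(
            a <= 0 for a in self.dirichlet_concentration
        ):
            raise ValueError("dirichlet_concentration must be 4 positive values")


@dataclass
class McmcSettings:
    """Chain configuration; defaults mirror the full-scale study."""

    n_chains: int = 10
    n_iterations: int = 3000
    n_burnin: int = 1000
    thinning: int = 1
    seed: int = 0
    init: str = "heuristic"  # or "random"
    rhat_threshold: float = 1.05
    corr_step: float = 0.05

    def __post_init__(self):
        if self.n_burnin >= self.n_iterations:
            raise ValueError("burn-in must be smaller than n_iterations")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.init not in ("heuristic", "random"):
            raise ValueError("init must be 'heuristic' or 'random'")


def _zscore(x):
    s = x.std()
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


def _prepare_data(Y):
    """Precompute pseudo-item outcomes, masks and kappa = y* - 1/2."""
    P, J = Y.shape
    y0 = (Y <= 2).astype(float)
    m1 = (Y >= 3).astype(float)
    y1 = (Y == 3).astype(float)
    m2 = (Y != 3).astype(float)
    y2 = ((Y == 1) | (Y == 5)).astype(float)
    sign = np.where(Y <= 2, -1.0, 1.0) * m2  # 0 where node 2 unobserved
    return {
        "P": P,
        "J": J,
        "Y": Y,
        "k0": y0 - 0.5,
        "k1": (y1 - 0.5) * m1,
        "k2": (y2 - 0.5) * m2,
        "m1": m1,
        "m2": m2,
        "sign": sign,
        "yidx": (Y - 1).astype(np.int64) if J else Y.astype(np.int64),
    }


def _class_logliks(data, state, classes):
    """Per-class per-person log-likelihood, shape (4, P).

    Computed from the category probabilities, i.e. marginally over the
    PG augmentation.  Unrequested classes are left at -inf.
    """
    P, J = data["P"], data["J"]
    L = np.full((N_CLASSES, P), -np.inf)
    if J == 0:
        L[list(classes)] = 0.0
        return L
    th = state["u"][:, 0][:, None]
    ers = state["u"][:, 1][:, None]
    mrs = state["u"][:, 2][:, None]
    ath = state["alpha_theta"][None, :]
    om = state["omega"]
    yidx = data["yidx"]
    for c in classes:
        amrs = state["alpha_mrs"][None, :, c]
        aers = state["alpha_ers"][None, :, c]
        b = state["beta"][:, :, c]
        p0 = expit(np.clip(-ath * th - amrs * mrs - b[None, :, 0],
                           -PREDICTOR_CLIP, PREDICTOR_CLIP))
        p1 = expit(np.clip(-ath * th + amrs * mrs - b[None, :, 1],
                           -PREDICTOR_CLIP, PREDICTOR_CLIP))
        ext = aers * ers - b[None, :, 2]
        p2d = expit(np.clip(-om * ath * th + ext, -PREDICTOR_CLIP, PREDICTOR_CLIP))
        p2a = expit(np.clip(om * ath * th + ext, -PREDICTOR_CLIP, PREDICTOR_CLIP))
        agree = (1 - p0) * (1 - p1)
        cat = np.stack(
            [p0 * p2d, p0 * (1 - p2d), (1 - p0) * p1,
             agree * (1 - p2a), agree * p2a], axis=-1)
        chosen = np.take_along_axis(cat, yidx[..., None], axis=2)[..., 0]
        L[c] = np.log(np.maximum(chosen, PROB_FLOOR)).sum(axis=1)
    return L


def _person_logliks(data, state, u, zi):
    """Log-likelihood of each person's responses under class zi[p]."""
    th = u[:, 0][:, None]
    ers = u[:, 1][:, None]
    mrs = u[:, 2][:, None]
    ath = state["alpha_theta"][None, :]
    om = state["omega"]
    aers = state["alpha_ers"][:, zi].T
    amrs = state["alpha_mrs"][:, zi].T
    b0 = state["beta"][:, 0, :][:, zi].T
    b1 = state["beta"][:, 1, :][:, zi].T
    b2 = state["beta"][:, 2, :][:, zi].T
    m1, m2, sign = data["m1"], data["m2"], data["sign"]
    s0 = 2.0 * data["k0"]  # +-1
    s1 = 2.0 * data["k1"]  # +-1 where observed, 0 elsewhere
    s2 = 2.0 * data["k2"]
    psi0 = np.clip(-ath * th - amrs * mrs - b0, -PREDICTOR_CLIP, PREDICTOR_CLIP)
    psi1 = np.clip(-ath * th + amrs * mrs - b1, -PREDICTOR_CLIP, PREDICTOR_CLIP)
    psi2 = np.clip(sign * (om * ath * th) + aers * ers - b2,
                   -PREDICTOR_CLIP, PREDICTOR_CLIP)
    ll = (
        log_expit(s0 * psi0)
        + m1 * log_expit(np.where(m1 > 0, s1 * psi1, 0.0))
        + m2 * log_expit(np.where(m2 > 0, s2 * psi2, 0.0))
    )
    return ll.sum(axis=1)


#: refresh-move variants: which trait columns are proposed fresh
_REFRESH_BLOCKS = ((1, 2), (1,), (2,))


def _refresh_move(data, state, rng, block):
    """Joint Metropolis refresh of (z_p, selected RS traits) per person.

    Proposes a fresh class from Categorical(pi) together with the RS
    traits in ``block`` drawn from their population conditional given
    the remaining traits; the Hastings ratio reduces to the response-
    likelihood ratio because the membership and trait proposal
    densities cancel against the prior.  This move lets a respondent
    jump between classes together with response-style traits consistent
    with the destination class, which plain one-site Gibbs cannot do
    once class-specific parameters have adapted.  Single-trait blocks
    keep the well-fitted other trait, enabling e.g. ERS-only <-> 2RS
    transitions.
    """
    P = data["P"]
    u = state["u"]
    R = state["R"]
    a = list(block)
    b = [i for i in range(3) if i not in block]
    # conditional N(mu, S) of u[a] given u[b]
    Rbb_inv = np.linalg.inv(R[np.ix_(b, b)])
    coef = R[np.ix_(a, b)] @ Rbb_inv
    S = R[np.ix_(a, a)] - coef @ R[np.ix_(b, a)]
    cholS = np.linalg.cholesky(S)
    mu = u[:, b] @ coef.T
    u_prop = u.copy()
    u_prop[:, a] = mu + rng.standard_normal((P, len(a))) @ cholS.T
    cum = np.cumsum(state["pi"])
    zi_prop = np.searchsorted(cum, rng.random(P)).astype(np.int64)
    zi_prop = np.minimum(zi_prop, N_CLASSES - 1)
    ll_cur = _person_logliks(data, state, u, state["zi"])
    ll_prop = _person_logliks(data, state, u_prop, zi_prop)
    accept = np.log(rng.random(P)) < ll_prop - ll_cur
    if accept.any():
        state["zi"] = np.where(accept, zi_prop, state["zi"])
        state["u"] = np.where(accept[:, None], u_prop, u)
    return int(accept.sum())


def _truncated_normal(rng, mean, sd, lower, upper=np.inf):
    a = (lower - mean) / sd
    b = (upper - mean) / sd if np.isfinite(upper) else np.full_like(a, np.inf)
    return truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)


def _init_state(data, kind, rng, init, fixed_class):
    P, J = data["P"], data["J"]
    state = {}
    state["alpha_theta"] = np.full(J, 1.0) + 0.05 * rng.standard_normal(J)
    state["alpha_theta"] = np.abs(state["alpha_theta"])
    state["omega"] = 0.5
    aers = np.zeros((J, N_CLASSES))
    amrs = np.zeros((J, N_CLASSES))
    for c in _ERS_CLASSES:
        aers[:, c] = 1.0
    for c in _MRS_CLASSES:
        amrs[:, c] = 0.6
    state["alpha_ers"] = aers
    state["alpha_mrs"] = amrs
    state["beta"] = np.zeros((J, 3, N_CLASSES))
    state["R"] = np.eye(3)
    state["pi"] = np.full(N_CLASSES, 0.25)
    if fixed_class is not None:
        state["zi"] = np.full(P, fixed_class - 1, dtype=np.int64)
    elif init == "heuristic" and J > 0:
        Y = data["Y"]
        e = ((Y == 1) | (Y == 5)).mean(axis=1)
        m = (Y == 3).mean(axis=1)
        he = e > np.median(e)
        hm = m > np.median(m)
        zi = np.select(
            [he & ~hm, ~he & hm, he & hm], [0, 1, 2], default=3
        ).astype(np.int64)
        # disperse chain starts: half the assignments are randomised so
        # chains do not share one deterministic starting partition
        scramble = rng.random(P) < 0.5
        zi[scramble] = rng.integers(0, N_CLASSES, size=int(scramble.sum()))
        state["zi"] = zi
    else:
        state["zi"] = rng.integers(0, N_CLASSES, size=P)
    if init == "heuristic" and J > 0:
        Y = data["Y"]
        th = _zscore(Y.mean(axis=1))
        ers = _zscore(((Y == 1) | (Y == 5)).mean(axis=1))
        mrs = _zscore((Y == 3).mean(axis=1))
        u = np.column_stack([th, ers, mrs]) + 0.3 * rng.standard_normal((P, 3))
    else:
        u = rng.standard_normal((P, 3))
    state["u"] = u
    return state


_CORR_PAIRS = ((0, 1), (0, 2), (1, 2))


def _free_corr_pairs(kind):
    active = set(_ACTIVE_TRAITS[kind])
    return [p for p in _CORR_PAIRS if set(p) <= active]


def _beta_specialise(data, state, zi, priors, rng):
    """One PG sweep updating only the class-specific difficulties to
    their conditional posterior means, given memberships and traits.
    Warm-start device (deterministic, no draws)."""
    P, J = data["P"], data["J"]
    k0, k1, k2 = data["k0"], data["k1"], data["k2"]
    m1, m2, sign = data["m1"], data["m2"], data["sign"]
    th = state["u"][:, 0][:, None]
    ers = state["u"][:, 1][:, None]
    mrs = state["u"][:, 2][:, None]
    ath = state["alpha_theta"][None, :]
    om = state["omega"]
    aers_pj = state["alpha_ers"][:, zi].T
    amrs_pj = state["alpha_mrs"][:, zi].T
    beta = state["beta"]
    zoh = np.zeros((P, N_CLASSES))
    zoh[np.arange(P), zi] = 1.0
    dvar = priors.difficulty_var
    b = [beta[:, k, :][:, zi].T for k in range(3)]
    psi = [
        np.clip(-ath * th - amrs_pj * mrs - b[0], -PREDICTOR_CLIP, PREDICTOR_CLIP),
        np.clip(-ath * th + amrs_pj * mrs - b[1], -PREDICTOR_CLIP, PREDICTOR_CLIP),
        np.clip(sign * (om * ath * th) + aers_pj * ers - b[2],
                -PREDICTOR_CLIP, PREDICTOR_CLIP),
    ]
    masks = [np.ones((P, J)), m1, m2]
    rests = [
        -ath * th - amrs_pj * mrs,
        (-ath * th + amrs_pj * mrs) * m1,
        (sign * om * ath * th + aers_pj * ers) * m2,
    ]
    kk = [k0, k1, k2]
    for node in range(3):
        w = np.zeros((P, J))
        obs = masks[node] > 0
        w[obs] = sample_pg(psi[node][obs])
        prec = 1.0 / dvar + w.T @ zoh
        lin = (w * rests[node] - kk[node]).T @ zoh
        beta[:, node, :] = lin / prec


def _pilot_init(data, priors, settings, chain_seed, rng):
    """Informed start for mixture chains.

    1. A brief single-class fit of the full tree (all loadings free)
       gives approximate traits, loadings and pooled difficulties.
    2. A short warm-start loop alternates (a) membership assignment
       from MARGINAL class likelihoods -- response-style traits
       integrated out by per-person importance sampling, so that the
       comparison carries the correct parsimony penalty instead of the
       overfit bias of point traits -- with (b) specialisation of the
       class-specific difficulties to the current members.
    3. Because class-level difficulty mismatch can masquerade as
       person-level style usage, wrongly swapped partitions are locally
       stable even under the marginal criterion; a final greedy test of
       the four single-style class swaps on the marginal mixture
       objective crosses to the better arrangement when one exists.

    Purely an initialization device: the stationary distribution of the
    chain is untouched.
    """
    pilot_settings = McmcSettings(
        n_chains=1, n_iterations=150, n_burnin=100, seed=chain_seed,
        init="heuristic")
    ch = _run_chain(data, "2rs", priors, pilot_settings,
                    _subseed(chain_seed, "pilot"), store_z=False)
    n = max(ch["n_kept"], 1)
    state = {
        "alpha_theta": ch["alpha_theta"].mean(axis=0),
        "omega": float(ch["omega"].mean()),
        "alpha_ers": np.zeros_like(ch["alpha_ers"][0]),
        "alpha_mrs": np.zeros_like(ch["alpha_mrs"][0]),
        "beta": np.repeat(
            ch["beta"].mean(axis=0)[:, :, 2:3], N_CLASSES, axis=2),
        "u": ch["u_sum"] / n,
        "pi": np.full(N_CLASSES, 0.25),
    }
    aers = ch["alpha_ers"].mean(axis=0)[:, 2]
    amrs = ch["alpha_mrs"].mean(axis=0)[:, 2]
    for c in _ERS_CLASSES:
        state["alpha_ers"][:, c] = aers
    for c in _MRS_CLASSES:
        state["alpha_mrs"][:, c] = amrs
    R = np.eye(3)
    for val, (i, j) in zip(ch["corr"].mean(axis=0), ch["corr_pairs"]):
        R[i, j] = R[j, i] = val
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        R = np.eye(3)
    state["R"] = R

    # importance-sampling bank for marginal class likelihoods
    P = data["P"]
    M = 32
    uhat = state["u"]
    Rinv = np.linalg.inv(R)
    sgn, logdetR = np.linalg.slogdet(R)
    u_bank = np.empty((M, P, 3))
    logw = np.empty((M, P))
    for m in range(M):
        eps = rng.standard_normal((P, 3))
        u_bank[m] = uhat + eps
        logw[m] = (-0.5 * np.einsum("pa,ab,pb->p", u_bank[m], Rinv, u_bank[m])
                   - 0.5 * logdetR + 0.5 * (eps ** 2).sum(axis=1))

    def marginals(st, classes=range(N_CLASSES)):
        L_m = np.full((M, N_CLASSES, P), -np.inf)
        for m in range(M):
            L_m[m] = _class_logliks(data, {**st, "u": u_bank[m]}, classes)
        return logsumexp(L_m + logw[:, None, :], axis=0) - np.log(M)

    # alternate marginal sorting with difficulty specialisation
    L_marg = marginals(state)
    for _ in range(5):
        zi = np.argmax(L_marg, axis=0)
        _beta_specialise(data, state, zi, priors, rng)
        L_marg = marginals(state)

    state["zi"] = np.argmax(L_marg, axis=0)

    # The marginal criterion under warm-start (pooled-loading) parameters
    # cannot reliably orient the weakly identified class axes: permuted
    # arrangements with re-specialised difficulties are locally stable.
    # Arbitrate by short trial runs -- a hundred Gibbs sweeps from a
    # candidate arrangement let the traits and loadings adapt, after
    # which the posterior mean deviance separates arrangements clearly.
    # Greedy search over the six pairwise class swaps (repeated once if
    # an improvement was found, so composite permutations such as
    # 3-cycles are reachable); the winning trial's end state starts the
    # chain.  Common random numbers across candidate trials sharpen the
    # comparison.
    def _swapped(st, ca, cb):
        out = {k: (v.copy() if isinstance(v, np.ndarray) else v)
               for k, v in st.items()}
        out["beta"][:, :, [ca, cb]] = st["beta"][:, :, [cb, ca]]
        out["pi"][[ca, cb]] = st["pi"][[cb, ca]]
        zi = st["zi"]
        out["zi"] = np.where(zi == ca, cb, np.where(zi == cb, ca, zi))
        return out

    def _marginal_score(st):
        """Response-style-marginalised mixture log-likelihood at a state.

        The conditional deviance rewards noise absorption by fitted RS
        traits, so it cannot arbitrate between class arrangements.
        Here the two RS traits are integrated out by 2-D Gauss-Hermite
        quadrature over their population conditional given each
        person's current substantive trait: deterministic (no Monte
        Carlo noise), and the residual error from conditioning on theta
        is common to all classes so it cancels in comparisons.
        """
        K = 9
        nodes, weights = np.polynomial.hermite.hermgauss(K)
        x = nodes * np.sqrt(2.0)
        logw1 = np.log(weights / np.sqrt(np.pi))
        grid = np.array([(a, b) for a in range(K) for b in range(K)])
        Rs = st["R"]
        r1 = Rs[1:, 0]
        S = Rs[1:, 1:] - np.outer(r1, r1)
        cholS = np.linalg.cholesky(S)
        theta = st["u"][:, 0]
        mu = np.outer(theta, r1)  # (P, 2)
        L_k = np.empty((K * K, N_CLASSES, P))
        logwk = np.empty(K * K)
        for k, (a, b) in enumerate(grid):
            eta = mu + cholS @ np.array([x[a], x[b]])
            u = np.column_stack([theta, eta])
            L_k[k] = _class_logliks(data, {**st, "u": u}, range(N_CLASSES))
            logwk[k] = logw1[a] + logw1[b]
        Lm = logsumexp(L_k + logwk[:, None, None], axis=0)
        logpi = np.log(np.maximum(st["pi"], PROB_FLOOR))
        score = float(logsumexp(logpi[:, None] + Lm, axis=0).sum())

        # Laplace-style parsimony correction for the class-specific RS
        # loadings: a populated class with free loadings pays roughly
        # 0.5 log(I/2pi) - log p(a-hat) per loading for the prior mass
        # its marginal likelihood spends on them.  Without it, hosting a
        # no-RS population in a loading-bearing class (loadings pinned
        # near zero) scores the same as hosting it in the structurally
        # correct class.
        J = data["J"]
        n_c = np.maximum(st["pi"], 0.0) * P
        m1_share = float(data["m1"].mean()) if J else 0.0
        m2_share = float(data["m2"].mean()) if J else 0.0
        lvar = priors.loading_var

        def _halfnormal_logpdf(x):
            return (0.5 * np.log(2.0 / (np.pi * lvar))
                    - 0.5 * np.asarray(x) ** 2 / lvar)

        for c in range(N_CLASSES):
            if n_c[c] < 1.0:
                continue
            if c in _ERS_CLASSES:
                info = max(0.2 * m2_share * n_c[c], 1.0)
                score -= float(np.sum(
                    0.5 * np.log(max(info / (2 * np.pi), 1.0))
                    - _halfnormal_logpdf(st["alpha_ers"][:, c])))
            if c in _MRS_CLASSES:
                info = max(0.2 * (1.0 + m1_share) * n_c[c], 1.0)
                score -= float(np.sum(
                    0.5 * np.log(max(info / (2 * np.pi), 1.0))
                    - _halfnormal_logpdf(st["alpha_mrs"][:, c])))
        return score

    def _trial(cand, seed):
        # long enough for traits and loadings to adapt to a proposed
        # arrangement before the marginal score is measured
        trial_settings = McmcSettings(
            n_chains=1, n_iterations=220, n_burnin=100, seed=chain_seed,
            init="random")
        ch_t = _run_chain(data, "mm", priors, trial_settings, seed,
                          store_z=False, init_state=cand)
        final = ch_t["final_state"]
        # score the trial's posterior-mean state: a single end-state
        # draw carries tens of nats of parameter noise, the mean state
        # does not
        n_t = max(ch_t["n_kept"], 1)
        R_t = np.eye(3)
        for val, (i, j) in zip(ch_t["corr"].mean(axis=0),
                               ch_t["corr_pairs"]):
            R_t[i, j] = R_t[j, i] = val
        try:
            np.linalg.cholesky(R_t)
        except np.linalg.LinAlgError:
            R_t = np.eye(3)
        mean_state = {
            "alpha_theta": ch_t["alpha_theta"].mean(axis=0),
            "omega": float(ch_t["omega"].mean()),
            "alpha_ers": ch_t["alpha_ers"].mean(axis=0),
            "alpha_mrs": ch_t["alpha_mrs"].mean(axis=0),
            "beta": ch_t["beta"].mean(axis=0),
            "u": ch_t["u_sum"] / n_t,
            "R": R_t,
            "pi": ch_t["pi"].mean(axis=0),
            "zi": final["zi"].copy(),
        }
        return final, mean_state, _marginal_score(mean_state)

    pairs = [(a, b) for a in range(N_CLASSES) for b in range(a + 1, N_CLASSES)]
    cur_state, cur_mean, cur_score = _trial(state, _subseed(chain_seed, "trial", 0))
    logger.debug("warm start %s: base score %.1f", chain_seed, cur_score)
    for rnd in (1, 2):
        seed_rnd = _subseed(chain_seed, "trial", rnd)
        improved = False
        for ca, cb in pairs:
            counts = np.bincount(cur_state["zi"], minlength=N_CLASSES)
            if min(counts[ca], counts[cb]) < max(0.02 * P, 5):
                # swap involving an (essentially) empty class: a trial
                # adds nothing but noise -- the same mean state scored
                # under both labelings isolates the structural
                # (parsimony) difference exactly
                cand_mean = _swapped(cur_mean, ca, cb)
                cand_score = _marginal_score(cand_mean)
                logger.debug(
                    "warm start %s rnd %d swap (%d,%d) [det]: %.1f vs %.1f",
                    chain_seed, rnd, ca, cb, cand_score, cur_score)
                if cand_score > cur_score:
                    cur_state = _swapped(cur_state, ca, cb)
                    cur_mean, cur_score = cand_mean, cand_score
                    improved = True
                continue
            cand_state, cand_mean, cand_score = _trial(
                _swapped(cur_state, ca, cb), seed_rnd)
            logger.debug("warm start %s rnd %d swap (%d,%d): %.1f vs %.1f",
                         chain_seed, rnd, ca, cb, cand_score, cur_score)
            if cand_score > cur_score:
                cur_state, cur_mean, cur_score = cand_state, cand_mean, cand_score
                improved = True
        if not improved:
            break
    return cur_state


def _run_chain(data, kind, priors, settings, chain_seed, store_z,
               init_state=None):
    """One MCMC chain; returns stored draws and trait summaries."""
    rng = np.random.default_rng(chain_seed)
    seed_pg(_subseed(chain_seed, "pg"))
    P, J = data["P"], data["J"]
    fixed_class = MODEL_KINDS[kind]
    classes = tuple(range(N_CLASSES)) if fixed_class is None else (fixed_class - 1,)
    corr_pairs = _free_corr_pairs(kind)
    if init_state is not None:
        state = {k: (v.copy() if isinstance(v, np.ndarray) else v)
                 for k, v in init_state.items()}
    elif kind == "mm" and settings.init == "heuristic" and J > 0:
        state = _pilot_init(data, priors, settings, chain_seed, rng)
    else:
        state = _init_state(data, kind, rng, settings.init, fixed_class)
    lvar, dvar = priors.loading_var, priors.difficulty_var
    om_lo, om_hi = priors.omega_bounds
    alpha0 = np.asarray(priors.dirichlet_concentration, dtype=float)

    n_keep = (settings.n_iterations - settings.n_burnin) // settings.thinning
    store = {
        "alpha_theta": np.empty((n_keep, J)),
        "omega": np.empty(n_keep),
        "alpha_ers": np.empty((n_keep, J, N_CLASSES)),
        "alpha_mrs": np.empty((n_keep, J, N_CLASSES)),
        "beta": np.empty((n_keep, J, 3, N_CLASSES)),
        "corr": np.empty((n_keep, len(corr_pairs))),
        "pi": np.empty((n_keep, N_CLASSES)),
        "deviance": np.empty(n_keep),
        "deviance_marginal": np.empty(n_keep),
    }
    if store_z:
        store["z"] = np.empty((n_keep, P), dtype=np.int8)
    u_sum = np.zeros((P, 3))
    u_sqsum = np.zeros((P, 3))
    corr_step = settings.corr_step
    corr_acc = 0
    corr_tries = 0

    k0, k1, k2 = data["k0"], data["k1"], data["k2"]
    m1, m2, sign = data["m1"], data["m2"], data["sign"]
    kept = 0
    L = _class_logliks(data, state, classes)

    for it in range(settings.n_iterations):
        zi = state["zi"]
        # --- memberships and class proportions (marginal over PG) ---
        if fixed_class is None:
            logp = np.log(np.maximum(state["pi"], PROB_FLOOR))[:, None] + L
            logp -= logsumexp(logp, axis=0)
            probs = np.exp(logp).T  # (P, 4)
            cum = np.cumsum(probs, axis=1)
            zi = np.sum(rng.random((P, 1)) > cum, axis=1).astype(np.int64)
            zi = np.minimum(zi, N_CLASSES - 1)
            state["zi"] = zi
            counts = np.bincount(zi, minlength=N_CLASSES)
            state["pi"] = rng.dirichlet(alpha0 + counts)

            # --- joint (z, RS-trait) refresh Metropolis moves --------
            # Class-specific parameters make wrongly partitioned
            # configurations self-reinforcing local modes under plain
            # one-site Gibbs; these moves cross between them.
            if J > 0:
                for block in _REFRESH_BLOCKS:
                    _refresh_move(data, state, rng, block)
                zi = state["zi"]

        if J > 0:
            zoh = np.zeros((P, N_CLASSES))
            zoh[np.arange(P), zi] = 1.0
            th = state["u"][:, 0][:, None]
            ers = state["u"][:, 1][:, None]
            mrs = state["u"][:, 2][:, None]
            ath = state["alpha_theta"][None, :]
            om = state["omega"]
            aers_pj = state["alpha_ers"][:, zi].T
            amrs_pj = state["alpha_mrs"][:, zi].T
            b0 = state["beta"][:, 0, :][:, zi].T
            b1 = state["beta"][:, 1, :][:, zi].T
            b2 = state["beta"][:, 2, :][:, zi].T

            psi0 = np.clip(-ath * th - amrs_pj * mrs - b0,
                           -PREDICTOR_CLIP, PREDICTOR_CLIP)
            psi1 = np.clip(-ath * th + amrs_pj * mrs - b1,
                           -PREDICTOR_CLIP, PREDICTOR_CLIP)
            psi2 = np.clip(sign * (om * ath * th) + aers_pj * ers - b2,
                           -PREDICTOR_CLIP, PREDICTOR_CLIP)

            # --- Polya-Gamma augmentation (fresh draw each sweep) ---
            w0 = sample_pg(psi0).reshape(P, J)
            w1 = np.zeros((P, J))
            w2 = np.zeros((P, J))
            obs1 = m1 > 0
            obs2 = m2 > 0
            w1[obs1] = sample_pg(psi1[obs1])
            w2[obs2] = sample_pg(psi2[obs2])

            # --- person traits: trivariate normal conditional ---
            A0 = np.stack(
                [np.broadcast_to(-ath, (P, J)), np.zeros((P, J)), -amrs_pj],
                axis=-1)
            A1 = np.stack(
                [np.broadcast_to(-ath, (P, J)), np.zeros((P, J)), amrs_pj],
                axis=-1)
            A2 = np.stack(
                [sign * om * ath, aers_pj * m2, np.zeros((P, J))], axis=-1)
            Rinv = np.linalg.inv(state["R"])
            prec = (
                Rinv[None]
                + np.einsum("pj,pja,pjb->pab", w0, A0, A0)
                + np.einsum("pj,pja,pjb->pab", w1, A1, A1)
                + np.einsum("pj,pja,pjb->pab", w2, A2, A2)
            )
            rhs = (
                np.einsum("pj,pja->pa", k0 - w0 * (-b0), A0)
                + np.einsum("pj,pja->pa", k1 - w1 * (-b1) * m1, A1)
                + np.einsum("pj,pja->pa", k2 - w2 * (-b2) * m2, A2)
            )
            chol = np.linalg.cholesky(prec)
            mu = np.linalg.solve(prec, rhs[..., None])[..., 0]
            eps = rng.standard_normal((P, 3))
            dev = np.linalg.solve(
                np.transpose(chol, (0, 2, 1)), eps[..., None])[..., 0]
            state["u"] = mu + dev
            th = state["u"][:, 0][:, None]
            ers = state["u"][:, 1][:, None]
            mrs = state["u"][:, 2][:, None]

            # --- node difficulties: normal conditionals per (j, c) ---
            m0_rest = -ath * th - amrs_pj * mrs
            m1_rest = (-ath * th + amrs_pj * mrs) * m1
            m2_rest = (sign * om * ath * th + aers_pj * ers) * m2
            beta = state["beta"]
            for node, (w, kk, rest) in enumerate(
                ((w0, k0, m0_rest), (w1, k1, m1_rest), (w2, k2, m2_rest))
            ):
                prec_b = 1.0 / dvar + w.T @ zoh
                lin_b = (w * rest - kk).T @ zoh
                mean_b = lin_b / prec_b
                draw = mean_b + rng.standard_normal(prec_b.shape) / np.sqrt(prec_b)
                beta[:, node, list(classes)] = draw[:, list(classes)]
            b0 = beta[:, 0, :][:, zi].T
            b1 = beta[:, 1, :][:, zi].T
            b2 = beta[:, 2, :][:, zi].T

            # --- ERS loadings: truncated-normal conditionals ---
            ers_cls = [c for c in _ERS_CLASSES if c in classes]
            if ers_cls:
                rest = (sign * om * ath * th - b2) * m2
                prec_a = 1.0 / lvar + (w2 * ers ** 2).T @ zoh
                lin_a = ((k2 - w2 * rest) * ers).T @ zoh
                mean_a = lin_a / prec_a
                sd_a = 1.0 / np.sqrt(prec_a)
                for c in ers_cls:
                    state["alpha_ers"][:, c] = _truncated_normal(
                        rng, mean_a[:, c], sd_a[:, c], 0.0)
                aers_pj = state["alpha_ers"][:, zi].T

            # --- MRS loadings: truncated-normal conditionals ---
            mrs_cls = [c for c in _MRS_CLASSES if c in classes]
            if mrs_cls:
                rest0 = -ath * th - b0
                rest1 = (-ath * th - b1) * m1
                prec_a = 1.0 / lvar + ((w0 + w1) * mrs ** 2).T @ zoh
                lin_a = (
                    (k0 - w0 * rest0) * (-mrs) + (k1 - w1 * rest1) * mrs
                ).T @ zoh
                mean_a = lin_a / prec_a
                sd_a = 1.0 / np.sqrt(prec_a)
                for c in mrs_cls:
                    state["alpha_mrs"][:, c] = _truncated_normal(
                        rng, mean_a[:, c], sd_a[:, c], 0.0)
                amrs_pj = state["alpha_mrs"][:, zi].T

            # --- substantive loadings (class-invariant, pooled) ---
            rest0 = -amrs_pj * mrs - b0
            rest1 = (amrs_pj * mrs - b1) * m1
            rest2 = (aers_pj * ers - b2) * m2
            a2 = sign * om * th
            prec_t = 1.0 / lvar + (
                (w0 + w1) * th ** 2 + w2 * a2 ** 2
            ).sum(axis=0)
            lin_t = (
                (k0 - w0 * rest0) * (-th)
                + (k1 - w1 * rest1) * (-th)
                + (k2 - w2 * rest2) * a2
            ).sum(axis=0)
            mean_t = lin_t / prec_t
            state["alpha_theta"] = _truncated_normal(
                rng, mean_t, 1.0 / np.sqrt(prec_t), 0.0)
            ath = state["alpha_theta"][None, :]

            # --- omega: normal conditional truncated to U(0, 2) support ---
            a_om = sign * ath * th
            rest = (aers_pj * ers - b2) * m2
            prec_o = float((w2 * a_om ** 2).sum())
            if prec_o > 0:
                lin_o = float(((k2 - w2 * rest) * a_om).sum())
                draw_o = _truncated_normal(
                    rng, np.atleast_1d(lin_o / prec_o),
                    np.atleast_1d(1.0 / np.sqrt(prec_o)), om_lo, om_hi)
                state["omega"] = float(np.atleast_1d(draw_o)[0])
            else:
                state["omega"] = rng.uniform(om_lo, om_hi)

            # --- trait correlations: element-wise RW Metropolis ---
            if corr_pairs:
                S = state["u"].T @ state["u"]
                R = state["R"]
                sgn, logdet = np.linalg.slogdet(R)
                ll_cur = -0.5 * (P * logdet + np.trace(np.linalg.solve(R, S)))
                for (i, jx) in corr_pairs:
                    prop = R.copy()
                    r_new = R[i, jx] + corr_step * rng.standard_normal()
                    corr_tries += 1
                    if abs(r_new) >= 1.0:
                        continue
                    prop[i, jx] = prop[jx, i] = r_new
                    try:
                        np.linalg.cholesky(prop)
                    except np.linalg.LinAlgError:
                        continue
                    sgn, logdet = np.linalg.slogdet(prop)
                    ll_prop = -0.5 * (
                        P * logdet + np.trace(np.linalg.solve(prop, S)))
                    if np.log(rng.random()) < ll_prop - ll_cur:
                        R = prop
                        ll_cur = ll_prop
                        corr_acc += 1
                state["R"] = R
                if it < settings.n_burnin and it % 50 == 49 and corr_tries:
                    rate = corr_acc / corr_tries
                    corr_step *= float(np.exp(0.5 * (rate - 0.44)))
                    corr_acc = 0
                    corr_tries = 0

        # --- deviance at the current draw (reused for next z update) ---
        L = _class_logliks(data, state, classes)
        if fixed_class is None:
            dev_cond = -2.0 * L[zi, np.arange(P)].sum()
            with np.errstate(divide="ignore"):
                logpi = np.log(np.maximum(state["pi"], PROB_FLOOR))[:, None]
            dev_marg = -2.0 * logsumexp(logpi + L, axis=0).sum()
        else:
            dev_cond = -2.0 * L[fixed_class - 1].sum()
            dev_marg = dev_cond

        if it >= settings.n_burnin and (it - settings.n_burnin) % settings.thinning == 0:
            if kept < n_keep:
                store["alpha_theta"][kept] = state["alpha_theta"]
                store["omega"][kept] = state["omega"]
                store["alpha_ers"][kept] = state["alpha_ers"]
                store["alpha_mrs"][kept] = state["alpha_mrs"]
                store["beta"][kept] = state["beta"]
                store["corr"][kept] = [state["R"][i, jx] for i, jx in corr_pairs]
                store["pi"][kept] = state["pi"]
                store["deviance"][kept] = dev_cond
                store["deviance_marginal"][kept] = dev_marg
                if store_z:
                    store["z"][kept] = (zi + 1).astype(np.int8)
                u_sum += state["u"]
                u_sqsum += state["u"] ** 2
                kept += 1

    store["corr_pairs"] = corr_pairs
    store["u_sum"] = u_sum
    store["u_sqsum"] = u_sqsum
    store["n_kept"] = kept
    store["final_state"] = state
    return store


def run_mcmc(Y, kind="mm", priors=None, settings=None):
    """Run all chains for one model on a persons x items response array.

    ``Y`` may have zero columns, in which case the sampler reduces to
    the prior (useful for prior-predictive checks of pi).

    Returns a list of per-chain draw dictionaries.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; choose from {list(MODEL_KINDS)}")
    priors = priors or PriorSpec()
    settings = settings or McmcSettings()
    Y = np.asarray(Y, dtype=np.int64)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-D")
    if Y.shape[1] and (np.ptp(Y, axis=0) == 0).any():
        warnings.warn("constant response column detected; estimates for that "
                      "item may be degenerate", stacklevel=2)
    data = _prepare_data(Y)
    store_z = MODEL_KINDS[kind] is None
    chains = []
    for c in range(settings.n_chains):
        chain_seed = _subseed(settings.seed, "chain", c)
        chains.append(
            _run_chain(data, kind, priors, settings, chain_seed, store_z))
    return chains
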