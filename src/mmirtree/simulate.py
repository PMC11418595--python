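"""Synthetic 5-point rating data under the four-class mixture tree.

The generator reproduces a fixed study design: traits drawn from a
multivariate normal with unit variances and a known correlation
structure, item loadings and difficulties from uniform distributions,
deterministic block assignment of persons to classes under nine
registered class-proportion conditions, and multinomial responses from
the class-selected category probabilities.

Defaults (2000 persons, 20 items, 10 replications per condition,
alpha_theta ~ U(0.75, 1.75), omega = 0.50, alpha_ers ~ U(0.75, 1.25),
alpha_mrs ~ U(0.50, 0.75), beta ~ U(-2, 2) independently per class,
cor(theta, eta_ers) = 0.20, cor(theta, eta_mrs) = 0.00,
cor(eta_ers, eta_mrs) = -0.40) are the generating conditions of the
study this package replicates and should not normally be changed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .trees import (
    CLASS_SPECS,
    N_CLASSES,
    ItemParameters,
    PersonParameters,
    RatingMatrix,
    mixture_category_probabilities,
)

__all__ = [
    "DEFAULT_TRAIT_CORR",
    "CONDITIONS",
    "SimulationCondition",
    "GeneratedDataset",
    "default_trait_correlation",
    "draw_person_traits",
    "draw_item_parameters",
    "assign_memberships",
    "simulate_responses",
    "generate_condition",
    "get_condition",
]

#: generating correlations (theta, eta_ers), (theta, eta_mrs), (ers, mrs)
DEFAULT_TRAIT_CORR = (0.20, 0.00, -0.40)


def default_trait_correlation() -> np.ndarray:
    """3x3 generating correlation matrix of (theta, eta_ers, eta_mrs)."""
    r12, r13, r23 = DEFAULT_TRAIT_CORR
    return np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the class-proportion design."""

    name: str
    pi_true: tuple
    n_persons: int = 2000
    n_items: int = 20
    n_replications: int = 10
    master_seed: int = 0

    def __post_init__(self):
        pi = np.asarray(self.pi_true, dtype=float)
        if pi.shape != (N_CLASSES,) or abs(pi.sum() - 1.0) > 1e-12 or (pi < 0).any():
            raise ValueError("pi_true must be a length-4 probability simplex")


def _registry():
    conds = {"equal": (0.25, 0.25, 0.25, 0.25)}
    dom_names = ("ers_dominated", "mrs_dominated", "2rs_dominated", "0rs_dominated")
    single_names = ("ers_only", "mrs_only", "2rs_only", "0rs_only")
    for c, (dn, sn) in enumerate(zip(dom_names, single_names)):
        dom = [0.10] * 4
        dom[c] = 0.70
        conds[dn] = tuple(dom)
        single = [0.0] * 4
        single[c] = 1.0
        conds[sn] = tuple(single)
    return conds


#: the nine registered class-proportion conditions
CONDITIONS = _registry()


def get_condition(name, n_persons=2000, n_items=20, n_replications=10,
                  master_seed=0) -> SimulationCondition:
    """Look up a registered condition by name."""
    try:
        pi = CONDITIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown condition {name!r}; choose from {sorted(CONDITIONS)}"
        ) from None
    return SimulationCondition(name, pi, n_persons, n_items, n_replications,
                               master_seed)


@dataclass
class GeneratedDataset:
    """A simulated dataset bundled with its generating ground truth."""

    ratings: RatingMatrix
    persons: PersonParameters
    items: ItemParameters
    z_true: np.ndarray
    pi_true: np.ndarray
    condition: str = ""
    replication: int = 0
    seeds: dict = field(default_factory=dict)


def _subseed(master_seed, *stage) -> int:
    """Derive an independent (< 2^31) sub-seed for a named stage."""
    keys = [int(master_seed) % (2 ** 31)]
    for s in stage:
        if isinstance(s, str):
            keys.append(zlib.crc32(s.encode()) % (2 ** 31))
        else:
            keys.append(int(s) % (2 ** 31))
    ss = np.random.SeedSequence(keys)
    return int(ss.generate_state(1)[0] % (2 ** 31))


def draw_person_traits(n, R_gen=None, seed=0) -> PersonParameters:
    """Draw n trait triples from MVN(0, R_gen) (unit variances)."""
    if R_gen is None:
        R_gen = default_trait_correlation()
    R_gen = np.asarray(R_gen, dtype=float)
    if np.any(np.linalg.eigvalsh(R_gen) <= 0):
        raise np.linalg.LinAlgError("R_gen must be positive definite")
    rng = np.random.default_rng(seed)
    u = rng.multivariate_normal(np.zeros(3), R_gen, size=n, method="cholesky")
    return PersonParameters(u[:, 0], u[:, 1], u[:, 2], R_gen)


def draw_item_parameters(J, seed=0) -> ItemParameters:
    """Draw item parameters from the generating uniform distributions.

    alpha_theta ~ U(0.75, 1.75) (class-invariant), omega fixed at 0.50,
    alpha_ers ~ U(0.75, 1.25) independently in the ERS_ONLY and TWO_RS
    classes, alpha_mrs ~ U(0.50, 0.75) independently in the MRS_ONLY and
    TWO_RS classes, all beta[j, k, c] ~ U(-2, 2) independently per
    class; structurally inactive loadings are exactly 0.
    """
    rng = np.random.default_rng(seed)
    alpha_theta = rng.uniform(0.75, 1.75, size=J)
    alpha_ers = np.zeros((J, N_CLASSES))
    alpha_mrs = np.zeros((J, N_CLASSES))
    for spec in CLASS_SPECS:
        c = spec.index - 1
        if spec.ers_active:
            alpha_ers[:, c] = rng.uniform(0.75, 1.25, size=J)
        if spec.mrs_active:
            alpha_mrs[:, c] = rng.uniform(0.50, 0.75, size=J)
    beta = rng.uniform(-2.0, 2.0, size=(J, 3, N_CLASSES))
    return ItemParameters(alpha_theta, 0.50, alpha_ers, alpha_mrs, beta)


def assign_memberships(n, pi_true) -> np.ndarray:
    """Deterministic contiguous block assignment in class order 1..4.

    Block sizes are round(n * pi_c) (round half up); the remainder is
    absorbed by the last class.  No randomness is involved.
    """
    pi = np.asarray(pi_true, dtype=float)
    if pi.shape != (N_CLASSES,) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("pi_true must be a length-4 simplex")
    sizes = np.floor(n * pi[:-1] + 0.5).astype(int)
    z = np.empty(n, dtype=np.int64)
    start = 0
    for c, size in enumerate(sizes, start=1):
        z[start:start + size] = c
        start += size
    z[start:] = N_CLASSES
    return z


def simulate_responses(persons, items, z, seed=0) -> RatingMatrix:
    """Multinomial responses from the class-selected category model."""
    probs = mixture_category_probabilities(persons, items, z)
    rng = np.random.default_rng(seed)
    P, J, _ = probs.shape
    cum = np.cumsum(probs, axis=-1)
    u = rng.random((P, J, 1))
    resp = 1 + np.sum(u > cum, axis=-1)
    return RatingMatrix(resp.astype(np.int64))


def generate_condition(condition, redraw_persons=False) -> list:
    """Generate all replications of one condition.

    Item parameters, person traits and memberships are drawn once per
    condition; only responses are re-drawn per replication (set
    ``redraw_persons=True`` to regenerate traits each replication too).
    Fully reproducible from (condition name, master_seed).
    """
    if isinstance(condition, str):
        condition = get_condition(condition)
    ms = condition.master_seed
    items = draw_item_parameters(condition.n_items,
                                 seed=_subseed(ms, condition.name, "items"))
    persons = draw_person_traits(condition.n_persons,
                                 seed=_subseed(ms, condition.name, "traits"))
    z = assign_memberships(condition.n_persons, condition.pi_true)
    out = []
    for rep in range(condition.n_replications):
        if redraw_persons and rep > 0:
            persons = draw_person_traits(
                condition.n_persons,
                seed=_subseed(ms, condition.name, "traits", rep))
        resp_seed = _subseed(ms, condition.name, "responses", rep)
        ratings = simulate_responses(persons, items, z, seed=resp_seed)
        out.append(GeneratedDataset(
            ratings=ratings, persons=persons, items=items, z_true=z.copy(),
            pi_true=np.asarray(condition.pi_true, dtype=float),
            condition=condition.name, replication=rep,
            seeds={"master": ms, "responses": resp_seed},
        ))
    return out
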