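"""Core IRTree mathematics for 5-point rating data.

A rating in {1,...,5} is decomposed into up to three binary decision
nodes: *disagreement* (categories 1-2 vs 3-5), *neutrality* (3 vs 4-5,
reached only after non-disagreement) and *extremity* (1 vs 2 on the
disagreement branch, 5 vs 4 on the agreement branch).  Each node follows
a 2PL-type Bernoulli model; the probability of an observed category is
the product of the node probabilities along its tree path.

Four response-strategy classes share this tree but differ in which
response-style (RS) loadings are structurally zero:

=====  =========  ==============================================
index  label      active response styles
=====  =========  ==============================================
1      ERS_ONLY   extreme RS at the extremity node
2      MRS_ONLY   midpoint RS at the disagreement/neutrality nodes
3      TWO_RS     both
4      ZERO_RS    neither (substantive trait only)
=====  =========  ==============================================

The mixture model activates exactly one class per respondent through a
latent membership indicator ``z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

__all__ = [
    "MISSING",
    "N_CLASSES",
    "CLASS_LABELS",
    "ClassSpec",
    "CLASS_SPECS",
    "RatingMatrix",
    "PseudoItemTable",
    "ItemParameters",
    "PersonParameters",
    "MixtureState",
    "decompose_responses",
    "recompose_responses",
    "node_probabilities",
    "category_probabilities",
    "mixture_category_probabilities",
    "log_likelihood",
]

#: sentinel for pseudo-items that are missing by design (node not traversed)
MISSING = -1

N_CLASSES = 4
CLASS_LABELS = ("ERS_ONLY", "MRS_ONLY", "TWO_RS", "ZERO_RS")

#: linear predictors are clipped to +-PREDICTOR_CLIP before the link
PREDICTOR_CLIP = 35.0
#: floor applied to probabilities inside logarithms
PROB_FLOOR = 1e-300


@dataclass(frozen=True)
class ClassSpec:
    """Which response styles a latent class engages."""

    index: int  # 1-based, fixed global enumeration
    label: str
    ers_active: bool
    mrs_active: bool


CLASS_SPECS = (
    ClassSpec(1, "ERS_ONLY", True, False),
    ClassSpec(2, "MRS_ONLY", False, True),
    ClassSpec(3, "TWO_RS", True, True),
    ClassSpec(4, "ZERO_RS", False, False),
)


class InvalidResponseError(ValueError):
    """A rating outside {1,...,5} or an inconsistent pseudo-item pattern."""


def _as_labels(labels, n, prefix):
    if labels is None:
        return [f"{prefix}{i + 1}" for i in range(n)]
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError(f"expected {n} {prefix} labels, got {len(labels)}")
    return labels


class RatingMatrix:
    """Persons x items matrix of integer 5-point ratings.

    Parameters
    ----------
    responses : array-like of int, shape (P, J)
        Every entry must lie in {1, 2, 3, 4, 5}; missing values are not
        allowed (apply listwise deletion beforehand, see
        :func:`mmirtree.io.read_ratings`).
    person_ids, item_ids : sequences of labels, optional
    """

    def __init__(self, responses, person_ids=None, item_ids=None):
        arr = np.asarray(responses)
        if arr.ndim != 2:
            raise ValueError("responses must be a 2-D persons x items array")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("need at least one person and one item")
        if not np.issubdtype(arr.dtype, np.integer):
            flt = np.asarray(arr, dtype=float)
            if np.isnan(flt).any():
                p, j = np.argwhere(np.isnan(flt))[0]
                raise InvalidResponseError(
                    f"missing value at person {p}, item {j}; "
                    "ratings must be listwise complete"
                )
            if not np.all(flt == np.round(flt)):
                raise InvalidResponseError("non-integer rating found")
            arr = flt.astype(np.int64)
        else:
            arr = arr.astype(np.int64)
        bad = (arr < 1) | (arr > 5)
        if bad.any():
            p, j = np.argwhere(bad)[0]
            raise InvalidResponseError(
                f"rating {arr[p, j]} out of range [1, 5] "
                f"at person index {p}, item index {j}"
            )
        self.responses = arr
        self.person_ids = _as_labels(person_ids, arr.shape[0], "p")
        self.item_ids = _as_labels(item_ids, arr.shape[1], "item")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RatingMatrix":
        return cls(df.to_numpy(), person_ids=df.index, item_ids=df.columns)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.responses, index=self.person_ids, columns=self.item_ids
        )

    def __repr__(self):
        return f"RatingMatrix({self.n_persons} persons x {self.n_items} items)"


# Table of node outcomes per response category, in node order
# (disagreement, neutrality, extremity); MISSING marks untraversed nodes.
_RESPONSE_TO_NODES = {
    1: (1, MISSING, 1),
    2: (1, MISSING, 0),
    3: (0, 1, MISSING),
    4: (0, 0, 0),
    5: (0, 0, 1),
}
_NODES_TO_RESPONSE = {v: k for k, v in _RESPONSE_TO_NODES.items()}

NODE_NAMES = ("node0", "node1", "node2")


class PseudoItemTable:
    """Binary node outcomes ``y*[p, j, k]`` with structural missingness.

    ``values`` is an int8 array of shape (P, J, 3) whose entries are 0,
    1 or :data:`MISSING`.  Node k indexes disagreement (0), neutrality
    (1) and extremity (2).
    """

    def __init__(self, values, person_ids=None, item_ids=None):
        arr = np.asarray(values, dtype=np.int8)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError("values must have shape (P, J, 3)")
        ok = (arr == 0) | (arr == 1) | (arr == MISSING)
        if not ok.all():
            raise InvalidResponseError("pseudo-item entries must be 0, 1 or MISSING")
        self.values = arr
        self.person_ids = _as_labels(person_ids, arr.shape[0], "p")
        self.item_ids = _as_labels(item_ids, arr.shape[1], "item")

    @property
    def shape(self):
        return self.values.shape

    def to_wide_dataframe(self) -> pd.DataFrame:
        """Wide layout with 3*J columns named <item>_node<k>; empty cells
        (NaN) mark structurally missing nodes."""
        P, J, _ = self.values.shape
        wide = self.values.astype(float).reshape(P, J * 3)
        wide[wide == MISSING] = np.nan
        cols = [f"{item}_{node}" for item in self.item_ids for node in NODE_NAMES]
        return pd.DataFrame(wide, index=self.person_ids, columns=cols)

    def __repr__(self):
        P, J, _ = self.values.shape
        return f"PseudoItemTable({P} persons x {J} items x 3 nodes)"


def decompose_responses(ratings: RatingMatrix) -> PseudoItemTable:
    """Recode ratings into the three binary pseudo-items per item.

    Coding: 1 -> (1, -, 1); 2 -> (1, -, 0); 3 -> (0, 1, -);
    4 -> (0, 0, 0); 5 -> (0, 0, 1), where "-" is missing by design.
    """
    lut = np.full((6, 3), MISSING, dtype=np.int8)
    for resp, nodes in _RESPONSE_TO_NODES.items():
        lut[resp] = nodes
    values = lut[ratings.responses]
    return PseudoItemTable(values, ratings.person_ids, ratings.item_ids)


def recompose_responses(table: PseudoItemTable) -> RatingMatrix:
    """Inverse of :func:`decompose_responses`.

    Raises
    ------
    InvalidResponseError
        If a (y0, y1, y2) triple does not match any rating's pattern,
        e.g. ``y0 = 1`` with an observed neutrality node.
    """
    P, J, _ = table.values.shape
    out = np.zeros((P, J), dtype=np.int64)
    flat = table.values.reshape(-1, 3)
    resp = np.zeros(flat.shape[0], dtype=np.int64)
    for i, triple in enumerate(map(tuple, flat)):
        try:
            resp[i] = _NODES_TO_RESPONSE[tuple(int(v) for v in triple)]
        except KeyError:
            p, j = divmod(i, J)
            raise InvalidResponseError(
                f"inconsistent pseudo-item pattern {tuple(triple)} "
                f"at person index {p}, item index {j}"
            ) from None
    out[:] = resp.reshape(P, J)
    return RatingMatrix(out, table.person_ids, table.item_ids)


@dataclass
class ItemParameters:
    """All item-side parameters of the four-class mixture tree.

    Attributes
    ----------
    alpha_theta : (J,) array
        Substantive-trait loadings, positive and class-invariant.
    omega : float
        Proportionality constant (> 0) scaling the substantive trait at
        the extremity node; its sign flips between the disagreement and
        agreement branches.
    alpha_ers : (J, 4) array
        ERS loadings per class; exactly 0 in classes where ERS is
        inactive (MRS_ONLY, ZERO_RS).
    alpha_mrs : (J, 4) array
        MRS loadings per class; exactly 0 where MRS is inactive
        (ERS_ONLY, ZERO_RS).
    beta : (J, 3, 4) array
        Node difficulties beta[j, k, c] for node k and class c; the
        extremity difficulty beta[j, 2, c] is shared by the agreement
        and disagreement branches.
    """

    alpha_theta: np.ndarray
    omega: float
    alpha_ers: np.ndarray
    alpha_mrs: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        self.alpha_theta = np.asarray(self.alpha_theta, dtype=float)
        self.alpha_ers = np.asarray(self.alpha_ers, dtype=float)
        self.alpha_mrs = np.asarray(self.alpha_mrs, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        J = self.alpha_theta.shape[0]
        if self.alpha_ers.shape != (J, N_CLASSES):
            raise ValueError("alpha_ers must have shape (J, 4)")
        if self.alpha_mrs.shape != (J, N_CLASSES):
            raise ValueError("alpha_mrs must have shape (J, 4)")
        if self.beta.shape != (J, 3, N_CLASSES):
            raise ValueError("beta must have shape (J, 3, 4)")
        self.validate()

    @property
    def n_items(self) -> int:
        return self.alpha_theta.shape[0]

    def validate(self):
        arrays = (self.alpha_theta, self.alpha_ers, self.alpha_mrs, self.beta)
        if not all(np.isfinite(a).all() for a in arrays) or not np.isfinite(
            self.omega
        ):
            raise ValueError("non-finite item parameter")
        if np.any(self.alpha_theta <= 0) or self.omega <= 0:
            raise ValueError("alpha_theta and omega must be positive")
        if np.any(self.alpha_ers < 0) or np.any(self.alpha_mrs < 0):
            raise ValueError("RS loadings must be non-negative")
        for spec in CLASS_SPECS:
            c = spec.index - 1
            if not spec.ers_active and np.any(self.alpha_ers[:, c] != 0.0):
                raise ValueError(f"alpha_ers must be exactly 0 in {spec.label}")
            if not spec.mrs_active and np.any(self.alpha_mrs[:, c] != 0.0):
                raise ValueError(f"alpha_mrs must be exactly 0 in {spec.label}")


@dataclass
class PersonParameters:
    """Person traits: substantive theta and the two RS traits.

    The population model is multivariate normal with zero means, unit
    variances and correlation matrix ``R`` over (theta, eta_ers,
    eta_mrs).
    """

    theta: np.ndarray
    eta_ers: np.ndarray
    eta_mrs: np.ndarray
    R: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.eta_ers = np.atleast_1d(np.asarray(self.eta_ers, dtype=float))
        self.eta_mrs = np.atleast_1d(np.asarray(self.eta_mrs, dtype=float))
        self.R = np.asarray(self.R, dtype=float)
        n = self.theta.shape[0]
        if self.eta_ers.shape[0] != n or self.eta_mrs.shape[0] != n:
            raise ValueError("trait vectors must share a common length")
        if self.R.shape != (3, 3):
            raise ValueError("R must be 3x3")
        if not np.allclose(self.R, self.R.T) or not np.allclose(
            np.diag(self.R), 1.0
        ):
            raise ValueError("R must be symmetric with a unit diagonal")
        if np.any(np.linalg.eigvalsh(self.R) <= 0):
            raise ValueError("R must be positive definite")

    @property
    def n_persons(self) -> int:
        return self.theta.shape[0]

    def as_matrix(self) -> np.ndarray:
        """(n, 3) matrix with columns (theta, eta_ers, eta_mrs)."""
        return np.column_stack([self.theta, self.eta_ers, self.eta_mrs])


@dataclass
class MixtureState:
    """Class proportions and memberships of the four-class mixture."""

    pi: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.z = np.asarray(self.z, dtype=np.int64)
        if self.pi.shape != (N_CLASSES,):
            raise ValueError("pi must have length 4")
        if abs(self.pi.sum() - 1.0) > 1e-12 or np.any(self.pi < 0):
            raise ValueError("pi must be a probability simplex (sum 1)")
        if np.any((self.z < 1) | (self.z > N_CLASSES)):
            raise ValueError("memberships must lie in {1, 2, 3, 4}")


def _inverse_link(x, link):
    x = np.clip(x, -PREDICTOR_CLIP, PREDICTOR_CLIP)
    if link == "logit":
        return expit(x)
    if link == "probit":
        return ndtr(x)
    raise ValueError(f"unknown link {link!r}; use 'logit' or 'probit'")


def node_probabilities(persons, items, class_index, link="logit"):
    """Endorsement probabilities of the three decision nodes.

    Parameters
    ----------
    persons : PersonParameters
    items : ItemParameters
    class_index : int in {1, 2, 3, 4}
        Latent class whose (class-specific) parameters are used.
        Loadings of inactive styles are structural zeros, so e.g.
        ZERO_RS probabilities never depend on the RS traits.
    link : {"logit", "probit"}

    Returns
    -------
    dict with keys ``p0``, ``p1``, ``p2_disagree``, ``p2_agree``, each a
    (P, J) array: the probabilities of endorsing disagreement,
    neutrality and extremity (on the disagreement and agreement branch
    respectively).
    """
    if not 1 <= class_index <= N_CLASSES:
        raise IndexError(f"class index {class_index} out of range 1..4")
    c = class_index - 1
    th = persons.theta[:, None]
    ers = persons.eta_ers[:, None]
    mrs = persons.eta_mrs[:, None]
    a_th = items.alpha_theta[None, :]
    a_ers = items.alpha_ers[None, :, c]
    a_mrs = items.alpha_mrs[None, :, c]
    b = items.beta  # (J, 3, 4)
    for arr in (th, ers, mrs):
        if not np.isfinite(arr).all():
            raise FloatingPointError("non-finite person parameter")
    p0 = _inverse_link(-a_th * th - a_mrs * mrs - b[None, :, 0, c], link)
    p1 = _inverse_link(-a_th * th + a_mrs * mrs - b[None, :, 1, c], link)
    ext = a_ers * ers - b[None, :, 2, c]
    p2d = _inverse_link(-items.omega * a_th * th + ext, link)
    p2a = _inverse_link(items.omega * a_th * th + ext, link)
    return {"p0": p0, "p1": p1, "p2_disagree": p2d, "p2_agree": p2a}


def category_probabilities(persons, items, class_index, link="logit"):
    """Probabilities of the five rating categories under one class.

    Returns a (P, J, 5) array; each 5-vector is a product of node
    probabilities along the tree path and sums to 1.
    """
    nodes = node_probabilities(persons, items, class_index, link=link)
    p0, p1 = nodes["p0"], nodes["p1"]
    p2d, p2a = nodes["p2_disagree"], nodes["p2_agree"]
    agree = (1.0 - p0) * (1.0 - p1)
    probs = np.stack(
        [
            p0 * p2d,
            p0 * (1.0 - p2d),
            (1.0 - p0) * p1,
            agree * (1.0 - p2a),
            agree * p2a,
        ],
        axis=-1,
    )
    return probs


def mixture_category_probabilities(persons, items, z, link="logit"):
    """Category probabilities with the component selected by membership.

    ``z`` is an integer vector in {1,...,4} of length P; person p's
    5-vector equals the category probabilities of their own class,
    evaluated at that class's item parameters.
    """
    z = np.atleast_1d(np.asarray(z, dtype=np.int64))
    if np.any((z < 1) | (z > N_CLASSES)):
        raise IndexError("membership indices must lie in {1, 2, 3, 4}")
    if z.shape[0] != persons.n_persons:
        raise ValueError("z must have one entry per person")
    out = np.empty((persons.n_persons, items.n_items, 5))
    for spec in CLASS_SPECS:
        mask = z == spec.index
        if not mask.any():
            continue
        sub = PersonParameters(
            persons.theta[mask],
            persons.eta_ers[mask],
            persons.eta_mrs[mask],
            persons.R,
        )
        out[mask] = category_probabilities(sub, items, spec.index, link=link)
    return out


def log_likelihood(ratings, persons, items, mixture, link="logit"):
    """Mixture log-likelihood of observed ratings given all parameters.

    Sums ``log P(y_pj | z_p, ...)`` over persons and items; structurally
    missing pseudo-items contribute no factor by construction of the
    category probabilities.
    """
    if isinstance(mixture, MixtureState):
        z = mixture.z
    else:
        z = np.asarray(mixture, dtype=np.int64)
    if ratings.n_persons != persons.n_persons:
        raise ValueError("ratings and persons disagree on P")
    if ratings.n_items != items.n_items:
        raise ValueError("ratings and items disagree on J")
    probs = mixture_category_probabilities(persons, items, z, link=link)
    P, J = ratings.responses.shape
    chosen = np.take_along_axis(
        probs, (ratings.responses - 1)[..., None], axis=2
    )[..., 0]
    with np.errstate(divide="ignore"):
        ll = float(np.sum(np.log(np.maximum(chosen, PROB_FLOOR))))
    return ll
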