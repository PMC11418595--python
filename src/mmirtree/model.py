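"""Model and Results objects for Bayesian IRTree fitting.

Usage follows the conventions of statistical modelling packages: build
a model from data, call ``fit()``, inspect the returned results::

    from mmirtree import MMIRTree

    model = MMIRTree(ratings)            # RatingMatrix / DataFrame / array
    res = model.fit(n_chains=2, n_iterations=1500, n_burnin=500, seed=7)
    print(res.summary())
    res.class_probabilities                # (P, 4) posterior memberships
    res.modal_classes                      # modal assignment, labels 1..4
    res.dic_result.dic

Single-class benchmark trees use :class:`IRTree` with
``kind in {"ers", "mrs", "2rs", "0rs"}``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import compare, diagnostics
from .sampler import MODEL_KINDS, McmcSettings, PriorSpec, run_mcmc
from .trees import (
    CLASS_LABELS,
    N_CLASSES,
    ItemParameters,
    PersonParameters,
    RatingMatrix,
)

__all__ = [
    "MMIRTree",
    "IRTree",
    "fit_model",
    "posterior_class_probabilities",
    "modal_assignment",
    "IRTreeResults",
]

_ERS_CLASSES = (0, 2)
_MRS_CLASSES = (1, 2)

#: chain defaults of the full-scale study, per model kind
_DEFAULT_CHAINS = {"mm": 10, "ers": 5, "mrs": 5, "2rs": 5, "0rs": 5}


def _coerce_ratings(data) -> RatingMatrix:
    if isinstance(data, RatingMatrix):
        return data
    if isinstance(data, pd.DataFrame):
        return RatingMatrix.from_dataframe(data)
    return RatingMatrix(np.asarray(data))


class _IRTreeModelBase:
    """Shared scaffolding of mixture and single-class tree models."""

    kind: str = "mm"

    def __init__(self, ratings, priors: PriorSpec | None = None):
        self.ratings = _coerce_ratings(ratings)
        self.priors = priors or PriorSpec()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs):
        return cls(RatingMatrix.from_dataframe(df), **kwargs)

    @property
    def n_persons(self):
        return self.ratings.n_persons

    @property
    def n_items(self):
        return self.ratings.n_items

    def fit(
        self,
        n_chains: int | None = None,
        n_iterations: int = 3000,
        n_burnin: int = 1000,
        thinning: int = 1,
        seed: int = 0,
        init: str = "heuristic",
        rhat_threshold: float = 1.05,
    ) -> "IRTreeResults":
        """Draw from the posterior and return a results object.

        Defaults mirror the full-scale study (10 chains for the mixture
        model, 5 for single-class models, 3000 iterations with a 1000
        iteration burn-in); scale them down for exploratory fits.
        """
        settings = McmcSettings(
            n_chains=n_chains if n_chains is not None else _DEFAULT_CHAINS[self.kind],
            n_iterations=n_iterations,
            n_burnin=n_burnin,
            thinning=thinning,
            seed=seed,
            init=init,
            rhat_threshold=rhat_threshold,
        )
        chains = run_mcmc(
            self.ratings.responses, kind=self.kind, priors=self.priors,
            settings=settings,
        )
        return IRTreeResults(self, chains, settings)


class MMIRTree(_IRTreeModelBase):
    """Four-class mixture multidimensional IRTree for 5-point ratings.

    Latent classes (1) ERS only, (2) MRS only, (3) both response
    styles, (4) neither, share the substantive-trait loadings and omega
    but have class-specific RS loadings and node difficulties; the RS
    loadings of unused styles are structural zeros.
    """

    kind = "mm"


class IRTree(_IRTreeModelBase):
    """Single-class benchmark IRTree.

    ``kind`` selects which response styles the (homogeneous) population
    is assumed to engage: ``"ers"``, ``"mrs"``, ``"2rs"`` or ``"0rs"``.
    """

    def __init__(self, ratings, kind="2rs", priors=None):
        if kind not in MODEL_KINDS or kind == "mm":
            raise ValueError("kind must be one of 'ers', 'mrs', '2rs', '0rs'")
        self.kind = kind
        super().__init__(ratings, priors=priors)


def fit_model(ratings, model="mm", priors=None, settings=None) -> "IRTreeResults":
    """Functional front door: fit one of the five tree models.

    ``model`` is ``"mm"`` or a single-class kind; ``settings`` is an
    optional :class:`~mmirtree.sampler.McmcSettings`.
    """
    cls = MMIRTree(ratings, priors=priors) if model == "mm" else IRTree(
        ratings, kind=model, priors=priors)
    settings = settings or McmcSettings(
        n_chains=_DEFAULT_CHAINS[model], n_iterations=3000, n_burnin=1000)
    return cls.fit(
        n_chains=settings.n_chains,
        n_iterations=settings.n_iterations,
        n_burnin=settings.n_burnin,
        thinning=settings.thinning,
        seed=settings.seed,
        init=settings.init,
        rhat_threshold=settings.rhat_threshold,
    )


def posterior_class_probabilities(z_draws) -> np.ndarray:
    """Share of iterations assigning each respondent to each class.

    ``z_draws`` has shape (n_draws, P) with values in 1..4; rows of the
    returned (P, 4) matrix sum to 1.
    """
    z = np.asarray(z_draws, dtype=np.int64)
    if z.ndim != 2:
        raise ValueError("z_draws must be (n_draws, n_persons)")
    P = z.shape[1]
    Pz = np.empty((P, N_CLASSES))
    for c in range(1, N_CLASSES + 1):
        Pz[:, c - 1] = (z == c).mean(axis=0)
    return Pz


def modal_assignment(Pz) -> np.ndarray:
    """Class with the highest posterior probability per respondent.

    Ties break toward the lowest class index.
    """
    Pz = np.asarray(Pz, dtype=float)
    return np.argmax(Pz, axis=1) + 1


class IRTreeResults:
    """Posterior draws, summaries and diagnostics of one fitted tree.

    Key attributes
    --------------
    params : pd.Series of posterior means of all structural parameters
    item_parameters : ItemParameters at the posterior means
    person_parameters : PersonParameters at the posterior trait means
    pi / class_probabilities / modal_classes : mixture quantities
        (mixture fits only)
    rhat : pd.Series of Gelman-Rubin statistics (n_chains >= 2)
    converged : bool, all monitored Rhat below the threshold
    dic_result : DicResult with dbar, pv, dic
    """

    def __init__(self, model, chains, settings):
        self.model = model
        self.kind = model.kind
        self.settings = settings
        self.chains = chains
        self._fixed_class = MODEL_KINDS[self.kind]
        self._classes = (
            tuple(range(N_CLASSES))
            if self._fixed_class is None
            else (self._fixed_class - 1,)
        )
        self._pool()

    # -- assembly ----------------------------------------------------
    def _stack(self, name):
        return np.stack([ch[name] for ch in self.chains])  # (C, S, ...)

    def _pool(self):
        chains = self.chains
        n_kept = sum(ch["n_kept"] for ch in chains)
        self.n_draws = n_kept
        self.alpha_theta = self._stack("alpha_theta").reshape(n_kept, -1).mean(0)
        self.omega = float(self._stack("omega").mean())
        aers = self._stack("alpha_ers")
        amrs = self._stack("alpha_mrs")
        beta = self._stack("beta")
        J = self.model.n_items
        self.alpha_ers = aers.reshape(-1, J, N_CLASSES).mean(0)
        self.alpha_mrs = amrs.reshape(-1, J, N_CLASSES).mean(0)
        self.beta = beta.reshape(-1, J, 3, N_CLASSES).mean(0)
        # zero out structurally masked / unestimated entries
        mask_ers = np.zeros(N_CLASSES)
        mask_ers[[c for c in _ERS_CLASSES if c in self._classes]] = 1.0
        mask_mrs = np.zeros(N_CLASSES)
        mask_mrs[[c for c in _MRS_CLASSES if c in self._classes]] = 1.0
        self.alpha_ers *= mask_ers
        self.alpha_mrs *= mask_mrs
        self.corr_pairs = chains[0]["corr_pairs"]
        corr = self._stack("corr").reshape(n_kept, -1)
        R = np.eye(3)
        for val, (i, j) in zip(corr.mean(0) if corr.size else [], self.corr_pairs):
            R[i, j] = R[j, i] = val
        self.R = R
        u_sum = sum(ch["u_sum"] for ch in chains)
        u_sqsum = sum(ch["u_sqsum"] for ch in chains)
        u_mean = u_sum / n_kept
        self._u_mean = u_mean
        self._u_sd = np.sqrt(np.maximum(u_sqsum / n_kept - u_mean ** 2, 0.0))
        self.deviance_draws = self._stack("deviance").ravel()
        self.deviance_marginal_draws = self._stack("deviance_marginal").ravel()
        self.dic_result = compare.compute_dic(self.deviance_draws)
        if self._fixed_class is None:
            self.pi = self._stack("pi").reshape(n_kept, -1).mean(0)
            self.pi_sd = self._stack("pi").reshape(n_kept, -1).std(0, ddof=1)
            z_draws = np.concatenate([ch["z"] for ch in chains], axis=0)
            self._class_probabilities = posterior_class_probabilities(z_draws)
            self.modal_classes = modal_assignment(self._class_probabilities)
        else:
            self.pi = None
            self._class_probabilities = None
            self.modal_classes = np.full(
                self.model.n_persons, self._fixed_class, dtype=np.int64)
        self._rhat = None

    # -- convenience views -------------------------------------------
    @property
    def n_persons(self):
        return self.model.n_persons

    @property
    def n_items(self):
        return self.model.n_items

    @property
    def class_probabilities(self) -> np.ndarray:
        """(P, 4) posterior membership probabilities (mixture fits only)."""
        if self._class_probabilities is None:
            raise ValueError(
                "posterior class probabilities are only defined for the "
                "mixture model; this is a single-class fit")
        return self._class_probabilities

    @property
    def theta(self):
        """Posterior mean substantive trait scores."""
        return self._u_mean[:, 0]

    @property
    def eta_ers(self):
        return self._u_mean[:, 1]

    @property
    def eta_mrs(self):
        return self._u_mean[:, 2]

    @property
    def item_parameters(self) -> ItemParameters:
        return ItemParameters(
            self.alpha_theta, self.omega, self.alpha_ers, self.alpha_mrs,
            self.beta)

    @property
    def person_parameters(self) -> PersonParameters:
        return PersonParameters(
            self.theta, self.eta_ers, self.eta_mrs, self.R)

    def marginal_dic(self):
        """DIC from the deviance marginalised over z (non-default)."""
        return compare.compute_dic(self.deviance_marginal_draws)

    # -- named monitored parameters ----------------------------------
    def _monitored(self):
        yield "alpha_theta", self._stack("alpha_theta")
        yield "omega", self._stack("omega")
        aers = self._stack("alpha_ers")
        amrs = self._stack("alpha_mrs")
        beta = self._stack("beta")
        for c in self._classes:
            if c in _ERS_CLASSES:
                yield f"alpha_ers[{CLASS_LABELS[c]}]", aers[:, :, :, c]
            if c in _MRS_CLASSES:
                yield f"alpha_mrs[{CLASS_LABELS[c]}]", amrs[:, :, :, c]
            yield f"beta[{CLASS_LABELS[c]}]", beta[:, :, :, :, c]
        if self.corr_pairs:
            yield "corr", self._stack("corr")
        if self._fixed_class is None:
            yield "pi", self._stack("pi")
        yield "deviance", self._stack("deviance")

    @property
    def rhat(self) -> pd.Series:
        """Gelman-Rubin statistic for every monitored scalar."""
        if self._rhat is None:
            if len(self.chains) < 2:
                raise ValueError("Rhat requires at least two chains")
            self._rhat = diagnostics.rhat_table(self.chains, self._monitored())
        return self._rhat

    @property
    def converged(self) -> bool:
        threshold = self.settings.rhat_threshold
        flag = bool((self.rhat < threshold).all())
        if not flag:
            warnings.warn(
                f"{int((self.rhat >= threshold).sum())} parameter(s) have "
                f"Rhat >= {threshold}; inspect results.rhat", stacklevel=2)
        return flag

    # -- summaries ----------------------------------------------------
    @property
    def params(self) -> pd.Series:
        """Posterior means of the structural parameters, named."""
        vals = {}
        for j, item in enumerate(self.model.ratings.item_ids):
            vals[f"alpha_theta[{item}]"] = self.alpha_theta[j]
        vals["omega"] = self.omega
        for c in self._classes:
            lab = CLASS_LABELS[c]
            for j, item in enumerate(self.model.ratings.item_ids):
                if c in _ERS_CLASSES:
                    vals[f"alpha_ers[{lab},{item}]"] = self.alpha_ers[j, c]
                if c in _MRS_CLASSES:
                    vals[f"alpha_mrs[{lab},{item}]"] = self.alpha_mrs[j, c]
                for k in range(3):
                    vals[f"beta[{lab},{item},node{k}]"] = self.beta[j, k, c]
        for val, (i, j) in zip(
            [self.R[i, j] for i, j in self.corr_pairs], self.corr_pairs
        ):
            names = ("theta", "eta_ers", "eta_mrs")
            vals[f"corr[{names[i]},{names[j]}]"] = val
        if self.pi is not None:
            for c in range(N_CLASSES):
                vals[f"pi[{CLASS_LABELS[c]}]"] = self.pi[c]
        return pd.Series(vals, name="posterior_mean")

    def summary(self) -> str:
        lines = []
        name = "MM-IRTree" if self.kind == "mm" else f"{self.kind.upper()} IRTree"
        lines.append(f"{name} results")
        lines.append("=" * 46)
        lines.append(
            f"persons: {self.n_persons}   items: {self.n_items}   "
            f"chains: {len(self.chains)}   kept draws: {self.n_draws}")
        d = self.dic_result
        lines.append(
            f"DIC: {d.dic:,.1f}   (Dbar {d.dbar:,.1f}, pV {d.pv:,.1f})")
        try:
            mx = float(self.rhat.max())
            lines.append(
                f"max Rhat: {mx:.3f} "
                f"({'converged' if mx < self.settings.rhat_threshold else 'NOT converged'} "
                f"at threshold {self.settings.rhat_threshold})")
        except ValueError:
            lines.append("max Rhat: n/a (single chain)")
        lines.append(f"omega: {self.omega:.3f}")
        if self.pi is not None:
            pi_txt = ", ".join(
                f"{CLASS_LABELS[c]}: {self.pi[c]:.3f} ({self.pi_sd[c]:.3f})"
                for c in range(N_CLASSES))
            lines.append(f"class proportions (PSD): {pi_txt}")
            counts = np.bincount(self.modal_classes, minlength=5)[1:]
            lines.append(
                "modal class sizes: "
                + ", ".join(f"{CLASS_LABELS[c]}: {counts[c]}" for c in range(4)))
            cert = compare.certainty(self.class_probabilities, self.modal_classes)
            lines.append(
                "certainty: " + ", ".join(
                    f"{CLASS_LABELS[c - 1]}: {v:.2f}" if v is not None else
                    f"{CLASS_LABELS[c - 1]}: --"
                    for c, v in cert.items()))
        lines.append("-" * 46)
        lines.append("item parameters (posterior means):")
        tab = pd.DataFrame(
            {"alpha_theta": self.alpha_theta}, index=self.model.ratings.item_ids)
        for c in self._classes:
            lab = CLASS_LABELS[c]
            if c in _ERS_CLASSES:
                tab[f"a_ers[{lab}]"] = self.alpha_ers[:, c]
            if c in _MRS_CLASSES:
                tab[f"a_mrs[{lab}]"] = self.alpha_mrs[:, c]
        lines.append(tab.round(3).to_string())
        return "\n".join(lines)

    def __repr__(self):
        return (f"<IRTreeResults kind={self.kind!r} P={self.n_persons} "
                f"J={self.n_items} draws={self.n_draws}>")
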