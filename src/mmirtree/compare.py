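"""DIC model comparison and recovery / classification metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import N_CLASSES, CLASS_LABELS

__all__ = [
    "DicResult",
    "compute_dic",
    "select_model",
    "bias_rmse",
    "hit_rate",
    "certainty",
    "theta_difference",
]


@dataclass(frozen=True)
class DicResult:
    """Deviance information criterion: DIC = Dbar + pV.

    ``dbar`` is the posterior mean deviance; ``pv`` the effective number
    of parameters, taken as half the (sample, n-1 denominator) variance
    of the deviance across iterations.
    """

    dbar: float
    pv: float

    @property
    def dic(self) -> float:
        return self.dbar + self.pv


def compute_dic(deviance_draws) -> DicResult:
    """DIC components from pooled post-burn-in deviance draws."""
    d = np.asarray(deviance_draws, dtype=float).ravel()
    if d.size < 2:
        raise ValueError("need at least 2 deviance draws")
    return DicResult(dbar=float(d.mean()), pv=float(d.var(ddof=1) / 2.0))


def select_model(fits) -> tuple:
    """Pick the smallest-DIC model among fits of the same data.

    ``fits`` maps model labels to Results objects (anything exposing
    ``.dic_result`` and ``.n_persons``/``.n_items``).  Returns
    ``(best_label, table)`` where the table lists DIC, pV and Dbar.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    shapes = {(f.n_persons, f.n_items) for f in fits.values()}
    if len(shapes) > 1:
        raise ValueError("fits were obtained on different data shapes")
    rows = {
        label: {"dic": f.dic_result.dic, "pv": f.dic_result.pv,
                "dbar": f.dic_result.dbar}
        for label, f in fits.items()
    }
    table = pd.DataFrame(rows).T[["dic", "pv", "dbar"]]
    best = table["dic"].idxmin()
    return best, table


def bias_rmse(estimates, truth, axis=None) -> tuple:
    """Mean bias and RMSE of estimates against ground truth.

    ``axis=None`` averages over everything (e.g. across items and nodes
    and replications at once); an integer/tuple axis averages only over
    those dimensions, mirroring explicit averaging schemes.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {tru.shape}")
    err = est - tru
    bias = err.mean(axis=axis)
    rmse = np.sqrt((err ** 2).mean(axis=axis))
    return bias, rmse


def hit_rate(z_hat, z_true) -> dict:
    """Per-class proportion of correctly assigned respondents.

    Classes absent from ``z_true`` map to ``None`` (undefined) rather
    than 0.
    """
    z_hat = np.asarray(z_hat, dtype=np.int64)
    z_true = np.asarray(z_true, dtype=np.int64)
    if z_hat.shape != z_true.shape:
        raise ValueError("z_hat and z_true must have equal length")
    out = {}
    for c in range(1, N_CLASSES + 1):
        members = z_true == c
        if not members.any():
            out[c] = None
        else:
            out[c] = float((z_hat[members] == c).mean())
    return out


def certainty(Pz, z_hat) -> dict:
    """Mean posterior probability of the assigned class, per class.

    For each class c, averages ``Pz[p, z_hat[p]]`` over the respondents
    modally assigned to c; classes with no members map to None.
    """
    Pz = np.asarray(Pz, dtype=float)
    z_hat = np.asarray(z_hat, dtype=np.int64)
    if Pz.shape != (z_hat.shape[0], N_CLASSES):
        raise ValueError("Pz must have shape (n_persons, 4)")
    maxp = Pz[np.arange(len(z_hat)), z_hat - 1]
    out = {}
    for c in range(1, N_CLASSES + 1):
        members = z_hat == c
        out[c] = float(maxp[members].mean()) if members.any() else None
    return out


def theta_difference(fit_a, fit_b, group_by=None):
    """Per-person difference of posterior mean trait scores (a - b).

    ``fit_a`` / ``fit_b`` expose ``.theta`` (posterior means).  With
    ``group_by`` (a class-assignment vector), also returns group means
    keyed by class label.
    """
    ta = np.asarray(fit_a.theta, dtype=float)
    tb = np.asarray(fit_b.theta, dtype=float)
    if ta.shape != tb.shape:
        raise ValueError("fits cover different persons")
    diff = ta - tb
    if group_by is None:
        return diff
    group_by = np.asarray(group_by, dtype=np.int64)
    means = {
        CLASS_LABELS[c - 1]: float(diff[group_by == c].mean())
        for c in range(1, N_CLASSES + 1)
        if (group_by == c).any()
    }
    return diff, means
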