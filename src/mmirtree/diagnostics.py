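"""Convergence diagnostics and posterior summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_rhat", "rhat_table", "summarize"]


def compute_rhat(draws) -> float:
    """Gelman-Rubin potential scale reduction factor.

    Parameters
    ----------
    draws : array, shape (n_chains, n_draws)
        Post-burn-in draws of one scalar parameter.

    Returns
    -------
    float
        sqrt(((n-1)/n * W + B/n) / W); approximately 1 at convergence
        and well above 1 when chains disagree.  Constant chains (zero
        within-chain variance) return 1.0 by convention.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need draws from at least two chains")
    m, n = draws.shape
    if n < 10:
        raise ValueError("need at least 10 draws per chain")
    chain_means = draws.mean(axis=1)
    W = draws.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def rhat_table(chains, names_and_arrays) -> pd.Series:
    """Rhat per scalar parameter across chains.

    ``names_and_arrays`` yields (name, per-chain stacked draws) where
    each array has shape (n_chains, n_draws, *param_shape).
    """
    out = {}
    for name, arr in names_and_arrays:
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2:
            out[name] = compute_rhat(arr)
        else:
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            for idx in range(flat.shape[2]):
                out[f"{name}[{idx}]"] = compute_rhat(flat[:, :, idx])
    return pd.Series(out, name="rhat")


def summarize(draws, axis=0) -> pd.DataFrame:
    """Posterior means and SDs of pooled scalar draws.

    ``draws`` is a mapping name -> array whose first axis indexes
    pooled post-burn-in iterations; class memberships are deliberately
    excluded (they are summarised by modal assignment instead).
    """
    rows = []
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.size == 0:
            raise ValueError(f"no draws for parameter {name!r}")
        flat = arr.reshape(arr.shape[0], -1)
        means = flat.mean(axis=0)
        sds = flat.std(axis=0, ddof=1) if flat.shape[0] > 1 else np.zeros(flat.shape[1])
        if flat.shape[1] == 1:
            rows.append((name, means[0], sds[0]))
        else:
            for i in range(flat.shape[1]):
                rows.append((f"{name}[{i}]", means[i], sds[i]))
    return pd.DataFrame(rows, columns=["parameter", "mean", "sd"]).set_index(
        "parameter"
    )
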