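"""Top-level simulation-study harness.

``run_study`` composes the full pipeline for each requested condition
and replication: simulate a dataset, fit the mixture tree and the four
single-class benchmark trees, evaluate model selection, classification
and parameter recovery, and aggregate everything into a JSON report.
Completed units are skipped on re-run (resumability via per-unit report
files plus a manifest).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .compare import bias_rmse, certainty, hit_rate, select_model
from .io import write_ratings, write_truth
from .model import fit_model
from .sampler import McmcSettings
from .simulate import _subseed, generate_condition, get_condition

__all__ = ["StudyConfig", "run_study"]

logger = logging.getLogger("mmirtree")

_MODELS = ("mm", "ers", "mrs", "2rs", "0rs")


@dataclass
class StudyConfig:
    """Configuration of a (possibly scaled-down) simulation study.

    With no overrides this reproduces the full-scale design: nine
    class-proportion conditions x 10 replications of 2000 persons x 20
    items, MM-IRTree fit with 10 chains x 3000 iterations (burn-in
    1000) and each single-class tree with 5 chains x 3000.  ``scale``
    proportionally reduces persons, chains and iterations for desk-size
    runs and is recorded in the manifest.
    """

    conditions: tuple = ("equal", "ers_dominated", "mrs_dominated",
                         "2rs_dominated", "0rs_dominated", "ers_only",
                         "mrs_only", "2rs_only", "0rs_only")
    n_replications: int = 10
    n_persons: int = 2000
    n_items: int = 20
    mm_settings: McmcSettings = field(default_factory=lambda: McmcSettings(
        n_chains=10, n_iterations=3000, n_burnin=1000))
    single_settings: McmcSettings = field(default_factory=lambda: McmcSettings(
        n_chains=5, n_iterations=3000, n_burnin=1000))
    models: tuple = _MODELS
    seed: int = 0
    scale: float = 1.0
    rhat_threshold: float = 1.05
    out_dir: str = "study_out"

    def scaled(self):
        """Apply the --scale factor to persons, chains and iterations."""
        if self.scale == 1.0:
            return self
        s = self.scale

        def shrink(st):
            burn = max(100, int(st.n_burnin * s))
            return McmcSettings(
                n_chains=max(2, int(round(st.n_chains * s))),
                n_iterations=max(burn + 100, int(st.n_iterations * s)),
                n_burnin=burn,
                thinning=st.thinning, seed=st.seed, init=st.init,
                rhat_threshold=st.rhat_threshold)

        cfg = StudyConfig(
            conditions=self.conditions,
            n_replications=self.n_replications,
            n_persons=max(50, int(self.n_persons * s)),
            n_items=self.n_items,
            mm_settings=shrink(self.mm_settings),
            single_settings=shrink(self.single_settings),
            models=self.models, seed=self.seed, scale=self.scale,
            rhat_threshold=self.rhat_threshold, out_dir=self.out_dir)
        return cfg


def _evaluate_unit(dataset, fits):
    """Model selection plus recovery metrics for one dataset."""
    best, table = select_model(fits)
    report = {
        "model_selection": {
            "best": best,
            "dic_table": {k: dict(v) for k, v in table.iterrows()},
        }
    }
    mm = fits.get("mm")
    if mm is not None:
        hr = hit_rate(mm.modal_classes, dataset.z_true)
        ct = certainty(mm.class_probabilities, mm.modal_classes)
        pi_bias, pi_rmse = bias_rmse(mm.pi, dataset.pi_true)
        a_bias, a_rmse = bias_rmse(mm.alpha_theta, dataset.items.alpha_theta)
        report["classification"] = {
            "hit_rate": {str(k): v for k, v in hr.items()},
            "certainty": {str(k): v for k, v in ct.items()},
            "pi_est": mm.pi.tolist(),
            "pi_bias": float(pi_bias),
            "pi_rmse": float(pi_rmse),
        }
        report["recovery"] = {
            "alpha_theta_bias": float(a_bias),
            "alpha_theta_rmse": float(a_rmse),
            "omega_est": mm.omega,
            "omega_bias": mm.omega - dataset.items.omega,
        }
        report["rhat_max"] = float(mm.rhat.max()) if len(mm.chains) > 1 else None
    return report


def run_study(config: StudyConfig) -> dict:
    """Run (or resume) the configured study; returns the study report."""
    cfg = config.scaled()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "scale": cfg.scale,
        "n_persons": cfg.n_persons,
        "n_items": cfg.n_items,
        "conditions": list(cfg.conditions),
        "n_replications": cfg.n_replications,
        "mm_settings": vars(cfg.mm_settings),
        "single_settings": vars(cfg.single_settings),
        "failures": [],
    }
    reports = {}
    for cond_name in cfg.conditions:
        cond = get_condition(
            cond_name, n_persons=cfg.n_persons, n_items=cfg.n_items,
            n_replications=cfg.n_replications,
            master_seed=_subseed(cfg.seed, cond_name))
        datasets = generate_condition(cond)
        for ds in datasets:
            unit = f"{cond_name}_rep{ds.replication}"
            unit_path = out / f"{unit}.json"
            if unit_path.exists():
                logger.info("skipping completed unit %s", unit)
                reports[unit] = json.loads(unit_path.read_text())
                continue
            t0 = time.time()
            write_ratings(ds.ratings, out / f"{unit}_ratings.csv")
            write_truth(ds, out / f"{unit}_truth.json")
            fits = {}
            for mdl in cfg.models:
                st = cfg.mm_settings if mdl == "mm" else cfg.single_settings
                st = McmcSettings(
                    n_chains=st.n_chains, n_iterations=st.n_iterations,
                    n_burnin=st.n_burnin, thinning=st.thinning,
                    seed=_subseed(cfg.seed, cond_name, ds.replication, mdl),
                    init=st.init, rhat_threshold=cfg.rhat_threshold)
                try:
                    fits[mdl] = fit_model(ds.ratings, model=mdl, settings=st)
                except Exception as exc:  # keep the study going
                    logger.error("fit %s failed on %s: %s", mdl, unit, exc)
                    manifest["failures"].append(
                        {"unit": unit, "model": mdl, "error": str(exc)})
            if len(fits) >= 2:
                report = _evaluate_unit(ds, fits)
            else:
                report = {"error": "too few successful fits"}
            report["elapsed_s"] = time.time() - t0
            unit_path.write_text(json.dumps(report, indent=1))
            reports[unit] = report
            logger.info("unit %s done in %.1fs", unit, report["elapsed_s"])
    study = {"manifest": manifest, "units": reports}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "study_report.json").write_text(json.dumps(study, indent=1))
    return study
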