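"""End-to-end two-stage pipeline: split, PLS extraction, model fits, reports.

This is the library-level engine behind the command-line interface.  A run
takes a :class:`~plsfpm.simulate.SurvivalDataset`, splits it into training
and test subsets by a seeded permutation (default 70% train), extracts PLS
components of the observed time (or log time) on the training covariates,
fits the requested survival families on the training scores, and produces
an AIC/BIC comparison (with held-out test log-likelihood), a factor-selection
report from the best converged model, and cumulative-hazard curve tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .models import (
    FittedModel,
    compare,
    cox_partial_loglik,
    cumhaz_curve,
    fit_cox,
    fit_fpm,
    model_loglik,
)
from .pls import PLSDecomposition, fit_pls, transform
from .simulate import SurvivalDataset

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_results", "replace_seed"]

ALL_FAMILIES = ("exponential", "gompertz", "gengamma", "genf", "cox")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    families: tuple = ALL_FAMILIES
    n_components: int | str = 2  # or "auto"
    train_fraction: float = 0.7
    response: str = "time"  # or "logtime"
    standardize: bool = True
    selection_rule: tuple = ("relative", 0.5)
    selection_statistic: str = "backproj"
    curve_grid_max: float = 12.0
    curve_grid_step: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if not self.families:
            raise ValueError("at least one family must be requested")
        for fam in self.families:
            if fam not in ALL_FAMILIES:
                raise ValueError(f"unknown family {fam!r}")
        if self.response not in ("time", "logtime"):
            raise ValueError("response must be 'time' or 'logtime'")
        if self.n_components != "auto" and int(self.n_components) < 1:
            raise ValueError("n_components must be >= 1 or 'auto'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["families"] = list(self.families)
        d["selection_rule"] = list(self.selection_rule)
        return d


def replace_seed(config: RunConfig, seed: int) -> RunConfig:
    return dataclasses.replace(config, seed=int(seed))


@dataclass
class PipelineResult:
    config: RunConfig
    decomp: PLSDecomposition
    models: dict  # family -> FittedModel
    comparison: pd.DataFrame
    factor_report: pd.DataFrame | None
    curves: pd.DataFrame
    train_idx: np.ndarray
    test_idx: np.ndarray
    n_components: int

    @property
    def best(self) -> FittedModel | None:
        conv = [m for m in self.models.values() if m.converged]
        if not conv:
            return None
        return min(conv, key=lambda m: (m.aic, m.bic, m.family))


def split_indices(n: int, train_fraction: float, seed: int):
    """Seeded-permutation train/test split."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.ceil(train_fraction * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _response_vector(times, response: str) -> np.ndarray:
    return np.log(times) if response == "logtime" else times


def choose_n_components(X, y, times, events, *, standardize=True, seed=0, k=5) -> int:
    """Cross-validated choice of the number of PLS components.

    Grid 1..min(10, p); the criterion is the held-out censored log-likelihood
    of a stage-2 exponential fit (fast and monotone enough to rank A).
    """
    n, p = X.shape
    grid = range(1, min(10, p, n - 2) + 1)
    rng = np.random.default_rng(seed)
    folds = rng.permutation(n) % k
    best_a, best_ll = 1, -np.inf
    for a in grid:
        ll = 0.0
        ok = True
        for f in range(k):
            tr, te = folds != f, folds == f
            if te.sum() == 0 or tr.sum() <= a + 2:
                ok = False
                break
            try:
                d = fit_pls(X[tr], y[tr], a, standardize=standardize)
            except ValueError:
                ok = False
                break
            m = fit_fpm(transform(d, X[tr]), times[tr], events[tr], "exponential")
            theta = np.asarray(m.diagnostics["theta"])
            ll += model_loglik(
                "exponential", theta, transform(d, X[te]), times[te], events[te]
            )
        if ok and ll > best_ll:
            best_a, best_ll = a, ll
    return best_a


def run_pipeline(dataset: SurvivalDataset, config: RunConfig) -> PipelineResult:
    """Run split -> PLS -> per-family fits -> comparison -> reports."""
    train_idx, test_idx = split_indices(dataset.n, config.train_fraction, config.seed)
    Xtr, Xte = dataset.X[train_idx], dataset.X[test_idx]
    ttr, tte = dataset.time[train_idx], dataset.time[test_idx]
    etr, ete = dataset.event[train_idx], dataset.event[test_idx]
    ytr = _response_vector(ttr, config.response)

    if config.n_components == "auto":
        A = choose_n_components(
            Xtr, ytr, ttr, etr, standardize=config.standardize, seed=config.seed
        )
    else:
        A = int(config.n_components)
    decomp = fit_pls(
        Xtr, ytr, A, standardize=config.standardize, column_names=dataset.column_names
    )
    Str = decomp.scores
    Ste = transform(decomp, Xte) if len(test_idx) else np.zeros((0, A))

    models: dict[str, FittedModel] = {}
    test_ll: dict[str, float] = {}
    for fam in config.families:
        if fam == "cox":
            m = fit_cox(Str, ttr, etr, decomp=decomp)
            if m.converged and len(test_idx):
                test_ll[fam] = cox_partial_loglik(m.component_coefs, Ste, tte, ete)
        else:
            m = fit_fpm(Str, ttr, etr, fam, decomp=decomp)
            if m.converged and len(test_idx):
                theta = np.asarray(m.diagnostics["theta"])
                test_ll[fam] = model_loglik(fam, theta, Ste, tte, ete)
        models[fam] = m

    comparison = compare(models.values())
    comparison["test_loglik"] = [
        test_ll.get(f, np.nan) for f in comparison["family"]
    ]

    best = min(
        (m for m in models.values() if m.converged),
        key=lambda m: (m.aic, m.bic, m.family),
        default=None,
    )
    factor_report = None
    if best is not None and best.covariate_coefs is not None:
        from .selection import select_factors

        factor_report = select_factors(
            decomp,
            best,
            config.selection_rule,
            statistic=config.selection_statistic,
        )

    grid = np.round(
        np.arange(0.0, config.curve_grid_max + 1e-9, config.curve_grid_step), 10
    )
    profile = dataset.X[train_idx].mean(axis=0)
    curve_frames = [
        cumhaz_curve(m, decomp, profile, grid)
        for m in models.values()
        if m.converged
    ]
    curves = (
        pd.concat(curve_frames, ignore_index=True)
        if curve_frames
        else pd.DataFrame(columns=["t", "family", "cumhaz"])
    )

    return PipelineResult(
        config=config,
        decomp=decomp,
        models=models,
        comparison=comparison,
        factor_report=factor_report,
        curves=curves,
        train_idx=train_idx,
        test_idx=test_idx,
        n_components=A,
    )


def dataset_hash(dataset: SurvivalDataset) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(dataset.time).tobytes())
    h.update(np.ascontiguousarray(dataset.event).tobytes())
    h.update(np.ascontiguousarray(dataset.X).tobytes())
    h.update(",".join(dataset.column_names).encode())
    return h.hexdigest()


def write_results(result: PipelineResult, outdir, dataset: SurvivalDataset) -> dict:
    """Write comparison/factors/curves CSVs plus a reproducibility manifest.

    Outputs are deterministic: identical dataset, config and seed give
    byte-identical files.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.comparison.to_csv(outdir / "comparison.csv", index=False)
    if result.factor_report is not None:
        result.factor_report.to_csv(outdir / "factors.csv", index=False)
    result.curves.to_csv(outdir / "curves.csv", index=False)
    params = {
        fam: (m.baseline_spec.as_flat_dict() if m.baseline_spec is not None else {"family": fam})
        for fam, m in result.models.items()
        if m.converged
    }
    manifest = {
        "package": "plsfpm",
        "version": __version__,
        "seed": result.config.seed,
        "config": result.config.to_dict(),
        "n_components": result.n_components,
        "dataset_sha256": dataset_hash(dataset),
        "n_obs": int(dataset.n),
        "n_events": int(dataset.event.sum()),
        "baseline_parameters": params,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
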