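"""Loading-weights factor selection and covariate-scale coefficient reports.

The PLS loading weights double as a filter statistic for variable selection:
covariates whose back-projected coefficient (default) or component-1 loading
weight is large in magnitude are flagged as influential.  Because no
universally accepted cutoff exists, two rules are offered — relative
(``|stat| >= c * max|stat|``, default c = 0.5) and absolute
(``|stat| >= c``).

Reported signs follow the AFT location convention: positive = longer
survival.  On the hazard scale the signs are opposite.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import pipeline as _pipeline
from .models import FittedModel
from .pls import PLSDecomposition

__all__ = ["select_factors", "stability_check"]


def _selection_statistic(decomp: PLSDecomposition, model: FittedModel, statistic: str):
    if statistic == "backproj":
        if model.covariate_coefs is None:
            raise ValueError(
                "model carries no back-projected coefficients; fit with decomp= "
                "or use statistic='loading'"
            )
        return np.asarray(model.covariate_coefs, dtype=float)
    if statistic == "loading":
        return decomp.weights[:, 0].copy()
    raise ValueError("statistic must be 'backproj' or 'loading'")


def select_factors(
    decomp: PLSDecomposition,
    model: FittedModel,
    threshold_rule=("relative", 0.5),
    *,
    statistic: str = "backproj",
) -> pd.DataFrame:
    """Rank covariates by a loading-weights selection statistic.

    Parameters
    ----------
    threshold_rule
        ``("relative", c)`` selects covariates with ``|stat| >= c * max|stat|``;
        ``("absolute", c)`` uses the raw cutoff ``|stat| >= c``.
    statistic
        ``"backproj"`` (absolute back-projected coefficient, default) or
        ``"loading"`` (absolute component-1 loading weight).

    Returns a report ordered by covariate input order with columns
    ``factor, coefficient, statistic, selected, sign``.
    """
    values = _selection_statistic(decomp, model, statistic)
    if len(values) != decomp.n_features:
        raise ValueError("statistic length mismatch with decomposition")
    rule, c = threshold_rule
    mags = np.abs(values)
    if rule == "relative":
        cutoff = c * mags.max() if mags.size else 0.0
    elif rule == "absolute":
        cutoff = c
    else:
        raise ValueError("threshold rule must be 'relative' or 'absolute'")
    selected = mags >= cutoff
    if not selected.any():
        warnings.warn("threshold rule selected no covariates", UserWarning, stacklevel=2)
    coefs = (
        model.covariate_coefs
        if model.covariate_coefs is not None
        else np.full(decomp.n_features, np.nan)
    )
    return pd.DataFrame(
        {
            "factor": decomp.column_names,
            "coefficient": coefs,
            "statistic": mags,
            "selected": selected,
            "sign": np.sign(values).astype(int),
        }
    )


def stability_check(dataset, config, n_splits: int) -> pd.DataFrame:
    """Selection frequency across seeded train/test resplits.

    Reruns the full two-stage pipeline on ``n_splits`` reshuffled training
    splits (seeds derived from ``config.seed``) and reports, per covariate,
    the fraction of splits in which it was selected.
    """
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    counts = np.zeros(dataset.p)
    done = 0
    for k in range(n_splits):
        cfg = _pipeline.replace_seed(config, config.seed + 1000 * (k + 1))
        try:
            result = _pipeline.run_pipeline(dataset, cfg)
        except ValueError:
            continue
        report = result.factor_report
        if report is None:
            continue
        counts += report["selected"].to_numpy(dtype=float)
        done += 1
    if done == 0:
        raise ValueError("no split produced a converged model")
    return pd.DataFrame(
        {"factor": dataset.column_names, "frequency": counts / done}
    )
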