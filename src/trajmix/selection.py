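"""BIC model selection over (G, lambda1) and post-selection unpenalized refits.

The search mirrors the standard workflow: for each candidate cluster number G
fit the mixture along a descending lasso path (warm-started), score every fit
with

    BIC = -2 * loglik + df * log(N),

where loglik is the *unpenalized* observed-data mixture log-likelihood,
df counts the nonzero fixed-effect coefficients over all clusters plus the 2G
variance parameters (d_g, sigma_g^2) and the G - 1 free mixing probabilities,
and N is the total number of observations (a config switch uses subjects
instead).  The minimum-BIC fit wins; ties break toward smaller G, then larger
lambda1 (the more parsimonious model).
"""

from __future__ import annotations

import dataclasses
import json
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .data import INTERCEPT, LongitudinalDataset, StandardizationInfo
from .mixture import (
    ClusterParams,
    FitConfig,
    MixtureModel,
    compute_lambda_max,
    fit_em,
    mixture_loglik,
)

logger = logging.getLogger(__name__)


class IllPosedRefitError(ValueError):
    """A cluster is too small for its selected-variable count."""


def degrees_of_freedom(model: MixtureModel) -> int:
    nnz = sum(int(np.count_nonzero(c.beta)) for c in model.components)
    return nnz + 2 * model.G + (model.G - 1)


def bic(model: MixtureModel, data: LongitudinalDataset, count: str | None = None) -> float:
    """Bayesian information criterion of a fitted mixture on its data."""
    if count is None:
        count = model.config.bic_count if model.config is not None else "observations"
    N = data.n_obs if count == "observations" else data.n_subjects
    ll = mixture_loglik(data, model)
    return float(-2.0 * ll + degrees_of_freedom(model) * np.log(N))


def default_lambda_grid(lam_max: float, n_lambda: int = 7) -> np.ndarray:
    """Log-spaced path from lambda_max down to 0.01*lambda_max, plus 0."""
    if lam_max <= 0:
        return np.array([0.0])
    path = np.geomspace(lam_max, 0.01 * lam_max, n_lambda)
    return np.concatenate([path, [0.0]])


@dataclasses.dataclass
class SearchRecord:
    G: int
    lambda1: float
    bic: float
    loglik: float
    n_nonzero: int
    converged: bool
    model: MixtureModel | None = None
    error: str | None = None


@dataclasses.dataclass
class SearchResult:
    """BIC surface over the (G, lambda1) grid and the selected model."""

    records: list[SearchRecord]
    best: MixtureModel
    best_record: SearchRecord
    standardization: StandardizationInfo | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "G": r.G,
                    "lambda1": r.lambda1,
                    "n_nonzero": r.n_nonzero,
                    "loglik": r.loglik,
                    "bic": r.bic,
                    "converged": r.converged,
                    "error": r.error,
                }
                for r in self.records
            ]
        )

    def save_grid(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    def to_json(self, path_or_buf) -> None:
        payload = {
            "grid": self.to_frame().to_dict(orient="records"),
            "best": self.best.to_dict(),
            "best_G": self.best_record.G,
            "best_lambda1": self.best_record.lambda1,
            "best_bic": self.best_record.bic,
        }
        if hasattr(path_or_buf, "write"):
            json.dump(payload, path_or_buf)
        else:
            with open(path_or_buf, "w") as fh:
                json.dump(payload, fh)


def model_search(
    data: LongitudinalDataset,
    G_grid,
    lambda_grid=None,
    config: FitConfig | None = None,
    n_lambda: int = 7,
    standardization: StandardizationInfo | None = None,
) -> SearchResult:
    """Exhaustive BIC grid search over cluster number and penalty strength.

    When ``lambda_grid`` is None each G gets its own default path from its
    computed lambda_max.  Fits along each path are warm-started at the
    previous (larger) lambda's solution.  Individual fit failures are recorded
    and skipped; the search fails only if every fit fails.
    """
    config = config or FitConfig()
    G_grid = sorted(set(int(g) for g in G_grid))
    if not G_grid:
        raise ValueError("G_grid must be nonempty")
    records: list[SearchRecord] = []
    for G in G_grid:
        if lambda_grid is None:
            lam_max = compute_lambda_max(data, G, config)
            lams = default_lambda_grid(lam_max, n_lambda)
        else:
            lams = np.sort(np.asarray(list(lambda_grid), dtype=float))[::-1]
        warm: list[ClusterParams] | None = None
        for lam in lams:
            try:
                model = fit_em(data, G, float(lam), config, init_params=warm)
                warm = model.components
                rec = SearchRecord(
                    G=G,
                    lambda1=float(lam),
                    bic=bic(model, data),
                    loglik=mixture_loglik(data, model),
                    n_nonzero=sum(int(np.count_nonzero(c.beta)) for c in model.components),
                    converged=model.converged,
                    model=model,
                )
            except Exception as exc:  # noqa: BLE001 - record and continue
                logger.warning("fit failed at (G=%d, lambda1=%.4g): %s", G, lam, exc)
                rec = SearchRecord(
                    G=G,
                    lambda1=float(lam),
                    bic=np.inf,
                    loglik=-np.inf,
                    n_nonzero=0,
                    converged=False,
                    error=str(exc),
                )
            records.append(rec)
            logger.info(
                "G=%d lambda1=%.4g iter=%s BIC=%.2f",
                G,
                lam,
                rec.model.n_iter if rec.model else "-",
                rec.bic,
            )
    ok = [r for r in records if r.model is not None]
    if not ok:
        raise RuntimeError("every fit in the grid search failed")
    best = min(ok, key=lambda r: (r.bic, r.G, -r.lambda1))
    return SearchResult(
        records=records, best=best.model, best_record=best, standardization=standardization
    )


# ------------------------------------------------------------------- refits
@dataclasses.dataclass
class ClusterRefit:
    """Unpenalized ML random-intercept LMM refit of one cluster."""

    cluster: int
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    pvalues: np.ndarray
    d: float
    sigma2: float
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.names,
                "coef": self.beta,
                "se": self.se,
                "z": self.z,
                "p": self.pvalues,
            }
        )


def refit_unpenalized(
    data: LongitudinalDataset,
    labels: np.ndarray,
    selected: list[list[str]],
    config: FitConfig | None = None,
) -> list[ClusterRefit]:
    """Per-cluster ML LMM on the selected variables, with Wald z statistics.

    Standard errors come from the inverse observed information of the fixed
    effects at the fitted variance parameters, Var(beta) = sigma^2 A^{-1}
    with A the GLS Gram matrix; p-values are two-sided normal.  Descriptive:
    they ignore the selection step.
    """
    labels = np.asarray(labels, dtype=int)
    G = len(selected)
    base = dataclasses.replace(
        config or FitConfig(), n_starts=1, tol=1e-10, max_iter=2000
    )
    out: list[ClusterRefit] = []
    for g in range(G):
        idx = np.where(labels == g)[0]
        if len(idx) == 0:
            raise ValueError(f"cluster {g} is empty")
        cols = [c for c in selected[g] if c != INTERCEPT]
        if len(idx) < len(cols) + 3:
            raise IllPosedRefitError(
                f"cluster {g}: {len(idx)} subjects for {len(cols)} selected variables"
            )
        sub = data.subset(idx).select_columns(cols)
        model = fit_em(sub, 1, 0.0, base)
        comp = model.components[0]
        from .mixture import _beta_gram  # GLS Gram at the fitted d

        A, _ = _beta_gram(sub, np.ones(sub.n_subjects), comp.d)
        cov = comp.sigma2 * np.linalg.inv(A)
        se = np.sqrt(np.diag(cov))
        z = comp.beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        out.append(
            ClusterRefit(
                cluster=g,
                names=list(sub.covariate_names),
                beta=comp.beta,
                se=se,
                z=z,
                pvalues=p,
                d=comp.d,
                sigma2=comp.sigma2,
                n_subjects=len(idx),
            )
        )
    return out
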