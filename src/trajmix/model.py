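"""Model / Results API over the mixture machinery.

``MixtureLMM`` holds the data and tuning choices; ``fit()`` runs the
multi-start alternating EM and returns a ``MixtureLMMResults`` carrying the
estimates, responsibilities, diagnostics, a text ``summary()`` and the
reporting surfaces (selection table, cluster summary, trajectory plot).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import report
from .data import (
    LongitudinalDataset,
    StandardizationInfo,
    read_long_table,
    standardize_covariates,
)
from .mixture import (
    ClusterParams,
    FitConfig,
    MixtureModel,
    assign_hard_labels,
    fit_em,
    mixture_loglik,
    penalized_mask_for,
    penalized_objective,
)


class MixtureLMM:
    """Mixture of random-intercept LMMs with a lasso on the fixed effects.

    Parameters
    ----------
    data : LongitudinalDataset
        Stacked longitudinal data (use ``from_dataframe`` to build it from a
        long-format table, with covariates standardized by default).
    G : int
        Number of mixture components.
    lambda1 : float
        Lasso penalty on the non-exempt fixed effects.
    config : FitConfig, optional
        EM tuning knobs (starts, seeds, tolerances).

    Examples
    --------
    >>> from trajmix import simulate, MixtureLMM
    >>> cohort, truth = simulate.simulate_cohort(simulate.default_taag_spec(), seed=0)
    >>> res = MixtureLMM.from_dataset(cohort, G=3, lambda1=5.0).fit()
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        data: LongitudinalDataset,
        G: int,
        lambda1: float = 0.0,
        config: FitConfig | None = None,
        standardization: StandardizationInfo | None = None,
    ):
        self.data = data
        self.G = int(G)
        self.lambda1 = float(lambda1)
        self.config = config or FitConfig()
        self.standardization = standardization

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        schema: Mapping,
        G: int,
        lambda1: float = 0.0,
        config: FitConfig | None = None,
        standardize: bool = True,
        exempt: Sequence[str] = (),
    ) -> "MixtureLMM":
        data = read_long_table(df, schema)
        info = None
        if standardize:
            data, info = standardize_covariates(data, exempt=exempt)
        return cls(data, G, lambda1, config, standardization=info)

    @classmethod
    def from_dataset(
        cls,
        data: LongitudinalDataset,
        G: int,
        lambda1: float = 0.0,
        config: FitConfig | None = None,
        standardize: bool = True,
        exempt: Sequence[str] = (),
    ) -> "MixtureLMM":
        info = None
        if standardize:
            data, info = standardize_covariates(data, exempt=exempt)
        return cls(data, G, lambda1, config, standardization=info)

    def fit(self, init_params: Sequence[ClusterParams] | None = None) -> "MixtureLMMResults":
        mixture = fit_em(self.data, self.G, self.lambda1, self.config, init_params)
        return MixtureLMMResults(self, mixture)

    def select(
        self,
        G_grid: Sequence[int] | None = None,
        lambda_grid: Sequence[float] | None = None,
        n_lambda: int = 7,
    ) -> "MixtureLMMResults":
        """BIC grid search over (G, lambda1); returns results for the winner.

        ``G_grid`` defaults to the model's own G.  The full grid is kept on
        the returned results as ``.search``.
        """
        from .selection import model_search

        result = model_search(
            self.data,
            G_grid if G_grid is not None else [self.G],
            lambda_grid,
            self.config,
            n_lambda=n_lambda,
            standardization=self.standardization,
        )
        res = MixtureLMMResults(self, result.best)
        res.search = result
        return res


class MixtureLMMResults:
    """Estimates, uncertainties proxies and diagnostics of a fitted mixture."""

    def __init__(self, model: MixtureLMM, mixture: MixtureModel):
        self.model = model
        self.mixture = mixture
        self.search = None  # populated by MixtureLMM.select

    # ------------------------------------------------------------ estimates
    @property
    def params(self) -> list[ClusterParams]:
        return self.mixture.components

    @property
    def mixing(self) -> np.ndarray:
        return self.mixture.pi

    @property
    def responsibilities(self) -> np.ndarray:
        return self.mixture.W

    @property
    def labels(self) -> np.ndarray:
        return assign_hard_labels(self.mixture.W)

    @property
    def converged(self) -> bool:
        return self.mixture.converged

    @property
    def n_iter(self) -> int:
        return self.mixture.n_iter

    @property
    def loglik(self) -> float:
        """Unpenalized observed-data mixture log-likelihood."""
        return mixture_loglik(self.model.data, self.mixture)

    @property
    def penalized_loglik(self) -> float:
        return penalized_objective(
            self.model.data,
            self.mixture.components,
            self.mixture.lambda1,
            self.mixture.lambda2,
            self.mixture.penalized_mask
            if self.mixture.penalized_mask is not None
            else penalized_mask_for(self.model.data, self.model.config),
        )

    @property
    def bic(self) -> float:
        from .selection import bic as _bic

        return _bic(self.mixture, self.model.data)

    # ------------------------------------------------------------ reporting
    def cluster_names(self, slope_threshold: float = 5.0) -> list[str]:
        return report.name_clusters(self.mixture, slope_threshold)

    def selection_table(self) -> pd.DataFrame:
        return report.selection_table(
            self.mixture, self.model.data.covariate_names, self.model.standardization
        )

    def cluster_summary(self) -> report.ClusterSummary:
        return report.summarize_clusters(self.model.data, self.labels, self.mixture)

    def plot_trajectories(self, path=None):
        return report.plot_mean_trajectories(
            self.model.data, self.labels, path, cluster_names=self.cluster_names()
        )

    def summary(self) -> str:
        data = self.model.data
        names = self.cluster_names()
        lines = [
            "Mixture of penalized linear mixed-effects models",
            "=" * 52,
            f"subjects: {data.n_subjects}   observations: {data.n_obs}   "
            f"candidates: {data.n_covariates - 1}",
            f"G = {self.mixture.G}   lambda1 = {self.mixture.lambda1:.4g}   "
            f"converged: {self.converged} ({self.n_iter} iterations)",
            f"loglik = {self.loglik:.3f}   BIC = {self.bic:.3f}",
            "",
            "Components",
            "-" * 52,
        ]
        sizes = np.bincount(self.labels, minlength=self.mixture.G)
        for g, c in enumerate(self.mixture.components):
            nnz = int(np.count_nonzero(c.beta)) - 1  # excluding intercept
            lines.append(
                f"[{g}] {names[g]:<12} n={sizes[g]:<4} pi={c.pi:.3f}  "
                f"intercept={c.beta[0]:8.3f}  wave={c.beta[1]:8.3f}  "
                f"sigma={np.sqrt(c.sigma2):6.3f}  d={c.d:6.3f}  nonzero={nnz}"
            )
        lines += ["", "Selected coefficients (original covariate scale)", "-" * 52]
        with pd.option_context("display.float_format", "{:0.3f}".format):
            lines.append(self.selection_table().fillna("").to_string())
        return "\n".join(lines)
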