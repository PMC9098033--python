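"""Finite mixture of lasso-penalized random-intercept linear mixed models.

Model.  Subject i with n_i stacked records belongs to latent cluster g with
probability pi_g.  Within cluster g,

    y_i = X_i beta_g + Z_i b_i + eps_i,     b_i ~ N(0, sigma_g^2 D_g),
    eps_i ~ N(0, sigma_g^2 I),

so marginally y_i ~ N(X_i beta_g, sigma_g^2 (Z_i D_g Z_i' + I)).  The default
random effect is a subject intercept (Z_i = 1, D_g = d_g a scalar), which
makes the within-subject covariance exchangeable: sigma^2 (d J + I).

Fitting alternates an exact E-step (posterior responsibilities and mixing
weights) with a penalized M-step per cluster: coordinate descent with
soft-thresholding on beta_g under the whitened weighted least-squares
objective, then a profile update of (d_g, sigma_g^2) by bounded 1-D search
(sigma^2 has a closed form given d).  The maximized objective is the
penalized observed-data log-likelihood

    sum_i log sum_g pi_g phi_g(y_i)  -  lambda1 * sum_g sum_{j penalized} |beta_gj|,

which every block update is guarded never to decrease, so the EM trace is
monotone up to floating-point noise.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import logging
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from .data import INTERCEPT, LongitudinalDataset

logger = logging.getLogger(__name__)

LOG2PI = float(np.log(2.0 * np.pi))


class ParameterError(ValueError):
    """Invalid model parameters (non-PSD D, bad G, ...)."""


class NumericalError(FloatingPointError):
    """A linear-algebra step failed for the given parameters."""


class EmptyClusterError(RuntimeError):
    """A cluster's effective size fell below the identifiability floor."""


@dataclasses.dataclass
class FitConfig:
    """Tuning knobs of the alternating EM fit.

    n_starts : number of initializations (1 k-means start + the rest random).
    seed : seeds k-means and the random starts.
    tol : stop when the relative objective improvement drops below this.
    cd_tol / cd_max_sweeps : inner coordinate-descent stopping rule.
    d_max : upper bound of the relative random-intercept variance search.
    min_cluster_frac : empty-cluster floor is max(2, frac * n) effective subjects.
    unpenalized : design columns exempt from the lasso (intercept always is).
    lambda2 : optional penalty on the random-intercept variance d_g (off by default).
    scale_penalty_by_size : multiply lambda1 by the cluster's effective size.
    bic_count : "observations" (default) or "subjects" — the N in df*log(N).
    """

    n_starts: int = 3
    seed: int = 0
    max_iter: int = 500
    tol: float = 1e-6
    cd_tol: float = 1e-8
    cd_max_sweeps: int = 1000
    d_max: float = 1e3
    d_xatol: float = 1e-8
    sigma2_floor: float = 1e-8
    min_cluster_frac: float = 0.005
    max_restarts: int = 3
    unpenalized: tuple[str, ...] = (INTERCEPT,)
    lambda2: float = 0.0
    scale_penalty_by_size: bool = False
    bic_count: str = "observations"


@dataclasses.dataclass
class ClusterParams:
    """One mixture component: Theta_g = (beta_g, d_g, sigma_g^2) plus pi_g."""

    beta: np.ndarray
    d: float
    sigma2: float
    pi: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.sigma2 <= 0:
            raise ParameterError("sigma2 must be positive")
        if self.d < 0:
            raise ParameterError("relative random-intercept variance d must be >= 0")

    @property
    def D(self) -> np.ndarray:
        return np.array([[self.d]])

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "d": float(self.d),
            "sigma2": float(self.sigma2),
            "pi": float(self.pi),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ClusterParams":
        return cls(
            beta=np.asarray(payload["beta"], dtype=float),
            d=float(payload["d"]),
            sigma2=float(payload["sigma2"]),
            pi=float(payload["pi"]),
        )


@dataclasses.dataclass
class MixtureModel:
    """A fitted (or constructed) mixture with diagnostics."""

    G: int
    components: list[ClusterParams]
    W: np.ndarray | None = None
    lambda1: float = 0.0
    lambda2: float = 0.0
    loglik_trace: list[float] = dataclasses.field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    penalized_mask: np.ndarray | None = None
    all_traces: list[list[float]] = dataclasses.field(default_factory=list)
    kkt_max: float | None = None
    warning: str | None = None
    config: FitConfig | None = None

    @property
    def pi(self) -> np.ndarray:
        return np.array([c.pi for c in self.components])

    def to_dict(self) -> dict:
        return {
            "G": self.G,
            "components": [c.to_dict() for c in self.components],
            "W": None if self.W is None else self.W.tolist(),
            "lambda1": float(self.lambda1),
            "lambda2": float(self.lambda2),
            "loglik_trace": [float(v) for v in self.loglik_trace],
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "penalized_mask": None
            if self.penalized_mask is None
            else self.penalized_mask.astype(bool).tolist(),
            "warning": self.warning,
            "config": None if self.config is None else dataclasses.asdict(self.config),
        }

    def to_json(self, path_or_buf) -> None:
        if hasattr(path_or_buf, "write"):
            json.dump(self.to_dict(), path_or_buf)
        else:
            with open(path_or_buf, "w") as fh:
                json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, payload: dict) -> "MixtureModel":
        cfg = payload.get("config")
        if cfg is not None:
            cfg = FitConfig(**{**cfg, "unpenalized": tuple(cfg["unpenalized"])})
        return cls(
            G=int(payload["G"]),
            components=[ClusterParams.from_dict(c) for c in payload["components"]],
            W=None if payload.get("W") is None else np.asarray(payload["W"], dtype=float),
            lambda1=float(payload.get("lambda1", 0.0)),
            lambda2=float(payload.get("lambda2", 0.0)),
            loglik_trace=list(payload.get("loglik_trace", [])),
            converged=bool(payload.get("converged", False)),
            n_iter=int(payload.get("n_iter", 0)),
            penalized_mask=None
            if payload.get("penalized_mask") is None
            else np.asarray(payload["penalized_mask"], dtype=bool),
            warning=payload.get("warning"),
            config=cfg,
        )

    @classmethod
    def from_json(cls, path_or_buf) -> "MixtureModel":
        if hasattr(path_or_buf, "read"):
            payload = json.load(path_or_buf)
        else:
            with open(path_or_buf) as fh:
                payload = json.load(fh)
        return cls.from_dict(payload)


# ----------------------------------------------------------------- densities
def marginal_covariance(Z_i: np.ndarray, D_g, sigma2_g: float) -> np.ndarray:
    """Within-subject marginal covariance sigma^2 (Z D Z' + I)."""
    Z_i = np.atleast_2d(np.asarray(Z_i, dtype=float))
    D = np.atleast_2d(np.asarray(D_g, dtype=float))
    if sigma2_g <= 0:
        raise ParameterError("sigma2 must be positive")
    if not np.allclose(D, D.T):
        raise ParameterError("D must be symmetric")
    if np.min(np.linalg.eigvalsh(D)) < -1e-10:
        raise ParameterError("D must be positive semidefinite")
    n_i = Z_i.shape[0]
    return sigma2_g * (Z_i @ D @ Z_i.T + np.eye(n_i))


def subject_loglik(
    y_i: np.ndarray, X_i: np.ndarray, Z_i: np.ndarray, theta: ClusterParams
) -> float:
    """Exact multivariate-normal log-density of one subject under one cluster."""
    y_i = np.asarray(y_i, dtype=float).ravel()
    V = marginal_covariance(Z_i, theta.D, theta.sigma2)
    r = y_i - np.asarray(X_i, dtype=float) @ theta.beta
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalError(
            f"singular marginal covariance (d={theta.d}, sigma2={theta.sigma2})"
        ) from exc
    u = np.linalg.solve(L, r)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return float(-0.5 * (len(y_i) * LOG2PI + logdet + u @ u))


def _component_logliks(data: LongitudinalDataset, components: Sequence[ClusterParams]) -> np.ndarray:
    """n x G matrix of per-subject log-densities, exploiting the exchangeable
    sigma^2 (d J + I) covariance of the random-intercept model."""
    n_i = data.n_i
    seg = data.starts[:-1]
    out = np.empty((data.n_subjects, len(components)))
    for g, c in enumerate(components):
        R = data.y - data.X @ c.beta
        s1 = np.add.reduceat(R, seg)
        s2 = np.add.reduceat(R * R, seg)
        a = c.d / (1.0 + n_i * c.d)
        quad = (s2 - a * s1 * s1) / c.sigma2
        out[:, g] = -0.5 * (
            n_i * (LOG2PI + np.log(c.sigma2)) + np.log1p(n_i * c.d) + quad
        )
    return out


def mixture_loglik(data: LongitudinalDataset, model: MixtureModel) -> float:
    """Observed-data log-likelihood sum_i log sum_g pi_g phi_g(y_i) (log-sum-exp)."""
    L = _component_logliks(data, model.components)
    with np.errstate(divide="ignore"):
        logpi = np.log(model.pi)
    return float(np.sum(logsumexp(L + logpi, axis=1)))


def penalized_objective(
    data: LongitudinalDataset,
    components: Sequence[ClusterParams],
    lambda1: float,
    lambda2: float,
    penalized_mask: np.ndarray,
) -> float:
    """Penalized observed-data objective maximized by the EM driver."""
    model = MixtureModel(G=len(components), components=list(components))
    ll = mixture_loglik(data, model)
    l1 = sum(float(np.sum(np.abs(c.beta[penalized_mask]))) for c in components)
    pen = lambda1 * l1 if l1 > 0 else 0.0  # inf * 0 := 0 at the all-zero point
    pen += lambda2 * sum(c.d for c in components)
    return ll - pen


def e_step(data: LongitudinalDataset, model: MixtureModel) -> tuple[np.ndarray, np.ndarray]:
    """Posterior responsibilities and updated mixing probabilities.

    w_ig = pi_g phi_g(y_i) / sum_l pi_l phi_l(y_i), computed in log space;
    pi_g = mean_i w_ig.  A component with pi_g = 0 receives zero
    responsibility everywhere.
    """
    L = _component_logliks(data, model.components)
    with np.errstate(divide="ignore"):
        lp = L + np.log(model.pi)
    norm = logsumexp(lp, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        W = np.exp(lp - norm)
    W[~np.isfinite(W)] = 0.0
    pi = W.sum(axis=0) / data.n_subjects
    return W, pi


# ------------------------------------------------------------------- M-step
def soft_threshold(z, lam):
    """Lasso shrinkage operator sign(z) * max(|z| - lam, 0)."""
    if lam < 0:
        raise ParameterError("threshold must be nonnegative")
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


def penalized_mask_for(data: LongitudinalDataset, config: FitConfig) -> np.ndarray:
    exempt = set(config.unpenalized) | {INTERCEPT}
    return np.array([name not in exempt for name in data.covariate_names])


def _default_warm(data: LongitudinalDataset) -> ClusterParams:
    p = data.n_covariates
    return ClusterParams(
        beta=np.zeros(p), d=0.5, sigma2=max(float(np.var(data.y)), 1.0), pi=1.0
    )


def _subject_sums(data: LongitudinalDataset):
    seg = data.starts[:-1]
    S = np.add.reduceat(data.X, seg, axis=0)  # per-subject column sums
    sy = np.add.reduceat(data.y, seg)
    return S, sy


def _beta_gram(data, w, d):
    """Weighted GLS normal-equation pieces A = sum_i w_i X_i' C_i^-1 X_i and
    b = sum_i w_i X_i' C_i^-1 y_i, using C^-1 = I - a J with a = d/(1+n_i d)."""
    n_i = data.n_i
    a = d / (1.0 + n_i * d)
    wr = np.repeat(w, n_i)
    S, sy = _subject_sums(data)
    wa = w * a
    A = (data.X * wr[:, None]).T @ data.X - (S * wa[:, None]).T @ S
    b = data.X.T @ (wr * data.y) - S.T @ (wa * sy)
    return A, b


def _update_cluster(
    data: LongitudinalDataset,
    w: np.ndarray,
    lambda1: float,
    config: FitConfig,
    warm: ClusterParams,
    pen: np.ndarray,
) -> tuple[ClusterParams, float]:
    """Blockwise ascent on one cluster's penalized weighted log-likelihood.

    Returns the updated parameters and the KKT gradient bound
    max_j |d/dbeta_j weighted loglik| / 1 evaluated at the penalized block
    (meaningful for the lambda_max computation when that block is zero).
    """
    n = data.n_subjects
    eff = float(w.sum())
    floor = max(2.0, config.min_cluster_frac * n)
    if eff < floor:
        raise EmptyClusterError(f"effective cluster size {eff:.2f} below floor {floor:.2f}")

    null_mode = np.isinf(lambda1)
    d, sigma2 = warm.d, warm.sigma2
    beta = warm.beta.copy()
    if null_mode:
        beta[pen] = 0.0

    A, b = _beta_gram(data, w, d)
    unpen = ~pen
    # exact solve of the unpenalized block given the penalized coordinates
    rhs = b[unpen] - A[np.ix_(unpen, pen)] @ beta[pen]
    beta[unpen] = np.linalg.solve(A[np.ix_(unpen, unpen)], rhs)
    g = A @ beta
    kkt = float(np.max(np.abs(b[pen] - g[pen])) / sigma2) if pen.any() else 0.0

    if not null_mode:
        lam_eff = lambda1 * (eff if config.scale_penalty_by_size else 1.0)
        thr = lam_eff * sigma2
        diag = np.diag(A)
        for _ in range(config.cd_max_sweeps):
            max_delta = 0.0
            for j in range(len(beta)):
                cj = b[j] - g[j] + diag[j] * beta[j]
                new = soft_threshold(cj, thr) / diag[j] if pen[j] else cj / diag[j]
                delta = new - beta[j]
                if delta != 0.0:
                    beta[j] = new
                    g += A[:, j] * delta
                    max_delta = max(max_delta, abs(delta))
            if max_delta <= config.cd_tol:
                break

    # ---- profile (d, sigma2) update given beta: sigma2 closed form per d
    seg = data.starts[:-1]
    n_i = data.n_i
    R = data.y - data.X @ beta
    s1 = np.add.reduceat(R, seg)
    s2 = np.add.reduceat(R * R, seg)
    wn = float(w @ n_i)

    def profile(dv: float) -> tuple[float, float]:
        a = dv / (1.0 + n_i * dv)
        q = float(w @ (s2 - a * s1 * s1))
        sig = max(q / wn, config.sigma2_floor)
        val = -0.5 * (
            wn * (LOG2PI + np.log(sig)) + float(w @ np.log1p(n_i * dv)) + q / sig
        )
        return val - config.lambda2 * dv, sig

    res = optimize.minimize_scalar(
        lambda dv: -profile(dv)[0],
        bounds=(0.0, config.d_max),
        method="bounded",
        options={"xatol": config.d_xatol},
    )
    candidates = [warm.d, 0.0, float(res.x)]
    vals = [profile(dv) for dv in candidates]
    best = int(np.argmax([v[0] for v in vals]))
    d_new = candidates[best]
    sigma2_new = vals[best][1]

    return ClusterParams(beta=beta, d=d_new, sigma2=sigma2_new, pi=eff / n), kkt


def _m_step_full(
    data: LongitudinalDataset,
    W: np.ndarray,
    lambda1: float,
    config: FitConfig,
    warm: Sequence[ClusterParams] | None,
    pen: np.ndarray,
) -> tuple[list[ClusterParams], float]:
    G = W.shape[1]
    comps: list[ClusterParams] = []
    kkt = 0.0
    for g in range(G):
        warm_g = warm[g] if warm is not None else _default_warm(data)
        c, k = _update_cluster(data, W[:, g], lambda1, config, warm_g, pen)
        comps.append(c)
        kkt = max(kkt, k)
    return comps, kkt


def m_step(
    data: LongitudinalDataset,
    W: np.ndarray,
    lambda1: float,
    config: FitConfig | None = None,
    warm: Sequence[ClusterParams] | None = None,
) -> list[ClusterParams]:
    """Penalized M-step: updated (beta_g, d_g, sigma_g^2, pi_g) for every cluster."""
    config = config or FitConfig()
    pen = penalized_mask_for(data, config)
    comps, _ = _m_step_full(data, W, lambda1, config, warm, pen)
    return comps


# ------------------------------------------------------------ initialization
def _trajectory_features(data: LongitudinalDataset) -> np.ndarray:
    """Per-subject (mean outcome, OLS slope over wave); slope 0 when n_i == 1."""
    feats = np.zeros((data.n_subjects, 2))
    for i in range(data.n_subjects):
        yi = data.y_i(i)
        wi = data.wave[data.subject_slice(i)].astype(float)
        feats[i, 0] = yi.mean()
        if len(yi) > 1 and np.ptp(wi) > 0:
            feats[i, 1] = np.polyfit(wi, yi, 1)[0]
    return feats


def _kmeans_responsibilities(data: LongitudinalDataset, G: int, seed: int) -> np.ndarray:
    from sklearn.cluster import KMeans

    feats = _trajectory_features(data)
    scale = feats.std(axis=0)
    scale[scale == 0] = 1.0
    labels = KMeans(n_clusters=G, n_init=10, random_state=seed).fit_predict(feats / scale)
    W = np.zeros((data.n_subjects, G))
    W[np.arange(data.n_subjects), labels] = 1.0
    return W


def _random_responsibilities(rng: np.random.Generator, n: int, G: int) -> np.ndarray:
    return rng.dirichlet(np.ones(G), size=n)


# ----------------------------------------------------------------- EM driver
@dataclasses.dataclass
class _EMState:
    components: list[ClusterParams]
    objective: float
    trace: list[float]
    converged: bool
    n_iter: int
    kkt_max: float


def _run_em(
    data: LongitudinalDataset,
    lambda1: float,
    config: FitConfig,
    pen: np.ndarray,
    W0: np.ndarray | None = None,
    params0: Sequence[ClusterParams] | None = None,
) -> _EMState:
    if params0 is not None:
        comps = [copy.deepcopy(c) for c in params0]
        kkt_max = 0.0
    else:
        comps, kkt_max = _m_step_full(data, W0, lambda1, config, None, pen)
    obj = penalized_objective(data, comps, lambda1, config.lambda2, pen)
    trace = [obj]
    best = (_copy_components(comps), obj)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        model = MixtureModel(G=len(comps), components=comps)
        W, _ = e_step(data, model)
        comps, kkt = _m_step_full(data, W, lambda1, config, comps, pen)
        kkt_max = max(kkt_max, kkt)
        prev = obj
        obj = penalized_objective(data, comps, lambda1, config.lambda2, pen)
        trace.append(obj)
        if obj > best[1]:
            best = (_copy_components(comps), obj)
        delta = obj - prev
        if delta < 0 or delta <= config.tol * (1.0 + abs(prev)):
            converged = True
            break
    return _EMState(
        components=best[0],
        objective=best[1],
        trace=trace,
        converged=converged,
        n_iter=it,
        kkt_max=kkt_max,
    )


def _copy_components(comps: Sequence[ClusterParams]) -> list[ClusterParams]:
    return [ClusterParams(c.beta.copy(), c.d, c.sigma2, c.pi) for c in comps]


def fit_em(
    data: LongitudinalDataset,
    G: int,
    lambda1: float,
    config: FitConfig | None = None,
    init_params: Sequence[ClusterParams] | None = None,
) -> MixtureModel:
    """Fit a G-component penalized mixture by multi-start alternating EM.

    Initialization: a k-means start on per-subject (mean, slope) trajectory
    features plus ``n_starts - 1`` random-responsibility starts (all seeded);
    ``init_params`` adds one warm start (used along the lambda path).  The run
    with the best final penalized objective wins.  A cluster whose effective
    size falls below the floor triggers a fresh restart up to
    ``config.max_restarts`` times; if it persists the best available model is
    returned with a warning flag.
    """
    config = config or FitConfig()
    if G < 1:
        raise ParameterError("G must be >= 1")
    if G > data.n_subjects:
        raise ParameterError(f"G={G} exceeds the number of subjects ({data.n_subjects})")
    pen = penalized_mask_for(data, config)
    rng = np.random.default_rng(config.seed)

    starts: list[dict] = []
    if G == 1:
        starts.append({"W0": np.ones((data.n_subjects, 1))})
    else:
        starts.append({"W0": _kmeans_responsibilities(data, G, config.seed)})
        for _ in range(max(config.n_starts - 1, 0)):
            starts.append({"W0": _random_responsibilities(rng, data.n_subjects, G)})
    if init_params is not None:
        starts.append({"params0": init_params})

    best: _EMState | None = None
    all_traces: list[list[float]] = []
    kkt_max = 0.0
    warning = None
    for start in starts:
        attempt, state = 0, None
        while state is None:
            try:
                state = _run_em(data, lambda1, config, pen, **start)
            except EmptyClusterError as exc:
                attempt += 1
                if attempt > config.max_restarts:
                    warning = f"persistent empty cluster: {exc}"
                    logger.warning("%s; start abandoned", warning)
                    break
                start = {"W0": _random_responsibilities(rng, data.n_subjects, G)}
        if state is None:
            continue
        all_traces.append(state.trace)
        kkt_max = max(kkt_max, state.kkt_max)
        if best is None or state.objective > best.objective:
            best = state
    if best is None:
        raise EmptyClusterError(
            f"all initializations collapsed a cluster (G={G}, lambda1={lambda1})"
        )

    final = MixtureModel(
        G=G,
        components=best.components,
        lambda1=float(lambda1),
        lambda2=config.lambda2,
        loglik_trace=best.trace,
        converged=best.converged,
        n_iter=best.n_iter,
        penalized_mask=pen,
        all_traces=all_traces,
        kkt_max=kkt_max,
        warning=warning,
        config=config,
    )
    W, _ = e_step(data, final)
    final.W = W
    return final


def compute_lambda_max(
    data: LongitudinalDataset, G: int = 1, config: FitConfig | None = None
) -> float:
    """Smallest penalty at which every penalized coefficient stays exactly zero.

    Runs the EM with the penalized block pinned at zero (lambda1 = inf) and
    records, at every M-step of every start, the per-cluster KKT bound
    max_j |gradient_j| / sigma_g^2 of the weighted GLS objective at the zero
    point.  For the same seeded initialization, any lambda1 >= the returned
    value reproduces that all-zero trajectory exactly, so the endpoint
    property holds for mixtures, not just for a single component.
    """
    model = fit_em(data, G, np.inf, config)
    return float(model.kkt_max)


def assign_hard_labels(W: np.ndarray) -> np.ndarray:
    """Posterior-mode cluster labels; ties go to the lowest cluster index."""
    return np.argmax(np.asarray(W), axis=1)
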