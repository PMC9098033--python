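"""Output surfaces: cluster summaries, selection tables, cross-tabulation,
agreement metrics and trajectory plots."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .data import INTERCEPT, WAVE, LongitudinalDataset, StandardizationInfo
from .mixture import MixtureModel


@dataclasses.dataclass
class ClusterSummary:
    """Per-cluster sizes, proportions and wave-by-wave outcome means/SDs."""

    table: pd.DataFrame
    sizes: np.ndarray
    proportions: np.ndarray


def summarize_clusters(
    data: LongitudinalDataset,
    labels: np.ndarray,
    model: MixtureModel | None = None,
) -> ClusterSummary:
    """Sample mean and SD of the outcome per cluster and wave.

    An empty cluster appears with size 0 and NaN summaries.  When a fitted
    model is supplied its intercept and wave coefficient are appended (on the
    scale the model was fitted on).
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != data.n_subjects:
        raise ValueError("labels must have one entry per subject")
    G = (model.G if model is not None else labels.max() + 1)
    row_labels = np.repeat(labels, data.n_i)
    waves = np.unique(data.wave)
    rows = []
    sizes = np.zeros(G, dtype=int)
    for g in range(G):
        sizes[g] = int(np.sum(labels == g))
        row = {"cluster": g, "size": sizes[g], "proportion": sizes[g] / data.n_subjects}
        for w in waves:
            sel = (row_labels == g) & (data.wave == w)
            vals = data.y[sel]
            row[f"mean_wave{w}"] = float(np.mean(vals)) if len(vals) else np.nan
            row[f"sd_wave{w}"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        if model is not None:
            row["intercept"] = float(model.components[g].beta[0])
            row[WAVE + "_coef"] = float(model.components[g].beta[1])
        rows.append(row)
    table = pd.DataFrame(rows)
    return ClusterSummary(table=table, sizes=sizes, proportions=sizes / data.n_subjects)


def name_clusters(
    model: MixtureModel, slope_threshold: float = 5.0
) -> list[str]:
    """Post-hoc trajectory names by wave-coefficient sign: flat slopes are
    maintainers, clearly negative decreasers, clearly positive increasers."""
    names = []
    counts: dict[str, int] = {}
    for c in model.components:
        slope = float(c.beta[1])
        if slope <= -slope_threshold:
            base = "decreaser"
        elif slope >= slope_threshold:
            base = "increaser"
        else:
            base = "maintainer"
        counts[base] = counts.get(base, 0) + 1
        names.append(base if counts[base] == 1 else f"{base}_{counts[base]}")
    return names


def selection_table(
    model: MixtureModel,
    names: list[str],
    std: StandardizationInfo | None = None,
) -> pd.DataFrame:
    """Per-cluster nonzero coefficients, back-transformed to the original
    covariate scale when standardization info is given.

    Rows: the intercept plus every variable nonzero in at least one cluster;
    zero entries are NaN (rendered blank).
    """
    G = model.G
    betas = np.column_stack([c.beta for c in model.components])
    nz_pattern = betas != 0.0
    if std is not None:
        betas = np.column_stack(
            [std.original_scale_coefs(model.components[g].beta) for g in range(G)]
        )
    keep = [
        j
        for j, name in enumerate(names)
        if name == INTERCEPT or nz_pattern[j].any()
    ]
    out = pd.DataFrame(
        betas[keep],
        index=[names[j] for j in keep],
        columns=[f"cluster_{g}" for g in range(G)],
    )
    # render true zeros blank, but never blank the intercept row
    mask = ~nz_pattern[keep]
    mask[[i for i, j in enumerate(keep) if names[j] == INTERCEPT]] = False
    return out.mask(mask)


def cross_tabulate(labels_a, labels_b) -> pd.DataFrame:
    """Contingency table of two labelings of the same subjects, with margins."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    return pd.crosstab(
        pd.Series(labels_a, name="labels_a"),
        pd.Series(labels_b, name="labels_b"),
        margins=True,
        margins_name="total",
    )


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement in [-1, 1]; 1 iff identical up to
    relabeling."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))


def align_labels(labels, reference) -> np.ndarray:
    """Relabel ``labels`` to maximize overlap with ``reference`` (Hungarian).

    Returns the permuted label vector; counts themselves are alignment-free.
    """
    labels = np.asarray(labels, dtype=int)
    reference = np.asarray(reference, dtype=int)
    k = max(labels.max(), reference.max()) + 1
    cost = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            cost[a, b] = -np.sum((labels == a) & (reference == b))
    _, mapping = linear_sum_assignment(cost)
    return mapping[labels]


def plot_mean_trajectories(
    data: LongitudinalDataset,
    labels: np.ndarray,
    path=None,
    cluster_names: list[str] | None = None,
):
    """Mean outcome per cluster and wave, one line per cluster."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels, dtype=int)
    row_labels = np.repeat(labels, data.n_i)
    waves = np.unique(data.wave)
    fig, ax = plt.subplots(figsize=(6, 4))
    for g in range(labels.max() + 1):
        means = [
            np.mean(data.y[(row_labels == g) & (data.wave == w)])
            if np.any((row_labels == g) & (data.wave == w))
            else np.nan
            for w in waves
        ]
        name = cluster_names[g] if cluster_names else f"cluster {g}"
        ax.plot(waves, means, marker="o", label=f"{name} (n={np.sum(labels == g)})")
    ax.set_xlabel("wave")
    ax.set_ylabel(f"mean {data.outcome_name}")
    ax.set_xticks(waves)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
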