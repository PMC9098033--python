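"""Long-format longitudinal data: containers, CSV IO, and covariate standardization.

The analysis operates on an unbalanced panel — one row per subject-wave with a
continuous outcome (daily MVPA minutes) and a set of numeric / dummy-coded
covariates.  :class:`LongitudinalDataset` stores the table in stacked form
(rows grouped by subject, sorted by wave) together with per-subject row
offsets, so that per-subject outcome vectors ``y_i`` and design matrices
``X_i`` are cheap slices.  The fixed-effects design always carries an
intercept column first and the wave indicator second; the random-effects
design defaults to the all-ones column (a subject random intercept).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INTERCEPT = "intercept"
WAVE = "wave"


class SchemaError(ValueError):
    """A required column role is missing or mis-declared."""


class DataError(ValueError):
    """The table violates a structural invariant (duplicates, bad types...)."""


class DegenerateCovariateError(ValueError):
    """A covariate is constant where variation is required."""


@dataclasses.dataclass
class LongitudinalDataset:
    """Stacked unbalanced longitudinal data with per-subject row offsets.

    Parameters
    ----------
    subject_ids : array of length n
        Unique subject identifiers, in the order subjects appear in the
        stacked arrays.
    y : array of length N
        Outcome, stacked over subjects (minutes/day for the motivating data).
    X : array, N x p
        Fixed-effects design.  Column 0 is the constant 1 (intercept) and
        column 1 the integer wave indicator (0, 1, 2, ...).
    wave : int array of length N
        Wave index per row; strictly increasing within each subject.
    covariate_names : list of p labels
        Names aligned with the columns of ``X``.
    starts : int array of length n + 1
        Row offsets: subject i occupies rows ``starts[i]:starts[i+1]``.
    outcome_name : str
        Label used when writing the table back out.
    """

    subject_ids: np.ndarray
    y: np.ndarray
    X: np.ndarray
    wave: np.ndarray
    covariate_names: list[str]
    starts: np.ndarray
    outcome_name: str = "y"

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.wave = np.asarray(self.wave, dtype=int)
        self.starts = np.asarray(self.starts, dtype=int)
        self.covariate_names = list(self.covariate_names)
        self.validate()

    # ------------------------------------------------------------------ sizes
    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    @property
    def n_i(self) -> np.ndarray:
        """Records per subject."""
        return np.diff(self.starts)

    # ------------------------------------------------------------- accessors
    def subject_slice(self, i: int) -> slice:
        return slice(self.starts[i], self.starts[i + 1])

    def y_i(self, i: int) -> np.ndarray:
        return self.y[self.subject_slice(i)]

    def X_i(self, i: int) -> np.ndarray:
        return self.X[self.subject_slice(i)]

    def Z_i(self, i: int) -> np.ndarray:
        """Random-effects design; the default random intercept (all ones)."""
        n_i = self.starts[i + 1] - self.starts[i]
        return np.ones((n_i, 1))

    def validate(self) -> None:
        n, N = self.n_subjects, self.n_obs
        if self.starts.shape != (n + 1,) or self.starts[0] != 0 or self.starts[-1] != N:
            raise DataError("row offsets do not partition the stacked arrays")
        if np.any(np.diff(self.starts) < 1):
            raise DataError("every subject needs at least one record")
        if self.X.shape != (N, len(self.covariate_names)):
            raise DataError("design shape does not match covariate names")
        if len(self.wave) != N:
            raise DataError("wave vector length mismatch")
        if self.covariate_names[0] != INTERCEPT or not np.allclose(self.X[:, 0], 1.0):
            raise DataError("column 0 of X must be the all-ones intercept")
        for i in range(n):
            w = self.wave[self.subject_slice(i)]
            if np.any(np.diff(w) <= 0):
                raise DataError(
                    f"wave index not strictly increasing for subject {self.subject_ids[i]!r}"
                )
        if len(np.unique(self.subject_ids)) != n:
            raise DataError("subject identifiers are not unique")

    # ------------------------------------------------------------ conversion
    def to_frame(self, subject_col: str = "subject_id") -> pd.DataFrame:
        """Long-format table (one row per subject-wave); intercept column dropped."""
        df = pd.DataFrame({subject_col: np.repeat(self.subject_ids, self.n_i)})
        df[WAVE] = self.wave
        df[self.outcome_name] = self.y
        for j, name in enumerate(self.covariate_names):
            if name in (INTERCEPT, WAVE):
                continue
            df[name] = self.X[:, j]
        return df

    def subset(self, subject_indices: Sequence[int]) -> "LongitudinalDataset":
        """New dataset restricted to the given subject indices (order kept)."""
        idx = np.asarray(subject_indices, dtype=int)
        rows = np.concatenate([np.arange(self.starts[i], self.starts[i + 1]) for i in idx])
        n_i = self.n_i[idx]
        return LongitudinalDataset(
            subject_ids=self.subject_ids[idx],
            y=self.y[rows],
            X=self.X[rows],
            wave=self.wave[rows],
            covariate_names=list(self.covariate_names),
            starts=np.concatenate([[0], np.cumsum(n_i)]),
            outcome_name=self.outcome_name,
        )

    def select_columns(self, names: Sequence[str]) -> "LongitudinalDataset":
        """New dataset keeping only the named design columns (intercept forced first)."""
        keep = [INTERCEPT] + [n for n in names if n != INTERCEPT]
        missing = [n for n in keep if n not in self.covariate_names]
        if missing:
            raise SchemaError(f"unknown design columns: {missing}")
        cols = [self.covariate_names.index(n) for n in keep]
        return LongitudinalDataset(
            subject_ids=self.subject_ids,
            y=self.y,
            X=self.X[:, cols],
            wave=self.wave,
            covariate_names=keep,
            starts=self.starts,
            outcome_name=self.outcome_name,
        )


@dataclasses.dataclass
class StandardizationInfo:
    """Per-covariate centering/scaling actually applied, for exact inversion.

    ``scaled`` flags the columns that were z-scored; exempt columns keep
    ``mean 0, sd 1`` entries so the transform is the identity there.
    """

    names: list[str]
    means: np.ndarray
    sds: np.ndarray
    scaled: np.ndarray  # boolean mask

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xs = np.array(X, dtype=float, copy=True)
        m = self.scaled
        Xs[:, m] = (Xs[:, m] - self.means[m]) / self.sds[m]
        return Xs

    def inverse(self, Xs: np.ndarray) -> np.ndarray:
        X = np.array(Xs, dtype=float, copy=True)
        m = self.scaled
        X[:, m] = X[:, m] * self.sds[m] + self.means[m]
        return X

    def original_scale_coefs(self, beta: np.ndarray) -> np.ndarray:
        """Map coefficients fitted on z-scored covariates back to raw scale.

        For a scaled column j, ``beta_raw[j] = beta[j] / sd[j]``; the
        intercept absorbs ``-sum_j beta[j] * mean[j] / sd[j]``.
        """
        beta = np.asarray(beta, dtype=float)
        out = beta.copy()
        m = self.scaled
        out[m] = beta[m] / self.sds[m]
        i0 = self.names.index(INTERCEPT)
        out[i0] = beta[i0] - np.sum(beta[m] * self.means[m] / self.sds[m])
        return out

    def to_json(self, path_or_buf) -> None:
        payload = {
            "names": self.names,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "scaled": self.scaled.astype(bool).tolist(),
        }
        if hasattr(path_or_buf, "write"):
            json.dump(payload, path_or_buf, indent=2)
        else:
            with open(path_or_buf, "w") as fh:
                json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path_or_buf) -> "StandardizationInfo":
        if hasattr(path_or_buf, "read"):
            payload = json.load(path_or_buf)
        else:
            with open(path_or_buf) as fh:
                payload = json.load(fh)
        return cls(
            names=list(payload["names"]),
            means=np.asarray(payload["means"], dtype=float),
            sds=np.asarray(payload["sds"], dtype=float),
            scaled=np.asarray(payload["scaled"], dtype=bool),
        )


# ---------------------------------------------------------------------- read
def _normalize_schema(schema: Mapping) -> dict:
    out = {
        "subject": schema.get("subject", "subject_id"),
        "wave": schema.get("wave", WAVE),
        "outcome": schema.get("outcome", "y"),
        "categorical": dict(schema.get("categorical", {}) or {}),
        "drop": list(schema.get("drop", []) or []),
    }
    if isinstance(schema.get("categorical"), (list, tuple)):
        out["categorical"] = {c: None for c in schema["categorical"]}
    return out


def read_long_table(
    source: str | IO | pd.DataFrame,
    schema: Mapping,
    check_constant: bool = True,
) -> LongitudinalDataset:
    """Read a long-format CSV (or DataFrame) into a :class:`LongitudinalDataset`.

    ``schema`` maps column roles: ``subject``, ``wave``, ``outcome``, optional
    ``categorical`` (list, or mapping column -> reference level) and ``drop``.
    All remaining columns are treated as numeric covariates.  Rows with any
    missing modeled value are dropped with a logged count.
    """
    sch = _normalize_schema(schema)
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)

    for role in ("subject", "wave", "outcome"):
        if sch[role] not in df.columns:
            raise SchemaError(f"missing required column {sch[role]!r} (role {role!r})")
    df = df.drop(columns=[c for c in sch["drop"] if c in df.columns])

    dup = df.duplicated(subset=[sch["subject"], sch["wave"]])
    if dup.any():
        first = df.loc[dup, [sch["subject"], sch["wave"]]].iloc[0]
        raise DataError(
            f"duplicate (subject, wave) pair: ({first.iloc[0]!r}, {first.iloc[1]!r})"
        )

    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.info("dropped %d rows with missing modeled values", n0 - len(df))
    if df.empty:
        raise DataError("no complete rows left after dropping missing values")

    cov_cols = [c for c in df.columns if c not in (sch["subject"], sch["wave"], sch["outcome"])]
    for col in cov_cols:
        if col in sch["categorical"]:
            continue
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise DataError(f"non-numeric covariate {col!r} not declared categorical")
    if not pd.api.types.is_numeric_dtype(df[sch["outcome"]]):
        raise DataError(f"outcome column {sch['outcome']!r} is not numeric")
    wave_vals = df[sch["wave"]]
    if not pd.api.types.is_numeric_dtype(wave_vals) or not np.allclose(
        wave_vals, np.round(wave_vals)
    ):
        raise DataError("wave column must hold integers")

    # reference-coded dummies, stable (sorted) level order
    for col, ref in sch["categorical"].items():
        if col not in df.columns:
            raise SchemaError(f"declared categorical column {col!r} not in table")
        levels = sorted(df[col].astype(str).unique())
        if ref is None:
            ref = levels[0]
        elif str(ref) not in levels:
            raise SchemaError(f"reference level {ref!r} absent from column {col!r}")
        for lev in levels:
            if lev == str(ref):
                continue
            df[f"{col}_{lev}"] = (df[col].astype(str) == lev).astype(float)
        df = df.drop(columns=[col])
    cov_cols = [c for c in df.columns if c not in (sch["subject"], sch["wave"], sch["outcome"])]

    df = df.sort_values([sch["subject"], sch["wave"]], kind="mergesort").reset_index(drop=True)
    subjects, inv = np.unique(df[sch["subject"]].to_numpy(), return_inverse=True)
    # rows are sorted by subject then wave, so inv is non-decreasing
    starts = np.concatenate([[0], np.cumsum(np.bincount(inv))])

    wave = df[sch["wave"]].to_numpy(dtype=int)
    y = df[sch["outcome"]].to_numpy(dtype=float)
    covs = df[cov_cols].to_numpy(dtype=float)
    if check_constant:
        for k, col in enumerate(cov_cols):
            if np.ptp(covs[:, k]) == 0:
                raise DegenerateCovariateError(
                    f"covariate {col!r} is constant across all rows"
                )
    X = np.column_stack([np.ones(len(df)), wave.astype(float), covs])
    names = [INTERCEPT, WAVE] + cov_cols
    return LongitudinalDataset(
        subject_ids=subjects,
        y=y,
        X=X,
        wave=wave,
        covariate_names=names,
        starts=starts,
        outcome_name=sch["outcome"],
    )


def write_long_table(data: LongitudinalDataset, path_or_buf, subject_col: str = "subject_id") -> None:
    """Write the dataset back to long-format CSV (round-trips with read_long_table)."""
    data.to_frame(subject_col=subject_col).to_csv(path_or_buf, index=False)


# -------------------------------------------------------------- standardize
def standardize_covariates(
    data: LongitudinalDataset,
    exempt: Iterable[str] = (),
) -> tuple[LongitudinalDataset, StandardizationInfo]:
    """Z-score design columns over all pooled rows.

    The intercept is always exempt and the outcome is never touched: the
    coefficients then stay in outcome units per covariate standard deviation
    and are back-transformable via :meth:`StandardizationInfo.original_scale_coefs`.
    The wave indicator is standardized like any other candidate covariate
    unless listed in ``exempt``.
    """
    exempt = set(exempt) | {INTERCEPT}
    p = data.n_covariates
    means = np.zeros(p)
    sds = np.ones(p)
    scaled = np.zeros(p, dtype=bool)
    for j, name in enumerate(data.covariate_names):
        if name in exempt:
            continue
        col = data.X[:, j]
        sd = float(np.std(col))
        if sd <= 0.0:
            raise DegenerateCovariateError(
                f"cannot standardize constant covariate {name!r}"
            )
        means[j] = float(np.mean(col))
        sds[j] = sd
        scaled[j] = True
    info = StandardizationInfo(
        names=list(data.covariate_names), means=means, sds=sds, scaled=scaled
    )
    out = LongitudinalDataset(
        subject_ids=data.subject_ids,
        y=data.y,
        X=info.transform(data.X),
        wave=data.wave,
        covariate_names=list(data.covariate_names),
        starts=data.starts,
        outcome_name=data.outcome_name,
    )
    return out, info
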