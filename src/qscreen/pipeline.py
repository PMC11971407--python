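"""Feature selection and kernel-input preparation.

Standardize the merged feature table with training-set statistics, rank
features by random-forest impurity importance, keep those at or above the
80th percentile, multiply each surviving column by its importance, order
columns by importance, scale by 10 so angles sit near magnitude 1, and
derive softmax measurement weights for the kernel.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

META_COLUMNS = ("label", "split")


def feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in META_COLUMNS]


@dataclass
class StandardizationParams:
    mean: pd.Series
    std: pd.Series
    median: pd.Series  # train medians used for imputation
    dropped: list[str] = field(default_factory=list)

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        cols = list(self.mean.index)
        out = df[cols].copy()
        out = out.fillna(self.median)
        out = (out - self.mean) / self.std
        for c in META_COLUMNS:
            if c in df.columns:
                out[c] = df[c]
        return out


def standardize(df: pd.DataFrame) -> tuple[pd.DataFrame, StandardizationParams]:
    """Z-score all rows using training-row means and population stds.

    Missing values are imputed with the training median first (logged);
    all-missing or constant columns are dropped with a warning.
    """
    cols = feature_columns(df)
    train = df.loc[df["split"] == "train", cols]
    keep, dropped = [], []
    for c in cols:
        col = train[c]
        if col.isna().all() or float(col.std(ddof=0)) == 0.0 \
                or not np.isfinite(col.std(ddof=0)):
            dropped.append(c)
        else:
            keep.append(c)
    if dropped:
        warnings.warn(f"dropping degenerate columns: {dropped}", stacklevel=2)
    median = train[keep].median()
    n_imputed = int(df[keep].isna().sum().sum())
    if n_imputed:
        logger.info("standardize: imputing %d missing values with train "
                    "medians", n_imputed)
    filled = train[keep].fillna(median)
    mean = filled.mean()
    std = filled.std(ddof=0)
    params = StandardizationParams(mean, std, median, dropped)
    return params.apply(df), params


@dataclass
class ImportanceProfile:
    """Normalized forest importances with the percentile selection mask."""

    importances: pd.Series
    percentile_cut: float = 80.0
    selected: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        total = float(self.importances.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("importances must sum to 1")
        if (self.importances < 0).any():
            raise ValueError("importances must be non-negative")
        if self.selected is None:
            self.selected = select_top_percentile(self.importances,
                                                  self.percentile_cut)


def rf_importances(df: pd.DataFrame, n_trees: int = 500,
                   seed: int = 0, percentile_cut: float = 80.0
                   ) -> ImportanceProfile:
    """Impurity-based importances of a forest fit on training rows only."""
    from sklearn.ensemble import RandomForestClassifier

    cols = feature_columns(df)
    train = df[df["split"] == "train"]
    y = train["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training rows contain a single class")
    X = train[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("standardize before computing importances")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X, y)
    imp = forest.feature_importances_
    imp = imp / imp.sum()
    return ImportanceProfile(pd.Series(imp, index=cols), percentile_cut)


def select_top_percentile(importances: pd.Series, q: float = 80.0
                          ) -> pd.Series:
    """Mask of features at or above the q-th percentile of importance.

    Linear-interpolation percentile with inclusive (>=) comparison, so a
    fully tied importance vector keeps every feature.
    """
    if len(importances) < 5:
        raise ValueError("need at least 5 features to select from")
    threshold = float(np.percentile(importances.to_numpy(), q))
    mask = importances >= threshold
    logger.info("select_top_percentile: kept %d of %d features (q=%g)",
                int(mask.sum()), len(mask), q)
    return mask


@dataclass
class KernelSpec:
    """Everything that determines the Gram matrix for a fitted pipeline.

    Columns are ordered by importance (descending, ties broken by name);
    each standardized column is multiplied by ``importance * scale``; the
    measurement weights are the softmax of the selected features' raw
    importances.
    """

    selected_feature_names: list[str]
    column_scalers: np.ndarray
    softmax_weights: np.ndarray
    standardization: StandardizationParams
    scale: float = 10.0

    def __post_init__(self) -> None:
        self.column_scalers = np.asarray(self.column_scalers, dtype=float)
        self.softmax_weights = np.asarray(self.softmax_weights, dtype=float)
        if not np.all(self.softmax_weights > 0):
            raise ValueError("softmax weights must be positive")
        if abs(self.softmax_weights.sum() - 1.0) > 1e-9:
            raise ValueError("softmax weights must sum to 1")

    @property
    def n_qubits(self) -> int:
        return len(self.selected_feature_names)

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        """Standardized -> importance-scaled matrix in kernel column order.

        Accepts either an already-standardized table or a raw one (the
        stored standardization parameters are idempotently applied to raw
        input by the caller; here the columns are selected, scaled and
        ordered)."""
        missing = [c for c in self.selected_feature_names
                   if c not in df.columns]
        if missing:
            raise ValueError(f"table lacks kernel columns: {missing}")
        X = df[self.selected_feature_names].to_numpy(dtype=float)
        return X * self.column_scalers

    def angle_wraparound_fraction(self, X: np.ndarray) -> float:
        """Fraction of encoded angles outside [-pi, pi] (data-quality check)."""
        return float(np.mean(np.abs(X) > np.pi))

    def to_dict(self) -> dict:
        return {
            "selected_feature_names": self.selected_feature_names,
            "column_scalers": self.column_scalers.tolist(),
            "softmax_weights": self.softmax_weights.tolist(),
            "scale": self.scale,
            "standardization": {
                "mean": self.standardization.mean.to_dict(),
                "std": self.standardization.std.to_dict(),
                "median": self.standardization.median.to_dict(),
                "dropped": self.standardization.dropped,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        st = d["standardization"]
        params = StandardizationParams(
            pd.Series(st["mean"]), pd.Series(st["std"]),
            pd.Series(st["median"]), list(st["dropped"]))
        return cls(list(d["selected_feature_names"]),
                   np.array(d["column_scalers"]),
                   np.array(d["softmax_weights"]), params,
                   scale=float(d["scale"]))


def softmax(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    e = np.exp(x - x.max())
    return e / e.sum()


def build_kernel_spec(std_df: pd.DataFrame, profile: ImportanceProfile,
                      params: StandardizationParams, scale: float = 10.0
                      ) -> tuple[KernelSpec, np.ndarray]:
    """Assemble the KernelSpec and the transformed matrix for all rows."""
    sel = profile.selected[profile.selected].index.tolist()
    if not sel:
        raise ValueError("empty feature selection")
    imp = profile.importances[sel]
    order = sorted(sel, key=lambda c: (-imp[c], c))
    importances_ordered = imp[order].to_numpy()
    spec = KernelSpec(
        selected_feature_names=order,
        column_scalers=importances_ordered * scale,
        softmax_weights=softmax(importances_ordered),
        standardization=params,
        scale=scale,
    )
    X = spec.transform(std_df)
    frac = spec.angle_wraparound_fraction(X)
    if frac > 0:
        logger.warning("%.1f%% of encoded angles exceed |pi| (wrap-around)",
                       100 * frac)
    return spec, X
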