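"""Data processing: holdout carving, SMOTE, normalization, feature selection.

The default stage order mirrors the study protocol: blinded holdout first,
then SMOTE on the remaining pool, z-score normalization (parameters saved),
the five-rule feature selection, and finally a stratified 70/30
train/validation split.  Applying SMOTE and fitting the normalizer before
the split leaks information between training and validation folds; the
``sound_practice`` order (holdout -> split -> SMOTE on train only ->
normalize fit on train -> select fit on train) is available wherever the
pipeline is invoked, and run reports record which order ran.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor

from .audio_io import AudioValidationError, Waveform
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

SMOTE_K_DEFAULT = 5
MISSING_THRESHOLD = 0.60
CORR_THRESHOLD = 0.995
CUM_IMPORTANCE_THRESHOLD = 0.99
N_IMPORTANCE_FITS = 10


# ---------------------------------------------------------------------------
# Blinded holdout
# ---------------------------------------------------------------------------

def carve_holdout(
    dataset: FeatureMatrix | Sequence[Waveform],
    n_per_class: int = 20,
    seed: int = 0,
):
    """Set aside ``n_per_class`` items per class as a blinded test set.

    Sampling is without replacement and seeded.  Works on either a
    :class:`FeatureMatrix` or a list of labeled waveforms; returns
    ``(test, remainder)`` of the same kind, disjoint and exhaustive.
    """
    if isinstance(dataset, FeatureMatrix):
        labels = dataset.labels
    else:
        labels = np.array([w.label for w in dataset])
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for klass in np.unique(labels):
        members = np.flatnonzero(labels == klass)
        if n_per_class > 0 and members.size <= n_per_class:
            raise AudioValidationError(
                f"class {klass!r} has only {members.size} members; cannot "
                f"hold out {n_per_class}")
        test_idx.extend(rng.choice(members, size=n_per_class, replace=False))
    test_set = set(test_idx)
    rest_idx = [i for i in range(len(labels)) if i not in test_set]
    test_idx = sorted(test_idx)
    if isinstance(dataset, FeatureMatrix):
        return dataset.take(test_idx), dataset.take(rest_idx)
    return ([dataset[i] for i in test_idx], [dataset[i] for i in rest_idx])


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote(matrix: FeatureMatrix, k: int = SMOTE_K_DEFAULT,
          seed: int = 0) -> FeatureMatrix:
    """Balance class counts by synthetic minority oversampling.

    Every minority class is grown to the majority count.  Each synthetic
    row is ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``: a point on
    the segment between a seeded-random minority row ``x`` and one of its
    ``k`` nearest minority neighbors (Euclidean distance, ``k`` reduced to
    class size - 1 when needed).  Original rows are preserved verbatim;
    synthetic rows are flagged in ``matrix.synthetic``.
    """
    counts = matrix.class_counts()
    for klass, n in counts.items():
        if n < 2:
            raise AudioValidationError(
                f"class {klass!r} has {n} sample(s); SMOTE needs >= 2")
    target = max(counts.values())
    if all(n == target for n in counts.values()):
        return matrix
    rng = np.random.default_rng(seed)
    X = matrix.X.to_numpy(dtype=float)
    new_rows: list[np.ndarray] = []
    new_labels: list[str] = []
    new_sources: list[str] = []
    for klass in sorted(counts):
        deficit = target - counts[klass]
        if deficit == 0:
            continue
        members = np.flatnonzero(matrix.labels == klass)
        pts = X[members]
        k_eff = min(k, len(members) - 1)
        # pairwise distances within the minority class only
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        nn = np.argsort(d2, axis=1)[:, :k_eff]
        base = rng.integers(0, len(members), size=deficit)
        pick = rng.integers(0, k_eff, size=deficit)
        u = rng.uniform(0.0, 1.0, size=deficit)
        for j in range(deficit):
            x = pts[base[j]]
            x_nn = pts[nn[base[j], pick[j]]]
            new_rows.append(x + u[j] * (x_nn - x))
            new_labels.append(klass)
            new_sources.append(f"smote:{klass}:{j}")
    X_out = pd.DataFrame(
        np.vstack([X, np.array(new_rows)]), columns=matrix.X.columns)
    return FeatureMatrix(
        X=X_out,
        labels=np.concatenate([matrix.labels, np.array(new_labels)]),
        sources=matrix.sources + new_sources,
        synthetic=np.concatenate(
            [matrix.synthetic, np.ones(len(new_rows), dtype=bool)]),
    )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class Normalization:
    """Per-feature z-score parameters, fitted once and reused.

    The mean and standard deviation are fitted on the training pool and
    saved so that validation and blinded-test matrices are transformed with
    the same parameters.  Zero-variance columns are flagged and mapped to 0.
    """

    mean: pd.Series
    std: pd.Series
    constant_columns: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean": self.mean.to_dict(),
            "std": self.std.to_dict(),
            "constant_columns": self.constant_columns,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Normalization":
        payload = json.loads(Path(path).read_text())
        return cls(mean=pd.Series(payload["mean"]),
                   std=pd.Series(payload["std"]),
                   constant_columns=payload["constant_columns"])


def fit_normalize(matrix: FeatureMatrix) -> Normalization:
    """Fit per-column mean and standard deviation (population SD)."""
    mean = matrix.X.mean()
    std = matrix.X.std(ddof=0)
    constant = std.index[std == 0].tolist()
    if constant:
        logger.warning("constant columns mapped to 0 after normalization: %s",
                       constant)
    return Normalization(mean=mean, std=std, constant_columns=constant)


def apply_normalize(matrix: FeatureMatrix, norm: Normalization) -> FeatureMatrix:
    """Apply saved z-score parameters; constant columns become all-zero."""
    if list(matrix.X.columns) != list(norm.mean.index):
        raise AudioValidationError(
            "column mismatch between matrix and saved normalization")
    safe_std = norm.std.replace(0.0, 1.0)
    Z = (matrix.X - norm.mean) / safe_std
    Z[norm.constant_columns] = 0.0
    return FeatureMatrix(X=Z, labels=matrix.labels, sources=list(matrix.sources),
                         synthetic=matrix.synthetic.copy())


# ---------------------------------------------------------------------------
# Five-rule feature selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Record of which features survived selection and why others did not.

    ``dropped`` maps each removed feature to the rule that removed it
    (``missing``, ``single_unique``, ``collinear``, ``zero_importance``,
    ``low_importance``); ``importances`` holds the normalized
    gradient-boosting importances of the features that were scored.
    """

    dropped: dict[str, str]
    kept: list[str]
    importances: pd.Series
    thresholds: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dropped": self.dropped,
            "kept": self.kept,
            "importances": self.importances.to_dict(),
            "thresholds": self.thresholds,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _importances(X: pd.DataFrame, y: np.ndarray, seed: int,
                 n_fits: int = N_IMPORTANCE_FITS) -> pd.Series:
    """Gain importance from gradient-boosted trees, averaged over seeded fits.

    Class labels are integer-encoded and fitted with a regression objective;
    min_child_samples is lowered from the LightGBM default so the trees can
    split on pools of a few hundred rows.
    """
    codes = pd.Categorical(y).codes.astype(float)
    total = np.zeros(X.shape[1])
    for i in range(n_fits):
        model = LGBMRegressor(
            n_estimators=100, random_state=seed + i, importance_type="gain",
            min_child_samples=5, verbose=-1, deterministic=True,
            force_row_wise=True, n_jobs=1,
        )
        model.fit(X.to_numpy(dtype=float), codes)
        total += model.feature_importances_
    return pd.Series(total / n_fits, index=X.columns)


def select_features(
    matrix: FeatureMatrix,
    thresholds: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[SelectionReport, FeatureMatrix]:
    """Apply the five removal rules in order and return the reduced matrix.

    1. drop columns with more than 60% missing entries;
    2. drop columns with a single unique value;
    3. among column pairs with ``|Pearson r| >= 0.995``, drop the
       later column in canonical order;
    4. drop columns with zero gradient-boosting importance;
    5. rank the rest by importance and drop those outside the minimal
       prefix reaching 0.99 cumulative normalized importance.
    """
    th = {"missing": MISSING_THRESHOLD, "corr": CORR_THRESHOLD,
          "cum_importance": CUM_IMPORTANCE_THRESHOLD}
    if thresholds:
        th.update(thresholds)
    if matrix.n_features < 2:
        raise AudioValidationError("need at least 2 features to select from")
    X = matrix.X
    dropped: dict[str, str] = {}

    missing_frac = X.isna().mean()
    for col in missing_frac.index[missing_frac > th["missing"]]:
        dropped[col] = "missing"
    X = X.drop(columns=list(dropped))

    for col in X.columns:
        if X[col].nunique(dropna=True) <= 1:
            dropped[col] = "single_unique"
    X = X.drop(columns=[c for c, r in dropped.items()
                        if r == "single_unique" and c in X.columns])

    corr = X.corr().abs()
    cols = list(X.columns)
    collinear: list[str] = []
    for j, later in enumerate(cols):
        for earlier in cols[:j]:
            if earlier in collinear:
                continue
            if corr.loc[earlier, later] >= th["corr"]:
                collinear.append(later)
                dropped[later] = "collinear"
                break
    X = X.drop(columns=collinear)

    imp = _importances(X.fillna(X.mean()), matrix.labels, seed=seed)
    total = imp.sum()
    if total <= 0:
        raise AudioValidationError(
            "gradient-boosting importance is zero for every feature")
    imp_norm = imp / total
    zero = imp_norm.index[imp_norm == 0].tolist()
    for col in zero:
        dropped[col] = "zero_importance"
    scored = imp_norm.drop(index=zero).sort_values(ascending=False)
    cum = scored.cumsum()
    n_keep = int(np.searchsorted(cum.to_numpy(), th["cum_importance"]) + 1)
    n_keep = min(n_keep, len(scored))
    for col in scored.index[n_keep:]:
        dropped[col] = "low_importance"
    kept = [c for c in matrix.X.columns if c not in dropped]
    if not kept:
        raise AudioValidationError("all features dropped; check thresholds")
    logger.info("feature selection kept %d of %d columns", len(kept),
                matrix.n_features)
    report = SelectionReport(dropped=dropped, kept=kept,
                             importances=imp_norm, thresholds=dict(th))
    reduced = FeatureMatrix(X=matrix.X[kept].copy(), labels=matrix.labels,
                            sources=list(matrix.sources),
                            synthetic=matrix.synthetic.copy())
    return report, reduced


# ---------------------------------------------------------------------------
# Stratified split
# ---------------------------------------------------------------------------

def split(matrix: FeatureMatrix, train_frac: float = 0.70,
          seed: int = 0) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Seeded stratified train/validation split.

    Per class, exactly ``round(train_frac * n_class)`` rows go to training;
    the partition is disjoint and exhaustive.
    """
    if not 0.0 < train_frac <= 1.0:
        raise AudioValidationError(f"train_frac must be in (0, 1], got {train_frac}")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for klass in np.unique(matrix.labels):
        members = np.flatnonzero(matrix.labels == klass)
        if members.size < 2 and train_frac < 1.0:
            raise AudioValidationError(
                f"class {klass!r} has a single row; cannot split")
        n_train = int(round(train_frac * members.size))
        shuffled = rng.permutation(members)
        train_idx.extend(shuffled[:n_train])
        val_idx.extend(shuffled[n_train:])
    return matrix.take(sorted(train_idx)), matrix.take(sorted(val_idx))
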