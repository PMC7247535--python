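"""Boosted-regression-tree correction of multibody strain predictions.

The coarse multibody model tracks the reference strain only loosely, with
a discrepancy that varies systematically with the loading kinematics.  A
least-squares gradient-boosted ensemble of 30 regression trees (LSBoost)
maps (MBM MPS95, peak angular velocity, peak angular acceleration) — per
plane, in seven canonical feature-set combinations — onto the reference
MPS95, for whole-plane, multi-axis resultant, and per-element regional
prediction.  Training uses a seeded random 60/40 train/test split with
fivefold cross-validation on the training portion; performance is
reported as RMSE, MAE and R^2 per split.

Tree ensembles cannot extrapolate beyond the range of their training
targets (predictions are sums of leaf means), so out-of-range inputs are
flagged rather than refused: feeding kinematics below the training range
yields a floor at roughly the smallest training targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import KFold

from .geometry import PlanarMesh
from .strain import relative_error, resultant_mps
from .surrogate import ReferenceDataset

#: The seven canonical feature sets (base features, expanded per plane).
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "MBM MPS": ("mbm_mps",),
    "Peak angular velocity": ("peak_ang_vel",),
    "Peak angular acceleration": ("peak_ang_accel",),
    "MBM MPS, peak angular velocity": ("mbm_mps", "peak_ang_vel"),
    "MBM MPS, peak angular acceleration": ("mbm_mps", "peak_ang_accel"),
    "Peak angular velocity, peak angular acceleration": ("peak_ang_vel", "peak_ang_accel"),
    "All": ("mbm_mps", "peak_ang_vel", "peak_ang_accel"),
}

#: LSBoost hyperparameters (fixed; recorded in model metadata).
N_TREES = 30
LEARNING_RATE = 0.1
MAX_DEPTH = 4
MIN_LEAF = 3


class MLError(ValueError):
    pass


@dataclass
class EvaluationReport:
    """RMSE / MAE / R^2 per split plus relative-error summary (percent)."""

    rmse: dict[str, float]
    mae: dict[str, float]
    r2: dict[str, float]
    rel_err_mean: dict[str, float]
    rel_err_sd: dict[str, float]
    n: dict[str, int]


@dataclass
class CorrectionModel:
    """Trained LSBoost ensemble with training-range metadata."""

    estimator: GradientBoostingRegressor
    feature_set: str
    feature_names: list[str]
    x_bounds: np.ndarray  # (2, n_features): min / max over training rows
    y_bounds: tuple[float, float]
    seed: int
    report: EvaluationReport | None = None
    meta: dict = field(default_factory=dict)


def assemble_features(
    dataset: ReferenceDataset,
    mbm_mps: np.ndarray | dict[str, np.ndarray],
    feature_set: str = "All",
    targets: np.ndarray | str = "mps95",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Build the (features, target) table for one dataset.

    ``mbm_mps`` is the coarse-model MPS95 per condition: an array for a
    single-plane dataset, or a {plane_id: array} map for multi-plane
    inputs (features are then expanded per plane, three to nine columns).
    ``targets`` selects the reference quantity: the per-plane MPS95
    (default), an explicit array (e.g. regional or resultant targets).
    """
    if feature_set not in FEATURE_SETS:
        raise MLError(f"unknown feature set {feature_set!r}")
    base = FEATURE_SETS[feature_set]
    if isinstance(mbm_mps, dict):
        planes = list(mbm_mps)
        per_plane = {
            p: {
                "mbm_mps": np.asarray(mbm_mps[p], dtype=float),
                "peak_ang_vel": dataset.peak_ang_vel,
                "peak_ang_accel": dataset.peak_ang_accel,
            }
            for p in planes
        }
    else:
        planes = [dataset.plane_id]
        per_plane = {
            dataset.plane_id: {
                "mbm_mps": np.asarray(mbm_mps, dtype=float),
                "peak_ang_vel": dataset.peak_ang_vel,
                "peak_ang_accel": dataset.peak_ang_accel,
            }
        }
    n = dataset.n_conditions
    cols = {}
    for feat in base:
        for p in planes:
            arr = per_plane[p][feat]
            if len(arr) != n:
                raise MLError(
                    f"feature {feat!r} for plane {p!r} has {len(arr)} rows, "
                    f"expected {n} (one per condition)"
                )
            cols[f"{feat}[{p}]"] = arr
    X = pd.DataFrame(cols)
    if isinstance(targets, str):
        if targets != "mps95":
            raise MLError(f"unknown target selector {targets!r}")
        y = dataset.mps95
    else:
        y = np.asarray(targets, dtype=float)
        if len(y) != n:
            raise MLError(f"targets have {len(y)} rows, expected {n}")
    return X, y


def _metrics(y_true, y_pred):
    rmse = float(np.sqrt(mean_squared_error(y_true, y_pred)))
    mae = float(mean_absolute_error(y_true, y_pred))
    if np.std(y_true) == 0:
        r2 = float("nan")
    else:
        r2 = float(r2_score(y_true, y_pred))
    pos = np.asarray(y_true) > 0
    if np.any(pos):
        rel = relative_error(np.asarray(y_pred)[pos], np.asarray(y_true)[pos])
        rel_mean, rel_sd = float(np.mean(rel)), float(np.std(rel))
    else:
        rel_mean = rel_sd = float("nan")
    return rmse, mae, r2, rel_mean, rel_sd


def _new_estimator(seed: int) -> GradientBoostingRegressor:
    return GradientBoostingRegressor(
        loss="squared_error",
        n_estimators=N_TREES,
        learning_rate=LEARNING_RATE,
        max_depth=MAX_DEPTH,
        min_samples_leaf=MIN_LEAF,
        random_state=seed,
    )


def train(
    X: pd.DataFrame,
    y: np.ndarray,
    split: float = 0.6,
    folds: int = 5,
    seed: int = 0,
    feature_set: str = "All",
) -> tuple[CorrectionModel, EvaluationReport]:
    """Fit an LSBoost correction model with a seeded 60/40 split and
    fivefold cross-validation on the training portion."""
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n = len(X)
    if n < 20:
        raise MLError(f"need at least 20 rows to train, got {n}")
    if np.std(y) == 0:
        warnings.warn("degenerate targets (zero variance); model will predict the constant")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(split * n))
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    Xtr, ytr = X.iloc[train_idx], y[train_idx]
    Xte, yte = X.iloc[test_idx], y[test_idx]

    # Fivefold CV on the training portion -> validation metrics.
    # Estimators are fitted on plain arrays; column names live in the
    # CorrectionModel metadata.
    Xtr_a, Xte_a = Xtr.to_numpy(dtype=float), Xte.to_numpy(dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    val_true, val_pred = [], []
    for fit_i, val_i in kf.split(Xtr_a):
        est = _new_estimator(seed)
        est.fit(Xtr_a[fit_i], ytr[fit_i])
        val_true.append(ytr[val_i])
        val_pred.append(est.predict(Xtr_a[val_i]))
    val_true = np.concatenate(val_true)
    val_pred = np.concatenate(val_pred)

    est = _new_estimator(seed)
    est.fit(Xtr_a, ytr)

    report_rows = {}
    for name, yt, yp in (
        ("training", ytr, est.predict(Xtr_a)),
        ("validation", val_true, val_pred),
        ("test", yte, est.predict(Xte_a)),
    ):
        report_rows[name] = _metrics(yt, yp) + (len(yt),)
    report = EvaluationReport(
        rmse={k: v[0] for k, v in report_rows.items()},
        mae={k: v[1] for k, v in report_rows.items()},
        r2={k: v[2] for k, v in report_rows.items()},
        rel_err_mean={k: v[3] for k, v in report_rows.items()},
        rel_err_sd={k: v[4] for k, v in report_rows.items()},
        n={k: v[5] for k, v in report_rows.items()},
    )
    model = CorrectionModel(
        estimator=est,
        feature_set=feature_set,
        feature_names=list(X.columns),
        x_bounds=np.vstack([Xtr.min().to_numpy(), Xtr.max().to_numpy()]),
        y_bounds=(float(ytr.min()), float(ytr.max())),
        seed=seed,
        report=report,
        meta={
            "n_trees": N_TREES,
            "learning_rate": LEARNING_RATE,
            "max_depth": MAX_DEPTH,
            "min_samples_leaf": MIN_LEAF,
            "split": split,
            "folds": folds,
            "train_idx": train_idx.tolist(),
            "test_idx": test_idx.tolist(),
        },
    )
    return model, report


def predict(model: CorrectionModel, X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble prediction plus per-row out-of-training-range flags.

    Inputs outside the training feature bounds are flagged, never
    altered: the ensemble then returns values pinned near the edge of
    the training-target range (the "floor" behaviour of boosted trees).
    """
    if isinstance(X, pd.DataFrame):
        missing = [c for c in model.feature_names if c not in X.columns]
        if missing:
            raise MLError(f"missing feature columns: {missing}")
        Xa = X[model.feature_names].to_numpy(dtype=float)
    else:
        Xa = np.atleast_2d(np.asarray(X, dtype=float))
        if Xa.shape[1] != len(model.feature_names):
            raise MLError(
                f"expected {len(model.feature_names)} features, got {Xa.shape[1]}"
            )
    yhat = model.estimator.predict(Xa)
    lo, hi = model.x_bounds
    flags = np.any((Xa < lo) | (Xa > hi), axis=1)
    return yhat, flags


def correct_planar(
    mbm_mps: dict[str, float],
    peaks: dict[str, tuple[float, float]],
    models: dict[str, CorrectionModel],
) -> dict:
    """Apply per-plane correction models and combine via the resultant.

    ``mbm_mps`` maps plane_id -> coarse-model MPS95; ``peaks`` maps
    plane_id -> (peak angular acceleration, peak angular velocity);
    ``models`` maps plane_id -> trained single-plane model.  Planes
    absent from ``mbm_mps`` contribute zero to the resultant.
    """
    corrected = {}
    flags = {}
    for plane, model in models.items():
        if plane not in mbm_mps:
            continue
        row = {}
        for name in model.feature_names:
            base = name.split("[")[0]
            if base == "mbm_mps":
                row[name] = mbm_mps[plane]
            elif base == "peak_ang_accel":
                row[name] = peaks[plane][0]
            elif base == "peak_ang_vel":
                row[name] = peaks[plane][1]
        yhat, fl = predict(model, pd.DataFrame([row]))
        corrected[plane] = float(yhat[0])
        flags[plane] = bool(fl[0])
    vals = [corrected.get(p, 0.0) for p in ("coronal", "sagittal", "axial")]
    return {
        "per_plane": corrected,
        "resultant": resultant_mps(*(max(v, 0.0) for v in vals)),
        "out_of_range": flags,
    }


@dataclass
class RegionalModels:
    """Per-triangle correction models and the exclusion ledger."""

    models: dict[int, CorrectionModel]
    reports: dict[int, EvaluationReport]
    excluded: dict[int, str]  # triangle id -> reason


def train_regional(
    dataset: ReferenceDataset,
    mbm_mps: np.ndarray,
    mesh: PlanarMesh,
    feature_set: str = "All",
    seed: int = 0,
    nonbrain_regions: list | None = None,
) -> RegionalModels:
    """One correction model per eligible triangular element.

    Features are identical to the whole-plane model; the target is the
    element's regional reference MPS.  Elements are excluded when
    (1) no fine element fell within the 10%-area averaging radius
    (regional reference is NaN), or (2) the element centroid lies in
    declared nonbrain matter (e.g. a ventricle), supplied as shapely
    geometries in ``nonbrain_regions``.
    """
    from shapely.geometry import Point

    X, _ = assemble_features(dataset, mbm_mps, feature_set=feature_set)
    pos = {n.id: n.ref_position for n in mesh.nodes}
    models: dict[int, CorrectionModel] = {}
    reports: dict[int, EvaluationReport] = {}
    excluded: dict[int, str] = {}
    for ti, tri in enumerate(mesh.triangles):
        centroid = np.mean([pos[v] for v in tri.vertices], axis=0)
        if nonbrain_regions and any(g.contains(Point(centroid)) for g in nonbrain_regions):
            excluded[tri.id] = "centroid_in_nonbrain_matter"
            continue
        y = dataset.regional_mps[:, ti]
        if np.any(np.isnan(y)):
            excluded[tri.id] = "no_fine_elements_in_radius"
            continue
        model, report = train(X, y, seed=seed, feature_set=feature_set)
        models[tri.id] = model
        reports[tri.id] = report
    return RegionalModels(models=models, reports=reports, excluded=excluded)


def feature_ablation(
    dataset: ReferenceDataset,
    mbm_mps: np.ndarray | dict[str, np.ndarray],
    seed: int = 0,
    targets: np.ndarray | str = "mps95",
) -> pd.DataFrame:
    """Evaluate all seven canonical feature sets with a shared split.

    Returns one row per feature set with training and validation RMSE,
    MAE and R^2; the best validation-RMSE row is flagged.
    """
    rows = []
    for name in FEATURE_SETS:
        X, y = assemble_features(dataset, mbm_mps, feature_set=name, targets=targets)
        _, report = train(X, y, seed=seed, feature_set=name)
        rows.append(
            {
                "feature_set": name,
                "train_rmse": report.rmse["training"],
                "train_mae": report.mae["training"],
                "train_r2": report.r2["training"],
                "val_rmse": report.rmse["validation"],
                "val_mae": report.mae["validation"],
                "val_r2": report.r2["validation"],
            }
        )
    df = pd.DataFrame(rows)
    df["best"] = df["val_rmse"] == df["val_rmse"].min()
    return df
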