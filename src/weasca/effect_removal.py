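"""Nuisance-effect removal and cross-validated classification.

A dominant nuisance factor (typically the individual animal or subject) is
removed from a spectral training set by subtracting its weighted-effect
contribution,

    X_corrected = X - Con_nuisance ,

with the decomposition fitted on the training rows only.  Inside a
leave-one-group-out cross-validation the held-out group's rows are *never*
corrected: a new individual's effect is unobservable, so test spectra enter
the classifier untouched.  Two classifier pipelines are provided, PCA-LDA
(linear discriminant analysis on leading training-set principal components)
and PLS-DA (linear discriminant analysis on supervised partial-least-squares
latent variables from one-hot class targets), each evaluated over a grid of
component counts in a corrected and an uncorrected arm.

Performance is reported as mean sensitivity — the unweighted mean of
per-class recalls — computed per fold and averaged, with the standard
deviation across folds as the reproducibility band.  A pooled-confusion
aggregate over all predictions is also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .design_coding import FactorDesign, ModelSpec, term_name
from .glm_core import _as_matrix, decompose

__all__ = ["CVConfig", "ArmResult", "CVResult", "remove_effect", "crossvalidate"]


def remove_effect(X, design: FactorDesign, model: ModelSpec, term) -> np.ndarray:
    """Subtract one term's weighted-effect contribution from ``X``.

    The decomposition is fitted on ``X`` itself under ``model``; refitting
    on the corrected matrix leaves (numerically) zero variance for the
    removed term.
    """
    name = term if isinstance(term, str) else term_name(tuple(term))
    dec = decompose(X, design, model)
    if name not in dec.contributions:
        raise KeyError(f"term {name!r} not in model {model.formula()!r}")
    return _as_matrix(X) - dec.contributions[name]


@dataclass
class CVConfig:
    """Configuration of the leave-one-group-out classification benchmark.

    Attributes
    ----------
    group_factor : factor defining the folds (one fold per level).
    label_factor : factor holding the class labels to predict.
    nuisance_term : term removed from each training set in the corrected
        arm (must be in ``model``).
    model : decomposition model for the removal; defaults to the nuisance
        main effect alone, under weighted-effect coding.
    classifier : ``"pca-lda"`` or ``"pls-da"``.
    component_grid : component counts to evaluate (default 1..20).
    lda_shrinkage : optional ridge for degenerate within-class scatter
        (uses the least-squares LDA solver when set).
    """

    group_factor: str
    label_factor: str
    nuisance_term: str
    model: ModelSpec | None = None
    classifier: str = "pca-lda"
    component_grid: tuple[int, ...] = tuple(range(1, 21))
    lda_shrinkage: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.classifier not in ("pca-lda", "pls-da"):
            raise ValueError(
                f"classifier must be 'pca-lda' or 'pls-da', got {self.classifier!r}"
            )
        if self.model is None:
            self.model = ModelSpec(
                ((self.nuisance_term,),), coding="weighted-effect"
            )
        if self.nuisance_term not in self.model.term_names:
            raise ValueError(
                f"nuisance term {self.nuisance_term!r} not in model "
                f"{self.model.formula()!r}"
            )
        grid = tuple(int(k) for k in self.component_grid)
        if not grid or min(grid) < 1:
            raise ValueError("component_grid must contain positive integers")
        self.component_grid = grid


@dataclass
class ArmResult:
    """Sensitivity summaries of one arm (corrected or uncorrected)."""

    component_grid: tuple[int, ...]
    fold_sensitivity: np.ndarray  # (folds, grid)
    mean_sensitivity: np.ndarray  # (grid,)
    sd_sensitivity: np.ndarray  # (grid,) across folds
    pooled_sensitivity: np.ndarray  # (grid,) from the pooled confusion
    predictions: dict[int, np.ndarray]  # component count -> per-obs labels

    @property
    def max_mean_sensitivity(self) -> float:
        return float(np.max(self.mean_sensitivity))


@dataclass
class CVResult:
    config: CVConfig
    folds: list[str]
    classes: list[str]
    corrected: ArmResult
    uncorrected: ArmResult
    # per-fold fingerprint of training-side quantities (corrected training
    # matrix sums); lets leakage tests assert that test rows never reach
    # the training pipeline
    train_checksums: dict[str, float] = field(default_factory=dict)


def _mean_recall(y_true: np.ndarray, y_pred: np.ndarray, classes) -> float:
    recalls = []
    for c in classes:
        mask = y_true == c
        if mask.any():
            recalls.append(float(np.mean(y_pred[mask] == c)))
    return float(np.mean(recalls)) if recalls else np.nan


def _fit_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    cfg: CVConfig,
    k: int,
) -> np.ndarray:
    """One classifier at one component count; all statistics train-side."""
    if cfg.lda_shrinkage is not None:
        lda = LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage=cfg.lda_shrinkage
        )
    else:
        lda = LinearDiscriminantAnalysis()
    if cfg.classifier == "pca-lda":
        k_max = min(train_X.shape[0] - 1, train_X.shape[1])
        if k > k_max:
            warnings.warn(
                f"component count {k} exceeds feasible rank {k_max}; truncated"
            )
            k = k_max
        pca = PCA(n_components=k, svd_solver="full").fit(train_X)
        lda.fit(pca.transform(train_X), train_y)
        return lda.predict(pca.transform(test_X))
    # pls-da: one-hot targets, discriminant on the latent scores
    classes = np.unique(train_y)
    Y = (train_y[:, None] == classes[None, :]).astype(float)
    k_max = min(train_X.shape[0] - 1, train_X.shape[1])
    if k > k_max:
        warnings.warn(
            f"component count {k} exceeds feasible rank {k_max}; truncated"
        )
        k = k_max
    pls = PLSRegression(n_components=k, scale=False).fit(train_X, Y)
    lda.fit(pls.transform(train_X), train_y)
    return lda.predict(pls.transform(test_X))


def crossvalidate(X, design: FactorDesign, cfg: CVConfig) -> CVResult:
    """Leave-one-group-out benchmark with and without nuisance removal.

    For each level of the grouping factor all its observations are held
    out; the nuisance decomposition is fitted on the remaining rows only;
    classifiers are trained on the corrected (arm 1) and uncorrected
    (arm 2) training matrices and predict the untouched held-out rows.
    """
    Xm = _as_matrix(X)
    if Xm.shape[0] != design.n:
        raise ValueError("response rows do not match design")
    groups = design.labels(cfg.group_factor)
    labels = design.labels(cfg.label_factor)
    fold_levels = list(design.levels(cfg.group_factor))
    if len(fold_levels) < 2:
        raise ValueError(
            f"grouping factor {cfg.group_factor!r} needs >= 2 levels"
        )
    classes = list(design.levels(cfg.label_factor))
    grid = cfg.component_grid
    obs_ids = np.asarray(design.obs_ids)

    fold_sens = {arm: np.full((len(fold_levels), len(grid)), np.nan) for arm in (0, 1)}
    preds = {arm: {k: np.empty(design.n, dtype=object) for k in grid} for arm in (0, 1)}
    checksums: dict[str, float] = {}

    for i, fold in enumerate(fold_levels):
        test_mask = groups == fold
        train_mask = ~test_mask
        train_y = labels[train_mask]
        missing = [c for c in classes if c not in train_y]
        if missing:
            raise ValueError(
                f"fold {fold!r}: training set lost class(es) {missing}"
            )
        train_design = design.subset(obs_ids[train_mask])
        corrected_train = remove_effect(
            Xm[train_mask], train_design, cfg.model, cfg.nuisance_term
        )
        checksums[fold] = float(np.sum(corrected_train))
        test_X = Xm[test_mask]
        test_y = labels[test_mask]
        for arm, train_X in ((0, corrected_train), (1, Xm[train_mask])):
            for j, k in enumerate(grid):
                y_pred = _fit_predict(train_X, train_y, test_X, cfg, k)
                fold_sens[arm][i, j] = _mean_recall(test_y, y_pred, classes)
                preds[arm][k][test_mask] = y_pred

    arms = {}
    for arm, key in ((0, "corrected"), (1, "uncorrected")):
        fs = fold_sens[arm]
        pooled = np.array(
            [
                _mean_recall(labels, preds[arm][k].astype(str), classes)
                for k in grid
            ]
        )
        arms[key] = ArmResult(
            component_grid=grid,
            fold_sensitivity=fs,
            mean_sensitivity=np.nanmean(fs, axis=0),
            sd_sensitivity=np.nanstd(fs, axis=0, ddof=1),
            pooled_sensitivity=pooled,
            predictions={k: preds[arm][k].astype(str) for k in grid},
        )
    return CVResult(
        config=cfg,
        folds=fold_levels,
        classes=classes,
        corrected=arms["corrected"],
        uncorrected=arms["uncorrected"],
        train_checksums=checksums,
    )
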