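"""Stacked ensemble over balanced subsets: base matrix, probability
features, feature selection, and the SVM meta-classifier.

The model is a two-level stack designed for imbalanced bioactivity data.
Level one trains one classifier per (algorithm, descriptor family,
balanced subset) triple — with the default roster of 6 algorithms,
5 descriptor families and 5 subsets that is 150 base classifiers.  Each
training compound is then re-described by the vector of base-classifier
probability scores

    PFV = [P(ML1, MD1, BTS1), P(ML1, MD1, BTS2), ..., P(ML_A, MD_D, BTS_K)]

ordered algorithm-major, then descriptor, then subset.  To avoid
leakage, a compound that belongs to a base model's own training subset
receives that model's out-of-fold cross-validation score; compounds
outside the subset (and all future compounds) receive the fitted
model's score.  Level two ranks the probability features by random
forest mean decrease of Gini impurity (MDGI), evaluates nested top-m
subsets by cross-validated MCC of an RBF-SVM meta-classifier, and fits
the final meta-classifier on the winning subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    cross_val_predict,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .errors import (
    ConfigurationError,
    IncompleteMatrixError,
    InputError,
    InvariantViolationError,
    SmilesParseError,
)
from .metrics import confusion, compute_metrics
from .sampling import BalancedSubset

warnings.filterwarnings("ignore", category=ConvergenceWarning)
# SVC(probability=True) is the Platt-scaled probability machinery this
# stack is built around; sklearn 1.9 deprecation noise is not actionable
warnings.filterwarnings(
    "ignore", message=".*probability.*deprecated.*", category=FutureWarning
)

ALGORITHM_ORDER = ("KNN", "MLP", "PLS", "RF", "SVM", "XGB")
FAMILY_ORDER = ("AP2DC", "CDKExt", "FP4C", "MACCS", "Pubchem")


class PLSClassifier(BaseEstimator, ClassifierMixin):
    """PLS-DA: partial-least-squares regression on a 0/1 response.

    scikit-learn ships PLS only as a regressor; for classification the
    standard discriminant-analysis trick regresses the binary label and
    clips the continuous prediction to [0, 1] as a probability score.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n_comp = min(self.n_components, X.shape[1], max(1, X.shape[0] - 1))
        self.pls_ = PLSRegression(n_components=n_comp)
        # constant columns are fine; PLS centers internally
        self.pls_.fit(X, y)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        raw = np.clip(self.pls_.predict(np.asarray(X, dtype=float)).ravel(), 0, 1)
        return np.column_stack([1 - raw, raw])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def make_estimator(algorithm: str, seed: int = 0, **params):
    """Fresh probability-emitting estimator for one roster algorithm."""
    if algorithm == "KNN":
        return KNeighborsClassifier(**{"n_neighbors": 5, **params})
    if algorithm == "MLP":
        return MLPClassifier(
            **{"hidden_layer_sizes": (32,), "max_iter": 500,
               "random_state": seed, **params}
        )
    if algorithm == "PLS":
        return PLSClassifier(**{"n_components": 2, **params})
    if algorithm == "RF":
        return RandomForestClassifier(
            **{"n_estimators": 500, "random_state": seed, "n_jobs": 1, **params}
        )
    if algorithm == "SVM":
        return SVC(
            **{"kernel": "rbf", "C": 1.0, "probability": True,
               "random_state": seed, **params}
        )
    if algorithm == "XGB":
        return XGBClassifier(
            **{"n_estimators": 300, "max_depth": 3, "learning_rate": 0.1,
               "random_state": seed, "n_jobs": 1, "verbosity": 0,
               "eval_metric": "logloss", **params}
        )
    raise ConfigurationError(
        f"unknown algorithm {algorithm!r}; valid: {list(ALGORITHM_ORDER)}"
    )


#: default hyperparameter grids for 10-fold CV tuning
DEFAULT_GRIDS = {
    "KNN": {"n_neighbors": [3, 5, 7, 9]},
    "MLP": {"hidden_layer_sizes": [(16,), (32,), (64,)]},
    "PLS": {"n_components": [2, 3, 4, 5, 6, 7, 8]},
    "RF": {"max_features": ["sqrt", 0.25]},
    "SVM": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01]},
    "XGB": {"max_depth": [3, 6], "learning_rate": [0.1, 0.3]},
}


@dataclass(frozen=True, order=True)
class BaseModelKey:
    """(algorithm, descriptor family, balanced subset) triple."""

    algorithm: str
    descriptor_family: str
    subset_index: int

    def __str__(self):
        return f"{self.algorithm}-{self.descriptor_family}-BTS{self.subset_index}"


def enumerate_keys(algorithms, families, k: int) -> list[BaseModelKey]:
    """All A×D×K keys, algorithm-major, then descriptor, then subset."""
    return [
        BaseModelKey(alg, fam, i)
        for alg in algorithms
        for fam in families
        for i in range(1, k + 1)
    ]


@dataclass
class PFVMatrix:
    """n_compounds × (A·D·K) matrix of base-classifier probability scores."""

    matrix: np.ndarray
    columns: list[BaseModelKey]

    def __post_init__(self):
        if self.matrix.shape[1] != len(self.columns):
            raise InvariantViolationError(
                f"matrix width {self.matrix.shape[1]} != "
                f"{len(self.columns)} column keys"
            )
        if np.isnan(self.matrix).any():
            raise InvariantViolationError("probability matrix contains NaN")
        if self.matrix.size and (
            self.matrix.min() < 0 or self.matrix.max() > 1
        ):
            raise InvariantViolationError("probability scores outside [0,1]")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def select(self, column_ids) -> np.ndarray:
        return self.matrix[:, list(column_ids)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=[str(k) for k in self.columns])


def _stratified_folds(y, folds, seed):
    counts = np.bincount(np.asarray(y, dtype=int), minlength=2)
    if counts.min() < 2:
        raise InputError("each class needs >= 2 members for stratified folds")
    folds = int(folds)
    if folds > len(y):
        raise InputError(f"{folds} folds exceed {len(y)} samples")
    folds = min(folds, counts.min())  # stratified refolding for small classes
    return StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)


def tune_base_classifier(
    algorithm: str, X, y, grid: dict | None = None,
    folds: int = 10, seed: int = 0,
):
    """Tune one base classifier by stratified CV grid search on MCC.

    Returns the estimator refitted on the full subset with the best
    hyperparameters.  ``grid=None`` uses the declared default grid.
    """
    if grid is None:
        grid = DEFAULT_GRIDS.get(algorithm, {})
    if not grid:
        raise ConfigurationError(f"empty hyperparameter grid for {algorithm}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    cv = _stratified_folds(y, folds, seed)
    search = GridSearchCV(
        make_estimator(algorithm, seed=seed),
        param_grid=grid,
        scoring="matthews_corrcoef",
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    search.fit(X, y)
    search.best_estimator_.cv_mcc_ = float(search.best_score_)
    return search.best_estimator_


def oof_probability(estimator, X, y, folds: int = 10, seed: int = 0) -> np.ndarray:
    """Out-of-fold probability of the positive class for every sample.

    Each sample is scored by the fold model that excluded it; the
    estimator's hyperparameters are cloned per fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    cv = _stratified_folds(y, folds, seed)
    proba = cross_val_predict(
        clone(estimator), X, y, cv=cv, method="predict_proba", n_jobs=1
    )[:, 1]
    return np.clip(proba, 0.0, 1.0)


@dataclass
class StackConfig:
    """Configuration of the whole stack."""

    algorithms: tuple = ALGORITHM_ORDER
    families: tuple = FAMILY_ORDER
    k: int | None = None            # balanced subsets; None = auto from ratio
    base_folds: int = 10            # OOF folds inside each subset
    selection_folds: int = 10       # meta-classifier CV folds
    selection_grid: tuple | None = None   # None = 10,20,...,width
    tune: bool = False              # grid-search base hyperparameters
    decision_threshold: float = 0.5
    mdgi_seeds: int = 5
    seed: int = 0


@dataclass
class BaseMatrix:
    """All fitted base models plus their within-subset OOF scores."""

    models: dict                    # BaseModelKey -> fitted estimator
    oof: dict                       # BaseModelKey -> OOF vector (subset order)
    subsets: list                   # BalancedSubset with row-index ids
    config: StackConfig


def train_base_matrix(blocks: dict, y, subsets, config: StackConfig) -> BaseMatrix:
    """Fit one base classifier per (algorithm, family, subset) triple.

    ``blocks`` maps family name → (n_total × d) matrix over the whole
    training set; subset ids are row indices into those matrices.
    """
    y = np.asarray(y, dtype=int)
    for fam in config.families:
        if fam not in blocks:
            raise ConfigurationError(f"missing descriptor block {fam!r}")
    models, oof = {}, {}
    for key in enumerate_keys(config.algorithms, config.families, len(subsets)):
        subset = subsets[key.subset_index - 1]
        rows = np.asarray(subset.ids, dtype=int)
        Xs = np.asarray(blocks[key.descriptor_family], dtype=float)[rows]
        ys = y[rows]
        seed = config.seed + key.subset_index
        if config.tune:
            model = tune_base_classifier(
                key.algorithm, Xs, ys, folds=config.base_folds, seed=seed
            )
        else:
            model = make_estimator(key.algorithm, seed=seed).fit(Xs, ys)
        models[key] = model
        oof[key] = oof_probability(
            model, Xs, ys, folds=config.base_folds, seed=seed
        )
    return BaseMatrix(models=models, oof=oof, subsets=list(subsets), config=config)


def build_pfv(blocks: dict, base: BaseMatrix, mode: str = "train") -> PFVMatrix:
    """Assemble the probability-feature matrix.

    ``train`` mode scores each training compound with the OOF value when
    it sits inside a base model's own subset and with the fitted model
    otherwise; ``apply`` mode scores every compound with the fitted
    models.  Width is always A·D·K.
    """
    if mode not in ("train", "apply"):
        raise ConfigurationError(f"mode must be 'train' or 'apply', got {mode!r}")
    config = base.config
    keys = enumerate_keys(config.algorithms, config.families, len(base.subsets))
    n = next(iter(blocks.values())).shape[0]
    cols = []
    fitted_cache: dict = {}
    for key in keys:
        if key not in base.models:
            raise IncompleteMatrixError(f"no fitted base model for {key}")
        model = base.models[key]
        cache_key = (id(model), key.descriptor_family)
        if cache_key not in fitted_cache:
            X = np.asarray(blocks[key.descriptor_family], dtype=float)
            fitted_cache[cache_key] = np.clip(
                model.predict_proba(X)[:, 1], 0.0, 1.0
            )
        scores = fitted_cache[cache_key].copy()
        if mode == "train":
            subset = base.subsets[key.subset_index - 1]
            rows = np.asarray(subset.ids, dtype=int)
            scores[rows] = base.oof[key]
        # rounding far below score resolution kills sub-ulp BLAS jitter,
        # so identical compounds in one batch get identical columns
        cols.append(np.round(scores, 12))
    return PFVMatrix(matrix=np.column_stack(cols) if cols else np.zeros((n, 0)),
                     columns=keys)


def rank_pfs_mdgi(
    pfv: PFVMatrix, y, seed: int = 0, n_seeds: int = 5, n_trees: int = 500
):
    """Rank probability features by random-forest mean decrease of Gini.

    Importances are averaged over ``n_seeds`` forest seeds to damp the
    seed sensitivity of any single fit.  Returns (ranking, scores):
    ``ranking`` lists column indices in decreasing importance,
    ``scores`` is importance per original column.
    """
    y = np.asarray(y, dtype=int)
    X = pfv.matrix
    if X.shape[1] == 0 or np.all(X == X[0:1, :]):
        raise InputError("all columns constant; MDGI ranking is undefined")
    importances = np.zeros(X.shape[1])
    for s in range(n_seeds):
        rf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed + s, n_jobs=1
        )
        rf.fit(X, y)
        importances += rf.feature_importances_
    importances /= n_seeds
    ranking = np.argsort(-importances, kind="stable")
    return ranking, importances


@dataclass
class SelectionResult:
    """Outcome of top-m probability-feature selection."""

    ranking: np.ndarray            # column indices, best first
    scores: np.ndarray             # MDGI importance per column
    grid: list                     # candidate m values
    cv_mcc_per_m: dict             # m -> pooled CV MCC
    chosen_m: int
    chosen_columns: list           # column indices of the winning subset


def _meta_estimator(seed: int):
    return SVC(kernel="rbf", C=1.0, probability=True, random_state=seed)


def select_feature_subset(
    ranking, pfv: PFVMatrix, y, grid=None, folds: int = 10, seed: int = 0,
    scores=None,
) -> SelectionResult:
    """Choose the top-m feature subset by cross-validated meta-MCC.

    For each candidate m an RBF-SVM meta-classifier is evaluated by
    stratified CV on the top-m ranked columns; the m with the highest
    pooled CV MCC wins, smallest m on ties.
    """
    y = np.asarray(y, dtype=int)
    width = pfv.width
    if grid is None:
        grid = list(range(10, width + 1, 10)) or [width]
    grid = sorted(set(int(m) for m in grid))
    if not grid:
        raise ConfigurationError("empty feature-subset grid")
    if any(m > width for m in grid):
        warnings.warn(
            f"grid values above PFV width {width} truncated", stacklevel=2
        )
        grid = [m for m in grid if m <= width] or [width]
    cv = _stratified_folds(y, folds, seed)
    cv_mcc = {}
    for m in grid:
        cols = ranking[:m]
        preds = cross_val_predict(
            _meta_estimator(seed), pfv.matrix[:, cols], y, cv=cv, n_jobs=1
        )
        cv_mcc[m] = compute_metrics(confusion(y, preds)).mcc
    best = max(cv_mcc.values())
    chosen_m = min(m for m in grid if cv_mcc[m] == best)
    return SelectionResult(
        ranking=np.asarray(ranking),
        scores=np.asarray(scores) if scores is not None else np.array([]),
        grid=grid,
        cv_mcc_per_m=cv_mcc,
        chosen_m=chosen_m,
        chosen_columns=list(np.asarray(ranking)[:chosen_m]),
    )


@dataclass
class MetaModel:
    """End-to-end artifact: base models + selection + meta-classifier."""

    base: BaseMatrix
    selection: SelectionResult
    meta: object                   # fitted SVC
    decision_threshold: float = 0.5
    featurizer_families: tuple = ()
    registry_dims: dict = field(default_factory=dict)

    def predict_from_blocks(self, blocks: dict) -> np.ndarray:
        pfv = build_pfv(blocks, self.base, mode="apply")
        proba = self.meta.predict_proba(pfv.select(self.selection.chosen_columns))
        return np.round(np.clip(proba[:, 1], 0.0, 1.0), 12)

    def save(self, path) -> None:
        from .featurize import FAMILY_REGISTRY
        import rdkit

        joblib.dump(
            {
                "model": self,
                "registry": {f: FAMILY_REGISTRY[f][0] for f in FAMILY_REGISTRY},
                "rdkit_version": rdkit.__version__,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "MetaModel":
        from .featurize import FAMILY_REGISTRY

        bundle = joblib.load(path)
        current = {f: FAMILY_REGISTRY[f][0] for f in FAMILY_REGISTRY}
        if bundle["registry"] != current:
            raise ConfigurationError(
                "model artifact was built against a different feature "
                f"registry: {bundle['registry']} != {current}"
            )
        return bundle["model"]


def fit_meta(pfv: PFVMatrix, y, selection: SelectionResult,
             threshold: float = 0.5, seed: int = 0,
             base: BaseMatrix | None = None,
             families: tuple = ()) -> MetaModel:
    """Fit the final SVM meta-classifier on the selected columns."""
    if max(selection.chosen_columns, default=-1) >= pfv.width:
        raise InvariantViolationError(
            "selection refers to columns beyond the PFV width"
        )
    y = np.asarray(y, dtype=int)
    meta = _meta_estimator(seed)
    meta.fit(pfv.select(selection.chosen_columns), y)
    return MetaModel(
        base=base, selection=selection, meta=meta,
        decision_threshold=threshold, featurizer_families=tuple(families),
    )


def fit_stack(blocks: dict, y, config: StackConfig | None = None):
    """Train the full stack from descriptor blocks and labels.

    Returns (MetaModel, training PFVMatrix).  ``blocks`` maps family
    name → feature matrix; families listed in the config must be
    present.  The positive class (label 1) is treated as the majority
    class when forming balanced subsets if it is the larger one.
    """
    from .sampling import make_balanced_subsets

    config = config or StackConfig()
    y = np.asarray(y, dtype=int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    maj, mino = (pos, neg) if len(pos) >= len(neg) else (neg, pos)
    subsets = make_balanced_subsets(maj, mino, k=config.k, seed=config.seed)
    base = train_base_matrix(blocks, y, subsets, config)
    pfv = build_pfv(blocks, base, mode="train")
    ranking, scores = rank_pfs_mdgi(
        pfv, y, seed=config.seed, n_seeds=config.mdgi_seeds
    )
    selection = select_feature_subset(
        ranking, pfv, y,
        grid=config.selection_grid,
        folds=config.selection_folds,
        seed=config.seed + 1,       # meta folds re-seeded independently
        scores=scores,
    )
    model = fit_meta(
        pfv, y, selection, threshold=config.decision_threshold,
        seed=config.seed, base=base, families=config.families,
    )
    return model, pfv


def predict(meta: MetaModel, smiles_list) -> pd.DataFrame:
    """Score SMILES end to end: standardize → descriptors → stack.

    Unparsable SMILES yield an error row (NaN probability) and the batch
    continues.
    """
    from .featurize import compute_descriptor_block, standardize_structure

    std, ok_idx, errors = [], [], {}
    for i, smi in enumerate(smiles_list):
        try:
            std.append(standardize_structure(smi))
            ok_idx.append(i)
        except SmilesParseError as exc:
            errors[i] = str(exc)
    n = len(smiles_list)
    proba = np.full(n, np.nan)
    if std:
        blocks = {
            fam: compute_descriptor_block(std, fam).matrix
            for fam in meta.featurizer_families
        }
        proba[ok_idx] = meta.predict_from_blocks(blocks)
    labels = np.where(
        np.isnan(proba), None,
        np.where(proba >= meta.decision_threshold, "active", "inactive"),
    )
    return pd.DataFrame(
        {
            "smiles": list(smiles_list),
            "probability": proba,
            "label": labels,
            "error": [errors.get(i) for i in range(n)],
        }
    )


def screen_library(meta: MetaModel, smiles_list, top_n: int | None = None
                   ) -> pd.DataFrame:
    """Rank a SMILES library by predicted activity probability.

    Descending probability, ties kept in input order; unparsable
    entries sink to the bottom.  ``top_n`` beyond the library size
    returns the full list with a warning.
    """
    table = predict(meta, smiles_list)
    table["input_position"] = np.arange(len(table))
    table = table.sort_values(
        ["probability", "input_position"],
        ascending=[False, True],
        kind="stable",
        na_position="last",
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    if top_n is not None:
        if top_n > len(table):
            warnings.warn(
                f"top_n={top_n} exceeds library size {len(table)}; "
                "returning the full ranking"
            )
        table = table.head(top_n)
    return table.drop(columns=["input_position"])
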