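"""Random-forest yield classification about a cutoff.

Specimens are labelled high- or low-yielding about a cutoff (default
40 ton ha^-1, above the regional average of ~30).  A random forest
relates the label to the survey features under stratified k-fold
cross-validation; AUC and classification accuracy (CA) are computed
from out-of-fold predictions, and the confusion matrix partitions the
specimens into true negatives (high-yielding, predicted balanced),
false negatives, false positives and true positives.  The TN quadrant
is the raw material of the diagnostic reference bank.

Convention: the *positive* class is "low-yielding / nutritionally
imbalanced"; high-yielding is the negative condition, so a correctly
classified high-yielder is a true negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder

from .coda import CodaError, ConfigurationError, NUTRIENTS, ValidationError
from .io import observations_to_frame
from .simulate import (
    DENSITY_FIELDS,
    MONTHS,
    ObservationRecord,
    SOIL_TEST_FIELDS,
    TEXTURE_FIELDS,
    FERTILIZER_ELEMENTS,
)

__all__ = [
    "DEFAULT_CUTOFF",
    "FEATURE_BLOCKS",
    "DEFAULT_LADDER",
    "YieldClassLabel",
    "ConfusionQuadrants",
    "AblationRow",
    "CvConfig",
    "ClassifierResult",
    "label_yield_class",
    "train_classifier",
    "confusion_partition",
    "ablation_study",
]

DEFAULT_CUTOFF = 40.0

#: Named feature blocks over the observation CSV schema.
FEATURE_BLOCKS: dict[str, tuple[str, ...]] = {
    "region": ("region",),
    "cultivar": ("cultivar",),
    "farming_system": ("farming_system",),
    "fertilization": tuple(f"fert_{e}" for e in FERTILIZER_ELEMENTS),
    "tissue_test": tuple(f"tissue_{p}" for p in NUTRIENTS),
    "soil_test": tuple(f"soil_{s}" for s in SOIL_TEST_FIELDS),
    "texture": tuple(f"texture_{t}" for t in TEXTURE_FIELDS),
    "density": DENSITY_FIELDS,
    "soil_series": ("soil_series",),
    "climate": tuple(f"temp_{m}" for m in MONTHS) + tuple(f"precip_{m}" for m in MONTHS),
}

_CATEGORICAL = {"region", "cultivar", "farming_system", "soil_series"}

#: Feature-set ladder for the ablation study: cumulative factor
#: combinations from region+cultivar alone up to the full feature set.
DEFAULT_LADDER: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("region+cultivar", ("region", "cultivar")),
    ("region+cultivar+climate", ("region", "cultivar", "climate")),
    ("region+cultivar+soil_test", ("region", "cultivar", "soil_test")),
    ("region+cultivar+tissue_test", ("region", "cultivar", "tissue_test")),
    ("region+cultivar+tissue_test+climate",
     ("region", "cultivar", "tissue_test", "climate")),
    ("region+cultivar+tissue_test+soil_test",
     ("region", "cultivar", "tissue_test", "soil_test")),
    ("region+cultivar+tissue_test+soil_test+texture+density",
     ("region", "cultivar", "tissue_test", "soil_test", "texture", "density")),
    ("region+cultivar+tissue_test+soil_test+texture+density+climate",
     ("region", "cultivar", "tissue_test", "soil_test", "texture", "density", "climate")),
)


@dataclass(frozen=True)
class YieldClassLabel:
    """high/low yield class about a cutoff; high requires strictly exceeding it."""

    value: str
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if self.value not in ("high", "low"):
            raise ValidationError(f"label must be 'high' or 'low', got {self.value!r}")


def label_yield_class(yield_t: float, cutoff: float = DEFAULT_CUTOFF) -> YieldClassLabel:
    """Label a yield: high iff it strictly exceeds the cutoff."""
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be > 0, got {cutoff}")
    if yield_t < 0:
        raise ValidationError(f"yield must be >= 0, got {yield_t}")
    return YieldClassLabel("high" if yield_t > cutoff else "low", cutoff=cutoff)


@dataclass(frozen=True)
class CvConfig:
    """Cross-validation settings: k ∈ {5, 10, 20}, seeded and stratified."""

    folds: int = 10
    seed: int = 0
    n_estimators: int = 500

    def __post_init__(self) -> None:
        if self.folds not in (5, 10, 20):
            raise ConfigurationError(f"folds must be one of 5, 10, 20; got {self.folds}")


@dataclass(frozen=True)
class ConfusionQuadrants:
    """Out-of-fold confusion-matrix partition of the evaluated records.

    tn: high-yielding, predicted balanced (the diagnostic standards);
    fn: low-yielding, predicted balanced;
    fp: high-yielding, predicted imbalanced (discarded from standards);
    tp: low-yielding, predicted imbalanced.
    """

    tn: tuple = ()
    fn: tuple = ()
    fp: tuple = ()
    tp: tuple = ()

    @property
    def counts(self) -> dict[str, int]:
        return {"tn": len(self.tn), "fn": len(self.fn),
                "fp": len(self.fp), "tp": len(self.tp)}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def ca(self) -> float:
        """Classification accuracy: (TN + TP) / total."""
        return (len(self.tn) + len(self.tp)) / self.total


@dataclass(frozen=True)
class AblationRow:
    feature_set: str
    auc: float
    ca: float


@dataclass
class ClassifierResult:
    """A fitted forest plus its out-of-fold cross-validation record."""

    model: Pipeline
    feature_columns: tuple[str, ...]
    cutoff: float
    cv: CvConfig
    keys: tuple                  # record keys in canonical evaluation order
    y_true_low: np.ndarray       # observed positive (low-yield) indicator
    oof_prob_low: np.ndarray     # out-of-fold P(low yield)
    auc: float
    ca: float

    @property
    def informative(self) -> bool:
        """AUC > 0.7 marks the model informative."""
        return self.auc > 0.7

    @property
    def oof_pred_low(self) -> np.ndarray:
        # probability ties at 0.5 resolve to imbalanced (positive)
        return self.oof_prob_low >= 0.5

    def prob_exceed_cutoff(self, record: ObservationRecord) -> float:
        """Refit-model probability that a specimen exceeds the yield cutoff."""
        X = _design_frame([record], self.feature_columns)
        p_low = self.model.predict_proba(X)[0, 1]
        return float(1.0 - p_low)


def _resolve_features(feature_set: Sequence[str]) -> tuple[str, ...]:
    cols: list[str] = []
    for block in feature_set:
        if block not in FEATURE_BLOCKS:
            raise ConfigurationError(
                f"unknown feature block {block!r}; known: {sorted(FEATURE_BLOCKS)}"
            )
        cols.extend(FEATURE_BLOCKS[block])
    if not cols:
        raise ConfigurationError("feature set is empty")
    return tuple(cols)


def _design_frame(records: Sequence[ObservationRecord] | pd.DataFrame,
                  columns: Sequence[str]) -> pd.DataFrame:
    df = records if isinstance(records, pd.DataFrame) else observations_to_frame(records)
    return df[list(columns)]


def _make_pipeline(columns: Sequence[str], cv: CvConfig) -> Pipeline:
    cat = [c for c in columns if c in _CATEGORICAL]
    num = [c for c in columns if c not in _CATEGORICAL]
    pre = ColumnTransformer(
        [("cat", OneHotEncoder(handle_unknown="ignore"), cat),
         ("num", "passthrough", num)]
    )
    forest = RandomForestClassifier(
        n_estimators=cv.n_estimators,
        max_features="sqrt",
        random_state=cv.seed,
        n_jobs=1,
    )
    return Pipeline([("prep", pre), ("forest", forest)])


def _canonical_order(records: Sequence[ObservationRecord]) -> list[ObservationRecord]:
    # canonical key sort makes CV metrics invariant to input record order
    return sorted(records, key=lambda r: r.key)


def train_classifier(
    records: Sequence[ObservationRecord],
    feature_set: Sequence[str] = ("region", "cultivar", "tissue_test", "soil_test",
                                  "texture", "density", "climate"),
    cutoff: float = DEFAULT_CUTOFF,
    cv: CvConfig | None = None,
) -> ClassifierResult:
    """Train the yield classifier and evaluate it out-of-fold.

    Features are the named blocks of :data:`FEATURE_BLOCKS`; categorical
    blocks are one-hot encoded.  Stratified k-fold CV (seeded) yields
    out-of-fold probabilities from which AUC and CA are computed; the
    returned model itself is refit on all records for probability
    reporting on new specimens.
    """
    cv = cv or CvConfig()
    recs = _canonical_order(records)
    columns = _resolve_features(feature_set)
    X = _design_frame(recs, columns)
    y = np.array([label_yield_class(r.yield_t, cutoff).value == "low" for r in recs])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError(
            "all records fall in a single yield class; classification is degenerate"
        )
    if counts.min() < cv.folds:
        raise ValidationError(
            f"smallest class has {counts.min()} records, fewer than {cv.folds} folds"
        )
    splitter = StratifiedKFold(n_splits=cv.folds, shuffle=True, random_state=cv.seed)
    oof = np.full(len(recs), np.nan)
    for train_idx, test_idx in splitter.split(X, y):
        pipe = _make_pipeline(columns, cv)
        pipe.fit(X.iloc[train_idx], y[train_idx])
        oof[test_idx] = pipe.predict_proba(X.iloc[test_idx])[:, 1]
    auc = float(roc_auc_score(y, oof))
    pred = oof >= 0.5
    ca = float((pred == y).mean())
    final = _make_pipeline(columns, cv)
    final.fit(X, y)
    return ClassifierResult(
        model=final,
        feature_columns=columns,
        cutoff=cutoff,
        cv=cv,
        keys=tuple(r.key for r in recs),
        y_true_low=y,
        oof_prob_low=oof,
        auc=auc,
        ca=ca,
    )


def confusion_partition(result: ClassifierResult) -> ConfusionQuadrants:
    """Partition the evaluated records into confusion-matrix quadrants.

    Uses the out-of-fold predictions held by the classifier result;
    training-set predictions are never used, so the TN bank is not
    optimistically inflated.
    """
    if np.isnan(result.oof_prob_low).any():
        raise ValidationError("out-of-fold predictions are incomplete")
    pred_low = result.oof_pred_low
    quad: dict[str, list] = {"tn": [], "fn": [], "fp": [], "tp": []}
    for key, is_low, p_low in zip(result.keys, result.y_true_low, pred_low):
        if is_low:
            quad["tp" if p_low else "fn"].append(key)
        else:
            quad["fp" if p_low else "tn"].append(key)
    return ConfusionQuadrants(**{k: tuple(v) for k, v in quad.items()})


def ablation_study(
    records: Sequence[ObservationRecord],
    ladder: Sequence[tuple[str, Sequence[str]]] = DEFAULT_LADDER,
    cutoff: float = DEFAULT_CUTOFF,
    cv: CvConfig | None = None,
) -> list[AblationRow]:
    """AUC/CA for each named feature subset under shared folds and seed.

    The same seeded stratified folds are used for every subset so rows
    are directly (paired) comparable.
    """
    cv = cv or CvConfig()
    if not ladder:
        raise ConfigurationError("ablation ladder is empty")
    rows = []
    for name, feature_set in ladder:
        res = train_classifier(records, feature_set, cutoff=cutoff, cv=cv)
        rows.append(AblationRow(feature_set=name, auc=res.auc, ca=res.ca))
    return rows
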