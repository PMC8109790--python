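"""Lagged-panel assembly and next-year yield modelling.

Carbohydrate and nutrient reserves built in year t influence yield in
year t+1.  The panel pairs each bed-year with its observed successor
year, and random-forest regressions relate next-year yield Y_{t+1} to
nested feature blocks: current tissue composition C_t (as ilr
coordinates), fertilization F_t, current yield Y_t and soil tests.
A next-year classifier about the yield cutoff yields a predictive
true-negative bank against which a specimen can be diagnosed for the
coming season.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import r2_score, roc_auc_score
from sklearn.model_selection import GroupKFold, StratifiedGroupKFold

from .coda import (
    CodaError,
    ConfigurationError,
    TissueComposition,
    ValidationError,
    build_default_sbp,
    ilr_transform,
)
from .classify import ConfusionQuadrants, CvConfig, DEFAULT_CUTOFF, label_yield_class
from .diagnose import BankSpecimen, DiagnosisReport, ReferenceBank, diagnose_local
from .simulate import FERTILIZER_ELEMENTS, ObservationRecord, SOIL_TEST_FIELDS

__all__ = [
    "PanelRecord",
    "YieldFunctionSpec",
    "YIELD_FUNCTION_VARIANTS",
    "NextYearClassification",
    "assemble_panel",
    "fit_yield_functions",
    "predict_next_year_class",
    "build_next_year_bank",
    "predictive_diagnosis",
]


@dataclass(frozen=True)
class PanelRecord:
    """One bed-year with an observed successor year."""

    bed: tuple                    # (region, site, bed)
    year: int
    composition: TissueComposition
    fertilization: dict[str, float]
    soil: dict[str, float]
    yield_t: float
    yield_next: float
    cultivar: str | None = None
    region: str | None = None

    @property
    def key(self) -> tuple:
        return (*self.bed, self.year)


@dataclass(frozen=True)
class YieldFunctionSpec:
    """One of the six nested next-year yield functions.

    Blocks: "tissue" (C_t as ilr coordinates), "fertilization" (F_t),
    "yield" (Y_t), "soil_test".
    """

    variant: int
    blocks: tuple[str, ...]

    def __post_init__(self) -> None:
        known = {"tissue", "fertilization", "yield", "soil_test"}
        bad = set(self.blocks) - known
        if bad:
            raise ConfigurationError(f"unknown feature block(s) {sorted(bad)}")
        if not self.blocks:
            raise ConfigurationError("yield function needs at least one block")


#: The six yield-function variants, from composition alone to the full
#: lagged feature set.
YIELD_FUNCTION_VARIANTS: tuple[YieldFunctionSpec, ...] = (
    YieldFunctionSpec(1, ("tissue",)),
    YieldFunctionSpec(2, ("tissue", "fertilization")),
    YieldFunctionSpec(3, ("tissue", "fertilization", "yield")),
    YieldFunctionSpec(4, ("fertilization", "yield", "soil_test")),
    YieldFunctionSpec(5, ("tissue", "yield", "soil_test")),
    YieldFunctionSpec(6, ("tissue", "fertilization", "yield", "soil_test")),
)


def assemble_panel(
    records: Sequence[ObservationRecord],
    exclude: Iterable[tuple[str, int]] = (),
) -> list[PanelRecord]:
    """Pair each bed-year with its consecutive successor year.

    ``exclude`` lists (site, year) pairs to drop before pairing (e.g.
    frost-damaged site-years); a bed-year forms a row only when year t+1
    of the same bed survives the exclusion.  Duplicate (bed, year)
    observations are a data-integrity error.
    """
    excluded = set(exclude)
    kept: dict[tuple, ObservationRecord] = {}
    for r in records:
        if (r.site, r.year) in excluded:
            continue
        bed_key = (r.region, r.site, r.bed)
        if (bed_key, r.year) in kept:
            raise ValidationError(
                f"duplicate observation for bed {bed_key} year {r.year}"
            )
        kept[(bed_key, r.year)] = r
    panel: list[PanelRecord] = []
    for (bed_key, year), r in sorted(kept.items()):
        nxt = kept.get((bed_key, year + 1))
        if nxt is None:
            continue
        panel.append(PanelRecord(
            bed=bed_key,
            year=year,
            composition=r.composition,
            fertilization=dict(r.fertilization),
            soil=dict(r.soil),
            yield_t=r.yield_t,
            yield_next=nxt.yield_t,
            cultivar=r.cultivar,
            region=r.region,
        ))
    return panel


_SBP = build_default_sbp()


def _bed_groups(panel: Sequence[PanelRecord]) -> np.ndarray:
    """Stable integer group labels, one per bed."""
    beds = sorted({p.bed for p in panel})
    index = {b: i for i, b in enumerate(beds)}
    return np.array([index[p.bed] for p in panel])


def _panel_design(panel: Sequence[PanelRecord], blocks: Sequence[str],
                  use_ilr: bool = True) -> pd.DataFrame:
    cols: dict[str, list[float]] = {}
    if "tissue" in blocks:
        if use_ilr:
            ilrs = np.vstack([ilr_transform(p.composition, _SBP).values for p in panel])
            for i in range(ilrs.shape[1]):
                cols[f"ilr_{i + 1}"] = ilrs[:, i].tolist()
        else:
            for i, part in enumerate(panel[0].composition.parts):
                cols[f"tissue_{part}"] = [p.composition.values[i] for p in panel]
    if "fertilization" in blocks:
        for e in FERTILIZER_ELEMENTS:
            cols[f"fert_{e}"] = [p.fertilization[e] for p in panel]
    if "yield" in blocks:
        cols["yield_t"] = [p.yield_t for p in panel]
    if "soil_test" in blocks:
        for s in SOIL_TEST_FIELDS:
            cols[f"soil_{s}"] = [p.soil[s] for p in panel]
    return pd.DataFrame(cols)


def fit_yield_functions(
    panel: Sequence[PanelRecord],
    variants: Sequence[YieldFunctionSpec] = YIELD_FUNCTION_VARIANTS,
    cv: CvConfig | None = None,
    use_ilr: bool = True,
) -> dict[int, float]:
    """Out-of-fold R² of each yield-function variant.

    Folds are grouped by bed so that no bed contributes to both the
    training and validation side of a split (years of the same bed are
    not independent), and the same folds and forest seed are shared by
    every variant for paired comparison.
    """
    cv = cv or CvConfig()
    panel = sorted(panel, key=lambda p: p.key)
    if len(panel) < 2 * cv.folds:
        raise ValidationError(f"panel of {len(panel)} rows is too small for {cv.folds} folds")
    y = np.array([p.yield_next for p in panel])
    if np.ptp(y) == 0:
        raise ValidationError("next-year yield is constant; R² is undefined")
    groups = _bed_groups(panel)
    splitter = GroupKFold(n_splits=cv.folds, shuffle=True, random_state=cv.seed)
    folds = list(splitter.split(np.zeros(len(panel)), y, groups))
    out: dict[int, float] = {}
    for spec in variants:
        X = _panel_design(panel, spec.blocks, use_ilr=use_ilr)
        oof = np.full(len(panel), np.nan)
        for train_idx, test_idx in folds:
            forest = RandomForestRegressor(
                n_estimators=cv.n_estimators, max_features="sqrt",
                random_state=cv.seed, n_jobs=1,
            )
            forest.fit(X.iloc[train_idx], y[train_idx])
            oof[test_idx] = forest.predict(X.iloc[test_idx])
        out[spec.variant] = float(r2_score(y, oof))
    return out


@dataclass(frozen=True)
class NextYearClassification:
    """Out-of-fold next-year classification about the cutoff."""

    quadrants: ConfusionQuadrants
    ca: float
    auc: float
    keys: tuple
    oof_prob_low: np.ndarray
    pred_yield_next: np.ndarray | None = None


def predict_next_year_class(
    panel: Sequence[PanelRecord],
    cutoff: float = DEFAULT_CUTOFF,
    cv: CvConfig | None = None,
    use_ilr: bool = True,
) -> NextYearClassification:
    """Classify next-year yield about the cutoff from current-year features.

    Uses the full variant-6 feature block (C_t, F_t, Y_t, soil test).
    Quadrants are out-of-fold: a panel row is a next-year true negative
    when its observed Y_{t+1} exceeds the cutoff and its predicted class
    is balanced.
    """
    cv = cv or CvConfig()
    panel = sorted(panel, key=lambda p: p.key)
    X = _panel_design(panel, ("tissue", "fertilization", "yield", "soil_test"),
                      use_ilr=use_ilr)
    y = np.array([label_yield_class(p.yield_next, cutoff).value == "low" for p in panel])
    if len(np.unique(y)) < 2:
        raise ValidationError("all panel rows fall in a single next-year class")
    groups = _bed_groups(panel)
    splitter = StratifiedGroupKFold(n_splits=cv.folds, shuffle=True, random_state=cv.seed)
    oof = np.full(len(panel), np.nan)
    for train_idx, test_idx in splitter.split(X, y, groups):
        forest = RandomForestClassifier(
            n_estimators=cv.n_estimators, max_features="sqrt",
            random_state=cv.seed, n_jobs=1,
        )
        forest.fit(X.iloc[train_idx], y[train_idx])
        oof[test_idx] = forest.predict_proba(X.iloc[test_idx])[:, 1]
    pred_low = oof >= 0.5
    quad: dict[str, list] = {"tn": [], "fn": [], "fp": [], "tp": []}
    for p, is_low, pl in zip(panel, y, pred_low):
        if is_low:
            quad["tp" if pl else "fn"].append(p.key)
        else:
            quad["fp" if pl else "tn"].append(p.key)
    quadrants = ConfusionQuadrants(**{k: tuple(v) for k, v in quad.items()})
    return NextYearClassification(
        quadrants=quadrants,
        ca=quadrants.ca,
        auc=float(roc_auc_score(y, oof)),
        keys=tuple(p.key for p in panel),
        oof_prob_low=oof,
    )


def build_next_year_bank(
    panel: Sequence[PanelRecord],
    result: NextYearClassification,
    cutoff: float = DEFAULT_CUTOFF,
) -> ReferenceBank:
    """Next-year TN bank: current-year compositions of beds whose observed
    next-year yield exceeded the cutoff and were predicted balanced."""
    by_key = {p.key: p for p in panel}
    specimens = tuple(
        BankSpecimen(
            key=key,
            composition=by_key[key].composition,
            yield_t=by_key[key].yield_next,
            cultivar=by_key[key].cultivar,
            region=by_key[key].region,
        )
        for key in result.quadrants.tn
    )
    if not specimens:
        raise ValidationError("next-year classification produced no true negatives")
    return ReferenceBank(specimens, cutoff=cutoff, scope_note="next-year TN")


def predictive_diagnosis(
    record: ObservationRecord,
    next_year_bank: ReferenceBank,
    filter_policy: str = "cultivar",
) -> DiagnosisReport:
    """Diagnose a specimen against the next-year reference bank.

    Mechanics are identical to local diagnosis; the attainable yield is
    the reference bed's next-year yield and the scope is "predictive".
    """
    return diagnose_local(record, next_year_bank, model=None,
                          filter_policy=filter_policy, scope="predictive")
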