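"""Reference banks and factor-specific nutrient diagnosis.

True-negative specimens — high-yielding and predicted nutritionally
balanced out-of-fold — form the reference bank.  A defective specimen
is diagnosed locally against its nearest successful neighbour in the
Aitchison (clr-space Euclidean) metric, whose yield is the attainable
yield, or regionally against the re-closed average composition of the
whole bank.  The perturbation vector diagnosed ⊖ reference ranks
nutrients by |ln ratio| as relative excess (>1) or shortage (<1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .coda import (
    NUTRIENTS,
    PARTS,
    TOTAL_MASS,
    CodaError,
    NutrientRanking,
    PerturbationVector,
    TissueComposition,
    ValidationError,
    aitchison_distance,
    perturbation,
    rank_nutrients,
)
from .classify import ClassifierResult, ConfusionQuadrants, label_yield_class
from .simulate import ObservationRecord

__all__ = [
    "EmptyBankError",
    "EmptyNeighborhoodError",
    "BankSpecimen",
    "ReferenceBank",
    "DiagnosisReport",
    "build_reference_bank",
    "nearest_successful",
    "diagnose_local",
    "diagnose_regional",
    "quartile_ranges",
]


class EmptyBankError(CodaError):
    """No reference specimens are available."""


class EmptyNeighborhoodError(CodaError):
    """Feature filters eliminated every bank candidate."""


@dataclass(frozen=True)
class BankSpecimen:
    """One diagnostic standard: a balanced, high-yielding observation."""

    key: tuple
    composition: TissueComposition
    yield_t: float
    cultivar: str | None = None
    region: str | None = None
    from_false_negative: bool = False


@dataclass(frozen=True)
class ReferenceBank:
    """The true-negative specimens used as diagnostic standards."""

    specimens: tuple[BankSpecimen, ...]
    cutoff: float
    scope_note: str = ""

    def __len__(self) -> int:
        return len(self.specimens)

    @property
    def cultivars(self) -> set[str]:
        return {s.cultivar for s in self.specimens if s.cultivar is not None}

    def mean_composition(self, geometric: bool = False) -> TissueComposition:
        """Component-wise bank average, re-closed to 1000 g kg^-1.

        Arithmetic by default; the geometric alternative is available
        because the averaging convention behind published regional rows
        is not always stated.
        """
        if not self.specimens:
            raise EmptyBankError("cannot average an empty reference bank")
        mat = np.vstack([s.composition.values for s in self.specimens])
        avg = np.exp(np.log(mat).mean(axis=0)) if geometric else mat.mean(axis=0)
        return TissueComposition(avg * (TOTAL_MASS / avg.sum()))


@dataclass(frozen=True)
class DiagnosisReport:
    """The full diagnostic readout for one specimen."""

    diagnosed_key: tuple
    scope: str                       # "local" | "regional" | "predictive"
    reference_key: tuple | str       # bank key or "TN-average"
    distance: float
    ratios: dict[str, float]         # raw diagnosed/reference ratios
    ranking: NutrientRanking
    attainable_yield: float | None = None
    probability_exceed_cutoff: float | None = None
    filters_used: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValidationError("distance must be >= 0")

    def to_dict(self) -> dict:
        """Deterministically ordered JSON document; distances shown at
        2 d.p. with full precision in the raw block."""
        entries = [
            {"part": e.part, "ratio": round(e.ratio, 4),
             "log_ratio": round(e.log_ratio, 4), "status": e.status}
            for e in self.ranking.entries
        ]
        return {
            "diagnosed": list(self.diagnosed_key),
            "scope": self.scope,
            "reference": (list(self.reference_key)
                          if isinstance(self.reference_key, tuple)
                          else self.reference_key),
            "distance": round(self.distance, 2),
            "attainable_yield": self.attainable_yield,
            "probability_exceed_cutoff": self.probability_exceed_cutoff,
            "excess": self.ranking.excess,
            "shortage": self.ranking.shortage,
            "ranking": entries,
            "filters_used": dict(self.filters_used),
            "raw": {
                "distance": self.distance,
                "ratios": {p: self.ratios[p] for p in PARTS},
            },
        }


def build_reference_bank(
    records: Sequence[ObservationRecord],
    quadrants: ConfusionQuadrants,
    cutoff: float,
    include_fn: bool = False,
) -> ReferenceBank:
    """Collect the true-negative specimens (optionally plus flagged FNs).

    False positives and true positives are never admitted: high tissue
    levels at low yield would bias the standards exactly the way the
    confusion-matrix screen is meant to prevent.
    """
    by_key = {r.key: r for r in records}
    specimens: list[BankSpecimen] = []
    for key in quadrants.tn:
        r = by_key[key]
        specimens.append(BankSpecimen(key, r.composition, r.yield_t,
                                      cultivar=r.cultivar, region=r.region))
    if include_fn:
        for key in quadrants.fn:
            r = by_key[key]
            specimens.append(BankSpecimen(key, r.composition, r.yield_t,
                                          cultivar=r.cultivar, region=r.region,
                                          from_false_negative=True))
    if not specimens:
        raise EmptyBankError(
            "no true-negative specimens; consider include_fn=True to admit "
            "balanced false negatives as additional benchmarks"
        )
    return ReferenceBank(tuple(specimens), cutoff=cutoff,
                         scope_note="TN" + ("+FN" if include_fn else ""))


def _filter_bank(bank: ReferenceBank, filters: Mapping[str, str] | None) -> list[BankSpecimen]:
    candidates = list(bank.specimens)
    if filters:
        for attr, value in filters.items():
            if attr not in ("cultivar", "region"):
                raise ValidationError(f"unsupported filter {attr!r}")
            candidates = [s for s in candidates if getattr(s, attr) == value]
        if not candidates:
            raise EmptyNeighborhoodError(
                f"no bank specimens left after filters {dict(filters)}"
            )
    return candidates


def nearest_successful(
    specimen: TissueComposition,
    bank: ReferenceBank,
    filters: Mapping[str, str] | None = None,
) -> tuple[BankSpecimen, float]:
    """The bank specimen at minimum Aitchison distance.

    Ties break to the higher yield, then to key order, so the result is
    invariant to bank ordering.
    """
    if not bank.specimens:
        raise EmptyBankError("reference bank is empty")
    candidates = _filter_bank(bank, filters)
    best = min(candidates,
               key=lambda s: (aitchison_distance(specimen, s.composition),
                              -s.yield_t, s.key))
    return best, aitchison_distance(specimen, best.composition)


def _default_filters(record: ObservationRecord, bank: ReferenceBank,
                     filter_policy: str) -> dict[str, str]:
    # default policy: constrain to same cultivar when the bank has it
    if filter_policy == "cultivar" and record.cultivar in bank.cultivars:
        return {"cultivar": record.cultivar}
    if filter_policy == "cultivar+region":
        f = {}
        if record.cultivar in bank.cultivars:
            f["cultivar"] = record.cultivar
        if any(s.region == record.region for s in bank.specimens):
            f["region"] = record.region
        return f
    return {}


def diagnose_local(
    record: ObservationRecord,
    bank: ReferenceBank,
    model: ClassifierResult | None = None,
    filter_policy: str = "cultivar",
    scope: str = "local",
) -> DiagnosisReport:
    """Diagnose a specimen against its nearest successful neighbour.

    The neighbour's yield is reported as the attainable yield; the
    perturbation vector diagnosed ⊖ reference ranks the nutrients.
    When a trained classifier is supplied, its refit probability of
    exceeding the yield cutoff is carried in the report.
    """
    filters = _default_filters(record, bank, filter_policy)
    ref, eps = nearest_successful(record.composition, bank, filters or None)
    p = perturbation(record.composition, ref.composition)
    report = DiagnosisReport(
        diagnosed_key=record.key,
        scope=scope,
        reference_key=ref.key,
        distance=eps,
        ratios=dict(p.ratios),
        ranking=rank_nutrients(p),
        attainable_yield=ref.yield_t,
        probability_exceed_cutoff=(
            model.prob_exceed_cutoff(record) if model is not None else None
        ),
        filters_used={k: v for k, v in filters.items()},
    )
    return report


def diagnose_regional(
    record: ObservationRecord,
    bank: ReferenceBank,
    model: ClassifierResult | None = None,
    geometric: bool = False,
) -> DiagnosisReport:
    """Diagnose a specimen against the bank-average composition.

    The regional reference is a statistical construct, so no attainable
    yield is reported.
    """
    reference = bank.mean_composition(geometric=geometric)
    eps = aitchison_distance(record.composition, reference)
    p = perturbation(record.composition, reference)
    return DiagnosisReport(
        diagnosed_key=record.key,
        scope="regional",
        reference_key="TN-average",
        distance=eps,
        ratios=dict(p.ratios),
        ranking=rank_nutrients(p),
        attainable_yield=None,
        probability_exceed_cutoff=(
            model.prob_exceed_cutoff(record) if model is not None else None
        ),
    )


def quartile_ranges(bank: ReferenceBank) -> dict[str, tuple[float, float]]:
    """First/third quartiles of each raw nutrient concentration over the
    bank (linear-interpolation quantile definition)."""
    if len(bank) < 4:
        raise ValidationError(
            f"quartile ranges need at least 4 bank specimens, got {len(bank)}"
        )
    mat = np.vstack([s.composition.values[:10] for s in bank.specimens])
    q1 = np.quantile(mat, 0.25, axis=0, method="linear")
    q3 = np.quantile(mat, 0.75, axis=0, method="linear")
    return {p: (float(a), float(b)) for p, a, b in zip(NUTRIENTS, q1, q3)}
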