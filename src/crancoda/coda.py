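"""Compositional (log-ratio) representation of cranberry tissue tests.

Tissue nutrient concentrations live on the simplex: the ten measured
nutrients plus a filling value (Fv) that completes the dry-weight
measurement unit of 1000 g kg^-1.  All diagnostic geometry — centred
log-ratios (clr), isometric log-ratios (ilr) under a sequential binary
partition (SBP), the Aitchison distance between a defective and a
successful composition, and the perturbation vector that ranks nutrients
as relative excess or shortage — is defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PARTS",
    "NUTRIENTS",
    "MACRONUTRIENTS",
    "MICRONUTRIENTS",
    "TOTAL_MASS",
    "CodaError",
    "ValidationError",
    "InfeasibleCompositionError",
    "ConfigurationError",
    "TissueComposition",
    "ClrCoordinates",
    "IlrCoordinates",
    "SequentialBinaryPartition",
    "PerturbationVector",
    "NutrientRanking",
    "RankedNutrient",
    "close_composition",
    "clr_transform",
    "ilr_transform",
    "aitchison_distance",
    "perturbation",
    "perturb_composition",
    "rank_nutrients",
    "build_default_sbp",
]

#: Fixed part order of the 11-part tissue composition.
PARTS: tuple[str, ...] = ("N", "P", "K", "Mg", "Ca", "B", "Cu", "Zn", "Mn", "Fe", "Fv")
NUTRIENTS: tuple[str, ...] = PARTS[:10]
MACRONUTRIENTS: tuple[str, ...] = ("N", "P", "K", "Mg", "Ca")
MICRONUTRIENTS: tuple[str, ...] = ("B", "Cu", "Zn", "Mn", "Fe")

#: Dry-weight measurement unit, g kg^-1.
TOTAL_MASS: float = 1000.0

_D = len(PARTS)
_CLOSURE_ATOL = 1e-6


class CodaError(Exception):
    """Base class for compositional-data errors."""


class ValidationError(CodaError):
    """A value violates a type invariant (non-positive part, part mismatch...)."""


class InfeasibleCompositionError(CodaError):
    """Nutrient concentrations sum to >= 1000 g kg^-1, leaving no filling value."""


class ConfigurationError(CodaError):
    """An SBP or option is inconsistent with the fixed part order."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueComposition:
    """An 11-part closed tissue composition (g kg^-1 dry weight).

    Parts follow :data:`PARTS`; the last part is the filling value
    Fv = 1000 − sum(nutrients).  All parts must be strictly positive and
    sum to 1000 within 1e-6.
    """

    values: np.ndarray

    def __init__(self, values: Sequence[float] | Mapping[str, float]):
        if isinstance(values, Mapping):
            missing = [p for p in PARTS if p not in values]
            if missing:
                raise ValidationError(f"missing part(s): {', '.join(missing)}")
            arr = np.array([float(values[p]) for p in PARTS])
        else:
            arr = np.asarray(values, dtype=float)
        if arr.shape != (_D,):
            raise ValidationError(
                f"expected {_D} parts in order {PARTS}, got shape {arr.shape}"
            )
        for label, v in zip(PARTS, arr):
            if not (v > 0) or not math.isfinite(v):
                raise ValidationError(f"part {label!r} must be strictly positive, got {v}")
        total = float(arr.sum())
        if abs(total - TOTAL_MASS) > _CLOSURE_ATOL:
            raise ValidationError(
                f"parts must sum to {TOTAL_MASS} g/kg within {_CLOSURE_ATOL}; got {total}"
            )
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @property
    def parts(self) -> dict[str, float]:
        """Ordered label → concentration mapping."""
        return dict(zip(PARTS, self.values))

    @property
    def nutrients(self) -> np.ndarray:
        """The ten nutrient concentrations, without Fv."""
        return self.values[:10]

    @property
    def filling_value(self) -> float:
        return float(self.values[-1])

    def __getitem__(self, label: str) -> float:
        try:
            return float(self.values[PARTS.index(label)])
        except ValueError:
            raise KeyError(label) from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TissueComposition):
            return NotImplemented
        return bool(np.array_equal(self.values, other.values))

    def __hash__(self) -> int:
        return hash(self.values.tobytes())

    def isclose(self, other: "TissueComposition", atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.values, other.values, atol=atol, rtol=0.0))


@dataclass(frozen=True)
class ClrCoordinates:
    """Centred log-ratio coordinates, one per part, summing to zero."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (_D,):
            raise ValidationError(f"clr vector must have length {_D}")
        if abs(arr.sum()) > 1e-9:
            raise ValidationError(f"clr values must sum to 0, got {arr.sum()}")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    def __getitem__(self, label: str) -> float:
        return float(self.values[PARTS.index(label)])

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


@dataclass(frozen=True)
class SequentialBinaryPartition:
    """An ordered hierarchy of D−1 binary contrasts over the fixed parts.

    Each contrast is a sign vector over :data:`PARTS` with entries in
    {+1, −1, 0}; the +1 group (r parts) is contrasted against the −1
    group (s parts).  The contrasts must form a valid top-down binary
    splitting: the first splits the full part set, and every later
    contrast splits a group created by an earlier one.
    """

    contrasts: np.ndarray
    sbp_id: str = "custom"

    def __post_init__(self) -> None:
        mat = np.asarray(self.contrasts, dtype=int)
        if mat.ndim != 2 or mat.shape[1] != _D:
            raise ConfigurationError(
                f"SBP contrasts must be a (D-1, {_D}) sign matrix over {PARTS}"
            )
        if mat.shape[0] != _D - 1:
            raise ConfigurationError(
                f"a full SBP over {_D} parts needs exactly {_D - 1} contrasts, "
                f"got {mat.shape[0]}"
            )
        if not np.isin(mat, (-1, 0, 1)).all():
            raise ConfigurationError("SBP entries must be in {+1, -1, 0}")
        self._validate_hierarchy(mat)
        mat.flags.writeable = False
        object.__setattr__(self, "contrasts", mat)

    @staticmethod
    def _validate_hierarchy(mat: np.ndarray) -> None:
        # Active groups start at the full part set; each contrast must split
        # exactly one active group into its +1 and -1 halves.
        active: list[frozenset[int]] = [frozenset(range(_D))]
        for i, row in enumerate(mat):
            plus = frozenset(np.flatnonzero(row == 1).tolist())
            minus = frozenset(np.flatnonzero(row == -1).tolist())
            if not plus or not minus:
                raise ConfigurationError(
                    f"contrast {i + 1} must have at least one +1 and one -1 part"
                )
            support = plus | minus
            if support not in active:
                raise ConfigurationError(
                    f"contrast {i + 1} does not split a previously unsplit group"
                )
            active.remove(support)
            for sub in (plus, minus):
                if len(sub) > 1:
                    active.append(sub)
        if active:
            raise ConfigurationError("SBP leaves some groups unsplit")

    def r_s(self, i: int) -> tuple[int, int]:
        """Numerator and denominator part counts of contrast ``i`` (0-based)."""
        row = self.contrasts[i]
        return int((row == 1).sum()), int((row == -1).sum())

    def __len__(self) -> int:
        return self.contrasts.shape[0]


@dataclass(frozen=True)
class IlrCoordinates:
    """Isometric log-ratio coordinates under a given SBP."""

    values: np.ndarray
    sbp_id: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (_D - 1,):
            raise ValidationError(f"ilr vector must have length {_D - 1}")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


@dataclass(frozen=True)
class PerturbationVector:
    """Component-wise diagnosed/reference concentration ratios, p = X ⊖ x.

    Ratios above 1 read as relative excess of the diagnosed specimen,
    below 1 as relative shortage.  ``centered`` records whether the
    ratios were re-closed to sum to the part count.
    """

    ratios: dict[str, float]
    centered: bool = False

    def __post_init__(self) -> None:
        if tuple(self.ratios) != PARTS:
            raise ValidationError(f"perturbation ratios must cover parts {PARTS} in order")
        for label, v in self.ratios.items():
            if not (v > 0) or not math.isfinite(v):
                raise ValidationError(f"ratio for {label!r} must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.ratios[p] for p in PARTS])

    def __getitem__(self, label: str) -> float:
        return self.ratios[label]


@dataclass(frozen=True)
class RankedNutrient:
    part: str
    ratio: float
    log_ratio: float
    status: str  # "excess" | "shortage" | "balanced"


@dataclass(frozen=True)
class NutrientRanking:
    """Nutrients ordered by |ln ratio| descending, tagged by direction."""

    entries: tuple[RankedNutrient, ...]
    tolerance: float

    @property
    def excess(self) -> list[str]:
        return [e.part for e in self.entries if e.status == "excess"]

    @property
    def shortage(self) -> list[str]:
        return [e.part for e in self.entries if e.status == "shortage"]

    @property
    def top(self) -> RankedNutrient | None:
        imbalanced = [e for e in self.entries if e.status != "balanced"]
        return imbalanced[0] if imbalanced else None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def close_composition(nutrients: Sequence[float] | Mapping[str, float]) -> TissueComposition:
    """Close ten nutrient concentrations to 1000 g kg^-1 with a filling value.

    Parameters
    ----------
    nutrients
        The ten nutrient concentrations (g kg^-1 dry weight) in the fixed
        order N, P, K, Mg, Ca, B, Cu, Zn, Mn, Fe, or a mapping with those
        keys.

    Returns
    -------
    TissueComposition
        The 11-part composition with Fv = 1000 − sum(nutrients).
    """
    if isinstance(nutrients, Mapping):
        missing = [p for p in NUTRIENTS if p not in nutrients]
        if missing:
            raise ValidationError(f"missing nutrient(s): {', '.join(missing)}")
        arr = np.array([float(nutrients[p]) for p in NUTRIENTS])
    else:
        arr = np.asarray(list(nutrients), dtype=float)
    if arr.shape != (10,):
        raise ValidationError(f"expected 10 nutrient concentrations, got {arr.shape}")
    for label, v in zip(NUTRIENTS, arr):
        if not (v > 0) or not math.isfinite(v):
            raise ValidationError(f"nutrient {label!r} must be strictly positive, got {v}")
    total = float(arr.sum())
    if total >= TOTAL_MASS:
        raise InfeasibleCompositionError(
            f"nutrient concentrations sum to {total} g/kg >= {TOTAL_MASS}; "
            "no filling value remains"
        )
    return TissueComposition(np.append(arr, TOTAL_MASS - total))


def clr_transform(comp: TissueComposition) -> ClrCoordinates:
    """Centred log-ratio: ln(part / geometric mean of all 11 parts)."""
    logs = np.log(comp.values)
    clr = logs - logs.mean()
    # enforce the sum-to-zero invariant against floating-point drift
    clr -= clr.sum() / _D
    return ClrCoordinates(clr)


def ilr_transform(comp: TissueComposition, sbp: SequentialBinaryPartition) -> IlrCoordinates:
    """Isometric log-ratio coordinates ilr_i = sqrt(rs/(r+s))·ln(G_r/G_s).

    G_r and G_s are the geometric means of the +1 and −1 groups of
    contrast i of the sequential binary partition.
    """
    logs = np.log(comp.values)
    out = np.empty(_D - 1)
    for i, row in enumerate(sbp.contrasts):
        plus = row == 1
        minus = row == -1
        r, s = int(plus.sum()), int(minus.sum())
        coeff = math.sqrt(r * s / (r + s))
        out[i] = coeff * (logs[plus].mean() - logs[minus].mean())
    return IlrCoordinates(out, sbp_id=sbp.sbp_id)


def aitchison_distance(a: TissueComposition, b: TissueComposition) -> float:
    """Euclidean distance between compositions in clr space.

    Identical to the Euclidean distance between their ilr coordinates
    under any valid SBP (the ilr basis is orthonormal).
    """
    diff = clr_transform(a).values - clr_transform(b).values
    return float(np.linalg.norm(diff))


def perturbation(
    diagnosed: TissueComposition,
    reference: TissueComposition,
    center: bool = False,
) -> PerturbationVector:
    """Perturbation vector p = diagnosed ⊖ reference = {X_i / x*_i}.

    Raw ratios are the default interpretation surface; with ``center``
    the ratios are re-closed to sum to the part count (the formal
    simplex-perturbation convention).
    """
    ratios = diagnosed.values / reference.values
    if center:
        ratios = ratios * (_D / ratios.sum())
    return PerturbationVector(dict(zip(PARTS, ratios.tolist())), centered=center)


def perturb_composition(comp: TissueComposition, ratios: Mapping[str, float] | np.ndarray) -> TissueComposition:
    """Apply a perturbation (component-wise multiply, then re-close): comp ⊕ p."""
    if isinstance(ratios, Mapping):
        r = np.array([float(ratios[p]) for p in PARTS])
    else:
        r = np.asarray(ratios, dtype=float)
    scaled = comp.values * r
    return TissueComposition(scaled * (TOTAL_MASS / scaled.sum()))


def rank_nutrients(
    p: PerturbationVector,
    exclude_filling: bool = True,
    tolerance: float = 0.01,
) -> NutrientRanking:
    """Rank nutrients by |ln ratio| descending as relative excess/shortage.

    A part whose |ln ratio| is at most ``tolerance`` is tagged balanced
    and omitted from the excess/shortage listings.  Fv is excluded by
    default.
    """
    labels = NUTRIENTS if exclude_filling else PARTS
    entries = []
    for label in labels:
        ratio = p[label]
        lr = math.log(ratio)
        if abs(lr) <= tolerance:
            status = "balanced"
        elif ratio > 1:
            status = "excess"
        else:
            status = "shortage"
        entries.append(RankedNutrient(label, ratio, lr, status))
    entries.sort(key=lambda e: (-abs(e.log_ratio), PARTS.index(e.part)))
    return NutrientRanking(tuple(entries), tolerance=tolerance)


def build_default_sbp() -> SequentialBinaryPartition:
    """The default balance design for the 11-part tissue composition.

    Contrast 1 separates the ten nutrients from the filling value;
    contrast 2 balances macronutrients {N,P,K,Mg,Ca} against
    micronutrients {B,Cu,Zn,Mn,Fe}; the remaining contrasts cascade
    left-to-right within each group in the fixed part order.  Distances
    are invariant to this choice; only the coordinate values depend on it.
    """
    rows = []
    row = np.ones(_D, dtype=int)
    row[-1] = -1
    rows.append(row)
    row = np.zeros(_D, dtype=int)
    for p in MACRONUTRIENTS:
        row[PARTS.index(p)] = 1
    for p in MICRONUTRIENTS:
        row[PARTS.index(p)] = -1
    rows.append(row)
    for group in (MACRONUTRIENTS, MICRONUTRIENTS):
        idx = [PARTS.index(p) for p in group]
        for k in range(len(idx) - 1):
            row = np.zeros(_D, dtype=int)
            row[idx[k]] = 1
            for j in idx[k + 1:]:
                row[j] = -1
            rows.append(row)
    return SequentialBinaryPartition(np.array(rows), sbp_id="default-macro-micro-cascade")
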