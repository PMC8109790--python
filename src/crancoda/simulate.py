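"""Synthetic multi-site, multi-year cranberry survey generator.

The generator emulates the statistical structure the diagnostic pipeline
assumes: tissue nutrients vary log-normally around a region×cultivar
optimum with micronutrients far more variable than macronutrients;
berry yield decays with the Aitchison distance of the tissue composition
from the local optimum; and next-year yield carries over a storage gain
from prior N+K fertilization and a depletion loss from prior yield.
Every record is schema-complete against the survey feature table
(region, farming system, cultivar, fertilization doses, tissue tests,
soil tests, texture, bulk density, soil series, monthly climate, yield).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .coda import (
    MACRONUTRIENTS,
    NUTRIENTS,
    PARTS,
    TOTAL_MASS,
    CodaError,
    ConfigurationError,
    TissueComposition,
    ValidationError,
    aitchison_distance,
    close_composition,
    perturb_composition,
)

__all__ = [
    "GeneratorConfig",
    "ObservationRecord",
    "LatentTruth",
    "generate_dataset",
    "plant_defect",
    "FERTILIZER_ELEMENTS",
    "SOIL_TEST_FIELDS",
    "TEXTURE_FIELDS",
    "DENSITY_FIELDS",
    "MONTHS",
]

FERTILIZER_ELEMENTS = ("N", "P", "K", "Mg", "S", "Cu", "B")
SOIL_TEST_FIELDS = (
    "pH", "total_C", "total_N",
    "m3_P", "m3_K", "m3_Ca", "m3_Mg", "m3_Cu", "m3_Zn", "m3_Mn", "m3_Fe", "m3_Al",
)
TEXTURE_FIELDS = (
    "clay", "silt", "very_coarse_sand", "coarse_sand",
    "medium_sand", "fine_sand", "very_fine_sand",
)
DENSITY_FIELDS = ("bd_0_10", "bd_10_20", "bd_20_30")
MONTHS = ("may", "jun", "jul", "aug", "sep", "oct")

#: Reference optimum: the across-region true-negative average tissue
#: composition (g kg^-1), the centre the generator jitters per
#: region×cultivar.
DEFAULT_OPTIMUM = {
    "N": 10.6, "P": 1.1, "K": 5.4, "Mg": 2.0, "Ca": 8.9,
    "B": 0.052, "Cu": 0.004, "Zn": 0.021, "Mn": 0.355, "Fe": 0.117,
}

_SOIL_SERIES = ("St-Judes", "St-Samuel", "Ste-Sophie")

# Seasonal baseline for monthly mean temperature (deg C), May..Oct.
_TEMP_BASE = np.array([11.0, 16.5, 19.5, 18.5, 14.0, 7.5])
# Monthly precipitation totals baseline (mm).
_PRECIP_BASE = np.array([90.0, 100.0, 110.0, 95.0, 100.0, 95.0])


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic survey.

    Defaults produce 10 sites × 20 beds × 5 years = 1000 bed-year
    observations with the log-scale nutrient variation and planted
    composition→yield and carryover links the analysis assumes.
    """

    n_sites: int = 10
    n_beds_per_site: int = 20
    years: tuple[int, ...] = (2014, 2015, 2016, 2017, 2018)
    regions: tuple[str, ...] = ("Quebec", "Wisconsin")
    region_weights: tuple[float, ...] = (0.75, 0.25)
    cultivars: tuple[str, ...] = ("Stevens", "Crimson Queen", "Ben Lear", "Pilgrim", "GH1")
    cultivar_weights: tuple[float, ...] = (0.70, 0.10, 0.08, 0.06, 0.06)
    farming_systems: tuple[str, ...] = ("conventional", "organic")
    farming_system_weights: tuple[float, ...] = (0.85, 0.15)
    optimum_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OPTIMUM)
    )
    #: log-scale SD of the per-region×cultivar jitter of the optimum.
    optimum_jitter_macro: float = 0.03
    optimum_jitter_micro: float = 0.10
    #: log-scale SDs of bed-year tissue variation about the local optimum.
    macro_log_sd: float = 0.08
    micro_log_sd: float = 0.35
    #: site yield ceiling (ton ha^-1), drawn uniformly in this range.
    yield_max_range: tuple[float, float] = (45.0, 65.0)
    #: decay scale of the Gaussian yield response to Aitchison distance.
    tau: float = 1.0
    #: carryover: storage gain per SD of prior N+K dose, depletion loss
    #: per SD of prior yield (ton ha^-1).
    beta_store: float = 2.0
    beta_dep: float = 3.0
    #: fixed standardization constants for the carryover terms.
    dose_loc: float = 90.0
    dose_scale: float = 45.0
    yield_loc: float = 30.0
    yield_scale: float = 10.0
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_beds_per_site < 1:
            raise ConfigurationError("n_sites and n_beds_per_site must be >= 1")
        years = tuple(self.years)
        if any(b - a != 1 for a, b in zip(years, years[1:])):
            raise ConfigurationError(f"years must be consecutive, got {years}")
        for name in ("optimum_jitter_macro", "optimum_jitter_micro",
                     "macro_log_sd", "micro_log_sd", "tau",
                     "dose_scale", "yield_scale"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.noise_sd < 0 or self.beta_store < 0 or self.beta_dep < 0:
            raise ConfigurationError("noise_sd, beta_store, beta_dep must be >= 0")
        lo, hi = self.yield_max_range
        if not (0 < lo <= hi):
            raise ConfigurationError("yield_max_range must satisfy 0 < lo <= hi")
        for ws, items in ((self.region_weights, self.regions),
                          (self.cultivar_weights, self.cultivars),
                          (self.farming_system_weights, self.farming_systems)):
            if len(ws) != len(items) or any(w < 0 for w in ws) or sum(ws) <= 0:
                raise ConfigurationError("sampling weights must be non-negative and match items")
        # validates positivity and feasibility of the optimum
        try:
            close_composition(self.optimum_composition)
        except CodaError as exc:
            raise ConfigurationError(f"invalid optimum composition: {exc}") from None


@dataclass(frozen=True)
class LatentTruth:
    """Non-serialized generator internals needed to re-evaluate planted yields."""

    optimum: TissueComposition
    potential: float      # yield_max × climate/soil modifier (ton ha^-1)
    carry: float          # carryover term already applied to this record
    noise: float          # Gaussian noise draw already applied
    tau: float            # decay scale the record was generated under


@dataclass
class ObservationRecord:
    """One bed-year observation with the full survey feature set."""

    region: str
    site: str
    bed: str
    year: int
    cultivar: str
    farming_system: str
    fertilization: dict[str, float]          # kg ha^-1, keys FERTILIZER_ELEMENTS
    composition: TissueComposition           # g kg^-1 tissue
    soil: dict[str, float]                   # keys SOIL_TEST_FIELDS
    texture: dict[str, float]                # %, keys TEXTURE_FIELDS, sums to 100
    bulk_density: dict[str, float]           # g cm^-3, keys DENSITY_FIELDS
    soil_series: str
    temperature: dict[str, float]            # deg C monthly means May-Oct
    precipitation: dict[str, float]          # mm monthly totals May-Oct
    yield_t: float                           # ton ha^-1
    latent: LatentTruth | None = None

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.region, self.site, self.bed, self.year)

    def __post_init__(self) -> None:
        if self.yield_t < 0:
            raise ValidationError(f"yield must be >= 0, got {self.yield_t}")
        tex_sum = sum(self.texture.values())
        if abs(tex_sum - 100.0) > 0.01:
            raise ValidationError(f"texture fractions must sum to 100, got {tex_sum}")


def _planted_yield(cfg: GeneratorConfig, latent_potential: float,
                   eps: float, carry: float, noise: float) -> float:
    """The planted yield model: Gaussian decay in compositional distance
    plus carryover and noise, floored at zero."""
    y = latent_potential * np.exp(-((eps / cfg.tau) ** 2)) + carry + noise
    return float(max(y, 0.0))


def _jitter_optimum(cfg: GeneratorConfig, rng: np.random.Generator) -> TissueComposition:
    base = np.array([cfg.optimum_composition[p] for p in NUTRIENTS])
    sds = np.array([
        cfg.optimum_jitter_macro if p in MACRONUTRIENTS else cfg.optimum_jitter_micro
        for p in NUTRIENTS
    ])
    return close_composition(base * np.exp(rng.normal(0.0, sds)))


def generate_dataset(config: GeneratorConfig) -> list[ObservationRecord]:
    """Generate the synthetic survey; deterministic given ``config.seed``.

    Sites are assigned a region, a yield ceiling and soil properties;
    beds within a site share a cultivar-specific optimum composition;
    each bed-year draws fertilization, a tissue composition around the
    bed optimum, and a yield from the planted response model.  From the
    second year on, yield gains ``beta_store``·z(prior N+K dose) and
    loses ``beta_dep``·z(prior yield) — the storage and depletion
    carryover the lagged analysis is meant to recover.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nutrient_sds = np.array([
        cfg.macro_log_sd if p in MACRONUTRIENTS else cfg.micro_log_sd
        for p in NUTRIENTS
    ])
    records: list[ObservationRecord] = []
    region_p = np.array(cfg.region_weights) / sum(cfg.region_weights)
    cultivar_p = np.array(cfg.cultivar_weights) / sum(cfg.cultivar_weights)
    system_p = np.array(cfg.farming_system_weights) / sum(cfg.farming_system_weights)

    # one optimum composition per region×cultivar, shared by all beds of
    # that combination — the local standard the diagnosis should recover
    optima = {
        (region, cultivar): _jitter_optimum(cfg, rng)
        for region in cfg.regions
        for cultivar in cfg.cultivars
    }

    for si in range(cfg.n_sites):
        site = f"S{si + 1:02d}"
        region = str(rng.choice(cfg.regions, p=region_p))
        yield_max = float(rng.uniform(*cfg.yield_max_range))
        soil_series = str(rng.choice(_SOIL_SERIES))
        # site-level soil template; beds jitter around it
        site_soil = {
            "pH": float(rng.normal(4.8, 0.25)),
            "total_C": float(rng.lognormal(np.log(20.0), 0.4)),    # g/kg
            "total_N": float(rng.lognormal(np.log(1.0), 0.4)),
            "m3_P": float(rng.lognormal(np.log(40.0), 0.4)),       # mg/kg
            "m3_K": float(rng.lognormal(np.log(35.0), 0.4)),
            "m3_Ca": float(rng.lognormal(np.log(300.0), 0.4)),
            "m3_Mg": float(rng.lognormal(np.log(40.0), 0.4)),
            "m3_Cu": float(rng.lognormal(np.log(1.0), 0.5)),
            "m3_Zn": float(rng.lognormal(np.log(2.0), 0.5)),
            "m3_Mn": float(rng.lognormal(np.log(5.0), 0.5)),
            "m3_Fe": float(rng.lognormal(np.log(150.0), 0.4)),
            "m3_Al": float(rng.lognormal(np.log(900.0), 0.3)),
        }
        texture_alpha = np.array([2.0, 4.0, 3.0, 8.0, 14.0, 10.0, 4.0])
        site_texture = rng.dirichlet(texture_alpha) * 100.0
        site_bd = 1.1 + 0.15 * np.arange(3) + rng.normal(0.0, 0.05, 3)
        # soil fitness factor, part of the bounded yield modifier
        soil_factor = float(np.clip(
            1.0 - 0.3 * abs(site_soil["pH"] - 4.75) + 0.02 * np.log(site_soil["m3_K"] / 35.0),
            0.85, 1.15,
        ))

        # per-year site climate and the climate part of the modifier
        year_climate = {}
        for year in cfg.years:
            temp = _TEMP_BASE + rng.normal(0.0, 1.2, 6)
            precip = np.clip(_PRECIP_BASE + rng.normal(0.0, 25.0, 6), 10.0, None)
            summer = float(temp[1:4].mean())
            climate_factor = float(np.clip(1.0 + 0.04 * (summer - 18.0), 0.85, 1.15))
            year_climate[year] = (temp, precip, climate_factor)

        for bi in range(cfg.n_beds_per_site):
            bed = f"{site}-B{bi + 1:02d}"
            cultivar = str(rng.choice(cfg.cultivars, p=cultivar_p))
            system = str(rng.choice(cfg.farming_systems, p=system_p))
            optimum = optima[(region, cultivar)]
            prev_yield: float | None = None
            prev_dose_nk: float | None = None
            for year in cfg.years:
                temp, precip, climate_factor = year_climate[year]
                modifier = float(np.clip(soil_factor * climate_factor, 0.8, 1.2))
                fert = {
                    "N": float(rng.choice([0, 15, 30, 45, 60])),
                    "P": float(rng.choice([0, 15, 30])),
                    "K": float(rng.choice([0, 40, 80, 120])),
                    "Mg": float(rng.choice([0, 12])),
                    "S": float(rng.choice([0, 50, 100])),
                    "Cu": float(rng.choice([0.0, 2.0])),
                    "B": float(rng.choice([0.0, 1.0])),
                }
                shocks = rng.normal(0.0, nutrient_sds)
                tissue = close_composition(optimum.nutrients * np.exp(shocks))
                eps = aitchison_distance(tissue, optimum)
                carry = 0.0
                if prev_yield is not None:
                    carry = (
                        cfg.beta_store * (prev_dose_nk - cfg.dose_loc) / cfg.dose_scale
                        - cfg.beta_dep * (prev_yield - cfg.yield_loc) / cfg.yield_scale
                    )
                noise = float(rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd > 0 else 0.0
                potential = yield_max * modifier
                y = _planted_yield(cfg, potential, eps, carry, noise)
                rec = ObservationRecord(
                    region=region,
                    site=site,
                    bed=bed,
                    year=int(year),
                    cultivar=cultivar,
                    farming_system=system,
                    fertilization=fert,
                    composition=tissue,
                    soil={k: float(v * np.exp(rng.normal(0.0, 0.05)))
                          if k != "pH" else float(v + rng.normal(0.0, 0.05))
                          for k, v in site_soil.items()},
                    texture=dict(zip(TEXTURE_FIELDS,
                                     (site_texture * (100.0 / site_texture.sum())).tolist())),
                    bulk_density=dict(zip(DENSITY_FIELDS, np.abs(site_bd).tolist())),
                    soil_series=soil_series,
                    temperature=dict(zip(MONTHS, temp.tolist())),
                    precipitation=dict(zip(MONTHS, precip.tolist())),
                    yield_t=y,
                    latent=LatentTruth(optimum=optimum, potential=potential,
                                       carry=carry, noise=noise, tau=cfg.tau),
                )
                records.append(rec)
                prev_yield = y
                prev_dose_nk = fert["N"] + fert["K"]
    return records


def plant_defect(
    record: ObservationRecord,
    nutrient: str,
    log_magnitude: float,
    config: GeneratorConfig | None = None,
) -> ObservationRecord:
    """Return a copy with one nutrient multiplied by exp(log_magnitude).

    The composition is re-closed and the yield re-evaluated under the
    planted response model (same carryover term and noise draw as the
    original record), so the defect's yield consequence is exact.
    Requires the generator's latent block; records read back from CSV
    cannot be re-planted.
    """
    if nutrient not in NUTRIENTS:
        raise ValidationError(
            f"can only plant defects on nutrients {NUTRIENTS}, got {nutrient!r}"
        )
    if record.latent is None:
        raise ValidationError(
            "record carries no latent generator state; plant_defect only applies "
            "to freshly generated records"
        )
    lat = record.latent
    cfg = config or dataclasses.replace(GeneratorConfig(), tau=lat.tau)
    ratios = {p: 1.0 for p in PARTS}
    ratios[nutrient] = float(np.exp(log_magnitude))
    new_comp = perturb_composition(record.composition, ratios)
    eps = aitchison_distance(new_comp, lat.optimum)
    y = _planted_yield(cfg, lat.potential, eps, lat.carry, lat.noise)
    out = dataclasses.replace(record, composition=new_comp, yield_t=y)
    return out
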