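"""Synthetic leaf-measurement datasets for parameter-recovery experiments.

The generator emulates the structure of a multi-experiment training table:
several genotypes per species, a spread of total leaf numbers (TLN), and one
length/width measurement per leaf position per plant.  Values come from the
expolinear-logistic model under a known ("truth") parameter set, perturbed
by independent measurement noise, so every fitting operation can be tested
for recovery without any external data.

Noise defaults are additive Gaussian with per-trait standard deviations of
20 mm (length) and 3 mm (width), loosely scaled to the dispersion of
published training tables; a proportional (CV) alternative is available.
Within-plant error correlation is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import default_parameter_set
from .model import predict_profile
from .params import SpeciesId, SpeciesParameterSet, Trait

__all__ = ["NoiseSpec", "SimConfig", "generate_dataset", "table1_style_panel"]

#: Observed TLN ranges per species in the published training tables.
SPECIES_TLN_RANGES = {
    SpeciesId.MAIZE: (11, 25),
    SpeciesId.SORGHUM: (9, 44),
    SpeciesId.PEARL_MILLET: (11, 27),
}

#: Physical floor (mm): no generated blade dimension falls below this.
FLOOR_MM = 1.0


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model applied independently per leaf and trait.

    ``model`` is "additive" (sd in mm) or "proportional" (coefficient of
    variation); zero noise reproduces the model predictions exactly.
    """

    model: str = "additive"
    length_sd: float = 20.0
    width_sd: float = 3.0
    length_cv: float = 0.05
    width_cv: float = 0.05

    def __post_init__(self):
        if self.model not in ("additive", "proportional"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if min(self.length_sd, self.width_sd, self.length_cv, self.width_cv) < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def sd_for(self, trait: Trait, mean) -> np.ndarray:
        mean = np.asarray(mean, dtype=float)
        if self.model == "additive":
            sd = self.length_sd if trait is Trait.BLADE_LENGTH else self.width_sd
            return np.full_like(mean, sd)
        cv = self.length_cv if trait is Trait.BLADE_LENGTH else self.width_cv
        return cv * mean


@dataclass(frozen=True)
class SimConfig:
    """Design of one synthetic panel.

    ``genotypes`` maps labels to parameter sets; ``None`` means the packaged
    generic set for the species.  ``genotype_cv`` optionally perturbs cm and
    L1 per genotype (lognormal, multiplicative) to emulate genotypic
    variation in leaf size.  The seed is mandatory: identical configs give
    byte-identical output.
    """

    species: SpeciesId
    tln_values: Sequence[int]
    plants_per_tln: int = 1
    genotypes: dict = field(default_factory=lambda: {"generic": None})
    noise: NoiseSpec = NoiseSpec()
    missing_rate: float = 0.0
    genotype_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.plants_per_tln < 1:
            raise ValueError("plants_per_tln must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.seed is None:
            raise ValueError("an explicit seed is mandatory")


def _perturb_genotype(
    pset: SpeciesParameterSet, cv: float, rng: np.random.Generator
) -> SpeciesParameterSet:
    """Multiplicative lognormal perturbation of cm and L1 for one genotype."""
    if cv <= 0:
        return pset
    sigma = np.sqrt(np.log1p(cv**2))
    traits = {}
    for trait, tp in pset.traits.items():
        factors = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=2)
        traits[trait] = replace(tp, cm=tp.cm * factors[0], L1=tp.L1 * factors[1])
    return replace(pset, traits=traits)


def generate_dataset(
    cfg: SimConfig, param_set: Optional[SpeciesParameterSet] = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate a leaf-record table plus the generating truth.

    Returns ``(records, truth)`` where ``records`` follows the leaf CSV
    dialect and ``truth`` maps genotype labels to the exact parameter sets
    the values were drawn from (after any genotype perturbation) — the
    reference for recovery tests.
    """
    base = param_set or default_parameter_set(cfg.species)
    rng = np.random.default_rng(cfg.seed)
    truth: dict[str, SpeciesParameterSet] = {}
    frames = []
    plant = 0
    for label, override in sorted(cfg.genotypes.items()):
        gset = override or base
        gset = _perturb_genotype(gset, cfg.genotype_cv, rng)
        truth[label] = gset
        for tln in cfg.tln_values:
            profile = predict_profile(gset, int(tln))
            for _ in range(cfg.plants_per_tln):
                plant += 1
                n = profile.tln
                length = profile.length_mm + rng.normal(
                    0.0, cfg.noise.sd_for(Trait.BLADE_LENGTH, profile.length_mm)
                ) if _noisy(cfg.noise, Trait.BLADE_LENGTH) else profile.length_mm.copy()
                width = profile.width_mm + rng.normal(
                    0.0, cfg.noise.sd_for(Trait.BLADE_WIDTH, profile.width_mm)
                ) if _noisy(cfg.noise, Trait.BLADE_WIDTH) else profile.width_mm.copy()
                length = np.maximum(length, FLOOR_MM)
                width = np.maximum(width, FLOOR_MM)
                if cfg.missing_rate > 0:
                    length = np.where(
                        rng.random(n) < cfg.missing_rate, np.nan, length
                    )
                    width = np.where(rng.random(n) < cfg.missing_rate, np.nan, width)
                frames.append(
                    pd.DataFrame(
                        {
                            "plant_id": f"p{plant:05d}",
                            "species": cfg.species.value,
                            "genotype": label,
                            "tln": int(tln),
                            "position": profile.positions,
                            "blade_length_mm": length,
                            "blade_width_mm": width,
                        }
                    )
                )
    records = pd.concat(frames, ignore_index=True)
    # drop rows where both measurements went missing
    keep = records[["blade_length_mm", "blade_width_mm"]].notna().any(axis=1)
    return records.loc[keep].reset_index(drop=True), truth


def _noisy(noise: NoiseSpec, trait: Trait) -> bool:
    sd = noise.length_sd if trait is Trait.BLADE_LENGTH else noise.width_sd
    cv = noise.length_cv if trait is Trait.BLADE_LENGTH else noise.width_cv
    return (noise.model == "additive" and sd > 0) or (
        noise.model == "proportional" and cv > 0
    )


def table1_style_panel(
    species, seed: int, plants_per_tln: int = 3, n_genotypes: int = 3
) -> pd.DataFrame:
    """Convenience preset: a multi-genotype panel spanning the TLN range
    observed for the species in the published training tables (maize 11-25,
    sorghum 9-44, pearl millet 11-27), with default measurement noise and
    mild genotypic variation.  Intended as a realistic fixture for tests
    and documentation."""
    species = SpeciesId(species)
    lo, hi = SPECIES_TLN_RANGES[species]
    cfg = SimConfig(
        species=species,
        tln_values=list(range(lo, hi + 1)),
        plants_per_tln=plants_per_tln,
        genotypes={f"G{i + 1}": None for i in range(n_genotypes)},
        genotype_cv=0.03,
        seed=seed,
    )
    records, _ = generate_dataset(cfg)
    return records
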