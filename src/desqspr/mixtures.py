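"""DES recipes, mole-fraction compositions, and mixture descriptors.

A deep eutectic solvent (DES) is specified here as a recipe: an ordered
list of constituents (hydrogen-bond acceptor, donor(s)) with molar
parts, plus a water content in weight percent.  Converting the water
mass fraction to moles requires molar masses, so the module ships a
small editable table for the common DES constituents (betaine, choline
chloride, ethylene glycol, propylene glycol, glycerol, urea) and water;
anything else must carry an explicit molar mass.  Choline chloride is a
single ion-pair constituent with one molar mass.

Mixture-level descriptors follow the linear mixing rule

    Sⁱ_mix = Σⱼ Xⱼ · Sⁱⱼ ,   i = 1…10,

the mole-fraction-weighted sum of the constituents' S-descriptors
(water included as a constituent).  The sum runs over however many
constituents the recipe has, so ternary DES work unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sigma_profiles import DescriptorVector, N_REGIONS

__all__ = [
    "MOLAR_MASS_G_PER_MOL",
    "WATER_MOLAR_MASS",
    "Constituent",
    "DESRecipe",
    "MixtureComposition",
    "mole_fractions_from_recipe",
    "mix_descriptors",
    "DESSystem",
    "enumerate_library",
]

#: Molar masses (g/mol) for the constituents of the screening library.
#: Editable: recipes with other chemicals must supply molar_mass explicitly.
MOLAR_MASS_G_PER_MOL: dict[str, float] = {
    "betaine": 117.15,
    "choline chloride": 139.62,  # ion pair
    "ethylene glycol": 62.07,
    "propylene glycol": 76.09,
    "glycerol": 92.09,
    "urea": 60.06,
    "water": 18.015,
}

WATER_MOLAR_MASS = MOLAR_MASS_G_PER_MOL["water"]

ROLES = ("HBA", "HBD", "water")


@dataclass(frozen=True)
class Constituent:
    """A DES constituent: identity, molar mass and its descriptor vector."""

    name: str
    molar_mass: float
    descriptors: DescriptorVector | None = None
    role: str = "HBD"

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValueError(f"{self.name}: molar mass must be positive")
        if self.role not in ROLES:
            raise ValueError(f"{self.name}: role must be one of {ROLES}")


@dataclass(frozen=True)
class DESRecipe:
    """A labelled DES formulation: constituents with molar parts + water wt%."""

    label: str
    constituents: tuple  # of (Constituent, molar_parts)
    water_wt_percent: float
    liquid_at_rt: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "constituents", tuple(self.constituents))
        if not self.constituents:
            raise ValueError(f"{self.label}: recipe needs at least one constituent")
        for c, parts in self.constituents:
            if not parts > 0:
                raise ValueError(f"{self.label}: molar parts must be positive ({c.name})")
        if not (0 <= self.water_wt_percent < 100):
            raise ValueError(
                f"{self.label}: water wt% must lie in [0, 100), got {self.water_wt_percent}"
            )


@dataclass(frozen=True)
class MixtureComposition:
    """Mole fractions of every constituent of a mixture, water last if present."""

    X: np.ndarray
    names: tuple

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "names", tuple(self.names))
        if X.ndim != 1 or X.size != len(self.names):
            raise ValueError("X and names must align")
        if np.any(X < 0):
            raise ValueError("mole fractions must be non-negative")
        if abs(X.sum() - 1.0) > 1e-12:
            raise ValueError(f"mole fractions must sum to 1, got {X.sum()!r}")

    @property
    def NC(self) -> int:
        return int(self.X.size)


def mole_fractions_from_recipe(recipe: DESRecipe) -> MixtureComposition:
    """Convert molar parts + water wt% into mole fractions.

    On a basis of the stated molar parts, the anhydrous DES mass is
    ``Σ partsⱼ·Mⱼ``; a water mass fraction ``w`` then contributes
    ``moles_water = (w/(1−w)) · mass_des / M_water`` and every mole
    fraction is taken over parts plus water moles.  The result is
    invariant to scaling all molar parts by a common factor.
    """
    w = recipe.water_wt_percent / 100.0
    if w >= 1.0:
        raise ValueError(f"{recipe.label}: water mass fraction must be < 1")
    parts = np.array([p for _, p in recipe.constituents], dtype=float)
    masses = np.array([c.molar_mass for c, _ in recipe.constituents], dtype=float)
    mass_des = float(parts @ masses)
    moles_water = (w / (1.0 - w)) * mass_des / WATER_MOLAR_MASS if w > 0 else 0.0
    total = parts.sum() + moles_water
    X = np.concatenate([parts, [moles_water]]) / total
    names = tuple(c.name for c, _ in recipe.constituents) + ("water",)
    return MixtureComposition(X=X, names=names)


def mix_descriptors(
    composition: MixtureComposition,
    constituents: Sequence[Constituent],
) -> DescriptorVector:
    """Mole-fraction-weighted mixture descriptors Sⁱ_mix = Σⱼ Xⱼ Sⁱⱼ."""
    if len(constituents) != composition.NC:
        raise ValueError(
            f"composition has {composition.NC} entries but "
            f"{len(constituents)} constituents were given"
        )
    S = np.zeros(N_REGIONS)
    truncated = 0.0
    for x, c in zip(composition.X, constituents):
        if c.descriptors is None:
            raise ValueError(f"{c.name}: constituent carries no descriptors")
        S += x * c.descriptors.S
        truncated += x * c.descriptors.truncated_mass
    return DescriptorVector(S=S, truncated_mass=truncated)


@dataclass(frozen=True)
class DESSystem:
    """A recipe template: one HBA/HBD combination reused at several water levels."""

    index: int
    abbrev: str
    constituents: tuple  # of (Constituent, molar_parts)
    solid_at: frozenset = field(default_factory=frozenset)  # water wt% levels

    def __post_init__(self) -> None:
        object.__setattr__(self, "constituents", tuple(self.constituents))
        object.__setattr__(self, "solid_at", frozenset(self.solid_at))


def enumerate_library(
    systems: Sequence[DESSystem],
    water_levels: Sequence[float],
) -> list[DESRecipe]:
    """Cross systems with water levels, skipping room-temperature solids.

    Labels follow the ``DES <system>.<level>`` scheme where the level
    index counts water levels in the given order (1-based), e.g. system 3
    at the second water level becomes ``DES 3.2``.
    """
    recipes: list[DESRecipe] = []
    seen: set[str] = set()
    for system in systems:
        for j, level in enumerate(water_levels, start=1):
            if level in system.solid_at:
                continue
            label = f"DES {system.index}.{j}"
            if label in seen:
                raise ValueError(f"duplicate DES label {label}")
            seen.add(label)
            recipes.append(
                DESRecipe(
                    label=label,
                    constituents=system.constituents,
                    water_wt_percent=float(level),
                )
            )
    return recipes
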