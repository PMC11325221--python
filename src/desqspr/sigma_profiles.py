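"""σ-profiles and their integration into the 10 S-descriptors.

A σ-profile is the histogram of a molecule's COSMO screening-charge
density σ over its surface: the abscissa is σ in e/Å², the ordinate the
surface area (Å²) carried by each σ bin.  Polar hydrogen-bond acceptors
pile area at negative σ, donors at positive σ, and nonpolar surface sits
near zero, so the profile is a compact fingerprint of a molecule's
polarity distribution.

The descriptor set used throughout this package reduces a profile to ten
numbers S¹…S¹⁰: the area integrated over ten contiguous regions of width
0.005 e/Å² spanning −0.025…+0.025 e/Å².  Profiles are treated as the
discrete histograms the COSMO software emits, so "area under the curve"
is a sum of per-point area weights; a grid point that falls exactly on
an interior region boundary contributes half of its area to each
neighbouring region, and mass outside ±0.025 e/Å² is tracked separately
as ``truncated_mass`` rather than being folded into the edge regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SIGMA_MIN",
    "SIGMA_MAX",
    "REGION_WIDTH",
    "N_REGIONS",
    "REGION_EDGES",
    "SigmaProfile",
    "DescriptorVector",
    "read_sigma_profile",
    "write_sigma_profile",
    "integrate_descriptors",
    "total_area",
    "descriptor_table",
]

#: Descriptor window on the σ axis (e/Å²) and the ten integration regions.
SIGMA_MIN = -0.025
SIGMA_MAX = 0.025
REGION_WIDTH = 0.005
N_REGIONS = 10
REGION_EDGES = tuple(np.round(SIGMA_MIN + REGION_WIDTH * np.arange(N_REGIONS + 1), 12))

#: Absolute tolerance for deciding that a grid point sits on a region boundary.
BOUNDARY_TOL = 1e-12

#: Relative tolerance for grid-uniformity validation.
GRID_RTOL = 1e-9


class SigmaProfileError(ValueError):
    """Malformed σ-profile input (non-uniform grid, negative ordinate, ...)."""


@dataclass(frozen=True)
class SigmaProfile:
    """A discrete σ-profile histogram.

    Parameters
    ----------
    name:
        Constituent identifier.
    sigma:
        Strictly increasing, uniformly spaced grid of screening-charge
        densities (e/Å²).
    p:
        Non-negative area weight (Å²) at each grid point.  By the time a
        profile is constructed the ordinate is always an *area* per grid
        point; density-convention files are rescaled on read.
    grid_spacing:
        Uniform step of the σ grid (e/Å²).
    """

    name: str
    sigma: np.ndarray
    p: np.ndarray
    grid_spacing: float

    def __post_init__(self) -> None:
        sigma = np.asarray(self.sigma, dtype=float)
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "p", p)
        if sigma.ndim != 1 or p.ndim != 1 or sigma.size != p.size:
            raise SigmaProfileError(
                f"{self.name}: sigma and p must be 1-D arrays of equal length"
            )
        if sigma.size < 1:
            raise SigmaProfileError(f"{self.name}: empty profile")
        if sigma.size > 1:
            steps = np.diff(sigma)
            if np.any(steps <= 0):
                idx = int(np.argmax(steps <= 0))
                raise SigmaProfileError(
                    f"{self.name}: sigma grid not strictly increasing at row "
                    f"{idx + 1} (sigma={sigma[idx + 1]:g} after {sigma[idx]:g})"
                )
            ref = steps[0]
            bad = np.abs(steps - ref) > GRID_RTOL * max(abs(ref), 1.0)
            if np.any(bad):
                idx = int(np.argmax(bad))
                raise SigmaProfileError(
                    f"{self.name}: non-uniform sigma grid at row {idx + 1} "
                    f"(step {steps[idx]:g} vs {ref:g})"
                )
        if np.any(p < 0):
            idx = int(np.argmax(p < 0))
            raise SigmaProfileError(
                f"{self.name}: negative ordinate {p[idx]:g} at sigma={sigma[idx]:g}"
            )
        if not np.all(np.isfinite(sigma)) or not np.all(np.isfinite(p)):
            raise SigmaProfileError(f"{self.name}: non-finite values in profile")

    @property
    def n_points(self) -> int:
        return int(self.sigma.size)


@dataclass(frozen=True)
class DescriptorVector:
    """The ten integrated S-descriptors of a profile or mixture.

    ``S[i]`` is the area (Å²) in region ``i+1``; ``truncated_mass`` is
    profile mass found outside the ±0.025 e/Å² descriptor window.
    """

    S: np.ndarray
    truncated_mass: float = 0.0
    region_edges: tuple = field(default=REGION_EDGES, repr=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        if S.shape != (N_REGIONS,):
            raise ValueError(f"descriptor vector must have exactly {N_REGIONS} values")
        if np.any(S < -BOUNDARY_TOL):
            raise ValueError("descriptor areas must be non-negative")
        if self.truncated_mass < -BOUNDARY_TOL:
            raise ValueError("truncated mass must be non-negative")

    def total(self) -> float:
        """Total accounted profile mass: Σᵢ Sⁱ + truncated mass."""
        return float(self.S.sum() + self.truncated_mass)

    def __iter__(self):
        return iter(self.S)


def _parse_rows(path: Path) -> list[tuple[int, float, float]]:
    rows: list[tuple[int, float, float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise SigmaProfileError(
                f"{path}: line {lineno}: expected two columns, got {len(parts)}"
            )
        try:
            s, v = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise SigmaProfileError(f"{path}: line {lineno}: non-numeric value") from exc
        rows.append((lineno, s, v))
    if not rows:
        raise SigmaProfileError(f"{path}: no data rows")
    return rows


def read_sigma_profile(
    path: str | Path,
    area_convention: str = "ordinate-is-area",
    name: str | None = None,
) -> SigmaProfile:
    """Read a two-column σ-profile text file.

    The file holds ``sigma  ordinate`` pairs, whitespace- or
    comma-separated, with ``#`` comments.  Rows are sorted by σ before
    validation, so row order in the file is immaterial.

    ``area_convention`` declares what the ordinate means and is never
    guessed from the data:

    * ``"ordinate-is-area"`` — each value is already the area (Å²)
      attached to its grid point.
    * ``"ordinate-is-density"`` — values are area densities p(σ) and are
      multiplied by the grid spacing, so downstream code always sums
      areas.
    """
    if area_convention not in ("ordinate-is-area", "ordinate-is-density"):
        raise ValueError(f"unknown area convention {area_convention!r}")
    path = Path(path)
    rows = sorted(_parse_rows(path), key=lambda r: r[1])
    sigma = np.array([r[1] for r in rows])
    p = np.array([r[2] for r in rows])
    for lineno, s, v in rows:
        if v < 0:
            raise SigmaProfileError(
                f"{path}: line {lineno}: negative ordinate {v:g}"
            )
    spacing = float(sigma[1] - sigma[0]) if sigma.size > 1 else REGION_WIDTH
    if area_convention == "ordinate-is-density":
        p = p * spacing
    return SigmaProfile(
        name=name if name is not None else path.stem,
        sigma=sigma,
        p=p,
        grid_spacing=spacing,
    )


def write_sigma_profile(profile: SigmaProfile, path: str | Path) -> None:
    """Write a profile back to the two-column text format (area convention)."""
    path = Path(path)
    lines = [f"# sigma-profile {profile.name}", "# sigma_e_per_A2  area_A2"]
    for s, v in zip(profile.sigma, profile.p):
        lines.append(f"{float(s)!r} {float(v)!r}")
    path.write_text("\n".join(lines) + "\n")


def total_area(profile: SigmaProfile) -> float:
    """Total surface area of the profile: the sum of per-point area weights."""
    return float(profile.p.sum())


def integrate_descriptors(profile: SigmaProfile) -> DescriptorVector:
    """Integrate a σ-profile into the ten S-descriptors.

    Each grid point's area is assigned to the region whose half-open
    interval contains its σ.  Points numerically on an interior boundary
    (|σ − edge| ≤ 1e-12) are split half/half between the two adjacent
    regions; points exactly at −0.025 or +0.025 belong wholly to regions
    1 and 10.  Mass strictly outside the window accumulates in
    ``truncated_mass`` and triggers a warning — the ten regions cover a
    fixed range and tail mass is never silently reassigned.
    """
    S = np.zeros(N_REGIONS)
    truncated = 0.0
    for s, a in zip(profile.sigma, profile.p):
        if a == 0.0:
            continue
        edge_hits = [
            k for k, e in enumerate(REGION_EDGES) if abs(s - e) <= BOUNDARY_TOL
        ]
        if edge_hits:
            k = edge_hits[0]
            if k == 0:
                S[0] += a
            elif k == N_REGIONS:
                S[N_REGIONS - 1] += a
            else:
                S[k - 1] += 0.5 * a
                S[k] += 0.5 * a
            continue
        if s < SIGMA_MIN or s > SIGMA_MAX:
            truncated += a
            continue
        idx = int(np.floor((s - SIGMA_MIN) / REGION_WIDTH))
        idx = min(max(idx, 0), N_REGIONS - 1)
        S[idx] += a
    if truncated > 0:
        warnings.warn(
            f"{profile.name}: {truncated:g} Å² of profile mass lies outside "
            f"[{SIGMA_MIN}, {SIGMA_MAX}] e/Å² and is excluded from S1–S10",
            stacklevel=2,
        )
    return DescriptorVector(S=S, truncated_mass=truncated)


def descriptor_table(
    items: Iterable[tuple[str, DescriptorVector]] | Sequence[tuple[str, DescriptorVector]],
) -> pd.DataFrame:
    """Tabulate named descriptor vectors as a DataFrame (name, S1..S10, truncated_mass)."""
    records = []
    for name, d in items:
        rec = {"name": name}
        rec.update({f"S{i + 1}": d.S[i] for i in range(N_REGIONS)})
        rec["truncated_mass"] = d.truncated_mass
        records.append(rec)
    return pd.DataFrame.from_records(records)
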