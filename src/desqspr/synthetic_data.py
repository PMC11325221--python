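"""Synthetic inputs for pipeline testing: σ-profiles, DES libraries,
decay series and descriptor→k ground truths with known parameters.

The generator emulates the statistical *structure* of a DES enzyme-
stability screen, not the chemistry of specific compounds:

* σ-profiles are sums of Gaussians on the ±0.025 e/Å² grid — hydrogen-
  bond acceptors carry most of their surface area at negative σ, donors
  at positive σ, water is bimodal in both signed tails, nonpolar surface
  sits near zero;
* a library mirrors a screening grid of HBA:HBD systems crossed with
  water levels (default 10 systems × 10/30/50 wt% with two solid entries
  excluded → 28 formulations), with mixture descriptors computed through
  the real profile-integration and mixing code — the generator never
  duplicates that math;
* residual-activity series decay exponentially with multiplicative
  Gaussian noise and, with some probability, early "overstabilization"
  points above 100% to exercise the censoring rule;
* ground-truth maps from mixture descriptors to log₁₀ k are either
  linear in a small planted descriptor subset or a shallow tanh MLP in
  the model search space, with the planted indices and parameters
  recorded for recovery assertions.

Every output is a deterministic function of the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import sigma_profiles as sp
from . import mixtures as mx
from .kinetics import ActivityTimeSeries
from .qspr_ann import QSPRDataset, DESCRIPTOR_COLUMNS

__all__ = [
    "SyntheticSpec",
    "SyntheticLibrary",
    "QSPRTruth",
    "synth_sigma_profile",
    "synth_library",
    "synth_decay_series",
    "synth_qspr_truth",
    "synth_recovery_table",
    "DEFAULT_SOLID_ENTRIES",
]

#: Grid-system/water-level pairs excluded as room-temperature solids in the
#: default library shape (system 4 at the two lowest water levels), so the
#: default 10 × 3 grid yields 28 formulations.
DEFAULT_SOLID_ENTRIES = frozenset({(4, 10.0), (4, 30.0)})

#: Per-role Gaussian peak layouts: (centre range e/Å², width range e/Å²,
#: mean area share) triples.  Every molecule draws its own centres, widths
#: and share split, so constituents of the same role still differ — the way
#: urea, glycerol and ethylene glycol genuinely carry different profiles.
ROLE_PEAKS = {
    "HBA": (((-0.020, -0.008), (0.002, 0.005), 0.57),
            ((-0.008, -0.002), (0.002, 0.004), 0.28),
            ((0.002, 0.012), (0.002, 0.004), 0.15)),
    "HBD": (((0.008, 0.020), (0.002, 0.005), 0.57),
            ((0.002, 0.008), (0.002, 0.004), 0.28),
            ((-0.012, -0.002), (0.002, 0.004), 0.15)),
    "water": (((-0.018, -0.012), (0.002, 0.004), 0.45),
              ((0.012, 0.018), (0.002, 0.004), 0.45),
              ((-0.004, 0.004), (0.003, 0.005), 0.10)),
    "nonpolar": (((-0.003, 0.003), (0.003, 0.005), 0.80),
                 ((-0.008, -0.003), (0.002, 0.004), 0.10),
                 ((0.003, 0.008), (0.002, 0.004), 0.10)),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study."""

    seed: int = 0
    n_systems: int = 10
    water_levels: tuple = (10.0, 30.0, 50.0)
    solid_entries: frozenset = DEFAULT_SOLID_ENTRIES
    n_grid: int = 51
    area_range: tuple = (80.0, 150.0)       # total profile area, Å²
    molar_mass_range: tuple = (50.0, 200.0)  # g/mol, synthetic constituents
    share_concentration: float = 25.0        # Dirichlet concentration on peak shares
    sigma_noise: float = 0.05                # multiplicative activity noise
    n_replicates: int = 3                    # technical replicates per time point
    overshoot_prob: float = 0.3              # chance of >100% early points
    overshoot_scale: float = 0.25            # relative inflation of those points
    truth_family: str = "shallow-mlp"        # or "linear"
    planted: tuple = (2, 5, 8)               # 0-based planted descriptor indices
    truth_noise_sd: float = 0.0              # additive noise on log10 k
    k_log10_center: float = -1.5             # log10 h^-1; decade scale of k
    k_log10_spread: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_noise < 0:
            raise ValueError("noise sd must be non-negative")
        if not 0 <= self.overshoot_prob <= 1:
            raise ValueError("overshoot probability must lie in [0, 1]")
        if self.truth_family not in ("linear", "shallow-mlp"):
            raise ValueError(f"unknown truth family {self.truth_family!r}")


def synth_sigma_profile(
    role: str,
    spec: SyntheticSpec = SyntheticSpec(),
    seed: int | None = None,
    name: str | None = None,
) -> sp.SigmaProfile:
    """A sum-of-Gaussians σ-profile histogram for one constituent role."""
    if role not in ROLE_PEAKS:
        raise ValueError(f"unknown role {role!r}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    grid = np.linspace(sp.SIGMA_MIN, sp.SIGMA_MAX, spec.n_grid)
    spacing = grid[1] - grid[0]
    total_area = rng.uniform(*spec.area_range)
    layout = ROLE_PEAKS[role]
    mean_shares = np.array([s for _, _, s in layout])
    shares = rng.dirichlet(mean_shares * spec.share_concentration)
    density = np.zeros_like(grid)
    for (c_range, w_range, _), share in zip(layout, shares):
        c = rng.uniform(*c_range)
        w = rng.uniform(*w_range)
        density += share * np.exp(-0.5 * ((grid - c) / w) ** 2)
    p = density / density.sum() * total_area
    return sp.SigmaProfile(
        name=name or f"{role}-{rng.integers(1e6)}",
        sigma=grid,
        p=p,
        grid_spacing=float(spacing),
    )


@dataclass
class SyntheticLibrary:
    """A generated DES library with everything downstream stages need."""

    spec: SyntheticSpec
    constituents: dict            # name -> Constituent (descriptors attached)
    profiles: dict                # name -> SigmaProfile
    systems: list                 # DESSystem templates
    recipes: list                 # DESRecipe, solids excluded
    descriptor_table: pd.DataFrame  # label + S1..S10 (+ water_wt_percent)

    @property
    def n(self) -> int:
        return len(self.recipes)


def _water_constituent(spec: SyntheticSpec, rng: np.random.Generator):
    profile = synth_sigma_profile("water", spec, seed=int(rng.integers(2**31 - 1)),
                                  name="water")
    return mx.Constituent(
        name="water",
        molar_mass=mx.WATER_MOLAR_MASS,
        descriptors=sp.integrate_descriptors(profile),
        role="water",
    ), profile


def synth_library(spec: SyntheticSpec = SyntheticSpec()) -> SyntheticLibrary:
    """Generate a full synthetic screening library.

    Each system gets its own synthetic HBA plus one or two HBDs with
    molar masses uniform in the spec's range; mixture descriptors are
    computed through :mod:`sigma_profiles` and :mod:`mixtures`.
    """
    rng = np.random.default_rng(spec.seed)
    water, water_profile = _water_constituent(spec, rng)
    constituents: dict[str, mx.Constituent] = {"water": water}
    profiles: dict[str, sp.SigmaProfile] = {"water": water_profile}
    systems: list[mx.DESSystem] = []
    for i in range(1, spec.n_systems + 1):
        n_hbd = int(rng.integers(1, 3))
        members = []
        for role, tag in [("HBA", "hba")] + [("HBD", f"hbd{j}") for j in range(n_hbd)]:
            name = f"sys{i}-{tag}"
            profile = synth_sigma_profile(role, spec,
                                          seed=int(rng.integers(2**31 - 1)),
                                          name=name)
            c = mx.Constituent(
                name=name,
                molar_mass=float(rng.uniform(*spec.molar_mass_range)),
                descriptors=sp.integrate_descriptors(profile),
                role=role,
            )
            constituents[name] = c
            profiles[name] = profile
            parts = float(rng.integers(1, 4))
            members.append((c, parts))
        solid_levels = frozenset(
            lvl for (sys_idx, lvl) in spec.solid_entries if sys_idx == i
        )
        systems.append(mx.DESSystem(index=i, abbrev=f"SYS{i}",
                                    constituents=tuple(members),
                                    solid_at=solid_levels))
    recipes = mx.enumerate_library(systems, spec.water_levels)
    records = []
    for recipe in recipes:
        comp = mx.mole_fractions_from_recipe(recipe)
        members = [c for c, _ in recipe.constituents] + [water]
        d = mx.mix_descriptors(comp, members)
        rec = {"label": recipe.label,
               "water_wt_percent": recipe.water_wt_percent}
        rec.update({f"S{j + 1}": d.S[j] for j in range(sp.N_REGIONS)})
        records.append(rec)
    table = pd.DataFrame.from_records(records)
    return SyntheticLibrary(spec=spec, constituents=constituents,
                            profiles=profiles, systems=systems,
                            recipes=recipes, descriptor_table=table)


def _sampling_times(k_true_per_day: float, max_day: float = 28.0) -> np.ndarray:
    """The screen's sampling cadence, one series' time points in days.

    First-day points at 0, 2, 4, 6 and 8 h and daily points through one
    week are always measured; the weekly extension (14, 21, 28 d)
    continues only until the true curve has crossed 50% residual
    activity (the first weekly point past the crossing is kept).
    """
    first_week = [0.0, 2 / 24, 4 / 24, 6 / 24, 8 / 24, 1, 2, 3, 4, 5, 6, 7]
    weekly = [t for t in (14.0, 21.0, 28.0) if t <= max_day]
    times = [t for t in first_week if t <= max_day]
    if k_true_per_day <= 0:
        return np.array(times + weekly)
    t_half = math.log(2) / k_true_per_day
    for t in weekly:
        # the visit at which the 50% crossing is first observed still happens;
        # later weekly visits are dropped
        if t_half > t - 7.0:
            times.append(t)
        else:
            break
    return np.array(sorted(set(times)))


def synth_decay_series(
    k_true_per_day: float,
    spec: SyntheticSpec = SyntheticSpec(),
    seed: int | None = None,
    label: str = "",
) -> ActivityTimeSeries:
    """An exponential residual-activity series with multiplicative noise.

    Residuals are ``100·exp(−k·t)·(1 + ε)`` with ε ~ N(0, σ_noise),
    averaged over ``n_replicates`` technical replicates per time point;
    the time-zero point is exactly 100 by the normalization convention.
    With probability ``overshoot_prob`` the points inside the first
    three days are inflated above 100% to mimic the transient
    "overstabilization" seen in viscous solvents.
    """
    if k_true_per_day < 0:
        raise ValueError("true rate must be non-negative")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    t = _sampling_times(k_true_per_day)
    clean = 100.0 * np.exp(-k_true_per_day * t)
    reps = max(int(spec.n_replicates), 1)
    noise = rng.normal(0.0, spec.sigma_noise, (reps, t.size)).mean(axis=0)
    residual = clean * (1.0 + noise)
    residual[0] = 100.0
    if rng.uniform() < spec.overshoot_prob:
        # overstabilization shows up while the enzyme is still mostly active
        early = (t > 0) & (t <= 3.0) & (clean >= 70.0)
        residual[early] = 100.0 * (
            1.0 + spec.overshoot_scale * rng.uniform(0.1, 1.0, early.sum())
        )
    residual = np.maximum(residual, 0.0)
    return ActivityTimeSeries(times=t, residual=residual, label=label)


#: Centres of the ten descriptor regions on the σ axis (e/Å²).
REGION_CENTERS = np.array(
    [sp.SIGMA_MIN + sp.REGION_WIDTH * (i + 0.5) for i in range(sp.N_REGIONS)]
)


def synth_recovery_table(
    n: int,
    seed: int = 0,
    planted: tuple = (2, 5, 8),
    spec: SyntheticSpec = SyntheticSpec(),
) -> pd.DataFrame:
    """A descriptor table designed for planted-signal recovery studies.

    Each row integrates one synthetic profile in which narrow peaks at
    the centres of the planted regions share a latent driver (so the
    planted descriptor columns are strongly mutually correlated and each
    tracks the signal marginally), while broad background peaks scatter
    independent mass over the whole window.  Feeding the result to
    :func:`synth_qspr_truth` with the linear family yields data where
    the planted descriptors — and only those — carry rank correlation
    with k.
    """
    rng = np.random.default_rng(seed)
    grid = np.linspace(sp.SIGMA_MIN, sp.SIGMA_MAX, spec.n_grid)
    records = []
    for i in range(n):
        u = rng.normal()
        density = np.zeros_like(grid)
        for j in planted:
            amp = 45.0 * (1.0 + 0.85 * np.tanh(u + 0.3 * rng.normal()))
            density += amp * np.exp(
                -0.5 * ((grid - REGION_CENTERS[j]) / 0.0009) ** 2
            )
        for _ in range(4):
            c = rng.uniform(sp.SIGMA_MIN + 0.002, sp.SIGMA_MAX - 0.002)
            w = rng.uniform(0.0015, 0.0035)
            density += rng.uniform(5.0, 25.0) * np.exp(-0.5 * ((grid - c) / w) ** 2)
        profile = sp.SigmaProfile(
            name=f"recovery-{i}", sigma=grid, p=density,
            grid_spacing=float(grid[1] - grid[0]),
        )
        d = sp.integrate_descriptors(profile)
        rec = {"label": f"SAMPLE {i + 1}"}
        rec.update({f"S{j + 1}": d.S[j] for j in range(sp.N_REGIONS)})
        records.append(rec)
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class QSPRTruth:
    """The generated ground-truth map and its bookkeeping."""

    family: str
    planted: tuple
    coefficients: dict
    z_mean: np.ndarray
    z_std: np.ndarray

    def log10_k(self, descriptors: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(descriptors, dtype=float))
        Z = (X[:, list(self.planted)] - self.z_mean) / self.z_std
        if self.family == "linear":
            w = np.asarray(self.coefficients["w"])
            return self.coefficients["b"] + Z @ w
        W1 = np.asarray(self.coefficients["W1"])
        b1 = np.asarray(self.coefficients["b1"])
        w2 = np.asarray(self.coefficients["w2"])
        return self.coefficients["b2"] + np.tanh(Z @ W1 + b1) @ w2


def synth_qspr_truth(
    descriptor_table: pd.DataFrame,
    spec: SyntheticSpec = SyntheticSpec(),
    seed: int | None = None,
    enzyme: str = "synthetic-enzyme",
) -> tuple[QSPRDataset, QSPRTruth]:
    """Attach a ground-truth response k to a descriptor table.

    ``log₁₀ k = g(planted descriptors) + noise`` where g is either
    linear or a shallow tanh network, scaled to the spec's log₁₀ k
    center and spread.  The returned :class:`QSPRTruth` records the
    planted indices and g's parameters for recovery assertions.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    X = descriptor_table[list(DESCRIPTOR_COLUMNS)].to_numpy(float)
    planted = tuple(int(i) for i in spec.planted)
    Zraw = X[:, list(planted)]
    z_mean = Zraw.mean(axis=0)
    z_std = Zraw.std(axis=0)
    z_std = np.where(z_std > 0, z_std, 1.0)
    q = len(planted)
    if spec.truth_family == "linear":
        # equal-magnitude weights, signs aligned with the planted columns'
        # mutual correlation so every planted descriptor tracks g marginally
        Zs = (Zraw - z_mean) / z_std
        R = np.corrcoef(Zs.T) if q > 1 else np.ones((1, 1))
        evec = np.linalg.eigh(R)[1][:, -1]
        signs = np.sign(evec)
        signs[signs == 0] = 1.0
        if signs[0] < 0:
            signs = -signs
        coeff = {"w": signs, "b": 0.0}
    else:
        # monotone in every planted descriptor (positive hidden weights on
        # sign-aligned inputs): nonlinear through tanh saturation and
        # hidden-unit interactions, but consistent with the monotone-
        # relevance assumption behind Spearman input screening.  Signs are
        # aligned with the planted columns' mutual correlation so their
        # contributions add instead of cancelling.
        Zs = (Zraw - z_mean) / z_std
        R = np.corrcoef(Zs.T) if q > 1 else np.ones((1, 1))
        evec = np.linalg.eigh(R)[1][:, -1]
        signs = np.sign(evec)
        signs[signs == 0] = 1.0
        if signs[0] < 0:
            signs = -signs
        h = 4
        coeff = {
            "W1": signs[:, None] * rng.uniform(0.2, 1.0, (q, h)),
            "b1": rng.uniform(-1.0, 1.0, h),
            "w2": rng.uniform(0.5, 1.0, h),
            "b2": 0.0,
        }
    truth = QSPRTruth(family=spec.truth_family, planted=planted,
                      coefficients=coeff, z_mean=z_mean, z_std=z_std)
    g = truth.log10_k(X)
    g_sd = g.std() or 1.0
    # rescale g to the requested log10 k location/spread
    if spec.truth_family == "linear":
        coeff = {"w": coeff["w"] * spec.k_log10_spread / g_sd,
                 "b": spec.k_log10_center - g.mean() * spec.k_log10_spread / g_sd}
    else:
        coeff = dict(coeff)
        coeff["w2"] = coeff["w2"] * spec.k_log10_spread / g_sd
        coeff["b2"] = spec.k_log10_center - g.mean() * spec.k_log10_spread / g_sd
    truth = QSPRTruth(family=spec.truth_family, planted=planted,
                      coefficients=coeff, z_mean=z_mean, z_std=z_std)
    log10k = truth.log10_k(X)
    if spec.truth_noise_sd > 0:
        log10k = log10k + rng.normal(0.0, spec.truth_noise_sd, log10k.size)
    table = descriptor_table.copy()
    table["k_per_h"] = 10.0**log10k
    dataset = QSPRDataset(table=table, enzyme=enzyme, transform="log10")
    return dataset, truth
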