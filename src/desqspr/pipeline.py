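"""File-based pipeline orchestration.

Each stage consumes files and writes files before the next stage starts,
so a run directory is a complete, re-runnable record: σ-profiles →
constituent descriptors → mixture descriptors → kinetic fits → QSPR
dataset → trained model → evaluation report, plus a provenance manifest
(config hash, seed, stage list).  Re-running with the same config and
inputs reproduces identical outputs.

The module also exposes :func:`run_synthetic_study`, the in-memory
end-to-end path used by the test-suite and the acceptance script:
generate a library, plant a descriptor→k truth, simulate decay series,
fit rate constants, select inputs, train networks and evaluate them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import sigma_profiles as sp
from . import mixtures as mx
from . import kinetics as kin
from . import qspr_ann as qa
from . import synthetic_data as syn
from . import evaluation as ev

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "run_synthetic_study",
    "SyntheticStudyResult",
    "stage_simulate",
    "stage_descriptors",
    "stage_mix",
    "stage_fit_kinetics",
    "stage_train",
    "stage_evaluate",
    "fit_series_with_fallback",
]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, with one explicit seed."""

    out_dir: str = "run"
    profiles_dir: str | None = None
    recipes_file: str | None = None
    kinetics_file: str | None = None
    area_convention: str = "ordinate-is-area"
    epsilon: float = 6220.0
    path_length: float = 0.61
    censoring_policy: str = "drop_over_100"
    selection_threshold: float = 0.4
    calibration_fraction: float = 55.0 / 84.0
    search_candidates: int = 20
    metric_denominator: str = "sep"
    seed: int = 0
    simulate: bool = True
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and the offending record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: PipelineConfig, out: Path) -> dict:
    """Emit the synthetic fixture tree: profiles/, recipes.yaml, decays.csv,
    truth.json."""
    spec = syn.SyntheticSpec(seed=config.seed, **config.synthetic)
    library = syn.synth_library(spec)
    profiles_dir = out / "profiles"
    profiles_dir.mkdir(parents=True, exist_ok=True)
    for name, profile in library.profiles.items():
        sp.write_sigma_profile(profile, profiles_dir / f"{name}.txt")
    systems_doc = {
        "water_levels": list(spec.water_levels),
        "systems": [
            {
                "index": s.index,
                "abbrev": s.abbrev,
                "solid_at": sorted(s.solid_at),
                "constituents": [
                    {"name": c.name, "molar_mass": c.molar_mass,
                     "role": c.role, "parts": parts}
                    for c, parts in s.constituents
                ],
            }
            for s in library.systems
        ],
    }
    (out / "recipes.yaml").write_text(yaml.safe_dump(systems_doc, sort_keys=False))

    dataset, truth = syn.synth_qspr_truth(library.descriptor_table, spec)
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    k_true = {}
    for label, k_h in zip(dataset.table["label"], dataset.table["k_per_h"]):
        k_day = float(k_h) * kin.HOURS_PER_DAY
        k_true[label] = float(k_h)
        series = syn.synth_decay_series(
            k_day, spec, seed=int(rng.integers(2**31 - 1)), label=label
        )
        for t, r in zip(series.times, series.residual):
            rows.append({"label": label, "time_days": t, "residual_percent": r})
    pd.DataFrame(rows).to_csv(out / "decays.csv", index=False)
    truth_doc = {
        "family": truth.family,
        "planted": list(truth.planted),
        "coefficients": {k: np.asarray(v).tolist()
                         for k, v in truth.coefficients.items()},
        "z_mean": truth.z_mean.tolist(),
        "z_std": truth.z_std.tolist(),
        "k_true_per_h": k_true,
    }
    (out / "truth.json").write_text(json.dumps(truth_doc, indent=1))
    return {"n_recipes": library.n, "n_profiles": len(library.profiles)}


def stage_descriptors(profiles_dir: Path, out_csv: Path,
                      area_convention: str = "ordinate-is-area") -> pd.DataFrame:
    """Integrate every σ-profile file into its S-descriptor row."""
    items = []
    for path in sorted(Path(profiles_dir).glob("*.txt")):
        try:
            profile = sp.read_sigma_profile(path, area_convention)
            items.append((profile.name, sp.integrate_descriptors(profile)))
        except sp.SigmaProfileError as exc:
            raise StageError("descriptors", str(exc)) from exc
    if not items:
        raise StageError("descriptors", f"no profile files in {profiles_dir}")
    table = sp.descriptor_table(items)
    table.to_csv(out_csv, index=False)
    return table


def stage_mix(recipes_file: Path, descriptors_csv: Path, out_csv: Path) -> pd.DataFrame:
    """Mole fractions + linear mixing: per-DES mixture descriptors."""
    doc = yaml.safe_load(Path(recipes_file).read_text())
    dtable = pd.read_csv(descriptors_csv).set_index("name")

    def constituent(entry: dict) -> mx.Constituent:
        name = entry["name"]
        if name not in dtable.index:
            raise StageError("mix", f"no descriptors for constituent {name!r}")
        row = dtable.loc[name]
        d = sp.DescriptorVector(
            S=row[[f"S{i + 1}" for i in range(sp.N_REGIONS)]].to_numpy(float),
            truncated_mass=float(row.get("truncated_mass", 0.0)),
        )
        return mx.Constituent(name=name, molar_mass=float(entry["molar_mass"]),
                              descriptors=d, role=entry.get("role", "HBD"))

    systems = []
    for s in doc["systems"]:
        members = tuple(
            (constituent(e), float(e["parts"])) for e in s["constituents"]
        )
        systems.append(mx.DESSystem(index=int(s["index"]),
                                    abbrev=s.get("abbrev", f"SYS{s['index']}"),
                                    constituents=members,
                                    solid_at=frozenset(s.get("solid_at", []))))
    water = constituent({"name": "water", "molar_mass": mx.WATER_MOLAR_MASS,
                         "role": "water"})
    recipes = mx.enumerate_library(systems, doc["water_levels"])
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
    table.to_csv(out_csv, index=False)
    return table


def fit_series_with_fallback(series: kin.ActivityTimeSeries,
                             policy: str = "drop_over_100") -> kin.InactivationFit:
    """Censor then fit; falls back to a fixed-100% intercept when censoring
    leaves only two points."""
    censored = kin.censor_series(series, policy)
    if censored.n_points >= 3:
        fit = kin.fit_first_order(censored)
    elif censored.n_points == 2:
        fit = kin.fit_first_order(censored, fix_intercept=True)
        fit = replace(fit, flags=fit.flags + ("intercept_fixed",))
    else:
        raise kin.FitError(f"{series.label}: fewer than 2 points after censoring")
    return fit


def stage_fit_kinetics(decays_csv: Path, out_csv: Path,
                       policy: str = "drop_over_100") -> pd.DataFrame:
    """Fit the first-order inactivation model per label."""
    data = pd.read_csv(decays_csv)
    records = []
    for label, grp in data.groupby("label", sort=True):
        grp = grp.sort_values("time_days")
        series = kin.ActivityTimeSeries(
            times=grp["time_days"].to_numpy(float),
            residual=grp["residual_percent"].to_numpy(float),
            label=str(label),
        )
        try:
            fit = fit_series_with_fallback(series, policy)
        except kin.FitError as exc:
            raise StageError("fit-kinetics", str(exc)) from exc
        records.append({
            "label": label,
            "k_per_h": fit.k_per_h,
            "k_per_day": fit.k_per_day,
            "k_stderr_per_day": fit.k_stderr_per_day,
            "A_R0": fit.A_R0,
            "t_half_days": fit.t_half_days,
            "n_used": fit.n_used,
            "censored_n": series.n_points - fit.n_used,
            "flags": ";".join(fit.flags),
        })
    table = pd.DataFrame.from_records(records)
    table.to_csv(out_csv, index=False)
    return table


def stage_train(mix_csv: Path, kinetics_csv: Path, out_dir: Path,
                threshold: float, calibration_fraction: float,
                n_candidates: int, seed: int,
                enzyme: str = "synthetic-enzyme") -> tuple:
    """Assemble the QSPR dataset, select inputs, split, and search."""
    mixes = pd.read_csv(mix_csv)
    fits = pd.read_csv(kinetics_csv)[["label", "k_per_h"]]
    table = mixes.merge(fits, on="label", how="inner")
    if len(table) < len(mixes):
        missing = set(mixes["label"]) - set(table["label"])
        raise StageError("train", f"no kinetics for labels {sorted(missing)}")
    dataset = qa.QSPRDataset(table=table, enzyme=enzyme, transform="log10")
    table.to_csv(out_dir / "dataset.csv", index=False)
    rho = qa.spearman_matrix(dataset)
    selected = qa.select_inputs(rho, threshold)
    spec = qa.SplitSpec(calibration_fraction=calibration_fraction, seed=seed)
    partition = qa.split_dataset(dataset.n, spec)
    arch_inputs = len(selected)
    model, leaderboard = qa.random_search(
        dataset, partition, selected, n_candidates=n_candidates, seed=seed
    )
    qa.save_model(model, out_dir / "model.json")
    leaderboard.to_csv(out_dir / "leaderboard.csv", index=False)
    (out_dir / "selection.json").write_text(json.dumps({
        "spearman_rho": rho.tolist(),
        "threshold": threshold,
        "selected_indices": list(selected),
        "selected_descriptors": [f"S{i + 1}" for i in selected],
        "network": model.architecture.name,
    }, indent=1))
    return dataset, partition, model, leaderboard


def stage_evaluate(dataset: qa.QSPRDataset, partition: qa.Partition,
                   model: qa.TrainedModel, out_path: Path,
                   denominator: str = "sep") -> ev.EvaluationReport:
    """Held-out prediction metrics + classification, serialized to JSON."""
    X = dataset.descriptors()
    y = dataset.response()
    idx = partition.prediction
    yhat = np.log10(qa.predict(model, X[idx])) if dataset.transform == "log10" \
        else qa.predict(model, X[idx])
    report = ev.prediction_metrics(y[idx], yhat,
                                   n_predictors=model.architecture.n_inputs,
                                   denominator=denominator)
    for key, value in model.metrics.items():
        setattr(report, key, value) if hasattr(report, key) else None
    doc = report.to_dict()
    doc["network"] = model.architecture.name
    doc["response_scale"] = dataset.transform
    Path(out_path).write_text(json.dumps(doc, indent=1, default=float))
    return report


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order, writing a provenance manifest at the end."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    if config.simulate:
        stage_simulate(config, out)
        stages.append("simulate")
        profiles_dir = out / "profiles"
        recipes_file = out / "recipes.yaml"
        decays_csv = out / "decays.csv"
    else:
        if not (config.profiles_dir and config.recipes_file and config.kinetics_file):
            raise StageError("config", "non-simulated runs need profiles_dir, "
                             "recipes_file and kinetics_file")
        profiles_dir = Path(config.profiles_dir)
        recipes_file = Path(config.recipes_file)
        decays_csv = Path(config.kinetics_file)

    stage_descriptors(profiles_dir, out / "descriptors.csv",
                      config.area_convention)
    stages.append("descriptors")
    stage_mix(recipes_file, out / "descriptors.csv", out / "mixtures.csv")
    stages.append("mix")
    stage_fit_kinetics(decays_csv, out / "kinetics.csv",
                       config.censoring_policy)
    stages.append("fit-kinetics")
    dataset, partition, model, _ = stage_train(
        out / "mixtures.csv", out / "kinetics.csv", out,
        threshold=config.selection_threshold,
        calibration_fraction=config.calibration_fraction,
        n_candidates=config.search_candidates,
        seed=config.seed,
    )
    stages.append("train")
    stage_evaluate(dataset, partition, model, out / "report.json",
                   config.metric_denominator)
    stages.append("evaluate")
    manifest = {
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


# ---------------------------------------------------------------------------
# in-memory end-to-end study

@dataclass
class SyntheticStudyResult:
    """Everything the end-to-end synthetic study produces."""

    library: syn.SyntheticLibrary
    truth: syn.QSPRTruth
    k_true_per_h: np.ndarray
    fits: pd.DataFrame
    dataset: qa.QSPRDataset
    spearman_rho: np.ndarray
    selected: tuple
    partition: qa.Partition
    model: qa.TrainedModel
    leaderboard: pd.DataFrame
    report: ev.EvaluationReport


def run_synthetic_study(
    seed: int = 0,
    spec: syn.SyntheticSpec | None = None,
    threshold: float | None = None,
    n_candidates: int = 12,
    settings: qa.TrainingSettings | None = None,
) -> SyntheticStudyResult:
    """Generate → simulate → fit → select → train → evaluate, in memory.

    The generated library's descriptors feed the planted truth map; rate
    constants are *measured* by fitting simulated decay series (never
    copied from the truth), then modelled from the mixture descriptors.
    With ``threshold=None`` all ten descriptors enter the network (the
    nets are free to down-weight irrelevant inputs); a float enables
    Spearman pre-screening at that |ρ| cutoff.
    """
    spec = replace(spec or syn.SyntheticSpec(), seed=seed)
    library = syn.synth_library(spec)
    truth_dataset, truth = syn.synth_qspr_truth(library.descriptor_table, spec)
    k_true_h = truth_dataset.table["k_per_h"].to_numpy(float)

    rng = np.random.default_rng(seed + 1)
    records = []
    for label, k_h in zip(truth_dataset.table["label"], k_true_h):
        series = syn.synth_decay_series(
            float(k_h) * kin.HOURS_PER_DAY, spec,
            seed=int(rng.integers(2**31 - 1)), label=label,
        )
        fit = fit_series_with_fallback(series)
        records.append({"label": label, "k_per_h": fit.k_per_h,
                        "k_per_day": fit.k_per_day,
                        "t_half_days": fit.t_half_days,
                        "n_used": fit.n_used,
                        "flags": ";".join(fit.flags)})
    fits = pd.DataFrame.from_records(records)

    table = library.descriptor_table.merge(fits[["label", "k_per_h"]], on="label")
    dataset = qa.QSPRDataset(table=table, enzyme="synthetic-enzyme",
                             transform="log10")
    rho = qa.spearman_matrix(dataset)
    if threshold is None:
        selected = tuple(range(qa.N_REGIONS))
    else:
        selected = qa.select_inputs(rho, threshold)
    partition = qa.split_dataset(dataset.n, qa.SplitSpec(seed=seed))
    model, leaderboard = qa.random_search(
        dataset, partition, selected, n_candidates=n_candidates, seed=seed,
        settings=settings,
    )
    X = dataset.descriptors()
    y = dataset.response()
    idx = partition.prediction
    yhat = np.log10(qa.predict(model, X[idx]))
    report = ev.prediction_metrics(y[idx], yhat,
                                   n_predictors=model.architecture.n_inputs)
    return SyntheticStudyResult(
        library=library, truth=truth, k_true_per_h=k_true_h, fits=fits,
        dataset=dataset, spearman_rho=rho, selected=selected,
        partition=partition, model=model, leaderboard=leaderboard,
        report=report,
    )
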