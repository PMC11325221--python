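"""Chemometric model evaluation: calibration metrics, prediction metrics,
and the RPD/RER quality classification.

Calibration metrics are the per-block coefficient of determination
R² = 1 − SS_res/SS_tot and RMSE over the training, test and validation
blocks.  Prediction metrics on the fully held-out set are the standard
chemometric battery:

    RMSEP = sqrt(Σe²/n)                    e = ŷ − y
    bias  = mean(e)
    SEP   = sqrt(Σ(e − bias)²/(n−1))       bias-corrected scatter
    RPD   = SD(observed)/SEP
    RER   = range(observed)/SEP
    R²_pred,adj = 1 − (1 − R²_pred)(n−1)/(n−p−1)

RPD and RER admit an RMSEP-denominator variant (``denominator="rmsep"``)
for sensitivity analysis; SEP is the default.

Quality bands: RPD < 1.4 → non-reliable, 1.4 ≤ RPD ≤ 2 → fair,
RPD > 2 → excellent.  Usability bands from RER: > 4 data screening,
> 10 quality control, > 15 quantification (highest band wins); a model
is "substantial" when R²_pred > 0.75.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "EvaluationReport",
    "calibration_metrics",
    "prediction_metrics",
    "classify_model",
    "QUALITY_LEVELS",
    "USABILITY_LEVELS",
]

QUALITY_LEVELS = ("non-reliable", "fair", "excellent")
USABILITY_LEVELS = ("none", "screening", "quality-control", "quantification")


@dataclass
class EvaluationReport:
    """Calibration + prediction metrics for one trained QSPR model."""

    r2_train: float = math.nan
    r2_test: float = math.nan
    r2_validation: float = math.nan
    rmse_train: float = math.nan
    rmse_test: float = math.nan
    rmse_validation: float = math.nan
    r2_pred: float = math.nan
    r2_pred_adj: float = math.nan
    rmsep: float = math.nan
    sep: float = math.nan
    bias: float = math.nan
    rpd: float = math.nan
    rer: float = math.nan
    n_pred: int = 0
    n_predictors: int = 0
    quality: str = ""
    usability: str = ""
    substantial: bool = False
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    ss_res = float(np.sum((observed - predicted) ** 2))
    if ss_tot == 0.0:
        return math.nan
    return 1.0 - ss_res / ss_tot


def calibration_metrics(
    observed: np.ndarray,
    predicted: np.ndarray,
    blocks: np.ndarray,
) -> dict[str, dict[str, float]]:
    """Per-block R² and RMSE.

    ``blocks`` labels each point (e.g. ``"train"``/``"test"``/
    ``"validation"``).  A block whose observations have zero variance
    gets R² = NaN with a flag entry instead of a crash.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    blocks = np.asarray(blocks)
    out: dict[str, dict[str, float]] = {}
    for name in dict.fromkeys(blocks.tolist()):
        m = blocks == name
        if m.sum() < 2:
            raise ValueError(f"block {name!r} has fewer than 2 points")
        o, p = observed[m], predicted[m]
        r2 = _r2(o, p)
        out[str(name)] = {
            "r2": r2,
            "rmse": float(np.sqrt(np.mean((o - p) ** 2))),
            "n": int(m.sum()),
            "zero_variance": bool(np.ptp(o) == 0),
        }
    return out


def prediction_metrics(
    observed: np.ndarray,
    predicted: np.ndarray,
    n_predictors: int,
    denominator: str = "sep",
) -> EvaluationReport:
    """Held-out prediction metrics (RMSEP, SEP, RPD, RER, adjusted R²)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    n = observed.size
    if n < 3:
        raise ValueError("prediction set needs at least 3 points")
    if denominator not in ("sep", "rmsep"):
        raise ValueError(f"unknown denominator {denominator!r}")
    e = predicted - observed
    rmsep = float(np.sqrt(np.mean(e**2)))
    bias = float(e.mean())
    sep = float(np.sqrt(np.sum((e - bias) ** 2) / (n - 1)))
    sd_obs = float(observed.std(ddof=1))
    rng_obs = float(np.ptp(observed))
    denom = sep if denominator == "sep" else rmsep
    rpd = sd_obs / denom if denom > 0 else math.inf
    rer = rng_obs / denom if denom > 0 else math.inf
    r2_pred = _r2(observed, predicted)
    flags: list[str] = []
    p = n_predictors
    if n - p - 1 > 0:
        r2_adj = 1.0 - (1.0 - r2_pred) * (n - 1) / (n - p - 1)
    else:
        r2_adj = math.nan
        flags.append("r2_adj_undefined")
    report = EvaluationReport(
        r2_pred=r2_pred,
        r2_pred_adj=r2_adj,
        rmsep=rmsep,
        sep=sep,
        bias=bias,
        rpd=rpd,
        rer=rer,
        n_pred=int(n),
        n_predictors=int(p),
        flags=flags,
    )
    quality, usability, substantial = classify_model(report)
    report.quality, report.usability, report.substantial = quality, usability, substantial
    return report


def classify_model(report: EvaluationReport) -> tuple[str, str, bool]:
    """Qualitative model classification from (RPD, RER, R²_pred).

    RPD bands: < 1.4 non-reliable; 1.4–2 (both ends inclusive) fair;
    > 2 excellent.  RER bands (highest wins): > 15 quantification,
    > 10 quality control, > 4 screening, otherwise none.  The
    "substantial" flag is R²_pred > 0.75.
    """
    rpd, rer = report.rpd, report.rer
    if rpd < 1.4:
        quality = "non-reliable"
    elif rpd <= 2.0:
        quality = "fair"
    else:
        quality = "excellent"
    if rer > 15.0:
        usability = "quantification"
    elif rer > 10.0:
        usability = "quality-control"
    elif rer > 4.0:
        usability = "screening"
    else:
        usability = "none"
    substantial = bool(report.r2_pred > 0.75)
    return quality, usability, substantial
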