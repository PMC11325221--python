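#!/usr/bin/env python
"""Train the QSPR networks: Spearman screening + randomized MLP search.

Joins mixture descriptors with fitted rate constants, screens inputs by
rank correlation, splits calibration/prediction, and searches MLP
architectures (widths 4–13, four activation functions), ranking by
validation R².  Writes dataset.csv, selection.json, leaderboard.csv and
model.json into the study tree.
"""

import argparse
import json
from pathlib import Path

from desqspr import pipeline as pl


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", type=Path, default=Path("results/study"))
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--threshold", type=float, default=0.4)
    parser.add_argument("--candidates", type=int, default=32)
    args = parser.parse_args()

    out = args.study
    dataset, partition, model, board = pl.stage_train(
        out / "mixtures.csv", out / "kinetics.csv", out,
        threshold=args.threshold, calibration_fraction=55.0 / 84.0,
        n_candidates=args.candidates, seed=args.seed,
    )
    selection = json.loads((out / "selection.json").read_text())
    print(f"selected inputs: {', '.join(selection['selected_descriptors'])} "
          f"(|rho| >= {args.threshold})")
    print(f"winner: {model.architecture.name} "
          f"({model.architecture.hidden_activation}/"
          f"{model.architecture.output_activation}) — "
          f"train R² {model.metrics['r2_train']:.4f}, "
          f"validation R² {model.metrics['r2_validation']:.4f}")
    print(f"leaderboard: {len(board)} candidates in {out/'leaderboard.csv'}")

    report = pl.stage_evaluate(dataset, partition, model, out / "report.json")
    print(f"held-out prediction: R²_pred {report.r2_pred:.4f}, "
          f"RMSEP {report.rmsep:.4f}, SEP {report.sep:.4f}")


if __name__ == "__main__":
    main()
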