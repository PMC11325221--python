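#!/usr/bin/env python
"""Chemometric verdict on the trained QSPR model.

Reads the study's report.json and prints the full prediction battery
(R²_pred, adjusted R², RMSEP, SEP, RPD, RER) with the quality bands:
RPD < 1.4 non-reliable / 1.4–2 fair / > 2 excellent, and RER > 4
screening / > 10 quality control / > 15 quantification.
"""

import argparse
import json
from pathlib import Path


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", type=Path, default=Path("results/study"))
    args = parser.parse_args()

    doc = json.loads((args.study / "report.json").read_text())
    print(f"network {doc['network']} on the {doc['response_scale']}(k) scale, "
          f"n_pred = {doc['n_pred']}")
    for key in ("r2_pred", "r2_pred_adj", "rmsep", "sep", "bias", "rpd", "rer"):
        print(f"  {key:>12} = {doc[key]:.4f}")
    print(f"  quality: {doc['quality']}   usability: {doc['usability']}   "
          f"substantial (R²_pred > 0.75): {doc['substantial']}")


if __name__ == "__main__":
    main()
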