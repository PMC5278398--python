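"""Confusion-matrix evaluation of the selected classifier, and the
reference-table cross-check.

Part 1 scores the out-of-fold predictions from 04_grid_search_svm.py:
confusion matrix, per-class precision/recall/F1, average F1 and accuracy.

Part 2 recomputes the same metrics from the packaged published confusion
matrix (20,700 windows) and prints them next to its published percentages —
a check that the metric implementation reproduces the reference report.

Writes results/metrics_synthetic.csv and results/metrics_reference.csv.
"""

from pathlib import Path

import pandas as pd

from hingeforce.evaluate import (
    load_reference_confusion,
    metrics,
    read_predictions_csv,
    round_percent,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def report_frame(report):
    frame = report.to_frame().map(round_percent)
    return frame


def main() -> None:
    cm = read_predictions_csv(ROOT / "predictions.csv")
    report = metrics(cm)
    frame = report_frame(report)
    frame.to_csv(ROOT / "metrics_synthetic.csv")
    print("synthetic cohort (out-of-fold predictions), % :")
    print(frame.to_string())
    print(f"average F1: {round_percent(report.average_f1)}%   "
          f"accuracy: {round_percent(report.accuracy)}%")

    ref = metrics(load_reference_confusion())
    ref_frame = report_frame(ref)
    ref_frame.to_csv(ROOT / "metrics_reference.csv")
    print("\nreference confusion matrix (20,700 windows), % :")
    print(ref_frame.to_string())
    print(f"average F1: {round_percent(ref.average_f1)}%   "
          f"accuracy: {round_percent(ref.accuracy)}%")


if __name__ == "__main__":
    main()
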