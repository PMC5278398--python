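"""Two-step (C, gamma) grid search with leave-one-subject-out validation.

Reads results/features.csv (from 03_extract_features.py) and scores an
RBF-SVM over an exponential coarse lattice, then a fine lattice centered on
the coarse optimum.  Every pair is evaluated by leave-one-subject-out
cross-validation with the scaler refit per fold, so accuracies measure
generalization to unseen subjects.

Writes results/grid_surface.csv and results/predictions.csv (out-of-fold
predictions of the selected model).
"""

from pathlib import Path

import pandas as pd

from hingeforce.behaviors import Behavior
from hingeforce.classify import FineSpec, GridSpec, grid_search
from hingeforce.features import from_table

ROOT = Path(__file__).resolve().parents[1] / "results"

COARSE = GridSpec(log2_C=(0.0, 4.0, 8.0), log2_gamma=(-11.0, -7.0, -3.0))
FINE = FineSpec(span=2.0, step=1.0)


def main() -> None:
    vectors = from_table(pd.read_csv(ROOT / "features.csv"))
    result = grid_search(vectors, coarse=COARSE, fine=FINE)

    pd.DataFrame(
        [{"C": c.C, "gamma": c.gamma, "accuracy": a} for c, a in result.grid]
    ).to_csv(ROOT / "grid_surface.csv", index=False)
    pd.DataFrame(
        {
            "actual": [v.label.name for v in vectors],
            "predicted": [Behavior(int(p)).name for p in result.best_predictions],
            "subject_id": [v.subject_id for v in vectors],
        }
    ).to_csv(ROOT / "predictions.csv", index=False)

    print(f"searched {len(result.grid)} (C, gamma) pairs over "
          f"{len({v.subject_id for v in vectors})} LOSO folds")
    print(f"best: C={result.best.C:g}, gamma={result.best.gamma:g} "
          f"at pooled accuracy {result.best_accuracy:.3f}")
    print(f"surface: {ROOT / 'grid_surface.csv'}")
    print(f"out-of-fold predictions: {ROOT / 'predictions.csv'}")


if __name__ == "__main__":
    main()
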