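#!/usr/bin/env python
"""LeNet CNN on per-cell lifetime-component images: channel-set comparison.

Trains the CNN on 40x40 per-cell stacks for two channel sets — all NAD(P)H
lifetime components vs NAD(P)H intensity alone — on 600 simulated cells per
run, and compares held-out accuracy.  Lifetime channels carry the phenotype
signal directly; per-image-normalized intensity carries mostly morphology,
so the all-component model should win.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import flimpheno as fp
from flimpheno import cnn

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 70


def main():
    OUT.mkdir(exist_ok=True)
    images, labels, names = fp.sample_cell_stacks(
        {"glycolysis_inhibited": 300, "oxphos_inhibited": 300}, seed=SEED)
    n_test = 150
    results = {}
    for setname in ("nadh_all", "nadh_intensity"):
        stacks = cnn.stacks_from_arrays(images, labels, names,
                                        cnn.CHANNEL_SETS[setname])
        cfg = cnn.TrainConfig(learning_rate=1e-3, epochs=10, patience=3,
                              seed=SEED)
        model, hist = fp.train_cnn(stacks[n_test:], cfg)
        rep = fp.evaluate_cnn(model, stacks[:n_test])
        results[setname] = rep
        pd.DataFrame(hist).to_csv(OUT / f"cnn_history_{setname}.csv",
                                  index=False)
        print(f"{setname}: test accuracy {rep['accuracy']:.3f}, "
              f"AUC {rep['auc']:.3f}, precision {rep['precision']:.3f}, "
              f"recall {rep['recall']:.3f} "
              f"({len(hist['epoch'])} epochs)")
    better = results["nadh_all"]["accuracy"] > results["nadh_intensity"]["accuracy"]
    print("all-NAD(P)H-component model outperforms intensity-only:", better)
    with open(OUT / "cnn_comparison.json", "w") as fh:
        json.dump(results, fh, indent=2)
    print(f"wrote {OUT / 'cnn_comparison.json'}")


if __name__ == "__main__":
    main()
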