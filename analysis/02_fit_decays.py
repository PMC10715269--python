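#!/usr/bin/env python
"""Fit per-pixel bi-exponential decays for both channels of the demo scene.

Applies 3x3 spatial binning, the per-channel peak-count thresholds (20
photons NAD(P)H, 3 FAD) and bounded least squares through the IRF, then
compares the recovered free-fraction map against the simulator's truth.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import flimpheno as fp
from flimpheno import io

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    cubes, irf, meta = io.load_scene_cubes(OUT / "scene.h5")
    import h5py
    with h5py.File(OUT / "scene.h5", "r") as f:
        true_a1 = f["truth/nadh/alpha1"][...]

    for ch in ("nadh", "fad"):
        flim = fp.fit_image(cubes[ch], irf)
        io.save_flim(OUT / "fits.h5", flim)
        io.save_flim_tiff(OUT / f"fits_{ch}.tif", flim)
        print(f"{ch}: {100 * flim.meta['valid_fraction']:.1f}% of pixels fitted, "
              f"mean reduced chi2 {flim.meta['mean_chi2']:.3f}")
        if ch == "nadh":
            m = flim.valid & ~np.isnan(true_a1)
            bias = np.nanmean(flim.alpha1[m] - true_a1[m])
            print(f"  alpha1 recovery bias vs truth: {bias:+.4f}")
    print(f"wrote {OUT / 'fits.h5'}")


if __name__ == "__main__":
    main()
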