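"""HDF5 / TIFF / CSV persistence for scenes, fits and labels."""

from __future__ import annotations

import json

import h5py
import numpy as np
import tifffile

from .fitting import FLIMImage
from .segmentation import SegmentationLabels
from .synth import (CHANNELS, IRF, GroundTruthScene, SceneSpec, TCSPCImage)


def save_scene(path, scene: GroundTruthScene, cubes, irf: IRF):
    """One HDF5 container: cubes, IRF, per-pixel truth, JSON metadata."""
    with h5py.File(path, "w") as f:
        for cube in cubes:
            g = f.create_group(f"cubes/{cube.channel}")
            g.create_dataset("counts", data=cube.counts, compression="gzip")
            g.attrs["dt"] = cube.dt
        f.create_dataset("irf/response", data=irf.response)
        f["irf"].attrs["dt"] = irf.dt
        f.create_dataset("truth/compartments", data=scene.compartments)
        f.create_dataset("truth/cell_ids", data=scene.cell_ids)
        for ch in CHANNELS:
            for p, img in scene.true_params[ch].items():
                f.create_dataset(f"truth/{ch}/{p}", data=img)
        f.attrs["metadata"] = json.dumps({
            "spec": {k: list(v) if isinstance(v, tuple) else v
                     for k, v in vars(scene.spec).items()},
            "phenotypes": {str(k): v for k, v in scene.phenotypes.items()},
        })


def load_scene_cubes(path):
    """Read back (cubes dict, IRF, metadata dict) from a scene container."""
    with h5py.File(path, "r") as f:
        cubes = {}
        for ch in f["cubes"]:
            g = f[f"cubes/{ch}"]
            cubes[ch] = TCSPCImage(counts=g["counts"][...],
                                   dt=float(g.attrs["dt"]), channel=ch)
        irf = IRF(response=f["irf/response"][...], dt=float(f["irf"].attrs["dt"]))
        meta = json.loads(f.attrs["metadata"])
    return cubes, irf, meta


def save_intensity_tiff(path, cube: TCSPCImage):
    tifffile.imwrite(path, cube.intensity.astype(np.float32))


def save_flim(path, flim: FLIMImage):
    """Parameter maps as an HDF5 group mirror."""
    with h5py.File(path, "a") as f:
        if flim.channel in f:
            del f[flim.channel]
        g = f.create_group(flim.channel)
        for name in ("alpha1", "tau1", "tau2", "c", "chi2", "intensity"):
            g.create_dataset(name, data=getattr(flim, name))
        g.create_dataset("valid", data=flim.valid)
        g.attrs["meta"] = json.dumps(flim.meta)


def load_flim(path, channel) -> FLIMImage:
    with h5py.File(path, "r") as f:
        g = f[channel]
        return FLIMImage(
            alpha1=g["alpha1"][...], tau1=g["tau1"][...], tau2=g["tau2"][...],
            c=g["c"][...], chi2=g["chi2"][...], intensity=g["intensity"][...],
            valid=g["valid"][...].astype(bool), channel=channel,
            meta=json.loads(g.attrs["meta"]))


def save_flim_tiff(path, flim: FLIMImage):
    """Multi-page 32-bit TIFF: alpha1, tau1, tau2, tau_m, intensity."""
    pages = np.stack([flim.alpha1, flim.tau1, flim.tau2, flim.tau_m,
                      flim.intensity]).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")


def save_labels(path, labels: SegmentationLabels):
    pages = np.stack([labels.cells, labels.nuclei, labels.cytoplasm,
                      labels.mitochondria.astype(np.int32)]).astype(np.uint16)
    tifffile.imwrite(path, pages, photometric="minisblack")


def load_labels(path) -> SegmentationLabels:
    pages = tifffile.imread(path).astype(np.int32)
    labels = SegmentationLabels(cells=pages[0], nuclei=pages[1],
                                cytoplasm=pages[2],
                                mitochondria=pages[3].astype(bool))
    from skimage.measure import regionprops
    labels.bboxes = {int(p.label): tuple(int(v) for v in p.bbox)
                     for p in regionprops(labels.cells)}
    return labels


def scene_spec_from_json(path) -> SceneSpec:
    with open(path) as fh:
        d = json.load(fh)
    for k in ("shape", "cell_radius", "nucleus_radius"):
        if k in d:
            d[k] = tuple(d[k])
    return SceneSpec(**d)
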