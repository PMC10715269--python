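"""Synthetic two-channel TCSPC fluorescence-lifetime scenes.

This module generates ground-truth cell scenes and the photon-count cubes a
time-correlated single-photon-counting (TCSPC) microscope would record from
them.  Each pixel of a scene carries a true bi-exponential decay

    I(t) = A * [alpha1 * exp(-t/tau1) + (1 - alpha1) * exp(-t/tau2)] (*) IRF + C

where ``alpha1`` is the fractional amplitude of the short-lifetime component,
``tau1 < tau2`` are the component lifetimes in nanoseconds, ``C`` is a
constant background per time bin and ``(*)`` denotes discrete convolution
with the normalized instrument response function.  Cells are compartmentalized
(dark nucleus, cytosol, bright mitochondrial puncta) and each cell draws its
decay parameters from a metabolic :class:`PhenotypeProfile`.

Two-channel conventions follow NAD(P)H / FAD autofluorescence imaging:
NAD(P)H is short-lived when free (its ``alpha1`` is the free fraction), FAD is
short-lived when protein-bound (its ``alpha1`` is the bound fraction).

Besides the full physics path (scene -> cubes), the module provides a
phenotype-level fast path (:func:`sample_cell_features`,
:func:`sample_cell_stacks`) that draws per-cell feature vectors or per-cell
40x40 parameter-image stacks directly from the same profiles, with calibrated
estimation noise standing in for the render-and-refit round trip.  This is
what the classifier-scale experiments (thousands of cells) use.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

NADH = "nadh"
FAD = "fad"
CHANNELS = (NADH, FAD)

BACKGROUND = 0
NUCLEUS = 1
CYTOSOL = 2
MITO = 3
COMPARTMENT_NAMES = {BACKGROUND: "background", NUCLEUS: "nucleus",
                     CYTOSOL: "cytosol", MITO: "mitochondria"}

#: canonical order of the twelve per-cell autofluorescence features
FEATURE_NAMES = [
    "redox_ratio", "flirr",
    "nadh_tm", "nadh_t1", "nadh_t2", "nadh_a1", "nadh_intensity",
    "fad_tm", "fad_t1", "fad_t2", "fad_a1", "fad_intensity",
]


class ValidationError(ValueError):
    """Raised when a simulation input violates its physical invariants."""


# --------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class DecayParams:
    """Mean/SD of bi-exponential decay parameters for one (channel, compartment).

    ``photons`` is the expected total photon count per pixel (background
    excluded); ``c`` is the constant background level in counts per time bin.
    SDs describe between-cell Gaussian jitter, truncated to valid ranges.
    """

    alpha1: float
    tau1: float
    tau2: float
    photons: float
    c: float = 0.0
    alpha1_sd: float = 0.0
    tau1_sd: float = 0.0
    tau2_sd: float = 0.0
    photons_sd: float = 0.0
    c_sd: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.alpha1 <= 1.0):
            raise ValidationError(f"alpha1={self.alpha1} outside [0, 1]")
        if not (0.0 < self.tau1 < self.tau2):
            raise ValidationError(
                f"require 0 < tau1 < tau2, got tau1={self.tau1}, tau2={self.tau2}")
        if self.photons < 0:
            raise ValidationError("expected photons must be >= 0")
        for sd in (self.alpha1_sd, self.tau1_sd, self.tau2_sd,
                   self.photons_sd, self.c_sd):
            if sd < 0:
                raise ValidationError("standard deviations must be >= 0")

    def sample(self, rng: np.random.Generator) -> "DecayParams":
        """Draw one jittered realization (a per-cell parameter set)."""
        a1 = float(np.clip(rng.normal(self.alpha1, self.alpha1_sd), 0.0, 1.0))
        t1 = float(max(rng.normal(self.tau1, self.tau1_sd), 0.05))
        t2 = float(max(rng.normal(self.tau2, self.tau2_sd), t1 * 1.05))
        ph = float(max(rng.normal(self.photons, self.photons_sd), 0.0))
        c = float(max(rng.normal(self.c, self.c_sd), 0.0))
        return DecayParams(alpha1=a1, tau1=t1, tau2=t2, photons=ph, c=c)


@dataclass(frozen=True)
class PhenotypeProfile:
    """Per-compartment, per-channel decay parameter distributions for one
    metabolic phenotype (e.g. control, glycolysis-inhibited, OXPHOS-inhibited).

    ``params`` maps ``(channel, compartment)`` to :class:`DecayParams`, with
    channel in {"nadh", "fad"} and compartment in {NUCLEUS, CYTOSOL, MITO}.
    """

    name: str
    params: dict = field(default_factory=dict)

    def get(self, channel: str, compartment: int) -> DecayParams:
        return self.params[(channel, compartment)]


@dataclass(frozen=True)
class SceneSpec:
    """Geometry of a simulated field of view."""

    shape: tuple = (256, 256)
    n_cells: int = 20
    cell_radius: tuple = (11.0, 16.0)
    nucleus_radius: tuple = (4.0, 6.0)
    # puncta per cytoplasm pixel; at disk radius 1-2 px this covers roughly a
    # fifth of the cytoplasm, the area fraction the brightest-20% proxy assumes
    mito_density: float = 0.04
    nucleus_intensity_ratio: float = 0.3
    seed: int = 0

    def validate(self):
        if self.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")
        if self.nucleus_radius[1] >= self.cell_radius[0]:
            raise ValidationError(
                "nucleus radius must be strictly smaller than cell radius")
        if not (0.0 < self.nucleus_intensity_ratio < 1.0):
            raise ValidationError("nucleus_intensity_ratio must be in (0, 1)")
        if self.mito_density < 0:
            raise ValidationError("mito_density must be >= 0")


@dataclass(frozen=True)
class IRF:
    """Time-binned instrument response histogram."""

    response: np.ndarray
    dt: float  # ns per bin

    def __post_init__(self):
        r = np.asarray(self.response, dtype=float)
        if r.ndim != 1 or r.size == 0:
            raise ValidationError("IRF must be a 1-D histogram")
        if np.any(r < 0):
            raise ValidationError("IRF must be nonnegative")
        if r.sum() <= 0:
            raise ValidationError("IRF must contain signal")
        object.__setattr__(self, "response", r)

    @property
    def n_bins(self) -> int:
        return self.response.size

    @property
    def normalized(self) -> np.ndarray:
        return self.response / self.response.sum()


@dataclass
class TCSPCImage:
    """Photon-count cube (rows, cols, time bins) for one spectral channel."""

    counts: np.ndarray
    dt: float
    channel: str

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ValidationError("TCSPC cube must be (rows, cols, bins)")
        if np.any(c < 0):
            raise ValidationError("photon counts must be nonnegative")
        self.counts = c

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def intensity(self) -> np.ndarray:
        """Total photons per pixel (sum over the time axis)."""
        return self.counts.sum(axis=2)


@dataclass
class GroundTruthScene:
    """A simulated field with full per-pixel truth.

    ``true_params[channel]`` maps parameter name ("alpha1", "tau1", "tau2",
    "photons", "c") to a float image; background pixels hold NaN except for
    "photons"/"c" which are 0 / ambient background.
    """

    spec: SceneSpec
    compartments: np.ndarray          # int image, codes above
    cell_ids: np.ndarray              # int image, 0 = background
    phenotypes: dict                  # cell id -> phenotype name
    true_params: dict                 # channel -> {param: image}
    cell_params: dict                 # (cell id, channel, compartment) -> DecayParams

    @property
    def n_cells(self) -> int:
        return int(len(self.phenotypes))


# --------------------------------------------------------------------------
# default time base and IRF

N_BINS_DEFAULT = 256
PERIOD_NS = 12.5          # 80 MHz laser repetition period
DT_DEFAULT = PERIOD_NS / N_BINS_DEFAULT


def gaussian_irf(n_bins: int = N_BINS_DEFAULT, dt: float = DT_DEFAULT,
                 center: float = 1.0, fwhm: float = 0.25) -> IRF:
    """Gaussian IRF centered early in the window (defaults: 1.0 ns, 0.25 ns FWHM)."""
    t = (np.arange(n_bins) + 0.5) * dt
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    r = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return IRF(response=r, dt=dt)


def delta_irf(n_bins: int = N_BINS_DEFAULT, dt: float = DT_DEFAULT) -> IRF:
    """Delta-function IRF (all weight in the first bin)."""
    r = np.zeros(n_bins)
    r[0] = 1.0
    return IRF(response=r, dt=dt)


# --------------------------------------------------------------------------
# phenotype presets
#
# Means encode the reported effect directions: inhibiting glycolysis lowers
# the free NAD(P)H fraction alpha1 and lengthens tau1/tau2; inhibiting OXPHOS
# (cyanide) does the opposite and raises NAD(P)H intensity while lowering FAD
# intensity (hence a lower intensity redox ratio).  FAD lifetimes carry no
# consistent phenotype shift.  Magnitudes are package choices, resolvable at
# the simulated photon budget (~1,000 photons per cytoplasm pixel).

_JITTER = dict(alpha1_sd=0.04, tau1_sd=0.05, tau2_sd=0.12,
               photons_sd=120.0, c_sd=0.0)
_FAD_BASE = dict(alpha1=0.70, tau1=0.35, tau2=2.2)


def _profile(name, nadh_a1, nadh_t1, nadh_t2, nadh_ph, fad_ph,
             fad_a1=None, nucleus_ratio=0.3, mito_gain=2.0, c=0.2):
    fad_a1 = _FAD_BASE["alpha1"] if fad_a1 is None else fad_a1
    params = {}
    for comp, ph_scale, a1_shift in ((NUCLEUS, nucleus_ratio, 0.0),
                                     (CYTOSOL, 1.0, 0.0),
                                     (MITO, mito_gain, -0.03)):
        params[(NADH, comp)] = DecayParams(
            alpha1=float(np.clip(nadh_a1 + a1_shift, 0, 1)),
            tau1=nadh_t1, tau2=nadh_t2,
            photons=nadh_ph * ph_scale, c=c, **_JITTER)
        params[(FAD, comp)] = DecayParams(
            alpha1=float(np.clip(fad_a1 - a1_shift, 0, 1)),
            tau1=_FAD_BASE["tau1"], tau2=_FAD_BASE["tau2"],
            photons=fad_ph * ph_scale, c=c, **_JITTER)
    return PhenotypeProfile(name=name, params=params)


def default_profiles(nucleus_ratio: float = 0.3,
                     mito_gain: float = 2.0) -> dict:
    """The shipped metabolic phenotype presets.

    Control NAD(P)H cytosol means are alpha1=0.75, tau1=0.5 ns, tau2=2.5 ns at
    1,000 expected photons per cytoplasm pixel.  Glycolysis inhibition shifts
    (alpha1, tau1, tau2) by (-0.06, +0.1, +0.3) with reduced intensities;
    OXPHOS inhibition shifts them by (+0.06, -0.1, -0.3) with brighter NAD(P)H
    and dimmer FAD.  The optional high-pyruvate preset raises the bound FAD
    fraction.
    """
    kw = dict(nucleus_ratio=nucleus_ratio, mito_gain=mito_gain)
    return {
        "control": _profile("control", 0.75, 0.50, 2.5, 1000.0, 450.0, **kw),
        "glycolysis_inhibited": _profile(
            "glycolysis_inhibited", 0.69, 0.60, 2.8, 800.0, 380.0, **kw),
        "oxphos_inhibited": _profile(
            "oxphos_inhibited", 0.81, 0.40, 2.2, 1200.0, 350.0, **kw),
        "high_pyruvate": _profile(
            "high_pyruvate", 0.75, 0.50, 2.5, 950.0, 480.0,
            fad_a1=0.78, **kw),
    }


# --------------------------------------------------------------------------
# decay model


def model_decay(alpha1: float, tau1: float, tau2: float, c: float,
                photons: float, irf: IRF) -> np.ndarray:
    """Expected counts per time bin for a bi-exponential decay through an IRF.

    The IRF-convolved noise-free curve (background excluded) is scaled to
    integrate to ``photons``; ``c`` counts per bin are then added.
    """
    if not (0.0 <= alpha1 <= 1.0):
        raise ValidationError(f"alpha1={alpha1} outside [0, 1]")
    if tau1 <= 0 or tau2 <= 0:
        raise ValidationError("lifetimes must be positive")
    if photons < 0 or c < 0:
        raise ValidationError("photons and background must be >= 0")
    shape = decay_shape(alpha1, tau1, tau2, irf)
    total = shape.sum()
    if photons == 0 or total <= 0:
        return np.full(irf.n_bins, float(c))
    return photons * shape / total + c


def decay_shape(alpha1: float, tau1: float, tau2: float, irf: IRF) -> np.ndarray:
    """Unnormalized IRF-convolved bi-exponential shape (no background)."""
    t = (np.arange(irf.n_bins) + 0.5) * irf.dt
    d = alpha1 * np.exp(-t / tau1) + (1.0 - alpha1) * np.exp(-t / tau2)
    return np.convolve(irf.normalized, d)[: irf.n_bins]


# --------------------------------------------------------------------------
# scene generation


def generate_scene(spec: SceneSpec, profile_assignment, rng_seed: int | None = None,
                   ) -> GroundTruthScene:
    """Place non-overlapping compartmentalized cells and draw per-cell truth.

    ``profile_assignment`` is either a list of :class:`PhenotypeProfile` (cells
    cycle through it) or a callable ``cell_index -> PhenotypeProfile``.
    Packing uses bounded rejection sampling; if fewer than ``spec.n_cells``
    fit, a warning is emitted and the scene holds the cells that were placed.
    """
    spec.validate()
    if isinstance(profile_assignment, PhenotypeProfile):
        profile_assignment = [profile_assignment]
    if callable(profile_assignment):
        prof_for = profile_assignment
    else:
        profs = list(profile_assignment)
        if not profs:
            raise ValidationError("at least one phenotype profile is required")
        prof_for = lambda i: profs[i % len(profs)]

    seed = spec.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    compartments = np.zeros((h, w), dtype=np.int8)
    cell_ids = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]

    # --- place cell centers by rejection sampling
    centers, radii = [], []
    attempts, max_attempts = 0, 300 * max(spec.n_cells, 1)
    while len(centers) < spec.n_cells and attempts < max_attempts:
        attempts += 1
        r = rng.uniform(*spec.cell_radius)
        cy = rng.uniform(r + 1, h - r - 1)
        cx = rng.uniform(r + 1, w - r - 1)
        if all(math.hypot(cy - oy, cx - ox) > r + orr + 2.0
               for (oy, ox), orr in zip(centers, radii)):
            centers.append((cy, cx))
            radii.append(r)
    if len(centers) < spec.n_cells:
        warnings.warn(
            f"placed only {len(centers)} of {spec.n_cells} requested cells",
            stacklevel=2)

    phenotypes, cell_params = {}, {}
    true_params = {ch: {p: np.full((h, w), np.nan)
                        for p in ("alpha1", "tau1", "tau2")}
                   for ch in CHANNELS}
    for ch in CHANNELS:
        true_params[ch]["photons"] = np.zeros((h, w))
        true_params[ch]["c"] = np.zeros((h, w))

    for i, ((cy, cx), r) in enumerate(zip(centers, radii)):
        cid = i + 1
        profile = prof_for(i)
        phenotypes[cid] = profile.name
        dist2 = (yy - cy) ** 2 + (xx - cx) ** 2
        cell_mask = dist2 <= r ** 2
        rn = rng.uniform(*spec.nucleus_radius)
        # nucleus offset stays well inside the cell
        max_off = max(r - rn - 2.0, 0.0)
        ang = rng.uniform(0, 2 * math.pi)
        off = rng.uniform(0, max_off * 0.5)
        ny, nx = cy + off * math.sin(ang), cx + off * math.cos(ang)
        nuc_mask = ((yy - ny) ** 2 + (xx - nx) ** 2 <= rn ** 2) & cell_mask
        cyto_mask = cell_mask & ~nuc_mask

        # mitochondrial puncta: Poisson-scattered disks of radius 1-2 px
        mito_mask = np.zeros_like(cell_mask)
        n_puncta = rng.poisson(spec.mito_density * cyto_mask.sum())
        cyto_idx = np.flatnonzero(cyto_mask)
        if n_puncta > 0 and cyto_idx.size:
            for flat in rng.choice(cyto_idx, size=min(n_puncta, cyto_idx.size),
                                   replace=False):
                py, px = divmod(int(flat), w)
                pr = rng.uniform(1.0, 2.0)
                mito_mask |= ((yy - py) ** 2 + (xx - px) ** 2 <= pr ** 2)
            mito_mask &= cyto_mask

        comp_masks = {NUCLEUS: nuc_mask, CYTOSOL: cyto_mask & ~mito_mask,
                      MITO: mito_mask}
        cell_ids[cell_mask] = cid
        for code, mask in comp_masks.items():
            compartments[mask] = code
            for ch in CHANNELS:
                params = profile.get(ch, code).sample(rng)
                cell_params[(cid, ch, code)] = params
                true_params[ch]["alpha1"][mask] = params.alpha1
                true_params[ch]["tau1"][mask] = params.tau1
                true_params[ch]["tau2"][mask] = params.tau2
                true_params[ch]["photons"][mask] = params.photons
                true_params[ch]["c"][mask] = params.c

    return GroundTruthScene(spec=spec, compartments=compartments,
                            cell_ids=cell_ids, phenotypes=phenotypes,
                            true_params=true_params, cell_params=cell_params)


def render_tcspc(scene: GroundTruthScene, irf: IRF, rng_seed: int = 0) -> tuple:
    """Render (NADH, FAD) photon-count cubes as independent Poisson draws.

    Expected curves are computed once per unique (cell, compartment) parameter
    set; background-only pixels contain only ambient background counts.
    """
    rng = np.random.default_rng(rng_seed)
    h, w = scene.compartments.shape
    cubes = []
    for ch in CHANNELS:
        expected = np.zeros((h, w, irf.n_bins))
        # background pixels: ambient level only (uses the 'c' image, 0 outside cells)
        c_img = scene.true_params[ch]["c"]
        expected += c_img[:, :, None]
        for (cid, pch, comp), params in scene.cell_params.items():
            if pch != ch:
                continue
            mask = (scene.cell_ids == cid) & (scene.compartments == comp)
            if not mask.any():
                continue
            curve = model_decay(params.alpha1, params.tau1, params.tau2,
                                0.0, params.photons, irf)
            expected[mask] = curve + params.c
        counts = rng.poisson(expected).astype(np.int32)
        cubes.append(TCSPCImage(counts=counts, dt=irf.dt, channel=ch))
    return tuple(cubes)


# --------------------------------------------------------------------------
# phenotype-level fast paths

# calibrated per-cell estimation noise standing in for render+refit scatter
# (SDs of cytoplasm-mean estimates at ~10^3 photons/pixel, hundreds of pixels)
_EST_SD = dict(alpha1=0.012, tau1=0.025, tau2=0.06, intensity_frac=0.04)


def _cytoplasm_mix(profile: PhenotypeProfile, ch: str,
                   rng: np.random.Generator, mito_fraction: float = 0.2):
    """Area-weighted cytoplasm (cytosol + mitochondria) truth for one cell."""
    cy = profile.get(ch, CYTOSOL).sample(rng)
    mt = profile.get(ch, MITO).sample(rng)
    wm = mito_fraction
    # mitochondria are brighter, so weight amplitudes by photon flux too
    flux = (1 - wm) * cy.photons + wm * mt.photons
    mix = lambda a, b: (1 - wm) * a + wm * b
    return dict(
        alpha1=mix(cy.alpha1, mt.alpha1),
        tau1=mix(cy.tau1, mt.tau1),
        tau2=mix(cy.tau2, mt.tau2),
        intensity=flux,
    )


def sample_cell_features(n_per_group: dict, seed: int = 0,
                         estimation_noise: bool = True,
                         profiles: dict | None = None,
                         batch: str = "sim") -> pd.DataFrame:
    """Draw per-cell twelve-feature vectors directly from phenotype profiles.

    ``n_per_group`` maps profile name -> number of cells.  Returns a tidy
    DataFrame with one row per cell: ``cell_id``, ``group``, ``batch`` and the
    twelve features in :data:`FEATURE_NAMES`.  Estimation noise emulates the
    scatter of cytoplasm-averaged estimates from fitted images.
    """
    profiles = default_profiles() if profiles is None else profiles
    rng = np.random.default_rng(seed)
    rows = []
    cid = 0
    for group, n in n_per_group.items():
        profile = profiles[group] if isinstance(group, str) else group
        for _ in range(n):
            cid += 1
            per_ch = {ch: _cytoplasm_mix(profile, ch, rng) for ch in CHANNELS}
            if estimation_noise:
                for ch in CHANNELS:
                    p = per_ch[ch]
                    p["alpha1"] = float(np.clip(
                        p["alpha1"] + rng.normal(0, _EST_SD["alpha1"]), 0, 1))
                    p["tau1"] += rng.normal(0, _EST_SD["tau1"])
                    p["tau2"] += rng.normal(0, _EST_SD["tau2"])
                    p["intensity"] *= max(
                        rng.normal(1.0, _EST_SD["intensity_frac"]), 0.0)
            nadh, fad = per_ch[NADH], per_ch[FAD]
            tot = nadh["intensity"] + fad["intensity"]
            rows.append({
                "cell_id": cid, "group": profile.name, "batch": batch,
                "redox_ratio": fad["intensity"] / tot if tot > 0 else np.nan,
                "flirr": ((1.0 - nadh["alpha1"]) / fad["alpha1"]
                          if fad["alpha1"] > 0 else np.nan),
                "nadh_tm": nadh["alpha1"] * nadh["tau1"]
                           + (1 - nadh["alpha1"]) * nadh["tau2"],
                "nadh_t1": nadh["tau1"], "nadh_t2": nadh["tau2"],
                "nadh_a1": nadh["alpha1"], "nadh_intensity": nadh["intensity"],
                "fad_tm": fad["alpha1"] * fad["tau1"]
                          + (1 - fad["alpha1"]) * fad["tau2"],
                "fad_t1": fad["tau1"], "fad_t2": fad["tau2"],
                "fad_a1": fad["alpha1"], "fad_intensity": fad["intensity"],
            })
    return pd.DataFrame(rows)


def shifted_population(features: pd.DataFrame, scale: dict | float,
                       batch: str = "typeB") -> pd.DataFrame:
    """A covariate-shifted copy of a feature table (a different "cell type").

    Each feature is multiplied by a constant baseline factor (``scale`` may be
    a single float or a per-feature dict), emulating systematic lifetime and
    intensity offsets between cell types while preserving relative,
    within-type effects.
    """
    out = features.copy()
    out["batch"] = batch
    for f in FEATURE_NAMES:
        s = scale.get(f, 1.0) if isinstance(scale, dict) else scale
        out[f] = out[f] * s
    return out


def sample_cell_stacks(n_per_group: dict, seed: int = 0, size: int = 40,
                       profiles: dict | None = None):
    """Draw per-cell 40x40 lifetime-component image stacks from the profiles.

    Returns ``(images, labels, channel_names)`` where ``images`` has shape
    (n_cells, 6, size, size) holding NADH tau1, tau2, alpha1, tau_m (all in
    ns / fraction units, unscaled), NADH intensity and FAD intensity, with
    non-cell pixels zeroed; ``labels`` is the per-cell group-name array.
    Geometry mirrors :func:`generate_scene` (dark nucleus, bright mitochondria)
    and per-pixel noise emulates fitted-map scatter.
    """
    profiles = default_profiles() if profiles is None else profiles
    rng = np.random.default_rng(seed)
    channel_names = ["nadh_t1", "nadh_t2", "nadh_a1", "nadh_tm",
                     "nadh_intensity", "fad_intensity"]
    images, labels = [], []
    yy, xx = np.mgrid[0:size, 0:size]
    # per-pixel scatter of fitted parameter maps after 3x3 binning
    px_sd = dict(alpha1=0.03, tau1=0.06, tau2=0.15, intensity_frac=0.10)
    for group, n in n_per_group.items():
        profile = profiles[group] if isinstance(group, str) else group
        for _ in range(n):
            r = rng.uniform(0.30 * size, 0.45 * size)
            cy, cx = (size - 1) / 2 + rng.normal(0, 1, 2)
            cell = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
            rn = rng.uniform(0.12 * size, 0.18 * size)
            ang = rng.uniform(0, 2 * math.pi)
            off = rng.uniform(0, max(r - rn - 2, 0) * 0.5)
            nuc = ((yy - cy - off * math.sin(ang)) ** 2
                   + (xx - cx - off * math.cos(ang)) ** 2 <= rn ** 2) & cell
            cyto = cell & ~nuc
            mito = np.zeros_like(cell)
            cyto_idx = np.flatnonzero(cyto)
            n_p = rng.poisson(0.04 * cyto_idx.size)
            if n_p and cyto_idx.size:
                for flat in rng.choice(cyto_idx, size=min(n_p, cyto_idx.size),
                                       replace=False):
                    py, px = divmod(int(flat), size)
                    pr = rng.uniform(1.0, 2.0)
                    mito |= ((yy - py) ** 2 + (xx - px) ** 2 <= pr ** 2)
                mito &= cyto
            comp_masks = {NUCLEUS: nuc, CYTOSOL: cyto & ~mito, MITO: mito}

            maps = {name: np.zeros((size, size)) for name in channel_names}
            for code, mask in comp_masks.items():
                if not mask.any():
                    continue
                ndh = profile.get(NADH, code).sample(rng)
                fad = profile.get(FAD, code).sample(rng)
                nmask = mask.sum()
                a1 = np.clip(ndh.alpha1 + rng.normal(0, px_sd["alpha1"], nmask), 0, 1)
                t1 = np.maximum(ndh.tau1 + rng.normal(0, px_sd["tau1"], nmask), 0.05)
                t2 = np.maximum(ndh.tau2 + rng.normal(0, px_sd["tau2"], nmask), t1)
                maps["nadh_a1"][mask] = a1
                maps["nadh_t1"][mask] = t1
                maps["nadh_t2"][mask] = t2
                maps["nadh_tm"][mask] = a1 * t1 + (1 - a1) * t2
                maps["nadh_intensity"][mask] = ndh.photons * np.maximum(
                    rng.normal(1, px_sd["intensity_frac"], nmask), 0)
                maps["fad_intensity"][mask] = fad.photons * np.maximum(
                    rng.normal(1, px_sd["intensity_frac"], nmask), 0)
            images.append(np.stack([maps[c] for c in channel_names]))
            labels.append(profile.name)
    images = np.asarray(images)
    labels = np.asarray(labels)
    order = rng.permutation(len(labels))
    return images[order], labels[order], channel_names
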