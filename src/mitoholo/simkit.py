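"""Forward simulator for the holographic permeability-transition assay.

Generates dual-channel (refractive-index + TMRM) time-lapse movies of
mitochondria together with per-organelle ground truth, under four
experimental archetypes:

``WT_FERUTININ``
    Ferutinin-induced calcium overload: gradual membrane depolarization
    followed, once the potential has fallen to a fixed fraction of its
    initial level, by high-conductance permeabilization that equalizes the
    organelle's refractive index with the cytosol — the organelle vanishes
    from the RI channel.
``WT_FERUTININ_CSA``
    Cyclosporin A blocks both depolarization and permeabilization; traces
    stay at baseline until the terminal FCCP anchor.
``FCCP_ONLY``
    Protonophore uncoupling: rapid depolarization with mitochondria
    remaining intact and visible in the RI channel.
``KO_FERUTININ``
    ATP-synthase/ANT knockout archetype: lower basal potential,
    ferutinin-induced depolarization, but no high-conductance
    permeabilization.

Every experiment ends with an FCCP anchor (potential collapse over the last
few frames) mirroring the acquisition protocol, which adds the uncoupler at
the end of each recording to provide the zero level for TMRM normalization.

Model
-----
Per organelle *i* with onset ``o_i = t_drug + |N(0, jitter_sd)|``:

    V_i(t) = v_basal                          for t <  o_i
    V_i(t) = v_basal * exp(-(t - o_i)/tau)    for t >= o_i

When the condition permits permeabilization, the trigger is the continuous
threshold crossing ``t* = o_i + tau * ln(1/theta)`` (``theta`` =
``perm_threshold``) plus a nonnegative Gaussian lag; RI contrast is 1 before
``perm_time`` and decays as ``exp(-(t - perm_time)/tau_ri_collapse)`` after.
Defaults are calibrated so the wild-type archetype has a ground-truth
residual potential fraction of exactly 0.15 and an onset-to-permeabilization
delay of 150 s, the headline single-organelle statistics of the assay.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

from .stacks_io import FrameStack, write_metadata, write_stack

CONDITIONS = ("WT_FERUTININ", "WT_FERUTININ_CSA", "FCCP_ONLY", "KO_FERUTININ")

#: conditions in which high-conductance permeabilization occurs
PERMEABILIZING_CONDITIONS = ("WT_FERUTININ",)
#: conditions in which ferutinin/FCCP triggers a depolarization onset
DEPOLARIZING_CONDITIONS = ("WT_FERUTININ", "FCCP_ONLY", "KO_FERUTININ")

# Calibration: threshold crossing sits 150 s after onset when
# tau_depol = 150 / ln(1/perm_threshold).
DEFAULT_PERM_THRESHOLD = 0.15
DEFAULT_DELAY_S = 150.0
DEFAULT_TAU_DEPOL = round(DEFAULT_DELAY_S / math.log(1.0 / DEFAULT_PERM_THRESHOLD), 2)  # 79.07 s

#: time constant of the terminal FCCP anchor collapse (s)
TAU_FCCP_ANCHOR = 8.0

# Rendering constants (16-bit counts). Chosen to emulate the assay's imaging:
# RI contrast of intact mitochondria well above cytosol noise, TMRM bright in
# polarized organelles, sub-pixel PSF blur at high NA.
RI_BACKGROUND = 100.0
RI_AMPLITUDE = 60.0
TMRM_BACKGROUND = 40.0
TMRM_AMPLITUDE = 160.0
EDGE_SIGMA = 1.0


@dataclass(frozen=True)
class KineticParams:
    """Phenomenological kinetics of depolarization and permeabilization.

    All time constants in seconds; potentials are dimensionless fractions of
    the fully polarized wild-type level.
    """

    v_basal: float = 1.0
    tau_depol: float = DEFAULT_TAU_DEPOL
    onset_jitter_sd: float = 20.0
    perm_threshold: float = DEFAULT_PERM_THRESHOLD
    perm_lag_mean: float = 0.0
    perm_lag_sd: float = 0.0
    tau_ri_collapse: float = 5.0
    bleach_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.v_basal <= 1.0):
            raise ValueError("v_basal must lie in (0, 1]")
        if self.tau_depol <= 0 or self.tau_ri_collapse <= 0:
            raise ValueError("time constants must be > 0")
        if not (0.0 < self.perm_threshold < 1.0):
            raise ValueError("perm_threshold must lie in (0, 1)")
        if self.onset_jitter_sd < 0 or self.perm_lag_sd < 0:
            raise ValueError("spread parameters must be >= 0")
        if not (0.0 <= self.bleach_rate < 1.0):
            raise ValueError("bleach_rate must lie in [0, 1)")


@dataclass(frozen=True)
class Ellipse:
    """Organelle footprint: centre (row, col), semi-axes (px), orientation (rad)."""

    center: tuple[float, float]
    axes: tuple[float, float]
    orientation: float = 0.0


@dataclass(frozen=True)
class NoiseParams:
    ri_sd: float = 4.0
    tmrm_sd: float = 4.0
    background_gradient: float = 0.0  # peak-to-peak counts of a linear ramp


# per-condition kinetic defaults; KO archetype has a lower basal potential,
# FCCP collapses the potential faster than the gradual ferutinin response
_CONDITION_KINETICS: dict[str, KineticParams] = {
    "WT_FERUTININ": KineticParams(),
    "WT_FERUTININ_CSA": KineticParams(),
    "FCCP_ONLY": KineticParams(tau_depol=30.0),
    "KO_FERUTININ": KineticParams(v_basal=0.6),
}


@dataclass(frozen=True)
class Scenario:
    condition: str
    n_mito: int
    n_frames: int = 80
    drug_frame: int = 10
    frame_interval: float = 15.0
    fccp_frame: int | None = 75  # terminal anchor; None disables it
    geometry: tuple[Ellipse, ...] = ()
    kinetics: KineticParams = field(default_factory=KineticParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    image_shape: tuple[int, int] = (128, 128)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; valid conditions: {', '.join(CONDITIONS)}"
            )
        if self.n_mito < 1:
            raise ValueError("n_mito must be >= 1")
        if not (0 <= self.drug_frame < self.n_frames):
            raise ValueError("drug_frame must lie in [0, n_frames)")
        if self.fccp_frame is not None and not (self.drug_frame < self.fccp_frame < self.n_frames):
            raise ValueError("fccp_frame must lie in (drug_frame, n_frames)")
        h, w = self.image_shape
        for k, e in enumerate(self.geometry):
            r, c = e.center
            m = max(e.axes) + 3.0 * EDGE_SIGMA
            if not (m <= r <= h - m and m <= c <= w - m):
                raise ValueError(f"organelle {k} ellipse does not fit inside the image bounds")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class OrganelleTruth:
    """Ground truth for one simulated mitochondrion."""

    index: int
    onset_s: float | None  # depolarization onset; None when CSA blocks it
    perm_s: float | None  # continuous permeabilization time; None if none occurs
    residual_fraction: float | None  # V(perm)/v_basal; None without permeabilization
    potential_curve: np.ndarray  # V(t) sampled at frame times, dimensionless
    ri_contrast_curve: np.ndarray  # 1 before perm, exp collapse after


@dataclass(frozen=True)
class GroundTruth:
    scenario: Scenario
    organelles: tuple[OrganelleTruth, ...]

    def to_frame(self) -> pd.DataFrame:
        """One row per organelle with events, residual fraction and geometry."""
        rows = []
        for org, ell in zip(self.organelles, self.scenario.geometry):
            rows.append(
                dict(
                    organelle_id=org.index,
                    onset_s=org.onset_s,
                    perm_s=org.perm_s,
                    residual_fraction=org.residual_fraction,
                    delay_s=None if org.perm_s is None else org.perm_s - org.onset_s,
                    center_row=ell.center[0],
                    center_col=ell.center[1],
                    axis_major=ell.axes[0],
                    axis_minor=ell.axes[1],
                    orientation=ell.orientation,
                )
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenario construction

def _place_geometry(rng: np.random.Generator, n: int, shape: tuple[int, int]) -> tuple[Ellipse, ...]:
    """Place n non-overlapping ellipses on a jittered grid inside the image."""
    h, w = shape
    margin = 12.0
    gx = int(np.ceil(np.sqrt(n)))
    gy = int(np.ceil(n / gx))
    cell_h = (h - 2 * margin) / gy
    cell_w = (w - 2 * margin) / gx
    if min(cell_h, cell_w) < 18.0:
        raise ValueError(f"cannot place {n} organelles in a {h}x{w} image without overlap")
    cells = rng.permutation(gx * gy)[:n]
    out = []
    for cell in cells:
        gr, gc = divmod(int(cell), gx)
        r = margin + (gr + 0.5) * cell_h + rng.uniform(-2.0, 2.0)
        c = margin + (gc + 0.5) * cell_w + rng.uniform(-2.0, 2.0)
        a = rng.uniform(4.5, 6.5)
        b = rng.uniform(2.5, 3.8)
        theta = rng.uniform(0.0, np.pi)
        out.append(Ellipse(center=(r, c), axes=(a, b), orientation=theta))
    return tuple(out)


def make_scenario(
    condition: str,
    n_mito: int = 10,
    n_frames: int = 80,
    drug_frame: int = 10,
    seed: int = 0,
    overrides: dict | None = None,
) -> Scenario:
    """Build a fully populated Scenario with condition-appropriate defaults.

    ``overrides`` accepts top-level Scenario fields plus dotted
    ``kinetics.*`` / ``noise.*`` keys; unknown keys are rejected.
    Deterministic given ``seed``.
    """
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; valid conditions: {', '.join(CONDITIONS)}"
        )
    if n_mito < 1:
        raise ValueError("n_mito must be >= 1")
    kinetics = _CONDITION_KINETICS[condition]
    noise = NoiseParams()
    fields: dict = dict(
        condition=condition,
        n_mito=n_mito,
        n_frames=n_frames,
        drug_frame=drug_frame,
        frame_interval=15.0,
        fccp_frame=max(drug_frame + 1, n_frames - 5),
        image_shape=(128, 128),
        seed=seed,
    )
    kin_over: dict = {}
    noise_over: dict = {}
    for key, value in (overrides or {}).items():
        if key.startswith("kinetics."):
            name = key.split(".", 1)[1]
            if name not in {f.name for f in dataclasses.fields(KineticParams)}:
                raise ValueError(f"unknown override {key!r}")
            kin_over[name] = value
        elif key.startswith("noise."):
            name = key.split(".", 1)[1]
            if name not in {f.name for f in dataclasses.fields(NoiseParams)}:
                raise ValueError(f"unknown override {key!r}")
            noise_over[name] = value
        elif key in fields or key == "geometry":
            fields[key] = value
        else:
            raise ValueError(f"unknown override {key!r}")
    kinetics = dataclasses.replace(kinetics, **kin_over)
    noise = dataclasses.replace(noise, **noise_over)
    rng = np.random.default_rng(seed)
    geometry = fields.pop("geometry", None)
    if geometry is None:
        geometry = _place_geometry(rng, fields["n_mito"], fields["image_shape"])
    return Scenario(geometry=tuple(geometry), kinetics=kinetics, noise=noise, **fields)


# ---------------------------------------------------------------------------
# kinetics

def simulate_kinetics(scenario: Scenario) -> GroundTruth:
    """Sample per-organelle potential and RI-contrast curves.

    Draw order (stream ``[seed, 1]``): for each organelle, the onset jitter
    then the permeabilization lag, whether or not the condition uses them,
    so the stream stays aligned across conditions.
    """
    sc = scenario
    k = sc.kinetics
    rng = np.random.default_rng([sc.seed, 1])
    times = sc.times
    t_drug = sc.drug_frame * sc.frame_interval
    t_fccp = None if sc.fccp_frame is None else sc.fccp_frame * sc.frame_interval

    organelles = []
    for i in range(sc.n_mito):
        jitter = abs(rng.normal(0.0, k.onset_jitter_sd)) if k.onset_jitter_sd > 0 else 0.0
        lag_draw = rng.normal(k.perm_lag_mean, k.perm_lag_sd) if k.perm_lag_sd > 0 else k.perm_lag_mean
        lag = max(0.0, lag_draw)

        if sc.condition in DEPOLARIZING_CONDITIONS:
            onset: float | None = t_drug + jitter
            dt = np.maximum(times - onset, 0.0)
            v = k.v_basal * np.exp(-dt / k.tau_depol)
        else:  # CSA: potential holds at baseline
            onset = None
            v = np.full_like(times, k.v_basal, dtype=float)

        if t_fccp is not None:
            anchor = np.where(times >= t_fccp, np.exp(-(times - t_fccp) / TAU_FCCP_ANCHOR), 1.0)
            v = v * anchor

        if sc.condition in PERMEABILIZING_CONDITIONS:
            # continuous threshold crossing of the depolarization exponential
            perm: float | None = onset + k.tau_depol * math.log(1.0 / k.perm_threshold) + lag
            residual: float | None = k.perm_threshold * math.exp(-lag / k.tau_depol)
            contrast = np.where(times < perm, 1.0, np.exp(-(times - perm) / k.tau_ri_collapse))
        else:
            perm = None
            residual = None
            contrast = np.ones_like(times)

        organelles.append(
            OrganelleTruth(
                index=i,
                onset_s=onset,
                perm_s=perm,
                residual_fraction=residual,
                potential_curve=v,
                ri_contrast_curve=contrast,
            )
        )
    return GroundTruth(scenario=sc, organelles=tuple(organelles))


# ---------------------------------------------------------------------------
# rendering

def _ellipse_mask(e: Ellipse, shape: tuple[int, int]) -> np.ndarray:
    if min(e.axes) <= 0:
        raise ValueError("degenerate zero-area ellipse")
    rr, cc = draw_ellipse(
        e.center[0], e.center[1], e.axes[0], e.axes[1], shape=shape, rotation=e.orientation
    )
    if rr.size == 0:
        raise ValueError("degenerate zero-area ellipse")
    mask = np.zeros(shape, dtype=float)
    mask[rr, cc] = 1.0
    return mask


def organelle_masks(scenario: Scenario) -> np.ndarray:
    """Binary footprint of each organelle, shape (n_mito, H, W)."""
    return np.stack([_ellipse_mask(e, scenario.image_shape) > 0 for e in scenario.geometry])


def ground_truth_mask(scenario: Scenario, ground_truth: GroundTruth, frame: int) -> np.ndarray:
    """Union of organelle footprints still present (contrast > 0.5) at ``frame``."""
    masks = organelle_masks(scenario)
    present = np.array([org.ri_contrast_curve[frame] > 0.5 for org in ground_truth.organelles])
    return masks[present].any(axis=0) if present.any() else np.zeros(scenario.image_shape, bool)


def render_movie(scenario: Scenario, ground_truth: GroundTruth) -> tuple[FrameStack, FrameStack]:
    """Render the RI and TMRM channels as 16-bit stacks sharing one time base.

    Each frame is background + the sum of PSF-blurred organelle footprints
    scaled by the per-frame RI contrast (RI channel) or membrane potential
    and cumulative bleach factor (TMRM channel), plus seeded Gaussian noise
    (stream ``[seed, 2]``; RI frames drawn first, then TMRM frames).
    """
    sc = scenario
    if ground_truth.scenario is not sc and ground_truth.scenario != sc:
        raise ValueError("ground truth was produced from a different scenario")
    h, w = sc.image_shape
    rng = np.random.default_rng([sc.seed, 2])

    # PSF-blurred unit footprints; scene composition is linear so blurring
    # the footprints once is equivalent to blurring every frame
    units = np.stack(
        [ndi.gaussian_filter(_ellipse_mask(e, sc.image_shape), EDGE_SIGMA) for e in sc.geometry]
    )
    contrast = np.stack([o.ri_contrast_curve for o in ground_truth.organelles])  # (n, T)
    potential = np.stack([o.potential_curve for o in ground_truth.organelles])

    gradient = 0.0
    if sc.noise.background_gradient:
        ramp = np.linspace(0.0, 1.0, w)[None, :] * np.ones((h, 1))
        gradient = sc.noise.background_gradient * ramp

    bleach = (1.0 - sc.kinetics.bleach_rate) ** np.arange(sc.n_frames)

    ri = np.einsum("nt,nhw->thw", contrast, units) * RI_AMPLITUDE + RI_BACKGROUND + gradient
    tmrm = (
        np.einsum("nt,nhw->thw", potential * bleach[None, :], units) * TMRM_AMPLITUDE
        + TMRM_BACKGROUND
        + gradient
    )
    if sc.noise.ri_sd > 0:
        ri = ri + rng.normal(0.0, sc.noise.ri_sd, size=ri.shape)
    if sc.noise.tmrm_sd > 0:
        tmrm = tmrm + rng.normal(0.0, sc.noise.tmrm_sd, size=tmrm.shape)

    def digitize(img: np.ndarray) -> np.ndarray:
        return np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    meta = dict(
        frame_interval=sc.frame_interval,
        drug_frame=sc.drug_frame,
        provenance=f"simkit condition={sc.condition} seed={sc.seed}",
    )
    ri_stack = FrameStack(pixels=digitize(ri), channel="RI", **meta)
    tmrm_stack = FrameStack(pixels=digitize(tmrm), channel="TMRM", **meta)
    return ri_stack, tmrm_stack


def simulate_experiment(scenario: Scenario) -> tuple[FrameStack, FrameStack, GroundTruth]:
    """Convenience: kinetics + rendering in one call."""
    gt = simulate_kinetics(scenario)
    ri, tmrm = render_movie(scenario, gt)
    return ri, tmrm, gt


def write_experiment(scenario: Scenario, outdir: str | Path) -> dict[str, Path]:
    """Simulate and write one experiment: two TIFFs, metadata YAML, truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ri, tmrm, gt = simulate_experiment(scenario)
    paths = {
        "ri": write_stack(ri, outdir / "ri.tif"),
        "tmrm": write_stack(tmrm, outdir / "tmrm.tif"),
    }
    meta = dict(
        condition=scenario.condition,
        n_mito=scenario.n_mito,
        n_frames=scenario.n_frames,
        drug_frame=scenario.drug_frame,
        frame_interval=scenario.frame_interval,
        fccp_frame=scenario.fccp_frame,
        seed=scenario.seed,
    )
    paths["metadata"] = write_metadata(meta, outdir / "metadata.yaml")
    truth_path = outdir / "ground_truth.csv"
    gt.to_frame().to_csv(truth_path, index=False)
    paths["ground_truth"] = truth_path
    return paths
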