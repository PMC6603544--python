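"""Synthetic pakchoi pot experiment: agronomic trajectories and rendered images.

The generator emulates the statistical structure of a four-treatment x
six-date greenhouse experiment on a rosette-forming leafy vegetable:

* **Trajectories.**  For a relative N supply ``s`` (dose divided by the
  conventional 0.191 g N/pot rate), shoot dry biomass grows
  geometrically from 0.02 g toward a dose-dependent final mass
  (0.62 g unfertilized, about 1.4 g at the full rate), and the latent
  nitrogen nutrition index relaxes exponentially from an early-stage
  value toward a dose-dependent asymptote — declining from about 0.77
  to 0.26 without fertilizer and hovering slightly above 1 at the full
  rate.  Shoot N concentration follows the generative link
  ``n_conc = nni_true * a * DM**b`` with the module's own dilution-curve
  parameters (a = 76.0 g/kg, b = 0.12), so downstream curve fitting can
  recover them exactly on noiseless data.  Optional multiplicative
  Gaussian noise (CV given by ``noise_cv``) perturbs biomass and N
  concentration; ``nni_true`` is recomputed from the noisy values so
  the link always holds exactly.

* **Images.**  Each sample is rendered as a rosette of overlapping
  elliptical leaves on a near-white/grey background.  Leaf color moves
  from pale yellow-green to deep green as a latent greenness (a
  monotone function of NNI) increases — so the mean excess green index
  2G - R - B over the plant rises strictly with greenness while staying
  inside the default segmentation band.  Within-leaf heterogeneity is
  per-pixel Gaussian intensity noise with amplitude ``texture_amp``
  (larger under N deficiency), and projected size scales with the
  square root of biomass so mask area is proportional to biomass.

The renderer is deliberately schematic (no shadows, specular highlights
or 3-D canopy structure): it exercises every downstream stage with a
known ground truth, it does not imitate photographs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb
from PIL import Image
from scipy.special import expit
from skimage.draw import ellipse

__all__ = [
    "DILUTION_A",
    "DILUTION_B",
    "AgronomicDesign",
    "LatentPlantState",
    "RenderedSample",
    "default_design",
    "nni_trajectory",
    "biomass_trajectory",
    "generate_trajectories",
    "state_from_record",
    "greenness_to_rgb",
    "render_plant",
    "generate_dataset",
]

#: Dilution-curve parameters of the generative link n = nni * a * DM**b,
#: chosen once by a log-log fit of the bundled reference Nc list against
#: the reference non-limiting biomass trajectory.
DILUTION_A = 76.0
DILUTION_B = 0.12

_FULL_DOSE = 0.191  # conventional rate, g N per pot


@dataclass
class AgronomicDesign:
    """Treatments (label -> N dose in g/pot), sampling days, replication."""

    treatments: dict[str, float] = field(
        default_factory=lambda: {"CK": 0.0, "T1": 0.134, "T2": 0.163, "T3": 0.191}
    )
    days: tuple[int, ...] = (7, 14, 21, 28, 35, 42)
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.treatments) < 2:
            raise ValueError("need at least 2 treatments")
        if len(self.days) < 2:
            raise ValueError("need at least 2 sampling dates")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(d < 0 for d in self.treatments.values()):
            raise ValueError("doses must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.treatments) * len(self.days) * self.replicates


def default_design(replicates: int = 16, seed: int = 0) -> AgronomicDesign:
    """The emulated study design; 16 replicates gives 384 samples."""
    return AgronomicDesign(replicates=replicates, seed=seed)


def nni_trajectory(day, dose) -> np.ndarray:
    """Noise-free latent NNI as a function of day and N dose."""
    s = np.sqrt(np.asarray(dose, dtype=float) / _FULL_DOSE)
    r0 = 0.77 + 0.29 * s
    rinf = 0.26 + 0.82 * s
    return rinf + (r0 - rinf) * np.exp(-0.09 * (np.asarray(day, float) - 7.0))


def biomass_trajectory(day, dose) -> np.ndarray:
    """Noise-free shoot dry biomass (g/plant) as a function of day and dose."""
    s = np.asarray(dose, dtype=float) / _FULL_DOSE
    b0 = 0.02
    bend = 0.62 + 0.75 * s**0.8
    return b0 * (bend / b0) ** (np.asarray(day, float) / 42.0)


def generate_trajectories(design: AgronomicDesign, noise_cv: float = 0.0) -> pd.DataFrame:
    """Growth records with ground-truth NNI for every design cell.

    One row per treatment x date x replicate, with columns ``treatment``,
    ``dose``, ``day``, ``replicate``, ``biomass_dm``, ``n_conc``,
    ``nni_true``.  Reproducible for a fixed ``design.seed``.
    """
    if not 0.0 <= noise_cv <= 0.3:
        raise ValueError("noise_cv must be in [0, 0.3]")
    rng = np.random.default_rng(design.seed)
    rows = []
    for trt, dose in design.treatments.items():
        for day in design.days:
            dm0 = float(biomass_trajectory(day, dose))
            nni0 = float(nni_trajectory(day, dose))
            nc0 = nni0 * DILUTION_A * dm0**DILUTION_B
            for rep in range(design.replicates):
                f_dm = max(1.0 + noise_cv * rng.standard_normal(), 0.1)
                f_n = max(1.0 + noise_cv * rng.standard_normal(), 0.1)
                dm = dm0 * f_dm
                n_conc = nc0 * f_n
                rows.append({
                    "treatment": trt, "dose": dose, "day": day,
                    "replicate": rep, "biomass_dm": dm, "n_conc": n_conc,
                    "nni_true": n_conc / (DILUTION_A * dm**DILUTION_B),
                })
    return pd.DataFrame(rows)


@dataclass
class LatentPlantState:
    """Latent appearance parameters for one rendered plant."""

    biomass_dm: float
    n_conc: float
    nni_true: float
    greenness: float
    texture_amp: float
    n_leaves: int
    scale_px: float

    def __post_init__(self) -> None:
        if self.biomass_dm <= 0 or self.n_conc <= 0:
            raise ValueError("biomass and N concentration must be positive")
        if not 0.0 <= self.greenness <= 1.0:
            raise ValueError("greenness must be in [0, 1]")
        if self.texture_amp < 0:
            raise ValueError("texture_amp must be >= 0")
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")


@dataclass
class RenderedSample:
    """A rendered image, its ground-truth mask and provenance."""

    image: np.ndarray
    truth_mask: np.ndarray
    state: LatentPlantState
    treatment: str = ""
    day: int = 0


def state_from_record(biomass_dm: float, n_conc: float, nni_true: float) -> LatentPlantState:
    """Deterministic map from an agronomic record to appearance latents.

    Greenness rises strictly with NNI (logistic link centred at
    NNI = 0.65), projected scale rises with the square root of biomass,
    and texture amplitude falls with NNI (deficient plants are more
    heterogeneous).
    """
    greenness = float(expit(2.2 * (nni_true - 0.65)))
    scale_px = 10.0 + 75.0 * float(np.sqrt(biomass_dm / 1.4))
    texture_amp = 3.0 + 5.0 * float(expit(3.0 * (1.0 - nni_true)))
    n_leaves = 6 + int(round(6.0 * min(biomass_dm, 1.4) / 1.4))
    return LatentPlantState(
        biomass_dm=biomass_dm, n_conc=n_conc, nni_true=nni_true,
        greenness=greenness, texture_amp=texture_amp, n_leaves=n_leaves,
        scale_px=scale_px,
    )


def greenness_to_rgb(greenness: float) -> np.ndarray:
    """Leaf color for a greenness in [0, 1]: pale yellow-green to deep green.

    Linear ramp in HSV (hue 80 -> 120 degrees, saturation rising, value
    falling); the resulting excess green index rises strictly from
    about 82 to 168, inside the default segmentation band.
    """
    g = float(greenness)
    h = (80.0 + 40.0 * g) / 360.0
    s = 0.30 + 0.25 * g
    v = 0.80 - 0.20 * g
    return hsv_to_rgb([h, s, v]) * 255.0


def render_plant(
    state: LatentPlantState,
    canvas_px: tuple[int, int] = (240, 240),
    background: float = 232.0,
    seed: int = 0,
) -> RenderedSample:
    """Render a rosette of overlapping elliptical leaves on a grey canvas.

    Leaves radiate from the canvas centre with angular jitter; all leaf
    pixels share one base color determined by ``state.greenness``, plus
    per-pixel Gaussian intensity noise of amplitude
    ``state.texture_amp`` applied equally to the three channels (so the
    excess green index of a pixel is noise-free).  Background pixels
    are near-white/grey and therefore fail the excess-green band of the
    segmentation stage.
    """
    H, W = canvas_px
    if 1.15 * state.scale_px > min(H, W) / 2:
        raise ValueError("rosette does not fit the canvas")
    rng = np.random.default_rng(seed)

    bg = np.clip(rng.normal(background, 2.0, size=(H, W)), 212.0, 250.0)
    img = np.repeat(bg[:, :, None], 3, axis=2)

    mask = np.zeros((H, W), dtype=bool)
    cr, cc = (H - 1) / 2.0, (W - 1) / 2.0
    n = state.n_leaves
    for k in range(n):
        phi = 2.0 * np.pi * k / n + rng.normal(0.0, 0.10)
        length = state.scale_px * (0.80 + 0.20 * rng.random())
        width = length * (0.52 + 0.15 * rng.random())
        d = 0.5 * length
        rr, cc_ = ellipse(
            cr + d * np.sin(phi), cc + d * np.cos(phi),
            length / 2.0, width / 2.0,
            shape=(H, W), rotation=phi + np.pi / 2.0,
        )
        mask[rr, cc_] = True
    if not mask.any():
        raise ValueError("rendered mask is empty")

    color = greenness_to_rgb(state.greenness)
    noise = rng.normal(0.0, state.texture_amp, size=(H, W)) if state.texture_amp > 0 else 0.0
    for ch in range(3):
        layer = img[:, :, ch]
        layer[mask] = color[ch] + (noise[mask] if state.texture_amp > 0 else 0.0)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return RenderedSample(image=image, truth_mask=mask, state=state)


def generate_dataset(
    design: AgronomicDesign,
    out_dir,
    canvas_px: tuple[int, int] = (240, 240),
    noise_cv: float = 0.05,
    write_truth_masks: bool = True,
) -> pd.DataFrame:
    """Render one PNG per design cell and write the ground-truth table.

    Creates ``images/`` (and optionally ``truth_masks/``) under
    ``out_dir`` plus ``truth.csv`` with columns ``sample_id``,
    ``treatment``, ``day``, ``replicate``, ``biomass_dm``, ``n_conc``,
    ``nni_true``, ``image_path``.  Fully deterministic for a fixed
    ``design.seed``.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    if write_truth_masks:
        mask_dir = out_dir / "truth_masks"
        mask_dir.mkdir(exist_ok=True)

    records = generate_trajectories(design, noise_cv=noise_cv)
    seeds = np.random.SeedSequence(design.seed).generate_state(len(records) + 1)[1:]
    paths = []
    for i, rec in records.iterrows():
        state = state_from_record(rec["biomass_dm"], rec["n_conc"], rec["nni_true"])
        sample = render_plant(state, canvas_px=canvas_px, seed=int(seeds[i]))
        sid = f"{rec['treatment']}_d{int(rec['day']):02d}_r{int(rec['replicate']):02d}"
        Image.fromarray(sample.image).save(img_dir / f"{sid}.png")
        if write_truth_masks:
            Image.fromarray((sample.truth_mask * 255).astype(np.uint8)).save(
                mask_dir / f"{sid}.png"
            )
        # path stored relative to out_dir so the table is location-independent
        paths.append((sid, f"images/{sid}.png"))
    truth = records.copy()
    truth.insert(0, "sample_id", [p[0] for p in paths])
    truth["image_path"] = [p[1] for p in paths]
    truth.to_csv(out_dir / "truth.csv", index=False)
    return truth
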