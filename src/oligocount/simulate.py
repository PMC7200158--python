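"""Seeded generators for every input the analysis stages consume.

Three generators:

* :func:`simulate_mals_series` — concentration/average-mass points from a
  ground-truth isodesmic K_D (the forward model of a SEC-MALS dilution
  series), with optional lognormal mass noise;
* :func:`simulate_tirf_stack` — short TIRF movies of diffraction-limited
  spots with known fluorophore copy numbers, per-fluorophore exponential
  photobleaching, a spatially varying background, Poisson shot noise plus
  Gaussian read noise, and slow spot diffusion;
* :func:`simulate_mgv_fields` — two sets of per-field mean gray values
  with a known fractional effect size, for the resampling statistics.

All randomness flows from a single seed (or Generator), so outputs are
byte-identical across runs with the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .isodesmic import MalsSeries, predict_average_mass
from .tirf import ImageStack

__all__ = [
    "TirfSimulationConfig",
    "GroundTruth",
    "simulate_mals_series",
    "simulate_tirf_stack",
    "simulate_mgv_fields",
    "DEFAULT_COPY_NUMBER_PROBS",
]

# Default copy-number distribution over 1..12 protomers per spot: mostly
# small complexes, with 10% of spots above 10 copies so that the
# ground-truth "fraction within 10x of a single fluorophore" is 0.90.
_w = 0.65 ** np.arange(1, 11)
DEFAULT_COPY_NUMBER_PROBS = np.concatenate([0.90 * _w / _w.sum(), [0.06, 0.04]])


@dataclass(frozen=True)
class TirfSimulationConfig:
    """Ground-truth description of a simulated spot-counting movie.

    Defaults emulate the live-cell imaging regime the pipeline targets:
    40 frames at 100 ms exposure, PSF sigma 1 px, single-fluorophore
    intensity 120 counts, per-fluorophore bleach rate 0.02/frame, a
    20-count background with a mild linear gradient, Poisson shot noise
    with 2-count Gaussian read noise, and slow (0.05 px/frame) spot
    diffusion.
    """

    shape: tuple[int, int] = (512, 512)
    n_spots: int = 150
    copy_number_probs: np.ndarray = field(
        default_factory=lambda: DEFAULT_COPY_NUMBER_PROBS.copy()
    )
    single_fluor_intensity: float = 120.0
    psf_sigma_px: float = 1.0
    background_level: float = 20.0
    background_gradient: float = 10.0
    shot_noise: bool = True
    read_noise_sd: float = 2.0
    bleach_rate: float = 0.02
    diffusion_sd_px: float = 0.05
    n_frames: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.copy_number_probs, dtype=float)
        object.__setattr__(self, "copy_number_probs", p)
        if p.ndim != 1 or p.size < 1 or np.any(p < 0):
            raise ValueError("copy_number_probs must be a non-negative vector")
        if not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("copy_number_probs must sum to 1")
        if self.n_frames < 1 or self.n_spots < 0:
            raise ValueError("n_frames >= 1 and n_spots >= 0 required")
        if min(self.bleach_rate, self.diffusion_sd_px, self.read_noise_sd) < 0:
            raise ValueError("rates and noise levels must be >= 0")
        if self.single_fluor_intensity <= 0 or self.psf_sigma_px <= 0:
            raise ValueError("single_fluor_intensity and psf_sigma_px must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Per-spot truth for a simulated movie.

    ``copy_numbers``: (n_spots,) true fluorophores per spot;
    ``positions``: (n_frames, n_spots, 2) true (row, col) per frame;
    ``intensities``: (n_frames, n_spots) true integrated signal per frame
    (g times the number of surviving fluorophores).
    """

    copy_numbers: np.ndarray
    positions: np.ndarray
    intensities: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n_frames, n_spots, _ = self.positions.shape
        for s in range(n_spots):
            for t in range(n_frames):
                rows.append(
                    {
                        "spot": s,
                        "frame": t,
                        "copy_number": int(self.copy_numbers[s]),
                        "row": self.positions[t, s, 0],
                        "col": self.positions[t, s, 1],
                        "intensity": self.intensities[t, s],
                    }
                )
        return pd.DataFrame(rows)


def simulate_mals_series(
    kd: float,
    monomer_mass: float,
    detector_concs_uM,
    noise_sd_frac: float = 0.0,
    max_order: int = 11,
    seed: int | np.random.Generator = 0,
) -> MalsSeries:
    """Forward-model a SEC-MALS series from a ground-truth K_D (nM).

    Each detector concentration (uM) is treated as the total protomer
    concentration; the noiseless number-average mass comes from the
    isodesmic forward model and is multiplied by lognormal noise with
    the given fractional standard deviation.
    """
    if kd <= 0:
        raise ValueError("kd must be > 0 nM")
    concs = np.asarray(detector_concs_uM, dtype=float)
    if np.any(concs <= 0):
        raise ValueError("detector concentrations must be > 0 uM")
    rng = np.random.default_rng(seed)
    masses = np.array(
        [
            predict_average_mass(kd, c * 1000.0, monomer_mass, max_order)
            for c in concs
        ]
    )
    if noise_sd_frac > 0:
        masses = masses * np.exp(rng.normal(0.0, noise_sd_frac, size=masses.shape))
    return MalsSeries(detector_conc=concs, average_mass=masses)


def _pixel_integrated_psf(row, col, sigma, yy, xx):
    """PSF integrated over pixel areas (difference of error functions)."""
    from scipy.special import erf

    s = sigma * np.sqrt(2.0)
    fy = 0.5 * (erf((yy + 0.5 - row) / s) - erf((yy - 0.5 - row) / s))
    fx = 0.5 * (erf((xx + 0.5 - col) / s) - erf((xx - 0.5 - col) / s))
    return fy * fx


def simulate_tirf_stack(
    config: TirfSimulationConfig,
) -> tuple[ImageStack, GroundTruth]:
    """Render a movie of bleaching, diffusing, diffraction-limited spots.

    Each spot carries n fluorophores drawn from the configured copy-number
    vector; each fluorophore independently survives frame-to-frame with
    probability exp(-bleach_rate) (all alive at frame 0).  The noiseless
    frame is background plus pixel-integrated Gaussian PSFs normalized so
    one surviving fluorophore contributes exactly g counts of summed
    signal; Poisson shot noise and then Gaussian read noise are applied.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.shape
    n_max = cfg.copy_number_probs.size

    copy_numbers = rng.choice(
        np.arange(1, n_max + 1), size=cfg.n_spots, p=cfg.copy_number_probs
    )
    margin = 6.0 * cfg.psf_sigma_px + 2.0
    pos0 = np.column_stack(
        [
            rng.uniform(margin, h - margin, cfg.n_spots),
            rng.uniform(margin, w - margin, cfg.n_spots),
        ]
    )

    # per-fluorophore survival (no blinking): alive until first failure
    survive_p = float(np.exp(-cfg.bleach_rate))
    alive_counts = np.zeros((cfg.n_frames, cfg.n_spots), dtype=int)
    for s in range(cfg.n_spots):
        n = int(copy_numbers[s])
        alive = np.ones(n, dtype=bool)
        for t in range(cfg.n_frames):
            alive_counts[t, s] = int(alive.sum())
            if t < cfg.n_frames - 1 and cfg.bleach_rate > 0:
                alive &= rng.random(n) < survive_p

    positions = np.empty((cfg.n_frames, cfg.n_spots, 2))
    positions[0] = pos0
    for t in range(1, cfg.n_frames):
        step = rng.normal(0.0, cfg.diffusion_sd_px, size=(cfg.n_spots, 2))
        positions[t] = positions[t - 1] + step

    col_idx = np.arange(w, dtype=float)
    row_idx = np.arange(h, dtype=float)
    background = (
        cfg.background_level
        + cfg.background_gradient * (col_idx[None, :] / max(w - 1, 1))
        + 0.0 * row_idx[:, None]
    )

    half = int(np.ceil(6.0 * cfg.psf_sigma_px))
    frames = np.empty((cfg.n_frames, h, w))
    g = cfg.single_fluor_intensity
    for t in range(cfg.n_frames):
        clean = np.array(background, dtype=float)
        for s in range(cfg.n_spots):
            k = alive_counts[t, s]
            if k == 0:
                continue
            r, c = positions[t, s]
            r0, r1 = int(np.floor(r)) - half, int(np.floor(r)) + half + 1
            c0, c1 = int(np.floor(c)) - half, int(np.floor(c)) + half + 1
            r0c, r1c = max(r0, 0), min(r1, h)
            c0c, c1c = max(c0, 0), min(c1, w)
            yy = row_idx[r0c:r1c, None]
            xx = col_idx[None, c0c:c1c]
            clean[r0c:r1c, c0c:c1c] += (
                g * k * _pixel_integrated_psf(r, c, cfg.psf_sigma_px, yy, xx)
            )
        img = rng.poisson(clean).astype(float) if cfg.shot_noise else clean
        if cfg.read_noise_sd > 0:
            img = img + rng.normal(0.0, cfg.read_noise_sd, size=img.shape)
        frames[t] = img

    truth = GroundTruth(
        copy_numbers=copy_numbers,
        positions=positions,
        intensities=g * alive_counts.astype(float),
    )
    return ImageStack(frames), truth


def simulate_mgv_fields(
    n_fields_a: int,
    n_fields_b: int,
    baseline: float = 100.0,
    effect_frac: float = 0.15,
    noise_sd: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two seeded sets of per-field MGVs with a known mean offset.

    Group A ~ Normal(baseline * (1 + effect_frac), noise_sd), group B ~
    Normal(baseline, noise_sd).
    """
    if n_fields_a < 1 or n_fields_b < 1:
        raise ValueError("both groups need at least one field")
    rng = np.random.default_rng(seed)
    a = rng.normal(baseline * (1.0 + effect_frac), noise_sd, size=n_fields_a)
    b = rng.normal(baseline, noise_sd, size=n_fields_b)
    return a, b
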