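"""Synthetic data with the statistical and geometric structure the
two-stage pipeline assumes.

Two generators are provided:

* :func:`sample_profiles` draws labeled CDR profiles from the forward
  generative model (group-dependent Fourier mean + CDAR covariate,
  per-eye random effect, group-specific within-eye noise), so the
  classifier can be exercised and validated against known truth;
* :func:`render_masks` rasterizes a concentric or offset cup/disc
  ellipse pair whose 24-direction radial-ratio profile, area ratio and
  vertical ratio are known in closed form, providing an analytic oracle
  for the mask-geometry stage; :func:`render_pseudo_fundus` colors such
  a mask into a toy RGB image that the segmentation network can learn.

The profile generator's defaults emulate fundus-derived CDR data:
healthy eyes with mean CDR around 0.45 and glaucomatous eyes around
0.7, mild elliptic asymmetry (small Fourier terms), a per-eye random
offset (sd ~0.06) and slightly noisier glaucomatous profiles, with
glaucoma prevalence 0.3 and group CDAR distributions centered at 0.5
(glaucoma) and 0.3 (healthy) with spread 0.1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (CDRProfile, Ellipse, LabelMask, GLAUCOMA, HEALTHY,
                       profile_angles, ray_ellipse_radius)
from .model import SpaGenParams, mean_vector

logger = logging.getLogger(__name__)


def default_generating_params() -> SpaGenParams:
    """Reference truth used throughout tests and simulations."""
    return SpaGenParams(
        beta0=0.35,
        beta_g0=0.18,
        beta_cdar=0.35,
        fourier_g=np.array([0.03, 0.05, 0.02, 0.01]),
        fourier_h=np.array([0.02, 0.04, 0.01, 0.01]),
        sigma_z2=0.004,
        sigma_g2=0.006,
        sigma_h2=0.003,
        prior_g=0.3,
        n_dirs=24,
    )


@dataclass
class SynthProfileConfig:
    params: SpaGenParams = field(default_factory=default_generating_params)
    n_eyes: int = 500
    glaucoma_fraction: float = 0.3
    cdar_mean_g: float = 0.5
    cdar_mean_h: float = 0.3
    cdar_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        if not 0.0 < self.glaucoma_fraction < 1.0:
            raise ValueError("glaucoma fraction must lie in (0, 1)")


@dataclass
class SyntheticProfiles:
    """A labeled synthetic cohort plus the fraction of clipped values."""

    profiles: list[CDRProfile]
    clip_rate: float

    def __iter__(self):
        return iter(self.profiles)

    def __len__(self):
        return len(self.profiles)


def sample_profiles(config: SynthProfileConfig | None = None) -> SyntheticProfiles:
    """Draw labeled CDR profiles from the forward generative model.

    Per eye: group ~ Bernoulli(glaucoma_fraction); CDAR from the group's
    normal law truncated to [0, 1]; z_i ~ N(0, sigma_z^2); within-eye
    noise i.i.d. with the group's variance.  Values are clipped to
    [0, 1] (a CDR is a ratio) and the clipping rate is reported.
    """
    config = config or SynthProfileConfig()
    p = config.params
    rng = np.random.default_rng(config.seed)
    n_dirs = p.n_dirs
    profiles = []
    n_clipped = 0
    for i in range(config.n_eyes):
        is_g = rng.random() < config.glaucoma_fraction
        mean_c = config.cdar_mean_g if is_g else config.cdar_mean_h
        cdar = float(np.clip(rng.normal(mean_c, config.cdar_sd), 0.0, 1.0))
        group = GLAUCOMA if is_g else HEALTHY
        mu = mean_vector(p, group, cdar if p.beta_cdar is not None else None)
        z = rng.normal(0.0, math.sqrt(p.sigma_z2)) if p.sigma_z2 > 0 else 0.0
        s2 = p.sigma_g2 if is_g else p.sigma_h2
        e = rng.normal(0.0, math.sqrt(s2), size=n_dirs) if s2 > 0 else np.zeros(n_dirs)
        y = mu + z + e
        clipped = np.clip(y, 0.0, 1.0)
        n_clipped += int(np.sum(clipped != y))
        profiles.append(CDRProfile(eye_id=f"synth{i:05d}", values=clipped,
                                   cdar=cdar, vcdr=float(np.clip(y.mean(), 0, 1)),
                                   label=group))
    clip_rate = n_clipped / (config.n_eyes * n_dirs)
    if clip_rate > 0:
        logger.info("clipped %.3f%% of simulated CDR values", 100 * clip_rate)
    return SyntheticProfiles(profiles=profiles, clip_rate=clip_rate)


# ---------------------------------------------------------------------------
# mask rendering
# ---------------------------------------------------------------------------

@dataclass
class SynthMaskConfig:
    image_size: tuple[int, int] = (256, 256)
    disc: Ellipse = field(default_factory=lambda: Ellipse((128.0, 128.0), (80.0, 70.0)))
    cup: Ellipse = field(default_factory=lambda: Ellipse((128.0, 128.0), (40.0, 35.0)))
    noise_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not _ellipse_contained(self.cup, self.disc):
            raise ValueError("cup ellipse must be contained in the disc ellipse")


def _ellipse_contained(inner: Ellipse, outer: Ellipse, n_check: int = 720) -> bool:
    t = np.linspace(0.0, 2.0 * math.pi, n_check, endpoint=False)
    a, b = inner.semi_axes
    phi = math.radians(inner.rotation_deg)
    # boundary points of the inner ellipse in (x, y=-row) coordinates
    x = a * np.cos(t) * math.cos(phi) - b * np.sin(t) * math.sin(phi) + inner.center[1]
    y = a * np.cos(t) * math.sin(phi) + b * np.sin(t) * math.cos(phi) - inner.center[0]
    rr = -y
    return bool(np.all(outer.elliptic_radius(rr, x) <= 1.0 + 1e-9))


def _radial_noise(rng: np.random.Generator, amplitude: float):
    """Smooth angular perturbation field rho(theta) = 1 + small Fourier sum."""
    if amplitude <= 0:
        return lambda theta: np.ones_like(theta)
    coef = rng.normal(0.0, 1.0, size=(3, 2))
    coef /= max(np.abs(coef).sum(), 1e-9)

    def rho(theta):
        out = np.ones_like(theta)
        for k in range(1, 4):
            out = out + amplitude * (coef[k - 1, 0] * np.cos(k * theta)
                                     + coef[k - 1, 1] * np.sin(k * theta))
        return out

    return rho


def _rasterize(ellipse: Ellipse, shape, rho) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    r_ell = ellipse.elliptic_radius(rr, cc)
    theta = np.arctan2(-(rr - ellipse.center[0]), cc - ellipse.center[1])
    return r_ell <= rho(theta)


def render_masks(config: SynthMaskConfig | None = None,
                 n_dirs: int = 24) -> tuple[LabelMask, CDRProfile]:
    """Rasterize a cup/disc ellipse pair and return the analytic profile.

    The analytic profile is the closed-form ray/ellipse radial ratio from
    the disc center (it refers to the noiseless ellipses; boundary noise,
    if any, perturbs only the raster).
    """
    config = config or SynthMaskConfig()
    rng = np.random.default_rng(config.seed)
    rho_disc = _radial_noise(rng, config.noise_amplitude)
    rho_cup = _radial_noise(rng, config.noise_amplitude)
    disc_px = _rasterize(config.disc, config.image_size, rho_disc)
    cup_px = _rasterize(config.cup, config.image_size, rho_cup)
    mask = LabelMask.from_binary(disc_px | cup_px, cup_px & disc_px)

    center = config.disc.center
    values = np.zeros(n_dirs)
    for i, ang in enumerate(profile_angles(n_dirs)):
        r_d = ray_ellipse_radius(center, ang, config.disc)
        r_c = ray_ellipse_radius(center, ang, config.cup)
        values[i] = 0.0 if r_d <= 0 else min(max(r_c / r_d, 0.0), 1.0)
    cdar = min(config.cup.area / config.disc.area, 1.0)
    vcdr = min(config.cup.vertical_extent / config.disc.vertical_extent, 1.0)
    analytic = CDRProfile(eye_id="analytic", values=values, cdar=cdar, vcdr=vcdr)
    return mask, analytic


def render_pseudo_fundus(mask: LabelMask, seed: int = 0,
                         border_fraction: float = 0.1) -> np.ndarray:
    """Color a label mask into a toy RGB fundus-like image (uint8 HxWx3).

    Background, disc rim and cup get distinct mean intensities plus mild
    Gaussian noise, and the image is framed by a black circular field
    border so the preprocessing crop has something to remove.  No attempt
    is made to imitate vessels or real fundus texture.
    """
    rng = np.random.default_rng(seed)
    h, w = mask.pixels.shape
    img = np.empty((h, w, 3), dtype=float)
    colors = {0: (120.0, 45.0, 30.0),   # background: dark red
              1: (215.0, 130.0, 60.0),  # rim: orange
              2: (250.0, 215.0, 110.0)}  # cup: pale yellow
    for lab, col in colors.items():
        img[mask.pixels == lab] = col
    img += rng.normal(0.0, 6.0, size=img.shape)

    rr, cc = np.mgrid[0:h, 0:w]
    radius = (1.0 - border_fraction) * min(h, w) / 2.0
    outside = (rr - (h - 1) / 2.0) ** 2 + (cc - (w - 1) / 2.0) ** 2 > radius**2
    img[outside] = 0.0
    return np.clip(img, 0, 255).astype(np.uint8)
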