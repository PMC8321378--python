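"""Cup/disc mask geometry: 24-direction CDR profiles, vCDR and CDAR.

The optic disc and cup are encoded as a per-pixel label image
(0 = background, 1 = neuroretinal rim / disc-only, 2 = cup; the *disc
region* is labels >= 1, cup included).  From such a mask this module
extracts the directional cup-to-disc ratio (CDR) profile: for rays cast
from the disc centroid at 15-degree intervals, the ratio of the cup's
radial extent to the disc's radial extent, clipped to [0, 1].  The
vertical CDR (vCDR) is the ratio of vertical pixel extents and the
cup-to-disc area ratio (CDAR) is the ratio of pixel counts.

Conventions
-----------
* coordinates are 0-based (row, col); the vertical axis is the row axis;
* angle 0 degrees points along +col (3 o'clock on screen) and angles
  increase counter-clockwise on screen (towards -row);
* direction d = 1..n_dirs corresponds to the angle 15 * (d - 1) degrees
  for the default 24 directions;
* rays are marched in fixed 0.25-px steps; the returned radius is the
  distance from the center to the outermost in-region pixel center hit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .errors import DegenerateMaskError, GeometryError

logger = logging.getLogger(__name__)

GLAUCOMA = "glaucoma"
HEALTHY = "healthy"

_RAY_STEP = 0.25


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LabelMask:
    """Per-pixel label image: 0 background, 1 disc-only (rim), 2 cup."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("label mask must be a 2-D array")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def disc(self) -> np.ndarray:
        """Boolean disc region (cup included)."""
        return self.pixels >= 1

    @property
    def cup(self) -> np.ndarray:
        return self.pixels == 2

    @classmethod
    def from_binary(cls, disc: np.ndarray, cup: np.ndarray) -> "LabelMask":
        """Build a LabelMask from two binary masks, clipping cup to disc.

        Cup pixels falling outside the disc are relabeled as disc and a
        warning is logged (the cup is anatomically contained in the disc).
        """
        disc = np.asarray(disc, dtype=bool)
        cup = np.asarray(cup, dtype=bool)
        if disc.shape != cup.shape:
            raise ValueError("disc and cup masks must have the same shape")
        outside = cup & ~disc
        n_out = int(outside.sum())
        if n_out:
            logger.warning("clipped %d cup pixel(s) lying outside the disc", n_out)
        labels = np.zeros(disc.shape, dtype=np.uint8)
        labels[disc | outside] = 1
        labels[cup & disc] = 2
        return cls(labels)


@dataclass
class CDRProfile:
    """One eye's directional CDR profile plus CDAR, vCDR and label."""

    eye_id: str
    values: np.ndarray
    cdar: float
    vcdr: float
    label: str | None = None  # "glaucoma" | "healthy" | None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be a 1-D vector")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("CDR values must lie in [0, 1]")
        for name in ("cdar", "vcdr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.label is not None and self.label not in (GLAUCOMA, HEALTHY):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def n_dirs(self) -> int:
        return self.values.size


@dataclass
class Ellipse:
    """Ellipse in image coordinates: center (row, col), semi-axes, rotation.

    ``rotation_deg`` is measured like ray angles: counter-clockwise on
    screen from the +col axis.  ``semi_axes = (a, b)`` with *a* along the
    rotated 0-degree axis.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation_deg: float = 0.0

    def contains(self, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
        q = self._local(rr, cc)
        a, b = self.semi_axes
        return (q[0] / a) ** 2 + (q[1] / b) ** 2 <= 1.0

    def elliptic_radius(self, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
        """sqrt((x'/a)^2 + (y'/b)^2): 1 on the boundary, < 1 inside."""
        q = self._local(rr, cc)
        a, b = self.semi_axes
        return np.sqrt((q[0] / a) ** 2 + (q[1] / b) ** 2)

    def _local(self, rr, cc):
        # screen-CCW rotation in (x, y) = (col, -row) coordinates
        phi = math.radians(self.rotation_deg)
        x = np.asarray(cc, dtype=float) - self.center[1]
        y = -(np.asarray(rr, dtype=float) - self.center[0])
        xl = math.cos(phi) * x + math.sin(phi) * y
        yl = -math.sin(phi) * x + math.cos(phi) * y
        return xl, yl

    @property
    def area(self) -> float:
        return math.pi * self.semi_axes[0] * self.semi_axes[1]

    @property
    def vertical_extent(self) -> float:
        """Full extent along the image row axis."""
        a, b = self.semi_axes
        phi = math.radians(self.rotation_deg)
        return 2.0 * math.hypot(a * math.sin(phi), b * math.cos(phi))


def ray_ellipse_radius(origin: tuple[float, float], angle_deg: float,
                       ellipse: Ellipse) -> float:
    """Distance from ``origin`` (row, col) to the ellipse boundary along a ray.

    Closed-form ray/ellipse intersection; returns the largest positive
    root, or 0.0 if the ray never reaches the ellipse.
    """
    phi = math.radians(ellipse.rotation_deg)
    th = math.radians(angle_deg)
    a, b = ellipse.semi_axes
    # origin and direction in the ellipse's local frame (x=col, y=-row)
    x0 = origin[1] - ellipse.center[1]
    y0 = -(origin[0] - ellipse.center[0])
    qx = math.cos(phi) * x0 + math.sin(phi) * y0
    qy = -math.sin(phi) * x0 + math.cos(phi) * y0
    dx, dy = math.cos(th), math.sin(th)
    ux = math.cos(phi) * dx + math.sin(phi) * dy
    uy = -math.sin(phi) * dx + math.cos(phi) * dy
    A = (ux / a) ** 2 + (uy / b) ** 2
    B = 2.0 * (qx * ux / a**2 + qy * uy / b**2)
    C = (qx / a) ** 2 + (qy / b) ** 2 - 1.0
    disc = B * B - 4.0 * A * C
    if disc < 0:
        return 0.0
    t = (-B + math.sqrt(disc)) / (2.0 * A)
    return max(t, 0.0)


# ---------------------------------------------------------------------------
# mask loading
# ---------------------------------------------------------------------------

def load_mask(path, encoding: dict[int, int] | None = None) -> LabelMask:
    """Read a label image and normalize it to the 0/1/2 scheme.

    Parameters
    ----------
    path:
        Raster image file (PNG/TIFF/...) holding per-pixel labels.
    encoding:
        Optional mapping from raw pixel values to {0, 1, 2}, e.g.
        ``{0: 0, 128: 1, 255: 2}``.  Without it, raw values already in
        {0, 1, 2} are taken as-is; otherwise up to three distinct raw
        values are mapped to 0/1/2 in ascending order.
    """
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("I") if im.mode not in ("L", "I", "I;16") else im)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read mask image {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return normalize_labels(arr, encoding)


def normalize_labels(arr: np.ndarray, encoding: dict[int, int] | None = None) -> LabelMask:
    """Map raw label values to {0,1,2} and enforce cup-inside-disc."""
    arr = np.asarray(arr)
    if encoding is None:
        uniq = np.unique(arr)
        if set(uniq.tolist()) <= {0, 1, 2}:
            encoding = {int(v): int(v) for v in uniq}
        elif uniq.size <= 3:
            encoding = {int(v): i for i, v in enumerate(uniq.tolist())}
        else:
            raise ValueError(
                f"mask has {uniq.size} distinct values; supply an explicit encoding"
            )
    labels = np.zeros(arr.shape, dtype=np.uint8)
    for raw, lab in encoding.items():
        if lab not in (0, 1, 2):
            raise ValueError("encoding must map onto labels {0, 1, 2}")
        labels[arr == raw] = lab
    mask = LabelMask.from_binary(labels >= 1, labels == 2)
    if not mask.disc.any():
        raise DegenerateMaskError("mask contains no disc pixels")
    return mask


# ---------------------------------------------------------------------------
# radial geometry
# ---------------------------------------------------------------------------

def _march(region: np.ndarray, center: tuple[float, float], angle_deg: float,
           step: float = _RAY_STEP) -> float:
    """Distance from center to the outermost region pixel along the ray.

    Fixed-step ray march; samples are snapped to the nearest pixel and the
    returned radius is the center-to-pixel-center distance of the last
    in-region sample (0.0 if no sample hits the region).
    """
    h, w = region.shape
    cr, cc = center
    th = math.radians(angle_deg)
    dr, dc = -math.sin(th), math.cos(th)
    t_max = math.hypot(h, w)
    best = 0.0
    hit = False
    for t in np.arange(0.0, t_max + step, step):
        r = int(round(cr + t * dr))
        c = int(round(cc + t * dc))
        if not (0 <= r < h and 0 <= c < w):
            break
        if region[r, c]:
            best = math.hypot(r - cr, c - cc)
            hit = True
    return best if hit else 0.0


def radial_boundary_distance(region: np.ndarray, center: tuple[float, float],
                             angle_deg: float, step: float = _RAY_STEP) -> float:
    """Radius of a binary region along one ray from ``center`` (row, col)."""
    region = np.asarray(region, dtype=bool)
    r0, c0 = int(round(center[0])), int(round(center[1]))
    if not (0 <= r0 < region.shape[0] and 0 <= c0 < region.shape[1] and region[r0, c0]):
        raise GeometryError("ray center lies outside the region")
    return _march(region, center, angle_deg, step)


def _fit_ellipse(region: np.ndarray) -> Ellipse | None:
    """Least-squares ellipse fit to a binary region's boundary, or None."""
    from skimage import measure

    contours = measure.find_contours(region.astype(float), 0.5)
    if not contours:
        return None
    pts = max(contours, key=len)[:, ::-1]  # EllipseModel wants (x, y) = (col, row)
    if hasattr(measure.EllipseModel, "from_estimate"):
        fit = measure.EllipseModel.from_estimate(pts)
        if not fit:
            return None
        xc, yc = fit.center
        a, b = fit.axis_lengths
        theta = fit.theta
    else:  # scikit-image < 0.26
        fit = measure.EllipseModel()
        if not fit.estimate(pts):
            return None
        xc, yc, a, b, theta = fit.params
    # model theta is CCW in (col, row); our rotation is CCW on screen (row down)
    return Ellipse(center=(yc, xc), semi_axes=(a, b), rotation_deg=-math.degrees(theta))


def profile_angles(n_dirs: int = 24) -> np.ndarray:
    """Ray angles in degrees for directions d = 1..n_dirs (15-degree steps)."""
    return np.arange(n_dirs) * (360.0 / n_dirs)


def extract_cdr_profile(mask: LabelMask, n_dirs: int = 24, eye_id: str = "eye",
                        label: str | None = None,
                        ellipse_fit: bool = False) -> CDRProfile:
    """Directional CDR profile of one eye from its label mask.

    Rays originate at the disc-region centroid.  Per direction,
    ``CDR_d = r_cup / r_disc`` clipped to [0, 1]; an empty cup along a ray
    contributes 0.  With ``ellipse_fit=True`` the raw boundaries are
    replaced by least-squares-fitted ellipses before measuring radii
    (mirroring annotation pipelines that store best-fitting ellipses).
    """
    if n_dirs < 4:
        raise ValueError("n_dirs must be at least 4")
    disc, cup = mask.disc, mask.cup
    if not disc.any():
        raise DegenerateMaskError("mask contains no disc pixels")
    rr, cc = np.nonzero(disc)
    center = (float(rr.mean()), float(cc.mean()))

    disc_ell = cup_ell = None
    if ellipse_fit:
        disc_ell = _fit_ellipse(disc)
        cup_ell = _fit_ellipse(cup) if cup.any() else None

    angles = profile_angles(n_dirs)
    values = np.zeros(n_dirs)
    for i, ang in enumerate(angles):
        if disc_ell is not None:
            r_disc = ray_ellipse_radius(center, ang, disc_ell)
        else:
            r_disc = _march(disc, center, ang)
        if not cup.any():
            r_cup = 0.0
        elif cup_ell is not None:
            r_cup = ray_ellipse_radius(center, ang, cup_ell)
        else:
            r_cup = _march(cup, center, ang)
        values[i] = 0.0 if r_disc <= 0 else min(max(r_cup / r_disc, 0.0), 1.0)

    return CDRProfile(eye_id=eye_id, values=values, cdar=compute_cdar(mask),
                      vcdr=compute_vcdr(mask), label=label)


def compute_cdar(mask: LabelMask) -> float:
    """Cup-to-disc area ratio: cup pixel count over disc-region pixel count."""
    n_disc = int(mask.disc.sum())
    if n_disc == 0:
        raise DegenerateMaskError("mask contains no disc pixels")
    return float(mask.cup.sum()) / n_disc


def compute_vcdr(mask: LabelMask) -> float:
    """Vertical CDR: ratio of cup to disc vertical extents in pixel rows."""
    disc_rows = np.nonzero(mask.disc.any(axis=1))[0]
    if disc_rows.size == 0:
        raise DegenerateMaskError("mask contains no disc pixels")
    cup_rows = np.nonzero(mask.cup.any(axis=1))[0]
    if cup_rows.size == 0:
        return 0.0
    cup_h = cup_rows[-1] - cup_rows[0] + 1
    disc_h = disc_rows[-1] - disc_rows[0] + 1
    return min(cup_h / disc_h, 1.0)


# ---------------------------------------------------------------------------
# profile tables (CSV dialect shared across the package)
# ---------------------------------------------------------------------------

def profiles_to_frame(profiles) -> pd.DataFrame:
    """Tabulate profiles as eye_id, d1..dN, cdar, vcdr, label."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to tabulate")
    n = profiles[0].n_dirs
    rows = []
    for p in profiles:
        if p.n_dirs != n:
            raise ValueError("profiles have inconsistent numbers of directions")
        row = {"eye_id": p.eye_id}
        row.update({f"d{i + 1}": v for i, v in enumerate(p.values)})
        row["cdar"] = p.cdar
        row["vcdr"] = p.vcdr
        row["label"] = p.label if p.label is not None else ""
        rows.append(row)
    return pd.DataFrame(rows)


def write_profiles(profiles, path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def read_profiles(path) -> list[CDRProfile]:
    df = pd.read_csv(path, dtype={"eye_id": str})
    dcols = sorted((c for c in df.columns if c.startswith("d") and c[1:].isdigit()),
                   key=lambda c: int(c[1:]))
    if not dcols:
        raise ValueError(f"{path!r} has no profile value columns d1..dN")
    out = []
    for _, row in df.iterrows():
        label = row.get("label", "")
        label = None if (pd.isna(label) or label == "") else str(label)
        out.append(CDRProfile(
            eye_id=str(row["eye_id"]),
            values=row[dcols].to_numpy(dtype=float),
            cdar=float(row["cdar"]),
            vcdr=float(row["vcdr"]),
            label=label,
        ))
    return out
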