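"""Synthetic CT phantoms of shot ballistic-soap blocks with known truth.

A phantom is a rectangular block of soap-like intensity surrounded by air,
containing a single air-filled wound cavity that opens at the entry face,
optional high-intensity metal fragments, optional streak artifacts near
large fragments, and Gaussian acquisition noise.  Every phantom carries a
:class:`PhantomTruth` record with the analytic cavity volume, the true
cavity axis, fragment positions and the maximal inscribed sphere of the
parametric cavity, so each downstream stage (segmentation, morphometry,
statistics) can be validated by parameter recovery.

Cavity families mimic the shapes different bullet classes leave behind:

``tumbling_spindle``
    a narrow entry channel with a spindle-shaped bulge deep in the block —
    a dimensionally stable bullet that tumbles at depth (brass-bullet
    class, bulge around 200 mm in full-size blocks).
``early_opening``
    near-maximal radius within the first quarter of the track, then a slow
    taper — a bullet whose expansion is triggered immediately by a tip
    insert (fragmenting copper class).
``tear_shaped``
    a smooth rise to a maximum and a long taper — continuously expanding
    deforming bullets (copper hollow-point and lead-core classes).
``cylinder`` / ``ellipsoid``
    analytic reference shapes for calibration tests.

All families are surfaces of revolution around an axis tilted by
``tilt_deg`` about the entry point; the tilt plane is x–z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from soapct.ballistics import BULLETS, ShotRecord
from soapct.volume_io import VoxelVolume

__all__ = [
    "CAVITY_FAMILIES",
    "PhantomSpec",
    "PhantomTruth",
    "default_cavity_params",
    "cavity_profile",
    "cavity_analytic_volume_ml",
    "params_for_volume",
    "generate_phantom",
    "enumerate_design",
]

CAVITY_FAMILIES = ("tumbling_spindle", "early_opening", "tear_shaped",
                   "cylinder", "ellipsoid")

#: CT intensity (HU) above which a voxel counts as metal.
FRAGMENT_THRESHOLD_HU = 2000.0


def default_cavity_params(family: str, length_mm: float = 300.0) -> dict:
    """Reasonable family parameters for a cavity of the given length.

    ``max_depth_mm`` (depth of the maximal diameter) defaults to 2/3 of
    the length for the tumbling spindle — in a full-size block this puts
    the bulge near 200 mm, where dimensionally stable brass bullets
    typically tumble — and 1/3 for the tear shape.
    """
    if family not in CAVITY_FAMILIES:
        raise ValueError(f"unknown cavity family {family!r}")
    p = {
        "length_mm": float(length_mm),
        "max_radius_mm": 18.0,
        "neck_radius_mm": 4.0,
        "tilt_deg": 0.0,
    }
    if family == "tumbling_spindle":
        p["max_depth_mm"] = 2.0 / 3.0 * length_mm
        p["width_mm"] = length_mm / 8.0
    elif family == "tear_shaped":
        p["max_depth_mm"] = length_mm / 3.0
        p["shape_power"] = 1.5
    return p


def _smoothstep(t):
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def cavity_profile(family: str, params: dict, depth_mm):
    """Radius (mm) of the cavity's surface of revolution at the given depth.

    Vectorized over ``depth_mm``; depths must lie in [0, length].
    """
    if family not in CAVITY_FAMILIES:
        raise ValueError(f"unknown cavity family {family!r}")
    d = np.asarray(depth_mm, dtype=float)
    L = float(params["length_mm"])
    if np.any(d < 0) or np.any(d > L):
        raise ValueError("depth outside [0, cavity length]")
    rmax = float(params["max_radius_mm"])
    neck = float(params.get("neck_radius_mm", 4.0))

    if family == "cylinder":
        r = np.full_like(d, rmax)
    elif family == "ellipsoid":
        half = L / 2.0
        ell = rmax * np.sqrt(np.clip(1.0 - ((d - half) / half) ** 2, 0.0, None))
        # entry channel up to mid-depth so the cavity opens at the face
        r = np.where(d <= half, np.maximum(neck, ell), ell)
    elif family == "tumbling_spindle":
        dmax = float(params.get("max_depth_mm", 2.0 / 3.0 * L))
        w = float(params.get("width_mm", L / 8.0))
        bump = rmax * np.exp(-0.5 * ((d - dmax) / w) ** 2)
        r = np.maximum(neck, bump)
    elif family == "tear_shaped":
        dmax = float(params.get("max_depth_mm", L / 3.0))
        alpha = float(params.get("shape_power", 1.5))
        t = d / dmax
        tear = rmax * np.where(t > 0, (t * np.exp(1.0 - t)) ** alpha, 0.0)
        r = np.maximum(neck, tear)
    else:  # early_opening
        quarter = 0.25 * L
        rise = _smoothstep(d / quarter)
        taper = np.where(d > quarter, 1.0 - 0.65 * (d - quarter) / (L - quarter), 1.0)
        r = neck + (rmax - neck) * rise * taper
    return float(r) if np.isscalar(depth_mm) else r


_N_DENSE = 4096


def _dense_profile(family, params):
    L = float(params["length_mm"])
    d = np.linspace(0.0, L, _N_DENSE)
    return d, cavity_profile(family, params, d)


def cavity_analytic_volume_ml(family: str, params: dict) -> float:
    """Volume (mL) of the parametric cavity, pi * integral of r(d)^2 dd.

    The tilt is a rigid rotation and does not change the volume.
    """
    d, r = _dense_profile(family, params)
    return float(np.pi * np.trapezoid(r**2, d)) / 1000.0


def params_for_volume(family: str, target_ml: float, params: dict) -> dict:
    """Scale ``max_radius_mm`` so the analytic cavity volume hits a target.

    The neck radius is kept fixed; the volume is monotone in the maximal
    radius, so a bracketed scalar solve suffices.
    """
    from scipy.optimize import brentq

    if target_ml <= 0:
        raise ValueError("target volume must be positive")

    def vol(rmax):
        q = dict(params, max_radius_mm=rmax)
        return cavity_analytic_volume_ml(family, q) - target_ml

    neck = float(params.get("neck_radius_mm", 4.0))
    lo, hi = neck + 0.05, 200.0
    if vol(lo) > 0:
        raise ValueError("target volume below the volume of the bare channel")
    rmax = brentq(vol, lo, hi, xtol=1e-6)
    return dict(params, max_radius_mm=float(rmax))


def _axis_frame(tilt_deg: float):
    """Unit axis (tilted about the entry point, in the x-z plane) and a
    perpendicular in-plane frame."""
    th = np.deg2rad(tilt_deg)
    u = np.array([np.sin(th), 0.0, np.cos(th)])
    e1 = np.array([np.cos(th), 0.0, -np.sin(th)])
    e2 = np.array([0.0, 1.0, 0.0])
    return u, e1, e2


def _true_max_sphere(family, params):
    """Maximal sphere inscribed in the parametric cavity, from the profile.

    For an axis point at depth d0 the nearest boundary is the entry plane
    (distance d0), the exit cap (distance L - d0), or the lateral surface
    (min over d of the distance to the profile curve).  The profiles are
    smooth and slowly varying near their maximum, so the maximal sphere is
    centered on the axis.
    """
    d, r = _dense_profile(family, params)
    L = float(params["length_mm"])
    d0 = np.linspace(0.0, L, 2048)
    lateral = np.sqrt((d[None, :] - d0[:, None]) ** 2 + r[None, :] ** 2).min(axis=1)
    radius = np.minimum(np.minimum(d0, L - d0), lateral)
    i = int(np.argmax(radius))
    return float(radius[i]), float(d0[i])


@dataclass
class PhantomSpec:
    """Parameters of one synthetic soap-block phantom.

    Intensities default to +100 HU soap, −1000 HU air and +3000 HU metal,
    which leaves margin on both segmentation thresholds (half the soap
    intensity for block/cavity, 2000 HU for metal).
    """

    cavity_family: str = "tear_shaped"
    cavity_params: dict = field(default_factory=dict)
    block_shape_mm: tuple = (250.0, 250.0, 400.0)
    voxel_spacing_mm: tuple = (1.0, 1.0, 1.0)
    soap_intensity_hu: float = 100.0
    air_intensity_hu: float = -1000.0
    fragment_intensity_hu: float = 3000.0
    n_fragments: int = 0
    fragment_radius_range_mm: tuple = (1.5, 3.0)
    streak_artifacts: bool = False
    noise_sd_hu: float = 5.0
    air_margin_mm: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cavity_params:
            # default cavity length: 3/4 of the block's long axis
            self.cavity_params = default_cavity_params(
                self.cavity_family, 0.75 * self.block_shape_mm[2])
        self.validate()

    def validate(self) -> None:
        if self.cavity_family not in CAVITY_FAMILIES:
            raise ValueError(f"unknown cavity family {self.cavity_family!r}")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")
        if any(s <= 0 for s in self.block_shape_mm):
            raise ValueError("block extents must be strictly positive")
        if self.fragment_intensity_hu <= FRAGMENT_THRESHOLD_HU:
            raise ValueError(
                f"fragment intensity must exceed the {FRAGMENT_THRESHOLD_HU:g} HU "
                "metal threshold")
        if not (self.air_intensity_hu < self.soap_intensity_hu
                < self.fragment_intensity_hu):
            raise ValueError("need air < soap < fragment intensity")
        if self.n_fragments < 0:
            raise ValueError("n_fragments must be nonnegative")
        if self.noise_sd_hu < 0:
            raise ValueError("noise sd must be nonnegative")
        self._check_cavity_fits()

    def _check_cavity_fits(self) -> None:
        X, Y, Z = self.block_shape_mm
        p = self.cavity_params
        L = float(p["length_mm"])
        tilt = float(p.get("tilt_deg", 0.0))
        d, r = _dense_profile(self.cavity_family, p)
        th = np.deg2rad(tilt)
        # entry point is centered on the entry face; axis tilts toward +x
        reach_x = np.max(d * np.sin(th) + r)
        reach_x_neg = np.max(r - d * np.sin(th))
        reach_y = float(np.max(r))
        reach_z = L * np.cos(th)
        if reach_x >= X / 2 or reach_x_neg >= X / 2 or reach_y >= Y / 2:
            raise ValueError("cavity exceeds the block's lateral extents")
        if reach_z >= Z:
            raise ValueError("cavity is longer than the block")


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom, for recovery testing."""

    cavity_family: str
    cavity_params: dict
    true_cavity_volume_ml: float
    true_axis_unit_vector: tuple
    true_tilt_deg: float
    true_max_sphere_radius_mm: float
    #: depth of the inscribed-sphere center along the cavity axis (mm)
    true_max_sphere_depth_mm: float
    #: same depth projected on the block long axis (z from the entry face)
    true_max_sphere_depth_z_mm: float
    true_max_diameter_depth_mm: float
    entry_point_mm: tuple
    fragment_centers_mm: list
    fragment_radii_mm: list
    streak_speck_centers_mm: list
    n_cavity_voxels: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PhantomTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _place_fragments(spec: PhantomSpec, rng, entry, u, e1, e2):
    """Sample non-overlapping fragment spheres in the soap near the cavity."""
    p = spec.cavity_params
    L = float(p["length_mm"])
    X, Y, Z = spec.block_shape_mm
    m = spec.air_margin_mm
    centers, radii = [], []
    lo, hi = spec.fragment_radius_range_mm
    for _ in range(spec.n_fragments):
        for _attempt in range(200):
            rad = float(rng.uniform(lo, hi))
            df = float(rng.uniform(0.25 * L, 0.95 * L))
            phi = float(rng.uniform(0, 2 * np.pi))
            gap = float(rng.uniform(1.0, 4.0))
            rho = cavity_profile(spec.cavity_family, p, df) + rad + gap
            c = entry + df * u + rho * (np.cos(phi) * e1 + np.sin(phi) * e2)
            inside = (m + rad + 1 < c[0] < m + X - rad - 1
                      and m + rad + 1 < c[1] < m + Y - rad - 1
                      and m + rad + 1 < c[2] < m + Z - rad - 1)
            clear = all(np.linalg.norm(c - c2) > rad + r2 + 3.0
                        for c2, r2 in zip(centers, radii))
            if inside and clear:
                centers.append(c)
                radii.append(rad)
                break
        else:
            raise RuntimeError("could not place all fragments without overlap")
    return centers, radii


def _paint_sphere(vol, spacing, origin, center, radius, value):
    lo = np.maximum(0, np.floor((center - radius - origin) / spacing)).astype(int)
    hi = np.minimum(np.array(vol.shape) - 1,
                    np.ceil((center + radius - origin) / spacing)).astype(int)
    ii = [origin[a] + np.arange(lo[a], hi[a] + 1) * spacing[a] - center[a]
          for a in range(3)]
    d2 = (ii[0][:, None, None] ** 2 + ii[1][None, :, None] ** 2
          + ii[2][None, None, :] ** 2)
    sub = vol[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    sub[d2 <= radius**2] = value


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, PhantomTruth]:
    """Render a phantom volume and its ground-truth record.

    Deterministic for a fixed ``spec.seed``: the same spec yields a
    bit-identical volume.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sp = np.asarray(spec.voxel_spacing_mm, dtype=float)
    m = spec.air_margin_mm
    X, Y, Z = spec.block_shape_mm
    extent = np.array([X + 2 * m, Y + 2 * m, Z + 2 * m])
    shape = np.ceil(extent / sp).astype(int)
    origin = sp / 2.0  # voxel centers at (i + 1/2) * spacing

    xs = origin[0] + np.arange(shape[0]) * sp[0]
    ys = origin[1] + np.arange(shape[1]) * sp[1]
    zs = origin[2] + np.arange(shape[2]) * sp[2]

    in_block = ((xs >= m) & (xs < m + X))[:, None, None] \
        & ((ys >= m) & (ys < m + Y))[None, :, None] \
        & ((zs >= m) & (zs < m + Z))[None, None, :]

    p = spec.cavity_params
    L = float(p["length_mm"])
    tilt = float(p.get("tilt_deg", 0.0))
    u, e1, e2 = _axis_frame(tilt)
    entry = np.array([m + X / 2.0, m + Y / 2.0, m])

    dx, dy, dz = xs - entry[0], ys - entry[1], zs - entry[2]
    # depth along the tilted axis depends only on (x, z); the squared
    # distance to the axis is |p - entry|^2 - depth^2
    d_xz = u[0] * dx[:, None] + u[2] * dz[None, :]
    dd, rr = _dense_profile(spec.cavity_family, p)
    r_xz = np.interp(d_xz, dd, rr)
    A = r_xz**2 + d_xz**2 - dx[:, None] ** 2 - dz[None, :] ** 2
    in_range = (d_xz >= 0.0) & (d_xz <= L)
    cavity = (dy[None, :, None] ** 2 <= A[:, None, :]) \
        & in_range[:, None, :] & in_block

    vol = np.full(shape, spec.air_intensity_hu, dtype=np.float32)
    vol[in_block] = spec.soap_intensity_hu
    vol[cavity] = spec.air_intensity_hu
    n_cavity_voxels = int(cavity.sum())

    centers, radii = ([], [])
    if spec.n_fragments > 0:
        centers, radii = _place_fragments(spec, rng, entry, u, e1, e2)
        for c, rad in zip(centers, radii):
            _paint_sphere(vol, sp, origin, c, rad, spec.fragment_intensity_hu)

    specks: list = []
    if spec.streak_artifacts and centers:
        med = float(np.median(radii))
        for c, rad in zip(centers, radii):
            if rad < med:
                continue
            # thin spokes of alternating +/-500 HU within 5 mm of the fragment
            for k in range(6):
                phi = float(rng.uniform(0, 2 * np.pi))
                cth = float(rng.uniform(-0.3, 0.3))
                dirv = np.array([np.sqrt(1 - cth**2) * np.cos(phi),
                                 np.sqrt(1 - cth**2) * np.sin(phi), cth])
                sign = 1.0 if k % 2 == 0 else -1.0
                for t in np.arange(rad + 1.0, rad + 5.0, min(sp)):
                    pos = c + t * dirv
                    idx = np.round((pos - origin) / sp).astype(int)
                    if np.all(idx >= 0) and np.all(idx < shape) \
                            and in_block[tuple(idx)] and not cavity[tuple(idx)] \
                            and vol[tuple(idx)] < FRAGMENT_THRESHOLD_HU:
                        vol[tuple(idx)] = spec.soap_intensity_hu + sign * 500.0
            # 1-2 bright specks mimicking streak-induced fake fragments
            for _k in range(int(rng.integers(1, 3))):
                for _attempt in range(100):
                    phi = float(rng.uniform(0, 2 * np.pi))
                    cth = float(rng.uniform(-0.5, 0.5))
                    dirv = np.array([np.sqrt(1 - cth**2) * np.cos(phi),
                                     np.sqrt(1 - cth**2) * np.sin(phi), cth])
                    t = rad + float(rng.uniform(2.0, 3.5))
                    pos = c + t * dirv
                    idx = np.round((pos - origin) / sp).astype(int)
                    if np.all(idx >= 1) and np.all(idx < shape - 1) \
                            and in_block[tuple(idx)] and not cavity[tuple(idx)]:
                        nb = vol[idx[0] - 1:idx[0] + 2, idx[1] - 1:idx[1] + 2,
                                 idx[2] - 1:idx[2] + 2]
                        if np.all(nb < FRAGMENT_THRESHOLD_HU):
                            vol[tuple(idx)] = spec.fragment_intensity_hu
                            specks.append(origin + idx * sp)
                            break

    if spec.noise_sd_hu > 0:
        vol += spec.noise_sd_hu * rng.standard_normal(vol.shape, dtype=np.float32)
        np.clip(vol, -2047.0, 32766.0, out=vol)

    r_sph, d_sph = _true_max_sphere(spec.cavity_family, p)
    truth = PhantomTruth(
        cavity_family=spec.cavity_family,
        cavity_params={k: float(v) for k, v in p.items()},
        true_cavity_volume_ml=cavity_analytic_volume_ml(spec.cavity_family, p),
        true_axis_unit_vector=tuple(float(v) for v in u),
        true_tilt_deg=tilt,
        true_max_sphere_radius_mm=r_sph,
        true_max_sphere_depth_mm=d_sph,
        true_max_sphere_depth_z_mm=d_sph * float(u[2]),
        true_max_diameter_depth_mm=float(dd[np.argmax(rr)]),
        entry_point_mm=tuple(float(v) for v in entry),
        fragment_centers_mm=[list(map(float, c)) for c in centers],
        fragment_radii_mm=[float(r) for r in radii],
        streak_speck_centers_mm=[list(map(float, s)) for s in specks],
        n_cavity_voxels=n_cavity_voxels,
    )
    return VoxelVolume(vol, sp, origin), truth


def enumerate_design(bullets=None, speeds_per_bullet=None,
                     repetitions: int = 2) -> list[ShotRecord]:
    """Enumerate shot-record stubs for a factorial speed/repetition design.

    Defaults to the four-bullet catalogue with its per-bullet speed lists
    and one repetition of each shot (two shots per configuration, 32
    blocks in total).  Ordering is deterministic: bullet, then speed
    ascending, then repetition index.
    """
    if bullets is None:
        bullets = list(BULLETS)
    if len(bullets) == 0:
        raise ValueError("need at least one bullet")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    stubs = []
    for b in bullets:
        bl = BULLETS[b] if isinstance(b, str) else b
        speeds = (speeds_per_bullet or {}).get(bl.abbreviation, bl.speeds_mps)
        if len(speeds) == 0:
            raise ValueError(f"bullet {bl.abbreviation} has no speeds")
        for v in sorted(speeds):
            for rep in range(repetitions):
                stubs.append(ShotRecord(
                    bullet=bl.abbreviation, caliber_mm=bl.caliber_mm,
                    mass_initial_g=bl.mass_g, speed_in_mps=float(v),
                    repetition=rep))
    return stubs
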