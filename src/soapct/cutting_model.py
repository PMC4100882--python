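"""The legacy cutting method: segment-wise truncated-cone cavity model.

Before volumetric CT, soap-block cavities were quantified by cutting the
block open, photographing it, and clicking sparse (depth, radius) points
along the cavity silhouette.  Between consecutive delineation points the
cavity is modeled as a truncated cone (frustum), so the total volume is a
sum of frustum volumes

    V_seg = (pi * h / 3) * (r1^2 + r1*r2 + r2^2)

and the cross-sectional area at any depth is ``pi * r(d)^2`` with ``r``
linearly interpolated between knots.  Because it assumes circular cross
sections, the method is systematically biased for elliptical cavity
regions; :func:`compare_methods` quantifies its agreement with CT-derived
volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ConeModel", "build_cone_model", "cone_area_profile",
           "read_knots_csv", "compare_methods"]


@dataclass(frozen=True)
class ConeModel:
    """Piecewise truncated-cone cavity model from sparse delineations."""

    depths_mm: np.ndarray
    radii_mm: np.ndarray
    segment_volumes_mm3: np.ndarray

    @property
    def volume_mm3(self) -> float:
        return float(self.segment_volumes_mm3.sum())

    @property
    def volume_ml(self) -> float:
        return self.volume_mm3 / 1000.0

    def radius_at(self, depth_mm):
        """Linearly interpolated radius (mm) at the given depth(s)."""
        return np.interp(depth_mm, self.depths_mm, self.radii_mm)


def build_cone_model(knots) -> ConeModel:
    """Build the frustum model from ordered (depth_mm, radius_mm) knots.

    Depths must be strictly increasing and radii nonnegative; at least two
    knots are required.
    """
    arr = np.asarray(knots, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (depth_mm, radius_mm) knots")
    d, r = arr[:, 0], arr[:, 1]
    if np.any(np.diff(d) <= 0):
        raise ValueError("knot depths must be strictly increasing")
    if np.any(r < 0):
        raise ValueError("radii must be nonnegative")
    h = np.diff(d)
    r1, r2 = r[:-1], r[1:]
    seg = np.pi * h / 3.0 * (r1**2 + r1 * r2 + r2**2)
    return ConeModel(d, r, seg)


def cone_area_profile(model: ConeModel, depth_step_mm: float = 1.0) -> pd.DataFrame:
    """Cross-sectional area (mm²) as a function of penetration depth.

    Samples ``pi * r(d)^2`` every ``depth_step_mm`` from the first to the
    last knot (both included).
    """
    if depth_step_mm <= 0:
        raise ValueError("depth step must be positive")
    d0, d1 = model.depths_mm[0], model.depths_mm[-1]
    depths = np.arange(d0, d1 + 0.5 * depth_step_mm, depth_step_mm)
    areas = np.pi * model.radius_at(depths) ** 2
    return pd.DataFrame({"depth_mm": depths, "area_mm2": areas})


def read_knots_csv(path, diameters: bool = False) -> ConeModel:
    """Read delineation knots from a two-column CSV.

    Expects columns ``depth_mm`` and ``radius_mm`` (or ``diameter_mm``
    with ``diameters=True``, halved on input — photographic delineations
    sometimes record the full cavity width).
    """
    df = pd.read_csv(path)
    if diameters:
        r = df["diameter_mm"].to_numpy() / 2.0
    else:
        r = df["radius_mm"].to_numpy()
    return build_cone_model(np.column_stack([df["depth_mm"].to_numpy(), r]))


def compare_methods(cone_volumes, ct_volumes, test: str = "wilcoxon") -> dict:
    """Agreement between cutting-method and CT cavity volumes.

    Returns the Pearson correlation of the paired volumes, the mean and sd
    of the relative differences ``(cutting - CT) / CT``, and a two-sided
    paired-test p-value (Wilcoxon signed-rank by default, ``test="ttest"``
    for the paired t-test).  A positive mean relative difference indicates
    the systematic overestimation expected of the cutting method.
    """
    cone = np.asarray(cone_volumes, dtype=float)
    ct = np.asarray(ct_volumes, dtype=float)
    if cone.shape != ct.shape:
        raise ValueError("paired volume lists must have equal length")
    if cone.size < 3:
        raise ValueError("need at least 3 paired volumes")
    r, _ = sps.pearsonr(cone, ct)
    rel = (cone - ct) / ct
    diff = cone - ct
    if test == "wilcoxon":
        if np.allclose(diff, 0.0):
            p = 1.0
        else:
            p = float(sps.wilcoxon(cone, ct).pvalue)
    elif test == "ttest":
        res = sps.ttest_rel(cone, ct)
        p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    else:
        raise ValueError(f"unknown paired test {test!r}")
    return {
        "pearson_r": float(r),
        "mean_relative_difference": float(rel.mean()),
        "sd_relative_difference": float(rel.std(ddof=1)),
        "paired_p": p,
        "n": int(cone.size),
    }
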