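"""End-to-end synthetic study: phantom → segmentation → morphometry → stats.

A *study* mirrors the factorial shooting design: a set of bullet types,
four impact speeds each, with repetitions.  For every shot the pipeline

1. derives the deposited energy from the bullet's mass, impact speed and
   a per-bullet exit model,
2. renders a phantom whose cavity volume follows the bullet family's
   generating volume–energy law (linear for the dimensionally stable and
   fragmenting classes, quadratic for the deforming classes) plus
   repetition noise,
3. segments block, cavity and fragments and computes all cavity
   descriptors,
4. simulates the legacy cutting method on the same cavity (sparse knots
   read off the widest silhouette every ~2 cm, truncated-cone model),

and finally runs the statistical layer: through-origin fits with AICc
selection per bullet, ANCOVA on volume and ratio slopes, ANOVA/Tukey on
deflection angle and depth of maximal damage, reproducibility
correlations of repeated shots, and the cutting-vs-CT comparison.

Everything is deterministic given the study seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from soapct import ballistics
from soapct.ballistics import BULLETS, ShotRecord
from soapct.cutting_model import build_cone_model, compare_methods
from soapct.morphometry import compute_cavity_metrics, CavityMetrics
from soapct.phantom import (PhantomSpec, default_cavity_params, generate_phantom,
                            enumerate_design, params_for_volume)
from soapct.segmentation import (FragmentSet, estimate_soap_intensity,
                                 segment_block, segment_cavity,
                                 segment_fragments, apply_streak_exclusion,
                                 SegmentationError)
from soapct.volume_io import VoxelVolume, read_volume

__all__ = ["StudyConfig", "run_study", "analyze_shot", "ShotAnalysisError"]

log = logging.getLogger("soapct")


class ShotAnalysisError(RuntimeError):
    """A pipeline stage failed; carries the shot id and stage name."""

    def __init__(self, shot_id: str, stage: str, cause: Exception):
        super().__init__(f"shot {shot_id}: stage {stage!r} failed: {cause}")
        self.shot_id = shot_id
        self.stage = stage
        self.cause = cause


#: cavity family left behind by each bullet class
DEFAULT_FAMILY_MAP = {
    "ILS": "tumbling_spindle",  # dimensionally stable: tumbles at depth
    "TAG": "early_opening",     # aluminum tip opens the bullet immediately
    "TSX": "tear_shaped",       # deforming: continuous expansion
    "NVU": "tear_shaped",
}

#: generating volume-energy law per bullet (mL over J)
DEFAULT_VOLUME_LAWS = {
    "ILS": {"type": "linear", "c": 0.05},
    "TAG": {"type": "linear", "c": 0.06},
    "TSX": {"type": "quadratic", "a": 0.03, "b": 1.0e-5},
    "NVU": {"type": "quadratic", "a": 0.03, "b": 1.1e-5},
}

#: exiting mass fraction at the bullet's top speed (scales linearly with
#: speed below that) — highest for the dimensionally stable brass bullet,
#: lowest for the lead-core bullet
DEFAULT_EXIT_FRACTIONS = {"ILS": 0.994, "TAG": 0.649, "TSX": 0.736, "NVU": 0.547}

#: mean deflection angle (degrees): the tumbling brass bullet deviates
#: around 6 degrees, the expanding bullets stay near the line of shooting
DEFAULT_TILT_MEAN = {"ILS": 6.0, "TAG": 1.5, "TSX": 1.2, "NVU": 1.2}
DEFAULT_TILT_SD = {"ILS": 0.8, "TAG": 0.5, "TSX": 0.4, "NVU": 0.4}

#: expected fragment count at the bullet's top energy (scaled-down study:
#: the lead-core bullet sheds by far the most fragments, brass none)
DEFAULT_FRAGMENT_RATES = {"ILS": 0.0, "TAG": 5.0, "TSX": 4.0, "NVU": 14.0}

#: fraction of the block long axis traversed by the cavity
DEFAULT_LENGTH_FRACTION = {"ILS": 0.85, "TAG": 0.70, "TSX": 0.72, "NVU": 0.72}


@dataclass
class StudyConfig:
    """Full configuration of a synthetic study run.

    The seed fully determines the run.  Block extents default to a
    laboratory-bench 110 x 110 x 280 mm block at 1 mm isotropic voxels;
    full-size parameters are configurable throughout.
    """

    bullets: tuple = ("ILS", "TAG", "TSX", "NVU")
    repetitions: int = 2
    speeds_per_bullet: dict | None = None
    block_shape_mm: tuple = (110.0, 110.0, 280.0)
    voxel_spacing_mm: tuple = (1.0, 1.0, 1.0)
    family_map: dict = field(default_factory=lambda: dict(DEFAULT_FAMILY_MAP))
    volume_laws: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_VOLUME_LAWS.items()})
    exit_fractions: dict = field(default_factory=lambda: dict(DEFAULT_EXIT_FRACTIONS))
    exit_speed_ratio: float = 0.25
    tilt_mean_deg: dict = field(default_factory=lambda: dict(DEFAULT_TILT_MEAN))
    tilt_sd_deg: dict = field(default_factory=lambda: dict(DEFAULT_TILT_SD))
    fragment_rates: dict = field(default_factory=lambda: dict(DEFAULT_FRAGMENT_RATES))
    length_fraction: dict = field(default_factory=lambda: dict(DEFAULT_LENGTH_FRACTION))
    #: multiplicative repetition noise on the generated cavity volume
    volume_noise_sd: float = 0.05
    noise_sd_hu: float = 5.0
    #: streak-artifact exclusion rule
    small_fragment_max_mm3: float = 8.0
    streak_proximity_mm: float = 5.0
    #: cutting-method simulation: knot spacing and delineation noise
    knot_spacing_mm: float = 20.0
    knot_noise_sd_mm: float = 0.3
    alpha: float = 0.05
    aic_criterion: str = "aicc"
    output_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        for b in self.bullets:
            if b not in BULLETS:
                raise ValueError(f"unknown bullet {b!r}")
            if b not in self.family_map:
                raise ValueError(f"bullet {b!r} has no cavity family")
            if b not in self.volume_laws:
                raise ValueError(f"bullet {b!r} has no volume-energy law")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for key in ("bullets", "block_shape_mm", "voxel_spacing_mm"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _law_volume(law: dict, energy_j: float) -> float:
    if law["type"] == "linear":
        return law["c"] * energy_j
    if law["type"] == "quadratic":
        return law["a"] * energy_j + law["b"] * energy_j**2
    raise ValueError(f"unknown volume law {law['type']!r}")


def analyze_shot(volume, shot_metadata: ShotRecord | None = None,
                 options: dict | None = None
                 ) -> tuple[CavityMetrics, FragmentSet, pd.DataFrame]:
    """Segment one block volume and compute all cavity descriptors.

    ``volume`` may be a :class:`VoxelVolume` or a path to a NIfTI or
    MetaImage file.  ``options`` accepts ``first_slice``/``last_slice``
    (cavity slice range; omitted = fully automatic), ``small_max_mm3``
    and ``proximity_mm`` (streak exclusion), and ``fragment_threshold_hu``.
    Returns the metrics, the fragment set and the cavity area profile;
    the deposited energy from ``shot_metadata`` is attached to the
    returned record.
    """
    opts = dict(options or {})
    shot_id = "?"
    if shot_metadata is not None:
        shot_id = f"{shot_metadata.bullet}@{shot_metadata.speed_in_mps:g}" \
                  f"/rep{shot_metadata.repetition}"
    if not isinstance(volume, VoxelVolume):
        volume = read_volume(volume)

    def stage(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kw)
        except (SegmentationError, ValueError) as exc:
            raise ShotAnalysisError(shot_id, name, exc) from exc
        log.info("shot %s: stage %s done in %.2fs", name and shot_id, name,
                 time.perf_counter() - t0)
        return out

    soap = stage("estimate_soap_intensity", estimate_soap_intensity, volume)
    block = stage("segment_block", segment_block, volume, soap)
    cavity = stage("segment_cavity", segment_cavity, volume, block,
                   opts.get("first_slice"), opts.get("last_slice"),
                   soap_intensity_hu=soap)
    fragments = stage("segment_fragments", segment_fragments, volume,
                      opts.get("fragment_threshold_hu", 2000.0))
    fragments = stage("apply_streak_exclusion", apply_streak_exclusion,
                      fragments, opts.get("small_max_mm3", 8.0),
                      opts.get("proximity_mm", 5.0))
    metrics, profile = stage("morphometry", compute_cavity_metrics, cavity, block)
    if shot_metadata is not None:
        shot_metadata.cavity_volume_ml = metrics.volume_ml
    return metrics, fragments, profile


def _cutting_knots(profile: pd.DataFrame, spacing_mm: float, noise_sd: float,
                   rng) -> np.ndarray:
    """Simulate photographic delineation from a measured area profile.

    One knot per ``spacing_mm`` of depth; the delineator traces the widest
    silhouette, so the radius is read off the maximal area in the window
    around each knot, plus click noise.
    """
    depths = profile["depth_mm"].to_numpy()
    areas = profile["area_mm2"].to_numpy()
    knot_d = np.arange(0.0, depths[-1] + 1e-9, spacing_mm)
    if knot_d[-1] < depths[-1]:
        knot_d = np.append(knot_d, depths[-1])
    radii = []
    for d in knot_d:
        sel = np.abs(depths - d) <= spacing_mm / 2.0
        a = areas[sel].max() if sel.any() else 0.0
        r = np.sqrt(a / np.pi) + rng.normal(0.0, noise_sd)
        radii.append(max(0.0, r))
    return np.column_stack([knot_d, radii])


def _shot_phantom_spec(cfg: StudyConfig, shot: ShotRecord, rng) -> PhantomSpec:
    """Phantom parameters realizing the generating laws for one shot."""
    b = shot.bullet
    family = cfg.family_map[b]
    length = cfg.length_fraction.get(b, 0.72) * cfg.block_shape_mm[2]
    params = default_cavity_params(family, length)
    target_ml = _law_volume(cfg.volume_laws[b], shot.deposited_energy_j)
    target_ml *= float(np.exp(rng.normal(0.0, cfg.volume_noise_sd)))
    params = params_for_volume(family, target_ml, params)
    params["tilt_deg"] = max(0.0, float(
        rng.normal(cfg.tilt_mean_deg.get(b, 1.0), cfg.tilt_sd_deg.get(b, 0.3))))
    top_e = max(ShotRecord(b, BULLETS[b].caliber_mm, BULLETS[b].mass_g,
                           v).deposited_energy_j for v in BULLETS[b].speeds_mps)
    rate = cfg.fragment_rates.get(b, 0.0) * shot.deposited_energy_j / top_e
    n_frag = int(min(20, rng.poisson(rate))) if rate > 0 else 0
    return PhantomSpec(
        cavity_family=family, cavity_params=params,
        block_shape_mm=tuple(cfg.block_shape_mm),
        voxel_spacing_mm=tuple(cfg.voxel_spacing_mm),
        n_fragments=n_frag, streak_artifacts=n_frag > 0,
        noise_sd_hu=cfg.noise_sd_hu,
        seed=int(rng.integers(2**31)))


def _apply_exit_model(cfg: StudyConfig, stub: ShotRecord) -> ShotRecord:
    b = BULLETS[stub.bullet]
    v_top = max(b.speeds_mps)
    frac = cfg.exit_fractions.get(stub.bullet, 0.0) * stub.speed_in_mps / v_top
    return ShotRecord(
        bullet=stub.bullet, caliber_mm=stub.caliber_mm,
        mass_initial_g=stub.mass_initial_g, speed_in_mps=stub.speed_in_mps,
        speed_out_mps=cfg.exit_speed_ratio * stub.speed_in_mps,
        mass_exit_g=frac * stub.mass_initial_g, repetition=stub.repetition)


def run_study(config: StudyConfig) -> dict:
    """Run the full synthetic study and return the study report.

    The report contains one record per shot (energies, measured and true
    cavity descriptors, fragment counts, cutting-method volume) and the
    study-level statistics.  Deterministic given ``config.seed``; if
    ``config.output_dir`` is set, ``report.json``, ``shots.csv`` and
    ``fragments.csv`` are written there.
    """
    config.validate()
    from soapct import stats as st

    stubs = enumerate_design(list(config.bullets), config.speeds_per_bullet,
                             config.repetitions)
    records = []
    cone_vols, ct_vols = [], []
    fragment_rows = []
    for i, stub in enumerate(stubs):
        rng = np.random.default_rng([config.seed, i])
        shot = _apply_exit_model(config, stub)
        shot_id = f"{shot.bullet}@{shot.speed_in_mps:g}/rep{shot.repetition}"
        t0 = time.perf_counter()
        spec = _shot_phantom_spec(config, shot, rng)
        volume, truth = generate_phantom(spec)
        log.info("shot %s: phantom rendered in %.2fs", shot_id,
                 time.perf_counter() - t0)
        metrics, fragments, profile = analyze_shot(
            volume, shot, {"small_max_mm3": config.small_fragment_max_mm3,
                           "proximity_mm": config.streak_proximity_mm})
        knots = _cutting_knots(profile, config.knot_spacing_mm,
                               config.knot_noise_sd_mm, rng)
        cone = build_cone_model(knots)
        cone_vols.append(cone.volume_ml)
        ct_vols.append(metrics.volume_ml)
        records.append({
            "shot_index": i, "bullet": shot.bullet,
            "speed_in_mps": shot.speed_in_mps,
            "speed_out_mps": shot.speed_out_mps,
            "mass_initial_g": shot.mass_initial_g,
            "mass_exit_g": shot.mass_exit_g,
            "repetition": shot.repetition,
            "deposited_energy_j": shot.deposited_energy_j,
            "volume_ml": metrics.volume_ml,
            "ratio_ml_per_j": ballistics.energy_volume_ratio(
                metrics.volume_ml, shot.deposited_energy_j),
            "deflection_deg": metrics.deflection_deg,
            "max_sphere_radius_mm": metrics.max_sphere_radius_mm,
            "max_damage_depth_mm": metrics.max_damage_depth_mm,
            "n_fragments_counted": fragments.n_counted,
            "n_fragments_total": fragments.n_total,
            "cutting_volume_ml": cone.volume_ml,
            "true_volume_ml": truth.true_cavity_volume_ml,
            "true_tilt_deg": truth.true_tilt_deg,
            "true_n_fragments": len(truth.fragment_radii_mm),
        })
        ft = fragments.table.copy()
        ft.insert(0, "shot_index", i)
        ft.insert(1, "bullet", shot.bullet)
        fragment_rows.append(ft)

    df = pd.DataFrame(records)
    report: dict = {
        "design": {"bullets": list(config.bullets),
                   "repetitions": config.repetitions,
                   "n_shots": len(records),
                   "n_configurations": len(records) // config.repetitions},
        "shots": records,
        "stats": {},
    }

    fits = {}
    for b in config.bullets:
        sub = df[df["bullet"] == b]
        x = sub["deposited_energy_j"].to_numpy()
        y = sub["volume_ml"].to_numpy()
        lin = st.fit_through_origin(x, y, 1)
        if x.size < 3:
            fits[b] = {"linear": {"coefficients": lin.coefficients,
                                  "r_squared": lin.r_squared}}
            continue
        quad = st.fit_through_origin(x, y, 2)
        sel = st.aic_select(lin, quad, criterion=config.aic_criterion)
        fits[b] = {
            "linear": {"coefficients": lin.coefficients, "r_squared": lin.r_squared,
                       "aic": lin.aic, "aicc": lin.aicc},
            "quadratic": {"coefficients": quad.coefficients,
                          "r_squared": quad.r_squared, "aic": quad.aic,
                          "aicc": quad.aicc},
            "selection": sel,
        }
    report["stats"]["volume_energy_fits"] = fits

    groups_vol = [(df[df["bullet"] == b]["deposited_energy_j"].to_numpy(),
                   df[df["bullet"] == b]["volume_ml"].to_numpy())
                  for b in config.bullets]
    groups_ratio = [(df[df["bullet"] == b]["deposited_energy_j"].to_numpy(),
                     df[df["bullet"] == b]["ratio_ml_per_j"].to_numpy())
                    for b in config.bullets]
    if len(config.bullets) >= 2:
        F, p = st.ancova_slopes(groups_vol)
        report["stats"]["ancova_volume_slopes"] = {"F": F, "p": p}
        F, p = st.ancova_slopes(groups_ratio)
        report["stats"]["ancova_ratio_slopes"] = {"F": F, "p": p}
        for what in ("deflection_deg", "max_damage_depth_mm"):
            gs = [df[df["bullet"] == b][what].to_numpy() for b in config.bullets]
            F, p, pairs = st.anova_tukey(gs)
            report["stats"][f"anova_{what}"] = {
                "F": F, "p": p,
                "tukey": [
                    {"pair": f"{config.bullets[int(r.group_a)]}-"
                             f"{config.bullets[int(r.group_b)]}",
                     "mean_diff": r.mean_diff, "p_adj": r.p_adj}
                    for r in pairs.itertuples()],
            }

    if config.repetitions >= 2:
        first = df[df["repetition"] == 0].sort_values("shot_index")
        second = df[df["repetition"] == 1].sort_values("shot_index")
        rep = st.reproducibility_correlation(
            first["volume_ml"].to_numpy(), second["volume_ml"].to_numpy(),
            groups=first["bullet"].to_numpy())
        cut_rep = st.reproducibility_correlation(
            first["cutting_volume_ml"].to_numpy(),
            second["cutting_volume_ml"].to_numpy())
        report["stats"]["reproducibility_ct"] = rep
        report["stats"]["reproducibility_cutting"] = cut_rep
    else:
        log.warning("repetitions = 1: reproducibility section omitted")

    report["stats"]["cutting_vs_ct"] = compare_methods(cone_vols, ct_vols)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        df.to_csv(out / "shots.csv", index=False)
        nonempty = [f for f in fragment_rows if len(f)]
        if nonempty:
            pd.concat(nonempty, ignore_index=True).to_csv(
                out / "fragments.csv", index=False)
    return report
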