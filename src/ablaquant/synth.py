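"""Seeded synthetic-data generators with ground-truth sidecars.

Every pipeline stage can be exercised without external data: DAB-stained
vessel scenes on a hematoxylin background (Beer-Lambert forward model),
CD31/LYVE-1/DAPI lymph-node fields with known vessel classes, exponential
tumor-growth cohorts with an instantaneous ablation fraction at treatment,
log-linear qPCR dilution series, 4PL ELISA plates, and live/dead
constructs derived from a solved electric field.  Generators are pure
functions of (spec, seed): identical specs give byte-identical outputs, and
each truth sidecar suffices to predict every downstream metric.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ihc
from .errors import ParameterError

__all__ = [
    "IHCSceneSpec",
    "LymphNodeSpec",
    "GrowthCohortSpec",
    "AssaySpec",
    "LiveDeadSpec",
    "gen_ihc_scene",
    "gen_if_lymphnode",
    "gen_growth_cohort",
    "gen_assay_fixtures",
    "gen_livedead",
    "write_manifest",
]


def _spec_hash(spec) -> str:
    payload = json.dumps(dataclasses.asdict(spec), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(outdir, spec, truth_paths: dict) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": spec.seed, "spec_hash": _spec_hash(spec),
                "spec": dataclasses.asdict(spec), "truth": truth_paths}
    path = outdir / "MANIFEST.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


# --------------------------------------------------------------------------
# chromogenic IHC scene
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IHCSceneSpec:
    """Brightfield H-DAB scene: elliptical vessel annuli on hematoxylin.

    Vessel outer areas are log-normal (median ~80 um^2 cross-sections);
    ``photon_budget`` sets Poisson shot noise (None disables noise
    entirely, making the Beer-Lambert forward model exactly invertible).
    """

    seed: int = 0
    shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.65
    n_vessels: int = 30
    vessel_area_um2_median: float = 80.0
    vessel_area_sigma_log: float = 0.5
    dab_od: float = 0.9
    hematoxylin_od: float = 0.35
    ring_fraction: float = 0.45  # lumen radius / outer radius
    min_separation_px: float = 4.0
    photon_budget: float | None = None
    read_noise: float = 2.0
    white_level: int = 255


@dataclass
class IHCScene:
    rgb: np.ndarray                  # uint8 (H, W, 3)
    rgb_float: np.ndarray            # pre-quantization intensities (exact
                                     # Beer-Lambert forward model)
    dab_concentration: np.ndarray    # the generating DAB OD map
    truth: pd.DataFrame
    spec: IHCSceneSpec

    def write(self, outdir) -> None:
        import tifffile
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(outdir / "scene.tif", self.rgb)
        self.truth.to_csv(outdir / "truth.csv", index=False)
        write_manifest(outdir, self.spec, {"truth": "truth.csv",
                                           "image": "scene.tif"})


def _place_centers(rng, shape, n, radii_px, min_sep_px, margin_extra=0.0,
                   max_tries=20000):
    """Rejection-sample disk centers with pairwise clearance."""
    centers = []
    tries = 0
    i = 0
    while len(centers) < n and tries < max_tries:
        tries += 1
        r = radii_px[len(centers)]
        margin = r + margin_extra + 1
        cy = rng.uniform(margin, shape[0] - margin)
        cx = rng.uniform(margin, shape[1] - margin)
        ok = all(np.hypot(cy - y, cx - x) >= r + radii_px[j] + min_sep_px
                 for j, (y, x) in enumerate(centers))
        if ok:
            centers.append((cy, cx))
            i += 1
    if len(centers) < n:
        raise ParameterError(
            f"could not place {n} non-overlapping vessels; lower n_vessels "
            f"or enlarge the scene")
    return centers


def gen_ihc_scene(spec: IHCSceneSpec = IHCSceneSpec()) -> IHCScene:
    """Render the scene and return image plus per-vessel ground truth."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    px = spec.pixel_size_um
    areas_um2 = spec.vessel_area_um2_median * np.exp(
        rng.normal(0.0, spec.vessel_area_sigma_log, spec.n_vessels))
    # outer radius of the annulus from the *outer* ellipse area
    radii_px = np.sqrt(areas_um2 / np.pi) / px
    elong = rng.uniform(0.7, 1.0, spec.n_vessels)  # minor/major axis ratio
    centers = _place_centers(rng, spec.shape, spec.n_vessels,
                             radii_px / np.sqrt(elong), spec.min_separation_px)

    yy, xx = np.mgrid[0:h, 0:w]
    dab = np.zeros((h, w))
    rows = []
    for i, ((cy, cx), r, q, a_um2) in enumerate(
            zip(centers, radii_px, elong, areas_um2)):
        major = r / np.sqrt(q)
        minor = r * np.sqrt(q)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = ((xx - cx) * ct + (yy - cy) * st) / major
        v = (-(xx - cx) * st + (yy - cy) * ct) / minor
        rho2 = u * u + v * v
        ring = (rho2 <= 1.0) & (rho2 >= spec.ring_fraction ** 2)
        dab[ring] = spec.dab_od
        rows.append({"id": i, "cx_px": cx, "cy_px": cy,
                     "outer_area_um2": a_um2,
                     "outer_area_px": float(np.count_nonzero(rho2 <= 1.0)),
                     "ring_area_px": float(np.count_nonzero(ring))})
    truth = pd.DataFrame(rows)

    hema = np.full((h, w), spec.hematoxylin_od)
    od = (hema[..., None] * ihc.HDAB_VECTORS.matrix[0]
          + dab[..., None] * ihc.HDAB_VECTORS.matrix[1])
    clean = spec.white_level * 10.0 ** (-od)
    intensity = clean
    if spec.photon_budget is not None:
        scale = spec.photon_budget / spec.white_level
        intensity = rng.poisson(clean * scale) / scale
        intensity = intensity + rng.normal(0, spec.read_noise, intensity.shape)
    rgb = np.clip(np.round(intensity), 0, spec.white_level).astype(np.uint8)
    return IHCScene(rgb, clean, dab, truth, spec)


# --------------------------------------------------------------------------
# immunofluorescent lymph node
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LymphNodeSpec:
    """CD31/LYVE-1/DAPI field with known lymphatic/blood vessel classes."""

    seed: int = 0
    shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.65
    n_lymphatic: int = 8
    n_blood: int = 12
    n_debris: int = 6
    vessel_radius_um: tuple[float, float] = (4.0, 12.0)
    debris_area_um2: tuple[float, float] = (2.0, 12.0)
    cd31_level: float = 180.0
    lyve1_level: float = 160.0
    background: float = 20.0
    noise_sd: float = 4.0
    node_margin_px: int = 10


@dataclass
class LymphNodeScene:
    channels: dict                  # {"cd31": .., "lyve1": .., "dapi": ..}
    node_polygon_um: tuple
    artifact_polygons_um: tuple
    truth: pd.DataFrame
    spec: LymphNodeSpec

    def write(self, outdir) -> None:
        import tifffile
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stack = np.stack([self.channels[k] for k in ("cd31", "lyve1", "dapi")])
        tifffile.imwrite(outdir / "lymphnode.tif",
                         stack.astype(np.float32))
        self.truth.to_csv(outdir / "truth.csv", index=False)
        ann = {"node_polygon_um": self.node_polygon_um,
               "artifact_polygons_um": self.artifact_polygons_um}
        (outdir / "annotations.json").write_text(json.dumps(ann))
        write_manifest(outdir, self.spec,
                       {"truth": "truth.csv", "image": "lymphnode.tif",
                        "annotations": "annotations.json"})


def gen_if_lymphnode(spec: LymphNodeSpec = LymphNodeSpec()) -> LymphNodeScene:
    """Render vessel disks inside a polygonal node annotation.

    Lymphatic vessels are CD31+LYVE-1+, blood vessels CD31+LYVE-1-; debris
    blobs fall below the 15 um^2 area filter.  Truth rows carry class,
    analytic area (pi r^2) and perimeter (2 pi r) per object.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    px = spec.pixel_size_um

    n_total = spec.n_lymphatic + spec.n_blood + spec.n_debris
    r_lo, r_hi = spec.vessel_radius_um
    radii_um = np.concatenate([
        rng.uniform(r_lo, r_hi, spec.n_lymphatic + spec.n_blood),
        np.sqrt(rng.uniform(*spec.debris_area_um2, spec.n_debris) / np.pi)])
    radii_px = radii_um / px
    centers = _place_centers(rng, spec.shape, n_total, radii_px,
                             min_sep_px=6.0,
                             margin_extra=spec.node_margin_px + 4)

    yy, xx = np.mgrid[0:h, 0:w]
    cd31 = np.zeros((h, w))
    lyve1 = np.zeros((h, w))
    rows = []
    classes = (["lymphatic"] * spec.n_lymphatic + ["blood"] * spec.n_blood
               + ["debris"] * spec.n_debris)
    for i, ((cy, cx), r_px, r_um, cls) in enumerate(
            zip(centers, radii_px, radii_um, classes)):
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px ** 2
        cd31[disk] = spec.cd31_level
        if cls == "lymphatic":
            lyve1[disk] = spec.lyve1_level
        rows.append({"id": i, "class": cls, "cx_px": cx, "cy_px": cy,
                     "radius_um": r_um, "area_um2": np.pi * r_um ** 2,
                     "perimeter_um": 2 * np.pi * r_um})
    truth = pd.DataFrame(rows)

    cd31 += spec.background + rng.normal(0, spec.noise_sd, (h, w))
    lyve1 += spec.background + rng.normal(0, spec.noise_sd, (h, w))
    dapi = spec.background + rng.normal(0, spec.noise_sd, (h, w))
    cd31 = np.clip(cd31, 0, None)
    lyve1 = np.clip(lyve1, 0, None)
    dapi = np.clip(dapi, 0, None)

    m = spec.node_margin_px * px
    node = ((m, m), ((w - spec.node_margin_px) * px, m),
            ((w - spec.node_margin_px) * px, (h - spec.node_margin_px) * px),
            (m, (h - spec.node_margin_px) * px))
    return LymphNodeScene({"cd31": cd31, "lyve1": lyve1, "dapi": dapi},
                          node, (), truth, spec)


# --------------------------------------------------------------------------
# tumor growth cohort
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthCohortSpec:
    """Exponential growth with lognormal rate/measurement noise.

    Defaults mirror the study conditions: ~7 animals per arm, baseline
    volume 142 mm^3 at the day-0 treatment, control growth of 135% on day 1
    (rate ln 2.35 per day), and an instantaneous 23.32% ablation fraction
    applied to the treated arm at treatment.
    """

    seed: int = 0
    n_per_group: int = 7
    days: tuple[int, ...] = (0, 1, 2, 3)
    treatment_day: int = 0
    baseline_mm3: float = 142.0
    growth_per_day_percent: float = 135.0
    ablation_fraction: float = 0.2332
    rate_sigma_log: float = 0.1
    measurement_sigma_log: float = 0.1
    baseline_sigma_log: float = 0.15


def gen_growth_cohort(spec: GrowthCohortSpec = GrowthCohortSpec()
                      ) -> pd.DataFrame:
    """Tidy growth table (animal, group, day, volume_mm3, treatment_day)."""
    rng = np.random.default_rng(spec.seed)
    base_rate = np.log(1.0 + spec.growth_per_day_percent / 100.0)
    rows = []
    for group in ("control", "treated"):
        for i in range(spec.n_per_group):
            v0 = spec.baseline_mm3 * np.exp(
                rng.normal(0, spec.baseline_sigma_log))
            rate = base_rate * np.exp(rng.normal(0, spec.rate_sigma_log))
            for day in spec.days:
                v = v0 * np.exp(rate * (day - spec.treatment_day))
                # baseline is measured just before pulsing on the treatment
                # day; ablation affects strictly later measurements
                if group == "treated" and day > spec.treatment_day:
                    v *= 1.0 - spec.ablation_fraction
                if spec.measurement_sigma_log > 0:
                    v *= np.exp(rng.normal(0, spec.measurement_sigma_log))
                rows.append({"animal": f"{group[0]}{i:02d}", "group": group,
                             "day": day, "volume_mm3": v,
                             "treatment_day": spec.treatment_day})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# assay fixtures
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AssaySpec:
    """qPCR and ELISA plate fixtures with known generating parameters."""

    seed: int = 0
    standard_concentrations: tuple[float, ...] = (
        2000.0, 1000.0, 500.0, 250.0, 125.0, 61.25, 31.125)
    efficiency: float = 1.0
    intercept_cq: float = 35.0
    cq_noise_sd: float = 0.2
    sample_quantities: tuple[float, ...] = (800.0, 200.0, 50.0)
    elisa_params: tuple[float, float, float, float] = (0.05, 1.3, 150.0, 2.4)
    elisa_standards: tuple[float, ...] = (1000.0, 500.0, 250.0, 125.0,
                                          62.5, 31.25, 15.625, 7.8125)
    elisa_noise_sd: float = 0.0
    elisa_sample_pg_ml: tuple[float, ...] = (400.0, 120.0)
    eluate_volume_ml: float = 0.2
    tissue_mass_mg: tuple[float, ...] = (8.0, 12.0)


def gen_assay_fixtures(spec: AssaySpec = AssaySpec()):
    """Return ``(qpcr_df, elisa_df, truth)`` fixtures.

    qPCR responses follow Cq = intercept + slope log10(conc) with
    slope = -1/log10(1 + efficiency); ELISA absorbances follow the 4PL with
    the given (a, b, c, d).  Truth carries the generating parameters.
    """
    rng = np.random.default_rng(spec.seed)
    slope = -1.0 / np.log10(1.0 + spec.efficiency)

    def cq_of(conc):
        return spec.intercept_cq + slope * np.log10(conc) + (
            rng.normal(0, spec.cq_noise_sd) if spec.cq_noise_sd > 0 else 0.0)

    rows = []
    well = 0
    for conc in spec.standard_concentrations:
        rows.append({"plate": 1, "well": f"S{well}", "target": "standard",
                     "sample": f"std_{conc:g}", "cq": cq_of(conc),
                     "concentration": conc, "role": "standard"})
        well += 1
    for i, q in enumerate(spec.sample_quantities):
        rows.append({"plate": 1, "well": f"U{i}", "target": "target_gene",
                     "sample": f"sample_{i}", "cq": cq_of(q),
                     "concentration": np.nan, "role": "sample"})
    qpcr = pd.DataFrame(rows)

    a, b, c, d = spec.elisa_params

    def absorb(x):
        y = d + (a - d) / (1.0 + (x / c) ** b)
        if spec.elisa_noise_sd > 0:
            y += rng.normal(0, spec.elisa_noise_sd)
        return y

    rows = []
    for i, conc in enumerate(spec.elisa_standards):
        rows.append({"plate": 1, "well": f"S{i}", "sample": f"std_{conc:g}",
                     "absorbance": absorb(conc), "concentration": conc,
                     "eluate_volume_ml": np.nan, "tissue_mass_mg": np.nan,
                     "role": "standard"})
    for i, conc in enumerate(spec.elisa_sample_pg_ml):
        rows.append({"plate": 1, "well": f"U{i}", "sample": f"sample_{i}",
                     "absorbance": absorb(conc), "concentration": np.nan,
                     "eluate_volume_ml": spec.eluate_volume_ml,
                     "tissue_mass_mg": spec.tissue_mass_mg[
                         i % len(spec.tissue_mass_mg)],
                     "role": "sample"})
    elisa = pd.DataFrame(rows)
    truth = {"slope": float(slope), "intercept": spec.intercept_cq,
             "sample_quantities": spec.sample_quantities,
             "elisa_params": spec.elisa_params,
             "elisa_sample_pg_ml": spec.elisa_sample_pg_ml}
    return qpcr, elisa, truth


# --------------------------------------------------------------------------
# live/dead construct from a field solution
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LiveDeadSpec:
    seed: int = 0
    live_level: float = 200.0
    dead_level: float = 220.0
    background: float = 10.0
    noise_sd: float = 0.0
    edge_blur_px: float = 0.0


@dataclass
class LiveDeadScene:
    live: np.ndarray
    dead: np.ndarray
    pixel_size_um: float
    truth: dict
    spec: LiveDeadSpec

    def write(self, outdir) -> None:
        import tifffile
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(outdir / "livedead.tif",
                         np.stack([self.live, self.dead]).astype(np.float32))
        (outdir / "truth.json").write_text(json.dumps(self.truth))
        write_manifest(outdir, self.spec, {"truth": "truth.json",
                                           "image": "livedead.tif"})


def gen_livedead(field_solution, lethal_threshold_v_per_cm: float,
                 spec: LiveDeadSpec = LiveDeadSpec()) -> LiveDeadScene:
    """Two-channel live/dead image from a solved field.

    The dead (propidium-iodide-like) channel is positive where
    ``|E| >= threshold`` on the solved plane (midplane of a 3-D solve), the
    live (calcein-like) channel elsewhere; truth stores the generating
    threshold and the exact grid area of the dead region.
    """
    from scipy import ndimage

    rng = np.random.default_rng(spec.seed)
    e = field_solution.e_magnitude_v_per_cm
    if e.ndim == 3:
        e = e[:, :, e.shape[2] // 2]
    dead_mask = e >= lethal_threshold_v_per_cm
    h_mm = field_solution.grid_step_mm
    area_mm2 = float(dead_mask.sum()) * h_mm ** 2
    dead = np.where(dead_mask, spec.dead_level, 0.0) + spec.background
    live = np.where(dead_mask, 0.0, spec.live_level) + spec.background
    if spec.edge_blur_px > 0:
        dead = ndimage.gaussian_filter(dead, spec.edge_blur_px)
        live = ndimage.gaussian_filter(live, spec.edge_blur_px)
    if spec.noise_sd > 0:
        dead = dead + rng.normal(0, spec.noise_sd, dead.shape)
        live = live + rng.normal(0, spec.noise_sd, live.shape)
    truth = {"lethal_threshold_v_per_cm": lethal_threshold_v_per_cm,
             "dead_area_mm2": area_mm2,
             "pixel_size_um": h_mm * 1000.0}
    return LiveDeadScene(np.clip(live, 0, None), np.clip(dead, 0, None),
                         h_mm * 1000.0, truth, spec)
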