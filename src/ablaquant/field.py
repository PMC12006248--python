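"""Quasi-static electric-field model for paired needle electrodes.

Irreversible-electroporation treatment planning reduces, at nominal pulse
amplitude, to the Laplace conduction problem ``div(sigma grad phi) = 0`` with
Dirichlet potentials ``+V/2`` and ``-V/2`` on the two electrode surfaces and a
zero-flux outer boundary.  Cells exposed to a field magnitude at or above the
lethal threshold ``E_th`` (measured in vitro, e.g. 1077 V/cm for 4T1 cells in
collagen hydrogels under a 2-5-2-5 bipolar burst) are counted as ablated.

The solver is a finite-difference scheme on a regular grid: face-centered
conductivities (harmonic mean), matrix-free preconditioned conjugate
gradients, and a cascadic coarse-to-fine initial guess.  Because the problem
is linear in the applied voltage, a single solve yields the whole
coverage-versus-voltage curve by rescaling ``|E|``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml

from .errors import InvalidGeometryError, InvalidRegionError, OutOfRangeError, \
    InconsistentWaveformError, SolverError

__all__ = [
    "ElectrodePair",
    "Region",
    "TissueDomain",
    "FieldSolution",
    "AblationPrediction",
    "BurstSchedule",
    "voltage_to_distance_ratio",
    "solve_field",
    "ablation_metrics",
    "extruded_ablation_metrics",
    "coverage_curve",
    "invert_threshold",
    "burst_schedule",
    "two_needle_tumor_domain",
    "sphere_radius_for_volume",
    "load_domain_config",
    "save_field",
    "load_field",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodePair:
    """Two monopolar needle electrodes driven at ``+V/2`` and ``-V/2``.

    Defaults follow a typical small-animal configuration: 0.4 mm diameter
    acupuncture needles, 4 mm center-to-center spacing, 4 mm exposed
    (conductive) length.  The pair is placed symmetrically about the origin
    along the x axis; the needle shafts run along z with the exposed segment
    centered on the xy midplane.
    """

    spacing_mm: float = 4.0
    diameter_mm: float = 0.4
    exposure_mm: float = 4.0
    applied_voltage_v: float = 600.0

    def __post_init__(self):
        if not (self.spacing_mm > self.diameter_mm > 0):
            raise InvalidGeometryError(
                f"require spacing > diameter > 0, got spacing={self.spacing_mm}, "
                f"diameter={self.diameter_mm}")
        if self.exposure_mm <= 0:
            raise InvalidGeometryError("electrode exposure must be positive")
        if self.applied_voltage_v < 0:
            raise InvalidGeometryError("applied voltage must be non-negative")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    @property
    def centers_mm(self) -> tuple[tuple[float, float], tuple[float, float]]:
        s = self.spacing_mm / 2.0
        return ((-s, 0.0), (s, 0.0))


@dataclass(frozen=True)
class Region:
    """A labeled conductivity region: full domain, sphere, slab or cylinder.

    ``axis`` selects the slab normal / cylinder axis (0=x, 1=y, 2=z);
    ``span_mm`` is the (lo, hi) extent along that axis for slabs/cylinders.
    """

    shape: str  # "full" | "sphere" | "slab" | "cylinder"
    conductivity_s_per_m: float
    label: str
    center_mm: tuple[float, ...] = (0.0, 0.0, 0.0)
    radius_mm: float | None = None
    axis: int = 2
    span_mm: tuple[float, float] | None = None

    def __post_init__(self):
        if self.conductivity_s_per_m <= 0:
            raise InvalidGeometryError("conductivity must be positive")
        if self.shape not in ("full", "sphere", "slab", "cylinder"):
            raise InvalidGeometryError(f"unknown region shape {self.shape!r}")
        if self.shape in ("sphere", "cylinder") and not self.radius_mm:
            raise InvalidGeometryError(f"{self.shape} region requires radius_mm")
        if self.shape == "slab" and self.span_mm is None:
            raise InvalidGeometryError("slab region requires span_mm")


@dataclass(frozen=True)
class TissueDomain:
    """Regular-grid solve domain.

    ``bounds_mm`` is ``((xmin, xmax), (ymin, ymax)[, (zmin, zmax)])``; regions
    are painted in order (later entries override earlier ones), so a
    homogeneous background is a single ``full`` region and a layered model
    stacks slabs/spheres on top of it.
    """

    bounds_mm: tuple[tuple[float, float], ...]
    regions: tuple[Region, ...]
    grid_step_mm: float
    dimensionality: int = 3

    def __post_init__(self):
        if self.dimensionality not in (2, 3):
            raise InvalidGeometryError("dimensionality must be 2 or 3")
        if len(self.bounds_mm) != self.dimensionality:
            raise InvalidGeometryError("bounds must match dimensionality")
        if self.grid_step_mm <= 0:
            raise InvalidGeometryError("grid step must be positive")
        for lo, hi in self.bounds_mm:
            if hi <= lo:
                raise InvalidGeometryError("degenerate bounding box")
        if not self.regions:
            raise InvalidGeometryError("at least one conductivity region required")

    def axes(self) -> tuple[np.ndarray, ...]:
        out = []
        for lo, hi in self.bounds_mm:
            n = int(round((hi - lo) / self.grid_step_mm)) + 1
            out.append(np.linspace(lo, lo + (n - 1) * self.grid_step_mm, n))
        return tuple(out)

    def validate_against(self, electrodes: ElectrodePair) -> None:
        """Geometry invariants tying the grid to the electrode pair."""
        if self.grid_step_mm > electrodes.diameter_mm / 2 + 1e-12:
            raise InvalidGeometryError(
                "grid step must be <= electrode diameter / 2 so the conductor "
                "is resolved by at least two cells across its radius")
        for lo, hi in self.bounds_mm:
            if lo > -3 * electrodes.spacing_mm + 1e-9 or hi < 3 * electrodes.spacing_mm - 1e-9:
                raise InvalidGeometryError(
                    "bounding box must extend >= 3x electrode spacing beyond "
                    "the electrode midpoint in every axis")


@dataclass
class FieldSolution:
    """Converged potential and field magnitude on the solve grid."""

    potential_v: np.ndarray
    e_magnitude_v_per_cm: np.ndarray
    grid_step_mm: float
    axes_mm: tuple[np.ndarray, ...]
    residual: float
    iterations: int
    domain: TissueDomain
    electrodes: ElectrodePair

    @property
    def dimensionality(self) -> int:
        return self.potential_v.ndim


@dataclass(frozen=True)
class AblationPrediction:
    """Coverage of a region by field at or above the lethal threshold."""

    lethal_threshold_v_per_cm: float
    ablated_measure: float   # mm^3 in 3-D, mm^2 in 2-D
    region_measure: float
    coverage_percent: float


@dataclass(frozen=True)
class BurstSchedule:
    cycles_per_burst: int
    energized_per_burst_us: float
    total_energized_us: float
    total_duration_s: float
    n_bursts: int


# --------------------------------------------------------------------------
# simple arithmetic operations
# --------------------------------------------------------------------------

def voltage_to_distance_ratio(voltage_v: float, spacing_mm: float) -> float:
    """Nominal field strength in V/cm: applied voltage over electrode spacing.

    600 V across 4 mm is the canonical 1500 V/cm setting.
    """
    if spacing_mm <= 0:
        raise InvalidGeometryError("electrode spacing must be positive")
    return voltage_v / (spacing_mm / 10.0)


def burst_schedule(waveform_us: Sequence[float] = (2.0, 5.0, 2.0, 5.0),
                   energized_per_burst_us: float = 100.0,
                   n_bursts: int = 200,
                   rate_hz: float = 1.0) -> BurstSchedule:
    """Burst arithmetic for a bipolar pulsing scheme.

    ``waveform_us`` is (positive width, inter-phase delay, negative width,
    inter-pulse delay); only the two pulse widths count as energized time.
    The canonical 2-5-2-5 scheme at 100 us/burst gives 25 cycles per burst.
    """
    if len(waveform_us) != 4:
        raise InconsistentWaveformError("waveform must be (w+, d1, w-, d2)")
    w_pos, d1, w_neg, d2 = (float(v) for v in waveform_us)
    if w_pos <= 0 or w_neg <= 0:
        raise InconsistentWaveformError("pulse widths must be positive")
    if d1 < 0 or d2 < 0:
        raise InconsistentWaveformError("delays must be non-negative")
    if energized_per_burst_us <= 0 or n_bursts <= 0 or rate_hz <= 0:
        raise InconsistentWaveformError("schedule parameters must be positive")
    cycles = energized_per_burst_us / (w_pos + w_neg)
    if abs(cycles - round(cycles)) > 1e-9:
        raise InconsistentWaveformError(
            f"energized time {energized_per_burst_us} us is not an integer "
            f"number of {w_pos}+{w_neg} us cycles")
    cycles = int(round(cycles))
    total_energized = n_bursts * energized_per_burst_us
    # bursts fire at the given repetition rate; the last burst's own width
    # (~cycles * full cycle time) is negligible next to the 1/rate spacing
    total_duration_s = n_bursts / rate_hz
    return BurstSchedule(cycles, energized_per_burst_us, total_energized,
                         total_duration_s, n_bursts)


def sphere_radius_for_volume(volume_mm3: float) -> float:
    """Radius of a sphere of the given volume (mm)."""
    return (3.0 * volume_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


# --------------------------------------------------------------------------
# finite-difference solver
# --------------------------------------------------------------------------

def _region_mask(region: Region, axes: tuple[np.ndarray, ...]) -> np.ndarray:
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    nd = len(axes)
    if region.shape == "full":
        return np.ones(tuple(len(a) for a in axes), dtype=bool)
    if region.shape == "sphere":
        c = region.center_mm
        r2 = sum((grids[i] - c[i]) ** 2 for i in range(nd))
        return r2 <= region.radius_mm ** 2
    if region.shape == "slab":
        lo, hi = region.span_mm
        ax = grids[region.axis]
        return np.broadcast_to((ax >= lo) & (ax <= hi),
                               tuple(len(a) for a in axes)).copy()
    if region.shape == "cylinder":
        c = region.center_mm
        others = [i for i in range(nd) if i != region.axis]
        r2 = sum((grids[i] - c[i]) ** 2 for i in others)
        mask = r2 <= region.radius_mm ** 2
        if region.span_mm is not None:
            lo, hi = region.span_mm
            mask = mask & (grids[region.axis] >= lo) & (grids[region.axis] <= hi)
        return np.broadcast_to(mask, tuple(len(a) for a in axes)).copy()
    raise InvalidRegionError(f"unknown region shape {region.shape!r}")


def _conductivity_map(domain: TissueDomain, axes) -> np.ndarray:
    sigma = np.zeros(tuple(len(a) for a in axes))
    for region in domain.regions:
        sigma[_region_mask(region, axes)] = region.conductivity_s_per_m
    if np.any(sigma <= 0):
        raise InvalidGeometryError("regions do not cover the bounding box")
    return sigma


def _electrode_masks(electrodes: ElectrodePair, axes, dim: int):
    """Rasterize each conductor as the set of nodes inside its radius.

    The first mask is the electrode at negative x (driven at ``-V/2``), the
    second at positive x (``+V/2``).
    """
    shape = tuple(len(a) for a in axes)
    masks = []
    for cx, cy in electrodes.centers_mm:
        x = axes[0][:, None]
        y = axes[1][None, :]
        inplane = (x - cx) ** 2 + (y - cy) ** 2 <= electrodes.radius_mm ** 2
        if not inplane.any():
            ix = int(np.argmin(np.abs(axes[0] - cx)))
            iy = int(np.argmin(np.abs(axes[1] - cy)))
            inplane = np.zeros(shape[:2], dtype=bool)
            inplane[ix, iy] = True
        if dim == 2:
            masks.append(inplane)
        else:
            half = electrodes.exposure_mm / 2.0
            inz = np.abs(axes[2]) <= half + 1e-12
            masks.append(inplane[:, :, None] & inz[None, None, :])
    if (masks[0] & masks[1]).any():
        raise InvalidGeometryError("electrode rasterizations overlap")
    return masks


_MIN_CUT_FRACTION = 0.1  # clamp for cut-cell fractions, keeps the diagonal bounded


def _cut_cell_weights(weights, fixed, electrodes: ElectrodePair, axes, dim: int):
    """Shortley-Weller boundary correction for faces crossing a conductor.

    Plain node rasterization imposes the Dirichlet value at node centers,
    which inflates the effective conductor radius by O(grid step) and biases
    the whole field low by several percent.  Scaling the weight of each face
    that crosses the true conductor surface by 1/theta — theta being the
    fractional distance from the outside node to the surface — restores
    second-order accuracy.  Only free-to-fixed links are modified, so the
    free-node system stays symmetric positive definite.
    """
    h = float(axes[0][1] - axes[0][0])
    a = electrodes.radius_mm
    nd = len(axes)
    if weights is None:
        weights = tuple(np.ones(_face_shape(tuple(len(ax) for ax in axes), k))
                        for k in range(nd))

    def surface_theta(node_coords, axis):
        """Distance fraction from an outside node to the nearest conductor
        surface along +/- axis; inf if the ray misses the conductor."""
        best = np.full(node_coords[0].shape, np.inf)
        for cx, cy in electrodes.centers_mm:
            if axis < 2:
                cc = (cx, cy)[axis]
                oc = (cx, cy)[1 - axis]
                other = node_coords[1 - axis]
                disc = a * a - (other - oc) ** 2
                with np.errstate(invalid="ignore"):
                    root = np.sqrt(disc)
                lo, hi = cc - root, cc + root
            else:
                lo = np.full(node_coords[0].shape, -electrodes.exposure_mm / 2)
                hi = -lo
            here = node_coords[axis]
            d = np.minimum(np.abs(here - lo), np.abs(here - hi))
            best = np.where(np.isnan(d), best, np.minimum(best, d))
        return best / h

    for axis in range(nd):
        lo_sl = tuple(slice(0, -1) if k == axis else slice(None) for k in range(nd))
        hi_sl = tuple(slice(1, None) if k == axis else slice(None) for k in range(nd))
        f_lo, f_hi = fixed[lo_sl], fixed[hi_sl]
        cut = f_lo ^ f_hi
        if not cut.any():
            continue
        idx = np.nonzero(cut)
        # outside-node index along this axis for each cut face
        out_idx = [i.copy() for i in idx]
        out_idx[axis] = out_idx[axis] + np.where(f_lo[idx], 1, 0)
        coords = [np.asarray(axes[k])[out_idx[k]] for k in range(nd)]
        theta = surface_theta(coords, axis)
        theta = np.clip(np.where(np.isfinite(theta), theta, 1.0),
                        _MIN_CUT_FRACTION, 1.0)
        w = weights[axis]
        w[idx] = w[idx] / theta
    return weights


def _face_shape(shape, axis):
    s = list(shape)
    s[axis] -= 1
    return tuple(s)


def _laplacian_apply(phi: np.ndarray, weights, out: np.ndarray) -> None:
    """out = div(w grad phi) with zero-flux outer boundary.

    ``weights`` is None for a homogeneous medium (unit face weights) or a
    tuple of face-weight arrays, one per axis.
    """
    out.fill(0.0)
    nd = phi.ndim
    for ax in range(nd):
        d = np.diff(phi, axis=ax)
        if weights is not None:
            d = d * weights[ax]
        lo = [slice(None)] * nd
        hi = [slice(None)] * nd
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        out[tuple(lo)] += d
        out[tuple(hi)] -= d


def _face_weights(sigma: np.ndarray):
    """Harmonic-mean face conductivities; None if the medium is uniform."""
    if np.allclose(sigma, sigma.flat[0]):
        return None
    weights = []
    nd = sigma.ndim
    for ax in range(nd):
        lo = [slice(None)] * nd
        hi = [slice(None)] * nd
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        a, b = sigma[tuple(lo)], sigma[tuple(hi)]
        w = 2.0 * a * b / (a + b)
        weights.append(w / sigma.flat[0])  # scale for conditioning only
    return tuple(weights)


def _dct_preconditioner(shape, scale: float):
    """Exact inverse of the constant-coefficient zero-flux Laplacian.

    The node-centered stencil with mirrored boundary conditions is
    diagonalized by the type-II discrete cosine transform, with 1-D
    eigenvalues ``2 cos(pi k / n) - 2``.  Applying its (pseudo-)inverse as a
    preconditioner leaves only the electrode Dirichlet constraints for
    conjugate gradients to resolve, which takes tens of iterations
    independent of grid size.  The singular constant mode is regularized to
    the smallest nonzero eigenvalue.
    """
    from scipy import fft as sfft

    eigs = [2.0 * np.cos(np.pi * np.arange(n) / n) - 2.0 for n in shape]
    lam = -sum(e.reshape([-1 if i == k else 1 for i in range(len(shape))])
               for k, e in enumerate(eigs))
    lam.flat[0] = np.min(lam[lam > 0])
    lam *= scale

    def minv(r):
        rh = sfft.dctn(r, type=2, norm="ortho")
        return sfft.idctn(rh / lam, type=2, norm="ortho")

    return minv


def _pcg(fixed: np.ndarray, fixed_vals: np.ndarray, weights, tol: float,
         maxiter: int):
    """Solve L(phi)=0 on free nodes, phi given on fixed nodes, by PCG."""
    shape = fixed.shape
    free = ~fixed
    g = np.zeros(shape)
    g[fixed] = fixed_vals
    tmp = np.empty(shape)
    _laplacian_apply(g, weights, tmp)
    b = np.where(free, tmp, 0.0)
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        return g, 0.0, 0
    scale = 1.0 if weights is None else float(np.mean([w.mean() for w in weights]))
    minv = _dct_preconditioner(shape, scale)

    def apply_A(p, out):
        _laplacian_apply(p, weights, out)
        np.negative(out, out)
        out[fixed] = 0.0

    def apply_M(r):
        z = minv(r)
        z[fixed] = 0.0
        return z

    x = np.zeros(shape)
    r = b.copy()
    z = apply_M(r)
    p = z.copy()
    rz = float(np.vdot(r, z))
    Ap = np.empty(shape)
    res = 1.0
    it = 0
    while res > tol and it < maxiter:
        apply_A(p, Ap)
        alpha = rz / float(np.vdot(p, Ap))
        x += alpha * p
        r -= alpha * Ap
        res = np.linalg.norm(r) / bnorm
        z = apply_M(r)
        rz_new = float(np.vdot(r, z))
        p = z + (rz_new / rz) * p
        rz = rz_new
        it += 1
    if res > tol:
        raise SolverError(
            f"conjugate gradients did not reach tolerance {tol} within "
            f"{maxiter} iterations (residual {res:.3e})", residual=res)
    return x + g, res, it


def solve_field(domain: TissueDomain, electrodes: ElectrodePair,
                tol: float = 1e-6, maxiter: int = 500,
                cut_cell: bool = True) -> FieldSolution:
    """Solve the conduction problem and return potential and ``|E|``.

    The potential is obtained by matrix-free conjugate gradients on the
    5/7-point stencil, preconditioned with an FFT-based exact inverse of the
    unconstrained zero-flux Laplacian; ``|E|`` follows by central
    differences.  ``cut_cell=True`` applies the Shortley-Weller correction
    on faces crossing the conductor surfaces, which removes the
    O(grid step) bias in the effective electrode radius.
    """
    domain.validate_against(electrodes)
    dim = domain.dimensionality
    v_half = electrodes.applied_voltage_v / 2.0

    axes = domain.axes()
    sigma = _conductivity_map(domain, axes)
    weights = _face_weights(sigma)
    masks = _electrode_masks(electrodes, axes, dim)
    fixed = masks[0] | masks[1]
    if cut_cell:
        weights = _cut_cell_weights(weights, fixed, electrodes, axes, dim)
    fixed_vals = np.where(masks[0][fixed], -v_half, +v_half)
    phi, res, it = _pcg(fixed, fixed_vals, weights, tol, maxiter)

    h = domain.grid_step_mm
    grads = np.gradient(phi, h)
    if dim == 2:
        e_mag = np.hypot(grads[0], grads[1]) * 10.0
    else:
        e_mag = np.sqrt(grads[0] ** 2 + grads[1] ** 2 + grads[2] ** 2) * 10.0

    # discrete maximum principle: interior potentials stay inside the
    # Dirichlet range (slack covers the iterative-solution error at tol)
    slack = 100.0 * tol * max(1.0, abs(v_half))
    if phi.max() > v_half + slack or phi.min() < -v_half - slack:
        raise SolverError("solution violates the discrete maximum principle")

    return FieldSolution(phi, e_mag, h, axes, res, it, domain, electrodes)


# --------------------------------------------------------------------------
# coverage and inversion
# --------------------------------------------------------------------------

def _resolve_region_mask(field_sol: FieldSolution, region) -> np.ndarray:
    if region is None:
        return np.ones(field_sol.potential_v.shape, dtype=bool)
    if isinstance(region, str):
        for r in field_sol.domain.regions:
            if r.label == region:
                region = r
                break
        else:
            raise InvalidRegionError(f"no region labeled {region!r}")
    mask = _region_mask(region, field_sol.axes_mm)
    if not mask.any():
        raise InvalidRegionError("region contains no grid nodes")
    return mask


def ablation_metrics(field_sol: FieldSolution, lethal_threshold_v_per_cm: float,
                     region: Region | str | None = None) -> AblationPrediction:
    """Volume (or area, in 2-D) of a region at or above the lethal threshold.

    Nodes exactly at the threshold count as ablated.
    """
    mask = _resolve_region_mask(field_sol, region)
    cell = field_sol.grid_step_mm ** field_sol.dimensionality
    e = field_sol.e_magnitude_v_per_cm
    n_region = int(mask.sum())
    n_ablated = int((e[mask] >= lethal_threshold_v_per_cm).sum())
    coverage = 100.0 * n_ablated / n_region
    return AblationPrediction(lethal_threshold_v_per_cm, n_ablated * cell,
                              n_region * cell, coverage)


def extruded_ablation_metrics(field_sol: FieldSolution,
                              lethal_threshold_v_per_cm: float,
                              tumor_volume_mm3: float = 142.0,
                              center_mm: tuple[float, float] = (0.0, 0.0),
                              ) -> AblationPrediction:
    """Spherical-tumor coverage from a cross-sectional (2-D) field solve.

    In the subcutaneous two-needle configuration the exposed conductors span
    the tumor depth and the tissue-air interface above confines the current,
    so the field is approximately invariant along the insertion axis: every
    depth slice of the tumor sees the same in-plane two-wire field.  Under
    that extrusion the volumetric coverage is the chord-length-weighted
    in-plane coverage: each node at in-plane distance ``rho`` from the tumor
    center is weighted by the chord ``2 sqrt(R^2 - rho^2)`` of the sphere.

    This is the appropriate forward model when comparing against treatment-
    planning predictions for subcutaneous tumors; ``ablation_metrics`` on a
    full 3-D solve applies when the exposed conductor is short relative to
    the target and no confining boundary is present.
    """
    if field_sol.dimensionality != 2:
        raise InvalidRegionError("extruded coverage requires a 2-D field solve")
    radius = sphere_radius_for_volume(tumor_volume_mm3)
    x, y = field_sol.axes_mm
    rho2 = ((x[:, None] - center_mm[0]) ** 2 + (y[None, :] - center_mm[1]) ** 2)
    chord = np.sqrt(np.clip(radius ** 2 - rho2, 0.0, None))
    total_w = float(chord.sum())
    if total_w == 0.0:
        raise InvalidRegionError("tumor sphere does not intersect the solved plane")
    hot = field_sol.e_magnitude_v_per_cm >= lethal_threshold_v_per_cm
    frac = float((chord * hot).sum()) / total_w
    return AblationPrediction(lethal_threshold_v_per_cm,
                              frac * tumor_volume_mm3, tumor_volume_mm3,
                              100.0 * frac)


def coverage_curve(domain: TissueDomain, electrodes: ElectrodePair,
                   ratios_v_per_cm: Sequence[float],
                   lethal_threshold_v_per_cm: float,
                   region: Region | str | None = None,
                   tol: float = 1e-6):
    """Coverage for a sweep of voltage-to-distance ratios.

    The conduction problem is linear in the applied voltage, so a single
    solve at the first positive ratio is rescaled exactly for the others.
    Returns a pandas DataFrame (ratio_v_per_cm, voltage_v, coverage_percent).
    """
    import pandas as pd

    ratios = sorted(float(r) for r in ratios_v_per_cm)
    if any(r <= 0 for r in ratios):
        raise InvalidGeometryError("voltage-to-distance ratios must be positive")
    v_ref = ratios[0] * electrodes.spacing_mm / 10.0
    ref = replace(electrodes, applied_voltage_v=v_ref)
    sol = solve_field(domain, ref, tol=tol)
    mask = _resolve_region_mask(sol, region)
    e_ref = sol.e_magnitude_v_per_cm[mask]
    cell = sol.grid_step_mm ** sol.dimensionality
    region_measure = float(mask.sum()) * cell
    rows = []
    for r in ratios:
        scale = r / ratios[0]
        ablated = float((e_ref * scale >= lethal_threshold_v_per_cm).sum()) * cell
        rows.append({
            "ratio_v_per_cm": r,
            "voltage_v": r * electrodes.spacing_mm / 10.0,
            "coverage_percent": 100.0 * ablated / region_measure,
        })
    return pd.DataFrame(rows)


def invert_threshold(field_sol: FieldSolution, measured_area_mm2: float) -> float:
    """Lethal threshold whose iso-field contour encloses the measured area.

    For a 2-D solve (or the electrode midplane of a 3-D solve) the mapping
    ``t -> area{|E| >= t}`` is a non-increasing step function over the sorted
    node values; the returned threshold is the grid quantile matching the
    measured lesion area.
    """
    e = field_sol.e_magnitude_v_per_cm
    if e.ndim == 3:
        k = e.shape[2] // 2
        e = e[:, :, k]
    cell = field_sol.grid_step_mm ** 2
    total = e.size * cell
    if measured_area_mm2 <= 0:
        raise OutOfRangeError("measured area must be positive")
    if measured_area_mm2 > total + 0.5 * cell:
        raise OutOfRangeError(
            f"measured area {measured_area_mm2} mm^2 exceeds the solved "
            f"plane area {total} mm^2")
    flat = np.sort(e.ravel())[::-1]
    k = int(round(measured_area_mm2 / cell))
    k = min(max(k, 1), flat.size)
    return float(flat[k - 1])


# --------------------------------------------------------------------------
# convenience builders and IO
# --------------------------------------------------------------------------

def two_needle_tumor_domain(tumor_volume_mm3: float = 142.0,
                            grid_step_mm: float = 0.1,
                            spacing_mm: float = 4.0,
                            conductivity_s_per_m: float = 0.5,
                            tumor_conductivity_s_per_m: float | None = None,
                            dimensionality: int = 3) -> TissueDomain:
    """Homogeneous box with a centered spherical tumor region.

    The box extends 3x the electrode spacing from the midpoint in every axis
    (the minimum that keeps the zero-flux boundary from influencing the
    near-electrode field).  By default the tumor shares the background
    conductivity, i.e. the sphere is purely a bookkeeping region for
    coverage; pass ``tumor_conductivity_s_per_m`` for a two-compartment model.
    """
    half = 3.0 * spacing_mm
    bounds = tuple(((-half, half),) * dimensionality)
    regions = [Region("full", conductivity_s_per_m, "background")]
    radius = sphere_radius_for_volume(tumor_volume_mm3)
    sigma_t = tumor_conductivity_s_per_m or conductivity_s_per_m
    center = (0.0,) * dimensionality
    regions.append(Region("sphere", sigma_t, "tumor", center_mm=center,
                          radius_mm=radius))
    return TissueDomain(bounds, tuple(regions), grid_step_mm, dimensionality)


def load_domain_config(path) -> tuple[TissueDomain, ElectrodePair]:
    """Read a YAML solve configuration (electrodes / regions / grid blocks)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    e = cfg["electrodes"]
    electrodes = ElectrodePair(
        spacing_mm=float(e["spacing_mm"]),
        diameter_mm=float(e["diameter_mm"]),
        exposure_mm=float(e.get("exposure_mm", 4.0)),
        applied_voltage_v=float(e.get("applied_voltage_v", 0.0)),
    )
    regions = []
    for r in cfg["regions"]:
        regions.append(Region(
            shape=r["shape"],
            conductivity_s_per_m=float(r["conductivity_s_per_m"]),
            label=r.get("label", r["shape"]),
            center_mm=tuple(r.get("center_mm", (0.0, 0.0, 0.0))),
            radius_mm=r.get("radius_mm"),
            axis=int(r.get("axis", 2)),
            span_mm=tuple(r["span_mm"]) if "span_mm" in r else None,
        ))
    g = cfg["grid"]
    domain = TissueDomain(
        bounds_mm=tuple(tuple(b) for b in g["bounds_mm"]),
        regions=tuple(regions),
        grid_step_mm=float(g["step_mm"]),
        dimensionality=int(g.get("dimensionality", 3)),
    )
    return domain, electrodes


def save_field(field_sol: FieldSolution, path) -> None:
    """Write potential and |E| as a compressed array container + JSON sidecar."""
    path = str(path)
    np.savez_compressed(path if path.endswith(".npz") else path + ".npz",
                        potential_v=field_sol.potential_v,
                        e_magnitude_v_per_cm=field_sol.e_magnitude_v_per_cm,
                        **{f"axis{i}_mm": a for i, a in enumerate(field_sol.axes_mm)})
    side = {
        "grid_step_mm": field_sol.grid_step_mm,
        "units": {"potential": "V", "e_magnitude": "V/cm", "axes": "mm"},
        "residual": field_sol.residual,
        "iterations": field_sol.iterations,
        "applied_voltage_v": field_sol.electrodes.applied_voltage_v,
    }
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w") as fh:
        json.dump(side, fh, indent=2)


def load_field(path) -> dict:
    """Load a saved field container back into arrays (plain dict)."""
    path = str(path)
    data = np.load(path if path.endswith(".npz") else path + ".npz")
    return {k: data[k] for k in data.files}
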