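"""Displacement-field analytics for skin-deformation imaging.

The central quantity of this package is the mean divergence of the skin
micro-displacement field inside the apparent contact area ``S``::

    <div u> = (1/|S|) * integral_S (d u_x / d x + d u_y / d y) dS

A positive mean divergence means the skin inside the contact expands
radially outward — the signature of a low-friction (slippery) contact.
This module provides:

* :class:`DisplacementField` — a 2-component displacement sampled on a
  regular grid with an apparent-contact mask;
* :func:`grid_interpolate` — barycentric gridding of scattered tracked
  features;
* :func:`mean_divergence` — the area-normalised divergence estimator
  (central differences inside the mask, second-order one-sided stencils
  at the mask boundary);
* :func:`decompose` — split into constant + divergent (curl-free) +
  rotational (divergence-free) + residual parts;
* strain utilities (:func:`strain_components`,
  :func:`strain_rate_series`, :func:`strain_energy`) and the
  trial-exclusion rule (:func:`global_displacement`).

Grid convention: arrays are indexed ``[iy, ix]``; ``grid_x`` varies
along columns, ``grid_y`` along rows.  All coordinates and
displacements are in mm.  The divergence is invariant under this
convention choice (adding a constant or rotating the axes does not
change it).
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.interpolate import LinearNDInterpolator
from scipy.sparse.linalg import lsqr
from scipy.spatial import QhullError

from .errors import (
    DegenerateGeometryError,
    InsufficientSupportError,
    ParameterError,
)

__all__ = [
    "DisplacementField",
    "FieldDecomposition",
    "StrainSummary",
    "GlobalDisplacement",
    "grid_interpolate",
    "mean_divergence",
    "decompose",
    "strain_components",
    "strain_rate_series",
    "strain_energy",
    "global_displacement",
]

#: Trials whose global (rigid) displacement magnitude exceeds this are
#: excluded from divergence analysis, mm.
GLOBAL_DISPLACEMENT_LIMIT_MM = 0.3

#: Default skin elastic modulus for strain-energy estimates, MPa.
DEFAULT_SKIN_MODULUS_MPA = 0.1
#: Default Poisson ratio of skin.
DEFAULT_SKIN_POISSON = 0.4
#: Default effective thickness of the strained skin layer, mm.
DEFAULT_SKIN_THICKNESS_MM = 1.0


@dataclass
class DisplacementField:
    """Gridded 2-component skin displacement with a contact mask.

    Attributes
    ----------
    grid_x, grid_y : ndarray
        Strictly increasing, uniformly spaced axis coordinates, mm.
    u_x, u_y : ndarray, shape (len(grid_y), len(grid_x))
        Displacement components on the grid, mm.
    mask : ndarray of bool
        Apparent-contact-area mask ``S``; analysis is restricted to it.
    pixel_resolution : float or None
        Provenance tag, mm/pixel of the source images.
    timestamp : float
        Acquisition time of the frame, s.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    u_x: np.ndarray
    u_y: np.ndarray
    mask: np.ndarray
    pixel_resolution: float | None = None
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.grid_x = np.asarray(self.grid_x, dtype=float)
        self.grid_y = np.asarray(self.grid_y, dtype=float)
        self.u_x = np.asarray(self.u_x, dtype=float)
        self.u_y = np.asarray(self.u_y, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        shape = (self.grid_y.size, self.grid_x.size)
        for name in ("u_x", "u_y", "mask"):
            if getattr(self, name).shape != shape:
                raise ParameterError(
                    f"{name} has shape {getattr(self, name).shape}, "
                    f"expected {shape} from the grid axes"
                )
        for ax_name, ax in (("grid_x", self.grid_x), ("grid_y", self.grid_y)):
            if ax.size < 2:
                raise ParameterError(f"{ax_name} needs at least 2 samples")
            d = np.diff(ax)
            if not np.all(d > 0) or not np.allclose(d, d[0], rtol=1e-8):
                raise ParameterError(f"{ax_name} must be uniform and increasing")
        if not self.mask.any():
            raise ParameterError("mask is empty: no apparent contact area")
        if not np.all(np.isfinite(self.u_x[self.mask])) or not np.all(
            np.isfinite(self.u_y[self.mask])
        ):
            raise ParameterError("non-finite displacement inside the contact mask")

    @property
    def spacing(self) -> tuple[float, float]:
        """(dx, dy) grid spacing in mm."""
        return (
            float(self.grid_x[1] - self.grid_x[0]),
            float(self.grid_y[1] - self.grid_y[0]),
        )

    @property
    def cell_area(self) -> float:
        """Area of one grid cell, mm^2."""
        dx, dy = self.spacing
        return dx * dy

    def to_frame(self):
        """Long-format table: x_mm, y_mm, ux_mm, uy_mm, mask."""
        import pandas as pd

        gx, gy = np.meshgrid(self.grid_x, self.grid_y)
        return pd.DataFrame(
            {
                "x_mm": gx.ravel(),
                "y_mm": gy.ravel(),
                "ux_mm": self.u_x.ravel(),
                "uy_mm": self.u_y.ravel(),
                "mask": self.mask.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame, **kwargs) -> "DisplacementField":
        """Rebuild a field from its long-format table."""
        xs = np.unique(frame["x_mm"].to_numpy())
        ys = np.unique(frame["y_mm"].to_numpy())
        shape = (ys.size, xs.size)
        if len(frame) != shape[0] * shape[1]:
            raise ParameterError("long-format table does not fill a full grid")
        order = np.lexsort(
            (frame["x_mm"].to_numpy(), frame["y_mm"].to_numpy())
        )
        return cls(
            grid_x=xs,
            grid_y=ys,
            u_x=frame["ux_mm"].to_numpy()[order].reshape(shape),
            u_y=frame["uy_mm"].to_numpy()[order].reshape(shape),
            mask=frame["mask"].to_numpy()[order].reshape(shape).astype(bool),
            **kwargs,
        )


@dataclass
class FieldDecomposition:
    """Constant + divergent + rotational + residual split of a field.

    ``constant_part + divergent_part + rotational_part + residual``
    reconstructs the input exactly on the mask.  The divergent part is
    the discrete gradient of a scalar potential (curl-free); the
    rotational part is the discrete curl of a streamfunction
    (divergence-free).
    """

    constant_part: np.ndarray
    divergent_part: tuple[np.ndarray, np.ndarray]
    rotational_part: tuple[np.ndarray, np.ndarray]
    residual: tuple[np.ndarray, np.ndarray]
    potential: np.ndarray = _dc_field(default=None, repr=False)
    streamfunction: np.ndarray = _dc_field(default=None, repr=False)


@dataclass
class StrainSummary:
    """Skin-strain summary of one frame or one trial.

    ``longitudinal_strain`` is the largest principal-strain magnitude
    over the contact mask, in percent.  Rate fields are filled by
    :func:`strain_rate_series`; ``strain_energy`` by
    :func:`strain_energy` (mJ).
    """

    longitudinal_strain: float
    strain_rate: np.ndarray | None = None
    times: np.ndarray | None = None
    peak_strain_rate: float | None = None
    force_at_peak: float | None = None
    strain_energy: float | None = None


@dataclass
class GlobalDisplacement:
    """Rigid-motion summary used by the trial-exclusion rule."""

    median_vector: np.ndarray
    magnitude: float
    excluded: bool
    reason: str = ""


# ---------------------------------------------------------------------------
# masked finite differences
# ---------------------------------------------------------------------------


def _masked_diff_matrix(
    mask: np.ndarray, axis: int, spacing: float
) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Sparse derivative along ``axis`` restricted to a mask.

    Returns ``(D, valid)`` where ``D`` maps values on masked cells
    (column-indexed by masked-cell order) to the derivative on masked
    cells (row-indexed the same way) and ``valid`` flags the masked
    cells where a stencil exists.  Central differences are used where
    both neighbours are masked; second-order one-sided stencils (exact
    for quadratics) where two same-side neighbours are masked; cells
    with neither are flagged invalid.
    """
    idx = -np.ones(mask.shape, dtype=np.int64)
    idx[mask] = np.arange(int(mask.sum()))

    def shift(m: np.ndarray, k: int) -> np.ndarray:
        out = np.zeros_like(m) if m.dtype == bool else np.full_like(m, -1)
        if k == 0:
            return m.copy()
        sl_to = [slice(None)] * m.ndim
        sl_from = [slice(None)] * m.ndim
        if k > 0:
            sl_to[axis] = slice(k, None)
            sl_from[axis] = slice(None, -k)
        else:
            sl_to[axis] = slice(None, k)
            sl_from[axis] = slice(-k, None)
        out[tuple(sl_to)] = m[tuple(sl_from)]
        return out

    m_p1, m_m1 = shift(mask, -1), shift(mask, 1)
    m_p2, m_m2 = shift(mask, -2), shift(mask, 2)
    i_p1, i_m1 = shift(idx, -1), shift(idx, 1)
    i_p2, i_m2 = shift(idx, -2), shift(idx, 2)

    central = mask & m_p1 & m_m1
    fwd = mask & ~central & m_p1 & m_p2
    bwd = mask & ~central & ~fwd & m_m1 & m_m2
    valid_full = central | fwd | bwd

    rows, cols, vals = [], [], []
    h = spacing

    def add(cells: np.ndarray, neighbour_idx: np.ndarray, coeff: float) -> None:
        r = idx[cells]
        c = neighbour_idx[cells]
        rows.append(r)
        cols.append(c)
        vals.append(np.full(r.size, coeff))

    add(central, i_p1, 1.0 / (2 * h))
    add(central, i_m1, -1.0 / (2 * h))
    add(fwd, idx, -3.0 / (2 * h))
    add(fwd, i_p1, 4.0 / (2 * h))
    add(fwd, i_p2, -1.0 / (2 * h))
    add(bwd, idx, 3.0 / (2 * h))
    add(bwd, i_m1, -4.0 / (2 * h))
    add(bwd, i_m2, 1.0 / (2 * h))

    n = int(mask.sum())
    D = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return D, valid_full[mask]


class _MaskedGradient:
    """Cached pair of masked derivative operators for one field grid."""

    def __init__(self, fld: DisplacementField) -> None:
        dx, dy = fld.spacing
        self.mask = fld.mask
        self.Dx, self.valid_x = _masked_diff_matrix(fld.mask, axis=1, spacing=dx)
        self.Dy, self.valid_y = _masked_diff_matrix(fld.mask, axis=0, spacing=dy)
        self.valid = self.valid_x & self.valid_y

    def dd(self, values: np.ndarray, which: str) -> np.ndarray:
        """Derivative of a gridded array on masked cells (flat vector)."""
        v = values[self.mask]
        return (self.Dx if which == "x" else self.Dy) @ v


def _require_support(grad: _MaskedGradient) -> None:
    if not grad.valid.any():
        raise InsufficientSupportError(
            "contact mask has no cell with enough neighbours for a "
            "derivative stencil"
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def grid_interpolate(
    points: np.ndarray,
    displacements: np.ndarray,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    *,
    contact_mask: np.ndarray | None = None,
    pixel_resolution: float | None = None,
    timestamp: float = 0.0,
) -> DisplacementField:
    """Barycentric interpolation of scattered feature displacements.

    Parameters
    ----------
    points : (n, 2) array
        Feature positions (x, y), mm.  At least 3 non-collinear points.
    displacements : (n, 2) array
        Displacement vectors at the points, mm.
    grid_x, grid_y : 1-d arrays
        Target regular grid axes, mm.
    contact_mask : bool array, optional
        Apparent-contact mask to intersect with the convex hull of the
        points.  Cells outside the hull are always masked out; the
        field is never extrapolated.
    """
    points = np.asarray(points, dtype=float)
    displacements = np.asarray(displacements, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 (x, y) points")
    # collinearity check: rank of centred coordinates
    centred = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-10 * max(1.0, np.abs(points).max())) < 2:
        raise DegenerateGeometryError("points are collinear; no area to interpolate")
    try:
        interp = LinearNDInterpolator(points, displacements)
    except QhullError as exc:  # pragma: no cover - rank check catches most
        raise DegenerateGeometryError(str(exc)) from exc
    gx, gy = np.meshgrid(np.asarray(grid_x, float), np.asarray(grid_y, float))
    vals = interp(np.column_stack([gx.ravel(), gy.ravel()]))
    u = vals.reshape(gy.shape + (2,))
    hull_mask = np.all(np.isfinite(u), axis=-1)
    mask = hull_mask if contact_mask is None else (hull_mask & contact_mask)
    u = np.where(hull_mask[..., None], u, 0.0)
    return DisplacementField(
        grid_x=np.asarray(grid_x, float),
        grid_y=np.asarray(grid_y, float),
        u_x=u[..., 0],
        u_y=u[..., 1],
        mask=mask,
        pixel_resolution=pixel_resolution,
        timestamp=timestamp,
    )


def mean_divergence(fld: DisplacementField, *, normalized: bool = True) -> float:
    """Mean (area-normalised) divergence of the displacement field.

    Central differences of ``u_x`` along x and ``u_y`` along y on
    masked cells, averaged over the cells with full stencil support.
    With ``normalized=False`` the raw surface integral (mm^2) is
    returned instead of the dimensionless mean.

    Positive values mean the skin expands radially outward.
    """
    grad = _MaskedGradient(fld)
    _require_support(grad)
    div = grad.dd(fld.u_x, "x") + grad.dd(fld.u_y, "y")
    div = div[grad.valid]
    if normalized:
        return float(div.mean())
    return float(div.sum() * fld.cell_area)


def divergence_map(fld: DisplacementField) -> np.ndarray:
    """Pointwise divergence on the grid (NaN outside stencil support)."""
    grad = _MaskedGradient(fld)
    out = np.full(fld.mask.shape, np.nan)
    div = grad.dd(fld.u_x, "x") + grad.dd(fld.u_y, "y")
    flat_idx = np.flatnonzero(fld.mask.ravel())[grad.valid]
    out.ravel()[flat_idx] = div[grad.valid]
    return out


def decompose(
    fld: DisplacementField,
    *,
    atol: float = 1e-14,
    iter_lim: int = 60000,
) -> FieldDecomposition:
    """Constant / divergent / rotational / residual decomposition.

    The constant part is the per-component median over the mask.  The
    remainder ``v`` is fit by least squares as ``v = grad(phi) +
    curl(psi)`` with ``curl(psi) = (d psi/dy, -d psi/dx)`` using the
    same masked stencils as :func:`mean_divergence`; the minimum-norm
    solution is computed with LSQR.  The divergent part is curl-free
    and the rotational part divergence-free by construction (discrete
    identities hold on interior cells).  Whatever the model cannot
    represent — including mask cells without stencil support — lands in
    the residual, so the reconstruction identity is exact.
    """
    grad = _MaskedGradient(fld)
    _require_support(grad)
    mask = fld.mask
    n = int(mask.sum())
    const = np.array(
        [np.median(fld.u_x[mask]), np.median(fld.u_y[mask])], dtype=float
    )
    vx = fld.u_x[mask] - const[0]
    vy = fld.u_y[mask] - const[1]

    R = sparse.eye(n, format="csr")[grad.valid]  # restrict rows to valid cells
    Gx, Gy = R @ grad.Dx, R @ grad.Dy
    # u_x = Gx phi + Gy psi ; u_y = Gy phi - Gx psi
    A = sparse.bmat([[Gx, Gy], [Gy, -Gx]], format="csr")
    b = np.concatenate([vx[grad.valid], vy[grad.valid]])
    sol = lsqr(A, b, atol=atol, btol=atol, iter_lim=iter_lim)[0]
    phi, psi = sol[:n], sol[n:]

    def embed(flat: np.ndarray) -> np.ndarray:
        out = np.zeros(mask.shape)
        out[mask] = flat
        return out

    div_x = embed(grad.Dx @ phi)
    div_y = embed(grad.Dy @ phi)
    rot_x = embed(grad.Dy @ psi)
    rot_y = embed(-(grad.Dx @ psi))
    # cells without stencil support carry their whole signal in the residual
    invalid = embed((~grad.valid).astype(float)).astype(bool)
    for arr in (div_x, div_y, rot_x, rot_y):
        arr[invalid] = 0.0
    res_x = np.where(mask, fld.u_x - const[0] - div_x - rot_x, 0.0)
    res_y = np.where(mask, fld.u_y - const[1] - div_y - rot_y, 0.0)
    return FieldDecomposition(
        constant_part=const,
        divergent_part=(div_x, div_y),
        rotational_part=(rot_x, rot_y),
        residual=(res_x, res_y),
        potential=embed(phi),
        streamfunction=embed(psi),
    )


def strain_components(fld: DisplacementField) -> StrainSummary:
    """Infinitesimal strain tensor and the longitudinal-strain summary.

    The strain tensor is ``eps = (grad u + grad u^T)/2`` from the same
    masked stencils; the reported longitudinal strain is the largest
    principal-strain magnitude over the mask, in percent.  Rigid
    translations give zero; small rigid rotations give zero to first
    order (the antisymmetric gradient part is discarded).
    """
    exx, eyy, exy, valid = _strain_fields(fld)
    e_max = _principal_magnitude(exx[valid], eyy[valid], exy[valid])
    return StrainSummary(longitudinal_strain=100.0 * float(e_max.max()))


def _strain_fields(fld: DisplacementField):
    grad = _MaskedGradient(fld)
    _require_support(grad)
    exx = grad.dd(fld.u_x, "x")
    eyy = grad.dd(fld.u_y, "y")
    exy = 0.5 * (grad.dd(fld.u_x, "y") + grad.dd(fld.u_y, "x"))
    return exx, eyy, exy, grad.valid


def _principal_magnitude(exx, eyy, exy):
    mean = 0.5 * (exx + eyy)
    radius = np.sqrt((0.5 * (exx - eyy)) ** 2 + exy**2)
    return np.maximum(np.abs(mean + radius), np.abs(mean - radius))


def strain_rate_series(
    fields: Sequence[DisplacementField],
    force_times: np.ndarray,
    force_values: np.ndarray,
) -> StrainSummary:
    """Longitudinal-strain rate over a trial and the force at its peak.

    The longitudinal strain of every frame is differentiated in time by
    central differences on the frame timestamps; the peak rate and the
    normal force (linearly interpolated to the peak instant) are
    reported.
    """
    if len(fields) < 2:
        raise InsufficientSupportError("need at least 2 frames for a strain rate")
    t = np.array([f.timestamp for f in fields], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ParameterError("frame timestamps must be strictly increasing")
    strain = np.array(
        [strain_components(f).longitudinal_strain for f in fields]
    )  # percent
    rate = np.gradient(strain, t)
    k = int(np.argmax(rate))
    force_at_peak = float(
        np.interp(t[k], np.asarray(force_times, float), np.asarray(force_values, float))
    )
    return StrainSummary(
        longitudinal_strain=float(strain[-1]),
        strain_rate=rate,
        times=t,
        peak_strain_rate=float(rate[k]),
        force_at_peak=force_at_peak,
    )


def strain_energy(
    fld: DisplacementField,
    elastic_modulus: float = DEFAULT_SKIN_MODULUS_MPA,
    skin_thickness: float = DEFAULT_SKIN_THICKNESS_MM,
    poisson: float = DEFAULT_SKIN_POISSON,
) -> float:
    """Linear plane-stress elastic energy of the strained layer, mJ.

    ``U = 1/2 integral sigma : eps dV`` over the masked cells of a skin
    layer of the given thickness, with Young's modulus in MPa
    (N/mm^2) and lengths in mm, so the result is in N.mm = mJ.  A
    uniform biaxial strain ``e`` over area ``A`` gives the closed form
    ``E e^2 A t / (1 - nu)``.
    """
    if not (elastic_modulus > 0 and skin_thickness > 0):
        raise ParameterError("elastic modulus and skin thickness must be positive")
    if not (-1.0 < poisson < 0.5):
        raise ParameterError(f"Poisson ratio {poisson} outside (-1, 0.5)")
    exx, eyy, exy, valid = _strain_fields(fld)
    exx, eyy, exy = exx[valid], eyy[valid], exy[valid]
    c = elastic_modulus / (1.0 - poisson**2)
    sxx = c * (exx + poisson * eyy)
    syy = c * (eyy + poisson * exx)
    sxy = elastic_modulus / (1.0 + poisson) * exy
    density = 0.5 * (sxx * exx + syy * eyy + 2.0 * sxy * exy)
    return float(density.sum() * fld.cell_area * skin_thickness)


def global_displacement(
    fld: DisplacementField,
    limit: float = GLOBAL_DISPLACEMENT_LIMIT_MM,
) -> GlobalDisplacement:
    """Median rigid displacement of the contact and the exclusion flag.

    Trials whose global displacement magnitude exceeds ``limit`` (0.3 mm
    by default) are flagged for exclusion so gross sliding of the whole
    contact cannot masquerade as a deformation cue.
    """
    med = np.array(
        [np.median(fld.u_x[fld.mask]), np.median(fld.u_y[fld.mask])], dtype=float
    )
    mag = float(np.hypot(*med))
    excluded = mag > limit
    reason = f"global displacement {mag:.3f} mm > {limit} mm" if excluded else ""
    return GlobalDisplacement(
        median_vector=med, magnitude=mag, excluded=excluded, reason=reason
    )
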