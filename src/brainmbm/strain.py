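"""Finite strain on triangular elements and maximum-principal-strain metrics.

For each triangle we relate reference side vectors da_i to deformed side
lengths through the Green (Lagrangian) strain tensor E^G,

    ds^2 - ds0^2 = 2 E^G_ij da_i da_j ,

equivalently E^G = (F^T F - I)/2 with F the affine deformation gradient of
the triangle.  The Hencky (true, logarithmic) strain follows by the
matrix logarithm E^H = log(I + 2 E^G)/2, whose principal values are the
logs of the principal stretches.  The maximum principal strain (MPS) of
an element is the larger Hencky eigenvalue; a whole-plane run is
summarised by the 95th percentile over elements of each element's peak
MPS over time, the common brain-injury-risk metric.  Per-plane values
combine across simultaneous three-axis loading as the Euclidean resultant
sqrt(MPS_x^2 + MPS_y^2 + MPS_z^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import SimulationResult
from .geometry import PlanarMesh


class StrainError(ValueError):
    pass


def deformation_gradient(ref_vertices: np.ndarray, def_vertices: np.ndarray) -> np.ndarray:
    """Affine deformation gradient F mapping reference to deformed triangle."""
    a = np.asarray(ref_vertices, dtype=float)
    x = np.asarray(def_vertices, dtype=float)
    D0 = np.column_stack([a[1] - a[0], a[2] - a[0]])
    if abs(np.linalg.det(D0)) < 1e-16:
        raise StrainError("degenerate reference triangle")
    D = np.column_stack([x[1] - x[0], x[2] - x[0]])
    return D @ np.linalg.inv(D0)


def green_from_deformation_gradient(F: np.ndarray) -> np.ndarray:
    return 0.5 * (F.T @ F - np.eye(2))


def green_strain(ref_vertices: np.ndarray, def_vertices: np.ndarray) -> np.ndarray:
    """Green strain tensor of a triangle from its side-length changes.

    Solves the three equations ds_k^2 - ds0_k^2 = 2 E_ij da_i da_j (one
    per side) for (Exx, Eyy, Exy) and cross-checks the result against the
    deformation-gradient route; the two formulations are algebraically
    identical for an affine map.
    """
    a = np.asarray(ref_vertices, dtype=float)
    x = np.asarray(def_vertices, dtype=float)
    sides = [(0, 1), (1, 2), (2, 0)]
    A = np.empty((3, 3))
    b = np.empty(3)
    for row, (i, j) in enumerate(sides):
        da = a[j] - a[i]
        dx = x[j] - x[i]
        A[row] = [da[0] ** 2, da[1] ** 2, 2.0 * da[0] * da[1]]
        b[row] = 0.5 * (dx @ dx - da @ da)
    if abs(np.linalg.det(A)) < 1e-24:
        raise StrainError("degenerate reference triangle")
    exx, eyy, exy = np.linalg.solve(A, b)
    E = np.array([[exx, exy], [exy, eyy]])
    E_f = green_from_deformation_gradient(deformation_gradient(a, x))
    if not np.allclose(E, E_f, atol=1e-8 * max(1.0, np.abs(E_f).max())):
        raise StrainError("side-length and deformation-gradient strains disagree")
    return E


def hencky_from_green(EG: np.ndarray) -> np.ndarray:
    """Hencky strain E^H = log(I + 2 E^G)/2 via eigendecomposition."""
    C = np.eye(2) + 2.0 * np.asarray(EG, dtype=float)
    w, V = np.linalg.eigh(0.5 * (C + C.T))
    if np.any(w <= 0):
        raise StrainError("I + 2 E^G is not positive definite: invalid deformation")
    return (V * (0.5 * np.log(w))) @ V.T


def principal_mps(E: np.ndarray) -> float:
    """Larger principal value of a symmetric 2x2 strain tensor."""
    E = np.asarray(E, dtype=float)
    mean = 0.5 * (E[0, 0] + E[1, 1])
    rad = np.hypot(0.5 * (E[0, 0] - E[1, 1]), E[0, 1])
    return float(mean + rad)


@dataclass
class StrainField:
    """Per-element MPS histories and time peaks for one simulation."""

    element_ids: np.ndarray  # (E,)
    time: np.ndarray  # (T,)
    mps_history: np.ndarray  # (T, E), Hencky MPS
    peak_mps: np.ndarray  # (E,)
    time_of_peak: np.ndarray  # (E,)


@dataclass
class MPSSummary:
    plane_id: str
    mps95: float
    element_peaks: np.ndarray


def _batched_hencky_mps(F: np.ndarray) -> np.ndarray:
    """Hencky MPS for an (..., 2, 2) stack of deformation gradients.

    Uses the closed-form eigenvalues of C = F^T F: the Hencky principal
    strains are log(w)/2 and log is monotone, so only the larger
    eigenvalue is needed.
    """
    C = np.einsum("...ki,...kj->...ij", F, F)
    mean = 0.5 * (C[..., 0, 0] + C[..., 1, 1])
    rad = np.hypot(0.5 * (C[..., 0, 0] - C[..., 1, 1]), C[..., 0, 1])
    wmax = mean + rad
    if np.any(wmax <= 0):
        raise StrainError("degenerate deformation: non-positive principal stretch")
    return 0.5 * np.log(wmax)


def mps_field(result: SimulationResult, mesh: PlanarMesh) -> StrainField:
    """Green -> Hencky -> principal MPS per element per output time."""
    brain_ids = mesh.brain_ids
    id_to_row = {nid: k for k, nid in enumerate(brain_ids)}
    tris = mesh.triangles
    vidx = np.array([[id_to_row[v] for v in t.vertices] for t in tris])  # (E, 3)
    ref = mesh.brain_positions  # (N, 2)
    pos = result.brain_positions  # (T, N, 2)

    D0 = np.stack(
        [
            np.column_stack([ref[v[1]] - ref[v[0]], ref[v[2]] - ref[v[0]]])
            for v in vidx
        ]
    )  # (E, 2, 2)
    invD0 = np.linalg.inv(D0)
    d1 = pos[:, vidx[:, 1]] - pos[:, vidx[:, 0]]  # (T, E, 2)
    d2 = pos[:, vidx[:, 2]] - pos[:, vidx[:, 0]]
    D = np.stack([d1, d2], axis=-1)  # (T, E, 2, 2)
    F = np.einsum("teij,ejk->teik", D, invD0)
    mps = _batched_hencky_mps(F)  # (T, E)
    peak_idx = np.argmax(mps, axis=0)
    cols = np.arange(mps.shape[1])
    return StrainField(
        element_ids=np.array([t.id for t in tris]),
        time=result.time,
        mps_history=mps,
        peak_mps=mps[peak_idx, cols],
        time_of_peak=result.time[peak_idx],
    )


def percentile_mps(field: StrainField, q: float = 95.0) -> float:
    """q-th percentile (linear interpolation) of per-element peak MPS."""
    if field.peak_mps.size == 0:
        raise StrainError("empty strain field")
    return float(np.percentile(field.peak_mps, q))


def mps_summary(field: StrainField, plane_id: str, q: float = 95.0) -> MPSSummary:
    return MPSSummary(plane_id=plane_id, mps95=percentile_mps(field, q), element_peaks=field.peak_mps)


def resultant_mps(mps_x: float, mps_y: float, mps_z: float) -> float:
    """Euclidean resultant of per-plane MPS for multi-axis loading."""
    vals = np.array([mps_x, mps_y, mps_z], dtype=float)
    if np.any(vals < 0):
        raise StrainError("resultant inputs must be >= 0")
    return float(np.sqrt(np.sum(vals**2)))


def relative_error(mps_pred: float | np.ndarray, mps_ref: float | np.ndarray) -> float | np.ndarray:
    """Relative error in percent: |pred - ref| / ref * 100."""
    ref = np.asarray(mps_ref, dtype=float)
    if np.any(ref <= 0):
        raise StrainError("reference MPS must be > 0")
    out = np.abs(np.asarray(mps_pred, dtype=float) - ref) / ref * 100.0
    return float(out) if out.ndim == 0 else out
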