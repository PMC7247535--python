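"""Fine-mesh reference ("FEM-like") dataset generation.

Calibration and the ML correction layer both need a richer ground truth
than the coarse multibody model itself.  The original ground truth — a
proprietary 3-D finite element head model — is not distributable, so this
module generates a structurally analogous stand-in: a refined planar
multibody mesh with a smooth heterogeneous stiffness field.  Its nodal
displacement histories are interpolated back to the coarse node
locations (inverse-distance, 3 nearest neighbours) and lightly noised,
and its strain field supplies whole-plane and regional reference MPS.
The point is the coarse-model-versus-richer-reference *relationship*:
a systematic, kinematics-dependent discrepancy that calibration shrinks
and the ML layer corrects.  All outputs are deterministic in (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import h5py
import numpy as np

from .dynamics import SimulationConfig, simulate
from .geometry import PlanarMesh, PlaneSpec, TriangleElement, build_mesh
from .kinematics import HaversinePulse, trace_from_pulse
from .strain import StrainField, mps_field, percentile_mps

#: Stiffness bounds for the heterogeneous field, N/m.
STIFFNESS_RANGE = (2000.0, 70_000.0)
#: Settle margin simulated past the longest pulse, s.
DEFAULT_SETTLE = 0.020


class SurrogateError(RuntimeError):
    pass


@dataclass(frozen=True)
class SurrogateSpec:
    """Configuration of the fine-mesh reference generator.

    ``refinement`` divides the coarse grid spacing (1 reproduces the
    coarse topology exactly — used for self-consistency and recovery
    experiments); ``stiffness_field`` maps (n, 2) positions to N/m within
    the declared range (None -> seeded radial-basis-bump default);
    ``noise_sd`` is the additive Gaussian displacement noise in metres.
    """

    refinement: int = 2
    noise_sd: float = 1e-4
    seed: int = 0
    stiffness_field: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.refinement < 1:
            raise SurrogateError("refinement must be >= 1")
        if self.noise_sd < 0:
            raise SurrogateError("noise_sd must be >= 0")


def default_stiffness_field(
    plane_spec: PlaneSpec, seed: int, base: float = 15_000.0, n_bumps: int = 3
) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth positive stiffness field: base + 3 seeded radial bumps.

    Bump centres are drawn inside the outline's bounding box, amplitudes
    in [5, 45] kN/m and widths ~ 0.4 of the larger semi-axis; the sum is
    clipped to the 2-70 kN/m search range.
    """
    rng = np.random.default_rng([seed, 0xB0B])
    a, b = plane_spec.semi_axes
    centers = rng.uniform([-a, -b], [a, b], size=(n_bumps, 2))
    amps = rng.uniform(5_000.0, 45_000.0, size=n_bumps)
    width = 0.4 * max(a, b)

    def field_fn(xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d2 = ((xy[:, None, :] - centers[None]) ** 2).sum(axis=2)
        k = base + (amps * np.exp(-d2 / (2 * width**2))).sum(axis=1)
        return np.clip(k, *STIFFNESS_RANGE)

    return field_fn


def make_fine_mesh(plane_spec: PlaneSpec, surrogate: SurrogateSpec) -> PlanarMesh:
    """Refined mesh on the same outline with field-sampled stiffnesses."""
    fine_spec = replace(plane_spec, grid_spacing=plane_spec.grid_spacing / surrogate.refinement)
    mesh = build_mesh(fine_spec)
    field_fn = surrogate.stiffness_field or default_stiffness_field(plane_spec, surrogate.seed)
    mids = np.array(
        [
            0.5 * (mesh.nodes[s.node_a].ref_position + mesh.nodes[s.node_b].ref_position)
            for s in mesh.springs
        ]
    )
    mesh.set_stiffness(np.asarray(field_fn(mids), dtype=float))
    return mesh


@dataclass
class ReferenceDataset:
    """Per-condition reference records on a shared coarse time base."""

    conditions: list[HaversinePulse]
    time: np.ndarray  # (T,)
    node_displacements: np.ndarray  # (C, N_coarse, T, 2), noised
    mps95: np.ndarray  # (C,)
    regional_mps: np.ndarray  # (C, n_triangles); NaN = no fine element in radius
    peak_ang_accel: np.ndarray  # (C,)
    peak_ang_vel: np.ndarray  # (C,)
    surrogate: SurrogateSpec
    plane_id: str
    skipped: list[HaversinePulse] = field(default_factory=list)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def trace_for(self, idx: int, dt: float | None = None):
        """Regenerate the driving trace of condition ``idx`` from its label."""
        return trace_from_pulse(self.conditions[idx], dt=dt, pad_to=float(self.time[-1]))

    # -- container I/O ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["plane_id"] = self.plane_id
            f.attrs["seed"] = self.surrogate.seed
            f.attrs["refinement"] = self.surrogate.refinement
            f.attrs["noise_sd"] = self.surrogate.noise_sd
            f.create_dataset("time", data=self.time)
            f.create_dataset("node_displacements", data=self.node_displacements)
            f.create_dataset("mps95", data=self.mps95)
            f.create_dataset("regional_mps", data=self.regional_mps)
            f.create_dataset("peak_ang_accel", data=self.peak_ang_accel)
            f.create_dataset("peak_ang_vel", data=self.peak_ang_vel)
            cond = np.array(
                [[p.peak_accel, p.delta_velocity] for p in self.conditions], dtype=float
            )
            f.create_dataset("conditions", data=cond)

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceDataset":
        with h5py.File(path, "r") as f:
            plane_id = f.attrs["plane_id"]
            surrogate = SurrogateSpec(
                refinement=int(f.attrs["refinement"]),
                noise_sd=float(f.attrs["noise_sd"]),
                seed=int(f.attrs["seed"]),
            )
            conditions = [
                HaversinePulse(float(a), float(v), axis=plane_id)
                for a, v in f["conditions"][...]
            ]
            return cls(
                conditions=conditions,
                time=f["time"][...],
                node_displacements=f["node_displacements"][...],
                mps95=f["mps95"][...],
                regional_mps=f["regional_mps"][...],
                peak_ang_accel=f["peak_ang_accel"][...],
                peak_ang_vel=f["peak_ang_vel"][...],
                surrogate=surrogate,
                plane_id=plane_id,
            )


def _idw_weights(coarse_xy: np.ndarray, fine_xy: np.ndarray, k: int = 3):
    """Inverse-distance weights over the k nearest fine nodes.

    Returns (indices (Nc, k), weights (Nc, k)).  A coincident fine node
    gets the full weight, so refinement 1 reproduces the coarse solution
    exactly.
    """
    d = np.linalg.norm(coarse_xy[:, None, :] - fine_xy[None], axis=2)
    idx = np.argsort(d, axis=1)[:, :k]
    dk = np.take_along_axis(d, idx, axis=1)
    w = np.zeros_like(dk)
    exact = dk[:, 0] < 1e-12
    w[exact, 0] = 1.0
    inv = 1.0 / np.maximum(dk[~exact], 1e-300)
    w[~exact] = inv / inv.sum(axis=1, keepdims=True)
    return idx, w


def neighborhood_mps(
    fine_field: StrainField,
    fine_mesh: PlanarMesh,
    triangle: TriangleElement,
    coarse_mesh: PlanarMesh,
) -> float:
    """Mean fine-element peak MPS around one coarse triangle.

    The averaging disc captures 10% of the triangle's reference area
    (pi r^2 = 0.10 * ref_area) and is centred at the triangle centroid,
    taken from ``coarse_mesh`` which owns the vertex coordinates.
    Returns NaN when no fine-element centroid falls inside the disc (the
    "no model" exclusion).
    """
    radius = np.sqrt(0.10 * triangle.ref_area / np.pi)
    centroid = np.mean(
        [coarse_mesh.nodes[v].ref_position for v in triangle.vertices], axis=0
    )
    fine_centroids = _triangle_centroids(fine_mesh)
    inside = np.linalg.norm(fine_centroids - centroid, axis=1) <= radius
    if not np.any(inside):
        return float("nan")
    return float(fine_field.peak_mps[inside].mean())


def _triangle_centroids(mesh: PlanarMesh) -> np.ndarray:
    pos = {n.id: n.ref_position for n in mesh.nodes}
    return np.array([np.mean([pos[v] for v in t.vertices], axis=0) for t in mesh.triangles])


def _regional_mps(
    fine_peaks: np.ndarray,
    fine_centroids: np.ndarray,
    coarse_mesh: PlanarMesh,
) -> np.ndarray:
    out = np.full(len(coarse_mesh.triangles), np.nan)
    coarse_centroids = _triangle_centroids(coarse_mesh)
    for i, tri in enumerate(coarse_mesh.triangles):
        r = np.sqrt(0.10 * tri.ref_area / np.pi)
        inside = np.linalg.norm(fine_centroids - coarse_centroids[i], axis=1) <= r
        if np.any(inside):
            out[i] = float(fine_peaks[inside].mean())
    return out


def make_reference(
    coarse_mesh: PlanarMesh,
    conditions: Sequence[HaversinePulse],
    surrogate: SurrogateSpec,
    sim_config: SimulationConfig | None = None,
    max_duration: float | None = None,
    settle: float = DEFAULT_SETTLE,
) -> ReferenceDataset:
    """Simulate the fine mesh per condition and package reference records.

    Conditions whose pulse duration exceeds ``max_duration`` (if given)
    are skipped and listed in ``dataset.skipped``.  The shared time base
    spans the longest retained pulse plus a settle margin.
    """
    sim_config = sim_config or SimulationConfig()
    kept = [c for c in conditions if max_duration is None or c.duration <= max_duration]
    skipped = [c for c in conditions if c not in kept]
    if not kept:
        raise SurrogateError("no conditions left after the duration cap")

    fine_mesh = make_fine_mesh(coarse_mesh.spec, surrogate)
    fine_centroids = _triangle_centroids(fine_mesh)
    t_end = max(c.duration for c in kept) + settle
    # Snap the shared time base onto the output grid (largest multiple
    # of output_dt not exceeding the window).
    n_t = int(np.floor(t_end / sim_config.output_dt + 1e-9)) + 1
    time = np.arange(n_t) * sim_config.output_dt

    coarse_xy = coarse_mesh.brain_positions
    fine_xy = fine_mesh.brain_positions
    idx, w = _idw_weights(coarse_xy, fine_xy)

    n_c = len(kept)
    disp = np.empty((n_c, len(coarse_xy), n_t, 2))
    mps95 = np.empty(n_c)
    regional = np.empty((n_c, len(coarse_mesh.triangles)))
    pk_a = np.empty(n_c)
    pk_v = np.empty(n_c)
    for ci, cond in enumerate(kept):
        trace = trace_from_pulse(cond, pad_to=t_end)
        res = simulate(fine_mesh, trace, sim_config, t_max=float(time[-1]))
        fld = mps_field(res, fine_mesh)
        mps95[ci] = percentile_mps(fld)
        regional[ci] = _regional_mps(fld.peak_mps, fine_centroids, coarse_mesh)
        pk_a[ci] = cond.peak_accel
        pk_v[ci] = cond.delta_velocity
        u_fine = res.brain_positions - fine_xy[None]  # (T, Nf, 2)
        u_coarse = np.einsum("nk,tnkj->tnj", w, u_fine[:, idx, :])  # (T, Nc, 2)
        rng = np.random.default_rng([surrogate.seed, ci])
        noise = rng.normal(0.0, surrogate.noise_sd, size=u_coarse.shape) if surrogate.noise_sd else 0.0
        disp[ci] = np.transpose(u_coarse + noise, (1, 0, 2))
    return ReferenceDataset(
        conditions=list(kept),
        time=time,
        node_displacements=disp,
        mps95=mps95,
        regional_mps=regional,
        peak_ang_accel=pk_a,
        peak_ang_vel=pk_v,
        surrogate=surrogate,
        plane_id=coarse_mesh.spec.plane_id,
        skipped=skipped,
    )
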