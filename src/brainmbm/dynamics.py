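"""Time integration of the planar mass-spring-damper equations of motion.

Each brain node is a point mass; skull nodes are massless, position-driven
constraints following a rigid rotation of the outline about the mesh
centroid.  For a spring with stiffness K and elongation delta, the force
is K*delta along the spring axis, with stiffness-proportional damping
beta*K*d(delta)/dt sharing the same axis (so beta carries seconds; the
shipped default beta = 0.0015 corresponds to "0.15% damping").

Two spring-direction conventions are supported:

``deformed`` (default)
    delta = |current separation| - rest length, acting along the current
    unit vector.  Geometrically exact; the rigidly rotated configuration
    is an equilibrium, so large skull rotations remain physical.
``reference``
    fully linearised: delta = e0 . (u_b - u_a) with the fixed reference
    unit vector e0, i.e. the constant-matrix small-displacement form.
    Response is exactly linear in the driving displacement, which the
    verification suite exploits (superposition, analytic oscillator).

Accelerations are integrated with the Dormand-Prince embedded
Runge-Kutta 5(4) scheme (scipy ``solve_ivp`` method ``RK45``) from the
reference configuration at rest, then interpolated onto a uniform output
grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .geometry import PlanarMesh, mesh_centroid
from .kinematics import KinematicTrace


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Integrator and damping settings for one multibody run."""

    damping_factor: float = 0.0015  # beta, stiffness-proportional (s)
    rel_tol: float = 1e-6
    abs_tol: float = 1e-9
    output_dt: float = 5e-4  # s
    direction_mode: str = "deformed"  # or "reference"

    def __post_init__(self):
        if not 0.0 <= self.damping_factor <= 0.05:
            raise ValueError("damping_factor must be within [0, 0.05]")
        if self.rel_tol <= 0 or self.abs_tol <= 0 or self.output_dt <= 0:
            raise ValueError("tolerances and output_dt must be > 0")
        if self.direction_mode not in ("reference", "deformed"):
            raise ValueError("direction_mode must be 'reference' or 'deformed'")


@dataclass
class SimulationResult:
    """Nodal position histories from one multibody run."""

    time: np.ndarray  # (T,)
    brain_positions: np.ndarray  # (T, N, 2)
    brain_velocities: np.ndarray  # (T, N, 2)
    skull_positions: np.ndarray  # (T, S, 2)
    config: SimulationConfig
    trace: KinematicTrace | None

    @property
    def brain_displacements(self) -> np.ndarray:
        return self.brain_positions - self.brain_positions[0]


def _rotation(theta: np.ndarray) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    R = np.empty(np.shape(theta) + (2, 2))
    R[..., 0, 0] = c
    R[..., 0, 1] = -s
    R[..., 1, 0] = s
    R[..., 1, 1] = c
    return R


def skull_trajectories(mesh: PlanarMesh, trace: KinematicTrace) -> np.ndarray:
    """Prescribed skull positions: rigid rotation about the mesh centroid.

    Returns an array of shape (T, n_skull, 2) on the trace's time grid.
    """
    c = mesh_centroid(mesh)
    arms = mesh.skull_positions - c  # (S, 2)
    R = _rotation(trace.ang_pos)  # (T, 2, 2)
    return c + np.einsum("tij,sj->tsi", R, arms)


class _System:
    """Precomputed arrays for fast right-hand-side evaluation."""

    def __init__(self, mesh: PlanarMesh, config: SimulationConfig):
        self.config = config
        self.ref_brain = mesh.brain_positions  # (N, 2)
        self.ref_skull = mesh.skull_positions  # (S, 2)
        self.masses = mesh.masses  # (N,)
        self.centroid = mesh_centroid(mesh)
        self.n = len(self.ref_brain)

        brain_ids = list(mesh.brain_ids)
        skull_ids = list(mesh.skull_ids)
        b_index = {nid: k for k, nid in enumerate(brain_ids)}
        s_index = {nid: k for k, nid in enumerate(skull_ids)}

        bb_a, bb_b, bb_k, bb_l = [], [], [], []
        sk_b, sk_s, sk_k, sk_l = [], [], [], []
        for s in mesh.springs:
            if s.node_a in b_index and s.node_b in b_index:
                bb_a.append(b_index[s.node_a])
                bb_b.append(b_index[s.node_b])
                bb_k.append(s.stiffness)
                bb_l.append(s.rest_length)
            else:
                brain_end = s.node_a if s.node_a in b_index else s.node_b
                skull_end = s.node_b if s.node_a in b_index else s.node_a
                sk_b.append(b_index[brain_end])
                sk_s.append(s_index[skull_end])
                sk_k.append(s.stiffness)
                sk_l.append(s.rest_length)
        self.bb_a = np.array(bb_a, dtype=int)
        self.bb_b = np.array(bb_b, dtype=int)
        self.bb_k = np.array(bb_k)
        self.bb_l = np.array(bb_l)
        self.sk_b = np.array(sk_b, dtype=int)
        self.sk_s = np.array(sk_s, dtype=int)
        self.sk_k = np.array(sk_k)
        self.sk_l = np.array(sk_l)
        # Reference unit vectors (a -> b).
        if len(self.bb_a):
            d = self.ref_brain[self.bb_b] - self.ref_brain[self.bb_a]
            self.bb_e0 = d / np.linalg.norm(d, axis=1, keepdims=True)
        else:
            self.bb_e0 = np.zeros((0, 2))
        if len(self.sk_b):
            d = self.ref_skull[self.sk_s] - self.ref_brain[self.sk_b]
            self.sk_e0 = d / np.linalg.norm(d, axis=1, keepdims=True)
        else:
            self.sk_e0 = np.zeros((0, 2))

    def forces(
        self,
        pos: np.ndarray,
        vel: np.ndarray,
        skull_pos: np.ndarray,
        skull_vel: np.ndarray,
    ) -> np.ndarray:
        cfg = self.config
        beta = cfg.damping_factor
        F = np.zeros_like(pos)

        def pair(xa, xb, va, vb, e0, K, L0):
            if cfg.direction_mode == "deformed":
                sep = xb - xa
                d = np.linalg.norm(sep, axis=1)
                if np.any(d < 1e-12):
                    raise SimulationError(
                        "coincident spring endpoints: direction undefined in deformed mode"
                    )
                e = sep / d[:, None]
                delta = d - L0
            else:
                e = e0
                # Projected elongation of the displacement difference.
                delta = np.einsum("ij,ij->i", e0, (xb - xa)) - L0
            ddot = np.einsum("ij,ij->i", e, vb - va)
            return (K * (delta + beta * ddot))[:, None] * e

        if len(self.bb_a):
            f = pair(
                pos[self.bb_a], pos[self.bb_b], vel[self.bb_a], vel[self.bb_b],
                self.bb_e0, self.bb_k, self.bb_l,
            )
            np.add.at(F, self.bb_a, f)
            np.add.at(F, self.bb_b, -f)
        if len(self.sk_b):
            f = pair(
                pos[self.sk_b], skull_pos[self.sk_s], vel[self.sk_b], skull_vel[self.sk_s],
                self.sk_e0, self.sk_k, self.sk_l,
            )
            np.add.at(F, self.sk_b, f)
        return F


def net_force(
    mesh: PlanarMesh,
    config: SimulationConfig,
    brain_positions: np.ndarray,
    brain_velocities: np.ndarray | None = None,
    skull_positions: np.ndarray | None = None,
    skull_velocities: np.ndarray | None = None,
) -> np.ndarray:
    """Net spring + damper force (N) on each brain node for one state."""
    sys_ = _System(mesh, config)
    if brain_velocities is None:
        brain_velocities = np.zeros_like(brain_positions)
    if skull_positions is None:
        skull_positions = sys_.ref_skull
    if skull_velocities is None:
        skull_velocities = np.zeros_like(skull_positions)
    return sys_.forces(brain_positions, brain_velocities, skull_positions, skull_velocities)


def simulate(
    mesh: PlanarMesh,
    trace: KinematicTrace | None,
    config: SimulationConfig | None = None,
    t_max: float | None = None,
    u0: np.ndarray | None = None,
    v0: np.ndarray | None = None,
    skull_displacements: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate the multibody model under a rotational pulse.

    Parameters
    ----------
    trace:
        Rotational kinematics driving the skull ring.  ``None`` leaves
        the skull fixed at its reference position (free-vibration runs).
    t_max:
        Simulation horizon; defaults to the trace end (or raises for
        trace-free runs).
    u0, v0:
        Optional initial brain displacements/velocities, shape (N, 2);
        default reference positions at rest.
    skull_displacements:
        Optional explicit skull displacement histories (T_trace, S, 2) on
        the trace time grid, overriding the rigid-rotation construction.
        Used for linear-response verification.
    """
    config = config or SimulationConfig()
    sys_ = _System(mesh, config)
    N = sys_.n
    c = sys_.centroid

    if t_max is None:
        if trace is None:
            raise SimulationError("t_max is required when no trace is given")
        t_max = float(trace.time[-1])

    if trace is not None:
        tt = trace.time
        if skull_displacements is not None:
            skull_hist = sys_.ref_skull[None] + skull_displacements
            skull_vel_hist = np.gradient(skull_hist, tt, axis=0)

            def skull_state(t):
                xp = np.empty((len(sys_.ref_skull), 2))
                vp = np.empty_like(xp)
                for k in range(2):
                    xp[:, k] = [np.interp(t, tt, skull_hist[:, s, k]) for s in range(xp.shape[0])]
                    vp[:, k] = [np.interp(t, tt, skull_vel_hist[:, s, k]) for s in range(xp.shape[0])]
                return xp, vp
        else:
            arms = sys_.ref_skull - c

            def skull_state(t):
                th = np.interp(t, tt, trace.ang_pos)
                om = np.interp(t, tt, trace.ang_vel)
                R = _rotation(th)
                rot_arms = arms @ R.T
                xp = c + rot_arms
                vp = om * np.column_stack([-rot_arms[:, 1], rot_arms[:, 0]])
                return xp, vp
    else:
        ref_skull = sys_.ref_skull
        zero_v = np.zeros_like(ref_skull)

        def skull_state(t):
            return ref_skull, zero_v

    minv = 1.0 / sys_.masses[:, None]
    ref = sys_.ref_brain

    def rhs(t, y):
        u = y[: 2 * N].reshape(N, 2)
        v = y[2 * N :].reshape(N, 2)
        xp, vp = skull_state(t)
        F = sys_.forces(ref + u, v, xp, vp)
        return np.concatenate([v.ravel(), (F * minv).ravel()])

    y0 = np.zeros(4 * N)
    if u0 is not None:
        y0[: 2 * N] = np.asarray(u0, dtype=float).ravel()
    if v0 is not None:
        y0[2 * N :] = np.asarray(v0, dtype=float).ravel()

    t_eval = np.arange(0.0, t_max + 0.5 * config.output_dt, config.output_dt)
    t_eval = np.clip(t_eval[t_eval <= t_max + 1e-12], 0.0, t_max)
    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        y0,
        method="RK45",
        rtol=config.rel_tol,
        atol=config.abs_tol,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success:
        raise SimulationError(
            f"integration failed at t = {sol.t[-1] if len(sol.t) else 0.0:.6g} s: {sol.message}"
        )
    T = len(sol.t)
    u = sol.y[: 2 * N].T.reshape(T, N, 2)
    v = sol.y[2 * N :].T.reshape(T, N, 2)
    skull_hist = np.array([skull_state(t)[0] for t in sol.t])
    return SimulationResult(
        time=sol.t,
        brain_positions=ref[None] + u,
        brain_velocities=v,
        skull_positions=skull_hist,
        config=config,
        trace=trace,
    )
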