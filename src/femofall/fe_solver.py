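"""Displacement-controlled sideways-fall FE analysis of hexahedral femur models.

Small-strain, elastic-perfectly-plastic (J2, tension/compression asymmetric)
hex8 solver with B-bar integration.  The loading mimics the cadaveric
side-fall test: the distal shaft section is fully clamped, the greater
trochanter surface is supported along the fall direction only, and the
femoral head surface is rigidly coupled (translations only) to a reference
point driven along the fall direction in displacement increments.  The
reaction force at the reference point, recorded against the imposed
displacement, yields the force-displacement curve from which strength and
the inelastic descriptors are extracted.

Failure detection: under small-strain perfect plasticity the reaction is
monotone non-decreasing toward the limit load, so a literal force drop
(criterion ``"drop"``) may never trigger; the ``"plateau"`` criterion
declares failure when the tangent stiffness dF/dd falls below a fraction of
the initial stiffness (limit-load attainment), and ``"drop_or_plateau"``
accepts either.  See docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from ._hex8 import bbar_matrices, full_b_matrices
from .curve_analysis import ForceDisplacementCurve
from .materials import MaterialPoint
from .mesh import HexMesh
from .plasticity import elastic_energy_density, stress_update

__all__ = [
    "FallConfiguration",
    "LoadProgram",
    "FEState",
    "FESystem",
    "ConstraintSet",
    "build_system",
    "apply_side_fall_bcs",
    "solve_increment",
    "run_side_fall",
    "run_unload",
    "NonConvergenceError",
]


class NonConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class FallConfiguration:
    """Side-fall direction parameterized by adduction / internal rotation.

    With the shaft axis along +z and the frontal plane x-z, the 0/0
    configuration loads along +x; adduction tilts the axis in the frontal
    plane, internal rotation spins it about the shaft axis.  Both angles are
    restricted to the 0-30 degree range covered by the fall-direction study.
    ``direction_override`` replaces the derived axis with an explicit unit
    vector (used e.g. for rotated-frame invariance checks).
    """

    adduction_deg: float = 0.0
    rotation_deg: float = 0.0
    direction_override: tuple | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.adduction_deg <= 30.0 and 0.0 <= self.rotation_deg <= 30.0):
            raise ValueError("fall angles must lie in [0, 30] degrees")

    @property
    def fall_direction(self) -> np.ndarray:
        if self.direction_override is not None:
            d = np.asarray(self.direction_override, dtype=float)
            return d / np.linalg.norm(d)
        a = np.radians(self.adduction_deg)
        r = np.radians(self.rotation_deg)
        return np.array([np.cos(a) * np.cos(r), np.cos(a) * np.sin(r), -np.sin(a)])


@dataclass(frozen=True)
class LoadProgram:
    """Displacement marching schedule and failure/convergence tolerances."""

    increment: float = 0.05  # mm of head displacement per step
    max_displacement: float = 6.0  # mm
    unload: bool = False
    drop_fraction: float = 0.999
    failure_criterion: str = "drop"  # "drop" | "plateau" | "drop_or_plateau"
    plateau_fraction: float = 0.02  # tangent / initial stiffness threshold
    newton_tol: float = 1e-6
    max_newton: int = 60
    max_halvings: int = 4

    def __post_init__(self) -> None:
        if self.increment <= 0:
            raise ValueError("increment must be positive")
        if self.max_displacement < self.increment:
            raise ValueError("max_displacement must be at least one increment")
        if self.failure_criterion not in ("drop", "plateau", "drop_or_plateau"):
            raise ValueError("unknown failure criterion")


@dataclass
class ConstraintSet:
    """Affine reduction u = Z q + c + lam * p of the global DOF vector.

    ``Z`` spans the free motions, ``c`` carries inhomogeneous Dirichlet
    values, ``p`` is the prescribed-mode shape (head nodes moving along the
    fall direction), scaled by the load parameter ``lam``.
    """

    Z: sp.csr_matrix
    c: np.ndarray
    p: np.ndarray
    n_retained: int  # reduced DOFs counting the prescribed axis as retained

    @property
    def n_free(self) -> int:
        return self.Z.shape[1]


def _tangent_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(d, ref)
    t1 /= np.linalg.norm(t1)
    return t1, np.cross(d, t1)


def build_constraints(
    n_nodes: int,
    fixed: dict | None = None,
    direction_fixed: list | None = None,
    rigid_group: tuple | None = None,
    prescribed: tuple | None = None,
) -> ConstraintSet:
    """General constraint assembly.

    fixed: {node: (mask3, values3)} per-component Dirichlet.
    direction_fixed: [(nodes, unit_vector)] zero motion along the vector.
    rigid_group: (nodes, unit_vector) translation-rigid group whose common
    translation along the vector is the prescribed load parameter; the two
    transverse translations remain free master DOFs.
    prescribed: (nodes, unit_vector) per-node prescribed motion along the
    vector (load parameter), transverse motion free per node.
    """
    ndof = 3 * n_nodes
    c = np.zeros(ndof)
    p = np.zeros(ndof)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    handled = np.zeros(n_nodes, dtype=bool)
    col = 0

    for node, (mask, values) in (fixed or {}).items():
        handled[node] = True
        for k in range(3):
            dof = 3 * node + k
            if mask[k]:
                c[dof] = values[k]
            else:
                rows.append(dof)
                cols.append(col)
                vals.append(1.0)
                col += 1

    for nodes, d in direction_fixed or []:
        d = np.asarray(d, float)
        d = d / np.linalg.norm(d)
        t1, t2 = _tangent_basis(d)
        for node in np.asarray(nodes):
            if handled[node]:
                raise ValueError(f"node {node} constrained twice")
            handled[node] = True
            for t in (t1, t2):
                for k in range(3):
                    rows.append(3 * node + k)
                    cols.append(col)
                    vals.append(t[k])
                col += 1

    if rigid_group is not None:
        nodes, d = rigid_group
        d = np.asarray(d, float)
        d = d / np.linalg.norm(d)
        t1, t2 = _tangent_basis(d)
        for t in (t1, t2):
            for node in np.asarray(nodes):
                if handled[node]:
                    raise ValueError(f"node {node} constrained twice")
                for k in range(3):
                    rows.append(3 * node + k)
                    cols.append(col)
                    vals.append(t[k])
            col += 1
        for node in np.asarray(nodes):
            handled[node] = True
            for k in range(3):
                p[3 * node + k] = d[k]

    if prescribed is not None:
        nodes, d = prescribed
        d = np.asarray(d, float)
        d = d / np.linalg.norm(d)
        t1, t2 = _tangent_basis(d)
        for node in np.asarray(nodes):
            if handled[node]:
                raise ValueError(f"node {node} constrained twice")
            handled[node] = True
            for k in range(3):
                p[3 * node + k] = d[k]
            for t in (t1, t2):
                for k in range(3):
                    rows.append(3 * node + k)
                    cols.append(col)
                    vals.append(t[k])
                col += 1

    free_nodes = np.flatnonzero(~handled)
    for node in free_nodes:
        for k in range(3):
            rows.append(3 * node + k)
            cols.append(col)
            vals.append(1.0)
            col += 1

    Z = sp.csr_matrix((vals, (rows, cols)), shape=(ndof, col))
    # retained = free columns plus the prescribed axis of the reference point
    n_retained = col + (1 if rigid_group is not None or prescribed is not None else 0)
    return ConstraintSet(Z=Z, c=c, p=p, n_retained=n_retained)


def apply_side_fall_bcs(mesh: HexMesh, config: FallConfiguration) -> ConstraintSet:
    """Side-fall constraint set from the mesh's three named node sets."""
    mesh.validate_side_fall_sets()
    d = config.fall_direction
    fixed = {
        int(n): (np.array([True] * 3), np.zeros(3))
        for n in mesh.node_sets["shaft_end"]
    }
    return build_constraints(
        mesh.n_nodes,
        fixed=fixed,
        direction_fixed=[(mesh.node_sets["trochanter_surface"], d)],
        rigid_group=(mesh.node_sets["head_surface"], d),
    )


class FESystem:
    """Assembled element operators for one mesh + material distribution."""

    def __init__(self, mesh: HexMesh, materials, integration: str = "bbar"):
        if len(materials) != mesh.n_elements:
            raise ValueError("one MaterialPoint per element required")
        self.mesh = mesh
        coords = mesh.element_coords()
        make_B = bbar_matrices if integration == "bbar" else full_b_matrices
        self.B, self.w, self.vol = make_B(coords)  # (M,8,6,24), (M,8), (M,)
        self.E = np.array([m.E for m in materials])[:, None] * np.ones((1, 8))
        self.nu = materials[0].nu
        self.syc = np.array([m.sigma_yc for m in materials])[:, None] * np.ones((1, 8))
        self.syt = np.array([m.sigma_yt for m in materials])[:, None] * np.ones((1, 8))
        from .plasticity import elastic_matrix

        # elastic moduli reused for the (slightly regularized) iteration
        # matrix: perfect plasticity zeroes the consistent tangent along
        # active flow directions, and a small elastic admixture keeps the
        # Newton matrix well conditioned without touching the converged
        # physics (the residual is always the true one)
        self.Cel = elastic_matrix(self.E, self.nu)
        self.tangent_regularization = 1e-3
        dofs = (3 * mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(
            mesh.n_elements, 24
        )
        self.edofs = dofs
        self._rows = np.repeat(dofs, 24, axis=1).ravel()
        self._cols = np.tile(dofs, (1, 24)).ravel()
        self.ndof = 3 * mesh.n_nodes

    def strains(self, u: np.ndarray) -> np.ndarray:
        ue = u[self.edofs]  # (M, 24)
        return (self.B @ ue[:, None, :, None])[..., 0]

    def response(self, u: np.ndarray, eps_p_n: np.ndarray):
        """Stress update from the last converged plastic strain field."""
        eps = self.strains(u)
        sigma, eps_p_new, D, dgamma = stress_update(
            eps, eps_p_n, self.E, self.nu, self.syc, self.syt
        )
        return eps, sigma, eps_p_new, D

    def internal_force(self, sigma: np.ndarray) -> np.ndarray:
        sw = sigma * self.w[..., None]  # (M, 8, 6)
        fe = (self.B.transpose(0, 1, 3, 2) @ sw[..., None])[..., 0].sum(axis=1)
        f = np.zeros(self.ndof)
        np.add.at(f, self.edofs.ravel(), fe.ravel())
        return f

    def stiffness(self, D: np.ndarray) -> sp.csr_matrix:
        DB = D @ self.B  # (M, 8, 6, 24)
        Ke = (self.B.transpose(0, 1, 3, 2) @ (DB * self.w[..., None, None])).sum(axis=1)
        return sp.csr_matrix(
            (Ke.ravel(), (self._rows, self._cols)), shape=(self.ndof, self.ndof)
        )

    def elastic_energy(self, u: np.ndarray, eps_p: np.ndarray) -> float:
        eps = self.strains(u)
        sigma, _, _, _ = stress_update(eps, eps_p, self.E, self.nu, self.syc, self.syt)
        return float(np.sum(elastic_energy_density(sigma, eps, eps_p) * self.w))


def build_system(mesh: HexMesh, materials, integration: str = "bbar") -> FESystem:
    return FESystem(mesh, materials, integration)


@dataclass
class FEState:
    """Converged solver state after one displacement increment."""

    u: np.ndarray
    eps_p: np.ndarray  # (M, 8, 6)
    sigma: np.ndarray  # (M, 8, 6)
    lam: float  # imposed head displacement, mm
    reaction: float  # reference-point reaction along the fall axis, N
    dissipated: float = 0.0  # cumulative plastic dissipation, N*mm
    external_work: float = 0.0  # cumulative trapezoidal work, N*mm
    system: FESystem | None = field(default=None, repr=False)
    constraints: ConstraintSet | None = field(default=None, repr=False)
    loading_curve: ForceDisplacementCurve | None = field(default=None, repr=False)
    delta_u: np.ndarray | None = field(default=None, repr=False)
    delta_lam: float | None = field(default=None, repr=False)
    force_scale: float = 0.0  # running max internal-force norm of the run

    @property
    def elastic_energy(self) -> float:
        return self.system.elastic_energy(self.u, self.eps_p)

    def plastic_strain_trace(self) -> float:
        """Max |tr eps_p| over integration points (deviatoric check)."""
        tr = self.eps_p[..., :3].sum(axis=-1)
        return float(np.max(np.abs(tr))) if tr.size else 0.0


def initial_state(system: FESystem, constraints: ConstraintSet) -> FEState:
    shape = (system.mesh.n_elements, 8, 6)
    return FEState(
        u=np.zeros(system.ndof),
        eps_p=np.zeros(shape),
        sigma=np.zeros(shape),
        lam=0.0,
        reaction=0.0,
        system=system,
        constraints=constraints,
    )


def _newton(system, constraints, u, eps_p_n, tol, max_iter, force_scale=0.0):
    """Damped Newton with backtracking line search on the residual norm.

    Perfect plasticity leaves near-zero tangent stiffness along active flow
    directions, so undamped steps can overshoot badly; halving the step
    until the reduced residual decreases restores global convergence.
    ``force_scale`` carries the running internal-force magnitude of the
    whole run so that nearly force-free states (end of unloading) converge.
    """
    Z = constraints.Z
    scale = max(1e-12, force_scale)
    eps, sigma, eps_p_new, D = system.response(u, eps_p_n)
    f_int = system.internal_force(sigma)
    rr = Z.T @ f_int
    res = float(np.linalg.norm(rr))
    for it in range(max_iter):
        scale = max(scale, float(np.linalg.norm(f_int)))
        if res <= tol * scale:
            return u, sigma, eps_p_new, f_int
        active = np.any(eps_p_new != eps_p_n, axis=-1)  # yielding points only
        Dk = D + (system.tangent_regularization * active)[..., None, None] * system.Cel
        K = system.stiffness(Dk)
        Kr = (Z.T @ (K @ Z)).tocsc()
        try:
            dq = splu(Kr).solve(-rr)
        except RuntimeError as exc:
            raise NonConvergenceError(
                "reduced stiffness is singular: an unconstrained rigid-body "
                f"mode remains ({exc})"
            ) from exc
        du = Z @ dq
        alpha = 1.0
        for _ in range(12):
            u_try = u + alpha * du
            eps, sigma_t, eps_p_t, D_t = system.response(u_try, eps_p_n)
            f_t = system.internal_force(sigma_t)
            rr_t = Z.T @ f_t
            res_t = float(np.linalg.norm(rr_t))
            if res_t < res or res_t <= tol * scale:
                break
            alpha *= 0.5
        u, sigma, eps_p_new, D, f_int, rr, res = (
            u_try, sigma_t, eps_p_t, D_t, f_t, rr_t, res_t,
        )
    if res <= 10 * tol * scale:  # accept marginal convergence
        return u, sigma, eps_p_new, f_int
    raise NonConvergenceError(f"Newton did not converge in {max_iter} iterations")


def solve_increment(state: FEState, delta_d: float, program: LoadProgram | None = None) -> FEState:
    """Advance the imposed head displacement by ``delta_d`` (mm, signed)."""
    program = program or LoadProgram()
    system, constraints = state.system, state.constraints
    if delta_d == 0.0:  # pure equilibration (e.g. after imposed Dirichlet)
        return _solve_one(state, 0.0, program)
    attempts = 0
    remaining = delta_d
    current = state
    step = delta_d
    while abs(remaining) > 1e-14:
        step = np.sign(remaining) * min(abs(step), abs(remaining))
        try:
            nxt = _solve_one(current, step, program)
        except NonConvergenceError:
            attempts += 1
            if attempts > program.max_halvings:
                raise
            step /= 2.0
            continue
        remaining -= step
        current = nxt
    return current


def _solve_one(state: FEState, delta_d: float, program: LoadProgram) -> FEState:
    system, constraints = state.system, state.constraints
    lam = state.lam + delta_d
    if state.delta_u is not None and state.delta_lam is not None and state.delta_lam != 0:
        # extrapolate the converged displacement increment; the prescribed
        # part scales exactly, the free part is a good predictor
        u0 = state.u + (delta_d / state.delta_lam) * state.delta_u
    else:
        u0 = state.u + delta_d * constraints.p
    u, sigma, eps_p, f_int = _newton(
        system, constraints, u0, state.eps_p, program.newton_tol,
        program.max_newton, force_scale=state.force_scale,
    )
    reaction = float(constraints.p @ f_int)
    d_eps_p = eps_p - state.eps_p
    sig_mid = 0.5 * (sigma + state.sigma)
    diss_inc = float(
        np.sum(
            (
                np.sum(sig_mid[..., :3] * d_eps_p[..., :3], axis=-1)
                + np.sum(sig_mid[..., 3:] * d_eps_p[..., 3:], axis=-1)
            )
            * system.w
        )
    )
    work_inc = 0.5 * (reaction + state.reaction) * delta_d
    return FEState(
        u=u,
        eps_p=eps_p,
        sigma=sigma,
        lam=lam,
        reaction=reaction,
        dissipated=state.dissipated + diss_inc,
        external_work=state.external_work + work_inc,
        system=system,
        constraints=constraints,
        loading_curve=state.loading_curve,
        delta_u=u - state.u,
        delta_lam=delta_d,
        force_scale=max(state.force_scale, float(np.linalg.norm(f_int))),
    )


@dataclass
class SideFallResult:
    curve: ForceDisplacementCurve
    F0: float
    D0: float
    state: FEState
    failed: bool


def run_side_fall(
    mesh: HexMesh,
    materials,
    config: FallConfiguration | None = None,
    program: LoadProgram | None = None,
) -> SideFallResult:
    """March the side-fall displacement program and detect failure.

    Returns the loading curve, the strength F0 (maximum reaction force),
    the displacement D0 at F0, and the converged state at the failure
    increment (or at max_displacement when failure was not reached).
    """
    config = config or FallConfiguration()
    program = program or LoadProgram()
    system = build_system(mesh, materials)
    constraints = apply_side_fall_bcs(mesh, config)
    state = initial_state(system, constraints)
    d_hist = [0.0]
    f_hist = [0.0]
    running_max = 0.0
    k_init = None
    failed = False
    n_steps = int(round(program.max_displacement / program.increment))
    prev_f = 0.0
    for i in range(n_steps):
        state = solve_increment(state, program.increment, program)
        d_hist.append(state.lam)
        f_hist.append(state.reaction)
        if k_init is None and state.lam > 0:
            k_init = state.reaction / state.lam
        drop = state.reaction < program.drop_fraction * running_max and running_max > 0
        tangent = (state.reaction - prev_f) / program.increment
        plateau = (
            k_init is not None
            and i >= 2
            and tangent < program.plateau_fraction * k_init
        )
        running_max = max(running_max, state.reaction)
        prev_f = state.reaction
        crit = program.failure_criterion
        if (crit in ("drop", "drop_or_plateau") and drop) or (
            crit in ("plateau", "drop_or_plateau") and plateau
        ):
            failed = True
            break
    if not failed:
        warnings.warn(
            "failure not reached before max_displacement; returning full curve",
            stacklevel=2,
        )
    curve = ForceDisplacementCurve(
        d=np.array(d_hist), f=np.array(f_hist), phase="loading"
    )
    i0 = int(np.argmax(curve.f))
    state.loading_curve = curve
    return SideFallResult(
        curve=curve, F0=float(curve.f[i0]), D0=float(curve.d[i0]), state=state, failed=failed
    )


@dataclass
class UnloadResult:
    curve: ForceDisplacementCurve
    D3: float
    dissipated_energy: float
    residual_energy: float


def run_unload(state: FEState, program: LoadProgram | None = None) -> UnloadResult:
    """Reverse the imposed displacement until the reaction force reaches zero.

    Returns the unloading curve, the residual displacement D3 (zero-force
    intercept), the dissipated energy (area between the loading and
    unloading curves) and the residual energy (nonlinear energy minus the
    dissipated energy).
    """
    program = program or LoadProgram()
    if state.loading_curve is None:
        raise ValueError("state carries no loading curve; run run_side_fall first")
    d_hist = [state.lam]
    f_hist = [state.reaction]
    current = state
    max_steps = int(np.ceil(state.lam / program.increment)) + 2
    for _ in range(max_steps):
        current = solve_increment(current, -program.increment, program)
        d_hist.append(current.lam)
        f_hist.append(current.reaction)
        if current.reaction <= 0.0:
            break
    else:
        raise RuntimeError("unloading did not bracket zero reaction force")
    if f_hist[-1] > 0.0:
        raise RuntimeError(
            "unloading reached zero displacement with positive force; "
            "zero crossing not bracketed"
        )
    curve = ForceDisplacementCurve(
        d=np.array(d_hist), f=np.array(f_hist), phase="unloading"
    )
    from .curve_analysis import residual_quantities, truncate_at_peak

    loading = truncate_at_peak(state.loading_curve)
    D3, e_dis, e_res = residual_quantities(loading, unloading=curve)
    return UnloadResult(curve=curve, D3=D3, dissipated_energy=e_dis, residual_energy=e_res)
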