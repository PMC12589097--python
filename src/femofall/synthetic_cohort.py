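"""Synthetic stand-ins for the clinical study data.

Three levels of synthesis, all seeded and deterministic:

* descriptor-level case-control cohorts: multivariate-normal draws per
  group, calibrated to the published group means/SDs (the between-descriptor
  correlation is unreported; a documented block-structured default is used);
* curve-level cohorts: per subject an elastic-plastic bilinear loading
  curve plus a linear unloading branch, constructed so that the extracted
  strength F0, failure displacement D0, residual displacement D3 and
  elastic limit D1 reproduce the configured group distributions exactly by
  construction;
* phantom meshes: small hexahedral femur proxies (graded beam or a
  swept-ellipse femur-like shape) with cortical shell / trabecular core
  compartments and stochastic density fields, carrying the node sets the
  side-fall solver needs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .materials import TissueCompartment
from .mesh import HexMesh

__all__ = [
    "GroupSpec",
    "PhantomSpec",
    "reference_cohort",
    "group_specs_from_reference",
    "default_correlation",
    "sample_descriptor_cohort",
    "sample_curve_cohort",
    "make_phantom",
    "density_summaries",
    "cortical_sbmd",
]

DESCRIPTOR_BLOCKS = {
    "density": ("aBMD_gcm2", "vBMD_int_mgcm3", "vBMD_trab_mgcm3", "sBMD_cort_mgcm2"),
    "force": ("F0_N", "F1_N"),
    "displacement": ("D0_mm", "D1_mm", "D2_mm", "D3_mm"),
    "energy": ("E_nl_Nmm", "E_lin_Nmm", "E_dis_Nmm", "E_res_Nmm"),
}
# within/between block correlation defaults (unreported in the source data;
# see docs/methods.md for the rationale and sensitivity caveat)
_WITHIN = {"density": 0.8, "force": 0.9, "displacement": 0.8, "energy": 0.7}
_BETWEEN = {
    frozenset(("force", "displacement")): 0.6,
    frozenset(("force", "energy")): 0.6,
    frozenset(("displacement", "energy")): 0.5,
    frozenset(("density", "force")): 0.3,
    frozenset(("density", "displacement")): 0.2,
    frozenset(("density", "energy")): 0.2,
}


def reference_cohort() -> dict:
    """The packaged reference case-control distribution fixture."""
    with importlib.resources.files("femofall.data").joinpath(
        "reference_cohort.yaml"
    ).open() as fh:
        return yaml.safe_load(fh)


def default_correlation(columns) -> pd.DataFrame:
    """Block-structured default correlation matrix for the given columns."""
    blocks = {}
    for name, cols in DESCRIPTOR_BLOCKS.items():
        for c in cols:
            blocks[c] = name
    unknown = [c for c in columns if c not in blocks]
    if unknown:
        raise KeyError(f"no correlation block for columns {unknown}")
    k = len(columns)
    R = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            bi, bj = blocks[columns[i]], blocks[columns[j]]
            r = _WITHIN[bi] if bi == bj else _BETWEEN[frozenset((bi, bj))]
            R[i, j] = R[j, i] = r
    _require_positive_definite(R, columns)
    return pd.DataFrame(R, index=list(columns), columns=list(columns))


def _require_positive_definite(R: np.ndarray, columns) -> None:
    w = np.linalg.eigvalsh(R)
    if w.min() <= 1e-10:
        w_clip = np.clip(w, 1e-6, None)
        raise ValueError(
            "correlation matrix is not positive definite "
            f"(min eigenvalue {w.min():.3e}); consider the nearest-PD repair: "
            f"clip eigenvalues to {w_clip.min():.1e} and renormalize the diagonal"
        )


@dataclass
class GroupSpec:
    """Sampling specification for one study group."""

    label: str
    n: int
    means: dict
    sds: dict
    correlation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.label not in ("control", "fracture"):
            raise ValueError("label must be 'control' or 'fracture'")
        if self.n <= 0:
            raise ValueError("group size must be positive")
        if set(self.means) != set(self.sds):
            raise ValueError("means and sds must cover the same descriptors")
        if any(s <= 0 for s in self.sds.values()):
            raise ValueError("all sds must be positive")

    @property
    def columns(self) -> list:
        return list(self.means)

    def corr_matrix(self, columns) -> np.ndarray:
        if self.correlation is None:
            return default_correlation(columns).to_numpy()
        R = self.correlation.loc[list(columns), list(columns)].to_numpy()
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation must be symmetric with unit diagonal")
        _require_positive_definite(R, columns)
        return R


def group_specs_from_reference(
    columns=None, n: int | None = None, correlation: pd.DataFrame | None = None
) -> tuple[GroupSpec, GroupSpec]:
    """Control and fracture GroupSpecs built from the packaged fixture."""
    ref = reference_cohort()
    out = []
    for label in ("control", "fracture"):
        grp = ref["groups"][label]
        cols = list(columns) if columns is not None else [
            c for c in grp if c != "n"
        ]
        out.append(
            GroupSpec(
                label=label,
                n=int(n if n is not None else grp["n"]),
                means={c: grp[c]["mean"] for c in cols},
                sds={c: grp[c]["sd"] for c in cols},
                correlation=correlation,
            )
        )
    return tuple(out)


def _sample_group(spec: GroupSpec, columns, rng, max_retries: int = 100) -> np.ndarray:
    mu = np.array([spec.means[c] for c in columns])
    sd = np.array([spec.sds[c] for c in columns])
    R = spec.corr_matrix(columns) if len(columns) > 1 else np.eye(1)
    L = np.linalg.cholesky(R)
    X = np.empty((spec.n, len(columns)))
    need = np.arange(spec.n)
    for _ in range(max_retries):
        z = rng.standard_normal((len(need), len(columns)))
        X[need] = mu + sd * (z @ L.T)
        need = need[np.any(X[need] <= 0.0, axis=1)]
        if len(need) == 0:
            return X
    raise RuntimeError("positivity rejection sampling exceeded retry budget")


def sample_descriptor_cohort(
    control: GroupSpec,
    fracture: GroupSpec,
    seed,
    columns=None,
) -> pd.DataFrame:
    """Descriptor-level case-control cohort (one MVN draw per subject).

    Non-positive draws are rejected and re-sampled, keeping every physical
    quantity positive.  Deterministic for a given (seed, specs) pair.
    """
    rng = np.random.default_rng(seed)
    columns = list(columns) if columns is not None else control.columns
    frames = []
    for spec, label, grp_id in ((control, "control", 0), (fracture, "fracture", 1)):
        X = _sample_group(spec, columns, rng)
        df = pd.DataFrame(X, columns=columns)
        df.insert(0, "group", label)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "subject_id", np.arange(len(out)))
    return out


# ---------------------------------------------------------------------------
# curve-level cohort


@dataclass
class CurveCohort:
    """Curve-level synthetic cohort: per-subject loading/unloading curves."""

    params: pd.DataFrame  # drawn F0/D0/D3/D1 (+ derived k1, F1, k2)
    loading: list
    unloading: list


_CURVE_COLUMNS = ("F0_N", "D0_mm", "D3_mm", "D1_mm")


def sample_curve_cohort(
    spec: GroupSpec,
    seed,
    n: int | None = None,
    n_points: int = 60,
    knee_frac: float = 0.1,
    max_retries: int = 100,
) -> CurveCohort:
    """Elastic-plastic curve family calibrated to a group specification.

    Per subject the quadruple (F0, D0, D3, D1) is drawn from the group's
    multivariate normal; the loading curve is bilinear with initial slope
    k1 = F0 / (D0 - D3) and breakpoint (D1, k1*D1) -- so that elastic
    unloading from (D0, F0) at slope k1 lands exactly at D3 -- optionally
    blended over a quadratic knee of relative width ``knee_frac``.  D1 is
    conditionally re-drawn (and as a last resort clamped) to keep
    D1 < D0 - D3, which guarantees F0 >= F1 and 0 <= k2 <= k1; the F0, D0
    and D3 marginals are untouched by this repair, which is what makes the
    extracted strength and residual displacement match the configured
    moments by construction.
    """
    from .curve_analysis import ForceDisplacementCurve

    rng = np.random.default_rng(seed)
    n = int(n if n is not None else spec.n)
    cols = list(_CURVE_COLUMNS)
    missing = [c for c in cols if c not in spec.means]
    if missing:
        raise KeyError(f"curve-level sampling needs {missing} in the group spec")
    mu = np.array([spec.means[c] for c in cols])
    sd = np.array([spec.sds[c] for c in cols])
    R = spec.corr_matrix(cols)
    L = np.linalg.cholesky(R)
    cov = np.outer(sd, sd) * R

    X = np.empty((n, 4))
    need = np.arange(n)
    for _ in range(max_retries):
        z = rng.standard_normal((len(need), 4))
        X[need] = mu + sd * (z @ L.T)
        F0, D0, D3, D1 = X[need].T
        bad = (F0 <= 0) | (D1 <= 0) | (D3 <= 0) | (D0 - D3 <= 0.05 * D0)
        need = need[bad]
        if len(need) == 0:
            break
    else:
        raise RuntimeError("curve-parameter rejection exceeded retry budget")

    # conditional repair of D1 given (F0, D0, D3): redraw from the
    # conditional normal until D1 < D0 - D3, then clamp
    i1 = 3
    rest = [0, 1, 2]
    S12 = cov[i1, rest]
    S22i = np.linalg.inv(cov[np.ix_(rest, rest)])
    w = S12 @ S22i
    cond_sd = float(np.sqrt(cov[i1, i1] - S12 @ S22i @ S12))
    limit = 0.98 * (X[:, 1] - X[:, 2])
    viol = np.flatnonzero(X[:, 3] >= limit)
    for i in viol:
        cmean = mu[i1] + w @ (X[i, rest] - mu[rest])
        for _ in range(max_retries):
            d1 = cmean + cond_sd * rng.standard_normal()
            if 0.0 < d1 < limit[i]:
                X[i, 3] = d1
                break
        else:
            X[i, 3] = limit[i]

    F0, D0, D3, D1 = X.T
    k1 = F0 / (D0 - D3)
    F1 = k1 * D1
    k2 = (F0 - F1) / (D0 - D1)
    loading, unloading = [], []
    for j in range(n):
        d = np.unique(
            np.concatenate(
                [np.linspace(0.0, D0[j], n_points), [D1[j]]]
            )
        )
        f = np.where(d <= D1[j], k1[j] * d, F1[j] + k2[j] * (d - D1[j]))
        if knee_frac > 0:
            # quadratic blend on [D1*(1-w), D1*(1+w)]: tangent-continuous,
            # preserves endpoints, leaves F0/D0/D3 untouched
            wj = knee_frac * D1[j]
            lo, hi = D1[j] - wj, min(D1[j] + wj, D0[j] - 1e-12)
            m = (d > lo) & (d < hi)
            if np.any(m):
                t = (d[m] - lo) / (hi - lo)
                f_lo = k1[j] * lo
                f_hi = F1[j] + k2[j] * (hi - D1[j])
                df_lo = k1[j] * (hi - lo)
                f[m] = (
                    f_lo
                    + df_lo * t
                    + (f_hi - f_lo - df_lo) * t**2
                )
        loading.append(ForceDisplacementCurve(d=d, f=f, phase="loading"))
        du = np.linspace(D0[j], D3[j] - 1e-9, 10)
        fu = np.maximum(k1[j] * (du - D3[j]), 0.0)
        fu[-1] = 0.0
        unloading.append(ForceDisplacementCurve(d=du, f=fu, phase="unloading"))
    params = pd.DataFrame(
        dict(F0_N=F0, D0_mm=D0, D3_mm=D3, D1_mm=D1, k1_Nmm=k1, F1_N=F1, k2_Nmm=k2)
    )
    return CurveCohort(params=params, loading=loading, unloading=unloading)


# ---------------------------------------------------------------------------
# phantoms


@dataclass
class PhantomSpec:
    """Generation parameters for a femur-proxy hexahedral phantom."""

    geometry: str = "graded_beam"  # or "femur_like"
    nx: int = 4
    ny: int = 4
    nz: int = 20
    length_mm: float = 100.0
    width_mm: float = 20.0
    shell_layers: int = 1
    cortical_density: float = 850.0  # mg/cm^3
    trabecular_density: float = 180.0  # mg/cm^3
    density_noise: float = 0.05  # relative SD of the nodal density field

    def __post_init__(self) -> None:
        if self.geometry not in ("graded_beam", "femur_like"):
            raise ValueError("geometry must be 'graded_beam' or 'femur_like'")
        if self.shell_layers < 1:
            raise ValueError("cortical shell needs at least one element layer")
        if min(self.cortical_density, self.trabecular_density) <= 0:
            raise ValueError("densities must be positive")
        if self.geometry == "graded_beam" and self.shell_layers >= min(self.nx, self.ny) / 2:
            raise ValueError("cortical shell thicker than the cross-section")


def make_phantom(spec: PhantomSpec, seed=0):
    """Build (HexMesh, per-node density field in mg/cm^3) for a phantom."""
    if spec.geometry == "graded_beam":
        return _graded_beam(spec, seed)
    return _femur_like(spec, seed)


def _structured_hexes(nx, ny, nz):
    def nid(i, j, k):
        return (k * (ny + 1) + j) * (nx + 1) + i

    elems = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                elems.append(
                    [
                        nid(i, j, k),
                        nid(i + 1, j, k),
                        nid(i + 1, j + 1, k),
                        nid(i, j + 1, k),
                        nid(i, j, k + 1),
                        nid(i + 1, j, k + 1),
                        nid(i + 1, j + 1, k + 1),
                        nid(i, j + 1, k + 1),
                    ]
                )
    return np.array(elems, dtype=np.int64)


def _graded_beam(spec: PhantomSpec, seed):
    nx, ny, nz = spec.nx, spec.ny, spec.nz
    rng = np.random.default_rng(seed)
    xs = np.linspace(0, spec.width_mm, nx + 1)
    ys = np.linspace(0, spec.width_mm, ny + 1)
    zs = np.linspace(0, spec.length_mm, nz + 1)
    K, J, I = np.meshgrid(zs, ys, xs, indexing="ij")
    nodes = np.column_stack([I.ravel(), J.ravel(), K.ravel()])
    elements = _structured_hexes(nx, ny, nz)
    comp = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                ring = min(i, j, nx - 1 - i, ny - 1 - j) < spec.shell_layers
                comp.append(
                    TissueCompartment.CORTICAL if ring else TissueCompartment.TRABECULAR
                )
    # nodal density: cortical level on the outer surface, trabecular inside
    nn = len(nodes)
    on_surface = (
        np.isclose(nodes[:, 0], 0)
        | np.isclose(nodes[:, 0], spec.width_mm)
        | np.isclose(nodes[:, 1], 0)
        | np.isclose(nodes[:, 1], spec.width_mm)
    )
    base = np.where(on_surface, spec.cortical_density, spec.trabecular_density)
    density = base * (1.0 + spec.density_noise * rng.standard_normal(nn))
    density = np.clip(density, 0.2 * spec.trabecular_density, None)
    ztol = 1e-9
    sets = {
        "shaft_end": np.flatnonzero(np.abs(nodes[:, 2]) < ztol),
        "head_surface": np.flatnonzero(np.abs(nodes[:, 2] - spec.length_mm) < ztol),
        "trochanter_surface": np.flatnonzero(
            np.isclose(nodes[:, 0], 0)
            & (nodes[:, 2] > 0.1 * spec.length_mm)
            & (nodes[:, 2] < 0.35 * spec.length_mm)
        ),
    }
    mesh = HexMesh(nodes=nodes, elements=elements, compartment=comp, node_sets=sets)
    return mesh, density


def _femur_like(spec: PhantomSpec, seed):
    """Swept-ellipse femur proxy: straight shaft, narrowed angled neck, head.

    The centerline runs along +z through the shaft then tilts toward +x
    through the neck; cross-sections are squares mapped onto ellipses whose
    radii shrink at the neck and swell again at the head.  The outer element
    ring is cortical.  Densities taper toward the neck so the phantom
    reaches its limit load within a few mm of head displacement.
    """
    rng = np.random.default_rng(seed)
    nc = max(spec.nx, 3)
    ns = max(spec.nz, 10)
    length = spec.length_mm
    t = np.linspace(0.0, 1.0, ns + 1)
    # centerline: shaft for t<0.5, then a 45-degree bend toward +x
    center = np.zeros((ns + 1, 3))
    bend = 0.5
    for i, ti in enumerate(t):
        if ti <= bend:
            center[i] = [0.0, 0.0, length * ti]
        else:
            s = (ti - bend) * length
            center[i] = [s * np.sin(np.radians(45)), 0.0, length * bend + s * np.cos(np.radians(45))]
    # section radius profile: shaft 1.0 -> neck 0.62 -> head 1.05 (relative)
    rel = np.interp(t, [0.0, 0.5, 0.62, 0.8, 0.9, 1.0], [1.0, 0.95, 0.8, 0.62, 1.0, 1.05])
    radius = 0.5 * spec.width_mm * rel

    # square -> disc mapping for the cross-section grid
    uv = np.linspace(-1.0, 1.0, nc + 1)
    U, V = np.meshgrid(uv, uv, indexing="ij")
    m = np.maximum(np.abs(U), np.abs(V))
    r2 = np.sqrt(U**2 + V**2)
    scale = np.where(r2 > 0, m / np.where(r2 > 0, r2, 1.0), 0.0)
    P = np.stack([U * scale, V * scale], axis=-1)  # unit-disc points

    # sweep frame: section normal along the centerline tangent
    nodes = []
    for i in range(ns + 1):
        tang = (
            center[min(i + 1, ns)] - center[max(i - 1, 0)]
        )
        tang = tang / np.linalg.norm(tang)
        e1 = np.cross(tang, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(tang, e1)
        for a in range(nc + 1):
            for b in range(nc + 1):
                # fast index b runs along e1 so (e1, e2, tangent) stays
                # right-handed for the structured connectivity
                xy = P[b, a] * radius[i]
                nodes.append(center[i] + xy[0] * e1 + xy[1] * e2)
    nodes = np.asarray(nodes)
    elements = _structured_hexes(nc, nc, ns)
    comp = []
    for k in range(ns):
        for j in range(nc):
            for i in range(nc):
                ring = min(i, j, nc - 1 - i, nc - 1 - j) < spec.shell_layers
                comp.append(
                    TissueCompartment.CORTICAL if ring else TissueCompartment.TRABECULAR
                )
    nn = len(nodes)
    per_sec = (nc + 1) ** 2
    sec_of_node = np.repeat(np.arange(ns + 1), per_sec)
    tn = t[sec_of_node]
    # density taper: full density in the shaft, reduced through neck/head
    taper = np.interp(tn, [0.0, 0.5, 0.7, 1.0], [1.0, 0.9, 0.55, 0.6])
    uvg = np.tile(m.ravel(), ns + 1)  # 0 at the core, 1 on the surface
    base = np.where(
        uvg > 1.0 - 1e-9, spec.cortical_density, spec.trabecular_density
    )
    density = base * taper * (1.0 + spec.density_noise * rng.standard_normal(nn))
    density = np.clip(density, 0.2 * spec.trabecular_density, None)

    head_secs = tn > 0.9 - 1e-9
    troch = (
        (np.abs(tn - 0.5) < 0.08)
        & (nodes[:, 0] < -0.8 * radius[np.searchsorted(t, 0.5)])
    )
    sets = {
        "shaft_end": np.flatnonzero(sec_of_node == 0),
        "head_surface": np.flatnonzero(head_secs & (uvg > 1.0 - 1e-9) | (sec_of_node == ns)),
        "trochanter_surface": np.flatnonzero(troch),
    }
    mesh = HexMesh(nodes=nodes, elements=elements, compartment=comp, node_sets=sets)
    return mesh, density


# ---------------------------------------------------------------------------
# density summaries


def cortical_sbmd(cortical_vbmd_mgcm3: float, thickness_cm: float) -> float:
    """Surface BMD (mg/cm^2) = cortical vBMD (mg/cm^3) x thickness (cm)."""
    return cortical_vbmd_mgcm3 * thickness_cm


def density_summaries(mesh: HexMesh, density, thickness_cm: float | None = None) -> dict:
    """Compartmental density summaries of a labelled phantom.

    Volume-weighted mean vBMD per compartment and overall (integral vBMD,
    all mg/cm^3), the mean cortical thickness (cm; estimated as cortical
    volume over outer-surface area unless given) and the cortical surface
    BMD (mg/cm^2).
    """
    from ._hex8 import bbar_matrices, shape_functions

    _, _, vol = bbar_matrices(mesh.element_coords())
    N = shape_functions(np.zeros((1, 3)))  # centroid values
    dens = np.asarray(density, dtype=float)
    rho_e = np.einsum("la,ea->el", N, dens[mesh.elements])[:, 0]
    is_cort = np.array([c is TissueCompartment.CORTICAL for c in mesh.compartment])
    if not is_cort.any() or is_cort.all():
        raise ValueError("phantom must contain both compartments")
    v_cort = vol[is_cort].sum()
    v_trab = vol[~is_cort].sum()
    vbmd_cort = float((rho_e[is_cort] * vol[is_cort]).sum() / v_cort)
    vbmd_trab = float((rho_e[~is_cort] * vol[~is_cort]).sum() / v_trab)
    vbmd_int = float((rho_e * vol).sum() / vol.sum())
    if thickness_cm is None:
        area = _outer_surface_area(mesh)
        thickness_cm = float(v_cort / area) / 10.0  # mm -> cm
    return dict(
        integral_vbmd_mgcm3=vbmd_int,
        trabecular_vbmd_mgcm3=vbmd_trab,
        cortical_vbmd_mgcm3=vbmd_cort,
        cortical_thickness_cm=thickness_cm,
        cortical_sbmd_mgcm2=cortical_sbmd(vbmd_cort, thickness_cm),
    )


_FACES = np.array(
    [
        [0, 3, 2, 1],
        [4, 5, 6, 7],
        [0, 1, 5, 4],
        [1, 2, 6, 5],
        [2, 3, 7, 6],
        [3, 0, 4, 7],
    ]
)


def _outer_surface_area(mesh: HexMesh) -> float:
    """Area (mm^2) of the boundary faces of the mesh, end caps excluded."""
    from collections import Counter

    face_count: Counter = Counter()
    for el in mesh.elements:
        for f in _FACES:
            face_count[frozenset(el[f])] += 1
    area = 0.0
    zmin, zmax = mesh.nodes[:, 2].min(), mesh.nodes[:, 2].max()
    for el in mesh.elements:
        for f in _FACES:
            key = frozenset(el[f])
            if face_count[key] != 1:
                continue
            quad = mesh.nodes[el[f]]
            zc = quad[:, 2].mean()
            if np.isclose(zc, zmin, atol=1e-6) or np.isclose(zc, zmax, atol=1e-6):
                continue  # end caps are not periosteal surface
            d1 = quad[2] - quad[0]
            d2 = quad[3] - quad[1]
            area += 0.5 * np.linalg.norm(np.cross(d1, d2))
    return area
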