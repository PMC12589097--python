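"""Mechanical descriptors from force-displacement curves.

A loading curve (head displacement d in mm vs. reaction force f in N) is
decomposed into an origin-anchored continuous bilinear approximation; the
breakpoint (D1, F1) marks the linear-elastic limit.  Ten descriptors follow:

======  =============================================  =========
F0, D0  strength (max force) and its displacement      N, mm
E_nl    nonlinear energy, area under loading to D0     N*mm
F1, D1  bilinear breakpoint force / displacement       N, mm
E_lin   linear elastic energy, 0.5*F1*D1               N*mm
D2      nonlinear (post-yield) deformation, D0 - D1    mm
D3      residual displacement after unloading          mm
E_dis   dissipated energy (loading minus recovered)    N*mm
E_res   residual (elastic) energy, E_nl - E_dis        N*mm
======  =============================================  =========

D3/E_dis come from a simulated unloading curve when available, otherwise
from elastic unloading at the initial slope k1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "ForceDisplacementCurve",
    "BilinearFit",
    "DescriptorSet",
    "DESCRIPTOR_COLUMNS",
    "extract_strength",
    "truncate_at_peak",
    "fit_bilinear",
    "nonlinear_energy",
    "linear_elastic_quantities",
    "nonlinear_deformation",
    "residual_quantities",
    "descriptor_set",
    "read_curve_csv",
    "write_curve_csv",
]

DESCRIPTOR_COLUMNS = (
    "F0_N",
    "D0_mm",
    "E_nl_Nmm",
    "F1_N",
    "D1_mm",
    "E_lin_Nmm",
    "D2_mm",
    "D3_mm",
    "E_dis_Nmm",
    "E_res_Nmm",
)


@dataclass(frozen=True)
class ForceDisplacementCurve:
    """Sampled force-displacement record for one loading phase."""

    d: np.ndarray
    f: np.ndarray
    phase: str = "loading"

    def __post_init__(self) -> None:
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))
        object.__setattr__(self, "f", np.asarray(self.f, dtype=float))
        if self.d.shape != self.f.shape or self.d.ndim != 1 or len(self.d) < 2:
            raise ValueError("curve needs matching 1D arrays of length >= 2")
        if self.phase not in ("loading", "unloading"):
            raise ValueError("phase must be 'loading' or 'unloading'")
        diffs = np.diff(self.d)
        if self.phase == "loading":
            if np.any(diffs <= 0):
                raise ValueError("loading displacement must be strictly increasing")
            if self.d[0] != 0.0 or self.f[0] != 0.0:
                raise ValueError("loading curve must start at (0, 0)")
        elif np.any(diffs >= 0):
            raise ValueError("unloading displacement must be strictly decreasing")

    def __len__(self) -> int:
        return len(self.d)


@dataclass(frozen=True)
class BilinearFit:
    """Continuous origin-anchored two-segment least-squares fit."""

    k1: float  # N/mm
    k2: float  # N/mm
    D1: float  # mm
    F1: float  # N
    sse: float
    degenerate: bool = False

    def predict(self, d):
        d = np.asarray(d, dtype=float)
        return np.where(d <= self.D1, self.k1 * d, self.F1 + self.k2 * (d - self.D1))


@dataclass(frozen=True)
class DescriptorSet:
    """The ten mechanical descriptors of one simulated femur."""

    F0: float
    D0: float
    E_nl: float
    F1: float
    D1: float
    E_lin: float
    D2: float
    D3: float
    E_dis: float
    E_res: float

    def validate(self, rtol: float = 1e-9, atol: float = 1e-9) -> None:
        checks = [
            self.F0 + atol >= self.F1 >= -atol,
            self.D0 + atol >= self.D1 >= -atol,
            abs(self.D2 - (self.D0 - self.D1)) <= atol + rtol * max(self.D0, 1.0),
            -atol <= self.D3 <= self.D0 + atol,
            -atol <= self.E_dis <= self.E_nl + atol + rtol * abs(self.E_nl),
            abs(self.E_res - (self.E_nl - self.E_dis))
            <= atol + rtol * max(abs(self.E_nl), 1.0),
        ]
        if not all(checks):
            raise ValueError(f"descriptor invariants violated: {self}")

    def to_dict(self) -> dict:
        return dict(
            zip(
                DESCRIPTOR_COLUMNS,
                (
                    self.F0,
                    self.D0,
                    self.E_nl,
                    self.F1,
                    self.D1,
                    self.E_lin,
                    self.D2,
                    self.D3,
                    self.E_dis,
                    self.E_res,
                ),
            )
        )


def extract_strength(curve: ForceDisplacementCurve) -> tuple[float, float]:
    """(F0, D0): maximum force and its displacement, first index on ties."""
    if curve.phase != "loading":
        raise ValueError("strength is defined on the loading curve")
    i = int(np.argmax(curve.f))
    return float(curve.f[i]), float(curve.d[i])


def truncate_at_peak(curve: ForceDisplacementCurve) -> ForceDisplacementCurve:
    """Loading curve cut at the strength point D0 (inclusive)."""
    i = int(np.argmax(curve.f))
    if i == 0:
        raise ValueError("curve peaks at the origin")
    return ForceDisplacementCurve(d=curve.d[: i + 1], f=curve.f[: i + 1], phase="loading")


def _segment_lstsq(d, f, Db):
    phi1 = np.minimum(d, Db)
    phi2 = np.maximum(d - Db, 0.0)
    A = np.column_stack([phi1, phi2])
    AtA = A.T @ A
    Atf = A.T @ f
    try:
        k = np.linalg.solve(AtA, Atf)
    except np.linalg.LinAlgError:
        k = np.linalg.lstsq(A, f, rcond=None)[0]
    resid = f - A @ k
    return k[0], k[1], float(resid @ resid)


def fit_bilinear(curve: ForceDisplacementCurve, grid: int = 200) -> BilinearFit:
    """Best continuous bilinear approximation anchored at the origin.

    The breakpoint is searched on a displacement grid (union of ``grid``
    uniform candidates and the sample abscissae between the 2nd and the
    penultimate points) and refined locally by bounded scalar minimization
    of the total SSE.
    """
    d, f = curve.d, curve.f
    if len(d) < 4:
        return _degenerate_fit(d, f)
    lo, hi = d[1], d[-2]
    if hi <= lo:
        return _degenerate_fit(d, f)
    candidates = np.union1d(np.linspace(lo, hi, grid), d[1:-1])
    sses = np.array([_segment_lstsq(d, f, Db)[2] for Db in candidates])
    best = int(np.argmin(sses))
    a = candidates[max(best - 1, 0)]
    b = candidates[min(best + 1, len(candidates) - 1)]
    if b > a:
        res = minimize_scalar(
            lambda Db: _segment_lstsq(d, f, Db)[2],
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-10 * max(hi, 1.0)},
        )
        Db = float(res.x) if res.fun <= sses[best] else float(candidates[best])
    else:
        Db = float(candidates[best])
    k1, k2, sse = _segment_lstsq(d, f, Db)
    if k1 <= 0 or not np.isfinite(sse):
        return _degenerate_fit(d, f)
    if k2 >= k1 * (1.0 - 1e-9):
        # no concave second regime: treat as a single line through the data
        return _degenerate_fit(d, f)
    return BilinearFit(k1=float(k1), k2=float(k2), D1=Db, F1=float(k1 * Db), sse=sse)


def _degenerate_fit(d, f) -> BilinearFit:
    k1 = float((d @ f) / (d @ d))
    resid = f - k1 * d
    D1 = float(d[-1])
    return BilinearFit(
        k1=k1, k2=k1, D1=D1, F1=k1 * D1, sse=float(resid @ resid), degenerate=True
    )


def nonlinear_energy(curve: ForceDisplacementCurve) -> float:
    """Trapezoidal area under the loading curve up to its last sample."""
    if np.any(np.diff(curve.d) <= 0):
        raise ValueError("displacement must be sorted increasing")
    return float(np.trapezoid(curve.f, curve.d))


def linear_elastic_quantities(fit: BilinearFit) -> tuple[float, float, float]:
    """(F1, D1, E_lin) with E_lin the triangle area 0.5*F1*D1."""
    return fit.F1, fit.D1, 0.5 * fit.F1 * fit.D1


def nonlinear_deformation(D0: float, D1: float) -> float:
    """Post-yield displacement D2 = D0 - D1."""
    if D1 > D0 + 1e-12:
        raise ValueError(f"D1={D1} exceeds D0={D0}")
    return max(D0 - D1, 0.0)


def residual_quantities(
    loading: ForceDisplacementCurve,
    unloading: ForceDisplacementCurve | None = None,
    k1: float | None = None,
) -> tuple[float, float, float]:
    """(D3, E_dis, E_res) from the unloading curve or the elastic fallback.

    With an unloading curve the residual displacement D3 is the zero-force
    intercept (linear interpolation between the bracketing samples) and the
    dissipated energy is the loading area minus the recovered area.  Without
    one, elastic unloading at slope ``k1`` gives D3 = D0 - F0/k1 and the
    recovered area is the triangle 0.5*F0*(D0 - D3).
    """
    F0, D0 = extract_strength(loading)
    e_nl = nonlinear_energy(loading)
    if unloading is not None:
        f = unloading.f
        d = unloading.d
        if f[-1] > 0:
            raise ValueError("unloading curve does not reach zero force")
        # first bracketing pair along the descending branch
        idx = np.flatnonzero(f <= 0.0)[0]
        if idx == 0:
            D3 = float(d[0])
        else:
            f1, f2 = f[idx - 1], f[idx]
            d1, d2 = d[idx - 1], d[idx]
            D3 = float(d1 + (0.0 - f1) * (d2 - d1) / (f2 - f1))
        dd = d[: idx + 1].copy()
        ff = f[: idx + 1].copy()
        dd[-1] = D3
        ff[-1] = 0.0
        recovered = float(np.trapezoid(ff[::-1], dd[::-1]))
    else:
        if k1 is None or k1 <= 0:
            raise ValueError("elastic fallback needs a positive slope k1")
        D3 = D0 - F0 / k1
        recovered = 0.5 * F0 * (D0 - D3)
    D3 = min(max(D3, 0.0), D0)
    e_dis = max(e_nl - recovered, 0.0)
    e_res = e_nl - e_dis
    return D3, e_dis, e_res


def descriptor_set(
    loading: ForceDisplacementCurve,
    unloading: ForceDisplacementCurve | None = None,
    grid: int = 200,
) -> DescriptorSet:
    """All ten descriptors from a loading (and optional unloading) curve."""
    F0, D0 = extract_strength(loading)
    trunc = truncate_at_peak(loading)
    e_nl = nonlinear_energy(trunc)
    fit = fit_bilinear(trunc, grid=grid)
    F1, D1, e_lin = linear_elastic_quantities(fit)
    F1 = min(F1, F0)
    D1 = min(D1, D0)
    D2 = nonlinear_deformation(D0, D1)
    D3, e_dis, e_res = residual_quantities(trunc, unloading=unloading, k1=fit.k1)
    return DescriptorSet(
        F0=F0, D0=D0, E_nl=e_nl, F1=F1, D1=D1, E_lin=0.5 * F1 * D1,
        D2=D2, D3=D3, E_dis=e_dis, E_res=e_res,
    )


def write_curve_csv(path, *curves: ForceDisplacementCurve) -> None:
    frames = [
        pd.DataFrame(
            {"displacement_mm": c.d, "force_N": c.f, "phase": c.phase}
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_curve_csv(path) -> list[ForceDisplacementCurve]:
    df = pd.read_csv(path)
    out = []
    for phase, grp in df.groupby("phase", sort=False):
        out.append(
            ForceDisplacementCurve(
                d=grp["displacement_mm"].to_numpy(),
                f=grp["force_N"].to_numpy(),
                phase=str(phase),
            )
        )
    return out
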