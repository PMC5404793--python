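"""Extracellular potentials by the line-source approximation.

Each compartment is a straight line segment carrying a uniform membrane
current; the potential at a point in a homogeneous resistive medium of
conductivity sigma is the closed-form line integral of point sources, and
fields superpose linearly.  The soma is treated as a thick line source along
the cell axis, and points closer to a segment than its radius are evaluated
at the radius (the membrane surface), which also removes the logarithmic
singularity on the axis.

The source current of a compartment is the total current it passes to the
extracellular space -- ionic plus capacitive.  By current conservation this
equals the net axial current received plus any electrode current, which is
how it is computed here (no numerical differentiation of the voltage).  The
segment currents therefore sum to the externally injected current at every
instant: the system is monopole-free in the absence of an electrode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cable import SimResult

__all__ = [
    "LineSourceSet",
    "FieldGrid",
    "segment_potential",
    "line_sources_from_result",
    "field_snapshot",
    "virtual_electrode",
]

DEFAULT_SIGMA_S_M = 0.3  # extracellular conductivity, S/m


def segment_potential(p0, p1, current_pa: float, point, sigma: float = DEFAULT_SIGMA_S_M,
                      radius_um: float = 0.0) -> float:
    """Potential (uV) at ``point`` of a uniform line current.

    ``p0``, ``p1``, ``point`` are 3-D coordinates in um; ``current_pa`` is
    the total membrane current of the segment (outward-positive).  Uses the
    arcsinh form of the line-source integral,
    phi = I / (4 pi sigma L) * [asinh(h1/r) - asinh(h0/r)],
    with h the longitudinal and r the radial distance; r is floored at
    ``radius_um``.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    point = np.asarray(point, dtype=float)
    axis = p1 - p0
    length = float(np.linalg.norm(axis))
    if length <= 0:
        raise ValueError("segment has zero length")
    u = axis / length
    rel = point - p0
    s = float(rel @ u)
    r = float(np.linalg.norm(rel - s * u))
    r = max(r, radius_um, 1e-9)
    val = np.arcsinh((length - s) / r) - np.arcsinh(-s / r)
    # pA / (S/m * um) -> uV  (1e-12 A / (S/m * 1e-6 m) = 1e-6 V)
    return float(current_pa / (4.0 * np.pi * sigma * length) * val)


@dataclass
class LineSourceSet:
    """Per-compartment line segments with their membrane-current traces.

    ``currents`` is (T, n_segments) in pA, outward-positive; at every sample
    the segment currents sum to the externally injected current.
    """

    p0: np.ndarray            # (n, 3) um
    p1: np.ndarray            # (n, 3)
    radius: np.ndarray        # (n,)
    t: np.ndarray             # (T,) ms
    currents: np.ndarray      # (T, n) pA
    sigma: float = DEFAULT_SIGMA_S_M

    def potential_weights(self, points: np.ndarray) -> np.ndarray:
        """(n_points, n_segments) matrix W so that phi = W @ I (uV per pA).

        Vectorized form of :func:`segment_potential` with unit current.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        w = np.empty((len(points), len(self.p0)))
        for j in range(len(self.p0)):
            p0, p1 = self.p0[j], self.p1[j]
            axis = p1 - p0
            length = float(np.linalg.norm(axis))
            u = axis / length
            rel = points - p0
            s = rel @ u
            r = np.linalg.norm(rel - s[:, None] * u, axis=1)
            r = np.maximum(r, max(float(self.radius[j]), 1e-9))
            val = np.arcsinh((length - s) / r) - np.arcsinh(-s / r)
            w[:, j] = val / (4.0 * np.pi * self.sigma * length)
        return w

    def potential_at(self, point, time_index=None) -> np.ndarray | float:
        w = self.potential_weights(np.asarray(point)[None, :])[0]
        if time_index is None:
            return self.currents @ w
        return float(self.currents[time_index] @ w)


def line_sources_from_result(result: SimResult,
                             sigma: float = DEFAULT_SIGMA_S_M) -> LineSourceSet:
    """Build the line-source set of a simulated cell laid out along the
    x-axis (soma spanning negative x, axon positive x)."""
    g = result.graph
    n = g.n
    p0 = np.zeros((n, 3))
    p1 = np.zeros((n, 3))
    p0[:, 0] = g.x0
    p1[:, 0] = g.x1
    return LineSourceSet(
        p0=p0, p1=p1, radius=g.radius.astype(float),
        t=result.t, currents=result.membrane_source_currents(), sigma=sigma)


@dataclass
class FieldGrid:
    """Extracellular potential (uV) and field E = -grad(phi) (uV/um = V/m)
    on a 2-D grid in a plane containing the cell axis."""

    x: np.ndarray             # (nx,) um
    z: np.ndarray             # (nz,) um
    phi: np.ndarray           # (nz, nx) uV
    ex: np.ndarray            # (nz, nx)
    ez: np.ndarray
    t_ms: float
    sigma: float = DEFAULT_SIGMA_S_M
    metadata: dict = field(default_factory=dict)

    def to_table(self, path: str | None = None):
        import pandas as pd

        xx, zz = np.meshgrid(self.x, self.z)
        df = pd.DataFrame({
            "x_um": xx.ravel(), "z_um": zz.ravel(),
            "phi_uv": self.phi.ravel(),
            "ex_v_per_m": self.ex.ravel(), "ez_v_per_m": self.ez.ravel(),
        })
        if path is not None:
            df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return df


def _default_grid(g) -> tuple[np.ndarray, np.ndarray]:
    margin = 100.0
    x = np.linspace(float(g.x0.min()) - margin, float(g.x1.max()) + margin, 81)
    z = np.linspace(-margin, margin, 41)
    return x, z


def field_snapshot(result: SimResult, t: float,
                   x: np.ndarray | None = None, z: np.ndarray | None = None,
                   sigma: float = DEFAULT_SIGMA_S_M,
                   sources: LineSourceSet | None = None) -> FieldGrid:
    """Extracellular potential and field in the x-z plane at time ``t`` (ms).

    The grid defaults to the cell's bounding box with 100 um margins.  The
    field is the central-difference gradient of the potential on the grid.
    """
    if not (result.t[0] <= t <= result.t[-1]):
        raise ValueError("t outside the recorded trace")
    src = sources or line_sources_from_result(result, sigma=sigma)
    if x is None or z is None:
        xd, zd = _default_grid(result.graph)
        x = xd if x is None else np.asarray(x, dtype=float)
        z = zd if z is None else np.asarray(z, dtype=float)
    k = int(np.argmin(np.abs(result.t - t)))
    xx, zz = np.meshgrid(x, z)
    points = np.column_stack([xx.ravel(), np.zeros(xx.size), zz.ravel()])
    w = src.potential_weights(points)
    phi = (w @ src.currents[k]).reshape(len(z), len(x))
    dphidx = np.gradient(phi, x, axis=1)
    dphidz = np.gradient(phi, z, axis=0)
    return FieldGrid(x=x, z=z, phi=phi, ex=-dphidx, ez=-dphidz,
                     t_ms=float(result.t[k]), sigma=sigma,
                     metadata={"sample_index": k})


def virtual_electrode(result: SimResult, point,
                      sigma: float = DEFAULT_SIGMA_S_M,
                      sources: LineSourceSet | None = None) -> np.ndarray:
    """Time series (uV) of the extracellular potential at a fixed point."""
    src = sources or line_sources_from_result(result, sigma=sigma)
    return np.asarray(src.potential_at(np.asarray(point, dtype=float)))
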