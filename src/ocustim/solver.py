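"""Quasi-static conduction solver (P1 tetrahedral FEM) and phase superposition.

The electric potential V solves div(sigma grad V) = 0 with zero normal
current on the non-electrode surface.  Two electrode models are provided:

``dirichlet`` (default, matches the montage pipeline)
    The two pads are held equipotential (+1/2, -1/2) and the solution is
    rescaled so the total current through the anode pad equals the requested
    drive; this is how fixed-potential pad simulations are reconciled with a
    current-programmed stimulator.

``injection``
    The drive current is injected as nodal sources distributed over each pad
    proportionally to nodal surface area (uniform current density).  Because
    the system matrix is identical for every drive, signed superposition of
    per-pair solutions is exact for this model up to solver error, which is
    what the joint-solve consistency check exploits.

At 10 Hz the quasi-static approximation holds and the phase of an AC drive
reduces to a sign: a same-phase pair combination is the (+,+) sum of static
solutions and an anti-phase combination the (+,-) sum.

Internally all quantities are SI (meters, amperes, volts); mesh coordinates
in mm and currents in mA are converted on entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .phantom import TissuePhantom, ElectrodePatch

__all__ = [
    "DEFAULT_CONDUCTIVITY",
    "ConductivityMap",
    "FieldSolution",
    "SolverError",
    "ConductionOperator",
    "solve_pair",
    "element_field",
    "superpose",
]


class SolverError(RuntimeError):
    """Singular or inconsistent conduction problem."""


#: Tissue conductivities at 10 Hz, S/m.  The head-skin value is far below
#: common literature figures but is kept verbatim as the default; override
#: it through :class:`ConductivityMap` if needed.
DEFAULT_CONDUCTIVITY: Mapping[str, float] = {
    "white_matter": 0.027656,
    "gray_matter": 0.027512,
    "csf": 2.0000,
    "bone": 0.020028,
    "skin": 0.0002,
    "eyeball": 0.41113,
}


@dataclass(frozen=True)
class ConductivityMap:
    """Tissue -> conductivity (S/m) with an informational frequency label."""

    values: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDUCTIVITY))
    frequency_hz: float = 10.0

    def __post_init__(self):
        for tissue, sigma in self.values.items():
            if not sigma > 0:
                raise ValueError(
                    f"conductivity of {tissue!r} must be positive, "
                    f"got {sigma}")

    def for_labels(self, labels: np.ndarray) -> np.ndarray:
        missing = set(np.unique(labels)) - set(self.values)
        if missing:
            raise ValueError(f"no conductivity for tissues {sorted(missing)}")
        lut = {t: s for t, s in self.values.items()}
        return np.array([lut[t] for t in labels])


@dataclass
class FieldSolution:
    """Potential and per-element field for one drive configuration."""

    potential: np.ndarray            # (N,) volts
    element_field: np.ndarray        # (M, 3) V/m
    element_field_magnitude: np.ndarray  # (M,) V/m, >= 0
    drive: dict
    residual: float
    n_nodes: int
    n_elements: int

    def scaled(self, factor: float) -> "FieldSolution":
        """Linearity in the drive: scale every field quantity."""
        return FieldSolution(
            potential=self.potential * factor,
            element_field=self.element_field * factor,
            element_field_magnitude=self.element_field_magnitude
            * abs(factor),
            drive={**self.drive, "scaled_by": factor},
            residual=self.residual, n_nodes=self.n_nodes,
            n_elements=self.n_elements)


class ConductionOperator:
    """Assembled stiffness matrix and element gradients for one phantom.

    Building the operator is the expensive step shared by every solve on the
    same phantom/conductivity pair, so callers running several montages
    should construct it once and pass it to :func:`solve_pair`.
    """

    def __init__(self, phantom: TissuePhantom,
                 sigma: ConductivityMap | None = None):
        self.phantom = phantom
        self.sigma = sigma or ConductivityMap()
        nodes_m = phantom.nodes * 1e-3
        tets = phantom.tets
        x = nodes_m[tets]                        # (M, 4, 3)
        d = (x[:, 1:] - x[:, :1]).transpose(0, 2, 1)   # columns p_i - p_0
        det = np.linalg.det(d)
        if np.any(np.abs(det) < 1e-30):
            bad = int(np.argmin(np.abs(det)))
            raise SolverError(f"degenerate tetrahedron {bad}")
        self.volumes = det / 6.0                 # m^3, positive by meshing
        ginv = np.linalg.inv(d)                  # rows = grad lambda_{1..3}
        grads = np.empty((len(tets), 4, 3))
        grads[:, 1:, :] = ginv
        grads[:, 0, :] = -ginv.sum(axis=1)
        self.grads = grads                       # 1/m
        sig = self.sigma.for_labels(phantom.tet_labels)
        ke = (sig * self.volumes)[:, None, None] * \
            np.einsum("mid,mjd->mij", grads, grads)
        ii = np.repeat(tets, 4, axis=1).reshape(-1)
        jj = np.tile(tets, (1, 4)).reshape(-1)
        n = len(nodes_m)
        self.stiffness = sp.coo_matrix(
            (ke.reshape(-1), (ii, jj)), shape=(n, n)).tocsr()
        self.n_nodes = n

    # -- boundary-value solves --------------------------------------------
    def _solve_reduced(self, fixed: np.ndarray, vfix: np.ndarray):
        K = self.stiffness
        n = self.n_nodes
        free = np.ones(n, dtype=bool)
        free[fixed] = False
        vd = np.zeros(n)
        vd[fixed] = vfix
        rhs = -(K @ vd)[free]
        Kff = K[free][:, free]
        try:
            lu = spla.splu(Kff.tocsc())
            vf = lu.solve(rhs)
        except RuntimeError as exc:     # pragma: no cover - singular matrix
            raise SolverError(f"sparse factorization failed: {exc}") from exc
        res = np.linalg.norm(Kff @ vf - rhs) / max(np.linalg.norm(rhs), 1e-30)
        v = vd.copy()
        v[free] = vf
        return v, res

    def solve_dirichlet_pair(self, anode: ElectrodePatch,
                             cathode: ElectrodePatch,
                             current_ma: float) -> FieldSolution:
        if len(np.intersect1d(anode.nodes, cathode.nodes)):
            raise SolverError("anode and cathode patches share nodes")
        if anode.nodes.size == 0 or cathode.nodes.size == 0:
            raise SolverError("empty electrode patch")
        fixed = np.concatenate([anode.nodes, cathode.nodes])
        vfix = np.concatenate([np.full(anode.nodes.size, 0.5),
                               np.full(cathode.nodes.size, -0.5)])
        v, res = self._solve_reduced(fixed, vfix)
        reactions = self.stiffness @ v
        i_anode = reactions[anode.nodes].sum()      # amperes at unit drive
        if abs(i_anode) < 1e-30:
            raise SolverError("zero anode flux; system is ill-conditioned")
        scale = current_ma * 1e-3 / i_anode
        v = v * scale
        v -= v.mean()                               # zero-mean gauge
        E, Emag = self._element_field(v)
        i_cathode = (self.stiffness @ v)[cathode.nodes].sum()
        drive = {"model": "dirichlet", "current_ma": current_ma,
                 "anode": _patch_desc(anode), "cathode": _patch_desc(cathode),
                 "anode_current_a": current_ma * 1e-3,
                 "cathode_current_a": float(i_cathode)}
        return FieldSolution(v, E, Emag, drive, float(res),
                             self.n_nodes, len(self.volumes))

    def solve_injection(self, patches: Sequence[ElectrodePatch],
                        currents_ma: Sequence[float]) -> FieldSolution:
        """Uniform-current-density drive over an arbitrary set of pads.

        Currents must sum to zero (charge conservation).  The singular
        Neumann system is solved by grounding one node, which is exact for a
        compatible right-hand side; the reported potential is zero-mean.
        """
        if len(patches) != len(currents_ma):
            raise SolverError("one current per patch required")
        total = float(np.sum(currents_ma))
        if abs(total) > 1e-12 * max(1.0, np.max(np.abs(currents_ma))):
            raise SolverError("injection currents must sum to zero")
        f = np.zeros(self.n_nodes)
        for patch, i_ma in zip(patches, currents_ma):
            if patch.nodes.size == 0:
                raise SolverError("empty electrode patch")
            f[patch.nodes] += patch.node_weights * (i_ma * 1e-3)
        K = self.stiffness
        free = np.ones(self.n_nodes, dtype=bool)
        free[0] = False
        Kff = K[free][:, free].tocsc()
        vf = spla.splu(Kff).solve(f[free])
        v = np.zeros(self.n_nodes)
        v[free] = vf
        res = np.linalg.norm(K @ v - f) / max(np.linalg.norm(f), 1e-30)
        v -= v.mean()
        E, Emag = self._element_field(v)
        drive = {"model": "injection",
                 "currents_ma": [float(c) for c in currents_ma],
                 "patches": [_patch_desc(p) for p in patches]}
        return FieldSolution(v, E, Emag, drive, float(res),
                             self.n_nodes, len(self.volumes))

    def solve_nodal_injection(self, node_indices, currents_ma) -> FieldSolution:
        """Point-like drive: inject the given currents at individual nodes.

        Used for validating against analytic point-source solutions, where a
        patch shrunk to one node is the closest discrete analogue.
        """
        node_indices = np.atleast_1d(np.asarray(node_indices, dtype=int))
        currents = np.atleast_1d(np.asarray(currents_ma, dtype=float))
        if abs(currents.sum()) > 1e-12 * max(1.0, np.abs(currents).max()):
            raise SolverError("injection currents must sum to zero")
        f = np.zeros(self.n_nodes)
        np.add.at(f, node_indices, currents * 1e-3)
        K = self.stiffness
        free = np.ones(self.n_nodes, dtype=bool)
        free[0] = False
        vf = spla.splu(K[free][:, free].tocsc()).solve(f[free])
        v = np.zeros(self.n_nodes)
        v[free] = vf
        res = np.linalg.norm(K @ v - f) / max(np.linalg.norm(f), 1e-30)
        v -= v.mean()
        E, Emag = self._element_field(v)
        drive = {"model": "nodal_injection",
                 "nodes": node_indices.tolist(),
                 "currents_ma": currents.tolist()}
        return FieldSolution(v, E, Emag, drive, float(res),
                             self.n_nodes, len(self.volumes))

    def _element_field(self, v: np.ndarray):
        E = -np.einsum("mid,mi->md", self.grads, v[self.phantom.tets])
        return E, np.linalg.norm(E, axis=1)


def _patch_desc(patch: ElectrodePatch) -> dict:
    return {"site": str(patch.center_spec),
            "edge_length_mm": patch.edge_length,
            "n_nodes": int(patch.nodes.size)}


def solve_pair(phantom: TissuePhantom, anode: ElectrodePatch,
               cathode: ElectrodePatch, sigma: ConductivityMap | None = None,
               current_ma: float | None = None,
               operator: ConductionOperator | None = None,
               model: str = "dirichlet") -> FieldSolution:
    """Solve the conduction problem for one electrode pair.

    ``current_ma`` defaults to the anode patch's configured current.  Passing
    a prebuilt ``operator`` skips matrix reassembly.
    """
    op = operator or ConductionOperator(phantom, sigma)
    i_ma = anode.current_ma if current_ma is None else current_ma
    if model == "dirichlet":
        return op.solve_dirichlet_pair(anode, cathode, i_ma)
    if model == "injection":
        return op.solve_injection([anode, cathode], [i_ma, -i_ma])
    raise ValueError(f"unknown electrode model {model!r}")


def element_field(phantom: TissuePhantom, potential: np.ndarray):
    """Per-element field E = -grad V and its magnitude for a nodal potential.

    The potential is interpolated piecewise-linearly, so E is constant on
    each tetrahedron; this matches reading out one field value per element.
    """
    if potential.shape != (len(phantom.nodes),):
        raise ValueError("potential must be defined on every node")
    nodes_m = phantom.nodes * 1e-3
    x = nodes_m[phantom.tets]
    d = (x[:, 1:] - x[:, :1]).transpose(0, 2, 1)
    det = np.linalg.det(d)
    bad = np.abs(det) < 1e-30
    if bad.any():
        raise SolverError(f"degenerate tetrahedron {int(np.nonzero(bad)[0][0])}")
    ginv = np.linalg.inv(d)
    grads = np.empty((len(phantom.tets), 4, 3))
    grads[:, 1:, :] = ginv
    grads[:, 0, :] = -ginv.sum(axis=1)
    E = -np.einsum("mid,mi->md", grads, potential[phantom.tets])
    return E, np.linalg.norm(E, axis=1)


def superpose(solutions: Sequence[FieldSolution],
              signs: Sequence[float]) -> FieldSolution:
    """Signed (phase) superposition of per-pair solutions.

    The combined element field is the signed vector sum; its magnitude is the
    norm of that sum, *not* the sum of magnitudes, so anti-phase drives can
    cancel.  All solutions must live on the same mesh.
    """
    if len(solutions) != len(signs) or not solutions:
        raise ValueError("need one sign per solution")
    n0, m0 = solutions[0].n_nodes, solutions[0].n_elements
    for s in solutions[1:]:
        if s.n_nodes != n0 or s.n_elements != m0:
            raise ValueError("solutions are defined on different meshes")
    v = sum(sg * s.potential for sg, s in zip(signs, solutions))
    E = sum(sg * s.element_field for sg, s in zip(signs, solutions))
    drive = {"model": "superposition",
             "signs": [float(s) for s in signs],
             "components": [s.drive for s in solutions]}
    return FieldSolution(v, E, np.linalg.norm(E, axis=1), drive,
                         max(s.residual for s in solutions), n0, m0)
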