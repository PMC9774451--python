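"""End-to-end montage experiments: phase comparison, current sweeps and the
current-path cancellation diagnostic.

A montage run solves the conduction problem once per electrode pair, forms
the same-phase (+,+) and anti-phase (+,-) superpositions, unwraps each
targeted eye surface and scores stimulation locality per target region.
The recommended phase maximizes the minimum, over target regions, of the
difference between the in-region maximum and the largest maximum in the
surrounding non-target zones (the upper zone plus adjacent lower regions
that are not themselves montage targets — when two neighboring bands are
both targets, spill between them is intended, not interference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import TissuePhantom
from .solver import (ConductivityMap, ConductionOperator, FieldSolution,
                     superpose)
from .montage import Montage, PlacedMontage, place_montage
from . import ocular

__all__ = ["PhaseComparison", "phase_signs", "run_arrangement",
           "current_sweep", "PathCrossing", "CrossingReport",
           "cancellation_diagnostic"]


def phase_signs(phase: str, n_pairs: int) -> list:
    """Signed superposition weights for a phase option.

    ``same`` drives every pair with the same waveform (+1 each); ``anti``
    inverts every second pair (+1, -1, ...).
    """
    if phase == "same":
        return [1.0] * n_pairs
    if phase == "anti":
        return [1.0 if i % 2 == 0 else -1.0 for i in range(n_pairs)]
    raise ValueError(f"unknown phase option {phase!r}")


@dataclass
class PhaseComparison:
    """Per-phase locality reports and the resulting phase recommendation."""

    montage_name: str
    currents_ma: list
    phase_reports: dict       # phase -> {(eye, region): LocalityReport}
    phase_scores: dict        # phase -> min-over-targets locality score
    recommended_phase: str
    provenance: dict

    def to_dict(self):
        return {
            "montage": self.montage_name,
            "currents_ma": self.currents_ma,
            "phases": {
                phase: {f"{eye}:{region}": rep.to_dict()
                        for (eye, region), rep in reports.items()}
                for phase, reports in self.phase_reports.items()},
            "phase_scores": self.phase_scores,
            "recommended_phase": self.recommended_phase,
            "provenance": self.provenance,
        }


def _target_score(report: ocular.LocalityReport, targets) -> float:
    """Locality score of one target region: the in-region maximum minus the
    largest maximum over adjacent regions that are not montage targets
    (spill between two co-targeted neighbors is intended, not
    interference).  When every adjacent region is itself a target the upper
    zone serves as the reference instead."""
    outside = [pk.value for name, pk in report.max_adjacent.items()
               if (report.eye, name) not in targets]
    if not outside:
        outside = [report.max_upper.value]
    return report.max_in.value - max(outside)


def evaluate_solution(phantom: TissuePhantom, solution: FieldSolution,
                      targets, grid_resolution_deg: float = 1.0) -> dict:
    """Locality reports for every montage target region of one solution."""
    reports = {}
    grids = {}
    for eye, region_name in targets:
        if eye not in grids:
            samples = ocular.extract_eye_surface(phantom, solution, eye)
            grids[eye] = ocular.interpolate_grid(samples,
                                                 grid_resolution_deg)
        region = next(r for r in ocular.partition_regions(eye)
                      if r.name == region_name)
        reports[(eye, region_name)] = ocular.locality_report(grids[eye],
                                                             region)
    return reports


def run_arrangement(phantom: TissuePhantom, montage: Montage,
                    sigma: ConductivityMap | None = None,
                    phases=("same", "anti"),
                    grid_resolution_deg: float = 1.0,
                    edge_length: float = 42.0,
                    operator: ConductionOperator | None = None,
                    placed: PlacedMontage | None = None) -> PhaseComparison:
    """Run a montage under each phase option and score locality.

    Deterministic given the phantom seed.  Raises ``ValueError`` for a
    montage without target regions; placement and solver errors propagate
    with montage context.
    """
    targets = montage.target_regions
    if not targets:
        raise ValueError(f"montage {montage.name!r} has no target regions")
    op = operator or ConductionOperator(phantom, sigma)
    placed = placed or place_montage(phantom, montage, edge_length)
    pair_solutions = [
        op.solve_dirichlet_pair(pp.anode, pp.cathode, pp.current_ma)
        for pp in placed.pairs]
    phase_reports, phase_scores = {}, {}
    for phase in phases:
        combined = superpose(pair_solutions,
                             phase_signs(phase, len(pair_solutions)))
        reports = evaluate_solution(phantom, combined, targets,
                                    grid_resolution_deg)
        phase_reports[phase] = reports
        phase_scores[phase] = min(_target_score(rep, targets)
                                  for rep in reports.values())
    recommended = max(phase_scores, key=phase_scores.get)
    prov = {"residuals": [s.residual for s in pair_solutions],
            "phantom_seed": phantom.provenance.get("seed"),
            "n_tets": int(len(phantom.tets)),
            "grid_resolution_deg": grid_resolution_deg}
    return PhaseComparison(
        montage_name=montage.name,
        currents_ma=[p.current_ma for p in montage.pairs],
        phase_reports=phase_reports, phase_scores=phase_scores,
        recommended_phase=recommended, provenance=prov)


def current_sweep(phantom: TissuePhantom, montage: Montage,
                  sigma: ConductivityMap | None = None,
                  current_grid=((1.0, 1.0),), phase: str = "same",
                  grid_resolution_deg: float = 1.0,
                  operator: ConductionOperator | None = None) -> list:
    """Locality reports over a grid of per-pair current settings.

    By linearity each pair is solved once at 1 mA and rescaled, so sweeping
    is cheap; a direct re-solve at any grid point reproduces the rescaled
    result to solver tolerance.  Returns a list of
    ``(currents, {(eye, region): LocalityReport})``.
    """
    targets = montage.target_regions
    if not targets:
        raise ValueError(f"montage {montage.name!r} has no target regions")
    op = operator or ConductionOperator(phantom, sigma)
    placed = place_montage(phantom, montage)
    unit = [op.solve_dirichlet_pair(pp.anode, pp.cathode, 1.0)
            for pp in placed.pairs]
    signs = phase_signs(phase, len(unit))
    out = []
    for currents in current_grid:
        if len(currents) != len(unit):
            raise ValueError("one current per pair required")
        if any(c <= 0 for c in currents):
            raise ValueError("currents must be positive")
        combined = superpose(unit, [s * c for s, c in zip(signs, currents)])
        out.append((tuple(float(c) for c in currents),
                    evaluate_solution(phantom, combined, targets,
                                      grid_resolution_deg)))
    return out


# ---------------------------------------------------------------------------
# current-path cancellation diagnostic

@dataclass
class PathCrossing:
    """Closest approach of the straight current-path chords of two pairs."""

    pair_a: str
    pair_b: str
    distance_mm: float
    location: np.ndarray
    crosses: bool
    near_patch: str | None

    def to_dict(self):
        return {"pair_a": self.pair_a, "pair_b": self.pair_b,
                "distance_mm": self.distance_mm,
                "location": [float(x) for x in self.location],
                "crosses": self.crosses, "near_patch": self.near_patch}


@dataclass
class CrossingReport:
    montage_name: str
    crossings: list       # of PathCrossing

    @property
    def any_crossing(self) -> bool:
        return any(c.crosses for c in self.crossings)

    def to_dict(self):
        return {"montage": self.montage_name,
                "crossings": [c.to_dict() for c in self.crossings]}


def _segment_distance(p0, p1, q0, q1):
    """Closest approach between 3D segments: (distance, midpoint, s, t)."""
    u, v, w = p1 - p0, q1 - q0, p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    den = a * c - b * b
    s = np.clip((b * e - c * d) / den, 0.0, 1.0) if den > 1e-12 else 0.0
    t = np.clip((b * s + e) / c, 0.0, 1.0) if c > 1e-12 else 0.0
    s = np.clip((b * t - d) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    pa, qb = p0 + s * u, q0 + t * v
    return float(np.linalg.norm(pa - qb)), 0.5 * (pa + qb), float(s), float(t)


def _point_segment_distance(pts, q0, q1):
    v = q1 - q0
    t = np.clip((pts - q0) @ v / (v @ v), 0.0, 1.0)
    return np.linalg.norm(pts - (q0 + t[:, None] * v), axis=1)


def _chords_cross(p0, p1, q0, q1, tol):
    """True when the two chords genuinely share a current corridor.

    Either a transversal crossing with the closest approach interior to
    both segments, or near-parallel chords running within ``tol`` of each
    other over most of their length (the overlapping-pad case).  Merely
    convergent endpoints (two pads returning to neighbouring cheek sites)
    do not count.
    """
    dist, loc, s, t = _segment_distance(p0, p1, q0, q1)
    if dist >= tol:
        return False, dist, loc
    du = (p1 - p0) / np.linalg.norm(p1 - p0)
    dv = (q1 - q0) / np.linalg.norm(q1 - q0)
    angle = np.degrees(np.arccos(np.clip(abs(du @ dv), 0, 1)))
    if angle > 15.0:
        interior = 0.05 < s < 0.95 and 0.05 < t < 0.95
        return interior, dist, loc
    # near-parallel: require the chords to share a corridor, not a point
    samples = p0 + np.linspace(0, 1, 21)[:, None] * (p1 - p0)
    med = float(np.median(_point_segment_distance(samples, q0, q1)))
    return med < tol, dist, loc


def cancellation_diagnostic(phantom: TissuePhantom, montage: Montage,
                            placed: PlacedMontage | None = None,
                            crossing_tolerance_mm: float = 8.0
                            ) -> CrossingReport:
    """Flag electrode-pair chords that cross within a pad footprint.

    The straight chord between a pair's pad centers is a coarse stand-in for
    its dominant current path; when two chords approach within
    ``crossing_tolerance_mm`` near a pad, anti-phase drives of the two pairs
    risk cancelling each other along the shared path.  A single-pair montage
    yields an empty report.
    """
    placed = placed or place_montage(phantom, montage)
    crossings = []
    for i in range(len(placed.pairs)):
        for j in range(i + 1, len(placed.pairs)):
            a, b = placed.pairs[i], placed.pairs[j]
            crosses, dist, loc = _chords_cross(
                a.anode.center, a.cathode.center,
                b.anode.center, b.cathode.center,
                crossing_tolerance_mm)
            near = None
            for pp in (a, b):
                for patch, side in ((pp.anode, "active"),
                                    (pp.cathode, "return")):
                    if np.linalg.norm(loc - patch.center) \
                            <= patch.edge_length / 2:
                        near = f"{pp.spec.letter}:{side}"
                        break
                if near:
                    break
            crossings.append(PathCrossing(
                pair_a=a.spec.letter, pair_b=b.spec.letter,
                distance_mm=dist, location=loc,
                crosses=bool(crosses), near_patch=near))
    return CrossingReport(montage_name=montage.name, crossings=crossings)
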