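"""Catalog of periocular electrode montages.

Each montage combines two electrode pairs drawn from the letter catalog
(A: temporal-right, B: temporal-left, C: central-right, D: central-left,
E: nasal), one pair per targeted lower ocular region.  Each pair consists of
an active pad near the targeted corneal region and a return pad on the
cheek.  The numbered arrangements mirror the seven two-pair combinations of
the letter pairs; the ``*_revised`` variants encode the montage corrections
(separating the overlapping cheek returns of arrangement 4, lowering the
temporal-right active pad for 1/3/5/7) and the ``*_corrected`` variants the
0.8 mA temporal / 1.5 mA nasal current rebalancing for the nasal
combinations.

Because exact pad coordinates for a real head are anatomy-dependent, sites
are specified as angular positions on the phantom skin (see
``phantom.SITE_TABLE``), not transcribed coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .phantom import (TissuePhantom, ElectrodePatch, place_electrode,
                      patch_overlap, mirror_site)

__all__ = ["PairSpec", "Montage", "PlacedPair", "PlacedMontage",
           "CatalogError", "montage_catalog", "catalog_names",
           "mirror_montage", "place_montage"]


class CatalogError(KeyError):
    """Unknown montage name."""


@dataclass(frozen=True)
class PairSpec:
    """One electrode pair: active (anode) site, return (cathode) site,
    drive current and the ocular region the pair targets."""

    letter: str
    active_site: str
    return_site: str
    current_ma: float
    target_eye: str
    target_region: str


@dataclass(frozen=True)
class Montage:
    """A named combination of electrode pairs with phase options."""

    name: str
    pairs: tuple          # of PairSpec
    phase_options: tuple = ("same", "anti")

    @property
    def target_regions(self) -> list:
        return [(p.target_eye, p.target_region) for p in self.pairs]


def _pair(letter, active, ret, target, current=1.0):
    eye, region = target
    return PairSpec(letter=letter, active_site=active, return_site=ret,
                    current_ma=current, target_eye=eye, target_region=region)


# The two pairs of the working same-eye combination (temporal + central)
# run parallel chords to nearly coincident low-medial cheek returns.  Driven
# same-phase, both pairs' currents exit through the shared low-medial path,
# sweeping the lower/nasal eye surface on the way; driven anti-phase the
# return currents cancel and the drive reduces to a short loop between the
# two active pads, confining the field to the targeted rim segments.
_A = _pair("A", "right_temporal_lower", "right_cheek_medial_low",
           ("right", "temporal"))
_B = _pair("B", "left_temporal_lower", "left_cheek_medial_low",
           ("left", "temporal"))
_C = _pair("C", "right_central_lower", "right_cheek_medial_low2",
           ("right", "central"))
_D = _pair("D", "left_central_lower", "left_cheek_medial_low2",
           ("left", "central"))
# When E occupies the medial lower face its neighbours' returns move
# laterally (and E's own return moves to the opposite cheek) so the pads
# do not collide.
_B_LAT = replace(_B, return_site="left_cheek_lateral_low")
_A_LAT = replace(_A, return_site="right_cheek_lateral_low")
_E_LEFT = _pair("E", "nasal_lower", "right_cheek_medial_low2",
                ("left", "nasal"))
_E_RIGHT = _pair("E", "nasal_lower", "left_cheek_medial_low2",
                 ("right", "nasal"))

# arrangement 4 is the degenerate crowded variant: the active pads overlap
# heavily and the returns overlap and are swapped sideways (the temporal
# active runs to the medial return and vice versa), so the two current-path
# chords cross between the pads; driven anti-phase the two nearly
# coincident pairs cancel each other
_B4 = _pair("B", "left_temporal_lower_crowded", "left_cheek_crossed_a",
            ("left", "temporal"))
_D4 = _pair("D", "left_central_lower_crowded", "left_cheek_crossed_b",
            ("left", "central"))
# revised temporal-right pair: active pad lowered to pull the peak away
# from the upper zone.
_A_REV = replace(_A, active_site="right_temporal_lower_adjusted")


def _corrected(pairs):
    """0.8 mA on the temporal pair, 1.5 mA on the nasal pair."""
    out = []
    for p in pairs:
        if p.target_region == "nasal":
            out.append(replace(p, current_ma=1.5))
        else:
            out.append(replace(p, current_ma=0.8))
    return tuple(out)


def _boosted(pairs):
    """1 mA / 1.5 mA nasal variant."""
    return tuple(replace(p, current_ma=1.5)
                 if p.target_region == "nasal" else p for p in pairs)


_COMBOS = {
    "A+B": (_A, _B),
    "B+C": (_B, _C),
    "A+D": (_A, _D),
    "B+D": (_B4, _D4),
    "A+C": (_A, _C),
    "B+E": (_B_LAT, _E_LEFT),
    "A+E": (_A_LAT, _E_RIGHT),
}
_NUMBERED = {f"electrode_{i}": combo
             for i, combo in enumerate(_COMBOS, start=1)}

_CATALOG: dict[str, tuple] = {}
for _name, _pairs in _COMBOS.items():
    _CATALOG[_name] = _pairs
for _name, _combo in _NUMBERED.items():
    _CATALOG[_name] = _COMBOS[_combo]

_CATALOG["B+E_corrected"] = _corrected(_COMBOS["B+E"])
_CATALOG["A+E_corrected"] = _corrected(_COMBOS["A+E"])
_CATALOG["B+E_boosted"] = _boosted(_COMBOS["B+E"])
_CATALOG["A+E_boosted"] = _boosted(_COMBOS["A+E"])
_CATALOG["electrode_6_corrected"] = _CATALOG["B+E_corrected"]
_CATALOG["electrode_7_corrected"] = _CATALOG["A+E_corrected"]
# the revision separates the crowded returns: pair B goes back to its
# temple return, the mirror image of the working temporal+central montage
_CATALOG["electrode_4_revised"] = (_B, _D)
for _i, _combo in (("1", "A+B"), ("3", "A+D"), ("5", "A+C"), ("7", "A+E")):
    _base = _CATALOG[_combo]
    _CATALOG[f"electrode_{_i}_revised"] = tuple(
        replace(p, active_site="right_temporal_lower_adjusted")
        if p.letter == "A" else p for p in _base)


def catalog_names() -> list[str]:
    return sorted(_CATALOG)


def montage_catalog(name: str, currents_ma=None) -> Montage:
    """Look up a montage by name, optionally overriding pair currents.

    Raises :class:`CatalogError` for unknown names.
    """
    try:
        pairs = _CATALOG[name]
    except KeyError as exc:
        raise CatalogError(
            f"unknown montage {name!r}; known: {catalog_names()}") from exc
    if currents_ma is not None:
        if len(currents_ma) != len(pairs):
            raise ValueError("one current per pair required")
        if any(c <= 0 for c in currents_ma):
            raise ValueError("currents must be positive")
        pairs = tuple(replace(p, current_ma=float(c))
                      for p, c in zip(pairs, currents_ma))
    return Montage(name=name, pairs=pairs)


def mirror_montage(montage: Montage) -> Montage:
    """Reflect a montage about the midsagittal plane.

    Left-eye target regions map to right-eye target regions exactly and all
    sites swap sides; the midline nasal site is its own mirror.
    """
    flip = {"left": "right", "right": "left"}
    pairs = tuple(replace(p,
                          active_site=mirror_site(p.active_site),
                          return_site=mirror_site(p.return_site),
                          target_eye=flip[p.target_eye])
                  for p in montage.pairs)
    return Montage(name=montage.name + "_mirrored", pairs=pairs)


@dataclass
class PlacedPair:
    spec: PairSpec
    anode: ElectrodePatch
    cathode: ElectrodePatch

    @property
    def current_ma(self) -> float:
        return self.spec.current_ma


@dataclass
class PlacedMontage:
    montage: Montage
    pairs: list           # of PlacedPair

    @property
    def target_regions(self) -> list:
        return self.montage.target_regions


def place_montage(phantom: TissuePhantom, montage: Montage,
                  edge_length: float = 42.0) -> PlacedMontage:
    """Project every pad of a montage onto the phantom skin.

    Within each pair the anode and cathode footprints must be disjoint
    (patches of *different* pairs may overlap, as in arrangement 4).
    """
    placed = []
    for spec in montage.pairs:
        anode = place_electrode(phantom, spec.active_site, edge_length,
                                current_ma=spec.current_ma)
        cathode = place_electrode(phantom, spec.return_site, edge_length,
                                  current_ma=-spec.current_ma)
        if len(patch_overlap(anode, cathode)):
            raise ValueError(
                f"pair {spec.letter}: anode and cathode footprints overlap")
        placed.append(PlacedPair(spec=spec, anode=anode, cathode=cathode))
    return PlacedMontage(montage=montage, pairs=placed)
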