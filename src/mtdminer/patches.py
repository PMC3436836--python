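"""Surface patch growing and the 35-column structural feature vector.

A patch is an edge-connected set of triangles whose channel values satisfy
an acceptance predicate across every traversed edge. Three predicates are
supported:

tolerance   |v1 - v2| < C across the edge
sign        strictly equal sign (zeros group with zeros)
binary      exactly equal value

Features: the five largest patch areas for each of the electrostatic
(signed, sign-connectivity), hydrophobic (tolerance growth over
Kyte-Doolittle >= 0 triangles) and hydrogen-bond (value-1 triangles)
categories, plus the 20 amino-acid surface propensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .structio import THREE_TO_ONE, SurfaceMesh

#: fixed amino-acid order for propensity columns (one-letter alphabetical).
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

MODES = ("tolerance", "sign", "binary")


@dataclass
class Patch:
    """Edge-connected same-property triangle set."""

    triangle_ids: np.ndarray
    area: float
    mean_value: float
    sign: int  # {+1, -1, 0}


@dataclass
class PatchGrowConfig:
    C: float = 1.5
    mode: str = "tolerance"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.C < 0:
            raise ValueError("growth tolerance C must be >= 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


def _edge_accepts(v1: float, v2: float, config: PatchGrowConfig) -> bool:
    if config.mode == "tolerance":
        return abs(v1 - v2) < config.C
    if config.mode == "sign":
        return np.sign(v1) == np.sign(v2)
    return v1 == v2


def grow_patches(mesh: SurfaceMesh, channel: str, config: PatchGrowConfig,
                 eligible: np.ndarray | None = None) -> list[Patch]:
    """Partition (eligible) triangles into patches by iterative flood fill.

    Seed triangles are taken in descending |value| then index order, or in a
    seeded random order when ``config.seed`` is set; because acceptance is
    an edge-local predicate the resulting partition is the connected
    components of the predicate graph and does not depend on seed order.
    """
    if channel not in mesh.channels:
        raise DataError(f"channel {channel!r} not mapped on mesh")
    values = mesh.channels[channel]
    n = mesh.n_triangles
    if eligible is None:
        eligible = np.ones(n, dtype=bool)
    neigh = mesh.triangle_neighbors()

    candidates = np.nonzero(eligible)[0]
    if config.seed is not None:
        rng = np.random.default_rng(config.seed)
        seed_order = candidates[rng.permutation(len(candidates))]
    else:
        order = np.lexsort((candidates, -np.abs(values[candidates])))
        seed_order = candidates[order]

    included = np.zeros(n, dtype=bool)
    included[~eligible] = True  # never visited
    patches: list[Patch] = []
    for seed_t in seed_order:
        if included[seed_t]:
            continue
        members = [int(seed_t)]
        included[seed_t] = True
        stack = [int(seed_t)]
        while stack:
            t = stack.pop()
            for u in neigh[t]:
                u = int(u)
                if included[u]:
                    continue
                if _edge_accepts(values[t], values[u], config):
                    included[u] = True
                    members.append(u)
                    stack.append(u)
        ids = np.array(sorted(members), dtype=int)
        areas = mesh.triangle_area[ids]
        area = float(areas.sum())
        mean_value = float(np.average(values[ids], weights=areas))
        patches.append(Patch(triangle_ids=ids, area=area,
                             mean_value=mean_value,
                             sign=int(np.sign(mean_value))))
    return patches


def top_k_patch_areas(patches: list[Patch], k: int = 5,
                      signed: bool = False) -> np.ndarray:
    """The k largest patch areas ranked by |area| descending.

    Values are area * sign when ``signed`` (electrostatic category), plain
    areas otherwise; zero-padded when fewer than k patches exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = [p.area * (p.sign if signed else 1) for p in patches]
    vals.sort(key=abs, reverse=True)
    vals = vals[:k] + [0.0] * max(0, k - len(vals))
    return np.array(vals)


def surface_propensities(mesh: SurfaceMesh) -> np.ndarray:
    """Fraction of surface area contributed by each amino-acid type.

    Order follows :data:`AA_ORDER`; triangles from non-standard residues
    are excluded from both numerator and denominator so the vector sums
    to 1.
    """
    if mesh.triangle_residue is None or mesh.residue_names is None:
        raise DataError("mesh lacks residue attribution")
    idx = {aa: i for i, aa in enumerate(AA_ORDER)}
    acc = np.zeros(20)
    for t, rid in enumerate(mesh.triangle_residue):
        one = THREE_TO_ONE.get(mesh.residue_names[rid])
        if one is not None:
            acc[idx[one]] += mesh.triangle_area[t]
    total = acc.sum()
    if total <= 0:
        raise DataError("no standard-residue surface area")
    return acc / total


@dataclass
class StructuralFeatureVector:
    """Fixed 35-column structural feature layout."""

    elec_patch_area: np.ndarray   # 5 signed areas
    hyd_patch_area: np.ndarray    # 5 areas
    hbond_patch_area: np.ndarray  # 5 areas
    propensity: np.ndarray        # 20 fractions, AA_ORDER

    _names: list[str] = field(default=None, repr=False, compare=False)

    @staticmethod
    def feature_names() -> list[str]:
        names = [f"elec_patch_{i}" for i in range(1, 6)]
        names += [f"hyd_patch_{i}" for i in range(1, 6)]
        names += [f"hbond_patch_{i}" for i in range(1, 6)]
        names += [f"prop_{aa}" for aa in AA_ORDER]
        return names

    def to_array(self) -> np.ndarray:
        return np.concatenate([self.elec_patch_area, self.hyd_patch_area,
                               self.hbond_patch_area, self.propensity])


def structural_features(mesh: SurfaceMesh, elec_channel: str = "elec",
                        hyd_channel: str = "kd", hbond_channel: str = "hbond",
                        hyd_tolerance: float = 1.5,
                        hyd_min: float = 0.0) -> StructuralFeatureVector:
    """The 35 structural features of a property-mapped surface.

    Electrostatic patches grow by sign connectivity over the whole surface
    and carry their sign; hydrophobic patches grow with tolerance
    ``hyd_tolerance`` over triangles with Kyte-Doolittle value >=
    ``hyd_min``; H-bond patches are connected value-1 regions.
    """
    elec = grow_patches(mesh, elec_channel, PatchGrowConfig(mode="sign"))
    hyd = grow_patches(mesh, hyd_channel,
                       PatchGrowConfig(C=hyd_tolerance, mode="tolerance"),
                       eligible=mesh.channels[hyd_channel] >= hyd_min)
    hb = grow_patches(mesh, hbond_channel, PatchGrowConfig(mode="binary"),
                      eligible=mesh.channels[hbond_channel] == 1)
    return StructuralFeatureVector(
        elec_patch_area=top_k_patch_areas(elec, 5, signed=True),
        hyd_patch_area=top_k_patch_areas(hyd, 5),
        hbond_patch_area=top_k_patch_areas(hb, 5),
        propensity=surface_propensities(mesh))
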