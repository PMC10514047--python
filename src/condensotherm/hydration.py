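"""Structural water metrics: tetrahedral order, hydrogen bonds, hydration
layer populations, chain radius of gyration, and piecewise-linear
crossover fitting.

Conventions (all configurable, all logged in reports):

* the tetrahedral order parameter uses the 4 nearest water oxygens with
  no distance cutoff (Errington-Debenedetti convention);
* the hydrogen-bond criterion defaults to donor-acceptor heavy-atom
  distance <= 0.35 nm and H-donor-acceptor angle <= 30 degrees;
* hydration-layer membership counts a water if any of its atoms lies
  within the cutoff (default 0.3 nm) of any protein atom, hydrogens
  included.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .trajectory import Frame, Topology, minimum_image, wrap_positions

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# tetrahedral order parameter
# ---------------------------------------------------------------------------

def tetrahedral_q_points(center: np.ndarray, neighbors: np.ndarray) -> float:
    """q for one center and its 4 neighbour positions (no PBC).

    q = 1 - 3/8 * sum_{j<k} (cos psi_jk + 1/3)^2 over the 6 angles at the
    center; 1 for a perfect tetrahedron, ~0 for random directions.
    """
    vecs = np.asarray(neighbors, dtype=float) - np.asarray(center, dtype=float)
    if vecs.shape != (4, 3):
        raise ValueError("need exactly 4 neighbors")
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    total = 0.0
    for j in range(3):
        for k in range(j + 1, 4):
            cos_psi = float(np.dot(vecs[j], vecs[k]))
            total += (cos_psi + 1.0 / 3.0) ** 2
    return 1.0 - 3.0 / 8.0 * total


def tetrahedral_q(
    frame: Frame, topology: Topology, selection: np.ndarray | None = None
) -> np.ndarray:
    """q per water oxygen, neighbours = 4 nearest water oxygens (minimum
    image).  Waters with fewer than 4 available neighbours get NaN."""
    oxy = selection if selection is not None else topology.water_oxygens
    pos = wrap_positions(frame.positions[oxy], frame.box)
    n = len(pos)
    if n < 5:
        raise ValueError("need at least 5 water oxygens (center + 4 neighbors)")
    tree = cKDTree(pos, boxsize=frame.box)
    _, idx = tree.query(pos, k=5)
    q = np.empty(n)
    for i in range(n):
        nbr = idx[i, 1:]
        vecs = minimum_image(pos[nbr] - pos[i], frame.box)
        q[i] = tetrahedral_q_points(np.zeros(3), vecs)
    return q


@dataclass
class QDistribution:
    """Histogram of tetrahedral order parameter values."""

    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    n_samples: int

    @property
    def density(self) -> np.ndarray:
        widths = np.diff(self.bin_edges)
        return self.counts / (self.counts.sum() * widths)


def q_distribution(
    q_values: np.ndarray | list[np.ndarray], bins: int = 60,
    range_: tuple[float, float] = (-3.0, 1.0),
) -> QDistribution:
    """Histogram + mean of q values; multiple frames are aggregated."""
    if isinstance(q_values, (list, tuple)):
        q_values = np.concatenate([np.asarray(v).ravel() for v in q_values])
    q = np.asarray(q_values, dtype=float).ravel()
    q = q[np.isfinite(q)]
    if len(q) == 0:
        raise ValueError("no q values")
    counts, edges = np.histogram(q, bins=bins, range=range_)
    return QDistribution(
        bin_edges=edges, counts=counts, mean=float(q.mean()), n_samples=len(q)
    )


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondCriterion:
    """Geometric H-bond criterion: donor-acceptor heavy-atom distance (nm)
    and H-donor-acceptor angle (degrees)."""

    distance: float = 0.35
    angle: float = 30.0

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0.0 < self.angle <= 90.0:
            raise ValueError("angle cutoff must be in (0, 90] degrees")


@dataclass
class HBondReport:
    n_bonds: int
    per_water: np.ndarray
    mean_per_water: float
    pairing: str
    criterion: HBondCriterion
    convention: str = "symmetric: per-water mean = 2 * bonds / n_waters"


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def count_hbonds(
    frame: Frame,
    topology: Topology,
    criterion: HBondCriterion | None = None,
    pairing: str = "water-water",
) -> HBondReport:
    """Count hydrogen bonds under the geometric criterion (minimum image).

    water-water: each water donates through its two hydrogens to other
    water oxygens; every D-H...A is counted once.  protein-water counts
    water-donor to protein N/O acceptors plus protein-donor (H covalently
    bound to N/O) to water oxygens.
    """
    criterion = criterion or HBondCriterion()
    if topology.n_waters == 0:
        raise ValueError("no waters in topology")
    box = frame.box
    oxy = topology.water_oxygens
    opos = wrap_positions(frame.positions[oxy], box)
    nw = len(oxy)
    per_water = np.zeros(nw)
    n_bonds = 0
    tree = cKDTree(opos, boxsize=box)
    if pairing == "water-water":
        pairs = tree.query_pairs(criterion.distance, output_type="ndarray")
        for a, b in pairs:
            # try both donor directions
            for don, acc in ((a, b), (b, a)):
                d_oo = minimum_image(
                    frame.positions[oxy[acc]] - frame.positions[oxy[don]], box
                )
                bonded = False
                for h_site in (1, 2):
                    h_idx = topology.waters[don, h_site]
                    d_oh = minimum_image(
                        frame.positions[h_idx] - frame.positions[oxy[don]], box
                    )
                    if _angle_deg(d_oh, d_oo) <= criterion.angle:
                        bonded = True
                        break
                if bonded:
                    n_bonds += 1
                    per_water[don] += 1
                    per_water[acc] += 1
        mean = 2.0 * n_bonds / nw
    elif pairing == "protein-water":
        prot = topology.protein_indices
        if len(prot) == 0:
            raise ValueError("no protein atoms for protein-water pairing")
        elements = np.array([n[0].upper() for n in topology.names])
        polar = prot[np.isin(elements[prot], ["N", "O"])]
        ppos = wrap_positions(frame.positions[polar], box)
        ptree = cKDTree(ppos, boxsize=box)
        # water donor -> protein acceptor
        for wi in range(nw):
            for acc_local in ptree.query_ball_point(opos[wi], criterion.distance):
                d_oa = minimum_image(
                    frame.positions[polar[acc_local]] - frame.positions[oxy[wi]], box
                )
                for h_site in (1, 2):
                    h_idx = topology.waters[wi, h_site]
                    d_oh = minimum_image(
                        frame.positions[h_idx] - frame.positions[oxy[wi]], box
                    )
                    if _angle_deg(d_oh, d_oa) <= criterion.angle:
                        n_bonds += 1
                        per_water[wi] += 1
                        break
        # protein donor (H on N/O) -> water oxygen
        hyd = prot[elements[prot] == "H"]
        for h in hyd:
            # covalently attached heavy atom
            d_ph = minimum_image(frame.positions[polar] - frame.positions[h], box)
            dist = np.linalg.norm(d_ph, axis=1)
            if len(dist) == 0 or dist.min() > 0.12:
                continue
            donor = polar[int(np.argmin(dist))]
            dpos = wrap_positions(frame.positions[donor][None, :], box)[0]
            for wi in tree.query_ball_point(dpos, criterion.distance):
                d_da = minimum_image(
                    frame.positions[oxy[wi]] - frame.positions[donor], box
                )
                d_dh = minimum_image(
                    frame.positions[h] - frame.positions[donor], box
                )
                if _angle_deg(d_dh, d_da) <= criterion.angle:
                    n_bonds += 1
                    per_water[wi] += 1
        mean = n_bonds / nw
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    logger.info(
        "HB count (%s): %d bonds, criterion d<=%.3f nm angle<=%.1f deg",
        pairing, n_bonds, criterion.distance, criterion.angle,
    )
    return HBondReport(
        n_bonds=n_bonds, per_water=per_water,
        mean_per_water=float(mean), pairing=pairing, criterion=criterion,
    )


def count_hbonds_bruteforce(
    frame: Frame, topology: Topology, criterion: HBondCriterion | None = None
) -> int:
    """Exhaustive all-pairs water-water HB count (oracle for tests)."""
    criterion = criterion or HBondCriterion()
    oxy = topology.water_oxygens
    n = len(oxy)
    count = 0
    for don in range(n):
        for acc in range(n):
            if don == acc:
                continue
            d_oo = minimum_image(
                frame.positions[oxy[acc]] - frame.positions[oxy[don]], frame.box
            )
            if np.linalg.norm(d_oo) > criterion.distance:
                continue
            for h_site in (1, 2):
                h_idx = topology.waters[don, h_site]
                d_oh = minimum_image(
                    frame.positions[h_idx] - frame.positions[oxy[don]], frame.box
                )
                if _angle_deg(d_oh, d_oo) <= criterion.angle:
                    count += 1
                    break
    return count


# ---------------------------------------------------------------------------
# hydration layer
# ---------------------------------------------------------------------------

@dataclass
class HydrationLayer:
    per_chain: np.ndarray
    total: int
    mean_per_chain: float
    normalized: float | None
    cutoff: float


def count_phl_waters(
    frame: Frame,
    topology: Topology,
    cutoff: float = 0.3,
    reference: float | None = None,
) -> HydrationLayer:
    """Waters with any atom within ``cutoff`` of any protein atom.

    Each hydration water is assigned to the chain owning its nearest
    protein atom; ``reference`` (waters per chain of a dilute single-chain
    system) normalizes the per-chain mean.
    """
    if topology.n_chains < 1:
        raise ValueError("need at least one chain")
    if reference is not None and reference <= 0:
        raise ValueError("reference must be positive")
    box = frame.box
    prot = topology.protein_indices
    ppos = wrap_positions(frame.positions[prot], box)
    ptree = cKDTree(ppos, boxsize=box)
    chain_of_atom = np.empty(len(prot), dtype=int)
    offset = 0
    for ci, chain in enumerate(topology.chains):
        chain_of_atom[offset:offset + chain.n_atoms] = ci
        offset += chain.n_atoms

    wpos = wrap_positions(
        frame.positions[topology.waters.reshape(-1)], box
    ).reshape(topology.n_waters, -1, 3)
    per_chain = np.zeros(topology.n_chains, dtype=int)
    total = 0
    for wi in range(topology.n_waters):
        dists, idxs = ptree.query(wpos[wi])
        best = int(np.argmin(dists))
        if dists[best] <= cutoff:
            total += 1
            per_chain[chain_of_atom[idxs[best]]] += 1
    mean = total / topology.n_chains
    return HydrationLayer(
        per_chain=per_chain,
        total=total,
        mean_per_chain=float(mean),
        normalized=(mean / reference) if reference else None,
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# radius of gyration
# ---------------------------------------------------------------------------

def radius_of_gyration(
    coords: np.ndarray, masses: np.ndarray, box: np.ndarray | None = None
) -> float:
    """Mass-weighted Rg (nm) of one chain, minimum-image unwrapped.

    Raises if consecutive atoms are farther apart than a quarter of the
    smallest box edge after minimum imaging (chain cannot be unwrapped
    reliably).
    """
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if box is not None:
        steps = minimum_image(np.diff(coords, axis=0), box)
        limit = float(np.min(box)) / 4.0
        if len(steps) and np.linalg.norm(steps, axis=1).max() > limit:
            raise ValueError(
                "broken chain: consecutive atoms farther than min(box)/4 "
                "after minimum imaging"
            )
        coords = np.vstack([coords[0], coords[0] + np.cumsum(steps, axis=0)])
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    return float(
        np.sqrt((masses * ((coords - com) ** 2).sum(axis=1)).sum() / masses.sum())
    )


# ---------------------------------------------------------------------------
# crossover fitting
# ---------------------------------------------------------------------------

@dataclass
class CrossoverFit:
    breakpoint: float
    slope_left: float
    slope_right: float
    intercept: float
    rss: float
    degenerate: bool = False
    breakpoint_sd: float | None = None

    @property
    def slope_ratio(self) -> float:
        if self.slope_left == 0:
            return math.inf
        return self.slope_right / self.slope_left


def _hinge_fit(x, y, w, knot):
    basis = np.column_stack([np.ones_like(x), x, np.maximum(x - knot, 0.0)])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(basis * sw[:, None], y * sw, rcond=None)
    resid = y - basis @ coef
    return coef, float(np.sum(w * resid ** 2))


def fit_crossover(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    refine: bool = True,
    replicates: list[np.ndarray] | None = None,
) -> CrossoverFit:
    """Continuous two-segment least-squares fit with breakpoint scan.

    Candidate knots are the interior data-grid points (>= 2 points on each
    side); the best knot is optionally refined continuously between its
    neighbours.  A fit that improves on a single line by < 1% RSS is
    flagged degenerate (breakpoint unreliable, slope ratio ~ 1).  When
    replicate y-vectors are given, the breakpoint SD over replicate refits
    is reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 points for a crossover fit")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)[order]

    def best_fit(yv):
        results = []
        for knot in x[2:-2]:
            coef, rss = _hinge_fit(x, yv, w, knot)
            results.append((rss, knot, coef))
        rss, knot, coef = min(results, key=lambda r: r[0])
        if refine:
            from scipy.optimize import minimize_scalar

            i = int(np.searchsorted(x, knot))
            lo = x[max(i - 1, 2 - 1)]
            hi = x[min(i + 1, n - 2)]
            if hi > lo:
                res = minimize_scalar(
                    lambda kk: _hinge_fit(x, yv, w, kk)[1],
                    bounds=(lo, hi), method="bounded",
                    options={"xatol": 1e-10},
                )
                coef2, rss2 = _hinge_fit(x, yv, w, float(res.x))
                if rss2 <= rss:
                    knot, coef, rss = float(res.x), coef2, rss2
        return knot, coef, rss

    knot, coef, rss = best_fit(y)
    # single straight line comparison
    basis1 = np.column_stack([np.ones_like(x), x])
    sw = np.sqrt(w)
    c1, *_ = np.linalg.lstsq(basis1 * sw[:, None], y * sw, rcond=None)
    rss1 = float(np.sum(w * (y - basis1 @ c1) ** 2))
    scale = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    degenerate = rss >= 0.99 * rss1 or rss1 <= 1e-12 * max(scale, 1e-300)

    bp_sd = None
    if replicates:
        bps = []
        for yr in replicates:
            yr = np.asarray(yr, dtype=float)[order]
            bps.append(best_fit(yr)[0])
        bp_sd = float(np.std(bps))

    if degenerate:
        return CrossoverFit(
            breakpoint=knot, slope_left=float(c1[1]), slope_right=float(c1[1]),
            intercept=float(c1[0]), rss=rss1, degenerate=True, breakpoint_sd=bp_sd,
        )
    return CrossoverFit(
        breakpoint=float(knot),
        slope_left=float(coef[1]),
        slope_right=float(coef[1] + coef[2]),
        intercept=float(coef[0]),
        rss=rss,
        degenerate=False,
        breakpoint_sd=bp_sd,
    )
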