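"""Protein conformational entropy from torsion-angle distributions.

Per-variable differential entropies are estimated with a
Kozachenko-Leonenko k-nearest-neighbour estimator using the circular
(wrap-around) metric; pairwise mutual information with the
Kraskov-Stoegbauer-Grassberger estimator on the torus.  Totals follow the
first-order maximum-information-spanning-tree (MIST) aggregation: the sum
of marginals minus the mutual information summed over the maximum
spanning tree of the pairwise-MI graph, a lower-order upper bound on the
joint entropy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import cKDTree
from scipy.special import digamma

from .constants import R_GAS
from .trajectory import Frame, Topology, minimum_image

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * math.pi


@dataclass
class TorsionSamples:
    """Circular samples per torsion variable per chain.

    ``data`` has shape (n_chains, n_variables, n_samples), radians in
    (-pi, pi].  ``labels`` is one (chain_id, residue, name) tuple per
    variable; variables are shared across chains (chains are copies of
    the same molecule).
    """

    labels: list[tuple]
    data: np.ndarray
    pair_mask: np.ndarray | None = None   # which variable pairs enter MI
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_chains, n_variables, n_samples)")
        if self.data.shape[1] != len(self.labels):
            raise ValueError("labels/variables mismatch")
        if np.any(self.data > math.pi + 1e-12) or np.any(self.data <= -math.pi - 1e-12):
            raise ValueError("torsion samples must lie in (-pi, pi]")

    @property
    def n_chains(self) -> int:
        return self.data.shape[0]

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class EntropyEstimate:
    """Conformational entropy estimate (per chain averages)."""

    marginals: np.ndarray                 # (n_variables,) nats
    mi_edges: list[tuple[int, int, float]]
    total: float                          # nats
    total_per_chain: np.ndarray           # (n_chains,)
    labels: list[tuple]
    k: int = 1

    @property
    def total_j_per_mol_k(self) -> float:
        return R_GAS * self.total

    @property
    def total_sd(self) -> float:
        if len(self.total_per_chain) < 2:
            return 0.0
        return float(np.std(self.total_per_chain))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (radians, (-pi, pi]) of four points.

    Raises ValueError if the three central atoms are collinear (undefined
    dihedral).
    """
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    nb1 = np.linalg.norm(b1)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("undefined dihedral: collinear atoms")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1) / nb1)
    return math.atan2(y, x)


def _chain_dihedrals(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """All consecutive-quadruplet dihedrals along one unwrapped chain."""
    steps = minimum_image(np.diff(positions, axis=0), box)
    unwrapped = np.vstack([positions[0], positions[0] + np.cumsum(steps, axis=0)])
    n = len(unwrapped) - 3
    out = np.empty(n)
    for i in range(n):
        try:
            out[i] = dihedral_angle(*unwrapped[i:i + 4])
        except ValueError:
            out[i] = np.nan   # flagged missing, not zero
    return out


def extract_torsions(
    frames: list[Frame], topology: Topology, cutoff: float = 0.8
) -> TorsionSamples:
    """Backbone torsions of every chain across frames.

    For bead-string chains each consecutive quadruplet defines one
    torsion.  ``cutoff`` (nm) sets the neighbourhood used to decide which
    torsion pairs enter the correlated (mutual-information) treatment:
    pairs whose central-bond midpoints lie within the cutoff in the first
    frame are eligible.
    """
    if not topology.chains:
        raise ValueError("topology has no chains")
    n_res = topology.chains[0].n_atoms
    if any(c.n_atoms != n_res for c in topology.chains):
        raise ValueError("chains of unequal length are not supported")
    if n_res < 4:
        raise ValueError("need at least 4 atoms per chain for a torsion")
    n_vars = n_res - 3
    data = np.empty((topology.n_chains, n_vars, len(frames)))
    for fi, frame in enumerate(frames):
        for ci, chain in enumerate(topology.chains):
            data[ci, :, fi] = _chain_dihedrals(
                frame.positions[chain.atom_indices], frame.box
            )
    labels = [(c.id, i + 1, f"chi{i + 1}") for c in topology.chains[:1] for i in range(n_vars)]

    # eligibility mask from central-bond midpoints in the first frame
    frame0 = frames[0]
    chain0 = topology.chains[0]
    pos = frame0.positions[chain0.atom_indices]
    steps = minimum_image(np.diff(pos, axis=0), frame0.box)
    unwrapped = np.vstack([pos[0], pos[0] + np.cumsum(steps, axis=0)])
    centers = 0.5 * (unwrapped[1:-2] + unwrapped[2:-1])   # (n_vars, 3)
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    mask = d <= cutoff
    np.fill_diagonal(mask, False)
    return TorsionSamples(labels=labels, data=data, pair_mask=mask)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _dedupe_jitter(x: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Deterministically jitter duplicate samples (logged)."""
    xs = np.sort(x)
    if np.min(np.diff(xs)) > tol:
        return x
    logger.warning("duplicate circular samples detected; applying 1e-10 jitter")
    jit = np.random.default_rng(0).uniform(-1e-10, 1e-10, size=x.shape)
    return x + jit


def knn_entropy(samples: np.ndarray, k: int = 1) -> float:
    """Kozachenko-Leonenko kNN differential entropy (nats) of one circular
    variable, using wrap-around distances and the digamma bias correction.
    """
    x = np.asarray(samples, dtype=float).ravel()
    n = len(x)
    if n <= k + 1:
        raise ValueError("need more than k+1 samples")
    x = _dedupe_jitter(x)
    pts = np.mod(x, TWO_PI).reshape(-1, 1)
    tree = cKDTree(pts, boxsize=TWO_PI)
    r, _ = tree.query(pts, k=k + 1)
    rk = np.maximum(r[:, k], 1e-300)
    # 1-D "ball volume" is 2r
    return float(
        digamma(n) - digamma(k) + np.mean(np.log(2.0 * rk))
    )


def knn_mutual_information(x: np.ndarray, y: np.ndarray, k: int = 3) -> float:
    """KSG-1 mutual information (nats) of two circular variables on the
    torus (Chebyshev metric, periodic boxes)."""
    x = np.mod(np.asarray(x, dtype=float).ravel(), TWO_PI)
    y = np.mod(np.asarray(y, dtype=float).ravel(), TWO_PI)
    n = len(x)
    if n != len(y):
        raise ValueError("sample size mismatch")
    if n <= k + 1:
        raise ValueError("need more than k+1 samples")
    joint = np.column_stack([x, y])
    tree = cKDTree(joint, boxsize=TWO_PI)
    eps, _ = tree.query(joint, k=k + 1, p=np.inf)
    eps_k = eps[:, k]
    tx = cKDTree(x.reshape(-1, 1), boxsize=TWO_PI)
    ty = cKDTree(y.reshape(-1, 1), boxsize=TWO_PI)
    nx = np.array(
        [len(tx.query_ball_point([xi], r)) - 1 for xi, r in zip(x, eps_k * (1 - 1e-12))]
    )
    ny = np.array(
        [len(ty.query_ball_point([yi], r)) - 1 for yi, r in zip(y, eps_k * (1 - 1e-12))]
    )
    mi = (
        digamma(k)
        + digamma(n)
        - float(np.mean(digamma(nx + 1) + digamma(ny + 1)))
    )
    return float(mi)


def mist_total(samples: TorsionSamples, k: int = 1, k_mi: int = 3) -> EntropyEstimate:
    """First-order MIST conformational entropy.

    Per chain: sum of marginal kNN entropies minus the pairwise MI summed
    over the maximum spanning tree of the MI graph (restricted to the
    eligibility mask when present).  The reported total is the mean over
    chains.  A single variable yields its marginal, with no tree.
    """
    n_chains, n_vars, _ = samples.data.shape
    totals = np.empty(n_chains)
    marg_acc = np.zeros(n_vars)
    edge_acc: dict[tuple[int, int], float] = {}
    for c in range(n_chains):
        marg = np.array([knn_entropy(samples.data[c, i], k=k) for i in range(n_vars)])
        marg_acc += marg
        if n_vars == 1:
            totals[c] = marg[0]
            continue
        w = np.zeros((n_vars, n_vars))
        for i in range(n_vars):
            for j in range(i + 1, n_vars):
                if samples.pair_mask is not None and not samples.pair_mask[i, j]:
                    continue
                mi = max(
                    knn_mutual_information(
                        samples.data[c, i], samples.data[c, j], k=k_mi
                    ),
                    0.0,
                )
                # cap at the smaller marginal: the KSG estimate diverges
                # (~ln n) for near-deterministic couplings, where the
                # correct first-order total collapses to one marginal
                w[i, j] = min(mi, max(min(marg[i], marg[j]), 0.0))
        # maximum spanning tree == minimum spanning tree of negated weights
        tree = minimum_spanning_tree(-w)
        ii, jj = tree.nonzero()
        tree_mi = 0.0
        for a, b in zip(ii, jj):
            e = (min(a, b), max(a, b))
            val = w[e[0], e[1]]
            tree_mi += val
            edge_acc[e] = edge_acc.get(e, 0.0) + val
        totals[c] = marg.sum() - tree_mi
    edges = [(a, b, v / n_chains) for (a, b), v in sorted(edge_acc.items())]
    return EntropyEstimate(
        marginals=marg_acc / n_chains,
        mi_edges=edges,
        total=float(totals.mean()),
        total_per_chain=totals,
        labels=samples.labels,
        k=k,
    )


def delta_conf_entropy(
    dense: EntropyEstimate, dilute: EntropyEstimate, T: float = 300.0
) -> tuple[float, float]:
    """(dS_P in J mol^-1 K^-1, -T dS_P in kJ/mol), dense minus dilute.

    Totals are already chain-averaged; the caller averages replicates.
    Positive -T dS_P means the conformational term disfavours the dense
    state.  Note: this is a rough estimate by construction (sampling
    limits of torsion-space entropies).
    """
    if len(dense.labels) != len(dilute.labels):
        raise ValueError(
            "variable sets differ: "
            f"{len(dense.labels)} dense vs {len(dilute.labels)} dilute variables"
        )
    ds = R_GAS * (dense.total - dilute.total)   # J/mol/K
    return float(ds), float(-T * ds / 1000.0)
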