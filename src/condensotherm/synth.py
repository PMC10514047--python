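"""Synthetic-data generators with attached analytic ground truth.

Every generator is deterministic under a fixed seed and attaches the
quantities a downstream consumer should recover (entropies per dof,
planted slopes and breakpoints, distribution entropies), so that each
pipeline stage can be tested against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import i0, i1

from .constants import KB, N_AVOGADRO, WATER_DENSITY
from .trajectory import (
    Chain,
    ConcentrationRecord,
    ConcentrationSeries,
    Frame,
    Topology,
    VelocitySeries,
    WaterModel,
)
from .twopt import ho_entropy_weight, sackur_tetrode


@dataclass
class SyntheticSpec:
    """Provenance record travelling with generated data."""

    kind: str
    parameters: dict
    seed: int
    ground_truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# velocity-series generators
# ---------------------------------------------------------------------------

def ho_entropy_per_dof(frequency: float, T: float) -> float:
    """Quantum harmonic-oscillator entropy per dof in units of k_B."""
    return float(ho_entropy_weight(np.array([frequency]), T)[0])


def gen_harmonic_ensemble(
    frequencies: list[float],
    T: float = 300.0,
    n_molecules: int = 64,
    duration: float = 20.0,
    dt: float = 0.004,
    mass: float = 18.0153,
    seed: int = 0,
) -> VelocitySeries:
    """Thermal ensemble of harmonic oscillators (translational dof only).

    Each Cartesian dof is an equal-variance superposition of the requested
    frequencies (THz); total variance satisfies equipartition.  Ground
    truth: the exact quantum HO entropy per dof at T, averaged over the
    frequency list.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError(
            "harmonic frequencies must be positive (the HO entropy diverges "
            "as the frequency approaches zero)"
        )
    nyquist = 1.0 / (2.0 * dt)
    if np.max(freqs) >= nyquist:
        raise ValueError(
            f"max frequency {np.max(freqs)} THz violates Nyquist limit "
            f"{nyquist} THz for dt = {dt} ps"
        )
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / dt)) + 1
    t = np.arange(n_frames) * dt
    k = len(freqs)
    sigma = math.sqrt(KB * T / (mass * k))
    # (freq, mol, axis) amplitudes
    a = rng.normal(scale=sigma, size=(k, n_molecules, 3))
    b = rng.normal(scale=sigma, size=(k, n_molecules, 3))
    # global rescale so the realized ensemble carries exactly 3N k_B T of
    # twice-kinetic energy (removes O(1/sqrt(N)) sampling error from the
    # attached ground truth)
    target = 3.0 * n_molecules * KB * T
    actual = 0.5 * mass * float(np.sum(a ** 2 + b ** 2))
    scale = math.sqrt(target / actual)
    a *= scale
    b *= scale
    phases = 2.0 * np.pi * freqs[:, None] * t[None, :]        # (k, frames)
    v = np.einsum("kf,kmd->fmd", np.cos(phases), a) + np.einsum(
        "kf,kmd->fmd", np.sin(phases), b
    )
    gt = {
        "entropy_per_dof_kb": float(
            np.mean([ho_entropy_per_dof(f, T) for f in freqs])
        ),
        "temperature": T,
    }
    return VelocitySeries(
        dt=dt,
        com_velocities=v,
        masses=np.full(n_molecules, mass),
        meta={
            "spec": SyntheticSpec(
                "harmonic_ensemble",
                {"frequencies": list(freqs), "T": T, "duration": duration, "dt": dt},
                seed,
                gt,
            ),
            "ground_truth": gt,
        },
    )


def gen_ideal_gas(
    mass: float = 18.0153,
    T: float = 300.0,
    density: float = 0.1,
    n: int = 256,
    duration: float = 100.0,
    dt: float = 0.05,
    seed: int = 0,
) -> VelocitySeries:
    """Free-flight Maxwell-Boltzmann gas: velocities constant in time.

    ``density`` is the molecular number density (molecules/nm^3).  Ground
    truth: the Sackur-Tetrode translational entropy at (m, T, rho).
    """
    if density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / dt)) + 1
    v0 = rng.normal(scale=math.sqrt(KB * T / mass), size=(n, 3))
    v = np.broadcast_to(v0, (n_frames, n, 3)).copy()
    gt = {
        "sackur_tetrode": sackur_tetrode(T, mass, density),
        "n_density": density,
        "temperature": T,
    }
    return VelocitySeries(
        dt=dt,
        com_velocities=v,
        masses=np.full(n, mass),
        meta={
            "spec": SyntheticSpec(
                "ideal_gas",
                {"mass": mass, "T": T, "density": density, "duration": duration},
                seed,
                gt,
            ),
            "ground_truth": gt,
        },
    )


# ---------------------------------------------------------------------------
# Langevin soft-sphere fluid
# ---------------------------------------------------------------------------

def _water_topology(n_waters: int, model: WaterModel, resid_start: int = 1) -> Topology:
    names = np.array(["OW", "HW1", "HW2"] * n_waters)
    resnames = np.array(["SOL"] * (3 * n_waters))
    resids = np.repeat(np.arange(resid_start, resid_start + n_waters), 3)
    masses = np.tile(model.site_masses()[:3], n_waters)
    waters = np.arange(3 * n_waters).reshape(n_waters, 3)
    model3 = WaterModel(name=model.name, n_sites=3, r_oh=model.r_oh,
                        angle_hoh=model.angle_hoh, d_om=model.d_om,
                        q_h=model.q_h, sigma=model.sigma, epsilon=model.epsilon)
    top = Topology(
        names=names, resnames=resnames, resids=resids, masses=masses,
        waters=waters, water_model=model3,
    )
    top.validate()
    return top


def _random_water_sites(
    centers: np.ndarray, model: WaterModel, rng: np.random.Generator
) -> np.ndarray:
    """Rigid 3-site waters at random orientations around given O positions."""
    from .waterbox import _random_rotations

    n = len(centers)
    sites = model.site_positions()[:3]
    rots = _random_rotations(rng, n)
    return (centers[:, None, :] + np.einsum("nab,sb->nsa", rots, sites)).reshape(-1, 3)


def gen_langevin_fluid(
    n_waters: int = 125,
    box: float = 1.7,
    T: float = 300.0,
    gamma: float = 2.0,
    duration: float = 5.0,
    dt: float = 0.002,
    out_every: float = 0.02,
    seed: int = 0,
    max_retries: int = 200,
) -> tuple[Topology, list[Frame]]:
    """Soft-sphere water-like fluid under BAOAB Langevin dynamics.

    Particles are purely repulsive (WCA) spheres carrying the mass of one
    water; emitted frames hold rigid 3-site waters (fixed random
    orientation per particle) so that downstream oxygen-based structural
    metrics apply.  gamma is the friction in 1/ps.
    """
    rng = np.random.default_rng(seed)
    model = WaterModel()
    sigma, eps = 0.30, 0.65
    rcut = sigma * 2.0 ** (1.0 / 6.0)
    mass = model.mass
    boxv = np.full(3, float(box))

    # non-overlapping initial placement
    pos = np.empty((n_waters, 3))
    placed = 0
    attempts = 0
    min_d = 0.8 * sigma
    while placed < n_waters:
        cand = rng.uniform(0, box, size=3)
        if placed == 0:
            ok = True
        else:
            d = pos[:placed] - cand
            d -= boxv * np.round(d / boxv)
            ok = bool(np.all((d ** 2).sum(axis=1) > min_d ** 2))
        if ok:
            pos[placed] = cand
            placed += 1
            attempts = 0
        else:
            attempts += 1
            if attempts > max_retries * n_waters:
                raise RuntimeError(
                    f"could not place {n_waters} particles in box {box} nm "
                    "without overlap"
                )
    vel = rng.normal(scale=math.sqrt(KB * T / mass), size=(n_waters, 3))

    def forces(p: np.ndarray) -> np.ndarray:
        d = p[:, None, :] - p[None, :, :]
        d -= boxv * np.round(d / boxv)
        r2 = (d ** 2).sum(axis=2)
        np.fill_diagonal(r2, np.inf)
        mask = r2 < rcut ** 2
        inv2 = np.where(mask, 1.0 / np.where(mask, r2, 1.0), 0.0)
        inv6 = inv2 ** 3 * sigma ** 6
        fmag = 24.0 * eps * (2.0 * inv6 ** 2 - inv6) * inv2
        return (fmag[:, :, None] * d).sum(axis=1)

    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt((1.0 - c1 ** 2) * KB * T / mass)
    f = forces(pos)
    stride = max(int(round(out_every / dt)), 1)
    nsteps = int(round(duration / dt))
    orient_rng = np.random.default_rng(seed + 1)
    rots_seed = orient_rng.integers(0, 2 ** 31)
    frames: list[Frame] = []

    def emit(t: float) -> None:
        site_rng = np.random.default_rng(rots_seed)  # same orientations each frame
        positions = _random_water_sites(pos, model, site_rng)
        velocities = np.repeat(vel, 3, axis=0)
        frames.append(
            Frame(positions=positions, box=boxv.copy(), time=t, velocities=velocities)
        )

    emit(0.0)
    for step in range(1, nsteps + 1):
        vel += 0.5 * dt * f / mass
        pos += 0.5 * dt * vel
        vel = c1 * vel + c2 * rng.normal(size=vel.shape)
        pos += 0.5 * dt * vel
        f = forces(pos)
        vel += 0.5 * dt * f / mass
        if step % stride == 0:
            emit(step * dt)
    return _water_topology(n_waters, model), frames


# ---------------------------------------------------------------------------
# toy condensate
# ---------------------------------------------------------------------------

# nominal concentration grid of the dense-phase series (mg/mL)
DEFAULT_RHO_SERIES = (25.0, 60.0, 100.0, 145.0, 205.0, 260.0, 350.0, 525.0)

# effective dry protein density used to split box volume into protein and
# water parts; chosen so that the 350 mg/mL, 17.2 kDa, 8-chain system holds
# ~2064 waters per chain
DRY_PROTEIN_DENSITY = 1.452  # g/cm^3


def condensate_box_edge(rho: float, n_chains: int, chain_mass: float) -> float:
    """Cubic box edge (nm) for n_chains of chain_mass (kDa) at rho (mg/mL)."""
    if rho <= 0 or n_chains <= 0 or chain_mass <= 0:
        raise ValueError("rho, n_chains and chain_mass must be positive")
    volume = n_chains * chain_mass * 1000.0 / (N_AVOGADRO * rho * 1e-24)  # nm^3
    return volume ** (1.0 / 3.0)


def concentration_from_box(box_edge: float, n_chains: int, chain_mass: float) -> float:
    """Protein mass concentration (mg/mL) from a cubic box edge (nm)."""
    return n_chains * chain_mass * 1000.0 / (N_AVOGADRO * box_edge ** 3 * 1e-24)


def waters_per_chain(rho: float, chain_mass: float) -> float:
    """Water count per chain from the volume left over by the protein."""
    v_box = chain_mass * 1000.0 / (N_AVOGADRO * rho * 1e-24)
    v_dry = chain_mass * 1000.0 / (N_AVOGADRO * DRY_PROTEIN_DENSITY * 1e-21)
    n_density_water = WATER_DENSITY * N_AVOGADRO * 1e-21 / 18.0153  # nm^-3
    return max(v_box - v_dry, 0.0) * n_density_water


@dataclass
class ToyCondensate:
    rho: float
    topology: Topology
    frame: Frame
    ground_truth: dict


def gen_toy_condensate(
    rho_series: list[float] | None = None,
    n_chains: int = 8,
    chain_mass: float = 17.2,
    n_residues: int = 40,
    water_fill: float = 1.0,
    seed: int = 0,
) -> list[ToyCondensate]:
    """Bead-string chains plus lattice waters at each concentration.

    Chains are non-physical random-walk bead strings (only geometry
    matters downstream); waters fill the remaining volume on a cubic
    lattice, scaled by ``water_fill`` (< 1 keeps test systems small while
    preserving the concentration trend of the water count).
    """
    rho_series = list(rho_series or DEFAULT_RHO_SERIES)
    rng = np.random.default_rng(seed)
    model = WaterModel()
    out = []
    for rho in rho_series:
        edge = condensate_box_edge(rho, n_chains, chain_mass)
        box = np.full(3, edge)
        n_w = int(round(waters_per_chain(rho, chain_mass) * n_chains * water_fill))

        # bead-string chains: wrapped random walks with 0.38 nm steps
        bead_mass = chain_mass * 1000.0 / n_residues
        chain_pos = []
        for _ in range(n_chains):
            start = rng.uniform(0, edge, size=3)
            steps = rng.normal(size=(n_residues - 1, 3))
            steps *= 0.38 / np.linalg.norm(steps, axis=1, keepdims=True)
            chain_pos.append(start + np.vstack([np.zeros(3), np.cumsum(steps, axis=0)]))
        chain_pos = np.array(chain_pos)          # (chains, res, 3)

        # water oxygens on a lattice, excluding sites near beads
        n_side = max(int(math.ceil((n_w / water_fill) ** (1.0 / 3.0))), 2) + 1
        spacing = edge / n_side
        grid = (
            np.stack(
                np.meshgrid(*[np.arange(n_side)] * 3, indexing="ij"), axis=-1
            ).reshape(-1, 3)
            + 0.5
        ) * spacing
        beads_wrapped = np.mod(chain_pos.reshape(-1, 3), edge)
        tree = cKDTree(beads_wrapped, boxsize=edge)
        near = tree.query_ball_point(grid, r=0.26)
        free = np.array([len(x) == 0 for x in near])
        candidates = grid[free]
        if len(candidates) < n_w:
            n_w = len(candidates)
        sel = rng.permutation(len(candidates))[:n_w]
        centers = candidates[sel]

        # assemble topology
        n_chain_atoms = n_chains * n_residues
        names = np.array(
            ["CA"] * n_chain_atoms + ["OW", "HW1", "HW2"] * n_w
        )
        resnames = np.array(["CHN"] * n_chain_atoms + ["SOL"] * (3 * n_w))
        # one residue per bead, restarting at 1 for each chain, so that the
        # chain partition survives a GRO round trip (chain break on resid
        # decrease)
        resids = np.concatenate(
            [
                np.tile(np.arange(1, n_residues + 1), n_chains),
                np.repeat(np.arange(1, n_w + 1), 3),
            ]
        )
        masses = np.concatenate(
            [np.full(n_chain_atoms, bead_mass), np.tile(model.site_masses()[:3], n_w)]
        )
        chains = [
            Chain(id=str(c), atom_indices=np.arange(c * n_residues, (c + 1) * n_residues))
            for c in range(n_chains)
        ]
        waters = (n_chain_atoms + np.arange(3 * n_w)).reshape(n_w, 3)
        model3 = WaterModel(name="toy", n_sites=3)
        top = Topology(
            names=names, resnames=resnames, resids=resids, masses=masses,
            chains=chains, waters=waters, water_model=model3,
        )
        top.validate()
        positions = np.vstack(
            [chain_pos.reshape(-1, 3), _random_water_sites(centers, model, rng)]
        )
        gt = {
            "rho": rho,
            "box_edge": edge,
            "n_waters": n_w,
            "waters_per_chain_nominal": waters_per_chain(rho, chain_mass),
            "water_fill": water_fill,
        }
        out.append(
            ToyCondensate(
                rho=rho,
                topology=top,
                frame=Frame(positions=positions, box=box, time=0.0),
                ground_truth=gt,
            )
        )
    return out


# ---------------------------------------------------------------------------
# concentration tables
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTables:
    series: ConcentrationSeries
    replicates: list[ConcentrationSeries]
    ground_truth: dict


def _piecewise(rho: np.ndarray, y0: float, slope1: float, slope2: float,
               breakpoint: float) -> np.ndarray:
    """Continuous two-segment line through (0, y0)."""
    rho = np.asarray(rho, dtype=float)
    return np.where(
        rho <= breakpoint,
        y0 + slope1 * rho,
        y0 + slope1 * breakpoint + slope2 * (rho - breakpoint),
    )


def gen_concentration_tables(
    breakpoint: float = 150.0,
    slopes: tuple[float, float] = (-0.008, -0.024),
    noise_sd: float = 0.0,
    rho_grid: list[float] | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    n_chains: int = 8,
    chain_mass: float = 17.2,
    bulk: dict | None = None,
    rho_dil: float = 1.0,
) -> SyntheticTables:
    """Planted concentration series mirroring the qualitative trends of the
    dense-phase study: piecewise-linear S(rho) with a slope crossover,
    decreasing protein energies, increasing per-water WW energy and a
    decreasing water count.

    ``slopes`` are the (below, above breakpoint) gradients of S_tot in
    J mol^-1 K^-1 per (mg/mL).  Gaussian replicate noise of width
    ``noise_sd`` (in the native units of each planted quantity) is applied
    per replicate; the mean series carries replicate SDs.
    """
    rho_grid = np.asarray(
        rho_grid if rho_grid is not None else DEFAULT_RHO_SERIES[:-1], dtype=float
    )
    bulk = dict(bulk or {})
    s_tot0 = bulk.get("s_tot", 54.7)
    s_tr0 = bulk.get("s_tr", 43.8)
    s_rot0 = s_tot0 - s_tr0
    e_ww0 = bulk.get("e_ww", -46.0)
    rng = np.random.default_rng(seed)

    tr_frac = s_tr0 / s_tot0
    planted = {
        "s_tot": lambda r: _piecewise(r, s_tot0, slopes[0], slopes[1], breakpoint),
        "s_tr": lambda r: _piecewise(
            r, s_tr0, slopes[0] * tr_frac, slopes[1] * tr_frac, breakpoint
        ),
        "e_pp": lambda r: -8000.0 - 6.0 * np.asarray(r, dtype=float),
        "e_pw": lambda r: -9000.0 - 8.0 * np.asarray(r, dtype=float),
        "e_ww": lambda r: e_ww0 + 0.004 * np.asarray(r, dtype=float),
    }

    def build(jitter: bool, rng_local: np.random.Generator) -> ConcentrationSeries:
        records = []
        nw_bulk = 10000
        noise = (lambda: rng_local.normal(scale=noise_sd)) if jitter else (lambda: 0.0)
        s_tot_b = s_tot0 + noise()
        s_tr_b = s_tr0 + noise() * tr_frac
        records.append(
            ConcentrationRecord(
                rho=rho_dil, n_chains=0, n_waters=nw_bulk,
                s_tot=s_tot_b, s_tr=s_tr_b, s_rot=s_tot_b - s_tr_b,
                e_pp=0.0, e_pw=0.0, e_ww=e_ww0 + noise(),
            )
        )
        for rho in rho_grid:
            n_w = int(round(waters_per_chain(rho, chain_mass))) * n_chains
            s_tot = float(planted["s_tot"](rho)) + noise()
            s_tr = float(planted["s_tr"](rho)) + noise() * tr_frac
            records.append(
                ConcentrationRecord(
                    rho=float(rho), n_chains=n_chains, n_waters=n_w,
                    s_tot=s_tot, s_tr=s_tr, s_rot=s_tot - s_tr,
                    e_pp=float(planted["e_pp"](rho)) + noise(),
                    e_pw=float(planted["e_pw"](rho)) + noise(),
                    e_ww=float(planted["e_ww"](rho)) + noise(),
                    n_phl=float(waters_per_chain(rho, chain_mass)) * 0.4,
                    box_edge=condensate_box_edge(rho, n_chains, chain_mass),
                )
            )
        return ConcentrationSeries(records)

    replicates = [
        build(noise_sd > 0, np.random.default_rng(rng.integers(0, 2 ** 31)))
        for _ in range(n_replicates)
    ]
    # mean series with replicate SDs
    mean_records = []
    for idx in range(len(replicates[0].records)):
        recs = [rep.records[idx] for rep in replicates]
        fields = ("s_tot", "s_tr", "s_rot", "e_pp", "e_pw", "e_ww")
        means = {f: float(np.mean([getattr(r, f) for r in recs])) for f in fields}
        means["s_tot"] = means["s_tr"] + means["s_rot"]
        sds = {f: float(np.std([getattr(r, f) for r in recs])) for f in fields}
        r0 = recs[0]
        mean_records.append(
            ConcentrationRecord(
                rho=r0.rho, n_chains=r0.n_chains, n_waters=r0.n_waters,
                n_phl=r0.n_phl, box_edge=r0.box_edge, sd=sds, **means,
            )
        )
    gt = {
        "breakpoint": breakpoint,
        "slopes": slopes,
        "bulk_s_tot": s_tot0,
        "planted": planted,
        "noise_sd": noise_sd,
    }
    return SyntheticTables(
        series=ConcentrationSeries(mean_records), replicates=replicates, ground_truth=gt
    )


# ---------------------------------------------------------------------------
# torsion samples
# ---------------------------------------------------------------------------

def von_mises_entropy(kappa: float) -> float:
    """Differential entropy (nats) of a von Mises distribution."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        return math.log(2.0 * math.pi)
    return math.log(2.0 * math.pi * i0(kappa)) - kappa * i1(kappa) / i0(kappa)


def gen_torsion_samples(
    spec: list[dict],
    n_samples: int = 10000,
    n_chains: int = 1,
    seed: int = 0,
):
    """Circular-variable samples with closed-form ground truth.

    ``spec`` is a list of per-variable dicts:

    * ``{"kind": "uniform"}``
    * ``{"kind": "von_mises", "mu": float, "kappa": float}``
    * ``{"kind": "coupled", "source": index, "kappa": float}`` -- the
      variable equals the source variable plus von Mises noise.  The
      source must be uniform so that the mutual information has the
      closed form ln(2 pi) - H_vM(kappa).

    Ground truth carries per-variable entropies (nats), the pairwise MI of
    every coupled pair, and the total joint entropy.
    """
    from .conformational import TorsionSamples

    rng = np.random.default_rng(seed)
    n_vars = len(spec)
    data = np.empty((n_chains, n_vars, n_samples))
    entropies = np.empty(n_vars)
    mi: dict[tuple[int, int], float] = {}
    for i, s in enumerate(spec):
        kind = s["kind"]
        if kind == "uniform":
            data[:, i, :] = rng.uniform(-np.pi, np.pi, size=(n_chains, n_samples))
            entropies[i] = math.log(2.0 * math.pi)
        elif kind == "von_mises":
            data[:, i, :] = rng.vonmises(
                s.get("mu", 0.0), s["kappa"], size=(n_chains, n_samples)
            )
            entropies[i] = von_mises_entropy(s["kappa"])
        elif kind == "coupled":
            src = s["source"]
            if src >= i:
                raise ValueError("coupled source must precede the variable")
            if spec[src]["kind"] != "uniform":
                raise ValueError(
                    "coupled source must be uniform for closed-form ground truth"
                )
            noise = rng.vonmises(0.0, s["kappa"], size=(n_chains, n_samples))
            theta = data[:, src, :] + noise
            data[:, i, :] = np.angle(np.exp(1j * theta))
            entropies[i] = math.log(2.0 * math.pi)  # marginal stays uniform
            mi[(src, i)] = math.log(2.0 * math.pi) - von_mises_entropy(s["kappa"])
        else:
            raise ValueError(f"unknown torsion spec kind {kind!r}")
    total = float(entropies.sum() - sum(mi.values()))
    gt = {
        "entropies": entropies.tolist(),
        "mutual_information": {f"{a}-{b}": v for (a, b), v in mi.items()},
        "joint_entropy": total,
    }
    labels = [("0", i, f"t{i}") for i in range(n_vars)]
    return TorsionSamples(
        labels=labels,
        data=data,
        meta={
            "spec": SyntheticSpec("torsion_samples", {"spec": spec}, seed, gt),
            "ground_truth": gt,
        },
    )
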