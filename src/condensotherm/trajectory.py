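"""Domain types and file IO for structures, trajectories and energy tables.

Unit conventions are fixed package-wide (see :mod:`condensotherm.constants`):
nm, ps, amu, kJ/mol, K.  Boxes are orthorhombic; triclinic input is
rejected.  Atoms may lie outside the box; all geometry operations apply the
minimum-image convention.

Supported external formats
--------------------------
* structures: GRO and PDB (parsed through MDAnalysis)
* trajectories: a documented plain-text frame format (see
  :func:`write_frames` / :func:`read_frames`) plus XTC/TRR through an
  MDAnalysis adapter
* energy tables: xvg-style two-column text (``#``/``@`` comment lines)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import ATOMIC_MASSES, mass_from_name

WATER_RESNAMES = {"SOL", "HOH", "WAT", "TIP3", "TIP4", "T4PD", "SPC"}
ION_RESNAMES = {"NA", "CL", "K", "MG", "CA2", "NA+", "CL-", "ION"}

ENERGY_LABELS = ("PP-intra", "PP-inter", "PP", "PW", "WW")


class ParseError(ValueError):
    """Raised when a structure/trajectory/table file cannot be parsed."""


# ---------------------------------------------------------------------------
# water model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaterModel:
    """Rigid water model specification.

    Default parameters are those of the four-site dispersion-corrected
    TIP4P-D family (the charge/LJ set used for the dense-phase work this
    package targets): OH bond 0.09572 nm, HOH angle 104.52 deg, massless
    charge site on the bisector.
    """

    name: str = "tip4p-d"
    n_sites: int = 4
    r_oh: float = 0.09572        # nm
    angle_hoh: float = 104.52    # degrees
    d_om: float = 0.01546        # nm, O -> virtual charge site
    q_h: float = 0.58            # e
    sigma: float = 0.3165        # nm, O-O Lennard-Jones
    epsilon: float = 0.93680     # kJ/mol
    m_o: float = ATOMIC_MASSES["O"]
    m_h: float = ATOMIC_MASSES["H"]

    @property
    def q_m(self) -> float:
        return -2.0 * self.q_h

    @property
    def mass(self) -> float:
        return self.m_o + 2.0 * self.m_h

    def site_positions(self) -> np.ndarray:
        """Canonical-frame site positions (O, H1, H2[, M]), shape (n,3).

        O at the origin, HOH bisector along +z, molecule in the xz plane.
        """
        half = math.radians(self.angle_hoh) / 2.0
        hx = self.r_oh * math.sin(half)
        hz = self.r_oh * math.cos(half)
        pos = [
            (0.0, 0.0, 0.0),
            (hx, 0.0, hz),
            (-hx, 0.0, hz),
        ]
        if self.n_sites == 4:
            pos.append((0.0, 0.0, self.d_om))
        return np.asarray(pos)

    def site_masses(self) -> np.ndarray:
        m = [self.m_o, self.m_h, self.m_h]
        if self.n_sites == 4:
            m.append(0.0)
        return np.asarray(m)

    def virtual_site_coeff(self) -> float:
        """a such that r_M = (1-2a) r_O + a r_H1 + a r_H2."""
        half = math.radians(self.angle_hoh) / 2.0
        return self.d_om / (2.0 * self.r_oh * math.cos(half))

    def principal_moments(self) -> np.ndarray:
        """Moments of inertia (amu nm^2) about the molecular principal axes.

        Axis order matches :func:`water_angular_velocities`:
        (H-H direction, HOH bisector, normal to the molecular plane).
        """
        pos = self.site_positions()[:3]
        m = self.site_masses()[:3]
        com = (m[:, None] * pos).sum(axis=0) / m.sum()
        rel = pos - com
        axes = np.array([
            [1.0, 0.0, 0.0],   # H-H direction
            [0.0, 0.0, 1.0],   # bisector (C2)
            [0.0, 1.0, 0.0],   # plane normal
        ])
        moments = np.empty(3)
        for k, e in enumerate(axes):
            proj = rel @ e
            moments[k] = float((m * ((rel ** 2).sum(axis=1) - proj ** 2)).sum())
        return moments


# ---------------------------------------------------------------------------
# topology / frames
# ---------------------------------------------------------------------------

@dataclass
class Chain:
    """A protein (or bead-string) chain: ordered atom indices."""

    id: str
    atom_indices: np.ndarray

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)


@dataclass
class Topology:
    """System composition: atom metadata plus molecule partition.

    Every atom belongs to exactly one molecule: a chain, a water, or an
    ion.  Waters are rigid with fixed internal geometry given by
    ``water_model``; ``waters`` holds one row of site indices per water
    molecule (O, H1, H2[, M]).
    """

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    masses: np.ndarray
    chains: list[Chain] = field(default_factory=list)
    waters: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=int))
    ions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    water_model: WaterModel = field(default_factory=WaterModel)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_waters(self) -> int:
        return len(self.waters)

    @property
    def protein_indices(self) -> np.ndarray:
        if not self.chains:
            return np.empty(0, dtype=int)
        return np.concatenate([c.atom_indices for c in self.chains])

    @property
    def water_oxygens(self) -> np.ndarray:
        if self.n_waters == 0:
            return np.empty(0, dtype=int)
        return self.waters[:, 0]

    def validate(self) -> None:
        counted = np.zeros(self.n_atoms, dtype=int)
        for c in self.chains:
            counted[c.atom_indices] += 1
        if self.n_waters:
            counted[self.waters.ravel()] += 1
        if len(self.ions):
            counted[self.ions] += 1
        if not np.all(counted == 1):
            bad = np.where(counted != 1)[0]
            raise ValueError(
                f"{len(bad)} atoms not assigned to exactly one molecule "
                f"(first few: {bad[:5].tolist()})"
            )


@dataclass
class Frame:
    """One trajectory frame: positions (nm), optional velocities (nm/ps),
    orthorhombic box edges (nm) and time stamp (ps)."""

    positions: np.ndarray
    box: np.ndarray
    time: float = 0.0
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("frame positions contain non-finite values")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three positive edge lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)


def minimum_image(vectors: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    box = np.asarray(box, dtype=float)
    return vectors - box * np.round(np.asarray(vectors, dtype=float) / box)


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap positions into [0, box)."""
    return np.mod(positions, np.asarray(box, dtype=float))


# ---------------------------------------------------------------------------
# velocity series
# ---------------------------------------------------------------------------

@dataclass
class VelocitySeries:
    """Time-ordered per-molecule velocities feeding the VACF/DoS machinery.

    ``com_velocities`` has shape (n_frames, n_molecules, 3) in nm/ps.
    ``angular_velocities`` (rad/ps, same shape) are expressed in each
    molecule's principal-axis frame and are present only for rigid species.
    ``principal_moments`` are the per-axis moments of inertia (amu nm^2)
    shared by all molecules of the species.
    """

    dt: float
    com_velocities: np.ndarray
    masses: np.ndarray
    angular_velocities: np.ndarray | None = None
    principal_moments: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.com_velocities = np.asarray(self.com_velocities, dtype=float)
        if self.com_velocities.ndim != 3:
            raise ValueError("com_velocities must be (n_frames, n_molecules, 3)")
        if self.n_frames < 2:
            raise ValueError("velocity series needs at least 2 frames")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        self.masses = np.broadcast_to(
            np.asarray(self.masses, dtype=float), (self.n_molecules,)
        ).copy()

    @property
    def n_frames(self) -> int:
        return self.com_velocities.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.com_velocities.shape[1]

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.dt

    def kinetic_energy(self, frame: int = 0) -> float:
        """COM + rotational kinetic energy of one frame (kJ/mol, total)."""
        v = self.com_velocities[frame]
        ke = 0.5 * float(np.sum(self.masses[:, None] * v ** 2))
        if self.angular_velocities is not None:
            w = self.angular_velocities[frame]
            ke += 0.5 * float(np.sum(self.principal_moments[None, :] * w ** 2))
        return ke


def water_com_velocities(
    topology: Topology, frame: Frame
) -> tuple[np.ndarray, np.ndarray]:
    """Per-water COM positions and velocities (mass-weighted site means)."""
    if frame.velocities is None:
        raise ValueError("frame has no velocities")
    sites = topology.waters[:, :3]  # M site is massless
    m = topology.water_model.site_masses()[:3]
    pos = frame.positions[sites]          # (nw, 3, 3)
    vel = frame.velocities[sites]
    # keep molecules whole: express H relative to O by minimum image
    rel = minimum_image(pos - pos[:, :1, :], frame.box)
    com_rel = np.einsum("s,nsd->nd", m, rel) / m.sum()
    com = pos[:, 0, :] + com_rel
    vcom = np.einsum("s,nsd->nd", m, vel) / m.sum()
    return com, vcom


def water_angular_velocities(topology: Topology, frame: Frame) -> np.ndarray:
    """Angular velocity of each rigid water in its principal frame (rad/ps).

    omega is obtained in the lab frame from the angular momentum about the
    COM (omega = I^-1 L with the instantaneous inertia tensor) and then
    projected onto the molecular axes (H-H direction, bisector, normal),
    matching the axis order of :meth:`WaterModel.principal_moments`.
    """
    if frame.velocities is None:
        raise ValueError("frame has no velocities")
    model = topology.water_model
    sites = topology.waters[:, :3]
    m = model.site_masses()[:3]
    pos = frame.positions[sites]
    vel = frame.velocities[sites]
    rel = minimum_image(pos - pos[:, :1, :], frame.box)
    com_rel = np.einsum("s,nsd->nd", m, rel) / m.sum()
    r = rel - com_rel[:, None, :]                       # site - COM
    vcom = np.einsum("s,nsd->nd", m, vel) / m.sum()
    vrel = vel - vcom[:, None, :]
    # angular momentum and inertia tensor about COM
    L = np.einsum("s,nsd->nd", m, np.cross(r, vrel))
    r2 = (r ** 2).sum(axis=2)
    eye = np.eye(3)
    inertia = np.einsum("s,ns,de->nde", m, r2, eye) - np.einsum(
        "s,nsd,nse->nde", m, r, r
    )
    omega_lab = np.linalg.solve(inertia, L[..., None])[..., 0]
    # molecular axes
    e_hh = r[:, 1, :] - r[:, 2, :]
    e_hh /= np.linalg.norm(e_hh, axis=1, keepdims=True)
    bis = 0.5 * (r[:, 1, :] + r[:, 2, :]) - r[:, 0, :]
    bis -= e_hh * np.einsum("nd,nd->n", bis, e_hh)[:, None]
    bis /= np.linalg.norm(bis, axis=1, keepdims=True)
    e_norm = np.cross(e_hh, bis)
    axes = np.stack([e_hh, bis, e_norm], axis=1)        # (nw, 3ax, 3)
    return np.einsum("nad,nd->na", axes, omega_lab)


def velocity_series_from_frames(
    topology: Topology, frames: list[Frame], rigid: bool = True
) -> VelocitySeries:
    """Build a per-water :class:`VelocitySeries` from trajectory frames."""
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    times = np.array([f.time for f in frames])
    dts = np.diff(times)
    dt = dts[0]
    if dt <= 0 or not np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
        raise ValueError("nonuniform frame stride in velocity trajectory")
    for f in frames:
        if f.velocities is None:
            raise ValueError(
                "trajectory frames carry no velocities; velocities are "
                "required for VACF/DoS work (they are not silently zeroed)"
            )
    for a, b in zip(frames, frames[1:]):
        if np.array_equal(a.velocities, b.velocities):
            raise ValueError(
                "duplicate consecutive frames detected (identical velocities); "
                "the frame stride is inconsistent with the sampling interval"
            )
    vcom = np.empty((len(frames), topology.n_waters, 3))
    omega = np.empty_like(vcom) if rigid else None
    for i, f in enumerate(frames):
        _, vcom[i] = water_com_velocities(topology, f)
        if rigid:
            omega[i] = water_angular_velocities(topology, f)
    return VelocitySeries(
        dt=dt,
        com_velocities=vcom,
        masses=np.full(topology.n_waters, topology.water_model.mass),
        angular_velocities=omega,
        principal_moments=topology.water_model.principal_moments() if rigid else None,
        meta={"source": "frames"},
    )


# ---------------------------------------------------------------------------
# energy tables
# ---------------------------------------------------------------------------

@dataclass
class EnergySeries:
    """Per-frame interaction energy of one component pair (kJ/mol)."""

    label: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.label not in ENERGY_LABELS:
            raise ValueError(
                f"label {self.label!r} not one of {ENERGY_LABELS}"
            )
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("energy series contains non-finite values")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values))


def read_energy_table(path: str | Path, label: str) -> EnergySeries:
    """Read an xvg-style two-column (time, energy) text table.

    Lines starting with ``#`` or ``@`` are ignored.  A non-numeric data row
    raises :class:`ParseError` naming the line.
    """
    times, values = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "@")):
                continue
            parts = s.split()
            try:
                t, e = float(parts[0]), float(parts[1])
            except (ValueError, IndexError) as exc:
                raise ParseError(
                    f"{path}: non-numeric data on line {lineno}: {s!r}"
                ) from exc
            times.append(t)
            values.append(e)
    if not times:
        raise ParseError(f"{path}: no data rows")
    return EnergySeries(label=label, times=np.array(times), values=np.array(values))


def write_energy_table(
    path: str | Path, series: EnergySeries, comment: str = ""
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# condensotherm energy table: {series.label}\n")
        if comment:
            fh.write(f"# {comment}\n")
        fh.write('@ xaxis label "Time (ps)"\n@ yaxis label "Energy (kJ/mol)"\n')
        for t, e in zip(series.times, series.values):
            fh.write(f"{t:.6f} {e:.10g}\n")


# ---------------------------------------------------------------------------
# concentration series
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationRecord:
    """Per-concentration summary record.

    Entropies are per water molecule (J mol^-1 K^-1); ``e_ww`` is per water
    molecule, ``e_pp``/``e_pw`` are per protein chain (kJ/mol).  A record
    with ``n_chains == 0`` is a bulk-water reference row.  ``sd`` carries
    replicate standard deviations keyed by field name.
    """

    rho: float
    n_chains: int
    n_waters: int
    s_tot: float = np.nan
    s_tr: float = np.nan
    s_rot: float = np.nan
    e_pp: float = np.nan
    e_pw: float = np.nan
    e_ww: float = np.nan
    n_phl: float = np.nan
    box_edge: float = np.nan
    sd: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError("rho must be positive")
        if self.n_waters < 0:
            raise ValueError("n_waters must be >= 0")
        if any(v < 0 for v in self.sd.values()):
            raise ValueError("replicate SDs must be >= 0")
        if (
            np.isfinite(self.s_tot)
            and np.isfinite(self.s_tr)
            and np.isfinite(self.s_rot)
            and not math.isclose(self.s_tot, self.s_tr + self.s_rot, rel_tol=1e-6, abs_tol=1e-6)
        ):
            raise ValueError("s_tot must equal s_tr + s_rot")

    @property
    def is_bulk(self) -> bool:
        return self.n_chains == 0

    @property
    def waters_per_chain(self) -> float:
        if self.n_chains == 0:
            raise ValueError("bulk record has no per-chain water count")
        return self.n_waters / self.n_chains


_RECORD_FIELDS = (
    "rho n_chains n_waters s_tot s_tr s_rot e_pp e_pw e_ww n_phl box_edge"
).split()


@dataclass
class ConcentrationSeries:
    """An ordered collection of :class:`ConcentrationRecord`."""

    records: list[ConcentrationRecord]

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.is_bulk, r.rho))

    @property
    def rhos(self) -> np.ndarray:
        return np.array([r.rho for r in self.records if not r.is_bulk])

    def bulk(self) -> ConcentrationRecord:
        for r in self.records:
            if r.is_bulk:
                return r
        raise ValueError("series has no bulk-water reference record")

    def has_bulk(self) -> bool:
        return any(r.is_bulk for r in self.records)

    def get(self, rho: float, atol: float = 1e-9) -> ConcentrationRecord:
        for r in self.records:
            if not r.is_bulk and abs(r.rho - rho) <= atol:
                return r
        raise KeyError(f"no record at rho = {rho}")

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.records:
            row = {f: getattr(r, f) for f in _RECORD_FIELDS}
            row.update({f"sd_{k}": v for k, v in r.sd.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df) -> "ConcentrationSeries":
        records = []
        for _, row in df.iterrows():
            kwargs = {f: row[f] for f in _RECORD_FIELDS if f in row and row.notna()[f]}
            kwargs["n_chains"] = int(kwargs.get("n_chains", 0))
            kwargs["n_waters"] = int(kwargs.get("n_waters", 0))
            sd = {
                k[3:]: row[k]
                for k in row.index
                if k.startswith("sd_") and np.isfinite(row[k])
            }
            records.append(ConcentrationRecord(sd=sd, **kwargs))
        return cls(records)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConcentrationSeries":
        import pandas as pd

        return cls.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# structure IO
# ---------------------------------------------------------------------------

def _build_topology(names, resnames, resids, segids) -> Topology:
    names = np.asarray(names)
    resnames = np.asarray([r.upper() for r in resnames])
    resids = np.asarray(resids, dtype=int)
    masses = np.array([mass_from_name(n) for n in names])
    n = len(names)

    is_water = np.isin(resnames, list(WATER_RESNAMES))
    is_ion = np.isin(resnames, list(ION_RESNAMES))
    is_protein = ~(is_water | is_ion)

    # group waters by residue
    waters = []
    i = 0
    n_sites = None
    while i < n:
        if not is_water[i]:
            i += 1
            continue
        j = i + 1
        # a new molecule starts on a resid change or when the leading atom
        # name repeats (guards against resid wrap-around in huge systems)
        while j < n and is_water[j] and resids[j] == resids[i] and names[j] != names[i]:
            j += 1
        group = list(range(i, j))
        if len(group) not in (3, 4):
            raise ParseError(
                f"water residue {resids[i]} has {len(group)} sites; expected 3 or 4"
            )
        if n_sites is None:
            n_sites = len(group)
        elif n_sites != len(group):
            raise ParseError("mixed water site counts in structure")
        waters.append(group)
        i = j

    # group protein atoms into chains: break on segid change or resid decrease
    chains: list[Chain] = []
    current: list[int] = []
    last_seg, last_resid = None, None
    for idx in range(n):
        if not is_protein[idx]:
            continue
        seg = segids[idx] if segids is not None else ""
        if current and (seg != last_seg or resids[idx] < last_resid):
            chains.append(Chain(id=str(len(chains)), atom_indices=np.array(current)))
            current = []
        current.append(idx)
        last_seg, last_resid = seg, resids[idx]
    if current:
        chains.append(Chain(id=str(len(chains)), atom_indices=np.array(current)))

    model = WaterModel() if (n_sites or 4) == 4 else WaterModel(name="tip3p-like", n_sites=3)
    top = Topology(
        names=names,
        resnames=resnames,
        resids=resids,
        masses=masses,
        chains=chains,
        waters=np.array(waters, dtype=int) if waters else np.empty((0, 3), dtype=int),
        ions=np.where(is_ion)[0],
        water_model=model,
    )
    top.validate()
    return top


def read_structure(path: str | Path, dialect: str | None = None) -> tuple[Topology, Frame]:
    """Read a GRO or PDB structure into (Topology, Frame).

    The dialect is inferred from the file suffix when not given.  Masses
    are filled from the element table; a missing or triclinic box is an
    error.
    """
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
    if dialect not in ("gro", "pdb"):
        raise ValueError(f"unsupported structure dialect {dialect!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format=dialect)
        except Exception as exc:
            raise ParseError(f"{path}: failed to parse as {dialect}: {exc}") from exc

    dims = u.dimensions
    if dims is None or not np.all(dims[:3] > 0):
        raise ParseError(f"{path}: missing simulation box")
    if not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise ParseError(f"{path}: triclinic box not supported (orthorhombic only)")

    atoms = u.atoms
    segids = (
        atoms.segids if hasattr(atoms, "segids") else None
    )
    top = _build_topology(atoms.names, atoms.resnames, atoms.resids, segids)
    positions = atoms.positions / 10.0  # Angstrom -> nm
    velocities = None
    if hasattr(atoms, "velocities"):
        try:
            velocities = atoms.velocities / 10.0  # A/ps -> nm/ps
        except Exception:
            velocities = None
    frame = Frame(
        positions=positions,
        box=dims[:3] / 10.0,
        time=0.0,
        velocities=velocities,
    )
    if frame.n_atoms != top.n_atoms:
        raise ParseError(f"{path}: atom count mismatch")
    return top, frame


def write_gro(
    path: str | Path, topology: Topology, frame: Frame, title: str = "condensotherm"
) -> None:
    """Write a GRO file (3-decimal positions, 4-decimal velocities)."""
    with open(path, "w") as fh:
        fh.write(f"{title}\n{topology.n_atoms:5d}\n")
        for i in range(topology.n_atoms):
            resid = int(topology.resids[i]) % 100000
            name = str(topology.names[i])[:5]
            resname = str(topology.resnames[i])[:5]
            x, y, z = frame.positions[i]
            line = f"{resid:5d}{resname:<5s}{name:>5s}{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
            if frame.velocities is not None:
                vx, vy, vz = frame.velocities[i]
                line += f"{vx:8.4f}{vy:8.4f}{vz:8.4f}"
            fh.write(line + "\n")
        fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# plain-text frame trajectory format
# ---------------------------------------------------------------------------
#
# Format (one file, text):
#   # condensotherm frames 1
#   natoms <N>
#   frame <time_ps> <lx> <ly> <lz> <has_velocities:0|1>
#   x y z [vx vy vz]          (N lines)
#   frame ...
#

def write_frames(path: str | Path, frames: list[Frame]) -> None:
    n = frames[0].n_atoms
    with open(path, "w") as fh:
        fh.write("# condensotherm frames 1\n")
        fh.write(f"natoms {n}\n")
        for f in frames:
            hasv = int(f.velocities is not None)
            fh.write(
                f"frame {f.time:.6f} {f.box[0]:.9g} {f.box[1]:.9g} {f.box[2]:.9g} {hasv}\n"
            )
            if hasv:
                data = np.hstack([f.positions, f.velocities])
            else:
                data = f.positions
            np.savetxt(fh, data, fmt="%.9g")


def read_frames(path: str | Path) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        header = fh.readline()
        if "condensotherm frames" not in header:
            raise ParseError(f"{path}: not a condensotherm frame file")
        line = fh.readline().split()
        if len(line) != 2 or line[0] != "natoms":
            raise ParseError(f"{path}: missing natoms header")
        n = int(line[1])
        lineno = 2
        while True:
            head = fh.readline()
            lineno += 1
            if not head:
                break
            parts = head.split()
            if parts[0] != "frame" or len(parts) != 6:
                raise ParseError(f"{path}: bad frame header on line {lineno}")
            time, lx, ly, lz = map(float, parts[1:5])
            hasv = bool(int(parts[5]))
            ncols = 6 if hasv else 3
            rows = np.empty((n, ncols))
            for i in range(n):
                row = fh.readline().split()
                lineno += 1
                if len(row) != ncols:
                    raise ParseError(f"{path}: bad atom row on line {lineno}")
                rows[i] = [float(v) for v in row]
            frames.append(
                Frame(
                    positions=rows[:, :3],
                    box=np.array([lx, ly, lz]),
                    time=time,
                    velocities=rows[:, 3:] if hasv else None,
                )
            )
    if not frames:
        raise ParseError(f"{path}: no frames")
    return frames


def write_velocity_series(path: str | Path, series: VelocitySeries) -> None:
    """Plain-text dump of a VelocitySeries (one frame per row)."""
    with open(path, "w") as fh:
        fh.write("# condensotherm velocity series 1\n")
        fh.write(f"dt {series.dt:.9g}\n")
        fh.write(f"n_molecules {series.n_molecules}\n")
        fh.write(f"mass {series.masses[0]:.9g}\n")
        hasw = int(series.angular_velocities is not None)
        fh.write(f"angular {hasw}\n")
        if hasw:
            I = series.principal_moments
            fh.write(f"principal_moments {I[0]:.9g} {I[1]:.9g} {I[2]:.9g}\n")
        for fi in range(series.n_frames):
            row = series.com_velocities[fi].ravel()
            if hasw:
                row = np.concatenate([row, series.angular_velocities[fi].ravel()])
            fh.write(" ".join(f"{v:.9g}" for v in row) + "\n")


def read_velocity_series(path: str | Path) -> VelocitySeries:
    with open(path) as fh:
        if "condensotherm velocity series" not in fh.readline():
            raise ParseError(f"{path}: not a condensotherm velocity series file")
        dt = float(fh.readline().split()[1])
        n_mol = int(fh.readline().split()[1])
        mass = float(fh.readline().split()[1])
        hasw = bool(int(fh.readline().split()[1]))
        moments = None
        if hasw:
            moments = np.array([float(v) for v in fh.readline().split()[1:]])
        data = np.loadtxt(fh)
    if data.ndim == 1:
        data = data[None, :]
    vcom = data[:, : 3 * n_mol].reshape(-1, n_mol, 3)
    omega = data[:, 3 * n_mol:].reshape(-1, n_mol, 3) if hasw else None
    return VelocitySeries(
        dt=dt,
        com_velocities=vcom,
        masses=np.full(n_mol, mass),
        angular_velocities=omega,
        principal_moments=moments,
    )


def read_velocity_trajectory(
    path: str | Path,
    topology: Topology,
    structure: str | Path | None = None,
) -> VelocitySeries:
    """Read a velocity trajectory into a per-water :class:`VelocitySeries`.

    Native support for the plain-text frame format; TRR is handled through
    an MDAnalysis adapter (``structure`` must then point to a matching
    GRO/PDB file).  XTC files never store velocities and are rejected.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xtc":
        raise ValueError("XTC stores no velocities; a TRR or text trajectory is required")
    if suffix == ".trr":
        import MDAnalysis as mda

        if structure is None:
            raise ValueError("TRR input needs a structure file for the adapter")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(structure), str(path))
        frames = []
        for ts in u.trajectory:
            if not ts.has_velocities:
                raise ValueError(f"{path}: trajectory frames carry no velocities")
            frames.append(
                Frame(
                    positions=ts.positions / 10.0,
                    box=ts.dimensions[:3] / 10.0,
                    time=ts.time,
                    velocities=ts.velocities / 10.0,
                )
            )
        return velocity_series_from_frames(topology, frames)
    frames = read_frames(path)
    return velocity_series_from_frames(topology, frames)
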