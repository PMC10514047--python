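"""Lightweight rigid four-site water MD engine (fixture generation only).

Velocity-Verlet dynamics of rigid dispersion-corrected four-site water
(SHAKE/RATTLE constrained, massless charge site on the bisector) with
Lennard-Jones plus reaction-field electrostatics under a molecule-based
cutoff, and a stochastic velocity-rescaling thermostat.  This is NOT a
production MD code: it exists to produce bulk-water velocity trajectories
with realistic spectral content for the 2PT entropy engine, at desk scale.

All kernels are numba-compiled; a ~500-molecule, 20 ps run takes a couple
of minutes on one CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .constants import KB, KE_COULOMB, N_AVOGADRO
from .trajectory import VelocitySeries, WaterModel


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _build_pairs(pos_o: np.ndarray, box: np.ndarray, rlist2: float,
                 pairs: np.ndarray) -> int:
    n = pos_o.shape[0]
    count = 0
    for i in range(n - 1):
        xi, yi, zi = pos_o[i, 0], pos_o[i, 1], pos_o[i, 2]
        for j in range(i + 1, n):
            dx = xi - pos_o[j, 0]
            dy = yi - pos_o[j, 1]
            dz = zi - pos_o[j, 2]
            dx -= box[0] * round(dx / box[0])
            dy -= box[1] * round(dy / box[1])
            dz -= box[2] * round(dz / box[2])
            if dx * dx + dy * dy + dz * dz < rlist2:
                pairs[count, 0] = i
                pairs[count, 1] = j
                count += 1
    return count


@njit(cache=True)
def _forces(r: np.ndarray, box: np.ndarray, pairs: np.ndarray, npairs: int,
            a_vs: float, c6: float, c12: float, q: np.ndarray,
            rc2: float, krf: float, crf: float, f: np.ndarray) -> float:
    """LJ (O-O) + reaction-field Coulomb (H,H,M sites) over the pair list.

    ``r``/``f`` have shape (n, 4, 3): sites O, H1, H2, M.  The M site is
    rebuilt from O/H positions before the call; its force is redistributed
    onto O and H here.  Returns the potential energy.

    Cutoffs are site-based.  With the conducting reaction field both the
    potential and the force vanish at the cutoff, and the LJ energy is
    shifted to zero there, so the dynamics conserve energy well despite
    the abrupt truncation.
    """
    n = r.shape[0]
    for i in range(n):
        for s in range(4):
            f[i, s, 0] = 0.0
            f[i, s, 1] = 0.0
            f[i, s, 2] = 0.0
    rc6 = rc2 * rc2 * rc2
    shift_lj = (c12 / rc6 - c6) / rc6
    epot = 0.0
    for p in range(npairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        # molecular minimum-image shift from the O-O displacement
        dx = r[i, 0, 0] - r[j, 0, 0]
        dy = r[i, 0, 1] - r[j, 0, 1]
        dz = r[i, 0, 2] - r[j, 0, 2]
        sx = box[0] * round(dx / box[0])
        sy = box[1] * round(dy / box[1])
        sz = box[2] * round(dz / box[2])
        dx -= sx
        dy -= sy
        dz -= sz
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            # O-O Lennard-Jones, potential-shifted
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            epot += (c12 * inv6 - c6) * inv6 - shift_lj
            flj = (12.0 * c12 * inv6 - 6.0 * c6) * inv6 * inv2
            f[i, 0, 0] += flj * dx
            f[i, 0, 1] += flj * dy
            f[i, 0, 2] += flj * dz
            f[j, 0, 0] -= flj * dx
            f[j, 0, 1] -= flj * dy
            f[j, 0, 2] -= flj * dz
        # site-site reaction-field Coulomb among charged sites (1..3)
        for si in range(1, 4):
            qi = q[si]
            for sj in range(1, 4):
                cx = r[i, si, 0] - r[j, sj, 0] - sx
                cy = r[i, si, 1] - r[j, sj, 1] - sy
                cz = r[i, si, 2] - r[j, sj, 2] - sz
                cr2 = cx * cx + cy * cy + cz * cz
                if cr2 >= rc2:
                    continue
                qq = KE_COULOMB * qi * q[sj]
                cr = math.sqrt(cr2)
                epot += qq * (1.0 / cr + krf * cr2 - crf)
                fc = qq * (1.0 / (cr2 * cr) - 2.0 * krf)
                f[i, si, 0] += fc * cx
                f[i, si, 1] += fc * cy
                f[i, si, 2] += fc * cz
                f[j, sj, 0] -= fc * cx
                f[j, sj, 1] -= fc * cy
                f[j, sj, 2] -= fc * cz
    # redistribute virtual-site force:  r_M = (1-2a) r_O + a r_H1 + a r_H2
    for i in range(n):
        for d in range(3):
            fm = f[i, 3, d]
            f[i, 0, d] += (1.0 - 2.0 * a_vs) * fm
            f[i, 1, d] += a_vs * fm
            f[i, 2, d] += a_vs * fm
            f[i, 3, d] = 0.0
    return epot


@njit(cache=True)
def _update_msite(r: np.ndarray, a_vs: float) -> None:
    n = r.shape[0]
    for i in range(n):
        for d in range(3):
            r[i, 3, d] = (1.0 - 2.0 * a_vs) * r[i, 0, d] + a_vs * (
                r[i, 1, d] + r[i, 2, d]
            )


@njit(cache=True)
def _shake_rattle_pos(r: np.ndarray, r_prev: np.ndarray, v: np.ndarray,
                      invm: np.ndarray, cons_i: np.ndarray, cons_j: np.ndarray,
                      d2: np.ndarray, dt: float, tol: float, maxit: int) -> None:
    """SHAKE on positions + first-order velocity correction."""
    n = r.shape[0]
    nc = cons_i.shape[0]
    for mol in range(n):
        for _ in range(maxit):
            worst = 0.0
            for c in range(nc):
                a = cons_i[c]
                b = cons_j[c]
                dx = r[mol, a, 0] - r[mol, b, 0]
                dy = r[mol, a, 1] - r[mol, b, 1]
                dz = r[mol, a, 2] - r[mol, b, 2]
                diff = dx * dx + dy * dy + dz * dz - d2[c]
                if abs(diff) > worst:
                    worst = abs(diff)
                # reference (pre-step) bond vector
                px = r_prev[mol, a, 0] - r_prev[mol, b, 0]
                py = r_prev[mol, a, 1] - r_prev[mol, b, 1]
                pz = r_prev[mol, a, 2] - r_prev[mol, b, 2]
                dot = dx * px + dy * py + dz * pz
                g = diff / (2.0 * dot * (invm[a] + invm[b]))
                ax = g * px
                ay = g * py
                az = g * pz
                r[mol, a, 0] -= ax * invm[a]
                r[mol, a, 1] -= ay * invm[a]
                r[mol, a, 2] -= az * invm[a]
                r[mol, b, 0] += ax * invm[b]
                r[mol, b, 1] += ay * invm[b]
                r[mol, b, 2] += az * invm[b]
                v[mol, a, 0] -= ax * invm[a] / dt
                v[mol, a, 1] -= ay * invm[a] / dt
                v[mol, a, 2] -= az * invm[a] / dt
                v[mol, b, 0] += ax * invm[b] / dt
                v[mol, b, 1] += ay * invm[b] / dt
                v[mol, b, 2] += az * invm[b] / dt
            if worst < tol:
                break


@njit(cache=True)
def _rattle_vel(r: np.ndarray, v: np.ndarray, invm: np.ndarray,
                cons_i: np.ndarray, cons_j: np.ndarray,
                tol: float, maxit: int) -> None:
    """Project site velocities onto the constraint manifold."""
    n = r.shape[0]
    nc = cons_i.shape[0]
    for mol in range(n):
        for _ in range(maxit):
            worst = 0.0
            for c in range(nc):
                a = cons_i[c]
                b = cons_j[c]
                dx = r[mol, a, 0] - r[mol, b, 0]
                dy = r[mol, a, 1] - r[mol, b, 1]
                dz = r[mol, a, 2] - r[mol, b, 2]
                rv = dx * (v[mol, a, 0] - v[mol, b, 0]) + dy * (
                    v[mol, a, 1] - v[mol, b, 1]
                ) + dz * (v[mol, a, 2] - v[mol, b, 2])
                if abs(rv) > worst:
                    worst = abs(rv)
                d2c = dx * dx + dy * dy + dz * dz
                k = rv / (d2c * (invm[a] + invm[b]))
                v[mol, a, 0] -= k * dx * invm[a]
                v[mol, a, 1] -= k * dy * invm[a]
                v[mol, a, 2] -= k * dz * invm[a]
                v[mol, b, 0] += k * dx * invm[b]
                v[mol, b, 1] += k * dy * invm[b]
                v[mol, b, 2] += k * dz * invm[b]
            if worst < tol:
                break


@njit(cache=True)
def _kinetic(v: np.ndarray, m: np.ndarray) -> float:
    n = v.shape[0]
    ke = 0.0
    for i in range(n):
        for s in range(3):
            ke += 0.5 * m[s] * (
                v[i, s, 0] ** 2 + v[i, s, 1] ** 2 + v[i, s, 2] ** 2
            )
    return ke


@njit(cache=True)
def _record_rigid_body(r: np.ndarray, v: np.ndarray, m: np.ndarray,
                       vcom_out: np.ndarray, omega_out: np.ndarray) -> None:
    """Per-molecule COM velocity and principal-frame angular velocity.

    Axis order: (H-H direction, HOH bisector, plane normal), matching
    WaterModel.principal_moments().
    """
    n = r.shape[0]
    mtot = m[0] + m[1] + m[2]
    for i in range(n):
        # COM position/velocity (sites of one molecule are never wrapped
        # apart: molecules stay whole in absolute coordinates)
        comx = (m[0] * r[i, 0, 0] + m[1] * r[i, 1, 0] + m[2] * r[i, 2, 0]) / mtot
        comy = (m[0] * r[i, 0, 1] + m[1] * r[i, 1, 1] + m[2] * r[i, 2, 1]) / mtot
        comz = (m[0] * r[i, 0, 2] + m[1] * r[i, 1, 2] + m[2] * r[i, 2, 2]) / mtot
        vcx = (m[0] * v[i, 0, 0] + m[1] * v[i, 1, 0] + m[2] * v[i, 2, 0]) / mtot
        vcy = (m[0] * v[i, 0, 1] + m[1] * v[i, 1, 1] + m[2] * v[i, 2, 1]) / mtot
        vcz = (m[0] * v[i, 0, 2] + m[1] * v[i, 1, 2] + m[2] * v[i, 2, 2]) / mtot
        vcom_out[i, 0] = vcx
        vcom_out[i, 1] = vcy
        vcom_out[i, 2] = vcz
        # angular momentum and inertia tensor about COM
        lx = ly = lz = 0.0
        ixx = iyy = izz = ixy = ixz = iyz = 0.0
        for s in range(3):
            rx = r[i, s, 0] - comx
            ry = r[i, s, 1] - comy
            rz = r[i, s, 2] - comz
            wx = v[i, s, 0] - vcx
            wy = v[i, s, 1] - vcy
            wz = v[i, s, 2] - vcz
            lx += m[s] * (ry * wz - rz * wy)
            ly += m[s] * (rz * wx - rx * wz)
            lz += m[s] * (rx * wy - ry * wx)
            r2 = rx * rx + ry * ry + rz * rz
            ixx += m[s] * (r2 - rx * rx)
            iyy += m[s] * (r2 - ry * ry)
            izz += m[s] * (r2 - rz * rz)
            ixy -= m[s] * rx * ry
            ixz -= m[s] * rx * rz
            iyz -= m[s] * ry * rz
        det = (
            ixx * (iyy * izz - iyz * iyz)
            - ixy * (ixy * izz - iyz * ixz)
            + ixz * (ixy * iyz - iyy * ixz)
        )
        wxl = (
            (iyy * izz - iyz * iyz) * lx
            + (ixz * iyz - ixy * izz) * ly
            + (ixy * iyz - ixz * iyy) * lz
        ) / det
        wyl = (
            (ixz * iyz - ixy * izz) * lx
            + (ixx * izz - ixz * ixz) * ly
            + (ixy * ixz - ixx * iyz) * lz
        ) / det
        wzl = (
            (ixy * iyz - ixz * iyy) * lx
            + (ixy * ixz - ixx * iyz) * ly
            + (ixx * iyy - ixy * ixy) * lz
        ) / det
        # molecular axes
        e1x = r[i, 1, 0] - r[i, 2, 0]
        e1y = r[i, 1, 1] - r[i, 2, 1]
        e1z = r[i, 1, 2] - r[i, 2, 2]
        norm = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
        e1x /= norm
        e1y /= norm
        e1z /= norm
        bx = 0.5 * (r[i, 1, 0] + r[i, 2, 0]) - r[i, 0, 0]
        by = 0.5 * (r[i, 1, 1] + r[i, 2, 1]) - r[i, 0, 1]
        bz = 0.5 * (r[i, 1, 2] + r[i, 2, 2]) - r[i, 0, 2]
        norm = math.sqrt(bx * bx + by * by + bz * bz)
        bx /= norm
        by /= norm
        bz /= norm
        e3x = e1y * bz - e1z * by
        e3y = e1z * bx - e1x * bz
        e3z = e1x * by - e1y * bx
        omega_out[i, 0] = wxl * e1x + wyl * e1y + wzl * e1z
        omega_out[i, 1] = wxl * bx + wyl * by + wzl * bz
        omega_out[i, 2] = wxl * e3x + wyl * e3y + wzl * e3z


@njit(cache=True)
def _md_chunk(r: np.ndarray, v: np.ndarray, f: np.ndarray,
              box: np.ndarray, dt: float, nsteps: int,
              m: np.ndarray, invm: np.ndarray,
              cons_i: np.ndarray, cons_j: np.ndarray, d2: np.ndarray,
              a_vs: float, c6: float, c12: float, q: np.ndarray,
              rc2: float, rlist2: float, krf: float, crf: float,
              pairs: np.ndarray, rebuild_every: int,
              r_prev: np.ndarray, pos_o: np.ndarray) -> float:
    """Advance nsteps of velocity Verlet; returns final potential energy."""
    n = r.shape[0]
    epot = 0.0
    npairs = 0
    for step in range(nsteps):
        if step % rebuild_every == 0:
            for i in range(n):
                for d in range(3):
                    pos_o[i, d] = r[i, 0, d] % box[d]
            npairs = _build_pairs(pos_o, box, rlist2, pairs)
        # half kick
        for i in range(n):
            for s in range(3):
                for d in range(3):
                    v[i, s, d] += 0.5 * dt * f[i, s, d] * invm[s]
        # drift + SHAKE
        for i in range(n):
            for s in range(3):
                for d in range(3):
                    r_prev[i, s, d] = r[i, s, d]
                    r[i, s, d] += dt * v[i, s, d]
        _shake_rattle_pos(r, r_prev, v, invm, cons_i, cons_j, d2, dt, 1e-12, 60)
        _update_msite(r, a_vs)
        epot = _forces(r, box, pairs, npairs, a_vs, c6, c12, q, rc2, krf, crf, f)
        # half kick + RATTLE
        for i in range(n):
            for s in range(3):
                for d in range(3):
                    v[i, s, d] += 0.5 * dt * f[i, s, d] * invm[s]
        _rattle_vel(r, v, invm, cons_i, cons_j, 1e-12, 60)
    return epot


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

@dataclass
class WaterBoxResult:
    series: VelocitySeries
    box_edge: float
    n_molecules: int
    temperature_mean: float
    n_density: float
    meta: dict


def _random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random rotation matrices (n, 3, 3) via quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)], -1),
            np.stack([2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)], -1),
            np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)], -1),
        ],
        axis=1,
    )


class WaterBox:
    """Bulk rigid-water system with velocity-Verlet dynamics."""

    def __init__(
        self,
        n_molecules: int = 512,
        temperature: float = 300.0,
        density: float = 0.997,           # g/cm^3
        model: WaterModel | None = None,
        cutoff: float = 0.9,              # nm
        seed: int = 0,
    ) -> None:
        self.model = model or WaterModel()
        self.n = int(n_molecules)
        self.T0 = float(temperature)
        self.rng = np.random.default_rng(seed)
        volume = self.n * self.model.mass / (density * N_AVOGADRO * 1e-21)  # nm^3
        self.box_edge = volume ** (1.0 / 3.0)
        self.box = np.full(3, self.box_edge)
        # site-based cutoffs reach rc + 2 r_OH beyond the O-O distance; keep
        # that within half the box so the molecular image choice is unique
        max_rc = self.box_edge / 2.0 - 2.0 * self.model.r_oh - 0.01
        if cutoff > max_rc:
            cutoff = max_rc
        self.rc = float(cutoff)
        # pair list radius: cutoff + max site offset from O on both
        # molecules (site-based cutoffs) + displacement skin
        self.rlist = self.rc + 2.0 * self.model.r_oh + 0.1
        # interaction parameters
        eps, sig = self.model.epsilon, self.model.sigma
        self.c6 = 4.0 * eps * sig ** 6
        self.c12 = 4.0 * eps * sig ** 12
        self.q = np.array([0.0, self.model.q_h, self.model.q_h, self.model.q_m])
        self.krf = 1.0 / (2.0 * self.rc ** 3)   # conducting reaction field
        self.crf = 3.0 / (2.0 * self.rc)
        self.a_vs = self.model.virtual_site_coeff()
        self.m = self.model.site_masses()[:3]
        self.invm = 1.0 / self.m
        d_oh = self.model.r_oh
        d_hh = 2.0 * d_oh * math.sin(math.radians(self.model.angle_hoh) / 2.0)
        self.cons_i = np.array([0, 0, 1], dtype=np.int64)
        self.cons_j = np.array([1, 2, 2], dtype=np.int64)
        self.d2 = np.array([d_oh ** 2, d_oh ** 2, d_hh ** 2])
        self.ndf = 6 * self.n - 3
        self._init_configuration()
        self._init_velocities()
        self._alloc()

    # -- setup ------------------------------------------------------------
    def _init_configuration(self) -> None:
        n_side = math.ceil(self.n ** (1.0 / 3.0))
        spacing = self.box_edge / n_side
        grid = np.array(
            [
                (i + 0.5, j + 0.5, k + 0.5)
                for i in range(n_side)
                for j in range(n_side)
                for k in range(n_side)
            ]
        )[: self.n] * spacing
        grid += self.rng.normal(scale=0.01, size=grid.shape)
        rots = _random_rotations(self.rng, self.n)
        sites = self.model.site_positions()[:3]
        self.r = np.empty((self.n, 4, 3))
        self.r[:, :3, :] = grid[:, None, :] + np.einsum("nab,sb->nsa", rots, sites)
        _update_msite(self.r, self.a_vs)

    def _init_velocities(self) -> None:
        sd = np.sqrt(KB * self.T0 / self.m)
        self.v = np.zeros((self.n, 4, 3))
        self.v[:, :3, :] = self.rng.normal(size=(self.n, 3, 3)) * sd[None, :, None]
        _rattle_vel(self.r, self.v, self.invm, self.cons_i, self.cons_j, 1e-12, 100)
        self._remove_com_motion()
        self._rescale_to_target()

    def _alloc(self) -> None:
        max_pairs = self.n * (self.n - 1) // 2
        self.pairs = np.empty((max_pairs, 2), dtype=np.int64)
        self.f = np.zeros_like(self.r)
        self._r_prev = np.empty_like(self.r)
        self._pos_o = np.empty((self.n, 3))
        npairs = _build_pairs(
            np.mod(self.r[:, 0, :], self.box), self.box, self.rlist ** 2, self.pairs
        )
        self.epot = _forces(
            self.r, self.box, self.pairs, npairs, self.a_vs, self.c6, self.c12,
            self.q, self.rc ** 2, self.krf, self.crf, self.f,
        )

    # -- thermo helpers ---------------------------------------------------
    def kinetic_energy(self) -> float:
        return _kinetic(self.v, self.m)

    def temperature(self) -> float:
        return 2.0 * self.kinetic_energy() / (self.ndf * KB)

    def _remove_com_motion(self) -> None:
        mass3 = np.concatenate([self.m, [0.0]])
        p = np.einsum("s,nsd->d", mass3, self.v)
        self.v[:, :3, :] -= (p / (self.m.sum() * self.n))[None, None, :]

    def _rescale_to_target(self) -> None:
        t = self.temperature()
        if t > 0:
            self.v *= math.sqrt(self.T0 / t)

    def _bussi_rescale(self, dt_coupling: float, tau: float) -> None:
        """Stochastic velocity rescaling (canonical sampling thermostat)."""
        t = self.temperature()
        if t <= 0:
            return
        c = math.exp(-dt_coupling / tau)
        ratio = self.T0 / (t * self.ndf)
        r1 = self.rng.normal()
        s = self.rng.chisquare(self.ndf - 1)
        alpha2 = (
            c
            + (1.0 - c) * ratio * (r1 ** 2 + s)
            + 2.0 * r1 * math.sqrt(c * (1.0 - c) * ratio)
        )
        self.v *= math.sqrt(max(alpha2, 0.0))

    # -- integration ------------------------------------------------------
    def run(self, nsteps: int, dt: float) -> None:
        """Advance nsteps without recording (no thermostat)."""
        self.epot = _md_chunk(
            self.r, self.v, self.f, self.box, dt, nsteps, self.m, self.invm,
            self.cons_i, self.cons_j, self.d2, self.a_vs, self.c6, self.c12,
            self.q, self.rc ** 2, self.rlist ** 2, self.krf, self.crf,
            self.pairs, 10, self._r_prev, self._pos_o,
        )

    def equilibrate(self, t_ps: float, dt: float = 0.002, tau: float = 0.2) -> None:
        nchunk = 20
        nsteps = int(round(t_ps / dt))
        done = 0
        while done < nsteps:
            n = min(nchunk, nsteps - done)
            self.run(n, dt)
            self._bussi_rescale(n * dt, tau)
            done += n
        self._remove_com_motion()

    def sample(
        self, t_ps: float, dt: float = 0.002, out_every: float = 0.004,
        tau: float = 2.0,
    ) -> VelocitySeries:
        """Production run recording per-molecule COM and angular velocities."""
        stride = max(int(round(out_every / dt)), 1)
        nsteps = int(round(t_ps / dt))
        nframes = nsteps // stride + 1
        vcom = np.empty((nframes, self.n, 3))
        omega = np.empty((nframes, self.n, 3))
        _record_rigid_body(self.r, self.v, self.m, vcom[0], omega[0])
        t_acc = 0.0
        for k in range(1, nframes):
            self.run(stride, dt)
            self._bussi_rescale(stride * dt, tau)
            _record_rigid_body(self.r, self.v, self.m, vcom[k], omega[k])
            t_acc += self.temperature()
        t_mean = t_acc / (nframes - 1)
        return VelocitySeries(
            dt=stride * dt,
            com_velocities=vcom,
            masses=np.full(self.n, self.model.mass),
            angular_velocities=omega,
            principal_moments=self.model.principal_moments(),
            meta={
                "temperature_mean": t_mean,
                "box_edge": self.box_edge,
                "n_density": self.n / self.box_edge ** 3,
                "engine": "condensotherm.waterbox",
            },
        )


def simulate_bulk_water(
    n_molecules: int = 512,
    temperature: float = 300.0,
    density: float = 0.997,
    equil_ps: float = 14.0,
    production_ps: float = 20.0,
    dt: float = 0.002,
    out_every: float = 0.004,
    seed: int = 0,
) -> WaterBoxResult:
    """Equilibrate and sample a bulk four-site water box.

    Returns a :class:`WaterBoxResult` whose ``series`` feeds directly into
    :func:`condensotherm.twopt.entropy_pipeline`.
    """
    boxsim = WaterBox(
        n_molecules=n_molecules, temperature=temperature, density=density, seed=seed
    )
    # gentle start from the lattice, then full-step equilibration
    boxsim.equilibrate(0.5, dt=0.0005, tau=0.05)
    boxsim.equilibrate(2.0, dt=dt, tau=0.1)
    boxsim.equilibrate(max(equil_ps - 2.5, 0.0), dt=dt, tau=0.5)
    series = boxsim.sample(production_ps, dt=dt, out_every=out_every)
    return WaterBoxResult(
        series=series,
        box_edge=boxsim.box_edge,
        n_molecules=boxsim.n,
        temperature_mean=series.meta["temperature_mean"],
        n_density=series.meta["n_density"],
        meta={"seed": seed, "equil_ps": equil_ps, "production_ps": production_ps},
    )
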