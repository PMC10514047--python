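"""Two-phase thermodynamics (2PT) entropy engine.

Pipeline: velocity autocorrelation -> density of states -> solid/gas
partition via the fluidicity -> molar translational and rotational
entropies.

The density of states is the cosine transform of the mass- (or inertia-)
weighted velocity autocorrelation function,

    I(nu) = 2/(k_B T) * integral C(t) exp(i 2 pi nu t) dt,

normalized so that integral_0^inf I(nu) d nu equals the number of weighted
degrees of freedom (3N per kind for rigid nonlinear molecules).  The
diffusive (gas-like) fraction f of the degrees of freedom is obtained from
the universal fluidicity equation

    2 D^-9/2 f^15/2 - 6 D^-3 f^5 - D^-3/2 f^7/2 + 6 D^-3/2 f^5/2 + 2f - 2 = 0

where D is the dimensionless normalized diffusivity built from the
zero-frequency intensity s0, temperature, molecular mass and number
density.  The gas component carries a hard-sphere lineshape

    I_g(nu) = s0 / (1 + (pi s0 nu / (6 f N_dof/3 * 3))^2)           (translation)

whose [0, inf) integral is f * N_dof; the solid remainder is integrated
against the quantum harmonic-oscillator entropy weight.  The gas degrees
of freedom are assigned the Carnahan-Starling hard-sphere entropy
(translation) or the classical rigid-rotor entropy (rotation).  These
closed forms follow the standard 2PT literature; they are frozen here and
covered by oracle tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import H_PLANCK, KB, R_GAS
from .trajectory import VelocitySeries

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# correlograms
# ---------------------------------------------------------------------------

@dataclass
class Correlogram:
    """Weighted velocity autocorrelation: values in amu nm^2/ps^2 (= kJ/mol),
    summed over molecules and axes, versus lag time."""

    lags: np.ndarray
    values: np.ndarray
    kind: str
    n_molecules: int = 0

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("translational", "rotational"):
            raise ValueError(f"unknown correlogram kind {self.kind!r}")
        if self.lags[0] != 0.0:
            raise ValueError("lags must start at 0")
        dl = np.diff(self.lags)
        if not np.allclose(dl, dl[0], rtol=1e-8):
            raise ValueError("lags must be uniform")
        if self.values[0] <= 0:
            raise ValueError("zero-lag autocorrelation must be positive")

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])


def _autocorr_fft(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Unbiased autocorrelation over axis 0 for each column of ``x``.

    Returns shape (n_lags, ...) with entry j equal to
    mean_t x(t) x(t+j) over the (n - j) valid origins.
    """
    n = x.shape[0]
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    fx = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft(fx * np.conj(fx), n=nfft, axis=0)[:n_lags]
    counts = (n - np.arange(n_lags)).reshape((-1,) + (1,) * (x.ndim - 1))
    return acf / counts


def compute_vacf(
    series: VelocitySeries, kind: str = "translational", max_lag: float | None = None
) -> Correlogram:
    """Mass/inertia-weighted VACF, ensemble-averaged over time origins and
    summed over molecules and axes.

    ``max_lag`` (ps) defaults to half the trajectory duration and may not
    exceed it.
    """
    if max_lag is None:
        max_lag = series.duration / 2.0
    if max_lag > series.duration / 2.0 + 1e-12:
        raise ValueError("max_lag exceeds half the trajectory duration")
    n_lags = int(round(max_lag / series.dt)) + 1
    if kind == "translational":
        v = series.com_velocities
        weights = series.masses                       # (n_mol,)
        acf = _autocorr_fft(v, n_lags)                # (lag, n_mol, 3)
        values = np.einsum("lmd,m->l", acf, weights)
    elif kind == "rotational":
        if series.angular_velocities is None:
            raise ValueError("series has no angular velocities")
        w = series.angular_velocities
        acf = _autocorr_fft(w, n_lags)
        values = np.einsum("lmd,d->l", acf, series.principal_moments)
    else:
        raise ValueError(f"unknown VACF kind {kind!r}")
    lags = np.arange(n_lags) * series.dt
    return Correlogram(lags=lags, values=values, kind=kind, n_molecules=series.n_molecules)


def compute_vacf_bruteforce(
    series: VelocitySeries, kind: str = "translational", max_lag: float | None = None
) -> Correlogram:
    """O(N^2) double-loop reference implementation (oracle for tests)."""
    if max_lag is None:
        max_lag = series.duration / 2.0
    n_lags = int(round(max_lag / series.dt)) + 1
    if kind == "translational":
        data = series.com_velocities
        weights = np.repeat(series.masses[:, None], 3, axis=1)
    else:
        data = series.angular_velocities
        weights = np.repeat(series.principal_moments[None, :], series.n_molecules, axis=0)
    n = data.shape[0]
    values = np.zeros(n_lags)
    for lag in range(n_lags):
        acc = 0.0
        for t0 in range(n - lag):
            acc += float(np.sum(weights * data[t0] * data[t0 + lag]))
        values[lag] = acc / (n - lag)
    return Correlogram(
        lags=np.arange(n_lags) * series.dt, values=values, kind=kind,
        n_molecules=series.n_molecules,
    )


# ---------------------------------------------------------------------------
# density of states
# ---------------------------------------------------------------------------

@dataclass
class DensityOfStates:
    """Spectral density I(nu) on a THz grid; integral ~ weighted dof count."""

    frequencies: np.ndarray
    intensity: np.ndarray
    kind: str
    temperature: float
    n_molecules: int
    meta: dict = field(default_factory=dict)

    @property
    def s0(self) -> float:
        return float(self.intensity[0])

    @property
    def dof(self) -> float:
        """Nominal weighted dof count (3 per molecule per kind)."""
        return 3.0 * self.n_molecules

    def integral(self) -> float:
        return float(np.trapezoid(self.intensity, self.frequencies))


def compute_dos(
    c: Correlogram,
    T: float,
    n_molecules: int | None = None,
    zero_padding: int = 2,
    window: str | None = None,
) -> DensityOfStates:
    """Cosine transform of the (even-extended) VACF scaled by 2/(k_B T).

    No window is applied by default; ``zero_padding`` multiplies the lag
    count to refine the frequency grid (resolution 1/(2 max_lag) without
    padding).  Both choices are recorded in the output metadata.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    values = c.values.copy()
    if window == "hann":
        values *= np.hanning(2 * len(values) - 1)[len(values) - 1:]
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    L = len(values) - 1
    npad = L * max(int(zero_padding), 1)
    padded = np.zeros(npad + 1)
    padded[: L + 1] = values
    # trapezoid weights on the even extension: half weight at the ends
    ext = np.concatenate([padded, padded[-2:0:-1]])
    ext[0] = padded[0]
    spec = np.fft.rfft(ext).real
    # subtract half of the duplicated end point contribution for trapezoid
    dt = c.dt
    intensity = (2.0 / (KB * T)) * dt * spec
    freqs = np.fft.rfftfreq(len(ext), d=dt)
    nmol = n_molecules if n_molecules is not None else c.n_molecules
    dos = DensityOfStates(
        frequencies=freqs,
        intensity=intensity,
        kind=c.kind,
        temperature=T,
        n_molecules=nmol,
        meta={"window": window, "zero_padding": zero_padding, "max_lag": c.lags[-1]},
    )
    clipped = float(np.sum(np.minimum(dos.intensity, 0.0)))
    dos.meta["negative_weight"] = clipped
    return dos


def dos_bruteforce(c: Correlogram, T: float) -> np.ndarray:
    """Naive discrete cosine transform oracle (no padding, no window)."""
    L = len(c.values) - 1
    freqs = np.arange(L + 1) / (2.0 * L * c.dt)
    out = np.empty(L + 1)
    t = c.lags
    for k, nu in enumerate(freqs):
        w = np.full(L + 1, 2.0)
        w[0] = 1.0
        # the even extension duplicates lags 1..L-1; lag L appears once in
        # a length-2L periodic extension
        w[L] = 1.0
        out[k] = float(np.sum(w * c.values * np.cos(2 * np.pi * nu * t))) * c.dt
    return (2.0 / (KB * T)) * out


# ---------------------------------------------------------------------------
# fluidicity
# ---------------------------------------------------------------------------

def fluidicity_polynomial(f: np.ndarray | float, delta: float) -> np.ndarray | float:
    """LHS of the universal 2PT fluidicity equation."""
    return (
        2.0 * delta ** -4.5 * f ** 7.5
        - 6.0 * delta ** -3.0 * f ** 5.0
        - delta ** -1.5 * f ** 3.5
        + 6.0 * delta ** -1.5 * f ** 2.5
        + 2.0 * f
        - 2.0
    )


def normalized_diffusivity(
    s0: float, T: float, mass: float, n_density: float, n_molecules: int
) -> float:
    """Dimensionless diffusivity Delta(s0, T, m, rho).

    ``s0`` is the zero-frequency DoS intensity (per THz, dof-summed over N
    molecules), ``n_density`` the molecular number density in nm^-3.
    """
    return (
        (2.0 * s0 / (9.0 * n_molecules))
        * math.sqrt(math.pi * KB * T / mass)
        * n_density ** (1.0 / 3.0)
        * (6.0 / math.pi) ** (2.0 / 3.0)
    )


def solve_fluidicity(
    dos: DensityOfStates, n_density: float, mass: float, T: float
) -> float:
    """Solve the fluidicity equation for f in [0, 1] by bracketed root
    finding (tolerance 1e-12).  s0 = 0 returns f = 0 (pure solid)."""
    s0 = dos.s0
    if s0 < -0.01 * dos.dof:
        raise ValueError(f"negative zero-frequency DoS intensity s0 = {s0:.4g}")
    if s0 <= 0.0:
        return 0.0   # no diffusive weight: pure solid
    delta = normalized_diffusivity(s0, T, mass, n_density, dos.n_molecules)
    lo, hi = 1e-300, 1.0
    flo, fhi = fluidicity_polynomial(lo, delta), fluidicity_polynomial(hi, delta)
    if flo * fhi > 0:
        raise ValueError(
            f"fluidicity equation has no sign change on [0,1] "
            f"(delta={delta:.6g}, p(0+)={flo:.3g}, p(1)={fhi:.3g})"
        )
    f = brentq(fluidicity_polynomial, lo, hi, args=(delta,), xtol=1e-12, rtol=1e-15)
    return float(f)


# ---------------------------------------------------------------------------
# DoS partition
# ---------------------------------------------------------------------------

def gas_lineshape(
    frequencies: np.ndarray, s0: float, f: float, dof: float
) -> np.ndarray:
    """Diffusive hard-sphere/rigid-rotor lineshape with I(0) = s0 and
    [0, inf) integral f * dof."""
    if f <= 0 or s0 <= 0:
        return np.zeros_like(frequencies)
    return s0 / (1.0 + (math.pi * s0 * frequencies / (2.0 * f * dof)) ** 2)


def partition_dos(
    dos: DensityOfStates, f: float
) -> tuple[DensityOfStates, DensityOfStates]:
    """Split I(nu) into gas (diffusive) and solid (remainder) parts.

    The solid part is clipped at zero; clipped weight is logged and stored
    in the metadata.  solid + gas reproduces the input wherever no clipping
    occurred.
    """
    gas_i = gas_lineshape(dos.frequencies, dos.s0, f, dos.dof)
    solid_i = dos.intensity - gas_i
    clipped = float(-np.sum(np.minimum(solid_i, 0.0) * np.gradient(dos.frequencies)))
    if clipped > 0.02 * dos.dof:
        logger.warning(
            "solid DoS clipping removed %.3g states (%.1f%% of dof)",
            clipped, 100.0 * clipped / dos.dof,
        )
    solid_i = np.maximum(solid_i, 0.0)
    mk = lambda inten, label: DensityOfStates(
        frequencies=dos.frequencies.copy(),
        intensity=inten,
        kind=dos.kind,
        temperature=dos.temperature,
        n_molecules=dos.n_molecules,
        meta={**dos.meta, "component": label, "clipped_weight": clipped, "f": f},
    )
    return mk(solid_i, "solid"), mk(gas_i, "gas")


# ---------------------------------------------------------------------------
# entropy weights
# ---------------------------------------------------------------------------

def ho_entropy_weight(frequencies: np.ndarray, T: float) -> np.ndarray:
    """Quantum harmonic-oscillator entropy weight per dof (units of k_B):
    W(nu) = bhv/(e^bhv - 1) - ln(1 - e^-bhv), bhv = h nu / k_B T.

    The nu -> 0 divergence is irrelevant in use because the solid DoS
    vanishes at zero frequency; the weight is set to 0 there.
    """
    bhv = H_PLANCK * np.asarray(frequencies, dtype=float) / (KB * T)
    out = np.zeros_like(bhv)
    nz = bhv > 0
    x = bhv[nz]
    out[nz] = x / np.expm1(x) - np.log1p(-np.exp(-x))
    return out


def carnahan_starling_z(y: float) -> float:
    """Carnahan-Starling hard-sphere compressibility factor."""
    return (1.0 + y + y ** 2 - y ** 3) / (1.0 - y) ** 3


def hs_entropy_per_molecule(
    T: float, mass: float, n_density: float, f: float, delta: float
) -> float:
    """Hard-sphere entropy per gas molecule in units of k_B.

    Ideal-gas (Sackur-Tetrode) entropy at effective density f*N/V plus the
    Carnahan-Starling excess at packing fraction y = f^{5/2} / delta^{3/2}.
    """
    y = f ** 2.5 / delta ** 1.5
    if y >= 1.0:
        raise ValueError(f"hard-sphere packing fraction {y:.3f} >= 1")
    thermal = (2.0 * math.pi * mass * KB * T / H_PLANCK ** 2) ** 1.5
    eff_volume = 1.0 / (f * n_density)
    return (
        2.5
        + math.log(thermal * eff_volume * carnahan_starling_z(y))
        + y * (3.0 * y - 4.0) / (1.0 - y) ** 2
    )


def sackur_tetrode(T: float, mass: float, n_density: float) -> float:
    """Ideal-gas translational entropy, J mol^-1 K^-1 per molecule."""
    thermal = (2.0 * math.pi * mass * KB * T / H_PLANCK ** 2) ** 1.5
    return R_GAS * (2.5 + math.log(thermal / n_density))


def rotational_temperatures(principal_moments: np.ndarray) -> np.ndarray:
    """Theta_k = h^2 / (8 pi^2 I_k k_B) in K."""
    I = np.asarray(principal_moments, dtype=float)
    if np.any(I <= 0):
        raise ValueError("principal moments must be positive")
    return H_PLANCK ** 2 / (8.0 * math.pi ** 2 * I * KB)


def rigid_rotor_entropy_per_molecule(
    T: float, principal_moments: np.ndarray, symmetry_number: int = 2
) -> float:
    """Classical rigid-rotor entropy per molecule in units of k_B."""
    theta = rotational_temperatures(principal_moments)
    return 1.5 + math.log(
        math.sqrt(math.pi) / symmetry_number * math.sqrt(T ** 3 / np.prod(theta))
    )


# ---------------------------------------------------------------------------
# entropy assembly
# ---------------------------------------------------------------------------

@dataclass
class EntropyBreakdown:
    """Molar entropies per molecule (J mol^-1 K^-1) with 2PT components."""

    s_tr: float = 0.0
    s_rot: float = 0.0
    s_tr_ho: float = 0.0
    s_tr_hs: float = 0.0
    s_rot_ho: float = 0.0
    s_rot_rr: float = 0.0
    f_tr: float = 0.0
    f_rot: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    @property
    def s_tot(self) -> float:
        return self.s_tr + self.s_rot

    def validate(self) -> None:
        for name in ("s_tr_ho", "s_tr_hs", "s_rot_ho", "s_rot_rr"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative entropy component {name}")
        for name in ("f_tr", "f_rot"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"fluidicity {name} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "S_tot": self.s_tot, "S_tr": self.s_tr, "S_rot": self.s_rot,
            "S_tr_HO": self.s_tr_ho, "S_tr_HS": self.s_tr_hs,
            "S_rot_HO": self.s_rot_ho, "S_rot_RR": self.s_rot_rr,
            "f_tr": self.f_tr, "f_rot": self.f_rot,
            "diagnostics": self.diagnostics,
        }


def gas_dof_analytic(s0: float, f: float, dof: float, nu_max: float) -> float:
    """Closed-form [0, nu_max] integral of the gas lineshape.

    Used instead of grid quadrature because the lineshape can be narrower
    than the frequency resolution for strongly diffusive systems."""
    if f <= 0 or s0 <= 0:
        return 0.0
    a = math.pi * s0 / (2.0 * f * dof)
    return (2.0 * f * dof / math.pi) * math.atan(a * nu_max)


def _component_entropy(
    solid: DensityOfStates,
    gas: DensityOfStates,
    f: float,
    T: float,
    gas_weight: float,
) -> tuple[float, float]:
    """(HO part, gas part) in J mol^-1 K^-1 per molecule."""
    n = solid.n_molecules
    w_ho = ho_entropy_weight(solid.frequencies, T)
    s_ho = R_GAS * float(np.trapezoid(solid.intensity * w_ho, solid.frequencies)) / n
    gas_dof = gas_dof_analytic(
        gas.s0, f, gas.dof, float(gas.frequencies[-1])
    )
    s_gas = R_GAS * gas_dof * (gas_weight / 3.0) / n
    return s_ho, s_gas


def entropy_2pt(
    solid_tr: DensityOfStates,
    gas_tr: DensityOfStates,
    f_tr: float,
    T: float,
    mass: float,
    n_density: float,
    solid_rot: DensityOfStates | None = None,
    gas_rot: DensityOfStates | None = None,
    f_rot: float = 0.0,
    principal_moments: np.ndarray | None = None,
    symmetry_number: int = 2,
) -> EntropyBreakdown:
    """Assemble the 2PT entropy from partitioned DoS components.

    Translational: solid against the HO weight, gas dof times the
    hard-sphere entropy.  Rotational (optional): solid against the HO
    weight, gas dof times the classical rigid-rotor entropy, which needs
    the principal moments and symmetry number of the molecule.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    delta_tr = normalized_diffusivity(
        max(gas_tr.s0, 1e-300), T, mass, n_density, solid_tr.n_molecules
    )
    if f_tr > 0:
        hs = hs_entropy_per_molecule(T, mass, n_density, f_tr, delta_tr)
        if hs < 0:
            # deep in the near-solid regime (packing fraction ~ 1) the CS
            # excess diverges; a negative absolute gas entropy is unphysical
            logger.warning(
                "hard-sphere entropy weight %.3g < 0 (near-solid regime); "
                "clamped to 0", hs,
            )
            hs = 0.0
    else:
        hs = 0.0
    s_tr_ho, s_tr_hs = _component_entropy(solid_tr, gas_tr, f_tr, T, hs)

    out = EntropyBreakdown(
        s_tr=s_tr_ho + s_tr_hs,
        s_tr_ho=s_tr_ho,
        s_tr_hs=s_tr_hs,
        f_tr=f_tr,
        diagnostics={
            "s0_tr": gas_tr.s0,
            "delta_tr": delta_tr,
            "clipped_tr": solid_tr.meta.get("clipped_weight", 0.0),
        },
    )
    if solid_rot is not None:
        if principal_moments is None:
            raise ValueError("rotational entropy requires principal moments")
        rr = rigid_rotor_entropy_per_molecule(T, principal_moments, symmetry_number)
        if rr < 0:
            logger.warning("rigid-rotor entropy weight %.3g < 0; clamped to 0", rr)
            rr = 0.0
        s_rot_ho, s_rot_rr = _component_entropy(solid_rot, gas_rot, f_rot, T, rr)
        out.s_rot = s_rot_ho + s_rot_rr
        out.s_rot_ho = s_rot_ho
        out.s_rot_rr = s_rot_rr
        out.f_rot = f_rot
        out.diagnostics.update(
            {
                "s0_rot": gas_rot.s0,
                "clipped_rot": solid_rot.meta.get("clipped_weight", 0.0),
            }
        )
    out.validate()
    return out


def entropy_pipeline(
    series: VelocitySeries,
    T: float,
    n_density: float,
    max_lag: float | None = None,
    symmetry_number: int = 2,
    zero_padding: int = 2,
    window: str | None = None,
) -> EntropyBreakdown:
    """Full 2PT chain: VACF -> DoS -> fluidicity -> partition -> entropy.

    ``n_density`` is the molecular number density (molecules/nm^3) of the
    species under analysis.  Rotational entropy is included when the
    series carries angular velocities.
    """
    mass = float(series.masses.mean())
    vacf_tr = compute_vacf(series, "translational", max_lag=max_lag)
    dos_tr = compute_dos(vacf_tr, T, zero_padding=zero_padding, window=window)
    f_tr = solve_fluidicity(dos_tr, n_density, mass, T)
    # near-solid guard: as Delta -> 0 the root approaches the y -> 1 packing
    # limit where the hard-sphere weight diverges; a vanishing gas fraction
    # is treated as pure solid
    if f_tr < 1e-3:
        f_tr = 0.0
    solid_tr, gas_tr = partition_dos(dos_tr, f_tr)

    kwargs: dict = {}
    f_rot = 0.0
    if series.angular_velocities is not None:
        vacf_rot = compute_vacf(series, "rotational", max_lag=max_lag)
        dos_rot = compute_dos(vacf_rot, T, zero_padding=zero_padding, window=window)
        f_rot = solve_fluidicity(dos_rot, n_density, mass, T)
        if f_rot < 1e-3:
            f_rot = 0.0
        solid_rot, gas_rot = partition_dos(dos_rot, f_rot)
        kwargs = dict(
            solid_rot=solid_rot,
            gas_rot=gas_rot,
            f_rot=f_rot,
            principal_moments=series.principal_moments,
            symmetry_number=symmetry_number,
        )
    result = entropy_2pt(
        solid_tr, gas_tr, f_tr, T, mass, n_density, **kwargs
    )
    result.diagnostics["dos_integral_tr"] = dos_tr.integral()
    result.diagnostics["dof_tr"] = dos_tr.dof
    if series.angular_velocities is not None:
        result.diagnostics["dos_integral_rot"] = dos_rot.integral()
    return result
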