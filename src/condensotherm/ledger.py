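"""Free-energy bookkeeping of condensate formation.

All Delta quantities are per protein chain (kJ/mol, entropies J mol^-1
K^-1) relative to a hypothetical homogeneous solution at concentration
rho, with the condensate concentration rho_cond as the end state:

* released waters: N_W(rho) - N_W(rho_cond); retained: N_W(rho_cond);
* solvation entropy/energy changes: bulk-vs-rho differences weighted by
  released counts plus condensate-vs-rho differences weighted by retained
  counts;
* the water-water enthalpy and entropy terms cancel identically
  (dE_WW - T dS_WW = 0, Ben-Naim compensation), so the solvation free
  energy reduces to the protein-water terms: dG_solv = dE_PW - T dS_PW;
* the protein term is dE_PP(rho) = E_PP(rho_cond) - E_PP(rho);
* total: dG = dG_solv + dE_PP - T dS_P, optionally plus the analytic
  mixing and interface estimates (excluded by default, as their
  magnitudes are far below the other terms).

Sign convention: negative dG favours condensate formation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import N_AVOGADRO, R_GAS
from .trajectory import ConcentrationRecord, ConcentrationSeries

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# water budget
# ---------------------------------------------------------------------------

@dataclass
class WaterBudget:
    """Released/retained water counts per protein at one concentration."""

    rho: float
    n_w: float          # waters per protein at rho
    released: float     # N_W(rho) - N_W(rho_cond)
    retained: float     # N_W(rho_cond)


def water_budget(
    series: ConcentrationSeries,
    rho_cond: float = 350.0,
    allow_above_cond: bool = False,
) -> list[WaterBudget]:
    """Per-protein released/retained water counts for every rho row.

    Rows above rho_cond would imply negative release and are rejected
    unless explicitly allowed.
    """
    cond = series.get(rho_cond)
    retained = cond.waters_per_chain
    out = []
    for rec in series.records:
        if rec.is_bulk:
            continue
        if rec.rho > rho_cond + 1e-9 and not allow_above_cond:
            raise ValueError(
                f"rho = {rec.rho} exceeds rho_cond = {rho_cond}; "
                "pass allow_above_cond=True to keep such rows"
            )
        n_w = rec.waters_per_chain
        out.append(
            WaterBudget(
                rho=rec.rho, n_w=n_w, released=n_w - retained, retained=retained
            )
        )
    return out


# ---------------------------------------------------------------------------
# per-quantity released/retained changes
# ---------------------------------------------------------------------------

@dataclass
class TugOfWar:
    """Released/retained/total split of one per-water quantity change."""

    released: np.ndarray
    retained: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.released + self.retained


def _released_retained(
    per_water_values: dict[float, float],
    bulk_value: float,
    cond_value: float,
    budgets: list[WaterBudget],
) -> TugOfWar:
    rele = np.array(
        [(bulk_value - per_water_values[b.rho]) * b.released for b in budgets]
    )
    reta = np.array(
        [(cond_value - per_water_values[b.rho]) * b.retained for b in budgets]
    )
    return TugOfWar(released=rele, retained=reta)


def solvation_entropy_changes(
    series: ConcentrationSeries,
    budgets: list[WaterBudget],
    rho_cond: float,
    T: float = 300.0,
    component: str = "s_tot",
) -> tuple[TugOfWar, np.ndarray]:
    """(per-protein entropy tug-of-war in J mol^-1 K^-1, T*dS_solv in kJ/mol).

    The bulk reference row (dilute phase treated as bulk water) must be
    present in the series.
    """
    if not series.has_bulk():
        raise ValueError(
            "series lacks the bulk-water reference row needed for the "
            "dilute-phase entropy S(rho_dil)"
        )
    svals = {
        r.rho: getattr(r, component) for r in series.records if not r.is_bulk
    }
    tug = _released_retained(
        svals,
        getattr(series.bulk(), component),
        getattr(series.get(rho_cond), component),
        budgets,
    )
    t_ds_solv = T * tug.total / 1000.0
    return tug, t_ds_solv


def solvation_energy_changes(
    series: ConcentrationSeries,
    budgets: list[WaterBudget],
    rho_cond: float,
) -> dict[str, TugOfWar]:
    """Released/retained interaction-energy changes per component (kJ/mol
    per protein) for the water-water and protein-water terms.

    e_ww is per water on input.  e_pw is stored per protein and is
    converted to a per-water value through the water count before the
    released/retained weighting (conversion logged); its bulk reference is
    zero (no protein in the dilute phase).
    """
    for rec in series.records:
        if not rec.is_bulk and (not np.isfinite(rec.e_ww) or not np.isfinite(rec.e_pw)):
            raise ValueError(f"record at rho={rec.rho} lacks WW/PW energy components")
    cond = series.get(rho_cond)
    ww_vals = {r.rho: r.e_ww for r in series.records if not r.is_bulk}
    ww = _released_retained(
        ww_vals, series.bulk().e_ww, cond.e_ww, budgets
    )
    logger.info("e_pw converted from per-protein to per-water via N_W(rho)")
    pw_vals = {
        r.rho: r.e_pw / r.waters_per_chain for r in series.records if not r.is_bulk
    }
    pw = _released_retained(
        pw_vals, 0.0, cond.e_pw / cond.waters_per_chain, budgets
    )
    return {"WW": ww, "PW": pw}


def apply_cancellation(
    t_ds_solv: np.ndarray | float, de_ww: np.ndarray | float
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """(T dS_PW, T dS_WW): the water-water entropy term is set equal to the
    water-water energy change by the compensation identity; the
    protein-water term is the non-cancelling remainder."""
    t_ds_ww = de_ww
    t_ds_pw = t_ds_solv - de_ww
    return t_ds_pw, t_ds_ww


def protein_energy_change(
    series: ConcentrationSeries, rho_cond: float
) -> np.ndarray:
    """dE_PP(rho) = E_PP(rho_cond) - E_PP(rho), per protein (kJ/mol)."""
    cond = series.get(rho_cond)
    return np.array(
        [cond.e_pp - r.e_pp for r in series.records if not r.is_bulk]
    )


# ---------------------------------------------------------------------------
# analytic estimators
# ---------------------------------------------------------------------------

def mixing_free_energy(rho_cond: float, rho_dil: float, T: float = 300.0) -> float:
    """Demixing free-energy estimate RT ln(rho_cond/rho_dil) in kJ/mol."""
    if rho_dil <= 0 or rho_cond <= 0:
        raise ValueError("concentrations must be positive")
    return R_GAS * T * math.log(rho_cond / rho_dil) / 1000.0


def interface_penalty(
    radius: float, gamma: float, rho_cond: float = 350.0, chain_mass: float = 17.2
) -> float:
    """Interface free energy per protein for a spherical droplet (kJ/mol).

    gamma (mN/m) times surface area divided by the protein amount in a
    droplet of the given radius (nm) at concentration rho_cond (mg/mL)
    for chains of chain_mass (kDa): 3 gamma M / (c r), per mole.
    """
    if radius <= 0 or gamma <= 0 or rho_cond <= 0 or chain_mass <= 0:
        raise ValueError("all interface-penalty inputs must be positive")
    # SI: gamma [J/m^2] * 3 M [kg/mol] / (c [kg/m^3] * r [m]) -> J/mol
    joules_per_mol = (
        3.0 * (gamma * 1e-3) * (chain_mass) / (rho_cond * radius * 1e-9)
    )
    return joules_per_mol / 1000.0


# ---------------------------------------------------------------------------
# ledger assembly
# ---------------------------------------------------------------------------

@dataclass
class ThermoLedger:
    """Tidy per-rho table of every Delta term plus options/provenance."""

    table: pd.DataFrame
    rho_cond: float
    temperature: float
    options: dict = field(default_factory=dict)
    replicate_tables: list[pd.DataFrame] = field(default_factory=list)

    def row(self, rho: float) -> pd.Series:
        match = self.table[np.isclose(self.table["rho"], rho)]
        if match.empty:
            raise KeyError(f"no ledger row at rho = {rho}")
        return match.iloc[0]

    def validate_identities(self, atol: float = 1e-9) -> None:
        t = self.table
        if not np.allclose(t["dE_WW"] - t["TdS_WW"], 0.0, atol=atol):
            raise AssertionError("water-water cancellation identity violated")
        lhs = t["dH_solv"] - t["TdS_solv"]
        rhs = t["dE_PW"] - t["TdS_PW"]
        if not np.allclose(lhs, rhs, atol=max(atol, 1e-9 * np.abs(lhs).max())):
            raise AssertionError("dG_solv route consistency violated")


def _assemble_single(
    series: ConcentrationSeries,
    rho_cond: float,
    T: float,
    ds_p: dict[float, float] | float | None,
    include_mix: bool,
    include_interface: bool,
    rho_dil: float,
    interface_radius: float,
    interface_gamma: float,
    chain_mass: float,
    allow_above_cond: bool,
) -> pd.DataFrame:
    budgets = water_budget(series, rho_cond, allow_above_cond=allow_above_cond)
    rhos = np.array([b.rho for b in budgets])
    s_tug, t_ds_solv = solvation_entropy_changes(series, budgets, rho_cond, T)
    energies = solvation_energy_changes(series, budgets, rho_cond)
    de_ww = energies["WW"].total
    de_pw = energies["PW"].total
    dh_solv = de_pw + de_ww
    t_ds_pw, t_ds_ww = apply_cancellation(t_ds_solv, de_ww)
    dg_solv = dh_solv - t_ds_solv          # equals de_pw - t_ds_pw identically
    de_pp = protein_energy_change(series, rho_cond)

    if ds_p is None:
        ds_p_arr = np.zeros_like(rhos)
    elif isinstance(ds_p, dict):
        ds_p_arr = np.array([ds_p.get(r, 0.0) for r in rhos])
    else:
        ds_p_arr = np.full_like(rhos, float(ds_p))
    # dS_P vanishes at the reference state like every other Delta
    ds_p_arr = np.where(np.isclose(rhos, rho_cond), 0.0, ds_p_arr)
    t_ds_p = T * ds_p_arr / 1000.0

    dg_total = dg_solv + de_pp - t_ds_p
    dg_mix = mixing_free_energy(rho_cond, rho_dil, T)
    dg_interface = interface_penalty(
        interface_radius, interface_gamma, rho_cond, chain_mass
    )
    if include_mix:
        dg_total = dg_total + dg_mix
    if include_interface:
        dg_total = dg_total + dg_interface

    return pd.DataFrame(
        {
            "rho": rhos,
            "N_released": [b.released for b in budgets],
            "N_retained": [b.retained for b in budgets],
            "dS_rele": s_tug.released,
            "dS_reta": s_tug.retained,
            "dS_tot": s_tug.total,
            "TdS_solv": t_ds_solv,
            "dE_WW_rele": energies["WW"].released,
            "dE_WW_reta": energies["WW"].retained,
            "dE_WW": de_ww,
            "dE_PW_rele": energies["PW"].released,
            "dE_PW_reta": energies["PW"].retained,
            "dE_PW": de_pw,
            "dH_solv": dh_solv,
            "TdS_WW": t_ds_ww,
            "TdS_PW": t_ds_pw,
            "dG_solv": dg_solv,
            "dE_PP": de_pp,
            "dS_P": ds_p_arr,
            "TdS_P": t_ds_p,
            "dG_mix": dg_mix,
            "dG_interface": dg_interface,
            "dG_total": dg_total,
        }
    )


def assemble_ledger(
    series: ConcentrationSeries,
    rho_cond: float = 350.0,
    T: float = 300.0,
    ds_p: dict[float, float] | float | None = None,
    include_mix: bool = False,
    include_interface: bool = False,
    rho_dil: float = 1.0,
    interface_radius: float = 20.0,
    interface_gamma: float = 0.5,
    chain_mass: float = 17.2,
    replicates: list[ConcentrationSeries] | None = None,
    allow_above_cond: bool = False,
) -> ThermoLedger:
    """Assemble the full ledger; optionally propagate replicate SDs.

    ``ds_p`` is the protein conformational entropy change (J mol^-1 K^-1
    per protein), constant or per-rho.  The mixing and interface estimates
    are always computed and reported but excluded from dG_total unless the
    corresponding flags are set (their magnitudes are negligible next to
    the other contributions).
    """
    table = _assemble_single(
        series, rho_cond, T, ds_p, include_mix, include_interface,
        rho_dil, interface_radius, interface_gamma, chain_mass, allow_above_cond,
    )
    rep_tables = []
    if replicates:
        n_rows = {len(r.records) for r in replicates}
        if len(n_rows) != 1:
            raise ValueError("inconsistent replicate row counts")
        for rep in replicates:
            rep_tables.append(
                _assemble_single(
                    rep, rho_cond, T, ds_p, include_mix, include_interface,
                    rho_dil, interface_radius, interface_gamma, chain_mass,
                    allow_above_cond,
                )
            )
        stack = np.stack([t.drop(columns="rho").to_numpy() for t in rep_tables])
        sds = stack.std(axis=0)
        for j, col in enumerate(table.columns.drop("rho")):
            table[f"sd_{col}"] = sds[:, j]
    ledger = ThermoLedger(
        table=table,
        rho_cond=rho_cond,
        temperature=T,
        options={
            "include_mix": include_mix,
            "include_interface": include_interface,
            "rho_dil": rho_dil,
            "interface_radius_nm": interface_radius,
            "interface_gamma_mN_per_m": interface_gamma,
            "chain_mass_kDa": chain_mass,
            "e_ww_convention": "per water on input",
            "e_pw_convention": "per protein on input, converted per water",
            "normalization": "per protein chain",
        },
        replicate_tables=rep_tables,
    )
    ledger.validate_identities()
    return ledger
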