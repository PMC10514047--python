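"""Manifest-driven end-to-end orchestration.

A run manifest (YAML/JSON) lists either a precomputed per-concentration
series table, or raw per-system inputs (structure, velocity trajectory,
energy tables) per (rho, replicate).  The pipeline builds the
ConcentrationSeries, assembles the free-energy ledger, and writes tidy
CSV/JSON reports plus a QC section recording every convention actually
used.  Runs are deterministic given the manifest and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import hydration, ledger as ledger_mod, twopt
from .trajectory import (
    ConcentrationRecord,
    ConcentrationSeries,
    read_energy_table,
    read_structure,
    read_velocity_trajectory,
)

logger = logging.getLogger(__name__)


class ManifestError(ValueError):
    """Raised when a run manifest fails validation."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class RunManifest:
    temperature: float = 300.0
    rho_cond: float = 350.0
    rho_dil: float = 1.0
    seed: int = 0
    chain_mass: float = 17.2
    series_table: Path | None = None
    replicate_tables: list[Path] = field(default_factory=list)
    systems: list[dict] = field(default_factory=list)
    ds_p: float | None = None
    include_mix: bool = False
    include_interface: bool = False
    max_lag: float | None = None
    raw: dict = field(default_factory=dict)


def load_manifest(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)


def validate_manifest(data: dict | str | Path, base_dir: Path | None = None) -> RunManifest:
    """Validate manifest contents; raises :class:`ManifestError` listing
    every problem found."""
    if not isinstance(data, dict):
        base_dir = base_dir or Path(data).parent
        data = load_manifest(data)
    base_dir = base_dir or Path(".")
    errors: list[str] = []

    m = RunManifest(
        temperature=float(data.get("temperature", 300.0)),
        rho_cond=float(data.get("rho_cond", 350.0)),
        rho_dil=float(data.get("rho_dil", 1.0)),
        seed=int(data.get("seed", 0)),
        chain_mass=float(data.get("chain_mass", 17.2)),
        ds_p=data.get("conf_entropy", {}).get("ds_p") if data.get("conf_entropy") else None,
        include_mix=bool(data.get("options", {}).get("include_mix", False)),
        include_interface=bool(data.get("options", {}).get("include_interface", False)),
        max_lag=data.get("max_lag"),
        raw=data,
    )

    def resolve(p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base_dir / p

    if "series_table" in data:
        m.series_table = resolve(data["series_table"])
        if not m.series_table.exists():
            errors.append(f"series_table does not exist: {m.series_table}")
        for rp in data.get("replicate_tables", []):
            rp = resolve(rp)
            m.replicate_tables.append(rp)
            if not rp.exists():
                errors.append(f"replicate table does not exist: {rp}")
    elif "systems" in data:
        rhos = set()
        has_bulk = False
        for i, sysd in enumerate(data["systems"]):
            entry = dict(sysd)
            if entry.get("bulk"):
                has_bulk = True
            else:
                if "rho" not in entry:
                    errors.append(f"system {i}: missing rho")
                else:
                    rhos.add(float(entry["rho"]))
            for key in ("structure", "velocity_trajectory"):
                if key in entry:
                    entry[key] = resolve(entry[key])
                    if not entry[key].exists():
                        errors.append(f"system {i}: {key} path missing: {entry[key]}")
            if "energies" in entry:
                entry["energies"] = {
                    k: resolve(v) for k, v in entry["energies"].items()
                }
                for k, v in entry["energies"].items():
                    if not v.exists():
                        errors.append(f"system {i}: energy table missing: {v}")
            m.systems.append(entry)
        if len(rhos) < 2:
            errors.append("need at least 2 distinct concentrations")
        if m.rho_cond not in rhos:
            errors.append(
                f"rho_cond = {m.rho_cond} has no system entry; the released-"
                "water count is defined relative to the condensate row"
            )
        if not has_bulk:
            errors.append(
                "no bulk-water reference entry; the dilute-phase entropy "
                "S(rho_dil) requires one"
            )
    else:
        errors.append("manifest must provide either series_table or systems")

    if errors:
        raise ManifestError(errors)
    return m


# ---------------------------------------------------------------------------
# raw-system processing
# ---------------------------------------------------------------------------

def process_system(entry: dict, manifest: RunManifest) -> tuple[ConcentrationRecord, dict]:
    """One (rho, replicate) raw system -> ConcentrationRecord + QC info."""
    qc: dict = {}
    top, frame = read_structure(entry["structure"])
    volume = float(np.prod(frame.box))
    is_bulk = bool(entry.get("bulk"))
    rho = manifest.rho_dil if is_bulk else float(entry["rho"])

    s_tot = s_tr = s_rot = float("nan")
    if "velocity_trajectory" in entry:
        series = read_velocity_trajectory(
            entry["velocity_trajectory"], top, structure=entry.get("structure")
        )
        n_density = top.n_waters / volume
        eb = twopt.entropy_pipeline(
            series, manifest.temperature, n_density, max_lag=manifest.max_lag
        )
        s_tot, s_tr, s_rot = eb.s_tot, eb.s_tr, eb.s_rot
        qc["entropy_diagnostics"] = eb.diagnostics

    e_pp = e_pw = e_ww = float("nan")
    energies = entry.get("energies", {})
    n_chains = top.n_chains
    if "PP" in energies and n_chains:
        e_pp = read_energy_table(energies["PP"], "PP").mean / n_chains
    if "PW" in energies and n_chains:
        e_pw = read_energy_table(energies["PW"], "PW").mean / n_chains
    if "WW" in energies and top.n_waters:
        e_ww = read_energy_table(energies["WW"], "WW").mean / top.n_waters
    if is_bulk:
        e_pp, e_pw = 0.0, 0.0

    n_phl = float("nan")
    if n_chains and top.n_waters:
        layer = hydration.count_phl_waters(frame, top)
        n_phl = layer.mean_per_chain
        qc["phl_cutoff_nm"] = layer.cutoff

    rec = ConcentrationRecord(
        rho=rho, n_chains=n_chains, n_waters=top.n_waters,
        s_tot=s_tot, s_tr=s_tr, s_rot=s_rot,
        e_pp=e_pp, e_pw=e_pw, e_ww=e_ww, n_phl=n_phl,
        box_edge=float(frame.box[0]),
    )
    return rec, qc


def _series_from_systems(manifest: RunManifest) -> tuple[ConcentrationSeries, list[ConcentrationSeries], dict]:
    groups: dict[tuple[float, bool], list[ConcentrationRecord]] = {}
    qc_all: dict = {}
    for i, entry in enumerate(manifest.systems):
        try:
            rec, qc = process_system(entry, manifest)
        except Exception as exc:
            rho = entry.get("rho", "bulk")
            raise RuntimeError(f"system processing failed at rho={rho}: {exc}") from exc
        key = (rec.rho, rec.is_bulk)
        groups.setdefault(key, []).append(rec)
        qc_all[f"system_{i}"] = qc

    records = []
    max_reps = max(len(v) for v in groups.values())
    replicate_series: list[ConcentrationSeries] = []
    fields = ("s_tot", "s_tr", "s_rot", "e_pp", "e_pw", "e_ww", "n_phl")
    for (rho, _), recs in sorted(groups.items()):
        if len(recs) < max_reps:
            logger.warning("rho=%s has %d replicates (< %d)", rho, len(recs), max_reps)
        def _agg(fn, f):
            vals_f = [getattr(r, f) for r in recs if np.isfinite(getattr(r, f))]
            return float(fn(vals_f)) if vals_f else float("nan")

        vals = {f: _agg(np.mean, f) for f in fields}
        if np.isfinite(vals["s_tr"]) and np.isfinite(vals["s_rot"]):
            vals["s_tot"] = vals["s_tr"] + vals["s_rot"]
        sds = {f: _agg(np.std, f) for f in fields}
        r0 = recs[0]
        records.append(
            ConcentrationRecord(
                rho=rho, n_chains=r0.n_chains, n_waters=r0.n_waters,
                box_edge=r0.box_edge, sd={k: v for k, v in sds.items() if np.isfinite(v)},
                **vals,
            )
        )
    series = ConcentrationSeries(records)
    return series, replicate_series, qc_all


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    series: ConcentrationSeries
    ledger: ledger_mod.ThermoLedger
    qc: dict
    output_files: dict


def run_pipeline(
    manifest: RunManifest | dict | str | Path, out_dir: str | Path = "condensotherm_out"
) -> RunResult:
    """Execute the full analysis described by the manifest."""
    if not isinstance(manifest, RunManifest):
        manifest = validate_manifest(manifest)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    qc: dict = {
        "seed": manifest.seed,
        "temperature": manifest.temperature,
        "rho_cond": manifest.rho_cond,
        "conventions": {
            "hb_criterion": "d(D..A) <= 0.35 nm, angle(H-D-A) <= 30 deg",
            "phl": "any water atom within 0.3 nm of any protein atom",
            "q_neighbors": "4 nearest water oxygens, no cutoff",
            "dos": "no window, zero padding x2",
        },
    }
    replicates: list[ConcentrationSeries] = []
    if manifest.series_table is not None:
        series = ConcentrationSeries.from_csv(manifest.series_table)
        replicates = [
            ConcentrationSeries.from_csv(p) for p in manifest.replicate_tables
        ]
    else:
        series, replicates, system_qc = _series_from_systems(manifest)
        qc["systems"] = system_qc

    led = ledger_mod.assemble_ledger(
        series,
        rho_cond=manifest.rho_cond,
        T=manifest.temperature,
        ds_p=manifest.ds_p,
        include_mix=manifest.include_mix,
        include_interface=manifest.include_interface,
        rho_dil=manifest.rho_dil,
        chain_mass=manifest.chain_mass,
        replicates=replicates or None,
    )

    series_csv = out_dir / "series.csv"
    ledger_csv = out_dir / "ledger.csv"
    report_json = out_dir / "report.json"
    series.to_csv(series_csv)
    led.table.to_csv(ledger_csv, index=False, float_format="%.10g")
    report = {
        "qc": qc,
        "options": led.options,
        "ledger": json.loads(led.table.to_json(orient="records")),
    }
    with open(report_json, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return RunResult(
        series=series,
        ledger=led,
        qc=qc,
        output_files={
            "series": series_csv, "ledger": ledger_csv, "report": report_json
        },
    )
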