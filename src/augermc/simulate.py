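"""End-to-end run orchestration: config, sampling loop, outputs, manifest.

A run samples ``n_events`` nuclear decays from a decay scheme, relaxes every
primary vacancy through the cascade engine (each cascade starts from a
neutral atom of its element), and writes a summary table, binned spectra,
a machine-readable manifest and, optionally, a per-emission trace log.
All randomness flows from a single seed; each event uses a substream derived
from (seed, event index), so any event is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .atomic import AtomTable, EnergyModel, RateSet, ValidationError, load_atom
from .cascade import CascadeEvent, run_cascade
from .decay import DecayScheme, NuclearEmission, load_decay_scheme, sample_decay_pathway
from .spectra import (
    SpectrumSet,
    SummaryTable,
    accumulate,
    energy_ledger,
    write_spectrum,
    write_summary,
)

__all__ = ["RunConfig", "RunResult", "run_simulation", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one simulation run."""

    scheme: str  # decay-scheme path
    atom_tables: dict[int, str]  # Z -> atomic-table path (emitting elements)
    zp1_tables: dict[int, str] = field(default_factory=dict)  # Z -> Z+1 table path
    n_events: int = 100_000
    seed: int = 1
    energy_model: str = "z_plus_one"
    bin_width_ev: float = 10.0
    occupancy_scaling: bool = True
    trace: bool = False
    outdir: str = "augermc_out"

    def validate(self) -> None:
        if self.n_events <= 0:
            raise ValidationError("n_events must be positive")
        if self.energy_model not in ("neutral", "z_plus_one"):
            raise ValidationError(f"unknown energy_model {self.energy_model!r}")
        if self.bin_width_ev <= 0:
            raise ValidationError("bin_width_ev must be positive")
        for label, path in [("scheme", self.scheme)] + [
            (f"atom_tables[{z}]", p) for z, p in self.atom_tables.items()
        ] + [(f"zp1_tables[{z}]", p) for z, p in self.zp1_tables.items()]:
            if not Path(path).is_file():
                raise ValidationError(f"{label}: file not found: {path}")


@dataclass
class RunResult:
    summary: SummaryTable
    spectra: SpectrumSet
    cascades: list[CascadeEvent]
    nuclear: list[NuclearEmission]
    ledger: dict[str, float]
    outdir: Path


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run config (keys as in RunConfig; paths relative to it)."""
    import yaml

    path = Path(path)
    obj = yaml.safe_load(path.read_text()) or {}
    base = path.parent

    def _rel(p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    return RunConfig(
        scheme=_rel(obj["scheme"]),
        atom_tables={int(z): _rel(p) for z, p in obj.get("atom_tables", {}).items()},
        zp1_tables={int(z): _rel(p) for z, p in obj.get("zp1_tables", {}).items()},
        n_events=int(obj.get("n_events", 100_000)),
        seed=int(obj.get("seed", 1)),
        energy_model=obj.get("energy_model", "z_plus_one"),
        bin_width_ev=float(obj.get("bin_width_ev", 10.0)),
        occupancy_scaling=bool(obj.get("occupancy_scaling", True)),
        trace=bool(obj.get("trace", False)),
        outdir=obj.get("outdir", "augermc_out"),
    )


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_simulation(config: RunConfig, progress: bool = False) -> RunResult:
    """Execute one run and write summary/spectrum/manifest (and trace) files.

    Deterministic given (config, seed): identical inputs produce
    byte-identical output files.
    """
    config.validate()
    scheme = load_decay_scheme(config.scheme)
    tables: dict[int, AtomTable] = {}
    rates: dict[int, RateSet] = {}
    for z, path in config.atom_tables.items():
        tables[z], rates[z] = load_atom(path)
        if tables[z].Z != z:
            raise ValidationError(f"atom table {path} has Z={tables[z].Z}, expected {z}")
    models: dict[int, EnergyModel] = {}
    for z, table in tables.items():
        if config.energy_model == "z_plus_one":
            if z in config.zp1_tables:
                zp1, _ = load_atom(config.zp1_tables[z])
            elif z + 1 in tables:
                zp1 = tables[z + 1]
            else:
                raise ValidationError(
                    f"energy_model=z_plus_one but no Z+1 table for Z={z}"
                )
            models[z] = EnergyModel("z_plus_one", table, zp1)
        else:
            models[z] = EnergyModel("neutral", table)

    nuclear: list[NuclearEmission] = []
    cascades: list[CascadeEvent] = []
    trace_rows: list[str] = []
    iterator = range(config.n_events)
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc="events")
        except ImportError:
            pass
    for i in iterator:
        rng = np.random.default_rng([config.seed, i])
        emissions, vacancies = sample_decay_pathway(scheme, tables, rng)
        nuclear.extend(emissions)
        if config.trace:
            for ne in emissions:
                trace_rows.append(
                    f"{i}\tnuclear\t0\t{ne.kind}\t{ne.shell or ''}\t\t"
                    f"\t{ne.energy * 1000.0:.4f}\t{ne.transition_id}"
                )
        for vac in vacancies:
            event = run_cascade(
                tables[vac.element_Z],
                rates[vac.element_Z],
                vac.subshell,
                rng,
                models[vac.element_Z],
                occupancy_scaling=config.occupancy_scaling,
                origin=vac.origin,
            )
            cascades.append(event)
            if config.trace:
                for e in event.emissions:
                    labels = list(e.shells) + [""] * (3 - len(e.shells))
                    trace_rows.append(
                        f"{i}\tatomic\t{e.step}\t{e.kind}\t{labels[0]}"
                        f"\t{labels[1]}\t{labels[2]}\t{e.energy:.4f}\t{vac.origin}"
                    )

    spectra, summary = accumulate(
        cascades, nuclear, config.n_events, bin_width=config.bin_width_ev
    )
    ledger = energy_ledger(cascades, nuclear, config.n_events)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_summary(summary, outdir / "summary.tsv")
    write_spectrum(spectra, outdir / "spectrum.tsv")
    if config.trace:
        header = "event\tsource\tstep\tkind\tX\tY\tZ\tenergy_eV\torigin"
        (outdir / "trace.tsv").write_text(
            "\n".join([header] + trace_rows) + "\n"
        )
    manifest = {
        "package": "augermc",
        "version": __version__,
        "numpy": np.__version__,
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_events": config.n_events,
        "n_cascades": len(cascades),
        "n_nuclear_emissions": len(nuclear),
        "mean_final_charge": (
            sum(ev.final_charge for ev in cascades) / len(cascades)
            if cascades
            else 0.0
        ),
        "auger_per_decay": sum(ev.n_auger for ev in cascades) / config.n_events,
        "xray_per_decay": sum(ev.n_xray for ev in cascades) / config.n_events,
        "energy_totals_keV_per_decay": ledger,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return RunResult(
        summary=summary,
        spectra=spectra,
        cascades=cascades,
        nuclear=nuclear,
        ledger=ledger,
        outdir=outdir,
    )
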