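"""Aggregation of simulated events into yields, summary tables and spectra.

Atomic emissions are grouped into the conventional transition classes:
Auger electrons by the principal shells involved (KLL, KLX, KXY, ...), with
the Coster-Kronig prefix when a final vacancy shares the initial vacancy's
principal shell (CK LLM, CK LLX, ...) and "Super CK" when all three subshells
lie in one principal shell; X-rays by the Siegbahn-style classes Kalpha1
(K <- L3), Kalpha2 (K <- L2), Kbeta (K <- M and beyond) and the plain
principal-shell letter for non-K lines.  In the class grammar, "X" and "Y"
stand for "any shell beyond the named principal shell".

Yields are reported per nuclear decay; spectra are histograms with
half-open, lower-edge-inclusive bins (default width 10 eV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .atomic import (
    AtomTable,
    EnergyModel,
    PRINCIPAL_ORDER,
    RateSet,
    ValidationError,
    shell_group,
)
from .cascade import AtomState, CascadeEvent, Emission, allowed_transitions
from .decay import NuclearEmission

__all__ = [
    "classify_emission",
    "classify_nuclear",
    "SpectrumSet",
    "SummaryTable",
    "accumulate",
    "deterministic_primary_yields",
    "energy_ledger",
    "write_summary",
    "read_summary",
    "write_spectrum",
    "read_spectrum",
]

KEV = 1000.0

#: fixed presentation order of radiation kinds
KIND_ORDER = ("gamma", "ce", "xray", "auger")


def _next_principal(letter: str) -> str | None:
    i = PRINCIPAL_ORDER.index(letter)
    return PRINCIPAL_ORDER[i + 1] if i + 1 < len(PRINCIPAL_ORDER) else None


def classify_emission(e: Emission) -> str:
    """Transition-class label of one atomic emission."""
    if e.kind == "xray":
        x, y = e.shells
        px, py = shell_group(x), shell_group(y)
        if px == "K":
            if y == "L3":
                return "Kα1"
            if y == "L2":
                return "Kα2"
            if py == "L":
                return "Kα3"  # K <- L1, forbidden in dipole order but possible
            return "Kβ"
        return px
    if e.kind == "auger":
        x, y, z = e.shells
        px, py, pz = shell_group(x), shell_group(y), shell_group(z)
        if px == py == pz:
            return f"Super CK {px}{px}{px}"
        if px in (py, pz):
            other = pz if py == px else py
            q = _next_principal(px)
            # conventional grouping: L-shell CK is subdivided by whether the
            # ejected electron comes from the next principal shell (CK LLM
            # vs CK LLX); deeper-shell CK is pooled as CK MMX, CK NNX, ...
            suffix = other if (px == "L" and other == q) else "X"
            return f"CK {px}{px}{suffix}"
        q = _next_principal(px)
        if px in ("K", "L"):
            in_q = (py == q) + (pz == q)
            if in_q == 2:
                return f"{px}{q}{q}"
            if in_q == 1:
                return f"{px}{q}X"
        # M- and deeper-shell Auger transitions are conventionally pooled
        return f"{px}XY"
    raise ValidationError(f"cannot classify emission of kind {e.kind!r}")


def classify_nuclear(ne: NuclearEmission) -> str:
    """Row label of one nuclear emission (gamma or conversion electron)."""
    if ne.kind == "gamma":
        return f"γ {ne.transition_id}"
    if ne.kind == "ce":
        return f"CE-{shell_group(ne.shell)} {ne.transition_id}"
    raise ValidationError(f"cannot classify nuclear emission {ne.kind!r}")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SpectrumSet:
    """Binned emission spectra, one histogram per radiation kind.

    ``hist[kind][k]`` is the intensity per nuclear decay falling in the
    half-open energy bin [k*w, (k+1)*w) eV with w = ``bin_width``.
    """

    bin_width: float = 10.0  # eV
    hist: dict[str, dict[int, float]] = field(default_factory=dict)

    def add(self, kind: str, energy_ev: float, weight: float) -> None:
        k = int(energy_ev // self.bin_width)
        bins = self.hist.setdefault(kind, {})
        bins[k] = bins.get(k, 0.0) + weight

    def total_yield(self, kind: str) -> float:
        return sum(self.hist.get(kind, {}).values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind in KIND_ORDER:
            for k in sorted(self.hist.get(kind, {})):
                rows.append(
                    {
                        "bin_lo_eV": k * self.bin_width,
                        "bin_hi_eV": (k + 1) * self.bin_width,
                        "kind": kind,
                        "intensity_per_decay": self.hist[kind][k],
                    }
                )
        return pd.DataFrame(
            rows, columns=["bin_lo_eV", "bin_hi_eV", "kind", "intensity_per_decay"]
        )


@dataclass
class SummaryTable:
    """Per-class mean energies and yields plus per-kind energy totals.

    ``table`` has columns (class, kind, mean_energy_keV, yield_per_decay);
    mean energies are intensity-weighted.  ``totals`` holds the energy
    release per nuclear decay in keV for each radiation kind.
    """

    table: pd.DataFrame
    totals: dict[str, float]

    def yield_of(self, cls: str) -> float:
        sel = self.table.loc[self.table["class"] == cls, "yield_per_decay"]
        return float(sel.sum())

    def mean_energy_of(self, cls: str) -> float:
        sel = self.table.loc[self.table["class"] == cls]
        if sel.empty:
            raise KeyError(cls)
        return float(sel["mean_energy_keV"].iloc[0])

    def kind_yield(self, kind: str) -> float:
        sel = self.table.loc[self.table["kind"] == kind, "yield_per_decay"]
        return float(sel.sum())


# ---------------------------------------------------------------------------
# accumulation
# ---------------------------------------------------------------------------

def accumulate(
    cascades: Iterable[CascadeEvent],
    nuclear: Iterable[NuclearEmission],
    n_decays: int,
    bin_width: float = 10.0,
) -> tuple[SpectrumSet, SummaryTable]:
    """Reduce simulated events to a spectrum set and a summary table.

    Yields are counts divided by ``n_decays``; the per-class mean energy is
    the energy-weighted (i.e. intensity-weighted) mean over the class's
    emissions.  Nuclear energies are in keV, atomic emissions in eV; the
    summary reports keV throughout.
    """
    if n_decays <= 0:
        raise ValidationError("n_decays must be positive")
    spectra = SpectrumSet(bin_width=bin_width)
    count: dict[tuple[str, str], int] = {}
    esum: dict[tuple[str, str], float] = {}  # keV

    def _tally(cls: str, kind: str, energy_kev: float) -> None:
        key = (cls, kind)
        count[key] = count.get(key, 0) + 1
        esum[key] = esum.get(key, 0.0) + energy_kev

    w = 1.0 / n_decays
    for ne in nuclear:
        _tally(classify_nuclear(ne), ne.kind, ne.energy)
        spectra.add(ne.kind, ne.energy * KEV, w)
    for ev in cascades:
        for e in ev.emissions:
            _tally(classify_emission(e), e.kind, e.energy / KEV)
            spectra.add(e.kind, e.energy, w)

    rows = []
    for (cls, kind), n in count.items():
        rows.append(
            {
                "class": cls,
                "kind": kind,
                "mean_energy_keV": esum[(cls, kind)] / n,
                "yield_per_decay": n / n_decays,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["class", "kind", "mean_energy_keV", "yield_per_decay"]
    )
    frame["_k"] = frame["kind"].map({k: i for i, k in enumerate(KIND_ORDER)})
    frame = (
        frame.sort_values(["_k", "class"], kind="mergesort")
        .drop(columns="_k")
        .reset_index(drop=True)
    )
    totals = {
        kind: sum(v for (c, k), v in esum.items() if k == kind) / n_decays
        for kind in KIND_ORDER
    }
    return spectra, SummaryTable(table=frame, totals=totals)


def energy_ledger(
    cascades: Iterable[CascadeEvent],
    nuclear: Iterable[NuclearEmission],
    n_decays: int,
) -> dict[str, float]:
    """Total energy release per nuclear decay (keV) by radiation kind."""
    if n_decays <= 0:
        raise ValidationError("n_decays must be positive")
    totals = {kind: 0.0 for kind in KIND_ORDER}
    for ne in nuclear:
        totals[ne.kind] += ne.energy
    for ev in cascades:
        for e in ev.emissions:
            totals[e.kind] += e.energy / KEV
    return {kind: v / n_decays for kind, v in totals.items()}


def deterministic_primary_yields(
    f_vacancies: Mapping[str, float],
    table: AtomTable,
    rates: RateSet,
    model: EnergyModel,
) -> pd.DataFrame:
    """Closed-form first-step yields from primary vacancy abundances.

    For f_X primary vacancies per decay on subshell X, the first-transition
    X-ray yield into class c is f_X * omega_X * N_Xc and the Auger yield
    f_X * (1 - omega_X) * N_Xc, with omega_X the fluorescence yield of the
    allowed channel set and N the normalized relative intensities.  Only the
    first transition of each cascade is described; the simulated cascade
    extends this through all subsequent steps.
    """
    rows: dict[tuple[str, str], float] = {}
    for x, f in f_vacancies.items():
        if f < 0:
            raise ValidationError(f"negative vacancy abundance for {x}")
        if f == 0 or x in table.valence_labels:
            continue
        state = AtomState.neutral(table)
        state.ionize(x, step=0)
        channels = allowed_transitions(state, x, rates, model)
        total = sum(c.weight for c in channels)
        if total <= 0:
            continue
        for c in channels:
            cls = classify_emission(Emission(c.kind, c.shells, c.energy, 1))
            key = (cls, c.kind)
            rows[key] = rows.get(key, 0.0) + f * c.weight / total
    frame = pd.DataFrame(
        [
            {"class": cls, "kind": kind, "yield_per_decay": y}
            for (cls, kind), y in rows.items()
        ],
        columns=["class", "kind", "yield_per_decay"],
    )
    frame["_k"] = frame["kind"].map({k: i for i, k in enumerate(KIND_ORDER)})
    return (
        frame.sort_values(["_k", "class"], kind="mergesort")
        .drop(columns="_k")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_summary(summary: SummaryTable, path: str | Path) -> None:
    """TSV: class rows (energies in keV, 4 decimals) then per-kind totals."""
    lines = ["class\tkind\tmean_energy_keV\tyield_per_decay"]
    for _, row in summary.table.iterrows():
        lines.append(
            f"{row['class']}\t{row['kind']}\t{row['mean_energy_keV']:.4f}"
            f"\t{row['yield_per_decay']:.6e}"
        )
    for kind in KIND_ORDER:
        lines.append(f"TOTAL\t{kind}\t{summary.totals.get(kind, 0.0):.4f}\t")
    Path(path).write_text("\n".join(lines) + "\n")


def read_summary(path: str | Path) -> SummaryTable:
    rows, totals = [], {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        cls, kind, e, y = line.split("\t")
        if cls == "TOTAL":
            totals[kind] = float(e)
        else:
            rows.append(
                {
                    "class": cls,
                    "kind": kind,
                    "mean_energy_keV": float(e),
                    "yield_per_decay": float(y),
                }
            )
    frame = pd.DataFrame(
        rows, columns=["class", "kind", "mean_energy_keV", "yield_per_decay"]
    )
    return SummaryTable(table=frame, totals=totals)


def write_spectrum(spectra: SpectrumSet, path: str | Path) -> None:
    """TSV with one row per non-empty bin."""
    frame = spectra.to_frame()
    lines = ["bin_lo_eV\tbin_hi_eV\tkind\tintensity_per_decay"]
    for _, row in frame.iterrows():
        lines.append(
            f"{row['bin_lo_eV']:.1f}\t{row['bin_hi_eV']:.1f}\t{row['kind']}"
            f"\t{row['intensity_per_decay']:.9e}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path, bin_width: float | None = None) -> SpectrumSet:
    lines = Path(path).read_text().splitlines()
    spectra: SpectrumSet | None = None
    for line in lines[1:]:
        lo, hi, kind, y = line.split("\t")
        lo, hi = float(lo), float(hi)
        if spectra is None:
            spectra = SpectrumSet(bin_width=bin_width or (hi - lo))
        bins = spectra.hist.setdefault(kind, {})
        bins[int(lo // spectra.bin_width)] = float(y)
    return spectra if spectra is not None else SpectrumSet(bin_width=bin_width or 10.0)
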