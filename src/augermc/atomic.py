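"""Atomic-structure data model: subshells, binding energies, transition rates.

The atom is described the way single-vacancy relaxation libraries describe it:
an ordered list of subshells (K, L1..L3, M1..M5, ...) with neutral occupancies
and neutral-atom binding energies, plus a set of radiative (X <- Y) and
non-radiative (X, YZ) transition rates valid for a single vacancy on X in an
otherwise neutral atom.  Transition energies are derived from binding-energy
differences; two pluggable models are provided, ``neutral`` (all energies from
neutral-atom binding energies) and ``z_plus_one`` (the ejected-electron binding
energy taken from the next element, approximating the singly ionized atom).

All energies are stored in electron-volts.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Subshell",
    "AtomTable",
    "RateSet",
    "EnergyModel",
    "AtomDataError",
    "ParseError",
    "ValidationError",
    "shell_group",
    "xray_energy",
    "auger_energy",
    "make_toy_atom",
    "load_atom",
    "dump_atom",
    "bundled_atom",
]

#: principal-shell letters in order of increasing principal quantum number
PRINCIPAL_ORDER = "KLMNOPQR"

_LABEL_RE = re.compile(r"^([KLMNOPQR])([1-9][0-9]?)?$")


class AtomDataError(Exception):
    """Base class for atomic-table problems."""


class ParseError(AtomDataError):
    """Malformed table file; message carries line/field context."""


class ValidationError(AtomDataError):
    """A structurally valid file violating a physical invariant."""


def shell_group(label: str) -> str:
    """Principal-shell letter of a subshell label (``"L2" -> "L"``)."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValidationError(f"unknown subshell label {label!r}")
    return m.group(1)


@dataclass(frozen=True)
class Subshell:
    """One electron subshell of a neutral atom."""

    label: str
    principal: str
    capacity: int
    binding_energy: float  # eV, neutral atom
    neutral_occupancy: int

    def __post_init__(self) -> None:
        if shell_group(self.label) != self.principal:
            raise ValidationError(
                f"subshell {self.label!r}: principal letter {self.principal!r} "
                f"does not match label"
            )
        if self.capacity <= 0:
            raise ValidationError(f"subshell {self.label}: capacity must be > 0")
        if not 0 <= self.neutral_occupancy <= self.capacity:
            raise ValidationError(
                f"subshell {self.label}: occupancy {self.neutral_occupancy} "
                f"outside [0, {self.capacity}]"
            )
        if self.binding_energy <= 0:
            raise ValidationError(
                f"subshell {self.label}: binding energy must be positive"
            )


@dataclass(frozen=True)
class AtomTable:
    """Ordered subshell structure of one element.

    Subshells are ordered from the K shell outward; binding energies must
    strictly decrease along that order.  ``valence_labels`` designates the
    terminal subshells at which vacancy propagation stops; by default it is
    the outermost occupied principal shell.
    """

    Z: int
    subshells: tuple[Subshell, ...]
    valence_labels: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        labels = [s.label for s in self.subshells]
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate subshell labels: {dup}")
        energies = [s.binding_energy for s in self.subshells]
        for a, b, la, lb in zip(energies, energies[1:], labels, labels[1:]):
            if not a > b:
                raise ValidationError(
                    f"binding energies must strictly decrease outward: "
                    f"{la}={a} eV followed by {lb}={b} eV"
                )
        if not self.valence_labels:
            object.__setattr__(
                self, "valence_labels", frozenset(self._default_valence(labels))
            )
        unknown = self.valence_labels - set(labels)
        if unknown:
            raise ValidationError(f"valence labels not in table: {sorted(unknown)}")

    def _default_valence(self, labels: Sequence[str]) -> list[str]:
        occupied = [s for s in self.subshells if s.neutral_occupancy > 0]
        outer = max(
            (PRINCIPAL_ORDER.index(s.principal) for s in occupied), default=0
        )
        letter = PRINCIPAL_ORDER[outer]
        return [s.label for s in self.subshells if s.principal == letter]

    # -- lookups -----------------------------------------------------------
    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.subshells)

    def __contains__(self, label: str) -> bool:
        return any(s.label == label for s in self.subshells)

    def __getitem__(self, label: str) -> Subshell:
        for s in self.subshells:
            if s.label == label:
                return s
        raise KeyError(label)

    def binding(self, label: str) -> float:
        """Neutral-atom binding energy in eV."""
        return self[label].binding_energy

    def s_subshells(self) -> list[Subshell]:
        """The s-subshells (K, L1, M1, ...) in order, one per principal shell."""
        out = []
        for letter in PRINCIPAL_ORDER:
            lab = "K" if letter == "K" else f"{letter}1"
            if lab in self:
                out.append(self[lab])
        return out


@dataclass(frozen=True)
class RateSet:
    """Single-vacancy transition rates for one element.

    ``radiative`` maps (X, Y) to the X-ray rate for filling a vacancy on X
    from Y; ``nonradiative`` maps (X, Y, Z) to the Auger rate filling X from Y
    while ejecting the Z electron.  Rates are in arbitrary but mutually
    consistent units and refer to a single vacancy on X in a neutral atom
    (``basis``).  The fluorescence yield of X is a derived quantity.
    """

    radiative: Mapping[tuple[str, str], float]
    nonradiative: Mapping[tuple[str, str, str], float]
    basis: str = "single-vacancy-neutral"

    def __post_init__(self) -> None:
        for key, rate in {**dict(self.radiative)}.items():
            if rate < 0:
                raise ValidationError(f"negative radiative rate for {key}: {rate}")
        for key, rate in {**dict(self.nonradiative)}.items():
            if rate < 0:
                raise ValidationError(f"negative non-radiative rate for {key}: {rate}")
        for x in self.initial_vacancies():
            if self.total(x) <= 0:
                raise ValidationError(f"subshell {x}: total transition rate is zero")

    def initial_vacancies(self) -> set[str]:
        xs = {x for (x, _y) in self.radiative}
        xs |= {x for (x, _y, _z) in self.nonradiative}
        return xs

    def radiative_from(self, x: str) -> dict[tuple[str, str], float]:
        return {k: v for k, v in self.radiative.items() if k[0] == x}

    def nonradiative_from(self, x: str) -> dict[tuple[str, str, str], float]:
        return {k: v for k, v in self.nonradiative.items() if k[0] == x}

    def radiative_total(self, x: str) -> float:
        return sum(self.radiative_from(x).values())

    def nonradiative_total(self, x: str) -> float:
        return sum(self.nonradiative_from(x).values())

    def total(self, x: str) -> float:
        return self.radiative_total(x) + self.nonradiative_total(x)

    def fluorescence_yield(self, x: str) -> float:
        """omega_X: probability that a single vacancy on X is filled radiatively."""
        total = self.total(x)
        if total <= 0:
            raise ValidationError(f"subshell {x}: no transitions, omega undefined")
        return self.radiative_total(x) / total

    def auger_yield(self, x: str) -> float:
        """1 - omega_X; complementary by construction."""
        return 1.0 - self.fluorescence_yield(x)


@dataclass(frozen=True)
class EnergyModel:
    """Transition-energy model.

    ``neutral`` takes every binding energy from the neutral atom of the
    emitting element.  ``z_plus_one`` approximates the binding energy of the
    ejected Auger electron (which leaves an atom that already carries a
    spectator vacancy) by the neutral binding energy of the same subshell in
    the next element, the classic Z/Z+1 rule.  Both are static stand-ins for
    a per-configuration self-consistent-field recomputation.
    """

    mode: str
    table: AtomTable
    table_zp1: AtomTable | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("neutral", "z_plus_one"):
            raise ValidationError(f"unknown energy model mode {self.mode!r}")
        if self.mode == "z_plus_one":
            if self.table_zp1 is None:
                raise ValidationError("z_plus_one mode requires the Z+1 atom table")
            if self.table_zp1.Z != self.table.Z + 1:
                raise ValidationError(
                    f"Z+1 table has Z={self.table_zp1.Z}, expected {self.table.Z + 1}"
                )

    def binding(self, label: str) -> float:
        return self.table.binding(label)

    def ejected_binding(self, label: str) -> float:
        """E_Z^Y: binding energy of the ejected electron's subshell."""
        if self.mode == "neutral":
            return self.table.binding(label)
        assert self.table_zp1 is not None
        if label not in self.table_zp1:
            raise ValidationError(
                f"subshell {label} missing from Z+1 table (Z={self.table_zp1.Z})"
            )
        return self.table_zp1.binding(label)


def xray_energy(x: str, y: str, model: EnergyModel) -> float | None:
    """Energy (eV) of the X-ray emitted filling a vacancy on ``x`` from ``y``.

    E = E_BE(X) - E_BE(Y).  Returns None when the result is not positive,
    i.e. the transition is energetically not allowed.
    """
    e = model.binding(x) - model.binding(y)
    return e if e > 0 else None


def auger_energy(x: str, y: str, z: str, model: EnergyModel) -> float | None:
    """Energy (eV) of the XYZ Auger electron, or None when not allowed.

    E = E_BE(X) - E_BE(Y) - E'(Z), with E'(Z) the ejected-electron binding
    energy under the model (neutral or Z+1).  By convention the shells are
    ordered so that E_BE(Y) >= E_BE(Z).
    """
    if model.binding(y) < model.binding(z):
        raise ValidationError(
            f"Auger convention violated: E_BE({y}) < E_BE({z}); swap Y and Z"
        )
    e = model.binding(x) - model.binding(y) - model.ejected_binding(z)
    return e if e > 0 else None


# ---------------------------------------------------------------------------
# toy-atom fixture generator
# ---------------------------------------------------------------------------

_TOY_LABELS = ("K", "L1", "L2", "L3", "M1", "M2", "M3", "M4", "M5", "N1")
_TOY_CAPACITY = {"K": 2, "L1": 2, "L2": 2, "L3": 4, "M1": 2, "M2": 2,
                 "M3": 4, "M4": 4, "M5": 6, "N1": 2}


def make_toy_atom(
    n_subshells: int,
    binding_energies: Sequence[float] | None = None,
    occupancies: Sequence[int] | None = None,
    rate_seed: int = 0,
) -> tuple[AtomTable, RateSet]:
    """Small fully synthetic atom for testing the cascade machinery.

    Subshells take the first ``n_subshells`` labels of K, L1, L2, L3, M1, ...
    with realistic capacities.  Every well-formed transition out of each
    non-valence subshell (radiative X <- Y and Auger X, YZ with Y, Z strictly
    outside X and E_Y >= E_Z) receives a reproducible pseudo-random rate in
    (0.1, 1.1).  Deterministic for a fixed ``rate_seed``.
    """
    if not 1 <= n_subshells <= len(_TOY_LABELS):
        raise ValidationError(
            f"n_subshells must be in [1, {len(_TOY_LABELS)}], got {n_subshells}"
        )
    labels = _TOY_LABELS[:n_subshells]
    if binding_energies is None:
        binding_energies = [1000.0 * 3.0 ** -(i) for i in range(n_subshells)]
    if occupancies is None:
        occupancies = [_TOY_CAPACITY[lab] for lab in labels]
    if len(binding_energies) != n_subshells or len(occupancies) != n_subshells:
        raise ValidationError(
            "binding_energies and occupancies must each have n_subshells entries"
        )
    subshells = tuple(
        Subshell(lab, shell_group(lab), _TOY_CAPACITY[lab], float(e), int(o))
        for lab, e, o in zip(labels, binding_energies, occupancies)
    )
    table = AtomTable(Z=sum(occupancies), subshells=subshells)

    rng = np.random.default_rng(rate_seed)
    radiative: dict[tuple[str, str], float] = {}
    nonradiative: dict[tuple[str, str, str], float] = {}
    for i, x in enumerate(labels):
        if x in table.valence_labels:
            continue
        outer = labels[i + 1:]
        for y in outer:
            if table[y].neutral_occupancy > 0:
                radiative[(x, y)] = round(0.1 + rng.random(), 6)
        for j, y in enumerate(outer):
            for z in outer[j:]:
                need = 2 if y == z else 1
                if (table[y].neutral_occupancy >= need
                        and table[z].neutral_occupancy >= need):
                    nonradiative[(x, y, z)] = round(0.1 + rng.random(), 6)
    return table, RateSet(radiative=radiative, nonradiative=nonradiative)


# ---------------------------------------------------------------------------
# table I/O (TSV dialect and JSON mirror)
# ---------------------------------------------------------------------------

_SECTIONS = ("element", "subshells", "radiative", "nonradiative")


def _parse_sections(text: str, path: str) -> dict[str, list[tuple[int, list[str]]]]:
    sections: dict[str, list[tuple[int, list[str]]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip()
            if current not in _SECTIONS:
                raise ParseError(f"{path}:{lineno}: unknown section [{current}]")
            sections.setdefault(current, [])
            continue
        if current is None:
            raise ParseError(f"{path}:{lineno}: data before any section header")
        sections[current].append((lineno, line.split("\t")))
    return sections


def _rows_to_dicts(
    rows: list[tuple[int, list[str]]], path: str, section: str
) -> list[tuple[int, dict[str, str]]]:
    if not rows:
        return []
    header_lineno, header = rows[0]
    out = []
    for lineno, cells in rows[1:]:
        if len(cells) > len(header):
            raise ParseError(
                f"{path}:{lineno}: [{section}] row has {len(cells)} fields, "
                f"header has {len(header)}"
            )
        cells = cells + [""] * (len(header) - len(cells))
        out.append((lineno, dict(zip(header, cells))))
    return out


def _get(row: dict[str, str], key: str, path: str, lineno: int, section: str) -> str:
    if key not in row or row[key] == "":
        raise ParseError(f"{path}:{lineno}: [{section}] missing field {key!r}")
    return row[key]


def load_atom(path: str | Path) -> tuple[AtomTable, RateSet]:
    """Read an atomic table (TSV dialect or its JSON mirror)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _atom_from_obj(json.loads(path.read_text()), str(path))
    text = path.read_text()
    name = str(path)
    sections = _parse_sections(text, name)
    if "subshells" not in sections:
        raise ParseError(f"{name}: missing [subshells] section")

    z = 0
    valence: list[str] = []
    for lineno, row in _rows_to_dicts(sections.get("element", []), name, "element"):
        z = int(_get(row, "Z", name, lineno, "element"))
        v = row.get("valence", "")
        if v:
            valence = [s.strip() for s in v.split(",") if s.strip()]

    subshells = []
    for lineno, row in _rows_to_dicts(sections["subshells"], name, "subshells"):
        try:
            subshells.append(
                Subshell(
                    label=_get(row, "label", name, lineno, "subshells"),
                    principal=_get(row, "principal", name, lineno, "subshells"),
                    capacity=int(_get(row, "capacity", name, lineno, "subshells")),
                    binding_energy=float(
                        _get(row, "binding_eV", name, lineno, "subshells")
                    ),
                    neutral_occupancy=int(
                        _get(row, "occupancy", name, lineno, "subshells")
                    ),
                )
            )
        except ValueError as exc:  # int()/float() failures
            raise ParseError(f"{name}:{lineno}: [subshells] {exc}") from exc
    if z == 0:
        z = sum(s.neutral_occupancy for s in subshells)

    radiative: dict[tuple[str, str], float] = {}
    for lineno, row in _rows_to_dicts(sections.get("radiative", []), name, "radiative"):
        key = (_get(row, "X", name, lineno, "radiative"),
               _get(row, "Y", name, lineno, "radiative"))
        try:
            radiative[key] = float(_get(row, "rate", name, lineno, "radiative"))
        except ValueError as exc:
            raise ParseError(f"{name}:{lineno}: [radiative] {exc}") from exc

    nonradiative: dict[tuple[str, str, str], float] = {}
    for lineno, row in _rows_to_dicts(
        sections.get("nonradiative", []), name, "nonradiative"
    ):
        key = (_get(row, "X", name, lineno, "nonradiative"),
               _get(row, "Y", name, lineno, "nonradiative"),
               _get(row, "Z", name, lineno, "nonradiative"))
        try:
            nonradiative[key] = float(_get(row, "rate", name, lineno, "nonradiative"))
        except ValueError as exc:
            raise ParseError(f"{name}:{lineno}: [nonradiative] {exc}") from exc

    table = AtomTable(Z=z, subshells=tuple(subshells),
                      valence_labels=frozenset(valence))
    rates = RateSet(radiative=radiative, nonradiative=nonradiative)
    _check_rate_labels(table, rates)
    return table, rates


def _atom_from_obj(obj: dict, name: str) -> tuple[AtomTable, RateSet]:
    try:
        subshells = tuple(
            Subshell(
                label=s["label"],
                principal=s.get("principal", shell_group(s["label"])),
                capacity=int(s["capacity"]),
                binding_energy=float(s["binding_eV"]),
                neutral_occupancy=int(s["occupancy"]),
            )
            for s in obj["subshells"]
        )
    except KeyError as exc:
        raise ParseError(f"{name}: subshell entry missing field {exc}") from exc
    table = AtomTable(
        Z=int(obj.get("Z") or sum(s.neutral_occupancy for s in subshells)),
        subshells=subshells,
        valence_labels=frozenset(obj.get("valence_labels", [])),
    )
    rates = RateSet(
        radiative={(r["X"], r["Y"]): float(r["rate"])
                   for r in obj.get("radiative", [])},
        nonradiative={(r["X"], r["Y"], r["Z"]): float(r["rate"])
                      for r in obj.get("nonradiative", [])},
    )
    _check_rate_labels(table, rates)
    return table, rates


def _check_rate_labels(table: AtomTable, rates: RateSet) -> None:
    for key in list(rates.radiative) + list(rates.nonradiative):
        for lab in key:
            if lab not in table:
                raise ValidationError(f"rate entry {key} references unknown subshell {lab}")


def dump_atom(table: AtomTable, rates: RateSet, path: str | Path,
              header: str = "") -> None:
    """Write an atomic table in the TSV dialect (round-trips with load_atom)."""
    lines = []
    if header:
        lines.extend(f"# {ln}" for ln in header.splitlines())
    lines.append("[element]")
    lines.append("Z\tvalence")
    lines.append(f"{table.Z}\t{','.join(sorted(table.valence_labels))}")
    lines.append("[subshells]")
    lines.append("label\tprincipal\tcapacity\toccupancy\tbinding_eV")
    for s in table.subshells:
        lines.append(
            f"{s.label}\t{s.principal}\t{s.capacity}\t{s.neutral_occupancy}"
            f"\t{s.binding_energy!r}"
        )
    lines.append("[radiative]")
    lines.append("X\tY\trate")
    for (x, y), r in sorted(rates.radiative.items()):
        lines.append(f"{x}\t{y}\t{r!r}")
    lines.append("[nonradiative]")
    lines.append("X\tY\tZ\trate")
    for (x, y, z), r in sorted(rates.nonradiative.items()):
        lines.append(f"{x}\t{y}\t{z}\t{r!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def bundled_atom(symbol: str) -> tuple[AtomTable, RateSet]:
    """Load one of the packaged reference tables ('Tc', 'Ru', 'Cd', 'In').

    These carry reference neutral-atom binding energies only; their rate
    sections are empty (single-vacancy rate libraries are distributed
    separately and loaded the same way).
    """
    from importlib.resources import as_file, files

    res = files("augermc.data").joinpath(f"{symbol.lower()}.tsv")
    if not res.is_file():
        raise FileNotFoundError(f"no bundled table for element {symbol!r}")
    with as_file(res) as p:
        return load_atom(p)
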