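"""Nuclear decay model: electron capture and internal conversion.

Electron capture (EC) removes a bound electron, so it is energetically
possible on shell X only when Q+ - E_i - E_BE(X) > 0, where Q+ is the
parent-daughter atomic mass difference and E_i the final nuclear level.
Relative subshell capture probabilities are built from adjacent-shell ratio
factors (the tabulated k_LK and analogues), each scaled by the squared ratio
of the neutrino energies, and then normalized so that P_K + P_L + ... = 1.

An electromagnetic transition of energy E_tr either emits a gamma ray or
converts on an atomic subshell X with conversion coefficient alpha_X =
P_X / P_gamma; the conversion electron carries E_tr - E_BE(X) - E_recoil and
the channel exists only when that energy is positive.

EC vacancies appear in the daughter element; conversion vacancies in the
element whose nucleus de-excites.  Each vacancy relaxes independently,
starting from a neutral atom: in practice conversion happens only after the
atom has fully relaxed from any preceding capture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .atomic import (
    AtomTable,
    ParseError,
    Subshell,
    ValidationError,
    shell_group,
    _rows_to_dicts,
)

__all__ = [
    "ECBranch",
    "EMTransition",
    "DecayScheme",
    "NuclearEmission",
    "PrimaryVacancy",
    "ec_allowed",
    "ec_subshell_probabilities",
    "conversion_electron_energy",
    "conversion_channel_probabilities",
    "sample_decay_pathway",
    "load_decay_scheme",
    "bundled_scheme",
]

KEV = 1000.0  # eV per keV

#: ratio-factor key for capture on principal shell q relative to shell p
_RATIO_KEYS = {("L", "K"): "kLK", ("M", "L"): "kML",
               ("N", "M"): "kNM", ("O", "N"): "kON"}


@dataclass(frozen=True)
class ECBranch:
    """One electron-capture branch to a fixed daughter level.

    ``ratio_factors`` carries the adjacent-shell factors (``kLK`` etc.) and,
    optionally, explicit per-subshell weights as ``w_<label>`` entries
    (unnormalized, relative to the K-shell chain weight of 1).
    """

    q_plus: float  # keV, parent minus daughter ground-state atomic masses
    level_energy: float  # keV, final nuclear level E_i
    branch_intensity: float  # probability per decay
    ratio_factors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.branch_intensity <= 1.0:
            raise ValidationError(
                f"EC branch intensity {self.branch_intensity} outside [0, 1]"
            )

    @property
    def delta_e(self) -> float:
        """Available decay energy Q+ - E_i in keV."""
        return self.q_plus - self.level_energy


@dataclass(frozen=True)
class EMTransition:
    """One electromagnetic transition of the decay scheme.

    ``intensity`` is the per-decay occurrence probability of the transition
    itself (photons per decay before conversion scaling); the photon share is
    intensity / (1 + sum of the energetically allowed alpha_X).
    """

    id: str
    energy: float  # keV, E_tr
    intensity: float
    icc: Mapping[str, float] = field(default_factory=dict)  # label -> alpha_X
    recoil_energy: float = 0.0  # keV

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise ValidationError(f"transition {self.id}: energy must be positive")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValidationError(
                f"transition {self.id}: intensity {self.intensity} outside [0, 1]"
            )
        for lab, a in self.icc.items():
            if a < 0:
                raise ValidationError(
                    f"transition {self.id}: negative alpha for {lab}"
                )


@dataclass(frozen=True)
class DecayScheme:
    parent: str
    halflife: str
    mode: str  # "EC" | "IT" | "mixed"
    branches: tuple[ECBranch, ...]
    transitions: tuple[EMTransition, ...]
    daughter_Z: int | None = None  # element receiving EC vacancies
    converter_Z: int | None = None  # element receiving conversion vacancies

    def __post_init__(self) -> None:
        if self.mode not in ("EC", "IT", "mixed"):
            raise ValidationError(f"unknown decay mode {self.mode!r}")
        if sum(b.branch_intensity for b in self.branches) > 1.0 + 1e-9:
            raise ValidationError("EC branch intensities sum to more than 1")
        if self.branches and self.daughter_Z is None:
            raise ValidationError("EC branches present but daughter_Z unset")
        if self.transitions and self.converter_Z is None:
            raise ValidationError("EM transitions present but converter_Z unset")


@dataclass(frozen=True)
class NuclearEmission:
    kind: str  # "gamma" | "ce"
    transition_id: str
    energy: float  # keV
    shell: str | None = None  # subshell label for conversion electrons


@dataclass(frozen=True)
class PrimaryVacancy:
    element_Z: int
    subshell: str
    origin: str  # "EC" or "IC:<transition id>"


# ---------------------------------------------------------------------------
# electron capture
# ---------------------------------------------------------------------------

def ec_allowed(branch: ECBranch, shell: Subshell) -> bool:
    """Capture on ``shell`` is possible iff the neutrino energy is positive."""
    return branch.delta_e - shell.binding_energy / KEV > 0


def ec_subshell_probabilities(
    branch: ECBranch, table: AtomTable
) -> dict[str, float]:
    """Normalized capture probabilities over the daughter's subshells.

    When only adjacent principal-shell ratio factors are given, all capture
    is assigned to the s-subshells (K, L1, M1, ...), where it overwhelmingly
    occurs for allowed transitions.  The chained ratios are accumulated as
    unnormalized weights {1, r_L, r_L r_M, ...} and normalized at the end,
    which is algebraically identical to the nested closed form.  Explicit
    ``w_<label>`` factors add further subshells with the given weight.
    Energetically forbidden shells get probability zero.
    """
    weights: dict[str, float] = {}
    chain = 1.0
    prev: Subshell | None = None
    for s in table.s_subshells():
        if prev is not None:
            key = _RATIO_KEYS.get((s.principal, prev.principal))
            k = float(branch.ratio_factors.get(key, 0.0)) if key else 0.0
            if k <= 0.0:
                chain = 0.0
            else:
                de = branch.delta_e
                num = de - s.binding_energy / KEV
                den = de - prev.binding_energy / KEV
                chain *= k * (num / den) ** 2 if den != 0 else 0.0
        weights[s.label] = chain if chain > 0 else 0.0
        prev = s
    for key, w in branch.ratio_factors.items():
        if key.startswith("w_"):
            lab = key[2:]
            if lab not in table:
                raise ValidationError(f"ratio factor {key}: unknown subshell {lab}")
            weights[lab] = weights.get(lab, 0.0) + float(w)
    for lab in list(weights):
        if not ec_allowed(branch, table[lab]):
            weights[lab] = 0.0
    total = sum(weights.values())
    if total <= 0.0:
        raise ValidationError(
            f"electron capture impossible: no allowed subshell for "
            f"Q+-E_i = {branch.delta_e:.4f} keV"
        )
    return {lab: w / total for lab, w in weights.items() if w > 0.0}


# ---------------------------------------------------------------------------
# internal conversion
# ---------------------------------------------------------------------------

def conversion_electron_energy(
    t: EMTransition, shell: Subshell
) -> float | None:
    """Kinetic energy (keV) of the conversion electron, or None if forbidden.

    E = E_tr - E_BE(X) - E_recoil; the channel exists only when E > 0.
    """
    e = t.energy - shell.binding_energy / KEV - t.recoil_energy
    return e if e > 0 else None


def conversion_channel_probabilities(
    t: EMTransition, table: AtomTable
) -> dict[str, float]:
    """Distribution over {'gamma'} and 'CE:<label>' for one transition.

    P(gamma) = 1 / (1 + sum alpha_X); P(CE on X) = alpha_X / (1 + sum alpha_X),
    the sum running over subshells whose conversion electron has positive
    energy (forbidden shells contribute nothing).
    """
    allowed: dict[str, float] = {}
    for lab, a in t.icc.items():
        if lab not in table:
            raise ValidationError(
                f"transition {t.id}: alpha given for unknown subshell {lab}"
            )
        if a > 0 and conversion_electron_energy(t, table[lab]) is not None:
            allowed[lab] = a
    denom = 1.0 + sum(allowed.values())
    out = {"gamma": 1.0 / denom}
    for lab, a in allowed.items():
        out[f"CE:{lab}"] = a / denom
    return out


# ---------------------------------------------------------------------------
# event sampling
# ---------------------------------------------------------------------------

def sample_decay_pathway(
    scheme: DecayScheme,
    tables: Mapping[int, AtomTable],
    rng: np.random.Generator,
) -> tuple[list[NuclearEmission], list[PrimaryVacancy]]:
    """Sample one nuclear decay: emissions plus primary atomic vacancies.

    One EC branch (at most) fires per decay according to the branch
    intensities and yields a single capture vacancy in the daughter element.
    Every EM transition then occurs as an independent Bernoulli draw of its
    per-decay intensity and resolves to a gamma ray or a conversion electron;
    each conversion electron leaves one vacancy.  Vacancies relax
    independently, each starting from a neutral atom of its element.
    """
    emissions: list[NuclearEmission] = []
    vacancies: list[PrimaryVacancy] = []

    if scheme.branches:
        dtable = tables[scheme.daughter_Z]
        u = rng.random()
        acc = 0.0
        for branch in scheme.branches:
            acc += branch.branch_intensity
            if u < acc:
                probs = ec_subshell_probabilities(branch, dtable)
                labels = list(probs)
                idx = _draw(rng, [probs[lab] for lab in labels])
                vacancies.append(
                    PrimaryVacancy(scheme.daughter_Z, labels[idx], "EC")
                )
                break

    for t in scheme.transitions:
        if rng.random() >= t.intensity:
            continue
        ctable = tables[scheme.converter_Z]
        channels = conversion_channel_probabilities(t, ctable)
        names = list(channels)
        idx = _draw(rng, [channels[n] for n in names])
        chosen = names[idx]
        if chosen == "gamma":
            emissions.append(NuclearEmission("gamma", t.id, t.energy))
        else:
            lab = chosen.split(":", 1)[1]
            e = conversion_electron_energy(t, ctable[lab])
            assert e is not None
            emissions.append(NuclearEmission("ce", t.id, e, shell=lab))
            vacancies.append(
                PrimaryVacancy(scheme.converter_Z, lab, f"IC:{t.id}")
            )
    return emissions, vacancies


def _draw(rng: np.random.Generator, weights: Sequence[float]) -> int:
    """Inverse-CDF draw of an index proportional to ``weights``."""
    total = float(sum(weights))
    u = rng.random() * total
    acc = 0.0
    for i, w in enumerate(weights):
        acc += w
        if u < acc:
            return i
    return len(weights) - 1  # guard against rounding at the top edge


# ---------------------------------------------------------------------------
# scheme I/O
# ---------------------------------------------------------------------------

_SCHEME_SECTIONS = ("parent", "ec_branches", "transitions")


def load_decay_scheme(path: str | Path) -> DecayScheme:
    """Read a decay scheme (TSV dialect or JSON mirror)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _scheme_from_obj(json.loads(path.read_text()))
    name = str(path)
    text = path.read_text()
    sections: dict[str, list[tuple[int, list[str]]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip()
            if current not in _SCHEME_SECTIONS:
                raise ParseError(f"{name}:{lineno}: unknown section [{current}]")
            sections.setdefault(current, [])
            continue
        if current is None:
            raise ParseError(f"{name}:{lineno}: data before any section header")
        sections[current].append((lineno, line.split("\t")))

    parent, halflife, mode = "", "", "IT"
    daughter_z: int | None = None
    converter_z: int | None = None
    for lineno, row in _rows_to_dicts(sections.get("parent", []), name, "parent"):
        parent = row.get("nuclide", "")
        halflife = row.get("halflife", "")
        mode = row.get("mode", "IT")
        if row.get("daughter_Z"):
            daughter_z = int(row["daughter_Z"])
        if row.get("converter_Z"):
            converter_z = int(row["converter_Z"])

    branches = []
    for lineno, row in _rows_to_dicts(
        sections.get("ec_branches", []), name, "ec_branches"
    ):
        try:
            ratios = {}
            if row.get("ratios"):
                for pair in row["ratios"].split(","):
                    k, _, v = pair.partition("=")
                    ratios[k.strip()] = float(v)
            branches.append(
                ECBranch(
                    q_plus=float(row["q_plus_keV"]),
                    level_energy=float(row["level_keV"]),
                    branch_intensity=float(row["intensity"]),
                    ratio_factors=ratios,
                )
            )
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{name}:{lineno}: [ec_branches] {exc}") from exc

    transitions = []
    for lineno, row in _rows_to_dicts(
        sections.get("transitions", []), name, "transitions"
    ):
        try:
            icc = {
                col[4:]: float(val)
                for col, val in row.items()
                if col.startswith("icc_") and val != ""
            }
            transitions.append(
                EMTransition(
                    id=row.get("id") or f"t{len(transitions) + 1}",
                    energy=float(row["energy_keV"]),
                    intensity=float(row["gamma_intensity"]),
                    icc=icc,
                    recoil_energy=float(row.get("recoil_keV") or 0.0),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{name}:{lineno}: [transitions] {exc}") from exc

    return DecayScheme(
        parent=parent,
        halflife=halflife,
        mode=mode,
        branches=tuple(branches),
        transitions=tuple(transitions),
        daughter_Z=daughter_z,
        converter_Z=converter_z,
    )


def _scheme_from_obj(obj: dict) -> DecayScheme:
    return DecayScheme(
        parent=obj.get("parent", ""),
        halflife=obj.get("halflife", ""),
        mode=obj.get("mode", "IT"),
        branches=tuple(
            ECBranch(
                q_plus=float(b["q_plus_keV"]),
                level_energy=float(b["level_keV"]),
                branch_intensity=float(b["intensity"]),
                ratio_factors=b.get("ratios", {}),
            )
            for b in obj.get("ec_branches", [])
        ),
        transitions=tuple(
            EMTransition(
                id=t.get("id") or f"t{i + 1}",
                energy=float(t["energy_keV"]),
                intensity=float(t["gamma_intensity"]),
                icc={k: float(v) for k, v in t.get("icc", {}).items()},
                recoil_energy=float(t.get("recoil_keV", 0.0)),
            )
            for i, t in enumerate(obj.get("transitions", []))
        ),
        daughter_Z=obj.get("daughter_Z"),
        converter_Z=obj.get("converter_Z"),
    )


def bundled_scheme(name: str) -> DecayScheme:
    """Load a packaged decay scheme ('tc99m' or 'in111')."""
    from importlib.resources import as_file, files

    res = files("augermc.data").joinpath(f"{name.lower()}.tsv")
    if not res.is_file():
        raise FileNotFoundError(f"no bundled decay scheme {name!r}")
    with as_file(res) as p:
        return load_decay_scheme(p)
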