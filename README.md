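# augermc

Monte Carlo simulation of the atomic radiations — Auger/Coster-Kronig
electrons and characteristic X-rays — emitted when a radionuclide decays by
electron capture (EC) or internal conversion (IC).

Auger emitters such as Tc-99m and In-111 are of interest for targeted
radionuclide therapy: the dozens of low-energy electrons released while the
atom relaxes after a nuclear decay deposit their energy within nanometres,
on the scale of a DNA molecule.  Predicting their spectrum requires
following the *vacancy cascade*: the primary inner-shell hole left by EC or
IC is filled from an outer shell, either radiatively (an X-ray) or
non-radiatively (an Auger electron, which turns one hole into two), and the
new holes propagate outward until every vacancy sits in the valence shell
or no transition is energetically possible.

## Model

**Primary vacancy.**  Electron capture on subshell $X$ is possible when
$Q^+ - E_i - E_{BE,X} > 0$; relative subshell capture probabilities are
built from adjacent-shell ratio factors, each scaled by the squared
neutrino-energy ratio
$P_L/P_K = k_{LK}\,\bigl((\Delta E - E_{L_1})/(\Delta E - E_K)\bigr)^2$,
and normalized so $P_K + P_L + \dots = 1$.  An electromagnetic transition of
energy $E_{tr}$ converts on subshell $X$ with probability
$\alpha_X / (1 + \sum \alpha)$, where $\alpha_X = P_X/P_\gamma$ is the
internal conversion coefficient, and the conversion electron carries
$E_{CE,X} = E_{tr} - E_{BE,X} - E_{recoil}$ (the channel exists only if this
is positive).

**Cascade.**  At each step the deepest queued vacancy is relaxed: all
energetically allowed channels out of it are enumerated — radiative with
$E_{XY} = E_{BE,X} - E_{BE,Y}$, non-radiative with
$E_{XYZ} = E_{BE,X} - E_{BE,Y} - E^{Y}_{Z}$ — and one is drawn with the
tabulated single-vacancy rates (occupancy-scaled) as weights.  The ejected
electron's binding energy $E^{Y}_{Z}$ is evaluated either from neutral-atom
values or by the Z/Z+1 rule (neutral values of the next element).  Vacancies
reaching the valence shell persist; they are never neutralized from the
environment.  First-step yields obey the closed forms
$Y_{KY} = f_K\,\omega_K\,N_{KY}$ and
$Y_{KYZ} = f_K\,(1-\omega_K)\,N_{KYZ}$, with $\omega_K$ the fluorescence
yield — the package uses these as analytic cross-checks of the sampler.

An exhaustive probability-tree oracle (`enumerate_cascade_tree`) expands the
complete cascade tree of a small atom exactly, giving an independent
reference distribution the Monte Carlo must reproduce.

## Worked example

```python
import numpy as np
from augermc import (bundled_atom, bundled_scheme, EnergyModel,
                     conversion_electron_energy, make_toy_atom)
from augermc.cascade import enumerate_cascade_tree, run_cascade

# nuclear part with bundled reference binding energies
tc, _ = bundled_atom("Tc")
scheme = bundled_scheme("tc99m")
g2 = next(t for t in scheme.transitions if t.id == "g2")
print(f"CE-K energy of the 140.511 keV transition: "
      f"{conversion_electron_energy(g2, tc['K']):.3f} keV")

# cascade on a 5-subshell toy atom: Monte Carlo vs exact tree
table, rates = make_toy_atom(5, rate_seed=3)
model = EnergyModel("neutral", table)
tree = enumerate_cascade_tree(table, rates, "K", model)
print(f"exact Auger electrons per K vacancy: {tree.expected_counts()['auger']:.4f}")
rng = np.random.default_rng(42)
events = [run_cascade(table, rates, "K", rng, model) for _ in range(100_000)]
print(f"MC    Auger electrons per K vacancy: {sum(e.n_auger for e in events)/1e5:.4f}")
print(f"mean final charge: {sum(e.final_charge for e in events)/1e5:.4f}")
```

prints

```
CE-K energy of the 140.511 keV transition: 119.467 keV
exact Auger electrons per K vacancy: 1.4235
MC    Auger electrons per K vacancy: 1.4232
mean final charge: 2.4232
```

The conversion electron of Tc-99m's 140.511 keV transition leaves the atom
with the K binding energy (21.044 keV) removed.  On the toy atom the
sampled mean Auger multiplicity matches the exact tree expectation, and the
mean final charge exceeds it by exactly one — the primary ionization —
because each Auger emission adds one unit of charge.

A full run from the command line:

```bash
augermc make-fixture --subshells 5 --seed 3 --out toy.tsv
augermc simulate --config run.yaml --events 100000 --seed 1 --trace
```

which writes `summary.tsv` (per-class yields and mean energies),
`spectrum.tsv` (10 eV-binned spectra per radiation kind), `manifest.json`
(config hash, seed, versions) and optionally `trace.tsv` (one line per
emission, replayable).

## Class grammar

Auger classes follow the conventional grouping: `KLL`, `KLX`, `KXY` (and
`LMM`, `LMX`, `LXY`) where the trailing `X`/`Y` mean "any shell beyond the
named principal shell"; the Coster-Kronig prefix `CK` marks a final vacancy
sharing the initial vacancy's principal shell (`CK LLM`, `CK LLX`,
`CK MMX`, `CK NNX`), `Super CK NNN` all three subshells in one principal
shell, and M- and deeper-shell ordinary Auger transitions are pooled as
`MXY`, `NXY`.  X-ray classes are Kα1 (K←L3), Kα2 (K←L2), Kβ (K←M and
beyond) and the principal-shell letter for non-K lines.

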