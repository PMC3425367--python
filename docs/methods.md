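# Methods

## Scope and model

`augermc` simulates the atomic-radiation emission that follows a nuclear
decay, in three stages:

1. **Nuclear event.**  At most one electron-capture branch fires per decay
   (multinomial over branch intensities); each electromagnetic transition of
   the scheme occurs as an independent Bernoulli draw of its per-decay
   occurrence intensity and resolves to a gamma ray or a conversion electron
   on one subshell.  Level-scheme routing (which transition follows which)
   is *not* modelled: treating per-transition intensities as independent
   draws reproduces all marginal per-decay yields exactly, and only
   coincidence observables — which the package does not report — would see
   the difference.
2. **Primary vacancies.**  Each capture or conversion leaves one vacancy.
   EC vacancies belong to the daughter element, conversion vacancies to the
   converting element.  Every vacancy relaxes independently, starting from
   a neutral atom of its element: conversion is assumed to happen only
   after the atom has fully relaxed from any earlier vacancy (the rare
   short-lived-level exception where a second conversion precedes full
   relaxation is not modelled).
3. **Cascade.**  The deepest (largest binding energy) queued vacancy is
   processed first: physically, inner vacancies are the shortest-lived; the
   ordering also makes the exhaustive tree well-defined.  Channels are
   enumerated from the single-vacancy rate table, filtered for electron
   availability and positive emission energy, and sampled with
   rate × occupancy-factor weights.  A vacancy terminates on reaching a
   valence subshell, or is frozen when no channel remains; frozen vacancies
   are reported separately.  No environmental neutralization occurs during
   the cascade.

## Transition energies

The reference treatment would recompute binding energies for every ionic
configuration reached during the cascade.  `augermc` instead offers two
static, pluggable models:

* `neutral` — all energies from neutral-atom binding energies:
  X-ray `E = E_X − E_Y`, Auger `E = E_X − E_Y − E_Z`.
* `z_plus_one` (default for real elements) — the ejected Auger electron's
  binding energy is taken from the same subshell of the next element
  (Z/Z+1 rule), approximating the extra binding felt in the presence of the
  spectator vacancy.

Both are standard approximations; the choice shifts Auger energies by
O(100 eV) for medium-Z elements (Tc KL1L2: 15.208 keV neutral vs
15.034 keV Z/Z+1) and, near thresholds, can close channels that neutral
energies would leave open.  Channels with non-positive energy are treated
as non-existent, and the remaining weights renormalize implicitly through
weighted sampling; no rate is redistributed to any specific channel.

## Occupancy scaling

Tabulated single-vacancy rates assume neutral occupancies.  During a
cascade the engine scales radiative rates by `n_Y / n_Y0` and Auger rates
by `(n_Y/n_Y0)·(n_Z/n_Z0)` — with `(n_Y−1)/(n_Y0−1)` as the second factor
when Y = Z — a statistical-availability correction in the spirit of the
Krause-Carlson multiple-vacancy correction.  It can be switched off
(`occupancy_scaling: false`) for sensitivity checks, since published
pilot-type calculations do not always state whether such a correction was
applied.

## Electron capture ratios

Subshell capture probabilities are built as the unnormalized chain
{1, r_L, r_L·r_M, …} from adjacent-shell ratio factors
`kLK, kML, kNM, kON`, each multiplied by the squared ratio of neutrino
energies `((ΔE − E_outer)/(ΔE − E_inner))²`, then normalized — algebraically
identical to the nested closed form, and checked in the tests against a
direct-normalization oracle.  Factors not supplied default to zero (the
chain stops).  When only principal-shell factors are given, all capture is
assigned to the s-subshells (K, L1, M1, …), where it overwhelmingly occurs
for allowed transitions; explicit `w_<label>` weights in the scheme file
add other subshells.  Energetically forbidden shells get probability zero;
if no shell is allowed the branch is an error.

## Bundled data

* **Atomic tables** (`tc.tsv`, `ru.tsv`, `cd.tsv`, `in.tsv`): neutral-atom
  binding energies transcribed from the standard X-ray Data Booklet /
  Bearden-Burr compilation for K through the N shell; outermost subshells
  not tabulated there (N4/N5 for Tc/Ru, O shells) carry nominal few-eV
  values, noted in each file header.  Two literature-degenerate pairs were
  nudged by 0.1 eV to keep binding energies strictly decreasing.  These
  tables carry **no transition rates**: single-vacancy rate libraries
  (EADL-derived) must be converted and supplied separately; with empty rate
  sections every vacancy freezes immediately, so the nuclear stage still
  runs and reports exact per-decay nuclear yields.
* **Decay schemes** (`tc99m.tsv`, `in111.tsv`): synthetic reconstructions.
  Occurrence intensities and principal-shell conversion coefficients are
  derived from evaluated per-decay emission intensities; the subshell
  splits of each principal-shell coefficient are chosen so the evaluated
  principal-shell mean conversion-electron energies are reproduced.  The
  In-111 capture-ratio factors (kLK = 0.095, kML = 0.20, kNM = 0.22,
  kON = 0.08) are adopted at the magnitudes of the standard capture-ratio
  compilations and give 97.7 % of primary EC vacancies on K + L1.  These
  files are inputs, not evaluations: they are flagged "synthetic
  reconstruction" in their headers.

## Toy atoms and what the tests show

`make_toy_atom(n, …, rate_seed)` builds a 1-10-subshell atom with realistic
labels/capacities, strictly decreasing binding energies (default geometric)
and reproducible pseudo-random rates on every well-formed outward
transition.  The defaults give cascades of a handful of steps with exactly
enumerable outcome trees (5-3000 outcomes), which is the regime where the
Monte Carlo can be validated *exactly*: the acceptance tests compare
sampled outcome frequencies at N = 10^5 against the tree probabilities at
4 binomial σ per outcome, pooling outcomes with expected count < 25 so the
normal approximation holds.

Toy atoms emulate the combinatorial structure of a relaxation cascade —
competing radiative/non-radiative channels, Coster-Kronig-like intra-shell
transitions, occupancy depletion, valence termination.  They do not emulate
real rate magnitudes, fluorescence-yield systematics with Z, or realistic
binding-energy spacings; passing the MC/oracle tests therefore validates
the *engine* (enumeration, weighting, sampling, bookkeeping, termination),
not the physical accuracy of any particular element's data, which is
carried entirely by the input tables.

## Numerical choices

* Energies are stored in eV internally (spanning ~2 eV to 6 MeV without
  precision loss); reports and tables print keV to 4 decimals.
* Channel selection is inverse-CDF on cumulative weights from a seeded
  64-bit generator (numpy PCG64); a top-edge guard returns the last channel
  if rounding pushes the draw past the total.
* Per-event substreams are `default_rng([seed, event_index])`, so any event
  is reproducible independently of execution order; identical
  (config, seed) runs produce byte-identical output files.
* Step bookkeeping: a transition filling a vacancy created at step s is
  recorded at step s + 1; primary vacancies are step 0.  Vacancy-abundance
  censuses count vacancies existing after all transitions of a given step.
* Histogram bins are half-open, lower-edge-inclusive `[k·w, (k+1)·w)` with
  w = 10 eV by default.
* Summary mean energies are intensity-weighted, including the per-kind
  totals block.
* The tree oracle refuses (rather than truncates) beyond a configurable
  node budget, defaulting to 2·10^5 nodes.

## Problem sizes

The bundled acceptance computation uses 2·10^5 decays per isotope for the
nuclear-radiation yields (binomial σ ≲ 7·10^-4 on the reported
probabilities) and 10^5 cascades for the toy-atom cross-check; the exact
tree provides the zero-variance reference.  These sizes put every reported
Monte Carlo value within a fraction of a percent of its expectation while
keeping a full reproduction under a minute on one core.

## Known limitations

* No shakeup/shakeoff, no Bremsstrahlung (inner or outer), no β spectra,
  no chemical/solid-state/molecular effects, no dosimetry or LET.
* Static energy models cannot reproduce satellite-line structure (the same
  transition class at configuration-dependent energies); each class appears
  at one energy per model.
* EC branch and EM transition draws are independent per decay; coincidence
  or cascade-correlation observables are out of scope.
* Real-isotope Auger yields require an external single-vacancy rate
  library; the package deliberately refuses to invent rates for real
  elements.
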