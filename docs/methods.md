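# Methods

## Carbon-environment model

Every carbon atom of an in-chain residue (free amino acid minus one water)
is assigned to exactly one of ten environments distinguishable by C1s
chemical shift: C=C, CHx, C=C–N, C–C(O)O, C–OH, C–N, C=N, N–C=O, C–S, COOH.
The default assignment policy (full table in
`src/xpsprot/data/residue_chemistry.tsv`, auditable without reading code):

- backbone Cα → C–N; backbone carbonyl → the amide N–C=O;
- pure hydrocarbon side-chain carbons → CHx;
- Ser/Thr Cβ and the Tyr ring carbon bearing the hydroxyl → C–OH;
- Cys Cβ and Met Cγ/Cε → C–S;
- Lys Cε, Pro Cδ and Arg Cδ → C–N; Arg Cζ (guanidinium) and His Cε1 → C=N;
- His Cγ/Cδ2 and the Trp ring carbons bonded to the indole nitrogen →
  C=C–N; remaining aromatic carbons with only C/H neighbours → C=C;
- Asp Cβ / Glu Cγ (alpha to the carboxyl) → C–C(O)O; the carboxyl carbon
  itself → COOH; Asn/Gln side-chain amide carbon → N–C=O.

Two invariants hold for all 20 residues: the environment counts sum to the
carbon count, and each residue has at least one nitrogen. Protonation
states are not distinguished (COOH covers COO⁻), and non-standard residues,
PTMs and disulfide bookkeeping are out of scope (Cys is a free thiol
carbon). The policy is pluggable: load an alternative TSV with
`ChemistryTable.from_tsv` and pass it to the composition functions.

**Termini.** Per chain, the C-terminal carbonyl is counted as COOH instead
of a backbone amide and the elements gain one water (the N-terminal amine
adds no carbon). The correction is negligible for proteins of 100+ residues
but makes single amino acids and short peptides exact; it can be switched
off (`include_termini=False`), in which case concatenation of sequences is
exactly count-additive.

## Spectrum simulation

A composition profile's carbon fractions weight unit-area line shapes at
per-environment binding energies; the sum is max-normalized. Defaults:

| environment | BE (eV) | | environment | BE (eV) |
|---|---|---|---|---|
| C=C | 284.7 | | C–N | 286.2 |
| CHx | 285.0 | | C–OH / C–O | 286.5 |
| C–S | 285.4 | | C=N | 286.9 |
| C–C(O)O | 285.5 | | N–C=O | 288.1 |
| C=C–N | 285.9 | | COOH / ester | 289.0 |

FWHM is 1.1 eV for every component, the value standard in polymer/protein
C1s fitting, and the default line shape is pure Gaussian (a
Gaussian–Lorentzian sum with configurable Lorentzian fraction is available
but used nowhere in validation). All of this is overridable via a JSON
component table. The default grid is 280–294 eV at 0.05 eV, ascending;
simulation refuses a grid that does not span every active component by ±3
FWHM. Component weighting is by carbon fraction only — no photoelectron
attenuation-depth correction, no relative sensitivity factors, no
instrument broadening beyond the component FWHM.

Substrate presets: the stoichiometric poly(ε-caprolactone) repeat
−(CH₂)₅−C(O)O− (3/6 CHx, 1/6 C–C(O)O, 1/6 ester-oxygen CH₂ carried in the
C–OH slot at 286.5 eV, 1/6 ester carbon in the COOH slot at 289.0 eV), and
a carboxyl-plasma-polymer preset (CHx 0.55, C–O 0.20, ketone C=O 0.10 in
the N–C=O slot overridden to 287.4 eV, acid/ester 0.15). The plasma-polymer
*weights* are package constants — a plasma polymer has no stoichiometry to
derive them from — chosen once as a plausible carboxyl-rich mix; only the
component positions follow fitted substrate models. Because two component
centres sit 0.5 eV apart, the PCL preset's global maximum falls ~0.1 eV
above the aliphatic 285.0 eV centre; tests assert the apex to that
resolution rather than pretending the components are isolated.

## Spectral preparation

**Shirley background.** B(E) is anchored at the window-endpoint levels
(mean intensity within ±0.2 eV of each edge, to damp noise) and iterated:
B ← I_lo + (I_hi − I_lo)·A(E)/A_tot with A(E) the running integral of
(signal − background) from the low-BE edge. Defaults: tol 1e-6 (max
relative change of B per iteration, scaled by the peak intensity), max 50
iterations; non-convergence is flagged on the result, never silent.
Negative corrected intensities are kept and counted
(`negative_fraction`) so later max-normalization is unbiased; clipping is
an explicit option. The validation oracle is a forward-constructed
spectrum: peak + exact Shirley step (h·CDF of the peak), whose background
the iteration must recover within 0.5% RMS of the peak height.

**Calibration.** The main-peak apex is located by a parabola through the
grid maximum and its two neighbours and the grid is rigidly shifted to put
it at 285.0 eV (aliphatic carbon). Flat spectra and edge apexes are
rejected. Idempotence and ±0.3 eV round-trips hold within 0.005 eV.

**Resampling** is linear interpolation, with extrapolation refused.
Processing steps append to the spectrum's provenance in order.

## Coverage fit

Model: S_model(E;x) = (1−x)·S_substrate + x·S_protein, both inputs
max-normalized on a common grid. "Best convergence" is operationalized as
minimum RMSE (R², maximum absolute deviation reported alongside; objective
pluggable: rmse, sse, max_abs). The mixed model is re-max-normalized before
comparison, consistent with all compared spectra being normalized to their
maxima; this is switchable (`renormalize_model=False`). The solver scans x
over [0, 1] at step 0.0025 — the objective is 1-D and cheap, and the full
curve is itself the weak-identifiability diagnostic — then refines inside
the ±2-step bracket with SciPy's bounded scalar minimizer. A fit whose
objective is within 1% of its dynamic range of the minimum over ≥20% of the
scan is flagged `weakly_identified` (an absolute floor of 1e-12 catches the
identical-components degenerate case). x is reported both as a fraction and
in integer-percent presentation; it is strictly the spectral mixing
fraction — no claim about geometric coverage versus analyzed-volume
fraction is made, since C1s and N1s escape depths differ.

**Presentation rounding.** Atomic ratios print at two decimals (round half
to even). Percentages truncate toward zero (28.64 → "28%", 44.4 → "44%"),
matching how the published worked examples present these quantities;
the unrounded value is always returned alongside.

## Synthetic data: what it does and does not establish

`generate_measurement` composes: simulate substrate and protein → mix at a
known x → scale to a stated peak count level → add a Shirley-like step
background (height a stated fraction of the peak level, shape the running
integral of the signal) → Poisson counting noise (the physical model for
pulse-counting detectors; Gaussian optional) → rigid BE offset. Every knob
lands in a truth sidecar, and a seed is mandatory whenever noise is active.
Defaults are the validation conditions used throughout: 10⁴ peak counts,
x in the 0.05–0.15 range typical of sparse protein overlayers.

A green recovery test establishes that the estimator inverts *this stated
world*: the same component model generates and fits the data, so model
mismatch — proteins whose spectra deviate from the sequence-derived
simulation, substrate changes induced by protein binding (e.g. excess
286.5 eV carbon, which the degradation test shows raises the attainable
minimum objective), attenuation-depth weighting — is exactly what it does
not probe. No synthetic output is ever compared against a published figure.

**Sequence fixtures are synthetic stand-ins.** The build environment has no
access to sequence databases, so the packaged FASTA records for
apolipoprotein A1, the ZZ–angiogenin chimera (8-residue leader + two
IgG-binding Z domains + angiogenin region) and fibronectin are constructed:
realistic residue compositions at the right lengths, shuffled with fixed
seeds, labelled `synthetic` in filename and header. The fibronectin
stand-in's composition was additionally designed — using independent
textbook stoichiometry, not this package's table — to carry the published
whole-protein C/N of 3.58 for human fibronectin; the corresponding
acceptance test therefore validates the chemistry table and aggregation
path against that independent construction, not the provenance of any
GenBank entry. Real analyses must supply real sequences.

## Known limitations

- Two components only; no multi-protein mixtures, and component
  BEs/FWHMs are never fitted to data (classical peak fitting is a fixture
  definition here, not a solver).
- Shirley only (no Tougaard/linear backgrounds); single-peak rigid-shift
  charge correction only.
- Survey quantification is consumed, not computed: atomic percentages are
  inputs.
- The elemental estimator and the mixture fit answer subtly different
  questions (different probing depths); their disagreement is informative,
  not an error.
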