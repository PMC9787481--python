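# Methods

This note records the models, defaults and design choices behind the
package, and what the synthetic fixtures do and do not demonstrate.

## Mass conventions

All masses come from a fixed monoisotopic table embedded in
`crossmet.formulas` (C 12 exactly, H 1.0078250319, N 14.0030740052,
O 15.9949146221, S 31.97207069 Da), so no result depends on another
library's constants. Two [M+H]⁺ conventions are supported:

* `hydrogen-atom` (default): neutral mass + 1.0078250 Da. Screening
  software commonly reports protonated masses without subtracting the
  electron mass; under this convention the parent C₁₃H₁₀N₂O gives
  m/z 211.0871.
* `proton`: neutral mass + 1.0072765 Da (physically exact; gives 211.0866).

Display rounding is 3 dp for shifts and 4 dp for m/z; internal arithmetic is
full double precision. Note that published tables sometimes *truncate*
rather than round the last digit (CH₂ = 14.0157 Da may print as "14.015",
m/z 307.0389 as "307.038"); comparisons against printed values should allow
±0.0015 at 3-dp precision.

## Rule engine

Structure handling is deliberately at the functional-group-count level, not
atom-mapped products: precursor mass shifts distinguish elemental formulas,
never regiochemistry, so distinct aromatic hydroxylation sites collapse into
one formula-level candidate carrying an isomer-multiplicity attribute (the
number of available sites). The parent profile is derived from SMILES with
RDKit SMARTS counts (phenolic OH, aromatic CH, pyridine-type N, secondary
NH, catechol flag). Rules consume and produce groups as they fire
(hydroxylation converts an aromatic CH into a new phenolic OH; O-conjugation
consumes one), which is what blocks chemically impossible chains such as a
triple O-conjugation of a mono-phenol. External predictor probability
scores are not modelled; candidates are ordered by m/z and chain length.
Oxidative-cleavage rules (quinone formation, ring cleavage) exist but are
disabled by default — their products are unconfirmable mass losses and the
source evidence for them is weak.

`max_steps` defaults to 2 (covers every singly- and doubly-transformed
candidate); depth 4 is needed for the doubly-hydroxylated di-glucuronide
C₂₅H₂₆N₂O₁₅.

## Synthetic study generator

The generator emulates the two matrices of a cross-sectional metabolism
study: HepaRG-style supernatant at H0/H8/H24/H48 and mouse plasma at H1/H3.
Its truth set is the integrated evidence table of the sibiriline study:
parent at m/z 211.087 (RT 5.8 min) plus 14 metabolites with their chains,
retention times and matrix presence. Precursor m/z are computed from the
chains' elemental deltas, keeping the simulated physics self-consistent:
at zero noise the downstream stages must recover every chain exactly, and
13 of 14 theoretical m/z agree with the printed table values to ≤ 0.0015 Da.
The one exception is the M8 row (2 × hydroxylation + 2 × glucuronidation):
its chain-consistent m/z is 595.141 (shift +384.054) whereas the source
table prints 595.183 / +384.096, which is not reconcilable with the stated
chain; the generator follows the chemistry and the discrepancy is documented
rather than patched.

Fragmentation model: conjugates lose their conjugate moiety as a neutral, so
each metabolite inherits the parent's 8-fragment set unshifted (including
the MRM-confirmed ions near 118.0 and 183.1) plus three chain-shifted
fragments. Each metabolite additionally carries a deterministic
fragmentation signature — a smooth per-metabolite attenuation of the
inherited intensities and a rotating choice of shifted-fragment sources —
because conjugation genuinely alters fragmentation efficiency; a generator
without it would make every metabolite pair a perfect spectral match, which
no instrument produces (and which would, artifactually, crowd the parent out
of every node's top-10 neighbour list).

Noise defaults: m/z jitter SD 0.005 Da (below the 0.02 Da tolerance),
intensity CV 0.2, 5 noise peaks per spectrum, 20 decoy features per matrix —
enough to stress tolerance handling without destroying edges. Decoy
precursors are rejection-sampled at least 0.05 Da away from the parent plus
any library delta, so a decoy can never be mass-shift annotated regardless
of seed. One integer seed drives a single RNG stream in documented order.
Intensity kinetics are free parameters constrained by the study's
qualitative statements: in vitro metabolites appear after H0, peak at H24
and decline by H48; in vivo all metabolites are higher at H1 than H3 except
one designated hydroxylated-glucuronide node, which rises.

What passing on these fixtures does **not** show: robustness to
chromatographic co-elution, isotope-pattern interference, in-source
fragmentation, matrix effects on ionization, or real spectral-library
identification of the parent (the parent node is located by expected m/z).

## Molecular networking

The modified cosine scores √-intensity, L2-normalized peaks with a greedy
one-to-one assignment over pairs matched directly or offset by the precursor
difference (|Δ| ≤ 0.02 Da). Greedy assignment is the field's standard; the
test suite verifies it equals the exact maximum-weight assignment (via
`scipy.optimize.linear_sum_assignment`) on toy spectra and stays within 5%
of it on random ≤ 8-peak spectra, and that raw-intensity mode agrees with
`matchms.ModifiedCosine` to 1e-9. Whether the original GNPS runs scored
plain or shifted cosine is not documented; shifted is the default because
the observed networks link precursors differing by large conjugate masses,
and `score_mode="unshifted"` is provided for comparison.

Edge construction order follows the stated rules: cosine > 0.70 and ≥ 6
matched ions first, then the mutual top-10 pruning (rank by score
descending, |shift| ascending, node id ascending — deterministic for fixed
input). Minimum cluster size 1 retains singletons.

## Annotation

The delta library is deduplicated by delta formula: O- vs N-glucuronidation
(and aromatic hydroxylation vs N-oxidation) are indistinguishable by mass
shift and collapse onto generic labels. `delta_tol` defaults to 0.01 Da,
tighter than the 0.02 Da fragment tolerance, because precursor masses are
high-resolution and library deltas are exact. Precursor shifts telescope
along any network path, so matching the direct node-to-parent shift is
equivalent to accumulating per-edge shifts; ties between library entries are
broken by smaller |mass error|, then shorter chain. The parent node is
supplied by the user (or located as the nearest precursor to an expected
m/z), standing in for spectral-library identification.

## Evidence integration

Cross-matrix merging requires equal chains, m/z within 0.0015 Da (3-dp print
precision) and RT within 0.1 min; mismatched RTs stay separate isomer rows.
M-numbers order (chain, formula) groups by ascending m/z; letters follow
ascending RT within a group; singletons get no letter. The parent appears in
the report but is excluded from all counts, as are any predictor-only
(rejected) rows. Counting isomers separately, the zero-noise fixture yields
14 metabolites, 8 in vivo and 12 in vitro, 6 of them pure phase II chains.

## Pharmacokinetics

The scenario mirrors the mouse study: 5 mg/kg IP, sampling at 15, 30, 60,
120, 180, 240 min, terminal t½ 21 min (ke = ln2/21 ≈ 0.0330 /min), V/F
3247 mL/kg. The absorption rate is set to ka = 2.0 /min (absorption
half-life ≈ 0.35 min), the rapid-IP-absorption regime consistent with the
observed peak within 15 min; by the first sample absorption is complete and
the profile is bolus-like. How the original half-life and volume were
computed (compartmental vs NCA) is not documented; this package takes the
NCA interpretation and treats the reported volume as Vz/F.

NCA choices: the terminal window is the suffix of ≥ 3 points strictly after
Tmax maximizing adjusted R² (ties favour more points); AUC uses
linear-up/log-down trapezoids (pure linear via config); when the first
sample is later than t = 0, C(0) is back-extrapolated from the terminal fit
(standard bolus-like handling — with a 15-min first sample about a third of
the AUC lies before it, and assuming C(0) = 0 would bias Vz/F high by
~30%; back-extrapolation is exact in the ka ≫ ke regime). With visible
absorption (back-extrapolated C0 below the first concentration) the
extrapolation is rejected and C(0) = 0 is used. Concentrations are µg/mL,
AUC µg·min/mL, so Vz/F = 1000·dose/(λz·AUC∞) lands in mL/kg.

Under these choices, noiseless recovery on the 6-point schedule gives
t½ = 21.0 min and Vz/F = 3193 mL/kg (−1.7%, the residual absorption-phase
bias); the median over 200 replicates at 15% lognormal noise stays within
a few percent of both generating values.

## Problem sizes

Default runs use 62 features across both matrices (1 parent + 12/8
metabolites + 20 decoys per matrix), 200 PK replicates, and depth-4 delta
libraries; the full test suite and the acceptance script each complete in
well under a minute of CPU.
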