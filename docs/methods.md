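# Methods

This note documents the models, defaults and numerical choices behind
each stage of the pipeline, what the synthetic generators emulate, and
the limits of what the tests demonstrate.

## Phosphosite representation

Sites carry 1-based positions (the field's "pS455" convention; all
file I/O is 1-based, internal array indexing 0-based) and a sequence
window of length `2h+1` centred on the phosphoacceptor, default
halfwidth `h = 7` so positions −7…+7 are visible — wide enough for the
−3 basic / +4/+5 hydrophobic / +2…+7 acidic substrate context.
Windows are padded with `'_'` beyond the termini; pads never enter
frequency counts.  Site tables are a minimal TSV dialect (required
columns `protein_id`, `position`, `residue`; `NA` for missing
numbers); full search-engine output parsing is out of scope.  A
localization-probability column is carried but no cutoff is applied by
default; callers who want a class-I style filter can subset on it.

## SILAC dephosphorylation score

The score of a site is the geometric mean of the four control/active
ratios; on the log2 scale the complete case is exactly
`0.25·Σ log2 rᵢ`.  Ratios are stored internally as control over
active-cofactor cells, so high scores mean holoenzyme-dependent
dephosphorylation; a design declared in the opposite orientation is
inverted once at design-mapping time.  Missing-data policy:

* `strict` (default) — all four ratios required, mirroring the
  complete-case formula; anything less is flagged unscored.
* `balanced` — mean of the available log-ratios, requiring ≥ 2 ratios
  with at least one per labelling orientation.  Labelling swaps leave
  the complete-case score unchanged, so this constraint is the minimal
  guard against label-bias artifacts in sparse tables.

Candidate selection uses a strict `score > threshold` inequality
(default 2.5) with descending-score order and lexicographic site-id
tie-breaks for determinism.

## Annotation enrichment

Terms annotate proteins while scores attach to sites, so site scores
are aggregated per protein first — default `max` (a protein is a
substrate if any site is), `mean` available.  Each term with ≥ 5
scored members is tested against all non-member proteins with a
two-sided Mann–Whitney test; `U` counts (member, other) pairs with
member greater, ties as 1/2, and the reported enrichment score is the
rank-biserial `s = 2U/(n1·n2) − 1 ∈ [−1, 1]`.  For `n1·n2 ≤ 400` the
p-value is exact: the permutation null of `U` is computed by a dynamic
program over the distinct pooled values (count-weighted over tie
groups), which equals literal enumeration of all `C(N, n1)`
assignments but in polynomial time; above that, the normal
approximation with tie and continuity correction.  FDR control is
Benjamini–Hochberg step-up (statsmodels), applied across all tested
terms; the reported view uses strict `mean_score > 1` and `q < 0.02`
cuts.  Annotations are flat term → protein sets; no ontology-graph
propagation.

## Motif model

The recognition pattern is S/T-x(2–3)-ϕ-L with ϕ = {L, I, V, M, F}:
leucine/isoleucine/valine dominate the observed +4/+5 enrichment, and
methionine/phenylalanine complete the standard aliphatic/aromatic
hydrophobic class; tryptophan is excluded because substitution-array
data for it is uninterpretable (tryptophan substitutions raise binding
nonspecifically).  The distal position requires leucine by default
("leucine preferred at the distal position"); a relaxed variant
accepts any ϕ there, for exploring stretched substrates whose distal
preference is less certain.  A spacer of 3 places ϕ at +4 and L at +5
(canonical register); spacer 2 gives +3/+4 (stretched).  When both
registers match at one position the canonical one is primary and the
alternative spacer is recorded.  Frequency matrices count non-pad
residues per position and normalise per position; the contrast matrix
is `log2` of pseudocount-adjusted frequencies with the pseudocount
(default 0.5) added on the count scale.  Note that with very
different foreground/background sizes, residues absent from the
smaller set acquire inflated adjusted frequencies; rank contrasts over
observed cells (see `examples/03_motif_analysis.py`).

## Single-timepoint kinetics

Product after a fixed incubation follows
`P = t·E·(kcat/KM)·C/(C/KM + 1)`, i.e. the Michaelis–Menten rate
multiplied by time with the substrate concentration treated as
constant over the window.  Substrate depletion is deliberately not
corrected — a documented caveat of the single-timepoint design, which
underestimates rates at low C where turnover is proportionally
largest.  Units: enzyme amounts are expressed in activity units
(1 U releases 15 µM phosphate in 15 min from 125 µM standard
peptide), so kcat is per unit rather than per molar enzyme.  The
specificity constant is reported with the conventional printed unit
string `µM·min⁻¹·U⁻¹`; dimensionally it is the low-C limit of
`P/(t·E·C)`, i.e. min⁻¹·U⁻¹ per µM substrate — both readings are
included in CLI JSON output rather than silently choosing one.

Fitting exploits that the model is linear in `kcat/KM` at fixed
`KM`: the profile SSE over a 400-point log grid of KM (from
min(C)/100 to 1000·max(C)) is minimised and refined by bounded scalar
optimisation, giving a deterministic fit with no random restarts.
The same profile yields a 95% likelihood interval for KM via the
F(1, n−2) SSE threshold (with a tiny absolute floor, 1e−12·ΣP², so
noise-free fits still produce an interval).  `km_reliable` is False
when fitted KM exceeds the highest assayed concentration, when the
interval spans more than one decade, or when it is open at either
grid end — reproducing the convention of starring K_M values the
assay cannot determine.  `kcat/KM` remains well determined in that
linear regime.  The dilution design defaults to 16 steps of 1.5-fold
from 1 mM with a 40/50 mix factor (40 µl substrate + 10 µl enzyme),
top in-reaction concentration 800 µM.  The pNPP normalisation assay
reuses the same machinery as a plain hyperbola (t = E = 1), averaging
duplicate concentrations first.

## BLI binding model

1:1 Langmuir binding: association
`R(t) = Req·(1 − e^−(kon·C+koff)·t)` with `Req = Rmax·C/(C + Kd)`,
dissociation mono-exponential with rate `koff`; `Kd = koff/kon`.
Mass transport and heterogeneous-ligand effects are not modelled.
Steady-state fitting is least squares on the isotherm in log(Kd),
log(Rmax) coordinates; when traces rather than equilibrium values are
supplied, Req is taken as the mean of the last 5% of the association
phase.  Degenerate flat responses return Rmax with Kd flagged
unidentifiable; a concentration span under 4-fold warns.  The global
kinetic fit refines (kon, koff, Rmax) jointly across concentrations
from a dissociation-phase log-linear koff and a steady-state
initialisation.

Binding fixtures store each peptide construct's Kd as a fold change
versus the wild-type Kd of 10.4 nM (I520A 4×, F522A 650×, W542A 40×,
R544A 3×, LFL-3A 900×, L574D 17×, F577A 16×, H578A 7×; R536P 300×,
Y534A 10× and HHH-A 50× are stored at their reported lower bounds
with `bound_flag=True` and excluded from equality-style checks).
Only equilibrium constants are reported for these constructs, so
fixture kinetics use the synthetic convention kon = 1e5 M⁻¹s⁻¹ (a
typical peptide–protein on-rate) with koff = kon·Kd; this choice
cancels out of every Kd and fold-change result.  Fixture simulations
use 8 log-spaced concentrations spanning Kd/20…20·Kd — bracketing
each construct's own Kd, as needed for weak mutants — with the
association window auto-set to ~12 dissociation time constants so the
slowest trace reaches equilibrium to ≲1e−4 of Req.

## TMT differential analysis

"Z-score across columns" is implemented as per-sample (column)
standardisation (mean 0, sd 1, ddof 1, missing values ignored and
preserved) — the interpretation that makes deltas comparable across
samples; per-site standardisation would destroy the treatment
contrast.  (DMSO − CD) deltas are formed within matched blocks
(replicate × region × MS mode) and pooled across region and MS mode,
so the default design yields 8 delta values per genotype per site.
The genotype comparison is Welch's unequal-variance t-test (the
pooled-variance test is available via a flag); sites with fewer than
two finite deltas in either group are reported untestable, never
imputed.  Hits use `p < alpha` (default 0.05, no multiplicity
correction by default — `bh_fdr` can be applied by the caller) and
the one-sided sign convention `diff_z > 0`, since cofactor-dependent
events are CD-induced dephosphorylations present in wild-type only; a
signless analysis just drops that filter.

## Synthetic data

Generators are pure functions of (parameters, seed); a top-level seed
fans out to per-generator streams by CRC32 hashing of the generator
name, so adding a generator never perturbs the others.  Defaults
define the simulated study conditions:

* proteome: 100 uniform-random proteins of length 60, 20 substrate
  proteins with one planted S-centred consensus window each (basic
  −3…−1, acidic +1…+3 and +6…+8, L at +4/+5) — every planted site
  matches the default motif pattern by construction;
* SILAC: 500 sites, substrate ratios centred at 2³ = 8-fold, lognormal
  noise sd 0.3 (log2 scale) per ratio — multiplicative noise matching
  the ratio scale;
* TMT: 2000 sites, effect 1.5 Z-units applied to WT/CD channels of
  planted sites, Gaussian noise sd 0.5 on the log-intensity scale,
  standard-normal per-site baselines, design 2 genotypes × DMSO/CD ×
  2 replicates × 2 regions × MS2/MS3;
* plates: the default dilution series with a linear standard curve
  (slope 0.01 A620/µM, intercept 0.05), Gaussian absorbance noise;
* sensorgrams: the fixture table above, noise-free by default.

What the generators do **not** emulate: peptide-level multiplicity
and roll-up, missing-not-at-random quantification, ratio compression,
retention-time or reporter-ion interference structure, batch effects,
or correlated sites within proteins.  Passing recovery tests
therefore demonstrates correctness of the statistical machinery under
idealised noise, not performance on real instrument output.

## Problem sizes and determinism

The test suite runs end-to-end on the generator defaults above
(500-site SILAC tables, 2000-site TMT matrices, 16-point plates,
8-concentration isotherms, 10,000-site null calibrations), sizes at
which every stage's behaviour is already resolved.  All stochastic
tests use fixed seeds; all fits are deterministic given their inputs
(profile-grid optimisation in kinetics, analytic initialisation in
BLI), so repeated runs are bit-reproducible.

## Known limitations

* The single-timepoint MM fit inherits the design's blindness to
  substrate depletion and to K_M above the assayed range (flagged,
  not fixed).
* Exact Mann–Whitney p-values are computed only up to `n1·n2 = 400`;
  beyond that the normal approximation's accuracy is that of the
  standard tie-corrected z-test.
* The steady-state Req extraction assumes the association phase was
  long enough to equilibrate; sensorgrams truncated early will bias
  Kd upward.
* Site identifiers must be reconciled by the caller (an explicit id
  mapping) when intersecting experiments that name sites differently.
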