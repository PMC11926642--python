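# Methods

This note documents the models, rules and numerical choices behind
`immunoprofile`, in the order data flows through the pipeline.

## Antibody success labels

Each antibody carries an outcome per technology (WB, IHC, ICC) drawn from
{`uncertain`, `approved`, `supported`, `enhanced`, `untested`}. A tested
technology *passes* when its outcome is approved/supported/enhanced and
*fails* when it is uncertain. The label is

* **successful** — every tested technology passed and ≥ 2 were tested;
* **unsuccessful** — every tested technology failed and ≥ 2 were tested;
* **unclassified** — mixed results, or fewer than two technologies tested.

Antibodies tested in exactly one technology are unclassified: a single
result is treated as insufficient evidence either way. The three labels
partition all 125 outcome combinations (asserted exhaustively in the
tests).

WB specificity compares observed band sizes (kDa) to the weight predicted
from the full protein sequence using average (not monoisotopic) residue
masses plus one water (18.0153 Da). A band is in-range iff it lies within
±20% of the prediction, boundaries inclusive ("more than ±20%" defines
out-of-range strictly). No bands → `no_binding`; any out-of-range band →
`unspecific`, whether or not an in-range band is also present; otherwise
`specific`. A blot with several in-range bands is classed specific by
default; `single_band_strict=True` treats it as unspecific instead — the
two readings of "a single band at the predicted size" differ only in this
corner, and the flag preserves both.

## Structural features

**Secondary structure.** Backbone hydrogen bonds are assigned with the
Kabsch–Sander electrostatic model: E = 0.084·332·(1/r(ON) + 1/r(CH) −
1/r(OH) − 1/r(CN)) kcal/mol, bond accepted below −0.5 kcal/mol. Amide
hydrogens are placed geometrically (1.01 Å from N, opposite the preceding
carbonyl) because predicted-structure PDB files carry no hydrogens;
prolines and chain starts donate nothing. Candidate partners are
prefiltered at 9 Å CA–CA. From the bond set: α-helix from pairs of
consecutive 4-turns; β-bridges (parallel and antiparallel patterns,
sequence separation ≥ 3); 3₁₀ and π helices from 3-/5-turn pairs where
nothing stronger claimed the residues. States collapse H/G/I → helix,
E/B → sheet, everything else → coil. Turn (T) and bend (S) states are not
tracked separately — they are coil in the 3-state scheme, which is all the
analysis consumes. On ideal constructs the labels agree with a reference
DSSP implementation (mdtraj's) to ≥ 95% on interior residues; chains of
fewer than 3 residues are all-coil with a warning.

**Solvent accessibility.** Shrake–Rupley with a 1.4 Å probe, Bondi
element radii (C 1.70, N 1.55, O 1.52, S 1.80 Å), heavy atoms only, and a
deterministic golden-spiral point set (default 960 points per atom;
quadrature error is well under the 5% checked against a 10,000-point
oracle). RSA divides a residue's SASA by a reference maximum for its
type. The shipped maxima are **self-consistent**: for each type X the
package builds Gly-X-Gly tripeptides over a grid of extended backbone
conformations and χ₁ rotamers and takes the maximal central-residue SASA,
computed with the same radii and geometry as the numerator
(`structure_features.reference_max_asa`, frozen into `constants.MAX_ASA`
at 3840 points). Published tables (e.g. the Tien et al. 2013 theoretical
set, shipped as `TIEN_MAX_ASA`) were derived with other radius sets and
conformational searches; mixing them with this package's SASA shifts all
RSA values down by ~10–20% and over-calls burial, so they are offered as
an option, not the default. RSA is not clipped at 1. **Buried** is the
strict threshold RSA < 0.07.

**Contacts.** Residue i's count is the number of residues j ≠ i with any
heavy-atom pair within 8 Å, inclusive. Sequence neighbours count
(`min_separation=1`), since no separation exclusion is part of the rule;
the parameter is exposed for sensitivity analysis. A KD-tree accelerates
the search but the result is bit-identical to the all-pairs definition
(asserted against a brute-force oracle).

## Immunogen windows

Immunogens are exact substrings of their protein; the first occurrence is
used and multiplicity warns (or errors in strict mode). Classifications:

* **position** — terminus iff start ≤ 25 or end ≥ L−24 ("at least partly
  within the first or last 25 residues"); else center.
* **disorder** — high iff min score ≥ 0.8; low iff max ≤ 0.2; else
  medium; windows with any missing score are `unavailable` and excluded
  from disorder-grouped analyses with a logged count.
* **majority secondary structure** — the most prevalent 3-state class;
  ties break coil → helix → sheet (coil is the modal class in this kind
  of data; the order is documented and configurable in one place).
* **TM relation** — `overlap` if any window residue lies in a TM range;
  `vicinity` if the protein has TM ranges but none intersect the window
  (no distance cap — the minimal reading of "in the vicinity"); `no_tm`
  otherwise. Overlap is monotone under window extension.
* **disulfide / PTM presence** — an annotated half-cystine or PTM site
  inside the window; bridges entirely outside the window do not count.

Aggregates over the window: buried-residue count, arithmetic mean of
per-residue contacts, and the number of maximal same-label
secondary-structure runs intersecting the window (a run clipped by the
window boundary still counts once; coil runs count — whether they should
is genuinely open, and counting all runs is the simpler, documented
choice).

## Cohort statistics

Grouped analyses run on records that pass the inclusion filters:
immunogen ≤ 50 residues, protein length 100–2000, label classified.
Success rates per group come with Pearson's chi-squared on the
group × outcome table, no Yates correction (exposed as a flag);
continuous aggregates use two-sided Mann–Whitney U — exact enumeration
for tie-free samples up to n = 20, otherwise the normal approximation
with tie correction. Significance is read at α = 0.05; the
disorder-by-position analysis reports three unadjusted tests (all /
terminus / center) as-is, with an optional Bonferroni flag as the only
multiplicity device.

Immunogen-length bins default to right-open edges
(19, 30, 50, 70, 90, 110, 203): the printed endpoints "<30" and "≥110"
with width-20 interior bins, configurable. Length-bin analyses run on the
pre-length-filter cohort, since the length effect is assessed before the
≤ 50 cut.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not the biophysics of real proteins:

* **Proteins** — lengths log-normal (median ≈ 450) clipped to 100–2000; a
  segment grammar fills the interior with helices (6–25), β-hairpins
  (strand 3–9 + 2-residue turn + strand), loops (4–30) and occasional
  long disordered linkers (20–60, 10% of segment draws), between two
  terminal coil tails (15–60). Each tail is disordered with probability
  0.5 — real termini are not uniformly disordered, and ordered tails are
  what makes the low-disorder/terminus group non-empty. Disorder scores
  are Beta draws per region: disordered tails/linkers Beta(40, 2),
  structured cores Beta(1.5, 30), ordinary loops Beta(2, 20). Burial and
  contact counts are Bernoulli/Poisson with per-class parameters ordered
  sheet > helix > coil > disordered. TM incidence 0.3 (a 15–25-residue
  span inside a helix), disulfide incidence 0.10 (the pair's positions
  become cysteines), PTM sites Poisson(3) per protein.
* **Immunogens** — lengths log-normal over 19–202 (median ≈ 40); 30% of
  windows are anchored at a terminus, emulating fragment selection that
  favours exposed chain ends; the rest are uniform.
* **Outcomes** — latent success ~ Bernoulli(logistic(β·x)) on the
  window's *true* features. Default coefficients (log-odds): intercept
  1.4, high disorder +2.0, terminus +0.1, sheet majority −0.8, TM overlap
  −1.6, disulfide −0.25, PTM +0.7, +0.015 per residue of immunogen length
  (centred at 50). Signs follow the direction of the effects the analysis
  is designed to detect, and magnitudes were set from the spread of
  grouped success rates such analyses report (overall ≈ 80%, a large
  disorder effect at the terminus, a clearly lowest TM-overlap group, a
  small insignificant disulfide effect); they are generator conditions,
  not estimates. Each technology is tested independently at its coverage
  probability (WB 0.413, IHC 0.7443, ICC 0.5959 — reported coverage
  marginals); tested technologies report a pass exactly when the latent
  success is true (per-technology flip noise is configurable, default 0,
  so labels identify the latent variable). Passing outcomes split
  approved/supported/enhanced 0.6/0.3/0.1. WB bands: one uniform in-range
  band under success (plus an out-of-range band at rate 0.2), and under
  failure either no band (rate 0.5) or an out-of-range band. An optional
  `most_positive_wb` flag emulates best-of-divergent-blots registration.
* **Determinism** — one SeedSequence per run, spawned per protein;
  identical config + seed gives byte-identical tables and PDB files.

**Two fidelity levels.** By default the pipeline profiles the generator's
feature tracks directly (fast enough for thousands of replicate
cohorts). With `with_structures=True` every protein gets an all-heavy-atom
ideal geometry (NeRF construction from canonical dihedrals; all-trans
side-chain templates; hairpin turns as type II′), and the geometric code
path — hydrogen-bond secondary structure, SASA, contacts — recomputes the
features from coordinates. On such cohorts the geometric labels reproduce
the generator's true disorder/position/TM classes at ≥ 99% and the
majority secondary structure at ≥ 90% (geometry-induced label noise at
segment boundaries is expected and tolerated).

**What passing tests do not show.** The generator's proteins are
geometrically idealized (no packing, no tertiary contacts beyond chance,
approximate ring closure), its disorder scores are iid within regions
rather than smoothly varying predictor output, and its effect model is
exactly logistic in the true features. Success on synthetic cohorts
therefore validates the *pipeline* — rules, estimators, calibration —
not any biological claim about real antibody data.

## Verification experiments

* **Null calibration** — all-zero effect model at a marginal rate of 0.8;
  1000 replicate record sets over a fixed protein library (100 proteins ×
  6 immunogens, short proteins for speed); both the grouped chi-squared
  (position) and the Mann–Whitney (mean contacts, successful vs.
  unsuccessful) must reject at 5% ± 2%.
* **Parameter recovery** — `recovery_config()` injects a single
  high-disorder effect of odds ratio 2.0 into 2000 records and the
  marginal odds ratio estimated from the cohort table must land in
  [1.5, 2.7]. The experiment is designed for estimator precision at that
  cohort size: baseline success 0.5 (a balanced Bernoulli maximises the
  information per record and keeps the log-OR standard error ≈ 0.24),
  half the windows terminus-anchored, and short probe windows (19–40) so
  most fall entirely within one disorder regime — a window straddling a
  boundary is classed medium and contributes nothing to the high/low
  contrast. The estimate centres slightly below 2 (marginal vs.
  conditional odds ratios are not collapsible), well inside the interval.
* **Qualitative orderings** — with the default effect model, 200
  replicate cohorts of 2000 records; in ≥ 95% of them, simultaneously:
  high- beats low-disorder at the terminus, coil-majority beats
  sheet-majority, TM-overlap is the lowest TM class, and PTM-containing
  beats PTM-free.
* **Oracle equivalence** — secondary structure vs. mdtraj's DSSP on ≥ 20
  ideal constructs (≥ 95% interior agreement); SASA vs. a 10,000-point
  Monte-Carlo oracle (≤ 5%); contacts bit-identical to brute force;
  masses vs. an elemental-composition oracle (≤ 0.01%); Mann–Whitney vs.
  exhaustive enumeration; chi-squared vs. the closed form (20.0 on
  [[30,10],[10,30]]).

Problem sizes throughout (chain lengths 12–30 for the geometric oracles,
100-protein libraries for calibration, 2000-record cohorts for recovery)
were chosen as the smallest at which the checked properties are stable.

## Known limitations

* PDB is the only structure dialect; mmCIF is a noted extension. Only the
  first chain of the first model is read; non-standard residues are
  rejected rather than mapped (how selenocysteine-containing immunogens
  should be handled is undecidable from the rules alone).
* The viewer module renders static figures plus JSON; it does not fetch
  annotations from any web service.
* Mass prediction ignores PTM- and oligomer-induced weight shifts, so a
  biologically specific blot can be classed unspecific; this is a
  property of the ±20% rule, not of the implementation.
* The DSSP implementation tracks only the states the 3-state collapse
  needs; 8-state output (T/S distinctions, β-bridge partners) is out of
  scope.
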