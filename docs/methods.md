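# Methods

## Quantification model

Protein abundance is quantified bottom-up from peptide peak intensities.
The rollup is a plain sum: `PPI_p,i = Σ_j I_j,i` over the peptides assigned
to protein *p* that were observed in sample *i*. Unobserved peptides
contribute nothing; a protein with no observed peptide in a sample has
*missing* PPI, never zero (and never PAI = −∞). The input table assigns
each peptide to exactly one protein — protein inference and shared-peptide
grouping are upstream concerns.

Normalization uses a single endogenous standard: the protein with the
highest PPI, which in SC tape strips is keratin 10. Operationally the
standard is the protein with the largest **total** PPI among proteins
observed with PPI > 0 in every sample, with exact ties broken to the
lexicographically smallest accession; a named accession can be forced via
`standard_protein` to mirror a fixed conventional choice. Requiring
complete observation guarantees the weights `wt_i = PPI_i(std)/PPI_k(std)`
are defined for all samples. Weights are computed across the whole analysis
batch (both arms, both timepoints jointly); a per-arm weighting would be a
trivial variant but the joint batch matches how a single MS batch is
normalized in practice.

`PAI = log10(PPI/wt)` is invariant to multiplying all intensities of one
sample by any constant — numerator and denominator scale identically. One
subtlety: the weight denominator refers to a fixed physical reference
sample *k*. If the reference is re-derived after a perturbation large
enough to move the argmax of the standard's PPI, every PAI entry shifts by
the constant `log10(M'/M)`; PAI is therefore defined up to a global
additive constant tied to the reference choice. `compute_weights` accepts a
pinned `reference_sample` for re-analyses where that constant must be
preserved. All within-sample contrasts and all between-sample comparisons
are unaffected either way.

A consequence of single-reference normalization worth knowing: any error in
the standard protein's own measurement (noise, or dropout of one of its
peptides) propagates as a *common-mode* shift to every protein of that
sample. Arm-mean fold changes therefore carry a small shared error
component in addition to per-protein noise; with 8 subjects and
peptide-level log10 noise 0.05 the common-mode standard error of an arm
mean is ≈ 0.025 log10 units.

## Baseline concordance filter

In a contralateral design both legs should present the same proteome
before treatment; proteins discordant at baseline (blood contamination,
unilateral inflammation markers) are uninterpretable for treatment
contrasts. The filter computes per protein the difference of arm means of
baseline PAI (pairwise-complete over subjects; proteins observed in fewer
than 2 subjects per arm are flagged insufficient and set aside), then
**retains the `floor(f·P)` proteins with smallest |diff|** at retention
fraction `f = 0.95`. The count rule is chosen because it reproduces the
canonical 172 → 163 retained / 9 excluded split exactly
(`floor(0.95 · 172) = 163`); a percentile-threshold reading
(`method="percentile"`) is provided as an alternative since the retention
phrase admits both. Boundary ties break on (|diff|, accession) for
determinism. Excluded proteins are reported with fold magnitudes
`10^|diff|`, sorted descending.

Arm means — not per-subject leg differences — define the baseline
difference, treating the arms as groups; a paired per-subject variant would
be stricter but tests a different null.

## Differential analysis

Per-arm change is `ΔPAI = PAI(day14) − PAI(baseline)` per subject; the arm
log fold change is the mean over subjects with both endpoints (a
geometric-mean-style fold, `fc = 10^lfc` — PAI is already log-scale, so
averaging per-subject ratios would mix scales). log2 conversions use
`log2(x) = log10(x)/log10(2)` exactly.

The significance family is the **between-arm** contrast
`d_s = ΔPAI_ff − ΔPAI_lotion` (the film's added effect over lotion, the
family highlighted in the two-arm scatter); within-arm change tests are
also computed and reported as separate q-value families, since grouped
significance counts can reasonably refer to either family.

### Exact Wilcoxon signed-rank

Zero differences are dropped before ranking (standard convention);
`|d| ≤ 1e-10` counts as zero so that log-scale floating-point residue in
noise-free fixtures does not read as signal — real ΔPAI values sit many
orders of magnitude above the tolerance. An all-zero vector returns p = 1
flagged degenerate rather than raising, so zero-noise null fixtures run end
to end. For n ≤ 25 remaining pairs with untied magnitudes, the two-sided
p-value is exact: the null distribution of the positive rank sum W⁺ over
all 2^n sign assignments is built by the subset-sum dynamic program
(polynomial product of `(1 + x^r)`), and
`p = min(1, 2·min(P(W ≤ w), P(W ≥ w)))`. With ties or larger n, a normal
approximation with tie-corrected variance
(`var = n(n+1)(2n+1)/24 − Σ(t³−t)/48`) and a 0.5 continuity correction is
used. With n = 8 subjects the exact two-sided floor is 2/2⁸ = 0.0078125 —
a hard limit on per-protein evidence that shapes everything downstream.

### Storey q-values

π₀ is estimated from `π₀(λ) = #{p > λ}/(m(1−λ))` on the grid
λ = 0.05, 0.10, …, 0.95, smoothed by a least-squares cubic over the grid
and evaluated at λ = 0.95 (a cubic with no interior knots, the
deterministic smoother variant; the bootstrap variant is intentionally not
used). The estimate is clamped to `[1/m, 1]` — the lower clamp keeps
q-values strictly positive. Then
`q_i = π₀ · min_{j: p_j ≥ p_i} (m·p_j / rank_j)`, monotone non-decreasing
in p and ≤ 1. Fixing π₀ = 1 yields exactly Benjamini–Hochberg adjusted
p-values, which is both a unit-test oracle and an available conservative
mode.

### Quadrants, ratios, scatter

Quadrant labels follow strict signs of `(lfc_lotion, lfc_ff)`: both
positive `up_up`, both negative `down_down`, the two discordant quadrants,
and `boundary` for an exact zero. The between-arm ratio is
`fc_ff / fc_lotion`. The scatter summary reports Pearson r over per-protein
pairs of log2 fold changes plus marginal histograms on shared bin edges;
zero variance on either axis flags r degenerate rather than erroring.

## Clinical endpoint statistics

Observer dryness scores are validated to the 0–4 range in 0.5 steps.
Changes are differences from the day-0 record per subject × arm; subjects
missing day 0 are excluded with a warning. For each endpoint, the
comparison family comprises between-arm tests at every day plus within-arm
changes vs day 0, adjusted together by Benjamini–Hochberg — a per-endpoint
(figure-wise) family; per-panel adjustment is the main alternative and
would only make day-0 comparisons slightly less conservative. The paired
t-test for immunofluorescence supports n as small as 3; zero-variance
differences are flagged degenerate (identical vectors give t = 0, p = 1; a
constant nonzero difference leaves p undefined) instead of producing a
spurious p = 0.

## Synthetic study generator

The generator emulates the study design: 8 subjects, two arms (lotion /
lotion + film on opposite legs), two timepoints, 172 proteins, one dominant
keratin-10-like standard. Per protein, a log10 baseline abundance is drawn
from N(6.0, 0.8) (arbitrary MS intensity units); the standard protein sits
deterministically at 6.0 + 3.0 so it dominates every sample. Each sample
receives a global log10 loading factor N(0, 0.15) applied multiplicatively
to **all** peptides including the standard — this is the quantity the PAI
normalization must remove. Per-protein per-sample measurement noise is
N(0, 0.05) on the log10 scale. Planted treatment effects add their ΔPAI in
the stated arm at day 14 only; planted baseline outliers add a persistent
offset to the film arm at both timepoints (so they perturb baseline
concordance without faking a day-14 change). A protein's sample intensity
is split across 2–8 peptides by fixed per-protein Dirichlet proportions
(ionization propensity), so the peptide-sum rollup reconstructs the protein
signal exactly; peptide records then drop out independently at
`missing_rate` (default 0.02). With zero noise, every planted effect
passes through to the downstream fold change exactly — the generator's
analytic pass-through property.

Default planted structure: the named SC marker proteins carry the
narrative fold changes (suprabasin 0.5×/1.9×, vimentin 1.2×/2.3×, ASPRV1
1.3×/2.0×, annexin A2 decreasing with the film, keratin subtypes, etc.;
markers with only a film fold get a lotion response of half the log fold),
plus a deterministic block of 72 generic response proteins with correlated
per-arm changes, mostly boosted in the film arm. Without such correlated
two-arm structure the lotion arm would be pure noise and the two-arm
scatter correlation near zero — unlike a real treated proteome, where both
arms share the lotion's action. Nine baseline-discordant proteins are
planted with between-arm folds 1.9–3.8× in alternating directions.
Intensities are modeled log-normal; this is an assumption of convenience,
not an empirical claim about any instrument.

Clinical endpoints use a linear improvement model with subject random
intercepts: observer score starts near 3.2 and falls 0.05/day (lotion) vs
0.09/day (film), quantized to 0.5 steps and clipped to [0, 4]; conductance
starts near 80 instrument units and rises 1.5/day vs 3.0/day;
immunofluorescence intensity is generated for a 3-subject biopsy subset at
day 5 with the film arm brighter. This is deliberately minimal — enough to
exercise the endpoint statistics, not a biological model.

What the generator does **not** emulate: raw spectra, retention times,
charge states, search-engine behavior, tape-strip depth profiles,
intensity-dependent missingness (dropout is uniform), peptide-level
interference, or subject-level covariates. Passing tests demonstrate the
pipeline's arithmetic, conventions and error control under the stated
stochastic model — they do not certify performance on real MS data with
structured missingness or heavier-tailed noise.

A single RNG seed determines everything; per-table substreams are spawned
in fixed order from the seed sequence, so identical configs give
byte-identical outputs.

## Calibration experiments and problem sizes

The test suite validates error control and recovery at the study's scale,
chosen to finish in minutes on one CPU:

- **FDR control**: 200 null studies (8 subjects, 150 proteins, noise 0.05,
  no missingness); mean fraction of q < 0.05 calls must not exceed
  0.05 + 2·MC-SE. With n = 8 the exact test's discreteness makes the
  realized level ≈ 0.047 at most; Storey's π₀ clamps to 1 on null data, so
  q-values reduce to BH and the observed rate is far below nominal.
- **Recovery**: 100 replicate studies with 48 of 150 proteins carrying a
  planted film-arm ΔPAI = log10(1.9) ≈ 0.279. The planted fraction (32%)
  mirrors the fraction of proteins a study of this design reports as
  significantly changed (≈30%), and matters statistically: the exact-test
  floor 2/256 with m = 150 means a **single** effect protein can never
  reach q < 0.05 at n = 8 — detection requires enough small p-values to
  drag the BH threshold up, i.e. a block of concordant effects, which is
  what a real treatment produces. An a-priori power calculation at these
  conditions gives mean per-protein detection ≈ 0.93; the suite requires
  > 0.90 mean detection and mean absolute ΔPAI bias < 0.05 log10 units
  (analytically ≈ 0.8 · sd(lfc) ≈ 0.028).
- Calibration studies set `missing_rate = 0`: uniform peptide dropout —
  in particular of the standard protein's peptides — adds common-mode
  variance that is a property of the normalization, not of the measurement
  noise whose effect these experiments isolate.

## Numerical conventions

- Missing is NaN everywhere in memory and `NA` in files; TSV output uses
  full float precision, `.` decimals, LF endings.
- `PPI = 0` is treated as missing on the log scale.
- Exact-test path requires untied |d|; average ranks feed the tie-corrected
  normal path otherwise.
- Filter and standard-protein ties break lexicographically by accession.
- The run manifest records parameters and SHA-256 checksums of all inputs
  and outputs; reruns on identical inputs are bit-identical (no
  timestamps).

## Known limitations

- Single-reference normalization transmits the standard protein's
  measurement error to all proteins (common-mode); a multi-protein or
  median-based reference would be more robust but is a different method.
- The exact-test floor at n = 8 bounds per-protein evidence at
  p = 0.0078; FDR-significant calls at this sample size are only possible
  for blocks of effects.
- The count-based retention rule always excludes `P − floor(0.95·P)`
  proteins, even when all baseline differences are small; the excluded set
  is then noise-ranked (the percentile variant shares the property at the
  threshold).
- Group assignments in the packaged function map are curatorial; proteins
  outside it land in `unassigned`.
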