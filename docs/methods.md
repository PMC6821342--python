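# Methods

This note documents the models, statistics, and numerical choices behind
`rnai_mosaic`, and what the synthetic-data generators do and do not emulate.

## Mutant identification by in silico complementation

### Model

A forward-genetic screen isolates `n` independent mutant strains from a
chemically mutagenised (ENU) population. Whole-genome sequencing of each
strain yields a table of candidate variants, most of which are incidental.
Classical complementation logic identifies the causal gene computationally:
if two independently isolated mutants carry *different* mutations in the
*same* gene, that gene is very likely causal in both, because two random
sets of mutated genes drawn from a genome of `N` genes rarely overlap.

Under the null hypothesis that mutant 1's `m1` mutated genes and mutant 2's
`m2` mutated genes are independent uniform draws without replacement from
`N` genes, the number of shared genes `X` is hypergeometric:

    P(X = j) = C(m1, j) C(N - m1, m2 - j) / C(N, m2)

and the reported p-value for an observed overlap of `k` genes is the tail
`P(X >= k)`. With `N = 20000` and `m1 = m2 = 30`, `P(X >= 1) = 0.044` and
`P(X >= 2) = 0.0009` — so even a single shared gene between one specific
pair is only marginally surprising, and with `n = 23` mutants there are
`n(n-1)/2 = 253` pairs. Family-wise control is Bonferroni: a pair is
significant when `p < alpha / 253` (`0.05 / 253 ≈ 2e-4`).

The tail is evaluated in log space (`scipy.special.gammaln` for the
log-binomial coefficients, log-sum-exp over the tail terms) so genome-scale
arguments do not underflow. The function is symmetric in `(m1, m2)` and
returns exactly 1.0 at `k = 0`.

### Filtering and background removal

Variant calls are retained when all of the following hold (all comparisons
inclusive): Phred quality >= 20, supporting reads >= 2, variant-read
fraction >= 0.66, and a consequential effect class (missense, nonsense,
splice junction, deletion). The fraction threshold can be lowered per gene
(`fraction_overrides`, e.g. 0.15) for loci present in extra transgenic
copies that dilute the variant-read fraction. Candidate deletions are
flagged from coverage tracks as maximal runs of >= 2 consecutive 10-kb
windows below 0.25x the track mean; window width, factor, and run length
are configuration, since "lower than average coverage" admits many
parameterisations.

Variants with identical `(chrom, pos, ref, alt)` in two or more mutants are
removed from **all** carriers: independently induced identical point
mutations are vanishingly improbable, so shared calls are pre-existing
background. Multi-allelic sites are separate records. `m1`/`m2` in the
hypergeometric test count distinct mutated *genes* per mutant after
filtering and background removal; variants without a gene annotation are
excluded from gene counting.

## 3D image quantification

### Object counting

Objects are maximal connected components of voxels with intensity >=
threshold, 26-connectivity by default (the convention of 3D object counters
in fluorescence microscopy; 6 and 18 are available). Volume is defined
*post-threshold*: voxel count x physical voxel volume. For mRNA foci, a
volume gate `[0.015, 0.2]` μm³ (inclusive on both ends) rejects
sub-resolution background speckle below and merged-object miscounts above;
the detection threshold for foci is 50 (raw intensity units).

### Depth-stratified nucleus calls

Detection sensitivity decays with imaging depth, so nucleus on/off calls
use a slice-range threshold profile (default: 70 for slices 1–160, 20 for
slices 161–319; slice indices 1-based). A nucleus is "on" when a detected
object's centroid lies within `match_radius` (default 2 μm) of its expected
centroid at the threshold of its slice range. Each object supports at most
one nucleus; assignment is greedy in nucleus-label order, each nucleus
claiming its nearest unclaimed object. This object-matching formulation
stands in for the original thresholding-plus-manual-verification workflow,
which has no algorithmic definition.

### Stack normalisation and ROI fluorescence

Stacks are normalised to a fixed slice count (default 319) by trimming
leading slices whose maximum intensity is at or below a noise floor and
appending zero slices, keeping depth coordinates comparable across animals.
ROI fluorescence on a 2D projection is the printed formula:
`sum(ROI) - area(ROI) x mean(background)`, which can be negative.

The "between two nuclei" counting region for foci is the axis-aligned
bounding box spanned by the two nuclear centroids expanded by a 0.5 μm
margin, with nuclear-mask voxels zeroed before detection; the region
definition is a package choice, since only the phrase "between two nuclei"
constrains it.

## Mosaicism over the intestinal lineage

The E blastomere produces 20 terminal intestinal cells; 10 undergo nuclear
division without cytokinesis (binucleate), 4 variably, 6 never — so an
animal carries 30–34 intestinal nuclei. The package encodes this as a
lineage table of (cell name, nucleation class). The true name-to-class
mapping is anatomical (figure-derived, not printed as text), so the default
table carries the correct 10/4/6 *counts* with placeholder E-lineage-style
names and is fully overridable from CSV.

Per-cell scoring across animals classifies each cell as `always_on` (failed
to silence in every animal — relied exclusively on the somatic RdRP),
`always_off` (silenced in every animal), or `mixed`. Binucleate concordance
(both nuclei of one cell share one state) is a validation check; the
generator enforces it and `check_binucleate_concordance` reports violations
in hand-built data. A discordant cell, if forced through scoring, counts as
"on" with a logged warning.

`sister_concordance_test` asks whether silencing follows lineage: the
statistic S is the mean over animals of the fraction of sister-cell pairs
with identical state, and the null permutes cell states within each animal
(preserving each animal's silencing burden, which varies substantially
animal-to-animal). p = (1 + #{S_perm >= S_obs}) / (1 + n_permutations).
Because S is discrete and ties with its permuted replicates are common, p
is conservative (sub-uniform) under the null rather than exactly uniform;
the test suite therefore checks validity and calibration at several levels
rather than strict KS uniformity. Default sister pairs are adjacent cells
in table order — a placeholder relation, overridable alongside the table.

## Supporting statistics

* **Wilson score interval with continuity correction** for single
  proportions: closed-form bounds solving
  `(|p̂ - p| - 1/(2n))² = z² p(1-p)/n`, with `k = 0` forcing lower = 0 and
  `k = n` forcing upper = 1, clipped to [0, 1]. The uncorrected Wilson
  interval is available behind a flag.
* **Difference of proportions**: Newcombe square-and-add interval built
  from the two single-sample Wilson intervals; significance = interval
  excludes 0.
* **Two-sample t-test**, two-tailed, classical equal-variance by default
  (Welch behind a flag); degenerate variance raises rather than returning
  NaN, except for identical constant samples, which return (0, 1).
* **Two-way ANOVA with replication** on a balanced `(a, b, r)` layout,
  `r >= 2`: direct sum-of-squares decomposition with interaction
  (`SS_total = SS_A + SS_B + SS_AB + SS_resid` to machine precision),
  F against the residual mean square. Unbalanced layouts are rejected.

## Synthetic data: what it emulates, and what it does not

### Cohorts

Each of 23 mutants receives Poisson(30) candidate mutations in genes drawn
uniformly without replacement from a 20,000-gene genome (matching the
worked-example scale of ~30 mutated genes per mutant; the true
per-mutant distribution is not documented, so Poisson is the natural count
model for independent rare hits). Quality, depth, and fraction are drawn to
straddle the filter thresholds: with probability 0.08 / 0.04 / 0.10 a
variant's quality / depth / fraction is drawn below its threshold,
otherwise above — enough sub-threshold mass that every filter is exercised
in every default cohort. Effect classes are drawn with missense dominating
(0.60) and ~27% non-consequential classes to exercise the effect filter.
Planted allelic series place distinct-position, filter-passing missense
variants in one gene across designated mutants; planted background places
byte-identical variants in >= 2 mutants. Not emulated: read alignment
artifacts, mutation clustering, linkage between variants, realistic ENU
mutational spectra, genome annotation.

### Image stacks

Nuclei are 3D Gaussian blobs (sigma = radius / 2) at arbitrary depths; an
"off" nucleus is simply rendered with a peak below its depth threshold.
Foci are truncated Gaussians whose sigma is calibrated against the actual
voxel raster so that the above-threshold voxel count equals
`round(volume / voxel_volume)` exactly in the noise-free case — without
this calibration, foci spanning < ~20 voxels quantise outside the ±20%
volume tolerance. Default voxel size is (0.125, 0.1, 0.1) μm (z step from
the acquisition geometry the package targets; x/y of that order for a 63x
confocal). Noise is folded-normal, clipped just below the configured noise
floor so empty leading slices stay classifiable as empty. Placements closer
than 2x the sum of effective radii are rejected unless `allow_overlap` is
set (used to construct deliberate merged pairs for the oversize gate).
Not emulated: realistic PSFs, depth-dependent attenuation, shot noise,
background gradients, touching nuclei — so passing tests demonstrate the
correctness of the counting/gating/matching logic, not robustness to real
microscope physics.

### Mosaic matrices

Per animal and cell, the silenced state is an independent Bernoulli draw
(default p_off = 0.5, scalar or per-cell); binucleate cells copy the state
to both nuclei; variable cells are binucleate with probability 0.5. Real
data need not be independent across cells or animals — the generator's
independence is precisely the null the sister-concordance test is built
against. Defaults (10 animals, 20 cells) match the cohort size the scoring
was designed for.

All generators take a single integer seed, use one `numpy` Generator per
call, and record the seed in their ground-truth/output metadata; identical
(config, seed) gives byte-identical output.

## Problem sizes in the default test run

The suite runs entirely on generated data: the flood-fill oracle
equivalence uses 150 + 100 random 10³ grids; family-wise error control uses
1000 cohort seeds (23 mutants each); planted-series recovery uses 100
seeds; the permutation-test calibration uses 400 seeds x 200 permutations;
the end-to-end demo uses a 64x256x256 stack and 10,000 permutations.

## Known limitations

* Effect annotation is an input; the package never derives effects from a
  genome annotation.
* Deletion detection is a simple coverage heuristic; it does not model
  mappability or GC bias.
* Nucleus identity (which blob is which cell) must be supplied; automated
  anatomical identification is out of scope.
* The default lineage name-to-class mapping and sister relation are
  placeholders carrying correct counts; analyses that depend on *which*
  named cell is binucleate must supply the anatomical table.
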