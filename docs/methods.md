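# Methods

## Scope and data model

`exomd` implements two desk-scale analysis stages around one shared set
of domain types. Stage 1 (variant prioritization) consumes an annotated
variant table (fixed-header TSV or VCF 4.2 with scores in INFO keys
`SIFT/PP2/MT/GERP/CADD/CONDEL`), a 6(+1)-column PED pedigree and a
carrier matrix; stage 2 (trajectory analytics) consumes a topology plus
frames of coordinates (multi-model PDB in Å, converted to nm at the
boundary, or a plain-text XYZ dialect in nm). All internal lengths are
nm, times ns, energies kJ/mol; genomic and residue positions are
1-based.

In the VCF dialect the per-tool scores are declared `Type=String` and
written with full `repr` precision. Declaring them `Float` would be more
idiomatic, but VCF libraries return Float INFO fields as 32-bit floats,
and the package guarantees lossless write→read round trips; strings
preserve the doubles exactly. The same concern shapes trajectory I/O:
the XYZ dialect round-trips bitwise, while PDB is inherently quantized
to 0.001 Å by its fixed-width records, so PDB round trips are exact only
for coordinates already at that precision.

## Filtration and co-segregation

The cascade applies rules in a fixed order — synonymous, homozygous,
common, not shared by the index cases — and the pipeline records, for
every excluded variant, the first rule that removed it, so a decision
log reads the way an analyst would narrate the filtering. Frequency
filtering uses the folded minor allele frequency `min(f, 1−f)` with an
inclusive threshold (default 1%, the conventional rare-disease cutoff);
a variant with no frequency record at all is treated as novel and never
removed by the frequency rule.

Co-segregation counts carriers among typed family members only:
individuals with unknown affection status, and untyped genotype calls,
contribute to no count. A variant passes iff
`affected_noncarriers ≤ max_phenocopies` (default 1 — dominant late-onset
diseases commonly harbour one sporadic case inside a Mendelian family)
and `unaffected_carriers ≤ max_unaffected_carriers` (default 0, full
penetrance; raise it to model reduced penetrance). The verdict is
defined purely by these two allowances; an all-absent genotype column
fails in any family with more typed affecteds than the phenocopy
allowance.

## Consensus calls and ranking

Raw scores map to categorical calls with documented cutoffs: SIFT ≤ 0.05
(inclusive, SIFT's published damaging cutoff), PolyPhen-2 HumDiv tiers
0.447 / 0.909 (both damaging tiers count as a deleterious vote; the fine
label is reported separately), MutationTaster ≥ 0.5, CADD phred ≥ 15,
Condel ≥ 0.522 (its published default). CADD's authors define percentile
tiers (≥10, ≥20, ≥30) rather than a binary cutoff; 15 sits between the
"top 10%" and "top 1%" tiers and cleanly separates scores practitioners
label deleterious (≈19+) from benign (≈5). GERP++ (range −12.3 to 6.17,
enforced at read time) sets a conservation *flag* at ≥ 2.0 rather than
casting a sixth vote, because conservation describes the site, not the
substitution. All cutoffs are overridable via `ConsensusThresholds` or
the CLI config file.

An absent score yields an `absent` call: it counts as a non-deleterious
vote (so missing data can only hurt a candidate, never help it) but
stays distinguishable from `benign` in reports. Ranking is a total
order: segregation-passing variants first, then descending
(votes, conserved flag, CADD), ties broken alphabetically by gene — so
permuting the input never changes the output.

## Trajectory observables

Superposition uses the Kabsch SVD construction with the determinant
correction that excludes reflections; selections of fewer than three
atoms, or collinear selections (second singular value ≈ 0), are
rejected because the rotation is undetermined. RMSD series fit each
frame to a fixed reference (frame 0 by default, matching the common
convention of MD analysis tools; the time-average structure is
available via a flag). RMSF superposes frames onto their time-average
structure by iterating fit → re-average to convergence (the fixed point
of the usual two-step scheme), then averages per-atom fluctuations
within each residue; fitting can be disabled for analytic tests. The
radius of gyration is mass-weighted by default (unit masses via a
flag).

SASA is Shrake–Rupley: `n_points` (default 960, floor 32) quasi-uniform
points per atom on the probe-expanded sphere (probe 0.14 nm), a point
buried if inside any other atom's expanded sphere. Sphere points come
from the deterministic golden-spiral construction, so SASA is
bit-reproducible with no RNG; at 960 points totals agree with a 4×
denser grid to well under 1% on random clusters. Default van der Waals
radii (N 0.155, C 0.170, O 0.152, S 0.180 nm) ship as a table and are
overridable per structure.

Summaries report mean ± sample SD (n−1) over frames at time ≥ an
equilibration cut; the CLI default cut is half the trajectory,
mirroring the common practice of analysing the equilibrated second half
of a production run.

## Essential dynamics and free-energy surfaces

The covariance matrix is built after removing rigid-body motion by
superposing every retained frame onto the average structure, optionally
√mass-weighted, normalized by the number of frames (population
covariance). Diagonalization uses the dense symmetric eigensolver;
selections are capped at 3N ≤ 3000 by default (an explicit override
exists) to keep the 3N×3N matrix desk-scale. Contributions are
`100·λ_i/trace`; projections use exactly the superposition and mean of
the covariance build, which makes "variance along PC1 equals λ₁" an
exact identity rather than an approximation — the combined
`essential_dynamics_analysis` entry point guarantees this.

The free-energy surface Boltzmann-inverts the normalized 2D histogram
of two order parameters, `ΔG = −k_B T ln(P/P_max)` with
k_B = 0.0083144621 kJ·mol⁻¹·K⁻¹, so the most-populated bin sits at 0 and
all visited bins are ≥ 0. ΔG is written with the *maximum* probability
in the denominator — the only normalization for which the stated
properties hold. Unvisited bins are flagged, never zero-filled
(a zero would claim maximal stability for unsampled states). Default
grid 32×32 spanning the data range with 1e-9 padding. Both (Rg, RMSD)
— the default — and (PC1, PC2) projections are supported as order
parameters.

Metastable states are counted as visited bins that are strict minima
over their visited 8-neighbourhood and whose lowest escape barrier — the
minimax path height to any lower bin, computed Dijkstra-style over
visited bins — is at least a depth threshold (default 1 k_B T). The
depth criterion is this package's operationalization of what is usually
judged visually from a landscape plot; it filters histogram-noise
minima while keeping genuinely separated basins, and the count is
monotone non-increasing in the threshold. Basins separated by unvisited
territory are, by construction, distinct (infinite barrier).

## Synthetic data

The family generator emulates the data-generating structure of a
dominant-disease family study: defaults are 5 affected / 4 unaffected
members, 3 exome-sequenced index cases, 1 phenocopy among the affecteds
and 20 background variants, matching the structure of the worked
example. The planted causal variant is heterozygous, novel and carried
by exactly the non-phenocopy affecteds; background variants draw a
population MAF from Beta(0.5, 3) (a mix of rare and common sites, so
every cascade rule is exercised), are synonymous with probability 0.3
and homozygous with probability 0.1, and are carried independently with
probability 1−(1−MAF)². Causal scores draw from deleterious-leaning
distributions (SIFT ~ Beta(1,20), PolyPhen-2/MutationTaster ~
Beta(20,1.5), CADD ~ N(28,3) truncated ≥ 0, GERP ~ N(5,0.5) clipped to
range, Condel ~ Beta(12,2)); background scores mirror these toward the
benign side. All draws are clipped to the tools' documented domains and
the whole dataset is bit-reproducible per seed.

The trajectory generator produces a 40-bead helical chain (one CA bead
of 110 amu per residue, 0.1 ns/frame, 1000 frames ≈ a 100 ns production
run at desk scale) in four modes: `static`; `harmonic` — independent
isotropic Gaussian displacements with per-residue target RMSF (per-axis
σ = amplitude/√3 so the planted amplitude *is* the expected RMSF);
`hinge` — a chosen sub-domain rotated rigidly by a sinusoidal angle
about an axis through its first atom, plus jitter; `two_state` — frames
alternate between the reference and a hinge-opened conformation with
geometric dwell times (mean 100 frames), emulating flexed/extended
domain transitions.

What the generator does **not** emulate: linkage between variants,
genotyping error, population structure, realistic score correlations
between tools, solvent, force-field physics, or continuous transition
paths between conformational states (two-state switching is
instantaneous). Passing recovery tests therefore demonstrates that the
estimators recover the statistical structure they are defined on — not
that a real protein or a real exome would behave as simply.

## Numerical choices and degenerate inputs

Ties in ranking break alphabetically; missing CADD sorts as −∞ inside
the rank key. Kabsch rejects < 3 or collinear atoms; RMSF and summaries
require ≥ 2 post-cut frames; SASA requires ≥ 32 sphere points and
positive radii; Rg requires positive total mass; the FES requires equal
series lengths and positive temperature; covariance requires symmetric
input (checked to 1e-8 relative) and respects the 3N cap. Eigenvalues
are reported descending; tiny negative eigenvalues from floating-point
(≥ −1e-9) are tolerated.

## Test and reproduction problem sizes

The suite pairs every estimator with an independent oracle: a
multi-start Nelder–Mead rotational search and SciPy's `align_vectors`
for Kabsch, a literal two-pass loop for the covariance, a brute-force
recount for segregation, an independent Shrake–Rupley implementation
for SASA, and closed forms everywhere one exists. Recovery studies run
at 20 family replicates, 2000-frame harmonic trajectories (40 beads)
and five 1500-frame two-state trajectories (30 beads) — sizes chosen so
the statistical assertions (Spearman ρ > 0.9, exact basin counts,
perfect top-1 recovery) are sharp while the full suite and the
reproduction script each finish in well under a minute.

## Known limitations

The published trajectory-scale numbers of the motivating study (e.g.
backbone RMSD 1.61 ± 0.26 nm for the wild type without its glycan,
PC1 contribution 70%, covariance trace 237.82 nm²) cannot be recomputed
because the underlying simulations were not deposited; this package
reproduces the *methods* and validates them on synthetic data with
known ground truth. The worked-example fixture carries real published
identifiers and scores, but genomic coordinates other than the CFAP65
site (the one published with its population frequency) are synthetic
placeholders. Periodic-boundary unwrapping, hydrogen-bond analysis and
secondary-structure assignment are out of scope.
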