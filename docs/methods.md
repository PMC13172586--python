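# Methods

This note documents the models, conventions and design decisions behind
`stonescreen`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic-data validation does and does not
establish.

## Descriptors

**Molecular weight.** Sum of average (isotope-abundance-weighted) residue
masses plus one water (18.0153 Da). Masses come from Biopython's IUPAC
tables, so values agree with the ProtParam web tool. Monoisotopic masses and
post-translational modifications are out of scope: MW is the unmodified
chain mass.

**Theoretical pI.** Net charge is the Henderson–Hasselbalch sum over the two
termini and the D, E, C, Y, H, K, R side chains; the pI is the zero crossing
on pH 0–14 found by bisection to |ΔpH| < 10⁻³. The default pKa values are
the Bjellqvist set as used by ProtParam, including its residue-specific
N-/C-terminal adjustments; any other set can be supplied as a `PKaSet`. The
charge is strictly decreasing in pH and both termini always ionize, so the
crossing exists and is unique.

**GRAVY.** Arithmetic mean of Kyte–Doolittle hydropathy values; < 0 is
hydrophilic.

**Instability index.** Guruprasad's statistic: (10/L) · Σ over the L−1
overlapping dipeptides of the published DIWV weight (Biopython's table; a
dipeptide absent from the table would weigh 1.0, though the published table
is complete). Unlike GRAVY this is order-sensitive, which the property tests
assert.

**Residue classes.** The composition report needs polar + nonpolar +
positive + negative to partition the 20 residues exactly (so the four
fractions sum to 1); aromatic overlaps the partition and is reported
separately. The default scheme is aromatic {F,W,Y}, positive {K,R,H},
negative {D,E}, polar {S,T,N,Q,C,Y,G}, nonpolar {A,V,L,I,P,M,F,W}. Published
composition figures rarely state their exact sets (histidine and glycine are
the usual ambiguities), so the scheme is fully configurable and recorded in
the run manifest.

**Classification thresholds.** Low/high MW at 50 kDa, stable/unstable at
instability 40, hydrophilic/hydrophobic at GRAVY 0. The literature defines
these with strict inequalities on both sides, leaving the boundary
undefined; this package uses "≥ threshold → upper class" uniformly
(40.0 → unstable, 0.0 → hydrophobic, 50 kDa → high). Boundaries are
measure-zero for real data, so the choice only matters for synthetic edge
cases.

**Oxalate-binding motifs.** Sequences are scanned against PROSITE-syntax
patterns. The default `all_starts` mode reports every (start, end) span
whose substring satisfies the pattern — overlapping matches included, and
for variable-range elements every achievable length; this is deterministic
and checkable against an exhaustive substring oracle. A greedy
`non_overlapping` mode exists for sensitivity analysis. A protein is
"oxalate-binding" iff its count ≥ 1. The shipped motif file is a synthetic
placeholder (lysine/arginine-core patterns); the OxaBIND definitions are not
redistributed, and any real analysis must substitute them. Reports record
the motif-file checksum so the substitution is auditable.

**Calcium-binding sites.** Counted from UniProt flat-text features: BINDING
features whose ligand is Ca(2+) and legacy CA_BIND regions are pooled, with
overlapping/adjacent spans merged so a contiguous ligand group counts once;
each DOMAIN feature described as "calcium-binding" adds one. Whether public
databases count residue-level or domain-level sites varies by entry; the
rule keeps both contributions and de-duplicates the span-based ones.

**Secondary structure.** The built-in predictor assigns each residue the
argmax over four states of window-averaged propensities (default window 17,
truncated at the termini; ties break helix > strand > turn > coil). The
helix/strand/turn columns are Chou–Fasman conformational parameters; the
coil column is a package-defined stand-in (turn − 0.05, with +0.20 boosts
for the canonical coil-formers G and P). This is deliberately *not* a
reimplementation of alignment-database predictors such as SOPMA — their
curated databases and self-optimization are not reproducible from a
parameter list — so per-protein agreement with SOPMA output is not expected
and not claimed. For analyses that must match a specific external tool, its
per-residue states or fractions are imported verbatim (`import_ss`), with
renormalization accepted only within [0.98, 1.02].

## Activity quantification

Each assay readout (crystal count per field, crystal size, aggregate count,
adherent crystals per field) is converted to percent change versus the mean
of the reference condition — the lysozyme negative control by default, the
protein-free blank optionally. Replicates are treated as independent
experiments (mean ± SEM; no pairing of fraction replicates to specific
control replicates). This percent-change form is a reconstruction: it is the
minimal definition consistent with activities reported as signed percentages
against a control, scale-invariant in the readout units, and exactly zero
for a fraction identical to the reference. It should be read as this
package's convention, not as any specific laboratory's unpublished formula.

## The correlation screen

**Unit of analysis.** The default unit is the pooled protein-in-fraction
entry. With fractions of 10, 12, 71, 71, 60, 55, 25, 38 and 6 proteins this
gives n = 348 entries, and p-values of the magnitude seen in real screens of
this design (e.g. p < 10⁻³ at |rs| ≈ 0.2) are only attainable at this n —
nine fraction means could never produce them. A `unit="fraction"` mode
(correlating abundance-weighted fraction means, n = 9) is provided for
sensitivity analysis. Fraction-level percentage properties (% calcium
binders, % high-MW, % stable, % hydrophilic and their complements) are
intrinsically per-fraction and always use n = 9.

**Abundance weighting.** Entry weights are MS intensities normalized within
fraction (weights sum to 1 per fraction; conservation is asserted
downstream). The abundance-weighted property is w·x; the abundance-weighted
activity assigns the whole-fraction activity to each member protein scaled
by its weight, w·a_f. This product form is the minimal reading under which
per-protein abundance can enter an activity measured per fraction.

An important statistical consequence, visible in both real and synthetic
screens: because every weighted property and every weighted activity share
the factor w, positive-valued activities induce substantial rank correlation
for *all* positive descriptors. A planted link is therefore recovered
together with a halo of co-significant descriptors, and the meaningful null
check is against assays whose activities are independent of the proteome
(see validation below), not against other descriptors within a linked assay.

**Spearman/BH.** rs is the Pearson correlation of mid-ranks; the two-sided
p-value uses the t approximation with n − 2 df, with an exhaustive
permutation option for n ≤ 9. Constant inputs yield a flagged NA cell that
is excluded from adjustment. Benjamini–Hochberg runs over all non-NA cells
of one screen (22 properties × 4 assays = 88 tests by default; per-activity
families via config). Significance requires p_adj < 0.05 **and**
|rs| > 0.8.

## Synthetic data

The generator emulates the study shape: 9 fractions with the protein counts
above; sequence lengths uniform on 80–7000 residues; residues drawn i.i.d.
from Swiss-Prot-like background frequencies; log-normal intensities
(σ = 2 log-units, a typical MS dynamic range); 18% of proteins receive
Ca(2+) BINDING features and 90% receive injected oxalate-motif copies
(1 + Poisson(1) per binder); four assays × 3 replicates against blank and
negative-control baselines.

Planted links operate at the level the screen analyses: the fraction's true
activity is an affine, strictly increasing map of its min-max-scaled
abundance-weighted descriptor mean, blended with an independent uniform
component by the link strength (strength 1 = purely descriptor-ordered,
0 = independent), then read out per replicate with Gaussian noise of 5
activity-percentage points. Activity ranges mirror the assay magnitudes of
fractionated-urine studies (aggregation 150–320%, adhesion 40–60%). Assays
without a planted link draw fraction activities from N(0, 15%) — a "no
effect" model whose sign mixing is what keeps the shared-weight artifact
from flagging null assays.

What the generator does **not** emulate: real proteome composition and
domain structure (i.i.d. residues have no motif clustering or low-complexity
regions), shared proteins across fractions, correlated descriptors beyond
what sequence statistics induce, realistic crystal kinetics, or MW
distributions of urinary proteomes (uniform lengths up to 7000 residues give
a mean MW near 380 kDa, higher than typical urine). Passing the validation
therefore shows that the *screen* detects planted monotone structure and
stays quiet on independent assays at the study's n — not that any biological
conclusion transfers.

## Validation sizes and numerical choices

The replicate studies use 200 seeded replicates in the test suite and 100 in
the acceptance script (the package's chosen compromise between Monte-Carlo
resolution and a few minutes of runtime): planted MW→aggregation at strength
0.9 must be flagged in ≥ 95% of planted replicates, and no property×assay
pair may be flagged in > 5% of null replicates. Oracles are independent of
the implementation path: a brute-force dipeptide sum for the instability
index, a 0.001-step grid scan of the charge curve for pI, an exhaustive
substring tester for motif scanning, mid-rank Pearson for Spearman, and a
hand step-up loop for BH.

Ties in the secondary-structure argmax break in a fixed state order;
p-values of exactly 0 (|rs| = 1) are clipped to the smallest positive float
before BH; TSV readers parse floats in round-trip mode so that write/read
cycles and reruns are byte-identical under a fixed seed.

## Known limitations

- The motif set and the secondary-structure predictor are stand-ins (see
  above); descriptor values that depend on them are internally consistent
  but not comparable to OxaBIND/SOPMA output.
- The abundance-weighted activity construction makes cells within a
  positive-activity assay strongly interdependent; significant cells should
  be read per-assay, not as independent discoveries.
- Replicates are modeled and analysed as independent; paired designs would
  need a different activity estimator.
- UniProt parsing targets the flat-text dialect only, and only the feature
  kinds used for calcium counting.
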