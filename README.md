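# stonescreen

Kidney stones are predominantly calcium oxalate (CaOx), and urinary proteins
are suspected to promote the successive steps of stone formation:
crystallization, crystal growth, crystal aggregation, and crystal adhesion to
renal cells. `stonescreen` is a reusable pipeline for studies that fractionate
a urinary proteome (e.g. by anion exchange on isoelectric point), measure each
fraction's crystal-promoting activity in vitro, identify the fraction's
proteins by MS/MS, and then ask: **which physicochemical properties of the
proteins correlate with which crystal-promoting activities?**

It is written for proteomics/biochemistry groups running such screens: the
library computes every descriptor, the statistics, and the report tables; a
CLI composes them end to end; and a seeded synthetic-data generator produces
complete fake studies so the whole pipeline is testable without any
downloads.

## What it computes

**Per-protein descriptors** (ProtParam-equivalent, from sequence):
average-mass MW; theoretical pI (Bjellqvist pKa set, bisection on the
Henderson–Hasselbalch net charge); GRAVY (mean Kyte–Doolittle hydropathy);
Guruprasad instability index (II = 10/L · Σ DIWV dipeptide weights);
residue-class composition (aromatic, polar, nonpolar, positively/negatively
charged) under a configurable disjoint-cover scheme; oxalate-binding motif
counts by PROSITE-pattern scanning; calcium-binding site counts from UniProt
features (BINDING with a Ca(2+) ligand, calcium-binding DOMAINs, legacy
CA_BIND); and four-state secondary-structure fractions from a built-in
window-propensity predictor or imported from an external tool's output.

**Per-fraction activities**: for each assay, percent change of the readout
versus the reference condition (lysozyme negative control by default),

    activity_i = 100 · (metric_fraction,i − mean(metric_ref)) / mean(metric_ref),

averaged over replicates with SEM; negative values are inhibition.

**The correlation screen**: protein *i* in fraction *f* gets weight
*w<sub>if</sub>* = its MS intensity over the fraction total. Each property
*x* and assay activity *a* are abundance-weighted per entry
(*w·x*, *w·a<sub>f</sub>*), pooled across all fractions, and tested with
Spearman's rank correlation (mid-ranks for ties, two-sided t approximation).
Fraction-level percentage properties (e.g. % high-MW proteins) are correlated
at the fraction level. All cells of the screen are Benjamini–Hochberg
adjusted as one family, and a cell is **significant iff p_adj < 0.05 AND
|r<sub>s</sub>| > 0.8**.

## Worked example

A complete synthetic study at the default size — 9 fractions with 10, 12, 71,
71, 60, 55, 25, 38 and 6 proteins (348 protein-in-fraction entries), links
planted from molecular weight to the aggregation and adhesion activities:

```bash
stonescreen simulate --seed 42 --out inputs
stonescreen profile --fasta inputs/proteins.fasta \
    --uniprot inputs/uniprot_features.txt --out prof
stonescreen activities --assays inputs/assays.tsv --out act
stonescreen screen --profiles prof/profiles.tsv \
    --abundance inputs/abundance.tsv --assays inputs/assays.tsv --out screen
```

The screen step prints `screen: 26/88 significant correlations` and
`screen/significant.tsv` begins:

```
property           assay        n    rs       p_adj
n_ox_motifs        aggregation  348  0.9354   0.0
n_ox_motifs        adhesion     348  0.9358   0.0
mw_da              aggregation  348  0.8977   0.0
mw_da              adhesion     348  0.9021   0.0
instability_index  aggregation  348  0.9947   0.0
gravy              aggregation  348 -0.9654   0.0
...
```

Every significant cell sits in the aggregation/adhesion columns: the planted
MW link is recovered, and because all abundance-weighted quantities share the
protein weight *w*, the other per-protein descriptors ride along — exactly
the behaviour this design exhibits on real data, which is why the null
false-positive rate is validated separately (see below). `act/activities.tsv`
holds the per-fraction activity panel, e.g. fraction SFQ1: aggregation
+220.3% ± 3.7 (promotion), growth +10.3% ± 1.4, from 3 replicates each.

Outputs are plain TSV plus one `manifest.json` per directory (input SHA-256
checksums, full configuration, tool version); reruns on identical inputs are
byte-identical.

## Caveats

The shipped oxalate-binding motif file is a **synthetic placeholder** — for a
real analysis replace it with the published OxaBIND patterns (every report
records the motif-file checksum). The built-in secondary-structure predictor
is a simple propensity stand-in, not a SOPMA reimplementation; import real
SOPMA output via `stonescreen.import_ss` for paper-grade comparisons. See
`docs/methods.md` for the full model description and limitations.
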