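# dualtcr

Dual-TCR (allelic inclusion) analysis for paired-chain single-cell V(D)J
data.

## The problem

A mature αβ T cell is usually assumed to express one TCR α-chain and one
β-chain, and most single-cell TCR workflows enforce that assumption by
keeping only the most abundant chain per locus. But incomplete allelic
exclusion means a sizeable minority of T cells transcribe two rearranged
*TRAV* or (more rarely) *TRBV* alleles — roughly 10% dual-α and a few
percent dual-β at the mRNA level. These dual-TCR cells are invisible to
standard pipelines, they can be differentially expanded across tissue
compartments, and discarding their secondary chains merges clonotypes and
understates repertoire diversity.

`dualtcr` is a toolkit for researchers working with 10x Genomics V(D)J or
AIRR Rearrangement output who want to quantify this population instead of
filtering it away. It:

1. **classifies** every cell by expressed allele counts — Single TCR
   (1α, 1β), Dual TCRα (2α, 1β), Dual TCRβ (1α, 2β) — while excluding
   2α+2β barcodes, which cannot be distinguished from cell-capture
   doublets, and cells missing a chain of either locus;
2. **defines clonotypes over the full chain multiset** (every retained
   chain, nucleotide-level `locus|V|J|CDR3nt`), so dual and single cells
   never collapse into one clone;
3. **compares clonal expansion** across tissue compartments (peripheral
   blood P, normal adjacent N, tumor T), CD4/CD8 subsets, and phenotype
   clusters with heteroscedasticity-robust statistics implemented from
   first principles: Welch's one-way ANOVA, the studentized-range
   distribution by numerical integration, and Games-Howell pairwise post
   hoc tests;
4. **quantifies diversity underestimation**: richness, Shannon, Simpson,
   and clonality with full dual-aware clonotypes versus clonotypes rebuilt
   from top chains only; and
5. ships a **synthetic repertoire generator** with ground-truth labels
   (configurable dual rates, per-tissue expansion multipliers, doublet
   injection, V-gene pseudogene skew), so the entire pipeline is testable
   without any external download.

## The statistics

For groups \(i = 1..k\) with sizes \(n_i\), means \(\bar{x}_i\), and
variances \(s_i^2\), Welch's ANOVA uses weights \(w_i = n_i/s_i^2\),
\(W = \sum w_i\), grand mean \(\bar{x} = \sum w_i \bar{x}_i / W\), and

    F = [ Σ w_i (x̄_i − x̄)² / (k−1) ] / [ 1 + 2(k−2)/(k²−1) · λ ],
    λ = Σ (1 − w_i/W)² / (n_i − 1),   df₁ = k−1,   df₂ = (k²−1)/(3λ).

Games-Howell compares each pair with SE \(\sqrt{s_i^2/n_i + s_j^2/n_j}\),
Welch–Satterthwaite degrees of freedom, and an adjusted p-value from the
studentized-range upper tail at \(q = t\sqrt{2}\) with \(k\) groups. The
studentized-range survival function is computed by numerically integrating
the classical double integral over the normal range probability and the
chi-based scale density (agrees with `scipy.stats.studentized_range` to
~1e-11 and with a 10⁶-draw Monte-Carlo sampler to <1e-3; both serve only as
test oracles).

## Worked example

Simulate a 20,000-cell repertoire at realistic composition (9.3% dual-α,
3.2% dual-β, 1.7% doublets, dual clones 2× expanded in tissue) and run the
full pipeline:

```sh
dualtcr simulate --n-cells 20000 --seed 1 --out sim/
dualtcr run --contigs sim/filtered_contig_annotations.csv \
            --metadata sim/cell_metadata.tsv --format 10x --out bundle/
```

`bundle/class_proportions.tsv` (the cell-level partition; fractions are over
cells with at least one chain of each locus):

```
stratum  allele_class         n_cells  fraction
all      SINGLE               17145    0.85725
all      DUAL_ALPHA           1880     0.094
all      DUAL_BETA            635      0.03175
all      MULTI_BOTH_EXCLUDED  340      0.017
```

The classifier recovers the simulated composition; the 1.7% of barcodes
with two alleles at both loci are excluded as doublet-indistinguishable.
`bundle/unique_clones_by_tissue.tsv` counts distinct clonotypes per
compartment (a clone spanning tissues counts in each):

```
allele_class  P     N     T
SINGLE        2857  3433  5205
DUAL_ALPHA    298   194   286
DUAL_BETA     106   66    104
```

`bundle/welch_games_howell.tsv` tests mean clone size across allele classes
within each compartment. In tumor, dual clones are significantly more
expanded than single-TCR clones (Welch F = 71.7, p ≈ 3e-24; Games-Howell
single-vs-dual-α p ≈ 2e-13 `***`, single-vs-dual-β p ≈ 1e-8 `***`), while
in blood no contrast is significant — the simulated tissue-restricted
expansion is recovered with the correct significance pattern.

`bundle/dual_drop_diversity.tsv` shows what a top-chain-only workflow would
report on the same cells:

```
keying   richness  shannon   simpson    clonality
full     12549     9.27686   0.999885   0.017011
dropped  12351     9.25318   0.999881   0.017865
```

i.e. discarding secondary chains loses 198 clonotypes (1.6% of richness)
and understates Shannon diversity, and `bundle/usage_TRB.tsv` flags the
pseudogene *TRBV21-1* as 8.5-fold enriched among dual-β clones relative to
single-TCR clones — the signature of a first, failed β rearrangement that
is still transcribed.

The same analysis runs on real data: point `--contigs` at a Cell Ranger
`filtered_contig_annotations.csv` (or `--format airr` for an AIRR
Rearrangement TSV) and `--metadata` at a per-barcode table with
`patient_id`, `tissue` (P/N/T or a mapping), `subset`, and `cluster`
columns.

## Layout

- `src/dualtcr/contig_io.py` — 10x / AIRR ingest, metadata join, writers
- `src/dualtcr/classify.py` — chain filters, per-cell profiles, allele classes
- `src/dualtcr/clonotype.py` — clone keys, clone tables, clone-size samples
- `src/dualtcr/diversity.py` — diversity indices, secondary-chain-drop comparison
- `src/dualtcr/stats.py` — Welch ANOVA, studentized range, Games-Howell, screens
- `src/dualtcr/synthetic_data.py` — repertoire simulator with ground truth
- `src/dualtcr/pipeline.py`, `cli.py` — report bundle orchestration and CLI

See `docs/methods.md` for the model, parameter defaults, and numerical
choices.
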