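# Methods

## Cell classification model

The unit of analysis is the barcode. Each contig row (one assembled chain
observation) passes an acceptance filter before counting as an expressed
allele:

- `frame_policy` — default `productive_only`: only in-frame/productive
  contigs count, matching the convention that a TCR "allele" is a
  translatable rearrangement. `include_nonproductive` is provided because
  transcribed-but-untranslatable rearrangements (pseudogene V segments such
  as *TRBV21-1*, out-of-frame secondary *TRAV*) are biologically real and
  informative about rearrangement history.
- `min_umis` (default 1) and `min_umi_fraction_of_top` (default 0.0) —
  evidence thresholds for secondary chains. The defaults accept any
  productive contig because public V(D)J deposits are typically already
  quality-filtered; both knobs exist for sensitivity analysis on raw data.
- Identical `(locus, V, J, CDR3nt)` observations within a barcode collapse
  with summed UMIs before counting.
- More than two distinct chains at one locus: default `cap_at_two_by_umis`
  keeps the top two (UMIs descending, lexicographic CDR3nt tie-break) so
  that the class partition stays exhaustive; `exclude_cell` instead sends
  the cell to the excluded class.

Classes by (α count, β count): (1,1) Single TCR; (2,1) Dual TCRα; (1,2)
Dual TCRβ; (≥2,≥2) excluded — a 2α2β profile is indistinguishable from a
capture doublet without a probabilistic deconvolution model, which is out
of scope; a count of zero at either locus is Incomplete. Fractions are
reported over cells with at least one chain of each locus: Incomplete
cells leave the denominator (they cannot form an αβ TCR), excluded
multi-both cells stay in it (they are real paired-chain barcodes). With
this denominator the four classes partition the population exactly.

Published estimates of the dual-α cell fraction in the same kind of data
vary between ~9% and ~13% depending on which denominator is used; the
package reports the partition defined above and leaves reconciliation of
differing published denominators to the user.

## Clonotype identity

A clonotype is the multiset of all retained chains of a cell, keyed as the
sorted concatenation of `locus|V|J|CDR3nt` tokens. Consequences: chain
order and UMI counts never affect identity; a dual cell never shares a
clone with a single cell even when their top chains coincide. Nucleotide-
level V+J+CDR3 is the strictest standard convention; `key_mode` offers
`vcdr3nt` (ignore J) and `vjcdr3aa` (amino-acid junction) variants.

Clone sizes are counted within-stratum: a clone with 3 blood cells and 2
tumor cells contributes size 3 to the blood sample and size 2 to the tumor
sample. Unique-clone-per-tissue counts attribute a spanning clone to every
tissue it appears in, so tissue columns need not sum to the overall unique
total. Clones are pooled across patients for size statistics; CD4/CD8 and
phenotype cluster labels come from the supplied metadata and are never
recomputed from expression.

## Secondary-chain-drop comparison

The "dropped" keying emulates workflows that keep only the dominant chain
per locus. The representative chain is chosen **per clone** — highest total
UMIs across the clone's cells, lexicographic CDR3nt tie-break — not per
cell. A per-cell choice would let UMI sampling noise nominate different
top chains in different cells of the same clone, artificially splitting
clones; with the clone-level consensus the drop is a many-to-one map on
clone keys, so dropped richness ≤ full richness holds as a theorem, with
strict inequality exactly when some pair of clones differs only in a
secondary allele. Shannon (nats), Simpson (1 − Σp²), richness, and
clonality (1 − H/ln S, zero when S ≤ 1) are reported for both keyings; no
rarefaction or richness extrapolation is attempted.

## Inference

Clone-size vectors are small-integer, heavily right-skewed, and have very
unequal variances and counts across groups, so classical ANOVA assumptions
fail structurally. The package implements Welch's heteroscedastic one-way
ANOVA, and Games-Howell post hoc tests on the studentized-range
distribution with Welch–Satterthwaite degrees of freedom, directly from
the group summaries (n, mean, unbiased variance). Mean-based comparison of
raw (untransformed) clone sizes is deliberate — it is the field's common
presentation for expansion — and a log transform is available as a config
option. Note that Welch's F does not equal the classical ANOVA F even at
exactly equal variances and sizes: the denominator correction
1 + 2(k−2)/(k²−1)·λ exceeds 1 at any finite n and vanishes as n → ∞.

The studentized-range survival function is evaluated as the outer integral
of the chi-scale density (log-domain for stability) times the inner
normal-range probability, the latter by 160-node Gauss-Legendre quadrature
on z ∈ [−9, w+9]; the outer integral uses adaptive quadrature split at
12 scale-SDs above the mode, with the df > 1e5 limit short-circuited to
the pure normal-range probability. Accuracy is ~1e-11 against an
independent implementation over q ∈ [0.5, 9], k ≤ 20, df ∈ [2, 1000].

Zero within-group variance (all clone sizes tied) is a hard error rather
than a silent fallback, because every statistic above divides by it;
strata with fewer than two clones are emitted flagged untestable. The
per-cluster screen flags a (cluster, dual class) pair only when the
Games-Howell adjusted p (Welch t when only two groups are testable) is
below α = 0.05 **and** the dual/single mean-size fold exceeds 2; no
additional multiple-testing correction is applied across clusters. Star
conventions: * < 0.05, ** < 0.01, *** < 0.001.

V-gene usage is tabulated over unique clones, a dual clone contributing
both V genes at its dual locus; the enrichment readout is the dual/single
frequency ratio per gene, with a small editable pseudogene annotation set
(the member that matters in practice is *TRBV21-1*).

## Synthetic repertoires

The generator emulates the statistical structure the pipeline consumes;
defaults are the composition reported for large pan-cancer T-cell atlases
and are treated as fixed study conditions:

| parameter | default | meaning |
|---|---|---|
| `dual_alpha_rate` | 0.093 | fraction of barcodes that are dual-α cells |
| `dual_beta_rate` | 0.032 | dual-β fraction |
| `doublet_rate` | 0.017 | fraction of barcodes that are merged cell pairs |
| `tissue_mix` | P .25 / N .30 / T .45 | compartment proportions |
| `clone_size_mean` | 1.5 | geometric clone-size mean (cells/clone) |
| `dual_expansion_multiplier` | P 1.0 / N 2.0 / T 2.0 | dual-clone size scaling per tissue |
| `dual_shared_primary_rate` | 0.2 | dual clones whose primary α+β pair coincides with a single clone's |
| `dual_beta_pseudogene_factor` | 10 | *TRBV21-1* weight multiplier in dual-β secondary chains |
| `primary_umi_mean` / `secondary_umi_mean` | 6.0 / 2.5 | shifted-Poisson UMI laws |

Cells are allocated to (tissue, class) strata by a single multinomial
draw, then partitioned into clones by a geometric size law whose mean is
scaled by the expansion multiplier (and optionally a per-cluster
multiplier) for dual classes; the geometric law was chosen for closed-form
expectations in tests. Doublets are created by generating extra cells and
merging uniformly random pairs under one barcode, with class probabilities
rescaled so the expected final composition equals the configured rates.
CDR3 sequences are unique random in-frame nucleotide strings (27–45 nt):
sequence content is irrelevant to every downstream computation, which keys
on identity only. `dual_shared_primary_rate` exists because with fully
unique chains no two clones could ever merge under the secondary-chain
drop; sharing the primary pair with an existing single clone models clone
pairs distinguishable only by their secondary allele. Secondary-chain UMIs
are drawn lower than primary, mirroring reduced expression of the
secondary allele and enabling `min_umi_fraction_of_top` sensitivity tests.

What the simulator does **not** model — and therefore what passing tests
do not demonstrate about real data: transcript dropout (every simulated
cell has complete chains, so Incomplete cells never arise), ambient/chimeric
contigs, sequencing error in CDR3s, per-patient repertoire structure,
V(D)J recombination biology, or any transcriptome. Truth-conditional
classification accuracy is 100% for non-doublet barcodes by construction;
on real data the same classifier inherits the upstream contig caller's
error modes.

## Problem sizes and verification

The bundled verification battery runs on one CPU in under a minute:
composition recovery on 20,000-cell repertoires (binomial-SE bounds),
expansion recovery with a 3× tissue multiplier (ratio within 20%,
Games-Howell significance pattern), statistics oracles (Welch k=2 ≡
squared Welch t at 1e-9; Games-Howell k=2 ≡ two-sided Welch t at 1e-6;
studentized range within 5e-3 of a 10⁶-draw Monte-Carlo sampler; null
type-I rate of Welch's ANOVA within [0.04, 0.06] over 2,000 equal-mean
lognormal datasets with group sizes 200–300, chosen large enough that the
asymptotic calibration of Welch's test applies to skewed data), and the
drop-rule theorem verified against a brute-force re-keying oracle on 100
randomized 300-cell repertoires.

## Known limitations

- No probabilistic doublet deconvolution: 2α2β barcodes are excluded, so
  genuine dual-α+dual-β cells (if they exist) are uncounted.
- Diversity is sample-level; no coverage adjustment across strata of
  different sequencing depth.
- The Games-Howell p-value is exact only under normal group means; for
  very small clone counts per stratum it is approximate, which is the
  standard caveat of the procedure.
- AIRR ingest requires `cell_id`; bulk rearrangement tables are rejected
  by design.
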