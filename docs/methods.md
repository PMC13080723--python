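# Methods

## Scope and data model

`chromsig` scores longitudinal bulk ATAC-seq samples for progress along the
CD8 naive → effector → memory differentiation axis. Its input boundary is a
called peak set (BED), a peak × sample integer count matrix (plain TSV or
featureCounts dialect, detected by the exact header names Chr/Start/End/
Strand/Length), a sample sheet (sample, donor, condition, day, replicate),
gene bodies (BED or GFF3 `gene` records), and a labeled reference expression
matrix with at least one cell per naive/effector/memory state. Everything
upstream — read QC, alignment, deduplication, peak calling — is out of
scope, as are batch correction, Tn5/GC bias and enhancer–gene linking.

All coordinates are held 0-based half-open; GFF3 (1-based inclusive) is
converted once at the I/O boundary (`start−1`, `end` unchanged). Cells in
the reference labeled outside the three required states are retained but
excluded from signature construction.

## Normalization chain

Raw counts pass through five stages in a fixed order, each stamped into a
provenance record:

1. `filter_low_count` — drop peaks whose **raw** mean count across samples
   is below `min_mean_raw` (default 10). The position of this filter (before
   length normalization) and its threshold are configuration; raw-count
   filtering was chosen as the conventional, scale-free option, and the
   removal list is returned so the choice is auditable.
2. `length_normalize` — counts per kilobase of peak, `c/(L/1000)`. The unit
   (kb) is a convention only: any constant factor cancels at the next stage.
3. `mean_scale` — divide each peak's row by its mean across samples, making
   each peak a relative profile with mean exactly 1. All-zero rows are left
   at zero and flagged rather than divided.
4. `library_normalize` — rescale each sample column to sum to
   `library_target` (default 10⁴, arbitrary and configurable).
5. `log_transform` — log₂(x+1), matching the log₂ fold-change conventions
   used elsewhere in the package.

Highly variable peaks are the `n_top` (default 5,000) largest
across-sample variances of the logged values, ties broken by input order.
PCA treats samples as observations and centered (not rescaled) peaks as
features; each component is sign-fixed so its largest-magnitude loading is
positive, which makes coordinates deterministic across LAPACK backends.

## Gene activity and scores

A peak is assigned to a gene iff the intervals share ≥1 bp on the same
chromosome under half-open arithmetic; strand is ignored and a peak may
serve several genes (no exclusive assignment — averaging makes double use
harmless, and multi-gene peaks are countable from the reverse index). The
implementation uses an interval tree but is contractually equal to the
all-pairs definition, which the tests enforce.

Gene activity is the arithmetic mean of the gene's surviving peak values
per sample. By default activity is aggregated from the **raw filtered
counts** — the most literal reading of "average of counts" — with a
configuration switch (`activity_source: logged`) to aggregate the fully
normalized matrix instead; both paths are exercised in the tests.

Δ expression subtracts, per gene, the mean activity of the sample's
baseline group at day 0. The default baseline policy is per condition
(`per_condition_day0`), so every condition's trajectory starts at exactly 0
and conditions are compared by shape rather than offset; `global_day0` is
available when all conditions share one pre-treatment baseline.

Signature weights come from per-state mean profiles of the log-normalized
reference (per cell: log₂(count/cellsum·10⁴ + 1); the base and target only
rescale the weights uniformly). The two scores are inner products of Δ with
`w_eff = effector − naive` and `w_mem = memory − effector`, summed over the
intersection of the activity and signature universes; genes on one side
only contribute zero and are counted in the log. The weights satisfy the
telescoping identity `w_eff + w_mem = memory − naive` exactly, and per-gene
contribution terms `Δ·w` sum to the scores exactly — both are tested as
identities.

The signature universe defaults to all reference genes intersected with the
activity genes. A restriction mode reduces the universe to a rank-sum
marker selection between two labeled groups (fold change ≥ `fc_min`, top
`top_n` by |z|), for workflows where scores should be driven by a curated
marker set.

## Statistical machinery

*Rank-sum screen.* The two-group Wilcoxon rank-sum test uses midranks, the
normal approximation with tie correction, and a signed z (positive = higher
in group A); genes that are constant across both groups get z = 0, p = 1.
The normal approximation is appropriate for the hundreds of cells per group
this screen is meant for; the test suite checks it against exact
permutation enumeration on a small worked case and against
`scipy.stats.mannwhitneyu` on tie-free data. Fold changes are computed on
de-logged means (2^x − 1) with a pseudocount ε = 10⁻⁹ guarding division by
zero. Multiple testing uses Benjamini–Hochberg throughout (verified against
a from-scratch step-up implementation).

*Differential memory contribution.* At a chosen day, each gene's memory
contribution `c_mem = Δ·w_mem` is compared between two conditions with a
per-gene Welch t-test across replicate samples (a rank-sum option is
available), BH-adjusted at α = 0.05. Calls: `high_memory` / `low_memory`
when significant (direction by the sign of the mean difference), else `ns`.
Welch across samples was chosen as the default because groups are small
(donors × replicates) with no variance-equality guarantee; the test choice
is recorded in the output provenance. Note the screen treats samples as
exchangeable within a condition — donor pairing is not exploited, which is
conservative when donor effects are large.

## Synthetic study design

The generator emulates the target experiment: 3 donors × 3 conditions
(untransduced, BATF, BATF3) × days 0/7/14 × 2 replicates over 2,000 genes
(~2.5 peaks per gene inside gene bodies plus 500 intergenic background
peaks on a 3-chromosome synthetic genome), and a 500-cells-per-state
labeled reference over the same genes.

Counts are negative-binomial, `var = μ + φμ²`, with per-peak log-normal
baselines (median 100 counts, log-sd 0.8). Default φ = 0.02 for the bulk
ATAC samples — a between-duplicate coefficient of variation of ~14%,
appropriate for technical-grade duplicates since donor-to-donor variation
is modeled separately as a 10%-CV log-normal donor factor shared across a
donor's samples — and φ = 0.5 for the single-cell reference. Library size
factors are U(0.8, 1.2) per sample; peak lengths U(200, 1000) bp so the
length term of the normalization chain is non-trivial, with the NB mean
scaled by length so longer peaks genuinely collect more reads.

Planted truth: 100 effector genes carry a +2.0 log₂ accessibility pulse at
day 7 (returning to 0 at day 14) in every condition, mirroring a shared
stimulation response; 100 memory genes rise 0 → +0.75 → +1.5 log₂ over days
0/7/14 in the BATF3 condition only. In the reference, effector genes are
+2.0 log₂ in both effector and memory states (accessibility gained in the
transition persists), memory genes +1.5 log₂ in the memory state only. The
ground-truth ledger records every shift, and the count emitter consumes the
ledger's own table, so ledger and emitter agree exactly (tested by
injecting a hook at the NB-mean construction and comparing against an
amplitude-zero run, whose random stream is identical).

What the generator does **not** emulate: fragment-level structure
(nucleosome periodicity, Tn5 insertion bias), GC effects, correlated peaks
within regulatory domains, batch effects beyond donor/library scalars, and
reference cross-contamination between states. Passing recovery tests
therefore demonstrates that the pipeline's algebra and statistics recover
planted signal under realistic count noise and design structure — not that
any particular biological dataset will show these effects.

## Validation quantities

`scripts/acceptance.py` (and the mirror tests in
`tests/test_acceptance.py`) recompute, from scratch at each run:
trajectory recovery over 20 independently seeded studies (memory score
strictly increasing only in the planted condition; effector score peaking
at day 7 everywhere); recall of 100 planted 4-fold markers among 2,000
nulls by the rank-sum + selection rule at 300 cells/group; empirical type-I
error of the rank-sum p-values at α = 0.05 over 2,000 null genes; recall of
planted memory genes and null specificity of the differential-contribution
screen; and byte-identity of a full pipeline rerun under a fixed seed. The
problem sizes match the default study design above; they keep the whole
validation run under a minute on one CPU.

## Numerical and degenerate-input choices

- All-zero peak rows survive mean scaling as zeros (flagged); an all-zero
  sample column is a hard error naming the sample, as is a low-count filter
  that would remove every peak.
- HVP and marker-selection ties break deterministically (input order / gene
  id), so outputs are stable across runs and platforms.
- Result TSVs are written with 6 significant digits and carry a digest of
  the resolved analytic configuration (output paths excluded) in a comment
  header, making artifacts diffable and traceable to the exact chain
  variant.
- The pipeline orchestrator validates configs exhaustively (all unknown
  keys and type errors reported at once) and leaves an `INCOMPLETE` marker
  naming the failing stage if a run aborts.

## Known limitations

- Scores are inner products on unstandardized units, so their magnitude
  depends on the activity scale and universe size; they are comparable
  within a study, not across studies.
- The memory-gene screen's α and test are design choices (Welch + BH at
  0.05 by default); absolute counts of significant genes depend on them and
  on replication depth, so such counts should be read as screen output, not
  as reproducible constants.
- Aggregating raw counts per gene (the default) leaves donor and library
  effects in the activity values; they enter Δ as additive noise and widen
  the per-gene tests rather than biasing between-condition comparisons,
  but a variance-component treatment of donors is out of scope.
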