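# Methods

`cnaclone` infers relative copy-number aberrations (CNAs) from deep
single-cell/single-nucleus RNA expression, detects genetic subclones at
chromosome-arm resolution, and classifies cells as neoplastic or — for
glial cells sharing only the tumor's initiating deletion —
pre-neoplastic. A synthetic-cohort simulator provides ground-truth
inputs for every stage. This note documents the model, the parameters
that matter, and the design choices made where the design was open.

## Matrix construction

Input is a cells × genes TPM-like matrix. Cells are kept when they
express ≥ `qc_min_genes` genes (default 1000) and their mitochondrial
read fraction (genes matching a configurable name prefix, default
`MT-`) is strictly below `qc_max_mito` (default 0.30). Values are
transformed to `log2((TPM/10) + 1)`; genes with mean log expression
strictly greater than 4.5 across the cells *of the matrix at hand* are
kept; each gene is then mean-centered. Two readings of the gene filter
are defensible — mean of log values versus log of mean TPM; we use the
mean of the log values, matching the order in which the transform and
the filter are applied. Filtering and centering are per assembled
analysis matrix (one patient's target cells plus the reference), not
per cohort, so the surviving gene set and the zero point both depend on
the cells being analysed — this is intentional: the reference cells
participate in defining "normal" for that patient's matrix.

Manually curated removals (doublet clusters, low-quality
microenvironment cells) are not re-derived; an exclusion list
reproduces them, and `preprocess.cell_accounting` reconciles the
resulting cohort sizes.

## Pooled reference

Because individual samples may lack sufficient stromal cells, a pooled
reference is built once: from every donor with at least
`ref_min_cells` (15) fibroblasts, endothelial or adrenocortical cells,
exactly `ref_sample_n` (15) cells of that type are sampled uniformly
without replacement. The per-donor cap prevents any donor from
dominating the envelope (a batch-effect guard). Sampling iterates in
sorted (type, donor) order under a fixed seed, so the reference is
reproducible. An alternate per-patient mode — the patient's own stroma
plus glia from normal tissue — is assembled through the same
`assemble_patient_matrix` interface by passing a different reference id
set; including normal glia in the reference absorbs glia-specific
transcriptional programs that would otherwise read as copy-number
events in glial cells.

## CNA inference

On the assembled, filtered, centered matrix:

1. genes are reordered by genomic position (chromosome, start; gene id
   breaks coordinate ties);
2. centered values are clipped to ±`clip_bound` (3), limiting the
   leverage of extreme single-gene observations;
3. a centered moving average of up to `window` (100) genes is taken at
   each position, truncated at chromosome boundaries (windows never
   span chromosomes; whether they should span centromeres is
   underdetermined — we let them, as arms are not separated in the
   gene ordering, and account for the resulting bleed below);
4. for each reference cell type, the mean smoothed profile is computed
   per position; at each position the maximum of these type means is
   subtracted from positive cell values and the minimum from negative
   values. A value whose sign flips carries no evidence beyond the
   normal envelope and is set to zero;
5. values strictly inside (−`noise_floor`, +`noise_floor`) (0.15) are
   zeroed. The band is open: boundary values of exactly ±0.15 are kept.

The envelope subtraction makes the procedure self-calibrating in a way
worth spelling out: per-gene centering shrinks a clonal event's
centered amplitude by the carrier fraction (carriers sit at
−e·(1−f), non-carriers at +e·f for a deletion of effect e carried by
fraction f of the matrix), but the diploid reference cells carry the
same +e·f offset, so subtracting the reference envelope restores
nearly the full effect in carriers and cancels it in non-carriers.

Degenerate inputs: an all-reference matrix yields an (almost) all-zero
CNA matrix; a window of 1 is the identity smoothing; unannotated genes
are dropped with a warning, and inference refuses to run if fewer than
half the genes are annotated.

## Subclone detection

Positions are ranked by mean |CNA| across cells and the top 2/3 kept
(ties broken by genome order) — cells must all remain for clustering,
so the reduction acts on positions. Cells are then overclustered: PCA
(≤20 components) embeds the reduced matrix, a k-nearest-neighbour
graph (k = 15) is built, and Leiden community detection
(RBConfiguration, resolution 0.5, seeded) produces the initial
partition. Arm events are called per cluster on the *full* CNA matrix
(mean over cells × arm positions; < −0.15 deletion, > +0.15
amplification, strict), and clusters with identical event profiles
across all arms are merged iteratively until all remaining profiles
differ on at least one arm. The loop strictly reduces the cluster
count, so it terminates in at most `initial_clusters − 1` rounds.

The embedding and the community-detection flavour are implementation
details; the testable surface is clone recovery, not coordinates. The
resolution default (0.5) reflects a known failure mode of
overclustering a denoised CNA matrix: at high resolution the graph
partition can group cells *by* their correlated smoothed-noise
excursions, and such a cluster's arm mean can cross the ±0.15 event
threshold, leaving a spurious subclone that the merge step (which
requires exact profile identity) cannot remove. A mildly
over-segmenting initial partition keeps per-cluster arm means averaged
over enough cells that noise stays inside the floor, while the merge
loop still does the clone-defining work.

## Neoplastic and glial classification

Per cell, *CNA signal* is the mean of absolute CNA values over the
cell's own top 20% of positions by |CNA| (ties by genome order), and
*CNA correlation* is the Pearson correlation (all positions; rank
correlation would be a one-line change) between the cell's profile and
the tumor profile — the average profile of the top 20% of candidate
tumor cells ranked by CNA signal (ties by cell id). Cutoffs for both
metrics are median + 2 sample SDs (n−1) of the reference cells, and
only cells strictly above both are malignant. The decision is
metric-based: a reference cell exceeding both cutoffs is flagged.
Both choices that were open — per-cell versus global top-20% gene
sets, and all-position versus reduced-position correlation — default
to the per-cell and all-position readings.

Glial (Schwann/sustentacular) cells are compared with the tumor's
arm-event profile (called on the malignant neuroendocrine cells). An
event is shared when arm *and* direction match at the same ±0.15
threshold. No shared event → non-neoplastic; shared set equal to the
tumor set → full match; a nonempty proper subset — canonically a lone
3p deletion, the second hit inactivating the remaining *VHL* allele —
→ pre-neoplastic. An empty tumor event set classifies all glia
non-neoplastic with a warning.

## Differential expression

Cluster-specific DEGs: per focal cluster, a two-sided Wilcoxon
rank-sum test per gene against every other cluster,
Bonferroni-adjusted within each comparison over the genes tested (the
matrix's post-4.5-filter genes); significant-up means adjusted
p < 0.05 and log2FC strictly > 0.5, with log2FC the difference of
group means in log2((TPM/10)+1) space; the specific set is the
intersection of up-lists over all pairwise comparisons. The rank-sum
p-value uses the exact permutation null when both groups are ≤25 cells
and no value is shared across groups (within-group ties leave the
statistic unchanged), otherwise the tie-corrected normal
approximation.

Recurrent pairwise DE: for a focal sample against each other sample
separately, a two-sided Welch t-test (the unequal-variance form is the
robust default where the test flavour was unspecified) with unadjusted
p; genes with log2FC ≥ 1 and p < 0.05 in *every* comparison are
recurrent.

## Synthetic cohorts

The simulator emulates multi-donor Smart-seq2-like cohorts with
neuroendocrine, Schwann/sustentacular, fibroblast, endothelial and
adrenocortical compartments. Per gene, a baseline log2 mean is drawn
Normal(5, 2) — leaving on the order of 60% of genes above the 4.5
filter; each cell type adds a diffuse program, per-gene offsets drawn
Normal(0, `type_effect_sd` = 0.2), the phenomenon the reference
envelope exists to absorb. Planted events shift all genes of an arm by
±`effect` log2 units in carrier cells, with carriers sampled per
(donor, type) at the configured fraction (count = round(fraction ×
group size)); Gaussian log2-space noise (`noise_sd`, default 0.6, a
residual-technical-noise level for deep nuclei after TPM
normalization) is added, then values are back-transformed through the
inverse of log2((TPM/10)+1) and floored at zero TPM. Optional
stressors, both defaulting to off: per-cell depth factors
(2^Normal(0, `depth_sd`)) and Bernoulli dropout. Depth defaults to
zero deliberately: TPM is depth-normalized by construction, and a
per-cell depth offset survives centering and smoothing
indistinguishably from a whole-genome event — no step of the method
calibrates it away.

The default genome is a miniature: five chromosomes, ten arms,
2240 genes (150–260 per arm; 3p carries 150, the event arm of the
canonical scenario). Arms are sized so that after gene filtering every
arm still spans well over one 100-gene window; with materially smaller
arms the window's bleed across a centromere becomes a large fraction
of the neighbouring arm and arm-level calls blur — a genome property,
not a tuning knob, since real chromosome arms carry hundreds of
expressed genes.

The canonical scenario (`vhl_like_cohort`) is a single donor with 300
tumor cells all carrying a 3p deletion (the second hit) plus a 1q
amplification (a later progression event), 200 glia with 10% carrying
the 3p deletion alone, and 40 cells of each stromal type, at
`noise_sd` 1.0 and effect 0.6. The tumor must carry at least one event
beyond 3p for "pre-neoplastic" to be a proper-subset status at all.

What the simulator does *not* emulate — transcriptome-wide
co-expression, cell-cycle structure, dropout-depth coupling,
allele-specific expression, batch structure beyond donor identity —
bounds what passing tests show: they validate the algorithmic chain
(calibration, smoothing, event calling, merging, classification)
under known truth, not robustness to every artefact of real tissue
data.

## Problem sizes and determinism

Default analyses run a 620-cell × 2240-gene cohort per scenario and
20 replicates for null calibration; these sizes make every stage's
behaviour measurable while keeping the whole suite and the
reproduction script fast on a single CPU. All randomness flows from
explicit seeds: the simulator from `CohortSpec.seed`, reference
sampling and clustering from their own seeds, and the pipeline fans a
single global seed out to per-stage seeds by hashing the stage name,
so results are reproducible stage-by-stage and bit-identical on
re-run.

## Known limitations

- Relative, not absolute, copy number: a near-clonal event in *all*
  profiled cells would be partially absorbed into the reference
  envelope only if the reference carried it too; conversely events in
  the reference cells corrupt the envelope.
- Arm-level resolution only; focal events smaller than the smoothing
  window are diluted below the noise floor.
- The ±0.15 floor and thresholds are calibrated for ~100-gene windows
  and deep data; shallow droplet data would need larger windows or a
  glia-inclusive reference (the per-patient mode).
- Exact-identity merging cannot repair a cluster whose spurious arm
  call crossed the threshold; the resolution default mitigates but
  does not eliminate this.
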