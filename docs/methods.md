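# Methods

This note documents the statistical procedures implemented in `tilseq`, the
assumptions behind them, the defaults that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Repertoire diversity and clonality

A repertoire is the set of unique productive TRB rearrangements in one
sample. Records are aggregated by CDR3 nucleotide sequence; non-productive
rearrangements (out-of-frame or containing a stop, flagged by the export's
status column or by `*`/`_`/non-standard letters in the protein sequence)
are retained for QC but excluded from all statistics, and frequencies are
always recomputed from read counts over productive records — file-supplied
frequencies are never trusted.

Diversity is summarized as Shannon entropy H = −Σ pᵢ ln pᵢ over unique
productive clonotypes, normalized entropy H/ln U, and clonality
1 − H/ln U. Natural logarithms are used internally; the normalized quantity
is base-invariant. Two conventions required a decision:

* **U = 1.** Normalized entropy is 0/0; we define clonality = 1, the limit
  as a second clone's frequency vanishes.
* **Similarity denominator.** "Shared unique sequences as a fraction of the
  total unique sequences in the two samples" can be read as the deduplicated
  union or the sum of the two unique counts. The default is the union
  (Jaccard); `denominator="sum"` is available. The two differ by at most a
  factor of 2 and induce the same sample ordering.

Sequence identity is case-insensitive with whitespace stripped. Records
with ambiguous nucleotides (N) are kept but excluded from nucleotype
analyses.

## Cross-tissue clone tracking

Within a patient, clonotypes are keyed by CDR3 amino-acid sequence (bulk)
or by the exact TRA/TRB amino-acid pair (single cell); cells with identical
TRB but different TRA are distinct clonotypes. A clone is *detected* in a
tissue at ≥ 1 read (configurable — there is no principled sequencing-floor
value, and 1 read is the most inclusive choice; raising it guards against
index hopping). The seven patterns (TUMOR, NAT, PBMC, TN, TP, PN, ALL)
partition the non-empty subsets of assayed tissues; patients missing a
tissue carry a `tissues_assayed` field so ALL is never claimed from two
tissues. Expansion is strict: tumor frequency > 0.01.

## Annotation, control library, public clones, convergence

Database matching is exact on the CDR3 protein sequence (optionally also
V/J); no fuzzy matching is attempted, so annotated fractions are lower
bounds. Control-library prevalence requires a donor-wise library (donor_id,
sequence); prevalence = carrier fraction of donors, and patient-unique means
prevalence 0. Public clonotypes require > 10 cells in at least one tumor
(implemented ≥ 11) and sharing by ≥ 10 patients. Convergent recombination
is called when ≥ 2 distinct nucleotide sequences encoding the same protein
each have ≥ 2 supporting cells/reads — the support floor prevents a single
sequencing artifact from creating a spurious nucleotype. Case/control
frequency contrasts are ratios of mean frequency among carrier samples;
sequences with no control carriers are reported with an infinite ratio and
excluded from aggregate means.

## Specificity grouping (simplified)

The full GLIPH2 machinery (Fisher enrichment against a naive reference,
V-gene bias correction, length modeling, HLA partitioning) is out of scope;
what downstream analysis consumes is the *group-size structure* per tissue,
which a much simpler construction already exposes. Motifs are interior
k-mers (first/last 3 residues trimmed; k ∈ {3, 4}) carried by ≥ 3 distinct
CDR3s; with a background repertoire, a motif must additionally be ≥ 10-fold
enriched in per-sequence carrier rate (pseudocount 1 on the background
carrier count — so a small background cannot certify large folds). Groups
are connected components over shared-motif edges plus equal-length
Hamming-distance-1 edges. All thresholds are configurable; none are
calibrated to any external tool's settings. Group identifiers are canonical
(named for the lexicographically smallest member), making output invariant
to input order.

## Single-cell integration

Cells with more than one distinct TRA or TRB CDR3 are removed as putative
doublets before pairing; cells with exactly one of each get a pair key.
Counts are library-size normalized to 10,000 per cell and log1p-transformed
(the conventional default; nothing downstream depends on the exact target
sum), and genes are z-scaled across cells for scoring.

* **Lineage.** CD4 ⇔ raw CD4 ≥ 1 and CD8A+CD8B < 1; CD8 symmetric; both →
  double positive (DP); neither → unassigned. The positivity floor of one
  raw count is deliberate and configurable: any higher floor discards real
  DP cells at typical 10X depths.
* **Phenotype.** Score(phenotype) = mean z-scaled log-normalized expression
  over that phenotype's markers; argmax wins if it beats the runner-up by a
  margin (default 0.05 z-units); zero-count cells and cells with no present
  markers are unassigned. The packaged marker table
  (`data/marker_genes.yaml`) uses compact, near-disjoint signatures for
  naive / T_scm / T_cm / T_em / T_eff / Th1 / Th2 / Th17 / T_reg and can be
  replaced wholesale. Protein aliases (TIM3, PD1, CD25, TNFSR9) are mapped
  to HGNC symbols internally.
* **Markers.** Per cluster versus rest: candidate genes must be expressed in
  ≥ 25% of the cluster's cells with |ln fold-change| ≥ 0.25 (Seurat-style,
  on expm1 of the log layer); candidates are tested by Wilcoxon rank-sum
  and BH-adjusted per cluster. Clusters of < 3 cells are skipped.
* **Gene sets.** Exhaustion {ICOS, HAVCR2, CTLA4, PDCD1, LAG3, TIGIT},
  activation {TNFRSF9, CD69, IL2RA}, effector {GZMB, PRF1, IFNG}; the score
  is the mean log-normalized expression; group contrasts use Welch t.
* **Bulk reconciliation.** Pearson r between bulk clonotype frequencies and
  single-cell cell fractions matched on the TRB protein sequence, reported
  on both raw and log10 scales (which scale the original comparison used is
  not determinable, so both are exposed); < 5 matches is an error.

## Spatial profiles

Cell tables are point sets in µm with boolean marker calls; the tumor
border is a polyline with a polygon marking the tumor side. Signed distance
is Euclidean distance to the nearest border segment, negative inside.
Density profiles use 50 µm bins over ±500 µm (both configurable). Bin areas
are obtained by deterministic grid sampling of the tissue mask at 5 µm
pitch rather than exact polygon clipping: it is exactly reproducible, free
of geometric edge cases, and its discretization error is < 1% for bins
larger than 0.01 mm², which is below the Poisson noise of any realistic
cell count. Density × area therefore reconstructs in-range counts exactly.
Infiltration calls compare mean density inside versus outside with a ±10%
dead zone (ratio in [0.9, 1.1] → indeterminate) so that sampling noise on a
flat profile does not force a directional call. Analyses are strictly 2-D;
no section-thickness correction is applied. CD4⁺CD8⁺ spatial cells (an IHC
thresholding artifact at some rate) are counted in both lineage classes and
flagged.

## Synthetic data generator

The generator emulates the statistical structure of a multi-platform
nephrectomy study; its defaults are the study conditions the test suite and
acceptance script run under.

* **Clone abundances** follow a normalized Zipf law over ranks (default
  exponent 1.1 over 500 clones/patient), giving a dominant clone in the
  5–25% range — the heavy-tailed, dominant-clone regime observed in
  clear-cell tumors. A log-normal alternative was considered and rejected
  as it adds a parameter without changing any tested behavior.
* **Tissue occupancy** is drawn per clone from a 7-way pattern probability
  vector; per-tissue reads are multinomial at depth 10⁵ per tissue.
* **Sequences.** CDR3 proteins are V-prefix + i.i.d. interior (from a fixed
  beta-chain-like amino-acid frequency table) + J-suffix; interior motif
  families are planted by substring insertion; nucleotide sequences come
  from random codon choice, with 10% of clones planted with two distinct
  nucleotypes (convergent recombination).
* **Cells.** 1,500 cells per tissue per patient (4,000 for the bulk-vs-sc
  depth experiment); 54.6% of cells carry both chains; 3% receive a second
  TRA/TRB pair (doublets); double-positive lineage is planted inside CD8
  clones at tissue-dependent rates yielding ~2.2% DP overall with ~83% of
  DP cells in tumor. Expression counts are Poisson draws from log-normal
  intensities (base ln-mean 2.0 per gene, cell–gene noise sd 0.2) on a
  300-gene universe containing all marker and gene-set genes; a cell's
  phenotype markers are elevated 2-fold, and exhaustion genes of
  tumor-restricted clones are shifted +1 ln-unit. The noise level is the
  generator's realism dial and is set so the marker-score classifier meets
  its stated ≥ 90% recovery contract at the 2-fold elevation.
* **Spatial.** Inhomogeneous Poisson points over a 2 × 1 mm rectangle with
  a straight (default) or sinusoidal border; class-specific inside/outside
  intensities (CD8 default 500:100 per mm², a 5× contrast); Ki67 positivity
  Bernoulli(0.15) per T cell; CAIX⁺ tumor cells fill the tumor side.
* **Control screen.** 55 donors; exactly 63.9% of expanded tumor clones are
  withheld from every donor (patient-unique), the rest planted into
  1 + Binomial(54, 0.2) donors. The public-clone cohort plants 4 sequences
  in 10–14 of 53 patients with > 10 cells in the top tumor, plus
  threshold-adjacent near-misses.

Everything is driven by one integer seed through independent
`SeedSequence` streams per stage, so outputs are byte-identical across runs
and platforms.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: V(D)J recombination biology (no gene-segment
usage, no junctional insertion model), sequencing error beyond multinomial
sampling, ambient RNA and empty droplets, batch effects, cell-type
composition shifts between tissues beyond the planted pattern/phenotype
structure, and any spatial correlation beyond the two-intensity border
model. Recovery results certify the *implementations* against known truth,
not the biological fidelity of any upstream pipeline.

## Problem sizes

The default test/acceptance conditions are 3 patients × 500 clones at depth
10⁵ per tissue, 13,500 cells × 300 genes, and spatial fields of 10³–10⁴
points; recovery experiments use 5–20 replicates. These sizes put Monte
Carlo error well inside every tested tolerance while keeping the full suite
in the tens of seconds.

## Known limitations

Exact-match annotation understates database overlap relative to fuzzy
matchers; the specificity module makes no claim of GLIPH2 output
equivalence; marker finding uses a single test (Wilcoxon) rather than a
model-based framework; the spatial module consumes segmented cell tables
and performs no image processing; and pipeline outputs are plot-ready
tables — no figures are rendered.
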