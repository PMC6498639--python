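# Methods

## The classification model

A small-scale duplication on the focal lineage turns one ancestral gene
into a parent copy P (the ancestral locus) and a child copy C.  The
single remaining copy A of the family in a sister species serves as a
proxy for the ancestral expression state.  All comparisons are made on
log2(TPM+1) profiles over the same ordered tissue list (nine grass
tissues by default).  Genes with log2(TPM+1) < 1 in every tissue are
treated as transcriptional noise and removed before any distance is
computed; a trio is classified only if parent, child and ancestral proxy
all survive this filter.  Retention requires ≥ 1 in at least one tissue,
i.e. the boundary is inclusive.

Three Euclidean distances are computed per trio: E_P,A, E_C,A, and
E_P+C,A, where the combined profile is formed by summing the two copies'
**raw TPM** per tissue and re-applying the log transform.  Summing on the
raw scale is the physically meaningful operation (transcript abundances
add) and makes the combination collapse exactly to the parent profile
when the child is silent; summing log values would not.

The divergence cutoff E_div is calibrated from the distances between
single-copy ortholog pairs of the two species (E_S1,S2): these pairs span
the same evolutionary divergence as a conserved duplicate copy and its
ancestral proxy, so their distance distribution is the natural null for
"no functional change".  The default is the empirical 0.95 quantile,
exposed as primary configuration (`q`) and recorded in every result;
a fixed cutoff can be supplied instead.  The rule table (≤ E_div means
"not diverged" in every comparison) is exhaustive and mutually exclusive
over non-negative distances, and raising E_div can only move trios toward
conservation, never away from it.

Neofunctionalization polarity (which copy diverged) is read from the
distance comparison itself and reported alongside the independent
parent/child polarity call, so "neofunctionalization of the child" is a
join of the two annotations.

## Parent/child polarity

Each ortholog-evidence source votes for the copy it links to the
ancestral gene; a source linking both or neither abstains.  Strict
majority wins; ties fall to the highest-priority source (default
OrthoMCL > i-ADHoRE > TribeMCL); pairs with no informative source are
excluded rather than polarised at random, because polarity errors
corrupt the parent/child asymmetry statistics downstream.  With three
sources each independently wrong at rate ε, majority voting recovers the
true parent at rate (1−ε)³ + 3ε(1−ε)².

## Family-size reconstruction

Ancestral family sizes are reconstructed by asymmetric Wagner parsimony:
a Sankoff dynamic programme over integer copy-number states 0..max_count,
where a +k change along a branch costs k·gain_penalty and a −k change
k·loss_penalty.  The defaults (gain 2, loss 1) encode that independent
gains are rarer than losses; both penalties are configuration, and
results — in particular how many events are attributed to deep branches —
depend on them.  Ties among co-optimal states are broken toward the
smaller copy number: conservative against phantom ancient copies and
deterministic.  max_count defaults to the family's maximum observed
count; with positive penalties larger states are never optimal (checked
against exhaustive enumeration in the tests).

SSD candidates are harvested from designated branches where a family
goes 1 → 2 and the designated sister species retains exactly one copy;
families violating the simple-pair pattern (1 → 3, multi-copy sister,
missing gene ids) are skipped with explicit reasons.  Events on
root-adjacent branches are inherently confounded with a root-state
change plus loss and cannot be polarised by parsimony on any penalty
setting; the synthetic species tree therefore embeds the focal/sister
pair among 14 outgroups so ~93% of single-gain events are recoverable.

## Duplication mechanism

A pair is RNA-mediated (retroposition) when the parent has multiple
exons and the child exactly one, DNA-mediated when both have multiple
exons, and unknown when both are single-exon.  A single-exon parent with
a multi-exon child matches no rule; it is left unknown and counted
separately rather than forced into either class, which would bias the
enrichment test.  Exon counts come from the representative transcript of
each gene, defined as the mRNA with the most exons (ties broken by
genomic span) — the choice that maximises the sensitivity of the
multi-exon criterion when a gene has several isoforms.

## Statistics

Expected counts for a mechanism × category table multiply each row total
by the pooled category proportions, so row totals are preserved exactly.
Each row is tested with a χ² goodness-of-fit statistic, no continuity
correction, df = cells − 1; this construction reproduces the published
two-decimal P-values from the published observed counts exactly.  Tissue
enrichment uses the exact two-tailed binomial test in the
small-probability-outcome convention (the sum of probabilities of all
outcomes no more likely than the observed one), with trials = number of
duplicates, success probability = the tissue's frequency among
single-copy genes, and Bonferroni factor = the number of tissues tested
(taken from the data, not hard-coded).  Pearson correlations between
expression divergence and Ka, Ks, Ka/Ks are assessed with Student's t,
t = r√(n−2)/√(1−r²); records with Ks ≥ 3 are excluded first to avoid
synonymous-site saturation.  Correlations default to one record per
duplicate copy.

τ (tissue specificity) is Σ(1−x_i)/(N−1) with x_i normalised by the
profile maximum; it is computed on log-transformed values, consistent
with every other expression computation in the pipeline (raw-scale
computation would only change τ through the monotone transform; the log
default keeps one scale throughout).

## The synthetic study

The generator emulates the statistical structure of the real inputs with
known truth.  Defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_tissues | 9 | the nine assayed tissues |
| n_single_copy | 3000 | ortholog pairs for calibration (matching the ~3000 filtered 1:1 orthologs per species pair in real data) |
| n_trios_per_mechanism | 100 | 400 trios total |
| sigma_o | 0.5 | per-observation log2 noise; gives single-copy distances centred near 1–3 with a 0.95 quantile ≈ 2.8 |
| delta | 2.5 (5·sigma_o) | minimum planted divergence of a diverged copy |
| drift_share | 0.7 | fraction of a duplicate pair's divergence variance shared between copies |
| concentration | 0.5 | Dirichlet tissue-weight concentration (sparsity / τ distribution) |
| rna_fraction | 0.1 | single-exon (retroposed) children |
| evidence_error | 0.05 | per-source polarity corruption rate |
| gain_rate / loss_rate | 0.01 / 0.02 | per-branch family-size event probabilities |

Ancestral profiles are sparse log-normal mixtures (total abundance
log-normal, spread by Dirichlet weights).  Orthologs and duplicate
copies add truncated Gaussian noise on the log scale.  For duplicate
pairs, 70% of the divergence variance is a lineage component shared by
both copies: young conserved duplicates retain a common cis-regulatory
state at birth and experience the same trans environment (and gene
conversion), so their profiles are strongly correlated.  The marginal
divergence of each conserved copy from the ancestral proxy still follows
the single-copy calibration distribution — the shared component only
correlates the two distances of a pair.

Mechanisms are planted exactly as classified: conservation adds noise
only; neofunctionalization re-draws one copy and pushes it to at least
delta from the ancestor; subfunctionalization partitions the ancestral
raw-TPM profile complementarily between the copies (tissues alternated
by abundance rank, so the pre-noise sum reconstructs the ancestor
exactly — this doubles as the identifiability check for the combined-
profile rule); specialization re-draws both copies with the combined
profile also forced beyond delta.  Subfunctionalization ancestors are
re-drawn until the second-ranked tissue carries ≥ 15 TPM, since a gene
expressed appreciably in fewer than two tissues cannot be
subfunctionalized observably.

Ka and Ks are log-normal draws correlated with each copy's realized
expression divergence (log-scale target correlations 0.45 and 0.40);
the Ka/Ks ratio then correlates weakly positively (~0.1) as an emergent
property, and ~4% of records receive Ks ≥ 3 to exercise the saturation
filter.  Age classes are assigned uniformly and independently of
mechanism — a null construction, so age-class tests on synthetic data
should be non-significant.

What the generator does **not** emulate: read-level quantification noise
and mapping ambiguity between paralogs, cross-species normalisation
artefacts, expression-level dependence of noise (variance is constant on
the log scale), correlated tissue structure (tissues are exchangeable),
and any sequence-level realism.  Passing recovery tests therefore shows
that the pipeline's logic and calibration are correct under the stated
noise model, not that real grass duplicates are classified with the same
accuracy.

## Calibration behaviour and known limitations

- Conserved-copy distances follow the calibration distribution by
  construction, so conservation recall is bounded by P(both distances ≤
  the 0.95 quantile) ≤ 0.95; with the shared-drift correlation it
  averages ≈ 0.92 at 100 trios, making it (with subfunctionalization)
  the most seed-sensitive class.
- The combined profile of a subfunctionalized pair compounds the
  positive (truncated) measurement noise of both copies in ancestrally
  silent tissues, so E_P+C,A sits stochastically slightly above the
  single-copy distribution; subfunctionalization recall averages ≈ 0.92
  and its failures are marginal E_P+C,A exceedances misread as
  specialization.
- The χ² null-calibration check draws category labels independently of
  rows with a **known** probability and tests each row against its true
  expectation.  The pipeline's plug-in construction (expectations
  estimated from the pooled table including the tested row) deflates the
  statistic by roughly (1 − n_row/N) and is therefore mildly
  conservative; the calibration check isolates the statistic itself.
- Wagner penalties are configuration, not estimated from the data;
  likelihood-based gain/loss rate inference is out of scope.
- Per-species cutoffs, real PLAZA/Expression Atlas inputs, and Ka/Ks
  estimation from sequences are outside the package; divergence values
  are consumed as a precomputed table.
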