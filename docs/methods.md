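# Methods

This note records the models, conventions and numerical choices behind
`tfactnet`, and what the synthetic benchmark does and does not establish.

## Information-theoretic GRN inference

**Model.** Gene expression profiles are treated as discrete random
variables over cells. For a candidate regulator R and target T, the
dependence I(T;R) may be shared with other genes; the inference asks how
much of it is *unique* to R. For each third gene P the decomposition

    I(T; R, P) = Unq(T;R) + Unq(T;P) + Rdn(T;R,P) + Syn(T;R,P)

is resolved with the Williams–Beer redundancy: per target outcome t the
smaller of the two sources' specific informations, averaged under p(t),

    Rdn(T;R,P) = Σ_t p(t) · min( I_spec(t;R), I_spec(t;P) ),
    I_spec(t;R) = Σ_r p(r|t) log2[ p(t|r)/p(t) ]  =  KL(p(r|t) ‖ p(r)) ≥ 0.

The pair score sums the unique fraction over all n−2 partners,
`PUC(R;T) = Σ_P [I(T;R) − Rdn(T;R,P)] / I(R;T)`, so PUC ∈ [0, n−2]. The
redundancy (hence PUC) is direction-dependent; when a regulator is also
in the target set the two directional scores are averaged, which keeps
the score well-defined for TF–TF pairs. Final weights are
`W = [F_R(PUC) + F_T(PUC)]/2` with F_X the empirical CDF ("fraction ≤")
of all scores involving gene X, guaranteeing W ∈ (0, 1] with the maximum
at exactly 1.

**Discretization.** Per gene, k equal-width bins over its observed range
of log-normalized expression, k = round(√m) by default (m = cells).
Bins are half-open with the last closed; values on an interior boundary
go right. A binary on/off mode (nonzero count) is available for very
sparse data. Constant genes occupy one bin and carry zero entropy.

**Numerics.** All entropies in bits; the unique *fraction* is base-
invariant. MI below 1e−12 is snapped to exactly 0 so the guarded
division `PUC ≡ 0 when I(R;T) = 0` also fires on float-noise MI;
negative Unq from float error is clipped at 0. The triplet loop is
O(n²·(n−2)·k) time and O(n²k) memory for the specific-information
tensor; a warning is emitted above 2,000 genes — the intended inputs are
TF panels plus variable genes, not whole transcriptomes.

## Prior evidence weights

- *Curated*: convex combination `(K_p S_p + K_m S_m + K_t S_t)/(K_p+K_m+K_t)`
  with defaults K=1 and scores S_p(n) = min(n,5)/5 (publication credit
  saturating at five), S_m = 1.0 / 0.6 / 0.3 for targeted / high-
  throughput / unknown assays, S_t = 1.0 / 0.7 / 0.3 for physical-direct /
  functional / unknown interaction types. The exact functional forms are a
  package choice (monotone-saturating credit, higher trust for targeted
  assays); all are pluggable.
- *ChIP-seq*: `Σ_i exp(−d_i/(k·D_TF))` over a TF's binding sites near a
  gene, with D_TF the TF's median site–TSS distance and scale k = 1. The
  normalization by a per-TF median makes TFs with broad vs sharp binding
  comparable; the decay form is the only dimensionally sensible reading
  of a distance-ratio exponential. Site–TSS distances use 0-based
  half-open coordinates, site midpoints, nearest TSS, strand ignored.
- *Motif*: `sqrt(phastcons · max(phylop, 0) · (−log10 p))` on matches
  pre-filtered to p ≤ 1e−4; negative phyloP (faster-than-neutral) is
  floored at zero rather than allowed to flip the sign under the root.
- *Knockout DE*: datasets are trusted only when the knocked-out TF is
  itself significantly down (p < 0.05, logFC < −1); within them, targets
  with p < 0.05 and |logFC| > 1 get weight −log10(p) (the sign makes
  weight increase with significance; a raw log10 would do the opposite).

Each source is min–max scaled to [0, 1] before integration, so the
logistic fusion `W = σ(a₀ + Σ aᵢ wᵢ)` treats sources uniformly. Defaults
a₀ = 0, aᵢ = 1 — no fitting is attempted; per-source overrides are
exposed. By default the prior sources define the candidate edge
universe and the GRN only modulates weights (the integration exists to
suppress expression-only false positives); `grn_only_edges=True` admits
GRN-only edges.

## Regulon calling

Per TF the integrated target weights (after the per-TF cap of 2,000) are
fitted by a normal (ML/population sd) and truncated at the upper
q-quantile, q = 0.01 (threshold μ + 2.3263σ). This presumes a
bulk-plus-small-tail weight distribution; degenerate cases (σ = 0, < 3
targets, or fewer survivors than the minimum regulon size of 10) fall
back to the top-10 by weight. The truncated list is then tested against
the TF's GRN ranking (genes the GRN never scored get statistic 0, ties
on gene id) with a weighted KS running sum, exponent 1 on |stat|; the
regulon is the leading edge — members at or before the maximum positive
deviation. Significance is plain Monte-Carlo over random same-size gene
sets with the add-one correction; the adaptive multilevel estimation of
extreme tails is deliberately not replicated because regulon calling
consumes the leading edge, not tail-precise p-values, and enrichment p
is not used as a filter by default. Note that with all-positive ranking
statistics the null ES of random sets is positively biased (top-ranked
genes carry larger step weights); under equal statistics the running sum
is a symmetric bridge and the null ES is centered at zero — the
calibration tests use that symmetric regime.

## Activity engines

All three engines see expression only through per-cell ranks (average
ranks on ties), so any strictly increasing per-cell transformation of
the data leaves scores unchanged.

- *Analytic rank enrichment* (default): ranks → quantiles t = rank/(n+1)
  → normal scores q = Φ⁻¹(t); `NES = Σ wᵢqᵢ / √(Σ wᵢ²)` with regulon
  likelihood weights w. One-tailed: regulons carry positively regulated
  targets only, no repression mode. Under exchangeable ranks NES is
  standard normal; at small panels the discrete quantile grid and
  without-replacement sampling shrink the sd below 1 (≈ 0.93 at 100
  genes), so null calibration holds at transcriptome-like panel sizes.
- *ssGSEA*: genes sorted descending; in-set steps proportional to
  (descending-rank value)^α (α = 0.25), out-of-set steps uniform; score =
  sum of the running difference. Cross-cell min–max normalization is off
  by default since the specificity layer re-normalizes.
- *AUCell-style*: `AUC = Σ_{k≤K} r(k) / (K·|regulon|)` with r(k) the
  regulon count among the top k genes and K = ceil(0.05·n).

## Cell-type specificity

The activity vector is min–max scaled and normalized to a probability
vector r (constant vectors become uniform — no preference, maximal
entropy); the ideal pattern r_c is uniform over the type's cells. Both
normalizations are required for the Jensen–Shannon divergence to be
defined; JSD is computed in bits so CSS = 1 − √JSD ∈ [0, 1], with 1 for
an exact indicator and 0 for disjoint support. The bootstrap p is the
fraction of label shuffles whose CSS exceeds the observed one (10,000 by
default; an optional add-one correction keeps p > 0 but is off so the
raw shuffle fraction is reported). "percent" — the detection-style
fraction — is the share of the type's cells whose activity exceeds the
TF's across-cell median. BH adjustment spans all (TF, type) pairs of a
run. Default significance thresholds: CSS > 0.3, adjusted p < 0.05,
percent > 0.1 — all configurable.

## Pathway enrichment

Jaccard similarity with an exact hypergeometric upper-tail p on the
overlap, universe = measured genes (not the genome); terms filtered to
10–2000 members after intersecting with the universe; BH within each
regulon. Redundancy collapse: average-linkage clustering on 1 − Jaccard
between enriched term gene sets, cut at 0.7 (an artifact choice — the
cut trades granularity against redundancy), smallest-p term per cluster
as representative, ties to the smaller term id.

## Perturbation benchmark

Arm QC uses Welch's unequal-variance t-test on the targeted TF's
log-normalized expression versus control, requiring p < 0.05 and logFC
(difference of log2 means) below −1 for knockouts (above +1 for
overexpression), and at least 10 cells per arm. AUROC is the tie-
corrected rank-sum statistic over the arm's cells plus the control cells
only, with control as the positive class for knockouts and labels
reversed for overexpression. Dropout corruption zeroes exactly
⌊ratio·g·m⌋ uniformly chosen matrix positions — already-zero entries
count toward the quota, so the increment in observed zeros is below the
nominal ratio — and recomputes the log-normalized layer.

## Synthetic data: what it emulates, what it does not

The generator draws a ground-truth network (TFs with disjoint-by-default
target blocks, edge weights U(0.5, 1)), latent per-cell TF activities
(base 0, shift δ where active, −δ in a TF's knockout arm), per-gene
baselines U(−1, 1), negative-binomial counts (variance μ + φμ², φ = 0.3)
scaled to a mean library size of 5,000, and Bernoulli dropout (10%
default). Two designs: a CRISPR-style screen (one control plus one
knockout arm per TF; all TFs active outside their own knockout arm, so
the TF's own transcript drops together with its targets — the assumption
the arm QC encodes) and a cell-type design (each TF active in one type).
The measured panel additionally carries unregulated background genes
(150 by default at the 5 TF × 30 target scale): real matrices are
dominated by genes outside any studied regulon, and without that bulk
the per-TF integrated weight distribution would be mostly tail, which no
upper-quantile truncation can represent. Prior corruption drops true
edges per source with probability fnr and adds false edges to a fraction
fpr of the source, weights = true weight plus U(0, 0.5) noise, min–max
scaled.

The benchmark harness admits GRN-only edges into the integration
universe: the corrupted prior's support is mostly true-positive by
construction, unlike real curated priors whose support is mostly
inactive in any one dataset, and admitting expression-derived candidates
restores the realistic bulk-plus-tail weight shape.

What passing means: the chain can recover planted regulons and activity
shifts through substantial count noise, dropout and prior corruption at
these effect sizes. What it does not establish: performance under batch
effects, correlated (non-independent) prior errors, overlapping regulons
with repression, doublets, or real dropout structure (expression-
dependent rather than uniform); and the synthetic effect size δ = 2 on
the latent log scale is generous relative to many real perturbations.

## Benchmark problem sizes

The knockout recovery benchmark uses the full stated design (5 TFs × 30
targets, 200 cells/arm, 3 prior sources at fpr = fnr = 0.2, 5 seeds).
The dropout-robustness sweep runs a reduced configuration (5 TFs × 10
targets, 60 cells/arm, 50 background genes, 10 seeds × 4 ratios) — the
claim it checks is a qualitative rank trend (median AUROC non-increasing
in dropout), which is insensitive to the panel scale, and the smaller
panels keep the 40-run sweep brisk.

## Determinism

Every stochastic step (GSEA permutations, bootstrap shuffles, synthetic
generation, dropout masks) takes an explicit seed; the pipeline derives
per-TF and per-pair seeds from one master seed, and repeated runs are
byte-identical. The implementation is single-threaded NumPy throughout,
so results cannot depend on scheduling.

## Known limitations

- Repression is out of scope: regulons carry positively regulated
  targets and the activity engines are one-tailed.
- The triplet decomposition is cubic in panel size; use gene panels.
- The normal-fit truncation misbehaves when high-weight targets are a
  large fraction (> ~15%) of a TF's candidates; the min-size fallback
  then caps the regulon at 10.
- Bootstrap p-values can be exactly 0 at finite shuffle counts unless
  the add-one correction is enabled.
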