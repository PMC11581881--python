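# Methods

## Scope and data model

`ssnlet` operates on four inputs: a gene × sample FPKM matrix, per-cytosine
bisulfite coverage (Bismark coverage dialect), a GFF3 gene annotation, and a
STRING-style PPI edge list, together with a sample sheet assigning each
sample to ground control (GC) or spaceflight (SF) and, for SF samples, the
LET of the heavy ion that hit it. LET is the regression target throughout;
a flown-but-unhit sample has LET = 0, which is distinct from the *absent*
LET of a GC sample (encoded as NaN, never 0). All matrices are oriented
genes × samples and all genomic coordinates are 1-based inclusive.

## Methylation quantification

The promoter of a gene spanning [s, e] is the strand-aware upstream window
([s − u, s − 1] on +, [e + 1, e + u] on −) with u = 2000 bp by default; the
gene body is the annotated span. Windows are clipped at the chromosome
start rather than dropped (a gene starting inside the first u bases keeps
its truncated promoter; a gene starting at position 1 has an empty window
and an undefined level). The level of a region pools read counts over all
covered cytosines first and divides once:

    ML = Σ mC / (Σ mC + Σ umC)

i.e. deeply covered cytosines weigh more than shallow ones, and the value
is invariant to uniform count rescaling. CpG/CHG/CHH contexts are pooled —
the coverage dialect consumed here does not distinguish them. A region with
no covered cytosines is missing (NaN); because the correlation and network
stages need complete vectors, a gene missing in *any* sample is dropped
from that methylation layer (the count is logged). A sample with zero
covered cytosines genome-wide is treated as a corrupt input, not as data.

## Single-sample networks

The aggregate network over the N samples of a stage/layer is the all-pairs
Pearson correlation matrix; LIONESS attributes to sample q the linear
extrapolation

    w_q(i,j) = N · r_all(i,j) − (N − 1) · r_without_q(i,j),

which requires N ≥ 4 so every leave-one-out correlation is defined on ≥ 3
samples. A pair involving a zero-variance gene takes r = 0 (logged), a
convention that keeps the construction total; NaN would silently poison
every downstream degree. Networks are built jointly on GC + SF samples of a
stage — the degree fold change needs GC degrees, and the per-layer network
counts (25 expression, 11 methylation in the emulated design) correspond to
the GC + SF totals.

Weighted networks are binarized by intersection with the PPI network: an
edge survives iff it is a PPI edge and |w| ≥ τ. τ (default 0.5) is an
explicit, user-visible stand-in for a sparsification rule that the SSN
literature leaves to the practitioner; overlap is monotone in τ (edge sets
only shrink), which the tests assert. Degrees are integers bounded above by
the gene's PPI degree; a gene absent from a network contributes degree 0,
and a gene in no network of the layer gets no row in the degree matrix.

## Fold change and screening

Level-mode fold change divides each SF value by the GC mean; genes whose GC
mean is zero are dropped from that FC matrix (logged) — the minimal rule
that keeps every downstream formula defined. Degree-mode adds one to every
degree before forming the ratio, so it is always finite and positive, and
equals exactly 1 when an SF degree matches the GC mean. Genes expressed in
no sample at all are removed before any network or FC computation.

A gene is *LET-related* when its FC vector correlates with the SF LET
vector: |PCC| > 0.5 and p < 0.05 in level mode, p < 0.05 in degree mode.
The p-value is the standard two-sided t test with n − 2 df (numerically
identical to the textbook t = r·√((n−2)/(1−r²)) transformation, asserted to
1e-12 in tests). No multiple-testing correction participates in the hit
rule — the thresholds are deliberately the raw ones — but a
Benjamini–Hochberg column is emitted alongside for the reader.
Cross-omics annotation correlates each gene's expression level (or degree)
with its promoter/body methylation level (or methylation degree) over the
samples both assays share — all shared samples by default, SF-only behind a
flag since including controls is a judgement call.

## Regression and the genetic algorithm

The LET model is multiple linear regression fitted by OLS; with up to 50
features and ~21 training samples the design can be rank-deficient, in
which case the minimum-norm least-squares solution is used (the fit is
total and the overfitting it implies is left visible in the cross-validated
score rather than masked). Fitness of a gene subset is the leave-one-out
cross-validated R² pooled over held-out predictions — a single R² per
model, with the Pearson correlation between actual and predicted LET
reported alongside.

GA mechanics: initial subset sizes uniform on [1, 50]; tournament selection
(size 3; roulette available behind a config switch); crossover pools the
*union* of both parents' genes and draws the offspring size uniformly from
[1, 50] if the pool exceeds 50, else from [1, m] — so no individual can
ever leave [1, 50]; mutation removes one gene uniformly and adds one gene
drawn from outside the pre-mutation individual (the removed gene cannot
return, guaranteeing a real change; if the individual already spans every
feature it is returned unchanged). Elitism (default 1) makes the best-so-far
fitness monotone. Defaults — population 100, 200 generations, crossover
0.8, mutation 0.2 — are conventional GA settings; the seed is mandatory and
every run is bit-reproducible from (inputs, config). Fitness values are
cached per subset, which changes nothing statistically.

## Synthetic data generator

The generator emulates the study design it stands in for: 3 GC + 22 SF
expression samples with the 22 measured LET values (0–250.8219 keV/μm,
including a flown-unhit sample at 0), methylation for 3 GC + 8 SF samples,
and two planted signals. Expression: per-gene log-normal baselines;
planted genes respond multiplicatively, `baseline · (1 + β·LET/LET_max)`,
with β drawn from [0.5, 2] and i.i.d. log-normal noise (σ = 0.1 by
default) on every value — multiplicative noise because FPKM is nonnegative
and heavy-tailed. Methylation: per-region binomial read counts (depth 30,
10 sites per region) whose success probability is constant per gene except
for planted genes, where it follows a logistic-affine function of the
gene's standardized log-expression — so planted methylation–expression
correlations exist by construction. The PPI is a preferential-attachment
graph (every gene non-isolated). What the generator does *not* emulate:
mapping artifacts, count overdispersion beyond log-normal, bisulfite
conversion error, LD-like co-expression blocks among null genes, or batch
effects — so green recovery tests certify the pipeline's statistical
machinery, not its behavior on real sequencing data.

## Numerical choices

Zero-variance Pearson pairs → r = 0 (networks) or NaN + non-hit
(screening, where a constant FC vector is reported, not hidden). Degree
ties in hub ranking: the top-k cut includes every gene tied with the k-th
degree, and ordering is (degree desc, gene id) for determinism. Matrix
round trips are bit-exact: floats are written with Python's shortest
round-trip rendering and parsed with a correctly-rounded reader. Pipeline
manifests record parameters, seed, per-stage tallies and SHA-256 checksums
of every output, and contain no timestamps, so identical config + seed
yields byte-identical manifests.

## Known limitations

With 22 SF samples and hundreds of candidate features, *model selection
overfits the selection criterion itself*: any ~20 features interpolate each
21-sample training fold, and searching tens of thousands of subsets finds
combinations of pure-noise genes whose pooled LOOCV R² approaches 1 —
higher than the truth subset's honest ~0.87–0.94 under the default noise
level. Consequently near-perfect R² values at this sample size should not
be read as generalization error estimates, and the GA-selected set is not
guaranteed to contain the truly responsive genes when redundant or noisy
alternatives score better; in seeded reference runs the selector recovers
between 1/5 and 4/5 of the planted genes depending on the seed while
always reporting R² ≥ 0.999. The screening stage, by contrast, recovers
planted genes exactly in the noiseless limit and reliably under default
noise. Nested (double) cross-validation or stability selection would be the
remedy, but both change the method and are out of scope. Other limitations:
Pearson-only association (no rank correlation), no context-stratified
methylation, no DMR calling, and enrichment analysis is left to external
tools (gene lists are emitted in plain text).
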