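# Methods

`phylorobust` implements a comparative robustness workflow for molecular
phylogenies: instead of producing one tree, it measures how conclusions
change as a dataset is manipulated in the ways practitioners actually
manipulate deep, rate-heterogeneous datasets — stripping fast-evolving
sites, removing long-branched and positionally unstable taxa, and adding
environmental sequences — and provides the statistics used to compare the
resulting reconstructions.  This note records the models, the estimators,
the numerical choices, and what the synthetic data do and do not emulate.

## Substitution models and likelihoods

Likelihoods use reversible Markov models: GTR (or any sub-model) for
nucleotides and the published LG/WAG empirical matrices for amino acids.
The rate matrix is Q = S diag(pi), rescaled so that the expected
substitution rate at stationarity is 1; branch lengths are therefore in
expected substitutions per site.  Among-site rate variation follows a
discrete-gamma model with k equal-probability categories of Gamma(alpha,
alpha); category rates are the **category means** (Yang's 1994 mean
method), not the medians, matching the behaviour of the common ML tools.
With k = 1 the single rate is 1 for any alpha.

Per-site likelihoods come from Felsenstein pruning, computed for all k
categories simultaneously and marginalized with a uniform category prior.
Transition matrices use the symmetric eigendecomposition
diag(sqrt(pi)) Q diag(1/sqrt(pi)); per-node partial vectors are rescaled by
their per-site maximum with log accumulators, so hundreds of taxa do not
underflow.  Gap, `?`, and `N`/`X` characters are marginalized (partial
vectors of ones); IUPAC ambiguity codes set their compatible states.  An
all-gap column has log-likelihood 0 by construction.  Correctness is
checked against exhaustive enumeration of internal-node states on 4-5-taxon
instances (1e-10) and by the pulley principle: rerooting a reversible-model
tree anywhere leaves every site likelihood unchanged (1e-9).

## Site-rate classification and stripping

Rate classification is empirical Bayes: with a fixed tree and model, each
column's posterior over the k categories is L_{c,j} / sum_m L_{c,m}
(uniform prior).  Columns are assigned by MAP, with ties broken toward the
slower class; class 0 is the slowest, class k-1 the fastest.  Two
consequences worth knowing:

* the **posterior-mean rate** is a shrinkage estimator — it tracks the
  true rate's rank well (Spearman >= 0.8 at 16 taxa x 1000 sites,
  alpha = 0.5) but is biased toward 1;
* MAP assignment typically leaves some slow middle classes **empty**: an
  invariant column's likelihood peaks at the slowest category, and a
  column with a single change already jumps several classes up.  Mean true
  rates still increase strictly across the populated classes.

Branch lengths are taken from the supplied tree and not re-optimized, and
the GTR parameters for classification are either user-supplied or a simple
one-pass surrogate (empirical frequencies, unit exchangeabilities); only
the gamma shape is estimated, by bounded Brent search (tolerance 1e-4).
An alignment with no rate-variation signal pins the shape to the lower
bound, with a warning.  Stripping removes the selected classes' columns,
by default only from the nucleotide partition — the protein partition of a
concatenated dataset is left intact — and per-column source indices are
preserved so stripped alignments remain traceable.

## Tree statistics

**Treeness** is the fraction of total branch length in internal edges,
computed on the unrooted topology (a root bifurcation is merged first so
the value does not depend on file rooting).  **Root-to-tip lengths** root
the tree at the midpoint of the outgroup's stem edge — the edge subtending
the outgroup clade as written, so a tree already rooted on its outgroup
keeps the written stem length — and long-branch screening ranks ingroup
taxa by root-to-tip length averaged over the supplied reconstructions.

**Leaf stability** for taxon X averages, over quartets {X, a, b, c}, the
margin f1 - f2 between the two most frequent of the three unrooted quartet
resolutions across the tree set.  This "difference" variant is the
default; "max" (f1) and an entropy-based variant are available behind a
flag, since the classical definitions come in several forms.  Quartets are
scored per tree from topological (unit-length) leaf distances via the
four-point condition, which is exact for binary trees and abstains on
unresolved quartets; trees missing any of the four taxa are skipped for
that quartet, and frequencies renormalize over the trees that resolve it.
Exact enumeration is used up to 2e6 quartets; beyond that, a stratified
sample of 1000 quartets per taxon (seeded) replaces it.  The sampled
estimator agrees with exact enumeration to well under 0.02 on the report
mean at m = 2000; per-taxon values carry sampling noise of ~0.01 at that
m.  The report's 95% CI is computed **across taxa** (normal
approximation), matching how a single CI per reconstruction is usually
quoted; a CI across bootstrap replicates would be a different quantity.

**Clade support** is bipartition frequency: the percentage of trees in
which the hypothesis members present in that tree form one side of a
split; trees with fewer than two members are skipped, and the complement
of a single taxon is trivially supported.  The support table renders each
hypothesis x reconstruction cell as a rounded integer percent, `nm` when
the members are present but non-monophyletic in that reconstruction's best
tree (regardless of replicate frequency), or `-` when fewer than two
members are sampled.  The majority-rule consensus includes splits with
frequency strictly above the threshold (>= 0.5, hence compatible) and
attaches the frequencies as supports.

## Topology tests

The test battery works entirely on a candidates x sites matrix of per-site
log-likelihoods.  RELL replicates draw columns with replacement — one
shared multinomial draw across candidates per replicate, which preserves
the correlation structure of the log-likelihood differences.

* **Weighted KH** tests candidate i against the ML candidate with the
  replicate-sd-standardized observed difference against its centered RELL
  null, one-sided.  (For a fixed pair the standardization cancels, so the
  weighted and unweighted pairwise p-values coincide.)
* **Weighted SH** uses the same observed statistic but a null that takes
  the maximum standardized difference over all candidates (including the
  zero own-term).  Because the SH null event contains the KH event
  replicate by replicate, p_wsh >= p_wkh holds exactly, by construction.
* **AU** fits the multiscale-bootstrap model: bootstrap probabilities of
  being best at ten scales r = 0.5..1.4 are probit-transformed and
  regressed on d sqrt(r) + c / sqrt(r) by weighted least squares with
  binomial-variance weights; p_au = 1 - Phi(d - c).  Probabilities of 0 or
  1 at a scale get the continuity correction 1/(2B); a candidate that is
  never (always) best at every scale is reported as p = 0 (1) with a
  degenerate-fit flag.  Replicate ties split their "best" count equally,
  so two identical candidates get p_au = 0.5 exactly.

Degenerate zero-variance differences (identical candidates) give p = 1 for
KH/SH by convention.  Under an exchangeable two-candidate null the
one-sided wkh rejection rate of a fixed candidate is alpha by symmetry
(the candidate is non-best half the time, and conditional on that its
p-value is uniform on [0, 1/2]); the acceptance suite verifies the
empirical rate stays within [alpha/2, 2 alpha] at alpha = 0.1.

## Stand-in inference

The pipeline's built-in inference is neighbour joining on Jukes-Cantor
distances with a column-resampling bootstrap.  It is a deliberately simple,
fast, deterministic stand-in that exercises the comparative machinery; the
experiment configuration accepts externally inferred tree files (ML or
Bayesian) per variant instead.  Distances are JC-corrected per partition
alphabet (s = 4 or 20) on the columns shared by each pair and combined
weighted by shared-column counts; saturated pairs are capped at a
configurable maximum (default 5 substitutions/site) with a warning.  NJ
uses Studier-Keppler updates; negative branch-length estimates are clamped
to zero with the deficit moved to the sibling edge, preserving the pair's
summed length.  The implementation is cross-checked against dendropy's NJ
(same unrooted topology) in the tests.

## Dereplication

Pairwise identity is global alignment with match 1, mismatch 0, affine
internal gaps (open -5 covering the first gap position, extend -1) and
free terminal gaps; identity = matches / aligned columns, excluding
terminal-overhang columns.  When several alignments tie on score the most
favourable identity (most matches, then fewest columns) is reported, so
the value is well-defined.  Dereplication is single-pass greedy: scanning
in input (or length-descending) order, a sequence is retained iff its
identity to every retained sequence is below the threshold (default 0.98);
the cluster map records which representative absorbed each discard.

## The synthetic data

`make_dataset` emulates the statistical structure the pipeline assumes:

* a clock-like pure-birth ingroup tree (default 40 taxa) rescaled to a
  mean root-to-tip depth of 0.5 substitutions/site, with a single
  root-adjacent outgroup attached at the same tip height;
* a 1000-column nucleotide partition under an HKY-style GTR
  (kappa = 4, frequencies 0.30/0.20/0.25/0.25) with gamma shape 0.5 in 8
  categories — strong among-site heterogeneity — and a 300-column LG
  protein partition, mirroring a concatenated rDNA + protein design;
* long-branch taxa: 4 taxa with terminal branches scaled x10 *before*
  sequences are evolved, so they genuinely accumulate substitutions;
* rogue taxa: 4 taxa with 75% of their characters replaced by uniform
  random states.  There is no canonical generative model for rogueness;
  this signal-erosion operationalization makes bootstrap placement
  unstable through the data, while `inject_rogue` offers the alternative
  tree-level operationalization (prune-and-regraft onto a random branch
  with probability p per replicate).

What the generator does **not** emulate: alignment error and ambiguous
regions (masking is accepted as an input site list, never inferred),
indels, compositional heterogeneity across lineages, heterotachy, and
paralogy in the protein partition.  Passing tests therefore show the
machinery is correct and well-calibrated under the stated model, not that
any particular empirical dataset satisfies that model.

## The experiment grid

`run_experiment` derives the standard eight variants from one base
dataset: `base`, three stripping levels (`-7`, `-76`, `-765`, removing the
fastest one/two/three classes from the nucleotide partition), `-LB`
(remove the n longest-branched taxa), `-us` (remove the n most unstable),
`-LB-us` (their union) and `+Env` (add a 0.98-dereplicated pool of
nucleotide-only copies, the protein block gap-filled).  Removal lists are
frozen from the **base** variant's trees before any derived variant is
built; classification likewise uses the base best tree.  Each variant is
re-inferred (200 bootstrap replicates by default) and scored by tree
length, treeness, mean leaf stability ± 95% CI, and the support table.
All randomness derives from per-operation streams seeded as
(seed, crc32(operation-name)), so runs are bit-reproducible and adding a
stage never perturbs another stage's draws.

On this generator, rate-stripping levels give strictly decreasing
nucleotide widths and non-increasing tree lengths, and removing the
injected long-branch and rogue taxa raises mean leaf stability relative to
the base variant — the qualitative behaviour the comparative design is
meant to detect.  The default problem sizes (40 taxa, 1000 + 300 sites,
200 bootstrap replicates; smaller fixtures in unit tests) were chosen as
the smallest grid on which these contrasts are unambiguous.

## Known limitations

* The NJ stand-in underestimates support for short internal edges compared
  to ML bootstrap; ingest externally inferred trees for real analyses.
* Quartet resolution uses topological distances, so zero-length internal
  edges in *binary* trees still count as resolved.
* The AU implementation uses a fixed default scale set and a single WLS
  fit; it does not iterate scale refinement the way dedicated tools do.
* Greedy dereplication is order-dependent by design (that is the
  documented semantics); `length-desc` ordering is available when a
  canonical order is preferred.
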