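# Methods

`lcaroot` implements a diagnostic and mitigation protocol for long-branch
attraction (LBA) at deep phylogenetic splits, together with the numerical
machinery it rests on: supermatrix editing, a pruning-likelihood engine,
exhaustive small-tree maximum-likelihood (ML) search, and rooting via a
marginal ML ancestral sequence reconstructed on a star tree. This note
documents the models, the parameters that matter, the numerical choices, and
what the synthetic experiments do and do not show.

## The problem and the protocol

When an ingroup contains one fast-evolving lineage and the only available
outgroups are highly divergent, the fast branch can be drawn toward the
outgroup/root, producing a spuriously basal placement. The protocol probes a
dataset with four parallel analyses:

* **A — full supermatrix, outgroup rooting.** Exhaustive ML search over all
  taxa; the tree is rooted on the outgroup's pendant edge (midpoint).
* **B — singleton pruning + outgroup removal.** Alignment columns in which at
  least one sequence carries a *private* character state (a state found in
  exactly one sequence) are removed, then the outgroup is dropped and the
  remaining taxa re-analyzed unrooted. Singleton removal homogenizes branch
  lengths: most of the fast lineage's private states disappear.
* **C — strain deletion variants.** When the fast lineage is represented by
  two near-identical strain sequences, states unique to the lineage but
  carried by both strains are invisible to singleton detection. Deleting one
  strain (each in turn) and re-pruning exposes them; the two 4-OTU analyses
  check that the fast lineage's placement is stable either way.
* **D — LCA rooting.** The outgroup is discarded entirely. Branch lengths of
  a star intree over the ingroup *lineages* are ML-optimized — when a strain
  pair is declared it stays resolved as a cherry inside the star, so the two
  near-identical sequences speak through one stem instead of casting two
  independent votes at the central node — the marginal posterior of the
  ancestral state at the central node is computed per site, and the
  maximum-a-posteriori (MAP) sequence — the ingroup's own last common
  ancestor — replaces the outgroup in a fresh exhaustive search on the
  *unpruned* ingroup alignment. The tree is rooted on the LCA tip. Because
  the intree presumes no relationships among lineages, the reconstruction is
  agnostic about the very hypothesis being tested.

The report compares rooted ingroup clades between A and D and records each
analysis's alignment length (pruning can only shorten: A >= B >= each C).
Order of operations in B/C: singletons are detected on the full supermatrix
for B; the C variants start from B's pruned alignment, drop one strain, and
re-prune. This guarantees the length ordering and matches the rationale that
strain deletion *exposes* previously shared private states.

## Substitution models

Time-reversible models on 4 (nucleotide) or 20 (amino acid) states:
`Q_ij = S_ij * pi_j` off-diagonal, rows summing to zero, rescaled to one
expected substitution per site at equilibrium. Shipped families:

* **LG** — the Le–Gascuel (2008) empirical amino-acid exchangeabilities and
  frequencies, packaged in PAML `lg.dat` layout (`data/lg.dat`).
* **GTR** — 6 nucleotide exchangeabilities (GT fixed as reference; 5 free).
* **JC** — the analytic special case used for closed-form tests.

Extensions: `+G<k>` discrete-Gamma rate heterogeneity (k equal-weight
categories whose rates are the means of Gamma(alpha, alpha) over equiprobable
quantile bins; k = 4 by default, the field standard), `+I` a proportion of
invariant sites, `+F` empirical state frequencies (zero counts floored at
1e-6 and renormalized so Q stays irreducible). `+I` is implemented as a
rate-0 category with weight `p_inv`, the Gamma rates scaled by 1/(1 - p_inv)
so the mean rate stays 1; because P(0) = I exactly, this reproduces the usual
invariant-site shortcut, including its interaction with gaps, without a
special code path. The same category machinery feeds the ancestral
posteriors, so the invariant category is mixed into ASR by its posterior
weight.

Transition probabilities use the pi-weighted symmetric eigendecomposition
(`D^{1/2} Q D^{-1/2}` is symmetric), which is numerically exact for
reversible Q; negative round-off entries are clipped to zero and P(0) returns
the exact identity.

Ancestral reconstruction could in principle use a general reversible
amino-acid matrix with all 189 exchangeabilities free (REVaa, as offered by
CodeML); those are not identifiable from a handful of OTUs at this scale,
so this package uses LG exchangeabilities throughout (the same family its
tree inference uses) and treats full REVaa estimation as out of scope.

## Likelihood engine

Felsenstein pruning over unique site patterns (columns are compressed once
per alignment and shared across candidate topologies). Gap and ambiguity
symbols contribute flat partial likelihoods. Per-node log-scaling guards
against underflow; it switches on automatically above 10 tips — for the
small trees this package targets, double precision cannot underflow (tip
contributions are bounded below by transition probabilities at the branch
bounds), and with scaling off an impossible column correctly yields -inf.

Branch lengths are optimized coordinate-wise within [1e-8, 20] expected
substitutions/site. The per-edge objective is evaluated in the eigenbasis:
with outside partial F and inside partial G for an edge, the per-site
likelihood at length t is `sum_j exp(lambda_j r t) (F~ . G~)_j`, so a scalar
search per edge costs one small matrix-vector product per evaluation. Each
cycle refreshes all directional partials once and sweeps every edge against
them (Jacobi style); a cycle that fails to improve the exact log-likelihood
is redone edge-by-edge with fresh partials (Gauss–Seidel), so accepted steps
never decrease the likelihood. Convergence: gain < 1e-6 per cycle, cap 50
cycles; these tolerances (and all others here) are engineering choices
exposed as keyword arguments.

Exhaustive topology search ranks all (2n-5)!! unrooted topologies (hard cap
n <= 8) with a cheaper coarse schedule — per edge, the best of ~24
log-spaced candidate lengths evaluated in one vectorized pass, plus a
parabolic refinement in log-length, for two cycles — then re-optimizes the
top 3 to convergence with the exact scalar search. Ranking is by
log-likelihood with ties broken by lexicographic canonical Newick, so the
output is a strict deterministic ranking even on uninformative data.

Model parameters (Gamma shape in [0.02, 100] on log scale, p_inv in
[0, 0.99], GTR exchangeabilities on log scale) are fitted by bounded scalar
or L-BFGS-B searches interleaved with branch-length cycles. AIC model choice
uses `AIC = 2k - 2 lnL` with k counting free model parameters plus free
branch lengths; ties prefer fewer parameters.

Branch support is the nonparametric bootstrap: columns resampled with
replacement to the original length, full exhaustive re-search per replicate,
support = fraction of replicate best trees containing each internal
bipartition of the reference tree. The bootstrap was chosen over the other
common support measures (SH-like aLRT as in PhyML, Bayesian clade
posteriors) because exhaustive re-search makes it exact and self-contained
at this scale; bootstrap proportions are not numerically comparable to
either alternative.

## Synthetic data

The simulator draws, per site, a rate category and a root state from the
equilibrium frequencies, then propagates states along branches with the
model's transition probabilities — sites i.i.d., gapless output, no indels,
no codon models, no rate drift along lineages. Simulator and estimator share
their model family deliberately, so parameter- and topology-recovery
experiments are well posed.

The canned LBA scenario emulates the study design: four ingroup lineages,
the fast one represented by a two-strain cherry (near-identical sequences,
default divergence 0.01 substitutions/site), plus one distant outgroup
attached at the ingroup root. Default geometry, in expected
substitutions/site:

| parameter          | default | meaning                                   |
|--------------------|---------|-------------------------------------------|
| `short_branch`     | 0.1     | pendant edges of ordinary lineages        |
| `long_branch`      | 1.0     | pendant edge of the fast lineage          |
| `outgroup_distance`| 2.0     | outgroup pendant edge                     |
| `internal_branch`  | 0.01    | internal ingroup edges                    |
| `strain_divergence`| 0.01    | distance between the two strain tips      |
| `n_sites`          | 5000    | alignment length                          |
| model              | LG+Gamma(alpha=1) | generating process              |

The internal edges are an order of magnitude shorter than the pendant edges:
the scenario models a deep, *rapid* radiation, which is where outgroup
placement carries little signal and attraction to the longest branch can
dominate. With internal edges as long as the pendant ones, exhaustive ML
recovers the generating topology essentially always at these alignment
lengths and no attraction occurs — a useful negative control, reachable by
setting `internal_branch = short_branch`.

The protocol's Monte-Carlo experiments infer under **LG+F with equal rates**
while the generator uses LG+Gamma. This underfitting is intentional: ML
long-branch attraction is a model-misfit phenomenon, and inference under a
model simpler than the generating process is the situation every real
analysis is in (empirical alignments violate LG+G+I+F too, e.g. through
site-specific amino-acid preferences that no +Gamma model captures). With
the matched model the attraction largely disappears at these simulation
settings — which is a statement about this simulator, not about real data.

What passing these experiments shows: the pipeline reproduces the
*direction* of the study's findings under a controlled misfit — the fast
lineage lands basal more often under outgroup rooting than under LCA
rooting, and singleton-pruned taxon-deletion analyses recover the true
sister grouping more often than the full outgroup-rooted analysis. What it
does not show: magnitudes comparable to the study's real alignments (whose
branch lengths and misfit structure are unknown), or robustness to
violations the simulator cannot produce (indels, heterotachy,
compositional drift).

## Numerical and design choices

* **Singleton detection with gaps:** gap/ambiguity symbols are transparent —
  never private themselves and never blocking another state from being
  private. Conservative: alignment uncertainty is not treated as signal.
* **Coordinates:** 0-based half-open column intervals internally; 1-based
  inclusive in human-readable reports.
* **Singleton pruning is single-pass** by default, matching a one-shot edit
  of a fixed alignment; repeated application (to a fixed point) sits behind
  `repeat=True`. One pass is *not* idempotent in general.
* **LCA sequence = per-site MAP state** (not a posterior draw or averaged
  profile), ties broken by alphabet order and flagged in the profile.
* **Star branch lengths are ML-optimized before ASR**; the reconstruction
  uses the same model family as tree inference, with empirical (+F)
  frequencies by default.
* **Analysis D uses the unpruned ingroup alignment** — the outgroup is
  replaced, not singleton-pruned; the pipeline enforces the pairing.
* **Rooting convention:** the root splits the chosen pendant edge at its
  midpoint; for reversible models this is display only (pulley principle).
* **Determinism:** every stochastic step takes an explicit seed; traversal
  and tie-break orders are fixed by the deterministic postorder of the
  input tree and lexicographic canonical Newick strings.

## Known limitations

* Star-based rooting places the root near the ingroup's *distance balance
  point*: the optimized star center is pulled toward tight clusters of
  tips, so the LCA tip attaches where distances balance, not necessarily at
  the historical root. Concordance with (artifact-free) outgroup rooting is
  therefore expected when the true root lies at or near the balance point —
  balanced radiations, or the long-fast-branch regime where excluding the
  attraction is what matters — but not for strongly asymmetric
  (caterpillar-like) ingroups. Declaring the strain pair (so it stays a
  cherry in the intree) removes the worst of this pull; an undeclared tight
  pair on a short stem can still draw the center onto itself, making the
  "LCA" approach the strain sequence.
* With byte-identical strain sequences, several placements of the
  near-zero-length edges tie exactly in likelihood and the deterministic
  tie-break does not guarantee the strain cherry; any nonzero divergence
  makes the cherry the strict optimum.
* Exhaustive search is capped at 8 taxa by design; there is no heuristic
  fallback.
* Branch lengths are bounded at 20 substitutions/site; data demanding
  longer branches pile up at the bound.

## Problem sizes used in the reproduction script

`scripts/acceptance.py` reruns the pipeline end to end at sizes chosen to
keep a complete run on one CPU core in the tens of minutes: 25 paired
replicates for the LBA rooting comparison, 10 seeds for 6-taxon topology
recovery (L = 5000), 5 seeds for ASR recovery (L = 2000), 10 seeds for AIC
model detection (L = 2000), and one 100-gene supermatrix (210 sites/gene)
for the editing arithmetic. The test suite (`tests/test_acceptance.py`) runs
the same experiments at the larger replicate counts quoted there.
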