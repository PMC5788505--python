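# Methods

This note documents the model, the numerical choices, and the synthetic
study conditions behind `pathmapper`, in the spirit of the methods
documentation of packages such as msprime or statsmodels.

## Pathway representation

A pathway model is a linear graph with strictly alternating ligand and
protein nodes, beginning and ending with a ligand (K proteins ⇒ K+1
ligands). Nodes are identities drawn from candidate pools; no
stoichiometry, cofactors, or fluxes are represented. Each candidate may
appear at most once per model, and only linear topologies are sampled;
cyclic or branched pathways are out of scope. A metabolite that
legitimately recurs in a real pathway (e.g. a shared cofactor) therefore
cannot be represented twice; we accept this simplification because the
score targets identity assignments, not mechanism. Pathways of unknown
length are handled by mapping each candidate length K independently;
cross-length models are assigned Hamming distance 1.0 so per-length
sub-ensembles cluster separately, and models are reported side by side
ranked by raw total score.

Positional constraints express anchors: a transporter solute-binding
protein fixed at the pathway start occupies protein position 1 like any
enzyme, with its ligand constrained at position 0.

## Restraints and normalization

All restraints are Z-scores so that heterogeneous sources combine on a
common scale; the composite score is their sum, and absent data simply
omit a term (never contributing a penalty). Higher scores are better.
Population statistics (ddof = 0 throughout, since each normalization
population is a complete reference set, not a sample) are computed once
per restraint set, making scoring pure: the same pathway always receives
the same score. Degenerate populations (sd < 1e−12) yield Z = 0 with a
warning rather than an error, so a constant restraint is uninformative
instead of fatal.

Specific choices, where the normalization population was genuinely open:

- **Docking (Z_VS).** Per-protein raw scores are standardized over that
  protein's full docked table. Pairs without a score — including every
  pair involving a dummy protein, which has no table — are excluded from
  the average rather than penalized.
- **Transformations (Z_CT).** For a triad (substrate, enzyme, product),
  all of the enzyme's SMIRKS transforms are applied at every matching
  site; similarity between the transformed substrate and any molecule is
  aggregated by the maximum over transforms × products × stereoisomer
  assignments, which rewards any single consistent reaction. The triad's
  Tanimoto coefficient is Z-scored against the same statistic computed
  between the transformed substrate and every candidate metabolite,
  mirroring the per-row docking normalization. A substrate matching no
  motif contributes TC = 0. Proteins with no transform at all — the dummy
  node, and transporters — fall back to the direct substrate-product
  comparison, since the dummy rule is defined by the absence of a
  transformation. Products are canonicalized and deduplicated but not
  tautomer-normalized.
- **Ligand-set similarity (Z_SEA).** w_AB = min(−log₁₀ E, 50); log base 10
  follows the ligand-set-comparison significance convention, and the cap
  makes the base immaterial for very significant pairs. Missing self
  E-values default to the cap (maximal self-confidence) with a warning;
  missing pair E-values count as E = 1 (S = 0). The normalization
  population is all unordered pairs of distinct non-dummy candidate
  proteins.
- **Endpoint / screening / homology (Z_CM, Z_HTS, Z_HS).** Each is a
  max-Tanimoto statistic Z-scored over the candidate metabolite pool (for
  Z_CM, over all candidate-vs-central comparisons). The candidate pool —
  rather than the full docked library — is used as the "all metabolites"
  population; it is the sampling space the statistic must discriminate
  within. When several screened or annotated proteins occur in one model
  their Z-scores are averaged, keeping the term on the same scale as a
  single observation.
- **Gene cluster (Z_GC).** Pair-set intersection normalized by the larger
  pair count, Z-scored against the distribution over all subsets of the
  candidate proteins with sizes 3..P (enumerated exhaustively up to 2^20
  subsets, sampled with a fixed seed and 10^5 draws beyond). The term is
  opt-in (`enable_gc`), intended for runs with decoy enzymes.

### Fingerprints and stereochemistry

Morgan fingerprints, radius 2, 2048 bits, chirality encoded. Radius and
width are community defaults; chirality is required because sugar-acid
interconversions differ only at stereocenters. The Tanimoto coefficient of
two empty fingerprints is defined as 0.0 (no evidence of similarity).
Molecules with k undefined stereocenters are expanded into min(2^k, 16)
assignments using RDKit's deterministic stereoisomer enumerator, and the
highest coefficient is used; the fixed enumeration order makes the cap
reproducible.

## Sampling

Metropolis Monte Carlo with simulated annealing. Moves: (i) swap two
same-type nodes within the model, (ii) replace a node with an unused
candidate of the same type; the move type is chosen uniformly among the
legal types and positions/candidates uniformly among legal ones (rejection
sampling from the uniform product space with an exhaustive fallback, so
heavily constrained instances remain correct). Constrained positions are
never violated. An improving or equal-score proposal is always accepted
without consuming a random draw; otherwise acceptance probability is
exp(−D/T) with D = old − new under score maximization. The temperature
follows T = 0.3·0.2^N + 0.1 with N = step/n_steps, decreasing from 0.40
to 0.16 over a run.

Every accepted state is recorded once (by canonical node-sequence key),
not only run endpoints. Runs start from a uniformly random valid pathway.
Per-run seeds are spawned from the master seed with numpy's splittable
`SeedSequence`, so ensembles are reproducible and order-independent. The
good-score cutoff is best − cutoff_sd × sd, with sd the population
standard deviation of the scores of `n_random_models` uniformly random
pathways; cutoff_sd defaults to 2.0, with 1.5 supported for longer
pathways where the good-scoring set would otherwise balloon.

Default protocol parameters (5,000,000 steps, 1000 runs, 10,000 random
models) are preserved in `SamplerConfig`; the test suite and the
acceptance script scale them down (hundreds to thousands of steps, 8–16
runs) because the desk-scale planted instances have 10^2–10^6 pathways and
converge well within those budgets — problem sizes used are stated in each
test and in the acceptance script.

## Ensemble analysis

Hamming distance = fraction of differing node positions (proteins and
ligands alike). Hierarchical clustering uses average linkage — a robust
default for a flat cut, recorded in the export metadata — implemented with
scipy; the flat cut keeps models whose cophenetic distance is ≤ 0.2 in one
cluster (models at exactly the cutoff merge). Cluster representatives are
the highest-scoring members, ties broken by lexicographic key, and cluster
ids are renumbered by representative score so outputs are deterministic.
Edge frequencies count the models containing each (protein, ligand, role)
edge; ranks are dense and tied frequencies share a rank. Convergence is
the cumulative fraction of all clusters discovered after r runs. The
NetIMP JSON export is canonical (sorted keys, fixed ordering), so
export → import → export is byte-identical.

## Candidate-library construction

The candidate metabolite set is the union of the top-N (default 1000)
metabolites of every docking screen and the library metabolites with
Tanimoto strictly above 0.75 to any transform product of those hits.
Expansion is a single pass — products of products are not expanded — and
"above" is implemented strictly, so an exact product match at a cutoff of
1.0 is excluded.

## The synthetic generator

The generator defines the study conditions; it is not a tuning dial. The
planted chain is pentane-1,5-diol oxidized stepwise (alcohol → aldehyde →
acid, then the same on the other terminus) to glutaric acid, giving exact,
auditable SMIRKS applications for K between 2 and 4; larger K raises a
configuration error naming the transform-chain step. Decoy metabolites are
drawn from a curated list of real small molecules; the first eight (the
default pool) are chosen so that no decoy is a one-step transform product
of another, avoiding accidental competing chains. Decoy enzymes carry
transforms (ketone reduction, N-methylation, nitrile hydration) that do
not match the planted chain.

Default conditions: K = 4, 3 decoy proteins, 8 decoy metabolites, docking
signal 1.5 (mean Z advantage of true enzyme-ligand pairs, on noise of
sd 1.0), adjacent-true-pair E-value 10^−30 (clearly significant but below
the w-cap; random pairs are drawn near E = 1), transform fidelity 1.0, an
anchor fixing the first enzyme and its ligand, screening hits for the
first enzyme, a homology reference for the last, and a central-metabolism
list containing the true end product plus standard central metabolites
(pyruvate, oxaloacetate, acetate). Docking scores are plain Gaussian noise
plus a shift — only the rank/Z structure of real physics-based scores
matters to the method, not their absolute values.

When the instance is small enough to enumerate (≤ 20,000 unconstrained
pathways) and a docking signal is present, generation verifies by
exhaustive search that the planted pathway is the global score optimum and
records the outcome.

The null configuration (`SyntheticConfig.null()`) zeroes every signal:
docking carries no true-pair advantage, all pair E-values are drawn from
the random-pair distribution, transforms are scrambled, and the anchor,
endpoint, screening, and homology components — which are informative by
construction — are omitted. Under these conditions the planted pathway's
score percentile among random pathways is uniform, which the test suite
checks with a KS test across independent problems (a single planted score
cannot be KS-tested directly, so uniformity of its percentile across
problems is the operational null property).

### What the generator does and does not emulate

It reproduces the *structure* of real inputs — per-protein score tables
with standardized signal, a symmetric E-value matrix, SMIRKS transforms,
anchors, hit lists — with planted ground truth, which is what the scoring
and sampling machinery consumes. It does not emulate KEGG-scale libraries
(a size knob exists but defaults are desk-scale), correlated docking noise
across related metabolites, partially wrong transforms, or E-value
structure among decoys. Passing tests therefore demonstrate that the
machinery integrates information correctly and recovers planted signal;
they do not certify performance on real docking outputs, where noise is
structured and restraints can be systematically biased.

## Known limitations

- Linear pathways only; a metabolite cannot appear twice in one model.
- The transformation term's population is recomputed per (enzyme,
  substrate) pair and cached; very large candidate pools make the first
  pass over a new pair O(|candidates|) in fingerprint comparisons.
- Scores across different pathway lengths K are compared on raw totals;
  no length correction is applied.
- The sampler re-scores the full pathway at every step (no incremental
  score updates); this keeps the score provably stale-free at the cost of
  speed on long pathways.
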