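# Methods

This note documents the models, decision rules, numerical choices and
known limitations of `xenoscan`, in the order the pipeline applies them.

## Taxonomic scoring

Hits are categorized against three configurable clades: a *self* clade
(the focal subfamily; its hits are ignored entirely), the *recipient*
clade (animals), and the donor kingdoms (Bacteria, Fungi, Viridiplantae;
anything else nonanimal is `DONOR:other`). Subjects carrying several
taxids are resolved conservatively: SELF if any taxid is SELF, DONOR only
if *all* taxids are nonrecipient, otherwise RECIPIENT — ambiguity is
always pushed toward the non-HGT interpretation. Unknown taxids raise by
default; a permissive mode maps them to `DONOR:other`.

The Aggregate Hit Score normalizes every retained hit's bitscore by the
query's best non-self bitscore and takes the signed sum (donor minus
recipient) over **all** retained hits. The published description of the
score underdetermines whether all hits or only the best per category
enter the sum; we sum all retained hits, which matches the score's stated
robustness rationale (one contaminant among hundreds of hits shifts the
sum by at most 1). Hits are filtered at e-value ≤ 1e−3 and capped at the
500 best per query (ties broken by e-value, then subject id, for
determinism) before scoring.

## Grouping

Candidates (AHS > 0) are clustered three ways: single-linkage on the
fraction of shared hits, with the overlap denominator `min(|hits(q1)|,
|hits(q2)|)` and threshold 0.70 (the denominator is a design choice — it
is tolerant to unequal hit counts between paralogs); by shared
orthogroup; and by intersecting domain-accession sets. Per connected
family of candidates the largest group whose inferred phylogeny predicts
a single HGT event is selected (ties: shared-hits > orthogroup > domain);
when no multi-member group passes, candidates fall back to singletons.
Whether the "most comprehensive single-event clustering" is chosen
globally or per family is not specified by the source procedure; we
choose per family.

## Tree inference

The pipeline's internal tree builder is Saitou–Nei neighbor joining on
Poisson-corrected distances `d = −ln(1 − p)` (p = mismatch fraction over
shared ungapped columns, capped at d = 10), after exact-duplicate removal
and removal of columns with > 50% gaps (a deliberately simple stand-in
for trimal's automated heuristic — not equivalent to it). Negative NJ
branch estimates are clamped to zero with compensation on the sibling
branch; on additive matrices the algorithm is exact (tested to 1e−9).
Internal-branch supports come from a standard nonparametric bootstrap
(column resampling, default 1000 replicates); both slots of the dual
"SH-aLRT/UFboot"-style support label carry the bootstrap percentage,
since only one resampling support is computed internally. Externally
inferred ML trees (e.g. IQ-TREE with dual supports) can be imported via
Newick and used unchanged.

Rooting for sister-branch analysis is by midpoint (ties broken by the
lexicographically smaller leaf-pair); the upstream procedure does not
state its rooting rule, so midpoint is a documented decision.

## Likelihoods and topology tests

Per-site log-likelihoods use Felsenstein pruning under the 20-state
Poisson model (uniform frequencies, closed-form transition probabilities)
with gaps/'X' as missing data; an arbitrary reversible exchangeability
matrix can be plugged in. Branch lengths are optimized coordinate-wise
with bounded Brent (xatol 1e−4, branch lengths in [0, 20]), one sweep by
default in the pipeline; the total lnL never decreases because updates
are accepted only on improvement.

The HGT topology is tested against a constrained NJ tree in which the
query and all animal-category leaves are forced monophyletic (the
constrained NJ forbids joins mixing constrained and outside clusters
until the constraint has coalesced). Tests operate on the two per-site
lnL vectors with RELL resampling (no re-optimization):

* KH — normal approximation, p = Φ(Δ/σ̂) with σ̂ from centered RELL sums;
* SH — centered max statistic;
* AU — multiscale bootstrap at scales r ∈ {0.5, …, 1.4}, replicate length
  round(r·n), probit-transformed win frequencies fitted by WLS to
  z(r) = d√r + c/√r, p = Φ(c − d). Degenerate curves (win counts < 5 or
  > B−5 at every scale) short-circuit to 0/1; exact ties are broken
  symmetrically with an infinitesimal jitter. Default B = 10,000 per
  scale; every resampling stage takes an explicit seed.

A group is `hgt_supported` when the constrained topology's AU p < α =
0.05 (α is a documented decision; the source procedure does not print
it). When a family contains no animal sequences besides the query, the
test is `untested` and the corresponding validation rule is not
applicable.

## Donor classification and events

The query clade Q is the smallest clade containing the group's queries,
then absorbed upward while its siblings consist solely of SELF-category
leaves (cryptic-species or sister-species homologs) — these are
co-recipients, not counter-evidence. The sister branch's donor
composition assigns the origin: one kingdom (with an absent, donor-free,
or same-kingdom ancestral sister) → that kingdom; a uniformly different
ancestral sister → `complex:k1|k2`; a mixed sister → `other` (no majority
vote — deliberately conservative); nonquery animal leaves in *both*
branches → `none`. Donor count is the number of donor leaves in sister
plus ancestral sister.

Events are maximal clades whose leaves are exclusively query/self
sequences; a transfer followed by tandem duplication therefore counts
once, and the total is a lower bound. Cross-species groups are merged via
orthogroup co-membership (transitively). A two-species event is
`single_ancestral` when the joint clade is monophyletic with supports ≥
(80, 95), `single_ancestral_weak` below that, `independent` when
non-monophyletic and the constrained-monophyly AU test rejects at 0.05,
else `inconclusive`.

## Validation

Six rejection rules (any un-overridden failure rejects): c1 donor count
< 3; c2 topology test not significant (overridable by the curator tokens
`misannotated_animal` / `animal_is_hgt`); c3 max donor identity > 70% and
either no cryptic-species homolog or `contamination_suspected`
(overridable by `donor_misannotated`); c4 mean donor identity < 30%; c5
mean donor alignment < 100 aa *and* mean query coverage < 50%; c6 local
score < 0 without duplication evidence (not applicable when unreported).
c4 uses the *mean* donor identity: the source text says "the identity
between the donor sequences and the HGT candidate" without an
aggregator, and the mean matches the rule's stated motivation (alignment
quality across donors). Manual-judgment subclauses are never inferred —
they enter only as explicit override tokens from an annotations TSV.

The local score uses a window of 10 genes per side (window size is not
printed by the source; it is configurable and logged), counts gene units
rather than base pairs, and ignores strand.

## GO enrichment

Raw p-values are exact hypergeometric upper tails (scipy) over the
annotated population after true-path propagation. FWER control defaults
to Holm (deterministic); a Westfall–Young-style min-p permutation null
(resampled study sets) is provided for closer fidelity to
randomization-based tools, at the cost of runtime and a required seed.
Redundancy refinement follows the elim idea: ancestors keep their
significance only if still nominally significant after removing study
genes explained by a significant descendant. The refinement rule of the
original tooling is not algorithmically documented; elim is the declared
substitute.

## Synthetic data

The generator emulates the *statistical shape* of the real inputs, not
their biology. Database taxa get latent evolutionary distances; hit
bitscores follow `aln_length × (a − b·distance) + N(0, sd)` truncated
positive (a = 1.5, b = 0.5 bits/column, sd = 5) and identities decay
linearly with distance. Planted transfer families receive ~8 donor-kingdom
hits at distances drawn so mean donor identity lands in the 40–65% band
(passing the 30/70% rules), three distant animal homologs, and a
cryptic-species homolog; contaminants are near-verbatim donor copies
(identity ≈ 85%) with no cryptic homolog, so they fail rule c3 by
construction. Family gene trees nest the query inside a shallow donor
clade (internal branches 0.08, sister and ancestral sister are donor
pairs, so donor count = 4) with a three-leaf animal outgroup on a 0.5
stem — deep enough that midpoint rooting always cuts the animal stem,
close enough that the constrained-monophyly test has power at the default
300 simulated columns. Alignments are simulated i.i.d. under the Poisson
model on those trees. Shared-ancestral events place the two species'
copies as sisters; independent events graft them at donor-separated
positions. One GO leaf term is enriched among transfers (P = 0.7 vs 0.03
background).

What passing these tests shows: the decision rules, statistics and tree
machinery behave correctly on data satisfying the model's assumptions at
study-like signal strengths. What they do not show: robustness to
alignment error, indels, rate heterogeneity, horizontal transfer between
donors, chimeric assemblies, or NR-scale taxon sampling — the generator
deliberately omits all of these (hit tables are produced directly from
latent distances; no aligner is run).

## Problem sizes and defaults

Default study conditions: 2 recipient species × 300 genes, 40 database
taxa, 20 planted transfer families (half pre-divergence), 2 contaminants,
300-column alignments, bootstrap B = 1000, AU B = 10,000 × 10 scales —
a full run is a couple of minutes on one core. The cross-species study
uses 2 × 120 genes with 5 ancestral + 5 independent families. The
sizes are chosen to give every rule a nontrivial decision at interactive
runtimes; all are `ScenarioConfig`/`PipelineConfig` fields.

## CLI surface

`simulate`, `score`, `cluster`, `tree`, `localscore`, `enrich`,
`run-all`, `evaluate`. Donor classification, validation and event
assessment consume multi-stage in-memory state (rooted trees + calls +
context) and are deliberately not standalone subcommands; they run inside
`run-all`, and their library functions are the programmatic interface.

## Known limitations

* NJ + nonparametric bootstrap stand in for ML inference + UFboot/SH-aLRT;
  both support slots carry the same bootstrap value.
* The Poisson model ignores amino-acid exchangeability structure and rate
  variation; model choice is pluggable but not selected automatically.
* The AU implementation follows the standard multiscale-bootstrap
  construction but is not a reimplementation of any specific tool's
  numerics; its calibration is verified empirically (rejection rate
  within [0.025, 0.075] at α = 0.05 under an exchangeable null).
* `complex` origins and `other` donors are detected but not further
  resolved; reconciliation-based transfer inference and event dating are
  out of scope.
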