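# Methods

## Model and procedure

`coreattach` treats a protein complex as a core–attachment object inside
an undirected, unweighted PPI graph. The core is a vertex set that
(locally) maximises the closeness function

cf(G′) = density(G′) · (1/|G′|) Σ_{v∈G′} |N_v ∩ G′| / |N_v|,

i.e. it is dense internally *and* captures most of its members'
interactions. Detection assumes complexes appear in the graph as
overlapping near-cliques: candidate cores start as maximal cliques of
size ≥ 3, and cliques whose neighbourhood affinity
NS(A, B) = |A∩B|²/(|A||B|) against a seed reaches the merge threshold
*t* are collapsed into one candidate (union → GO filter → greedy cf
pruning). The merge loop is run to convergence first within each
clique-size stratum, then once over the pooled strata; processing sizes
separately prevents large cliques from annexing smaller ones before the
small ones have consolidated into their own candidates. Returned cores
are pairwise dissimilar (NS < t), size ≥ 3, cf-locally-optimal under
single removals, and functionally coherent when GO is enabled.
Attachments are then accreted greedily: the boundary vertex that most
increases cf is admitted while any strict increase exists. Growth is
purely topological; proteins removed from a core by the GO filter can
re-enter the complex as attachments.

The two optimality conditions are deliberately split across the phases:
cores are optima under *removal*, complexes are optima under *addition*
(growth's stopping rule). A core that admitted every cf-improving
neighbour during detection would leave nothing for the attachment phase
to add, and would also re-merge candidate cores that the threshold *t*
is supposed to keep apart — it would erase the characteristic
discontinuity of the t-performance curve at 4/9, the NS of two size-3
cores sharing two proteins. Under this reading the removal-side and
addition-side conditions are simultaneously satisfiable; asserting both
on the cores alone is not.

## Functional interdependence

For GO items *i*, *j*: with re_ij the number of edges joining an
*i*-annotated protein to a *j*-annotated one (each edge counted once),
m_x the number of edges with ≥ 1 endpoint annotated *x*, and
ee_ij = m_i·m_j/|E|,

fr_ij = (re_ij − ee_ij) / [ ee_ij (1 − Σ_k ee_ik/|E|)(1 − Σ_k ee_kj/|E|) ],

with the sums over all items present. Items are interdependent when
fr > 1.96 (strict). Two numerical caveats are documented rather than
patched:

- **The denominator carries no square root**, although 1.96 is the
  two-sided 5% normal critical value. A `z-score` variant dividing by
  the square root of the same denominator is available
  (`fr_variant="z-score"`); the default follows the plain form.
- **ee is conservative.** Because m_x counts edges touching *x* on
  either endpoint, ee double-counts orientation: under a
  random-placement null with disjoint single-item annotations the
  observed re centres near ee/2, not ee (verified by simulation in the
  test suite). The fr > 1.96 rule therefore under-declares
  interdependence; it never inflates it. Detection degrades gracefully:
  pairs with ee = 0 or non-positive bracket factors are defined
  non-interdependent instead of raising.

A core's *dominant item* is the GO item annotating the most members
(ties → lexicographically smallest item ID); the coherence filter keeps
a protein iff it carries the dominant item or an item interdependent
with it. A candidate whose members carry no annotation at all is kept
unfiltered; individual unannotated proteins in an otherwise annotated
candidate are removed (and may return as attachments). Annotations are
used as given — no ancestor propagation over the GO DAG — and all three
ontologies are accepted; `AnnotationMap.restrict_items` lets callers
restrict to a namespace.

## Numerical choices

- All cf comparisons that drive decisions (pruning, growth, the
  invariant checks) use exact rational arithmetic
  (`fractions.Fraction`). Competing removals can tie at *exactly* equal
  cf — the worked merge example contains a three-way exact tie — and
  float summation over unordered sets would resolve such ties by hash
  order, making runs irreproducible. The public `density`/`closeness`
  API returns floats in [0, 1].
- Tie-breaks are fixed conventions: greedy *removal* ties break toward
  the lexicographically largest protein ID (this convention also
  reproduces the published worked merge trace end-to-end); greedy
  *addition* ties in growth break toward the smallest ID; dominant-item
  ties break toward the smallest item ID.
- All clique/core collections are kept in canonical order (size, then
  sorted member tuple), so results are independent of hash seeding.
- NS comparisons use ≥ t for family inclusion and loop termination;
  t = 4/9 therefore still merges two triangles sharing an edge, while
  t = 0.45 does not.
- The merge loop carries a safety cap (`max_iterations`, default 100):
  merging creates new candidates and convergence is not guaranteed in
  general; at the cap the current state is returned with a warning. The
  loop also stops early when an iteration reproduces its input exactly.
- Degenerate inputs: clusters below size 2 cannot be scored; scoring a
  cluster containing an isolated (degree-0) protein is an error, but
  isolated proteins never enter cliques or boundaries, so the pipeline
  never trips this; empty merge results (family filtered below the
  minimum core size) are dropped silently and counted in the log.

## Parameters

| parameter | default | meaning |
|---|---|---|
| t | 0.4 | NS merge threshold in (0, 1]. Larger t → more, smaller complexes. Values > 4/9 stop size-3 cores sharing two proteins from merging and flood the output with low-confidence triangles; keep t ≤ 0.44. |
| min_core_size | 3 | smallest admissible core (a complex needs at least a triangle). |
| fr_threshold | 1.96 | interdependence cutoff (two-sided 5% normal critical value). |
| use_go | True | False disables every GO filter (pure-topology ablation mode). |
| fr_variant | as-printed | or `z-score` (square-root denominator). |
| ω (evaluation) | 0.2 | NS threshold at which a prediction and a reference complex count as matching. |

## Synthetic data

The generator emulates the structural assumptions the detector relies
on, with defaults fixed as the package's reference study condition:
10 complexes, core sizes 4–8 wired as near-cliques at p_core = 0.9,
1–3 attachments each wired to the core at p_attach = 0.5 (with one
guaranteed core edge), 40 background proteins, background noise edges at
p_background = 0.01 over non-complex pairs, 20% of complexes sharing two
core proteins with a neighbour, one dedicated GO term per complex
dropped from core members with probability 0.05, and 15 decoy terms
sprinkled 1–2 per protein. Everything derives from one seeded
`numpy` generator; the seed is mandatory.

What it does *not* emulate — and hence what passing tests do not show
about real data: experimental false positives are represented only as
uniform noise edges (real screens have systematic, bait-dependent
error); degree distributions are homogeneous rather than scale-free;
annotation incompleteness is uniform dropout rather than
study-bias-correlated; attachment proteins are complex-specific rather
than shared hubs; and the planted truth is unambiguous, unlike curated
catalogues which are themselves incomplete. Recovery scores on this
benchmark (F ≈ 0.95 at the defaults) characterise algorithmic
correctness, not expected performance on experimental interactomes.

These sizes (≈115 proteins, ≈250 edges per network) keep a full
50-seed invariant sweep plus the recovery and ablation checks in the
test suite at a few seconds total.

## Known limitations

- The merge loop's fixed point is reached in one or two iterations on
  realistic inputs, but pathological inputs can oscillate; the cap then
  returns a state that may contain a similar pair (logged).
- The fr statistic is undefined for items so prevalent that a bracket
  factor turns non-positive (m_x·Σ_k m_k > |E|²); such items can anchor
  coherence only as the dominant item itself.
- Unannotated proteins cannot survive in a GO-filtered core; on sparsely
  annotated genomes the `--no-go` mode or the attachment phase must
  recover them.
- Evaluation compares full member sets; it does not score the
  core/attachment split itself.
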