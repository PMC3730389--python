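# Methods

## The association statistic

For a binary study × acupoint incidence matrix (m studies, p acupoints),
the pairwise score is

    MI(x, y) = P(x, y) · ln( P(x, y) / (P(x) · P(y)) ),

with P(x) = n_x/m and P(x, y) = n_xy/m computed from integer tallies. This
is the single pointwise-mutual-information term of joint presence, weighted
by co-usage frequency — deliberately *not* the full Shannon mutual
information of the 2×2 table. Consequences worth knowing:

* the statistic is 0 exactly at independence and for never-co-used pairs
  (the 0·ln 0 = 0 limit convention);
* it can be negative (co-usage below the independence expectation);
  negative values are retained in the matrix and simply never survive a
  positive binarization threshold;
* it is strictly increasing in n_xy above the independence count
  ⌈n_x n_y/m⌉, which is what makes integer co-usage counts recoverable
  from rounded published values (see the fixture);
* natural log throughout; values are in nats.

A pair with a never-used endpoint has an undefined marginal; the matrix
builder refuses all-zero columns and directs callers to the frequency
filter (strict inequality: frequency must exceed the cut, so a point at
exactly 5% is dropped). Usage percentages render half-up at one decimal
(27/53 → 50.9), matching the convention of published usage tables.

## Binarization and network selection

The MI matrix is thresholded at every R on a fixed grid (0.001…0.999, step
0.001; edge iff MI **strictly** exceeds R). Grid values are carried as
integer thousandths, so recorded thresholds like 0.022 are exact. The scan
records edge count, edge density E/(p(p−1)/2), and whether the network is a
single connected component ("fully connected" in the graph-connectivity
sense, not a complete graph); `r_max_connected` is the largest grid R
before fragmentation. Analysis networks are the connected grid networks
with density inside a band — default 0.39–0.50, chosen to retain only
strong edges while preserving connectivity — and the default analysis
network is the one whose density is nearest 0.40, ties resolved toward the
larger (sparser) threshold.

Strongly modular data can defeat this selection wholesale: when all
between-module association sits below independence, *no* positive
threshold yields a connected network (the planted generator below produces
exactly this situation). The pipeline then falls back, with a logged
warning, to in-band selection ignoring connectivity; module detection
proceeds per component, which is the right answer for such data. The
stand-alone `select_by_density` function does not fall back — it raises —
so library users opting out of the pipeline keep the strict contract.

## Centralities and modules

Degree is the row sum of the adjacency. Betweenness uses Brandes'
algorithm (via networkx); the normalized value divides the raw
unordered-pair count by (p−1)(p−2)/2 so the middle of a path graph scores
exactly 1. Because published tables rarely state their normalization, both
raw and normalized values are emitted.

Modularity is the Newman–Girvan quantity
Q = (1/2l) Σ_ij (a_ij − k_i k_j/2l) δ_ij = Σ_c (e_c/l − (d_c/2l)²).
Some sources print the same double sum with a 1/(4l) prefactor; that is
exactly half the standard value and cannot change the argmax partition, so
the standard form is the default (it satisfies the clean identities Q = 0
for one module and Q = 0.5 for two disjoint triangles split by component)
and a `quarter_prefactor` flag reproduces the halved convention.

Detection maximizes Q by alternating two deterministic passes until Q
stops improving: greedy agglomeration of whole communities (merge the pair
with the largest positive ΔQ), and single-node refinement in which a node
may move to any community *or out into a new singleton* (the singleton
move is what lets the search undo over-eager merges). `restarts` seeded
runs perturb tie-breaks and sweep order; run 0 is fully deterministic and
the best Q wins, ties resolved toward the lexicographically smaller
assignment. The result is reproducible for a fixed (seed, restarts).
`exact_best_partition` enumerates all set partitions (refused above 12
nodes) as the testing oracle; on random instances with up to 10 nodes the
heuristic attains the exhaustive optimum in ≥95% of cases and by
construction never exceeds it.

Numerical points: ΔQ comparisons use a 1e-12 slack so float noise cannot
flip a tie; refinement is capped at 50 sweeps (never reached in practice);
zero-edge graphs are rejected rather than given a conventional Q.

## The planted prescription-module generator

Each simulated study draws one acupoint group ("prescription theme") from
the mixing weights (uniform by default over three groups mirroring the
local / distant-meridian / symptom-differentiation themes, sizes 14/9/10),
then includes each in-group acupoint with probability `p_within` (default
0.9) and every other acupoint with `p_background` (default 0.05). The
closed-form usage frequency is w·p_within + (1−w)·p_background per
acupoint.

What the model emulates: group-coherent prescriptions, realistic marginal
frequencies, seeded reproducibility. What it does **not** emulate: studies
that mix themes in one prescription. Under the one-theme-per-study model,
between-group pairs are *sub-independent* — observing x ∈ A makes the
study type-A, depressing y ∈ B — so between-group MI is systematically
negative (≈ −0.04 at the defaults) and the thresholded network is three
disconnected cliques at every positive R, with maximum density equal to
the within-group pair fraction (≈0.33 for the default groups). Recovery
experiments therefore run the pipeline with a density band bracketing that
value (0.25–0.40, target 0.33) and exercise the disconnected fallback.
Passing recovery tests show the chain MI → binarize → detect reconstructs
planted co-selection structure; they do not show that real prescription
corpora are this cleanly separable — real data mix themes within studies,
which is precisely what keeps real networks connectable.

## The synthetic 53×33 LBP fixture

The raw incidence matrix of the 53-trial low-back-pain corpus behind the
published summary tables is not available. The shipped fixture
(`data/lbp53_synthetic_incidence.csv`, checksummed) is a *synthetic*
matrix constructed to satisfy every published anchor exactly:

* marginals: n_x = round(pct·53/100) for all 33 published usage
  percentages; every count round-trips to the printed percentage at one
  decimal (so the percentages were rounded, not truncated);
* co-usage counts for the 13 published high-MI pairs: for each pair the
  integer k ∈ [max(0, n_x+n_y−53), min(n_x, n_y)] whose MI rounds to the
  printed 4-decimal value — unique in every case (asserted), e.g.
  BL24–BL25 forces k = 17 = n_BL24, i.e. containment;
* no *unconstrained* pair reaches MI 0.17, so the >0.17 pair list of the
  fixture is exactly the 13 published pairs;
* a structural gate: the 0.39–0.50 density band must be reachable by a
  connected network, as in the published analysis.

Construction: the pair-constraint graph is split into connected
components; each component's joint membership-pattern counts (Venn cells)
are solved exactly as a small integer program (scipy's HiGHS MILP backend)
with the MI caps as linear bounds and a seeded random objective; concrete
rows are then assigned to patterns, and unconstrained columns filled, by a
seeded greedy that prefers rows already used by same-theme columns (themes
= the three published modules) under running cap checks. Dead ends restart
the whole placement with a derived seed — backtracking by restart — and
the first completion passing all gates is kept; the search order is fixed,
so regeneration is bit-reproducible and a test asserts the shipped CSV
equals the rebuilt one.

Everything the anchors do not pin down — degrees, betweenness, the
detected partition, the exact r_max_connected — is a property of the
completion, not of the unavailable data, and is reported as illustrative
only. (That the fixture's detected modules coincide with the three
published module groups is by construction of the theme-biased completion,
not a finding.)

## Reporting conventions

MI at 4 decimals, frequency at 1 decimal (half-up), betweenness at 5
decimals. The usage table sorts by descending frequency, ties by label;
the pair table by descending MI. Pair tags: L iff both members lie in the
configured local set, which defaults to the 14 lumbar-local module
acupoints; note that published tags also treat GB30 (buttock region) as
local, so reproducing published L/D labels exactly requires overriding
`local_set` — anatomical locality is an input, not something the data
decide. GraphML export carries degree, betweenness and module id per node;
the run manifest (JSON) records seed, grid, chosen threshold, density and
Q. Report CSVs are byte-stable for a fixed config and seed.

## Problem sizes in the test suite

Oracle-backed checks run at the scale where exhaustive computation is
exact and fast: betweenness against full path enumeration on 200 graphs of
up to 8 nodes; modularity against full set-partition search on 100 graphs
of up to 10 nodes; recovery over 20 seeded replicates at m = 300. These
sizes make the oracles literal (every path, every partition) while keeping
the default suite under a minute.
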