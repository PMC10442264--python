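# Methods

## Sampling unit and filters

The unit of association sampling is the **survey**: one group's composition
and predominant activity at one time point.  One survey = one sampling
period; surveys repeated on the same day for (essentially) the same group
are treated as resights and removed, so the joint-but-apart term of the
half-weight index is structurally zero.  The resight rule is membership
Jaccard overlap > 0.5 with an earlier retained survey of the same date; the
threshold is configurable (`SurveyFilterConfig.resight_overlap_threshold`)
because "same group" is an operational call that field protocols make in
slightly different ways.  Foraging, unknown-activity and competitive
surveys are excluded by default — males aggregated at a food patch or in a
large conflict are not evidence of affiliation — as is everything outside
August–December, the window where mating season and field seasons overlap.
Individuals missing from the alliance registry are ignored when classifying
a survey's alliance-level content but still count as group members for
association indices.

## Association

For a dyad (A, B): `HWI = x / (x + y_AB + (y_A + y_B)/2)` with `x` the
number of periods together, `y_AB` both-seen-apart (here 0), `y_A`/`y_B`
only-one-seen.  HWI is 1 iff two males are only ever seen together, 0 iff
never together.  Individuals under a configurable minimum sighting count
(default 1) are dropped from matrices, since their indices are undefined or
wildly unstable; study-style presence thresholds ("seen in more than two of
six years") can be expressed by pre-filtering the roster.

The preferential-association test permutes the individual × survey incidence
matrix by sequential checkerboard swaps, preserving every group size and
every individual's sighting count.  Defaults: 1000 burn-in swaps, 100 swaps
between retained samples — enough decorrelation that the test's type-I error
sits at the nominal 5% within binomial error (the test suite checks this on
200 unstructured societies).  The p-value is two-sided with add-one
correction (`p = 2·(min(n_ge, n_le)+1)/(n_perm+1)`, capped at 1).  The test
statistic defaults to the coefficient of variation of the dyadic HWI, the
usual choice for detecting differentiated relationships; mean and SD are
also available.  Only the group-membership (checkerboard) permutation
variant is implemented; a data-stream variant would need observation-order
metadata that the survey table does not carry.

## Community detection

Agglomeration runs on the similarity scale: merge the cluster pair with the
highest average pairwise HWI, record that average as the merge height, so
heights are non-increasing (this equals UPGMA on distance 1 − HWI, which the
tests verify against scipy).  Ties are broken by the lexicographically
smallest member id so results are platform-deterministic.

A cut at level *h* keeps together every dyad whose cophenetic join height is
≥ *h*.  Q is evaluated at every distinct merge height plus the
all-singletons cut; Newman's weighted modularity is used with zero-weight
dyads contributing nothing, and a single-cluster partition scores exactly 0.
Ties on Q resolve to the highest cut level.  Because "the" level of a
dendrogram band is ambiguous by half a band, diagnostics report both the
maximizing merge height (`cut_at_qmax`) and the midpoint to the next higher
band (`cut_midpoint`).  A gregariousness-corrected modularity variant exists
in some social-network packages; the plain Newman form is the default here
and the only one implemented — on HWI matrices of this size the choice did
not affect which partition wins in any case we examined synthetically.

CCC is the Pearson correlation between dyadic HWI and cophenetic join
heights, computed on the similarity scale directly (so a faithful hierarchy
gives +1, and the conventional CCC > 0.8 "good representation" threshold
applies without sign gymnastics).  Zero-variance inputs make it undefined
(NaN, logged) rather than silently 0.

## Strength

`wStrength(i)` sums HWI from male *i* to his own second-order alliance;
`bStrength(i)` sums HWI to all members of alliances that are
third-order-allied with his.  Both are normalized by the maximum of the same
measure **within the male's own alliance** — that is the reading under which
"normalized between-alliance strength" answers "how connected is this male
to third-order allies *compared to other members of his alliance*"; a
whole-network normalization scope is available as an option.  When an
alliance holds several third-order alliances at once, pooled bStrength is
reported alongside a per-partner breakdown (`bstrength_by_partner`), since
the pooled number hides which partnership carries the weight.  An alliance
whose maximum is zero (e.g. no third-order partner) yields NaN normalized
values with a warning — reporting 0/0 as 1 or 0 would both be lies.

Temporal snapshots re-run the entire chain (filter → HWI → clustering →
strengths) on date-windowed survey subsets with per-period rosters, so
deaths and membership changes propagate everywhere rather than being patched
into a single pooled matrix.

## Fusion-event coding

A pair counts once per event per category regardless of how many records it
generates; the PR+D0 category (petting/rubbing plus within-touching-distance
near-contacts) is a superset of PR by construction.  A three-male synchrony
decomposes into its three pairs by default (tallies are pair-based), with a
no-decompose option.  Column totals (summing per-event unique counts) and
cross-event deduplicated counts are both reported and deliberately not
reconciled: "unique pairs" is ambiguous between the two framings and the
two numbers genuinely differ whenever a pair is active in several events.
Cohen's kappa handles the degenerate single-shared-label case as 1.0 by
convention (with a warning); reliability across more than two coders is the
unweighted mean of pairwise kappas.

The packaged ten-event behavior log (`alliancenet.datasets`) reproduces the
published per-event unique-pair structure of the field study's fusion
observations; the acting pair identities are synthetic draws from the
period roster, because only counts, not identities, were published.

## Synthetic societies

The generator emulates the survey process over a planted three-level
society.  Each survey: pick a seed first-order unit uniformly among living
units; include each of its members with `p_unit_cohesion` (default 0.95 —
units are near-obligate companions); attach each other unit of the same
alliance independently with `p2` (default 0.35 — alliance-mates are frequent
but not constant companions); for each third-order alliance of the seed's
alliance, attach one partner-alliance unit with probability `p3`, chosen
with weight `bridge_bias` (default 3.0) on a designated bridge unit.  `p3`
defaults to 0.12 for the primary alliance pair (0.08 for the secondary pair
in the late-period preset): this puts third-order dyadic HWI in the weak
0.05–0.13 band observed in real multi-level dolphin networks and makes
roughly a tenth of mixed surveys third-order associations.  Dates are
uniform over the configured range; mortality removes individuals after
their last date.

Every dyad's expected per-survey presence and co-sighting probability has a
closed form under this process (attachments are independent given the seed,
which is what makes the cross-alliance factorization exact), giving a
large-sample expected HWI `2E[x]/(E[n_A]+E[n_B])` per dyad class.  The test
suite verifies the closed forms against exhaustive enumeration of the
generative process on a tiny society and against Monte-Carlo at 20,000
surveys (agreement within 0.02; observed ≈ 0.004).  Expectations ignore
mortality (they describe the full-roster process) and are flagged as such
when mortality is configured.

Presets `T1`/`T3` mirror the structure of the study population (alliances of
12/7/5, then 10/5/5 members; one third-order alliance early, two
concurrent ones late) — structure only, no claim of reproducing field
values.  Default problem size is 2000 surveys per generated society, a
scale at which alliance recovery is essentially deterministic while the
whole suite runs in well under a minute per scenario.

### What the generator does and does not emulate

It reproduces: unit-seeded group formation, three nested association tiers
with realistic separation (unit ≈ 0.95, alliance ≈ 0.42, third-order ≈
0.06–0.11 expected HWI), bridge-concentrated inter-alliance contact,
seasonal date scatter, activity labels, scripted mortality.  It does not
emulate: space (ranging, encounter structure), females and consortships,
observation effort bias, identification error, gradual bond drift within a
period, or demographic turnover beyond scripted deaths.  Passing recovery
tests therefore shows the estimators resolve the planted association
structure at field-like sampling depth — not that field data are this
clean.

## Numerical and degenerate-input choices

Merge-height ties and equal-Q cuts break deterministically (lexicographic /
highest level).  Agglomeration tolerance 1e-12 separates "tie" from
"greater".  All-zero matrices make modularity undefined (NaN, logged), and
`best_partition` then falls back to the single-cluster partition.  Matrix
CSVs round-trip at 4 decimals; re-read matrices are symmetrized by
averaging to absorb rounding.  Empty filter output is legal (warned, not
fatal).  All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global RNG state is touched.

## Known limitations

The permutation null uses one fixed swap schedule rather than adaptive
mixing diagnostics; very dense or very sparse incidence matrices may need a
longer burn-in.  Modularity maximization is restricted to
dendrogram-consistent partitions (as in the standard workflow for these
data), so it cannot detect communities that violate the hierarchy.  Strength
normalization within small alliances is noisy — with a two-male alliance,
`wStrength_N` is 1 for both by construction.  The field study's own
matrices are required to reproduce its printed Q/CCC/HWI values; see
`data/external/README.md`.
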