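# alliancenet

Social-network analysis of multi-level male alliances in fission–fusion
animal societies, built around the system in which such alliances are best
documented: Indo-Pacific bottlenose dolphins (*Tursiops aduncus*) of Shark
Bay, where pairs/trios of males (first-order alliances) nest within stable
teams of 4–14 (second-order alliances), some of which cooperate as
"alliances of alliances" (third-order alliances).

The package takes group-composition **surveys** (timestamped snapshots of a
group's members and predominant activity) through the full analysis chain a
behavioral ecologist would run:

1. **Filtering** — keep resting/travelling/socializing groups in the field
   season (August–December), drop same-day resights (membership Jaccard
   overlap > 0.5 with an earlier same-day survey) and inter-group conflicts.
2. **Association** — the half-weight index per dyad,
   `HWI = x / (x + y_AB + (y_A + y_B)/2)`, which with one group per sampling
   period reduces to `2x / (n_A + n_B)`; optional permutation test for
   preferential association (checkerboard swaps preserving group sizes and
   individual sighting counts).
3. **Community detection** — average-linkage agglomerative clustering on the
   HWI similarity scale; the dendrogram cut is chosen by maximizing Newman's
   weighted modularity `Q = Σ_c [W_c/W − (S_c/2W)²]`, and the fit of the
   hierarchy is diagnosed by the cophenetic correlation coefficient (CCC),
   with CCC > 0.8 read as a good representation.
4. **Strength** — per male, `wStrength` (summed HWI to his own second-order
   alliance) and `bStrength` (summed HWI to third-order-allied alliances),
   each normalized by the maximum within his alliance (`wStrength_N`,
   `bStrength_N` ∈ [0, 1]); discrete temporal snapshots re-run the whole
   chain per period; `unit_mean_hwi` tracks cohesion between first-order
   units.
5. **Fusion coding** — unique-pair tallies of affiliative behavior
   (petting/rubbing, D0 near-contacts, synchronous surfacing) during
   inter-alliance fusion events, split into second- vs third-order pairs,
   plus Cohen's kappa for inter-coder reliability.
6. **Synthetic societies** — a unit-seeded generative model of the survey
   process with closed-form expected HWI per dyad class, so the whole chain
   is testable against known ground truth without field data.

## Worked example

```
$ alliancenet simulate --preset T1 --seed 0 --n-surveys 2000 -o results/demo
wrote 2000 surveys for 24 individuals
$ alliancenet report -s results/demo/surveys.csv -r results/demo/registry.yaml -o results/demo
```

The report summary (abridged) for this run:

```json
{
  "n_surveys": 1027,
  "n_individuals": 24,
  "q_max": 0.4090,
  "cut_at_qmax": 0.3559,
  "ccc": 0.9970,
  "n_clusters": 3
}
```

Reading: of the 2000 simulated surveys, 1027 survive the activity/season/
resight filters; clustering the resulting HWI matrix finds maximum
modularity Q = 0.41 cutting the dendrogram at HWI ≈ 0.36, yielding exactly
the three planted second-order alliances (12, 7 and 5 males), and the
dendrogram represents the dyadic associations almost perfectly
(CCC = 0.997).  The same numbers are printed by the numbered drivers under
`analysis/` (01 simulate → 02 associations → 03 communities → 04 strength →
05 fusion tallies), which also verify that the designated bridge trios carry
the top normalized between-alliance strengths and that the fusion coder
reproduces the generator's true tallies.

`alliancenet tally` with no arguments tallies the packaged ten-fusion-event
behavior log: 20 unique third-order petting/rubbing pairs and 5 unique
third-order synch pairs across events, 13 intra-alliance petting/rubbing
pairs after cross-event deduplication (7 KS, 4 RR, 2 PD).

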