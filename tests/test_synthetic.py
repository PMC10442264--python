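import itertools
from datetime import date

import numpy as np
import pytest

from alliancenet.association import association_matrix
from alliancenet.community import cluster_diagnostics
from alliancenet.strength import SnapshotSpec, strength_table, temporal_snapshots
from alliancenet.synthetic import (
    SocietyConfig,
    classify_dyad,
    config_from_yaml,
    expected_hwi,
    expected_hwi_dyad,
    generate_fusion_log,
    generate_surveys,
    preset_t1,
    preset_t3,
)
from alliancenet.fusion_coding import tally_event


def tiny_config(**kw):
    defaults = dict(
        alliances={
            "X": (frozenset({"A", "B"}), frozenset({"C", "D"})),
            "Y": (frozenset({"E", "F"}), frozenset({"G", "H"})),
        },
        third_order={frozenset({"X", "Y"}): 0.2},
        bridge_units={"X": frozenset({"A", "B"}), "Y": frozenset({"E", "F"})},
        n_surveys=400,
        seed=0,
    )
    defaults.update(kw)
    return SocietyConfig(**defaults)


class TestConfigValidation:
    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            tiny_config(p2=1.5)

    def test_overlapping_units_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            tiny_config(
                alliances={
                    "X": (frozenset({"A", "B"}), frozenset({"B", "C"})),
                }
            )

    def test_bridge_unit_must_belong_to_alliance(self):
        with pytest.raises(ValueError, match="bridge"):
            tiny_config(bridge_units={"X": frozenset({"E", "F"})})

    def test_unknown_third_order_alliance_rejected(self):
        with pytest.raises(ValueError, match="third-order"):
            tiny_config(third_order={frozenset({"X", "Z"}): 0.1})


class TestGenerateSurveys:
    def test_reproducible_under_seed(self):
        s1, _ = generate_surveys(tiny_config(seed=5))
        s2, _ = generate_surveys(tiny_config(seed=5))
        assert [(s.date, s.members) for s in s1] == [(s.date, s.members) for s in s2]
        s3, _ = generate_surveys(tiny_config(seed=6))
        assert [(s.date, s.members) for s in s1] != [(s.date, s.members) for s in s3]

    def test_isolated_units_when_no_attachment(self):
        cfg = tiny_config(p2=0.0, third_order={frozenset({"X", "Y"}): 0.0})
        surveys, _ = generate_surveys(cfg)
        units = [u for us in cfg.alliances.values() for u in us]
        for s in surveys:
            assert any(s.members <= u for u in units)

    def test_no_third_order_contact_when_p3_zero(self):
        cfg = tiny_config(third_order={frozenset({"X", "Y"}): 0.0})
        surveys, _ = generate_surveys(cfg)
        m = association_matrix(surveys, cfg.individuals, min_sightings=0)
        for a, b in itertools.combinations(cfg.individuals, 2):
            if cfg.alliance_of(a) != cfg.alliance_of(b):
                assert m.get(a, b) == 0.0

    def test_class_ordering_within_gt_alliance_gt_cross(self):
        cfg = preset_t1(seed=11, n_surveys=2000)
        surveys, truth = generate_surveys(cfg)
        m = association_matrix(surveys, cfg.individuals)
        means = {c: [] for c in truth.expected_hwi_by_class}
        for a, b in itertools.combinations(cfg.individuals, 2):
            means[classify_dyad(cfg, a, b)].append(m.get(a, b))
        assert (
            np.mean(means["within_unit"])
            > np.mean(means["within_alliance"])
            > np.mean(
                means["third_order_bridge"] + means["third_order_nonbridge"]
            )
        )
        assert np.mean(means["third_order_bridge"]) > np.mean(
            means["third_order_nonbridge"]
        )

    def test_dates_in_range_and_activities_from_distribution(self):
        cfg = tiny_config()
        surveys, _ = generate_surveys(cfg)
        for s in surveys:
            assert cfg.start <= s.date <= cfg.end
            assert s.activity in cfg.activity_dist

    def test_mortality_removes_individual_after_last_date(self):
        cfg = tiny_config(
            n_surveys=600, mortality=(("A", date(2009, 12, 31)),)
        )
        surveys, _ = generate_surveys(cfg)
        late = [s for s in surveys if s.date > date(2009, 12, 31)]
        assert late and all("A" not in s.members for s in late)
        early = [s for s in surveys if s.date <= date(2009, 12, 31)]
        assert any("A" in s.members for s in early)

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "society.yaml"
        p.write_text(
            """
alliances:
  X: [[A, B], [C, D]]
  Y: [[E, F]]
third_order:
  - pair: [X, Y]
    p3: 0.15
bridge_units:
  X: [A, B]
p2: 0.4
n_surveys: 50
seed: 3
mortality:
  - id: A
    last_date: 2009-10-01
"""
        )
        cfg = config_from_yaml(p)
        assert cfg.p2 == 0.4
        assert cfg.third_order[frozenset({"X", "Y"})] == 0.15
        assert cfg.mortality == (("A", date(2009, 10, 1)),)
        surveys, _ = generate_surveys(cfg)
        assert len(surveys) == 50


class TestExpectedHWI:
    def test_degenerate_within_unit_is_one(self):
        cfg = tiny_config(
            p_unit_cohesion=1.0, p2=0.0, third_order={frozenset({"X", "Y"}): 0.0}
        )
        assert expected_hwi(cfg, "within_unit") == pytest.approx(1.0)

    def test_non_allied_zero_without_common_ally(self):
        cfg = preset_t1()
        assert expected_hwi(cfg, "non_allied") == 0.0

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            expected_hwi(tiny_config(), "besties")

    def test_matches_monte_carlo(self):
        """Closed-form per-class expectations vs simulation at 20k surveys."""
        cfg = preset_t1(seed=7, n_surveys=20000)
        surveys, truth = generate_surveys(cfg)
        m = association_matrix(surveys, cfg.individuals)
        obs = {c: [] for c in truth.expected_hwi_by_class}
        for a, b in itertools.combinations(cfg.individuals, 2):
            obs[classify_dyad(cfg, a, b)].append(m.get(a, b))
        for cls, exp in truth.expected_hwi_by_class.items():
            mc = np.mean(obs[cls]) if obs[cls] else 0.0
            assert mc == pytest.approx(exp, abs=0.02), cls

    def test_dyad_level_expectation_brute_force_oracle(self):
        """Exact per-dyad expectation vs exhaustive enumeration of the
        generative process on a tiny society."""
        cfg = SocietyConfig(
            alliances={
                "X": (frozenset({"A", "B"}), frozenset({"C", "D"})),
                "Y": (frozenset({"E", "F"}),),
            },
            third_order={frozenset({"X", "Y"}): 0.3},
            bridge_units={"X": frozenset({"A", "B"})},
            p_unit_cohesion=0.8,
            p2=0.5,
            seed=0,
        )
        ids = cfg.individuals
        units = [(a, u) for a, us in cfg.alliances.items() for u in us]

        def brute_presence_probs():
            """Enumerate seed choice x attachment outcomes x member coin
            flips exactly, accumulating P(member set)."""
            from itertools import product

            pres = {i: 0.0 for i in ids}
            co = {frozenset(p): 0.0 for p in itertools.combinations(ids, 2)}
            pc = cfg.p_unit_cohesion
            for seed_aid, seed_unit in units:
                p_seed = 1.0 / len(units)
                # attachment indicator sets: same-alliance units + one unit
                # per allied alliance
                own = [u for a, u in units if a == seed_aid and u != seed_unit]
                allied = cfg.partners_of(seed_aid)
                # enumerate attachment outcomes
                own_opts = list(product([0, 1], repeat=len(own)))
                ally_opts = []
                for partner, p3 in allied:
                    punits = [u for a, u in units if a == partner]
                    opts = [(None, 1 - p3)]
                    weights = [cfg.unit_weight(partner, u) for u in punits]
                    tot = sum(weights)
                    for u, w in zip(punits, weights):
                        opts.append((u, p3 * w / tot))
                    ally_opts.append(opts)
                for own_choice in own_opts:
                    p_own = 1.0
                    present_units = [seed_unit]
                    for inc, u in zip(own_choice, own):
                        p_own *= cfg.p2 if inc else (1 - cfg.p2)
                        if inc:
                            present_units.append(u)
                    for ally_choice in product(*ally_opts) if ally_opts else [()]:
                        p_ally = 1.0
                        chosen = list(present_units)
                        for u, pu in ally_choice:
                            p_ally *= pu
                            if u is not None:
                                chosen.append(u)
                        p_out = p_seed * p_own * p_ally
                        pool = [i for u in chosen for i in u]
                        for i in pool:
                            pres[i] += p_out * pc
                        for x, y in itertools.combinations(sorted(pool), 2):
                            co[frozenset({x, y})] += p_out * pc * pc
            return pres, co

        pres, co = brute_presence_probs()
        from alliancenet.synthetic import (
            _per_survey_cosighting,
            _per_survey_presence,
        )

        for i in ids:
            assert _per_survey_presence(cfg, i) == pytest.approx(pres[i])
        for a, b in itertools.combinations(ids, 2):
            assert _per_survey_cosighting(cfg, a, b) == pytest.approx(
                co[frozenset({a, b})]
            ), (a, b)
            exp = expected_hwi_dyad(cfg, a, b)
            denom = pres[a] + pres[b]
            assert exp == pytest.approx(
                2 * co[frozenset({a, b})] / denom if denom else 0.0
            )


class TestFusionLogGeneration:
    def test_zero_rates_empty_log(self):
        cfg = tiny_config()
        events, records, tallies = generate_fusion_log(
            cfg, n_events=5, rates={"PET": 0, "RUB": 0, "D0": 0, "SYNCH": 0}
        )
        assert records == []
        assert all(len(t.third_pr_d0_pairs) == 0 for t in tallies)

    def test_saturated_rates_every_pair_everywhere(self):
        cfg = tiny_config()
        events, records, tallies = generate_fusion_log(
            cfg, n_events=3, rates={"PET": 1.0, "RUB": 1.0, "D0": 1.0, "SYNCH": 1.0}
        )
        for ev, t in zip(events, tallies):
            n = len(ev.participants)
            total_pairs = n * (n - 1) // 2
            assert t.third_pr_pairs == t.third_pr_d0_pairs
            assert (
                len(t.third_pr_pairs)
                + len(t.second_pr_pairs)
                + len(t.non_allied_pr_pairs)
                == total_pairs
            )

    def test_tally_matches_generator_truth_many_seeds(self):
        cfg = preset_t3(seed=0)
        reg = cfg.to_registry(periods=("ALL",))
        for seed in range(50):
            events, records, truth_tallies = generate_fusion_log(
                cfg, n_events=4, seed=seed
            )
            by_event = {}
            for r in records:
                by_event.setdefault(r.event_id, []).append(r)
            for ev, truth in zip(events, truth_tallies):
                recomputed = tally_event(
                    by_event.get(ev.event_id, []), reg, "ALL", event=ev
                )
                assert recomputed.third_pr_pairs == truth.third_pr_pairs
                assert recomputed.third_pr_d0_pairs == truth.third_pr_d0_pairs
                assert recomputed.second_pr_pairs == truth.second_pr_pairs
                assert recomputed.third_synch_pairs == truth.third_synch_pairs

    def test_no_third_order_config_rejected(self):
        cfg = tiny_config(third_order={})
        with pytest.raises(ValueError, match="third-order"):
            generate_fusion_log(cfg, n_events=2)


class TestPipelineRecovery:
    def test_planted_alliances_recovered_single_seed(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = preset_t1(seed=123, n_surveys=2000)
        surveys, truth = generate_surveys(cfg)
        m = association_matrix(surveys, cfg.individuals)
        diag = cluster_diagnostics(m)
        planted = [truth.planted_partition[i] for i in m.ids]
        assert adjusted_rand_score(planted, diag.best.labels(m.ids)) == 1.0

    def test_mortality_propagates_to_snapshots(self):
        cfg = preset_t1(seed=4, n_surveys=1500)
        cfg = type(cfg)(
            **{
                **cfg.__dict__,
                "mortality": (("MID", date(2010, 12, 31)),),
                "end": date(2011, 12, 31),
                "n_surveys": 1500,
            }
        )
        surveys, _ = generate_surveys(cfg)
        roster = frozenset(cfg.individuals)
        spec = SnapshotSpec(
            periods=(("T1", 2009, 2010), ("T2", 2011, 2011)),
            rosters={"T1": roster, "T2": roster - {"MID"}},
        )
        reg = cfg.to_registry(periods=("T1", "T2"))
        snaps = temporal_snapshots(surveys, spec, reg, min_sightings=1)
        assert "MID" in snaps["T1"].matrix.ids
        assert "MID" not in snaps["T2"].matrix.ids
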