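"""Cross-tree aggregation: proportions, confidence rule, branch calls,
rate summaries and the reconstruction loop."""

import numpy as np
import pytest

from mkasr import aggregate, mk, synthetic, traits
from mkasr.aggregate import (
    AnalysisConfig,
    CladeNodeStates,
    TreeRecord,
    clade_state_proportions,
    confidence_and_branch_calls,
    rate_table,
    reconstruct_over_sample,
    render_clade_table,
    round_half_up,
)
from mkasr.treeio import CladeDefinition, TreeSample, parse_newick


def _record(i, crown, stem, model="ER", rate=0.1, mono=True):
    return TreeRecord(
        trait="tr",
        tree_index=i,
        model=model,
        rates={"0 to 1": rate, "1 to 0": rate},
        logL=-1.0,
        aic=4.0,
        converged=True,
        aic_table={},
        clades={"c": CladeNodeStates(crown, stem, mono, 3)},
    )


class TestProportions:
    def test_two_thirds_one_third(self):
        recs = [_record(i, c, 0) for i, c in enumerate([0, 0, 1])]
        tab = clade_state_proportions(recs)
        crown = tab[tab.node_kind == "crown"].set_index("state").proportion
        assert crown[0] == pytest.approx(2 / 3)
        assert crown[1] == pytest.approx(1 / 3)
        rendered = render_clade_table(tab)
        assert set(rendered[rendered.node_kind == "crown"].rendered) == {"0.67", "0.33"}

    def test_unanimous(self):
        recs = [_record(i, 1, 1) for i in range(300)]
        tab = clade_state_proportions(recs)
        assert tab[(tab.node_kind == "crown") & (tab.state == 1)].proportion.iloc[0] == 1.0

    def test_sums_to_one_and_stem_denominator_drops_rootless(self):
        recs = [_record(0, 0, None), _record(1, 0, 1), _record(2, 1, 1)]
        tab = clade_state_proportions(recs)
        for kind in ("crown", "stem"):
            sub = tab[tab.node_kind == kind]
            assert sub.proportion.sum() == pytest.approx(1.0, abs=1e-9)
        assert tab[tab.node_kind == "stem"].n_trees.iloc[0] == 2

    def test_removing_trees_moves_proportions_boundedly(self):
        rng = np.random.default_rng(0)
        recs = [_record(i, int(rng.integers(2)), 0) for i in range(40)]
        full = clade_state_proportions(recs)
        p_full = full[(full.node_kind == "crown") & (full.state == 0)].proportion.iloc[0]
        for m in (4, 10):
            part = clade_state_proportions(recs[m:])
            p = part[(part.node_kind == "crown") & (part.state == 0)].proportion.iloc[0]
            assert abs(p - p_full) <= m / (40 - m) + 1e-12


class TestConfidenceAndCalls:
    def test_exact_threshold_is_not_confident(self):
        recs = [_record(i, 0 if i < 18 else 1, 0) for i in range(20)]  # 0.90 exactly
        tab = clade_state_proportions(recs)
        (call,) = confidence_and_branch_calls(tab, AnalysisConfig())
        assert not call.crown_confident
        assert call.call == "equivocal"

    def test_strong_change_requires_both_confident_and_differing(self):
        recs = [_record(i, 1, 0) for i in range(20)]
        (call,) = confidence_and_branch_calls(clade_state_proportions(recs))
        assert call.call == "strong-change"
        assert call.crown_state == 1 and call.stem_state == 0

    def test_no_change_when_same_state(self):
        recs = [_record(i, 0, 0) for i in range(20)]
        (call,) = confidence_and_branch_calls(clade_state_proportions(recs))
        assert call.call == "no-change"

    def test_equivocal_stem_blocks_call(self):
        crown = [1] * 20
        stem = [0] * 11 + [1] * 9  # 0.55
        recs = [_record(i, c, s) for i, (c, s) in enumerate(zip(crown, stem))]
        (call,) = confidence_and_branch_calls(clade_state_proportions(recs))
        assert call.call == "equivocal"

    def test_bold_flag_matches_confidence(self):
        recs = [_record(i, 0 if i < 19 else 1, 0) for i in range(20)]
        tab = clade_state_proportions(recs)
        rendered = render_clade_table(tab)
        calls = confidence_and_branch_calls(tab)
        top = rendered[(rendered.node_kind == "crown") & (rendered.state == 0)]
        assert bool(top.bold.iloc[0]) == calls[0].crown_confident


class TestRateTable:
    def test_single_tree_avg_min_max_equal(self):
        rt = rate_table([_record(0, 0, 0, rate=0.3)])
        row = rt.rates.iloc[0]
        assert row.average == row["min"] == row["max"] == 0.3

    def test_average_and_range(self):
        recs = [_record(i, 0, 0, rate=r) for i, r in enumerate([0.1, 0.2, 0.3])]
        rt = rate_table(recs)
        row = rt.rates[rt.rates.transition == "0 to 1"].iloc[0]
        assert row.average == pytest.approx(0.2)
        assert (row["min"], row["max"]) == (0.1, 0.3)

    def test_models_never_pooled(self):
        recs = [
            _record(0, 0, 0, model="ER", rate=0.1),
            _record(1, 0, 0, model="ARD", rate=0.9),
        ]
        rt = rate_table(recs)
        assert set(rt.rates.model) == {"ER", "ARD"}
        er = rt.rates[(rt.rates.model == "ER") & (rt.rates.transition == "0 to 1")]
        assert er["max"].iloc[0] == 0.1
        assert rt.model_fractions.fraction.sum() == pytest.approx(1.0)


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(0.005, 0.01), (0.985, 0.99), (0.995, 1.0), (0.125, 0.13), (0.904, 0.9)]
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_up(x, 2) == expected


class TestReconstructOverSample:
    def _study(self, seed=1, n_tips=30, n_trees=4):
        spec = synthetic.GeneratorSpec(n_tips=n_tips, sample_size=n_trees, seed=seed)
        return synthetic.make_study(spec)

    def test_uniform_character_reconstructs_uniformly(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        sample = TreeSample([tree])
        tips = mk.TipStates(k=2, states={l: 1 for l in "ABCD"})
        clades = [CladeDefinition("ab", frozenset("AB"))]
        recs = reconstruct_over_sample(sample, tips, clades, AnalysisConfig(n_draws=10))
        assert recs[0].clades["ab"].crown_state == 1
        assert recs[0].clades["ab"].stem_state == 1

    def test_deterministic_given_seed(self):
        study = self._study()
        sp = traits.collapse_to_species(study.matrix)
        tips, _ = traits.tip_states_for_trait(
            sp, "leaflet_type", study.sample[0].tip_labels
        )
        cfg = AnalysisConfig(n_draws=20, seed=77)
        a = reconstruct_over_sample(study.sample, tips, study.clades, cfg)
        b = reconstruct_over_sample(study.sample, tips, study.clades, cfg)
        for ra, rb in zip(a, b):
            assert ra.model == rb.model and ra.rates == rb.rates
            assert {c: vars(v) for c, v in ra.clades.items()} == {
                c: vars(v) for c, v in rb.clades.items()
            }

    def test_absent_clade_marked_missing(self):
        study = self._study()
        sp = traits.collapse_to_species(study.matrix)
        tips, _ = traits.tip_states_for_trait(
            sp, "ad_cell_type", study.sample[0].tip_labels
        )
        ghost = CladeDefinition("ghost", frozenset({"zz1", "zz2"}))
        recs = reconstruct_over_sample(
            study.sample, tips, [ghost], AnalysisConfig(n_draws=5, seed=1)
        )
        assert all(r.clades["ghost"].missing for r in recs)

    def test_forced_derived_state_recovered_on_generating_branch(self):
        study = self._study(seed=3, n_tips=40, n_trees=8)
        sp = traits.collapse_to_species(study.matrix)
        tips, _ = traits.tip_states_for_trait(
            sp, "ad_cell_type", study.sample[0].tip_labels
        )
        cfg = AnalysisConfig(n_draws=30, seed=3)
        recs = reconstruct_over_sample(study.sample, tips, study.clades, cfg)
        tab = clade_state_proportions(recs, tips.state_names)
        calls = confidence_and_branch_calls(tab, cfg)
        focal = study.clades[0].name
        strong = [c.clade for c in calls if c.call == "strong-change"]
        assert strong == [focal]
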