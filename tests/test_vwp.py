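import dataclasses

import numpy as np
import pandas as pd
import pytest

from lexcompnet.grunet import batch_forward, init_params
from lexcompnet.phonology import VocabularyItem
from lexcompnet.representations import AggregateSpec, jaccard
from lexcompnet.synth import gen_vwp_fixture
from lexcompnet.vwp import (
    CANDIDATE_CLASSES,
    RelatednessTables,
    TrialSpec,
    grand_average,
    relatedness_flags,
    results_frame,
    rhyme_of,
    run_trial,
    select_trials,
)


class TestRhyme:
    def test_rhyme_is_last_vowel_to_end(self, toy_inventory):
        assert rhyme_of(("b", "a", "t"), toy_inventory) == ("a", "t")
        assert rhyme_of(("k", "o"), toy_inventory) == ("o",)

    def test_no_vowel_falls_back_to_whole_label(self, toy_inventory):
        assert rhyme_of(("b", "t"), toy_inventory) == ("b", "t")

    def test_final_n_mode(self, toy_inventory):
        assert rhyme_of(("b", "a", "t"), toy_inventory, mode="final-n") == ("a", "t")


class TestRelatednessFlags:
    def _setup(self):
        # 5 items with hand-built binary vectors over 8 dims
        sem = np.array(
            [
                [1, 1, 1, 1, 0, 0, 0, 0],
                [1, 1, 1, 0, 1, 0, 0, 0],  # J with 0: 3/5
                [0, 0, 0, 0, 1, 1, 1, 1],  # J with 0: 0
                [1, 1, 0, 0, 1, 1, 0, 0],  # J with 0: 2/6
                [1, 0, 1, 0, 1, 0, 1, 0],  # J with 0: 2/6
            ],
            dtype=float,
        )
        vis = sem[::-1].copy()
        vocab = [
            VocabularyItem("a", ("b", "a"), "c"),
            VocabularyItem("b", ("b", "o"), "c"),
            VocabularyItem("c", ("k", "a"), "c"),
            VocabularyItem("d", ("t", "o"), "c"),
            VocabularyItem("e", ("t", "a"), "c"),
        ]
        tables = RelatednessTables.from_binary([v.item_id for v in vocab], sem, vis)
        return vocab, tables, sem, vis

    def test_self_comparison_rejected(self, toy_inventory):
        vocab, tables, _, _ = self._setup()
        with pytest.raises(ValueError):
            relatedness_flags(vocab[0], vocab[0], tables, toy_inventory)

    def test_maximum_pair_is_related(self, toy_inventory):
        vocab, tables, sem, _ = self._setup()
        # pair (a,b) has the largest semantic Jaccard of all 10 pairs
        f = relatedness_flags(vocab[0], vocab[1], tables, toy_inventory)
        assert f["sem_related"]

    def test_flags_match_hand_computed_percentiles(self, toy_inventory):
        vocab, tables, sem, vis = self._setup()
        # independent oracle: percentile over all 10 pairwise values
        ids = [v.item_id for v in vocab]
        sem_vals = [jaccard(sem[i], sem[j]) for i in range(5) for j in range(i + 1, 5)]
        hi = np.percentile(sem_vals, 85)
        lo = np.percentile(sem_vals, 15)
        for i in range(5):
            for j in range(i + 1, 5):
                f = relatedness_flags(vocab[i], vocab[j], tables, toy_inventory)
                expected = jaccard(sem[i], sem[j])
                assert f["sem_related"] == (expected >= hi)
                assert f["sem_unrelated"] == (expected <= lo)

    def test_onset_share_follows_first_phone(self, toy_inventory):
        vocab, tables, _, _ = self._setup()
        assert relatedness_flags(vocab[0], vocab[1], tables, toy_inventory)["onset_share"]
        assert not relatedness_flags(vocab[0], vocab[2], tables, toy_inventory)["onset_share"]


class TestSelectTrials:
    def test_engineered_fixture_yields_exactly_its_trials(self, vwp_fixture):
        trials = select_trials(vwp_fixture.vocab, vwp_fixture.tables(),
                               vwp_fixture.inventory)
        assert set(trials) == set(vwp_fixture.expected_trials)

    def test_removing_prel_items_leaves_no_trials(self, vwp_fixture):
        drop = {"prel", "prel2"}
        keep = [v for v in vwp_fixture.vocab if v.item_id not in drop]
        idx = [i for i, v in enumerate(vwp_fixture.vocab) if v.item_id not in drop]
        tables = RelatednessTables.from_binary(
            [v.item_id for v in keep],
            vwp_fixture.sem_binary[idx],
            vwp_fixture.vis_binary[idx],
        )
        assert select_trials(keep, tables, vwp_fixture.inventory) == []

    def test_result_invariant_to_vocabulary_order(self, vwp_fixture):
        shuffled = gen_vwp_fixture(seed=99)  # same items, different row order
        trials = select_trials(shuffled.vocab, shuffled.tables(), shuffled.inventory)
        base = select_trials(vwp_fixture.vocab, vwp_fixture.tables(),
                             vwp_fixture.inventory)
        assert set(trials) == set(base)

    def test_no_shared_onsets_means_no_trials(self, vwp_fixture):
        # drop the only onset-sharing competitor pair by removing 't'
        keep = [v for v in vwp_fixture.vocab if v.item_id != "t"]
        idx = [i for i, v in enumerate(vwp_fixture.vocab) if v.item_id != "t"]
        tables = RelatednessTables.from_binary(
            [v.item_id for v in keep],
            vwp_fixture.sem_binary[idx],
            vwp_fixture.vis_binary[idx],
        )
        assert select_trials(keep, tables, vwp_fixture.inventory) == []

    def test_selected_trials_pass_flag_reverification(self, vwp_fixture):
        tables = vwp_fixture.tables()
        by_id = {v.item_id: v for v in vwp_fixture.vocab}
        for t in select_trials(vwp_fixture.vocab, tables, vwp_fixture.inventory):
            target = by_id[t.target_id]
            f = relatedness_flags(target, by_id[t.prel_id], tables,
                                  vwp_fixture.inventory)
            assert f["onset_share"] and not f["rhyme_share"]
            assert f["sem_unrelated"] and f["vis_unrelated"]
            f = relatedness_flags(target, by_id[t.srel_id], tables,
                                  vwp_fixture.inventory)
            assert f["sem_related"] and f["vis_unrelated"]


class TestRunTrial:
    def test_activations_match_independent_reimplementation(self, fixture_dataset):
        ds = fixture_dataset
        params = init_params(ds.X.shape[2], ds.spec.total_dim, 5)
        spec = TrialSpec("t", "prel", "srel", "vrel", "urel")
        semvis = {i: ds.semvis_targets[k] for k, i in enumerate(ds.item_ids)}
        x = ds.X[ds.item_ids.index("t")]
        res = run_trial(params, spec, x, semvis, ds.spec)
        # brute-force oracle: slice -> binarize -> Jaccard per step
        hs, _ = batch_forward(params, x[None])
        for t in range(x.shape[0]):
            out = (hs[0, t, ds.spec.semvis] > 0.5).astype(float)
            for j, cid in enumerate(spec.candidate_ids()):
                assert res.activations[t, j] == pytest.approx(
                    jaccard(out, semvis[cid])
                )

    def test_urel_relative_activation_is_zero(self, fixture_dataset):
        ds = fixture_dataset
        params = init_params(ds.X.shape[2], ds.spec.total_dim, 6)
        spec = TrialSpec("t", "prel", "srel", "vrel", "urel")
        semvis = {i: ds.semvis_targets[k] for k, i in enumerate(ds.item_ids)}
        res = run_trial(params, spec, ds.X[ds.item_ids.index("t")], semvis, ds.spec)
        assert np.all(res.relative[:, 3] == 0.0)

    def test_attended_is_argmax_of_raw_activations(self, fixture_dataset):
        ds = fixture_dataset
        params = init_params(ds.X.shape[2], ds.spec.total_dim, 7)
        spec = TrialSpec("t", "prel", "srel", "vrel", "urel")
        semvis = {i: ds.semvis_targets[k] for k, i in enumerate(ds.item_ids)}
        res = run_trial(params, spec, ds.X[ds.item_ids.index("t")], semvis, ds.spec)
        np.testing.assert_array_equal(res.attended,
                                      np.argmax(res.activations, axis=1))


class TestGrandAverage:
    def _frame(self, rel_by_class, trial=0):
        rows = []
        T = len(next(iter(rel_by_class.values())))
        for t in range(T):
            for cls in CANDIDATE_CLASSES:
                rows.append((0, trial, "t", t, cls, 0.0, rel_by_class[cls][t], "PREL"))
        return pd.DataFrame(rows, columns=["model_seed", "trial", "target",
                                           "timestep", "class", "activation",
                                           "relative_activation", "attended"])

    def test_single_trial_average_equals_trial(self):
        rel = {"PREL": [0.3, 0.2], "SREL": [0.1, 0.4], "VREL": [0.0, 0.1],
               "UREL": [0.0, 0.0]}
        table, _ = grand_average([self._frame(rel)])
        prel = table[table["class"] == "PREL"].sort_values("timestep")
        np.testing.assert_allclose(prel["mean"], rel["PREL"])

    def test_identical_trials_have_zero_ci_width(self):
        rel = {"PREL": [0.3], "SREL": [0.1], "VREL": [0.0], "UREL": [0.0]}
        table, _ = grand_average([self._frame(rel, 0), self._frame(rel, 1)])
        assert np.all(table["ci_hi"] - table["ci_lo"] == 0.0)

    def test_crossover_detection(self):
        rel = {"PREL": [0.3, 0.2, 0.05], "SREL": [0.1, 0.15, 0.4],
               "VREL": [0.0, 0.0, 0.3], "UREL": [0.0, 0.0, 0.0]}
        _, crossover = grand_average([self._frame(rel)])
        assert crossover == 2

    def test_no_results_raises(self):
        with pytest.raises(ValueError):
            grand_average([])
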