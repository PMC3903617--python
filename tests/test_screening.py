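"""Saturation-screen orchestration: library, reference, filter, ranking."""

import numpy as np
import pytest

from affimut.mutate import MinimizationConfig, build_ensemble
from affimut.screening import (EnergyHistogram, MutationResult, ScreeningConfig,
                               delta_energy, enumerate_library, filter_no_contact,
                               movable_keys_for, mutation_seed, rank_and_select,
                               wt_reference)
from affimut.structure import CdrSelection, StructureError
from affimut.synth import ToyComplexSpec, make_toy_complex


class TestEnumerateLibrary:
    def test_nineteen_specs_per_position(self, toy_complex):
        specs = enumerate_library(toy_complex, CdrSelection([("A", 5)]))
        assert len(specs) == 19
        wt = toy_complex.get_residue("A", 5).name
        assert all(s.target3 != wt for s in specs)

    def test_sixty_two_positions_give_full_library_size(self, library, ff_params):
        """The saturation library for a 62-residue CDR has 62*19 entries."""
        seq = "AS" * 31  # 62 mutable residues
        spec = ToyComplexSpec(seq_a=seq, seq_b="ASASA", separation=25.0, seed=1)
        s = make_toy_complex(spec, library=library, params=ff_params)
        sel = CdrSelection([("A", i + 1) for i in range(62)])
        specs = enumerate_library(s, sel)
        assert len(specs) == 1178

    def test_duplicate_positions_rejected(self, toy_complex):
        with pytest.raises(StructureError):
            enumerate_library(toy_complex,
                              CdrSelection([("A", 5), ("A", 5)]))

    def test_deterministic_order(self, toy_complex):
        sel = CdrSelection([("A", 5), ("A", 3)])
        a = [ (s.chain_id, s.number, s.target3)
              for s in enumerate_library(toy_complex, sel)]
        b = [ (s.chain_id, s.number, s.target3)
              for s in enumerate_library(toy_complex, sel)]
        assert a == b
        assert a[0][1] == 5  # given position order preserved


class TestWtReference:
    def test_fixed_seed_identical_median(self, toy_complex):
        cfg = ScreeningConfig(n_models_per_mutation=5, n_wt_models=10,
                              master_seed=3)
        h1, m1, _ = wt_reference(toy_complex, cfg)
        h2, m2, _ = wt_reference(toy_complex, cfg)
        assert m1 == m2
        assert np.array_equal(h1.counts, h2.counts)

    def test_subsample_median_consistent_with_larger_run(self, toy_complex):
        cfg_small = ScreeningConfig(n_models_per_mutation=5, n_wt_models=30,
                                    master_seed=5)
        cfg_big = ScreeningConfig(n_models_per_mutation=5, n_wt_models=120,
                                  master_seed=5)
        _, _, ens_small = wt_reference(toy_complex, cfg_small)
        h_big, m_big, _ = wt_reference(toy_complex, cfg_big)
        e = np.array(ens_small.energies())
        rng = np.random.default_rng(0)
        boot = [np.median(rng.choice(e, size=len(e))) for _ in range(300)]
        assert abs(np.median(e) - m_big) < 3 * max(np.std(boot), 1e-9)

    def test_rigid_interface_collapses_to_static_energy(self, library, ff_params):
        """All-Ala/Gly interfaces have nothing to perturb: the reference is a
        zero-width distribution at the static interaction energy."""
        from affimut.energy import interaction_energy
        spec = ToyComplexSpec(seq_a="AGAGAGA", seq_b="AGAGAGA",
                              separation=9.5, seed=2)
        s = make_toy_complex(spec, library=library, params=ff_params)
        cfg = ScreeningConfig(n_models_per_mutation=5, n_wt_models=10)
        hist, stat, _ = wt_reference(s, cfg)
        assert stat == pytest.approx(interaction_energy(s).e_total, abs=1e-12)
        assert hist.iqr == 0.0


class TestFilterNoContact:
    def test_counts_match_brute_force_recount(self, toy_complex, library, ff_params):
        from affimut.mutate import MutationSpec
        cfg = ScreeningConfig(n_models_per_mutation=8, n_wt_models=5)
        keys = sorted(set(movable_keys_for(toy_complex, cfg)) | {("A", 5)})
        ens = build_ensemble(toy_complex, MutationSpec("A", 5, "LYS", "sample"),
                             8, cfg.minimization, seed=4, library=library,
                             params=ff_params, movable_keys=keys,
                             keep_structures=True)
        kept, dropped = filter_no_contact(ens, 4.5)
        # oracle: recount contacts by scanning every kept/dropped model
        n_contact = 0
        for m in ens.models:
            pa = np.array([a.position for a in m.structure.atoms("A")])
            pb = np.array([a.position for a in m.structure.atoms("B")])
            d = np.linalg.norm(pa[:, None] - pb[None, :], axis=-1)
            if d.min() <= 4.5:
                n_contact += 1
        assert len(kept) == n_contact
        assert dropped == len(ens.models) - n_contact

    def test_distant_model_dropped_close_model_kept(self, toy_complex, library,
                                                    ff_params):
        from affimut.mutate import ModelEnsemble, ModelRecord
        from affimut.energy import EnergyBreakdown
        far = ModelRecord(None, EnergyBreakdown(0, 0), True, 1,
                          min_cross_distance=100.0)
        near = ModelRecord(None, EnergyBreakdown(-1, 0), True, 1,
                           min_cross_distance=4.0)
        ens = ModelEnsemble("X", [far, near], 0)
        kept, dropped = filter_no_contact(ens, 4.5)
        assert kept == [-1.0] and dropped == 1


class TestDeltaAndRanking:
    def test_identical_ensembles_give_zero_delta(self):
        energies = [-3.0, -2.0, -1.0]
        assert delta_energy(energies, float(np.median(energies))) == 0.0

    def test_empty_energies_rejected(self):
        with pytest.raises(ValueError):
            delta_energy([], 0.0)

    def _result(self, aa, de, selected=False, no_contact=False):
        return MutationResult(
            mutation_id=f"A-S5{aa}", chain_id="A", number=5, wt_aa="S",
            mut_aa=aa, energies=[de], n_filtered=0, median=de, mean=de,
            delta_e=de, delta_e_mean=de, selected=selected,
            no_contact=no_contact)

    def test_sorted_ascending_with_deterministic_ties(self):
        cfg = ScreeningConfig()
        results = [self._result("K", -1.0), self._result("E", -1.0),
                   self._result("W", 2.0), self._result("R", -5.0)]
        ranked = rank_and_select(results, cfg)
        assert [r.mut_aa for r in ranked] == ["R", "E", "K", "W"]

    def test_no_contact_results_sink_to_the_bottom(self):
        cfg = ScreeningConfig()
        results = [self._result("A", np.nan, no_contact=True),
                   self._result("R", -2.0)]
        ranked = rank_and_select(results, cfg)
        assert [r.mut_aa for r in ranked] == ["R", "A"]

    def test_all_positive_deltas_select_nothing(self):
        cfg = ScreeningConfig()
        results = [self._result("K", 0.5), self._result("W", 2.0)]
        ranked = rank_and_select(results, cfg)
        assert not any(r.selected for r in ranked)


class TestWtIdentityControl:
    def test_control_delta_distributes_around_zero(self, toy_complex,
                                                   library, ff_params):
        """Re-modeling the wild-type identity through the mutant pipeline
        shifts the median by less than twice its bootstrap error."""
        from affimut.mutate import MutationSpec
        cfg = ScreeningConfig(n_models_per_mutation=30, n_wt_models=30,
                              master_seed=21)
        hist, wt_stat, wt_ens = wt_reference(toy_complex, cfg, library, ff_params)
        keys = sorted(set(movable_keys_for(toy_complex, cfg)) | {("A", 5)})
        ens = build_ensemble(toy_complex, MutationSpec("A", 5, "SER", "sample"),
                             30, cfg.minimization, seed=77, library=library,
                             params=ff_params, movable_keys=keys)
        rng = np.random.default_rng(0)

        def boot_se(vals):
            e = np.asarray(vals)
            return np.std([np.median(rng.choice(e, size=len(e)))
                           for _ in range(300)])

        pooled = np.hypot(boot_se(ens.energies()), boot_se(wt_ens.energies()))
        assert abs(np.median(ens.energies()) - hist.median) \
            < 2 * max(pooled, 1e-6)


class TestSeeding:
    def test_per_mutation_seed_stable_and_distinct(self):
        s1 = mutation_seed(42, "A-S5R").generate_state(1)[0]
        s2 = mutation_seed(42, "A-S5R").generate_state(1)[0]
        s3 = mutation_seed(42, "A-S5K").generate_state(1)[0]
        s4 = mutation_seed(43, "A-S5R").generate_state(1)[0]
        assert s1 == s2
        assert len({s1, s3, s4}) == 3


class TestHistogram:
    def test_counts_cover_all_models(self):
        e = np.random.default_rng(0).normal(size=57)
        h = EnergyHistogram.from_energies(e)
        assert h.counts.sum() == 57
        assert h.median == pytest.approx(np.median(e))
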