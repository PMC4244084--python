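"""Generators: ground-truth consistency, determinism, kinetics and regimes."""

import numpy as np
import pytest

from oligotraj.aggregation import classify_frame
from oligotraj.contacts import residue_contacts
from oligotraj.errors import ConfigurationError, ValidationError
from oligotraj.kinetics import KineticsConfig, bound_series
from oligotraj.model import write_trajectory
from oligotraj.synthetic import (
    BrownianParams,
    KineticScenario,
    brownian_toy_sim,
    build_bead_model,
    markov_binding_generator,
    oligomer_scene_builder,
)


class TestBeadModel:
    def test_peptides_numbered_17_to_42(self):
        model = build_bead_model(3, "acd_dimer")
        chain = model.chain("0")
        nums = [n for n, _ in chain.residues]
        assert nums[0] == 17 and nums[-1] == 42 and len(nums) == 26

    def test_inhibitor_entities(self):
        assert build_bead_model(2, "acd_dimer").inhibitor_chain_ids == ["X", "Y"]
        assert build_bead_model(2, "lysozyme").inhibitor_chain_ids == ["L"]
        assert not build_bead_model(2, None).has_inhibitor


class TestMarkovGenerator:
    def test_absorbing_bound_state(self):
        sc = KineticScenario(n_peptides=3, k_on=1.0, k_off=0.0, n_frames=40,
                             dt=0.5, seed=4, initial_bound=(True,) * 3)
        traj, truth = markov_binding_generator(sc)
        assert truth.bound.all()
        for s in bound_series(traj, config=KineticsConfig()):
            assert s.b.all()

    def test_never_binds_without_on_rate(self):
        sc = KineticScenario(n_peptides=3, k_on=0.0, k_off=0.5, n_frames=40,
                             dt=0.5, seed=4, initial_bound=(False,) * 3)
        _, truth = markov_binding_generator(sc)
        assert not truth.bound.any()

    def test_self_validation_passes_on_random_scenarios(self):
        # validate=True re-analyzes every frame with the contact definitions
        for seed in (0, 1):
            sc = KineticScenario(n_peptides=6, n_frames=60, dt=0.2, k_on=0.3,
                                 k_off=0.2, k_dimer=0.05, k_undimer=0.3,
                                 seed=seed)
            markov_binding_generator(sc, validate=True)

    def test_seed_determinism_bytes(self, tmp_path):
        sc = KineticScenario(n_peptides=4, n_frames=25, dt=0.2, seed=123)
        out = []
        for k in range(2):
            traj, _ = markov_binding_generator(sc, validate=False)
            p = tmp_path / f"t{k}.txt"
            write_trajectory(traj, p)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_occupancy_matches_stationary_probability(self):
        k_on, k_off = 0.2, 0.1
        sc = KineticScenario(n_peptides=8, n_frames=3001, dt=0.5,
                             k_on=k_on, k_off=k_off, seed=6)
        _, truth = markov_binding_generator(sc, validate=False)
        p_stat = k_on / (k_on + k_off)
        occ = truth.bound.mean()
        # binomial-ish SE with an effective correlation time of ~1/(kon+koff)
        n_eff = truth.bound.shape[1] * sc.n_frames * sc.dt * (k_on + k_off)
        se = np.sqrt(p_stat * (1 - p_stat) / n_eff)
        assert abs(occ - p_stat) < 3 * se + 0.02

    def test_residence_intervals_mean(self):
        sc = KineticScenario(n_peptides=8, n_frames=3001, dt=0.5,
                             k_on=0.2, k_off=0.1, seed=8)
        _, truth = markov_binding_generator(sc, validate=False)
        ivals = np.concatenate(truth.residence_intervals())
        # censored intervals bias the mean down a bit; loose check
        assert ivals.mean() == pytest.approx(1 / 0.1, rel=0.25)

    def test_too_many_peptides_for_patches(self):
        with pytest.raises(ConfigurationError):
            sc = KineticScenario(n_peptides=10, inhibitor="lysozyme",
                                 n_frames=2, seed=0)
            markov_binding_generator(sc)

    def test_box_too_small_rejected(self):
        sc = KineticScenario(n_peptides=10, box_edge=40.0, n_frames=3, seed=0,
                             k_on=0.0, k_off=1.0, initial_bound=(False,) * 10)
        with pytest.raises(ConfigurationError):
            markov_binding_generator(sc)


class TestSceneBuilder:
    def test_ten_free_monomers(self):
        model, frame, truth = oligomer_scene_builder([(1, False)] * 10)
        state = classify_frame(residue_contacts(frame, model), model)
        assert all(len(g) == 1 for g in state.partition)
        assert not any(state.bound.values())

    def test_snapshot_composition_trimer_dimer_bound(self):
        spec = [(3, True), (2, True)] + [(1, False)] * 5
        model, frame, truth = oligomer_scene_builder(spec, seed=5)
        state = classify_frame(residue_contacts(frame, model), model)
        counts = state.species_counts(True)
        assert counts["complexed_small_oligomer"] == 2
        assert counts["free_monomer"] == 5
        assert counts["free_small_oligomer"] == 0

    def test_small_large_boundary(self):
        for size, cls in [(5, "free_small_oligomer"), (6, "free_large_oligomer")]:
            model, frame, _ = oligomer_scene_builder(
                [(size, False)] + [(1, False)] * (10 - size), seed=2)
            state = classify_frame(residue_contacts(frame, model), model)
            assert state.species_counts(True)[cls] == 1

    def test_bound_without_inhibitor_rejected(self):
        with pytest.raises(ConfigurationError):
            oligomer_scene_builder([(2, True)], inhibitor=None)

    def test_exactly_one_member_docked(self):
        model, frame, truth = oligomer_scene_builder([(4, True)] +
                                                     [(1, False)] * 6, seed=1)
        from oligotraj.aggregation import complexation_flags
        flags = complexation_flags(residue_contacts(frame, model), model)
        assert sum(flags.values()) == 1
        assert truth.bound.sum() == 1


class TestBrownianToy:
    def _oligomer_fraction(self, traj):
        n_pep = len(traj.model.peptide_chain_ids)
        fracs = []
        for frame in traj.frames[len(traj.frames) // 2:]:
            state = classify_frame(residue_contacts(frame, traj.model),
                                   traj.model)
            in_oligo = sum(len(g) for g in state.partition if len(g) > 1)
            fracs.append(in_oligo / n_pep)
        return float(np.mean(fracs))

    def test_ideal_gas_limit_stays_monomeric(self):
        fractions = [
            self._oligomer_fraction(brownian_toy_sim(BrownianParams(
                n_peptides=4, box_edge=70.0, eps_pp=0.0, n_steps=600,
                save_every=60, seed=seed)))
            for seed in (0, 1, 2)
        ]
        assert np.mean(fractions) < 0.15

    def test_strong_attraction_aggregates(self):
        fractions = [
            self._oligomer_fraction(brownian_toy_sim(BrownianParams(
                n_peptides=4, box_edge=45.0, eps_pp=1.5, n_steps=1500,
                save_every=100, seed=seed)))
            for seed in (0, 1, 2)
        ]
        assert np.mean(fractions) > 0.5

    def test_unstable_step_detected(self):
        with pytest.raises(ValidationError):
            BrownianParams(dt=1.0)           # fails the stability heuristic
        with pytest.raises(RuntimeError):
            # enormous attraction drives a blow-up at a formally stable step
            brownian_toy_sim(BrownianParams(n_peptides=4, box_edge=40.0,
                                            eps_pp=500.0, n_steps=400,
                                            seed=0))

    def test_seeded_and_reproducible(self):
        p = BrownianParams(n_peptides=2, n_steps=100, save_every=50, seed=42)
        a = brownian_toy_sim(p)
        b = brownian_toy_sim(p)
        assert np.array_equal(a.frames[-1].coords, b.frames[-1].coords)
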