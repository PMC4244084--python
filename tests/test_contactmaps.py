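"""Residue-level contact probability maps and profiles."""

import numpy as np
import pytest

from conftest import make_record, point_system
from oligotraj.contactmaps import (
    inhibitor_peptide_map,
    per_residue_profile,
    per_type_profile,
    quaternary_map,
    tertiary_map,
)
from oligotraj.errors import EmptyResultError
from oligotraj.model import ChainRole, ChainSpec, SystemModel


def _system(n_pep=2, pep_len=12, inh_len=10):
    spec = {str(i): ("peptide", pep_len) for i in range(n_pep)}
    spec["X"] = ("inhibitor", inh_len)
    return point_system(spec)


def _idx(model, chain):
    return model.chain_residue_indices(chain)


def _dock_pairs(model, pep, n=6, inh_rows=(0,)):
    """Pairs docking peptide residues 0..n-1 onto the given inhibitor rows."""
    p = _idx(model, pep)
    x = _idx(model, "X")
    return [(int(p[i]), int(x[inh_rows[i % len(inh_rows)]])) for i in range(n)]


class TestInhibitorPeptideMap:
    def test_persistent_docking_pattern_recovered(self):
        model = _system()
        pairs = _dock_pairs(model, "0", n=6)
        records = [make_record(model, pairs, t) for t in range(50)]
        cmap = inhibitor_peptide_map(records, model, threshold=5)
        # peptide '1' never binds: only peptide-'0' frames qualify
        assert cmap.n_observations == 50
        for i in range(6):
            assert cmap.probability[0, i] == pytest.approx(1.0)
        assert np.nansum(cmap.probability) == pytest.approx(6.0)

    def test_no_binding_is_empty_result(self):
        model = _system()
        records = [make_record(model, [])]
        with pytest.raises(EmptyResultError):
            inhibitor_peptide_map(records, model)

    def test_probabilities_bounded_on_random_data(self, rng):
        model = _system()
        records = []
        n_res = model.n_residues
        for t in range(40):
            pairs = {tuple(sorted(rng.choice(n_res, 2, replace=False)))
                     for _ in range(60)}
            records.append(make_record(model, list(pairs), t))
        try:
            cmap = inhibitor_peptide_map(records, model, threshold=5)
        except EmptyResultError:
            return
        assert np.nanmin(cmap.probability) >= 0.0
        assert np.nanmax(cmap.probability) <= 1.0
        assert cmap.counts.sum() >= 0

    def test_planted_bernoulli_pattern(self, rng):
        """A cell present in a known fraction of complexed observations is
        recovered to that fraction."""
        model = _system()
        base = _dock_pairs(model, "0", n=6)
        extra = (int(_idx(model, "0")[10]), int(_idx(model, "X")[7]))
        records = []
        hits = 0
        for t in range(600):
            pairs = list(base)
            if rng.random() < 0.3:
                pairs.append(extra)
                hits += 1
            records.append(make_record(model, pairs, t))
        cmap = inhibitor_peptide_map(records, model, threshold=5)
        assert cmap.probability[7, 10] == pytest.approx(hits / 600, abs=1e-12)
        assert abs(cmap.probability[7, 10] - 0.3) < 0.05


class TestProfiles:
    def test_per_residue_any_contact_dominates_rows(self):
        model = _system()
        # residue 0 of the peptide touches two inhibitor residues, each 50%
        p0 = int(_idx(model, "0")[0])
        x = _idx(model, "X")
        base = _dock_pairs(model, "0", n=6, inh_rows=(3,))
        records = []
        for t in range(100):
            pairs = list(base)
            pairs.append((p0, int(x[0]) if t % 2 else int(x[1])))
            records.append(make_record(model, pairs, t))
        cmap = inhibitor_peptide_map(records, model, threshold=5)
        profile = per_residue_profile(cmap)
        # each single pair has probability 0.5, but ANY-contact gives 1.0
        assert cmap.probability[0, 0] == pytest.approx(0.5)
        assert cmap.probability[1, 0] == pytest.approx(0.5)
        assert profile[0] == pytest.approx(1.0)
        assert (profile >= np.nanmax(cmap.probability, axis=0) - 1e-12).all()

    def test_per_type_half_bound_arginine(self):
        # inhibitor with exactly two arginines: one always in contact, one never
        pep = ChainSpec("0", ChainRole.PEPTIDE,
                        tuple((i + 1, "ALA") for i in range(8)))
        inh = ChainSpec("X", ChainRole.INHIBITOR,
                        ((1, "ARG"), (2, "GLY"), (3, "ARG"), (4, "GLY")))
        n = 12
        model = SystemModel([pep, inh],
                            [np.array([i], dtype=np.intp) for i in range(n)],
                            ["CA"] * n, ["C"] * n)
        p = _idx(model, "0")
        x = _idx(model, "X")
        pairs = [(int(p[i]), int(x[0])) for i in range(6)]  # ARG1 carries all
        records = [make_record(model, pairs, t) for t in range(20)]
        prof = per_type_profile(records, model, side="inhibitor", threshold=5)
        assert prof["R"] == pytest.approx(0.5)
        assert prof["G"] == pytest.approx(0.0)
        assert prof["W"] is None       # absent type flagged, not zero

    def test_per_type_values_bounded(self, rng):
        model = _system()
        records = [make_record(model, _dock_pairs(model, "0", n=6), t)
                   for t in range(10)]
        prof = per_type_profile(records, model, side="peptide", threshold=5)
        vals = [v for v in prof.values() if v is not None]
        assert all(0.0 <= v <= 1.0 for v in vals)


class TestTertiaryMap:
    def test_extended_chain_all_zero(self):
        model = _system()
        base = _dock_pairs(model, "0", n=6)
        records = [make_record(model, base, t) for t in range(10)]
        cmap = tertiary_map(records, model, population="complexed")
        assert np.nansum(cmap.probability) == 0.0

    def test_hairpin_antidiagonal(self):
        model = _system(pep_len=12)
        p = _idx(model, "0")
        L = 12
        hairpin = [(int(p[k]), int(p[L - 1 - k])) for k in range(4)]
        base = _dock_pairs(model, "0", n=6)
        records = [make_record(model, base + hairpin, t) for t in range(30)]
        cmap = tertiary_map(records, model, population="complexed")
        for k in range(4):
            assert cmap.probability[k, L - 1 - k] == pytest.approx(1.0)
            assert cmap.probability[L - 1 - k, k] == pytest.approx(1.0)

    def test_sequential_band_masked(self):
        model = _system()
        p = _idx(model, "0")
        base = _dock_pairs(model, "0", n=6)
        near = [(int(p[0]), int(p[1])), (int(p[2]), int(p[4]))]
        records = [make_record(model, base + near, t) for t in range(5)]
        cmap = tertiary_map(records, model, population="complexed")
        L = len(cmap.row_labels)
        band = np.abs(np.subtract.outer(np.arange(L), np.arange(L))) < 3
        assert np.isnan(cmap.probability[band]).all()

    def test_free_population_excludes_bound_frames(self):
        model = _system()
        p1 = _idx(model, "1")
        intra = [(int(p1[0]), int(p1[5]))]
        base = _dock_pairs(model, "0", n=6)      # peptide 0 bound, 1 free
        records = [make_record(model, base + intra, t) for t in range(10)]
        free = tertiary_map(records, model, population="free")
        assert free.n_observations == 10          # only peptide '1'
        assert free.probability[0, 5] == pytest.approx(1.0)


class TestQuaternaryMap:
    def _dimer_records(self, model, bound=True, n_frames=25):
        p0, p1 = _idx(model, "0"), _idx(model, "1")
        L = len(p0)
        # antiparallel C-terminal pairing
        dimer = [(int(p0[L - 1 - k]), int(p1[L - 6 + k])) for k in range(6)]
        base = _dock_pairs(model, "0", n=6) if bound else []
        return [make_record(model, base + dimer, t) for t in range(n_frames)]

    def test_cterminal_block_elevated(self):
        model = _system(pep_len=12)
        records = self._dimer_records(model, bound=True)
        cmap = quaternary_map(records, model, population="complexed")
        assert cmap.probability[11, 6] == pytest.approx(1.0)
        assert np.nansum(cmap.probability[:4, :4]) == 0.0

    def test_symmetric(self):
        model = _system(pep_len=12)
        cmap = quaternary_map(self._dimer_records(model, bound=True), model,
                              population="complexed")
        assert np.allclose(cmap.probability, cmap.probability.T)
        assert np.nanmax(cmap.probability) <= 1.0

    def test_no_dimers_is_empty(self):
        model = _system()
        records = [make_record(model, _dock_pairs(model, "0", n=6), t)
                   for t in range(5)]
        with pytest.raises(EmptyResultError):
            quaternary_map(records, model, population="complexed")

    def test_free_population_requires_both_unbound(self):
        model = _system(pep_len=12)
        bound_recs = self._dimer_records(model, bound=True)
        with pytest.raises(EmptyResultError):
            quaternary_map(bound_recs, model, population="free")
        free_recs = self._dimer_records(model, bound=False)
        cmap = quaternary_map(free_recs, model, population="free")
        assert cmap.probability[11, 6] == pytest.approx(1.0)

    def test_exchange_symmetry_of_identical_chains(self):
        """Relabeling the two identical peptide chains leaves the map alone."""
        model = _system(pep_len=12)
        p0, p1 = _idx(model, "0"), _idx(model, "1")
        dimer = [(int(p0[2]), int(p1[9]))] + \
                [(int(p0[k]), int(p1[k])) for k in range(6)]
        swapped = [(int(p1[2]), int(p0[9]))] + \
                  [(int(p1[k]), int(p0[k])) for k in range(6)]
        base0 = _dock_pairs(model, "0", n=6)
        base1 = _dock_pairs(model, "1", n=6)
        a = quaternary_map([make_record(model, base0 + dimer, 0.0)], model)
        b = quaternary_map([make_record(model, base1 + swapped, 0.0)], model)
        assert np.allclose(a.probability, b.probability)
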