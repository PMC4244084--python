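"""Shared fixtures: tiny hand-built systems and fabricated contact records."""

from __future__ import annotations

import numpy as np
import pytest

from oligotraj.contacts import ContactRecord, chain_pair_key
from oligotraj.model import ChainRole, ChainSpec, Frame, SystemModel


def point_system(chain_spec: dict[str, tuple[str, int]]) -> SystemModel:
    """System of single-atom ('CA') residues.

    chain_spec maps chain id -> (role, n_residues); residues are numbered
    from 1 within each chain.
    """
    chains = []
    n_res = 0
    for cid, (role, n) in chain_spec.items():
        chains.append(ChainSpec(
            cid, ChainRole(role),
            tuple((i + 1, "ALA") for i in range(n)),
        ))
        n_res += n
    residue_atoms = [np.array([i], dtype=np.intp) for i in range(n_res)]
    return SystemModel(chains, residue_atoms, ["CA"] * n_res, ["C"] * n_res)


def make_frame(coords, box=200.0, time=0.0) -> Frame:
    box = np.atleast_1d(np.asarray(box, dtype=float))
    if box.size == 1:
        box = np.repeat(box, 3)
    return Frame(time, np.asarray(coords, dtype=float), box)


def make_record(model: SystemModel, pairs, time: float = 0.0) -> ContactRecord:
    """Fabricate a ContactRecord from residue-index pairs (chain-pair
    counts derived consistently)."""
    norm = frozenset((min(i, j), max(i, j)) for i, j in pairs)
    counts: dict[tuple[str, str], int] = {}
    for i, j in norm:
        key = chain_pair_key(model.residue_chain[i], model.residue_chain[j])
        counts[key] = counts.get(key, 0) + 1
    return ContactRecord(time, norm, counts)


@pytest.fixture
def two_residue_system() -> SystemModel:
    return point_system({"A": ("peptide", 1), "B": ("peptide", 1)})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240601)
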