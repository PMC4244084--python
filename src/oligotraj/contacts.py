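"""Residue–residue heavy-atom contact detection under periodic boundaries.

Two residues are in contact when any pair of their heavy atoms is within the
cutoff (default 5 Å, boundary inclusive), with minimum-image correction in
an orthorhombic box.  Two independent routes are provided:

* :func:`residue_contacts` — fast path: periodic k-d tree neighbor search
  (brute force below 200 atoms, where the tree buys nothing);
* :func:`residue_contacts_brute` — the O(n²) minimum-image oracle used by
  the test suite to cross-check the fast path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyResultError, ValidationError
from .model import Frame, SystemModel

__all__ = [
    "ContactConfig",
    "ContactRecord",
    "residue_contacts",
    "residue_contacts_brute",
    "chain_pair_contact_count",
    "contact_count_distribution",
]

_BRUTE_FORCE_MAX_ATOMS = 200


def chain_pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ContactConfig:
    """Contact-detection conventions.

    cutoff: Å, boundary inclusive (d <= cutoff is a contact).
    minimum_image: apply the minimum-image convention (orthorhombic box).
    exclusion_k: ignore intra-chain pairs with sequence separation <= k
        (0 = only the trivial self-pair is excluded); used by the
        tertiary-contact maps.
    count_atom_pairs: additionally tally heavy-atom pair counts per chain
        pair (the residue-pair count is the primary convention).
    """

    cutoff: float = 5.0
    minimum_image: bool = True
    exclusion_k: int = 0
    count_atom_pairs: bool = False

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be > 0")


@dataclass
class ContactRecord:
    """Per-frame residue-pair contacts and per-chain-pair counts."""

    time: float
    pairs: frozenset[tuple[int, int]]                       # i < j, global residue idx
    chain_pair_counts: dict[tuple[str, str], int]
    chain_pair_atom_counts: dict[tuple[str, str], int] | None = None

    def count(self, chain_a: str, chain_b: str) -> int:
        return self.chain_pair_counts.get(chain_pair_key(chain_a, chain_b), 0)


def _min_image(diff: np.ndarray, box: np.ndarray) -> np.ndarray:
    return diff - box * np.round(diff / box)


def _atom_pairs_tree(coords: np.ndarray, box: np.ndarray, cutoff: float,
                     minimum_image: bool) -> np.ndarray:
    if minimum_image:
        wrapped = np.mod(coords, box)
        # guard against coordinates landing exactly on the upper box face
        wrapped = np.where(wrapped >= box, 0.0, wrapped)
        tree = cKDTree(wrapped, boxsize=box)
    else:
        tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs.reshape(-1, 2)


def _atom_pairs_brute(coords: np.ndarray, box: np.ndarray, cutoff: float,
                      minimum_image: bool) -> np.ndarray:
    n = coords.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    diff = coords[ii] - coords[jj]
    if minimum_image:
        diff = _min_image(diff, box)
    d2 = np.einsum("ij,ij->i", diff, diff)
    keep = d2 <= cutoff * cutoff
    return np.column_stack([ii[keep], jj[keep]])


def _chain_codes(model: SystemModel) -> tuple[np.ndarray, list[str]]:
    """Cached integer chain code per global residue."""
    cached = getattr(model, "_oligotraj_chain_codes", None)
    if cached is not None:
        return cached
    ids = [c.chain_id for c in model.chains]
    code = {cid: i for i, cid in enumerate(ids)}
    arr = np.array([code[c] for c in model.residue_chain], dtype=np.intp)
    model._oligotraj_chain_codes = (arr, ids)
    return arr, ids


def _reduce_to_record(atom_pairs: np.ndarray, frame: Frame, model: SystemModel,
                      config: ContactConfig) -> ContactRecord:
    res_of = model.atom_residue
    chain_code, chain_ids = _chain_codes(model)
    num_of = np.asarray(model.residue_numbers)
    n_res = model.n_residues

    def _count_by_chain_pair(lo: np.ndarray, hi: np.ndarray) -> dict:
        out: dict[tuple[str, str], int] = {}
        if lo.size:
            ca = np.minimum(chain_code[lo], chain_code[hi])
            cb = np.maximum(chain_code[lo], chain_code[hi])
            keys, cnt = np.unique(ca * len(chain_ids) + cb, return_counts=True)
            for k, c in zip(keys, cnt):
                out[chain_pair_key(chain_ids[k // len(chain_ids)],
                                   chain_ids[k % len(chain_ids)])] = int(c)
        return out

    if atom_pairs.size:
        ri = res_of[atom_pairs[:, 0]]
        rj = res_of[atom_pairs[:, 1]]
        keep = ri != rj
        ri, rj = ri[keep], rj[keep]
        lo = np.minimum(ri, rj)
        hi = np.maximum(ri, rj)
        lo, hi = np.divmod(np.unique(lo * n_res + hi), n_res)
        if config.exclusion_k > 0:
            drop = (chain_code[lo] == chain_code[hi]) & \
                (np.abs(num_of[lo] - num_of[hi]) <= config.exclusion_k)
            lo, hi = lo[~drop], hi[~drop]
    else:
        lo = hi = np.empty(0, dtype=np.intp)

    pair_set = frozenset(zip(lo.tolist(), hi.tolist()))
    counts = _count_by_chain_pair(lo, hi)

    atom_counts = None
    if config.count_atom_pairs:
        ra = res_of[atom_pairs[:, 0]] if atom_pairs.size else np.empty(0, np.intp)
        rb = res_of[atom_pairs[:, 1]] if atom_pairs.size else np.empty(0, np.intp)
        k = ra != rb
        atom_counts = _count_by_chain_pair(ra[k], rb[k])

    return ContactRecord(frame.time, pair_set, counts, atom_counts)


def _check_box(frame: Frame, config: ContactConfig) -> None:
    if config.minimum_image and (frame.box < 2 * config.cutoff).any():
        warnings.warn(
            "box edge smaller than twice the cutoff: minimum-image contact "
            "assignment is ambiguous",
            stacklevel=3,
        )


def residue_contacts(frame: Frame, model: SystemModel,
                     config: ContactConfig | None = None) -> ContactRecord:
    """Detect all residue-pair contacts in one frame (fast path)."""
    config = config or ContactConfig()
    _check_box(frame, config)
    if frame.coords.shape[0] != model.n_atoms:
        raise ValidationError("frame does not match the system topology")
    if model.n_atoms < _BRUTE_FORCE_MAX_ATOMS:
        ap = _atom_pairs_brute(frame.coords, frame.box, config.cutoff,
                               config.minimum_image)
    else:
        ap = _atom_pairs_tree(frame.coords, frame.box, config.cutoff,
                              config.minimum_image)
    return _reduce_to_record(ap, frame, model, config)


def residue_contacts_brute(frame: Frame, model: SystemModel,
                           config: ContactConfig | None = None) -> ContactRecord:
    """O(n²) minimum-image oracle; independent of the k-d tree path."""
    config = config or ContactConfig()
    _check_box(frame, config)
    ap = _atom_pairs_brute(frame.coords, frame.box, config.cutoff,
                           config.minimum_image)
    return _reduce_to_record(ap, frame, model, config)


def chain_pair_contact_count(record: ContactRecord, chains_a: Iterable[str],
                             chains_b: Iterable[str]) -> int:
    """Number of residue pairs in contact with one residue in chain set A
    and the other in chain set B (A, B disjoint)."""
    set_a, set_b = set(chains_a), set(chains_b)
    if set_a & set_b:
        raise ValidationError("chain sets must be disjoint")
    total = 0
    for a in set_a:
        for b in set_b:
            total += record.count(a, b)
    return total


def contact_count_distribution(
    records: Sequence[ContactRecord],
    pairing: str,
    model: SystemModel,
    aggregation_states: Sequence["AggregationState"] | None = None,  # noqa: F821
    threshold: int = 5,
):
    """Normalized distribution of contact counts for bound complexes.

    pairing:
      * ``"peptide-peptide"`` — every unordered peptide pair, per frame;
      * ``"inhibitor-monomer"`` — inhibitor vs peptides that are monomers
        in that frame (requires *aggregation_states*);
      * ``"inhibitor-oligomer"`` — inhibitor vs whole oligomers (n >= 2).

    Only complexes with more than *threshold* contacts enter.  Returns a
    pandas Series (index: contact count, values: probability, sums to 1).
    """
    import pandas as pd

    counts: list[int] = []
    pep = model.peptide_chain_ids
    inh = model.inhibitor_chain_ids
    if pairing == "peptide-peptide":
        for rec in records:
            for i, p in enumerate(pep):
                for q in pep[i + 1:]:
                    c = rec.count(p, q)
                    if c > threshold:
                        counts.append(c)
    elif pairing in {"inhibitor-monomer", "inhibitor-oligomer"}:
        if not inh:
            raise ValidationError("model has no inhibitor chains")
        if aggregation_states is None:
            raise ValidationError(f"pairing {pairing!r} needs aggregation states")
        if len(aggregation_states) != len(records):
            raise ValidationError("records / aggregation states length mismatch")
        want_monomer = pairing == "inhibitor-monomer"
        for rec, st in zip(records, aggregation_states):
            for group in st.partition:
                if (len(group) == 1) != want_monomer:
                    continue
                c = chain_pair_contact_count(rec, group, inh)
                if c > threshold:
                    counts.append(c)
    else:
        raise ValidationError(f"unknown pairing spec {pairing!r}")

    if not counts:
        raise EmptyResultError(f"no complexes with > {threshold} contacts "
                               f"for pairing {pairing!r}")
    ser = pd.Series(counts).value_counts(normalize=True).sort_index()
    ser.index.name = "n_contacts"
    ser.name = "probability"
    return ser
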