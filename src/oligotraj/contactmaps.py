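"""Ensemble-averaged residue-level contact probabilities.

Three families of maps, all conditioned on binding the same way:

* inhibitor × peptide pairwise maps and the derived per-residue / per-type
  profiles, over "complexed" peptide-frame observations (a peptide with
  strictly more than `threshold` residue contacts to the inhibitor);
* tertiary maps: intra-peptide contacts with sequence separation >= 3
  (i±1 and i±2 neighbours masked out), for the complexed or free population;
* quaternary maps: cross-chain peptide–peptide contacts over interacting
  dimer combinations, where (for the complexed population) at least one
  member is inhibitor-bound.

Probabilities are conditioned fractions: pooled observations across
peptides, frames and runs; each cell is the fraction of qualifying
observations in which that residue pair is in contact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .aggregation import complexation_flags
from .contacts import ContactRecord
from .errors import EmptyResultError, ValidationError
from .model import AA_THREE_TO_ONE, SystemModel

__all__ = [
    "ContactProbabilityMap",
    "inhibitor_peptide_map",
    "per_residue_profile",
    "per_type_profile",
    "tertiary_map",
    "quaternary_map",
]


@dataclass
class ContactProbabilityMap:
    row_labels: list
    col_labels: list
    probability: np.ndarray            # (rows, cols) in [0, 1]; NaN = masked
    counts: np.ndarray                 # raw contact counts per cell
    n_observations: int
    conditioning: str
    col_any_counts: np.ndarray | None = None   # per column: obs with any row contact

    def __post_init__(self) -> None:
        if not self.conditioning:
            raise ValidationError("conditioning descriptor must be non-empty")
        finite = self.probability[np.isfinite(self.probability)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValidationError("probabilities outside [0, 1]")


def _peptide_layout(model: SystemModel) -> tuple[list[str], dict[int, tuple[str, int]], list[int]]:
    """Map global residue index -> (peptide chain, position); peptides must
    share one residue numbering (identical chains)."""
    pep = model.peptide_chain_ids
    numbers = None
    pos_of: dict[int, tuple[str, int]] = {}
    for p in pep:
        chain = model.chain(p)
        nums = [n for n, _ in chain.residues]
        if numbers is None:
            numbers = nums
        elif nums != numbers:
            raise ValidationError("peptide chains do not share one residue numbering")
        for k, (n, _) in enumerate(chain.residues):
            pos_of[model.residue_index[(p, n)]] = (p, k)
    return pep, pos_of, list(numbers or [])


def _inhibitor_layout(model: SystemModel) -> tuple[list[str], dict[int, int]]:
    labels: list[str] = []
    row_of: dict[int, int] = {}
    for c in model.inhibitor_chain_ids:
        chain = model.chain(c)
        for n, _ in chain.residues:
            row_of[model.residue_index[(c, n)]] = len(labels)
            labels.append(f"{c}:{n}")
    return labels, row_of


def _complexed_flags(record: ContactRecord, model: SystemModel, threshold: int
                     ) -> dict[str, bool]:
    if model.has_inhibitor:
        return complexation_flags(record, model, threshold)
    return dict.fromkeys(model.peptide_chain_ids, False)


def inhibitor_peptide_map(records: Sequence[ContactRecord], model: SystemModel,
                          threshold: int = 5, conditioned: bool = True
                          ) -> ContactProbabilityMap:
    """Inhibitor residues × peptide residues contact probabilities.

    An observation is one (frame, peptide); with ``conditioned`` (default)
    only complexed peptides (> threshold inhibitor contacts) enter.
    """
    if not model.has_inhibitor:
        raise ValidationError("model has no inhibitor entity")
    pep, pos_of, pep_numbers = _peptide_layout(model)
    inh_labels, row_of = _inhibitor_layout(model)
    n_rows, n_cols = len(inh_labels), len(pep_numbers)
    counts = np.zeros((n_rows, n_cols))
    col_any = np.zeros(n_cols)
    n_obs = 0
    for rec in records:
        bound = _complexed_flags(rec, model, threshold)
        qualifying = {p for p in pep if bound[p] or not conditioned}
        if not qualifying:
            continue
        n_obs += len(qualifying)
        per_pep_cols: dict[str, set[int]] = {p: set() for p in qualifying}
        for a, b in rec.pairs:
            for inh_res, pep_res in ((a, b), (b, a)):
                if inh_res in row_of and pep_res in pos_of:
                    p, k = pos_of[pep_res]
                    if p in qualifying:
                        counts[row_of[inh_res], k] += 1
                        per_pep_cols[p].add(k)
        for cols in per_pep_cols.values():
            for k in cols:
                col_any[k] += 1
    if n_obs == 0:
        raise EmptyResultError("no complexed peptide-frame observations")
    return ContactProbabilityMap(
        row_labels=inh_labels, col_labels=pep_numbers,
        probability=counts / n_obs, counts=counts, n_observations=n_obs,
        conditioning=("complexed peptide-frames, inhibitor contacts > "
                      f"{threshold}" if conditioned else "all peptide-frames"),
        col_any_counts=col_any,
    )


def per_residue_profile(cmap: ContactProbabilityMap) -> np.ndarray:
    """Probability each peptide residue contacts ANY inhibitor residue,
    from the per-observation any-contact bookkeeping (not a row sum)."""
    if cmap.col_any_counts is None:
        raise ValidationError("map carries no per-observation any-contact counts")
    return cmap.col_any_counts / cmap.n_observations


def per_type_profile(records: Sequence[ContactRecord], model: SystemModel,
                     side: str = "inhibitor", threshold: int = 5
                     ) -> dict[str, float | None]:
    """Mean any-contact probability per amino-acid type on one side.

    For each residue of the chosen side, its probability of contacting any
    residue of the opposite side (over complexed peptide-frame
    observations); residues of one type are then averaged.  Types absent
    from the sequence map to None (absent, not zero).
    """
    if side not in {"inhibitor", "peptide"}:
        raise ValidationError("side must be 'inhibitor' or 'peptide'")
    cmap = inhibitor_peptide_map(records, model, threshold)
    if side == "peptide":
        probs = per_residue_profile(cmap)
        pep0 = model.chain(model.peptide_chain_ids[0])
        types = [AA_THREE_TO_ONE.get(name, "X") for _, name in pep0.residues]
    else:
        # per inhibitor residue: fraction of observations with any contact
        # to the observed peptide; row counts alone cannot distinguish
        # "two pairs once" from "one pair twice", so recompute per-row.
        probs = _inhibitor_any_profile(records, model, threshold, cmap.n_observations)
        types = []
        for c in model.inhibitor_chain_ids:
            types += [AA_THREE_TO_ONE.get(name, "X")
                      for _, name in model.chain(c).residues]
    out: dict[str, float | None] = {}
    arr = np.asarray(probs)
    for aa in sorted(AA_THREE_TO_ONE.values()):
        sel = [i for i, t in enumerate(types) if t == aa]
        out[aa] = float(arr[sel].mean()) if sel else None
    return out


def _inhibitor_any_profile(records, model, threshold, n_obs):
    pep, pos_of, _ = _peptide_layout(model)
    inh_labels, row_of = _inhibitor_layout(model)
    any_counts = np.zeros(len(inh_labels))
    for rec in records:
        bound = _complexed_flags(rec, model, threshold)
        qualifying = {p for p in pep if bound[p]}
        if not qualifying:
            continue
        touched: set[tuple[int, str]] = set()
        for a, b in rec.pairs:
            for inh_res, pep_res in ((a, b), (b, a)):
                if inh_res in row_of and pep_res in pos_of:
                    p, _k = pos_of[pep_res]
                    if p in qualifying:
                        touched.add((row_of[inh_res], p))
        for row, _p in touched:
            any_counts[row] += 1
    return any_counts / n_obs


def tertiary_map(records: Sequence[ContactRecord], model: SystemModel,
                 population: str = "complexed", threshold: int = 5,
                 min_separation: int = 3) -> ContactProbabilityMap:
    """Intra-peptide contact probabilities at sequence separation >= 3.

    The |i - j| <= 2 band (sequential neighbours) is masked to NaN.
    population "complexed": peptides with > threshold inhibitor contacts in
    that frame; "free": peptides at or below it (all peptides, in a control
    system without inhibitor).
    """
    if population not in {"complexed", "free"}:
        raise ValidationError("population must be 'complexed' or 'free'")
    pep, pos_of, numbers = _peptide_layout(model)
    L = len(numbers)
    counts = np.zeros((L, L))
    n_obs = 0
    for rec in records:
        bound = _complexed_flags(rec, model, threshold)
        qualifying = {p for p in pep if bound[p] == (population == "complexed")}
        n_obs += len(qualifying)
        for a, b in rec.pairs:
            if a in pos_of and b in pos_of:
                pa, ka = pos_of[a]
                pb, kb = pos_of[b]
                if pa == pb and pa in qualifying and abs(ka - kb) >= min_separation:
                    counts[ka, kb] += 1
                    counts[kb, ka] += 1
    if n_obs == 0:
        raise EmptyResultError(f"no {population} peptide-frame observations")
    prob = counts / n_obs
    band = np.abs(np.subtract.outer(np.arange(L), np.arange(L))) < min_separation
    prob[band] = np.nan
    return ContactProbabilityMap(
        row_labels=numbers, col_labels=numbers, probability=prob,
        counts=counts, n_observations=n_obs,
        conditioning=f"{population} peptide-frames; |i-j| >= {min_separation}",
    )


def quaternary_map(records: Sequence[ContactRecord], model: SystemModel,
                   population: str = "complexed", threshold: int = 5
                   ) -> ContactProbabilityMap:
    """Cross-chain peptide–peptide contact probabilities over interacting
    dimer combinations.

    A pair-frame qualifies when the two peptides share > threshold mutual
    contacts and (complexed population) at least one member is
    inhibitor-bound, or (free population) neither is.  Ordered observations
    are symmetrized by construction.
    """
    if population not in {"complexed", "free"}:
        raise ValidationError("population must be 'complexed' or 'free'")
    pep, pos_of, numbers = _peptide_layout(model)
    L = len(numbers)
    counts = np.zeros((L, L))
    n_obs = 0
    for rec in records:
        bound = _complexed_flags(rec, model, threshold)
        pairs_q: set[frozenset[str]] = set()
        for i, p in enumerate(pep):
            for q in pep[i + 1:]:
                if rec.count(p, q) <= threshold:
                    continue
                if population == "complexed" and (bound[p] or bound[q]):
                    pairs_q.add(frozenset((p, q)))
                elif population == "free" and not bound[p] and not bound[q]:
                    pairs_q.add(frozenset((p, q)))
        if not pairs_q:
            continue
        n_obs += 2 * len(pairs_q)       # ordered observations
        cells: dict[frozenset[str], set[tuple[int, int]]] = \
            {pq: set() for pq in pairs_q}
        for a, b in rec.pairs:
            if a in pos_of and b in pos_of:
                pa, ka = pos_of[a]
                pb, kb = pos_of[b]
                key = frozenset((pa, pb))
                if pa != pb and key in pairs_q:
                    cells[key].add((ka, kb))
                    cells[key].add((kb, ka))
        for cellset in cells.values():   # binarized per dimer observation
            for ka, kb in cellset:
                counts[ka, kb] += 1
    if n_obs == 0:
        raise EmptyResultError(f"no qualifying {population} peptide pairs")
    # fraction of (ordered) dimer observations in which residues i and j of
    # the two chains touch in either orientation; symmetric by construction
    prob = 2 * counts / n_obs
    return ContactProbabilityMap(
        row_labels=numbers, col_labels=numbers, probability=prob,
        counts=counts, n_observations=n_obs,
        conditioning=(f"{population} interacting dimer combinations, mutual "
                      f"contacts > {threshold}"),
    )
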