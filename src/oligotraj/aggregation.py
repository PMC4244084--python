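"""Per-frame oligomer detection and species classification.

A peptide pair with strictly more than `threshold` (default 5) residue
contacts is an edge of the peptide graph; oligomers are its connected
components (isolated peptides are monomers).  A peptide is inhibitor-bound
when it forms strictly more than `threshold` contacts with the inhibitor
entity; an oligomer is "complexed" as soon as one member is bound.

Species classes follow the usual small/large split: small oligomer
n = 2–5 chains, large oligomer n > 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .contacts import ContactConfig, ContactRecord, chain_pair_contact_count, residue_contacts
from .errors import ConfigurationError, ValidationError
from .model import SystemModel, Trajectory

__all__ = [
    "AggregationState",
    "SpeciesTimeSeries",
    "SPECIES_COLUMNS",
    "peptide_graph",
    "oligomers",
    "complexation_flags",
    "classify_frame",
    "species_counts",
    "multirun_average",
]

SPECIES_COLUMNS = [
    "free_monomer",
    "free_small_oligomer",
    "free_large_oligomer",
    "complexed_monomer",
    "complexed_small_oligomer",
    "complexed_large_oligomer",
    "uncomplexed_inhibitor",
]

DEFAULT_THRESHOLD = 5          # "more than five contacts": strictly > 5
SMALL_OLIGOMER_MAX = 5         # small oligomer n = 2..5; large n > 5


@dataclass
class AggregationState:
    """Partition of peptide chains into oligomers plus binding flags."""

    time: float
    partition: list[frozenset[str]]
    bound: dict[str, bool]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group in self.partition:
            if seen & group:
                raise ValidationError("oligomer partition is not disjoint")
            seen |= group
        if seen != set(self.bound):
            raise ValidationError("partition does not cover the peptide chains")

    @property
    def complexed(self) -> list[bool]:
        """Per-oligomer flag: true iff >= 1 member peptide is bound."""
        return [any(self.bound[p] for p in group) for group in self.partition]

    def species_counts(self, has_inhibitor: bool) -> dict[str, float]:
        row = dict.fromkeys(SPECIES_COLUMNS, 0.0)
        for group, cx in zip(self.partition, self.complexed):
            n = len(group)
            size = ("monomer" if n == 1
                    else "small_oligomer" if n <= SMALL_OLIGOMER_MAX
                    else "large_oligomer")
            prefix = "complexed" if cx else "free"
            row[f"{prefix}_{size}"] += 1
        if has_inhibitor:
            row["uncomplexed_inhibitor"] = 0.0 if any(self.bound.values()) else 1.0
        else:
            row["uncomplexed_inhibitor"] = np.nan
        return row


def peptide_graph(record: ContactRecord, model: SystemModel,
                  threshold: int = DEFAULT_THRESHOLD) -> set[frozenset[str]]:
    """Edges between peptide chains sharing > threshold residue contacts."""
    pep = model.peptide_chain_ids
    edges: set[frozenset[str]] = set()
    for i, p in enumerate(pep):
        for q in pep[i + 1:]:
            if record.count(p, q) > threshold:
                edges.add(frozenset((p, q)))
    return edges


def oligomers(edges: set[frozenset[str]], peptide_chains: list[str]
              ) -> list[frozenset[str]]:
    """Partition peptide chains into connected components of the graph."""
    g = nx.Graph()
    g.add_nodes_from(peptide_chains)
    for e in edges:
        a, b = tuple(e)
        if a not in g or b not in g:
            raise ValidationError(f"edge {a}-{b} references unknown peptide chain")
        g.add_edge(a, b)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    # deterministic order: by first chain id in input order
    order = {c: i for i, c in enumerate(peptide_chains)}
    return sorted(comps, key=lambda c: min(order[x] for x in c))


def complexation_flags(record: ContactRecord, model: SystemModel,
                       threshold: int = DEFAULT_THRESHOLD) -> dict[str, bool]:
    """Per-peptide flag: > threshold contacts with the inhibitor entity."""
    inh = model.inhibitor_chain_ids
    if not inh:
        raise ConfigurationError("model has no inhibitor entity")
    return {
        p: chain_pair_contact_count(record, [p], inh) > threshold
        for p in model.peptide_chain_ids
    }


def classify_frame(record: ContactRecord, model: SystemModel,
                   threshold: int = DEFAULT_THRESHOLD) -> AggregationState:
    edges = peptide_graph(record, model, threshold)
    part = oligomers(edges, model.peptide_chain_ids)
    if model.has_inhibitor:
        bound = complexation_flags(record, model, threshold)
    else:
        bound = dict.fromkeys(model.peptide_chain_ids, False)
    return AggregationState(record.time, part, bound)


@dataclass
class SpeciesTimeSeries:
    """Time-binned mean species counts (default bin width 50 ns)."""

    bin_edges: np.ndarray              # (n_bins + 1,) ns
    table: pd.DataFrame                # n_bins rows, SPECIES_COLUMNS
    n_frames: np.ndarray               # frames per bin
    partial_last_bin: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def species_counts(traj: Trajectory, contact_config: ContactConfig | None = None,
                   bin_width: float = 50.0,
                   threshold: int = DEFAULT_THRESHOLD) -> SpeciesTimeSeries:
    """Classify every frame, then average the class counts in time bins."""
    if bin_width <= 0:
        raise ValidationError("bin width must be > 0")
    contact_config = contact_config or ContactConfig()
    records = [residue_contacts(f, traj.model, contact_config) for f in traj.frames]
    states = [classify_frame(r, traj.model, threshold) for r in records]
    return species_counts_from_states(states, traj.model.has_inhibitor, bin_width)


def species_counts_from_states(states: list[AggregationState], has_inhibitor: bool,
                               bin_width: float = 50.0) -> SpeciesTimeSeries:
    if not states:
        raise ValidationError("need at least one classified frame")
    times = np.array([s.time for s in states])
    t0 = times[0]
    n_bins = int(np.ceil((times[-1] - t0) / bin_width)) or 1
    edges = t0 + bin_width * np.arange(n_bins + 1)
    which = np.clip(((times - t0) / bin_width).astype(int), 0, n_bins - 1)

    rows = pd.DataFrame([s.species_counts(has_inhibitor) for s in states])
    table = rows.groupby(which).mean().reindex(range(n_bins))
    n_frames = np.bincount(which, minlength=n_bins)
    partial = times[-1] < edges[-1] - 1e-9
    return SpeciesTimeSeries(edges, table[SPECIES_COLUMNS], n_frames,
                             partial_last_bin=bool(partial))


def multirun_average(series: list[SpeciesTimeSeries]) -> SpeciesTimeSeries:
    """Unweighted mean across runs, per bin and species class."""
    if not series:
        raise ValidationError("need at least one run")
    ref = series[0]
    for s in series[1:]:
        if s.bin_edges.shape != ref.bin_edges.shape or \
                not np.allclose(s.bin_edges, ref.bin_edges):
            raise ValidationError("runs have mismatched bin edges")
    mean = sum(s.table[SPECIES_COLUMNS] for s in series) / len(series)
    n = np.sum([s.n_frames for s in series], axis=0)
    return SpeciesTimeSeries(ref.bin_edges.copy(), mean, n,
                             partial_last_bin=any(s.partial_last_bin for s in series))
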