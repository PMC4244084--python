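"""2D potential-of-mean-force surfaces over contact-count observables.

For every peptide in every frame two observables are collected: the number
of residue contacts with the inhibitor entity (x) and with all other
peptides (y).  Boltzmann inversion of the joint histogram gives

    W(x, y) = -kB T ln[ P(x, y) / Pmax ]          (kcal/mol)

so the most populated bin sits at W = 0 and empty bins are masked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .contacts import ContactConfig, ContactRecord, chain_pair_contact_count, residue_contacts
from .errors import EmptyResultError, ValidationError
from .model import SystemModel, Trajectory

__all__ = [
    "LandscapeConfig",
    "PMFGrid",
    "observable_series",
    "observables_from_records",
    "pmf2d",
    "region_population",
]

KB_KCAL_MOL_K = 0.0019872041   # Boltzmann constant, kcal/mol/K


@dataclass(frozen=True)
class LandscapeConfig:
    """temperature in K (default 325); histogram bin width in contacts."""

    temperature: float = 325.0
    kB: float = KB_KCAL_MOL_K
    bin_width: int = 1
    contour_interval: float = 0.5     # kcal/mol, for plotting only

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0")
        if self.bin_width < 1:
            raise ValidationError("bin width must be >= 1 contact")

    @property
    def kBT(self) -> float:
        return self.kB * self.temperature


@dataclass
class PMFGrid:
    x_centers: np.ndarray
    y_centers: np.ndarray
    P: np.ndarray                  # (nx, ny), sums to 1 over unmasked bins
    W: np.ndarray                  # kcal/mol; +inf on masked (empty) bins
    mask: np.ndarray               # True where the bin is empty
    temperature: float


def observables_from_records(records: Sequence[ContactRecord],
                             model: SystemModel) -> np.ndarray:
    """(x, y) samples: one row per peptide per frame.

    x = residue contacts with the inhibitor entity,
    y = residue contacts with all other peptides.
    """
    inh = model.inhibitor_chain_ids
    if not inh:
        raise ValidationError("model has no inhibitor entity")
    pep = model.peptide_chain_ids
    samples = np.empty((len(records) * len(pep), 2), dtype=np.intp)
    k = 0
    for rec in records:
        for p in pep:
            others = [q for q in pep if q != p]
            samples[k, 0] = chain_pair_contact_count(rec, [p], inh)
            samples[k, 1] = chain_pair_contact_count(rec, [p], others)
            k += 1
    return samples


def observable_series(traj: Trajectory, contact_config: ContactConfig | None = None
                      ) -> np.ndarray:
    contact_config = contact_config or ContactConfig()
    records = [residue_contacts(f, traj.model, contact_config) for f in traj.frames]
    return observables_from_records(records, traj.model)


def pmf2d(samples: np.ndarray, config: LandscapeConfig | None = None) -> PMFGrid:
    """Histogram (x, y) samples and Boltzmann-invert to a free-energy grid."""
    config = config or LandscapeConfig()
    samples = np.asarray(samples)
    if samples.size == 0:
        raise EmptyResultError("no samples to histogram")
    if samples.ndim != 2 or samples.shape[1] != 2:
        raise ValidationError("samples must be (n, 2)")
    w = config.bin_width
    x_edges = np.arange(samples[:, 0].min() - 0.5,
                        samples[:, 0].max() + 0.5 + w, w)
    y_edges = np.arange(samples[:, 1].min() - 0.5,
                        samples[:, 1].max() + 0.5 + w, w)
    H, _, _ = np.histogram2d(samples[:, 0], samples[:, 1],
                             bins=(x_edges, y_edges))
    P = H / H.sum()
    mask = H == 0
    W = np.full_like(P, np.inf)
    pmax = P.max()
    with np.errstate(divide="ignore"):
        W[~mask] = -config.kBT * np.log(P[~mask] / pmax)
    return PMFGrid(
        x_centers=0.5 * (x_edges[:-1] + x_edges[1:]),
        y_centers=0.5 * (y_edges[:-1] + y_edges[1:]),
        P=P, W=W, mask=mask, temperature=config.temperature,
    )


def region_population(samples: np.ndarray,
                      predicate: Callable[[np.ndarray, np.ndarray], np.ndarray]
                      ) -> float:
    """Fraction of (x, y) samples in the region selected by *predicate*.

    predicate receives the x and y arrays and returns a boolean array, e.g.
    ``lambda x, y: (x >= 5) & (y < 5)`` for the inhibitor-bound-monomer
    basin of the free-energy surface.
    """
    samples = np.asarray(samples)
    if samples.size == 0:
        return 0.0
    sel = np.asarray(predicate(samples[:, 0], samples[:, 1]), dtype=bool)
    if sel.shape != (samples.shape[0],):
        raise ValidationError("predicate must return one boolean per sample")
    return float(sel.mean())
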