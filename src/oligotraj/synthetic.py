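"""Synthetic coarse-grained trajectories with exactly known ground truth.

Real binding trajectories of this kind (ten short amyloid peptides plus one
inhibitor protein in a ~120–124 Å periodic cubic box) are expensive to
produce and rarely deposited, so every analysis stage in this package is
exercised against generated data instead.  Two generators with opposite
trade-offs:

* :func:`markov_binding_generator` — each peptide's inhibitor-bound state
  evolves as an independent two-state Markov chain; coordinates are placed
  from verified geometric templates (docked pose with well over five
  residue contacts; unbound placement at >= 15 Å from the inhibitor and
  >= 10 Å from other peptides).  Ground truth is exact by construction and
  self-validated against the contact definitions at generation time.
* :func:`brownian_toy_sim` — an overdamped Langevin bead-per-residue toy
  with emergent aggregation, for integration tests (no exact truth).

Peptides are 26-residue single-bead-per-residue chains numbered 17–42
(mirroring Aβ17–42) so residue-indexed maps carry realistic labels.  The
inhibitor is either an 85-residue-per-domain two-chain dimer ("acd_dimer",
chains X/Y numbered 66–150) or a single 130-residue chain ("lysozyme",
chain L numbered 1–130).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import sequences
from .aggregation import classify_frame
from .contacts import ContactConfig, residue_contacts
from .errors import ConfigurationError, ValidationError
from .model import AA_ONE_TO_THREE, ChainRole, ChainSpec, Frame, SystemModel, Trajectory

__all__ = [
    "KineticScenario",
    "GroundTruth",
    "BrownianParams",
    "build_bead_model",
    "markov_binding_generator",
    "oligomer_scene_builder",
    "brownian_toy_sim",
]

_BOND = 3.8          # Å, Cα-Cα virtual bond / peptide lattice spacing
_INH_SPACING = 4.6   # Å, inhibitor bead lattice spacing
_DOCK_GAP = 3.2      # Å, docked face to inhibitor face
_MIN_INHIBITOR_SEP = 15.0   # Å, unbound peptide to inhibitor (heavy atoms)
_MIN_PEPTIDE_SEP = 10.0     # Å, unbound peptide to any other peptide
_STACK = 2 * _BOND + _DOCK_GAP   # center-to-center of two face-stacked blobs


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def _bead_chain(chain_id: str, role: ChainRole, seq: str, first: int) -> ChainSpec:
    residues = tuple(
        (first + i, AA_ONE_TO_THREE[a]) for i, a in enumerate(seq)
    )
    return ChainSpec(chain_id, role, residues)


def build_bead_model(n_peptides: int = 10, inhibitor: str | None = "acd_dimer",
                     peptide_seq: str = sequences.ABETA_17_42,
                     peptide_first_residue: int = sequences.ABETA_FIRST_RESIDUE,
                     ) -> SystemModel:
    """One-bead-per-residue SystemModel: peptide chains '0'..'9' plus the
    chosen inhibitor entity ('acd_dimer' -> chains X, Y; 'lysozyme' -> L;
    None -> control system)."""
    if not 1 <= n_peptides <= 10:
        raise ValidationError("n_peptides must be in 1..10 (single-char chain ids)")
    chains = [
        _bead_chain(str(i), ChainRole.PEPTIDE, peptide_seq, peptide_first_residue)
        for i in range(n_peptides)
    ]
    if inhibitor == "acd_dimer":
        for cid in ("X", "Y"):
            chains.append(_bead_chain(cid, ChainRole.INHIBITOR,
                                      sequences.ACD_66_150,
                                      sequences.ACD_FIRST_RESIDUE))
    elif inhibitor == "lysozyme":
        chains.append(_bead_chain("L", ChainRole.INHIBITOR,
                                  sequences.LYSOZYME_1_130,
                                  sequences.LYSOZYME_FIRST_RESIDUE))
    elif inhibitor is not None:
        raise ValidationError(f"unknown inhibitor kind {inhibitor!r}")
    n_res = sum(len(c.residues) for c in chains)
    residue_atoms = [np.array([i], dtype=np.intp) for i in range(n_res)]
    return SystemModel(chains, residue_atoms,
                       atom_names=["CA"] * n_res,
                       atom_elements=["C"] * n_res)


# ---------------------------------------------------------------------------
# Geometry templates
# ---------------------------------------------------------------------------

def _peptide_template(n_res: int) -> np.ndarray:
    """Serpentine walk over a 3x3x3 bead lattice (spacing = bond length):
    a compact blob whose consecutive beads stay bonded-neighbour close."""
    pts = []
    for iz in range(3):
        for iy in range(3):
            xr = range(3) if iy % 2 == 0 else range(2, -1, -1)
            for ix in xr:
                pts.append((ix, iy if iz % 2 == 0 else 2 - iy, iz))
    coords = (np.array(pts[:n_res], dtype=float) - 1.0) * _BOND
    return coords - coords.mean(axis=0)


def _axis_rotation(axis: np.ndarray) -> np.ndarray:
    """Rotation taking +x to the given (axis-aligned) unit vector."""
    axis = np.asarray(axis, dtype=float)
    x = axis / np.linalg.norm(axis)
    helper = np.array([0.0, 0.0, 1.0]) if abs(x[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    y = np.cross(helper, x)
    y /= np.linalg.norm(y)
    z = np.cross(x, y)
    return np.column_stack([x, y, z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


@dataclass
class _InhibitorGeometry:
    coords: np.ndarray                 # centered at origin
    patches: list[tuple[np.ndarray, np.ndarray]]   # (dock center, outward normal)


def _inhibitor_geometry(kind: str | None) -> _InhibitorGeometry | None:
    """Static inhibitor bead lattice + docking patches on its surface."""
    if kind is None:
        return None
    s = _INH_SPACING
    if kind == "acd_dimer":
        # two 5x17 sheets stacked in x: an elongated beta-sandwich-like slab
        y = (np.arange(5) - 2.0) * s
        z = (np.arange(17) - 8.0) * s
        sheet = np.array([(0.0, yy, zz) for zz in z for yy in y])
        coords = np.concatenate([sheet + [-s / 2, 0, 0], sheet + [s / 2, 0, 0]])
        half_x, half_y = s / 2, 2 * s
        patches = []
        for zc in (-5 * s, 0.0, 5 * s):
            for sign in (1.0, -1.0):
                patches.append((np.array([sign * half_x, 0.0, zc]),
                                np.array([sign, 0.0, 0.0])))
                patches.append((np.array([0.0, sign * half_y, zc]),
                                np.array([0.0, sign, 0.0])))
    elif kind == "lysozyme":
        # compact 5x5x6 block (first 130 of 150 lattice sites)
        pts = [(ix, iy, iz) for iz in range(6) for iy in range(5) for ix in range(5)]
        coords = (np.array(pts[:130], dtype=float) - [2, 2, 2.5]) * s
        coords -= coords.mean(axis=0)
        patches = []
        for ax in range(3):
            for sign in (1.0, -1.0):
                normal = np.zeros(3)
                normal[ax] = sign
                extent = coords[:, ax].max() if sign > 0 else -coords[:, ax].min()
                patches.append((normal * extent, normal))
    else:
        raise ValidationError(f"unknown inhibitor kind {kind!r}")
    return _InhibitorGeometry(coords, patches)


def _docked_pose(template: np.ndarray, geometry: _InhibitorGeometry,
                 patch: int, stack_index: int = 0) -> np.ndarray:
    center, normal = geometry.patches[patch]
    R = _axis_rotation(normal)
    offset = _DOCK_GAP + _BOND + stack_index * _STACK
    return template @ R.T + center + normal * offset


# ---------------------------------------------------------------------------
# Markov binding generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticScenario:
    """Study conditions for the two-state binding generator.

    Defaults mirror the simulated-system shape this package targets: ten
    26-residue peptides and one two-domain inhibitor in a 124 Å cubic box,
    frames every 0.2 ns over 200 ns, binding kinetics with a ~100 ns mean
    residence (k_off = 0.01/ns) at two-thirds stationary occupancy.
    """

    n_peptides: int = 10
    k_on: float = 0.02          # /ns per peptide
    k_off: float = 0.01         # /ns per peptide
    k_dimer: float = 0.0        # /ns, optional peptide pairing
    k_undimer: float = 0.0      # /ns
    dt: float = 0.2             # ns between saved frames
    n_frames: int = 1001
    box_edge: float = 124.0
    seed: int = 0
    inhibitor: str = "acd_dimer"
    jitter_sigma: float = 0.3   # Å Gaussian positional noise
    initial_bound: tuple[bool, ...] | None = None   # default: stationary draw

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_dimer", "k_undimer"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.dt <= 0:
            raise ValidationError("dt must be > 0")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.box_edge <= 0:
            raise ValidationError("box edge must be > 0")


@dataclass
class GroundTruth:
    """Exact generator bookkeeping, aligned with the emitted trajectory."""

    times: np.ndarray
    bound: np.ndarray                      # (n_frames, n_peptides) bool
    partitions: list[list[frozenset[str]]] # per frame
    peptide_ids: list[str]
    scenario: KineticScenario | None = None

    def residence_intervals(self) -> list[np.ndarray]:
        """Realized continuously-bound interval durations (ns) per peptide."""
        dt = float(np.median(np.diff(self.times))) if len(self.times) > 1 else 0.0
        out = []
        for j in range(self.bound.shape[1]):
            b = np.concatenate(([0], self.bound[:, j].astype(np.int8), [0]))
            d = np.diff(b)
            runs = np.flatnonzero(d == -1) - np.flatnonzero(d == 1)
            out.append(runs * dt)
        return out


def _min_image_dists_sq(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    diff -= box * np.round(diff / box)
    return np.einsum("ijk,ijk->ij", diff, diff)


def _min_image_center_dist(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    d = a - b
    d -= box * np.round(d / box)
    return float(np.linalg.norm(d))


def _place_unbound(template: np.ndarray, placed: list[np.ndarray],
                   inh_coords: np.ndarray | None, box: np.ndarray,
                   rng: np.random.Generator, max_tries: int = 2000) -> np.ndarray:
    """Random placement under the separation constraints, with
    bounding-sphere early-outs before any full bead-distance check."""
    r_self = float(np.linalg.norm(template, axis=1).max())
    if inh_coords is not None:
        inh_center = inh_coords.mean(axis=0)
        r_inh = float(np.linalg.norm(inh_coords - inh_center, axis=1).max())
    others = [(o, o.mean(axis=0), float(np.linalg.norm(o - o.mean(axis=0),
                                                       axis=1).max()))
              for o in placed]
    for _ in range(max_tries):
        R = _random_rotation(rng)
        center = rng.uniform(0.0, box)
        cand = None
        if inh_coords is not None:
            cd = _min_image_center_dist(center, inh_center, box)
            if cd < _MIN_INHIBITOR_SEP + r_self + r_inh:
                cand = template @ R.T + center
                if _min_image_dists_sq(cand, inh_coords, box).min() \
                        < _MIN_INHIBITOR_SEP ** 2:
                    continue
        ok = True
        for other, oc, orad in others:
            cd = _min_image_center_dist(center, oc, box)
            if cd >= _MIN_PEPTIDE_SEP + r_self + orad:
                continue
            if cand is None:
                cand = template @ R.T + center
            if _min_image_dists_sq(cand, other, box).min() < _MIN_PEPTIDE_SEP ** 2:
                ok = False
                break
        if ok:
            return template @ R.T + center if cand is None else cand
    raise ConfigurationError(
        "could not place an unbound peptide under the separation constraints; "
        "box too small for the composition"
    )


def markov_binding_generator(scenario: KineticScenario, validate: bool = True
                             ) -> tuple[Trajectory, GroundTruth]:
    """Generate a trajectory whose binding kinetics are exactly known.

    Each peptide flips between inhibitor-bound and free with per-frame
    switch probabilities 1 - exp(-k dt).  Bound peptides are docked at a
    randomly chosen free surface patch of the inhibitor; free peptides are
    re-placed uniformly under the minimum-separation constraints.  With
    ``validate`` the emitted frames are re-analyzed with the contact
    definitions and must reproduce the ground truth exactly.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    model = build_bead_model(sc.n_peptides, sc.inhibitor)
    geometry = _inhibitor_geometry(sc.inhibitor)
    if geometry is None:
        raise ConfigurationError("the Markov generator needs an inhibitor; "
                                 "use the scene builder for control systems")
    template = _peptide_template(len(sequences.ABETA_17_42))
    box = np.full(3, sc.box_edge)
    box_center = box / 2.0
    inh_coords = geometry.coords + box_center
    n_patches = len(geometry.patches)
    if sc.n_peptides > n_patches:
        raise ConfigurationError("more peptides than docking patches")

    p_bind = 1.0 - np.exp(-sc.k_on * sc.dt)
    p_unbind = 1.0 - np.exp(-sc.k_off * sc.dt)
    p_dim = 1.0 - np.exp(-sc.k_dimer * sc.dt)
    p_undim = 1.0 - np.exp(-sc.k_undimer * sc.dt)

    if sc.initial_bound is not None:
        if len(sc.initial_bound) != sc.n_peptides:
            raise ValidationError("initial_bound length mismatch")
        bound = np.array(sc.initial_bound, dtype=bool)
    else:
        p_stat = sc.k_on / (sc.k_on + sc.k_off) if (sc.k_on + sc.k_off) > 0 else 0.0
        bound = rng.random(sc.n_peptides) < p_stat

    patch_of = np.full(sc.n_peptides, -1, dtype=int)
    free_patches = list(range(n_patches))
    rng.shuffle(free_patches)
    for j in np.flatnonzero(bound):
        patch_of[j] = free_patches.pop()

    partner = np.full(sc.n_peptides, -1, dtype=int)   # dimer partner or -1

    pep_ids = model.peptide_chain_ids
    pep_atoms = [model.chain_atom_indices(p) for p in pep_ids]
    inh_atoms = (np.concatenate([model.chain_atom_indices(c)
                                 for c in model.inhibitor_chain_ids]))

    frames: list[Frame] = []
    bound_log = np.zeros((sc.n_frames, sc.n_peptides), dtype=bool)
    partitions: list[list[frozenset[str]]] = []

    def is_leader(j: int) -> bool:
        """In a dimer, only the lower-index member ('leader') may dock; the
        other member rides stacked outward, mirroring the picture of an
        oligomer attaching to the inhibitor through one member."""
        return partner[j] < 0 or j < partner[j]

    for fi in range(sc.n_frames):
        if fi > 0:
            # optional dimer update first
            if p_undim > 0 or p_dim > 0:
                for j in range(sc.n_peptides):
                    k = partner[j]
                    if k > j and rng.random() < p_undim:
                        partner[j] = partner[k] = -1
                if p_dim > 0:
                    free = [j for j in range(sc.n_peptides) if partner[j] < 0]
                    rng.shuffle(free)
                    while len(free) >= 2:
                        j = free.pop()
                        if rng.random() < p_dim:
                            k = free.pop(int(rng.integers(len(free))))
                            partner[j], partner[k] = k, j
                # a freshly-dimerized follower gives up any dock it held
                for j in range(sc.n_peptides):
                    if bound[j] and not is_leader(j):
                        bound[j] = False
                        free_patches.append(patch_of[j])
                        patch_of[j] = -1
            # two-state binding update (leaders only)
            u = rng.random(sc.n_peptides)
            for j in range(sc.n_peptides):
                if not is_leader(j):
                    continue
                if bound[j] and u[j] < p_unbind:
                    bound[j] = False
                    free_patches.append(patch_of[j])
                    patch_of[j] = -1
                elif not bound[j] and u[j] < p_bind and free_patches:
                    bound[j] = True
                    k = int(rng.integers(len(free_patches)))
                    patch_of[j] = free_patches.pop(k)

        # geometry for this frame
        coords = np.empty((model.n_atoms, 3))
        coords[inh_atoms] = inh_coords
        placed: list[np.ndarray] = []
        pep_coords: list[np.ndarray | None] = [None] * sc.n_peptides
        for j in range(sc.n_peptides):          # docked leaders
            if bound[j]:
                pep_coords[j] = _docked_pose(template, geometry, patch_of[j]) \
                    + box_center
                placed.append(pep_coords[j])
        for j in range(sc.n_peptides):          # free leaders (dimers as a unit)
            if pep_coords[j] is None and is_leader(j):
                if partner[j] >= 0:
                    direction = _random_rotation(rng)[:, 0]
                    pair_template = np.concatenate(
                        [template, template + direction * _STACK])
                    pair_template -= pair_template.mean(axis=0)
                    both = _place_unbound(pair_template, placed, inh_coords,
                                          box, rng)
                    pep_coords[j] = both[:len(template)]
                    pep_coords[partner[j]] = both[len(template):]
                    placed += [pep_coords[j], pep_coords[partner[j]]]
                else:
                    pep_coords[j] = _place_unbound(template, placed, inh_coords,
                                                   box, rng)
                    placed.append(pep_coords[j])
        for j in range(sc.n_peptides):          # followers of docked leaders
            if pep_coords[j] is None:
                k = partner[j]
                _c, direction = geometry.patches[patch_of[k]]
                pep_coords[j] = pep_coords[k] + direction * _STACK
                placed.append(pep_coords[j])
        for j in range(sc.n_peptides):
            coords[pep_atoms[j]] = pep_coords[j]
        coords += rng.normal(scale=sc.jitter_sigma, size=coords.shape)

        t = fi * sc.dt
        frames.append(Frame(t, coords, box.copy()))
        bound_log[fi] = bound
        part: list[frozenset[str]] = []
        done = set()
        for j in range(sc.n_peptides):
            if j in done:
                continue
            if partner[j] >= 0:
                part.append(frozenset((pep_ids[j], pep_ids[partner[j]])))
                done.add(partner[j])
            else:
                part.append(frozenset((pep_ids[j],)))
        partitions.append(part)

    traj = Trajectory(model, frames)
    truth = GroundTruth(traj.times, bound_log, partitions, pep_ids, sc)
    if validate:
        _validate_against_truth(traj, truth)
    return traj, truth


def _validate_against_truth(traj: Trajectory, truth: GroundTruth) -> None:
    cfg = ContactConfig()
    for fi, frame in enumerate(traj.frames):
        rec = residue_contacts(frame, traj.model, cfg)
        state = classify_frame(rec, traj.model)
        got_bound = np.array([state.bound[p] for p in truth.peptide_ids])
        if not np.array_equal(got_bound, truth.bound[fi]):
            raise ConfigurationError(
                f"generator self-check failed at frame {fi}: bound flags "
                f"{got_bound.tolist()} != truth {truth.bound[fi].tolist()}"
            )
        if set(state.partition) != set(truth.partitions[fi]):
            raise ConfigurationError(
                f"generator self-check failed at frame {fi}: oligomer "
                "partition disagrees with ground truth"
            )


# ---------------------------------------------------------------------------
# Oligomer scene builder
# ---------------------------------------------------------------------------

def oligomer_scene_builder(oligomer_spec: Sequence[tuple[int, bool]],
                           inhibitor: str | None = "acd_dimer",
                           box_edge: float = 124.0, seed: int = 0,
                           validate: bool = True
                           ) -> tuple[SystemModel, Frame, GroundTruth]:
    """Build one frame with a prescribed oligomer composition.

    *oligomer_spec* is a sequence of ``(size, inhibitor_bound)`` tuples,
    e.g. ``[(3, True), (2, True)] + [(1, False)] * 5`` for one bound trimer,
    one bound dimer and five free monomers.  Bound oligomers have exactly
    one member docked; intra-oligomer neighbours share well over five
    contacts, distinct oligomers share none.
    """
    sizes = [s for s, _ in oligomer_spec]
    if any(s < 1 for s in sizes):
        raise ValidationError("oligomer sizes must be >= 1")
    n_pep = sum(sizes)
    if n_pep > 10:
        raise ConfigurationError("composition exceeds 10 peptide chains")
    bound_oligos = [b for _, b in oligomer_spec]
    if any(bound_oligos) and inhibitor is None:
        raise ConfigurationError("bound oligomers need an inhibitor")

    rng = np.random.default_rng(seed)
    model = build_bead_model(n_pep, inhibitor)
    geometry = _inhibitor_geometry(inhibitor)
    template = _peptide_template(len(sequences.ABETA_17_42))
    box = np.full(3, box_edge)
    box_center = box / 2.0

    pep_ids = model.peptide_chain_ids
    pep_atoms = [model.chain_atom_indices(p) for p in pep_ids]
    coords = np.empty((model.n_atoms, 3))
    inh_coords = None
    if geometry is not None:
        inh_coords = geometry.coords + box_center
        inh_atoms = np.concatenate([model.chain_atom_indices(c)
                                    for c in model.inhibitor_chain_ids])
        coords[inh_atoms] = inh_coords

    n_bound = sum(bound_oligos)
    if geometry is not None and n_bound > len(geometry.patches):
        raise ConfigurationError("more bound oligomers than docking patches")
    free_patches = list(range(len(geometry.patches))) if geometry else []
    rng.shuffle(free_patches)

    placed: list[np.ndarray] = []
    partition: list[frozenset[str]] = []
    bound_flags = np.zeros(n_pep, dtype=bool)
    j = 0
    for size, is_bound in oligomer_spec:
        members = list(range(j, j + size))
        j += size
        if is_bound:
            patch = free_patches.pop()
            stack = [_docked_pose(template, geometry, patch, stack_index=k)
                     + box_center for k in range(size)]
            bound_flags[members[0]] = True
        else:
            # free oligomer: stack along a random direction from a free spot
            direction = _random_rotation(rng)[:, 0]
            stacked_template = np.concatenate(
                [template + direction * (k * _STACK) for k in range(size)])
            base = _place_unbound(stacked_template - stacked_template.mean(axis=0),
                                  placed, inh_coords, box, rng)
            stack = [base[k * len(template):(k + 1) * len(template)]
                     for k in range(size)]
        for m, c in zip(members, stack):
            coords[pep_atoms[m]] = c
            placed.append(c)
        partition.append(frozenset(pep_ids[m] for m in members))

    frame = Frame(0.0, coords, box)
    truth = GroundTruth(np.array([0.0]), bound_flags[None, :], [partition],
                        pep_ids, None)
    if validate:
        _validate_against_truth(Trajectory(model, [frame]), truth)
    return model, frame, truth


# ---------------------------------------------------------------------------
# Brownian toy simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BrownianParams:
    """Overdamped Langevin bead-chain toy with emergent aggregation.

    Energies in kcal/mol, lengths in Å, times in ns.  The inhibitor bead
    cluster is held static; its per-bead stickiness models a uniformly
    attractive ("lysozyme-like") or patchy ("ACD-like") surface.
    """

    n_peptides: int = 6
    n_residues: int = 26
    box_edge: float = 60.0
    eps_pp: float = 0.0          # peptide-peptide attraction depth
    inhibitor: str | None = None
    eps_pi: float = 0.0          # peptide-inhibitor stickiness (mean)
    patchy: bool = False         # if True, only half the inhibitor beads stick
    temperature: float = 325.0
    diffusion: float = 10.0      # Å²/ns free-bead diffusion coefficient
    k_bond: float = 2.0          # kcal/mol/Å² harmonic bond stiffness
    bond_length: float = _BOND
    attr_sigma: float = 4.5      # Å attraction range
    rep_eps: float = 5.0         # kcal/mol soft-core repulsion
    rep_sigma: float = 2.0       # Å repulsion range
    dt: float = 0.005            # ns integration step
    n_steps: int = 2000
    save_every: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.diffusion <= 0:
            raise ValidationError("dt and diffusion must be > 0")
        # overdamped stability heuristic: bond relaxation per step << 1
        if 2.0 * self.k_bond * self.diffusion / (0.0019872041 * self.temperature) \
                * self.dt > 0.5:
            raise ValidationError("time step too large for the bond stiffness")


def brownian_toy_sim(params: BrownianParams) -> Trajectory:
    """Integrate the bead-chain toy and return the saved trajectory."""
    p = params
    kBT = 0.0019872041 * p.temperature
    mobility = p.diffusion / kBT          # Å²/(kcal/mol)/ns
    rng = np.random.default_rng(p.seed)

    model = build_bead_model(p.n_peptides, p.inhibitor,
                             peptide_seq=sequences.ABETA_17_42[:p.n_residues])
    box = np.full(3, p.box_edge)
    n_pep_beads = p.n_peptides * p.n_residues
    geometry = _inhibitor_geometry(p.inhibitor)

    # initial condition: straightened chains on a loose grid
    x = np.empty((model.n_atoms, 3))
    grid = int(np.ceil(p.n_peptides ** (1 / 3)))
    cell = p.box_edge / grid
    for j in range(p.n_peptides):
        gx, gy, gz = j % grid, (j // grid) % grid, j // grid ** 2
        start = (np.array([gx, gy, gz]) + 0.5) * cell
        chain = np.tile(start, (p.n_residues, 1))
        chain[:, 0] += (np.arange(p.n_residues) - p.n_residues / 2) * p.bond_length
        x[j * p.n_residues:(j + 1) * p.n_residues] = chain
    if geometry is not None:
        x[n_pep_beads:] = geometry.coords + box / 2.0

    sticky = np.zeros(model.n_atoms)
    sticky[:n_pep_beads] = 1.0
    if geometry is not None and p.eps_pi > 0:
        n_inh = model.n_atoms - n_pep_beads
        eps_i = np.full(n_inh, p.eps_pi)
        if p.patchy:
            mask = rng.random(n_inh) < 0.5
            eps_i = np.where(mask, 2 * p.eps_pi, 0.0)   # same mean, patchy
        inh_eps = eps_i
    else:
        inh_eps = None

    bonds_i = []
    bonds_j = []
    for j in range(p.n_peptides):
        base = j * p.n_residues
        bonds_i += list(range(base, base + p.n_residues - 1))
        bonds_j += list(range(base + 1, base + p.n_residues))
    bonds_i = np.array(bonds_i)
    bonds_j = np.array(bonds_j)

    chain_of = np.repeat(np.arange(p.n_peptides), p.n_residues)
    r_list = 3.0 * p.attr_sigma
    frames: list[Frame] = []
    amp = np.sqrt(2.0 * p.diffusion * p.dt)

    for step in range(p.n_steps + 1):
        forces = np.zeros_like(x)
        # harmonic bonds (no wrapping: chains stay compact vs the box)
        d = x[bonds_j] - x[bonds_i]
        d -= box * np.round(d / box)
        r = np.linalg.norm(d, axis=1)
        f = (p.k_bond * (r - p.bond_length) / np.maximum(r, 1e-9))[:, None] * d
        np.add.at(forces, bonds_i, f)
        np.add.at(forces, bonds_j, -f)

        # nonbonded: soft repulsion everywhere, Gaussian attraction where sticky
        wrapped = np.mod(x, box)
        wrapped = np.where(wrapped >= box, 0.0, wrapped)
        tree = cKDTree(wrapped, boxsize=box)
        pairs = tree.query_pairs(r_list, output_type="ndarray")
        if pairs.size:
            ii, jj = pairs[:, 0], pairs[:, 1]
            # skip bonded/next-neighbour pairs within one chain
            both_pep = (ii < n_pep_beads) & (jj < n_pep_beads)
            same_chain = both_pep & (chain_of[np.minimum(ii, n_pep_beads - 1)] ==
                                     chain_of[np.minimum(jj, n_pep_beads - 1)])
            near_seq = same_chain & (np.abs(ii - jj) <= 2)
            keep = ~near_seq
            ii, jj = ii[keep], jj[keep]
            dvec = x[jj] - x[ii]
            dvec -= box * np.round(dvec / box)
            r2 = np.einsum("ij,ij->i", dvec, dvec)
            r1 = np.sqrt(np.maximum(r2, 1e-12))
            # repulsion magnitude (positive = push apart)
            mag = (p.rep_eps / p.rep_sigma ** 2) * np.exp(-r2 / (2 * p.rep_sigma ** 2))
            # attraction
            eps_pair = np.zeros_like(r1)
            eps_pair[(ii < n_pep_beads) & (jj < n_pep_beads)] = p.eps_pp
            if inh_eps is not None:
                pi_mask = (ii < n_pep_beads) != (jj < n_pep_beads)
                inh_idx = np.where(ii >= n_pep_beads, ii, jj) - n_pep_beads
                eps_pair[pi_mask] = inh_eps[inh_idx[pi_mask]]
            mag -= (eps_pair / p.attr_sigma ** 2) * np.exp(-r2 / (2 * p.attr_sigma ** 2))
            fpair = (mag)[:, None] * dvec   # force on i along -dvec when mag>0
            np.add.at(forces, ii, -fpair)
            np.add.at(forces, jj, fpair)

        if step > 0:
            disp = mobility * forces * p.dt + amp * rng.normal(size=x.shape)
            if geometry is not None:
                disp[n_pep_beads:] = 0.0     # inhibitor held static
            if np.abs(disp).max() > 5.0:
                raise RuntimeError(
                    f"unstable integration at step {step}: max displacement "
                    f"{np.abs(disp).max():.1f} Å in one step"
                )
            x = x + disp
        if step % p.save_every == 0:
            frames.append(Frame(step * p.dt, x.copy(), box.copy()))
    return Trajectory(model, frames)
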