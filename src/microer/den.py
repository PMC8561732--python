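"""Deformable elastic network (DEN) restraints.

A DEN is a random subset of short atom-pair distances restrained to
adaptive reference values: E = weight * sum_p (d_p - d_ref_p)^2.  The
references drift toward a blend of the current and the initial geometry,

    d_ref <- d_ref + kappa * (gamma * (d_now - d_ref) + (1 - gamma) * (d_init - d_ref)),

so with gamma = 1 the network slowly follows the model (fully adaptive)
and with gamma = 0 it anchors to the starting structure.  Every
``reselect_interval`` macrocycles a random fraction of the pairs is
replaced by freshly drawn candidates so the initial pair choice does not
bias the sampling; the default interval is 500 macrocycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model_io import StructureModel

__all__ = ["DENParams", "DENRestraint", "DENNetwork", "build_network",
           "den_energy_gradient", "update_references", "reselect_pairs"]


class DENError(ValueError):
    pass


@dataclass(frozen=True)
class DENRestraint:
    atom_pair: tuple[int, int]  # indices into the model's atom order
    d_ref: float
    d_init: float

    def __post_init__(self) -> None:
        i, j = self.atom_pair
        if i == j:
            raise DENError("restraint pair must be two distinct atoms")
        if self.d_ref <= 0 or self.d_init <= 0:
            raise DENError("reference distances must be positive")


@dataclass(frozen=True)
class DENParams:
    """DEN configuration; see module docstring for the update rule."""

    weight: float = 10.0          # kcal mol^-1 A^-2
    gamma: float = 1.0            # adaptivity: 0 = anchor to start, 1 = follow current
    kappa: float = 0.1            # update rate per triggered update
    update_interval: int = 1      # macrocycles
    reselect_interval: int = 500  # macrocycles
    reselect_fraction: float = 0.2
    pair_cutoff: float = 8.0      # A
    min_seq_sep: int = 2          # residues (intra-chain); inter-chain pairs always allowed
    density: float = 1.0          # restraints per atom
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.update_interval < 1 or self.reselect_interval < 1:
            raise DENError("intervals must be >= 1 macrocycle")
        if self.pair_cutoff <= 0:
            raise DENError("pair_cutoff must be positive")
        if not 0.0 <= self.gamma <= 1.0 or not 0.0 <= self.kappa <= 1.0:
            raise DENError("gamma and kappa must lie in [0, 1]")
        if not 0.0 <= self.reselect_fraction <= 1.0:
            raise DENError("reselect_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class DENNetwork:
    restraints: tuple[DENRestraint, ...]
    params: DENParams
    rng_state: dict = field(compare=False, default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "restraints", tuple(self.restraints))

    @property
    def n_restraints(self) -> int:
        return len(self.restraints)

    def pair_array(self) -> np.ndarray:
        return np.array([r.atom_pair for r in self.restraints], dtype=int).reshape(-1, 2)

    def d_ref_array(self) -> np.ndarray:
        return np.array([r.d_ref for r in self.restraints], dtype=float)

    def to_table(self) -> list[tuple[int, int, float, float]]:
        """(atom_i, atom_j, d_ref, d_init) rows for inspection."""
        return [(r.atom_pair[0], r.atom_pair[1], r.d_ref, r.d_init) for r in self.restraints]


def _candidate_pairs(model: StructureModel, params: DENParams) -> np.ndarray:
    """All atom pairs within the cutoff passing the sequence-separation rule."""
    pos = model.positions
    n = len(pos)
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    chain = np.array([a.chain_id for a in model.atoms])
    res = np.array([a.res_id for a in model.atoms])
    iu, ju = np.triu_indices(n, k=1)
    ok = dist[iu, ju] <= params.pair_cutoff
    same_chain = chain[iu] == chain[ju]
    ok &= ~same_chain | (np.abs(res[iu] - res[ju]) >= params.min_seq_sep)
    return np.column_stack([iu[ok], ju[ok]])


def build_network(model: StructureModel, params: DENParams) -> DENNetwork:
    """Draw a seeded random restraint set from the candidate pairs.

    The target size is ``round(density * n_atoms)``; if fewer candidates
    exist, all of them are used (an empty network is valid but inert).
    """
    if model.n_atoms < 2:
        raise DENError("need at least 2 atoms to build a network")
    rng = np.random.default_rng(params.rng_seed)
    cand = _candidate_pairs(model, params)
    n_target = int(round(params.density * model.n_atoms))
    pos = model.positions
    if len(cand) == 0:
        return DENNetwork(restraints=(), params=params)
    take = min(n_target, len(cand))
    chosen = cand[np.sort(rng.choice(len(cand), size=take, replace=False))]
    d = np.sqrt(((pos[chosen[:, 0]] - pos[chosen[:, 1]]) ** 2).sum(axis=1))
    restraints = tuple(
        DENRestraint(atom_pair=(int(i), int(j)), d_ref=float(dd), d_init=float(dd))
        for (i, j), dd in zip(chosen, d)
    )
    return DENNetwork(restraints=restraints, params=params)


def den_energy_gradient(network: DENNetwork, positions: np.ndarray):
    """Harmonic DEN energy (kcal/mol) and its per-atom gradient.

    E = weight * sum (d - d_ref)^2; the gradient is analytic.  Distances
    are translation/rotation invariant, so the energy is too.
    """
    positions = np.asarray(positions, dtype=float)
    grad = np.zeros_like(positions)
    if network.n_restraints == 0:
        return 0.0, grad
    pairs = network.pair_array()
    d_ref = network.d_ref_array()
    diff = positions[pairs[:, 0]] - positions[pairs[:, 1]]
    d = np.sqrt((diff**2).sum(axis=1))
    if np.any(d < 1e-8):
        raise DENError("coincident restrained atoms: distance gradient singular")
    w = network.params.weight
    energy = float(w * ((d - d_ref) ** 2).sum())
    coeff = (2.0 * w * (d - d_ref) / d)[:, None] * diff
    np.add.at(grad, pairs[:, 0], coeff)
    np.add.at(grad, pairs[:, 1], -coeff)
    return energy, grad


def update_references(network: DENNetwork, positions: np.ndarray, macrocycle: int) -> DENNetwork:
    """Blend reference distances toward current/initial geometry on schedule.

    Triggers when ``macrocycle % update_interval == 0``; otherwise the
    network is returned unchanged.
    """
    p = network.params
    if network.n_restraints == 0 or macrocycle % p.update_interval != 0:
        return network
    positions = np.asarray(positions, dtype=float)
    pairs = network.pair_array()
    diff = positions[pairs[:, 0]] - positions[pairs[:, 1]]
    d_now = np.sqrt((diff**2).sum(axis=1))
    new = []
    for r, dn in zip(network.restraints, d_now):
        target = p.gamma * (dn - r.d_ref) + (1.0 - p.gamma) * (r.d_init - r.d_ref)
        new.append(replace(r, d_ref=r.d_ref + p.kappa * target))
    return DENNetwork(restraints=tuple(new), params=p, rng_state=network.rng_state)


def reselect_pairs(network: DENNetwork, model: StructureModel, macrocycle: int) -> DENNetwork:
    """Replace a random fraction of restraints with fresh candidate pairs.

    Triggers when ``macrocycle % reselect_interval == 0`` (and the
    macrocycle is positive).  New restraints take d_ref = d_init = the
    current distance.  The draw is seeded by (rng_seed, macrocycle), so a
    full run's reselection history is reproducible.
    """
    p = network.params
    if macrocycle <= 0 or macrocycle % p.reselect_interval != 0:
        return network
    if p.reselect_fraction == 0.0 or network.n_restraints == 0:
        return network
    rng = np.random.default_rng((p.rng_seed, macrocycle))
    n_drop = int(round(p.reselect_fraction * network.n_restraints))
    if n_drop == 0:
        return network
    drop = set(rng.choice(network.n_restraints, size=n_drop, replace=False).tolist())
    kept = [r for i, r in enumerate(network.restraints) if i not in drop]

    cand = _candidate_pairs(model, p)
    existing = {tuple(r.atom_pair) for r in kept}
    avail = [tuple(c) for c in cand if tuple(c) not in existing]
    rng.shuffle(avail)
    pos = model.positions
    new = []
    for i, j in avail[:n_drop]:
        d = float(np.linalg.norm(pos[i] - pos[j]))
        new.append(DENRestraint(atom_pair=(int(i), int(j)), d_ref=d, d_init=d))
    # insufficient candidates -> network shrinks (valid, noted by caller)
    return DENNetwork(restraints=tuple(kept + new), params=p, rng_state=network.rng_state)
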