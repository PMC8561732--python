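"""Restrained Langevin dynamics with time-averaged X-ray restraints.

One *macrocycle* is a fixed block of dynamics steps.  At each macrocycle
boundary the engine accumulates the instantaneous structure factors into
the rolling time average, scores R_work/R_free, and runs the DEN
update/reselection schedule; within the macrocycle, atoms evolve under

    F = -grad( E_geometry + E_DEN + xray_energy_scale * wx * T_xray )

integrated with the BAOAB Langevin splitting (which reduces to velocity
Verlet at zero friction and temperature).  Snapshots collected after
burn-in form the output ensemble; their per-atom fluctuations (RMSF)
are the sampled counterpart of a B factor via B = 8 pi^2 rmsf^2 / 3.

Units: kcal/mol, Angstrom, ps, K, amu; the usual conversion factor
turns kcal/mol/A/amu into A/ps^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .den import DENNetwork, DENParams, build_network, den_energy_gradient, reselect_pairs, update_references
from .model_io import ReflectionSet, StructureModel
from .tls import B_PER_U, DisorderModel, combine_levels
from .xray import (
    SFCalcParams,
    TimeAveragedSF,
    XrayError,
    _direct_sum,
    _s2,
    _target_grad_arrays,
    accumulate_time_average,
    calc_structure_factors,
    r_factors,
)

__all__ = [
    "GeometryTerms",
    "ERConfig",
    "EnsembleResult",
    "default_geometry",
    "run_ensemble_refinement",
    "compute_rmsf",
    "ensemble_b_equivalent",
]

KB = 0.0019872041  # kcal mol^-1 K^-1
ACC = 418.4  # (kcal/mol/A) / amu -> A/ps^2
MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}


class EngineError(RuntimeError):
    pass


@dataclass(frozen=True)
class GeometryTerms:
    """Toy force field: harmonic bonds and angles plus soft-core repulsion.

    Stands in for a full MD force field; ideal values are typically taken
    from the input structure so that the unrestrained minimum is the
    starting geometry.
    """

    bond_pairs: np.ndarray          # (nb, 2) int
    bond_ideal: np.ndarray          # (nb,) A
    bond_k: float = 300.0           # kcal mol^-1 A^-2
    angle_triples: np.ndarray = None  # (na, 3) int
    angle_ideal: np.ndarray = None    # (na,) rad
    angle_k: float = 50.0           # kcal mol^-1 rad^-2
    repulsion_cutoff: float = 2.2   # A
    repulsion_k: float = 20.0       # kcal mol^-1 A^-2
    excluded: frozenset = frozenset()  # pairs excluded from repulsion

    def __post_init__(self) -> None:
        if min(self.bond_k, self.angle_k, self.repulsion_k, 0.0) < 0:
            raise ValueError("force constants must be non-negative")


def default_geometry(model: StructureModel, n_link_bonds: int = 4) -> GeometryTerms:
    """Toy bonded topology: intra-residue cliques plus inter-residue links.

    Every atom pair within a residue is bonded (the residue behaves as a
    semi-rigid unit, standing in for the covalent + improper-torsion
    stiffness of a real residue), and consecutive residues of a chain are
    joined by the ``n_link_bonds`` closest cross-residue atom pairs, which
    leaves hinge-like inter-residue flexibility.  Ideal lengths are the
    input model's current values, so the unrestrained energy minimum is
    the starting structure.
    """
    pos = model.positions
    bonds: list[tuple[int, int]] = []
    res_atoms: list[np.ndarray] = []
    res_chain: list[str] = []
    for ch, ss_map in model.hierarchy.items():
        for ss, res_map in ss_map.items():
            for res_id in sorted(res_map):
                res_atoms.append(np.asarray(res_map[res_id], dtype=int))
                res_chain.append(ch)
    for idxs in res_atoms:
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                bonds.append((int(idxs[a]), int(idxs[b])))
    for r in range(len(res_atoms) - 1):
        if res_chain[r] != res_chain[r + 1]:
            continue
        ia, ib = res_atoms[r], res_atoms[r + 1]
        d = np.sqrt(((pos[ia][:, None, :] - pos[ib][None, :, :]) ** 2).sum(axis=-1))
        order = np.argsort(d.ravel(), kind="stable")[: min(n_link_bonds, d.size)]
        for flat in order:
            bonds.append((int(ia[flat // len(ib)]), int(ib[flat % len(ib)])))
    bonds = np.array(sorted(set(tuple(sorted(b)) for b in bonds)), dtype=int).reshape(-1, 2)
    bond_ideal = np.sqrt(((pos[bonds[:, 0]] - pos[bonds[:, 1]]) ** 2).sum(axis=1))

    excluded = {tuple(sorted(p)) for p in bonds.tolist()}
    return GeometryTerms(
        bond_pairs=bonds,
        bond_ideal=bond_ideal,
        angle_triples=np.zeros((0, 3), dtype=int),
        angle_ideal=np.zeros(0),
        excluded=frozenset(excluded),
    )


def _angles(pos: np.ndarray, triples: np.ndarray) -> np.ndarray:
    v1 = pos[triples[:, 0]] - pos[triples[:, 1]]
    v2 = pos[triples[:, 2]] - pos[triples[:, 1]]
    cosang = (v1 * v2).sum(axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def geometry_energy_gradient(geom: GeometryTerms, pos: np.ndarray):
    """Analytic energy and gradient of the toy force field."""
    energy = 0.0
    grad = np.zeros_like(pos)
    if len(geom.bond_pairs):
        i, j = geom.bond_pairs[:, 0], geom.bond_pairs[:, 1]
        diff = pos[i] - pos[j]
        d = np.sqrt((diff**2).sum(axis=1))
        delta = d - geom.bond_ideal
        energy += geom.bond_k * float(delta @ delta)
        coeff = (2.0 * geom.bond_k * delta / np.maximum(d, 1e-12))[:, None] * diff
        np.add.at(grad, i, coeff)
        np.add.at(grad, j, -coeff)
    if geom.angle_triples is not None and len(geom.angle_triples):
        a, b, c = geom.angle_triples.T
        v1 = pos[a] - pos[b]
        v2 = pos[c] - pos[b]
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        cosang = np.clip((v1 * v2).sum(axis=1) / (n1 * n2), -1.0 + 1e-10, 1.0 - 1e-10)
        theta = np.arccos(cosang)
        delta = theta - geom.angle_ideal
        energy += geom.angle_k * float(delta @ delta)
        # d theta / d r via standard angle-gradient formulas
        sin = np.sqrt(1.0 - cosang**2)
        dth = 2.0 * geom.angle_k * delta
        ga = (dth / (n1 * sin))[:, None] * (cosang[:, None] * v1 / n1[:, None] - v2 / n2[:, None]) * -1.0
        gc = (dth / (n2 * sin))[:, None] * (cosang[:, None] * v2 / n2[:, None] - v1 / n1[:, None]) * -1.0
        np.add.at(grad, a, ga)
        np.add.at(grad, c, gc)
        np.add.at(grad, b, -(ga + gc))
    if geom.repulsion_k > 0:
        diff = pos[:, None, :] - pos[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
        iu, ju = np.triu_indices(len(pos), k=1)
        close = d[iu, ju] < geom.repulsion_cutoff
        if close.any():
            ii, jj = iu[close], ju[close]
            keep = np.array(
                [tuple(sorted((int(i), int(j)))) not in geom.excluded for i, j in zip(ii, jj)]
            )
            ii, jj = ii[keep], jj[keep]
            if len(ii):
                dd = d[ii, jj]
                pen = geom.repulsion_cutoff - dd
                energy += geom.repulsion_k * float(pen @ pen)
                coeff = (-2.0 * geom.repulsion_k * pen / np.maximum(dd, 1e-12))[:, None] * diff[ii, jj]
                np.add.at(grad, ii, coeff)
                np.add.at(grad, jj, -coeff)
    return energy, grad


@dataclass(frozen=True)
class ERConfig:
    """Full run configuration for one ensemble-refinement simulation."""

    wx: float = 1.0
    tx: float = 1.0                     # macrocycles
    steps_per_macrocycle: int = 50
    n_macrocycles: int = 200
    temperature: float = 300.0          # K
    friction: float = 1.0               # ps^-1
    timestep: float = 0.002             # ps
    snapshot_interval: int = 1          # macrocycles
    burn_in: int | None = None          # default: 20% of n_macrocycles
    rng_seed: int = 0
    den: DENParams | None = None
    disorder: DisorderModel | None = None
    disorder_levels: set | None = None  # subset of level indices; None = all
    xray_energy_scale: float = 3000.0   # kcal/mol per unit of normalized target
    xray_refresh_steps: int = 1         # recompute X-ray gradient every k steps
    force_guard: float = 1e5            # kcal/mol/A
    velocity_guard: float = 1e4         # A/ps

    def __post_init__(self) -> None:
        burn = self.resolved_burn_in
        if self.n_macrocycles <= burn:
            raise ValueError("n_macrocycles must exceed burn_in")
        if self.snapshot_interval < 1 or self.steps_per_macrocycle < 1:
            raise ValueError("intervals must be >= 1")

    @property
    def resolved_burn_in(self) -> int:
        if self.burn_in is not None:
            return self.burn_in
        return int(0.2 * self.n_macrocycles)


@dataclass
class EnsembleResult:
    snapshots: list[StructureModel]
    r_work_history: np.ndarray
    r_free_history: np.ndarray
    target_history: np.ndarray
    energy_history: np.ndarray  # (n_macrocycles, 2): kinetic, potential kcal/mol
    final_r_work: float
    final_r_free: float
    rmsf: np.ndarray
    disorder_b: np.ndarray
    config: ERConfig


def _disorder_b(config: ERConfig, model: StructureModel) -> np.ndarray:
    if config.disorder is None:
        return np.zeros(model.n_atoms)
    return combine_levels(config.disorder, model, config.disorder_levels)


def run_ensemble_refinement(
    model: StructureModel,
    reflections: ReflectionSet,
    config: ERConfig,
    geometry: GeometryTerms | None = None,
) -> EnsembleResult:
    """Run one seeded ER simulation and collect the snapshot ensemble.

    The simulated structure carries zero atomic B; all modelled disorder
    enters through the input disorder model's Debye-Waller contribution,
    and the remaining disorder must be sampled by the dynamics -- exactly
    the division of labour the input disorder model controls.
    """
    geom = geometry if geometry is not None else default_geometry(model)
    disorder_b = _disorder_b(config, model)
    sf_params = SFCalcParams()
    sim_model = model.with_b_iso(np.zeros(model.n_atoms))

    rng = np.random.default_rng(config.rng_seed)
    pos = sim_model.positions
    n = sim_model.n_atoms
    masses = np.array([MASSES.get(e, 12.011) for e in sim_model.elements])[:, None]
    mass_frac = masses / masses.sum()
    com0 = (mass_frac * pos).sum(axis=0)

    kT = KB * config.temperature
    if kT > 0:
        vel = rng.normal(size=(n, 3)) * np.sqrt(kT * ACC / masses)
    else:
        vel = np.zeros((n, 3))
    dt = config.timestep
    c1 = np.exp(-config.friction * dt)
    c2 = np.sqrt(max(0.0, (1.0 - c1 * c1)) * kT * ACC / masses) if kT > 0 else 0.0

    network = build_network(sim_model, config.den) if config.den is not None else None
    state = TimeAveragedSF(tx=config.tx)

    # static arrays for the structure-factor hot path
    hkl = reflections.hkl.astype(float)
    cell = np.asarray(sim_model.cell, dtype=float)
    s2 = _s2(hkl, cell)
    f_occ = sim_model.occupancies * sf_params.factors(sim_model.elements)
    b_total = disorder_b if sf_params.include_disorder_b else np.zeros(n)
    f_obs = reflections.f_obs
    work = reflections.work_mask
    rho = state.rho

    def rest_grad(p):
        _, g = geometry_energy_gradient(geom, p)
        if network is not None and network.n_restraints:
            _, g_den = den_energy_gradient(network, p)
            g = g + g_den
        return g

    def energies(p, v):
        kinetic = float(0.5 * (masses * v**2).sum() / ACC)
        pot, _ = geometry_energy_gradient(geom, p)
        if network is not None and network.n_restraints:
            e_den, _ = den_energy_gradient(network, p)
            pot += e_den
        return kinetic, pot

    snapshots: list[StructureModel] = []
    r_work_hist, r_free_hist, target_hist, energy_hist = [], [], [], []
    burn_in = config.resolved_burn_in

    for mc in range(1, config.n_macrocycles + 1):
        energy_hist.append(energies(pos, vel))
        f_now = _direct_sum(hkl, cell, s2, f_occ, b_total, pos)
        state = accumulate_time_average(state, f_now)
        score = r_factors(reflections, state.f_bar, wx=config.wx)
        r_work_hist.append(score.r_work)
        r_free_hist.append(score.r_free)
        target_hist.append(score.target_value)

        if network is not None:
            network = update_references(network, pos, mc)
            network = reselect_pairs(network, sim_model.with_positions(pos), mc)

        def xray_force_at(p):
            if config.wx <= 0:
                return 0.0
            _, xray_grad = _target_grad_arrays(
                state.f_bar, rho, hkl, cell, s2, f_occ, b_total, p,
                f_obs, work, config.wx,
            )
            return -config.xray_energy_scale * xray_grad

        xray_force = xray_force_at(pos)
        force = -rest_grad(pos) + xray_force
        for step in range(config.steps_per_macrocycle):
            if np.abs(force).max() > config.force_guard:
                raise EngineError(f"integration failure at macrocycle {mc}: force blow-up")
            # BAOAB splitting; forces are re-evaluated after the move so
            # both half-kicks of every component use current positions
            vel = vel + 0.5 * dt * force * ACC / masses
            pos = pos + 0.5 * dt * vel
            if kT > 0 and config.friction > 0:
                vel = c1 * vel + c2 * rng.normal(size=(n, 3))
            pos = pos + 0.5 * dt * vel
            if config.wx > 0 and (step + 1) % config.xray_refresh_steps == 0:
                xray_force = xray_force_at(pos)
            force = -rest_grad(pos) + xray_force
            vel = vel + 0.5 * dt * force * ACC / masses
            if np.abs(vel).max() > config.velocity_guard:
                raise EngineError(f"integration failure at macrocycle {mc}: velocity blow-up")
            # |F| is invariant under rigid translation, so centre-of-mass
            # motion is unrestrained; remove it (standard MD practice)
            vel = vel - (mass_frac * vel).sum(axis=0)
            pos = pos + (com0 - (mass_frac * pos).sum(axis=0))

        if mc > burn_in and (mc - burn_in) % config.snapshot_interval == 0:
            snapshots.append(sim_model.with_positions(pos))

    # final score: ensemble-and-time-averaged F over snapshots
    if snapshots:
        f_ens = calc_structure_factors(snapshots, reflections, disorder_b, sf_params)
        final = r_factors(reflections, f_ens, wx=config.wx)
        final_r_work, final_r_free = final.r_work, final.r_free
    else:
        final_r_work = final_r_free = float("nan")

    rmsf = compute_rmsf(snapshots) if len(snapshots) >= 2 else np.zeros(n)
    return EnsembleResult(
        snapshots=snapshots,
        r_work_history=np.array(r_work_hist),
        r_free_history=np.array(r_free_hist),
        target_history=np.array(target_hist),
        energy_history=np.array(energy_hist),
        final_r_work=final_r_work,
        final_r_free=final_r_free,
        rmsf=rmsf,
        disorder_b=disorder_b,
        config=config,
    )


def compute_rmsf(snapshots: list[StructureModel]) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the snapshot mean, A."""
    if len(snapshots) < 2:
        raise ValueError("need >= 2 snapshots to compute fluctuations")
    stack = np.array([s.positions for s in snapshots])
    mean = stack.mean(axis=0)
    return np.sqrt(((stack - mean) ** 2).sum(axis=2).mean(axis=0))


def ensemble_b_equivalent(rmsf: np.ndarray) -> np.ndarray:
    """B-factor equivalent of sampled fluctuations: B = 8 pi^2 rmsf^2 / 3."""
    rmsf = np.asarray(rmsf, dtype=float)
    return B_PER_U * rmsf**2 / 3.0
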