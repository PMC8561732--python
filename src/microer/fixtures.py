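"""Synthetic toy crystals with known hierarchical disorder.

The generator manufactures a ground-truth ensemble by layering independent
rigid motions on a base structure, mirroring the physical picture of
motions on top of motions:

1. chain level: rigid translation (sigma_chain_trans per axis) and
   small-angle rotation about the chain centroid (sigma_chain_rot);
2. secondary-structure level: small-angle rotation about each SS-element
   centroid (sigma_ss_rot);
3. residue level: libration about each residue centroid (sigma_res_lib);
4. atomic level: independent isotropic jitter (sigma_atom).

Rotations sample an axis uniformly on the sphere and an angle ~ N(0,
sigma^2); to first order the displacement covariance of an atom at offset
r from the rotation centre is sigma^2 (|r|^2 I - r r^T) / 3, giving the
closed-form per-layer B factors stored as ``truth_level_b``.  Reflection
amplitudes are |mean F| over the conformer ensemble with optional
multiplicative noise, and the "classically refined input model" is
emulated by the base structure carrying B factors derived from the
ensemble positional variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .model_io import ReflectionRecord, ReflectionSet, StructureModel, AtomRecord
from .tls import B_PER_U
from .xray import SFCalcParams, calc_structure_factors

__all__ = ["DisorderSpec", "Fixture", "build_toy_structure", "generate_fixture"]

MAX_ROT_SIGMA = 0.3  # rad; beyond this the small-angle correspondence degrades


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class DisorderSpec:
    """Generative disorder parameters (one sigma per layer)."""

    sigma_chain_trans: float = 0.0  # A
    sigma_chain_rot: float = 0.0    # rad
    sigma_ss_rot: float = 0.0       # rad
    sigma_res_lib: float = 0.0      # rad
    sigma_atom: float = 0.0         # A
    n_conformers: int = 200
    noise_frac: float = 0.0
    free_fraction: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        sigmas = (self.sigma_chain_trans, self.sigma_chain_rot, self.sigma_ss_rot,
                  self.sigma_res_lib, self.sigma_atom)
        if any(s < 0 for s in sigmas):
            raise FixtureError("sigmas must be non-negative")
        if self.n_conformers < 1:
            raise FixtureError("n_conformers must be >= 1")
        if not 0.0 < self.free_fraction < 1.0:
            raise FixtureError("free_fraction must lie in (0, 1)")
        for s in (self.sigma_chain_rot, self.sigma_ss_rot, self.sigma_res_lib):
            if s > MAX_ROT_SIGMA:
                warnings.warn(
                    f"rotation sigma {s} rad exceeds {MAX_ROT_SIGMA}; "
                    "small-angle TLS correspondence degrades", stacklevel=2,
                )


@dataclass
class Fixture:
    """Ground-truth ensemble plus everything derived from it."""

    truth_ensemble: list[StructureModel]
    mean_model: StructureModel
    reflections: ReflectionSet
    truth_level_b: dict[str, np.ndarray]  # layer label -> per-atom B (A^2)
    spec: DisorderSpec
    warnings: list[str] = field(default_factory=list)


_ATOM_NAMES = ["N", "CA", "C", "O", "CB", "CG", "CD", "CE"]
_ATOM_ELEMENTS = {"N": "N", "O": "O"}


def build_toy_structure(
    n_chains: int = 1,
    n_ss_per_chain: int = 2,
    n_res_per_ss: int = 5,
    atoms_per_res: int = 4,
    cell: tuple[float, float, float] = (30.0, 25.0, 25.0),
) -> StructureModel:
    """Deterministic clash-free toy polymer with a hairpin-like fold.

    Each secondary-structure element is a straight twisted segment of
    residues; consecutive segments run antiparallel with a lateral
    offset.  Each residue carries ``atoms_per_res`` atoms (named N, CA,
    C, O, ...) at varied distances from the residue centre.  Chains are
    stacked with an inter-chain offset.  Guarantees a minimum inter-atom
    distance of 1.2 A.
    """
    if min(n_chains, n_ss_per_chain, n_res_per_ss, atoms_per_res) < 1:
        raise FixtureError("all counts must be >= 1")
    if atoms_per_res > len(_ATOM_NAMES):
        raise FixtureError(f"atoms_per_res capped at {len(_ATOM_NAMES)}")

    atoms: list[AtomRecord] = []
    atom_id = 1
    # Each SS element is a straight twisted segment; consecutive segments
    # run antiparallel with a lateral offset (a hairpin-like fold), so the
    # chain-level, SS-level and residue-level libration signatures are
    # geometrically distinct.  Atom offsets point to cube corners with
    # varied radii (pairwise separation stays >= 1.2 A), so libration
    # about the residue centre produces a non-flat intra-residue profile.
    rise = 3.2          # A between residue centres along a segment
    strand_sep = 5.0    # A between consecutive antiparallel segments
    twist = 100.0 * np.pi / 180.0
    # fixed offsets with varied radii AND varied axial/equatorial character,
    # so no single group-level libration axis can reproduce the intra-residue
    # pattern (pairwise separation >= 1.28 A; >= 1.35 A among the first four)
    offsets = np.array(
        [
            [0.315, 1.395, 0.163],
            [-0.926, -0.618, -0.195],
            [0.028, -1.550, -0.278],
            [0.134, 0.098, -1.167],
            [-1.154, 0.859, -0.319],
            [1.501, 0.284, -0.053],
            [0.631, 0.456, 0.905],
            [-1.177, 0.067, 0.898],
        ]
    )
    # segment axes alternate between +z and +y (an L-shaped / zigzag fold):
    # orthogonal, unequally placed segments keep the chain centroid away
    # from every segment middle, which makes chain-level and SS-level
    # libration B-profiles linearly independent
    axes = [np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0])]
    # frame rotation aligning the local offset z-axis with the segment axis
    frames = [np.eye(3), np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, -1.0, 0.0]])]
    seg_len = rise * (n_res_per_ss - 1)
    for ci in range(n_chains):
        chain_id = chr(ord("A") + ci)
        chain_shift = np.array([(seg_len + strand_sep + 8.0) * ci, 0.0, 0.0])
        base = np.zeros(3)
        for si in range(n_ss_per_chain):
            ss_id = f"S{si + 1}"
            axis = axes[si % 2]
            frame = frames[si % 2]
            for rj in range(n_res_per_ss):
                ri = si * n_res_per_ss + rj
                t = ri * twist
                centre = base + axis * rise * rj + chain_shift
                rot = np.array(
                    [[np.cos(t), -np.sin(t), 0.0], [np.sin(t), np.cos(t), 0.0], [0.0, 0.0, 1.0]]
                )
                for ai in range(atoms_per_res):
                    name = _ATOM_NAMES[ai]
                    pos = centre + frame @ rot @ offsets[ai]
                    atoms.append(
                        AtomRecord(
                            atom_id=atom_id,
                            name=name,
                            element=_ATOM_ELEMENTS.get(name, "C"),
                            chain_id=chain_id,
                            ss_id=ss_id,
                            res_id=ri + 1,
                            position=pos,
                            occupancy=1.0,
                            b_iso=0.0,
                        )
                    )
                    atom_id += 1
            # next segment turns the corner: continue from this segment's
            # end, displaced laterally so the fold does not self-intersect
            base = base + axis * (seg_len + rise) + np.array([strand_sep, 0.0, 0.0]) * (
                1.0 if si % 2 == 0 else -1.0
            )

    positions = np.array([a.position for a in atoms])
    extent = positions.max(axis=0) - positions.min(axis=0)
    if np.any(extent > np.asarray(cell) - 2.0):
        raise FixtureError(f"cell {cell} too small for chain extent {extent}")
    # recentre into the cell
    shift = 0.5 * np.asarray(cell) - 0.5 * (positions.max(axis=0) + positions.min(axis=0))
    atoms = [
        AtomRecord(**{**_fields(a), "position": a.position + shift}) for a in atoms
    ]
    model = StructureModel(atoms, cell)
    d = _min_distance(model.positions)
    if d < 1.2:
        raise FixtureError(f"internal geometry error: min inter-atom distance {d:.2f} A")
    return model


def _fields(a: AtomRecord) -> dict:
    return {
        "atom_id": a.atom_id, "name": a.name, "element": a.element,
        "chain_id": a.chain_id, "ss_id": a.ss_id, "res_id": a.res_id,
        "position": a.position, "occupancy": a.occupancy, "b_iso": a.b_iso,
    }


def _min_distance(pos: np.ndarray) -> float:
    diff = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(d, np.inf)
    return float(d.min())


def _random_rotation(rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Rotation matrix: axis uniform on the sphere, angle ~ N(0, sigma^2)."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.normal(0.0, sigma)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _rotation_b(offsets: np.ndarray, sigma: float) -> np.ndarray:
    """Closed-form B from a uniform-axis small-angle rotation layer.

    Cov(u) = sigma^2 (|r|^2 I - r r^T) / 3, so tr(U) = (2/3) sigma^2 |r|^2
    and B = (8 pi^2 / 3) tr(U) = (16 pi^2 / 9) sigma^2 |r|^2.
    """
    r2 = (offsets**2).sum(axis=1)
    return (B_PER_U / 3.0) * (2.0 / 3.0) * sigma**2 * r2


def _enumerate_hkl(cell, d_min: float) -> np.ndarray:
    """Friedel-unique reflection indices with d >= d_min (P1, no (0,0,0))."""
    cell = np.asarray(cell, dtype=float)
    hmax = np.floor(cell / d_min).astype(int)
    hs = np.arange(-hmax[0], hmax[0] + 1)
    ks = np.arange(-hmax[1], hmax[1] + 1)
    ls = np.arange(-hmax[2], hmax[2] + 1)
    H, K, L = np.meshgrid(hs, ks, ls, indexing="ij")
    hkl = np.column_stack([H.ravel(), K.ravel(), L.ravel()])
    inv_d2 = ((hkl / cell) ** 2).sum(axis=1)
    keep = (inv_d2 > 0) & (inv_d2 <= 1.0 / d_min**2)
    hkl = hkl[keep]
    # Friedel half: keep h > 0, or h == 0 and k > 0, or h == k == 0 and l > 0
    first_nonzero_positive = (
        (hkl[:, 0] > 0)
        | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0))
        | ((hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0))
    )
    return hkl[first_nonzero_positive]


def generate_fixture(base: StructureModel, spec: DisorderSpec, d_min: float = 2.0) -> Fixture:
    """Layered-disorder ensemble, mean model, reflections and truth decomposition."""
    notes: list[str] = []
    if spec.n_conformers < 10:
        notes.append(f"n_conformers={spec.n_conformers} < 10: variance estimates unstable")
    rng = np.random.default_rng(spec.rng_seed)
    base_pos = base.positions
    n = base.n_atoms

    chain_groups = base.groups("chain")
    ss_groups = base.groups("secondary_structure")
    res_groups = base.groups("residue")

    conformers = []
    for _ in range(spec.n_conformers):
        pos = base_pos.copy()
        # residue libration
        if spec.sigma_res_lib > 0:
            for idxs in res_groups.values():
                idxs = np.asarray(idxs)
                centre = base_pos[idxs].mean(axis=0)
                R = _random_rotation(rng, spec.sigma_res_lib)
                pos[idxs] = (pos[idxs] - centre) @ R.T + centre
        # secondary-structure rotation
        if spec.sigma_ss_rot > 0:
            for idxs in ss_groups.values():
                idxs = np.asarray(idxs)
                centre = base_pos[idxs].mean(axis=0)
                R = _random_rotation(rng, spec.sigma_ss_rot)
                pos[idxs] = (pos[idxs] - centre) @ R.T + centre
        # chain rigid transform
        for idxs in chain_groups.values():
            idxs = np.asarray(idxs)
            centre = base_pos[idxs].mean(axis=0)
            if spec.sigma_chain_rot > 0:
                R = _random_rotation(rng, spec.sigma_chain_rot)
                pos[idxs] = (pos[idxs] - centre) @ R.T + centre
            if spec.sigma_chain_trans > 0:
                pos[idxs] = pos[idxs] + rng.normal(0.0, spec.sigma_chain_trans, size=3)
        # atomic jitter
        if spec.sigma_atom > 0:
            pos = pos + rng.normal(0.0, spec.sigma_atom, size=(n, 3))
        conformers.append(base.with_positions(pos))

    # mean model: base coordinates, B from per-atom positional variance
    stack = np.array([c.positions for c in conformers])  # (M, n, 3)
    var_per_axis = stack.var(axis=0).mean(axis=1)  # mean over axes
    b_mean = B_PER_U * var_per_axis
    mean_model = base.with_positions(stack.mean(axis=0)).with_b_iso(b_mean)

    # analytic per-layer decomposition
    truth: dict[str, np.ndarray] = {}
    chain_b = np.full(n, B_PER_U * spec.sigma_chain_trans**2)
    for idxs in chain_groups.values():
        idxs = np.asarray(idxs)
        offsets = base_pos[idxs] - base_pos[idxs].mean(axis=0)
        chain_b[idxs] += _rotation_b(offsets, spec.sigma_chain_rot)
    truth["chain"] = chain_b
    ss_b = np.zeros(n)
    for idxs in ss_groups.values():
        idxs = np.asarray(idxs)
        offsets = base_pos[idxs] - base_pos[idxs].mean(axis=0)
        ss_b[idxs] = _rotation_b(offsets, spec.sigma_ss_rot)
    truth["secondary_structure"] = ss_b
    res_b = np.zeros(n)
    for idxs in res_groups.values():
        idxs = np.asarray(idxs)
        offsets = base_pos[idxs] - base_pos[idxs].mean(axis=0)
        res_b[idxs] = _rotation_b(offsets, spec.sigma_res_lib)
    truth["residue"] = res_b
    truth["atomic"] = np.full(n, B_PER_U * spec.sigma_atom**2)

    # reflections: |mean F| over the ensemble, multiplicative noise, free flags
    hkl = _enumerate_hkl(base.cell, d_min)
    refl_probe = ReflectionSet(
        [ReflectionRecord(hkl=tuple(h), f_obs=0.0, sigma=1.0, free_flag=False) for h in hkl],
        d_min=d_min,
    )
    f_mean = calc_structure_factors(conformers, refl_probe, params=SFCalcParams())
    amps = np.abs(f_mean)
    if spec.noise_frac > 0:
        amps = np.maximum(amps * (1.0 + rng.normal(0.0, spec.noise_frac, size=len(amps))), 0.0)
        sigmas = np.maximum(spec.noise_frac * np.abs(f_mean), 1e-6)
    else:
        sigmas = np.maximum(0.01 * amps, 1e-6)
    n_free = max(1, int(round(spec.free_fraction * len(hkl))))
    free_idx = rng.choice(len(hkl), size=n_free, replace=False)
    free = np.zeros(len(hkl), dtype=bool)
    free[free_idx] = True
    records = [
        ReflectionRecord(hkl=tuple(h), f_obs=float(a), sigma=float(s), free_flag=bool(fl))
        for h, a, s, fl in zip(hkl, amps, sigmas, free)
    ]
    reflections = ReflectionSet(records, d_min=d_min)

    return Fixture(
        truth_ensemble=conformers,
        mean_model=mean_model,
        reflections=reflections,
        truth_level_b=truth,
        spec=spec,
        warnings=notes,
    )
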