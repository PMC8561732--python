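"""Standard study conditions: the reference toy crystal and run settings.

Everything downstream (worked examples, property checks, the acceptance
script) uses these fixed conditions so that results are comparable.  The
toy crystal is a single 40-atom chain of two secondary-structure elements
in a small orthogonal P1 cell, with hierarchical disorder dominated by
rotational layers so that the B-factor profile is strongly heterogeneous:
a low-B core near the rotation centres and a high-B exterior, which is
the regime where the pTLS baseline misbehaves.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .den import DENParams
from .engine import ERConfig
from .fixtures import DisorderSpec, Fixture, build_toy_structure, generate_fixture
from .model_io import StructureModel
from .tls import DisorderModel, fit_echt, fit_ptls

__all__ = [
    "standard_structure",
    "standard_spec",
    "single_layer_spec",
    "standard_fixture",
    "standard_er_config",
    "standard_variants",
]

#: resolution of the synthetic data, Angstrom
D_MIN = 2.3

#: generative disorder of the standard (heterogeneous) crystal; the
#: fine-scale layers dominate, giving a low-B core and a high-B exterior
#: that a single chain-level TLS group cannot describe -- the regime in
#: which the pTLS baseline overestimates the collective component
SIGMA_CHAIN_TRANS = 0.10  # A     -> flat B ~ 0.8 A^2
SIGMA_CHAIN_ROT = 0.03    # rad   -> up to ~1 A^2 at the chain ends
SIGMA_SS_ROT = 0.15       # rad   -> up to ~6 A^2 at SS-element ends
SIGMA_RES_LIB = 0.25      # rad   -> up to ~3 A^2 at residue peripheries
SIGMA_ATOM = 0.10         # A     -> flat B ~ 0.8 A^2
N_CONFORMERS = 300
NOISE_FRAC = 0.02
FREE_FRACTION = 0.1


def standard_structure() -> StructureModel:
    """One chain, 2 SS elements x 5 residues x 4 atoms, small P1 cell."""
    return build_toy_structure(
        n_chains=1, n_ss_per_chain=2, n_res_per_ss=5, atoms_per_res=4,
        cell=(12.0, 20.0, 22.0),
    )


def standard_spec(seed: int = 0, n_conformers: int = N_CONFORMERS) -> DisorderSpec:
    return DisorderSpec(
        sigma_chain_trans=SIGMA_CHAIN_TRANS,
        sigma_chain_rot=SIGMA_CHAIN_ROT,
        sigma_ss_rot=SIGMA_SS_ROT,
        sigma_res_lib=SIGMA_RES_LIB,
        sigma_atom=SIGMA_ATOM,
        n_conformers=n_conformers,
        noise_frac=NOISE_FRAC,
        free_fraction=FREE_FRACTION,
        rng_seed=seed,
    )


def single_layer_spec(layer: str, seed: int = 0, n_conformers: int = 500) -> DisorderSpec:
    """Disorder spec with only one populated layer (for parameter recovery)."""
    kwargs = dict(n_conformers=n_conformers, noise_frac=0.0,
                  free_fraction=FREE_FRACTION, rng_seed=seed)
    if layer == "chain":
        return DisorderSpec(sigma_chain_trans=SIGMA_CHAIN_TRANS,
                            sigma_chain_rot=SIGMA_CHAIN_ROT, **kwargs)
    if layer == "secondary_structure":
        return DisorderSpec(sigma_ss_rot=SIGMA_SS_ROT, **kwargs)
    if layer == "residue":
        return DisorderSpec(sigma_res_lib=SIGMA_RES_LIB, **kwargs)
    raise ValueError(f"unknown layer {layer!r}")


def standard_fixture(seed: int = 0, n_conformers: int = N_CONFORMERS) -> Fixture:
    return generate_fixture(standard_structure(), standard_spec(seed, n_conformers), d_min=D_MIN)


def standard_er_config(**overrides) -> ERConfig:
    """Reference ER settings for the standard fixture.

    Sized so that one run takes seconds: short macrocycles and a reduced
    macrocycle count, with the DEN reselection interval scaled down in
    proportion so the schedule still triggers within a run.
    """
    defaults = dict(
        wx=1.0,
        tx=8.0,
        steps_per_macrocycle=40,
        n_macrocycles=100,
        temperature=5.0,
        friction=10.0,
        timestep=0.002,
        snapshot_interval=1,
        rng_seed=0,
        den=DENParams(weight=30.0, reselect_interval=50, rng_seed=0),
        xray_energy_scale=5000.0,
        xray_refresh_steps=1,
    )
    defaults.update(overrides)
    return ERConfig(**defaults)


def standard_variants(fixture: Fixture, ptls_fraction: float = 0.9):
    """Fit disorder models to the fixture's mean model and list the variants.

    Returns ``(label, DisorderModel, level_subset)`` tuples for: no input
    disorder, hierarchical levels 1, 1+2, 1+2+3, and the pTLS baseline.
    """
    echt = fit_echt(fixture.mean_model)
    ptls = fit_ptls(fixture.mean_model, ptls_fraction=ptls_fraction)
    return [
        ("none", None, None),
        ("L1", echt, {1}),
        ("L1+2", echt, {1, 2}),
        ("L1+2+3", echt, {1, 2, 3}),
        (f"pTLS={ptls_fraction}", ptls, None),
    ]
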