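"""Structure factors, time-averaged X-ray target and R factors.

Structure factors are computed by direct summation in an orthogonal P1
cell:

    F(h) = sum_j occ_j f_j exp(-B_j s^2 / 4) exp(2 pi i h . x_frac,j)

with s = |reciprocal-lattice vector| and B_j the atomic B factor plus, if
enabled, the input disorder model's per-atom contribution (the
Debye-Waller route by which a TLS disorder model enters the refinement).

The time-averaged target keeps an exponentially decaying rolling average
of F_calc with memory factor rho = exp(-1/TX) per macrocycle; the X-ray
residual is a least-squares amplitude target on the work set with a
fitted overall scale, and R factors are the standard normalized amplitude
disagreements (free-set R uses the work-set scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import ReflectionSet, StructureModel

__all__ = [
    "SFCalcParams",
    "TimeAveragedSF",
    "XrayScore",
    "calc_structure_factors",
    "accumulate_time_average",
    "xray_target_gradient",
    "r_factors",
]


class XrayError(ValueError):
    pass


#: constant single-Gaussian-free form factors (electron counts)
DEFAULT_FORM_FACTORS = {"C": 6.0, "N": 7.0, "O": 8.0, "S": 16.0, "H": 1.0, "P": 15.0}


@dataclass(frozen=True)
class SFCalcParams:
    """Structure-factor calculation options.

    ``form_factor`` maps element symbols to a constant scattering factor;
    ``include_disorder_b`` adds the disorder model's per-atom B to the
    atomic B in the Debye-Waller exponent.
    """

    form_factor: dict = field(default_factory=lambda: dict(DEFAULT_FORM_FACTORS))
    include_disorder_b: bool = True

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.form_factor.values()):
            raise XrayError("form factors must be positive")

    def factors(self, elements: list[str]) -> np.ndarray:
        try:
            return np.array([self.form_factor[e] for e in elements], dtype=float)
        except KeyError as exc:
            raise XrayError(f"no form factor for element {exc}") from exc


_MAX_EXPONENT = 500.0


def _s2(hkl: np.ndarray, cell) -> np.ndarray:
    """Squared reciprocal-vector length per reflection, A^-2."""
    return ((hkl / np.asarray(cell, dtype=float)) ** 2).sum(axis=1)


def _direct_sum(
    hkl: np.ndarray,
    cell: np.ndarray,
    s2: np.ndarray,
    f_occ: np.ndarray,
    b: np.ndarray,
    positions: np.ndarray,
) -> np.ndarray:
    """Array-level direct summation (hot path for the dynamics engine)."""
    exponent = np.outer(s2, b) / 4.0
    if exponent.max(initial=0.0) > _MAX_EXPONENT:
        raise XrayError("Debye-Waller exponent overflow: B * s^2 / 4 too large")
    phase = 2.0 * np.pi * (hkl @ (positions / cell).T)
    return (f_occ * np.exp(-exponent) * np.exp(1j * phase)).sum(axis=1)


def calc_structure_factors(
    model: StructureModel | list[StructureModel],
    reflections: ReflectionSet,
    disorder_b: np.ndarray | None = None,
    params: SFCalcParams | None = None,
) -> np.ndarray:
    """Complex F per reflection by direct summation.

    For an ensemble (list of models) the result is the mean over member
    structure factors, which is exact for a uniformly weighted ensemble.
    """
    params = params or SFCalcParams()
    models = model if isinstance(model, list) else [model]
    hkl = reflections.hkl.astype(float)
    cell = models[0].cell
    s2 = _s2(hkl, cell)

    total = np.zeros(len(hkl), dtype=complex)
    for m in models:
        b = m.b_iso
        if disorder_b is not None and params.include_disorder_b:
            b = b + np.asarray(disorder_b, dtype=float)
        f_occ = m.occupancies * params.factors(m.elements)
        total += _direct_sum(hkl, np.asarray(cell, dtype=float), s2, f_occ, b, m.positions)
    return total / len(models)


@dataclass
class TimeAveragedSF:
    """Rolling exponential average of F_calc.

    rho = exp(-1/TX) with TX in macrocycle units; the first accumulation
    initializes f_bar to the instantaneous value.
    """

    tx: float
    f_bar: np.ndarray | None = None
    n_accumulated: int = 0

    def __post_init__(self) -> None:
        if self.tx < 0:
            raise XrayError("TX must be non-negative")

    @property
    def rho(self) -> float:
        if self.tx <= 0:
            return 0.0  # memoryless limit
        return float(np.exp(-1.0 / self.tx))


def accumulate_time_average(state: TimeAveragedSF, f_now: np.ndarray) -> TimeAveragedSF:
    """One accumulation step: f_bar <- rho f_bar + (1 - rho) f_now."""
    f_now = np.asarray(f_now, dtype=complex)
    if not np.all(np.isfinite(f_now)):
        raise XrayError("non-finite structure factors")
    if state.f_bar is None or state.n_accumulated == 0:
        return TimeAveragedSF(tx=state.tx, f_bar=f_now.copy(), n_accumulated=1)
    rho = state.rho
    return TimeAveragedSF(
        tx=state.tx,
        f_bar=rho * state.f_bar + (1.0 - rho) * f_now,
        n_accumulated=state.n_accumulated + 1,
    )


def _scale(f_obs: np.ndarray, f_model: np.ndarray) -> float:
    denom = float(f_model @ f_model)
    if denom <= 0:
        raise XrayError("scale undefined: |F_model| identically zero on the work set")
    return float(f_obs @ f_model) / denom


def _target_grad_arrays(
    f_bar: np.ndarray | None,
    rho: float,
    hkl: np.ndarray,
    cell: np.ndarray,
    s2: np.ndarray,
    f_occ: np.ndarray,
    b: np.ndarray,
    positions: np.ndarray,
    f_obs: np.ndarray,
    work: np.ndarray,
    wx: float,
):
    """Array-level LS target and positional gradient (engine hot path)."""
    exponent = np.outer(s2, b) / 4.0
    if exponent.max(initial=0.0) > _MAX_EXPONENT:
        raise XrayError("Debye-Waller exponent overflow: B * s^2 / 4 too large")
    phase = 2.0 * np.pi * (hkl @ (positions / cell).T)
    contrib = f_occ * np.exp(-exponent) * np.exp(1j * phase)  # (n_refl, n_atoms)
    f_now = contrib.sum(axis=1)
    if f_bar is None:
        f_eff = f_now
        w_inst = 1.0
    else:
        f_eff = rho * f_bar + (1.0 - rho) * f_now
        w_inst = 1.0 - rho

    amp = np.abs(f_eff)
    k = _scale(f_obs[work], amp[work])
    norm = float(f_obs[work] @ f_obs[work])
    resid = f_obs[work] - k * amp[work]
    target = wx * float(resid @ resid) / norm

    damp = np.zeros(len(f_obs))
    damp[work] = wx * (-2.0 * k) * resid / norm
    dcomplex = damp * (f_eff.conj() / np.maximum(amp, 1e-300)) * w_inst
    core = dcomplex[:, None] * contrib
    grad = np.empty((positions.shape[0], 3))
    for alpha in range(3):
        coeff = 2.0 * np.pi * hkl[:, alpha] / cell[alpha]
        grad[:, alpha] = np.real(1j * (coeff[:, None] * core)).sum(axis=0)
    return target, grad


def xray_target_gradient(
    state: TimeAveragedSF,
    reflections: ReflectionSet,
    model: StructureModel,
    wx: float,
    disorder_b: np.ndarray | None = None,
    params: SFCalcParams | None = None,
):
    """Weighted LS amplitude target against the time-averaged F and its
    positional gradient.

    target = wx * sum_work (|F_obs| - k |f_eff|)^2 / sum_work |F_obs|^2

    where f_eff = rho * f_bar + (1 - rho) * F_now(x) blends the stored
    average with the instantaneous structure factors of ``model`` and the
    scale k minimizes the target on the work set.  Only the instantaneous
    term is differentiated (the stored average is treated as a constant);
    because k is at its least-squares optimum, the k-dependence contributes
    nothing to the gradient (envelope theorem), so the analytic gradient
    equals the finite-difference gradient of the full expression.  Free
    reflections never enter the target or the gradient.
    """
    params = params or SFCalcParams()
    if wx == 0.0:
        return 0.0, np.zeros((model.n_atoms, 3))
    work = reflections.work_mask
    if not work.any():
        raise XrayError("empty work set")

    hkl = reflections.hkl.astype(float)
    cell = np.asarray(model.cell, dtype=float)
    b = model.b_iso
    if disorder_b is not None and params.include_disorder_b:
        b = b + np.asarray(disorder_b, dtype=float)
    f_bar = None if (state.f_bar is None or state.n_accumulated == 0) else state.f_bar
    return _target_grad_arrays(
        f_bar, state.rho, hkl, cell, _s2(hkl, cell),
        model.occupancies * params.factors(model.elements),
        b, model.positions, reflections.f_obs, work, wx,
    )


@dataclass(frozen=True)
class XrayScore:
    r_work: float
    r_free: float
    target_value: float
    scale_k: float


def r_factors(reflections: ReflectionSet, f_model: np.ndarray, wx: float = 1.0) -> XrayScore:
    """R = sum||F_obs| - k|F_model|| / sum|F_obs| over work and free sets.

    The scale k is fitted by least squares on the work set only and reused
    for the free set (free reflections never influence the scaling).
    """
    amp = np.abs(np.asarray(f_model))
    f_obs = reflections.f_obs
    work = reflections.work_mask
    free = reflections.free_mask
    if not work.any():
        raise XrayError("empty work set")
    if not free.any():
        raise XrayError("r_free undefined: empty free set")
    k = _scale(f_obs[work], amp[work])

    def r(mask):
        return float(np.abs(f_obs[mask] - k * amp[mask]).sum() / f_obs[mask].sum())

    resid = f_obs[work] - k * amp[work]
    target = wx * float(resid @ resid) / float(f_obs[work] @ f_obs[work])
    return XrayScore(r_work=r(work), r_free=r(free), target_value=target, scale_k=k)
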