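"""Two-stage TX/WX parameter search and disorder-model comparison.

The quality landscape of ensemble refinement is dominated by the
relaxation time TX with a weaker, roughly orthogonal dependence on the
X-ray weight WX, so a full 2D grid search can be replaced by two linear
searches: TX is varied at a default WX, then WX is varied at the chosen
TX.  The continuous pTLS-fraction dimension of the legacy approach is
replaced by a discrete list of disorder-model variants (combinations of
hierarchical levels, or a pTLS baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import ERConfig, GeometryTerms, run_ensemble_refinement
from .model_io import ReflectionSet, StructureModel

__all__ = ["SweepPlan", "SweepResult", "two_stage_argmin", "run_two_stage_sweep", "compare_variants"]


@dataclass(frozen=True)
class SweepPlan:
    """Grids and variants for one two-stage search."""

    tx_grid: tuple[float, ...] = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
    wx_grid: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
    wx_default: float = 1.0
    disorder_variants: tuple = ()   # (label, DisorderModel, level subset or None)
    replicate_seeds: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if not self.tx_grid or not self.wx_grid:
            raise ValueError("grids must be non-empty")
        if not self.replicate_seeds:
            raise ValueError("need at least one replicate seed")


@dataclass
class SweepResult:
    variant: str
    table: pd.DataFrame  # columns: variant, stage, wx, tx, seed, r_work, r_free, failed
    best_tx: float
    best_wx: float
    best_r_work: float
    best_r_free: float


def two_stage_argmin(evaluate, tx_grid, wx_grid, wx_default):
    """Two linear searches over a scalar objective ``evaluate(tx, wx)``.

    Stage 1 scans ``tx_grid`` at ``wx_default`` and picks the minimizing
    tx; stage 2 scans ``wx_grid`` at that tx.  Ties break toward smaller
    tx, then smaller wx (grids are scanned in sorted order).  Returns
    ``(tx_best, wx_best, value, rows)`` with one row per evaluation.
    """
    rows = []
    best_tx, best_v1 = None, np.inf
    for tx in sorted(tx_grid):
        v = evaluate(tx, wx_default)
        rows.append(("tx", tx, wx_default, v))
        if np.isfinite(v) and v < best_v1 - 1e-15:
            best_tx, best_v1 = tx, v
    if best_tx is None:
        raise RuntimeError("all stage-1 evaluations failed")
    best_wx, best_v2 = None, np.inf
    for wx in sorted(wx_grid):
        if wx == wx_default:
            v = dict(((r[1], r[2]), r[3]) for r in rows).get((best_tx, wx))
            if v is None:
                v = evaluate(best_tx, wx)
        else:
            v = evaluate(best_tx, wx)
        rows.append(("wx", best_tx, wx, v))
        if np.isfinite(v) and v < best_v2 - 1e-15:
            best_wx, best_v2 = wx, v
    return best_tx, best_wx, best_v2, rows


def run_two_stage_sweep(
    model: StructureModel,
    reflections: ReflectionSet,
    plan: SweepPlan,
    base_config: ERConfig,
    geometry: GeometryTerms | None = None,
) -> list[SweepResult]:
    """Run the two-stage TX-then-WX search for every disorder variant.

    Each grid point runs once per replicate seed; the stage objective is
    the mean final R_free over seeds.  Failed runs are recorded and
    excluded from the argmin.
    """
    variants = plan.disorder_variants or (("none", None, None),)
    results = []
    for label, disorder, levels in variants:
        records = []

        def evaluate(tx, wx, _label=label, _disorder=disorder, _levels=levels):
            vals = []
            for seed in plan.replicate_seeds:
                cfg = replace(
                    base_config, tx=tx, wx=wx, rng_seed=seed,
                    disorder=_disorder, disorder_levels=_levels,
                )
                try:
                    res = run_ensemble_refinement(model, reflections, cfg, geometry)
                    records.append((_label, wx, tx, seed, res.final_r_work, res.final_r_free, False))
                    vals.append(res.final_r_free)
                except Exception:
                    records.append((_label, wx, tx, seed, np.nan, np.nan, True))
            return float(np.mean(vals)) if vals else np.inf

        tx_best, wx_best, v_best, _ = two_stage_argmin(
            evaluate, plan.tx_grid, plan.wx_grid, plan.wx_default
        )
        df = pd.DataFrame(
            records, columns=["variant", "wx", "tx", "seed", "r_work", "r_free", "failed"]
        )
        at_best = df[(df.tx == tx_best) & (df.wx == wx_best) & ~df.failed]
        results.append(
            SweepResult(
                variant=label,
                table=df,
                best_tx=tx_best,
                best_wx=wx_best,
                best_r_work=float(at_best.r_work.mean()),
                best_r_free=float(v_best),
            )
        )
    return results


def compare_variants(results: list[SweepResult]) -> pd.DataFrame:
    """Best row per disorder variant, sorted by R_free then variant label."""
    if not results:
        raise ValueError("no sweep results to compare")
    rows = [
        {
            "disorder_model": r.variant,
            "r_work": r.best_r_work,
            "r_free": r.best_r_free,
            "wx": r.best_wx,
            "tx": r.best_tx,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(["r_free", "disorder_model"], kind="stable").reset_index(drop=True)
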