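"""Tabular and graphical reports: B-factor profiles and results tables.

The tabular exports are the testable surface; plots are optional
artifacts rendered from the same aligned tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model_io import StructureModel
from .tls import DisorderModel, combine_levels

__all__ = ["profile_report", "results_table", "plot_profiles"]


def profile_report(
    model: StructureModel,
    disorder_models: list[tuple[str, DisorderModel, set | None]],
) -> pd.DataFrame:
    """Aligned per-atom B-profile table: the input model plus each variant.

    ``disorder_models`` is a list of ``(label, model, level_subset)``;
    ``level_subset=None`` uses all levels.  All series share the model's
    atom ordering, so profile curves can be overlaid directly.
    """
    data = {
        "atom_id": model.atom_ids,
        "input": model.b_iso,
    }
    for label, dm, levels in disorder_models:
        series = combine_levels(dm, model, levels)
        if len(series) != model.n_atoms:
            raise ValueError(f"profile {label!r} misaligned with atom order")
        data[label] = series
    return pd.DataFrame(data)


def results_table(sweep_results: list) -> pd.DataFrame:
    """Lowest-R_free row per refinement variant, print-table layout.

    Columns: refinement label, DEN on/off marker, disorder model,
    R_work/R_free, WX, TX and the pTLS fraction ('-' where inapplicable).
    Formatting is deterministic for identical inputs.
    """
    if not sweep_results:
        raise ValueError("no results")
    rows = []
    for r in sweep_results:
        is_ptls = r.variant.lower().startswith("ptls")
        ptls_col = r.variant.split("=", 1)[1] if (is_ptls and "=" in r.variant) else "-"
        rows.append(
            {
                "refinement": "ER",
                "disorder_model": r.variant,
                "r_work": round(r.best_r_work, 4),
                "r_free": round(r.best_r_free, 4),
                "wx": r.best_wx,
                "tx": r.best_tx,
                "ptls": ptls_col if is_ptls else "-",
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["r_free", "disorder_model"], kind="stable").reset_index(drop=True)


def plot_profiles(profiles: pd.DataFrame, path: str, ylabel: str = "B factor (A$^2$)") -> None:
    """Render a profile table (as from :func:`profile_report`) to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    x = np.arange(len(profiles))
    for col in profiles.columns:
        if col == "atom_id":
            continue
        ax.plot(x, profiles[col], label=col, lw=1.2)
    ax.set_xlabel("atom (model order)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
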