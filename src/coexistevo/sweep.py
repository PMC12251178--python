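"""Parameter sweeps over (mutation rate, mean effect, DFE shape).

For every grid cell a batch of Wright-Fisher replicates is run and each
replicate is scored against the experimental marker pattern (the
low-abundance strain loses one neutral marker, the resident strain keeps
both, both strains coexist). The fraction of compatible replicates is the
heatmap quantity; a two-sided Fisher exact test compares the simulated
compatible/incompatible split with the experimental one (8 of 8 co-colonized
mice showing the pattern), and cells whose split is *not* significantly
different from the experiment are starred.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulator import (
    DEFAULT_EXTINCTION_THRESHOLD,
    DEFAULT_LOSS_THRESHOLD,
    DFEParams,
    SimParams,
    classify_outcome,
    run_replicate,
)

__all__ = [
    "GridSpec",
    "SweepCell",
    "fisher_exact_2x2",
    "run_grid",
    "export_heatmap",
    "read_heatmap",
]

DEFAULT_ALPHA = 0.05

#: canonical DFE shapes explored: fixed effect plus gamma shapes 100, 10, 1
DEFAULT_SHAPES: tuple[object, ...] = ("fixed", 100.0, 10.0, 1.0)


@dataclass(frozen=True)
class GridSpec:
    """Sweep grid: log-spaced u and mean-s values crossed with DFE shapes.

    Defaults bound desk runtime (5 x 4 x 4 cells, 10 replicates each); the
    full experimental ranges are u in [1e-8, 1e-4] and s in [1e-4, 1e-1].
    """

    u_values: tuple[float, ...] = tuple(np.logspace(-8, -4, 5))
    s_values: tuple[float, ...] = tuple(np.logspace(-4, -1, 4))
    dfe_shapes: tuple[object, ...] = DEFAULT_SHAPES
    replicates: int = 10
    n_total: int = 10**6
    generations: int = 1600
    initial_fractions: tuple[float, float, float, float] = (0.05, 0.05, 0.45, 0.45)
    record_every: int = 1600
    loss_threshold: float = DEFAULT_LOSS_THRESHOLD
    extinction_threshold: float = DEFAULT_EXTINCTION_THRESHOLD

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(u < 0 for u in self.u_values):
            raise ValueError("u values must be non-negative")
        if any(s <= 0 for s in self.s_values):
            raise ValueError("s values must be positive")

    def dfe_for(self, shape: object, mean_s: float) -> DFEParams:
        if shape == "fixed":
            return DFEParams(kind="fixed", mean_s=mean_s)
        return DFEParams(kind="gamma", mean_s=mean_s, shape=float(shape))


@dataclass(frozen=True)
class SweepCell:
    """Outcome summary of one (u, mean_s, shape) grid cell."""

    u: float
    mean_s: float
    shape: object
    n_compatible: int
    replicates: int
    fisher_p: float
    alpha: float = DEFAULT_ALPHA

    @property
    def compatibility_fraction(self) -> float:
        return self.n_compatible / self.replicates

    @property
    def starred(self) -> bool:
        """Starred = simulated split not significantly different from the data."""
        return self.fisher_p > self.alpha


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    The two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's.
    An all-zero table returns 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def run_grid(
    grid: GridSpec,
    experimental: tuple[int, int] = (8, 8),
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> list[SweepCell]:
    """Run all grid cells; deterministic given ``seed``.

    ``experimental`` is (n_compatible_mice, n_mice). Replicate r of cell c
    uses seed ``seed + c * replicates + r`` so every replicate across the
    grid has its own stream.
    """
    exp_c, exp_n = experimental
    if not (0 <= exp_c <= exp_n) or exp_n < 1:
        raise ValueError("experimental counts invalid")
    cells: list[SweepCell] = []
    cell_index = 0
    for shape in grid.dfe_shapes:
        for u in grid.u_values:
            for mean_s in grid.s_values:
                n_comp = 0
                for r in range(grid.replicates):
                    params = SimParams(
                        n_total=grid.n_total,
                        generations=grid.generations,
                        u=u,
                        dfe=grid.dfe_for(shape, mean_s),
                        initial_fractions=grid.initial_fractions,
                        seed=seed + cell_index * grid.replicates + r,
                        record_every=grid.record_every,
                    )
                    outcome = classify_outcome(
                        run_replicate(params),
                        loss_threshold=grid.loss_threshold,
                        extinction_threshold=grid.extinction_threshold,
                    )
                    n_comp += outcome.compatible
                p = fisher_exact_2x2(
                    exp_c, exp_n - exp_c, n_comp, grid.replicates - n_comp
                )
                cells.append(
                    SweepCell(
                        u=u,
                        mean_s=mean_s,
                        shape=shape,
                        n_compatible=n_comp,
                        replicates=grid.replicates,
                        fisher_p=p,
                        alpha=alpha,
                    )
                )
                cell_index += 1
    return cells


def _shape_sort_key(shape: object) -> float:
    return float("inf") if shape == "fixed" else float(shape)


def cells_to_frame(cells: Sequence[SweepCell]) -> pd.DataFrame:
    """Long-format table sorted by (shape, u, mean_s)."""
    if not cells:
        raise ValueError("no sweep cells to export")
    df = pd.DataFrame(
        {
            "u": [c.u for c in cells],
            "mean_s": [c.mean_s for c in cells],
            "shape": [str(c.shape) for c in cells],
            "n_compatible": [c.n_compatible for c in cells],
            "replicates": [c.replicates for c in cells],
            "compatibility_fraction": [c.compatibility_fraction for c in cells],
            "fisher_p": [c.fisher_p for c in cells],
            "starred": [c.starred for c in cells],
        }
    )
    df["_shape_key"] = [
        _shape_sort_key(s if s != "fixed" else "fixed") for s in df["shape"]
    ]
    df = df.sort_values(["_shape_key", "u", "mean_s"], kind="stable")
    return df.drop(columns="_shape_key").reset_index(drop=True)


def export_heatmap(
    cells: Sequence[SweepCell], path, figure_path: str | None = None
) -> pd.DataFrame:
    """Write the sweep table as TSV; optionally render heatmap panels.

    The figure (one panel per DFE shape, compatibility fraction over the
    u x mean_s grid, starred cells marked) is cosmetic and not part of the
    numeric contract.
    """
    df = cells_to_frame(cells)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    if figure_path is not None:
        _render_heatmap(df, figure_path)
    return df


def read_heatmap(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _render_heatmap(df: pd.DataFrame, figure_path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shapes = list(dict.fromkeys(df["shape"]))
    fig, axes = plt.subplots(1, len(shapes), figsize=(4 * len(shapes), 3.5), squeeze=False)
    for ax, shape in zip(axes[0], shapes):
        sub = df[df["shape"] == shape]
        pivot = sub.pivot_table(
            index="u", columns="mean_s", values="compatibility_fraction"
        )
        im = ax.imshow(pivot.values, origin="lower", vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(len(pivot.columns)))
        ax.set_xticklabels([f"{v:.0e}" for v in pivot.columns], rotation=45)
        ax.set_yticks(range(len(pivot.index)))
        ax.set_yticklabels([f"{v:.0e}" for v in pivot.index])
        ax.set_xlabel("mean s")
        ax.set_ylabel("u")
        ax.set_title(f"DFE shape = {shape}")
        starred = sub[sub["starred"]]
        for _, row in starred.iterrows():
            yi = list(pivot.index).index(row["u"])
            xi = list(pivot.columns).index(row["mean_s"])
            ax.plot(xi, yi, "k*", markersize=10)
        fig.colorbar(im, ax=ax, label="compatible fraction")
    fig.tight_layout()
    fig.savefig(figure_path, dpi=150)
    plt.close(fig)
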