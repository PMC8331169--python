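"""Online Kohonen self-organizing map on a hexagonal grid.

Units live on a hexagonal lattice (odd rows offset by half a unit,
vertical spacing √3/2) and are numbered 1-based in row-major order, so
the unit labels match the conventional "SOM1..SOM12" naming of a 6×2 map.
Training is the classic online algorithm: for each presented gene profile
the best-matching unit (BMU) is the nearest codebook vector (ties → lowest
index), and every unit within the current neighborhood radius of the BMU
moves toward the profile by the current learning rate.  Both the learning
rate and the radius decay linearly over epochs; the radius starts at 2/3
of the grid diagonal and ends at 0, so late epochs update only the BMU.
The default neighborhood is a hard bubble (h = 1 inside the radius);
a Gaussian mode is available.  After training, assignments are recomputed
exactly as nearest-codebook, which is the invariant all summaries rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SomFit", "SomSummary", "som_train", "som_summarize", "select_som_clusters", "hex_coordinates"]


def hex_coordinates(rows: int, cols: int) -> np.ndarray:
    """Planar coordinates of a rows × cols hexagonal grid, row-major."""
    coords = np.empty((rows * cols, 2))
    for r in range(rows):
        for c in range(cols):
            coords[r * cols + c] = (c + 0.5 * (r % 2), r * np.sqrt(3) / 2.0)
    return coords


@dataclass
class SomFit:
    grid_rows: int
    grid_cols: int
    codebook: np.ndarray                 # units × dims
    assignment: pd.Series                # gene -> unit index (1-based row-major)
    distance_to_bmu: pd.Series           # per-gene Euclidean distance
    column_ids: list[str]
    params: dict = field(default_factory=dict)
    quantization_trace: list[float] = field(default_factory=list)

    topology: str = "hexagonal"

    @property
    def n_units(self) -> int:
        return self.grid_rows * self.grid_cols

    def unit_members(self, unit: int) -> list[str]:
        if not 1 <= unit <= self.n_units:
            raise ValueError(f"unknown unit id {unit}; valid: 1..{self.n_units}")
        return list(self.assignment.index[self.assignment == unit])


@dataclass
class SomSummary:
    """Per-unit mean scaled expression by tissue class, plus member counts."""

    means: pd.DataFrame       # units × tissue classes (NaN for empty units)
    gene_counts: pd.Series    # per unit


def _bmu(x: np.ndarray, codebook: np.ndarray) -> tuple[int, float]:
    d2 = np.sum((codebook - x) ** 2, axis=1)
    i = int(np.argmin(d2))  # argmin returns the lowest index on ties
    return i, float(np.sqrt(d2[i]))


def som_train(
    sm,
    rows: int,
    cols: int,
    epochs: int = 100,
    alpha: tuple[float, float] = (0.05, 0.01),
    seed: int = 0,
    neighborhood: str = "bubble",
) -> SomFit:
    """Train a rows × cols hexagonal SOM on the rows of a ScaledMatrix.

    The codebook is initialized from ``rows*cols`` distinct gene profiles
    sampled with the given seed; presentation order is reshuffled each
    epoch.  The same seed and input produce a bit-identical fit.
    """
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be positive")
    x = sm.values.to_numpy(dtype=float)
    genes = list(sm.values.index)
    n_units = rows * cols
    if n_units > len(genes):
        raise ValueError(
            f"{n_units} units but only {len(genes)} genes; use a smaller grid"
        )
    if neighborhood not in ("bubble", "gaussian"):
        raise ValueError("neighborhood must be 'bubble' or 'gaussian'")

    rng = np.random.default_rng(seed)
    init_idx = rng.choice(len(genes), size=n_units, replace=False)
    codebook = x[init_idx].copy()

    coords = hex_coordinates(rows, cols)
    diag = float(
        np.sqrt(
            (coords[:, 0].max() - coords[:, 0].min()) ** 2
            + (coords[:, 1].max() - coords[:, 1].min()) ** 2
        )
    )
    radius0 = (2.0 / 3.0) * diag
    a0, a1 = alpha
    denom = max(epochs - 1, 1)

    trace = []
    for epoch in range(epochs):
        frac = epoch / denom
        a = a0 + (a1 - a0) * frac
        radius = radius0 * (1.0 - frac)
        order = rng.permutation(len(genes))
        qerr = 0.0
        for i in order:
            bmu, dist = _bmu(x[i], codebook)
            qerr += dist
            unit_d = np.linalg.norm(coords - coords[bmu], axis=1)
            if neighborhood == "bubble":
                h = (unit_d <= radius).astype(float)
            else:
                sigma = max(radius, 1e-9)
                h = np.exp(-(unit_d ** 2) / (2.0 * sigma ** 2))
                h[unit_d > 3.0 * sigma] = 0.0
                h[bmu] = 1.0
            upd = h > 0
            codebook[upd] += a * h[upd, np.newaxis] * (x[i] - codebook[upd])
        trace.append(qerr / len(genes))

    # final assignment: exact nearest codebook, ties -> lowest unit index
    assign = np.empty(len(genes), dtype=int)
    dists = np.empty(len(genes))
    for i in range(len(genes)):
        bmu, dist = _bmu(x[i], codebook)
        assign[i] = bmu + 1
        dists[i] = dist

    return SomFit(
        grid_rows=rows,
        grid_cols=cols,
        codebook=codebook,
        assignment=pd.Series(assign, index=genes, name="unit"),
        distance_to_bmu=pd.Series(dists, index=genes, name="distance_to_bmu"),
        column_ids=list(sm.values.columns),
        params={
            "epochs": epochs,
            "alpha_start": a0,
            "alpha_end": a1,
            "radius_start": radius0,
            "radius_end": 0.0,
            "seed": seed,
            "neighborhood": neighborhood,
        },
        quantization_trace=trace,
    )


def som_summarize(fit: SomFit, sm, meta=None) -> SomSummary:
    """Mean scaled expression of each unit's members per tissue class.

    When the ScaledMatrix columns are tissue-class means, classes are the
    columns themselves; otherwise per-sample columns are grouped by the
    tissue classes in ``meta`` (or the matrix's own class labels).
    Empty units are reported with count 0 and NaN means.
    """
    shared = sm.values.index.intersection(fit.assignment.index)
    if len(shared) != len(fit.assignment):
        raise ValueError("fit and matrix must share gene ids")
    vals = sm.values.loc[fit.assignment.index]

    classes = None
    if meta is not None:
        classes = meta["tissue_class"].reindex(vals.columns)
    elif sm.tissue_classes is not None:
        classes = sm.tissue_classes.reindex(vals.columns)
    if classes is not None and not classes.isna().any():
        order = list(dict.fromkeys(classes))
        vals = vals.T.groupby(classes.values).mean().T[order]

    units = pd.RangeIndex(1, fit.n_units + 1, name="unit")
    means = vals.groupby(fit.assignment).mean().reindex(units)
    counts = fit.assignment.value_counts().reindex(units, fill_value=0).sort_index()
    return SomSummary(means=means, gene_counts=counts.rename("n_genes"))


def select_som_clusters(fit: SomFit, units) -> list[str]:
    """Genes belonging to the requested units, in the fit's gene order."""
    units = set(units)
    for u in units:
        if not 1 <= u <= fit.n_units:
            raise ValueError(f"unknown unit id {u}; valid: 1..{fit.n_units}")
    mask = fit.assignment.isin(units)
    return list(fit.assignment.index[mask])
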