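"""Self-organizing map over standardized temporal expression profiles.

A small rectangular Kohonen map (default 2 x 3 = six units) is trained
online on per-gene z-scored time profiles: best-matching unit by
Euclidean distance, Gaussian neighborhood on the grid, learning rate and
radius decaying linearly over epochs.  Each gene is then assigned to its
best-matching unit, giving the six temporal expression bins used to
color and partition the co-expression network.

The map is deterministic given the seed: codebook initialization samples
distinct input vectors and the per-epoch presentation order is drawn
from the same generator, so the processing order is part of the seed
contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "SomModel",
    "SomAssignment",
    "standardize_profiles",
    "train_som",
    "assign_som_bins",
    "bin_purity",
]


@dataclass
class SomModel:
    rows: int
    cols: int
    codebook: np.ndarray  # units x time points, unit u at (u // cols, u % cols)
    training_params: dict = field(default_factory=dict)
    quantization_error_trace: list[float] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def unit_coords(self, unit: int) -> tuple[int, int]:
        return unit // self.cols, unit % self.cols

    @property
    def initial_quantization_error(self) -> float:
        return self.quantization_error_trace[0]

    @property
    def final_quantization_error(self) -> float:
        return self.quantization_error_trace[-1]


@dataclass
class SomAssignment:
    units: pd.Series  # gene -> unit index
    counts: np.ndarray  # members per unit
    mean_profiles: np.ndarray  # units x time points (NaN for empty units)
    sd_profiles: np.ndarray

    def unit_of(self) -> dict[str, int]:
        return {g: int(u) for g, u in self.units.items()}

    def to_frame(self, model: SomModel) -> pd.DataFrame:
        rows = []
        for gene, unit in self.units.items():
            r, c = model.unit_coords(int(unit))
            rows.append({"gene": gene, "unit": int(unit), "unit_row": r, "unit_col": c})
        return pd.DataFrame(rows)


def standardize_profiles(matrix: ExpressionMatrix, design: SampleDesign) -> pd.DataFrame:
    """Per-gene replicate-mean profiles, centered and scaled to unit SD.

    Zero-variance profiles map to the zero vector (with a warning) so
    that pattern-free genes carry no direction.
    """
    profiles = design.replicate_means(matrix)
    centered = profiles.sub(profiles.mean(axis=1), axis=0)
    sd = profiles.std(axis=1, ddof=0)
    flat = sd <= 1e-12
    if flat.any():
        logger.warning("%d zero-variance profile(s) standardized to zero", int(flat.sum()))
    sd_safe = sd.mask(flat, 1.0)
    z = centered.div(sd_safe, axis=0)
    z[flat] = 0.0
    return z


def _arrange_on_grid(seeds: np.ndarray, grid_sq: np.ndarray) -> np.ndarray:
    """Order initial codebook vectors so similar seeds sit on adjacent units.

    A topologically frustrated seeding (similar clusters on distant units)
    makes neighborhood training collapse clusters onto shared units.  For
    small maps the best permutation is found exactly by minimizing the sum
    of seed distances over grid-adjacent unit pairs; larger maps keep the
    sampling order.
    """
    n_units = len(seeds)
    if n_units > 8:
        return seeds
    from itertools import permutations

    adjacent = [
        (a, b)
        for a in range(n_units)
        for b in range(a + 1, n_units)
        if grid_sq[a, b] == 1.0
    ]
    dist = ((seeds[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    best_perm, best_cost = None, np.inf
    for perm in permutations(range(n_units)):
        cost = sum(dist[perm[a], perm[b]] for a, b in adjacent)
        if cost < best_cost:
            best_cost, best_perm = cost, perm
    return seeds[list(best_perm)].copy()


def _quantization_error(x: np.ndarray, codebook: np.ndarray) -> float:
    d = np.linalg.norm(x[:, None, :] - codebook[None, :, :], axis=2)
    return float(d.min(axis=1).mean())


def train_som(
    z_profiles: pd.DataFrame,
    rows: int = 2,
    cols: int = 3,
    epochs: int = 200,
    seed: int = 0,
    lr_initial: float = 0.5,
    lr_final: float = 0.01,
    radius_initial: float | None = None,
    radius_final: float = 0.25,
) -> SomModel:
    """Classic online Kohonen training on z-profiles.

    One epoch presents every input once in a seeded random order; the
    learning rate and Gaussian neighborhood radius decay linearly from
    their initial to final values over the epochs.
    """
    x = np.asarray(z_profiles.values, dtype=float)
    n, dim = x.shape
    n_units = rows * cols
    if n < n_units:
        raise ValueError(f"need >= {n_units} genes to train a {rows}x{cols} map, have {n}")
    if radius_initial is None:
        radius_initial = max(rows, cols) / 2.0

    rng = np.random.default_rng(seed)
    # initialize from input vectors: seeded first pick, then greedy
    # farthest-point sampling — spreads the seeds across clusters and
    # avoids dead units when clusters are as numerous as units
    chosen = [int(rng.integers(n))]
    min_dist = ((x - x[chosen[0]]) ** 2).sum(axis=1)
    while len(chosen) < n_units:
        nxt = int(np.argmax(min_dist))
        chosen.append(nxt)
        min_dist = np.minimum(min_dist, ((x - x[nxt]) ** 2).sum(axis=1))
    codebook = x[chosen].copy()

    coords = np.array([(u // cols, u % cols) for u in range(n_units)], dtype=float)
    grid_sq = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    codebook = _arrange_on_grid(codebook, grid_sq)

    trace = [_quantization_error(x, codebook)]
    denom = max(epochs - 1, 1)
    for epoch in range(epochs):
        frac = epoch / denom
        lr = lr_initial + (lr_final - lr_initial) * frac
        radius = radius_initial + (radius_final - radius_initial) * frac
        gauss_denom = 2.0 * radius * radius
        for i in rng.permutation(n):
            xi = x[i]
            dists = ((codebook - xi) ** 2).sum(axis=1)
            bmu = int(np.argmin(dists))  # argmin takes the lowest index on ties
            h = np.exp(-grid_sq[bmu] / gauss_denom)
            codebook += (lr * h)[:, None] * (xi - codebook)
        trace.append(_quantization_error(x, codebook))

    return SomModel(
        rows=rows,
        cols=cols,
        codebook=codebook,
        training_params={
            "epochs": epochs,
            "seed": seed,
            "lr_initial": lr_initial,
            "lr_final": lr_final,
            "radius_initial": radius_initial,
            "radius_final": radius_final,
        },
        quantization_error_trace=trace,
    )


def assign_som_bins(model: SomModel, z_profiles: pd.DataFrame) -> SomAssignment:
    """Map each gene to its best-matching unit (ties to the lowest index)."""
    x = np.asarray(z_profiles.values, dtype=float)
    if x.shape[1] != model.codebook.shape[1]:
        raise ValueError(
            f"profile dimension {x.shape[1]} != codebook dimension {model.codebook.shape[1]}"
        )
    d = np.linalg.norm(x[:, None, :] - model.codebook[None, :, :], axis=2)
    units = d.argmin(axis=1)

    counts = np.bincount(units, minlength=model.n_units)
    mean_profiles = np.full((model.n_units, x.shape[1]), np.nan)
    sd_profiles = np.full((model.n_units, x.shape[1]), np.nan)
    for u in range(model.n_units):
        members = x[units == u]
        if len(members):
            mean_profiles[u] = members.mean(axis=0)
            sd_profiles[u] = members.std(axis=0, ddof=0)
    return SomAssignment(
        units=pd.Series(units, index=z_profiles.index, dtype=int),
        counts=counts,
        mean_profiles=mean_profiles,
        sd_profiles=sd_profiles,
    )


def bin_purity(units: pd.Series, gene_class: dict[str, str]) -> float:
    """Purity of SOM bins against planted classes after majority relabeling.

    Each bin is relabeled to its majority class; purity is the fraction of
    genes whose class matches their bin's majority label.
    """
    frame = pd.DataFrame(
        {"unit": units, "cls": [gene_class[g] for g in units.index]}
    )
    best = frame.groupby("unit")["cls"].agg(lambda s: s.value_counts().max()).sum()
    return float(best) / len(frame)
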