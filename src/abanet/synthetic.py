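"""Synthetic ABA-incubation expression time series with planted structure.

Emulates the study design the pipeline targets: five time points
(0, 2, 12, 24, 72 h of incubation in abscisic acid) with three replicates
each, log2 intensities floored near 4.  Four responsive gene classes are
planted — early-response genes step up or down sharply between 0 and 2 h
and then hold ("ER_up"/"ER_down"), late-response genes ramp gradually in
log-time ("LR_up"/"LR_down") — over a flat background.  Named gene sets
(regulon-like, LEA-like, TF-like) are nested inside the responsive blocks
so that DEG recovery, network modularity, SOM binning and hub enrichment
can all be scored against a known truth object.

Noise model: each gene carries a small profile jitter shared across
replicates (gene identity) plus i.i.d. per-observation replicate noise;
flooring is applied after noise, mirroring the post-normalization
transform order of the real pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, SampleDesign, write_gmt

__all__ = [
    "CLASSES",
    "RESPONSIVE_CLASSES",
    "SyntheticConfig",
    "SyntheticTruth",
    "class_templates",
    "generate_dataset",
    "write_truth",
    "read_truth",
]

CLASSES = ("ER_up", "ER_down", "LR_up", "LR_down", "flat")
RESPONSIVE_CLASSES = CLASSES[:4]

_DEFAULT_FRACTIONS = {
    "ER_up": 0.25,
    "ER_down": 0.15,
    "LR_up": 0.15,
    "LR_down": 0.10,
    "flat": 0.35,
}

# planted set name -> (host class, fraction of that class recruited)
_DEFAULT_SETS = {
    "regulon": ("ER_up", 0.4),
    "lea": ("ER_up", 0.25),
    "tf": ("LR_up", 0.3),
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 600
    time_points_h: tuple[float, ...] = (0.0, 2.0, 12.0, 24.0, 72.0)
    n_replicates: int = 3
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONS)
    )
    amplitude_log2: float = 4.0
    noise_sd_log2: float = 0.25
    shape_jitter_sd: float = 0.02
    baseline_log2: float = 7.0
    floor_value: float = 4.0
    seed: int = 0
    planted_sets: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: dict(_DEFAULT_SETS)
    )

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        t = np.asarray(self.time_points_h, dtype=float)
        if t[0] != 0.0:
            raise ValueError("first time point must be 0 (control)")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time points must be strictly increasing")
        unknown = set(self.class_fractions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in class_fractions: {sorted(unknown)}")
        fractions = [self.class_fractions.get(c, 0.0) for c in CLASSES]
        if any(f < 0 for f in fractions):
            raise ValueError("class fractions must be non-negative")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {sum(fractions)}, not 1")
        if self.amplitude_log2 < 0:
            raise ValueError("amplitude_log2 must be >= 0")
        if self.noise_sd_log2 < 0 or self.shape_jitter_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for name, (cls, frac) in self.planted_sets.items():
            if cls not in CLASSES:
                raise ValueError(f"planted set {name!r}: unknown class {cls!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"planted set {name!r}: fraction {frac} outside [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth for recovery scoring."""

    gene_class: dict[str, str]
    set_membership: dict[str, list[str]]
    template_profiles: dict[str, np.ndarray]

    def genes_of_class(self, cls: str) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == cls]

    @property
    def responsive_genes(self) -> list[str]:
        return [g for g, c in self.gene_class.items() if c != "flat"]

    @property
    def flat_genes(self) -> list[str]:
        return self.genes_of_class("flat")


def class_templates(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Per-class log2 offsets from baseline over the time grid.

    ER classes are a step completed by the first treated time point; LR
    classes ramp as amplitude * log(1+t)/log(1+t_max).
    """
    t = np.asarray(config.time_points_h, dtype=float)
    step = np.where(t > 0, config.amplitude_log2, 0.0)
    ramp = config.amplitude_log2 * np.log1p(t) / np.log1p(t[-1])
    return {
        "ER_up": step,
        "ER_down": -step,
        "LR_up": ramp,
        "LR_down": -ramp,
        "flat": np.zeros_like(t),
    }


def _class_counts(config: SyntheticConfig) -> dict[str, int]:
    # largest-remainder apportionment, ties broken by class order
    raw = {c: config.class_fractions.get(c, 0.0) * config.n_genes for c in CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = config.n_genes - sum(counts.values())
    order = sorted(CLASSES, key=lambda c: (-(raw[c] - counts[c]), CLASSES.index(c)))
    for c in order[:short]:
        counts[c] += 1
    return counts


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SampleDesign, SyntheticTruth]:
    """Generate a floored log2 expression matrix, its design, and the truth.

    Fully reproducible from ``config.seed``: the RNG draw order is fixed as
    (1) profile jitter, (2) replicate noise, (3) planted-set sampling in
    sorted set-name order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    templates = class_templates(config)
    counts = _class_counts(config)

    width = max(5, len(str(config.n_genes)))
    gene_ids: list[str] = []
    gene_class: dict[str, str] = {}
    i = 1
    for cls in CLASSES:
        for _ in range(counts[cls]):
            gid = f"G{i:0{width}d}"
            gene_ids.append(gid)
            gene_class[gid] = cls
            i += 1

    t = np.asarray(config.time_points_h, dtype=float)
    n_t, n_r = len(t), config.n_replicates
    class_idx = np.array([CLASSES.index(gene_class[g]) for g in gene_ids])
    template_stack = np.stack([templates[c] for c in CLASSES])  # classes x times

    jitter = rng.normal(0.0, config.shape_jitter_sd, size=(config.n_genes, n_t))
    noise = rng.normal(0.0, config.noise_sd_log2, size=(config.n_genes, n_t, n_r))
    profiles = config.baseline_log2 + template_stack[class_idx] + jitter
    values = profiles[:, :, None] + noise
    values = np.maximum(values, config.floor_value)

    sample_ids = [f"t{tp:g}h_r{r + 1}" for tp in t for r in range(n_r)]
    matrix = ExpressionMatrix(
        pd.DataFrame(
            values.reshape(config.n_genes, n_t * n_r),
            index=gene_ids,
            columns=sample_ids,
        )
    )
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "time_h": np.repeat(t, n_r),
                "replicate": np.tile(np.arange(1, n_r + 1), n_t),
            }
        )
    )

    set_membership: dict[str, list[str]] = {}
    for name in sorted(config.planted_sets):
        cls, frac = config.planted_sets[name]
        pool = [g for g in gene_ids if gene_class[g] == cls]
        k = int(round(frac * len(pool)))
        if k > len(pool):
            raise ValueError(f"planted set {name!r} exceeds class {cls!r} size")
        chosen = rng.choice(len(pool), size=k, replace=False)
        set_membership[name] = sorted(pool[j] for j in chosen)

    truth = SyntheticTruth(
        gene_class=gene_class,
        set_membership=set_membership,
        template_profiles={c: templates[c].copy() for c in CLASSES},
    )
    return matrix, design, truth


def write_truth(truth: SyntheticTruth, class_path: str | Path, gmt_path: str | Path) -> None:
    """Write gene classes as two-column TSV and planted sets as GMT."""
    frame = pd.DataFrame(
        sorted(truth.gene_class.items()), columns=["gene", "class"]
    )
    frame.to_csv(class_path, sep="\t", index=False)
    sets = [
        GeneSet(name=name, description="planted", members=list(members))
        for name, members in truth.set_membership.items()
    ]
    write_gmt(sets, gmt_path)


def read_truth(class_path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(class_path, sep="\t")
    return dict(zip(frame["gene"].astype(str), frame["class"].astype(str)))
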