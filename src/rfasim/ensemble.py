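"""Parameter-space sampling and contour-boxplot summarization.

Treatment simulations carry uncertainty from hard-to-measure tissue
parameters and from needle placement. The sampler varies up to two
parameters simultaneously — tissue perfusion, tumor perfusion, specific
heat capacity, thermal conductivity, or the needle geometry itself — with
it_p1 and it_p2 iterations each, producing it_p1 * it_p2 distinct
configurations that are simulated independently.

The resulting lesion ensemble is condensed with a contour-boxplot variant:
each member's band depth is the fraction of member pairs whose intersection
and union sandwich it; the deepest member is the median lesion, low-depth
members are outliers, and intersection/union bands summarize the central
half and the full non-outlier envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Literal, Sequence

import numpy as np

from .bioheat import Protocol, SolverOptions, run_protocol
from .cell_death import CellDeathParams
from .errors import EnsembleError
from .needle import NeedleGeometry, perturb_needle
from .phantom import Mask, Phantom

__all__ = [
    "ParameterSpec",
    "EnsembleResult",
    "build_configs",
    "apply_parameter",
    "run_ensemble",
    "band_depth",
    "contour_boxplot",
]

PARAMETER_NAMES = (
    "tissue_perfusion",
    "tumor_perfusion",
    "heat_capacity",
    "thermal_conductivity",
    "needle",
)


@dataclass(frozen=True)
class ParameterSpec:
    """One varied parameter: range, iteration count, and sampling mode.

    For scalar parameters ``low``/``high`` bound the range in the
    parameter's own units; ``sampling`` is 'linear' (both endpoints
    included; a single iteration uses the midpoint) or 'random' (uniform in
    the range, seeded). For ``name='needle'`` the value list is the variant
    index 0..iterations-1 and ``r`` is the perturbation ball radius in mm.
    """

    name: str
    low: float | None = None
    high: float | None = None
    iterations: int = 1
    sampling: Literal["linear", "random"] = "linear"
    r: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in PARAMETER_NAMES:
            raise EnsembleError(f"unknown parameter {self.name!r}; expected one of {PARAMETER_NAMES}")
        if self.iterations < 1:
            raise EnsembleError("iterations must be >= 1")
        if self.name == "needle":
            if self.r is None or self.r < 0:
                raise EnsembleError("needle variation requires a perturbation radius r >= 0")
        else:
            if self.low is None or self.high is None:
                raise EnsembleError(f"parameter {self.name!r} requires a (low, high) range")
            if self.low > self.high:
                raise EnsembleError("parameter range must satisfy low <= high")
        if self.sampling not in ("linear", "random"):
            raise EnsembleError(f"unknown sampling mode {self.sampling!r}")

    def values(self) -> np.ndarray:
        """Per-parameter value list (variant indices for the needle)."""
        if self.name == "needle":
            return np.arange(self.iterations)
        if self.sampling == "linear":
            if self.iterations == 1:
                return np.array([(self.low + self.high) / 2.0])
            return np.linspace(self.low, self.high, self.iterations)
        rng = np.random.default_rng(self.seed)
        return rng.uniform(self.low, self.high, size=self.iterations)


@dataclass(frozen=True, eq=False)
class EnsembleResult:
    """Lesion ensemble with its contour-boxplot summary.

    band50 and envelope are (inner, outer) = (intersection, union) mask
    pairs over the top-depth half and over all non-outlier members.
    """

    configs: list[dict]
    lesions: list[Mask]
    depths: np.ndarray | None = None
    median_index: int | None = None
    band50: tuple[Mask, Mask] | None = None
    envelope: tuple[Mask, Mask] | None = None
    outlier_indices: list[int] | None = None


def build_configs(p1: ParameterSpec, p2: ParameterSpec | None = None) -> list[dict]:
    """Cartesian product of the per-parameter value lists.

    Two specs with it_p1 and it_p2 iterations yield exactly it_p1 * it_p2
    configurations, ordered with p2 varying fastest.
    """
    if p2 is not None and p2.name == p1.name:
        raise EnsembleError(f"parameter {p1.name!r} named twice")
    v1 = p1.values()
    if p2 is None:
        return [{p1.name: v} for v in v1]
    v2 = p2.values()
    return [{p1.name: a, p2.name: b} for a in v1 for b in v2]


def apply_parameter(phantom: Phantom, name: str, value: float) -> Phantom:
    """Phantom with one scalar tissue parameter overridden.

    tissue_perfusion / tumor_perfusion set the perfusion field on healthy
    parenchyma / tumor voxels; heat_capacity and thermal_conductivity apply
    to all non-vessel ROI voxels (vessel voxels are Dirichlet heat sinks and
    never enter the solve).
    """
    p = phantom.properties
    roi = phantom.liver_roi.values
    healthy = roi & ~phantom.tumor.values & ~phantom.vessels.values
    non_vessel = roi & ~phantom.vessels.values
    if name == "tissue_perfusion":
        f = p.perfusion.copy()
        f[healthy] = value
        p = replace(p, perfusion=f)
    elif name == "tumor_perfusion":
        f = p.perfusion.copy()
        f[phantom.tumor.values] = value
        p = replace(p, perfusion=f)
    elif name == "heat_capacity":
        f = p.heat_capacity.copy()
        f[non_vessel] = value
        p = replace(p, heat_capacity=f)
    elif name == "thermal_conductivity":
        f = p.conductivity.copy()
        f[non_vessel] = value
        p = replace(p, conductivity=f)
    else:
        raise EnsembleError(f"unknown scalar parameter {name!r}")
    return phantom.with_properties(p)


def run_ensemble(
    phantom: Phantom,
    needle: NeedleGeometry,
    protocol: Protocol,
    configs: Sequence[dict],
    cell_params: CellDeathParams = CellDeathParams(),
    options: SolverOptions = SolverOptions(),
    needle_spec: ParameterSpec | None = None,
) -> EnsembleResult:
    """One full simulation per configuration; lesion order matches config order.

    Needle-variant indices in the configs are materialized once from
    ``needle_spec`` (perturbation radius r, iteration count, seed), so a
    fixed spec seed makes the whole ensemble bit-reproducible.
    """
    configs = list(configs)
    if not configs:
        raise EnsembleError("ensemble requires at least one configuration")
    variants: list[NeedleGeometry] | None = None
    if any("needle" in c for c in configs):
        if needle_spec is None or needle_spec.name != "needle":
            raise EnsembleError("configs vary the needle but no needle ParameterSpec was given")
        variants = perturb_needle(
            needle, needle_spec.r, n=needle_spec.iterations, seed=needle_spec.seed
        )
    lesions: list[Mask] = []
    for config in configs:
        ph = phantom
        nd = needle
        for name, value in config.items():
            if name == "needle":
                nd = variants[int(value)]
            else:
                ph = apply_parameter(ph, name, float(value))
        result = run_protocol(ph, nd, protocol, cell_params=cell_params, options=options)
        lesions.append(result.lesion)
    return EnsembleResult(configs=configs, lesions=lesions)


def band_depth(lesions: Sequence[Mask]) -> np.ndarray:
    """Contour band depth of each ensemble member.

    depth(c) = fraction of unordered pairs (i, j) with i != j != c such that

        lesion_i  intersect  lesion_j  is a subset of  lesion_c
        and lesion_c is a subset of lesion_i union lesion_j.

    The member under evaluation is excluded from the pairs (j = 2 subset
    size, the standard contour-band-depth convention).
    """
    n = len(lesions)
    if n < 3:
        raise EnsembleError(f"band depth requires >= 3 ensemble members, got {n}")
    masks = [m.values for m in lesions]
    depths = np.zeros(n)
    pairs = list(combinations(range(n), 2))
    inter = {}
    union = {}
    for i, j in pairs:
        inter[(i, j)] = masks[i] & masks[j]
        union[(i, j)] = masks[i] | masks[j]
    for c in range(n):
        good = 0
        total = 0
        for i, j in pairs:
            if c in (i, j):
                continue
            total += 1
            if np.all(inter[(i, j)] <= masks[c]) and np.all(masks[c] <= union[(i, j)]):
                good += 1
        depths[c] = good / total
    return depths


def contour_boxplot(
    lesions: Sequence[Mask],
    configs: Sequence[dict] | None = None,
    outlier_depth_threshold: float = 0.1,
) -> EnsembleResult:
    """Contour-boxplot summary: median lesion, 50% band, envelope, outliers.

    The median is the deepest member (ties broken toward the lowest index);
    members with depth below the threshold are outliers; band50 is the
    (intersection, union) of the deepest half of the non-outlier members and
    the envelope that of all non-outlier members.
    """
    lesions = list(lesions)
    depths = band_depth(lesions)
    n = len(lesions)
    outliers = [i for i in range(n) if depths[i] < outlier_depth_threshold]
    keep = [i for i in range(n) if depths[i] >= outlier_depth_threshold]
    if not keep:
        raise EnsembleError("degenerate ensemble: every member is an outlier")
    median_index = int(np.argmax(depths))  # argmax takes the lowest index on ties

    order = sorted(keep, key=lambda i: (-depths[i], i))
    half = order[: max(1, int(np.ceil(len(order) / 2)))]

    grid = lesions[0].grid

    def inter_union(indices: list[int]) -> tuple[Mask, Mask]:
        inner = np.ones(grid.shape, dtype=bool)
        outer = np.zeros(grid.shape, dtype=bool)
        for i in indices:
            inner &= lesions[i].values
            outer |= lesions[i].values
        return Mask(grid, inner), Mask(grid, outer)

    band50 = inter_union(half)
    envelope = inter_union(keep)
    return EnsembleResult(
        configs=list(configs) if configs is not None else [{} for _ in lesions],
        lesions=lesions,
        depths=depths,
        median_index=median_index,
        band50=band50,
        envelope=envelope,
        outlier_indices=outliers,
    )
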