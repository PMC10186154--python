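"""Synthetic counts generators with ground-truth labels.

Three designs are covered:

* time courses — genes measured on an equally spaced time grid with
  replicates.  Dynamic genes follow sine latents f(x) = a sin(x b + d) + c
  (b ~ U[pi/4, 2 pi], d ~ U[0, 2 pi]) or natural cubic splines through
  randomly drawn control points; non-dynamic genes are constant at the
  median of a dynamic gene's latent function.  Counts are NB with mean
  exp(f) and dispersion drawn from a low (U[0.01, 0.1]) or high (U[1, 3])
  regime.
* spatial patterns — locations on a jittered 2-D grid; patterned genes get
  a smooth Gaussian-bump latent surface, flat genes a constant, with
  optional spatially structured size confounding to exercise the
  normalization step.
* branching trajectories — two lineages sharing a trunk latent before a
  true branch point and diverging smoothly after it.

All draws come from a single seeded generator, so a design is bit-for-bit
reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .gp import CountsDataset

__all__ = [
    "SimulationDesign",
    "simulate_timecourse",
    "simulate_spatial",
    "simulate_branching",
    "ALPHA_RANGES",
    "SINE_B_RANGE",
    "SINE_D_RANGE",
    "AMPLITUDE_RANGE",
    "LEVEL_RANGES",
]

ALPHA_RANGES = {"low": (0.01, 0.1), "high": (1.0, 3.0)}
SINE_B_RANGE = (np.pi / 4.0, 2.0 * np.pi)
SINE_D_RANGE = (0.0, 2.0 * np.pi)
# amplitude a and baseline c ranges (natural-log scale of the count mean)
AMPLITUDE_RANGE = (0.5, 2.5)
LEVEL_RANGES = {"low": (0.5, 2.0), "high": (3.0, 6.0)}


@dataclass
class SimulationDesign:
    """Time-course design: sizes, regimes and the latent function family."""

    n_genes: int = 600
    fraction_dynamic: float = 0.5
    timepoints: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 1.0, 11))
    replicates: int = 2
    expression_level: str = "high"
    dispersion_level: str = "low"
    function_family: str = "mixed"  # sine | spline | mixed
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_dynamic <= 1.0:
            raise ValueError("fraction_dynamic must be in [0, 1]")
        if self.expression_level not in LEVEL_RANGES:
            raise ValueError("expression_level must be 'low' or 'high'")
        if self.dispersion_level not in ALPHA_RANGES:
            raise ValueError("dispersion_level must be 'low' or 'high'")
        if self.function_family not in ("sine", "spline", "mixed"):
            raise ValueError("function_family must be sine, spline or mixed")
        self.timepoints = np.asarray(self.timepoints, dtype=float)


def _nb_draw(rng, mu, alpha):
    if alpha <= 1e-12:
        return rng.poisson(mu)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu))


def _spline_latent(rng, x, c_range, a_range):
    """Natural cubic spline through two interior control points (C^2).

    The control points are drawn one per half of the domain; well-separated
    knots keep the cubic from oscillating far outside the knot values.
    """
    xi = np.array([rng.uniform(0.1, 0.45), rng.uniform(0.55, 0.9)])
    knots_x = np.concatenate([[x.min()], xi, [x.max()]])
    c = rng.uniform(*c_range)
    a = rng.uniform(*a_range)
    knots_y = c + a * rng.uniform(-1.0, 1.0, size=4)
    cs = CubicSpline(knots_x, knots_y, bc_type="natural")
    return cs(x), dict(c=c, a=a)


def simulate_timecourse(design: SimulationDesign):
    """Generate a counts time course plus a ground-truth table.

    Returns (CountsDataset, DataFrame); the truth table records per gene
    whether it is dynamic, the latent family, the drawn parameters
    (a, b, c, d for sines), the dispersion, and the latent values' median.
    """
    rng = np.random.default_rng(design.seed)
    grid = design.timepoints
    x = np.repeat(grid, design.replicates)
    n_dyn = int(round(design.fraction_dynamic * design.n_genes))
    a_lo, a_hi = AMPLITUDE_RANGE
    c_range = LEVEL_RANGES[design.expression_level]
    al_lo, al_hi = ALPHA_RANGES[design.dispersion_level]

    latents = np.zeros((design.n_genes, grid.size))
    rows = []
    dyn_medians: list[float] = []
    for g in range(n_dyn):
        if design.function_family == "mixed":
            family = "sine" if g % 2 == 0 else "spline"
        else:
            family = design.function_family
        if family == "sine":
            a = rng.uniform(a_lo, a_hi)
            b = rng.uniform(*SINE_B_RANGE)
            d = rng.uniform(*SINE_D_RANGE)
            c = rng.uniform(*c_range)
            f = a * np.sin(grid * b + d) + c
            params = dict(a=a, b=b, c=c, d=d)
        else:
            f, params = _spline_latent(rng, grid, c_range, (a_lo, a_hi))
            params.update(b=np.nan, d=np.nan)
        dynamic = bool(np.ptp(f) > 1e-9)  # a degenerate draw is reclassified
        latents[g] = f
        dyn_medians.append(float(np.median(f)))
        rows.append(dict(family=family, is_dynamic=dynamic, **params))
    for g in range(n_dyn, design.n_genes):
        med = dyn_medians[(g - n_dyn) % max(n_dyn, 1)] if n_dyn else float(
            np.mean(LEVEL_RANGES[design.expression_level]))
        latents[g] = med
        rows.append(dict(family="constant", is_dynamic=False,
                         a=np.nan, b=np.nan, c=med, d=np.nan))

    alphas = rng.uniform(al_lo, al_hi, size=design.n_genes)
    counts = np.zeros((design.n_genes, x.size), dtype=np.int64)
    for g in range(design.n_genes):
        mu = np.exp(np.repeat(latents[g], design.replicates))
        counts[g] = _nb_draw(rng, mu, alphas[g])

    truth = pd.DataFrame(rows)
    truth.insert(0, "gene", [f"gene_{i}" for i in range(design.n_genes)])
    truth["alpha"] = alphas
    truth["latent_median"] = np.median(latents, axis=1)
    ds = CountsDataset(counts=counts, coords=x,
                       gene_names=truth["gene"].tolist())
    return ds, truth


def simulate_spatial(
    n_genes: int,
    n_locations: int,
    pattern_fraction: float = 0.5,
    dispersion: str = "low",
    seed: int = 0,
    *,
    expression_level: str = "high",
    confounding: bool = False,
    confounding_strength: float = 1.5,
):
    """2-D spatial counts on a jittered grid with smooth patterned genes.

    Patterned genes get a Gaussian-bump latent surface
    f(x) = c + a exp(-||x - x0||^2 / (2 w^2)); flat genes are constant at c.
    With ``confounding`` on, every gene's mean is additionally multiplied
    by a smooth location size factor u_i, emulating spatially structured
    cell-size variation that the NB-regression normalization should absorb.
    """
    if n_locations < 25:
        raise ValueError("need at least 25 locations")
    if not 0.0 <= pattern_fraction <= 1.0:
        raise ValueError("pattern_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_locations)))
    gx, gy = np.meshgrid(np.linspace(0, 1, side), np.linspace(0, 1, side))
    coords = np.column_stack([gx.ravel(), gy.ravel()])[:n_locations]
    coords = coords + rng.uniform(-0.3, 0.3, coords.shape) / side

    n_pat = int(round(pattern_fraction * n_genes))
    c_range = LEVEL_RANGES[expression_level]
    al_lo, al_hi = ALPHA_RANGES[dispersion]
    a_lo, a_hi = AMPLITUDE_RANGE

    if confounding:
        x0 = rng.uniform(0.2, 0.8, size=2)
        w = rng.uniform(0.2, 0.4)
        bump = np.exp(-np.sum((coords - x0) ** 2, axis=1) / (2 * w**2))
        size_factor = np.exp(confounding_strength * (bump - bump.mean()))
    else:
        size_factor = np.ones(n_locations)

    counts = np.zeros((n_genes, n_locations), dtype=np.int64)
    rows = []
    alphas = rng.uniform(al_lo, al_hi, size=n_genes)
    for g in range(n_genes):
        c = rng.uniform(*c_range)
        if g < n_pat:
            a = rng.uniform(a_lo, a_hi)
            x0 = rng.uniform(0.2, 0.8, size=2)
            w = rng.uniform(0.15, 0.35)
            f = c + a * np.exp(-np.sum((coords - x0) ** 2, axis=1) / (2 * w**2))
            rows.append(dict(is_pattern=True, c=c, a=a, width=w))
        else:
            f = np.full(n_locations, c)
            rows.append(dict(is_pattern=False, c=c, a=np.nan, width=np.nan))
        counts[g] = _nb_draw(rng, size_factor * np.exp(f), alphas[g])

    truth = pd.DataFrame(rows)
    truth.insert(0, "gene", [f"gene_{i}" for i in range(n_genes)])
    truth["alpha"] = alphas
    ds = CountsDataset(counts=counts, coords=coords,
                       gene_names=truth["gene"].tolist())
    return ds, truth


def simulate_branching(
    n_cells: int,
    x_b_true: float = 0.5,
    effect_size: float = 3.0,
    alpha: float = 0.2,
    seed: int = 0,
    *,
    baseline: Optional[dict] = None,
):
    """One gene observed along two lineages that diverge at ``x_b_true``.

    Cells get pseudotimes U[0, 1] and a trunk/branch label; the trunk
    latent is a smooth sine, and after the branch point the branch latent
    smoothly departs by ``effect_size`` (the latent log-mean offset reached
    at pseudotime 1).  Returns (CountsDataset with lineage labels, truth dict).
    """
    if not 0.0 < x_b_true <= 1.0:
        raise ValueError("x_b_true must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    base = dict(a=1.5, b=5.0, c=3.0, d=0.5)
    base.update(baseline or {})
    x = rng.uniform(0.0, 1.0, size=n_cells)
    lineage = np.array(["trunk"] * n_cells, dtype=object)
    lineage[rng.permutation(n_cells)[: n_cells // 2]] = "branch"
    f = base["a"] * np.sin(x * base["b"] + base["d"]) + base["c"]
    g_lat = f.copy()
    if x_b_true < 1.0:
        post = np.clip(x - x_b_true, 0.0, None) / (1.0 - x_b_true)
        g_lat = f + effect_size * post
    latent = np.where(lineage == "branch", g_lat, f)
    y = _nb_draw(rng, np.exp(latent), alpha)
    ds = CountsDataset(counts=y[None, :], coords=x, labels=lineage,
                       gene_names=["gene_0"])
    truth = dict(x_b=x_b_true, effect_size=effect_size, alpha=alpha, **base)
    return ds, truth
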