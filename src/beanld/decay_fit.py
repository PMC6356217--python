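"""Hill-Weir expected r2 curve, decay fitting and threshold distances.

The drift-recombination expectation of r2 between two sites at scaled
recombination ``C = rho * d`` (``rho = 4 N_e r`` per bp, ``d`` the distance
in bp), with a finite-sample correction for ``n`` sampled haplotypes:

    E(r2) = [(10 + C) / ((2 + C)(11 + C))]
            * [1 + ((3 + C)(12 + 12 C + C^2)) / (n (2 + C)(11 + C))]

The single fitted parameter is ``rho_per_bp``; the curve is strictly
decreasing in ``C``, so threshold-crossing distances are found by
bisection. Inbred lines are treated as single haplotypes, so ``n`` is the
number of accessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UnidentifiableFitError, ValidationError

RHO_GRID_LO = 1e-9
RHO_GRID_HI = 1.0


def expected_r2(C, n: int):
    """Expected r2 at scaled recombination ``C`` for sample size ``n``.

    Vectorized over ``C``. At ``C = 0`` and large ``n`` the value tends to
    10/22 = 5/11.
    """
    if n < 2:
        raise ValidationError("n must be >= 2")
    C = np.asarray(C, dtype=float)
    if (C < 0).any():
        raise ValidationError("C must be >= 0")
    base = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    corr = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (
        n * (2.0 + C) * (11.0 + C)
    )
    out = base * corr
    return float(out) if out.ndim == 0 else out


def _golden_section(f, lo: float, hi: float, iters: int = 120) -> float:
    """Deterministic golden-section minimization on ``[lo, hi]``."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
        if b - a < 1e-15:
            break
    return 0.5 * (a + b)


@dataclass
class DecayFit:
    """Fitted decay curve: ``C = rho_per_bp * distance_bp``."""

    rho_per_bp: float
    n: int
    sse: float
    n_pairs: int
    measure: str = "r2"
    at_lower_bound: bool = False
    at_upper_bound: bool = False


def fit_C(
    distances_bp,
    ld_values,
    n: int,
    *,
    measure: str = "r2",
    n_grid: int = 240,
) -> DecayFit:
    """Least-squares fit of ``rho_per_bp`` to LD-vs-distance data.

    One-dimensional objective, minimized deterministically by a log-spaced
    grid scan over ``rho in [1e-9, 1]`` followed by bounded scalar
    refinement between the grid neighbours of the best point.
    """
    d = np.asarray(distances_bp, dtype=float)
    y = np.asarray(ld_values, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValidationError("distances and LD values must be equal-length 1-D")
    if len(d) < 10:
        raise ValidationError("need at least 10 pairs to fit the decay curve")
    if (d <= 0).any():
        raise ValidationError("distances must be positive")
    if np.unique(d).size < 2:
        raise UnidentifiableFitError("all distances equal: rho not identifiable")
    if ((y < 0) | (y > 1)).any():
        raise ValidationError("LD values must lie in [0, 1]")

    def sse_at(log_rho: float) -> float:
        rho = 10.0**log_rho
        return float(np.sum((y - expected_r2(rho * d, n)) ** 2))

    grid = np.linspace(np.log10(RHO_GRID_LO), np.log10(RHO_GRID_HI), n_grid)
    vals = np.array([sse_at(g) for g in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    best_log = _golden_section(sse_at, lo, hi)
    if sse_at(best_log) > vals[k]:
        best_log = float(grid[k])
    rho = 10.0**best_log
    step = grid[1] - grid[0]
    at_lower = k == 0 and best_log <= grid[0] + step / 2
    at_upper = k == n_grid - 1 and best_log >= grid[-1] - step / 2
    return DecayFit(
        rho_per_bp=rho,
        n=n,
        sse=sse_at(best_log),
        n_pairs=len(d),
        measure=measure,
        at_lower_bound=bool(at_lower),
        at_upper_bound=bool(at_upper),
    )


def decay_distance(
    fit: DecayFit, threshold: float = 0.1, *, rtol: float = 1e-10
) -> float | None:
    """Distance (bp) at which the fitted curve crosses ``threshold``.

    Returns ``None`` ("unreachable") if the threshold is at or above the
    curve's value at zero distance. The curve is strictly decreasing in
    distance (checked numerically), so bisection applies.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must lie in (0, 1)")
    rho, n = fit.rho_per_bp, fit.n
    at0 = expected_r2(0.0, n)
    if threshold >= at0:
        return None
    # numerical monotonicity guard over a broad distance grid
    probe = expected_r2(rho * np.geomspace(1e-3, 1e12, 200), n)
    if not (np.diff(probe) < 1e-15).all():
        raise ValidationError("fitted curve is not strictly decreasing")
    lo, hi = 0.0, 1.0
    while expected_r2(rho * hi, n) > threshold:
        hi *= 10.0
        if hi > 1e15:
            return None
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected_r2(rho * mid, n) > threshold:
            lo = mid
        else:
            hi = mid
        if hi - lo <= rtol * max(hi, 1.0):
            break
    return 0.5 * (lo + hi)


def binned_decay_profile(
    distances_bp, ld_values, bin_edges
) -> pd.DataFrame:
    """Mean LD per distance bin; empty bins appear with count 0.

    Bins are ``[edge_i, edge_{i+1})``, the last bin closed on the right.
    """
    d = np.asarray(distances_bp, dtype=float)
    y = np.asarray(ld_values, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or not (np.diff(edges) > 0).all():
        raise ValidationError("bin edges must be increasing with >= 2 entries")
    which = np.digitize(d, edges, right=False) - 1
    which[d == edges[-1]] = len(edges) - 2
    mids = 0.5 * (edges[:-1] + edges[1:])
    means = np.full(len(mids), np.nan)
    counts = np.zeros(len(mids), dtype=int)
    for b in range(len(mids)):
        sel = which == b
        counts[b] = int(sel.sum())
        if counts[b]:
            means[b] = float(y[sel].mean())
    return pd.DataFrame(
        {"bin_mid_bp": mids, "mean_ld": means, "n_pairs": counts}
    )
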