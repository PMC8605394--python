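"""Independent brute-force oracles for the community solver tests.

These deliberately avoid the bisection/FVA code paths: growth is located
by scanning a mu grid for feasibility, and flux extremes by fixing the
abundance split on a grid (with local refinement) and solving plain
scaled LPs.
"""

from __future__ import annotations

import numpy as np

from camp.steadycom import CommunityLP


def grid_search_mu(cm, step=1e-3, mu_max=2.0):
    """Largest feasible mu on a regular grid (feasibility = the scaled LP
    admits total abundance >= 1)."""
    lp = CommunityLP(cm)
    best = 0.0
    for mu in np.arange(0.0, mu_max + step, step):
        if lp.max_total_abundance(float(mu)) >= 1.0 - 1e-9:
            best = float(mu)
        else:
            break
    return best


def _extreme_in_window(lp, mu, lo, hi, reaction_id, sense):
    """Flux extreme with the first member's abundance confined to a
    window (the partner takes the complement through sum X = 1)."""
    first = next(iter(lp.x))
    var = lp.x[first]
    saved = (var.lb, var.ub)
    try:
        var.lb, var.ub = lo, hi
        status, value, _, _ = lp.optimize(mu, {reaction_id: 1.0}, sense)
        return value if status == "optimal" else None
    finally:
        var.lb, var.ub = saved


def brute_force_flux_extreme(cm, reaction_id, mu, sense="max",
                             iterations=40):
    """Flux extreme at fixed mu by subdividing the abundance axis.

    The windowed extreme (best flux with the first member's abundance
    restricted to an interval) is a concave function of the window, so
    repeatedly halving the abundance interval and descending into the
    better half converges to the extreme over the whole simplex while
    only ever solving plain windowed LPs.
    """
    lp = CommunityLP(cm)
    lo, hi = 0.0, 1.0
    worst = -np.inf if sense == "max" else np.inf
    best = worst
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        v_left = _extreme_in_window(lp, mu, lo, mid, reaction_id, sense)
        v_right = _extreme_in_window(lp, mu, mid, hi, reaction_id, sense)
        v_left = worst if v_left is None else v_left
        v_right = worst if v_right is None else v_right
        take_left = v_left >= v_right if sense == "max" else v_left <= v_right
        if take_left:
            hi, best = mid, v_left
        else:
            lo, best = mid, v_right
        if not np.isfinite(best):
            raise AssertionError("no feasible abundance split")
    return best
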