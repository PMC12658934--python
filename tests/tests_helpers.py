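"""Shared data-generation helpers for the test suite."""

import itertools

import numpy as np
import pandas as pd


def decay_pairs(seed, n_sites=25, slope=-0.002, sd_u=0.03, sd_v=0.03,
                sd_e=0.05, n_pairs=None, d_range=(1.0, 100.0), quadratic=0.0,
                vertex_km=60.0, break_km=None, rise_slope=0.004):
    """Crossed-random-intercept pair data with a known distance effect.

    ``quadratic > 0`` adds a U-shaped component ``quadratic * (d - vertex)^2``.
    ``break_km`` instead makes the distance effect piecewise: similarity
    declines with ``slope`` up to the breakpoint and then *rises* with
    ``rise_slope`` — the valley pattern the distance-threshold
    sensitivity scan must detect.
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(0, sd_u, n_sites)
    v = rng.normal(0, sd_v, n_sites)
    pairs = list(itertools.combinations(range(n_sites), 2))
    if n_pairs is not None:
        idx = rng.choice(len(pairs), size=min(n_pairs, len(pairs)), replace=False)
        pairs = [pairs[k] for k in idx]
    rows = []
    for i, j in pairs:
        d = float(rng.uniform(*d_range))
        sri, srj = (rng.poisson(12, 2) + 1).tolist()
        sp = float(rng.uniform(0, 1))
        if break_km is not None:
            dist_effect = slope * min(d, break_km) + rise_slope * max(d - break_km, 0.0)
        else:
            dist_effect = slope * d + quadratic * (d - vertex_km) ** 2
        y = (0.5 + dist_effect
             + 0.002 * sri + 0.002 * srj + 0.05 * sp
             + u[i] + v[j] + float(rng.normal(0, sd_e)))
        rows.append(dict(site_i=f"S{i:02d}", site_j=f"S{j:02d}", sim=y, geo_km=d,
                         plantSR_i=sri, plantSR_j=srj, sim_plants=sp))
    return pd.DataFrame(rows)
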