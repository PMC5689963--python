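"""Independent, loop-based reference transport used as a test oracle.

Re-implements the ray-trace / depth-kernel / cloud-in-cell deposition with
plain per-particle Python loops, sharing no code with the package's
vectorized transport.  Only usable at tiny particle counts.
"""

import math

import numpy as np


def _mu(e):
    return 0.04 + 0.05 * math.exp(-e / 3.0)


def _beta(e):
    return max(5.0 / (1.0 + e / 2.0), 2.0 * _mu(e))


def _kernel(pclass, e, d):
    if pclass == 2:  # electron
        r = max(0.5 * e, 1e-3)
        return 2.0 * e / r * (1.0 - d / r) if d < r else 0.0
    mu, beta = _mu(e), _beta(e)
    n0 = e / (1.0 / mu - 1.0 / beta)
    return max(n0 * (math.exp(-mu * d) - math.exp(-beta * d)), 0.0)


def reference_transport(batch, grid, n_histories=None, step=None):
    """Dose grid from a particle batch, one particle at a time."""
    origin = np.asarray(grid.origin, dtype=float)
    dv = np.asarray(grid.voxel_size, dtype=float)
    dims = grid.dims
    upper = origin + dv * np.asarray(dims)
    ds = float(step) if step is not None else float(min(dv))
    vol = float(np.prod(dv))
    dose = np.zeros(dims)
    n_hist = len(batch) if n_histories is None else n_histories

    pos_all = batch.positions3()
    for i in range(len(batch)):
        pos = pos_all[i]
        d = batch.direction[i]
        t0, t1 = 0.0, math.inf
        for ax in range(3):
            if d[ax] == 0.0:
                if not origin[ax] <= pos[ax] <= upper[ax]:
                    t0, t1 = 1.0, 0.0
                continue
            a = (origin[ax] - pos[ax]) / d[ax]
            b = (upper[ax] - pos[ax]) / d[ax]
            t0 = max(t0, min(a, b))
            t1 = min(t1, max(a, b))
        if t1 <= t0:
            continue
        n_steps = int(math.ceil((t1 - t0) / ds))
        for k in range(n_steps):
            s = t0 + (k + 0.5) * ds
            if s >= t1:
                break
            depth = s - t0
            amount = (batch.weight[i]
                      * _kernel(int(batch.pclass[i]),
                                float(batch.energy[i]), depth) * ds / vol)
            p = pos + s * d
            f = (p - origin) / dv - 0.5
            i0 = np.floor(f).astype(int)
            frac = f - i0
            for cx in (0, 1):
                for cy in (0, 1):
                    for cz in (0, 1):
                        iv = (i0[0] + cx, i0[1] + cy, i0[2] + cz)
                        if any(iv[a] < 0 or iv[a] >= dims[a]
                               for a in range(3)):
                            continue
                        wgt = ((frac[0] if cx else 1 - frac[0])
                               * (frac[1] if cy else 1 - frac[1])
                               * (frac[2] if cz else 1 - frac[2]))
                        dose[iv] += amount * wgt
    return dose / max(n_hist, 1)
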