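"""Independent brute-force oracles for the test suite."""

import numpy as np


def profile_grid_fit(ages, factors, n_grid=60, n_shrink=9):
    """Brute-force power-law least-squares oracle, independent of the fitter.

    Profiles the scale in closed form — for fixed (b, c) the optimal a is
    sum(y*g)/sum(g*g) with g = (x+b)^c — over a (b, c) grid that is
    repeatedly shrunk around the best cell.  Pure numpy; no scipy.
    """
    x = np.asarray(ages, float)
    y = np.asarray(factors, float)
    b_lo, b_hi = 1e-3, 5.0
    c_lo, c_hi = -2.0, -0.01
    best = None
    for _ in range(n_shrink):
        bs = np.linspace(b_lo, b_hi, n_grid)
        cs = np.linspace(c_lo, c_hi, n_grid)
        # g[i, j, k] = (x_k + b_i) ** c_j
        g = (x[None, None, :] + bs[:, None, None]) ** cs[None, :, None]
        a = (g @ y) / np.einsum("ijk,ijk->ij", g, g)
        ssr = np.sum((a[:, :, None] * g - y[None, None, :]) ** 2, axis=2)
        ssr[a <= 0] = np.inf
        i, j = np.unravel_index(np.argmin(ssr), ssr.shape)
        if best is None or ssr[i, j] < best[0]:
            best = (float(ssr[i, j]), float(a[i, j]), float(bs[i]), float(cs[j]))
        _, _, b_star, c_star = best
        b_span = (b_hi - b_lo) * 0.12
        c_span = (c_hi - c_lo) * 0.12
        b_lo, b_hi = max(1e-4, b_star - b_span), b_star + b_span
        c_lo, c_hi = c_star - c_span, min(-1e-4, c_star + c_span)
    return best[1], best[2], best[3]
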