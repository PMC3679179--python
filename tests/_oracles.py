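"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written the slow, obvious way (explicit
loops, plain subgradient descent) and shares no code path with the package
implementations it checks.
"""

from __future__ import annotations

import numpy as np


def loop_circular_convolve(u: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Triple-loop circular convolution with a centered odd kernel."""
    H, W = u.shape
    kh, kw = taps.shape
    ch, cw = kh // 2, kw // 2
    out = np.zeros_like(u)
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    acc += taps[a, b] * u[(i - (a - ch)) % H, (j - (b - cw)) % W]
            out[i, j] = acc
    return out


def loop_grad(u: np.ndarray):
    """Index-by-index forward differences with Neumann last row/column."""
    H, W = u.shape
    px = np.zeros_like(u)
    py = np.zeros_like(u)
    for i in range(H):
        for j in range(W):
            if i < H - 1:
                px[i, j] = u[i + 1, j] - u[i, j]
            if j < W - 1:
                py[i, j] = u[i, j + 1] - u[i, j]
    return px, py


def loop_tv(u: np.ndarray) -> float:
    px, py = loop_grad(u)
    return float(np.sqrt(px**2 + py**2).sum())


def rof_energy(g: np.ndarray, f: np.ndarray, w: float) -> float:
    return loop_tv(g) + 0.5 * w * float(((g - f) ** 2).sum())


def _tv_subgradient(g: np.ndarray) -> np.ndarray:
    """A subgradient of the isotropic TV at g (zero on flat gradients)."""
    px = np.zeros_like(g)
    py = np.zeros_like(g)
    px[:-1, :] = g[1:, :] - g[:-1, :]
    py[:, :-1] = g[:, 1:] - g[:, :-1]
    mag = np.sqrt(px**2 + py**2)
    safe = np.where(mag > 0, mag, 1.0)
    qx = np.where(mag > 0, px / safe, 0.0)
    qy = np.where(mag > 0, py / safe, 0.0)
    out = np.zeros_like(g)
    out[:-1, :] -= qx[:-1, :]
    out[1:, :] += qx[:-1, :]
    out[:, :-1] -= qy[:, :-1]
    out[:, 1:] += qy[:, :-1]
    return out


def subgradient_rof_min(f: np.ndarray, w: float, iters: int = 12000) -> float:
    """Best ROF energy found by plain subgradient descent.

    Strongly convex step schedule 2/(w (t+1)); tracks the running minimum.
    """

    def energy(g):
        px = np.zeros_like(g)
        py = np.zeros_like(g)
        px[:-1, :] = g[1:, :] - g[:-1, :]
        py[:, :-1] = g[:, 1:] - g[:, :-1]
        return float(np.sqrt(px**2 + py**2).sum() + 0.5 * w * ((g - f) ** 2).sum())

    g = f.copy()
    best = energy(g)
    for t in range(1, iters + 1):
        s = _tv_subgradient(g) + w * (g - f)
        g = g - (2.0 / (w * (t + 1))) * s
        e = energy(g)
        if e < best:
            best = e
    return best


def graph_nltv_energy(g: np.ndarray, f: np.ndarray, W, reg_weight: float) -> float:
    """Graph ROF energy computed from the dense weight matrix by loops."""
    Wd = np.asarray(W.matrix.todense())
    gf = g.ravel()
    n = gf.size
    tv = 0.0
    for x in range(n):
        s = 0.0
        for y in range(n):
            if Wd[x, y] > 0:
                s += Wd[x, y] * (gf[y] - gf[x]) ** 2
        tv += np.sqrt(s)
    return tv + 0.5 * reg_weight * float(((g - f) ** 2).sum())


def _graph_tv_subgradient(g: np.ndarray, Wd: np.ndarray) -> np.ndarray:
    gf = g.ravel()
    n = gf.size
    diffs = gf[None, :] - gf[:, None]
    row_norm = np.sqrt((Wd * diffs**2).sum(axis=1))
    S = np.where(row_norm[:, None] > 0, Wd * diffs / np.where(row_norm[:, None] > 0, row_norm[:, None], 1.0), 0.0)
    sub = S.sum(axis=0) - S.sum(axis=1)
    return sub.reshape(g.shape)


def subgradient_nltv_min(f: np.ndarray, W, reg_weight: float, iters: int = 12000) -> float:
    """Best graph-ROF energy found by plain subgradient descent.

    Uses the dense weight matrix throughout — an independent route from the
    package's sparse edge-data formulation.
    """
    Wd = np.asarray(W.matrix.todense())

    def energy(g):
        gf = g.ravel()
        diffs = gf[None, :] - gf[:, None]
        tv = np.sqrt((Wd * diffs**2).sum(axis=1)).sum()
        return tv + 0.5 * reg_weight * float(((g - f) ** 2).sum())

    g = f.copy()
    best = energy(g)
    for t in range(1, iters + 1):
        s = _graph_tv_subgradient(g, Wd) + reg_weight * (g - f)
        g = g - (2.0 / (reg_weight * (t + 1))) * s
        e = energy(g)
        if e < best:
            best = e
    return best


def loop_patch_distance(u: np.ndarray, x, y, r: int, G: np.ndarray) -> float:
    """G-weighted squared patch distance with symmetric boundary reflection."""
    pad = np.pad(u, r, mode="symmetric")
    xi, xj = x[0] + r, x[1] + r
    yi, yj = y[0] + r, y[1] + r
    acc = 0.0
    for a in range(-r, r + 1):
        for b in range(-r, r + 1):
            d = pad[xi + a, xj + b] - pad[yi + a, yj + b]
            acc += G[a + r, b + r] * d * d
    return acc


def loop_ssim(x: np.ndarray, y: np.ndarray, data_range: float = 1.0) -> float:
    """Sliding-window SSIM with an 11x11 Gaussian window, reflect boundary."""
    size, sigma = 11, 1.5
    r = size // 2
    ax = np.arange(-r, r + 1)
    G = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma**2))
    G /= G.sum()
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    xp = np.pad(x, r, mode="symmetric")
    yp = np.pad(y, r, mode="symmetric")
    H, W = x.shape
    total = 0.0
    for i in range(H):
        for j in range(W):
            wx = xp[i : i + size, j : j + size]
            wy = yp[i : i + size, j : j + size]
            mx = (G * wx).sum()
            my = (G * wy).sum()
            vx = (G * wx * wx).sum() - mx * mx
            vy = (G * wy * wy).sum() - my * my
            cov = (G * wx * wy).sum() - mx * my
            total += ((2 * mx * my + c1) * (2 * cov + c2)) / (
                (mx * mx + my * my + c1) * (vx + vy + c2)
            )
    return total / (H * W)
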