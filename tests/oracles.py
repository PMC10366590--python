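"""Independent brute-force reference implementations used only by tests.

These are deliberately naive (nested Python loops, explicit dense algebra)
so they share no code path with the package implementation.
"""

import numpy as np


def naive_conv3d(x, w, b=None, stride=(1, 1, 1)):
    """Direct nested-loop strided cross-correlation with "same" padding."""
    co, ci, kx, ky, kz = w.shape
    sx, sy, sz = stride
    px, py, pz = (kx - 1) // 2, (ky - 1) // 2, (kz - 1) // 2
    xp = np.pad(x, ((0, 0), (px, px), (py, py), (pz, pz)))
    oshape = tuple(-(-n // s) for n, s in zip(x.shape[1:], stride))
    out = np.zeros((co,) + oshape)
    for o in range(co):
        for X in range(oshape[0]):
            for Y in range(oshape[1]):
                for Z in range(oshape[2]):
                    acc = 0.0
                    for c in range(ci):
                        for i in range(kx):
                            for j in range(ky):
                                for k in range(kz):
                                    acc += w[o, c, i, j, k] * xp[c, X * sx + i, Y * sy + j, Z * sz + k]
                    out[o, X, Y, Z] = acc + (0.0 if b is None else b[o])
    return out


def naive_avg_pool3d(x, kernel=3, stride=(2, 2, 2)):
    """Nested-loop average pooling with "same" zero padding (zeros counted)."""
    c = x.shape[0]
    k = (kernel,) * 3 if np.isscalar(kernel) else tuple(kernel)
    sx, sy, sz = stride
    px, py, pz = (k[0] - 1) // 2, (k[1] - 1) // 2, (k[2] - 1) // 2
    xp = np.pad(x, ((0, 0), (px, px), (py, py), (pz, pz)))
    oshape = tuple(-(-n // s) for n, s in zip(x.shape[1:], stride))
    out = np.zeros((c,) + oshape)
    for ch in range(c):
        for X in range(oshape[0]):
            for Y in range(oshape[1]):
                for Z in range(oshape[2]):
                    acc = 0.0
                    for i in range(k[0]):
                        for j in range(k[1]):
                            for kk in range(k[2]):
                                acc += xp[ch, X * sx + i, Y * sy + j, Z * sz + kk]
                    out[ch, X, Y, Z] = acc / (k[0] * k[1] * k[2])
    return out


def naive_global_avg_pool(t):
    """Double-loop per-channel spatial mean."""
    c = t.shape[0]
    out = np.zeros(c)
    for ch in range(c):
        total, count = 0.0, 0
        for val in t[ch].ravel():
            total += val
            count += 1
        out[ch] = total / count
    return out


def dense_ridge_solution(G, Y, lam):
    """Explicit dense (lam I + G'G)^(-1) G' Y via matrix inverse."""
    G = np.asarray(G, dtype=float)
    A = lam * np.eye(G.shape[1]) + G.T @ G
    return np.linalg.inv(A) @ G.T @ np.asarray(Y, dtype=float)
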