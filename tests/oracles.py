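"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the library:
direct circular filter-bank convolution for the wavelet packet transform,
dense rasterization for box counts, and a generic constrained primal solve
for the twin-SVM quadratic programs.
"""

import numpy as np
from scipy.optimize import minimize

# Published Daubechies-6 low-pass decomposition taps (12 coefficients).
DB6_DEC_LO = np.array([
    -0.0010773010853084796, 0.004777257510945511, 0.0005538422011614961,
    -0.03158203931748603, 0.027522865530305727, 0.09750160558732304,
    -0.12976686756726194, -0.22626469396543983, 0.31525035170919763,
    0.7511339080210954, 0.49462389039845306, 0.11154074335010947,
])
# Quadrature-mirror high-pass: g[k] = (-1)^(k+1) h[L-1-k]. The two QMF sign
# conventions differ only by a global sign of the detail branch; this is the
# one the decomposition under test uses, so coefficients compare directly.
DB6_DEC_HI = np.array([
    (-1.0) ** (k + 1) * DB6_DEC_LO[len(DB6_DEC_LO) - 1 - k]
    for k in range(len(DB6_DEC_LO))
])


def periodized_analysis(x, taps):
    """One analysis branch: circular convolution then dyadic downsampling.

    out[k] = sum_j taps[j] * x[(2k + L/2 - j) mod n] — the standard
    periodized filter-bank convention (half-filter phase offset).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    L = taps.size
    out = np.empty(n // 2)
    for k in range(n // 2):
        idx = (2 * k + L // 2 - np.arange(L)) % n
        out[k] = float(taps @ x[idx])
    return out


def wavelet_packet_cascade(x, level):
    """Full wavelet-packet tree by explicit db6 convolve-and-downsample.

    Returns the 2**level terminal nodes in natural (Paley) order: at each
    split the low-pass child precedes the high-pass child.
    """
    nodes = [np.asarray(x, dtype=float)]
    for _ in range(level):
        nxt = []
        for node in nodes:
            nxt.append(periodized_analysis(node, DB6_DEC_LO))
            nxt.append(periodized_analysis(node, DB6_DEC_HI))
        nodes = nxt
    return nodes


def rasterized_box_count(samples, delta, points_per_segment=2000):
    """Brute-force box count: densely sample the normalized polyline and
    mark every touched box (same grid convention: origin-anchored, boundary
    values to the upper box, top edge clamped to the last box)."""
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    t = np.arange(n) / (n - 1)
    lo, hi = samples.min(), samples.max()
    y = np.full(n, 0.5) if hi - lo <= 0 else (samples - lo) / (hi - lo)
    n_boxes = max(1, int(round(1.0 / delta)))  # exact NB x NB tiling

    def columns_of(tv):
        # columns are closed intervals: a point on a shared edge belongs to
        # both adjacent columns
        c = int(np.clip(np.floor(tv * n_boxes), 0, n_boxes - 1))
        cols = {c}
        if abs(tv * n_boxes - round(tv * n_boxes)) < 1e-9:
            edge = int(round(tv * n_boxes))
            for cc in (edge - 1, edge):
                if 0 <= cc <= n_boxes - 1:
                    cols.add(cc)
        return cols

    boxes = set()
    per_col_rows: dict = {}
    for i in range(n - 1):
        frac = np.linspace(0.0, 1.0, points_per_segment)
        ts = t[i] + frac * (t[i + 1] - t[i])
        ys = y[i] + frac * (y[i + 1] - y[i])
        rows = np.clip(np.floor(ys * n_boxes).astype(int), 0, n_boxes - 1)
        prev = None
        for tv, r in zip(ts, rows):
            cols = columns_of(tv)
            for cc in cols:
                boxes.add((cc, int(r)))
                # fill any rows stepped over between consecutive dense points
                if prev is not None and cc in prev[0]:
                    r0, r1 = sorted((prev[1], int(r)))
                    for rr in range(r0, r1 + 1):
                        boxes.add((cc, rr))
            prev = (cols, int(r))
    return len(boxes)


def primal_twsvm_brute(K_own, K_other, c, ridge=1e-6):
    """Solve one twin-SVM primal directly over (u, b, slack) with SLSQP.

    Minimizes 1/2||K_own u + b||^2 + (ridge/2)||[u;b]||^2 + c * sum(slack)
    subject to -(K_other u + b) + slack >= 1, slack >= 0 (the ridge term
    matches the regularized problem the dual path actually solves).
    Returns (v, objective) with v = [u; b].
    """
    m_own, mtot = K_own.shape
    m_other = K_other.shape[0]
    H = np.column_stack([K_own, np.ones(m_own)])
    G = np.column_stack([K_other, np.ones(m_other)])
    dim = mtot + 1

    def obj(z):
        v, s = z[:dim], z[dim:]
        return (0.5 * float(np.sum((H @ v) ** 2))
                + 0.5 * ridge * float(v @ v) + c * float(np.sum(s)))

    cons = [
        {"type": "ineq", "fun": lambda z: -(G @ z[:dim]) + z[dim:] - 1.0},
        {"type": "ineq", "fun": lambda z: z[dim:]},
    ]
    best = None
    for x0_scale in (0.0, 0.1):
        x0 = np.full(dim + m_other, x0_scale)
        res = minimize(obj, x0, constraints=cons, method="SLSQP",
                       options={"maxiter": 3000, "ftol": 1e-14})
        if best is None or res.fun < best.fun:
            best = res
    return best.x[:dim], float(best.fun)
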