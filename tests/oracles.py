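"""Shared brute-force reference implementations (independent oracles).

Everything here is written as plain per-pixel loops straight from the
definitions, deliberately ignoring the vectorized strategies of the
package, so the two routes share no code.
"""

import numpy as np

from stereovol.cross_aggregation import CrossArms

LUMA = (0.299, 0.587, 0.114)

DIR_STEPS = {"left": (0, -1), "right": (0, 1), "up": (-1, 0), "down": (1, 0)}


def gray_ref(img):
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 2:
        return img
    h, w, _ = img.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            out[y, x] = sum(img[y, x, c] * LUMA[c] for c in range(3))
    return out


def census_ref(gray, window):
    """Census bit strings by explicit window loops with edge clamping."""
    wr, wc = window
    h, w = gray.shape
    out = np.empty((h, w), dtype=object)
    for y in range(h):
        for x in range(w):
            bits = []
            for dy in range(-(wr // 2), wr // 2 + 1):
                for dx in range(-(wc // 2), wc // 2 + 1):
                    if dy == 0 and dx == 0:
                        continue
                    qy = min(max(y + dy, 0), h - 1)
                    qx = min(max(x + dx, 0), w - 1)
                    bits.append("1" if gray[y, x] < gray[qy, qx] else "0")
            out[y, x] = "".join(bits)
    return out


def grad_ref(gray):
    h, w = gray.shape
    gx = np.zeros((h, w))
    gy = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            gx[y, x] = (gray[y, min(x + 1, w - 1)] - gray[y, max(x - 1, 0)]) / 2.0
            gy[y, x] = (gray[min(y + 1, h - 1), x] - gray[max(y - 1, 0), x]) / 2.0
    return gx, gy


def fused_ref(left, right, params):
    """Triple-loop reference for the whole fused cost volume."""
    gl, gr = gray_ref(left), gray_ref(right)
    h, w = gl.shape
    cl = census_ref(gl, params.census_window)
    cr = census_ref(gr, params.census_window)
    glx, gly = grad_ref(gl)
    grx, gry = grad_ref(gr)
    l3 = np.asarray(left, dtype=np.float64)
    r3 = np.asarray(right, dtype=np.float64)
    if l3.ndim == 2:
        l3 = np.repeat(l3[:, :, None], 3, axis=2)
        r3 = np.repeat(r3[:, :, None], 3, axis=2)
    n_d = params.d_max - params.d_min + 1
    vol = np.full((h, w, n_d), 3.0)
    for i, d in enumerate(range(params.d_min, params.d_max + 1)):
        for y in range(h):
            for x in range(w):
                if x - d < 0:
                    continue
                ham = sum(a != b for a, b in zip(cl[y, x], cr[y, x - d]))
                grad = abs(glx[y, x] - grx[y, x - d]) + abs(gly[y, x] - gry[y, x - d])
                sd = ((l3[y, x] - r3[y, x - d]) ** 2).mean()
                vol[y, x, i] = (
                    3.0
                    - np.exp(-grad / params.lambda_grad)
                    - np.exp(-sd / params.lambda_sd)
                    - np.exp(-ham / params.lambda_census)
                )
    return vol


def arms_ref(image, params):
    """Exhaustive per-pixel arm walk following the three growth rules."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    h, w = img.shape[:2]

    def dc(a, b):
        return np.abs(img[a] - img[b]).max()

    out = {}
    for name, (dy, dx) in DIR_STEPS.items():
        arm = np.zeros((h, w), dtype=np.int32)
        for y in range(h):
            for x in range(w):
                l = 0
                while True:
                    nl = l + 1
                    qy, qx = y + nl * dy, x + nl * dx
                    if not (0 <= qy < h and 0 <= qx < w):
                        break
                    if nl >= params.L1:
                        break
                    prev = (y + l * dy, x + l * dx)
                    if not (dc((y, x), (qy, qx)) < params.tau1):
                        break
                    if not (dc((qy, qx), prev) < params.tau1):
                        break
                    if nl > params.L2 and not (dc((y, x), (qy, qx)) < params.tau2):
                        break
                    l = nl
                arm[y, x] = l
        out[name] = arm
    return CrossArms(**out)


def region_ref(arms, p, horizontal_first):
    """Independent support-region enumeration from raw arm arrays."""
    row, col = p
    pts = set()
    if horizontal_first:
        for c in range(col - arms.left[row, col], col + arms.right[row, col] + 1):
            for r in range(row - arms.up[row, c], row + arms.down[row, c] + 1):
                pts.add((r, c))
    else:
        for r in range(row - arms.up[row, col], row + arms.down[row, col] + 1):
            for c in range(col - arms.left[r, col], col + arms.right[r, col] + 1):
                pts.add((r, c))
    return pts


def aggregate_ref(values, arms_l, arms_r, d_min, vertical_first):
    """Brute-force enumerated mean over the joint support region."""
    h, w, n_d = values.shape
    out = values.copy()
    for i in range(n_d):
        d = d_min + i
        for y in range(h):
            for x in range(w):
                if x - d < 0:
                    continue
                U = region_ref(arms_l, (y, x), horizontal_first=not vertical_first)
                Ur = region_ref(arms_r, (y, x - d), horizontal_first=not vertical_first)
                joint = [q for q in U if (q[0], q[1] - d) in Ur]
                if joint:
                    out[y, x, i] = np.mean([values[r, c, i] for r, c in joint])
    return out
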