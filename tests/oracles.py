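"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the vectorized code paths of the package: plain
Python loops, string-based uniform-pattern counting, and direct per-index
recomputation, so that agreement with the package is a meaningful check.
"""

import math

import numpy as np

# Neighbor order must match the package contract: n=0 east, counter-clockwise.
OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


def brute_scale(matrix):
    matrix = np.asarray(matrix, dtype=float)
    lo, hi = matrix.min(), matrix.max()
    if hi == lo:
        return np.zeros(matrix.shape, dtype=int)
    out = np.empty(matrix.shape, dtype=int)
    for i in range(matrix.shape[0]):
        for j in range(matrix.shape[1]):
            # round-half-even, as python's round() implements
            out[i, j] = round(255.0 * (matrix[i, j] - lo) / (hi - lo))
    return out


def brute_code_maps(img):
    img = np.asarray(img, dtype=int)
    rows, cols = img.shape
    t_global = img.mean()
    mags = [
        abs(int(img[i + dr, j + dc]) - int(img[i, j]))
        for i in range(1, rows - 1)
        for j in range(1, cols - 1)
        for dr, dc in OFFSETS
    ]
    t_mag = sum(mags) / len(mags)
    c = np.zeros((rows - 2, cols - 2), dtype=int)
    s = np.zeros((rows - 2, cols - 2), dtype=int)
    m = np.zeros((rows - 2, cols - 2), dtype=int)
    for i in range(1, rows - 1):
        for j in range(1, cols - 1):
            center = int(img[i, j])
            c[i - 1, j - 1] = 1 if center >= t_global else 0
            s_code = m_code = 0
            for n, (dr, dc) in enumerate(OFFSETS):
                diff = int(img[i + dr, j + dc]) - center
                if diff >= 0:
                    s_code += 2 ** n
                if abs(diff) >= t_mag:
                    m_code += 2 ** n
            s[i - 1, j - 1] = s_code
            m[i - 1, j - 1] = m_code
    return c, s, m


def u2_bin(code, n_bits=8):
    """u2 bin of a code via string rotation counting (58 uniform + catch-all)."""
    bits = format(code, f"0{n_bits}b")
    transitions = sum(bits[i] != bits[(i + 1) % n_bits] for i in range(n_bits))
    if transitions > 2:
        return 58
    uniform = sorted(
        cc for cc in range(2 ** n_bits)
        if sum(
            format(cc, f"0{n_bits}b")[i] != format(cc, f"0{n_bits}b")[(i + 1) % n_bits]
            for i in range(n_bits)
        ) <= 2
    )
    return uniform.index(code)


_U2 = [u2_bin(code) for code in range(256)]


def brute_descriptor(matrix):
    """Full 236-dim CLBP descriptor by per-pixel loops and recounting."""
    c, s, m = brute_code_maps(brute_scale(matrix))
    hist_s = [0] * 59
    hist_m = [0] * 59
    joint = [0] * 118
    for ci, si, mi in zip(c.ravel(), s.ravel(), m.ravel()):
        hist_s[_U2[si]] += 1
        hist_m[_U2[mi]] += 1
        joint[ci * 59 + _U2[mi]] += 1
    return np.array(hist_s + hist_m + joint, dtype=float)


def brute_ctd(groups):
    """(C, T, D) indices of a group string by direct counting."""
    n = len(groups)
    comp = [groups.count(g) / n * 100.0 for g in "123"]
    trans = []
    for a, b in (("1", "2"), ("1", "3"), ("2", "3")):
        count = sum(
            1 for i in range(n - 1)
            if {groups[i], groups[i + 1]} == {a, b}
        )
        trans.append(count / (n - 1) * 100.0 if n > 1 else 0.0)
    dist = []
    for g in "123":
        pos = [i + 1 for i, ch in enumerate(groups) if ch == g]
        if not pos:
            dist.extend([0.0] * 5)
            continue
        for q in (0.0, 0.25, 0.5, 0.75, 1.0):
            k = max(1, math.ceil(q * len(pos)))
            dist.append(pos[k - 1] / n * 100.0)
    return np.array(comp), np.array(trans), np.array(dist)
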