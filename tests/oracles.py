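"""Naive double-loop reference implementations of the kernel/difference
focus measures.

Deliberately written with explicit Python loops and no shared code with the
package, so they serve as an independent oracle on small frames.
"""

import math

SQRT2 = math.sqrt(2.0)


def tenengrad(img, a, theta=0.0):
    h, w = len(img), len(img[0])
    o1 = [[-1, 0, 1], [-a, 0, a], [-1, 0, 1]]
    total = 0.0
    for i in range(1, h - 1):
        for j in range(1, w - 1):
            gx = gy = 0.0
            for m in range(3):
                for n in range(3):
                    gx += o1[m][n] * img[i + m - 1][j + n - 1]
                    gy += o1[n][m] * img[i + m - 1][j + n - 1]
            if math.hypot(gx, gy) > theta:
                total += gx * gx + gy * gy
    return total


def _lap_responses(img, i, j):
    rx = -img[i][j - 1] + 2 * img[i][j] - img[i][j + 1]
    ry = -img[i - 1][j] + 2 * img[i][j] - img[i + 1][j]
    d1 = (img[i - 1][j + 1] - 2 * img[i][j] + img[i + 1][j - 1]) / SQRT2
    d2 = (img[i - 1][j - 1] - 2 * img[i][j] + img[i + 1][j + 1]) / SQRT2
    return rx, ry, d1, d2


def laplacian_energy(img, variant):
    h, w = len(img), len(img[0])
    total = 0.0
    for i in range(1, h - 1):
        for j in range(1, w - 1):
            rx, ry, d1, d2 = _lap_responses(img, i, j)
            if variant == "EOL":
                total += (rx + ry) ** 2
            elif variant == "SML":
                total += abs(rx) + abs(ry)
            elif variant == "DLF":
                total += abs(rx) + abs(ry) + abs(d1) + abs(d2)
    return total


def derivative_fm(img, k, p, theta=0.0):
    h, w = len(img), len(img[0])
    total = 0.0
    for i in range(h):
        for j in range(w - k):
            d = abs(img[i][j] - img[i][j + k])
            if d > theta:
                total += d**p
    return total


def energy_of_gradient(img):
    h, w = len(img), len(img[0])
    total = 0.0
    for i in range(h - 1):
        for j in range(w):
            total += (img[i + 1][j] - img[i][j]) ** 2
    for i in range(h):
        for j in range(w - 1):
            total += (img[i][j + 1] - img[i][j]) ** 2
    return total


def boddeke(img):
    h, w = len(img), len(img[0])
    total = 0.0
    for i in range(h):
        for j in range(1, w - 1):
            total += (img[i][j + 1] - img[i][j - 1]) ** 2
    return total


def vollath_f4(img, axis=0):
    h, w = len(img), len(img[0])
    if axis == 1:
        img = [[img[i][j] for i in range(h)] for j in range(w)]
        h, w = w, h
    lag1 = sum(img[i][j] * img[i + 1][j] for i in range(h - 1) for j in range(w))
    lag2 = sum(img[i][j] * img[i + 2][j] for i in range(h - 2) for j in range(w))
    return lag1 - lag2


def vollath_f5(img, axis=0):
    h, w = len(img), len(img[0])
    mu = sum(sum(row) for row in img) / (h * w)
    if axis == 1:
        img = [[img[i][j] for i in range(h)] for j in range(w)]
        h, w = w, h
    lag1 = sum(img[i][j] * img[i + 1][j] for i in range(h - 1) for j in range(w))
    return lag1 - h * w * mu * mu


def midfreq_dct(img):
    h, w = len(img), len(img[0])
    mask = [[1, 1, -1, -1], [1, 1, -1, -1], [-1, -1, 1, 1], [-1, -1, 1, 1]]
    total = 0.0
    for i in range(h - 3):
        for j in range(w - 3):
            r = sum(mask[m][n] * img[i + m][j + n] for m in range(4) for n in range(4))
            total += r * r
    return total
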