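"""Independent brute-force oracles used by the test suite.

Everything here is written as plainly as possible — explicit voxel loops,
direct formula transcriptions, exhaustive searches — and deliberately shares
no code with the package implementation it checks.
"""

import math

import numpy as np


def mae_loop(a, b, roi):
    total = n = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            for k in range(a.shape[2]):
                if roi[i, j, k]:
                    total += abs(a[i, j, k] - b[i, j, k])
                    n += 1
    return total / n


def me_loop(a, b, roi):
    total = n = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            for k in range(a.shape[2]):
                if roi[i, j, k]:
                    total += a[i, j, k] - b[i, j, k]
                    n += 1
    return total / n


def psnr_loop(a, b, roi):
    total = n = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            for k in range(a.shape[2]):
                if roi[i, j, k]:
                    total += (a[i, j, k] - b[i, j, k]) ** 2
                    n += 1
    mse = total / n
    max_ct = b.max()
    return 10.0 * math.log10(max_ct * max_ct / mse)


def ssim_formula(a, b, L=4095.0):
    """Direct transcription of the global SSIM closed form."""
    c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    va, vb = ((a - mu_a) ** 2).mean(), ((b - mu_b) ** 2).mean()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a ** 2 + mu_b ** 2 + c1) * (va + vb + c2)
    )


def l1_loop(y, g):
    total = 0.0
    flat_y, flat_g = y.ravel(), g.ravel()
    for i in range(flat_y.size):
        total += abs(flat_y[i] - flat_g[i])
    return total / flat_y.size


def nmi_histogram(a, b, bins=64):
    """Joint-histogram normalized mutual information, built by hand."""
    a, b = np.ravel(a), np.ravel(b)
    width = 2.0 / bins
    h = np.zeros((bins, bins))
    for x, y in zip(a, b):
        i = min(int((x + 1.0) / width), bins - 1)
        j = min(int((y + 1.0) / width), bins - 1)
        h[i, j] += 1
    p = h / h.sum()
    pa, pb = p.sum(axis=1), p.sum(axis=0)

    def ent(q):
        return -sum(v * math.log(v) for v in q.ravel() if v > 0)

    ha, hb = ent(pa), ent(pb)
    if ha == 0 or hb == 0:
        return 1.0 if np.array_equal(a, b) else 0.0
    mi = ha + hb - ent(p)
    return mi / math.sqrt(ha * hb)


def lsgan_d_loss_loop(real, fake):
    s = 0.0
    for v in np.ravel(real):
        s += (v - 1.0) ** 2
    s /= np.size(real)
    t = 0.0
    for v in np.ravel(fake):
        t += v * v
    return s + t / np.size(fake)


def dvh_fraction(doses_in_structure, d):
    """Fraction of structure receiving >= d, by counting."""
    count = sum(1 for v in doses_in_structure if v >= d)
    return count / len(doses_in_structure)


def dx_percentile(doses_in_structure, x):
    """Dx% as the (1 - x/100) linearly interpolated order statistic."""
    s = sorted(doses_in_structure)
    q = (1.0 - x / 100.0) * (len(s) - 1)
    lo = int(math.floor(q))
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (q - lo) * (s[hi] - s[lo])


def _trilinear(vol, x, y, z):
    """Hand-rolled trilinear interpolation at fractional voxel index (x,y,z),
    clamped to the grid (nearest-edge extension)."""
    nx, ny, nz = vol.shape
    x = min(max(x, 0.0), nx - 1.0)
    y = min(max(y, 0.0), ny - 1.0)
    z = min(max(z, 0.0), nz - 1.0)
    i0, j0, k0 = int(x), int(y), int(z)
    i1, j1, k1 = min(i0 + 1, nx - 1), min(j0 + 1, ny - 1), min(k0 + 1, nz - 1)
    fx, fy, fz = x - i0, y - j0, z - k0
    out = 0.0
    for di, wi in ((0, 1 - fx), (1, fx)):
        for dj, wj in ((0, 1 - fy), (1, fy)):
            for dk, wk in ((0, 1 - fz), (1, fz)):
                ii = i1 if di else i0
                jj = j1 if dj else j0
                kk = k1 if dk else k0
                out += wi * wj * wk * vol[ii, jj, kk]
    return out


def gamma_pass_rate_exhaustive(ref, ev, spacing, dose_percent, dta_mm,
                               threshold=0.10, step_mm=0.1):
    """Exhaustive gamma search on a fine cubic lattice out to 2×DTA."""
    max_ref = ref.max()
    delta_d = dose_percent / 100.0 * max_ref
    roi = ref > threshold * max_ref
    offsets = []
    k = int(2 * dta_mm / step_mm + 1e-9)
    for oi in range(-k, k + 1):
        for oj in range(-k, k + 1):
            for ok in range(-k, k + 1):
                r = math.sqrt((oi * step_mm) ** 2 + (oj * step_mm) ** 2 + (ok * step_mm) ** 2)
                if r <= 2 * dta_mm + 1e-9:
                    offsets.append((oi * step_mm, oj * step_mm, ok * step_mm, r))
    # sorting by radius lets the search stop once the spatial term alone
    # exceeds the best gamma^2 so far — exact, since the spatial term is
    # monotone along the sorted list
    offsets.sort(key=lambda t: t[3])
    passed = total = 0
    for i in range(ref.shape[0]):
        for j in range(ref.shape[1]):
            for kk in range(ref.shape[2]):
                if not roi[i, j, kk]:
                    continue
                total += 1
                best = float("inf")
                for ox, oy, oz, r in offsets:
                    spatial = (r / dta_mm) ** 2
                    if spatial >= best:
                        break
                    val = _trilinear(ev, i + ox / spacing[0], j + oy / spacing[1],
                                     kk + oz / spacing[2])
                    g2 = ((val - ref[i, j, kk]) / delta_d) ** 2 + spatial
                    if g2 < best:
                        best = g2
                if best <= 1.0:
                    passed += 1
    return 100.0 * passed / total


def resample_linear_1d_axis0(vals, in_spacing, out_n, out_spacing):
    """Direct corner-anchored linear interpolation along axis 0 only."""
    out = np.empty((out_n,) + vals.shape[1:])
    for j in range(out_n):
        phys = (j + 0.5) * out_spacing
        x = phys / in_spacing - 0.5
        x = min(max(x, 0.0), vals.shape[0] - 1.0)
        i0 = int(x)
        i1 = min(i0 + 1, vals.shape[0] - 1)
        f = x - i0
        out[j] = (1 - f) * vals[i0] + f * vals[i1]
    return out
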