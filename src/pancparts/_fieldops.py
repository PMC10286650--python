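"""Low-level displacement-field kernels.

Hot loops of the demons registration: trilinear/nearest warping of volumes
and fused composition of 3-component displacement fields, jitted with
numba when available (a fused kernel computes the 8 trilinear weights once
per voxel for all 3 components).  A scipy fallback keeps the package
functional without numba; results agree to interpolation rounding.

All fields are (3, X, Y, Z) voxel-unit displacements; sampling clamps to
the volume edge (nearest boundary mode).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally installed
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(fastmath=True)
def _warp_image_kernel(vol, disp, order, out):  # pragma: no cover - jitted
    nx, ny, nz = vol.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                x = i + disp[0, i, j, k]
                y = j + disp[1, i, j, k]
                z = k + disp[2, i, j, k]
                if x < 0.0:
                    x = 0.0
                elif x > nx - 1:
                    x = nx - 1.0
                if y < 0.0:
                    y = 0.0
                elif y > ny - 1:
                    y = ny - 1.0
                if z < 0.0:
                    z = 0.0
                elif z > nz - 1:
                    z = nz - 1.0
                if order == 0:
                    out[i, j, k] = vol[int(round(x)), int(round(y)), int(round(z))]
                else:
                    x0 = int(np.floor(x)); y0 = int(np.floor(y)); z0 = int(np.floor(z))
                    x1 = min(x0 + 1, nx - 1)
                    y1 = min(y0 + 1, ny - 1)
                    z1 = min(z0 + 1, nz - 1)
                    fx = x - x0; fy = y - y0; fz = z - z0
                    c00 = vol[x0, y0, z0] * (1 - fx) + vol[x1, y0, z0] * fx
                    c10 = vol[x0, y1, z0] * (1 - fx) + vol[x1, y1, z0] * fx
                    c01 = vol[x0, y0, z1] * (1 - fx) + vol[x1, y0, z1] * fx
                    c11 = vol[x0, y1, z1] * (1 - fx) + vol[x1, y1, z1] * fx
                    c0 = c00 * (1 - fy) + c10 * fy
                    c1 = c01 * (1 - fy) + c11 * fy
                    out[i, j, k] = c0 * (1 - fz) + c1 * fz


@njit(fastmath=True)
def _compose_kernel(a, b, out):  # pragma: no cover - jitted
    # out(x) = b(x) + a(x + b(x)); trilinear weights shared by components
    _, nx, ny, nz = a.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                x = i + b[0, i, j, k]
                y = j + b[1, i, j, k]
                z = k + b[2, i, j, k]
                if x < 0.0:
                    x = 0.0
                elif x > nx - 1:
                    x = nx - 1.0
                if y < 0.0:
                    y = 0.0
                elif y > ny - 1:
                    y = ny - 1.0
                if z < 0.0:
                    z = 0.0
                elif z > nz - 1:
                    z = nz - 1.0
                x0 = int(np.floor(x)); y0 = int(np.floor(y)); z0 = int(np.floor(z))
                x1 = min(x0 + 1, nx - 1)
                y1 = min(y0 + 1, ny - 1)
                z1 = min(z0 + 1, nz - 1)
                fx = x - x0; fy = y - y0; fz = z - z0
                w000 = (1 - fx) * (1 - fy) * (1 - fz)
                w100 = fx * (1 - fy) * (1 - fz)
                w010 = (1 - fx) * fy * (1 - fz)
                w110 = fx * fy * (1 - fz)
                w001 = (1 - fx) * (1 - fy) * fz
                w101 = fx * (1 - fy) * fz
                w011 = (1 - fx) * fy * fz
                w111 = fx * fy * fz
                for d in range(3):
                    out[d, i, j, k] = b[d, i, j, k] + (
                        a[d, x0, y0, z0] * w000 + a[d, x1, y0, z0] * w100
                        + a[d, x0, y1, z0] * w010 + a[d, x1, y1, z0] * w110
                        + a[d, x0, y0, z1] * w001 + a[d, x1, y0, z1] * w101
                        + a[d, x0, y1, z1] * w011 + a[d, x1, y1, z1] * w111)


def warp_image(vol: np.ndarray, disp: np.ndarray, order: int = 1) -> np.ndarray:
    """Sample `vol` at identity + disp; order 1 trilinear, 0 nearest."""
    vol = np.ascontiguousarray(vol, dtype=np.float64)
    disp = np.ascontiguousarray(disp, dtype=np.float64)
    if _HAVE_NUMBA:
        out = np.empty_like(vol)
        _warp_image_kernel(vol, disp, order, out)
        return out
    return _warp_image_scipy(vol, disp, order)


def compose(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Displacement of x -> x + b(x) + a(x + b(x)) (apply b, then a)."""
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if _HAVE_NUMBA:
        out = np.empty_like(a)
        _compose_kernel(a, b, out)
        return out
    out = np.empty_like(a)
    for d in range(3):
        out[d] = _warp_image_scipy(a[d], b, 1)
    return out + b


def _warp_image_scipy(vol, disp, order):
    from scipy.ndimage import map_coordinates

    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in vol.shape],
                        indexing="ij")
    coords = np.stack([g + d for g, d in zip(grids, disp)])
    return map_coordinates(vol, coords, order=order, mode="nearest")
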