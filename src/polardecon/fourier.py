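"""FFT convolution plumbing shared by the forward model and the solvers.

Volumes are padded by half the kernel support per axis (zero boundary) so
wrap-around never reaches phantom content; ``boundary='wrap'`` keeps the
cyclic grid, which is exact for spatially uniform objects (lake responses)
and for pseudoinverse round-trip checks.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft


def padded_shape(vol_shape, ker_shape, boundary: str = "pad") -> tuple:
    if boundary == "wrap":
        return tuple(int(n) for n in vol_shape)
    if boundary != "pad":
        raise ValueError(f"unknown boundary {boundary!r}")
    return tuple(
        sfft.next_fast_len(int(n) + int(k) - 1, real=True)
        for n, k in zip(vol_shape, ker_shape)
    )


def _center_kernel(kernel: np.ndarray, pshape: tuple) -> np.ndarray:
    """Embed a centered (odd-support) kernel with its center at index 0."""
    k = kernel.shape[-3:]
    out = np.zeros(kernel.shape[:-3] + pshape, dtype=kernel.dtype)
    out[..., : k[0], : k[1], : k[2]] = kernel
    for ax, n in zip((-3, -2, -1), k):
        out = np.roll(out, -(n // 2), axis=ax)
    return out


def kernel_otfs(kernels: np.ndarray, pshape: tuple) -> np.ndarray:
    """rfftn of centered kernels; leading axes are batch axes.

    Precision follows the input dtype (float32 → complex64).
    """
    kernels = np.asarray(kernels)
    if kernels.dtype not in (np.float32, np.float64):
        kernels = kernels.astype(np.float32)
    embedded = _center_kernel(kernels, pshape)
    out = sfft.rfftn(embedded, axes=(-3, -2, -1))
    return out.astype(np.complex64 if kernels.dtype == np.float32 else np.complex128)


def volume_rfft(vol: np.ndarray, pshape: tuple) -> np.ndarray:
    return sfft.rfftn(vol, s=pshape, axes=(-3, -2, -1))


def volume_irfft(spec: np.ndarray, pshape: tuple, out_shape: tuple) -> np.ndarray:
    full = sfft.irfftn(spec, s=pshape, axes=(-3, -2, -1))
    return full[..., : out_shape[0], : out_shape[1], : out_shape[2]]
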