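"""Tiny numpy autodiff engine powering the dual-branch network."""

import ctypes as _ctypes


def _tune_allocator() -> None:
    """Keep large allocations on the heap instead of mmap.

    Training allocates many multi-megabyte temporaries per step; with
    glibc's default mmap threshold each one is returned to the kernel on
    free and re-zeroed on the next allocation, which dominates runtime.
    Raising the mmap/trim thresholds lets the allocator recycle those
    blocks. Best-effort: silently skipped on non-glibc platforms.
    """
    try:
        libc = _ctypes.CDLL("libc.so.6", use_errno=True)
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
    except (OSError, AttributeError):  # pragma: no cover
        pass


_tune_allocator()

from .optim import Adam
from .tensor import (
    Tensor,
    add,
    concat_channels,
    conv2d,
    instance_norm,
    relu,
    smooth3,
    softmax_channels,
    upsample2x,
)

__all__ = ["Tensor", "Adam", "conv2d", "relu", "add", "upsample2x", "smooth3",
           "concat_channels", "instance_norm", "softmax_channels"]
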