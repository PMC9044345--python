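"""A compact numpy reverse-mode tensor engine for the denoising networks."""

import ctypes as _ctypes
import sys as _sys


_LIBC = None


def _tune_allocator() -> None:
    # Training allocates many short-lived multi-MB feature maps; with glibc's
    # default mmap threshold each one is a fresh mmap/munmap whose page faults
    # dominate the runtime.  Keeping large blocks on the heap lets them be
    # reused.  Best-effort: silently skipped off glibc/Linux.
    global _LIBC
    if not _sys.platform.startswith("linux"):
        return
    try:
        libc = _ctypes.CDLL("libc.so.6", use_errno=True)
        # 64 MB: hot feature maps (a few MB) stay on the reusable heap; rare
        # huge blocks (full-width weight tensors) go to mmap and are returned
        # to the OS on free instead of fragmenting the heap
        libc.mallopt(-3, 64 << 20)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
        _LIBC = libc
    except (OSError, AttributeError):  # pragma: no cover
        pass


def trim_heap() -> None:
    """Return freed heap pages to the OS (glibc malloc_trim; no-op elsewhere).

    The allocator tuning above trades memory growth for speed; long training
    loops call this between epochs to cap the resident-set high-water mark.
    """
    if _LIBC is not None:
        try:
            _LIBC.malloc_trim(0)
        except (OSError, AttributeError):  # pragma: no cover
            pass


_tune_allocator()

from . import autograd
from .autograd import Tensor
from .modules import BatchNorm2d, Conv2d, ConvBNReLU, Module, Parameter
from .optim import Adam
from .serialize import load_config_dict, load_weights, save_checkpoint

__all__ = [
    "autograd",
    "Tensor",
    "Module",
    "Parameter",
    "Conv2d",
    "BatchNorm2d",
    "ConvBNReLU",
    "Adam",
    "save_checkpoint",
    "load_weights",
    "load_config_dict",
]
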