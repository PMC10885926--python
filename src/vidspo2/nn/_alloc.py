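"""glibc allocator tuning for large-array workloads.

The training loops allocate and free many multi-MB activation buffers per
step.  With glibc defaults these exceed the mmap threshold, so every free
returns pages to the OS and every fresh allocation pays page-fault cost,
throttling elementwise numpy ops well below memory bandwidth.  Raising the
mmap/trim thresholds keeps the buffers on the heap for reuse.  Best-effort:
silently skipped on non-glibc platforms.
"""

import ctypes

M_TRIM_THRESHOLD = -1
M_MMAP_THRESHOLD = -3


def tune_allocator(threshold: int = 1 << 30) -> bool:
    try:
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(M_MMAP_THRESHOLD, threshold)
        libc.mallopt(M_TRIM_THRESHOLD, threshold)
        return True
    except (OSError, AttributeError):  # pragma: no cover
        return False
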