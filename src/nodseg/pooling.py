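"""Center-weighted ("central") pooling.

The operator replaces uniform stride-2 max pooling on a nodule-centred axis
of length Q by a tiling of non-uniform max windows: size-1 windows in the
middle (where the nodule sits, preserving detail), size-3 windows at the
edges (discarding periphery aggressively), size-2 windows in between.  The
window counts (n1, n2, n3) for sizes (1, 2, 3) are the unique non-negative
integer solution of

    n1 + 2*n2 + 3*n3 = Q        (the windows tile the axis)
    n1 +   n2 +   n3 = Q/2      (the axis is halved, like stride-2 pooling)
    n1 +   n3        = n2       (half of all windows have size 2)

whose closed form is (Q/8, Q/4, Q/8); Q must therefore be divisible by 8.
For Q = 64 this gives (8, 16, 8) and for Q = 8 it gives (1, 2, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "solve_kernel_counts", "enumerate_kernel_counts", "build_partition",
    "PoolingPartition", "central_pool_1d", "central_pool_2d", "central_pool_3d",
]


class NoIntegerSolutionError(ValueError):
    pass


def solve_kernel_counts(Q: int) -> tuple[int, int, int]:
    """Closed-form window counts (n1, n2, n3) for an axis of length Q."""
    if Q <= 0:
        raise ValueError(f"axis length must be positive, got {Q}")
    if Q % 8 != 0:
        raise NoIntegerSolutionError(
            f"no non-negative integer window counts exist for Q={Q}: the unique "
            f"solution of the constraint system is (Q/8, Q/4, Q/8), which "
            f"requires Q divisible by 8")
    return (Q // 8, Q // 4, Q // 8)


def enumerate_kernel_counts(Q: int) -> list[tuple[int, int, int]]:
    """All solutions of the constraint system by exhaustive search.

    Brute force over every triple in 0..Q; used as the independent
    cross-check of :func:`solve_kernel_counts`.
    """
    out = []
    for n1 in range(Q + 1):
        for n2 in range(Q + 1):
            n3 = Q // 2 - n1 - n2
            if n3 < 0 or n3 > Q:
                continue
            if (n1 + 2 * n2 + 3 * n3 == Q and 2 * (n1 + n2 + n3) == Q
                    and n1 + n3 == n2):
                out.append((n1, n2, n3))
    return out


@dataclass(frozen=True)
class PoolingPartition:
    """Ordered max-window sizes tiling one axis of length Q."""

    axis_length: int
    counts: tuple[int, int, int]
    layout: tuple[int, ...]
    starts: np.ndarray = field(repr=False, compare=False, default=None)
    sizes: np.ndarray = field(repr=False, compare=False, default=None)

    def to_dict(self):
        return {"axis_length": self.axis_length,
                "counts": {"size1": self.counts[0], "size2": self.counts[1],
                           "size3": self.counts[2]},
                "layout": list(self.layout)}


def build_partition(Q: int) -> PoolingPartition:
    """Centrally symmetric layout: 3s outermost, then 2s, size-1 in the middle.

    When the count of a window size is odd the extra window is placed on the
    leading (low-index) side.
    """
    n1, n2, n3 = solve_kernel_counts(Q)
    lead3, trail3 = (n3 + 1) // 2, n3 // 2
    lead2, trail2 = (n2 + 1) // 2, n2 // 2
    layout = (3,) * lead3 + (2,) * lead2 + (1,) * n1 + (2,) * trail2 + (3,) * trail3
    sizes = np.asarray(layout, dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    return PoolingPartition(Q, (n1, n2, n3), layout, starts, sizes)


def central_pool_1d(values, partition: PoolingPartition):
    """Max over each layout window of a length-Q axis (axis must be last)."""
    values = np.asarray(values)
    if values.shape[-1] != partition.axis_length:
        raise ValueError(
            f"axis length {values.shape[-1]} does not match partition "
            f"Q={partition.axis_length}")
    return _pool_last_axis(values, partition)


def _pool_last_axis(arr, partition):
    s, k = partition.starts, partition.sizes
    cands = [np.take(arr, s, axis=-1),
             np.take(arr, s + np.minimum(1, k - 1), axis=-1),
             np.take(arr, s + k - 1, axis=-1)]
    return np.maximum.reduce(cands)


def central_pool_2d(plane):
    """Separable 2D central pooling of a QxQ plane -> (Q/2)x(Q/2).

    Applied along rows then columns with the same partition; each output
    cell is the max over the Cartesian product of its two axis windows.
    Leading axes (channels, slices) are broadcast.
    """
    plane = np.asarray(plane)
    q = plane.shape[-1]
    if plane.shape[-2] != q:
        raise ValueError(f"plane must be square, got {plane.shape[-2:]}")
    part = build_partition(q)
    out = _pool_last_axis(plane, part)
    out = _pool_last_axis(np.swapaxes(out, -1, -2), part)
    return np.swapaxes(out, -1, -2)


def central_pool_3d(block):
    """3D central pooling of (..., Z, Q, Q) feature maps.

    2D central pooling is applied within every slice; the slice axis is
    itself centrally pooled only when Z is divisible by 8 (the solvability
    condition), otherwise it is left unpooled so an 11-slice stack keeps
    its 2.5D structure.
    """
    block = np.asarray(block)
    out = central_pool_2d(block)
    z = block.shape[-3]
    if z % 8 == 0:
        part = build_partition(z)
        out = np.moveaxis(_pool_last_axis(np.moveaxis(out, -3, -1), part), -1, -3)
    return out
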