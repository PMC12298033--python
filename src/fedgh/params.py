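"""Flat parameter vectors with a named-slice layout.

Every aggregation strategy in this package operates on a single flat
``float64`` vector per model.  The :class:`Layout` records, for each layer
tensor, its name, offset into the flat vector and shape, so that the flat
representation and the per-layer dictionary representation are exactly
inter-convertible (a bijection, tested as such).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np

__all__ = ["Layout", "ParamVector", "ClientUpdate", "LayoutMismatchError"]


class LayoutMismatchError(ValueError):
    """Two parameter vectors with different layouts were combined."""


@dataclass(frozen=True)
class Layout:
    """Ordered (name, offset, shape) slice map over a flat vector."""

    entries: tuple[tuple[str, int, tuple[int, ...]], ...]

    @classmethod
    def from_shapes(cls, shapes: Mapping[str, tuple[int, ...]]) -> "Layout":
        entries = []
        offset = 0
        for name, shape in shapes.items():
            entries.append((name, offset, tuple(shape)))
            offset += int(np.prod(shape, dtype=np.int64)) if shape else 1
        return cls(tuple(entries))

    @property
    def size(self) -> int:
        if not self.entries:
            return 0
        name, offset, shape = self.entries[-1]
        return offset + int(np.prod(shape, dtype=np.int64))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.entries)

    def slice_of(self, name: str) -> slice:
        for n, offset, shape in self.entries:
            if n == name:
                return slice(offset, offset + int(np.prod(shape, dtype=np.int64)))
        raise KeyError(name)

    def shape_of(self, name: str) -> tuple[int, ...]:
        for n, _, shape in self.entries:
            if n == name:
                return shape
        raise KeyError(name)

    def __iter__(self) -> Iterator[tuple[str, int, tuple[int, ...]]]:
        return iter(self.entries)


@dataclass
class ParamVector:
    """A model's parameters as one flat vector plus its layout."""

    values: np.ndarray
    layout: Layout

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size != self.layout.size:
            raise LayoutMismatchError(
                f"vector has {self.values.size} entries, layout expects {self.layout.size}"
            )

    @classmethod
    def from_arrays(cls, arrays: Mapping[str, np.ndarray]) -> "ParamVector":
        """Flatten a name→tensor dictionary into a single vector."""
        layout = Layout.from_shapes({k: v.shape for k, v in arrays.items()})
        values = np.concatenate([np.asarray(v, dtype=np.float64).ravel() for v in arrays.values()]) \
            if arrays else np.zeros(0)
        return cls(values, layout)

    def to_arrays(self) -> dict[str, np.ndarray]:
        """Inverse of :meth:`from_arrays`; reshapes each slice to its tensor."""
        out = {}
        for name, offset, shape in self.layout:
            n = int(np.prod(shape, dtype=np.int64))
            out[name] = self.values[offset : offset + n].reshape(shape).copy()
        return out

    def check_same_layout(self, other: "ParamVector") -> None:
        if self.layout != other.layout:
            raise LayoutMismatchError("parameter layouts differ")

    def copy(self) -> "ParamVector":
        return ParamVector(self.values.copy(), self.layout)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class ClientUpdate:
    """One client's contribution to a round: post-training parameters,
    its local sample count, and (optionally) its local validation loss
    used by quality-weighted aggregation."""

    client_id: int
    params: ParamVector
    n_samples: int
    val_loss: float | None = None
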