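"""Binned cis contact matrices with sparse triplet text I/O.

A :class:`ContactMatrix` is a symmetric, upper-triangular-stored map of
``(bin_i, bin_j)`` (``i <= j``) to a non-negative, possibly fractional
count.  The on-disk form is a plain triplet text file::

    # duphic contact matrix
    # bin_size=5000
    # n_bins=200
    bin_i<TAB>bin_j<TAB>count

which keeps fixtures diff-able and free of binary formats.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["ContactMatrix", "read_triplet", "write_triplet"]


class ContactMatrix:
    """Symmetric binned contact map with fractional counts.

    Entries are stored upper-triangular (``i <= j``); the diagonal is
    stored once.  ``mass`` is the sum over stored entries, i.e. each
    contact (read) contributes exactly once.
    """

    __slots__ = ("bin_size", "n_bins", "_entries")

    def __init__(self, bin_size: int, n_bins: int, entries: dict | None = None):
        if bin_size <= 0 or n_bins <= 0:
            raise ValueError("bin_size and n_bins must be positive")
        self.bin_size = int(bin_size)
        self.n_bins = int(n_bins)
        self._entries: dict[tuple[int, int], float] = {}
        if entries:
            for (i, j), c in entries.items():
                self.add(i, j, c)

    # -- mutation -----------------------------------------------------
    def add(self, i: int, j: int, count: float = 1.0) -> None:
        if count < 0:
            raise ValueError("counts must be non-negative")
        i, j = (int(i), int(j)) if i <= j else (int(j), int(i))
        if not (0 <= i <= j < self.n_bins):
            raise IndexError(f"bin pair ({i},{j}) outside [0,{self.n_bins})")
        if count == 0:
            return
        self._entries[(i, j)] = self._entries.get((i, j), 0.0) + float(count)

    # -- access -------------------------------------------------------
    def get(self, i: int, j: int) -> float:
        i, j = (i, j) if i <= j else (j, i)
        return self._entries.get((i, j), 0.0)

    @property
    def entries(self) -> dict[tuple[int, int], float]:
        return dict(self._entries)

    @property
    def mass(self) -> float:
        return float(sum(self._entries.values()))

    def __len__(self) -> int:
        return len(self._entries)

    def copy(self) -> "ContactMatrix":
        out = ContactMatrix(self.bin_size, self.n_bins)
        out._entries = dict(self._entries)
        return out

    def to_dense(self) -> np.ndarray:
        """Full symmetric dense array; diagonal entries appear once."""
        a = np.zeros((self.n_bins, self.n_bins))
        for (i, j), c in self._entries.items():
            a[i, j] = c
            if i != j:
                a[j, i] = c
        return a

    @classmethod
    def from_dense(cls, a: np.ndarray, bin_size: int) -> "ContactMatrix":
        a = np.asarray(a, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("expected a square matrix")
        if not np.allclose(a, a.T):
            raise ValueError("expected a symmetric matrix")
        out = cls(bin_size, a.shape[0])
        ii, jj = np.nonzero(np.triu(a))
        for i, j in zip(ii.tolist(), jj.tolist()):
            out._entries[(i, j)] = float(a[i, j])
        return out

    def row_sums(self) -> np.ndarray:
        """Per-bin total contact coverage (symmetric marginal)."""
        s = np.zeros(self.n_bins)
        for (i, j), c in self._entries.items():
            s[i] += c
            if i != j:
                s[j] += c
        return s


def write_triplet(matrix: ContactMatrix, path: str | Path) -> Path:
    path = Path(path)
    lines = ["# duphic contact matrix",
             f"# bin_size={matrix.bin_size}",
             f"# n_bins={matrix.n_bins}"]
    for (i, j) in sorted(matrix._entries):
        lines.append(f"{i}\t{j}\t{matrix._entries[(i, j)]!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_triplet(path: str | Path) -> ContactMatrix:
    path = Path(path)
    bin_size = n_bins = None
    entries: dict[tuple[int, int], float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if "=" in body:
                key, _, val = body.partition("=")
                if key == "bin_size":
                    bin_size = int(val)
                elif key == "n_bins":
                    n_bins = int(val)
            continue
        i_s, j_s, c_s = line.split("\t")
        entries[(int(i_s), int(j_s))] = float(c_s)
    if bin_size is None or n_bins is None:
        raise ValueError(f"{path}: missing bin_size/n_bins header")
    out = ContactMatrix(bin_size, n_bins)
    for (i, j), c in entries.items():
        out.add(i, j, c)
    return out
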