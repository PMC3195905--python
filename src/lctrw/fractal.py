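"""Generalized Sierpinski carpet (GSC) supports.

A support is defined by a generator mask: a boolean ``ν × ν`` (2-D) or
``ν × ν × ν`` (3-D) grid of allowed cells, of which at most half may be
deleted.  The fractal is the ``k_max``-fold self-similar iteration of the
generator.  Supports are *virtual*: accessibility of a lattice site is
decided on demand by stage-wise coarse-graining (renormalization), never by
materializing the full lattice.

The accessibility rule: a point with non-negative integer coordinates
belongs to iteration stage ``k`` when its largest coordinate lies in
``[ν^(k-1), ν^k)``.  Starting from that stage, the coarse cell
``floor(x / ν^(k-1))`` must be allowed in the generator; the remainder
``x mod ν^(k-1)`` is carried to stage ``k-1``, and so on down to stage 1.
A site is accessible iff it survives every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GeneratorMask",
    "FractalSupport",
    "stage_of",
    "is_accessible",
    "enumerate_accessible",
    "standard_carpet_mask",
    "full_mask",
]

# Refuse exhaustive enumeration beyond this many lattice sites.
_ENUMERATION_LIMIT = 10**7


@dataclass(frozen=True)
class GeneratorMask:
    """Generator of a generalized Sierpinski carpet.

    Parameters
    ----------
    nu
        Linear subdivision base ``ν ≥ 2``.
    allowed
        Boolean array of shape ``(ν,)*dim`` (dim 2 or 3); ``True`` marks an
        accessible cell.  At most half of the cells may be deleted.
    """

    nu: int
    allowed: np.ndarray

    def __post_init__(self) -> None:
        allowed = np.asarray(self.allowed, dtype=bool)
        object.__setattr__(self, "allowed", allowed)
        if self.nu < 2:
            raise ValueError(f"base ν must be ≥ 2, got {self.nu}")
        if allowed.ndim not in (2, 3):
            raise ValueError("generator mask must be 2- or 3-dimensional")
        if allowed.shape != (self.nu,) * allowed.ndim:
            raise ValueError(
                f"mask shape {allowed.shape} does not match ν={self.nu}"
            )
        n_cells = allowed.size
        n_deleted = n_cells - int(allowed.sum())
        if n_deleted > n_cells // 2:
            raise ValueError(
                f"{n_deleted} of {n_cells} cells deleted; a GSC generator "
                "may delete at most half"
            )
        if not allowed.any():
            raise ValueError("generator must keep at least one cell")

    @property
    def dim(self) -> int:
        return self.allowed.ndim

    @property
    def n_allowed(self) -> int:
        return int(self.allowed.sum())

    # -- text format: rows of '0'/'1'; 3-D masks are ν blank-line-separated
    #    blocks of ν rows each (block index = first coordinate).

    @classmethod
    def from_text(cls, text: str) -> "GeneratorMask":
        blocks: list[list[str]] = [[]]
        for line in text.splitlines():
            line = line.strip()
            if not line:
                if blocks[-1]:
                    blocks.append([])
                continue
            blocks[-1].append(line)
        if blocks and not blocks[-1]:
            blocks.pop()
        if not blocks:
            raise ValueError("empty mask text")
        grids = []
        for rows in blocks:
            grid = np.array(
                [[c == "1" for c in row] for row in rows], dtype=bool
            )
            grids.append(grid)
        arr = grids[0] if len(grids) == 1 else np.array(grids)
        return cls(nu=arr.shape[-1], allowed=arr)

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorMask":
        return cls.from_text(Path(path).read_text())

    def to_text(self) -> str:
        if self.dim == 2:
            return "\n".join(
                "".join("1" if v else "0" for v in row) for row in self.allowed
            ) + "\n"
        blocks = []
        for plane in self.allowed:
            blocks.append(
                "\n".join("".join("1" if v else "0" for v in row) for row in plane)
            )
        return "\n\n".join(blocks) + "\n"


def standard_carpet_mask() -> GeneratorMask:
    """The standard 3×3 Sierpinski carpet generator (center cell deleted)."""
    allowed = np.ones((3, 3), dtype=bool)
    allowed[1, 1] = False
    return GeneratorMask(nu=3, allowed=allowed)


def full_mask(nu: int = 3, dim: int = 2) -> GeneratorMask:
    """An all-allowed generator: the support is the full lattice."""
    return GeneratorMask(nu=nu, allowed=np.ones((nu,) * dim, dtype=bool))


@dataclass(frozen=True)
class FractalSupport:
    """A GSC support iterated to stage ``k_max`` (side length ``ν^k_max``)."""

    generator: GeneratorMask
    k_max: int = 1
    _pows: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValueError("iteration depth k_max must be ≥ 1")
        pows = self.generator.nu ** np.arange(self.k_max + 1, dtype=np.int64)
        object.__setattr__(self, "_pows", pows)

    @property
    def nu(self) -> int:
        return self.generator.nu

    @property
    def dim(self) -> int:
        return self.generator.dim

    @property
    def side(self) -> int:
        """Side length of the bounding box in lattice units."""
        return int(self._pows[self.k_max])

    def in_bounds(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points))
        return ((pts >= 0) & (pts < self.side)).all(axis=-1)

    def accessible(self, points: np.ndarray) -> np.ndarray:
        """Vectorized accessibility test.

        Parameters
        ----------
        points
            Integer array of shape ``(m, dim)`` (or ``(dim,)``).

        Returns
        -------
        Boolean array of shape ``(m,)``.
        """
        pts = np.atleast_2d(np.asarray(points))
        if pts.shape[-1] != self.dim:
            raise ValueError(
                f"points have dimension {pts.shape[-1]}, support is {self.dim}-D"
            )
        if not np.issubdtype(pts.dtype, np.integer):
            if not np.all(pts == np.floor(pts)):
                raise ValueError("lattice coordinates must be integers")
            pts = pts.astype(np.int64)
        if not self.in_bounds(pts).all():
            raise ValueError("point outside the support bounding box")
        rem = pts.astype(np.int64).copy()
        ok = np.ones(len(rem), dtype=bool)
        # Coarse-graining only applies from the stage the point belongs to;
        # all-zero leading digits (stages above stage_of) are skipped, and
        # stage 1 is always checked.
        started = np.zeros(len(rem), dtype=bool)
        allowed = self.generator.allowed
        for k in range(self.k_max, 0, -1):
            unit = self._pows[k - 1]
            digit = rem // unit
            rem -= digit * unit
            started |= (digit != 0).any(axis=-1)
            check = started | (k == 1)
            cell_ok = allowed[tuple(digit.T)]
            ok &= cell_ok | ~check
        return ok


def random_accessible_sites(
    support: FractalSupport, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``n`` uniformly random accessible sites by rejection.

    At most half of the generator cells are deleted, so the acceptance rate
    is at least ``2^{-k_max}``; in practice a handful of rounds suffice.
    """
    out = np.empty((n, support.dim), dtype=np.int64)
    filled = 0
    while filled < n:
        cand = rng.integers(0, support.side, size=(2 * (n - filled) + 8, support.dim))
        good = cand[support.accessible(cand)][: n - filled]
        out[filled : filled + len(good)] = good
        filled += len(good)
    return out


def stage_of(point, nu: int) -> int:
    """Iteration stage a point belongs to: smallest ``k ≥ 1`` with all
    coordinates below ``ν^k`` (largest coordinate in ``[ν^(k-1), ν^k)``)."""
    coords = np.asarray(point)
    if not np.issubdtype(coords.dtype, np.integer):
        if not np.all(coords == np.floor(coords)):
            raise ValueError("coordinates must be integers")
        coords = coords.astype(np.int64)
    if (coords < 0).any():
        raise ValueError("coordinates must be non-negative")
    m = int(coords.max())
    k = 1
    while m >= nu**k:
        k += 1
    return k


def is_accessible(point, support: FractalSupport) -> bool:
    """Scalar accessibility query (stage-wise coarse-graining)."""
    return bool(support.accessible(np.asarray(point))[0])


def enumerate_accessible(support: FractalSupport, k: int) -> int:
    """Exhaustively count accessible sites in ``[0, ν^k)^dim``.

    Intended as a test oracle for the on-demand rule; refuses lattices
    larger than ~10⁷ sites.
    """
    if k < 1 or k > support.k_max:
        raise ValueError(f"stage k must be in [1, {support.k_max}]")
    side = support.nu**k
    total = side**support.dim
    if total > _ENUMERATION_LIMIT:
        raise ValueError(
            f"enumeration of {total} sites exceeds the {_ENUMERATION_LIMIT} limit"
        )
    grids = np.indices((side,) * support.dim).reshape(support.dim, -1).T
    return int(support.accessible(grids).sum())
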