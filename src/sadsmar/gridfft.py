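"""Real/reciprocal-space transforms on periodic unit-cell grids.

Conventions: density is synthesized as

    rho(x) = sum_H [ F_H exp(-2 pi i H.x) + conj(F_H) exp(+2 pi i H.x) ]

over a Friedel hemisphere of reflections, so an atom contributing
f exp(+2 pi i H.r) to F_H produces a positive peak at x = r.  The
analysis direction returns exactly the coefficients that were put in
(machine precision), which the recycling engine relies on.

Grids are 0-based with node (0,0,0) at the cell origin; dimensions are
2,3,5-smooth and chosen so the node spacing is at most dmin/3.
"""

from __future__ import annotations

import numpy as np
import gemmi

__all__ = ["smooth_235", "grid_shape", "GridTransform", "expand_to_p1_hemisphere",
           "hemisphere_canonical"]


def smooth_235(n: int) -> int:
    """Smallest 2,3,5-smooth integer >= n."""
    best = 1 << (max(n, 1) - 1).bit_length()   # fallback power of two
    p5 = 1
    while p5 < best:
        p35 = p5
        while p35 < best:
            p2 = p35
            while p2 < n:
                p2 *= 2
            best = min(best, p2)
            p35 *= 3
        p5 *= 5
    return best


def grid_shape(cell: gemmi.UnitCell, dmin: float, factor: float = 3.0) -> tuple:
    """FFT-friendly grid dimensions with spacing <= dmin/factor."""
    if dmin <= 0:
        raise ValueError("dmin must be positive")
    return tuple(
        smooth_235(int(np.ceil(length * factor / dmin)))
        for length in (cell.a, cell.b, cell.c)
    )


def hemisphere_canonical(hkl: np.ndarray) -> tuple:
    """Map each reflection to the canonical Friedel hemisphere.

    Returns (hkl_canonical, flipped) where ``flipped`` marks reflections
    that were negated (their coefficients must be conjugated)."""
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    h, k, l = hkl[:, 0], hkl[:, 1], hkl[:, 2]
    flip = (l < 0) | ((l == 0) & (k < 0)) | ((l == 0) & (k == 0) & (h < 0))
    out = np.where(flip[:, None], -hkl, hkl)
    return out, flip


class GridTransform:
    """Precomputed mapping between a hemisphere reflection list and a
    periodic FFT grid; synthesize() and analyse() are exact inverses on
    the listed coefficients."""

    def __init__(self, hkl: np.ndarray, shape: tuple):
        hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
        self.hkl = hkl
        self.shape = tuple(int(n) for n in shape)
        nx, ny, nz = self.shape
        if np.any(np.abs(hkl) >= np.array([nx, ny, nz]) // 2):
            raise ValueError("grid too coarse for reflection list (need spacing <= dmin/2)")
        ip = np.ravel_multi_index(
            (hkl[:, 0] % nx, hkl[:, 1] % ny, hkl[:, 2] % nz), self.shape
        )
        im = np.ravel_multi_index(
            ((-hkl[:, 0]) % nx, (-hkl[:, 1]) % ny, (-hkl[:, 2]) % nz), self.shape
        )
        if len(np.unique(ip)) != len(ip):
            raise ValueError("duplicate reflections in list")
        if np.intersect1d(ip, im).size:
            raise ValueError("list contains Friedel-degenerate reflections (both +H and -H)")
        self._ip, self._im = ip, im

    def synthesize(self, coeffs: np.ndarray) -> np.ndarray:
        """Hemisphere coefficients -> real density grid."""
        g = np.zeros(self.shape, dtype=complex).ravel()
        g[self._ip] = coeffs
        g[self._im] = np.conj(coeffs)
        return np.fft.fftn(g.reshape(self.shape)).real

    def analyse(self, rho: np.ndarray) -> np.ndarray:
        """Real density grid -> hemisphere coefficients."""
        g = np.fft.ifftn(rho).ravel()
        return g[self._ip]


def expand_to_p1_hemisphere(hkl: np.ndarray, spacegroup: str,
                            values: dict | None = None):
    """Expand symmetry-unique reflections to the P1 Friedel hemisphere.

    Each unique reflection H is mapped through every rotational symmetry
    operation; the resulting indices are reduced to the canonical
    hemisphere and de-duplicated.  Friedel-symmetric per-reflection
    quantities in ``values`` (amplitudes, X, sigmas...) are copied to
    every image.  Returns (hkl_p1, parent_index, dphi, flip [, expanded])
    with the image phase given by

        phi_image = (-1 if flip else +1) * (phi_parent + dphi),

    dphi being the symmetry phase shift in radians and ``flip`` marking
    images stored as their Friedel mate (conjugated coefficient).
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    ops = gemmi.SpaceGroup(spacegroup).operations()
    all_hkl, parent, shift, flips = [], [], [], []
    for op in ops:
        new = np.array([op.apply_to_hkl(list(h)) for h in hkl], dtype=int)
        dphi = np.array([op.phase_shift(list(h)) for h in hkl], dtype=float)
        can, flip = hemisphere_canonical(new)
        all_hkl.append(can)
        parent.append(np.arange(len(hkl)))
        shift.append(dphi)
        flips.append(flip)
    all_hkl = np.concatenate(all_hkl)
    parent = np.concatenate(parent)
    shift = np.concatenate(shift)
    flips = np.concatenate(flips)
    _, keep = np.unique(all_hkl, axis=0, return_index=True)
    keep = np.sort(keep)
    all_hkl, parent, shift, flips = all_hkl[keep], parent[keep], shift[keep], flips[keep]
    if values is None:
        return all_hkl, parent, shift, flips
    expanded = {k: np.asarray(v)[parent] for k, v in values.items()}
    return all_hkl, parent, shift, flips, expanded
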