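"""Post-refinement Fourier recycling, peak interpretation and scoring.

After SMAR converges, phases are polished by classical Fourier
recycling using the Gamma amplitudes

    Gamma = [K eps sum_j sigma''_j^2 exp(-2 B s^2)]^(1/2) * X,

i.e. X put back on an absolute-like scale so the map behaves like a
substructure electron density.  Each recycling cycle synthesizes the
map, picks the strongest peaks (twice the expected site count by
default -- generous enough that a partially superposed solution keeps
its dominant copy alive), and recomputes model phases by direct
summation over the picked peaks with strengths proportional to their
heights.  Peak heights are always reported in rho_peak/sigma units, so
they are invariant under global map scaling.

The final model is scored with the correlation-based residual
R_CC = 100 * (1 - CC(X, X_calc)) over the reflections with X >= 0.7.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

import gemmi

from .gridfft import GridTransform
from .reflection_io import SubstructureModel

__all__ = [
    "gamma_amplitudes",
    "fourier_recycle",
    "peak_search",
    "estimate_occupancies",
    "r_cc",
    "model_structure_factors",
    "DEFAULT_PEAK_SIGMA",
]

DEFAULT_PEAK_SIGMA = 5.0


def gamma_amplitudes(x: np.ndarray, s: np.ndarray, epsilon: np.ndarray,
                     k: float, b: float, sigma_dprime: np.ndarray) -> np.ndarray:
    """Gamma = sqrt(K eps sum sigma''^2 exp(-2 B s^2)) * X."""
    if k <= 0:
        raise ValueError("K must be positive")
    sum_s2dp = float(np.sum(np.asarray(sigma_dprime, dtype=float) ** 2))
    pref = np.sqrt(k * np.asarray(epsilon, dtype=float) * sum_s2dp
                   * np.exp(-2.0 * b * np.asarray(s, dtype=float) ** 2))
    return pref * np.asarray(x, dtype=float)


def model_structure_factors(hkl: np.ndarray, frac: np.ndarray,
                            weights: np.ndarray) -> np.ndarray:
    """Direct summation F(H) = sum_i w_i exp(+2 pi i H.r_i) over sites."""
    phase = np.exp(2j * np.pi * (np.asarray(hkl) @ np.asarray(frac).T))
    return phase @ np.asarray(weights, dtype=float)


def peak_search(rho: np.ndarray, cell: gemmi.UnitCell, spacegroup: str = "P 1",
                sigma_cutoff: float = DEFAULT_PEAK_SIGMA,
                merge_tol: float = 0.5,
                max_peaks: int | None = None) -> SubstructureModel:
    """Local maxima of a periodic map above ``sigma_cutoff`` (in
    rho_peak/sigma units), with sub-node positions from per-axis
    quadratic interpolation and symmetry-equivalent peaks (within
    ``merge_tol`` Angstrom) reduced to the highest representative."""
    sigma = float(np.std(rho))
    if sigma == 0.0:
        return SubstructureModel(frac=np.zeros((0, 3)))
    footprint = ndimage.maximum_filter(rho, size=3, mode="wrap")
    is_max = (rho >= footprint) & (rho / sigma >= sigma_cutoff)
    nodes = np.argwhere(is_max)
    if len(nodes) == 0:
        return SubstructureModel(frac=np.zeros((0, 3)))
    nodes = nodes[np.argsort(-rho[tuple(nodes.T)])]
    shape = np.array(rho.shape)

    ops = gemmi.SpaceGroup(spacegroup).operations()
    op_list = [(np.array(op.rot) / op.DEN, np.array(op.tran) / op.DEN)
               for op in ops]
    orth = np.array(cell.orth.mat.tolist())

    def interpolate(node):
        offset = np.zeros(3)
        value = rho[tuple(node)]
        height = value
        for axis in range(3):
            lo = node.copy(); lo[axis] = (lo[axis] - 1) % shape[axis]
            hi = node.copy(); hi[axis] = (hi[axis] + 1) % shape[axis]
            fm, fp = rho[tuple(lo)], rho[tuple(hi)]
            denom = fm - 2.0 * value + fp
            if denom < 0:
                off = float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))
                offset[axis] = off
                height += -0.25 * (fm - fp) * off  # parabola apex correction
        return np.mod((node + offset) / shape, 1.0), height / sigma

    kept_f, kept_h = [], []
    for node in nodes:
        f, h = interpolate(node)
        if kept_f:
            arr = np.array(kept_f)
            dup = False
            for rot, tran in op_list:
                d = arr - (rot @ f + tran)
                d -= np.round(d)
                if np.any(np.linalg.norm(d @ orth.T, axis=1) < merge_tol):
                    dup = True
                    break
            if dup:
                continue
        kept_f.append(f)
        kept_h.append(h)
        if max_peaks is not None and len(kept_f) >= max_peaks:
            break
    return SubstructureModel(frac=np.array(kept_f).reshape(-1, 3),
                             height=np.array(kept_h))


def fourier_recycle(hkl: np.ndarray, gamma: np.ndarray, phases: np.ndarray,
                    cell: gemmi.UnitCell, shape: tuple, n_expected: int,
                    n_cycles: int = 5, peak_factor: float = 2.0,
                    sigma_cutoff: float = 1.0):
    """Fourier recycling of substructure phases (typically 5-10 cycles).

    Returns (final map, final phases).  Raises if a cycle finds no
    peaks, which indicates the trial had not actually converged.
    """
    gt = GridTransform(np.asarray(hkl, dtype=int), shape)
    phases = np.asarray(phases, dtype=float).copy()
    n_pick = max(1, int(round(peak_factor * n_expected)))
    rho = gt.synthesize(gamma * np.exp(1j * phases))
    for _ in range(n_cycles):
        rho = gt.synthesize(gamma * np.exp(1j * phases))
        peaks = peak_search(rho, cell, "P 1", sigma_cutoff=sigma_cutoff,
                            max_peaks=n_pick)
        if len(peaks) == 0:
            raise RuntimeError(
                "no map peaks above threshold: the source trial "
                "probably did not converge"
            )
        sel = slice(0, min(n_pick, len(peaks)))
        f_model = model_structure_factors(hkl, peaks.frac[sel], peaks.height[sel])
        phases = np.angle(f_model)
    return rho, phases


def estimate_occupancies(model: SubstructureModel, reference_total: float) -> SubstructureModel:
    """Occupancies by normalizing the sum of peak heights to the known
    total scatterer content; values above 1 are truncated to 1.00."""
    if reference_total <= 0:
        raise ValueError("reference total must be positive")
    if len(model) == 0:
        raise ValueError("no sites to assign occupancies to")
    occ = model.height * reference_total / model.height.sum()
    model.occupancy = np.minimum(occ, 1.0)
    return model


def r_cc(x_exp: np.ndarray, x_calc: np.ndarray, threshold: float = 0.7) -> float:
    """Correlation-based residual 100 * (1 - CC) over X >= threshold."""
    x_exp = np.asarray(x_exp, dtype=float)
    x_calc = np.asarray(x_calc, dtype=float)
    sel = x_exp >= threshold
    if not np.any(sel) or len(x_exp[sel]) < 2:
        raise ValueError(f"no reflections with X >= {threshold}")
    cc = np.corrcoef(x_exp[sel], x_calc[sel])[0, 1]
    return float(100.0 * (1.0 - cc))
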