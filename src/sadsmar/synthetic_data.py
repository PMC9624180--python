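"""Protein-like synthetic crystals and noisy Bijvoet-pair data sets.

The generator emulates the regime SAD substructure solvers face: a unit
cell packed with many weak "light" atoms (carbon-like, f0 = 6) plus a
few strong, well separated anomalous scatterers, isotropic displacement,
and independent Gaussian noise on the |F+| and |F-| amplitudes whose
true sigma is recorded with the data.  Ground truth (the anomalous
sites) is returned alongside, so recovery can be scored exactly.

Presets mirror the standard experimental regimes:

========================  =====================================================
``se_like_small``         8 Se-like sites (f'' = 3.9) among 400 light atoms in
                          a 40 x 50 x 60 A cell, B = 15 A^2, dmin = 2.5 A; a
                          compact cell with a strong signal, sized for
                          desk-scale recovery runs.
``se_like``               the same sites among 1200 light atoms: a realistic
                          protein:substructure scattering ratio whose Bijvoet
                          ratio falls in the 0.012-0.070 envelope typical of
                          experimental SAD data.
``s_like_weak``           3 sulfur-like sites (f'' = 1.1), weak-signal S-SAD.
``iodide_like``           6 iodide-like sites (f'' = 6.9) with occupancies
                          graded over [0.3, 1.0], as after a halide soak.
``tiny``                  2 sites among 30 light atoms; smoke-test sized.
========================  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .reflection_io import ReflectionSet, SubstructureModel, logger
from .sf_oracle import AtomSite, CrystalModel, structure_factor_arrays, unique_reflections

__all__ = ["FixtureSpec", "generate_crystal", "simulate_dataset", "make_fixture",
           "PRESETS"]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic crystal + data set."""

    cell: tuple = (40.0, 50.0, 60.0, 90.0, 90.0, 90.0)
    spacegroup: str = "P 1"
    n_light: int = 400
    n_anom: int = 8
    anom_element: str = "Se"
    anom_f0: float = 34.0
    anom_f_prime: float = 0.0
    anom_f_dprime: float = 3.9
    anom_occupancies: np.ndarray | None = None
    light_f0: float = 6.0
    b_range: tuple = (15.0, 15.0)
    dmin: float = 2.5
    noise_fraction: float = 0.05
    min_distance: float = 1.5
    min_as_separation: float = 7.0
    seed: int = 2022

    def __post_init__(self) -> None:
        if self.n_anom < 1:
            raise ValueError("need at least one anomalous scatterer")
        if self.noise_fraction < 0:
            raise ValueError("noise fraction must be >= 0")
        if self.min_as_separation <= self.dmin:
            raise ValueError("anomalous-scatterer separation must exceed dmin")
        if self.anom_occupancies is not None:
            self.anom_occupancies = np.asarray(self.anom_occupancies, dtype=float)
            if len(self.anom_occupancies) != self.n_anom:
                raise ValueError("one occupancy per anomalous site required")

    @property
    def gemmi_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.cell)


def _min_image_dist(cell: gemmi.UnitCell, frac_a: np.ndarray, frac_b: np.ndarray) -> np.ndarray:
    """Periodic Cartesian distances between one point and an array of points."""
    d = frac_b - frac_a
    d -= np.round(d)
    orth = np.array(cell.orth.mat.tolist())
    return np.linalg.norm(d @ orth.T, axis=-1)


def _place(rng, cell, n, min_self, existing, min_existing, label, max_tries=5000):
    placed = list(existing)
    n_existing = len(existing)
    out = []
    for _ in range(n):
        for attempt in range(max_tries):
            cand = rng.uniform(0.0, 1.0, 3)
            arr = np.array(placed) if placed else np.zeros((0, 3))
            if len(arr):
                dist = _min_image_dist(cell, cand, arr)
                lim = np.full(len(arr), min_self)
                lim[:n_existing] = min_existing
                if np.any(dist < lim):
                    continue
            placed.append(cand)
            out.append(cand)
            break
        else:
            raise RuntimeError(
                f"could not place {label} atom after {max_tries} tries; "
                f"minimum-distance constraint ({min_self:.2f} A) too tight"
            )
    return np.array(out).reshape(-1, 3)


def generate_crystal(spec: FixtureSpec) -> CrystalModel:
    """Random model satisfying the packing constraints; deterministic per seed.

    Anomalous sites are placed first with the (larger) mutual separation
    ``min_as_separation``; light atoms follow with the generic
    ``min_distance`` to everything already placed.
    """
    rng = np.random.default_rng(spec.seed + 1)
    cell = spec.gemmi_cell
    as_frac = _place(rng, cell, spec.n_anom, spec.min_as_separation,
                     np.zeros((0, 3)), spec.min_as_separation, "anomalous")
    light_frac = _place(rng, cell, spec.n_light, spec.min_distance,
                        as_frac, spec.min_distance, "light")
    b_lo, b_hi = spec.b_range
    occ = (spec.anom_occupancies if spec.anom_occupancies is not None
           else np.ones(spec.n_anom))
    atoms = [
        AtomSite(element=spec.anom_element, frac=as_frac[i],
                 occupancy=float(occ[i]),
                 b_iso=float(rng.uniform(b_lo, b_hi)),
                 f0=spec.anom_f0, f_prime=spec.anom_f_prime,
                 f_dprime=spec.anom_f_dprime, anomalous=True)
        for i in range(spec.n_anom)
    ]
    atoms += [
        AtomSite(element="C", frac=light_frac[i],
                 b_iso=float(rng.uniform(b_lo, b_hi)), f0=spec.light_f0)
        for i in range(spec.n_light)
    ]
    return CrystalModel(cell=cell, spacegroup=spec.spacegroup, atoms=atoms)


def simulate_dataset(model: CrystalModel, spec: FixtureSpec) -> ReflectionSet:
    """Noisy Bijvoet-pair amplitudes from the exact structure factors.

    Gaussian noise with sigma = noise_fraction * |F| is added
    independently to |F+| and |F-|; the recorded sigmas are the true
    noise sigmas.  Negative noisy amplitudes are clipped to zero (and
    counted in the log).
    """
    hkl = unique_reflections(model.cell, model.spacegroup, spec.dmin)
    arr = structure_factor_arrays(model, hkl)
    f_plus = np.abs(arr["f_plus"])
    f_minus = np.abs(arr["f_minus"])
    sig_plus = spec.noise_fraction * f_plus
    sig_minus = spec.noise_fraction * f_minus
    if spec.noise_fraction > 0:
        rng = np.random.default_rng(spec.seed + 2)
        f_plus = f_plus + rng.normal(0.0, 1.0, len(f_plus)) * sig_plus
        f_minus = f_minus + rng.normal(0.0, 1.0, len(f_minus)) * sig_minus
        n_clipped = int(np.sum(f_plus < 0) + np.sum(f_minus < 0))
        if n_clipped:
            logger.warning("clipped %d negative noisy amplitudes to zero", n_clipped)
        f_plus = np.clip(f_plus, 0.0, None)
        f_minus = np.clip(f_minus, 0.0, None)
    return ReflectionSet(
        cell=model.cell, spacegroup=model.spacegroup,
        wavelength=0.979,
        hkl=hkl, f_plus=f_plus, sig_plus=sig_plus,
        f_minus=f_minus, sig_minus=sig_minus,
    )


PRESETS = {
    "tiny": dict(cell=(20.0, 22.0, 24.0, 90.0, 90.0, 90.0), n_light=30, n_anom=2,
                 anom_f_dprime=4.0, dmin=3.0, min_as_separation=6.0,
                 noise_fraction=0.0),
    "se_like_small": dict(n_light=400, n_anom=8, anom_f_dprime=3.9, dmin=2.5,
                          noise_fraction=0.05),
    # noise fractions of the realistic presets are set so the precision
    # indicator <|D|>/<sigma(|D|)> lands near the usability threshold
    # (>1.5) that experimental SAD data must meet; 2.5% amplitude noise
    # on the Se preset gives ~1.6, mirroring redundant synchrotron data
    "se_like": dict(n_light=1200, n_anom=8, anom_f_dprime=3.9, dmin=2.5,
                    noise_fraction=0.025),
    "s_like_weak": dict(n_light=1200, n_anom=3, anom_element="S", anom_f0=16.0,
                        anom_f_dprime=1.1, dmin=3.0, noise_fraction=0.005),
    "iodide_like": dict(n_light=400, n_anom=6, anom_element="I", anom_f0=53.0,
                        anom_f_dprime=6.9, dmin=2.8, noise_fraction=0.02,
                        anom_occupancies=np.linspace(1.0, 0.3, 6)),
}


def make_fixture(name: str, **overrides):
    """Reproducible (model, reflections, ground-truth sites) bundle.

    ``overrides`` update the preset's FixtureSpec fields (typically
    ``seed`` or ``noise_fraction``).  The seed and preset name are
    recorded in the ground-truth provenance.
    """
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    params = dict(PRESETS[name])
    params.update(overrides)
    spec = FixtureSpec(**params)
    model = generate_crystal(spec)
    refs = simulate_dataset(model, spec)
    anom = model.anomalous_atoms
    truth = SubstructureModel(
        frac=np.array([a.frac for a in anom]),
        height=np.array([a.occupancy * a.f_dprime for a in anom]),
        occupancy=np.array([a.occupancy for a in anom]),
        provenance={"preset": name, "seed": spec.seed,
                    "noise_fraction": spec.noise_fraction},
    )
    return model, refs, truth
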