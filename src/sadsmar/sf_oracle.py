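"""Ground-truth structure factors with anomalous dispersion.

Direct complex summation over a known atomic model gives, per acentric
reflection H, the Bijvoet mates F(+H) and F(-H), the exact anomalous
difference |D| = ||F+| - |F-||, and the component decomposition needed
for the small-substructure approximation

    |D| ~= 2 |F''_A| |sin psi|,

where F''_A is the imaginary (f'') part of the anomalous-scatterer
substructure and psi is the phase angle between the total normal
structure factor and the substructure's normal part.  The phase
convention is F(H) = sum_j f_j exp(+2 pi i H.r_j), with isotropic
displacement damping exp(-B s^2), s = sin(theta)/lambda.

Everything downstream (synthetic data, selection, phasing) is validated
against this module, so it stays deliberately simple: by default f0 is a
constant electron count per element (|D| and the normalized X are ratio
quantities, so resolution-independent f0 loses nothing); 4-Gaussian
international-tables form factors are available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .reflection_io import ReflectionSet

__all__ = [
    "AtomSite",
    "CrystalModel",
    "StructureFactorRecord",
    "ConditionReport",
    "SignalIndicators",
    "unique_reflections",
    "calc_structure_factors",
    "structure_factor_arrays",
    "exact_anomalous_difference",
    "approx_anomalous_difference",
    "psi_angle",
    "condition_diagnostics",
    "signal_indicators",
    "ELECTRON_COUNTS",
]

# constant-f0 approximation: electron counts of the elements used here
ELECTRON_COUNTS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "CL": 17,
    "ZN": 30, "SE": 34, "CD": 48, "I": 53,
}


@dataclass
class AtomSite:
    """One atom: fractional coordinates, occupancy, isotropic B and the
    scattering-factor pieces f0 (normal), f' and f'' (anomalous)."""

    element: str
    frac: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 0.0
    f0: float | None = None
    f_prime: float = 0.0
    f_dprime: float = 0.0
    anomalous: bool = False

    def __post_init__(self) -> None:
        self.frac = np.mod(np.asarray(self.frac, dtype=float), 1.0)
        if self.f0 is None:
            key = self.element.upper()
            if key not in ELECTRON_COUNTS:
                raise ValueError(f"no default f0 for element {self.element!r}")
            self.f0 = float(ELECTRON_COUNTS[key])
        if self.b_iso < 0:
            raise ValueError("B_iso must be >= 0")
        if self.f_dprime < 0:
            raise ValueError("f'' must be >= 0")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass
class CrystalModel:
    """Full unit-cell contents with a designated anomalous substructure."""

    cell: gemmi.UnitCell
    spacegroup: str
    atoms: list

    @property
    def anomalous_atoms(self) -> list:
        return [a for a in self.atoms if a.anomalous]

    def require_anomalous(self) -> None:
        if not self.anomalous_atoms:
            raise ValueError("SAD simulation requires at least one anomalous atom")


@dataclass
class StructureFactorRecord:
    hkl: tuple
    f_plus: complex
    f_minus: complex
    f_normal_total: complex
    f_a_normal: complex
    f_a_imag: complex
    s: float


@dataclass
class ConditionReport:
    """Magnitude-ratio surrogates for the validity conditions of the
    2|F''_A||sin psi| approximation."""

    ratio_fdp: float   # |F''_A| / |F|_av
    ratio_fa: float    # |F_A| / |F|_av
    trusted: bool
    degenerate: bool = False


def unique_reflections(cell: gemmi.UnitCell, spacegroup: str, dmin: float,
                       acentric_only: bool = True) -> np.ndarray:
    """Symmetry-unique reflections to resolution dmin (systematic
    absences excluded, origin excluded)."""
    if dmin <= 0:
        raise ValueError("dmin must be positive")
    sg = gemmi.SpaceGroup(spacegroup)
    ops = sg.operations()
    asu = gemmi.ReciprocalAsu(sg)
    hmax = int(cell.a / dmin) + 1
    kmax = int(cell.b / dmin) + 1
    lmax = int(cell.c / dmin) + 1
    out = []
    inv_d2_max = 1.0 / dmin**2
    for h in range(-hmax, hmax + 1):
        for k in range(-kmax, kmax + 1):
            for l in range(-lmax, lmax + 1):
                if h == k == l == 0:
                    continue
                idx = [h, k, l]
                if cell.calculate_1_d2(idx) > inv_d2_max:
                    continue
                if not asu.is_in(idx):
                    continue
                if ops.is_systematically_absent(idx):
                    continue
                if acentric_only and ops.is_reflection_centric(idx):
                    continue
                out.append(idx)
    if not out:
        raise ValueError(
            f"no reflections to dmin={dmin} A; dmin exceeds the lowest-resolution reflection"
        )
    return np.array(out, dtype=int)


def _f0_matrix(model: CrystalModel, s2: np.ndarray, f0_model: str) -> np.ndarray:
    """(n_refl, n_atoms) normal scattering factors."""
    if f0_model == "constant":
        return np.broadcast_to(
            np.array([a.f0 for a in model.atoms]), (len(s2), len(model.atoms))
        )
    if f0_model == "it92":
        cols = []
        for a in model.atoms:
            it92 = gemmi.Element(a.element).it92
            aa = np.array(it92.a)
            bb = np.array(it92.b)
            cols.append(np.exp(-np.outer(s2, bb)) @ aa + it92.c)
        return np.column_stack(cols)
    raise ValueError(f"unknown f0 model {f0_model!r}")


def structure_factor_arrays(model: CrystalModel, hkl: np.ndarray,
                            f0_model: str = "constant") -> dict:
    """Vectorized direct summation; returns component arrays keyed by
    f_plus, f_minus, f_normal_total, f_a_normal, f_a_imag, s."""
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    cell = model.cell
    s2 = 0.25 * np.array([cell.calculate_1_d2(list(h)) for h in hkl])
    frac = np.array([a.frac for a in model.atoms])          # (n_at, 3)
    occ = np.array([a.occupancy for a in model.atoms])
    b = np.array([a.b_iso for a in model.atoms])
    fp = np.array([a.f_prime for a in model.atoms])
    fdp = np.array([a.f_dprime for a in model.atoms])
    anom = np.array([a.anomalous for a in model.atoms], dtype=bool)

    f0 = _f0_matrix(model, s2, f0_model)                    # (n_h, n_at)
    damp = np.exp(-np.outer(s2, b))
    phase = np.exp(2j * np.pi * (hkl @ frac.T))             # (n_h, n_at)
    t_plus = phase * damp
    t_minus = np.conj(phase) * damp

    w_normal = occ * (f0 + fp)                              # (n_h, n_at)
    w_total = w_normal + 1j * (occ * fdp)
    f_plus = (t_plus * w_total).sum(axis=1)
    f_minus = (t_minus * w_total).sum(axis=1)
    f_normal_total = (t_plus * w_normal).sum(axis=1)
    f_a_normal = (t_plus[:, anom] * w_normal[:, anom]).sum(axis=1)
    f_a_imag = (t_plus[:, anom] * (occ * fdp)[None, :][:, anom]).sum(axis=1)
    return {
        "hkl": hkl,
        "f_plus": f_plus,
        "f_minus": f_minus,
        "f_normal_total": f_normal_total,
        "f_a_normal": f_a_normal,
        "f_a_imag": f_a_imag,
        "s": np.sqrt(s2),
    }


def calc_structure_factors(model: CrystalModel, dmin: float,
                           f0_model: str = "constant") -> list:
    """Direct-summation structure factors for every symmetry-unique
    acentric reflection to ``dmin``."""
    hkl = unique_reflections(model.cell, model.spacegroup, dmin)
    arr = structure_factor_arrays(model, hkl, f0_model=f0_model)
    return [
        StructureFactorRecord(
            hkl=tuple(int(v) for v in arr["hkl"][i]),
            f_plus=complex(arr["f_plus"][i]),
            f_minus=complex(arr["f_minus"][i]),
            f_normal_total=complex(arr["f_normal_total"][i]),
            f_a_normal=complex(arr["f_a_normal"][i]),
            f_a_imag=complex(arr["f_a_imag"][i]),
            s=float(arr["s"][i]),
        )
        for i in range(len(hkl))
    ]


def exact_anomalous_difference(rec: StructureFactorRecord) -> float:
    """|D| = ||F+| - |F-||, the exact Bijvoet amplitude difference."""
    return abs(abs(rec.f_plus) - abs(rec.f_minus))


def psi_angle(rec: StructureFactorRecord) -> float:
    """Angle between the total normal structure factor and the
    substructure's normal part, wrapped to (-pi, pi]; NaN when the
    substructure contribution vanishes."""
    if abs(rec.f_a_normal) == 0.0:
        return float("nan")
    psi = math.atan2(rec.f_normal_total.imag, rec.f_normal_total.real) - math.atan2(
        rec.f_a_normal.imag, rec.f_a_normal.real
    )
    psi = (psi + math.pi) % (2.0 * math.pi) - math.pi
    if psi == -math.pi:
        psi = math.pi
    return psi


def approx_anomalous_difference(rec: StructureFactorRecord) -> float:
    """Small-substructure approximation 2 |F''_A| |sin psi|; NaN when
    psi is undefined (|F_A| = 0)."""
    psi = psi_angle(rec)
    if math.isnan(psi):
        return float("nan")
    return 2.0 * abs(rec.f_a_imag) * abs(math.sin(psi))


def condition_diagnostics(rec: StructureFactorRecord,
                          fdp_ratio_max: float = 0.3,
                          fa_ratio_max: float | None = None) -> ConditionReport:
    """Magnitude ratios governing the validity of the approximation.

    The approximation is derived for a substructure much weaker than the
    total scattering; by default it is trusted when |F''_A|/|F|_av <= 0.3
    (and, if ``fa_ratio_max`` is given, |F_A|/|F|_av below it too).
    """
    f_av = 0.5 * (abs(rec.f_plus) + abs(rec.f_minus))
    if f_av <= np.finfo(float).eps:
        return ConditionReport(ratio_fdp=float("inf"), ratio_fa=float("inf"),
                               trusted=False, degenerate=True)
    r_fdp = abs(rec.f_a_imag) / f_av
    r_fa = abs(rec.f_a_normal) / f_av
    trusted = r_fdp <= fdp_ratio_max
    if fa_ratio_max is not None:
        trusted = trusted and r_fa <= fa_ratio_max
    return ConditionReport(ratio_fdp=r_fdp, ratio_fa=r_fa, trusted=trusted)


@dataclass
class SignalIndicators:
    """Anomalous-signal strength diagnostics.

    bijvoet_ratio = <|D|>/<|F|_av> and d_over_sigma = <|D|>/<sigma(|D|)>,
    over the whole resolution range and in the outermost shell.  A
    useful anomalous data set shows d_over_sigma > 1.5 overall."""

    bijvoet_ratio: float
    d_over_sigma: float
    bijvoet_ratio_outer: float
    d_over_sigma_outer: float
    shell_s_max: np.ndarray = field(default=None)
    shell_d_over_sigma: np.ndarray = field(default=None)


def signal_indicators(refs: ReflectionSet, n_shells: int = 10) -> SignalIndicators:
    ac = refs.acentric()
    d = ac.d_abs
    f_av = ac.f_av
    sig_d = ac.sig_d
    s = ac.s
    n_shells = max(1, min(n_shells, len(ac) // 2 or 1))
    edges = np.quantile(s, np.linspace(0, 1, n_shells + 1))
    shell = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_shells - 1)

    def _ratio(num, den):
        return float(num / den) if den > 0 else float("nan")

    outer = shell == n_shells - 1
    shell_smax = np.array([s[shell == i].max() for i in range(n_shells)])
    shell_ds = np.array(
        [_ratio(np.mean(d[shell == i]), np.mean(sig_d[shell == i]))
         for i in range(n_shells)]
    )
    return SignalIndicators(
        bijvoet_ratio=_ratio(np.mean(d), np.mean(f_av)),
        d_over_sigma=_ratio(np.mean(d), np.mean(sig_d)),
        bijvoet_ratio_outer=_ratio(np.mean(d[outer]), np.mean(f_av[outer])),
        d_over_sigma_outer=_ratio(np.mean(d[outer]), np.mean(sig_d[outer])),
        shell_s_max=shell_smax,
        shell_d_over_sigma=shell_ds,
    )
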