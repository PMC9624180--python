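"""Reflection-data and site I/O.

The native exchange format is a small self-contained text dialect ("HKL
text"): ``#``-prefixed metadata lines carrying the unit cell, space-group
symbol and wavelength, followed by whitespace-separated columns

    h k l Fplus sigFplus Fminus sigFminus

one Bijvoet pair per row.  Amplitudes are written with 6 significant
figures and rows are sorted by (h, k, l), so a file re-written after
reading is byte-identical.  Substructure sites travel as PDB HETATM
records (via gemmi), with the occupancy column holding the estimated
occupancy and the B column the peak height in rho_peak/sigma units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger("sadsmar")

__all__ = [
    "ReflectionSet",
    "SubstructureModel",
    "read_hkl",
    "write_hkl",
    "read_sites_pdb",
    "write_sites_pdb",
    "read_config",
    "write_config",
    "HklParseError",
]


class HklParseError(ValueError):
    """Malformed HKL text input; message carries the offending line number."""


def _spacegroup(symbol: str) -> gemmi.SpaceGroup:
    try:
        return gemmi.SpaceGroup(symbol)
    except Exception as exc:
        raise HklParseError(f"unknown space-group symbol {symbol!r}") from exc


@dataclass
class ReflectionSet:
    """Merged Bijvoet-pair reflection data for one crystal.

    Arrays are index-aligned; ``hkl`` is an (n, 3) integer array of the
    canonical (sorted) unique reflections.  Centric reflections carry no
    anomalous difference (``d_abs`` is NaN for them) and are excluded
    from anomalous processing via :meth:`acentric`.
    """

    cell: gemmi.UnitCell
    spacegroup: str
    wavelength: float
    hkl: np.ndarray
    f_plus: np.ndarray
    sig_plus: np.ndarray
    f_minus: np.ndarray
    sig_minus: np.ndarray
    centric: np.ndarray = field(default=None)
    epsilon: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=int))
        for name in ("f_plus", "sig_plus", "f_minus", "sig_minus"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.hkl) == 0:
            raise ValueError("empty reflection set")
        order = np.lexsort((self.hkl[:, 2], self.hkl[:, 1], self.hkl[:, 0]))
        self.hkl = self.hkl[order]
        for name in ("f_plus", "sig_plus", "f_minus", "sig_minus"):
            setattr(self, name, getattr(self, name)[order])
        uniq = np.unique(self.hkl, axis=0)
        if len(uniq) != len(self.hkl):
            raise ValueError("duplicate hkl in reflection set")
        # centric flags and epsilon factors always recomputed from the group
        ops = _spacegroup(self.spacegroup).operations()
        self.centric = np.array(
            [ops.is_reflection_centric(list(h)) for h in self.hkl], dtype=bool
        )
        self.epsilon = np.array(
            [ops.epsilon_factor(list(h)) for h in self.hkl], dtype=float
        )

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def f_av(self) -> np.ndarray:
        return 0.5 * (self.f_plus + self.f_minus)

    @property
    def d_abs(self) -> np.ndarray:
        """|D| = ||F+| - |F-||; NaN for centric reflections."""
        d = np.abs(self.f_plus - self.f_minus)
        return np.where(self.centric, np.nan, d)

    @property
    def sig_d(self) -> np.ndarray:
        return np.sqrt(self.sig_plus**2 + self.sig_minus**2)

    @property
    def d_spacing(self) -> np.ndarray:
        return np.array([self.cell.calculate_d(list(h)) for h in self.hkl])

    @property
    def s(self) -> np.ndarray:
        """sin(theta)/lambda = 1/(2d) in 1/Angstrom."""
        return 0.5 / self.d_spacing

    def acentric(self) -> "ReflectionSet":
        return self.subset(~self.centric)

    def subset(self, mask: np.ndarray) -> "ReflectionSet":
        if not np.any(mask):
            raise ValueError("subset selects no reflections")
        return ReflectionSet(
            cell=self.cell,
            spacegroup=self.spacegroup,
            wavelength=self.wavelength,
            hkl=self.hkl[mask],
            f_plus=self.f_plus[mask],
            sig_plus=self.sig_plus[mask],
            f_minus=self.f_minus[mask],
            sig_minus=self.sig_minus[mask],
        )


@dataclass
class SubstructureModel:
    """Anomalous-scatterer sites: fractional coordinates, peak heights
    (rho_peak/sigma) and occupancy estimates, sorted by descending height."""

    frac: np.ndarray
    height: np.ndarray = None
    occupancy: np.ndarray = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frac = np.atleast_2d(np.asarray(self.frac, dtype=float))
        if self.frac.size == 0:
            self.frac = self.frac.reshape(0, 3)
        n = len(self.frac)
        if self.height is None:
            self.height = np.ones(n)
        self.height = np.asarray(self.height, dtype=float)
        if self.occupancy is not None:
            self.occupancy = np.asarray(self.occupancy, dtype=float)
        if n > 1:
            order = np.argsort(-self.height, kind="stable")
            self.frac = self.frac[order]
            self.height = self.height[order]
            if self.occupancy is not None:
                self.occupancy = self.occupancy[order]

    def __len__(self) -> int:
        return len(self.frac)


# ---------------------------------------------------------------------------
# HKL text dialect


def _fmt(x: float) -> str:
    return format(float(x), ".6g")


def read_hkl(path) -> ReflectionSet:
    """Parse the HKL text dialect.

    Header lines ``# CELL``, ``# SPACEGROUP`` and ``# WAVELENGTH`` are
    mandatory.  A ``-`` in the F-/sigF- columns marks a missing Friedel
    mate; such rows are skipped with a warning.  Any other non-numeric
    field is a parse error reported with its line number.
    """
    path = Path(path)
    cell = spacegroup = wavelength = None
    hkl, cols = [], [[], [], [], []]
    n_skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if not parts:
                    continue
                key = parts[0].upper()
                try:
                    if key == "CELL":
                        cell = gemmi.UnitCell(*(float(v) for v in parts[1:7]))
                    elif key == "SPACEGROUP":
                        spacegroup = " ".join(parts[1:])
                        _spacegroup(spacegroup)
                    elif key == "WAVELENGTH":
                        wavelength = float(parts[1])
                except HklParseError:
                    raise
                except Exception as exc:
                    raise HklParseError(
                        f"{path.name}:{lineno}: bad header line {line!r}"
                    ) from exc
                continue
            parts = line.split()
            if len(parts) != 7:
                raise HklParseError(
                    f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            if any(p == "-" for p in parts[3:7]):
                n_skipped += 1
                logger.warning("%s:%d: missing Friedel mate, row skipped", path.name, lineno)
                continue
            try:
                h, k, l = (int(p) for p in parts[:3])
                vals = [float(p) for p in parts[3:7]]
            except ValueError as exc:
                raise HklParseError(
                    f"{path.name}:{lineno}: non-numeric field in {line!r}"
                ) from exc
            hkl.append((h, k, l))
            for c, v in zip(cols, vals):
                c.append(v)
    missing = [
        name
        for name, v in (("CELL", cell), ("SPACEGROUP", spacegroup), ("WAVELENGTH", wavelength))
        if v is None
    ]
    if missing:
        raise HklParseError(f"{path.name}: missing header field(s): {', '.join(missing)}")
    if not hkl:
        raise HklParseError(f"{path.name}: no data rows")
    if n_skipped:
        logger.warning("%s: skipped %d rows lacking a Friedel mate", path.name, n_skipped)
    return ReflectionSet(
        cell=cell,
        spacegroup=spacegroup,
        wavelength=wavelength,
        hkl=np.array(hkl),
        f_plus=np.array(cols[0]),
        sig_plus=np.array(cols[1]),
        f_minus=np.array(cols[2]),
        sig_minus=np.array(cols[3]),
    )


def write_hkl(refs: ReflectionSet, path) -> None:
    """Write the canonical HKL text form (sorted, 6 significant figures)."""
    if len(refs) == 0:
        raise ValueError("refusing to write an empty reflection set")
    c = refs.cell
    lines = [
        f"# CELL {_fmt(c.a)} {_fmt(c.b)} {_fmt(c.c)} {_fmt(c.alpha)} {_fmt(c.beta)} {_fmt(c.gamma)}",
        f"# SPACEGROUP {refs.spacegroup}",
        f"# WAVELENGTH {_fmt(refs.wavelength)}",
    ]
    for i in range(len(refs)):
        h, k, l = refs.hkl[i]
        lines.append(
            f"{h} {k} {l} {_fmt(refs.f_plus[i])} {_fmt(refs.sig_plus[i])} "
            f"{_fmt(refs.f_minus[i])} {_fmt(refs.sig_minus[i])}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sites in PDB format


def write_sites_pdb(model: SubstructureModel, path, cell: gemmi.UnitCell,
                    spacegroup: str = "P 1", element: str = "Se") -> None:
    """Write sites as HETATM records: occupancy column = estimated
    occupancy, B column = peak height in rho_peak/sigma units."""
    st = gemmi.Structure()
    st.cell = cell
    st.spacegroup_hm = gemmi.SpaceGroup(spacegroup).hm
    mdl = gemmi.Model("1")
    chain = gemmi.Chain("A")
    el = gemmi.Element(element)
    for i in range(len(model)):
        res = gemmi.Residue()
        res.name = element.upper()
        res.seqid = gemmi.SeqId(i + 1, " ")
        res.het_flag = "H"
        atom = gemmi.Atom()
        atom.name = element.upper()
        atom.element = el
        frac = np.mod(model.frac[i], 1.0)  # wrap, never reject
        atom.pos = cell.orthogonalize(gemmi.Fractional(*frac))
        atom.occ = float(model.occupancy[i]) if model.occupancy is not None else 1.0
        atom.b_iso = float(model.height[i])
        res.add_atom(atom)
        chain.add_residue(res)
    mdl.add_chain(chain)
    st.add_model(mdl)
    st.setup_entities()
    st.write_pdb(str(path))


def read_sites_pdb(path, element: str | None = None) -> SubstructureModel:
    """Inverse of :func:`write_sites_pdb`.

    With ``element`` given, atoms of other elements (waters etc.) are
    ignored.  A malformed/absent CRYST1 record is an error.
    """
    st = gemmi.read_structure(str(path))
    # gemmi substitutes a dummy 1x1x1 cell when CRYST1 is absent/mangled
    if st.cell.volume <= 1.001 or st.cell.a <= 1.0:
        raise ValueError(f"{path}: missing or malformed CRYST1 record")
    frac, height, occ = [], [], []
    want = gemmi.Element(element).name if element else None
    for mdl in st:
        for chain in mdl:
            for res in chain:
                for atom in res:
                    if want and atom.element.name != want:
                        continue
                    f = st.cell.fractionalize(atom.pos)
                    frac.append([f.x, f.y, f.z])
                    height.append(atom.b_iso)
                    occ.append(atom.occ)
    return SubstructureModel(
        frac=np.array(frac).reshape(-1, 3),
        height=np.array(height),
        occupancy=np.array(occ),
        provenance={"source": str(path), "cell": st.cell.parameters,
                    "spacegroup": st.spacegroup_hm},
    )


# ---------------------------------------------------------------------------
# Flat key=value configuration files (mirror CLI flags)


def read_config(path) -> dict:
    cfg = {}
    for lineno, raw in enumerate(open(path), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        cfg[key] = value
    return cfg


def write_config(cfg: dict, path) -> None:
    Path(path).write_text(
        "".join(f"{k}={v}\n" for k, v in sorted(cfg.items()))
    )
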