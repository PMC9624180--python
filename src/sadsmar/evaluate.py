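"""Compare found substructures with reference sites.

Because the recycling refines phases under lattice symmetry only, a
correct solution may differ from the reference by any allowed origin
translation of the space group, by an enantiomorph inversion, and by
symmetry images of individual sites.  ``match_sites`` searches this
ambiguity group -- per-group tables of permissible origin shifts,
continuous shifts along polar directions, optional inversion -- and
reports the best one-to-one site correspondence within a capture
radius, with the r.m.s.d. over matched pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy import optimize

from .reflection_io import SubstructureModel

__all__ = ["MatchReport", "match_sites", "run_report", "allowed_origins",
           "expand_sites", "ORIGIN_RULES"]

_HALF = (0.0, 0.5)
_ALL_HALF = [(a, b, c) for a in _HALF for b in _HALF for c in _HALF]

# permissible origin translations (discrete part) and polar directions,
# keyed by the space-group symbol without spaces
ORIGIN_RULES = {
    "P1": {"polar": (True, True, True), "discrete": [(0.0, 0.0, 0.0)]},
    "P21": {"polar": (False, True, False),
            "discrete": [(a, 0.0, c) for a in _HALF for c in _HALF]},
    "C2": {"polar": (False, True, False),
           "discrete": [(0.0, 0.0, 0.0), (0.0, 0.0, 0.5)]},
    "P212121": {"polar": (False, False, False), "discrete": _ALL_HALF},
    "P21212": {"polar": (False, False, False), "discrete": _ALL_HALF},
    "C2221": {"polar": (False, False, False),
              "discrete": [(0.0, 0.0, 0.0), (0.5, 0.0, 0.0),
                           (0.0, 0.0, 0.5), (0.5, 0.0, 0.5)]},
    "P41212": {"polar": (False, False, False),
               "discrete": [(0.0, 0.0, 0.0), (0.5, 0.5, 0.0),
                            (0.0, 0.0, 0.5), (0.5, 0.5, 0.5)]},
    "P43212": {"polar": (False, False, False),
               "discrete": [(0.0, 0.0, 0.0), (0.5, 0.5, 0.0),
                            (0.0, 0.0, 0.5), (0.5, 0.5, 0.5)]},
    "P6122": {"polar": (False, False, False),
              "discrete": [(0.0, 0.0, 0.0), (0.0, 0.0, 0.5)]},
    "P6522": {"polar": (False, False, False),
              "discrete": [(0.0, 0.0, 0.0), (0.0, 0.0, 0.5)]},
}


def _rule_key(spacegroup: str) -> str:
    return gemmi.SpaceGroup(spacegroup).short_name()


def allowed_origins(spacegroup: str) -> dict:
    key = _rule_key(spacegroup)
    if key not in ORIGIN_RULES:
        raise ValueError(
            f"unsupported space group {spacegroup!r}; supported: "
            + ", ".join(sorted(ORIGIN_RULES))
        )
    return ORIGIN_RULES[key]


@dataclass
class MatchReport:
    n_found: int
    n_reference: int
    n_matched: int
    n_reference_orbits_matched: int
    rmsd: float
    origin_shift: np.ndarray
    inverted: bool
    pairs: list = field(default_factory=list)   # (found_idx, ref_idx, distance)

    def matched_reference(self) -> set:
        return {j for _, j, _ in self.pairs}


def _sym_ops(spacegroup: str, invert: bool):
    ops = gemmi.SpaceGroup(spacegroup).operations()
    out = []
    for op in ops:
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        # conjugating the group by inversion negates the translations;
        # comparing inverted sites therefore uses the {R | -t} set
        out.append((rot, -tran if invert else tran))
    return out


def _pair_distances(found, ref_images, orth):
    """(n_found, n_ref) periodic distances, minimized over symmetry images.

    ref_images: (n_ops, n_ref, 3)."""
    d = found[:, None, None, :] - ref_images[None, :, :, :]
    d -= np.round(d)
    dist = np.linalg.norm(d @ orth.T, axis=-1)
    return dist.min(axis=1)


def _greedy(dist, capture):
    pairs = []
    dist = dist.copy()
    while True:
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        dmin = dist[i, j]
        if not np.isfinite(dmin) or dmin > capture:
            break
        pairs.append((int(i), int(j), float(dmin)))
        dist[i, :] = np.inf
        dist[:, j] = np.inf
    return pairs


def _score(found, ref, ops, orth, shift, capture):
    images = np.stack([(rot @ ref.T).T + tran + shift for rot, tran in ops])
    dist = _pair_distances(found, images, orth)
    pairs = _greedy(dist, capture)
    if pairs:
        rmsd = float(np.sqrt(np.mean([d**2 for _, _, d in pairs])))
    else:
        rmsd = float("nan")
    return pairs, rmsd


def expand_sites(model: SubstructureModel, spacegroup: str,
                 merge_tol: float = 1e-3) -> SubstructureModel:
    """Expand unique sites to the whole cell by the space-group
    operations; provenance['parent'] maps each image to its orbit."""
    ops = _sym_ops(spacegroup, invert=False)
    frac, height, parent = [], [], []
    for j in range(len(model)):
        seen = []
        for rot, tran in ops:
            img = np.mod(rot @ model.frac[j] + tran, 1.0)
            if any(np.linalg.norm(np.mod(img - s + 0.5, 1.0) - 0.5) < merge_tol
                   for s in seen):
                continue   # special position: image coincides
            seen.append(img)
            frac.append(img)
            height.append(model.height[j])
            parent.append(j)
    out = SubstructureModel(frac=np.array(frac), height=np.array(height))
    # re-sorting by height permutes rows; recompute parents accordingly
    order = np.argsort(-np.array(height), kind="stable")
    out.provenance["parent"] = np.array(parent)[order]
    out.provenance["n_orbits"] = len(model)
    return out


def match_sites(found: SubstructureModel, reference: SubstructureModel,
                spacegroup: str, cell: gemmi.UnitCell,
                capture_radius: float = 1.5,
                allow_inversion: bool = True) -> MatchReport:
    """Best correspondence between found and reference sites modulo the
    crystallographic ambiguities of ``spacegroup``.

    The search enumerates the group's permissible origin shifts (with
    continuous polar components seeded from site-difference candidates
    and refined numerically), both hands, and all symmetry images;
    assignment is greedy nearest-neighbour within ``capture_radius``.
    The report keeps the winning shift/hand and the matched pairs.
    """
    if len(found) == 0 or len(reference) == 0:
        raise ValueError("both site lists must be non-empty")
    rule = allowed_origins(spacegroup)
    polar = np.array(rule["polar"], dtype=bool)
    orth = np.array(cell.orth.mat.tolist())
    fnd_all = np.mod(found.frac, 1.0)
    ref = np.mod(reference.frac, 1.0)

    best = None
    for invert in ([False, True] if allow_inversion else [False]):
        fnd = np.mod(-fnd_all, 1.0) if invert else fnd_all
        ops = _sym_ops(spacegroup, invert)
        # candidate shifts: differences that superpose at least one pair
        cands = []
        n_f = min(len(fnd), 12)
        n_r = min(len(ref), 12)
        for rot, tran in ops:
            img = (rot @ ref[:n_r].T).T + tran
            diff = fnd[:n_f, None, :] - img[None, :, :]
            cands.append(np.mod(diff.reshape(-1, 3), 1.0))
        cands = np.concatenate(cands)
        for disc in rule["discrete"]:
            proj = cands.copy()
            proj[:, ~polar] = np.array(disc)[~polar]
            if not polar.any():
                proj = proj[:1]
            uniq = np.unique(np.round(proj, 3), axis=0)
            for shift in uniq:
                pairs, rmsd = _score(fnd, ref, ops, orth, shift, capture_radius)
                key = (len(pairs), -rmsd if pairs else -np.inf)
                if best is None or key > best[0]:
                    best = (key, shift.copy(), invert, pairs, rmsd)

    # refine continuous (polar) shift components around the best candidate
    if polar.any() and best is not None and best[3]:
        _, shift0, invert, _, _ = best
        fnd = np.mod(-fnd_all, 1.0) if invert else fnd_all
        ops = _sym_ops(spacegroup, invert)

        def objective(v):
            shift = shift0.copy()
            shift[polar] = v
            pairs, rmsd = _score(fnd, ref, ops, orth, shift, capture_radius)
            if not pairs:
                return 1e6
            return -len(pairs) * 10.0 + rmsd

        res = optimize.minimize(objective, shift0[polar], method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-10,
                                         "maxiter": 400})
        shift = shift0.copy()
        shift[polar] = res.x
        pairs, rmsd = _score(fnd, ref, ops, orth, shift, capture_radius)
        key = (len(pairs), -rmsd if pairs else -np.inf)
        if key >= best[0]:
            best = (key, shift, invert, pairs, rmsd)

    _, shift, invert, pairs, rmsd = best
    return MatchReport(
        n_found=len(found),
        n_reference=len(reference),
        n_matched=len(pairs),
        n_reference_orbits_matched=len({j for _, j, _ in pairs}),
        rmsd=rmsd,
        origin_shift=np.mod(shift, 1.0),
        inverted=invert,
        pairs=pairs,
    )


def run_report(*, n_dset: int, n_unique_acentric: int, trials_summary: dict,
               r_cc_value: float | None, n_sites_found: int, n_sites_reference: int,
               match: MatchReport | None = None, seeds: dict | None = None,
               thresholds: dict | None = None) -> dict:
    """Machine-readable one-run record mirroring the usual solution
    table: completeness c_D, converging-trial count, cycles, CC_h, R_CC,
    site counts and separation."""
    from . import __version__
    rec = {
        "c_d": n_dset / n_unique_acentric,
        "n_dset": n_dset,
        "n_unique_acentric": n_unique_acentric,
        "n_converged": trials_summary.get("n_converged"),
        "ncycle": trials_summary.get("ncycle_mean_converged"),
        "cc_h_best": trials_summary.get("cc_max"),
        "cc_h_gap": trials_summary.get("cc_gap"),
        "r_cc": r_cc_value,
        "n_sites_found": n_sites_found,
        "n_sites_reference": n_sites_reference,
        "rmsd": None if match is None else match.rmsd,
        "n_sites_matched": None if match is None else match.n_reference_orbits_matched,
        "seeds": seeds or {},
        "thresholds": thresholds or {},
        "version": __version__,
    }
    json.dumps(rec, default=float)   # guarantee serializability
    return rec
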