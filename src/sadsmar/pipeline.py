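"""End-to-end orchestration: data -> |D| set -> SMAR trials -> Fourier
recycling -> sites -> report.  Thin glue over the stage modules; every
step is available separately."""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

from . import evaluate, fourier_refine, preprocess, smar_engine
from .reflection_io import ReflectionSet, SubstructureModel, logger
from .sf_oracle import unique_reflections


@dataclass
class PipelineResult:
    dset: preprocess.DSet
    k: float
    b: float
    trials: smar_engine.TrialsResult
    problem: smar_engine.SmarProblem
    rho: np.ndarray
    phases: np.ndarray
    sites: SubstructureModel
    r_cc: float
    report: dict


def build_dset(refs: ReflectionSet, sigma_dprime, ecut=preprocess.DEFAULT_ECUT,
               dfcut=preprocess.DEFAULT_DFCUT, outlier=preprocess.DEFAULT_OUTLIER):
    """Selection + Wilson scaling + X normalization in one call."""
    dset = preprocess.select_dset(refs, ecut=ecut, dfcut=dfcut, outlier=outlier)
    k, b, _ = preprocess.fit_wilson_anomalous(dset, sigma_dprime)
    preprocess.compute_X(dset, k, b, sigma_dprime)
    return dset, k, b


def solve(refs: ReflectionSet, sigma_dprime, n_expected_sites: int,
          n_trials: int = 25, base_seed: int = 0,
          options: smar_engine.SmarOptions | None = None,
          ecut=preprocess.DEFAULT_ECUT, dfcut=preprocess.DEFAULT_DFCUT,
          outlier=preprocess.DEFAULT_OUTLIER,
          n_recycle: int = 8, peak_sigma: float = fourier_refine.DEFAULT_PEAK_SIGMA,
          occupancy_total: float | None = None,
          reference: SubstructureModel | None = None) -> PipelineResult:
    """Solve a substructure from merged Bijvoet pairs.

    ``n_expected_sites`` is the expected number of anomalous sites in
    the asymmetric unit; since recycling runs under lattice symmetry,
    the whole-cell expectation is that count times the space-group
    order.  ``reference`` (known sites) adds a match report.
    """
    sigma_dprime = np.asarray(sigma_dprime, dtype=float)
    dset, k, b = build_dset(refs, sigma_dprime, ecut=ecut, dfcut=dfcut,
                            outlier=outlier)
    problem = smar_engine.SmarProblem(dset, options)
    trials = smar_engine.run_trials(dset, n_trials=n_trials, base_seed=base_seed,
                                    problem=problem)
    n_ops = len(gemmi.SpaceGroup(refs.spacegroup).operations())
    n_expected_cell = n_expected_sites * n_ops
    s_p1 = dset.refs.s[problem.parent]
    eps_p1 = dset.refs.epsilon[problem.parent]
    gamma = fourier_refine.gamma_amplitudes(problem.x_exp, s_p1, eps_p1,
                                            k, b, sigma_dprime)

    # Fourier-recycle every trial and keep the model with the lowest
    # correlation residual R_CC: the converged-level CC_h is nearly
    # degenerate across trials, whereas R_CC ranks the recycled models
    # by how well a point-atom substructure explains the data.  Two
    # model widths are tried per trial -- a tight one that condenses a
    # clean solution and a generous one that keeps the dominant copy of
    # a partially superposed solution alive
    best = None
    for state in trials.states:
        for peak_factor in (1.2, 2.0):
            try:
                rho_t, phases_t = fourier_refine.fourier_recycle(
                    problem.hkl, gamma, state.phases, refs.cell, problem.shape,
                    n_expected=n_expected_cell, n_cycles=n_recycle,
                    peak_factor=peak_factor,
                )
                sites_t = fourier_refine.peak_search(
                    rho_t, refs.cell, "P 1", sigma_cutoff=peak_sigma,
                    max_peaks=4 * n_expected_cell)
                if len(sites_t) == 0:
                    continue
                x_calc_t = np.abs(fourier_refine.model_structure_factors(
                    problem.hkl, sites_t.frac, sites_t.height))
                rcc_t = fourier_refine.r_cc(problem.x_exp, x_calc_t)
            except (ValueError, RuntimeError):
                continue
            if best is None or rcc_t < best[0]:
                best = (rcc_t, state, rho_t, phases_t, sites_t, x_calc_t)
    if best is None:
        raise RuntimeError("no trial produced an interpretable map")
    rcc, best_state, rho, phases, sites, x_calc = best
    logger.info("selected trial seed=%d CC_h=%.4f R_CC=%.1f",
                best_state.seed, best_state.cc, rcc)
    sites.provenance.update({"trial_seed": best_state.seed,
                             "trial_cycles": best_state.cycle})
    if occupancy_total is not None and len(sites):
        fourier_refine.estimate_occupancies(sites, occupancy_total)
    match = None
    if reference is not None and len(sites):
        # found sites live in the whole cell under lattice symmetry only:
        # expand the reference by the space group and match in P1 (free origin)
        ref_full = evaluate.expand_sites(reference, refs.spacegroup)
        match = evaluate.match_sites(sites, ref_full, "P 1", refs.cell)
    n_orbits_matched = None
    if match is not None:
        parent = ref_full.provenance["parent"]
        n_orbits_matched = len({int(parent[j]) for _, j, _ in match.pairs})
        match.n_reference_orbits_matched = n_orbits_matched
    n_unique_ac = len(unique_reflections(refs.cell, refs.spacegroup,
                                         float(refs.d_spacing.min())))
    report = evaluate.run_report(
        n_dset=len(dset), n_unique_acentric=n_unique_ac,
        trials_summary=trials.summary(), r_cc_value=rcc,
        n_sites_found=len(sites),
        n_sites_reference=0 if reference is None else len(reference),
        match=match,
        seeds={"base_seed": base_seed},
        thresholds={"ecut": ecut, "dfcut": dfcut, "outlier": outlier,
                    "xcut": problem.options.xcut, "t": problem.options.mask_t,
                    "peak_sigma": peak_sigma},
    )
    result = PipelineResult(dset=dset, k=k, b=b, trials=trials, problem=problem,
                            rho=rho, phases=phases, sites=sites, r_cc=rcc,
                            report=report)
    result.match = match
    return result
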