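"""Self-validation sweeps: FWE calibration and target-coverage checks.

These routines regenerate synthetic cohorts from scratch and measure the
pipeline's statistical operating characteristics; they back both the
acceptance test suite and the standalone acceptance report script.
"""

from __future__ import annotations

import sys

import numpy as np

from doseatlas.volume_io import GridSpec
from doseatlas.synthetic_cohort import (
    PhantomParams,
    make_cohort,
    make_template_phantom,
    sample_record,
    simulate_dose,
    target_coverage,
)
from doseatlas.voxel_stats import make_design, permutation_fwe

__all__ = ["null_fwe_rate", "coverage_sweep", "effect_recovery_dice"]


def null_fwe_rate(n_replicates: int = 100, base_seed: int = 1,
                  n_per_group: int = 10, n_perm: int = 250,
                  alpha: float = 0.05, grid: GridSpec | None = None,
                  tails: str = "two-sided", verbose: bool = False) -> float:
    """Empirical family-wise error rate of the permutation TFCE test.

    Generates ``n_replicates`` null cohorts (identical generative law for
    both technique groups, ``effect_size=0``) with seeds ``base_seed ..
    base_seed + n_replicates - 1``, runs the two-tailed permutation test
    with age and gender covariates, and returns the fraction of replicates
    in which any voxel reaches per-tail FWE significance at ``alpha``.
    """
    grid = grid or GridSpec.centered(24, 6.0)
    params = PhantomParams(effect_size_gy=0.0)
    n_false = 0
    for i in range(n_replicates):
        seed = base_seed + i
        cohort, truth = make_cohort(n_per_group, seed=seed, grid=grid,
                                    params=params)
        data = [truth.dose_template[r.id] for r in cohort.subjects]
        design = make_design(cohort.table)
        res = permutation_fwe(data, design, truth.brain_mask, n_perm=n_perm,
                              seed=seed, alpha=alpha, tails=tails)
        hit = bool(res.sig_pos.data.any() or res.sig_neg.data.any())
        n_false += hit
        if verbose:
            print(f"  null replicate {i + 1}/{n_replicates} "
                  f"(seed {seed}): {'FALSE POSITIVE' if hit else 'clean'}",
                  file=sys.stderr)
    return n_false / n_replicates


def coverage_sweep(n_subjects: int = 50, base_seed: int = 1,
                   grid: GridSpec | None = None) -> list[float]:
    """Per-subject fraction of target voxels at or above the prescription.

    Draws ``n_subjects`` subjects (demographics from the cohort sampler,
    default generator parameters) with seeds ``base_seed ..`` and simulates
    each dose field on the template grid.
    """
    grid = grid or GridSpec.mni_2mm()
    params = PhantomParams()
    _, truth = make_template_phantom(grid, seed=base_seed, params=params)
    out = []
    for i in range(n_subjects):
        seed = base_seed + i
        rng = np.random.default_rng(seed)
        rec = sample_record(rng, f"cov-{seed}",
                            "IMRT" if i % 2 == 0 else "VMAT")
        dose = simulate_dose(rec, truth.head_support_mask,
                             truth.target_center, params, seed=seed,
                             effect_mask=truth.effect_mask)
        out.append(target_coverage(dose, rec, truth.target_center, params))
    return out


def effect_recovery_dice(n_per_group: int = 15, seed: int = 7,
                         effect_size: float = 3.0, n_perm: int = 500,
                         grid: GridSpec | None = None) -> float:
    """Dice overlap between detected and injected technique-effect voxels."""
    grid = grid or GridSpec.centered(24, 6.0)
    params = PhantomParams(effect_size_gy=effect_size)
    cohort, truth = make_cohort(n_per_group, seed=seed, grid=grid,
                                params=params)
    data = [truth.dose_template[r.id] for r in cohort.subjects]
    design = make_design(cohort.table)
    res = permutation_fwe(data, design, truth.brain_mask, n_perm=n_perm,
                          seed=seed)
    sig = res.sig_pos.data.astype(bool) | res.sig_neg.data.astype(bool)
    truth_mask = truth.effect_mask.data.astype(bool)
    denom = sig.sum() + truth_mask.sum()
    if denom == 0:
        return 0.0
    return 2.0 * (sig & truth_mask).sum() / denom
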