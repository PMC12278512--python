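"""Reusable simulation experiments composed from the library.

These drive the analysis scripts, the acceptance checks and the heavier
statistical tests: relatedness recovery in open-pollinated families,
REML heritability recovery, cross-generation validation patterns, and the
cambial-age (AWE vs SAD) training sweep. Every experiment takes an integer
seed and is deterministic given it.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg

from . import blup, phenotypes, validation
from .relationships import blend, build_G, pair_mean, relatedness_summary
from .synthetic_data import (
    SimConfig,
    assign_design,
    assign_qtl_effects,
    simulate_founders,
    simulate_open_pollination,
    simulate_population,
    simulate_ring_phenotypes,
)

__all__ = [
    "relatedness_study",
    "h2_recovery",
    "approach_comparison",
    "sweep_variability",
    "adjusted_whole_core",
]


def relatedness_study(
    seed: int,
    n_founders: int = 500,
    n_families: int = 65,
    progeny_per_family: int = 6,
    n_markers: int = 5000,
    maf_range=(0.1, 0.5),
    full_sib_fraction: float = 0.0,
) -> dict:
    """Distribution of VanRaden G coefficients in simulated open-pollinated
    families: within-family, among-family, and dam-offspring means.

    With independently drawn fathers the expectations are the classical
    0.25 (maternal half-sibs), 0.0 (unrelated families) and 0.5
    (parent-offspring).
    """
    config = SimConfig(
        n_founders=n_founders,
        n_families_phenotyped=n_families,
        progeny_per_family_per_trial=progeny_per_family,
        n_trials=1,
        n_markers=n_markers,
        maf_range=tuple(maf_range),
        full_sib_fraction=full_sib_fraction,
        seed=seed,
    )
    founders = simulate_founders(config)
    pedigree, progeny = simulate_open_pollination(founders, config)
    from .relationships import GenotypeMatrix

    combined = GenotypeMatrix(
        np.concatenate([founders.ids, progeny.ids]),
        founders.markers,
        np.vstack([founders.codes, progeny.codes]),
    )
    G = build_G(combined)  # observed frequencies over all genotyped samples

    prog_frame = pedigree.frame[pedigree.frame["generation"] == 1]
    fam = dict(zip(prog_frame["id"], prog_frame["dam"]))
    summary = relatedness_summary(G.submatrix(list(fam)), fam)
    dam_pairs = [(d, i) for i, d in fam.items()]
    return {
        "within_family_mean": summary.within_mean,
        "among_family_mean": summary.among_mean,
        "dam_offspring_mean": pair_mean(G, dam_pairs),
        "n_within_pairs": summary.n_within,
        "n_among_pairs": summary.n_among,
        "n_dam_offspring_pairs": len(dam_pairs),
        "n_progeny": progeny.n_individuals,
        "n_markers": n_markers,
        "summary": summary,
        "G": G,
        "pedigree": pedigree,
    }


def h2_recovery(
    seed: int,
    h2_targets=(0.1, 0.5, 0.7),
    n_reps: int = 20,
    n_founders: int = 200,
    n_families: int = 100,
    progeny_per_family: int = 8,
    n_markers: int = 2000,
    n_qtl: int = 200,
    algorithm: str = "ai",
) -> pd.DataFrame:
    """GBLUP REML recovery of the simulated narrow-sense heritability.

    Each replicate simulates founders plus open-pollinated families
    (n_founders + n_families*progeny individuals), builds G from the
    markers, draws a fresh polygenic architecture per target h2, phenotypes
    every individual as true breeding value plus N(0, 1-h2) noise, and fits
    the single-kernel REML. Genotypes/eigendecomposition are shared across
    h2 levels within a replicate.
    """
    rows = []
    for rep in range(n_reps):
        config = SimConfig(
            n_founders=n_founders,
            n_families_phenotyped=n_families,
            progeny_per_family_per_trial=progeny_per_family,
            n_trials=1,
            n_markers=n_markers,
            n_qtl=n_qtl,
            seed=int(np.random.default_rng([seed, rep]).integers(2**31)),
        )
        founders = simulate_founders(config)
        pedigree, progeny = simulate_open_pollination(founders, config)
        from .relationships import GenotypeMatrix

        combined = GenotypeMatrix(
            np.concatenate([founders.ids, progeny.ids]),
            founders.markers,
            np.vstack([founders.codes, progeny.codes]),
        )
        G = blend(build_G(combined), 0.98)
        eig = linalg.eigh(G.values)
        noise_rng = np.random.default_rng([seed, rep, 7])
        for h2 in h2_targets:
            cfg_h2 = SimConfig(**{**config.to_dict(), "target_h2": h2,
                                  "maf_range": tuple(config.maf_range)})
            _, tbv = assign_qtl_effects(combined, cfg_h2, founder_ids=founders.ids)
            y = tbv.to_numpy() + noise_rng.normal(
                0.0, np.sqrt(1.0 - h2), size=combined.n_individuals
            )
            vc = blup.reml_fit(y, G, algorithm=algorithm, eig=eig)
            rows.append({"rep": rep, "h2_target": h2, "h2_hat": vc.h2,
                         "sigma2_a": vc.sigma2_a, "sigma2_e": vc.sigma2_e,
                         "converged": vc.converged})
    return pd.DataFrame(rows)


def awe_h2_recovery(
    seed: int,
    target_h2: float = 0.5,
    n_reps: int = 20,
    n_founders: int = 250,
    n_families: int = 65,
    progeny: int = 6,
    n_markers: int = 2000,
) -> pd.DataFrame:
    """Heritability recovery through the full ring pipeline: simulate radial
    profiles, summarize as design-adjusted whole-core AWE, fit GBLUP.

    Exercises the generator's variance budget (polygenic + permanent +
    AR(1) + ring noise + blocks) end to end: the REML h2 on whole-core AWE
    should track ``target_h2``.
    """
    rows = []
    for rep in range(n_reps):
        cfg = SimConfig(
            n_founders=n_founders,
            n_families_phenotyped=n_families,
            progeny_per_family_per_trial=progeny,
            n_trials=2,
            n_markers=n_markers,
            target_h2=target_h2,
            seed=int(np.random.default_rng([seed, rep, 11]).integers(2**31)),
        )
        sim = simulate_population(cfg)
        G = blend(build_G(sim.genotypes), 0.98)
        adjusted = adjusted_whole_core(sim)
        ids = list(adjusted.index)
        vc = blup.reml_fit(adjusted.to_numpy(), G.submatrix(ids), algorithm="ai")
        rows.append({"rep": rep, "h2_target": target_h2, "h2_hat": vc.h2,
                     "n": len(ids), "converged": vc.converged})
    return pd.DataFrame(rows)


def adjusted_whole_core(
    sim, kernel=None, derivation: str = "whole-core", trait: str = "density"
) -> pd.Series:
    """Adjusted phenotype series (id -> y') for one derivation across all
    cohorts: block adjustment within each progeny trial, mean-centering for
    the archive G0 clones."""
    traits = phenotypes.derive_traits(sim.ring_table, derivation, trait=trait)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # expected: archive has no blocks
        adj = phenotypes.adjust_phenotypes(traits, sim.design, relationship=kernel)
    return pd.Series(adj["adjusted"].to_numpy(), index=adj["id"].to_numpy())


def _small_population(seed, h2, n_founders, n_families, progeny, n_markers,
                      n_blocks=8, rho=0.7):
    config = SimConfig(
        n_founders=n_founders,
        n_families_phenotyped=n_families,
        progeny_per_family_per_trial=progeny,
        n_trials=2,
        n_blocks_per_trial=n_blocks,
        n_markers=n_markers,
        n_qtl=min(100, n_markers),
        target_h2=h2,
        ring_age_correlation=rho,
        seed=seed,
    )
    return simulate_population(config)


def approach_comparison(
    seed: int,
    h2_levels=(0.6, 0.1),
    n_reps: int = 20,
    n_founders: int = 80,
    n_families: int = 30,
    progeny: int = 4,
    n_markers: int = 800,
    algorithm: str = "ai",
) -> pd.DataFrame:
    """PA/ACC of GBLUP under Approaches A/B/C for traits of contrasting
    heritability, on reduced-scale populations.

    Traits share each replicate's genotypes and pedigree but carry
    independent QTL architectures at the stated target h2 (the two-trait
    design contrasts heritability level, not trait identity).
    """
    rows = []
    for rep in range(n_reps):
        rep_seed = int(np.random.default_rng([seed, rep]).integers(2**31))
        base = _small_population(rep_seed, h2_levels[0], n_founders, n_families,
                                 progeny, n_markers)
        G = blend(build_G(base.genotypes), 0.98)
        cohorts = pd.Series(base.design["cohort"].to_numpy(),
                            index=base.design["id"].to_numpy())
        for h2 in h2_levels:
            if h2 == base.config.target_h2:
                sim = base
            else:
                cfg = SimConfig(**{**base.config.to_dict(), "target_h2": h2,
                                   "maf_range": tuple(base.config.maf_range)})
                _, tbv = assign_qtl_effects(base.genotypes, cfg,
                                            founder_ids=base.genotypes.ids[:n_founders])
                rings = simulate_ring_phenotypes(tbv, base.design, cfg)
                sim = base.__class__(config=cfg, pedigree=base.pedigree,
                                     genotypes=base.genotypes,
                                     true_breeding_values=tbv, ring_table=rings,
                                     design=base.design, qtl_effects=None)
            adjusted = adjusted_whole_core(sim, kernel=G)
            for approach in ("A", "B", "C"):
                for res in validation.run_approach(
                    approach, "GBLUP", adjusted, cohorts, G,
                    trait=f"h2={h2}", algorithm=algorithm
                ):
                    rows.append({"rep": rep, "h2_target": h2,
                                 "approach": approach,
                                 "validation_cohort": res.validation_cohort,
                                 "pa": res.pa, "acc": res.acc,
                                 "h2_hat": res.h2,
                                 "n_train": res.n_train, "n_valid": res.n_valid})
    return pd.DataFrame(rows)


def sweep_variability(
    seed: int,
    n_reps: int = 20,
    rho: float = 0.7,
    h2: float = 0.4,
    n_founders: int = 60,
    n_families: int = 25,
    progeny: int = 3,
    n_markers: int = 600,
    rings=range(1, 22),
    algorithm: str = "ai",
) -> pd.DataFrame:
    """AWE- vs SAD-trained GBLUP along cambial age, on reduced-scale
    populations with AR(1) ring deviations.

    Returns one row per (replicate, mode, ring, window, trial) with the
    progeny-validated PA, for comparing how smoothly the two training
    phenotypes behave along the core.
    """
    rows = []
    for rep in range(n_reps):
        rep_seed = int(np.random.default_rng([seed, rep, 3]).integers(2**31))
        sim = _small_population(rep_seed, h2, n_founders, n_families, progeny,
                                n_markers, rho=rho)
        G = blend(build_G(sim.genotypes), 0.98)
        g0_ids = sim.design.loc[sim.design["cohort"] == "G0", "id"]
        g0_rings = sim.ring_table[sim.ring_table["id"].isin(g0_ids)]
        adj_whole = adjusted_whole_core(sim, kernel=None)
        adj_juv = adjusted_whole_core(sim, kernel=None, derivation="juvenile")
        targets = {}
        for trial in ("H", "E"):
            ids = sim.design.loc[sim.design["cohort"] == f"G1{trial}", "id"]
            targets[(trial, "whole-core")] = adj_whole.loc[adj_whole.index.isin(ids)]
            targets[(trial, "juvenile-10")] = adj_juv.loc[adj_juv.index.isin(ids)]
        for mode in ("AWE", "SAD"):
            for res in validation.early_training_sweep(
                g0_rings, targets, G, mode, rings=rings, algorithm=algorithm
            ):
                rows.append({"rep": rep, "mode": res.mode, "ring": res.ring,
                             "window": res.window, "trial": res.trial,
                             "pa": res.pa, "acc": res.acc, "h2_hat": res.h2})
    return pd.DataFrame(rows)
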