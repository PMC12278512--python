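"""Synthetic two-generation open-pollinated breeding populations.

Emulates the structure of a conifer progeny-testing program: a set of
presumably unrelated plus-tree founders (G0) sampled under Hardy-Weinberg
equilibrium at unlinked biallelic markers; open-pollinated maternal
families planted in randomized incomplete-block trials (G1), whose fathers
are hidden members of the founder pollen pool (so recorded pedigrees say
"half-sib" while the realized genomic relatedness can exceed 0.25 when
siblings share a father); polygenic additive trait architecture with a
target narrow-sense heritability; and pith-to-bark radial profiles of a
density-like trait over annual rings with a saturating cambial-age trend
and age-age correlated tree-level deviations.

All randomness derives from ``SimConfig.seed``; each generator seeds its
own stream so a fixed seed reproduces output bit for bit, whether the
steps run individually or through :func:`simulate_population`.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .relationships import GenotypeMatrix, Pedigree, UNKNOWN

__all__ = [
    "SimConfig",
    "SimOutput",
    "simulate_founders",
    "simulate_open_pollination",
    "assign_qtl_effects",
    "assign_design",
    "simulate_ring_phenotypes",
    "simulate_population",
    "cambial_trend",
]

# distinct sub-stream tags so each stage has its own reproducible stream
_STREAMS = {"founders": 1, "pollination": 2, "qtl": 3, "design": 4, "rings": 5}


def _rng(config: "SimConfig", stage: str, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stage], salt])


@dataclass
class SimConfig:
    """Study-scale parameters for the simulated breeding population.

    Defaults mirror the scale of a two-trial open-pollinated spruce
    progeny test: ~500 founders, 65 phenotyped+genotyped families with 6
    progeny per family in each of 2 trials, radial profiles of 21 rings on
    the parents and 16 on the progeny. ``full_sib_fraction`` is the
    probability that a new progeny shares its father with an earlier sibling
    of the same dam; the default 0.04 raises the expected within-family
    genomic relationship from the half-sib 0.25 to ~0.26.
    """

    n_founders: int = 500
    n_families_phenotyped: int = 65
    progeny_per_family_per_trial: int = 6
    n_trials: int = 2
    n_blocks_per_trial: int = 20
    n_markers: int = 5000
    n_qtl: int = 200
    maf_range: tuple = (0.1, 0.5)
    target_h2: float = 0.4
    full_sib_fraction: float = 0.04
    n_rings_g0: int = 21
    n_rings_g1: int = 16
    ring_age_correlation: float = 0.7
    seed: int = 0
    # nuisance-structure parameters (trait simulated on a unit-variance scale)
    block_sd: float = 0.5
    ring_noise_sd: float = 0.1
    perm_env_fraction: float = 0.85
    trend_amplitude: float = 2.0
    trend_scale: float = 6.0
    deviation_scale: float = 1.0

    def __post_init__(self) -> None:
        counts = {
            "n_founders": self.n_founders,
            "n_families_phenotyped": self.n_families_phenotyped,
            "progeny_per_family_per_trial": self.progeny_per_family_per_trial,
            "n_trials": self.n_trials,
            "n_blocks_per_trial": self.n_blocks_per_trial,
            "n_markers": self.n_markers,
            "n_qtl": self.n_qtl,
            "n_rings_g0": self.n_rings_g0,
            "n_rings_g1": self.n_rings_g1,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if self.n_families_phenotyped > self.n_founders:
            raise ValueError("more phenotyped families than founders")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.target_h2 < 1.0:
            raise ValueError("target_h2 must be in [0, 1); residual variance must stay positive")
        if not 0.0 <= self.full_sib_fraction < 1.0:
            raise ValueError("full_sib_fraction must be in [0, 1)")
        if not 0.0 < self.ring_age_correlation <= 1.0:
            raise ValueError("ring_age_correlation must be in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d


@dataclass
class SimOutput:
    config: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    true_breeding_values: pd.Series
    ring_table: pd.DataFrame
    design: pd.DataFrame
    qtl_effects: pd.Series
    true_sires: dict = field(default_factory=dict)


def trial_names(n_trials: int) -> list[str]:
    base = ["H", "E"]
    return [base[i] if i < 2 else f"T{i + 1}" for i in range(n_trials)]


def simulate_founders(config: SimConfig, rng=None) -> GenotypeMatrix:
    """Unrelated founders under Hardy-Weinberg equilibrium at unlinked loci,
    with per-marker allele frequencies uniform on ``maf_range``."""
    rng = rng or _rng(config, "founders")
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=config.n_markers) if hi > lo else np.full(config.n_markers, lo)
    codes = rng.binomial(2, p, size=(config.n_founders, config.n_markers)).astype(float)
    ids = np.array([f"G0_{i:04d}" for i in range(1, config.n_founders + 1)], dtype=object)
    markers = np.array([f"M{j:06d}" for j in range(1, config.n_markers + 1)], dtype=object)
    return GenotypeMatrix(ids, markers, codes)


def _gametes(codes: np.ndarray, rng) -> np.ndarray:
    """One gamete per row of parental 0/1/2 codes (Mendelian, unlinked)."""
    g = codes / 2.0
    het = codes == 1.0
    g[het] = rng.integers(0, 2, size=int(het.sum()))
    return g


def simulate_open_pollination(
    founders: GenotypeMatrix, config: SimConfig, rng=None
) -> tuple[Pedigree, GenotypeMatrix]:
    """Open-pollinated progeny of the first ``n_families_phenotyped``
    founders, ``progeny_per_family_per_trial`` per family in each trial.

    Each progeny gets one gamete from its dam and one from a father drawn
    from the founder pollen pool (never the dam itself); with probability
    ``full_sib_fraction`` the father is recycled from an earlier sibling,
    producing hidden full-sibs within nominal half-sib families. The
    pedigree records the dam only (sire unknown, mirroring open
    pollination); true sires are logged in a ``true_sire`` column for
    validating relationship estimates.
    """
    if founders.has_missing():
        raise ValueError("founder genotypes must be complete")
    if founders.n_individuals < 2:
        raise ValueError("need at least 2 founders for open pollination")
    rng = rng or _rng(config, "pollination")
    trials = trial_names(config.n_trials)
    dam_ids = founders.ids[: config.n_families_phenotyped]
    dam_idx = {d: i for i, d in enumerate(founders.ids)}

    rows = []
    prog_codes = []
    for fam_no, dam in enumerate(dam_ids, start=1):
        fathers_used: list[int] = []
        for trial in trials:
            for k in range(1, config.progeny_per_family_per_trial + 1):
                if fathers_used and rng.random() < config.full_sib_fraction:
                    father = int(fathers_used[rng.integers(len(fathers_used))])
                else:
                    while True:
                        father = int(rng.integers(founders.n_individuals))
                        if founders.ids[father] != dam:
                            break
                fathers_used.append(father)
                assert founders.ids[father] != dam, "selfing excluded"
                gd = _gametes(founders.codes[dam_idx[dam]][None, :], rng)[0]
                gs = _gametes(founders.codes[father][None, :], rng)[0]
                pid = f"G1_{fam_no:03d}_{trial}{k:02d}"
                rows.append(
                    {"id": pid, "dam": dam, "sire": UNKNOWN, "generation": 1,
                     "group": UNKNOWN, "true_sire": founders.ids[father]}
                )
                prog_codes.append(gd + gs)

    founder_rows = pd.DataFrame(
        {"id": founders.ids, "dam": UNKNOWN, "sire": UNKNOWN, "generation": 0,
         "group": UNKNOWN, "true_sire": UNKNOWN}
    )
    ped = Pedigree(pd.concat([founder_rows, pd.DataFrame(rows)], ignore_index=True))
    prog = GenotypeMatrix(
        np.array([r["id"] for r in rows], dtype=object),
        founders.markers,
        np.array(prog_codes),
    )
    return ped, prog


def assign_qtl_effects(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    founder_ids=None,
    rng=None,
) -> tuple[pd.Series, pd.Series]:
    """Additive effects on a random marker subset, and the implied true
    breeding values.

    Effects are zero-mean normal draws rescaled so the additive variance in
    the founder generation equals ``target_h2`` (total phenotypic variance
    is 1 before design effects, with residual variance ``1 - target_h2``).
    ``target_h2 = 0`` yields all-zero effects and breeding values.
    """
    rng = rng or _rng(config, "qtl")
    if genotypes.has_missing():
        raise ValueError("genotypes must be complete to compute breeding values")
    effects = pd.Series(0.0, index=list(genotypes.markers))
    if config.target_h2 == 0.0:
        tbv = pd.Series(0.0, index=list(genotypes.ids))
        return effects, tbv
    qtl_pos = rng.choice(genotypes.n_markers, size=config.n_qtl, replace=False)
    beta = np.zeros(genotypes.n_markers)
    beta[qtl_pos] = rng.normal(size=config.n_qtl)
    raw = genotypes.codes @ beta
    if founder_ids is None:
        founder_vals = raw
    else:
        pos = {v: i for i, v in enumerate(genotypes.ids)}
        founder_vals = raw[[pos[i] for i in founder_ids]]
    v = np.var(founder_vals, ddof=1)
    if v <= 0.0:
        raise ValueError("QTL subset is monomorphic in the founders; cannot scale")
    scale = np.sqrt(config.target_h2 / v)
    beta *= scale
    bv = (genotypes.codes @ beta)
    bv -= np.mean(founder_vals) * scale
    return pd.Series(beta, index=list(genotypes.markers)), pd.Series(bv, index=list(genotypes.ids))


def assign_design(pedigree: Pedigree, config: SimConfig, rng=None) -> pd.DataFrame:
    """Trial/block assignment: G1 trees get a random block within their
    trial (randomized incomplete blocks, single-tree plots); G0 archive
    clones have no block design."""
    rng = rng or _rng(config, "design")
    names = sorted(trial_names(config.n_trials), key=len, reverse=True)
    rows = []
    for _, rec in pedigree.frame.iterrows():
        if rec["generation"] == 1:
            suffix = rec["id"].split("_")[-1]  # trial tag embedded in the id
            trial = next(t for t in names if suffix.startswith(t))
            block = int(rng.integers(1, config.n_blocks_per_trial + 1))
            rows.append({"id": rec["id"], "trial": trial, "block": block,
                         "generation": 1, "cohort": f"G1{trial}"})
        else:
            rows.append({"id": rec["id"], "trial": "archive", "block": 0,
                         "generation": 0, "cohort": "G0"})
    return pd.DataFrame(rows)


def cambial_trend(ring: np.ndarray, config: SimConfig) -> np.ndarray:
    """Population cambial-age trend: low juvenile values rising to a
    plateau, ``amplitude * (1 - exp(-ring / scale))``."""
    return config.trend_amplitude * (1.0 - np.exp(-np.asarray(ring, float) / config.trend_scale))


def simulate_ring_phenotypes(
    breeding_values: pd.Series,
    design: pd.DataFrame,
    config: SimConfig,
    rng=None,
) -> pd.DataFrame:
    """Ring-level trait values and widths for every designed tree.

    ring value = trend(r) + breeding value + block effect
                 + permanent tree deviation + AR(1) deviation over rings
                 + independent ring noise.

    The tree-level deviation has total variance ``(1 - target_h2) *
    deviation_scale**2`` split between a whole-core permanent component
    (fraction ``perm_env_fraction``) and an AR(1) component with lag-1
    correlation ``ring_age_correlation``, giving a compound-symmetry +
    AR(1) age-age correlation profile. Ring widths decline with cambial age
    and are strictly positive.
    """
    rng = rng or _rng(config, "rings")
    missing = set(design["id"]) - set(breeding_values.index)
    if missing:
        raise ValueError(f"ids lacking breeding values: {sorted(missing)[:5]}")

    var_resid = (1.0 - config.target_h2) * config.deviation_scale**2
    s_perm = np.sqrt(config.perm_env_fraction * var_resid)
    s_ar = np.sqrt((1.0 - config.perm_env_fraction) * var_resid)
    rho = config.ring_age_correlation

    block_eff = {
        (t, b): rng.normal(0.0, config.block_sd) if config.block_sd > 0 else 0.0
        for t, b in design.loc[design["generation"] == 1, ["trial", "block"]]
        .drop_duplicates()
        .itertuples(index=False)
    }

    frames = []
    for rec in design.itertuples(index=False):
        n_rings = config.n_rings_g0 if rec.generation == 0 else config.n_rings_g1
        rings = np.arange(1, n_rings + 1)
        perm = rng.normal(0.0, s_perm) if s_perm > 0 else 0.0
        ar = np.zeros(n_rings)
        if s_ar > 0:
            ar[0] = rng.normal(0.0, s_ar)
            innov_sd = s_ar * np.sqrt(max(0.0, 1.0 - rho**2))
            eps = rng.normal(0.0, 1.0, size=n_rings - 1) if n_rings > 1 else np.empty(0)
            for r in range(1, n_rings):
                ar[r] = rho * ar[r - 1] + innov_sd * eps[r - 1]
        noise = (
            rng.normal(0.0, config.ring_noise_sd, size=n_rings)
            if config.ring_noise_sd > 0
            else np.zeros(n_rings)
        )
        beff = block_eff.get((rec.trial, rec.block), 0.0) if rec.generation == 1 else 0.0
        values = (
            cambial_trend(rings, config)
            + float(breeding_values[rec.id])
            + beff
            + perm
            + ar
            + noise
        )
        mean_w = 0.5 + 3.5 * np.exp(-0.06 * (rings - 1))
        widths = mean_w * np.exp(rng.normal(0.0, 0.15, size=n_rings))
        frames.append(
            pd.DataFrame({"id": rec.id, "ring": rings, "width_mm": widths, "value": values})
        )
    out = pd.concat(frames, ignore_index=True)
    assert (out["width_mm"] > 0).all()
    return out


def simulate_population(config: SimConfig) -> SimOutput:
    """Run all generators and bundle the result."""
    founders = simulate_founders(config)
    pedigree, progeny = simulate_open_pollination(founders, config)
    genotypes = GenotypeMatrix(
        np.concatenate([founders.ids, progeny.ids]),
        founders.markers,
        np.vstack([founders.codes, progeny.codes]),
    )
    effects, tbv = assign_qtl_effects(genotypes, config, founder_ids=founders.ids)
    design = assign_design(pedigree, config)
    rings = simulate_ring_phenotypes(tbv, design, config)
    true_sires = {
        r["id"]: r["true_sire"]
        for _, r in pedigree.frame.iterrows()
        if r.get("true_sire", UNKNOWN)
    }
    return SimOutput(
        config=config,
        pedigree=pedigree,
        genotypes=genotypes,
        true_breeding_values=tbv,
        ring_table=rings,
        design=design,
        qtl_effects=effects,
        true_sires=true_sires,
    )
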