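"""Independent cross-generation / cross-environment validation.

Training and validation sets never share individuals or environments.
Three designs over the cohorts (G0 parents, G1H and G1E progeny trials):

* Approach A — forward prediction: train on G0 phenotypes, validate on
  each progeny trial;
* Approach B — train on G1H, validate on G1E (across environments) and on
  G0 (backward prediction);
* Approach C — train on G1E, validate on G1H and G0.

The kernel (A or G) always spans all available individuals, so breeding
values of unphenotyped validation trees are obtained through relationship
covariances when Henderson's equations are solved. Predictive ability (PA)
is the Pearson correlation between adjusted phenotypes and predicted
breeding values in the validation set; prediction accuracy is
``ACC = PA / sqrt(h2)`` with the training-fit heritability, reported as NA
when h2 is below an estimability threshold.

The cambial-age sweep trains on parental wood density summarized either
cumulatively (area-weighted up to ring k; AWE mode) or from the single
ring k (SAD mode), for k = 1..21, and validates against progeny juvenile
(innermost 10 rings) and whole-core area-weighted density.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats, linalg

from . import blup
from .relationships import RelationshipMatrix

__all__ = [
    "APPROACHES",
    "ValidationResult",
    "SweepResult",
    "predictive_ability",
    "prediction_accuracy",
    "run_approach",
    "early_training_sweep",
    "results_to_frame",
]

# approach -> (training cohort, validation cohorts)
APPROACHES = {
    "A": ("G0", ["G1H", "G1E"]),
    "B": ("G1H", ["G1E", "G0"]),
    "C": ("G1E", ["G1H", "G0"]),
}


@dataclass
class ValidationResult:
    approach: str
    model: str
    trait: str
    train_cohort: str
    validation_cohort: str
    pa: float
    acc: float  # NaN when inestimable
    h2: float
    n_train: int
    n_valid: int
    acc_reason: str = ""


@dataclass
class SweepResult:
    mode: str  # AWE or SAD
    ring: int
    window: str  # juvenile-10 or whole-core
    trial: str
    pa: float
    acc: float
    h2: float
    n_train: int
    n_valid: int
    acc_flagged: bool = False  # beyond the display reliability cutoff


def predictive_ability(y_prime, y_hat) -> float:
    """Pearson correlation between adjusted and predicted phenotypes on the
    validation individuals."""
    y_prime = np.asarray(y_prime, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y_prime.size != y_hat.size:
        raise ValueError("paired vectors of unequal length")
    if y_prime.size < 3:
        raise ValueError("need at least 3 paired values for a correlation")
    if np.std(y_prime) == 0.0 or np.std(y_hat) == 0.0:
        warnings.warn("zero variance on one side; PA undefined", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(y_prime, y_hat).statistic)


def prediction_accuracy(pa: float, h2_train: float, h2_min: float = 1e-3) -> float:
    """ACC = PA / sqrt(h2); NaN when the training h2 is inestimable."""
    if not 0.0 <= h2_train <= 1.0:
        raise ValueError("h2 must be in [0, 1]")
    if h2_train < h2_min or np.isnan(pa):
        return float("nan")
    return float(pa / np.sqrt(h2_train))


def _fit_and_predict(y_train, train_ids, kernel, algorithm, tol, max_iter, eig=None):
    K_tt = kernel.submatrix(train_ids)
    vc = blup.reml_fit(y_train, K_tt, algorithm=algorithm, tol=tol,
                       max_iter=max_iter, eig=eig)
    fit = blup.solve_mme(y_train, kernel, train_ids, vc)
    return vc, fit


def run_approach(
    approach: str,
    model: str,
    adjusted: pd.Series,
    cohorts: pd.Series,
    kernel: RelationshipMatrix,
    trait: str = "density",
    algorithm: str = "em",
    tol: float = 1e-6,
    max_iter: int = 500,
    h2_source: str = "train",
) -> list[ValidationResult]:
    """One approach for one trait and one model (ABLUP or GBLUP).

    ``adjusted`` maps id -> y' for every phenotyped individual; ``cohorts``
    maps id -> cohort label; ``kernel`` spans every individual to use
    (phenotyped or not). Individuals absent from the kernel are excluded
    (for GBLUP that reproduces the genotyped-only subset).
    """
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}")
    train_cohort, valid_cohorts = APPROACHES[approach]
    kernel_ids = set(kernel.ids)
    phenotyped = [i for i in adjusted.index if i in kernel_ids]
    train_ids = [i for i in phenotyped if cohorts.get(i) == train_cohort]
    if len(train_ids) < 3:
        raise ValueError(f"approach {approach}: fewer than 3 training individuals")
    vc, fit = _fit_and_predict(
        adjusted.loc[train_ids].to_numpy(), train_ids, kernel, algorithm, tol, max_iter
    )
    h2 = vc.h2
    results = []
    for vcoh in valid_cohorts:
        valid_ids = [i for i in phenotyped if cohorts.get(i) == vcoh]
        if not valid_ids:
            raise ValueError(f"validation cohort {vcoh} absent from kernel/phenotypes")
        overlap = set(train_ids) & set(valid_ids)
        if overlap:
            raise RuntimeError(
                f"training and validation sets share individuals: {sorted(overlap)[:5]}"
            )
        pa = predictive_ability(
            adjusted.loc[valid_ids].to_numpy(), fit.ebv.loc[valid_ids].to_numpy()
        )
        acc = prediction_accuracy(pa, h2)
        results.append(
            ValidationResult(
                approach=approach, model=model, trait=trait,
                train_cohort=train_cohort, validation_cohort=vcoh,
                pa=pa, acc=acc, h2=h2,
                n_train=len(train_ids), n_valid=len(valid_ids),
                acc_reason="inestimable" if np.isnan(acc) else "",
            )
        )
    return results


def early_training_sweep(
    g0_rings: pd.DataFrame,
    validation_targets: dict,
    kernel: RelationshipMatrix,
    mode: str,
    rings=range(1, 22),
    min_fraction: float = 0.5,
    acc_display_max_ring: int = 16,
    algorithm: str = "em",
    tol: float = 1e-6,
    max_iter: int = 500,
) -> list[SweepResult]:
    """Train GBLUP on G0 density at increasing cambial age; validate on
    progeny.

    ``g0_rings`` is the parental ring table; ``validation_targets`` maps
    ``(trial, window)`` -> Series of adjusted validation phenotypes, with
    window in {"juvenile-10", "whole-core"}. ``mode`` is "AWE" (cumulative
    area-weighted up to ring k) or "SAD" (single ring k). Rings measured on
    fewer than ``min_fraction`` of G0 trees are skipped; trees lacking ring
    k are dropped from training at that k. ACC rows beyond
    ``acc_display_max_ring`` are flagged as low-reliability.
    """
    from . import phenotypes as ph

    if mode not in ("AWE", "SAD"):
        raise ValueError("mode must be 'AWE' or 'SAD'")
    kernel_ids = set(kernel.ids)
    g0_ids = [i for i in g0_rings["id"].unique() if i in kernel_ids]
    if not g0_ids:
        raise ValueError("no G0 trees present in the kernel")
    g0_rings = g0_rings[g0_rings["id"].isin(g0_ids)]
    n_g0 = len(g0_ids)
    max_ring = g0_rings.groupby("id")["ring"].max()

    # one eigendecomposition per distinct training set, reused across rings
    eig_cache: dict = {}
    results: list[SweepResult] = []
    for k in rings:
        have = max_ring.index[max_ring >= k]
        if len(have) < min_fraction * n_g0:
            warnings.warn(f"ring {k}: <{min_fraction:.0%} of G0 trees reach it; skipped",
                          stacklevel=2)
            continue
        if mode == "AWE":
            y = ph.awe_table(g0_rings, upto_ring=k)
        else:
            y = ph.sad_table(g0_rings, ring=k)
        y = y.loc[[i for i in have if i in y.index]]
        train_ids = list(y.index)
        y_train = y.to_numpy() - y.to_numpy().mean()  # archive clones: center only
        key = tuple(train_ids)
        if key not in eig_cache:
            eig_cache[key] = linalg.eigh(kernel.submatrix(train_ids).values)
        vc, fit = _fit_and_predict(
            y_train, train_ids, kernel, algorithm, tol, max_iter, eig=eig_cache[key]
        )
        for (trial, window), target in validation_targets.items():
            valid_ids = [i for i in target.index if i in kernel_ids]
            overlap = set(train_ids) & set(valid_ids)
            if overlap:
                raise RuntimeError(
                    f"sweep: training/validation overlap {sorted(overlap)[:5]}"
                )
            pa = predictive_ability(
                target.loc[valid_ids].to_numpy(), fit.ebv.loc[valid_ids].to_numpy()
            )
            acc = prediction_accuracy(pa, vc.h2)
            results.append(
                SweepResult(
                    mode=mode, ring=int(k), window=window, trial=trial,
                    pa=pa, acc=acc, h2=vc.h2,
                    n_train=len(train_ids), n_valid=len(valid_ids),
                    acc_flagged=int(k) > acc_display_max_ring,
                )
            )
    return results


def results_to_frame(results) -> pd.DataFrame:
    """Tidy frame (one row per result) from ValidationResult/SweepResult lists."""
    from dataclasses import asdict

    return pd.DataFrame([asdict(r) for r in results])
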