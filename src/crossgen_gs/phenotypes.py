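"""Analysis-ready trait values from ring tables, and design adjustment.

A wood core is a sequence of annual rings from the pith outward. Assuming
circular rings, ring ``i`` with cumulative radius ``r_i`` occupies the
annulus area ``a_i = pi * (r_i^2 - r_{i-1}^2)``, and the area-weighted
trait value up to ring ``k`` is

    AWE_k = sum_{i<=k} a_i * d_i / sum_{i<=k} a_i,

where ``d_i`` is the ring-i trait value. The single-annual-ring direct
value (SAD) at ring ``k`` is just ``d_k``; the juvenile value is the AWE
over the innermost ``min(10, n_rings)`` rings.

Before model training, phenotypes are adjusted for trial design: per
trial the mixed model ``y = mu + W b + Z u + e`` (grand mean fixed,
incomplete blocks random, additive genetic effect with a supplied
relationship kernel) is fitted by REML and ``y' = y - mu_hat - W b_hat``
retains genetic and residual variation only. Breeding-archive clones with
no block design are mean-centered.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import blup
from .relationships import RelationshipMatrix

__all__ = [
    "validate_ring_table",
    "compute_awe",
    "awe_table",
    "extract_sad",
    "sad_table",
    "juvenile_value",
    "whole_core_value",
    "derive_traits",
    "adjust_phenotypes",
]


def validate_ring_table(rings: pd.DataFrame, value_col: str = "value") -> None:
    required = {"id", "ring", "width_mm", value_col}
    missing = required - set(rings.columns)
    if missing:
        raise ValueError(f"ring table missing columns {sorted(missing)}")
    if rings.duplicated(["id", "ring"]).any():
        dup = rings.loc[rings.duplicated(["id", "ring"]), ["id", "ring"]].iloc[0]
        raise ValueError(f"duplicate ring row: id={dup['id']} ring={dup['ring']}")
    if (rings["width_mm"] <= 0).any():
        raise ValueError("non-positive ring widths present")
    for tid, grp in rings.groupby("id", sort=False):
        r = np.sort(grp["ring"].to_numpy())
        if r[0] != 1 or not np.array_equal(r, np.arange(1, len(r) + 1)):
            raise ValueError(f"rings of tree {tid} not consecutive from 1")


def _areas(widths: np.ndarray) -> np.ndarray:
    radii = np.cumsum(widths)
    prev = np.concatenate([[0.0], radii[:-1]])
    return np.pi * (radii**2 - prev**2)


def compute_awe(
    rings: pd.DataFrame, tree_id, upto_ring: int, value_col: str = "value"
) -> float:
    """Cumulative area-weighted value over rings 1..k for one tree."""
    if upto_ring < 1:
        raise ValueError("upto_ring must be >= 1")
    sub = rings.loc[rings["id"] == tree_id].sort_values("ring")
    if sub.empty:
        raise KeyError(f"no rings for tree {tree_id}")
    have = set(sub["ring"])
    gaps = [r for r in range(1, upto_ring + 1) if r not in have]
    if gaps:
        raise ValueError(f"tree {tree_id} missing ring(s) {gaps} below {upto_ring}")
    sub = sub.loc[sub["ring"] <= upto_ring]
    a = _areas(sub["width_mm"].to_numpy())
    d = sub[value_col].to_numpy()
    return float(np.sum(a * d) / np.sum(a))


def awe_table(
    rings: pd.DataFrame, upto_ring: int | None = None, value_col: str = "value"
) -> pd.Series:
    """AWE per tree, vectorized. ``upto_ring=None`` uses each tree's whole
    core; otherwise trees lacking ring ``upto_ring`` are omitted."""
    df = rings.sort_values(["id", "ring"]).copy()
    if upto_ring is not None:
        counts = df.groupby("id")["ring"].max()
        keep = counts.index[counts >= upto_ring]
        df = df[df["id"].isin(keep) & (df["ring"] <= upto_ring)]
    radii = df.groupby("id")["width_mm"].cumsum()
    prev = radii - df["width_mm"]
    area = np.pi * (radii**2 - prev**2)
    num = (area * df[value_col]).groupby(df["id"]).sum()
    den = area.groupby(df["id"]).sum()
    return (num / den).rename("awe")


def extract_sad(
    rings: pd.DataFrame, tree_id, ring: int, value_col: str = "value"
) -> float:
    """The ring-k trait value, unchanged (single annual-ring direct)."""
    sub = rings.loc[(rings["id"] == tree_id) & (rings["ring"] == ring), value_col]
    if sub.empty:
        raise ValueError(f"tree {tree_id} has no ring {ring}")
    return float(sub.iloc[0])


def sad_table(rings: pd.DataFrame, ring: int, value_col: str = "value") -> pd.Series:
    sub = rings.loc[rings["ring"] == ring]
    return pd.Series(sub[value_col].to_numpy(), index=sub["id"].to_numpy(), name="sad")


def juvenile_value(
    rings: pd.DataFrame, tree_id, value_col: str = "value", window: int = 10
) -> float:
    """AWE over the innermost min(window, n_rings) rings (juvenile core)."""
    n = int(rings.loc[rings["id"] == tree_id, "ring"].max())
    if not n:
        raise KeyError(f"no rings for tree {tree_id}")
    return compute_awe(rings, tree_id, min(window, n), value_col=value_col)


def juvenile_table(rings: pd.DataFrame, value_col: str = "value", window: int = 10) -> pd.Series:
    nmax = rings.groupby("id")["ring"].max()
    parts = []
    for n, ids in nmax.groupby(nmax):
        k = min(window, int(n))
        sub = rings[rings["id"].isin(ids.index)]
        parts.append(awe_table(sub, upto_ring=k, value_col=value_col))
    return pd.concat(parts).rename("juvenile")


def whole_core_value(rings: pd.DataFrame, tree_id, value_col: str = "value") -> float:
    n = int(rings.loc[rings["id"] == tree_id, "ring"].max())
    return compute_awe(rings, tree_id, n, value_col=value_col)


def derive_traits(
    rings: pd.DataFrame,
    derivation: str,
    k: int | None = None,
    trait: str = "density",
    value_col: str = "value",
) -> pd.DataFrame:
    """TraitTable rows (id, trait, derivation, value) for one derivation:
    ``awe`` (requires k), ``sad`` (requires k), ``juvenile`` or
    ``whole-core``."""
    if derivation == "awe":
        if k is None:
            raise ValueError("AWE derivation needs upto-ring k")
        vals = awe_table(rings, upto_ring=k, value_col=value_col)
        tag = f"AWE-upto-{k}"
    elif derivation == "sad":
        if k is None:
            raise ValueError("SAD derivation needs ring k")
        vals = sad_table(rings, ring=k, value_col=value_col)
        tag = f"SAD-ring-{k}"
    elif derivation == "juvenile":
        vals = juvenile_table(rings, value_col=value_col)
        tag = "juvenile-10"
    elif derivation == "whole-core":
        vals = awe_table(rings, upto_ring=None, value_col=value_col)
        tag = "whole-core"
    else:
        raise ValueError(f"unknown derivation {derivation!r}")
    return pd.DataFrame({"id": vals.index, "trait": trait, "derivation": tag,
                         "value": vals.to_numpy()})


def adjust_phenotypes(
    traits: pd.DataFrame,
    design: pd.DataFrame,
    relationship: RelationshipMatrix | None = None,
    block_as: str = "random",
    tol: float = 1e-6,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Remove trial design variation: per trait/derivation/trial fit
    ``y = mu + W b + Z u + e`` and return ``y' = y - mu_hat - b_hat``.

    ``relationship`` supplies the additive kernel for the genetic term; with
    ``None`` the model drops the genetic term. Trials with fewer than two
    blocks (e.g. the G0 archive) are mean-centered with a warning. With
    ``block_as="fixed"`` blocks enter as fixed effects (sum-to-zero, via
    least squares).
    """
    need = {"id", "trait", "derivation", "value"}
    if not need <= set(traits.columns):
        raise ValueError(f"trait table needs columns {sorted(need)}")
    des = design.set_index("id")
    missing = set(traits["id"]) - set(des.index)
    if missing:
        raise ValueError(f"designs missing for ids, e.g. {sorted(missing)[:5]}")

    out_rows = []
    for (trait, deriv), tgrp in traits.groupby(["trait", "derivation"], sort=False):
        tgrp = tgrp.assign(
            trial=des.loc[tgrp["id"], "trial"].to_numpy(),
            block=des.loc[tgrp["id"], "block"].to_numpy(),
        )
        for trial, grp in tgrp.groupby("trial", sort=False):
            y = grp["value"].to_numpy(dtype=float)
            ids = grp["id"].to_numpy()
            blocks = grp["block"].to_numpy()
            ublocks = np.unique(blocks)
            if len(ublocks) < 2:
                warnings.warn(
                    f"trial {trial!r}: <2 blocks; adjustment reduces to mean-centering",
                    stacklevel=2,
                )
                adj = y - y.mean()
            elif block_as == "fixed":
                adj = _adjust_fixed_blocks(y, blocks, ublocks)
            else:
                adj = _adjust_random_blocks(
                    y, ids, blocks, ublocks, relationship, tol, max_iter
                )
            out_rows.append(pd.DataFrame({"id": ids, "trait": trait,
                                          "derivation": deriv, "adjusted": adj}))
    return pd.concat(out_rows, ignore_index=True)


def _adjust_fixed_blocks(y, blocks, ublocks):
    # intercept + sum-to-zero block contrasts
    n = y.size
    B = len(ublocks)
    X = np.ones((n, B))
    for j, b in enumerate(ublocks[:-1]):
        X[:, j + 1] = (blocks == b).astype(float) - (blocks == ublocks[-1]).astype(float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    eff = {b: coef[j + 1] for j, b in enumerate(ublocks[:-1])}
    eff[ublocks[-1]] = -sum(eff.values())
    return y - coef[0] - np.array([eff[b] for b in blocks])


def _adjust_random_blocks(y, ids, blocks, ublocks, relationship, tol, max_iter):
    n = y.size
    W = (blocks[:, None] == ublocks[None, :]).astype(float)
    terms = [blup.RandomTerm("block", W)]
    if relationship is not None:
        K = relationship.submatrix(ids)
        terms.append(blup.RandomTerm("genetic", np.eye(n), K.values))
    fit = blup.reml_multi(y, np.ones((n, 1)), terms, algorithm="ai",
                          tol=tol, max_iter=max_iter)
    block_blup = fit.blups["block"]
    return y - fit.beta[0] - W @ block_blup
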