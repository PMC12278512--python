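"""Relationship matrices and SNP quality control.

Two covariance kernels drive BLUP breeding-value prediction:

* the pedigree numerator relationship matrix ``A``, built by the tabular
  method over a topological ordering of the pedigree, optionally with
  phantom-parent genetic groups absorbing population structure among
  founders with unknown parents, and
* the VanRaden genomic relationship matrix ``G = (M - P)(M - P)' /
  (2 * sum_i p_i (1 - p_i))``, where ``M`` holds 0/1/2 allele counts and
  column ``i`` of ``P`` is ``2 p_i`` (twice the allele frequency).

QC mirrors standard SNP filtering for exome-capture data: minor allele
frequency, per-individual and per-site missingness, heterozygote excess and
an exact Hardy-Weinberg test, applied in that order.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "Pedigree",
    "RelationshipMatrix",
    "QcReport",
    "qc_filter",
    "hwe_exact_pvalue",
    "impute_missing",
    "build_A",
    "build_G",
    "blend",
    "relatedness_summary",
    "pair_mean",
    "RelatednessSummary",
]

UNKNOWN = ""  # sentinel for an unknown parent in pedigree frames


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic markers, coded 0/1/2 with NaN for missing.

    Codes count copies of the alternative allele. ``allele_freqs`` returns
    the observed alternative-allele frequency per marker, ignoring missing
    entries.
    """

    ids: np.ndarray
    markers: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.markers = np.asarray(self.markers, dtype=object)
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.ids), len(self.markers)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.ids)} ids x {len(self.markers)} markers"
            )
        valid = np.isnan(self.codes) | np.isin(self.codes, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.unique(self.codes[~valid])
            raise ValueError(f"invalid genotype codes {bad}; expected 0/1/2/missing")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids in genotype matrix")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_freqs(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            return np.nanmean(self.codes, axis=0) / 2.0

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.codes)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.codes).any())

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        idx = _index_of(self.ids, ids)
        return GenotypeMatrix(self.ids[idx], self.markers, self.codes[idx, :])

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """``keep`` is a boolean mask or an array of marker names."""
        keep = np.asarray(keep)
        if keep.dtype != bool:
            keep = np.isin(self.markers, keep)
        return GenotypeMatrix(self.ids, self.markers[keep], self.codes[:, keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.ids, columns=self.markers)


def _index_of(haystack: np.ndarray, needles) -> np.ndarray:
    pos = {v: i for i, v in enumerate(haystack)}
    try:
        return np.array([pos[n] for n in needles], dtype=int)
    except KeyError as exc:
        raise KeyError(f"id {exc.args[0]!r} not present") from None


class Pedigree:
    """Acyclic parent map with optional genetic-group labels.

    Stored as a frame with columns ``id, dam, sire, generation, group`` (and
    optionally ``true_sire`` when a simulator logs hidden fathers). Unknown
    parents are the empty string. Parents referenced but never listed as
    records are auto-promoted to founders with a warning.
    """

    COLS = ["id", "dam", "sire", "generation", "group"]

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        for col in ("dam", "sire"):
            df[col] = df[col].fillna(UNKNOWN).astype(str).replace("nan", UNKNOWN)
        df["id"] = df["id"].astype(str)
        if "generation" not in df:
            df["generation"] = 0
        if "group" not in df:
            df["group"] = UNKNOWN
        df["group"] = df["group"].fillna(UNKNOWN).astype(str).replace("nan", UNKNOWN)
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate pedigree ids: {dups}")
        known = set(df["id"])
        orphans = sorted(
            {p for p in pd.concat([df["dam"], df["sire"]]) if p and p not in known}
        )
        if orphans:
            warnings.warn(
                f"{len(orphans)} parents not listed as records; promoted to founders",
                stacklevel=2,
            )
            add = pd.DataFrame(
                {"id": orphans, "dam": UNKNOWN, "sire": UNKNOWN, "generation": -1,
                 "group": UNKNOWN}
            )
            df = pd.concat([df, add], ignore_index=True)
        self.frame = df.reset_index(drop=True)
        self._check_acyclic()

    def _graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.frame["id"])
        for _, row in self.frame.iterrows():
            for p in (row["dam"], row["sire"]):
                if p:
                    g.add_edge(p, row["id"])
        return g

    def _check_acyclic(self) -> None:
        bad = self.frame["id"] == self.frame["dam"]
        bad |= self.frame["id"] == self.frame["sire"]
        if bad.any():
            raise ValueError("individual listed as its own parent")
        if not nx.is_directed_acyclic_graph(self._graph()):
            raise ValueError("pedigree contains a cycle")

    @property
    def ids(self) -> np.ndarray:
        return self.frame["id"].to_numpy(dtype=object)

    def topological_order(self) -> list[str]:
        """Ids with every parent preceding its offspring."""
        return list(nx.lexicographical_topological_sort(self._graph()))

    def parents(self, individual: str) -> tuple[str, str]:
        row = self.frame.loc[self.frame["id"] == individual]
        if row.empty:
            raise KeyError(individual)
        return row["dam"].iloc[0], row["sire"].iloc[0]

    def founders(self) -> list[str]:
        f = self.frame
        return f.loc[(f["dam"] == UNKNOWN) & (f["sire"] == UNKNOWN), "id"].tolist()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class RelationshipMatrix:
    """Labeled symmetric covariance kernel (pedigree A, genomic G, or blend)."""

    ids: np.ndarray
    values: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix not square over its ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix not symmetric")

    def submatrix(self, ids) -> "RelationshipMatrix":
        idx = _index_of(self.ids, ids)
        return RelationshipMatrix(
            self.ids[idx], self.values[np.ix_(idx, idx)], self.kind, dict(self.meta)
        )

    def indices(self, ids) -> np.ndarray:
        return _index_of(self.ids, ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


# ---------------------------------------------------------------------------
# Quality control


@dataclass
class QcReport:
    """Per-filter removal counts, in application order."""

    steps: list = field(default_factory=list)  # (name, markers_removed, inds_removed)
    n_markers_in: int = 0
    n_individuals_in: int = 0
    n_markers_out: int = 0
    n_individuals_out: int = 0

    def add(self, name: str, markers: int = 0, individuals: int = 0) -> None:
        self.steps.append({"filter": name, "markers_removed": int(markers),
                           "individuals_removed": int(individuals)})

    def validate(self) -> None:
        m = sum(s["markers_removed"] for s in self.steps)
        i = sum(s["individuals_removed"] for s in self.steps)
        assert self.n_markers_in - m == self.n_markers_out
        assert self.n_individuals_in - i == self.n_individuals_out

    def to_dict(self) -> dict:
        return {
            "n_markers_in": self.n_markers_in,
            "n_individuals_in": self.n_individuals_in,
            "n_markers_out": self.n_markers_out,
            "n_individuals_out": self.n_individuals_out,
            "steps": self.steps,
        }


def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact two-sided Hardy-Weinberg test for one biallelic SNP.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the probabilities no larger than that of the observed
    configuration (Wigginton-style exact SNP-HWE).
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    # log-probability of each possible het count, up to a shared constant
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (
        hets * math.log(2.0)
        - _lgamma_arr(hets + 1)
        - _lgamma_arr(homr + 1)
        - _lgamma_arr(homc + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(x)


def qc_filter(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.05,
    ind_missing_max: float = 0.70,
    site_missing_max: float = 0.70,
    het_max: float = 0.60,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply SNP/individual filters in order: MAF, individual missingness,
    site missingness, heterozygote excess / Hardy-Weinberg deviation.

    Raises ``ValueError`` (with the report attached as ``.report``) if
    nothing survives.
    """
    report = QcReport(
        n_markers_in=genotypes.n_markers, n_individuals_in=genotypes.n_individuals
    )
    gm = genotypes

    p = gm.allele_freqs()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    keep = ~(maf < maf_min)  # NaN-frequency (all-missing) markers pass to later step
    report.add("maf", markers=int((~keep).sum()))
    gm = gm.subset_markers(keep)

    ind_missing = np.isnan(gm.codes).mean(axis=1) if gm.n_markers else np.zeros(gm.n_individuals)
    keep_ind = ind_missing <= ind_missing_max
    report.add("individual_missingness", individuals=int((~keep_ind).sum()))
    gm = GenotypeMatrix(gm.ids[keep_ind], gm.markers, gm.codes[keep_ind, :])

    site_missing = np.isnan(gm.codes).mean(axis=0) if gm.n_individuals else np.ones(gm.n_markers)
    keep = site_missing <= site_missing_max
    report.add("site_missingness", markers=int((~keep).sum()))
    gm = gm.subset_markers(keep)

    n_het = np.nansum(gm.codes == 1, axis=0)
    n_hom0 = np.nansum(gm.codes == 0, axis=0)
    n_hom2 = np.nansum(gm.codes == 2, axis=0)
    n_called = n_het + n_hom0 + n_hom2
    with np.errstate(invalid="ignore", divide="ignore"):
        het_rate = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)
    hwe_p = np.array(
        [hwe_exact_pvalue(int(h), int(a), int(b)) for h, a, b in zip(n_het, n_hom0, n_hom2)]
    )
    keep = ~((het_rate > het_max) | (hwe_p < hwe_p_min))
    report.add("het_excess_hwe", markers=int((~keep).sum()))
    gm = gm.subset_markers(keep)

    report.n_markers_out = gm.n_markers
    report.n_individuals_out = gm.n_individuals
    report.validate()
    if gm.n_markers == 0 or gm.n_individuals == 0:
        err = ValueError("no markers/individuals survive QC")
        err.report = report
        raise err
    return gm, report


def impute_missing(genotypes: GenotypeMatrix, round_codes: bool = False) -> GenotypeMatrix:
    """Replace missing codes with the marker mean ``2 p_i`` (optionally
    rounded to the nearest integer code)."""
    codes = genotypes.codes.copy()
    p = genotypes.allele_freqs()
    if np.isnan(p).any():
        bad = genotypes.markers[np.isnan(p)]
        raise ValueError(f"markers entirely missing (QC should remove them): {bad[:5]}")
    fill = 2.0 * p
    if round_codes:
        fill = np.clip(np.round(fill), 0, 2)
    rows, cols = np.nonzero(np.isnan(codes))
    codes[rows, cols] = fill[cols]
    return GenotypeMatrix(genotypes.ids, genotypes.markers, codes)


# ---------------------------------------------------------------------------
# A matrix (tabular method)


def build_A(
    pedigree: Pedigree,
    use_groups: bool = False,
    include_phantoms: bool = False,
) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    ``A_ii = 1 + 0.5 * A[dam, sire]`` and ``A_ij = 0.5 * (A[j, dam(i)] +
    A[j, sire(i)])`` over a topological ordering; unknown parents contribute
    zero. With ``use_groups`` every unknown-parent slot of a record carrying
    a genetic-group label is replaced by a phantom founder shared by that
    group, so group-mates with unknown parents become related like
    paternal half-sibs of the phantom ancestor.
    """
    frame = pedigree.frame
    dam_of = dict(zip(frame["id"], frame["dam"]))
    sire_of = dict(zip(frame["id"], frame["sire"]))
    phantoms: list[str] = []
    if use_groups:
        for _, row in frame.iterrows():
            grp = row["group"]
            if not grp:
                continue
            ph = f"__group__{grp}"
            if row["dam"] == UNKNOWN:
                dam_of[row["id"]] = ph
            if row["sire"] == UNKNOWN:
                sire_of[row["id"]] = ph
            if ph not in phantoms and (row["dam"] == UNKNOWN or row["sire"] == UNKNOWN):
                phantoms.append(ph)

    order = phantoms + pedigree.topological_order()
    pos = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, ind in enumerate(order):
        d = pos.get(dam_of.get(ind, UNKNOWN), -1)
        s = pos.get(sire_of.get(ind, UNKNOWN), -1)
        if d >= i or s >= i:
            raise ValueError(f"{ind} appears before one of its parents")
        row = np.zeros(i)
        if d >= 0:
            row += 0.5 * A[d, :i]
        if s >= 0:
            row += 0.5 * A[s, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[d, s] if d >= 0 and s >= 0 else 0.0)

    out_ids = order if include_phantoms else [i for i in order if i not in set(phantoms)]
    idx = np.array([pos[i] for i in out_ids])
    # return in the pedigree's original record order (phantoms appended if kept)
    original = [i for i in pedigree.ids if i in set(out_ids)]
    if include_phantoms:
        original = phantoms + original
    idx = np.array([pos[i] for i in original])
    return RelationshipMatrix(
        np.array(original, dtype=object),
        A[np.ix_(idx, idx)],
        "A",
        {"use_groups": use_groups, "n_groups": len(phantoms)},
    )


# ---------------------------------------------------------------------------
# G matrix (VanRaden)


def build_G(
    genotypes: GenotypeMatrix,
    freqs: np.ndarray | None = None,
    centering: str = "vanraden",
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix.

    ``G = W W' / (2 * sum p (1 - p))`` with ``W = M - P``. The standard
    (default) ``P`` column is ``2 p_i``; ``centering="as-printed"`` uses
    ``2 (p_i - 0.5)`` instead, for comparison with sources that print the
    formula that way. With observed frequencies and complete data the
    default G has exactly zero row sums.
    """
    if genotypes.has_missing():
        raise ValueError("missing genotypes; run impute_missing first")
    p = genotypes.allele_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    if p.shape != (genotypes.n_markers,):
        raise ValueError("allele-frequency vector length mismatch")
    if np.any((p <= 0.0) | (p >= 1.0)):
        bad = genotypes.markers[(p <= 0.0) | (p >= 1.0)]
        raise ValueError(f"monomorphic markers present (QC must precede): {bad[:5]}")
    if centering == "vanraden":
        P = 2.0 * p
    elif centering == "as-printed":
        P = 2.0 * (p - 0.5)
    else:
        raise ValueError(f"unknown centering {centering!r}")
    W = genotypes.codes - P
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    G = (W @ W.T) / denom
    G = 0.5 * (G + G.T)  # enforce exact symmetry against rounding
    return RelationshipMatrix(
        genotypes.ids,
        G,
        "G",
        {
            "n_markers": genotypes.n_markers,
            "centering": centering,
            "freq_source": "observed" if freqs is None else "supplied",
        },
    )


def blend(
    K: RelationshipMatrix, weight: float = 0.98, reference="identity"
) -> RelationshipMatrix:
    """Shrink a kernel toward a reference for invertibility:
    ``w * K + (1 - w) * ref``. ``reference`` is ``"identity"`` or a
    RelationshipMatrix (e.g. the pedigree A submatrix over the same ids)."""
    if not 0.0 < weight <= 1.0:
        raise ValueError("blend weight must be in (0, 1]")
    if reference == "identity":
        ref = np.eye(len(K.ids))
        ref_kind = "identity"
    else:
        if not np.array_equal(reference.ids, K.ids):
            reference = reference.submatrix(K.ids)
        ref = reference.values
        ref_kind = reference.kind
    vals = weight * K.values + (1.0 - weight) * ref
    meta = dict(K.meta)
    meta.update({"blend_weight": weight, "blend_reference": ref_kind})
    kind = K.kind if weight == 1.0 else "blended"
    return RelationshipMatrix(K.ids, vals, kind, meta)


# ---------------------------------------------------------------------------
# Relatedness summaries


@dataclass
class RelatednessSummary:
    within_mean: float
    among_mean: float
    n_within: int
    n_among: int
    within_hist: tuple
    among_hist: tuple
    bin_width: float = 0.05


def _hist(values: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    if values.size == 0:
        return np.array([]), np.array([0.0])
    lo = math.floor(values.min() / bin_width) * bin_width
    hi = math.ceil(values.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    counts, edges = np.histogram(values, bins=edges)
    return counts, edges


def relatedness_summary(
    K: RelationshipMatrix, family_map, bin_width: float = 0.05
) -> RelatednessSummary:
    """Partition off-diagonal coefficients into within- vs among-family
    pairs and summarize (means, counts, fixed-width histograms)."""
    fam = pd.Series(family_map)
    missing = [i for i in K.ids if i not in fam.index]
    if missing:
        raise KeyError(f"family map misses ids, e.g. {missing[:5]}")
    labels = fam.loc[list(K.ids)].to_numpy()
    iu, ju = np.triu_indices(len(K.ids), k=1)
    vals = K.values[iu, ju]
    same = labels[iu] == labels[ju]
    within = vals[same]
    among = vals[~same]
    return RelatednessSummary(
        within_mean=float(within.mean()) if within.size else float("nan"),
        among_mean=float(among.mean()) if among.size else float("nan"),
        n_within=int(within.size),
        n_among=int(among.size),
        within_hist=_hist(within, bin_width),
        among_hist=_hist(among, bin_width),
        bin_width=bin_width,
    )


def pair_mean(K: RelationshipMatrix, pairs) -> float:
    """Mean kernel entry over explicit (id_a, id_b) pairs, e.g. dam-offspring."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no pairs supplied")
    ia = K.indices([a for a, _ in pairs])
    ib = K.indices([b for _, b in pairs])
    return float(K.values[ia, ib].mean())
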