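"""QC filters, pedigree A (vs recursive and gene-dropping oracles),
VanRaden G identities, blending and relatedness summaries."""
import math

import numpy as np
import pandas as pd
import pytest

from crossgen_gs import relationships as rel
from tests._oracles import gene_drop_A, random_pedigree, recursive_kinship_A


def gm_from(codes, ids=None, markers=None):
    codes = np.asarray(codes, float)
    ids = ids or [f"i{k}" for k in range(codes.shape[0])]
    markers = markers or [f"m{k}" for k in range(codes.shape[1])]
    return rel.GenotypeMatrix(ids, markers, codes)


class TestQc:
    def test_hand_counted_toy(self, rng):
        n = 10
        codes = np.zeros((n, 4))
        # marker 0: MAF 0.30; marker 1: MAF 0.05... make 0.02 impossible at n=10,
        # use one alt allele in 2n=20 -> 0.05 < threshold? equals threshold: keep.
        codes[:3, 0] = [1, 1, 1]  # p = 3/20 = 0.15
        codes[0, 1] = 1  # p = 0.05 -> not < 0.05, kept; drop via 0 alt instead
        codes[:, 1] = 0  # monomorphic, MAF 0 -> removed
        codes[:4, 2] = [1, 2, 1, 2]  # p = 6/20 = 0.3
        codes[: int(0.8 * n), 3] = np.nan  # 80% missing
        codes[int(0.8 * n):, 3] = [1, 1]  # MAF 0.5 among called
        gm = gm_from(codes)
        out, report = rel.qc_filter(gm)
        assert list(out.markers) == ["m0", "m2"]
        steps = {s["filter"]: s["markers_removed"] for s in report.steps}
        assert steps["maf"] == 1
        assert steps["site_missingness"] == 1
        assert report.n_markers_out == 2

    def test_clean_matrix_passes_through(self, rng):
        codes = rng.binomial(2, 0.4, size=(50, 8)).astype(float)
        gm = gm_from(codes)
        out, report = rel.qc_filter(gm)
        np.testing.assert_array_equal(out.codes, gm.codes)
        assert report.n_markers_out == 8 and report.n_individuals_out == 50

    def test_monomorphic_removed_and_empty_output_raises(self):
        gm = gm_from(np.zeros((6, 1)))
        with pytest.raises(ValueError) as exc:
            rel.qc_filter(gm)
        assert exc.value.report.steps[0]["markers_removed"] == 1

    def test_heterozygote_excess_removed(self, rng):
        codes = rng.binomial(2, 0.5, size=(60, 3)).astype(float)
        codes[:, 0] = 1.0  # all-het marker: het excess + extreme HWE deviation
        out, report = rel.qc_filter(gm_from(codes))
        assert "m0" not in list(out.markers)
        assert {s["filter"]: s for s in report.steps}["het_excess_hwe"][
            "markers_removed"] >= 1

    def test_high_missing_individual_removed(self, rng):
        codes = rng.binomial(2, 0.4, size=(12, 10)).astype(float)
        codes[0, :8] = np.nan  # 80% missing individual
        out, report = rel.qc_filter(gm_from(codes))
        assert out.n_individuals == 11


def test_hwe_exact_pvalue_matches_enumeration():
    """Oracle: direct enumeration of P(het count | allele counts) with
    factorials."""
    def oracle(nh, n1, n2):
        n = nh + n1 + n2
        rare = 2 * min(n1, n2) + nh
        # unnormalized configuration weights 2^h / (h! r! c!)
        hs = list(range(rare % 2, rare + 1, 2))
        ws = []
        for h in hs:
            r = (rare - h) // 2
            c = n - h - r
            ws.append(2**h / (math.factorial(h) * math.factorial(r) * math.factorial(c)))
        tot = sum(ws)
        p_obs = ws[hs.index(nh)] / tot
        return sum(w / tot for w in ws if w / tot <= p_obs * (1 + 1e-12))

    for nh, n1, n2 in [(5, 3, 2), (0, 10, 10), (20, 0, 0), (7, 7, 7), (1, 49, 0)]:
        assert np.isclose(rel.hwe_exact_pvalue(nh, n1, n2), oracle(nh, n1, n2),
                          rtol=1e-10)


class TestImpute:
    def test_mean_imputation_and_mask_preserved(self):
        gm = gm_from([[0, 1], [2, np.nan], [1, 1]])
        out = rel.impute_missing(gm)
        assert np.isclose(out.codes[1, 1], 2 * (2 / 4))  # 2p of marker 2
        obs = ~gm.missing_mask()
        np.testing.assert_array_equal(out.codes[obs], gm.codes[obs])
        rounded = rel.impute_missing(gm, round_codes=True)
        assert rounded.codes[1, 1] == 1.0
        np.testing.assert_array_equal(rel.impute_missing(out).codes, out.codes)

    def test_fully_missing_marker_rejected(self):
        gm = gm_from([[np.nan], [np.nan]])
        with pytest.raises(ValueError, match="entirely missing"):
            rel.impute_missing(gm)


def ped_frame(rows):
    return rel.Pedigree(pd.DataFrame(rows, columns=["id", "dam", "sire"]))


class TestBuildA:
    def test_textbook_relationships(self):
        ped = ped_frame([
            ("f1", "", ""), ("f2", "", ""),
            ("kid", "f1", "f2"),        # parent-offspring 0.5, A_kid,kid = 1
            ("hs1", "f1", ""), ("hs2", "f1", ""),  # maternal half-sibs 0.25
            ("inb", "kid", "f1"),       # parent-offspring mating: inbred
        ])
        A = rel.build_A(ped).to_frame()
        assert A.loc["f1", "f2"] == 0.0
        assert A.loc["f1", "f1"] == 1.0
        assert A.loc["kid", "f1"] == 0.5
        assert A.loc["hs1", "hs2"] == 0.25
        assert A.loc["kid", "kid"] == 1.0
        assert A.loc["inb", "inb"] == 1.25  # 1 + 0.5*A(kid,f1)

    def test_matches_recursive_kinship_oracle_on_random_pedigrees(self, rng):
        for _ in range(25):
            parents = random_pedigree(rng, int(rng.integers(5, 21)))
            ids, A_oracle = recursive_kinship_A(parents)
            frame = pd.DataFrame(
                [(i, d or "", s or "") for i, (d, s) in parents.items()],
                columns=["id", "dam", "sire"],
            )
            A = rel.build_A(rel.Pedigree(frame)).submatrix(ids)
            np.testing.assert_allclose(A.values, A_oracle, atol=1e-12)

    def test_matches_gene_dropping_within_monte_carlo_error(self, rng):
        parents = random_pedigree(rng, 12)
        ids, A_mc = gene_drop_A(parents, n_reps=100_000, rng=rng)
        frame = pd.DataFrame(
            [(i, d or "", s or "") for i, (d, s) in parents.items()],
            columns=["id", "dam", "sire"],
        )
        A = rel.build_A(rel.Pedigree(frame)).submatrix(ids)
        np.testing.assert_allclose(A.values, A_mc, atol=0.01)

    def test_cycle_and_self_parent_rejected(self):
        with pytest.raises(ValueError, match="own parent"):
            ped_frame([("a", "a", "")])
        with pytest.raises(ValueError, match="cycle"):
            ped_frame([("a", "b", ""), ("b", "a", "")])

    def test_phantom_group_sires_make_group_mates_half_sibs(self):
        frame = pd.DataFrame({
            "id": ["d1", "d2", "d3", "x", "y", "z"],
            "dam": ["", "", "", "d1", "d2", "d3"],
            "sire": [""] * 6,
            "group": ["", "", "", "north", "north", "south"],
        })
        A = rel.build_A(rel.Pedigree(frame), use_groups=True).to_frame()
        assert A.loc["x", "y"] == 0.25  # shared phantom sire for group "north"
        assert A.loc["x", "z"] == 0.0
        assert "__group__north" not in A.index  # phantoms excluded by default
        A_ph = rel.build_A(rel.Pedigree(frame), use_groups=True,
                           include_phantoms=True).to_frame()
        assert A_ph.loc["x", "__group__north"] == 0.5

    def test_child_listed_before_parent_is_fine(self):
        ped = ped_frame([("kid", "mum", ""), ("mum", "", "")])
        A = rel.build_A(ped).to_frame()
        assert A.loc["kid", "mum"] == 0.5


class TestBuildG:
    def test_row_sums_zero_with_observed_freqs(self, rng):
        codes = rng.binomial(2, rng.uniform(0.1, 0.5, 40), size=(30, 40)).astype(float)
        keep = ~((codes.mean(0) == 0) | (codes.mean(0) == 2))
        G = rel.build_G(gm_from(codes[:, keep]))
        np.testing.assert_allclose(G.values.sum(axis=1), 0.0, atol=1e-8)

    def test_hand_example_two_markers(self):
        # codes [[0,2],[1,1],[2,0]], observed p = (0.5, 0.5):
        # W = M - 2p = [[-1,1],[0,0],[1,-1]], denom = 2*(0.25+0.25) = 1
        G = rel.build_G(gm_from([[0, 2], [1, 1], [2, 0]]))
        np.testing.assert_allclose(np.diag(G.values), [2.0, 0.0, 2.0])
        assert np.isclose(G.values[0, 2], -2.0)
        np.testing.assert_allclose(G.values.sum(axis=1), 0.0, atol=1e-12)

    def test_duplicate_individuals_identical_entries(self, rng):
        codes = rng.binomial(2, 0.4, size=(5, 30)).astype(float)
        codes[1] = codes[0]
        G = rel.build_G(gm_from(codes))
        assert np.isclose(G.values[0, 1], G.values[0, 0])
        assert np.isclose(G.values[1, 1], G.values[0, 0])

    def test_missing_and_monomorphic_rejected(self, rng):
        with pytest.raises(ValueError, match="missing"):
            rel.build_G(gm_from([[0, np.nan], [1, 1], [2, 0]]))
        with pytest.raises(ValueError, match="monomorphic"):
            rel.build_G(gm_from([[0, 0], [1, 0], [2, 0]]))

    def test_printed_centering_variant_differs(self, rng):
        codes = rng.binomial(2, 0.3, size=(8, 20)).astype(float)
        keep = ~((codes.mean(0) == 0) | (codes.mean(0) == 2))
        gm = gm_from(codes[:, keep])
        g_std = rel.build_G(gm)
        g_printed = rel.build_G(gm, centering="as-printed")
        assert not np.allclose(g_std.values, g_printed.values)
        assert not np.allclose(g_printed.values.sum(axis=1), 0.0, atol=1e-6)


class TestBlend:
    def test_identity_weight_is_noop_and_linear_in_w(self, rng):
        codes = rng.binomial(2, 0.4, size=(6, 25)).astype(float)
        codes[1] = codes[0]
        G = rel.build_G(gm_from(codes))
        assert rel.blend(G, 1.0).values is not None
        np.testing.assert_array_equal(rel.blend(G, 1.0).values, G.values)
        b0 = rel.blend(G, 0.98).values
        bmid = rel.blend(G, 0.5).values
        np.testing.assert_allclose(bmid, 0.5 * G.values + 0.5 * np.eye(6))
        # duplicate rows make G singular; blending restores invertibility
        assert np.linalg.eigvalsh(G.values).min() < 1e-10
        assert np.linalg.eigvalsh(b0).min() > 0
        assert list(rel.blend(G, 0.9).ids) == list(G.ids)

    def test_blend_toward_A_submatrix(self, rng):
        codes = rng.binomial(2, 0.4, size=(3, 30)).astype(float)
        poly = ~((codes.mean(0) == 0) | (codes.mean(0) == 2))
        codes = codes[:, poly]
        G = rel.build_G(gm_from(codes, ids=["a", "b", "c"]))
        A = rel.RelationshipMatrix(["a", "b", "c"], np.eye(3) * 1.1, "A")
        out = rel.blend(G, 0.9, reference=A)
        np.testing.assert_allclose(out.values, 0.9 * G.values + 0.1 * A.values)
        with pytest.raises(ValueError):
            rel.blend(G, 0.0)


class TestRelatednessSummary:
    def test_pedigree_half_sib_families_exactly_quarter(self):
        rows = [("d1", "", ""), ("d2", "", "")]
        for fam, dam in enumerate(["d1", "d2"]):
            for k in range(3):
                rows.append((f"c{fam}{k}", dam, ""))
        A = rel.build_A(ped_frame(rows))
        kids = [i for i in A.ids if i.startswith("c")]
        fam_map = {i: i[1] for i in kids}
        s = rel.relatedness_summary(A.submatrix(kids), fam_map)
        assert s.within_mean == 0.25
        assert s.among_mean == 0.0
        assert s.n_within == 6 and s.n_among == 9
        counts, edges = s.within_hist
        assert np.isclose(edges[1] - edges[0], 0.05)
        assert counts.sum() == 6

    def test_pair_mean_and_missing_family(self):
        A = rel.RelationshipMatrix(["a", "b"], np.eye(2), "A")
        assert rel.pair_mean(A, [("a", "b")]) == 0.0
        with pytest.raises(KeyError):
            rel.relatedness_summary(A, {"a": 1})
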