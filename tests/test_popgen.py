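"""Nei distance, Neighbor-Joining, PCoA, and private-allele statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from poolvar.popgen import (cap_infinite, nei_distance, neighbor_joining, pcoa,
                            private_allele_stats)
from poolvar.variants import VariantKey, VariantTable, summarize_variants


def nei_bruteforce(px, py):
    """Independent locus-by-locus summation oracle for Nei's (1972) D."""
    jx = sum(p**2 + (1 - p) ** 2 for p in px) / len(px)
    jy = sum(p**2 + (1 - p) ** 2 for p in py) / len(py)
    jxy = sum(p * q + (1 - p) * (1 - q) for p, q in zip(px, py)) / len(px)
    if jxy == 0:
        return math.inf
    return -math.log(jxy / math.sqrt(jx * jy))


def _freqs(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index")


def tip_distances(tree) -> pd.DataFrame:
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)


class TestNeiDistance:
    def test_identical_rows_zero(self):
        d = nei_distance(_freqs({"X": [0.2, 0.7], "Y": [0.2, 0.7]}))
        assert d.loc["X", "Y"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # X=(1.0, 0.0), Y=(0.5, 0.5): Jx=1, Jy=0.5, Jxy=0.5 -> D=-ln(1/sqrt(2))
        d = nei_distance(_freqs({"X": [1.0, 0.0], "Y": [0.5, 0.5]}))
        assert d.loc["X", "Y"] == pytest.approx(0.34657, abs=1e-4)
        assert d.loc["X", "Y"] == pytest.approx(nei_bruteforce([1, 0], [0.5, 0.5]))

    def test_matches_bruteforce_on_random_matrices(self, rng):
        p = rng.random((5, 12))
        d = nei_distance(pd.DataFrame(p, index=list("ABCDE")))
        for i, j in itertools.combinations(range(5), 2):
            expected = nei_bruteforce(p[i], p[j])
            assert d.iloc[i, j] == pytest.approx(expected, abs=1e-10)

    def test_disjoint_fixation_infinite(self):
        d = nei_distance(_freqs({"X": [1.0], "Y": [0.0]}))
        assert np.isinf(d.loc["X", "Y"])
        capped = cap_infinite(d)
        assert np.isfinite(capped.to_numpy()).all()

    def test_locus_permutation_invariance(self, rng):
        p = rng.random((4, 10))
        perm = rng.permutation(10)
        d1 = nei_distance(pd.DataFrame(p))
        d2 = nei_distance(pd.DataFrame(p[:, perm]))
        assert np.allclose(d1.to_numpy(), d2.to_numpy())

    def test_monomorphic_locus_dilutes_distance(self):
        base = {"X": [0.9, 0.1], "Y": [0.1, 0.9]}
        d0 = nei_distance(_freqs(base)).loc["X", "Y"]
        diluted = {"X": [0.9, 0.1, 0.0], "Y": [0.1, 0.9, 0.0]}
        d1 = nei_distance(_freqs(diluted)).loc["X", "Y"]
        assert 0 < d1 < d0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            nei_distance(_freqs({"X": [1.2], "Y": [0.1]}))
        with pytest.raises(ValueError):
            nei_distance(_freqs({"X": [0.1]}))


def _dm(data, labels):
    return pd.DataFrame(np.asarray(data, dtype=float), index=labels,
                        columns=labels)


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        tree = neighbor_joining(_dm([[0, 3.5], [3.5, 0]], ["A", "B"]))
        td = tip_distances(tree)
        assert td.loc["A", "B"] == pytest.approx(3.5)

    def test_three_taxa_closed_form(self):
        # v_i = (d_ij + d_ik - d_jk) / 2
        d = _dm([[0, 5, 9], [5, 0, 8], [9, 8, 0]], ["A", "B", "C"])
        tree = neighbor_joining(d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((5 + 9 - 8) / 2)
        assert lengths["B"] == pytest.approx((5 + 8 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 8 - 5) / 2)

    def test_additive_four_taxon_exact_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): additive path-length matrix
        d = _dm([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                ["A", "B", "C", "D"])
        tree = neighbor_joining(d)
        td = tip_distances(tree)
        assert np.allclose(td.loc[d.index, d.columns].to_numpy(), d.to_numpy())
        # four-point condition picks AB|CD among the three possible splits
        sums = {
            "AB|CD": d.loc["A", "B"] + d.loc["C", "D"],
            "AC|BD": d.loc["A", "C"] + d.loc["B", "D"],
            "AD|BC": d.loc["A", "D"] + d.loc["B", "C"],
        }
        assert min(sums, key=sums.get) == "AB|CD"
        names = {frozenset(t.name for t in child.tips())
                 for child in tree.children if not child.is_tip()}
        assert frozenset({"A", "B"}) in names or frozenset({"C", "D"}) in names

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_additive_five_taxon_exact_recovery(self, seed):
        # random caterpillar ((((A,B),C),D),E) with positive branch lengths:
        # NJ must reproduce every pairwise path length exactly
        rng = np.random.default_rng(seed)
        import skbio

        lengths = rng.uniform(0.5, 3.0, size=8)
        nwk = ("((((A:{0},B:{1}):{2},C:{3}):{4},D:{5}):{6},E:{7});"
               .format(*lengths))
        import io as _io
        src = skbio.TreeNode.read(_io.StringIO(nwk))
        dm = src.tip_tip_distances()
        d = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
        tree = neighbor_joining(d)
        td = tip_distances(tree)
        assert np.allclose(td.loc[d.index, d.columns].to_numpy(), d.to_numpy(),
                           atol=1e-9)

    def test_agrees_with_skbio_nj_topology(self, rng):
        import skbio
        from skbio.tree import nj as skbio_nj

        p = rng.random((6, 25))
        d = nei_distance(pd.DataFrame(p, index=list("ABCDEF")))
        ours = neighbor_joining(d)
        theirs = skbio_nj(skbio.DistanceMatrix(d.to_numpy(), list(d.index)))
        assert ours.compare_rfd(theirs) == 0.0

    def test_infinite_entries_rejected_with_guidance(self):
        d = _dm([[0, np.inf], [np.inf, 0]], ["A", "B"])
        with pytest.raises(ValueError, match="cap_infinite"):
            neighbor_joining(d)


class TestPcoa:
    def test_all_zero_distances_no_axes(self):
        d = _dm(np.zeros((4, 4)), list("ABCD"))
        ord_ = pcoa(d)
        assert ord_.n_axes == 0

    def test_collinear_points_single_axis(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        d = _dm(np.abs(pts - pts.T), list("ABC"))
        ord_ = pcoa(d)
        assert ord_.n_axes == 1
        rec = np.abs(ord_.coordinates.to_numpy() -
                     ord_.coordinates.to_numpy().T)
        assert np.allclose(rec, d.to_numpy(), atol=1e-10)

    def test_square_two_equal_eigenvalues(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        from scipy.spatial.distance import pdist, squareform
        d = _dm(squareform(pdist(pts)), list("ABCD"))
        ord_ = pcoa(d)
        pos = ord_.eigenvalues[ord_.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_euclidean_reconstruction_to_1e8(self, rng):
        pts = rng.normal(size=(7, 3))
        from scipy.spatial.distance import pdist, squareform
        d = _dm(squareform(pdist(pts)), [f"P{i}" for i in range(7)])
        coords = pcoa(d).coordinates.to_numpy()
        rec = squareform(pdist(coords))
        assert np.allclose(rec, d.to_numpy(), atol=1e-8)

    def test_matches_skbio_eigenvalues(self, rng):
        from skbio import DistanceMatrix
        from skbio.stats.ordination import pcoa as skbio_pcoa

        pts = rng.normal(size=(6, 2))
        from scipy.spatial.distance import pdist, squareform
        dmat = squareform(pdist(pts))
        ours = pcoa(_dm(dmat, list("ABCDEF")))
        theirs = skbio_pcoa(DistanceMatrix(dmat, list("ABCDEF")))
        assert np.allclose(ours.eigenvalues[:2],
                           theirs.eigvals.to_numpy()[:2], atol=1e-8)


class TestPrivateAlleles:
    def _meta(self, mapping):
        return pd.DataFrame({"group": pd.Series(mapping)},
                            index=pd.Index(list(mapping), name="accession"))

    def test_single_private_variant_counted(self):
        k1 = VariantKey("amp1", 1, "A", "G")
        k2 = VariantKey("amp1", 2, "C", "T")
        vaf = pd.DataFrame({"X": [0.5, 0.2], "Y": [0.0, 0.3]},
                           index=pd.Index([k1, k2]))
        table = VariantTable(vaf)
        per_acc, per_group = private_allele_stats(
            summarize_variants(table), vaf, self._meta({"X": "wild", "Y": "modern"}))
        assert per_acc.loc["X", "n_private"] == 1
        assert per_acc.loc["X", "mean_private_vaf"] == pytest.approx(0.5)
        assert per_acc.loc["Y", "n_private"] == 0
        assert per_group.loc["wild", "mean_private_vaf"] == pytest.approx(0.5)

    def test_no_private_variants_all_zero(self):
        k = VariantKey("amp1", 1, "A", "G")
        vaf = pd.DataFrame({"X": [0.5], "Y": [0.2]}, index=pd.Index([k]))
        per_acc, _ = private_allele_stats(
            summarize_variants(VariantTable(vaf)), vaf,
            self._meta({"X": "wild", "Y": "wild"}))
        assert (per_acc["n_private"] == 0).all()

    def test_unknown_accession_rejected(self):
        k = VariantKey("amp1", 1, "A", "G")
        vaf = pd.DataFrame({"X": [0.5]}, index=pd.Index([k]))
        with pytest.raises(ValueError, match="missing"):
            private_allele_stats(summarize_variants(VariantTable(vaf)), vaf,
                                 self._meta({"Z": "wild"}))
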