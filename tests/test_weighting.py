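"""SNP-gene mapping, P-value weights, selection and relationship matrices."""

import numpy as np
import pandas as pd
import pytest

from mwgwas import (
    build_grm,
    build_nrm,
    map_snps_to_genes,
    select_snps,
    snp_weights,
)


def brute_force_assignments(snps, genes):
    rows = []
    for s in snps.itertuples(index=False):
        hits = [
            g.gene_id
            for g in genes.itertuples(index=False)
            if str(g.chrom) == str(s.chrom) and g.start <= s.pos <= g.end
        ]
        if hits:
            rows.extend((s.snp_id, h) for h in hits)
        else:
            rows.append((s.snp_id, None))
    return pd.DataFrame(rows, columns=["snp_id", "gene_id"])


class TestMapSnpsToGenes:
    def test_inclusive_boundaries_and_intergenic(self):
        snps = pd.DataFrame(
            {"snp_id": ["s1", "s2", "s3"], "chrom": ["chr1"] * 3, "pos": [100, 200, 150]}
        )
        genes = pd.DataFrame(
            {"gene_id": ["gA"], "chrom": ["chr1"], "start": [100], "end": [140]}
        )
        out = map_snps_to_genes(snps, genes).set_index("snp_id")["gene_id"]
        assert out["s1"] == "gA"  # pos == start is inside
        assert out["s2"] is None
        assert out["s3"] is None

    def test_matches_brute_force_on_overlapping_intervals(self, rng):
        snps = pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(25)],
                "chrom": rng.choice(["chr1", "chr2"], 25),
                "pos": rng.integers(1, 500, 25),
            }
        )
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(8)],
                "chrom": rng.choice(["chr1", "chr2"], 8),
                "start": rng.integers(1, 400, 8),
            }
        )
        genes["end"] = genes["start"] + rng.integers(20, 200, 8)
        got = map_snps_to_genes(snps, genes)
        expected = brute_force_assignments(snps, genes)
        key = lambda df: sorted(map(tuple, df.fillna("NA").to_numpy()))
        assert key(got) == key(expected)

    def test_disjoint_chromosomes_error(self):
        snps = pd.DataFrame({"snp_id": ["s"], "chrom": ["chrX"], "pos": [5]})
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"], "start": [1], "end": [10]})
        with pytest.raises(ValueError, match="chromosome"):
            map_snps_to_genes(snps, genes)


class TestSnpWeights:
    def _toy(self):
        assignments = pd.DataFrame(
            {
                "snp_id": ["s1", "s2", "s3", "s4", "s5", "s6"],
                "gene_id": ["gA", "gA", "gB", None, "gC", None],
            }
        )
        pvals = pd.Series({"gA": 0.01, "gB": 1.0, "gC": 1e-6})
        return assignments, pvals

    def test_hand_computed_table(self):
        assignments, pvals = self._toy()
        wt = snp_weights(assignments, pvals)
        assert wt.weights["s1"] == pytest.approx(2.0)  # -log10(0.01)
        assert wt.weights["s2"] == pytest.approx(2.0)
        assert wt.weights["s3"] == 0.0  # P = 1
        assert wt.weights["s4"] == 0.0  # intergenic
        assert wt.weights["s5"] == pytest.approx(6.0)
        assert wt.weights["s6"] == 0.0

    def test_floor_in_all_weighted_mode(self):
        assignments, pvals = self._toy()
        wt = snp_weights(assignments, pvals, mode="all_weighted")
        assert wt.weights["s4"] == pytest.approx(0.00001)
        assert wt.weights["s1"] == pytest.approx(2.0)

    def test_multi_gene_snp_takes_max_weight(self):
        assignments = pd.DataFrame(
            {"snp_id": ["s1", "s1"], "gene_id": ["gA", "gB"]}
        )
        wt = snp_weights(assignments, pd.Series({"gA": 0.1, "gB": 0.001}))
        assert wt.weights["s1"] == pytest.approx(3.0)

    def test_zero_pvalue_error(self):
        assignments, pvals = self._toy()
        with pytest.raises(ValueError, match="> 0"):
            snp_weights(assignments, pvals.replace(0.01, 0.0))


class TestSelectSnps:
    def test_strict_boundary(self):
        w = pd.Series({"a": 1.9, "b": 2.0, "c": 2.1})
        assert select_snps(w, 2.0) == ["c"]

    def test_empty_selection_error(self):
        with pytest.raises(ValueError, match="no SNP pass"):
            select_snps(pd.Series({"a": 0.0, "b": 0.0}), 2.0)

    def test_matches_brute_force(self, rng):
        w = pd.Series(rng.uniform(0, 6, 50), index=[f"s{i}" for i in range(50)])
        got = select_snps(w, 3.0)
        expected = [s for s, v in w.items() if v > 3.0]
        assert got == expected


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=50)
@given(
    weights=st.lists(
        st.floats(min_value=0.0, max_value=10.0, allow_nan=False), min_size=1, max_size=30
    ),
    t=st.floats(min_value=1.0, max_value=9.0, allow_nan=False),
)
def test_floor_never_changes_selection_above_one(weights, t):
    """Raising zero weights to the 1e-5 floor cannot alter which SNP pass
    any threshold t >= 1."""
    w = pd.Series(weights, index=[f"s{i}" for i in range(len(weights))])
    floored = w.where(w > 0.0, 0.00001)
    sel_raw = list(w.index[w > t])
    sel_floor = list(floored.index[floored > t])
    assert sel_raw == sel_floor


class TestBuildGrm:
    def test_hand_computed_vanraden_toy(self):
        # 3 animals x 2 SNP; hand calculation:
        # p = (mean dosage)/2 = (1/2, 1/3); centered M = dosage - 2p
        geno = pd.DataFrame(
            [[0, 1], [1, 0], [2, 1]], index=["a1", "a2", "a3"], columns=["s1", "s2"]
        )
        grm = build_grm(geno)
        p = np.array([0.5, 1 / 3])
        M = geno.to_numpy() - 2 * p
        denom = 2 * np.sum(p * (1 - p))
        expected = M @ M.T / denom
        assert np.allclose(grm.G, expected, atol=1e-12)
        assert grm.denominator == pytest.approx(denom)

    def test_weight_scaling_law(self, rng):
        geno = pd.DataFrame(
            rng.binomial(2, 0.3, size=(10, 8)), columns=[f"s{i}" for i in range(8)]
        )
        w = pd.Series(rng.uniform(0.5, 2, 8), index=geno.columns)
        g1 = build_grm(geno, w)
        g2 = build_grm(geno, 3.0 * w)
        assert np.allclose(g2.G, 9.0 * g1.G, rtol=1e-10)

    def test_duplicated_animal_rows_identical(self, rng):
        geno = pd.DataFrame(rng.binomial(2, 0.4, size=(6, 10)))
        geno.loc[6] = geno.loc[0]
        grm = build_grm(geno)
        assert np.allclose(grm.G[0], grm.G[6])

    def test_symmetry_psd_and_diag(self, rng):
        geno = pd.DataFrame(rng.binomial(2, rng.uniform(0.1, 0.5, 40), size=(30, 40)))
        grm = build_grm(geno)
        assert (grm.G == grm.G.T).all()
        eigs = np.linalg.eigvalsh(grm.G)
        assert eigs.min() >= -1e-8 * np.trace(grm.G)
        assert np.diag(grm.G).mean() == pytest.approx(1.0, abs=0.2)

    def test_monomorphic_excluded_and_all_monomorphic_error(self):
        geno = pd.DataFrame([[0, 1], [0, 1], [0, 2]], columns=["mono", "poly"])
        grm = build_grm(geno)
        assert grm.excluded_monomorphic == ["mono"]
        assert grm.snp_ids == ["poly"]
        with pytest.raises(ValueError, match="monomorphic"):
            build_grm(pd.DataFrame([[0, 2], [0, 2]], columns=["m1", "m2"]))

    def test_bad_codes_rejected(self):
        with pytest.raises(ValueError, match="0/1/2"):
            build_grm(pd.DataFrame([[0, 3], [1, 1]]))


class TestBuildNrm:
    def test_founders_identity(self):
        ped = pd.DataFrame({"animal": ["a", "b"], "sire": [0, 0], "dam": [0, 0]})
        A, ids = build_nrm(ped)
        assert np.array_equal(A, np.eye(2))

    def test_sire_offspring_half(self):
        ped = pd.DataFrame(
            {"animal": ["sire", "dam", "kid"], "sire": [0, 0, "sire"], "dam": [0, 0, "dam"]}
        )
        A, ids = build_nrm(ped)
        i = {a: k for k, a in enumerate(ids)}
        assert A[i["sire"], i["kid"]] == pytest.approx(0.5)
        assert A[i["kid"], i["kid"]] == pytest.approx(1.0)

    def test_full_sib_mating_inbreeding(self):
        # founders f1 x f2 -> sibs s1, s2; s1 x s2 -> inbred (F = 0.25)
        ped = pd.DataFrame(
            {
                "animal": ["f1", "f2", "s1", "s2", "inbred"],
                "sire": [0, 0, "f1", "f1", "s1"],
                "dam": [0, 0, "f2", "f2", "s2"],
            }
        )
        A, ids = build_nrm(ped)
        i = {a: k for k, a in enumerate(ids)}
        assert A[i["s1"], i["s2"]] == pytest.approx(0.5)  # full sibs
        assert A[i["inbred"], i["inbred"]] == pytest.approx(1.25)

    def test_unsorted_input_and_cycle_detection(self):
        ped = pd.DataFrame(
            {"animal": ["kid", "sire", "dam"], "sire": ["sire", 0, 0], "dam": ["dam", 0, 0]}
        )
        A, ids = build_nrm(ped)
        i = {a: k for k, a in enumerate(ids)}
        assert A[i["sire"], i["kid"]] == pytest.approx(0.5)
        cyc = pd.DataFrame({"animal": ["x", "y"], "sire": ["y", "x"], "dam": [0, 0]})
        with pytest.raises(ValueError, match="cycle"):
            build_nrm(cyc)
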