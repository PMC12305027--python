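import math

import numpy as np
import pytest

from goten.alleles import AlleleObservation
from goten.genotyper import (
    GenotypeModel,
    UmiConsensus,
    build_consensuses,
    cluster_umis,
    collapse_umi,
    filter_high_specificity,
    genotype_cell,
    genotype_cells,
)
from goten.pipeline import run_cohort
from goten.tagging import TagExtractionConfig

from conftest import make_cohort


def obs(umi, allele="ref", q=30, cbc="CELL", read_id="r"):
    return AlleleObservation(read_id, cbc, umi, "+", allele, q, 0)


class TestClusterUmis:
    def test_distant_umis_unmerged(self):
        group = [obs("AAAAAAAAAAAA"), obs("AAATTTAAAAAA")]
        merged = cluster_umis(group)
        assert {o.umi for o in merged} == {"AAAAAAAAAAAA", "AAATTTAAAAAA"}

    def test_small_neighbor_merges_into_large(self):
        group = [obs("AAAAAAAAAAAA", read_id=f"r{i}") for i in range(10)]
        group.append(obs("AAAAAAAAAAAT", read_id="r10"))
        merged = cluster_umis(group)
        assert {o.umi for o in merged} == {"AAAAAAAAAAAA"}

    def test_balanced_neighbors_unmerged(self):
        # 5 vs 5 reads: the count condition 5 >= 2*5 - 1 fails
        group = [obs("AAAAAAAAAAAA", read_id=f"a{i}") for i in range(5)]
        group += [obs("AAAAAAAAAAAT", read_id=f"b{i}") for i in range(5)]
        merged = cluster_umis(group)
        assert {o.umi for o in merged} == {"AAAAAAAAAAAA", "AAAAAAAAAAAT"}

    def test_matches_exhaustive_network_oracle(self):
        """Merging agrees with an exhaustive pairwise network built from the
        directional rule."""
        rng = np.random.default_rng(17)
        umis, counts = [], {}
        base = "ACGTACGTACGT"
        pool = [base]
        for i in range(12):
            u = list(pool[rng.integers(len(pool))])
            u[rng.integers(12)] = "ACGT"[rng.integers(4)]
            pool.append("".join(u))
        for u in pool:
            counts[u] = counts.get(u, 0) + int(rng.integers(1, 9))
        group = [
            obs(u, read_id=f"{u}_{i}") for u, c in counts.items() for i in range(c)
        ]
        merged = cluster_umis(group)
        got = {o.umi for o in merged}

        # oracle: visit UMIs in (descending count, lexicographic) order and
        # merge into the first retained UMI satisfying the directional rule
        def dist(a, b):
            return sum(x != y for x, y in zip(a, b))  # equal length: Hamming

        order = sorted(counts, key=lambda u: (-counts[u], u))
        retained = []
        for u in order:
            if not any(
                counts[p] >= 2 * counts[u] - 1 and dist(p, u) <= 1 for p in retained
            ):
                retained.append(u)
        assert got == set(retained)

    def test_mixed_cells_rejected(self):
        with pytest.raises(ValueError):
            cluster_umis([obs("A" * 12, cbc="C1"), obs("A" * 12, cbc="C2")])


class TestCollapseUmi:
    def test_unanimous_ref_reads(self):
        cons = collapse_umi([obs("U", "ref", 20, read_id=f"r{i}") for i in range(3)])
        assert cons.allele == "ref" and cons.n_reads == 3

    def test_quality_weighted_majority(self):
        # 2 ref @Q20 (weight 1.98) beat 1 alt @Q10 (weight 0.90)
        group = [obs("U", "ref", 20, read_id="a"), obs("U", "ref", 20, read_id="b"),
                 obs("U", "alt", 10, read_id="c")]
        cons = collapse_umi(group)
        assert cons.allele == "ref" and cons.n_reads == 2
        # epsilon: product of supporting error probs 0.01*0.01, floored at 0.005
        assert cons.epsilon_umi == pytest.approx(0.005)

    def test_epsilon_above_floor_kept(self):
        cons = collapse_umi([obs("U", "alt", 7)])
        assert cons.allele == "alt"
        assert cons.epsilon_umi == pytest.approx(10 ** -0.7)

    def test_exact_tie_discarded(self):
        assert collapse_umi([obs("U", "ref", 20, read_id="a"),
                             obs("U", "alt", 20, read_id="b")]) is None

    def test_other_and_missing_only_discarded(self):
        group = [obs("U", "other", 20), AlleleObservation("r", "CELL", "U", "+", "missing", None, None)]
        assert collapse_umi(group) is None


def cons(allele, eps=0.01, cbc="CELL", umi="U"):
    return UmiConsensus(cbc, umi, allele, 1, eps)


class TestGenotypeCell:
    MODEL = GenotypeModel(mode="high_sensitivity")

    def test_five_ref_zero_alt_posterior_and_ref_call(self):
        # 0.5^5 / (0.5^5 + 0.99^5) with beta = pi = 0.5, eps = 0.01
        g = genotype_cell([cons("ref", umi=f"U{i}") for i in range(5)], self.MODEL)
        expected = 0.5**5 / (0.5**5 + 0.99**5)
        assert g.posterior_het == pytest.approx(expected, abs=1e-12)
        assert g.posterior_het == pytest.approx(0.032, abs=5e-4)
        assert g.call == "ref"

    def test_two_ref_three_alt_called_mut(self):
        umis = [cons("ref", umi="U1"), cons("ref", umi="U2"),
                cons("alt", umi="U3"), cons("alt", umi="U4"), cons("alt", umi="U5")]
        g = genotype_cell(umis, self.MODEL)
        l_het = 0.5**5
        l_ref = 0.99**2 * 0.01**3
        assert g.posterior_het == pytest.approx(l_het / (l_het + l_ref), rel=1e-10)
        assert g.posterior_het > 0.9999 and g.call == "mut"

    def test_single_ref_umi_is_no_call(self):
        g = genotype_cell([cons("ref")], GenotypeModel(min_umis_ref_call=2,
                                                       mode="high_sensitivity"))
        assert g.call == "no-call"

    def test_empty_cell_raises(self):
        with pytest.raises(ValueError):
            genotype_cell([], self.MODEL)

    def test_informative_prior_shifts_posterior(self):
        evidence = [cons("alt", umi="U1"), cons("ref", umi="U2")]
        flat = genotype_cell(evidence, GenotypeModel(mode="high_sensitivity"))
        skeptical = genotype_cell(
            evidence, GenotypeModel(pi_mut=0.05, mode="high_sensitivity")
        )
        assert skeptical.posterior_het < flat.posterior_het


class TestModes:
    def test_filter_keeps_exact_cbc_umi_gene_matches(self):
        import pandas as pd

        tags = pd.DataFrame(
            {"cbc": ["C1", "C2"], "umi": ["U1", "U2"], "gene": ["MTOR", "MTOR"],
             "count": [1, 1]}
        )
        keep = cons("ref", cbc="C1", umi="U1")
        wrong_cell = cons("ref", cbc="C2", umi="U1")  # umi exists, other cell
        out = filter_high_specificity([keep, wrong_cell], tags, "MTOR")
        assert out == [keep]

    def test_empty_tag_table_warns_and_empties(self):
        import pandas as pd

        tags = pd.DataFrame(columns=["cbc", "umi", "gene", "count"])
        with pytest.warns(UserWarning):
            assert filter_high_specificity([cons("ref")], tags, "MTOR") == []

    def test_mode_nesting_on_simulated_run(self, target):
        """High-specificity genotyped cells are a subset of high-sensitivity
        cells; identical surviving evidence never flips ref to mut."""
        cohort = make_cohort(target, n_cells=50, capture_prob=0.6, seed=31)
        hs = run_cohort(cohort.reads, cohort.whitelist, cohort.target,
                        tags=cohort.tags, annotation=cohort.annotation,
                        model=GenotypeModel(mode="high_specificity"))
        sens = run_cohort(cohort.reads, cohort.whitelist, cohort.target,
                          tags=cohort.tags, annotation=cohort.annotation,
                          model=GenotypeModel(mode="high_sensitivity"))
        spec_cells = set(hs.genotypes["cbc"])
        sens_cells = set(sens.genotypes["cbc"])
        assert spec_cells <= sens_cells
        merged = hs.genotypes.merge(sens.genotypes, on="cbc", suffixes=("_hs", "_sn"))
        same_evidence = (
            (merged["n_umi_ref_hs"] == merged["n_umi_ref_sn"])
            & (merged["n_umi_alt_hs"] == merged["n_umi_alt_sn"])
        )
        flips = merged[same_evidence & (merged["call_hs"] == "ref")
                       & (merged["call_sn"] == "mut")]
        assert flips.empty


class TestBuildConsensuses:
    def test_pipeline_counts_conserved(self, target, cohort):
        res = run_cohort(cohort.reads, cohort.whitelist, cohort.target,
                         tags=cohort.tags, annotation=cohort.annotation,
                         model=GenotypeModel(mode="high_sensitivity"))
        # every consensus cell appears at most once in the genotype table
        assert res.genotypes["cbc"].is_unique
        assert set(res.genotypes["cbc"]) == set(res.consensuses["cbc"])
        assert res.stats["n_tagged"] + res.stats["n_rejected"] == res.stats["n_reads_in"]
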