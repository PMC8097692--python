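"""Chromosome/band aggregation and the percentage-reporting conventions."""
import numpy as np
import pandas as pd
import pytest

from xcierosion import genome_map
from xcierosion.utils import percent


def _annotation(genes, chromosomes, cytobands=None):
    return pd.DataFrame(
        {
            "gene_id": genes,
            "protein_accession": [f"P{i}" for i in range(len(genes))],
            "chromosome": chromosomes,
            "cytoband": cytobands or [f"{c}p11" for c in chromosomes],
            "ribosome_60S": False,
            "ribosome_40S": False,
            "ribosome_biogenesis": False,
            "histone": False,
        }
    )


def _de(genes, fc, q=None):
    return pd.DataFrame(
        {
            "log2_fc": fc,
            "q_value": q if q is not None else [1.0] * len(genes),
            "p_value": 0.5,
        },
        index=pd.Index(genes, name="gene_id"),
    )


class TestDePercentages:
    def test_printed_count_arithmetic(self):
        """The reported autosomal percentages follow from the printed counts."""
        assert genome_map.de_percentages(1087, 1344, 12042) == (9.0, 11.2)
        pct_up, pct_down = genome_map.de_percentages(2383, 107, 8593)
        assert pct_down == 1.2
        # 2383/8593 = 27.73% half-up rounds to 27.7, not the reported 27.8
        assert pct_up == 27.7

    def test_zero_counts(self):
        assert genome_map.de_percentages(0, 0, 500) == (0.0, 0.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            genome_map.de_percentages(5, 6, 10)
        with pytest.raises(ValueError):
            genome_map.de_percentages(1, 1, 0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            total = int(rng.integers(10, 10000))
            up = int(rng.integers(0, total + 1))
            down = int(rng.integers(0, total - up + 1))
            pct_up, pct_down = genome_map.de_percentages(up, down, total)
            pct_ns = percent(total - up - down, total)
            # three half-up roundings each contribute at most 0.05
            assert pct_up + pct_down + pct_ns == pytest.approx(100.0, abs=0.15)


class TestChromosomeSummary:
    def test_identical_fc_vectors_correlate_perfectly(self):
        genes = [f"g{i}" for i in range(5)]
        ann = _annotation(genes, ["1"] * 5)
        fc = [0.1, 0.5, -0.2, 0.3, 0.0]
        out = genome_map.summarize_by_chromosome(_de(genes, fc), _de(genes, fc), ann)
        assert out["pearson_r_rna_vs_protein_fc"].iloc[0] == pytest.approx(1.0)

    def test_reversed_vectors_anticorrelate(self):
        genes = ["a", "b", "c"]
        ann = _annotation(genes, ["2"] * 3)
        out = genome_map.summarize_by_chromosome(
            _de(genes, [1.0, 2.0, 3.0]), _de(genes, [3.0, 2.0, 1.0]), ann
        )
        assert out["pearson_r_rna_vs_protein_fc"].iloc[0] == pytest.approx(-1.0)

    def test_median_and_sem_match_direct_formulas(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(10)]
        ann = _annotation(genes, ["7"] * 10)
        fc_rna = rng.normal(0, 1, 10)
        fc_prot = rng.normal(0, 1, 10)
        out = genome_map.summarize_by_chromosome(_de(genes, fc_rna), _de(genes, fc_prot), ann)
        rna_row = out[out["layer"] == "rna"].iloc[0]
        assert rna_row["median_log2_fc"] == pytest.approx(np.median(fc_rna))
        assert rna_row["sem"] == pytest.approx(np.std(fc_rna, ddof=1) / np.sqrt(10))
        assert rna_row["pearson_r_rna_vs_protein_fc"] == pytest.approx(
            np.corrcoef(fc_rna, fc_prot)[0, 1]
        )

    def test_small_chromosome_has_missing_correlation(self):
        genes = ["a", "b", "c"]
        ann = _annotation(genes, ["1", "1", "3"])
        out = genome_map.summarize_by_chromosome(
            _de(genes, [1.0, 2.0, 3.0]), _de(genes, [1.0, 2.0, 3.0]), ann
        )
        chr3 = out[out["chromosome"] == "3"]
        assert np.isnan(chr3["pearson_r_rna_vs_protein_fc"]).all()
        assert (chr3["median_log2_fc"] == 3.0).all()

    def test_medians_ignore_gene_order_and_missing_fc(self):
        genes = [f"g{i}" for i in range(6)]
        ann = _annotation(genes, ["5"] * 6)
        fc = [0.1, 0.2, 0.3, 0.4, 0.5, np.nan]
        a = genome_map.summarize_by_chromosome(_de(genes, fc), _de(genes, fc), ann)
        shuffled = _de(genes, fc).sample(frac=1.0, random_state=2)
        b = genome_map.summarize_by_chromosome(shuffled, shuffled, ann)
        assert a["median_log2_fc"].tolist() == b["median_log2_fc"].tolist()
        assert a["median_log2_fc"].iloc[0] == pytest.approx(0.3)


class TestBandSummary:
    def test_single_gene_bands(self):
        genes = ["a", "b"]
        ann = _annotation(genes, ["1", "2"], ["1p11", "2q21"])
        vals = pd.Series([0.7, -0.2], index=genes)
        out = genome_map.band_summary(vals, ann, "log2_fc_rna").set_index("cytoband")
        assert out.loc["1p11", "median_value"] == 0.7
        assert out.loc["2q21", "n_genes"] == 1

    def test_odd_n_median(self):
        genes = ["a", "b", "c"]
        ann = _annotation(genes, ["1"] * 3, ["1p11"] * 3)
        out = genome_map.band_summary(pd.Series([0.1, 0.3, 0.5], index=genes), ann, "m")
        assert out["median_value"].iloc[0] == pytest.approx(0.3)

    def test_matches_sort_based_median_oracle(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(40)]
        bands = [f"1p{11 + i % 4}" for i in range(40)]
        ann = _annotation(genes, ["1"] * 40, bands)
        vals = pd.Series(rng.normal(size=40), index=genes)
        out = genome_map.band_summary(vals, ann, "m").set_index("cytoband")
        for band in set(bands):
            members = sorted(vals[[g for g, b in zip(genes, bands) if b == band]])
            n = len(members)
            med = members[n // 2] if n % 2 else (members[n // 2 - 1] + members[n // 2]) / 2
            assert out.loc[band, "median_value"] == pytest.approx(med)
            assert out.loc[band, "n_genes"] == n


class TestAbundanceCorrelation:
    def _mapping(self, genes):
        return pd.Series([f"P_{g}" for g in genes], index=genes)

    def test_perfect_monotone_identity(self):
        genes = [f"g{i}" for i in range(10)]
        rng = np.random.default_rng(1)
        tpm = pd.DataFrame(
            {"l1": np.exp(rng.normal(3, 1, 10)), "l2": np.exp(rng.normal(3, 1, 10))},
            index=genes,
        )
        mapping = self._mapping(genes)
        # log10 copies as an exact affine image of log2(tpm medians + pc)
        med = np.log2(tpm.median(axis=1) + 0.01)
        copies = pd.DataFrame({"l1": 10 ** (med * 0.5 + 2)})
        copies.index = mapping[genes]
        r, n = genome_map.rna_protein_abundance_correlation(tpm, copies, mapping)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_antimonotone_fixture_is_negative(self):
        genes = ["a", "b", "c", "d"]
        tpm = pd.DataFrame({"l1": [1.0, 2.0, 4.0, 8.0]}, index=genes)
        mapping = self._mapping(genes)
        copies = pd.DataFrame({"l1": [1e8, 1e7, 1e6, 1e5]})
        copies.index = mapping[genes]
        r, _ = genome_map.rna_protein_abundance_correlation(tpm, copies, mapping)
        assert r < 0

    def test_correlation_rises_as_coupling_noise_falls(self):
        """Monte-Carlo: shrinking the RNA-protein coupling noise in the
        generator drives the abundance correlation toward 1."""
        from xcierosion import CohortConfig, generate_cohort
        from xcierosion import proteomics_quant as pq

        rs = []
        for noise in (2.5, 1.0, 0.2):
            b = generate_cohort(
                CohortConfig(n_genes_autosome=150, n_genes_x=10, n_female_low=4,
                             n_female_medium=1, n_female_high=4, n_male=2,
                             plex_size=4, coupling_noise_ln=noise, seed=21)
            )
            filtered = pq.filter_protein_groups(b.protein_groups)
            copies = pq.ruler_copy_numbers(filtered, b.annotation)
            mapping = b.annotation.set_index("gene_id")["protein_accession"]
            mapping = mapping[mapping != ""]
            r, _ = genome_map.rna_protein_abundance_correlation(b.rna, copies, mapping)
            rs.append(r)
        assert rs[0] < rs[1] < rs[2]
        assert rs[2] > 0.85

    def test_constant_vector_rejected(self):
        genes = ["a", "b", "c"]
        tpm = pd.DataFrame({"l1": [1.0, 2.0, 3.0]}, index=genes)
        mapping = self._mapping(genes)
        copies = pd.DataFrame({"l1": [5.0, 5.0, 5.0]})
        copies.index = mapping[genes]
        with pytest.raises(ValueError, match="constant|undefined"):
            genome_map.rna_protein_abundance_correlation(tpm, copies, mapping)
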