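"""Proteomic-ruler copy numbers, batch correction, content and ratios."""
import numpy as np
import pandas as pd
import pytest

from xcierosion import io_formats
from xcierosion import proteomics_quant as pq

AVOGADRO = 6.02214076e23


def make_protein_groups(rows, line_ids):
    """rows: dict accession -> (gene, mw_da, rup, flags, {line: intensity})"""
    data = []
    for acc, (gene, mw, rup, flags, intens) in rows.items():
        rec = {
            "accessions": acc,
            "gene_name": gene,
            "mw_da": mw,
            "razor_unique_peptides": rup,
            "is_contaminant": "contaminant" in flags,
            "is_reverse": "reverse" in flags,
            "is_only_site": "only_site" in flags,
        }
        for line in line_ids:
            rec[line] = intens.get(line, np.nan)
        data.append(rec)
    columns = io_formats.PROTEIN_GROUP_META + list(line_ids)
    return io_formats.validate_protein_groups(
        pd.DataFrame(data, columns=columns), line_ids
    )


def annotation_for(accessions, histones=()):
    return pd.DataFrame(
        {
            "gene_id": [f"g_{a}" for a in accessions],
            "protein_accession": list(accessions),
            "chromosome": "1",
            "cytoband": "1p11",
            "ribosome_60S": False,
            "ribosome_40S": False,
            "ribosome_biogenesis": False,
            "histone": [a in histones for a in accessions],
        }
    )


def sheet_for(line_ids, plexes=None):
    return pd.DataFrame(
        {
            "line_id": line_ids,
            "donor_sex": "female",
            "tmt_plex": plexes or ["p1"] * len(line_ids),
            "donor_id": [f"d{i}" for i in range(len(line_ids))],
        }
    )


class TestFilter:
    def test_qc_flags_and_rup_rule(self):
        table = make_protein_groups(
            {
                "P1": ("A", 1e4, 5, ["contaminant"], {"l1": 1.0}),
                "P2": ("B", 1e4, 5, ["reverse"], {"l1": 1.0}),
                "P3": ("C", 1e4, 5, ["only_site"], {"l1": 1.0}),
                "P4": ("D", 1e4, 2, [], {"l1": 1.0}),
                "P5": ("E", 1e4, 3, [], {"l1": 1.0}),
            },
            ["l1"],
        )
        out = pq.filter_protein_groups(table)
        assert out.index.tolist() == ["P5"]  # RUP exactly 3 is retained

    def test_empty_table_passes_through(self):
        table = make_protein_groups({}, ["l1"])
        assert len(pq.filter_protein_groups(table)) == 0


class TestRuler:
    def test_sole_histone_mass_equals_dna_mass(self):
        table = make_protein_groups({"H4": ("H4C1", 11367.0, 10, [], {"l1": 5e6})}, ["l1"])
        ann = annotation_for(["H4"], histones=["H4"])
        copies = pq.ruler_copy_numbers(table, ann)
        mass_pg = pq.protein_content_pg(copies, table["mw_da"])
        assert mass_pg["l1"] == pytest.approx(6.5, rel=1e-12)

    def test_hand_computed_copies(self):
        """Histone I=100, protein B I=50 at 5 kDa, 6.5 pg DNA ->
        mass_B = 3.25 pg and copies_B = 3.25e-12 * N_A / 5000."""
        table = make_protein_groups(
            {
                "H4": ("H4C1", 11367.0, 10, [], {"l1": 100.0}),
                "B": ("GENB", 5000.0, 5, [], {"l1": 50.0}),
            },
            ["l1"],
        )
        ann = annotation_for(["H4", "B"], histones=["H4"])
        copies = pq.ruler_copy_numbers(table, ann)
        expected = 3.25e-12 * AVOGADRO / 5000.0
        assert copies.loc["B", "l1"] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.914e8, rel=1e-3)

    def test_per_line_rescaling_is_cancelled(self, small_cohort):
        filtered = pq.filter_protein_groups(small_cohort.protein_groups)
        copies = pq.ruler_copy_numbers(filtered, small_cohort.annotation)
        scaled = filtered.copy()
        scaled.attrs.update(filtered.attrs)
        line = filtered.attrs["line_ids"][0]
        scaled[line] = scaled[line] * 10.0
        copies2 = pq.ruler_copy_numbers(scaled, small_cohort.annotation)
        pd.testing.assert_frame_equal(copies, copies2)

    def test_histone_mass_closure(self, small_cohort):
        """Summed histone mass per line equals the DNA mass constant exactly."""
        filtered = pq.filter_protein_groups(small_cohort.protein_groups)
        copies = pq.ruler_copy_numbers(filtered, small_cohort.annotation)
        hist = pq.histone_mask(filtered, small_cohort.annotation)
        hist_mass = pq.protein_content_pg(copies.loc[hist], filtered.loc[hist, "mw_da"])
        assert np.allclose(hist_mass, 6.5, rtol=1e-12)

    def test_zero_histone_signal_names_line(self):
        table = make_protein_groups(
            {"H4": ("H4C1", 11367.0, 10, [], {"l1": 100.0, "l2": 0.0})}, ["l1", "l2"]
        )
        ann = annotation_for(["H4"], histones=["H4"])
        with pytest.raises(ValueError, match="l2"):
            pq.ruler_copy_numbers(table, ann)

    def test_missing_intensity_gives_missing_copies(self):
        table = make_protein_groups(
            {
                "H4": ("H4C1", 11367.0, 10, [], {"l1": 100.0}),
                "B": ("GENB", 5000.0, 5, [], {}),
            },
            ["l1"],
        )
        ann = annotation_for(["H4", "B"], histones=["H4"])
        copies = pq.ruler_copy_numbers(table, ann)
        assert np.isnan(copies.loc["B", "l1"])


class TestBatchCorrect:
    def _copies(self):
        return pd.DataFrame(
            {"l1": [1e6, 2e6], "l2": [2e6, 4e6], "l3": [1e6, 2e6], "l4": [2e6, 4e6]},
            index=["P1", "P2"],
        )

    def test_equal_plexes_are_a_no_op(self):
        copies = self._copies()
        mw = pd.Series([5e4, 5e4], index=["P1", "P2"])
        sheet = sheet_for(["l1", "l2", "l3", "l4"], ["p1", "p1", "p2", "p2"])
        out, factors = pq.batch_correct(copies, sheet, mw)
        assert np.allclose(factors, 1.0)
        pd.testing.assert_frame_equal(out, copies)

    def test_inflated_plex_gets_half_factor(self):
        copies = self._copies()
        copies[["l3", "l4"]] *= 2.0
        mw = pd.Series([5e4, 5e4], index=["P1", "P2"])
        sheet = sheet_for(["l1", "l2", "l3", "l4"], ["p1", "p1", "p2", "p2"])
        out, factors = pq.batch_correct(copies, sheet, mw)
        assert factors["p2"] / factors["p1"] == pytest.approx(0.5, rel=1e-12)

    def test_idempotent_and_ratio_preserving(self):
        copies = self._copies()
        copies[["l3", "l4"]] *= 3.0
        mw = pd.Series([5e4, 5e4], index=["P1", "P2"])
        sheet = sheet_for(["l1", "l2", "l3", "l4"], ["p1", "p1", "p2", "p2"])
        once, _ = pq.batch_correct(copies, sheet, mw)
        twice, factors2 = pq.batch_correct(once, sheet, mw)
        pd.testing.assert_frame_equal(once, twice)
        assert np.allclose(factors2, 1.0)
        # within-plex ratios between proteins unchanged
        assert np.allclose(once.loc["P2"] / once.loc["P1"], copies.loc["P2"] / copies.loc["P1"])

    def test_recovers_injected_plex_effects(self, study_cohort):
        filtered = pq.filter_protein_groups(study_cohort.protein_groups)
        raw = pq.ruler_copy_numbers(filtered, study_cohort.annotation)
        _, factors = pq.batch_correct(raw, study_cohort.sample_sheet, filtered["mw_da"])
        effects = study_cohort.truth.plex_effects
        log_resid = np.log(factors * effects[factors.index])
        assert np.corrcoef(np.log(factors), -np.log(effects[factors.index]))[0, 1] > 0.8
        assert np.median(np.abs(log_resid - log_resid.mean())) < 0.05


class TestContentAndRatio:
    def test_unit_identity(self):
        copies = pd.DataFrame({"l1": [AVOGADRO]}, index=["P1"])
        mw = pd.Series([1.0], index=["P1"])
        assert pq.protein_content_pg(copies, mw)["l1"] == pytest.approx(1e12)

    def test_additivity(self):
        copies = pd.DataFrame({"l1": [3e6, 7e6]}, index=["P1", "P2"])
        mw = pd.Series([2e4, 9e4], index=["P1", "P2"])
        total = pq.protein_content_pg(copies, mw)["l1"]
        only_a = pq.protein_content_pg(copies.iloc[[0]], mw)["l1"]
        only_b = pq.protein_content_pg(copies.iloc[[1]], mw)["l1"]
        assert total == pytest.approx(only_a + only_b, rel=1e-12)

    def test_matches_spreadsheet_fixture(self):
        copies = pd.DataFrame(
            {"l1": [1e6, 2e6, 5e5], "l2": [3e6, 1e6, 4e5]}, index=["P1", "P2", "P3"]
        )
        mw = pd.Series([2.5e4, 5.0e4, 1.2e5], index=["P1", "P2", "P3"])
        out = pq.protein_content_pg(copies, mw)
        for line in ("l1", "l2"):  # independent arithmetic, protein by protein
            expected = sum(
                copies.loc[p, line] * mw[p] / AVOGADRO * 1e12 for p in copies.index
            )
            assert out[line] == pytest.approx(expected, rel=1e-12)

    def test_subunit_ratio_examples(self):
        copies = pd.DataFrame(
            {"l1": [60.0, 40.0, 30.0, 20.0], "l2": [200.0, 100.0, 60.0, 40.0]},
            index=["A1", "A2", "B1", "B2"],
        )
        ann = annotation_for(["A1", "A2", "B1", "B2"])
        ann["ribosome_60S"] = [True, True, False, False]
        ann["ribosome_40S"] = [False, False, True, True]
        ratio = pq.subunit_ratio(copies, ann)
        assert ratio["l1"] == pytest.approx(2.0)
        assert ratio["l2"] == pytest.approx(3.0)
        doubled = copies.copy()
        doubled.loc[["A1", "A2"]] *= 2.0
        assert pq.subunit_ratio(doubled, ann)["l1"] == pytest.approx(4.0)

    def test_zero_denominator_is_nan(self):
        copies = pd.DataFrame({"l1": [60.0, 0.0]}, index=["A1", "B1"])
        ann = annotation_for(["A1", "B1"])
        ann["ribosome_60S"] = [True, False]
        ann["ribosome_40S"] = [False, True]
        assert np.isnan(pq.subunit_ratio(copies, ann)["l1"])


class TestGroupContent:
    def test_welch_hand_oracle(self):
        t, df, p = pq.welch_t(np.array([1.0, 2, 3]), np.array([2.0, 4, 6]))
        assert t == pytest.approx(-2 / np.sqrt(5 / 3), rel=1e-9)
        assert t == pytest.approx(-1.549, abs=1e-3)
        assert df == pytest.approx(50 / 17, rel=1e-9)

    def test_identical_groups(self):
        content = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], index=list("abcdef"))
        out = pq.group_content_summary(content, {"A": list("abc"), "B": list("def")})
        row = out.iloc[0]
        assert row["percent_difference"] == 0.0
        assert row["welch_p"] == pytest.approx(1.0)

    def test_thirteen_percent_construction(self):
        b = pd.Series([10.0, 20.0, 30.0], index=["b1", "b2", "b3"])
        a = (b * 1.13).rename(index={"b1": "a1", "b2": "a2", "b3": "a3"})
        content = pd.concat([a, b])
        out = pq.group_content_summary(content, {"A": list(a.index), "B": list(b.index)})
        assert out.iloc[0]["percent_difference"] == pytest.approx(13.0)

    def test_small_group_rejected(self):
        content = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError, match="fewer than 2"):
            pq.group_content_summary(content, {"A": ["a"], "B": ["b", "c"]})
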