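"""Quantification filter, reference normalization, corrected ratios, volcano."""

import numpy as np
import pandas as pd
import pytest

from aggrefinger import proteomics as prot
from aggrefinger import synthetic as syn


def quant_table(rows, channels=("c1", "c2"), reference_map=None):
    df = pd.DataFrame(rows)
    df.attrs["channels"] = list(channels)
    if reference_map:
        df.attrs["reference_map"] = reference_map
    return df


class TestFilterQuantified:
    @pytest.mark.parametrize("peptides,unique,contaminant,kept", [
        (2, 1, False, True),   # the published minimum
        (3, 0, False, False),  # no unique peptide
        (1, 1, False, False),  # too few peptides
        (5, 3, True, False),   # contaminant regardless of counts
    ])
    def test_quantification_rule(self, peptides, unique, contaminant, kept):
        t = quant_table([{"accession": "P1", "peptides": peptides,
                          "unique_peptides": unique,
                          "contaminant": contaminant, "c1": 1.0, "c2": 1.0}])
        assert (len(prot.filter_quantified(t)) == 1) is kept

    def test_keratin_prefix_removed(self):
        t = quant_table([{"accession": "KRT_X", "peptides": 5,
                          "unique_peptides": 2, "contaminant": False,
                          "c1": 1.0, "c2": 1.0}])
        assert prot.filter_quantified(t).empty

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="peptides"):
            prot.filter_quantified(pd.DataFrame({"accession": ["P1"]}))


class TestReferenceNormalize:
    def test_equal_reference_sums_identity(self):
        t = quant_table(
            [{"accession": "P1", "c1": 2.0, "c2": 4.0, "r1": 1.0, "r2": 1.0}],
            reference_map={"c1": "r1", "c2": "r2"})
        out = prot.reference_normalize(t)
        assert out["c1"].iloc[0] == 2.0 and out["c2"].iloc[0] == 4.0

    def test_double_reference_sum_halves_channel(self):
        t = quant_table(
            [{"accession": "P1", "c1": 6.0, "c2": 6.0, "r1": 1.0, "r2": 2.0}],
            reference_map={"c1": "r1", "c2": "r2"})
        out = prot.reference_normalize(t)
        assert out["c2"].iloc[0] / out["c1"].iloc[0] == pytest.approx(0.5)

    def test_zero_reference_sum_rejected(self):
        t = quant_table(
            [{"accession": "P1", "c1": 1.0, "c2": 1.0, "r1": 0.0, "r2": 1.0}],
            reference_map={"c1": "r1", "c2": "r2"})
        with pytest.raises(ValueError, match="reference"):
            prot.reference_normalize(t)


class TestCorrectedRatios:
    def _tables(self, agg_case=4.0, tot_case=1.0):
        controls, cases = ["ctl1", "ctl2"], ["cs1", "cs2", "cs3"]
        tot = pd.DataFrame({"accession": ["P1"],
                            **{c: [10.0] for c in controls},
                            **{c: [10.0 * tot_case] for c in cases}})
        agg = pd.DataFrame({"accession": ["P1"],
                            **{c: [10.0] for c in controls},
                            **{c: [10.0 * agg_case] for c in cases}})
        return tot, agg, controls, cases

    def test_correction_cancels_proteome_wide_change(self):
        tot, agg, ctl, cs = self._tables(agg_case=2.0, tot_case=2.0)
        out = prot.compute_corrected_ratios(tot, agg, ctl, cs)
        assert out["mean_log2_corrected"].iloc[0] == pytest.approx(0.0)

    def test_aggregate_specific_enrichment_preserved(self):
        tot, agg, ctl, cs = self._tables(agg_case=4.0, tot_case=1.0)
        out = prot.compute_corrected_ratios(tot, agg, ctl, cs)
        assert out["mean_log2_corrected"].iloc[0] == pytest.approx(2.0)

    def test_common_factor_invariance(self):
        """Scaling one case's total AND aggregate abundance by the same
        factor leaves the corrected ratio unchanged."""
        tot, agg, ctl, cs = self._tables()
        r1 = prot.compute_corrected_ratios(tot, agg, ctl, cs)
        tot2, agg2 = tot.copy(), agg.copy()
        tot2["cs1"] *= 7.0
        agg2["cs1"] *= 7.0
        r2 = prot.compute_corrected_ratios(tot2, agg2, ctl, cs)
        assert r1["mean_log2_corrected"].iloc[0] == pytest.approx(
            r2["mean_log2_corrected"].iloc[0])

    def test_zero_control_mean_dropped_with_reason(self):
        tot, agg, ctl, cs = self._tables()
        tot.loc[:, ctl] = 0.0
        out = prot.compute_corrected_ratios(tot, agg, ctl, cs)
        assert out.empty
        assert "zero_control_mean" in set(out.attrs["dropped"]["reason"])


class TestVolcano:
    @pytest.mark.parametrize("log2,nlp,call", [
        (-0.022, 0.0357, "ns"),   # a quantified but unchanged target protein
        (0.49, 1.69, "ns"),       # significant p but fails the fold cut
        (1.5, 2.0, "enriched"),
        (-1.5, 2.0, "depleted"),
        (1.5, 1.0, "ns"),
    ])
    def test_threshold_partition(self, log2, nlp, call):
        rec = pd.DataFrame({"accession": ["X"], "mean_log2_corrected": [log2],
                            "neg_log10_p": [nlp]})
        assert prot.volcano_classify(rec)["call"].iloc[0] == call


class TestEndToEnd:
    def test_spike_in_recovery(self, proteomics_tables):
        (total, agg, truth), enriched = proteomics_tables
        total = prot.reference_normalize(prot.filter_quantified(total))
        agg = prot.reference_normalize(prot.filter_quantified(agg))
        out = prot.volcano_classify(prot.compute_corrected_ratios(
            total, agg, truth["controls"], truth["cases"])).set_index("accession")
        assert out.loc["P00050", "call"] == "enriched"
        assert out.loc["P00050", "mean_log2_corrected"] == pytest.approx(2.0, abs=0.3)
        assert out.loc["P00051", "call"] == "depleted"
        null = out.drop(["P00050", "P00051"])
        assert (null["call"] != "ns").mean() <= 0.03

    def test_contaminants_absent_downstream(self, proteomics_tables):
        (total, _, truth), _ = proteomics_tables
        filtered = prot.filter_quantified(total)
        assert not set(truth["contaminants"]) & set(filtered["accession"])
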