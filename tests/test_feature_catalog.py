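import math

import numpy as np
import pytest

from seq2abundance.feature_catalog import (
    CDS_FEATURES,
    MANIFEST,
    MRNA_COLUMN,
    TIR_FEATURES,
    PWM,
    assemble_feature_table,
    build_tai_weights,
    cai,
    composition_features,
    count_sd_motifs,
    default_cai_weights,
    default_sd_pwm,
    default_tai_weights,
    group_of_column,
    relative_adaptiveness,
    score_sd_motif,
    tai,
)
from seq2abundance.sequence_io import ExpressionRecord, GeneRegions


class TestManifest:
    def test_exactly_107_sequence_features(self):
        assert len(MANIFEST) == 107
        assert len(TIR_FEATURES) == 16
        assert len(CDS_FEATURES) == 91
        assert len(set(MANIFEST)) == 107

    def test_group_labels_cover_manifest(self):
        groups = {group_of_column(c) for c in MANIFEST}
        assert groups == {"TIR", "CDS"}
        assert group_of_column(MRNA_COLUMN) == "mRNA"


class TestPWM:
    def test_uniform_pwm_scores_zero(self):
        pwm = PWM(frequencies=np.full((4, 3), 0.25))
        assert pwm.score("ACG") == 0.0

    def test_single_column_log_odds(self):
        # f(A)=1, background 0.25, pseudo 0 -> log2(4) = 2 at the A
        pwm = PWM(frequencies=np.array([[1.0], [0.0], [0.0], [0.0]]))
        score, offset, spacing = score_sd_motif("T" * 10 + "A" + "T" * 44, pwm)
        assert score == pytest.approx(2.0)
        assert offset == 10

    def test_spacing_convention(self):
        # motif of length 6 ending at TIR position -5 -> 4 nt spacing
        pwm = PWM(frequencies=np.tile(
            np.array([[0.97], [0.01], [0.01], [0.01]]), (1, 6)))
        tir = "C" * 15 + "AAAAAA" + "C" * 4 + "G" * 30
        score, offset, spacing = score_sd_motif(tir, pwm)
        assert offset == 15  # motif ends at TIR position -5
        assert spacing == 4

    def test_window_shorter_than_motif(self):
        pwm = PWM(frequencies=np.full((4, 6), 0.25))
        with pytest.raises(ValueError):
            score_sd_motif("A" * 55, pwm, scan_window=(0, 4))

    def test_motif_count_threshold(self):
        pwm = PWM(frequencies=np.array([[1.0], [0.0], [0.0], [0.0]]),
                  pseudocount=0.0)
        tir = ("ATA" * 9)[:25] + "G" * 30
        n_hits = count_sd_motifs(tir, pwm, threshold=1.0)
        assert n_hits == sum(1 for b in tir[:25] if b == "A")

    def test_default_pwm_loads(self):
        pwm = default_sd_pwm()
        assert pwm.length == 6
        assert pwm.score("AGGAGG") > pwm.score("TTTTTT")


class TestCodonWeights:
    def test_relative_adaptiveness_ratio(self):
        w = relative_adaptiveness({"GAA": 300, "GAG": 100}).w
        assert w["GAA"] == 1.0
        assert w["GAG"] == pytest.approx(1 / 3)

    def test_equal_counts_all_one(self):
        counts = {c: 10 for c in default_cai_weights().w}
        w = relative_adaptiveness(counts).w
        assert all(v == 1.0 for v in w.values())

    def test_zero_count_floor(self):
        w = relative_adaptiveness({"TGT": 0, "TGC": 50}).w
        assert w["TGT"] == 0.01 and w["TGC"] == 1.0

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            relative_adaptiveness({})


class TestCAI:
    def test_maximal_codons_give_one(self):
        w = default_cai_weights()
        assert w.w["GAA"] == 1.0
        assert cai("ATG" + "GAA" * 5 + "TAA", w) == pytest.approx(1.0)

    def test_hand_geometric_mean(self):
        from seq2abundance.feature_catalog import CodonWeightTable

        w = CodonWeightTable(w={"GAA": 1.0, "GAG": 0.25}, source="cai")
        assert cai("GAAGAGGAA", w) == pytest.approx(0.25 ** (1 / 3))

    def test_stop_codon_excluded(self):
        w = default_cai_weights()
        assert cai("ATGGAAACC", w) == pytest.approx(cai("ATGGAAACCTAA", w))

    def test_single_codon_families_excluded(self):
        w = default_cai_weights()
        # ATG and TGG contribute nothing; GAA carries the value
        assert cai("ATGTGGGAATAA", w) == pytest.approx(w.w["GAA"])

    def test_only_excluded_codons_raises(self):
        w = default_cai_weights()
        with pytest.raises(ValueError):
            cai("ATGTGGTAA", w)


class TestTAI:
    def test_uniform_weights_give_one(self):
        from seq2abundance.feature_catalog import CodonWeightTable, SENSE_CODONS

        w = CodonWeightTable(w={c: 1.0 for c in SENSE_CODONS}, source="tai")
        assert tai("ATGGAACGTTAA", w) == pytest.approx(1.0)

    def test_single_codon_value(self):
        from seq2abundance.feature_catalog import CodonWeightTable, SENSE_CODONS

        w = {c: 1.0 for c in SENSE_CODONS}
        w["ATG"] = 0.5
        wt = CodonWeightTable(w=w, source="tai")
        assert tai("ATGTAA", wt) == pytest.approx(0.5)

    def test_two_codon_geometric_mean(self):
        from seq2abundance.feature_catalog import CodonWeightTable, SENSE_CODONS

        w = {c: 1.0 for c in SENSE_CODONS}
        w["GAA"], w["CGT"] = 0.8, 0.2
        wt = CodonWeightTable(w=w, source="tai")
        assert tai("GAACGTTAA", wt) == pytest.approx(math.sqrt(0.16))

    def test_build_from_copy_numbers(self):
        wt = build_tai_weights({"TTC": 4, "GAA": 2})  # Glu, Phe tRNAs
        assert wt.w["GAA"] == 1.0  # perfect WC match to the most abundant tRNA
        assert 0 < wt.w["GAG"] < 1.0  # wobble-read only
        assert max(wt.w.values()) == 1.0

    def test_default_weights_in_unit_interval(self):
        w = default_tai_weights()
        assert all(0 < v <= 1 for v in w.w.values())


class TestComposition:
    def test_direct_counts(self):
        reg = GeneRegions("g", "A" * 55, "ATGAAATAA")
        f = composition_features(reg)
        assert f["codon_ATG"] == pytest.approx(0.5)
        assert f["codon_AAA"] == pytest.approx(0.5)
        assert f["aa_M"] == pytest.approx(0.5)
        assert f["aa_K"] == pytest.approx(0.5)
        assert f["protein_length"] == 2
        assert f["stop_TAA"] == 1.0 and f["stop_TAG"] == 0.0

    def test_poly_a_content(self):
        reg = GeneRegions("g", "A" * 55, "AAA" * 10)
        f = composition_features(reg)
        assert f["a_content"] == 1.0 and f["at_content"] == 1.0
        assert f["gc_content"] == 0.0

    def test_frequencies_sum_to_one(self, small_bundle):
        df = small_bundle.feature_table.data
        codon_cols = [c for c in df.columns if c.startswith("codon_")]
        aa_cols = [c for c in df.columns if c.startswith("aa_")]
        assert np.allclose(df[codon_cols].sum(axis=1), 1.0)
        assert np.allclose(df[aa_cols].sum(axis=1), 1.0)

    def test_gc3_excludes_stop(self):
        reg = GeneRegions("g", "A" * 55, "ATGGAGTAA")  # thirds: G, G
        assert composition_features(reg)["gc3_content"] == 1.0


class TestAssembly:
    def test_design_table_has_108_predictors(self, small_bundle):
        df = small_bundle.feature_table.data
        assert df.shape[1] == 108
        assert MRNA_COLUMN in df.columns

    def test_determinism(self, small_bundle):
        regions = small_bundle.regions[:15]
        expr = [r for r in small_bundle.expression if any(
            r.gene_id == g.gene_id for g in regions)]
        t1 = assemble_feature_table(regions, expr)
        t2 = assemble_feature_table(regions, expr)
        assert t1.data.equals(t2.data)

    def test_duplicate_gene_ids_rejected(self, small_bundle):
        regions = [small_bundle.regions[0], small_bundle.regions[0]]
        with pytest.raises(ValueError):
            assemble_feature_table(regions, small_bundle.expression)

    def test_missing_expression_skips_gene(self, small_bundle, caplog):
        regions = small_bundle.regions[:5]
        expr = [r for r in small_bundle.expression
                if r.gene_id in {g.gene_id for g in regions[:4]}]
        table = assemble_feature_table(regions, expr)
        assert len(table.data) == 4

    def test_sentinel_imputed_with_column_median(self):
        """A gene whose TIR cannot hybridize the anti-SD probe receives the
        column median of the hybridization energies."""
        rng = np.random.default_rng(4)
        regions = []
        for i in range(6):
            up = "".join(rng.choice(list("ACGT"), size=9)) + "AGGAGG" + \
                "".join(rng.choice(list("ACGT"), size=10))
            cds = "ATG" + "GAA" * 20 + "TAA"
            regions.append(GeneRegions(f"g{i}", up + cds[:30], cds))
        # poly-C TIR cannot pair the purine-rich probe at all
        regions.append(GeneRegions("gx", "C" * 55, "ATG" + "GAA" * 20 + "TAA"))
        expr = [ExpressionRecord(r.gene_id, 10.0, 100.0) for r in regions]
        table = assemble_feature_table(regions, expr)
        assert "gx" in table.imputed.get("exterior_loop_dg", [])
        others = table.data.drop(index="gx")["exterior_loop_dg"]
        assert table.data.loc["gx", "exterior_loop_dg"] == pytest.approx(
            others.median()
        )

    def test_schema_stable_under_energy_engine_swap(self, small_bundle):
        """Swapping the folding engine's parameter set changes feature values
        but never column names or dtypes."""
        from dataclasses import replace

        from seq2abundance.feature_catalog import sequence_feature_frame
        from seq2abundance.rna_energy import EnergyModel

        regions = small_bundle.regions[:8]
        base = sequence_feature_frame(regions)
        alt_model = replace(
            EnergyModel.default(),
            stack_table={
                k: 1.5 * v
                for k, v in EnergyModel.default().stack_table.items()
            },
        )
        alt = sequence_feature_frame(regions, energy_model=alt_model)
        assert list(alt.columns) == list(base.columns)
        assert (alt.dtypes == base.dtypes).all()
        assert not alt["tir_fold_dg"].equals(base["tir_fold_dg"])

    def test_roundtrip_tsv(self, small_bundle, tmp_path):
        table = small_bundle.feature_table
        table.to_tsv(tmp_path / "features.tsv")
        from seq2abundance.feature_catalog import FeatureTable

        back = FeatureTable.from_tsv(tmp_path / "features.tsv")
        assert list(back.data.columns) == list(table.data.columns)
        assert np.allclose(back.data.to_numpy(), table.data.to_numpy())
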