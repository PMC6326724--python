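"""Gene models, consequence annotation, joint translation, filter cascade."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

import lofscan as L
from lofscan.lof_caller import LofCallerError, translate
from conftest import write_gene_fixture


def make_cds(n_codons, stop="TAA", body_codon="GCT"):
    """ATG + (n_codons - 2) alanines + stop: protein length n_codons - 1."""
    return "ATG" + body_codon * (n_codons - 2) + stop


def revcomp(s):
    return str(Seq(s).reverse_complement())


class TestLoadGeneModels:
    def test_multi_transcript_excluded_single_retained(self, tmp_path):
        cds = make_cds(100)
        genes = [
            {"gene_id": "keep", "strand": "+", "intervals": [(1001, 1300)], "cds": cds},
            {"gene_id": "drop", "strand": "+", "intervals": [(2001, 2300)], "cds": cds, "n_mrna": 2},
        ]
        paths = write_gene_fixture(tmp_path, genes)
        models, report = L.load_gene_models(paths["gff3"], paths["fasta"])
        assert set(models) == {"keep"}
        assert report == {"retained": 1, "multi_transcript": 1, "parse_error": 0, "no_sequence": 0}
        assert models["keep"].ref_protein_len == 99

    def test_length_mismatch_skipped(self, tmp_path):
        genes = [
            {"gene_id": "bad", "strand": "+", "intervals": [(1001, 1299)], "cds": make_cds(100)}
        ]
        paths = write_gene_fixture(tmp_path, genes)
        models, report = L.load_gene_models(paths["gff3"], paths["fasta"])
        assert models == {} and report["parse_error"] == 1

    def test_minus_strand_two_exon_assembly(self, tmp_path):
        # 2-exon minus-strand gene: genomic = revcomp of CDS halves, CDS
        # assembled 5'->3'; reference translation must start with M
        cds = make_cds(40, body_codon="TGG")  # ATG + 38 Trp + TAA, 120 nt
        left_genomic = revcomp(cds[60:])  # 3' half sits at lower coordinates
        right_genomic = revcomp(cds[:60])
        genes = [
            {
                "gene_id": "minus",
                "strand": "-",
                "intervals": [(501, 560), (661, 720)],
                "cds": cds,
            }
        ]
        paths = write_gene_fixture(tmp_path, genes)
        models, _ = L.load_gene_models(paths["gff3"], paths["fasta"])
        model = models["minus"]
        protein = translate(model.ref_cds)
        assert protein.startswith("M") and protein.endswith("*")
        # offset 0 (the A of ATG) maps to the highest genomic coordinate
        assert model.genomic_to_cds(720) == 0
        assert model.genomic_to_cds(501) == 119


def simple_model(n_codons=100, start=1001, cds=None):
    cds = cds or make_cds(n_codons)
    return L.GeneModel(
        gene_id="g", chrom="chr1", strand="+",
        cds_intervals=[(start, start + len(cds) - 1)], ref_cds=cds,
    )


class TestAnnotateConsequence:
    def test_stop_gained(self):
        # TGG codon mid-CDS: G->A at third base makes TGA
        cds = "ATG" + "GCT" * 10 + "TGG" + "GCT" * 10 + "TAA"
        model = simple_model(cds=cds)
        v = L.Variant("chr1", 1001 + 35, "G", "A")
        assert L.annotate_consequence(v, model) == "premature_stop"

    def test_frameshift_and_inframe_deletions(self):
        model = simple_model()
        pos = 1001 + 30
        assert L.annotate_consequence(
            L.Variant("chr1", pos, model.ref_cds[30:33], model.ref_cds[30]), model
        ) == "frameshift"
        assert L.annotate_consequence(
            L.Variant("chr1", pos, model.ref_cds[30:34], model.ref_cds[30]), model
        ) == "inframe"

    def test_start_loss_synonymous_missense_noncoding(self):
        model = simple_model()
        assert L.annotate_consequence(L.Variant("chr1", 1001, "A", "C"), model) == "start_loss"
        # GCT -> GCC is still Ala
        assert L.annotate_consequence(L.Variant("chr1", 1001 + 5, "T", "C"), model) == "synonymous"
        # GCT -> GTT is Ala -> Val
        assert L.annotate_consequence(L.Variant("chr1", 1001 + 4, "C", "T"), model) == "missense"
        assert L.annotate_consequence(L.Variant("chr1", 50, "A", "C"), model) == "noncoding"

    def test_non_acgt_rejected(self):
        with pytest.raises(LofCallerError):
            L.annotate_consequence(L.Variant("chr1", 1001, "A", "N"), simple_model())


class TestApplyVariantsAndTranslate:
    def test_reference_identity(self):
        model = simple_model()
        pred = L.apply_variants_and_translate("e", model, [])
        assert pred.truncation_fraction == 0.0 and pred.mechanism == "none"

    def test_premature_stop_quarter_lost(self):
        # premature stop with a quarter of the 200-residue protein lost
        cds = "ATG" + "GCT" * 148 + "TGG" + "GCT" * 50 + "TAA"
        model = simple_model(cds=cds)
        assert model.ref_protein_len == 200
        # TGG is codon index 149 (0-based): protein length becomes 150? The
        # stop lands at the mutated codon, so 149 residues precede it.
        v = L.Variant("chr1", 1001 + 149 * 3 + 2, "G", "A")
        pred = L.apply_variants_and_translate("e", model, [v])
        assert pred.predicted_len == 149
        assert pred.truncation_fraction == pytest.approx(1 - 149 / 200)
        assert pred.mechanism == "premature_stop"

    def test_compensating_frameshifts_restore_frame(self):
        # +1 bp then +2 bp insertions close together: frame restored between
        # them; protein keeps >= 90% of its length -> functional.  The AGT
        # tract supplies a shifted-frame stop so the lone insertion truncates.
        cds = "ATG" + "GCA" * 10 + "AGT" * 5 + "GCA" * 83 + "TAA"
        model = simple_model(cds=cds)
        ins1 = L.Variant("chr1", 1001 + 8, "A", "AG")
        ins2 = L.Variant("chr1", 1001 + 14, "A", "AGG")
        joint = L.apply_variants_and_translate("e", model, [ins1, ins2])
        single = L.apply_variants_and_translate("e", model, [ins1])
        assert single.truncation_fraction >= 0.10  # alone it is LoF
        assert joint.truncation_fraction < 0.10  # jointly compensated
        assert L.classify_allele(joint) == 0
        # oracle: manual splice + translation
        seq = cds[:9] + "G" + cds[9:]
        seq = seq[:16] + "GG" + seq[16:]
        aa = str(Seq(seq[: len(seq) - len(seq) % 3]).translate())
        expected = aa.find("*")
        assert joint.predicted_len == expected

    def test_start_loss_with_rescue_atg(self):
        # start disrupted; rescue ATG planted at codon 11 of 99
        cds = "ATG" + "GCT" * 10 + "ATG" + "GCT" * 87 + "TAA"
        model = simple_model(cds=cds)
        assert model.ref_protein_len == 99
        pred = L.apply_variants_and_translate(
            "e", model, [L.Variant("chr1", 1002, "T", "C")]
        )
        assert pred.mechanism == "start_loss"
        assert pred.predicted_len == 99 - 11
        assert pred.truncation_fraction == pytest.approx(11 / 99)
        assert L.classify_allele(pred) == 1  # 0.111 >= 0.10

    def test_start_loss_without_rescue_loses_everything(self):
        model = simple_model()  # body is all GCT: no downstream ATG
        pred = L.apply_variants_and_translate(
            "e", model, [L.Variant("chr1", 1001, "A", "C")]
        )
        assert pred.predicted_len == 0 and pred.truncation_fraction == 1.0

    def test_overlapping_alleles_rejected(self):
        model = simple_model()
        v1 = L.Variant("chr1", 1010, model.ref_cds[9:12], model.ref_cds[9])
        v2 = L.Variant("chr1", 1011, "C", "G")
        with pytest.raises(LofCallerError, match="overlap"):
            L.apply_variants_and_translate("e", model, [v1, v2])

    def test_ref_mismatch_rejected(self):
        model = simple_model()
        with pytest.raises(LofCallerError, match="mismatch"):
            L.apply_variants_and_translate(
                "e", model, [L.Variant("chr1", 1004, "T", "C")]
            )


class TestClassifyAllele:
    @pytest.mark.parametrize(
        "fraction,expected", [(0.10, 1), (0.05, 0), (0.0, 0), (1.0, 1), (0.0999, 0)]
    )
    def test_threshold_inclusive(self, fraction, expected):
        pred = L.ProteinPrediction("e", "g", 0, 100, fraction, "premature_stop")
        assert L.classify_allele(pred) == expected


class TestPrefilter:
    def build(self, tmp_path, n_samples, carriers, missing=()):
        cds = "ATG" + "GCT" * 20 + "TGG" + "GCT" * 20 + "TAA"
        genes = [{"gene_id": "g", "strand": "+", "intervals": [(1001, 1000 + len(cds))], "cds": cds}]
        samples = [f"e{i}" for i in range(n_samples)]
        gts = []
        for i in range(n_samples):
            if i in missing:
                gts.append(".")
            elif i in carriers:
                gts.append("1")
            else:
                gts.append("0")
        paths = write_gene_fixture(
            tmp_path, genes, vcf_rows=[(1001 + 21 * 3 + 2, "G", "A", gts)], samples=samples
        )
        models, _ = L.load_gene_models(paths["gff3"], paths["fasta"])
        calls, samples = L.load_variant_calls(paths["vcf"], models)
        return calls, len(samples)

    def test_exactly_five_percent_retained(self, tmp_path):
        calls, n = self.build(tmp_path, 20, carriers={0})  # 1/20 = 5%
        retained, _ = L.prefilter_genes(calls, n)
        assert retained == ["g"]

    def test_four_percent_dropped(self, tmp_path):
        calls, n = self.build(tmp_path, 25, carriers={0})  # 1/25 = 4%
        retained, report = L.prefilter_genes(calls, n)
        assert retained == [] and report.loc["g", "carrier_freq"] == pytest.approx(0.04)

    def test_six_percent_missing_dropped(self, tmp_path):
        calls, n = self.build(tmp_path, 50, carriers={0, 1, 2, 3}, missing={4, 5, 6})
        retained, report = L.prefilter_genes(calls, n)
        assert retained == [] and report.loc["g", "missing_rate"] == pytest.approx(0.06)


class TestFilterCascadeFixture:
    def build(self, tmp_path):
        """Three genes built so exactly one survives the full cascade.

        survivor: 10% of ecotypes carry a mid-CDS premature stop.
        shallow:  carriers' stop sits in the final 5% of the protein
                  (translated loss < 10%), so the post-translation filter
                  removes it.
        compensated: every carrier has a +1/+2 frameshift pair restoring
                  frame, so the re-applied 5% LoF frequency filter drops it.
        """
        n = 20
        samples = [f"e{i}" for i in range(n)]
        carriers = {0, 1}  # 10%
        cds_a = "ATG" + "GCT" * 40 + "TGG" + "GCT" * 40 + "TAA"
        cds_b = "ATG" + "GCT" * 95 + "TGG" + "GCT" * 2 + "TAA"
        cds_c = "ATG" + "GCA" * 98 + "TAA"
        genes = [
            {"gene_id": "survivor", "strand": "+", "intervals": [(1001, 1000 + len(cds_a))], "cds": cds_a},
            {"gene_id": "shallow", "strand": "+", "intervals": [(3001, 3000 + len(cds_b))], "cds": cds_b},
            {"gene_id": "compensated", "strand": "+", "intervals": [(5001, 5000 + len(cds_c))], "cds": cds_c},
        ]
        gt = lambda c: ["1" if i in c else "0" for i in range(n)]
        rows = [
            (1001 + 41 * 3 + 2, "G", "A", gt(carriers)),  # survivor stop at codon 41/121
            (3001 + 96 * 3 + 2, "G", "A", gt(carriers)),  # shallow stop at codon 96/98
            (5001 + 8, "A", "AG", gt(carriers)),  # +1 bp
            (5001 + 14, "A", "AGG", gt(carriers)),  # +2 bp, frame restored
        ]
        return write_gene_fixture(tmp_path, genes, vcf_rows=rows, samples=samples)

    def test_exactly_one_gene_survives(self, tmp_path):
        paths = self.build(tmp_path)
        matrix = L.call_lof(paths["vcf"], paths["gff3"], paths["fasta"])
        assert list(matrix.states.columns) == ["survivor"]
        assert matrix.states["survivor"].sum() == 2
        summary = matrix.gene_summary
        assert not summary.loc["compensated", "retained"]
        # shallow gene never reaches the final matrix either
        assert "shallow" not in matrix.states.columns

    def test_matrix_entries_binary_or_missing(self, tmp_path):
        paths = self.build(tmp_path)
        matrix = L.call_lof(paths["vcf"], paths["gff3"], paths["fasta"])
        vals = matrix.states.to_numpy().ravel()
        assert set(vals[np.isfinite(vals)]) <= {0.0, 1.0}


class TestUniqueAlleles:
    def make_matrix(self, lengths_by_ecotype, n=10, ref_len=100):
        states = pd.DataFrame(
            {"g": [1.0 if e in lengths_by_ecotype else 0.0 for e in range(n)]},
            index=pd.Index([f"e{i}" for i in range(n)], name="ecotype"),
        )
        states.index = [f"e{i}" for i in range(n)]
        preds = pd.DataFrame(
            [
                (f"e{e}", "g", plen, ref_len, 1 - plen / ref_len, "premature_stop", 1)
                for e, plen in lengths_by_ecotype.items()
            ],
            columns=["ecotype", "gene_id", "predicted_len", "reference_len",
                     "truncation_fraction", "mechanism", "is_lof"],
        )
        summary = pd.DataFrame(index=pd.Index(["g"], name="gene_id"))
        return L.FunctionalStateMatrix(states, preds, summary)

    def test_two_unique_lengths(self):
        m = self.make_matrix({0: 85, 1: 85, 2: 40})
        table = L.count_unique_alleles(m)
        assert table.loc["g", "n_unique"] == 2
        assert table.loc["g", "lof_freq"] == pytest.approx(0.3)
        assert table.loc["g", "mean_allele_freq"] == pytest.approx((0.2 + 0.1) / 2)

    def test_no_carriers(self):
        m = self.make_matrix({})
        table = L.count_unique_alleles(m)
        assert table.loc["g", "n_unique"] == 0

    def test_single_shared_length(self):
        m = self.make_matrix({i: 40 for i in range(5)})
        table = L.count_unique_alleles(m)
        assert table.loc["g", "n_unique"] == 1
        assert table.loc["g", "mean_allele_freq"] == pytest.approx(0.5)


class TestSyntheticRoundTrip:
    def test_matrix_matches_simulation_exactly(self, small_panel, small_matrix):
        """At missing_rate 0 the recovered matrix equals the simulated one."""
        true = small_panel.true_states[small_matrix.states.columns]
        pd.testing.assert_frame_equal(small_matrix.states, true, check_names=False)

    def test_retained_genes_are_those_above_frequency(self, small_panel, small_matrix):
        freq = small_panel.true_states.mean(axis=0)
        expected = set(freq.index[freq >= 0.05])
        assert set(small_matrix.states.columns) == expected

    def test_every_emitted_lof_variant_called_lof(self, small_panel, small_matrix):
        """Round trip: generator alleles -> caller predictions, length-exact."""
        by_gene = {g.gene_id: g for g in small_panel.sim_genes}
        preds = small_matrix.predictions
        lof = preds[preds["is_lof"] == 1]
        assert len(lof) > 100
        for gene_id, sub in lof.groupby("gene_id"):
            allowed = {a.protein_len for a in by_gene[gene_id].alleles}
            assert set(sub["predicted_len"]) <= allowed

    def test_truncation_fractions_match_bruteforce_oracle(self, small_panel, small_matrix):
        """Splice-and-translate oracle on the generator's CDS-space edits."""
        by_gene = {g.gene_id: g for g in small_panel.sim_genes}
        carriers = small_panel.true_states
        checked = 0
        for row in small_matrix.predictions.itertuples():
            gene = by_gene[row.gene_id]
            if carriers.loc[row.ecotype, row.gene_id] != 1.0:
                continue  # neutral-variant-only carriers
            # oracle: apply each allele; the ecotype carries exactly one
            matches = []
            for al in gene.alleles:
                seq = gene.cds[: al.offset] + al.alt + gene.cds[al.offset + len(al.ref):]
                start = 0
                if seq[:3] != "ATG":
                    start = next(
                        (o for o in range(0, len(seq) - 2, 3) if seq[o:o + 3] == "ATG"),
                        None,
                    )
                if start is None:
                    plen = 0
                else:
                    aa = str(Seq(seq[start: len(seq) - (len(seq) - start) % 3]).translate())
                    plen = aa.find("*") if "*" in aa else len(aa)
                matches.append(plen)
            assert row.predicted_len in matches
            checked += 1
        assert checked > 100

    def test_filter_monotonicity(self, small_matrix):
        """Lowering freq_min never removes a retained gene (summary check)."""
        summary = small_matrix.gene_summary
        loose = set(summary.index[summary["lof_freq"] >= 0.02])
        strict = set(summary.index[summary["lof_freq"] >= 0.05])
        assert strict <= loose
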