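"""Curation rules: labelling, primary filter, augmentation, test-set hygiene."""

from datetime import date

import pytest

from prp.curation import (
    AUGMENT_REVIEW_STATUS,
    ClinicalRecord,
    CurationConfig,
    LabeledVariantSet,
    augment_rare_tn,
    build_test_set,
    build_training_set,
    first_quartile_af,
    label_record,
    normalize_token,
    primary_filter,
    records_from_vcf,
)

MULTI = "criteria_provided,_multiple_submitters,_no_conflicts"
SINGLE = "criteria_provided,_single_submitter"


def rec(pos, sig, status=MULTI, consequence="missense", af=None,
        registered=None, gene=None, ref="A", alt="G"):
    return ClinicalRecord(
        key=("chr1", pos, ref, alt),
        consequence=consequence,
        clinical_significance=sig,
        review_status=status,
        af=af,
        first_registered=registered,
        gene=gene,
    )


class TestLabeling:
    @pytest.mark.parametrize(
        "sig,label",
        [
            ("Pathogenic", "TP"),
            ("Likely_pathogenic", "TP"),
            ("Pathogenic/Likely_pathogenic", "TP"),
            ("Benign", "TN"),
            ("Likely_benign", "TN"),
            ("Benign/Likely_benign", "TN"),
            ("Uncertain_significance", None),
            ("Conflicting_interpretations_of_pathogenicity", None),
            ("drug_response", None),
            ("LP/P", "TP"),
            ("LB/B", "TN"),
        ],
    )
    def test_significance_map(self, sig, label):
        assert label_record(rec(1, sig), CurationConfig()) == label

    def test_token_normalization(self):
        assert normalize_token(" Likely_Benign ") == "likely benign"
        assert (
            normalize_token(MULTI)
            == "criteria provided multiple submitters no conflicts"
        )

    def test_overlapping_label_sets_rejected(self):
        with pytest.raises(ValueError):
            CurationConfig(
                tp_set=frozenset({"pathogenic"}), tn_set=frozenset({"pathogenic"})
            )


class TestPrimaryFilter:
    def test_six_record_worked_example(self):
        records = [
            rec(1, "Pathogenic", status=MULTI),                      # keep TP
            rec(2, "Benign", status="reviewed_by_expert_panel"),     # keep TN
            rec(3, "Pathogenic", status=SINGLE),                     # tier too low
            rec(4, "Uncertain_significance", status=MULTI),          # VUS
            rec(5, "Pathogenic", status=MULTI, consequence="synonymous"),
            rec(1, "Pathogenic", status=MULTI),                      # duplicate key
        ]
        out = primary_filter(records, CurationConfig())
        assert out.counts() == {"TP": 1, "TN": 1}
        assert out.keys() == {("chr1", 1, "A", "G"), ("chr1", 2, "A", "G")}
        assert all(lr.provenance == "primary" for lr in out.records)

    def test_practice_guideline_accepted(self):
        out = primary_filter(
            [rec(1, "Benign", status="practice_guideline")], CurationConfig()
        )
        assert len(out) == 1

    def test_all_nssnv_consequences_pass(self):
        records = [
            rec(i, "Pathogenic", consequence=c)
            for i, c in enumerate(
                ("missense", "start_lost", "stop_gained", "stop_lost"), start=1
            )
        ]
        assert len(primary_filter(records, CurationConfig())) == 4


class TestAugmentation:
    def pool(self, n=20, af=1e-5):
        return [rec(100 + i, "Benign", status=SINGLE, af=af) for i in range(n)]

    def test_eligibility_rules(self):
        cfg = CurationConfig(augment_size=100, seed=3)
        records = (
            self.pool(5)
            + [rec(200, "Benign", status=SINGLE, af=3e-4)]       # not strictly <
            + [rec(201, "Benign", status=SINGLE, af=None)]       # AF missing
            + [rec(202, "Benign", status=MULTI, af=1e-5)]        # wrong tier
            + [rec(203, "Pathogenic", status=SINGLE, af=1e-5)]   # wrong label
        )
        with pytest.warns(UserWarning, match="eligible"):
            out = augment_rare_tn(records, cfg)
        assert {lr.record.key[1] for lr in out} == {100, 101, 102, 103, 104}
        assert all(lr.provenance == "augmentation" for lr in out)

    def test_boundary_af_just_below_cutoff_included(self):
        cfg = CurationConfig(augment_size=10, seed=0)
        with pytest.warns(UserWarning):
            out = augment_rare_tn(
                [rec(1, "Benign", status=SINGLE, af=3e-4 - 1e-12)], cfg
            )
        assert len(out) == 1

    def test_seeded_sample_is_deterministic_and_seed_sensitive(self):
        records = self.pool(50)
        cfg_a = CurationConfig(augment_size=10, seed=7)
        a1 = augment_rare_tn(records, cfg_a)
        a2 = augment_rare_tn(records, cfg_a)
        assert [lr.record.key for lr in a1] == [lr.record.key for lr in a2]
        b = augment_rare_tn(records, CurationConfig(augment_size=10, seed=8))
        assert [lr.record.key for lr in a1] != [lr.record.key for lr in b]

    def test_excluded_keys_never_sampled(self):
        records = self.pool(10)
        cfg = CurationConfig(augment_size=10, seed=0)
        exclude = {records[0].key, records[1].key}
        with pytest.warns(UserWarning):
            out = augment_rare_tn(records, cfg, exclude_keys=exclude)
        assert exclude.isdisjoint({lr.record.key for lr in out})

    def test_training_set_union_disjoint(self):
        records = [rec(1, "Pathogenic"), rec(2, "Benign")] + self.pool(30)
        cfg = CurationConfig(augment_size=5, seed=1)
        out = build_training_set(records, cfg)
        assert out.counts() == {"TP": 1, "TN": 6}
        assert len(out.keys()) == len(out)  # key uniqueness via __post_init__


class TestFirstQuartile:
    def test_worked_examples(self):
        afs = [1e-4, 2e-4, 3e-4, 4e-4]
        records = [rec(i, "Benign", af=a) for i, a in enumerate(afs, 1)]
        assert first_quartile_af(records) == pytest.approx(1.75e-4)
        records5 = records + [rec(9, "Benign", af=5e-4)]
        assert first_quartile_af(records5) == pytest.approx(2e-4)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            first_quartile_af([rec(1, "Benign", af=1e-4)] * 3)


class TestTestSet:
    def test_dedup_date_and_conflicts(self):
        training = primary_filter([rec(1, "Pathogenic")], CurationConfig())
        earlier = LabeledVariantSet(
            primary_filter([rec(2, "Benign")], CurationConfig()).records
        )
        records = [
            rec(1, "Pathogenic", registered=date(2023, 1, 1)),  # in training
            rec(2, "Benign", registered=date(2023, 1, 1)),      # in earlier test
            rec(3, "Pathogenic", registered=date(2021, 12, 31)),  # too old
            rec(4, "Pathogenic", registered=date(2022, 1, 1)),  # cutoff day kept
            rec(5, "Benign", registered=None),                  # no date -> kept
            rec(6, "Pathogenic", registered=date(2023, 1, 1)),  # conflicted ...
            rec(6, "Benign", registered=date(2023, 1, 1)),      # ... both dropped
        ]
        out = build_test_set(records, training, [earlier], CurationConfig())
        assert {k[1] for k in out.keys()} == {4, 5}

    def test_sources_without_review_status_bypass_tier_filter(self):
        training = LabeledVariantSet([])
        out = build_test_set(
            [rec(1, "LP/P", status=None), rec(2, "LB/B", status=None)],
            training,
            config=CurationConfig(),
        )
        assert out.counts() == {"TP": 1, "TN": 1}


class TestPlantedIntegration:
    def test_planted_vcf_roundtrip(self, tmp_path):
        from prp.pipeline import _manifest_consequences, train_plant
        from prp.simulate import (
            SimulationConfig,
            load_dates,
            simulate_clinvar_vcf,
            simulate_reference,
        )

        cfg = SimulationConfig(seed=5, n_genes=6, cds_length_range=(90, 150))
        reference = simulate_reference(cfg)
        plant = train_plant()
        manifest = simulate_clinvar_vcf(cfg, reference, tmp_path, plant=plant)
        records = records_from_vcf(
            manifest["vcf"],
            _manifest_consequences(manifest),
            dates=load_dates(manifest["dates"]),
        )
        curation = CurationConfig(augment_size=60, seed=5)
        out = build_training_set(records, curation)
        by_cell = {
            (c["sig"], normalize_token(c["status"])): c["n"]
            for c in manifest["cells"]
        }
        multi = "criteria provided multiple submitters no conflicts"
        # planted: P multi + LP expert -> TP; B multi + LB guideline ->
        # primary TN; rare single-submitter LB -> augmentation
        assert out.counts()["TP"] == (
            by_cell[("Pathogenic", multi)]
            + by_cell[("Likely_pathogenic", "reviewed by expert panel")]
        )
        n_aug = by_cell[("Likely_benign", "criteria provided single submitter")]
        assert out.counts()["TN"] == (
            by_cell[("Benign", multi)]
            + by_cell[("Likely_benign", "practice guideline")]
            + n_aug
        )
        by_prov = {}
        for lr in out.records:
            by_prov[lr.provenance] = by_prov.get(lr.provenance, 0) + 1
        assert by_prov["augmentation"] == n_aug
        # every curated key was planted with a matching label
        planted_tp = {
            tuple(k)
            for c in manifest["cells"]
            if c["sig"] in ("Pathogenic", "Likely_pathogenic")
            for k in c["keys"]
        }
        for key, label in out.labels().items():
            key = (key[0], int(key[1]), key[2], key[3])
            assert (label == "TP") == (key in planted_tp)


class TestRecordsFromVcf:
    def test_info_fields_and_af_fallback(self, tmp_path):
        vcf = tmp_path / "c.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            '##INFO=<ID=CLNSIG,Number=1,Type=String,Description="s">\n'
            '##INFO=<ID=CLNREVSTAT,Number=1,Type=String,Description="r">\n'
            '##INFO=<ID=AF,Number=A,Type=Float,Description="af">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            f"chr1\t100\t.\tA\tG\t.\t.\tCLNSIG=Benign;CLNREVSTAT={SINGLE};AF=0.0001\n"
            "chr1\t200\t.\tC\tT\t.\t.\tCLNSIG=Pathogenic\n"
        )
        records = records_from_vcf(
            vcf,
            {
                ("chr1", 100, "A", "G"): ("missense", "g1"),
                ("chr1", 200, "C", "T"): "stop_gained",
            },
        )
        assert len(records) == 2
        assert records[0].af == pytest.approx(1e-4)
        assert records[0].gene == "g1"
        assert records[1].review_status is None and records[1].af is None

    def test_unannotated_variants_skipped(self, tmp_path):
        vcf = tmp_path / "c.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            '##INFO=<ID=CLNSIG,Number=1,Type=String,Description="s">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tA\tG\t.\t.\tCLNSIG=Benign\n"
        )
        assert records_from_vcf(vcf, {}) == []
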