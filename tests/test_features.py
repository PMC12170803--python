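"""Feature engine: NPF counting, alignment frequencies, conservation
aggregation, substitution/intolerance lookups, preprocessing, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prp.features import (
    AF_FEATURES,
    FEATURE_CATEGORIES,
    FEATURE_NAMES,
    alignment_frequency,
    apply_preprocessor,
    assemble_features,
    build_npf_table,
    codon_usage_features,
    conservation_features,
    fit_preprocessor,
    intolerance_features,
    npf_features,
    spearman_matrix,
    substitution_features,
)
from prp.resources import STANDARD_AA, load_bundle
from prp.variants import CodingEffect, GenomicVariant, TranscriptModel


def brute_force_npf(proteome, i, j, k):
    """Sliding-window oracle for the triplet frequency n(A_ijk)/n(A_j)."""
    n_triplet = 0
    n_center = 0
    for seq in proteome.values():
        n_center += seq.count(j)
        for t in range(len(seq) - 2):
            if seq[t : t + 3] == i + j + k:
                n_triplet += 1
    return n_triplet / n_center if n_center else None


def make_effect(**kw):
    defaults = dict(
        consequence="missense",
        cds_pos=5,
        codon_index=2,
        ref_codon="GCT",
        alt_codon="GTT",
        ref_aa="A",
        alt_aa="V",
        prev_aa="M",
        next_aa="W",
        codon_genomic_span=(103, 104, 105),
    )
    defaults.update(kw)
    return CodingEffect(**defaults)


class TestNPF:
    def test_worked_single_sequence(self):
        table = build_npf_table({"g1": "AAA"})
        assert table.center_counts["A"] == 3
        assert table.triplet_counts[("A", "A", "A")] == 1
        assert table.frequency("A", "A", "A") == pytest.approx(1 / 3)

    def test_worked_duplicate_sequences(self):
        table = build_npf_table({"g1": "ARA", "g2": "ARA"})
        assert table.frequency("A", "R", "A") == 1.0

    def test_npfalt_substitutes_center_only(self):
        table = build_npf_table({"g1": "ARA", "g2": "ARA"})
        ref, alt = npf_features(
            make_effect(ref_aa="R", alt_aa="A", prev_aa="A", next_aa="A"), table
        )
        assert ref == 1.0
        assert alt == 0.0  # (A,A,A) never occurs; 6 alanines counted

    def test_short_sequence_contributes_no_triplets(self):
        table = build_npf_table({"g1": "AG"})
        assert table.triplet_counts == {}
        # center 'A' seen once, triplet never -> frequency 0, not missing
        assert table.frequency("A", "A", "G") == 0.0

    def test_terminus_and_stop_rules(self):
        table = build_npf_table({"g1": "ARA"})
        assert npf_features(make_effect(prev_aa=None), table) == (None, None)
        _, alt = npf_features(make_effect(alt_aa="*", prev_aa="A", next_aa="A"), table)
        assert alt is None

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            build_npf_table({})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_sliding_window_oracle(self, data):
        n_seq = data.draw(st.integers(1, 4))
        proteome = {
            f"g{i}": data.draw(
                st.text(alphabet="ARNDQ", min_size=0, max_size=30)
            )
            for i in range(n_seq)
        }
        if not any(proteome.values()):
            proteome["g_pad"] = "A"
        table = build_npf_table(proteome)
        for i in "AR":
            for j in "ARN":
                for k in "AD":
                    assert table.frequency(i, j, k) == brute_force_npf(
                        proteome, i, j, k
                    )


class TestAlignmentFrequency:
    def test_uniform_dna_column(self):
        assert alignment_frequency("ACGTN", "A", 5) == pytest.approx(0.2)

    def test_protein_column_by_counting(self):
        assert alignment_frequency("VVVVI", "V", 20) == pytest.approx(0.8)

    def test_gap_only_column_missing(self):
        assert alignment_frequency("----", "A") is None

    def test_gaps_removed_from_denominator(self):
        assert alignment_frequency("A--C", "A") == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN-", min_size=1, max_size=40))
    def test_frequencies_sum_to_one(self, column):
        freqs = [alignment_frequency(column, s) for s in "ACGTN"]
        if column.replace("-", "") == "":
            assert all(f is None for f in freqs)
        else:
            assert sum(freqs) == pytest.approx(1.0, abs=1e-9)


class TestConservation:
    @pytest.fixture()
    def setup(self, tmp_path):
        tx = TranscriptModel("g1", "g1.t1", "chr1", "+", ((100, 111),))
        variant = GenomicVariant("chr1", 104, "C", "T")
        effect = make_effect()
        return tx, variant, effect, tmp_path

    def _bundle(self, tmp_path, scores, domains="g1\t1\t2\n"):
        track = tmp_path / "track.tsv"
        track.write_text(
            "".join(f"chr1\t{p}\t{s}\n" for p, s in scores.items())
        )
        dom = tmp_path / "dom.tsv"
        dom.write_text(domains)
        return load_bundle({"track_phyloP100": str(track), "domains": str(dom)})

    def test_constant_track_collapses_all_levels(self, setup):
        tx, variant, effect, tmp_path = setup
        bundle = self._bundle(tmp_path, {p: 1.7 for p in range(100, 112)})
        out = conservation_features(variant, effect, tx, bundle)
        for level in ("allele", "codon", "domain", "gene"):
            assert out[f"phyloP100_{level}"] == pytest.approx(1.7)

    def test_codon_mean_is_arithmetic(self, setup):
        tx, variant, effect, tmp_path = setup
        bundle = self._bundle(tmp_path, {103: 0.0, 104: 3.0, 105: 3.0})
        out = conservation_features(variant, effect, tx, bundle)
        assert out["phyloP100_codon"] == pytest.approx(2.0)
        assert 0.0 <= out["phyloP100_codon"] <= 3.0

    def test_variant_outside_all_domains_missing(self, setup):
        tx, variant, effect, tmp_path = setup
        bundle = self._bundle(
            tmp_path, {p: 1.0 for p in range(100, 112)}, domains="g1\t4\t4\n"
        )
        out = conservation_features(variant, effect, tx, bundle)
        assert out["phyloP100_domain"] is None

    def test_uncovered_track_yields_missing(self, setup):
        tx, variant, effect, tmp_path = setup
        bundle = self._bundle(tmp_path, {200: 1.0})
        out = conservation_features(variant, effect, tx, bundle)
        assert out["phyloP100_allele"] is None
        assert out["phyloP470_gene"] is None  # track absent entirely


class TestLookups:
    def test_codon_usage_lookups(self, tmp_path):
        rows = {"GCT": 0.28, "TGA": 0.01}
        # pad to 64 codons summing to 1
        from itertools import product

        codons = ["".join(c) for c in product("ACGT", repeat=3)]
        rest = (1 - sum(rows.values())) / (64 - len(rows))
        p = tmp_path / "cu.tsv"
        p.write_text(
            "".join(f"{c}\t{rows.get(c, rest):.12f}\n" for c in codons)
        )
        bundle = load_bundle({"codon_usage": str(p)})
        cf_ref, cf_alt = codon_usage_features(
            make_effect(ref_codon="GCT", alt_codon="TGA"), bundle
        )
        assert cf_ref == pytest.approx(0.28)
        assert cf_alt == pytest.approx(0.01)

    def test_substitution_lookups(self, sim_bundle):
        bundle, _ = sim_bundle
        b, p, g, cst, ast = substitution_features(
            make_effect(ref_aa="A", alt_aa="A"), bundle
        )
        assert g == 0.0
        b, _, _, _, _ = substitution_features(
            make_effect(ref_aa="W", alt_aa="W"), bundle
        )
        assert b == 11
        _, _, _, cst, _ = substitution_features(
            make_effect(ref_codon="XXX", alt_codon="YYY"), bundle
        )
        assert cst is None

    def test_intolerance_lookup_and_missing(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("g1\t0.99\t0.009\t0.001\n")
        bundle = load_bundle({"constraint": str(p)})
        assert intolerance_features("g1", bundle) == (0.99, 0.009, 0.001)
        assert intolerance_features("nope", bundle) == (None, None, None)


class TestAssemble:
    def test_canonical_order_and_count(self, sim_reference, sim_bundle):
        bundle, _ = sim_bundle
        gene, tx = next(iter(sim_reference.transcripts.items()))
        pos = tx.cds_positions()[4]
        ref = sim_reference.genome[tx.chrom][pos - 1]
        alt = "A" if ref != "A" else "G"
        from prp.variants import call_coding_effect

        v = GenomicVariant(tx.chrom, pos, ref, alt)
        eff = call_coding_effect(v, tx, sim_reference.genome)
        if eff.consequence == "synonymous":
            pytest.skip("toy position happened to be synonymous")
        vec = assemble_features(v, eff, tx, bundle)
        assert tuple(vec) == FEATURE_NAMES
        assert len(vec) == 34
        # no AF tables loaded -> AF features missing pre-imputation
        assert vec["gnomAD_AFv2"] is None and vec["gnomAD_AFv4"] is None

    def test_rejects_synonymous(self, sim_reference, sim_bundle):
        bundle, _ = sim_bundle
        with pytest.raises(ValueError):
            assemble_features(
                GenomicVariant("chr1", 1, "A", "G"),
                make_effect(consequence="synonymous"),
                next(iter(sim_reference.transcripts.values())),
                bundle,
            )

    def test_category_partition(self):
        cats = [f for group in FEATURE_CATEGORIES.values() for f in group]
        assert tuple(cats) == FEATURE_NAMES
        assert [len(g) for g in FEATURE_CATEGORIES.values()] == [6, 20, 5, 3]


class TestPreprocessing:
    def test_median_imputation_then_zscore(self):
        df = pd.DataFrame({"Grantham": [1.0, 2.0, 3.0, np.nan]})
        model = fit_preprocessor(df)
        assert model.impute["Grantham"] == 2.0
        out = apply_preprocessor(model, df)
        filled = np.array([1, 2, 3, 2.0])
        expected = (filled - filled.mean()) / filled.std()
        np.testing.assert_allclose(out["Grantham"].to_numpy(), expected)

    def test_af_features_impute_zero(self):
        df = pd.DataFrame({"gnomAD_AFv4": [0.5, np.nan, 0.1]})
        model = fit_preprocessor(df)
        assert model.impute["gnomAD_AFv4"] == 0.0

    def test_fit_set_is_standardized(self, separable_table):
        df, _ = separable_table
        out = apply_preprocessor(fit_preprocessor(df), df)
        np.testing.assert_allclose(out.mean().to_numpy(), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(ddof=0).to_numpy(), 1.0, atol=1e-9)

    def test_apply_never_reestimates(self, separable_table):
        df, _ = separable_table
        model = fit_preprocessor(df)
        shifted = df + 100.0
        out = apply_preprocessor(model, shifted)
        assert (out.mean() > 5).all()  # used the stored center, not a new one

    def test_constant_column_scale_one(self):
        df = pd.DataFrame({"pLI": [0.5, 0.5, 0.5]})
        model = fit_preprocessor(df)
        assert model.scale["pLI"] == 1.0

    def test_schema_mismatch_rejected(self, separable_table):
        df, _ = separable_table
        model = fit_preprocessor(df)
        with pytest.raises(ValueError):
            apply_preprocessor(model, df[list(df.columns[:-1])])


class TestSpearman:
    def test_monotone_and_inverse(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        df = pd.DataFrame({"a": a, "b": 2 * a, "c": -a})
        corr = spearman_matrix(df)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(corr.values, corr.values.T, equal_nan=True)
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(1000, 4)), columns=list("abcd"))
        corr = spearman_matrix(df)
        off = corr.values[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_constant_column_missing(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        corr = spearman_matrix(df)
        assert np.isnan(corr.loc["a", "b"])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            spearman_matrix(pd.DataFrame({"a": [1.0, 2.0]}))
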