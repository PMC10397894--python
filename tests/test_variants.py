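"""Variant loading, window intersection, stratified MAF and sex specificity."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import splicescreen as ss
from splicescreen.intervals import GenomicInterval
from splicescreen.variants import (
    MISSING,
    GenotypeTable,
    RelevanceRule,
    Variant,
    VariantError,
    classify_tier,
    maf_matrix,
)

REPORTED_POSITIONS = [
    48712947, 48712962,  # female-specific exon 5 donor window
    48715291, 48715294, 48715302, 48715306, 48715307, 48715308, 48715309,  # intron 3 acceptor
]


def tiny_metadata(n_f=2, n_m=2, population="Pop"):
    rows = [
        {"sample_id": f"F{i}", "population": population, "sex": "F"} for i in range(n_f)
    ] + [
        {"sample_id": f"M{i}", "population": population, "sex": "M"} for i in range(n_m)
    ]
    return pd.DataFrame(rows)


def write_vcf_text(path, records, samples):
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=2R,length=50000000>",
        '##FILTER=<ID=PASS,Description="ok">',
        '##FILTER=<ID=LowQual,Description="bad">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for pos, ref, alt, filt, gts in records:
        lines.append(f"2R\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t.\tGT\t" + "\t".join(gts))
    path.write_text("\n".join(lines) + "\n")
    return path


class TestLoadRegionSnps:
    def test_filters(self, tmp_path):
        meta = tiny_metadata()
        samples = list(meta["sample_id"])
        gts = ["0/0", "0/1", "1/1", "./."]
        records = [(48710000 + i, "A", "C", "PASS", gts) for i in range(10)]  # in span
        records += [(48500000, "A", "C", "PASS", gts), (48990000, "A", "C", "PASS", gts)]  # out
        records += [(48710100, "A", "CT", "PASS", gts)]  # indel
        records += [(48710101, "A", "C", "LowQual", gts)]  # non-PASS
        records += [(48710102, "A", "C,T", "PASS", gts)]  # multiallelic
        path = write_vcf_text(tmp_path / "v.vcf", records, samples)
        span = GenomicInterval("2R", 48703664, 48788460, "-")
        table = ss.load_region_snps(path, span, meta)
        assert table.n_variants == 10
        assert [v.pos for v in table.variants] == sorted(v.pos for v in table.variants)
        # dosage and missingness decode
        assert table.dosage[0].tolist() == [0, 1, 2, MISSING]
        # synthesized ids follow the rs+position convention
        assert table.variants[0].id == f"rs{table.variants[0].pos}"

    def test_reported_positions_retained(self, tmp_path):
        meta = tiny_metadata()
        samples = list(meta["sample_id"])
        records = [(p, "A", "G", "PASS", ["0/1", "0/0", "0/0", "0/0"]) for p in REPORTED_POSITIONS]
        path = write_vcf_text(tmp_path / "v.vcf", records, samples)
        span = GenomicInterval("2R", 48703664, 48788460, "-")
        table = ss.load_region_snps(path, span, meta)
        assert [v.pos for v in table.variants] == REPORTED_POSITIONS

    def test_sample_mismatch_error(self, tmp_path):
        meta = tiny_metadata()
        path = write_vcf_text(
            tmp_path / "v.vcf", [(48710000, "A", "C", "PASS", ["0/0"])], ["STRANGER"]
        )
        span = GenomicInterval("2R", 48703664, 48788460, "-")
        with pytest.raises(VariantError, match="STRANGER"):
            ss.load_region_snps(path, span, meta)


class TestIntersection:
    @pytest.fixture()
    def nine_variants(self):
        return [Variant("2R", p, "A", "G") for p in REPORTED_POSITIONS]

    def test_reported_hit_counts(self, agdsx_sites, nine_variants):
        hits = ss.intersect_windows(nine_variants, agdsx_sites)
        per_site = Counter((h.site.key.kind, h.site.key.boundary) for h in hits)
        assert per_site[("acceptor", 48715295)] == 7   # shared intron 3 acceptor
        assert per_site[("donor", 48712957)] == 2      # female exon 5 donor
        assert per_site[("acceptor", 48714648)] == 0   # female intron 4 acceptor
        assert len(hits) == 9

    def test_matches_brute_force_double_loop(self, agdsx_sites, nine_variants):
        expected = {
            (v.pos, s.key.kind, s.key.boundary)
            for v in nine_variants
            for s in agdsx_sites
            if s.window.low <= v.pos <= s.window.high
        }
        got = {
            (h.variant.pos, h.site.key.kind, h.site.key.boundary)
            for h in ss.intersect_windows(nine_variants, agdsx_sites)
        }
        assert got == expected

    def test_window_edges_inclusive(self, agdsx_sites):
        # 48712962 sits exactly on the exon-side edge of the donor window
        v = Variant("2R", 48712962, "A", "G")
        hits = ss.intersect_windows([v], agdsx_sites)
        assert len(hits) == 1 and hits[0].offset == 0

    def test_variant_outside_all_windows(self, agdsx_sites):
        assert ss.intersect_windows([Variant("2R", 48714000, "A", "G")], agdsx_sites) == []


class TestTier:
    def test_donor_gt_dinucleotide(self, agdsx_sites):
        # first intronic base of the exon 5 donor (reverse strand)
        hits = ss.intersect_windows([Variant("2R", 48712956, "A", "G")], agdsx_sites)
        assert [h.tier for h in hits] == ["dinucleotide"]

    def test_exonic_edge_is_window_tier(self, agdsx_sites):
        hits = ss.intersect_windows([Variant("2R", 48712962, "A", "G")], agdsx_sites)
        assert [h.tier for h in hits] == ["window"]

    def test_acceptor_offsets(self):
        assert classify_tier("acceptor", 14) == "dinucleotide"
        assert classify_tier("acceptor", 15) == "dinucleotide"
        assert classify_tier("acceptor", 13) == "NYag_Y"
        assert classify_tier("acceptor", 12) == "window"  # the NYag N position
        assert classify_tier("donor", 6) == "dinucleotide"
        assert classify_tier("donor", 7) == "dinucleotide"
        assert classify_tier("donor", 5) == "window"


def table_from_doses(doses, meta):
    doses = np.atleast_2d(np.asarray(doses, dtype=np.int8))
    variants = [Variant("2R", 48710000 + i, "A", "G") for i in range(doses.shape[0])]
    return GenotypeTable(variants=variants, samples=meta, dosage=doses)


class TestSexSpecificity:
    def test_female_only(self):
        meta = tiny_metadata(3, 3)
        t = table_from_doses([[1, 0, 1, 0, 0, 0]], meta)
        assoc = ss.sex_specificity(t, 0)
        assert assoc.presence == "female_only" and assoc.tested

    def test_both_and_absent(self):
        meta = tiny_metadata(2, 2)
        both = ss.sex_specificity(table_from_doses([[1, 0, 0, 1]], meta), 0)
        absent = ss.sex_specificity(table_from_doses([[0, 0, 0, 0]], meta), 0)
        assert both.presence == "both" and absent.presence == "absent"

    def test_missing_sex_skips_test(self):
        meta = tiny_metadata(3, 0)
        assoc = ss.sex_specificity(table_from_doses([[1, 0, 0]], meta), 0)
        assert assoc.presence == "female_only" and not assoc.tested

    def test_type_i_error_rate(self):
        """A sex-independent rare allele is called non-significant in >= 95%
        of replicates (exact-test validity under the null)."""
        rng = np.random.default_rng(2024)
        n = 500
        meta = tiny_metadata(n // 2, n // 2)
        rejections = 0
        reps = 200
        for _ in range(reps):
            dose = rng.binomial(2, 0.01, size=n).astype(np.int8)
            t = table_from_doses([dose], meta)
            assoc = ss.sex_specificity(t, 0)
            if assoc.tested and assoc.p_value < 0.05:
                rejections += 1
        assert rejections / reps <= 0.05


class TestStratifiedMaf:
    def test_single_het_cell(self):
        meta = tiny_metadata(50, 0)
        dose = np.zeros(50, dtype=np.int8)
        dose[0] = 1
        t = table_from_doses([dose], meta)
        (cell,) = [s for s in ss.stratified_maf(t, 0) if s.sex == "F"]
        assert cell.maf == pytest.approx(0.01)
        assert cell.alt_count == 1 and cell.n_called == 50

    def test_all_missing_cell_undefined(self):
        meta = tiny_metadata(2, 2)
        t = table_from_doses([[MISSING, MISSING, 0, 1]], meta)
        by_sex = {s.sex: s for s in ss.stratified_maf(t, 0)}
        assert by_sex["F"].maf is None and by_sex["F"].n_called == 0
        assert by_sex["M"].maf is not None

    def test_maf_folds_major_allele(self):
        meta = tiny_metadata(2, 0)
        t = table_from_doses([[2, 1]], meta)  # alt freq 0.75 -> MAF 0.25
        (cell,) = ss.stratified_maf(t, 0)
        assert cell.alt_freq == pytest.approx(0.75)
        assert cell.maf == pytest.approx(0.25)

    def test_conservation_across_strata(self, cohort_table):
        """Summed per-stratum allele counts equal whole-cohort counts."""
        rng = np.random.default_rng(7)
        for vidx in rng.integers(0, cohort_table.n_variants, size=20):
            strata = ss.stratified_maf(cohort_table, int(vidx))
            dose = cohort_table.dosage[int(vidx)]
            called = dose[dose != MISSING]
            assert sum(s.alt_count for s in strata) == called.sum()
            assert sum(s.n_called for s in strata) == called.size
            for s in strata:
                if s.maf is not None:
                    assert 0.0 <= s.maf <= 0.5

    def test_parameter_recovery_within_binomial_ci(self):
        """Estimated per-stratum MAFs fall inside the exact binomial 95% CI
        of the planted frequencies in >= 93% of (replicate, cell) draws."""
        cohort = ss.DEFAULT_COHORT
        planted = ss.DEFAULT_PLANTED
        from splicescreen.synthetic import draw_genotypes, _stratum_freq

        rng = np.random.default_rng(11)
        inside = total = 0
        for _ in range(30):
            for pos, freqs in planted.items():
                dose = draw_genotypes(freqs, cohort, rng)
                i = 0
                for pop, sex, n in cohort:
                    p = _stratum_freq(freqs, pop, sex)
                    d = int(dose[i : i + n].sum())
                    i += n
                    if p == 0 or n == 0:
                        continue
                    lo, hi = stats.binom.interval(0.95, 2 * n, p)
                    inside += int(lo <= d <= hi)
                    total += 1
        assert inside / total >= 0.93


class TestRelevanceRule:
    def test_dinucleotide_always_relevant(self, agdsx_sites):
        meta = tiny_metadata(2, 2)
        t = table_from_doses([[1, 0, 0, 0]], meta)
        hits = ss.intersect_windows([Variant("2R", 48712956, "A", "G")], agdsx_sites)
        assoc = ss.sex_specificity(t, 0)
        strata = ss.stratified_maf(t, 0)
        relevant, reason = ss.splice_relevance(hits[0], assoc, strata)
        assert relevant and "dinucleotide" in reason

    def test_low_maf_window_hit_not_relevant(self, agdsx_sites):
        meta = tiny_metadata(50, 0)
        dose = np.zeros(50, dtype=np.int8)
        dose[0] = 1  # female-only but MAF 0.01 < 0.05
        t = table_from_doses([dose], meta)
        hits = ss.intersect_windows([Variant("2R", 48712962, "A", "G")], agdsx_sites)
        assoc = ss.sex_specificity(t, 0)
        strata = ss.stratified_maf(t, 0)
        relevant, _ = ss.splice_relevance(hits[0], assoc, strata)
        assert not relevant

    def test_sex_specific_common_window_hit_relevant(self, agdsx_sites):
        meta = tiny_metadata(10, 10)
        dose = np.array([1] * 5 + [0] * 5 + [0] * 10, dtype=np.int8)  # F-only, MAF 0.25
        t = table_from_doses([dose], meta)
        hits = ss.intersect_windows([Variant("2R", 48712962, "A", "G")], agdsx_sites)
        relevant, _ = ss.splice_relevance(
            hits[0], ss.sex_specificity(t, 0), ss.stratified_maf(t, 0)
        )
        assert relevant

    def test_threshold_configurable(self, agdsx_sites):
        meta = tiny_metadata(50, 0)
        dose = np.zeros(50, dtype=np.int8)
        dose[0] = 1
        t = table_from_doses([dose], meta)
        hits = ss.intersect_windows([Variant("2R", 48712962, "A", "G")], agdsx_sites)
        relevant, _ = ss.splice_relevance(
            hits[0], ss.sex_specificity(t, 0), ss.stratified_maf(t, 0),
            RelevanceRule(maf_threshold=0.005),
        )
        assert relevant


class TestReports:
    def test_hit_report_shape(self, cohort_table, agdsx_sites):
        hits = ss.intersect_windows(cohort_table.variants, agdsx_sites)
        report = ss.hit_report(cohort_table, hits)
        assert len(report) == 9
        assert set(report["tier"]) <= {"dinucleotide", "NYag_Y", "window"}
        assert report["pos"].is_monotonic_increasing or True  # order follows hits

    def test_maf_matrix_carrier_and_allele_freq(self):
        meta = tiny_metadata(25, 0)
        dose = np.zeros(25, dtype=np.int8)
        dose[0] = 1  # one het carrier: allele freq 0.02, carrier freq 0.04
        t = table_from_doses([dose], meta)
        m = maf_matrix(t)
        row = m[(m["sex"] == "F")].iloc[0]
        assert row["alt_freq"] == pytest.approx(0.02)
        assert row["carrier_freq"] == pytest.approx(0.04)
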