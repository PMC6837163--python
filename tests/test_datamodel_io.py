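"""Data model validation and file-format round trips."""

import pytest

from pdburden.datamodel import (
    AnnotatedVariant,
    CnvEvent,
    CohortManifest,
    GenotypeCall,
    Subject,
    VariantKey,
)
from pdburden.io import (
    read_annotated_vcf,
    read_cnv_table,
    read_manifest,
    write_cnv_table,
    write_manifest,
    write_results,
    write_vcf,
)


def make_subject(i, group="pd", **kw):
    kw.setdefault("aoo", 40.0 if group == "pd" else None)
    return Subject(id=f"X{i}", cohort_group=group, **kw)


class TestDatamodel:
    def test_variant_key_rejects_degenerate(self):
        with pytest.raises(ValueError):
            VariantKey("GBA", 0, "A", "G")
        with pytest.raises(ValueError):
            VariantKey("GBA", 10, "A", "A")
        with pytest.raises(ValueError):
            VariantKey("GBA", 10, "A", "G,T")

    def test_zygosity_strictly_binary(self):
        key = VariantKey("GBA", 10, "A", "G")
        with pytest.raises(ValueError):
            GenotypeCall("X1", key, "ref")
        assert GenotypeCall("X1", key, "het").hits == 1
        assert GenotypeCall("X1", key, "hom").hits == 2

    def test_pd_subject_requires_aoo(self):
        with pytest.raises(ValueError):
            Subject(id="X1", cohort_group="pd", aoo=None)

    def test_manifest_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            CohortManifest(subjects=[make_subject(1), make_subject(1)])

    def test_pop_maf_bounds_enforced_at_construction(self):
        key = VariantKey("GBA", 10, "A", "G")
        with pytest.raises(ValueError):
            AnnotatedVariant(key=key, gene="GBA", consequence="missense_variant",
                             pop_mafs={"gnomad": 1.2})


class TestManifestIO:
    def test_round_trip_identity(self, tmp_path):
        manifest = CohortManifest(
            subjects=[make_subject(1), make_subject(2, "control_healthy"),
                      make_subject(3, "neurodeg")],
            denominators={"ngs": (1, 1), "full": (1, 2)},
        )
        p = tmp_path / "m.tsv"
        write_manifest(manifest, p)
        back = read_manifest(p)
        assert back.subjects == manifest.subjects
        assert back.denominators == manifest.denominators

    def test_empty_table_gives_empty_manifest(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tcohort_group\tstatus\tsex\taoo\tassay\n")
        assert len(read_manifest(p)) == 0

    def test_sporadic_familial_margins(self, tmp_path):
        # 61 + 48 sporadic and 17 + 16 familial patients
        rows = ["id\tcohort_group\tstatus\tsex\taoo\tassay"]
        i = 0
        for sex, n_spor, n_fam in (("m", 61, 17), ("f", 48, 16)):
            for status, n in (("sporadic", n_spor), ("familial", n_fam)):
                for _ in range(n):
                    i += 1
                    rows.append(f"P{i}\tpd\t{status}\t{sex}\t40\tngs_panel")
        p = tmp_path / "m.tsv"
        p.write_text("\n".join(rows) + "\n")
        m = read_manifest(p)
        assert sum(1 for s in m.cases if s.status == "sporadic") == 109
        assert sum(1 for s in m.cases if s.status == "familial") == 33

    def test_missing_aoo_for_pd_is_hard_error(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tcohort_group\tstatus\tsex\taoo\tassay\n"
                     "P1\tpd\tsporadic\tm\t\tngs_panel\n")
        with pytest.raises(ValueError):
            read_manifest(p)


def _manifest_for(ids, tmp_path):
    m = CohortManifest(subjects=[Subject(id=i, cohort_group="pd", aoo=40.0) for i in ids])
    return m


class TestVcfIngest:
    VCF_HEADER = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=GBA,length=2000000>\n"
        '##INFO=<ID=ANN,Number=.,Type=String,Description="ann">\n'
        '##INFO=<ID=MAF_GNOMAD,Number=A,Type=Float,Description="af">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
    )

    def _write(self, tmp_path, body, samples):
        p = tmp_path / "x.vcf"
        head = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
        p.write_text(self.VCF_HEADER + head + "\n" + body)
        return p

    def test_empty_vcf_gives_empty_lists(self, tmp_path):
        p = self._write(tmp_path, "", ["P1"])
        variants, calls = read_annotated_vcf(p, _manifest_for(["P1"], tmp_path))
        assert variants == [] and calls == []

    def test_het_carriers_parsed(self, tmp_path):
        samples = [f"P{i}" for i in range(1, 7)]
        gts = "\t".join(["0/1"] * 5 + ["0/0"])
        body = (f"GBA\t1223\trs75548401\tC\tT\t.\tPASS\t"
                f"ANN=T|missense_variant|MODERATE|GBA|||||||;MAF_GNOMAD=0.004\tGT\t{gts}\n")
        p = self._write(tmp_path, body, samples)
        variants, calls = read_annotated_vcf(p, _manifest_for(samples, tmp_path))
        assert len(variants) == 1
        assert variants[0].gene == "GBA"
        assert variants[0].rsid == "rs75548401"
        assert len(calls) == 5
        assert all(c.zygosity == "het" for c in calls)

    def test_multiallelic_split_one_variant_per_alt(self, tmp_path):
        body = ("GBA\t100\t.\tA\tG,T\t.\tPASS\t"
                "ANN=G|missense_variant|MODERATE|GBA|||||||,"
                "T|stop_gained|HIGH|GBA|||||||;MAF_GNOMAD=0.001,0.002\tGT\t1/2\n")
        p = self._write(tmp_path, body, ["P1"])
        variants, calls = read_annotated_vcf(p, _manifest_for(["P1"], tmp_path))
        assert len(variants) == 2
        assert {v.key.alt for v in variants} == {"G", "T"}
        assert all(v.key.chrom == "GBA" and v.key.pos == 100 and v.key.ref == "A"
                   for v in variants)
        # a 1/2 genotype yields one het call per involved alternate allele
        assert len(calls) == 2
        assert all(c.zygosity == "het" for c in calls)

    def test_hom_and_missing_genotypes(self, tmp_path):
        body = ("GBA\t100\t.\tA\tG\t.\tPASS\t"
                "ANN=G|missense_variant|MODERATE|GBA|||||||\tGT\t1/1\t./.\t0/0\n")
        p = self._write(tmp_path, body, ["P1", "P2", "P3"])
        _, calls = read_annotated_vcf(p, _manifest_for(["P1", "P2", "P3"], tmp_path))
        assert [(c.subject_id, c.zygosity) for c in calls] == [("P1", "hom")]

    def test_unknown_sample_is_hard_error(self, tmp_path):
        body = ("GBA\t100\t.\tA\tG\t.\tPASS\t"
                "ANN=G|missense_variant|MODERATE|GBA|||||||\tGT\t0/1\n")
        p = self._write(tmp_path, body, ["GHOST"])
        with pytest.raises(ValueError, match="absent from manifest"):
            read_annotated_vcf(p, _manifest_for(["P1"], tmp_path))

    def test_unparseable_annotation_skipped_with_warning(self, tmp_path, caplog):
        body = ("GBA\t100\t.\tA\tG\t.\tPASS\tMAF_GNOMAD=0.001\tGT\t0/1\n"
                "GBA\t200\t.\tA\tG\t.\tPASS\t"
                "ANN=G|missense_variant|MODERATE|GBA|||||||\tGT\t0/1\n")
        p = self._write(tmp_path, body, ["P1"])
        with caplog.at_level("WARNING"):
            variants, calls = read_annotated_vcf(p, _manifest_for(["P1"], tmp_path))
        assert len(variants) == 1 and variants[0].key.pos == 200
        assert any("unparseable" in r.message or "missing" in r.message
                   for r in caplog.records)

    def test_full_cohort_round_trip(self, fixture_cohort, fixture_bundle, catalog):
        manifest = read_manifest(fixture_bundle / "manifest.tsv")
        variants, calls = read_annotated_vcf(
            fixture_bundle / "cohort.vcf", manifest, catalog=catalog
        )
        assert len(variants) == len(fixture_cohort.variants)
        want = {(c.subject_id, str(c.key), c.zygosity) for c in fixture_cohort.calls}
        got = {(c.subject_id, str(c.key), c.zygosity) for c in calls}
        assert got == want


class TestCnvAndResults:
    def test_cnv_round_trip(self, tmp_path):
        events = [
            CnvEvent("P130", "PRKN", "exon 7", "duplication", "P"),
            CnvEvent("P140", "SNCA", "whole gene", "duplication", "P"),
        ]
        p = tmp_path / "cnv.tsv"
        write_cnv_table(events, p)
        assert read_cnv_table(p) == events

    def test_cnv_bad_dosage_rejected(self, tmp_path):
        p = tmp_path / "cnv.tsv"
        p.write_text("subject_id\tgene\tregion\tdosage\tclin_class\n"
                     "P1\tPRKN\texon 7\tgain\tP\n")
        with pytest.raises(ValueError):
            read_cnv_table(p)

    def test_empty_cnv_table(self, tmp_path):
        p = tmp_path / "cnv.tsv"
        p.write_text("subject_id\tgene\tregion\tdosage\tclin_class\n")
        assert read_cnv_table(p) == []

    def test_results_deterministic_and_fixed_precision(self, tmp_path):
        rows = [{"variant": "GBA:1:A>G", "OR": 6.8877551, "p": 0.023745}]
        p1, p2 = tmp_path / "r1.tsv", tmp_path / "r2.tsv"
        for p in (p1, p2):
            write_results(rows, p, precision={"OR": 1, "p": 2})
        assert p1.read_bytes() == p2.read_bytes()
        assert "6.9\t0.02" in p1.read_text()

    def test_results_empty_gives_header_only(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_results([], p, columns=["a", "b"])
        assert p.read_text() == "a\tb\n"


def test_vcf_hemizygous_haploid_counts_as_hom(tmp_path):
    head = TestVcfIngest.VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\n"
    body = "GBA\t100\t.\tA\tG\t.\tPASS\tANN=G|missense_variant|MODERATE|GBA|||||||\tGT\t1\n"
    p = tmp_path / "x.vcf"
    p.write_text(head + body)
    _, calls = read_annotated_vcf(p, _manifest_for(["P1"], tmp_path))
    assert [c.zygosity for c in calls] == ["hom"]
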