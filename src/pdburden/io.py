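"""Readers and writers for the external formats.

* **Manifest** — TSV with one row per subject (``id, cohort_group, status,
  sex, aoo, assay``). Denominator scopes are stored in leading ``#scope``
  comment lines so a manifest round-trips through write/read unchanged.
* **VCF 4.2** — multi-sample, with a SnpEff-style pipe-delimited ``ANN``
  INFO field (``Allele|Annotation|Impact|Gene|...``). Which INFO keys carry
  population frequencies, predictor calls and the clinical class is declared
  in an :class:`AnnotationConfig` (the run config), not hard-coded, because
  annotation pipelines name them differently. Parsed with cyvcf2.
* **CNV table** — TSV of MLPA-style exon dosage events.
* **Results** — TSV with deterministic column order and fixed precision.

Multi-allelic records are split into one variant per alternate allele at
ingest. Genotypes: 0/1 -> het, 1/1 -> hom; 0/0 and ./. are dropped; a
genotype like 1/2 yields one het call per involved alternate allele.
Haploid (hemizygous) alternate genotypes count as homozygous by default
(two hits), configurable via ``hemizygous_as_hom``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from cyvcf2 import VCF

from .catalog import GeneCatalog
from .datamodel import (
    AnnotatedVariant,
    CnvEvent,
    CohortManifest,
    GenotypeCall,
    Subject,
    VariantKey,
)

__all__ = [
    "AnnotationConfig",
    "read_annotated_vcf",
    "read_cnv_table",
    "read_manifest",
    "write_cnv_table",
    "write_manifest",
    "write_results",
]

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

MANIFEST_COLUMNS = ("id", "cohort_group", "status", "sex", "aoo", "assay")
CNV_COLUMNS = ("subject_id", "gene", "region", "dosage", "clin_class")


@dataclass(frozen=True)
class AnnotationConfig:
    """Declares where annotations live in the VCF INFO column.

    ``pop_maf_keys`` maps a population label to the INFO key holding its
    allele frequency (Number=A). ``predictor_keys`` is the ordered list of
    INFO keys carrying in-silico predictor calls, decoded through
    ``predictor_vocab`` (unmapped or absent values become ``missing``).
    """

    pop_maf_keys: Mapping[str, str] = field(
        default_factory=lambda: {
            "kg_all": "MAF_1KG",
            "esp": "MAF_ESP",
            "exac": "MAF_EXAC",
            "gnomad": "MAF_GNOMAD",
        }
    )
    predictor_keys: tuple[str, ...] = ("PRED_SIFT", "PRED_PP2", "PRED_MT")
    predictor_vocab: Mapping[str, str] = field(
        default_factory=lambda: {"D": "damaging", "T": "tolerated"}
    )
    clin_key: Optional[str] = "CLNSIG"
    hemizygous_as_hom: bool = True


# ---------------------------------------------------------------------------
# manifest

def read_manifest(path: PathLike) -> CohortManifest:
    denominators: dict[str, tuple[int, int]] = {}
    rows: list[dict] = []
    with open(path, newline="") as fh:
        header: Optional[list[str]] = None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#scope"):
                _, label, n_case, n_ctrl = line.split("\t")
                denominators[label] = (int(n_case), int(n_ctrl))
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                missing = set(MANIFEST_COLUMNS) - set(header)
                if missing:
                    raise ValueError(f"manifest header lacks columns: {sorted(missing)}")
                continue
            rows.append(dict(zip(header, parts)))
    subjects = [
        Subject(
            id=r["id"],
            cohort_group=r["cohort_group"],
            status=r["status"],
            sex=r["sex"],
            aoo=float(r["aoo"]) if r["aoo"] not in ("", ".", "NA") else None,
            assay=r["assay"],
        )
        for r in rows
    ]
    return CohortManifest(subjects=subjects, denominators=denominators)


def write_manifest(manifest: CohortManifest, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        for label in sorted(manifest.denominators):
            n_case, n_ctrl = manifest.denominators[label]
            fh.write(f"#scope\t{label}\t{n_case}\t{n_ctrl}\n")
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for s in manifest.subjects:
            aoo = "" if s.aoo is None else format(s.aoo, "g")
            fh.write(f"{s.id}\t{s.cohort_group}\t{s.status}\t{s.sex}\t{aoo}\t{s.assay}\n")


# ---------------------------------------------------------------------------
# VCF

def _info_alt_value(info_value, alt_index: int):
    """Pick the per-alt entry from a possibly tuple-valued INFO field."""
    if info_value is None:
        return None
    if isinstance(info_value, str) and "," in info_value:
        info_value = info_value.split(",")
    if isinstance(info_value, (tuple, list)):
        val = info_value[alt_index] if alt_index < len(info_value) else None
        return None if val in (".", "", None) else val
    if info_value == ".":
        return None
    return info_value if alt_index == 0 else None


def _parse_ann(ann: str, alt: str) -> Optional[tuple[str, str, Optional[str], Optional[str]]]:
    """Return (consequence, gene, hgvs_c, hgvs_p) for this alt, or None."""
    for entry in ann.split(","):
        fields = entry.split("|")
        if len(fields) < 4:
            continue
        if fields[0] != alt:
            continue
        consequence, gene = fields[1], fields[3]
        hgvs_c = fields[9] if len(fields) > 9 and fields[9] else None
        hgvs_p = fields[10] if len(fields) > 10 and fields[10] else None
        return consequence, gene, hgvs_c, hgvs_p
    return None


def read_annotated_vcf(
    path: PathLike,
    manifest: CohortManifest,
    config: Optional[AnnotationConfig] = None,
    catalog: Optional[GeneCatalog] = None,
) -> tuple[list[AnnotatedVariant], list[GenotypeCall]]:
    """Ingest a multi-sample annotated VCF.

    Every VCF sample must appear in the manifest (hard error otherwise).
    Records whose annotation string cannot be parsed are skipped with a
    logged warning. When a catalog is given, each variant's ``risk_flag`` is
    set from the risk registry.
    """
    if config is None:
        config = AnnotationConfig()
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = set(samples) - manifest.ids()
    if unknown:
        raise ValueError(f"VCF samples absent from manifest: {sorted(unknown)[:5]}")
    variants: list[AnnotatedVariant] = []
    calls: list[GenotypeCall] = []
    for rec in vcf:
        ann = rec.INFO.get("ANN")
        rsid = rec.ID if rec.ID and rec.ID.startswith("rs") else None
        genotypes = rec.genotypes  # [[a0, a1, phased], ...]
        for alt_index, alt in enumerate(rec.ALT):
            parsed = _parse_ann(ann, alt) if ann else None
            if parsed is None:
                log.warning(
                    "skipping %s:%s alt %s: missing or unparseable ANN entry",
                    rec.CHROM, rec.POS, alt,
                )
                continue
            consequence, gene, hgvs_c, hgvs_p = parsed
            pop_mafs = {}
            for label, key in config.pop_maf_keys.items():
                val = _info_alt_value(rec.INFO.get(key), alt_index)
                if val is not None:
                    # VCF floats are 32-bit; renormalize so a frequency
                    # written as 0.01 compares exactly at the rarity ceiling
                    pop_mafs[label] = float(f"{float(val):.6g}")
            votes = []
            for key in config.predictor_keys:
                raw = _info_alt_value(rec.INFO.get(key), alt_index)
                votes.append(config.predictor_vocab.get(str(raw), "missing") if raw else "missing")
            clin = None
            if config.clin_key:
                raw = _info_alt_value(rec.INFO.get(config.clin_key), alt_index)
                if raw and str(raw) in ("P", "LP", "US", "LB", "B"):
                    clin = str(raw)
            key = VariantKey(chrom=str(rec.CHROM), pos=rec.POS, ref=rec.REF, alt=alt)
            var = AnnotatedVariant(
                key=key,
                gene=gene,
                consequence=consequence,
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
                rsid=rsid,
                predictor_votes=tuple(votes),
                pop_mafs=pop_mafs,
                clin_class=clin,
            )
            if catalog is not None:
                var = var.with_risk_flag(catalog.registry_entry(var) is not None)
            variants.append(var)
            allele_number = alt_index + 1
            for sample, gt in zip(samples, genotypes):
                alleles = [a for a in gt[:-1] if a is not None and a >= 0]
                n_alt = sum(1 for a in alleles if a == allele_number)
                if n_alt == 0:
                    continue
                if n_alt >= 2 or (len(alleles) == 1 and config.hemizygous_as_hom):
                    zyg = "hom"
                else:
                    zyg = "het"
                calls.append(GenotypeCall(subject_id=sample, key=key, zygosity=zyg))
    return variants, calls


def write_vcf(
    variants: Sequence[AnnotatedVariant],
    calls: Sequence[GenotypeCall],
    sample_ids: Sequence[str],
    path: PathLike,
    config: Optional[AnnotationConfig] = None,
) -> None:
    """Emit a VCF 4.2 text file that :func:`read_annotated_vcf` round-trips.

    One record per variant (the synthetic layout uses one contig per gene, so
    multi-allelic records never arise here). Genotypes not present in
    ``calls`` are written as 0/0.
    """
    if config is None:
        config = AnnotationConfig()
    inv_vocab = {v: k for k, v in config.predictor_vocab.items()}
    gt_map: dict[tuple, str] = {}
    for c in calls:
        gt_map[(c.subject_id, c.key)] = "1/1" if c.zygosity == "hom" else "0/1"
    contigs = sorted({v.key.chrom for v in variants})
    with open(path, "w", newline="") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig},length=2000000>\n")
        fh.write(
            '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
            "'Allele|Annotation|Annotation_Impact|Gene_Name|Gene_ID|Feature_Type|Feature_ID|"
            "Transcript_BioType|Rank|HGVS.c|HGVS.p'\">\n"
        )
        for key in config.pop_maf_keys.values():
            fh.write(
                f'##INFO=<ID={key},Number=A,Type=Float,Description="Population allele frequency">\n'
            )
        for key in config.predictor_keys:
            fh.write(
                f'##INFO=<ID={key},Number=A,Type=String,Description="In-silico predictor call">\n'
            )
        if config.clin_key:
            fh.write(
                f'##INFO=<ID={config.clin_key},Number=A,Type=String,'
                'Description="Clinical significance">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT")
        fh.write("\t" + "\t".join(sample_ids) + "\n")
        ordered = sorted(variants, key=lambda v: (v.key.chrom, v.key.pos, v.key.alt))
        for v in ordered:
            info_parts = [
                "ANN="
                + "|".join(
                    [
                        v.key.alt,
                        v.consequence,
                        "MODERATE",
                        v.gene,
                        v.gene,
                        "transcript",
                        f"{v.gene}.1",
                        "protein_coding",
                        "1/1",
                        v.hgvs_c or "",
                        v.hgvs_p or "",
                    ]
                )
            ]
            for label, key in config.pop_maf_keys.items():
                if label in v.pop_mafs:
                    info_parts.append(f"{key}={v.pop_mafs[label]:.6g}")
            for key, vote in zip(config.predictor_keys, v.predictor_votes):
                if vote != "missing":
                    info_parts.append(f"{key}={inv_vocab[vote]}")
            if config.clin_key and v.clin_class:
                info_parts.append(f"{config.clin_key}={v.clin_class}")
            gts = "\t".join(gt_map.get((s, v.key), "0/0") for s in sample_ids)
            fh.write(
                f"{v.key.chrom}\t{v.key.pos}\t{v.rsid or '.'}\t{v.key.ref}\t{v.key.alt}"
                f"\t.\tPASS\t{';'.join(info_parts)}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# CNV table

def read_cnv_table(path: PathLike) -> list[CnvEvent]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [
            CnvEvent(
                subject_id=r["subject_id"],
                gene=r["gene"],
                region=r["region"],
                dosage=r["dosage"],
                clin_class=r.get("clin_class") or None,
            )
            for r in reader
        ]


def write_cnv_table(events: Sequence[CnvEvent], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(CNV_COLUMNS) + "\n")
        for ev in events:
            fh.write(
                f"{ev.subject_id}\t{ev.gene}\t{ev.region}\t{ev.dosage}\t{ev.clin_class or ''}\n"
            )


# ---------------------------------------------------------------------------
# results

def write_results(
    rows: Sequence[Mapping],
    path: PathLike,
    columns: Optional[Sequence[str]] = None,
    precision: Mapping[str, int] = (),
) -> None:
    """Write a results table as TSV with deterministic column order.

    ``precision`` maps column name -> decimal places; other floats are
    emitted with ``repr``-style shortest form. Re-running on identical input
    produces byte-identical output.
    """
    precision = dict(precision)
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            cells = []
            for col in columns:
                val = row.get(col, "")
                if val is None:
                    cells.append("")
                elif col in precision and isinstance(val, float):
                    cells.append(f"{val:.{precision[col]}f}")
                elif isinstance(val, float):
                    cells.append(format(val, "g"))
                elif isinstance(val, bool):
                    cells.append("true" if val else "false")
                else:
                    cells.append(str(val))
            fh.write("\t".join(cells) + "\n")
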