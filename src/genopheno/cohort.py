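"""Cohort assembly: genotypes, per-variant annotations, phenotypes, filters.

Variant identity is the 4-tuple (chrom, 1-based pos, ref, alt) after
bi-allelic decomposition; inputs are assumed left-normalised upstream.
Genotype calls are coded 0 (hom-ref), 1 (het), 2 (hom-alt) and -1
(missing); a missing call counts the patient as a non-carrier downstream,
with the distortion bounded by the per-variant missingness filter.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import pysam

from .config import GenonConfig
from .errors import FormatError, RowValidationError, SchemaError
from .ontology import HpoOntology

logger = logging.getLogger(__name__)

MISSING = -1

VariantKey = Tuple[str, int, str, str]

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene",
    "gnomad_ac", "gnomad_an", "gnomad_hom",
    "cadd_phred", "filter", "coding_distance",
]


@dataclasses.dataclass
class Patient:
    patient_id: str
    hpo_terms: Set[str]


@dataclasses.dataclass
class VariantAnnotation:
    """Per-variant annotation row (population frequency + deleteriousness)."""

    variant_key: VariantKey
    gene_ids: Set[str]
    gnomad_ac: int
    gnomad_an: int
    gnomad_hom: int
    cadd_phred: float
    filter_status: str
    coding_distance: int
    missing_rate: Optional[float] = None
    gnomad_covered: bool = True

    def validate(self, line: Optional[int] = None) -> None:
        if self.gnomad_covered:
            if self.gnomad_ac < 0 or self.gnomad_an < 0 or self.gnomad_hom < 0:
                raise RowValidationError("gnomAD counts must be non-negative", line)
            if self.gnomad_ac > self.gnomad_an:
                raise RowValidationError(
                    f"gnomad_ac ({self.gnomad_ac}) > gnomad_an ({self.gnomad_an})", line)
            if 2 * self.gnomad_hom > self.gnomad_ac:
                raise RowValidationError(
                    f"2 x gnomad_hom ({self.gnomad_hom}) > gnomad_ac ({self.gnomad_ac})", line)
        if self.cadd_phred < 0:
            raise RowValidationError("cadd_phred must be non-negative", line)
        if self.coding_distance < 0:
            raise RowValidationError("coding_distance must be non-negative", line)
        if self.missing_rate is not None and not (0.0 <= self.missing_rate <= 1.0):
            raise RowValidationError("missing_rate must lie in [0, 1]", line)


class GenotypeMatrix:
    """Dense patients x variants call matrix (int8; -1 encodes missing)."""

    def __init__(self, patients: Sequence[str], variants: Sequence[VariantKey],
                 calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(patients), len(variants)):
            raise FormatError(
                f"calls shape {calls.shape} does not match "
                f"{len(patients)} patients x {len(variants)} variants")
        bad = ~np.isin(calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise FormatError("genotype calls must be one of {-1, 0, 1, 2}")
        self.patients = list(patients)
        self.variants = list(variants)
        self.calls = calls
        self.patient_index = {p: i for i, p in enumerate(self.patients)}
        self.variant_index = {v: i for i, v in enumerate(self.variants)}

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def missing_rates(self) -> np.ndarray:
        if self.n_patients == 0:
            return np.zeros(self.n_variants)
        return (self.calls == MISSING).mean(axis=0)

    def subset_variants(self, keep: Iterable[VariantKey]) -> "GenotypeMatrix":
        keep = list(keep)
        idx = [self.variant_index[v] for v in keep]
        return GenotypeMatrix(self.patients, keep, self.calls[:, idx].copy())


@dataclasses.dataclass
class CohortData:
    """Everything one run needs: patients, calls, annotations, gene index."""

    patients: List[Patient]
    genotypes: GenotypeMatrix
    annotations: Dict[VariantKey, VariantAnnotation]
    gene_index: Dict[str, List[VariantKey]]

    def __post_init__(self):
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate patient ids in cohort")
        for key in self.genotypes.variants:
            if key not in self.annotations:
                raise FormatError(f"variant {key} has no annotation")
        indexed = {v for keys in self.gene_index.values() for v in keys}
        if indexed != set(self.annotations):
            raise FormatError("gene_index does not cover exactly the annotated variants")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def patient_by_id(self) -> Dict[str, Patient]:
        return {p.patient_id: p for p in self.patients}


def _decompose_gt(gt: Optional[tuple], alt_index: int) -> int:
    """Map a pysam GT tuple onto the call code for one alt allele."""
    if gt is None:
        return MISSING
    if any(allele is None for allele in gt):
        return MISSING
    if len(gt) != 2:
        return MISSING
    return min(2, sum(1 for allele in gt if allele == alt_index))


def read_vcf(path) -> GenotypeMatrix:
    """Read a multi-sample VCF into a genotype matrix.

    Multi-allelic records are decomposed into one bi-allelic variant per
    alt allele; phase separators are ignored and any half-call is missing.
    """
    path = str(path)
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if len(set(samples)) != len(samples):
            raise FormatError("duplicate sample id in VCF header")
        if "GT" not in vcf.header.formats:
            raise FormatError("VCF has no GT format field")
        variants: List[VariantKey] = []
        columns: List[np.ndarray] = []
        for rec in vcf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                key = (str(rec.chrom), int(rec.pos), str(rec.ref), str(alt))
                col = np.empty(len(samples), dtype=np.int8)
                for si, sample in enumerate(samples):
                    col[si] = _decompose_gt(rec.samples[sample].get("GT"), ai)
                variants.append(key)
                columns.append(col)
    calls = (np.stack(columns, axis=1) if columns
             else np.empty((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(samples, variants, calls)


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write the matrix back out as a minimal VCF 4.2 text file."""
    code_to_gt = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    contigs = []
    for chrom, _, _, _ in genotypes.variants:
        if chrom not in contigs:
            contigs.append(chrom)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in contigs:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.patients) + "\n")
        for vi, (chrom, pos, ref, alt) in enumerate(genotypes.variants):
            gts = "\t".join(code_to_gt[int(c)] for c in genotypes.calls[:, vi])
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n")


def read_annotations(source) -> Dict[VariantKey, VariantAnnotation]:
    """Read the per-variant annotation TSV.

    An empty ``gnomad_an`` cell marks a variant as not covered in gnomAD
    (it survives loading but is removed by :func:`filter_variants`).
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"annotation TSV missing columns: {missing_cols}")
    annotations: Dict[VariantKey, VariantAnnotation] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header row
        an_text = str(row.gnomad_an).strip()
        covered = an_text != ""
        try:
            ann = VariantAnnotation(
                variant_key=(str(row.chrom), int(row.pos), str(row.ref), str(row.alt)),
                gene_ids={g.strip() for g in str(row.gene).split(",") if g.strip()},
                gnomad_ac=int(row.gnomad_ac) if covered else 0,
                gnomad_an=int(an_text) if covered else 0,
                gnomad_hom=int(row.gnomad_hom) if covered else 0,
                cadd_phred=float(row.cadd_phred),
                filter_status=str(row.filter),
                coding_distance=int(row.coding_distance),
                gnomad_covered=covered,
            )
        except ValueError as exc:
            raise RowValidationError(str(exc), line) from exc
        ann.validate(line=line)
        if not ann.gene_ids:
            raise RowValidationError("empty gene column", line)
        annotations[ann.variant_key] = ann
    return annotations


def write_annotations(annotations: Dict[VariantKey, VariantAnnotation], path) -> None:
    rows = []
    for key in sorted(annotations, key=_variant_sort_key):
        ann = annotations[key]
        rows.append({
            "chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
            "gene": ",".join(sorted(ann.gene_ids)),
            "gnomad_ac": ann.gnomad_ac if ann.gnomad_covered else "",
            "gnomad_an": ann.gnomad_an if ann.gnomad_covered else "",
            "gnomad_hom": ann.gnomad_hom if ann.gnomad_covered else "",
            "cadd_phred": repr(ann.cadd_phred),
            "filter": ann.filter_status,
            "coding_distance": ann.coding_distance,
        })
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def _variant_sort_key(key: VariantKey):
    chrom, pos, ref, alt = key
    return (chrom.rjust(8, "0"), pos, ref, alt)


def read_phenotypes(source, ontology: Optional[HpoOntology] = None) -> List[Patient]:
    """Read the two-column phenotype TSV (patient_id, comma-separated terms).

    Term ids absent from the ontology are dropped per term; patients left
    with no resolvable term are dropped entirely, both with a warning.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    for col in ("patient_id", "hpo_ids"):
        if col not in df.columns:
            raise SchemaError(f"phenotype TSV missing column: {col}")
    patients: List[Patient] = []
    seen: Set[str] = set()
    for row in df.itertuples(index=False):
        pid = str(row.patient_id).strip()
        if pid in seen:
            raise FormatError(f"duplicate patient id {pid!r} in phenotype table")
        seen.add(pid)
        raw_terms = [t.strip() for t in str(row.hpo_ids).split(",") if t.strip()]
        terms: Set[str] = set()
        for term in raw_terms:
            if ontology is None:
                terms.add(term)
            elif term in ontology:
                terms.add(ontology.resolve(term))
            else:
                logger.warning("patient %s: unresolvable term %s ignored", pid, term)
        if not terms:
            logger.warning("patient %s has no resolvable HPO terms; dropped", pid)
            continue
        patients.append(Patient(patient_id=pid, hpo_terms=terms))
    return patients


def write_phenotypes(patients: Sequence[Patient], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient_id\thpo_ids\n")
        for patient in patients:
            fh.write(f"{patient.patient_id}\t{','.join(sorted(patient.hpo_terms))}\n")


def build_gene_index(annotations: Dict[VariantKey, VariantAnnotation]) -> Dict[str, List[VariantKey]]:
    index: Dict[str, List[VariantKey]] = {}
    for key in sorted(annotations, key=_variant_sort_key):
        for gene in annotations[key].gene_ids:
            index.setdefault(gene, []).append(key)
    return index


def load_cohort(vcf_path, annotations_path, phenotypes_path,
                ontology: Optional[HpoOntology] = None) -> CohortData:
    """Assemble a cohort from the three input files.

    Genotyped variants without an annotation row are dropped with a
    warning; missing rates are computed from the genotype matrix.
    """
    genotypes = read_vcf(vcf_path)
    annotations = read_annotations(annotations_path)
    patients = read_phenotypes(phenotypes_path, ontology)
    return assemble_cohort(patients, genotypes, annotations)


def assemble_cohort(patients: List[Patient], genotypes: GenotypeMatrix,
                    annotations: Dict[VariantKey, VariantAnnotation]) -> CohortData:
    for ann in annotations.values():
        ann.validate()
    known = [v for v in genotypes.variants if v in annotations]
    n_dropped = genotypes.n_variants - len(known)
    if n_dropped:
        logger.warning("%d genotyped variants had no annotation; dropped", n_dropped)
        genotypes = genotypes.subset_variants(known)
    annotations = {k: v for k, v in annotations.items() if k in genotypes.variant_index}
    rates = genotypes.missing_rates()
    for key, ann in annotations.items():
        if ann.missing_rate is None:
            ann.missing_rate = float(rates[genotypes.variant_index[key]])
    return CohortData(
        patients=patients,
        genotypes=genotypes,
        annotations=annotations,
        gene_index=build_gene_index(annotations),
    )


def filter_variants(cohort: CohortData, config: GenonConfig) -> CohortData:
    """Apply the variant filters and return a new cohort.

    A variant is retained iff it passes the caller filter, is covered in
    gnomAD, lies within ``coding_distance_max`` bp of a coding region, and
    has per-cohort missingness strictly below ``missing_rate_max``.
    """
    rates = cohort.genotypes.missing_rates()
    removed = {"filter_status": 0, "gnomad_uncovered": 0, "non_coding": 0, "missingness": 0}
    keep: List[VariantKey] = []
    for key in cohort.genotypes.variants:
        ann = cohort.annotations[key]
        rate = ann.missing_rate
        if rate is None:
            rate = float(rates[cohort.genotypes.variant_index[key]])
        ok = True
        if ann.filter_status != "PASS":
            removed["filter_status"] += 1
            ok = False
        if not (ann.gnomad_covered and ann.gnomad_an > 0):
            removed["gnomad_uncovered"] += 1
            ok = False
        if ann.coding_distance > config.coding_distance_max:
            removed["non_coding"] += 1
            ok = False
        if rate >= config.missing_rate_max:
            removed["missingness"] += 1
            ok = False
        if ok:
            keep.append(key)
    logger.info("variant filter: kept %d of %d (removed per rule: %s)",
                len(keep), cohort.genotypes.n_variants, removed)
    if not keep:
        logger.warning("variant filter removed every variant")
    genotypes = cohort.genotypes.subset_variants(keep)
    annotations = {k: dataclasses.replace(cohort.annotations[k]) for k in keep}
    rates = genotypes.missing_rates()
    for key, ann in annotations.items():
        if ann.missing_rate is None:
            ann.missing_rate = float(rates[genotypes.variant_index[key]])
    return CohortData(
        patients=list(cohort.patients),
        genotypes=genotypes,
        annotations=annotations,
        gene_index=build_gene_index(annotations),
    )
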