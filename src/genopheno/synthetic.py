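"""Self-contained synthetic cohorts with planted gene-phenotype associations.

Generates an ontology, phenotypes, genotypes, gnomAD-style annotations and
a truth set that exhibit the statistical structure the screening method
assumes: rare, high-CADD causal variants enriched in term carriers under a
planted mode of inheritance, on top of Hardy-Weinberg background noise.

gnomAD fields are derived deterministically from the simulated allele
frequency (rather than resampled) so genotype-frequency binning is exactly
controllable in tests.  Planted carrier counts are exact, not expected.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cohort import (CohortData, GenotypeMatrix, Patient, VariantAnnotation,
                     VariantKey, assemble_cohort, write_annotations,
                     write_phenotypes, write_vcf)
from .config import DOMINANT, MOIS, RECESSIVE
from .errors import ParameterError
from .ontology import HpoOntology, HpoTerm, write_obo
from .screen import TruthRecord, write_truth

logger = logging.getLogger(__name__)

#: allele-frequency mixture components: name -> (low, high), sampled log-uniformly
AF_RANGES = {
    "rare": (1e-6, 2e-4),
    "low": (2e-4, 1e-3),
    "common": (1e-3, 1e-2),
}


@dataclasses.dataclass(frozen=True)
class PlantedAssociation:
    """One causal gene-term-MOI relationship realised exactly in the cohort."""

    gene: str
    #: ontology term carried by affected patients; ``None`` picks the next
    #: free leaf term of the simulated ontology (ids are seed-dependent)
    term_id: Optional[str]
    moi: str
    n_carriers_in_cases: int
    causal_cadd_range: Tuple[float, float] = (25.0, 35.0)
    causal_gf: float = 1e-4
    penetrance: float = 1.0
    phenocopy_rate: float = 0.0
    #: gnomAD allele frequency of the causal variants; defaults to causal_gf
    #: for dominant plants and 2e-3 (a realistic carrier frequency) for
    #: recessive plants, whose genotype frequency is governed by HOM instead.
    causal_allele_frequency: Optional[float] = None
    n_causal_variants: int = 2
    #: optional common-variant contamination: a GF ~ contaminant_af variant
    #: with het carriers enriched in cases, stressing the signal ratio.
    contaminant_af: Optional[float] = None
    contaminant_cadd: float = 30.0
    contaminant_case_hets: int = 0

    def __post_init__(self):
        if self.moi not in MOIS:
            raise ParameterError(f"planted MOI must be one of {MOIS}")
        if not (0 < self.causal_gf < 0.00025):
            raise ParameterError("causal_gf must lie below the rare threshold 0.00025")
        if not (0.0 <= self.penetrance <= 1.0 and 0.0 <= self.phenocopy_rate <= 1.0):
            raise ParameterError("penetrance and phenocopy_rate must lie in [0, 1]")
        if self.n_causal_variants < 1 or (self.moi == RECESSIVE and self.n_causal_variants < 2):
            raise ParameterError("recessive plants need >= 2 causal variants")

    @property
    def allele_frequency(self) -> float:
        if self.causal_allele_frequency is not None:
            return self.causal_allele_frequency
        return self.causal_gf if self.moi == DOMINANT else 2e-3


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    n_patients: int = 500
    n_background_genes: int = 50
    variants_per_gene: float = 8.0
    af_spectrum: Tuple[float, float, float] = (0.5, 0.3, 0.2)  # rare, low, common
    cadd_benign: Tuple[float, float] = (8.0, 4.0)    # mean, sd
    cadd_damaging: Tuple[float, float] = (28.0, 5.0)
    cadd_damaging_prob: float = 0.25
    planted: Tuple[PlantedAssociation, ...] = ()
    missing_rate_range: Tuple[float, float] = (0.0, 0.1)
    gnomad_an: int = 2 * 250_000
    prob_fail_filter: float = 0.02
    prob_noncoding: float = 0.02
    ontology_depth: int = 3
    ontology_branching: int = 3
    terms_per_patient: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ParameterError("n_patients must be >= 2")
        if abs(sum(self.af_spectrum) - 1.0) > 1e-9:
            raise ParameterError("af_spectrum weights must sum to 1")
        if any(w < 0 for w in self.af_spectrum):
            raise ParameterError("af_spectrum weights must be non-negative")
        lo, hi = self.missing_rate_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ParameterError("missing_rate_range must be within [0, 1]")
        for plant in self.planted:
            if plant.n_carriers_in_cases > self.n_patients:
                raise ParameterError(
                    f"plant in {plant.gene}: {plant.n_carriers_in_cases} carriers "
                    f"exceed {self.n_patients} patients")


@dataclasses.dataclass
class SimulatedCohort:
    cohort: CohortData
    ontology: HpoOntology
    obo_text: str
    truth: List[TruthRecord]
    params: SimulationParams
    planted_carriers: Dict[Tuple[str, str], List[str]]


def simulate_ontology(depth: int, branching: int, seed: int) -> Tuple[HpoOntology, str]:
    """Balanced is_a tree: 1 + b + b^2 + ... + b^(depth-1) terms.

    Term ids are drawn from a seeded generator, so two seeds give the same
    topology with different labels.
    """
    if depth < 2:
        raise ParameterError("ontology depth must be >= 2")
    if branching < 1:
        raise ParameterError("ontology branching must be >= 1")
    rng = np.random.default_rng(seed)
    n_terms = sum(branching ** level for level in range(depth))
    ids: List[int] = []
    seen = set()
    while len(ids) < n_terms:
        for value in rng.integers(1, 10_000_000, size=2 * n_terms + 8):
            value = int(value)
            if value not in seen:
                seen.add(value)
                ids.append(value)
                if len(ids) == n_terms:
                    break
    term_ids = [f"HP:{i:07d}" for i in ids]
    terms: Dict[str, HpoTerm] = {}
    terms[term_ids[0]] = HpoTerm(term_id=term_ids[0], name="synthetic root")
    level_start = 0
    level_size = 1
    next_index = 1
    counter = 0
    for _ in range(depth - 1):
        parents = term_ids[level_start:level_start + level_size]
        for parent in parents:
            for _ in range(branching):
                tid = term_ids[next_index]
                counter += 1
                terms[tid] = HpoTerm(term_id=tid, name=f"synthetic term {counter}",
                                     parent_ids={parent})
                next_index += 1
        level_start += level_size
        level_size *= branching
    ontology = HpoOntology(terms)
    return ontology, write_obo(ontology)


def _truncated_normal(rng, mean, sd, low, high, size):
    values = rng.normal(mean, sd, size=size)
    return np.clip(values, low, high)


def simulate_cohort(params: SimulationParams) -> SimulatedCohort:
    """Realise a full cohort; deterministic for a fixed seed."""
    ontology, obo_text = simulate_ontology(params.ontology_depth,
                                           params.ontology_branching, params.seed)
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    patient_ids = [f"P{i:05d}" for i in range(n)]
    an = params.gnomad_an

    gene_names = [f"G{i:04d}" for i in range(1, params.n_background_genes + 1)]
    n_var_per_gene = np.maximum(1, rng.poisson(params.variants_per_gene,
                                               size=len(gene_names)))

    keys: List[VariantKey] = []
    genes_of: List[str] = []
    afs: List[float] = []
    cadds: List[float] = []
    for gi, gene in enumerate(gene_names):
        chrom = str(gi % 22 + 1)
        base = (gi + 1) * 1_000_000
        for vi in range(int(n_var_per_gene[gi])):
            keys.append((chrom, base + vi * 50 + 1, "A", "T"))
            genes_of.append(gene)
            component = rng.choice(3, p=params.af_spectrum)
            lo, hi = list(AF_RANGES.values())[component]
            afs.append(float(np.exp(rng.uniform(math.log(lo), math.log(hi)))))
            if rng.random() < params.cadd_damaging_prob:
                mean, sd = params.cadd_damaging
            else:
                mean, sd = params.cadd_benign
            cadds.append(float(_truncated_normal(rng, mean, sd, 0.0, 39.999, None)))

    af_arr = np.array(afs)
    calls = rng.binomial(2, np.broadcast_to(af_arr, (n, len(afs)))).astype(np.int8)

    fail_filter = rng.random(len(afs)) < params.prob_fail_filter
    noncoding = rng.random(len(afs)) < params.prob_noncoding
    coding_distance = np.where(noncoding, rng.integers(6, 500, size=len(afs)), 0)

    lo_miss, hi_miss = params.missing_rate_range
    miss_rate = rng.uniform(lo_miss, hi_miss, size=len(afs))
    miss_mask = rng.random((n, len(afs))) < miss_rate
    calls[miss_mask] = -1

    # a cohort VCF only contains variants somebody actually carries
    observed = np.nonzero((calls > 0).any(axis=0))[0]
    calls = calls[:, observed]
    keys = [keys[j] for j in observed]
    genes_of = [genes_of[j] for j in observed]
    cadds = [cadds[j] for j in observed]
    af_arr = af_arr[observed]
    fail_filter = fail_filter[observed]
    coding_distance = coding_distance[observed]

    annotations: Dict[VariantKey, VariantAnnotation] = {}
    for j, key in enumerate(keys):
        ac = max(1, int(round(af_arr[j] * an)))
        hom = min(int(round(af_arr[j] ** 2 * an / 2.0)), ac // 2)
        annotations[key] = VariantAnnotation(
            variant_key=key, gene_ids={genes_of[j]},
            gnomad_ac=ac, gnomad_an=an, gnomad_hom=hom,
            cadd_phred=float(cadds[j]),
            filter_status="LOWQUAL" if fail_filter[j] else "PASS",
            coding_distance=int(coding_distance[j]),
        )

    # resolve planted terms before assigning background phenotypes: the
    # planted term's case set must be governed only by penetrance and
    # phenocopy_rate, so background draws exclude the planted terms
    leaves = sorted(t for t in ontology.terms
                    if not ontology.children(t) and t != ontology.root_id)
    plants: List[PlantedAssociation] = []
    for plant_index, plant in enumerate(params.planted):
        if plant.term_id in (None, ""):
            if not leaves:
                raise ParameterError("ontology has no leaf terms to plant on")
            plant = dataclasses.replace(plant,
                                        term_id=leaves[plant_index % len(leaves)])
        if plant.term_id not in ontology:
            raise ParameterError(f"planted term {plant.term_id} not in ontology")
        plants.append(plant)
    planted_terms = {p.term_id for p in plants}

    background_pool = sorted(t for t in ontology.terms
                             if t != ontology.root_id and t not in planted_terms)
    patient_terms: List[set] = []
    for _ in range(n):
        draws = rng.choice(len(background_pool), size=params.terms_per_patient,
                           replace=True)
        patient_terms.append({background_pool[d] for d in draws})

    extra_cols: List[np.ndarray] = []
    extra_keys: List[VariantKey] = []
    truth: List[TruthRecord] = []
    planted_carriers: Dict[Tuple[str, str], List[str]] = {}
    plant_pos = 100_000_000

    for plant in plants:
        if plant.gene in gene_names:
            chrom = str(gene_names.index(plant.gene) % 22 + 1)
        else:
            gene_names.append(plant.gene)
            chrom = str((len(gene_names) - 1) % 22 + 1)
        carriers = rng.choice(n, size=plant.n_carriers_in_cases, replace=False)
        carriers = np.sort(carriers)
        planted_carriers[(plant.gene, plant.term_id)] = [patient_ids[i] for i in carriers]

        causal_af = plant.allele_frequency
        causal_ac = max(1, int(round(causal_af * an)))
        # one CADD value per plant: equal-scoring causal variants anchor each
        # other under the compound-het rule, so carriers share a single bin
        causal_cadds = np.full(plant.n_causal_variants,
                               rng.uniform(*plant.causal_cadd_range))
        causal_cols = []
        for cv in range(plant.n_causal_variants):
            key = (chrom, plant_pos, "A", "T")
            plant_pos += 50
            if plant.moi == DOMINANT:
                # GF (allele frequency) must stay below the rare threshold
                ac = max(1, int(round(plant.causal_gf * an)))
                hom = 0
            else:
                ac = causal_ac
                hom = 0  # ultra-rare convention: no homozygotes observed
            annotations[key] = VariantAnnotation(
                variant_key=key, gene_ids={plant.gene},
                gnomad_ac=ac, gnomad_an=an, gnomad_hom=hom,
                cadd_phred=float(causal_cadds[cv]),
                filter_status="PASS", coding_distance=0,
            )
            if plant.moi == RECESSIVE:
                col = rng.binomial(2, causal_af, size=n).astype(np.int8)
                col[col == 2] = 1  # background homozygotes would fake biallelism
            else:
                col = np.zeros(n, dtype=np.int8)
            extra_keys.append(key)
            causal_cols.append(col)

        if plant.moi == RECESSIVE:
            # exactly the chosen carriers are biallelic (compound het on the
            # first two causal variants); strip accidental second hits
            for ci in range(1, len(causal_cols)):
                both = (causal_cols[0] >= 1) & (causal_cols[ci] >= 1)
                causal_cols[ci][both] = 0
            causal_cols[0][carriers] = 1
            causal_cols[1][carriers] = 1
        else:
            for idx, patient in enumerate(carriers):
                causal_cols[idx % len(causal_cols)][patient] = 1

        # phenotype assignment: penetrance among carriers, phenocopies outside
        carrier_set = set(int(i) for i in carriers)
        for i in range(n):
            if i in carrier_set:
                if rng.random() < plant.penetrance:
                    patient_terms[i].add(plant.term_id)
            elif rng.random() < plant.phenocopy_rate:
                patient_terms[i].add(plant.term_id)

        if plant.contaminant_af is not None:
            key = (chrom, plant_pos, "A", "T")
            plant_pos += 50
            caf = plant.contaminant_af
            ac = int(round(caf * an))
            hom = min(int(round(caf ** 2 * an / 2.0)), ac // 2)
            annotations[key] = VariantAnnotation(
                variant_key=key, gene_ids={plant.gene},
                gnomad_ac=ac, gnomad_an=an, gnomad_hom=hom,
                cadd_phred=float(plant.contaminant_cadd),
                filter_status="PASS", coding_distance=0,
            )
            col = rng.binomial(2, caf, size=n).astype(np.int8)
            closure = ontology.descendants(plant.term_id)
            case_idx = [i for i in range(n) if patient_terms[i] & closure]
            ordered = ([i for i in case_idx if i in carrier_set]
                       + [i for i in case_idx if i not in carrier_set])
            for i in ordered[:plant.contaminant_case_hets]:
                col[i] = max(col[i], 1)
            extra_keys.append(key)
            causal_cols.append(col)

        truth.append(TruthRecord(gene=plant.gene, term_id=plant.term_id, moi=plant.moi))
        extra_cols.extend(causal_cols)

    if extra_cols:
        calls = np.concatenate([calls, np.stack(extra_cols, axis=1)], axis=1)
        keys = keys + extra_keys

    patients = [Patient(patient_id=pid, hpo_terms=set(terms) or {ontology.root_id})
                for pid, terms in zip(patient_ids, patient_terms)]
    genotypes = GenotypeMatrix(patient_ids, keys, calls)
    cohort = assemble_cohort(patients, genotypes, annotations)
    return SimulatedCohort(cohort=cohort, ontology=ontology, obo_text=obo_text,
                           truth=truth, params=params,
                           planted_carriers=planted_carriers)


def write_simulation(sim: SimulatedCohort, outdir) -> Dict[str, str]:
    """Write the five cohort files plus a parameter manifest; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "annotations": outdir / "annotations.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "obo": outdir / "ontology.obo",
        "truth": outdir / "truth.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_vcf(sim.cohort.genotypes, paths["vcf"])
    write_annotations(sim.cohort.annotations, paths["annotations"])
    write_phenotypes(sim.cohort.patients, paths["phenotypes"])
    with open(paths["obo"], "w", encoding="utf-8") as fh:
        fh.write(sim.obo_text)
    write_truth(sim.truth, paths["truth"])
    manifest = {"params": params_to_dict(sim.params), "seed": sim.params.seed}
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}


def params_to_dict(params: SimulationParams) -> dict:
    d = dataclasses.asdict(params)
    d["planted"] = [dataclasses.asdict(p) for p in params.planted]
    return d


def params_from_dict(data: dict) -> SimulationParams:
    data = dict(data)
    plants = []
    for p in data.get("planted", []) or []:
        q = dict(p)
        for key in ("causal_cadd_range",):
            if key in q and q[key] is not None:
                q[key] = tuple(q[key])
        plants.append(PlantedAssociation(**q))
    data["planted"] = tuple(plants)
    for key in ("af_spectrum", "cadd_benign", "cadd_damaging", "missing_rate_range"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return SimulationParams(**data)
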