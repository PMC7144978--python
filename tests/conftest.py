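import logging

import numpy as np
import pytest

from genopheno.cohort import (GenotypeMatrix, Patient, VariantAnnotation,
                              assemble_cohort)
from genopheno.config import GenonConfig
from genopheno.ontology import parse_obo

logging.getLogger("genopheno").setLevel(logging.ERROR)
for name in ("genopheno.scoring", "genopheno.screen", "genopheno.genon",
             "genopheno.cohort", "genopheno.ontology", "genopheno.synthetic"):
    logging.getLogger(name).setLevel(logging.ERROR)

SMALL_OBO = """\
format-version: 1.2

[Term]
id: HP:0000001
name: All

[Term]
id: HP:0000002
name: branch A
is_a: HP:0000001 ! All

[Term]
id: HP:0000003
name: leaf B under A
is_a: HP:0000002

[Term]
id: HP:0000004
name: branch C
is_a: HP:0000001

[Term]
id: HP:0000005
name: old name
is_obsolete: true
replaced_by: HP:0000002
"""


@pytest.fixture(scope="session")
def small_ontology():
    return parse_obo(SMALL_OBO)


@pytest.fixture
def config():
    return GenonConfig()


def build_cohort(patients, variant_specs, calls):
    """Assemble a cohort from plain dicts.

    ``patients``: {patient_id: set of term ids}
    ``variant_specs``: list of dicts with keys chrom,pos,ref,alt,gene,ac,an,
        hom,cadd and optional filter,coding_distance
    ``calls``: (n_patients, n_variants) array-like of {-1,0,1,2}
    """
    patient_objs = [Patient(pid, set(terms)) for pid, terms in patients.items()]
    keys = []
    annotations = {}
    for spec in variant_specs:
        key = (str(spec["chrom"]), int(spec["pos"]), spec.get("ref", "A"),
               spec.get("alt", "T"))
        keys.append(key)
        annotations[key] = VariantAnnotation(
            variant_key=key,
            gene_ids={spec["gene"]} if isinstance(spec["gene"], str) else set(spec["gene"]),
            gnomad_ac=int(spec["ac"]),
            gnomad_an=int(spec["an"]),
            gnomad_hom=int(spec.get("hom", 0)),
            cadd_phred=float(spec["cadd"]),
            filter_status=spec.get("filter", "PASS"),
            coding_distance=int(spec.get("coding_distance", 0)),
        )
    matrix = GenotypeMatrix(list(patients), keys, np.asarray(calls, dtype=np.int8))
    return assemble_cohort(patient_objs, matrix, annotations)


@pytest.fixture
def tiny_cohort(small_ontology):
    """10 cases of HP:0000003 (leaf), 100 controls; one rare damaging variant
    in GENE1 carried by 3 cases and 1 control; one common benign variant."""
    patients = {}
    calls = []
    for i in range(110):
        pid = f"P{i:03d}"
        patients[pid] = {"HP:0000003"} if i < 10 else {"HP:0000004"}
        carrier = i in (0, 1, 2, 10)  # 3 cases + 1 control
        calls.append([1 if carrier else 0, 1 if i % 2 else 0])
    variant_specs = [
        dict(chrom="1", pos=100, gene="GENE1", ac=5, an=100000, hom=0, cadd=30.0),
        dict(chrom="1", pos=200, gene="GENE1", ac=5000, an=1000000, hom=12,
             cadd=2.0),
    ]
    return build_cohort(patients, variant_specs, calls)
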