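"""Heatmap engine: genotype-frequency binning, carriers, per-bin Fisher tests.

A heatmap for one (gene, HPO term, mode-of-inheritance) triple bins the
gene's variants on genotype frequency (GF) x CADD, identifies per-bin
patient carriers (with compound-heterozygote logic under the recessive
model), and applies a one-sided Fisher exact test for case enrichment in
every non-empty bin.
"""

from __future__ import annotations

import json
import logging
import math
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .config import DOMINANT, GF_HOMOZYGOTE, MOIS, RECESSIVE, GenonConfig
from .cohort import CohortData, VariantAnnotation, VariantKey
from .errors import (GenophenoError, UndefinedFrequencyError, UnknownGeneError)
from .ontology import HpoOntology, split_cases

logger = logging.getLogger(__name__)

EXCLUDED = None  # sentinel returned by assign_bin for GF >= gf_max


def genotype_frequency(ann: VariantAnnotation, moi: str,
                       convention: str = GF_HOMOZYGOTE) -> float:
    """MOI-dependent genotype frequency from gnomAD counts.

    Dominant: allele frequency AC/AN.  Recessive: estimated homozygote
    frequency 2*HOM/AN, unless ``convention`` selects the allele-frequency
    comparator, in which case AC/AN is used for both branches.
    """
    if moi not in MOIS:
        raise GenophenoError(f"unknown mode of inheritance {moi!r}")
    if ann.gnomad_an <= 0:
        raise UndefinedFrequencyError(
            f"variant {ann.variant_key} has gnomad_an == 0 (should have been filtered)")
    if moi == DOMINANT or convention != GF_HOMOZYGOTE:
        return ann.gnomad_ac / ann.gnomad_an
    return 2.0 * ann.gnomad_hom / ann.gnomad_an


def assign_bin(gf: float, cadd: float, config: GenonConfig):
    """Map (GF, CADD) onto a (cadd_row, gf_col) half-open-interval bin.

    Returns ``EXCLUDED`` (None) when gf >= gf_max; CADD values at or above
    cadd_max clamp into the top CADD row.  Column 0 is the rare column.
    """
    if gf < 0 or cadd < 0:
        raise GenophenoError("gf and cadd must be non-negative")
    if gf >= config.gf_max:
        return EXCLUDED
    col = int(gf / config.gf_bin_width)
    col = min(col, config.n_gf_cols - 1)
    row = int(cadd / config.cadd_bin_height)
    row = min(row, config.n_cadd_rows - 1)
    return (row, col)


def bin_fisher(case_carriers: int, n_cases: int,
               control_carriers: int, n_controls: int) -> float:
    """One-sided (enrichment-in-cases) Fisher exact p for the 2x2 table
    [[a, n_cases - a], [c, n_controls - c]].

    Equals the hypergeometric upper tail P(X >= a) with N = n_cases +
    n_controls, K = a + c carriers, drawing n_cases patients.
    """
    a, c = int(case_carriers), int(control_carriers)
    if a < 0 or c < 0 or n_cases < 0 or n_controls < 0:
        raise GenophenoError("counts must be non-negative")
    if a > n_cases or c > n_controls:
        raise GenophenoError("carrier counts exceed group sizes")
    if n_cases + n_controls == 0:
        raise GenophenoError("empty cohort")
    if a == 0:
        return 1.0
    p = float(stats.hypergeom.sf(a - 1, n_cases + n_controls, a + c, n_cases))
    return min(1.0, max(p, 5e-324))


def _fisher_batch(a: np.ndarray, c: np.ndarray, n_cases: int, n_controls: int) -> np.ndarray:
    a = np.asarray(a, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    p = stats.hypergeom.sf(a - 1, n_cases + n_controls, a + c, n_cases)
    p = np.clip(p, 5e-324, 1.0)
    p[a == 0] = 1.0
    return p


def z_from_p(p, config: GenonConfig):
    """z = Phi^-1(1 - p), with p clipped to keep z finite."""
    lo, hi = config.p_clip
    return stats.norm.isf(np.clip(p, lo, hi))


class BinCell:
    """One non-empty GF x CADD bin of a heatmap."""

    __slots__ = ("cadd_row", "gf_col", "variant_keys", "_case_idx", "_control_idx",
                 "_patients", "p_value", "z_score")

    def __init__(self, cadd_row: int, gf_col: int, variant_keys: Tuple[VariantKey, ...],
                 case_idx: np.ndarray, control_idx: np.ndarray,
                 patients: Sequence[str], p_value: float, z_score: float):
        self.cadd_row = cadd_row
        self.gf_col = gf_col
        self.variant_keys = tuple(variant_keys)
        self._case_idx = case_idx
        self._control_idx = control_idx
        self._patients = patients
        self.p_value = p_value
        self.z_score = z_score

    @property
    def is_rare(self) -> bool:
        return self.gf_col == 0

    @property
    def n_case_carriers(self) -> int:
        return int(self._case_idx.size)

    @property
    def n_control_carriers(self) -> int:
        return int(self._control_idx.size)

    @property
    def case_carriers(self) -> frozenset:
        return frozenset(self._patients[i] for i in self._case_idx)

    @property
    def control_carriers(self) -> frozenset:
        return frozenset(self._patients[i] for i in self._control_idx)

    def __repr__(self):
        return (f"BinCell(row={self.cadd_row}, col={self.gf_col}, "
                f"n_variants={len(self.variant_keys)}, "
                f"a={self.n_case_carriers}, c={self.n_control_carriers}, "
                f"p={self.p_value:.3g})")


class GenonHeatmap:
    """Full bin grid for one (gene, term, MOI) with rare/non-rare bookkeeping."""

    def __init__(self, gene: str, term_id: str, moi: str, cells: List[BinCell],
                 n_cases: int, n_controls: int, config: GenonConfig):
        self.gene = gene
        self.term_id = term_id
        self.moi = moi
        self.cells = sorted(cells, key=lambda cell: (cell.cadd_row, cell.gf_col))
        self.n_cases = n_cases
        self.n_controls = n_controls
        self.config = config

    @property
    def k_rare(self) -> int:
        return sum(1 for cell in self.cells if cell.is_rare)

    @property
    def k_nonrare(self) -> int:
        return sum(1 for cell in self.cells if not cell.is_rare)

    @property
    def is_empty(self) -> bool:
        return not self.cells

    def rare_cells(self) -> List[BinCell]:
        return [cell for cell in self.cells if cell.is_rare]

    def nonrare_cells(self) -> List[BinCell]:
        return [cell for cell in self.cells if not cell.is_rare]

    def to_records(self) -> List[dict]:
        config = self.config
        return [{
            "cadd_row_low": cell.cadd_row * config.cadd_bin_height,
            "gf_col_low": cell.gf_col * config.gf_bin_width,
            "n_variants": len(cell.variant_keys),
            "case_carriers": cell.n_case_carriers,
            "control_carriers": cell.n_control_carriers,
            "p": cell.p_value,
            "z": cell.z_score,
            "minus_ln_p": -math.log(cell.p_value),
        } for cell in self.cells]

    def to_tsv(self, path) -> None:
        columns = ["cadd_row_low", "gf_col_low", "n_variants", "case_carriers",
                   "control_carriers", "p", "z", "minus_ln_p"]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(columns) + "\n")
            for rec in self.to_records():
                fh.write("\t".join(repr(rec[c]) if isinstance(rec[c], float)
                                   else str(rec[c]) for c in columns) + "\n")

    def to_json_obj(self) -> dict:
        return {
            "gene": self.gene,
            "term_id": self.term_id,
            "moi": self.moi,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "k_rare": self.k_rare,
            "k_nonrare": self.k_nonrare,
            "cells": self.to_records(),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_obj(), fh, indent=1, sort_keys=True)
            fh.write("\n")


class GeneLayout:
    """Term-independent binning of one gene under one MOI.

    Caches, per non-empty bin, the member variants and the boolean carrier
    mask over the cohort's patient ordering; a heatmap for any term is then
    an intersection of these masks with the term's case mask.
    """

    __slots__ = ("gene", "moi", "cells")

    def __init__(self, gene: str, moi: str,
                 cells: List[Tuple[int, int, Tuple[VariantKey, ...], np.ndarray]]):
        self.gene = gene
        self.moi = moi
        self.cells = cells  # (row, col, variant_keys, carrier_mask)


def _recessive_carrier_matrix(calls: np.ndarray, cadds: np.ndarray,
                              gfs: np.ndarray) -> np.ndarray:
    """Per (patient, gene-variant) recessive qualification matrix.

    A patient qualifies via variant v if hom-alt at v, or het at v with a
    het/hom call at a distinct variant u of the same gene having
    cadd(u) >= cadd(v) and GF(u) <= GF(v).  Phase is not assessed.
    """
    het = calls == 1
    alt = calls >= 1
    hom = calls == 2
    m = calls.shape[1]
    out = hom.copy()
    for j in range(m):
        eligible = (cadds >= cadds[j]) & (gfs <= gfs[j])
        eligible[j] = False
        if eligible.any():
            partner = alt[:, eligible].any(axis=1)
            out[:, j] |= het[:, j] & partner
    return out


def gene_layout(cohort: CohortData, gene: str, moi: str,
                config: GenonConfig) -> GeneLayout:
    """Bin a gene's variants and compute per-bin carrier masks."""
    if gene not in cohort.gene_index:
        raise UnknownGeneError(f"gene {gene!r} not in cohort gene index")
    keys = cohort.gene_index[gene]
    gidx = np.array([cohort.genotypes.variant_index[k] for k in keys], dtype=np.int64)
    anns = [cohort.annotations[k] for k in keys]
    gfs = np.array([genotype_frequency(a, moi, config.gf_convention) for a in anns])
    cadds = np.array([a.cadd_phred for a in anns])
    bins = [assign_bin(gf, cadd, config) for gf, cadd in zip(gfs, cadds)]

    calls = cohort.genotypes.calls[:, gidx]
    if moi == RECESSIVE:
        qualifies = _recessive_carrier_matrix(calls, cadds, gfs)
    else:
        qualifies = calls >= 1

    grouped: Dict[Tuple[int, int], List[int]] = {}
    for j, b in enumerate(bins):
        if b is not EXCLUDED:
            grouped.setdefault(b, []).append(j)
    cells = []
    for (row, col), js in sorted(grouped.items()):
        mask = qualifies[:, js].any(axis=1)
        # a bin is non-empty when somebody qualifies as a carrier; under the
        # recessive model most variant-bearing bins have no biallelic carrier
        # and contribute no evidence, so they are never materialised
        if mask.any():
            cells.append((row, col, tuple(keys[j] for j in js), mask))
    return GeneLayout(gene, moi, cells)


def find_carriers(cohort: CohortData, gene: str, cell_variants: Iterable[VariantKey],
                  moi: str, config: GenonConfig) -> Set[str]:
    """Patient ids qualifying as carriers of a bin's variants under ``moi``.

    Dominant: any non-missing het/hom call on a cell variant.  Recessive:
    hom-alt on a cell variant, or het plus a second qualifying variant
    anywhere in the gene (compound heterozygote, presumed in trans).
    """
    if gene not in cohort.gene_index:
        raise UnknownGeneError(f"gene {gene!r} not in cohort gene index")
    cell_variants = set(cell_variants)
    keys = cohort.gene_index[gene]
    unknown = cell_variants - set(keys)
    if unknown:
        raise GenophenoError(f"cell variants not in gene {gene}: {sorted(unknown)}")
    gidx = np.array([cohort.genotypes.variant_index[k] for k in keys], dtype=np.int64)
    anns = [cohort.annotations[k] for k in keys]
    gfs = np.array([genotype_frequency(a, moi, config.gf_convention) for a in anns])
    cadds = np.array([a.cadd_phred for a in anns])
    calls = cohort.genotypes.calls[:, gidx]
    if moi == RECESSIVE:
        qualifies = _recessive_carrier_matrix(calls, cadds, gfs)
    else:
        qualifies = calls >= 1
    js = [j for j, k in enumerate(keys) if k in cell_variants]
    mask = qualifies[:, js].any(axis=1)
    patients = cohort.genotypes.patients
    return {patients[i] for i in np.nonzero(mask)[0]}


def case_mask_for_term(cohort: CohortData, ontology: HpoOntology, term_id) -> np.ndarray:
    """Boolean case mask over the genotype matrix's patient ordering."""
    cases, _ = split_cases(ontology, cohort.patients, term_id)
    patients = cohort.genotypes.patients
    mask = np.zeros(len(patients), dtype=bool)
    for i, pid in enumerate(patients):
        if pid in cases:
            mask[i] = True
    return mask


def heatmap_from_layout(layout: GeneLayout, case_mask: np.ndarray,
                        patients: Sequence[str], term_id: str,
                        config: GenonConfig) -> GenonHeatmap:
    n_cases = int(case_mask.sum())
    n_controls = int(case_mask.size - n_cases)
    cells: List[BinCell] = []
    if layout.cells:
        a = np.array([int((m & case_mask).sum()) for (_, _, _, m) in layout.cells])
        totals = np.array([int(m.sum()) for (_, _, _, m) in layout.cells])
        c = totals - a
        p = _fisher_batch(a, c, n_cases, n_controls)
        z = z_from_p(p, config)
        for (row, col, keys, mask), pv, zv in zip(layout.cells, p, z):
            case_idx = np.nonzero(mask & case_mask)[0]
            control_idx = np.nonzero(mask & ~case_mask)[0]
            cells.append(BinCell(row, col, keys, case_idx, control_idx,
                                 patients, float(pv), float(zv)))
    return GenonHeatmap(layout.gene, term_id, layout.moi, cells,
                        n_cases, n_controls, config)


def build_heatmap(cohort: CohortData, ontology: HpoOntology, gene: str,
                  term_id, moi: str, config: GenonConfig,
                  layout: Optional[GeneLayout] = None,
                  case_mask: Optional[np.ndarray] = None) -> GenonHeatmap:
    """Build the full heatmap for one (gene, term, MOI) triple.

    ``layout`` and ``case_mask`` may be supplied to reuse work across
    terms/genes; they must derive from the same cohort and config.
    """
    if layout is None:
        layout = gene_layout(cohort, gene, moi, config)
    if case_mask is None:
        case_mask = case_mask_for_term(cohort, ontology, term_id)
    term_label = term_id if isinstance(term_id, str) else "&".join(term_id)
    heatmap = heatmap_from_layout(layout, case_mask, cohort.genotypes.patients,
                                  term_label, config)
    if heatmap.is_empty:
        logger.debug("gene %s has no binned variants under %s; empty heatmap",
                       gene, moi)
    return heatmap
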