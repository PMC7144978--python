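"""Cohort-wide screening, positive-term selection and truth-set benchmarking."""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import statistics
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .config import DOMINANT, GF_ALLELE, RECESSIVE, GenonConfig
from .cohort import CohortData
from .errors import SchemaError
from .genon import (GeneLayout, build_heatmap, case_mask_for_term, gene_layout,
                    heatmap_from_layout)
from .ontology import HpoOntology
from .scoring import (UNDETERMINED, GenonResult, hgf_only_moi,
                      score_from_heatmaps, sort_results)

logger = logging.getLogger(__name__)

MODELS = ("phenogenon", "fisher_method", "hgf_only", "recessive_af")

XLINKED = "x-linked"
VALID_TRUTH_MOI = (DOMINANT, RECESSIVE, XLINKED)


@dataclasses.dataclass(frozen=True)
class TruthRecord:
    """One hand-curated known gene-term-MOI relationship."""

    gene: str
    term_id: str
    moi: str


def read_truth(source) -> List[TruthRecord]:
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "hpo_id", "moi"):
        if col not in df.columns:
            raise SchemaError(f"truth TSV missing column: {col}")
    records = []
    seen = set()
    for row in df.itertuples(index=False):
        moi = str(row.moi).strip().lower()
        if moi not in VALID_TRUTH_MOI:
            raise SchemaError(f"truth MOI must be one of {VALID_TRUTH_MOI}, got {moi!r}")
        key = (row.gene, row.hpo_id)
        if key in seen:
            raise SchemaError(f"duplicate truth record for {key}")
        seen.add(key)
        records.append(TruthRecord(gene=str(row.gene), term_id=str(row.hpo_id), moi=moi))
    return records


def write_truth(records: Sequence[TruthRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\thpo_id\tmoi\n")
        for rec in records:
            fh.write(f"{rec.gene}\t{rec.term_id}\t{rec.moi}\n")


# ---------------------------------------------------------------------------
# per-pair scoring


def _np_from_layout(layout: GeneLayout, case_mask: np.ndarray) -> int:
    """Case patients carrying at least one rare-column bin of the gene."""
    union = np.zeros(case_mask.size, dtype=bool)
    for row, col, keys, mask in layout.cells:
        if col == 0:
            union |= mask
    return int((union & case_mask).sum())


def count_np(cohort: CohortData, ontology: HpoOntology, gene: str, term_id,
             moi: str, config: GenonConfig) -> int:
    """NP: number of case patients qualifying as rare-column carriers."""
    layout = gene_layout(cohort, gene, moi, config)
    case_mask = case_mask_for_term(cohort, ontology, term_id)
    return _np_from_layout(layout, case_mask)


def _score_pair_from_caches(cohort: CohortData, gene: str, term_label: str,
                            case_mask: np.ndarray, layouts: Dict[str, GeneLayout],
                            config: GenonConfig) -> GenonResult:
    patients = cohort.genotypes.patients
    hm_dom = heatmap_from_layout(layouts[DOMINANT], case_mask, patients,
                                 term_label, config)
    hm_rec = heatmap_from_layout(layouts[RECESSIVE], case_mask, patients,
                                 term_label, config)
    np_dom = _np_from_layout(layouts[DOMINANT], case_mask)
    np_rec = _np_from_layout(layouts[RECESSIVE], case_mask)
    return score_from_heatmaps(hm_dom, hm_rec, config, np_dom, np_rec,
                               int(case_mask.sum()))


def score_pair(cohort: CohortData, ontology: HpoOntology, gene: str, term_id,
               config: GenonConfig) -> GenonResult:
    """Score one gene-term pair under both MOI branches.

    Deterministic for fixed inputs; a gene with zero retained variants
    yields all-zero scores and an undetermined MOI.
    """
    layouts = {moi: gene_layout(cohort, gene, moi, config)
               for moi in (DOMINANT, RECESSIVE)}
    case_mask = case_mask_for_term(cohort, ontology, term_id)
    term_label = term_id if isinstance(term_id, str) else "&".join(term_id)
    return _score_pair_from_caches(cohort, gene, term_label, case_mask,
                                   layouts, config)


def _selected_np(result: GenonResult, config: GenonConfig) -> int:
    """NP under the better-scoring MOI (max of both when undetermined)."""
    if config.np_basis == "n_cases":
        return result.n_cases
    if result.predicted_moi == DOMINANT:
        return result.np_dom
    if result.predicted_moi == RECESSIVE:
        return result.np_rec
    return max(result.np_dom, result.np_rec)


def screen_cohort(cohort: CohortData, ontology: HpoOntology, config: GenonConfig,
                  terms: Optional[Sequence] = None,
                  genes: Optional[Sequence[str]] = None,
                  apply_np_cutoff: bool = True) -> List[GenonResult]:
    """Score every (gene, term) pair and return the ranked result list.

    ``terms`` defaults to every ontology term with at least one case; an
    entry may be a tuple of term ids, in which case cases must carry all
    of them (conjunction query).  Pairs whose NP under the better-scoring
    MOI falls below ``config.np_cutoff`` are dropped when
    ``apply_np_cutoff`` is set.
    """
    if terms is None:
        terms = sorted(ontology.terms)
    case_masks = {}
    term_labels = {}
    for term in terms:
        label = term if isinstance(term, str) else "&".join(term)
        mask = case_mask_for_term(cohort, ontology, term)
        if mask.sum() >= 1:
            case_masks[label] = mask
            term_labels[label] = term
    if not case_masks:
        logger.warning("no term has any case; empty screen")
        return []
    if genes is None:
        genes = sorted(cohort.gene_index)
    else:
        genes = sorted(genes)
    results: List[GenonResult] = []
    for gene in genes:
        layouts = {moi: gene_layout(cohort, gene, moi, config)
                   for moi in (DOMINANT, RECESSIVE)}
        for label in sorted(case_masks):
            result = _score_pair_from_caches(cohort, gene, label,
                                             case_masks[label], layouts, config)
            if apply_np_cutoff and _selected_np(result, config) < config.np_cutoff:
                continue
            results.append(result)
    if not results:
        logger.warning("no gene-term pair passed the NP cutoff (%d)", config.np_cutoff)
    return sort_results(results)


def screen_models(cohort: CohortData, ontology: HpoOntology, config: GenonConfig,
                  terms: Optional[Sequence] = None,
                  genes: Optional[Sequence[str]] = None,
                  include_recessive_af: bool = True,
                  apply_np_cutoff: bool = True) -> Dict[str, List[GenonResult]]:
    """Screen once and expose the results under every comparator model.

    phenogenon / fisher_method / hgf_only share one set of heatmaps; the
    recessive_af comparator re-screens with allele frequency substituted
    for the recessive genotype frequency.
    """
    base = screen_cohort(cohort, ontology, config, terms, genes, apply_np_cutoff)
    out = {"phenogenon": base, "fisher_method": base, "hgf_only": base}
    if include_recessive_af:
        af_config = config.replace(gf_convention=GF_ALLELE)
        out["recessive_af"] = screen_cohort(cohort, ontology, af_config, terms,
                                            genes, apply_np_cutoff)
    return out


# ---------------------------------------------------------------------------
# model accessors


def model_moi(result: GenonResult, model: str) -> str:
    if model in ("phenogenon", "recessive_af"):
        return result.predicted_moi
    if model == "hgf_only":
        return hgf_only_moi(result.hgf_dom, result.hgf_rec)
    if model == "fisher_method":
        if result.fisher_dom > result.fisher_rec:
            return DOMINANT
        if result.fisher_rec > result.fisher_dom:
            return RECESSIVE
        return UNDETERMINED
    raise ValueError(f"unknown model {model!r}")


def model_score(result: GenonResult, model: str) -> float:
    """Selection score: the model's association strength for the pair."""
    if model == "fisher_method":
        return max(result.fisher_dom, result.fisher_rec)
    if model == "hgf_only":
        return result.hgf_max
    moi = model_moi(result, model)
    if moi == UNDETERMINED:
        return result.hgf_max
    return result.hgf_for(moi)


def model_np(result: GenonResult, model: str) -> int:
    moi = model_moi(result, model)
    if moi == UNDETERMINED:
        return max(result.np_dom, result.np_rec)
    return result.np_for(moi)


# ---------------------------------------------------------------------------
# positive-term selection and benchmarking


def select_positive_terms(results: Sequence[GenonResult],
                          config: GenonConfig,
                          score: Callable[[GenonResult], float] = None) -> Set[str]:
    """Terms scoring at least ``sd_multiplier`` sample standard deviations
    above the gene's mean score.

    Requires >= 2 scored terms (sample s.d. is undefined otherwise).  When
    every score is equal (s = 0) all terms pass, which typically signals
    too few terms and is logged.
    """
    if score is None:
        score = lambda r: model_score(r, "phenogenon")
    results = list(results)
    if len({r.gene for r in results}) > 1:
        raise ValueError("select_positive_terms expects results for a single gene")
    if len(results) < 2:
        logger.warning("select_positive_terms needs >= 2 terms; returning empty set")
        return set()
    values = [score(r) for r in results]
    mu = statistics.fmean(values)
    s = statistics.stdev(values)
    if s == 0:
        logger.warning("zero score spread for gene %s; every term selected",
                       results[0].gene)
    threshold = mu + config.sd_multiplier * s
    return {r.term_id for r, v in zip(results, values) if v >= threshold}


def _term_matches_truth(term_id: str, truth_term: str,
                        ontology: Optional[HpoOntology], mode: str) -> bool:
    if term_id == truth_term:
        return True
    if mode != "ontology" or ontology is None:
        return False
    try:
        resolved = ontology.resolve(term_id)
        truth_resolved = ontology.resolve(truth_term)
    except KeyError:
        return False
    return (truth_resolved in ontology.descendants(resolved)
            or resolved in ontology.descendants(truth_resolved))


def _matching_truth(gene: str, term_id: str, truth: Sequence[TruthRecord],
                    ontology: Optional[HpoOntology], mode: str) -> List[TruthRecord]:
    return [t for t in truth if t.gene == gene
            and _term_matches_truth(term_id, t.term_id, ontology, mode)]


@dataclasses.dataclass
class BenchmarkReport:
    """Error-rate curves for the four prediction models.

    ``hpo_rows``: per NP cutoff and model, the positive-term error rate
    (false positives / all positives; ``None`` when nothing was selected).
    ``moi_rows``: per HGF cutoff and model, the MOI error rate over
    truth-matched pairs above the cutoff.
    """

    hpo_rows: List[dict]
    moi_rows: List[dict]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.hpo_rows:
            rows.append({"curve": "hpo_error", "cutoff": r["cutoff"],
                         "model": r["model"], "metric": "error_rate",
                         "value": r["error_rate"], "n": r["n_positive"]})
            rows.append({"curve": "hpo_error", "cutoff": r["cutoff"],
                         "model": r["model"], "metric": "n_evaluated",
                         "value": r["n_evaluated"], "n": r["n_evaluated"]})
        for r in self.moi_rows:
            rows.append({"curve": "moi_error", "cutoff": r["cutoff"],
                         "model": r["model"], "metric": "error_rate",
                         "value": r["error_rate"], "n": r["n_predicted"]})
        return pd.DataFrame(rows, columns=["curve", "cutoff", "model", "metric",
                                           "value", "n"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json_obj(self) -> dict:
        return {"hpo_error": self.hpo_rows, "moi_error": self.moi_rows}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_obj(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def hpo_error_counts(results: Sequence[GenonResult], truth: Sequence[TruthRecord],
                     np_cutoff: int, model: str, config: GenonConfig,
                     ontology: Optional[HpoOntology] = None) -> Tuple[int, int, int]:
    """(n_positive, n_false, n_evaluated) for one model at one NP cutoff."""
    eligible = [r for r in results if model_np(r, model) >= np_cutoff]
    by_gene: Dict[str, List[GenonResult]] = {}
    for r in eligible:
        by_gene.setdefault(r.gene, []).append(r)
    n_pos = 0
    n_false = 0
    for gene, gene_results in sorted(by_gene.items()):
        positives = select_positive_terms(
            gene_results, config, score=lambda r: model_score(r, model))
        for term in positives:
            n_pos += 1
            if not _matching_truth(gene, term, truth, ontology, config.truth_matching):
                n_false += 1
    return n_pos, n_false, len(eligible)


def moi_error_counts(results: Sequence[GenonResult], truth: Sequence[TruthRecord],
                     hgf_cutoff: float, model: str, config: GenonConfig,
                     ontology: Optional[HpoOntology] = None) -> Tuple[int, int]:
    """(n_predicted, n_wrong) over truth-matched pairs above the cutoff.

    Undetermined predictions count as errors; an x-linked truth MOI makes
    any dominant/recessive call an error (the model only has two branches).
    """
    n_pred = 0
    n_wrong = 0
    for r in results:
        if model_score(r, model) <= hgf_cutoff:
            continue
        matches = _matching_truth(r.gene, r.term_id, truth, ontology,
                                  config.truth_matching)
        if not matches:
            continue
        call = model_moi(r, model)
        n_pred += 1
        truth_mois = {t.moi for t in matches}
        if call == UNDETERMINED or call not in truth_mois:
            n_wrong += 1
    return n_pred, n_wrong


def benchmark(results_by_model: Dict[str, Sequence[GenonResult]],
              truth: Sequence[TruthRecord],
              np_cutoffs: Sequence[int], hgf_cutoffs: Sequence[float],
              config: GenonConfig,
              ontology: Optional[HpoOntology] = None) -> BenchmarkReport:
    """Error-rate curves for every model on identical pair sets.

    A cutoff with zero evaluable pairs records an absent (None) error
    rate, never 0.
    """
    hpo_rows = []
    for cutoff in np_cutoffs:
        for model in MODELS:
            if model not in results_by_model:
                continue
            n_pos, n_false, n_eval = hpo_error_counts(
                results_by_model[model], truth, cutoff, model, config, ontology)
            hpo_rows.append({
                "cutoff": cutoff, "model": model,
                "error_rate": (n_false / n_pos) if n_pos else None,
                "n_positive": n_pos, "n_false": n_false, "n_evaluated": n_eval,
            })
    moi_rows = []
    for cutoff in hgf_cutoffs:
        for model in MODELS:
            if model not in results_by_model:
                continue
            n_pred, n_wrong = moi_error_counts(
                results_by_model[model], truth, cutoff, model, config, ontology)
            moi_rows.append({
                "cutoff": cutoff, "model": model,
                "error_rate": (n_wrong / n_pred) if n_pred else None,
                "n_predicted": n_pred, "n_wrong": n_wrong,
            })
    return BenchmarkReport(hpo_rows=hpo_rows, moi_rows=moi_rows)
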