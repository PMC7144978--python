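"""Collapse heatmaps into association scores and call the mode of inheritance.

The goodness-of-fit score (HGF) is the negative log upper-tail normal
probability of a weighted, scaled Stouffer combination of the rare-column
z scores.  The signal ratio (SR) measures how much of the heatmap's
-ln(p) mass sits in the rare column; M = HGF x SR per MOI branch, and the
larger branch is the predicted mode of inheritance.  Comparator scorers
(Fisher's method; HGF-only MOI calls) are provided for benchmarking.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import List, Optional, Sequence

import pandas as pd
from scipy import stats

from .config import DOMINANT, RECESSIVE, GenonConfig
from .errors import UndefinedScoreError
from .genon import GenonHeatmap

logger = logging.getLogger(__name__)

UNDETERMINED = "undetermined"


def scaled_stouffer_z(heatmap: GenonHeatmap, config: GenonConfig) -> float:
    """Weighted Stouffer combination of per-bin z scores, scaled by the
    number of contributing bins (default denominator: k_rare itself).

    Only rare-column bins contribute under the default configuration.
    Returns 0 with a warning when no bin contributes.
    """
    cells = heatmap.rare_cells() if config.stouffer_cells == "rare" else heatmap.cells
    if not cells:
        logger.debug("no contributing bins for %s/%s/%s; Z = 0",
                       heatmap.gene, heatmap.term_id, heatmap.moi)
        return 0.0
    weights = [config.weight_for_row(cell.cadd_row) for cell in cells]
    total = sum(w * cell.z_score for w, cell in zip(weights, cells))
    k = len(cells)
    if config.stouffer_denominator == "k_rare":
        denom = float(k)
    elif config.stouffer_denominator == "sqrt_k_rare":
        denom = math.sqrt(k)
    else:  # sqrt_sum_w2, the classical weighted Stouffer normalisation
        denom = math.sqrt(sum(w * w for w in weights))
    if denom == 0:
        logger.warning("zero Stouffer denominator (all weights 0); Z = 0")
        return 0.0
    return total / denom


def hgf(z: float, config: Optional[GenonConfig] = None) -> float:
    """Goodness of fit: -log(1 - Phi(z)), via the log survival function so
    large z does not underflow."""
    base = config.hgf_log_base if config is not None else math.e
    value = -float(stats.norm.logsf(z))
    if base != math.e:
        value /= math.log(base)
    return value


def signal_ratio(heatmap: GenonHeatmap, config: Optional[GenonConfig] = None) -> float:
    """Fraction of the heatmap's -ln(p) mass in the rare column.

    With the default denominator (all non-empty cells) SR lies in [0, 1].
    The literal non-rare-only reading is available via
    ``config.sr_denominator = "nonrare"`` and is unbounded.
    """
    if heatmap.is_empty:
        raise UndefinedScoreError("signal ratio undefined on an empty heatmap")
    rare = sum(-math.log(cell.p_value) for cell in heatmap.rare_cells())
    nonrare = sum(-math.log(cell.p_value) for cell in heatmap.nonrare_cells())
    denom_mode = config.sr_denominator if config is not None else "all"
    denom = rare + nonrare if denom_mode == "all" else nonrare
    if denom == 0:
        if rare > 0:
            return math.inf  # only reachable in the literal non-rare-only mode
        logger.debug("all bin p-values are 1 for %s/%s/%s; SR = 0",
                       heatmap.gene, heatmap.term_id, heatmap.moi)
        return 0.0
    return rare / denom


def m_score(hgf_value: float, sr: float) -> float:
    """MOI-branch score: M = HGF x SR."""
    return hgf_value * sr


def predict_moi(m_dom: float, m_rec: float) -> str:
    """The larger M wins; an exact tie is undetermined."""
    if m_dom > m_rec:
        return DOMINANT
    if m_rec > m_dom:
        return RECESSIVE
    return UNDETERMINED


def hgf_only_moi(hgf_dom: float, hgf_rec: float) -> str:
    """Comparator MOI call using the raw HGF scores only."""
    if hgf_dom > hgf_rec:
        return DOMINANT
    if hgf_rec > hgf_dom:
        return RECESSIVE
    return UNDETERMINED


def fisher_combine(heatmap: GenonHeatmap) -> float:
    """Fisher's method over the rare-column p-values (unweighted comparator).

    X^2 = -2 * sum(ln p_i) referred to chi-squared with 2k degrees of
    freedom; returns the combined upper-tail p.
    """
    cells = heatmap.rare_cells()
    if not cells:
        raise UndefinedScoreError("Fisher's method undefined with no rare bins")
    x2 = -2.0 * sum(math.log(cell.p_value) for cell in cells)
    return float(stats.chi2.sf(x2, 2 * len(cells)))


@dataclasses.dataclass
class GenonResult:
    """Scores for one gene-term pair under both MOI branches."""

    gene: str
    term_id: str
    hgf_dom: float
    hgf_rec: float
    sr_dom: float
    sr_rec: float
    m_dom: float
    m_rec: float
    predicted_moi: str
    np_dom: int
    np_rec: int
    n_cases: int
    fisher_dom: float = 0.0  # -ln combined rare-column p, Fisher's method
    fisher_rec: float = 0.0

    @property
    def hgf_max(self) -> float:
        return max(self.hgf_dom, self.hgf_rec)

    def hgf_for(self, moi: str) -> float:
        return self.hgf_dom if moi == DOMINANT else self.hgf_rec

    def np_for(self, moi: str) -> int:
        return self.np_dom if moi == DOMINANT else self.np_rec


def score_from_heatmaps(hm_dom: GenonHeatmap, hm_rec: GenonHeatmap,
                        config: GenonConfig, np_dom: int, np_rec: int,
                        n_cases: int) -> GenonResult:
    """Assemble a :class:`GenonResult` from the two MOI heatmaps.

    Empty heatmaps score 0 throughout (with a warning from the Z stage).
    """
    scores = {}
    for moi, hm in ((DOMINANT, hm_dom), (RECESSIVE, hm_rec)):
        if hm.is_empty:
            scores[moi] = (0.0, 0.0, 0.0)
            continue
        z = scaled_stouffer_z(hm, config)
        h = hgf(z, config) if hm.rare_cells() or config.stouffer_cells == "all" else 0.0
        sr = signal_ratio(hm, config)
        scores[moi] = (h, sr, m_score(h, sr))
    hgf_dom, sr_dom, m_dom = scores[DOMINANT]
    hgf_rec, sr_rec, m_rec = scores[RECESSIVE]

    def fisher_neglogp(hm):
        if hm.is_empty or not hm.rare_cells():
            return 0.0
        p = fisher_combine(hm)
        return -math.log(max(p, 5e-324))

    return GenonResult(
        gene=hm_dom.gene,
        term_id=hm_dom.term_id,
        hgf_dom=hgf_dom, hgf_rec=hgf_rec,
        sr_dom=sr_dom, sr_rec=sr_rec,
        m_dom=m_dom, m_rec=m_rec,
        predicted_moi=predict_moi(m_dom, m_rec),
        np_dom=np_dom, np_rec=np_rec,
        n_cases=n_cases,
        fisher_dom=fisher_neglogp(hm_dom),
        fisher_rec=fisher_neglogp(hm_rec),
    )


RESULT_COLUMNS = [
    "gene", "term_id", "term_name", "n_cases", "np_dom", "np_rec",
    "hgf_dom", "hgf_rec", "sr_dom", "sr_rec", "m_dom", "m_rec",
    "predicted_moi", "fisher_dom", "fisher_rec",
]


def sort_results(results: Sequence[GenonResult]) -> List[GenonResult]:
    """Max-HGF descending, ties broken lexicographically by (gene, term)."""
    return sorted(results, key=lambda r: (-r.hgf_max, r.gene, r.term_id))


def results_to_frame(results: Sequence[GenonResult], ontology=None) -> pd.DataFrame:
    rows = []
    for r in sort_results(results):
        name = ""
        if ontology is not None and r.term_id in ontology:
            name = ontology.name(r.term_id)
        rows.append({
            "gene": r.gene, "term_id": r.term_id, "term_name": name,
            "n_cases": r.n_cases, "np_dom": r.np_dom, "np_rec": r.np_rec,
            "hgf_dom": r.hgf_dom, "hgf_rec": r.hgf_rec,
            "sr_dom": r.sr_dom, "sr_rec": r.sr_rec,
            "m_dom": r.m_dom, "m_rec": r.m_rec,
            "predicted_moi": r.predicted_moi,
            "fisher_dom": r.fisher_dom, "fisher_rec": r.fisher_rec,
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results: Sequence[GenonResult], path, ontology=None) -> None:
    results_to_frame(results, ontology).to_csv(path, sep="\t", index=False,
                                               float_format="%.10g")


def read_results(source) -> List[GenonResult]:
    """Read a results TSV back into result objects (term names dropped)."""
    df = pd.read_csv(source, sep="\t", dtype={"gene": str, "term_id": str})
    results = []
    for row in df.itertuples(index=False):
        results.append(GenonResult(
            gene=row.gene, term_id=row.term_id,
            hgf_dom=float(row.hgf_dom), hgf_rec=float(row.hgf_rec),
            sr_dom=float(row.sr_dom), sr_rec=float(row.sr_rec),
            m_dom=float(row.m_dom), m_rec=float(row.m_rec),
            predicted_moi=str(row.predicted_moi),
            np_dom=int(row.np_dom), np_rec=int(row.np_rec),
            n_cases=int(row.n_cases),
            fisher_dom=float(getattr(row, "fisher_dom", 0.0)),
            fisher_rec=float(getattr(row, "fisher_rec", 0.0)),
        ))
    return results
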