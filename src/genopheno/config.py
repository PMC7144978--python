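"""Run configuration for binning, scoring and screening.

All thresholds of the method live here so that every stage receives one
immutable object.  Defaults reproduce the published parameterisation:
CADD bin height 5, genotype-frequency bin width 1/4000, rare threshold
equal to the bin width, and a per-CADD-row weight ramp that saturates at
1.0 for rows at or above CADD 20.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError

DOMINANT = "dominant"
RECESSIVE = "recessive"
MOIS = (DOMINANT, RECESSIVE)

#: Recessive genotype frequency uses the estimated homozygote frequency.
GF_HOMOZYGOTE = "homozygote_frequency"
#: Comparator convention: allele frequency is used for the recessive branch too.
GF_ALLELE = "allele_frequency"

STOUFFER_DENOMS = ("k_rare", "sqrt_k_rare", "sqrt_sum_w2")
SR_DENOMS = ("all", "nonrare")
STOUFFER_CELLS = ("rare", "all")
NP_BASES = ("np", "n_cases")

DEFAULT_WEIGHTS = (0.2, 0.4, 0.6, 0.8, 1.0, 1.0, 1.0, 1.0)


@dataclasses.dataclass(frozen=True)
class GenonConfig:
    """Immutable parameter set for a full run."""

    cadd_bin_height: float = 5.0
    gf_bin_width: float = 0.00025
    rare_threshold: float = 0.00025
    cadd_max: float = 40.0
    gf_max: float = 0.01
    weights: tuple = DEFAULT_WEIGHTS
    p_clip: tuple = (1e-300, 1.0 - 1e-16)
    stouffer_denominator: str = "k_rare"
    stouffer_cells: str = "rare"
    hgf_log_base: float = math.e
    sr_denominator: str = "all"
    gf_convention: str = GF_HOMOZYGOTE
    np_cutoff: int = 60
    np_basis: str = "np"
    sd_multiplier: float = 1.0
    truth_matching: str = "ontology"
    missing_rate_max: float = 0.20
    coding_distance_max: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.gf_bin_width <= 0:
            raise ConfigError("gf_bin_width must be > 0")
        if self.cadd_bin_height <= 0:
            raise ConfigError("cadd_bin_height must be > 0")
        if self.gf_max <= 0 or self.cadd_max <= 0:
            raise ConfigError("gf_max and cadd_max must be > 0")
        w = tuple(float(x) for x in self.weights)
        object.__setattr__(self, "weights", w)
        if len(w) < self.n_cadd_rows:
            raise ConfigError(
                f"weights has length {len(w)} but {self.n_cadd_rows} CADD rows are possible"
            )
        if any(x < 0 for x in w):
            raise ConfigError("weights must be non-negative")
        if any(b < a for a, b in zip(w, w[1:])):
            raise ConfigError("weights must be non-decreasing with CADD row")
        lo, hi = self.p_clip
        if not (0 < lo < hi <= 1):
            raise ConfigError("p_clip must satisfy 0 < lo < hi <= 1")
        if self.stouffer_denominator not in STOUFFER_DENOMS:
            raise ConfigError(f"stouffer_denominator must be one of {STOUFFER_DENOMS}")
        if self.stouffer_cells not in STOUFFER_CELLS:
            raise ConfigError(f"stouffer_cells must be one of {STOUFFER_CELLS}")
        if self.sr_denominator not in SR_DENOMS:
            raise ConfigError(f"sr_denominator must be one of {SR_DENOMS}")
        if self.gf_convention not in (GF_HOMOZYGOTE, GF_ALLELE):
            raise ConfigError("gf_convention must be homozygote_frequency or allele_frequency")
        if self.np_basis not in NP_BASES:
            raise ConfigError(f"np_basis must be one of {NP_BASES}")
        if self.truth_matching not in ("ontology", "exact"):
            raise ConfigError("truth_matching must be 'ontology' or 'exact'")
        if self.hgf_log_base <= 1:
            raise ConfigError("hgf_log_base must be > 1")

    @property
    def n_cadd_rows(self) -> int:
        return int(math.ceil(self.cadd_max / self.cadd_bin_height))

    @property
    def n_gf_cols(self) -> int:
        return int(math.ceil(self.gf_max / self.gf_bin_width))

    def weight_for_row(self, row: int) -> float:
        if row >= len(self.weights):
            raise ConfigError(f"no weight defined for CADD row {row}")
        return self.weights[row]

    def replace(self, **kwargs) -> "GenonConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["weights"] = list(self.weights)
        d["p_clip"] = list(self.p_clip)
        return d

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "GenonConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in ("weights", "p_clip"):
            if key in kwargs and isinstance(kwargs[key], Sequence):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "GenonConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError("config file must contain a key-value mapping")
        return cls.from_mapping(data)
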