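"""Pipeline configuration.

A single flat configuration object carries every numeric criterion used
across the pipeline: the redundancy thresholds for building the query gene
set, the intron-length-polymorphism threshold, the primer design
constraints (Tm, length, product size), the in-silico PCR stringency, and
the gel co-migration model.  Defaults encode the published marker-design
criteria: dedup at e-value <= 1e-5 with coverage > 80%, targeted introns
whose alien (V) size differs >= 10% from every wheat homoeolog, primers of
18-25 nt (optimum 20) with Tm 55-65 degC (optimum 60), and products roughly
50 bp larger than the targeted intron.
"""

from __future__ import annotations

import configparser
import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union


class ConfigError(ValueError):
    """Raised when a configuration value violates an invariant."""


@dataclass
class PipelineConfig:
    # gene-set deduplication
    dedup_evalue_cutoff: float = 1e-5
    dedup_coverage_cutoff: float = 0.80
    dedup_coverage_denominator: str = "shorter"  # or "longer"

    # spliced mapping
    seed_k: int = 15
    min_intron_bp: int = 40
    junction_tolerance_bp: int = 12
    min_query_coverage: float = 0.50

    # polymorphism filter
    polymorphism_threshold: float = 0.10
    polymorphism_denominator: str = "wheat"  # or "max" / "mean"

    # primer design
    tm_min: float = 55.0
    tm_opt: float = 60.0
    tm_max: float = 65.0
    primer_len_min: int = 18
    primer_len_opt: int = 20
    primer_len_max: int = 25
    gc_min: float = 0.30
    gc_max: float = 0.70
    max_mononucleotide_run: int = 4
    max_complementarity: int = 8
    product_overhead_bp: int = 50

    # in-silico PCR
    epcr_max_product_bp: int = 3000
    epcr_max_mismatch: int = 2
    epcr_3prime_exact_bp: int = 5

    # band clustering (gel co-migration model)
    comigration_abs_bp: int = 4
    comigration_rel: float = 0.01

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            "dedup_evalue_cutoff", "dedup_coverage_cutoff", "seed_k",
            "min_intron_bp", "junction_tolerance_bp", "polymorphism_threshold",
            "primer_len_min", "primer_len_opt", "primer_len_max",
            "product_overhead_bp", "epcr_max_product_bp",
            "epcr_3prime_exact_bp", "comigration_abs_bp", "comigration_rel",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if not (self.tm_min <= self.tm_opt <= self.tm_max):
            raise ConfigError("require tm_min <= tm_opt <= tm_max")
        if not (self.primer_len_min <= self.primer_len_opt <= self.primer_len_max):
            raise ConfigError("require primer_len_min <= primer_len_opt <= primer_len_max")
        if self.dedup_coverage_denominator not in ("shorter", "longer"):
            raise ConfigError("dedup_coverage_denominator must be 'shorter' or 'longer'")
        if self.polymorphism_denominator not in ("wheat", "max", "mean"):
            raise ConfigError("polymorphism_denominator must be 'wheat', 'max' or 'mean'")
        if self.epcr_max_mismatch < 0:
            raise ConfigError("epcr_max_mismatch must be >= 0")

    # -- flat key=value / INI round-trip -----------------------------------

    def to_ini(self, path: Union[str, Path]) -> None:
        cp = configparser.ConfigParser()
        cp["intronit"] = {k: repr(v) if not isinstance(v, str) else v
                          for k, v in dataclasses.asdict(self).items()}
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_ini(cls, path: Union[str, Path], **overrides) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        read = cp.read(path)
        if not read:
            raise ConfigError(f"cannot read config file {path}")
        section = cp["intronit"] if cp.has_section("intronit") else cp[cp.sections()[0]]
        kwargs = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        for key, raw in section.items():
            if key not in fields:
                raise ConfigError(f"unknown config key: {key}")
            current = getattr(defaults, key)
            kwargs[key] = raw if isinstance(current, str) else type(current)(
                float(raw) if isinstance(current, float) else raw)
        kwargs.update(overrides)
        return cls(**kwargs)
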