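"""Pipeline configuration.

All analysis thresholds live in one dataclass so every stage logs the exact
values it ran with and the CLI can expose each one as a flag.  The on-disk
format is a flat ``key = value`` file (one pair per line, ``#`` comments).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from pathlib import Path


class ConfigError(ValueError):
    """Raised when a configuration value violates its documented range."""


@dataclass
class PipelineConfig:
    """Thresholds and sizes shared across pipeline stages.

    Attributes
    ----------
    cis_window_bp:
        A SNP-gene pair is cis when both sit on the same chromosome and the
        SNP is within this distance of the gene's transcription start site
        (inclusive at the boundary).
    fdr_threshold:
        Benjamini-Hochberg q-value cut-off applied separately to the cis and
        trans strata when selecting network edges.  Deliberately permissive
        (0.2) because network centrality is more sensitive to false-negative
        than to false-positive edges.
    maf_min, call_rate_min:
        SNP quality filters: minor allele frequency and genotype call rate.
        SNPs with call rate strictly below ``call_rate_min`` or MAF strictly
        below ``maf_min`` are removed.
    expr_count_min, expr_min_samples:
        A gene is kept when at least ``expr_min_samples`` samples have a raw
        read count >= ``expr_count_min``.
    gwas_p_threshold:
        Genome-wide significance bar applied to GWAS labels before any SNP
        is treated as a risk SNP.
    ld_r2_threshold:
        Risk status propagates to network SNPs with r² strictly greater than
        this with a labelled risk SNP.
    min_risk_blocks:
        Minimum number of risk LD blocks a community must contain before it
        can be called enriched.
    promoter_upstream_bp, promoter_downstream_bp:
        Promoter interval around the TSS in the direction of transcription.
    n_resamples:
        Resampling count for the degree-matched cancer-degree null.
    rng_seed:
        Seed for every stochastic operation in the pipeline.
    """

    cis_window_bp: int = 1_000_000
    fdr_threshold: float = 0.2
    maf_min: float = 0.05
    call_rate_min: float = 0.9
    expr_count_min: int = 6
    expr_min_samples: int = 10
    gwas_p_threshold: float = 5e-8
    ld_r2_threshold: float = 0.8
    min_risk_blocks: int = 4
    promoter_upstream_bp: int = 750
    promoter_downstream_bp: int = 250
    n_resamples: int = 10_000
    rng_seed: int = 0

    _FRACTIONS = ("fdr_threshold", "maf_min", "call_rate_min", "ld_r2_threshold")
    _POSITIVE = (
        "cis_window_bp",
        "expr_count_min",
        "expr_min_samples",
        "min_risk_blocks",
        "promoter_upstream_bp",
        "promoter_downstream_bp",
        "n_resamples",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in self._FRACTIONS:
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name}={v!r} must lie in (0, 1]")
        if not (0 < self.gwas_p_threshold <= 1):
            raise ConfigError(f"gwas_p_threshold={self.gwas_p_threshold!r} must lie in (0, 1]")
        for name in self._POSITIVE:
            v = getattr(self, name)
            if int(v) != v or v <= 0:
                raise ConfigError(f"{name}={v!r} must be a positive integer")
            setattr(self, name, int(v))
        if int(self.rng_seed) != self.rng_seed or self.rng_seed < 0:
            raise ConfigError(f"rng_seed={self.rng_seed!r} must be a non-negative integer")
        self.rng_seed = int(self.rng_seed)

    # ---- flat key/value serialization -------------------------------------

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)!r}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = _parse_scalar(value)
        return cls(**kwargs)

    def replace(self, **overrides) -> "PipelineConfig":
        return dataclasses.replace(self, **overrides)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _parse_scalar(text: str):
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        raise ConfigError(f"cannot parse config value {text!r}") from None
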