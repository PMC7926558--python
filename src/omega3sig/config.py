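"""Run configuration: every analysis cutoff in one validated object.

The defaults are the cutoffs used throughout the pipeline: biotype-specific
CPM expression thresholds (1 CPM for protein-coding genes, 0.5 for lncRNA,
required in at least half of the samples), biotype-specific fold-change
cutoffs for differential-expression calls (|log2FC| > 0.2 coding,
> 0.15 non-coding, BH-adjusted p < 0.05), the correlation-network edge
thresholds (|r| > 0.6, p < 0.05), the variability quantile width (0.25,
i.e. quartile strata) and the exosome detectability fraction (top 20% of
human genes by exosomal read abundance).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "write_config"]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """All tunable thresholds of the signature-selection pipeline."""

    cpm_coding: float = 1.0     # CPM expression threshold, protein-coding
    cpm_lnc: float = 0.5        # CPM expression threshold, lncRNA
    frac_samples: float = 0.5   # fraction of samples that must pass the CPM threshold
    lfc_coding: float = 0.2     # |log2FC| call threshold, protein-coding (strict >)
    lfc_lnc: float = 0.15       # |log2FC| call threshold, lncRNA (strict >)
    alpha: float = 0.05         # BH-adjusted significance level for DE calls
    corr_r: float = 0.6         # |Pearson r| threshold for lncRNA-mRNA edges (strict >)
    corr_p: float = 0.05        # nominal p threshold for network edges
    quantile: float = 0.25      # width of the most/least-variable CV strata
    exo_top_frac: float = 0.2   # exosome detectability: top fraction by read count
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fractions = ("frac_samples", "quantile", "exo_top_frac", "alpha", "corr_p")
        for key in fractions:
            v = getattr(self, key)
            if not (0.0 < v < 1.0):
                raise ValueError(f"config key {key!r} must lie in (0, 1), got {v}")
        for key in ("cpm_coding", "cpm_lnc", "lfc_coding", "lfc_lnc"):
            v = getattr(self, key)
            if v < 0:
                raise ValueError(f"config key {key!r} must be >= 0, got {v}")
        if not (0.0 < self.corr_r < 1.0):
            raise ValueError(f"config key 'corr_r' must lie in (0, 1), got {self.corr_r}")
        if int(self.rng_seed) != self.rng_seed or self.rng_seed < 0:
            raise ValueError(f"config key 'rng_seed' must be a non-negative integer")

    def threshold_for_biotype(self, biotype: str, kind: str) -> float:
        """Biotype-specific cutoff; `other` biotypes use the coding thresholds."""
        if kind == "cpm":
            return self.cpm_lnc if biotype == "lncRNA" else self.cpm_coding
        if kind == "lfc":
            return self.lfc_lnc if biotype == "lncRNA" else self.lfc_coding
        raise ValueError(f"unknown threshold kind {kind!r}")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML key-value config; absent keys take the defaults above.

    Unknown keys and out-of-range values raise ``ValueError`` naming the key.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a key-value mapping")
        values.update(loaded)
    values.update(overrides)
    unknown = set(values) - _FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**values)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the resolved configuration next to run outputs (reproducibility)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
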