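"""Pipeline configuration: a validated, YAML-backed parameter bundle.

One structured file drives an end-to-end run; CLI flags override config keys.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Validated parameters for a full pipeline run.

    Paths are to TSV/CSV inputs as documented in the io module; tolerances and
    alpha govern the association and enrichment stages.
    """

    # input tables (all optional so `simulate` can fill them in)
    biomarker_panel: str | None = None
    threshold_table: str | None = None
    beta_matrix: str | None = None
    probe_annotation: str | None = None
    expression_matrix: str | None = None
    gene_id_map: str | None = None
    signature_matrix: str | None = None
    gmt: str | None = None
    out_dir: str = "alcyte_run"

    # AL scoring
    al_method: str = "index"  # index | zscore
    al_index_cutoff: float = 2.0  # low iff score <= cutoff
    dichotomize_at_cutoff: int = 0  # value exactly at cutoff scores this

    # preprocessing
    female_x_window: tuple[float, float] = (0.35, 0.65)
    duplicate_gene_policy: str = "sum"  # sum | first | max-mean

    # deconvolution
    refactor_k: int = 6
    refactor_t: int = 500

    # association
    dm_threshold: float = 0.10
    state_p_threshold: float = 0.05
    min_subset: int = 5
    min_subset_frac: float = 0.05
    alpha: float = 0.05

    # enrichment
    enrichment_alpha: float = 0.05
    min_set_size: int = 0
    max_set_size: int = 0  # 0 = no cap

    seed: int = 0

    def __post_init__(self) -> None:
        if self.al_method not in ("index", "zscore"):
            raise ValueError(f"al_method must be 'index' or 'zscore', got {self.al_method!r}")
        for name in ("dm_threshold", "min_subset_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("alpha", "enrichment_alpha", "state_p_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not (isinstance(self.seed, int) and self.seed >= 0):
            raise ValueError("seed must be a non-negative integer")
        lo, hi = self.female_x_window
        if not 0 <= lo < hi <= 1:
            raise ValueError("female_x_window must be an increasing pair within [0, 1]")
        if self.duplicate_gene_policy not in ("sum", "first", "max-mean"):
            raise ValueError("duplicate_gene_policy must be sum|first|max-mean")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "female_x_window" in raw:
            raw["female_x_window"] = tuple(raw["female_x_window"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["female_x_window"] = list(self.female_x_window)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
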