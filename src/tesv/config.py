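"""Run configuration: every numeric threshold of the pipeline in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class RunConfig:
    """All tunable thresholds, with the analysis defaults.

    min_sv_len            floor (strict >) for a one-sided indel to count as
                          a structural variant, bp
    share_threshold       inclusive fraction of feature bp required in
                          alignable (shared) or own-lineage SV (polymorphic)
                          sequence
    sv_te_threshold       strict fraction for the TE-content tests of SV
                          classification
    window_bp / step_bp   sliding-window geometry of the SNP-depletion scan
    alignable_floor       strict minimum alignable bp for a window to qualify
    rate_denom            a window qualifies when snp_count * rate_denom <
                          alignable_bp (i.e. rate < 1/rate_denom)
    min_run               minimum consecutive qualifying windows per region
    trim_bp               bp trimmed from each raw region end for downstream
                          analyses
    family_min_copies     minimum family copy number for per-family summaries
    active_min_events     strict minimum of TE=SV events in SNP-depleted
                          regions to flag a family as candidate-active
    boundary_bp           inclusive distance for the structural-boundary
                          annotation filter
    hh_frac / hs_frac     strict own-length overlap fractions of the
                          homology-homology / homology-structural filters
    seed                  RNG seed for every stochastic tie-break
    """

    min_sv_len: int = 50
    share_threshold: float = 0.95
    sv_te_threshold: float = 0.95
    window_bp: int = 1_000_000
    step_bp: int = 250_000
    alignable_floor: int = 950_000
    rate_denom: int = 10_000
    min_run: int = 5
    trim_bp: int = 100_000
    family_min_copies: int = 20
    active_min_events: int = 10
    boundary_bp: int = 5
    hh_frac: float = 0.10
    hs_frac: float = 0.05
    hh_keep_longer: bool = False
    seed: int = 42

    def __post_init__(self):
        if self.min_sv_len < 0:
            raise ValueError("min_sv_len must be >= 0")
        for name in ("share_threshold", "sv_te_threshold", "hh_frac", "hs_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.step_bp > self.window_bp:
            raise ValueError("step_bp must not exceed window_bp")
        if self.alignable_floor > self.window_bp:
            raise ValueError("alignable_floor must not exceed window_bp")
        for name in ("rate_denom", "min_run", "window_bp", "step_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.trim_bp < 0 or self.boundary_bp < 0:
            raise ValueError("trim_bp and boundary_bp must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
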