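"""Run configuration: every tunable default of the pipeline in one record.

The resolved configuration is echoed verbatim into every output record
so a run can be reproduced from its own artifacts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields


@dataclass
class RunConfig:
    # ensemble sampling
    backend: str = "exact"
    n_samples: int = 1000
    sampler_seed: int = 0
    exact_length_cap: int = 30
    # reactivity pseudo-energies (kcal/mol)
    pseudo_energy_slope: float = 1.8
    pseudo_energy_intercept: float = -0.6
    # conflict detection
    f_min: float = 0.05
    f_max: float = 0.95
    mi_threshold_u: float = 0.5
    min_stem_len: int = 3
    overlap_threshold: int = 3
    # conformation prediction / barrier
    mea_gamma: float = 1.0
    beam_width: int = 50
    # classifier scan
    frag_len: int = 186
    frag_overlap: int = 93
    # mutation design
    refold_fraction: float = 0.6
    complement_run_threshold: int = 4
    exhaustive_interval_cap: int = 7
    random_candidate_budget: int = 100_000
    max_verify_candidates: int = 200
    shift_target_min: float = 0.8
    shift_rival_max: float = 0.2
    # conformation_share | interval_contact | pair_mean | fold_membership
    stem_fraction_mode: str = "conformation_share"
    stem_presence_frac: float = 0.8  # fold_membership mode only
    # reactivity normalization
    outlier_decile: float = 0.10
    min_coverage: int = 100
    ac_only: bool = True
    # probing support test
    support_top_t: int = 5
    support_jaccard: float = 0.5

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kwargs) -> "RunConfig":
        d = self.to_dict()
        d.update(kwargs)
        return RunConfig.from_dict(d)
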