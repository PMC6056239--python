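"""Run configuration: one structured YAML file whose defaults reproduce the
published model settings (45 CG sites per subunit; LJ epsilon 10 kcal/mol;
screening length 8 A; dielectric 1 or 3; Coulomb cutoff 30 A; Langevin at
310 K with 1000 fs damping; hills of 0.001 kcal/mol and 0.3 A every 50 fs
with bias factor 10; metabasin offset 6 kcal/mol updated every 100 ps on a
0.5 kcal/mol exterior-bias change; analysis thresholds 4 A / 12 A / 1%)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    seed: int = 1
    # inputs
    structure_path: str | None = None
    role_map: dict | None = None
    # coarse-graining
    sites_per_subunit: int = 45
    variance_fraction: float = 0.9
    # elastic network
    enm_cutoffs: dict = field(default_factory=lambda: {"formin": 50.0, "actin": 30.0})
    enm_fit_tol: float = 0.05
    enm_fit_alpha: float = 0.5
    enm_max_iter: int = 200
    # force field
    lj_epsilon: float = 10.0
    lambda_debye: float = 8.0
    eps_r: float = 1.0
    coulomb_cutoff: float = 30.0
    sigma_min: float = 1.0
    # Langevin dynamics
    temperature: float = 310.0
    damping_fs: float = 1000.0
    timestep_fs: float = 10.0
    n_steps: int = 100000
    stride: int = 100
    # metadynamics
    hill_height: float = 0.001
    hill_width: float = 0.3
    hill_pace_fs: float = 50.0
    bias_factor: float = 10.0
    metabasin_offset: float = 6.0
    domain_update_ps: float = 100.0
    exterior_threshold: float = 0.5
    # analysis thresholds
    overlap_threshold: float = 4.0
    contact_threshold: float = 12.0
    overlap_time_fraction: float = 0.01
    salt_bridge_criterion: float = 4.0

    def validate(self) -> None:
        positive = ["sites_per_subunit", "lj_epsilon", "lambda_debye",
                    "coulomb_cutoff", "temperature", "timestep_fs",
                    "hill_height", "hill_width", "hill_pace_fs",
                    "overlap_threshold", "contact_threshold",
                    "salt_bridge_criterion"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")
        if not (0 < self.variance_fraction <= 1):
            raise ValueError("variance_fraction must lie in (0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg
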