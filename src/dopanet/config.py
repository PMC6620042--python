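"""Configuration objects for the simulation and analysis pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic PET/fMRI working-memory cohort.

    Defaults mirror the study design being emulated: 51 subjects, 97 cortical
    nodes (42 default-mode, the rest task-positive), 275 EPI volumes at
    TR = 2 s, 18 twenty-second n-back blocks (six each of 0/1/2-back)
    separated by 10 s of rest, and 31-frame PET time-activity curves.

    Connectivity structure is planted on the Fisher-z scale: the within-DMN
    correlation at load L is tanh(atanh(base_corr_dmn) + dmn_slope * L), so a
    linear per-edge regression of z on load recovers the slope exactly in
    expectation.
    """

    n_subjects: int = 51
    n_nodes: int = 97
    n_dmn_nodes: int = 42
    tr: float = 2.0
    n_volumes: int = 275
    block_len: float = 20.0
    rest_len: float = 10.0
    blocks_per_load: int = 6
    trials_per_block: int = 10

    # baseline Pearson correlations (load 0). The within-network baselines
    # must sit well above the equicorrelation floor -1/(n-1) so that the
    # planted negative load slopes remain representable at load 2.
    base_corr_dmn: float = 0.45
    base_corr_tpn: float = 0.25
    base_corr_between: float = 0.05

    # planted load slopes, Fisher-z units per load level
    mean_dmn_slope: float = -0.10
    sd_dmn_slope: float = 0.08
    mean_tpn_slope: float = 0.06

    # latent D2/3 binding potential of the caudate
    bp_mean: float = 2.0
    bp_sd: float = 0.35

    # planted couplings
    rho_bp_slope: float = 0.45           # Spearman(bp_caudate, dmn_slope)
    behav_slope_coupling: float = 0.5    # pRT-seconds per z-unit of DMN slope
    direct_bp_behaviour: float = 0.0     # pRT-seconds per BP_ND unit
    behav_noise_sd: float = 0.060        # residual sd of planted robustness

    # block-to-block DMN connectivity fluctuation and its within-subject
    # coupling to block performance (seconds of RT per z-unit of strength)
    dmn_block_jitter_sd: float = 0.10
    block_strength_coupling: float = -0.10

    # stable load-independent individual differences in overall network
    # connectivity (z-units); cancels exactly in the load slope but
    # dominates whole-session means, as in real cohorts
    subject_base_z_sd: float = 0.08

    # measurement noise
    noise_sd: float = 0.10               # iid BOLD noise on unit-variance signal
    tac_noise_frac: float = 0.05         # TAC noise fraction, var ~ 1/frame_dur

    # condition-dependent covariance follows the task with this delay,
    # matching the haemodynamic lag assumed by the analysis stage
    hemodynamic_delay_s: float = 4.0

    target_rate: float = 0.30            # per-trial probability of a target
    seed: int = 0

    @property
    def n_blocks(self) -> int:
        return 3 * self.blocks_per_load

    @property
    def n_tpn_nodes(self) -> int:
        return self.n_nodes - self.n_dmn_nodes

    @property
    def session_length_s(self) -> float:
        return self.n_volumes * self.tr

    def validate(self) -> "CohortConfig":
        for name in ("n_subjects", "n_nodes", "n_dmn_nodes", "n_volumes",
                     "blocks_per_load", "trials_per_block"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_dmn_nodes >= self.n_nodes:
            raise ConfigurationError("n_dmn_nodes must be < n_nodes")
        for name in ("base_corr_dmn", "base_corr_tpn", "base_corr_between"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ConfigurationError(f"{name} must lie strictly in (-1, 1)")
        if not -1.0 < self.rho_bp_slope < 1.0:
            raise ConfigurationError("rho_bp_slope must lie strictly in (-1, 1)")
        if self.tr <= 0 or self.block_len <= 0 or self.rest_len < 0:
            raise ConfigurationError("tr/block_len must be positive, rest_len >= 0")
        total = self.n_blocks * (self.block_len + self.rest_len)
        if total > self.session_length_s:
            raise ConfigurationError(
                f"schedule needs {total:.0f}s but session is only "
                f"{self.session_length_s:.0f}s")
        return self

    def null(self) -> "CohortConfig":
        """A copy with all planted couplings switched off."""
        return dataclasses.replace(
            self, rho_bp_slope=0.0, behav_slope_coupling=0.0,
            direct_bp_behaviour=0.0, block_strength_coupling=0.0)


@dataclass
class ConsensusSettings:
    n_iter: int = 1000
    threshold: float = 0.5
    gamma: float = 1.0
    max_rounds: int = 50


@dataclass
class SRTMSettings:
    k2a_min: float = 0.001   # 1/min
    k2a_max: float = 1.0     # 1/min
    n_basis: int = 100
    dt: float = 1.0          # fine-grid resolution, seconds
    refine: bool = True


@dataclass
class AnalysisConfig:
    """Settings for the full analysis over a simulated or loaded cohort."""

    penalization_ratios: Sequence[float] = (2.5, 3.0, 3.5, 4.0)
    lag_volumes: int = 2
    consensus: ConsensusSettings = field(default_factory=ConsensusSettings)
    srtm: SRTMSettings = field(default_factory=SRTMSettings)
    n_boot: int = 10_000
    network_detection: str = "consensus"   # "consensus" | "apriori"
    seed: int = 0

    def validate(self) -> "AnalysisConfig":
        if any(r < 1 for r in self.penalization_ratios):
            raise ConfigurationError("penalization ratios must be >= 1")
        if self.network_detection not in ("consensus", "apriori"):
            raise ConfigurationError(
                "network_detection must be 'consensus' or 'apriori'")
        if self.consensus.n_iter < 1:
            raise ConfigurationError("consensus n_iter must be >= 1")
        return self


def config_hash(cfg) -> str:
    """Stable short hash of any (nested) dataclass configuration."""
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (tuple, set)):
            return list(o)
        raise TypeError(type(o))
    payload = json.dumps(cfg, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
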