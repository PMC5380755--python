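"""Reproduction surfaces: the computations behind the package's headline
checks, shared by the test suite and ``scripts/acceptance.py``.

Two groups: (a) arithmetic on the published per-participant decoding
correlations (summary statistics, frontal drop) and protocol conformance
counts; (b) simulation-based recovery of the published per-level behavioral
and cardiac fixed effects from the generator + mixed-model chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior_stats import lmm_trend
from .montage import default_montage
from .reference import frontal_drop_percent, rmvr_summary
from .synthetic import generate_behavior, generate_design

__all__ = ["SlopeRecovery", "recover_slope", "RECOVERY_PARAMETERS",
           "design_conformance"]

#: parameters with published per-level fixed effects, and whether the
#: published number is stated as a magnitude of a decrease
RECOVERY_PARAMETERS: dict[str, dict] = {
    "heart_rate": {"generating": 0.89, "magnitude": False},
    "rmssd": {"generating": -1.24, "magnitude": True},
    "reaction_time": {"generating": 0.23, "magnitude": False},
    "time_in_correct_range": {"generating": -6.6, "magnitude": True},
}


@dataclass
class SlopeRecovery:
    parameter: str
    generating: float
    mean_slope: float          # signed, averaged over replicates
    mc_se: float               # Monte-Carlo SE of the replicate mean
    n_replicates: int
    n_participants: int
    n_trials: int

    @property
    def reported(self) -> float:
        """On the published scale (magnitude for reported decreases)."""
        mag = RECOVERY_PARAMETERS[self.parameter]["magnitude"]
        return abs(self.mean_slope) if mag else self.mean_slope

    @property
    def within_2se(self) -> bool:
        return abs(self.mean_slope - self.generating) <= 2 * self.mc_se


def recover_slope(parameter: str, n_replicates: int = 20,
                  n_participants: int = 12, seed: int = 0) -> SlopeRecovery:
    """Generate replicate sessions with the published effect as the
    generating slope, refit the mixed model, and average the estimates."""
    generating = RECOVERY_PARAMETERS[parameter]["generating"]
    rng = np.random.default_rng(seed)
    slopes = []
    for rep in range(n_replicates):
        s = int(rng.integers(0, 2**31 - 1))
        design = generate_design(seed=s)
        tbl = generate_behavior(design, n_participants=n_participants,
                                seed=s + 1)
        res = lmm_trend(tbl, parameter, compute_lrt=False)
        slopes.append(res.slope)
    slopes = np.asarray(slopes)
    return SlopeRecovery(parameter, generating, float(slopes.mean()),
                         float(slopes.std(ddof=1) / np.sqrt(len(slopes))),
                         n_replicates, n_participants,
                         len(design))


def design_conformance(seed: int = 0) -> dict[str, int]:
    design = generate_design(seed=seed)
    montage = default_montage()
    return {
        "n_trials": len(design),
        "n_distinct_speeds": len({t.sign_speed for t in design.trials}),
        "n_channels": len(montage),
        "n_frontal_channels": len(montage.frontal_ids),
    }
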