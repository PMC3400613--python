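"""Synthetic flow-cytometry event tables.

One simulated "tube" holds lymphocytes and CD14+ monocytes together, with
forward/side scatter and CD14 drawn from well-separated lognormal clusters so
that scatter/CD14 gating is near-perfect by construction.  Fluorescence is
simulated on the log10 scale (Gaussian components in decades, i.e. lognormal
linear intensities), matching decade-scaled cytometer axes:

* ``FL_green`` follows a two-component mixture per cell type — the low/high
  ROS-producing subpopulations.  Under PMA stimulation all green intensities
  are multiplied by a configurable factor.
* ``FL_red`` is built as ``FL_green x ratio`` where the log10 red/green ratio
  follows the JC-1 mixture of low- and high-membrane-potential components.
  Under CCCP the ratio mixture collapses: component means drop and the low
  fraction rises, emulating chemical depolarization.

Ground-truth labels (cell type, ROS component, potential component) travel in
``true_*`` columns so recovery can be scored downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CONDITIONS = ("basal", "PMA", "CCCP")


@dataclass(frozen=True)
class LogMixture:
    """Two-component Gaussian mixture on log10 intensity (decades)."""

    mu_low: float
    sd_low: float
    mu_high: float
    sd_high: float
    pi_high: float

    def __post_init__(self):
        if not 0.0 <= self.pi_high <= 1.0:
            raise ValueError("pi_high must lie in [0, 1]")
        if self.sd_low <= 0 or self.sd_high <= 0:
            raise ValueError("component SDs must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Returns (log10 values, component labels 0=low / 1=high)."""
        hi = rng.uniform(size=n) < self.pi_high
        x = np.where(
            hi,
            rng.normal(self.mu_high, self.sd_high, n),
            rng.normal(self.mu_low, self.sd_low, n),
        )
        return x, hi.astype(int)

    def linear_mean(self, component: str = "high") -> float:
        """Arithmetic mean of the lognormal component on the linear scale."""
        mu, sd = (self.mu_high, self.sd_high) if component == "high" else (self.mu_low, self.sd_low)
        ln10 = np.log(10.0)
        return float(np.exp(mu * ln10 + (sd * ln10) ** 2 / 2.0))


@dataclass(frozen=True)
class ScatterCluster:
    """Lognormal FSC/SSC/CD14 cluster for one cell population."""

    fsc_mu: float
    fsc_sd: float
    ssc_mu: float
    ssc_sd: float
    cd14_mu: float
    cd14_sd: float


@dataclass(frozen=True)
class CytometrySimConfig:
    """Per-subject distributional truth for one simulated cytometry panel."""

    lymph_ros: LogMixture = LogMixture(1.00, 0.10, 1.28, 0.12, 0.554)
    mono_ros: LogMixture = LogMixture(1.20, 0.15, 2.15, 0.18, 0.758)
    # JC-1 log10(red/green) ratio mixtures; pi_high = fraction of high-potential cells
    lymph_psi: LogMixture = LogMixture(-0.35, 0.08, 0.50, 0.15, 1.0 - 0.147)
    mono_psi: LogMixture = LogMixture(0.45, 0.15, 0.45, 0.15, 1.0)
    pma_shift_lymph: float = 2.0
    pma_shift_mono: float = 4.0
    # CCCP collapse: component means drop (decades) and the low fraction rises
    cccp_low_shift: float = 0.15
    cccp_high_shift: float = 0.40
    cccp_low_sd: float = 0.20
    cccp_high_sd: float = 0.15
    cccp_pi_low: float = 0.85
    lymph_scatter: ScatterCluster = ScatterCluster(2.00, 0.05, 1.70, 0.06, 0.50, 0.15)
    mono_scatter: ScatterCluster = ScatterCluster(2.30, 0.05, 2.25, 0.07, 2.00, 0.15)
    n_lymph: int = 15000
    n_mono: int = 3000
    seed: int = 0

    def psi_mixture(self, cell_type: str, condition: str) -> LogMixture:
        base = self.lymph_psi if cell_type == "lymphocyte" else self.mono_psi
        if condition != "CCCP":
            return base
        # monocytes show a single potential population: depolarization shifts it
        # down without creating a low fraction
        pi_high = 1.0 - self.cccp_pi_low if base.pi_high < 1.0 else 1.0
        return LogMixture(
            mu_low=base.mu_low - self.cccp_low_shift,
            sd_low=self.cccp_low_sd,
            mu_high=base.mu_high - self.cccp_high_shift,
            sd_high=self.cccp_high_sd,
            pi_high=pi_high,
        )


def simulate_events(
    cfg: CytometrySimConfig, condition: str, subject_id: str = "S000"
) -> pd.DataFrame:
    """Simulate one tube (lymphocytes + monocytes) under one condition.

    Returns an event table with columns ``subject_id, condition, FSC, SSC,
    CD14, FL_green, FL_red`` plus ``true_cell_type``, ``true_ros_high`` and
    ``true_psi_low`` ground-truth labels.  Deterministic in (cfg, condition).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    # condition-specific stream so tubes are independent but reproducible
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), CONDITIONS.index(condition)])
    )
    parts = []
    for cell_type, n, ros, scat, pma in (
        ("lymphocyte", cfg.n_lymph, cfg.lymph_ros, cfg.lymph_scatter, cfg.pma_shift_lymph),
        ("monocyte", cfg.n_mono, cfg.mono_ros, cfg.mono_scatter, cfg.pma_shift_mono),
    ):
        log_green, ros_hi = ros.sample(n, rng)
        if condition == "PMA":
            log_green = log_green + np.log10(pma)
        psi = cfg.psi_mixture(cell_type, condition)
        log_ratio, psi_hi = psi.sample(n, rng)
        parts.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "condition": condition,
                    "FSC": 10 ** rng.normal(scat.fsc_mu, scat.fsc_sd, n),
                    "SSC": 10 ** rng.normal(scat.ssc_mu, scat.ssc_sd, n),
                    "CD14": 10 ** rng.normal(scat.cd14_mu, scat.cd14_sd, n),
                    "FL_green": 10**log_green,
                    "FL_red": 10 ** (log_green + log_ratio),
                    "true_cell_type": cell_type,
                    "true_ros_high": ros_hi,
                    "true_psi_low": 1 - psi_hi,
                }
            )
        )
    out = pd.concat(parts, ignore_index=True)
    out.attrs["subject_id"] = subject_id
    out.attrs["condition"] = condition
    return out
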