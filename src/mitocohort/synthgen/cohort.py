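"""Synthetic five-group cohort with known subject-level ground truth.

The cohort design mirrors a cross-sectional HIV/antiretroviral-therapy study:
an uninfected control group, an untreated (ART-naive) infected group and three
first-line treatment groups.  Each subject carries latent traits that set the
parameters of their cytometry panel (ROS mixture means, JC-1 ratio mixtures,
PMA response) and, for imaged subjects, their cells' network morphology.

Viral load is lognormal in infected groups with a 40 copies/ml detection
floor (values below it are flagged censored, as in suppressed treated
patients).  Selected functional traits are coupled to log10 viral load through
a Gaussian copula: each trait's latent z is ``r * z_vl + sqrt(1-r^2) * eps``,
so the subject-level Pearson correlation between the trait and log viral load
approaches the configured ``r`` (up to the mild lognormal attenuation, which
is documented rather than corrected).

Group-level effect sizes follow the study's qualitative picture: infection
shifts lymphocyte parameters strongly, therapy partially rescues them, and
monocytes respond to therapy rather than to infection.  Printed subpopulation
fractions (high-ROS %, low-potential %) are used directly as the group truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events import CytometrySimConfig, simulate_events
from .imaging import CellImage, ImageSimConfig, render_cell_image
from .networks import InfeasibleNetworkError, generate_network

GROUPS = ("Control", "ART-naive", "2NRTI+1PI/r", "2NRTI+1NNRTI", "3NRTI")
INFECTED_GROUPS = GROUPS[1:]
TREATED_GROUPS = GROUPS[2:]

VIRAL_LOAD_FLOOR = 40.0  # copies/ml detection limit

# cohort-reported subpopulation fractions per group
LYMPH_PI_HIGH_ROS = {"Control": 0.554, "ART-naive": 0.480, "2NRTI+1PI/r": 0.551,
                     "2NRTI+1NNRTI": 0.501, "3NRTI": 0.476}
MONO_PI_HIGH_ROS = {"Control": 0.758, "ART-naive": 0.707, "2NRTI+1PI/r": 0.711,
                    "2NRTI+1NNRTI": 0.710, "3NRTI": 0.662}
LYMPH_PI_LOW_PSI = {"Control": 0.147, "ART-naive": 0.1256, "2NRTI+1PI/r": 0.170,
                    "2NRTI+1NNRTI": 0.153, "3NRTI": 0.163}


@dataclass(frozen=True)
class GroupEffect:
    """Additive decade shifts / multiplicative factors applied to the base
    cytometry panel for one cohort group."""

    lymph_ros_shift: float = 0.0      # decades on the high-ROS component mean
    lymph_pma_factor: float = 2.0     # PMA/basal green MFI factor, lymphocytes
    lymph_psi_low_shift: float = 0.0  # decades on the low-potential ratio mean
    mono_ros_shift: float = 0.0
    mono_pma_factor: float = 4.0
    mono_psi_shift: float = 0.0
    subject_sd_scale: float = 1.0     # heterogeneity multiplier


# infection hits lymphocytes (raised basal ROS, exhausted PMA reserve, deeper
# low-potential depolarization); therapy partially rescues lymphocytes and
# slightly perturbs monocytes; the 3NRTI group is the most heterogeneous
GROUP_EFFECTS: dict[str, GroupEffect] = {
    "Control": GroupEffect(),
    "ART-naive": GroupEffect(lymph_ros_shift=0.20, lymph_pma_factor=1.55,
                             lymph_psi_low_shift=-0.10),
    "2NRTI+1PI/r": GroupEffect(lymph_ros_shift=0.11, lymph_pma_factor=1.80,
                               lymph_psi_low_shift=-0.05, mono_ros_shift=0.03,
                               mono_pma_factor=3.6, mono_psi_shift=0.02),
    "2NRTI+1NNRTI": GroupEffect(lymph_ros_shift=0.16, lymph_pma_factor=1.65,
                                lymph_psi_low_shift=-0.08, mono_ros_shift=0.06,
                                mono_pma_factor=3.3, mono_psi_shift=0.04),
    "3NRTI": GroupEffect(lymph_ros_shift=0.09, lymph_pma_factor=1.85,
                         lymph_psi_low_shift=-0.04, mono_ros_shift=0.04,
                         mono_pma_factor=3.7, mono_psi_shift=0.03,
                         subject_sd_scale=1.6),
}


@dataclass(frozen=True)
class MorphologyParams:
    """Group-level network morphology truth for one cell type."""

    vv_pct: float
    n_fragments_mean: float
    branch_density: float


# infection lowers lymphocyte volume density and branching (fragmentation
# unchanged); therapy reverses density but not branching; monocyte networks
# respond to therapy (denser, more branched), not to infection
MORPHOLOGY: dict[str, dict[str, MorphologyParams]] = {
    "lymphocyte": {
        "Control": MorphologyParams(15.0, 5.0, 0.020),
        "ART-naive": MorphologyParams(10.5, 5.0, 0.011),
        "2NRTI+1PI/r": MorphologyParams(13.5, 5.0, 0.013),
        "2NRTI+1NNRTI": MorphologyParams(12.5, 5.0, 0.012),
        "3NRTI": MorphologyParams(13.0, 5.0, 0.012),
    },
    "monocyte": {
        "Control": MorphologyParams(15.0, 5.0, 0.015),
        "ART-naive": MorphologyParams(15.0, 5.0, 0.015),
        "2NRTI+1PI/r": MorphologyParams(19.0, 4.0, 0.022),
        "2NRTI+1NNRTI": MorphologyParams(19.0, 4.0, 0.022),
        "3NRTI": MorphologyParams(19.0, 4.0, 0.022),
    },
}

IMAGE_CFG = {
    "lymphocyte": ImageSimConfig(cell_radius_px=45.0, nucleus_radius_px=30.0),
    "monocyte": ImageSimConfig(cell_radius_px=70.0, nucleus_radius_px=25.0),
}


@dataclass(frozen=True)
class CohortSimConfig:
    """Design of one synthetic cohort draw."""

    group_sizes: dict = field(default_factory=lambda: {
        "Control": 49, "ART-naive": 49, "2NRTI+1PI/r": 27,
        "2NRTI+1NNRTI": 27, "3NRTI": 27,
    })
    subject_effect_sd: float = 0.08   # decades, between-subject spread of log-scale means
    pi_subject_sd: float = 0.05      # absolute spread of subpopulation fractions
    pma_subject_sd: float = 0.06      # decades on the log10 PMA factor
    viral_load_log_mu: float = 4.2    # ART-naive log10 copies/ml
    viral_load_log_sd: float = 0.8
    treated_log_mu: float = 1.2       # suppressed treated patients
    treated_log_sd: float = 0.4
    rho_ros_vl: float = 0.355         # lymph basal high-ROS MFI vs log10 VL
    rho_psi_vl: float = -0.417        # lymph high-potential ratio vs log10 VL
    rho_pct_low_vl: float = 0.457     # lymph low-potential % vs log10 VL
    rho_mono_psi_vl: float = -0.455   # monocyte potential ratio vs log10 VL
    n_lymph_events: int = 15000
    n_mono_events: int = 3000
    images_per_subject: int = 30      # per cell type, for imaged subjects
    imaging_subjects_per_group: int = 3
    base_cytometry: CytometrySimConfig = CytometrySimConfig()
    seed: int = 0

    def __post_init__(self):
        for r in (self.rho_ros_vl, self.rho_psi_vl, self.rho_pct_low_vl,
                  self.rho_mono_psi_vl):
            if not -1.0 < r < 1.0:
                raise ValueError("copula correlations must lie in (-1, 1)")
        if min(self.group_sizes.values()) < 2:
            raise ValueError("every group needs at least 2 subjects")


@dataclass
class CohortData:
    metadata: pd.DataFrame          # subject_id, group, viral_load, censored
    true_params: pd.DataFrame       # subject-level true functional parameters
    subject_configs: dict           # subject_id -> CytometrySimConfig
    events: dict | None = None      # subject_id -> {condition: event table}
    images: dict | None = None      # subject_id -> {cell_type: [CellImage, ...]}
    imaged_subjects: dict | None = None  # group -> {"min"/"med"/"max": subject_id}


def _coupled(rng: np.random.Generator, z_vl: float, rho: float) -> float:
    return rho * z_vl + np.sqrt(1.0 - rho**2) * rng.normal()


def draw_subject_traits(cfg: CohortSimConfig) -> CohortData:
    """Draw subject metadata, viral loads and true parameter values (no event
    tables or images) — the light-weight core of :func:`simulate_cohort`."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    base = cfg.base_cytometry
    ln10 = np.log(10.0)
    meta_rows, true_rows, configs = [], [], {}
    subj_idx = 0
    for group in GROUPS:
        if group not in cfg.group_sizes:
            continue
        eff = GROUP_EFFECTS[group]
        sd = cfg.subject_effect_sd * eff.subject_sd_scale
        pi_sd = cfg.pi_subject_sd * eff.subject_sd_scale
        for _ in range(int(cfg.group_sizes[group])):
            sid = f"S{subj_idx:03d}"
            subj_idx += 1
            z_vl = rng.normal()
            if group == "ART-naive":
                vl = 10 ** (cfg.viral_load_log_mu + cfg.viral_load_log_sd * z_vl)
            elif group in TREATED_GROUPS:
                vl = 10 ** (cfg.treated_log_mu + cfg.treated_log_sd * z_vl)
            else:
                vl = np.nan
            censored = bool(np.isnan(vl) or vl < VIRAL_LOAD_FLOOR)
            z_ros = _coupled(rng, z_vl, cfg.rho_ros_vl)
            z_psi = _coupled(rng, z_vl, cfg.rho_psi_vl)
            z_pct = _coupled(rng, z_vl, cfg.rho_pct_low_vl)
            z_mono = _coupled(rng, z_vl, cfg.rho_mono_psi_vl)

            lymph_ros = replace(
                base.lymph_ros,
                mu_high=base.lymph_ros.mu_high + eff.lymph_ros_shift + sd * z_ros,
                mu_low=base.lymph_ros.mu_low + sd * rng.normal(),
                pi_high=float(np.clip(LYMPH_PI_HIGH_ROS[group] + pi_sd * rng.normal(),
                                      0.05, 0.95)),
            )
            mono_ros = replace(
                base.mono_ros,
                mu_high=base.mono_ros.mu_high + eff.mono_ros_shift + sd * rng.normal(),
                mu_low=base.mono_ros.mu_low + sd * rng.normal(),
                pi_high=float(np.clip(MONO_PI_HIGH_ROS[group] + pi_sd * rng.normal(),
                                      0.05, 0.95)),
            )
            pi_low = float(np.clip(LYMPH_PI_LOW_PSI[group] + pi_sd * z_pct, 0.02, 0.60))
            lymph_psi = replace(
                base.lymph_psi,
                mu_high=base.lymph_psi.mu_high + sd * z_psi,
                mu_low=base.lymph_psi.mu_low + eff.lymph_psi_low_shift + sd * rng.normal(),
                pi_high=1.0 - pi_low,
            )
            mono_mu = base.mono_psi.mu_high + eff.mono_psi_shift + sd * z_mono
            mono_psi = replace(base.mono_psi, mu_high=mono_mu, mu_low=mono_mu)
            pma_l = eff.lymph_pma_factor * 10 ** (cfg.pma_subject_sd * rng.normal())
            pma_m = eff.mono_pma_factor * 10 ** (cfg.pma_subject_sd * rng.normal())

            scfg = replace(
                base,
                lymph_ros=lymph_ros, mono_ros=mono_ros,
                lymph_psi=lymph_psi, mono_psi=mono_psi,
                pma_shift_lymph=pma_l, pma_shift_mono=pma_m,
                n_lymph=cfg.n_lymph_events, n_mono=cfg.n_mono_events,
                seed=int(np.random.SeedSequence([int(cfg.seed), 1, subj_idx]).generate_state(1)[0] % 2**31),
            )
            configs[sid] = scfg
            meta_rows.append({"subject_id": sid, "group": group,
                              "viral_load": vl, "censored": censored})
            psi_sd_term = (base.lymph_psi.sd_high * ln10) ** 2 / 2.0
            true_rows.append({
                "subject_id": sid,
                "group": group,
                "lymph_a": lymph_ros.linear_mean("high"),
                "lymph_b": pma_l,
                "lymph_c_high": float(np.exp(lymph_psi.mu_high * ln10 + psi_sd_term)),
                "lymph_c_low": float(np.exp(
                    lymph_psi.mu_low * ln10 + (base.lymph_psi.sd_low * ln10) ** 2 / 2.0)),
                "lymph_c_low_pct": 100.0 * pi_low,
                "mono_a": mono_ros.linear_mean("high"),
                "mono_b": pma_m,
                "mono_c": float(np.exp(mono_mu * ln10 + (base.mono_psi.sd_high * ln10) ** 2 / 2.0)),
            })
    metadata = pd.DataFrame(meta_rows)
    true_params = pd.DataFrame(true_rows)
    return CohortData(metadata=metadata, true_params=true_params, subject_configs=configs)


def subject_event_tables(scfg: CytometrySimConfig, subject_id: str) -> dict[str, pd.DataFrame]:
    return {cond: simulate_events(scfg, cond, subject_id)
            for cond in ("basal", "PMA", "CCCP")}


def _imaging_selection(data: CohortData, per_group: int) -> dict[str, dict[str, str]]:
    """Representative subjects per group by basal high-ROS lymphocyte MFI:
    minimal, median-rank and maximal (the imaging selection rule)."""
    from ..cohortstats import select_representative_subjects

    out = {}
    tp = data.true_params
    for group, sub in tp.groupby("group", sort=False):
        series = pd.Series(sub["lymph_a"].to_numpy(), index=sub["subject_id"])
        out[group] = select_representative_subjects(series)
    return out


def subject_cell_images(
    data: CohortData,
    subject_id: str,
    images_per_subject: int,
    seed: int,
) -> dict[str, list[CellImage]]:
    """Render one subject's image batch (both cell types) from their group's
    morphology truth plus subject- and cell-level jitter."""
    group = data.metadata.set_index("subject_id").loc[subject_id, "group"]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    out: dict[str, list[CellImage]] = {}
    for cell_type in ("lymphocyte", "monocyte"):
        mp = MORPHOLOGY[cell_type][group]
        icfg = IMAGE_CFG[cell_type]
        subj_vv = float(np.clip(mp.vv_pct + rng.normal(0, 1.2), 3.0, 30.0))
        subj_bd = float(max(0.0, mp.branch_density + rng.normal(0, 0.0015)))
        cells = []
        for c in range(images_per_subject):
            vv = float(np.clip(rng.normal(subj_vv, 1.0), 3.0, 30.0))
            nf = max(1, int(rng.poisson(mp.n_fragments_mean)))
            bd = float(max(0.0, rng.normal(subj_bd, 0.001)))
            net_seed = int(rng.integers(0, 2**31 - 1))
            try:
                truth = generate_network(
                    icfg.cell_radius_px - 4, vv, nf, bd, tube_radius_px=2,
                    seed=net_seed,
                )
            except InfeasibleNetworkError:
                truth = generate_network(
                    icfg.cell_radius_px - 4, vv, max(1, nf - 2), bd,
                    tube_radius_px=2, seed=net_seed + 1,
                )
            img = render_cell_image(
                truth, replace(icfg, seed=int(rng.integers(0, 2**31 - 1))),
                cell_id=f"{subject_id}_{cell_type[:1]}{c:02d}",
                cell_type=cell_type,
            )
            cells.append(img)
        out[cell_type] = cells
    return out


def simulate_cohort(
    cfg: CohortSimConfig,
    include_events: bool = True,
    include_images: bool = True,
) -> CohortData:
    """Full cohort draw: metadata + true parameters, per-subject event tables
    for the three conditions and, for the representative imaging subset
    (min/median/max basal high-ROS MFI per group), rendered cell image batches.
    """
    data = draw_subject_traits(cfg)
    if include_events:
        data.events = {
            sid: subject_event_tables(scfg, sid)
            for sid, scfg in data.subject_configs.items()
        }
    if include_images and cfg.images_per_subject > 0:
        data.imaged_subjects = _imaging_selection(data, cfg.imaging_subjects_per_group)
        data.images = {}
        for group, picks in data.imaged_subjects.items():
            for sid in dict.fromkeys(picks.values()):
                data.images[sid] = subject_cell_images(
                    data, sid, cfg.images_per_subject,
                    seed=int(np.random.SeedSequence(
                        [int(cfg.seed), 2, int(sid[1:])]).generate_state(1)[0] % 2**31),
                )
    return data
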