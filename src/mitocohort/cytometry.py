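"""Event-level cytometry analysis: gating, ROS subpopulation splitting, JC-1
membrane-potential ratios with depolarization-calibrated quadrants, and the
per-subject functional parameter vectors.

Subpopulation boundaries that an operator would place by hand on a cytometer
are standardized here as BIC-selected one- vs two-component Gaussian mixtures
on log10 intensity, with the split point at the equal-posterior crossing.
MFI (mean fluorescence intensity) is the arithmetic mean of linear intensities
within the events assigned to a component.

The ΔΨm (inner membrane potential) proxy is the per-event JC-1 red/green
ratio.  The quadrant marker separating low- from high-potential lymphocytes is
calibrated per subject on the CCCP (depolarized) tube — the upper edge of the
collapsed mode, mean + 2 SD on the log ratio — and then applied unchanged to
the basal tube.  Monocytes show a single potential population and are never
split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

log = logging.getLogger(__name__)

MIN_GATE_EVENTS = 100


class CalibrationError(ValueError):
    """CCCP tube does not look depolarized relative to basal (swapped tubes?)."""


class MissingConditionError(KeyError):
    """A required acquisition condition is absent for this subject."""


@dataclass(frozen=True)
class GateConfig:
    """Scatter rectangle for lymphocytes and the CD14 fallback boundary (linear)."""

    fsc_min: float = 10**1.85
    fsc_max: float = 10**2.15
    ssc_min: float = 10**1.50
    ssc_max: float = 10**1.90
    cd14_fallback: float = 10**1.25


@dataclass
class RosSplit:
    bimodal: bool
    log_threshold: float
    pi_high: float
    mfi_low: float
    sd_low: float
    mfi_high: float
    sd_high: float
    n_events: int
    fallback: bool = False


@dataclass
class PsiResult:
    ratio_threshold: float | None
    pct_low: float
    mean_ratio_high: float
    mean_ratio_low: float
    mean_ratio: float
    n_events: int
    n_excluded: int


@dataclass
class SubjectFunctionalVector:
    """The functional parameter vector: 8 entries for lymphocytes
    (a, b, c_high, c_low, c_low_pct, d_high, d_low, d_low_pct),
    4 for monocytes (a, b, c, d)."""

    subject_id: str
    cell_type: str
    values: dict[str, float]

    LYMPH_KEYS = ("a", "b", "c_high", "c_low", "c_low_pct", "d_high", "d_low", "d_low_pct")
    MONO_KEYS = ("a", "b", "c", "d")

    def to_series(self) -> pd.Series:
        keys = self.LYMPH_KEYS if self.cell_type == "lymphocyte" else self.MONO_KEYS
        return pd.Series({k: self.values[k] for k in keys}, name=self.subject_id)


# ---------------------------------------------------------------------------
# gating

def _cd14_threshold(cd14: np.ndarray, cfg: GateConfig) -> float:
    """Valley of the log10 CD14 distribution; falls back to a fixed boundary
    when the distribution is not clearly bimodal."""
    x = np.log10(cd14[cd14 > 0])
    hist, edges = np.histogram(x, bins=128)
    sm = gaussian_filter1d(hist.astype(float), 2.0)
    peaks, _ = find_peaks(sm, prominence=0.02 * sm.max())
    if len(peaks) >= 2:
        top2 = peaks[np.argsort(sm[peaks])[-2:]]
        lo, hi = sorted(top2)
        # a genuine negative/positive split is at least half a decade wide;
        # closer peaks are histogram noise within a single population
        if edges[hi] - edges[lo] > 0.5:
            valley = lo + int(np.argmin(sm[lo : hi + 1]))
            return float(10 ** ((edges[valley] + edges[valley + 1]) / 2.0))
    return cfg.cd14_fallback


def gate_populations(
    events: pd.DataFrame, cfg: GateConfig = GateConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split one tube into (lymphocytes, monocytes).

    Monocytes are CD14-positive events (above the valley of the CD14
    log-distribution).  Lymphocytes are events inside the FSC/SSC rectangle
    that are CD14-negative, so no CD14+ cell survives the lymphocyte gate.
    Idempotent: gating an already-gated table returns it unchanged.
    """
    required = {"FSC", "SSC", "CD14", "FL_green", "FL_red"}
    missing = required - set(events.columns)
    if missing:
        raise KeyError(f"event table lacks columns: {sorted(missing)}")
    thr = _cd14_threshold(events["CD14"].to_numpy(), cfg)
    cd14_pos = events["CD14"] > thr
    mono = events[cd14_pos].copy()
    in_rect = (
        events["FSC"].between(cfg.fsc_min, cfg.fsc_max)
        & events["SSC"].between(cfg.ssc_min, cfg.ssc_max)
    )
    lymph = events[in_rect & ~cd14_pos].copy()
    for name, tbl in (("lymphocyte", lymph), ("monocyte", mono)):
        tbl.attrs.update(events.attrs)
        tbl.attrs["population"] = name
        tbl.attrs["low_n"] = len(tbl) < MIN_GATE_EVENTS
        if tbl.attrs["low_n"]:
            log.warning("gate %s holds only %d events", name, len(tbl))
    return lymph, mono


# ---------------------------------------------------------------------------
# mixture machinery

def _fit_gmm(x: np.ndarray, k: int, seed: int = 0) -> GaussianMixture:
    X = x.reshape(-1, 1)
    if k == 1:
        means = np.array([[x.mean()]])
    else:
        means = np.quantile(x, [0.25, 0.75]).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=k, covariance_type="full", means_init=means,
        n_init=1, random_state=seed, reg_covar=1e-6, max_iter=500, tol=1e-6,
    )
    with warnings.catch_warnings():
        # a tight tolerance occasionally hits max_iter; the fit is still fine
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm.fit(X)
    return gm

def _equal_posterior_threshold(gm: GaussianMixture) -> float:
    """Point between the two component means where posteriors cross (solved on
    the quadratic of the two log densities; grid fallback for edge cases)."""
    (m1,), (m2,) = gm.means_
    s1, s2 = np.sqrt(gm.covariances_[:, 0, 0])
    w1, w2 = gm.weights_
    if m1 > m2:
        m1, m2, s1, s2, w1, w2 = m2, m1, s2, s1, w2, w1
    a = 1 / (2 * s2**2) - 1 / (2 * s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2) + np.log((w1 * s2) / (w2 * s1))
    if abs(a) < 1e-12:
        roots = np.array([-c / b]) if abs(b) > 1e-12 else np.array([])
    else:
        disc = b**2 - 4 * a * c
        roots = (-b + np.array([1.0, -1.0]) * np.sqrt(max(disc, 0.0))) / (2 * a)
    inside = [r for r in np.atleast_1d(roots) if m1 <= r <= m2]
    if inside:
        return float(inside[0])
    return float((m1 + m2) / 2.0)


# ---------------------------------------------------------------------------
# ROS

def split_ros(
    events: pd.DataFrame,
    delta_decades: float = 0.15,
    min_weight: float = 0.01,
    seed: int = 0,
) -> RosSplit:
    """Low/high-ROS subpopulation split on log10 green fluorescence.

    The population is called bimodal when the two-component mixture wins by BIC
    *and* the component means differ by more than ``delta_decades`` *and* both
    weights exceed ``min_weight``; otherwise the whole-population MFI is
    reported (``pi_high`` undefined, components degenerate to the population).

    ``pi_high`` is the fitted weight of the high component — the model-based
    fraction of high-ROS events, which stays unbiased when the components
    overlap; component MFIs use the hard assignment at the equal-posterior
    threshold, matching how an operator reads marker-split statistics.
    """
    green = events["FL_green"].to_numpy()
    keep = green > 0
    x = np.log10(green[keep])
    if len(x) < MIN_GATE_EVENTS:
        raise ValueError(f"need >= {MIN_GATE_EVENTS} events, got {len(x)}")
    gm1 = _fit_gmm(x, 1, seed)
    gm2 = _fit_gmm(x, 2, seed)
    X = x.reshape(-1, 1)
    separation = float(abs(gm2.means_[1, 0] - gm2.means_[0, 0]))
    fallback = bool(gm2.weights_.min() < min_weight)
    bimodal = (
        gm2.bic(X) < gm1.bic(X) and separation > delta_decades and not fallback
    )
    lin = green[keep]
    if not bimodal:
        return RosSplit(
            bimodal=False, log_threshold=float("nan"), pi_high=float("nan"),
            mfi_low=float("nan"), sd_low=float("nan"),
            mfi_high=float(lin.mean()), sd_high=float(lin.std()),
            n_events=len(x), fallback=fallback,
        )
    thr = _equal_posterior_threshold(gm2)
    hi = x > thr
    hi_comp = int(np.argmax(gm2.means_[:, 0]))
    return RosSplit(
        bimodal=True,
        log_threshold=thr,
        pi_high=float(gm2.weights_[hi_comp]),
        mfi_low=float(lin[~hi].mean()),
        sd_low=float(lin[~hi].std()),
        mfi_high=float(lin[hi].mean()),
        sd_high=float(lin[hi].std()),
        n_events=len(x),
    )


# ---------------------------------------------------------------------------
# membrane potential

def _log_ratio(events: pd.DataFrame) -> tuple[np.ndarray, int]:
    green = events["FL_green"].to_numpy()
    red = events["FL_red"].to_numpy()
    ok = (green > 0) & (red > 0)
    return np.log10(red[ok] / green[ok]), int((~ok).sum())


def calibrate_quadrant(
    cccp_events: pd.DataFrame,
    basal_events: pd.DataFrame | None = None,
    seed: int = 0,
) -> float:
    """Quadrant marker (linear red/green ratio) from the CCCP tube.

    A two-component mixture is fit to the log10 ratio of the depolarized tube;
    the threshold is the collapsed (lower) component's mean + 2 SD.  When the
    basal tube is supplied, a sanity check requires the CCCP ratio distribution
    to be left-shifted; otherwise the tubes were probably swapped.
    """
    cond = cccp_events["condition"].iloc[0] if "condition" in cccp_events else None
    if cond is not None and cond != "CCCP":
        raise CalibrationError(f"expected a CCCP tube, got condition={cond!r}")
    r, _ = _log_ratio(cccp_events)
    if len(r) < MIN_GATE_EVENTS:
        raise ValueError(f"need >= {MIN_GATE_EVENTS} CCCP events")
    if basal_events is not None:
        rb, _ = _log_ratio(basal_events)
        if r.mean() >= rb.mean():
            raise CalibrationError(
                "CCCP ratio distribution is not left-shifted versus basal; "
                "check that the conditions are not swapped"
            )
    gm = _fit_gmm(r, 2, seed)
    lo = int(np.argmin(gm.means_[:, 0]))
    mu = float(gm.means_[lo, 0])
    sd = float(np.sqrt(gm.covariances_[lo, 0, 0]))
    return float(10 ** (mu + 2.0 * sd))


def compute_psi(
    events: pd.DataFrame, threshold: float | None, cell_type: str = "lymphocyte"
) -> PsiResult:
    """Per-event ΔΨm proxy (red/green) summarized against a quadrant marker.

    Lymphocytes are split at ``threshold`` into low/high-potential
    subpopulations; monocytes (or ``threshold=None``) report the overall mean
    ratio only.  Events with nonpositive intensities are excluded and counted.
    """
    logr, n_excl = _log_ratio(events)
    if n_excl:
        log.info("compute_psi: excluded %d nonpositive-intensity events", n_excl)
    ratio = 10**logr
    mean_ratio = float(ratio.mean())
    if threshold is None or cell_type == "monocyte":
        return PsiResult(None, float("nan"), float("nan"), float("nan"),
                         mean_ratio, len(ratio), n_excl)
    low = ratio < threshold
    return PsiResult(
        ratio_threshold=float(threshold),
        pct_low=float(100.0 * low.mean()),
        mean_ratio_high=float(ratio[~low].mean()) if (~low).any() else float("nan"),
        mean_ratio_low=float(ratio[low].mean()) if low.any() else float("nan"),
        mean_ratio=mean_ratio,
        n_events=len(ratio),
        n_excluded=n_excl,
    )


# ---------------------------------------------------------------------------
# subject vectors

def assemble_vector(
    subject_id: str,
    ros_basal: RosSplit,
    ros_pma: RosSplit,
    psi_basal: PsiResult,
    psi_cccp: PsiResult,
    cell_type: str,
) -> SubjectFunctionalVector:
    """Fold per-condition statistics into the subject's functional vector."""
    for name, obj in (("ros_basal", ros_basal), ("ros_pma", ros_pma),
                      ("psi_basal", psi_basal), ("psi_cccp", psi_cccp)):
        if obj is None:
            raise MissingConditionError(f"{subject_id}/{cell_type}: missing {name}")
    a = ros_basal.mfi_high
    b = ros_pma.mfi_high / ros_basal.mfi_high
    if cell_type == "monocyte":
        values = {
            "a": a,
            "b": b,
            "c": psi_basal.mean_ratio,
            "d": psi_basal.mean_ratio / psi_cccp.mean_ratio,
        }
    else:
        values = {
            "a": a,
            "b": b,
            "c_high": psi_basal.mean_ratio_high,
            "c_low": psi_basal.mean_ratio_low,
            "c_low_pct": psi_basal.pct_low,
            "d_high": psi_basal.mean_ratio_high / psi_cccp.mean_ratio_high,
            "d_low": psi_basal.mean_ratio_low / psi_cccp.mean_ratio_low,
            "d_low_pct": psi_cccp.pct_low / psi_basal.pct_low
            if psi_basal.pct_low > 0 else float("nan"),
        }
    return SubjectFunctionalVector(subject_id, cell_type, values)


def analyze_subject(
    tables: dict[str, pd.DataFrame],
    subject_id: str = "",
    gate_cfg: GateConfig = GateConfig(),
    delta_decades: float = 0.15,
    min_weight: float = 0.01,
    seed: int = 0,
) -> dict[str, SubjectFunctionalVector]:
    """Full per-subject pipeline from raw tubes {condition: event table} to the
    lymphocyte (8-dim) and monocyte (4-dim) functional vectors."""
    for cond in ("basal", "PMA", "CCCP"):
        if cond not in tables:
            raise MissingConditionError(f"{subject_id}: no {cond} tube")
    gated = {cond: gate_populations(tbl, gate_cfg) for cond, tbl in tables.items()}
    out = {}
    for ct, idx in (("lymphocyte", 0), ("monocyte", 1)):
        ros_b = split_ros(gated["basal"][idx], delta_decades, min_weight, seed)
        ros_p = split_ros(gated["PMA"][idx], delta_decades, min_weight, seed)
        if ct == "lymphocyte":
            thr = calibrate_quadrant(gated["CCCP"][idx], gated["basal"][idx], seed)
        else:
            thr = None
        psi_b = compute_psi(gated["basal"][idx], thr, ct)
        psi_c = compute_psi(gated["CCCP"][idx], thr, ct)
        out[ct] = assemble_vector(subject_id, ros_b, ros_p, psi_b, psi_c, ct)
    return out
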