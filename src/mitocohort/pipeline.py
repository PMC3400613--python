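"""End-to-end orchestration: synthetic cohort -> event analysis -> subject
vectors -> discriminant and univariate statistics, with a run report that
enumerates every exclusion.

This module is the library behind both the command line and the analysis
scripts; each stage is usable on its own.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd

from . import cohortstats, cytometry, discrim, morphometry
from .config import RunConfig, RunReport
from .synthgen.cohort import CohortData, simulate_cohort

log = logging.getLogger(__name__)


def subject_vectors(
    cohort: CohortData, cfg: RunConfig, report: RunReport | None = None
) -> dict[str, pd.DataFrame]:
    """Per-subject functional vectors for both cell types.

    Returns {"lymphocyte": df, "monocyte": df}; rows are subjects, columns the
    vector entries plus ``group``.  Subjects whose tubes fail analysis are
    excluded and recorded in the report.
    """
    gate_cfg = cytometry.GateConfig(
        fsc_min=cfg.gate_fsc_min, fsc_max=cfg.gate_fsc_max,
        ssc_min=cfg.gate_ssc_min, ssc_max=cfg.gate_ssc_max,
    )
    groups = cohort.metadata.set_index("subject_id")["group"]
    rows: dict[str, list[pd.Series]] = {"lymphocyte": [], "monocyte": []}
    for sid, tables in (cohort.events or {}).items():
        try:
            vecs = cytometry.analyze_subject(
                tables, sid, gate_cfg, cfg.ros_delta_decades,
                cfg.ros_min_weight, cfg.seed,
            )
        except (cytometry.CalibrationError, cytometry.MissingConditionError,
                ValueError) as err:
            log.warning("subject %s excluded from vectors: %s", sid, err)
            if report is not None:
                report.exclude("cytometry", sid, str(err))
            continue
        for ct, vec in vecs.items():
            s = vec.to_series()
            if not np.all(np.isfinite(s.to_numpy(dtype=float))):
                if report is not None:
                    report.exclude("cytometry", f"{sid}/{ct}", "non-finite vector entry")
                continue
            s["group"] = groups.loc[sid]
            rows[ct].append(s.rename(sid))
    out = {}
    for ct, lst in rows.items():
        df = pd.DataFrame(lst)
        df.index.name = "subject_id"
        out[ct] = df
    return out


def morphometry_table(
    cohort: CohortData, report: RunReport | None = None
) -> pd.DataFrame:
    """Stereological records for every rendered cell, tagged with group."""
    if not cohort.images:
        raise ValueError("cohort carries no images; simulate with images enabled")
    groups = cohort.metadata.set_index("subject_id")["group"]
    frames = []
    for sid, by_type in cohort.images.items():
        for ct, imgs in by_type.items():
            records, failures = morphometry.batch_morphometry(imgs, [sid] * len(imgs))
            if report is not None:
                for _, row in failures.iterrows():
                    report.exclude("morphometry", row["cell_id"], row["reason"])
            records["group"] = groups.loc[sid]
            frames.append(records)
    return pd.concat(frames, ignore_index=True)


def discriminant_summary(
    df: pd.DataFrame, parameters: list[str], level: float = 0.95
) -> dict:
    """Fit canonical axes on ``parameters`` with ``df['group']`` labels and
    report the tests, variance fractions and confidence circles."""
    X = df[parameters]
    groups = df["group"].to_numpy()
    model = discrim.fit_cda(X, groups)
    tests = discrim.test_groups(model, X, groups)
    circles = discrim.confidence_circles(model, level)
    return {
        "model": model,
        "tests": tests,
        "circles": circles,
        "variance_fraction": model.variance_fraction,
        "combined_variance_pct_2axes": float(
            100.0 * model.variance_fraction[: min(2, len(model.variance_fraction))].sum()
        ),
    }


# the functional parameters correlated with viral load: basal high-ROS MFI and
# the potential-related lymphocyte parameters, plus monocyte potential
VL_CORRELATIONS = [
    ("lymphocyte", "a", "ROS production by high-ROS lymphocytes"),
    ("lymphocyte", "c_high", "potential of high-potential lymphocytes"),
    ("lymphocyte", "c_low_pct", "% low-potential lymphocytes"),
    ("monocyte", "a", "ROS production by high-ROS monocytes"),
    ("monocyte", "c", "potential of monocytes"),
]


def viral_load_correlations(
    vectors: dict[str, pd.DataFrame], metadata: pd.DataFrame,
    group: str = "ART-naive",
) -> pd.DataFrame:
    """Pearson correlations between functional parameters and log10 viral load
    in uncensored subjects of one group (the untreated patients)."""
    meta = metadata.set_index("subject_id")
    rows = []
    for ct, param, label in VL_CORRELATIONS:
        df = vectors[ct]
        sel = df[df["group"] == group]
        vl = meta.loc[sel.index, "viral_load"]
        cen = meta.loc[sel.index, "censored"]
        ok = ~cen
        res = cohortstats.correlate(
            vl[ok].to_numpy(), sel.loc[ok, param].to_numpy(dtype=float),
            log_x=True, x_name="log10 viral load", y_name=label,
        )
        rows.append({"cell_type": ct, "parameter": param, "label": label,
                     "r": res.r, "n": res.n, "p_value": res.p_value,
                     "n_censored_excluded": int(cen.sum())})
    return pd.DataFrame(rows)


def run_all(cfg: RunConfig) -> tuple[RunReport, dict]:
    """The whole study pipeline on one synthetic cohort draw."""
    report = RunReport(config_hash=cfg.config_hash(), seed=cfg.seed)
    import mitocohort
    report.versions = {"mitocohort": mitocohort.__version__,
                       "numpy": np.__version__, "pandas": pd.__version__}
    cohort = simulate_cohort(
        cfg.cohort_config(),
        include_events=cfg.run_cytometry,
        include_images=cfg.run_morphometry and cfg.images_per_subject > 0,
    )
    report.stage_counts["subjects"] = len(cohort.metadata)
    results: dict = {"metadata": cohort.metadata, "true_params": cohort.true_params}

    if cfg.run_cytometry:
        vectors = subject_vectors(cohort, cfg, report)
        results["vectors"] = vectors
        report.stage_counts["lymphocyte_vectors"] = len(vectors["lymphocyte"])
        report.stage_counts["monocyte_vectors"] = len(vectors["monocyte"])

    if cfg.run_morphometry and cohort.images:
        morpho = morphometry_table(cohort, report)
        results["morphometry"] = morpho
        report.stage_counts["cells_analyzed"] = len(morpho)

    if cfg.run_discrim and "vectors" in results:
        summaries = {}
        for ct, params in (
            ("lymphocyte", list(cytometry.SubjectFunctionalVector.LYMPH_KEYS)),
            ("monocyte", list(cytometry.SubjectFunctionalVector.MONO_KEYS)),
        ):
            summaries[f"functional_{ct}"] = discriminant_summary(
                results["vectors"][ct], params, cfg.circle_confidence)
        if "morphometry" in results:
            for ct in ("lymphocyte", "monocyte"):
                sub = results["morphometry"]
                sub = sub[sub["cell_type"] == ct]
                summaries[f"morphological_{ct}"] = discriminant_summary(
                    sub, ["vv_pct", "fragmentation", "branching"],
                    cfg.circle_confidence)
        results["discriminant"] = summaries

    if cfg.run_stats and "vectors" in results:
        results["correlations"] = viral_load_correlations(
            results["vectors"], cohort.metadata)
    results["report"] = report
    return report, results


def format_test_report(name: str, summary: dict) -> str:
    """Human-readable block mirroring a figure-legend style summary."""
    t = summary["tests"]
    lines = [
        f"== {name} ==",
        f"combined variance of first two axes: {summary['combined_variance_pct_2axes']:.2f}%",
        f"Wilks' Lambda = {t.wilks_lambda:.4f}, Rao's F({t.df1:.0f}, {t.df2:.1f}) = "
        f"{t.rao_F:.3f}, p = {t.p_value:.2e}",
        f"Roy's greatest root = {t.roys_root:.4f}, F({t.roy_df1:.0f}, {t.roy_df2:.0f}) = "
        f"{t.roy_F:.3f}, p = {t.roy_p:.2e}",
        "pairwise Bonferroni-adjusted p-values:",
        t.pairwise_p.round(4).to_string(),
    ]
    return "\n".join(lines)
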