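"""Self-contained recovery and validation experiments.

Each function simulates its own inputs from a seed, runs the relevant pipeline
stage, and returns the measured quantities.  They back the acceptance tests,
the acceptance script and the numbered analysis scripts, so every reported
number is recomputed from scratch at run time.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, stats

from . import cohortstats, cytometry, discrim, morphometry, pipeline
from .synthgen import (
    CohortSimConfig,
    CytometrySimConfig,
    ImageSimConfig,
    draw_subject_traits,
    generate_network,
    render_cell_image,
    simulate_cohort,
    simulate_events,
)
from .morphometry import SegmentationResult, skeletonize_network


# ---------------------------------------------------------------------------
# skeleton taxonomy vs brute force

def _brute_taxonomy(sk: np.ndarray):
    counts = {0: 0, 1: 0, 2: 0, 3: 0}
    h, w = sk.shape
    for r, c in np.argwhere(sk):
        n = 0
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr or dc) and 0 <= r + dr < h and 0 <= c + dc < w and sk[r + dr, c + dc]:
                    n += 1
        counts[min(n, 3)] += 1
    seen = np.zeros_like(sk, dtype=bool)
    frags = 0
    for r0, c0 in np.argwhere(sk):
        if seen[r0, c0]:
            continue
        frags += 1
        stack = [(r0, c0)]
        while stack:
            r, c = stack.pop()
            if seen[r, c]:
                continue
            seen[r, c] = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (dr or dc) and 0 <= rr < h and 0 <= cc < w and sk[rr, cc]:
                        stack.append((rr, cc))
    return counts, frags


def skeleton_oracle_agreement(seed: int = 0, n_masks: int = 50) -> dict:
    """Fraction (%) of random masks on which the pixel-class counts and the
    fragment count equal exhaustive neighbour counting / flood fill."""
    rng = np.random.default_rng(seed)
    agree = 0
    total = 0
    for _ in range(n_masks):
        mask = rng.random((28, 28)) < 0.25
        if not mask.any():
            continue
        total += 1
        sk = skeletonize_network(
            SegmentationResult(np.ones_like(mask), mask, 0, 0), prune_spurs_px=0
        )
        counts, frags = _brute_taxonomy(sk.skeleton_mask)
        ok = (
            sk.n_isolated == counts[0] and sk.n_ends == counts[1]
            and sk.n_through == counts[2] and sk.n_branch == counts[3]
            and sk.n_fragments == frags
            and sum(counts.values()) == sk.total_length_px
        )
        agree += ok
    return {"agreement_pct": 100.0 * agree / total, "n": total}


def stereology_closed_form(seed: int = 0) -> dict:
    """Volume-density error (percentage points) of a noise-free render and the
    closed-form line/cross skeleton checks (0 = all exact)."""
    truth = generate_network(66, 15.0, 4, 0.01, tube_radius_px=1, seed=seed)
    cfg = ImageSimConfig(image_size_px=(180, 180), cell_radius_px=70,
                         psf_sigma_px=0.0, noise_gaussian_sd=0.0, seed=0)
    rec = morphometry.analyze_cell(render_cell_image(truth, cfg))
    vv_err = abs(rec.vv_pct - truth.target_vv_pct)

    line = np.zeros((7, 9), dtype=bool)
    line[3, 2:7] = True
    sk = skeletonize_network(SegmentationResult(np.ones_like(line), line, 0, 0))
    line_ok = (sk.n_ends, sk.n_through, sk.n_branch, sk.n_fragments) == (2, 3, 0, 1)
    srec = morphometry.compute_stereology(
        SegmentationResult(np.ones_like(line), line, 0, 0), sk)
    line_ok &= srec.fragmentation == 1 / 5 and srec.branching == 0.0

    cross = np.zeros((7, 7), dtype=bool)
    cross[3, 3] = True
    for dr, dc in ((-1, -1), (-1, 1), (1, -1), (1, 1)):
        cross[3 + dr, 3 + dc] = True
    skx = skeletonize_network(SegmentationResult(np.ones_like(cross), cross, 0, 0))
    cross_ok = (skx.n_branch, skx.n_ends, skx.n_fragments) == (1, 4, 1)
    return {
        "vv_abs_error_pct_points": float(vv_err),
        "fixtures_exact": bool(line_ok and cross_ok),
        "fragments_exact": rec.n_fragments == truth.n_fragments,
    }


# ---------------------------------------------------------------------------
# morphometry parameter recovery

GRID_VV = (5.0, 15.0, 30.0)
GRID_FRAGMENTS = (1, 5, 10)
GRID_BRANCH_DENSITY = (0.0, 0.015, 0.03)


def morphometry_recovery(
    seed: int = 0,
    replicates: int = 2,
    cell_radius_px: float = 120.0,
    image_size: int = 300,
    psf_sigma_px: float = 1.0,
    noise_sd: float = 3.0,
) -> dict:
    """Rank correlation between configured truth and measured values of the
    three stereological parameters over the density x fragmentation x
    branching grid (``replicates`` networks per grid point, per-point means)."""
    rng = np.random.default_rng(seed)
    agg = {k: ([], []) for k in ("vv", "fragmentation", "branching")}
    for vv in GRID_VV:
        for nf in GRID_FRAGMENTS:
            for bd in GRID_BRANCH_DENSITY:
                tt = {k: [] for k in agg}
                ms = {k: [] for k in agg}
                for _ in range(replicates):
                    net_seed = int(rng.integers(0, 2**31 - 1))
                    truth = generate_network(cell_radius_px, vv, nf, bd,
                                             tube_radius_px=2, seed=net_seed)
                    cfg = ImageSimConfig(
                        image_size_px=(image_size, image_size),
                        cell_radius_px=cell_radius_px + 2,
                        psf_sigma_px=psf_sigma_px, noise_gaussian_sd=noise_sd,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    rec = morphometry.analyze_cell(render_cell_image(truth, cfg))
                    tt["vv"].append(truth.target_vv_pct)
                    ms["vv"].append(rec.vv_pct)
                    tt["fragmentation"].append(truth.n_fragments / truth.total_length_px)
                    ms["fragmentation"].append(rec.fragmentation)
                    tt["branching"].append(truth.n_branch_nodes / truth.total_length_px)
                    ms["branching"].append(rec.branching)
                for k in agg:
                    agg[k][0].append(np.mean(tt[k]))
                    agg[k][1].append(np.mean(ms[k]))
    return {
        f"spearman_{k}": float(stats.spearmanr(t, m).statistic)
        for k, (t, m) in agg.items()
    }


# ---------------------------------------------------------------------------
# subpopulation-fraction recovery (control settings)

def subpopulation_recovery(
    seed: int = 0, n_seeds: int = 50, n_lymph: int = 6000, n_mono: int = 2500
) -> dict:
    """Mean recovered high-ROS fractions (lymphocyte, monocyte) and
    low-potential lymphocyte percentage at the control-group settings."""
    rng = np.random.default_rng(seed)
    pis_l, pis_m, pcts = [], [], []
    for _ in range(n_seeds):
        cfg = CytometrySimConfig(seed=int(rng.integers(0, 2**31 - 1)),
                                 n_lymph=n_lymph, n_mono=n_mono)
        basal = simulate_events(cfg, "basal")
        cccp = simulate_events(cfg, "CCCP")
        lymb, mono = cytometry.gate_populations(basal)
        lymc, _ = cytometry.gate_populations(cccp)
        pis_l.append(cytometry.split_ros(lymb).pi_high)
        pis_m.append(cytometry.split_ros(mono).pi_high)
        thr = cytometry.calibrate_quadrant(lymc, lymb)
        pcts.append(cytometry.compute_psi(lymb, thr, "lymphocyte").pct_low)
    return {
        "pct_high_ros_lymphocytes": float(100 * np.mean(pis_l)),
        "pct_high_ros_monocytes": float(100 * np.mean(pis_m)),
        "pct_low_psi_lymphocytes": float(np.mean(pcts)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# viral-load correlation recovery

def correlation_recovery(seed: int = 0, n_reps: int = 200, n_subjects: int = 44) -> dict:
    """Mean recovered Pearson r between subject parameters and log10 viral
    load over replicate untreated-group draws."""
    rs = {"lymph_ros": [], "lymph_psi_high": [], "lymph_pct_low": [], "mono_psi": []}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cfg = CohortSimConfig(
            group_sizes={"ART-naive": n_subjects}, images_per_subject=0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        data = draw_subject_traits(cfg)
        merged = data.true_params.merge(data.metadata, on="subject_id")
        ok = ~merged["censored"]
        vl = merged.loc[ok, "viral_load"].to_numpy()
        for key, col in (("lymph_ros", "lymph_a"), ("lymph_psi_high", "lymph_c_high"),
                         ("lymph_pct_low", "lymph_c_low_pct"), ("mono_psi", "mono_c")):
            rs[key].append(
                cohortstats.correlate(vl, merged.loc[ok, col].to_numpy(), log_x=True).r
            )
    return {f"r_{k}": float(np.mean(v)) for k, v in rs.items()} | {"n_reps": n_reps}


# ---------------------------------------------------------------------------
# discriminant numerical checks

def discriminant_checks(seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    means = rng.normal(0, 1.0, (5, 8))
    X = np.vstack([rng.normal(means[i], 1.0, (12, 8)) for i in range(5)])
    groups = np.repeat([f"g{i}" for i in range(5)], 12)
    model = discrim.fit_cda(X, groups)
    H, E, _ = discrim._sscp(X, groups)
    ref = np.sort(np.real(linalg.eig(np.linalg.solve(E, H))[0]))[::-1]
    eig_err = float(np.max(np.abs(model.eigenvalues - ref[: len(model.eigenvalues)])))

    # two groups: Wilks test must equal the Hotelling T^2 closed form
    n1 = n2 = 10
    p = 3
    Y = np.vstack([rng.normal(0, 1, (n1, p)), rng.normal(0.8, 1, (n2, p))])
    g2 = np.repeat(["a", "b"], [n1, n2])
    comp = discrim.test_groups(discrim.fit_cda(Y, g2), Y, g2)
    d = Y[:n1].mean(0) - Y[n1:].mean(0)
    S = (np.cov(Y[:n1].T) * (n1 - 1) + np.cov(Y[n1:].T) * (n2 - 1)) / (n1 + n2 - 2)
    t2 = (n1 * n2) / (n1 + n2) * d @ np.linalg.solve(S, d)
    lam_ref = 1 / (1 + t2 / (n1 + n2 - 2))
    hotelling_err = float(abs(comp.wilks_lambda - lam_ref))

    # identical distributions relabeled: no separation
    Z = rng.normal(size=(80, 4))
    gz = np.tile(["a", "b", "c", "d"], 20)
    comp_null = discrim.test_groups(discrim.fit_cda(Z, gz), Z, gz)
    return {
        "eigen_max_abs_diff": eig_err,
        "hotelling_identity_abs_diff": hotelling_err,
        "relabeled_wilks_lambda": float(comp_null.wilks_lambda),
    }


# ---------------------------------------------------------------------------
# box-plot fences

def box_fence_agreement(seed: int = 0, n_samples: int = 1000) -> dict:
    """Fraction (%) of random samples whose whisker limits equal an exhaustive
    scan over all observations satisfying the fence inequalities."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_samples):
        n = int(rng.integers(4, 60))
        v = rng.standard_t(df=3, size=n) * rng.uniform(0.5, 20)
        bs = cohortstats.box_stats(v)
        iqr = bs.q3 - bs.q1
        lo = min(x for x in v if x >= bs.q1 - 1.5 * iqr)
        hi = max(x for x in v if x <= bs.q3 + 1.5 * iqr)
        agree += (bs.lower_limit == lo) and (bs.upper_limit == hi)
    return {"agreement_pct": 100.0 * agree / n_samples, "n": n_samples}


# ---------------------------------------------------------------------------
# end-to-end differential response

def differential_response(
    seed: int = 0,
    n_reps: int = 50,
    n_per_group: int = 12,
    n_lymph: int = 2500,
    n_mono: int = 1200,
    alpha: float = 0.05,
) -> dict:
    """Untreated-vs-control cohorts carry a lymphocyte-only effect: count the
    replicates where the discriminant separation is significant for lymphocyte
    vectors and non-significant for monocyte vectors."""
    rng = np.random.default_rng(seed)
    run_cfg_kwargs = dict(
        group_sizes={"Control": n_per_group, "ART-naive": n_per_group},
        n_lymph_events=n_lymph, n_mono_events=n_mono, images_per_subject=0,
    )
    lymph_sig = mono_ns = joint = 0
    for _ in range(n_reps):
        cfg = CohortSimConfig(seed=int(rng.integers(0, 2**31 - 1)), **run_cfg_kwargs)
        cohort = simulate_cohort(cfg, include_images=False)
        from .config import RunConfig
        vectors = pipeline.subject_vectors(
            cohort, RunConfig(seed=int(cfg.seed)), report=None)
        ps = {}
        for ct in ("lymphocyte", "monocyte"):
            df = vectors[ct]
            params = [c for c in df.columns if c != "group"]
            model = discrim.fit_cda(df[params], df["group"].to_numpy())
            comp = discrim.test_groups(model, df[params], df["group"].to_numpy())
            ps[ct] = comp.p_value
        ls = ps["lymphocyte"] < alpha
        mn = ps["monocyte"] >= alpha
        lymph_sig += ls
        mono_ns += mn
        joint += ls and mn
    return {
        "joint_success_pct": 100.0 * joint / n_reps,
        "lymphocyte_significant_pct": 100.0 * lymph_sig / n_reps,
        "monocyte_nonsignificant_pct": 100.0 * mono_ns / n_reps,
        "n_reps": n_reps,
    }
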