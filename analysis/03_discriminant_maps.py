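#!/usr/bin/env python
"""Canonical-score maps: scatter the subjects (or cells) on the first two
canonical axes with each group's 95% confidence circle, for the functional and
morphological analyses of both cell types.  Requires results from
01_run_cohort_pipeline.py being reproducible from the same seed (the cohort is
re-simulated here).

Writes results/map_<analysis>.svg.
"""

import sys
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from mitocohort import pipeline
from mitocohort.config import RunConfig

OUT = Path(__file__).resolve().parents[1] / "results"


MAX_POINTS_PER_GROUP = 60  # keep the SVGs light; circles summarize the rest


def plot_map(name: str, summary: dict, path: Path) -> None:
    model = summary["model"]
    fig, ax = plt.subplots(figsize=(5, 5))
    for gname, sub in model.scores.groupby("group", sort=False):
        if len(sub) > MAX_POINTS_PER_GROUP:
            sub = sub.iloc[:: len(sub) // MAX_POINTS_PER_GROUP + 1]
        sc = ax.scatter(sub["can1"], sub.get("can2", 0), s=12, alpha=0.6, label=gname)
        color = sc.get_facecolor()[0]
        for c in summary["circles"]:
            if c.group == str(gname):
                ax.add_patch(plt.Circle(c.center, c.radius, fill=False,
                                        color=color, lw=1.5))
    ax.set_xlabel("canonical axis 1")
    ax.set_ylabel("canonical axis 2")
    ax.set_title(f"{name}\n(first two axes: "
                 f"{summary['combined_variance_pct_2axes']:.1f}% of variance)")
    ax.legend(fontsize=7)
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def main(seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)
    cfg = RunConfig(seed=seed)
    _, results = pipeline.run_all(cfg)
    for name, summary in results["discriminant"].items():
        p = OUT / f"map_{name}.svg"
        plot_map(name, summary, p)
        print("wrote", p)


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
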