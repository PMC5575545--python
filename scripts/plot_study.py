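#!/usr/bin/env python
"""Draw bias and RMSE panels from a study results table.

Reads the tidy CSV written by ``armselect study`` and produces one
figure per scenario with bias and RMSE as functions of K (or of the
allocation-ratio correlation when the table has a ``correlation``
column), one line per method, faceted by stage. Diagnostic plotting
only — nothing here feeds back into the estimators.

Usage::

    python scripts/plot_study.py results.csv --out scratch/figures
"""

from __future__ import annotations

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_scenario(df: pd.DataFrame, scenario: str, x: str, out_dir: Path) -> Path:
    stages = [s for s in ("interim", "final", "two_stage")
              if s in set(df["stage"])]
    fig, axes = plt.subplots(
        2, len(stages), figsize=(4 * len(stages), 7), sharex=True,
        squeeze=False,
    )
    for col, stage in enumerate(stages):
        sub = df[df["stage"] == stage]
        for metric, row in (("bias", 0), ("rmse", 1)):
            ax = axes[row][col]
            for method, grp in sub.groupby("method"):
                grp = grp.sort_values(x)
                ax.errorbar(
                    grp[x], grp[metric],
                    yerr=grp["mc_se"] if metric == "bias" else None,
                    marker="o", label=method, capsize=2,
                )
            if metric == "bias":
                ax.axhline(0.0, color="grey", lw=0.8)
                ax.set_title(stage)
            ax.set_ylabel(metric)
            ax.set_xlabel(x)
    axes[0][0].legend(frameon=False)
    fig.suptitle(f"{scenario} scenario")
    fig.tight_layout()
    path = out_dir / f"study_{scenario}.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("results", type=Path)
    parser.add_argument("--out", type=Path, default=Path("scratch/figures"))
    args = parser.parse_args()

    df = pd.read_csv(args.results)
    x = "correlation" if "correlation" in df.columns else "K"
    args.out.mkdir(parents=True, exist_ok=True)
    for scenario in sorted(set(df["scenario"])):
        path = plot_scenario(df[df["scenario"] == scenario], scenario, x, args.out)
        print(path)


if __name__ == "__main__":
    main()
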