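#!/usr/bin/env python
"""Optional helper: induction-profile heatmaps with the decision front.

Usage:
    python scripts/plot_profiles.py --out scratch/profiles.png
    python scripts/plot_profiles.py --params my_params.json --knockout GAL80

Needs matplotlib (not a package dependency).
"""
from __future__ import annotations

import argparse
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from galvar import (  # noqa: E402
    apply_knockout,
    decision_front,
    read_params,
    reference_parameters,
    simulate_grid,
)


def main(argv=None) -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--params", type=Path, default=None)
    ap.add_argument("--knockout", action="append", default=[])
    ap.add_argument("--out", type=Path, default=Path("profiles.png"))
    args = ap.parse_args(argv)

    params = read_params(args.params) if args.params else reference_parameters()
    for gene in args.knockout:
        params = apply_knockout(params, gene)

    profile = simulate_grid(params)
    front = decision_front(profile)
    grid = profile.grid
    gal = [g for g in grid.galactose_levels if g > 0]
    glu = [g for g in grid.glucose_levels if g > 0]

    fig, axes = plt.subplots(1, 2, figsize=(11, 4), constrained_layout=True)
    for ax, data, title in (
        (axes[0], profile.normalized_high, "high branch (ON init)"),
        (axes[1], profile.normalized_low, "low branch (OFF init)"),
    ):
        shown = np.where(profile.mask, np.nan, data)
        # display columns left->right = low->high galactose, rows top->down
        # = high->low glucose, zero row/column at the axis origin side
        img = shown[:, ::-1]
        im = ax.imshow(img, vmin=0, vmax=1, cmap="viridis", aspect="auto")
        ax.set_title(title)
        ax.set_xticks(range(len(grid.galactose_levels)))
        ax.set_xticklabels(
            [f"{g:g}" for g in grid.galactose_levels[::-1]], rotation=90
        )
        ax.set_yticks(range(len(grid.glucose_levels)))
        ax.set_yticklabels([f"{g:g}" for g in grid.glucose_levels])
        ax.set_xlabel("galactose (% w/v)")
        ax.set_ylabel("glucose (% w/v)")
        if front.crossings:
            xs, ys = [], []
            rev_gal = list(grid.galactose_levels[::-1])
            for g, ga in front.crossings:
                iy = list(grid.glucose_levels).index(g)
                lg = np.log(ga)
                lads = np.log([x if x > 0 else np.nan for x in rev_gal])
                xs.append(float(np.nanargmin(np.abs(lads - lg))
                                + (lg - lads[int(np.nanargmin(np.abs(lads - lg)))])
                                / (np.log(2))))
                ys.append(iy)
            ax.plot(xs, ys, "r-o", ms=3, lw=1.5, label="decision front")
            ax.legend(loc="lower left", fontsize=7)
    fig.colorbar(im, ax=axes, shrink=0.8, label="normalized Gal1p")
    fig.savefig(args.out, dpi=150)
    print(f"wrote {args.out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
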