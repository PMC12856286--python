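#!/usr/bin/env python
"""Net Benefit across treatment thresholds (decision curves).

Expected-mode curves for all seven strategies on the 0.5-20% grid, with
the per-test improvement over clinical-only decisions.  Optionally plots
them when matplotlib is available (PNG under results/figures/).
"""
from pathlib import Path

import pandas as pd

from dxtwin.pipeline import RunConfig, run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results"


def maybe_plot(cohort: str) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("matplotlib not installed; skipping figures")
        return
    df = pd.read_csv(OUT / f"decision_curve_{cohort}.csv")
    figdir = OUT / "figures"
    figdir.mkdir(exist_ok=True)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 8), sharex=True)
    for key, label in (("treat_none", "treat none"),
                       ("treat_all", "treat all"),
                       ("clinical", "clinical only"),
                       ("mp", "clinical + MammaPrint"),
                       ("otbin", "clinical + binary OncotypeDX"),
                       ("otcont", "clinical + continuous OncotypeDX")):
        sub = df[df.strategy == key]
        ax1.plot(100 * sub.threshold, sub.net_benefit, label=label)
        if key in ("mp", "otbin", "otcont"):
            ax2.plot(100 * sub.threshold, sub.delta_nb, label=label)
    ax1.set_ylabel("Net Benefit per 1000")
    ax1.set_ylim(-15, 25)
    ax1.legend(fontsize=8)
    ax2.set_xlabel("treatment threshold (%)")
    ax2.set_ylabel("improvement over clinical only")
    ax2.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(figdir / f"decision_curves_{cohort}.png", dpi=150)
    print(f"wrote {figdir / f'decision_curves_{cohort}.png'}")


def main():
    for cohort in ("mindact", "tailorx"):
        run_pipeline(RunConfig(cohort=cohort, stages=("curve",),
                               out_dir=str(OUT)))
        df = pd.read_csv(OUT / f"decision_curve_{cohort}.csv")
        at5 = df[df.threshold == 0.05].set_index("strategy")
        print(f"{cohort} at the 5% threshold: delta NB per 1000 = "
              f"MP {at5.loc['mp', 'delta_nb']:+.1f}, "
              f"binary OT {at5.loc['otbin', 'delta_nb']:+.1f}, "
              f"continuous OT {at5.loc['otcont', 'delta_nb']:+.1f}")
        maybe_plot(cohort)


if __name__ == "__main__":
    main()
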