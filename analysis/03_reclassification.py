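#!/usr/bin/env python
"""Reclassification of treatment decisions by each genomic test.

Uses a realized 200k-patient cohort: the decision flips are deterministic
score functions, but the correct/incorrect split needs the untreated
twin's simulated outcome.
"""
from pathlib import Path

from dxtwin.pipeline import RunConfig, run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    for cohort in ("mindact", "tailorx"):
        run_pipeline(RunConfig(cohort=cohort, n_patients=200_000, seed=1,
                               stages=("reclassification",),
                               out_dir=str(OUT)))
        print(f"{cohort}: wrote reclassification fractions")
    print("Key check (MINDACT, 5% threshold): MammaPrint reclassifies "
          "~16% of patients (~10% to treatment, ~6% away from it); the "
          "continuous OncotypeDX also ~16% but with the directions "
          "roughly reversed.")


if __name__ == "__main__":
    main()
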