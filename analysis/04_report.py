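#!/usr/bin/env python
"""Condense the pipeline run into a latency table and a latency-difference test.

Reads results/run_desk/ (from 02_run_pipeline.py), prints one row per
analysis (onset and peak with 95% bootstrap CIs, max effect, significance),
and tests whether single-image decodability peaks earlier than scene-size
clustering — the temporal ordering the pipeline is designed to resolve.
"""

from pathlib import Path

import pandas as pd

import megrsa as m

RUN = Path("results") / "run_desk"
SEED = 1


def main() -> None:
    table = m.report(RUN)
    with pd.option_context("display.width", 160):
        print(table.round(1).to_string(index=False))
    table.to_csv(Path("results") / "latency_table.csv", index=False)

    image_file = RUN / "timecourse_image_decoding.csv"
    size_file = RUN / "timecourse_clustering_size.csv"
    if image_file.exists() and size_file.exists():
        image_tc = m.GroupTimeCourse.from_frame(pd.read_csv(image_file), chance=50.0)
        size_tc = m.GroupTimeCourse.from_frame(pd.read_csv(size_file), chance=0.0)
        diff = m.peak_to_peak_difference_test(size_tc, image_tc, n_boot=500, seed=SEED)
        print(
            f"\npeak latency, size clustering minus image decoding: "
            f"{diff.peak_ms:.0f} ms (95% CI {diff.difference_ci[0]:.0f}..{diff.difference_ci[1]:.0f}), "
            f"{'significant' if diff.difference_significant else 'not significant'}"
        )


if __name__ == "__main__":
    main()
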