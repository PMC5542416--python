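#!/usr/bin/env python
"""Run the full decoding + RSA + inference pipeline on synthetic data with
a known scene-size effect.

A multivariate size effect (onset 140 ms, peak 200 ms, offset 300 ms,
250 fT against a 100 fT correlated noise floor) is injected into a
desk-scale dataset; the pipeline should recover a significant size
clustering cluster overlapping the injected window, significant size
cross-classification across the other factors, and a size-model RSA peak —
while clutter/contrast/luminance curves stay flat.

Writes all artifacts to results/run_desk/.
"""

from pathlib import Path

import pandas as pd

import megrsa as m

SEED = 1


def main() -> None:
    config = m.RunConfig(
        profile="desk",
        seed=SEED,
        n_repetitions=2,
        time_decim=8,  # 40 ms latency grid keeps the run short
        cross_targets=("size",),
        effects=[dict(factor="size", onset_ms=140.0, peak_ms=200.0, offset_ms=300.0, amplitude=250.0)],
    )
    out = m.run_pipeline(config, Path("results") / "run_desk")
    summary = pd.read_csv(out / "summary.csv")
    with pd.option_context("display.width", 140):
        print(summary[["analysis", "significant", "onset_ms", "peak_ms", "max_effect"]].to_string(index=False))
    sig = summary.loc[summary["significant"], "analysis"].tolist()
    print(f"\nsignificant analyses: {sig}")


if __name__ == "__main__":
    main()
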