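#!/usr/bin/env python
"""Hierarchical regression ledgers for spatial memory and protein outcomes.

Runs the study on the seed-0 cohort and fits the ordered-block ledgers:
work condition -> daily rhythm dynamics (amplitude change, REM latency) ->
sleep drive (NREM bout length + quiet-wake SWE) -> serum corticosterone
(protein outcomes only). Also fits the two step-3 variants (NREM SWE;
cumulative sleep) for the spatial-memory outcome to show that only the
sleep-drive markers carry predictive power. Writes results/ledger_<outcome>.csv
and results/ledger_mwm_variants.csv.
"""

import warnings
from pathlib import Path

import pandas as pd

from shiftwork.hierarchy import hierarchical_ledger
from shiftwork.pipeline import STEP3_VARIANTS, ledger_blocks, run_study
from shiftwork.synthetic import OUTCOME_NAMES, CohortSpec, generate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def show(frame: pd.DataFrame) -> None:
    for _, r in frame.iterrows():
        delta = "" if pd.isna(r.deltaAdjR2) else f" (change {r.deltaAdjR2:+.2f})"
        print(
            f"  step {r.step} {r.block:22s} R2 {r.R2:.2f}  adj R2 {r.adjR2:.2f}{delta}"
            f"  F({r.df1:.0f},{r.df2:.0f}) = {r.F:.2f}, p = {r.p:.3f}"
        )


def main() -> None:
    spec = CohortSpec(seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_study(generate_cohort(spec))
    RESULTS.mkdir(exist_ok=True)
    for outcome in OUTCOME_NAMES:
        frame = report.ledgers[outcome]
        frame.to_csv(RESULTS / f"ledger_{outcome}.csv", index=False)
        print(f"{outcome} (n = {frame['n'].iloc[0]}):")
        show(frame)

    # step-3 variants for the spatial-memory outcome
    variants = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for variant in sorted(STEP3_VARIANTS):
            led = hierarchical_ledger(
                report.animal_metrics, "mwm_latency", ledger_blocks("mwm_latency", variant)
            )
            frame = led.to_frame()
            frame.insert(0, "variant", variant)
            variants.append(frame)
    var_frame = pd.concat(variants, ignore_index=True)
    var_frame.to_csv(RESULTS / "ledger_mwm_variants.csv", index=False)
    print("step-3 variants, spatial memory (final adjusted R2):")
    for variant, sub in var_frame.groupby("variant"):
        print(f"  {variant:18s} adj R2 {sub['adjR2'].iloc[-1]:+.2f}")


if __name__ == "__main__":
    main()
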