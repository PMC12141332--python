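#!/usr/bin/env python
"""Evaluate the three screening decision trees on the 9.56M-newborn cohort.

Reports the expected screening-performance tallies per strategy (diagnosed
hearing-loss cases, hearing aids, cochlear implants, early interventions,
gene-panel screenees, ototoxic-deafness cases avoided) and writes
results/screening_counts.csv (full precision) and *_report.csv (integers).
"""

from pathlib import Path

import pandas as pd

from hearscreen.params import load_parameters
from hearscreen.trees import STRATEGIES, TALLY_NAMES, build_strategy, evaluate_tree, round_half_up

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    params = load_parameters()
    n = params.cohort_size
    cols = {}
    for s in STRATEGIES:
        alloc = evaluate_tree(build_strategy(s, params), n, strategy=s)
        cols[s] = [alloc.tallies[t] for t in TALLY_NAMES]
    full = pd.DataFrame(cols, index=list(TALLY_NAMES))
    report = full.map(round_half_up)
    full.to_csv(OUT / "screening_counts.csv")
    report.to_csv(OUT / "screening_counts_report.csv")
    print(f"cohort: {n:,} newborns\n")
    print(report.to_string())
    print(
        "\nUNHS-only and targeted screening confirm the same "
        f"{report.loc['hearing_loss_diagnosed', 'unhs_only']:,} hearing-loss cases "
        f"({report.loc['early_interventions', 'unhs_only']:,} early interventions); "
        "gene screening of referrals changes etiological knowledge and "
        f"ototoxicity warnings ({report.loc['ototoxicity_avoided', 'targeted']} avoided cases), "
        "not audiological diagnoses. Concurrent screening warns "
        f"{report.loc['ototoxicity_avoided', 'concurrent']:,} mtDNA carriers."
    )


if __name__ == "__main__":
    main()
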