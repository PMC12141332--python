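#!/usr/bin/env python
"""Build the calibrated synthetic life table the cohort model runs on.

Generates annual death probabilities from an infant-mortality term plus
Gompertz-Makeham adult mortality, checks the life-expectancy calibration
(target: about 78 years at birth), and writes results/lifetable.csv.
"""

from pathlib import Path

from hearscreen.lifetable import life_expectancy, make_life_table, write_life_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    lt = make_life_table()
    e0 = life_expectancy(lt)
    write_life_table(lt, OUT / "lifetable.csv")
    print(f"life table: {len(lt)} ages, q[0]={lt.q[0]:.4f}, q[77]={lt.q[77]:.4f}")
    print(f"life expectancy at birth: {e0:.2f} years (calibration target ~78)")
    print(f"wrote {OUT / 'lifetable.csv'}")


if __name__ == "__main__":
    main()
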