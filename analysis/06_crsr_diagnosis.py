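#!/usr/bin/env python
"""Parse the reference CRS-R table and apply the MCS/VS diagnostic rule.

Validates all 18 patient records (totals must equal subscore sums), applies
the printed criteria, and reports where the rule disagrees with the
recorded diagnosis: four patients recorded as UWS score visual = 2, which
the printed MCS column (visual 2-5) labels MCS.  The disagreement is
surfaced, not corrected.  Writes results/crsr_diagnosis.csv.
"""

import argparse
from pathlib import Path

from nirsdoc.crsr import diagnose_table, load_reference_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "crsr_diagnosis.csv")
    args = ap.parse_args()

    out = diagnose_table(load_reference_cohort())
    args.out.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(args.out, index=False)
    cols = ["no", "diagnosis", "crsr", "total", "rule_diagnosis", "agreement"]
    print(out[cols].to_string(index=False))
    n_dis = int((~out["agreement"]).sum())
    print(f"\n{len(out) - n_dis}/{len(out)} records agree with the recorded "
          f"diagnosis; disagreements (all visual = 2): "
          f"patients {sorted(out.loc[~out['agreement'], 'no'])}")


if __name__ == "__main__":
    main()
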