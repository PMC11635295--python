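#!/usr/bin/env python
"""Generate the reference synthetic DOC cohort.

Produces 18 subjects (8 MCS-like, 10 UWS-like) of 20-min, 48-channel,
dual-wavelength recordings with planted bad channels, and writes them to
results/cohort/ as per-subject CSV plus a ground-truth JSON sidecar and the
montage as TOML.  Everything downstream (02-06) reads this directory.
"""

import argparse
from pathlib import Path

from nirsdoc.synthcohort import SynthConfig, generate_cohort, write_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--duration", type=float, default=1200.0)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "cohort")
    args = ap.parse_args()

    cfg = SynthConfig(seed=args.seed, duration=args.duration)
    recordings, gt = generate_cohort(cfg)
    write_cohort(args.out, recordings, gt, config=cfg)
    n_mcs = gt.labels.count("MCS")
    print(f"wrote {len(recordings)} subjects ({n_mcs} MCS-like, "
          f"{len(recordings) - n_mcs} UWS-like) to {args.out}")
    print(f"planted bad channels (0-based index, defect): {gt.planted_bad_channels}")


if __name__ == "__main__":
    main()
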