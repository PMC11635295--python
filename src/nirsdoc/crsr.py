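"""Coma Recovery Scale-Revised (CRS-R) parsing and rule-based diagnosis.

CRS-R scores are transcribed in the compact clinical notation
``total(d1 d2 d3 d4 d5 d6)`` with single-digit subscores in the order
auditory, visual, motor, oromotor, communication, arousal (e.g.
``9(132102)``).  The diagnostic rule distinguishes the minimally conscious
state (MCS) from the vegetative state (VS / unresponsive wakefulness
syndrome):

    MCS if ANY of:  auditory 3-4, visual 2-5, motor 3-6, oromotor 3,
                    communication 1-3
    VS  if ALL of:  auditory <= 2, visual <= 1, motor <= 2, oromotor <= 2,
                    communication 0

Within the stored subscore ranges the two columns are mutually exclusive
and exhaustive (asserted by :func:`diagnose`).  The communication subscale
is stored 0-3: the clinical scale tops at 2, but the printed MCS rule reads
"1 to 3", and both conventions are accepted verbatim.

Note that the printed rule labels visual = 2 patients MCS; transcribed
cohort tables may record such patients as UWS.  :func:`diagnose_table`
surfaces the disagreement through an agreement flag instead of silently
"correcting" either side.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources

import pandas as pd

__all__ = [
    "SUBSCALES",
    "SUBSCALE_RANGES",
    "CRSRRecord",
    "parse_score",
    "format_score",
    "diagnose",
    "diagnose_table",
    "load_reference_cohort",
]

SUBSCALES = ("auditory", "visual", "motor", "oromotor", "communication", "arousal")
SUBSCALE_RANGES = {
    "auditory": (0, 4),
    "visual": (0, 5),
    "motor": (0, 6),
    "oromotor": (0, 3),
    "communication": (0, 3),  # clinical top is 2; 3 accepted per the printed rule
    "arousal": (0, 3),
}

_SCORE_RE = re.compile(r"^\s*(\d{1,2})\((\d{6})\)\s*$")


@dataclass(frozen=True)
class CRSRRecord:
    auditory: int
    visual: int
    motor: int
    oromotor: int
    communication: int
    arousal: int
    diagnosis: str | None = None

    def __post_init__(self) -> None:
        for name in SUBSCALES:
            v = getattr(self, name)
            lo, hi = SUBSCALE_RANGES[name]
            if not lo <= v <= hi:
                raise ValueError(f"{name} score {v} outside {lo}..{hi}")

    @property
    def total(self) -> int:
        return sum(getattr(self, name) for name in SUBSCALES)

    def subscores(self) -> tuple[int, ...]:
        return tuple(getattr(self, name) for name in SUBSCALES)


def parse_score(text: str) -> CRSRRecord:
    """Parse ``total(d1d2d3d4d5d6)`` into a validated record (no diagnosis).

    Raises ``ValueError`` naming the offending field for malformed strings,
    out-of-range digits, or a total inconsistent with the digit sum.
    """
    m = _SCORE_RE.match(text)
    if not m:
        raise ValueError(f"malformed CRS-R score string: {text!r}")
    total = int(m.group(1))
    digits = [int(d) for d in m.group(2)]
    rec = CRSRRecord(**dict(zip(SUBSCALES, digits)))  # range-checks each field
    if total != sum(digits):
        raise ValueError(
            f"total {total} does not equal the subscore sum {sum(digits)} in {text!r}"
        )
    return rec


def format_score(rec: CRSRRecord) -> str:
    """Inverse of :func:`parse_score`: ``total(d1..d6)``."""
    return f"{rec.total}({''.join(str(d) for d in rec.subscores())})"


def diagnose(rec: CRSRRecord) -> str:
    """Apply the MCS/VS criteria; returns ``"MCS"`` or ``"VS"``.

    The MCS column is a disjunction, the VS column a conjunction; over all
    valid subscores exactly one of them holds, which is asserted.
    """
    mcs = (
        3 <= rec.auditory <= 4
        or 2 <= rec.visual <= 5
        or 3 <= rec.motor <= 6
        or rec.oromotor == 3
        or 1 <= rec.communication <= 3
    )
    vs = (
        rec.auditory <= 2
        and rec.visual <= 1
        and rec.motor <= 2
        and rec.oromotor <= 2
        and rec.communication == 0
    )
    assert mcs != vs, f"criteria not mutually exclusive/exhaustive for {rec}"
    return "MCS" if mcs else "VS"


def diagnose_table(table: pd.DataFrame, score_column: str = "crsr",
                   diagnosis_column: str = "diagnosis") -> pd.DataFrame:
    """Parse and diagnose every row of a patient table.

    Adds the six parsed subscores, the validated total, the rule-based
    diagnosis, and — when a recorded diagnosis column is present — an
    ``agreement`` flag comparing rule vs record (UWS and VS are synonyms).
    """
    if len(table) == 0:
        raise ValueError("empty patient table")
    out = table.copy()
    records = [parse_score(str(s)) for s in out[score_column]]
    for i, name in enumerate(SUBSCALES):
        out[name] = [r.subscores()[i] for r in records]
    out["total"] = [r.total for r in records]
    out["rule_diagnosis"] = [diagnose(r) for r in records]
    if diagnosis_column in out.columns:
        recorded = out[diagnosis_column].astype(str).str.upper().replace({"UWS": "VS"})
        out["agreement"] = recorded == out["rule_diagnosis"]
    return out


def load_reference_cohort() -> pd.DataFrame:
    """The shipped 18-patient DOC cohort table (CRS-R strings, demographics)."""
    with resources.files("nirsdoc.data").joinpath("doc_cohort.csv").open() as f:
        return pd.read_csv(f)
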