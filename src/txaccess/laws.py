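"""State minor consent/confidentiality law classification.

Every state (plus DC-style districts) carries one law record with four flags:

* ``consent_all_minors`` — legislation lets *all* minors of a certain age
  consent to contraceptive services;
* ``confidentiality_guaranteed`` — confidentiality of those services is
  guaranteed by statute;
* ``physician_discretion_disclosure`` — minors may consent, but physicians
  may disclose contraceptive care to parents at their discretion;
* ``limited_categories_only`` — only certain categories of minors (e.g.
  emancipated) may consent.

The *primary* classification calls a state protective only when minors can
both consent and are guaranteed confidentiality.  The *expanded* variant,
used as a sensitivity analysis, additionally counts consent-with-physician-
discretion states as protective.  Law status is treated as constant over the
study window: one record per state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

VARIANTS = ("primary", "expanded")

PROTECTIVE = "protective"
NOT_PROTECTIVE = "not_protective"


class LawClassificationError(ValueError):
    """Raised when a law record is incomplete or inconsistent."""


@dataclass(frozen=True)
class StateLaw:
    """One state's minor consent/confidentiality statute summary."""

    state: str
    consent_all_minors: bool
    confidentiality_guaranteed: bool
    physician_discretion_disclosure: bool = False
    limited_categories_only: bool = False

    def __post_init__(self) -> None:
        for f in (
            "consent_all_minors",
            "confidentiality_guaranteed",
            "physician_discretion_disclosure",
            "limited_categories_only",
        ):
            v = getattr(self, f)
            if v is None or (not isinstance(v, (bool,)) and v not in (0, 1)):
                raise LawClassificationError(
                    f"state {self.state!r}: flag {f!r} missing or non-boolean: {v!r}"
                )


def classify_state(law: StateLaw, variant: str = "primary") -> str:
    """Classify one state's law as ``protective`` or ``not_protective``.

    primary
        protective iff minors can consent AND confidentiality is guaranteed
        (a "universal minor confidentiality" state).
    expanded
        additionally protective when minors can consent but disclosure is at
        physician discretion (partially protective states folded in).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if law.consent_all_minors and law.confidentiality_guaranteed:
        return PROTECTIVE
    if (
        variant == "expanded"
        and law.consent_all_minors
        and law.physician_discretion_disclosure
    ):
        return PROTECTIVE
    return NOT_PROTECTIVE


def protective_states(laws: Iterable[StateLaw], variant: str = "primary") -> set[str]:
    """Set of state codes classified protective under ``variant``."""
    return {law.state for law in laws if classify_state(law, variant) == PROTECTIVE}


_FLAG_COLS = [
    "consent_all_minors",
    "confidentiality_guaranteed",
    "physician_discretion_disclosure",
    "limited_categories_only",
]


def laws_from_frame(df: pd.DataFrame) -> list[StateLaw]:
    """Build law records from a table with ``state`` plus the four flag columns."""
    missing = {"state", *_FLAG_COLS} - set(df.columns)
    if missing:
        raise LawClassificationError(f"law table missing columns: {sorted(missing)}")
    return [
        StateLaw(
            state=str(row.state),
            consent_all_minors=bool(row.consent_all_minors),
            confidentiality_guaranteed=bool(row.confidentiality_guaranteed),
            physician_discretion_disclosure=bool(row.physician_discretion_disclosure),
            limited_categories_only=bool(row.limited_categories_only),
        )
        for row in df.itertuples(index=False)
    ]


def laws_to_frame(laws: Iterable[StateLaw]) -> pd.DataFrame:
    """Tabulate law records with both derived status columns."""
    rows = []
    for law in laws:
        rows.append(
            {
                "state": law.state,
                **{c: getattr(law, c) for c in _FLAG_COLS},
                "status_primary": classify_state(law, "primary"),
                "status_expanded": classify_state(law, "expanded"),
            }
        )
    return pd.DataFrame(rows)


def read_laws_csv(path) -> list[StateLaw]:
    return laws_from_frame(pd.read_csv(path))


def write_laws_csv(laws: Iterable[StateLaw], path) -> None:
    laws_to_frame(laws).to_csv(path, index=False)
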