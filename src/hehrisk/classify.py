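"""Risk classifiers for high-hyperdiploid ALL gain patterns.

The central rule is the UKALL-HeH profile: a patient is **good risk**
when the karyotype carries both +17 and +18, or exactly one of +17/+18
together with the absence of both +5 and +20; everyone else is **poor
risk**.  Patients with both +17 and +18 are good risk regardless of
+5/+20.  Comparator classifications implemented here are the Children's
Oncology Group double (+4,+10) and triple (+4,+10,+17) trisomies and the
NCI clinical risk group (age and presenting white cell count).

All classifiers evaluate gains as presence (>=1 extra copy); copy
multiplicity is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .karyotype import CHROMOSOMES, _ORDER

GOOD = "GOOD"
POOR = "POOR"


@dataclass(frozen=True)
class RiskCall:
    """A single classifier verdict with the gain evidence behind it."""

    classifier: str
    call: str
    basis: tuple[str, ...]


def _check_labels(gains: Iterable[str]) -> frozenset[str]:
    gs = frozenset(str(g) for g in gains)
    for g in gs:
        if g not in _ORDER:
            raise ValueError(f"invalid chromosome label: {g!r}")
    return gs


def classify_ukall_heh(gains: Iterable[str]) -> RiskCall:
    """Apply the UKALL-HeH good/poor decision rule to a gain set.

    GOOD iff (+17 and +18) or (exactly one of +17/+18 with neither +5
    nor +20); POOR otherwise.
    """
    gs = _check_labels(gains)
    has17, has18 = "17" in gs, "18" in gs
    has5, has20 = "5" in gs, "20" in gs
    if has17 and has18:
        return RiskCall("UKALL_HEH", GOOD, ("+17", "+18"))
    if (has17 or has18) and not has5 and not has20:
        present = "+17" if has17 else "+18"
        return RiskCall("UKALL_HEH", GOOD, (present, "no +5", "no +20"))
    if has17 or has18:
        present = "+17" if has17 else "+18"
        culprits = tuple(f"+{c}" for c in ("5", "20") if c in gs)
        return RiskCall("UKALL_HEH", POOR, (present,) + culprits)
    return RiskCall("UKALL_HEH", POOR, ("no +17", "no +18"))


def is_good_risk(gains: Iterable[str]) -> bool:
    """Boolean shorthand for :func:`classify_ukall_heh`."""
    return classify_ukall_heh(gains).call == GOOD


def classify_cog(gains: Iterable[str]) -> tuple[bool, bool]:
    """COG double trisomy (+4,+10) and triple trisomy (+4,+10,+17) status."""
    gs = _check_labels(gains)
    double = {"4", "10"} <= gs
    triple = double and "17" in gs
    return double, triple


def classify_nci(age_years: float, wcc: float) -> str:
    """NCI risk group: STANDARD iff age < 10 years and WCC < 50 x 10^9/L."""
    if age_years < 0 or wcc < 0:
        raise ValueError("age and white cell count must be non-negative")
    return "STANDARD" if (age_years < 10 and wcc < 50) else "HIGH"


def add_risk_calls(df: pd.DataFrame) -> pd.DataFrame:
    """Append classifier columns to a normalised gains table.

    Expects the 24 binary ``gain_*`` columns plus ``modal_low``/
    ``modal_high`` and, for the NCI call, ``age_years`` and ``wcc``.
    Adds ``ukall_heh``, ``cog_dt``, ``cog_tt``, ``modal_cat`` and (when
    possible) ``nci_risk``.
    """
    from .karyotype import Karyotype, modal_category

    out = df.copy()
    gain_sets = [
        frozenset(lab for lab in CHROMOSOMES if row[f"gain_{lab}"])
        for _, row in df.iterrows()
    ]
    out["ukall_heh"] = [classify_ukall_heh(gs).call for gs in gain_sets]
    cog = [classify_cog(gs) for gs in gain_sets]
    out["cog_dt"] = [d for d, _ in cog]
    out["cog_tt"] = [t for _, t in cog]
    out["modal_cat"] = [
        modal_category(
            Karyotype(raw_string="", modal_low=int(r.modal_low), modal_high=int(r.modal_high))
        )
        for r in df.itertuples()
    ]
    if {"age_years", "wcc"} <= set(df.columns):
        out["nci_risk"] = [
            classify_nci(a, w) for a, w in zip(df["age_years"], df["wcc"])
        ]
    return out
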