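"""ISCN karyotype parsing and cohort screening for high-hyperdiploid ALL.

High hyperdiploidy (HeH) is defined by a modal chromosome number of 51-65
(up to 67) arising from non-random whole-chromosome gains.  This module
turns raw ISCN karyotype strings (e.g. ``"55,XY,+4,+6,+10,+14,+17,+18,
+21,+21,+X"``) into structured :class:`Karyotype` records, computes the
modal-number category used for risk stratification, and applies the
standard cohort screens: removal of fusion-positive cases and of
suspected masked hypodiploidy (a doubled near-haploid clone that mimics
high hyperdiploidy).

Only the stem (first) clone of a multi-clone karyotype is parsed; the
remainder is retained verbatim.  The supported ISCN dialect covers the
modal-number prefix (single value or a range such as ``51-53``), the sex
chromosome field, whole-chromosome ``+N``/``-N`` tokens, ``idem``, and
cell counts in square brackets (stripped).  Structural-rearrangement
tokens (``t``, ``del``, ``dup``, ``add``, ``der``, ``i``, ``inv``,
``ins``, ``dic``, ``r``, ``mar``) set ``has_structural`` and are kept
verbatim so that serialisation round-trips, but they never contribute to
the gain/loss multisets.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Chromosome labels in natural cytogenetic order (1..22, X, Y).
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
AUTOSOMES: frozenset[str] = frozenset(str(i) for i in range(1, 23))
_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}

# Record flags
MASKED_HYPODIPLOID_SUSPECT = "MASKED_HYPODIPLOID_SUSPECT"
UNPARSEABLE_TOKENS = "UNPARSEABLE_TOKENS"
MODAL_RANGE = "MODAL_RANGE"

# Modal-number categories used for stratified reporting.
MODAL_CATEGORIES = ("51-53", "54-57", "58-65", "unclassifiable", "not_heh")
_MODAL_BINS = ((51, 53), (54, 57), (58, 65))

_MODAL_RE = re.compile(r"^(\d+)(?:[-~](\d+))?$")
_SEX_RE = re.compile(r"^[XY]+$")
_GAINLOSS_RE = re.compile(r"^([+−-])([0-9]+|X|Y)$")
_STRUCTURAL_RE = re.compile(
    r"^[+−-]?(t|del|dup|add|der|idic|i|inv|ins|dic|r|trc)\(.*\)?$"
)
_MAR_RE = re.compile(r"^[+−-]?\d*mar$")
_CELLCOUNT_RE = re.compile(r"\[[^\]]*\]")


class KaryotypeParseError(ValueError):
    """Raised when a karyotype string has no interpretable modal prefix."""

    def __init__(self, token: str, message: str):
        self.token = token
        super().__init__(f"{message} (offending token: {token!r})")


def sort_labels(labels: Iterable[str]) -> tuple[str, ...]:
    """Sort chromosome labels in natural cytogenetic order (1..22, X, Y)."""
    return tuple(sorted(labels, key=_ORDER.__getitem__))


@dataclass(frozen=True)
class Karyotype:
    """Structured view of a (stem-clone) ISCN karyotype.

    ``gains`` and ``losses`` are multisets stored as sorted tuples:
    a tetrasomy appears twice in ``gains`` (two extra copies).
    """

    raw_string: str
    modal_low: int
    modal_high: int
    gains: tuple[str, ...] = ()
    losses: tuple[str, ...] = ()
    has_structural: bool = False
    flags: frozenset[str] = frozenset()
    sex_field: Optional[str] = None
    structural_tokens: tuple[str, ...] = ()
    unknown_tokens: tuple[str, ...] = ()
    subclones: tuple[str, ...] = ()

    def __post_init__(self):
        for lab in (*self.gains, *self.losses):
            if lab not in _ORDER:
                raise ValueError(f"invalid chromosome label: {lab!r}")
        if self.modal_low > self.modal_high:
            raise ValueError("modal_low must not exceed modal_high")

    @property
    def gain_set(self) -> frozenset[str]:
        """Distinct gained chromosomes (trisomy status, multiplicity ignored)."""
        return frozenset(self.gains)

    @property
    def gain_counts(self) -> Counter:
        return Counter(self.gains)

    @property
    def modal_unambiguous(self) -> bool:
        return self.modal_low == self.modal_high


def _parse_sex_field(tok: str) -> tuple[list[str], list[str]]:
    """Interpret the sex chromosome field relative to a constitutional baseline.

    ``XY``/``XX`` are normal; supernumerary X or Y (e.g. ``XXY``) count as
    gains, a lone ``X`` as loss of one sex chromosome.  The constitutional
    baseline is taken as XY when a Y is present and XX otherwise.
    """
    n_x, n_y = tok.count("X"), tok.count("Y")
    gains: list[str] = []
    losses: list[str] = []
    base_x, base_y = (1, 1) if n_y > 0 else (2, 0)
    gains += ["X"] * max(0, n_x - base_x)
    gains += ["Y"] * max(0, n_y - base_y)
    losses += ["X"] * max(0, base_x - n_x)
    losses += ["Y"] * max(0, base_y - n_y)
    return gains, losses


def parse_iscn(text: str) -> Karyotype:
    """Parse an ISCN karyotype string into a :class:`Karyotype`.

    Only the stem clone (before the first ``/``) is parsed; sub-clones are
    retained in ``subclones`` and ignored with a warning.  Raises
    :class:`KaryotypeParseError` when the modal-number prefix is missing or
    non-numeric; unknown trailing tokens set the ``UNPARSEABLE_TOKENS``
    flag instead of failing.
    """
    if not text or not text.strip():
        raise KaryotypeParseError(text, "empty karyotype string")
    raw = text.strip()
    cleaned = _CELLCOUNT_RE.sub("", raw)
    clones = [c.strip() for c in cleaned.split("/") if c.strip()]
    if not clones:
        raise KaryotypeParseError(raw, "no clone found")
    stem, subclones = clones[0], tuple(clones[1:])
    if subclones:
        logger.warning("ignoring %d sub-clone(s) in %r", len(subclones), raw)

    tokens = [t.strip() for t in stem.split(",")]
    m = _MODAL_RE.match(tokens[0])
    if m is None:
        raise KaryotypeParseError(tokens[0], "modal-number prefix absent or non-numeric")
    modal_low = int(m.group(1))
    modal_high = int(m.group(2)) if m.group(2) else modal_low
    if modal_low > modal_high:
        modal_low, modal_high = modal_high, modal_low

    gains: list[str] = []
    losses: list[str] = []
    structural: list[str] = []
    unknown: list[str] = []
    sex_field: Optional[str] = None

    rest = tokens[1:]
    if rest and _SEX_RE.match(rest[0]):
        sex_field = rest[0]
        g, l = _parse_sex_field(sex_field)
        gains += g
        losses += l
        rest = rest[1:]

    for tok in rest:
        if not tok:
            continue
        if tok == "idem":
            continue
        gl = _GAINLOSS_RE.match(tok)
        if gl:
            if gl.group(2) in _ORDER:
                (gains if gl.group(1) == "+" else losses).append(gl.group(2))
            else:
                unknown.append(tok)
            continue
        if _STRUCTURAL_RE.match(tok) or _MAR_RE.match(tok):
            structural.append(tok)
            continue
        unknown.append(tok)

    flags: set[str] = set()
    if modal_low < modal_high:
        flags.add(MODAL_RANGE)
    if unknown:
        flags.add(UNPARSEABLE_TOKENS)

    # Masked-hypodiploidy screen: a doubled near-haploid/low-hypodiploid
    # clone presents as HeH with most gained autosomes tetrasomic.  Flag
    # when >=2 distinct autosomes are gained and >=60% of them carry two
    # or more extra copies.
    auto_counts = Counter(g for g in gains if g in AUTOSOMES)
    if len(auto_counts) >= 2:
        doubled = sum(1 for c in auto_counts.values() if c >= 2)
        if doubled / len(auto_counts) >= 0.60:
            flags.add(MASKED_HYPODIPLOID_SUSPECT)

    return Karyotype(
        raw_string=raw,
        modal_low=modal_low,
        modal_high=modal_high,
        gains=sort_labels(gains),
        losses=sort_labels(losses),
        has_structural=bool(structural),
        flags=frozenset(flags),
        sex_field=sex_field,
        structural_tokens=tuple(structural),
        unknown_tokens=tuple(unknown),
        subclones=subclones,
    )


def to_iscn(k: Karyotype) -> str:
    """Serialise a :class:`Karyotype` back to canonical ISCN.

    The canonical form lists the modal number (or range), the sex field if
    present, gains then losses in natural chromosome order, then any
    structural tokens verbatim.  Re-parsing the result reproduces the
    record provided it carries no unparseable tokens.
    """
    parts = [
        str(k.modal_low) if k.modal_unambiguous else f"{k.modal_low}-{k.modal_high}"
    ]
    sex_gl: tuple[list[str], list[str]] = ([], [])
    if k.sex_field is not None:
        parts.append(k.sex_field)
        sex_gl = _parse_sex_field(k.sex_field)
    sex_gains, sex_losses = Counter(sex_gl[0]), Counter(sex_gl[1])
    gains = Counter(k.gains) - sex_gains
    losses = Counter(k.losses) - sex_losses
    for lab in sort_labels(gains.keys()):
        parts += [f"+{lab}"] * gains[lab]
    for lab in sort_labels(losses.keys()):
        parts += [f"-{lab}"] * losses[lab]
    parts += list(k.structural_tokens)
    parts += list(k.unknown_tokens)
    return ",".join(parts)


def modal_category(k: Karyotype) -> str:
    """Assign the modal-number category (51-53, 54-57 or 58-65).

    Returns ``"not_heh"`` when the count is outside the HeH range
    (modal_high < 51 or modal_low > 67) and ``"unclassifiable"`` when a
    modal range straddles a category boundary.
    """
    if k.modal_high < 51 or k.modal_low > 67:
        return "not_heh"
    for lo, hi in _MODAL_BINS:
        if lo <= k.modal_low and k.modal_high <= hi:
            return f"{lo}-{hi}"
    return "unclassifiable"


#: Fusion genes whose presence excludes a case from the HeH cohort: the
#: fusion, not the hyperdiploidy, is taken as the primary abnormality.
EXCLUSION_FUSIONS = ("BCR-ABL1", "ETV6-RUNX1", "KMT2A", "TCF3-PBX1")


@dataclass
class ScreenResult:
    """Outcome of the cohort inclusion/exclusion screen."""

    included: list[Karyotype]
    excluded: list[tuple[Karyotype, str]]
    counts: dict = field(default_factory=dict)


def screen_cohort(
    records: Sequence[tuple[Karyotype, Optional[str]]],
) -> ScreenResult:
    """Apply the HeH cohort screens to ``(karyotype, fusion)`` pairs.

    Exclusion reasons, checked in order: ``"fusion"`` for any concomitant
    fusion annotation, ``"masked_hypodiploidy"`` for suspected doubled
    hypodiploid clones, ``"not_heh"`` for modal numbers outside 51-67.
    The result partitions the input and logs exclusion counts.
    """
    included: list[Karyotype] = []
    excluded: list[tuple[Karyotype, str]] = []
    for k, fusion in records:
        if fusion:
            excluded.append((k, "fusion"))
        elif MASKED_HYPODIPLOID_SUSPECT in k.flags:
            excluded.append((k, "masked_hypodiploidy"))
        elif modal_category(k) == "not_heh":
            excluded.append((k, "not_heh"))
        else:
            included.append(k)
    counts = Counter(reason for _, reason in excluded)
    counts["included"] = len(included)
    logger.info("cohort screen: %s", dict(counts))
    return ScreenResult(included=included, excluded=excluded, counts=dict(counts))


# ---------------------------------------------------------------------------
# Tabular I/O


def gains_table(
    karyotypes: Sequence[Karyotype], ids: Optional[Sequence] = None
) -> pd.DataFrame:
    """Build the normalised gains table: one row per patient, 24 binary
    ``gain_*`` columns plus ``modal_low``, ``modal_high`` and ``flags``."""
    if ids is None:
        ids = list(range(len(karyotypes)))
    rows = []
    for pid, k in zip(ids, karyotypes):
        row = {"patient_id": pid}
        gs = k.gain_set
        for lab in CHROMOSOMES:
            row[f"gain_{lab}"] = int(lab in gs)
        row["modal_low"] = k.modal_low
        row["modal_high"] = k.modal_high
        row["flags"] = ";".join(sorted(k.flags))
        rows.append(row)
    return pd.DataFrame(rows)


def read_iscn_lines(path) -> list[Karyotype]:
    """Parse a one-ISCN-per-line text file."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(parse_iscn(line))
    return out


def parse_cohort_csv(path, karyotype_column: str = "karyotype") -> pd.DataFrame:
    """Read a cohort CSV with a karyotype column and append the gains table."""
    df = pd.read_csv(path)
    karys = [parse_iscn(s) for s in df[karyotype_column]]
    tab = gains_table(karys, ids=df.index)
    tab = tab.drop(columns=["patient_id"])
    return pd.concat([df.reset_index(drop=True), tab.reset_index(drop=True)], axis=1)
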