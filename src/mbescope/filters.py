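"""Post-call hard filtering and edit counting for RNA/DNA variant records.

Deaminase off-target activity shows up in RNA-seq as A>G / T>C calls
(A-to-I editing read as G by the sequencer) and C>T / G>A calls (C-to-U),
and in WGS as an excess of SNVs over the parent sample. This module
re-implements the stated GATK-style hard filter —

    QUAL < 25 || MQ < 20.0 || QD < 2.0 || FS > 30.0 || DP < 20

(a record *fails* when any clause of the disjunction holds; boundary values
pass, as the strict inequalities dictate) — and the counting summaries
applied to the records that survive it. Without transcript annotation the
strand of an RNA edit is unknowable, so A>G and T>C are pooled as the
A-to-I class (likewise C>T/G>A as C-to-U); the full 12-class transition
table is exposed so annotation-aware callers can re-slice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from ._seq import DNA_BASES

_CLAUSE_ORDER = ("QUAL", "MQ", "QD", "FS", "DP")
ALL_TRANSITIONS = tuple(
    f"{a}>{b}" for a in DNA_BASES for b in DNA_BASES if a != b
)


@dataclass(frozen=True)
class CalledVariantLite:
    """Minimal variant-call record for hard filtering and edit counting.

    Any annotation may be None (missing); missing values fail the filter
    with reason ``missing:<FIELD>`` rather than passing silently.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None
    mq: float | None = None
    qd: float | None = None
    fs: float | None = None
    dp: int | None = None

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in DNA_BASES
            and self.alt in DNA_BASES
            and self.ref != self.alt
        )

    @property
    def transition(self) -> str:
        return f"{self.ref}>{self.alt}"


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter thresholds; defaults reproduce the stated expression."""

    qual_min: float = 25.0
    mq_min: float = 20.0
    qd_min: float = 2.0
    fs_max: float = 30.0
    dp_min: int = 20

    def __post_init__(self) -> None:
        for name in ("qual_min", "mq_min", "qd_min", "fs_max", "dp_min"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"threshold {name} must be finite")


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    failed_clauses: tuple[str, ...]


def hard_filter(
    v: CalledVariantLite, t: FilterThresholds = FilterThresholds()
) -> FilterResult:
    """Evaluate the hard-filter disjunction on one record.

    Fails iff any clause holds; the failed-clause list is returned in the
    fixed order QUAL, MQ, QD, FS, DP. A missing annotation fails as
    ``missing:<FIELD>``.
    """
    failed: list[str] = []
    checks = (
        ("QUAL", v.qual, lambda x: x < t.qual_min),
        ("MQ", v.mq, lambda x: x < t.mq_min),
        ("QD", v.qd, lambda x: x < t.qd_min),
        ("FS", v.fs, lambda x: x > t.fs_max),
        ("DP", v.dp, lambda x: x < t.dp_min),
    )
    for name, value, clause in checks:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            failed.append(f"missing:{name}")
        elif clause(value):
            failed.append(name)
    return FilterResult(not failed, tuple(failed))


@dataclass
class EditCounts:
    """Counting summary over the records passing the hard filter."""

    a_to_i: int = 0  # A>G pooled with T>C
    c_to_u: int = 0  # C>T pooled with G>A
    total_pass: int = 0  # all passing SNVs
    n_fail: int = 0
    n_non_snv: int = 0
    transitions: dict[str, int] = field(
        default_factory=lambda: {t: 0 for t in ALL_TRANSITIONS}
    )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": tr, "count": self.transitions[tr]}
            for tr in ALL_TRANSITIONS
        ]
        rows += [
            {"class": "A-to-I", "count": self.a_to_i},
            {"class": "C-to-U", "count": self.c_to_u},
            {"class": "total_pass", "count": self.total_pass},
            {"class": "n_fail", "count": self.n_fail},
            {"class": "n_non_snv", "count": self.n_non_snv},
        ]
        return pd.DataFrame(rows)


def count_edits(
    variants: list[CalledVariantLite],
    t: FilterThresholds = FilterThresholds(),
) -> EditCounts:
    """Apply the hard filter and count passing SNVs by transition class.

    Non-SNV records are skipped (counted in ``n_non_snv``); failing records
    are counted in ``n_fail``. ``total_pass`` is the WGS-style total SNV
    count relative to whatever baseline the caller already subtracted.
    """
    out = EditCounts()
    for v in variants:
        if not v.is_snv:
            out.n_non_snv += 1
            continue
        if not hard_filter(v, t).passed:
            out.n_fail += 1
            continue
        out.total_pass += 1
        out.transitions[v.transition] += 1
        if v.transition in ("A>G", "T>C"):
            out.a_to_i += 1
        elif v.transition in ("C>T", "G>A"):
            out.c_to_u += 1
    return out


def subtract_by_position(
    variants: list[CalledVariantLite],
    parent: list[CalledVariantLite],
) -> list[CalledVariantLite]:
    """Drop records sharing (contig, pos, ref, alt) with a parent sample.

    Helper for 'relative to the parent sample' comparisons; whether and how
    to use it is the caller's choice.
    """
    seen = {(p.contig, p.pos, p.ref, p.alt) for p in parent}
    return [
        v for v in variants if (v.contig, v.pos, v.ref, v.alt) not in seen
    ]
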