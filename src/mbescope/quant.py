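"""Quantification of base-editing outcomes from amplicon reads.

The read model is gapless: reads are full-length copies of the amplicon
reference (indel-bearing reads are rejected by length — indel calling is out
of scope). All statistics derive from one object, the per-position
substitution matrix: counts of A/C/G/T calls at every reference position,
with N and out-of-alphabet calls excluded from the informative depth at that
position.

From the matrix the module derives editing profiles in protospacer
coordinates (strand-aware, so a minus-strand placement reports plus-strand
T→C as A→G at the mapped position), cross-site window summaries, the called
editing window (positions reaching at least a fraction of the peak mean),
product purity (outcome-base mix among edited reads), allele tables over the
editable window positions, dinucleotide context preference, on/off-target
ratios with a one-read floor for zero off-target counts, and R-loop
sum/max statistics.

Tie-breaking everywhere: the smallest position/coordinate wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import DNA_BASES, complement, pattern_matches_at, validate_dna
from .editors import BaseEditorSpec
from .scan import PamPlacement, genomic_index, strand_base

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(DNA_BASES):
    _CODE[ord(_b)] = _i


class ReadRejectionError(ValueError):
    """More than half of the reads were rejected (length mismatch)."""


@dataclass(frozen=True)
class AmpliconDesign:
    """An amplicon reference with the protospacer placement being assayed."""

    reference: str
    placement: PamPlacement
    editor: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "reference", validate_dna(self.reference, what="reference")
        )
        s, e = self.placement.protospacer_interval
        if not (0 <= s and e <= len(self.reference)):
            raise ValueError("placement protospacer outside reference")


def validate_design(design: AmpliconDesign, spec: BaseEditorSpec) -> None:
    """Re-check that the placement's PAM actually matches on the reference."""
    pl = design.placement
    s, e = pl.pam_interval
    window = design.reference[s:e]
    if pl.strand == "-":
        from ._seq import revcomp

        window = revcomp(window)
    if not pattern_matches_at(window, 0, spec.pam):
        raise ValueError(
            f"PAM {spec.pam} does not match reference at {pl.pam_interval} "
            f"({pl.strand} strand: {window})"
        )


@dataclass
class SubstitutionMatrix:
    """Per-position A/C/G/T read counts against an amplicon reference."""

    reference: str
    counts: np.ndarray  # shape (len(reference), 4), columns A,C,G,T
    n_reads: int
    n_rejected: int = 0

    @property
    def depth(self) -> np.ndarray:
        """Informative depth per position (N/other calls excluded)."""
        return self.counts.sum(axis=1)

    def base_fraction(self, position: int, base: str) -> float:
        d = self.depth[position]
        if d == 0:
            return float("nan")
        return self.counts[position, DNA_BASES.index(base)] / d

    def edit_fraction(self, position: int, from_base: str, to_base: str) -> float:
        """Fraction of reads calling *to_base* at a *from_base* reference
        position (NaN at zero depth)."""
        if self.reference[position] != from_base:
            raise ValueError(
                f"reference base at {position} is "
                f"{self.reference[position]!r}, not {from_base!r}"
            )
        return self.base_fraction(position, to_base)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(DNA_BASES))
        df.insert(0, "ref", list(self.reference))
        df.insert(0, "position", np.arange(1, len(self.reference) + 1))
        df["depth"] = self.depth
        return df


def tabulate_substitutions(
    reads: list[str], design: AmpliconDesign
) -> SubstitutionMatrix:
    """Tally read bases per reference position (gapless model).

    Reads whose length differs from the reference are rejected and counted;
    if more than half are rejected a :class:`ReadRejectionError` is raised.
    """
    ref_len = len(design.reference)
    kept = [r.upper() for r in reads if len(r) == ref_len]
    n_rejected = len(reads) - len(kept)
    if reads and n_rejected * 2 > len(reads):
        raise ReadRejectionError(
            f"{n_rejected}/{len(reads)} reads rejected by length"
        )
    counts = np.zeros((ref_len, 4), dtype=np.int64)
    if kept:
        arr = np.frombuffer("".join(kept).encode("ascii"), dtype=np.uint8)
        codes = _CODE[arr].reshape(len(kept), ref_len)
        for b in range(4):
            counts[:, b] = (codes == b).sum(axis=0)
    return SubstitutionMatrix(design.reference, counts, len(kept), n_rejected)


@dataclass
class EditingProfile:
    """edit_from→edit_to frequency per protospacer position.

    Positions where the reference (on the placement strand) is not the
    editor's substrate base are *absent*, which is distinct from 0 and is
    preserved through aggregation.
    """

    editor: str
    frequencies: dict[int, float] = field(default_factory=dict)
    depths: dict[int, int] = field(default_factory=dict)

    def __getitem__(self, position: int) -> float:
        return self.frequencies[position]

    def positions(self) -> list[int]:
        return sorted(self.frequencies)


def window_profile(
    m: SubstitutionMatrix,
    design: AmpliconDesign,
    spec: BaseEditorSpec,
    *,
    min_depth: int = 1,
) -> EditingProfile:
    """Editing frequency at every substrate position of the protospacer.

    Covers positions 0..L under the Cas12f convention (position 0 is the R
    of the PAM, itself editable when it is the substrate base) and 1..L
    under the SpCas9 convention. Minus-strand placements are
    complement-corrected: plus-strand T→C counts report as A→G.
    """
    pl = design.placement
    lo = 0 if pl.convention == "cas12f_r_zero" else 1
    prof = EditingProfile(spec.name or design.editor)
    for pos in range(lo, pl.length + 1):
        g = genomic_index(pl, pos)
        if not (0 <= g < len(m.reference)):
            continue
        if strand_base(m.reference, pl, pos) != spec.edit_from:
            continue
        to_plus = spec.edit_to if pl.strand == "+" else complement(spec.edit_to)
        depth = int(m.depth[g])
        if depth < min_depth:
            continue
        prof.frequencies[pos] = m.base_fraction(g, to_plus)
        prof.depths[pos] = depth
    return prof


def aggregate_profiles(profiles: list[EditingProfile]) -> pd.DataFrame:
    """Cross-site per-position mean ± SEM.

    A position absent from a profile is excluded from both numerator and
    denominator there; ``n`` is reported per position. SEM is NaN for n < 2.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    by_pos: dict[int, list[float]] = {}
    for p in profiles:
        for pos, f in p.frequencies.items():
            by_pos.setdefault(pos, []).append(f)
    rows = []
    for pos in sorted(by_pos):
        vals = np.asarray(by_pos[pos], dtype=float)
        n = len(vals)
        rows.append(
            {
                "position": pos,
                "mean": vals.mean(),
                "sem": vals.std(ddof=1) / math.sqrt(n) if n > 1 else float("nan"),
                "n": n,
            }
        )
    return pd.DataFrame(rows).set_index("position")


def call_window(
    agg: pd.DataFrame, threshold_fraction: float = 0.5
) -> tuple[set[int], int | None]:
    """Call the editing window from an aggregated profile.

    The window is every position whose mean reaches ``threshold_fraction``
    of the peak mean; the peak is the argmax (ties: smallest position).
    An all-zero aggregate yields an empty window and no peak.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    if agg.empty:
        return set(), None
    means = agg["mean"]
    peak_val = means.max()
    if not peak_val > 0:
        return set(), None
    window = set(means.index[means >= threshold_fraction * peak_val])
    peak = int(min(means.index[means == peak_val]))
    return window, peak


def product_purity(
    m: SubstitutionMatrix, position: int, from_base: str
) -> tuple[dict[str, float], bool]:
    """Outcome-base mix among edited reads at one substrate position.

    An *edited* read is any read with a non-reference call at the position.
    Returns (fractions-by-outcome-base, defined). With zero edited reads
    the result is flagged undefined (fractions all NaN), never silently 0.
    """
    if m.reference[position] != from_base:
        raise ValueError(
            f"reference base at {position} is {m.reference[position]!r}, "
            f"not {from_base!r}"
        )
    ref_idx = DNA_BASES.index(from_base)
    edited = {
        b: int(m.counts[position, i])
        for i, b in enumerate(DNA_BASES)
        if i != ref_idx
    }
    total = sum(edited.values())
    if total == 0:
        return {b: float("nan") for b in edited}, False
    return {b: c / total for b, c in edited.items()}, True


@dataclass
class AlleleTable:
    """Joint read outcomes over the editable window positions."""

    positions: tuple[int, ...]  # protospacer positions, ascending
    table: pd.DataFrame  # columns: allele, count, proportion, is_reference, is_desired
    desired_among_all: float
    desired_among_edited: float  # NaN when no edited reads
    n_reads: int
    n_excluded: int  # reads with N at a window position


def allele_outcomes(
    reads: list[str],
    design: AmpliconDesign,
    spec: BaseEditorSpec,
    desired: dict[int, str],
) -> AlleleTable:
    """Tabulate joint editing outcomes across the editable window positions.

    ``desired`` maps protospacer positions to their intended outcome base
    (the editor's product base, on the placement strand). The desired allele
    carries the desired state at those positions and the reference base at
    every other editable position. Reads with N at any window position are
    excluded and counted. The unedited reference combination is always
    present in the table (count 0 if unobserved).
    """
    pl = design.placement
    for pos, state in desired.items():
        if state != spec.edit_to:
            raise ValueError(
                f"desired state at position {pos} is {state!r}, "
                f"not the editor product {spec.edit_to!r}"
            )
    editable = tuple(
        pos
        for pos in sorted(spec.activity_window)
        if 0 <= genomic_index(pl, pos) < len(design.reference)
        and strand_base(design.reference, pl, pos) == spec.edit_from
    )
    missing = set(desired) - set(editable)
    if missing:
        raise ValueError(f"desired positions not editable here: {sorted(missing)}")
    gidx = [genomic_index(pl, pos) for pos in editable]
    ref_allele = tuple(spec.edit_from for _ in editable)
    desired_allele = tuple(
        desired.get(pos, spec.edit_from) for pos in editable
    )

    counts: dict[tuple[str, ...], int] = {ref_allele: 0}
    n_excluded = 0
    ref_len = len(design.reference)
    for r in reads:
        if len(r) != ref_len:
            n_excluded += 1
            continue
        bases = tuple(
            r[g] if pl.strand == "+" else complement(r[g]) for g in gidx
        )
        if any(b not in DNA_BASES for b in bases):
            n_excluded += 1
            continue
        counts[bases] = counts.get(bases, 0) + 1

    n_reads = sum(counts.values())
    rows = []
    for allele in sorted(counts):
        c = counts[allele]
        rows.append(
            {
                "allele": "".join(
                    f"{pos}{b}" for pos, b in zip(editable, allele)
                ),
                "count": c,
                "proportion": c / n_reads if n_reads else float("nan"),
                "is_reference": allele == ref_allele,
                "is_desired": allele == desired_allele,
            }
        )
    table = pd.DataFrame(rows)
    n_desired = counts.get(desired_allele, 0)
    n_edited = n_reads - counts.get(ref_allele, 0)
    return AlleleTable(
        positions=editable,
        table=table,
        desired_among_all=n_desired / n_reads if n_reads else float("nan"),
        desired_among_edited=n_desired / n_edited if n_edited else float("nan"),
        n_reads=n_reads,
        n_excluded=n_excluded,
    )


def context_preference(
    entries: list[tuple[SubstitutionMatrix, AmpliconDesign]],
    spec: BaseEditorSpec,
    *,
    min_depth: int = 1,
) -> dict[str, pd.DataFrame]:
    """Mean editing frequency per dinucleotide context class.

    Each editable protospacer position contributes one observation to its
    3′-neighbour class (target base first, e.g. CA/CT/CC/CG for a CBE) and
    one to its 5′-neighbour class (target base second, e.g. AC/CC/GC/TC),
    with neighbours read on the placement strand. Classes with zero
    observations are absent. Ranks use competition ranking, so classes with
    equal means share a rank.
    """
    obs3: dict[str, list[float]] = {}
    obs5: dict[str, list[float]] = {}
    for m, design in entries:
        pl = design.placement
        prof = window_profile(m, design, spec, min_depth=min_depth)
        step = 1 if pl.strand == "+" else -1
        for pos, f in prof.frequencies.items():
            g = genomic_index(pl, pos)
            g3, g5 = g + step, g - step
            if 0 <= g3 < len(m.reference):
                b3 = m.reference[g3] if pl.strand == "+" else complement(
                    m.reference[g3]
                )
                if b3 in DNA_BASES:
                    obs3.setdefault(spec.edit_from + b3, []).append(f)
            if 0 <= g5 < len(m.reference):
                b5 = m.reference[g5] if pl.strand == "+" else complement(
                    m.reference[g5]
                )
                if b5 in DNA_BASES:
                    obs5.setdefault(b5 + spec.edit_from, []).append(f)

    def summarise(obs: dict[str, list[float]]) -> pd.DataFrame:
        rows = [
            {"context": ctx, "n": len(vals), "mean": float(np.mean(vals))}
            for ctx, vals in sorted(obs.items())
        ]
        df = pd.DataFrame(rows, columns=["context", "n", "mean"])
        if not df.empty:
            df["rank"] = [
                1 + int((df["mean"] > m_).sum()) for m_ in df["mean"]
            ]
            df = df.sort_values(
                ["rank", "context"], kind="stable"
            ).reset_index(drop=True)
        return df

    return {"three_prime": summarise(obs3), "five_prime": summarise(obs5)}


def on_off_ratio(
    on_freq: float, off_freq: float, off_depth: int
) -> tuple[float, bool]:
    """On-target / off-target frequency ratio with a one-read floor.

    Zero observed off-target edits are floored at one read (1/off_depth) so
    the ratio stays finite; the returned flag records when the floor was
    applied.
    """
    if not (0 <= on_freq <= 1 and 0 <= off_freq <= 1):
        raise ValueError("frequencies must lie in [0, 1]")
    if off_depth <= 0:
        raise ValueError("off_depth must be positive")
    floor = 1.0 / off_depth
    floored = off_freq < floor
    return on_freq / max(off_freq, floor), floored


def max_edit_frequency(
    m: SubstitutionMatrix, design: AmpliconDesign, spec: BaseEditorSpec,
    *, min_depth: int = 1,
) -> float:
    """Highest substrate-position editing frequency at a site (0 if none)."""
    prof = window_profile(m, design, spec, min_depth=min_depth)
    return max(prof.frequencies.values(), default=0.0)


def rloop_stats(
    m: SubstitutionMatrix, window: tuple[int, int], base: str
) -> dict:
    """Sum and max of per-position edit frequencies over an R-loop window.

    ``window`` is 0-based half-open on the matrix reference; only positions
    whose reference base equals *base* (A→G or C→T read-through) contribute.
    Returns the summed frequency, the maximum with its position (ties:
    smallest coordinate), and a ``defined`` flag that is False when the
    window holds no such base.
    """
    if base not in ("A", "C"):
        raise ValueError("base must be 'A' or 'C'")
    to_base = {"A": "G", "C": "T"}[base]
    s, e = window
    if not (0 <= s <= e <= len(m.reference)):
        raise ValueError("window outside matrix")
    freqs = [
        (g, m.base_fraction(g, to_base))
        for g in range(s, e)
        if m.reference[g] == base and m.depth[g] > 0
    ]
    if not freqs:
        return {"sum": 0.0, "max": float("nan"), "max_position": None,
                "defined": False}
    total = float(sum(f for _, f in freqs))
    max_f = max(f for _, f in freqs)
    max_pos = min(g for g, f in freqs if f == max_f)
    return {"sum": total, "max": float(max_f), "max_position": int(max_pos),
            "defined": True}
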