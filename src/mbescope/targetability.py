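"""Variant targetability: can a base editor correct (or install) an SNV?

A pathogenic SNV is *correctable* by an editor when the patient (alt) allele,
read on either strand, is the editor's substrate base and some PAM placement
puts it inside the activity window — so that the programmed edit restores
the reference allele. It is *precisely* correctable when some qualifying
placement puts the target inside the precision window with no same-substrate
bystander elsewhere in the activity window of that placement (the strictest
reading of "single-base resolution"; a laxer scope that tolerates bystanders
outside the precision window is available via ``bystander_scope``).

Scanning is always performed on the alt-carrying flank — the molecule
actually present in the patient genome — so a variant may create or destroy
its own PAM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._seq import complement, revcomp, validate_dna
from .editors import BaseEditorSpec, EditorRegistry
from .scan import (
    PamPlacement,
    find_pam_sites,
    genomic_index,
    protospacer_position,
    strand_base,
)

TRANSITION_CLASSES = ("A>G", "C>T", "G>A", "T>C")


class FlankTooShortError(ValueError):
    """Flank cannot host every placement whose window could cover the site."""


class ChemistryError(ValueError):
    """The requested change is not producible by the editor on either strand."""


@dataclass(frozen=True)
class VariantLite:
    """Minimal SNV record with its sequence neighbourhood.

    ``flank`` carries the *reference* allele at index ``center`` (default:
    the middle of the string); ``pos`` is 1-based on ``contig``.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    label: str = ""
    flank: str = ""
    center: int = -1

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref == alt is not a variant")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("SNVs only")
        validate_dna(self.ref + self.alt, allow_n=False, what="ref/alt")
        if self.flank:
            validate_dna(self.flank, what="flank")
            c = self.center if self.center >= 0 else len(self.flank) // 2
            object.__setattr__(self, "center", c)
            if self.flank[c] != self.ref:
                raise ValueError(
                    f"{self.contig}:{self.pos} flank center base "
                    f"{self.flank[c]!r} != ref {self.ref!r}"
                )

    @property
    def transition_class(self) -> str:
        return f"{self.ref}>{self.alt}"


@dataclass(frozen=True)
class PlacementHit:
    """One qualifying placement: where the target sits and its bystanders."""

    placement: PamPlacement
    target_position: int
    bystander_positions: tuple[int, ...]

    @property
    def n_bystanders(self) -> int:
        return len(self.bystander_positions)


@dataclass
class TargetabilityResult:
    variant: VariantLite
    editor: str
    mode: str  # "correct" or "install"
    placements: list[PlacementHit] = field(default_factory=list)
    correctable: bool = False
    precise: bool = False


def _required_margin(spec: BaseEditorSpec) -> int:
    # A window placement may need the full protospacer plus PAM on one side.
    return spec.protospacer_length + len(spec.pam) - 1


def _hits_on_sequence(
    seq: str, site: int, product_is: str | None, spec: BaseEditorSpec,
    contig: str,
) -> list[PlacementHit]:
    """All placements putting *site* in the activity window such that the
    editor's substrate sits there on the placement strand (and, for
    correction, editing yields *product_is* on the plus strand)."""
    hits = []
    for pl in find_pam_sites(seq, spec, contig):
        pos = protospacer_position(pl, site)
        if pos is None or pos not in spec.activity_window:
            continue
        if strand_base(seq, pl, pos) != spec.edit_from:
            continue
        produced = spec.edit_to if pl.strand == "+" else complement(spec.edit_to)
        if product_is is not None and produced != product_is:
            continue
        bystanders = tuple(
            q
            for q in sorted(spec.activity_window)
            if q != pos
            and 0 <= genomic_index(pl, q) < len(seq)
            and strand_base(seq, pl, q) == spec.edit_from
        )
        hits.append(PlacementHit(pl, pos, bystanders))
    return hits


def _is_precise(hit: PlacementHit, spec: BaseEditorSpec, scope: str) -> bool:
    if hit.target_position not in spec.precision_window:
        return False
    if scope == "activity":
        return hit.n_bystanders == 0
    if scope == "outside_precision":
        return not any(
            q not in spec.precision_window for q in hit.bystander_positions
        )
    raise ValueError(f"bad bystander_scope {scope!r}")


def classify_correctable(
    v: VariantLite, spec: BaseEditorSpec, *, bystander_scope: str = "activity"
) -> TargetabilityResult:
    """Classify one variant against one editor (correction mode).

    Raises :class:`FlankTooShortError` rather than silently returning a
    false negative when the flank cannot host every relevant placement.
    """
    if not v.flank:
        raise FlankTooShortError(f"{v.contig}:{v.pos}: no flank provided")
    margin = _required_margin(spec)
    if v.center < margin or len(v.flank) - 1 - v.center < margin:
        raise FlankTooShortError(
            f"{v.contig}:{v.pos}: flank margins "
            f"({v.center}, {len(v.flank) - 1 - v.center}) < required {margin}"
        )
    # the patient molecule carries the alt allele
    seq_alt = v.flank[: v.center] + v.alt + v.flank[v.center + 1 :]
    hits = _hits_on_sequence(seq_alt, v.center, v.ref, spec, v.contig)
    res = TargetabilityResult(v, spec.name, "correct", hits, bool(hits))
    res.precise = any(_is_precise(h, spec, bystander_scope) for h in hits)
    return res


def classify_precise(
    v: VariantLite, spec: BaseEditorSpec, *, bystander_scope: str = "activity"
) -> TargetabilityResult:
    """Same scan as :func:`classify_correctable`; kept as an explicit entry
    point for precision queries."""
    return classify_correctable(v, spec, bystander_scope=bystander_scope)


def design_installation(
    seq: str,
    site: int,
    ref: str,
    alt: str,
    spec: BaseEditorSpec,
    contig: str = "seq",
    *,
    bystander_scope: str = "activity",
) -> list[TargetabilityResult]:
    """Rank sgRNA placements that install ref→alt at 0-based *site* of *seq*.

    Ranking: precision-window placement first, then fewer bystanders, then
    preferred positions, then smaller protospacer position. Each candidate
    is returned as its own single-placement result.
    """
    seq = validate_dna(seq, what="sequence")
    if seq[site] != ref:
        raise ValueError(f"sequence base at {site} is {seq[site]!r}, not {ref!r}")
    plus_ok = ref == spec.edit_from and alt == spec.edit_to
    minus_ok = (
        complement(ref) == spec.edit_from and complement(alt) == spec.edit_to
    )
    if not (plus_ok or minus_ok):
        raise ChemistryError(
            f"{ref}>{alt} is not {spec.edit_from}→{spec.edit_to} on the plus "
            f"strand nor {complement(ref)}>{complement(alt)} = "
            f"{spec.edit_from}→{spec.edit_to} on the minus strand"
        )
    variant = VariantLite(contig, site + 1, ref, alt, flank=seq, center=site)
    hits = _hits_on_sequence(seq, site, None, spec, contig)
    hits = [
        h
        for h in hits
        if (h.placement.strand == "+" and plus_ok)
        or (h.placement.strand == "-" and minus_ok)
    ]

    def rank_key(h: PlacementHit):
        return (
            0 if h.target_position in spec.precision_window else 1,
            h.n_bystanders,
            0
            if spec.preferred_positions and h.target_position in spec.preferred_positions
            else 1,
            h.target_position,
        )

    out = []
    for h in sorted(hits, key=rank_key):
        r = TargetabilityResult(variant, spec.name, "install", [h], True)
        r.precise = _is_precise(h, spec, bystander_scope)
        out.append(r)
    return out


def cohort_fractions(
    variants: list[VariantLite],
    registry: EditorRegistry,
    editors: list[str],
    *,
    bystander_scope: str = "activity",
) -> pd.DataFrame:
    """Per-editor, per-transition-class correctable/precise fractions.

    Rows are (editor, class) for the four ClinVar-style transition classes
    plus ``all``; numerators and denominators are emitted alongside the
    fractions so every figure is auditable. Classes with zero members get
    NaN fractions (undefined), never 0.
    """
    rows = []
    for name in editors:
        spec = registry[name]
        verdicts = [
            classify_correctable(v, spec, bystander_scope=bystander_scope)
            for v in variants
        ]
        groups: dict[str, list[TargetabilityResult]] = {
            c: [] for c in TRANSITION_CLASSES
        }
        for v, r in zip(variants, verdicts):
            groups.setdefault(v.transition_class, []).append(r)
        groups["all"] = verdicts
        for cls in (*TRANSITION_CLASSES, *sorted(set(groups) - set(TRANSITION_CLASSES) - {"all"}), "all"):
            rs = groups[cls]
            n = len(rs)
            nc = sum(r.correctable for r in rs)
            np_ = sum(r.precise for r in rs)
            rows.append(
                {
                    "editor": name,
                    "class": cls,
                    "n": n,
                    "n_correctable": nc,
                    "n_precise": np_,
                    "frac_correctable": nc / n if n else float("nan"),
                    "frac_precise": np_ / n if n else float("nan"),
                    "frac_precise_of_correctable": (
                        np_ / nc if nc else float("nan")
                    ),
                }
            )
    return pd.DataFrame(rows)


def strand_flip(v: VariantLite) -> VariantLite:
    """The same physical variant described on the opposite strand."""
    return VariantLite(
        v.contig,
        v.pos,
        complement(v.ref),
        complement(v.alt),
        v.label,
        revcomp(v.flank),
        len(v.flank) - 1 - v.center if v.flank else -1,
    )
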