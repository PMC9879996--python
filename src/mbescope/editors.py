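"""Base editors as data: chemistry, PAM, coordinate convention, windows.

A base editor is fully described, for targeting purposes, by which base it
converts (A→G for adenine base editors, C→T for cytosine base editors), which
PAM its Cas module requires and on which side of the protospacer that PAM
sits, how protospacer positions are numbered, and which protospacer positions
it edits at appreciable frequency (the *activity window*), possibly with a
narrower high-precision tier and a set of preferred positions.

Two coordinate conventions are first-class:

``cas12f_r_zero``
    Un1Cas12f1-style: the PAM (e.g. TTTR) lies 5′ of the protospacer on the
    protospacer strand, the R of the PAM is position 0, and the base
    immediately 3′ of it is position 1.

``spcas9_pam_distal``
    SpCas9-style: the PAM (NGG) lies 3′ of the protospacer and positions
    1..20 are counted from the PAM-distal end, so position 20 abuts the PAM.

The packaged default registry encodes the windows of a family of
Cas12f-derived miniature ABEs/CBEs (N-/C-terminal and internal deaminase
fusions, with or without the RRA activity mutations) plus two nCas9-based
TadA-reprogrammed CBEs, together with composite "union" pseudo-editors used
for cohort-level targetability scans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator, Mapping

from ._seq import validate_iupac

PAM_SIDES = ("five_prime", "three_prime")
CONVENTIONS = ("cas12f_r_zero", "spcas9_pam_distal")

_CHEMISTRIES = {("A", "G"), ("C", "T")}


class RegistryError(ValueError):
    """A registry file or entry failed validation."""


@dataclass(frozen=True)
class BaseEditorSpec:
    """One base editor's targeting chemistry and window geometry.

    Parameters
    ----------
    name
        Unique editor identifier, e.g. ``"N-dRRAABE-TadA*(82G)"``.
    edit_from, edit_to
        The conversion chemistry on the protospacer strand: A→G (ABE) or
        C→T (CBE).
    pam
        IUPAC PAM pattern, e.g. ``"TTTR"`` or ``"NGG"``.
    pam_side
        ``"five_prime"`` or ``"three_prime"`` relative to the protospacer.
    convention
        Protospacer numbering convention (see module docstring).
    activity_window
        Protospacer positions edited at appreciable frequency. Stored as an
        explicit set so non-contiguous windows are representable.
    precision_window
        Subset of the activity window counted as high-precision placements.
    preferred_positions
        Optional subset of the activity window with the highest activity.
    context_ranking
        Optional ordered partition of dinucleotide context classes, keyed
        ``"three_prime"`` (target base first) and ``"five_prime"`` (target
        base second); classes in one inner list are tied.
    protospacer_length
        Spacer length in nt; 20 for every packaged editor.
    """

    name: str
    edit_from: str
    edit_to: str
    pam: str
    pam_side: str
    convention: str
    activity_window: frozenset[int]
    precision_window: frozenset[int]
    preferred_positions: frozenset[int] | None = None
    context_ranking: Mapping[str, tuple[tuple[str, ...], ...]] | None = None
    protospacer_length: int = 20

    def __post_init__(self) -> None:
        if (self.edit_from, self.edit_to) not in _CHEMISTRIES:
            raise RegistryError(
                f"{self.name}: chemistry must be A→G or C→T, "
                f"got {self.edit_from}→{self.edit_to}"
            )
        validate_iupac(self.pam, what=f"{self.name}: pam")
        if self.pam_side not in PAM_SIDES:
            raise RegistryError(f"{self.name}: bad pam_side {self.pam_side!r}")
        if self.convention not in CONVENTIONS:
            raise RegistryError(f"{self.name}: bad convention {self.convention!r}")
        object.__setattr__(self, "activity_window", frozenset(self.activity_window))
        object.__setattr__(self, "precision_window", frozenset(self.precision_window))
        if self.preferred_positions is not None:
            object.__setattr__(
                self, "preferred_positions", frozenset(self.preferred_positions)
            )
        if not self.activity_window:
            raise RegistryError(f"{self.name}: empty activity window")
        if not self.precision_window <= self.activity_window:
            raise RegistryError(
                f"{self.name}: precision_window is not a subset of activity_window"
            )
        if self.preferred_positions is not None and not (
            self.preferred_positions <= self.activity_window
        ):
            raise RegistryError(
                f"{self.name}: preferred_positions is not a subset of activity_window"
            )
        lo, hi = min(self.activity_window), max(self.activity_window)
        if self.convention == "cas12f_r_zero" and lo < 1:
            raise RegistryError(
                f"{self.name}: cas12f_r_zero window positions must be >= 1 "
                f"(position 0 is the R of the PAM)"
            )
        if self.convention == "spcas9_pam_distal" and not (
            1 <= lo and hi <= self.protospacer_length
        ):
            raise RegistryError(
                f"{self.name}: spcas9_pam_distal window must lie in "
                f"1..{self.protospacer_length}"
            )
        if self.protospacer_length < 1:
            raise RegistryError(f"{self.name}: bad protospacer_length")

    @property
    def is_abe(self) -> bool:
        return self.edit_from == "A"

    @property
    def is_cbe(self) -> bool:
        return self.edit_from == "C"


def complement_edit(spec: BaseEditorSpec) -> tuple[str, str]:
    """The editor's conversion as seen on the opposite strand.

    An A→G edit on one strand appears as T→C on the other; C→T appears as
    G→A. Applying this twice returns the original chemistry.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return comp[spec.edit_from], comp[spec.edit_to]


@dataclass
class EditorRegistry:
    """Named collection of :class:`BaseEditorSpec` with per-entry provenance."""

    editors: dict[str, BaseEditorSpec] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> BaseEditorSpec:
        try:
            return self.editors[name]
        except KeyError:
            raise KeyError(
                f"unknown editor {name!r}; known: {', '.join(sorted(self.editors))}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.editors

    def __iter__(self) -> Iterator[str]:
        return iter(self.editors)

    def __len__(self) -> int:
        return len(self.editors)

    def names(self) -> list[str]:
        return sorted(self.editors)

    def add(self, spec: BaseEditorSpec, provenance: str) -> None:
        if spec.name in self.editors:
            raise RegistryError(f"duplicate editor name {spec.name!r}")
        if not provenance:
            raise RegistryError(f"{spec.name}: provenance note is mandatory")
        self.editors[spec.name] = spec
        self.provenance[spec.name] = provenance

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        entries = {}
        for name in sorted(self.editors):
            s = self.editors[name]
            entry = {
                "edit_from": s.edit_from,
                "edit_to": s.edit_to,
                "pam": s.pam,
                "pam_side": s.pam_side,
                "convention": s.convention,
                "activity_window": sorted(s.activity_window),
                "precision_window": sorted(s.precision_window),
                "protospacer_length": s.protospacer_length,
                "provenance": self.provenance[name],
            }
            if s.preferred_positions is not None:
                entry["preferred_positions"] = sorted(s.preferred_positions)
            if s.context_ranking is not None:
                entry["context_ranking"] = {
                    side: [list(tier) for tier in tiers]
                    for side, tiers in s.context_ranking.items()
                }
            entries[name] = entry
        return {"format_version": 1, "editors": entries}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "EditorRegistry":
        if "editors" not in payload:
            raise RegistryError("registry file lacks an 'editors' mapping")
        reg = cls()
        for name, entry in payload["editors"].items():
            try:
                ranking = entry.get("context_ranking")
                if ranking is not None:
                    ranking = {
                        side: tuple(tuple(tier) for tier in tiers)
                        for side, tiers in ranking.items()
                    }
                preferred = entry.get("preferred_positions")
                spec = BaseEditorSpec(
                    name=name,
                    edit_from=entry["edit_from"],
                    edit_to=entry["edit_to"],
                    pam=entry["pam"],
                    pam_side=entry["pam_side"],
                    convention=entry["convention"],
                    activity_window=frozenset(entry["activity_window"]),
                    precision_window=frozenset(entry["precision_window"]),
                    preferred_positions=(
                        frozenset(preferred) if preferred is not None else None
                    ),
                    context_ranking=ranking,
                    protospacer_length=entry.get("protospacer_length", 20),
                )
            except (KeyError, RegistryError, ValueError) as exc:
                raise RegistryError(f"registry entry {name!r} invalid: {exc}") from exc
            reg.add(spec, entry.get("provenance", ""))
        return reg


def load_registry(path=None) -> EditorRegistry:
    """Load an editor registry from *path*, or the packaged default.

    The packaged default covers the characterised miniature ABE/CBE family:
    per-construct activity windows (e.g. A2–A4 for the N-terminal TadA-8e
    fusion, single-base C3 for the TadA-reprogrammed CBEs), precision tiers,
    preferred positions and context preference rankings where characterised,
    and the ``miniABE-any`` / ``miniCBE-any`` union pseudo-editors spanning
    A2–A18 and C3–C20 used for cohort scans.
    """
    if path is None:
        payload = json.loads(
            resources.files("mbescope.data").joinpath("editors.json").read_text()
        )
    else:
        with open(path) as fh:
            payload = json.load(fh)
    return EditorRegistry.from_dict(payload)


def with_window(spec: BaseEditorSpec, activity, precision=None) -> BaseEditorSpec:
    """Convenience copy of *spec* with replaced windows (for what-if scans)."""
    activity = frozenset(activity)
    precision = frozenset(precision) if precision is not None else activity
    return replace(spec, activity_window=activity, precision_window=precision)
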