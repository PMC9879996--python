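"""Oriented PAM placement enumeration and protospacer coordinate algebra.

Internally all coordinates are 0-based half-open on the plus strand of the
scanned contig; reported TSV coordinates are 1-based inclusive. A
*placement* fixes one protospacer on one strand together with the genomic
index of its numbering anchor:

* ``cas12f_r_zero`` — anchor is the R base of the TTTR PAM; the anchor maps
  to protospacer position 0 and the base immediately 3′ of it (on the
  placement strand) to position 1.
* ``spcas9_pam_distal`` — anchor is the PAM-proximal protospacer end, which
  maps to position L (= 20 by default); position 1 is PAM-distal.

Overlapping PAM matches are all reported; deduplication is the caller's
concern. The scan is a plain linear pass — these are desk-scale contigs
(amplicons, variant flanks, reference snippets), not genomes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

from ._seq import pattern_matches_at, revcomp, validate_dna
from .editors import BaseEditorSpec


class ConventionMismatch(ValueError):
    """A coordinate query used a convention other than the placement's."""


@dataclass(frozen=True)
class PamPlacement:
    """One oriented PAM + protospacer placement on a contig.

    ``pam_interval`` and ``protospacer_interval`` are 0-based half-open
    intervals in plus-strand coordinates regardless of ``strand``;
    ``anchor_index`` is the genomic index of the numbering anchor (see
    module docstring).
    """

    contig: str
    strand: str  # "+" or "-"
    pam_interval: tuple[int, int]
    anchor_index: int
    protospacer_interval: tuple[int, int]
    convention: str
    length: int = 20

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        ps, pe = self.protospacer_interval
        if pe - ps != self.length:
            raise ValueError("protospacer interval length != configured length")


def find_pam_sites(
    seq: str, spec: BaseEditorSpec, contig: str = "seq"
) -> list[PamPlacement]:
    """Enumerate every PAM placement of *spec* on both strands of *seq*.

    Only placements whose full protospacer lies within *seq* are returned,
    sorted by (PAM start, strand) with "+" before "-". ``N`` in the sequence
    matches only ``N`` in the PAM pattern.
    """
    seq = validate_dna(seq, what="sequence")
    pam = spec.pam
    plen = len(pam)
    L = spec.protospacer_length
    n = len(seq)
    rc_pam = revcomp(pam)  # pattern as it reads on the plus strand for minus hits
    out: list[PamPlacement] = []

    if spec.pam_side == "five_prime":
        # plus strand: PAM then protospacer, left to right
        for s in range(0, n - plen - L + 1):
            if pattern_matches_at(seq, s, pam):
                out.append(
                    PamPlacement(
                        contig, "+", (s, s + plen), s + plen - 1,
                        (s + plen, s + plen + L), spec.convention, L,
                    )
                )
        # minus strand: protospacer then PAM in plus coordinates
        for j in range(L, n - plen + 1):
            if pattern_matches_at(seq, j, rc_pam):
                out.append(
                    PamPlacement(
                        contig, "-", (j, j + plen), j,
                        (j - L, j), spec.convention, L,
                    )
                )
    else:  # three_prime PAM (SpCas9-style)
        # plus strand: protospacer then PAM
        for s in range(0, n - plen - L + 1):
            if pattern_matches_at(seq, s + L, pam):
                out.append(
                    PamPlacement(
                        contig, "+", (s + L, s + L + plen), s + L - 1,
                        (s, s + L), spec.convention, L,
                    )
                )
        # minus strand: PAM then protospacer in plus coordinates
        for p in range(0, n - plen - L + 1):
            if pattern_matches_at(seq, p, rc_pam):
                out.append(
                    PamPlacement(
                        contig, "-", (p, p + plen), p + plen,
                        (p + plen, p + plen + L), spec.convention, L,
                    )
                )

    out.sort(key=lambda pl: (pl.pam_interval[0], pl.strand))
    return out


def protospacer_position(
    placement: PamPlacement, genomic_index: int, convention: str | None = None
) -> int | None:
    """Map a genomic index to a protospacer position, or None if outside.

    Under ``cas12f_r_zero`` valid positions are 0..L (0 = the R anchor);
    under ``spcas9_pam_distal`` they are 1..L (L = PAM-proximal end).
    """
    if convention is not None and convention != placement.convention:
        raise ConventionMismatch(
            f"placement uses {placement.convention!r}, queried with {convention!r}"
        )
    sign = 1 if placement.strand == "+" else -1
    if placement.convention == "cas12f_r_zero":
        pos = sign * (genomic_index - placement.anchor_index)
        return pos if 0 <= pos <= placement.length else None
    # spcas9_pam_distal: anchor is the position-L end
    pos = placement.length - sign * (placement.anchor_index - genomic_index)
    return pos if 1 <= pos <= placement.length else None


def genomic_index(placement: PamPlacement, position: int) -> int:
    """Inverse of :func:`protospacer_position` (no bounds clipping)."""
    sign = 1 if placement.strand == "+" else -1
    if placement.convention == "cas12f_r_zero":
        return placement.anchor_index + sign * position
    return placement.anchor_index - sign * (placement.length - position)


def strand_base(seq: str, placement: PamPlacement, position: int) -> str:
    """Base at a protospacer position as read on the placement strand."""
    g = genomic_index(placement, position)
    b = seq[g]
    if placement.strand == "-":
        b = revcomp(b)
    return b


def write_placements_tsv(placements: list[PamPlacement], path) -> None:
    """Write placements as TSV with 1-based inclusive coordinates."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "contig", "strand", "pam_start", "pam_end",
                "protospacer_start", "protospacer_end", "anchor", "convention",
            ]
        )
        for pl in placements:
            w.writerow(
                [
                    pl.contig, pl.strand,
                    pl.pam_interval[0] + 1, pl.pam_interval[1],
                    pl.protospacer_interval[0] + 1, pl.protospacer_interval[1],
                    pl.anchor_index + 1, pl.convention,
                ]
            )
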