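"""Independent brute-force oracles used to certify the implementation.

These deliberately avoid the package's placement machinery: they work in
oriented-strand space with per-offset pattern checks and, for
correctability, literally simulate the programmed edit and compare
molecules.
"""

from __future__ import annotations

from mbescope._seq import base_matches, complement, revcomp


def naive_pam_scan(seq: str, spec) -> set[tuple[str, int, int]]:
    """All (strand, pam_start, pam_end) placements, plus-strand coords."""
    pam, L = spec.pam, spec.protospacer_length
    n = len(seq)
    out = set()
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for o in range(n - len(pam) + 1):
            if not all(
                base_matches(s[o + i], pam[i]) for i in range(len(pam))
            ):
                continue
            if spec.pam_side == "five_prime":
                if o + len(pam) + L > n:
                    continue
            else:
                if o - L < 0:
                    continue
            if strand == "+":
                out.add((strand, o, o + len(pam)))
            else:
                out.add((strand, n - (o + len(pam)), n - o))
    return out


def _oriented_windows(s: str, spec):
    """Yield (window-position -> oriented index) maps for each PAM hit."""
    pam, L = spec.pam, spec.protospacer_length
    for o in range(len(s) - len(pam) + 1):
        if not all(base_matches(s[o + i], pam[i]) for i in range(len(pam))):
            continue
        if spec.pam_side == "five_prime":
            anchor = o + len(pam) - 1
            if anchor + L >= len(s):
                continue
            yield {q: anchor + q for q in spec.activity_window}
        else:
            start = o - L
            if start < 0:
                continue
            yield {q: start + q - 1 for q in spec.activity_window}


def naive_correctable(v, spec) -> tuple[bool, bool]:
    """(correctable, precise) by simulating the edit and comparing molecules.

    The patient molecule carries the alt allele; an edit at an oriented
    index is applied literally and the result compared, base by base, with
    the healthy (ref-carrying) molecule.
    """
    patient = v.flank[: v.center] + v.alt + v.flank[v.center + 1 :]
    healthy = v.flank  # ref at center by construction
    correctable = precise = False
    for strand in "+-":
        s = patient if strand == "+" else revcomp(patient)
        healthy_s = healthy if strand == "+" else revcomp(healthy)
        for win in _oriented_windows(s, spec):
            for q, idx in win.items():
                if s[idx] != spec.edit_from:
                    continue
                edited = s[:idx] + spec.edit_to + s[idx + 1 :]
                if edited != healthy_s:
                    continue
                correctable = True
                bystander = any(
                    s[j] == spec.edit_from
                    for qq, j in win.items()
                    if qq != q
                )
                if q in spec.precision_window and not bystander:
                    precise = True
    return correctable, precise


def filter_expression(qual, mq, qd, fs, dp) -> bool:
    """Direct transcription of the hard-filter disjunction (True = pass)."""
    return not (qual < 25 or mq < 20.0 or qd < 2.0 or fs > 30.0 or dp < 20)
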