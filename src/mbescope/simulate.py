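"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the three data classes the pipeline consumes:

* **variant cohorts** (ClinVar-style SNVs with flanking sequence) in which an
  exact planted number of variants is correctable / precisely correctable by
  a named editor — built by inverse construction (choose a window position,
  write the PAM, withhold or add bystanders) and *verified* by an internal
  brute-force enumerator with rejection sampling, so truth is computed, not
  assumed; incidental PAM collisions in the uniform background are left in
  place for the scanner to cope with;
* **amplicon reads** with planted per-position editing frequencies, an
  outcome-base purity mix, an independent or linked (single latent edited
  state) co-editing model, and post-editing uniform substitution sequencing
  error; the linked model plants an exact (rounded) count of fully edited
  reads so allele proportions are exact at zero error;
* **variant-call records** scheduled to pass the hard filter or to fail
  exactly one named clause.

All randomness flows from one mandatory integer seed; per-stream generators
are derived from it by fixed offsets, so identical configurations reproduce
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import DNA_BASES, IUPAC, base_matches, complement, revcomp
from .editors import BaseEditorSpec, EditorRegistry
from .filters import CalledVariantLite, FilterThresholds, hard_filter
from .quant import AmpliconDesign
from .scan import find_pam_sites, genomic_index
from .targetability import VariantLite

_CLAUSES = ("QUAL", "MQ", "QD", "FS", "DP")


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator; the seed is mandatory.

    Defaults mirror the scales the pipeline is exercised at: 5000 reads per
    amplicon, cohorts of 100 variants with 25 correctable of which 10
    precisely, 0.1% per-base substitution sequencing error, and a uniform
    GC-neutral background composition.
    """

    seed: int
    read_count: int = 5000
    editing_frequencies: dict[int, float] | None = None
    purity: dict[str, float] | None = None
    co_editing: str = "independent"  # or "linked"
    error_rate: float = 0.001
    cohort_size: int = 100
    n_correctable: int = 25
    n_precise: int = 10
    flank_radius: int = 30
    n_records: int = 100
    n_fail: int = 40

    def __post_init__(self) -> None:
        if self.co_editing not in ("independent", "linked"):
            raise SimConfigError(f"bad co_editing {self.co_editing!r}")
        if not 0 <= self.error_rate <= 1:
            raise SimConfigError("error_rate outside [0, 1]")
        for d in (self.editing_frequencies, self.purity):
            if d is not None and not all(0 <= v <= 1 for v in d.values()):
                raise SimConfigError("rates must lie in [0, 1]")
        if self.purity is not None and self.purity:
            if not math.isclose(sum(self.purity.values()), 1.0):
                raise SimConfigError("purity mix must sum to 1")
        if not (
            0 <= self.n_precise <= self.n_correctable <= self.cohort_size
        ):
            raise SimConfigError(
                "need n_precise <= n_correctable <= cohort_size"
            )
        if not 0 <= self.n_fail <= self.n_records:
            raise SimConfigError("need n_fail <= n_records")


def _rng(seed: int, stream: int) -> np.random.Generator:
    # fixed-offset sub-streams: one seeded SeedSequence per (seed, stream)
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream)))


def _random_dna(rng: np.random.Generator, n: int) -> list[str]:
    return [DNA_BASES[i] for i in rng.integers(0, 4, n)]


# ---------------------------------------------------------------------------
# amplicon reads


def make_amplicon(
    spec: BaseEditorSpec,
    seed: int,
    *,
    length: int = 100,
    pam_start: int = 30,
    substrate_positions: tuple[int, ...] = (),
    editor: str | None = None,
) -> AmpliconDesign:
    """Construct a plus-strand amplicon with one planted PAM placement.

    The editor's substrate base is written at the requested protospacer
    positions and kept out of the remaining window positions, so planted
    editing frequencies are attributable position by position.
    """
    rng = _rng(seed, 10)
    pam = spec.pam
    L = spec.protospacer_length
    seq = _random_dna(rng, length)
    # write a concrete PAM instance
    for i, letter in enumerate(pam):
        choices = sorted(IUPAC[letter])
        seq[pam_start + i] = choices[rng.integers(0, len(choices))]
    if spec.pam_side == "five_prime":
        anchor = pam_start + len(pam) - 1
        gidx = {q: anchor + q for q in range(1, L + 1)}
    else:
        proto_start = pam_start - L
        if proto_start < 0:
            raise SimConfigError("pam_start leaves no room for the protospacer")
        gidx = {q: proto_start + q - 1 for q in range(1, L + 1)}
    non_substrate = [b for b in DNA_BASES if b != spec.edit_from]
    for q, g in gidx.items():
        if q in substrate_positions:
            seq[g] = spec.edit_from
        elif q in spec.activity_window:
            seq[g] = non_substrate[rng.integers(0, 3)]
    reference = "".join(seq)
    placements = [
        pl
        for pl in find_pam_sites(reference, spec, "amplicon")
        if pl.strand == "+" and pl.pam_interval[0] == pam_start
    ]
    if not placements:
        raise SimConfigError("planted PAM placement not recoverable")
    return AmpliconDesign(reference, placements[0], editor or spec.name)


def simulate_reads(
    design: AmpliconDesign, spec: BaseEditorSpec, cfg: SimConfig
) -> tuple[list[str], dict[int, float]]:
    """Draw amplicon reads with planted editing; returns (reads, truth).

    Truth is the planted per-position frequency map (protospacer
    coordinates). Sequencing error is applied after editing.
    """
    freqs = cfg.editing_frequencies or {}
    pl = design.placement
    ref = design.reference
    n, L = cfg.read_count, len(ref)
    for pos in freqs:
        g = genomic_index(pl, pos)
        if not (0 <= g < L):
            raise SimConfigError(f"position {pos} outside the amplicon")
        b = ref[g] if pl.strand == "+" else complement(ref[g])
        if b != spec.edit_from:
            raise SimConfigError(
                f"planted frequency at position {pos}, but reference base "
                f"there is {b!r}, not {spec.edit_from!r}"
            )
    purity = cfg.purity or {spec.edit_to: 1.0}
    outcome_bases = sorted(purity)
    outcome_probs = np.array([purity[b] for b in outcome_bases])

    code = {b: i for i, b in enumerate(DNA_BASES)}
    ref_codes = np.array([code.get(b, 4) for b in ref], dtype=np.uint8)
    reads = np.tile(ref_codes, (n, 1))

    def outcome_code(draw: np.ndarray) -> np.ndarray:
        # outcome base is stated on the placement strand
        bases = [outcome_bases[i] for i in draw]
        if pl.strand == "-":
            bases = [complement(b) for b in bases]
        return np.array([code[b] for b in bases], dtype=np.uint8)

    rng = _rng(cfg.seed, 20)
    if cfg.co_editing == "independent":
        for pos in sorted(freqs):
            g = genomic_index(pl, pos)
            mask = rng.random(n) < freqs[pos]
            k = int(mask.sum())
            if k:
                draw = rng.choice(len(outcome_bases), size=k, p=outcome_probs)
                reads[mask, g] = outcome_code(draw)
    else:  # linked: one latent edited state per read, exact planted count
        rates = set(freqs.values())
        if len(rates) > 1:
            raise SimConfigError(
                "linked co-editing requires one common frequency"
            )
        if freqs:
            p = rates.pop()
            k = round(p * n)
            edited = rng.permutation(n)[:k]
            for pos in sorted(freqs):
                g = genomic_index(pl, pos)
                draw = rng.choice(
                    len(outcome_bases), size=len(edited), p=outcome_probs
                )
                reads[edited, g] = outcome_code(draw)

    if cfg.error_rate > 0:
        err = rng.random((n, L)) < cfg.error_rate
        shift = rng.integers(1, 4, size=(n, L), dtype=np.uint8)
        reads = np.where(err, (reads + shift) % 4, reads)

    decode = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = decode[reads].tobytes().decode("ascii")
    return [out[i * L : (i + 1) * L] for i in range(n)], dict(freqs)


# ---------------------------------------------------------------------------
# variant cohorts


def _oracle_verdict(
    flank_ref: str, center: int, ref: str, alt: str, spec: BaseEditorSpec
) -> tuple[bool, bool]:
    """Brute-force (correctable, precise) verdict on an alt-carrying flank.

    Independent enumerator over every offset and strand of the oriented
    sequence; used only to certify generator ground truth.
    """
    seq_plus = flank_ref[:center] + alt + flank_ref[center + 1 :]
    pam, L = spec.pam, spec.protospacer_length
    correctable = precise = False
    for strand in ("+", "-"):
        s = seq_plus if strand == "+" else revcomp(seq_plus)
        c = center if strand == "+" else len(s) - 1 - center
        ref_s = ref if strand == "+" else complement(ref)
        for o in range(len(s) - len(pam) + 1):
            if not all(
                base_matches(s[o + i], pam[i]) for i in range(len(pam))
            ):
                continue
            if spec.pam_side == "five_prime":
                anchor = o + len(pam) - 1
                if anchor + L >= len(s):
                    continue
                pos_of = lambda idx: idx - anchor  # noqa: E731
                idx_of = lambda q: anchor + q  # noqa: E731
            else:
                start = o - L
                if start < 0:
                    continue
                pos_of = lambda idx: idx - start + 1  # noqa: E731
                idx_of = lambda q: start + q - 1  # noqa: E731
            q = pos_of(c)
            if q not in spec.activity_window:
                continue
            if s[c] != spec.edit_from or ref_s != spec.edit_to:
                continue
            correctable = True
            bystander = any(
                s[idx_of(qq)] == spec.edit_from
                for qq in spec.activity_window
                if qq != q and 0 <= idx_of(qq) < len(s)
            )
            if q in spec.precision_window and not bystander:
                precise = True
    return correctable, precise


def _plant_variant(
    rng: np.random.Generator,
    spec: BaseEditorSpec,
    radius: int,
    intent: str,  # "precise" | "correctable" | "none"
    ident: int,
) -> VariantLite:
    """Construct one variant whose oracle verdict equals *intent*."""
    if spec.pam_side != "five_prime":
        raise SimConfigError("cohort planting supports 5'-PAM editors")
    L, plen = spec.protospacer_length, len(spec.pam)
    center = radius
    if intent == "correctable" and len(spec.activity_window) == 1 and (
        spec.precision_window == spec.activity_window
    ):
        raise SimConfigError(
            f"{spec.name}: a single-position window admits no "
            "correctable-but-imprecise variant"
        )
    for _ in range(1000):
        flank = _random_dna(rng, 2 * radius + 1)
        if intent == "none":
            cls = ("A>G", "C>T", "G>A", "T>C")[rng.integers(0, 4)]
            ref, alt = cls[0], cls[2]
        else:
            strand = "+-"[rng.integers(0, 2)]
            window = sorted(
                spec.precision_window
                if intent == "precise"
                else spec.activity_window
            )
            p = window[rng.integers(0, len(window))]
            if strand == "+":
                ref, alt = spec.edit_to, spec.edit_from
                anchor = center - p
                pam_g = list(range(anchor - plen + 1, anchor + 1))
                pam_letters = spec.pam
                idx_of = lambda q: anchor + q  # noqa: E731
            else:
                ref, alt = complement(spec.edit_to), complement(spec.edit_from)
                anchor = center + p
                pam_g = list(range(anchor, anchor + plen))
                pam_letters = revcomp(spec.pam)
                idx_of = lambda q: anchor - q  # noqa: E731
            for g, letter in zip(pam_g, pam_letters):
                choices = sorted(IUPAC[letter])
                flank[g] = choices[rng.integers(0, len(choices))]
            substrate_plus = (
                spec.edit_from if strand == "+" else complement(spec.edit_from)
            )
            non_sub = [b for b in DNA_BASES if b != substrate_plus]
            others = [
                q for q in sorted(spec.activity_window) if q != p
            ]
            if intent == "precise":
                for q in others:
                    g = idx_of(q)
                    if 0 <= g < len(flank) and g != center:
                        if flank[g] == substrate_plus:
                            flank[g] = non_sub[rng.integers(0, 3)]
            else:  # correctable but not precise: force a bystander
                candidates = [
                    q for q in others
                    if 0 <= idx_of(q) < len(flank) and idx_of(q) != center
                ]
                if candidates:
                    q = candidates[rng.integers(0, len(candidates))]
                    flank[idx_of(q)] = substrate_plus
        flank[center] = ref
        flank_str = "".join(flank)
        correctable, precise = _oracle_verdict(
            flank_str, center, ref, alt, spec
        )
        ok = {
            "precise": correctable and precise,
            "correctable": correctable and not precise,
            "none": not correctable,
        }[intent]
        if ok:
            return VariantLite(
                contig=f"var{ident:05d}",
                pos=center + 1,
                ref=ref,
                alt=alt,
                label="pathogenic",
                flank=flank_str,
                center=center,
            )
    raise SimConfigError(f"could not plant a {intent!r} variant")


def simulate_cohort(
    cfg: SimConfig, registry: EditorRegistry, editor: str
) -> tuple[list[VariantLite], pd.DataFrame]:
    """Variant cohort with exact planted correctable/precise counts.

    Returns the variants (in shuffled order) and a truth table listing each
    variant's certified verdict for *editor*.
    """
    spec = registry[editor]
    rng = _rng(cfg.seed, 30)
    intents = (
        ["precise"] * cfg.n_precise
        + ["correctable"] * (cfg.n_correctable - cfg.n_precise)
        + ["none"] * (cfg.cohort_size - cfg.n_correctable)
    )
    order = rng.permutation(len(intents))
    variants, rows = [], []
    for ident, j in enumerate(order):
        intent = intents[j]
        v = _plant_variant(rng, spec, cfg.flank_radius, intent, ident)
        variants.append(v)
        rows.append(
            {
                "contig": v.contig,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "class": v.transition_class,
                "editor": editor,
                "correctable": intent != "none",
                "precise": intent == "precise",
            }
        )
    return variants, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# called variant records


_PASS_RANGES = {
    "QUAL": (25.0, 60.0),
    "MQ": (20.0, 60.0),
    "QD": (2.0, 40.0),
    "FS": (0.0, 30.0),
    "DP": (20, 100),
}
_FAIL_RANGES = {
    "QUAL": (0.0, 25.0),
    "MQ": (0.0, 20.0),
    "QD": (0.0, 2.0),
    "FS": (30.0, 60.0),
    "DP": (0, 20),
}


def simulate_called_variants(
    cfg: SimConfig,
    t: FilterThresholds = FilterThresholds(),
    schedule: list[str] | None = None,
) -> tuple[list[CalledVariantLite], pd.DataFrame]:
    """Variant-call records scheduled to pass or fail one named clause.

    The default schedule holds ``n_records - n_fail`` passes followed by
    failures cycling through the five clauses, shuffled. Returns (records,
    truth table with the intended pass flag and failing clause).
    """
    if schedule is None:
        fails = [_CLAUSES[i % len(_CLAUSES)] for i in range(cfg.n_fail)]
        schedule = ["pass"] * (cfg.n_records - cfg.n_fail) + fails
    bad = set(schedule) - {"pass", *_CLAUSES}
    if bad:
        raise SimConfigError(f"unknown schedule entries: {sorted(bad)}")
    rng = _rng(cfg.seed, 40)
    schedule = [schedule[i] for i in rng.permutation(len(schedule))]

    def draw(field: str, fail: bool) -> float | int:
        lo, hi = (_FAIL_RANGES if fail else _PASS_RANGES)[field]
        if field == "DP":
            return int(rng.integers(lo, hi))
        if fail and field == "FS":
            # FS fails strictly above the threshold
            return float(np.nextafter(lo, hi) + rng.random() * (hi - lo - 1))
        if fail:
            # strict '<' clauses: stay below the threshold
            return float(rng.uniform(lo, np.nextafter(hi, lo)))
        return float(rng.uniform(lo, hi))

    records, rows = [], []
    transitions = [
        (a, b) for a in DNA_BASES for b in DNA_BASES if a != b
    ]
    for i, entry in enumerate(schedule):
        ref, alt = transitions[rng.integers(0, len(transitions))]
        rec = CalledVariantLite(
            contig="chr1",
            pos=1000 + i,
            ref=ref,
            alt=alt,
            qual=draw("QUAL", entry == "QUAL"),
            mq=draw("MQ", entry == "MQ"),
            qd=draw("QD", entry == "QD"),
            fs=draw("FS", entry == "FS"),
            dp=draw("DP", entry == "DP"),
        )
        res = hard_filter(rec, t)
        # certify the construction rather than assuming it
        if res.passed != (entry == "pass"):
            raise SimConfigError(
                f"record {i} did not realise its schedule entry {entry!r}"
            )
        records.append(rec)
        rows.append(
            {
                "contig": rec.contig,
                "pos": rec.pos,
                "should_pass": entry == "pass",
                "failing_clause": "" if entry == "pass" else entry,
            }
        )
    return records, pd.DataFrame(rows)


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Copy of *cfg* with a different seed (other conditions unchanged)."""
    return replace(cfg, seed=seed)
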