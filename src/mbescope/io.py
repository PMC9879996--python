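"""File-format adapters: FASTA/FASTQ via Biopython, VCF reading via cyvcf2.

VCF writing is a minimal text emitter for the two record shapes this package
produces (cohort SNVs with a significance label; called variants carrying
QUAL plus MQ/QD/FS/DP in INFO); the files round-trip through cyvcf2.
"""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .filters import CalledVariantLite
from .targetability import VariantLite

# -- FASTA / FASTQ ----------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(records: dict[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_fastq(path) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: list[str], path, *, prefix: str = "read", quality: int = 40) -> None:
    """Write reads with a constant per-base quality (the simulator emits no
    quality model)."""

    def records():
        for i, seq in enumerate(reads):
            rec = SeqRecord(Seq(seq), id=f"{prefix}{i:06d}", description="")
            rec.letter_annotations["phred_quality"] = [quality] * len(seq)
            yield rec

    SeqIO.write(records(), str(path), "fastq")


# -- cohort VCF -------------------------------------------------------------


def write_cohort_vcf(variants: list[VariantLite], path) -> None:
    """One SNV per record; the pathogenicity label goes to INFO/CLNSIG."""
    contigs: dict[str, int] = {}
    for v in variants:
        contigs[v.contig] = max(
            contigs.get(v.contig, 0), v.pos + len(v.flank)
        )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            '##INFO=<ID=CLNSIG,Number=1,Type=String,'
            'Description="Clinical significance label">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = f"CLNSIG={v.label}" if v.label else "."
            fh.write(
                f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}\n"
            )


def read_cohort_vcf(
    path, flanks: dict[str, str], *, radius: int = 30
) -> list[VariantLite]:
    """Read SNVs and attach flanks extracted from *flanks* around each pos.

    Records whose contig lacks a sequence, or whose flank would run off the
    contig, are skipped — classification must never silently misjudge them.
    """
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        if rec.ALT is None or len(rec.ALT) != 1:
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            continue
        seq = flanks.get(rec.CHROM)
        if seq is None:
            continue
        center0 = rec.POS - 1
        lo, hi = center0 - radius, center0 + radius + 1
        if lo < 0 or hi > len(seq):
            continue
        label = rec.INFO.get("CLNSIG") or ""
        out.append(
            VariantLite(
                contig=rec.CHROM,
                pos=rec.POS,
                ref=ref,
                alt=alt,
                label=label,
                flank=seq[lo:hi],
                center=radius,
            )
        )
    return out


# -- called-variant VCF -----------------------------------------------------


def write_called_vcf(records: list[CalledVariantLite], path) -> None:
    contigs = sorted({r.contig for r in records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in contigs:
            fh.write(f"##contig=<ID={name}>\n")
        for ident, typ, desc in (
            ("MQ", "Float", "RMS mapping quality"),
            ("QD", "Float", "Quality by depth"),
            ("FS", "Float", "Fisher strand bias"),
            ("DP", "Integer", "Read depth"),
        ):
            fh.write(
                f'##INFO=<ID={ident},Number=1,Type={typ},Description="{desc}">\n'
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            qual = "." if r.qual is None else f"{r.qual:.4g}"
            info_parts = []
            for key, val in (("MQ", r.mq), ("QD", r.qd), ("FS", r.fs)):
                if val is not None:
                    info_parts.append(f"{key}={val:.4g}")
            if r.dp is not None:
                info_parts.append(f"DP={r.dp}")
            info = ";".join(info_parts) or "."
            fh.write(
                f"{r.contig}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{qual}\t.\t{info}\n"
            )


def read_called_vcf(path) -> list[CalledVariantLite]:
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        alt = rec.ALT[0] if rec.ALT else ""
        dp = rec.INFO.get("DP")
        out.append(
            CalledVariantLite(
                contig=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                qual=rec.QUAL,
                mq=rec.INFO.get("MQ"),
                qd=rec.INFO.get("QD"),
                fs=rec.INFO.get("FS"),
                dp=int(dp) if dp is not None else None,
            )
        )
    return out
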