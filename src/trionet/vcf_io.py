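"""Thin pysam-based VCF 4.2 reading/writing used across the package."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam

__all__ = ["SiteCall", "write_vcf", "read_vcf"]


@dataclass(frozen=True)
class SiteCall:
    """One VCF body record for one sample."""

    contig: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    gt: tuple[int | None, int | None]
    qual: float | None = None
    filter: str = "PASS"

    @property
    def is_ref_call(self) -> bool:
        return self.gt == (0, 0)


def _header(contig: str, contig_length: int, sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line('##FILTER=<ID=LowQual,Description="Low quality call">')
    header.add_sample(sample)
    return header


def write_vcf(
    path: str | Path,
    calls: Sequence[SiteCall],
    sample: str = "SAMPLE",
    contig_length: int = 500_000_000,
) -> Path:
    """Write position-sorted calls to an uncompressed single-sample VCF.

    Rejects unsorted or duplicated positions rather than silently reordering.
    """
    path = Path(path)
    if not calls:
        raise ValueError("refusing to write an empty VCF")
    contigs = {c.contig for c in calls}
    positions = [(c.contig, c.pos) for c in calls]
    if len(set(positions)) != len(positions) or positions != sorted(positions):
        raise ValueError("calls must be position-sorted and free of duplicates")
    header = _header(calls[0].contig, contig_length, sample)
    for extra in sorted(contigs - {calls[0].contig}):
        header.add_line(f"##contig=<ID={extra},length={contig_length}>")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in calls:
            rec = out.new_record(
                contig=call.contig,
                start=call.pos - 1,
                stop=call.pos - 1 + len(call.ref),  # keeps END sane for symbolic ALTs
                alleles=(call.ref,) + call.alts,
                qual=call.qual,
            )
            rec.samples[sample]["GT"] = call.gt
            rec.samples[sample].phased = False
            if call.filter != "PASS":
                rec.filter.add(call.filter)
            else:
                rec.filter.add("PASS")
            out.write(rec)
    return path


def read_vcf(path: str | Path) -> list[SiteCall]:
    """Read a single-sample VCF back into SiteCall records."""
    out: list[SiteCall] = []
    with pysam.VariantFile(str(path)) as vf:
        sample = list(vf.header.samples)[0]
        for rec in vf:
            gt = rec.samples[sample].get("GT", (None, None))
            if gt is None:
                gt = (None, None)
            filt = list(rec.filter.keys())
            out.append(
                SiteCall(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    gt=tuple(gt) if len(gt) == 2 else (None, None),
                    qual=rec.qual,
                    filter=filt[0] if filt else "PASS",
                )
            )
    return out
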