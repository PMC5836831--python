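"""Promoter-region extraction, variant application, and table / format I/O.

Coordinate convention: the transcription-start anchor is position +1 of a
1-based sequence and there is no position 0, so offset ``-k`` means the
k-th base upstream of the anchor.  The canonical scoring window is the
51-nt region [-70; -20], which hosts every experimentally supported
TBP-binding site of the promoters handled here.  Whether the anchor is a
TSS or a start codon is the caller's choice; the arithmetic is identical.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import (
    AlphabetError,
    AmbiguousContextError,
    BoundaryError,
    ContextNotFoundError,
    MarkerTableError,
)
from .records import Delta, MarkerRecord, Rank, format_alpha, parse_alpha

_VALID = re.compile(r"^[ACGT]+$")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

CANONICAL_START = -70
CANONICAL_END = -20


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PromoterRegion:
    """A promoter window on which all affinity scoring happens.

    ``start_offset``/``end_offset`` are inclusive offsets relative to the
    anchor at +1 (negative = upstream, no position 0).
    """

    gene_symbol: str
    sequence: str
    start_offset: int = CANONICAL_START
    end_offset: int = CANONICAL_END
    source_id: str | None = None

    def __post_init__(self):
        seq = self.sequence.upper()
        if not _VALID.match(seq):
            bad = sorted(set(seq) - set("ACGT"))
            raise AlphabetError(
                f"{self.gene_symbol or 'region'}: non-ACGT characters {bad} in sequence")
        expected = self.end_offset - self.start_offset + 1
        if self.start_offset < 0 <= self.end_offset:
            expected -= 1  # the offset scale has no position 0
        if len(seq) != expected:
            raise ValueError(
                f"sequence length {len(seq)} does not match offsets "
                f"[{self.start_offset}; {self.end_offset}] (expected {expected})")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class VariantSpec:
    """A SNP or short indel described by its flank context.

    ``ref_allele``/``alt_allele`` use ``-`` for the empty allele; either may
    instead be a symbolic insert name (e.g. ``18bp``) to be resolved against
    a named-insert dictionary before scoring.
    """

    variant_id: str
    flank5: str
    ref_allele: str
    alt_allele: str
    flank3: str
    insert_name: str | None = None
    gene_symbol: str | None = None

    def __post_init__(self):
        for attr in ("flank5", "flank3"):
            object.__setattr__(self, attr, getattr(self, attr).upper())
        for attr in ("ref_allele", "alt_allele"):
            value = getattr(self, attr).strip()
            object.__setattr__(self, attr, value.upper() if _VALID.match(value.upper()) else value)
        if self._concrete(self.ref_allele) == "" and self._concrete(self.alt_allele) == "":
            raise ValueError(f"{self.variant_id}: ref and alt alleles cannot both be empty")

    @staticmethod
    def _concrete(allele: str) -> str | None:
        """Sequence for an allele field, '' for '-', None if symbolic."""
        if allele in ("-", ""):
            return ""
        first = allele.split(",")[0].strip().upper()
        return first if _VALID.match(first) else None

    @property
    def ref_sequence(self) -> str:
        seq = self._concrete(self.ref_allele)
        if seq is None:
            raise ContextNotFoundError(
                f"{self.variant_id}: symbolic allele {self.ref_allele!r} is unresolved")
        return seq

    @property
    def alt_sequence(self) -> str:
        seq = self._concrete(self.alt_allele)
        if seq is None:
            raise ContextNotFoundError(
                f"{self.variant_id}: symbolic allele {self.alt_allele!r} is unresolved")
        return seq

    def inverse(self) -> "VariantSpec":
        """The variant that undoes this one (ref and alt swapped)."""
        return replace(self, ref_allele=self.alt_allele, alt_allele=self.ref_allele)


def extract_region(sequence: str, tss_position: int, gene_symbol: str = "",
                   source_id: str | None = None,
                   start_offset: int = CANONICAL_START,
                   end_offset: int = CANONICAL_END) -> PromoterRegion:
    """Cut the [start_offset; end_offset] window upstream of a 1-based anchor.

    With the defaults this returns the canonical 51-nt [-70; -20] region.
    """
    if start_offset > end_offset:
        raise ValueError("start_offset must not exceed end_offset")
    if end_offset >= 0:
        raise ValueError("offsets must be upstream of the anchor (negative)")
    start = tss_position + start_offset  # no position 0: -1 maps to tss-1
    end = tss_position + end_offset
    if start < 1:
        raise BoundaryError(
            f"region [{start_offset}; {end_offset}] of anchor {tss_position} "
            f"starts at position {start} before the sequence")
    if end > len(sequence):
        raise BoundaryError(
            f"region end {end} exceeds sequence length {len(sequence)}")
    window = sequence[start - 1:end].upper()
    if not _VALID.match(window):
        bad = sorted(set(window) - set("ACGT"))
        raise AlphabetError(f"non-ACGT characters {bad} in extracted region")
    return PromoterRegion(gene_symbol=gene_symbol, sequence=window,
                          start_offset=start_offset, end_offset=end_offset,
                          source_id=source_id)


def _count_overlapping(haystack: str, needle: str) -> int:
    return len(re.findall(f"(?={re.escape(needle)})", haystack))


def apply_variant(region: PromoterRegion | str, variant: VariantSpec) -> str:
    """Replace the ancestral allele by the minor allele inside its flanks.

    The context ``flank5 + ref + flank3`` must occur exactly once in the
    region; anything else is an error rather than a silent first-match edit.
    Returns the mutant nucleotide string (its length may differ from the
    input for indels).
    """
    sequence = region.sequence if isinstance(region, PromoterRegion) else region.upper()
    ref, alt = variant.ref_sequence, variant.alt_sequence
    context = variant.flank5 + ref + variant.flank3
    if not context:
        raise ContextNotFoundError(f"{variant.variant_id}: empty context")
    hits = _count_overlapping(sequence, context)
    if hits == 0:
        raise ContextNotFoundError(
            f"{variant.variant_id}: context {context!r} not found in region")
    if hits > 1:
        raise AmbiguousContextError(
            f"{variant.variant_id}: context {context!r} occurs {hits} times")
    replacement = variant.flank5 + alt + variant.flank3
    return sequence.replace(context, replacement)


# ---------------------------------------------------------------------------
# Marker tables (TSV transcription of the candidate-marker tables)
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ("gene", "variant_id", "flank5", "wt", "mut", "flank3",
                 "kd_wt_nM", "kd_mut_nM", "delta", "z", "alpha", "rank",
                 "annotation", "flags")


def parse_marker_table(path: str | Path) -> list[MarkerRecord]:
    """Read a marker-table TSV into records.

    Empty numeric cells become ``None`` (rows flagged ``incomplete``);
    malformed rows raise :class:`MarkerTableError` with their line number.
    """
    records: list[MarkerRecord] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(TABLE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise MarkerTableError(f"missing columns: {sorted(missing)}", line=1)
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row))
            except (ValueError, KeyError) as exc:
                raise MarkerTableError(str(exc), line=lineno) from exc
    return records


def _parse_row(row: Mapping[str, str]) -> MarkerRecord:
    def number(cell: str | None) -> float | None:
        cell = (cell or "").strip()
        return float(cell) if cell else None

    def text(cell: str | None) -> str:
        return (cell or "").strip()

    alpha_cell, rank_cell = text(row["alpha"]), text(row["rank"])
    return MarkerRecord(
        gene_symbol=text(row["gene"]),
        variant_id=text(row["variant_id"]),
        flank5=text(row["flank5"]).upper(),
        wt_allele=text(row["wt"]),
        mut_allele=text(row["mut"]),
        flank3=text(row["flank3"]).upper(),
        kd_wt_nM=number(row["kd_wt_nM"]),
        kd_mut_nM=number(row["kd_mut_nM"]),
        delta=Delta.parse(text(row["delta"]) or "="),
        z=number(row["z"]),
        alpha=parse_alpha(alpha_cell) if alpha_cell else None,
        rank=Rank.parse(rank_cell) if rank_cell else None,
        annotation=text(row["annotation"]),
        flags=tuple(f for f in text(row.get("flags")).split(",") if f),
    )


def write_marker_table(records: Iterable[MarkerRecord], path: str | Path) -> None:
    """Write records to TSV; re-parsing the file reproduces them exactly."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TABLE_COLUMNS)
        for rec in records:
            writer.writerow([
                rec.gene_symbol,
                rec.variant_id,
                rec.flank5.lower(),
                rec.wt_allele,
                rec.mut_allele,
                rec.flank3.lower(),
                _format_number(rec.kd_wt_nM),
                _format_number(rec.kd_mut_nM),
                rec.delta.value,
                _format_number(rec.z),
                format_alpha(rec.alpha) if rec.alpha is not None else "",
                rec.rank.value if rec.rank is not None else "",
                rec.annotation,
                ",".join(rec.flags),
            ])


def _format_number(value: float | None) -> str:
    if value is None:
        return ""
    return repr(value)  # shortest exact round-trip representation


# ---------------------------------------------------------------------------
# Standard genomic formats
# ---------------------------------------------------------------------------

def promoters_from_fasta(path: str | Path,
                         tss_map: Mapping[str, int] | None = None,
                         reverse_strand: bool = False) -> list[PromoterRegion]:
    """Load promoter regions from FASTA.

    Records whose id appears in ``tss_map`` are cut to [-70; -20] around the
    mapped 1-based anchor; records without an anchor must already be exactly
    the 51-nt region.  ``reverse_strand=True`` reverse-complements each
    sequence first (promoter on the minus strand of the given sequence).
    """
    from Bio import SeqIO

    regions = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if reverse_strand:
            seq = reverse_complement(seq)
        if tss_map and rec.id in tss_map:
            regions.append(extract_region(seq, tss_map[rec.id],
                                          gene_symbol=rec.id, source_id=rec.id))
        else:
            regions.append(PromoterRegion(gene_symbol=rec.id, sequence=seq,
                                          source_id=rec.id))
    return regions


def regions_from_bed(genome_fasta: str | Path, bed_path: str | Path) -> list[PromoterRegion]:
    """Load 51-bp promoter windows given as BED intervals on a genome FASTA.

    BED is 0-based half-open; the name column supplies the gene symbol and a
    ``-`` in the strand column requests the reverse complement.  Each
    interval must span exactly 51 bp.
    """
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta), sequence_always_upper=True)
    regions = []
    with open(bed_path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            strand = fields[5] if len(fields) > 5 else "+"
            if end - start != CANONICAL_END - CANONICAL_START + 1:
                raise ValueError(
                    f"{name}: BED interval must span exactly "
                    f"{CANONICAL_END - CANONICAL_START + 1} bp, got {end - start}")
            seq = genome[chrom][start:end].seq
            if strand == "-":
                seq = reverse_complement(seq)
            regions.append(PromoterRegion(gene_symbol=name, sequence=seq,
                                          source_id=f"{chrom}:{start}-{end}({strand})"))
    return regions


def variants_from_vcf(vcf_path: str | Path, genome_fasta: str | Path,
                      flank: int = 10) -> list[VariantSpec]:
    """Convert minimal VCF records (CHROM, POS, ID, REF, ALT) to flank form.

    Flanks of ``flank`` nt are sliced from the reference genome around each
    REF allele; multi-allelic records are split, one spec per ALT.
    """
    import pysam
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta), sequence_always_upper=True)
    variants = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            chrom_seq = genome[rec.chrom]
            start0 = rec.pos - 1
            flank5 = chrom_seq[max(0, start0 - flank):start0].seq
            flank3 = chrom_seq[start0 + len(rec.ref):start0 + len(rec.ref) + flank].seq
            for i, alt in enumerate(rec.alts or ()):
                vid = rec.id or f"{rec.chrom}:{rec.pos}"
                if len(rec.alts) > 1:
                    vid = f"{vid}.{i + 1}"
                variants.append(VariantSpec(
                    variant_id=vid, flank5=flank5,
                    ref_allele=rec.ref or "-", alt_allele=alt or "-",
                    flank3=flank3))
    return variants
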