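"""Sequence and variant I/O: SAM, VCF, FASTQ, a pileup TSV dialect.

Also home to the call-set container and its algebra (subtraction of the
matched-normal calls, union of caller outputs), pileup extraction from
alignments, and the read-level FASTQ quality-control stage.

Coordinates are 1-based inclusive everywhere (VCF convention).
"""
from __future__ import annotations

import functools
import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .lod_core import NUCLEOTIDES, InconsistentInputError, Pileup, ReadObservation

log = logging.getLogger(__name__)

__all__ = [
    "GenomicSite",
    "VariantRecord",
    "CallSet",
    "SequencedRead",
    "QCSummary",
    "ParseError",
    "ContigError",
    "read_variants",
    "write_variants",
    "extract_pileup",
    "extract_pileups",
    "read_pileup_tsv",
    "subtract_callsets",
    "union_callsets",
    "apply_qc",
    "fastq_qc",
    "read_known_sites",
]


class ParseError(ValueError):
    """A malformed input file."""


class ContigError(ValueError):
    """A requested contig is absent from an alignment header."""


@functools.total_ordering
@dataclass(frozen=True)
class GenomicSite:
    """A 1-based position on a named contig."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    def sort_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def __lt__(self, other: "GenomicSite") -> bool:
        return self.sort_key() < other.sort_key()

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}"


Key = tuple[str, int, str, str]


@dataclass
class VariantRecord:
    """One candidate SNV with its annotations and caller provenance."""

    site: GenomicSite
    ref: str
    alt: str
    id: str | None = None
    qual: float | None = None
    population_af: float | None = None
    functional_class: str | None = None
    provenance: set[str] = field(default_factory=set)
    annotations: dict[str, float | int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(
                f"SNV alleles must be A/C/G/T, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.site}")

    @property
    def key(self) -> Key:
        return (self.site.chrom, self.site.pos, self.ref, self.alt)

    def copy(self) -> "VariantRecord":
        return VariantRecord(
            site=self.site,
            ref=self.ref,
            alt=self.alt,
            id=self.id,
            qual=self.qual,
            population_af=self.population_af,
            functional_class=self.functional_class,
            provenance=set(self.provenance),
            annotations=dict(self.annotations),
        )


class CallSet:
    """Variant records keyed by (chrom, pos, ref, alt), iterated in genomic order."""

    def __init__(self, records: Iterable[VariantRecord] = (), label: str = ""):
        self.label = label
        self._records: dict[Key, VariantRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: VariantRecord) -> None:
        if rec.key in self._records:
            raise ValueError(f"duplicate record key {rec.key}")
        self._records[rec.key] = rec

    def get(self, key: Key) -> VariantRecord | None:
        return self._records.get(key)

    def keys(self) -> set[Key]:
        return set(self._records)

    def __contains__(self, item) -> bool:
        key = item.key if isinstance(item, VariantRecord) else tuple(item)
        return key in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(
            sorted(
                self._records.values(),
                key=lambda r: (r.site.sort_key(), r.ref, r.alt),
            )
        )

    def __repr__(self) -> str:
        return f"CallSet(label={self.label!r}, n={len(self)})"


# INFO keys used when round-tripping annotations through VCF.
_ANNOTATION_INFO: dict[str, tuple[str, str]] = {
    "lod_t": ("LODT", "Float"),
    "lod_n": ("LODN", "Float"),
    "f_hat": ("FHAT", "Float"),
    "tumor_depth": ("DPT", "Integer"),
    "normal_depth": ("DPN", "Integer"),
    "target_vaf": ("TVAF", "Float"),
}
_INFO_ANNOTATION = {info: (name, typ) for name, (info, typ) in _ANNOTATION_INFO.items()}


def _info_get(row, key):
    """INFO lookup tolerant of keys absent from the header declaration."""
    try:
        return row.info.get(key)
    except (KeyError, ValueError):
        return None


def read_variants(
    path,
    label: str = "",
    af_key: str = "AF",
    functional_key: str = "FCLASS",
) -> CallSet:
    """Read SNV records from a VCF 4.x file into a :class:`CallSet`.

    Multi-allelic rows are split into one record per alt allele; rows whose
    ref or alt is not a single canonical nucleotide are skipped (counted in
    the log).  The population allele frequency is taken from the INFO key
    ``af_key``; the functional class from ``functional_key``; provenance
    from PROV.
    """
    calls = CallSet(label=label)
    skipped = 0
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot read VCF {path}: {exc}") from exc
    with vf:
        for n, row in enumerate(vf, start=1):
            try:
                alts = row.alts or ()
                for i, alt in enumerate(alts):
                    if len(row.ref) != 1 or alt is None or len(alt) != 1:
                        skipped += 1
                        continue
                    ref, alt = row.ref.upper(), alt.upper()
                    if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
                        skipped += 1
                        continue
                    af = _info_get(row, af_key)
                    if isinstance(af, tuple):
                        af = af[i] if i < len(af) else None
                    fclass = _info_get(row, functional_key)
                    if isinstance(fclass, tuple):
                        fclass = ",".join(fclass)
                    prov = _info_get(row, "PROV") or ()
                    if isinstance(prov, str):
                        prov = (prov,)
                    annotations: dict[str, float | int] = {}
                    for info_key, (name, typ) in _INFO_ANNOTATION.items():
                        val = _info_get(row, info_key)
                        if isinstance(val, tuple):
                            val = val[0]
                        if val is not None:
                            annotations[name] = int(val) if typ == "Integer" else float(val)
                    calls.add(
                        VariantRecord(
                            site=GenomicSite(row.chrom, row.pos),
                            ref=ref,
                            alt=alt,
                            id=row.id,
                            qual=row.qual,
                            population_af=float(af) if af is not None else None,
                            functional_class=str(fclass) if fclass is not None else None,
                            provenance=set(prov) | ({label} if label else set()),
                            annotations=annotations,
                        )
                    )
            except ValueError as exc:
                raise ParseError(f"malformed VCF record #{n} in {path}: {exc}") from exc
    if skipped:
        log.info("read_variants(%s): skipped %d non-SNV allele(s)", path, skipped)
    return calls


def write_variants(calls: CallSet, path, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a :class:`CallSet` as a sorted VCF with LOD annotations in INFO."""
    header = pysam.VariantHeader()
    chroms = sorted({r.site.chrom for r in calls})
    for chrom in chroms:
        length = (contig_lengths or {}).get(chrom, 2**29)
        header.contigs.add(chrom, length=length)
    header.info.add("AF", "A", "Float", "Population allele frequency")
    header.info.add("FCLASS", "1", "String", "Functional class")
    header.info.add("PROV", ".", "String", "Caller provenance")
    for name, (info, typ) in _ANNOTATION_INFO.items():
        header.info.add(info, "1", typ, name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in calls:
            row = out.new_record(
                contig=rec.site.chrom,
                start=rec.site.pos - 1,
                alleles=(rec.ref, rec.alt),
            )
            row.id = rec.id
            if rec.qual is not None:
                row.qual = rec.qual
            if rec.population_af is not None:
                row.info["AF"] = (rec.population_af,)
            if rec.functional_class is not None:
                row.info["FCLASS"] = rec.functional_class.replace(" ", "_")
            if rec.provenance:
                row.info["PROV"] = tuple(sorted(rec.provenance))
            for name, value in rec.annotations.items():
                if name in _ANNOTATION_INFO:
                    row.info[_ANNOTATION_INFO[name][0]] = value
            out.write(row)


def _open_alignments(alignments) -> tuple[pysam.AlignmentFile, bool]:
    if isinstance(alignments, (str, Path)):
        return pysam.AlignmentFile(str(alignments), check_sq=False), True
    return alignments, False


def extract_pileups(
    alignments,
    site_refs: Mapping[GenomicSite, str],
    min_bq: int = 5,
    min_mq: int = 1,
) -> dict[GenomicSite, Pileup]:
    """Single-pass pileup extraction at a set of sites.

    One observation per read whose CIGAR aligns a query base to the site.
    Excluded: unmapped/secondary/supplementary reads, duplicate-flagged
    reads, reads below ``min_mq``, deletions and reference skips spanning
    the site, soft-clipped positions, N bases, and bases below ``min_bq``.

    ``alignments`` may be a SAM/BAM path or an open ``pysam.AlignmentFile``
    (streamed; no index required).
    """
    aln, own = _open_alignments(alignments)
    try:
        missing = sorted({s.chrom for s in site_refs} - set(aln.references or ()))
        if missing:
            raise ContigError(
                "contig(s) absent from alignment header: " + ", ".join(missing)
            )
        by_contig: dict[str, dict[int, GenomicSite]] = {}
        for site in site_refs:
            by_contig.setdefault(site.chrom, {})[site.pos - 1] = site
        sorted_pos = {c: sorted(d) for c, d in by_contig.items()}
        obs: dict[GenomicSite, list[ReadObservation]] = {s: [] for s in site_refs}

        for read in aln.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
            ):
                continue
            if read.mapping_quality < min_mq:
                continue
            contig_pos = by_contig.get(read.reference_name)
            if not contig_pos:
                continue
            positions = sorted_pos[read.reference_name]
            lo = bisect_left(positions, read.reference_start)
            hi = bisect_right(positions, (read.reference_end or read.reference_start) - 1)
            if lo >= hi:
                continue
            wanted = set(positions[lo:hi])
            seq = read.query_sequence
            quals = read.query_qualities
            if seq is None or quals is None:
                continue
            strand = "-" if read.is_reverse else "+"
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if rpos not in wanted:
                    continue
                base = seq[qpos].upper()
                if base not in NUCLEOTIDES:
                    continue
                bq = quals[qpos]
                if bq < min_bq:
                    continue
                obs[contig_pos[rpos]].append(
                    ReadObservation(base, bq, read.mapping_quality, strand)
                )
        return {
            site: Pileup(ref_allele=site_refs[site], observations=tuple(obs[site]), site=site)
            for site in site_refs
        }
    finally:
        if own:
            aln.close()


def extract_pileup(
    alignments, site: GenomicSite, ref_allele: str, min_bq: int = 5, min_mq: int = 1
) -> Pileup:
    """Pileup for a single site (see :func:`extract_pileups`)."""
    return extract_pileups(alignments, {site: ref_allele}, min_bq, min_mq)[site]


def read_pileup_tsv(path) -> dict[GenomicSite, Pileup]:
    """Read the alignment-free pileup TSV dialect.

    Columns (tab-separated, no header): chrom, pos (1-based), ref, base
    string, quality string (phred+33); one row per site per sample.
    """
    pileups: dict[GenomicSite, Pileup] = {}
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(f"{path}:{n}: expected 5 columns, got {len(fields)}")
            chrom, pos_s, ref, bases, quals = fields
            if len(bases) != len(quals):
                raise ParseError(
                    f"{path}:{n}: base string and quality string lengths differ"
                )
            try:
                site = GenomicSite(chrom, int(pos_s))
            except ValueError as exc:
                raise ParseError(f"{path}:{n}: {exc}") from exc
            observations = tuple(
                ReadObservation(b.upper(), ord(q) - 33)
                for b, q in zip(bases, quals)
                if b.upper() in NUCLEOTIDES
            )
            if site in pileups:
                raise ParseError(f"{path}:{n}: duplicate site {site}")
            pileups[site] = Pileup(ref_allele=ref.upper(), observations=observations, site=site)
    return pileups


def read_known_sites(path) -> set[Key]:
    """Known-variant (dbSNP-like) site keys from a VCF or a 4-column TSV.

    The TSV form is header-less: chrom, pos (1-based), ref, alt.
    """
    path = Path(path)
    if path.suffix.lower() in {".vcf", ".gz", ".bcf"}:
        return read_variants(path).keys()
    keys: set[Key] = set()
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{n}: expected 4 columns (chrom pos ref alt)")
            keys.add((fields[0], int(fields[1]), fields[2].upper(), fields[3].upper()))
    return keys


def subtract_callsets(tumor: CallSet, normal: CallSet) -> CallSet:
    """Records of ``tumor`` whose allele-aware key is absent from ``normal``."""
    out = CallSet(label=tumor.label)
    for rec in tumor:
        if rec not in normal:
            out.add(rec.copy())
    return out


def _merge_records(a: VariantRecord, b: VariantRecord) -> VariantRecord:
    merged = a.copy()
    merged.id = a.id if a.id is not None else b.id
    merged.qual = a.qual if a.qual is not None else b.qual
    merged.population_af = (
        a.population_af if a.population_af is not None else b.population_af
    )
    merged.functional_class = (
        a.functional_class if a.functional_class is not None else b.functional_class
    )
    merged.provenance = set(a.provenance) | set(b.provenance)
    merged.annotations = {**b.annotations, **a.annotations}
    return merged


def union_callsets(a: CallSet, b: CallSet, label: str | None = None) -> CallSet:
    """Key-wise union; colliding records merge annotations and provenance."""
    refs_at: dict[tuple[str, int], str] = {}
    for rec in list(a) + list(b):
        prev = refs_at.setdefault((rec.site.chrom, rec.site.pos), rec.ref)
        if prev != rec.ref:
            raise InconsistentInputError(
                f"conflicting reference alleles at {rec.site}: {prev!r} vs {rec.ref!r}"
            )
    out = CallSet(label=label if label is not None else f"{a.label}+{b.label}")
    for rec in a:
        out.add(rec.copy())
    for rec in b:
        existing = out.get(rec.key)
        if existing is None:
            out.add(rec.copy())
        else:
            out._records[rec.key] = _merge_records(existing, rec)
    return out


@dataclass
class SequencedRead:
    """An unaligned read: name, bases and per-base phred qualities."""

    name: str
    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ParseError(
                f"read {self.name}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality values"
            )


@dataclass
class QCSummary:
    total: int = 0
    kept: int = 0
    trimmed: int = 0
    dropped: int = 0


def apply_qc(
    read: SequencedRead, min_q: int = 20, max_lowq_frac: float = 0.8
) -> SequencedRead | None:
    """Trim low-quality 3' bases, then drop reads dominated by low quality.

    Bases with q < ``min_q`` are trimmed from the 3' end until a base at or
    above the threshold is reached.  The read is then dropped when the
    fraction of remaining bases below the threshold exceeds
    ``max_lowq_frac``, or when nothing remains.
    """
    end = len(read.qualities)
    while end > 0 and read.qualities[end - 1] < min_q:
        end -= 1
    if end == 0:
        return None
    lowq = sum(1 for q in read.qualities[:end] if q < min_q)
    if lowq / end > max_lowq_frac:
        return None
    if end == len(read.bases):
        return read
    return SequencedRead(read.name, read.bases[:end], read.qualities[:end])


def fastq_qc(
    in_path,
    out_path,
    min_q: int = 20,
    max_lowq_frac: float = 0.8,
    encoding: str = "phred33",
) -> QCSummary:
    """File-level FASTQ QC (see :func:`apply_qc`); returns kept/trimmed/dropped counts."""
    fmt = {"phred33": "fastq", "phred64": "fastq-illumina"}.get(encoding)
    if fmt is None:
        raise ValueError(f"unknown quality encoding {encoding!r}")
    summary = QCSummary()
    with open(out_path, "w") as out:
        try:
            for rec in SeqIO.parse(str(in_path), fmt):
                summary.total += 1
                read = SequencedRead(
                    rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"])
                )
                result = apply_qc(read, min_q=min_q, max_lowq_frac=max_lowq_frac)
                if result is None:
                    summary.dropped += 1
                    continue
                summary.kept += 1
                if len(result.bases) < len(read.bases):
                    summary.trimmed += 1
                out_rec = SeqRecord(
                    Seq(result.bases),
                    id=result.name,
                    description="",
                    letter_annotations={"phred_quality": list(result.qualities)},
                )
                SeqIO.write(out_rec, out, fmt)
        except ValueError as exc:
            raise ParseError(f"malformed FASTQ {in_path}: {exc}") from exc
    return summary
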