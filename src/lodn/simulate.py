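"""Artificial-tumor construction and synthetic read simulation.

Emulates the benchmarking protocol: plant single-nucleotide variants into
an existing alignment at target allele fractions (spike-in), thin an
alignment to a lower coverage (downsample), split one sample into two
pseudo-samples for specificity testing, and generate fully synthetic
reads with a uniform per-base error rate plus a truth VCF.

All randomness flows through an explicit seed; every operation is
bit-reproducible given (input, seed).
"""
from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seq_io import CallSet, GenomicSite, VariantRecord, write_variants
from .lod_core import NUCLEOTIDES

log = logging.getLogger(__name__)

__all__ = [
    "SpikeInSpec",
    "TruthSet",
    "SimConfig",
    "SimResult",
    "DuplicateSiteError",
    "parse_truth_table",
    "builtin_truth_table_path",
    "builtin_truth_sets",
    "map_truth_to_contig",
    "spike_in",
    "downsample",
    "split_sample",
    "synth_reads",
    "truth_callset",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


class DuplicateSiteError(ValueError):
    """The same site appears twice within one truth-table column."""


@dataclass(frozen=True)
class SpikeInSpec:
    """One variant to plant: site, alleles and the target allele fraction."""

    site: GenomicSite
    ref: str
    alt: str
    target_vaf: float

    def __post_init__(self) -> None:
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(f"alleles must be A/C/G/T at {self.site}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.site}")
        if not 0.0 < self.target_vaf <= 1.0:
            raise ValueError(
                f"target VAF must lie in (0, 1], got {self.target_vaf} at {self.site}"
            )


@dataclass(frozen=True)
class TruthSet:
    """A named collection of spike-in specifications with unique sites."""

    specs: tuple[SpikeInSpec, ...]
    label: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "specs",
            tuple(sorted(self.specs, key=lambda s: s.site.sort_key())),
        )
        sites = [s.site for s in self.specs]
        if len(set(sites)) != len(sites):
            raise DuplicateSiteError(f"duplicate sites in truth set {self.label!r}")

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {(s.site.chrom, s.site.pos, s.ref, s.alt) for s in self.specs}

    def vaf_of(self, site: GenomicSite) -> float | None:
        for s in self.specs:
            if s.site == site:
                return s.target_vaf
        return None


@dataclass(frozen=True)
class SimConfig:
    """Synthetic read generator settings.

    ``mean_depth`` in reads, ``read_length`` in bases, ``base_quality`` a
    uniform phred value, ``error_rate`` the per-base substitution
    probability (uniform over the three wrong bases).
    """

    mean_depth: float = 80.0
    read_length: int = 100
    base_quality: int = 30
    error_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


@dataclass
class SimResult:
    reference: str
    contig: str
    n_reads: int
    mean_depth: float
    sam_path: Path | None
    vcf_path: Path | None
    fasta_path: Path | None
    truth: CallSet


def parse_truth_table(path) -> dict[str, TruthSet]:
    """Parse a spike-in truth table into one :class:`TruthSet` per VAF column.

    Expected tab-separated columns: ``chrom``, ``pos``, ``ref``, ``alt``,
    then one VAF column per artificial tumor; ``NA`` cells are skipped, so
    each column's size is simply what the table contains.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"truth table {path} lacks columns: {sorted(missing)}")
    vaf_columns = [c for c in df.columns if c not in required]
    out: dict[str, TruthSet] = {}
    for col in vaf_columns:
        specs = []
        seen: set[GenomicSite] = set()
        for _, row in df.iterrows():
            vaf = row[col]
            if pd.isna(vaf):
                continue
            site = GenomicSite(str(row["chrom"]), int(row["pos"]))
            if site in seen:
                raise DuplicateSiteError(
                    f"duplicate site {site} in column {col!r} of {path}"
                )
            seen.add(site)
            specs.append(
                SpikeInSpec(site, str(row["ref"]).upper(), str(row["alt"]).upper(), float(vaf))
            )
        out[col] = TruthSet(tuple(specs), label=col)
    return out


def builtin_truth_table_path() -> Path:
    """Path of the packaged artificial-tumor truth table."""
    return Path(resources.files("lodn.data") / "artificial_tumors.tsv")


def builtin_truth_sets() -> dict[str, TruthSet]:
    """Truth sets of the packaged artificial-tumor table (low / intermediate /
    high tumor columns plus the matched-normal VAF column)."""
    return parse_truth_table(builtin_truth_table_path())


def map_truth_to_contig(
    truth: TruthSet,
    companions: Iterable[TruthSet] = (),
    spacing: int = 1000,
    margin: int = 200,
    contig: str = "sim1",
) -> tuple[TruthSet, list[TruthSet], int]:
    """Relocate truth sites onto one synthetic contig, evenly spaced.

    Returns the relocated truth set, relocated companions (e.g. the
    matched-normal VAF column restricted to shared sites), and the contig
    length.  Site order is preserved; alleles are unchanged.
    """
    mapping: dict[GenomicSite, GenomicSite] = {}
    for i, spec in enumerate(truth):
        mapping[spec.site] = GenomicSite(contig, margin + i * spacing + 1)
    relocated = TruthSet(
        tuple(
            SpikeInSpec(mapping[s.site], s.ref, s.alt, s.target_vaf) for s in truth
        ),
        label=truth.label,
    )
    relocated_companions = []
    for comp in companions:
        specs = tuple(
            SpikeInSpec(mapping[s.site], s.ref, s.alt, s.target_vaf)
            for s in comp
            if s.site in mapping
        )
        relocated_companions.append(TruthSet(specs, label=comp.label))
    length = margin + (len(truth) - 1) * spacing + margin + 1 if len(truth) else 2 * margin
    return relocated, relocated_companions, length


def _eligible_query_pos(read: pysam.AlignedSegment, pos0: int, min_bq: int, min_mq: int) -> int | None:
    """Query index of the base a read aligns to pos0, or None if ineligible."""
    if (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.mapping_quality < min_mq
    ):
        return None
    if not (read.reference_start <= pos0 < (read.reference_end or 0)):
        return None
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == pos0:
            if read.query_qualities[qpos] < min_bq:
                return None
            return qpos
    return None


def spike_in(
    in_sam,
    truth: TruthSet,
    out_sam,
    seed: int,
    min_bq: int = 5,
    min_mq: int = 1,
) -> pd.DataFrame:
    """Plant variants into an alignment at the truth set's target VAFs.

    At each site, ``k = round-half-up(target_vaf * eligible_depth)`` reads
    (at least 1) are chosen uniformly without replacement and have their
    aligned base rewritten to the alt allele — qualities, CIGAR, names and
    every other field untouched.  Eligibility mirrors pileup extraction
    (mapped primary non-duplicate reads with the base present and above the
    quality floors), so the realized VAF matches what the classifier sees.

    Returns a per-site report (target_vaf, eligible_depth, n_mutated,
    realized_vaf); uncovered sites trigger a warning and are excluded.
    """
    rng = np.random.default_rng(seed)
    with pysam.AlignmentFile(str(in_sam), check_sq=False) as aln:
        header = aln.header.to_dict()
        reads = list(aln.fetch(until_eof=True))

    rows = []
    uncovered = []
    for spec in truth:  # TruthSet iterates in deterministic genomic order
        pos0 = spec.site.pos - 1
        eligible: list[tuple[int, int]] = []
        for i, read in enumerate(reads):
            if read.reference_name != spec.site.chrom:
                continue
            qpos = _eligible_query_pos(read, pos0, min_bq, min_mq)
            if qpos is not None:
                eligible.append((i, qpos))
        depth = len(eligible)
        if depth == 0:
            uncovered.append(spec.site)
            warnings.warn(f"spike_in: no eligible reads cover {spec.site}", stacklevel=2)
            continue
        k = max(1, int(np.floor(spec.target_vaf * depth + 0.5)))
        k = min(k, depth)
        chosen = rng.choice(depth, size=k, replace=False)
        for j in chosen:
            i, qpos = eligible[j]
            read = reads[i]
            quals = read.query_qualities
            seq = list(read.query_sequence)
            seq[qpos] = spec.alt
            read.query_sequence = "".join(seq)
            read.query_qualities = quals  # assignment to sequence clears them
        rows.append(
            {
                "chrom": spec.site.chrom,
                "pos": spec.site.pos,
                "ref": spec.ref,
                "alt": spec.alt,
                "target_vaf": spec.target_vaf,
                "eligible_depth": depth,
                "n_mutated": k,
                "realized_vaf": k / depth,
            }
        )
    if uncovered:
        log.warning("spike_in: %d site(s) had no eligible coverage: %s",
                    len(uncovered), ", ".join(map(str, uncovered)))
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as out:
        for read in reads:
            out.write(read)
    return pd.DataFrame(rows)


def _name_fraction(seed: int, name: str) -> float:
    digest = hashlib.blake2b(f"{seed}:{name}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") / 2**64


def downsample(in_sam, out_sam, target_depth: float, current_depth: float, seed: int) -> int:
    """Thin an alignment to ``target_depth`` by keeping each read *name*
    (both mates together) with probability target/current via a seeded hash.

    Returns the number of alignment records written.
    """
    if target_depth > current_depth:
        raise ValueError(
            f"target depth {target_depth} exceeds current depth {current_depth}"
        )
    if target_depth <= 0 or current_depth <= 0:
        raise ValueError("depths must be positive")
    p = target_depth / current_depth
    written = 0
    with pysam.AlignmentFile(str(in_sam), check_sq=False) as aln:
        with pysam.AlignmentFile(str(out_sam), "w", header=aln.header) as out:
            for read in aln.fetch(until_eof=True):
                if _name_fraction(seed, read.query_name) < p:
                    out.write(read)
                    written += 1
    return written


def split_sample(in_sam, out_a, out_b, seed: int) -> tuple[int, int]:
    """Split one alignment into two disjoint halves by read name.

    Read names are ordered by a seeded hash (emulating query-name sorting
    of randomized names) and assigned alternately to the two halves, so
    mates stay together, the halves are disjoint, and their union is the
    input.  Returns the record counts of the two halves.
    """
    with pysam.AlignmentFile(str(in_sam), check_sq=False) as aln:
        names: dict[str, None] = {}
        for read in aln.fetch(until_eof=True):
            names.setdefault(read.query_name)
    ordered = sorted(names, key=lambda n: (_name_fraction(seed, n), n))
    assignment = {name: (i % 2 == 0) for i, name in enumerate(ordered)}
    n_a = n_b = 0
    with pysam.AlignmentFile(str(in_sam), check_sq=False) as aln:
        with pysam.AlignmentFile(str(out_a), "w", header=aln.header) as fa, \
             pysam.AlignmentFile(str(out_b), "w", header=aln.header) as fb:
            for read in aln.fetch(until_eof=True):
                if assignment[read.query_name]:
                    fa.write(read)
                    n_a += 1
                else:
                    fb.write(read)
                    n_b += 1
    return n_a, n_b


def truth_callset(vaf_map: Mapping[GenomicSite, tuple[str, str, float]], label: str = "truth") -> CallSet:
    calls = CallSet(label=label)
    for site, (ref, alt, vaf) in vaf_map.items():
        calls.add(
            VariantRecord(
                site=site, ref=ref, alt=alt,
                provenance={label},
                annotations={"target_vaf": float(vaf)},
            )
        )
    return calls


def synth_reads(
    contig_length: int,
    cfg: SimConfig,
    vaf_map: Mapping[GenomicSite, tuple[str, str, float]] | None = None,
    out_sam=None,
    out_vcf=None,
    out_fasta=None,
    contig: str = "sim1",
    reference: str | None = None,
) -> SimResult:
    """Generate a random reference segment and tiled single-end reads.

    Reads of ``cfg.read_length`` start uniformly over the contig to reach
    ``cfg.mean_depth`` on average; per-base errors are injected at
    ``cfg.error_rate`` (uniform over the three wrong bases); then each
    ``vaf_map`` entry ``site -> (ref, alt, vaf)`` forces the reference base
    to ``ref`` and flips each covering read to ``alt`` with probability
    ``vaf``.  Output is a coordinate-sorted SAM, a truth VCF and the
    reference FASTA; everything is determined by ``cfg.seed``.

    Pass ``reference`` (a sequence of length ``contig_length``) to reuse an
    existing genome — e.g. to draw a matched normal from the same reference
    as its tumor.
    """
    vaf_map = dict(vaf_map or {})
    for site, (ref, alt, vaf) in vaf_map.items():
        if not 0.0 <= vaf <= 1.0:
            raise ValueError(f"VAF must lie in [0, 1], got {vaf} at {site}")
        if site.chrom != contig or not 1 <= site.pos <= contig_length:
            raise ValueError(f"site {site} outside contig {contig}:1-{contig_length}")
        if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES or ref == alt:
            raise ValueError(f"bad alleles {ref}>{alt} at {site}")

    rng = np.random.default_rng(cfg.seed)
    L = cfg.read_length
    if contig_length < L:
        raise ValueError("contig shorter than the read length")

    if reference is not None:
        if len(reference) != contig_length:
            raise ValueError(
                f"reference length {len(reference)} != contig_length {contig_length}"
            )
        ref_codes = np.array([_CODE[b] for b in reference.upper()], dtype=np.uint8)
    else:
        ref_codes = rng.integers(0, 4, size=contig_length, dtype=np.uint8)
    for site, (ref, _alt, _vaf) in vaf_map.items():
        ref_codes[site.pos - 1] = _CODE[ref]

    n_reads = int(round(cfg.mean_depth * contig_length / L))
    starts = np.sort(rng.integers(0, contig_length - L + 1, size=n_reads))
    reads = ref_codes[starts[:, None] + np.arange(L)[None, :]].copy()

    if cfg.error_rate > 0:
        err = rng.random(reads.shape) < cfg.error_rate
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        reads[err] = (reads[err] + shift) % 4

    for site in sorted(vaf_map):
        ref, alt, vaf = vaf_map[site]
        pos0 = site.pos - 1
        covering = np.nonzero((starts <= pos0) & (pos0 < starts + L))[0]
        carrier = covering[rng.random(covering.size) < vaf]
        reads[carrier, pos0 - starts[carrier]] = _CODE[alt]

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": contig, "LN": int(contig_length)}],
    }
    qual = np.full(L, cfg.base_quality, dtype=np.uint8)
    sam_path = Path(out_sam) if out_sam is not None else None
    if sam_path is not None:
        with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
            ah = out.header
            for i in range(n_reads):
                a = pysam.AlignedSegment(ah)
                a.query_name = f"r{i:07d}"
                a.flag = 0
                a.reference_id = 0
                a.reference_start = int(starts[i])
                a.mapping_quality = 60
                a.cigartuples = [(0, L)]
                a.query_sequence = _BASE_BYTES[reads[i]].tobytes().decode()
                a.query_qualities = pysam.qualitystring_to_array(
                    chr(cfg.base_quality + 33) * L
                )
                out.write(a)

    reference = _BASE_BYTES[ref_codes].tobytes().decode()
    fasta_path = Path(out_fasta) if out_fasta is not None else None
    if fasta_path is not None:
        SeqIO.write(
            SeqRecord(Seq(reference), id=contig, description=""), str(fasta_path), "fasta"
        )

    truth = truth_callset(vaf_map)
    vcf_path = Path(out_vcf) if out_vcf is not None else None
    if vcf_path is not None:
        write_variants(truth, vcf_path, contig_lengths={contig: contig_length})

    depth = n_reads * L / contig_length
    return SimResult(
        reference=reference,
        contig=contig,
        n_reads=n_reads,
        mean_depth=depth,
        sam_path=sam_path,
        vcf_path=vcf_path,
        fasta_path=fasta_path,
        truth=truth,
    )
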