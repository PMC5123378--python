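"""The somatic-discovery pipeline stages.

Candidates from an independent tumor/normal caller are first reduced by
subtracting the normal-sample calls, then each surviving candidate is
re-examined jointly: pileups are extracted from both alignments and the
depth-gated LOD classifier decides somatic / germline / not detected.
The retained calls are merged (union) with a joint caller's output and
passed through functional-class and population-frequency filters.

Every stage returns a per-record tally alongside its call set so that
before/after counts are reproducible on any input.
"""
from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pysam
from Bio import SeqIO

from .lod_core import (
    INSUFFICIENT_DEPTH,
    NUCLEOTIDES,
    SOMATIC,
    ThresholdConfig,
    classify_somatic,
)
from .seq_io import (
    CallSet,
    ContigError,
    GenomicSite,
    Key,
    VariantRecord,
    extract_pileups,
    subtract_callsets,
    union_callsets,
)

log = logging.getLogger(__name__)

__all__ = [
    "PROVENANCE_TAG",
    "FUNCTIONAL_KEEP",
    "known_site_keys",
    "apply_gatk_lodn",
    "relaxed_reanalysis",
    "functional_filter",
    "population_filter",
    "scan_candidates",
    "run_pipeline",
]

PROVENANCE_TAG = "GATK-LODN"

#: Functional classes retained by :func:`functional_filter` (normalised to
#: lower case with underscores; "nonsynonymous SNV" style labels match).
FUNCTIONAL_KEEP = frozenset({"nonsynonymous", "nonsynonymous_snv", "stopgain", "stoploss"})


def known_site_keys(known_sites) -> set:
    """Normalise a known-sites source to a set of (chrom,pos,ref,alt) keys.

    Accepts None, a :class:`CallSet`, or any iterable of 4-tuples.
    """
    if known_sites is None:
        return set()
    if isinstance(known_sites, CallSet):
        return known_sites.keys()
    return {tuple(k) for k in known_sites}


def _is_known(rec: VariantRecord, keys: set, position_only: bool) -> bool:
    if rec.id is not None:
        return True
    if position_only:
        positions = {(k[0], k[1]) for k in keys}
        return (rec.site.chrom, rec.site.pos) in positions
    return rec.key in keys


def apply_gatk_lodn(
    candidates: CallSet,
    tumor,
    normal,
    known_sites=None,
    cfg: ThresholdConfig | None = None,
    min_bq: int = 5,
    min_mq: int = 1,
    position_only_known: bool = False,
) -> tuple[CallSet, Counter]:
    """Joint tumor/normal LOD classification of candidate SNVs.

    For each candidate, tumor and normal pileups are extracted (one pass
    per alignment source) and the depth-gated classifier runs; only
    verdict == somatic records survive, annotated with lod_t, lod_n, f_hat
    and both depths.  Returns (retained call set, per-verdict tally).
    """
    cfg = cfg or ThresholdConfig()
    keys = known_site_keys(known_sites)
    site_refs = {rec.site: rec.ref for rec in candidates}
    tally: Counter = Counter()
    out = CallSet(label=PROVENANCE_TAG)
    if not site_refs:
        return out, tally
    tumor_pileups = extract_pileups(tumor, site_refs, min_bq=min_bq, min_mq=min_mq)
    normal_pileups = extract_pileups(normal, site_refs, min_bq=min_bq, min_mq=min_mq)
    for rec in candidates:
        known = _is_known(rec, keys, position_only_known)
        result = classify_somatic(
            tumor_pileups[rec.site],
            normal_pileups[rec.site],
            rec.alt,
            cfg=cfg,
            known_site=known,
        )
        tally[result.verdict] += 1
        if result.verdict != SOMATIC:
            continue
        kept = rec.copy()
        s = result.scores
        kept.annotations.update(
            lod_t=round(s.lod_t, 4),
            lod_n=round(s.lod_n, 4),
            f_hat=round(s.f_hat, 4),
            tumor_depth=s.tumor_depth,
            normal_depth=s.normal_depth,
        )
        kept.provenance.add(PROVENANCE_TAG)
        out.add(kept)
    log.info("apply_gatk_lodn: %d candidates -> %d somatic (%s)",
             len(candidates), len(out), dict(tally))
    return out, tally


def relaxed_reanalysis(
    candidates: CallSet, tumor, normal, known_sites=None, **kwargs
) -> tuple[CallSet, Counter]:
    """Re-run the LOD filter with the lowered sensitivity-oriented preset.

    Because every threshold is lowered or unchanged, the output is a
    superset of the default-threshold output on the same input.
    """
    return apply_gatk_lodn(
        candidates, tumor, normal, known_sites,
        cfg=ThresholdConfig.relaxed(), **kwargs,
    )


def _normalise_class(value: str) -> str:
    return value.strip().lower().replace(" ", "_").replace("-", "_")


def functional_filter(
    calls: CallSet, keep_classes: frozenset[str] = FUNCTIONAL_KEEP
) -> tuple[CallSet, Counter]:
    """Keep exonic SNVs that are non-synonymous or gain/lose a stop codon.

    Records without a functional class are removed and tallied separately.
    """
    out = CallSet(label=calls.label)
    tally: Counter = Counter()
    for rec in calls:
        if rec.functional_class is None:
            tally["missing_class"] += 1
            continue
        if _normalise_class(rec.functional_class) in keep_classes:
            tally["kept"] += 1
            out.add(rec.copy())
        else:
            tally["removed"] += 1
    return out, tally


def population_filter(calls: CallSet, max_maf: float = 0.05) -> tuple[CallSet, Counter]:
    """Remove likely polymorphisms: population MAF strictly above ``max_maf``.

    Records with no recorded frequency are kept (removal needs positive
    evidence of being common).
    """
    out = CallSet(label=calls.label)
    tally: Counter = Counter()
    for rec in calls:
        af = rec.population_af
        if af is not None and not 0.0 <= af <= 1.0:
            raise ValueError(f"population AF outside [0, 1] at {rec.site}: {af}")
        if af is not None and af > max_maf:
            tally["removed"] += 1
        else:
            tally["kept"] += 1
            out.add(rec.copy())
    return out, tally


def _load_reference(reference) -> dict[str, str]:
    if isinstance(reference, Mapping):
        return {str(k): str(v).upper() for k, v in reference.items()}
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(reference), "fasta")
    }


def scan_candidates(
    alignments,
    reference,
    min_alt: int = 2,
    min_bq: int = 5,
    min_mq: int = 1,
    label: str = "scan",
) -> CallSet:
    """Permissive single-sample candidate scanner.

    Emits a candidate SNV at every site where at least ``min_alt`` quality-
    passing reads carry the same non-reference base.  Deliberately lenient:
    it exists to produce a raw per-sample candidate list for the joint LOD
    stage to classify.  ``reference`` is a FASTA path or a {contig: seq}
    mapping.
    """
    ref_seqs = _load_reference(reference)
    counts: dict[str, np.ndarray] = {}
    code = {ord(b): i for i, b in enumerate("ACGT")}
    own = isinstance(alignments, (str, Path))
    aln = pysam.AlignmentFile(str(alignments), check_sq=False) if own else alignments
    try:
        lengths = dict(zip(aln.references or (), aln.lengths or ()))
        for read in aln.fetch(until_eof=True):
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.mapping_quality < min_mq
            ):
                continue
            contig = read.reference_name
            if contig not in ref_seqs:
                continue
            if contig not in counts:
                counts[contig] = np.zeros((lengths.get(contig, len(ref_seqs[contig])), 4), dtype=np.int32)
            seq = read.query_sequence
            quals = read.query_qualities
            if seq is None or quals is None:
                continue
            cig = read.cigartuples
            if cig is not None and len(cig) == 1 and cig[0][0] == 0:
                # fast path: gapless full-length match
                codes = np.frombuffer(seq.encode(), dtype=np.uint8)
                qarr = np.asarray(quals, dtype=np.int32)
                base_idx = np.full(codes.shape, -1, dtype=np.int8)
                for byte, idx in code.items():
                    base_idx[codes == byte] = idx
                ok = (base_idx >= 0) & (qarr >= min_bq)
                rpos = read.reference_start + np.nonzero(ok)[0]
                np.add.at(counts[contig], (rpos, base_idx[ok].astype(np.intp)), 1)
            else:
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    b = seq[qpos].upper()
                    if b in "ACGT" and quals[qpos] >= min_bq:
                        counts[contig][rpos, "ACGT".index(b)] += 1
    finally:
        if own:
            aln.close()

    out = CallSet(label=label)
    for contig, mat in counts.items():
        refseq = ref_seqs[contig]
        hot = np.nonzero(mat.max(axis=1) >= min_alt)[0]
        for pos0 in hot:
            if pos0 >= len(refseq):
                continue
            ref = refseq[pos0]
            if ref not in NUCLEOTIDES:
                continue
            for j, altbase in enumerate("ACGT"):
                if altbase == ref or mat[pos0, j] < min_alt:
                    continue
                out.add(
                    VariantRecord(
                        site=GenomicSite(contig, int(pos0) + 1),
                        ref=ref,
                        alt=altbase,
                        provenance={label},
                    )
                )
    return out


def run_pipeline(
    mutect_calls: CallSet,
    gatk_tumor: CallSet,
    gatk_normal: CallSet,
    tumor,
    normal,
    known_sites=None,
    cfg: ThresholdConfig | None = None,
    max_maf: float = 0.05,
    **lodn_kwargs,
) -> tuple[CallSet, dict]:
    """End-to-end merge: subtract, LOD-classify, union, then filter.

    candidates = gatk_tumor \\ gatk_normal; the LOD stage retains somatic
    candidates; the final list is the union with the joint caller's calls,
    filtered on functional class and population frequency.  Returns the
    final call set and a per-stage count dictionary.
    """
    candidates = subtract_callsets(gatk_tumor, gatk_normal)
    lodn_calls, verdicts = apply_gatk_lodn(
        candidates, tumor, normal, known_sites, cfg=cfg, **lodn_kwargs
    )
    merged = union_callsets(mutect_calls, lodn_calls, label="merged")
    after_functional, functional_tally = functional_filter(merged)
    final, population_tally = population_filter(after_functional, max_maf=max_maf)
    counts = {
        "mutect": len(mutect_calls),
        "gatk_tumor": len(gatk_tumor),
        "gatk_normal": len(gatk_normal),
        "candidates": len(candidates),
        "lodn_verdicts": dict(verdicts),
        "lodn_somatic": len(lodn_calls),
        "union": len(merged),
        "after_functional_filter": len(after_functional),
        "functional_tally": dict(functional_tally),
        "final": len(final),
        "population_tally": dict(population_tally),
    }
    log.info("run_pipeline stage counts: %s", counts)
    return final, counts
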