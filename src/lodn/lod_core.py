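"""Per-read likelihood model and tumor/normal log-odds (LOD) statistics.

A candidate single-nucleotide variant is scored against two pileups — one
from the tumor sample and one from the matched normal.  Each aligned base
``b`` observed at the site contributes a likelihood under an allele-fraction
model ``f``:

    P(b | f) = f * P(b | alt) + (1 - f) * P(b | ref)

where ``P(b | a) = 1 - e`` when the observed base equals allele ``a`` and
``e / 3`` otherwise, with ``e`` the phred-derived probability that the base
call is wrong.  Reads are conditionally independent, so the site likelihood
is the product over the pileup (computed in log10 space).

Two log-odds statistics follow:

* ``LOD_T`` on the tumor pileup compares the maximum-likelihood allele
  fraction ``f_hat`` against ``f = 0`` (no variant).  Large values mean the
  variant is confidently *detected* in the tumor.
* ``LOD_N`` on the normal pileup compares ``f = 0`` (reference only, all
  non-reference bases are sequencing noise) against ``f = 0.5`` (germline
  heterozygote).  Large values mean the normal sample is confidently clean,
  supporting a *somatic* classification.

Classification gates on minimum read depth first, then on ``LOD_T`` versus
the detection threshold, then on ``LOD_N`` versus the germline threshold —
with a stricter normal-side threshold at known polymorphic (dbSNP-like)
sites, where prior odds of a germline variant are higher.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NUCLEOTIDES",
    "MAX_ERROR_PROB",
    "InconsistentInputError",
    "ReadObservation",
    "Pileup",
    "ThresholdConfig",
    "LodScores",
    "SomaticClassification",
    "SOMATIC",
    "GERMLINE",
    "NOT_DETECTED",
    "INSUFFICIENT_DEPTH",
    "VERDICTS",
    "base_error_prob",
    "read_likelihood",
    "site_log_likelihood",
    "compute_lod_n",
    "compute_lod_t",
    "classify_somatic",
]

NUCLEOTIDES = frozenset("ACGT")

# Clamp so that 1 - e never drops below e/3 (inversion would make a
# miscalled base *more* likely than a correct one at q < 2).
MAX_ERROR_PROB = 0.75

SOMATIC = "somatic"
GERMLINE = "germline"
NOT_DETECTED = "not_detected"
INSUFFICIENT_DEPTH = "insufficient_depth"
VERDICTS = frozenset({SOMATIC, GERMLINE, NOT_DETECTED, INSUFFICIENT_DEPTH})


class InconsistentInputError(ValueError):
    """Inputs that disagree with each other (e.g. mismatched ref alleles)."""


@dataclass(frozen=True)
class ReadObservation:
    """One aligned base at a site: the call, its qualities and strand."""

    base: str
    base_quality: int
    map_quality: int = 60
    strand: str = "+"
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if self.base not in NUCLEOTIDES:
            raise ValueError(f"base must be one of A/C/G/T, got {self.base!r}")
        if self.base_quality < 0 or self.map_quality < 0:
            raise ValueError("phred qualities must be non-negative")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class Pileup:
    """The stack of read observations covering one genomic position."""

    ref_allele: str
    observations: tuple[ReadObservation, ...] = ()
    site: object | None = None  # typically a seq_io.GenomicSite

    def __post_init__(self) -> None:
        if self.ref_allele not in NUCLEOTIDES:
            raise ValueError(f"ref allele must be A/C/G/T, got {self.ref_allele!r}")
        object.__setattr__(self, "observations", tuple(self.observations))

    @property
    def depth(self) -> int:
        return len(self.observations)

    def base_count(self, base: str) -> int:
        return sum(1 for o in self.observations if o.base == base)


@dataclass(frozen=True)
class ThresholdConfig:
    """Decision surface of the classifier.

    ``theta_t`` gates detection (LOD_T), ``theta_n`` gates the somatic
    verdict (LOD_N), and ``theta_n_dbsnp`` replaces ``theta_n`` at known
    polymorphic sites.  Depth minima are applied to the filtered pileups
    before any likelihood is computed.  All comparisons are inclusive (>=).
    """

    theta_t: float = 6.5
    theta_n: float = 2.2
    theta_n_dbsnp: float = 5.5
    min_normal_depth: int = 8
    min_tumor_depth: int = 14

    def __post_init__(self) -> None:
        for name in ("theta_t", "theta_n", "theta_n_dbsnp"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("min_normal_depth", "min_tumor_depth"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{name} must be a positive integer")

    @classmethod
    def relaxed(cls, **overrides) -> "ThresholdConfig":
        """Lowered thresholds used for sensitivity-oriented re-analysis."""
        overrides.setdefault("theta_t", 4.5)
        overrides.setdefault("theta_n_dbsnp", 3.0)
        return cls(**overrides)


@dataclass(frozen=True)
class LodScores:
    f_hat: float
    lod_t: float
    lod_n: float
    tumor_depth: int
    normal_depth: int


@dataclass(frozen=True)
class SomaticClassification:
    verdict: str
    scores: LodScores | None
    known_site: bool = False

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def base_error_prob(q: int) -> float:
    """Phred quality -> probability the base call is wrong, clamped to 0.75."""
    if q < 0:
        raise ValueError(f"phred quality must be non-negative, got {q}")
    return min(10.0 ** (-q / 10.0), MAX_ERROR_PROB)


def _check_alleles(ref: str, alt: str) -> None:
    if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
        raise ValueError(f"alleles must be A/C/G/T, got ref={ref!r} alt={alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt alleles must differ (both {ref!r})")


def read_likelihood(obs: ReadObservation, ref: str, alt: str, f: float) -> float:
    """P(observed base | allele fraction f) for a single read."""
    _check_alleles(ref, alt)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"allele fraction must lie in [0, 1], got {f}")
    e = base_error_prob(obs.base_quality)
    p_ref = 1.0 - e if obs.base == ref else e / 3.0
    p_alt = 1.0 - e if obs.base == alt else e / 3.0
    return f * p_alt + (1.0 - f) * p_ref


def _prob_arrays(pileup: Pileup, alt: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-read P(b|ref) and P(b|alt) vectors for the pileup."""
    ref = pileup.ref_allele
    _check_alleles(ref, alt)
    n = pileup.depth
    p_ref = np.empty(n)
    p_alt = np.empty(n)
    for i, obs in enumerate(pileup.observations):
        e = base_error_prob(obs.base_quality)
        p_ref[i] = 1.0 - e if obs.base == ref else e / 3.0
        p_alt[i] = 1.0 - e if obs.base == alt else e / 3.0
    return p_ref, p_alt


def site_log_likelihood(pileup: Pileup, alt: str, f: float) -> float:
    """log10 likelihood of the pileup under allele fraction ``f``.

    Empty pileups carry no evidence and return 0 (log of an empty product).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"allele fraction must lie in [0, 1], got {f}")
    if pileup.depth == 0:
        _check_alleles(pileup.ref_allele, alt)
        return 0.0
    p_ref, p_alt = _prob_arrays(pileup, alt)
    return float(np.sum(np.log10(f * p_alt + (1.0 - f) * p_ref)))


def compute_lod_n(normal_pileup: Pileup, alt: str) -> float:
    """LOD_N: log10 [ P(pileup | f=0) / P(pileup | f=0.5) ] on the normal.

    Model 1 — the variant does not exist in the normal sample and every
    non-reference base is sequencing noise.  Model 2 — the variant truly
    exists as a germline heterozygote.  Positive values favour model 1.
    """
    if normal_pileup.depth == 0:
        _check_alleles(normal_pileup.ref_allele, alt)
        return 0.0
    p_ref, p_alt = _prob_arrays(normal_pileup, alt)
    ll_noise = np.sum(np.log10(p_ref))
    ll_het = np.sum(np.log10(0.5 * p_alt + 0.5 * p_ref))
    return float(ll_noise - ll_het)


def _fraction_grid(pileup: Pileup, alt: str) -> np.ndarray:
    grid = np.arange(101) / 100.0
    if pileup.depth:
        f_emp = pileup.base_count(alt) / pileup.depth
        grid = np.union1d(grid, [f_emp])
    return grid


def compute_lod_t(tumor_pileup: Pileup, alt: str) -> tuple[float, float]:
    """(f_hat, LOD_T) on the tumor pileup.

    ``f_hat`` maximises the site likelihood over the grid {0, 0.01, ..., 1}
    augmented with the empirical alt fraction; ties break toward smaller f.
    ``LOD_T = ll(f_hat) - ll(0) >= 0`` since f = 0 is in the grid.
    """
    _check_alleles(tumor_pileup.ref_allele, alt)
    if tumor_pileup.depth == 0:
        return 0.0, 0.0
    p_ref, p_alt = _prob_arrays(tumor_pileup, alt)
    fs = _fraction_grid(tumor_pileup, alt)
    # ll[j] = sum_i log10(f_j * p_alt_i + (1 - f_j) * p_ref_i)
    ll = np.sum(np.log10(np.outer(fs, p_alt) + np.outer(1.0 - fs, p_ref)), axis=1)
    j = int(np.argmax(ll))  # first (smallest-f) maximum on exact ties
    return float(fs[j]), float(ll[j] - ll[0])


def classify_somatic(
    tumor_pileup: Pileup,
    normal_pileup: Pileup,
    alt: str,
    cfg: ThresholdConfig | None = None,
    known_site: bool = False,
) -> SomaticClassification:
    """Depth-gated two-stage somatic/germline call for one candidate SNV.

    Order of decisions: insufficient_depth (before any likelihood),
    not_detected (LOD_T below theta_t), then somatic vs germline on LOD_N
    against theta_n (theta_n_dbsnp at known sites).  All inclusive (>=).
    """
    cfg = cfg or ThresholdConfig()
    if tumor_pileup.ref_allele != normal_pileup.ref_allele:
        raise InconsistentInputError(
            "tumor and normal pileups disagree on the reference allele: "
            f"{tumor_pileup.ref_allele!r} vs {normal_pileup.ref_allele!r}"
        )
    if (
        normal_pileup.depth < cfg.min_normal_depth
        or tumor_pileup.depth < cfg.min_tumor_depth
    ):
        return SomaticClassification(INSUFFICIENT_DEPTH, None, known_site)

    f_hat, lod_t = compute_lod_t(tumor_pileup, alt)
    lod_n = compute_lod_n(normal_pileup, alt)
    scores = LodScores(f_hat, lod_t, lod_n, tumor_pileup.depth, normal_pileup.depth)

    if lod_t < cfg.theta_t:
        return SomaticClassification(NOT_DETECTED, scores, known_site)
    theta = cfg.theta_n_dbsnp if known_site else cfg.theta_n
    verdict = SOMATIC if lod_n >= theta else GERMLINE
    return SomaticClassification(verdict, scores, known_site)
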