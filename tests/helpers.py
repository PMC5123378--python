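"""Shared test utilities.

``exact_*`` functions form an independent oracle for the likelihood core:
per-read probabilities are converted exactly to 50-digit decimals, site
likelihoods are direct products (no logs), the allele-fraction grid search
compares products directly, and log10 is applied only to the final ratio.
"""
from decimal import Decimal, getcontext
from fractions import Fraction

import pysam

from lodn.lod_core import Pileup, ReadObservation

getcontext().prec = 50


def exact_read_probs(base: str, q: int, ref: str, alt: str) -> tuple[Decimal, Decimal]:
    e = min(10.0 ** (-q / 10.0), 0.75)
    p_ref = 1.0 - e if base == ref else e / 3.0
    p_alt = 1.0 - e if base == alt else e / 3.0
    return Decimal(p_ref), Decimal(p_alt)


def exact_product(obs: list[tuple[str, int]], ref: str, alt: str, f) -> Decimal:
    """Direct product of per-read likelihoods at allele fraction ``f``."""
    f = Decimal(Fraction(f).numerator) / Decimal(Fraction(f).denominator)
    total = Decimal(1)
    for base, q in obs:
        p_ref, p_alt = exact_read_probs(base, q, ref, alt)
        total *= f * p_alt + (1 - f) * p_ref
    return total


def exact_lod_n(obs: list[tuple[str, int]], ref: str, alt: str) -> float:
    if not obs:
        return 0.0
    ratio = exact_product(obs, ref, alt, 0) / exact_product(obs, ref, alt, Fraction(1, 2))
    return float(ratio.log10())


def exact_lod_t(obs: list[tuple[str, int]], ref: str, alt: str) -> tuple[float, float]:
    """Grid-search MLE in exact probability space; first (smallest-f) max."""
    if not obs:
        return 0.0, 0.0
    grid = [Fraction(i, 100) for i in range(101)]
    emp = Fraction(sum(1 for b, _ in obs if b == alt), len(obs))
    if emp not in grid:
        grid = sorted(grid + [emp])
    products = [exact_product(obs, ref, alt, f) for f in grid]
    best = 0
    for j in range(1, len(products)):
        if products[j] > products[best]:
            best = j
    lod = (products[best] / products[0]).log10()
    return float(grid[best]), float(lod)


def make_pileup(ref: str, bases: str, q: int = 30, site=None) -> Pileup:
    """Pileup from a base string at uniform quality."""
    return Pileup(
        ref_allele=ref,
        observations=tuple(ReadObservation(b, q) for b in bases),
        site=site,
    )


def obs_list(pileup: Pileup) -> list[tuple[str, int]]:
    return [(o.base, o.base_quality) for o in pileup.observations]


def write_paired_sam(path, n_pairs: int, contig: str = "c1", length: int = 2000,
                     read_len: int = 50, seed: int = 0) -> None:
    """A small coordinate-unsorted paired-end SAM for pair-integrity tests."""
    import numpy as np

    rng = np.random.default_rng(seed)
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": contig, "LN": length}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i in range(n_pairs):
            start1 = int(rng.integers(0, length - 3 * read_len))
            start2 = start1 + read_len + int(rng.integers(0, read_len))
            for mate, (start, flag) in enumerate([(start1, 99), (start2, 147)]):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"pair{i:05d}"
                a.flag = flag
                a.reference_id = 0
                a.reference_start = start
                a.mapping_quality = 60
                a.cigartuples = [(0, read_len)]
                a.query_sequence = "".join(rng.choice(list("ACGT"), read_len))
                a.query_qualities = pysam.qualitystring_to_array("I" * read_len)
                a.next_reference_id = 0
                a.next_reference_start = start2 if mate == 0 else start1
                out.write(a)
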