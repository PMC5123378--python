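"""Benchmark scoring: confusion counts, coverage titration, split-sample
specificity, and the spike-recovery experiment on synthetic pairs.

True/false positives are matched allele-aware on (chrom, pos, ref, alt).
PPV = TP / (TP + FP) and FDR = FP / (TP + FP); both are undefined (rendered
"NA", never 0) when no positive calls were made.
"""
from __future__ import annotations

import logging
import tempfile
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .lod_core import SOMATIC, ThresholdConfig, classify_somatic
from .seq_io import CallSet, GenomicSite, extract_pileups
from .simulate import (
    SimConfig,
    TruthSet,
    downsample,
    map_truth_to_contig,
    split_sample,
    synth_reads,
)

log = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "score_callset",
    "coverage_titration",
    "specificity_experiment",
    "spike_recovery",
    "simulate_truth_pair",
    "plot_coverage_curve",
]

Caller = Callable[[object, object], CallSet]  # (tumor source, normal source) -> calls


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/FP against a truth set, with PPV and FDR derived."""

    tp: int
    fn: int
    fp: int

    @property
    def ppv(self) -> float | None:
        called = self.tp + self.fp
        return self.tp / called if called else None

    @property
    def fdr(self) -> float | None:
        called = self.tp + self.fp
        return self.fp / called if called else None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "ppv": "NA" if self.ppv is None else self.ppv,
            "fdr": "NA" if self.fdr is None else self.fdr,
        }


def score_callset(calls: CallSet, truth: TruthSet) -> ConfusionCounts:
    """Allele-aware confusion counts of a call set against a truth set."""
    truth_keys = truth.keys()
    call_keys = calls.keys()
    tp = len(call_keys & truth_keys)
    return ConfusionCounts(tp=tp, fn=len(truth_keys) - tp, fp=len(call_keys - truth_keys))


def simulate_truth_pair(
    tumor_truth: TruthSet,
    normal_truth: TruthSet | None,
    seed: int,
    sim_cfg: SimConfig | None = None,
    workdir=None,
    spacing: int = 1000,
    contig_length: int | None = None,
) -> tuple[Path, Path, Path, TruthSet]:
    """Build a matched synthetic tumor/normal SAM pair for a truth set.

    Truth sites are relocated onto one synthetic contig (``spacing`` bases
    apart) so the pair can be generated at any scale; the normal sample
    carries the matched-normal VAFs at shared sites (0 elsewhere).  Returns
    (tumor SAM, normal SAM, reference FASTA, relocated truth).
    """
    cfg = sim_cfg or SimConfig()
    workdir = Path(workdir) if workdir is not None else Path(tempfile.mkdtemp(prefix="lodn-sim-"))
    workdir.mkdir(parents=True, exist_ok=True)
    relocated, companions, min_length = map_truth_to_contig(
        tumor_truth, [normal_truth] if normal_truth is not None else [], spacing=spacing
    )
    length = max(contig_length or 0, min_length)
    tumor_map = {s.site: (s.ref, s.alt, s.target_vaf) for s in relocated}
    normal_map = {s.site: (s.ref, s.alt, 0.0) for s in relocated}
    if companions:
        for s in companions[0]:
            normal_map[s.site] = (s.ref, s.alt, s.target_vaf)

    tumor_sam = workdir / f"tumor_s{seed}.sam"
    normal_sam = workdir / f"normal_s{seed}.sam"
    fasta = workdir / f"ref_s{seed}.fa"
    # Both samples are drawn from one shared reference genome (the tumor's
    # draw) with independent read/error seeds.
    tumor_cfg = SimConfig(
        mean_depth=cfg.mean_depth, read_length=cfg.read_length,
        base_quality=cfg.base_quality, error_rate=cfg.error_rate,
        seed=(2 * seed) % 2**31,
    )
    normal_cfg = SimConfig(
        mean_depth=cfg.mean_depth, read_length=cfg.read_length,
        base_quality=cfg.base_quality, error_rate=cfg.error_rate,
        seed=(2 * seed + 1) % 2**31,
    )
    tumor_result = synth_reads(
        length, tumor_cfg, tumor_map, out_sam=tumor_sam, out_fasta=fasta
    )
    synth_reads(
        length, normal_cfg, normal_map, out_sam=normal_sam,
        reference=tumor_result.reference,
    )
    return tumor_sam, normal_sam, fasta, relocated


def spike_recovery(
    tumor_truth: TruthSet,
    normal_truth: TruthSet | None,
    seed: int,
    sim_cfg: SimConfig | None = None,
    thresholds: ThresholdConfig | None = None,
    workdir=None,
) -> tuple[int, Counter]:
    """Classify every truth site on a synthetic pair; count somatic verdicts.

    Generates an ~``sim_cfg.mean_depth`` tumor/normal pair carrying the
    truth-set VAFs (normal-column VAFs in the matched normal, 0 where
    absent), extracts both pileups at each truth site and runs the default
    classifier with every site treated as unknown (non-dbSNP).  Returns
    (number of truth sites called somatic, per-verdict tally).
    """
    with tempfile.TemporaryDirectory(prefix="lodn-rec-") as tmp:
        wd = Path(workdir) if workdir is not None else Path(tmp)
        tumor_sam, normal_sam, _fasta, relocated = simulate_truth_pair(
            tumor_truth, normal_truth, seed, sim_cfg, workdir=wd
        )
        site_refs = {s.site: s.ref for s in relocated}
        tumor_pileups = extract_pileups(tumor_sam, site_refs)
        normal_pileups = extract_pileups(normal_sam, site_refs)
        tally: Counter = Counter()
        for spec in relocated:
            result = classify_somatic(
                tumor_pileups[spec.site],
                normal_pileups[spec.site],
                spec.alt,
                cfg=thresholds,
                known_site=False,
            )
            tally[result.verdict] += 1
        return tally[SOMATIC], tally


def coverage_titration(
    tumor_sam,
    normal_sam,
    truth: TruthSet,
    caller: Caller,
    grid: Sequence[int] = tuple(range(5, 85, 5)),
    seeds: Iterable[int] = (0,),
    source_depth: float = 80.0,
    method: str = "GATK-LODN",
    workdir=None,
) -> pd.DataFrame:
    """Downsample both samples over a coverage grid and score each level.

    Returns a tidy frame with one row per (coverage, seed): tp, fn, fp and
    the derived rates.  TP + FN equals the truth-set size at every level.
    """
    rows = []
    with tempfile.TemporaryDirectory(prefix="lodn-titr-") as tmp:
        wd = Path(workdir) if workdir is not None else Path(tmp)
        wd.mkdir(parents=True, exist_ok=True)
        for seed in seeds:
            for level in grid:
                if level > source_depth:
                    raise ValueError(
                        f"grid level {level}X exceeds source depth {source_depth}X"
                    )
                t_out = wd / f"t_{level}x_s{seed}.sam"
                n_out = wd / f"n_{level}x_s{seed}.sam"
                downsample(tumor_sam, t_out, level, source_depth, seed=seed * 10007 + level)
                downsample(normal_sam, n_out, level, source_depth, seed=seed * 10007 + level + 1)
                counts = score_callset(caller(t_out, n_out), truth)
                rows.append(
                    {
                        "coverage": level,
                        "method": method,
                        "seed": seed,
                        **counts.as_dict(),
                    }
                )
    return pd.DataFrame(rows)


def specificity_experiment(
    sam_path,
    caller: Caller,
    seed: int,
    workdir=None,
    both_orientations: bool = True,
) -> dict[str, int]:
    """Split one sample in two and count calls between the halves.

    The two halves come from the same library, so every emitted call is a
    false positive by construction.  Reported for both role assignments
    (half A as tumor, then half B) since the classifier is asymmetric.
    """
    with tempfile.TemporaryDirectory(prefix="lodn-spec-") as tmp:
        wd = Path(workdir) if workdir is not None else Path(tmp)
        wd.mkdir(parents=True, exist_ok=True)
        half_a = wd / "half_a.sam"
        half_b = wd / "half_b.sam"
        split_sample(sam_path, half_a, half_b, seed=seed)
        out = {"a_vs_b": len(caller(half_a, half_b))}
        if both_orientations:
            out["b_vs_a"] = len(caller(half_b, half_a))
        return out


def plot_coverage_curve(df: pd.DataFrame, path) -> None:
    """Write a TP/FN-versus-coverage figure for a titration frame."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for method, sub in df.groupby("method"):
        agg = sub.groupby("coverage")[["tp", "fn"]].mean()
        ax.plot(agg.index, agg["tp"], marker="o", label=f"{method} TP")
        ax.plot(agg.index, agg["fn"], marker="s", linestyle="--", label=f"{method} FN")
    ax.set_xlabel("simulated coverage (X)")
    ax.set_ylabel("variant count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
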