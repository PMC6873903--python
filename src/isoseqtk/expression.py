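"""Transcript quantification summaries and differential-expression calling.

Counts are inputs (fragment counts per transcript and sample); expression is
normalized to FPKM (fragments per kilobase of transcript per million mapped
fragments).  The two-condition contrast (seawater SW relative to freshwater
FW) reports log2 fold change — with ``+inf``/``-inf`` when one condition is
silent and ``NA`` when both are — a per-transcript p-value, and a
Benjamini-Hochberg FDR.  A transcript is a DET (differentially expressed
transcript) at FDR < 0.05 and |fold change| >= 2.

The per-transcript p-value provider is pluggable.  The built-in default is
a moderated t-test on log2(FPKM + 1): per-transcript variances are shrunk
toward a common prior by empirical Bayes (the classic squeeze of sample
variances toward a fitted scaled inverse chi-square prior), which recovers
the information sharing that makes count-based tools usable at two or three
replicates per condition.  A Welch t-test and an exact permutation test are
available as alternatives (the permutation p-value granularity is
1/C(n1+n2, n1), far too coarse at n = 3).  Genes with two or more DETs are
grouped into ``similar`` (all fold changes one sign) or ``opposite`` (both
signs) expression patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

FDR_THRESHOLD = 0.05
MIN_ABS_LOG2FC = 1.0  # |fold change| >= 2


@dataclass
class CountMatrix:
    """Fragment counts (transcripts x samples) with design and lengths."""

    counts: pd.DataFrame  # index: transcript ids, columns: sample ids
    condition: Mapping[str, str]  # sample -> {"FW", "SW"}
    gene_of: Mapping[str, str]  # transcript -> gene
    lengths: Mapping[str, int]  # transcript -> bp

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        groups = {self.condition[s] for s in self.counts.columns}
        if not {"FW", "SW"} <= groups:
            raise ValueError("need at least one sample per condition (FW and SW)")

    def samples(self, cond: str) -> list[str]:
        return [s for s in self.counts.columns if self.condition[s] == cond]


@dataclass
class DETResult:
    transcript_id: str
    gene_id: str
    mean_fpkm_fw: float
    mean_fpkm_sw: float
    log2fc: float | None  # None encodes NA; +/-inf allowed
    pvalue: float | None
    fdr: float | None
    is_det: bool = False
    direction: str | None = None  # up | down


@dataclass(frozen=True)
class GeneDETPattern:
    gene_id: str
    det_transcripts: tuple[str, ...]
    pattern: str  # similar | opposite


def fpkm(count: float, transcript_len_bp: int, total_mapped_fragments: float) -> float:
    """10^9 * count / (library size * transcript length)."""
    if transcript_len_bp <= 0:
        raise ValueError("transcript length must be positive")
    if total_mapped_fragments <= 0:
        raise ValueError("library size must be positive")
    return 1e9 * count / (total_mapped_fragments * transcript_len_bp)


def fpkm_matrix(cm: CountMatrix) -> pd.DataFrame:
    """Per-sample FPKM for every transcript (library size = column sum)."""
    totals = cm.counts.sum(axis=0)
    lengths = pd.Series({t: cm.lengths[t] for t in cm.counts.index}, dtype=float)
    return 1e9 * cm.counts.div(totals, axis=1).div(lengths, axis=0)


def log2fc(mean_fw: float, mean_sw: float) -> float | None:
    """log2(SW/FW); +inf when FW silent, -inf when SW silent, NA when both."""
    if mean_fw < 0 or mean_sw < 0:
        raise ValueError("means must be non-negative")
    if mean_fw == 0 and mean_sw == 0:
        return None
    if mean_fw == 0:
        return math.inf
    if mean_sw == 0:
        return -math.inf
    return math.log2(mean_sw / mean_fw)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    if len(pvalues) == 0:
        return []
    arr = np.asarray(pvalues, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    return list(multipletests(arr, method="fdr_bh")[1])


def welch_log_test(fw: np.ndarray, sw: np.ndarray) -> float:
    """Welch t-test on log2(FPKM + 1); p = 1 for degenerate inputs."""
    a, b = np.log2(fw + 1.0), np.log2(sw + 1.0)
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return float(p) if np.isfinite(p) else 1.0


def permutation_log_test(fw: np.ndarray, sw: np.ndarray) -> float:
    """Exact permutation test on the difference of mean log2(FPKM + 1)."""
    a, b = np.log2(fw + 1.0), np.log2(sw + 1.0)
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    n = len(a)
    idx = range(len(pooled))
    count = 0
    total = 0
    for chosen in combinations(idx, n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(chosen)] = True
        if abs(pooled[mask].mean() - pooled[~mask].mean()) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (x > 0)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return y


def _squeeze_var(s2: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of sample variances toward a common prior.

    Fits a scaled inverse chi-square prior (s0^2, d0) to the observed
    variances by matching moments of log(s2), then returns the posterior
    variances (d0*s0^2 + df*s2)/(d0 + df) and the prior df d0 (inf when the
    variances are consistent with a single common value).
    """
    s2 = np.maximum(s2, 1e-10)
    z = np.log(s2) - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    evar = float(np.var(z, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s20 = math.exp(
            float(np.mean(z)) + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
        post = (d0 * s20 + df * s2) / (d0 + df)
        return post, d0
    s20 = math.exp(float(np.mean(z)))
    return np.full_like(s2, s20), math.inf


def moderated_log_pvalues(fw: np.ndarray, sw: np.ndarray) -> np.ndarray:
    """Moderated t-test p-values, row-wise, on log2(FPKM + 1) matrices.

    ``fw`` and ``sw`` are (transcripts x replicates) arrays.  Per-transcript
    pooled variances are squeezed toward the empirical-Bayes prior; the t
    statistic then has df = d0 + n1 + n2 - 2.
    """
    a, b = np.log2(fw + 1.0), np.log2(sw + 1.0)
    n1, n2 = a.shape[1], b.shape[1]
    df = n1 + n2 - 2
    if df <= 0:
        raise ValueError("need at least two replicates in total per transcript")
    v1 = a.var(axis=1, ddof=1) if n1 > 1 else np.zeros(a.shape[0])
    v2 = b.var(axis=1, ddof=1) if n2 > 1 else np.zeros(b.shape[0])
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    post, d0 = _squeeze_var(s2, df)
    se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
    t = (b.mean(axis=1) - a.mean(axis=1)) / se
    total_df = min(d0 + df, 1e6)
    return 2.0 * stats.t.sf(np.abs(t), total_df)


def differential_expression(
    cm: CountMatrix,
    test: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> list[DETResult]:
    """Per-transcript contrast of SW vs FW with BH-adjusted p-values.

    With ``test=None`` (default) p-values come from the moderated t-test
    computed jointly over all transcripts; otherwise ``test`` is called per
    transcript with the FW and SW FPKM vectors.
    """
    fpkms = fpkm_matrix(cm)
    fw = fpkms[cm.samples("FW")].to_numpy(dtype=float)
    sw = fpkms[cm.samples("SW")].to_numpy(dtype=float)
    mfw = fw.mean(axis=1)
    msw = sw.mean(axis=1)

    results: list[DETResult] = []
    testable: list[int] = []
    for i, tid in enumerate(fpkms.index):
        lfc = log2fc(float(mfw[i]), float(msw[i]))
        if lfc is not None:
            testable.append(i)
        results.append(
            DETResult(
                transcript_id=tid,
                gene_id=cm.gene_of.get(tid, tid),
                mean_fpkm_fw=float(mfw[i]),
                mean_fpkm_sw=float(msw[i]),
                log2fc=lfc,
                pvalue=None,
                fdr=None,
            )
        )
    if testable:
        if test is None:
            pvec = moderated_log_pvalues(fw[testable], sw[testable])
        else:
            pvec = np.array([test(fw[i], sw[i]) for i in testable])
        pvec = np.clip(pvec, 0.0, 1.0)
        for i, p in zip(testable, pvec):
            results[i].pvalue = float(p)
        for i, q in zip(testable, bh_adjust(pvec)):
            results[i].fdr = float(q)
    return call_dets(results)


def call_dets(
    results: list[DETResult],
    fdr_threshold: float = FDR_THRESHOLD,
    min_abs_log2fc: float = MIN_ABS_LOG2FC,
) -> list[DETResult]:
    """Flag DETs: FDR below threshold and |log2FC| >= threshold (inf counts)."""
    for r in results:
        r.is_det = False
        r.direction = None
        if r.log2fc is None or r.fdr is None:
            continue
        if r.fdr < fdr_threshold and abs(r.log2fc) >= min_abs_log2fc:
            r.is_det = True
            r.direction = "up" if r.log2fc > 0 else "down"
    return results


def det_counts(results: Iterable[DETResult]) -> dict[str, int]:
    counts = {"up": 0, "down": 0}
    for r in results:
        if r.is_det:
            counts[r.direction] += 1
    return counts


def group_gene_patterns(results: Iterable[DETResult]) -> list[GeneDETPattern]:
    """Pattern (similar/opposite) for genes contributing two or more DETs."""
    by_gene: dict[str, list[DETResult]] = {}
    for r in results:
        if r.is_det:
            by_gene.setdefault(r.gene_id, []).append(r)
    patterns = []
    for gene in sorted(by_gene):
        dets = by_gene[gene]
        if len(dets) < 2:
            continue
        signs = {r.direction for r in dets}
        patterns.append(
            GeneDETPattern(
                gene_id=gene,
                det_transcripts=tuple(sorted(r.transcript_id for r in dets)),
                pattern="similar" if len(signs) == 1 else "opposite",
            )
        )
    return patterns


def ddct(
    ct_target_a: float, ct_ref_a: float, ct_target_b: float, ct_ref_b: float
) -> float:
    """Relative expression by the 2^-ddCT method (a = calibrator condition)."""
    ddct_val = (ct_target_b - ct_ref_b) - (ct_target_a - ct_ref_a)
    return 2.0 ** (-ddct_val)
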