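"""Transcriptome Shannon entropy as a homeostasis metric.

A transcriptome's Shannon entropy, H = -sum p_i log2 p_i over per-gene
expression proportions within one sample, summarises how evenly
transcription is spread across genes.  A perturbation that destabilises
the transcriptome shifts H; comparing treatment and control entropies
therefore gives a single global stability read-out, complementary to
per-gene differential expression.

Proportions are invariant to any per-sample linear scaling, so raw
counts, CPM and TPM-like inputs all give the same H; only gene-length
re-weighting would change it (see the package docs).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass(frozen=True)
class EntropyResult:
    sample_id: str
    H: float            # bits by default (see `base`)
    n_expressed: int    # genes with abundance > 0


@dataclasses.dataclass(frozen=True)
class EntropyComparison:
    t_statistic: float
    pvalue: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int


def shannon_entropy(abundance, *, sample_id: str = "sample",
                    base: float = 2.0) -> EntropyResult:
    """Shannon entropy of one expression profile.

    Zero-abundance genes contribute nothing (0 * log 0 := 0); an all-zero
    profile has no defined entropy and raises.  Default base 2 (bits).
    """
    a = np.asarray(abundance, dtype=float)
    if a.ndim != 1:
        raise ValueError("abundance must be one-dimensional")
    if np.any(a < 0):
        raise ValueError("abundance must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError(f"sample {sample_id!r}: all-zero profile, entropy undefined")
    p = a[a > 0] / total
    p = p[p > 0]  # guard against underflow of tiny abundances
    h = float(-(p * (np.log(p) / np.log(base))).sum())
    if h == 0.0:
        h = 0.0  # normalise -0.0 from a point-mass profile
    return EntropyResult(sample_id=sample_id, H=h, n_expressed=int((a > 0).sum()))


def entropy_per_sample(counts: pd.DataFrame, *, base: float = 2.0
                       ) -> list[EntropyResult]:
    """Entropy of every column of a genes-x-samples matrix."""
    return [shannon_entropy(counts[c].to_numpy(), sample_id=str(c), base=base)
            for c in counts.columns]


def compare_entropy(group_a: Sequence[EntropyResult],
                    group_b: Sequence[EntropyResult]) -> EntropyComparison:
    """Two-sided Student's t-test (pooled variance) on per-sample entropies."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    a = np.array([r.H for r in group_a])
    b = np.array([r.H for r in group_b])
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):  # zero pooled variance with equal means
        t, p = 0.0, 1.0
    return EntropyComparison(
        t_statistic=float(t), pvalue=float(p),
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        n_a=len(a), n_b=len(b),
    )
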