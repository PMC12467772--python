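"""Differential-expression screening and qPCR relative expression.

The regulation screen is the study's rule: a gene is a DEG when
|log2 fold change| > 1 and Benjamini–Hochberg FDR < 0.05, with the sign of
the fold change giving the direction (up/down); everything else is ``ns``.
The internal test behind the screen is a deliberately simple Welch t-test
on log2(size-factor-normalised count + 1) — a declared simplified stand-in
for a negative-binomial GLM fit; users with DESeq2 (or similar) output
load it through :func:`read_deg_table`, and the thresholds are applied
identically either way.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_LFC_THRESHOLD = 1.0
DEFAULT_FDR_THRESHOLD = 0.05


@dataclasses.dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    log2fc: float
    pvalue: float
    fdr: float
    status: str  # "up" | "down" | "ns"


@dataclasses.dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR observation: target and endogenous-reference Ct in one condition."""

    ct_target: float
    ct_reference: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise ValueError("Ct values must be positive cycle counts")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, order-preserving.

    Monotonicity is enforced by the cumulative minimum from the largest
    rank; adjusted values are capped at 1 and equal the input when a
    single p-value is supplied.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify(log2fc: float, fdr: float,
             lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
             fdr_threshold: float = DEFAULT_FDR_THRESHOLD) -> str:
    """Apply the screen: strict inequalities, boundary genes are ``ns``."""
    if fdr < fdr_threshold and log2fc > lfc_threshold:
        return "up"
    if fdr < fdr_threshold and log2fc < -lfc_threshold:
        return "down"
    return "ns"


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample size factors: median ratio to the gene-wise geometric mean.

    Genes with a zero in any sample are excluded from the reference (their
    geometric mean is zero).  Falls back to library-size scaling if no gene
    survives the filter.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.sum() == 0:
        lib = arr.sum(axis=0)
        sf = lib / np.exp(np.mean(np.log(np.maximum(lib, 1.0))))
        return pd.Series(sf, index=counts.columns, name="size_factor")
    log_ref = np.log(arr[positive]).mean(axis=1, keepdims=True)
    sf = np.exp(np.median(np.log(arr[positive]) - log_ref, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def simple_de_screen(counts: pd.DataFrame, sample_sheet: pd.DataFrame, *,
                     treatment: str = "treatment", control: str = "control",
                     stage: str | None = None,
                     lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
                     fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
                     equal_var: bool = True) -> list[DEGRecord]:
    """Screen a count matrix for regulated genes, treatment over control.

    Normalisation is median-of-ratios; the per-gene test is a two-sided
    two-sample t on log2(normalised count + 1); p-values are BH-adjusted;
    the thresholds then assign up/down/ns.  All-zero genes get log2fc 0
    via the pseudocount, never NaN.

    The default is the pooled-variance (Student's) t: with only a few
    replicates per group the Satterthwaite df estimate behind Welch's
    test is unstable (it collapses toward 2 whenever one group's sample
    variance degenerates), which both mis-calibrates the null and caps
    the attainable p-value; ``equal_var=False`` selects Welch for designs
    with enough replicates to estimate per-group variances.
    """
    sheet = sample_sheet
    if stage is not None:
        sheet = sheet[sheet["stage"] == stage]
    t_ids = sheet.loc[sheet["group"] == treatment, "sample_id"].tolist()
    c_ids = sheet.loc[sheet["group"] == control, "sample_id"].tolist()
    if len(t_ids) < 2 or len(c_ids) < 2:
        raise ValueError(
            f"need >= 2 replicates per group, got {len(t_ids)} treatment /"
            f" {len(c_ids)} control" + (f" for stage {stage!r}" if stage else "")
        )
    missing = [s for s in t_ids + c_ids if s not in counts.columns]
    if missing:
        raise ValueError(f"sample sheet names absent from counts: {missing}")
    sub = counts[t_ids + c_ids]
    if (sub.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")

    sf = median_of_ratios_size_factors(sub)
    norm = sub.to_numpy(dtype=float) / sf.to_numpy()
    log = np.log2(norm + 1.0)
    a = log[:, : len(t_ids)]
    b = log[:, len(t_ids) :]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    tstat, pvals = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    # zero-variance genes (identical values in both groups) test as ns
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    fdr = bh_fdr(pvals)
    return [
        DEGRecord(g, float(l), float(p), float(q),
                  classify(float(l), float(q), lfc_threshold, fdr_threshold))
        for g, l, p, q in zip(counts.index, log2fc, pvals, fdr)
    ]


def read_deg_table(path: str | Path, *,
                   lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
                   fdr_threshold: float = DEFAULT_FDR_THRESHOLD) -> list[DEGRecord]:
    """Load an external DEG table (e.g. DESeq2 output exported as TSV).

    Requires columns gene_id, log2fc, pvalue, fdr; statuses are recomputed
    from the thresholds, never trusted from the file.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "log2fc", "pvalue", "fdr"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"DEG table {path} missing column(s): {', '.join(missing)}")
    records: list[DEGRecord] = []
    for i, row in df.iterrows():
        try:
            l, p, q = float(row["log2fc"]), float(row["pvalue"]), float(row["fdr"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"DEG table {path}, row {i + 2}: non-numeric cell") from exc
        if math.isnan(l) or math.isnan(p) or math.isnan(q):
            raise ValueError(f"DEG table {path}, row {i + 2}: non-numeric cell")
        records.append(
            DEGRecord(str(row["gene_id"]), l, p, q,
                      classify(l, q, lfc_threshold, fdr_threshold))
        )
    return records


def write_deg_table(path: str | Path, records: list[DEGRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2fc\tpvalue\tfdr\tstatus\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.log2fc:.6g}\t{r.pvalue:.6g}\t{r.fdr:.6g}\t{r.status}\n")


def read_counts(counts_path: str | Path, samples_path: str | Path
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a genes-x-samples count TSV and its sample sheet."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {counts_path}: {dupes}")
    sheet = pd.read_csv(samples_path, sep="\t")
    required = ["sample_id", "group", "stage", "replicate"]
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet {samples_path} missing: {', '.join(missing)}")
    return counts, sheet


def ddct(treated: QpcrMeasurement, control: QpcrMeasurement) -> float:
    """Relative expression by the 2^-ddCt method (target vs reference gene).

    Returns 2 ** -((Ct_target - Ct_ref)_treated - (Ct_target - Ct_ref)_control);
    1.0 means no change relative to the control condition.
    """
    return 2.0 ** -(treated.delta_ct - control.delta_ct)
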