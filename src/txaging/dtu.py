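"""Differential transcript usage: isoform share of a gene, regressed on age.

For every transcript, its reads in a sample are expressed as a percentage
of the sample's total reads over all transcripts of the same gene.  A
linear regression of that percentage on age tests whether the isoform's
*relative* contribution shifts over the lifespan — which can move even
when the isoform's *absolute* abundance (log2(TPM + 1) scale) is flat,
because the gene total itself changes.  Both regressions are provided so
the two scales can be contrasted per transcript.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import fit_linear
from .normalize import CountMatrix, NormalizedMatrix

__all__ = ["UsageTable", "usage_percentages", "usage_regression", "abs_regression"]


@dataclass
class UsageTable:
    """Per transcript x sample usage percentages plus the gene map.

    ``usage`` is NaN for samples where the gene's total is zero (the share
    is undefined there); elsewhere each gene's usages sum to 100 per
    sample.
    """

    usage: pd.DataFrame  # transcripts x samples, percent
    tx2gene: pd.Series
    n_transcripts: pd.Series  # per gene


def usage_percentages(iso_counts: CountMatrix, tx2gene: pd.Series) -> UsageTable:
    """Convert transcript counts to within-gene usage percentages."""
    unmapped = iso_counts.feature_ids.difference(tx2gene.index)
    if len(unmapped):
        raise ValueError(f"unmapped transcripts: {list(unmapped[:5])}")
    genes = tx2gene.reindex(iso_counts.feature_ids)
    totals = iso_counts.counts.groupby(genes).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        usage = 100.0 * iso_counts.counts / totals
    usage = usage.where(totals > 0)  # undefined share when the gene is silent
    n_tx = genes.groupby(genes).size()
    n_tx.name = "n_transcripts"
    return UsageTable(usage=usage, tx2gene=genes, n_transcripts=n_tx)


def usage_regression(
    table: UsageTable,
    ages,
    sexes=None,
    alpha: float = 0.05,
    min_samples: int = 10,
) -> pd.DataFrame:
    """OLS of usage percentage on age (plus sex unless ``sexes`` is None).

    Samples where a gene's usage is undefined are dropped for that gene's
    transcripts; transcripts with fewer than ``min_samples`` usable
    samples are skipped with a reason.  Returns a per-transcript frame
    with slope (percentage points per year), Wald p, and a significance
    flag at ``alpha``.
    """
    ages = np.asarray(ages, dtype=float)
    sex_arr = np.asarray(sexes, dtype=float) if sexes is not None else np.zeros_like(ages)
    rows = []
    for tid in table.usage.index:
        y = table.usage.loc[tid].to_numpy()
        ok = np.isfinite(y)
        row = {"transcript_id": tid, "gene_id": table.tx2gene.loc[tid]}
        if ok.sum() < min_samples:
            row.update(
                usage_beta_age=np.nan, usage_se=np.nan, usage_p=np.nan,
                significant=False, skipped_reason=f"fewer than {min_samples} usable samples",
            )
            rows.append(row)
            continue
        sex_ok = sex_arr[ok] if sexes is not None else None
        fit = fit_linear(y[ok], ages[ok], sex_ok, feature_id=tid, drop_nonfinite=False)
        row.update(
            usage_beta_age=fit.beta_age,
            usage_se=fit.se_age,
            usage_p=fit.p_wald,
            significant=bool(fit.converged and fit.p_wald < alpha),
            skipped_reason="",
        )
        rows.append(row)
    return pd.DataFrame.from_records(rows, index="transcript_id")


def abs_regression(tpm: NormalizedMatrix, ages, sexes=None) -> pd.DataFrame:
    """OLS of absolute abundance (log2(TPM+1)) on age (plus sex).

    The companion to :func:`usage_regression`: a transcript whose usage
    share falls while its gene total rises can show a flat absolute trend.
    """
    if tpm.unit not in {"log2TPM1", "TPM"}:
        raise ValueError("abs_regression expects a TPM-scale matrix")
    vals = tpm.values
    if tpm.unit == "TPM":
        if (vals.values < 0).any():
            raise ValueError("negative TPM values")
        vals = np.log2(vals + 1.0)
    elif (vals.values < 0).any():
        raise ValueError("negative log2(TPM+1) values")
    ages = np.asarray(ages, dtype=float)
    sex_arr = np.asarray(sexes, dtype=float) if sexes is not None else None
    rows = []
    for tid in vals.index:
        y = vals.loc[tid].to_numpy()
        fit = fit_linear(y, ages, sex_arr, feature_id=tid)
        rows.append(
            {
                "transcript_id": tid,
                "abs_beta_age": fit.beta_age,
                "abs_se": fit.se_age,
                "abs_p": fit.p_wald,
            }
        )
    return pd.DataFrame.from_records(rows, index="transcript_id")
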