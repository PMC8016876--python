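"""Group-wise differential exon usage between young and old sample groups.

For each exon the per-sample response is the pair (reads on this exon,
reads on the rest of the gene).  A negative-binomial GLM with log link is
fit on the stacked pairs with terms ``group + bin + group:bin`` and an
offset of log(per-sample gene total), so the coefficients model the
exon's *share* of its gene; the interaction term asks whether that share
differs between groups, tested by a likelihood-ratio chi-square with one
degree of freedom.  This is the core exon-vs-rest contrast of the
DEXSeq-style design, with a shared ML dispersion per exon instead of the
full per-sample fixed-effects model.  P-values are Benjamini-Hochberg
adjusted across all exons tested in one run (FDR threshold default 0.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ExonUsageResult", "bh_adjust", "exon_usage_test", "intersect_with_dtu"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ExonUsageResult:
    """Per-exon interaction test results with FDR control."""

    table: pd.DataFrame  # exon_id-indexed: gene_id, usage means, lr_stat, p, fdr, significant
    skipped: pd.DataFrame  # exon_id, reason
    fdr_threshold: float


def _estimate_alpha(y, X, offset) -> float:
    """Moment-based dispersion (NB2 alpha) under the full-model design.

    alpha solves var = mu + alpha*mu^2 with mu from a Poisson fit of the
    full model.  The same alpha is then held fixed in both the full and
    reduced GLM fits — letting each model refit its own dispersion would
    allow the reduced model to absorb the interaction into
    overdispersion and deflate the LRT.  Under- or equi-dispersed data
    fall back to near-Poisson (alpha -> 0).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
            mu = pois.fittedvalues
            alpha = float(np.sum((y - mu) ** 2 - mu) / np.sum(mu**2))
        except Exception:
            alpha = 0.0
    if not np.isfinite(alpha):
        alpha = 0.0
    return float(np.clip(alpha, 1e-8, 1e4))


def _fit_nb_llf(y, X, offset, alpha: float) -> tuple[float, bool]:
    """Log-likelihood of an NB GLM at fixed dispersion."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            glm = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
            ).fit()
            return float(glm.llf), True
        except Exception:
            return np.nan, False


def exon_usage_test(
    exon_counts: pd.DataFrame,
    exon2gene: pd.Series,
    groups: pd.Series,
    fdr_threshold: float = 0.1,
    exon_coords: pd.DataFrame | None = None,
) -> ExonUsageResult:
    """Test every exon for a group difference in its within-gene usage.

    Parameters
    ----------
    exon_counts
        Exon x sample integer count table.
    exon2gene
        Map exon_id -> gene_id; only genes with >= 2 exons are testable.
    groups
        Per-sample labels; exactly two distinct values (e.g. ``young`` /
        ``old``), each with >= 2 samples.
    exon_coords
        Optional frame (exon_id-indexed: chrom, start, end, strand) in
        0-based half-open convention, passed through to the output.
    """
    groups = pd.Series(groups).reindex(exon_counts.columns)
    levels = sorted(groups.dropna().unique().tolist())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    gvec = (groups == levels[1]).astype(float).to_numpy()
    for lev in levels:
        if (groups == lev).sum() < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 samples")

    genes = exon2gene.reindex(exon_counts.index)
    if genes.isna().any():
        missing = exon_counts.index[genes.isna()]
        raise ValueError(f"unmapped exons: {list(missing[:5])}")
    gene_totals = exon_counts.groupby(genes).transform("sum")

    rows, skipped = [], []
    n_exons_per_gene = genes.groupby(genes).size()
    for exon_id in exon_counts.index:
        gene = genes.loc[exon_id]
        if n_exons_per_gene.loc[gene] < 2:
            skipped.append((exon_id, "single-exon gene"))
            continue
        this = exon_counts.loc[exon_id].to_numpy(dtype=float)
        total = gene_totals.loc[exon_id].to_numpy(dtype=float)
        rest = total - this
        usable = total > 0
        # a group with no expressed samples gives the contrast nothing to
        # compare against
        if any((usable & (gvec == g)).sum() < 2 for g in (0.0, 1.0)):
            skipped.append((exon_id, "zero gene totals in one group"))
            continue
        t, r, gv, tot = this[usable], rest[usable], gvec[usable], total[usable]
        n = len(t)
        y = np.concatenate([t, r])
        bin_ind = np.concatenate([np.ones(n), np.zeros(n)])  # 1 = this exon
        grp = np.concatenate([gv, gv])
        offset = np.log(np.concatenate([tot, tot]))
        X_full = np.column_stack([np.ones(2 * n), grp, bin_ind, grp * bin_ind])
        X_red = X_full[:, :3]
        alpha = _estimate_alpha(y, X_full, offset)
        llf_full, ok_f = _fit_nb_llf(y, X_full, offset, alpha)
        llf_red, ok_r = _fit_nb_llf(y, X_red, offset, alpha)
        if not (ok_f and ok_r) or not np.isfinite(llf_full - llf_red):
            skipped.append((exon_id, "model fit failed"))
            continue
        lr = max(2.0 * (llf_full - llf_red), 0.0)
        p = float(stats.chi2.sf(lr, df=1))
        mean_usage = {}
        for g, lev in zip((0.0, 1.0), levels):
            sel = gv == g
            mean_usage[f"mean_usage_{lev}"] = float(np.mean(t[sel] / tot[sel]))
        row = {"exon_id": exon_id, "gene_id": gene, "lr_stat": lr, "p": p}
        row.update(mean_usage)
        if exon_coords is not None and exon_id in exon_coords.index:
            row.update(exon_coords.loc[exon_id].to_dict())
        rows.append(row)

    table = pd.DataFrame.from_records(rows).set_index("exon_id") if rows else pd.DataFrame(
        columns=["gene_id", "lr_stat", "p", "fdr", "significant"]
    )
    if len(table):
        table["fdr"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["fdr"] < fdr_threshold
    skipped_df = pd.DataFrame(skipped, columns=["exon_id", "reason"])
    return ExonUsageResult(table=table, skipped=skipped_df, fdr_threshold=fdr_threshold)


def intersect_with_dtu(
    exon_result: ExonUsageResult | pd.DataFrame,
    dtu_result: pd.DataFrame,
    fdr_threshold: float | None = None,
    dtu_alpha: float = 0.01,
) -> pd.DataFrame:
    """Genes significant in both the exon test and the DTU age regression.

    ``dtu_result`` is the per-transcript frame from
    :func:`txaging.dtu.usage_regression` (needs ``gene_id`` and
    ``usage_p``).  Thresholds are parameters because the two analyses use
    different scales of evidence (FDR for exons, raw p for DTU).
    """
    table = exon_result.table if isinstance(exon_result, ExonUsageResult) else exon_result
    if fdr_threshold is None:
        fdr_threshold = (
            exon_result.fdr_threshold
            if isinstance(exon_result, ExonUsageResult)
            else 0.1
        )
    if not len(table):
        return pd.DataFrame(columns=["gene_id"])
    exon_genes = set(table.loc[table["fdr"] < fdr_threshold, "gene_id"])
    dtu_sig = dtu_result[dtu_result["usage_p"] < dtu_alpha]
    dtu_genes = set(dtu_sig["gene_id"])
    shared = sorted(exon_genes & dtu_genes)
    rows = []
    for gene in shared:
        ex = table[(table["gene_id"] == gene) & (table["fdr"] < fdr_threshold)]
        dt = dtu_sig[dtu_sig["gene_id"] == gene]
        rows.append(
            {
                "gene_id": gene,
                "best_exon_fdr": float(ex["fdr"].min()),
                "best_dtu_p": float(dt["usage_p"].min()),
                "n_exons": len(ex),
                "n_transcripts": len(dt),
            }
        )
    return pd.DataFrame.from_records(rows)
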