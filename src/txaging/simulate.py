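"""Synthetic bulk RNA-seq data with known ground truth.

Emulates the statistical structure the age-association pipeline assumes:
a cohort of healthy adults sampled over a wide age range (defaults: 53
samples, ages 22-83), gene-level counts that follow a negative-binomial
distribution whose mean varies log-linearly with age and sex, a subset of
genes carrying structural (true) zeros, isoform tables whose within-gene
usage proportions drift linearly with age, and protein abundances with a
tunable mRNA-protein correlation.

Every generated feature has a matching record in :class:`SyntheticTruth`,
so downstream estimates can be scored against the generating parameters.

The negative binomial is parameterized by (mean mu, size k) with
``variance = mu + mu**2 / k``; larger ``k`` means less overdispersion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .normalize import CountMatrix, to_cpm

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_counts",
    "simulate_isoforms",
    "simulate_proteins",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort and count model.

    Attributes
    ----------
    n_samples, age_range
        Cohort size and (min, max) age in years; ages are drawn uniformly
        unless ``fixed_ages`` is given.
    n_genes, frac_age_assoc, beta_age_effect, frac_positive
        Number of genes; fraction carrying a true age effect; per-year
        log-scale effect magnitude; fraction of affected genes with a
        positive effect (age-associated transcriptomes skew positive).
    dispersion_range, baseline_mean_range
        Uniform ranges for the NB size parameter and the baseline expected
        count per gene.
    frac_structural_zero_genes
        Fraction of genes whose counts are forced to zero in a random,
        per-gene sample subset (structural zeros — true absence, not
        sampling dropout).
    library_size
        If set, per-sample NB means are rescaled so expected totals equal
        this read depth; if ``None`` the realized column sums serve as
        library sizes.
    n_transcripts_per_gene, frac_dtu_genes, usage_drift_magnitude
        Isoform layer: transcripts per gene (inclusive integer range),
        fraction of multi-isoform genes with a usage trend, and the trend
        slope in percentage points per year.
    frac_protein_coupled, protein_corr_target
        Protein layer: fraction of genes whose protein tracks its mRNA,
        and the expected Pearson correlation for those genes.
    beta_sex_effect
        Log-scale sex effect applied to age-associated genes (default 0).
    """

    n_samples: int = 53
    age_range: tuple[float, float] = (22.0, 83.0)
    n_genes: int = 2000
    frac_age_assoc: float = 0.02
    beta_age_effect: float = 0.02
    frac_positive: float = 0.9
    dispersion_range: tuple[float, float] = (2.0, 50.0)
    baseline_mean_range: tuple[float, float] = (20.0, 500.0)
    frac_structural_zero_genes: float = 0.05
    library_size: float | None = None
    n_transcripts_per_gene: tuple[int, int] = (1, 4)
    frac_dtu_genes: float = 0.1
    usage_drift_magnitude: float = 0.3
    frac_protein_coupled: float = 0.5
    protein_corr_target: float = 0.6
    beta_sex_effect: float = 0.0
    fixed_ages: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_age_assoc",
            "frac_positive",
            "frac_structural_zero_genes",
            "frac_dtu_genes",
            "frac_protein_coupled",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if not -1.0 <= self.protein_corr_target <= 1.0:
            raise ValueError("protein_corr_target must be in [-1, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must satisfy min < max")
        if self.library_size is not None and self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.n_transcripts_per_gene[0] < 1:
            raise ValueError("need at least one transcript per gene")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SyntheticTruth:
    """Generating parameters per feature, for recovery scoring.

    ``genes`` columns: true_beta_age, true_beta_sex, true_dispersion,
    baseline_mean, is_structural_zero.  ``zero_samples`` maps each
    structural-zero gene to its masked sample set.  ``transcripts`` (filled
    by :func:`simulate_isoforms`) columns: gene_id, base_usage,
    true_usage_slope (percentage points per year).  ``proteins`` (filled by
    :func:`simulate_proteins`) columns: coupled, target_corr.
    """

    genes: pd.DataFrame
    zero_samples: dict[str, list[str]] = field(default_factory=dict)
    transcripts: pd.DataFrame | None = None
    proteins: pd.DataFrame | None = None


def simulate_counts(
    config: SimConfig,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw a gene-level count matrix plus sample table and ground truth.

    Counts follow ``NB(mean = m_g * exp(b_g * (age - mid) + c_g * sex),
    size = k_g)``; centering age at the range midpoint keeps the baseline
    mean interpretable as the expected count of a mid-aged sample.  Ages
    are uniform over ``age_range``; sex is assigned 0/1 (0 = reference)
    in near-equal numbers, independent of age.
    """
    rng = config.rng()
    n, g = config.n_samples, config.n_genes

    if config.fixed_ages is not None:
        ages = np.asarray(config.fixed_ages, dtype=float)
        if len(ages) != n:
            raise ValueError("fixed_ages length must equal n_samples")
    else:
        ages = rng.uniform(*config.age_range, size=n)
    sexes = rng.permutation(np.arange(n) % 2)
    sample_ids = [f"S{i:03d}" for i in range(n)]
    gene_ids = [f"G{i:05d}" for i in range(g)]

    baseline = rng.uniform(*config.baseline_mean_range, size=g)
    size = rng.uniform(*config.dispersion_range, size=g)

    n_assoc = int(round(config.frac_age_assoc * g))
    assoc = rng.choice(g, size=n_assoc, replace=False)
    beta_age = np.zeros(g)
    signs = np.where(rng.random(n_assoc) < config.frac_positive, 1.0, -1.0)
    beta_age[assoc] = signs * config.beta_age_effect
    beta_sex = np.zeros(g)
    beta_sex[assoc] = config.beta_sex_effect

    mid = 0.5 * (config.age_range[0] + config.age_range[1])
    eta = (
        np.log(baseline)[:, None]
        + beta_age[:, None] * (ages - mid)[None, :]
        + beta_sex[:, None] * sexes[None, :]
    )
    if not np.all(np.isfinite(eta)):
        bad = gene_ids[int(np.argwhere(~np.isfinite(eta))[0, 0])]
        raise FloatingPointError(f"non-finite NB mean for gene {bad}")
    mu = np.exp(eta)
    if config.library_size is not None:
        mu = mu * (config.library_size / mu.sum(axis=0))[None, :]
    if not np.all(np.isfinite(mu)):
        bad = gene_ids[int(np.argwhere(~np.isfinite(mu))[0, 0])]
        raise FloatingPointError(f"non-finite NB mean for gene {bad}")

    p = size[:, None] / (size[:, None] + mu)
    counts = rng.negative_binomial(size[:, None], p)

    n_zero_genes = int(round(config.frac_structural_zero_genes * g))
    zero_genes = rng.choice(g, size=n_zero_genes, replace=False)
    zero_samples: dict[str, list[str]] = {}
    is_zero = np.zeros(g, dtype=bool)
    for gi in zero_genes:
        frac = rng.uniform(0.3, 0.9)
        k = max(1, int(round(frac * n)))
        mask = rng.choice(n, size=k, replace=False)
        counts[gi, mask] = 0
        is_zero[gi] = True
        zero_samples[gene_ids[gi]] = [sample_ids[j] for j in sorted(mask)]

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        biotype=pd.Series("protein_coding", index=gene_ids, name="biotype"),
    )
    samples = pd.DataFrame(
        {"age": ages, "sex": sexes}, index=pd.Index(sample_ids, name="sample_id")
    )
    truth = SyntheticTruth(
        genes=pd.DataFrame(
            {
                "true_beta_age": beta_age,
                "true_beta_sex": beta_sex,
                "true_dispersion": size,
                "baseline_mean": baseline,
                "is_structural_zero": is_zero,
            },
            index=gene_ids,
        ),
        zero_samples=zero_samples,
    )
    return cm, samples, truth


def simulate_isoforms(
    cm: CountMatrix,
    config: SimConfig,
    truth: SyntheticTruth,
    samples: pd.DataFrame | None = None,
) -> tuple[CountMatrix, pd.Series]:
    """Split gene counts into transcript counts with age-drifting usage.

    Each gene's count in each sample is divided multinomially across its
    transcripts.  For drift genes the proportion vector moves linearly
    with age at ``true_usage_slope`` percentage points per year (the gain
    assigned to the first transcript is balanced by equal losses across
    the rest), clamped to the simplex; clamping is reported with a warning
    because it bends the nominal linear trend.  Transcript counts sum to
    the gene count in every sample, exactly.
    """
    rng = np.random.default_rng(config.seed + 1)
    ages = (
        samples["age"].to_numpy()
        if samples is not None
        else np.full(cm.counts.shape[1], np.nan)
    )
    if samples is None:
        raise ValueError("sample table with ages is required for usage drift")
    mid = 0.5 * (config.age_range[0] + config.age_range[1])

    lo, hi = config.n_transcripts_per_gene
    records = []
    tx_rows = []
    tx_ids: list[str] = []
    tx_gene: list[str] = []
    clamped = 0
    counts = cm.counts.to_numpy()
    for gi, gene in enumerate(cm.feature_ids):
        t = int(rng.integers(lo, hi + 1))
        base = rng.dirichlet(np.full(t, 5.0)) if t > 1 else np.ones(1)
        slope = np.zeros(t)
        if t > 1 and rng.random() < config.frac_dtu_genes:
            s = config.usage_drift_magnitude / 100.0  # fraction per year
            slope[0] = s
            slope[1:] = -s / (t - 1)
        props = base[:, None] + slope[:, None] * (ages - mid)[None, :]
        if (props < 0).any() or (props > 1).any():
            clamped += 1
        props = np.clip(props, 0.0, None)
        props = props / props.sum(axis=0, keepdims=True)
        gc = counts[gi]
        split = np.empty((t, len(gc)), dtype=np.int64)
        for s_i, c in enumerate(gc):
            split[:, s_i] = rng.multinomial(int(c), props[:, s_i])
        for ti in range(t):
            tid = f"{gene}.T{ti}"
            tx_ids.append(tid)
            tx_gene.append(gene)
            tx_rows.append(split[ti])
            records.append(
                {
                    "transcript_id": tid,
                    "gene_id": gene,
                    "base_usage": base[ti] * 100.0,
                    "true_usage_slope": slope[ti] * 100.0,
                }
            )
    if clamped:
        warnings.warn(
            f"usage drift pushed proportions outside [0,1] for {clamped} genes; "
            "clamped to the simplex",
            stacklevel=2,
        )
    iso = CountMatrix(
        counts=pd.DataFrame(
            np.vstack(tx_rows), index=tx_ids, columns=cm.sample_ids
        ),
        library_size=cm.library_size,
    )
    tx2gene = pd.Series(tx_gene, index=pd.Index(tx_ids, name="transcript_id"), name="gene_id")
    truth.transcripts = pd.DataFrame.from_records(records, index="transcript_id")
    return iso, tx2gene


def simulate_proteins(
    cm: CountMatrix, config: SimConfig, truth: SyntheticTruth | None = None
) -> pd.DataFrame:
    """Protein abundances with a tunable mRNA correlation.

    For the coupled subset, protein = log2CPM + Gaussian noise with the
    noise SD chosen so the expected Pearson correlation equals
    ``protein_corr_target`` (sd_noise = sd_mrna * sqrt(1/r^2 - 1)); the
    remaining genes get independent noise.  Zero counts contribute their
    log2(CPM + 1) value so every gene yields a finite protein level.
    """
    r = config.protein_corr_target
    if not -1.0 <= r <= 1.0:
        raise ValueError("protein_corr_target must be in [-1, 1]")
    rng = np.random.default_rng(config.seed + 2)
    x = to_cpm(cm, log2=True, pseudo=1.0).values.to_numpy()
    g, n = x.shape
    coupled = rng.random(g) < config.frac_protein_coupled
    sd = x.std(axis=1, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    prot = np.empty_like(x)
    sign = np.sign(r) if r != 0 else 0.0
    if r != 0:
        noise_sd = sd * np.sqrt(max(1.0 / r**2 - 1.0, 0.0))
        prot[coupled] = sign * x[coupled] + rng.normal(
            0.0, noise_sd[coupled, None], size=(coupled.sum(), n)
        )
    else:
        prot[coupled] = rng.normal(0.0, sd[coupled, None], size=(coupled.sum(), n))
    prot[~coupled] = rng.normal(0.0, sd[~coupled, None], size=((~coupled).sum(), n))
    out = pd.DataFrame(prot, index=cm.feature_ids, columns=cm.sample_ids)
    if truth is not None:
        truth.proteins = pd.DataFrame(
            {"coupled": coupled, "target_corr": np.where(coupled, r, 0.0)},
            index=cm.feature_ids,
        )
    return out


def write_truth_tsv(truth: SyntheticTruth, path) -> None:
    """Write the per-gene truth table (zero-sample sets joined by commas)."""
    df = truth.genes.copy()
    df["zero_samples"] = [
        ",".join(truth.zero_samples.get(g, [])) for g in df.index
    ]
    df.to_csv(path, sep="\t", index_label="gene_id")


def write_config(config: SimConfig, path) -> None:
    """Write the config as a flat ``key: value`` text file."""
    with open(path, "w") as fh:
        for k, v in asdict(config).items():
            if k == "fixed_ages" and v is not None:
                v = ",".join(str(a) for a in v)
            fh.write(f"{k}: {v}\n")
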