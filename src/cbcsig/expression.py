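"""Count-level quantification and a negative-binomial differential-expression engine.

TPM quantification follows the standard definition (per-gene count rate
``count/length`` scaled so each sample sums to one million), and expression
is log-transformed as ``log2(TPM + 1)``.

The DE engine is a deliberately simple, documented negative-binomial Wald
test, designed as a replaceable stand-in: downstream signature logic accepts
a DEG table from any engine. Per gene, group means of library-size-normalized
counts are compared on the log scale; the variance of each log group mean is
estimated by the delta method from the NB mean-variance relation
``Var = mu + phi*mu^2``, where the per-gene method-of-moments dispersion is
winsorized at three times the common (across-gene mean) dispersion and then
shrunk 50% toward it. The Wald statistic is referred to a t distribution
whose effective degrees of freedom account for the variance moderation (the
raw within-group df, inflated by the shrinkage and winsorization of the
dispersion estimator; 24 at n=3 per group). P-values are Benjamini-Hochberg
adjusted; genes with ``adjusted_p < 0.05`` are called significant by default.

Library sizes are normalized by median-of-ratios size factors, falling back
to total-count scaling when the geometric means are degenerate (no gene
expressed in every sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CONTRASTS = {
    "C_vs_SL": ("control", "stress_low"),
    "C_vs_SH": ("control", "stress_high"),
    "SL_vs_SH": ("stress_low", "stress_high"),
}


class ExpressionError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Gene x sample integer counts with gene lengths and sample group labels."""

    gene_ids: list[str]
    gene_names: list[str]
    gene_lengths: np.ndarray
    sample_ids: list[str]
    sample_groups: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_lengths = np.asarray(self.gene_lengths, dtype=float)
        self.counts = np.asarray(self.counts)
        g, s = self.counts.shape
        if not (len(self.gene_ids) == len(self.gene_names) == self.gene_lengths.size == g):
            raise ExpressionError("gene annotation lengths do not match count rows")
        if not (len(self.sample_ids) == len(self.sample_groups) == s):
            raise ExpressionError("sample annotation lengths do not match count columns")
        if np.any(self.gene_lengths <= 0):
            raise ExpressionError("gene lengths must be > 0")
        if np.any(self.counts < 0):
            raise ExpressionError("counts must be non-negative")

    def subset_samples(self, keep) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return CountMatrix(
            self.gene_ids,
            self.gene_names,
            self.gene_lengths,
            [self.sample_ids[i] for i in idx],
            [self.sample_groups[i] for i in idx],
            self.counts[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.sample_ids)
        df.insert(0, "length", self.gene_lengths.astype(int))
        df.insert(0, "gene_name", self.gene_names)
        df.insert(0, "gene_id", self.gene_ids)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def sample_sheet(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.sample_ids, "group": self.sample_groups})

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t")
        for col in ("gene_id", "gene_name", "length"):
            if col not in df.columns:
                raise ExpressionError(f"{counts_path}: missing column {col!r}")
        sheet = pd.read_csv(samples_path, sep="\t")
        if not {"sample", "group"}.issubset(sheet.columns):
            raise ExpressionError(f"{samples_path}: expected columns sample, group")
        sample_ids = [s for s in sheet["sample"] if s in df.columns]
        groups = dict(zip(sheet["sample"], sheet["group"]))
        return cls(
            gene_ids=df["gene_id"].tolist(),
            gene_names=df["gene_name"].tolist(),
            gene_lengths=df["length"].to_numpy(float),
            sample_ids=sample_ids,
            sample_groups=[groups[s] for s in sample_ids],
            counts=df[sample_ids].to_numpy(),
        )


@dataclass
class TPMMatrix:
    """Transcripts-per-million values on the same axes as the source counts."""

    gene_ids: list[str]
    gene_names: list[str]
    sample_ids: list[str]
    sample_groups: list[str]
    values: np.ndarray


def counts_to_tpm(cm: CountMatrix) -> TPMMatrix:
    """TPM: length-normalized count rates scaled to one million per sample."""
    col_sums = cm.counts.sum(axis=0)
    if np.any(col_sums == 0):
        bad = [s for s, tot in zip(cm.sample_ids, col_sums) if tot == 0]
        raise ExpressionError(f"all-zero count column(s): {bad}")
    rates = cm.counts / cm.gene_lengths[:, None]
    tpm = 1e6 * rates / rates.sum(axis=0, keepdims=True)
    return TPMMatrix(cm.gene_ids, cm.gene_names, cm.sample_ids, cm.sample_groups, tpm)


def log_transform(values) -> np.ndarray:
    """Elementwise log2(x + 1); raises on negative input."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ExpressionError("log_transform requires non-negative values")
    return np.log2(arr + 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ExpressionError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors with a total-count fallback.

    The reference is the per-gene geometric mean over samples; genes with a
    zero count in any sample drop out of the median. If no gene survives,
    scaling falls back to relative total counts.
    """
    counts = np.asarray(counts, dtype=float)
    positive = np.all(counts > 0, axis=1)
    if positive.any():
        logc = np.log(counts[positive])
        ref = logc.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logc - ref, axis=0))
    else:
        totals = counts.sum(axis=0)
        if np.all(totals == 0):
            raise ExpressionError("cannot normalize an all-zero matrix")
        sf = totals / np.exp(np.log(totals[totals > 0]).mean())
    return sf / np.exp(np.log(sf).mean())


def common_dispersion(counts: np.ndarray, group_sizes: tuple[int, int]) -> float:
    """Across-gene mean of the unclipped MoM dispersion for a two-group layout.

    ``counts`` must be normalized counts with the first group's columns
    first. This is the shrinkage target the DE engine uses, exposed so that
    downstream per-gene re-tests (e.g. the outlier filter) can run under the
    same dispersion context.
    """
    na, nb = group_sizes
    q = np.asarray(counts, dtype=float)
    qa, qb = q[:, :na], q[:, na : na + nb]
    m_a, m_b = qa.mean(axis=1), qb.mean(axis=1)
    ss = ((qa - m_a[:, None]) ** 2).sum(axis=1) + ((qb - m_b[:, None]) ** 2).sum(axis=1)
    var = ss / (na + nb - 2)
    m_pool = (na * m_a + nb * m_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = np.where(m_pool > 0, (var - m_pool) / np.square(m_pool), 0.0)
    expressed = m_pool > 0
    return max(float(phi_raw[expressed].mean()), 0.0) if expressed.any() else 0.0


def de_test(
    cm: CountMatrix,
    contrast: str,
    alpha: float = 0.05,
    shrinkage: float = 0.5,
    dispersion_cap: float = 3.0,
    wald_df: float | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """NB Wald test between the two groups of a contrast; BH-adjusted p-values.

    ``contrast`` is one of ``C_vs_SL``, ``C_vs_SH``, ``SL_vs_SH`` (or any
    ``"<groupA>_vs_<groupB>"`` naming two sample groups). Fold changes are
    reported as log2(B/A), i.e. direction "up" means up in the second group.
    Each group needs at least two samples. Returns one row per gene with
    columns gene_symbol, gene_name, contrast, log2_fold_change, p_value,
    adjusted_p, direction, significant.
    """
    if contrast in CONTRASTS:
        group_a, group_b = CONTRASTS[contrast]
    else:
        parts = contrast.split("_vs_")
        if len(parts) != 2:
            raise ExpressionError(f"cannot parse contrast {contrast!r}")
        group_a, group_b = parts
    ia = [i for i, g in enumerate(cm.sample_groups) if g == group_a]
    ib = [i for i, g in enumerate(cm.sample_groups) if g == group_b]
    if len(ia) < 2 or len(ib) < 2:
        raise ExpressionError(
            f"contrast {contrast}: need >= 2 samples per group "
            f"(have {len(ia)} {group_a}, {len(ib)} {group_b})"
        )
    counts = cm.counts[:, ia + ib].astype(float)
    sf = size_factors(counts)
    q = counts / sf
    qa, qb = q[:, : len(ia)], q[:, len(ia):]
    na, nb = qa.shape[1], qb.shape[1]
    m_a, m_b = qa.mean(axis=1), qb.mean(axis=1)

    # pooled within-group variance -> method-of-moments dispersion
    ss = ((qa - m_a[:, None]) ** 2).sum(axis=1) + ((qb - m_b[:, None]) ** 2).sum(axis=1)
    var = ss / (na + nb - 2)
    m_pool = (na * m_a + nb * m_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = np.where(m_pool > 0, (var - m_pool) / np.square(m_pool), 0.0)
    expressed = m_pool > 0
    # unclipped mean is the less biased estimate of the common dispersion
    common = max(float(phi_raw[expressed].mean()), 0.0) if expressed.any() else 0.0
    phi = np.clip(phi_raw, 0.0, None)
    if dispersion_cap is not None and common > 0:
        phi = np.minimum(phi, dispersion_cap * common)
    phi_shrunk = (1.0 - shrinkage) * phi + shrinkage * common

    a_, b_ = m_a + pseudocount, m_b + pseudocount
    log_ratio = np.log(b_) - np.log(a_)
    se = np.sqrt((1.0 / a_ + phi_shrunk) / na + (1.0 / b_ + phi_shrunk) / nb)
    z = log_ratio / se
    if wald_df is None:
        # moderated-variance effective df: raw within-group df inflated for
        # the reduced variance of the shrunk+winsorized dispersion estimate
        # (1/(1-shrinkage)^2 from shrinkage, x1.5 from winsorization),
        # calibrated by simulation against nominal type-I error
        wald_df = 1.5 * (na + nb - 2) / max((1.0 - shrinkage) ** 2, 1e-6)
    p = 2.0 * stats.t.sf(np.abs(z), wald_df)
    p[~expressed] = 1.0
    adj = bh_adjust(p)
    lfc = log_ratio / np.log(2.0)
    return pd.DataFrame(
        {
            "gene_symbol": cm.gene_ids,
            "gene_name": cm.gene_names,
            "contrast": contrast,
            "base_mean": m_pool,
            "log2_fold_change": lfc,
            "p_value": p,
            "adjusted_p": adj,
            "direction": np.where(lfc >= 0, "up", "down"),
            "significant": adj < alpha,
        }
    )


def pca_outlier_flag(log_tpm: np.ndarray, k: float = 3.0, n_components: int = 2) -> list[int]:
    """Flag samples isolated in the first principal components.

    ``log_tpm`` is gene x sample. Samples are projected onto the first two
    PCs; a sample is flagged when its nearest-neighbor distance there exceeds
    ``k`` times the median nearest-neighbor distance. Returns flagged sample
    column indices.
    """
    x = np.asarray(log_tpm, dtype=float).T  # samples x genes
    n = x.shape[0]
    if n < 3:
        raise ExpressionError("pca_outlier_flag requires >= 3 samples")
    if n <= n_components:
        raise ExpressionError("need more samples than principal components")
    centered = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[:n_components].T
    d = np.sqrt(((proj[:, None, :] - proj[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    med = float(np.median(nn))
    return [i for i in range(n) if nn[i] > k * med]
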