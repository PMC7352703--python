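"""Expression filtering, sample diagnostics, NB differential expression,
multi-method consensus, over-representation testing and qPCR validation.

The differential test is a per-feature negative-binomial Wald test on
median-of-ratios-normalised counts with a method-of-moments dispersion
estimate.  It is a single native test; the consensus machinery additionally
accepts result tables produced by external DE tools so a multi-method
"confirmed by all methods" call can be expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "DeResult",
    "QcSummary",
    "filter_expressed",
    "size_factors_median_of_ratios",
    "normalized_counts",
    "poisson_distance",
    "pca_samples",
    "nb_de_test",
    "bh_adjust",
    "consensus_de",
    "hypergeometric_enrichment",
    "qc_totals",
    "delta_delta_ct",
]


@dataclass
class CountMatrix:
    """Feature-by-sample integer count matrix with per-sample group labels."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_features, n_samples)
    group_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n_feat, n_samp = self.counts.shape
        if n_feat != len(self.feature_ids) or n_samp != len(self.sample_ids):
            raise ValueError("count matrix dimensions inconsistent with ids")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.group_labels and len(self.group_labels) != n_samp:
            raise ValueError("one group label per sample required")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def groups(self) -> dict[str, np.ndarray]:
        """Map group label -> boolean sample mask (insertion order)."""
        out: dict[str, np.ndarray] = {}
        labels = np.asarray(self.group_labels)
        for g in dict.fromkeys(self.group_labels):
            out[g] = labels == g
        return out

    @classmethod
    def from_tsv(cls, counts_path, design_path=None) -> "CountMatrix":
        """Load a counts TSV (feature_id + one column per sample) and an
        optional design TSV (sample_id, group)."""
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        groups: list[str] = []
        if design_path is not None:
            design = pd.read_csv(design_path, sep="\t")
            design = design.set_index("sample_id").loc[list(df.columns)]
            groups = list(design["group"])
        return cls(
            feature_ids=list(df.index),
            sample_ids=list(df.columns),
            counts=df.to_numpy(),
            group_labels=groups,
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.counts, index=self.feature_ids, columns=self.sample_ids
        ).rename_axis("feature_id").to_csv(path, sep="\t")


@dataclass
class DeResult:
    feature_id: str
    base_mean: float
    log2_fc: float
    p_value: float
    p_adjusted: float = float("nan")
    biotype: str = ""


@dataclass
class QcSummary:
    """Per-library read-accounting summary (read counts, not pairs)."""

    sample_ids: list[str]
    raw_reads: list[int]
    trimmed_reads: list[int]
    mapped_reads: list[int]
    uniquely_mapped: list[int]
    multi_mapped: list[int]
    too_many_loci: list[int]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        rows = (self.raw_reads, self.trimmed_reads, self.mapped_reads,
                self.uniquely_mapped, self.multi_mapped, self.too_many_loci)
        if any(len(r) != n for r in rows):
            raise ValueError("per-sample QC rows must align with sample_ids")
        for i in range(n):
            if not (self.uniquely_mapped[i] + self.multi_mapped[i]
                    + self.too_many_loci[i] <= self.mapped_reads[i]
                    <= self.trimmed_reads[i] <= self.raw_reads[i]):
                raise ValueError(
                    f"QC hierarchy violated for sample {self.sample_ids[i]}"
                )

    @classmethod
    def from_tsv(cls, path) -> "QcSummary":
        """Read a QC TSV: first column = statistic name, one column per sample."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        key = {
            "raw_reads": "raw_reads", "trimmed_reads": "trimmed_reads",
            "mapped_reads": "mapped_reads", "uniquely_mapped": "uniquely_mapped",
            "multi_mapped": "multi_mapped", "too_many_loci": "too_many_loci",
        }
        rows = {key[k]: [int(v) for v in df.loc[k]] for k in key}
        return cls(sample_ids=list(df.columns), **rows)


def qc_totals(qc: QcSummary) -> dict[str, int]:
    """Sum each statistic across libraries and convert reads to read pairs.

    Mate-paired totals must divide evenly by two; an odd sum raises.
    """
    out: dict[str, int] = {}
    for stat in ("raw_reads", "trimmed_reads", "mapped_reads",
                 "uniquely_mapped", "multi_mapped", "too_many_loci"):
        total = int(sum(getattr(qc, stat)))
        if total % 2:
            raise ValueError(f"{stat}: total {total} is odd; counts are mate-paired")
        out[stat] = total // 2
    return out


def filter_expressed(cm: CountMatrix, min_fraction: float = 0.5) -> CountMatrix:
    """Keep features detected (count > 0) in at least ``min_fraction`` of samples.

    The threshold is ``ceil(min_fraction * n_samples)`` samples; feature order
    is preserved.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    if cm.n_features == 0:
        raise ValueError("empty count matrix")
    need = int(np.ceil(min_fraction * cm.n_samples))
    keep = (cm.counts > 0).sum(axis=1) >= need
    return CountMatrix(
        feature_ids=[f for f, k in zip(cm.feature_ids, keep) if k],
        sample_ids=list(cm.sample_ids),
        counts=cm.counts[keep],
        group_labels=list(cm.group_labels),
    )


def size_factors_median_of_ratios(cm: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors against a per-feature geometric mean
    pseudo-reference, over features with nonzero counts in every sample."""
    counts = cm.counts.astype(float)
    usable = (counts > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; "
            "consider a pseudo-reference fallback"
        )
    sub = counts[usable]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    return np.exp(np.median(ratios, axis=0))


def normalized_counts(cm: CountMatrix) -> np.ndarray:
    return cm.counts / size_factors_median_of_ratios(cm)[None, :]


def poisson_distance(cm: CountMatrix) -> np.ndarray:
    """Between-sample distance matrix on variance-stabilised counts.

    Counts are divided by median-of-ratios size factors and mapped through
    the square-root stabilisation ``2*sqrt(x)`` appropriate for Poisson-like
    noise; the result is the Euclidean distance between sample columns,
    scaled by 1/sqrt(n_features) so depth of the feature catalogue does not
    dominate.
    """
    if cm.n_samples < 2:
        raise ValueError("need >= 2 samples")
    y = 2.0 * np.sqrt(normalized_counts(cm))
    diff = y[:, :, None] - y[:, None, :]
    d = np.sqrt((diff ** 2).sum(axis=0) / cm.n_features)
    np.fill_diagonal(d, 0.0)
    return d


def pca_samples(cm: CountMatrix, n_components: int = 2):
    """PCA of samples on centered log2(normalised count + 1).

    Returns ``(scores, variance_fractions)`` where scores has one row per
    sample.  Variance fractions are non-increasing and sum to <= 1.
    """
    from sklearn.decomposition import PCA

    if cm.n_samples < 3:
        raise ValueError("need >= 3 samples for PCA")
    x = np.log2(normalized_counts(cm) + 1.0).T  # samples x features
    n_components = min(n_components, cm.n_samples - 1, x.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    return scores, pca.explained_variance_ratio_


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-value in input")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _nb_dispersion_mom(counts: np.ndarray, group_masks: list[np.ndarray],
                       floor: float = 1e-8) -> np.ndarray:
    """Method-of-moments NB dispersion alpha per feature, pooled across groups.

    For NB, var = mu + alpha*mu^2, so alpha = (var - mu)/mu^2 within each
    group; groups are combined by a replicate-weighted average and the result
    floored at ``floor``.
    """
    n_feat = counts.shape[0]
    num = np.zeros(n_feat)
    den = 0.0
    for mask in group_masks:
        sub = counts[:, mask]
        n = mask.sum()
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(mu > 0, (var - mu) / np.maximum(mu, 1e-300) ** 2, 0.0)
        num += alpha * (n - 1)
        den += n - 1
    return np.maximum(num / den, floor)


def nb_de_test(cm: CountMatrix) -> list[DeResult]:
    """Per-feature negative-binomial Wald test between two groups.

    log2 fold change is treatment over control on normalised group means
    with a 0.5 pseudocount; the Wald statistic uses a delta-method variance
    of the log mean under NB sampling with a method-of-moments dispersion
    floored at 1e-8.  All-zero features report log2_fc 0, p 1.  The group
    listed first in ``group_labels`` order is taken as control.
    """
    groups = cm.groups()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    (ctrl_name, ctrl_mask), (trt_name, trt_mask) = groups.items()
    if ctrl_mask.sum() < 2 or trt_mask.sum() < 2:
        raise ValueError("need >= 2 replicates per group")

    norm = normalized_counts(cm)
    alpha = _nb_dispersion_mom(norm, [ctrl_mask, trt_mask])

    mu_c = norm[:, ctrl_mask].mean(axis=1)
    mu_t = norm[:, trt_mask].mean(axis=1)
    n_c, n_t = int(ctrl_mask.sum()), int(trt_mask.sum())
    base_mean = norm.mean(axis=1)

    log2_fc = np.log2(mu_t + 0.5) - np.log2(mu_c + 0.5)

    # delta method: Var(ln mu_hat) ~= (mu + alpha mu^2) / (n mu^2)
    def var_log_mean(mu, n):
        mu_safe = np.maximum(mu, 0.5)
        return (mu_safe + alpha * mu_safe ** 2) / (n * mu_safe ** 2)

    se_ln = np.sqrt(var_log_mean(mu_c, n_c) + var_log_mean(mu_t, n_t))
    se_log2 = se_ln / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_log2 > 0, log2_fc / se_log2, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    degenerate = (cm.counts.sum(axis=1) == 0)
    log2_fc = np.where(degenerate, 0.0, log2_fc)
    p = np.where(degenerate, 1.0, np.clip(p, 0.0, 1.0))

    padj = bh_adjust(p)
    return [
        DeResult(fid, float(bm), float(fc), float(pv), float(pa))
        for fid, bm, fc, pv, pa in zip(cm.feature_ids, base_mean, log2_fc, p, padj)
    ]


def de_results_to_frame(results: list[DeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "base_mean": [r.base_mean for r in results],
            "log2FC": [r.log2_fc for r in results],
            "pvalue": [r.p_value for r in results],
            "padj": [r.p_adjusted for r in results],
            "biotype": [r.biotype for r in results],
        }
    )


def consensus_de(tables: list[pd.DataFrame], alpha: float = 0.05):
    """Features significant in every method with a concordant fold-change sign.

    Each table needs columns feature_id, p_adjusted (or padj), log2_fc (or
    log2FC).  Returns ``(consensus_frame, venn_counts)`` where the frame
    carries the mean log2 fold change across methods and venn_counts maps
    each method index (and "consensus") to its significant-set size.
    """
    if len(tables) < 2:
        raise ValueError("need at least two result tables")
    sig_sets: list[set[str]] = []
    fcs: list[dict[str, float]] = []
    for i, tab in enumerate(tables):
        t = tab.rename(columns={"padj": "p_adjusted", "log2FC": "log2_fc"})
        if t["feature_id"].duplicated().any():
            raise ValueError(f"duplicated feature_id in table {i}")
        sig = t[t["p_adjusted"] < alpha]
        sig_sets.append(set(sig["feature_id"]))
        fcs.append(dict(zip(t["feature_id"], t["log2_fc"])))
    common = set.intersection(*sig_sets)
    consensus = sorted(
        f for f in common
        if len({np.sign(fc[f]) for fc in fcs if f in fc}) == 1
        and np.sign(fcs[0][f]) != 0
    )
    venn = {f"method_{i}": len(s) for i, s in enumerate(sig_sets)}
    venn["consensus"] = len(consensus)
    frame = pd.DataFrame(
        {
            "feature_id": consensus,
            "mean_log2_fc": [
                float(np.mean([fc[f] for fc in fcs if f in fc])) for f in consensus
            ],
        }
    )
    return frame, venn


def hypergeometric_enrichment(query_set, gene_sets: dict[str, set],
                              universe) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    Gene sets are intersected with the universe before testing; BH is
    applied across sets.  Columns: set_name, overlap, set_size, p, padj.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_set)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    n_univ, n_query = len(universe), len(query)
    for name, members in gene_sets.items():
        members = set(members) & universe
        k = len(query & members)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(members), n_query))
        rows.append((name, k, len(members), min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size", "p"])
    df["padj"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


def delta_delta_ct(target_ct: dict[str, float],
                   reference_cts: dict[str, list[float]],
                   groups: dict[str, str],
                   control_group: str):
    """Comparative-CT relative quantification with a Student t-test.

    ``target_ct`` maps sample -> CT of the target gene; ``reference_cts``
    maps sample -> CT values of >= 2 reference genes.  dCT is the target CT
    minus the arithmetic mean of the reference CTs (the CT-space equivalent
    of a geometric-mean reference in expression space); ddCT subtracts the
    control-group mean dCT, and fold change is 2**(-ddCT).  Returns
    ``(fold_by_group, p_value)`` with a two-sided equal-variance t-test on
    the per-sample dCT values.
    """
    samples = list(target_ct)
    if set(samples) != set(groups):
        raise ValueError("samples in target_ct and groups must match")
    dct = {}
    for s in samples:
        refs = reference_cts.get(s)
        if refs is None or len(refs) < 2:
            raise ValueError(f"sample {s}: need CTs for >= 2 reference genes")
        if any(v is None or np.isnan(v) for v in [target_ct[s], *refs]):
            raise ValueError(f"sample {s}: missing CT value")
        dct[s] = target_ct[s] - float(np.mean(refs))
    group_names = list(dict.fromkeys(groups.values()))
    if len(group_names) != 2 or control_group not in group_names:
        raise ValueError("exactly two groups including the control required")
    by_group = {g: [dct[s] for s in samples if groups[s] == g] for g in group_names}
    ctrl_mean = float(np.mean(by_group[control_group]))
    fold = {
        g: float(2.0 ** (-(np.mean(by_group[g]) - ctrl_mean))) for g in group_names
    }
    other = next(g for g in group_names if g != control_group)
    t_p = stats.ttest_ind(by_group[other], by_group[control_group],
                          equal_var=True).pvalue
    return fold, float(t_p)
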