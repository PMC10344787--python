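"""Differential phosphosite analysis and cumulative phosphorylation-state scoring.

The analysis operates on a phosphopeptide × sample intensity matrix with a
group design. The stages mirror standard label-free phosphoproteomics
practice:

1. ``preprocess`` — log2 transform, per-sample median centring, and
   imputation of missing values from a per-sample down-shifted Gaussian
   (missing peptide intensities in LFQ data are predominantly
   low-abundance, so imputed values are drawn from the left tail).
2. ``welch_test`` / ``differential_analysis`` — two-tailed heteroscedastic
   (Welch) t-test per site against a control group.
3. ``call_significance`` — Benjamini–Hochberg FDR at 0.05; when BH yields
   no hits but the raw p-value distribution is anti-conservative (excess
   mass near zero), a fallback rule is applied instead: raw p < 0.05
   combined with fold change > 1.5.
4. ``delta_ps`` — per protein, the cumulative phosphorylation-state change
   is the sum of log2 fold changes over that protein's sites with
   p < 0.05; proteins beyond ±2σ of the cohort distribution are classed
   hyper-/hypo-phosphorylated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

ALPHA = 0.05
FOLD_CHANGE_CUTOFF = 1.5


@dataclass
class PhosphoPeptideTable:
    """Phosphopeptide intensity matrix with protein annotations and design.

    Attributes
    ----------
    intensities
        DataFrame indexed by site id (protein + residue + position),
        columns are sample names; values are positive intensities with
        NaN for missing observations.
    proteins
        Series mapping each site id to its protein id.
    design
        Mapping from sample name to group label.
    """

    intensities: pd.DataFrame
    proteins: pd.Series
    design: Mapping[str, str]
    log_scale: bool = False  # True after preprocess: values are log2-centred

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            dups = self.intensities.index[self.intensities.index.duplicated()].unique()
            raise DataError(f"duplicate site ids: {list(dups[:5])}")
        if not self.intensities.index.equals(self.proteins.index):
            self.proteins = self.proteins.reindex(self.intensities.index)
            if self.proteins.isna().any():
                missing = self.proteins.index[self.proteins.isna()]
                raise DataError(f"sites without protein annotation: {list(missing[:5])}")
        unknown = [s for s in self.intensities.columns if s not in self.design]
        if unknown:
            raise DataError(f"samples missing from design: {unknown}")
        if not self.log_scale:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                if np.nanmin(self.intensities.to_numpy(dtype=float), initial=np.inf) < 0:
                    raise DataError("negative intensities are not allowed")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.intensities.columns:
            seen.setdefault(self.design[s], None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.intensities.columns if self.design[s] == group]


def preprocess(
    table: PhosphoPeptideTable,
    seed: int,
    down_shift: float = 1.8,
    width: float = 0.3,
) -> PhosphoPeptideTable:
    """Log2-transform, median-centre per sample, and impute missing values.

    Missing entries are drawn per sample from a Gaussian down-shifted from
    the observed distribution: mean ``sample_mean - down_shift * sample_sd``
    and standard deviation ``width * sample_sd``, computed on the
    log2-centred observed values. This emulates the low-abundance origin of
    missing LFQ intensities.

    Raises
    ------
    DataError
        If any sample has no observed values (naming the sample).
    """
    rng = np.random.default_rng(seed)
    x = np.log2(table.intensities.to_numpy(dtype=float))
    for j, sample in enumerate(table.intensities.columns):
        if np.all(np.isnan(x[:, j])):
            raise DataError(f"sample {sample!r} has no observed intensities")
    # per-sample median centring
    med = np.nanmedian(x, axis=0, keepdims=True)
    x = x - med
    # down-shifted Gaussian imputation, one draw per missing cell
    for j in range(x.shape[1]):
        col = x[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        obs = col[~miss]
        mu = obs.mean() - down_shift * obs.std(ddof=1 if obs.size > 1 else 0)
        sd = width * obs.std(ddof=1 if obs.size > 1 else 0)
        col[miss] = rng.normal(mu, sd, size=int(miss.sum()))
    out = pd.DataFrame(x, index=table.intensities.index, columns=table.intensities.columns)
    return PhosphoPeptideTable(
        intensities=out, proteins=table.proteins, design=dict(table.design), log_scale=True
    )


def welch_test(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Two-tailed Welch (heteroscedastic) t-test.

    Returns ``(t, p)`` with Welch–Satterthwaite degrees of freedom. When
    both groups have zero variance and equal means the test is degenerate
    and ``(0.0, 1.0)`` is returned by convention.

    Raises
    ------
    DataError
        If either group has fewer than 2 observations.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise DataError("welch_test requires >=2 non-missing values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def detect_anticonservative(
    p: np.ndarray, alpha: float = ALPHA, excess_factor: float = 1.5
) -> bool:
    """Detect an anti-conservative p-value distribution.

    A distribution is flagged anti-conservative when the observed fraction
    of p-values below ``alpha`` exceeds ``excess_factor`` times the uniform
    expectation ``alpha``. This is a deterministic surrogate for visual
    histogram inspection.

    Raises
    ------
    DataError
        With fewer than 50 p-values the histogram is uninformative; use
        BH alone.
    """
    p = np.asarray(p, dtype=float)
    if p.size < 50:
        raise DataError(
            "too few p-values to assess the distribution; apply BH correction only"
        )
    return float(np.mean(p < alpha)) > excess_factor * alpha


def call_significance(results: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """Apply the BH rule, falling back to p + fold-change when BH is empty.

    ``results`` must carry columns ``p``, ``p_adj`` and ``log2fc``. The BH
    rule (``p_adj < alpha``) is applied first. Only when it yields zero
    hits *and* the raw p-value distribution is anti-conservative is the
    fallback applied: raw ``p < alpha`` combined with
    ``|log2fc| > log2(1.5)``. The ``procedure`` column records which rule
    produced the calls.
    """
    out = results.copy()
    bh_sig = out["p_adj"] < alpha
    procedure = "BH"
    if not bh_sig.any() and len(out) >= 50 and detect_anticonservative(out["p"].to_numpy(), alpha):
        procedure = "fallback"
        sig = (out["p"] < alpha) & (out["log2fc"].abs() > np.log2(FOLD_CHANGE_CUTOFF))
    else:
        sig = bh_sig
    out["significant"] = sig
    out["procedure"] = procedure
    logger.info("significance procedure=%s, %d/%d sites called", procedure, int(sig.sum()), len(out))
    return out


def differential_analysis(
    table: PhosphoPeptideTable,
    control: str,
    treatment: str,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-site Welch tests of ``treatment`` vs ``control`` on log2 data.

    ``table`` must already be preprocessed (log2 scale, no missing
    values). Returns a DataFrame indexed by site id with columns
    ``protein_id, log2fc, t, p, p_adj, significant, procedure``.
    """
    for g in (control, treatment):
        if len(table.samples_in(g)) < 2:
            raise DataError(f"group {g!r} has fewer than 2 samples")
    a = table.intensities[table.samples_in(treatment)].to_numpy(dtype=float)
    b = table.intensities[table.samples_in(control)].to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise DataError("differential_analysis requires a preprocessed (complete) table")
    tvals = np.empty(a.shape[0])
    pvals = np.empty(a.shape[0])
    for i in range(a.shape[0]):
        tvals[i], pvals[i] = welch_test(a[i], b[i])
    res = pd.DataFrame(
        {
            "protein_id": table.proteins,
            "log2fc": a.mean(axis=1) - b.mean(axis=1),
            "t": tvals,
            "p": pvals,
            "p_adj": bh_adjust(pvals),
        },
        index=table.intensities.index,
    )
    return call_significance(res, alpha=alpha)


@dataclass
class DeltaPsRecord:
    """Per-protein cumulative phosphorylation-state score."""

    protein_id: str
    delta_ps: float
    n_sig: int
    klass: str  # hyper | hypo | none


def delta_ps(
    results: pd.DataFrame,
    alpha: float = ALPHA,
    sigma_over: str = "all",
) -> pd.DataFrame:
    """Per-protein cumulative phosphorylation-state (∆Ps) scores.

    For each protein, ∆Ps is the sum of log2 fold changes over its sites
    with raw ``p < alpha``; a protein with no such site scores exactly 0.
    The classification threshold is ±2σ where σ is the population
    standard deviation of the ∆Ps values across proteins.

    Parameters
    ----------
    results
        Per-site results with columns ``protein_id, log2fc, p``.
    sigma_over
        ``"all"`` (default) computes σ over every protein including the
        zeros; ``"nonzero"`` restricts to proteins with ∆Ps != 0.

    Returns
    -------
    DataFrame indexed by protein id with columns
    ``delta_ps, n_sig, klass`` plus the threshold in ``attrs['two_sigma']``.
    """
    if sigma_over not in ("all", "nonzero"):
        raise ConfigurationError("sigma_over must be 'all' or 'nonzero'")
    if len(results) == 0:
        out = pd.DataFrame(columns=["delta_ps", "n_sig", "klass"])
        out.attrs["two_sigma"] = 0.0
        return out
    sig = results["p"] < alpha
    contrib = results["log2fc"].where(sig, 0.0)
    grouped = pd.DataFrame({"delta_ps": contrib, "n_sig": sig.astype(int)}).groupby(
        results["protein_id"], sort=True
    )
    out = grouped.sum()
    vals = out["delta_ps"].to_numpy()
    pool = vals if sigma_over == "all" else vals[vals != 0]
    sigma = float(np.std(pool)) if pool.size else 0.0
    two_sigma = 2.0 * sigma
    klass = np.where(vals > two_sigma, "hyper", np.where(vals < -two_sigma, "hypo", "none"))
    out["klass"] = klass
    out.attrs["two_sigma"] = two_sigma
    return out


def zscore_sites(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Z-score each site (row) to mean 0 and unit population sd across samples.

    Zero-variance rows are mapped to all-zero rows with a warning.
    """
    values = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if np.isnan(values).any():
        raise DataError("zscore_sites requires a complete matrix; run preprocess first")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population sd
    # a row of identical values can report a tiny nonzero sd from the
    # inexact mean; detect flatness by range instead
    flat = (values.max(axis=1, keepdims=True) == values.min(axis=1, keepdims=True)) | (sd == 0)
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance rows z-scored to 0", stacklevel=2)
    z = np.where(~flat, (values - mean) / np.where(flat, 1.0, sd), 0.0)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return z


@dataclass
class ClusterSummary:
    """Hierarchical clustering of z-scored sites."""

    assignments: pd.Series  # site -> cluster id (1..k)
    zscores: pd.DataFrame
    group_means: pd.DataFrame | None = field(default=None)  # cluster x group mean z


def cluster_sites(
    zmatrix: pd.DataFrame,
    k: int,
    design: Mapping[str, str] | None = None,
) -> ClusterSummary:
    """Agglomerative (Ward, Euclidean) clustering of z-scored site profiles.

    The dendrogram is cut to ``k`` flat clusters. When a design is given,
    the per-cluster mean z per group is reported, which is how coordinate
    modulation of a cluster across conditions is summarised.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k > len(zmatrix):
        raise ConfigurationError(f"k={k} exceeds number of sites ({len(zmatrix)})")
    if k == 1 or len(zmatrix) == 1:
        labels = np.ones(len(zmatrix), dtype=int)
    else:
        Z = linkage(zmatrix.to_numpy(dtype=float), method="ward", metric="euclidean")
        labels = fcluster(Z, t=k, criterion="maxclust")
    assignments = pd.Series(labels, index=zmatrix.index, name="cluster")
    group_means = None
    if design is not None:
        groups: dict[str, list[str]] = {}
        for s in zmatrix.columns:
            groups.setdefault(design[s], []).append(s)
        rows = {}
        for cid in sorted(set(labels)):
            sub = zmatrix.loc[assignments == cid]
            rows[cid] = {g: float(sub[cols].to_numpy().mean()) for g, cols in groups.items()}
        group_means = pd.DataFrame.from_dict(rows, orient="index")
        group_means.index.name = "cluster"
    return ClusterSummary(assignments=assignments, zscores=zmatrix, group_means=group_means)


def compare_cluster_groups(
    zmatrix: pd.DataFrame,
    assignments: pd.Series,
    design: Mapping[str, str],
    cluster: int,
) -> pd.DataFrame:
    """Kruskal–Wallis plus Dunn post-hoc comparison of a cluster across groups.

    The per-sample mean z of the cluster's sites is the test variable.
    This is a convenience wrapper around routine rank statistics; Dunn
    z-statistics use the tie-corrected pooled-rank variance and BH-adjusted
    two-sided p-values.
    """
    sites = assignments.index[assignments == cluster]
    if len(sites) == 0:
        raise DataError(f"cluster {cluster} is empty")
    per_sample = zmatrix.loc[sites].mean(axis=0)
    groups: dict[str, np.ndarray] = {}
    for s in per_sample.index:
        groups.setdefault(design[s], [])
        groups[design[s]].append(per_sample[s])
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(names) < 2:
        raise DataError("need at least two groups")
    H, p_kw = stats.kruskal(*arrays)
    # Dunn's test on pooled ranks
    pooled = np.concatenate(arrays)
    ranks = stats.rankdata(pooled)
    n = pooled.size
    offsets = np.cumsum([0] + [a.size for a in arrays])
    mean_ranks = [ranks[offsets[i]:offsets[i + 1]].mean() for i in range(len(arrays))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(var_base * (1 / arrays[i].size + 1 / arrays[j].size))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            rows.append({"group_a": names[i], "group_b": names[j], "z": z,
                         "p": 2 * stats.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out.attrs["kruskal_H"] = float(H)
    out.attrs["kruskal_p"] = float(p_kw)
    return out


def report_fractions(n_sig: int, n_total: int) -> float:
    """Percentage of significant features, rounded to two decimals."""
    if n_total <= 0:
        raise DataError("n_total must be positive")
    if not 0 <= n_sig <= n_total:
        raise DataError("n_sig must lie in [0, n_total]")
    return round(100.0 * n_sig / n_total, 2)
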