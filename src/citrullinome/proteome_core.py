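"""Abundance-table preprocessing and group-level statistics for LFQ proteomics.

The central object is :class:`AbundanceTable`, a protein × sample intensity
matrix (missing values allowed) with a sample → group map.  The functions in
this module implement the standard label-free workflow applied to the serum
citrullinome: filtering on per-group presence, log2 transformation,
k-nearest-neighbour imputation, Wilcoxon / t two-group tests, Spearman
correlation, Benjamini–Hochberg adjustment, and per-protein differential
expression.

Missingness in LFQ data is typically intensity-dependent (missing not at
random), which is why filtering and imputation are applied on the log2 scale
before any testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

INTENSITY_PREFIX = "LFQ.intensity."


@dataclass
class AbundanceTable:
    """Protein × sample intensity matrix with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with one column per sample.
        ``NaN`` encodes a missing (unquantified) intensity.
    groups
        Series mapping sample id → group label.  Every sample column must
        have a group.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate protein ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        # keep group order aligned with the sample columns
        self.groups = self.groups.reindex(self.values.columns)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_labels(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        return list(dict.fromkeys(self.groups))

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(self.values.copy(), self.groups.copy())

    # -- TSV round trip -----------------------------------------------------

    def to_tsv(self, path: str | Path, sample_map_path: str | Path) -> None:
        """Write intensities and the sample → group sidecar as TSV.

        The intensity file has a ``protein_id`` column followed by one
        ``LFQ.intensity.<sample>`` column per sample; missing cells are empty.
        """
        out = self.values.copy()
        out.columns = [INTENSITY_PREFIX + s for s in out.columns]
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t", na_rep="")
        sm = pd.DataFrame({"sample": self.groups.index, "group": self.groups.values})
        sm.to_csv(sample_map_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sample_map_path: str | Path) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", index_col="protein_id")
        df.columns = [
            c[len(INTENSITY_PREFIX):] if c.startswith(INTENSITY_PREFIX) else c
            for c in df.columns
        ]
        df.index.name = None
        sm = pd.read_csv(sample_map_path, sep="\t")
        groups = pd.Series(sm["group"].values, index=sm["sample"].values)
        return cls(df, groups)


def filter_by_group_presence(t: AbundanceTable, min_frac: float = 0.7) -> AbundanceTable:
    """Retain proteins observed in ≥ ``min_frac`` of samples of at least one group.

    Group-specific proteins (fully observed in one group, absent in the
    other) are deliberately kept: presence is evaluated within each group
    separately.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    if t.n_proteins == 0 or t.n_samples == 0:
        raise ValueError("empty abundance table")
    keep = pd.Series(False, index=t.values.index)
    for g in t.group_labels():
        cols = t.samples_in_group(g)
        frac = t.values[cols].notna().mean(axis=1)
        keep |= frac >= min_frac
    return AbundanceTable(t.values.loc[keep].copy(), t.groups.copy())


def log2_transform(t: AbundanceTable, pseudo: float = 0.0) -> AbundanceTable:
    """log2(value + pseudo) per cell; missing cells stay missing."""
    if (t.values < 0).any().any():
        raise ValueError("negative intensities")
    with np.errstate(divide="ignore"):
        out = np.log2(t.values + pseudo)
    return AbundanceTable(out, t.groups.copy())


def _protein_distance_matrix(x: np.ndarray, obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """RMS Euclidean distance between protein rows over mutually observed samples.

    Returns (distance matrix, shared-sample counts); distance is inf where no
    sample is shared.  Scaling the squared distance by the number of shared
    samples makes distances comparable between pairs with different overlap.
    """
    a = np.where(obs, x, 0.0)
    a2 = a * a
    m = obs.astype(float)
    shared = m @ m.T
    ss = a2 @ m.T + m @ a2.T - 2.0 * (a @ a.T)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.sqrt(np.maximum(ss, 0.0) / shared)
    d[shared == 0] = np.inf
    return d, shared


def knn_impute(t: AbundanceTable, k: int = 10) -> AbundanceTable:
    """Impute missing cells from the k nearest proteins observed at that sample.

    For a missing cell (protein p, sample s) the neighbours are the k
    proteins closest to p — by RMS Euclidean distance over the samples both
    proteins were observed in — that themselves have an observed value at s;
    the imputed value is their unweighted mean.  If fewer than k neighbours
    are eligible all of them are used; with none, the protein's own observed
    mean is substituted (logged).  Intended to run on log2 intensities.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = t.values.to_numpy(dtype=float)
    obs = ~np.isnan(x)
    if (~obs.any(axis=1)).any():
        bad = [t.protein_ids[i] for i in np.flatnonzero(~obs.any(axis=1))]
        raise ValueError(f"proteins with no observed values (filter first): {bad[:5]}")
    if obs.all():
        return t.copy()
    dist, _ = _protein_distance_matrix(x, obs)
    np.fill_diagonal(dist, np.inf)
    row_means = np.array([x[i, obs[i]].mean() for i in range(x.shape[0])])
    out = x.copy()
    # stable neighbour order: distance, then protein index
    order = np.argsort(dist, axis=1, kind="stable")
    for i, j in zip(*np.nonzero(~obs)):
        eligible = [q for q in order[i] if obs[q, j] and np.isfinite(dist[i, q])]
        if not eligible:
            log.warning(
                "protein %s: no eligible neighbour at sample %s; using its observed mean",
                t.protein_ids[i], t.sample_ids[j],
            )
            out[i, j] = row_means[i]
        else:
            nn = eligible[:k]
            out[i, j] = x[nn, j].mean()
    return AbundanceTable(pd.DataFrame(out, index=t.values.index, columns=t.values.columns),
                          t.groups.copy())


def _wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n1, n2 = len(x), len(y)
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    has_ties = np.unique(combined).size < n
    if n <= 12 and not has_ties:
        # exact two-sided p by enumerating every assignment of group labels
        dev = abs(w - mu)
        hits = total = 0
        for idx in combinations(range(n), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
                hits += 1
        return w, hits / total
    # normal approximation with tie correction and continuity correction
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    z = max(abs(w - mu) - 0.5, 0.0) / np.sqrt(var)
    return w, min(1.0, 2.0 * stats.norm.sf(z))


def two_group_test(x, y, method: str = "wilcoxon") -> tuple[float, float]:
    """Two-sided two-sample test.

    ``wilcoxon``: rank-sum statistic of ``x``; exact p by enumeration when
    n1+n2 ≤ 12 with no ties, otherwise normal approximation with tie and
    continuity corrections.  ``student_t``: pooled-variance t;
    ``welch_t``: unpooled.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 values per group")
    if method == "wilcoxon":
        return _wilcoxon_rank_sum(x, y)
    if method in ("student_t", "welch_t"):
        res = stats.ttest_ind(x, y, equal_var=(method == "student_t"))
        tstat = float(res.statistic)
        p = float(res.pvalue)
        if np.isnan(tstat):  # both groups constant and equal
            return 0.0, 1.0
        return tstat, p
    raise ValueError(f"unknown method {method!r}")


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal lengths >= 3")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero variance in ranks")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Per-protein differential-expression results (case vs control).

    ``table`` is indexed by protein id with columns log2fc (case − control on
    the log2 scale), stat, p, padj, direction and significant.
    """

    table: pd.DataFrame
    case: str
    control: str
    alpha: float
    lfc_cutoff: float
    method: str = "wilcoxon"

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t")


def differential_expression(
    t: AbundanceTable,
    alpha: float = 0.05,
    lfc_cutoff: float = 0.0,
    method: str = "wilcoxon",
    case: str | None = None,
    control: str | None = None,
) -> DEResult:
    """Per-protein two-group test with BH adjustment on a complete log2 table.

    The fold change is the difference of group means on the log2 scale
    (case − control).  The table must already be filtered, log2-transformed
    and imputed.
    """
    if not t.is_complete():
        raise ValueError("table contains missing values; impute first")
    labels = t.group_labels()
    if len(labels) != 2:
        raise ValueError(f"differential expression needs exactly 2 groups, got {labels}")
    if case is None or control is None:
        case, control = sorted(labels)
        if "control" in labels and case == "control":
            case, control = control, case
    cs = t.samples_in_group(case)
    ct = t.samples_in_group(control)
    if len(cs) < 2 or len(ct) < 2:
        raise ValueError("each group needs at least 2 samples")
    xc = t.values[cs].to_numpy(dtype=float)
    xt = t.values[ct].to_numpy(dtype=float)
    stats_, ps = [], []
    for i in range(t.n_proteins):
        s, p = two_group_test(xc[i], xt[i], method=method)
        stats_.append(s)
        ps.append(p)
    log2fc = xc.mean(axis=1) - xt.mean(axis=1)
    padj = bh_adjust(ps)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "stat": stats_,
            "p": ps,
            "padj": padj,
            "direction": np.where(log2fc >= 0, "up", "down"),
        },
        index=t.values.index,
    )
    table["significant"] = (table["padj"] < alpha) & (table["log2fc"].abs() >= lfc_cutoff)
    return DEResult(table, case=case, control=control, alpha=alpha,
                    lfc_cutoff=lfc_cutoff, method=method)
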