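"""Alpha/beta diversity, ordination, taxon aggregation, and the per-OTU
covariate correlation screen.

Shannon entropy is reported in nats.  Chao1 uses the classic estimator
S_obs + F1^2/(2 F2) when doubletons exist and the bias-corrected form
S_obs + F1 (F1 - 1)/2 when F2 = 0.  Principal coordinates analysis uses
Gower centering with percent variance relative to the sum of *positive*
eigenvalues (negative eigenvalues are reported but excluded from the
denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .datatypes import CovariateTable, OtuTable

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__", "d__")


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def chao1(counts) -> float:
    """Chao1 richness estimate for a single sample's OTU counts."""
    x = np.asarray(counts)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("all-zero sample: Chao1 undefined")
    s_obs = x.size
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    if f2 > 0:
        return s_obs + f1**2 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def shannon(counts) -> float:
    """Shannon entropy (nats) of a single sample's OTU counts."""
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero sample: Shannon undefined")
    p = x[x > 0] / total
    return float(-np.sum(p * np.log(p)))


@dataclass
class AlphaDiversity:
    sample_ids: list
    s_obs: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    chao1: np.ndarray
    shannon: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s_obs": self.s_obs,
                "f1": self.f1,
                "f2": self.f2,
                "chao1": self.chao1,
                "shannon": self.shannon,
            },
            index=self.sample_ids,
        )


def alpha_diversity(table: OtuTable) -> AlphaDiversity:
    n = table.n_samples
    s_obs = np.zeros(n, dtype=int)
    f1 = np.zeros(n, dtype=int)
    f2 = np.zeros(n, dtype=int)
    c1 = np.zeros(n)
    sh = np.zeros(n)
    for s in range(n):
        col = table.counts[:, s]
        s_obs[s] = int(np.sum(col > 0))
        f1[s] = int(np.sum(col == 1))
        f2[s] = int(np.sum(col == 2))
        c1[s] = chao1(col)
        sh[s] = shannon(col)
    return AlphaDiversity(list(table.sample_ids), s_obs, f1, f2, c1, sh)


# ---------------------------------------------------------------------------
# Beta diversity and ordination
# ---------------------------------------------------------------------------

@dataclass
class DissimilarityMatrix:
    sample_ids: list
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix diagonal must be zero")

    @property
    def mean_offdiagonal(self) -> float:
        return float(np.mean(squareform(self.matrix, checks=False)))

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


def bray_curtis(table: OtuTable, use_proportions: bool = False) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    d(x, y) = sum |x_i - y_i| / sum (x_i + y_i), computed on raw counts by
    default or on relative abundances with ``use_proportions=True``.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = table.relative_abundance().T if use_proportions else table.counts.T.astype(float)
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        warnings.warn("all-zero samples present; their dissimilarities are undefined")
    D = squareform(pdist(X, metric="braycurtis"))
    D = np.nan_to_num(D, nan=np.nan)  # keep NaN for all-zero pairs explicit
    return DissimilarityMatrix(list(table.sample_ids), D)


@dataclass
class Ordination:
    sample_ids: list
    coordinates: np.ndarray       # (n_samples, n_axes), scaled by sqrt(eigval)
    eigenvalues: np.ndarray       # all eigenvalues, non-increasing
    pct_explained: np.ndarray     # per retained axis, % of positive-eigval sum


def pcoa(d: DissimilarityMatrix, n_axes: int = 3) -> Ordination:
    """Principal coordinates analysis by Gower-centered eigen-decomposition."""
    D = d.matrix
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2.0
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12, 1e-10 * abs(eigval[0]))
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating"
        )
        n_axes = n_pos
    coords = eigvec[:, :n_axes] * np.sqrt(eigval[:n_axes])
    pct = 100.0 * eigval[:n_axes] / eigval[pos].sum()
    return Ordination(list(d.sample_ids), coords, eigval, pct)


# ---------------------------------------------------------------------------
# Taxon aggregation
# ---------------------------------------------------------------------------

def _lineage_token(lineage: str | None, rank: str) -> str:
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if lineage is None:
        return "unclassified"
    parts = [p.strip() for p in str(lineage).split(";")]
    cleaned = []
    for p in parts:
        low = p.lower()
        for pref in _RANK_PREFIXES:
            if low.startswith(pref):
                p = p[3:]
                break
        cleaned.append(p.strip())
    idx = RANKS.index(rank)
    if idx >= len(cleaned):
        return "unclassified"
    token = cleaned[idx]
    if token == "" or token.lower().startswith("unclassified"):
        return "unclassified"
    return token


def aggregate_taxa(table: OtuTable, rank: str, top_n: int | None = None) -> pd.DataFrame:
    """Group OTUs at a taxonomic rank into per-sample relative abundances.

    Groups are ranked by campaign-wide mean abundance; beyond `top_n` they
    pool into ``other``.  OTUs lacking the rank pool into ``unclassified``.
    Columns (samples) each sum to 1.
    """
    if table.taxonomy is None:
        raise ValueError("OTU table has no taxonomy")
    tokens = [_lineage_token(t, rank) for t in table.taxonomy]
    rel = table.relative_abundance()
    df = pd.DataFrame(rel, columns=table.sample_ids)
    df["_group"] = tokens
    grouped = df.groupby("_group").sum()
    named = grouped.drop(index="unclassified", errors="ignore")
    order = named.mean(axis=1).sort_values(ascending=False).index.tolist()
    if top_n is not None and len(order) > top_n:
        top, tail = order[:top_n], order[top_n:]
        other = named.loc[tail].sum(axis=0)
        named = named.loc[top]
        named.loc["other"] = other
    else:
        named = named.loc[order]
    if "unclassified" in grouped.index:
        named.loc["unclassified"] = grouped.loc["unclassified"]
    named.index.name = rank
    return named


# ---------------------------------------------------------------------------
# Correlation screen
# ---------------------------------------------------------------------------

@dataclass
class CorrelationScreenResult:
    table: pd.DataFrame           # otu_id, covariate, kind, r, p, sign, significant, strongest
    alpha: float
    n_samples: int

    def significant_counts(self) -> pd.DataFrame:
        sig = self.table[self.table["significant"]]
        return (
            sig.groupby(["covariate", "sign"]).size().unstack(fill_value=0)
        )


def correlation_screen(
    table: OtuTable,
    covariates: CovariateTable,
    alpha: float = 0.05,
    fdr: bool = False,
) -> CorrelationScreenResult:
    """Pearson screen of per-OTU relative abundance against each covariate.

    Two-sided p-values from the t distribution with n-2 degrees of freedom,
    uncorrected by default (Benjamini-Hochberg optional via ``fdr=True``).
    Constant OTUs or covariates are skipped with a note.  The strongest
    correlation per OTU (largest |r| among its significant hits within the
    covariate class) is flagged.
    """
    shared = [s for s in table.sample_ids if s in covariates.sample_ids]
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    t_idx = [table.sample_ids.index(s) for s in shared]
    c_idx = [covariates.sample_ids.index(s) for s in shared]
    rel = table.relative_abundance()[:, t_idx]
    Z = covariates.values[c_idx, :]
    n = len(shared)

    # standardize; constant rows/columns flagged
    def standardize(M, axis):
        mu = M.mean(axis=axis, keepdims=True)
        sd = M.std(axis=axis, keepdims=True)
        const = np.ravel(sd == 0)
        sd = np.where(sd == 0, 1.0, sd)
        return (M - mu) / sd, const

    Xs, const_otu = standardize(rel, axis=1)
    Zs, const_cov = standardize(Z, axis=0)
    if np.any(const_cov):
        bad = [covariates.covariate_names[j] for j in np.where(const_cov)[0]]
        warnings.warn(f"constant covariates skipped: {bad}")
    if np.any(const_otu):
        warnings.warn(f"{int(const_otu.sum())} constant OTUs skipped")

    R = (Xs @ Zs) / n
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / (1.0 - R**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(p), 0.0, p)  # |r| = 1 exactly

    rows = []
    for i in range(table.n_otus):
        if const_otu[i]:
            continue
        for j in range(len(covariates.covariate_names)):
            if const_cov[j]:
                continue
            rows.append(
                (
                    table.otu_ids[i],
                    covariates.covariate_names[j],
                    covariates.kind,
                    R[i, j],
                    p[i, j],
                    "positive" if R[i, j] >= 0 else "negative",
                )
            )
    df = pd.DataFrame(rows, columns=["otu_id", "covariate", "kind", "r", "p", "sign"])
    if fdr:
        df["p_adj"] = stats.false_discovery_control(df["p"], method="bh")
        df["significant"] = df["p_adj"] < alpha
    else:
        df["significant"] = df["p"] < alpha
    df["strongest"] = False
    sig = df[df["significant"]]
    if len(sig):
        idx = sig.assign(absr=sig["r"].abs()).groupby("otu_id")["absr"].idxmax()
        df.loc[idx.to_numpy(), "strongest"] = True
    return CorrelationScreenResult(df, alpha, n)
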