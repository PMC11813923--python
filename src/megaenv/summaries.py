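"""Descriptive statistics, correlations, clustering, PCA and botanical
composition tables for MET datasets and BLUP matrices."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .errors import ParameterError
from .traits import TRANSITIONAL_MERGE


def descriptive_stats(dataset, traits=None) -> pd.DataFrame:
    """Per (environment, trait): mean, sd, se, CV%, min, max, range.

    Cells with a single observation report sd/se/CV as NaN with a
    ``flag``; CV is flagged undefined when the mean is 0.
    """
    traits = list(traits) if traits is not None else dataset.trait_columns
    rows = []
    for trial, sub in dataset.frame.groupby("trial_id", sort=True):
        for trait in traits:
            x = sub[trait].dropna()
            if x.empty:
                warnings.warn(f"no observations for {trait} in {trial}; "
                              "row omitted", stacklevel=2)
                continue
            n = len(x)
            mean = float(x.mean())
            flag = ""
            if n < 2:
                sd = se = cv = np.nan
                flag = "single observation"
            else:
                sd = float(x.std(ddof=1))
                se = sd / np.sqrt(n)
                if mean == 0:
                    cv = np.nan
                    flag = "CV undefined (mean 0)"
                else:
                    cv = 100.0 * sd / mean
            rows.append((trial, trait, n, mean, sd, se, cv,
                         float(x.min()), float(x.max()),
                         float(x.max() - x.min()), flag))
    return pd.DataFrame(rows, columns=["trial_id", "trait", "n", "mean",
                                       "sd", "se", "cv_percent", "min",
                                       "max", "range", "flag"])


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Pearson r with its t-test p-value on pairwise-complete data."""
    x = pd.Series(x, dtype=float)
    y = pd.Series(y, dtype=float).reindex(x.index)
    ok = x.notna() & y.notna()
    n = int(ok.sum())
    if n < 3:
        raise ParameterError("need >= 3 pairwise-complete observations")
    xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ParameterError("correlation undefined: zero variance")
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p), n


@dataclass
class CorrelationReport:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def significant(self, alpha: float = 0.01) -> pd.DataFrame:
        """r masked (NaN) where p >= alpha; diagonal kept."""
        mask = (self.p < alpha) | np.eye(len(self.r), dtype=bool)
        return self.r.where(mask)


def correlation_matrix(frame: pd.DataFrame) -> CorrelationReport:
    """Pairwise-complete Pearson correlations between the columns."""
    cols = list(frame.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), len(frame))
    for i in range(k):
        n[i, i] = frame[cols[i]].notna().sum()
        for j in range(i + 1, k):
            rij, pij, nij = pearson_with_p(frame[cols[i]], frame[cols[j]])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
            n[i, j] = n[j, i] = nij
    mk = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return CorrelationReport(mk(r), mk(p), mk(n))


@dataclass
class ClusterReport:
    linkage_matrix: np.ndarray
    labels: pd.Series                   # genotype -> cluster id (1..k)
    diameters: pd.Series                # mean pairwise within-cluster dist
    inter_distances: pd.DataFrame       # mean pairwise between-cluster dist


def hierarchical_clusters(blup_matrix: pd.DataFrame, k: int) -> ClusterReport:
    """Complete-linkage clustering on Euclidean distances.

    Cluster diameter is the average pairwise within-cluster distance and
    inter-cluster distance the average pairwise between-cluster distance
    (average linkage between the complete-linkage clusters, as is
    conventional for cluster diagnostics).
    """
    if blup_matrix.isna().any().any():
        raise ParameterError("BLUP matrix must be complete")
    n = len(blup_matrix)
    if k > n:
        raise ParameterError(f"k={k} exceeds {n} genotypes")
    X = blup_matrix.to_numpy(float)
    Z = linkage(X, method="complete", metric="euclidean")
    labels = pd.Series(fcluster(Z, t=k, criterion="maxclust"),
                       index=blup_matrix.index, name="cluster")
    D = squareform(pdist(X))
    ids = sorted(labels.unique())
    diam = {}
    for c in ids:
        idx = np.flatnonzero((labels == c).to_numpy())
        if len(idx) < 2:
            diam[c] = 0.0
        else:
            sub = D[np.ix_(idx, idx)]
            diam[c] = float(sub[np.triu_indices(len(idx), 1)].mean())
    inter = pd.DataFrame(0.0, index=ids, columns=ids)
    for a in ids:
        ia = np.flatnonzero((labels == a).to_numpy())
        for b in ids:
            if b <= a:
                continue
            ib = np.flatnonzero((labels == b).to_numpy())
            val = float(D[np.ix_(ia, ib)].mean())
            inter.loc[a, b] = inter.loc[b, a] = val
    return ClusterReport(Z, labels, pd.Series(diam, name="diameter"), inter)


@dataclass
class PCAReport:
    eigenvalues: np.ndarray
    proportion: np.ndarray
    loadings: pd.DataFrame     # traits x PCs, orthonormal columns
    scores: pd.DataFrame       # genotypes x PCs


def pca(blup_matrix: pd.DataFrame, standardize: bool = True) -> PCAReport:
    """Correlation-matrix PCA (default) of a genotype x trait matrix."""
    if blup_matrix.shape[1] < 2:
        raise ParameterError("PCA needs >= 2 traits")
    X = blup_matrix.to_numpy(float)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = sorted(blup_matrix.columns[sd == 0])
            raise ParameterError(f"constant trait column(s) {bad}: "
                                 "standardization undefined")
        X = X / sd
    C = (X.T @ X) / (len(X) - 1)
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    for k in range(eigvec.shape[1]):  # deterministic sign: largest loading +
        j = int(np.argmax(np.abs(eigvec[:, k])))
        if eigvec[j, k] < 0:
            eigvec[:, k] *= -1.0
    cols = [f"PC{k + 1}" for k in range(len(eigval))]
    return PCAReport(
        eigenvalues=eigval,
        proportion=eigval / eigval.sum(),
        loadings=pd.DataFrame(eigvec, index=blup_matrix.columns,
                              columns=cols),
        scores=pd.DataFrame(X @ eigvec, index=blup_matrix.index,
                            columns=cols),
    )


def merge_transitional(btype: str) -> str:
    """Map a transitional seed type onto its main type (package convention:
    the first-named main type); main types pass through, anything else is
    "unknown"."""
    if btype in ("paucijuga", "minor", "equina", "major"):
        return btype
    return TRANSITIONAL_MERGE.get(btype, "unknown")


def botanical_composition(cluster_labels: pd.Series,
                          botanical_assignment: dict[str, str]
                          ) -> pd.DataFrame:
    """Integer percentage of botanical types per cluster and overall.

    Transitional types are merged into main types first; unassigned
    genotypes count as "unknown".  Columns sum to 100 up to rounding.
    """
    types = ["paucijuga", "minor", "equina", "major", "unknown"]
    merged = {g: merge_transitional(botanical_assignment.get(g, "unknown"))
              for g in cluster_labels.index}
    clusters = sorted(cluster_labels.unique())
    out = pd.DataFrame(0, index=types, columns=[*clusters, "overall"])
    for col, members in [*((c, cluster_labels.index[cluster_labels == c])
                           for c in clusters),
                         ("overall", cluster_labels.index)]:
        n = len(members)
        for t in types:
            count = sum(1 for g in members if merged[g] == t)
            out.loc[t, col] = (int(np.floor(100.0 * count / n + 0.5))
                               if n else 0)
    return out
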