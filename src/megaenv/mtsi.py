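"""Multi-trait stability selection: WAASB, WAASBY and the MTSI ranking.

WAASB (weighted average of absolute scores) measures a genotype's
instability from the SVD of its genotype-by-environment interaction BLUP
matrix: all axes' absolute scores, weighted by the share of interaction
variance each axis explains.  Zero interaction means WAASB = 0,
maximally stable.

WAASBY blends rescaled mean performance (weight theta_Y, default 70) and
rescaled stability (theta_S, default 30) into one 0-100 score per trait.
Before any of that, trait values are pushed through an ideotype
transformation that folds deviations from the target value I so the most
desirable value becomes an extreme (largest when I sits in the upper half
of the observed range, smallest otherwise).

MTSI is the Euclidean distance between a genotype and the ideotype (the
all-100 WAASBY row) in the space of retained factor scores of the WAASBY
matrix; genotypes are ranked ascending and the best round(SI * n) are
selected (SI = 15% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MegaenvError, ParameterError
from .traits import DEFAULT_IDEOTYPE

#: The three analysis presets: which traits, restricted to which
#: mega-environment group (None = all environments).
STUDY_PRESETS: dict[str, dict] = {
    "SE": {"traits": ("NOB", "HFP", "PPN", "SPP"), "mega_env": "SE"},
    "NE": {"traits": ("NOB", "HFP", "PPN", "SPP"), "mega_env": "NE"},
    "single": {"traits": ("PH", "PPF", "PL"), "mega_env": None},
}


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def ideotype_transform(x: pd.Series, ideal: float, xmin: float | None = None,
                       xmax: float | None = None) -> pd.Series:
    """Fold trait values around the ideotype target I.

    Y = I + |X - I| when I lies below the range midpoint (desired value
    becomes the smallest), Y = I - |X - I| otherwise (desired value
    becomes the largest).  All transformed values must stay positive —
    downstream rescaling assumes it — so a non-positive Y is an error
    naming the offending genotypes rather than a silent clamp.
    """
    x = pd.Series(x, dtype=float)
    xmin = float(x.min()) if xmin is None else xmin
    xmax = float(x.max()) if xmax is None else xmax
    if not xmax > xmin:
        raise ParameterError("ideotype transform needs xmax > xmin")
    if ideal < (xmin + xmax) / 2.0:
        y = ideal + (x - ideal).abs()
    else:
        y = ideal - (x - ideal).abs()
    if (y <= 0).any():
        bad = sorted(y.index[y <= 0])
        raise MegaenvError(
            f"ideotype transform produced non-positive values for {bad}; "
            "check the target against the trait range")
    return y


def higher_is_better_after_transform(ideal: float, xmin: float,
                                     xmax: float) -> bool:
    """Direction of merit of a transformed trait (see ideotype_transform)."""
    return ideal >= (xmin + xmax) / 2.0


def compute_waasb(gei_blups: pd.DataFrame) -> pd.Series:
    """WAASB_i = sum_k |score_ik| EP_k / sum_k EP_k over all nonzero axes.

    Scores are symmetric-scaled SVD scores (lambda^0.5 u) of the
    genotype-by-environment interaction BLUP matrix; EP_k is the share of
    interaction variance on axis k.  Sign flips of singular vectors leave
    the result unchanged.
    """
    if gei_blups.shape[1] < 2:
        raise ParameterError("need >= 2 environments for WAASB")
    M = gei_blups.to_numpy(float)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    total = float((s**2).sum())
    if total == 0:
        warnings.warn("interaction BLUP matrix is all zero; WAASB degenerate "
                      "(all genotypes maximally stable)", stacklevel=2)
        return pd.Series(0.0, index=gei_blups.index, name="WAASB")
    keep = s > 0
    scores = np.abs(U[:, keep] * np.sqrt(s[keep]))
    ep = s[keep] ** 2 / total
    waasb = scores @ ep / ep.sum()
    return pd.Series(waasb, index=gei_blups.index, name="WAASB")


def rescale(values: pd.Series, higher_is_better: bool) -> pd.Series:
    """Linear 0-100 rescaling; the most desirable value maps to 100.

    r_i = (a - b)/(Omax - Omin) * (O_i - Omax) + a with (a, b) = (100, 0)
    when higher values are desirable and (0, 100) otherwise.
    """
    values = pd.Series(values, dtype=float)
    omin, omax = float(values.min()), float(values.max())
    if not omax > omin:
        raise ParameterError("rescale undefined for a constant column")
    a, b = (100.0, 0.0) if higher_is_better else (0.0, 100.0)
    return (a - b) / (omax - omin) * (values - omax) + a


def waasby(r_y, r_w, theta_y: float = 70.0, theta_s: float = 30.0):
    """Weighted blend of rescaled performance and rescaled stability."""
    if theta_y < 0 or theta_s < 0:
        raise ParameterError("weights must be >= 0")
    if theta_y + theta_s == 0:
        raise ParameterError("weights must not both be zero")
    return (r_y * theta_y + r_w * theta_s) / (theta_y + theta_s)


# ---------------------------------------------------------------------------
# factor analysis of the WAASBY matrix
# ---------------------------------------------------------------------------

def _varimax(loadings: np.ndarray, tol: float = 1e-10,
             max_iter: int = 500) -> np.ndarray:
    """Varimax rotation (normalized) of a loading matrix."""
    p, k = loadings.shape
    if k < 2:
        return loadings.copy()
    R = np.eye(k)
    var_old = 0.0
    L = loadings
    for _ in range(max_iter):
        LR = L @ R
        U, s, Vt = np.linalg.svd(
            L.T @ (LR**3 - LR @ np.diag(np.sum(LR**2, axis=0)) / p))
        R = U @ Vt
        var_new = s.sum()
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    return L @ R


@dataclass
class FactorModel:
    """Factor analysis of the WAASBY matrix (principal-component
    extraction from the trait correlation matrix, varimax rotation,
    regression-method scores)."""

    loadings: pd.DataFrame        # traits x factors (rotated)
    eigenvalues: np.ndarray
    n_factors: int
    scores: pd.DataFrame          # genotypes x factors
    ideotype_scores: pd.Series
    communalities: pd.Series
    column_means: pd.Series
    column_sds: pd.Series


def factor_model(waasby_matrix: pd.DataFrame) -> FactorModel:
    """Extract factors from the correlation matrix of the WAASBY matrix.

    Factors with eigenvalue >= 1 are retained (always at least one),
    loadings are varimax-rotated, and genotype scores are computed by the
    regression method F = Z R^-1 A.  The ideotype is the all-100 WAASBY
    row standardized and scored through the same pipeline.
    """
    W = waasby_matrix
    if W.shape[1] < 2:
        raise ParameterError("factor analysis needs >= 2 traits")
    if W.shape[0] < W.shape[1] + 1:
        raise ParameterError("factor analysis needs more genotypes "
                             "than traits")
    means = W.mean(axis=0)
    sds = W.std(axis=0, ddof=1)
    if (sds == 0).any():
        raise ParameterError(
            "constant WAASBY column(s): " + repr(sorted(W.columns[sds == 0]))
            + "; prune these traits")
    Z = (W - means) / sds
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    cond = np.linalg.cond(R)
    if cond > 1e10:
        raise ParameterError(
            "singular trait correlation matrix (condition number "
            f"{cond:.2g}); prune collinear traits")
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    nf = max(int(np.sum(eigval >= 1.0 - 1e-8)), 1)
    A = eigvec[:, :nf] * np.sqrt(eigval[:nf])
    A = _varimax(A)
    # orient each factor so its largest-magnitude loading is positive
    for k in range(nf):
        j = int(np.argmax(np.abs(A[:, k])))
        if A[j, k] < 0:
            A[:, k] *= -1.0
    Rinv = np.linalg.inv(R)
    F = Z.to_numpy() @ Rinv @ A
    z_ideal = ((100.0 - means) / sds).to_numpy()
    f_ideal = z_ideal @ Rinv @ A
    cols = [f"FA{k + 1}" for k in range(nf)]
    return FactorModel(
        loadings=pd.DataFrame(A, index=W.columns, columns=cols),
        eigenvalues=eigval,
        n_factors=nf,
        scores=pd.DataFrame(F, index=W.index, columns=cols),
        ideotype_scores=pd.Series(f_ideal, index=cols),
        communalities=pd.Series((A**2).sum(axis=1), index=W.columns),
        column_means=means,
        column_sds=sds,
    )


# ---------------------------------------------------------------------------
# ranking and selection
# ---------------------------------------------------------------------------

def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class MTSIRanking:
    mtsi: pd.Series               # ascending is better
    ranking: pd.Series            # genotype ids, best first
    selected: list[str]
    selection_intensity: float
    factors: FactorModel | None = None
    waasby_matrix: pd.DataFrame | None = None


def mtsi_rank(scores: pd.DataFrame, ideotype_scores: pd.Series,
              selection_intensity: float = 15.0,
              factors: FactorModel | None = None,
              waasby_matrix: pd.DataFrame | None = None) -> MTSIRanking:
    """Rank genotypes by distance to the ideotype in factor-score space.

    MTSI_i = sqrt(sum_j (F_ij - F_j)^2); the best round(SI * n / 100)
    genotypes (half-up rounding) are selected.
    """
    if not 0 < selection_intensity <= 100:
        raise ParameterError("selection intensity must be in (0, 100]")
    diffs = scores - ideotype_scores
    mtsi = pd.Series(np.sqrt((diffs**2).sum(axis=1)), index=scores.index,
                     name="MTSI")
    ranking = mtsi.sort_values(kind="stable")
    n_sel = round_half_up(selection_intensity / 100.0 * len(mtsi))
    return MTSIRanking(mtsi, ranking, list(ranking.index[:n_sel]),
                       selection_intensity, factors, waasby_matrix)


def selection_count(n: int, selection_intensity: float = 15.0) -> int:
    """Number of genotypes selected at the given intensity (half-up)."""
    if not 0 < selection_intensity <= 100:
        raise ParameterError("selection intensity must be in (0, 100]")
    return round_half_up(selection_intensity / 100.0 * n)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def run_mtsi_pipeline(dataset, traits, ideotype: dict[str, float]
                      | None = None, mega_env: str | None = None,
                      mega_env_map: dict[str, str] | None = None,
                      theta_y: float = 70.0, theta_s: float = 30.0,
                      selection_intensity: float = 15.0) -> MTSIRanking:
    """Ideotype transform -> per-trait WAASB + performance -> rescale ->
    WAASBY -> factor analysis -> MTSI ranking.

    When ``mega_env`` names a group in ``mega_env_map``, the dataset is
    restricted to that group's trials and every stage (including the
    interaction SVD behind WAASB) is refitted on the subset.
    """
    from .mixed_models import extract_blups, fit_multitrial_lmm

    ideotype = dict(DEFAULT_IDEOTYPE if ideotype is None else ideotype)
    missing = [t for t in traits if t not in ideotype]
    if missing:
        raise ParameterError(f"no ideotype target for traits {missing}")
    if mega_env is not None:
        if mega_env_map is None:
            raise ParameterError("mega_env given without a mega_env_map")
        trials = [t for t, g in mega_env_map.items() if g == mega_env]
        if not trials:
            raise ParameterError(f"no trials in mega-environment {mega_env!r}")
        dataset = dataset.subset_trials(trials)

    r_y_cols, r_w_cols = {}, {}
    for trait in traits:
        obs = dataset.frame[trait].dropna()
        xmin, xmax = float(obs.min()), float(obs.max())
        transformed = dataset.frame.copy()
        transformed[trait] = ideotype_transform(
            dataset.frame[trait], ideotype[trait], xmin, xmax)
        sub = type(dataset)(transformed, dataset.registry)
        fit = fit_multitrial_lmm(sub, trait, check_connected=False)
        bl = extract_blups(fit)
        performance = bl.grand_mean + bl.genotype_blups
        hib = higher_is_better_after_transform(ideotype[trait], xmin, xmax)
        r_y_cols[trait] = rescale(performance, hib)
        w = compute_waasb(bl.gei_blups)
        if float(w.max() - w.min()) == 0.0:
            # no interaction at all: every genotype is maximally stable
            r_w_cols[trait] = pd.Series(100.0, index=w.index)
        else:
            r_w_cols[trait] = rescale(w, higher_is_better=False)
    r_y = pd.DataFrame(r_y_cols)
    r_w = pd.DataFrame(r_w_cols)
    W = waasby(r_y, r_w, theta_y, theta_s)
    fm = factor_model(W)
    return mtsi_rank(fm.scores, fm.ideotype_scores, selection_intensity,
                     factors=fm, waasby_matrix=W)
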