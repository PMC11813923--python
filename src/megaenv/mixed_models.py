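"""Multi-trial mixed models: variance components, BLUPs, heritability.

Per trait the multi-trial model is

    y = trial (fixed) + genotype + genotype:trial + row(trial) + col(trial) + e

with all non-trial terms random, fitted by REML.  Generalized (Cullis)
heritability is H2 = 1 - vblup / (2 var_g), where vblup is the mean
prediction-error variance of a difference between two genotype BLUPs —
the right reliability notion when genotypes are unequally replicated, as
in augmented p-rep series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import METDataset
from .design import connectivity_from_dataset
from .errors import MegaenvError, ParameterError
from .reml import REMLResult, _design_matrix, reml_fit

COMPONENT_ORDER = ("genotype", "genotype:trial", "row", "col", "residual")


@dataclass(frozen=True)
class VarianceComponents:
    """REML variance components for one trait, with percentage shares.

    ``sigma2_rc`` pools the row and column components, matching how
    row/column variance is usually reported for p-rep series.
    """

    trait: str
    sigma2_g: float
    sigma2_ge: float
    sigma2_rc: float
    sigma2_e: float

    @property
    def total(self) -> float:
        return self.sigma2_g + self.sigma2_ge + self.sigma2_rc + self.sigma2_e

    def percentages(self) -> dict[str, float]:
        return variance_percentages(
            (self.sigma2_g, self.sigma2_ge, self.sigma2_rc, self.sigma2_e))

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages()
        return pd.DataFrame({
            "component": ["genotypic", "genotype_x_environment",
                          "row_and_column", "residual"],
            "variance": [self.sigma2_g, self.sigma2_ge, self.sigma2_rc,
                         self.sigma2_e],
            "percent": [pct["genotypic"], pct["genotype_x_environment"],
                        pct["row_and_column"], pct["residual"]],
        })


def variance_percentages(components) -> dict[str, float]:
    """Each component as a percentage of the total variance."""
    comps = [float(c) for c in components]
    total = sum(comps)
    if total <= 0:
        raise ParameterError("percentages undefined: total variance is 0")
    names = ["genotypic", "genotype_x_environment", "row_and_column",
             "residual"]
    return {n: 100.0 * c / total for n, c in zip(names, comps)}


@dataclass
class BlupSet:
    """Genotype and genotype-by-environment BLUPs for one trait."""

    trait: str
    genotype_blups: pd.Series
    gei_blups: pd.DataFrame     # genotypes x trials; 0 for unobserved cells
    vblup: float
    grand_mean: float
    trial_means: pd.Series      # fitted fixed trial means

    def standardized(self) -> pd.Series:
        """z-scored genotype BLUPs (mean 0, sd 1) for clustering/PCA."""
        sd = self.genotype_blups.std(ddof=1)
        if sd == 0:
            return self.genotype_blups * 0.0
        return (self.genotype_blups - self.genotype_blups.mean()) / sd

    def predicted_values(self) -> pd.DataFrame:
        """Model-based genotype x trial predictions mu_j + G_i + GE_ij."""
        pred = self.gei_blups.add(self.genotype_blups, axis=0)
        return pred.add(self.trial_means, axis=1)


@dataclass(frozen=True)
class HeritabilityResult:
    trait: str
    h2: float
    clamped: bool
    vblup: float
    var_g: float


class MultiTrialFit:
    """Handle to a fitted multi-trial model for one trait."""

    def __init__(self, trait: str, result: REMLResult, genotypes: list,
                 trials: list, ge_levels: list, trial_means: pd.Series):
        self.trait = trait
        self.result = result
        self.genotypes = genotypes
        self.trials = trials
        self._ge_levels = ge_levels
        self._trial_means = trial_means

    @property
    def converged(self) -> bool:
        return self.result.converged

    def variance_components(self) -> VarianceComponents:
        c = self.result.components
        return VarianceComponents(
            self.trait, c["genotype"], c["genotype:trial"],
            c.get("row", 0.0) + c.get("col", 0.0), c["residual"])

    def blups(self) -> BlupSet:
        res = self.result
        g = pd.Series(res.blup("genotype"), index=self.genotypes,
                      name=self.trait)
        ge = pd.DataFrame(0.0, index=pd.Index(self.genotypes),
                          columns=self.trials)
        for (geno, trial), val in zip(self._ge_levels,
                                      res.blup("genotype:trial")):
            ge.loc[geno, trial] = val
        if res.components["genotype"] == 0.0:
            g[:] = 0.0
            vblup = 0.0
        else:
            vblup = mean_pairwise_difference_variance(res.pev("genotype"))
        grand = float(self._trial_means.mean())
        return BlupSet(self.trait, g, ge, vblup, grand, self._trial_means)

    def heritability(self) -> HeritabilityResult:
        vc = self.variance_components()
        bl = self.blups()
        return generalized_heritability(bl.vblup, vc.sigma2_g, self.trait)


def mean_pairwise_difference_variance(pev: np.ndarray) -> float:
    """Exact mean over all genotype pairs of Var(BLUP_i - BLUP_j)."""
    g = pev.shape[0]
    if g < 2:
        raise ParameterError("need >= 2 genotypes for vblup")
    d = np.diag(pev)
    # sum over ordered pairs of d_i + d_j - 2 pev_ij, then halve for pairs
    total = 2.0 * (g * d.sum() - pev.sum())
    return float(total / (g * (g - 1)))


def _multi_trial_design(frame: pd.DataFrame, trait: str):
    obs = frame.dropna(subset=[trait])
    y = obs[trait].to_numpy(float)
    trials = sorted(obs["trial_id"].unique())
    X = np.ones((len(obs), len(trials)))
    for j, t in enumerate(trials[1:], start=1):
        X[:, j] = (obs["trial_id"] == t).to_numpy(float)
    names = ["(intercept)"] + [f"trial[{t}]" for t in trials[1:]]
    Zg, genotypes = _design_matrix(obs["genotype_id"])
    Zge, ge_levels = _design_matrix(
        list(zip(obs["genotype_id"], obs["trial_id"])))
    Zr, _ = _design_matrix(list(zip(obs["trial_id"], obs["row"])))
    Zc, _ = _design_matrix(list(zip(obs["trial_id"], obs["col"])))
    re = {"genotype": Zg, "genotype:trial": Zge, "row": Zr, "col": Zc}
    return obs, y, X, names, re, genotypes, trials, ge_levels


def fit_multitrial_lmm(dataset: METDataset, trait: str,
                       check_connected: bool = True) -> MultiTrialFit:
    """Fit the per-trait multi-trial model by REML.

    Requires the trait observed in at least two trials; a disconnected
    trial graph triggers a warning because cross-trial genotype contrasts
    are then not identifiable.
    """
    if trait not in dataset.frame.columns:
        raise ParameterError(f"trait {trait!r} not in dataset")
    frame = dataset.frame
    n_trials = frame.dropna(subset=[trait])["trial_id"].nunique()
    if n_trials < 2:
        raise ParameterError(
            f"trait {trait!r} observed in {n_trials} trial(s); need >= 2")
    if check_connected:
        report = connectivity_from_dataset(dataset)
        if not report.connected:
            warnings.warn(
                "trial graph is not connected; variance components and "
                "cross-trial BLUP contrasts may be non-identifiable",
                stacklevel=2)
    obs, y, X, names, re, genotypes, trials, ge_levels = \
        _multi_trial_design(frame, trait)
    result = reml_fit(y, X, re, fixed_names=names)
    beta = pd.Series(result.beta, index=result.fixed_names)
    mu = beta["(intercept)"]
    trial_means = pd.Series(
        {t: mu + (beta.get(f"trial[{t}]", 0.0)) for t in trials},
        name=trait)
    return MultiTrialFit(trait, result, genotypes, trials, ge_levels,
                         trial_means)


def extract_blups(fit: MultiTrialFit) -> BlupSet:
    """BLUPs and vblup from a converged multi-trial fit."""
    if not fit.converged:
        raise MegaenvError("model did not converge; refusing to extract BLUPs")
    return fit.blups()


def generalized_heritability(vblup: float, var_g: float,
                             trait: str = "") -> HeritabilityResult:
    """Cullis generalized heritability H2 = 1 - vblup / (2 var_g).

    Clamped into [0, 1]; the ``clamped`` flag records when that happened.
    """
    if var_g <= 0:
        raise ParameterError("heritability undefined for var_g <= 0")
    if vblup < 0:
        raise ParameterError("vblup must be >= 0")
    raw = 1.0 - vblup / (2.0 * var_g)
    h2 = min(max(raw, 0.0), 1.0)
    return HeritabilityResult(trait, h2, clamped=(h2 != raw), vblup=vblup,
                              var_g=var_g)


def per_environment_heritability(dataset: METDataset,
                                 trait: str) -> dict[str, HeritabilityResult]:
    """Single-trial H2 per environment (genotype, row, col random)."""
    out = {}
    for trial in dataset.trials:
        sub = dataset.frame[dataset.frame["trial_id"] == trial]
        obs = sub.dropna(subset=[trait])
        if obs.empty:
            continue
        counts = obs["genotype_id"].value_counts()
        if (counts < 2).all():
            raise MegaenvError(
                f"trial {trial}: no genotype is replicated; residual "
                "variance is not separable from genotypic variance")
        y = obs[trait].to_numpy(float)
        X = np.ones((len(obs), 1))
        Zg, _ = _design_matrix(obs["genotype_id"])
        Zr, _ = _design_matrix(obs["row"])
        Zc, _ = _design_matrix(obs["col"])
        result = reml_fit(y, X, {"genotype": Zg, "row": Zr, "col": Zc},
                          fixed_names=["(intercept)"])
        var_g = result.components["genotype"]
        if var_g == 0.0:
            out[trial] = HeritabilityResult(trait, 0.0, clamped=False,
                                            vblup=0.0, var_g=0.0)
            continue
        vblup = mean_pairwise_difference_variance(result.pev("genotype"))
        out[trial] = generalized_heritability(vblup, var_g, trait)
    return out


@dataclass
class BotanicalFit:
    """Fixed botanical-type effects versus the paucijuga reference."""

    trait: str
    table: pd.DataFrame   # term, estimate, se, df, t, p, stars
    unstable_types: list[str]
    result: REMLResult

    @property
    def intercept(self) -> float:
        return float(self.table.loc[self.table["term"] == "(intercept)",
                                    "estimate"].iloc[0])

    def shift(self, btype: str) -> float:
        return float(self.table.loc[self.table["term"] == btype,
                                    "estimate"].iloc[0])


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def fit_botanical_model(dataset: METDataset, trait: str,
                        botanical_assignment: dict[str, str]) -> BotanicalFit:
    """Botanical type as fixed effect; environment and genotype random.

    Genotypes of unknown type are excluded; the intercept is the
    paucijuga reference level.  Types with fewer than two genotypes are
    flagged unstable with a warning.
    """
    frame = dataset.frame.dropna(subset=[trait]).copy()
    frame["btype"] = frame["genotype_id"].map(
        lambda g: botanical_assignment.get(g, "unknown"))
    frame = frame[frame["btype"].isin(
        ["paucijuga", "minor", "equina", "major"])]
    types_present = sorted(frame["btype"].unique())
    if len(types_present) < 2:
        raise ParameterError(
            "need >= 2 botanical types; only found " + repr(types_present))
    order = [t for t in ["paucijuga", "minor", "equina", "major"]
             if t in types_present]
    geno_per_type = frame.groupby("btype")["genotype_id"].nunique()
    unstable = sorted(geno_per_type.index[geno_per_type < 2])
    if unstable:
        warnings.warn(f"botanical types with < 2 genotypes (estimates "
                      f"unstable): {unstable}", stacklevel=2)
    y = frame[trait].to_numpy(float)
    X = np.ones((len(frame), len(order)))
    for j, t in enumerate(order[1:], start=1):
        X[:, j] = (frame["btype"] == t).to_numpy(float)
    names = ["(intercept)"] + order[1:]
    Zg, _ = _design_matrix(frame["genotype_id"])
    Ze, _ = _design_matrix(frame["trial_id"])
    result = reml_fit(y, X, {"genotype": Zg, "environment": Ze},
                      fixed_names=names)
    table = result.fixed_effects()
    table["stars"] = [_stars(p) for p in table["p"]]
    return BotanicalFit(trait, table, unstable, result)
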