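"""Synthetic multi-environment trial generator.

Simulates plot-level phenotypes with the structure the downstream mixed
model assumes: for trait *t* on the plot of genotype *i* in trial *j* at
grid position (row, col),

    y = mu_j + G_i + GE_ij + r_row + c_col + eps

with G_i ~ N(0, var_g) plus an additive botanical-type shift, row and
column effects each N(0, var_rc / 2), and residual eps ~ N(0, var_e).
Trial means are mu_j = mu + E_j with E_j ~ N(0, env_sd^2).

The interaction term carries a planted mega-environment structure.  Trials
belong to groups (e.g. a southern and a northern mega-environment); every
genotype draws one loading per group, and

    GE_ij = var_ge^(1/2) * (c * lam[i, group(j)] + eta_ij) / sqrt(c^2 + 1)

where c is ``crossover_strength`` and eta is unstructured N(0, 1) noise.
Var(GE) = var_ge for every c; as c grows, genotype rankings become
consistent within a group and cross over between groups, which is exactly
the pattern the which-won-where analysis is designed to detect.

Defaults reproduce the study conditions of the EUCLEG faba bean
collection: 220 genotypes in nine trials at four locations (Table-2-style
p-rep layouts with 15 duplicated checks and 5 six-fold standards per
trial), per-trait variance components from the multi-trial REML analysis,
and botanical-type shifts applied to genotypes assigned a type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import METDataset
from .design import TrialDesign, TrialSpec, build_augmented_prep_layout
from .errors import ParameterError
from .traits import (BOTANICAL_FREQUENCIES, BOTANICAL_SHIFTS,
                     DEFAULT_GRAND_MEANS, DEFAULT_VARIANCES, TRAIT_CODES,
                     TRAITS, TraitRegistry)


@dataclass(frozen=True)
class TraitParams:
    """Per-trait simulation parameters (units of the trait, variances squared)."""

    mu: float
    var_g: float
    var_ge: float
    var_rc: float
    var_e: float
    env_sd: float = 0.0  # sd of the trial main effect around mu

    def __post_init__(self) -> None:
        for name in ("var_g", "var_ge", "var_rc", "var_e"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.env_sd < 0:
            raise ParameterError("env_sd must be >= 0")


@dataclass
class SimulationParams:
    """Everything the generator needs; same params + seed => same dataset."""

    n_genotypes: int
    trial_specs: list[TrialSpec]
    trait_params: dict[str, TraitParams]
    trial_meta: dict[str, tuple[str, int]]  # trial_id -> (location, year)
    mega_env_map: dict[str, str]            # trial_id -> group label
    crossover_strength: float = 0.0
    botanical_effects: dict[str, dict[str, float]] | None = None
    botanical_assignment: dict[str, str] | None = None
    drop_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crossover_strength < 0:
            raise ParameterError("crossover_strength must be >= 0")
        if not 0 <= self.drop_rate < 1:
            raise ParameterError("drop_rate must be in [0, 1)")
        for spec in self.trial_specs:
            if spec.trial_id not in self.mega_env_map:
                raise ParameterError(
                    f"trial {spec.trial_id} has no mega-environment group")


def genotype_names(n: int) -> list[str]:
    return [f"G{i + 1:03d}" for i in range(n)]


def default_botanical_assignment(genotypes, seed: int = 0) -> dict[str, str]:
    """Assign botanical types at the whole-collection frequencies."""
    rng = np.random.default_rng(seed)
    types = list(BOTANICAL_FREQUENCIES)
    probs = np.array(list(BOTANICAL_FREQUENCIES.values()))
    draws = rng.choice(len(types), size=len(genotypes), p=probs / probs.sum())
    return {g: types[k] for g, k in zip(genotypes, draws)}

# Table-2-style trial structure: singles per trial at each location-year.
_STUDY_TRIALS = [
    ("AG18", "AG", 2018, 80), ("AG19", "AG", 2019, 80),
    ("IFC18", "IFC", 2018, 79), ("IFC19", "IFC", 2019, 79),
    ("IFC20", "IFC", 2020, 79), ("BO18", "BO", 2018, 80),
    ("BO19", "BO", 2019, 78), ("GU18", "GU", 2018, 80),
    ("GU19", "GU", 2019, 77),
]

#: Southern (Spain + Serbia) vs northern (Finland + Belgium) groups.
STUDY_MEGA_ENV_MAP = {"AG18": "SE", "AG19": "SE", "IFC18": "SE",
                      "IFC19": "SE", "IFC20": "SE", "BO18": "NE",
                      "BO19": "NE", "GU18": "NE", "GU19": "NE"}


def study_trial_specs(seed: int = 0) -> list[TrialSpec]:
    """Nine 14x10 p-rep trials with the study's per-trial entry counts.

    Trials with fewer than 80 unreplicated entries mask the corresponding
    number of grid cells (the physical arrangement of the reduced trials is
    not documented; masking is this package's convention).
    """
    specs = []
    for k, (tid, _, _, n_single) in enumerate(_STUDY_TRIALS):
        specs.append(TrialSpec(tid, n_single=n_single, n_dup_checks=15,
                               n_standards=5, grid_rows=14, grid_cols=10,
                               seed=seed * 1009 + k, n_masked=80 - n_single))
    return specs


def default_simulation_params(n_genotypes: int = 220, seed: int = 0,
                              crossover_strength: float = 1.0,
                              botanical: bool = True) -> SimulationParams:
    """The study conditions: 220 genotypes, nine Table-2-style trials,
    per-trait variance components from the multi-trial REML analysis, and a
    moderate planted crossover between the southern and northern groups.

    Trial main-effect sd defaults to twice the interaction sd: locations
    and years move trait means far more than any genotype does (sowing
    season alone shifts phenology by months).
    """
    trait_params = {}
    for code in TRAIT_CODES:
        vg, vge, vrc, ve = DEFAULT_VARIANCES[code]
        trait_params[code] = TraitParams(
            mu=DEFAULT_GRAND_MEANS[code], var_g=vg, var_ge=vge,
            var_rc=vrc, var_e=ve, env_sd=2.0 * np.sqrt(vge))
    genos = genotype_names(n_genotypes)
    return SimulationParams(
        n_genotypes=n_genotypes,
        trial_specs=study_trial_specs(seed),
        trait_params=trait_params,
        trial_meta={tid: (loc, yr) for tid, loc, yr, _ in _STUDY_TRIALS},
        mega_env_map=dict(STUDY_MEGA_ENV_MAP),
        crossover_strength=crossover_strength,
        botanical_effects=BOTANICAL_SHIFTS if botanical else None,
        botanical_assignment=(default_botanical_assignment(genos, seed)
                              if botanical else None),
        seed=seed,
    )


def recovery_study_params(seed: int, n_genotypes: int = 150,
                          trait: str = "DTF") -> SimulationParams:
    """Conditions of the REML parameter-recovery study: nine 7x10 p-rep
    trials (44 singles, 10 duplicated checks, 1 six-fold standard each)
    of 150 genotypes, simulated at the multi-trial variance components of
    the named trait, no botanical shifts, no crossover."""
    vg, vge, vrc, ve = DEFAULT_VARIANCES[trait]
    tp = {trait: TraitParams(DEFAULT_GRAND_MEANS[trait], vg, vge, vrc, ve,
                             env_sd=np.sqrt(vge))}
    locations = ["L1", "L1", "L1", "L2", "L2", "L3", "L3", "L4", "L4"]
    years = [2018, 2019, 2020, 2018, 2019, 2018, 2019, 2018, 2019]
    specs = [TrialSpec(f"T{k + 1}", n_single=44, n_dup_checks=10,
                       n_standards=1, grid_rows=7, grid_cols=10,
                       seed=seed * 977 + k) for k in range(9)]
    return SimulationParams(
        n_genotypes=n_genotypes, trial_specs=specs, trait_params=tp,
        trial_meta={s.trial_id: (locations[k], years[k])
                    for k, s in enumerate(specs)},
        mega_env_map={s.trial_id: "all" for s in specs},
        seed=seed)


def crossover_study_params(seed: int, n_genotypes: int = 40
                           ) -> SimulationParams:
    """Conditions of the mega-environment recovery study: a
    crossover-dominated MET of 40 genotypes in eight environments (four
    locations x two years, two planted groups of two locations), every
    genotype replicated six-fold per trial.  The interaction variance
    dwarfs the genotypic variance and ``crossover_strength`` = 50 makes
    the interaction almost purely the planted group structure, so the
    partition detected by which-won-where should match the partition
    implied by the planted group winners in nearly every run."""
    envs = [("E1", "N", 2018), ("E2", "N", 2019), ("E3", "S", 2018),
            ("E4", "S", 2019), ("E5", "W", 2018), ("E6", "W", 2019),
            ("E7", "K", 2018), ("E8", "K", 2019)]
    group = {"N": "A", "S": "A", "W": "B", "K": "B"}
    specs = [TrialSpec(t, n_single=0, n_dup_checks=0,
                       n_standards=n_genotypes, grid_rows=n_genotypes,
                       grid_cols=6, seed=seed * 31 + i)
             for i, (t, _, _) in enumerate(envs)]
    return SimulationParams(
        n_genotypes=n_genotypes, trial_specs=specs,
        trait_params={"DTF": TraitParams(80.0, 2.0, 100.0, 0.1, 0.5,
                                         env_sd=3.0)},
        trial_meta={t: (loc, yr) for t, loc, yr in envs},
        mega_env_map={t: group[loc] for t, loc, _ in envs},
        crossover_strength=50.0, seed=seed)


def crossover_study_designs(params: SimulationParams) -> list[TrialDesign]:
    """Layouts for the recovery study (every genotype a six-fold entry)."""
    genos = genotype_names(params.n_genotypes)
    return [build_augmented_prep_layout(s, [], [], genos)
            for s in params.trial_specs]


def planted_partition(effects: "SimulatedEffects", trait: str,
                      params: SimulationParams) -> frozenset[frozenset[str]]:
    """Location partition implied by the planted group winners.

    Groups whose structured winner coincides merge: a shared winner means
    the planted truth is a single mega-environment for those locations.
    """
    winners = effects.planted_group_winner(trait)
    by_winner: dict[str, set[str]] = {}
    for trial, grp in params.mega_env_map.items():
        loc = params.trial_meta[trial][0]
        by_winner.setdefault(winners[grp], set()).add(loc)
    return frozenset(frozenset(v) for v in by_winner.values())


def allocate_designs(params: SimulationParams) -> list[TrialDesign]:
    """Allocate genotypes to trials and randomize each layout.

    Checks and standards are a fixed pool common to every trial (that is
    what connects the series); unreplicated entries rotate through the
    remaining genotypes in contiguous circular slices of one seeded
    permutation, so every genotype is tested in several trials.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 101]))
    genos = genotype_names(params.n_genotypes)
    n_checks = max(s.n_dup_checks for s in params.trial_specs)
    n_std = max(s.n_standards for s in params.trial_specs)
    if n_checks + n_std >= params.n_genotypes:
        raise ParameterError("not enough genotypes for checks and standards")
    check_ids = genos[:n_checks]
    standard_ids = genos[n_checks:n_checks + n_std]
    entries = genos[n_checks + n_std:]
    pool = list(rng.permutation(entries))
    designs, ptr = [], 0
    for spec in params.trial_specs:
        if spec.n_single > len(pool):
            raise ParameterError(
                f"trial {spec.trial_id} needs {spec.n_single} entries but "
                f"only {len(pool)} genotypes are available")
        take = [pool[(ptr + i) % len(pool)] for i in range(spec.n_single)]
        ptr = (ptr + spec.n_single) % len(pool)
        designs.append(build_augmented_prep_layout(
            spec, take, check_ids[:spec.n_dup_checks],
            standard_ids[:spec.n_standards]))
    return designs


@dataclass
class SimulatedEffects:
    """The effects actually drawn, for calibration checks."""

    trial_means: dict[str, dict[str, float]]        # trait -> trial -> mu_j
    genotype: dict[str, pd.Series]                  # trait -> G_i (shift incl.)
    genotype_raw: dict[str, pd.Series]              # trait -> G_i (no shift)
    interaction: dict[str, pd.DataFrame]            # trait -> geno x trial
    #: structured crossover loadings, trait -> genotypes x groups, already
    #: scaled by sqrt(var_ge) * c / sqrt(c^2 + 1); the planted group-level
    #: winner of group m is argmax over i of genotype + loading[:, m]
    structured: dict[str, pd.DataFrame] = None

    def planted_group_winner(self, trait: str) -> dict[str, str]:
        """Winning genotype per mega-environment group implied by the
        structured (noise-free) part of the simulation."""
        tab = self.structured[trait].add(self.genotype[trait], axis=0)
        return {m: tab[m].idxmax() for m in tab.columns}


def simulate_met(params: SimulationParams, designs: list[TrialDesign]
                 | None = None, return_effects: bool = False):
    """Draw a phenotype dataset; same (params, seed) => identical output."""
    designs = designs if designs is not None else allocate_designs(params)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 202]))
    genos = genotype_names(params.n_genotypes)
    trials = [d.spec.trial_id for d in designs]
    groups = sorted(set(params.mega_env_map.values()))
    g_index = pd.Index(genos, name="genotype_id")

    base_rows = []
    for d in designs:
        loc, yr = params.trial_meta[d.spec.trial_id]
        for (r, c), (g, k) in sorted(d.assignment.items()):
            base_rows.append((d.spec.trial_id, loc, yr, r, c, g, k))
    frame = pd.DataFrame(base_rows, columns=["trial_id", "location", "year",
                                             "row", "col", "genotype_id",
                                             "rep_class"])

    effects = SimulatedEffects({}, {}, {}, {}, {})
    cs = params.crossover_strength
    scale = np.sqrt(cs * cs + 1.0)
    for code, tp in params.trait_params.items():
        mu_j = {t: tp.mu + tp.env_sd * rng.standard_normal() for t in trials}
        g_raw = pd.Series(np.sqrt(tp.var_g) * rng.standard_normal(len(genos)),
                          index=g_index)
        g_eff = g_raw.copy()
        if params.botanical_effects and params.botanical_assignment:
            for g in genos:
                btype = params.botanical_assignment.get(g, "unknown")
                shift = params.botanical_effects.get(btype, {})
                g_eff[g] += shift.get(code, 0.0)
        lam = {m: rng.standard_normal(len(genos)) for m in groups}
        coef = np.sqrt(tp.var_ge) * cs / scale
        effects.structured[code] = pd.DataFrame(
            {m: coef * lam[m] for m in groups}, index=g_index)
        ge = np.empty((len(genos), len(trials)))
        for j, t in enumerate(trials):
            eta = rng.standard_normal(len(genos))
            struct = lam[params.mega_env_map[t]]
            ge[:, j] = np.sqrt(tp.var_ge) * (cs * struct + eta) / scale
        ge_df = pd.DataFrame(ge, index=g_index, columns=trials)

        values = np.empty(len(frame))
        for d in designs:
            t = d.spec.trial_id
            mask = frame["trial_id"] == t
            sub = frame[mask]
            r_eff = {r: np.sqrt(tp.var_rc / 2) * rng.standard_normal()
                     for r in range(1, d.spec.grid_rows + 1)}
            c_eff = {c: np.sqrt(tp.var_rc / 2) * rng.standard_normal()
                     for c in range(1, d.spec.grid_cols + 1)}
            eps = np.sqrt(tp.var_e) * rng.standard_normal(len(sub))
            vals = (mu_j[t]
                    + g_eff.loc[sub["genotype_id"]].to_numpy()
                    + ge_df.loc[sub["genotype_id"], t].to_numpy()
                    + np.array([r_eff[r] for r in sub["row"]])
                    + np.array([c_eff[c] for c in sub["col"]])
                    + eps)
            values[np.flatnonzero(mask.to_numpy())] = vals
        # truncate to the biologically admissible range (heights, counts
        # and ratios cannot go negative; strictly-positive traits get a
        # small positive floor so downstream log/fold transforms stay
        # defined, as they are for real field measurements)
        trait_def = TRAITS.get(code)
        if trait_def is not None:
            lo, hi = trait_def.lower, trait_def.upper
            if lo == 0.0:
                lo = 0.01 * abs(tp.mu) if tp.mu else 0.0
            values = np.clip(values, lo if lo is not None else -np.inf,
                             hi if hi is not None else np.inf)
        frame[code] = values
        effects.trial_means[code] = mu_j
        effects.genotype[code] = g_eff
        effects.genotype_raw[code] = g_raw
        effects.interaction[code] = ge_df

    if params.drop_rate > 0:
        keep = rng.random(len(frame)) >= params.drop_rate
        frame = frame[keep].reset_index(drop=True)

    dataset = METDataset(frame, TraitRegistry())
    return (dataset, effects) if return_effects else dataset
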