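"""Augmented p-rep trial layouts and cross-trial connectivity.

An augmented partially-replicated (p-rep) trial tests mostly unreplicated
entries on a row-by-column grid, with a subset of check genotypes
duplicated and a few standard cultivars replicated six-fold.  The
replicated plots estimate the error variance, allow block (row/column)
adjustment and — because the same checks recur in every trial — connect
otherwise disjoint trials of a multi-environment series.

Grids that hold fewer plots than cells (e.g. a 14x10 field with 137-139
usable plots) are modelled by masking cells: masked cells are drawn with
the layout seed and left unplanted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .errors import LayoutInfeasibleError, ParameterError

REP_PLOTS = {"single": 1, "check": 2, "standard": 6}


@dataclass(frozen=True)
class TrialSpec:
    """Size and composition of one augmented p-rep trial.

    The grid must be exactly filled:
    ``n_single + 2*n_dup_checks + 6*n_standards + n_masked ==
    grid_rows*grid_cols``.
    """

    trial_id: str
    n_single: int
    n_dup_checks: int
    n_standards: int
    grid_rows: int
    grid_cols: int
    seed: int = 0
    n_masked: int = 0

    def __post_init__(self) -> None:
        for name in ("n_single", "n_dup_checks", "n_standards",
                     "grid_rows", "grid_cols", "n_masked"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    @property
    def n_plots(self) -> int:
        return self.n_single + 2 * self.n_dup_checks + 6 * self.n_standards

    @property
    def n_accessions(self) -> int:
        return self.n_single + self.n_dup_checks + self.n_standards

    def check_fill(self) -> None:
        cells = self.grid_rows * self.grid_cols - self.n_masked
        if self.n_plots != cells:
            diff = self.n_plots - cells
            kind = "surplus" if diff > 0 else "deficit"
            raise LayoutInfeasibleError(
                f"trial {self.trial_id}: layout needs {self.n_plots} plots "
                f"but the grid offers {cells} usable cells "
                f"({kind} of {abs(diff)} plots)")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


@dataclass(frozen=True)
class TrialDesign:
    """A realized layout: every usable cell carries one genotype."""

    spec: TrialSpec
    assignment: dict[tuple[int, int], tuple[str, str]]  # (row,col) -> (geno, rep_class)
    masked_cells: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    @property
    def genotypes(self) -> set[str]:
        return {g for g, _ in self.assignment.values()}

    def plot_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for geno, _ in self.assignment.values():
            counts[geno] = counts.get(geno, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [(r, c, g, k)
                for (r, c), (g, k) in sorted(self.assignment.items())]
        return pd.DataFrame(rows, columns=["row", "col", "genotype_id",
                                           "rep_class"])


def build_augmented_prep_layout(spec: TrialSpec, entry_ids, check_ids,
                                standard_ids) -> TrialDesign:
    """Randomize an augmented p-rep layout on the trial grid.

    Entries appear once, checks twice and standards six times; plot
    positions are a uniform random permutation of the usable cells, seeded
    by ``spec.seed`` (the same seed reproduces the layout exactly).
    Spatial balance of the replicated plots is a diagnostic for the caller,
    not a constraint.
    """
    entry_ids, check_ids, standard_ids = (list(entry_ids), list(check_ids),
                                          list(standard_ids))
    if len(entry_ids) != spec.n_single:
        raise LayoutInfeasibleError(
            f"trial {spec.trial_id}: {len(entry_ids)} entries supplied, "
            f"{spec.n_single} required")
    if len(check_ids) != spec.n_dup_checks:
        raise LayoutInfeasibleError(
            f"trial {spec.trial_id}: {len(check_ids)} checks supplied, "
            f"{spec.n_dup_checks} required")
    if len(standard_ids) != spec.n_standards:
        raise LayoutInfeasibleError(
            f"trial {spec.trial_id}: {len(standard_ids)} standards supplied, "
            f"{spec.n_standards} required")
    spec.check_fill()

    rng = np.random.default_rng(spec.seed)
    cells = [(r, c) for r in range(1, spec.grid_rows + 1)
             for c in range(1, spec.grid_cols + 1)]
    masked_idx = rng.choice(len(cells), size=spec.n_masked, replace=False)
    masked = frozenset(cells[i] for i in masked_idx)
    usable = [cell for cell in cells if cell not in masked]

    plots: list[tuple[str, str]] = []
    plots += [(g, "single") for g in entry_ids]
    plots += [(g, "check") for g in check_ids for _ in range(2)]
    plots += [(g, "standard") for g in standard_ids for _ in range(6)]
    order = rng.permutation(len(plots))
    assignment = {usable[i]: plots[j] for i, j in enumerate(order)}
    return TrialDesign(spec, assignment, masked)


@dataclass(frozen=True)
class ConnectivityReport:
    """Shared-genotype structure of a set of trial designs."""

    graph: nx.Graph
    connected: bool
    shared: dict[tuple[str, str], int]

    @property
    def disconnected_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, n in self.shared.items() if n == 0]

    @property
    def min_overlap(self) -> int:
        return min(self.shared.values()) if self.shared else 0

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, n) for (a, b), n in sorted(self.shared.items())]
        return pd.DataFrame(rows, columns=["trial_a", "trial_b",
                                           "shared_genotypes"])


def check_connectivity(designs) -> ConnectivityReport:
    """Report whether trials form one genotype-connected component.

    Two trials are linked when they share at least one genotype.  An empty
    overlap is a reported outcome, not an error: disconnected series make
    cross-trial genotype comparisons non-identifiable downstream.
    """
    designs = list(designs)
    if not designs:
        raise ParameterError("need at least one design")
    graph = nx.Graph()
    sets = {}
    for d in designs:
        graph.add_node(d.spec.trial_id)
        sets[d.spec.trial_id] = d.genotypes
    shared = {}
    for a, b in combinations(sets, 2):
        n = len(sets[a] & sets[b])
        shared[(a, b)] = n
        if n > 0:
            graph.add_edge(a, b, weight=n)
    return ConnectivityReport(graph, nx.is_connected(graph), shared)


def connectivity_from_dataset(dataset) -> ConnectivityReport:
    """Connectivity of an :class:`~megaenv.data.METDataset` by trial."""
    graph = nx.Graph()
    sets = (dataset.frame.groupby("trial_id", sort=False)["genotype_id"]
            .agg(set).to_dict())
    for t in sets:
        graph.add_node(t)
    shared = {}
    for a, b in combinations(sets, 2):
        n = len(sets[a] & sets[b])
        shared[(a, b)] = n
        if n > 0:
            graph.add_edge(a, b, weight=n)
    return ConnectivityReport(graph, nx.is_connected(graph), shared)
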