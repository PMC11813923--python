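"""GGE biplot analysis: which-won-where and mean-vs-stability.

The GGE model environment-centers the genotype-by-environment table of
means (or BLUP-based predictions) and decomposes it by SVD:

    Y_ij - mu_j = sum_k lambda_k alpha_ik gamma_jk

Rank-2 biplot coordinates scale the orthonormal scores by lambda^f for
genotypes and lambda^(1-f) for environments; f = 0.5 ("symmetric
scaling") is the default, f = 1 is genotype-focused and f = 0
environment-focused.  The inner product of the rank-2 coordinates
reconstructs the rank-2 approximation of the centered table for every f.

The which-won-where view takes the convex hull of the genotype points;
the rays perpendicular to the hull edges (the normal fan) cut the plane
into sectors, each owned by one vertex genotype, which is the rank-2
winner for every environment whose score vector falls in that sector.
Locations whose year-instances all fall in sectors won by the same
genotype are grouped into mega-environments; a single deviating year
breaks repeatability and the trait reports one mega-environment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, ParameterError


@dataclass
class TwoWayTable:
    """Genotype x environment table of means with environment metadata."""

    trait: str
    values: pd.DataFrame                       # genotypes x environments
    env_meta: pd.DataFrame                     # env, location, year
    predicted_mask: pd.DataFrame | None = None  # True where model-filled

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[1] < 2:
            raise ParameterError("need >= 2 environments")
        if v.shape[0] < 3:
            raise ParameterError("need >= 3 genotypes")
        if v.isna().all(axis=1).any() or v.isna().all(axis=0).any():
            raise ParameterError("fully-missing row or column in table")

    def subset(self, environments) -> "TwoWayTable":
        envs = [e for e in self.values.columns if e in set(environments)]
        meta = self.env_meta[self.env_meta["env"].isin(envs)]
        mask = (self.predicted_mask[envs]
                if self.predicted_mask is not None else None)
        return TwoWayTable(self.trait, self.values[envs].copy(),
                           meta.reset_index(drop=True), mask)


def build_two_way(values: pd.DataFrame, env_meta: pd.DataFrame,
                  trait: str = "", fill: pd.DataFrame | None = None
                  ) -> TwoWayTable:
    """Assemble a two-way table; missing cells are filled from ``fill``
    (model-based predictions) and flagged in ``predicted_mask``."""
    values = values.copy()
    mask = values.isna()
    if mask.any().any():
        if fill is None:
            raise ParameterError(
                "table has missing cells and no predictions to fill them")
        values = values.where(~mask, fill)
        if values.isna().any().any():
            raise ParameterError("predictions do not cover all missing cells")
    return TwoWayTable(trait, values, env_meta, mask)


def two_way_from_blups(blup_set, env_meta: pd.DataFrame) -> TwoWayTable:
    """Two-way table of model predictions mu_j + G_i + GE_ij (complete)."""
    pred = blup_set.predicted_values()
    mask = pd.DataFrame(False, index=pred.index, columns=pred.columns)
    return TwoWayTable(blup_set.trait, pred, env_meta, mask)


@dataclass
class GGEModel:
    """SVD of the environment-centered two-way table."""

    trait: str
    centered: pd.DataFrame
    singular_values: np.ndarray     # descending
    genotype_scores: pd.DataFrame   # orthonormal alpha (genotypes x axes)
    env_scores: pd.DataFrame        # orthonormal gamma (environments x axes)
    f: float
    env_meta: pd.DataFrame

    @property
    def varexp(self) -> np.ndarray:
        s2 = self.singular_values**2
        total = s2.sum()
        return s2 / total if total > 0 else s2

    @property
    def varexp_pc12(self) -> float:
        """Percent of G+GE variation captured by the rank-2 biplot."""
        v = self.varexp
        return float(100.0 * (v[:2].sum()))

    def genotype_coords(self) -> pd.DataFrame:
        """Rank-2 biplot coordinates lambda^f * alpha."""
        lam = self.singular_values[:2] ** self.f
        return self.genotype_scores.iloc[:, :2] * lam

    def env_coords(self) -> pd.DataFrame:
        """Rank-2 biplot coordinates lambda^(1-f) * gamma."""
        lam = self.singular_values[:2] ** (1.0 - self.f)
        return self.env_scores.iloc[:, :2] * lam

    def rank2_inner(self) -> pd.DataFrame:
        """Genotype x environment inner products of the rank-2 model."""
        return pd.DataFrame(
            self.genotype_coords().to_numpy()
            @ self.env_coords().to_numpy().T,
            index=self.centered.index, columns=self.centered.columns)


def fit_gge(table: TwoWayTable, f: float = 0.5) -> GGEModel:
    """Environment-center the table and decompose it by SVD.

    Singular-vector signs are oriented so that each axis's
    largest-magnitude environment loading is positive (a reproducible
    convention; all rankings are invariant to it).
    """
    if not 0.0 <= f <= 1.0:
        raise ParameterError("scaling exponent f must be in [0, 1]")
    Y = table.values
    M = Y - Y.mean(axis=0)
    U, s, Vt = np.linalg.svd(M.to_numpy(), full_matrices=False)
    if s[0] > 0:  # numerically-zero axes are exactly zero
        s[s < 1e-12 * s[0]] = 0.0
    for k in range(len(s)):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    axes = [f"PC{k + 1}" for k in range(len(s))]
    return GGEModel(
        trait=table.trait,
        centered=M,
        singular_values=s,
        genotype_scores=pd.DataFrame(U, index=Y.index, columns=axes),
        env_scores=pd.DataFrame(Vt.T, index=Y.columns, columns=axes),
        f=f,
        env_meta=table.env_meta,
    )


# ---------------------------------------------------------------------------
# which-won-where geometry
# ---------------------------------------------------------------------------

def convex_hull(points: np.ndarray) -> list[int]:
    """Indices of hull vertices in counterclockwise order (monotone chain).

    Collinear points on an edge are dropped; ties in coordinates are
    resolved by index order, so the result is deterministic.
    """
    n = len(points)
    order = sorted(range(n), key=lambda i: (points[i, 0], points[i, 1], i))

    def cross(o, a, b):
        return ((points[a, 0] - points[o, 0]) * (points[b, 1] - points[o, 1])
                - (points[a, 1] - points[o, 1]) * (points[b, 0] - points[o, 0]))

    lower: list[int] = []
    for i in order:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], i) <= 0:
            lower.pop()
        lower.append(i)
    upper: list[int] = []
    for i in reversed(order):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], i) <= 0:
            upper.pop()
        upper.append(i)
    return lower[:-1] + upper[:-1]


@dataclass
class WhichWonWhereResult:
    trait: str
    hull_vertices: list[str]                 # counterclockwise genotype ids
    sector_rays: np.ndarray                  # boundary angles, sorted
    env_sector: dict[str, int]
    sector_winner: dict[int, str]
    mega_environments: list[dict]            # [{locations, winner, envs}]
    repeatable: bool

    @property
    def env_winner(self) -> dict[str, str]:
        return {e: self.sector_winner[s] for e, s in self.env_sector.items()}


def which_won_where(model: GGEModel) -> WhichWonWhereResult:
    """Partition environments into sectors won by hull-vertex genotypes.

    Sector boundaries are the rays through the outward normals of the
    hull edges; an environment lying exactly on a boundary joins the
    counterclockwise sector.  Requires genuinely two-dimensional scores
    (lambda_2 > 0).
    """
    if len(model.singular_values) < 2 or model.singular_values[1] <= 0:
        raise DegenerateGeometryError(
            "rank-2 geometry undefined (lambda_2 = 0); use the rank-1 "
            "mean-performance ranking instead")
    G = model.genotype_coords()
    E = model.env_coords()
    pts = G.to_numpy()
    hull = convex_hull(pts)
    hull_ids = [G.index[i] for i in hull]
    h = len(hull)
    # outward normal angle of each edge (hull is counterclockwise)
    ray_angles = []
    for k in range(h):
        a, b = pts[hull[k]], pts[hull[(k + 1) % h]]
        edge = b - a
        normal = np.array([edge[1], -edge[0]])  # right-hand normal = outward
        ray_angles.append(np.arctan2(normal[1], normal[0]))
    # sector of vertex k lies between the rays of its two adjacent edges
    order = np.argsort(ray_angles)
    sorted_rays = np.array([ray_angles[i] for i in order])
    # vertex owning the sector starting at sorted ray r_m is the head vertex
    # of that edge (edge k runs vertex k -> k+1; its normal cone side toward
    # increasing angle belongs to vertex k+1)
    sector_vertex = {m: hull_ids[(order[m] + 1) % h] for m in range(h)}

    def sector_of(angle: float) -> int:
        # sector m covers [ray_m, ray_{m+1}); boundary joins the CCW side
        idx = int(np.searchsorted(sorted_rays, angle, side="right")) - 1
        return idx % h

    env_sector = {}
    for j, env in enumerate(E.index):
        v = E.iloc[j].to_numpy()
        env_sector[env] = sector_of(float(np.arctan2(v[1], v[0])))
    sector_winner = {m: sector_vertex[m] for m in range(h)}

    meta = model.env_meta.set_index("env")
    mega, repeatable = _mega_environments(
        {e: sector_winner[s] for e, s in env_sector.items()}, meta)
    return WhichWonWhereResult(model.trait, hull_ids, sorted_rays, env_sector,
                               sector_winner, mega, repeatable)


def _mega_environments(env_winner: dict[str, str], meta: pd.DataFrame):
    """Group locations whose year-instances all share a winner.

    Repeatability requires every location to have >= 2 year-instances
    with the same winning genotype; any disagreement (or a single-year
    location) collapses the verdict to one mega-environment.
    """
    by_loc: dict[str, list[str]] = {}
    for env, winner in env_winner.items():
        loc = meta.loc[env, "location"]
        by_loc.setdefault(loc, []).append(env)
    winners_by_loc = {}
    for loc, envs in by_loc.items():
        winners = {env_winner[e] for e in envs}
        if len(envs) < 2 or len(winners) > 1:
            return ([{"locations": sorted(by_loc),
                      "winner": None,
                      "envs": sorted(env_winner)}], False)
        winners_by_loc[loc] = winners.pop()
    groups: dict[str, list[str]] = {}
    for loc, w in winners_by_loc.items():
        groups.setdefault(w, []).append(loc)
    mega = [{"locations": sorted(locs), "winner": w,
             "envs": sorted(e for e in env_winner
                            if meta.loc[e, "location"] in set(locs))}
            for w, locs in sorted(groups.items())]
    return mega, True


def brute_force_winner(model: GGEModel) -> dict[str, str]:
    """Independent rank-2 winner per environment: argmax over all
    genotypes of the rank-2 inner product (ties to the lowest label)."""
    inner = model.rank2_inner()
    out = {}
    for env in inner.columns:
        col = inner[env]
        best = col.max()
        out[env] = sorted(col.index[col >= best - 0.0])[0]
    return out


# ---------------------------------------------------------------------------
# mean vs stability (average-environment coordination view)
# ---------------------------------------------------------------------------

@dataclass
class MeanStabilityResult:
    trait: str
    aea: np.ndarray                       # unit vector of the AEA
    mean_performance: pd.Series           # signed projection on the AEA
    stability: pd.Series                  # |orthogonal projection| (>= 0)
    ranking: pd.Series                    # by mean performance, best first
    ideal_point: np.ndarray
    ideal_distance: pd.Series
    ideal_ranking: pd.Series              # by distance to the ideal, best 1st


def mean_vs_stability(model: GGEModel) -> MeanStabilityResult:
    """Project genotypes on the average-environment axis (AEA).

    The AEA points from the origin toward the mean of the environment
    rank-2 coordinates; a genotype's signed projection on it is its mean
    performance, the orthogonal projection length its instability.  The
    ideal genotype sits on the AEA at the largest observed projection;
    genotypes are also ranked by Euclidean distance to that point.
    """
    E = model.env_coords().to_numpy()
    mean_env = E.mean(axis=0)
    norm = np.linalg.norm(mean_env)
    scale = np.abs(E).max()
    if norm <= 1e-10 * max(scale, 1e-300):
        raise DegenerateGeometryError("average environment vector is zero; "
                                      "AEA undefined")
    aea = mean_env / norm
    ortho = np.array([-aea[1], aea[0]])
    G = model.genotype_coords()
    pts = G.to_numpy()
    proj = pd.Series(pts @ aea, index=G.index, name="mean_performance")
    stab = pd.Series(np.abs(pts @ ortho), index=G.index, name="stability")
    ranking = proj.sort_values(ascending=False)
    ideal = aea * proj.max()
    dist = pd.Series(np.linalg.norm(pts - ideal, axis=1), index=G.index,
                     name="ideal_distance")
    return MeanStabilityResult(model.trait, aea, proj, stab, ranking, ideal,
                               dist, dist.sort_values())


def plot_which_won_where(model: GGEModel, result: WhichWonWhereResult,
                         path) -> None:
    """Polygon view: genotype points, hull, sector rays, environments."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    G, E = model.genotype_coords(), model.env_coords()
    fig, ax = plt.subplots(figsize=(7, 7))
    ax.scatter(G.iloc[:, 0], G.iloc[:, 1], s=8, color="0.6")
    hull_pts = G.loc[result.hull_vertices]
    closed = pd.concat([hull_pts, hull_pts.iloc[[0]]])
    ax.plot(closed.iloc[:, 0], closed.iloc[:, 1], "b-", lw=1)
    for g in result.hull_vertices:
        ax.annotate(g, G.loc[g], fontsize=8, color="blue")
    rmax = 1.1 * float(np.abs(G.to_numpy()).max())
    for ang in result.sector_rays:
        ax.plot([0, rmax * np.cos(ang)], [0, rmax * np.sin(ang)],
                "k--", lw=0.5)
    for env in E.index:
        ax.annotate(env, E.loc[env], fontsize=9, color="darkgreen")
        ax.scatter(*E.loc[env], marker="^", color="darkgreen")
    v = model.varexp * 100
    ax.set_xlabel(f"PC1 ({v[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({v[1]:.1f}%)")
    ax.set_title(f"Which-won-where: {model.trait}")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mean_stability(model: GGEModel, result: MeanStabilityResult,
                        path) -> None:
    """AEC view: AEA arrow, genotype projections, ideal genotype."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    G = model.genotype_coords()
    fig, ax = plt.subplots(figsize=(7, 7))
    ax.scatter(G.iloc[:, 0], G.iloc[:, 1], s=8, color="0.6")
    rmax = 1.1 * float(np.abs(G.to_numpy()).max())
    ax.annotate("", xy=result.aea * rmax, xytext=(0, 0),
                arrowprops=dict(arrowstyle="->", color="red"))
    ortho = np.array([-result.aea[1], result.aea[0]])
    ax.plot([-ortho[0] * rmax, ortho[0] * rmax],
            [-ortho[1] * rmax, ortho[1] * rmax], "r--", lw=0.7)
    ax.scatter(*result.ideal_point, marker="*", s=150, color="red")
    v = model.varexp * 100
    ax.set_xlabel(f"PC1 ({v[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({v[1]:.1f}%)")
    ax.set_title(f"Mean vs stability: {model.trait}")
    fig.savefig(path, dpi=120)
    plt.close(fig)
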