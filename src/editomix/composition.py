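"""Cell-composition analysis of bulk editomes.

A bulk tissue's editing level at a site is the expression-weighted average
of its cell types' levels:

    level(s) = sum_c f_c * w_c(g(s)) * L_c(s) / sum_c f_c * w_c(g(s))

where f_c are cell-type fractions, w_c FPKM-like expression weights of the
host gene, and L_c(s) the per-cell-type editing level. This module provides
the forward mixing model, a neuronal-density perturbation, nonparametric
differential-editing statistics (exact Mann-Whitney for the small group
sizes typical of injury cohorts, Benjamini-Hochberg correction), editome
correlation and clustering, and a least-squares inverse that recovers the
neuronal-fraction change from bulk editomes alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

MixtureSpec = dict[str, float]


def validate_mixture(mixture: MixtureSpec) -> None:
    if not mixture:
        raise ValueError("mixture must not be empty")
    if any(f < 0 for f in mixture.values()):
        raise ValueError("mixture fractions must be non-negative")
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture fractions sum to {total}, expected 1")


@dataclass
class TissueEditome:
    """Predicted bulk editome for one mixture."""

    levels: pd.Series  # per-site predicted level
    repeat_index: float | None
    mixture: MixtureSpec
    provenance: str = ""


@dataclass
class CorrelationResult:
    pairs: pd.DataFrame  # point label, delta_cell, delta_condition
    r: float
    r2: float
    p: float


@dataclass
class ClusterTree:
    labels: list[str]
    linkage: np.ndarray
    distances: pd.DataFrame
    two_groups: dict[str, int]
    dropped: list[str] = field(default_factory=list)

    def newick(self) -> str:
        """Serialize the dendrogram as a Newick string."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


@dataclass
class FractionChangeEstimate:
    fractions_pre: dict[str, float]
    fractions_post: dict[str, float]
    neuron_delta: float  # relative change of the neuron fraction
    residual_pre: float
    residual_post: float
    ill_conditioned: bool


# ---------------------------------------------------------------------------
# forward model


def _site_weights(
    sites: pd.Index,
    cells: list[str],
    expression: pd.DataFrame | None,
    gene_of_site: pd.Series | None,
) -> np.ndarray:
    """(site x cell) expression-weight matrix; uniform when not supplied."""
    w = np.ones((len(sites), len(cells)))
    if expression is not None and gene_of_site is not None:
        for i, s in enumerate(sites):
            gene = gene_of_site.get(s)
            if gene in expression.index:
                w[i] = expression.loc[gene, cells].to_numpy(dtype=float)
    return w


def mix_editomes(
    cell_levels: pd.DataFrame,
    mixture: MixtureSpec,
    expression: pd.DataFrame | None = None,
    gene_of_site: pd.Series | None = None,
    p_repeat: dict[str, float] | None = None,
) -> TissueEditome:
    """Predict the bulk editome of a mixture of cell-type editomes.

    ``cell_levels`` is (site x cell type); with uniform weights the site
    level reduces to sum_c f_c L_c(s). The repeat index is mixed with
    read-output weights (uniform by default, i.e. the plain f-weighted
    mean of per-cell repeat rates).
    """
    validate_mixture(mixture)
    missing = set(mixture) - set(cell_levels.columns)
    if missing:
        raise ValueError(f"no editome for cell types: {sorted(missing)}")
    cells = list(mixture)
    f = np.array([mixture[c] for c in cells])
    L = cell_levels[cells].to_numpy(dtype=float)
    w = _site_weights(cell_levels.index, cells, expression, gene_of_site)
    denom = (w * f).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        lvl = (L * w * f).sum(axis=1) / denom
    lvl[denom == 0] = np.nan
    levels = pd.Series(lvl, index=cell_levels.index, name="level")

    rep = None
    if p_repeat is not None:
        rep = float(sum(mixture[c] * p_repeat.get(c, 0.0) for c in cells))
    return TissueEditome(levels=levels, repeat_index=rep, mixture=dict(mixture))


def simulate_density_change(base: MixtureSpec, neuron_delta: float, neuron: str = "neuron") -> MixtureSpec:
    """Scale the neuronal fraction by (1 + delta), redistributing the rest.

    The mass gained or lost by neurons is spread over the other cell types
    proportionally to their base fractions, so the output still sums to 1.
    """
    validate_mixture(base)
    if neuron not in base:
        raise ValueError(f"no {neuron!r} fraction in mixture")
    f_n = base[neuron] * (1.0 + neuron_delta)
    if not 0.0 <= f_n <= 1.0:
        raise ValueError(f"neuronal fraction {f_n:.3f} outside [0, 1]")
    rest = 1.0 - base[neuron]
    out = {}
    for ct, frac in base.items():
        if ct == neuron:
            out[ct] = f_n
        elif rest > 0:
            out[ct] = frac * (1.0 - f_n) / rest
        else:
            out[ct] = 0.0
    return out


def simulate_site_counts(
    cell_levels: pd.DataFrame,
    mixture: MixtureSpec,
    depth: float,
    rng: np.random.Generator,
    expression: pd.DataFrame | None = None,
    gene_of_site: pd.Series | None = None,
) -> pd.Series:
    """Measured site levels at finite depth (binomial sufficient statistic).

    Each site's edited-read count is Binomial(Poisson(depth), mixed level),
    exactly the distribution induced by error-free read simulation; used
    for seed batteries where full read emission would be wasteful.
    """
    tissue = mix_editomes(cell_levels, mixture, expression, gene_of_site)
    out = {}
    for s, lvl in tissue.levels.items():
        if not np.isfinite(lvl):
            out[s] = np.nan
            continue
        n = int(rng.poisson(depth))
        out[s] = rng.binomial(n, lvl) / n if n else np.nan
    return pd.Series(out, name="level")


# ---------------------------------------------------------------------------
# statistics


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration (tie-aware).

    Returns (U of x, p). Every C(n, nx) assignment of the pooled values to
    group x is enumerated; the two-sided p counts splits whose U is at
    least as extreme (on either tail) as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    n = nx + ny
    gt = (pooled[:, None] > pooled[None, :]).astype(float)
    gt += 0.5 * (pooled[:, None] == pooled[None, :])
    np.fill_diagonal(gt, 0.0)

    obs_idx = np.arange(nx)
    u_obs = _u_of(gt, obs_idx, n)
    u_lo = min(u_obs, nx * ny - u_obs)
    u_hi = nx * ny - u_lo
    total = comb(n, nx)
    extreme = 0
    for idx in combinations(range(n), nx):
        u = _u_of(gt, np.array(idx), n)
        if u <= u_lo + 1e-9 or u >= u_hi - 1e-9:
            extreme += 1
    return u_obs, extreme / total


def _u_of(gt: np.ndarray, idx: np.ndarray, n: int) -> float:
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    return float(gt[np.ix_(mask, ~mask)].sum())


def mann_whitney(x, y, exact_max: int = 8) -> float:
    """Two-sided Mann-Whitney p: exact enumeration for small groups,
    normal approximation with tie correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be non-empty")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    if min(len(x), len(y)) <= exact_max:
        return mann_whitney_exact(x, y)[1]
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up q-values (thin wrapper over statsmodels)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def differential_editing(
    levels_a: pd.DataFrame,
    levels_b: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "bh",
) -> pd.DataFrame:
    """Per-site differential editing between two sample groups.

    ``levels_a``/``levels_b`` are (site x sample) level frames (fractions).
    Sites with fewer than 2 non-missing replicates in either group are
    skipped with a reason. Deltas are reported in percentage points
    (mean_b - mean_a) x 100 to match the convention of recoding-site
    panels. ``correction``: "bh" or "bonferroni".
    """
    if correction not in ("bh", "bonferroni"):
        raise ValueError("correction must be 'bh' or 'bonferroni'")
    rows = []
    sites = levels_a.index.union(levels_b.index)
    for s in sites:
        a = levels_a.loc[s].dropna().to_numpy(dtype=float) if s in levels_a.index else np.array([])
        b = levels_b.loc[s].dropna().to_numpy(dtype=float) if s in levels_b.index else np.array([])
        if len(a) < 2 or len(b) < 2:
            rows.append({"site": s, "skipped": True, "reason": "fewer than 2 replicates"})
            continue
        p = mann_whitney(a, b)
        delta = (b.mean() - a.mean()) * 100
        rows.append(
            {
                "site": s,
                "skipped": False,
                "reason": "",
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "delta": delta,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("site")
    tested = out.index[~out["skipped"]]
    if len(tested):
        p = out.loc[tested, "p"].to_numpy(dtype=float)
        if correction == "bh":
            q = benjamini_hochberg(p)
        else:
            q = np.minimum(p * len(p), 1.0)
        out.loc[tested, "q"] = q
        out.loc[tested, "significant"] = q <= alpha
        out.loc[tested, "direction"] = np.where(
            out.loc[tested, "delta"] > 0, "up", np.where(out.loc[tested, "delta"] < 0, "down", "none")
        )
    return out


def editome_correlation(
    cell_a: pd.Series,
    cell_b: pd.Series,
    cond_treated: pd.Series,
    cond_control: pd.Series,
    sites: pd.Index | None = None,
    repeat_deltas: tuple[float, float] | None = None,
) -> CorrelationResult:
    """Correlate cell-type editing differences with a condition contrast.

    ``delta_cell = cell_a - cell_b`` (e.g. neuron minus astrocyte) and
    ``delta_condition = treated - control`` per shared site; the repeat
    index deltas, when given as ``(cell_delta, condition_delta)``, enter as
    one additional equally weighted point.
    """
    if sites is None:
        sites = cell_a.index
    sites = pd.Index(sites)
    df = pd.DataFrame(
        {
            "delta_cell": cell_a.reindex(sites) - cell_b.reindex(sites),
            "delta_condition": cond_treated.reindex(sites) - cond_control.reindex(sites),
        },
        index=sites,
    ).dropna()
    df["point"] = df.index.astype(str)
    if repeat_deltas is not None:
        extra = pd.DataFrame(
            [{"delta_cell": repeat_deltas[0], "delta_condition": repeat_deltas[1], "point": "repeat_index"}]
        )
        df = pd.concat([df, extra], ignore_index=True)
    if len(df) < 3:
        raise ValueError("need at least 3 shared points for correlation")
    if df["delta_cell"].std() == 0 or df["delta_condition"].std() == 0:
        raise ValueError("zero variance in one delta vector; correlation undefined")
    r, p = stats.pearsonr(df["delta_cell"], df["delta_condition"])
    return CorrelationResult(pairs=df[["point", "delta_cell", "delta_condition"]], r=float(r), r2=float(r) ** 2, p=float(p))


def cluster_editomes(matrix: pd.DataFrame, min_shared_sites: int = 3) -> ClusterTree:
    """Average-linkage clustering of samples on 1 - Pearson distance.

    ``matrix`` is (site x sample); pairwise correlations use complete
    pairs only. Samples with fewer than ``min_shared_sites`` usable sites
    are dropped (logged in ``dropped``). The two-group cut is taken at the
    tallest merge.
    """
    usable = matrix.notna().sum(axis=0)
    dropped = list(matrix.columns[usable < min_shared_sites])
    mat = matrix.drop(columns=dropped)
    samples = list(mat.columns)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples with enough usable sites")

    n = len(samples)
    dist = pd.DataFrame(0.0, index=samples, columns=samples)
    for i in range(n):
        for j in range(i + 1, n):
            sub = mat[[samples[i], samples[j]]].dropna()
            if len(sub) < min_shared_sites:
                raise ValueError(
                    f"samples {samples[i]} and {samples[j]} share fewer than {min_shared_sites} sites"
                )
            r = sub.iloc[:, 0].corr(sub.iloc[:, 1])
            if np.isnan(r):  # zero variance in a complete-pair vector
                r = 0.0
            dist.iloc[i, j] = dist.iloc[j, i] = 1.0 - r
    condensed = np.array([dist.iloc[i, j] for i in range(n) for j in range(i + 1, n)])
    Z = hierarchy.linkage(condensed, method="average")
    cut = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    return ClusterTree(
        labels=samples,
        linkage=Z,
        distances=dist,
        two_groups={s: int(g) for s, g in zip(samples, cut)},
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# inverse model


def pool_non_neuron(
    cell_levels: pd.DataFrame, mixture: MixtureSpec, neuron: str = "neuron"
) -> pd.DataFrame:
    """Collapse non-neuron editomes into one pooled profile.

    Brain editomes split into two groups — neuronal and non-neuronal — and
    a density change that redistributes mass proportionally leaves the
    relative mix of non-neuron types unchanged. The bulk editome is then
    exactly a two-component mixture of the neuron editome and this pooled
    (baseline-fraction-weighted) non-neuron editome, which is far better
    conditioned for inverse estimation than seven nearly proportional
    profiles.
    """
    validate_mixture(mixture)
    others = {c: f for c, f in mixture.items() if c != neuron and c in cell_levels.columns}
    total = sum(others.values())
    if total <= 0:
        raise ValueError("mixture has no non-neuron mass to pool")
    pooled = sum(cell_levels[c] * (f / total) for c, f in others.items())
    return pd.DataFrame({neuron: cell_levels[neuron], "non_neuron": pooled})


def _fit_fractions(
    tissue: pd.Series,
    cell_levels: pd.DataFrame,
    weights: np.ndarray,
) -> tuple[np.ndarray, float, bool]:
    """Solve min ||M f|| s.t. sum(f) = 1 for the mixing residual matrix M.

    The mixing equation multiplied through by its denominator is linear and
    homogeneous in f: sum_c f_c w_c(s) (L_c(s) - y_s) = 0 per site, which
    with the simplex constraint becomes an equality-constrained least
    squares problem solved via its KKT system.
    """
    sites = tissue.dropna().index.intersection(cell_levels.dropna().index)
    y = tissue.loc[sites].to_numpy(dtype=float)
    L = cell_levels.loc[sites].to_numpy(dtype=float)
    w = weights[[list(tissue.index).index(s) for s in sites]] if weights.ndim == 2 else None
    M = (L - y[:, None]) * (w if w is not None else 1.0)
    k = M.shape[1]
    A = M.T @ M
    # A alone is singular for exact mixtures (M f* = 0); the simplex
    # constraint restores uniqueness unless cell editomes are collinear,
    # which shows up as an ill-conditioned KKT system.
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = 2 * A
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.zeros(k + 1)
    rhs[k] = 1.0
    if np.linalg.cond(kkt) > 1e10:
        return np.full(k, np.nan), np.nan, True
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.full(k, np.nan), np.nan, True
    f = sol[:k]
    residual = float(np.linalg.norm(M @ f))
    return f, residual, False


def estimate_fraction_change(
    tissue_pre: pd.Series,
    tissue_post: pd.Series,
    cell_levels: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    gene_of_site: pd.Series | None = None,
    neuron: str = "neuron",
) -> FractionChangeEstimate:
    """Recover cell-type fractions before/after a condition from bulk editomes.

    Fits the mixing equation by constrained least squares for each
    condition and reports the relative change of the neuronal fraction.
    Collinear cell editomes make the fit ill-conditioned; the flag is set
    and no estimate is returned.
    """
    cells = list(cell_levels.columns)
    if neuron not in cells:
        raise ValueError(f"no {neuron!r} column in cell editomes")
    w = _site_weights(cell_levels.index, cells, expression, gene_of_site)

    f_pre, res_pre, bad_pre = _fit_fractions(tissue_pre.reindex(cell_levels.index), cell_levels, w)
    f_post, res_post, bad_post = _fit_fractions(tissue_post.reindex(cell_levels.index), cell_levels, w)
    ill = bad_pre or bad_post
    if ill:
        return FractionChangeEstimate({}, {}, np.nan, res_pre, res_post, True)
    pre = dict(zip(cells, map(float, f_pre)))
    post = dict(zip(cells, map(float, f_post)))
    delta = (post[neuron] - pre[neuron]) / pre[neuron] if pre[neuron] else np.nan
    return FractionChangeEstimate(pre, post, float(delta), res_pre, res_post, False)
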