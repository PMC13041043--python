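"""Taxa-table community analytics.

Operates on a samples x ASVs count matrix with rank-addressable lineages:
rank aggregation to relative abundances, nitrifier guild subsetting
(AOA / AOB / NOB by taxonomic match rules), taxa richness, Bray-Curtis
dissimilarity, non-metric multidimensional scaling (Kruskal stress-1 with
pool-adjacent-violators monotone regression), PERMANOVA and a
betadisper-style test of group dispersion homogeneity.

The distance, ordination and permutation machinery is implemented here
rather than delegated, so each piece can be validated against independent
oracles.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "TaxaTable",
    "GuildDefinition",
    "DEFAULT_GUILDS",
    "OrdinationResult",
    "PermanovaResult",
    "relative_abundance",
    "assign_guilds",
    "subset_nitrifiers",
    "richness",
    "bray_curtis",
    "nmds",
    "permanova",
    "dispersion_homogeneity",
    "top_taxa_display",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass
class TaxaTable:
    """Counts (samples x ASVs), per-ASV lineages and sample metadata.

    ``counts``: DataFrame indexed by sample_id, columns = ASV ids.
    ``taxonomy``: DataFrame indexed by asv_id with columns in RANKS
    (missing assignments as NaN/empty; at least ``domain`` assigned).
    ``meta``: DataFrame indexed by sample_id (fjord/region, year, depth_m,
    water_mass); optional for purely compositional operations.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    meta: pd.DataFrame | None = None

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = set(self.counts.columns) - set(self.taxonomy.index)
        if missing:
            raise ValueError(f"ASVs without taxonomy: {sorted(missing)[:5]}")
        dom = self.taxonomy.loc[list(self.counts.columns), "domain"]
        if dom.isna().any() or (dom.astype(str).str.len() == 0).any():
            raise ValueError("every ASV must have at least domain assigned")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)


def relative_abundance(table: TaxaTable, rank: str | None = None
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample proportions, optionally aggregated at a rank.

    ASVs unassigned at the requested rank are pooled into
    ``Unclassified_<parent>`` where parent is the nearest assigned higher
    rank.  Samples with zero total counts are excluded and returned in the
    second element.

    Returns (proportions DataFrame, list of excluded sample ids).
    """
    counts = table.counts
    totals = counts.sum(axis=1)
    excluded = list(totals.index[totals == 0])
    counts = counts.loc[totals > 0]
    if rank is None:
        props = counts.div(counts.sum(axis=1), axis=0)
        return props, excluded
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    tax = table.taxonomy.loc[list(counts.columns)]
    names = []
    rank_pos = RANKS.index(rank)
    for asv in counts.columns:
        name = tax.at[asv, rank]
        if pd.isna(name) or str(name) == "":
            parent = "root"
            for higher in reversed(RANKS[:rank_pos]):
                v = tax.at[asv, higher]
                if not (pd.isna(v) or str(v) == ""):
                    parent = str(v)
                    break
            name = f"Unclassified_{parent}"
        names.append(str(name))
    agg = counts.T.groupby(pd.Index(names, name=rank)).sum().T
    props = agg.div(agg.sum(axis=1), axis=0)
    return props, excluded


# --------------------------------------------------------------------------
# Nitrifier guilds
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GuildDefinition:
    """An ASV belongs to the guild iff any (rank, name) rule matches."""
    guild: str
    rules: tuple[tuple[str, str], ...]

    def matches(self, lineage: pd.Series) -> bool:
        for rank, name in self.rules:
            v = lineage.get(rank)
            if not pd.isna(v) and str(v) == name:
                return True
        return False


DEFAULT_GUILDS = (
    GuildDefinition("AOA", (("class", "Nitrososphaeria"),)),
    GuildDefinition("AOB", (("family", "Nitrosomonadaceae"),
                            ("genus", "Nitrosococcus"))),
    GuildDefinition("NOB", (("phylum", "Nitrospinota"),
                            ("phylum", "Nitrospirota"),
                            ("genus", "Nitrotoga"),
                            ("genus", "Nitrobacter"))),
)


def assign_guilds(taxonomy: pd.DataFrame,
                  guilds: tuple[GuildDefinition, ...] = DEFAULT_GUILDS
                  ) -> tuple[pd.Series, dict[str, list[str]]]:
    """Map each ASV to a guild (or None) and report multi-guild overlaps.

    Overlapping ASVs are counted once, by guild precedence = the order of
    ``guilds`` (default AOA > AOB > NOB).
    """
    assignment = {}
    overlaps: dict[str, list[str]] = {}
    for asv, lineage in taxonomy.iterrows():
        hits = [g.guild for g in guilds if g.matches(lineage)]
        assignment[asv] = hits[0] if hits else None
        if len(hits) > 1:
            overlaps[asv] = hits
    return pd.Series(assignment, name="guild"), overlaps


def subset_nitrifiers(table: TaxaTable,
                      guilds: tuple[GuildDefinition, ...] = DEFAULT_GUILDS
                      ) -> pd.DataFrame:
    """Per-sample guild relative abundance against the TOTAL community.

    No rescaling of the nitrifier subset to 100 % is applied; the non-guild
    remainder is reported split by domain as ``Other_Archaea`` /
    ``Other_Bacteria`` (anything else under ``Other``).
    """
    props, _ = relative_abundance(table)
    assignment, _ = assign_guilds(table.taxonomy.loc[list(props.columns)],
                                  guilds)
    guild_names = [g.guild for g in guilds]
    out = pd.DataFrame(0.0, index=props.index,
                       columns=guild_names + ["Other_Archaea", "Other_Bacteria",
                                              "Other"])
    domains = table.taxonomy.loc[list(props.columns), "domain"].astype(str)
    for asv in props.columns:
        g = assignment[asv]
        if g is None:
            d = domains[asv]
            g = {"Archaea": "Other_Archaea",
                 "Bacteria": "Other_Bacteria"}.get(d, "Other")
        out[g] += props[asv]
    if (out["Other"] == 0).all():
        out = out.drop(columns="Other")
    return out


def richness(table: TaxaTable) -> pd.Series:
    """Number of ASVs with count > 0 per sample."""
    return (table.counts > 0).sum(axis=1).rename("richness")


# --------------------------------------------------------------------------
# Bray-Curtis
# --------------------------------------------------------------------------

def bray_curtis(abundances) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity between rows.

    d(i, j) = sum|x_i - x_j| / sum(x_i + x_j).  Raises if two all-zero rows
    are present (their mutual distance is undefined).
    """
    x = np.asarray(abundances, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D samples x taxa array")
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    zero_rows = np.flatnonzero(x.sum(axis=1) == 0)
    if len(zero_rows) >= 2:
        raise ValueError(
            f"distance undefined between all-zero samples {zero_rows.tolist()}"
        )
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[i] - x[i + 1:]).sum(axis=1)
        tot = (x[i] + x[i + 1:]).sum(axis=1)
        d[i, i + 1:] = d[i + 1:, i] = diff / tot
    return d


def _check_distance(dist) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


# --------------------------------------------------------------------------
# nMDS
# --------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: np.ndarray
    stress: float
    converged: bool
    iterations: int
    stress_history: list[float] = field(default_factory=list)


def _pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: least-squares non-decreasing fit."""
    n = len(y)
    level = y.astype(float).copy()
    weight = np.ones(n)
    # blocks as (value, weight) merged right-to-left
    vals, wts, sizes = [], [], []
    for v, w in zip(level, weight):
        vals.append(v)
        wts.append(w)
        sizes.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            w2 = wts.pop(); v2 = vals.pop(); s2 = sizes.pop()
            w1 = wts.pop(); v1 = vals.pop(); s1 = sizes.pop()
            vals.append((v1 * w1 + v2 * w2) / (w1 + w2))
            wts.append(w1 + w2)
            sizes.append(s1 + s2)
    out = np.empty(n)
    pos = 0
    for v, s in zip(vals, sizes):
        out[pos:pos + s] = v
        pos += s
    return out


def _pcoa_coords(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = evecs[:, :k] * np.sqrt(np.clip(evals[:k], 0, None))
    return coords


def _config_distances(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def _stress1(d_config: np.ndarray, disparities: np.ndarray) -> float:
    denom = (d_config ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d_config - disparities) ** 2).sum() / denom))


def _nmds_single(d: np.ndarray, x0: np.ndarray, max_iter: int,
                 tol: float) -> tuple[np.ndarray, float, bool, int, list]:
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    delta = d[iu]
    # primary (weak) ties: within tied dissimilarities, order by current
    # config distance so ties impose no constraint
    x = x0.copy()
    best_stress = np.inf
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dc = _config_distances(x)
        dvec = dc[iu]
        order = np.lexsort((dvec, delta))
        dhat_sorted = _pava(dvec[order])
        dhat = np.empty_like(dvec)
        dhat[order] = dhat_sorted
        # normalize disparities to the scale of the configuration distances
        ss = (dhat ** 2).sum()
        if ss > 0:
            dhat = dhat * np.sqrt((dvec ** 2).sum() / ss)
        stress = _stress1(dvec, dhat)
        if stress > best_stress + 1e-15:
            break  # keep monotone reported sequence
        history.append(stress)
        if best_stress - stress < tol and it > 1:
            best_stress = min(best_stress, stress)
            converged = True
            break
        best_stress = stress
        if stress == 0.0:
            converged = True
            break
        # Guttman transform toward the disparities
        dh = np.zeros((n, n))
        dh[iu] = dhat
        dh = dh + dh.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dc > 0, dh / np.where(dc > 0, dc, 1.0), 0.0)
        b = -ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = (b @ x) / n
    return x, best_stress, converged, it, history


def nmds(dist, k: int = 2, seed: int = 0, max_iter: int = 300,
         n_restarts: int = 20, tol: float = 1e-6) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Runs one PCoA-seeded start plus ``n_restarts`` random starts and keeps
    the best configuration, centered and rotated to its principal axes.
    """
    d = _check_distance(dist)
    n = d.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for k={k}")
    rng = np.random.default_rng(seed)
    starts = [_pcoa_coords(d, k)]
    scale = d.max() if d.max() > 0 else 1.0
    for _ in range(n_restarts):
        starts.append(rng.normal(scale=scale, size=(n, k)))
    best = None
    for x0 in starts:
        x, stress, conv, its, hist = _nmds_single(d, x0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, conv, its, hist)
        if stress < tol * 1e-3:
            break
    x, stress, conv, its, hist = best
    x = x - x.mean(axis=0)
    # principal-axis rotation
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    return OrdinationResult(x, stress, conv, its, hist)


# --------------------------------------------------------------------------
# PERMANOVA and dispersion
# --------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p: float
    n_permutations: int
    exhaustive: bool = False


def _group_indices(grouping) -> tuple[np.ndarray, list[np.ndarray]]:
    labels = np.asarray(grouping)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    idx = [np.flatnonzero(labels == g) for g in uniq]
    if any(len(i) == 0 for i in idx):
        raise ValueError("empty group")
    return labels, idx


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int
                 ) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(members, members)].sum() / (2.0 * len(members))
    ss_between = ss_total - ss_within
    df_b = n_groups - 1
    df_w = n - n_groups
    if ss_within == 0:
        f = np.inf
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def _multiset_permutations(items):
    """Distinct permutations of a multiset, lexicographic order."""
    counter = Counter(items)
    keys = sorted(counter)
    n = len(items)
    out = [None] * n

    def rec(pos):
        if pos == n:
            yield tuple(out)
            return
        for k in keys:
            if counter[k]:
                counter[k] -= 1
                out[pos] = k
                yield from rec(pos + 1)
                counter[k] += 1

    yield from rec(0)


def _n_distinct_relabelings(sizes: list[int]) -> int:
    total = factorial(sum(sizes))
    for s in sizes:
        total //= factorial(s)
    return total


def permanova(dist, grouping, n_perm: int = 999, seed: int = 0
              ) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) under free label
    permutation; when the number of distinct relabelings is <= n_perm the
    null distribution is enumerated exhaustively instead.
    """
    d = _check_distance(dist)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels, idx = _group_indices(grouping)
    uniq = pd.unique(labels)
    codes = np.searchsorted(np.sort(uniq.astype(str)),
                            np.asarray(labels).astype(str))
    n_groups = len(uniq)
    d2 = d ** 2
    f_obs, r2 = _permanova_f(d2, codes, n_groups)

    sizes = [len(i) for i in idx]
    n_distinct = _n_distinct_relabelings(sizes)
    tol = 1e-12
    if n_distinct <= n_perm:
        count_ge = 0
        n_seen = 0
        for perm in _multiset_permutations(codes.tolist()):
            n_seen += 1
            f_p, _ = _permanova_f(d2, np.asarray(perm), n_groups)
            if f_p >= f_obs - tol:
                count_ge += 1
        p = count_ge / n_seen
        return PermanovaResult(f_obs, r2, p, n_seen, exhaustive=True)

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        perm_codes = rng.permutation(codes)
        f_p, _ = _permanova_f(d2, perm_codes, n_groups)
        if f_p >= f_obs - tol:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    return PermanovaResult(f_obs, r2, p, n_perm)


def _centroid_distances(d: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """betadisper-style distances to group centroids in PCoA space.

    Negative eigenvalues are kept as an 'imaginary' block; squared
    distances combine real and imaginary parts by difference, floored at 0.
    """
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(g)
    pos = evals > 1e-10
    neg = evals < -1e-10
    x_re = evecs[:, pos] * np.sqrt(evals[pos])
    x_im = evecs[:, neg] * np.sqrt(-evals[neg])
    z = np.empty(n)
    for gcode in np.unique(codes):
        members = np.flatnonzero(codes == gcode)
        c_re = x_re[members].mean(axis=0)
        c_im = x_im[members].mean(axis=0) if x_im.size else np.zeros(0)
        d2_re = ((x_re[members] - c_re) ** 2).sum(axis=1)
        d2_im = ((x_im[members] - c_im) ** 2).sum(axis=1) if x_im.size else 0.0
        z[members] = np.sqrt(np.clip(d2_re - d2_im, 0, None))
    return z


def _anova_f(z: np.ndarray, codes: np.ndarray) -> float:
    grand = z.mean()
    ss_b = ss_w = 0.0
    groups = np.unique(codes)
    for g in groups:
        zg = z[codes == g]
        ss_b += len(zg) * (zg.mean() - grand) ** 2
        ss_w += ((zg - zg.mean()) ** 2).sum()
    df_b = len(groups) - 1
    df_w = len(z) - len(groups)
    scale = float((z ** 2).sum()) + 1e-300
    if ss_w <= 1e-20 * scale:
        return 0.0 if ss_b <= 1e-20 * scale else np.inf
    return (ss_b / df_b) / (ss_w / df_w)


def dispersion_homogeneity(dist, grouping, n_perm: int = 999, seed: int = 0
                           ) -> PermanovaResult:
    """Permutation test for homogeneity of multivariate group dispersion."""
    d = _check_distance(dist)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels, _ = _group_indices(grouping)
    uniq = pd.unique(labels)
    codes = np.searchsorted(np.sort(uniq.astype(str)),
                            np.asarray(labels).astype(str))
    z = _centroid_distances(d, codes)
    f_obs = _anova_f(z, codes)
    grand = z.mean()
    ss_total = ((z - grand) ** 2).sum()
    groups = np.unique(codes)
    ss_b = sum(len(z[codes == g]) * (z[codes == g].mean() - grand) ** 2
               for g in groups)
    r2 = ss_b / ss_total if ss_total > 0 else 0.0
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        f_p = _anova_f(z, rng.permutation(codes))
        if f_p >= f_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    return PermanovaResult(f_obs, r2, p, n_perm)


def top_taxa_display(props: pd.DataFrame, n_top: int = 9) -> pd.DataFrame:
    """Keep the n_top taxa by grand mean abundance, pool the rest as Other."""
    means = props.mean(axis=0).sort_values(ascending=False)
    top = list(means.index[:n_top])
    rest = [c for c in props.columns if c not in top]
    out = props[top].copy()
    if rest:
        out["Other"] = props[rest].sum(axis=1)
    return out
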