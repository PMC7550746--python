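"""Self-organizing-map exposure profiles and cluster-validity consensus.

Participants are clustered on their standardized multipollutant
concentration vectors with a batch-trained Kohonen map: a small rectangular
grid of nodes, each carrying a codebook vector in chemical space.  Each
epoch assigns every sample to its best-matching unit (BMU, minimum
Euclidean distance) and then replaces every codebook vector by the
neighborhood-weighted mean of the samples, with a Gaussian neighborhood on
the grid whose radius anneals linearly and is then held at its final value
for the last stretch of epochs.  In the zero-radius limit an epoch is
exactly a Lloyd (k-means) step, so the map degenerates gracefully to
k-means while retaining its spatially ordered topology at larger radii.

Map size is chosen by consensus across five internal cluster-validity
statistics (within/between sum-of-squares ratio, Calinski-Harabasz, Dunn,
mean silhouette, Pearson Gamma) computed on the occupied nodes of every
candidate grid from 4 to 25 nodes: candidates are ranked per statistic and
the minimum mean rank wins, with ties resolved toward fewer profiles and
then toward the squarest grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .preprocess import StandardizedMatrix

__all__ = [
    "SOMParams",
    "SOMGrid",
    "SOMFit",
    "ValidityReport",
    "train_som",
    "assign_profiles",
    "cluster_validity",
    "candidate_grids",
    "select_som_size",
    "characterize_profiles",
    "adjusted_rand_index",
]

MIN_PROFILES, MAX_PROFILES = 4, 25


@dataclass(frozen=True)
class SOMParams:
    epochs: int = 60
    radius_initial: float | None = None  # default: max(rows, cols) / 2
    radius_final: float = 0.0
    #: fraction of epochs spent annealing; the radius then holds at
    #: ``radius_final`` so late epochs are plain Lloyd steps when it is 0
    anneal_fraction: float = 0.9
    init: str = "sample"  # or "pca"


@dataclass
class SOMGrid:
    rows: int
    cols: int
    codebook: np.ndarray  # (rows*cols, n_chemicals)
    params: SOMParams
    seed: int

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def node_coords(self) -> np.ndarray:
        r, c = np.divmod(np.arange(self.n_nodes), self.cols)
        return np.column_stack([r, c]).astype(float)


@dataclass
class SOMFit:
    grid: SOMGrid
    assignment: np.ndarray  # per-sample node index
    quantization_error: float
    qe_history: np.ndarray = field(repr=False, default=None)

    @property
    def occupied_profiles(self) -> np.ndarray:
        return np.unique(self.assignment)

    @property
    def n_occupied(self) -> int:
        return len(self.occupied_profiles)


@dataclass
class ValidityReport:
    table: pd.DataFrame  # per candidate: rows, cols, the 5 stats, ranks, mean_rank, selected
    selected: tuple[int, int]


def _as_array(X) -> np.ndarray:
    if isinstance(X, StandardizedMatrix):
        return X.values.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _bmu(X: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    # argmin resolves distance ties to the lowest node index
    return np.argmin(cdist(X, codebook, metric="sqeuclidean"), axis=1)


def _init_codebook(X: np.ndarray, n_nodes: int, params: SOMParams,
                   rng: np.random.Generator) -> np.ndarray:
    if params.init == "pca":
        mean = X.mean(axis=0)
        _, _, vt = np.linalg.svd(X - mean, full_matrices=False)
        rows = int(np.ceil(np.sqrt(n_nodes)))
        a = np.linspace(-2, 2, rows)
        grid_pts = np.array([(i, j) for i in a for j in a])[:n_nodes]
        return mean + grid_pts @ vt[:2]
    # draw from the unique rows so datasets differing only in row
    # multiplicity initialize (and hence train) identically
    Xu = np.unique(X, axis=0)
    replace = len(Xu) < n_nodes
    idx = rng.choice(len(Xu), size=n_nodes, replace=replace)
    return Xu[idx].copy()


def train_som(X, rows: int, cols: int, params: SOMParams | None = None,
              seed: int = 0) -> SOMFit:
    """Train a batch SOM; deterministic for a fixed seed.

    Rows are brought to a canonical (lexicographic) order before training,
    so both the seeded initialization and every floating-point reduction
    are invariant to the order samples arrive in.
    """
    params = params or SOMParams()
    Xin = _as_array(X)
    n_nodes = rows * cols
    if len(Xin) == 0:
        raise ValueError("empty input")
    if len(Xin) < n_nodes:
        raise ValueError(f"need at least {n_nodes} samples for a {rows}x{cols} map")
    order = np.lexsort(Xin.T[::-1])
    Xs = Xin[order]

    rng = np.random.default_rng(seed)
    codebook = _init_codebook(Xs, n_nodes, params, rng)
    coords = np.column_stack(np.divmod(np.arange(n_nodes), cols)).astype(float)
    grid_d2 = cdist(coords, coords, metric="sqeuclidean")
    r0 = params.radius_initial if params.radius_initial is not None else max(rows, cols) / 2.0
    rf = params.radius_final
    n_anneal = max(int(np.ceil(params.anneal_fraction * params.epochs)), 1)

    qe_hist = np.empty(params.epochs)
    for epoch in range(params.epochs):
        if epoch < n_anneal and n_anneal > 1:
            radius = r0 + (rf - r0) * epoch / (n_anneal - 1)
        else:
            radius = rf
        bmu = _bmu(Xs, codebook)
        d2 = cdist(Xs, codebook, metric="euclidean")
        qe_hist[epoch] = d2[np.arange(len(Xs)), bmu].mean()
        if radius > 1e-12:
            H = np.exp(-grid_d2 / (2 * radius**2))  # (nodes, nodes)
        else:
            H = np.eye(n_nodes)
        w = H[:, bmu]  # (nodes, samples): weight of each sample for each node
        denom = w.sum(axis=1)
        num = w @ Xs
        nonempty = denom > 1e-300
        codebook[nonempty] = num[nonempty] / denom[nonempty, None]
        # dead-unit repair: late in the anneal, re-seed one BMU-less node per
        # epoch onto the worst-fit sample; the final held-radius epochs are
        # left as plain Lloyd steps so the quantization error is monotone
        if radius < 1.0 and epoch < n_anneal - 1:
            hits = np.bincount(bmu, minlength=n_nodes)
            empty = np.flatnonzero(hits == 0)
            if len(empty):
                d_bmu = cdist(Xs, codebook, metric="sqeuclidean")[
                    np.arange(len(Xs)), _bmu(Xs, codebook)
                ]
                codebook[empty[0]] = Xs[np.argmax(d_bmu)]

    grid = SOMGrid(rows, cols, codebook, params, seed)
    assignment = _bmu(Xin, codebook)
    qe = cdist(Xin, codebook)[np.arange(len(Xin)), assignment].mean()
    return SOMFit(grid=grid, assignment=assignment, quantization_error=float(qe),
                  qe_history=qe_hist)


def assign_profiles(fit: SOMFit, X) -> np.ndarray:
    """Best-matching-unit label per sample; ties go to the lowest node index."""
    Xa = _as_array(X)
    if Xa.shape[1] != fit.grid.codebook.shape[1]:
        raise ValueError(
            f"dimension mismatch: {Xa.shape[1]} chemicals vs codebook {fit.grid.codebook.shape[1]}"
        )
    return _bmu(Xa, fit.grid.codebook)


# ---------------------------------------------------------------------------
# cluster validity
# ---------------------------------------------------------------------------

def cluster_validity(X, labels) -> dict[str, float]:
    """The five internal validity statistics on occupied clusters.

    wss_bss_ratio: sum of squared distances to cluster centroids over
    between-cluster sum of squares (total SS minus WSS); lower is better.
    calinski_harabasz: (BSS/(k-1)) / (WSS/(n-k)).
    dunn: minimum single-linkage inter-cluster distance over the maximum
    intra-cluster diameter.
    mean_silhouette: average silhouette width, singletons contributing 0.
    pearson_gamma: Pearson correlation between the pairwise-distance vector
    and the 0/1 different-cluster indicator.
    """
    Xa = _as_array(X)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k, n = len(uniq), len(Xa)
    if k < 2:
        raise ValueError("validity statistics need at least 2 occupied clusters")

    centroids = np.stack([Xa[labels == u].mean(axis=0) for u in uniq])
    wss = 0.0
    for u, cen in zip(uniq, centroids):
        diff = Xa[labels == u] - cen
        wss += float((diff**2).sum())
    grand = Xa.mean(axis=0)
    tss = float(((Xa - grand) ** 2).sum())
    bss = tss - wss
    wss_bss = wss / bss if bss > 0 else np.inf
    ch = (bss / (k - 1)) / (wss / (n - k)) if n > k and wss > 0 else np.inf

    D = squareform(pdist(Xa))
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    dvec = D[iu]
    gvec = (~same)[iu].astype(float)

    # Dunn
    max_diam = 0.0
    for u in uniq:
        mask = labels == u
        if mask.sum() > 1:
            max_diam = max(max_diam, float(D[np.ix_(mask, mask)].max()))
    inter = dvec[gvec == 1]
    min_inter = float(inter.min()) if len(inter) else np.inf
    if min_inter == 0.0:
        dunn = 0.0  # coincident clusters: no separation regardless of diameter
    elif max_diam > 0:
        dunn = min_inter / max_diam
    else:
        dunn = np.inf

    # silhouette with singleton s = 0
    sil = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own > 1:
            a = D[i, own].sum() / (n_own - 1)
            b = min(D[i, labels == u].mean() for u in uniq if u != labels[i])
            sil[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    mean_sil = float(sil.mean())

    sd_d, sd_g = dvec.std(), gvec.std()
    if sd_d > 0 and sd_g > 0:
        gamma = float(np.corrcoef(dvec, gvec)[0, 1])
    else:
        gamma = 0.0

    return {
        "wss_bss_ratio": float(wss_bss),
        "calinski_harabasz": float(ch),
        "dunn": float(dunn),
        "mean_silhouette": mean_sil,
        "pearson_gamma": gamma,
    }


# lower-is-better flag per statistic
_STAT_ASCENDING = {
    "wss_bss_ratio": True,
    "calinski_harabasz": False,
    "dunn": False,
    "mean_silhouette": False,
    "pearson_gamma": False,
}


def candidate_grids(lo: int = MIN_PROFILES, hi: int = MAX_PROFILES) -> list[tuple[int, int]]:
    """All (rows, cols) with rows <= cols and lo <= rows*cols <= hi."""
    out = []
    for r in range(1, int(np.sqrt(hi)) + 1):
        for c in range(r, hi + 1):
            if lo <= r * c <= hi:
                out.append((r, c))
    return sorted(out, key=lambda rc: (rc[0] * rc[1], rc[1] - rc[0]))


def select_som_size(
    X,
    candidates: list[tuple[int, int]] | None = None,
    params: SOMParams | None = None,
    seed: int = 0,
) -> tuple[ValidityReport, SOMFit]:
    """Train every candidate grid and pick the validity-consensus winner.

    Each candidate is trained with the shared seed; the five statistics are
    computed on its occupied-node assignment and ranked across candidates
    (rank 1 best).  The candidate with the lowest mean rank is selected;
    ties break toward fewer profiles, then the squarest shape.  Candidates
    collapsing to a single occupied node are dropped as degenerate.
    """
    Xa = _as_array(X)
    if candidates is None:
        candidates = [rc for rc in candidate_grids() if rc[0] * rc[1] <= len(Xa)]
    rows_out, fits = [], {}
    for r, c in candidates:
        if not MIN_PROFILES <= r * c <= MAX_PROFILES:
            raise ValueError(f"candidate {r}x{c} outside the {MIN_PROFILES}-{MAX_PROFILES} profile range")
        fit = train_som(Xa, r, c, params=params, seed=seed)
        if fit.n_occupied < 2:
            continue
        stats_ = cluster_validity(Xa, fit.assignment)
        fits[(r, c)] = fit
        rows_out.append({"rows": r, "cols": c, "n_profiles": r * c,
                         "n_occupied": fit.n_occupied, **stats_})
    if not rows_out:
        raise ValueError("all candidate maps degenerate (single occupied node)")
    table = pd.DataFrame(rows_out)
    for stat, asc in _STAT_ASCENDING.items():
        vals = table[stat] if asc else -table[stat]
        # ordinal ranking keeps ranks a permutation even under ties
        table[f"rank_{stat}"] = vals.rank(method="first").astype(int)
    rank_cols = [f"rank_{s}" for s in _STAT_ASCENDING]
    table["mean_rank"] = table[rank_cols].mean(axis=1)
    order = table.sort_values(
        ["mean_rank", "n_profiles"],
        kind="mergesort",
    ).copy()
    best_rank, best_n = order.iloc[0][["mean_rank", "n_profiles"]]
    tied = order[(order["mean_rank"] == best_rank) & (order["n_profiles"] == best_n)]
    tied = tied.assign(squareness=(tied["cols"] - tied["rows"]).abs()).sort_values(
        ["squareness", "rows"], kind="mergesort"
    )
    sel = (int(tied.iloc[0]["rows"]), int(tied.iloc[0]["cols"]))
    table["selected"] = [(r, c) == sel for r, c in zip(table["rows"], table["cols"])]
    return ValidityReport(table=table, selected=sel), fits[sel]


# ---------------------------------------------------------------------------
# profile characterization
# ---------------------------------------------------------------------------

def characterize_profiles(
    fit: SOMFit,
    std: StandardizedMatrix,
    cov=None,
    min_n: int = 10,
    exceptional_threshold: float = 1.0,
) -> dict:
    """Describe each occupied profile chemically and demographically.

    Per profile: membership count, per-chemical median standardized
    concentration, and the chemicals whose profile median is at least
    ``exceptional_threshold`` standardized SDs (flagged "exceptional", the
    profiles' defining high exposures).  Profiles with fewer than ``min_n``
    members are listed as rare and excluded from the covariate breakdown.
    Covariates summarize as medians (continuous) or rounded percentages per
    level (categorical).
    """
    labels = fit.assignment
    values = std.values
    n = len(values)
    profiles = {}
    rare = []
    cov_df = None
    if cov is not None:
        cov_df = cov.data if hasattr(cov, "data") else cov
        cov_df = cov_df.loc[std.samples["participant_id"]]
    for node in fit.occupied_profiles:
        mask = labels == node
        med = values[mask].median(axis=0)
        exceptional = sorted(med[med >= exceptional_threshold].index)
        entry = {
            "n": int(mask.sum()),
            "share": round(float(mask.mean()), 4),
            "median_standardized": med,
            "exceptional_chemicals": exceptional,
            "rare": bool(mask.sum() < min_n),
        }
        if entry["rare"]:
            rare.append(int(node))
        elif cov_df is not None:
            summary = {}
            sub = cov_df[mask]
            for col in cov_df.columns:
                s = sub[col]
                if pd.api.types.is_numeric_dtype(s):
                    summary[col] = {"median": float(s.median())}
                else:
                    pct = (s.value_counts(normalize=True) * 100).round().astype(int)
                    summary[col] = pct.to_dict()
            entry["covariates"] = summary
        profiles[int(node)] = entry
    return {
        "n_samples": n,
        "n_grid_nodes": fit.grid.n_nodes,
        "n_occupied": fit.n_occupied,
        "rare_profiles": rare,
        "profiles": profiles,
    }


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement between two labelings."""
    a, b = np.asarray(a), np.asarray(b)
    ua, ub = np.unique(a, return_inverse=True)[1], np.unique(b, return_inverse=True)[1]
    contingency = np.zeros((ua.max() + 1, ub.max() + 1))
    np.add.at(contingency, (ua, ub), 1)
    comb2 = lambda x: x * (x - 1) / 2.0
    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    n = comb2(len(a))
    expected = sum_a * sum_b / n
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
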