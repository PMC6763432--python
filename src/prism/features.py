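"""Single-synapse feature tables and the downstream statistics.

One row per synapse with per-channel integrated intensity, area and mean
intensity (zero when no colocalized punctum exists); well-level two-stage
averaging; pairwise Pearson correlation networks; treatment comparisons by
two-tailed Student's t-test on well means; normalization, t-SNE embedding,
kernel-density sub-type maps and Ward hierarchical clustering of synapse
profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.ndimage import maximum_filter
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

__all__ = [
    "CorrelationNetwork",
    "GroupComparison",
    "extract_features",
    "summarize_wells",
    "pairwise_correlations",
    "compare_groups",
    "correlation_difference_test",
    "normalize_for_embedding",
    "embed_tsne",
    "density_regions",
    "cluster_profiles",
]


@dataclass(frozen=True)
class CorrelationNetwork:
    """Channels as nodes, mean Pearson r as edge weights above a strict threshold."""

    channels: list[str]
    matrix: pd.DataFrame  # symmetric, unit diagonal, mean r over groups
    threshold: float

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"a": a, "b": b, "r": self.matrix.loc[a, b]}
            for a, b in combinations(self.channels, 2)
            if self.matrix.loc[a, b] > self.threshold
        ]
        return pd.DataFrame(rows, columns=["a", "b", "r"])

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.channels)
        for _, row in self.edges.iterrows():
            g.add_edge(row["a"], row["b"], weight=row["r"])
        return g


@dataclass(frozen=True)
class GroupComparison:
    """Per feature: group means relative to untreated, 95% CI, t statistic, p-value."""

    table: pd.DataFrame


def extract_features(
    synapses,
    assignments: dict[str, pd.DataFrame],
    puncta_sets: dict,
    corrected_images: dict[str, np.ndarray] | None = None,
    non_synaptic_channels: tuple[str, ...] = (),
    well: str = "A1",
    image_id: str = "0",
) -> pd.DataFrame:
    """Build the per-synapse feature table.

    For each synaptic channel the colocalized punctum's integrated
    intensity and area are recorded (zero for both when no punctum lies
    within the colocalization radius); mean intensity = integrated / area.
    Non-synaptic channels (MAP2, Tuj-1) are measured as the mean pixel
    intensity of the corrected image within the synapsin punctum footprint.
    """
    syn_tab = synapses.table
    out = pd.DataFrame(
        {
            "synapse_id": syn_tab["id"].to_numpy(),
            "well": well,
            "image_id": image_id,
            "x": syn_tab["x"].to_numpy(),
            "y": syn_tab["y"].to_numpy(),
        }
    )
    for ch, assign in assignments.items():
        pset = puncta_sets[ch]
        ptab = pset.table.set_index("id")
        inten = np.zeros(len(syn_tab))
        area = np.zeros(len(syn_tab))
        for i, row in assign.reset_index(drop=True).iterrows():
            pid = int(row["punctum_id"])
            if pid < 0:
                continue
            if pid not in ptab.index:
                raise KeyError(f"assignment references missing punctum {pid} in {ch}")
            inten[i] = ptab.loc[pid, "integrated_intensity"]
            area[i] = ptab.loc[pid, "area_um2"]
        out[f"{ch}_intensity"] = inten
        out[f"{ch}_area_um2"] = area
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"{ch}_mean_intensity"] = np.where(area > 0, inten / area, 0.0)
    if corrected_images and non_synaptic_channels:
        syn_labels = puncta_sets["__synapsin_labels__"]
        for ch in non_synaptic_channels:
            img = corrected_images[ch]
            vals = np.zeros(len(syn_tab))
            for i, sid in enumerate(syn_tab["id"].to_numpy()):
                mask = syn_labels == sid
                vals[i] = img[mask].mean() if mask.any() else 0.0
            out[f"{ch}_mean_intensity"] = vals
    return out


def summarize_wells(table: pd.DataFrame, feature_columns: list[str] | None = None) -> pd.DataFrame:
    """Two-stage averaging: synapses -> per-image means -> per-well means.

    Images are weighted equally within a well regardless of their synapse
    counts (the per-image mean, not the pooled mean, is averaged).
    """
    if feature_columns is None:
        feature_columns = [
            c
            for c in table.columns
            if c not in ("synapse_id", "well", "image_id", "x", "y", "treatment", "batch")
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    keep_meta = [c for c in ("treatment", "batch") if c in table.columns]
    per_image = table.groupby(["well", "image_id"], sort=True)[feature_columns].mean()
    per_well = per_image.groupby(level="well", sort=True).mean().reset_index()
    if keep_meta:
        meta = table.groupby("well", sort=True)[keep_meta].first().reset_index()
        per_well = per_well.merge(meta, on="well")
    empty = table.groupby("well")[feature_columns[0]].count() == 0
    if empty.any():
        warnings.warn(f"excluding empty wells: {list(empty[empty].index)}")
    return per_well


def pairwise_correlations(
    table: pd.DataFrame,
    channels: list[str],
    by: str = "batch",
    feature: str = "intensity",
    threshold: float = 0.35,
) -> CorrelationNetwork:
    """Mean per-group Pearson correlation between channel intensities.

    Pearson r is computed between every channel pair within each group
    (culture batch or well), averaged over groups; network edges connect
    pairs whose mean r is strictly greater than the threshold.
    """
    cols = {ch: f"{ch}_{feature}" for ch in channels}
    groups = list(table.groupby(by)) if by in table.columns else [("all", table)]
    k = len(channels)
    acc = np.zeros((k, k))
    cnt = np.zeros((k, k))
    for gname, g in groups:
        if len(g) < 3:
            warnings.warn(f"group {gname!r} has fewer than 3 synapses; skipped")
            continue
        for i, j in combinations(range(k), 2):
            a = g[cols[channels[i]]].to_numpy(float)
            b = g[cols[channels[j]]].to_numpy(float)
            if a.std() == 0 or b.std() == 0:
                warnings.warn(
                    f"zero-variance channel in group {gname!r}: pair "
                    f"({channels[i]}, {channels[j]}) skipped for this group"
                )
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            acc[i, j] += r
            cnt[i, j] += 1
    mean_r = np.eye(k)
    for i, j in combinations(range(k), 2):
        mean_r[i, j] = mean_r[j, i] = acc[i, j] / cnt[i, j] if cnt[i, j] else np.nan
    mat = pd.DataFrame(mean_r, index=channels, columns=channels)
    return CorrelationNetwork(channels=list(channels), matrix=mat, threshold=threshold)


def compare_groups(
    well_table: pd.DataFrame,
    untreated_label: str,
    treated_label: str,
    feature_columns: list[str] | None = None,
    group_column: str = "treatment",
    welch: bool = False,
) -> GroupComparison:
    """Compare treated and untreated wells feature by feature.

    Well means are scaled relative to the untreated group mean; the
    two-sample two-tailed Student's t-test (pooled variance by default,
    Welch behind a flag) is applied to well values, and 95% confidence
    intervals of the relative group means are reported.
    """
    g0 = well_table[well_table[group_column] == untreated_label]
    g1 = well_table[well_table[group_column] == treated_label]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("need at least 2 wells per group")
    if feature_columns is None:
        feature_columns = [
            c
            for c in well_table.columns
            if c not in ("well", group_column, "batch")
            and pd.api.types.is_numeric_dtype(well_table[c])
        ]
    rows = []
    for col in feature_columns:
        a = g0[col].to_numpy(float)
        b = g1[col].to_numpy(float)
        ref = a.mean()
        scale = ref if ref != 0 else 1.0
        t, p = stats.ttest_ind(b, a, equal_var=not welch)
        if np.isnan(t):  # identical zero-variance groups
            t, p = 0.0, 1.0
        rows.append(
            {
                "feature": col,
                "untreated_mean": ref,
                "treated_mean": b.mean(),
                "relative_untreated": 1.0,
                "relative_treated": b.mean() / scale,
                "ci95_untreated_half": _ci95_half(a) / abs(scale),
                "ci95_treated_half": _ci95_half(b) / abs(scale),
                "t": float(t),
                "p": float(p),
                "n_untreated": len(a),
                "n_treated": len(b),
            }
        )
    return GroupComparison(table=pd.DataFrame(rows))


def _ci95_half(x: np.ndarray) -> float:
    if len(x) < 2 or x.std(ddof=1) == 0:
        return 0.0
    return float(stats.t.ppf(0.975, len(x) - 1) * stats.sem(x))


def per_well_correlations(
    table: pd.DataFrame, channels: list[str], feature: str = "intensity"
) -> pd.DataFrame:
    """Pearson r of every channel pair computed separately in each well."""
    cols = {ch: f"{ch}_{feature}" for ch in channels}
    meta_cols = [c for c in ("treatment", "batch") if c in table.columns]
    rows = []
    for well, g in table.groupby("well"):
        rec: dict = {"well": well}
        for c in meta_cols:
            rec[c] = g[c].iloc[0]
        for a, b in combinations(channels, 2):
            va = g[cols[a]].to_numpy(float)
            vb = g[cols[b]].to_numpy(float)
            rec[f"{a}|{b}"] = (
                float(np.corrcoef(va, vb)[0, 1]) if va.std() and vb.std() and len(g) > 2 else np.nan
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def correlation_difference_test(
    well_corr: pd.DataFrame,
    untreated_label: str,
    treated_label: str,
    group_column: str = "treatment",
    replicate_column: str = "batch",
) -> pd.DataFrame:
    """Replicate-centered t-test on per-well pairwise correlations.

    Within each biological replicate, the mean untreated correlation is
    subtracted from every well's correlation for that pair; treated and
    untreated differences are then compared by a two-tailed Student's
    t-test per channel pair.
    """
    pair_cols = [c for c in well_corr.columns if "|" in c]
    for rep, g in well_corr.groupby(replicate_column):
        if not (g[group_column] == untreated_label).any():
            raise ValueError(f"replicate {rep!r} has no untreated wells")
    centered = well_corr.copy()
    for rep, g in well_corr.groupby(replicate_column):
        base = g.loc[g[group_column] == untreated_label, pair_cols].mean()
        centered.loc[g.index, pair_cols] = g[pair_cols] - base
    rows = []
    for col in pair_cols:
        a = centered.loc[centered[group_column] == untreated_label, col].dropna().to_numpy()
        b = centered.loc[centered[group_column] == treated_label, col].dropna().to_numpy()
        t, p = stats.ttest_ind(b, a, equal_var=True)
        if np.isnan(t):
            t, p = 0.0, 1.0
        rows.append(
            {
                "pair": col,
                "mean_diff_untreated": a.mean() if len(a) else np.nan,
                "mean_diff_treated": b.mean() if len(b) else np.nan,
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def normalize_for_embedding(
    table: pd.DataFrame, feature_columns: list[str], pseudocount: float = 1.0
) -> pd.DataFrame:
    """log-transform and normalize features for embedding/clustering.

    x -> log(x + pseudocount), then divide by the standard deviation, then
    subtract the minimum; every output column has sd 1 and min 0.  The
    pseudocount handles the exact zeros produced by the
    no-colocalized-punctum rule.  Zero-variance features are dropped with a
    warning.
    """
    out = {}
    for col in feature_columns:
        x = np.log(table[col].to_numpy(float) + pseudocount)
        sd = x.std()
        if sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
            warnings.warn(f"dropping zero-variance feature {col!r}")
            continue
        x = x / sd
        out[col] = x - x.min()
    return pd.DataFrame(out, index=table.index)


def embed_tsne(
    matrix: pd.DataFrame | np.ndarray,
    perplexity: float = 40.0,
    n_iter: int = 5000,
    subsample: int | None = 10000,
    seed: int = 0,
) -> np.ndarray:
    """2D t-SNE embedding of normalized synapse profiles.

    Exact-gradient t-SNE with PCA initialization; rows are randomly
    subsampled (seeded) when the table exceeds ``subsample``.  The
    embedding itself is a standard algorithm — the defined part of this
    pipeline is the preprocessing and the parameters.
    """
    X = np.asarray(matrix, float)
    rng = np.random.default_rng(seed)
    if subsample is not None and len(X) > subsample:
        X = X[rng.choice(len(X), size=subsample, replace=False)]
    if len(X) <= 3 * perplexity:
        raise ValueError(f"need more than 3x perplexity = {3 * perplexity:.0f} samples")
    init = PCA(n_components=2, random_state=seed).fit_transform(X)
    init = init / np.maximum(init[:, 0].std(), 1e-12) * 1e-4
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=n_iter,
        method="exact",
        init=init,
        random_state=seed,
    )
    return ts.fit_transform(X)


def density_regions(
    coords: np.ndarray,
    bandwidth: str | float = "scott",
    grid_size: int = 100,
    mode_quantile: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Kernel density estimate of an embedding with candidate sub-type modes.

    Gaussian KDE evaluated on a square grid; local maxima whose density
    exceeds the given quantile of the positive grid densities are reported
    as candidate sub-type centers.  With near-uniform data the mode count
    is unstable and flagged low-confidence.
    """
    coords = np.asarray(coords, float)
    if len(coords) < 10:
        raise ValueError("need at least 10 points for a density map")
    kde = stats.gaussian_kde(coords.T, bw_method=bandwidth)
    # pad the grid by several kernel widths so the density mass is captured
    bw = np.sqrt(np.diag(kde.covariance))
    pad = 0.05 * (coords.max(0) - coords.min(0) + 1e-9) + 4.0 * bw
    x = np.linspace(coords[:, 0].min() - pad[0], coords[:, 0].max() + pad[0], grid_size)
    y = np.linspace(coords[:, 1].min() - pad[1], coords[:, 1].max() + pad[1], grid_size)
    xx, yy = np.meshgrid(x, y)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid_size, grid_size)
    cell = (x[1] - x[0]) * (y[1] - y[0])
    local_max = (dens == maximum_filter(dens, size=5)) & (
        dens > np.quantile(dens[dens > 0], mode_quantile)
    )
    my, mx = np.nonzero(local_max)
    modes = np.column_stack([x[mx], y[my]])
    dens_at_modes = dens[my, mx]
    # flat densities => many shallow maxima => low confidence; assess relief
    # inside the data's bounding box so grid padding does not inflate it
    in_x = (x >= coords[:, 0].min()) & (x <= coords[:, 0].max())
    in_y = (y >= coords[:, 1].min()) & (y <= coords[:, 1].max())
    core = dens[np.ix_(in_y, in_x)]
    relief = (core.max() - np.median(core)) / core.max() if core.max() > 0 else 0.0
    info = {
        "mode_density": dens_at_modes,
        "integral": float(dens.sum() * cell),
        "low_confidence": bool(relief < 0.5),
        "grid_x": x,
        "grid_y": y,
    }
    return dens, modes, info


def cluster_profiles(matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Ward hierarchical clustering of synapses and of features.

    Agglomerative clustering with the Euclidean metric and Ward linkage,
    applied both over rows (synapses) and over columns (features);
    returns (row_linkage, feature_linkage) in scipy linkage format.
    """
    X = np.asarray(matrix, float)
    if np.isnan(X).any():
        raise ValueError("NaN features cannot be clustered")
    row_link = linkage(X, method="ward", metric="euclidean")
    feat_link = linkage(X.T, method="ward", metric="euclidean")
    return row_link, feat_link
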