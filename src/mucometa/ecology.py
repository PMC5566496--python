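"""Mucosal community ecology statistics.

Rarefaction by subsampling to the lowest read count, Shannon diversity and a
per-sample Tau similarity index (mean Kendall tau-b against the rest of the
cohort), normalization of indices to each patient's on-tumour value,
Bray-Curtis dissimilarity with Ward-linkage clustering and patient
concordance detection, nonmetric multidimensional scaling (NMDS), and the
univariate genus-histology and cluster-histology association tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OtuTable",
    "Dendrogram",
    "NmdsResult",
    "rarefy",
    "relative_abundance",
    "shannon_index",
    "tau_index",
    "normalize_index_to_tumour",
    "bray_curtis",
    "ward_cluster",
    "patient_concordance",
    "nmds",
    "taxon_feature_tests",
    "cluster_feature_association",
]


@dataclass
class OtuTable:
    """Samples x genera integer counts with patient/site links."""

    counts: pd.DataFrame          # index = sample ids, columns = genus names
    patient_ids: pd.Series
    sites: pd.Series

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids {dup}")
        vals = c.to_numpy()
        if (vals < 0).any() or not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        for s in (self.patient_ids, self.sites):
            if not s.index.equals(c.index):
                raise ValueError("metadata index does not match count table")

    @classmethod
    def from_frames(cls, counts: pd.DataFrame, meta: pd.DataFrame) -> "OtuTable":
        meta = meta.loc[counts.index]
        return cls(counts=counts, patient_ids=meta["patient_id"], sites=meta["site"])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genus_names(self) -> list[str]:
        return list(self.counts.columns)


def rarefy(t: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Subsample every row without replacement to exactly ``depth`` reads.

    Defaults to the lowest row sum, matching normalization to the lowest
    number of reads.  Rows already at ``depth`` are returned unchanged.
    """
    sums = t.counts.sum(axis=1)
    if depth is None:
        depth = int(sums.min())
    if (sums < depth).any():
        bad = sums.index[sums < depth].tolist()
        raise ValueError(f"depth {depth} exceeds the read count of samples {bad}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(t.counts.to_numpy())
    for i, (_, row) in enumerate(t.counts.iterrows()):
        vals = row.to_numpy()
        if vals.sum() == depth:
            out[i] = vals
        else:
            out[i] = rng.multivariate_hypergeometric(vals, depth)
    counts = pd.DataFrame(out, index=t.counts.index, columns=t.counts.columns)
    return OtuTable(counts=counts, patient_ids=t.patient_ids, sites=t.sites)


def relative_abundance(t: OtuTable) -> pd.DataFrame:
    sums = t.counts.sum(axis=1)
    if (sums == 0).any():
        bad = sums.index[sums == 0].tolist()
        raise ValueError(f"all-zero rows {bad}")
    return t.counts.div(sums, axis=0)


# ------------------------------------------------------------------ indices


def shannon_index(p: np.ndarray) -> float:
    """Shannon diversity H = -sum p ln p (natural log) over p > 0."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundance")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("abundances must sum to 1; normalize the count row first")
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def shannon_per_sample(t: OtuTable) -> pd.Series:
    rel = relative_abundance(t)
    return rel.apply(lambda row: shannon_index(row.to_numpy()), axis=1)


def tau_index(t: OtuTable, sample_id: str) -> float:
    """Mean Kendall tau-b between one sample's genus vector and all others.

    A per-sample community-similarity score: 1 when the sample ranks genera
    exactly like every other sample.  NaN (reported missing) when the
    sample's abundance vector is constant, where rank correlation is
    undefined.
    """
    if len(t.counts) < 2:
        raise ValueError("tau index needs at least 2 samples")
    x = t.counts.loc[sample_id].to_numpy(dtype=float)
    if np.all(x == x[0]):
        return float("nan")
    taus = []
    for other in t.counts.index:
        if other == sample_id:
            continue
        y = t.counts.loc[other].to_numpy(dtype=float)
        if np.all(y == y[0]):
            continue
        taus.append(stats.kendalltau(x, y).statistic)
    return float(np.mean(taus)) if taus else float("nan")


def tau_per_sample(t: OtuTable) -> pd.Series:
    return pd.Series({sid: tau_index(t, sid) for sid in t.counts.index})


def normalize_index_to_tumour(
    values: pd.Series, patient_ids: pd.Series, sites: pd.Series, tumour_site: str = "tumour"
) -> pd.Series:
    """Divide each sample's index by its patient's on-tumour value."""
    tumour_value: dict = {}
    for sid in values.index:
        if sites.loc[sid] == tumour_site:
            tumour_value[patient_ids.loc[sid]] = values.loc[sid]
    out = {}
    for sid in values.index:
        pid = patient_ids.loc[sid]
        if pid not in tumour_value:
            raise ValueError(f"patient {pid} has no {tumour_site} sample")
        tv = tumour_value[pid]
        if tv == 0:
            raise ValueError(f"patient {pid} has a zero on-tumour index value")
        out[sid] = values.loc[sid] / tv
    return pd.Series(out)


# -------------------------------------------------------- distances & trees


def bray_curtis(t: OtuTable) -> pd.DataFrame:
    """Bray-Curtis dissimilarity d(u,v) = sum|u-v| / sum(u+v), in [0, 1]."""
    X = t.counts.to_numpy(dtype=float)
    if (X.sum(axis=1) == 0).any():
        raise ValueError("all-zero rows have undefined Bray-Curtis distance")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=t.counts.index, columns=t.counts.index)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over samples (scipy linkage encoding)."""

    linkage: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if (np.diff(heights) < -1e-10).any():
            raise ValueError("merge heights must be non-decreasing")

    def cut(self, k: int) -> pd.Series:
        if k > len(self.sample_ids):
            raise ValueError(f"cannot cut {len(self.sample_ids)} leaves into {k} clusters")
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.sample_ids[node.id]
            left, right = rec(node.left), rec(node.right)
            dl = node.dist - (0 if node.left.is_leaf() else node.left.dist)
            dr = node.dist - (0 if node.right.is_leaf() else node.right.dist)
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return rec(tree) + ";"


def ward_cluster(D: pd.DataFrame, k: int | None = None) -> Dendrogram:
    """Ward-linkage agglomeration of a precomputed distance matrix.

    Uses the Lance-Williams Ward update on the supplied dissimilarities
    (Bray-Curtis here, which is not Euclidean; merge heights remain
    monotone).
    """
    ids = list(D.index)
    if k is not None and k > len(ids):
        raise ValueError(f"k={k} exceeds sample count {len(ids)}")
    condensed = squareform(D.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method="ward")
    return Dendrogram(linkage=Z, sample_ids=ids)


def patient_concordance(
    dend: Dendrogram, patient_ids: Mapping[str, str] | pd.Series
) -> tuple[pd.Series, int]:
    """Which patients' samples form a private subtree of the dendrogram.

    A patient is concordant iff the smallest subtree containing all of that
    patient's samples contains no other patient's samples — the criterion
    behind counting individuals whose on-tumour, 5 cm and 10 cm biopsies
    cluster together.  Returns the per-patient booleans and the count.
    """
    ids = dend.sample_ids
    patient = pd.Series({sid: patient_ids[sid] for sid in ids})
    tree = hierarchy.to_tree(dend.linkage)
    leafsets: dict[int, frozenset[int]] = {}

    def collect(node) -> frozenset[int]:
        if node.is_leaf():
            leafsets[node.id] = frozenset([node.id])
        else:
            leafsets[node.id] = collect(node.left) | collect(node.right)
        return leafsets[node.id]

    collect(tree)
    result = {}
    for pid in patient.unique():
        want = frozenset(i for i, sid in enumerate(ids) if patient[sid] == pid)
        if len(want) < 2:
            raise ValueError(f"patient {pid} has fewer than 2 samples in the tree")
        # smallest node covering all of the patient's leaves
        best = min(
            (ls for ls in leafsets.values() if want <= ls),
            key=len,
        )
        result[pid] = best == want
    flags = pd.Series(result)
    return flags, int(flags.sum())


# --------------------------------------------------------------------- NMDS


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float               # Kruskal stress-1
    n_restarts: int
    best_seed: int
    converged: bool
    all_stresses: np.ndarray


def nmds(
    D: pd.DataFrame,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
) -> NmdsResult:
    """Nonmetric MDS minimizing Kruskal stress-1.

    Iterative majorization (SMACOF) with monotone regression of the fitted
    distances on the observed dissimilarities; the best of ``n_restarts``
    random starts is returned, and its stress is <= the stress of every
    restart by construction.
    """
    Dm = np.asarray(D, dtype=float)
    n = Dm.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    seeds = np.random.SeedSequence(seed).generate_state(n_restarts)
    best = None
    stresses = []
    for s in seeds:
        s = int(s % (2**31 - 1))
        coords, stress, n_iter = smacof(
            Dm,
            metric=False,
            n_components=k,
            init=None,
            n_init=1,
            max_iter=max_iter,
            eps=1e-9,
            random_state=s,
            normalized_stress=True,
            return_n_iter=True,
        )
        stresses.append(stress)
        if best is None or stress < best[1]:
            best = (coords, stress, s, n_iter < max_iter)
    coords, stress, best_seed, converged = best
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return NmdsResult(
        coordinates=pd.DataFrame(coords, index=D.index, columns=cols),
        stress=float(stress),
        n_restarts=n_restarts,
        best_seed=best_seed,
        converged=bool(converged),
        all_stresses=np.asarray(stresses),
    )


# ------------------------------------------------------- univariate testing


def taxon_feature_tests(
    t: OtuTable, feature: pd.Series, ordinal: bool = False
) -> pd.DataFrame:
    """Per-genus rank tests of relative abundance against a clinical feature.

    Binary features use a two-sided Mann-Whitney U; ordinal features (e.g. T
    stage) use Kruskal-Wallis across levels.  Direction is the sign of the
    median difference (top minus bottom level); BH-FDR q accompanies each raw
    p.  All-zero genera get p = 1 by convention.
    """
    rel = relative_abundance(t)
    f = feature.loc[rel.index]
    levels = sorted(f.unique())
    if len(levels) < 2:
        raise ValueError("feature has a single level")
    if not ordinal and len(levels) != 2:
        raise ValueError("binary test requested for a feature with >2 levels")
    rows = []
    for genus in rel.columns:
        x = rel[genus]
        if (t.counts[genus] == 0).all():
            rows.append((genus, 0, 1.0))
            continue
        grouped = [x[f == lv].to_numpy() for lv in levels]
        direction = int(np.sign(np.median(grouped[-1]) - np.median(grouped[0])))
        if ordinal:
            stat = stats.kruskal(*grouped)
        else:
            stat = stats.mannwhitneyu(grouped[0], grouped[1], alternative="two-sided")
        p = float(stat.pvalue) if np.isfinite(stat.pvalue) else 1.0
        rows.append((genus, direction, p))
    out = pd.DataFrame(rows, columns=["genus", "direction", "p"]).set_index("genus")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def cluster_feature_association(
    clusters: pd.Series, features: pd.DataFrame, ordinal: Sequence[str] = ()
) -> pd.DataFrame:
    """Association of cluster membership with clinical features.

    Categorical features use Fisher's exact test for 2x2 tables and the
    chi-square test for larger tables; features named in ``ordinal`` use
    Kruskal-Wallis of the feature level across clusters.
    """
    if clusters.nunique() < 2:
        raise ValueError("need at least two clusters")
    rows = []
    for col in features.columns:
        f = features[col].loc[clusters.index]
        if f.nunique() < 2:
            raise ValueError(f"feature {col!r} has a single level")
        if col in ordinal:
            groups = [f[clusters == c].to_numpy(dtype=float) for c in sorted(clusters.unique())]
            stat = stats.kruskal(*groups)
            rows.append((col, "kruskal-wallis", float(stat.pvalue)))
            continue
        table = pd.crosstab(clusters, f).to_numpy()
        if table.shape == (2, 2):
            _, p = stats.fisher_exact(table)
            rows.append((col, "fisher-exact", float(p)))
        else:
            chi = stats.chi2_contingency(table)
            rows.append((col, "chi-square", float(chi.pvalue)))
    return pd.DataFrame(rows, columns=["feature", "test", "p"]).set_index("feature")
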