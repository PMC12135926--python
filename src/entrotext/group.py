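"""Group-level comparison: one-way ANOVA, mean ranking and 2-D embedding.

Each of the six entropy features is compared across classes with a classical
(equal-variance) one-way ANOVA, F = (SSB/df_b)/(SSW/df_w), followed by
pairwise mean differences with Tukey-HSD-adjusted p values (unadjusted
pairwise t tests — "LSD" — by flag). Classes are additionally ranked by
group mean per feature, and the whole table is embedded in 2-D with t-SNE
for visual inspection of class structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE
from sklearn.preprocessing import StandardScaler

from entrotext.features import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class PairwiseDiff:
    """Mean difference (I − J) between two classes with adjusted p value."""

    class_i: str
    class_j: str
    mean_difference: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL

    @property
    def stars(self) -> str:
        return "*" if self.significant else ""


@dataclass
class AnovaResult:
    feature: str
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    pairwise: list[PairwiseDiff] = field(default_factory=list)


@dataclass
class GroupRanking:
    """Class labels ordered by descending group mean for one feature."""

    feature: str
    ordered_labels: list[str]
    means: dict[str, float]
    tie: bool = False


@dataclass
class Embedding2D:
    coords: pd.DataFrame  # columns: doc_id, class_label, x, y
    seed: int
    perplexity: float


def _groups(table: pd.DataFrame, feature: str) -> dict[str, np.ndarray]:
    return {
        label: sub[feature].to_numpy(dtype=float)
        for label, sub in table.groupby("class_label", sort=True)
    }


def one_way_anova(groups: dict[str, np.ndarray], feature: str = "") -> AnovaResult:
    """Classical one-way ANOVA omnibus test over labelled groups."""
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups, got {len(groups)}")
    arrays = list(groups.values())
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs >= 2 observations")
    means = [a.mean() for a in arrays]
    if all(a.var() == 0.0 for a in arrays) and len(set(means)) > 1:
        raise ValueError("zero within-group variance with unequal means: F undefined")
    f_stat, p_value = stats.f_oneway(*arrays)
    n_total = sum(len(a) for a in arrays)
    return AnovaResult(
        feature=feature,
        f_statistic=float(f_stat),
        p_value=float(p_value),
        df_between=len(groups) - 1,
        df_within=n_total - len(groups),
    )


def pairwise_mean_differences(
    groups: dict[str, np.ndarray], feature: str = "", method: str = "tukey"
) -> list[PairwiseDiff]:
    """All ordered pairwise mean differences with post-hoc p values.

    ``method="tukey"`` (default) uses Tukey's HSD; ``method="lsd"`` uses
    unadjusted two-sample t tests. Differences are exactly antisymmetric:
    the (J, I) entry is the negation of (I, J) with the same p value.
    """
    if method not in ("tukey", "lsd"):
        raise ValueError(f"method must be 'tukey' or 'lsd', got {method!r}")
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups for pairwise comparison")
    arrays = [groups[lab] for lab in labels]
    means = {lab: float(groups[lab].mean()) for lab in labels}

    p_lookup: dict[frozenset, float] = {}
    if method == "tukey":
        res = stats.tukey_hsd(*arrays)
        for i, li in enumerate(labels):
            for j, lj in enumerate(labels):
                if i < j:
                    p_lookup[frozenset((li, lj))] = float(res.pvalue[i, j])
    else:
        for i, li in enumerate(labels):
            for j, lj in enumerate(labels):
                if i < j:
                    _, p = stats.ttest_ind(groups[li], groups[lj])
                    p_lookup[frozenset((li, lj))] = float(p)

    out: list[PairwiseDiff] = []
    for li, lj in permutations(labels, 2):
        out.append(
            PairwiseDiff(
                class_i=li,
                class_j=lj,
                mean_difference=means[li] - means[lj],
                p_value=p_lookup[frozenset((li, lj))],
            )
        )
    return out


def analyze_features(
    table: pd.DataFrame, method: str = "tukey"
) -> list[AnovaResult]:
    """Omnibus ANOVA plus pairwise differences for each of the six features."""
    results = []
    for feature in FEATURE_COLUMNS:
        groups = _groups(table, feature)
        res = one_way_anova(groups, feature)
        res.pairwise = pairwise_mean_differences(groups, feature, method=method)
        results.append(res)
    return results


def anova_table(results: list[AnovaResult]) -> pd.DataFrame:
    """Flatten ANOVA results into a report table (one row per ordered pair)."""
    rows = []
    for res in results:
        for pw in res.pairwise:
            rows.append({
                "feature": res.feature,
                "class_i": pw.class_i,
                "class_j": pw.class_j,
                "mean_difference": pw.mean_difference,
                "p_value": pw.p_value,
                "significant": pw.stars,
                "omnibus_F": res.f_statistic,
                "omnibus_p": res.p_value,
            })
    return pd.DataFrame(rows)


def rank_by_mean(table: pd.DataFrame) -> list[GroupRanking]:
    """Classes ordered by descending group mean, per feature.

    Exact ties are broken lexicographically and flagged.
    """
    rankings = []
    for feature in FEATURE_COLUMNS:
        means = table.groupby("class_label", sort=True)[feature].mean()
        ordered = sorted(means.index, key=lambda lab: (-means[lab], lab))
        tie = means.duplicated().any()
        rankings.append(
            GroupRanking(
                feature=feature,
                ordered_labels=list(ordered),
                means={lab: float(means[lab]) for lab in means.index},
                tie=bool(tie),
            )
        )
    return rankings


def tsne_embed(
    table: pd.DataFrame, seed: int = 0, perplexity: float = 30.0
) -> Embedding2D:
    """Embed the standardized six-feature table in 2-D with t-SNE.

    Perplexity is auto-reduced (and logged) when the table is too small for
    the requested value; deterministic under a fixed seed on one platform.
    """
    n = len(table)
    if n < 5:
        raise ValueError(f"need >= 5 rows for a meaningful embedding, got {n}")
    max_perplexity = (n - 1) / 3.0
    if perplexity > max_perplexity:
        logger.info("reducing perplexity %.1f -> %.1f for %d rows",
                    perplexity, max_perplexity, n)
        perplexity = max_perplexity
    X = StandardScaler().fit_transform(table.loc[:, list(FEATURE_COLUMNS)].to_numpy())
    emb = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        max_iter=1000,
        random_state=seed,
    ).fit_transform(X)
    coords = pd.DataFrame({
        "doc_id": table["doc_id"].to_numpy(),
        "class_label": table["class_label"].to_numpy(),
        "x": emb[:, 0],
        "y": emb[:, 1],
    })
    return Embedding2D(coords=coords, seed=seed, perplexity=float(perplexity))


def plot_embedding(embedding: Embedding2D, path) -> None:
    """Scatter plot of the 2-D embedding, coloured by class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for label, sub in embedding.coords.groupby("class_label", sort=True):
        ax.scatter(sub["x"], sub["y"], s=8, alpha=0.6, label=label)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.legend(title="class")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
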