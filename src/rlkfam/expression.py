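"""RPKM expression profiling, clustering, and qPCR relative quantification.

Expression values follow RPKM = 1e9 * c / (N * L) with c the read count,
N the library size (column totals of the count matrix by default) and L
the summed exon length of the gene. "Self-normalized log" values are
log2(RPKM + 1) followed by a per-gene z-score, the convention of
heatmap tools; heatmaps are ordered by average-linkage hierarchical
clustering on 1 - Pearson correlation.

qPCR fold changes use the delta-delta-Ct method: dCt = Ct_target -
Ct_reference per sample, ddCt contrasts each sample's dCt against the
calibrator-group mean, fold = 2**(-ddCt). Group comparisons use a
two-sided two-sample t-test with the conventional star annotation
(p < 0.05 -> "*", p < 0.01 -> "**").
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats

from .types import RlkfamError


def rpkm(
    counts: pd.DataFrame,
    gene_length_bp: pd.Series | dict,
    library_sizes: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads."""
    lengths = pd.Series(gene_length_bp).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise RlkfamError(f"missing gene lengths for {missing}")
    if (lengths <= 0).any():
        raise RlkfamError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = pd.Series(library_sizes).reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise RlkfamError("library sizes must be positive")
    return 1e9 * counts.div(library_sizes, axis=1).div(lengths, axis=0)


def normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) then per-row z-score; constant rows map to zeros."""
    logged = np.log2(matrix + 1.0)
    mean = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=0)
    out = logged.sub(mean, axis=0)
    nonconst = sd > 0
    out.loc[nonconst] = out.loc[nonconst].div(sd[nonconst], axis=0)
    out.loc[~nonconst] = 0.0
    return out


def hierarchical_cluster(
    matrix: pd.DataFrame, method: str = "average"
) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Average-linkage clustering of rows on 1 - Pearson distance.

    Returns (scipy linkage matrix, ordered row ids, reordered matrix).
    Rows with zero variance would make the correlation undefined; they are
    assigned distance 1 to everything (uncorrelated) rather than dropped.
    """
    if len(matrix) < 2:
        raise RlkfamError("clustering needs >= 2 rows")
    arr = matrix.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    n = len(arr)
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    ok = sd > 0
    if ok.sum() >= 2:
        sub = arr[ok]
        corr = np.corrcoef(sub)
        d = 1.0 - corr
        np.fill_diagonal(d, 0.0)
        d[d < 0] = 0.0
        idx = np.where(ok)[0]
        dist[np.ix_(idx, idx)] = d
    linkage = hierarchy.linkage(squareform(dist, checks=False), method=method)
    order = hierarchy.leaves_list(linkage)
    ids = [matrix.index[i] for i in order]
    return linkage, ids, matrix.loc[ids]


def write_heatmap(
    matrix: pd.DataFrame, tsv_path: str, png_path: Optional[str] = None
) -> None:
    """Clustered heatmap: ordered TSV always, PNG rendering on request."""
    _, _, ordered = hierarchical_cluster(matrix)
    ordered.to_csv(tsv_path, sep="\t")
    if png_path:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, max(3, 0.15 * len(ordered))))
        im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r")
        ax.set_xticks(range(len(ordered.columns)))
        ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
        ax.set_yticks([])
        fig.colorbar(im, ax=ax, shrink=0.6)
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# qPCR

QPCR_COLUMNS = ["sample", "gene", "ct", "replicate", "group"]


def read_qpcr(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(QPCR_COLUMNS) - set(df.columns)
    if missing:
        raise RlkfamError(f"{path}: missing qPCR columns {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise RlkfamError(f"{path}: Ct values must be positive")
    return df


def ddct(
    records: pd.DataFrame,
    reference_gene: str,
    calibrator_group: str,
    target_gene: Optional[str] = None,
) -> pd.DataFrame:
    """Replicate-level 2**(-ddCt) fold changes.

    Each (sample, replicate) must include the reference gene; its Ct is
    subtracted from the target Ct to give dCt, and ddCt contrasts dCt
    against the calibrator group's mean dCt for the same target.
    """
    df = records.copy()
    targets = (
        [target_gene]
        if target_gene
        else sorted(set(df["gene"]) - {reference_gene})
    )
    if not targets:
        raise RlkfamError("no target genes besides the reference")
    ref = df[df["gene"] == reference_gene].set_index(["sample", "replicate"])["ct"]
    out_rows = []
    for gene in targets:
        sub = df[df["gene"] == gene]
        for row in sub.itertuples(index=False):
            key = (row.sample, row.replicate)
            if key not in ref.index:
                raise RlkfamError(
                    f"missing reference gene Ct for sample={row.sample} "
                    f"replicate={row.replicate}"
                )
            out_rows.append(
                {
                    "gene": gene,
                    "sample": row.sample,
                    "replicate": row.replicate,
                    "group": row.group,
                    "dct": row.ct - float(ref.loc[key]),
                }
            )
    out = pd.DataFrame(out_rows)
    folds = []
    for gene, sub in out.groupby("gene"):
        calib = sub[sub["group"] == calibrator_group]
        if calib.empty:
            raise RlkfamError(f"no calibrator-group measurements for {gene}")
        base = calib["dct"].mean()
        sub = sub.assign(ddct=sub["dct"] - base)
        sub = sub.assign(fold=2.0 ** (-sub["ddct"]))
        folds.append(sub)
    return pd.concat(folds, ignore_index=True)


# ---------------------------------------------------------------------------
# t-test annotation

def ttest_annotate(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = False
) -> tuple[float, float, str]:
    """Two-sided two-sample t-test with star annotation.

    Student's (equal-variance) flavour by default; Welch via flag. Two
    groups with zero pooled variance are handled directly: identical
    means give (0, 1, "") and different means a significant separation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise RlkfamError("each group needs >= 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = np.inf * np.sign(a.mean() - b.mean()), 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(t), float(p)
    if p < 0.01:
        stars = "**"
    elif p < 0.05:
        stars = "*"
    else:
        stars = ""
    return t, p, stars
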