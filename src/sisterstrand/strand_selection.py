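"""Sister-pair log-ratio matrices, A/AC/C classification and clustering.

A *sister pair* is the couple of mature miRNAs excised from the 5' and 3'
arms of one hairpin precursor. Per sample, the pair's signal is the
log2(ratio) between the 5' and 3' intensities. In the thresholded variant,
intensities at or below the dataset median count as "not expressed": samples
where only the 5' (resp. 3') arm is expressed are set to the sentinel
max finite log-ratio + 0.1 (resp. min finite − 0.1), and samples where
neither arm is expressed are missing and excluded from all distances.

Pairs are classified over samples as

* ``A``  — alternatively expressed: the two arms are never expressed together;
* ``C``  — concurrently expressed whenever expressed;
* ``AC`` — alternative in some samples and concurrent in others;
* ``NOT_EXPRESSED`` — neither arm ever passes the threshold.

Clustering is UPGMA (unweighted average linkage) on Euclidean distances;
missing cells are handled by pairwise-complete squared distances rescaled to
the full dimensionality.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .annotation import AnnotationSet
from .datasets import ExpressionMatrix, call_expressed

log = logging.getLogger(__name__)

STATUS_BOTH = "B"
STATUS_ONLY5 = "5"
STATUS_ONLY3 = "3"
STATUS_NEITHER = "N"

LABELS = ("A", "AC", "C", "NOT_EXPRESSED")

COMPARABLE_RULES = ("median", "mean", "all", "any")


@dataclass(frozen=True)
class SisterPair:
    pair_id: str
    hairpin_id: str
    mature5_id: str
    mature3_id: str


@dataclass
class LogRatioMatrix:
    """Pair-by-sample log2(5'/3') values with per-cell status flags.

    ``values`` holds finite log-ratios and sentinel values; missing cells
    (status ``N``) are NaN. ``sentinel_hi``/``sentinel_lo`` record the
    sentinels used for one-arm-only cells (None for raw, both-expressed
    matrices and after standardization).
    """

    values: pd.DataFrame
    status: pd.DataFrame
    sentinel_hi: Optional[float] = None
    sentinel_lo: Optional[float] = None

    @property
    def pair_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "pair_id"
        out.to_csv(path, sep="\t", float_format="%.10g")

    def status_to_tsv(self, path) -> None:
        out = self.status.copy()
        out.index.name = "pair_id"
        out.to_csv(path, sep="\t")


@dataclass
class PairClass:
    pair_id: str
    label: str
    n_samples_concurrent: int
    n_samples_alternative: int
    comparable: Optional[bool] = None


@dataclass
class Dendrogram:
    """Average-linkage merge tree over named items."""

    ids: list[str]
    linkage: np.ndarray  # scipy linkage matrix

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Partition the items into ``k`` flat clusters."""
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.ids, (int(x) for x in labels)))

    def leaf_order(self) -> list[str]:
        return [self.ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.ids[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"


# ---------------------------------------------------------------------------
# Pair enumeration and ratio matrices
# ---------------------------------------------------------------------------

def enumerate_sister_pairs(ann: AnnotationSet, matrix: ExpressionMatrix) -> list[SisterPair]:
    """One pair per hairpin whose 5p and 3p matures are both measured.

    Identical (mature5, mature3) identifier couples arising from hairpins at
    different genomic locations are collapsed to a single pair.
    """
    features = set(matrix.feature_ids)
    seen: dict[tuple[str, str], str] = {}
    pairs: list[SisterPair] = []
    for hid in sorted(ann.hairpins):
        matures = ann.matures_of(hid)
        if len(matures) != 2:
            continue
        by_arm = {m.arm: m for m in matures}
        if set(by_arm) != {"5p", "3p"}:
            raise ValueError(f"hairpin {hid}: arms not assigned")
        m5, m3 = by_arm["5p"], by_arm["3p"]
        if m5.mature_id not in features or m3.mature_id not in features:
            continue
        key = (m5.mature_id, m3.mature_id)
        if key in seen:
            log.info("pair %s/%s from %s duplicates %s; kept once", *key, hid, seen[key])
            continue
        seen[key] = hid
        pairs.append(SisterPair(f"{m5.mature_id}|{m3.mature_id}", hid, m5.mature_id, m3.mature_id))
    return pairs


def raw_log_ratio(matrix: ExpressionMatrix, pairs: Sequence[SisterPair]) -> LogRatioMatrix:
    """Per-sample log2(5'/3') of strictly positive intensities (all cells B)."""
    rows = []
    for p in pairs:
        x5 = matrix.data.loc[p.mature5_id].to_numpy(dtype=float)
        x3 = matrix.data.loc[p.mature3_id].to_numpy(dtype=float)
        if (x5 <= 0).any() or (x3 <= 0).any():
            raise ValueError(
                f"pair {p.pair_id}: zero or negative intensity; "
                "use thresholded_log_ratio for matrices with unexpressed cells"
            )
        rows.append(np.log2(x5 / x3))
    values = pd.DataFrame(rows, index=[p.pair_id for p in pairs], columns=matrix.sample_ids)
    status = pd.DataFrame(STATUS_BOTH, index=values.index, columns=values.columns)
    return LogRatioMatrix(values, status)


def thresholded_log_ratio(
    matrix: ExpressionMatrix, pairs: Sequence[SisterPair], threshold: float
) -> LogRatioMatrix:
    """Log-ratio matrix with the expression threshold applied.

    Intensities at or below the threshold are treated as not expressed.
    Cells where both arms are expressed carry the finite log2 ratio; cells
    with a single expressed arm carry sentinel extremes derived from the
    finite values of this matrix (max+0.1 / min-0.1); cells with neither arm
    expressed are missing.
    """
    calls = call_expressed(matrix, threshold)
    n_pairs, n_samples = len(pairs), len(matrix.sample_ids)
    values = np.full((n_pairs, n_samples), np.nan)
    status = np.full((n_pairs, n_samples), STATUS_NEITHER, dtype=object)
    for i, p in enumerate(pairs):
        x5 = matrix.data.loc[p.mature5_id].to_numpy(dtype=float)
        x3 = matrix.data.loc[p.mature3_id].to_numpy(dtype=float)
        e5 = calls.loc[p.mature5_id].to_numpy()
        e3 = calls.loc[p.mature3_id].to_numpy()
        both = e5 & e3
        values[i, both] = np.log2(x5[both] / x3[both])
        status[i, both] = STATUS_BOTH
        status[i, e5 & ~e3] = STATUS_ONLY5
        status[i, ~e5 & e3] = STATUS_ONLY3
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("no sample with both arms expressed: sentinel extremes undefined")
    hi = float(finite.max()) + 0.1
    lo = float(finite.min()) - 0.1
    values[status == STATUS_ONLY5] = hi
    values[status == STATUS_ONLY3] = lo
    vdf = pd.DataFrame(values, index=[p.pair_id for p in pairs], columns=matrix.sample_ids)
    sdf = pd.DataFrame(status, index=vdf.index, columns=vdf.columns)
    return LogRatioMatrix(vdf, sdf, sentinel_hi=hi, sentinel_lo=lo)


def standardize_rows(lrm: LogRatioMatrix) -> LogRatioMatrix:
    """Z-score each pair row over its non-missing cells (ddof=1).

    Sentinel cells take part as ordinary values (they encode the strength of
    alternative expression); missing cells stay missing. Rows with fewer than
    two observed cells or zero spread are dropped with a warning.
    """
    vals = lrm.values.to_numpy(dtype=float)
    keep_rows = []
    dropped: dict[str, list[str]] = {"<2 observed cells": [], "zero spread": []}
    out = np.full_like(vals, np.nan)
    for i, pid in enumerate(lrm.pair_ids):
        row = vals[i]
        obs = np.isfinite(row)
        n = int(obs.sum())
        if n < 2:
            dropped["<2 observed cells"].append(pid)
            continue
        sd = row[obs].std(ddof=1)
        if sd == 0:
            dropped["zero spread"].append(pid)
            continue
        out[i, obs] = (row[obs] - row[obs].mean()) / sd
        keep_rows.append(i)
    for reason, pids in dropped.items():
        if pids:
            log.warning("standardize_rows: dropped %d rows (%s): %s%s",
                        len(pids), reason, ", ".join(pids[:5]),
                        ", ..." if len(pids) > 5 else "")
    values = pd.DataFrame(out[keep_rows], index=[lrm.pair_ids[i] for i in keep_rows],
                          columns=lrm.sample_ids)
    status = lrm.status.iloc[keep_rows].copy()
    return LogRatioMatrix(values, status)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def comparable_flag(
    matrix: ExpressionMatrix,
    pair: SisterPair,
    threshold: float,
    bound: float = 1.0,
    rule: str = "median",
) -> Optional[bool]:
    """Whether the two arms are expressed at comparable levels when concurrent.

    Two levels are comparable in a sample when |log2(5'/3')| does not exceed
    ``bound`` (default 1, i.e. within two-fold). The per-pair flag aggregates
    the per-sample |log2 ratio| over concurrent samples with the chosen rule
    (median by default; also mean / all / any). Returns None when the pair
    has no concurrent sample.
    """
    if rule not in COMPARABLE_RULES:
        raise ValueError(f"rule must be one of {COMPARABLE_RULES}, got {rule!r}")
    x5 = matrix.data.loc[pair.mature5_id].to_numpy(dtype=float)
    x3 = matrix.data.loc[pair.mature3_id].to_numpy(dtype=float)
    both = (x5 > threshold) & (x3 > threshold)
    if not both.any():
        return None
    absratio = np.abs(np.log2(x5[both] / x3[both]))
    if rule == "median":
        agg = float(np.median(absratio))
    elif rule == "mean":
        agg = float(np.mean(absratio))
    elif rule == "all":
        agg = float(np.max(absratio))
    else:  # any
        agg = float(np.min(absratio))
    return bool(agg <= bound)


def classify_pairs(
    matrix: ExpressionMatrix,
    pairs: Sequence[SisterPair],
    threshold: float,
    comparable_bound: float = 1.0,
    comparable_rule: str = "median",
) -> pd.DataFrame:
    """Per-pair A/AC/C/NOT_EXPRESSED labels with concurrency counts.

    A sample is *alternative* when exactly one arm is expressed and
    *concurrent* when both are. Labels follow: A (never concurrent, at least
    one alternative sample), C (never alternative, at least one concurrent),
    AC (both kinds occur), NOT_EXPRESSED (neither ever).
    """
    calls = call_expressed(matrix, threshold)
    records = []
    for p in pairs:
        e5 = calls.loc[p.mature5_id].to_numpy()
        e3 = calls.loc[p.mature3_id].to_numpy()
        n_alt = int((e5 ^ e3).sum())
        n_conc = int((e5 & e3).sum())
        if n_alt == 0 and n_conc == 0:
            label = "NOT_EXPRESSED"
        elif n_conc == 0:
            label = "A"
        elif n_alt == 0:
            label = "C"
        else:
            label = "AC"
        comp = comparable_flag(matrix, p, threshold, comparable_bound, comparable_rule)
        records.append(
            {
                "pair_id": p.pair_id,
                "label": label,
                "n_samples_concurrent": n_conc,
                "n_samples_alternative": n_alt,
                "comparable": comp,
            }
        )
    return pd.DataFrame(records).set_index("pair_id")


def summarize_class_counts(
    counts: Mapping[str, Mapping[str, int]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-dataset counts/percentages and cross-dataset mean +/- sd per label.

    ``counts`` maps dataset id to ``{label: count}``. Percentages are taken
    over the full pair set of each dataset (expressed plus not-expressed
    pairs). Cross-dataset statistics are the unweighted mean and sample
    standard deviation (ddof=1) of each label's percentage.
    """
    if not counts:
        raise ValueError("at least one dataset required")
    rows = []
    for ds, c in counts.items():
        total = sum(int(c.get(lbl, 0)) for lbl in LABELS)
        if total == 0:
            raise ValueError(f"dataset {ds}: no pairs")
        row = {"dataset": ds, "total": total}
        for lbl in LABELS:
            n = int(c.get(lbl, 0))
            row[f"n_{lbl}"] = n
            row[f"pct_{lbl}"] = 100.0 * n / total
        row["n_expressed"] = total - int(c.get("NOT_EXPRESSED", 0))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("dataset")
    cross_rows = []
    for lbl in LABELS:
        pct = table[f"pct_{lbl}"]
        cross_rows.append(
            {
                "label": lbl,
                "mean_pct": float(pct.mean()),
                "sd_pct": float(pct.std(ddof=1)) if len(pct) > 1 else float("nan"),
            }
        )
    cross = pd.DataFrame(cross_rows).set_index("label")
    return table, cross


def classification_summary(
    class_tables: Mapping[str, pd.DataFrame]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize per-dataset classify_pairs outputs across datasets."""
    counts = {
        ds: tbl["label"].value_counts().to_dict() for ds, tbl in class_tables.items()
    }
    return summarize_class_counts(counts)


# ---------------------------------------------------------------------------
# Hierarchical clustering (UPGMA, Euclidean, missing-aware)
# ---------------------------------------------------------------------------

def _pairwise_euclidean_missing(X: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    """Condensed Euclidean distances with pairwise-complete rescaling.

    For two items observed together on m of p dimensions, the squared
    distance over the shared dimensions is rescaled by p/m before the square
    root. A pair of items with no shared observed dimension is an error.
    """
    n, p = X.shape
    obs = np.isfinite(X)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = obs[i] & obs[j]
            m = int(mask.sum())
            if m == 0:
                raise ValueError(
                    f"items {ids[i]!r} and {ids[j]!r} share no observed cell; "
                    "distance undefined"
                )
            diff = X[i, mask] - X[j, mask]
            dm[i, j] = dm[j, i] = math.sqrt(float(diff @ diff) * (p / m))
    return squareform(dm, checks=False)


def hierarchical_cluster(lrm: LogRatioMatrix, axis: str = "samples") -> Dendrogram:
    """UPGMA dendrogram of samples or pairs from the log-ratio matrix.

    Items are ordered lexically before linkage so that ties resolve
    deterministically.
    """
    if axis not in ("samples", "pairs"):
        raise ValueError(f"axis must be 'samples' or 'pairs', got {axis!r}")
    if axis == "samples":
        ids = sorted(lrm.sample_ids)
        X = lrm.values.loc[:, ids].to_numpy(dtype=float).T
    else:
        ids = sorted(lrm.pair_ids)
        X = lrm.values.loc[ids].to_numpy(dtype=float)
    if len(ids) < 2:
        raise ValueError("clustering requires at least 2 items")
    condensed = _pairwise_euclidean_missing(X, ids)
    Z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(ids=ids, linkage=Z)
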