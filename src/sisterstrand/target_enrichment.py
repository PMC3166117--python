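"""Integration of miRNA-target predictions with expression anti-correlation.

Predicted miRNA-target relations are scored by the Pearson correlation of
the regulator and target expression profiles over matched samples. The
relations with negative correlation form the *background*; the most
anti-correlated c% of the background (percentile cutoff) are "supported".
Against an independent set of validated interactions, the enrichment score
at a cutoff is observed/expected validated relations, with the expected
count allocated proportionally from the background.

Two modes are contrasted: REAL uses measured miRNA profiles; PROXY replaces
each intragenic miRNA by its host gene's expression profile. Before scoring,
the regulator matrix of each mode is filtered: the quartile with the lowest
Shannon entropy (almost invariable profiles) and/or the quartile with the
lowest mean expression are removed.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, HostAssignment
from .datasets import ExpressionMatrix, match_samples

log = logging.getLogger(__name__)

DEFAULT_CUTOFFS = (1, 2, 3, 4, 5, 10, 25, 50, 100)

RELATION_COLUMNS = ["mirna_id", "target_gene_id"]


def shannon_entropy(profile: Sequence[float]) -> float:
    """Shannon entropy (bits) of a non-negative profile normalized to sum 1.

    Zero entries contribute nothing; an all-zero profile is an error.
    """
    x = np.asarray(profile, dtype=float)
    if (x < 0).any():
        raise ValueError("profile must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero profile: entropy undefined")
    p = x[x > 0] / total
    return float(-(p * np.log2(p)).sum())


def filter_mirnas(
    matrix: ExpressionMatrix, entropy_q: float = 0.25, mean_q: float = 0.25
) -> list[str]:
    """Drop almost-invariable and weakly expressed regulators.

    Removes the union of the ``ceil(n*entropy_q)`` features with the lowest
    Shannon entropy and the ``ceil(n*mean_q)`` features with the lowest mean
    expression (ranked ascending, ties broken by feature id). Returns the
    sorted retained ids; removing everything is an error.
    """
    ids = matrix.feature_ids
    n = len(ids)
    if n == 0:
        raise ValueError("empty matrix")
    vals = matrix.data
    entropies = {}
    for fid in ids:
        row = vals.loc[fid].to_numpy(dtype=float)
        entropies[fid] = shannon_entropy(row) if row.sum() > 0 else -math.inf
    means = {fid: float(vals.loc[fid].mean()) for fid in ids}

    def lowest(metric: Mapping[str, float], q: float) -> set[str]:
        k = math.ceil(n * q)
        if k <= 0:
            return set()
        ranked = sorted(ids, key=lambda f: (metric[f], f))
        return set(ranked[:k])

    removed = lowest(entropies, entropy_q) | lowest(means, mean_q)
    retained = sorted(set(ids) - removed)
    if not retained:
        raise ValueError("filters would remove every regulator")
    log.info("filter_mirnas: retained %d of %d features", len(retained), n)
    return retained


def read_relations(path) -> pd.DataFrame:
    """Load a relation TSV (mirna_id, gene_id pairs, one per line)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns[:2])
    df = df.rename(columns={cols[0]: "mirna_id", cols[1]: "target_gene_id"})
    return normalize_relations(df)


def normalize_relations(relations: pd.DataFrame) -> pd.DataFrame:
    """Exact-identity normalization: strip whitespace, drop duplicates/NAs."""
    out = relations[RELATION_COLUMNS].copy()
    for c in RELATION_COLUMNS:
        out[c] = out[c].astype(str).str.strip()
    bad = (out == "") | (out == "nan")
    if bad.any().any():
        raise ValueError("relation table contains missing identifiers")
    return out.drop_duplicates(ignore_index=True)


def score_relations(
    regulators: pd.DataFrame,
    genes: ExpressionMatrix,
    predictions: pd.DataFrame,
    mode: str = "REAL",
    scale: str = "log2",
) -> pd.DataFrame:
    """Pearson r for each prediction whose regulator and target are measured.

    ``regulators`` is a profile table indexed by regulator id over the same
    samples as ``genes`` (for PROXY it holds host-gene profiles re-indexed by
    the mature ids they stand in for). Predictions naming an absent
    regulator or target are dropped and counted in the log. ``scale``
    selects correlation on log2 intensities (default) or linear.
    """
    if list(regulators.columns) != genes.sample_ids:
        raise ValueError("regulator and gene profiles are not sample-matched")
    pred = normalize_relations(predictions)
    have = pred["mirna_id"].isin(regulators.index) & pred["target_gene_id"].isin(genes.data.index)
    n_dropped = int((~have).sum())
    if n_dropped:
        log.info("score_relations[%s]: %d predictions dropped (unmeasured ids)", mode, n_dropped)
    pred = pred[have].reset_index(drop=True)
    if len(pred) == 0:
        raise ValueError("no scorable relation")
    R = regulators.to_numpy(dtype=float)
    G = genes.data.to_numpy(dtype=float)
    if scale == "log2":
        if (R <= 0).any() or (G <= 0).any():
            raise ValueError("non-positive intensity: cannot correlate on log2 scale")
        R = np.log2(R)
        G = np.log2(G)
    elif scale != "linear":
        raise ValueError(f"scale must be 'log2' or 'linear', got {scale!r}")

    def zrows(M: np.ndarray) -> np.ndarray:
        mu = M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = np.nan
        return (M - mu) / sd

    zr = zrows(R)
    zg = zrows(G)
    ridx = pd.Index(regulators.index).get_indexer(pred["mirna_id"])
    gidx = genes.data.index.get_indexer(pred["target_gene_id"])
    n = R.shape[1]
    r = np.einsum("ij,ij->i", zr[ridx], zg[gidx]) / (n - 1)
    out = pred.copy()
    out["r"] = np.clip(r, -1.0, 1.0)
    out["mode"] = mode
    const = out["r"].isna()
    if const.any():
        log.warning("score_relations[%s]: dropped %d constant-profile relations", mode, int(const.sum()))
        out = out[~const].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("no scorable relation")
    return out


def negative_background(scored: pd.DataFrame) -> pd.DataFrame:
    """Relations with r < 0: the pool the percentile cutoffs act on."""
    return scored[scored["r"] < 0].reset_index(drop=True)


def select_supported(scored: pd.DataFrame, percentile_c: float) -> pd.DataFrame:
    """The ``c``% most negative relations of the negative background.

    Selection size is ``ceil(c/100 * |background|)``; ordering (and boundary
    ties) are resolved by (r, mirna_id, target_gene_id).
    """
    if not 0 < percentile_c <= 100:
        raise ValueError(f"percentile must be in (0, 100], got {percentile_c}")
    bg = negative_background(scored)
    if len(bg) == 0:
        raise ValueError("empty negative-correlation background")
    bg = bg.sort_values(["r", "mirna_id", "target_gene_id"], kind="mergesort")
    k = math.ceil(percentile_c / 100.0 * len(bg))
    return bg.head(k).reset_index(drop=True)


def _relation_set(df: pd.DataFrame) -> set[tuple[str, str]]:
    return set(zip(df["mirna_id"], df["target_gene_id"]))


def enrichment_score(
    selected: pd.DataFrame, validated: pd.DataFrame, background: pd.DataFrame
) -> dict[str, float]:
    """Observed/expected validated relations in a selected subset.

    expected = |selected| * |validated in background| / |background|.
    Empty background or no validated relation in the background is an error.
    """
    if len(background) == 0:
        raise ValueError("empty background")
    vset = _relation_set(validated)
    bset = _relation_set(background)
    n_val_bg = len(vset & bset)
    if n_val_bg == 0:
        raise ValueError("no validated relation in the background: score undefined")
    sset = _relation_set(selected)
    observed = len(sset & vset)
    expected = len(sset) * n_val_bg / len(bset)
    return {
        "n_selected": len(sset),
        "observed": observed,
        "expected": expected,
        "score": observed / expected,
        "n_background": len(bset),
        "n_validated_in_background": n_val_bg,
    }


def enrichment_curve(
    scored: pd.DataFrame,
    validated: pd.DataFrame,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    mode: str = "REAL",
) -> pd.DataFrame:
    """Enrichment score across percentile cutoffs for one scored relation set."""
    bg = negative_background(scored)
    rows = []
    for c in cutoffs:
        sel = select_supported(scored, c)
        point = enrichment_score(sel, validated, bg)
        point["cutoff"] = c
        point["mode"] = mode
        rows.append(point)
    return pd.DataFrame(rows)[
        ["mode", "cutoff", "n_selected", "observed", "expected", "score",
         "n_background", "n_validated_in_background"]
    ]


def proxy_regulator_profiles(
    mirna: ExpressionMatrix,
    genes: ExpressionMatrix,
    assignments: Iterable[HostAssignment],
    ann: AnnotationSet,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Host-gene profiles standing in for their intragenic mature miRNAs.

    Returns a profile table indexed by mature id (values = host-gene rows)
    restricted to intragenic miRNAs measured in the miRNA matrix and with a
    measured host gene, plus the mature -> host mapping.
    """
    mapping: dict[str, str] = {}
    rows = {}
    for a in assignments:
        if a.status != "intragenic" or a.host_gene_id not in genes.data.index:
            continue
        for mid in ann.hairpins[a.hairpin_id].mature_ids:
            if mid not in mirna.data.index:
                continue
            mapping[mid] = a.host_gene_id
            rows[mid] = genes.data.loc[a.host_gene_id]
    if not rows:
        raise ValueError("no intragenic miRNA with a measured host gene")
    profiles = pd.DataFrame(rows).T
    profiles = profiles.loc[sorted(profiles.index)]
    profiles.columns = genes.sample_ids
    return profiles, mapping


def run_real_vs_proxy(
    mirna: ExpressionMatrix,
    genes: ExpressionMatrix,
    assignments: Sequence[HostAssignment],
    ann: AnnotationSet,
    predictions: pd.DataFrame,
    validated: pd.DataFrame,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    entropy_q: float = 0.25,
    mean_q: float = 0.25,
    scale: str = "log2",
    exclude_self_targets: bool = True,
) -> dict[str, pd.DataFrame]:
    """REAL vs PROXY enrichment curves plus the overlap of validated hits.

    REAL scores predictions with measured miRNA profiles; PROXY rescores the
    predictions of intragenic miRNAs using their host-gene profiles as
    stand-ins. Each mode filters its own regulator matrix by the entropy and
    mean-expression quartile rule. In PROXY, a prediction whose target is
    the regulator's own host gene is excluded (it would trivially correlate
    with itself). The overlap table reports, per cutoff, the intersection
    and Jaccard index of the validated relations detected by the two modes.
    """
    validated = normalize_relations(validated)
    if len(validated) == 0:
        raise ValueError("empty validated set")
    mirna, genes = match_samples(mirna, genes)

    # REAL: measured miRNA profiles, filtered
    retained = filter_mirnas(mirna, entropy_q, mean_q)
    real_reg = mirna.data.loc[retained]
    real_scored = score_relations(real_reg, genes, predictions, mode="REAL", scale=scale)
    real_curve = enrichment_curve(real_scored, validated, cutoffs, mode="REAL")

    # PROXY: host-gene profiles as stand-ins, filtered on the proxy profiles
    proxy_profiles, mapping = proxy_regulator_profiles(mirna, genes, assignments, ann)
    proxy_em = ExpressionMatrix(proxy_profiles.copy())
    proxy_retained = filter_mirnas(proxy_em, entropy_q, mean_q)
    proxy_reg = proxy_profiles.loc[proxy_retained]
    pred_proxy = normalize_relations(predictions)
    if exclude_self_targets:
        is_self = pred_proxy.apply(
            lambda row: mapping.get(row["mirna_id"]) == row["target_gene_id"], axis=1
        )
        if is_self.any():
            log.info("PROXY: excluding %d self-target predictions", int(is_self.sum()))
            pred_proxy = pred_proxy[~is_self].reset_index(drop=True)
    proxy_scored = score_relations(proxy_reg, genes, pred_proxy, mode="PROXY", scale=scale)
    proxy_curve = enrichment_curve(proxy_scored, validated, cutoffs, mode="PROXY")

    # overlap of detected validated relations, per cutoff
    vset = _relation_set(validated)
    overlap_rows = []
    for c in cutoffs:
        hits_real = _relation_set(select_supported(real_scored, c)) & vset
        hits_proxy = _relation_set(select_supported(proxy_scored, c)) & vset
        union = hits_real | hits_proxy
        overlap_rows.append(
            {
                "cutoff": c,
                "n_real_hits": len(hits_real),
                "n_proxy_hits": len(hits_proxy),
                "n_intersection": len(hits_real & hits_proxy),
                "jaccard": (len(hits_real & hits_proxy) / len(union)) if union else float("nan"),
            }
        )
    return {
        "real_curve": real_curve,
        "proxy_curve": proxy_curve,
        "overlap": pd.DataFrame(overlap_rows),
        "real_scored": real_scored,
        "proxy_scored": proxy_scored,
    }
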