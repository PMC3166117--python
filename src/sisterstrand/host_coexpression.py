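"""Co-expression of intragenic mature miRNAs with their host genes.

For every intragenic hairpin, each of its mature miRNAs is correlated
(Pearson, over matched samples) with the expression profile of the host
gene. Two-sided p-values come from the exact t transform with n-2 degrees
of freedom; multiplicity is controlled per dataset with Benjamini-Hochberg
q-values. When a host carries both matures of one hairpin, the sister pair
can be collapsed to the record with the higher correlation (which, if
anything, overestimates the general co-expression tendency).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotationSet, HostAssignment
from .datasets import ExpressionMatrix

log = logging.getLogger(__name__)

RECORD_COLUMNS = ["mature_id", "host_gene_id", "n", "r", "p"]

FDR_METHODS = {"bh": "fdr_bh", "by": "fdr_by"}


def pearson_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("pearson_test requires n >= 3")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance profile: correlation undefined")
    r = float(np.cov(x, y, ddof=1)[0, 1] / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, min(1.0, p)


def pearson_permutation_test(
    x: np.ndarray, y: np.ndarray, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Permutation alternative to the t transform for very small n (< 8)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r, _ = pearson_test(x, y)
    rng = np.random.default_rng(seed)
    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    n = x.size
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rp = float(zx @ zy[perm]) / (n - 1)
        if abs(rp) >= abs(r) - 1e-12:
            hits += 1
    return r, (hits + 1) / (n_perm + 1)


def correlate_mirna_host(
    mirna: ExpressionMatrix,
    genes: ExpressionMatrix,
    assignments: Iterable[HostAssignment],
    ann: AnnotationSet,
    scale: str = "linear",
) -> pd.DataFrame:
    """Pearson correlation records for every (mature miRNA, host gene) couple.

    Matrices must already be sample-matched. Pairs whose mature or host is
    not measured are skipped and logged, as are couples with fewer than 3
    samples or a zero-variance profile. ``scale`` selects whether Pearson is
    computed on linear intensities (default) or on their log2.
    """
    if scale not in ("linear", "log2"):
        raise ValueError(f"scale must be 'linear' or 'log2', got {scale!r}")
    if mirna.sample_ids != genes.sample_ids:
        raise ValueError("matrices are not sample-matched; call match_samples first")
    records = []
    n_skipped = 0
    for a in assignments:
        if a.status != "intragenic":
            continue
        if a.host_gene_id not in genes.data.index:
            n_skipped += 1
            continue
        g = genes.data.loc[a.host_gene_id].to_numpy(dtype=float)
        for mid in ann.hairpins[a.hairpin_id].mature_ids:
            if mid not in mirna.data.index:
                n_skipped += 1
                continue
            m = mirna.data.loc[mid].to_numpy(dtype=float)
            xm, xg = m, g
            if scale == "log2":
                if (m <= 0).any() or (g <= 0).any():
                    log.warning("skipping %s/%s: non-positive value on log2 scale", mid, a.host_gene_id)
                    n_skipped += 1
                    continue
                xm, xg = np.log2(m), np.log2(g)
            if xm.size < 3:
                log.warning("skipping %s/%s: fewer than 3 samples", mid, a.host_gene_id)
                n_skipped += 1
                continue
            if xm.std(ddof=1) == 0 or xg.std(ddof=1) == 0:
                log.warning("skipping %s/%s: zero-variance profile", mid, a.host_gene_id)
                n_skipped += 1
                continue
            r, p = pearson_test(xm, xg)
            records.append(
                {"mature_id": mid, "host_gene_id": a.host_gene_id, "n": xm.size, "r": r, "p": p}
            )
    if n_skipped:
        log.info("correlate_mirna_host: skipped %d couples", n_skipped)
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def fdr_adjust(records: pd.DataFrame, method: str = "bh") -> pd.DataFrame:
    """Attach FDR-adjusted q-values (Benjamini-Hochberg by default)."""
    if method not in FDR_METHODS:
        raise ValueError(f"method must be one of {sorted(FDR_METHODS)}, got {method!r}")
    out = records.copy()
    if len(out) == 0:
        out["q"] = pd.Series(dtype=float)
        return out
    _, q, _, _ = multipletests(out["p"].to_numpy(), method=FDR_METHODS[method])
    out["q"] = q
    return out


def collapse_best_of_pair(records: pd.DataFrame, ann: AnnotationSet) -> pd.DataFrame:
    """Keep, per (host, hairpin) with two mature records, only the higher r.

    Ties go to the 5p arm (logged). Records of single-mature hairpins pass
    through unchanged.
    """
    if len(records) == 0:
        return records.copy()
    arm = {m.mature_id: m.arm for m in ann.matures.values()}
    hairpin = {m.mature_id: m.hairpin_id for m in ann.matures.values()}
    out = records.copy()
    out["_hairpin"] = out["mature_id"].map(hairpin)
    keep = []
    for (_host, _hp), grp in out.groupby(["host_gene_id", "_hairpin"], sort=False):
        if len(grp) == 1:
            keep.append(grp.index[0])
            continue
        rmax = grp["r"].max()
        best = grp[grp["r"] == rmax]
        if len(best) > 1:
            log.info("collapse_best_of_pair: tie at r=%.3g for %s; keeping 5p", rmax, _hp)
            five = best[best["mature_id"].map(arm) == "5p"]
            keep.append((five if len(five) else best).index[0])
        else:
            keep.append(best.index[0])
    return out.loc[sorted(keep)].drop(columns="_hairpin").reset_index(drop=True)


def summarize_correlation_counts(
    counts: Mapping[str, Mapping[str, int]]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-dataset correlation summary from raw counts, plus cross stats.

    ``counts`` maps dataset id to a dict with keys ``total``, ``positive``,
    ``gt_025``, ``gt_05``, ``fdr`` (counts of records with r>0, r>0.25,
    r>0.5, q below the FDR threshold). Returns the per-dataset table with
    percentages and the unweighted mean/sample-sd of the positive percentage
    across datasets.
    """
    if not counts:
        raise ValueError("at least one dataset required")
    rows = []
    for ds, c in counts.items():
        total = int(c["total"])
        if total == 0:
            log.warning("dataset %s: empty record set", ds)
            rows.append({"dataset": ds, "total": 0, "n_positive": 0, "pct_positive": 0.0,
                         "n_gt_025": 0, "pct_gt_025": 0.0, "n_gt_05": 0, "pct_gt_05": 0.0,
                         "n_fdr": 0, "pct_fdr": 0.0})
            continue
        row = {"dataset": ds, "total": total}
        for key, col in (("positive", "positive"), ("gt_025", "gt_025"),
                         ("gt_05", "gt_05"), ("fdr", "fdr")):
            n = int(c[key])
            row[f"n_{col}"] = n
            row[f"pct_{col}"] = 100.0 * n / total
        rows.append(row)
    table = pd.DataFrame(rows).set_index("dataset")
    pos = table["pct_positive"]
    cross = {
        "positive_pct_mean": float(pos.mean()),
        "positive_pct_sd": float(pos.std(ddof=1)) if len(pos) > 1 else float("nan"),
    }
    return table, cross


def summarize_correlations(
    records_per_dataset: Mapping[str, pd.DataFrame], fdr_threshold: float = 0.01
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Count r>0, r>0.25, r>0.5 and q<threshold records per dataset."""
    counts = {}
    for ds, rec in records_per_dataset.items():
        if len(rec) and "q" not in rec.columns:
            raise ValueError(f"dataset {ds}: records lack q values; run fdr_adjust first")
        counts[ds] = {
            "total": len(rec),
            "positive": int((rec["r"] > 0).sum()) if len(rec) else 0,
            "gt_025": int((rec["r"] > 0.25).sum()) if len(rec) else 0,
            "gt_05": int((rec["r"] > 0.5).sum()) if len(rec) else 0,
            "fdr": int((rec["q"] < fdr_threshold).sum()) if len(rec) else 0,
        }
    return summarize_correlation_counts(counts)
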