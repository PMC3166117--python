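"""Genomic annotation: intervals, arm assignment and host-gene relationships.

Coordinates are stored 0-based half-open ``[start, end)``; GFF3 input
(1-based closed) is converted on read and back on write. A hairpin is
*intragenic* iff some gene interval fully contains it (by default on the same
strand, since intragenic miRNAs are candidates for co-transcription from the
host-gene promoter); otherwise it is intergenic.

Arm (5p/3p) assignment follows transcript orientation: on the + strand the
mature with the smaller genomic start lies on the 5' arm; on the − strand the
mature with the larger start does.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

log = logging.getLogger(__name__)

GENE_FEATURE = "gene"
HAIRPIN_FEATURE = "miRNA_primary_transcript"
MATURE_FEATURE = "miRNA"


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval on a strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """Full containment, irrespective of strand."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


@dataclass
class GeneRecord:
    gene_id: str
    interval: GenomicInterval
    biotype: str = "protein_coding"


@dataclass
class MatureRecord:
    mature_id: str
    hairpin_id: str
    interval: GenomicInterval
    arm: Optional[str] = None  # "5p" or "3p", derived


@dataclass
class HairpinRecord:
    hairpin_id: str
    interval: GenomicInterval
    mature_ids: list[str] = field(default_factory=list)


@dataclass
class HostAssignment:
    hairpin_id: str
    status: str  # "intragenic" | "intergenic"
    host_gene_id: Optional[str] = None
    n_containing_genes: int = 0


@dataclass
class AnnotationSet:
    """Genes, hairpins and mature miRNAs sharing one coordinate system."""

    genes: dict[str, GeneRecord] = field(default_factory=dict)
    hairpins: dict[str, HairpinRecord] = field(default_factory=dict)
    matures: dict[str, MatureRecord] = field(default_factory=dict)

    def matures_of(self, hairpin_id: str) -> list[MatureRecord]:
        hp = self.hairpins[hairpin_id]
        return [self.matures[m] for m in hp.mature_ids]

    def validate(self) -> None:
        """Consistency check: matures lie within their hairpin, same strand."""
        for m in self.matures.values():
            hp = self.hairpins.get(m.hairpin_id)
            if hp is None:
                raise ValueError(f"mature {m.mature_id} references unknown hairpin {m.hairpin_id}")
            if not hp.interval.contains(m.interval):
                raise ValueError(f"mature {m.mature_id} not contained in hairpin {m.hairpin_id}")
            if hp.interval.strand != m.interval.strand:
                raise ValueError(f"mature {m.mature_id} on opposite strand of hairpin {m.hairpin_id}")


# ---------------------------------------------------------------------------
# GFF3 I/O (miRBase-style: gene / miRNA_primary_transcript / miRNA features,
# mature -> hairpin link through the Derives_from attribute)
# ---------------------------------------------------------------------------

def read_gff3(path: Union[str, Path]) -> AnnotationSet:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    ann = AnnotationSet()
    for feat in db.features_of_type(GENE_FEATURE):
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        biotype = feat.attributes.get("biotype", ["protein_coding"])[0]
        gid = feat.attributes["ID"][0]
        ann.genes[gid] = GeneRecord(gid, iv, biotype)
    for feat in db.features_of_type(HAIRPIN_FEATURE):
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        hid = feat.attributes["ID"][0]
        ann.hairpins[hid] = HairpinRecord(hid, iv)
    for feat in db.features_of_type(MATURE_FEATURE):
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        mid = feat.attributes["ID"][0]
        hid = feat.attributes["Derives_from"][0]
        if hid not in ann.hairpins:
            raise ValueError(f"mature {mid} Derives_from unknown hairpin {hid}")
        ann.matures[mid] = MatureRecord(mid, hid, iv)
        ann.hairpins[hid].mature_ids.append(mid)
    for hp in ann.hairpins.values():
        hp.mature_ids.sort()
    assign_all_arms(ann)
    return ann


def write_gff3(ann: AnnotationSet, path: Union[str, Path]) -> None:
    def line(iv: GenomicInterval, ftype: str, attrs: str) -> str:
        return "\t".join(
            [iv.chrom, "sisterstrand", ftype, str(iv.start + 1), str(iv.end),
             ".", iv.strand, ".", attrs]
        )

    rows = ["##gff-version 3"]
    for g in sorted(ann.genes.values(), key=lambda r: (r.interval.chrom, r.interval.start, r.gene_id)):
        rows.append(line(g.interval, GENE_FEATURE, f"ID={g.gene_id};biotype={g.biotype}"))
    for hp in sorted(ann.hairpins.values(), key=lambda r: (r.interval.chrom, r.interval.start, r.hairpin_id)):
        rows.append(line(hp.interval, HAIRPIN_FEATURE, f"ID={hp.hairpin_id}"))
        for mid in hp.mature_ids:
            m = ann.matures[mid]
            rows.append(line(m.interval, MATURE_FEATURE, f"ID={m.mature_id};Derives_from={hp.hairpin_id}"))
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Arm assignment
# ---------------------------------------------------------------------------

def assign_arms(hairpin: HairpinRecord, matures: Sequence[MatureRecord]) -> list[MatureRecord]:
    """Set the 5p/3p arm of 1-2 matures from their position in the hairpin.

    Sister-pair order is kept consistent with the physical position of the
    mature sequences in the precursor (5'-to-3' transcript order).
    """
    if not 1 <= len(matures) <= 2:
        raise ValueError(f"hairpin {hairpin.hairpin_id}: expected 1-2 matures, got {len(matures)}")
    for m in matures:
        if not hairpin.interval.contains(m.interval):
            raise ValueError(f"mature {m.mature_id} lies outside hairpin {hairpin.hairpin_id}")
        if m.interval.strand != hairpin.interval.strand:
            raise ValueError(f"mature {m.mature_id} on opposite strand of hairpin {hairpin.hairpin_id}")
    plus = hairpin.interval.strand == "+"
    if len(matures) == 2:
        a, b = matures
        if a.interval.overlaps(b.interval):
            raise ValueError(
                f"matures {a.mature_id} and {b.mature_id} of hairpin {hairpin.hairpin_id} overlap"
            )
        left, right = (a, b) if a.interval.start < b.interval.start else (b, a)
        five, three = (left, right) if plus else (right, left)
        return [replace(five, arm="5p"), replace(three, arm="3p")]
    (m,) = matures
    hp_mid = (hairpin.interval.start + hairpin.interval.end) / 2
    m_mid = (m.interval.start + m.interval.end) / 2
    left_of_mid = m_mid < hp_mid
    arm = "5p" if (left_of_mid == plus) else "3p"
    return [replace(m, arm=arm)]


def assign_all_arms(ann: AnnotationSet) -> None:
    for hp in ann.hairpins.values():
        matures = [ann.matures[m] for m in hp.mature_ids]
        if not matures:
            continue
        for assigned in assign_arms(hp, matures):
            ann.matures[assigned.mature_id] = assigned


# ---------------------------------------------------------------------------
# Intragenic classification
# ---------------------------------------------------------------------------

def classify_intragenic(
    hairpins: Iterable[HairpinRecord],
    genes: Iterable[GeneRecord],
    require_same_strand: bool = True,
) -> list[HostAssignment]:
    """Label each hairpin intragenic/intergenic by full gene containment.

    Only hairpins fully included in a gene's spanned region count as
    intragenic. When several genes contain a hairpin the shortest (most
    specific) container is chosen as host, ties broken by gene_id; the
    ambiguity is logged.
    """
    trees: dict[str, IntervalTree] = {}
    for i, g in enumerate(genes):
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, (i, g)
        )
    out: list[HostAssignment] = []
    for hp in sorted(hairpins, key=lambda h: h.hairpin_id):
        tree = trees.get(hp.interval.chrom)
        containing: list[GeneRecord] = []
        if tree is not None:
            for iv in tree.overlap(hp.interval.start, hp.interval.end):
                g = iv.data[1]
                if not g.interval.contains(hp.interval):
                    continue
                if require_same_strand and g.interval.strand != hp.interval.strand:
                    continue
                containing.append(g)
        if not containing:
            out.append(HostAssignment(hp.hairpin_id, "intergenic"))
            continue
        containing.sort(key=lambda g: (g.interval.length, g.gene_id))
        if len(containing) > 1:
            log.info(
                "hairpin %s contained in %d genes; choosing shortest host %s",
                hp.hairpin_id, len(containing), containing[0].gene_id,
            )
        out.append(
            HostAssignment(hp.hairpin_id, "intragenic", containing[0].gene_id, len(containing))
        )
    return out


def count_multi_mirna_hosts(
    assignments: Iterable[HostAssignment], ann: AnnotationSet
) -> dict[str, object]:
    """Counts of intragenic matures, distinct hosts and multi-miRNA hosts."""
    host_matures: dict[str, set[str]] = {}
    for a in assignments:
        if a.status != "intragenic":
            continue
        hp = ann.hairpins[a.hairpin_id]
        host_matures.setdefault(a.host_gene_id, set()).update(hp.mature_ids)
    n_intragenic = sum(len(v) for v in host_matures.values())
    n_hosts = len(host_matures)
    n_multi = sum(1 for v in host_matures.values() if len(v) >= 2)
    return {
        "n_intragenic_mirnas": n_intragenic,
        "n_host_genes": n_hosts,
        "n_hosts_with_2plus": n_multi,
        "frac_hosts_with_2plus": (n_multi / n_hosts) if n_hosts else 0.0,
    }


# ---------------------------------------------------------------------------
# Host-gene length comparison (Wilcoxon rank-sum)
# ---------------------------------------------------------------------------

def _exact_rank_sum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided rank-sum p by enumeration of all group assignments.

    Handles ties through midranks; the doubled midranks are integers, so the
    exact null distribution of the group rank-sum is obtained by a subset-sum
    count over equally likely subsets. Two-sided p = min(1, 2*min tail).
    """
    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    ranks2 = np.asarray(np.rint(2 * stats.rankdata(pooled)), dtype=int)
    obs = int(ranks2[:n].sum())
    total = ranks2.sum()
    # dp[j] maps achievable doubled-rank-sums of j-subsets to counts
    dp: list[dict[int, int]] = [dict() for _ in range(n + 1)]
    dp[0][0] = 1
    for r in ranks2:
        for j in range(min(n, len(ranks2)) - 1, -1, -1):
            if not dp[j]:
                continue
            tgt = dp[j + 1]
            for s, c in dp[j].items():
                tgt[s + r] = tgt.get(s + r, 0) + c
    dist = dp[n]
    n_total = math.comb(n + m, n)
    lo = sum(c for s, c in dist.items() if s <= obs)
    hi = sum(c for s, c in dist.items() if s >= obs)
    return min(1.0, 2.0 * min(lo, hi) / n_total)


def rank_sum_test(x: Sequence[float], y: Sequence[float], exact_max: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration (tie-aware) when both groups have at most ``exact_max``
    observations; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = list(x)
    y = list(y)
    if not x or not y:
        raise ValueError("both groups must be non-empty")
    if len(x) <= exact_max and len(y) <= exact_max:
        return _exact_rank_sum_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
    return float(res.pvalue)


def host_length_comparison(
    host_genes: Sequence[GeneRecord], all_genes: Sequence[GeneRecord]
) -> dict[str, float]:
    """Compare host-gene spans with all remaining genes.

    Returns arithmetic mean lengths per group, their ratio (host/rest) and a
    two-sided Wilcoxon rank-sum p-value. Host genes are removed from the
    comparison group.
    """
    host_ids = {g.gene_id for g in host_genes}
    host_len = [g.interval.length for g in host_genes]
    rest_len = [g.interval.length for g in all_genes if g.gene_id not in host_ids]
    if not host_len or not rest_len:
        raise ValueError("both host and non-host groups must be non-empty")
    mean_host = float(np.mean(host_len))
    mean_rest = float(np.mean(rest_len))
    return {
        "n_host": len(host_len),
        "n_rest": len(rest_len),
        "mean_host": mean_host,
        "mean_rest": mean_rest,
        "ratio": mean_host / mean_rest,
        "wilcoxon_p": rank_sum_test(host_len, rest_len),
    }


def assignments_to_table(assignments: Iterable[HostAssignment]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "hairpin_id": a.hairpin_id,
                "status": a.status,
                "host_gene_id": a.host_gene_id if a.host_gene_id is not None else "",
                "n_containing_genes": a.n_containing_genes,
            }
            for a in assignments
        ]
    )
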