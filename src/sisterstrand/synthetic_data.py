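"""Synthetic study generator with known ground truth.

Emulates the structure of matched miRNA/gene microarray studies: several
tissue groups of samples; hairpins carrying one or two mature miRNAs with
planted strand-selection behaviours; intragenic versus intergenic hairpin
placement with host genes drawn long; tunable miRNA-host-gene coupling; and
planted anti-correlated true-target relations hidden among decoy
predictions.

Intensities are generated log-normally: per-cell levels are laid out on the
log2 scale, Gaussian noise is added, and the result is exponentiated. The
"expressed" threshold is not planted: it emerges as the median of the
generated matrix, which the generator balances by adding single-mature
filler hairpins at background level so that the median falls between the
planted low and high intensity clusters. Correlations (miRNA-host and
miRNA-target) are planted through a Gaussian copula on the log2 scale.

Strand-selection modes and the pair class they plant:

==================== =============================================== =======
mode                 per-sample arm levels                           label
==================== =============================================== =======
fixed_bias           favoured arm high everywhere; other arm high-   AC
                     bias in one tissue, low elsewhere
tissue_flip          both high; offset +/- bias/2 with sign          C
                     flipping between tissues
concurrent_comparable both high; |offset| < 1                        C
alternative          favoured high, other low, every sample          A
silent               both low                                        NOT_EXPRESSED
==================== =============================================== =======

Every downstream module consumes only the emitted files (GFF3 + TSVs);
GroundTruth is for tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .annotation import (
    AnnotationSet,
    GeneRecord,
    GenomicInterval,
    HairpinRecord,
    MatureRecord,
    assign_all_arms,
    write_gff3,
)
from .datasets import ExpressionMatrix
from .target_enrichment import filter_mirnas

log = logging.getLogger(__name__)

MODES = ("fixed_bias", "tissue_flip", "concurrent_comparable", "alternative", "silent")

HAIRPIN_LEN = 80
MATURE_LEN = 22


def _default_pairs_per_mode() -> dict[str, int]:
    return {m: 50 for m in MODES}


@dataclass
class SimulationConfig:
    """Study-design knobs of the generator (defaults = the standard design)."""

    seed: int = 0
    n_tissues: int = 2
    samples_per_tissue: int = 20
    n_pairs_per_mode: dict[str, int] = field(default_factory=_default_pairs_per_mode)
    bias_magnitude: float = 2.0      # log2 units of arm offset for biased modes
    noise_sd: float = 0.1            # log2-scale Gaussian noise
    baseline_mean: float = 8.0       # log2 intensity of the matrix midpoint
    baseline_sd: float = 1.0         # spread of per-gene mean log2 intensities
    level_separation: float = 3.0    # log2 distance of high/low clusters from baseline
    n_genes: int = 2000
    frac_intragenic: float = 0.5
    frac_multi_mirna_hosts: float = 0.1
    host_coupling_rho: float = 0.2
    gene_profile_sd: float = 1.0     # log2 sd of gene expression profiles
    gene_length_log2_mean: float = 14.5
    gene_length_log2_sd: float = 0.8
    host_length_factor: float = 6.0
    n_true_targets: int = 500
    true_target_r: float = -0.7
    n_decoy_predictions: int = 10_000
    n_validated: int = 50
    filter_entropy_q: float = 0.25
    filter_mean_q: float = 0.25

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.n_pairs_per_mode.values()):
            raise ValueError("pair counts must be >= 0")
        if abs(self.host_coupling_rho) > 1 or abs(self.true_target_r) > 1:
            raise ValueError("correlations must lie in [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        unknown = set(self.n_pairs_per_mode) - set(MODES)
        if unknown:
            raise ValueError(f"unknown modes: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return self.n_tissues * self.samples_per_tissue

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimulationConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


@dataclass
class GroundTruth:
    """Generator bookkeeping: what was planted where (tests only)."""

    pair_mode: dict[str, str] = field(default_factory=dict)        # hairpin -> mode
    pair_label: dict[str, str] = field(default_factory=dict)       # hairpin -> A/AC/C/NOT_EXPRESSED
    favoured_arm: dict[str, str] = field(default_factory=dict)     # hairpin -> 5p/3p
    hairpin_host: dict[str, str] = field(default_factory=dict)     # hairpin -> host gene
    mature_host: dict[str, str] = field(default_factory=dict)      # mature -> host gene
    sample_tissue: dict[str, str] = field(default_factory=dict)
    coupled_mature: dict[str, str] = field(default_factory=dict)   # host gene -> mature
    true_relations: list[tuple[str, str]] = field(default_factory=list)
    decoy_relations: list[tuple[str, str]] = field(default_factory=list)
    validated: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = dataclasses.asdict(self)
        payload["true_relations"] = [list(t) for t in self.true_relations]
        payload["decoy_relations"] = [list(t) for t in self.decoy_relations]
        payload["validated"] = [list(t) for t in self.validated]
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    annotation: AnnotationSet
    truth: GroundTruth
    mirna: ExpressionMatrix
    genes: ExpressionMatrix
    metadata: pd.DataFrame
    predictions: pd.DataFrame
    validated: pd.DataFrame

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gff3(self.annotation, outdir / "genome.gff3")
        self.mirna.to_tsv(outdir / "mirna.tsv")
        self.genes.to_tsv(outdir / "genes.tsv")
        self.metadata.to_csv(outdir / "meta.tsv", sep="\t", index=False)
        self.predictions.to_csv(outdir / "predictions.tsv", sep="\t", index=False)
        self.validated.to_csv(outdir / "validated.tsv", sep="\t", index=False)
        self.truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------
# High/low bookkeeping: balance the matrix so its median falls in the gap
# ---------------------------------------------------------------------------

def _mode_cell_counts(cfg: SimulationConfig) -> tuple[int, int]:
    """Total (high, low) cells contributed by all sister-pair matures."""
    S = cfg.n_samples
    St = cfg.samples_per_tissue
    high = low = 0
    for mode, n in cfg.n_pairs_per_mode.items():
        if mode == "alternative":
            high += n * S
            low += n * S
        elif mode == "silent":
            low += n * 2 * S
        elif mode in ("concurrent_comparable", "tissue_flip"):
            high += n * 2 * S
        elif mode == "fixed_bias":
            high += n * (S + St)
            low += n * (S - St)
    return high, low


def _filler_plan(cfg: SimulationConfig) -> tuple[int, int, int]:
    """(n fillers at the majority-balancing level, 1 if a mixed filler is
    needed, high cells of the mixed filler). Fillers are single-mature
    hairpins whose cells sit at the level that equalizes the high and low
    cell counts, keeping the matrix median inside the gap."""
    high, low = _mode_cell_counts(cfg)
    S = cfg.n_samples
    excess = high - low  # >0: too many highs -> add low fillers
    n_full, rem = divmod(abs(excess), S)
    if rem == 0:
        return n_full, 0, 0
    # One extra mixed filler absorbs the remainder: it carries h cells at the
    # majority level and S-h at the balancing level, leaving |high-low| <= 1
    # with any spare cell on the low side (so the median call stays clean).
    h = (S - rem) // 2  # minority (majority-level) cells in the mixed filler
    return n_full, 1, h


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[AnnotationSet, GroundTruth]:
    """Generate genes, hairpins and matures with planted host relationships."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[0])
    truth = GroundTruth()
    ann = AnnotationSet()

    pair_ids: list[str] = []
    k = 0
    for mode in MODES:
        for _ in range(cfg.n_pairs_per_mode.get(mode, 0)):
            hid = f"sim-mir-{k:04d}"
            pair_ids.append(hid)
            truth.pair_mode[hid] = mode
            k += 1
    n_full_fill, n_mixed, _ = _filler_plan(cfg)
    filler_ids = [f"sim-mir-f{j:04d}" for j in range(n_full_fill + n_mixed)]
    for hid in filler_ids:
        truth.pair_mode[hid] = "filler"
    all_hairpins = pair_ids + filler_ids
    n_hairpins = len(all_hairpins)

    # hosts: long genes; multi hosts carry two hairpins
    n_intragenic = int(round(cfg.frac_intragenic * n_hairpins))
    n_hosts = int(round(n_intragenic / (1.0 + cfg.frac_multi_mirna_hosts))) if n_intragenic else 0
    n_multi = n_intragenic - n_hosts
    if n_multi < 0:
        n_hosts, n_multi = n_intragenic, 0
    if n_hosts > cfg.n_genes:
        raise ValueError("infeasible placement: more host genes required than genes simulated")
    n_intergenic = n_hairpins - n_intragenic
    if n_intergenic > cfg.n_genes:
        raise ValueError("infeasible placement: not enough intergenic gaps for hairpins")

    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    host_idx = set(rng.choice(cfg.n_genes, size=n_hosts, replace=False).tolist()) if n_hosts else set()
    lengths = np.exp2(
        rng.normal(cfg.gene_length_log2_mean, cfg.gene_length_log2_sd, cfg.n_genes)
    )
    lengths = np.maximum(lengths, 500).astype(int)
    if host_idx:
        hosts = np.array(sorted(host_idx))
        lengths[hosts] = np.maximum(
            (lengths[hosts] * cfg.host_length_factor).astype(int), 1000
        )

    cursor = 10_000
    gap_starts: list[int] = []
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    for i, gid in enumerate(gene_ids):
        gap = int(rng.integers(2000, 6000))
        gap_starts.append(cursor + 200)
        cursor += gap
        iv = GenomicInterval("chr1", cursor, cursor + int(lengths[i]), str(strands[i]))
        ann.genes[gid] = GeneRecord(gid, iv)
        cursor += int(lengths[i])

    # hairpin -> host slots (multi hosts contribute two slots)
    host_list = sorted(host_idx)
    slots: list[int] = []
    multi_hosts = set(rng.choice(host_list, size=n_multi, replace=False).tolist()) if n_multi else set()
    for gi in host_list:
        slots.append(gi)
        if gi in multi_hosts:
            slots.append(gi)
    assert len(slots) == n_intragenic

    order = rng.permutation(n_hairpins)
    intragenic_hairpins = [all_hairpins[i] for i in order[:n_intragenic]]
    intergenic_hairpins = [all_hairpins[i] for i in order[n_intragenic:]]

    placed_in_host: dict[int, int] = {}
    for hid, gi in zip(intragenic_hairpins, slots):
        g = ann.genes[gene_ids[gi]]
        nth = placed_in_host.get(gi, 0)
        frac = 0.2 if nth == 0 else 0.7
        placed_in_host[gi] = nth + 1
        start = g.interval.start + int(frac * g.interval.length)
        iv = GenomicInterval("chr1", start, start + HAIRPIN_LEN, g.interval.strand)
        ann.hairpins[hid] = HairpinRecord(hid, iv)
        truth.hairpin_host[hid] = g.gene_id

    for j, hid in enumerate(intergenic_hairpins):
        start = gap_starts[j]
        strand = str(rng.choice(["+", "-"]))
        iv = GenomicInterval("chr1", start, start + HAIRPIN_LEN, strand)
        ann.hairpins[hid] = HairpinRecord(hid, iv)

    # matures: pairs carry both arms, fillers one
    for hid in all_hairpins:
        hp = ann.hairpins[hid]
        s, e, strand = hp.interval.start, hp.interval.end, hp.interval.strand
        left = GenomicInterval("chr1", s + 4, s + 4 + MATURE_LEN, strand)
        right = GenomicInterval("chr1", e - 4 - MATURE_LEN, e - 4, strand)
        base = hid.replace("sim-mir-", "sim-miR-")
        is_pair = truth.pair_mode[hid] != "filler"
        if is_pair:
            five, three = (left, right) if strand == "+" else (right, left)
            for arm, iv in (("5p", five), ("3p", three)):
                mid = f"{base}-{arm}"
                ann.matures[mid] = MatureRecord(mid, hid, iv)
                hp.mature_ids.append(mid)
        else:
            # single filler mature sits on the 5' arm of its hairpin
            iv = left if strand == "+" else right
            mid = f"{base}-5p"
            ann.matures[mid] = MatureRecord(mid, hid, iv)
            hp.mature_ids.append(mid)
        hp.mature_ids.sort()
        if hid in truth.hairpin_host:
            for mid in hp.mature_ids:
                truth.mature_host[mid] = truth.hairpin_host[hid]
    assign_all_arms(ann)
    return ann, truth


# ---------------------------------------------------------------------------
# miRNA expression
# ---------------------------------------------------------------------------

def simulate_strand_expression(
    cfg: SimulationConfig,
    ann: AnnotationSet,
    truth: GroundTruth,
    rng: Optional[np.random.Generator] = None,
) -> ExpressionMatrix:
    """Generate the mature-miRNA intensity matrix with planted pair modes."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[1])
    T, St = cfg.n_tissues, cfg.samples_per_tissue
    S = cfg.n_samples
    samples = [f"t{t}_s{j:02d}" for t in range(T) for j in range(St)]
    tissue_of = np.repeat(np.arange(T), St)
    for sid, t in zip(samples, tissue_of):
        truth.sample_tissue[sid] = f"tissue{t}"

    bm, sep, bias = cfg.baseline_mean, cfg.level_separation, cfg.bias_magnitude
    hi_level, lo_level = bm + sep, bm - sep

    feature_ids: list[str] = []
    rows: list[np.ndarray] = []

    _, n_mixed, mixed_high = _filler_plan(cfg)
    excess_sign = 1 if _mode_cell_counts(cfg)[0] >= _mode_cell_counts(cfg)[1] else -1
    filler_level = lo_level if excess_sign > 0 else hi_level
    mixed_minority = hi_level if excess_sign > 0 else lo_level

    for hid in sorted(ann.hairpins):
        hp = ann.hairpins[hid]
        mode = truth.pair_mode.get(hid, "filler")
        if mode == "filler":
            (mid,) = hp.mature_ids
            row = np.full(S, filler_level)
            if n_mixed and mixed_high and hid == max(
                h for h, m in truth.pair_mode.items() if m == "filler"
            ):
                # the mixed filler fine-tunes the high/low balance
                pos = rng.choice(S, size=mixed_high, replace=False)
                row[pos] = mixed_minority
            feature_ids.append(mid)
            rows.append(row)
            continue
        by_arm = {ann.matures[m].arm: m for m in hp.mature_ids}
        favoured = str(rng.choice(["5p", "3p"]))
        other = "3p" if favoured == "5p" else "5p"
        truth.favoured_arm[hid] = favoured
        fav = np.empty(S)
        oth = np.empty(S)
        if mode == "alternative":
            fav[:], oth[:] = hi_level, lo_level
            label = "A"
        elif mode == "silent":
            fav[:], oth[:] = lo_level, lo_level
            label = "NOT_EXPRESSED"
        elif mode == "concurrent_comparable":
            delta = float(rng.uniform(0.2, 0.9))
            fav[:], oth[:] = hi_level + delta / 2, hi_level - delta / 2
            label = "C"
        elif mode == "tissue_flip":
            s0 = int(rng.choice([-1, 1]))
            signs = s0 * (-1) ** tissue_of
            fav[:] = hi_level + signs * bias / 2
            oth[:] = hi_level - signs * bias / 2
            label = "C"
        else:  # fixed_bias
            conc_t = int(rng.integers(T))
            fav[:] = hi_level
            oth[:] = np.where(tissue_of == conc_t, hi_level - bias, lo_level)
            label = "AC" if T >= 2 else "C"
        truth.pair_label[hid] = label
        feature_ids.append(by_arm[favoured])
        rows.append(fav)
        feature_ids.append(by_arm[other])
        rows.append(oth)

    levels = np.vstack(rows)
    if cfg.noise_sd > 0:
        levels = levels + rng.normal(0.0, cfg.noise_sd, levels.shape)
    data = pd.DataFrame(np.exp2(levels), index=feature_ids, columns=samples)
    data = data.sort_index()
    return ExpressionMatrix(data)


def sample_metadata(cfg: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    rows = []
    for i, (sid, tissue) in enumerate(truth.sample_tissue.items()):
        rows.append(
            {
                "sample_id": sid,
                "dataset_id": "SIM",
                "tissue": tissue,
                "condition": "normal" if i % 2 == 0 else "disease",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene expression, host coupling and target relations
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        return np.zeros_like(x), mu, 0.0
    return (x - mu) / sd, mu, sd


def simulate_host_and_targets(
    cfg: SimulationConfig,
    ann: AnnotationSet,
    truth: GroundTruth,
    mirna: ExpressionMatrix,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate the gene matrix plus prediction/validated relation tables.

    Host genes are coupled to the log2 profile of one of their mature
    miRNAs with Pearson ``host_coupling_rho`` (Gaussian copula, matching
    profile sd so that rho=1 with zero noise is an exact linear relation).
    True-target genes are drawn anti-correlated (``true_target_r``) with
    regulators sampled from the filtered, intragenic matures; decoy
    predictions link independent profiles.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[2])
    if cfg.n_validated > cfg.n_true_targets:
        raise ValueError("n_validated cannot exceed n_true_targets")
    S = cfg.n_samples
    samples = mirna.sample_ids
    gene_ids = sorted(ann.genes)
    n_genes = len(gene_ids)

    mus = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n_genes)
    Z = rng.normal(0.0, 1.0, (n_genes, S))
    levels = mus[:, None] + cfg.gene_profile_sd * Z
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    mirna_log2 = np.log2(mirna.data)

    # host coupling
    host_to_hairpins: dict[str, list[str]] = {}
    for hid, gid in sorted(truth.hairpin_host.items()):
        host_to_hairpins.setdefault(gid, []).append(hid)
    rho = cfg.host_coupling_rho
    for gid in sorted(host_to_hairpins):
        hp = ann.hairpins[sorted(host_to_hairpins[gid])[0]]
        mids = sorted(hp.mature_ids)
        by_arm = {ann.matures[m].arm: m for m in mids}
        mid = by_arm.get("5p", mids[0])
        if mid not in mirna.data.index:
            continue
        zm, _, sm = _zscore(mirna_log2.loc[mid].to_numpy())
        eps = rng.normal(0.0, 1.0, S)
        i = gene_pos[gid]
        levels[i] = mus[i] + sm * (rho * zm + math.sqrt(max(0.0, 1 - rho * rho)) * eps)
        truth.coupled_mature[gid] = mid

    # true targets: regulators from the filtered intragenic matures
    predictions: list[tuple[str, str]] = []
    if cfg.n_true_targets > 0 or cfg.n_decoy_predictions > 0:
        retained = set(filter_mirnas(mirna, cfg.filter_entropy_q, cfg.filter_mean_q))
        eligible = sorted(retained & set(truth.mature_host))
        if not eligible:
            raise ValueError("no eligible regulator: no retained intragenic mature miRNA")
        host_genes = set(truth.hairpin_host.values())
        free_genes = sorted(set(gene_ids) - host_genes)
        if cfg.n_true_targets > len(free_genes):
            raise ValueError("not enough non-host genes for the requested true targets")
        rt = cfg.true_target_r
        target_genes = [free_genes[i] for i in rng.choice(len(free_genes), cfg.n_true_targets, replace=False)]
        regulators = [eligible[i] for i in rng.integers(0, len(eligible), cfg.n_true_targets)]
        for mid, gid in zip(regulators, target_genes):
            zm, _, _ = _zscore(mirna_log2.loc[mid].to_numpy())
            eps = rng.normal(0.0, 1.0, S)
            i = gene_pos[gid]
            levels[i] = mus[i] + cfg.gene_profile_sd * (
                rt * zm + math.sqrt(max(0.0, 1 - rt * rt)) * eps
            )
            truth.true_relations.append((mid, gid))
        predictions.extend(truth.true_relations)

        # decoys: independent miRNA-gene pairs, never a regulator's own host
        taken = set(truth.true_relations)
        n_needed = cfg.n_decoy_predictions
        guard = 0
        while len(truth.decoy_relations) < n_needed:
            guard += 1
            if guard > 200:
                raise ValueError("cannot draw enough unique decoy predictions")
            batch = max(1000, n_needed)
            ms = rng.integers(0, len(eligible), batch)
            gs = rng.integers(0, n_genes, batch)
            for a, b in zip(ms, gs):
                if len(truth.decoy_relations) >= n_needed:
                    break
                mid, gid = eligible[a], gene_ids[b]
                rel = (mid, gid)
                if rel in taken or truth.mature_host.get(mid) == gid:
                    continue
                taken.add(rel)
                truth.decoy_relations.append(rel)
        predictions.extend(truth.decoy_relations)

        if cfg.n_validated:
            pick = rng.choice(len(truth.true_relations), cfg.n_validated, replace=False)
            truth.validated = [truth.true_relations[i] for i in sorted(pick)]

    genes_em = ExpressionMatrix(pd.DataFrame(np.exp2(levels), index=gene_ids, columns=samples))
    pred_df = pd.DataFrame(predictions, columns=["mirna_id", "target_gene_id"])
    if len(pred_df):
        pred_df = pred_df.iloc[rng.permutation(len(pred_df))].reset_index(drop=True)
    val_df = pd.DataFrame(truth.validated, columns=["mirna_id", "target_gene_id"])
    return genes_em, pred_df, val_df


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Run the full generator with deterministic per-stage random streams."""
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(3)]
    ann, truth = simulate_annotation(cfg, streams[0])
    mirna = simulate_strand_expression(cfg, ann, truth, streams[1])
    genes, predictions, validated = simulate_host_and_targets(cfg, ann, truth, mirna, streams[2])
    meta = sample_metadata(cfg, truth)
    return SimulatedStudy(cfg, ann, truth, mirna, genes, meta, predictions, validated)
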