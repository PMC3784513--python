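"""Recurrently mutated coordinates, motif enrichment E_i, tissue shares and
pathway hit ranking.

A coordinate mutated in at least two distinct patient samples is a candidate
driver signal.  With d_i the number of distinct recurrent coordinates whose
canonical context is motif i, the relative enrichment is

    E_i = D_i / T_i,    D_i = d_i / sum(d_i),    T_i = t_i / sum(t_i),

which is ~1 for every motif when recurrence is independent of flanking
sequence.  The tissue share S_n = s_n / sum(s_n) with s_n = t_n / c_n
normalizes recurrent hits at a chosen motif set (t_n per tissue) by each
tissue's total substitution count c_n, so equally-behaving tissues contribute
equal percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .motifs import MOTIFS, ContextError, MotifCountTable, canonical_context
from .mutation_io import MutationDataset

__all__ = [
    "RecurrenceTable",
    "find_recurrent_sites",
    "motif_enrichment",
    "tissue_share",
    "read_gmt",
    "pathway_hit_ranking",
]


@dataclass
class RecurrenceTable:
    """Recurrent coordinates with their motif assignment and per-motif d_i."""

    sites: pd.DataFrame  # chrom, pos, ref, n_samples, motif, tissues
    d: pd.Series  # distinct recurrent coordinates per canonical motif
    min_samples: int = 2

    @property
    def total(self) -> int:
        return int(self.d.sum())


def find_recurrent_sites(
    ds: MutationDataset,
    genome: Mapping[str, str],
    min_samples: int = 2,
) -> RecurrenceTable:
    """Coordinates hit by >= ``min_samples`` distinct samples, with contexts.

    Repeated hits by the same sample count once; a coordinate counts once
    toward its motif's d_i no matter how many samples beyond the threshold
    hit it.  Coordinates at A:T pairs or without an extractable canonical
    context appear in ``sites`` with motif NaN but do not enter d_i.
    """
    rec = ds.records
    if rec["sample"].isna().any():
        raise ValueError("recurrence analysis requires sample labels on all records")
    per_site = (
        rec.drop_duplicates(subset=["sample", "chrom", "pos"])
        .groupby(["chrom", "pos"])
        .agg(
            ref=("ref", "first"),
            n_samples=("sample", "nunique"),
            tissues=("tissue", lambda s: tuple(sorted(set(s.dropna())))),
        )
        .reset_index()
    )
    hits = per_site[per_site["n_samples"] >= min_samples].copy()
    motifs = []
    for row in hits.itertuples(index=False):
        try:
            motifs.append(canonical_context(genome, row.chrom, row.pos, row.ref))
        except ContextError:
            motifs.append(None)
    hits["motif"] = motifs
    d = (
        hits["motif"]
        .value_counts()
        .reindex(list(MOTIFS))
        .fillna(0)
        .astype(np.int64)
    )
    return RecurrenceTable(hits.reset_index(drop=True), d, min_samples=min_samples)


def motif_enrichment(
    rt: RecurrenceTable | pd.Series, t: MotifCountTable | pd.Series
) -> pd.DataFrame:
    """E_i = (d_i / sum d) / (t_i / sum t) per canonical motif.

    Motifs with t_i = 0 get E_i = NaN and are flagged undefined.
    """
    d = rt.d if isinstance(rt, RecurrenceTable) else rt
    d = d.reindex(list(MOTIFS)).fillna(0).astype(np.int64)
    t_series = (t.counts if isinstance(t, MotifCountTable) else t).reindex(
        list(MOTIFS)
    ).fillna(0).astype(np.int64)
    if d.sum() == 0:
        raise ValueError("no recurrent sites: sum(d_i) is zero")
    big_d = d / d.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        big_t = t_series / t_series.sum()
        e = big_d / big_t.replace(0, np.nan)
    return pd.DataFrame(
        {"d": d, "t": t_series, "D": big_d, "T": big_t, "E": e,
         "defined": t_series > 0}
    )


def tissue_share(
    recurrent_hits: Mapping[str, int] | pd.Series,
    totals: Mapping[str, int] | pd.Series,
) -> pd.DataFrame:
    """Normalized tissue shares S_n of recurrent hits at a chosen motif set.

    ``recurrent_hits`` is t_n (recurrent hits attributed to tissue n) and
    ``totals`` is c_n (that tissue's total substitution count); tissues with
    c_n = 0 are excluded with a warning.  Shares sum to one.
    """
    t_n = pd.Series(recurrent_hits, dtype=float)
    c_n = pd.Series(totals, dtype=float).reindex(t_n.index)
    if c_n.isna().any():
        missing = list(t_n.index[c_n.isna()])
        raise ValueError(f"no total substitution count for tissues: {missing}")
    zero = c_n == 0
    if zero.any():
        warnings.warn(f"excluding tissues with zero totals: {list(t_n.index[zero])}")
        t_n, c_n = t_n[~zero], c_n[~zero]
    s_n = t_n / c_n
    denom = s_n.sum()
    if denom == 0:
        raise ValueError("no recurrent hits in any included tissue")
    share = s_n / denom
    return pd.DataFrame(
        {"t_n": t_n, "c_n": c_n, "s_n": s_n, "S": share, "percent": 100 * share}
    )


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Gene sets from a GMT file (name, description, member genes...)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    if not sets:
        raise ValueError(f"{path}: no gene sets parsed")
    return sets


def pathway_hit_ranking(
    sample_genes: Mapping[str, Iterable[str]],
    gene_sets: Mapping[str, Iterable[str]],
    sample_tissue: Mapping[str, str] | None = None,
) -> dict:
    """Rank pathways by how often patient samples hit them.

    For each pathway and tissue, the score is the percentage of that tissue's
    samples with at least one mutated member gene; the combined ranking score
    is the unweighted mean of per-tissue percentages.  Per-pathway gene hit
    counts (number of samples mutating each member gene) are retained for
    heatmap export.
    """
    if not gene_sets:
        raise ValueError("empty gene set collection")
    gene_sets = {name: frozenset(gs) for name, gs in gene_sets.items()}
    sample_genes = {s: frozenset(gs) for s, gs in sample_genes.items()}
    if sample_tissue is None:
        sample_tissue = {s: "all" for s in sample_genes}
    tissues = sorted(set(sample_tissue.values()))
    by_tissue = {
        t: [s for s in sample_genes if sample_tissue.get(s) == t] for t in tissues
    }

    percent = pd.DataFrame(index=sorted(gene_sets), columns=tissues, dtype=float)
    gene_hits: dict[str, pd.Series] = {}
    for name, members in gene_sets.items():
        hit_counts: dict[str, int] = {g: 0 for g in sorted(members)}
        for s, genes in sample_genes.items():
            for g in genes & members:
                hit_counts[g] += 1
        gene_hits[name] = pd.Series(hit_counts, dtype=np.int64)
        for t in tissues:
            samples = by_tissue[t]
            if not samples:
                percent.loc[name, t] = np.nan
                continue
            n_hit = sum(1 for s in samples if sample_genes[s] & members)
            percent.loc[name, t] = 100 * n_hit / len(samples)
    combined = percent.mean(axis=1, skipna=True).rename("combined_score")
    ranking = (
        percent.join(combined)
        .sort_values("combined_score", ascending=False, kind="stable")
    )
    return {"ranking": ranking, "per_tissue_percent": percent, "gene_hits": gene_hits}
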