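"""Transcription-strand orientation of mutations and splice-junction profiles.

The non-transcribed (NT) strand of a gene carries the same sequence as the
mRNA; the transcribed (T) strand is the template.  Because every canonical
context fixes which strand carries the mutated guanine (a ref=G record has
the G on the forward strand, a ref=C record on the reverse), each genic
mutation can be oriented: G on the NT strand vs G on the T strand, yielding
the per-motif asymmetry ratio r = NT / T.

Splice positions are transcription-oriented with no position zero: the last
exonic base is -1 for donors, the first intronic base +1 (the canonical
donor GT sits at +1,+2); acceptor windows index intronic bases as negative
approaching the junction (the canonical AG at -2,-1) and exonic bases as
positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .motifs import (
    MOTIFS,
    ContextError,
    canonical_context,
    resolve_chrom,
    reverse_complement,
)
from .mutation_io import MutationDataset

__all__ = [
    "GeneModel",
    "Junction",
    "GeneIndex",
    "read_gene_models",
    "orient_mutation",
    "strand_ratio_per_motif",
    "splice_position_profile",
    "junction_conservation",
]


@dataclass(frozen=True)
class Junction:
    """One exon-intron boundary, described by its intron's genomic extent."""

    kind: str  # "donor" or "acceptor"
    chrom: str
    strand: str
    intron_start: int  # 1-based inclusive first intronic base
    intron_end: int  # 1-based inclusive last intronic base
    gene_id: str = ""

    def offset(self, pos: int) -> int:
        """Transcription-oriented signed position of ``pos`` (no zero)."""
        i0, i1 = self.intron_start, self.intron_end
        if self.kind == "donor":
            if self.strand == "+":
                return pos - i0 + 1 if pos >= i0 else pos - i0
            return i1 - pos + 1 if pos <= i1 else i1 - pos
        if self.strand == "+":
            return pos - i1 if pos > i1 else pos - i1 - 1
        return i0 - pos if pos < i0 else -(pos - i0 + 1)


@dataclass
class GeneModel:
    """A gene with ordered, non-overlapping exons (1-based inclusive)."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in exons:
            if b < a:
                raise ValueError(f"{self.gene_id}: inverted exon ({a}, {b})")
        for (_, b1), (a2, _) in zip(exons, exons[1:]):
            if a2 <= b1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (b1 + 1, a2 - 1) for (_, b1), (a2, _) in zip(self.exons, self.exons[1:])
        ]

    def junctions(self) -> list[Junction]:
        """One donor and one acceptor per intron; single-exon genes have none."""
        out = []
        for i0, i1 in self.introns:
            for kind in ("donor", "acceptor"):
                out.append(
                    Junction(kind, self.chrom, self.strand, i0, i1, self.gene_id)
                )
        return out


def read_gene_models(path) -> list[GeneModel]:
    """Simplified gene-model TSV: gene_id, chrom, strand, exon_starts, exon_ends
    (comma-separated, 1-based inclusive).  BED12 is also accepted (12 columns,
    0-based half-open blocks)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) >= 12 and parts[9].rstrip(",").replace(",", "").isdigit():
                chrom, chrom_start = parts[0], int(parts[1])
                gene_id, strand = parts[3], parts[5]
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                starts = [int(x) for x in parts[11].rstrip(",").split(",")]
                exons = [
                    (chrom_start + s + 1, chrom_start + s + sz)
                    for s, sz in zip(starts, sizes)
                ]
            else:
                gene_id, chrom, strand, starts_s, ends_s = parts[:5]
                starts = [int(x) for x in starts_s.rstrip(",").split(",")]
                ends = [int(x) for x in ends_s.rstrip(",").split(",")]
                exons = list(zip(starts, ends))
            genes.append(GeneModel(gene_id, chrom, strand, exons))
    return genes


class GeneIndex:
    """Interval lookup of gene spans and collected junctions, per chromosome."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        self.junctions: dict[str, list[Junction]] = {}
        for g in self.genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree.addi(g.start, g.end + 1, g)  # half-open over 1-based coords
            self.junctions.setdefault(g.chrom, []).extend(g.junctions())

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        resolved = resolve_chrom(chrom, self._trees)
        if resolved is None:
            return []
        return [iv.data for iv in self._trees[resolved].at(pos)]

    def junctions_for(self, chrom: str) -> list[Junction]:
        resolved = resolve_chrom(chrom, self.junctions)
        return self.junctions.get(resolved, []) if resolved else []


def orient_mutation(
    chrom: str, pos: int, ref: str, genes: GeneIndex
) -> str:
    """Orientation of a G:C mutation relative to transcription.

    Returns "NT" when the mutated guanine lies on the non-transcribed strand
    of the (unique-strand) overlapping gene(s), "T" when on the template
    strand, "ambiguous" for overlapping genes on opposite strands, and
    "intergenic" outside all genes.  ref must be G or C (the canonical
    context fixes the G strand).
    """
    ref = ref.upper()
    if ref not in "GC":
        raise ValueError("orientation is defined only for G/C reference alleles")
    hits = genes.overlapping(chrom, pos)
    if not hits:
        return "intergenic"
    strands = {g.strand for g in hits}
    if len(strands) > 1:
        return "ambiguous"
    gene_strand = strands.pop()
    g_strand = "+" if ref == "G" else "-"
    return "NT" if g_strand == gene_strand else "T"


def strand_ratio_per_motif(
    ds: MutationDataset, genes: GeneIndex, genome: Mapping[str, str]
) -> pd.DataFrame:
    """Per-motif NT and T counts and the asymmetry ratio r = NT / T.

    Only records inside genes with a unique strand and with an extractable
    canonical context are tallied; r is NaN where T = 0 (flagged).  ln(r) is
    included for regression against stacking or ionization descriptors.
    """
    counts = pd.DataFrame(0, index=list(MOTIFS), columns=["NT", "T"], dtype=np.int64)
    for row in ds.records.itertuples(index=False):
        if row.ref not in "GC" or row.chrom not in genome:
            continue
        try:
            motif = canonical_context(genome, row.chrom, row.pos, row.ref)
        except ContextError:
            continue
        if motif is None:
            continue
        side = orient_mutation(row.chrom, row.pos, row.ref, genes)
        if side in ("NT", "T"):
            counts.loc[motif, side] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        r = counts["NT"] / counts["T"].replace(0, np.nan)
    out = counts.copy()
    out["r"] = r
    out["ln_r"] = np.log(r.where(r > 0))
    out["defined"] = counts["T"] > 0
    return out


def splice_position_profile(
    ds: MutationDataset, genes: GeneIndex, window: int = 20
) -> dict:
    """Counts of mutations at signed positions around donor/acceptor junctions.

    Each mutation within ``window`` of a junction increments the signed
    position of its nearest junction; exact distance ties between two
    junctions increment both and are reported in ``n_ties``.
    """
    positions = [p for p in range(-window, window + 1) if p != 0]
    profiles = {
        kind: pd.Series(0, index=positions, dtype=np.int64)
        for kind in ("donor", "acceptor")
    }
    n_ties = 0
    for row in ds.records.itertuples(index=False):
        juncs = genes.junctions_for(row.chrom)
        best: list[tuple[int, Junction]] = []
        best_abs = window + 1
        for j in juncs:
            off = j.offset(row.pos)
            a = abs(off)
            if a > window:
                continue
            if a < best_abs:
                best, best_abs = [(off, j)], a
            elif a == best_abs:
                best.append((off, j))
        if not best:
            continue
        if len(best) > 1:
            n_ties += 1
        for off, j in best:
            profiles[j.kind][off] += 1
    return {"donor": profiles["donor"], "acceptor": profiles["acceptor"],
            "n_ties": n_ties, "window": window}


def _junction_window_seq(
    genome: Mapping[str, str], j: Junction, window: int
) -> str | None:
    """Transcribed-orientation sequence at positions -window..+window."""
    seq = genome[j.chrom]
    i0, i1 = j.intron_start, j.intron_end
    if j.kind == "donor":
        lo, hi = (i0 - window, i0 + window) if j.strand == "+" else (
            i1 - window + 1, i1 + window + 1
        )
    else:
        lo, hi = (i1 - window + 1, i1 + window + 1) if j.strand == "+" else (
            i0 - window, i0 + window
        )
    # lo/hi are 1-based inclusive bounds of a 2*window slice
    if lo < 1 or hi - 1 > len(seq):
        return None
    word = seq[lo - 1 : hi - 1]
    return word if j.strand == "+" else reverse_complement(word)


def junction_conservation(
    genome: Mapping[str, str], genes: GeneIndex, window: int = 25
) -> dict:
    """Per-position base frequencies around unique donor/acceptor junctions.

    For each signed position (transcription orientation, no zero) the
    fraction of junctions carrying each base is computed; ``conservation``
    is the maximum base fraction per position.  Junction windows truncated
    by a sequence end are skipped.
    """
    positions = [p for p in range(-window, window + 1) if p != 0]
    out = {}
    for kind in ("donor", "acceptor"):
        uniq = {
            (j.chrom, j.strand, j.intron_start, j.intron_end)
            for chrom_juncs in genes.junctions.values()
            for j in chrom_juncs
            if j.kind == kind
        }
        counts = pd.DataFrame(0, index=positions, columns=list("ACGT"), dtype=np.int64)
        n = 0
        for chrom, strand, i0, i1 in sorted(uniq):
            word = _junction_window_seq(
                genome, Junction(kind, chrom, strand, i0, i1), window
            )
            if word is None:
                continue
            n += 1
            for p, base in zip(positions, word):
                if base in "ACGT":
                    counts.loc[p, base] += 1
        freq = counts.div(counts.sum(axis=1).replace(0, np.nan), axis=0)
        out[kind] = {
            "frequencies": freq,
            "conservation": freq.max(axis=1),
            "n_junctions": n,
        }
    return out
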