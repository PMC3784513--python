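"""Synthetic genomes, gene models and context-biased mutation catalogs.

Every analysis stage in this package is recovery-testable against data with
known ground truth.  The generator emulates the statistical structure the
analyses assume: an i.i.d. background genome at a stated GC content, a
mappability mask covering a stated fraction, genes with canonical GT..AG
introns, and a site-wise independent Bernoulli mutation process whose
per-site rate is

    rate(site) = mu * kappa_CpG^[CGNN] * kappa_GpR^[DGRN] * kappa_P4A^[NGRA]
                 * exp(a - b * VIP(trimer))^[vip model on, DGN]
                 * beta^[G on the non-transcribed strand of a gene]
                 * splice positional weight (optional),

evaluated through the same canonical-context machinery the analyses use.
Recurrent coordinates can be injected into a chosen number of samples.  All
sampling is driven by a single integer seed and is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import (
    MOTIFS,
    Genome,
    MappabilityMask,
    enumerate_motifs,
    gc_site_contexts,
)
from .physchem import VIP_TRIMER_EV
from .transcription import GeneModel, Junction

__all__ = [
    "SyntheticConfig",
    "make_genome",
    "make_genes",
    "simulate_mutations",
    "simulate_catalog",
    "motif_rate_multipliers",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ALTS = {b: tuple(c for c in "ACGT" if c != b) for b in "ACGT"}


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults are a genome-wide-like null scenario
    with a CpG hotspot and a milder GpR effect."""

    genome_length: int = 1_000_000
    gc_content: float = 0.41
    chrom_name: str = "chr1"
    mappable_fraction: float = 0.9
    mappable_window: int = 1_000
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (200, 2_000)
    intergenic_gap: tuple[int, int] = (500, 5_000)
    # mutation model
    mu: float = 1e-4
    kappa_cpg: float = 5.0
    kappa_gpr: float = 2.0
    kappa_p4a: float = 1.0
    vip_intercept: float | None = None  # a in exp(a - b * VIP)
    vip_slope: float | None = None  # b; None disables the VIP term
    nt_bias: float = 1.0
    splice_weights: dict[tuple[str, int], float] | None = None
    # clustered (kataegis-like) bursts; off by default
    n_clusters: int = 0
    cluster_halfwidth: int = 500
    cluster_multiplier: float = 10.0
    # samples
    n_samples: int = 10
    tissues: tuple[str, ...] = ("tissue_1",)
    recurrent_sites: tuple[tuple[str, int, int], ...] = ()
    dataset_name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.genome_length < 100:
            raise ValueError("genome_length must be >= 100")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        for name in ("mu", "kappa_cpg", "kappa_gpr", "kappa_p4a", "nt_bias",
                     "cluster_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def make_genome(
    cfg: SyntheticConfig, seed: int
) -> tuple[Genome, MappabilityMask | None]:
    """I.i.d. random genome at the configured GC content, plus a mask.

    The mask keeps each ``mappable_window``-sized tile independently with
    probability ``mappable_fraction``; ``mappable_fraction >= 1`` returns
    mask=None (everything mappable).
    """
    rng = np.random.default_rng(seed)
    gc = cfg.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=cfg.genome_length, p=probs)
    seq = _BASE_BYTES[codes].tobytes().decode("ascii")
    genome = Genome({cfg.chrom_name: seq})
    if cfg.mappable_fraction >= 1.0:
        return genome, None
    n_win = int(np.ceil(cfg.genome_length / cfg.mappable_window))
    keep = rng.random(n_win) < cfg.mappable_fraction
    ivals = [
        (i * cfg.mappable_window, min((i + 1) * cfg.mappable_window, cfg.genome_length))
        for i in range(n_win)
        if keep[i]
    ]
    if not ivals:  # degenerate draw on tiny genomes: keep one window
        ivals = [(0, min(cfg.mappable_window, cfg.genome_length))]
    mask = MappabilityMask({cfg.chrom_name: np.asarray(ivals)}, label="synthetic")
    return genome, mask


def make_genes(
    genome: Genome, cfg: SyntheticConfig, seed: int
) -> tuple[Genome, list[GeneModel]]:
    """Place non-overlapping genes and write canonical splice junctions.

    Genes are laid out left to right with random intergenic gaps and random
    strands; each intron's first two transcribed bases are forced to GT and
    its last two to AG (strand-aware, so minus-strand introns read CT..AC on
    the forward strand).  Returns a new genome with the edits applied; if the
    sequence is too short, fewer genes are placed with a warning.
    """
    rng = np.random.default_rng(seed)
    chrom = cfg.chrom_name
    seq = bytearray(genome[chrom], "ascii")
    length = len(seq)
    genes: list[GeneModel] = []
    cursor = 1 + rng.integers(*cfg.intergenic_gap)
    for gi in range(cfg.n_genes):
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        ex_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, size=n_ex)
        in_lens = rng.integers(
            cfg.intron_length[0], cfg.intron_length[1] + 1, size=n_ex - 1
        )
        span = int(ex_lens.sum() + in_lens.sum())
        if cursor + span + 4 > length:
            warnings.warn(
                f"sequence exhausted: placed {gi} of {cfg.n_genes} genes"
            )
            break
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        p = int(cursor)
        for k in range(n_ex):
            exons.append((p, p + int(ex_lens[k]) - 1))
            p += int(ex_lens[k])
            if k < n_ex - 1:
                p += int(in_lens[k])
        gene = GeneModel(f"gene_{gi + 1:03d}", chrom, strand, exons)
        for i0, i1 in gene.introns:  # 1-based inclusive intron bounds
            if strand == "+":
                seq[i0 - 1 : i0 + 1] = b"GT"
                seq[i1 - 2 : i1] = b"AG"
            else:
                seq[i0 - 1 : i0 + 1] = b"CT"
                seq[i1 - 2 : i1] = b"AC"
        genes.append(gene)
        cursor = gene.end + 1 + int(rng.integers(*cfg.intergenic_gap))
    new_genome = Genome({**{c: genome[c] for c in genome}, chrom: seq.decode("ascii")})
    return new_genome, genes


def motif_rate_multipliers(cfg: SyntheticConfig) -> np.ndarray:
    """Per-motif rate multiplier vector (length 64, motif order)."""
    flags = enumerate_motifs()
    mult = np.ones(len(MOTIFS))
    mult[flags["cgnn"].to_numpy()] *= cfg.kappa_cpg
    mult[flags["dgrn"].to_numpy()] *= cfg.kappa_gpr
    mult[flags["ngra"].to_numpy()] *= cfg.kappa_p4a
    if cfg.vip_slope is not None:
        a = cfg.vip_intercept if cfg.vip_intercept is not None else 0.0
        for i, motif in enumerate(MOTIFS):
            trimer = motif[:3]
            if trimer in VIP_TRIMER_EV:
                mult[i] *= np.exp(a - cfg.vip_slope * VIP_TRIMER_EV[trimer])
    return mult


def _splice_factor(
    cfg: SyntheticConfig, genes: Sequence[GeneModel], chrom: str, length: int
) -> np.ndarray | None:
    if not cfg.splice_weights:
        return None
    factor = np.ones(length)
    max_off = max(abs(o) for (_, o) in cfg.splice_weights)
    for gene in genes:
        if gene.chrom != chrom:
            continue
        for j in gene.junctions():
            anchor = j.intron_start if (
                (j.kind == "donor") == (j.strand == "+")
            ) else j.intron_end
            for pos in range(anchor - max_off - 2, anchor + max_off + 3):
                if not 1 <= pos <= length:
                    continue
                w = cfg.splice_weights.get((j.kind, j.offset(pos)))
                if w is not None:
                    factor[pos - 1] *= w
    return factor


def simulate_mutations(
    genome: Genome,
    genes: Sequence[GeneModel],
    mask: MappabilityMask | None,
    cfg: SyntheticConfig,
    seed: int,
) -> pd.DataFrame:
    """Draw a multi-sample catalog of substitutions at G:C sites.

    Each mappable G/C site with an extractable canonical context is mutated
    independently per sample with probability mu times the product of its
    applicable context multipliers (see module docstring); the alt allele is
    uniform over the three alternatives.  Listed recurrent coordinates are
    forced into the first k samples.  Raises before sampling if any per-site
    rate would exceed 1.
    """
    rng = np.random.default_rng(seed)
    mult = motif_rate_multipliers(cfg)
    tissues = cfg.tissues if cfg.tissues else ("tissue_1",)
    samples = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    sample_tissue = {s: tissues[i % len(tissues)] for i, s in enumerate(samples)}

    frames = []
    for chrom in genome:
        seq = genome[chrom]
        pos0, motif_idx, forward = gc_site_contexts(seq)
        if mask is not None:
            keep = mask.contains_many(chrom, pos0)
            pos0, motif_idx, forward = pos0[keep], motif_idx[keep], forward[keep]
        if pos0.size == 0:
            continue
        rate = cfg.mu * mult[motif_idx]

        if cfg.nt_bias != 1.0 and genes:
            nt = np.zeros(pos0.shape, dtype=bool)
            covered = np.zeros(pos0.shape, dtype=bool)
            for gene in genes:
                if gene.chrom != chrom:
                    continue
                inside = (pos0 >= gene.start - 1) & (pos0 <= gene.end - 1)
                site_plus = forward  # G on forward strand
                nt |= inside & (site_plus == (gene.strand == "+"))
                covered |= inside
            rate = np.where(nt & covered, rate * cfg.nt_bias, rate)

        sf = _splice_factor(cfg, genes, chrom, len(seq))
        if sf is not None:
            rate = rate * sf[pos0]

        if cfg.n_clusters > 0:
            centers = rng.integers(0, len(seq), size=cfg.n_clusters)
            burst = np.zeros(pos0.shape, dtype=bool)
            for c in centers:
                burst |= np.abs(pos0 - c) <= cfg.cluster_halfwidth
            rate = np.where(burst, rate * cfg.cluster_multiplier, rate)

        if rate.max(initial=0.0) > 1.0:
            raise ValueError(
                f"per-site mutation rate exceeds 1 (max {rate.max():.3g}); "
                "lower mu or the multipliers"
            )

        ref = np.where(forward, "G", "C")
        for s in samples:
            hit = rng.random(pos0.shape[0]) < rate
            if not hit.any():
                continue
            hp, hr = pos0[hit], ref[hit]
            alt_idx = rng.integers(0, 3, size=hp.shape[0])
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": hp + 1,
                        "ref": hr,
                        "alt": [_ALTS[b][k] for b, k in zip(hr, alt_idx)],
                        "sample": s,
                        "tissue": sample_tissue[s],
                    }
                )
            )

    for chrom, pos, k in cfg.recurrent_sites:
        base = genome[chrom][pos - 1].upper()
        if base not in "ACGT":
            raise ValueError(f"recurrent site {chrom}:{pos} is {base!r}")
        k = min(k, len(samples))
        alts = [_ALTS[base][int(i)] for i in rng.integers(0, 3, size=k)]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": base,
                    "alt": alts,
                    "sample": samples[:k],
                    "tissue": [sample_tissue[s] for s in samples[:k]],
                }
            )
        )

    cols = ["chrom", "pos", "ref", "alt", "sample", "tissue"]
    if not frames:
        records = pd.DataFrame(columns=cols)
    else:
        records = pd.concat(frames, ignore_index=True)[cols]
    records["dataset"] = cfg.dataset_name
    return records.sort_values(["chrom", "pos", "sample"], kind="stable").reset_index(
        drop=True
    )


def simulate_catalog(cfg: SyntheticConfig, seed: int) -> dict:
    """Full pipeline: genome + mask, genes with junctions, mutation catalog.

    The three stages draw from independent streams spawned from ``seed``, so
    the catalog is reproducible end to end from a single integer.
    """
    s_genome, s_genes, s_mut = np.random.SeedSequence(seed).spawn(3)
    genome, mask = make_genome(cfg, np.random.default_rng(s_genome).integers(2**31))
    genome, genes = make_genes(
        genome, cfg, np.random.default_rng(s_genes).integers(2**31)
    )
    records = simulate_mutations(
        genome, genes, mask, cfg, np.random.default_rng(s_mut).integers(2**31)
    )
    return {"genome": genome, "mask": mask, "genes": genes, "records": records}
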