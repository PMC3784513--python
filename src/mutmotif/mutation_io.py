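"""Reading, validation, deduplication and context annotation of SBS catalogs.

A catalog is a table of single-base substitutions (chrom, pos, ref, alt, with
optional sample/tissue labels).  Positions follow the 1-based VCF convention.
Coordinate-level deduplication collapses repeated hits of the same genomic
coordinate within a dataset to one count (homozygous calls and repeated calls
across samples count once), matching how mutated-motif numerators m_i are
tallied; the undeduplicated records are kept for recurrence analysis, which
needs per-sample hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import (
    MOTIFS,
    ContextError,
    MappabilityMask,
    canonical_context,
)

logger = logging.getLogger(__name__)

#: average GC content of the mappable genome / exome used as the null for the
#: G:C mutation-fraction binomial test
GENOME_GC = 0.41
EXOME_GC = 0.55

_REQUIRED = ("chrom", "pos", "ref", "alt")
_SNV_BASES = frozenset("ACGT")


@dataclass
class MutationDataset:
    """A validated catalog of single-base substitutions."""

    records: pd.DataFrame
    scope: str = "genome"  # "genome" or "exome"
    background_gc: float | None = None
    name: str = "dataset"
    skipped: pd.DataFrame | None = None
    n_collapsed: int = 0

    def __post_init__(self) -> None:
        if self.scope not in ("genome", "exome"):
            raise ValueError(f"scope must be 'genome' or 'exome', got {self.scope!r}")
        if self.background_gc is None:
            self.background_gc = GENOME_GC if self.scope == "genome" else EXOME_GC
        if not 0 <= self.background_gc <= 1:
            raise ValueError("background_gc must lie in [0, 1]")
        df = self.records.copy()
        for col in _REQUIRED:
            if col not in df.columns:
                raise ValueError(f"missing mandatory column {col!r}")
        for col in ("sample", "tissue"):
            if col not in df.columns:
                df[col] = pd.NA
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        df["ref"] = df["ref"].astype(str).str.upper()
        df["alt"] = df["alt"].astype(str).str.upper()
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


def _strip_chr(series: pd.Series) -> pd.Series:
    return series.str.replace(r"^chr", "", regex=True)


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw table into valid SNV rows and skipped rows with reasons."""
    ref_ok = df["ref"].isin(_SNV_BASES)
    alt_ok = df["alt"].isin(_SNV_BASES)
    differs = df["ref"] != df["alt"]
    good = ref_ok & alt_ok & differs
    skipped = df.loc[~good].copy()
    reasons = np.where(
        ~ref_ok | ~alt_ok, "not_single_base_substitution", "ref_equals_alt"
    )
    skipped["reason"] = reasons[~good.to_numpy()]
    return df.loc[good], skipped


def read_mutations(
    path: str | Path,
    fmt: str = "auto",
    scope: str = "genome",
    name: str | None = None,
    normalize_chroms: bool = True,
) -> MutationDataset:
    """Read a mutation catalog from TSV or a minimal VCF-like file.

    The TSV dialect has a header with columns chrom, pos, ref, alt and
    optional sample/tissue.  The VCF subset uses only CHROM/POS/REF/ALT;
    multi-allelic rows are split and non-SNV rows skipped (counts logged).
    ``normalize_chroms`` strips a leading "chr" so "chr1" and "1" agree.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "vcf" if path.suffix.lower() in (".vcf",) else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        df.columns = [c.lower() for c in df.columns]
        for col in _REQUIRED:
            if col not in df.columns:
                raise ValueError(f"{path}: missing mandatory column {col!r}")
    elif fmt == "vcf":
        raw = pd.read_csv(
            path, sep="\t", dtype=str, comment="#", header=None, usecols=range(5),
            names=["chrom", "pos", "id", "ref", "alt"],
        )
        raw = raw.drop(columns="id")
        raw = raw.assign(alt=raw["alt"].str.split(",")).explode("alt")
        df = raw
    else:
        raise ValueError(f"unknown format {fmt!r}")

    df = df.dropna(subset=list(_REQUIRED))
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    bad_pos = df["pos"].isna()
    if bad_pos.any():
        logger.warning("%s: %d rows with unparseable positions skipped",
                       path, int(bad_pos.sum()))
    df = df.loc[~bad_pos]
    df["ref"] = df["ref"].str.upper()
    df["alt"] = df["alt"].str.upper()
    if normalize_chroms:
        df["chrom"] = _strip_chr(df["chrom"].astype(str))

    good, skipped = _validate_rows(df)
    if len(skipped):
        logger.warning("%s: skipped %d non-SNV rows", path, len(skipped))
    return MutationDataset(
        good, scope=scope, name=name or path.stem, skipped=skipped
    )


def from_dataframe(
    df: pd.DataFrame, scope: str = "genome", name: str = "dataset", **kw
) -> MutationDataset:
    """Wrap an in-memory records table (e.g. simulator output) as a dataset."""
    good, skipped = _validate_rows(
        df.assign(ref=df["ref"].str.upper(), alt=df["alt"].str.upper())
    )
    return MutationDataset(good, scope=scope, name=name, skipped=skipped, **kw)


def deduplicate(ds: MutationDataset, within_sample: bool = False) -> MutationDataset:
    """Collapse repeated hits of one genomic coordinate to a single count.

    By default collapsing is across samples within the dataset (coordinate
    mutated more than once in a dataset counts once, regardless of alt allele
    or zygosity).  ``within_sample=True`` keys on (sample, chrom, pos)
    instead.
    """
    keys = ["sample", "chrom", "pos"] if within_sample else ["chrom", "pos"]
    before = len(ds.records)
    dedup = ds.records.drop_duplicates(subset=keys, keep="first")
    n_collapsed = before - len(dedup)
    if n_collapsed:
        logger.info("%s: collapsed %d duplicate coordinate hits", ds.name, n_collapsed)
    return MutationDataset(
        dedup.reset_index(drop=True),
        scope=ds.scope,
        background_gc=ds.background_gc,
        name=ds.name,
        skipped=ds.skipped,
        n_collapsed=n_collapsed,
    )


def gc_fraction(ds: MutationDataset) -> dict:
    """Fraction of substitutions at G:C pairs with its exact binomial test.

    The observed count of G/C reference alleles is tested two-sided against
    the dataset's background GC content (0.41 genome-wide, 0.55 exome-wide).
    """
    n = len(ds.records)
    if n == 0:
        raise ValueError("empty dataset")
    k = int(ds.records["ref"].isin(("G", "C")).sum())
    test = stats.binomtest(k, n, ds.background_gc, alternative="two-sided")
    return {
        "fraction": k / n,
        "binomial_p": test.pvalue,
        "n": n,
        "k": k,
        "background_gc": ds.background_gc,
    }


def annotate_contexts(
    ds: MutationDataset,
    genome: Mapping[str, str],
    mask: MappabilityMask | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Tally deduplicated records into canonical-motif counts m_i.

    Each G/C record whose position is mappable and whose canonical tetramer is
    extractable contributes one count to its motif.  All other records are
    returned in an exclusion report with one of the reasons at_site /
    unmappable / no_context / ref_mismatch / unknown_chrom; the invariant
    sum(m_i) + len(excluded) == len(records) always holds.
    """
    m = pd.Series(0, index=list(MOTIFS), dtype=np.int64)
    excluded: list[dict] = []
    for row in ds.records.itertuples(index=False):
        reason = None
        if row.chrom not in genome:
            reason = "unknown_chrom"
        elif mask is not None and not mask.contains(row.chrom, row.pos - 1):
            reason = "unmappable"
        else:
            try:
                motif = canonical_context(genome, row.chrom, row.pos, row.ref)
            except ContextError as err:
                logger.warning("excluded record: %s", err)
                reason = "ref_mismatch"
            else:
                if motif is None:
                    reason = "at_site" if row.ref in "AT" else "no_context"
        if reason is None:
            m[motif] += 1
        else:
            excluded.append(
                {"chrom": row.chrom, "pos": row.pos, "ref": row.ref,
                 "alt": row.alt, "reason": reason}
            )
    report = pd.DataFrame(
        excluded, columns=["chrom", "pos", "ref", "alt", "reason"]
    )
    return m, report
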