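"""Canonical 5'-NGNN-3' motif classes and genome-wide context counting.

A single-base substitution at a G:C pair is described by the double-stranded
tetranucleotide around it, written 5'->3' on the strand that carries the
mutated guanine at the second position (P2).  Mutations at a C on the forward
strand are folded onto the reverse strand by reverse complementation, so every
G:C site maps to exactly one of 64 G-centered tetramer classes.

Position names follow the field convention P1 G P3 P4, with the degenerate
symbols N (any base), D (= A/G/T, i.e. not C at P1), B (= C/G/T), R (purine)
and Y (pyrimidine).  Four tetramers (AGCT, CGCG, GGCC, TGCA) equal their own
reverse complement and therefore contain two distinct mutable guanines per
double-stranded occurrence; occurrence-based counting doubles them.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BASES",
    "MOTIFS",
    "MOTIF_INDEX",
    "SELF_COMPLEMENTARY",
    "SUBSETS",
    "Genome",
    "MappabilityMask",
    "MotifCountTable",
    "ContextError",
    "reverse_complement",
    "canonical_context",
    "enumerate_motifs",
    "count_genome_motifs",
    "count_motifs_tetramerwise",
    "gc_site_contexts",
]

BASES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: the 64 canonical G-centered tetramers, lexicographic over (P1, P3, P4)
MOTIFS: tuple[str, ...] = tuple(
    f"{p1}G{p3}{p4}" for p1 in BASES for p3 in BASES for p4 in BASES
)
MOTIF_INDEX: dict[str, int] = {m: i for i, m in enumerate(MOTIFS)}

SELF_COMPLEMENTARY = frozenset({"AGCT", "CGCG", "GGCC", "TGCA"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_RE = re.compile(r"[^ACGTNacgtn]")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of ``seq`` (A/C/G/T/N, case kept)."""
    bad = _VALID_RE.search(seq)
    if bad is not None:
        raise ValueError(
            f"non-nucleotide character {bad.group()!r} at position {bad.start()}"
        )
    return seq.translate(_COMPLEMENT)[::-1]


def _motif_subsets(motif: str) -> dict[str, bool]:
    p1, _, p3, p4 = motif
    dgnn = p1 != "C"
    return {
        "cgnn": p1 == "C",
        "dgnn": dgnn,
        "dgrn": dgnn and p3 in PURINES,
        "dgyn": dgnn and p3 in PYRIMIDINES,
        "dgan": dgnn and p3 == "A",
        "dgbn": dgnn and p3 != "A",
        "ngra": p3 in PURINES and p4 == "A",
        "self_complementary": motif in SELF_COMPLEMENTARY,
    }


def enumerate_motifs() -> pd.DataFrame:
    """All 64 canonical motifs with their subset membership flags.

    Returns a DataFrame indexed by motif with boolean columns
    cgnn/dgnn/dgrn/dgyn/dgan/dgbn/ngra/self_complementary.
    """
    return pd.DataFrame([_motif_subsets(m) for m in MOTIFS], index=list(MOTIFS))


_FLAGS = enumerate_motifs()

#: named motif subsets used throughout the analyses
SUBSETS: dict[str, tuple[str, ...]] = {
    "ALL": MOTIFS,
    **{
        name.upper(): tuple(_FLAGS.index[_FLAGS[name]])
        for name in ("cgnn", "dgnn", "dgrn", "dgyn", "dgan", "dgbn", "ngra")
    },
}


class ContextError(ValueError):
    """Reference allele disagrees with the genome sequence."""


def resolve_chrom(name: str, keys) -> str | None:
    """Match a chromosome name against ``keys``, tolerating a "chr" prefix."""
    if name in keys:
        return name
    if name.startswith("chr") and name[3:] in keys:
        return name[3:]
    if "chr" + name in keys:
        return "chr" + name
    return None


class Genome(Mapping[str, str]):
    """In-memory reference sequences, uppercased on load.

    Thin mapping from sequence name to string; built from a dict or a FASTA
    file (via pyfaidx).  With ``mask_lowercase=True`` soft-masked (lowercase)
    bases are converted to N so they drop out of numerators and denominators.
    """

    def __init__(self, sequences: Mapping[str, str], mask_lowercase: bool = False):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if mask_lowercase:
                seq = re.sub(r"[acgtn]", "N", seq)
            self._seqs[name] = seq.upper()

    @classmethod
    def from_fasta(cls, path: str | Path, mask_lowercase: bool = False) -> "Genome":
        from pyfaidx import Fasta

        with Fasta(str(path), as_raw=True, sequence_always_upper=False) as fa:
            seqs = {name: str(fa[name][:]) for name in fa.keys()}
        return cls(seqs, mask_lowercase=mask_lowercase)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def __getitem__(self, name: str) -> str:
        resolved = resolve_chrom(name, self._seqs)
        if resolved is None:
            raise KeyError(name)
        return self._seqs[resolved]

    def __contains__(self, name: object) -> bool:
        return isinstance(name, str) and resolve_chrom(name, self._seqs) is not None

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)


@dataclass
class MappabilityMask:
    """Uniquely mappable regions, per sequence, as merged half-open intervals.

    Mirrors the "mappability index of 1" style of genome mask: only positions
    inside the mask are scored, both for observed mutations and for the
    genome-wide motif denominators.
    """

    intervals: dict[str, np.ndarray]  # (n, 2) int arrays, 0-based half-open
    label: str = "mask"

    def __post_init__(self) -> None:
        merged = {}
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if np.any(arr[:, 1] <= arr[:, 0]):
                raise ValueError(f"empty or inverted interval on {chrom}")
            arr = arr[np.argsort(arr[:, 0])]
            out: list[list[int]] = []
            for s, e in arr:
                if out and s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[chrom] = np.asarray(out, dtype=np.int64)
        self.intervals = merged

    @classmethod
    def from_bed(cls, path: str | Path, label: str | None = None) -> "MappabilityMask":
        """Read a BED3 file (0-based half-open, per the BED standard)."""
        ivals: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                ivals.setdefault(chrom, []).append((int(start), int(end)))
        return cls(
            {c: np.asarray(v) for c, v in ivals.items()},
            label=label or Path(path).stem,
        )

    def contains(self, chrom: str, pos0: int) -> bool:
        return bool(self.contains_many(chrom, np.asarray([pos0]))[0])

    def contains_many(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Vectorized membership for 0-based positions on ``chrom``."""
        resolved = resolve_chrom(chrom, self.intervals)
        arr = self.intervals.get(resolved) if resolved else None
        pos0 = np.asarray(pos0, dtype=np.int64)
        if arr is None or arr.size == 0:
            return np.zeros(pos0.shape, dtype=bool)
        idx = np.searchsorted(arr[:, 0], pos0, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(pos0.shape, dtype=bool)
        inside[ok] = pos0[ok] < arr[idx[ok], 1]
        return inside


@dataclass
class MotifCountTable:
    """Genome-wide mappable site counts t_i, one entry per canonical motif."""

    counts: pd.Series
    mask_label: str = "none"

    def __post_init__(self) -> None:
        counts = self.counts.reindex(list(MOTIFS)).fillna(0).astype(np.int64)
        if (counts < 0).any():
            raise ValueError("negative motif count")
        self.counts = counts

    def __getitem__(self, motif: str) -> int:
        return int(self.counts[motif])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self, path: str | Path) -> None:
        out = enumerate_motifs().copy()
        out.insert(0, "count", self.counts)
        out["mask_label"] = self.mask_label
        out.to_csv(path, sep="\t", index_label="motif")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MotifCountTable":
        df = pd.read_csv(path, sep="\t", index_col="motif")
        label = str(df["mask_label"].iloc[0]) if len(df) else "none"
        return cls(df["count"], mask_label=label)


# ---------------------------------------------------------------------------
# sequence encoding helpers (A=0, C=1, G=2, T=3; anything else -1)

_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

# reverse-complement lookup on 4-mer codes (base-4, most significant = 5' end)
_RC4 = np.empty(256, dtype=np.int16)
for _code in range(256):
    _digits = [(_code >> (2 * _k)) & 3 for _k in (3, 2, 1, 0)]
    _rc = [3 - _d for _d in reversed(_digits)]
    _RC4[_code] = (_rc[0] << 6) | (_rc[1] << 4) | (_rc[2] << 2) | _rc[3]

# map a 4-mer code with G at index 1 to its motif index, else -1
_MOTIF_OF_CODE = np.full(256, -1, dtype=np.int16)
for _m, _idx in MOTIF_INDEX.items():
    _code = 0
    for _b in _m:
        _code = (_code << 2) | BASES.index(_b)
    _MOTIF_OF_CODE[_code] = _idx


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_codes(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """4-mer codes for every window start, plus a validity flag (no N)."""
    n = codes.shape[0]
    if n < 4:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    c = codes.astype(np.int64)
    k4 = (c[:-3] << 6) | (c[1:-2] << 4) | (c[2:-1] << 2) | c[3:]
    valid = (c[:-3] >= 0) & (c[1:-2] >= 0) & (c[2:-1] >= 0) & (c[3:] >= 0)
    return k4, valid


def gc_site_contexts(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Every scorable G:C site of one forward-strand sequence.

    Returns ``(pos0, motif_idx, g_on_forward)``: 0-based positions of all G and
    C bases whose canonical tetramer lies fully inside the sequence and is
    N-free, the canonical motif index of each, and whether the mutable guanine
    sits on the forward strand (True for a G base, False for a C base).
    """
    codes = _encode(seq)
    k4, valid = _window_codes(codes)
    n = codes.shape[0]

    pos = np.arange(n)
    is_g = codes == 2
    is_c = codes == 1

    # G at P2 of a forward window starting one base 5'
    g_pos = pos[is_g & (pos >= 1) & (pos <= n - 3)]
    g_pos = g_pos[valid[g_pos - 1]]
    g_motif = _MOTIF_OF_CODE[k4[g_pos - 1]]

    # C is the reverse-strand G; its canonical window starts two bases 5'
    c_pos = pos[is_c & (pos >= 2) & (pos <= n - 2)]
    c_pos = c_pos[valid[c_pos - 2]]
    c_motif = _MOTIF_OF_CODE[_RC4[k4[c_pos - 2]]]

    pos0 = np.concatenate([g_pos, c_pos])
    motif = np.concatenate([g_motif, c_motif]).astype(np.int16)
    forward = np.concatenate(
        [np.ones(g_pos.shape, dtype=bool), np.zeros(c_pos.shape, dtype=bool)]
    )
    order = np.argsort(pos0, kind="stable")
    return pos0[order], motif[order], forward[order]


def canonical_context(
    genome: Mapping[str, str], chrom: str, pos: int, ref: str
) -> str | None:
    """Canonical G-centered tetramer of the G:C site at (chrom, pos).

    ``pos`` is 1-based.  For ref=G the forward 4-mer covering [pos-1, pos+2]
    is returned; for ref=C the reverse complement of the forward 4-mer
    covering [pos-2, pos+1], so the mutated base always sits at P2 as G.
    Returns None for A/T sites and for 4-mers that run off the sequence end or
    contain N.  Raises :class:`ContextError` on a ref/genome mismatch.
    """
    seq = genome[chrom]
    if not 1 <= pos <= len(seq):
        raise ContextError(f"{chrom}:{pos} outside sequence of length {len(seq)}")
    base = seq[pos - 1].upper()
    ref = ref.upper()
    if base != ref:
        raise ContextError(
            f"reference mismatch at {chrom}:{pos}: expected {ref}, genome has {base}"
        )
    if ref in "AT":
        return None
    if ref == "G":
        lo, hi = pos - 2, pos + 2  # 0-based slice bounds
    else:  # ref == "C"
        lo, hi = pos - 3, pos + 1
    if lo < 0 or hi > len(seq):
        return None
    word = seq[lo:hi].upper()
    if "N" in word or len(word) != 4:
        return None
    return word if ref == "G" else reverse_complement(word)


def count_genome_motifs(
    genome: Mapping[str, str], mask: MappabilityMask | None = None
) -> MotifCountTable:
    """Per-site canonical motif counts t_i over all sequences.

    Every G and every C on the forward strand whose canonical tetramer is
    fully inside the sequence and N-free contributes one count to its
    canonical motif class, provided its own position is mappable (mask=None
    counts every position).  This per-site rule reproduces occurrence-based
    tetramer counting with the self-complementary doubling convention.
    """
    totals = np.zeros(len(MOTIFS), dtype=np.int64)
    any_seq = False
    for chrom in genome:
        seq = genome[chrom]
        if len(seq) >= 4:
            any_seq = True
        pos0, motif, _ = gc_site_contexts(seq)
        if mask is not None:
            keep = mask.contains_many(chrom, pos0)
            motif = motif[keep]
        if motif.size:
            totals += np.bincount(motif, minlength=len(MOTIFS))
    if not any_seq:
        warnings.warn("empty genome: all motif counts are zero", stacklevel=2)
    label = mask.label if mask is not None else "none"
    return MotifCountTable(pd.Series(totals, index=list(MOTIFS)), mask_label=label)


def count_motifs_tetramerwise(
    genome: Mapping[str, str], mask: MappabilityMask | None = None
) -> MotifCountTable:
    """Occurrence-based oracle for :func:`count_genome_motifs`.

    Slides a 4-mer window along the forward strand and credits motif X once
    for each occurrence of X and once for each occurrence of its reverse
    complement; self-complementary motifs therefore receive two credits per
    occurrence.  Only defined without a mask (a whole tetramer has no single
    site to test for mappability).
    """
    if mask is not None:
        raise ValueError("tetramer-wise counting is defined only for mask=None")
    occ = np.zeros(256, dtype=np.int64)
    any_seq = False
    for chrom in genome:
        seq = genome[chrom]
        if len(seq) >= 4:
            any_seq = True
        k4, valid = _window_codes(_encode(seq))
        if k4.size:
            occ += np.bincount(k4[valid], minlength=256)
    if not any_seq:
        warnings.warn("empty genome: all motif counts are zero", stacklevel=2)
    totals = np.zeros(len(MOTIFS), dtype=np.int64)
    for motif, idx in MOTIF_INDEX.items():
        code = 0
        for b in motif:
            code = (code << 2) | BASES.index(b)
        totals[idx] = occ[code] + occ[_RC4[code]]
    return MotifCountTable(pd.Series(totals, index=list(MOTIFS)))
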