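"""Mappability-normalized mutated-motif fractions and group contrasts.

For motif i with m_i observed (deduplicated, mappable) mutations and t_i
mappable genomic sites, the mutated-motif fraction is f_i = m_i / t_i, and the
normalized fraction over a stated subset is F_i = f_i / sum(f_i), so that the
F_i sum to one over that subset.  Group contrasts (CGNN vs DGNN, DGRN vs DGYN,
DGAN vs DGBN, ...) are two-tailed Welch t-tests across motif-level f_i, with a
pooled two-proportion z-test fallback for sparse catalogs in which some motif
classes have no observed mutation at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import MOTIFS, SUBSETS, MotifCountTable, enumerate_motifs

__all__ = [
    "FractionTable",
    "motif_fractions",
    "normalize",
    "compare_groups",
    "p4_adenine_ratio",
    "resolve_subset",
]

#: -log10 P is capped here; smaller p-values are flagged as underflow
MINUS_LOG10_P_CAP = 308.0


def resolve_subset(subset: str | Iterable[str]) -> tuple[str, ...]:
    """A named subset ("CGNN", "DGRN", ...) or an explicit motif collection."""
    if isinstance(subset, str):
        try:
            return SUBSETS[subset.upper()]
        except KeyError:
            raise KeyError(
                f"unknown subset {subset!r}; known: {sorted(SUBSETS)}"
            ) from None
    motifs = tuple(subset)
    unknown = [m for m in motifs if m not in MOTIFS]
    if unknown:
        raise KeyError(f"not canonical motifs: {unknown}")
    return motifs


@dataclass
class FractionTable:
    """Per-motif m_i, t_i, f_i (and F_i after :func:`normalize`)."""

    table: pd.DataFrame  # index = motif; columns m, t, f, defined [, F]
    subset_label: str = "ALL"
    name: str = "dataset"

    def __post_init__(self) -> None:
        required = {"m", "t", "f", "defined"}
        if not required <= set(self.table.columns):
            raise ValueError(f"fraction table needs columns {sorted(required)}")

    @property
    def f(self) -> pd.Series:
        return self.table["f"]

    @property
    def m(self) -> pd.Series:
        return self.table["m"]

    @property
    def t(self) -> pd.Series:
        return self.table["t"]

    def subset(self, subset: str | Iterable[str]) -> pd.DataFrame:
        return self.table.loc[list(resolve_subset(subset))]

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.join(enumerate_motifs())
        out.to_csv(path, sep="\t", index_label="motif")


def motif_fractions(
    m: pd.Series, t: MotifCountTable | pd.Series, name: str = "dataset"
) -> FractionTable:
    """Elementwise f_i = m_i / t_i over the 64 canonical motifs.

    A motif with t_i = 0 and m_i > 0 is an impossible observation and raises;
    t_i = 0 with m_i = 0 is flagged undefined (f_i = NaN).
    """
    t_series = t.counts if isinstance(t, MotifCountTable) else t
    m = m.reindex(list(MOTIFS)).fillna(0).astype(np.int64)
    t_series = t_series.reindex(list(MOTIFS)).fillna(0).astype(np.int64)
    impossible = (t_series == 0) & (m > 0)
    if impossible.any():
        bad = list(m.index[impossible])
        raise ValueError(f"mutations observed at motifs with zero sites: {bad}")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = m / t_series.replace(0, np.nan)
    table = pd.DataFrame(
        {"m": m, "t": t_series, "f": f, "defined": t_series > 0}
    )
    return FractionTable(table, name=name)


def normalize(ft: FractionTable, subset: str | Iterable[str] = "DGNN") -> FractionTable:
    """Add F_i = f_i / sum(f_i) over ``subset``; off-subset motifs get no F_i."""
    motifs = resolve_subset(subset)
    sub = ft.table.loc[list(motifs)]
    total = sub["f"].sum(skipna=True)
    if not np.isfinite(total) or total <= 0:
        raise ValueError(f"subset {subset!r} has no positive defined fractions")
    table = ft.table.copy()
    table["F"] = np.nan
    table.loc[list(motifs), "F"] = sub["f"] / total
    label = subset if isinstance(subset, str) else "custom"
    return FractionTable(table, subset_label=label, name=ft.name)


def _minus_log10(p: float) -> tuple[float, bool]:
    if p <= 0 or -np.log10(max(p, 5e-324)) > MINUS_LOG10_P_CAP:
        return MINUS_LOG10_P_CAP, True
    return float(-np.log10(p)), False


def compare_groups(
    ft: FractionTable,
    group_a: str | Iterable[str],
    group_b: str | Iterable[str],
    test: str = "auto",
) -> dict:
    """Two-tailed contrast of mutated-motif fractions between two motif groups.

    ``welch_t`` compares the per-motif f_i of the two groups with an
    unequal-variance t-test; ``two_proportion_z`` pools m and t within each
    group into two binomial proportions, the fallback used for sparse catalogs
    where some motif class has no observed mutation.  ``auto`` picks the
    z-test whenever any defined group member has m_i = 0.  Undefined f_i
    (t_i = 0) are excluded from both tests.
    """
    a_motifs, b_motifs = resolve_subset(group_a), resolve_subset(group_b)
    if set(a_motifs) & set(b_motifs):
        raise ValueError("contrast groups must be disjoint")
    sub_a = ft.table.loc[list(a_motifs)].query("defined")
    sub_b = ft.table.loc[list(b_motifs)].query("defined")
    if len(sub_a) == 0 or len(sub_b) == 0:
        raise ValueError("a contrast group has no defined fractions")

    if test == "auto":
        test = (
            "two_proportion_z"
            if (sub_a["m"] == 0).any() or (sub_b["m"] == 0).any()
            else "welch_t"
        )

    fa, fb = sub_a["f"].to_numpy(), sub_b["f"].to_numpy()
    out = {
        "test": test,
        "n_a": len(fa),
        "n_b": len(fb),
        "mean_a": float(fa.mean()),
        "mean_b": float(fb.mean()),
        "sd_a": float(fa.std(ddof=1)) if len(fa) > 1 else np.nan,
        "sd_b": float(fb.std(ddof=1)) if len(fb) > 1 else np.nan,
    }
    if test == "welch_t":
        if len(fa) < 2 or len(fb) < 2:
            raise ValueError(
                "welch_t needs >=2 defined fractions per group; "
                "use test='two_proportion_z'"
            )
        res = stats.ttest_ind(fa, fb, equal_var=False)
        out["statistic"], pvalue = float(res.statistic), float(res.pvalue)
        out["df"] = float(res.df)
    elif test == "two_proportion_z":
        m_a, t_a = int(sub_a["m"].sum()), int(sub_a["t"].sum())
        m_b, t_b = int(sub_b["m"].sum()), int(sub_b["t"].sum())
        pooled = (m_a + m_b) / (t_a + t_b)
        se = np.sqrt(pooled * (1 - pooled) * (1 / t_a + 1 / t_b))
        if se == 0:
            raise ValueError("degenerate z-test: pooled proportion is 0 or 1")
        z = (m_a / t_a - m_b / t_b) / se
        out["statistic"] = float(z)
        pvalue = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown test {test!r}")
    out["p"] = pvalue
    out["minus_log10_p"], out["underflow"] = _minus_log10(pvalue)
    return out


def p4_adenine_ratio(ft: FractionTable) -> dict:
    """Per-stem ratio of the P4-adenine fraction to the mean non-A fraction.

    For each of the eight purine-P3 stems (P1, G, P3 with P3 in {A, G}), the
    fraction of mutations at P4=A is divided by the average fraction over
    P4 in {C, G, T}.  Stems with any undefined member fraction, or a zero
    denominator, are skipped with a warning.  Returns the per-stem table plus
    the mean +/- SD summary over usable stems.
    """
    rows = []
    for p1 in "ACGT":
        for p3 in "AG":
            members = {p4: f"{p1}G{p3}{p4}" for p4 in "ACGT"}
            fvals = {p4: ft.table.loc[m, "f"] for p4, m in members.items()}
            if any(not np.isfinite(v) for v in fvals.values()):
                warnings.warn(f"stem {p1}G{p3}*: undefined member fraction, skipped")
                continue
            denom = np.mean([fvals["C"], fvals["G"], fvals["T"]])
            if denom == 0:
                warnings.warn(f"stem {p1}G{p3}*: zero non-A fractions, skipped")
                continue
            rows.append({"stem": f"{p1}G{p3}", "ratio": fvals["A"] / denom})
    per_stem = pd.DataFrame(rows, columns=["stem", "ratio"]).set_index("stem")
    ratios = per_stem["ratio"].to_numpy()
    return {
        "per_stem": per_stem,
        "mean": float(ratios.mean()) if len(ratios) else np.nan,
        "sd": float(ratios.std(ddof=1)) if len(ratios) > 1 else np.nan,
        "n_stems": len(ratios),
    }
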