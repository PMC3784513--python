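"""Physicochemical descriptors of G-centered motifs and log-linear fits.

Two descriptors are supported.  The vertical ionization potential (VIP) of a
guanine-centered DGN trimer is the minimum energy needed to abstract an
electron from the stacked bases without nuclear relaxation; low-VIP guanine
runs act as traps for migrating electron holes, so a log-linear dependence of
mutation fractions on VIP is the signature of one-electron-oxidation
mutagenesis.  The mean absolute base-stacking free energy <dG(nu)> of a
tetramer is the average of its three ordered dinucleotide steps
(P1pG + GpP3 + P3pP4) / 3.

The VIP table is shipped as packaged data; the stacking-step table shipped by
default is a synthetic placeholder (see its file header) because published
step values are configuration the user supplies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .fractions import FractionTable
from .motifs import BASES, PURINES

__all__ = [
    "VIP_TRIMER_EV",
    "VIP_FREE_GUANINE_EV",
    "VIP_FREE_GUANINE_EXPERIMENTAL_EV",
    "StackingStepTable",
    "combine_fractions",
    "vip_lookup",
    "mean_stacking_energy",
    "aggregate_to_trimers",
    "fit_log_linear",
]

_STEPS = tuple(a + b for a in BASES for b in BASES)


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("mutmotif.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def _load_vips() -> tuple[dict[str, float], float, float]:
    df = _read_packaged("vip_trimers.tsv").set_index("trimer")["vip_ev"]
    free = float(df.pop("G"))
    free_exp = float(df.pop("G_exp"))
    table = {str(k): float(v) for k, v in df.items()}
    assert len(table) == 12
    return table, free, free_exp


#: VIPs (eV) of the 12 guanine-centered DGN trimers; free-guanine references
VIP_TRIMER_EV, VIP_FREE_GUANINE_EV, VIP_FREE_GUANINE_EXPERIMENTAL_EV = _load_vips()


def vip_lookup(trimer: str) -> float:
    """VIP in eV of a DGN trimer, or of free guanine for trimer="G".

    Only the 12 D-5' trimers (D = A/G/T, central G) have computed values;
    CGN or any other string raises.
    """
    trimer = trimer.upper()
    if trimer == "G":
        return VIP_FREE_GUANINE_EV
    if trimer not in VIP_TRIMER_EV:
        raise KeyError(
            f"no VIP for {trimer!r}: values exist only for the 12 DGN trimers "
            "(5' base A/G/T, central G) and free guanine 'G'"
        )
    return VIP_TRIMER_EV[trimer]


@dataclass
class StackingStepTable:
    """Absolute stacking free energies dG(nu) for the 16 dinucleotide steps."""

    steps: dict[str, float]
    source: str = "unspecified"

    def __post_init__(self) -> None:
        missing = [s for s in _STEPS if s not in self.steps]
        if missing:
            raise ValueError(f"stacking table missing steps: {missing}")
        extra = [s for s in self.steps if s not in _STEPS]
        if extra:
            raise ValueError(f"stacking table has non-step keys: {extra}")
        if not all(np.isfinite(v) for v in self.steps.values()):
            raise ValueError("stacking energies must be finite")

    @classmethod
    def from_tsv(cls, path: str | Path, source: str | None = None) -> "StackingStepTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            dict(zip(df["step"].str.upper(), df["dg"].astype(float))),
            source=source or Path(path).stem,
        )

    @classmethod
    def synthetic_default(cls) -> "StackingStepTable":
        """The packaged synthetic placeholder honoring the qualitative
        purine-purine >> purine-pyrimidine > pyrimidine-purine >
        pyrimidine-pyrimidine ordering."""
        df = _read_packaged("stacking_steps_synthetic.tsv")
        return cls(
            dict(zip(df["step"], df["dg"].astype(float))),
            source="synthetic placeholder",
        )


def mean_stacking_energy(
    motif: str, steps: StackingStepTable, allow_cgnn: bool = False
) -> float:
    """Mean dG(nu) over a motif's three ordered steps (P1P2, P2P3, P3P4).

    By convention this descriptor is used for the DGNN motifs (P1 != C);
    pass ``allow_cgnn=True`` to evaluate all 64.
    """
    motif = motif.upper()
    if len(motif) != 4 or motif[1] != "G":
        raise ValueError(f"{motif!r} is not a canonical G-centered tetramer")
    if motif[0] == "C" and not allow_cgnn:
        raise ValueError(
            f"{motif!r} is a CGNN motif; stacking means are defined on DGNN "
            "(use allow_cgnn=True to override)"
        )
    vals = []
    for step in (motif[0:2], motif[1:3], motif[2:4]):
        if step not in steps.steps:
            raise KeyError(f"stacking table has no value for step {step!r}")
        vals.append(steps.steps[step])
    return float(np.mean(vals))


def aggregate_to_trimers(ft: FractionTable) -> pd.DataFrame:
    """Collapse tetramer counts to G-centered trimers by summing over P4.

    m and t are summed within each (P1, G, P3) stem and f = sum(m)/sum(t);
    returns a 16-row table indexed by NGN trimer (12 of which are DGN and
    carry VIP values).
    """
    df = ft.table.copy()
    df["trimer"] = [m[:3] for m in df.index]
    agg = df.groupby("trimer")[["m", "t"]].sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        agg["f"] = agg["m"] / agg["t"].replace(0, np.nan)
    agg["defined"] = agg["t"] > 0
    return agg


def combine_fractions(
    tables: Mapping[str, FractionTable],
    subset: str = "DGNN",
    normalize_first: bool = True,
) -> pd.Series:
    """Average per-motif fractions across datasets for a combined regression.

    With ``normalize_first`` (default) each dataset's subset fractions are
    scaled to unit sum before averaging, giving every dataset equal weight
    irrespective of its mutation burden; otherwise raw f_i are averaged.
    """
    from .fractions import resolve_subset

    motifs = list(resolve_subset(subset))
    rows = []
    for name, ft in tables.items():
        f = ft.table.loc[motifs, "f"]
        if normalize_first:
            total = f.sum(skipna=True)
            if not total > 0:
                warnings.warn(f"dataset {name!r} has no positive fractions; skipped")
                continue
            f = f / total
        rows.append(f.rename(name))
    if not rows:
        raise ValueError("no usable datasets to combine")
    return pd.concat(rows, axis=1).mean(axis=1, skipna=True)


def fit_log_linear(
    y: pd.Series | np.ndarray,
    x: pd.Series | np.ndarray,
    bootstrap_b: int = 1000,
    seed: int | None = None,
) -> dict:
    """Ordinary least squares of ln(y) on x, with bootstrap significance
    persistence.

    y values <= 0 or non-finite are excluded with a warning (a motif with no
    observed mutations carries no information about the log rate).  The
    returned ``p_alpha`` is the fraction of ``bootstrap_b`` case resamples
    (points drawn with replacement, seeded) whose refit slope has p < 0.05;
    degenerate resamples (constant x) count as non-significant.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("x and y must have the same length")
    usable = np.isfinite(y) & np.isfinite(x) & (y > 0)
    n_excluded = int((~usable).sum())
    if n_excluded:
        warnings.warn(f"excluding {n_excluded} points with y<=0 or missing values")
    x, y = x[usable], y[usable]
    if len(y) < 3:
        raise ValueError("need at least 3 usable points for a log-linear fit")
    if np.ptp(x) == 0:
        raise ValueError("descriptor x is constant; slope undefined")
    ln_y = np.log(y)
    res = stats.linregress(x, ln_y)

    rng = np.random.default_rng(seed)
    n = len(y)
    hits = 0
    for _ in range(bootstrap_b):
        idx = rng.integers(0, n, size=n)
        if np.ptp(x[idx]) == 0:
            continue
        if stats.linregress(x[idx], ln_y[idx]).pvalue < 0.05:
            hits += 1
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "slope_se": float(res.stderr),
        "p_alpha": hits / bootstrap_b if bootstrap_b else np.nan,
        "n_used": n,
        "n_excluded": n_excluded,
    }
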