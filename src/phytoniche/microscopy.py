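"""Cell abundances from counting-chamber records, and the microscopy vs
pigment-chemotaxonomy method comparison.

Abundance follows the standard settle-and-count formula

    N = (A / Ac) * (V1 / V0) * (n / V) * 1000        [cells/L]

with A the chamber area (mm^2), Ac the area actually scanned, V0 the
original sample volume (mL), V1 the settled/concentrated volume (mL), V the
chamber volume (mL) and n the cells counted.  Defaults reflect a 500 mL
Lugol-preserved sample concentrated to 30 mL and counted in a 0.1 mL
(20 x 20 mm) chamber.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CountRecord", "abundance", "abundance_table",
           "aggregate_replicates", "compare_methods"]

CHEMTAX_GROUPS = ("Bacillariophyta", "Chlorophyta", "Cryptophyta",
                  "Cyanophyta", "Pyrrophyta")


@dataclass(frozen=True)
class CountRecord:
    """A single chamber count with its geometry and volumes."""

    sample_id: str
    group: str
    n: int
    A: float = 400.0   # chamber area, mm^2
    Ac: float = 400.0  # counted area, mm^2
    V0: float = 500.0  # original sample volume, mL
    V1: float = 30.0   # concentrated volume, mL
    V: float = 0.1     # chamber volume, mL

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("count n must be >= 0")
        if self.Ac <= 0 or self.V <= 0:
            raise ZeroDivisionError("Ac and V must be > 0")
        if self.Ac > self.A:
            raise ValueError("counted area cannot exceed chamber area")
        if self.V0 <= 0 or self.V1 <= 0:
            raise ValueError("volumes must be > 0")


def abundance(rec: CountRecord) -> float:
    """Cells per litre for one count record."""
    return (rec.A / rec.Ac) * (rec.V1 / rec.V0) * (rec.n / rec.V) * 1000.0


def abundance_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Vectorised abundance for a table of count records.

    Expects columns n, A, Ac, V0, V1, V (and carries through sample_id,
    group and replicate when present).  Adds an ``abundance`` column in
    cells/L.
    """
    req = ["n", "A", "Ac", "V0", "V1", "V"]
    missing = [c for c in req if c not in counts.columns]
    if missing:
        raise KeyError(f"count table lacks column(s): {missing}")
    df = counts.copy()
    if (df["Ac"] <= 0).any() or (df["V"] <= 0).any():
        raise ZeroDivisionError("Ac and V must be > 0")
    if (df["n"] < 0).any():
        raise ValueError("counts must be >= 0")
    if (df["Ac"] > df["A"]).any():
        raise ValueError("counted area cannot exceed chamber area")
    df["abundance"] = (df["A"] / df["Ac"]) * (df["V1"] / df["V0"]) \
        * (df["n"] / df["V"]) * 1000.0
    return df


def aggregate_replicates(counts: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of replicate abundances per (sample, group).

    The sd of a single replicate is undefined and reported as NaN.
    """
    df = abundance_table(counts)
    agg = (df.groupby(["sample_id", "group"], sort=False)["abundance"]
             .agg(abundance="mean", sd=lambda a: a.std(ddof=1),
                  n_replicates="count")
             .reset_index())
    return agg


def compare_methods(abund: pd.DataFrame, comp: pd.DataFrame,
                    groups=CHEMTAX_GROUPS) -> pd.DataFrame:
    """Per-group OLS of log10(pigment-derived concentration) on
    log10(microscopy abundance), pooling all samples.

    Zero values on either side are excluded from the fit (both quantities
    span orders of magnitude, so the comparison is on log-log scale); the
    number excluded is reported.  Groups with fewer than 3 positive pairs
    are skipped (slope/r reported as NaN).
    """
    if "abundance" not in abund.columns:
        raise KeyError("abundance table needs an 'abundance' column")
    wide = abund.pivot_table(index="sample_id", columns="group",
                             values="abundance", aggfunc="mean")
    comp_i = comp.set_index("sample_id") if "sample_id" in comp.columns \
        else comp
    rows = []
    for g in groups:
        if g not in wide.columns or g not in comp_i.columns:
            rows.append((g, np.nan, np.nan, np.nan, 0, 0))
            continue
        joined = pd.concat([wide[g].rename("abund"),
                            comp_i[g].rename("conc")], axis=1).dropna()
        pos = (joined["abund"] > 0) & (joined["conc"] > 0)
        n_zero = int((~pos).sum())
        sub = joined[pos]
        if len(sub) < 3:
            rows.append((g, np.nan, np.nan, np.nan, len(sub), n_zero))
            continue
        res = stats.linregress(np.log10(sub["abund"]), np.log10(sub["conc"]))
        rows.append((g, res.slope, res.intercept, res.rvalue, len(sub),
                     n_zero))
    return pd.DataFrame(rows, columns=["group", "slope", "intercept", "r",
                                       "n", "n_excluded"])
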