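"""Tabulation and contingency statistics for karyotype survey data.

A species table records, per species: taxon group, heterogamety (XY or ZW)
and fusion class (none, XA, YA, ZA, WA), with explicit flags for the
categories excluded from fusion counts (XO/ZO/WO systems, species with
multiple segregating sex-determination mechanisms, and species carrying
fusions of both chromosomes of a pair).  The module tabulates fusion counts
per group and computes two-sided Fisher's exact tests of the association
between heterogamety and fused status.

A packaged vertebrate survey summary ships as per-group counts
(``data/table1_counts.tsv``); :func:`expand_counts` turns it into a
species-level table with synthetic placeholder names for exercising the
pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "FUSION_CLASSES",
    "EXCLUSION_FLAGS",
    "load_table1_counts",
    "expand_counts",
    "load_species_table",
    "write_species_table",
    "tabulate_fusions",
    "fusion_contingency",
    "ContingencyTable2x2",
    "fisher_exact_2x2",
]

FUSION_CLASSES = ("YA", "XA", "WA", "ZA")
#: row flags that exclude a species from the per-class fusion counts
EXCLUSION_FLAGS = ("XO", "ZO", "WO", "multi_sdm", "dual_fusion")

_COUNT_COLS = {"YA": "ya", "XA": "xa", "WA": "wa", "ZA": "za"}


def load_table1_counts() -> pd.DataFrame:
    """Per-group counts of fused and unfused species in the packaged
    vertebrate karyotype survey (fish, amphibians, reptiles, birds,
    mammals), including the excluded categories as separate columns."""
    with resources.files("karyofuse.data").joinpath("table1_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def expand_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Expand per-group counts into a species-level table.

    Species names are synthetic placeholders (``Fish_ya_0001`` etc.); the
    expansion is the exact inverse of :func:`tabulate_fusions`, which makes a
    round-trip test of the tabulation rules possible without shipping the
    underlying database.
    """
    rows = []

    def add(group: str, n: int, het: str, fusion: str, flag: str, tag: str) -> None:
        for i in range(int(n)):
            rows.append({
                "species": f"{group}_{tag}_{i + 1:04d}",
                "genus": f"{group}_{tag}",
                "group": group,
                "heterogamety": het,
                "fusion": fusion,
                "flag": flag,
            })

    for _, r in counts.iterrows():
        g = r["group"]
        add(g, r["ya"], "XY", "YA", "", "ya")
        add(g, r["xa"], "XY", "XA", "", "xa")
        add(g, r["wa"], "ZW", "WA", "", "wa")
        add(g, r["za"], "ZW", "ZA", "", "za")
        n_xy_unfused = r["xy_systems"] - r["ya"] - r["xa"]
        n_zw_unfused = r["zw_systems"] - r["wa"] - r["za"]
        add(g, n_xy_unfused, "XY", "none", "", "xy")
        add(g, n_zw_unfused, "ZW", "none", "", "zw")
        add(g, r.get("xo", 0), "XY", "none", "XO", "xo")
        add(g, r.get("zo", 0), "ZW", "none", "ZO", "zo")
        add(g, r.get("wo", 0), "ZW", "none", "WO", "wo")
        add(g, r.get("multi_sdm", 0), "XY", "none", "multi_sdm", "multi")
        add(g, r.get("dual_fusion_zw", 0), "ZW", "none", "dual_fusion", "dualzw")
        add(g, r.get("dual_fusion_xy", 0), "XY", "none", "dual_fusion", "dualxy")
    return pd.DataFrame(rows)


def load_species_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", keep_default_na=False)
    required = {"species", "heterogamety", "fusion"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"species table missing columns: {sorted(missing)}")
    if table["species"].duplicated().any():
        dups = table.loc[table["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species: {dups[:5]}")
    return table


def write_species_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def tabulate_fusions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group counts of each fusion class and of XY/ZW system totals.

    Rows flagged with any of :data:`EXCLUSION_FLAGS` are excluded from both
    the fusion-class counts and the system totals, following the survey's
    footnote rules.  Unknown heterogamety or fusion categories raise with the
    offending rows listed.
    """
    table = table.copy()
    if "group" not in table.columns:
        table["group"] = "all"
    if "flag" not in table.columns:
        table["flag"] = ""
    bad_het = ~table["heterogamety"].isin(["XY", "ZW"])
    bad_fus = ~table["fusion"].isin(["none", *FUSION_CLASSES])
    if (bad_het | bad_fus).any():
        bad = table.loc[bad_het | bad_fus, "species"].tolist()
        raise ValueError(f"unknown heterogamety/fusion category in rows: {bad[:10]}")
    known_flags = {""} | set(EXCLUSION_FLAGS)
    bad_flag = ~table["flag"].isin(known_flags)
    if bad_flag.any():
        raise ValueError(
            f"unknown flags: {sorted(set(table.loc[bad_flag, 'flag']))}")
    counted = table[table["flag"] == ""]

    out = []
    for group, sub in counted.groupby("group", sort=False):
        rec = {"group": group}
        for cls in FUSION_CLASSES:
            rec[_COUNT_COLS[cls]] = int((sub["fusion"] == cls).sum())
        rec["xy_systems"] = int((sub["heterogamety"] == "XY").sum())
        rec["zw_systems"] = int((sub["heterogamety"] == "ZW").sum())
        out.append(rec)
    result = pd.DataFrame(out, columns=["group", "ya", "xa", "wa", "za",
                                        "xy_systems", "zw_systems"])
    if result.empty:
        result = pd.DataFrame([{"group": "all", "ya": 0, "xa": 0, "wa": 0,
                                "za": 0, "xy_systems": 0, "zw_systems": 0}])
    return result


def fusion_contingency(tabulated: pd.DataFrame,
                       groups: Iterable[str] | None = None) -> "ContingencyTable2x2":
    """Fused/unfused x XY/ZW contingency table from tabulated counts
    (optionally restricted to some groups)."""
    t = tabulated if groups is None else tabulated[tabulated["group"].isin(list(groups))]
    fused_xy = int((t["ya"] + t["xa"]).sum())
    fused_zw = int((t["wa"] + t["za"]).sum())
    unfused_xy = int(t["xy_systems"].sum()) - fused_xy
    unfused_zw = int(t["zw_systems"].sum()) - fused_zw
    return ContingencyTable2x2(fused_xy, unfused_xy, fused_zw, unfused_zw)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows are e.g. XY/ZW, columns fused/unfused."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def _log_hypergeom_pmf(a: int, r1: int, r2: int, c1: int, n: int) -> float:
    # P(A = a) for fixed margins r1 (row 1), r2, c1 (col 1), total n
    return (gammaln(r1 + 1) - gammaln(a + 1) - gammaln(r1 - a + 1)
            + gammaln(r2 + 1) - gammaln(c1 - a + 1) - gammaln(r2 - c1 + a + 1)
            - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1)))


def fisher_exact_2x2(table: ContingencyTable2x2 | Iterable[Iterable[int]],
                     sided: str = "two-sided") -> Tuple[float, float]:
    """Fisher's exact test for a 2x2 table: (p-value, odds ratio).

    The two-sided p-value sums the hypergeometric probabilities of all
    tables (with the same margins) whose probability does not exceed the
    observed one (probability ordering), matching the classic definition;
    one-sided variants sum the appropriate tail.  Factorials are evaluated
    in log space.  A zero margin yields p = 1 with an undefined (nan) odds
    ratio where appropriate.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    odds = math.nan if b * c == 0 else (a * d) / (b * c)
    if b * c == 0 and a * d > 0:
        odds = math.inf
    elif b * c == 0 and a * d == 0:
        odds = math.nan
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0, odds

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = np.array([_log_hypergeom_pmf(x, r1, r2, c1, n) for x in support])
    p_obs = logp[a - lo]
    if sided == "two-sided":
        # relative tolerance guards against ties broken by rounding
        mask = logp <= p_obs + 1e-7
    elif sided == "greater":
        mask = support >= a
    elif sided == "less":
        mask = support <= a
    else:
        raise ValueError("sided must be 'two-sided', 'greater' or 'less'")
    p = float(np.exp(logp[mask]).sum())
    return min(p, 1.0), odds
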