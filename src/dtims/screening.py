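"""Suspect-screening lookup and inter-library CCS reproducibility.

``screen`` matches a measured (m/z, CCS, mode) feature against a curated
library within ppm and percent-CCS tolerances — the core suspect-screening
operation the library exists for.  ``compare_libraries`` quantifies
inter-laboratory reproducibility by pairing two libraries on
(chemical, ion type) and binning the CCS percent differences at the
community's conventional 2% and 5% cuts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chem
from .curation import pct_diff
from .library_io import Library

__all__ = ["Query", "screen", "screen_table", "compare_libraries"]


@dataclass(frozen=True)
class Query:
    """One measured feature to look up: m/z (Th), CCS (A^2), ionization mode,
    and an optional ion-type restriction."""

    mz: float
    ccs: float
    mode: str
    ion_type: str | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.ccs <= 0:
            raise ValueError("query mz and ccs must be positive")


def screen(
    q: Query,
    lib: Library,
    ppm_tol: float = 10.0,
    ccs_tol: float = 2.0,
) -> pd.DataFrame:
    """Return library entries matching the query within both tolerances.

    Gates (inclusive): same mode; same ion type if the query restricts it;
    |mass error| <= ppm_tol; CCS percent difference <= ccs_tol.  Each match
    carries a heuristic score (1 - |ppm|/ppm_tol) * (1 - pct/ccs_tol) in
    [0, 1]; results are sorted by descending score, ties broken by smaller
    CCS difference then lexical chemical_id.  The raw errors are always
    reported alongside the score.
    """
    if ppm_tol <= 0 or ccs_tol <= 0:
        raise ValueError("tolerances must be positive")
    e = lib.entries
    out_cols = list(e.columns) + ["mass_error_ppm_query", "ccs_pct_diff", "score"]
    if e.empty:
        return pd.DataFrame(columns=out_cols)
    mask = e["mode"] == q.mode
    if q.ion_type is not None:
        mask &= e["ion_type"] == chem.normalize_ion_type(q.ion_type)
    cand = e.loc[mask].copy()
    if cand.empty:
        return pd.DataFrame(columns=out_cols)
    lib_mz = cand["mz_measured_mean"].fillna(cand["mz_theoretical"]).to_numpy(float)
    lib_ccs = cand["ccs_mean_A2"].to_numpy(float)
    ppm = 1e6 * (q.mz - lib_mz) / lib_mz
    pct = 200.0 * np.abs(q.ccs - lib_ccs) / (q.ccs + lib_ccs)
    ok = (np.abs(ppm) <= ppm_tol) & (pct <= ccs_tol)
    cand = cand.loc[ok]
    cand["mass_error_ppm_query"] = ppm[ok]
    cand["ccs_pct_diff"] = pct[ok]
    cand["score"] = (1.0 - np.abs(ppm[ok]) / ppm_tol) * (1.0 - pct[ok] / ccs_tol)
    cand = cand.sort_values(
        by=["score", "ccs_pct_diff", "chemical_id"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return cand.reset_index(drop=True)


def screen_table(
    queries: pd.DataFrame,
    lib: Library,
    ppm_tol: float = 10.0,
    ccs_tol: float = 2.0,
) -> pd.DataFrame:
    """Screen a table of queries (columns mz, ccs, mode[, ion_type]);
    returns matches stacked with a query_index column."""
    parts = []
    for i, row in queries.iterrows():
        q = Query(
            mz=float(row["mz"]), ccs=float(row["ccs"]), mode=row["mode"],
            ion_type=row.get("ion_type") if "ion_type" in queries.columns else None,
        )
        hits = screen(q, lib, ppm_tol=ppm_tol, ccs_tol=ccs_tol)
        hits.insert(0, "query_index", i)
        parts.append(hits)
    if not parts:
        return pd.DataFrame()
    return pd.concat(parts, ignore_index=True)


def compare_libraries(
    a: Library, b: Library, include_mode: bool = False
) -> dict:
    """Pair two libraries and bin CCS percent differences at 2% / 5%.

    Pairing key is (chemical_id, ion_type) — mode excluded by default since
    different laboratories may source the same ion type differently; pass
    ``include_mode=True`` to require it.  Multiple entries per key within a
    library are averaged before pairing.  Bin upper bounds are inclusive:
    <=2%, (2%, 5%], >5%.  With zero pairs the fractions are reported as None.
    """
    key = ["chemical_id", "ion_type"] + (["mode"] if include_mode else [])

    def collapse(lib: Library) -> pd.DataFrame:
        return (
            lib.entries.groupby(key, as_index=False)["ccs_mean_A2"].mean()
        )

    pairs = collapse(a).merge(collapse(b), on=key, suffixes=("_a", "_b"))
    pairs = pairs.dropna(subset=["ccs_mean_A2_a", "ccs_mean_A2_b"])
    n = len(pairs)
    if n == 0:
        return {"n_paired": 0, "frac_le2": None, "frac_2to5": None,
                "frac_gt5": None, "pairs": pairs}
    d = np.array([
        pct_diff(x, y)
        for x, y in zip(pairs["ccs_mean_A2_a"], pairs["ccs_mean_A2_b"])
    ])
    pairs = pairs.assign(pct_diff=d)
    return {
        "n_paired": int(n),
        "frac_le2": float(np.mean(d <= 2.0)),
        "frac_2to5": float(np.mean((d > 2.0) & (d <= 5.0))),
        "frac_gt5": float(np.mean(d > 5.0)),
        "pairs": pairs,
    }
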