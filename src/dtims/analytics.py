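"""Detection-frequency, mode-overlap and contingency analytics.

Given a curated library and the chemical inventory it was built from, these
functions reproduce the standard descriptive analyses of a screening
campaign: which chemicals were detected in which ionization modes (with the
seven-region overlap partition behind a three-set Venn diagram), per-class
detection rates, intra-laboratory replicate-spread summaries, and 2x2
contingency analyses (Fisher's exact test) relating detection to chemical
stability or predicted ionization amenability.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .chem import MODES
from .library_io import Library

__all__ = [
    "detection_matrix",
    "ModeOverlap",
    "mode_overlap",
    "class_detection_rates",
    "FisherResult",
    "fisher_exact_2x2",
    "detection_contingency",
    "replicate_spread_summary",
]


def detection_matrix(
    library: Library, inventory: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Chemical x mode boolean detection table derived from library presence.

    Rows cover the inventory when given (undetected chemicals appear as
    all-False rows), otherwise only chemicals present in the library.
    """
    e = library.entries
    detected = e.groupby(["chemical_id", "mode"]).size().unstack(fill_value=0) > 0
    if inventory is not None:
        idx = pd.Index(inventory["chemical_id"].unique(), name="chemical_id")
    else:
        idx = detected.index
    out = pd.DataFrame(False, index=idx, columns=list(MODES))
    for mode in detected.columns:
        if mode in out.columns:
            common = detected.index.intersection(idx)
            out.loc[common, mode] = detected.loc[common, mode]
    return out


@dataclass(frozen=True)
class ModeOverlap:
    """Seven-region partition of detected chemicals across the three modes.

    ``regions`` is keyed by '&'-joined mode combinations (e.g. 'ESI+',
    'ESI+&APCI+', 'ESI+&ESI-&APCI+'); each chemical is counted in exactly
    the region of the full set of modes that detected it.
    """

    regions: dict[str, int]
    totals: dict[str, int]
    uniques: dict[str, int]
    n_detected: int


def mode_overlap(matrix: pd.DataFrame) -> ModeOverlap:
    """Partition detected chemicals into the 7 exclusive mode-combination regions."""
    modes = [m for m in MODES if m in matrix.columns]
    regions = {}
    for r in range(1, len(modes) + 1):
        for combo in combinations(modes, r):
            in_combo = np.ones(len(matrix), dtype=bool)
            for m in combo:
                in_combo &= matrix[m].to_numpy(bool)
            for m in modes:
                if m not in combo:
                    in_combo &= ~matrix[m].to_numpy(bool)
            regions["&".join(combo)] = int(in_combo.sum())
    totals = {m: int(matrix[m].sum()) for m in modes}
    uniques = {m: regions[m] for m in modes}
    return ModeOverlap(
        regions=regions,
        totals=totals,
        uniques=uniques,
        n_detected=int(matrix.any(axis=1).sum()),
    )


def class_detection_rates(
    matrix: pd.DataFrame, inventory: pd.DataFrame
) -> pd.DataFrame:
    """Per-class totals, detected counts and detection fractions.

    Chemicals with an unknown/missing class label are grouped under
    'Unclassified'.  An empty class reports n_total = 0 and a NaN fraction.
    """
    inv = inventory.drop_duplicates("chemical_id").set_index("chemical_id")
    cls = inv["class"].reindex(matrix.index).fillna("Unclassified")
    detected_any = matrix.any(axis=1)
    rows = []
    for label, members in matrix.groupby(cls):
        n_total = len(members)
        n_det = int(detected_any.loc[members.index].sum())
        row = {
            "class": label,
            "n_total": n_total,
            "n_detected": n_det,
            "fraction": n_det / n_total if n_total else np.nan,
        }
        for m in members.columns:
            row[f"n_{m}"] = int(members[m].sum())
        rows.append(row)
    return pd.DataFrame(rows).sort_values("class").reset_index(drop=True)


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    table: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool


def fisher_exact_2x2(table) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    Two-sidedness follows the probability-mass criterion: p is the sum of
    hypergeometric probabilities (margins fixed) of all tables no more
    probable than the observed one.  A zero row or column margin leaves no
    alternative tables; by convention p = 1 and the result is flagged
    degenerate.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    if t.sum() < 1:
        raise ValueError("table total must be >= 1")
    degenerate = bool((t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any())
    if degenerate:
        return FisherResult(p_value=1.0, odds_ratio=float("nan"),
                            table=tuple(map(tuple, t)), degenerate=True)
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return FisherResult(p_value=float(p), odds_ratio=float(odds),
                        table=tuple(map(tuple, t)), degenerate=False)


def detection_contingency(
    matrix: pd.DataFrame,
    inventory: pd.DataFrame,
    flag: str,
    modes: list[str] | None = None,
) -> dict:
    """Cross-tabulate detection against a boolean inventory flag and test it.

    ``flag`` names an inventory column such as 'stable', 'amenable_pos' or
    'amenable_neg'; chemicals without a value for the flag are excluded
    (mirroring campaigns where stability data covers only part of the
    inventory).  ``modes`` restricts what counts as 'detected' (default: any
    mode).  Returns counts, cell fractions and the Fisher result.
    """
    inv = inventory.drop_duplicates("chemical_id").set_index("chemical_id")
    if flag not in inv.columns:
        raise KeyError(f"inventory has no column {flag!r}")
    flags = inv[flag].reindex(matrix.index)
    known = flags.notna()
    sub = matrix.loc[known]
    fl = flags.loc[known].astype(bool)
    cols = [m for m in (modes or list(sub.columns)) if m in sub.columns]
    det = sub[cols].any(axis=1)
    n11 = int((det & fl).sum())
    n10 = int((det & ~fl).sum())
    n01 = int((~det & fl).sum())
    n00 = int((~det & ~fl).sum())
    total = n11 + n10 + n01 + n00
    fisher = fisher_exact_2x2([[n11, n10], [n01, n00]])
    return {
        "flag": flag,
        "n_total": total,
        "table": {"detected_flagged": n11, "detected_unflagged": n10,
                  "undetected_flagged": n01, "undetected_unflagged": n00},
        "fractions": {
            k: (v / total if total else None)
            for k, v in (("detected_flagged", n11), ("detected_unflagged", n10),
                         ("undetected_flagged", n01), ("undetected_unflagged", n00))
        },
        "p_value": fisher.p_value,
        "odds_ratio": fisher.odds_ratio,
        "degenerate": fisher.degenerate,
    }


def replicate_spread_summary(
    library: Library,
    rejection_log: pd.DataFrame | None = None,
    inventory: pd.DataFrame | None = None,
    threshold_pct: float = 1.0,
) -> dict:
    """Intra-laboratory reproducibility summary of replicate percent differences.

    Pure function of the library (and optionally the rejection log): per
    ionization mode and per chemical class, the count of entries, median
    replicate percent difference, and the fraction at or below the
    threshold (conventionally 1%).  Rejected replicate groups are tallied
    per mode when a rejection log is supplied.
    """
    e = library.entries
    out: dict = {"threshold_pct": threshold_pct, "by_mode": {}, "by_class": {}}
    if len(e):
        for mode, sub in e.groupby("mode"):
            d = sub["replicate_pct_diff"].dropna()
            out["by_mode"][mode] = {
                "n": int(len(sub)),
                "median_pct_diff": float(d.median()) if len(d) else None,
                "frac_le_threshold": float((d <= threshold_pct).mean()) if len(d) else None,
            }
        if inventory is not None:
            classes = dict(
                zip(inventory["chemical_id"], inventory.get("class", pd.Series(dtype=str)))
            )
            cls = e["chemical_id"].map(lambda c: classes.get(c, "Unclassified"))
        else:
            cls = e["class"].fillna("Unclassified")
        for label, sub in e.groupby(cls):
            d = sub["replicate_pct_diff"].dropna()
            out["by_class"][str(label)] = {
                "n": int(len(sub)),
                "median_pct_diff": float(d.median()) if len(d) else None,
                "frac_le_threshold": float((d <= threshold_pct).mean()) if len(d) else None,
            }
    if rejection_log is not None and len(rejection_log):
        rej = rejection_log[rejection_log["reason"].isin(["replicate", "insufficient_replicates"])]
        out["rejected_replicate_groups_by_mode"] = (
            rej.groupby("mode").size().astype(int).to_dict() if len(rej) else {}
        )
    return out
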