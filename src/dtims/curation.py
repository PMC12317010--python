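"""QC cascade: raw per-run feature observations -> consensus library entries.

The curation pipeline mirrors the quality-control practice used when
building drift-tube CCS reference libraries:

1.  CCS computation — arrival times are inverted through the single-field
    calibration (features may instead carry pre-computed CCS).
2.  Expected-ion assignment — a feature is kept only if its measured m/z is
    within a ppm gate of the m/z expected for its candidate ion species
    (default: |error| < 10 ppm) AND its observed M+1/M abundance ratio is
    consistent with the 13C isotope pattern predicted from the formula.
3.  Replicate consensus — per (chemical, ion type, mode) group, at least
    two replicates must agree to within a percent-difference gate
    (default <= 1%); the consensus CCS and m/z are arithmetic means over the
    agreeing subset.
4.  Trendline filter — a power law Omega = a * (m/z)^b is fitted per
    polarity across the consensus entries; entries deviating more than a
    percent gate from the trend (default 15%) are removed.  This rejects
    multimer-streaking artifacts: solution multimers that drift as the
    multimer but dissociate to monomer m/z afterwards, showing anomalously
    large CCS per m/z.

Every input observation ends up either contributing to a library entry or
in the rejection log with a closed-enum reason: mass_error, isotope,
replicate, insufficient_replicates, trendline, missing_formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem
from .calibration import NITROGEN, BufferGas, SingleFieldFit, ccs_from_arrival

__all__ = [
    "REJECTION_REASONS",
    "FEATURE_COLUMNS",
    "CurationConfig",
    "pct_diff",
    "compute_ccs",
    "assign_expected_ions",
    "replicate_consensus",
    "CCSTrendline",
    "TrendlineFit",
    "fit_ccs_mz_trendline",
    "trend_pct_deviation",
    "filter_trendline",
    "build_library",
]

REJECTION_REASONS = (
    "mass_error",
    "isotope",
    "replicate",
    "insufficient_replicates",
    "trendline",
    "missing_formula",
)

FEATURE_COLUMNS = [
    "run_id", "chemical_id", "mode", "ion_type", "mz",
    "arrival_time_ms", "ccs_A2", "abund_M", "abund_M1", "replicate",
]


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds of the QC cascade.

    ppm_max
        Mass-error gate in ppm; strict ``<`` by default (``ppm_inclusive``
        switches to ``<=``).
    replicate_pct_max
        Maximum pairwise percent difference between replicate CCS values
        (inclusive).
    trend_pct_max
        Maximum percent deviation from the fitted CCS-m/z trendline
        (inclusive).
    min_replicates
        Minimum number of mutually agreeing replicates for a consensus.
    trendline_scope
        'per_polarity' (default), 'global' or 'per_ion_type'.
    trend_form
        'power' (default) or 'linear'.
    """

    ppm_max: float = 10.0
    replicate_pct_max: float = 1.0
    trend_pct_max: float = 15.0
    min_replicates: int = 2
    isotope_tol: chem.IsotopeTolerance = field(default_factory=chem.IsotopeTolerance)
    ppm_inclusive: bool = False
    check_m2: bool = False
    trendline_scope: str = "per_polarity"
    trend_form: str = "power"

    def __post_init__(self) -> None:
        if min(self.ppm_max, self.replicate_pct_max, self.trend_pct_max) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.min_replicates < 2:
            raise ValueError("min_replicates must be >= 2")
        if self.trendline_scope not in ("per_polarity", "global", "per_ion_type"):
            raise ValueError(f"unknown trendline_scope {self.trendline_scope!r}")
        if self.trend_form not in ("power", "linear"):
            raise ValueError(f"unknown trend_form {self.trend_form!r}")

    def to_dict(self) -> dict:
        return {
            "ppm_max": self.ppm_max,
            "replicate_pct_max": self.replicate_pct_max,
            "trend_pct_max": self.trend_pct_max,
            "min_replicates": self.min_replicates,
            "isotope_rel_tol": self.isotope_tol.rel_tol,
            "isotope_abs_floor": self.isotope_tol.abs_floor,
            "ppm_inclusive": self.ppm_inclusive,
            "trendline_scope": self.trendline_scope,
            "trend_form": self.trend_form,
        }


def pct_diff(a: float, b: float) -> float:
    """Symmetric percent difference: 100 * |a - b| / mean(a, b)."""
    if a <= 0 or b <= 0:
        raise ValueError("pct_diff requires positive inputs")
    return 200.0 * abs(a - b) / (a + b)


def compute_ccs(
    features: pd.DataFrame,
    fit: SingleFieldFit | None,
    gas: BufferGas = NITROGEN,
) -> pd.DataFrame:
    """Fill the ccs_A2 column from arrival times through a single-field fit.

    Rows already carrying a CCS are left untouched.  The ion mass entering
    the reduced mass is measured m/z times |z| for the annotated ion type.
    """
    out = features.copy()
    if "ccs_A2" not in out.columns:
        out["ccs_A2"] = np.nan
    need = out["ccs_A2"].isna()
    if need.any():
        if fit is None:
            raise ValueError("arrival times present but no calibration fit supplied")
        if "arrival_time_ms" not in out.columns:
            raise ValueError("features lack both ccs_A2 and arrival_time_ms")
        sub = out.loc[need]
        z = sub["ion_type"].map(chem.ion_charge).to_numpy(int)
        ccs = [
            ccs_from_arrival(t, mz * abs(zz), zz, fit, gas)
            for t, mz, zz in zip(
                sub["arrival_time_ms"].to_numpy(float),
                sub["mz"].to_numpy(float), z,
            )
        ]
        out.loc[need, "ccs_A2"] = ccs
    return out


def _reject(rows: pd.DataFrame, reason: str) -> pd.DataFrame:
    assert reason in REJECTION_REASONS
    out = rows.copy()
    out["reason"] = reason
    return out


def assign_expected_ions(
    features: pd.DataFrame,
    inventory: pd.DataFrame,
    config: CurationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mass-error and isotope-distribution gates.

    Returns ``(retained, rejected)``.  Retained rows gain columns
    ``mz_theoretical``, ``mass_error_ppm`` and ``isotope_ratio``; rejected
    rows gain ``reason`` (mass_error / isotope / missing_formula).
    """
    config = config or CurationConfig()
    formulas = dict(zip(inventory["chemical_id"], inventory["formula"]))

    parsed: dict[str, chem.ElementalFormula | None] = {}
    for cid, f in formulas.items():
        try:
            parsed[cid] = chem.parse_formula(f)
        except chem.FormulaError:
            parsed[cid] = None

    mz_cache: dict[tuple[str, str], float] = {}
    ratio_cache: dict[str, float] = {}

    retained_idx, rejected_parts = [], []
    mz_theo_col, err_col, ratio_col = [], [], []
    reasons = {}

    for idx, row in features.iterrows():
        cid = row["chemical_id"]
        f = parsed.get(cid)
        if f is None:
            reasons[idx] = "missing_formula"
            continue
        ion = chem.normalize_ion_type(row["ion_type"])
        key = (formulas[cid], ion)
        if key not in mz_cache:
            mz_cache[key] = chem.ion_mz(f, ion)
        mz_theo = mz_cache[key]
        err = chem.ppm_error(float(row["mz"]), mz_theo)
        ok_mass = abs(err) <= config.ppm_max if config.ppm_inclusive else abs(err) < config.ppm_max
        if not ok_mass:
            reasons[idx] = "mass_error"
            continue
        abund_m = float(row["abund_M"])
        if abund_m <= 0:
            reasons[idx] = "isotope"
            continue
        ratio = float(row["abund_M1"]) / abund_m
        fkey = formulas[cid]
        if fkey not in ratio_cache:
            ratio_cache[fkey] = chem.predicted_m1_ratio(f)
        predicted = ratio_cache[fkey]
        band = max(config.isotope_tol.rel_tol * predicted, config.isotope_tol.abs_floor)
        if abs(ratio - predicted) > band:
            reasons[idx] = "isotope"
            continue
        retained_idx.append(idx)
        mz_theo_col.append(mz_theo)
        err_col.append(err)
        ratio_col.append(ratio)

    retained = features.loc[retained_idx].copy()
    retained["mz_theoretical"] = mz_theo_col
    retained["mass_error_ppm"] = err_col
    retained["isotope_ratio"] = ratio_col

    if reasons:
        rej = features.loc[list(reasons)].copy()
        rej["reason"] = [reasons[i] for i in rej.index]
        rejected_parts.append(rej)
    rejected = (
        pd.concat(rejected_parts)
        if rejected_parts
        else _reject(features.iloc[0:0], "mass_error").iloc[0:0]
    )
    return retained, rejected


def _best_agreeing_subset(ccs: np.ndarray, pct_max: float, min_n: int):
    """Largest subset of replicate CCS values whose pairwise percent
    difference stays within ``pct_max``.

    Because pct_diff of positive values is maximized at the subset extremes,
    the optimum is a contiguous window in sorted order.  Returns indices into
    the input array, or None if no window of size >= min_n qualifies.
    Ties between equally large windows go to the tightest one.
    """
    order = np.argsort(ccs)
    s = ccs[order]
    n = len(s)
    best: tuple[int, float, int] | None = None  # (size, -spread, start)
    for i in range(n):
        for j in range(i + min_n - 1, n):
            spread = pct_diff(s[i], s[j])
            if spread <= pct_max:
                cand = (j - i + 1, -spread, i)
                if best is None or cand > best:
                    best = cand
    if best is None:
        return None
    size, _, start = best
    return order[start : start + size]


def replicate_consensus(
    group: pd.DataFrame, config: CurationConfig | None = None
) -> tuple[dict | None, pd.DataFrame]:
    """Consensus over replicates of one (chemical, ion type, mode) group.

    Returns ``(entry_dict_or_None, rejected_rows)``.  The entry carries the
    mean CCS and m/z of the agreeing replicate subset; observations outside
    that subset are rejected with reason 'replicate', and groups smaller than
    ``min_replicates`` with 'insufficient_replicates'.
    """
    config = config or CurationConfig()
    if group.empty:
        return None, group.iloc[0:0]
    if len(group) < config.min_replicates:
        return None, _reject(group, "insufficient_replicates")
    ccs = group["ccs_A2"].to_numpy(float)
    subset = _best_agreeing_subset(ccs, config.replicate_pct_max, config.min_replicates)
    if subset is None:
        return None, _reject(group, "replicate")
    sub = group.iloc[subset]
    leftover = group.drop(index=sub.index)
    sub_ccs = sub["ccs_A2"].to_numpy(float)
    first = group.iloc[0]
    entry = {
        "chemical_id": first["chemical_id"],
        "ion_type": chem.normalize_ion_type(first["ion_type"]),
        "mode": first["mode"],
        "mz_theoretical": float(sub["mz_theoretical"].iloc[0])
        if "mz_theoretical" in sub
        else np.nan,
        "mz_measured_mean": float(sub["mz"].mean()),
        "mass_error_ppm": float(sub["mass_error_ppm"].mean())
        if "mass_error_ppm" in sub
        else np.nan,
        "ccs_mean_A2": float(sub_ccs.mean()),
        "replicate_pct_diff": float(pct_diff(sub_ccs.min(), sub_ccs.max())),
        "n_replicates": int(len(sub)),
        "_obs_index": list(sub.index),
    }
    rejected = _reject(leftover, "replicate") if len(leftover) else leftover.iloc[0:0]
    return entry, rejected


@dataclass(frozen=True)
class TrendlineFit:
    """Fitted CCS-m/z trend, Omega = a * (m/z)^b (or a + b*m/z for linear).

    ``n_used`` counts points surviving the robust re-fit; ``resid_mad`` is
    the median absolute deviation of (log-)residuals from the first pass.
    """

    a: float
    b: float
    form: str
    n_used: int
    resid_mad: float

    def predict(self, mz) -> np.ndarray | float:
        mz = np.asarray(mz, dtype=float)
        out = self.a * mz**self.b if self.form == "power" else self.a + self.b * mz
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "form": self.form,
                "n_used": self.n_used, "resid_mad": self.resid_mad}


class CCSTrendline:
    """Model for the main CCS-versus-m/z trend across library entries.

    Fitted by least squares (log-log space for the power form), then
    re-fitted once excluding points whose residual deviates more than three
    MADs from the median residual, so multimer-streaking outliers do not
    drag the trend.
    """

    def __init__(self, mz, ccs, form: str = "power") -> None:
        self.mz = np.asarray(mz, dtype=float)
        self.ccs = np.asarray(ccs, dtype=float)
        if len(self.mz) < 5:
            raise ValueError("trendline fit needs at least 5 entries")
        if np.ptp(self.mz) <= 0:
            raise ValueError("degenerate design: all entries share one m/z")
        if np.any(self.mz <= 0) or np.any(self.ccs <= 0):
            raise ValueError("mz and ccs must be positive")
        if form not in ("power", "linear"):
            raise ValueError(f"unknown trend form {form!r}")
        self.form = form

    def _ols(self, mz, ccs) -> tuple[float, float, np.ndarray]:
        if self.form == "power":
            x, y = np.log(mz), np.log(ccs)
            bcoef, loga = np.polyfit(x, y, 1)
            a = float(np.exp(loga))
            resid = y - (loga + bcoef * x)
            return a, float(bcoef), resid
        bcoef, a = np.polyfit(mz, ccs, 1)
        resid = ccs - (a + bcoef * mz)
        return float(a), float(bcoef), resid

    def fit(self) -> TrendlineFit:
        a, b, resid = self._ols(self.mz, self.ccs)
        med = np.median(resid)
        mad = float(np.median(np.abs(resid - med)))
        keep = np.abs(resid - med) <= 3.0 * mad + 1e-12
        if keep.sum() >= 5 and np.ptp(self.mz[keep]) > 0 and not keep.all():
            a, b, _ = self._ols(self.mz[keep], self.ccs[keep])
        return TrendlineFit(a=a, b=b, form=self.form, n_used=int(keep.sum()),
                            resid_mad=mad)


def fit_ccs_mz_trendline(entries: pd.DataFrame, form: str = "power") -> TrendlineFit:
    """Fit the main trend on consensus entries (columns mz_measured_mean, ccs_mean_A2)."""
    return CCSTrendline(entries["mz_measured_mean"], entries["ccs_mean_A2"], form=form).fit()


def trend_pct_deviation(entries: pd.DataFrame, trend: TrendlineFit) -> np.ndarray:
    expected = trend.predict(entries["mz_measured_mean"].to_numpy(float))
    observed = entries["ccs_mean_A2"].to_numpy(float)
    return 100.0 * np.abs(observed - expected) / expected


def filter_trendline(
    entries: pd.DataFrame,
    trend: TrendlineFit,
    config: CurationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split entries into (retained, removed) by percent deviation from trend.

    The gate is inclusive: a deviation of exactly ``trend_pct_max`` is kept.
    Removed entries carry reason 'trendline'.
    """
    config = config or CurationConfig()
    dev = trend_pct_deviation(entries, trend)
    retained = entries.loc[dev <= config.trend_pct_max].copy()
    retained["trend_pct_dev"] = dev[dev <= config.trend_pct_max]
    removed = entries.loc[dev > config.trend_pct_max].copy()
    removed["trend_pct_dev"] = dev[dev > config.trend_pct_max]
    removed["reason"] = "trendline"
    return retained, removed


def _polarity_key(ion_type: str) -> str:
    return "positive" if chem.ion_polarity(ion_type) > 0 else "negative"


def build_library(
    features: pd.DataFrame,
    inventory: pd.DataFrame,
    fit: SingleFieldFit | None = None,
    config: CurationConfig | None = None,
    gas: BufferGas = NITROGEN,
):
    """Run the full QC cascade and assemble a curated library.

    Returns ``(Library, rejection_log)``.  The rejection log mirrors input
    feature rows plus a ``reason`` column; conservation holds exactly:
    ``len(features) == sum(entry n_replicates) + len(rejection_log)``.

    Trendlines are fitted per scope group (polarity by default); a scope
    group with fewer than 5 consensus entries is too small to define a trend
    and passes unfiltered (trend deviation reported as NaN).
    """
    from .library_io import Library  # local import to avoid a cycle

    config = config or CurationConfig()
    features = features.reset_index(drop=True)
    features = compute_ccs(features, fit, gas)

    retained, rejected = assign_expected_ions(features, inventory, config)
    rejection_parts = [rejected] if len(rejected) else []

    entries: list[dict] = []
    for _, group in retained.groupby(["chemical_id", "ion_type", "mode"], sort=True):
        entry, rej = replicate_consensus(group, config)
        if entry is not None:
            entries.append(entry)
        if len(rej):
            rejection_parts.append(rej)

    entry_df = pd.DataFrame(entries)
    trends: dict[str, TrendlineFit] = {}
    if len(entry_df):
        if config.trendline_scope == "global":
            scopes = pd.Series("all", index=entry_df.index)
        elif config.trendline_scope == "per_ion_type":
            scopes = entry_df["ion_type"]
        else:
            scopes = entry_df["ion_type"].map(_polarity_key)
        kept_parts = []
        for scope, sub in entry_df.groupby(scopes):
            if len(sub) < 5:
                sub = sub.copy()
                sub["trend_pct_dev"] = np.nan
                kept_parts.append(sub)
                continue
            trend = fit_ccs_mz_trendline(sub, form=config.trend_form)
            trends[str(scope)] = trend
            kept, removed = filter_trendline(sub, trend, config)
            kept_parts.append(kept)
            for _, row in removed.iterrows():
                obs = features.loc[row["_obs_index"]].copy()
                obs["reason"] = "trendline"
                rejection_parts.append(obs)
        entry_df = pd.concat(kept_parts).sort_index() if kept_parts else entry_df

    rejection_log = (
        pd.concat(rejection_parts).sort_index()
        if rejection_parts
        else features.iloc[0:0].assign(reason=pd.Series(dtype=str))
    )

    contributing = entry_df.get("_obs_index", pd.Series(dtype=object))
    meta = {
        "source": "dtims.build_library",
        "gas": {"name": gas.name, "molar_mass_da": gas.molar_mass_da},
        "calibration": fit.to_dict() if fit is not None else None,
        "curation": config.to_dict(),
        "trendlines": {k: v.to_dict() for k, v in trends.items()},
        "counts": {
            "n_input_observations": int(len(features)),
            "n_contributing_observations": int(
                sum(len(ix) for ix in contributing)
            ),
            "n_rejected_observations": int(len(rejection_log)),
        },
    }
    lib = Library.from_entries(entry_df, inventory=inventory, metadata=meta)
    return lib, rejection_log
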