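"""Campaign orchestration: run-order planning and the calibrate-curate-analyze pipeline.

``plan_run_order`` arranges injections so that isomeric chemicals (identical
monoisotopic mass within 5 ppm) are separated by at least a configurable
number of other standards, preventing carryover interferences, and inserts
methanol-wash markers at a fixed cadence.

``run_pipeline`` executes the full workflow from a declarative YAML/JSON
config: simulate (optional) -> calibrate -> curate -> analyze, writing all
artifacts stamped with a config hash and seed; re-running an identical
config reproduces identical artifact bytes.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import analytics, chem
from .calibration import NITROGEN, SingleFieldCalibration, read_calibrant_table
from .curation import CurationConfig, build_library
from .library_io import Library, count_summary, read_inventory, write_library
from .synthetic import SimulationConfig, simulate_campaign

__all__ = ["RunPlan", "PlanningError", "PipelineError", "plan_run_order", "run_pipeline"]

ISOMER_PPM = 5.0


class PlanningError(ValueError):
    """Raised when no injection order can satisfy the isomer-gap constraint."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str) -> None:
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class RunPlan:
    """Ordered injection list with wash markers every ``wash_every`` injections."""

    order: tuple[str, ...]
    wash_after: tuple[int, ...]  # 1-based injection counts after which to wash
    min_gap: int
    wash_every: int

    def to_frame(self) -> pd.DataFrame:
        washes = set(self.wash_after)
        return pd.DataFrame({
            "position": range(1, len(self.order) + 1),
            "chemical_id": self.order,
            "wash_after": [p in washes for p in range(1, len(self.order) + 1)],
        })


def _isomer_groups(inventory: pd.DataFrame) -> dict[str, int]:
    """Assign each chemical a mass-group id; chemicals within 5 ppm share one."""
    masses = []
    for _, row in inventory.iterrows():
        masses.append(
            (chem.monoisotopic_mass(chem.parse_formula(row["formula"])), row["chemical_id"])
        )
    masses.sort()
    group_of: dict[str, int] = {}
    gid = -1
    prev_mass = None
    for mass, cid in masses:
        if prev_mass is None or (mass - prev_mass) / prev_mass * 1e6 > ISOMER_PPM:
            gid += 1
        group_of[cid] = gid
        prev_mass = mass
    return group_of


def plan_run_order(
    inventory: pd.DataFrame, min_gap: int = 3, wash_every: int = 24
) -> RunPlan:
    """Greedy isomer-separating injection order.

    Any two chemicals of (effectively) identical monoisotopic mass end up at
    least ``min_gap`` positions apart.  At each slot the planner picks, among
    chemicals whose mass group was not used in the previous ``min_gap - 1``
    slots, one from the largest remaining group (ties broken by input
    order), which is the optimal strategy for cooldown scheduling; with no
    isomers at all this preserves the input order exactly.  Deterministic
    given the input order.
    """
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1")
    if wash_every < 1:
        raise ValueError("wash_every must be >= 1")
    ids = list(inventory["chemical_id"])
    if len(set(ids)) != len(ids):
        raise PlanningError("inventory chemical_ids must be unique (dedup first)")
    group_of = _isomer_groups(inventory)

    remaining: dict[int, list[str]] = {}
    for pos, cid in enumerate(ids):
        remaining.setdefault(group_of[cid], []).append(cid)
    input_rank = {cid: i for i, cid in enumerate(ids)}

    order: list[str] = []
    last_used: dict[int, int] = {}
    n = len(ids)
    for slot in range(n):
        candidates = [
            g for g, members in remaining.items()
            if members and (g not in last_used or slot - last_used[g] >= min_gap)
        ]
        if not candidates:
            blocked = max(
                (g for g, m in remaining.items() if m),
                key=lambda g: len(remaining[g]),
            )
            sample = remaining[blocked][:3]
            raise PlanningError(
                f"cannot separate isomer group containing {sample} by "
                f"min_gap={min_gap}: too many isomers for the available fillers"
            )
        best = min(
            candidates,
            key=lambda g: (-len(remaining[g]), input_rank[remaining[g][0]]),
        )
        order.append(remaining[best].pop(0))
        last_used[best] = slot
    wash_after = tuple(range(wash_every, n + 1, wash_every))
    return RunPlan(order=tuple(order), wash_after=wash_after,
                   min_gap=min_gap, wash_every=wash_every)


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    path = Path(config)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _config_hash(cfg: dict) -> str:
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(config, out_dir=None) -> dict:
    """Execute simulate (optional) -> calibrate -> curate -> analyze.

    ``config`` is a dict or a path to a YAML/JSON file with keys:

    - ``seed`` (int), ``out_dir`` (path, may be overridden by the argument)
    - either ``simulate`` (SimulationConfig fields) or ``inputs`` with paths
      ``inventory``, ``features``, ``calibrants``, ``calibrant_arrivals``
    - optional ``curation`` (CurationConfig fields)

    Writes calibration.json, library.csv, library.json, rejection_log.csv,
    analytics.json and run_summary.json into ``out_dir``.  Artifacts are
    staged and moved in only on success; a stage failure removes partial
    output and raises :class:`PipelineError` naming the stage.
    """
    cfg = _load_config(config)
    out_dir = Path(out_dir or cfg.get("out_dir", "dtims_out"))
    seed = int(cfg.get("seed", 0))
    staging = out_dir.with_name(out_dir.name + ".staging")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)

    try:
        # ---- stage: inputs -------------------------------------------------
        stage = "simulate" if "simulate" in cfg else "load-inputs"
        try:
            if "simulate" in cfg:
                sim_kwargs = dict(cfg["simulate"])
                sim_kwargs.setdefault("seed", seed)
                data = simulate_campaign(SimulationConfig(**sim_kwargs))
                inventory = data["inventory"]
                features = data["features"]
                calibrants = data["calibrants"]
                cal_arrivals = data["calibrant_arrivals"]
            else:
                paths = cfg["inputs"]
                inventory = read_inventory(paths["inventory"])
                features = pd.read_csv(paths["features"], comment="#")
                calibrants = read_calibrant_table(paths["calibrants"])
                cal_arrivals = pd.read_csv(paths["calibrant_arrivals"], comment="#")
        except (KeyError, FileNotFoundError, ValueError) as exc:
            raise PipelineError(stage, str(exc)) from exc

        # ---- stage: calibrate ----------------------------------------------
        try:
            fit = SingleFieldCalibration(
                cal_arrivals[["calibrant_id", "arrival_time_ms"]], calibrants
            ).fit()
            (staging / "calibration.json").write_text(
                json.dumps(fit.to_dict(), indent=1, sort_keys=True) + "\n"
            )
        except Exception as exc:
            raise PipelineError("calibrate", str(exc)) from exc

        # ---- stage: curate -------------------------------------------------
        try:
            curation_cfg = CurationConfig(**cfg.get("curation", {}))
            library, rejection_log = build_library(
                features, inventory, fit=fit, config=curation_cfg
            )
            write_library(library, staging / "library.csv")
            write_library(library, staging / "library.json")
            rejection_log.to_csv(staging / "rejection_log.csv", index=False,
                                 lineterminator="\n")
        except Exception as exc:
            raise PipelineError("curate", str(exc)) from exc

        # ---- stage: analyze ------------------------------------------------
        try:
            matrix = analytics.detection_matrix(library, inventory)
            overlap = analytics.mode_overlap(matrix)
            rates = analytics.class_detection_rates(matrix, inventory)
            report = {
                "counts": count_summary(library, inventory),
                "mode_overlap": {
                    "regions": overlap.regions,
                    "totals": overlap.totals,
                    "uniques": overlap.uniques,
                    "n_detected": overlap.n_detected,
                },
                "class_detection_rates": json.loads(
                    rates.to_json(orient="records")
                ),
                "replicate_spread": analytics.replicate_spread_summary(
                    library, rejection_log, inventory
                ),
                "rejections_by_reason": rejection_log.groupby("reason").size()
                .astype(int).to_dict() if len(rejection_log) else {},
            }
            for flag in ("stable", "amenable_pos", "amenable_neg"):
                if flag in inventory.columns and inventory[flag].notna().any():
                    modes = (["ESI+"] if flag == "amenable_pos"
                             else ["ESI-"] if flag == "amenable_neg" else None)
                    report[f"contingency_{flag}"] = analytics.detection_contingency(
                        matrix, inventory, flag, modes=modes
                    )
            (staging / "analytics.json").write_text(
                json.dumps(report, indent=1, sort_keys=True) + "\n"
            )
        except Exception as exc:
            raise PipelineError("analyze", str(exc)) from exc

        summary = {
            "config_hash": _config_hash(cfg),
            "seed": seed,
            "stages": ["calibrate", "curate", "analyze"],
            "counts": {
                "inventory": int(len(inventory)),
                "features": int(len(features)),
                "library_entries": int(len(library)),
                "rejected_observations": int(len(rejection_log)),
            },
        }
        (staging / "run_summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n"
        )
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise

    if out_dir.exists():
        shutil.rmtree(out_dir)
    staging.rename(out_dir)
    return {
        "out_dir": out_dir,
        "library": library,
        "rejection_log": rejection_log,
        "fit": fit,
        "summary": summary,
    }
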