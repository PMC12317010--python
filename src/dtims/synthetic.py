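"""Seeded physics-based generator of inventories, calibrant runs and features.

Emulates a library-building campaign end to end so every pipeline stage has
a deterministic, no-download test surface with full ground truth:

* an inventory of xenobiotic-like chemicals (real molecular formulas drawn
  from a bundled template set, 100-800 Da) assigned to the thirteen broad
  use classes of environmental screening campaigns;
* per-chemical true CCS values scattered log-normally around a power-law
  CCS-m/z trend, with per-(class, mode) detectability;
* per-run feature tables: arrival times from the Mason-Schamp drift-time
  relation plus a fixed instrumental offset and Gaussian noise, measured
  m/z with ppm-scale noise, and M / M+1 abundances from the predicted
  isotope pattern;
* the two artifact processes the QC cascade exists to catch: multimer
  streaking (features at monomer m/z with dimer-scale CCS, +25-60% above
  trend) and degraded chemicals that emit no features at all;
* a synthetic tune-mix calibrant table and its arrival times, so the
  single-field calibration is exercised rather than assumed.

Randomness is split into one independent stream per stage from the master
seed, so adding a stage never perturbs earlier streams; identical seeds
give identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem
from .calibration import (
    NITROGEN,
    BufferGas,
    InstrumentGeometry,
    mason_schamp_drift_time,
)

__all__ = [
    "FORMULA_TEMPLATES",
    "DEFAULT_CLASS_MIX",
    "DEFAULT_DETECT_PROB",
    "SimulationConfig",
    "GroundTruth",
    "synthetic_calibrant_table",
    "simulate_inventory",
    "simulate_runs",
    "simulate_campaign",
    "make_fixture_suite",
]

# (name, Hill formula) templates of real xenobiotic-like molecules spanning
# roughly 100-800 Da; repeated formulas across templates are genuine isomer
# pairs (e.g. anthracene/phenanthrene), which keeps the isotope checks and
# the isomer-aware run-order planner meaningful.
FORMULA_TEMPLATES: tuple[tuple[str, str], ...] = (
    ("caffeine", "C8H10N4O2"),
    ("atrazine", "C8H14ClN5"),
    ("simazine", "C7H12ClN5"),
    ("thiabendazole", "C10H7N3S"),
    ("triamterene", "C12H11N7"),
    ("bosentan", "C27H29N5O6S"),
    ("bisphenol-a", "C15H16O2"),
    ("bisphenol-s", "C12H10O4S"),
    ("deet", "C12H17NO"),
    ("carbaryl", "C12H11NO2"),
    ("carbofuran", "C12H15NO3"),
    ("chlorpyrifos", "C9H11Cl3NO3PS"),
    ("diazinon", "C12H21N2O3PS"),
    ("malathion", "C10H19O6PS2"),
    ("parathion", "C10H14NO5PS"),
    ("permethrin", "C21H20Cl2O3"),
    ("imidacloprid", "C9H10ClN5O2"),
    ("fipronil", "C12H4Cl2F6N4OS"),
    ("2,4-d", "C8H6Cl2O3"),
    ("dicamba", "C8H6Cl2O3"),
    ("triclosan", "C12H7Cl3O2"),
    ("pfoa", "C8HF15O2"),
    ("pfos", "C8HF17O3S"),
    ("pfbs", "C4HF9O3S"),
    ("hfpo-da", "C6HF11O3"),
    ("naphthalene", "C10H8"),
    ("anthracene", "C14H10"),
    ("phenanthrene", "C14H10"),
    ("pyrene", "C16H10"),
    ("fluoranthene", "C16H10"),
    ("benzo[a]pyrene", "C20H12"),
    ("tbbpa", "C15H12Br4O2"),
    ("bde-47", "C12H6Br4O"),
    ("tcep", "C6H12Cl3O4P"),
    ("triphenyl-phosphate", "C18H15O4P"),
    ("ibuprofen", "C13H18O2"),
    ("naproxen", "C14H14O3"),
    ("acetaminophen", "C8H9NO2"),
    ("diclofenac", "C14H11Cl2NO2"),
    ("carbamazepine", "C15H12N2O"),
    ("fluoxetine", "C17H18F3NO"),
    ("sertraline", "C17H17Cl2N"),
    ("atorvastatin", "C33H35FN2O5"),
    ("warfarin", "C19H16O4"),
    ("metformin", "C4H11N5"),
    ("sulfamethoxazole", "C10H11N3O3S"),
    ("trimethoprim", "C14H18N4O3"),
    ("ciprofloxacin", "C17H18FN3O3"),
    ("erythromycin", "C37H67NO13"),
    ("tetracycline", "C22H24N2O8"),
    ("estradiol", "C18H24O2"),
    ("testosterone", "C19H28O2"),
    ("cortisol", "C21H30O5"),
    ("cholecalciferol", "C27H44O"),
    ("aspartame", "C14H18N2O5"),
    ("sucralose", "C12H19Cl3O8"),
    ("vanillin", "C8H8O3"),
    ("methylparaben", "C8H8O3"),
    ("propylparaben", "C10H12O3"),
    ("bht", "C15H24O"),
    ("nonylphenol", "C15H24O"),
    ("bha", "C11H16O2"),
    ("octocrylene", "C24H27NO2"),
    ("oxybenzone", "C14H12O3"),
    ("avobenzone", "C20H22O3"),
    ("dehp", "C24H38O4"),
    ("dibutyl-phthalate", "C16H22O4"),
    ("dimethyl-phthalate", "C10H10O4"),
    ("melamine", "C3H6N6"),
    ("sds", "C12H26O4S"),
    ("rhodamine-b", "C28H31ClN2O3"),
    ("indigo", "C16H10N2O2"),
    ("methylene-blue", "C16H18ClN3S"),
    ("aflatoxin-b1", "C17H12O6"),
    ("ochratoxin-a", "C20H18ClNO6"),
    ("strychnine", "C21H22N2O2"),
    ("nicotine", "C10H14N2"),
    ("bromodichloromethane", "CHBrCl2"),
    ("chloral-hydrate", "C2H3Cl3O2"),
    ("trichloroacetic-acid", "C2HCl3O2"),
    ("dichloroacetic-acid", "C2H2Cl2O2"),
    ("decamethylcyclopentasiloxane", "C10H30O5Si5"),
)

# Thirteen broad use classes with inventory fractions typical of a large
# regulatory screening library (industrial chemicals and pesticides dominate).
DEFAULT_CLASS_MIX: dict[str, float] = {
    "Natural Toxin": 6 / 4685,
    "Disinfection By-Product": 14 / 4685,
    "PFAS": 17 / 4685,
    "PAH": 31 / 4685,
    "Surfactant": 78 / 4685,
    "Flame Retardant": 120 / 4685,
    "Plastic": 154 / 4685,
    "Colour Dye": 172 / 4685,
    "Cosmetic Ingredient": 360 / 4685,
    "Pharmaceutical": 615 / 4685,
    "Food Additive": 634 / 4685,
    "Pesticide": 948 / 4685,
    "Chemical Industrial": 1536 / 4685,
}

# Detection probability lookup: specific (class, mode) keys override the
# per-mode base rates.  Base rates reflect that ESI+ detects the most
# chemicals, ESI- second, APCI+ fewest; class overrides encode the strong
# chemistry effects (PAHs ionize by APCI, PFAS by ESI-, dyes and
# pharmaceuticals ionize well everywhere, food additives poorly).
DEFAULT_DETECT_PROB: dict = {
    "ESI+": 0.30,
    "ESI-": 0.25,
    "APCI+": 0.18,
    ("PAH", "ESI+"): 0.05,
    ("PAH", "ESI-"): 0.02,
    ("PAH", "APCI+"): 0.60,
    ("PFAS", "ESI+"): 0.05,
    ("PFAS", "ESI-"): 0.75,
    ("PFAS", "APCI+"): 0.02,
    ("Colour Dye", "ESI+"): 0.55,
    ("Colour Dye", "ESI-"): 0.35,
    ("Pharmaceutical", "ESI+"): 0.50,
    ("Pharmaceutical", "ESI-"): 0.40,
    ("Food Additive", "ESI+"): 0.12,
    ("Food Additive", "ESI-"): 0.10,
    ("Food Additive", "APCI+"): 0.05,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic campaign.

    Defaults emulate a duplicate-injection three-mode campaign: each
    chemical injected twice per ionization mode, arrival times from the
    drift-tube physics with a fixed 0.25 ms transport offset, ~2 ppm mass
    accuracy, 0.05 ms drift-time noise, 5% log-normal CCS scatter around a
    power-law trend, 5% multimer-streaking artifacts and 3% degraded
    chemicals.
    """

    n_chemicals: int = 100
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    trend_a: float = 9.8          # CCS = a * (m/z)^b around which truth scatters
    trend_b: float = 0.5
    ccs_scatter_sigma: float = 0.05   # lognormal sigma, fraction of trend CCS
    drift_noise_sigma_ms: float = 0.05
    mz_noise_sigma_ppm: float = 2.0
    isotope_noise_rel: float = 0.05   # relative noise on the M+1/M ratio
    detect_prob: dict = field(default_factory=lambda: dict(DEFAULT_DETECT_PROB))
    p_sodiated: float = 0.5           # P([M+Na]+ also emitted | ESI+ detection)
    p_apci_protonated: float = 0.9
    p_apci_radical: float = 0.15
    multimer_rate: float = 0.05
    degraded_rate: float = 0.03
    n_replicates: int = 2
    geometry: InstrumentGeometry = field(default_factory=InstrumentGeometry)
    gas: BufferGas = field(default_factory=lambda: NITROGEN)
    beta_scale: float = 1.0           # instrument quirk multiplying true drift times
    t_fix_ms: float = 0.25            # fixed mobility-independent transport offset
    calibrant_noise_sigma_ms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chemicals < 1:
            raise ValueError("n_chemicals must be >= 1")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9 or any(v < 0 for v in self.class_mix.values()):
            raise ValueError("class_mix fractions must be non-negative and sum to 1")
        for name in ("ccs_scatter_sigma", "drift_noise_sigma_ms", "mz_noise_sigma_ppm",
                     "isotope_noise_rel", "calibrant_noise_sigma_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("multimer_rate", "degraded_rate", "p_sodiated",
                     "p_apci_protonated", "p_apci_radical"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class GroundTruth:
    """Per-chemical truth behind the emitted tables.

    ``chemicals`` has one row per chemical (class, artifact labels,
    stability/amenability flags, per-mode detect flags); ``ions`` one row
    per (chemical, ion type) with the true m/z and the clean true CCS
    (before any multimer inflation).
    """

    chemicals: pd.DataFrame
    ions: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "chemicals": json.loads(self.chemicals.to_json(orient="records")),
            "ions": json.loads(self.ions.to_json(orient="records")),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n",
                              encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            chemicals=pd.DataFrame(payload["chemicals"]),
            ions=pd.DataFrame(payload["ions"]),
        )


def synthetic_calibrant_table(cfg: SimulationConfig) -> pd.DataFrame:
    """Ten singly charged tune-mix-like calibrants spanning m/z 118-1522.

    Reference CCS values sit on the configured trend with a small
    deterministic wiggle so the design is not artificially collinear.
    """
    mz = np.array([118.0, 218.0, 322.0, 466.0, 622.0, 822.0, 922.0, 1122.0, 1322.0, 1522.0])
    wiggle = 1.0 + 0.02 * np.sin(np.arange(len(mz)))
    ccs = cfg.trend_a * mz**cfg.trend_b * wiggle
    return pd.DataFrame({
        "calibrant_id": [f"CAL{i + 1:02d}" for i in range(len(mz))],
        "mz": mz,
        "z": 1,
        "ccs_ref": np.round(ccs, 4),
    })


def _detect_p(detect_prob: dict, cls: str, mode: str) -> float:
    if (cls, mode) in detect_prob:
        return float(detect_prob[(cls, mode)])
    return float(detect_prob.get(mode, 0.0))


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("inventory", "ccs", "detection", "flags", "runs")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def simulate_inventory(cfg: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the chemical inventory and the full ground truth behind it."""
    rngs = _streams(cfg.seed)
    rng = rngs["inventory"]

    classes = list(cfg.class_mix)
    probs = np.array([cfg.class_mix[c] for c in classes])
    cls_draw = rng.choice(len(classes), size=cfg.n_chemicals, p=probs)

    t_idx = rng.integers(0, len(FORMULA_TEMPLATES), size=cfg.n_chemicals)
    records = []
    for i in range(cfg.n_chemicals):
        name, formula = FORMULA_TEMPLATES[t_idx[i]]
        records.append({
            "chemical_id": f"DTXSIM{i + 1:07d}",
            "name": f"{name}-{i + 1}",
            "formula": formula,
            "class": classes[cls_draw[i]],
        })
    inv = pd.DataFrame(records)

    # true CCS per (chemical, ion type): trend x lognormal scatter
    rng_ccs = rngs["ccs"]
    ion_rows = []
    for _, row in inv.iterrows():
        f = chem.parse_formula(row["formula"])
        for ion in chem.ION_TYPES:
            mz = chem.ion_mz(f, ion)
            scatter = float(np.exp(rng_ccs.normal(0.0, cfg.ccs_scatter_sigma)))
            ion_rows.append({
                "chemical_id": row["chemical_id"],
                "ion_type": ion,
                "mz_true": mz,
                "ccs_true": cfg.trend_a * mz**cfg.trend_b * scatter,
            })
    ions = pd.DataFrame(ion_rows)

    # detectability, artifact labels and stability/amenability flags
    rng_det = rngs["detection"]
    det = {}
    for mode in chem.MODES:
        p = inv["class"].map(lambda c: _detect_p(cfg.detect_prob, c, mode)).to_numpy(float)
        det[mode] = rng_det.random(cfg.n_chemicals) < p
    sodiated = rng_det.random(cfg.n_chemicals) < cfg.p_sodiated
    apci_h = rng_det.random(cfg.n_chemicals) < cfg.p_apci_protonated
    apci_rad = rng_det.random(cfg.n_chemicals) < cfg.p_apci_radical

    rng_fl = rngs["flags"]
    degraded = rng_fl.random(cfg.n_chemicals) < cfg.degraded_rate
    multimer = (rng_fl.random(cfg.n_chemicals) < cfg.multimer_rate) & ~degraded
    multimer_scale = np.where(
        multimer, 1.25 + 0.35 * rng_fl.random(cfg.n_chemicals), 1.0
    )
    detected_any = det["ESI+"] | det["ESI-"] | det["APCI+"]
    # flags correlate with detection so contingency analytics have signal
    stable = rng_fl.random(cfg.n_chemicals) < np.where(detected_any & ~degraded, 0.75, 0.35)
    amen_pos = rng_fl.random(cfg.n_chemicals) < np.where(det["ESI+"], 0.80, 0.25)
    amen_neg = rng_fl.random(cfg.n_chemicals) < np.where(det["ESI-"], 0.80, 0.25)

    chem_truth = inv.copy()
    for mode in chem.MODES:
        chem_truth[f"det_{mode}"] = det[mode]
    chem_truth["emit_sodiated"] = sodiated
    chem_truth["emit_apci_protonated"] = apci_h
    chem_truth["emit_apci_radical"] = apci_rad
    chem_truth["degraded"] = degraded
    chem_truth["multimer"] = multimer
    chem_truth["multimer_ccs_scale"] = multimer_scale
    chem_truth["stable"] = stable
    chem_truth["amenable_pos"] = amen_pos
    chem_truth["amenable_neg"] = amen_neg

    inv = inv.assign(stable=stable, amenable_pos=amen_pos, amenable_neg=amen_neg)
    return inv, GroundTruth(chemicals=chem_truth, ions=ions)


# ion types emitted per mode (subject to the per-chemical emission draws)
_MODE_IONS = {
    "ESI+": ("[M+H]+", "[M+Na]+"),
    "ESI-": ("[M-H]-",),
    "APCI+": ("[M+H]+", "[M]+"),
}


def simulate_runs(
    cfg: SimulationConfig,
    inventory: pd.DataFrame,
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit calibrant arrivals and per-mode, per-replicate feature tables.

    Returns ``(calibrants, calibrant_arrivals, features)`` in the exact CSV
    schemas the calibration and curation stages consume.
    """
    rng = _streams(cfg.seed)["runs"]

    calibrants = synthetic_calibrant_table(cfg)
    cal_rows = []
    for _, c in calibrants.iterrows():
        t_d = mason_schamp_drift_time(
            c["ccs_ref"], c["mz"] * abs(int(c["z"])), int(c["z"]),
            cfg.geometry, cfg.gas,
        )
        noise = rng.normal(0.0, cfg.calibrant_noise_sigma_ms) if cfg.calibrant_noise_sigma_ms else 0.0
        cal_rows.append({
            "calibrant_id": c["calibrant_id"],
            "arrival_time_ms": cfg.beta_scale * t_d + cfg.t_fix_ms + noise,
        })
    cal_arrivals = pd.DataFrame(cal_rows)

    ions = truth.ions.set_index(["chemical_id", "ion_type"])
    tchem = truth.chemicals.set_index("chemical_id")
    m1_cache: dict[str, float] = {}

    feat_rows = []
    for cid, row in tchem.iterrows():
        if row["degraded"]:
            continue
        formula = chem.parse_formula(row["formula"])
        if row["formula"] not in m1_cache:
            m1_cache[row["formula"]] = chem.predicted_m1_ratio(formula)
        m1_ratio = m1_cache[row["formula"]]
        for mode in chem.MODES:
            if not row[f"det_{mode}"]:
                continue
            emitted = []
            for ion in _MODE_IONS[mode]:
                if mode == "ESI+" and ion == "[M+Na]+" and not row["emit_sodiated"]:
                    continue
                if mode == "APCI+" and ion == "[M+H]+" and not row["emit_apci_protonated"]:
                    continue
                if mode == "APCI+" and ion == "[M]+" and not row["emit_apci_radical"]:
                    continue
                emitted.append(ion)
            if mode == "APCI+" and not emitted:
                emitted = ["[M+H]+"]  # a detected chemical emits at least one ion
            for ion in emitted:
                tr = ions.loc[(cid, ion)]
                ccs_emit = float(tr["ccs_true"]) * float(row["multimer_ccs_scale"])
                z = chem.ion_charge(ion)
                for rep in range(1, cfg.n_replicates + 1):
                    mz_meas = float(tr["mz_true"]) * (
                        1.0 + rng.normal(0.0, cfg.mz_noise_sigma_ppm) * 1e-6
                    )
                    t_d = mason_schamp_drift_time(
                        ccs_emit, float(tr["mz_true"]) * abs(z), z,
                        cfg.geometry, cfg.gas,
                    )
                    t_a = (
                        cfg.beta_scale * t_d + cfg.t_fix_ms
                        + rng.normal(0.0, cfg.drift_noise_sigma_ms)
                    )
                    abund_m = float(np.exp(rng.normal(np.log(1e5), 0.5)))
                    ratio = m1_ratio * (1.0 + rng.normal(0.0, cfg.isotope_noise_rel))
                    feat_rows.append({
                        "run_id": f"{mode}_rep{rep}",
                        "chemical_id": cid,
                        "mode": mode,
                        "ion_type": ion,
                        "mz": mz_meas,
                        "arrival_time_ms": t_a,
                        "abund_M": abund_m,
                        "abund_M1": max(abund_m * ratio, 0.0),
                        "replicate": rep,
                    })
    features = pd.DataFrame(
        feat_rows,
        columns=["run_id", "chemical_id", "mode", "ion_type", "mz",
                 "arrival_time_ms", "abund_M", "abund_M1", "replicate"],
    )
    return calibrants, cal_arrivals, features


def simulate_campaign(cfg: SimulationConfig):
    """Convenience: inventory + truth + calibrants + arrivals + features."""
    inventory, truth = simulate_inventory(cfg)
    calibrants, cal_arrivals, features = simulate_runs(cfg, inventory, truth)
    return {
        "inventory": inventory,
        "truth": truth,
        "calibrants": calibrants,
        "calibrant_arrivals": cal_arrivals,
        "features": features,
    }


_FIXTURES = {
    "tiny": (10, 101),
    "small": (100, 102),
    "medium": (1000, 103),
}


def make_fixture_suite(out_dir, sizes: dict | None = None) -> dict:
    """Write the pinned-seed fixture sets (tiny/10, small/100, medium/1000).

    Each set gets inventory.csv, calibrants.csv, calibrant_arrivals.csv,
    features.csv and truth.json plus a manifest of row counts; regeneration
    under the same seeds is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for label, (n, seed) in (sizes or _FIXTURES).items():
        sub = out_dir / label
        sub.mkdir(exist_ok=True)
        data = simulate_campaign(SimulationConfig(n_chemicals=n, seed=seed))
        for key in ("inventory", "calibrants", "calibrant_arrivals", "features"):
            df = data[key]
            csv = df.to_csv(index=False, lineterminator="\n", float_format="%.10g")
            (sub / f"{key}.csv").write_text(csv, encoding="utf-8", newline="")
        data["truth"].to_json(sub / "truth.json")
        manifest[label] = {
            "n_chemicals": n,
            "seed": seed,
            "rows": {
                key: int(len(data[key]))
                for key in ("inventory", "calibrants", "calibrant_arrivals", "features")
            },
        }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
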