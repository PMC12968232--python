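"""Run configuration for the end-to-end study pipeline."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .synthetic import SimulationConfig, config_from_json

#: Default synonym lists (exact-match after normalization).  A bare
#: "IVACAFTOR" belongs only to the single-agent product list so that
#: combination products never match it by substring.
DEFAULT_SYNONYMS: dict[str, tuple[str, ...]] = {
    "ORKAMBI": (
        "ORKAMBI",
        "LUMACAFTOR/IVACAFTOR",
        "LUMACAFTOR AND IVACAFTOR",
        "VX-809 VX-770",
    ),
    "KALYDECO": ("KALYDECO", "IVACAFTOR"),
    "SYMDEKO": (
        "SYMDEKO",
        "TEZACAFTOR/IVACAFTOR",
        "TEZACAFTOR/IVACAFTOR/IVACAFTOR",
    ),
}


@dataclass
class RunConfig:
    """Everything one `run-all` needs; all randomness flows from ``seed``."""

    input_mode: str = "synthetic"  # "synthetic" | "faers"
    faers_dir: str | None = None
    quarters: tuple[str, ...] = ()
    synthetic: SimulationConfig | None = None
    target_name: str = "ORKAMBI"
    target_synonyms: tuple[str, ...] = DEFAULT_SYNONYMS["ORKAMBI"]
    comparators: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "KALYDECO": DEFAULT_SYNONYMS["KALYDECO"],
            "SYMDEKO": DEFAULT_SYNONYMS["SYMDEKO"],
        }
    )
    pt_soc_path: str | None = None  # required for faers input
    label_terms: tuple[str, ...] = ()
    dme_terms: tuple[str, ...] = ()
    ime_terms: tuple[str, ...] = ()
    label_terms_path: str | None = None
    dme_terms_path: str | None = None
    ime_terms_path: str | None = None
    indication_filter: str | None = None  # e.g. "Cystic fibrosis"; default off
    min_cases: int = 3
    alpha: float = 0.05
    bcpnn_variant: str = "shrinkage"
    outcome_pt: str = "Depression"
    strata: tuple[tuple[str, str, str], ...] = (
        ("sex", "M", "F"),
        ("weight_group", "50-100", "<50"),
        ("frequency", "QD", "BID"),
        ("fatal", "True", "False"),
    )
    seed: int = 0
    record_timestamps: bool = False

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "faers"):
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")
        if self.input_mode == "faers":
            if not self.faers_dir or not self.quarters:
                raise ValueError("faers input needs faers_dir and quarters")
            if not self.pt_soc_path:
                raise ValueError("faers input needs a PT->SOC mapping path")
            if not Path(self.faers_dir).exists():
                raise FileNotFoundError(self.faers_dir)
        if self.input_mode == "synthetic" and self.synthetic is None:
            self.synthetic = default_synthetic_config(seed=self.seed)

    def to_json(self) -> str:
        d = asdict(self)
        if self.synthetic is not None:
            syn = asdict(self.synthetic)
            syn["tto_models"] = {
                "|".join(k): v for k, v in self.synthetic.tto_models.items()
            }
            d["synthetic"] = syn
        return json.dumps(d, indent=1, sort_keys=True, default=str)


def default_synthetic_config(seed: int = 0, n_reports: int = 4000) -> SimulationConfig:
    """The bundled study-shaped scenario: one strongly over-reported
    respiratory event and a psychiatric event planted for the target drug
    only, plus one event elevated for all three CF drugs (the
    disease-progression pattern)."""
    drug_catalog = (
        ("ORKAMBI", 0.25),
        ("KALYDECO", 0.10),
        ("SYMDEKO", 0.10),
    ) + tuple((f"OTHER DRUG {i:02d}", 0.06875) for i in range(1, 9))
    planted = (
        ("ORKAMBI", "Infective pulmonary exacerbation of cystic fibrosis", 12.0),
        ("ORKAMBI", "Dyspnoea", 4.0),
        ("ORKAMBI", "Depression", 2.5),
        ("ORKAMBI", "Cough", 3.0),
        ("KALYDECO", "Cough", 3.0),
        ("SYMDEKO", "Cough", 3.0),
    )
    return SimulationConfig(
        n_reports=n_reports,
        seed=seed,
        drug_catalog=drug_catalog,
        planted_signals=planted,
    )


DEFAULT_LABEL_TERMS = (
    "Infective pulmonary exacerbation of cystic fibrosis",
    "Dyspnoea",
)
DEFAULT_IME_TERMS = ("Depression", "Suicidal ideation", "Rhabdomyolysis")


def default_run_config(seed: int = 0, n_reports: int = 4000) -> RunConfig:
    return RunConfig(
        input_mode="synthetic",
        synthetic=default_synthetic_config(seed=seed, n_reports=n_reports),
        label_terms=DEFAULT_LABEL_TERMS,
        ime_terms=DEFAULT_IME_TERMS,
        seed=seed,
    )


def run_config_from_json(path: str | Path) -> RunConfig:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if isinstance(data.get("synthetic"), dict):
        syn = data["synthetic"]
        tmp = Path(path).with_suffix(".tmp-syn.json")
        # reuse the SimulationConfig JSON loader's tuple coercion
        tmp.write_text(json.dumps(syn), encoding="utf-8")
        try:
            data["synthetic"] = config_from_json(tmp)
        finally:
            tmp.unlink(missing_ok=True)
    elif isinstance(data.get("synthetic"), str):
        data["synthetic"] = config_from_json(data["synthetic"])
    for key in ("quarters", "target_synonyms", "label_terms", "dme_terms", "ime_terms"):
        if key in data:
            data[key] = tuple(data[key])
    if "comparators" in data:
        data["comparators"] = {k: tuple(v) for k, v in data["comparators"].items()}
    if "strata" in data:
        data["strata"] = tuple(tuple(s) for s in data["strata"])
    return RunConfig(**data)
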