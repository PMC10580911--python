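"""Named study-condition fixtures, shipped as YAML package data.

Each fixture pairs an assay design that mirrors a printed experimental
protocol with a ground truth for the quantity the corresponding fitter
should recover.  Fixtures make every stage of the pipeline verifiable by
parameter recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from .errors import DataError

__all__ = ["Fixture", "load_fixture", "list_fixtures"]


@dataclass(frozen=True)
class Fixture:
    name: str
    kind: str                    # "progress" | "itc" | "dsf"
    design: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    inhibitor_grid: tuple = ()   # molar, progress fixtures only
    ramp: dict = field(default_factory=dict)        # dsf only
    baselines: dict = field(default_factory=dict)   # dsf only
    quench_tau: float = 6.0      # deg C, dsf only

    def make_progress_design(self, total_inhibitor: float):
        from .progress import AssayDesign
        d = self.design
        return AssayDesign(
            total_enzyme=d["enzyme"], total_inhibitor=total_inhibitor,
            substrate_conc=d["substrate"], temperature=d["temperature"],
            duration=d["duration"], sampling_interval=d["sampling_interval"],
            product_extinction=d["extinction"], path_length=d["path_length"],
            baseline_absorbance=d["baseline"], kcat=d["kcat"], km=d["km"])

    def make_titration_design(self):
        from .itc import TitrationDesign
        d = self.design
        return TitrationDesign.uniform(
            cell_volume=d["cell_volume"], cell_conc=d["cell_conc"],
            syringe_conc=d["syringe_conc"], n_injections=d["n_injections"],
            injection_volume=d["injection_volume"],
            temperature=d["temperature"])


_UNIT = {  # YAML field suffix -> multiplier into SI
    "_nM": 1e-9, "_uM": 1e-6, "_mM": 1e-3, "_M": 1.0,
    "_uL": 1e-6, "_L": 1.0, "_s": 1.0, "_per_s": 1.0,
    "_per_M_s": 1.0, "_M_cm": 1.0, "_cm": 1.0, "_C": 1.0,
    "_kJ_mol": 1e3, "_J_mol": 1.0, "_C_per_s": 1.0, "_uJ": 1e-6,
}


_SUFFIXES = sorted(_UNIT, key=len, reverse=True)  # longest match wins


def _to_si(mapping: dict) -> dict:
    """Strip unit suffixes from keys and convert values to SI."""
    out = {}
    for key, val in mapping.items():
        for suffix in _SUFFIXES:
            mult = _UNIT[suffix]
            if key.endswith(suffix):
                base = key[: -len(suffix)]
                out[base] = (val * mult if isinstance(val, (int, float))
                             else [v * mult for v in val])
                break
        else:
            out[key] = val
    return out


def _fixture_from_dict(doc: dict) -> Fixture:
    kind = doc["kind"]
    design = _to_si(doc.get("design", {}))
    truth = _to_si(doc.get("truth", {}))
    grid = tuple(v * 1e-9 for v in doc.get("inhibitor_grid_nM", []))
    ramp = _to_si(doc.get("ramp", {}))
    baselines = doc.get("baselines", {})
    return Fixture(name=doc["name"], kind=kind, design=design, truth=truth,
                   inhibitor_grid=grid, ramp=ramp, baselines=baselines,
                   quench_tau=doc.get("quench_tau_C", 6.0))


def list_fixtures() -> list[str]:
    pkg = resources.files("tightbind") / "fixtures"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_fixture(name: str) -> Fixture:
    pkg = resources.files("tightbind") / "fixtures" / f"{name}.yaml"
    try:
        text = pkg.read_text()
    except FileNotFoundError:
        raise DataError(f"unknown fixture {name!r}; available: "
                        f"{', '.join(list_fixtures())}") from None
    return _fixture_from_dict(yaml.safe_load(text))
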