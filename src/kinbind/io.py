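"""Plain-text round-trip I/O: transient CSVs, YAML configs, manifests.

Floats are written at full precision (17 significant digits) so that a
write/read round trip reproduces every generated value bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .fret import FretCalibration
from .kinetics import RateConstants
from .synthetic import TitrationDesign, TitrationSeries

__all__ = [
    "save_titration",
    "load_titration",
    "load_rates",
    "load_calibration",
    "load_design",
]

_FMT = "%.17g"


def save_titration(series: TitrationSeries, outdir) -> Path:
    """One CSV per transient plus a manifest.json carrying design and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, (conc, y, flag) in enumerate(
        zip(series.concentrations, series.transients, series.flags)
    ):
        name = f"transient_{i:02d}.csv"
        names.append(name)
        with open(outdir / name, "w") as fh:
            fh.write(f"# titrant_M={_FMT % conc}\n")
            fh.write(f"# scheme={series.design.scheme}\n")
            if flag:
                fh.write(f"# flag={flag}\n")
            fh.write("time_s,intensity\n")
            for t, v in zip(series.time, y):
                fh.write(f"{_FMT % t},{_FMT % v}\n")
    manifest = {
        "design": {
            "seed": series.design.seed,
            "fixed_species": series.design.fixed_species,
            "fixed_conc": series.design.fixed_conc,
            "titrant_multiples": list(series.design.titrant_multiples),
            "scheme": series.design.scheme,
            "duration": series.design.duration,
            "sample_rate": series.design.sample_rate,
            "dead_time": series.design.dead_time,
            "noise_sigma": series.design.noise_sigma,
            "pre_equilibrated": series.design.pre_equilibrated,
        },
        "transients": names,
        "flags": series.flags,
    }
    if series.truth:
        manifest["truth"] = {
            "rates": series.truth["rates"].to_dict(),
            "calib": series.truth["calib"].to_dict(),
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def load_titration(indir) -> TitrationSeries:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    d = manifest["design"]
    design = TitrationDesign(
        seed=d["seed"], fixed_species=d["fixed_species"],
        fixed_conc=d["fixed_conc"],
        titrant_multiples=tuple(d["titrant_multiples"]), scheme=d["scheme"],
        duration=d["duration"], sample_rate=d["sample_rate"],
        dead_time=d["dead_time"], noise_sigma=d["noise_sigma"],
        pre_equilibrated=d["pre_equilibrated"],
    )
    concs, transients, time = [], [], None
    for name in manifest["transients"]:
        conc = None
        times, vals = [], []
        with open(indir / name) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    if line.startswith("# titrant_M="):
                        conc = float(line.split("=", 1)[1])
                    continue
                if line.startswith("time_s"):
                    continue
                t, v = line.split(",")
                times.append(float(t))
                vals.append(float(v))
        concs.append(conc)
        transients.append(np.array(vals))
        time = np.array(times)
    truth = {}
    if "truth" in manifest:
        truth = {
            "rates": RateConstants.from_dict(manifest["truth"]["rates"]),
            "calib": FretCalibration.from_dict(manifest["truth"]["calib"]),
        }
    return TitrationSeries(
        design=design, time=time, concentrations=np.array(concs),
        transients=transients, flags=manifest["flags"], truth=truth,
    )


def load_rates(path) -> RateConstants:
    """YAML/JSON rate constants keyed k1, k_minus1, kb, k_minusb, kr, k_minusr."""
    return RateConstants.from_dict(yaml.safe_load(Path(path).read_text()))


def load_calibration(path) -> FretCalibration:
    return FretCalibration.from_dict(yaml.safe_load(Path(path).read_text()))


def load_mixing(path):
    """YAML/JSON mixing condition keyed P_total_M, I_total_M
    (optionally pre_equilibrated)."""
    from .kinetics import MixingCondition

    d = yaml.safe_load(Path(path).read_text())
    return MixingCondition(
        P_total=float(d["P_total_M"]), I_total=float(d["I_total_M"]),
        pre_equilibrated=bool(d.get("pre_equilibrated", True)),
    )


def load_design(path) -> TitrationDesign:
    d = yaml.safe_load(Path(path).read_text())
    if "titrant_multiples" in d:
        d["titrant_multiples"] = tuple(d["titrant_multiples"])
    return TitrationDesign(**d)
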