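"""File formats and run manifests.

Spike trains travel as two-column whitespace-delimited text (time_s,
neuron_id); efficacy and rate traces as CSV; stationary-PDF exports as a
two-column CSV plus a JSON sidecar with the scalar summaries.  Every CLI run
emits a manifest echoing the command, the full configuration, the seeds and
the output files, so a run can be reproduced bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calcium import StationaryCalciumPDF

__all__ = [
    "read_spike_train",
    "write_spike_train",
    "write_trace",
    "read_trace",
    "export_pdf",
    "RunManifest",
    "load_config",
]


def write_spike_train(path, times, neuron_ids=None) -> None:
    """Write spikes as two columns: time (s) and neuron id."""
    times = np.asarray(times, dtype=float)
    if neuron_ids is None:
        neuron_ids = np.zeros(times.size, dtype=int)
    np.savetxt(path, np.column_stack([times, np.asarray(neuron_ids)]),
               fmt="%.9f %d")


def read_spike_train(path):
    """Read a two-column spike file; returns (times, neuron_ids)."""
    text = Path(path).read_text().strip()
    if not text:
        return np.empty(0), np.empty(0, dtype=int)
    data = np.loadtxt(path, ndmin=2)
    return data[:, 0], data[:, 1].astype(int)


def write_trace(path, times, **columns) -> None:
    pd.DataFrame({"time_s": times, **columns}).to_csv(path, index=False)


def read_trace(path) -> pd.DataFrame:
    return pd.read_csv(path)


def export_pdf(pdf: StationaryCalciumPDF, csv_path, json_path=None) -> None:
    """Two-column (c, density) CSV plus a JSON sidecar with the alpha
    fractions, normalisation and near-zero mass."""
    pd.DataFrame({"c": pdf.grid, "density": pdf.density}).to_csv(
        csv_path, index=False)
    if json_path is None:
        json_path = Path(csv_path).with_suffix(".json")
    with open(json_path, "w") as fh:
        json.dump({"alpha_d": pdf.alpha_d, "alpha_p": pdf.alpha_p,
                   "Z": pdf.Z, "point_mass_at_zero": pdf.point_mass_at_zero},
                  fh, indent=2)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


@dataclass
class RunManifest:
    """Record of one CLI run: enough to reproduce all stochastic outputs."""

    command: str
    config: dict
    seed: int
    version: str = __version__
    substitutions: list = field(default_factory=list)  # desk-scale notes
    outputs: list = field(default_factory=list)

    def note(self, text: str) -> None:
        self.substitutions.append(text)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(_jsonable(dataclasses.asdict(self)), fh, indent=2,
                      sort_keys=True)
        self_path = str(path)
        if self_path not in self.outputs:
            self.outputs.append(self_path)


def load_config(path) -> dict:
    """YAML or JSON configuration file (decided by extension)."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix in {".yaml", ".yml"}:
            return yaml.safe_load(fh)
        return json.load(fh)
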