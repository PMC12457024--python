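"""Run manifests and tabular report generation.

Every simulation writes a manifest (inputs, grid, tolerances, seeds,
package version, timestamp) next to its outputs so results remain
traceable; the report builder assembles side-by-side species/condition
comparison tables from summary JSON files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field
from datetime import datetime, timezone

import pandas as pd

from . import __version__

__all__ = ["RunManifest", "write_summary", "build_comparison"]


@dataclass
class RunManifest:
    command: str
    parameter_hash: str
    grid_spec: dict
    tolerances: dict
    seed: int | None = None
    package_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    @staticmethod
    def hash_parameters(data: dict) -> str:
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))

    def write(self, path) -> None:
        pathlib.Path(path).write_text(self.to_json())


def write_summary(summary_dict: dict, manifest: RunManifest, path) -> None:
    """Write a summary JSON referencing the manifest that produced it."""
    # no timestamp here: summary files must be byte-reproducible
    payload = dict(summary_dict)
    payload["_manifest"] = {"parameter_hash": manifest.parameter_hash,
                            "package_version": manifest.package_version}
    pathlib.Path(path).write_text(json.dumps(payload, indent=2))


# rows shown in the comparison table, in print order
_ROWS = [
    ("IOP_mmHg", "IOP (mmHg)"),
    ("Qu_over_Qprod", "unconventional outflow fraction Qu/Qprod"),
    ("c2S_over_c2B", "<c2>_S / c2_B"),
    ("u_S", "scleral outflow velocity u_S (m/s)"),
    ("u_CC", "choriocapillaris exchange u_CC (m/s)"),
    ("SA_leak_rate", "SA leakage rate (mol/s)"),
    ("atRA_synthesis_rate", "atRA synthesis rate (mol/s)"),
    ("atRA_blood_leak_rate", "atRA leakage rate from blood (mol/s)"),
    ("atRA_scleral_consumption_rate", "atRA scleral consumption (mol/s)"),
    ("mean_c3_S_nM", "<c3>_S (nM)"),
    ("c3_orbit_nM", "c3 at orbit (nM)"),
]


def build_comparison(summaries: list[dict]) -> pd.DataFrame:
    """Side-by-side table from summary dictionaries.

    Columns are labelled species/condition; when both mouse conditions
    are present a feeding/control ratio column is appended.
    """
    if not summaries:
        raise ValueError("no summaries to report")
    cols = {}
    for s in summaries:
        for key, _ in _ROWS:
            if key not in s:
                raise KeyError(f"summary is missing field {key!r}")
        label = f"{s.get('species', '?')}/{s.get('condition', '?')}"
        cols[label] = [s[key] for key, _ in _ROWS]
    df = pd.DataFrame(cols, index=[label for _, label in _ROWS])
    if "mouse/feeding" in cols and "mouse/control" in cols:
        df["feeding/control ratio"] = (
            df["mouse/feeding"] / df["mouse/control"])
    df.index.name = "quantity"
    return df
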