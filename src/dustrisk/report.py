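"""Human-readable summary rendering and the run manifest.

Machine tables keep full precision; rendered tables show 4 significant
figures with classification labels and the regulatory threshold
annotations (HI = 1; CRI = 10⁻⁶ negligible, 10⁻⁵ strict, 10⁻⁴ harmful).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .indices import PollutionResult
from .risk import CRI_HARMFUL, CRI_NEGLIGIBLE, CRI_STRICT_FLAG, RiskResult


def _sig4(x) -> str:
    try:
        return f"{float(x):.4g}"
    except (TypeError, ValueError):
        return str(x)


def format_table(df: pd.DataFrame) -> str:
    """Render a frame with floats at 4 significant figures."""
    if df.empty:
        return "\t".join(map(str, df.columns)) + "\n(empty)"
    show = df.copy()
    for col in show.columns:
        if pd.api.types.is_float_dtype(show[col]):
            show[col] = show[col].map(_sig4)
    return show.to_string(index=False)


def render_summary(pollution: PollutionResult | None = None,
                   risk: RiskResult | None = None) -> str:
    """Compose the human-readable report body."""
    parts: list[str] = []
    if pollution is not None and not pollution.by_fraction.empty:
        parts.append("Per-fraction cross-site mean EF and Igeo")
        parts.append(format_table(pollution.by_fraction))
    if risk is not None:
        if not risk.hazard.empty:
            hi = (risk.hazard.groupby(["receptor", "analyte"])["hi"]
                  .mean().reset_index().rename(columns={"hi": "mean_hi"}))
            parts.append("Mean hazard index by analyte and receptor (threshold HI = 1)")
            parts.append(format_table(hi))
        if not risk.carcinogenic.empty:
            cri = (risk.carcinogenic.groupby(["analyte", "route"])
                   [["ladd", "cri"]].mean().reset_index())
            cri["class"] = cri["cri"].map(
                lambda v: "negligible" if v < CRI_NEGLIGIBLE
                else ("tolerable" if v <= CRI_HARMFUL else "harmful"))
            cri["above_1e-5"] = cri["cri"] > CRI_STRICT_FLAG
            parts.append("Mean carcinogenic risk by analyte and route "
                         f"(negligible < {CRI_NEGLIGIBLE:g}; strict flag {CRI_STRICT_FLAG:g}; "
                         f"harmful > {CRI_HARMFUL:g})")
            parts.append(format_table(cri))
    return "\n\n".join(parts) if parts else "(no results)"


def file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Provenance record of one pipeline run."""

    config_digest: str
    input_digests: Mapping[str, str]
    artifacts: Mapping[str, str]  # name -> sha256 of emitted file
    seed: int | None = None
    software_version: str = ""
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def to_json(self) -> str:
        return json.dumps({
            "config_digest": self.config_digest,
            "input_digests": dict(self.input_digests),
            "artifacts": dict(self.artifacts),
            "seed": self.seed,
            "software_version": self.software_version,
            "timestamp": self.timestamp,
        }, indent=2, sort_keys=True)


def build_manifest(config_path: Path | None, inputs: Mapping[str, Path],
                   artifacts: Mapping[str, Path], seed: int | None = None,
                   version: str = "") -> RunManifest:
    return RunManifest(
        config_digest=file_digest(config_path) if config_path else "",
        input_digests={k: file_digest(p) for k, p in inputs.items()},
        artifacts={k: file_digest(p) for k, p in artifacts.items()},
        seed=seed, software_version=version)
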