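"""Result writers and run manifests.

Every command writes a ``manifest.json`` next to its outputs recording the
configuration hash, seed, package version, timestamp, command line, and the
files produced, so that deterministic runs can be reproduced bit-for-bit
from the manifest inputs.  Machine outputs carry full precision; a separate
human-readable text table is rounded for presentation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from .cea import CEACResult, CEATable


def config_hash(config_text: str) -> str:
    return hashlib.sha256(config_text.encode()).hexdigest()


@dataclass
class RunManifest:
    command: str
    config_sha256: str
    seed: int | None
    package_version: str
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    outputs: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path


def format_cea_text(cea_tab: CEATable) -> str:
    """Rounded presentation table mirroring the published layout."""
    lines = [
        f"{'Strategy':<40} {'Costs, $':>12} {'QALYs':>7} "
        f"{'Inc. costs, $':>14} {'Inc. QALYs':>11}  {'ICER ($/QALY)':<20}"
    ]
    for _, row in cea_tab.table.iterrows():
        if row["label"] in ("optimal", "reference"):
            label = "Optimal strategy" if row["label"] == "optimal" else "Reference"
            inc_c = inc_q = "NA"
        elif row["label"] == "dominated":
            label = "Dominated"
            inc_c, inc_q = f"{row['inc_cost']:,.0f}", f"{row['inc_qalys']:.2f}"
        elif row["label"] == "extended-dominated":
            label = "Extended dominated"
            inc_c, inc_q = f"{row['inc_cost']:,.0f}", f"{row['inc_qalys']:.2f}"
        else:
            label = f"{row['icer']:,.0f}"
            inc_c, inc_q = f"{row['inc_cost']:,.0f}", f"{row['inc_qalys']:.2f}"
        lines.append(
            f"{row['name']:<40.40} {row['cost']:>12,.0f} {row['qalys']:>7.2f} "
            f"{inc_c:>14} {inc_q:>11}  {label:<20}"
        )
    if cea_tab.cost_effective:
        lines.append("")
        for wtp, sid in cea_tab.cost_effective.items():
            lines.append(f"Cost-effective at ${wtp:,.0f}/QALY: strategy {sid}")
    return "\n".join(lines) + "\n"


def write_cea_outputs(cea_tab: CEATable, out_dir: Path, stem: str) -> list[str]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.json"
    txt_path = out_dir / f"{stem}.txt"
    cea_tab.to_csv(csv_path)
    json_path.write_text(json.dumps(cea_tab.to_json_dict(), indent=2, default=float) + "\n")
    txt_path.write_text(format_cea_text(cea_tab))
    return [p.name for p in (csv_path, json_path, txt_path)]


def write_ceac_outputs(result: CEACResult, out_dir: Path, stem: str = "ceac") -> list[str]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{stem}.csv"
    result.to_csv(path)
    return [path.name]
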