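"""Publication-style tabular output and run manifests."""

from __future__ import annotations

import hashlib
import io
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

FOREST_COLUMNS = ["parameter", "estimate", "ci_low", "ci_high", "p_lt0", "p_gt0"]


def forest_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Forest-plot companion table: one row per parameter with the posterior
    estimate, 95% credible interval and the probabilities either side of
    zero, formatted to 3 decimals (ASCII hyphen for minus signs)."""
    rows = []
    for name, r in summary.iterrows():
        rows.append(
            {
                "parameter": name,
                "estimate": f"{r['mean']:.3f}",
                "ci_low": f"{r['ci_low']:.3f}",
                "ci_high": f"{r['ci_high']:.3f}",
                "p_lt0": f"{r['p_lt0']:.3f}",
                "p_gt0": f"{r['p_gt0']:.3f}",
            }
        )
    return pd.DataFrame(rows, columns=FOREST_COLUMNS)


def render_forest(table: pd.DataFrame) -> str:
    """Render the forest table as 'estimate (low, high)' lines plus tail
    probabilities, e.g. '-0.037 (-0.053, -0.022)'."""
    lines = []
    for _, r in table.iterrows():
        lines.append(
            f"{r['parameter']}: {r['estimate']} ({r['ci_low']}, {r['ci_high']})"
            f"  P(<0)={r['p_lt0']} P(>0)={r['p_gt0']}"
        )
    return "\n".join(lines)


def parse_forest(text: str) -> pd.DataFrame:
    """Parse :func:`render_forest` output back into a numeric table."""
    rows = []
    for line in text.strip().splitlines():
        name, rest = line.split(": ", 1)
        est, rest = rest.split(" (", 1)
        interval, probs = rest.split(")", 1)
        lo, hi = interval.split(", ")
        p_lt = probs.split("P(<0)=")[1].split(" ")[0]
        p_gt = probs.split("P(>0)=")[1]
        rows.append(
            {
                "parameter": name,
                "estimate": float(est),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "p_lt0": float(p_lt),
                "p_gt0": float(p_gt),
            }
        )
    return pd.DataFrame(rows, columns=FOREST_COLUMNS)


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


@dataclass
class RunManifest:
    """Traceability record: config hash, seed, stage list, input checksums."""

    config_hash: str
    seed: int
    stages: list[str] = field(default_factory=list)
    input_checksums: dict[str, str] = field(default_factory=dict)
    created: float = field(default_factory=time.time)
    package_version: str = ""

    @classmethod
    def for_run(cls, config_dict: dict, seed: int, inputs: dict[str, Path]):
        buf = io.StringIO()
        yaml.safe_dump(config_dict, buf, sort_keys=True)
        checksums = {
            name: _sha256(Path(p).read_bytes()) for name, p in inputs.items()
        }
        from . import __version__

        return cls(
            config_hash=_sha256(buf.getvalue().encode()),
            seed=seed,
            input_checksums=checksums,
            package_version=__version__,
        )

    def record(self, stage: str) -> None:
        self.stages.append(stage)

    def write(self, path: Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stages": self.stages,
            "input_checksums": self.input_checksums,
            "created": self.created,
            "package_version": self.package_version,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
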