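"""Result writers and the run manifest."""

from __future__ import annotations

import datetime as _dt
import json
import sys
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import __version__
from .config import STANDIN_INPUTS, config_hash
from .engine import CohortResult
from .outcomes import IncrementalResult, per_10k

__all__ = ["write_manifest", "write_arm_outcomes", "write_incremental",
           "write_ceac", "write_psa_samples"]


def write_manifest(out_dir: str | Path, seed: int, cfg: Mapping[str, Any],
                   extra: Mapping[str, Any] | None = None) -> Path:
    """Write manifest.json: version, seed, config hash, stand-ins, command line."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "package_version": __version__,
        "master_seed": int(seed),
        "config_hash": config_hash(cfg),
        "standin_inputs": list(STANDIN_INPUTS),
        "command_line": sys.argv,
        **(dict(extra) if extra else {}),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def write_arm_outcomes(path: str | Path, result: CohortResult) -> None:
    """One row per (arm, outcome): mean and Monte-Carlo SE."""
    rows = []
    for arm_name, arm in (("screening", result.screening),
                          ("no_screening", result.no_screening)):
        for outcome, mean in (("cost", arm.mean_cost), ("qaly", arm.mean_qaly),
                              ("life_years", arm.mean_life_years),
                              ("fractures", arm.mean_fractures)):
            rows.append({"arm": arm_name, "outcome": outcome, "mean": mean,
                         "se": arm.se(outcome), "n": arm.n})
        for site, label in enumerate(("hip", "vertebral", "nhnv")):
            rows.append({"arm": arm_name, "outcome": f"fractures_{label}",
                         "mean": float(arm.fractures[site].mean()), "se": float("nan"),
                         "n": arm.n})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_incremental(path: str | Path, inc: IncrementalResult) -> None:
    """Per-person and per-10 000 incremental rows with the dominance label."""
    rows = []
    for scale_name, r in (("per_person", inc), ("per_10k", per_10k(inc))):
        rows.append({
            "scale": scale_name, "delta_cost": r.delta_cost,
            "delta_qaly": r.delta_qaly, "delta_ly": r.delta_ly,
            "fractures_averted": r.fractures_averted,
            "icer": r.icer if r.icer is not None else float("nan"),
            "dominance": r.label, "se_cost": r.se_cost, "se_qaly": r.se_qaly,
            "n": r.n,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ceac(path: str | Path, ceac_df: pd.DataFrame) -> None:
    ceac_df.to_csv(path, index=False)


def write_psa_samples(path: str | Path, samples: Sequence) -> None:
    pd.DataFrame([s.__dict__ for s in samples]).to_csv(path, index=False)
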