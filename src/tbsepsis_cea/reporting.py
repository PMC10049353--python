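"""CSV/JSON writers and run metadata shared by the CLI and the examples."""

from __future__ import annotations

import csv
import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

from . import __version__
from .cea import CEResult
from .parameters import ParameterSet, StructureConfig, parameter_hash

__all__ = ["write_cea_csv", "write_run_metadata"]


def write_cea_csv(results: Sequence[CEResult], path, params: ParameterSet | None = None) -> None:
    """One row per diagnostic strategy: C1, C0, E1, E0, increments, ICER.

    Monetary columns are rounded to cents for display; incremental effect is
    kept at full precision (its printed precision is the reader's choice).
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["strategy", "cost_treat_all", "cost_soc", "effect_treat_all",
                  "effect_soc", "incremental_cost", "incremental_effect", "icer",
                  "dominance"]
        if params is not None:
            header.append("parameter_hash")
        w.writerow(header)
        phash = parameter_hash(params) if params is not None else None
        for r in results:
            row = [
                r.strategy_name,
                f"{r.cost_treat_all:.2f}",
                f"{r.cost_soc:.2f}",
                repr(r.effect_treat_all),
                repr(r.effect_soc),
                f"{r.incremental_cost:.2f}",
                repr(r.incremental_effect),
                "" if r.icer is None else f"{r.icer:.2f}",
                r.dominance,
            ]
            if phash is not None:
                row.append(phash)
            w.writerow(row)


def write_run_metadata(
    path,
    params: ParameterSet,
    structure: StructureConfig,
    seed: int | None = None,
    extra: dict | None = None,
) -> None:
    """Provenance sidecar: parameter hash, structure, version, seed."""
    payload = {
        "package": "tbsepsis-cea",
        "version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "python": platform.python_version(),
        "parameter_hash": parameter_hash(params),
        "structure": structure.model_dump(),
        "seed": seed,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
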