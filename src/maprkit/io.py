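"""Round-trip-safe readers/writers and run manifests.

CSV dialect: comma separator, UTF-8, mandatory header row, numeric cells
unquoted.  Every latent-scale output records its anchoring convention so
values from different fits are never compared on incommensurable scales.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import ClassificationSystem
from .exceptions import ValidationError
from .mapr import LLTMFit
from .rasch import PersonFit, RaschFit, ResponseMatrix

__all__ = [
    "read_response_matrix",
    "write_response_matrix",
    "read_classification",
    "write_classification",
    "read_state_list",
    "rasch_fit_to_dict",
    "lltm_fit_to_dict",
    "write_json",
    "write_rasch_fit",
    "write_lltm_fit",
    "write_person_fit",
    "write_manifest",
]


def read_response_matrix(path: str | Path) -> ResponseMatrix:
    return ResponseMatrix.from_csv(path)


def write_response_matrix(data: ResponseMatrix, path: str | Path) -> None:
    data.to_csv(path)


def read_classification(path: str | Path) -> ClassificationSystem:
    return ClassificationSystem.from_config(path)


def write_classification(system: ClassificationSystem, path: str | Path) -> None:
    system.to_config(path)


def read_state_list(path: str | Path) -> list[str]:
    """State codes: one per line, or a CSV with a 'state' column."""
    path = Path(path)
    text = path.read_text(encoding="utf-8").strip()
    if not text:
        raise ValidationError(f"empty state list {path}")
    first = text.splitlines()[0]
    if "," in first:
        df = pd.read_csv(path, dtype=str)
        if "state" not in df.columns:
            raise ValidationError("state CSV must have a 'state' column")
        return df["state"].tolist()
    return [line.strip() for line in text.splitlines() if line.strip()]


def rasch_fit_to_dict(fit: RaschFit) -> dict:
    return {
        "model": "holistic",
        "anchor": list(fit.anchor) if isinstance(fit.anchor, tuple) else fit.anchor,
        "items": list(fit.items),
        "beta": [float(b) for b in fit.beta],
        "se_beta": [float(s) for s in fit.se_beta],
        "log_cl": float(fit.log_cl),
        "n_persons_used": fit.n_persons_used,
        "dropped_persons": list(fit.dropped_persons),
        "dropped_items": list(fit.dropped_items),
        "iterations": fit.iterations,
        "converged": fit.converged,
        "data_fingerprint": fit.data_fingerprint,
    }


def lltm_fit_to_dict(fit: LLTMFit) -> dict:
    return {
        "model": "attribute",
        "anchor": "reference-levels",
        "system": fit.system.to_dict(),
        "columns": list(fit.columns),
        "alpha": [float(a) for a in fit.alpha],
        "se_alpha": [float(s) for s in fit.se_alpha],
        "log_cl": float(fit.log_cl),
        "items": list(fit.items),
        "implied_beta": [float(b) for b in fit.implied_beta],
        "n_persons_used": fit.n_persons_used,
        "dropped_persons": list(fit.dropped_persons),
        "iterations": fit.iterations,
        "converged": fit.converged,
        "interactions": [list(x) for x in fit.interactions],
        "data_fingerprint": fit.data_fingerprint,
    }


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_rasch_fit(fit: RaschFit, out_dir: str | Path, stem: str = "rasch_fit") -> list[Path]:
    out_dir = Path(out_dir)
    jpath = out_dir / f"{stem}.json"
    cpath = out_dir / f"{stem}.csv"
    write_json(rasch_fit_to_dict(fit), jpath)
    pd.DataFrame({"item": fit.items, "beta": fit.beta, "se": fit.se_beta}).to_csv(
        cpath, index=False
    )
    return [jpath, cpath]


def write_lltm_fit(fit: LLTMFit, out_dir: str | Path, stem: str = "mapr_fit") -> list[Path]:
    out_dir = Path(out_dir)
    jpath = out_dir / f"{stem}.json"
    cpath = out_dir / f"{stem}.csv"
    write_json(lltm_fit_to_dict(fit), jpath)
    pd.DataFrame(
        {"parameter": list(fit.columns), "alpha": fit.alpha, "se": fit.se_alpha}
    ).to_csv(cpath, index=False)
    return [jpath, cpath]


def write_person_fit(fit: PersonFit, out_dir: str | Path, stem: str = "persons") -> list[Path]:
    out_dir = Path(out_dir)
    cpath = out_dir / f"{stem}.csv"
    pd.DataFrame({
        "person": fit.persons if fit.persons is not None
        else [f"p{i + 1:04d}" for i in range(len(fit.theta))],
        "raw_score": fit.raw_scores,
        "theta": fit.theta,
        "se": fit.se_theta,
        "extreme": fit.extreme.astype(int),
    }).to_csv(cpath, index=False)
    return [cpath]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    inputs: list,
    outputs: list,
    config: dict,
    seed: int | None = None,
) -> Path:
    """Write a run manifest linking outputs to inputs by checksum."""
    out_dir = Path(out_dir)
    manifest = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "outputs": {str(Path(p).name): _sha256(Path(p)) for p in outputs},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    write_json(manifest, path)
    return path
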