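"""CSV/FASTA/JSON readers and writers for the pipeline's file formats.

CSV files are UTF-8, comma-separated with a mandatory header row; lines
starting with ``#`` carry provenance (package version, seed, input hashes)
and are skipped on read. Numeric columns round-trip at 12 significant
digits.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .cascade import TimeCourse
from .condensation import CondensationEndpointSet
from .kinetics import SaturationCurve
from .masses import Peptide
from .purification import PurificationStep

logger = logging.getLogger("betakin")

__all__ = [
    "read_saturation",
    "read_endpoints",
    "read_timecourse",
    "write_timecourse",
    "read_fasta",
    "read_purification",
    "provenance_header",
    "write_json",
]


def provenance_header(seed: int | None = None, inputs: list[str | Path] | None = None) -> str:
    """Comment block recording version, seed and input hashes."""
    lines = [f"# betakin {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for path in inputs or []:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
        lines.append(f"# input: {Path(path).name} sha256:{digest}")
    return "\n".join(lines) + "\n"


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input not found: {path}")
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except Exception as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    return df


def read_saturation(path: str | Path) -> SaturationCurve:
    """Read substrate_mM / rate_uM_per_min columns; replicates are averaged."""
    df = _read_csv(path, ["substrate_mM", "rate_uM_per_min"])
    if "replicate" in df.columns:
        df = df.groupby("substrate_mM", as_index=False)["rate_uM_per_min"].mean()
    df = df.sort_values("substrate_mM")
    return SaturationCurve(
        substrate_conc=df["substrate_mM"].to_numpy(float),
        rate=df["rate_uM_per_min"].to_numpy(float),
    )


def read_endpoints(path: str | Path, t_h: float) -> CondensationEndpointSet:
    df = _read_csv(path, ["bet0_uM", "dopax_uM"])
    df = df.sort_values("bet0_uM")
    return CondensationEndpointSet(
        bet0=df["bet0_uM"].to_numpy(float),
        dopax_at_t=df["dopax_uM"].to_numpy(float),
        t=t_h,
    )


def read_timecourse(path: str | Path) -> TimeCourse:
    """Read a t_h + species-columns CSV into a TimeCourse."""
    df = _read_csv(path, ["t_h"])
    species = [c for c in df.columns if c != "t_h"]
    if not species:
        raise ValueError(f"{path}: no species columns beyond t_h")
    return TimeCourse(
        times=df["t_h"].to_numpy(float),
        data=df[species].to_numpy(float),
        species=tuple(species),
    )


def write_timecourse(
    course: TimeCourse,
    path: str | Path,
    seed: int | None = None,
) -> None:
    path = Path(path)
    df = pd.DataFrame({"t_h": course.times})
    for i, name in enumerate(course.species):
        df[name] = course.data[:, i]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(provenance_header(seed=seed))
        df.to_csv(fh, index=False, float_format="%.12g")


def read_fasta(path: str | Path, record_id: str | None = None) -> Peptide:
    """First (or named) record of a FASTA file as a Peptide."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    if record_id is None:
        if len(records) > 1:
            warnings.warn(f"{path}: {len(records)} records; using first ({records[0].id})")
            logger.warning("%s: multiple records, using first (%s)", path, records[0].id)
        record = records[0]
    else:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise ValueError(f"{path}: no record with id {record_id!r}")
        record = matches[0]
    return Peptide(str(record.seq).upper())


def read_purification(path: str | Path) -> list[PurificationStep]:
    df = _read_csv(path, ["step", "volume_ml", "protein_mg_per_ml", "activity"])
    steps = []
    for _, row in df.iterrows():
        sa = row.get("specific_activity")
        steps.append(
            PurificationStep(
                name=str(row["step"]),
                volume=float(row["volume_ml"]),
                protein_conc=float(row["protein_mg_per_ml"]),
                activity=float(row["activity"]),
                specific_activity=None if sa is None or pd.isna(sa) else float(sa),
            )
        )
    return steps


def write_json(payload: dict, path: str | Path | None, seed: int | None = None) -> str:
    """Serialize results deterministically; write to path or return the text."""
    payload = dict(payload)
    payload.setdefault("version", __version__)
    if seed is not None:
        payload.setdefault("seed", seed)
    text = json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and obj == float("inf"):
        return "inf"
    return obj
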