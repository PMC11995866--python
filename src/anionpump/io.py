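"""CSV dialects and JSON result records shared by all stages.

Matrix CSVs carry the wavelength grid in the first column and one data
column per condition; the header row holds the condition values themselves
(concentrations in mM for titrations, times in seconds for transients), so a
file round-trips into the same typed object it was written from.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import SpectrumSeries
from .errors import FormatError
from .photocycle import TransientDataset
from .transport import MutantPanel, PhTrace

__all__ = [
    "write_titration_csv",
    "write_transient_csv",
    "write_ph_csv",
    "write_panel_csv",
    "read_matrix_csv",
    "read_ph_csv",
    "read_panel_csv",
    "ResultRecord",
    "file_digest",
]


def write_titration_csv(series: SpectrumSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        series.absorbance,
        columns=[repr(float(c)) for c in series.concentrations_mM],
    )
    df.insert(0, "wavelength_nm", series.wavelengths_nm)
    df.to_csv(path, index=False)


def write_transient_csv(data: TransientDataset, path: str | Path) -> None:
    df = pd.DataFrame(data.deltaA, columns=[repr(float(t)) for t in data.times_s])
    df.insert(0, "wavelength_nm", data.wavelengths_nm)
    df.to_csv(path, index=False)


def write_ph_csv(trace: PhTrace, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": trace.times_s, "pH": trace.ph})
    df.attrs = {}
    with open(path, "w", newline="") as fh:
        fh.write(f"# light_on_s={trace.light_on_s!r} light_off_s={trace.light_off_s!r}\n")
        df.to_csv(fh, index=False)


def write_panel_csv(panel: MutantPanel, path: str | Path) -> None:
    df = panel.data.copy()
    df["expression"] = df["mutant"].map(panel.expression)
    df.to_csv(path, index=False)


def _parse_header_values(columns, path: Path, kind: str) -> np.ndarray:
    try:
        values = np.array([float(c) for c in columns], dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric header column {exc}") from exc
    if np.unique(values).size != values.size:
        dupes = [v for v in values if np.sum(values == v) > 1]
        raise FormatError(f"{path}: duplicated {kind} column(s) {sorted(set(dupes))}")
    return values


def read_matrix_csv(path: str | Path, kind: str):
    """Read a titration or transient matrix CSV into its typed object.

    ``kind`` is ``"titration"`` (header = concentrations in mM) or
    ``"transient"`` (header = times in seconds).  Unsorted grids are
    re-sorted with a warning; ragged/non-numeric files raise
    :class:`FormatError` naming the offending location.
    """
    import warnings

    path = Path(path)
    if kind not in ("titration", "transient"):
        raise FormatError(f"kind must be titration|transient, got {kind!r}")
    with open(path) as fh:
        raw_header = fh.readline().strip().split(",")
    if len(set(raw_header)) != len(raw_header):
        dupes = sorted({c for c in raw_header if raw_header.count(c) > 1})
        raise FormatError(f"{path}: duplicated header column(s) {dupes}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: unparseable CSV ({exc})") from exc
    if df.columns[0] != "wavelength_nm":
        raise FormatError(f"{path}: first column must be wavelength_nm, got {df.columns[0]!r}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise FormatError(f"{path}: non-numeric cell(s) in column {col!r}, row(s) {list(bad[:5])}")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing cells")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    header = _parse_header_values(df.columns[1:], path, "concentration" if kind == "titration" else "time")
    M = df.iloc[:, 1:].to_numpy(dtype=float)

    order = np.argsort(wl)
    if not np.all(order == np.arange(wl.size)):
        warnings.warn(f"{path}: wavelengths not ascending; re-sorting", stacklevel=2)
        wl, M = wl[order], M[order]
    corder = np.argsort(header)
    if not np.all(corder == np.arange(header.size)):
        warnings.warn(f"{path}: header values not ascending; re-sorting", stacklevel=2)
        header, M = header[corder], M[:, corder]

    if kind == "titration":
        return SpectrumSeries(wavelengths_nm=wl, concentrations_mM=header, absorbance=M)
    return TransientDataset(wavelengths_nm=wl, times_s=header, deltaA=M)


def read_ph_csv(path: str | Path) -> PhTrace:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise FormatError(f"{path}: missing '# light_on_s=... light_off_s=...' header line")
    try:
        meta = dict(tok.split("=") for tok in first[1:].split())
        on, off = float(meta["light_on_s"]), float(meta["light_off_s"])
    except (ValueError, KeyError) as exc:
        raise FormatError(f"{path}: bad event header {first!r}") from exc
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != ["time_s", "pH"]:
        raise FormatError(f"{path}: expected columns time_s,pH got {list(df.columns)}")
    return PhTrace(
        times_s=df["time_s"].to_numpy(dtype=float),
        ph=df["pH"].to_numpy(dtype=float),
        light_on_s=on,
        light_off_s=off,
    )


def read_panel_csv(path: str | Path) -> MutantPanel:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"mutant", "anion", "replicate", "slope", "expression"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    expression = (
        df[["mutant", "expression"]].drop_duplicates().set_index("mutant")["expression"].to_dict()
    )
    return MutantPanel(data=df.drop(columns=["expression"]), expression=expression)


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file's bytes (stable input fingerprint for records)."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


@dataclasses.dataclass(frozen=True)
class ResultRecord:
    """Serializable record of one analysis stage.

    Captures the stage name, input-file digests, the parameter echo, the
    stage payload, and the seed, so a result can be traced back to exactly
    what produced it.  ``timestamp`` is excluded from equality so identical
    reruns compare equal.
    """

    stage: str
    inputs: dict
    parameters: dict
    outputs: dict
    seed: int | None = None
    timestamp: str = dataclasses.field(default="", compare=False)

    def to_json(self, path: str | Path | None = None) -> str:
        record = _jsonify(self)
        if not record["timestamp"]:
            record["timestamp"] = datetime.now(timezone.utc).isoformat()
        text = json.dumps(record, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ResultRecord":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(**d)
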