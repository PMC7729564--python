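"""File I/O: event tables (CSV and FCS 3.0/3.1), summaries, configs.

Event tables are comma-delimited with one header row and columns exactly
``event_id, FSC_A, FSC_H, SSC_A, VIAB, DNA_A, DNA_W``.  Output tables carry
a provenance header comment (``# quiescreen config=<hash> seed=<n>``) which
readers skip.  A minimal list-mode FCS 3.0/3.1 reader is included so
acquisition files can be ingested with a channel-name map; FCS writing is
out of scope.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .gating import REQUIRED_CHANNELS, WellSummary

EVENT_COLUMNS = ("event_id",) + REQUIRED_CHANNELS


def write_table(df: pd.DataFrame, path, header_comment: Optional[str] = None
                ) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_event_table(events: pd.DataFrame, path,
                      header_comment: Optional[str] = None) -> None:
    write_table(events[list(EVENT_COLUMNS)], path, header_comment)


@dataclass
class EventTableResult:
    events: pd.DataFrame
    n_dropped: int  # rows removed for negative/missing intensities


def read_event_table(path, channel_map: Optional[Mapping[str, str]] = None
                     ) -> EventTableResult:
    """Read a CSV or FCS event table into the standard column layout.

    ``channel_map`` renames source channels to the standard names (required
    for FCS files whose $PnN labels differ).  Rows with any negative
    intensity are dropped and counted in the anomaly tally.
    """
    path = Path(path)
    if path.suffix.lower() == ".fcs":
        df = read_fcs(path)
    else:
        df = pd.read_csv(path, comment="#")
    if channel_map:
        df = df.rename(columns=dict(channel_map))
    missing = [c for c in REQUIRED_CHANNELS if c not in df.columns]
    if missing:
        raise ValueError(f"event table {path} missing channels: {missing}")
    if "event_id" not in df.columns:
        df.insert(0, "event_id", np.arange(len(df)))
    df = df[list(EVENT_COLUMNS)]
    ok = (df[list(REQUIRED_CHANNELS)] >= 0).all(axis=1) & df.notna().all(axis=1)
    dropped = int((~ok).sum())
    return EventTableResult(df[ok].reset_index(drop=True), dropped)


# --- minimal FCS 3.0 / 3.1 reader --------------------------------------------

def _parse_text_segment(raw: bytes) -> Dict[str, str]:
    delim = raw[:1].decode("latin-1")
    parts = raw.decode("latin-1").split(delim)
    # parts[0] is empty (leading delimiter); pairs follow
    kv = parts[1:]
    out = {}
    for key, val in zip(kv[::2], kv[1::2]):
        if key:
            out[key.strip().upper()] = val
    return out


def read_fcs(path) -> pd.DataFrame:
    """Read a list-mode FCS 3.0/3.1 file ($DATATYPE F, D or I).

    Returns a DataFrame with one column per parameter, named by $PnN.
    Only uncompensated raw list-mode data is supported.
    """
    raw = Path(path).read_bytes()
    version = raw[:6].decode("ascii", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise ValueError(f"unsupported FCS version {version!r}")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = _parse_text_segment(raw[text_start:text_end + 1])
    data_start = int(raw[26:34] or b"0")
    data_end = int(raw[34:42] or b"0")
    if data_start == 0:
        data_start = int(text["$BEGINDATA"])
        data_end = int(text["$ENDDATA"])
    if text.get("$MODE", "L").upper() != "L":
        raise ValueError("only list-mode ($MODE L) FCS data is supported")
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    dtype_code = text["$DATATYPE"].strip().upper()
    byteord = text.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    if dtype_code == "F":
        np_dtype = np.dtype(f"{endian}f4")
    elif dtype_code == "D":
        np_dtype = np.dtype(f"{endian}f8")
    elif dtype_code == "I":
        bits = {int(text[f"$P{i}B"]) for i in range(1, n_par + 1)}
        if len(bits) != 1 or next(iter(bits)) not in (16, 32):
            raise ValueError("integer FCS data requires uniform $PnB of 16 or 32")
        np_dtype = np.dtype(f"{endian}u{next(iter(bits)) // 8}")
    else:
        raise ValueError(f"unsupported $DATATYPE {dtype_code!r}")
    count = n_par * n_tot
    data = np.frombuffer(raw, dtype=np_dtype, count=count, offset=data_start)
    return pd.DataFrame(data.reshape(n_tot, n_par).astype(float), columns=names)


# --- summaries, fits, layout, ground truth ------------------------------------

def summary_to_row(strain_id: str, day: float, s: WellSummary) -> dict:
    return {"strain_id": strain_id, "day": day, "n_events": s.n_events,
            "n_singlets": s.n_singlets, "n_doublets": s.n_doublets,
            "n_live": s.n_live, "n_dead": s.n_dead,
            "mortality_pct": s.mortality_pct, "g0_pct": s.g0_pct,
            "g2_pct": s.g2_pct, "g1m_pct": s.g1m_pct,
            "unclassified_pct": s.unclassified_pct, "qc_pass": s.qc_pass,
            "flags": ";".join(s.flags)}


def write_ground_truth(truth_dict: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(truth_dict, indent=1, sort_keys=True,
                               default=float))


def read_layout(path) -> pd.DataFrame:
    """Plate layout: delimited text with columns strain_id, well, day."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    need = {"strain_id", "well", "day"}
    if not need.issubset(df.columns):
        raise ValueError(f"layout must have columns {sorted(need)}")
    return df


def config_hash(config_dict: dict) -> str:
    canon = yaml.safe_dump(config_dict, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_yaml(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    return out or {}
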