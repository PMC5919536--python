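"""Dataset and result I/O.

Two CSV dialects are supported.  The *extended* dialect is the package's
native format for day-resolved records (columns ``donor_id, seq, day,
titer, boostered``); the *s1* dialect mirrors anonymised public releases in
which all timing information has been removed (columns ``donor_id, seq,
titer, boostered``) — such records support counting and magnitude-style
description but not fitting.  Both are plain UTF-8 comma-separated files
with a mandatory header; comment lines starting with ``#`` (used to embed
the seed and configuration hash of the run that produced a file) are
ignored on reading.

Fit results are serialised as a flat key-value text file (one parameter per
line) plus a per-donor CSV.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .fitting import StageFitResult, per_donor_residuals
from .model import DonorRecord

__all__ = [
    "S1Record",
    "read_dataset",
    "write_dataset",
    "dataset_summary",
    "save_fit",
    "load_fit_params",
    "save_donor_report",
    "config_hash",
    "load_config",
    "save_config",
]

_S1_COLUMNS = ["donor_id", "seq", "titer", "boostered"]
_EXTENDED_COLUMNS = ["donor_id", "seq", "day", "titer", "boostered"]


@dataclass(frozen=True)
class S1Record:
    """One donor's titer sequence without timing information.

    ``obs_days`` is intentionally absent (``None``) so that fitting
    functions can refuse such records with a clear message.
    """

    donor_id: str
    titers: np.ndarray
    boostered: np.ndarray  # 0/1 per measurement

    obs_days = None

    @property
    def n_obs(self) -> int:
        return len(self.titers)

    @property
    def n_boosters(self) -> int:
        return int(np.sum(self.boostered))


def _header_lines(seed: int | None, cfg_hash: str | None) -> str:
    lines = []
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if cfg_hash is not None:
        lines.append(f"# config_hash: {cfg_hash}")
    return "".join(line + "\n" for line in lines)


def write_dataset(
    records: Sequence[DonorRecord],
    path: str | Path,
    dialect: str = "extended",
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> None:
    """Write donor records as CSV in the chosen dialect.

    Boosters are represented by a 0/1 flag on the donation at which they
    were administered, so every booster day must also be an observation day.
    """
    if dialect not in ("extended", "s1"):
        raise ValueError(f"unknown dialect {dialect!r}")
    frames = []
    for rec in records:
        boostered = np.isin(rec.obs_days, rec.booster_days).astype(int)
        if boostered.sum() != rec.n_boosters:
            missing = sorted(set(rec.booster_days) - set(rec.obs_days))
            raise ValueError(
                f"donor {rec.donor_id}: booster days {missing} have no same-day "
                "donation and cannot be represented in the flag column"
            )
        frame = pd.DataFrame(
            {
                "donor_id": rec.donor_id,
                "seq": np.arange(1, rec.n_obs + 1),
                "day": rec.obs_days.astype(int),
                "titer": rec.measured_titers,
                "boostered": boostered,
            }
        )
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    if dialect == "s1":
        table = table[_S1_COLUMNS]
    else:
        table = table[_EXTENDED_COLUMNS]
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_lines(seed, cfg_hash))
        table.to_csv(fh, index=False)


def read_dataset(
    path: str | Path,
    dialect: str = "auto",
    column_map: dict | None = None,
) -> list:
    """Read donor records from CSV.

    ``dialect`` is ``"extended"``, ``"s1"`` or ``"auto"`` (decided by the
    presence of a day column).  ``column_map`` renames non-standard source
    columns to the expected names (e.g. ``{"Donor": "donor_id"}``).
    Malformed rows are reported with their line numbers.
    """
    path = Path(path)
    table = pd.read_csv(path, comment="#")
    if column_map:
        table = table.rename(columns=column_map)
    with open(path, encoding="utf-8") as fh:
        n_comment = 0
        for line in fh:
            if line.startswith("#"):
                n_comment += 1
            else:
                break
    line_offset = n_comment + 2  # 1-based data lines start after comments + header

    if dialect == "auto":
        dialect = "extended" if "day" in table.columns else "s1"
    required = _EXTENDED_COLUMNS if dialect == "extended" else _S1_COLUMNS
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s): {', '.join(missing)}")

    problems = []
    titer = pd.to_numeric(table["titer"], errors="coerce")
    for idx in table.index[titer.isna()]:
        problems.append(f"line {idx + line_offset}: non-numeric titer {table.loc[idx, 'titer']!r}")
    for idx in table.index[titer < 0]:
        problems.append(f"line {idx + line_offset}: negative titer {titer[idx]}")
    if problems:
        raise ValueError(f"{path.name}: malformed rows:\n" + "\n".join(problems))
    table["titer"] = titer

    records: list = []
    for donor_id, g in table.groupby("donor_id", sort=False):
        g = g.sort_values("seq")
        if dialect == "extended":
            days = g["day"].to_numpy(float)
            records.append(
                DonorRecord(
                    donor_id=str(donor_id),
                    obs_days=days,
                    measured_titers=g["titer"].to_numpy(float),
                    booster_days=days[g["boostered"].to_numpy(int) == 1],
                )
            )
        else:
            records.append(
                S1Record(
                    donor_id=str(donor_id),
                    titers=g["titer"].to_numpy(float),
                    boostered=g["boostered"].to_numpy(int),
                )
            )
    return records


def dataset_summary(records: Sequence) -> dict:
    """Counts of donors, titer measurements and booster events."""
    return {
        "n_donors": len(records),
        "n_titers": int(sum(r.n_obs for r in records)),
        "n_boosters": int(sum(r.n_boosters for r in records)),
    }


# ---------------------------------------------------------------------------
# fit results


def save_fit(
    result: StageFitResult,
    prefix: str | Path,
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> None:
    """Write ``<prefix>.params.txt`` (key = value lines) and, when per-donor
    estimates exist, ``<prefix>.donors.csv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.params.txt", "w", encoding="utf-8") as fh:
        fh.write(_header_lines(seed, cfg_hash))
        fh.write(f"stage = {result.stage}\n")
        fh.write(f"converged = {result.converged}\n")
        fh.write(f"iterations = {result.iterations}\n")
        if result.loglik is not None:
            fh.write(f"loglik = {result.loglik!r}\n")
        for key in sorted(result.params):
            fh.write(f"{key} = {result.params[key]!r}\n")
    if result.per_donor is not None:
        with open(f"{prefix}.donors.csv", "w", encoding="utf-8", newline="") as fh:
            fh.write(_header_lines(seed, cfg_hash))
            result.per_donor.to_csv(fh, index=False)


def load_fit_params(prefix: str | Path) -> dict:
    """Read back a ``save_fit`` parameter file (values as floats/bools)."""
    out: dict = {}
    with open(f"{prefix}.params.txt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if value in ("True", "False"):
                out[key] = value == "True"
            else:
                try:
                    out[key] = float(value)
                except ValueError:
                    out[key] = value
    return out


def save_donor_report(
    records: Sequence[DonorRecord],
    fit: StageFitResult,
    path: str | Path,
    seed: int | None = None,
    cfg_hash: str | None = None,
) -> pd.DataFrame:
    """Per-donor fit summary (parameters + MAE/MSE), sorted by MAE descending.

    The ordering mirrors how per-donor fit galleries are usually browsed:
    worst-described donors first.  The sort is stable, so ties keep their
    input order.
    """
    residuals = per_donor_residuals(records, fit)
    merged = fit.per_donor.merge(residuals[["donor_id", "mae", "mse"]], on="donor_id")
    merged = merged.sort_values("mae", ascending=False, kind="stable").reset_index(drop=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_lines(seed, cfg_hash))
        merged.to_csv(fh, index=False)
    return merged


# ---------------------------------------------------------------------------
# configuration


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
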