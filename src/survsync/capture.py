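"""Capture-history data: containers, readers/writers, filtering and m-arrays.

A capture (encounter) history is a binary detection vector over annual
occasions, one row per marked individual, labelled with the colony of
ringing.  The first detection marks the release occasion; the Cormack-
Jolly-Seber likelihood conditions on it.  Two on-disk dialects are
supported: a plain CSV (``id,colony,first_year,y<YYYY>,...``) and a
minimal MARK ``.inp`` dialect (history string followed by one frequency
column per colony, semicolon-terminated).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CaptureDataset",
    "CaptureDataError",
    "MArray",
    "read_dataset",
    "write_dataset",
    "filter_transients",
    "left_truncate",
    "build_marray",
]


class CaptureDataError(ValueError):
    """Raised for malformed capture-history data; carries offending ids/lines."""


@dataclass(frozen=True)
class CaptureDataset:
    """Binary detection histories for marked individuals at annual occasions.

    Attributes
    ----------
    occasions : (T,) int array of strictly increasing calendar years.
    colonies : ordered colony labels.
    ids : (n,) individual identifiers.
    colony_index : (n,) int index into ``colonies``.
    Y : (n, T) 0/1 detection matrix; first 1 in each row is the release.
    """

    occasions: np.ndarray
    colonies: tuple[str, ...]
    ids: np.ndarray
    colony_index: np.ndarray
    Y: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "occasions", np.asarray(self.occasions, dtype=int))
        object.__setattr__(self, "colonies", tuple(self.colonies))
        object.__setattr__(self, "ids", np.asarray(self.ids, dtype=object))
        object.__setattr__(self, "colony_index", np.asarray(self.colony_index, dtype=int))
        object.__setattr__(self, "Y", np.asarray(self.Y, dtype=np.int8))
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.Y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.Y.shape[1]

    @property
    def n_colonies(self) -> int:
        return len(self.colonies)

    @property
    def first_index(self) -> np.ndarray:
        """Index of the release occasion (first detection) per individual."""
        return np.argmax(self.Y == 1, axis=1)

    @property
    def last_index(self) -> np.ndarray:
        """Index of the last detection per individual."""
        T = self.n_occasions
        return T - 1 - np.argmax(self.Y[:, ::-1] == 1, axis=1)

    @property
    def first_release_year(self) -> np.ndarray:
        return self.occasions[self.first_index]

    def validate(self) -> None:
        Y = self.Y
        if Y.ndim != 2:
            raise CaptureDataError("detection matrix must be 2-D")
        if Y.shape[0] != len(self.ids) or Y.shape[0] != len(self.colony_index):
            raise CaptureDataError("ids / colony_index / histories lengths disagree")
        if Y.shape[1] != len(self.occasions):
            raise CaptureDataError("history length does not match number of occasions")
        if np.any(np.diff(self.occasions) <= 0):
            raise CaptureDataError("occasion years must be strictly increasing")
        bad = ~np.isin(Y, (0, 1)).all(axis=1)
        if bad.any():
            raise CaptureDataError(f"non-binary detections for ids {list(self.ids[bad])}")
        empty = Y.sum(axis=1) == 0
        if empty.any():
            raise CaptureDataError(f"individuals with no detections: {list(self.ids[empty])}")
        if self.colony_index.min(initial=0) < 0 or (
            self.n_individuals and self.colony_index.max() >= self.n_colonies
        ):
            raise CaptureDataError("colony index out of range")

    # -- helpers ---------------------------------------------------------
    def subset(self, mask: np.ndarray) -> "CaptureDataset":
        mask = np.asarray(mask)
        return CaptureDataset(self.occasions, self.colonies, self.ids[mask],
                              self.colony_index[mask], self.Y[mask])

    def select_colony(self, colony: str) -> "CaptureDataset":
        """Single-colony view (colony list collapses to one label)."""
        c = self.colonies.index(colony)
        mask = self.colony_index == c
        return CaptureDataset(self.occasions, (colony,), self.ids[mask],
                              np.zeros(mask.sum(), dtype=int), self.Y[mask])

    def equals(self, other: "CaptureDataset", ignore_ids: bool = False) -> bool:
        same = (
            np.array_equal(self.occasions, other.occasions)
            and self.colonies == other.colonies
            and np.array_equal(self.colony_index, other.colony_index)
            and np.array_equal(self.Y, other.Y)
        )
        if ignore_ids:
            return same
        return same and np.array_equal(self.ids, other.ids)

    def to_frame(self) -> pd.DataFrame:
        cols = {"id": self.ids,
                "colony": [self.colonies[c] for c in self.colony_index],
                "first_year": self.first_release_year}
        for j, year in enumerate(self.occasions):
            cols[f"y{year}"] = self.Y[:, j]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_dataset(data: CaptureDataset, path, format: str = "csv") -> None:
    path = Path(path)
    if format == "csv":
        data.to_frame().to_csv(path, index=False)
    elif format == "inp":
        C = data.n_colonies
        with open(path, "w") as fh:
            for i in range(data.n_individuals):
                hist = "".join(map(str, data.Y[i]))
                freqs = ["1" if c == data.colony_index[i] else "0" for c in range(C)]
                fh.write(f"{hist} {' '.join(freqs)};\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_csv(path) -> CaptureDataset:
    df = pd.read_csv(path, dtype={"id": str, "colony": str})
    ycols = [c for c in df.columns if c.startswith("y") and c[1:].isdigit()]
    if not ycols or "id" not in df.columns or "colony" not in df.columns:
        raise CaptureDataError(f"{path}: expected columns id,colony,first_year,y<YYYY>...")
    years = np.array(sorted(int(c[1:]) for c in ycols))
    Y = df[[f"y{y}" for y in years]].to_numpy()
    errors = []
    if np.isnan(Y.astype(float)).any():
        rows = np.where(np.isnan(Y.astype(float)).any(axis=1))[0]
        errors += [f"line {r + 2}: ragged/missing history (id={df['id'][r]})" for r in rows]
    colonies = tuple(dict.fromkeys(df["colony"]))
    colony_index = np.array([colonies.index(c) for c in df["colony"]])
    Y = np.nan_to_num(Y.astype(float)).astype(np.int8)
    first = np.argmax(Y == 1, axis=1)
    if "first_year" in df.columns:
        declared = df["first_year"].to_numpy()
        for r in range(len(df)):
            if Y[r].sum() == 0:
                errors.append(f"line {r + 2}: empty history (id={df['id'][r]})")
                continue
            if years[first[r]] != declared[r]:
                if declared[r] in years and Y[r, list(years).index(declared[r])] == 0:
                    errors.append(
                        f"line {r + 2}: no detection at declared first_year "
                        f"{declared[r]} (id={df['id'][r]})")
                elif declared[r] > years[first[r]]:
                    errors.append(
                        f"line {r + 2}: detection before declared first release "
                        f"(id={df['id'][r]})")
                else:
                    errors.append(
                        f"line {r + 2}: declared first_year {declared[r]} outside "
                        f"occasions (id={df['id'][r]})")
    if errors:
        raise CaptureDataError(f"{path}: " + "; ".join(errors))
    return CaptureDataset(years, colonies, df["id"].to_numpy(dtype=object),
                          colony_index, Y)


def _read_inp(path, occasions=None, colonies=None) -> CaptureDataset:
    histories, colony_idx, errors = [], [], []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if not line.endswith(";"):
            errors.append(f"line {lineno}: missing terminating ';'")
            continue
        parts = line[:-1].split()
        if len(parts) < 2:
            errors.append(f"line {lineno}: expected '<history> <freqs>;'")
            continue
        hist, freqs = parts[0], parts[1:]
        if not set(hist) <= {"0", "1"}:
            errors.append(f"line {lineno}: non-binary history {hist!r}")
            continue
        try:
            f = [int(v) for v in freqs]
        except ValueError:
            errors.append(f"line {lineno}: non-integer group frequency")
            continue
        if sum(v > 0 for v in f) != 1 or min(f) < 0:
            errors.append(f"line {lineno}: exactly one positive group frequency required")
            continue
        group = next(i for i, v in enumerate(f) if v > 0)
        histories += [[int(ch) for ch in hist]] * f[group]
        colony_idx += [group] * f[group]
    if errors:
        raise CaptureDataError(f"{path}: " + "; ".join(errors))
    lengths = {len(h) for h in histories}
    if len(lengths) > 1:
        raise CaptureDataError(f"{path}: ragged histories of lengths {sorted(lengths)}")
    T = lengths.pop() if histories else 0
    n_groups = max(colony_idx, default=-1) + 1
    if occasions is None:
        occasions = np.arange(1, T + 1)
    if colonies is None:
        colonies = tuple(f"group{i + 1}" for i in range(n_groups))
    ids = np.array([f"inp_{i + 1}" for i in range(len(histories))], dtype=object)
    return CaptureDataset(np.asarray(occasions), tuple(colonies), ids,
                          np.array(colony_idx, dtype=int),
                          np.array(histories, dtype=np.int8))


def read_dataset(path, format: str = "csv", occasions=None,
                 colonies=None) -> CaptureDataset:
    """Read a capture-history file in the ``csv`` or ``inp`` dialect.

    ``occasions``/``colonies`` override the defaults for ``inp`` files,
    which carry neither calendar years nor colony names.
    """
    if format == "csv":
        return _read_csv(path)
    if format == "inp":
        return _read_inp(path, occasions=occasions, colonies=colonies)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def filter_transients(data: CaptureDataset) -> tuple[CaptureDataset, dict]:
    """Drop individuals never detected again after their first release.

    Removing never-re-encountered birds strips transients and prospectors
    that would otherwise inflate apparent mortality; it also removes the
    residents that happened never to be re-detected.  The report gives
    per-colony removal counts and fractions.
    """
    resighted = data.Y.sum(axis=1) > 1
    report: dict = {"colonies": {}, "n_before": int(data.n_individuals),
                    "n_removed": int((~resighted).sum())}
    for c, name in enumerate(data.colonies):
        mask = data.colony_index == c
        n = int(mask.sum())
        removed = int((mask & ~resighted).sum())
        report["colonies"][name] = {
            "n_before": n,
            "n_removed": removed,
            "fraction_removed": removed / n if n else 0.0,
        }
    return data.subset(resighted), report


def left_truncate(data: CaptureDataset, start_year: int) -> CaptureDataset:
    """Drop occasions before ``start_year``.

    Individuals first released earlier but detected at or after the new
    start keep their history with the first post-truncation detection
    acting as the release (the CJS likelihood conditions on an actual
    encounter); individuals never detected from ``start_year`` on are
    dropped.
    """
    occ = data.occasions
    if start_year > occ[-1]:
        raise ValueError(f"start_year {start_year} is after the last occasion {occ[-1]}")
    k = int(np.searchsorted(occ, start_year))
    if k == 0:
        return data
    Y = data.Y[:, k:]
    keep = Y.sum(axis=1) > 0
    return CaptureDataset(occ[k:], data.colonies, data.ids[keep],
                          data.colony_index[keep], Y[keep])


# ---------------------------------------------------------------------------
# m-array
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MArray:
    """Per-colony m-array: releases by occasion of next re-encounter.

    ``m[c, i, j]`` counts individuals of colony ``c`` released (captured)
    at occasion ``i`` and next re-detected at occasion ``j > i``.
    """

    colonies: tuple[str, ...]
    occasions: np.ndarray
    m: np.ndarray              # (C, T, T)
    releases: np.ndarray       # (C, T)
    never_seen_again: np.ndarray  # (C, T)

    def check(self) -> None:
        assert (self.m >= 0).all()
        assert np.allclose(self.m.sum(axis=2) + self.never_seen_again, self.releases)
        assert all(np.allclose(np.tril(self.m[c]), 0) for c in range(len(self.colonies)))


def build_marray(data: CaptureDataset) -> MArray:
    C, T = data.n_colonies, data.n_occasions
    m = np.zeros((C, T, T), dtype=int)
    releases = np.zeros((C, T), dtype=int)
    never = np.zeros((C, T), dtype=int)
    for i in range(data.n_individuals):
        c = data.colony_index[i]
        det = np.flatnonzero(data.Y[i])
        for a, b in zip(det[:-1], det[1:]):
            releases[c, a] += 1
            m[c, a, b] += 1
        releases[c, det[-1]] += 1
        never[c, det[-1]] += 1
    out = MArray(data.colonies, data.occasions, m, releases, never)
    out.check()
    return out


def removal_report_to_json(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
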