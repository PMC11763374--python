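"""File formats: trajectory tables (CSV/TSV), Praat TextGrids (long and
short format read, long format write), condition manifests, and score
configuration files (YAML/JSON).

Trajectory tables have a ``time`` column (seconds) and one unit-annotated
column per channel, e.g. ``time,f0[st],F2[Hz]``.  Empty cells load as masked
(NaN) samples.  Pitch helpers convert Hz to semitones relative to a declared
reference; conversions never happen implicitly.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError, ParseError
from .score import (
    DEFAULT_FRACTIONS,
    Dimension,
    DimensionInventory,
    GestureSpec,
    SyllableSpec,
    TargetParams,
    Interval,
)
from .sequencing import Channel, Trajectory, TrajectorySet

__all__ = [
    "read_trajectory_table",
    "write_trajectory_table",
    "read_textgrid",
    "write_textgrid",
    "read_manifest",
    "read_score_config",
    "hz_to_st",
    "st_to_hz",
]

_CHANNEL_RE = re.compile(r"^(?P<name>[^\[\]]+)\[(?P<unit>[^\[\]]*)\]$")


def hz_to_st(hz, ref: float) -> np.ndarray:
    """Semitones relative to ``ref`` Hz: ``12*log2(hz/ref)``."""
    if ref <= 0:
        raise InvalidInputError("reference frequency must be > 0")
    return 12.0 * np.log2(np.asarray(hz, dtype=float) / ref)


def st_to_hz(st, ref: float) -> np.ndarray:
    if ref <= 0:
        raise InvalidInputError("reference frequency must be > 0")
    return ref * np.power(2.0, np.asarray(st, dtype=float) / 12.0)


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return {"csv": ",", "tsv": "\t"}[fmt]
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def write_trajectory_table(path, trajset: TrajectorySet, fmt: str | None = None) -> None:
    """Write ``time`` plus one ``name[unit]`` column per channel."""
    path = Path(path)
    sep = _sep_for(path, fmt)
    first = next(iter(trajset.trajectories.values()))
    data = {"time": first.times}
    for name, traj in trajset.trajectories.items():
        if len(traj.times) != len(first.times) or not np.allclose(
            traj.times, first.times, atol=1e-9
        ):
            raise InvalidInputError("channels must share one clock to be tabled")
        data[f"{name}[{traj.channel.unit}]"] = traj.values
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_trajectory_table(
    path, fmt: str | None = None, allow_resample: bool = False
) -> TrajectorySet:
    """Read a trajectory table; enforce a uniform sample rate.

    Non-uniform time steps raise unless ``allow_resample`` is set, in which
    case channels are linearly resampled onto a uniform grid at the median
    rate.  Masked (empty) cells load as NaN.
    """
    path = Path(path)
    sep = _sep_for(path, fmt)
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a time column plus at least one channel", line=1)
    cols = list(df.columns)
    if cols[0].strip().lower().split("[")[0] != "time":
        raise ParseError(f"first column must be 'time', got {cols[0]!r}", line=1)
    times = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(~np.isfinite(times)):
        bad = int(np.flatnonzero(~np.isfinite(times))[0])
        raise ParseError("non-finite time value", line=bad + 2)
    if len(times) > 1:
        dt = np.diff(times)
        if np.any(dt <= 0):
            bad = int(np.flatnonzero(dt <= 0)[0])
            raise ParseError("time not strictly increasing", line=bad + 3)
        step = np.median(dt)
        uniform = np.all(np.abs(dt - step) <= 1e-6)
        if not uniform and not allow_resample:
            bad = int(np.flatnonzero(np.abs(dt - step) > 1e-6)[0])
            raise ParseError(
                "non-uniform sample times (pass allow_resample to resample)",
                line=bad + 3,
            )
    else:
        step = None

    trajectories: dict[str, Trajectory] = {}
    for col in cols[1:]:
        m = _CHANNEL_RE.match(col.strip())
        if not m:
            raise ParseError(
                f"channel column {col!r} lacks a declared unit (expected name[unit])",
                line=1,
            )
        values = df[col].to_numpy(dtype=float)
        t = times
        if step is not None and not np.all(np.abs(np.diff(times) - step) <= 1e-6):
            n = int(round((times[-1] - times[0]) / step))
            t = times[0] + np.arange(n + 1) * step
            good = np.isfinite(values)
            values = np.interp(t, times[good], values[good])
        trajectories[m["name"].strip()] = Trajectory(
            times=t, values=values, channel=Channel(m["name"].strip(), m["unit"].strip())
        )
    rate = 1.0 / step if step else 0.0
    return TrajectorySet(trajectories=trajectories, rate=rate)


# --- TextGrid ---------------------------------------------------------------

def write_textgrid(path, tiers: dict[str, list[Interval]], xmin: float | None = None,
                   xmax: float | None = None) -> None:
    """Write interval tiers as a long-format Praat TextGrid."""
    all_ints = [i for ints in tiers.values() for i in ints]
    if not all_ints:
        raise InvalidInputError("no intervals to write")
    if xmin is None:
        xmin = min(i.start for i in all_ints)
    if xmax is None:
        xmax = max(i.end for i in all_ints)
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {xmin:.12g}",
        f"xmax = {xmax:.12g}",
        "tiers? <exists>",
        f"size = {len(tiers)}",
        "item []:",
    ]
    for ti, (name, intervals) in enumerate(tiers.items(), start=1):
        # fill gaps so every tier tiles [xmin, xmax], as Praat requires
        filled: list[Interval] = []
        pos = xmin
        for iv in sorted(intervals, key=lambda i: i.start):
            if iv.start > pos + 1e-12:
                filled.append(Interval("", pos, iv.start))
            filled.append(iv)
            pos = iv.end
        if pos < xmax - 1e-12:
            filled.append(Interval("", pos, xmax))
        lines += [
            f"    item [{ti}]:",
            '        class = "IntervalTier"',
            f'        name = "{name}"',
            f"        xmin = {xmin:.12g}",
            f"        xmax = {xmax:.12g}",
            f"        intervals: size = {len(filled)}",
        ]
        for ii, iv in enumerate(filled, start=1):
            lines += [
                f"        intervals [{ii}]:",
                f"            xmin = {iv.start:.12g}",
                f"            xmax = {iv.end:.12g}",
                f'            text = "{iv.label}"',
            ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_textgrid(path) -> dict[str, list[Interval]]:
    """Read a Praat TextGrid (long or short format) into interval tiers."""
    text = Path(path).read_text(encoding="utf-8")
    if "ooTextFile" not in text.split("\n", 1)[0] and "ooTextFile" not in text:
        raise ParseError(f"{path}: not a Praat TextGrid", line=1)
    if re.search(r"item\s*\[", text):
        return _read_textgrid_long(text)
    return _read_textgrid_short(text)


def _read_textgrid_long(text: str) -> dict[str, list[Interval]]:
    tiers: dict[str, list[Interval]] = {}
    current: str | None = None
    cur_class = ""
    pending: dict[str, float | str] = {}
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        m = re.match(r'class\s*=\s*"(.*)"', line)
        if m:
            cur_class = m.group(1)
            continue
        m = re.match(r'name\s*=\s*"(.*)"', line)
        if m and cur_class:
            if cur_class != "IntervalTier":
                current = None
                continue
            current = m.group(1)
            tiers[current] = []
            continue
        if current is None:
            continue
        m = re.match(r"intervals\s*\[\d+\]", line)
        if m:
            pending = {}
            continue
        m = re.match(r"xmin\s*=\s*([-\d.eE+]+)", line)
        if m and "xmin" not in pending:
            pending["xmin"] = float(m.group(1))
            continue
        m = re.match(r"xmax\s*=\s*([-\d.eE+]+)", line)
        if m and "xmin" in pending and "xmax" not in pending:
            pending["xmax"] = float(m.group(1))
            continue
        m = re.match(r'text\s*=\s*"(.*)"', line)
        if m and "xmax" in pending:
            tiers[current].append(
                Interval(m.group(1), float(pending["xmin"]), float(pending["xmax"]))
            )
            pending = {}
    if not tiers:
        raise ParseError("no interval tiers found")
    return tiers


def _read_textgrid_short(text: str) -> dict[str, list[Interval]]:
    # short format: bare values in a fixed order
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    try:
        idx = lines.index("<exists>")
    except ValueError:
        raise ParseError("short TextGrid missing '<exists>' marker") from None
    pos = idx + 1
    n_tiers = int(lines[pos]); pos += 1
    tiers: dict[str, list[Interval]] = {}
    for _ in range(n_tiers):
        tier_class = lines[pos].strip('"'); pos += 1
        name = lines[pos].strip('"'); pos += 1
        pos += 2  # tier xmin, xmax
        n_int = int(lines[pos]); pos += 1
        intervals = []
        for _ in range(n_int):
            xmin = float(lines[pos]); xmax = float(lines[pos + 1])
            label = lines[pos + 2].strip('"')
            pos += 3
            intervals.append(Interval(label, xmin, xmax))
        if tier_class == "IntervalTier":
            tiers[name] = intervals
    if not tiers:
        raise ParseError("no interval tiers found")
    return tiers


# --- Manifests and score configs --------------------------------------------

def _load_structured(path) -> dict:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() == ".json":
            return json.loads(text)
        return yaml.safe_load(text)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc


def read_manifest(path) -> dict[str, list[Path]]:
    """Read a manifest mapping condition labels to trajectory-table files.

    Schema: ``{"conditions": {label: [file, ...], ...}}``; paths are resolved
    relative to the manifest.
    """
    path = Path(path)
    doc = _load_structured(path)
    if not isinstance(doc, dict) or "conditions" not in doc:
        raise ParseError(f"{path}: manifest needs a 'conditions' mapping")
    out: dict[str, list[Path]] = {}
    for label, files in doc["conditions"].items():
        resolved = []
        for f in files:
            p = (path.parent / f).resolve()
            if not p.exists():
                raise ParseError(f"{path}: missing file {f!r} for condition {label!r}")
            resolved.append(p)
        out[str(label)] = resolved
    return out


def read_score_config(path) -> tuple[list[SyllableSpec], DimensionInventory]:
    """Read a syllable-score configuration (YAML or JSON).

    Schema::

        dimensions:
          - {name: f0, unit: st, tier: T}
          - {name: lip-aperture, unit: arb, tier: C}
        syllables:
          - label: ma
            duration: 0.2
            onset:
              - {label: m, role: onset-C,
                 targets: {lip-aperture: {slope: 0, height: -5, strength: 40}},
                 constrained: [lip-aperture]}
            nucleus: [...]
            tone: {label: H, role: tone-T, targets: {f0: {...}}}
    """
    doc = _load_structured(path)
    if not isinstance(doc, dict) or "dimensions" not in doc or "syllables" not in doc:
        raise ParseError(f"{path}: config needs 'dimensions' and 'syllables'")

    inventory = DimensionInventory(
        Dimension(d["name"], d.get("unit", ""), d.get("tier", "V"))
        for d in doc["dimensions"]
    )

    def gesture(node: dict, default_role: str) -> GestureSpec:
        targets = {
            dim: TargetParams(
                float(t.get("slope", 0.0)), float(t["height"]), float(t["strength"])
            )
            for dim, t in node["targets"].items()
        }
        constrained = node.get("constrained")
        return GestureSpec(
            role=node.get("role", default_role),
            targets=targets,
            constrained=frozenset(constrained) if constrained is not None else None,
            label=node.get("label", ""),
        )

    syllables = []
    for node in doc["syllables"]:
        syllables.append(
            SyllableSpec(
                onset=tuple(gesture(g, "onset-C") for g in node.get("onset", [])),
                nucleus=tuple(gesture(g, "nucleus-V") for g in node.get("nucleus", [])),
                coda=gesture(node["coda"], "coda-C") if node.get("coda") else None,
                tone=gesture(node["tone"], "tone-T") if node.get("tone") else None,
                phonation=gesture(node["phonation"], "phonation-Ph")
                if node.get("phonation")
                else None,
                duration=float(node.get("duration", 0.2)),
                fractions=dict(node.get("fractions", DEFAULT_FRACTIONS)),
                label=node.get("label", ""),
            )
        )
    return syllables, inventory
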