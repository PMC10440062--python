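"""Reading and writing TPS-dialect landmark files.

The dialect is the one produced by the tpsDig/tpsUtil family: records
begin with ``LM=<k>`` followed by k whitespace-separated coordinate
pairs, then optional ``IMAGE=``, ``ID=``, ``SCALE=`` and ``COMMENT=``
lines. Keys are matched case-insensitively on read; unknown keys are
ignored with a warning (files in the wild vary). Writing is strict:
LM, coordinates at six decimals, IMAGE, ID and (when present) SCALE.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .base import FACTOR_COLUMNS, LandmarkConfiguration, LandmarkScheme, ShapeDataset

logger = logging.getLogger(__name__)

_KEY_RE = re.compile(r"^\s*([A-Za-z]+)\s*=\s*(.*?)\s*$")
_KNOWN_KEYS = {"LM", "IMAGE", "ID", "SCALE", "COMMENT"}


class TPSParseError(ValueError):
    """Malformed TPS file content."""


def read_tps(
    path,
    flip_y: bool = False,
    image_heights: Mapping[str, float] | None = None,
    operator: str = "",
    group: str = "",
) -> list:
    """Parse a TPS file into a list of :class:`LandmarkConfiguration`.

    ``SCALE=`` factors are applied multiplicatively so returned
    coordinates are in physical units when a scale is present. With
    ``flip_y`` the y axis is inverted per record using
    ``image_heights[image_ref]`` (pixel flip happens before scaling).
    Trials are numbered by occurrence: the m-th record sharing an ID
    within one file becomes trial m.

    ``operator``/``group`` pre-fill those factor fields for every record
    (the TPS dialect itself carries neither).
    """
    path = Path(path)
    if flip_y and image_heights is None:
        raise ValueError("flip_y=True requires image_heights")
    lines = path.read_text().splitlines()

    configs: list[LandmarkConfiguration] = []
    seen_ids: dict[str, int] = {}
    i = 0
    n_lines = len(lines)
    record_index = 0
    while i < n_lines:
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        m = _KEY_RE.match(line)
        if not m or m.group(1).upper() != "LM":
            raise TPSParseError(f"{path.name}:{i + 1}: expected LM= record header, got {line!r}")
        try:
            k = int(m.group(2))
        except ValueError:
            raise TPSParseError(f"{path.name}:{i + 1}: non-integer LM count {m.group(2)!r}") from None
        record_index += 1
        i += 1
        pts = np.empty((k, 2), dtype=float)
        for j in range(k):
            while i < n_lines and not lines[i].strip():
                i += 1
            if i >= n_lines or _KEY_RE.match(lines[i]) and not _is_pair(lines[i]):
                raise TPSParseError(
                    f"{path.name}: record {record_index}: LM={k} but only "
                    f"{j} coordinate line(s) follow"
                )
            parts = lines[i].split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"{path.name}:{i + 1}: expected an x y coordinate pair, got {lines[i]!r}"
                )
            try:
                pts[j, 0] = float(parts[0])
                pts[j, 1] = float(parts[1])
            except ValueError:
                raise TPSParseError(
                    f"{path.name}:{i + 1}: non-numeric coordinate in {lines[i]!r}"
                ) from None
            i += 1
        meta = {"IMAGE": "", "ID": "", "SCALE": None}
        while i < n_lines:
            stripped = lines[i].strip()
            if not stripped:
                i += 1
                continue
            km = _KEY_RE.match(lines[i])
            if km is None or _is_pair(lines[i]):
                raise TPSParseError(f"{path.name}:{i + 1}: unexpected line {lines[i]!r}")
            key = km.group(1).upper()
            if key == "LM":
                break
            if key == "SCALE":
                try:
                    meta["SCALE"] = float(km.group(2))
                except ValueError:
                    raise TPSParseError(
                        f"{path.name}:{i + 1}: non-numeric SCALE {km.group(2)!r}"
                    ) from None
            elif key in ("IMAGE", "ID"):
                meta[key] = km.group(2)
            elif key == "COMMENT":
                pass
            else:
                logger.warning("%s:%d: ignoring unknown TPS key %s=", path.name, i + 1, key)
            i += 1

        if flip_y:
            img = meta["IMAGE"]
            if img not in image_heights:
                raise ValueError(
                    f"flip_y: no image height for record {record_index} (IMAGE={img!r})"
                )
            pts[:, 1] = image_heights[img] - pts[:, 1]
        if meta["SCALE"] is not None:
            pts = pts * meta["SCALE"]
        specimen = meta["ID"] or f"record_{record_index}"
        seen_ids[specimen] = seen_ids.get(specimen, 0) + 1
        configs.append(
            LandmarkConfiguration(
                points=pts,
                specimen_id=specimen,
                image_ref=meta["IMAGE"],
                scale=meta["SCALE"],
                operator=operator,
                group=group,
                trial=seen_ids[specimen],
            )
        )
    return configs


def _is_pair(line: str) -> bool:
    parts = line.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0]), float(parts[1])
    except ValueError:
        return False
    return True


def write_tps(configs: Sequence[LandmarkConfiguration], path) -> None:
    """Write configurations in TPS dialect, one record per configuration.

    Coordinates are emitted at six decimals. When a configuration
    carries a scale factor, pixel-frame coordinates (``points / scale``)
    are written together with a ``SCALE=`` line so that reading the file
    back reproduces the stored physical coordinates.
    """
    ks = {c.k for c in configs}
    if len(ks) > 1:
        offenders = sorted({c.specimen_id for c in configs if c.k != min(ks)})
        raise ValueError(f"heterogeneous landmark counts; offending specimen_ids: {offenders}")
    out = []
    for c in configs:
        out.append(f"LM={c.k}")
        pts = c.points if c.scale is None else c.points / c.scale
        for x, y in pts:
            out.append(f"{x:.6f} {y:.6f}")
        out.append(f"IMAGE={c.image_ref}")
        out.append(f"ID={c.specimen_id}")
        if c.scale is not None:
            out.append(f"SCALE={c.scale:.6f}")
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


def assemble_dataset(configs: Sequence[LandmarkConfiguration], scheme: LandmarkScheme) -> ShapeDataset:
    """Stack configurations into a :class:`ShapeDataset` in input order."""
    for c in configs:
        if c.k != scheme.n_landmarks:
            raise ValueError(
                f"configuration {c.specimen_id!r} has {c.k} landmarks, scheme expects "
                f"{scheme.n_landmarks}"
            )
    coords = np.stack([c.points for c in configs]) if configs else np.empty((0, scheme.n_landmarks, 2))
    factors = pd.DataFrame(
        {
            "specimen_id": [c.specimen_id for c in configs],
            "group": [c.group for c in configs],
            "operator": [c.operator for c in configs],
            "trial": [c.trial for c in configs],
        }
    )
    return ShapeDataset(coords, factors, scheme)


# ----------------------------------------------------------------------
# factor table and scheme files

def read_factors(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"specimen_id": str, "group": str, "operator": str})
    missing = [c for c in FACTOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"factor CSV {path} missing columns {missing}")
    df["trial"] = df["trial"].astype(int)
    return df


def write_factors(factors: pd.DataFrame, path) -> None:
    factors.loc[:, list(FACTOR_COLUMNS)].to_csv(path, index=False)


def read_scheme(path) -> LandmarkScheme:
    with open(path) as fh:
        return LandmarkScheme.from_dict(yaml.safe_load(fh))


def write_scheme(scheme: LandmarkScheme, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scheme.to_dict(), fh, sort_keys=False)


def attach_factors(
    configs: Iterable[LandmarkConfiguration], factors: pd.DataFrame
) -> list:
    """Fill group labels on configurations by specimen_id lookup."""
    by_id = factors.drop_duplicates("specimen_id").set_index("specimen_id")["group"]
    out = []
    for c in configs:
        if c.specimen_id not in by_id.index:
            raise KeyError(f"specimen {c.specimen_id!r} absent from factor table")
        c.group = str(by_id[c.specimen_id])
        out.append(c)
    return out
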