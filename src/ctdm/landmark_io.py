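"""Reading, validating and writing 2D landmark datasets.

Supports the TPS exchange format written by the tpsDig family of
digitizing tools (``LM=`` record headers with optional ``ID=``,
``IMAGE=``, ``SCALE=`` and ``COMMENT=`` keys), a spreadsheet-friendly
wide CSV layout, and YAML/JSON landmark schemas describing
semilandmark curves and the bilateral pair map used for
symmetrization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, TPSParseError, ValidationError

__all__ = [
    "LandmarkConfiguration",
    "LandmarkSchema",
    "ShapeSample",
    "ValidationFinding",
    "ValidationReport",
    "read_tps",
    "write_tps",
    "read_csv_wide",
    "write_csv_wide",
    "read_schema",
    "write_schema",
    "validate_sample",
]


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2D landmark coordinates plus identity metadata."""

    specimen_id: str
    coords: np.ndarray  # (k, 2) float array
    group: str | None = None
    sex: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"coords must be a (k, 2) array, got shape {self.coords.shape}"
            )

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    def copy_with(self, coords: np.ndarray) -> "LandmarkConfiguration":
        return LandmarkConfiguration(
            specimen_id=self.specimen_id,
            coords=np.asarray(coords, dtype=float),
            group=self.group,
            sex=self.sex,
            extras=dict(self.extras),
        )


@dataclass(frozen=True)
class LandmarkSchema:
    """Landmark template: semilandmark curves and the bilateral pair map.

    Parameters
    ----------
    n_landmarks:
        Total number of landmarks per configuration.
    curves:
        Ordered index lists. Each curve runs anchor, interior
        semilandmarks, anchor; only the interior points slide.
    pairs:
        Left/right homologous index pairs used by symmetrization.
    midline:
        Indices of unpaired (midsagittal) landmarks.
    """

    n_landmarks: int
    curves: tuple[tuple[int, ...], ...] = ()
    pairs: tuple[tuple[int, int], ...] = ()
    midline: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_landmarks < 1:
            raise SchemaError("n_landmarks must be positive")
        object.__setattr__(
            self, "curves", tuple(tuple(int(i) for i in c) for c in self.curves)
        )
        object.__setattr__(
            self, "pairs", tuple((int(a), int(b)) for a, b in self.pairs)
        )
        object.__setattr__(self, "midline", tuple(int(i) for i in self.midline))
        all_idx = [i for c in self.curves for i in c]
        all_idx += [i for p in self.pairs for i in p]
        all_idx += list(self.midline)
        for i in all_idx:
            if not 0 <= i < self.n_landmarks:
                raise SchemaError(f"index {i} out of range [0, {self.n_landmarks})")
        for c in self.curves:
            if len(c) < 3:
                raise SchemaError("each curve needs two anchors and >=1 interior point")
        interiors = [i for c in self.curves for i in c[1:-1]]
        if len(interiors) != len(set(interiors)):
            raise SchemaError("a semilandmark belongs to more than one curve interior")
        paired = [i for p in self.pairs for i in p]
        if len(paired) != len(set(paired)):
            raise SchemaError("pair map assigns a landmark to more than one pair")
        if set(paired) & set(self.midline):
            raise SchemaError("midline landmarks cannot also be paired")

    @property
    def semilandmarks(self) -> frozenset[int]:
        """Interior (sliding) points of all curves."""
        return frozenset(i for c in self.curves for i in c[1:-1])

    @property
    def supports_symmetrization(self) -> bool:
        """True when pairs plus midline cover every landmark."""
        covered = {i for p in self.pairs for i in p} | set(self.midline)
        return covered == set(range(self.n_landmarks))

    def to_dict(self) -> dict:
        return {
            "n_landmarks": self.n_landmarks,
            "curves": [list(c) for c in self.curves],
            "pairs": [list(p) for p in self.pairs],
            "midline": list(self.midline),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LandmarkSchema":
        return cls(
            n_landmarks=int(d["n_landmarks"]),
            curves=tuple(tuple(c) for c in d.get("curves", ())),
            pairs=tuple(tuple(p) for p in d.get("pairs", ())),
            midline=tuple(d.get("midline", ())),
        )


@dataclass
class ShapeSample:
    """A homogeneous collection of landmark configurations."""

    configurations: list[LandmarkConfiguration]
    schema: LandmarkSchema | None = None
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    def __getitem__(self, i):
        return self.configurations[i]

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    @property
    def groups(self) -> np.ndarray:
        return np.array([c.group for c in self.configurations], dtype=object)

    def coords_array(self) -> np.ndarray:
        """Stack coordinates into an (n, k, 2) array."""
        ks = {c.n_landmarks for c in self.configurations}
        if len(ks) > 1:
            raise ValidationError(f"heterogeneous landmark counts: {sorted(ks)}")
        return np.stack([c.coords for c in self.configurations])


# ---------------------------------------------------------------------------
# TPS format
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {"LM", "IMAGE", "ID", "SCALE", "COMMENT"}


def read_tps(path: str | Path, schema: LandmarkSchema | None = None) -> ShapeSample:
    """Read a tpsDig-style TPS file.

    Each record starts with ``LM=<k>`` followed by k whitespace-separated
    coordinate lines; trailing ``IMAGE=``, ``ID=``, ``SCALE=`` and
    ``COMMENT=`` keys are captured. ``SCALE=`` multiplies the stored
    coordinates. Unknown keys are preserved in ``extras``. Coordinates
    are taken exactly as written (no axis flip).
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines()]
    configs: list[LandmarkConfiguration] = []
    i = 0
    record_index = 0
    while i < len(lines):
        line = lines[i]
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSParseError(
                f"record {record_index}: expected LM= header, got {line!r}"
            )
        try:
            n_lm = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"record {record_index}: bad LM count {line!r}") from exc
        i += 1
        pts = []
        while i < len(lines) and len(pts) < n_lm:
            row = lines[i]
            if not row:
                i += 1
                continue
            if "=" in row and not _looks_numeric(row):
                break  # ran into the next key before enough coordinates
            parts = row.split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"record {record_index}: coordinate line {row!r} is not 'x y'"
                )
            try:
                pts.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TPSParseError(
                    f"record {record_index}: non-numeric coordinate {row!r}"
                ) from exc
            i += 1
        if len(pts) != n_lm:
            raise TPSParseError(
                f"record {record_index}: LM={n_lm} but found {len(pts)} coordinate lines"
            )
        extras: dict = {}
        specimen_id: str | None = None
        scale: float | None = None
        while i < len(lines):
            row = lines[i]
            if not row:
                i += 1
                continue
            if row.upper().startswith("LM="):
                break
            if "=" not in row:
                raise TPSParseError(
                    f"record {record_index}: unexpected line {row!r} after coordinates"
                )
            key, value = row.split("=", 1)
            key_u = key.strip().upper()
            value = value.strip()
            if key_u == "ID":
                specimen_id = value
            elif key_u == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise TPSParseError(
                        f"record {record_index}: non-numeric SCALE {value!r}"
                    ) from exc
                extras["scale"] = scale
            elif key_u == "IMAGE":
                extras["image"] = value
            elif key_u == "COMMENT":
                extras["comment"] = value
            else:
                extras[key.strip().lower()] = value
            i += 1
        coords = np.asarray(pts, dtype=float)
        if scale is not None:
            coords = coords * scale
        if specimen_id is None:
            specimen_id = f"specimen_{record_index}"
        configs.append(
            LandmarkConfiguration(specimen_id=specimen_id, coords=coords, extras=extras)
        )
        record_index += 1
    return ShapeSample(configurations=configs, schema=schema, provenance=str(path))


def _looks_numeric(row: str) -> bool:
    parts = row.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0])
        float(parts[1])
    except ValueError:
        return False
    return True


def write_tps(sample: ShapeSample, path: str | Path) -> None:
    """Write a sample as a TPS file; round-trips coordinates and ids exactly.

    Coordinates are written at full precision and SCALE is not re-applied
    (coordinates are stored already scaled).
    """
    if len(sample) == 0:
        raise ValueError("cannot write an empty sample")
    path = Path(path)
    out = []
    for c in sample:
        out.append(f"LM={c.n_landmarks}")
        for x, y in c.coords:
            out.append(f"{float(x)!r} {float(y)!r}")
        if "image" in c.extras:
            out.append(f"IMAGE={c.extras['image']}")
        out.append(f"ID={c.specimen_id}")
        if "comment" in c.extras:
            out.append(f"COMMENT={c.extras['comment']}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Wide CSV format
# ---------------------------------------------------------------------------

def read_csv_wide(path: str | Path, schema: LandmarkSchema | None = None) -> ShapeSample:
    """Read the wide CSV layout ``specimen_id,group,sex,x1,y1,...,xk,yk``."""
    df = pd.read_csv(path)
    coord_cols = [c for c in df.columns if c[0] in "xy" and c[1:].isdigit()]
    k = len(coord_cols) // 2
    configs = []
    for _, row in df.iterrows():
        coords = np.column_stack(
            [
                [row[f"x{i}"] for i in range(1, k + 1)],
                [row[f"y{i}"] for i in range(1, k + 1)],
            ]
        )
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(row["specimen_id"]),
                coords=coords,
                group=str(row["group"]) if "group" in df.columns else None,
                sex=str(row["sex"]) if "sex" in df.columns else None,
            )
        )
    return ShapeSample(configurations=configs, schema=schema, provenance=str(path))


def write_csv_wide(sample: ShapeSample, path: str | Path) -> None:
    if len(sample) == 0:
        raise ValueError("cannot write an empty sample")
    k = sample[0].n_landmarks
    rows = []
    for c in sample:
        row: dict = {"specimen_id": c.specimen_id, "group": c.group, "sex": c.sex}
        for i in range(k):
            row[f"x{i+1}"] = c.coords[i, 0]
            row[f"y{i+1}"] = c.coords[i, 1]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Schema files
# ---------------------------------------------------------------------------

def read_schema(path: str | Path) -> LandmarkSchema:
    """Read a landmark schema from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return LandmarkSchema.from_dict(data)


def write_schema(schema: LandmarkSchema, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(schema.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(schema.to_dict()))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationFinding:
    specimen_id: str
    kind: str  # "count_mismatch" | "non_finite" | "duplicate_id"
    detail: str


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def __bool__(self) -> bool:  # truthy iff clean, mirroring "analysis-ready"
        return self.ok

    def __str__(self) -> str:
        if self.ok:
            return "sample is analysis-ready"
        return "\n".join(f"{f.specimen_id}: {f.kind} ({f.detail})" for f in self.findings)


def validate_sample(sample: ShapeSample, schema: LandmarkSchema | None = None) -> ValidationReport:
    """Check a sample for landmark-count mismatches, non-finite coordinates
    and duplicated specimen ids. Empty report iff the sample is analysis-ready."""
    schema = schema or sample.schema
    report = ValidationReport()
    seen: set[str] = set()
    for c in sample:
        if schema is not None and c.n_landmarks != schema.n_landmarks:
            report.findings.append(
                ValidationFinding(
                    c.specimen_id,
                    "count_mismatch",
                    f"{c.n_landmarks} landmarks, schema expects {schema.n_landmarks}",
                )
            )
        if not np.all(np.isfinite(c.coords)):
            bad = np.argwhere(~np.isfinite(c.coords))
            report.findings.append(
                ValidationFinding(
                    c.specimen_id, "non_finite", f"landmark rows {sorted(set(bad[:, 0]))}"
                )
            )
        if c.specimen_id in seen:
            report.findings.append(
                ValidationFinding(c.specimen_id, "duplicate_id", "specimen_id repeated")
            )
        seen.add(c.specimen_id)
    return report
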