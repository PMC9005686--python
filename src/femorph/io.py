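"""Readers and writers for landmark files, meshes, and the packaged metadata.

Native landmark format: one CSV per specimen with columns
``index,role,x,y,z`` (UTF-8, comma-separated, millimetres). The classic
TPS-file dialect (``LM3=k`` blocks followed by ``k`` whitespace-separated
coordinate lines, optional ``ID=``/``IMAGE=`` keys) is also read and written
for interoperability with legacy digitizing software.

Metadata: the packaged transcriptions of the study's specimen table (72
femora from 36 archosauriform species, locomotor codes B/Q with C for
indeterminate, mapped to I here) and of its input-vs-predicted locomotor-mode
table ship under ``femorph/data`` and load through
:func:`load_packaged_table1` / :func:`load_packaged_table2`.
"""

from __future__ import annotations

import csv
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .landmarks import LandmarkConfiguration, LandmarkScheme, SpecimenRecord, TriangleMesh

log = logging.getLogger(__name__)

_MODE_MAP = {"B": "B", "Q": "Q", "C": "I", "I": "I"}


# ---------------------------------------------------------------------------
# landmark files
# ---------------------------------------------------------------------------

def write_landmarks(config: LandmarkConfiguration, path: str | Path) -> None:
    """Write the native per-specimen CSV (index, role, x, y, z)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "role", "x", "y", "z"])
        for i, (role, xyz) in enumerate(zip(config.scheme.roles, config.coords)):
            writer.writerow([i, role] + [f"{float(v):.17g}" for v in xyz])


def write_tps(config: LandmarkConfiguration, path: str | Path) -> None:
    """Write a classic TPS-format file with a single LM3 block."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"LM3={config.k}\n")
        for xyz in config.coords:
            fh.write(" ".join(f"{float(v):.17g}" for v in xyz) + "\n")
        fh.write(f"ID={config.specimen_id}\n")


def read_landmarks(
    path: str | Path,
    scheme: LandmarkScheme | None = None,
    fmt: str = "tabular",
    specimen_id: str | None = None,
) -> LandmarkConfiguration:
    """Read one specimen's landmark configuration.

    Parameters
    ----------
    path:
        File to read.
    scheme:
        Expected scheme. Required for ``tabular`` only when the file's roles
        should be cross-checked; if omitted, a scheme is reconstructed from
        the file's role column (``tabular``) or all landmarks are treated as
        anatomical (``tps-classic``).
    fmt:
        ``"tabular"`` (native CSV) or ``"tps-classic"``.
    """
    path = Path(path)
    if fmt == "tabular":
        rows = list(csv.reader(path.open()))
        if not rows or [c.lower() for c in rows[0][:5]] != ["index", "role", "x", "y", "z"]:
            raise ValueError(f"{path}: missing native landmark header")
        body = [r for r in rows[1:] if r]
        idx = [int(r[0]) for r in body]
        if sorted(idx) != list(range(len(body))):
            raise ValueError(f"{path}: landmark indices must be 0..k-1 without duplicates")
        order = np.argsort(idx)
        roles = tuple(body[i][1] for i in order)
        try:
            coords = np.array([[float(body[i][2]), float(body[i][3]), float(body[i][4])]
                               for i in order])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric coordinate ({exc})") from None
        if scheme is None:
            scheme = LandmarkScheme(n_total=len(roles), roles=roles, name=path.stem)
        elif scheme.n_total != len(body):
            raise ValueError(
                f"{path}: {len(body)} landmarks but scheme {scheme.name!r} "
                f"expects {scheme.n_total}"
            )
    elif fmt == "tps-classic":
        coords_list: list[list[float]] = []
        expect = None
        sid = None
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3="):
                expect = int(line.split("=", 1)[1])
            elif upper.startswith("ID="):
                sid = line.split("=", 1)[1]
            elif upper.startswith(("IMAGE=", "SCALE=", "LM=")):
                continue
            else:
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(f"{path}: expected 3 coordinates per line, got {line!r}")
                try:
                    coords_list.append([float(p) for p in parts])
                except ValueError:
                    raise ValueError(f"{path}: non-numeric coordinate in {line!r}") from None
        if expect is None:
            raise ValueError(f"{path}: no LM3= block found")
        if len(coords_list) != expect:
            raise ValueError(f"{path}: LM3={expect} but {len(coords_list)} coordinate lines")
        coords = np.array(coords_list)
        if scheme is None:
            scheme = LandmarkScheme(n_total=expect, roles=("anatomical",) * expect,
                                    name=path.stem)
        elif scheme.n_total != expect:
            raise ValueError(f"{path}: LM3={expect} does not match scheme "
                             f"{scheme.name!r} ({scheme.n_total})")
        if sid and specimen_id is None:
            specimen_id = sid
    else:
        raise ValueError(f"unknown landmark format {fmt!r}")

    log.info("read %d landmarks from %s", len(coords), path)
    return LandmarkConfiguration(specimen_id=specimen_id or path.stem,
                                 coords=coords, scheme=scheme)


def mirror_configuration(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Reflect a configuration across the x=0 plane (left/right mirroring).

    Negating a single axis is sufficient preparation for superimposition
    because GPA removes position and orientation; the mirrored flag and side
    are toggled so provenance is never lost.
    """
    out = config.copy()
    out.coords = config.coords.copy()
    out.coords[:, 0] *= -1.0
    out.mirrored = not config.mirrored
    out.side = {"left": "right", "right": "left"}[config.side]
    return out


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def read_mesh(path: str | Path) -> TriangleMesh:
    """Load a PLY/OBJ/STL triangle mesh (units assumed mm).

    Degenerate (zero-area) faces are dropped with a logged count; a mesh with
    no usable faces is an error.
    """
    import trimesh

    path = Path(path)
    mesh = trimesh.load_mesh(str(path), process=False)
    faces = np.asarray(mesh.faces, dtype=int)
    verts = np.asarray(mesh.vertices, dtype=float)
    if faces.size == 0 or verts.size == 0:
        raise ValueError(f"{path}: empty mesh")
    areas = _triangle_areas(verts, faces)
    keep = areas > 0
    dropped = int((~keep).sum())
    if dropped:
        log.warning("%s: dropped %d zero-area faces", path, dropped)
        faces = faces[keep]
        if len(faces) == 0:
            raise ValueError(f"{path}: all faces degenerate")
    log.info("read mesh %s: %d vertices, %d faces", path, len(verts), len(faces))
    return TriangleMesh(vertices=verts, faces=faces)


def write_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    mesh.to_trimesh().export(str(path))


def _triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a, b, c = (vertices[faces[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


# ---------------------------------------------------------------------------
# metadata tables
# ---------------------------------------------------------------------------

def _clade_of(higher_order: str) -> str:
    ho = higher_order.lower()
    if ho.startswith("pseudosuchia"):
        return "pseudosuchian"
    if ho.startswith("avemetatarsalia"):
        return "avemetatarsalian"
    return "non-archosaurian"


def read_specimen_table(path: str | Path) -> list[SpecimenRecord]:
    """Parse a femoral specimen table into one record per femur.

    Rows listing two femora of the same individual (sides ``"L, R"`` with two
    lengths) are split into ``_L``/``_R`` records, since the whole pipeline is
    per-femur. Locomotor code ``C`` (indeterminate) maps to ``I``.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"species", "locomotor_mode", "sides", "femoral_length_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records: list[SpecimenRecord] = []
    for _, row in df.iterrows():
        mode = str(row["locomotor_mode"]).strip()
        if mode not in _MODE_MAP:
            raise ValueError(f"{path}: unknown locomotor mode code {mode!r} "
                             f"for {row['species']}")
        sides = [s.strip() for s in str(row["sides"]).split(",")]
        lengths = [float(v) for v in str(row["femoral_length_mm"]).split(",")]
        if len(sides) != len(lengths):
            raise ValueError(f"{path}: side/length count mismatch for {row['species']}")
        base_id = f"{row.get('abbreviation', row['species'])}_" \
                  f"{str(row.get('number', '')).replace(' ', '')}"
        for side_code, fl in zip(sides, lengths):
            side = {"L": "left", "R": "right"}[side_code]
            sid = base_id if len(sides) == 1 else f"{base_id}_{side_code}"
            records.append(SpecimenRecord(
                specimen_id=sid,
                species=str(row["species"]),
                clade=_clade_of(str(row.get("higher_order", ""))),
                input_mode=_MODE_MAP[mode],
                femoral_length=fl,
                side=side,
                juvenile=str(row.get("juvenile", "0")).strip() in ("1", "true", "True"),
                digitization=str(row.get("digitization", "")),
            ))
    log.info("read %d femur records from %s", len(records), path)
    return records


def read_mode_table(path: str | Path) -> pd.DataFrame:
    """Read an input-vs-predicted locomotor mode table (name, input, predicted)."""
    df = pd.read_csv(path, dtype=str)
    need = {"name", "input_mode", "predicted_mode"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    bad = set(df["input_mode"]) - {"B", "Q", "I"}
    if bad:
        raise ValueError(f"{path}: unknown input mode codes {sorted(bad)}")
    return df


def _data_path(name: str):
    return resources.files("femorph.data").joinpath(name)


def load_packaged_table1() -> list[SpecimenRecord]:
    """The packaged 72-femur specimen-table transcription."""
    with resources.as_file(_data_path("table1_specimens.csv")) as p:
        return read_specimen_table(p)


def load_packaged_table2() -> pd.DataFrame:
    """The packaged input-vs-predicted locomotor-mode transcription (72 rows)."""
    with resources.as_file(_data_path("table2_knn.csv")) as p:
        return read_mode_table(p)
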