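"""Readers and writers for the surface formats the pipeline touches.

Supported formats
-----------------
* FreeSurfer binary triangle surface (magic ``0xFFFFFE``) — via nibabel.
* FreeSurfer new-format curv/morph file (magic ``0xFFFFFF``) — via nibabel.
* FreeSurfer ASCII surface (``#!ascii`` header) and ASCII label files.
* Plain-text dialects: one-value-per-line morph maps, 0-based index lists
  for masks (base declared in a header comment), and a subjects x vertices
  TSV cohort bundle.

Every path is also accepted gzipped (``.gz`` suffix).
"""
from __future__ import annotations

import gzip
import io as _stdio
import os
import shutil
import tempfile
from pathlib import Path

import nibabel.freesurfer.io as fsio
import numpy as np

from .model import (
    CohortThickness,
    DimensionError,
    FormatError,
    InvariantError,
    ParameterError,
    TriangleMesh,
    VertexMask,
    VertexScalarMap,
)

__all__ = [
    "read_surface",
    "write_surface",
    "read_morph",
    "write_morph",
    "read_label",
    "write_label",
    "load_cohort",
    "read_cohort_tsv",
    "write_cohort_tsv",
    "write_lsctp_map",
]

_TRIANGLE_MAGIC = b"\xff\xff\xfe"
_MORPH_MAGIC = b"\xff\xff\xff"


def _is_gzip(path: Path) -> bool:
    return path.suffix == ".gz"


def _peek(path: Path, n: int) -> bytes:
    opener = gzip.open if _is_gzip(path) else open
    with opener(path, "rb") as fh:
        return fh.read(n)


def _materialize(path: Path):
    """Return a real (decompressed) file path plus a cleanup flag.

    nibabel's FreeSurfer readers want an on-disk path, so gzipped inputs are
    decompressed into a temporary file first.
    """
    if not _is_gzip(path):
        return path, False
    suffix = Path(path.stem).suffix or ".bin"
    tmp = tempfile.NamedTemporaryFile(suffix=suffix, delete=False)
    with gzip.open(path, "rb") as src:
        shutil.copyfileobj(src, tmp)
    tmp.close()
    return Path(tmp.name), True


def _text_lines(path: Path) -> list:
    opener = gzip.open if _is_gzip(path) else open
    with opener(path, "rt") as fh:
        return fh.read().splitlines()


def read_surface(path) -> TriangleMesh:
    """Read a triangle surface (FreeSurfer binary or ASCII)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such surface file: {path}")
    head = _peek(path, 8)
    if len(head) < 3:
        raise FormatError(f"surface file too short ({len(head)} bytes): {path}")
    name = path.stem if not _is_gzip(path) else Path(path.stem).stem
    if head[:3] == _TRIANGLE_MAGIC:
        real, cleanup = _materialize(path)
        try:
            coords, faces = fsio.read_geometry(str(real))
        except Exception as exc:  # truncated / corrupt payload
            raise FormatError(f"truncated or corrupt surface file {path}: {exc}") from exc
        finally:
            if cleanup:
                os.unlink(real)
        return TriangleMesh(vertex_coords=coords, faces=faces, name=name)
    if head.startswith(b"#!ascii"):
        return _read_ascii_surface(path, name)
    raise FormatError(
        f"not a FreeSurfer triangle surface (magic 0x{head[:3].hex()} found, "
        f"expected 0x{_TRIANGLE_MAGIC.hex()}): {path}"
    )


def _read_ascii_surface(path: Path, name: str) -> TriangleMesh:
    lines = [ln for ln in _text_lines(path) if ln.strip()]
    try:
        nv, nf = (int(tok) for tok in lines[1].split()[:2])
        body = np.array(
            [ln.split() for ln in lines[2 : 2 + nv + nf]], dtype=np.float64
        )
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed ASCII surface {path}: {exc}") from exc
    if body.shape[0] != nv + nf:
        raise FormatError(
            f"ASCII surface {path} declares {nv}+{nf} rows, found {body.shape[0]}"
        )
    coords = body[:nv, :3]
    faces = body[nv:, :3].astype(np.int64)
    return TriangleMesh(vertex_coords=coords, faces=faces, name=name)


def write_surface(mesh: TriangleMesh, path) -> None:
    """Write a surface as FreeSurfer binary (default) or ASCII (``.asc``)."""
    path = Path(path)
    stem = Path(path.stem) if _is_gzip(path) else path
    if stem.suffix == ".asc":
        lines = ["#!ascii surface written by lsctp", f"{mesh.n_vertices} {mesh.n_faces}"]
        lines += [f"{x:.9f} {y:.9f} {z:.9f} 0" for x, y, z in mesh.vertex_coords]
        lines += [f"{a} {b} {c} 0" for a, b, c in mesh.faces]
        _write_text(path, "\n".join(lines) + "\n")
        return
    if _is_gzip(path):
        tmp = tempfile.NamedTemporaryFile(delete=False)
        tmp.close()
        fsio.write_geometry(tmp.name, mesh.vertex_coords, mesh.faces)
        with open(tmp.name, "rb") as src, gzip.open(path, "wb") as dst:
            shutil.copyfileobj(src, dst)
        os.unlink(tmp.name)
    else:
        fsio.write_geometry(str(path), mesh.vertex_coords, mesh.faces)


def _write_text(path: Path, text: str) -> None:
    opener = gzip.open if _is_gzip(Path(path)) else open
    with opener(path, "wt") as fh:
        fh.write(text)


def read_morph(path) -> VertexScalarMap:
    """Read a per-vertex scalar map (curv/morph binary or one value per line)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such morph file: {path}")
    head = _peek(path, 3)
    subject = path.stem if not _is_gzip(path) else Path(path.stem).stem
    if head == _MORPH_MAGIC:
        real, cleanup = _materialize(path)
        try:
            values = fsio.read_morph_data(str(real))
        except Exception as exc:
            raise FormatError(f"truncated or corrupt morph file {path}: {exc}") from exc
        finally:
            if cleanup:
                os.unlink(real)
        return VertexScalarMap(values=values, subject_id=subject)
    # plain-text fallback: one value per line, '#' comments
    try:
        rows = [
            float(ln.split()[0])
            for ln in _text_lines(path)
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
    except (ValueError, UnicodeDecodeError) as exc:
        raise FormatError(
            f"not a morph file (magic 0x{head.hex()} found, expected "
            f"0x{_MORPH_MAGIC.hex()}) and not parseable as text: {path}"
        ) from exc
    return VertexScalarMap(values=np.array(rows), subject_id=subject)


def write_morph(vmap: VertexScalarMap, path) -> None:
    """Write a scalar map as FreeSurfer morph (default) or text (``.txt``/``.asc``)."""
    path = Path(path)
    stem = Path(path.stem) if _is_gzip(path) else path
    values = np.nan_to_num(vmap.values, nan=0.0) if vmap.allow_nan else vmap.values
    if stem.suffix in {".txt", ".asc", ".tsv"}:
        text = "# one value per vertex, written by lsctp\n"
        text += "\n".join(f"{v:.9g}" for v in values) + "\n"
        _write_text(path, text)
        return
    if _is_gzip(path):
        buf = _stdio.BytesIO()
        fsio.write_morph_data(buf, values)
        with gzip.open(path, "wb") as dst:
            dst.write(buf.getvalue())
    else:
        fsio.write_morph_data(str(path), values)


def read_label(path, n_vertices: int, label: str = "") -> VertexMask:
    """Read a vertex mask from a FreeSurfer ASCII label or a plain index list.

    Plain index lists are 0-based; a ``# index-base: B`` header line may
    declare another base.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such label file: {path}")
    lines = _text_lines(path)
    label = label or (path.stem if not _is_gzip(path) else Path(path.stem).stem)
    base = 0
    data_lines = []
    is_fs = any(ln.lstrip().startswith("#!ascii label") for ln in lines[:1])
    for ln in lines:
        s = ln.strip()
        if not s:
            continue
        if s.startswith("#"):
            if "index-base:" in s:
                base = int(s.split("index-base:")[1].split()[0])
            continue
        data_lines.append(s)
    if is_fs and data_lines:
        # first data line is the declared count; rows are "index x y z value"
        declared = int(data_lines[0].split()[0])
        rows = data_lines[1:]
        if len(rows) != declared:
            raise FormatError(
                f"label {path} declares {declared} vertices, found {len(rows)}"
            )
        indices = np.array([int(r.split()[0]) for r in rows], dtype=np.int64)
    else:
        try:
            indices = np.array([int(s.split()[0]) for s in data_lines], dtype=np.int64)
        except ValueError as exc:
            raise FormatError(f"malformed label file {path}: {exc}") from exc
        indices -= base
    return VertexMask.from_indices(n_vertices, indices, label=label)


def write_label(mask: VertexMask, path, coords=None) -> None:
    """Write a mask as a FreeSurfer ASCII label (or ``.txt`` index list)."""
    path = Path(path)
    stem = Path(path.stem) if _is_gzip(path) else path
    idx = mask.indices
    if stem.suffix == ".txt":
        text = "# index-base: 0\n" + "\n".join(str(i) for i in idx) + "\n"
        _write_text(path, text)
        return
    if coords is None:
        coords = np.zeros((mask.n_vertices, 3))
    lines = [f"#!ascii label, written by lsctp ({mask.label})", str(len(idx))]
    lines += [
        f"{i}  {coords[i, 0]:.3f}  {coords[i, 1]:.3f}  {coords[i, 2]:.3f} 0.000000"
        for i in idx
    ]
    _write_text(path, "\n".join(lines) + "\n")


def load_cohort(paths, mesh: TriangleMesh, subject_ids=None) -> CohortThickness:
    """Load per-subject morph files into a cohort matrix (row order = input order)."""
    paths = [Path(p) for p in paths]
    if len(paths) < 2:
        raise ParameterError(f"a cohort needs at least 2 morph files, got {len(paths)}")
    maps = [read_morph(p) for p in paths]
    if subject_ids is None:
        subject_ids = [m.subject_id for m in maps]
    for p, m in zip(paths, maps):
        if m.n_vertices != mesh.n_vertices:
            raise DimensionError(
                f"{p}: {m.n_vertices} values for a mesh of {mesh.n_vertices} vertices"
            )
    matrix = np.vstack([m.values for m in maps])
    for sid, row in zip(subject_ids, matrix):
        if (row < 0).any():
            v = int(np.flatnonzero(row < 0)[0])
            raise InvariantError(
                f"negative thickness for subject {sid!r} at vertex {v}"
            )
    return CohortThickness(matrix=matrix, subject_ids=list(subject_ids))


def write_cohort_tsv(cohort: CohortThickness, path) -> None:
    """Write a cohort as TSV: header line, then one subject row per line."""
    lines = ["subject_id\t" + "\t".join(f"v{j}" for j in range(cohort.n_vertices))]
    for sid, row in zip(cohort.subject_ids, cohort.matrix):
        lines.append(sid + "\t" + "\t".join(f"{x:.9g}" for x in row))
    _write_text(Path(path), "\n".join(lines) + "\n")


def read_cohort_tsv(path, mesh: TriangleMesh = None) -> CohortThickness:
    """Read a subjects x vertices TSV cohort bundle."""
    lines = [ln for ln in _text_lines(Path(path)) if ln.strip()]
    if not lines or not lines[0].startswith("subject_id"):
        raise FormatError(f"cohort TSV {path} lacks the one-line header")
    ids, rows = [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        ids.append(parts[0])
        rows.append(np.array(parts[1:], dtype=np.float64))
    matrix = np.vstack(rows)
    if mesh is not None and matrix.shape[1] != mesh.n_vertices:
        raise DimensionError(
            f"cohort TSV has {matrix.shape[1]} columns for a mesh of "
            f"{mesh.n_vertices} vertices"
        )
    return CohortThickness(matrix=matrix, subject_ids=ids)


def write_lsctp_map(lmap, path_prefix, coords=None) -> None:
    """Export an LSCTP map as morph + companion label (+ TSV).

    Excluded vertices are written as 0 in the morph file; the inclusion mask
    is saved alongside as ``<prefix>.included.label`` and the full map as
    ``<prefix>.tsv``.
    """
    prefix = Path(path_prefix)
    values = np.where(lmap.included.mask, np.nan_to_num(lmap.mean_r, nan=0.0), 0.0)
    write_morph(VertexScalarMap(values=values), prefix.with_suffix(".mean_r"))
    write_label(lmap.included, str(prefix) + ".included.label", coords=coords)
    lines = ["# LSCTP map: mean Fisher-averaged inter-subject correlation (r scale)",
             f"# diameter_mm: {lmap.diameter}",
             f"# n_subjects: {lmap.n_subjects}",
             f"# n_pairs: {lmap.n_pairs}",
             "vertex\tmean_r\tincluded"]
    for v in range(lmap.mean_r.shape[0]):
        r = lmap.mean_r[v]
        lines.append(f"{v}\t{'' if np.isnan(r) else format(r, '.9g')}\t{int(lmap.included.mask[v])}")
    _write_text(prefix.with_suffix(".tsv"), "\n".join(lines) + "\n")
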